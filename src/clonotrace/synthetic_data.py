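"""Synthetic cohort generator with full ground truth.

Emulates the statistical structure the CH-tracking analysis assumes:

* per-gene clone growth with doubling times in the reported post-CAR range
  (~150-400 days), as logistic-capped exponential expansion of the clone
  cell fraction;
* binomial read sampling at ~2800x de-duplicated depth with a per-base
  background error rate;
* cfDNA / PBL / BM compartment concordance via a multiplicative lognormal
  factor on VAF;
* single-cell genotype matrices with allelic dropout (ADO), lineage-biased
  clone penetrance, and rare CAR-vector-positive T cells with a configurable
  true co-occurrence multiplier inside a designated CH clone.

Every emitted observation is backed by a retained ground-truth record so that
downstream estimators (selection test, doubling time, clone caller,
enrichment ratio) can be validated by parameter recovery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .variant_model import VafObservation, classify_ch_gene

LINEAGES = ("T_CD4", "T_CD8", "NK", "B", "monocyte",
            "other_myeloid", "progenitor", "erythroid")

#: Baseline marrow lineage composition for wildtype cells (post-CAR marrows
#: are B-cell poor and effector-T / myeloid rich).
DEFAULT_LINEAGE_PROBS: Mapping[str, float] = {
    "T_CD4": 0.13, "T_CD8": 0.20, "NK": 0.07, "B": 0.03,
    "monocyte": 0.25, "other_myeloid": 0.15, "progenitor": 0.09,
    "erythroid": 0.08,
}

#: Myeloid-skewed composition for DDR-gene clones.
MYELOID_BIASED_PROBS: Mapping[str, float] = {
    "T_CD4": 0.04, "T_CD8": 0.06, "NK": 0.05, "B": 0.01,
    "monocyte": 0.38, "other_myeloid": 0.24, "progenitor": 0.12,
    "erythroid": 0.10,
}

#: Lymphoid-leaning composition used for DNMT3A-like age-related clones.
LYMPHOID_BIASED_PROBS: Mapping[str, float] = {
    "T_CD4": 0.18, "T_CD8": 0.22, "NK": 0.10, "B": 0.05,
    "monocyte": 0.20, "other_myeloid": 0.12, "progenitor": 0.07,
    "erythroid": 0.06,
}

STATIC = "static"

#: Default per-gene growth: (initial clone-fraction range, doubling time in
#: days or "static"). Doubling times follow the reported post-CAR gene-level
#: estimates; initial fractions put most clones below 2% VAF, where the
#: ultra-deep assay operates.
DEFAULT_GENES_WITH_RATES: Mapping[str, tuple[tuple[float, float], float | str]] = {
    "PPM1D": ((0.004, 0.04), 159.0),
    "DNMT3A": ((0.004, 0.04), 253.0),
    "TP53": ((0.004, 0.04), 263.0),
    "TET2": ((0.004, 0.04), 374.0),
    "ASXL1": ((0.004, 0.04), 374.0),
}


@dataclass
class SimulationConfig:
    """Study-condition parameters for cohort simulation.

    Defaults mirror the profiled post-CAR cohort: ~2800x de-duplicated
    depth, sampling from day -30 through day ~1 year relative to infusion
    (day 0), high cfDNA/PBL concordance (lognormal sd 0.15), and rare CAR+
    cells (~0.5% of T cells) in single-cell matrices.
    """

    n_patients: int = 40
    genes_with_rates: Mapping[str, tuple[tuple[float, float], float | str]] = \
        field(default_factory=lambda: dict(DEFAULT_GENES_WITH_RATES))
    #: probability a patient carries a clone of each configured gene
    gene_prevalence: float = 0.5
    timepoints_days: Sequence[int] = (-30, 0, 28, 90, 180, 365)
    depth_mean: float = 2800.0
    error_rate: float = 1e-4
    compartment_sd: float = 0.15
    compartments: Sequence[str] = ("cfDNA", "PBL")
    sc_n_cells: int = 5000
    ado_rate: float = 0.1
    car_fraction: float = 0.005
    car_nont_leak: float = 0.01
    car_ch_enrichment_true: float = 4.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("error_rate", "compartment_sd", "ado_rate",
                     "car_fraction", "gene_prevalence"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0 and name != "compartment_sd":
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be positive")
        days = list(self.timepoints_days)
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValueError("timepoints_days must be strictly increasing")
        worst = 0.0
        for gene, ((f_lo, f_hi), td) in self.genes_with_rates.items():
            if not (0.0 < f_lo <= f_hi < 1.0):
                raise ValueError(f"bad initial fraction range for {gene}")
            if td != STATIC and float(td) == 0.0:
                raise ValueError(f"doubling time for {gene} must be nonzero")
            worst += f_hi
        if worst > 1.0:
            raise ValueError(
                f"clone fractions may sum to {worst:.3f} > 1 at t=0; "
                "reduce initial fraction ranges")
        if self.car_ch_enrichment_true * self.car_fraction > 1.0:
            raise ValueError("car_ch_enrichment_true * car_fraction > 1")


@dataclass
class TrueClone:
    """Ground-truth clone: one variant set growing as a unit."""

    clone_id: str
    patient_id: str
    variant_ids: tuple[str, ...]
    genes: tuple[str, ...]
    f0: float                       # clone cell fraction at day 0
    doubling_time: float | str      # days, or "static"
    loh: bool = False               # hom at its loci; VAF = fraction
    lineage_probs: Mapping[str, float] = field(
        default_factory=lambda: dict(MYELOID_BIASED_PROBS))
    car_target: bool = False        # designated vector-integration clone

    def fraction_at(self, t: float) -> float:
        return clone_fraction_at(self.f0, self.doubling_time, t)

    def vaf_at(self, t: float) -> float:
        f = self.fraction_at(t)
        return f if self.loh else f / 2.0


@dataclass
class SyntheticCohort:
    config: SimulationConfig
    true_clones: list[TrueClone]
    observations: pd.DataFrame
    truth_log: dict                 # patient -> variant -> {day: fraction}
    sc_matrices: dict = field(default_factory=dict)   # patient -> DataFrame

    @property
    def patients(self) -> list[str]:
        return sorted({c.patient_id for c in self.true_clones})


# ---------------------------------------------------------------------------
# Growth law
# ---------------------------------------------------------------------------

def clone_fraction_at(f0: float, doubling_time: float | str, t: float) -> float:
    """Clone cell fraction under logistic-capped exponential growth.

    f(t) = f0 e^{rt} / (1 - f0 + f0 e^{rt}),  r = ln 2 / T_d.

    A pure exponential would eventually exceed fraction 1; the logistic form
    keeps f in (0, 1) while matching 2^{t/T_d} scaling for small clones.
    ``doubling_time`` may be "static" or infinite (no growth); negative
    values model contracting clones (half-life |T_d|).
    """
    if not 0.0 < f0 < 1.0:
        raise ValueError(f"f0={f0} must be in (0, 1)")
    if doubling_time == STATIC or (
            isinstance(doubling_time, float) and math.isinf(doubling_time)):
        return f0
    r = math.log(2.0) / float(doubling_time)
    # compute in log space to avoid overflow at large r*t; clamp away from the
    # open-interval endpoints where the float saturates
    ert = math.exp(min(r * t, 700.0))
    f = f0 * ert / (1.0 - f0 + f0 * ert)
    return min(max(f, 5e-324), math.nextafter(1.0, 0.0))


# ---------------------------------------------------------------------------
# Read sampling
# ---------------------------------------------------------------------------

def sample_read_counts(true_vaf: float, depth: float, error_rate: float,
                       rng: np.random.Generator) -> tuple[int, int] | None:
    """Draw (alt, total) read counts for one observation.

    Total depth is Poisson around the target; alt reads are binomial with
    success probability true_vaf + (1 - true_vaf) * error_rate (background
    substitutions on wild-type molecules). Returns None when total depth is
    zero: a zero-depth site is missing, never VAF 0.
    """
    if not 0.0 <= true_vaf <= 1.0:
        raise ValueError(f"true_vaf={true_vaf} outside [0, 1]")
    total = int(rng.poisson(depth)) if depth > 0 else 0
    if total == 0:
        return None
    p = true_vaf + (1.0 - true_vaf) * error_rate
    alt = int(rng.binomial(total, min(p, 1.0)))
    return alt, total


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

def _patient_rng(seed: int, patient_index: int) -> np.random.Generator:
    # stable per-patient stream: depends only on (cohort seed, patient index)
    return np.random.default_rng(np.random.SeedSequence([seed, patient_index]))


def _draw_clones(config: SimulationConfig, patient_id: str,
                 rng: np.random.Generator) -> list[TrueClone]:
    clones: list[TrueClone] = []
    total_f0 = 0.0
    for gene, ((f_lo, f_hi), td) in config.genes_with_rates.items():
        if rng.random() >= config.gene_prevalence:
            continue
        f0 = float(rng.uniform(f_lo, f_hi))
        if total_f0 + f0 > 1.0:
            continue  # shared-fraction cap: skip clones that would overfill
        total_f0 += f0
        vid = f"{patient_id}:{gene}:{len(clones)}"
        bias = (LYMPHOID_BIASED_PROBS
                if classify_ch_gene(gene) == "age_related"
                else MYELOID_BIASED_PROBS)
        clones.append(TrueClone(
            clone_id=f"{patient_id}_c{len(clones)}", patient_id=patient_id,
            variant_ids=(vid,), genes=(gene,), f0=f0, doubling_time=td,
            lineage_probs=dict(bias)))
    return clones


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Simulate a full cohort of longitudinal VAF observations.

    Deterministic given ``config.seed``; per-patient RNG streams are derived
    from (seed, patient index) so any patient subset reproduces exactly.
    """
    config.validate()
    all_clones: list[TrueClone] = []
    rows: list[dict] = []
    truth_log: dict[str, dict] = {}

    for i in range(config.n_patients):
        patient_id = f"P{i:03d}"
        rng = _patient_rng(config.seed, i)
        clones = _draw_clones(config, patient_id, rng)
        all_clones.extend(clones)
        truth_log[patient_id] = {}

        for day in config.timepoints_days:
            # shared-fraction cap at each timepoint
            fracs = np.array([c.fraction_at(day) for c in clones])
            scale = 1.0 / fracs.sum() if fracs.sum() > 1.0 else 1.0
            for clone, frac in zip(clones, fracs):
                frac = float(frac * scale)
                true_vaf_pbl = frac if clone.loh else frac / 2.0
                for vid in clone.variant_ids:
                    truth_log[patient_id].setdefault(vid, {})[int(day)] = frac
                for comp in config.compartments:
                    if comp == "PBL":
                        true_vaf = true_vaf_pbl
                    else:
                        # cfDNA / BM: multiplicative lognormal deviation
                        factor = float(rng.lognormal(0.0, config.compartment_sd))
                        true_vaf = min(true_vaf_pbl * factor, 1.0)
                    drawn = sample_read_counts(
                        true_vaf, config.depth_mean, config.error_rate, rng)
                    if drawn is None:
                        continue
                    alt, total = drawn
                    for vid, gene in zip(clone.variant_ids, clone.genes):
                        rows.append({
                            "patient_id": patient_id, "variant_id": vid,
                            "gene": gene, "day": int(day),
                            "compartment": comp, "alt": alt, "depth": total,
                        })

    obs = pd.DataFrame(rows, columns=["patient_id", "variant_id", "gene",
                                      "day", "compartment", "alt", "depth"])
    if len(obs):
        obs["vaf"] = obs["alt"] / obs["depth"]
        from .variant_model import is_detectable
        obs["detectable"] = [
            is_detectable(a, d, config.error_rate)
            for a, d in zip(obs["alt"], obs["depth"])]
    else:
        obs["vaf"] = pd.Series(dtype=float)
        obs["detectable"] = pd.Series(dtype=bool)
    return SyntheticCohort(config=config, true_clones=all_clones,
                           observations=obs, truth_log=truth_log)


# ---------------------------------------------------------------------------
# Single-cell matrix simulation
# ---------------------------------------------------------------------------

def simulate_single_cell_matrix(clones: Sequence[TrueClone],
                                config: SimulationConfig,
                                rng: np.random.Generator | None = None,
                                day: float = 180.0) -> pd.DataFrame:
    """Simulate one cells x amplicons genotype matrix with lineage and CAR.

    Each cell is assigned a ground-truth clone (or wildtype) by the clone
    cell fractions at ``day``, a lineage from the clone's lineage
    distribution, genotype calls 0/1/2 per amplicon with allelic dropout
    applied to het calls (lost calls become ref or missing with equal
    probability), and a CAR flag. CAR is carried by T cells at rate
    ``car_fraction``; inside the designated integration clone the rate is
    multiplied by ``car_ch_enrichment_true``, with the out-of-clone rate
    compensated so the marginal CAR+ T-cell rate is unchanged.

    Columns: cell_id, clone_truth, lineage, car_flag, then one column per
    amplicon with observed calls (0=ref, 1=het, 2=hom, NaN=missing).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n = int(config.sc_n_cells)
    fracs = np.array([c.fraction_at(day) for c in clones], dtype=float)
    if fracs.sum() > 1.0:
        raise ValueError("clone fractions sum > 1")

    probs = np.append(fracs, 1.0 - fracs.sum())     # last slot = wildtype
    assignment = rng.choice(len(probs), size=n, p=probs)

    amplicons = sorted({v for c in clones for v in c.variant_ids})
    amp_index = {a: j for j, a in enumerate(amplicons)}

    lineage = np.empty(n, dtype=object)
    geno_true = np.zeros((n, len(amplicons)), dtype=float)
    for k, clone in enumerate(clones):
        mask = assignment == k
        m = int(mask.sum())
        if m == 0:
            continue
        lp = np.array([clone.lineage_probs.get(l, 0.0) for l in LINEAGES])
        lp = lp / lp.sum()
        lineage[mask] = rng.choice(LINEAGES, size=m, p=lp)
        call = 2.0 if clone.loh else 1.0
        for vid in clone.variant_ids:
            geno_true[mask, amp_index[vid]] = call
    wt_mask = assignment == len(clones)
    if wt_mask.any():
        lp = np.array([DEFAULT_LINEAGE_PROBS[l] for l in LINEAGES])
        lineage[wt_mask] = rng.choice(LINEAGES, size=int(wt_mask.sum()),
                                      p=lp / lp.sum())

    # allelic dropout on het calls: lost with prob ado_rate; of lost calls,
    # half read as ref, half as missing
    geno_obs = geno_true.copy()
    if config.ado_rate > 0:
        het = geno_true == 1.0
        lost = het & (rng.random(geno_true.shape) < config.ado_rate)
        to_na = lost & (rng.random(geno_true.shape) < 0.5)
        geno_obs[lost] = 0.0
        geno_obs[to_na] = np.nan

    # CAR flag
    is_t = np.isin(lineage.astype(str), ("T_CD4", "T_CD8"))
    car = np.zeros(n, dtype=bool)
    target_idx = next((k for k, c in enumerate(clones) if c.car_target), None)
    p0 = config.car_fraction
    if target_idx is None or p0 == 0.0:
        car[is_t] = rng.random(int(is_t.sum())) < p0
    else:
        in_clone_t = is_t & (assignment == target_idx)
        out_t = is_t & ~in_clone_t
        n_t = int(is_t.sum())
        q = in_clone_t.sum() / n_t if n_t else 0.0
        e = config.car_ch_enrichment_true
        p_in = e * p0
        p_out = p0 * (1.0 - e * q) / (1.0 - q) if q < 1.0 else 0.0
        if p_in > 1.0 or p_out < 0.0:
            raise ValueError(
                f"enrichment {e} with clone T-share {q:.3f} implies an "
                "out-of-clone CAR probability outside [0, 1]")
        car[in_clone_t] = rng.random(int(in_clone_t.sum())) < p_in
        car[out_t] = rng.random(int(out_t.sum())) < p_out
    non_t = ~is_t
    car[non_t] = rng.random(int(non_t.sum())) < p0 * config.car_nont_leak

    clone_names = [c.clone_id for c in clones] + ["WT"]
    df = pd.DataFrame({
        "cell_id": [f"cell{j:06d}" for j in range(n)],
        "clone_truth": [clone_names[a] for a in assignment],
        "lineage": lineage.astype(str),
        "car_flag": car,
    })
    for a in amplicons:
        df[a] = geno_obs[:, amp_index[a]]
    return df
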