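"""Single-cell DNA clone architecture: clone calling, hierarchy, CAR enrichment.

Input is a cells x amplicons genotype matrix (0=ref, 1=het, 2=hom,
NaN=missing) with a pre-annotated lineage label and a per-cell CAR-vector
detection flag, as produced by combined single-cell DNA genotyping with
antibody-based surface readout. Provides

* clone assignment: each distinct set of mutant amplicons defines a clone;
  cells with missing calls are rescued only when their observed calls match
  exactly one called clone pattern;
* mutational-hierarchy inference over clone variant sets (minimal strict
  subset edges), with the gained-mutation pattern labeled age->DDR,
  DDR->age, or sequential-TP53;
* lineage penetrance (myeloid vs lymphoid mutated-cell fractions and
  plurality label) per clone and rolled up per gene;
* CAR-vector co-occurrence with a CH clone: observed vs expected CAR+ clone
  cells among T cells under independence, with a Fisher exact test;
* CD4:CD8 skew by CAR or CH stratum (pooled odds ratio, with a
  Mantel-Haenszel per-patient stratified option);
* cohort-level CAR population summaries.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .variant_model import classify_ch_gene

logger = logging.getLogger(__name__)

META_COLUMNS = ("cell_id", "clone_truth", "lineage", "car_flag")
T_LINEAGES = ("T_CD4", "T_CD8")

#: lineage -> compartment map; progenitor and erythroid sit on the myeloid
#: side (judgment call, configurable)
DEFAULT_LINEAGE_MAP: Mapping[str, str] = {
    "T_CD4": "lymphoid", "T_CD8": "lymphoid", "NK": "lymphoid",
    "B": "lymphoid", "monocyte": "myeloid", "other_myeloid": "myeloid",
    "progenitor": "myeloid", "erythroid": "myeloid",
}


@dataclass
class Clone:
    """A unique set of mutant amplicons carried by >= min_cells cells."""

    clone_id: str
    variant_set: frozenset[str]
    n_cells: int
    cell_ids: list[str] = field(default_factory=list, repr=False)
    lineage_counts: dict[str, int] = field(default_factory=dict)
    car_pos_cells: int = 0
    hom_fraction: dict[str, float] = field(default_factory=dict)

    @property
    def is_wildtype(self) -> bool:
        return len(self.variant_set) == 0


@dataclass
class HierarchyEdge:
    parent_clone: str
    child_clone: str
    gained_variants: frozenset[str]
    pattern: str    # age_then_ddr | ddr_then_age | tp53_sequential | other


def amplicon_columns(matrix: pd.DataFrame) -> list[str]:
    return [c for c in matrix.columns if c not in META_COLUMNS]


def _gene_of(amplicon: str) -> str:
    """Amplicon ids carry the gene symbol, e.g. 'P001:TP53:0' or 'TP53_R280G'."""
    for token in str(amplicon).replace("_", ":").split(":"):
        if classify_ch_gene(token) != "non_ch":
            return token.upper()
    return str(amplicon).upper()


# ---------------------------------------------------------------------------
# Clone calling
# ---------------------------------------------------------------------------

def assign_clones(matrix: pd.DataFrame, min_cells: int = 2
                  ) -> tuple[list[Clone], pd.DataFrame]:
    """Group cells into clones by their exact set of mutant amplicon calls.

    A call of 1 (het) or 2 (hom) marks the amplicon mutant. Cells with
    complete calls define the clone patterns; groups smaller than
    ``min_cells`` fold into unassigned. Cells with any missing call are
    assigned only when their observed calls are consistent with exactly one
    called pattern (conservative under allelic dropout: ambiguous cells never
    split or seed clones). Wildtype cells form the empty-set group.

    Returns (clones, unassigned report). The clone list includes the
    wildtype group when present; ``assignment`` columns are added to the
    report for unassigned cells with the reason.
    """
    amps = amplicon_columns(matrix)
    geno = matrix[amps].to_numpy(dtype=float)
    mutant = (geno == 1.0) | (geno == 2.0)
    missing = np.isnan(geno)
    complete = ~missing.any(axis=1)

    # patterns from complete cells
    pattern_cells: dict[frozenset, list[int]] = {}
    for i in np.flatnonzero(complete):
        key = frozenset(np.compress(mutant[i], amps))
        pattern_cells.setdefault(key, []).append(i)

    called = {k: v for k, v in pattern_cells.items() if len(v) >= min_cells}
    unassigned_rows: list[tuple[int, str]] = []
    for k, v in pattern_cells.items():
        if k not in called:
            unassigned_rows.extend((i, "group_below_min_cells") for i in v)

    # rescue incomplete cells: observed loci must match exactly one pattern
    patterns = list(called.keys())
    for i in np.flatnonzero(~complete):
        obs_loci = ~missing[i]
        if not obs_loci.any():
            unassigned_rows.append((i, "all_missing"))
            continue
        cell_mut = mutant[i]
        matches = [
            k for k in patterns
            if all((amps[j] in k) == cell_mut[j]
                   for j in np.flatnonzero(obs_loci))
        ]
        if len(matches) == 1:
            called[matches[0]].append(i)
        else:
            reason = "no_matching_clone" if not matches else "ambiguous"
            unassigned_rows.append((i, reason))

    clones: list[Clone] = []
    order = sorted(called, key=lambda k: (len(k), sorted(k)))
    for idx, key in enumerate(order):
        cells = called[key]
        sub = matrix.iloc[cells]
        hom_frac = {}
        for a in sorted(key):
            calls = sub[a].to_numpy(dtype=float)
            obs = calls[~np.isnan(calls)]
            hom_frac[a] = float((obs == 2.0).mean()) if len(obs) else float("nan")
        clones.append(Clone(
            clone_id="WT" if not key else f"clone{idx}",
            variant_set=key, n_cells=len(cells),
            cell_ids=sub["cell_id"].tolist(),
            lineage_counts=sub["lineage"].value_counts().to_dict(),
            car_pos_cells=int(sub["car_flag"].astype(bool).sum()),
            hom_fraction=hom_frac))

    if unassigned_rows:
        idxs, reasons = zip(*unassigned_rows)
        report = matrix.iloc[list(idxs)][["cell_id", "lineage"]].copy()
        report["reason"] = reasons
    else:
        report = pd.DataFrame(columns=["cell_id", "lineage", "reason"])
    return clones, report.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Hierarchy
# ---------------------------------------------------------------------------

def _pattern_label(ancestral: frozenset[str], gained: frozenset[str]) -> str:
    anc_genes = {_gene_of(a) for a in ancestral}
    gain_genes = {_gene_of(a) for a in gained}
    if "TP53" in anc_genes and "TP53" in gain_genes:
        return "tp53_sequential"
    anc_classes = {classify_ch_gene(g) for g in anc_genes}
    gain_classes = {classify_ch_gene(g) for g in gain_genes}
    if anc_classes <= {"age_related"} and "ddr" in gain_classes:
        return "age_then_ddr"
    if "ddr" in anc_classes and gain_classes <= {"age_related"}:
        return "ddr_then_age"
    return "other"


def infer_hierarchy(clones: Sequence[Clone]) -> list[HierarchyEdge]:
    """Minimal strict-subset edges among CH clone variant sets.

    parent.variant_set is a strict subset of child.variant_set with no
    intermediate called clone in between; the resulting edge set is the
    transitive reduction of the subset partial order, hence acyclic.
    """
    ch = [c for c in clones if not c.is_wildtype]
    edges = []
    for parent, child in itertools.permutations(ch, 2):
        if not parent.variant_set < child.variant_set:
            continue
        intermediate = any(
            parent.variant_set < m.variant_set < child.variant_set
            for m in ch)
        if intermediate:
            continue
        gained = frozenset(child.variant_set - parent.variant_set)
        edges.append(HierarchyEdge(
            parent_clone=parent.clone_id, child_clone=child.clone_id,
            gained_variants=gained,
            pattern=_pattern_label(parent.variant_set, gained)))
    return edges


# ---------------------------------------------------------------------------
# Lineage penetrance
# ---------------------------------------------------------------------------

def lineage_penetrance(clone: Clone,
                       lineage_map: Mapping[str, str] = DEFAULT_LINEAGE_MAP
                       ) -> dict:
    """Mutated-cell lineage breakdown of one clone.

    Returns per-compartment (myeloid/lymphoid) fractions of the clone's
    cells and the plurality compartment.
    """
    if clone.n_cells < 1:
        raise ValueError("clone has no cells")
    counts = {"myeloid": 0, "lymphoid": 0}
    for lineage, n in clone.lineage_counts.items():
        comp = lineage_map.get(lineage)
        if comp is None:
            logger.warning("lineage %r missing from lineage map", lineage)
            continue
        counts[comp] += n
    total = sum(counts.values())
    fractions = {k: (v / total if total else float("nan"))
                 for k, v in counts.items()}
    plurality = max(counts, key=lambda k: counts[k])
    return {"clone_id": clone.clone_id, "n_cells": clone.n_cells,
            "myeloid_fraction": fractions["myeloid"],
            "lymphoid_fraction": fractions["lymphoid"],
            "plurality": plurality}


def gene_penetrance_rollup(clones: Sequence[Clone],
                           lineage_map: Mapping[str, str] = DEFAULT_LINEAGE_MAP
                           ) -> pd.DataFrame:
    """Per-gene lineage penetrance across clones carrying that gene."""
    rows = []
    for clone in clones:
        if clone.is_wildtype:
            continue
        pen = lineage_penetrance(clone, lineage_map)
        for gene in {_gene_of(a) for a in clone.variant_set}:
            rows.append({"gene": gene, **pen})
    if not rows:
        return pd.DataFrame(columns=["gene", "n_clones", "n_lymphoid_plurality",
                                     "mean_lymphoid_fraction"])
    df = pd.DataFrame(rows)
    out = df.groupby("gene", sort=True).agg(
        n_clones=("clone_id", "size"),
        n_lymphoid_plurality=("plurality", lambda s: int((s == "lymphoid").sum())),
        mean_lymphoid_fraction=("lymphoid_fraction", "mean"),
    ).reset_index()
    return out


# ---------------------------------------------------------------------------
# CAR-vector enrichment & population summaries
# ---------------------------------------------------------------------------

def car_ch_enrichment(matrix: pd.DataFrame, clone: Clone,
                      include_singletons: bool = True) -> dict:
    """CAR-vector co-occurrence with one CH clone among T cells.

    Under independence, expected CAR+ clone cells = N_T * p(CAR+|T) *
    p(clone|T); the enrichment ratio is observed / expected, with a
    two-sided Fisher exact test on the (CAR+/-, clone+/-) 2x2 among T cells.
    ``include_singletons=False`` reports the ratio as 0 when the clone holds
    only a single CAR+ cell (observed co-occurrences that cannot be
    distinguished from sporadic integration).
    """
    t = matrix[matrix["lineage"].isin(T_LINEAGES)]
    n_t = len(t)
    clone_cells = set(clone.cell_ids)
    in_clone = t["cell_id"].isin(clone_cells).to_numpy()
    car = t["car_flag"].astype(bool).to_numpy()
    n_car = int(car.sum())
    if n_car == 0:
        return {"clone_id": clone.clone_id, "skipped": True,
                "reason": "no CAR+ T cells"}
    observed = int((car & in_clone).sum())
    if not include_singletons and observed <= 1:
        observed = 0
    expected = n_t * (n_car / n_t) * (in_clone.sum() / n_t) if n_t else 0.0
    ratio = observed / expected if expected > 0 else float("nan")
    table = [[observed, n_car - observed],
             [int(in_clone.sum()) - observed,
              n_t - n_car - int(in_clone.sum()) + observed]]
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return {"clone_id": clone.clone_id, "skipped": False,
            "n_t_cells": n_t, "observed": observed,
            "expected": float(expected), "ratio": float(ratio),
            "fisher_p": float(p)}


def cd4_cd8_skew(matrix: pd.DataFrame, stratify_by: str = "CH",
                 clones: Sequence[Clone] | None = None,
                 patient_col: str | None = None) -> dict:
    """CD4:CD8 ratio among T cells, split by CAR or CH status.

    ``stratify_by="CAR"`` uses the car_flag; ``stratify_by="CH"`` marks a T
    cell positive when it carries any mutant call (or belongs to a nonempty
    called clone when ``clones`` is given). Returns the CD4:CD8 ratio in the
    positive and negative stratum and the pooled odds ratio
    (CD4+pos * CD8+neg) / (CD8+pos * CD4+neg); with ``patient_col`` set, a
    Mantel-Haenszel per-patient stratified OR is added.
    """
    t = matrix[matrix["lineage"].isin(T_LINEAGES)].copy()
    if t.empty:
        raise ValueError("no T cells in matrix")
    if stratify_by == "CAR":
        positive = t["car_flag"].astype(bool).to_numpy()
    elif stratify_by == "CH":
        if clones is not None:
            pos_cells = set().union(*(c.cell_ids for c in clones
                                      if not c.is_wildtype)) if clones else set()
            positive = t["cell_id"].isin(pos_cells).to_numpy()
        else:
            amps = [c for c in amplicon_columns(t) if c != patient_col]
            geno = t[amps].to_numpy(dtype=float)
            positive = np.nansum((geno == 1.0) | (geno == 2.0), axis=1) > 0
    else:
        raise ValueError("stratify_by must be 'CAR' or 'CH'")

    cd4 = (t["lineage"] == "T_CD4").to_numpy()
    a = int((cd4 & positive).sum())       # CD4, stratum+
    b = int((~cd4 & positive).sum())      # CD8, stratum+
    c = int((cd4 & ~positive).sum())      # CD4, stratum-
    d = int((~cd4 & ~positive).sum())     # CD8, stratum-

    def ratio(x, y):
        return x / y if y else float("nan")

    out = {"ratio_pos": ratio(a, b), "ratio_neg": ratio(c, d),
           "odds_ratio": (a * d) / (b * c) if b * c else float("nan"),
           "n_pos": a + b, "n_neg": c + d}
    if patient_col is not None and patient_col in t.columns:
        from statsmodels.stats.contingency_tables import StratifiedTable
        tables = []
        for _, grp in t.groupby(patient_col):
            gp = grp.index
            pos_g = positive[t.index.get_indexer(gp)]
            cd4_g = cd4[t.index.get_indexer(gp)]
            tbl = np.array([[int((cd4_g & pos_g).sum()),
                             int((cd4_g & ~pos_g).sum())],
                            [int((~cd4_g & pos_g).sum()),
                             int((~cd4_g & ~pos_g).sum())]], dtype=float)
            if tbl.sum() > 0:
                tables.append(tbl)
        if tables:
            out["odds_ratio_mh"] = float(
                StratifiedTable(tables).oddsratio_pooled)
    return out


def car_population_summary(matrices: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Per-sample CAR+ population summary.

    For each sample: fraction of all cells CAR+, fraction of CAR+ cells with
    a T lineage, and fraction of CAR+ T cells that are CD4+. Zero CAR+ cells
    yields zeros with n_car=0 as the marker.
    """
    rows = []
    for sample, m in matrices.items():
        car = m[m["car_flag"].astype(bool)]
        n_car = len(car)
        car_t = car[car["lineage"].isin(T_LINEAGES)]
        rows.append({
            "sample": sample,
            "n_cells": len(m),
            "n_car": n_car,
            "car_fraction": n_car / len(m) if len(m) else float("nan"),
            "car_t_fraction": len(car_t) / n_car if n_car else 0.0,
            "car_cd4_fraction": (
                (car_t["lineage"] == "T_CD4").mean() if len(car_t) else 0.0),
        })
    return pd.DataFrame(rows)
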