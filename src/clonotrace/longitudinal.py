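"""Longitudinal CH dynamics: trajectories, selection, doubling times.

Operates on a tidy observation table (columns: patient_id, variant_id, gene,
day, compartment, alt, depth, vaf, detectable) and provides

* trajectory construction per (patient, variant, compartment);
* the paired pre/post-infusion gene-level selection test — earliest
  pre-infusion (day <= 0) vs latest post-infusion (day >= 25) VAF per
  variant, per-gene Wilcoxon signed-rank on log2 fold change with
  Benjamini-Hochberg correction across tested genes;
* growth-rate / doubling-time estimation by log-linear regression of VAF on
  time over detectable points, with per-gene median summaries;
* the fraction of mutations with increased VAF;
* cfDNA vs PBL (or BM) compartment concordance;
* per-patient clonal-competition detection (one clone significantly rising
  while another falls).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .variant_model import compute_vaf

logger = logging.getLogger(__name__)

#: pseudo-floor added to both VAFs before taking log2 fold change, so that
#: sub-detection pre-infusion values yield finite ratios
DEFAULT_EPSILON = 0.001
PRE_MAX_DAY = 0
POST_MIN_DAY = 25


@dataclass
class Trajectory:
    """Time-ordered observations of one variant in one compartment."""

    patient_id: str
    variant_id: str
    gene: str
    compartment: str
    observations: pd.DataFrame  # sorted by day

    @property
    def days(self) -> np.ndarray:
        return self.observations["day"].to_numpy()

    @property
    def vafs(self) -> np.ndarray:
        return self.observations["vaf"].to_numpy()


@dataclass
class DoublingTimeEstimate:
    variant_id: str
    patient_id: str
    gene: str
    compartment: str
    growth_rate: float          # per day, r = slope * ln 2
    doubling_time: float        # days; inf for flat, negative = half-life
    n_points: int
    fit_r2: float


@dataclass
class CompetitionReport:
    patient_id: str
    competing: bool
    dominant_variant: str | None = None
    declining_variant: str | None = None
    detail: str = ""


def build_trajectories(observations: pd.DataFrame) -> list[Trajectory]:
    """Group observations by (patient, variant, compartment), day-ordered.

    Undetectable points are retained (flagged via the ``detectable`` column).
    Duplicate (variant, day, compartment) rows keep the higher-depth record.
    """
    if observations.empty:
        return []
    obs = observations.sort_values("depth", ascending=False)
    before = len(obs)
    obs = obs.drop_duplicates(
        subset=["patient_id", "variant_id", "compartment", "day"], keep="first")
    if len(obs) < before:
        logger.warning("dropped %d duplicate observations (kept higher depth)",
                       before - len(obs))
    out = []
    for (pid, vid, comp), grp in obs.groupby(
            ["patient_id", "variant_id", "compartment"], sort=True):
        grp = grp.sort_values("day").reset_index(drop=True)
        gene = grp["gene"].iloc[0] if "gene" in grp else ""
        out.append(Trajectory(pid, vid, gene, comp, grp))
    return out


def pair_pre_post(trajectories: list[Trajectory],
                  pre_max_day: int = PRE_MAX_DAY,
                  post_min_day: int = POST_MIN_DAY,
                  epsilon: float = DEFAULT_EPSILON) -> pd.DataFrame:
    """Pair the earliest pre-infusion with the latest post-infusion VAF.

    For each variant trajectory with at least one observation at day <=
    ``pre_max_day`` and one at day >= ``post_min_day``, emits one row with
    both VAFs and log2((vaf_post + eps) / (vaf_pre + eps)). Variants lacking
    either side are excluded (count available as the difference in length).
    """
    rows = []
    for tr in trajectories:
        obs = tr.observations[tr.observations["depth"] > 0]
        pre = obs[obs["day"] <= pre_max_day]
        post = obs[obs["day"] >= post_min_day]
        if pre.empty or post.empty:
            continue
        p0 = pre.loc[pre["day"].idxmin()]
        p1 = post.loc[post["day"].idxmax()]
        vaf_pre, vaf_post = float(p0["vaf"]), float(p1["vaf"])
        rows.append({
            "patient_id": tr.patient_id, "variant_id": tr.variant_id,
            "gene": tr.gene, "compartment": tr.compartment,
            "day_pre": int(p0["day"]), "day_post": int(p1["day"]),
            "vaf_pre": vaf_pre, "vaf_post": vaf_post,
            "log2_fold_change": math.log2((vaf_post + epsilon)
                                          / (vaf_pre + epsilon)),
        })
    cols = ["patient_id", "variant_id", "gene", "compartment", "day_pre",
            "day_post", "vaf_pre", "vaf_post", "log2_fold_change"]
    return (pd.DataFrame(rows, columns=cols)
            .sort_values(["patient_id", "variant_id", "compartment"])
            .reset_index(drop=True))


def gene_selection_test(paired_deltas: pd.DataFrame, alpha: float = 0.05,
                        min_variants: int = 3) -> pd.DataFrame:
    """Per-gene test for post-infusion selection with FDR control.

    One-sample Wilcoxon signed-rank of the paired log2 fold changes against
    zero (two-sided), per gene with >= ``min_variants`` informative pairs;
    Benjamini-Hochberg across the tested genes. A gene whose deltas are all
    exactly zero gets p = 1 by convention. Returns one row per tested gene
    with statistic, p, BH q, direction, and a ``selected`` flag (q < alpha).
    """
    results = []
    for gene, grp in paired_deltas.groupby("gene", sort=True):
        lfc = grp["log2_fold_change"].to_numpy(dtype=float)
        if len(lfc) < min_variants:
            logger.info("gene %s untested (%d < %d paired variants)",
                        gene, len(lfc), min_variants)
            continue
        if np.allclose(lfc, 0.0):
            stat, p = 0.0, 1.0
        else:
            res = stats.wilcoxon(lfc, alternative="two-sided")
            stat, p = float(res.statistic), float(res.pvalue)
        direction = "up" if np.median(lfc) > 0 else (
            "down" if np.median(lfc) < 0 else "none")
        results.append({"gene": gene, "n_variants": len(lfc),
                        "statistic": stat, "p_value": p,
                        "direction": direction})
    out = pd.DataFrame(results, columns=["gene", "n_variants", "statistic",
                                         "p_value", "direction"])
    if len(out):
        out["q_value"] = benjamini_hochberg(out["p_value"].to_numpy())
        out["selected"] = out["q_value"] < alpha
    else:
        out["q_value"] = pd.Series(dtype=float)
        out["selected"] = pd.Series(dtype=bool)
    return out


def benjamini_hochberg(p_values: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values (q-values)."""
    _, q, _, _ = multipletests(p_values, method="fdr_bh")
    return q


def estimate_growth(trajectory: Trajectory,
                    detect_only: bool = True) -> DoublingTimeEstimate | None:
    """Estimate clone growth rate by OLS of log2(VAF) on day.

    Restricted to detectable observations by default: imputing undetectable
    points at a floor would inflate apparent slopes. The slope is in
    doublings/day, so T_d = 1/slope; r = slope * ln 2 per day. Returns None
    (a reasoned skip) with fewer than two usable points.
    """
    obs = trajectory.observations
    if detect_only:
        obs = obs[obs["detectable"].astype(bool)]
    obs = obs[(obs["depth"] > 0) & (obs["vaf"] > 0)]
    if len(obs) < 2:
        return None
    x = obs["day"].to_numpy(dtype=float)
    y = np.log2(obs["vaf"].to_numpy(dtype=float))
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - np.sum(resid ** 2) / ss_tot if ss_tot > 0 else 1.0
    if abs(slope) < 1e-12:
        td = math.inf
    else:
        td = 1.0 / slope
    return DoublingTimeEstimate(
        variant_id=trajectory.variant_id, patient_id=trajectory.patient_id,
        gene=trajectory.gene, compartment=trajectory.compartment,
        growth_rate=slope * math.log(2.0), doubling_time=td,
        n_points=len(obs), fit_r2=float(r2))


def estimates_to_frame(estimates: list[DoublingTimeEstimate]) -> pd.DataFrame:
    cols = ["patient_id", "variant_id", "gene", "compartment",
            "growth_rate", "doubling_time", "n_points", "fit_r2"]
    return pd.DataFrame(
        [{c: getattr(e, c) for c in cols} for e in estimates], columns=cols)


def summarize_gene_doubling(estimates: list[DoublingTimeEstimate],
                            genes_of_interest: tuple[str, ...] = (
                                "PPM1D", "DNMT3A", "TP53"),
                            expanding_only: bool = True) -> pd.DataFrame:
    """Per-gene median doubling time over variant-level estimates.

    Listed genes are summarized individually; every other CH gene is pooled
    into "other". Emits the expanding-clone (positive growth rate) subset
    summary and, alongside, the all-clone median. Empty groups are absent.
    """
    df = estimates_to_frame(estimates)
    if df.empty:
        return pd.DataFrame(columns=["gene", "n", "median_doubling_time",
                                     "median_doubling_time_all"])
    df["group"] = [g if g in genes_of_interest else "other"
                   for g in df["gene"]]
    rows = []
    for group, grp in df.groupby("group", sort=True):
        expanding = grp[grp["growth_rate"] > 0]
        sub = expanding if expanding_only else grp
        if sub.empty:
            continue
        rows.append({
            "gene": group,
            "n": len(sub),
            "median_doubling_time": float(sub["doubling_time"].median()),
            "median_doubling_time_all": float(
                grp["doubling_time"].median()) if len(grp) else math.nan,
        })
    return pd.DataFrame(rows)


def fraction_increased(paired_deltas: pd.DataFrame,
                       by: str = "gene") -> pd.DataFrame:
    """Share of variants whose VAF increased pre -> post, per group.

    Ties (vaf_post == vaf_pre) count as not increased.
    """
    if paired_deltas.empty:
        return pd.DataFrame(columns=[by, "n", "n_increased", "fraction"])
    d = paired_deltas.copy()
    d["increased"] = d["vaf_post"] > d["vaf_pre"]
    out = (d.groupby(by, sort=True)["increased"]
           .agg(n="size", n_increased="sum").reset_index())
    out["fraction"] = out["n_increased"] / out["n"]
    return out


def compartment_concordance(observations: pd.DataFrame,
                            comp_a: str = "cfDNA", comp_b: str = "PBL",
                            detect_only: bool = True
                            ) -> tuple[float, float, int]:
    """Pearson correlation of VAFs between two compartments.

    Pairs observations of the same (patient, variant, day) across the two
    compartments; pairs where either side is undetectable are excluded.
    Returns (r, r^2, n pairs); (nan, nan, n) when fewer than 3 pairs or an
    axis has zero variance.
    """
    keys = ["patient_id", "variant_id", "day"]
    a = observations[observations["compartment"] == comp_a]
    b = observations[observations["compartment"] == comp_b]
    merged = a.merge(b, on=keys, suffixes=("_a", "_b"))
    if detect_only:
        merged = merged[merged["detectable_a"].astype(bool)
                        & merged["detectable_b"].astype(bool)]
    n = len(merged)
    if n < 3:
        return math.nan, math.nan, n
    x = merged["vaf_a"].to_numpy(dtype=float)
    y = merged["vaf_b"].to_numpy(dtype=float)
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        return math.nan, math.nan, n
    r = float(stats.pearsonr(x, y).statistic)
    return r, r * r, n


def detect_clonal_competition(trajectories: list[Trajectory],
                              ) -> CompetitionReport:
    """Flag clonal competition among one patient's CH trajectories.

    Competition = over a shared time window, one variant's VAF rises while
    another falls, both changes exceeding their summed exact-binomial 95%
    half-widths (CI separation). The dominant variant is the significant
    riser with the largest gain.
    """
    if not trajectories:
        raise ValueError("no trajectories supplied")
    pid = trajectories[0].patient_id
    if any(t.patient_id != pid for t in trajectories):
        raise ValueError("trajectories span multiple patients")
    if len(trajectories) < 2:
        return CompetitionReport(pid, False, detail="fewer than 2 trajectories")

    def significant_change(tr: Trajectory, lo_day: int, hi_day: int):
        """(delta, significant) between first/last obs inside the window."""
        obs = tr.observations
        obs = obs[(obs["day"] >= lo_day) & (obs["day"] <= hi_day)
                  & (obs["depth"] > 0)]
        if len(obs) < 2:
            return 0.0, False
        first, last = obs.iloc[0], obs.iloc[-1]
        _, ci_f = compute_vaf(int(first["alt"]), int(first["depth"]))
        _, ci_l = compute_vaf(int(last["alt"]), int(last["depth"]))
        delta = float(last["vaf"] - first["vaf"])
        if delta > 0:
            sig = ci_l[0] > ci_f[1]   # later lower bound above earlier upper
        else:
            sig = ci_l[1] < ci_f[0]
        return delta, bool(sig)

    lo = max(int(t.days.min()) for t in trajectories)
    hi = min(int(t.days.max()) for t in trajectories)
    if hi <= lo:
        return CompetitionReport(pid, False, detail="no shared window")
    risers, fallers = [], []
    for tr in trajectories:
        delta, sig = significant_change(tr, lo, hi)
        if sig and delta > 0:
            risers.append((delta, tr.variant_id))
        elif sig and delta < 0:
            fallers.append((delta, tr.variant_id))
    if risers and fallers:
        dominant = max(risers)[1]
        declining = min(fallers)[1]
        return CompetitionReport(pid, True, dominant, declining,
                                 detail=f"window [{lo}, {hi}]")
    return CompetitionReport(pid, False, detail=f"window [{lo}, {hi}]")
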