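"""Cohort-level classification and summaries.

Patient-level CCUS / ICUS / tMN labels from cytopenia status and CH variant
calls, CH prevalence as a function of VAF threshold, mutation-burden
summaries, gene-outcome (tMN) association, and the printed-ratio helper
used for reported percentages.

CCUS (clonal cytopenia of undetermined significance) requires cytopenia plus
a CH mutation at the clinical VAF threshold (default 2%) without a
morphologic myeloid neoplasm; a cytopenic patient whose only clones sit
below that threshold is ICUS (idiopathic), matching clinical convention for
sub-threshold clones detected by ultra-deep sequencing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

CLINICAL_VAF_THRESHOLD = 0.02
LABELS = ("tMN", "CCUS", "ICUS", "CH_only", "none")


@dataclass
class ClinicalRecord:
    patient_id: str
    cytopenic: bool | None
    morphologic_mds_aml: bool = False
    tmn_flag: bool = False
    n_cell_therapies: int = 1
    therapy_days: Mapping[str, int] = field(default_factory=dict)
    relapse_status: str = "none"

    def __post_init__(self) -> None:
        if self.tmn_flag and not self.morphologic_mds_aml:
            # tMN requires a morphologic or molecular myeloid diagnosis
            self.morphologic_mds_aml = True


@dataclass
class PatientClassification:
    patient_id: str
    label: str
    supporting_variants: tuple[str, ...] = ()


def classify_patient(record: ClinicalRecord, variants: pd.DataFrame,
                     clinical_vaf_threshold: float = CLINICAL_VAF_THRESHOLD
                     ) -> PatientClassification:
    """Assign one mutually exclusive label: tMN / CCUS / ICUS / CH_only / none.

    ``variants`` holds this patient's post-CAR calls with columns
    variant_id, vaf, and (optionally) detectable. Precedence: a tMN
    diagnosis overrides everything; a cytopenic patient with a detectable CH
    variant at VAF >= threshold is CCUS; cytopenic without such a clone is
    ICUS; non-cytopenic carriers are CH_only.
    """
    if record.cytopenic is None:
        raise ValueError(f"{record.patient_id}: cytopenia status missing; "
                         "record unclassifiable")
    v = variants if variants is not None else pd.DataFrame(columns=["variant_id", "vaf"])
    if "detectable" in v.columns:
        v = v[v["detectable"].astype(bool)]
    above = v[v["vaf"] >= clinical_vaf_threshold]
    if record.tmn_flag:
        label = "tMN"
        support = tuple(v["variant_id"])
    elif record.cytopenic and len(above):
        label = "CCUS"
        support = tuple(above["variant_id"])
    elif record.cytopenic:
        label = "ICUS"
        support = tuple(v["variant_id"])
    elif len(v):
        label = "CH_only"
        support = tuple(v["variant_id"])
    else:
        label = "none"
        support = ()
    return PatientClassification(record.patient_id, label, support)


def prevalence_by_threshold(variants: pd.DataFrame, thresholds: Sequence[float],
                            n_patients: int | None = None) -> pd.DataFrame:
    """Fraction of patients carrying >= 1 functional CH variant at VAF >= t.

    ``variants`` has columns patient_id, vaf, and optionally ``functional``
    and ``detectable`` (both restricted to True when present). Threshold 0
    means any detectable variant. ``n_patients`` sets the denominator
    (defaults to patients appearing in the table).
    """
    v = variants.copy()
    for col in ("functional", "detectable"):
        if col in v.columns:
            v = v[v[col].astype(bool)]
    denom = n_patients if n_patients is not None else v["patient_id"].nunique()
    rows = []
    for t in thresholds:
        carriers = v.loc[v["vaf"] >= t, "patient_id"].nunique()
        rows.append({"threshold": t, "n_carriers": carriers,
                     "n_patients": denom,
                     "prevalence": carriers / denom if denom else float("nan")})
    return pd.DataFrame(rows)


def mutation_burden(variants: pd.DataFrame,
                    group_labels: Mapping[str, str]) -> pd.DataFrame:
    """Unique functional CH variants per patient, summarized per group.

    ``group_labels`` maps patient_id -> group; patients in a group but
    absent from the variant table count as zero mutations.
    """
    v = variants.copy()
    if "functional" in v.columns:
        v = v[v["functional"].astype(bool)]
    per_patient = v.groupby("patient_id")["variant_id"].nunique()
    rows = []
    groups: dict[str, list[float]] = {}
    for pid, grp in group_labels.items():
        groups.setdefault(grp, []).append(float(per_patient.get(pid, 0)))
    for grp in sorted(groups):
        counts = np.array(groups[grp])
        rows.append({"group": grp, "n_patients": len(counts),
                     "mean_mutations": float(counts.mean()),
                     "median_mutations": float(np.median(counts))})
    return pd.DataFrame(rows)


def gene_outcome_association(exposure: pd.Series, outcome: pd.Series) -> dict:
    """Odds ratio for a binary gene-presence exposure vs a binary outcome.

    2x2 OR with Haldane-Anscombe 0.5 correction when any cell is zero,
    Woolf logit 95% CI on the corrected table, and a Fisher exact p on the
    raw counts. Both series are indexed by patient.
    """
    e = exposure.astype(bool)
    o = outcome.astype(bool)
    a = int((e & o).sum())        # exposed, outcome
    b = int((e & ~o).sum())       # exposed, no outcome
    c = int((~e & o).sum())       # unexposed, outcome
    d = int((~e & ~o).sum())      # unexposed, no outcome
    if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
        return {"odds_ratio": float("nan"), "ci95": (float("nan"),) * 2,
                "fisher_p": float("nan"), "table": (a, b, c, d),
                "degenerate": True}
    corr = 0.5 if 0 in (a, b, c, d) else 0.0
    aa, bb, cc, dd = (a + corr, b + corr, c + corr, d + corr)
    or_ = (aa * dd) / (bb * cc)
    se = float(np.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd))
    lo = float(np.exp(np.log(or_) - 1.96 * se))
    hi = float(np.exp(np.log(or_) + 1.96 * se))
    _, p = stats.fisher_exact([[a, b], [c, d]])
    return {"odds_ratio": float(or_), "ci95": (lo, hi),
            "fisher_p": float(p), "table": (a, b, c, d), "degenerate": False}


def fraction_summary(numerator: int, denominator: int) -> dict:
    """Printed-ratio helper: 100*num/den rounded half-away-from-zero, 1 dp."""
    if denominator <= 0:
        return {"fraction": float("nan"), "percent": float("nan"),
                "text": f"{numerator}/{denominator} (undefined)"}
    frac = numerator / denominator
    pct = float(Decimal(100 * Decimal(numerator) / Decimal(denominator))
                .quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))
    return {"fraction": frac, "percent": pct,
            "text": f"{numerator}/{denominator} ({pct}%)"}


def multi_therapy_flag(record: ClinicalRecord,
                       tmn_day: int | None = None) -> bool:
    """True when >= 2 cellular therapies preceded oncogenic transformation.

    Counts CAR infusions and autologous transplants in ``therapy_days``
    occurring before the tMN date; with no tMN date all recorded therapies
    count. Missing therapy history yields a conservative False.
    """
    if not record.therapy_days:
        if record.n_cell_therapies >= 2:
            return True
        import logging
        logging.getLogger(__name__).warning(
            "%s: no therapy dates; multi_therapy_flag defaults False",
            record.patient_id)
        return False
    days = record.therapy_days.values()
    if tmn_day is not None:
        days = [d for d in days if d < tmn_day]
    return len(list(days)) >= 2


def classification_table(classifications: Sequence[PatientClassification]
                         ) -> pd.DataFrame:
    return pd.DataFrame(
        [{"patient_id": c.patient_id, "label": c.label,
          "supporting_variants": ";".join(c.supporting_variants)}
         for c in classifications],
        columns=["patient_id", "label", "supporting_variants"])
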