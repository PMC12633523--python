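"""Core variant data model for clonal hematopoiesis (CH) analysis.

Defines the :class:`Variant` and :class:`VafObservation` records shared by
every downstream stage, VAF point estimates with exact binomial confidence
intervals, a detectability call for sub-2% VAF mutations at ultra-deep
(~2800x de-duplicated) depth, CH gene classification into age-related versus
DNA-damage-response (DDR) classes, and multi-hit TP53 / loss-of-heterozygosity
(LOH) flagging.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

logger = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# Curated CH gene panel.
#
# 17 genes; DNMT3A and TET2 are the canonical age-related CH genes, every
# other panel gene is treated as DNA-damage-response / chemotherapy-selected
# class for the age-vs-DDR contrasts. The panel is a default configuration,
# editable by passing a custom table to classify_ch_gene.
# ---------------------------------------------------------------------------

AGE_RELATED_GENES = frozenset({"DNMT3A", "TET2"})

DEFAULT_PANEL = (
    "DNMT3A", "TET2", "ASXL1", "TP53", "PPM1D", "CHEK2", "ATM", "SF3B1",
    "SRSF2", "U2AF1", "JAK2", "CBL", "GNB1", "GNAS", "KRAS", "NRAS", "IDH2",
)

#: Protein domain intervals (1-based, closed) used by the "functional"
#: missense filter. Truncating variants are functional anywhere.
DEFAULT_DOMAINS: Mapping[str, Sequence[tuple[int, int]]] = {
    "TP53": [(94, 312)],            # DNA-binding domain
    "DNMT3A": [(291, 374), (476, 614), (634, 912)],  # PWWP, ADD, methyltransferase
}

#: Default per-base background substitution rate after de-duplication.
DEFAULT_ERROR_RATE = 1e-4
#: Minimum supporting reads for a detectable call.
DEFAULT_MIN_ALT = 3
#: One-sided binomial tail cutoff for detectability.
DETECT_TAIL_P = 1e-3
#: VAF above which a heterozygous clone is suspected of LOH.
LOH_VAF_THRESHOLD = 0.55

CH_CLASSES = ("age_related", "ddr", "other_ch", "non_ch")
COMPARTMENTS = ("cfDNA", "PBL", "BM")


@dataclass(frozen=True)
class Variant:
    """One somatic mutation, shared across all assays of a patient."""

    variant_id: str
    patient_id: str
    gene: str
    chrom: str = "."
    pos: int = 0          # 1-based
    ref: str = "N"
    alt: str = "N"
    protein_change: str = ""
    ch_class: str = "non_ch"
    functional: bool = True

    def __post_init__(self) -> None:
        if self.ch_class not in CH_CLASSES:
            raise ValueError(f"unknown ch_class {self.ch_class!r}")


@dataclass
class VafObservation:
    """Alt/total read counts for one variant at one (day, compartment).

    ``day`` is an integer relative to infusion (day 0 = infusion day).
    ``vaf`` is None when depth == 0 (undefined, never coerced to zero).
    """

    variant_id: str
    day: int
    compartment: str
    alt: int
    depth: int
    patient_id: str = ""
    gene: str = ""
    vaf: float | None = field(default=None)
    detectable: bool = field(default=False)

    def __post_init__(self) -> None:
        if self.compartment not in COMPARTMENTS:
            raise ValueError(f"unknown compartment {self.compartment!r}")
        if self.alt > self.depth:
            raise ValueError(f"alt ({self.alt}) > depth ({self.depth})")
        if self.depth > 0:
            self.vaf = self.alt / self.depth
        else:
            self.vaf = None
        self.detectable = self.depth > 0 and is_detectable(self.alt, self.depth)


# ---------------------------------------------------------------------------
# VAF estimation
# ---------------------------------------------------------------------------

def compute_vaf(alt: int, depth: int, alpha: float = 0.05
                ) -> tuple[float | None, tuple[float, float] | None]:
    """Point VAF estimate alt/depth with an exact (Clopper-Pearson) CI.

    Returns ``(None, None)`` for depth 0: a zero-depth observation carries no
    information and must never be read as VAF 0.
    """
    if depth < 0 or alt < 0 or alt > depth:
        raise ValueError(f"invalid counts alt={alt}, depth={depth}")
    if depth == 0:
        return None, None
    lo, hi = proportion_confint(alt, depth, alpha=alpha, method="beta")
    return alt / depth, (float(lo), float(hi))


def is_detectable(alt: int, depth: int,
                  error_rate: float = DEFAULT_ERROR_RATE,
                  min_alt: int = DEFAULT_MIN_ALT) -> bool:
    """Detection call replacing read-level error suppression.

    A variant is detectable when it has at least ``min_alt`` supporting reads
    and the one-sided binomial tail P(X >= alt | depth, error_rate) is below
    1e-3, i.e. the alt count is not plausibly background error. At ~2800x
    depth this resolves mutations well below the conventional 2% VAF cutoff.
    """
    if depth <= 0 or alt < min_alt:
        return False
    tail = stats.binom.sf(alt - 1, depth, error_rate)
    return bool(tail < DETECT_TAIL_P)


# ---------------------------------------------------------------------------
# CH gene classification & functional filter
# ---------------------------------------------------------------------------

def classify_ch_gene(gene: str, panel: Iterable[str] = DEFAULT_PANEL) -> str:
    """Classify a gene symbol into age_related / ddr / non_ch.

    DNMT3A and TET2 are age-related CH; every other panel gene is DDR
    (chemotherapy-selected); off-panel genes are non_ch. Symbol casing is
    normalized to upper case before lookup.
    """
    symbol = str(gene).strip().upper()
    panel_upper = {str(g).strip().upper() for g in panel}
    if symbol in AGE_RELATED_GENES and symbol in panel_upper:
        return "age_related"
    if symbol in panel_upper:
        return "ddr"
    logger.debug("gene %r not on CH panel; classified non_ch", gene)
    return "non_ch"


_TRUNCATING_RE = re.compile(r"(\*|fs|X$|del$|splice)", re.IGNORECASE)
_MISSENSE_RE = re.compile(r"^[A-Z](\d+)[A-Z]$")


def is_functional(protein_change: str, gene: str,
                  domains: Mapping[str, Sequence[tuple[int, int]]] = DEFAULT_DOMAINS,
                  ) -> bool:
    """Operational 'functional variant' filter.

    Truncating changes (nonsense, frameshift, splice) are functional anywhere;
    missense changes are functional when they fall inside a configured
    protein domain interval (e.g. the TP53 DNA-binding domain). Genes with no
    configured domain treat any missense as functional.
    """
    pc = str(protein_change).strip()
    if not pc:
        return False
    if _TRUNCATING_RE.search(pc):
        return True
    m = _MISSENSE_RE.match(pc)
    if not m:
        return False
    gene_domains = domains.get(str(gene).strip().upper())
    if gene_domains is None:
        return True
    position = int(m.group(1))
    return any(lo <= position <= hi for lo, hi in gene_domains)


# ---------------------------------------------------------------------------
# Multi-hit TP53 and LOH
# ---------------------------------------------------------------------------

def flag_multi_hit_tp53(variants_in_clone: Iterable[Variant | str],
                        loh_flag: bool = False) -> bool:
    """True when a clone carries presumed biallelic TP53 disruption.

    Either two distinct TP53 variants in the same clone, or one TP53 variant
    together with loss of heterozygosity at the locus.
    """
    tp53 = set()
    for v in variants_in_clone:
        if isinstance(v, Variant):
            if v.gene.upper() == "TP53":
                tp53.add(v.variant_id)
        else:
            # bare "GENE p.change" style identifiers
            if str(v).upper().startswith("TP53"):
                tp53.add(str(v))
    if len(tp53) >= 2:
        return True
    return len(tp53) >= 1 and bool(loh_flag)


def detect_loh_from_trajectory(observations: Sequence[VafObservation]) -> bool:
    """Call LOH from a longitudinal VAF series of one variant.

    A heterozygous clone cannot exceed VAF 0.5; sustained VAF above 0.55
    (margin for sampling noise) indicates loss of the wild-type allele.
    True when VAF > 0.55 at two or more consecutive timepoints, or at a
    single terminal timepoint whose exact-binomial lower bound exceeds 0.5.
    """
    obs = sorted((o for o in observations if o.depth > 0), key=lambda o: o.day)
    if not obs:
        return False
    above = [o.vaf > LOH_VAF_THRESHOLD for o in obs]
    for i in range(len(above) - 1):
        if above[i] and above[i + 1]:
            return True
    last = obs[-1]
    if above[-1]:
        _, ci = compute_vaf(last.alt, last.depth)
        if ci is not None and ci[0] > 0.5:
            return True
    return False


def observations_to_frame(observations: Iterable[VafObservation]):
    """Tabulate VafObservation records into a pandas DataFrame."""
    import pandas as pd

    rows = [
        {
            "patient_id": o.patient_id,
            "variant_id": o.variant_id,
            "gene": o.gene,
            "day": o.day,
            "compartment": o.compartment,
            "alt": o.alt,
            "depth": o.depth,
            "vaf": np.nan if o.vaf is None else o.vaf,
            "detectable": o.detectable,
        }
        for o in observations
    ]
    cols = ["patient_id", "variant_id", "gene", "day", "compartment",
            "alt", "depth", "vaf", "detectable"]
    return pd.DataFrame(rows, columns=cols)
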