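"""Readers, writers, run configuration, and the end-to-end pipeline.

Observation tables travel as UTF-8 tab-delimited files (columns patient_id,
variant_id, gene, day, compartment, alt, depth) or as a minimal VCF dialect
(1-based positions; one sample column per (patient, compartment, day),
named ``PATIENT|COMPARTMENT|dDAY``, with per-sample AD/DP format fields).
Single-cell matrices are tab-delimited with NA for missing genotype calls.
Every table written by the pipeline carries a ``# config_hash=`` comment for
provenance; readers skip comment lines.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

OBS_COLUMNS = ["patient_id", "variant_id", "gene", "day", "compartment",
               "alt", "depth"]
COMPARTMENT_ALIASES = {
    "cfdna": "cfDNA", "plasma": "cfDNA", "pbl": "PBL", "pbmc": "PBL",
    "pdwb": "PBL", "bm": "BM", "marrow": "BM",
}


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        stream=sys.stderr, level=getattr(logging, level.upper()),
        format="%(levelname)s %(name)s: %(message)s")


def config_hash(obj) -> str:
    """Stable short hash of a configuration object for table provenance."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        obj = dataclasses.asdict(obj)
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def write_table(df: pd.DataFrame, path: str | Path,
                cfg_hash: str | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        if cfg_hash:
            fh.write(f"# config_hash={cfg_hash}\n")
        df.to_csv(fh, sep="\t", index=False, na_rep="NA")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", na_values=["NA"])


# ---------------------------------------------------------------------------
# Observation tables
# ---------------------------------------------------------------------------

def _validate_observations(df: pd.DataFrame, source: str) -> pd.DataFrame:
    missing = [c for c in OBS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{source}: missing columns {missing}")
    df = df.copy()
    df["day"] = df["day"].astype(int)
    df["compartment"] = [
        COMPARTMENT_ALIASES.get(str(c).strip().lower(), str(c).strip())
        for c in df["compartment"]]
    bad_comp = ~df["compartment"].isin(("cfDNA", "PBL", "BM"))
    bad_counts = (df["alt"] > df["depth"]) | (df["alt"] < 0) | (df["depth"] < 0)
    bad = bad_comp | bad_counts
    if bad.any():
        lines = (df.index[bad] + 2).tolist()  # 1-based incl. header
        raise ValueError(
            f"{source}: {int(bad.sum())} malformed rows "
            f"(unknown compartment or alt > depth) at lines {lines[:20]}")
    df["alt"] = df["alt"].astype(int)
    df["depth"] = df["depth"].astype(int)
    with np.errstate(invalid="ignore"):
        df["vaf"] = np.where(df["depth"] > 0, df["alt"] / df["depth"], np.nan)
    from .variant_model import is_detectable
    df["detectable"] = [is_detectable(a, d)
                        for a, d in zip(df["alt"], df["depth"])]
    return df.reset_index(drop=True)


def read_observations(path: str | Path, format: str = "tsv") -> pd.DataFrame:
    """Read and schema-validate a variant observation table (TSV or VCF)."""
    path = Path(path)
    if format == "tsv":
        raw = read_table(path)
        if raw.empty and not set(OBS_COLUMNS) <= set(raw.columns):
            raise ValueError(f"{path}: empty file without a valid header")
        return _validate_observations(raw, str(path))
    if format == "vcf":
        return _read_observations_vcf(path)
    raise ValueError(f"unknown format {format!r}")


def _read_observations_vcf(path: Path) -> pd.DataFrame:
    import pysam

    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            gene = rec.info.get("GENE", ".")
            # multi-allelic records are split: one row per alt allele
            for alt_i, alt_allele in enumerate(rec.alts or ()):
                vid = rec.id or f"{rec.chrom}:{rec.pos}:{rec.ref}>{alt_allele}"
                if len(rec.alts) > 1:
                    vid = f"{vid}:{alt_allele}"
                for sample in samples:
                    call = rec.samples[sample]
                    ad, dp = call.get("AD"), call.get("DP")
                    if ad is None or dp is None or ad[0] is None:
                        continue
                    try:
                        patient, compartment, day_tok = sample.split("|")
                    except ValueError as err:
                        raise ValueError(
                            f"{path}: sample {sample!r} not in "
                            "PATIENT|COMPARTMENT|dDAY form") from err
                    rows.append({
                        "patient_id": patient, "variant_id": vid,
                        "gene": gene, "day": int(day_tok.lstrip("d")),
                        "compartment": compartment,
                        "alt": int(ad[1 + alt_i]), "depth": int(dp),
                    })
    return _validate_observations(
        pd.DataFrame(rows, columns=OBS_COLUMNS), str(path))


def write_observations_vcf(obs: pd.DataFrame, path: str | Path) -> None:
    """Write observations as a minimal single-file VCF (text, uncompressed).

    Synthetic variants without genomic coordinates get placeholder loci on
    chromosome 1 (stable order). One sample column per (patient,
    compartment, day); AD = (ref, alt), DP = depth.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    variants = sorted(obs["variant_id"].unique())
    pos_of = {v: 1000 + 10 * i for i, v in enumerate(variants)}
    samples = sorted({f"{p}|{c}|d{d}" for p, c, d in
                      zip(obs["patient_id"], obs["compartment"], obs["day"])})
    lookup = {(r.variant_id, f"{r.patient_id}|{r.compartment}|d{r.day}"):
              (int(r.alt), int(r.depth)) for r in obs.itertuples()}
    gene_of = dict(zip(obs["variant_id"], obs["gene"]))

    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##contig=<ID=1>\n")
        fh.write('##INFO=<ID=GENE,Number=1,Type=String,'
                 'Description="Gene symbol">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,'
                 'Description="Allelic depths">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,'
                 'Description="Read depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for v in variants:
            cells = []
            for s in samples:
                hit = lookup.get((v, s))
                cells.append("./.:.:." if hit is None
                             else f".:{hit[1] - hit[0]},{hit[0]}:{hit[1]}")
            fh.write(f"1\t{pos_of[v]}\t{v}\tA\tT\t.\t.\tGENE={gene_of[v]}\t"
                     "GT:AD:DP\t" + "\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# Single-cell matrices and truth logs
# ---------------------------------------------------------------------------

def write_sc_matrix(matrix: pd.DataFrame, path: str | Path,
                    cfg_hash: str | None = None) -> None:
    write_table(matrix, path, cfg_hash)


def read_sc_matrix(path: str | Path) -> pd.DataFrame:
    df = read_table(path)
    required = {"cell_id", "lineage", "car_flag"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: missing {required - set(df.columns)}")
    df["car_flag"] = df["car_flag"].astype(bool)
    return df


def write_truth_log(truth_log: dict, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(truth_log, fh, indent=1, default=str)


# ---------------------------------------------------------------------------
# Run configuration and pipeline
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    observations: str
    out_dir: str
    sc_matrix: str | None = None
    clinical: str | None = None
    obs_format: str = "tsv"
    epsilon: float = 0.001
    fdr_alpha: float = 0.05
    clinical_vaf: float = 0.02
    pre_max_day: int = 0
    post_min_day: int = 25
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        if not Path(self.observations).exists():
            raise FileNotFoundError(self.observations)
        for p in (self.sc_matrix, self.clinical):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)
        if not (0 < self.fdr_alpha < 1 and 0 <= self.clinical_vaf < 1
                and 0 < self.epsilon < 0.1):
            raise ValueError("threshold outside documented range")


def run_pipeline(config: RunConfig) -> dict:
    """Execute build -> pair -> select -> doubling (-> sc-arch) (-> cohort).

    Writes every stage table into ``config.out_dir`` plus a JSON manifest
    with package version, seed, thresholds, and the config hash. Returns the
    results bundle in memory. A stage failure halts the run but leaves a
    partial-results manifest on disk.
    """
    from . import __version__, longitudinal, single_cell

    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    h = config_hash(config)
    manifest = {"version": __version__, "seed": config.seed,
                "config_hash": h,
                "thresholds": {"epsilon": config.epsilon,
                               "fdr_alpha": config.fdr_alpha,
                               "clinical_vaf": config.clinical_vaf,
                               "pre_max_day": config.pre_max_day,
                               "post_min_day": config.post_min_day},
                "stages": []}
    bundle: dict = {"manifest": manifest}

    def finish_stage(name: str) -> None:
        manifest["stages"].append(name)
        with open(out / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=1)

    try:
        obs = read_observations(config.observations, config.obs_format)
        bundle["observations"] = obs
        finish_stage("read")

        trajectories = longitudinal.build_trajectories(obs)
        bundle["trajectories"] = trajectories
        finish_stage("track")

        paired = longitudinal.pair_pre_post(
            trajectories, config.pre_max_day, config.post_min_day,
            config.epsilon)
        write_table(paired, out / "paired_deltas.tsv", h)
        bundle["paired_deltas"] = paired
        finish_stage("pair")

        selection = longitudinal.gene_selection_test(paired, config.fdr_alpha)
        write_table(selection, out / "selection.tsv", h)
        bundle["selection"] = selection
        finish_stage("select")

        estimates = [e for e in (longitudinal.estimate_growth(t)
                                 for t in trajectories) if e is not None]
        est_df = longitudinal.estimates_to_frame(estimates)
        write_table(est_df, out / "doubling_times.tsv", h)
        gene_td = longitudinal.summarize_gene_doubling(estimates)
        write_table(gene_td, out / "gene_doubling.tsv", h)
        bundle["doubling"] = est_df
        bundle["gene_doubling"] = gene_td
        finish_stage("doubling")

        frac = longitudinal.fraction_increased(paired)
        write_table(frac, out / "fraction_increased.tsv", h)
        bundle["fraction_increased"] = frac
        finish_stage("fraction_increased")

        competition = []
        by_patient: dict[str, list] = {}
        for t in trajectories:
            if t.compartment == "cfDNA":
                by_patient.setdefault(t.patient_id, []).append(t)
        for pid, trs in sorted(by_patient.items()):
            if len(trs) >= 2:
                rep = longitudinal.detect_clonal_competition(trs)
                competition.append({
                    "patient_id": pid, "competing": rep.competing,
                    "dominant_variant": rep.dominant_variant or "NA",
                    "declining_variant": rep.declining_variant or "NA"})
        comp_df = pd.DataFrame(
            competition, columns=["patient_id", "competing",
                                  "dominant_variant", "declining_variant"])
        write_table(comp_df, out / "competition.tsv", h)
        bundle["competition"] = comp_df
        finish_stage("compete")

        if config.sc_matrix is not None:
            matrix = read_sc_matrix(config.sc_matrix)
            clones, unassigned = single_cell.assign_clones(matrix)
            clone_df = pd.DataFrame([
                {"clone_id": c.clone_id,
                 "variant_set": ";".join(sorted(c.variant_set)) or ".",
                 "n_cells": c.n_cells, "car_pos_cells": c.car_pos_cells}
                for c in clones])
            write_table(clone_df, out / "clones.tsv", h)
            edges = single_cell.infer_hierarchy(clones)
            edge_df = pd.DataFrame([
                {"parent": e.parent_clone, "child": e.child_clone,
                 "gained": ";".join(sorted(e.gained_variants)),
                 "pattern": e.pattern} for e in edges],
                columns=["parent", "child", "gained", "pattern"])
            write_table(edge_df, out / "hierarchy.tsv", h)
            pen = single_cell.gene_penetrance_rollup(clones)
            write_table(pen, out / "penetrance.tsv", h)
            bundle["clones"] = clones
            bundle["hierarchy"] = edges
            bundle["penetrance"] = pen
            finish_stage("sc-arch")
        else:
            manifest["stages"].append("sc-arch:skipped (no matrix input)")

        if config.clinical is not None:
            from .cohort import ClinicalRecord, classification_table, classify_patient
            clin = read_table(config.clinical)
            classifications = []
            for rec in clin.itertuples():
                record = ClinicalRecord(
                    patient_id=str(rec.patient_id),
                    cytopenic=bool(rec.cytopenic),
                    tmn_flag=bool(getattr(rec, "tmn_flag", False)))
                pv = obs[(obs["patient_id"] == record.patient_id)
                         & (obs["day"] >= config.post_min_day)]
                pv = (pv.sort_values("day").groupby("variant_id").tail(1)
                      [["variant_id", "vaf", "detectable"]])
                classifications.append(
                    classify_patient(record, pv, config.clinical_vaf))
            cls_df = classification_table(classifications)
            write_table(cls_df, out / "classification.tsv", h)
            bundle["classification"] = cls_df
            finish_stage("cohort")
        else:
            manifest["stages"].append("cohort:skipped (no clinical input)")

        finish_stage("done")
    except Exception:
        manifest["stages"].append("FAILED")
        with open(out / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=1)
        raise
    return bundle
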