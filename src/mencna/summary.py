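"""Cohort-level descriptive outputs.

Demographics, per-gene mutation recurrence across patients, CNA-feature
recurrence stratified by NF2 status, and an oncoprint-style sample x feature
landscape matrix. A small example cohort (10 meningioma patients whose
tumours progressed in WHO grade, with their panel variant calls) is bundled
as plain TSV for worked examples.

Stratified percentages always use patient-level denominators; tumour counts
are reported alongside as explicit numerators, with replicate samples of one
tumour counted once.
"""

from __future__ import annotations

from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cna import SegmentCall

ARM_LEVEL_TYPES = ("LOSS", "GAIN", "LOH", "ABERRANT")


def load_example_cohort() -> tuple[pd.DataFrame, pd.DataFrame]:
    """Bundled example cohort: (baseline characteristics, variant calls)."""
    base = resources.files("mencna.data")
    patients = pd.read_csv(base / "cohort_baseline.tsv", sep="\t")
    variants = pd.read_csv(base / "cohort_variants.tsv", sep="\t")
    return patients, variants


def summarize_demographics(records: pd.DataFrame) -> dict:
    """Mean/range age, sex counts, radiation fraction, grade distributions."""
    rec = records
    if len(rec) == 0:
        raise ValueError("empty patient table")
    for col in ("initial_grade", "final_grade"):
        bad = ~rec[col].isin([1, 2, 3])
        if bad.any():
            raise ValueError(f"invalid WHO grade in {col}: "
                             f"{sorted(rec.loc[bad, col].unique())}")
    if (rec["final_grade"] < rec["initial_grade"]).any():
        raise ValueError("final grade below initial grade (progression cohort)")
    if (rec["age_at_diagnosis"] <= 0).any():
        raise ValueError("non-positive age")
    return {
        "n_patients": int(len(rec)),
        "mean_age": float(rec["age_at_diagnosis"].mean()),
        "min_age": int(rec["age_at_diagnosis"].min()),
        "max_age": int(rec["age_at_diagnosis"].max()),
        "sex_counts": rec["sex"].value_counts().to_dict(),
        "radiation_fraction": float((rec["radiation"] == "Yes").mean()),
        "ecog_counts": rec["ecog"].value_counts().sort_index().to_dict()
        if "ecog" in rec.columns else {},
        "initial_grade_counts": rec["initial_grade"].value_counts().sort_index().to_dict(),
        "final_grade_counts": rec["final_grade"].value_counts().sort_index().to_dict(),
        "progressed_to_grade3": int((rec["final_grade"] == 3).sum()),
    }


def count_mutation_recurrence(variants: pd.DataFrame,
                              n_patients: int | None = None) -> pd.DataFrame:
    """Per-gene patient recurrence of kept variants.

    Returns one row per gene: n_patients with >= 1 variant, patient fraction,
    and the maximum number of distinct variants any single patient carries in
    the gene (distinct by the ``variant`` label if present, else by site).
    """
    if len(variants) == 0:
        return pd.DataFrame(columns=["gene_id", "n_patients", "patient_fraction",
                                     "max_distinct_variants"])
    v = variants.copy()
    if "variant" not in v.columns:
        v["variant"] = (v["chrom"].astype(str) + ":" + v["pos"].astype(str)
                        + v["ref"] + ">" + v["alt"])
    total = n_patients if n_patients is not None else v["patient_id"].nunique()
    per_gene = v.groupby("gene_id").agg(
        n_patients=("patient_id", "nunique"))
    distinct = (v.drop_duplicates(["gene_id", "patient_id", "variant"])
                .groupby(["gene_id", "patient_id"]).size()
                .groupby("gene_id").max())
    per_gene["patient_fraction"] = per_gene["n_patients"] / total
    per_gene["max_distinct_variants"] = distinct
    return (per_gene.reset_index()
            .sort_values(["n_patients", "gene_id"], ascending=[False, True])
            .reset_index(drop=True))


def distinct_variants_for(variants: pd.DataFrame, patient_id: str,
                          gene_id: str) -> int:
    v = variants[(variants["patient_id"] == patient_id)
                 & (variants["gene_id"] == gene_id)]
    label = v["variant"] if "variant" in v.columns else (
        v["chrom"].astype(str) + ":" + v["pos"].astype(str))
    return int(label.nunique())


def _collapse_replicates(sample_map: pd.DataFrame) -> pd.DataFrame:
    sm_tab = sample_map.copy()
    if "replicate_of" not in sm_tab.columns:
        sm_tab["replicate_of"] = None
    sm_tab["tumour_id"] = sm_tab["replicate_of"].where(
        sm_tab["replicate_of"].notna(), sm_tab["sample_id"])
    return sm_tab


def tumour_features(calls: Sequence[SegmentCall]) -> set[str]:
    """Arm-level CNA feature keys for one tumour, e.g. ``LOSS 1p``.

    Arm-level (non-focal) types yield ``TYPE chrom-arm`` keys; when both arms
    of a chromosome carry the same type the two collapse into a
    whole-chromosome key (``LOSS 10``). Focal types yield
    ``FOCAL_* chrom-arm`` keys.
    """
    by_chrom: dict[tuple[str, str], set[str]] = {}
    feats: set[str] = set()
    for s in calls:
        short = s.chrom.removeprefix("chr")
        if s.cna_type in ARM_LEVEL_TYPES:
            by_chrom.setdefault((short, s.cna_type), set()).add(s.arm)
        else:
            feats.add(f"{s.cna_type} {short}{s.arm}")
    for (short, ctype), arms in by_chrom.items():
        if arms >= {"p", "q"}:
            feats.add(f"{ctype} {short}")
        else:
            for arm in arms:
                feats.add(f"{ctype} {short}{arm}")
    return feats


def recurrence_by_feature(calls_by_sample: Mapping[str, Sequence[SegmentCall]],
                          sample_map: pd.DataFrame,
                          nf2_flags: Mapping[str, bool]) -> pd.DataFrame:
    """CNA feature recurrence with NF2-stratified patient percentages."""
    sm_tab = _collapse_replicates(sample_map)
    rows = []
    for tumour_id, tsub in sm_tab.groupby("tumour_id", sort=True):
        feats: set[str] = set()
        for s in tsub["sample_id"]:
            feats |= tumour_features(calls_by_sample[s])
        patient = tsub["patient_id"].iloc[0]
        for f in feats:
            rows.append((f, patient, tumour_id))
    if not rows:
        return pd.DataFrame(columns=["feature", "n_patients", "n_tumours",
                                     "pct_nf2_mutant", "pct_nf2_not_detected"])
    long = pd.DataFrame(rows, columns=["feature", "patient_id", "tumour_id"])
    patients = sm_tab["patient_id"].unique()
    n_mut = sum(bool(nf2_flags.get(p, False)) for p in patients)
    n_wt = len(patients) - n_mut

    out = []
    for feature, fsub in long.groupby("feature", sort=True):
        pset = set(fsub["patient_id"])
        k_mut = sum(bool(nf2_flags.get(p, False)) for p in pset)
        k_wt = len(pset) - k_mut
        out.append({
            "feature": feature,
            "n_patients": len(pset),
            "n_tumours": fsub["tumour_id"].nunique(),
            "pct_nf2_mutant": 100.0 * k_mut / n_mut if n_mut else np.nan,
            "pct_nf2_not_detected": 100.0 * k_wt / n_wt if n_wt else np.nan,
        })
    return (pd.DataFrame(out)
            .sort_values(["n_patients", "feature"], ascending=[False, True])
            .reset_index(drop=True))


def landscape_matrix(variants: pd.DataFrame,
                     calls_by_sample: Mapping[str, Sequence[SegmentCall]],
                     sample_map: pd.DataFrame) -> pd.DataFrame:
    """Sample x feature categorical matrix for oncoprint-style plotting.

    Mutation columns (``MUT <gene>``) hold "MUT"; CNA columns
    (``CNA <feature>``) hold the CNA type; empty cells hold "". Rows are
    ordered by patient then sample id.
    """
    sm_tab = sample_map.sort_values(["patient_id", "sample_id"])
    known = set(sm_tab["sample_id"])
    orphans = sorted(set(variants["sample_id"].unique()) - known) if len(variants) else []
    orphans += sorted(set(calls_by_sample) - known)
    if orphans:
        raise ValueError(f"samples absent from sample map: {orphans}")

    cells: dict[tuple[str, str], str] = {}
    for _, row in (variants.iterrows() if len(variants) else iter([])):
        cells[(row["sample_id"], f"MUT {row['gene_id']}")] = "MUT"
    for sample_id, calls in calls_by_sample.items():
        for f in tumour_features(calls):
            ctype, region = f.split(" ", 1)
            cells[(sample_id, f"CNA {region}")] = ctype

    columns = sorted({c for _, c in cells})
    mat = pd.DataFrame("", index=list(sm_tab["sample_id"]), columns=columns)
    for (sample_id, col), val in cells.items():
        mat.loc[sample_id, col] = val
    mat.index.name = "sample_id"
    return mat
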