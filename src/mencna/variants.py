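"""Somatic variant filter cascade and within-cohort recurrence annotation.

A putative variant table (one row per variant call per sample) is reduced to
a high-confidence set of likely somatic mutations by a conjunction of rules:

* synonymous changes are dropped (no expected functional effect),
* a minimum depth of coverage removes poorly mapped regions,
* VAF below 0.1 is dropped as likely FFPE/sequencing artefact and VAF above
  0.9 as likely homozygous germline (the closed band [0.1, 0.9] is kept),
* population allele frequency above 1e-4 is dropped as likely germline
  polymorphism (a missing frequency counts as 0: absent from the database).

Membership in the kept set is order-free; the per-rule removal counts in the
report attribute each removed record to the first failing rule in a fixed
canonical order (synonymous, depth, VAF-low, VAF-high, population frequency).

Kept variants are then annotated with their recurrence across the cohort:
the fraction of distinct patients carrying the identical change. Highly
recurrent variants are flagged (likely unfiltered germline or artefact) but
never removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

REQUIRED_COLUMNS = ("sample_id", "gene_id", "chrom", "pos", "ref", "alt",
                    "consequence", "depth", "vaf", "pop_freq")

RULE_ORDER = ("synonymous", "low_depth", "low_vaf", "high_vaf", "pop_freq")


class VariantValidationError(ValueError):
    pass


@dataclass(frozen=True)
class FilterThresholds:
    """Cut-offs of the somatic filter cascade (defaults per the method)."""

    min_depth: int = 50
    vaf_min: float = 0.1
    vaf_max: float = 0.9
    max_pop_freq: float = 0.0001
    drop_synonymous: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.vaf_min < self.vaf_max <= 1.0:
            raise ValueError("need 0 <= vaf_min < vaf_max <= 1")
        if self.min_depth < 0:
            raise ValueError("min_depth must be non-negative")


@dataclass
class FilterReport:
    n_in: int
    n_kept: int
    removed_by_rule: dict[str, int] = field(default_factory=dict)
    flags: pd.DataFrame | None = None  # per-record pass/fail per rule

    def to_dict(self) -> dict:
        return {"n_in": self.n_in, "n_kept": self.n_kept,
                "removed_by_rule": dict(self.removed_by_rule)}


def validate_variants(records: pd.DataFrame) -> pd.DataFrame:
    missing = set(REQUIRED_COLUMNS) - set(records.columns)
    if missing:
        raise VariantValidationError(f"variant table missing columns: {sorted(missing)}")
    rec = records.copy()
    rec["pop_freq"] = rec["pop_freq"].fillna(0.0)
    bad = rec[(rec["vaf"] < 0) | (rec["vaf"] > 1)]
    if not bad.empty:
        r = bad.iloc[0]
        raise VariantValidationError(
            f"VAF outside [0,1] for {r['sample_id']} {r['chrom']}:{r['pos']} "
            f"{r['ref']}>{r['alt']} (vaf={r['vaf']})")
    if (rec["depth"] < 0).any():
        raise VariantValidationError("negative depth in variant table")
    return rec


def rule_flags(records: pd.DataFrame, thresholds: FilterThresholds) -> pd.DataFrame:
    """Boolean failure indicator per record per rule (True = rule removes it)."""
    t = thresholds
    flags = pd.DataFrame(index=records.index)
    flags["synonymous"] = t.drop_synonymous & (records["consequence"] == "synonymous")
    flags["low_depth"] = records["depth"] < t.min_depth
    flags["low_vaf"] = records["vaf"] < t.vaf_min
    flags["high_vaf"] = records["vaf"] > t.vaf_max
    flags["pop_freq"] = records["pop_freq"] > t.max_pop_freq
    return flags


def apply_filters(records: pd.DataFrame,
                  thresholds: FilterThresholds = FilterThresholds(),
                  ) -> tuple[pd.DataFrame, FilterReport]:
    """Return (kept records, report). Kept = records failing no rule."""
    rec = validate_variants(records)
    flags = rule_flags(rec, thresholds)
    any_fail = flags.any(axis=1)
    kept = rec[~any_fail].reset_index(drop=True)

    removed: dict[str, int] = {}
    unattributed = flags.copy()
    for rule in RULE_ORDER:
        first_fail = unattributed[rule]
        removed[rule] = int(first_fail.sum())
        unattributed = unattributed[~first_fail]
    report = FilterReport(n_in=len(rec), n_kept=len(kept),
                          removed_by_rule=removed, flags=flags)
    return kept, report


def annotate_cohort_frequency(kept: pd.DataFrame,
                              sample_to_patient: pd.Series | dict,
                              recurrent_flag_threshold: float = 0.5,
                              ) -> pd.DataFrame:
    """Annotate each kept variant with its within-cohort patient frequency.

    ``cohort_freq`` = distinct patients carrying the identical
    (chrom, pos, ref, alt) change / total patients. Replicate samples of one
    tumour map to the same patient and therefore count once. Variants above
    ``recurrent_flag_threshold`` get ``recurrent_flag=True`` (likely
    unfiltered germline polymorphism or artefact) but are not removed.
    """
    if len(kept) == 0:
        out = kept.copy()
        out["cohort_freq"] = pd.Series(dtype=float)
        out["recurrent_flag"] = pd.Series(dtype=bool)
        return out
    mapping = pd.Series(sample_to_patient)
    out = kept.copy()
    if "patient_id" not in out.columns:
        out["patient_id"] = out["sample_id"].map(mapping)
    else:
        out["patient_id"] = out["patient_id"].fillna(out["sample_id"].map(mapping))
    unknown = out["patient_id"].isna()
    if unknown.any():
        raise VariantValidationError(
            f"samples with no patient mapping: {sorted(out.loc[unknown, 'sample_id'].unique())}")
    n_patients = mapping.nunique() if len(mapping) else out["patient_id"].nunique()
    key = ["chrom", "pos", "ref", "alt"]
    per_variant = out.groupby(key)["patient_id"].nunique() / n_patients
    out["cohort_freq"] = out.set_index(key).index.map(per_variant)
    out["recurrent_flag"] = out["cohort_freq"] > recurrent_flag_threshold
    return out
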