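"""Association between genomic aberrations and copy-number load.

Each patient contributes one observation: the mean, over their (distinct)
tumours, of the fraction of panel genes carrying any copy-number change
(1/0 per gene per tumour, irrespective of the CNA type). Averaging within
patients avoids the strong correlation among samples from the same patient;
replicate samples of one tumour are collapsed first.

The load is regressed on a binary aberration flag (e.g. NF2-mutant) with a
logit-link quasibinomial GLM: binomial-family IRLS with unit prior weights
and a freely estimated dispersion phi = Pearson chi^2 / (n - 2). The group
coefficient is tested with a Wald t statistic on n - 2 degrees of freedom,
matching the common quasibinomial-on-proportions idiom. P-values across a
screen of flags are adjusted with the Benjamini-Hochberg step-up.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cna import SegmentCall
from .panel import PanelDesign


@dataclass
class PatientAggregate:
    patient_id: str
    copy_load: float
    n_tumours: int
    flags: dict[str, bool]

    def __post_init__(self) -> None:
        if not 0.0 <= self.copy_load <= 1.0:
            raise ValueError(f"copy_load must be in [0,1], got {self.copy_load}")


@dataclass
class AssociationResult:
    flag: str
    coef: float
    se: float
    dispersion: float
    statistic: float
    p_value: float
    q_value: float | None
    n_flagged: int
    n_unflagged: int
    estimable: bool = True


def tumour_gene_changed(calls: Sequence[SegmentCall],
                        panel: PanelDesign) -> pd.Series:
    """1/0 per panel gene: covered by any segment call (all six types)."""
    genes = panel.gene_order()
    changed = pd.Series(0, index=genes["gene_id"], dtype=int)
    for seg in calls:
        changed[list(seg.gene_ids)] = 1
    return changed


def aggregate_patient_copy_load(
    calls_by_sample: Mapping[str, Sequence[SegmentCall]],
    panel: PanelDesign,
    sample_map: pd.DataFrame,
    patient_flags: Mapping[str, Mapping[str, bool]] | None = None,
) -> list[PatientAggregate]:
    """Per-patient averaged binary copy-number load.

    ``sample_map`` needs columns sample_id, patient_id and optionally
    replicate_of; replicates are collapsed onto their source tumour (gene
    counted as changed if changed in any replicate) before the per-patient
    mean over tumours.
    """
    sm_tab = sample_map.copy()
    if "replicate_of" not in sm_tab.columns:
        sm_tab["replicate_of"] = None
    missing = [s for s in sm_tab["sample_id"] if s not in calls_by_sample]
    if missing:
        raise KeyError(f"no call table for samples: {missing}")
    sm_tab["tumour_id"] = sm_tab["replicate_of"].where(
        sm_tab["replicate_of"].notna(), sm_tab["sample_id"])

    aggregates = []
    for patient_id, psub in sm_tab.groupby("patient_id", sort=True):
        tumour_loads = []
        for _, tsub in psub.groupby("tumour_id", sort=True):
            vecs = [tumour_gene_changed(calls_by_sample[s], panel)
                    for s in tsub["sample_id"]]
            merged = (pd.concat(vecs, axis=1).max(axis=1)
                      if len(vecs) > 1 else vecs[0])
            tumour_loads.append(float(merged.mean()))
        flags = dict((patient_flags or {}).get(patient_id, {}))
        aggregates.append(PatientAggregate(
            patient_id=patient_id, copy_load=float(np.mean(tumour_loads)),
            n_tumours=len(tumour_loads), flags=flags))
    return aggregates


def fit_quasibinomial(aggregates: Sequence[PatientAggregate],
                      flag: str) -> AssociationResult:
    """Quasibinomial GLM of copy_load on one binary aberration flag."""
    y = np.array([a.copy_load for a in aggregates], dtype=float)
    g = np.array([bool(a.flags.get(flag, False)) for a in aggregates])
    n = len(y)
    n1, n0 = int(g.sum()), int((~g).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError(f"flag {flag!r} must split patients into two "
                         f"non-empty groups (got {n1} vs {n0})")
    df_resid = n - 2
    if df_resid <= 0:
        raise ValueError("need at least 3 patients")

    # separation: a group pinned at 0 or 1 has a diverging log-odds coefficient
    m1, m0 = y[g].mean(), y[~g].mean()
    if m1 in (0.0, 1.0) or m0 in (0.0, 1.0):
        sign = np.sign(m1 - m0) if m1 != m0 else 0.0
        return AssociationResult(flag=flag, coef=float(sign * np.inf),
                                 se=np.nan, dispersion=np.nan,
                                 statistic=np.nan, p_value=np.nan,
                                 q_value=None, n_flagged=n1, n_unflagged=n0,
                                 estimable=False)

    X = sm.add_constant(g.astype(float))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # non-integer binomial endog
        model = sm.GLM(y, X, family=sm.families.Binomial())
        res = model.fit(scale="X2")
    coef = float(res.params[1])
    se = float(res.bse[1])
    phi = float(res.scale)
    t_stat = coef / se
    p = float(2 * stats.t.sf(abs(t_stat), df=df_resid))
    return AssociationResult(flag=flag, coef=coef, se=se, dispersion=phi,
                             statistic=t_stat, p_value=p, q_value=None,
                             n_flagged=n1, n_unflagged=n0)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, preserving input order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def association_screen(aggregates: Sequence[PatientAggregate],
                       flags: Sequence[str]) -> pd.DataFrame:
    """One quasibinomial model per aberration flag; BH across the screen."""
    results = [fit_quasibinomial(aggregates, f) for f in flags]
    estimable = [r for r in results if r.estimable]
    if estimable:
        q = bh_adjust([r.p_value for r in estimable])
        for r, qv in zip(estimable, q):
            r.q_value = float(qv)
    rows = [{
        "flag": r.flag, "coef": r.coef, "se": r.se, "dispersion": r.dispersion,
        "statistic": r.statistic, "p_value": r.p_value, "q_value": r.q_value,
        "n_flagged": r.n_flagged, "n_unflagged": r.n_unflagged,
        "estimable": r.estimable,
    } for r in results]
    return pd.DataFrame(rows)
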