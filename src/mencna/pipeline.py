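"""Pipeline driver: simulate -> filter -> call CNA -> associate -> summarize.

All randomness flows from a single top-level seed, expanded per stage and per
sample through ``numpy.random.SeedSequence`` spawn keys, so a rerun with the
same configuration and inputs reproduces every output byte for byte (the run
manifest records per-file checksums to support that claim).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from .association import (PatientAggregate, aggregate_patient_copy_load,
                          association_screen)
from .cna import (CnaThresholds, SegmentationResult, call_segments,
                  compute_baf, compute_lfc, fit_gmm_1d, infer_sex)
from .simulate import CohortBundle, SimulationConfig, simulate_cohort
from .summary import landscape_matrix, recurrence_by_feature
from .variants import FilterThresholds, annotate_cohort_frequency, apply_filters

log = logging.getLogger("mencna")


@dataclass
class PipelineConfig:
    out_dir: str
    seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    filter_thresholds: FilterThresholds = field(default_factory=FilterThresholds)
    cna_thresholds: CnaThresholds = field(default_factory=CnaThresholds)
    flags: tuple[str, ...] = ("NF2",)
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        self.simulation.seed = self.seed
        self.simulation.validate()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "out_dir" not in raw:
            raise ValueError("pipeline config must set out_dir")
        sim = SimulationConfig(**{
            k: (tuple(v) if isinstance(v, list) else v)
            for k, v in raw.get("simulation", {}).items()})
        filt = FilterThresholds(**raw.get("filter_thresholds", {}))
        cna = CnaThresholds(**{
            k: (tuple(v) if isinstance(v, list) else v)
            for k, v in raw.get("cna_thresholds", {}).items()})
        return cls(out_dir=raw["out_dir"], seed=int(raw.get("seed", 0)),
                   simulation=sim, filter_thresholds=filt, cna_thresholds=cna,
                   flags=tuple(raw.get("flags", ("NF2",))),
                   log_level=raw.get("log_level", "INFO"))

    def config_hash(self) -> str:
        payload = json.dumps({
            "seed": self.seed, "simulation": asdict(self.simulation),
            "filter": asdict(self.filter_thresholds),
            "cna": asdict(self.cna_thresholds), "flags": list(self.flags),
        }, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    version: str
    config_hash: str
    seed: int
    checksums: dict[str, str]
    started: float
    finished: float

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class CohortResults:
    """In-memory pipeline products for one cohort."""

    bundle: CohortBundle
    kept_variants: pd.DataFrame
    filter_reports: dict[str, dict]
    segmentation: dict[str, SegmentationResult]
    sexes: dict[str, str]
    aggregates: list[PatientAggregate]
    association: pd.DataFrame


def gmm_seed(base_seed: int, stage: int, index: int) -> int:
    """Stable per-stage/per-sample sub-seed below 2**31."""
    ss = np.random.SeedSequence(entropy=base_seed, spawn_key=(stage, index))
    return int(ss.generate_state(1)[0] % (2 ** 31))


def call_sample_cna(depth: pd.DataFrame, snp_counts: pd.DataFrame, panel,
                    thresholds: CnaThresholds, seed: int) -> SegmentationResult:
    """Run the full per-sample CNA chain (LFC, BAF, two GMMs, segmentation)."""
    lfc = compute_lfc(depth, panel)
    baf = compute_baf(snp_counts, panel, thresholds)
    lfc_fit = fit_gmm_1d(lfc.table["lfc"], thresholds.k_range, seed=seed,
                         n_restarts=thresholds.n_restarts)
    baf_fit = fit_gmm_1d(baf.table["baf"], thresholds.k_range, seed=seed,
                         n_restarts=thresholds.n_restarts)
    return call_segments(lfc, baf, lfc_fit, baf_fit, panel.arms, thresholds)


def patient_flags_from_variants(kept: pd.DataFrame, patients: list[str],
                                flag_genes: tuple[str, ...]) -> dict[str, dict[str, bool]]:
    flags: dict[str, dict[str, bool]] = {p: {} for p in patients}
    for gene in flag_genes:
        carriers = set(kept.loc[kept["gene_id"] == gene, "patient_id"])
        for p in patients:
            flags[p][gene] = p in carriers
    return flags


def process_cohort(bundle: CohortBundle,
                   filter_thresholds: FilterThresholds = FilterThresholds(),
                   cna_thresholds: CnaThresholds = CnaThresholds(),
                   flags: tuple[str, ...] = ("NF2",),
                   seed: Optional[int] = None) -> CohortResults:
    """Filter variants, call CNAs and run the association screen in memory."""
    seed = bundle.config.seed if seed is None else seed
    sample_map = bundle.sample_map()
    sample_to_patient = dict(zip(sample_map["sample_id"], sample_map["patient_id"]))

    kept_parts, reports = [], {}
    for s in bundle.samples:
        kept, report = apply_filters(s.variants, filter_thresholds)
        kept_parts.append(kept)
        reports[s.sample_id] = report.to_dict()
    kept_all = (pd.concat(kept_parts, ignore_index=True)
                if kept_parts else pd.DataFrame())
    if len(kept_all):
        kept_all = annotate_cohort_frequency(kept_all, sample_to_patient)

    segmentation, sexes = {}, {}
    for i, s in enumerate(bundle.samples):
        segmentation[s.sample_id] = call_sample_cna(
            s.depth, s.snp_counts, bundle.panel, cna_thresholds,
            seed=gmm_seed(seed, 20, i))
        sexes[s.sample_id] = infer_sex(s.depth)
        log.debug("sample %s: %d segments", s.sample_id,
                  len(segmentation[s.sample_id].segments))

    patients = list(bundle.patients["patient_id"])
    pflags = patient_flags_from_variants(kept_all, patients, flags) \
        if len(kept_all) else {p: {g: False for g in flags} for p in patients}
    calls_by_sample = {sid: r.segments for sid, r in segmentation.items()}
    aggregates = aggregate_patient_copy_load(
        calls_by_sample, bundle.panel, sample_map, pflags)
    usable = [f for f in flags
              if 0 < sum(a.flags.get(f, False) for a in aggregates) < len(aggregates)]
    association = association_screen(aggregates, usable) if usable else pd.DataFrame()
    return CohortResults(bundle=bundle, kept_variants=kept_all,
                         filter_reports=reports, segmentation=segmentation,
                         sexes=sexes, aggregates=aggregates,
                         association=association)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute every stage, write all stage outputs plus a manifest."""
    from . import __version__

    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    started = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    log.info("stage simulate: seed=%d", config.seed)
    bundle = simulate_cohort(config.simulation)
    mio.write_panel_bed(bundle.panel, out / "panel.bed")
    mio.write_snp_loci(bundle.panel, out / "snp_loci.tsv")
    mio.write_arms(bundle.panel.arms, out / "arms.tsv")
    bundle.sample_map().to_csv(out / "samples.tsv", sep="\t", index=False)
    bundle.patients.to_csv(out / "patients.tsv", sep="\t", index=False)
    sample_dir = out / "samples"
    sample_dir.mkdir(exist_ok=True)
    for s in bundle.samples:
        mio.write_depth_table(s.depth, sample_dir / f"{s.sample_id}.depth.tsv")
        mio.write_snp_counts(s.snp_counts, sample_dir / f"{s.sample_id}.snps.tsv")
    mio.write_variants(bundle.all_variants(), out / "variants.raw.tsv")
    mio.write_truth({s.sample_id: s.truth_events for s in bundle.samples},
                    out / "truth.json")

    log.info("stage filter + call-cna + associate")
    results = process_cohort(bundle, config.filter_thresholds,
                             config.cna_thresholds, config.flags,
                             seed=config.seed)
    mio.write_variants(results.kept_variants, out / "variants.kept.tsv")
    mio.write_json(results.filter_reports, out / "filter_report.json")
    seg_frames = []
    for sid, segres in results.segmentation.items():
        f = segres.to_frame()
        f.insert(0, "sample_id", sid)
        if len(f):
            seg_frames.append(f)
    if seg_frames:
        segments = pd.concat(seg_frames, ignore_index=True)
    else:
        segments = pd.DataFrame(columns=["sample_id", "chrom", "arm", "start",
                                         "end", "cna_type", "arm_fraction",
                                         "n_genes", "n_loci", "mean_lfc",
                                         "mean_fold", "gene_ids"])
    mio.write_segments(segments, out / "segments.tsv")
    mio.write_json({"inferred_sex": results.sexes}, out / "sex_check.json")
    pd.DataFrame([{"patient_id": a.patient_id, "copy_load": a.copy_load,
                   "n_tumours": a.n_tumours, **a.flags}
                  for a in results.aggregates]).to_csv(
        out / "aggregates.tsv", sep="\t", index=False)
    results.association.to_csv(out / "association.tsv", sep="\t", index=False)

    log.info("stage summarize")
    nf2_flags = {a.patient_id: bool(a.flags.get("NF2", False))
                 for a in results.aggregates}
    calls_by_sample = {sid: r.segments for sid, r in results.segmentation.items()}
    recurrence = recurrence_by_feature(calls_by_sample, bundle.sample_map(),
                                       nf2_flags)
    recurrence.to_csv(out / "cna_recurrence.tsv", sep="\t", index=False)
    landscape = landscape_matrix(results.kept_variants, calls_by_sample,
                                 bundle.sample_map())
    landscape.to_csv(out / "landscape.tsv", sep="\t")

    checksums = {str(p.relative_to(out)): _sha256(p)
                 for p in sorted(out.rglob("*")) if p.is_file()
                 and p.name != "manifest.json"}
    manifest = RunManifest(version=__version__,
                           config_hash=config.config_hash(), seed=config.seed,
                           checksums=checksums, started=started,
                           finished=time.time())
    mio.write_json(manifest.to_dict(), out / "manifest.json")
    return manifest
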