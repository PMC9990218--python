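"""Readers and writers for the pipeline's plain-text interchange formats.

TSV is the canonical interchange; BED carries the panel gene intervals and
VCF is accepted as a convenience dialect for variant input. Coordinates are
0-based half-open internally and in BED/TSV; VCF's 1-based positions are
converted on read. Every writer's output round-trips through its paired
reader.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .panel import PanelDesign
from .simulate import TruthEvent
from .variants import REQUIRED_COLUMNS, VariantValidationError


class FormatError(ValueError):
    pass


# --- panel -----------------------------------------------------------------

def write_panel_bed(panel: PanelDesign, path: str | Path) -> None:
    bed = panel.genes[["chrom", "start", "end", "gene_id"]]
    bed.to_csv(path, sep="\t", header=False, index=False)


def read_panel_bed(path: str | Path) -> pd.DataFrame:
    bed = pd.read_csv(path, sep="\t", header=None,
                      names=["chrom", "start", "end", "gene_id"])
    if bed[["start", "end"]].isna().any().any():
        raise FormatError(f"malformed BED file: {path}")
    return bed


def write_snp_loci(panel: PanelDesign, path: str | Path) -> None:
    panel.snp_loci.to_csv(path, sep="\t", index=False)


def read_snp_loci(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t",
                       dtype={"chrom": str, "pos": "int64"})


def write_arms(arms: pd.DataFrame, path: str | Path) -> None:
    arms.to_csv(path, sep="\t", index=False)


def read_arms(path: str | Path) -> pd.DataFrame:
    arms = pd.read_csv(path, sep="\t")
    missing = {"chrom", "arm", "start", "end"} - set(arms.columns)
    if missing:
        raise FormatError(f"arms table missing columns: {sorted(missing)}")
    return arms


# --- depth and SNP counts --------------------------------------------------

DEPTH_COLUMNS = ("gene_id", "chrom", "start", "end", "median_depth")


def write_depth_table(depth: pd.DataFrame, path: str | Path) -> None:
    depth[list(DEPTH_COLUMNS)].to_csv(path, sep="\t", index=False)


def read_depth_table(path: str | Path,
                     panel: PanelDesign | None = None) -> pd.DataFrame:
    tab = pd.read_csv(path, sep="\t")
    missing = set(DEPTH_COLUMNS) - set(tab.columns)
    if missing:
        raise FormatError(f"depth table missing columns: {sorted(missing)}")
    if panel is not None:
        known = set(panel.genes["gene_id"])
        extra = sorted(set(tab["gene_id"]) - known)
        if extra:
            raise FormatError(f"depth table has genes not in panel: {extra}")
        tab = (panel.genes[["gene_id"]]
               .merge(tab, on="gene_id", how="left"))
        if tab["median_depth"].isna().any():
            absent = tab.loc[tab["median_depth"].isna(), "gene_id"].tolist()
            raise FormatError(f"depth table missing panel genes: {absent[:5]}")
    return tab


def write_snp_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts[["chrom", "pos", "ref_count", "alt_count"]].to_csv(
        path, sep="\t", index=False)


def read_snp_counts(path: str | Path) -> pd.DataFrame:
    tab = pd.read_csv(path, sep="\t")
    missing = {"chrom", "pos", "ref_count", "alt_count"} - set(tab.columns)
    if missing:
        raise FormatError(f"SNP count table missing columns: {sorted(missing)}")
    return tab


# --- variants --------------------------------------------------------------

def write_variants(variants: pd.DataFrame, path: str | Path) -> None:
    variants.to_csv(path, sep="\t", index=False)


def read_variants(path: str | Path, dialect: str = "tsv") -> pd.DataFrame:
    """Read a variant table (TSV canonical; VCF convenience dialect).

    For VCF, per-sample records are built from INFO/FORMAT fields: GENE and
    CONSEQUENCE and POP_AF from INFO, depth and VAF from the DP and AF FORMAT
    fields. VCF 1-based POS is converted to the internal 0-based frame.
    """
    if dialect == "tsv":
        tab = pd.read_csv(path, sep="\t")
        missing = set(REQUIRED_COLUMNS) - set(tab.columns)
        if missing:
            raise FormatError(f"variant table missing columns: {sorted(missing)}")
        if len(tab) == 0:
            import warnings
            warnings.warn(f"empty variant table: {path}")
        return tab
    if dialect == "vcf":
        return _read_vcf(path)
    raise FormatError(f"unknown variant dialect {dialect!r}")


def _read_vcf(path: str | Path) -> pd.DataFrame:
    import pysam

    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        sample_names = list(vcf.header.samples)
        for i, rec in enumerate(vcf):
            try:
                gene = rec.info.get("GENE", ".")
                consequence = rec.info.get("CONSEQUENCE", "non_synonymous")
                pop = rec.info.get("POP_AF", 0.0)
                pop = float(pop[0] if isinstance(pop, tuple) else pop)
                for sname in sample_names:
                    fmt = rec.samples[sname]
                    dp, af = fmt.get("DP"), fmt.get("AF")
                    if dp is None or af is None:
                        continue
                    af = af[0] if isinstance(af, tuple) else af
                    rows.append((sname, gene, rec.chrom, rec.pos - 1, rec.ref,
                                 rec.alts[0] if rec.alts else ".", consequence,
                                 int(dp), float(af), pop))
            except (TypeError, ValueError, IndexError) as exc:
                raise FormatError(f"malformed VCF record near line {i + 1} "
                                  f"in {path}: {exc}") from exc
    return pd.DataFrame(rows, columns=["sample_id", "gene_id", "chrom", "pos",
                                       "ref", "alt", "consequence", "depth",
                                       "vaf", "pop_freq"])


# --- segments, aggregates, truth -------------------------------------------

def write_segments(segments_frame: pd.DataFrame, path: str | Path) -> None:
    segments_frame.to_csv(path, sep="\t", index=False)


def read_segments(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", keep_default_na=False,
                       dtype={"chrom": str, "arm": str, "cna_type": str})


def write_truth(events_by_sample: dict[str, list[TruthEvent]],
                path: str | Path) -> None:
    payload = {sid: [ev.to_dict() for ev in evs]
               for sid, evs in events_by_sample.items()}
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_truth(path: str | Path) -> dict[str, list[TruthEvent]]:
    payload = json.loads(Path(path).read_text())
    return {sid: [TruthEvent.from_dict(d) for d in evs]
            for sid, evs in payload.items()}


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True))


def require_variant_schema(tab: pd.DataFrame) -> pd.DataFrame:
    missing = set(REQUIRED_COLUMNS) - set(tab.columns)
    if missing:
        raise VariantValidationError(f"missing variant columns: {sorted(missing)}")
    return tab
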