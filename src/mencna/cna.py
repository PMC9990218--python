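"""Copy-number inference from panel depth and SNP allele fractions.

The method works from two per-sample signals on a shared panel frame:

* per-gene depth log-fold-change, ``LFC = log2(median gene depth / median
  sample depth)``, where the sample median (over autosomal genes) estimates
  the dominant baseline copy number;
* per-SNP B-allele fraction, ``BAF = alt / (ref + alt)``. A BAF near 0.5
  marks a heterozygous site, near 0 or 1 a homozygous site; deviations from
  those states mark allelic imbalance (loss, gain, or copy-neutral LOH).

Each signal is clustered independently with a 1-D Gaussian mixture model,
selecting the number of components that minimises the BIC. Genes take the
{loss, neutral, gain} label of their maximum-responsibility LFC component
(the neutral component is the one with mean nearest 0); runs of same-label
genes along a chromosome arm become segments, and segments are classified
into six types: LOSS/GAIN when the span covers at least a third of the arm,
FOCAL_LOSS/FOCAL_GAIN below that, LOH for depth-neutral allelic imbalance
consistent with clonal copy-neutral loss of heterozygosity, and ABERRANT
when the depth and BAF evidence clearly deviate from diploid but cannot be
assigned a single clean type (weak or conflicting signals, e.g. low purity
or subclonality).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.mixture import GaussianMixture

from .panel import AUTOSOMES, PanelDesign


class CnaError(ValueError):
    pass


@dataclass(frozen=True)
class CnaThresholds:
    """Tunable rule set replacing the original visual inspection step.

    ``delta_lfc`` separates loss/gain components from the neutral one on the
    LFC scale; ``delta_confident`` is the minimum |LFC offset| for a clean
    clonal LOSS/GAIN call (weaker deviations are typed ABERRANT);
    ``loh_min_fold`` is the minimum mean folded-BAF deviation for a clean
    clonal LOH call. All are method choices, configurable and documented.
    """

    delta_lfc: float = 0.3
    delta_confident: float = 0.4
    baf_het_band: float = 0.1
    baf_hom_band: float = 0.4
    min_locus_depth: int = 30
    gap_tolerance: int = 1      # BAF-scan runs
    depth_gap_tolerance: int = 4  # loss/gain runs bridge longer neutral gaps
    smoothing_window: int = 5   # odd; median filter over per-arm gene labels
    min_segment_genes: int = 3
    min_seed_genes: int = 2     # seeds required before the arm rescue pass
    aberrant_min_genes: int = 5  # weak (ABERRANT) depth runs below this are noise
    min_segment_loci: int = 10
    min_gene_loci: int = 5
    het_depletion_ratio: float = 0.5
    strong_depletion_ratio: float = 0.25
    gene_imbalance_fraction: float = 0.3
    segment_imbalance_fraction: float = 0.15
    loh_min_fold: float = 0.25
    fold_cap: float = 0.45
    arm_fraction_cut: float = 1.0 / 3.0
    k_range: tuple[int, int] = (1, 6)
    n_restarts: int = 5


@dataclass
class LfcProfile:
    table: pd.DataFrame          # gene_id, chrom, start, end, arm, lfc
    sample_median: float
    excluded_genes: list[str] = field(default_factory=list)


@dataclass
class BafProfile:
    table: pd.DataFrame          # chrom, pos, arm, gene_id, depth, baf, folded, band
    n_excluded: int = 0
    het_band: float = 0.1
    hom_band: float = 0.4


@dataclass
class MixtureFit:
    """A selected 1-D Gaussian mixture (components sorted by mean)."""

    k: int
    weights: np.ndarray
    means: np.ndarray
    variances: np.ndarray
    log_likelihood: float
    bic: float
    bic_by_k: dict[int, float]
    converged: bool
    seed: int
    n: int

    def to_dict(self) -> dict:
        return {
            "k": self.k, "weights": self.weights.tolist(),
            "means": self.means.tolist(), "variances": self.variances.tolist(),
            "log_likelihood": self.log_likelihood, "bic": self.bic,
            "bic_by_k": {str(k): v for k, v in self.bic_by_k.items()},
            "converged": self.converged, "seed": self.seed, "n": self.n,
        }


@dataclass(frozen=True)
class SegmentCall:
    chrom: str
    arm: str
    start: int
    end: int
    cna_type: str                # LOSS, GAIN, FOCAL_LOSS, FOCAL_GAIN, LOH, ABERRANT
    arm_fraction: float
    gene_ids: tuple[str, ...]
    n_loci: int
    mean_lfc: float
    mean_fold: float


@dataclass
class SegmentationResult:
    segments: list[SegmentCall]
    gene_labels: pd.DataFrame    # gene_id, chrom, arm, start, end, lfc, label
    leftover_runs: list[tuple[str, ...]]  # sub-minimal same-label runs (diagnostics)

    def to_frame(self) -> pd.DataFrame:
        rows = [{
            "chrom": s.chrom, "arm": s.arm, "start": s.start, "end": s.end,
            "cna_type": s.cna_type, "arm_fraction": s.arm_fraction,
            "n_genes": len(s.gene_ids), "n_loci": s.n_loci,
            "mean_lfc": s.mean_lfc, "mean_fold": s.mean_fold,
            "gene_ids": ",".join(s.gene_ids),
        } for s in self.segments]
        cols = ["chrom", "arm", "start", "end", "cna_type", "arm_fraction",
                "n_genes", "n_loci", "mean_lfc", "mean_fold", "gene_ids"]
        return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# profiles


def compute_lfc(depth_table: pd.DataFrame, panel: PanelDesign) -> LfcProfile:
    """Per-gene log2 depth ratio against the autosomal sample median."""
    genes = panel.gene_order()[["gene_id", "chrom", "start", "end", "arm"]]
    merged = genes.merge(depth_table[["gene_id", "median_depth"]], on="gene_id",
                         how="left")
    if merged["median_depth"].isna().any():
        missing = merged.loc[merged["median_depth"].isna(), "gene_id"].tolist()
        raise CnaError(f"depth table missing panel genes: {missing[:5]}")
    usable = merged["median_depth"] > 0
    if not usable.any():
        raise CnaError("no usable coverage: all gene depths are zero")
    sample_median = float(merged.loc[usable, "median_depth"].median())
    excluded = merged.loc[~usable, "gene_id"].tolist()
    out = merged[usable].copy()
    out["lfc"] = np.log2(out["median_depth"] / sample_median)
    out = out[["gene_id", "chrom", "start", "end", "arm", "lfc"]].reset_index(drop=True)
    return LfcProfile(table=out, sample_median=sample_median,
                      excluded_genes=excluded)


def compute_baf(snp_counts: pd.DataFrame, panel: PanelDesign,
                thresholds: CnaThresholds = CnaThresholds()) -> BafProfile:
    """BAF per locus with zygosity band labels from the folded deviation
    |BAF - 0.5| (HET within ``baf_het_band``, HOM beyond ``baf_hom_band``,
    IMBALANCED in between). Loci under ``min_locus_depth`` are excluded."""
    if (snp_counts[["ref_count", "alt_count"]] < 0).any().any():
        raise CnaError("negative allele counts")
    loci = panel.snp_loci[["chrom", "pos", "arm", "gene_id"]]
    merged = loci.merge(snp_counts, on=["chrom", "pos"], how="inner")
    merged["depth"] = merged["ref_count"] + merged["alt_count"]
    keep = merged["depth"] >= thresholds.min_locus_depth
    n_excluded = int((~keep).sum())
    out = merged[keep].copy()
    out["baf"] = out["alt_count"] / out["depth"]
    out["folded"] = (out["baf"] - 0.5).abs()
    het, hom = thresholds.baf_het_band, thresholds.baf_hom_band
    out["band"] = np.where(out["folded"] <= het, "HET",
                           np.where(out["folded"] > hom, "HOM", "IMBALANCED"))
    out = out[["chrom", "pos", "arm", "gene_id", "depth", "baf", "folded",
               "band"]].reset_index(drop=True)
    return BafProfile(table=out, n_excluded=n_excluded, het_band=het, hom_band=hom)


# ---------------------------------------------------------------------------
# mixture fitting


def fit_gmm_1d(values: Iterable[float], k_range: tuple[int, int] = (1, 6),
               seed: int = 0, n_restarts: int = 5,
               covariance_type: str = "tied") -> MixtureFit:
    """EM fit per K with restarts; return the BIC-minimal model.

    BIC = p ln(n) - 2 lnL; deterministic for a given seed. The default tied
    covariance shares one variance across components: per-gene LFC noise has
    a common scale, and an untied fit lets a dominant neutral component
    inflate its variance and swallow small loss/gain clusters.
    """
    x = np.asarray(list(values), dtype=float)
    x = x[np.isfinite(x)][:, None]
    n = len(x)
    ks = [k for k in range(k_range[0], k_range[1] + 1) if n >= 5 * k]
    if not ks:
        raise CnaError(f"too few values (n={n}) for K in {k_range}")
    fits, bic_by_k = {}, {}
    for k in ks:
        best = None
        # dual initialisation: k-means centres a dominant mode well, while
        # k-means++ seeding can isolate tiny clusters k-means merges away
        for init in ("kmeans", "k-means++"):
            gm = GaussianMixture(n_components=k, covariance_type=covariance_type,
                                 n_init=n_restarts, random_state=seed,
                                 max_iter=500, tol=1e-6, init_params=init)
            with warnings.catch_warnings():
                # non-convergence is handled explicitly via converged_
                warnings.simplefilter("ignore")
                gm.fit(x)
            if not gm.converged_:
                continue
            if best is None or gm.lower_bound_ > best.lower_bound_:
                best = gm
        if best is None:
            continue
        fits[k] = best
        bic_by_k[k] = float(best.bic(x))
    if not fits:
        raise CnaError(f"EM failed to converge for every K in {ks} (n={n})")
    best_k = min(bic_by_k, key=lambda k: (bic_by_k[k], k))
    gm = fits[best_k]
    order = np.argsort(gm.means_.ravel())
    if covariance_type == "tied":
        variances = np.full(best_k, float(gm.covariances_.ravel()[0]))
    else:
        variances = gm.covariances_.reshape(-1)[order].copy()
    return MixtureFit(
        k=best_k,
        weights=gm.weights_[order].copy(),
        means=gm.means_.ravel()[order].copy(),
        variances=variances,
        log_likelihood=float(gm.score(x) * n),
        bic=bic_by_k[best_k], bic_by_k=bic_by_k,
        converged=True, seed=seed, n=n,
    )


def responsibilities(fit: MixtureFit, values: np.ndarray) -> np.ndarray:
    """Posterior component membership probabilities, n x K."""
    x = np.asarray(values, dtype=float)[:, None]
    dens = fit.weights * norm.pdf(x, fit.means, np.sqrt(fit.variances))
    total = dens.sum(axis=1, keepdims=True)
    total[total == 0] = 1.0
    return dens / total


def neutral_component(fit: MixtureFit) -> int:
    """Component with mean nearest 0; ties broken toward larger weight."""
    d = np.abs(fit.means)
    best = np.flatnonzero(d == d.min())
    if len(best) > 1:
        best = best[np.argsort(-fit.weights[best])]
    return int(best[0])


# ---------------------------------------------------------------------------
# segmentation and classification


def _label_genes(lfc: LfcProfile, lfc_fit: MixtureFit,
                 thresholds: CnaThresholds) -> pd.DataFrame:
    tab = lfc.table.copy()
    resp = responsibilities(lfc_fit, tab["lfc"].to_numpy())
    comp = resp.argmax(axis=1)
    neutral = neutral_component(lfc_fit)
    offsets = lfc_fit.means - lfc_fit.means[neutral]
    comp_label = np.where(offsets < -thresholds.delta_lfc, "loss",
                          np.where(offsets > thresholds.delta_lfc, "gain",
                                   "neutral"))
    tab["component"] = comp
    tab["label"] = comp_label[comp]
    tab["offset"] = offsets[comp]
    tab["neutral_mean"] = lfc_fit.means[neutral]
    return tab


def _rescue_arm_labels(sub: pd.DataFrame, fit: MixtureFit,
                       thresholds: CnaThresholds) -> list[str]:
    """Equal-prior relabelling on arms that carry a loss/gain seed.

    Max-responsibility assignment under a dominant neutral component pushes
    the decision boundary toward a rare loss/gain component and shears off
    part of a true event run. On arms where at least one gene already took a
    non-neutral label, neutral genes are reassigned to the nearest component
    mean (variance-scaled, weights ignored) among the labels present there.
    Arms with no seed are left untouched, so the pass cannot invent events
    on a quiet genome.
    """
    labels = np.asarray(sub["label"].tolist())
    present = {t for t in set(labels) - {"neutral"}
               if (labels == t).sum() >= thresholds.min_seed_genes}
    if not present:
        return list(labels)
    neutral = neutral_component(fit)
    lfc = sub["lfc"].to_numpy()
    # centre of each class: neutral from the fit, loss/gain from the arm's
    # own seed genes (fitted means of rare components drift on to outliers)
    centres = {"neutral": float(fit.means[neutral])}
    for target in present:
        centres[target] = float(lfc[labels == target].mean())
    names = list(centres)
    dist = np.abs(lfc[:, None] - np.array([centres[c] for c in names]))
    return [names[i] for i in dist.argmin(axis=1)]


def _smooth_labels(labels: list[str], window: int) -> list[str]:
    """Median-filter {loss, neutral, gain} labels along an arm.

    Removes isolated misassignments that would otherwise fragment a run;
    a 3-gene focal block survives the default window of 5.
    """
    if window <= 1 or len(labels) < 3:
        return list(labels)
    code = {"loss": -1, "neutral": 0, "gain": 1}
    inv = {-1: "loss", 0: "neutral", 1: "gain"}
    x = np.array([code[l] for l in labels])
    half = window // 2
    padded = np.pad(x, half, mode="edge")
    out = [int(np.median(padded[i:i + window])) for i in range(len(x))]
    return [inv[v] for v in out]


def _runs(labels: list[str], target: str, gap_tolerance: int) -> list[list[int]]:
    """Indices of ``target``-labelled positions grouped into runs, bridging
    up to ``gap_tolerance`` interposed *neutral* positions."""
    idx = [i for i, lab in enumerate(labels) if lab == target]
    runs: list[list[int]] = []
    for i in idx:
        if runs:
            prev = runs[-1][-1]
            between = labels[prev + 1:i]
            if len(between) <= gap_tolerance and all(b == "neutral" for b in between):
                runs[-1].append(i)
                continue
        runs.append([i])
    return runs


def _baf_stats(baf_tab: pd.DataFrame, sample_het: float,
               thresholds: CnaThresholds) -> dict:
    n = len(baf_tab)
    if n == 0:
        return {"n_loci": 0, "het_frac": np.nan, "imb_frac": np.nan,
                "fold_mag": np.nan, "n_mid": 0}
    het_frac = float((baf_tab["band"] == "HET").mean())
    mid = baf_tab[(baf_tab["folded"] > thresholds.baf_het_band)
                  & (baf_tab["folded"] <= thresholds.fold_cap)]
    return {
        "n_loci": n, "het_frac": het_frac,
        "imb_frac": float((baf_tab["band"] == "IMBALANCED").mean()),
        "fold_mag": float(mid["folded"].mean()) if len(mid) else np.nan,
        "n_mid": int(len(mid)),
    }


def _imbalance_present(stats: dict, sample_het: float,
                       thresholds: CnaThresholds) -> bool:
    if stats["n_loci"] == 0:
        return False
    depleted = stats["het_frac"] < thresholds.het_depletion_ratio * sample_het
    return depleted or stats["imb_frac"] >= thresholds.segment_imbalance_fraction


def call_segments(lfc: LfcProfile, baf: BafProfile, lfc_fit: MixtureFit,
                  baf_fit: Optional[MixtureFit], arms: pd.DataFrame,
                  thresholds: CnaThresholds = CnaThresholds()
                  ) -> SegmentationResult:
    """Segment the genome and classify segments into the six CNA types.

    ``baf_fit`` is accepted for diagnostics/evidence symmetry; the zygosity
    bands that drive the classification come from the folded-BAF thresholds.
    """
    genes = _label_genes(lfc, lfc_fit, thresholds)
    baf_tab = baf.table
    sample_het = float((baf_tab["band"] == "HET").mean()) if len(baf_tab) else 0.0

    segments: list[SegmentCall] = []
    leftovers: list[tuple[str, ...]] = []
    in_segment: set[str] = set()

    for (chrom, arm), sub in genes.groupby(["chrom", "arm"], sort=False):
        arm_row = arms[(arms["chrom"] == chrom) & (arms["arm"] == arm)]
        if arm_row.empty:
            raise CnaError(f"missing arm definition for {chrom}{arm}")
        a0, a1 = int(arm_row["start"].iloc[0]), int(arm_row["end"].iloc[0])
        sub = sub.sort_values("start")
        rescued = _rescue_arm_labels(sub, lfc_fit, thresholds)
        sub = sub.assign(label=rescued)
        labels = _smooth_labels(rescued, thresholds.smoothing_window)
        genes.loc[sub.index, "label"] = labels  # final (smoothed) assignments
        sub = sub.reset_index(drop=True)
        sub["label"] = labels
        arm_loci = baf_tab[(baf_tab["chrom"] == chrom) & (baf_tab["arm"] == arm)]

        for target in ("loss", "gain"):
            for run in _runs(labels, target, thresholds.depth_gap_tolerance):
                members = sub.iloc[run]
                if len(run) < thresholds.min_segment_genes:
                    leftovers.append(tuple(members["gene_id"]))
                    continue
                start = int(members["start"].min())
                end = int(members["end"].max())
                span_loci = arm_loci[(arm_loci["pos"] >= start)
                                     & (arm_loci["pos"] < end)]
                stats = _baf_stats(span_loci, sample_het, thresholds)
                seg_offset = float(members["lfc"].mean()
                                   - members["neutral_mean"].iloc[0])
                frac = (end - start) / (a1 - a0)
                base = target.upper() if frac >= thresholds.arm_fraction_cut \
                    else f"FOCAL_{target.upper()}"
                cna_type = base
                if abs(seg_offset) < thresholds.delta_confident:
                    # clear deviation but too weak for a clean clonal state;
                    # short weak runs are indistinguishable from noise
                    if len(run) < thresholds.aberrant_min_genes:
                        leftovers.append(tuple(members["gene_id"]))
                        continue
                    cna_type = "ABERRANT"
                elif (stats["n_loci"] >= thresholds.min_segment_loci
                      and not _imbalance_present(stats, sample_het, thresholds)):
                    # depth change unsupported by any allelic imbalance
                    cna_type = "ABERRANT"
                segments.append(SegmentCall(
                    chrom=chrom, arm=arm, start=start, end=end,
                    cna_type=cna_type, arm_fraction=frac,
                    gene_ids=tuple(members["gene_id"]),
                    n_loci=stats["n_loci"],
                    mean_lfc=float(members["lfc"].mean()),
                    mean_fold=stats["fold_mag"]))
                in_segment.update(members["gene_id"])

        # LOH / depth-neutral imbalance scan over genes outside depth segments.
        # Skipped when depth segments already explain >= 1/3 of the arm: the
        # imbalance there is accounted for by the copy change itself.
        n_arm_seg = int(sub["gene_id"].isin(in_segment).sum())
        if n_arm_seg >= len(sub) * thresholds.arm_fraction_cut:
            continue
        free = sub[~sub["gene_id"].isin(in_segment)].reset_index(drop=True)
        imb_flags = []
        for _, g in free.iterrows():
            gl = baf_tab[baf_tab["gene_id"] == g["gene_id"]]
            if g["label"] != "neutral" or len(gl) < thresholds.min_gene_loci:
                imb_flags.append("neutral")
                continue
            st = _baf_stats(gl, sample_het, thresholds)
            depleted = st["het_frac"] < thresholds.strong_depletion_ratio * sample_het
            imb = depleted or st["imb_frac"] >= thresholds.gene_imbalance_fraction
            imb_flags.append("imb" if imb else "neutral")
        for run in _runs(imb_flags, "imb", thresholds.gap_tolerance):
            members = free.iloc[run]
            if len(run) < thresholds.min_segment_genes:
                continue
            start = int(members["start"].min())
            end = int(members["end"].max())
            run_loci = baf_tab[baf_tab["gene_id"].isin(members["gene_id"])]
            stats = _baf_stats(run_loci, sample_het, thresholds)
            if (stats["n_loci"] < thresholds.min_segment_loci
                    or not _imbalance_present(stats, sample_het, thresholds)):
                continue  # no run-level imbalance: not a call
            seg_offset = float(members["lfc"].mean()
                               - members["neutral_mean"].iloc[0])
            frac = (end - start) / (a1 - a0)
            if abs(seg_offset) >= thresholds.delta_confident:
                # clear depth deviation the mixture missed: type by depth
                direction = "GAIN" if seg_offset > 0 else "LOSS"
                cna_type = direction if frac >= thresholds.arm_fraction_cut \
                    else f"FOCAL_{direction}"
            elif abs(seg_offset) > thresholds.delta_lfc / 2:
                cna_type = "ABERRANT"  # imbalance with non-neutral depth drift
            elif (stats["n_mid"] >= thresholds.min_gene_loci
                  and stats["fold_mag"] >= thresholds.loh_min_fold):
                cna_type = "LOH"       # clonal copy-neutral LOH magnitude
            elif stats["het_frac"] < thresholds.strong_depletion_ratio * sample_het \
                    and stats["n_mid"] < thresholds.min_gene_loci:
                cna_type = "LOH"       # complete het loss (purity ~ 1)
            else:
                cna_type = "ABERRANT"  # weak/partial imbalance (subclonal-like)
            segments.append(SegmentCall(
                chrom=chrom, arm=arm, start=start, end=end, cna_type=cna_type,
                arm_fraction=frac, gene_ids=tuple(members["gene_id"]),
                n_loci=stats["n_loci"],
                mean_lfc=float(members["lfc"].mean()),
                mean_fold=stats["fold_mag"]))
            in_segment.update(members["gene_id"])

    chrom_rank = {c: i for i, c in enumerate(AUTOSOMES)}
    segments.sort(key=lambda s: (chrom_rank.get(s.chrom, 99), s.arm, s.start))
    return SegmentationResult(segments=segments, gene_labels=genes,
                              leftover_runs=leftovers)


# ---------------------------------------------------------------------------
# sex inference and replicate concordance


def infer_sex(depth_table: pd.DataFrame,
              x_ratio_cut: float = 0.75, y_ratio_cut: float = 0.1) -> str:
    """Classify sample sex from X/Y vs autosome median coverage."""
    auto = depth_table[depth_table["chrom"].isin(AUTOSOMES)]
    x = depth_table[depth_table["chrom"] == "chrX"]
    y = depth_table[depth_table["chrom"] == "chrY"]
    if x.empty or auto.empty:
        return "undetermined"
    auto_med = float(auto["median_depth"].median())
    if auto_med <= 0:
        return "undetermined"
    x_ratio = float(x["median_depth"].median()) / auto_med
    y_ratio = float(y["median_depth"].median()) / auto_med if not y.empty else 0.0
    if x_ratio >= x_ratio_cut and y_ratio < y_ratio_cut:
        return "female"
    if x_ratio < x_ratio_cut and y_ratio >= y_ratio_cut:
        return "male"
    return "undetermined"


@dataclass
class ConcordanceReport:
    variants_identical: bool
    segments_identical: bool
    segment_type_concordance: float
    variant_discordance: pd.DataFrame
    segment_discordance: pd.DataFrame

    @property
    def identical(self) -> bool:
        return self.variants_identical and self.segments_identical


def _variant_keys(variants: pd.DataFrame) -> set[tuple]:
    cols = ["gene_id", "chrom", "pos", "ref", "alt"]
    return set(map(tuple, variants[cols].itertuples(index=False, name=None)))


def verify_replicates(calls_a: list[SegmentCall], calls_b: list[SegmentCall],
                      variants_a: pd.DataFrame, variants_b: pd.DataFrame
                      ) -> ConcordanceReport:
    """Exact-match check of kept-variant sets and segment assignments between
    two replicate samples of the same tumour."""
    va, vb = _variant_keys(variants_a), _variant_keys(variants_b)
    vd = sorted(va ^ vb)
    variant_disc = pd.DataFrame(vd, columns=["gene_id", "chrom", "pos", "ref",
                                             "alt"] if vd else None)

    full_a = {(s.chrom, s.arm, s.start, s.end, s.cna_type) for s in calls_a}
    full_b = {(s.chrom, s.arm, s.start, s.end, s.cna_type) for s in calls_b}
    type_a = {(s.chrom, s.arm, s.cna_type) for s in calls_a}
    type_b = {(s.chrom, s.arm, s.cna_type) for s in calls_b}
    union = type_a | type_b
    concord = len(type_a & type_b) / len(union) if union else 1.0
    sd = sorted((type_a ^ type_b))
    seg_disc = pd.DataFrame(sd, columns=["chrom", "arm", "cna_type"] if sd else None)
    return ConcordanceReport(
        variants_identical=not vd,
        segments_identical=full_a == full_b,
        segment_type_concordance=concord,
        variant_discordance=variant_disc,
        segment_discordance=seg_disc,
    )
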