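"""Synthetic multi-tumour meningioma-like cohort generator.

Emulates the data model of a deep hybrid-capture panel run on matched tumours
from patients whose meningiomas progressed in grade: a ~500-gene autosomal
panel with ~13k common-SNP loci, several tumours per patient, arm-level and
focal copy-number events plus copy-neutral LOH injected with known truth,
tumour purity (optionally subclonal) diluting both depth and allele-fraction
signals, negative-binomial depth noise, binomial allele counts, and variant
tables mixing somatic drivers, germline polymorphisms and low-VAF FFPE-like
artefacts. The truth channel is retained on every sample so downstream stages
can be scored for parameter recovery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .panel import AUTOSOMES, PanelDesign, default_arm_table

_BASES = np.array(list("ACGT"))

#: target allele state (n_A, n_B) for each event type, applied to a (1,1) baseline
EVENT_STATES = {
    "LOSS": (1, 0),
    "FOCAL_LOSS": (1, 0),
    "GAIN": (2, 1),
    "FOCAL_GAIN": (3, 1),
    "LOH": (2, 0),
}

#: recurrent arm-level event menu for the high-CNA ("NF2-like") patient class,
#: mirroring the arms most often hit in NF2-mutant meningiomas
HIGH_CLASS_MENU = [
    ("LOSS", "chr1", "p"),
    ("LOSS", "chr10", "p"),
    ("LOSS", "chr10", "q"),
    ("LOSS", "chr6", "q"),
    ("LOSS", "chr9", "p"),
    ("LOSS", "chr14", "q"),
    ("LOSS", "chr18", "q"),
    ("LOSS", "chr2", "p"),
    ("LOH", "chr3", "p"),
    ("LOH", "chr4", "p"),
    ("GAIN", "chr1", "q"),
    ("GAIN", "chr2", "q"),
]

QUIET_CLASS_MENU = [
    ("GAIN", "chr17", "q"),
    ("LOSS", "chr11", "p"),
]


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class TruthEvent:
    """An injected copy-number event with its target allele state."""

    chrom: str
    arm: str
    start: int
    end: int
    event_type: str  # one of EVENT_STATES keys
    n_a: int
    n_b: int
    subclonal: bool = False

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_STATES:
            raise ConfigurationError(f"unknown event type {self.event_type!r}")
        if self.n_a < 0 or self.n_b < 0:
            raise ConfigurationError("allele copies must be non-negative")
        if self.end <= self.start:
            raise ConfigurationError("event span must be half-open, end > start")

    @property
    def expected_call(self) -> str:
        """CNA type an ideal caller should report (subclonal events are
        expected to be flagged ABERRANT rather than typed cleanly)."""
        return "ABERRANT" if self.subclonal else self.event_type

    def to_dict(self) -> dict:
        return {
            "chrom": self.chrom, "arm": self.arm, "start": int(self.start),
            "end": int(self.end), "event_type": self.event_type,
            "n_a": int(self.n_a), "n_b": int(self.n_b),
            "subclonal": bool(self.subclonal),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TruthEvent":
        return cls(**d)


@dataclass
class SimulationConfig:
    """Knobs of the synthetic cohort. All rates are fractions in [0, 1].

    ``baseline_depth`` is the diploid per-gene median depth in reads;
    ``depth_dispersion`` is the negative-binomial size parameter (larger =
    closer to Poisson). ``het_fraction`` is the fraction of SNP loci that are
    germline-heterozygous in each patient.
    """

    n_patients: int = 10
    tumours_per_patient: int = 3
    n_genes: int = 523
    n_snp_loci: int = 13294
    baseline_depth: float = 9000.0
    depth_dispersion: float = 100.0
    het_fraction: float = 0.33
    purity: float = 0.8
    subclone_fraction: Optional[float] = None  # if set, injected events are subclonal
    seed: int = 0
    high_cna_fraction: float = 0.4
    quiet_event_rate: float = 0.3
    quiet_focal_mean: float = 1.0  # Poisson mean of small focal events, quiet class
    extra_events_range: tuple[int, int] = (3, 7)  # extra arm events in high class
    focal_event_rate: float = 0.3
    replicate_patients: int = 0
    include_sex_genes: bool = True
    n_x_genes: int = 6
    n_y_genes: int = 4
    gene_length: int = 20000
    snp_in_gene_fraction: float = 0.9
    # variant menu
    n_passenger_somatic: int = 2      # per tumour, clonal non-synonymous
    n_synonymous_somatic: int = 3     # per tumour
    n_germline_variants: int = 30     # per patient, VAF ~ 0.5 / 1.0
    n_artefact_variants: int = 20     # per tumour, FFPE-like low VAF
    n_lowdepth_variants: int = 3      # per tumour, fails the depth rule
    artefact_vaf_range: tuple[float, float] = (0.01, 0.12)
    seq_error: float = 0.002
    max_total_copies: int = 8

    def validate(self) -> None:
        if self.n_genes < 1 or self.n_snp_loci < 1:
            raise ConfigurationError("n_genes and n_snp_loci must be positive")
        if self.n_snp_loci < self.n_genes:
            raise ConfigurationError("need at least one SNP locus per gene")
        for name in ("het_fraction", "purity", "high_cna_fraction",
                     "quiet_event_rate", "focal_event_rate",
                     "snp_in_gene_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if self.subclone_fraction is not None and not 0.0 <= self.subclone_fraction <= 1.0:
            raise ConfigurationError("subclone_fraction must be in [0, 1]")
        if self.baseline_depth <= 0 or self.depth_dispersion <= 0:
            raise ConfigurationError("depth parameters must be positive")
        if self.seed is None:
            raise ConfigurationError("seed is mandatory")


@dataclass
class TumourSample:
    """One tumour's simulated observables plus its generating truth."""

    sample_id: str
    patient_id: str
    sex: str
    depth: pd.DataFrame       # gene_id, chrom, start, end, median_depth
    snp_counts: pd.DataFrame  # chrom, pos, ref_count, alt_count
    variants: pd.DataFrame    # variant table incl. truth_label column
    truth_events: list[TruthEvent]
    gene_true_label: pd.Series  # gene_id -> {loss, neutral, gain} (depth direction)
    replicate_of: Optional[str] = None


@dataclass
class CohortBundle:
    """Patients x tumours with full generating truth."""

    panel: PanelDesign
    samples: list[TumourSample]
    patients: pd.DataFrame  # patient_id, cna_class, nf2_mutant, sex
    config: SimulationConfig

    def sample_map(self) -> pd.DataFrame:
        """sample_id -> patient_id / replicate_of table."""
        return pd.DataFrame(
            [(s.sample_id, s.patient_id, s.replicate_of) for s in self.samples],
            columns=["sample_id", "patient_id", "replicate_of"],
        )

    def all_variants(self) -> pd.DataFrame:
        if not self.samples:
            return pd.DataFrame()
        return pd.concat([s.variants for s in self.samples], ignore_index=True)

    def truth_copy_load(self) -> pd.DataFrame:
        """Per-patient ground-truth copy-number load from the injected events
        (fraction of autosomal panel genes covered by any event, averaged
        over the patient's distinct tumours)."""
        auto = self.panel.autosomal_genes
        chrom = auto["chrom"].to_numpy()
        mid = ((auto["start"] + auto["end"]) // 2).to_numpy()
        rows = []
        for s in self.samples:
            if s.replicate_of is not None:
                continue
            covered = np.zeros(len(auto), dtype=bool)
            for ev in s.truth_events:
                covered |= (chrom == ev.chrom) & (mid >= ev.start) & (mid < ev.end)
            rows.append((s.patient_id, float(covered.mean())))
        tab = pd.DataFrame(rows, columns=["patient_id", "load"])
        return (tab.groupby("patient_id", as_index=False)["load"].mean()
                .rename(columns={"load": "copy_load"}))


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=tuple(key)))


# ---------------------------------------------------------------------------
# panel generation


def generate_panel(config: SimulationConfig) -> PanelDesign:
    """Lay out ``n_genes`` autosomal genes proportionally to arm lengths and
    scatter ``n_snp_loci`` SNP loci within (and near) gene footprints."""
    config.validate()
    rng = _rng(config.seed, 0)
    arms = default_arm_table(include_sex=True)
    auto_arms = arms[arms["chrom"].isin(AUTOSOMES)].reset_index(drop=True)

    lengths = (auto_arms["end"] - auto_arms["start"]).to_numpy(dtype=float)
    quota = lengths / lengths.sum() * config.n_genes
    counts = np.floor(quota).astype(int)
    remainder = config.n_genes - counts.sum()
    if remainder > 0:
        for i in np.argsort(-(quota - counts))[:remainder]:
            counts[i] += 1

    rows = []
    for (_, arm_row), n_arm in zip(auto_arms.iterrows(), counts):
        if n_arm == 0:
            continue
        a0, a1 = int(arm_row["start"]), int(arm_row["end"])
        slot = (a1 - a0) / n_arm
        for j in range(n_arm):
            lo = a0 + j * slot
            hi = lo + slot - config.gene_length
            start = int(rng.uniform(lo, max(hi, lo + 1)))
            rows.append((arm_row["chrom"], start, start + config.gene_length,
                         arm_row["arm"]))
    genes = pd.DataFrame(rows, columns=["chrom", "start", "end", "arm"])
    order = genes["chrom"].map({c: i for i, c in enumerate(AUTOSOMES)})
    genes = genes.assign(_o=order).sort_values(["_o", "start"]).drop(columns="_o")
    genes = genes.reset_index(drop=True)
    genes.insert(0, "gene_id", [f"G{i + 1:04d}" for i in range(len(genes))])

    # a recognisable tumour-suppressor stand-in on 22q for driver injection
    on_22q = (genes["chrom"] == "chr22") & (genes["arm"] == "q")
    if on_22q.any():
        genes.loc[genes.index[on_22q][0], "gene_id"] = "NF2"

    if config.include_sex_genes:
        sex_rows = []
        for chrom, n_sex, prefix in (("chrX", config.n_x_genes, "XG"),
                                     ("chrY", config.n_y_genes, "YG")):
            if n_sex <= 0:
                continue
            arm_row = arms[(arms["chrom"] == chrom) & (arms["arm"] == "q")].iloc[0]
            a0, a1 = int(arm_row["start"]), int(arm_row["end"])
            slot = (a1 - a0) / n_sex
            for j in range(n_sex):
                start = int(a0 + j * slot + slot * 0.25)
                sex_rows.append((f"{prefix}{j + 1}", chrom, start,
                                 start + config.gene_length, "q"))
        genes = pd.concat(
            [genes, pd.DataFrame(sex_rows, columns=genes.columns)],
            ignore_index=True,
        )

    auto = genes[genes["chrom"].isin(AUTOSOMES)].reset_index(drop=True)
    parts: list[pd.DataFrame] = []
    needed = config.n_snp_loci
    while needed > 0:  # top up after dropping position collisions
        host_idx = rng.integers(0, len(auto), size=needed)
        in_gene = rng.random(needed) < config.snp_in_gene_fraction
        host = auto.iloc[host_idx].reset_index(drop=True)
        offset = rng.integers(0, config.gene_length, size=needed)
        flank = rng.integers(1, 50000, size=needed)
        flank_sign = rng.choice([-1, 1], size=needed)
        pos = np.where(in_gene, host["start"].to_numpy() + offset,
                       host["start"].to_numpy() + flank_sign * flank)
        pos = np.maximum(pos, 1)
        ref_i = rng.integers(0, 4, size=needed)
        alt_i = (ref_i + rng.integers(1, 4, size=needed)) % 4
        parts.append(pd.DataFrame({
            "chrom": host["chrom"].to_numpy(), "pos": pos.astype(np.int64),
            "ref": _BASES[ref_i], "alt": _BASES[alt_i],
            "arm": host["arm"].to_numpy(), "gene_id": host["gene_id"].to_numpy(),
        }))
        combined = pd.concat(parts, ignore_index=True).drop_duplicates(["chrom", "pos"])
        parts = [combined]
        needed = config.n_snp_loci - len(combined)
    snp = parts[0]
    snp = snp.assign(_o=snp["chrom"].map({c: i for i, c in enumerate(AUTOSOMES)}))
    snp = snp.sort_values(["_o", "pos"]).drop(columns="_o").reset_index(drop=True)

    return PanelDesign(genes=genes, snp_loci=snp, arms=arms)


# ---------------------------------------------------------------------------
# per-patient germline context


@dataclass
class GermlineContext:
    """Patient-constant genotypes and germline variants, shared by all of a
    patient's tumours (and replicates)."""

    genotype: np.ndarray   # per SNP locus: 0 hom-ref, 1 het, 2 hom-alt
    alt_hap: np.ndarray    # per locus, 0 = allele A carries alt, 1 = allele B
    variants: pd.DataFrame


def make_germline(panel: PanelDesign, config: SimulationConfig,
                  rng: np.random.Generator) -> GermlineContext:
    n = panel.n_snp_loci
    u = rng.random(n)
    genotype = np.zeros(n, dtype=np.int8)
    genotype[u < config.het_fraction] = 1
    hom_alt = (u >= config.het_fraction) & (u < config.het_fraction + (1 - config.het_fraction) * 0.3)
    genotype[hom_alt] = 2
    alt_hap = rng.integers(0, 2, size=n).astype(np.int8)

    auto = panel.autosomal_genes.reset_index(drop=True)
    k = min(config.n_germline_variants, len(auto))
    idx = rng.choice(len(auto), size=k, replace=False)
    host = auto.iloc[idx]
    pos = host["start"].to_numpy() + rng.integers(0, config.gene_length, size=k)
    ref_i = rng.integers(0, 4, size=k)
    alt_i = (ref_i + rng.integers(1, 4, size=k)) % 4
    homozygous = rng.random(k) < 0.2
    variants = pd.DataFrame({
        "gene_id": host["gene_id"].to_numpy(), "chrom": host["chrom"].to_numpy(),
        "pos": pos.astype(np.int64), "ref": _BASES[ref_i], "alt": _BASES[alt_i],
        "consequence": "non_synonymous",
        "target_vaf": np.where(homozygous, 1.0, 0.5),
        # common polymorphisms: population frequency above the 1e-4 cut
        "pop_freq": 10.0 ** rng.uniform(-3.5, -0.5, size=k),
        "truth_label": "germline",
    })
    return GermlineContext(genotype=genotype, alt_hap=alt_hap, variants=variants)


# ---------------------------------------------------------------------------
# tumour simulation


def _copy_states(chrom: np.ndarray, pos_lo: np.ndarray, pos_hi: np.ndarray,
                 events: list[TruthEvent]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-interval (n_a, n_b, subclonal) against the (1,1) diploid baseline.

    An interval takes an event's state when its midpoint falls inside the
    event span on the same chromosome (events are non-overlapping).
    """
    n_a = np.ones(len(chrom), dtype=np.int64)
    n_b = np.ones(len(chrom), dtype=np.int64)
    sub = np.zeros(len(chrom), dtype=bool)
    mid = (pos_lo + pos_hi) // 2
    for ev in events:
        hit = (chrom == ev.chrom) & (mid >= ev.start) & (mid < ev.end)
        n_a[hit] = ev.n_a
        n_b[hit] = ev.n_b
        sub[hit] = ev.subclonal
    return n_a, n_b, sub


def _mixture_weights(config: SimulationConfig, subclonal: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray, float]:
    """(weight of event-bearing cells, weight of event-free tumour cells,
    weight of normal cells) under purity and optional subclonality."""
    rho = config.purity
    f = config.subclone_fraction if config.subclone_fraction is not None else 1.0
    w_event = np.where(subclonal, rho * f, rho)
    w_rest = rho - w_event
    return w_event, w_rest, 1.0 - rho


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, size_param: float) -> np.ndarray:
    mean = np.asarray(mean, dtype=float)
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    p = size_param / (size_param + mean[pos])
    out[pos] = rng.negative_binomial(size_param, p)
    return out


def expected_depth_factor(n_a: int, n_b: int, purity: float,
                          subclone_fraction: Optional[float] = None) -> float:
    """Closed-form depth ratio vs diploid for an allele state under purity."""
    f = 1.0 if subclone_fraction is None else subclone_fraction
    w_event, w_rest, w_norm = purity * f, purity * (1 - f), 1 - purity
    return (w_event * (n_a + n_b) + (w_rest + w_norm) * 2) / 2.0


def expected_het_baf(n_a: int, n_b: int, purity: float, alt_on_a: bool = True,
                     subclone_fraction: Optional[float] = None) -> float:
    """Closed-form BAF at a germline-het locus under an allele state."""
    f = 1.0 if subclone_fraction is None else subclone_fraction
    w_event, w_rest, w_norm = purity * f, purity * (1 - f), 1 - purity
    alt = w_event * (n_a if alt_on_a else n_b) + (w_rest + w_norm) * 1
    tot = w_event * (n_a + n_b) + (w_rest + w_norm) * 2
    return alt / tot


def simulate_tumour(panel: PanelDesign, truth: list[TruthEvent],
                    config: SimulationConfig, *,
                    rng: Optional[np.random.Generator] = None,
                    germline: Optional[GermlineContext] = None,
                    sample_id: str = "S1", patient_id: str = "P1",
                    sex: str = "female",
                    replicate_of: Optional[str] = None) -> TumourSample:
    """Draw one tumour's depth table, SNP allele counts and variant table."""
    config.validate()
    _validate_events(panel, truth)
    if rng is None:
        rng = _rng(config.seed, 2, 0, 0)
    if germline is None:
        germline = make_germline(panel, config, rng)

    genes = panel.genes.reset_index(drop=True)
    g_na, g_nb, g_sub = _copy_states(
        genes["chrom"].to_numpy(), genes["start"].to_numpy(),
        genes["end"].to_numpy(), truth)
    w_event, w_rest, w_norm = _mixture_weights(config, g_sub)
    factor = (w_event * (g_na + g_nb) + (w_rest + w_norm) * 2) / 2.0

    # sex chromosomes: female X at diploid factor, no Y; male X/Y haploid
    is_x = genes["chrom"].to_numpy() == "chrX"
    is_y = genes["chrom"].to_numpy() == "chrY"
    if sex == "female":
        factor = np.where(is_y, 0.0, factor)
    else:
        factor = np.where(is_x | is_y, 0.5, factor)

    depth = _nb_draw(rng, config.baseline_depth * factor, config.depth_dispersion)
    depth_table = genes[["gene_id", "chrom", "start", "end"]].copy()
    depth_table["median_depth"] = depth

    snp = panel.snp_loci.reset_index(drop=True)
    s_na, s_nb, s_sub = _copy_states(
        snp["chrom"].to_numpy(), snp["pos"].to_numpy(),
        snp["pos"].to_numpy() + 1, truth)
    w_event, w_rest, w_norm = _mixture_weights(config, s_sub)
    tot = w_event * (s_na + s_nb) + (w_rest + w_norm) * 2
    gt, hap = germline.genotype, germline.alt_hap
    alt_event = np.where(gt == 2, s_na + s_nb,
                         np.where(gt == 1, np.where(hap == 0, s_na, s_nb), 0))
    alt_rest = np.where(gt == 2, 2, np.where(gt == 1, 1, 0))
    alt = w_event * alt_event + (w_rest + w_norm) * alt_rest
    p_alt = np.divide(alt, tot, out=np.full(len(snp), 0.0), where=tot > 0)
    e = config.seq_error
    p_alt = p_alt * (1 - 2 * e) + e
    loc_factor = tot / 2.0
    loc_depth = _nb_draw(rng, config.baseline_depth * loc_factor,
                         config.depth_dispersion)
    alt_count = rng.binomial(loc_depth, p_alt)
    snp_counts = pd.DataFrame({
        "chrom": snp["chrom"], "pos": snp["pos"],
        "ref_count": loc_depth - alt_count, "alt_count": alt_count,
    })

    variants = _simulate_variants(panel, truth, config, rng, germline,
                                  depth_table, sample_id, patient_id)

    exp = (g_na + g_nb).astype(float)
    labels = np.where(exp > 2, "gain", np.where(exp < 2, "loss", "neutral"))
    labels = np.where(g_sub, "neutral", labels)  # subclonal: ambiguous by design
    gene_true_label = pd.Series(labels, index=genes["gene_id"], name="true_label")
    gene_true_label = gene_true_label[genes["chrom"].isin(AUTOSOMES).to_numpy()]

    return TumourSample(
        sample_id=sample_id, patient_id=patient_id, sex=sex,
        depth=depth_table, snp_counts=snp_counts, variants=variants,
        truth_events=list(truth), gene_true_label=gene_true_label,
        replicate_of=replicate_of,
    )


def _validate_events(panel: PanelDesign, events: list[TruthEvent]) -> None:
    for ev in events:
        try:
            a0, a1 = panel.arm_bounds(ev.chrom, ev.arm)
        except KeyError as exc:
            raise ConfigurationError(str(exc)) from exc
        if ev.start < a0 or ev.end > a1:
            raise ConfigurationError(
                f"event {ev.event_type} {ev.chrom}{ev.arm} outside arm bounds")
    spans = sorted((e.chrom, e.start, e.end) for e in events)
    for (c1, s1, e1), (c2, s2, e2) in zip(spans, spans[1:]):
        if c1 == c2 and s2 < e1:
            raise ConfigurationError("truth events overlap")


def _variant_vaf(n_a: int, n_b: int, subclonal: bool, config: SimulationConfig) -> float:
    """Clonal somatic variant on the better-retained haplotype."""
    f = config.subclone_fraction if (subclonal and config.subclone_fraction is not None) else 1.0
    w_event, w_rest, w_norm = config.purity * f, config.purity * (1 - f), 1 - config.purity
    mut_copies = max(n_a, n_b) if (n_a + n_b) > 0 else 0
    tot = w_event * (n_a + n_b) + (w_rest + w_norm) * 2
    return (w_event * mut_copies) / tot if tot > 0 else 0.0


def _simulate_variants(panel, truth, config, rng, germline, depth_table,
                       sample_id, patient_id) -> pd.DataFrame:
    auto = panel.autosomal_genes.reset_index(drop=True)
    depth_by_gene = depth_table.set_index("gene_id")["median_depth"]
    g_na, g_nb, g_sub = _copy_states(
        auto["chrom"].to_numpy(), auto["start"].to_numpy(),
        auto["end"].to_numpy(), truth)
    state = {g: (int(a), int(b), bool(s)) for g, a, b, s in
             zip(auto["gene_id"], g_na, g_nb, g_sub)}

    rows = []

    def add(gene_id, chrom, pos, ref, alt, consequence, vaf, pop_freq, label,
            depth_reads=None):
        if depth_reads is None:
            base = float(depth_by_gene.get(gene_id, config.baseline_depth))
            depth_reads = int(max(_nb_draw(rng, np.array([base]),
                                           config.depth_dispersion)[0], 1))
        alt_reads = rng.binomial(depth_reads, min(max(vaf, 0.0), 1.0))
        rows.append((sample_id, patient_id, gene_id, chrom, int(pos), ref, alt,
                     consequence, int(depth_reads), alt_reads / depth_reads,
                     float(pop_freq), label))

    # germline polymorphisms: present in every tumour of the patient
    for _, v in germline.variants.iterrows():
        add(v["gene_id"], v["chrom"], v["pos"], v["ref"], v["alt"],
            v["consequence"], v["target_vaf"], v["pop_freq"], v["truth_label"])

    def random_site(host):
        pos = int(host["start"]) + int(rng.integers(0, config.gene_length))
        ref_i = int(rng.integers(0, 4))
        alt_i = (ref_i + int(rng.integers(1, 4))) % 4
        return pos, _BASES[ref_i], _BASES[alt_i]

    for _ in range(config.n_passenger_somatic):
        host = auto.iloc[int(rng.integers(0, len(auto)))]
        pos, ref, alt = random_site(host)
        na, nb, sub = state[host["gene_id"]]
        add(host["gene_id"], host["chrom"], pos, ref, alt, "non_synonymous",
            _variant_vaf(na, nb, sub, config), 0.0, "somatic")

    for _ in range(config.n_synonymous_somatic):
        host = auto.iloc[int(rng.integers(0, len(auto)))]
        pos, ref, alt = random_site(host)
        add(host["gene_id"], host["chrom"], pos, ref, alt, "synonymous",
            config.purity / 2, 0.0, "synonymous")

    lo, hi = config.artefact_vaf_range
    for _ in range(config.n_artefact_variants):
        host = auto.iloc[int(rng.integers(0, len(auto)))]
        pos, ref, alt = random_site(host)
        add(host["gene_id"], host["chrom"], pos, ref, alt, "non_synonymous",
            float(rng.uniform(lo, hi)), 0.0, "artefact")

    for _ in range(config.n_lowdepth_variants):
        host = auto.iloc[int(rng.integers(0, len(auto)))]
        pos, ref, alt = random_site(host)
        add(host["gene_id"], host["chrom"], pos, ref, alt, "non_synonymous",
            config.purity / 2, 0.0, "low_depth",
            depth_reads=int(rng.integers(10, 50)))

    return pd.DataFrame(rows, columns=[
        "sample_id", "patient_id", "gene_id", "chrom", "pos", "ref", "alt",
        "consequence", "depth", "vaf", "pop_freq", "truth_label"])


# ---------------------------------------------------------------------------
# cohort simulation


def _arm_event(panel: PanelDesign, etype: str, chrom: str, arm: str,
               subclonal: bool) -> TruthEvent:
    a0, a1 = panel.arm_bounds(chrom, arm)
    na, nb = EVENT_STATES[etype]
    return TruthEvent(chrom, arm, a0, a1, etype, na, nb, subclonal=subclonal)


def _focal_event(panel: PanelDesign, etype: str, rng: np.random.Generator,
                 subclonal: bool, taken: set[tuple[str, str]]) -> Optional[TruthEvent]:
    genes = panel.gene_order()
    for _ in range(20):
        arm_key = tuple(genes[["chrom", "arm"]].iloc[int(rng.integers(0, len(genes)))])
        if arm_key in taken:
            continue
        sub = genes[(genes["chrom"] == arm_key[0]) & (genes["arm"] == arm_key[1])]
        if len(sub) < 12:  # keep focal span well under 1/3 of the arm's genes
            continue
        i = int(rng.integers(0, len(sub) - 3))
        block = sub.iloc[i:i + 3]
        na, nb = EVENT_STATES[etype]
        return TruthEvent(arm_key[0], arm_key[1], int(block["start"].min()),
                          int(block["end"].max()), etype, na, nb, subclonal=subclonal)
    return None


def draw_patient_events(panel: PanelDesign, cna_class: str,
                        config: SimulationConfig,
                        rng: np.random.Generator) -> list[TruthEvent]:
    """Sample the shared truth-event set for one patient.

    High-CNA patients always lose 22q (the NF2 arm) and draw several further
    recurrent arm events; quiet patients carry at most one event.
    """
    sub = config.subclone_fraction is not None
    events: list[TruthEvent] = []
    taken: set[tuple[str, str]] = set()
    if cna_class == "high":
        events.append(_arm_event(panel, "LOSS", "chr22", "q", sub))
        taken.add(("chr22", "q"))
        lo, hi = config.extra_events_range
        n_extra = int(rng.integers(lo, hi + 1))
        idx = rng.choice(len(HIGH_CLASS_MENU), size=min(n_extra, len(HIGH_CLASS_MENU)),
                         replace=False)
        for i in idx:
            etype, chrom, arm = HIGH_CLASS_MENU[int(i)]
            events.append(_arm_event(panel, etype, chrom, arm, sub))
            taken.add((chrom, arm))
        if rng.random() < config.focal_event_rate:
            etype = "FOCAL_GAIN" if rng.random() < 0.5 else "FOCAL_LOSS"
            ev = _focal_event(panel, etype, rng, sub, taken)
            if ev is not None:
                events.append(ev)
    else:
        if rng.random() < config.quiet_event_rate:
            etype, chrom, arm = QUIET_CLASS_MENU[int(rng.integers(0, len(QUIET_CLASS_MENU)))]
            if (chrom, arm) not in taken:
                events.append(_arm_event(panel, etype, chrom, arm, sub))
                taken.add((chrom, arm))
        # quiet genomes still carry the odd small focal change
        for _ in range(int(rng.poisson(config.quiet_focal_mean))):
            etype = "FOCAL_GAIN" if rng.random() < 0.5 else "FOCAL_LOSS"
            ev = _focal_event(panel, etype, rng, sub, taken)
            if ev is not None:
                events.append(ev)
                taken.add((ev.chrom, ev.arm))
    return events


def simulate_cohort(config: SimulationConfig,
                    panel: Optional[PanelDesign] = None) -> CohortBundle:
    """Generate a full cohort: panel, patients split into a high-CNA
    ("NF2-like") class and a quiet class, tumours with shared per-patient
    truth, and optional duplicated samples tagged as replicates."""
    config.validate()
    if panel is None:
        panel = generate_panel(config)
    if config.tumours_per_patient == 0:
        warnings.warn("tumours_per_patient=0: returning an empty cohort")

    class_rng = _rng(config.seed, 10)
    n_high = int(round(config.high_cna_fraction * config.n_patients))
    classes = np.array(["high"] * n_high + ["quiet"] * (config.n_patients - n_high))
    class_rng.shuffle(classes)
    sexes = np.where(class_rng.random(config.n_patients) < 0.5, "female", "male")

    samples: list[TumourSample] = []
    patient_rows = []
    nf2_gene = "NF2" if (panel.genes["gene_id"] == "NF2").any() else None
    for p in range(config.n_patients):
        pid = f"P{p + 1:02d}"
        cls = str(classes[p])
        germ_rng = _rng(config.seed, 1, p)
        germline = make_germline(panel, config, germ_rng)
        events = draw_patient_events(panel, cls, config, germ_rng)
        nf2_mutant = cls == "high" and nf2_gene is not None
        driver = None
        if nf2_mutant:
            host = panel.genes.set_index("gene_id").loc[nf2_gene]
            pos = int(host["start"]) + int(germ_rng.integers(0, config.gene_length))
            ref_i = int(germ_rng.integers(0, 4))
            driver = (nf2_gene, host["chrom"], pos, _BASES[ref_i],
                      _BASES[(ref_i + 1) % 4])
        patient_rows.append((pid, cls, nf2_mutant, str(sexes[p])))

        for t in range(config.tumours_per_patient):
            sid = f"{pid}-T{t + 1}"
            s = simulate_tumour(
                panel, events, config, rng=_rng(config.seed, 2, p, t),
                germline=germline, sample_id=sid, patient_id=pid,
                sex=str(sexes[p]))
            if driver is not None:
                s.variants = _with_driver(s, driver, config,
                                          _rng(config.seed, 4, p, t))
            samples.append(s)
        if p < config.replicate_patients and config.tumours_per_patient > 0:
            # a replicate re-sequences the same tumour extraction: depth and
            # allele counts get fresh noise, the variant records (including
            # FFPE lesions) are those of the source tumour
            sid = f"{pid}-T1R"
            s = simulate_tumour(
                panel, events, config, rng=_rng(config.seed, 3, p),
                germline=germline, sample_id=sid, patient_id=pid,
                sex=str(sexes[p]), replicate_of=f"{pid}-T1")
            source = next(x for x in samples if x.sample_id == f"{pid}-T1")
            s.variants = source.variants.assign(sample_id=sid)
            samples.append(s)

    patients = pd.DataFrame(patient_rows,
                            columns=["patient_id", "cna_class", "nf2_mutant", "sex"])
    return CohortBundle(panel=panel, samples=samples, patients=patients,
                        config=config)


def _with_driver(sample: TumourSample, driver, config: SimulationConfig,
                 rng: np.random.Generator) -> pd.DataFrame:
    """Append the patient's clonal driver mutation to one tumour's table."""
    gene_id, chrom, pos, ref, alt = driver
    # driver on the retained haplotype of the (usually lost) driver arm
    na, nb, sub = 1, 1, False
    for ev in sample.truth_events:
        if ev.chrom == chrom and ev.start <= pos < ev.end:
            na, nb, sub = ev.n_a, ev.n_b, ev.subclonal
    vaf = _variant_vaf(na, nb, sub, config)
    base = float(sample.depth.set_index("gene_id")["median_depth"].get(
        gene_id, config.baseline_depth))
    depth_reads = int(max(base, 1))
    alt_reads = rng.binomial(depth_reads, min(max(vaf, 0.0), 1.0))
    row = pd.DataFrame([{
        "sample_id": sample.sample_id, "patient_id": sample.patient_id,
        "gene_id": gene_id, "chrom": chrom, "pos": int(pos), "ref": ref,
        "alt": alt, "consequence": "non_synonymous", "depth": depth_reads,
        "vaf": alt_reads / depth_reads, "pop_freq": 0.0,
        "truth_label": "driver"}])
    return pd.concat([sample.variants, row], ignore_index=True)
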