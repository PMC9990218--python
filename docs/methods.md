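# Methods

## Setting and data model

The package targets tumour-only, deep hybrid-capture panel sequencing of
FFPE meningioma tissue: ~523 cancer-relevant autosomal genes, ~13,294
common-SNP loci inside and near the capture targets, several tumours per
patient (serial resections), occasional duplicate samples of one tumour for
quality control, and no matched germline. Inputs are plain-text tables: a
panel BED, a chromosome-arm TSV, per-sample per-gene median-depth TSVs,
per-sample SNP allele-count TSVs, and variant tables (TSV, or VCF with
`GENE`/`CONSEQUENCE`/`POP_AF` INFO and `DP`/`AF` FORMAT fields).
Coordinates are 0-based half-open internally; VCF positions convert on
read.

## Somatic filter cascade

Membership in the kept set is the conjunction of independent predicates —
non-synonymous, depth ≥ `min_depth` (50), `vaf_min` ≤ VAF ≤ `vaf_max`
([0.1, 0.9], both endpoints kept, since removal is strict inequality),
population frequency ≤ `max_pop_freq` (10⁻⁴, missing treated as 0, the
permissive reading) — so the result is idempotent and order-free; the
report attributes each removal to the first failing rule in a fixed
canonical order for bookkeeping only. Cohort recurrence is computed over
distinct patients (replicates collapse to one tumour) and only flags, never
filters: with no matched normal, a variant seen in most patients is more
plausibly an unfiltered polymorphism or artefact than a shared driver.

## Copy-number model

For a tumour of purity ρ and a region with allele copies (n_A, n_B) on a
diploid background, the expected depth ratio against the sample baseline is
`(ρ(n_A+n_B) + 2(1−ρ))/2` and the expected BAF at a germline-het site is
`(ρ·n_alt + (1−ρ))/(ρ(n_A+n_B) + 2(1−ρ))`. A one-copy loss at ρ = 0.8
therefore sits at LFC = log2(0.6) ≈ −0.74 with folded BAF
|0.833 − 0.5| ≈ 0.33; copy-neutral LOH (2,0) keeps LFC at 0 with folded BAF
0.4; a one-copy gain (2,1) sits at LFC ≈ +0.49 with folded BAF ≈ 0.14.
These closed forms (`expected_depth_factor`, `expected_het_baf`) are the
oracles for both the simulator's and the caller's tests.

## Mixture fitting and labelling

LFC and BAF values are clustered independently with 1-D Gaussian mixtures
fit by EM, K ∈ 1..6, five restarts per K, selecting the K that minimises
BIC (asserted exactly in the tests). Two deliberate robustness choices:

- **Tied variance.** Per-gene LFC noise has a common scale, and an untied
  fit lets the dominant neutral component inflate its variance and swallow
  a small loss/gain cluster (tens of genes among ~500). Tying the variance
  keeps rare components honest; the BIC parameter count is 2K.
- **Dual initialisation.** k-means centres the dominant mode well but can
  merge a 3-gene focal cluster away; k-means++ seeding can isolate it. Both
  are run and the better log-likelihood kept, per K.

Genes take the label of their maximum-responsibility component, with the
neutral component the one whose mean is nearest 0 (ties toward larger
weight) and loss/gain labels requiring a component-mean offset beyond
`delta_lfc` (default 0.3 — safely below the weakest clonal event offset of
~0.45 at purity 0.8 and above the spacing a split-neutral component pair
can produce at the simulator's noise scale). Because a dominant neutral
weight biases the responsibility boundary against rare components, arms
that already carry at least one non-neutral seed gene get an equal-prior
rescue pass: neutral genes there are reassigned to the nearest class
centre (neutral centre from the fit; loss/gain centres from the arm's own
seed genes). Arms with no seed are untouched, so the pass cannot invent
events on a quiet genome. A window-5 median filter over each arm's label
sequence then removes isolated misassignments; a 3-gene focal block
survives it.

## Segmentation and the six types

Runs of same-label genes along an arm become segments spanning their first
to last gene. Depth (loss/gain) runs bridge up to `depth_gap_tolerance` = 4
interposed neutral genes — four consecutive misassignments inside a real
arm event are vanishingly unlikely, so this stops fragmentation without
enabling noise runs — while BAF-scan runs use `gap_tolerance` = 1. Runs
need `min_segment_genes` = 3 members (shorter ones are reported as
diagnostics, not calls), the rescue pass needs `min_seed_genes` = 2 seed
genes, and a weak run destined for ABERRANT needs `aberrant_min_genes` = 5
(a short weak run is indistinguishable from noise). `arm_fraction` is genomic span over arm span; depth-loss/gain
segments with arm_fraction ≥ 1/3 are LOSS/GAIN, below that FOCAL_LOSS /
FOCAL_GAIN. BAF evidence over the span is summarised as the HET-band locus
fraction (folded deviation ≤ 0.1), the IMBALANCED fraction (0.1 < folded ≤
0.4; folded > 0.4 is HOM, strict so that the purity-0.8 LOH expectation of
exactly 0.4 counts as imbalance), and the mean folded deviation of mid-band
loci (folded in (0.1, 0.45], excluding near-perfect homozygotes).

Replacing the original human inspection step, classification applies an
explicit rule set:

- a depth segment whose |mean LFC offset| is below `delta_confident` (0.4)
  is **ABERRANT**: a clear deviation too weak for any clean clonal state
  (one-copy events at purity ≤ ~0.5, or subclonal events, land here);
- a depth segment with ≥ `min_segment_loci` informative loci but no
  allelic imbalance (HET fraction not depleted below 0.5× the sample-wide
  HET rate, imbalanced fraction < 0.15) is **ABERRANT** (conflicting
  evidence);
- arms less than 1/3 covered by depth segments are scanned for runs of
  depth-neutral genes with gene-level imbalance (strong HET depletion,
  < 0.25× the sample rate, or ≥ 30% imbalanced loci; ≥ 5 loci per gene).
  A run with run-level imbalance is **LOH** when its mid-band folded mean
  is ≥ `loh_min_fold` (0.25, i.e. consistent with clonal copy-neutral LOH
  at purity ≥ ~0.5) or when HET signal is erased entirely with no mid-band
  loci (the purity-1 case); weaker or intermediate imbalance is
  **ABERRANT**; a clear depth offset the mixture missed is typed by depth
  direction instead.

Sex is checked from coverage: X-to-autosome median ratio ≥ 0.75 with
Y-ratio < 0.1 is female; X < 0.75 with Y ≥ 0.1 is male; anything else is
undetermined.

## Association model

Each patient contributes one observation: the mean over their distinct
tumours of the fraction of panel genes covered by any segment call,
irrespective of type (replicates collapsed by union first). The load is
regressed on a binary flag with a binomial-family GLM (logit link, unit
prior weights — the standard quasibinomial-on-proportions idiom),
dispersion φ = Pearson χ²/(n−2), and a Wald t-test on n−2 df; the
implementation reproduces R's `glm(quasibinomial)` coefficient, SE,
dispersion and p-value to ≥ 5 decimals on a frozen example. Groups pinned
at a load of exactly 0 or 1 are flagged non-estimable (separation) rather
than fitted. The screen fits one model per flag and BH-adjusts across
flags.

## Synthetic cohort generator

The generator defines the study conditions, not a tuning surface:

- **Panel**: genes allocated to autosomal arms proportionally to
  approximate GRCh38 arm lengths, one 20 kb gene per slot; 90% of SNP loci
  inside gene footprints, 10% in ≤ 50 kb flanks; optional chrX/chrY genes
  only for sex inference. Defaults 523 genes / 13,294 loci.
- **Depth**: per-gene median depth is negative binomial with mean
  `baseline_depth` × copy factor and size (dispersion) 100 — gene-level
  medians of deep capture data are far less dispersed than raw per-base
  counts, and size 100 puts the LFC noise sd near 0.16, a demanding but
  realistic regime. Default baseline 9,000× (deep panel); recovery suites
  run at 500× to stress the caller.
- **Allele counts**: binomial around the purity-mixed expectation with
  sequencing-error floor 0.002; per-patient germline genotypes
  (`het_fraction` 0.33, hom-alt 30% of the remainder) are shared across a
  patient's tumours.
- **Events**: patients split into a high-CNA "NF2-like" class (default
  40%: always LOSS 22q, plus 3–7 draws from a recurrent menu of losses on
  1p/10p/10q/6q/9p/14q/18q/2p, LOH on 3p/4p, gains on 1q/2q, plus an
  optional focal event) and a quiet class (one 17q-gain/11p-loss arm event
  with probability 0.3 plus Poisson(1) 3-gene focal events — real non-NF2
  tumours are not CNA-free, and all-zero loads would make the association
  screen degenerate). Events are patient-constant across tumours,
  mirroring the recurrence of CNAs across resections of one tumour.
  Allele states: LOSS/FOCAL_LOSS (1,0), GAIN (2,1), FOCAL_GAIN (3,1),
  LOH (2,0). Purity defaults to 0.8; `subclone_fraction` dilutes events to
  a cell subpopulation, and such events are expected to be called
  ABERRANT.
- **Variants**: per patient, 30 germline polymorphisms (target VAF 0.5 or
  1.0, population frequency 10^U(−3.5,−0.5) > 10⁻⁴); per tumour, 2 clonal
  non-synonymous passengers, 3 synonymous, 20 FFPE-like artefacts with VAF
  uniform in [0.01, 0.12] (straddling the 0.1 cut on purpose), 3 low-depth
  records; NF2-like patients carry a clonal NF2 driver on the retained
  haplotype of the lost 22q arm. A replicate sample re-sequences the same
  extraction: depths and allele counts are drawn with fresh noise while
  the variant records are inherited from the source tumour — artefact
  lesions live in the shared DNA, and independent re-draws of
  boundary-VAF artefacts would make replicate call-table identity
  unattainable by construction.

What the generator does **not** emulate: GC/mappability waves and
capture-efficiency bias in depth, position-correlated FFPE damage,
mutational signatures, phased haplotypes, read-level data, or
radiotherapy-induced change over time. Passing tests therefore demonstrate
correctness of the statistical machinery under a clean overdispersed-count
model, not robustness to every real-data artefact; on real panels the
LFC/BAF profiles should be inspected alongside the calls, as the six-type
vocabulary (notably ABERRANT) is designed to surface ambiguity rather than
hide it.

## Determinism and numerics

All randomness descends from one integer seed through
`numpy.random.SeedSequence` spawn keys (fixed per stage, patient, tumour);
GMM seeds derive per sample the same way, so reruns are byte-identical and
the pipeline manifest's file checksums are stable (log level has no effect
on outputs). EM uses tolerance 1e-6 and ≤ 500 iterations; non-convergent K
are skipped and an error is raised only if every K fails. Zero-depth genes
are excluded from LFC (flagged), loci under 30 reads from BAF. Even gene
counts make the median-of-LFC interpolate between two genes, so the
"median LFC = 0" invariant holds to ~1e-3 rather than exactly.

## Problem sizes in the test and acceptance suites

Chosen as the package's own validation design: filter and BH oracles at
1,000 records/vectors (exact agreement required); GMM recovery over 100
seeded replicates of K ∈ {1,2,3}, n = 500, sd = 0.05; CNA recovery on one
8-patient full-scale cohort (523 genes, 13,294 loci, depth 500, purity
0.8) requiring every arm-level LOSS/GAIN/LOH recovered as exactly one
correctly-typed segment and ≥ 95% gene-label accuracy; replicate
concordance on 4 duplicate pairs at the 9,000× default depth (the regime
of the identity claim); association type-I error over 1,000 null fits
(target band [0.03, 0.08]) and power over 200 truth-load cohorts (the
power of the screen given the generator's class effect; re-running full
CNA inference per replicate would add nothing to the power question, which
concerns the GLM, and is exercised separately by the recovery suite).

## Known limitations

Absolute copy number and ploidy are out of scope (calls are relative to
the sample's dominant baseline, so a genome-doubled tumour would shift the
frame); LOH detection needs enough informative loci per gene (~5) and
arm-scale runs, so focal LOH is not called; the ABERRANT class is a
catch-all whose boundary thresholds (`delta_confident`, `loh_min_fold`)
encode a purity ≈ 0.5 working point; the association screen treats
patients as exchangeable and cannot model within-patient grade contrasts;
and the quiet/high two-class generator is a caricature of real cohort
structure, sufficient for power/calibration checks but not for estimating
real-world effect sizes.
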