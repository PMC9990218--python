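"""Synthetic cohort generator: determinism, closed-form expectations, truth."""

import numpy as np
import pytest

from mencna import (SimulationConfig, TruthEvent, generate_panel,
                    simulate_cohort, simulate_tumour)
from mencna.panel import AUTOSOMES
from mencna.simulate import (ConfigurationError, _arm_event, _rng,
                             expected_depth_factor, expected_het_baf,
                             make_germline)


class TestGeneratePanel:
    def test_requested_sizes(self, full_panel):
        assert full_panel.n_genes == 523
        assert full_panel.n_snp_loci == 13294

    def test_genes_cover_all_autosomes_proportionally(self, full_panel):
        by_chrom = full_panel.autosomal_genes["chrom"].value_counts()
        assert set(by_chrom.index) == set(AUTOSOMES)
        # chr1 is ~5x longer than chr21
        assert by_chrom["chr1"] > by_chrom["chr21"]

    def test_single_gene_panel(self):
        cfg = SimulationConfig(n_genes=1, n_snp_loci=1, seed=3,
                               include_sex_genes=False)
        panel = generate_panel(cfg)
        assert panel.n_genes == 1
        gene = panel.autosomal_genes.iloc[0]
        assert (panel.snp_loci["arm"] == gene["arm"]).all()
        assert (panel.snp_loci["chrom"] == gene["chrom"]).all()

    def test_same_seed_identical(self):
        cfg = SimulationConfig(n_genes=80, n_snp_loci=500, seed=9)
        a, b = generate_panel(cfg), generate_panel(cfg)
        assert a.genes.to_csv() == b.genes.to_csv()
        assert a.snp_loci.to_csv() == b.snp_loci.to_csv()

    def test_nonpositive_sizes_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_panel(SimulationConfig(n_genes=0, n_snp_loci=10, seed=1))
        with pytest.raises(ConfigurationError):
            SimulationConfig(n_genes=10, n_snp_loci=5, seed=1).validate()

    def test_every_locus_inside_an_arm(self, small_panel):
        for _, row in small_panel.snp_loci.iterrows():
            a0, a1 = small_panel.arm_bounds(row["chrom"], row["arm"])
            assert a0 <= row["pos"] < a1


@pytest.fixture(scope="module")
def panel():
    return generate_panel(SimulationConfig(n_genes=300, n_snp_loci=2500, seed=4))


class TestSimulateTumour:

    def test_depth_mean_matches_copy_mixed_baseline(self, panel):
        """Mean simulated gene depth over 10,000 draws is within 1% of
        baseline_depth x copy factor (law of large numbers)."""
        cfg = SimulationConfig(n_genes=300, n_snp_loci=2500, seed=4,
                               baseline_depth=500.0)
        depths = []
        for t in range(40):
            s = simulate_tumour(panel, [], cfg, rng=_rng(cfg.seed, 2, 0, t))
            auto = s.depth[s.depth["chrom"].isin(AUTOSOMES)]
            depths.append(auto["median_depth"].to_numpy())
        mean = np.concatenate(depths).mean()
        assert mean == pytest.approx(500.0, rel=0.01)

    def test_purity1_one_copy_loss_halves_depth(self, panel):
        cfg = SimulationConfig(n_genes=300, n_snp_loci=2500, seed=4,
                               purity=1.0, baseline_depth=2000.0)
        ev = _arm_event(panel, "LOSS", "chr1", "q", False)
        s = simulate_tumour(panel, [ev], cfg, rng=_rng(1, 2, 0, 0))
        on = s.depth["chrom"].eq("chr1") & s.depth["start"].ge(ev.start)
        ratio = s.depth.loc[on, "median_depth"].mean() / 2000.0
        assert ratio == pytest.approx(0.5, abs=0.05)
        assert expected_depth_factor(1, 0, 1.0) == 0.5

    def test_purity1_copy_neutral_loh_keeps_depth_extreme_baf(self, panel):
        cfg = SimulationConfig(n_genes=300, n_snp_loci=2500, seed=4,
                               purity=1.0, baseline_depth=2000.0)
        ev = _arm_event(panel, "LOH", "chr1", "q", False)
        germ = make_germline(panel, cfg, _rng(7, 1, 0))
        s = simulate_tumour(panel, [ev], cfg, rng=_rng(7, 2, 0, 0), germline=germ)
        on = s.depth["chrom"].eq("chr1") & s.depth["start"].ge(ev.start)
        assert s.depth.loc[on, "median_depth"].mean() / 2000.0 == pytest.approx(1.0, abs=0.08)
        loci = panel.snp_loci.reset_index(drop=True)
        het = (germ.genotype == 1) & (loci["chrom"] == "chr1").to_numpy() \
            & (loci["pos"] >= ev.start).to_numpy()
        counts = s.snp_counts[het]
        baf = counts["alt_count"] / (counts["ref_count"] + counts["alt_count"])
        # every het site collapses to (near-)homozygous under pure LOH
        assert ((baf < 0.05) | (baf > 0.95)).all()
        assert expected_depth_factor(2, 0, 1.0) == 1.0

    def test_impure_loss_lfc_matches_closed_form(self, panel):
        """Mean per-gene LFC on a one-copy-loss arm at purity 0.8 approaches
        log2(0.8*0.5 + 0.2) = -0.737 (50 genes, depth 500)."""
        cfg = SimulationConfig(n_genes=300, n_snp_loci=2500, seed=4,
                               purity=0.8, baseline_depth=500.0)
        ev = _arm_event(panel, "LOSS", "chr1", "q", False)
        s = simulate_tumour(panel, [ev], cfg, rng=_rng(2, 2, 0, 0))
        auto = s.depth[s.depth["chrom"].isin(AUTOSOMES)]
        sample_median = auto.loc[auto["median_depth"] > 0, "median_depth"].median()
        on = auto["chrom"].eq("chr1") & auto["start"].ge(ev.start)
        lfc = np.log2(auto.loc[on, "median_depth"] / sample_median)
        assert lfc.mean() == pytest.approx(np.log2(0.8 * 0.5 + 0.2), abs=0.08)

    def test_het_baf_matches_purity_mixture(self, panel):
        """Het-locus BAF mean under copy-neutral LOH at purity 0.8 approaches
        the closed-form folded value 0.4."""
        cfg = SimulationConfig(n_genes=300, n_snp_loci=2500, seed=4,
                               purity=0.8, baseline_depth=500.0)
        ev = _arm_event(panel, "LOH", "chr1", "q", False)
        germ = make_germline(panel, cfg, _rng(8, 1, 0))
        s = simulate_tumour(panel, [ev], cfg, rng=_rng(8, 2, 0, 0), germline=germ)
        loci = panel.snp_loci.reset_index(drop=True)
        het = (germ.genotype == 1) & (loci["chrom"] == "chr1").to_numpy() \
            & (loci["pos"] >= ev.start).to_numpy()
        counts = s.snp_counts[het]
        folded = (counts["alt_count"] / (counts["ref_count"] + counts["alt_count"])
                  - 0.5).abs()
        assert folded.mean() == pytest.approx(0.4, abs=0.02)
        assert expected_het_baf(2, 0, 0.8) == pytest.approx(0.9)

    def test_event_outside_arm_rejected(self, panel):
        cfg = SimulationConfig(n_genes=300, n_snp_loci=2500, seed=4)
        a0, a1 = panel.arm_bounds("chr1", "p")
        bad = TruthEvent("chr1", "p", a0, a1 + 10_000_000, "LOSS", 1, 0)
        with pytest.raises(ConfigurationError):
            simulate_tumour(panel, [bad], cfg)

    def test_overlapping_events_rejected(self, panel):
        cfg = SimulationConfig(n_genes=300, n_snp_loci=2500, seed=4)
        e1 = _arm_event(panel, "LOSS", "chr1", "p", False)
        with pytest.raises(ConfigurationError):
            simulate_tumour(panel, [e1, e1], cfg)


class TestSimulateCohort:
    def test_class_split(self, small_panel):
        cfg = SimulationConfig(n_patients=10, tumours_per_patient=1, n_genes=60,
                               n_snp_loci=1500, seed=6, high_cna_fraction=0.4)
        bundle = simulate_cohort(cfg, panel=small_panel)
        assert (bundle.patients["cna_class"] == "high").sum() == 4
        assert bundle.patients["nf2_mutant"].sum() == 4

    def test_empty_cohort_warns(self, small_panel):
        cfg = SimulationConfig(n_patients=2, tumours_per_patient=0, n_genes=60,
                               n_snp_loci=1500, seed=6)
        with pytest.warns(UserWarning):
            bundle = simulate_cohort(cfg, panel=small_panel)
        assert bundle.samples == []

    def test_seed_determinism_bitwise(self, small_panel):
        cfg = SimulationConfig(n_patients=3, tumours_per_patient=2, n_genes=60,
                               n_snp_loci=1500, seed=12, replicate_patients=1)
        a = simulate_cohort(cfg, panel=small_panel)
        b = simulate_cohort(cfg, panel=small_panel)
        for sa, sb in zip(a.samples, b.samples):
            assert sa.depth.to_csv() == sb.depth.to_csv()
            assert sa.snp_counts.to_csv() == sb.snp_counts.to_csv()
            assert sa.variants.to_csv() == sb.variants.to_csv()

    def test_replicates_share_truth_with_independent_counts(self, small_panel):
        cfg = SimulationConfig(n_patients=4, tumours_per_patient=1, n_genes=60,
                               n_snp_loci=1500, seed=13, replicate_patients=2,
                               high_cna_fraction=0.5)
        bundle = simulate_cohort(cfg, panel=small_panel)
        smap = bundle.sample_map()
        pairs = smap[smap["replicate_of"].notna()]
        assert len(pairs) == 2
        by_id = {s.sample_id: s for s in bundle.samples}
        for _, row in pairs.iterrows():
            rep, src = by_id[row["sample_id"]], by_id[row["replicate_of"]]
            assert [e.to_dict() for e in rep.truth_events] == \
                [e.to_dict() for e in src.truth_events]
            assert not rep.depth["median_depth"].equals(src.depth["median_depth"])
            # variant records come from the same extraction
            assert rep.variants.drop(columns="sample_id").equals(
                src.variants.drop(columns="sample_id"))

    def test_truth_events_round_trip(self, small_panel, tmp_path):
        from mencna.io import read_truth, write_truth

        cfg = SimulationConfig(n_patients=3, tumours_per_patient=2, n_genes=60,
                               n_snp_loci=1500, seed=14, high_cna_fraction=0.7)
        bundle = simulate_cohort(cfg, panel=small_panel)
        events = {s.sample_id: s.truth_events for s in bundle.samples}
        write_truth(events, tmp_path / "truth.json")
        back = read_truth(tmp_path / "truth.json")
        assert back == events

    def test_truth_copy_load_in_unit_interval(self, small_panel):
        cfg = SimulationConfig(n_patients=6, tumours_per_patient=2, n_genes=60,
                               n_snp_loci=1500, seed=15)
        bundle = simulate_cohort(cfg, panel=small_panel)
        loads = bundle.truth_copy_load()
        assert len(loads) == 6
        assert loads["copy_load"].between(0, 1).all()
        high = set(bundle.patients.loc[bundle.patients["cna_class"] == "high",
                                       "patient_id"])
        merged = loads.set_index("patient_id")["copy_load"]
        assert min(merged[p] for p in high) > max(
            merged[p] for p in merged.index if p not in high)
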