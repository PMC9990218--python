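"""CNA inference: LFC/BAF formulas, GMM/BIC selection, segment classification."""

import numpy as np
import pandas as pd
import pytest

from mencna import (CnaThresholds, SimulationConfig, call_segments, compute_baf,
                    compute_lfc, fit_gmm_1d, generate_panel, infer_sex,
                    simulate_tumour, verify_replicates)
from mencna.cna import CnaError, SegmentCall, neutral_component
from mencna.pipeline import call_sample_cna
from mencna.simulate import _arm_event, _focal_event, _rng, make_germline


# --------------------------------------------------------------------------
# independent EM oracle (no sklearn): quantile-init restarts, full variance


def _em_once(x, k, means0, max_iter=300, tol=1e-8):
    n = len(x)
    w = np.full(k, 1.0 / k)
    mu = means0.copy()
    var = np.full(k, np.var(x) / k + 1e-8)
    ll_old = -np.inf
    for _ in range(max_iter):
        dens = w * np.exp(-0.5 * (x[:, None] - mu) ** 2 / var) / np.sqrt(2 * np.pi * var)
        tot = dens.sum(axis=1, keepdims=True)
        tot[tot == 0] = 1e-300
        r = dens / tot
        ll = float(np.log(tot).sum())
        nk = r.sum(axis=0) + 1e-12
        w = nk / n
        mu = (r * x[:, None]).sum(axis=0) / nk
        var = (r * (x[:, None] - mu) ** 2).sum(axis=0) / nk + 1e-9
        if abs(ll - ll_old) < tol:
            break
        ll_old = ll
    return ll, mu

def oracle_select_k(x, k_max=6, restarts=8, seed=0):
    rng = np.random.default_rng(seed)
    best = {}
    for k in range(1, k_max + 1):
        lls = []
        for r in range(restarts):
            q = np.sort(rng.uniform(0, 1, k)) if r else np.linspace(0.1, 0.9, k)
            ll, _ = _em_once(x, k, np.quantile(x, q))
            lls.append(ll)
        p = 3 * k - 1
        best[k] = p * np.log(len(x)) - 2 * max(lls)
    return min(best, key=best.get)


class TestLfc:
    def test_closed_forms(self, toy_panel):
        depth = toy_panel.genes[["gene_id", "chrom", "start", "end"]].copy()
        depth["median_depth"] = [100, 200, 50, 100, 100, 100]
        prof = compute_lfc(depth, toy_panel)
        lfc = prof.table.set_index("gene_id")["lfc"]
        assert lfc["A1"] == pytest.approx(0.0)
        assert lfc["A2"] == pytest.approx(1.0)
        assert lfc["A3"] == pytest.approx(-1.0)
        assert prof.sample_median == 100

    def test_zero_depth_gene_excluded(self, toy_panel):
        depth = toy_panel.genes[["gene_id", "chrom", "start", "end"]].copy()
        depth["median_depth"] = [100, 0, 100, 100, 100, 100]
        prof = compute_lfc(depth, toy_panel)
        assert prof.excluded_genes == ["A2"]
        assert "A2" not in set(prof.table["gene_id"])

    def test_all_zero_depth_is_error(self, toy_panel):
        depth = toy_panel.genes[["gene_id", "chrom", "start", "end"]].copy()
        depth["median_depth"] = 0
        with pytest.raises(CnaError, match="no usable coverage"):
            compute_lfc(depth, toy_panel)

    def test_median_lfc_is_zero_by_construction(self, small_panel):
        cfg = SimulationConfig(n_genes=60, n_snp_loci=1500, seed=31,
                               baseline_depth=500.0)
        s = simulate_tumour(small_panel, [], cfg, rng=_rng(31, 2, 0, 0))
        prof = compute_lfc(s.depth, small_panel)
        # exact zero up to even-count median interpolation between two genes
        assert prof.table["lfc"].median() == pytest.approx(0.0, abs=1e-3)


class TestBaf:
    def _profile(self, toy_panel, ref, alt):
        counts = toy_panel.snp_loci[["chrom", "pos"]].copy()
        counts["ref_count"] = ref
        counts["alt_count"] = alt
        return compute_baf(counts, toy_panel)

    def test_balanced_het(self, toy_panel):
        prof = self._profile(toy_panel, 50, 50)
        assert (prof.table["baf"] == 0.5).all()
        assert (prof.table["band"] == "HET").all()

    def test_homozygous(self, toy_panel):
        prof = self._profile(toy_panel, 100, 0)
        assert (prof.table["baf"] == 0.0).all()
        assert (prof.table["band"] == "HOM").all()

    def test_imbalanced_band(self, toy_panel):
        prof = self._profile(toy_panel, 90, 10)  # folded deviation exactly 0.4
        assert (prof.table["band"] == "IMBALANCED").all()

    def test_low_depth_locus_excluded(self, toy_panel):
        counts = toy_panel.snp_loci[["chrom", "pos"]].copy()
        counts["ref_count"] = 10
        counts["alt_count"] = 10
        prof = compute_baf(counts, toy_panel)
        assert len(prof.table) == 0
        assert prof.n_excluded == len(toy_panel.snp_loci)

    def test_negative_counts_rejected(self, toy_panel):
        counts = toy_panel.snp_loci[["chrom", "pos"]].copy()
        counts["ref_count"] = -1
        counts["alt_count"] = 10
        with pytest.raises(CnaError):
            compute_baf(counts, toy_panel)


class TestGmm:
    @pytest.mark.parametrize("true_k,centres", [
        (1, [0.0]), (2, [0.0, 1.0]), (3, [-1.0, 0.0, 1.0])])
    def test_k_recovery_matches_oracle(self, true_k, centres):
        rng = np.random.default_rng(40 + true_k)
        x = np.concatenate([rng.normal(c, 0.05, 500 // true_k) for c in centres])
        fit = fit_gmm_1d(x, seed=1)
        assert fit.k == true_k
        assert oracle_select_k(x, seed=1) == true_k
        assert np.allclose(np.sort(fit.means), centres, atol=0.02)

    def test_selected_bic_is_minimal(self):
        rng = np.random.default_rng(44)
        x = np.concatenate([rng.normal(0, 0.05, 250), rng.normal(1, 0.05, 250)])
        fit = fit_gmm_1d(x, seed=3)
        assert fit.bic == min(fit.bic_by_k.values())
        assert all(fit.bic <= b for b in fit.bic_by_k.values())

    def test_deterministic_for_seed(self):
        rng = np.random.default_rng(45)
        x = rng.normal(0, 1, 400)
        a, b = fit_gmm_1d(x, seed=7), fit_gmm_1d(x, seed=7)
        assert a.k == b.k and np.array_equal(a.means, b.means)

    def test_too_few_values_is_error(self):
        with pytest.raises(CnaError):
            fit_gmm_1d([0.1, 0.2], k_range=(1, 6))

    def test_neutral_component_nearest_zero(self):
        rng = np.random.default_rng(46)
        x = np.concatenate([rng.normal(-0.7, 0.05, 100), rng.normal(0, 0.05, 300)])
        fit = fit_gmm_1d(x, seed=2)
        assert abs(fit.means[neutral_component(fit)]) < 0.1


# --------------------------------------------------------------------------
# segmentation scenarios on the full-scale panel


def run_scenario(full_panel, events, purity, subclone=None, seed=5):
    cfg = SimulationConfig(n_patients=1, tumours_per_patient=1,
                           baseline_depth=500.0, seed=seed, purity=purity,
                           subclone_fraction=subclone)
    germ = make_germline(full_panel, cfg, _rng(seed, 1, 0))
    s = simulate_tumour(full_panel, events, cfg, rng=_rng(seed, 2, 0, 0),
                        germline=germ)
    res = call_sample_cna(s.depth, s.snp_counts, full_panel, CnaThresholds(),
                          seed=1)
    return s, res


class TestCallSegments:
    def test_full_arm_loss_single_segment(self, full_panel):
        ev = _arm_event(full_panel, "LOSS", "chr1", "p", False)
        _, res = run_scenario(full_panel, [ev], purity=1.0)
        losses = [s for s in res.segments if s.cna_type == "LOSS"]
        assert len(losses) == 1
        assert losses[0].chrom == "chr1" and losses[0].arm == "p"
        assert losses[0].arm_fraction > 0.9

    def test_three_gene_gain_is_focal(self, full_panel):
        rng = _rng(6, 9)
        ev = _focal_event(full_panel, "FOCAL_GAIN", rng, False, set())
        s, res = run_scenario(full_panel, [ev], purity=0.8)
        focal = [x for x in res.segments if x.cna_type == "FOCAL_GAIN"]
        assert len(focal) == 1
        assert focal[0].arm_fraction <= 1 / 3
        assert set(focal[0].gene_ids) == set(
            s.gene_true_label[s.gene_true_label == "gain"].index)

    def test_copy_neutral_loh_pure_sample(self, full_panel):
        ev = _arm_event(full_panel, "LOH", "chr3", "p", False)
        _, res = run_scenario(full_panel, [ev], purity=1.0)
        loh = [s for s in res.segments if s.cna_type == "LOH"]
        assert len(loh) == 1 and loh[0].chrom == "chr3"
        assert abs(loh[0].mean_lfc) < 0.1  # copy-neutral: depth unchanged

    def test_low_purity_events_become_aberrant(self, full_panel):
        events = [_arm_event(full_panel, "LOSS", "chr1", "p", False),
                  _arm_event(full_panel, "LOH", "chr3", "p", False)]
        _, res = run_scenario(full_panel, events, purity=0.4)
        assert {s.cna_type for s in res.segments} <= {"ABERRANT"}
        assert len(res.segments) >= 1

    def test_subclonal_events_become_aberrant(self, full_panel):
        events = [_arm_event(full_panel, "LOSS", "chr1", "p", True),
                  _arm_event(full_panel, "LOH", "chr3", "p", True)]
        _, res = run_scenario(full_panel, events, purity=0.8, subclone=0.5)
        assert {s.cna_type for s in res.segments} <= {"ABERRANT"}
        assert len(res.segments) >= 1

    def test_nonneutral_genes_partition_into_segments(self, full_panel):
        events = [_arm_event(full_panel, "LOSS", "chr1", "p", False),
                  _arm_event(full_panel, "GAIN", "chr2", "q", False)]
        _, res = run_scenario(full_panel, events, purity=0.8)
        seg_genes = [g for s in res.segments for g in s.gene_ids]
        assert len(seg_genes) == len(set(seg_genes))  # no overlap
        labels = res.gene_labels
        non_neutral = set(labels.loc[labels["label"] != "neutral", "gene_id"])
        leftover = {g for run in res.leftover_runs for g in run}
        assert non_neutral == set(seg_genes) | leftover

    def test_missing_arm_definition_is_error(self, toy_panel):
        depth = toy_panel.genes[["gene_id", "chrom", "start", "end"]].copy()
        rng = np.random.default_rng(0)
        depth["median_depth"] = rng.integers(400, 600, len(depth))
        prof = compute_lfc(depth, toy_panel)
        counts = toy_panel.snp_loci[["chrom", "pos"]].copy()
        counts["ref_count"] = 50
        counts["alt_count"] = 50
        baf = compute_baf(counts, toy_panel)
        fit = fit_gmm_1d(np.r_[prof.table["lfc"], rng.normal(0, .1, 30)], k_range=(1, 2), seed=1)
        arms = toy_panel.arms[toy_panel.arms["chrom"] != "chr2"]
        with pytest.raises(CnaError, match="chr2"):
            call_segments(prof, baf, fit, None, arms)


class TestSexInference:
    def _depth(self, x_factor, y_factor):
        rows = [("G%d" % i, "chr%d" % (i % 22 + 1), 0, 1, 1000) for i in range(40)]
        rows += [(f"X{i}", "chrX", 0, 1, int(1000 * x_factor)) for i in range(4)]
        rows += [(f"Y{i}", "chrY", 0, 1, int(1000 * y_factor)) for i in range(3)]
        return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end",
                                           "median_depth"])

    def test_female_male_borderline(self):
        assert infer_sex(self._depth(1.0, 0.0)) == "female"
        assert infer_sex(self._depth(0.5, 0.5)) == "male"
        assert infer_sex(self._depth(0.6, 0.05)) == "undetermined"

    def test_simulated_sexes_recovered(self, small_panel):
        cfg = SimulationConfig(n_genes=60, n_snp_loci=1500, seed=33)
        for sex in ("female", "male"):
            s = simulate_tumour(small_panel, [], cfg, rng=_rng(33, 2, 0, 0),
                                sex=sex)
            assert infer_sex(s.depth) == sex

    def test_no_sex_genes_undetermined(self):
        tab = self._depth(1, 1)
        assert infer_sex(tab[~tab["chrom"].isin(["chrX", "chrY"])]) == "undetermined"


class TestVerifyReplicates:
    def _calls(self):
        return [SegmentCall("chr1", "p", 0, 10_000_000, "LOSS", 0.9,
                            ("G1", "G2", "G3"), 50, -0.7, 0.3)]

    def _variants(self):
        return pd.DataFrame([{"gene_id": "NF2", "chrom": "chr22", "pos": 5,
                              "ref": "A", "alt": "T"}])

    def test_identical_inputs(self):
        rep = verify_replicates(self._calls(), self._calls(),
                                self._variants(), self._variants())
        assert rep.identical
        assert rep.segment_type_concordance == 1.0

    def test_discordance_listed(self):
        other = [SegmentCall("chr1", "p", 0, 10_000_000, "GAIN", 0.9,
                             ("G1", "G2", "G3"), 50, 0.5, 0.1)]
        rep = verify_replicates(self._calls(), other,
                                self._variants(), self._variants().iloc[:0])
        assert not rep.identical
        assert len(rep.segment_discordance) == 2  # one type each side
        assert len(rep.variant_discordance) == 1
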