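"""Composite interval mapping: LOD arithmetic, cofactors, calling, hotspots."""

import numpy as np
import pytest

from binqtl import cim, sim
from binqtl.cim import _lod_pair, _scan_dense, _scan_masked
from binqtl.core import ScanResult, ValidationError
from binqtl.phenostats import line_means


def _single_marker_lod_oracle(X, y):
    """Independent per-bin regression LOD via explicit lstsq."""
    n, p = X.shape
    out = np.zeros(p)
    for b in range(p):
        C1 = np.column_stack([np.ones(n), X[:, b]])
        r1 = y - C1 @ np.linalg.lstsq(C1, y, rcond=None)[0]
        r0 = y - y.mean()
        out[b] = (n / 2) * np.log10((r0 @ r0) / (r1 @ r1))
    return out


@pytest.fixture(scope="module")
def qtl_data():
    ms = sim.SimMapSpec([sim.ChromSpec("chr1", 25, 0.08),
                         sim.ChromSpec("chr2", 25, 0.08)])
    g = sim.simulate_ril_genotypes(ms, 213, seed=21)
    model = sim.TraitModel("SH", qtls=[sim.QtlEffect(12, 0.7)], sigma_e=1.0)
    ph = sim.simulate_phenotypes(g, model, densities=("LD",),
                                 experiments=("Ex1",), n_reps=2, seed=22)
    y = line_means(ph, "SH", "LD", "Ex1").reindex(g.lines).to_numpy()
    return g, y


class TestLodArithmetic:
    def test_closed_form(self):
        # RSS ratio 1.2 on 100 lines: LOD = 50 log10(1.2) = 3.959
        assert _lod_pair(1.2, 1.0, 100) == pytest.approx(3.959, abs=1e-3)

    def test_equal_rss_gives_zero(self):
        assert _lod_pair(5.0, 5.0, 80) == 0.0

    def test_zero_cofactor_scan_equals_single_marker_oracle(self, qtl_data):
        g, y = qtl_data
        scan = cim.cim_scan(g, y, cofactors=[])
        oracle = _single_marker_lod_oracle(g.numeric(), y)
        np.testing.assert_allclose(scan.lod, oracle, atol=1e-8)

    def test_masked_path_agrees_with_dense_when_complete(self, qtl_data):
        g, y = qtl_data
        X = g.numeric()
        cof = cim.select_cofactors(X, y, 2)
        np.testing.assert_allclose(
            _scan_masked(X, y, cof), _scan_dense(X, y, cof), atol=1e-8
        )

    def test_lod_affine_invariance(self, qtl_data):
        g, y = qtl_data
        cof = cim.select_cofactors(g, y, 3)
        lod1 = cim.cim_scan(g, y, cof).lod
        lod2 = cim.cim_scan(g, -2.5 * y + 7.0, cof).lod
        np.testing.assert_allclose(lod1, lod2, atol=1e-8)

    def test_nonzero_window_rejected(self, qtl_data):
        g, y = qtl_data
        with pytest.raises(ValidationError):
            cim.cim_scan(g, y, [], window_cm=5.0)


class TestCofactorSelection:
    def test_k_zero_is_empty(self, qtl_data):
        g, y = qtl_data
        assert cim.select_cofactors(g, y, 0) == []

    def test_k_exceeding_half_lines_is_error(self, qtl_data):
        g, y = qtl_data
        with pytest.raises(ValidationError):
            cim.select_cofactors(g, y, 200)

    def test_strong_qtl_selected_near_truth(self):
        ms = sim.SimMapSpec([sim.ChromSpec("chr1", 40, 0.08)])
        hits = 0
        for s in range(20):
            g = sim.simulate_ril_genotypes(ms, 213, seed=600 + s)
            model = sim.TraitModel("SH", qtls=[sim.QtlEffect(20, 1.0)], sigma_e=1.0)
            ph = sim.simulate_phenotypes(g, model, densities=("LD",),
                                         experiments=("Ex1",), n_reps=1,
                                         seed=700 + s)
            y = line_means(ph, "SH", "LD", "Ex1").reindex(g.lines)
            sel = cim.select_cofactors(g, y, 1)
            if sel and abs(sel[0] - 20) <= 5:
                hits += 1
        assert hits >= 19

    def test_three_qtls_one_cofactor_each(self):
        ms = sim.SimMapSpec([sim.ChromSpec(f"chr{i+1}", 20, 0.08) for i in range(3)])
        truth = [10, 30, 50]  # one per chromosome
        good = 0
        for s in range(20):
            g = sim.simulate_ril_genotypes(ms, 213, seed=800 + s)
            model = sim.TraitModel(
                "SH", qtls=[sim.QtlEffect(b, 1.0) for b in truth], sigma_e=1.0
            )
            ph = sim.simulate_phenotypes(g, model, densities=("LD",),
                                         experiments=("Ex1",), n_reps=1,
                                         seed=900 + s)
            y = line_means(ph, "SH", "LD", "Ex1").reindex(g.lines)
            sel = sorted(cim.select_cofactors(g, y, 3))
            regions = [b // 20 for b in sel]
            if sorted(regions) == [0, 1, 2]:
                good += 1
        assert good >= 18


class TestPermutationThreshold:
    def test_seed_determinism(self, qtl_data):
        g, y = qtl_data
        t1 = cim.permutation_threshold(g, y, n_perm=120, k=2, seed=5)
        t2 = cim.permutation_threshold(g, y, n_perm=120, k=2, seed=5)
        assert t1 == t2

    def test_small_n_perm_warns(self, qtl_data):
        g, y = qtl_data
        with pytest.warns(UserWarning, match="unstable"):
            cim.permutation_threshold(g, y, n_perm=50, k=0, seed=1)


class TestCallQtls:
    def _toy(self, lod):
        ms = sim.SimMapSpec([sim.ChromSpec("chr1", len(lod), 0.2)])
        g = sim.simulate_ril_genotypes(ms, 60, seed=31)
        y = g.numeric()[:, 2] + np.random.default_rng(32).normal(0, 0.5, 60)
        return g, y, ScanResult(lod=np.array(lod, float), trait="SH")

    def test_profile_peak_and_interval(self):
        g, y, scan = self._toy([1, 4, 5, 4, 1])
        calls = cim.call_qtls(scan, 3.0, g, y)
        assert len(calls) == 1
        c = calls[0]
        assert c.peak_index == 2
        assert (c.ci_lo_index, c.ci_hi_index) == (1, 3)  # LOD >= 5 - 1.5

    def test_flat_profile_below_threshold_no_calls(self):
        g, y, scan = self._toy([1, 1.2, 1, 0.8, 1])
        assert cim.call_qtls(scan, 3.0, g, y) == []

    def test_nearby_peaks_within_interval_merged(self):
        g, y, scan = self._toy([1, 4.8, 4.0, 4.9, 1])
        calls = cim.call_qtls(scan, 3.0, g, y)
        assert len(calls) == 1 and calls[0].peak_index == 3

    def test_distinct_peaks_both_called(self):
        lod = [4.5, 1.0, 0.2, 0.1, 0.2, 1.0, 5.0]
        g, y, scan = self._toy(lod)
        calls = cim.call_qtls(scan, 3.0, g, y)
        assert [c.peak_index for c in calls] == [0, 6]
        assert calls[0].name.startswith("qSH_1.")

    def test_main_effect_classification_rule(self):
        """LOD > 3 alone is not enough: Var% must also exceed 10."""
        ms = sim.SimMapSpec([sim.ChromSpec("chr1", 10, 0.2)])
        g = sim.simulate_ril_genotypes(ms, 213, seed=33)
        x = g.numeric()[:, 4]
        rng = np.random.default_rng(34)
        strong = 1.0 * x + rng.normal(0, 1.0, 213)  # PVE ~ 50%
        weak = 0.25 * x + rng.normal(0, 1.0, 213)   # PVE ~ 6%
        for y, klass in [(strong, "main-effect"), (weak, "minor")]:
            scan = cim.cim_scan(g, y, [], trait="SH")
            calls = cim.call_qtls(scan, min(2.0, scan.lod.max() - 0.1), g, y)
            assert calls and calls[0].klass == klass
            if klass == "main-effect":
                assert calls[0].var_pct > 10 and calls[0].lod > 3

    def test_sign_convention_positive_means_nip_increases(self):
        ms = sim.SimMapSpec([sim.ChromSpec("chr1", 6, 0.2)])
        g = sim.simulate_ril_genotypes(ms, 120, seed=35)
        x = g.numeric()[:, 2]
        y = -0.8 * x + np.random.default_rng(36).normal(0, 0.3, 120)
        scan = cim.cim_scan(g, y, [])
        calls = cim.call_qtls(scan, 3.0, g, y)
        assert calls and calls[0].additive_effect < 0  # 9311 allele increases


class TestHotspots:
    def _call(self, trait, chrom, peak, lo, hi):
        return cim.QTLCall(
            name=f"q{trait}_1.1", trait=trait, density="LD", experiment="Ex1",
            chrom=chrom, peak_index=peak, peak_bin=f"bin{peak}", position=peak,
            lod=5.0, additive_effect=0.5, var_pct=12.0,
            ci_lo_index=lo, ci_hi_index=hi,
            ci_lo_bin=f"bin{lo}", ci_hi_bin=f"bin{hi}", klass="main-effect",
        )

    def test_two_traits_same_bin_is_one_hotspot(self):
        calls = [self._call("SH", "chr1", 5, 3, 7),
                 self._call("FLL", "chr1", 5, 4, 6)]
        hs = cim.detect_hotspots(calls)
        assert len(hs) == 1 and hs[0].traits == {"SH", "FLL"}

    def test_disjoint_intervals_no_hotspot(self):
        calls = [self._call("SH", "chr1", 5, 3, 7),
                 self._call("FLL", "chr1", 20, 18, 22)]
        assert cim.detect_hotspots(calls) == []

    def test_same_trait_cluster_not_a_hotspot(self):
        calls = [self._call("SH", "chr1", 5, 3, 7),
                 self._call("SH", "chr1", 6, 4, 8)]
        assert cim.detect_hotspots(calls) == []

    def test_pleiotropic_locus_recovered_with_three_members(self):
        ms = sim.SimMapSpec([sim.ChromSpec("chr1", 30, 0.08)])
        g = sim.simulate_ril_genotypes(ms, 213, seed=37)
        calls = []
        for i, trait in enumerate(["SH", "FLL", "SLL"]):
            model = sim.TraitModel(trait, qtls=[sim.QtlEffect(15, 1.0)], sigma_e=0.8)
            ph = sim.simulate_phenotypes(g, model, densities=("LD",),
                                         experiments=("Ex1",), n_reps=1,
                                         seed=38 + i)
            y = line_means(ph, trait, "LD", "Ex1").reindex(g.lines)
            scan = cim.cim_scan(g, y, [], trait=trait)
            calls += cim.call_qtls(scan, 3.0, g, y)
        hs = cim.detect_hotspots(calls)
        assert len(hs) == 1 and len(hs[0].traits) == 3
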