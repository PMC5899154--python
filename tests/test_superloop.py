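"""Sliding-window loop significance testing and super-loop quantification."""

import numpy as np
import pytest
from helpers import BIN, make_map
from scipy import stats as sps

import tadloop as tl
from tadloop import GenomicRegion as GR


def rect_spec(seed, loops=(), depth=5e5):
    """Off-diagonal 2 Mb x 2 Mb rectangle between two distant anchors."""
    return tl.SyntheticSpec(
        extent=GR("chrX", 23_000_000, 25_000_000),
        col_extent=GR("chrX", 48_000_000, 50_000_000),
        bin_size=BIN, depth=depth, loops=tuple(loops), seed=seed)


ANCHOR_ROW = GR("chrX", 23_980_000, 24_020_000)
ANCHOR_COL = GR("chrX", 48_980_000, 49_020_000)
LOOP = tl.LoopSpec(ANCHOR_ROW, ANCHOR_COL, fold=5.0)
SPEC67 = tl.WindowSpec(6, 7, ANCHOR_ROW, ANCHOR_COL)


class TestExtractTargetWindow:
    def test_size_is_42_bins(self):
        cmap = tl.sample_map(rect_spec(1))
        assert len(tl.extract_target_window(cmap, SPEC67)) == 42

    def test_known_entries(self):
        values = np.arange(25, dtype=float).reshape(5, 5)
        cmap = make_map(values, col_start=100 * BIN)
        spec = tl.WindowSpec(1, 2,
                             GR("chrX", 2 * BIN, 3 * BIN),
                             GR("chrX", 102 * BIN, 103 * BIN))
        # center (2, 2); even col dimension extends downstream
        assert tl.extract_target_window(cmap, spec) == [12.0, 13.0]

    def test_constant_map_constant_window(self):
        cmap = make_map(np.full((20, 20), 3.0), col_start=700 * BIN)
        spec = tl.WindowSpec(6, 7, GR("chrX", 9 * BIN, 11 * BIN),
                             GR("chrX", 709 * BIN, 711 * BIN))
        assert tl.extract_target_window(cmap, spec) == [3.0] * 42

    def test_window_exceeding_extent_rejected(self):
        cmap = make_map(np.full((10, 10), 1.0), col_start=100 * BIN)
        spec = tl.WindowSpec(6, 7, GR("chrX", 0, BIN),
                             GR("chrX", 100 * BIN, 101 * BIN))
        with pytest.raises(ValueError, match="exceeds"):
            tl.extract_target_window(cmap, spec)


class TestSlideWindowTest:
    def test_position_grid_arithmetic(self):
        cmap = tl.sample_map(rect_spec(2))
        res = tl.slide_window_test(cmap, SPEC67,
                                   tl.extract_target_window(cmap, SPEC67))
        assert res.t.shape == (45, 44)
        assert res.n_positions == 1980

    def test_constant_map_all_p_one(self):
        cmap = make_map(np.full((20, 20), 2.0), col_start=200 * BIN)
        spec = tl.WindowSpec(3, 3, GR("chrX", 9 * BIN, 11 * BIN),
                             GR("chrX", 209 * BIN, 211 * BIN))
        res = tl.slide_window_test(cmap, spec,
                                   tl.extract_target_window(cmap, spec))
        np.testing.assert_array_equal(res.p[res.valid], 1.0)

    def test_self_position_p_is_one(self):
        cmap = tl.sample_map(rect_spec(3, loops=[LOOP]))
        target = tl.extract_target_window(cmap, SPEC67)
        res = tl.slide_window_test(cmap, SPEC67, target)
        from tadloop.superloop import _window_origin
        r0, c0 = _window_origin(cmap, SPEC67)
        assert res.p[r0, c0] == 1.0
        assert res.t[r0, c0] == 0.0

    def test_matches_scipy_welch_per_position(self):
        cmap = tl.sample_map(rect_spec(4))
        target = tl.extract_target_window(cmap, SPEC67)
        res = tl.slide_window_test(cmap, SPEC67, target)
        rng = np.random.default_rng(0)
        for _ in range(20):
            i = rng.integers(0, res.t.shape[0])
            j = rng.integers(0, res.t.shape[1])
            window = cmap.values[i:i + 6, j:j + 7].ravel()
            ref = sps.ttest_ind(window, target, equal_var=False)
            assert res.t[i, j] == pytest.approx(ref.statistic, rel=1e-9)
            assert res.p[i, j] == pytest.approx(ref.pvalue, rel=1e-9)

    def test_diagonal_positions_invalid_on_square_map(self):
        rng = np.random.default_rng(5)
        base = rng.poisson(10, (20, 20)).astype(float)
        cmap = make_map(np.triu(base) + np.triu(base, 1).T)
        spec = tl.WindowSpec(3, 3, GR("chrX", 2 * BIN, 3 * BIN),
                             GR("chrX", 15 * BIN, 16 * BIN))
        res = tl.slide_window_test(cmap, spec,
                                   tl.extract_target_window(cmap, spec))
        assert not res.valid[4, 4]      # window [4:7]x[4:7] sits on diagonal
        assert res.valid[0, 10]

    def test_heavily_masked_windows_invalid(self):
        values = np.full((20, 20), 5.0)
        values[:10, :] = np.nan
        cmap = make_map(values, col_start=300 * BIN)
        spec = tl.WindowSpec(4, 4, GR("chrX", 14 * BIN, 15 * BIN),
                             GR("chrX", 314 * BIN, 315 * BIN))
        res = tl.slide_window_test(cmap, spec,
                                   tl.extract_target_window(cmap, spec))
        assert not res.valid[0, 0]   # fully masked window
        assert res.valid[12, 0]

    def test_exclude_target_flag(self):
        cmap = tl.sample_map(rect_spec(6))
        target = tl.extract_target_window(cmap, SPEC67)
        res = tl.slide_window_test(cmap, SPEC67, target, exclude_target=True)
        from tadloop.superloop import _window_origin
        r0, c0 = _window_origin(cmap, SPEC67)
        assert not res.valid[r0, c0]

    def test_planted_loop_shifts_pvalues_down(self):
        wins = []
        for seed in range(5):
            wt = tl.sample_map(rect_spec(100 + seed, loops=[LOOP]))
            ko = tl.sample_map(rect_spec(200 + seed))
            fracs = []
            for cmap in (wt, ko):
                target = tl.extract_target_window(cmap, SPEC67)
                res = tl.slide_window_test(cmap, SPEC67, target)
                fracs.append(np.mean(res.valid_pvalues() < 0.05))
            wins.append(fracs[0] > fracs[1])
        assert sum(wins) >= 4


class TestComparePvalueDensities:
    def _result(self, seed, loops=()):
        cmap = tl.sample_map(rect_spec(seed, loops=loops))
        target = tl.extract_target_window(cmap, SPEC67)
        return tl.slide_window_test(cmap, SPEC67, target)

    def test_identical_grids_null_anova(self):
        res = self._result(7)
        cmp = tl.compare_pvalue_densities([res, res], ["a", "b"])
        assert cmp.f_statistic == pytest.approx(0.0, abs=1e-9)
        assert cmp.p_value == pytest.approx(1.0)

    def test_two_condition_anova_equals_squared_t(self):
        a, b = self._result(8), self._result(9)
        cmp = tl.compare_pvalue_densities([a, b], ["a", "b"])
        t = sps.ttest_ind(a.valid_pvalues(), b.valid_pvalues(),
                          equal_var=True)
        assert cmp.f_statistic == pytest.approx(t.statistic ** 2, abs=1e-6)

    def test_planted_loop_separates_conditions(self):
        wt = self._result(10, loops=[LOOP])
        ko = self._result(11)
        male = self._result(12)
        cmp = tl.compare_pvalue_densities([wt, ko, male],
                                          ["wt", "ko", "male"])
        assert cmp.p_value < 0.05
        assert cmp.densities[0] is not None

    def test_null_pvalues_uniform(self):
        # a true null needs a flat expectation: an inter-chromosomal
        # rectangle has no distance-decay gradient across positions
        spec = tl.SyntheticSpec(
            extent=GR("chrX", 23_000_000, 25_000_000),
            col_extent=GR("chr9", 48_000_000, 50_000_000),
            bin_size=BIN, depth=5e5, seed=13)
        cmap = tl.sample_map(spec)
        wspec = tl.WindowSpec(6, 7, GR("chrX", 23_980_000, 24_020_000),
                              GR("chr9", 48_980_000, 49_020_000))
        res = tl.slide_window_test(cmap, wspec,
                                   tl.extract_target_window(cmap, wspec))
        ks = sps.kstest(res.valid_pvalues(), "uniform")
        assert ks.statistic < 0.1

    def test_decay_gradient_breaks_uniformity(self):
        # within-chromosome rectangles carry a decay trend, so distant
        # positions genuinely differ from the target window
        res = self._result(13)
        ks = sps.kstest(res.valid_pvalues(), "uniform")
        assert ks.statistic > 0.1


def quad_regions():
    """Four labeled anchor loci at 100 kb bins: one 2-bin, three 1-bin."""
    return {
        "Firre": GR("chrX", 50_500_000, 50_600_000),
        "Dxz4": GR("chrX", 72_800_000, 73_000_000),   # 2 bins wide
        "x75": GR("chrX", 103_400_000, 103_500_000),
        "Icce": GR("chrX", 7_200_000, 7_300_000),
    }


def quad_map(values=None, fill=4.0):
    bs = 100_000
    n = 1100
    if values is None:
        values = np.full((n, n), fill)
    return tl.BinnedContactMap(GR("chrX", 0, n * bs), GR("chrX", 0, n * bs),
                               bs, values)


class TestSuperloopQuant:
    def test_pair_sample_sizes(self):
        quants = {(q.label_a, q.label_b): q.n
                  for q in tl.superloop_quant(quad_map(), quad_regions())}
        # pairs involving the 2-bin locus flatten 3x4 = 12 bin pairs,
        # the rest 3x3 = 9
        for pair, n in quants.items():
            assert n == (12 if "Dxz4" in pair else 9)

    def test_constant_map_identical_values(self):
        for q in tl.superloop_quant(quad_map(fill=2.5), quad_regions()):
            assert set(q.values) == {2.5}

    def test_overlapping_padded_regions_rejected(self):
        regions = dict(quad_regions())
        regions["x75"] = GR("chrX", 72_650_000, 72_750_000)  # pads into Dxz4
        with pytest.raises(ValueError, match="overlap"):
            tl.superloop_quant(quad_map(), regions)


class TestCompareSuperloop:
    def _quants(self, wt_vals, ko_vals):
        wt = tl.SuperLoopQuant("a", "b", 100_000, tuple(wt_vals))
        ko = tl.SuperLoopQuant("a", "b", 100_000, tuple(ko_vals))
        return wt, ko

    def test_identical_vectors_degenerate(self):
        res = tl.compare_superloop(*self._quants([2.0] * 9, [2.0] * 9))
        assert res.degenerate and res.p_value == 1.0
        assert res.ratio == pytest.approx(1.0)

    def test_lost_loop_detected(self):
        rng = np.random.default_rng(20)
        wt = rng.poisson(50, 12).astype(float)   # planted 5x enrichment
        ko = rng.poisson(10, 12).astype(float)
        res = tl.compare_superloop(*self._quants(wt, ko))
        assert res.p_value < 0.05 and res.ratio < 1

    def test_swap_symmetry(self):
        rng = np.random.default_rng(21)
        a = rng.poisson(30, 12).astype(float)
        b = rng.poisson(18, 12).astype(float)
        fwd = tl.compare_superloop(*self._quants(a, b))
        rev = tl.compare_superloop(*self._quants(b, a))
        assert fwd.p_value == pytest.approx(rev.p_value, abs=1e-12)
        assert fwd.ratio == pytest.approx(1.0 / rev.ratio, rel=1e-9)

    def test_gain_yields_ratio_above_one(self):
        res = tl.compare_superloop(*self._quants([10.0, 11, 9, 10],
                                                 [20.0, 21, 19, 20]))
        assert res.ratio > 1

    def test_mismatched_pairs_rejected(self):
        wt = tl.SuperLoopQuant("a", "b", 0, (1.0, 2.0))
        ko = tl.SuperLoopQuant("a", "c", 0, (1.0, 2.0))
        with pytest.raises(ValueError):
            tl.compare_superloop(wt, ko)
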