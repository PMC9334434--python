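"""Binning, relPecks normalisation, cumulative curves and the KS comparison."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pecktrack.data import DisplayGeometry, PeckPool
from pecktrack.heatmap import (
    HeatmapGrid,
    bin_pecks,
    compare_correct_error,
    cumulative_curve,
    difference_map,
    relative_heatmap,
)


def pool_from_xy(xy: np.ndarray, label: str = "X") -> PeckPool:
    xy = np.asarray(xy, dtype=float)
    events = pd.DataFrame(
        {
            "x": xy[:, 0],
            "y": xy[:, 1],
            "trial_index": np.arange(len(xy)),
            "stimulus_class": label,
            "outcome": "correct",
            "peck_index": 1,
        }
    )
    return PeckPool(events=events, selector={})


class TestBinPecks:
    @pytest.mark.parametrize(
        "xy,cell",
        [
            ((0.0, 0.0), (0, 0)),
            ((5.0, 5.0), (14, 14)),  # top/right edge folds into the last square
            ((2.5, 2.5), (7, 7)),
            ((0.34, 0.0), (1, 0)),  # just past the first square edge (1/3 cm)
        ],
    )
    def test_cell_assignment(self, geometry, xy, cell):
        counts = bin_pecks(pool_from_xy([xy]), geometry)
        assert counts[cell] == 1 and counts.sum() == 1

    def test_uniform_pecks_conserved(self, geometry, rng):
        xy = rng.uniform(0, 5, size=(1000, 2))
        counts = bin_pecks(pool_from_xy(xy), geometry)
        assert counts.sum() == 1000
        assert counts.mean() == pytest.approx(1000 / 225)

    def test_empty_pool_gives_zero_grid(self, geometry):
        counts = bin_pecks(pool_from_xy(np.empty((0, 2))), geometry)
        assert counts.sum() == 0


class TestRelativeHeatmap:
    def test_point_mass(self, geometry):
        counts = np.zeros((15, 15), dtype=int)
        counts[3, 4] = 10
        grid = relative_heatmap(counts, geometry)
        assert grid.values[3, 4] == 100.0 and grid.values.sum() == 100.0

    def test_four_to_one_split(self, geometry):
        counts = np.zeros((15, 15), dtype=int)
        counts[0, 0], counts[1, 1] = 4, 1
        grid = relative_heatmap(counts, geometry)
        assert grid.values[0, 0] == 80.0 and grid.values[1, 1] == 20.0

    def test_empty_grid_warns_and_zeroes(self, geometry):
        with pytest.warns(UserWarning, match="empty pool"):
            grid = relative_heatmap(np.zeros((15, 15), dtype=int), geometry)
        assert grid.values.sum() == 0.0 and grid.total_pecks == 0

    @given(
        st.lists(st.integers(min_value=0, max_value=50), min_size=225, max_size=225)
    )
    @settings(max_examples=50, deadline=None)
    def test_normalisation_invariant(self, flat):
        counts = np.array(flat).reshape(15, 15)
        if counts.sum() == 0:
            return
        grid = relative_heatmap(counts, DisplayGeometry())
        assert grid.values.sum() == pytest.approx(100.0, abs=1e-9)
        assert (grid.values >= 0).all()


class TestDifferenceMap:
    def test_identical_grids_cancel(self, geometry):
        counts = np.random.default_rng(0).integers(0, 5, size=(15, 15))
        counts[0, 0] += 1
        a = relative_heatmap(counts, geometry)
        assert np.all(difference_map(a, a) == 0.0)

    def test_opposed_point_masses(self, geometry):
        ca, cb = np.zeros((15, 15), int), np.zeros((15, 15), int)
        ca[2, 3], cb[9, 9] = 7, 3
        diff = difference_map(relative_heatmap(ca, geometry), relative_heatmap(cb, geometry))
        assert diff[2, 3] == 100.0 and diff[9, 9] == -100.0
        assert diff.sum() == pytest.approx(0.0)

    def test_geometry_mismatch_rejected(self):
        g1, g2 = DisplayGeometry(), DisplayGeometry(grid_n=5)
        a = relative_heatmap(np.ones((15, 15), int), g1)
        b = relative_heatmap(np.ones((5, 5), int), g2)
        with pytest.raises(ValueError, match="geometr"):
            difference_map(a, b)


class TestCumulativeCurve:
    def test_point_mass_is_one_from_rank_one(self):
        counts = np.zeros((15, 15), int)
        counts[4, 4] = 33
        fr = cumulative_curve(counts).fractions
        assert fr[0] == 1.0 and fr[-1] == 1.0

    def test_uniform_counts_are_linear(self):
        fr = cumulative_curve(np.ones((15, 15), int)).fractions
        assert np.allclose(fr, np.arange(1, 226) / 225)

    def test_toy_counts_hand_computed(self):
        # counts {5,3,2}: cumulative shares 5/10, 8/10, 10/10
        fr = cumulative_curve(np.array([[5, 3, 2]])).fractions
        assert np.allclose(fr, [0.5, 0.8, 1.0])

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError, match="at least one peck"):
            cumulative_curve(np.zeros((15, 15), int))

    @given(st.permutations(list(range(225))))
    @settings(max_examples=25, deadline=None)
    def test_invariant_to_cell_permutation(self, perm):
        rng = np.random.default_rng(42)
        counts = rng.integers(0, 10, size=225)
        base = cumulative_curve(counts.reshape(15, 15)).fractions
        shuffled = cumulative_curve(counts[np.array(perm)].reshape(15, 15)).fractions
        assert np.allclose(base, shuffled)


class TestKSComparison:
    def test_identical_pools_give_zero(self, geometry, rng):
        xy = rng.uniform(0, 5, size=(300, 2))
        res = compare_correct_error(pool_from_xy(xy), pool_from_xy(xy), geometry)
        assert res.D == 0.0 and not res.significant

    def test_point_mass_vs_uniform_analytic_d(self, geometry):
        # point-mass curve is 1 everywhere; the exactly-uniform curve is
        # r/225, so the gap peaks at rank 1: D = 1 - 1/225
        mass = pool_from_xy(np.tile([[2.5, 2.5]], (225, 1)))
        centres = np.array(
            [
                ((i + 0.5) * geometry.square_side, (j + 0.5) * geometry.square_side)
                for i in range(15)
                for j in range(15)
            ]
        )
        res = compare_correct_error(mass, pool_from_xy(centres), geometry)
        assert res.D == pytest.approx(1 - 1 / 225)
        assert res.significant

    def test_symmetric_in_pools(self, geometry, rng):
        a = pool_from_xy(rng.normal(2.5, 0.5, size=(400, 2)).clip(0, 5))
        b = pool_from_xy(rng.uniform(0, 5, size=(400, 2)))
        r1 = compare_correct_error(a, b, geometry)
        r2 = compare_correct_error(b, a, geometry)
        assert r1.D == r2.D and r1.p == r2.p

    def test_default_alpha_is_bonferroni_over_eight(self, geometry, rng):
        xy = rng.uniform(0, 5, size=(100, 2))
        res = compare_correct_error(pool_from_xy(xy), pool_from_xy(xy), geometry)
        assert res.alpha_adjusted == pytest.approx(0.05 / 8)

    def test_empty_pool_rejected(self, geometry, rng):
        xy = rng.uniform(0, 5, size=(10, 2))
        with pytest.raises(ValueError, match="non-empty"):
            compare_correct_error(pool_from_xy(np.empty((0, 2))), pool_from_xy(xy), geometry)

    def test_asymptotic_p_matches_scipy_on_raw_samples(self, rng):
        # sanity-check the asymptotic formula itself against scipy's
        # two-sample KS in asymptotic mode on ordinary 1-D samples
        from scipy.stats import ks_2samp

        from pecktrack.heatmap import ks_two_sample_pvalue

        a, b = rng.normal(size=200), rng.normal(0.3, size=300)
        ref = ks_2samp(a, b, method="asymp")
        assert ks_two_sample_pvalue(ref.statistic, 200, 300) == pytest.approx(
            ref.pvalue, rel=1e-6
        )


def test_heatmap_grid_validation(geometry):
    with pytest.raises(ValueError, match="sum to 100"):
        HeatmapGrid(values=np.ones((15, 15)), total_pecks=10, geometry=geometry)
    with pytest.raises(ValueError, match="shape"):
        HeatmapGrid(values=np.zeros((5, 5)), total_pecks=0, geometry=geometry)
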