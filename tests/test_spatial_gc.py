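"""Snapshot-based spatial Granger causality: strengths, tests, calibration."""

import numpy as np
import pytest
from scipy import stats

from engramfield.spatial_gc import (
    GCResult,
    SnapshotSeries,
    coefficient_of_variation,
    gc_over_time,
    gc_significance,
    gc_strength,
    select_order,
    window_axis_correlation,
)
from engramfield.synthetic import make_coupled_spatial_pair


class TestGCStrength:
    def test_null_strengths_are_small(self):
        a, b = make_coupled_spatial_pair(32, "none", 0.0, 1.0, n_snapshots=200, seed=1)
        vals = [gc_strength(b[i], a[i], p=1) for i in range(200)]
        assert np.median(vals) < 0.05

    def test_constructed_dependence_is_strong(self, rng):
        src = rng.standard_normal(40)
        tgt = np.roll(src, 1)  # tgt[x] = src[x-1] exactly
        tgt[0] = 0.0
        assert gc_strength(tgt, src, p=1) > 5.0

    def test_non_negative(self, rng):
        for _ in range(20):
            a = rng.standard_normal(30)
            b = rng.standard_normal(30)
            assert gc_strength(a, b, p=2) >= 0.0

    def test_affine_invariance(self, rng):
        a = rng.standard_normal(40)
        b = rng.standard_normal(40)
        s0 = gc_strength(a, b, p=1)
        assert gc_strength(3.0 * a - 2.0, b, p=1) == pytest.approx(s0, rel=1e-8)
        assert gc_strength(a, -0.5 * b + 1.0, p=1) == pytest.approx(s0, rel=1e-8)

    def test_shuffled_source_matches_independent_null(self, rng):
        # strengths against a shuffled copy of the target behave like the
        # independent-source null (same spatial marginals, no structure)
        a, _ = make_coupled_spatial_pair(32, "none", 0.0, 1.0, n_snapshots=100, seed=2)
        perm = rng.permutation(32)
        shuf = [gc_strength(a[i], a[i][perm], p=1) for i in range(100)]
        b = make_coupled_spatial_pair(32, "none", 0.0, 1.0, n_snapshots=100, seed=3)[1]
        null = [gc_strength(a[i], b[i], p=1) for i in range(100)]
        ks = stats.ks_2samp(shuf, null)
        assert ks.pvalue > 0.01

    def test_orientation_modes(self, rng):
        a, b = rng.standard_normal((2, 30))
        both = gc_strength(a, b, p=1, orientation="both")
        fwd = gc_strength(a, b, p=1, orientation="forward")
        bwd = gc_strength(a, b, p=1, orientation="backward")
        assert both == pytest.approx(0.5 * (fwd + bwd))


class TestSignificance:
    def test_perfect_dependence_tiny_pvalue(self, rng):
        src = rng.standard_normal(40)
        tgt = np.roll(src, 1)
        tgt[0] = 0.0
        s = gc_strength(tgt, src, p=1)
        assert gc_significance(s, n_obs=39, p=1) < 1e-10

    def test_null_pvalues_roughly_uniform(self):
        n_rep = 400
        pvals = []
        for i in range(n_rep):
            a, b = make_coupled_spatial_pair(32, "none", 0.0, 1.0, 1, seed=1000 + i)
            s = gc_strength(b[0], a[0], p=1)
            pvals.append(gc_significance(s, n_obs=31, p=1))
        assert stats.kstest(pvals, "uniform").pvalue > 0.01
        rate = np.mean(np.asarray(pvals) < 0.05)
        assert abs(rate - 0.05) < 0.03

    def test_insufficient_observations_rejected(self):
        with pytest.raises(ValueError):
            gc_significance(0.5, n_obs=3, p=1)


class TestDirectionality:
    def test_recovers_coupling_direction(self):
        a, b = make_coupled_spatial_pair(
            32, "a_to_b", coupling=0.8, innovation_sd=1.0, n_snapshots=200, seed=5
        )
        wins = sum(
            gc_strength(b[i], a[i], 1) > gc_strength(a[i], b[i], 1) for i in range(200)
        )
        assert wins / 200 >= 0.95

    def test_gc_over_time_direction_labels(self):
        a, b = make_coupled_spatial_pair(32, "a_to_b", 0.8, 1.0, 50, seed=6)
        fld = SnapshotSeries(a, "field")
        act = SnapshotSeries(b, "activity")
        f2a, a2f = gc_over_time(fld, act, p=1)
        assert f2a.direction == ("field", "activity")
        assert a2f.direction == ("activity", "field")
        assert np.mean(f2a.strengths) > np.mean(a2f.strengths)
        assert np.all(f2a.significance_mask == (f2a.pvalues < 0.05))

    def test_mismatched_grids_rejected(self):
        with pytest.raises(ValueError):
            gc_over_time(SnapshotSeries(np.zeros((5, 16))), SnapshotSeries(np.zeros((5, 20))))


class TestOrderSelection:
    def test_spatial_ar1_selects_order_one(self):
        hits = 0
        for i in range(20):
            a, b = make_coupled_spatial_pair(64, "none", 0.0, 1.0, 10, seed=i)
            hits += select_order(a, b, max_order=4, criterion="BIC") == 1
        assert hits >= 18

    def test_forced_single_order(self):
        a, b = make_coupled_spatial_pair(32, "none", 0.0, 1.0, 3, seed=0)
        assert select_order(a, b, max_order=1) == 1

    def test_spatial_ar2_selects_order_two(self, rng):
        hits = 0
        for i in range(20):
            r = np.random.default_rng(i)
            e = r.standard_normal((10, 64))
            x = np.zeros_like(e)
            for k in range(2, 64):
                x[:, k] = 0.4 * x[:, k - 1] - 0.5 * x[:, k - 2] + e[:, k]
            y = r.standard_normal((10, 64))
            hits += select_order(x, y, max_order=4, criterion="BIC") == 2
        assert hits >= 15

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError):
            select_order(np.zeros((3, 32)), np.ones((3, 32)), 2)


class TestCV:
    def test_constant_vector_zero(self):
        assert coefficient_of_variation([2.0, 2.0, 2.0]) == 0.0

    def test_hand_computed_value(self):
        # {1, 3}: mean 2, sample sd sqrt(2) -> 70.71%
        assert coefficient_of_variation([1.0, 3.0]) == pytest.approx(70.7107, abs=1e-3)

    def test_scale_invariance(self, rng):
        v = np.abs(rng.standard_normal(20)) + 1.0
        assert coefficient_of_variation(5.0 * v) == pytest.approx(
            coefficient_of_variation(v)
        )

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError):
            coefficient_of_variation([-1.0, 1.0])


class TestWindowAxisCorrelation:
    def test_constant_mask_rejected(self):
        with pytest.raises(ValueError):
            window_axis_correlation(np.ones(50), [np.random.rand(4, 50)])

    def test_mask_derived_from_axis_correlates(self, rng):
        H = rng.standard_normal((4, 200))
        course = np.mean(np.abs(H), axis=0)
        mask = (course > np.median(course)).astype(float)
        out = window_axis_correlation(mask, [H])
        assert out[0]["correlation"] > 0.5
        assert out[0]["significant"]

    def test_independent_axis_usually_not_significant(self):
        n_sig = 0
        for i in range(60):
            r = np.random.default_rng(i)
            H = r.standard_normal((3, 100))
            mask = r.integers(0, 2, 100).astype(float)
            if mask.min() == mask.max():
                continue
            n_sig += window_axis_correlation(mask, [H])[0]["significant"]
        assert n_sig <= 10  # ~5% nominal rate


def test_gcresult_cv_and_summary():
    res = GCResult(
        strengths=np.array([1.0, 3.0]),
        pvalues=np.array([0.01, 0.2]),
        direction=("field", "activity"),
        order_p=1,
    )
    assert res.cv_percent == pytest.approx(70.7107, abs=1e-3)
    s = res.summary()
    assert s["direction"] == "field->activity"
    assert s["fraction_significant"] == 0.5
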