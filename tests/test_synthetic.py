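"""Synthetic LFP generator and calibration fixtures."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from engramfield.field_model import BidomainParams
from engramfield.synthetic import (
    GeneratorConfig,
    channel_positions,
    default_ensemble,
    make_coupled_spatial_pair,
    make_null_rdm_pair,
    make_task_design,
    read_recording,
    simulate_coupled_recordings,
    simulate_recording,
    write_recording,
)


class TestTaskDesign:
    def test_six_trials_cover_all_angles_once(self):
        angles = (0, 60, 120, 180, 240, 300)
        tbl = make_task_design(6, angles, seed=3)
        assert sorted(tbl["cue_angle_deg"]) == sorted(float(a) for a in angles)

    def test_single_trial(self):
        tbl = make_task_design(1, (0,), seed=0)
        assert len(tbl) == 1 and tbl["cue_angle_deg"].iloc[0] == 0.0

    def test_deterministic(self):
        a = make_task_design(100, (0, 60), seed=1)
        b = make_task_design(100, (0, 60), seed=1)
        assert a.equals(b)

    @given(n=st.integers(1, 50), k=st.integers(1, 6), seed=st.integers(0, 100))
    @settings(max_examples=30, deadline=None)
    def test_balance_and_ids(self, n, k, seed):
        angles = tuple(range(0, 360, 360 // k))[:k]
        tbl = make_task_design(n, angles, seed=seed)
        counts = tbl["cue_angle_deg"].value_counts()
        assert counts.max() - counts.min() <= 1
        assert list(tbl["trial_id"]) == list(range(n))

    def test_empty_angle_set_rejected(self):
        with pytest.raises(ValueError):
            make_task_design(5, (), seed=0)


class TestSimulateRecording:
    def test_zero_noise_zero_cue_stays_at_baseline(self, positions16):
        ens = default_ensemble(positions16, noise_sd=0.0)
        cfg = GeneratorConfig(
            n_trials=2, n_channels=16, delay_ms=50, cue_angles_deg=(0.0,),
            ensemble=ens, cue_amplitude=0.0, master_seed=0,
        )
        rec = simulate_recording(cfg)
        assert np.allclose(rec.data, 0.0)

    def test_pulse_decays_back_to_baseline(self, positions16):
        ens = default_ensemble(positions16, noise_sd=0.0)
        cfg = GeneratorConfig(
            n_trials=1, n_channels=16, delay_ms=200, cue_angles_deg=(90.0,),
            ensemble=ens, cue_amplitude=0.05, cue_pulse_ms=20.0, master_seed=0,
        )
        rec = simulate_recording(cfg)
        norms = np.linalg.norm(rec.data[0], axis=0)
        post = norms[25:]
        assert np.all(np.diff(post) < 0)  # monotone decay after input offset
        assert post[-1] < 0.1 * post[0]

    def test_bit_identical_under_same_seed(self, small_ensemble):
        cfg = GeneratorConfig(
            n_trials=3, n_channels=16, delay_ms=60, ensemble=small_ensemble,
            master_seed=9,
        )
        assert np.array_equal(simulate_recording(cfg).data, simulate_recording(cfg).data)

    def test_unstable_model_refused(self, positions16):
        ens = default_ensemble(positions16, kernel_amplitude=10.0)
        cfg = GeneratorConfig(
            n_trials=1, n_channels=16, delay_ms=10, ensemble=ens, master_seed=0
        )
        with pytest.raises(ValueError, match="eigenvalue"):
            simulate_recording(cfg)

    def test_ephaptic_gain_zero_matches_non_ephaptic_bitwise(self, small_ensemble, bidomain):
        base = dict(
            n_trials=3, n_channels=16, delay_ms=80, ensemble=small_ensemble,
            master_seed=4,
        )
        off = simulate_recording(GeneratorConfig(**base))
        on = simulate_recording(
            GeneratorConfig(**base, ephaptic=True, field_params=bidomain, ephaptic_gain=0.0)
        )
        assert np.array_equal(off.data, on.data)

    def test_ephaptic_requires_field_params(self, small_ensemble):
        with pytest.raises(ValueError):
            GeneratorConfig(
                n_trials=1, n_channels=16, ensemble=small_ensemble, ephaptic=True
            )

    def test_baseline_variance_is_stationary(self, positions16):
        # with noise only, the cross-channel variance shows no trend in the
        # second half of the trial (slope-test p-values not concentrated at 0)
        ens = default_ensemble(positions16, noise_sd=0.05)
        cfg = GeneratorConfig(
            n_trials=20, n_channels=16, delay_ms=300, cue_angles_deg=(0.0,),
            ensemble=ens, cue_amplitude=0.0, master_seed=11,
        )
        rec = simulate_recording(cfg)
        pvals = []
        for trial in rec.data:
            var_t = trial.var(axis=0)
            half = var_t[var_t.size // 2 :]
            res = stats.linregress(np.arange(half.size), half)
            pvals.append(res.pvalue)
        assert np.mean(pvals) > 0.01

    def test_invariants_of_recording(self, small_recording):
        rec = small_recording
        assert np.all(np.isfinite(rec.data))
        assert np.all(np.diff(rec.channel_positions_mm) > 0)
        assert rec.data.shape[2] == 150


class TestCoupledAreas:
    def test_feedforward_changes_area2_only(self, small_ensemble):
        base = dict(
            n_trials=2, n_channels=16, delay_ms=60, ensemble=small_ensemble,
            master_seed=2,
        )
        a0, b0 = simulate_coupled_recordings(
            GeneratorConfig(**base), GeneratorConfig(**base), w_ff=0.0
        )
        a1, b1 = simulate_coupled_recordings(
            GeneratorConfig(**base), GeneratorConfig(**base), w_ff=0.1
        )
        assert np.array_equal(a0.data, a1.data)
        assert not np.array_equal(b0.data, b1.data)


class TestSpatialPairFixture:
    def test_uncoupled_pair_uncorrelated(self):
        a, b = make_coupled_spatial_pair(64, "none", 0.0, 1.0, n_snapshots=200, seed=0)
        corr = np.corrcoef(a.ravel(), b.ravel())[0, 1]
        assert abs(corr) < 0.03

    def test_zero_coupling_equals_none(self):
        a0, b0 = make_coupled_spatial_pair(32, "none", 0.0, 1.0, 5, seed=3)
        a1, b1 = make_coupled_spatial_pair(32, "a_to_b", 0.0, 1.0, 5, seed=3)
        assert np.array_equal(a0, a1) and np.array_equal(b0, b1)

    def test_negative_coupling_rejected(self):
        with pytest.raises(ValueError):
            make_coupled_spatial_pair(16, "a_to_b", -0.1, 1.0, 1, 0)

    def test_deterministic(self):
        x = make_coupled_spatial_pair(16, "a_to_b", 0.5, 1.0, 3, seed=5)
        y = make_coupled_spatial_pair(16, "a_to_b", 0.5, 1.0, 3, seed=5)
        assert np.array_equal(x[0], y[0]) and np.array_equal(x[1], y[1])


class TestNullRDMFixture:
    def test_shape_and_invariants(self):
        a, b = make_null_rdm_pair(6, seed=1)
        for m in (a, b):
            assert m.shape == (6, 6)
            assert np.allclose(m, m.T)
            assert np.allclose(np.diag(m), 0.0)
            off = m[np.triu_indices(6, 1)]
            assert np.all((off >= 0) & (off <= 2))

    def test_deterministic(self):
        assert np.array_equal(make_null_rdm_pair(5, 2)[0], make_null_rdm_pair(5, 2)[0])

    def test_too_few_conditions(self):
        with pytest.raises(ValueError):
            make_null_rdm_pair(2, 0)


def test_hdf5_round_trip(tmp_path, small_recording):
    path = tmp_path / "rec.h5"
    write_recording(small_recording, path)
    back = read_recording(path)
    assert np.array_equal(back.data, small_recording.data)
    assert np.array_equal(back.channel_positions_mm, small_recording.channel_positions_mm)
    assert back.time_step_ms == small_recording.time_step_ms
    assert list(back.trials["cue_angle_deg"]) == list(small_recording.trials["cue_angle_deg"])
    assert back.provenance["n_trials"] == small_recording.provenance["n_trials"]
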