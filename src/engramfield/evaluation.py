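"""End-to-end evaluation experiments for the package's main claims.

Each function runs one self-contained experiment — forward-model algebra,
estimator calibration, model recovery, slaving diagnostics, or the full
pipeline — from scratch at a given seed and returns a dict of summary
numbers. The test suite asserts on these numbers at fixed tolerances and
``scripts/acceptance.py`` reports them.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from . import field_model as fm
from . import mode_dynamics as md
from . import rsa as rsa_mod
from . import spatial_gc as gc_mod
from .inference import FitConfig, bayes_factor, compare_models, reml_fit_design
from .pipeline import run_pipeline
from .synthetic import (
    bmc_study_config,
    make_coupled_spatial_pair,
    make_null_rdm_pair,
    simulate_recording,
)

SLAVING_KERNEL = np.array([[0.9, 0.1], [0.1, 0.7]])


def bidomain_checks(seed: int = 0) -> dict:
    """Kernel limits, symmetry, linearity and the cosine-mode response."""
    rng = np.random.default_rng(seed)
    par = fm.BidomainParams(a_mm=0.1, y_mm=0.5)
    k = np.linspace(0.1, 40.0, 200)
    evenness = float(np.max(np.abs(fm.bidomain_kernel(k, par) - fm.bidomain_kernel(-k, par))))
    x = np.linspace(0.0, 2.0, 64)
    v1, v2 = rng.standard_normal((2, 64))
    a, b = 1.3, -0.7
    lhs = fm.extracellular_potential(a * v1 + b * v2, x, par)
    rhs = a * fm.extracellular_potential(v1, x, par) + b * fm.extracellular_potential(v2, x, par)
    sup_resid = float(np.max(np.abs(lhs - rhs)) / np.max(np.abs(lhs)))
    k0 = 2 * np.pi * np.fft.fftfreq(64, d=x[1] - x[0])[4]
    V = np.cos(k0 * x)
    Ve = fm.extracellular_potential(V, x, par)
    gain = -(4 * np.pi * par.sigma_e / par.sigma_i) * fm.bidomain_kernel(np.array([k0]), par)[0]
    cos_err = float(np.max(np.abs(Ve - gain * V)) / np.max(np.abs(Ve)))
    return {
        "W_at_zero": float(fm.bidomain_kernel(np.array([0.0]), par)[0]),
        "evenness_max_abs_diff": evenness,
        "superposition_rel_residual": sup_resid,
        "cosine_mode_rel_error": cos_err,
        "n": 64,
    }


def farfield_checks() -> dict:
    """Multipole coefficient value and relaxation fixed point."""
    p_unit = fm.FarFieldParams(tau_EP_ms=1.0, gamma=1.0, r_mm=1.0, L_mm=1.0)
    Z_unit = fm.multipole_coefficient(p_unit)
    p = fm.FarFieldParams(tau_EP_ms=3.0, gamma=0.8, r_mm=2.0, L_mm=1.0)
    Z = fm.multipole_coefficient(p)
    drive, dt = 1.5, 0.01
    v = 0.0
    for _ in range(int(30 * p.tau_EP_ms / dt)):
        v = fm.step_farfield(v, drive, p, dt)
    target = p.tau_EP_ms * Z * drive
    return {
        "Z_unit_params": float(Z_unit),
        "fixed_point_rel_error": float(abs(v - target) / abs(target)),
        "n": int(30 * p.tau_EP_ms / dt),
    }


def reml_checks(seed: int = 0, n_problems: int = 100) -> dict:
    """Weight recovery at SNR 10 and Free-Energy monotonicity."""
    rng = np.random.default_rng(seed)
    H = rng.standard_normal((200 * 5, 6))
    w = rng.standard_normal(6)
    signal = H @ w
    Y = signal + (np.std(signal) / 10.0) * rng.standard_normal(signal.size)
    res = reml_fit_design(Y, H)
    corr = float(np.corrcoef(res.w, w)[0, 1])
    worst = 0.0
    for _ in range(n_problems):
        n, p = int(rng.integers(30, 120)), int(rng.integers(2, 6))
        Hr = rng.standard_normal((n, p))
        Yr = Hr @ rng.standard_normal(p) + rng.uniform(0.05, 1.0) * rng.standard_normal(n)
        path = reml_fit_design(Yr, Hr).free_energy_path
        worst = max(worst, float(np.max(-np.diff(path), initial=0.0)))
    return {
        "recovery_corr": corr,
        "max_free_energy_decrease": worst,
        "n": n_problems,
    }


def bmc_recovery(seed: int = 0, n_per_model: int = 50) -> dict:
    """Signed-winner confusion of the ephaptic vs non-ephaptic comparison."""
    field_cfg = fm.BidomainParams(a_mm=0.1, y_mm=0.5)
    hits = {True: 0, False: 0}
    means = {True: [], False: []}
    for ephaptic in (False, True):
        for i in range(n_per_model):
            ds_seed = seed * 1_000_003 + i
            rec = simulate_recording(bmc_study_config(ephaptic, seed=ds_seed))
            res = compare_models(rec, field_cfg, FitConfig(split_seed=ds_seed))
            expected = "ephaptic" if ephaptic else "non_ephaptic"
            hits[ephaptic] += res.signed_winner == expected
            means[ephaptic].append(res.mean_bf)
    return {
        "accuracy_non_ephaptic_pct": 100.0 * hits[False] / n_per_model,
        "accuracy_ephaptic_pct": 100.0 * hits[True] / n_per_model,
        "accuracy_overall_pct": 100.0 * (hits[False] + hits[True]) / (2 * n_per_model),
        "mean_bf_non_ephaptic_data": float(np.mean(means[False])),
        "mean_bf_ephaptic_data": float(np.mean(means[True])),
        "sign_convention_positive_favours_non_ephaptic": bayes_factor(0.0, 10.0) > 0,
        "n": 2 * n_per_model,
    }


def gc_checks(seed: int = 0, n_null: int = 1000, n_directional: int = 200) -> dict:
    """F-test calibration under the null and directionality recovery."""
    pvals = np.empty(n_null)
    for i in range(n_null):
        a, b = make_coupled_spatial_pair(32, "none", 0.0, 1.0, 1, seed=seed * 7 + i)
        s = gc_mod.gc_strength(b[0], a[0], p=1)
        pvals[i] = gc_mod.gc_significance(s, n_obs=31, p=1)
    type1 = float(np.mean(pvals < 0.05))
    ks_p = float(stats.kstest(pvals, "uniform").pvalue)
    a, b = make_coupled_spatial_pair(
        32, "a_to_b", coupling=0.8, innovation_sd=1.0,
        n_snapshots=n_directional, seed=seed + 12345,
    )
    wins = sum(
        gc_mod.gc_strength(b[i], a[i], 1) > gc_mod.gc_strength(a[i], b[i], 1)
        for i in range(n_directional)
    )
    return {
        "null_type1_error": type1,
        "null_ks_pvalue": ks_p,
        "direction_recovery_pct": 100.0 * wins / n_directional,
        "cv_of_1_3_pct": gc_mod.coefficient_of_variation([1.0, 3.0]),
        "n": n_null,
    }


def slaving_checks(seed: int = 0) -> dict:
    """Adiabatic tracking error and its monotone decay across ratios."""
    ratios = (1, 3, 10, 30, 100)
    errs, rho = md.slaving_error_curve(SLAVING_KERNEL, ratios=ratios, seed=seed)
    return {
        "tracking_error_ratio100_pct": 100.0 * float(errs[-1]),
        "spearman_error_vs_ratio": rho,
        "errors_pct": [100.0 * float(e) for e in errs],
        "n": len(ratios),
    }


def determinant_checks(seed: int = 0, n_systems: int = 100) -> dict:
    """Block-determinant identities and the shared-coupling implication."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    implication_ok = 0
    for _ in range(n_systems):
        A, C, D = (rng.standard_normal((4, 4)) + 2 * np.eye(4) for _ in range(3))
        rep = md.engram_condition(md.two_area_from_blocks(A, np.zeros((4, 4)), C, D))
        worst = max(worst, rep["factorization_residual"])
        implication_ok += rep["implication_holds"]
    sys_unit = md.build_two_area_blocks(
        np.zeros((2, 2)), np.zeros((2, 2)), 1.0, 1.0, 0.5, 1.0, 1.0, beta=0.0
    )
    return {
        "max_factorization_residual": float(worst),
        "implication_holds_fraction": implication_ok / n_systems,
        "det_J_unit_params": float(np.linalg.det(sys_unit.J)),
        "n": n_systems,
    }


def rsa_checks(seed: int = 0, n_replicates: int = 1000, n_relabelings: int = 1000) -> dict:
    """Deviation identities and randomization-test calibration."""
    a, _ = make_null_rdm_pair(6, seed=seed)
    rev = a.max() + a.min() - a
    np.fill_diagonal(rev, 0.0)
    rejections = 0
    for i in range(n_replicates):
        x, y = make_null_rdm_pair(6, seed=seed * 11 + 1 + i)
        res = rsa_mod.randomization_test(x, y, n_relabelings=n_relabelings, seed=i)
        rejections += res.p_value <= 0.05
    return {
        "deviation_identical": float(rsa_mod.deviation(a, a)),
        "deviation_rank_reversed": float(rsa_mod.deviation(a, rev)),
        "null_rejection_rate": rejections / n_replicates,
        "n": n_replicates,
    }


def end_to_end(seed: int = 0) -> dict:
    """One seeded two-area pipeline run on ephaptic-generator data."""
    rep = run_pipeline({"master_seed": seed})
    bmc = rep.stages["bmc"]["summary"]
    gc = rep.stages["gc"]["summary"]["area1"]
    rsa = rep.stages["rsa"]["summary"]
    return {
        "mean_bf_area1": bmc["area1"]["mean_bf"],
        "mean_bf_area2": bmc["area2"]["mean_bf"],
        "winner_area1": bmc["area1"]["winner"],
        "winner_area2": bmc["area2"]["winner"],
        "gc_field_to_activity_mean": gc["field_to_activity"]["mean_strength"],
        "gc_activity_to_field_mean": gc["activity_to_field"]["mean_strength"],
        "cv_field_to_activity_pct": gc["field_to_activity"]["cv_percent"],
        "cv_activity_to_field_pct": gc["activity_to_field"]["cv_percent"],
        "rsa_field_deviation": rsa["field"]["deviation"],
        "rsa_field_pvalue": rsa["field"]["p_value"],
        "rsa_lfp_pvalue": rsa["lfp"]["p_value"],
        "n": rep.config["n_trials"],
    }
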