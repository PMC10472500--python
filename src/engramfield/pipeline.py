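"""End-to-end orchestration: simulate -> field -> BMC -> spatial GC -> RSA.

Two areas are simulated: an FEF-like area 1 that feeds forward into an
SEF-like area 2 (asymmetric coupling ``w_ff``); each stage then runs on the
simulated recordings and its summary lands in a :class:`RunReport`. A
failed stage is recorded (with the error) and its dependents are skipped;
every run is a pure function of the validated config and the master seed,
whose hash is stamped into the report and every written artifact.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .field_model import BidomainParams, bidomain_operator
from .inference import FitConfig, compare_models
from .rsa import build_rdm, deviation, randomization_test, trial_patterns
from .spatial_gc import SnapshotSeries, gc_over_time
from .synthetic import (
    DEFAULT_CUE_ANGLES,
    GeneratorConfig,
    channel_positions,
    default_ensemble,
    simulate_coupled_recordings,
    write_recording,
)

__all__ = ["PipelineConfig", "RunReport", "validate_config", "run_pipeline"]

SCHEMA_VERSION = 1


@dataclass(frozen=True)
class PipelineConfig:
    """Validated, normalized configuration of a full pipeline run."""

    # task / generator (defaults: the calibrated desk-scale study conditions)
    n_trials: int = 36
    n_channels: int = 16
    delay_ms: float = 400.0
    time_step_ms: float = 1.0
    cue_angles_deg: tuple[float, ...] = DEFAULT_CUE_ANGLES
    patch_length_mm: float = 2.0
    tau_X_ms: float = 20.0
    gain: float = 1.0
    threshold: float = 0.0
    kernel_amplitude: float = 0.08
    kernel_width_mm: float = 0.12
    noise_sd: float = 0.02
    cue_amplitude: float = 0.01
    cue_width_mm: float = 0.3
    ephaptic: bool = True
    ephaptic_gain: float = 8.0
    w_ff: float = 0.02
    # field model
    sigma_e: float = 1.0
    sigma_i: float = 1.0
    a_mm: float = 0.1
    y_mm: float = 0.5
    # inference
    order_J: int = 4
    # spatial GC
    gc_order_p: int = 1
    gc_alpha: float = 0.05
    gc_orientation: str = "forward"
    # rsa
    rsa_n_relabelings: int = 10_000
    # run
    out_dir: str | None = None
    master_seed: int = 0
    schema_version: int = SCHEMA_VERSION

    def field_params(self) -> BidomainParams:
        return BidomainParams(self.sigma_e, self.sigma_i, self.a_mm, self.y_mm)

    def generator(self, area_seed_offset: int = 0) -> GeneratorConfig:
        positions = channel_positions(self.n_channels, self.patch_length_mm)
        ens = default_ensemble(
            positions,
            tau_X_ms=self.tau_X_ms,
            gain=self.gain,
            threshold=self.threshold,
            kernel_amplitude=self.kernel_amplitude,
            kernel_width_mm=self.kernel_width_mm,
            noise_sd=self.noise_sd,
        )
        return GeneratorConfig(
            n_trials=self.n_trials,
            n_channels=self.n_channels,
            delay_ms=self.delay_ms,
            time_step_ms=self.time_step_ms,
            cue_angles_deg=self.cue_angles_deg,
            patch_length_mm=self.patch_length_mm,
            ensemble=ens,
            ephaptic=self.ephaptic,
            field_params=self.field_params() if self.ephaptic else None,
            ephaptic_gain=self.ephaptic_gain,
            cue_amplitude=self.cue_amplitude,
            cue_width_mm=self.cue_width_mm,
            master_seed=self.master_seed + area_seed_offset,
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cue_angles_deg"] = list(self.cue_angles_deg)
        return d

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def validate_config(source) -> PipelineConfig:
    """Normalize a YAML path / dict into a PipelineConfig, aggregating errors.

    Unknown keys and out-of-range values are collected and reported
    together in a single ValueError.
    """
    if isinstance(source, PipelineConfig):
        return source
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            raw = yaml.safe_load(fh) or {}
    else:
        raw = dict(source or {})
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    errors = [f"unknown key: {k}" for k in raw if k not in known]
    raw = {k: v for k, v in raw.items() if k in known}
    if "cue_angles_deg" in raw:
        raw["cue_angles_deg"] = tuple(float(a) for a in raw["cue_angles_deg"])
    positive = [
        "n_trials", "n_channels", "delay_ms", "time_step_ms", "tau_X_ms",
        "patch_length_mm", "sigma_e", "sigma_i", "a_mm",
    ]
    for key in positive:
        if key in raw and not (isinstance(raw[key], (int, float)) and raw[key] > 0):
            errors.append(f"{key} must be a positive number (got {raw[key]!r})")
    for key in ("noise_sd", "ephaptic_gain", "w_ff", "kernel_width_mm"):
        if key in raw and not isinstance(raw[key], (int, float)):
            errors.append(f"{key} must be numeric (got {raw[key]!r})")
    if errors:
        raise ValueError("invalid pipeline config:\n  " + "\n  ".join(errors))
    cfg = PipelineConfig(**raw)
    try:
        cfg.field_params()
        cfg.generator()
    except ValueError as exc:
        raise ValueError(f"invalid pipeline config: {exc}") from exc
    return cfg


@dataclass
class RunReport:
    """Per-stage summaries of one pipeline run."""

    config: dict
    config_hash: str
    master_seed: int
    version: str = __version__
    stages: dict = field(default_factory=dict)

    def record(self, name: str, status: str, summary=None, error: str | None = None):
        entry = {"status": status}
        if summary is not None:
            entry["summary"] = summary
        if error is not None:
            entry["error"] = error
        self.stages[name] = entry

    def completed(self, name: str) -> bool:
        return self.stages.get(name, {}).get("status") == "completed"

    def to_json(self, path=None) -> str:
        payload = json.dumps(dataclasses.asdict(self), indent=2, default=_jsonify)
        if path is not None:
            Path(path).write_text(payload)
        return payload


def _jsonify(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serializable: {type(x)}")


def _field_series(rec, B: np.ndarray) -> np.ndarray:
    """Per-trial field data: B applied to every snapshot."""
    return np.einsum("cd,ndt->nct", B, rec.data)


def run_pipeline(config: PipelineConfig | dict | str) -> RunReport:
    """Execute all stages on a two-area simulated dataset.

    Returns the report; if ``config.out_dir`` is set, HDF5/CSV/JSON
    artifacts are written there as well.
    """
    cfg = validate_config(config)
    report = RunReport(cfg.to_dict(), cfg.config_hash, cfg.master_seed)
    out = Path(cfg.out_dir) if cfg.out_dir else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    # --- simulate ----------------------------------------------------------
    try:
        rec_a, rec_b = simulate_coupled_recordings(
            cfg.generator(0), cfg.generator(1), w_ff=cfg.w_ff
        )
        for rec in (rec_a, rec_b):
            rec.provenance["config_hash"] = cfg.config_hash
        report.record(
            "simulate",
            "completed",
            {
                "n_trials": rec_a.n_trials,
                "n_channels": rec_a.data.shape[1],
                "n_time": rec_a.data.shape[2],
                "rms_area1": float(np.sqrt(np.mean(rec_a.data**2))),
                "rms_area2": float(np.sqrt(np.mean(rec_b.data**2))),
            },
        )
        if out is not None:
            write_recording(rec_a, out / "area1.h5")
            write_recording(rec_b, out / "area2.h5")
    except Exception as exc:  # pragma: no cover - defensive
        report.record("simulate", "failed", error=repr(exc))
        for stage in ("field", "bmc", "gc", "rsa"):
            report.record(stage, "skipped", error="simulate failed")
        return report

    # --- field -------------------------------------------------------------
    try:
        B = bidomain_operator(rec_a.channel_positions_mm, cfg.field_params())
        field_a = _field_series(rec_a, B)
        field_b = _field_series(rec_b, B)
        report.record(
            "field",
            "completed",
            {
                "max_abs_Ve_area1": float(np.max(np.abs(field_a))),
                "max_abs_Ve_area2": float(np.max(np.abs(field_b))),
            },
        )
    except Exception as exc:
        report.record("field", "failed", error=repr(exc))
        report.record("gc", "skipped", error="field failed")
        report.record("rsa", "skipped", error="field failed")
        field_a = field_b = None

    # --- Bayesian model comparison -----------------------------------------
    try:
        fit_cfg = FitConfig(order_J=cfg.order_J, split_seed=cfg.master_seed)
        bmc = {}
        for name, rec in (("area1", rec_a), ("area2", rec_b)):
            cmp_res = compare_models(rec, cfg.field_params(), fit_cfg)
            bmc[name] = {
                "mean_bf": cmp_res.mean_bf,
                "winner": cmp_res.winner,
                "signed_winner": cmp_res.signed_winner,
                "bf_mean_per_angle": cmp_res.bf_mean_per_angle,
                "complexity_diff": cmp_res.complexity_diff,
            }
            if out is not None:
                cmp_res.to_frame().to_csv(out / f"bmc_{name}.csv", index=False)
        report.record("bmc", "completed", bmc)
    except Exception as exc:
        report.record("bmc", "failed", error=repr(exc))

    # --- spatial GC ---------------------------------------------------------
    if field_a is not None:
        try:
            gc_summary = {}
            rows = []
            for name, rec, fld in (("area1", rec_a, field_a), ("area2", rec_b, field_b)):
                act = SnapshotSeries(rec.data.mean(axis=0).T, "activity", name)
                fse = SnapshotSeries(fld.mean(axis=0).T, "field", name)
                f2a, a2f = gc_over_time(
                    fse, act, p=cfg.gc_order_p, alpha=cfg.gc_alpha,
                    orientation=cfg.gc_orientation,
                )
                gc_summary[name] = {
                    "field_to_activity": f2a.summary(),
                    "activity_to_field": a2f.summary(),
                }
                for res in (f2a, a2f):
                    for i, (s, p) in enumerate(zip(res.strengths, res.pvalues)):
                        rows.append(
                            {"area": name, "snapshot": i,
                             "direction": "->".join(res.direction),
                             "strength": s, "pvalue": p,
                             "significant": p < cfg.gc_alpha}
                        )
            fa = SnapshotSeries(field_a.mean(axis=0).T, "field_area1", "area1")
            fb = SnapshotSeries(field_b.mean(axis=0).T, "field_area2", "area2")
            ab, ba = gc_over_time(
                fa, fb, p=cfg.gc_order_p, alpha=cfg.gc_alpha,
                orientation=cfg.gc_orientation,
            )
            gc_summary["between_areas"] = {
                "area1_to_area2": ab.summary(),
                "area2_to_area1": ba.summary(),
            }
            report.record("gc", "completed", gc_summary)
            if out is not None:
                pd.DataFrame(rows).to_csv(out / "gc.csv", index=False)
        except Exception as exc:
            report.record("gc", "failed", error=repr(exc))

    # --- RSA ----------------------------------------------------------------
    if field_a is not None:
        try:
            rsa_summary = {}
            angles = sorted(set(float(a) for a in rec_a.cue_angles))
            for source, da, db in (
                ("lfp", rec_a.data, rec_b.data),
                ("field", field_a, field_b),
            ):
                pats_a, pats_b = {}, {}
                for ang in angles:
                    idx = np.flatnonzero(np.isclose(rec_a.cue_angles, ang))
                    pats_a[ang] = trial_patterns(da[idx]).mean(axis=0)
                    pats_b[ang] = trial_patterns(db[idx]).mean(axis=0)
                rdm_a = build_rdm(pats_a, source=source, area="area1")
                rdm_b = build_rdm(pats_b, source=source, area="area2")
                res = randomization_test(
                    rdm_a, rdm_b, n_relabelings=cfg.rsa_n_relabelings,
                    seed=cfg.master_seed + 17,
                )
                rsa_summary[source] = {
                    "deviation": deviation(rdm_a, rdm_b),
                    "p_value": res.p_value,
                    "n_relabelings": res.n_relabelings,
                }
                if out is not None:
                    pd.DataFrame(
                        rdm_a.matrix, index=angles, columns=angles
                    ).to_csv(out / f"rdm_{source}_area1.csv")
                    pd.DataFrame(
                        rdm_b.matrix, index=angles, columns=angles
                    ).to_csv(out / f"rdm_{source}_area2.csv")
            report.record("rsa", "completed", rsa_summary)
        except Exception as exc:
            report.record("rsa", "failed", error=repr(exc))

    if out is not None:
        report.to_json(out / "report.json")
    return report
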