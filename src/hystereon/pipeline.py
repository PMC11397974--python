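"""End-to-end pipeline: simulate -> schedule -> identify -> estimate ->
forecast -> evaluate, with a reproducible run manifest.

For each synthetic subject the pipeline

1. builds the protocol timeline and generates the full sensor record;
2. estimates impedance spectra from every session's forced-oscillation
   record and identifies the constant-phase model, giving the *measured*
   hysteresivity per session and band;
3. keeps direct measurements only at the calibration sessions {1, 5, 10}
   and trains the HR-driven estimator on them;
4. derives 1-Hz HR from the ECG leads, trains the HR forecaster, and runs
   the dual-step forecast (next-window HR -> hysteresivity);
5. scores both paths against the generator's ground truth on the
   non-calibration sessions.

Reruns with the same config are seed-identical; the manifest records the
config hash, all derived seeds, and every metric report.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .errors import ConfigError, HystereonError
from .estimator import (
    CalibrationSet, SequenceModelConfig, estimate_eta, estimates_to_csv,
    prepare_sequences, train_estimator,
)
from .forecaster import ForecastConfig, derive_hr_input, forecast_eta, train_hr_forecaster
from .impedance import estimate_spectrum, fit_constant_phase
from .metrics import evaluate
from .preprocess import PreprocessConfig, remove_outliers, smooth
from .protocol import align_stream, build_timeline, eqv_extraction_windows
from .synthdata import SubjectProfile, generate_session, random_profiles

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "process_subject", "evaluate_cohort"]


def _sub_seed(base: int, offset: int) -> int:
    return int((base + offset) % (2**31 - 1))


@dataclass
class RunConfig:
    """One config drives every stage; unknown keys are rejected by name."""

    n_subjects: int = 1
    seed: int = 0
    n_sessions: int = 10
    calibration_sessions: tuple = (1, 5, 10)
    bands: tuple = ("low", "high")
    fot_noise_sd: float = 0.01
    ecg_noise_sd: float = 0.02
    forecast_from_ecg: bool = True
    write_ecg: bool = False
    metrics_method: str = "ttest"
    out_dir: str = "hystereon_run"
    estimator: dict = field(default_factory=dict)
    forecaster: dict = field(default_factory=dict)
    preprocess: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.calibration_sessions = tuple(int(s) for s in self.calibration_sessions)
        self.bands = tuple(self.bands)
        for b in self.bands:
            if b not in ("low", "high"):
                raise ConfigError(f"unknown band {b!r}")
        if any(s < 1 or s > self.n_sessions for s in self.calibration_sessions):
            raise ConfigError("calibration_sessions must lie in 1..n_sessions")
        # validate nested configs eagerly so bad keys fail before any work
        self.estimator_config(0)
        self.forecaster_config(0)
        self.preprocess_config()

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def _nested(self, cls_, data: dict, seed: int | None = None):
        known = {f.name for f in dataclasses.fields(cls_)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown {cls_.__name__} keys: {sorted(unknown)}")
        kwargs = dict(data)
        if seed is not None and "seed" not in kwargs:
            kwargs["seed"] = seed
        return cls_(**kwargs)

    def estimator_config(self, seed: int) -> SequenceModelConfig:
        return self._nested(SequenceModelConfig, self.estimator, seed)

    def forecaster_config(self, seed: int) -> ForecastConfig:
        return self._nested(ForecastConfig, self.forecaster, seed)

    def preprocess_config(self) -> PreprocessConfig:
        return self._nested(PreprocessConfig, self.preprocess)

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _measured_eta(session, band: str, cfg: RunConfig) -> dict:
    """Identify the constant-phase model for every session of one band."""
    out = {}
    for rec in session.fot_records[band]:
        spectrum = estimate_spectrum(rec.pressure, rec.flow, rec.grid, rec.fs,
                                     band=band, session_index=rec.session_index)
        params = fit_constant_phase(spectrum)
        out[rec.session_index] = params.eta
    return out


def process_subject(profile: SubjectProfile, cfg: RunConfig) -> dict:
    """Run every stage for one subject; returns the subject's result bundle."""
    timeline = build_timeline(n_sessions=cfg.n_sessions)
    session = generate_session(
        profile, timeline, fot_noise_sd=cfg.fot_noise_sd,
        ecg_noise_sd=cfg.ecg_noise_sd, with_ecg=cfg.forecast_from_ecg,
        bands=cfg.bands,
    )
    pre_cfg = cfg.preprocess_config()
    hr_clean = smooth(remove_outliers(session.streams["hr"], pre_cfg),
                      pre_cfg.smooth_window)
    windows = eqv_extraction_windows(timeline)
    hr_segments = {seg.session_index: seg
                   for seg in align_stream(hr_clean, windows)}

    if cfg.forecast_from_ecg:
        ecg_hr = derive_hr_input(
            (session.streams["ecg_lead1"], session.streams["ecg_lead2"]),
            timeline, pre_cfg,
        )
    else:
        ecg_hr = hr_segments

    fc_cfg = cfg.forecaster_config(_sub_seed(profile.seed, 7))
    forecaster = train_hr_forecaster(ecg_hr, fc_cfg)
    order = sorted(ecg_hr)
    hr_forecasts = {
        order[i + 1]: forecaster.forecast_window(ecg_hr[order[i]].values)
        for i in range(len(order) - 1)
    }

    result = {"subject_id": profile.subject_id, "seed": profile.seed, "bands": {}}
    for bi, band in enumerate(cfg.bands):
        measured = _measured_eta(session, band, cfg)
        calibration = CalibrationSet.from_measurements(
            measured, band=band, sessions=cfg.calibration_sessions)
        est_cfg = cfg.estimator_config(_sub_seed(profile.seed, 100 + bi))
        data = prepare_sequences(hr_segments, calibration, est_cfg)
        model = train_estimator(data)
        estimates = estimate_eta(model, data, n_sessions=cfg.n_sessions)
        forecasts = forecast_eta(hr_forecasts, model, calibration)

        truth = session.true_eta[band]
        non_cal = [s for s in range(1, cfg.n_sessions + 1)
                   if s not in cfg.calibration_sessions]
        est_map = {e.session_index: e.eta_hat for e in estimates}
        fc_map = {e.session_index: e.eta_hat for e in forecasts}
        est_sessions = [s for s in non_cal if s in est_map]
        fc_sessions = [s for s in non_cal if s in fc_map]

        result["bands"][band] = {
            "measured_eta": measured,
            "true_eta": {s: float(truth[s - 1]) for s in range(1, cfg.n_sessions + 1)},
            "estimates": [dataclasses.asdict(e) for e in estimates],
            "forecasts": [dataclasses.asdict(e) for e in forecasts],
            "estimation_pairs": {
                "sessions": est_sessions,
                "true": [float(truth[s - 1]) for s in est_sessions],
                "pred": [est_map[s] for s in est_sessions],
            },
            "forecast_pairs": {
                "sessions": fc_sessions,
                "true": [float(truth[s - 1]) for s in fc_sessions],
                "pred": [fc_map[s] for s in fc_sessions],
            },
            "estimation_metrics": evaluate(
                [truth[s - 1] for s in est_sessions],
                [est_map[s] for s in est_sessions],
                method=cfg.metrics_method,
            ).to_dict(),
            "forecast_metrics": evaluate(
                [truth[s - 1] for s in fc_sessions],
                [fc_map[s] for s in fc_sessions],
                method=cfg.metrics_method,
            ).to_dict(),
        }
    return result


def _write_subject_artifacts(profile, cfg: RunConfig, result: dict,
                             out_dir: Path) -> None:
    import pandas as pd

    sdir = out_dir / profile.subject_id
    sdir.mkdir(parents=True, exist_ok=True)
    for band, bundle in result["bands"].items():
        pd.DataFrame([
            {"session_index": s,
             "true_eta": bundle["true_eta"][s],
             "measured_eta": bundle["measured_eta"].get(s)}
            for s in sorted(bundle["true_eta"])
        ]).to_csv(sdir / f"eta_{band}.csv", index=False)
        for key in ("estimates", "forecasts"):
            pd.DataFrame(bundle[key]).to_csv(sdir / f"{key}_{band}.csv", index=False)


def run_pipeline(cfg: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Execute all stages for every subject and write the run manifest."""
    out = Path(out_dir or cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    profiles = random_profiles(cfg.n_subjects, seed=cfg.seed)
    timeline = build_timeline(n_sessions=cfg.n_sessions)
    timeline.to_json(out / "timeline.json")

    manifest = {
        "package_version": __version__,
        "config": asdict(cfg),
        "config_hash": cfg.hash(),
        "n_sessions": cfg.n_sessions,
        "calibration_sessions": list(cfg.calibration_sessions),
        "subjects": [],
    }
    for profile in profiles:
        try:
            result = process_subject(profile, cfg)
        except HystereonError as exc:
            raise type(exc)(
                f"subject {profile.subject_id}: {exc}"
            ) from exc
        _write_subject_artifacts(profile, cfg, result, out)
        for band, bundle in result["bands"].items():
            bundle["counts"] = {
                "sessions": cfg.n_sessions,
                "calibration": len(cfg.calibration_sessions),
                "estimated": sum(1 for e in bundle["estimates"]
                                 if e["source"] == "model"),
                "forecast": sum(1 for e in bundle["forecasts"]
                                if e["source"] == "forecast"),
            }
        manifest["subjects"].append(result)
        logger.info("subject %s done", profile.subject_id)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=float))
    return manifest


def evaluate_cohort(n_subjects: int = 20, seed: int = 0,
                    cfg: RunConfig | None = None) -> dict:
    """Pooled estimation- and forecast-path accuracy on a synthetic cohort.

    Runs the full pipeline for ``n_subjects`` seeded subjects and pools the
    (true, predicted) hysteresivity pairs of all non-calibration sessions
    across subjects and bands, for both the estimation path (measured HR)
    and the dual-step forecast path (ECG-derived, forecasted HR).
    """
    cfg = cfg or RunConfig()
    cfg = dataclasses.replace(cfg, n_subjects=n_subjects, seed=seed)
    profiles = random_profiles(n_subjects, seed=seed)
    pools = {"estimation": ([], []), "forecast": ([], [])}
    per_subject = []
    for profile in profiles:
        result = process_subject(profile, cfg)
        for band, bundle in result["bands"].items():
            for path, key in (("estimation", "estimation_pairs"),
                              ("forecast", "forecast_pairs")):
                pools[path][0].extend(bundle[key]["true"])
                pools[path][1].extend(bundle[key]["pred"])
        per_subject.append(result)

    out = {"n_subjects": n_subjects, "seed": seed, "per_subject": per_subject}
    for path, (y, y_hat) in pools.items():
        rep = evaluate(y, y_hat, method=cfg.metrics_method)
        out[path] = rep.to_dict()
    return out
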