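"""Hysteresivity estimation from continuous heart rate with sparse calibration.

Direct forced-oscillation measurements are reduced from ten per protocol to
three: sessions {1, 5, 10} keep their device-measured hysteresivity and act
as calibration points.  A sequence model (one LSTM layer, 50 hidden units,
linear regression head) is trained per subject on overlapping stride-1
sub-windows of the calibration sessions' 1-Hz HR segments, each labeled with
that session's measured eta; the remaining sessions are estimated by
averaging the model's window-level predictions.  Inputs and labels are
z-scored with statistics fitted on the training data only, and predictions
are mapped back through the inverse transform.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import CoverageError, InvalidArgumentError
from .nn import LSTMRegressor
from .preprocess import NormParams
from .streams import SensorStream

__all__ = [
    "CalibrationSet",
    "SequenceModelConfig",
    "EtaEstimate",
    "SequenceData",
    "EtaModel",
    "prepare_sequences",
    "train_estimator",
    "estimate_eta",
    "estimates_to_csv",
]

DEFAULT_CALIBRATION_SESSIONS = (1, 5, 10)


@dataclass
class CalibrationSet:
    """Sessions with a direct device measurement of eta (one band)."""

    eta_values: dict  # session_index -> measured eta
    band: str = "low"

    def __post_init__(self) -> None:
        self.eta_values = {int(k): float(v) for k, v in self.eta_values.items()}
        if not self.eta_values:
            raise InvalidArgumentError("calibration set is empty")
        if any(k < 1 for k in self.eta_values):
            raise InvalidArgumentError("calibration session indices are 1-based")

    @property
    def session_indices(self) -> tuple:
        return tuple(sorted(self.eta_values))

    @classmethod
    def from_measurements(cls, eta_by_session: dict, band: str = "low",
                          sessions=DEFAULT_CALIBRATION_SESSIONS) -> "CalibrationSet":
        missing = [s for s in sessions if s not in eta_by_session]
        if missing:
            raise InvalidArgumentError(f"no measured eta for calibration sessions {missing}")
        return cls({s: eta_by_session[s] for s in sessions}, band=band)


@dataclass
class SequenceModelConfig:
    """Estimator hyperparameters (defaults follow the single-layer, 50-unit
    architecture with Adam at 1e-3 for at most 200 epochs)."""

    hidden_units: int = 50
    n_layers: int = 1
    input_window: int = 60  # samples of 1-Hz HR = 1 min
    max_epochs: int = 200
    learning_rate: float = 1e-3
    split_ratio: float = 0.7
    patience: int = 20
    batch_size: int | None = None  # full-batch by default
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hidden_units < 1:
            raise InvalidArgumentError("hidden_units must be >= 1")
        if not 0.0 < self.split_ratio < 1.0:
            raise InvalidArgumentError("split_ratio must lie in (0, 1)")
        if self.input_window < 1:
            raise InvalidArgumentError("input_window must be >= 1")


@dataclass
class EtaEstimate:
    """Per-session hysteresivity with its provenance."""

    session_index: int
    eta_hat: float
    source: str  # "calibration" | "model" | "forecast"
    band: str = "low"


@dataclass
class SequenceData:
    """Windowed training and inference sets plus the fitted normalizations."""

    x_train: np.ndarray  # (N, T)
    y_train: np.ndarray  # (N,)
    train_sessions: np.ndarray  # (N,) session index per window
    inference: dict  # session_index -> (M, T) windows, normalized
    x_norm: NormParams
    y_norm: NormParams
    calibration: CalibrationSet
    config: SequenceModelConfig


def _windows(values: np.ndarray, width: int, stride: int = 1) -> np.ndarray:
    n = values.size - width + 1
    if n < 1:
        raise InvalidArgumentError(
            f"segment of {values.size} samples shorter than input_window {width}"
        )
    idx = np.arange(0, n, stride)
    return values[idx[:, None] + np.arange(width)]


def _segment_map(hr_segments) -> dict:
    if isinstance(hr_segments, dict):
        return {int(k): v for k, v in hr_segments.items()}
    out = {}
    for seg in hr_segments:
        if seg.session_index is None:
            raise InvalidArgumentError("segment without session_index")
        out[int(seg.session_index)] = seg
    return out


def prepare_sequences(
    hr_segments,
    calibration: CalibrationSet,
    cfg: SequenceModelConfig | None = None,
) -> SequenceData:
    """Build training pairs and inference inputs from per-session HR segments.

    ``hr_segments`` is a dict ``session_index -> SensorStream`` (or a list of
    segments carrying session indices).  Training pairs are all stride-1
    windows of length ``cfg.input_window`` from calibration sessions, labeled
    with that session's measured eta; inference inputs are the same windowing
    of every non-calibration session.  Both are z-scored with training-set
    statistics only.
    """
    cfg = cfg or SequenceModelConfig()
    segmap = _segment_map(hr_segments)
    missing = [s for s in calibration.session_indices if s not in segmap]
    if missing:
        raise InvalidArgumentError(f"no HR segment for calibration sessions {missing}")

    xs, ys, sess = [], [], []
    for s in calibration.session_indices:
        try:
            w = _windows(segmap[s].values, cfg.input_window)
        except InvalidArgumentError as exc:
            raise InvalidArgumentError(f"session {s}: {exc}") from exc
        xs.append(w)
        ys.append(np.full(w.shape[0], calibration.eta_values[s]))
        sess.append(np.full(w.shape[0], s))
    x_train = np.concatenate(xs)
    y_train = np.concatenate(ys)

    x_norm = NormParams(float(x_train.mean()), float(x_train.std()) or 1.0)
    y_sd = float(y_train.std())
    y_norm = NormParams(float(y_train.mean()), y_sd if y_sd > 0 else 1.0)

    inference = {}
    for s, seg in segmap.items():
        if s in calibration.eta_values:
            continue
        try:
            w = _windows(seg.values, cfg.input_window)
        except InvalidArgumentError as exc:
            raise InvalidArgumentError(f"session {s}: {exc}") from exc
        inference[s] = x_norm.apply(w)

    return SequenceData(
        x_train=x_norm.apply(x_train),
        y_train=y_norm.apply(y_train),
        train_sessions=np.concatenate(sess),
        inference=inference,
        x_norm=x_norm,
        y_norm=y_norm,
        calibration=calibration,
        config=cfg,
    )


@dataclass
class EtaModel:
    """Trained estimator: the sequence model plus its normalizations."""

    net: LSTMRegressor
    x_norm: NormParams
    y_norm: NormParams
    config: SequenceModelConfig
    loss_history: list = field(default_factory=list)

    def predict_window_batch(self, windows_norm: np.ndarray) -> np.ndarray:
        """Window-level eta predictions, already inverse-normalized."""
        return self.y_norm.invert(self.net.predict(windows_norm))

    def predict_session(self, hr_values: np.ndarray) -> float:
        """Session-level eta from a raw (physical-units) HR segment."""
        w = _windows(np.asarray(hr_values, float), self.config.input_window)
        preds = self.predict_window_batch(self.x_norm.apply(w))
        return float(max(np.mean(preds), 1e-6))

    def save(self, path: str | Path) -> None:
        """Checkpoint: network weights (npz) + sidecar JSON header."""
        import dataclasses
        import json

        path = Path(path)
        self.net.save(path)
        header = {
            "x_norm": dataclasses.asdict(self.x_norm),
            "y_norm": dataclasses.asdict(self.y_norm),
            "config": dataclasses.asdict(self.config),
        }
        path.with_suffix(".json").write_text(json.dumps(header, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "EtaModel":
        import json

        path = Path(path)
        header = json.loads(path.with_suffix(".json").read_text())
        return cls(
            net=LSTMRegressor.load(path if path.suffix == ".npz"
                                   else path.with_suffix(".npz")),
            x_norm=NormParams(**header["x_norm"]),
            y_norm=NormParams(**header["y_norm"]),
            config=SequenceModelConfig(**header["config"]),
        )


def train_estimator(data: SequenceData, cfg: SequenceModelConfig | None = None) -> EtaModel:
    """Train the per-subject sequence model on the calibration windows."""
    cfg = cfg or data.config
    if data.x_train.shape[0] == 0:
        raise InvalidArgumentError("train_estimator: empty training set")
    net = LSTMRegressor(
        input_dim=1, hidden_units=cfg.hidden_units, n_layers=cfg.n_layers,
        output_mode="last", seed=cfg.seed,
    )
    net.fit(
        data.x_train, data.y_train,
        max_epochs=cfg.max_epochs, learning_rate=cfg.learning_rate,
        patience=cfg.patience, batch_size=cfg.batch_size,
    )
    return EtaModel(net, data.x_norm, data.y_norm, cfg, net.fit_log.loss)


def estimate_eta(
    model: EtaModel,
    data: SequenceData,
    calibration: CalibrationSet | None = None,
    n_sessions: int | None = None,
) -> list[EtaEstimate]:
    """Per-session estimates: calibration pass-through + model predictions.

    Calibration sessions echo their measured value exactly (source
    ``"calibration"``); every other session's estimate is the mean of the
    model's window-level predictions mapped back to physical units (source
    ``"model"``), clipped to be positive.
    """
    calibration = calibration or data.calibration
    estimates = {
        s: EtaEstimate(s, v, "calibration", calibration.band)
        for s, v in calibration.eta_values.items()
    }
    for s, w in data.inference.items():
        preds = model.predict_window_batch(w)
        estimates[s] = EtaEstimate(s, float(max(np.mean(preds), 1e-6)),
                                   "model", calibration.band)
    if n_sessions is not None:
        missing = [s for s in range(1, n_sessions + 1) if s not in estimates]
        if missing:
            raise CoverageError(f"no HR segment or calibration for sessions {missing}")
    return [estimates[s] for s in sorted(estimates)]


def estimates_to_csv(estimates: list[EtaEstimate], path: str | Path) -> None:
    pd.DataFrame([{
        "session_index": e.session_index, "eta_hat": e.eta_hat,
        "source": e.source, "band": e.band,
    } for e in estimates]).to_csv(path, index=False)
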