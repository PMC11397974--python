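"""Dual-step forecasting: ECG -> heart rate -> hysteresivity.

The forecasting path starts from the wearable's two ECG leads.  Beats are
detected on Lead II (falling back to Lead I), converted to a 1-Hz
instantaneous heart-rate series per extraction window, and cleaned with the
preprocessing pipeline.  A two-layer, 150-unit sequence model then predicts
the next measurement window's HR sequence from the previous one — the
prediction horizon being the inter-measurement interval (11 min for the
low-frequency FOT device, 12 min for RESMON).  The forecasted HR feeds the
calibration-trained estimator, yielding forecast hysteresivity values.

The module also houses the Lead I -> Lead II predictor: a two-layer,
100-unit sequence-to-sequence model trained with Adam for at most 200
epochs on a chronological 70:30 train/validation split, reported with the
normalised-RMSE fit percentage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .errors import InvalidArgumentError, QualityError
from .estimator import CalibrationSet, EtaEstimate, EtaModel
from .metrics import evaluate
from .nn import LSTMRegressor
from .preprocess import NormParams, PreprocessConfig, remove_outliers, smooth
from .protocol import ProtocolTimeline, eqv_extraction_windows, inter_measurement_interval
from .streams import SensorStream

__all__ = [
    "ForecastConfig",
    "LeadPredictConfig",
    "detect_beats",
    "derive_hr_input",
    "HrForecaster",
    "train_hr_forecaster",
    "forecast_eta",
    "predict_lead2_from_lead1",
]


@dataclass
class ForecastConfig:
    """HR-forecaster hyperparameters (two LSTM layers of 150 units)."""

    hidden_units: int = 150
    n_layers: int = 2
    horizon: float = 11.0  # minutes; 11 for FOT, 12 for RESMON
    history_length: int = 120  # samples of 1-Hz HR per window
    max_epochs: int = 200
    learning_rate: float = 1e-3
    split_ratio: float = 0.7
    patience: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_layers < 1:
            raise InvalidArgumentError("n_layers must be >= 1")
        if self.horizon <= 0:
            raise InvalidArgumentError("horizon must be > 0")


@dataclass
class LeadPredictConfig:
    """Lead I -> Lead II predictor hyperparameters (two layers, 100 units,
    Adam, max 200 epochs, chronological 70:30 split)."""

    hidden_units: int = 100
    n_layers: int = 2
    max_epochs: int = 200
    learning_rate: float = 5e-3
    split_ratio: float = 0.7
    chunk: int = 128  # samples per training subsequence
    batch_size: int | None = None  # full-batch by default
    patience: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.split_ratio < 1.0:
            raise InvalidArgumentError("split_ratio must lie in (0, 1)")


# ---------------------------------------------------------------------------
# ECG -> 1-Hz heart rate
# ---------------------------------------------------------------------------

def detect_beats(ecg: SensorStream, min_rr_s: float = 0.25) -> np.ndarray:
    """R-peak times (s) by thresholded peak picking on the QRS complexes."""
    if len(ecg) == 0:
        raise InvalidArgumentError("detect_beats: empty ECG stream")
    x = ecg.values
    height = 0.5 * float(np.percentile(x, 99.9))
    peaks, _ = find_peaks(x, height=height, distance=max(int(min_rr_s * ecg.fs), 1))
    return ecg.t[peaks]


def _window_hr_series(beats: np.ndarray, start_s: float, end_s: float,
                      max_gap_frac: float = 0.1) -> np.ndarray | None:
    """1-Hz instantaneous HR over [start_s, end_s) from beat times.

    Returns None if beats are missing over more than ``max_gap_frac`` of the
    window (quality gate, judged on inter-beat gaps > 2 s).
    """
    pad = 2.0  # use beats slightly outside the window to anchor the edges
    b = beats[(beats >= start_s - pad) & (beats < end_s + pad)]
    if b.size < 3:
        return None
    gaps = np.diff(b)
    uncovered = float(np.sum(np.clip(gaps - 2.0, 0.0, None)))
    if uncovered > max_gap_frac * (end_s - start_s):
        return None
    rr_t = 0.5 * (b[:-1] + b[1:])
    hr_inst = 60.0 / gaps
    grid = np.arange(start_s, end_s, 1.0)
    return np.interp(grid, rr_t, hr_inst)


def derive_hr_input(
    ecg_leads: tuple[SensorStream, SensorStream],
    timeline: ProtocolTimeline,
    preprocess_cfg: PreprocessConfig | None = None,
) -> dict:
    """Per-session 1-Hz HR series derived from the ECG leads.

    Beats are detected on Lead II, with Lead I as fallback for windows where
    Lead II quality is insufficient; windows failing on both leads raise
    :class:`QualityError`.  Each series is Hampel-filtered and smoothed.
    """
    lead1, lead2 = ecg_leads
    for lead in (lead1, lead2):
        if len(lead) == 0:
            raise InvalidArgumentError("derive_hr_input: empty ECG lead")
    cfg = preprocess_cfg or PreprocessConfig()
    windows = eqv_extraction_windows(timeline)
    covered = min(lead1.t[-1], lead2.t[-1]) + 1.0 / lead1.fs
    if covered < windows[-1].end * 60.0 - 1e-9:
        raise InvalidArgumentError("ECG leads do not cover the protocol timeline")

    beats2 = detect_beats(lead2)
    beats1 = detect_beats(lead1)
    out = {}
    for w in windows:
        s0, s1 = w.start * 60.0, w.end * 60.0
        hr = _window_hr_series(beats2, s0, s1)
        if hr is None:
            hr = _window_hr_series(beats1, s0, s1)
        if hr is None:
            raise QualityError(
                f"session {w.session_index}: undetectable beats over more than "
                f"10% of the extraction window on both leads"
            )
        stream = SensorStream("hr_ecg", np.arange(s0, s1, 1.0), hr, 1.0,
                              units="beats/min", session_index=w.session_index)
        stream = smooth(remove_outliers(stream, cfg), cfg.smooth_window)
        out[w.session_index] = stream
    return out


# ---------------------------------------------------------------------------
# HR forecasting
# ---------------------------------------------------------------------------

@dataclass
class HrForecaster:
    """Trained next-window HR model with its normalization."""

    net: LSTMRegressor
    norm: NormParams
    config: ForecastConfig
    loss_history: list = field(default_factory=list)

    def forecast_window(self, hr_window: np.ndarray) -> np.ndarray:
        """Forecast the next window's 1-Hz HR sequence from the current one."""
        z = self.norm.apply(np.asarray(hr_window, float))[None, :]
        return self.norm.invert(self.net.predict(z)[0])


def train_hr_forecaster(sessions: dict, cfg: ForecastConfig | None = None) -> HrForecaster:
    """Train the sequence model on consecutive-window pairs.

    ``sessions`` maps session index to a 1-Hz HR stream of
    ``cfg.history_length`` samples.  Training pairs (window_k -> window_k+1)
    are taken from the chronologically earlier ``split_ratio`` fraction of
    the record; at least 3 sessions of history are required.
    """
    cfg = cfg or ForecastConfig()
    order = sorted(sessions)
    if len(order) < 3:
        raise InvalidArgumentError("train_hr_forecaster: needs >= 3 sessions of history")
    series = []
    for s in order:
        v = np.asarray(sessions[s].values, float)
        if v.size != cfg.history_length:
            raise InvalidArgumentError(
                f"session {s}: expected {cfg.history_length}-sample window, got {v.size}"
            )
        series.append(v)
    pairs = list(zip(series[:-1], series[1:]))
    n_train = max(int(round(cfg.split_ratio * len(pairs))), 2)
    train_pairs = pairs[:n_train]

    x = np.stack([p[0] for p in train_pairs])
    y = np.stack([p[1] for p in train_pairs])
    norm = NormParams(float(x.mean()), float(x.std()) or 1.0)

    net = LSTMRegressor(
        input_dim=1, hidden_units=cfg.hidden_units, n_layers=cfg.n_layers,
        output_mode="sequence", seed=cfg.seed,
    )
    net.fit(norm.apply(x), norm.apply(y), max_epochs=cfg.max_epochs,
            learning_rate=cfg.learning_rate, patience=cfg.patience)
    return HrForecaster(net, norm, cfg, net.fit_log.loss)


def forecast_eta(
    hr_forecasts: dict,
    estimator_model: EtaModel,
    calibration: CalibrationSet,
) -> list[EtaEstimate]:
    """Map forecasted per-session HR windows to forecast hysteresivity.

    ``hr_forecasts`` maps session index to a forecasted 1-Hz HR array (in
    beats/min).  Each non-calibration window passes through the trained
    estimator exactly as measured HR would (the composition is the identity
    when the HR forecast is error-free); calibration sessions echo their
    measured value.
    """
    if estimator_model is None:
        raise InvalidArgumentError("forecast_eta: estimator model is required")
    estimates = {
        s: EtaEstimate(s, v, "calibration", calibration.band)
        for s, v in calibration.eta_values.items()
    }
    for s, hr in hr_forecasts.items():
        s = int(s)
        if s in estimates:
            continue
        values = hr.values if isinstance(hr, SensorStream) else np.asarray(hr, float)
        estimates[s] = EtaEstimate(s, estimator_model.predict_session(values),
                                   "forecast", calibration.band)
    return [estimates[s] for s in sorted(estimates)]


def forecast_horizon_minutes(timeline: ProtocolTimeline, device: str) -> float:
    """The forecast target starts one inter-measurement interval after the
    last observed window (11 min FOT / 12 min RESMON by default)."""
    return inter_measurement_interval(timeline, device)


# ---------------------------------------------------------------------------
# Lead I -> Lead II prediction
# ---------------------------------------------------------------------------

def _chunk(x: np.ndarray, width: int) -> np.ndarray:
    n = (x.size // width) * width
    if n == 0:
        raise InvalidArgumentError(f"series of {x.size} samples shorter than chunk {width}")
    return x[:n].reshape(-1, width)


def predict_lead2_from_lead1(
    lead1: SensorStream,
    lead2: SensorStream,
    cfg: LeadPredictConfig | None = None,
) -> tuple[SensorStream, dict]:
    """Train the sequence-to-sequence lead predictor and evaluate it.

    The record is split chronologically (first ``split_ratio`` fraction for
    training); both leads are z-scored with training statistics, cut into
    ``cfg.chunk``-sample subsequences for truncated backpropagation, and the
    validation portion is predicted and scored.  Returns the predicted Lead
    II over the validation span and a report with fit %, MSE, R² and the
    training trajectory.
    """
    cfg = cfg or LeadPredictConfig()
    if len(lead1) != len(lead2):
        raise InvalidArgumentError(
            f"lead length mismatch: {len(lead1)} vs {len(lead2)} samples"
        )
    if abs(lead1.fs - lead2.fs) > 1e-9:
        raise InvalidArgumentError("leads must share a sampling rate")
    if len(lead1) == 0:
        raise InvalidArgumentError("empty ECG leads")

    n_train = int(round(cfg.split_ratio * len(lead1)))
    x_tr, y_tr = lead1.values[:n_train], lead2.values[:n_train]
    x_val, y_val = lead1.values[n_train:], lead2.values[n_train:]
    if min(x_tr.size, x_val.size) < cfg.chunk:
        raise InvalidArgumentError("record too short for the configured chunk size")

    x_norm = NormParams(float(x_tr.mean()), float(x_tr.std()) or 1.0)
    y_norm = NormParams(float(y_tr.mean()), float(y_tr.std()) or 1.0)

    net = LSTMRegressor(
        input_dim=1, hidden_units=cfg.hidden_units, n_layers=cfg.n_layers,
        output_mode="sequence", seed=cfg.seed,
    )
    net.fit(
        _chunk(x_norm.apply(x_tr), cfg.chunk),
        _chunk(y_norm.apply(y_tr), cfg.chunk),
        max_epochs=cfg.max_epochs, learning_rate=cfg.learning_rate,
        patience=cfg.patience, batch_size=cfg.batch_size,
    )

    n_val = (x_val.size // cfg.chunk) * cfg.chunk
    pred_norm = net.predict(_chunk(x_norm.apply(x_val), cfg.chunk)).ravel()
    y_pred = y_norm.invert(pred_norm)
    y_true = y_val[:n_val]
    t_val = lead2.t[n_train:n_train + n_val]

    report = evaluate(y_true, y_pred).to_dict()
    report.update(n_train=int(n_train), n_val=int(n_val),
                  epochs_run=net.fit_log.epochs_run)
    predicted = SensorStream("ecg_lead2_pred", t_val, y_pred, lead2.fs, units="mV")
    return predicted, report
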