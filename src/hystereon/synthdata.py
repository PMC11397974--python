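"""Synthetic subject sessions with known ground truth.

Every downstream stage (impedance identification, calibration-based
estimation, dual-step forecasting) is exercised on sessions produced here,
so each generated quantity carries its generating parameters:

* a 1-Hz heart-rate profile = baseline + slow drift (Gaussian-smoothed noise
  with a ~5-min correlation time) + short-term variability, clipped to the
  physiological 40–180 beats/min range;
* two-lead ECG synthesized beat by beat from a three-kernel (P/QRS/T)
  Gaussian template, with Lead II a fixed amplitude-scaled, kernel-reweighted
  transform of Lead I plus independent noise;
* per-session constant-phase impedance parameters whose hysteresivity is
  linearly coupled to the session heart rate with Gaussian scatter — the
  mechanism that realizes the moderate (~0.4) HR–eta correlation the
  pipeline is designed around;
* multisine forced-oscillation pressure/flow records on the low
  (0.2–2 Hz, 120 s) and high (5–37 Hz, 60 s) excitation bands, with a
  0.25-Hz breathing flow component and white noise.

All randomness flows from the subject's seed (one sub-stream per output),
so regeneration is bit-identical.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .errors import InvalidArgumentError
from .impedance import BANDS, ConstantPhaseParams, alpha_from_eta, constant_phase_impedance
from .protocol import ProtocolTimeline, build_timeline, eqv_extraction_windows
from .streams import SensorStream

__all__ = [
    "SubjectProfile",
    "SyntheticSession",
    "FotRecord",
    "LEAD2_DEFAULT_TRANSFORM",
    "LEAD2_IDENTITY_TRANSFORM",
    "generate_hr_profile",
    "generate_ecg",
    "generate_session_params",
    "generate_fot_signals",
    "generate_session",
    "random_profiles",
]

# stream-specific sub-seed tags so channels are independent but reproducible
_TAGS = {"hr": 11, "ecg": 23, "params": 37, "fot": 53, "rr": 67, "st": 71}

#: Default Lead I -> Lead II morphing: overall amplitude scale plus per-wave
#: gains (Lead II projects the cardiac vector closer to its mean axis, so the
#: R and T waves gain relative to Lead I).
LEAD2_DEFAULT_TRANSFORM = {
    "scale": 1.1, "offset": 0.0, "gain_p": 0.9, "gain_qrs": 1.15, "gain_t": 1.25,
}
LEAD2_IDENTITY_TRANSFORM = {
    "scale": 1.0, "offset": 0.0, "gain_p": 1.0, "gain_qrs": 1.0, "gain_t": 1.0,
}

# (amplitude mV, center offset s, width s) of the P/QRS/T Gaussian kernels,
# offsets relative to the R peak and scaled by sqrt(RR)
_ECG_KERNELS = {
    "p": (0.15, -0.16, 0.025),
    "qrs": (1.0, 0.0, 0.012),
    "t": (0.35, 0.30, 0.06),
}


@dataclass
class SubjectProfile:
    """Generator ground truth for one synthetic subject.

    ``coupling_gamma`` is the relative change in hysteresivity per relative
    change in heart rate; ``noise_sd_eta`` the per-session scatter around the
    coupled value.  The defaults put the session-level HR–eta correlation
    near the 0.4 design target (see the closed form in
    :func:`generate_session_params`).
    """

    subject_id: str = "S1"
    age: float = 30.0  # years
    weight: float = 70.0  # kg
    height: float = 175.0  # cm
    bmi: float | None = None  # kg/m^2, derived if omitted
    hr_baseline: float = 70.0  # beats/min
    eta_baseline: float = 0.55  # dimensionless
    coupling_gamma: float = 0.5
    noise_sd_eta: float = 0.033
    seed: int = 0

    def __post_init__(self) -> None:
        derived = self.weight / (self.height / 100.0) ** 2
        if self.bmi is None:
            self.bmi = round(derived, 1)
        elif abs(self.bmi - derived) > 0.5:
            raise InvalidArgumentError(
                f"bmi {self.bmi} inconsistent with weight/height^2 = {derived:.1f}"
            )
        if not 40.0 <= self.hr_baseline <= 180.0:
            raise InvalidArgumentError("hr_baseline must lie in [40, 180] beats/min")
        if self.eta_baseline <= 0:
            raise InvalidArgumentError("eta_baseline must be > 0")
        if self.noise_sd_eta < 0:
            raise InvalidArgumentError("noise_sd_eta must be >= 0")

    def rng(self, tag: str) -> np.random.Generator:
        """Independent, reproducible random stream for one output channel."""
        return np.random.default_rng([self.seed, _TAGS[tag]])


@dataclass
class FotRecord:
    """One forced-oscillation pressure/flow record with its excitation grid."""

    t: np.ndarray  # s
    pressure: np.ndarray  # cmH2O
    flow: np.ndarray  # L/s
    grid: np.ndarray  # Hz
    band: str
    fs: float
    session_index: int = 1

    def to_csv(self, path: str | Path, true_params: ConstantPhaseParams | None = None,
               seed: int | None = None) -> None:
        pd.DataFrame({"t_s": self.t, "pressure": self.pressure,
                      "flow": self.flow}).to_csv(path, index=False)
        meta = {"grid_hz": list(map(float, self.grid)), "band": self.band,
                "fs": self.fs, "session_index": self.session_index}
        if seed is not None:
            meta["seed"] = seed
        if true_params is not None:
            meta["true_params"] = true_params.to_dict()
        Path(path).with_suffix(".json").write_text(json.dumps(meta, indent=2))


@dataclass
class SyntheticSession:
    """Complete generated record for one subject's two-hour protocol."""

    profile: SubjectProfile
    timeline: ProtocolTimeline
    streams: dict  # name -> SensorStream
    hr_per_session: np.ndarray  # windowed mean HR, one per session
    true_params: dict  # band -> list[ConstantPhaseParams], one per session
    fot_records: dict = field(default_factory=dict)  # band -> list[FotRecord]

    @property
    def true_eta(self) -> dict:
        return {band: np.array([p.eta for p in plist])
                for band, plist in self.true_params.items()}


# ---------------------------------------------------------------------------
# heart rate
# ---------------------------------------------------------------------------

def generate_hr_profile(
    duration: float,
    profile: SubjectProfile,
    fs: float = 1.0,
    drift_sd: float = 4.0,
    drift_tau: float = 300.0,
    short_sd: float = 2.0,
    short_tau: float = 10.0,
) -> SensorStream:
    """Heart-rate series: baseline + slow drift + short-term variability.

    The drift is white noise smoothed with a Gaussian kernel of width
    ``drift_tau`` seconds (>5-min timescale by default) and rescaled to SD
    ``drift_sd``; short-term variability is the same construction at
    ``short_tau``.  Values are clipped to the physiological [40, 180] range.
    """
    if duration <= 0:
        raise InvalidArgumentError("generate_hr_profile: duration must be > 0")
    rng = profile.rng("hr")
    n = int(round(duration * fs))
    t = np.arange(n) / fs

    def _component(sd: float, tau: float) -> np.ndarray:
        # draw even when sd == 0 so component toggling does not shift the
        # stream consumed by the other component
        w = rng.standard_normal(n)
        if sd == 0.0:
            return np.zeros(n)
        s = gaussian_filter1d(w, sigma=tau * fs, mode="reflect")
        realized = s.std()
        return s * (sd / realized) if realized > 0 else np.zeros(n)

    drift = _component(drift_sd, drift_tau)
    short = _component(short_sd, short_tau)
    hr = np.clip(profile.hr_baseline + drift + short, 40.0, 180.0)
    return SensorStream("hr", t, hr, fs, units="beats/min")


# ---------------------------------------------------------------------------
# two-lead ECG
# ---------------------------------------------------------------------------

def _beat_times(hr: SensorStream, t_end: float) -> np.ndarray:
    """Beat onsets from instantaneous HR: each RR interval is 60/HR at the
    current beat time (HR linearly interpolated)."""
    times = []
    t = 0.0
    while t < t_end:
        times.append(t)
        hr_now = float(np.interp(t, hr.t, hr.values))
        t += 60.0 / hr_now
    return np.array(times)


def _render_lead(t: np.ndarray, beats: np.ndarray, fs: float,
                 gains: dict) -> np.ndarray:
    """Sum of P/QRS/T Gaussian kernels over all beats (vectorized per beat)."""
    x = np.zeros_like(t)
    rr = np.diff(beats, append=beats[-1] + (beats[-1] - beats[-2] if beats.size > 1 else 1.0))
    for k, (beat, rr_k) in enumerate(zip(beats, rr)):
        s = math.sqrt(max(rr_k, 0.3))
        for wave, (amp, off, width) in _ECG_KERNELS.items():
            mu = beat + off * s
            lo = max(int((mu - 5 * width) * fs), 0)
            hi = min(int((mu + 5 * width) * fs) + 1, t.size)
            if lo >= hi:
                continue
            tt = t[lo:hi]
            x[lo:hi] += amp * gains[f"gain_{wave}"] * np.exp(
                -0.5 * ((tt - mu) / width) ** 2
            )
    return x


def generate_ecg(
    hr: SensorStream,
    lead_transform: dict | None = None,
    seed: int = 0,
    fs: float = 256.0,
    noise_sd: float = 0.02,
) -> tuple[SensorStream, SensorStream]:
    """Synthesize (Lead I, Lead II) driven by an instantaneous-HR stream.

    Lead I is the reference template; Lead II re-renders the same beat train
    with the transform's per-wave gains, then applies the affine
    ``scale * x + offset`` and adds independent noise.  With zero noise and
    the identity transform the two leads are identical.
    """
    if len(hr) == 0:
        raise InvalidArgumentError("generate_ecg: empty HR stream")
    if np.any(hr.values <= 0):
        raise InvalidArgumentError("generate_ecg: HR values must be positive")
    tr = dict(LEAD2_DEFAULT_TRANSFORM if lead_transform is None else lead_transform)

    t_end = hr.t[-1] + 1.0 / hr.fs
    n = int(round(t_end * fs))
    t = np.arange(n) / fs
    beats = _beat_times(hr, t_end)

    rng = np.random.default_rng([seed, _TAGS["ecg"]])
    identity_gains = {f"gain_{w}": 1.0 for w in _ECG_KERNELS}
    lead1 = _render_lead(t, beats, fs, identity_gains)
    lead2 = _render_lead(t, beats, fs, {k: tr[k] for k in identity_gains})
    lead2 = tr["scale"] * lead2 + tr["offset"]
    if noise_sd > 0:
        lead1 = lead1 + rng.normal(0.0, noise_sd, n)
        lead2 = lead2 + rng.normal(0.0, noise_sd, n)

    return (
        SensorStream("ecg_lead1", t, lead1, fs, units="mV"),
        SensorStream("ecg_lead2", t, lead2, fs, units="mV"),
    )


# ---------------------------------------------------------------------------
# per-session constant-phase parameters
# ---------------------------------------------------------------------------

def generate_session_params(
    profile: SubjectProfile,
    hr_per_session,
    n_sessions: int | None = None,
    base_r: float = 2.5,
    base_l: float = 0.01,
    base_d: float = 15.0,
    jitter_rel: float = 0.02,
) -> list[ConstantPhaseParams]:
    """Per-session model parameters with HR-coupled hysteresivity.

    The coupling is linear with Gaussian scatter:

        eta_k = eta0 * (1 + gamma * (HR_k - hr0) / hr0) + eps_k,
        eps_k ~ N(0, noise_sd_eta^2),

    and alpha is back-computed from eta_k (alpha = (2/pi) arctan(1/eta)), so
    the session's constant-phase spectrum carries exactly that
    hysteresivity.  The implied session-level correlation is

        corr(HR, eta) = b*sd_HR / sqrt(b^2 sd_HR^2 + noise_sd_eta^2),
        b = eta0 * gamma / hr0.

    R, L, D are drawn once per subject around typical adult values and given
    small per-session relative jitter.
    """
    hr_per_session = np.asarray(hr_per_session, dtype=float)
    if n_sessions is None:
        n_sessions = hr_per_session.size
    if n_sessions < 1:
        raise InvalidArgumentError("generate_session_params: n_sessions must be >= 1")
    if hr_per_session.size != n_sessions:
        raise InvalidArgumentError(
            f"hr_per_session has {hr_per_session.size} entries, expected {n_sessions}"
        )
    rng = profile.rng("params")
    r_subj = base_r * (1.0 + 0.1 * rng.standard_normal())
    l_subj = base_l * (1.0 + 0.1 * rng.standard_normal())
    d_subj = base_d * (1.0 + 0.1 * rng.standard_normal())

    hr0, eta0 = profile.hr_baseline, profile.eta_baseline
    eps = rng.normal(0.0, profile.noise_sd_eta, n_sessions) \
        if profile.noise_sd_eta > 0 else np.zeros(n_sessions)
    jit = 1.0 + jitter_rel * rng.standard_normal((3, n_sessions))

    out = []
    for k in range(n_sessions):
        eta_k = eta0 * (1.0 + profile.coupling_gamma * (hr_per_session[k] - hr0) / hr0)
        eta_k = max(eta_k + eps[k], 0.05)
        out.append(ConstantPhaseParams(
            R=max(r_subj * jit[0, k], 1e-3),
            L=max(l_subj * jit[1, k], 0.0),
            D=max(d_subj * jit[2, k], 1e-3),
            alpha=alpha_from_eta(eta_k),
        ))
    return out


# ---------------------------------------------------------------------------
# forced-oscillation pressure/flow records
# ---------------------------------------------------------------------------

#: Sampling rates for the synthesized FOT records, per band.
FOT_FS = {"low": 50.0, "high": 200.0}


def generate_fot_signals(
    params: ConstantPhaseParams,
    band: str,
    duration: float | None = None,
    noise_sd: float = 0.01,
    seed: int = 0,
    breathing_rel_amp: float = 0.2,
    breathing_freq: float = 0.25,
    pressure_rms: float = 1.0,
    session_index: int = 1,
) -> FotRecord:
    """Multisine pressure excitation and the model's steady-state flow.

    Pressure is a multisine over the band's excitation grid with seeded
    random phases and an integer number of periods in the record; flow is
    the exact frequency-wise response ``Q(f) = P(f)/Z(f)`` plus a breathing
    component at ``breathing_freq`` Hz (amplitude relative to excitation-flow
    RMS) plus white noise.  Noise of SD ``noise_sd`` (pressure units) is also
    added to the pressure channel, scaled by the flow/pressure RMS ratio on
    the flow channel.
    """
    if band not in BANDS:
        raise InvalidArgumentError(f"unknown band {band!r}; expected one of {list(BANDS)}")
    grid = np.asarray(BANDS[band]["grid"], dtype=float)
    fs = FOT_FS[band]
    if duration is None:
        duration = BANDS[band]["duration_s"]
    if duration <= 0:
        raise InvalidArgumentError("duration must be > 0")
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    if np.any(np.abs(grid * duration - np.rint(grid * duration)) > 1e-9):
        raise InvalidArgumentError(
            f"duration {duration} s is not an integer number of periods of the "
            f"'{band}' grid"
        )

    rng = np.random.default_rng([seed, _TAGS["fot"]])
    phases = rng.uniform(0.0, 2.0 * np.pi, grid.size)
    amp = pressure_rms * math.sqrt(2.0 / grid.size)  # equal-amplitude lines

    z = constant_phase_impedance(grid, params.R, params.L, params.D, params.alpha)
    pressure = np.zeros(n)
    flow = np.zeros(n)
    for f_k, ph_k, z_k in zip(grid, phases, z):
        arg = 2.0 * np.pi * f_k * t + ph_k
        pressure += amp * np.cos(arg)
        flow += (amp / np.abs(z_k)) * np.cos(arg - np.angle(z_k))

    if breathing_rel_amp > 0:
        flow_rms = float(np.sqrt(np.mean(flow**2)))
        flow = flow + breathing_rel_amp * flow_rms * np.sin(
            2.0 * np.pi * breathing_freq * t
        )
    if noise_sd > 0:
        flow_scale = float(np.sqrt(np.mean(flow**2))) / max(
            float(np.sqrt(np.mean(pressure**2))), 1e-12
        )
        pressure = pressure + rng.normal(0.0, noise_sd, n)
        flow = flow + rng.normal(0.0, noise_sd * flow_scale, n)

    return FotRecord(t, pressure, flow, grid, band, fs, session_index)


# ---------------------------------------------------------------------------
# whole-protocol session assembly
# ---------------------------------------------------------------------------

def generate_session(
    profile: SubjectProfile,
    timeline: ProtocolTimeline | None = None,
    fot_noise_sd: float = 0.01,
    ecg_noise_sd: float = 0.02,
    with_fot_records: bool = True,
    with_ecg: bool = True,
    bands=("low", "high"),
) -> SyntheticSession:
    """Generate the complete two-hour record for one subject.

    Streams span exactly the protocol duration; the per-session heart rate
    driving the hysteresivity coupling is the mean HR over each 2-min
    wearable extraction window (co-timed with the FOT measurement).
    """
    timeline = timeline or build_timeline()
    duration_s = timeline.total_duration * 60.0

    hr = generate_hr_profile(duration_s, profile)
    windows = eqv_extraction_windows(timeline)
    hr_per_session = np.array([
        float(np.mean(hr.slice_time(w.start * 60.0, w.end * 60.0).values))
        for w in windows
    ])

    streams = {"hr": hr}
    if with_ecg:
        lead1, lead2 = generate_ecg(hr, seed=profile.seed, noise_sd=ecg_noise_sd)
        streams["ecg_lead1"] = lead1
        streams["ecg_lead2"] = lead2

    # slow auxiliary channels (respiratory rate, skin temperature) at 0.2 Hz
    rr_rng, st_rng = profile.rng("rr"), profile.rng("st")
    n_slow = int(round(duration_s * 0.2))
    t_slow = np.arange(n_slow) / 0.2
    rr_vals = 15.0 + gaussian_filter1d(rr_rng.standard_normal(n_slow), 60 * 0.2,
                                       mode="reflect") * 4.0
    st_vals = 33.0 + gaussian_filter1d(st_rng.standard_normal(n_slow), 120 * 0.2,
                                       mode="reflect") * 1.5
    streams["rr"] = SensorStream("rr", t_slow, np.clip(rr_vals, 6, 40), 0.2,
                                 units="breaths/min")
    streams["st"] = SensorStream("st", t_slow, st_vals, 0.2, units="degC")

    true_params = {}
    fot_records = {}
    for band in bands:
        plist = generate_session_params(profile, hr_per_session, timeline.n_sessions)
        true_params[band] = plist
        if with_fot_records:
            fot_records[band] = [
                generate_fot_signals(
                    p, band, noise_sd=fot_noise_sd,
                    seed=profile.seed * 1000 + 10 * k + (0 if band == "low" else 1),
                    session_index=k + 1,
                )
                for k, p in enumerate(plist)
            ]
    return SyntheticSession(profile, timeline, streams, hr_per_session,
                            true_params, fot_records)


def random_profiles(n: int, seed: int = 0) -> list[SubjectProfile]:
    """Draw a cohort of subject profiles with realistic biometric spread.

    Biometrics span the measured-cohort ranges (age 28–40 y, weight 51–90 kg,
    height 160–180 cm); resting HR is uniform on [60, 85] beats/min and the
    hysteresivity baseline normal around 0.55 (SD 0.15, truncated to
    [0.25, 0.95]) — healthy-adult tissue values.
    """
    if n < 1:
        raise InvalidArgumentError("random_profiles: n must be >= 1")
    rng = np.random.default_rng(seed)
    profiles = []
    for i in range(n):
        height = rng.uniform(160.0, 180.0)
        weight = rng.uniform(51.0, 90.0)
        profiles.append(SubjectProfile(
            subject_id=f"SYN{i + 1:03d}",
            age=float(rng.integers(28, 41)),
            weight=round(weight, 1),
            height=round(height, 1),
            hr_baseline=float(np.round(rng.uniform(60.0, 85.0), 1)),
            eta_baseline=float(np.clip(rng.normal(0.55, 0.15), 0.25, 0.95)),
            seed=int(rng.integers(0, 2**31 - 1)),
        ))
    return profiles
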