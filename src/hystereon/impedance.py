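"""Respiratory impedance estimation and constant-phase model identification.

The forced-oscillation technique superimposes a small multisine pressure
excitation on tidal breathing and records the resulting airflow.  At each
excitation frequency f the respiratory impedance is the pressure/flow
frequency response, Z(f) = P(f)/Q(f), a complex quantity whose real part is
resistance and whose imaginary part is reactance (in cmH2O·s/L).

The tissue mechanics are summarized by the constant-phase model

    Z(jw) = R + jwL + (G - jH) * w^(-alpha),      w = 2*pi*f,

with airway resistance R, inertance L, tissue damping G and tissue elastance
H sharing a single fractional exponent alpha in (0, 1).  We parameterize the
tissue term by its magnitude D and phase: G = D*cos(alpha*pi/2),
H = D*sin(alpha*pi/2).  Hysteresivity — the marker this pipeline estimates
and forecasts — is

    eta = G / H = cot(alpha*pi/2),

a dimensionless index of tissue heterogeneity that increases with airway
remodeling.  Identification is multistart nonlinear least squares on the
stacked real/imaginary residuals over (R, L, D, alpha).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import DegenerateInputError, FitFailureError, InvalidArgumentError

__all__ = [
    "BANDS",
    "ImpedanceSpectrum",
    "ConstantPhaseParams",
    "constant_phase_impedance",
    "alpha_from_eta",
    "estimate_spectrum",
    "fit_constant_phase",
    "compute_eta",
]

#: Excitation bands: (f_min, f_max) in Hz and the default excitation grid.
BANDS = {
    "low": {"range": (0.2, 2.0), "grid": (0.2, 0.4, 0.6, 0.8, 1.0, 1.2, 1.6, 2.0),
            "duration_s": 120.0},
    "high": {"range": (5.0, 37.0), "grid": (5.0, 11.0, 17.0, 23.0, 29.0, 37.0),
             "duration_s": 60.0},
}


@dataclass
class ImpedanceSpectrum:
    """Complex impedance at discrete excitation frequencies, one session/band."""

    frequencies: np.ndarray  # Hz, strictly increasing
    z_values: np.ndarray  # complex, cmH2O·s/L
    band: str = "low"
    session_index: int = 1

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.z_values = np.asarray(self.z_values, dtype=complex)
        if self.frequencies.size != self.z_values.size:
            raise InvalidArgumentError("frequencies and z_values must have equal length")
        if self.frequencies.size < 4:
            raise InvalidArgumentError(
                "spectrum needs >= 4 frequencies (model has 4 free parameters)"
            )
        if np.any(np.diff(self.frequencies) <= 0):
            raise InvalidArgumentError("frequencies must be strictly increasing")
        if not (np.all(np.isfinite(self.frequencies))
                and np.all(np.isfinite(self.z_values.view(float)))):
            raise InvalidArgumentError("spectrum contains NaN/Inf entries")
        if self.band in BANDS:
            lo, hi = BANDS[self.band]["range"]
            if self.frequencies[0] < lo - 1e-9 or self.frequencies[-1] > hi + 1e-9:
                raise InvalidArgumentError(
                    f"frequencies outside the '{self.band}' band range {lo}-{hi} Hz"
                )

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({
            "freq_hz": self.frequencies,
            "z_real": self.z_values.real,
            "z_imag": self.z_values.imag,
        }).to_csv(path, index=False)
        meta = {"band": self.band, "session_index": self.session_index}
        Path(path).with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def from_csv(cls, path: str | Path, band: str | None = None,
                 session_index: int | None = None) -> "ImpedanceSpectrum":
        df = pd.read_csv(path)
        meta_path = Path(path).with_suffix(".json")
        meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
        return cls(
            df["freq_hz"].to_numpy(float),
            df["z_real"].to_numpy(float) + 1j * df["z_imag"].to_numpy(float),
            band=band or meta.get("band", "low"),
            session_index=session_index or meta.get("session_index", 1),
        )


@dataclass
class ConstantPhaseParams:
    """Identified constant-phase model parameters with derived tissue indices.

    ``G = D*cos(alpha*pi/2)`` and ``H = D*sin(alpha*pi/2)`` are derived, not
    free; hysteresivity ``eta = G/H = cot(alpha*pi/2)`` depends on alpha only.
    """

    R: float  # airway resistance, cmH2O·s/L
    L: float  # inertance, cmH2O·s²/L
    D: float  # tissue coefficient magnitude, cmH2O/L per w^alpha
    alpha: float  # fractional exponent, in (0, 1)
    fit_residual: float = 0.0  # sum of squared complex residuals
    converged: bool = field(default=True, compare=False)

    def __post_init__(self) -> None:
        if self.R < 0 or self.L < 0:
            raise InvalidArgumentError("R and L must be >= 0")
        if self.D <= 0:
            raise InvalidArgumentError("D must be > 0")
        if not 0.0 < self.alpha < 1.0:
            raise InvalidArgumentError("alpha must lie in (0, 1)")

    @property
    def G(self) -> float:
        """Tissue damping, cmH2O/L."""
        return self.D * math.cos(self.alpha * math.pi / 2.0)

    @property
    def H(self) -> float:
        """Tissue elastance, cmH2O/L."""
        return self.D * math.sin(self.alpha * math.pi / 2.0)

    @property
    def eta(self) -> float:
        """Hysteresivity G/H = cot(alpha*pi/2)."""
        return compute_eta(self)

    def impedance(self, f: np.ndarray) -> np.ndarray:
        return constant_phase_impedance(f, self.R, self.L, self.D, self.alpha)

    def to_dict(self) -> dict:
        return {
            "R": self.R, "L": self.L, "D": self.D, "alpha": self.alpha,
            "G": self.G, "H": self.H, "eta": self.eta,
            "fit_residual": self.fit_residual, "converged": self.converged,
        }


def constant_phase_impedance(f, R: float, L: float, D: float, alpha: float) -> np.ndarray:
    """Evaluate Z(jw) = R + jwL + D*exp(-j*alpha*pi/2)*w^(-alpha) at f (Hz).

    Accepts D = 0 (pure R-L limit) so generators can realize the resistive
    degenerate case.
    """
    f = np.asarray(f, dtype=float)
    if np.any(f <= 0):
        raise InvalidArgumentError("frequencies must be > 0")
    w = 2.0 * math.pi * f
    z = R + 1j * w * L
    if D != 0.0:
        g = D * math.cos(alpha * math.pi / 2.0)
        h = D * math.sin(alpha * math.pi / 2.0)
        z = z + (g - 1j * h) * w ** (-alpha)
    return z


def alpha_from_eta(eta: float) -> float:
    """Invert eta = cot(alpha*pi/2): alpha = (2/pi)*arctan(1/eta)."""
    if eta <= 0:
        raise InvalidArgumentError("eta must be > 0")
    return (2.0 / math.pi) * math.atan(1.0 / eta)


def compute_eta(params: ConstantPhaseParams) -> float:
    """Hysteresivity eta = G/H; requires tissue elastance H > 0."""
    h = params.D * math.sin(params.alpha * math.pi / 2.0)
    if h <= 0:
        raise InvalidArgumentError("compute_eta requires H > 0")
    return params.D * math.cos(params.alpha * math.pi / 2.0) / h


# ---------------------------------------------------------------------------
# spectrum estimation from pressure/flow records
# ---------------------------------------------------------------------------

def _grid_fundamental_period(grid: np.ndarray) -> Fraction:
    """Common period (s) of all grid frequencies, as an exact fraction."""
    fracs = [Fraction(f).limit_denominator(10**6) for f in grid]
    g = fracs[0]
    for fr in fracs[1:]:
        g = Fraction(math.gcd(g.numerator, fr.numerator),
                     (g.denominator * fr.denominator)
                     // math.gcd(g.denominator, fr.denominator))
        # gcd of fractions: gcd(num)/lcm(den)
    return 1 / g


def estimate_spectrum(
    pressure: np.ndarray,
    flow: np.ndarray,
    grid,
    fs: float,
    band: str = "low",
    session_index: int = 1,
    transient_fraction: float = 0.1,
) -> ImpedanceSpectrum:
    """Estimate Z(f) = P(f)/Q(f) at the excitation-grid bins.

    The leading ``transient_fraction`` of the record is discarded, the
    remainder is trimmed to an integer number of fundamental periods of the
    grid (so every grid frequency falls exactly on a DFT bin), the mean is
    removed, and Z is the ratio of the DFT coefficients at the grid bins.
    Off-grid bins are ignored.

    Both series are tapered with a periodic Hann window before the DFT.  A
    sinusoid exactly on a bin spreads only into the two adjacent bins under
    this window (grid lines are far further apart than that, and the window
    factor cancels in the P/Q ratio), while leakage from off-bin
    interference — chiefly the breathing component inside the low band — is
    suppressed by orders of magnitude relative to a rectangular window.
    """
    pressure = np.asarray(pressure, dtype=float)
    flow = np.asarray(flow, dtype=float)
    grid = np.asarray(grid, dtype=float)
    if pressure.size == 0 or flow.size == 0:
        raise InvalidArgumentError("estimate_spectrum: empty series")
    if pressure.size != flow.size:
        raise InvalidArgumentError("pressure and flow must have equal length")
    if grid.size < 4:
        raise InvalidArgumentError("excitation grid needs >= 4 frequencies")
    if fs <= 2.0 * grid.max():
        raise InvalidArgumentError(
            f"fs = {fs} Hz does not satisfy fs > 2*max(grid) = {2 * grid.max()} Hz"
        )

    n0 = int(math.floor(transient_fraction * pressure.size))
    p, q = pressure[n0:], flow[n0:]

    period = _grid_fundamental_period(grid)  # seconds, exact
    samples_per_period = period * Fraction(fs).limit_denominator(10**6)
    if samples_per_period.denominator != 1:
        raise InvalidArgumentError(
            f"grid fundamental period {float(period)} s is not an integer number "
            f"of samples at fs = {fs} Hz"
        )
    spp = int(samples_per_period)
    m = (p.size // spp) * spp
    if m < spp:
        raise InvalidArgumentError(
            f"record too short to resolve the grid: needs >= {spp} samples after "
            f"transient removal, has {p.size}"
        )
    p, q = p[:m], q[:m]
    p = p - p.mean()
    q = q - q.mean()

    # periodic Hann: exact-bin lines leak into +/-1 bin only
    window = 0.5 - 0.5 * np.cos(2.0 * np.pi * np.arange(m) / m)
    pf = np.fft.rfft(p * window)
    qf = np.fft.rfft(q * window)
    bins = grid * m / fs
    k = np.rint(bins).astype(int)
    if not np.allclose(bins, k, atol=1e-6):
        raise InvalidArgumentError("grid frequencies do not fall on DFT bins after trimming")

    # window-amplitude-normalized flow coefficient guards the division
    q_amp = 2.0 * np.abs(qf[k]) / window.sum()
    if np.any(q_amp < 1e-12):
        fbad = grid[q_amp < 1e-12]
        raise DegenerateInputError(
            f"flow Fourier coefficient vanishes at grid frequencies {fbad.tolist()} Hz"
        )
    z = pf[k] / qf[k]
    return ImpedanceSpectrum(grid, z, band=band, session_index=session_index)


# ---------------------------------------------------------------------------
# constant-phase identification
# ---------------------------------------------------------------------------

def _residuals(x: np.ndarray, w: np.ndarray, z_obs: np.ndarray) -> np.ndarray:
    r_, l_, d_, a_ = x
    z_mod = (r_ + 1j * w * l_
             + d_ * np.exp(-1j * a_ * math.pi / 2.0) * w ** (-a_))
    diff = z_mod - z_obs
    return np.concatenate([diff.real, diff.imag])


def _linear_prefit(w: np.ndarray, z_obs: np.ndarray) -> tuple[float, float]:
    """Rough (R, L) from the real-part level and high-frequency reactance slope."""
    r0 = max(float(np.median(z_obs.real)), 1e-6)
    hi = w >= np.median(w)
    x_hi, w_hi = z_obs.imag[hi], w[hi]
    slope = float(np.polyfit(w_hi, x_hi, 1)[0]) if w_hi.size >= 2 else 0.0
    return r0, max(slope, 0.0)


def fit_constant_phase(
    spectrum: ImpedanceSpectrum,
    n_d_starts: int = 8,
    alpha_starts=(0.3, 0.5, 0.7),
    max_nfev: int = 500,
) -> ConstantPhaseParams:
    """Identify (R, L, D, alpha) by multistart nonlinear least squares.

    Minimizes the sum of squared complex residuals
    ``sum_f |Z_obs(f) - Z_model(f)|^2`` with bounds R, L >= 0,
    D in [1e-6, 1e6], alpha in [0.01, 0.99].  Starts combine a linear
    pre-fit for (R, L) with ``n_d_starts`` log-spaced D values scaled to the
    observed tissue-term magnitude and alpha in ``alpha_starts``; the best
    converged start wins.
    """
    f = spectrum.frequencies
    w = 2.0 * math.pi * f
    z_obs = spectrum.z_values

    r0, l0 = _linear_prefit(w, z_obs)
    # scale D starts to the magnitude the tissue term needs at the lowest
    # frequency (where w^-alpha dominates)
    d_scale = max(abs(z_obs[0]) * w[0] ** 0.5, 1e-3)
    d_starts = d_scale * np.logspace(-2, 2, n_d_starts)

    lb = [0.0, 0.0, 1e-6, 0.01]
    ub = [np.inf, np.inf, 1e6, 0.99]

    best = None
    diagnostics = []
    for a0 in alpha_starts:
        for d0 in d_starts:
            x0 = np.clip([r0, l0, d0, a0],
                         [1e-9, 0.0, 1e-6, 0.01], [1e9, 1e9, 1e6, 0.99])
            try:
                sol = least_squares(
                    _residuals, x0, args=(w, z_obs), bounds=(lb, ub),
                    method="trf", ftol=1e-12, xtol=1e-12, gtol=1e-12,
                    max_nfev=max_nfev,
                )
            except Exception as exc:  # pragma: no cover - scipy internal failure
                diagnostics.append({"x0": list(x0), "error": str(exc)})
                continue
            diagnostics.append({"x0": list(x0), "cost": float(sol.cost),
                                "status": int(sol.status)})
            if sol.status <= 0:
                continue
            if best is None or sol.cost < best.cost:
                best = sol
    if best is None:
        raise FitFailureError("constant-phase fit: no start converged", diagnostics)

    r_, l_, d_, a_ = best.x
    return ConstantPhaseParams(
        R=float(r_), L=float(l_), D=float(d_), alpha=float(a_),
        fit_residual=float(2.0 * best.cost),  # cost = 0.5 * sum(residual^2)
        converged=True,
    )
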