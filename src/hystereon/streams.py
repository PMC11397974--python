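"""Timestamped single-channel physiological streams and their CSV dialect.

A :class:`SensorStream` is one channel (an ECG lead, heart rate, respiratory
rate, skin temperature) sampled at a fixed rate, with timestamps in seconds
from the protocol origin (start of the first forced-oscillation measurement).
Streams are written as two-column CSV (``t_s``, ``value``), UTF-8, header
row, '.' decimal separator — one file per channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError

__all__ = ["SensorStream"]


@dataclass
class SensorStream:
    """One fixed-rate physiological channel.

    Parameters
    ----------
    name:
        Channel name, e.g. ``"hr"``, ``"ecg_lead1"``.
    t:
        Sample timestamps in seconds from the protocol origin, equispaced.
    values:
        Sample values; same length as ``t``.
    fs:
        Sampling rate in Hz.
    units:
        Physical units of ``values`` (informational).
    """

    name: str
    t: np.ndarray
    values: np.ndarray
    fs: float
    units: str = ""
    session_index: int | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.t.shape != self.values.shape:
            raise InvalidArgumentError(
                f"stream '{self.name}': t and values have different lengths "
                f"({self.t.size} vs {self.values.size})"
            )
        if self.fs <= 0:
            raise InvalidArgumentError(f"stream '{self.name}': fs must be > 0")

    def __len__(self) -> int:
        return self.t.size

    @property
    def duration(self) -> float:
        """Nominal covered duration in seconds (n samples / fs)."""
        return len(self) / self.fs

    def slice_time(self, start_s: float, end_s: float) -> "SensorStream":
        """Samples with ``start_s <= t < end_s`` (half-open window)."""
        mask = (self.t >= start_s) & (self.t < end_s)
        return SensorStream(self.name, self.t[mask], self.values[mask], self.fs,
                            self.units, self.session_index)

    def with_values(self, values: np.ndarray) -> "SensorStream":
        """Copy of the stream with the same timestamps and new values."""
        return SensorStream(self.name, self.t.copy(), np.asarray(values, float),
                            self.fs, self.units, self.session_index)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t_s": self.t, "value": self.values})

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, name: str | None = None,
                 units: str = "") -> "SensorStream":
        df = pd.read_csv(path)
        if not {"t_s", "value"}.issubset(df.columns):
            raise InvalidArgumentError(
                f"{path}: stream CSV must have columns 't_s' and 'value'"
            )
        t = df["t_s"].to_numpy(float)
        if t.size < 2:
            fs = 1.0
        else:
            dt = np.diff(t)
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
                raise InvalidArgumentError(f"{path}: timestamps are not equispaced")
            fs = 1.0 / dt[0]
        return cls(name or Path(path).stem, t, df["value"].to_numpy(float), fs, units)
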