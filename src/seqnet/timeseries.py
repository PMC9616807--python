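"""Multivariate time-series container and spike-train smoothing.

The :class:`TimeSeries` is the common currency of the package: an
``(n_units, n_steps)`` array of signal values on a fixed sampling grid,
used both for simulated membrane potentials / firing rates and for
kernel-smoothed spike trains from recordings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import signal


@dataclass
class TimeSeries:
    """Units x time matrix with a fixed sampling step.

    Parameters
    ----------
    values : ndarray, shape (n_units, n_steps)
        Signal values, arbitrary amplitude units.
    dt : float
        Sampling step in milliseconds.
    unit_ids : sequence of str, optional
        Ordered unit labels; defaults to ``"u0" .. "u{N-1}"``.
    """

    values: np.ndarray
    dt: float
    unit_ids: list[str] = field(default=None)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D (n_units, n_steps) array")
        n, t = self.values.shape
        if n < 1 or t < 2:
            raise ValueError(f"need at least 1 unit and 2 timepoints, got {n}x{t}")
        if not np.isfinite(self.values).all():
            raise ValueError("values contain NaN or infinite entries")
        if not (np.isscalar(self.dt) or np.ndim(self.dt) == 0) or self.dt <= 0:
            raise ValueError(f"dt must be a positive scalar, got {self.dt!r}")
        self.dt = float(self.dt)
        if self.unit_ids is None:
            self.unit_ids = [f"u{i}" for i in range(n)]
        else:
            self.unit_ids = [str(u) for u in self.unit_ids]
            if len(self.unit_ids) != n:
                raise ValueError("unit_ids length does not match number of units")

    @property
    def n_units(self) -> int:
        return self.values.shape[0]

    @property
    def n_steps(self) -> int:
        return self.values.shape[1]

    @property
    def duration(self) -> float:
        """Total duration in ms."""
        return self.n_steps * self.dt

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_steps) * self.dt

    # ------------------------------------------------------------------ I/O
    def to_csv(self, path) -> None:
        """Write as delimited text: rows = time, columns = units.

        The first line is a comment header carrying the sampling step; the
        second line holds the unit ids.
        """
        path = Path(path)
        with open(path, "w") as fh:
            fh.write(f"# seqnet-timeseries dt_ms={self.dt!r}\n")
            pd.DataFrame(self.values.T, columns=self.unit_ids).to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path) -> "TimeSeries":
        path = Path(path)
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("# seqnet-timeseries"):
                raise ValueError(f"{path} is not a seqnet time-series file")
            dt = float(header.split("dt_ms=")[1].strip())
            df = pd.read_csv(fh)
        return cls(values=df.to_numpy().T, dt=dt, unit_ids=list(df.columns))

    def to_npz(self, path) -> None:
        """Binary container with the same schema as the text format."""
        np.savez(path, values=self.values, dt=self.dt,
                 unit_ids=np.array(self.unit_ids))

    @classmethod
    def from_npz(cls, path) -> "TimeSeries":
        with np.load(path, allow_pickle=False) as z:
            return cls(values=z["values"], dt=float(z["dt"]),
                       unit_ids=[str(u) for u in z["unit_ids"]])


def load_events(path) -> list[tuple[float, str]]:
    """Read spike events from two-column delimited text (time_ms, unit_id)."""
    df = pd.read_csv(path, comment="#", header=None, names=["time_ms", "unit_id"],
                     skipinitialspace=True)
    return [(float(t), str(u)) for t, u in zip(df["time_ms"], df["unit_id"])]


def spikes_to_rate(
    events: Iterable[tuple[float, object]],
    dt: float,
    kernel_width: float = 10.0,
    unit_ids: Sequence[object] = None,
    t_stop: float = None,
) -> TimeSeries:
    """Smooth spike events into firing-rate traces.

    Spikes are binned at ``dt`` and filtered with a causal exponential kernel
    of time constant ``kernel_width`` (ms), normalised to unit area, so a
    homogeneous train of rate ``r`` per ms averages to ``r``.

    Parameters
    ----------
    events : iterable of (time_ms, unit_id)
        Spike times must be non-negative.
    dt : float
        Output sampling step (ms); recordings in this package use 2 ms bins.
    kernel_width : float
        Exponential time constant (ms); default 10 ms.
    unit_ids : sequence, optional
        The declared unit set. Required to fix the output dimension when a
        unit fires no spikes; events with unknown ids are rejected.
    t_stop : float, optional
        Output duration (ms); defaults to the last spike time plus one bin.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if kernel_width <= 0:
        raise ValueError("kernel_width must be positive")
    events = [(float(t), str(u)) for t, u in events]
    if any(t < 0 for t, _ in events):
        raise ValueError("event times must be non-negative")
    if unit_ids is None:
        unit_ids = sorted({u for _, u in events})
        if not unit_ids:
            raise ValueError("no events and no declared unit set: output shape unknown")
    unit_ids = [str(u) for u in unit_ids]
    index = {u: i for i, u in enumerate(unit_ids)}
    unknown = {u for _, u in events if u not in index}
    if unknown:
        raise ValueError(f"events reference units outside the declared set: {sorted(unknown)}")
    if not events:
        warnings.warn("empty event list: returning an all-zero series")
    if t_stop is None:
        t_stop = (max((t for t, _ in events), default=0.0)) + dt
    n_steps = max(int(np.ceil(t_stop / dt)), 2)

    counts = np.zeros((len(unit_ids), n_steps))
    for t, u in events:
        b = min(int(t // dt), n_steps - 1)
        counts[index[u], b] += 1.0

    # Causal exponential filter y[t] = decay*y[t-1] + x[t]; discrete kernel
    # area is dt/(1-decay), divided out so the kernel integrates to 1.
    decay = np.exp(-dt / kernel_width)
    rates = signal.lfilter([1.0], [1.0, -decay], counts, axis=1)
    rates *= (1.0 - decay) / dt
    return TimeSeries(values=rates, dt=dt, unit_ids=unit_ids)
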