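"""Synthetic photosynthetic photon flux density (PPFD) forcing.

Generates an idealized high-latitude growing-season PPFD series — each day
a truncated half-sine of configurable daylight length centred on solar
noon — and reads/writes user-supplied forcing as CSV.  This is a synthetic
stand-in with plausible subarctic June–July defaults (61 days, 20 h
daylight, 800 umol m^-2 s^-1 peak); absolute seasonal GPP totals driven by
it are internally consistent but not tied to any particular station record.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import pandas as pd

__all__ = ["PPFDSeries", "synthesize_ppfd", "read_ppfd_csv", "write_ppfd_csv"]

SECONDS_PER_DAY = 86_400


@dataclass(frozen=True)
class PPFDSeries:
    """Regularly spaced PPFD time series (umol photons m^-2 s^-1)."""

    timestamps: pd.DatetimeIndex
    ppfd: np.ndarray
    timestep_s: float

    def __post_init__(self) -> None:
        ppfd = np.asarray(self.ppfd, dtype=float)
        ts = pd.DatetimeIndex(self.timestamps)
        if ppfd.size == 0:
            raise ValueError("PPFD series is empty")
        if ppfd.size != ts.size:
            raise ValueError("timestamps and ppfd lengths differ")
        if np.any(~np.isfinite(ppfd)) or np.any(ppfd < 0):
            bad = int(np.flatnonzero(~np.isfinite(ppfd) | (ppfd < 0))[0])
            raise ValueError(f"ppfd must be finite and >= 0 (first bad row: {bad})")
        if ts.size > 1:
            deltas = np.diff(ts.asi8) / 1e9
            if np.any(deltas <= 0) or not np.allclose(deltas, deltas[0]):
                raise ValueError("timestamps must be strictly increasing with constant spacing")
            if not np.isclose(deltas[0], self.timestep_s):
                raise ValueError("timestep_s does not match timestamp spacing")
        object.__setattr__(self, "ppfd", ppfd)
        object.__setattr__(self, "timestamps", ts)

    def __len__(self) -> int:
        return self.ppfd.size

    @property
    def n_days(self) -> float:
        return len(self) * self.timestep_s / SECONDS_PER_DAY


def synthesize_ppfd(
    n_days: int = 61,
    timestep_s: int = 1800,
    peak: float = 800.0,
    daylight_hours: float = 20.0,
    noise_sd: float = 0.0,
    seed: Optional[int] = None,
    start: Union[str, pd.Timestamp] = "2007-06-01",
) -> PPFDSeries:
    """Synthesize a half-sine diel PPFD cycle repeated over ``n_days``.

    Each day PPFD follows ``peak * sin(pi * (t - t0) / D)`` inside a
    daylight window of ``D = daylight_hours`` centred at solar noon, and is
    zero outside it.  Optional Gaussian noise (sd ``noise_sd``) is added and
    the result clipped at zero; generation is deterministic for a given
    seed.
    """
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    if not 0 < daylight_hours <= 24:
        raise ValueError("daylight_hours must lie in (0, 24]")
    if not peak > 0:
        raise ValueError("peak must be > 0")
    if timestep_s <= 0 or SECONDS_PER_DAY % timestep_s:
        raise ValueError("timestep_s must be a positive divisor of 86400")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")

    steps_per_day = SECONDS_PER_DAY // timestep_s
    n = n_days * steps_per_day
    seconds = (np.arange(n) % steps_per_day) * timestep_s
    daylight_s = daylight_hours * 3600.0
    t0 = 12 * 3600.0 - daylight_s / 2.0
    phase = (seconds - t0) / daylight_s
    ppfd = np.where(
        (phase >= 0) & (phase <= 1), peak * np.sin(np.pi * np.clip(phase, 0, 1)), 0.0
    )
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        ppfd = ppfd + rng.normal(0.0, noise_sd, n)
    ppfd = np.clip(ppfd, 0.0, None)
    timestamps = pd.date_range(start=start, periods=n, freq=f"{timestep_s}s")
    return PPFDSeries(timestamps=timestamps, ppfd=ppfd, timestep_s=float(timestep_s))


def write_ppfd_csv(series: PPFDSeries, path) -> None:
    """Write a series as CSV with ISO-8601 ``timestamp`` and ``ppfd`` columns."""
    pd.DataFrame(
        {"timestamp": series.timestamps.strftime("%Y-%m-%dT%H:%M:%S"), "ppfd": series.ppfd}
    ).to_csv(path, index=False)


def read_ppfd_csv(path) -> PPFDSeries:
    """Read and validate a PPFD forcing CSV.

    Expects ``timestamp`` (ISO-8601) and ``ppfd`` columns with constant
    spacing; rejects negative values, irregular spacing and empty files
    with specific errors.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"forcing file {path} is empty") from exc
    missing = {"timestamp", "ppfd"} - set(df.columns)
    if missing:
        raise ValueError(f"forcing file {path} is missing columns: {sorted(missing)}")
    if len(df) == 0:
        raise ValueError(f"forcing file {path} contains no rows")
    ppfd = df["ppfd"].to_numpy(dtype=float)
    negative = np.flatnonzero(ppfd < 0)
    if negative.size:
        raise ValueError(f"negative ppfd at data row {int(negative[0])} of {path}")
    ts = pd.DatetimeIndex(pd.to_datetime(df["timestamp"]))
    if len(ts) > 1:
        deltas = np.diff(ts.asi8) / 1e9
        if np.any(deltas <= 0) or not np.allclose(deltas, deltas[0]):
            raise ValueError(f"irregular timestamp spacing in {path}")
        step = float(deltas[0])
    else:
        step = 1800.0
    return PPFDSeries(timestamps=ts, ppfd=ppfd, timestep_s=step)
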