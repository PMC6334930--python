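"""Synthetic behavioural data with known ground truth.

Two generators emulate the data shapes this toolkit analyses:

* **Activity counts** as logged by a beam-crossing monitor: one count per
  60 s reading, Poisson with a rate modulated sinusoidally at a circadian
  (or experimentally lengthened) period, optionally gated by a square-wave
  light-dark cycle, and optionally truncated to zero after a death time —
  exactly the signature dead-animal curation must detect.
* **Position in the tube** at 0.1 Hz in [0, 1]: a slow circadian drift of
  the mean position plus a fast pacing oscillation whose period may itself
  be scheduled over the day (frequency modulation), plus Gaussian noise.

Both are pure functions of their spec (including its seed), and
:func:`write_dam2_fixture` serialises activity series into genuine DAM2
monitor files plus a metadata CSV, so the whole import path can be tested
round-trip without any recorded data.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from datetime import datetime, timedelta
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .time_utils import days, hours

__all__ = [
    "ActivitySimSpec",
    "PositionSimSpec",
    "simulate_activity",
    "simulate_position",
    "write_dam2_fixture",
]


@dataclass(frozen=True)
class ActivitySimSpec:
    """Ground truth for a simulated activity series.

    rate_per_min:
        Baseline beam-crossing rate (counts per minute); ~2/min is a
        typical healthy-fly daytime level.
    amplitude:
        Relative sinusoidal modulation depth in [0, 1]; 0 gives an
        arrhythmic (homogeneous Poisson) series.
    period:
        Period of the sinusoidal rate modulation, seconds.
    ld_period / l_factor / d_factor:
        Optional square-wave light-dark modulation: the rate is multiplied
        by ``l_factor`` during the first half of each ``ld_period`` and
        ``d_factor`` during the second. ``ld_period=None`` disables it
        (constant-light conditions).
    duration / interval:
        Recording length and reading interval, seconds.
    death_time:
        If set, the rate is hard-truncated to zero from this time on.
    """

    rate_per_min: float = 2.0
    amplitude: float = 0.5
    period: float = hours(24)
    ld_period: float | None = None
    l_factor: float = 1.0
    d_factor: float = 1.0
    duration: float = days(10)
    interval: float = 60.0
    death_time: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rate_per_min < 0:
            raise ValueError("rate_per_min must be non-negative")
        if not 0 <= self.amplitude <= 1:
            raise ValueError("amplitude must be in [0, 1]")
        if self.duration <= 0 or self.interval <= 0:
            raise ValueError("duration and interval must be positive")


def simulate_activity(spec: ActivitySimSpec) -> pd.DataFrame:
    """Draw one activity series: columns t (seconds) and activity (counts).

    Counts at reading time t are Poisson with mean
    ``rate_per_min * interval/60 * (1 + amplitude*sin(2*pi*t/period)) * LD(t)``,
    zero from ``death_time`` on. Deterministic given the spec's seed.
    """
    rng = np.random.default_rng(spec.seed)
    t = np.arange(spec.interval, spec.duration + spec.interval / 2, spec.interval)
    rate = spec.rate_per_min * spec.interval / 60.0
    mean = rate * (1 + spec.amplitude * np.sin(2 * np.pi * t / spec.period))
    if spec.ld_period is not None:
        in_l = np.mod(t, spec.ld_period) < spec.ld_period / 2
        mean = mean * np.where(in_l, spec.l_factor, spec.d_factor)
    mean = np.clip(mean, 0, None)
    counts = rng.poisson(mean)
    if spec.death_time is not None:
        counts = np.where(t >= spec.death_time, 0, counts)
    return pd.DataFrame({"t": t, "activity": counts.astype(int)})


@dataclass(frozen=True)
class PositionSimSpec:
    """Ground truth for a simulated tube-position series (0 = food end).

    The position is ``clip(mean(t) + amplitude*sin(2*pi*phi(t)) + noise)``
    where the fast-oscillation phase integrates an instantaneous period
    schedule ``d phi/dt = 1/p(t)``: a constant p gives steady pacing, a
    schedule drifting over the day gives the frequency-modulated pattern.
    """

    duration: float = days(5)
    interval: float = 10.0  # 0.1 Hz sampling
    fast_period: float | Callable[[np.ndarray], np.ndarray] = 120.0
    fast_amplitude: float = 0.2
    mean_level: float = 0.5
    mean_drift_amplitude: float = 0.2
    mean_drift_period: float = hours(24)
    noise_sd: float = 0.05
    seed: int = 0


def simulate_position(spec: PositionSimSpec) -> pd.DataFrame:
    """Draw one position series: columns t and position, clipped to [0, 1]."""
    rng = np.random.default_rng(spec.seed)
    t = np.arange(0.0, spec.duration, spec.interval)
    if callable(spec.fast_period):
        p = np.asarray(spec.fast_period(t), dtype=float)
    else:
        p = np.full(t.size, float(spec.fast_period))
    if (p <= 0).any():
        raise ValueError("fast-oscillation period schedule must be positive")
    phase = np.cumsum(spec.interval / p)
    mean = spec.mean_level + spec.mean_drift_amplitude * np.sin(
        2 * np.pi * t / spec.mean_drift_period
    )
    position = mean + spec.fast_amplitude * np.sin(2 * np.pi * phase)
    if spec.noise_sd > 0:
        position = position + rng.normal(0, spec.noise_sd, t.size)
    return pd.DataFrame({"t": t, "position": np.clip(position, 0.0, 1.0)})


def write_dam2_fixture(
    channel_series: Mapping[int, Sequence[int]],
    monitor_name: str,
    start_datetime: datetime | str,
    out_dir: str,
    interval: float = 60.0,
    extra_meta: Mapping[int, Mapping] | None = None,
    metadata_name: str = "metadata.csv",
) -> tuple[str, str]:
    """Write simulated counts as a DAM2 monitor file plus a metadata CSV.

    *channel_series* maps 1-based channel numbers (at most 32) to count
    sequences of equal length; unmentioned channels are written as zeros.
    Readings start one interval after *start_datetime* (the monitor reports
    counts accumulated since the previous reading). The metadata CSV gets
    one row per provided channel with the mandatory linking columns, plus
    any per-channel *extra_meta* user columns. Returns
    ``(monitor_path, metadata_path)``.
    """
    if not channel_series:
        raise ValueError("no channels given")
    channels = sorted(channel_series)
    if channels[0] < 1 or channels[-1] > 32:
        raise ValueError("channel numbers must be within 1..32")
    lengths = {len(v) for v in channel_series.values()}
    if len(lengths) != 1:
        raise ValueError("all channel series must have the same length")
    n = lengths.pop()
    if isinstance(start_datetime, str):
        start_datetime = datetime.fromisoformat(start_datetime)

    counts = np.zeros((n, 32), dtype=int)
    for ch, series in channel_series.items():
        arr = np.asarray(series, dtype=int)
        if (arr < 0).any():
            raise ValueError(f"negative counts on channel {ch}")
        counts[:, ch - 1] = arr

    os.makedirs(out_dir, exist_ok=True)
    monitor_path = os.path.join(out_dir, monitor_name)
    with open(monitor_path, "w") as fh:
        for i in range(n):
            ts = start_datetime + timedelta(seconds=(i + 1) * interval)
            date = f"{ts.day} {ts.strftime('%b %y')}"
            fields = [str(i + 1), date, ts.strftime("%H:%M:%S"), "1",
                      "0", "0", "0", "0", "0", "0"]
            fields += [str(c) for c in counts[i]]
            fh.write("\t".join(fields) + "\n")

    stop = start_datetime + timedelta(seconds=n * interval)
    rows = []
    for ch in channels:
        row = {
            "file": monitor_name,
            "start_datetime": start_datetime.strftime("%Y-%m-%d %H:%M:%S"),
            "stop_datetime": stop.strftime("%Y-%m-%d %H:%M:%S"),
            "region_id": ch,
        }
        if extra_meta and ch in extra_meta:
            row.update(extra_meta[ch])
        rows.append(row)
    metadata_path = os.path.join(out_dir, metadata_name)
    pd.DataFrame(rows).to_csv(metadata_path, index=False)
    return monitor_path, metadata_path
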