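"""Curation of behavioural series: movement scoring, death detection, survival filters.

An animal that dies (or escapes) mid-experiment keeps producing reads — all
zeros — which downstream statistics would happily interpret as profound
inactivity. Curation truncates each individual's series at the first
sustained spell of immobility: scanning windows of ``time_window`` seconds,
an animal is called dead from the first window in which it moved less than
``prop_immobile`` (default 1%) of the time, and every read from that window
start onward is discarded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import LinkedBehaviourTable
from .time_utils import days

__all__ = [
    "CurationParams",
    "derive_moving",
    "curate_dead_animals",
    "filter_min_lifespan",
    "curation_report",
]


@dataclass(frozen=True)
class CurationParams:
    """Dead-animal detection settings.

    target_variable:
        Boolean variable scanned for immobility (usually ``moving``).
    prop_immobile:
        An individual is dead in a window if its mean of the target there is
        strictly below this fraction (default 0.01: immobile >99% of the time).
    time_window:
        Window length in seconds over which immobility must be sustained.
    resolution:
        Number of window start positions per ``time_window``; the scan stride
        is ``time_window / resolution``.
    """

    target_variable: str = "moving"
    prop_immobile: float = 0.01
    time_window: float = days(2)
    resolution: int = 24

    def __post_init__(self) -> None:
        if not 0 < self.prop_immobile < 1:
            raise ValueError("prop_immobile must be in (0, 1)")
        if self.time_window <= 0:
            raise ValueError("time_window must be positive")
        if self.resolution < 1:
            raise ValueError("resolution must be >= 1")

    @property
    def stride(self) -> float:
        return self.time_window / self.resolution


def derive_moving(
    table: LinkedBehaviourTable,
    activity_var: str = "activity",
    threshold: float = 0,
    out_var: str = "moving",
) -> LinkedBehaviourTable:
    """Add a boolean movement variable: ``moving = activity > threshold``."""
    if activity_var not in table.data.columns:
        raise KeyError(f"no variable {activity_var!r} in data")
    out = table.copy()
    out.data[out_var] = out.data[activity_var].to_numpy() > threshold
    return out


def _first_dead_window(t: np.ndarray, target: np.ndarray, params: CurationParams) -> float | None:
    """Earliest window start from which the animal is scored dead, or None.

    Windows are ``[w, w + time_window)`` with w on a grid of stride
    ``time_window/resolution`` anchored at the first read; the mean of the
    target is taken over the reads actually present in the window (no
    imputation). Individuals spanning less than one time_window are never
    scored.
    """
    if t.size == 0 or t[-1] - t[0] < params.time_window:
        return None
    starts = np.arange(t[0], t[-1] + params.stride / 2, params.stride)
    # prefix sums for O(1) windowed means
    csum = np.concatenate([[0.0], np.cumsum(target.astype(float))])
    lo = np.searchsorted(t, starts, side="left")
    hi = np.searchsorted(t, starts + params.time_window, side="left")
    n = hi - lo
    with np.errstate(invalid="ignore"):
        frac = (csum[hi] - csum[lo]) / n
    dead = (n > 0) & (frac < params.prop_immobile)
    if not dead.any():
        return None
    return float(starts[int(np.argmax(dead))])


def curate_dead_animals(
    table: LinkedBehaviourTable,
    target_variable: str = "moving",
    prop_immobile: float = 0.01,
    time_window: float = days(2),
    resolution: int = 24,
) -> LinkedBehaviourTable:
    """Discard every read after the first sustained-immobility window, per animal.

    Animals scored dead in their very first window keep zero rows and
    disappear from the data view of the metadata. The operation is
    idempotent and only ever removes a suffix (in t) of each series.
    """
    params = CurationParams(target_variable, prop_immobile, time_window, resolution)
    if target_variable not in table.data.columns:
        raise KeyError(f"no variable {target_variable!r} in data")
    keep = np.ones(len(table.data), dtype=bool)
    for _, idx in table.data.groupby(table.key, sort=False).indices.items():
        sub = table.data.iloc[idx]
        order = np.argsort(sub["t"].to_numpy(), kind="stable")
        t = sub["t"].to_numpy()[order]
        target = sub[target_variable].to_numpy()[order]
        w_star = _first_dead_window(t, target, params)
        if w_star is not None:
            keep[idx] = sub["t"].to_numpy() < w_star
    return table.filter_data(keep)


def curation_report(
    table: LinkedBehaviourTable,
    target_variable: str = "moving",
    prop_immobile: float = 0.01,
    time_window: float = days(2),
    resolution: int = 24,
) -> pd.DataFrame:
    """Per-animal curation outcome: truncation time and reads kept/removed."""
    params = CurationParams(target_variable, prop_immobile, time_window, resolution)
    rows = []
    for animal_id, sub in table.per_id():
        t = np.sort(sub["t"].to_numpy())
        target = sub[target_variable].to_numpy()[np.argsort(sub["t"].to_numpy(), kind="stable")]
        w_star = _first_dead_window(t, target, params)
        n_kept = int((t < w_star).sum()) if w_star is not None else t.size
        rows.append(
            {
                "id": animal_id,
                "truncation_time": np.nan if w_star is None else w_star,
                "n_kept": n_kept,
                "n_removed": t.size - n_kept,
            }
        )
    return pd.DataFrame(rows)


def filter_min_lifespan(table: LinkedBehaviourTable, min_t: float) -> LinkedBehaviourTable:
    """Keep individuals observed strictly beyond *min_t* seconds (max(t) > min_t)."""
    last_t = table.data.groupby(table.key, sort=False)["t"].max()
    valid = set(last_t.index[last_t > min_t])
    return table.filter_data(table.data[table.key].isin(valid).to_numpy())
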