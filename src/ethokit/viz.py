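"""Plots for behavioural time series — and the summaries behind them.

Every plotting function returns ``(figure, table)``: the rendered
matplotlib figure and the numeric summary it draws, so analyses can assert
on (and export) the numbers rather than the pixels. The layouts follow the
conventions of circadian behaviour work: per-individual quality-control
tile plots, double-plotted actograms, periodograms with their significance
line, and population time courses with bootstrap confidence ribbons, all
annotated with light-dark (or subjective-day) bars.
"""

from __future__ import annotations

from dataclasses import dataclass

import matplotlib

matplotlib.use("Agg")  # headless rendering; callers only ever save figures

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .core import LinkedBehaviourTable, bin_time
from .time_utils import days, hours, mins

__all__ = [
    "LdSpec",
    "tile_summary",
    "actogram_layout",
    "ld_annotations",
    "bootstrap_mean_ci",
    "population_timecourse",
    "plot_tiles",
    "plot_actogram",
    "plot_periodogram",
    "plot_population_timecourse",
]


@dataclass(frozen=True)
class LdSpec:
    """A light regime for axis annotations.

    ``period`` and ``l_duration`` define the light-dark square wave
    (lights on during the first ``l_duration`` seconds of each period from
    ``phase``). ``regime`` is ``"LD"`` (dark drawn black) or ``"LL"``
    (constant light: the subjective night is drawn grey instead).
    """

    period: float = days(1)
    phase: float = 0.0
    l_duration: float = hours(12)
    regime: str = "LD"

    def __post_init__(self) -> None:
        if not 0 < self.l_duration <= self.period:
            raise ValueError("need 0 < l_duration <= period")
        if self.regime not in ("LD", "LL"):
            raise ValueError("regime must be 'LD' or 'LL'")


# ---------------------------------------------------------------------------
# numeric summarisers
# ---------------------------------------------------------------------------


def tile_summary(
    table: LinkedBehaviourTable, var: str = "moving", bin_width: float = mins(30)
) -> pd.DataFrame:
    """Fraction of time each individual spends with *var* true, per time bin.

    Rows are (id, t, value) with t the left bin edge; rendering maps each
    individual to one raster line whose colour intensity is the value.
    """
    chunks = []
    for animal_id, sub in table.per_id():
        binned = bin_time(sub["t"], sub[var].astype(float), bin_width, "mean")
        binned.insert(0, "id", animal_id)
        chunks.append(binned)
    if not chunks:
        return pd.DataFrame(columns=["id", "t", "value"])
    return pd.concat(chunks, ignore_index=True)


def actogram_layout(
    t: np.ndarray,
    values: np.ndarray,
    period: float = days(1),
    multiplot: int = 2,
) -> pd.DataFrame:
    """Lay a series out as (double-)plotted actogram rows.

    Row ``r`` (one per period, counted from the earliest period present)
    displays the reads with ``t`` in ``[r*period, (r+multiplot)*period)``
    at within-row abscissa ``x = t - r*period``; with ``multiplot=2`` each
    read is therefore drawn on its own day's row and repeated on the
    previous row, which makes drifting rhythms readable. Returns rows
    (row, x, t, value).
    """
    if multiplot < 1:
        raise ValueError("multiplot must be >= 1")
    t = np.asarray(t, dtype=float)
    values = np.asarray(values, dtype=float)
    if t.size == 0:
        return pd.DataFrame(columns=["row", "x", "t", "value"])
    day_index = np.floor(t / period).astype(int)
    first = day_index.min()
    last = day_index.max()
    chunks = []
    for offset in range(multiplot):
        row = day_index - offset
        keep = row >= first
        chunks.append(
            pd.DataFrame(
                {
                    "row": row[keep] - first,
                    "x": t[keep] - (row[keep]) * period,
                    "t": t[keep],
                    "value": values[keep],
                }
            )
        )
    out = pd.concat(chunks, ignore_index=True)
    return out.sort_values(["row", "x"], ignore_index=True)


def ld_annotations(spec: LdSpec, t_range: tuple[float, float]) -> pd.DataFrame:
    """Alternating light/dark boxes tiling a time range.

    Returns rows (start, end, phase, colour): phase ``L`` boxes are white;
    ``D`` boxes are black under an LD regime and grey ("subjective night")
    under constant light.
    """
    lo, hi = t_range
    if not lo < hi:
        raise ValueError("empty t_range")
    dark_colour = "black" if spec.regime == "LD" else "grey"
    first_cycle = int(np.floor((lo - spec.phase) / spec.period))
    rows = []
    k = first_cycle
    while spec.phase + k * spec.period < hi:
        cycle_start = spec.phase + k * spec.period
        for phase_name, start, end, colour in (
            ("L", cycle_start, cycle_start + spec.l_duration, "white"),
            ("D", cycle_start + spec.l_duration, cycle_start + spec.period, dark_colour),
        ):
            if end > lo and start < hi and end > start:
                rows.append(
                    {"start": max(start, lo), "end": min(end, hi),
                     "phase": phase_name, "colour": colour}
                )
        k += 1
    return pd.DataFrame(rows)


def bootstrap_mean_ci(
    values: np.ndarray,
    n_boot: int = 1000,
    conf: float = 0.95,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float, float]:
    """Nonparametric bootstrap percentile CI of the mean: (mean, lo, hi).

    Deterministic given the seed (or an externally managed Generator).
    """
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise ValueError("no finite values to bootstrap")
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    idx = rng.integers(0, values.size, size=(n_boot, values.size))
    means = values[idx].mean(axis=1)
    tail = (1 - conf) / 2
    lo, hi = np.quantile(means, [tail, 1 - tail])
    return float(values.mean()), float(lo), float(hi)


def population_timecourse(
    table: LinkedBehaviourTable,
    var: str,
    bin_width: float = mins(30),
    by: str | None = None,
    n_boot: int = 1000,
    conf: float = 0.95,
    seed: int = 0,
) -> pd.DataFrame:
    """Group-mean time course with bootstrap CI, resampling individuals.

    Each individual is first averaged within time bins; the group mean and
    its percentile bootstrap CI are then computed across those per-id bin
    means, so the resampling unit is the individual (a per-read bootstrap
    would understate the uncertainty). Returns rows
    (group, t, mean, lo, hi, n).
    """
    per_id = tile_summary(table, var, bin_width)
    if per_id.empty:
        return pd.DataFrame(columns=["group", "t", "mean", "lo", "hi", "n"])
    if by is None:
        per_id["group"] = "all"
    else:
        group_of = table.meta[by]
        per_id["group"] = per_id["id"].map(group_of)
    rng = np.random.default_rng(seed)
    rows = []
    for (group, t), sub in per_id.groupby(["group", "t"], sort=True):
        mean, lo, hi = bootstrap_mean_ci(sub["value"].to_numpy(), n_boot, conf, rng)
        rows.append({"group": group, "t": t, "mean": mean, "lo": lo, "hi": hi,
                     "n": len(sub)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# rendered figures (each returns figure + the table it draws)
# ---------------------------------------------------------------------------


def _annotate_ld(ax, spec: LdSpec | None, t_range, scale=1.0) -> None:
    if spec is None:
        return
    boxes = ld_annotations(spec, t_range)
    for box in boxes.itertuples(index=False):
        ax.axvspan(
            box.start * scale, box.end * scale, ymax=0.03,
            color=box.colour, ec="black", lw=0.4, zorder=5,
        )


def plot_tiles(
    table: LinkedBehaviourTable,
    var: str = "moving",
    bin_width: float = mins(30),
    label: str | None = None,
    ld: LdSpec | None = None,
):
    """QC raster: one line per individual, colour = fraction of time var is true."""
    summary = tile_summary(table, var, bin_width)
    ids = summary["id"].unique().tolist()
    labels = (
        [str(table.meta.loc[i, label]) for i in ids] if label is not None else ids
    )
    fig, ax = plt.subplots(figsize=(9, max(2, 0.16 * len(ids) + 1)))
    if len(ids):
        t_edges = np.sort(summary["t"].unique())
        grid = (
            summary.pivot_table(index="id", columns="t", values="value")
            .reindex(index=ids, columns=t_edges)
            .to_numpy()
        )
        extent = (
            t_edges[0] / days(1),
            (t_edges[-1] + bin_width) / days(1),
            len(ids) - 0.5,
            -0.5,
        )
        ax.imshow(grid, aspect="auto", cmap="Blues", vmin=0, vmax=1, extent=extent)
        ax.set_yticks(range(len(ids)), labels=labels, fontsize=6)
        _annotate_ld(ax, ld, (t_edges[0], t_edges[-1] + bin_width), scale=1 / days(1))
    ax.set_xlabel("time (days)")
    ax.set_ylabel("individual")
    fig.tight_layout()
    return fig, summary


def plot_actogram(
    t: np.ndarray,
    values: np.ndarray,
    period: float = days(1),
    multiplot: int = 2,
    title: str | None = None,
):
    """Double-plotted actogram of one individual's series."""
    layout = actogram_layout(t, values, period, multiplot)
    n_rows = int(layout["row"].max()) + 1 if len(layout) else 1
    fig, axes = plt.subplots(
        n_rows, 1, sharex=True, figsize=(8, 0.5 * n_rows + 1), squeeze=False
    )
    vmax = float(np.nanmax(values)) if len(layout) else 1.0
    for r in range(n_rows):
        ax = axes[r, 0]
        sub = layout[layout["row"] == r]
        ax.fill_between(
            sub["x"] / hours(1), 0, sub["value"], step="mid", color="0.2", lw=0
        )
        ax.set_ylim(0, max(vmax, 1e-9))
        ax.set_yticks([])
        ax.set_ylabel(r, rotation=0, ha="right", va="center", fontsize=7)
        ax.set_xlim(0, multiplot * period / hours(1))
    axes[-1, 0].set_xlabel("time in row (h)")
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    return fig, layout


def plot_periodogram(pg: pd.DataFrame, relative: bool = False, title: str | None = None):
    """Periodogram trace with its significance line and labelled rank-1 peak."""
    pg = pg.sort_values("period")
    fig, ax = plt.subplots(figsize=(6, 4))
    y = pg["power"] - pg["signif_threshold"] if relative else pg["power"]
    ax.plot(pg["period"] / hours(1), y, color="0.2", lw=1)
    if not relative:
        ax.plot(
            pg["period"] / hours(1), pg["signif_threshold"], color="red", lw=1,
            label="significance threshold",
        )
        ax.legend(frameon=False, fontsize=8)
    if "peak" in pg.columns:
        top = pg[pg["peak"] == 1]
        for row in top.itertuples(index=False):
            ypk = row.power - row.signif_threshold if relative else row.power
            ax.plot(row.period / hours(1), ypk, "+", color="tab:blue", ms=12, mew=2)
            ax.annotate(
                f"{row.period / hours(1):.1f} h",
                (row.period / hours(1), ypk),
                textcoords="offset points", xytext=(4, 4), fontsize=8,
            )
    ax.set_xlabel("period (h)")
    ax.set_ylabel("relative power" if relative else "power")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    return fig, pg


def plot_population_timecourse(
    table: LinkedBehaviourTable,
    var: str,
    bin_width: float = mins(30),
    by: str | None = None,
    n_boot: int = 1000,
    conf: float = 0.95,
    seed: int = 0,
    ld: LdSpec | None = None,
):
    """Mean time course per group with a bootstrap confidence ribbon."""
    tc = population_timecourse(table, var, bin_width, by, n_boot, conf, seed)
    fig, ax = plt.subplots(figsize=(8, 4))
    for group, sub in tc.groupby("group", sort=True):
        ax.plot(sub["t"] / days(1), sub["mean"], label=str(group), lw=1.2)
        ax.fill_between(sub["t"] / days(1), sub["lo"], sub["hi"], alpha=0.3)
    if len(tc):
        _annotate_ld(ax, ld, (tc["t"].min(), tc["t"].max() + bin_width), scale=1 / days(1))
    ax.set_xlabel("time (days)")
    ax.set_ylabel(var)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    return fig, tc
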