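"""Multi-scale analysis: Morlet continuous wavelet transform spectrograms.

Behavioural variables are often modulated at several nested timescales at
once — e.g. an animal pacing its tube with a ~1 min stride rhythm whose
period is itself modulated over the 24 h day. A periodogram collapses time
and cannot show such frequency modulation; the continuous wavelet
transform (CWT) keeps a time axis, giving power as a function of both time
and period.

The transform used here is the standard zero-padded FFT implementation of
the Morlet wavelet with centre frequency ``omega0`` (default 6): scales
are log-spaced with ``dj`` sub-octaves, and relate to Fourier periods by
the factor ``lambda = 4*pi / (omega0 + sqrt(2 + omega0^2))`` (~1.033 for
omega0 = 6, so scale and period are nearly interchangeable). A
cone-of-influence mask flags cells within one wavelet e-folding time of
either edge; those cells are excluded from all folded averages.

For circadian work the time axis is folded over one day
(:func:`fold_daily`), averaged within the light and dark phases
(:func:`marginal_power`), and averaged across individuals
(:func:`population_mean_spectrogram`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import LinkedBehaviourTable
from .periodogram import resample_table
from .time_utils import days, hours

__all__ = [
    "Spectrogram",
    "FoldedSpectrogram",
    "morlet_fourier_factor",
    "cwt_power",
    "spectrogram_table",
    "fold_daily",
    "marginal_power",
    "population_mean_spectrogram",
    "ridge_periods",
]


def morlet_fourier_factor(omega0: float = 6.0) -> float:
    """Ratio of Fourier period to Morlet scale: ``4*pi/(omega0 + sqrt(2+omega0^2))``."""
    return 4 * np.pi / (omega0 + np.sqrt(2 + omega0**2))


@dataclass
class Spectrogram:
    """Time-by-period wavelet power for one individual.

    ``power[i, j]`` is the squared modulus of the transform at time
    ``times[i]`` and Fourier period ``periods[j]``; ``in_coi[i, j]`` is True
    where the cell lies inside the cone of influence (edge-contaminated).
    """

    id: str
    times: np.ndarray
    periods: np.ndarray
    power: np.ndarray
    in_coi: np.ndarray

    def masked_power(self) -> np.ndarray:
        """Power with edge-contaminated cells set to NaN."""
        out = self.power.copy()
        out[self.in_coi] = np.nan
        return out


@dataclass
class FoldedSpectrogram:
    """Wavelet power averaged over the circadian day into fixed phase bins."""

    id: str
    phase: np.ndarray  # left edges of phase bins, seconds in [0, day)
    periods: np.ndarray
    power: np.ndarray  # phase x period; NaN where no uncontaminated data


def _interpolate_gaps(values: np.ndarray, max_gap: int = 10) -> tuple[np.ndarray, np.ndarray]:
    """Linearly fill NaN runs; return (filled, mask of fills longer than max_gap)."""
    x = values.astype(float).copy()
    bad = ~np.isfinite(x)
    if bad.all():
        raise ValueError("series is entirely missing")
    idx = np.arange(x.size)
    x[bad] = np.interp(idx[bad], idx[~bad], x[~bad])
    long_gap = np.zeros(x.size, dtype=bool)
    if bad.any():
        # flag runs of consecutive missing samples longer than max_gap
        run_start = None
        for i in range(x.size + 1):
            if i < x.size and bad[i]:
                run_start = i if run_start is None else run_start
            elif run_start is not None:
                if i - run_start > max_gap:
                    long_gap[run_start:i] = True
                run_start = None
    return x, long_gap


def cwt_power(
    values: np.ndarray,
    delta: float,
    period_range: tuple[float, float],
    dj: float = 1 / 20,
    omega0: float = 6.0,
    t0: float = 0.0,
    series_id: str = "series",
    max_gap: int = 10,
) -> Spectrogram:
    """Morlet wavelet power of a regular series over log-spaced periods.

    Periods run from ``period_range[0]`` upward in steps of ``2**dj``
    (i.e. ``dj`` sub-octaves per octave) up to ``period_range[1]``. The
    series is mean-subtracted, NaN gaps are linearly interpolated (spans
    longer than *max_gap* samples are added to the cone-of-influence mask),
    and the transform is computed on a zero-padded FFT. Power at scale ``s``
    is ``|W(t, s)|^2`` with the ``sqrt(2*pi*s/dt)`` frequency-domain
    normalisation, so a unit-amplitude sinusoid rings at the same height at
    every period.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    p_min, p_max = period_range
    if not 0 < p_min < p_max:
        raise ValueError("invalid period_range")
    if p_min < 2 * delta:
        raise ValueError("minimum period must be at least 2 sampling intervals")
    if p_max > n * delta / 2:
        raise ValueError("maximum period exceeds half the series duration")
    if n * delta < 2 * p_min:
        raise ValueError("series shorter than two cycles of the minimum period")

    x, long_gap = _interpolate_gaps(values, max_gap)
    x = x - x.mean()

    lam = morlet_fourier_factor(omega0)
    s0 = p_min / lam
    n_scales = int(np.floor(np.log2(p_max / p_min) / dj)) + 1
    scales = s0 * 2 ** (dj * np.arange(n_scales))
    periods = scales * lam

    n_pad = int(2 ** np.ceil(np.log2(n)))
    xhat = np.fft.fft(x, n_pad)
    omega = 2 * np.pi * np.fft.fftfreq(n_pad, d=delta)
    pos = omega > 0

    power = np.empty((n, n_scales))
    norm = np.pi ** (-0.25)
    for j, s in enumerate(scales):
        psi_hat = np.zeros(n_pad)
        psi_hat[pos] = norm * np.sqrt(2 * np.pi * s / delta) * np.exp(
            -0.5 * (s * omega[pos] - omega0) ** 2
        )
        w = np.fft.ifft(xhat * psi_hat)[:n]
        power[:, j] = np.abs(w) ** 2

    # cone of influence: within one e-folding time sqrt(2)*s of either edge
    t_rel = delta * np.arange(n)
    dist_edge = np.minimum(t_rel, t_rel[-1] - t_rel)
    in_coi = dist_edge[:, None] < np.sqrt(2) * scales[None, :]
    in_coi |= long_gap[:, None]

    return Spectrogram(
        id=series_id,
        times=t0 + t_rel,
        periods=periods,
        power=power,
        in_coi=in_coi,
    )


def spectrogram_table(
    table: LinkedBehaviourTable,
    var: str = "position",
    delta: float = 10.0,
    period_range: tuple[float, float] = (30.0, hours(32)),
    dj: float = 1 / 20,
    omega0: float = 6.0,
) -> list[Spectrogram]:
    """Resample one variable per individual and compute its wavelet spectrogram."""
    return [
        cwt_power(
            series.values, delta, period_range, dj=dj, omega0=omega0,
            t0=series.t0, series_id=series.id,
        )
        for series in resample_table(table, var, delta)
    ]


def fold_daily(
    spec: Spectrogram, day: float = days(1), n_phase_bins: int = 144
) -> FoldedSpectrogram:
    """Average a spectrogram over the circadian day into fixed phase bins.

    Each time sample lands in phase bin ``floor((t mod day) / (day / bins))``;
    power is averaged over all samples of a bin across every recorded day,
    skipping cells inside the cone of influence. Bins with no clean data are
    NaN.
    """
    if spec.times[-1] - spec.times[0] < day:
        raise ValueError("record shorter than one day: nothing to fold")
    width = day / n_phase_bins
    bins = (np.mod(spec.times, day) / width).astype(int) % n_phase_bins
    power = np.where(spec.in_coi, np.nan, spec.power)
    out = np.full((n_phase_bins, spec.periods.size), np.nan)
    for b in range(n_phase_bins):
        rows = power[bins == b]
        if rows.size:
            with np.errstate(invalid="ignore"):
                out[b] = np.nanmean(rows, axis=0)
    return FoldedSpectrogram(
        id=spec.id,
        phase=width * np.arange(n_phase_bins),
        periods=spec.periods.copy(),
        power=out,
    )


def marginal_power(
    folded: FoldedSpectrogram,
    phases: dict[str, tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Mean folded power per period within named phase windows.

    By default the light phase is ``[0, 12 h)`` and the dark phase
    ``[12 h, 24 h)``. Returns a long frame (phase, period, power).
    """
    if phases is None:
        phases = {"L": (0.0, hours(12)), "D": (hours(12), hours(24))}
    rows = []
    for name, (lo, hi) in phases.items():
        sel = (folded.phase >= lo) & (folded.phase < hi)
        if not sel.any():
            raise ValueError(f"phase window {name!r} contains no phase bins")
        with np.errstate(invalid="ignore"):
            mean = np.nanmean(folded.power[sel], axis=0)
        rows.append(pd.DataFrame({"phase": name, "period": folded.periods, "power": mean}))
    return pd.concat(rows, ignore_index=True)


def population_mean_spectrogram(
    folded: list[FoldedSpectrogram], group_id: str = "population"
) -> FoldedSpectrogram:
    """Element-wise mean of folded spectrograms sharing one (phase, period) grid."""
    if not folded:
        raise ValueError("no spectrograms to average")
    ref = folded[0]
    for f in folded[1:]:
        if f.power.shape != ref.power.shape or not (
            np.allclose(f.periods, ref.periods) and np.allclose(f.phase, ref.phase)
        ):
            raise ValueError("folded spectrograms are on different grids")
    stack = np.stack([f.power for f in folded])
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(stack, axis=0)
    return FoldedSpectrogram(
        id=group_id, phase=ref.phase.copy(), periods=ref.periods.copy(), power=mean
    )


def ridge_periods(power: np.ndarray, periods: np.ndarray) -> np.ndarray:
    """Per-row period of maximum power (NaN rows yield NaN)."""
    out = np.full(power.shape[0], np.nan)
    for i, row in enumerate(power):
        if np.isfinite(row).any():
            out[i] = periods[np.nanargmax(row)]
    return out
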