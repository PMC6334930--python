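"""Circadian rhythmicity statistics: periodograms, peaks, population summaries.

Four period-estimation methods are provided, all returning a common table
of (period, power, significance threshold):

* **chi-square** (Sokolove & Bushell): for each candidate period of ``r``
  sampling bins, the series is folded into ``r`` phase classes; the
  statistic ``Q_P = (N/r) * sum_h (M_h - Mbar)^2 / s^2`` compares the
  between-phase variance with the total variance and is chi-square
  distributed with ``r - 1`` degrees of freedom under the null of no
  periodicity. The workhorse of fly circadian analysis.
* **Lomb-Scargle**: classical normalised periodogram for (possibly
  irregular) samples, with the M-independent-frequencies significance
  level ``z* = -ln(1 - (1 - alpha)^(1/M))``.
* **autocorrelation**: sample ACF at each lag, with the usual
  ``z_{1-alpha/2}/sqrt(N)`` white-noise band.
* **Fourier**: discrete Fourier power normalised by ``N * s^2`` (unit mean
  under white noise), with the same M-frequency exponential-null threshold
  as Lomb-Scargle.

Rhythmicity is then decided per individual by automatic peak detection: a
peak is a local maximum above its significance threshold that also
dominates a +/-5% period neighbourhood; peaks are ranked by power minus
threshold ("relative power"). An individual with any rank-1 peak is called
rhythmic; group-level prevalence can be compared with a grouped binomial
GLM (:func:`two_group_logit_fit`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as _signal
from scipy import stats as _stats

from .core import LinkedBehaviourTable
from .time_utils import hours, mins

__all__ = [
    "RegularSeries",
    "LogitFit",
    "resample_series",
    "resample_table",
    "chi_sq_periodogram",
    "ls_periodogram",
    "ac_periodogram",
    "fourier_periodogram",
    "periodogram",
    "find_peaks",
    "summarize_rhythmicity",
    "group_summary",
    "two_group_logit_fit",
    "fit_rhythmicity_glm",
]

DEFAULT_PERIOD_RANGE = (hours(16), hours(32))


@dataclass
class RegularSeries:
    """A regularly sampled series for one individual; missing bins are NaN."""

    id: str
    t0: float
    delta: float
    values: np.ndarray

    @property
    def t(self) -> np.ndarray:
        return self.t0 + self.delta * np.arange(self.values.size)


def resample_series(
    t: np.ndarray, values: np.ndarray, delta: float, t0: float | None = None
) -> tuple[float, np.ndarray]:
    """Average a (t, value) series onto a regular grid of spacing *delta*.

    Grid point ``k`` holds the mean of the values with
    ``t in [t0 + k*delta, t0 + (k+1)*delta)``; empty bins are NaN.
    Returns ``(t0, grid_values)``.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    t = np.asarray(t, dtype=float)
    values = np.asarray(values, dtype=float)
    if t.size == 0:
        return (0.0 if t0 is None else t0), np.empty(0)
    if t0 is None:
        t0 = float(t.min())
    k = np.floor((t - t0) / delta).astype(int)
    valid = k >= 0
    k = k[valid]
    v = values[valid]
    n_bins = int(k.max()) + 1 if k.size else 0
    sums = np.bincount(k, weights=v, minlength=n_bins)
    counts = np.bincount(k, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        grid = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return t0, grid


def resample_table(
    table: LinkedBehaviourTable, var: str, delta: float
) -> list[RegularSeries]:
    """Resample one variable of every individual onto its own regular grid."""
    out = []
    for animal_id, sub in table.per_id():
        t = sub["t"].to_numpy(dtype=float)
        v = sub[var].to_numpy(dtype=float)
        order = np.argsort(t, kind="stable")
        t0, grid = resample_series(t[order], v[order], delta)
        out.append(RegularSeries(id=animal_id, t0=t0, delta=delta, values=grid))
    return out


# ---------------------------------------------------------------------------
# periodogram estimators
# ---------------------------------------------------------------------------


def _check_series(values: np.ndarray) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    finite = values[np.isfinite(values)]
    if finite.size == 0:
        raise ValueError("empty series")
    if np.nanvar(finite) == 0:
        raise ValueError("constant series: periodogram undefined")
    return values


def chi_sq_periodogram(
    values: np.ndarray,
    delta: float,
    period_range: tuple[float, float] = DEFAULT_PERIOD_RANGE,
    alpha: float = 0.05,
    correction: str = "sidak",
) -> pd.DataFrame:
    """Sokolove-Bushell chi-square periodogram of a regular series.

    Candidate periods are the integer multiples of *delta* inside
    *period_range* (phase folding needs whole bins). Missing bins (NaN) are
    simply dropped from every mean: phase means, the grand mean and the
    variance all use the available points, and ``K = N_available / r``.

    The significance threshold at each period is a quantile of chi-square
    with ``r - 1`` degrees of freedom. *correction* sets the level per
    period: ``"sidak"`` (default) uses ``1 - (1-alpha)^(1/M)`` over the M
    candidate periods, so one whole periodogram of a non-rhythmic series
    crosses its threshold somewhere with probability of only about alpha;
    ``"bonferroni"`` uses ``alpha/M``; ``"none"`` uses the raw per-period
    ``alpha`` (appropriate when a single pre-specified period is tested,
    and the convention behind textbook worked examples).
    """
    values = _check_series(values)
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if correction not in ("sidak", "bonferroni", "none"):
        raise ValueError("correction must be 'sidak', 'bonferroni' or 'none'")
    finite = np.isfinite(values)
    idx = np.nonzero(finite)[0]
    x = values[finite]
    n_avail = x.size
    grand_mean = x.mean()
    s2 = np.mean((x - grand_mean) ** 2)

    r_lo = max(2, int(math.ceil(period_range[0] / delta)))
    r_hi = int(math.floor(period_range[1] / delta))
    if r_hi < r_lo:
        raise ValueError("period_range contains no integer multiple of delta")
    if values.size < 2 * r_hi:
        raise ValueError(
            f"series too short: need at least {2 * r_hi} bins for the maximum period"
        )
    rs = np.arange(r_lo, r_hi + 1)
    if correction == "sidak":
        level = 1 - (1 - alpha) ** (1 / rs.size)
    elif correction == "bonferroni":
        level = alpha / rs.size
    else:
        level = alpha
    power = np.empty(rs.size)
    for j, r in enumerate(rs):
        h = idx % r
        sums = np.bincount(h, weights=x, minlength=r)
        counts = np.bincount(h, minlength=r)
        occupied = counts > 0
        phase_means = sums[occupied] / counts[occupied]
        power[j] = (n_avail / r) * np.sum((phase_means - grand_mean) ** 2) / s2
    thresh = _stats.chi2.ppf(1 - level, df=rs - 1)
    return pd.DataFrame(
        {"period": rs * delta, "power": power, "signif_threshold": thresh}
    )


def _ls_frequency_grid(
    span: float, period_range: tuple[float, float], oversampling: int
) -> np.ndarray:
    f_lo = 1.0 / period_range[1]
    f_hi = 1.0 / period_range[0]
    df = 1.0 / (oversampling * span)
    return np.arange(f_lo, f_hi + df / 2, df)


def ls_periodogram(
    t: np.ndarray,
    values: np.ndarray,
    period_range: tuple[float, float] = DEFAULT_PERIOD_RANGE,
    alpha: float = 0.05,
    oversampling: int = 4,
) -> pd.DataFrame:
    """Classical normalised Lomb-Scargle periodogram (irregular sampling allowed).

    Power is normalised by the sample variance so that white-noise power is
    unit-mean exponential; the constant significance threshold corrects for
    the M evaluated frequencies: ``z* = -ln(1 - (1 - alpha)^(1/M))``. A
    constant series yields zero power everywhere (and hence no peaks).
    """
    t = np.asarray(t, dtype=float)
    values = np.asarray(values, dtype=float)
    ok = np.isfinite(t) & np.isfinite(values)
    t, y = t[ok], values[ok]
    if t.size < 3:
        raise ValueError("need at least 3 finite observations")
    freqs = _ls_frequency_grid(float(t.max() - t.min()), period_range, oversampling)
    m = freqs.size
    z_star = -math.log(1 - (1 - alpha) ** (1.0 / m))
    var = y.var()
    if var == 0:
        power = np.zeros(m)
    else:
        power = _signal.lombscargle(t, y - y.mean(), 2 * np.pi * freqs) / var
    out = pd.DataFrame(
        {"period": 1.0 / freqs, "power": power, "signif_threshold": z_star}
    )
    return out.sort_values("period", ignore_index=True)


def ac_periodogram(
    values: np.ndarray,
    delta: float,
    period_range: tuple[float, float] = DEFAULT_PERIOD_RANGE,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Autocorrelation periodogram: sample ACF at each candidate lag.

    The white-noise significance band is ``Phi^{-1}(1 - alpha/2)/sqrt(N)``.
    Missing bins are replaced by the series mean before computing the ACF
    (equivalent to dropping them from every product term).
    """
    values = _check_series(values)
    lag_lo = max(1, int(math.ceil(period_range[0] / delta)))
    lag_hi = int(math.floor(period_range[1] / delta))
    if values.size < 2 * lag_hi:
        raise ValueError("series too short for the maximum lag")
    x = values.copy()
    mean = np.nanmean(x)
    x = np.where(np.isfinite(x), x, mean) - mean
    denom = np.sum(x**2)
    acf = np.array([np.sum(x[: x.size - L] * x[L:]) for L in range(lag_lo, lag_hi + 1)])
    acf = acf / denom
    n = values[np.isfinite(values)].size
    thresh = _stats.norm.ppf(1 - alpha / 2) / math.sqrt(n)
    lags = np.arange(lag_lo, lag_hi + 1)
    return pd.DataFrame(
        {"period": lags * delta, "power": acf, "signif_threshold": thresh}
    )


def fourier_periodogram(
    values: np.ndarray,
    delta: float,
    period_range: tuple[float, float] = DEFAULT_PERIOD_RANGE,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Discrete Fourier periodogram at the Fourier frequencies in range.

    Power is ``|X_k|^2 / (N * s^2)`` of the mean-subtracted series, which is
    unit-mean exponential under white noise; the threshold applies the same
    M-frequency correction as the Lomb-Scargle estimator.
    """
    values = _check_series(values)
    if values.size < 4:
        raise ValueError("need at least 4 samples")
    x = values.copy()
    mean = np.nanmean(x)
    x = np.where(np.isfinite(x), x, mean) - mean
    n = x.size
    s2 = np.mean(x**2)
    spec = np.abs(np.fft.rfft(x)) ** 2 / (n * s2)
    freqs = np.fft.rfftfreq(n, d=delta)
    with np.errstate(divide="ignore"):
        periods = np.where(freqs > 0, 1.0 / np.maximum(freqs, 1e-300), np.inf)
    keep = (periods >= period_range[0]) & (periods <= period_range[1])
    if not keep.any():
        raise ValueError("no Fourier frequency falls in period_range")
    m = int(keep.sum())
    z_star = -math.log(1 - (1 - alpha) ** (1.0 / m))
    out = pd.DataFrame(
        {"period": periods[keep], "power": spec[keep], "signif_threshold": z_star}
    )
    return out.sort_values("period", ignore_index=True)


_METHODS = {
    "chi_sq": chi_sq_periodogram,
    "ac": ac_periodogram,
    "fourier": fourier_periodogram,
}


def periodogram(
    table: LinkedBehaviourTable,
    var: str = "moving",
    delta: float = mins(10),
    period_range: tuple[float, float] = DEFAULT_PERIOD_RANGE,
    alpha: float = 0.05,
    method: str = "chi_sq",
    **kwargs,
) -> pd.DataFrame:
    """Resample one variable per individual and compute its periodogram.

    *method* is one of ``chi_sq``, ``ls``, ``ac``, ``fourier``. Individuals
    whose series is too short or constant are skipped with a note column in
    no rows (they simply produce no periodogram, hence count as arrhythmic
    downstream). Returns a long frame (id, period, power, signif_threshold).
    """
    chunks = []
    for series in resample_table(table, var, delta):
        try:
            if method == "ls":
                finite = np.isfinite(series.values)
                pg = ls_periodogram(
                    series.t[finite], series.values[finite], period_range, alpha, **kwargs
                )
            elif method in _METHODS:
                pg = _METHODS[method](series.values, delta, period_range, alpha, **kwargs)
            else:
                raise ValueError(f"unknown method {method!r}")
        except ValueError as exc:
            if "unknown method" in str(exc):
                raise
            continue  # degenerate series: no periodogram for this individual
        pg.insert(0, "id", series.id)
        chunks.append(pg)
    if not chunks:
        return pd.DataFrame(columns=["id", "period", "power", "signif_threshold"])
    return pd.concat(chunks, ignore_index=True)


# ---------------------------------------------------------------------------
# peaks and summaries
# ---------------------------------------------------------------------------


def _find_peaks_single(pg: pd.DataFrame, n_peaks: int) -> np.ndarray:
    period = pg["period"].to_numpy(dtype=float)
    power = pg["power"].to_numpy(dtype=float)
    thresh = pg["signif_threshold"].to_numpy(dtype=float)
    n = power.size
    ranks = np.zeros(n, dtype=int)
    if n == 0:
        return ranks
    candidates = []
    for i in range(n):
        if power[i] <= thresh[i]:
            continue
        if i > 0 and power[i] < power[i - 1]:
            continue
        if i < n - 1 and power[i] < power[i + 1]:
            continue
        window = (period >= 0.95 * period[i]) & (period <= 1.05 * period[i])
        if power[i] < power[window].max():
            continue
        candidates.append(i)
    # dominance can hold for several grid points of one plateau; keep the first
    candidates = sorted(
        candidates, key=lambda i: (-(power[i] - thresh[i]), period[i])
    )
    kept: list[int] = []
    for i in candidates:
        if any(abs(period[i] - period[j]) <= 0.05 * period[j] for j in kept):
            continue
        kept.append(i)
        if len(kept) == n_peaks:
            break
    for rank, i in enumerate(kept, start=1):
        ranks[i] = rank
    return ranks


def find_peaks(pg: pd.DataFrame, n_peaks: int = 3) -> pd.DataFrame:
    """Annotate a periodogram table with peak ranks.

    A candidate peak is a local maximum of power exceeding its significance
    threshold and maximal within +/-5% of its own period; candidates are
    ranked 1..n_peaks by descending relative power (power - threshold). All
    other rows get rank 0. Works on single-individual tables or long tables
    with an ``id`` column.
    """
    out = pg.copy()
    if "id" in out.columns:
        parts = []
        for _, sub in out.groupby("id", sort=False):
            sub = sub.sort_values("period")
            sub["peak"] = _find_peaks_single(sub, n_peaks)
            parts.append(sub)
        return pd.concat(parts, ignore_index=True)
    out = out.sort_values("period", ignore_index=True)
    out["peak"] = _find_peaks_single(out, n_peaks)
    return out


def summarize_rhythmicity(pg: pd.DataFrame) -> pd.DataFrame:
    """One row per individual: is_rhythmic, first peak period and relative power.

    An individual is rhythmic iff it has a rank-1 peak; its first peak
    period is that peak's period, and the relative power is power minus the
    significance threshold there. Arrhythmic individuals get NaN for both.
    """
    if "peak" not in pg.columns:
        raise ValueError("periodogram has no 'peak' column; run find_peaks first")
    frame = pg if "id" in pg.columns else pg.assign(id="series")
    rows = []
    for animal_id, sub in frame.groupby("id", sort=False):
        top = sub[sub["peak"] == 1]
        if len(top):
            period = float(top["period"].iloc[0])
            rel = float(top["power"].iloc[0] - top["signif_threshold"].iloc[0])
            rows.append({"id": animal_id, "is_rhythmic": True,
                         "first_peak_period": period, "first_peak_rel_power": rel})
        else:
            rows.append({"id": animal_id, "is_rhythmic": False,
                         "first_peak_period": np.nan, "first_peak_rel_power": np.nan})
    return pd.DataFrame(rows)


def group_summary(summary: pd.DataFrame, by: str) -> pd.DataFrame:
    """Population table per group: period mean/sd (hours), % rhythmic, counts.

    Mirrors the conventional reporting of circadian screens: per group the
    mean and SD of the first peak period over rhythmic individuals (in
    hours), the percentage rhythmic, and the raw counts. Numeric columns are
    rounded to two digits (round-half-even).
    """
    if by not in summary.columns:
        raise KeyError(f"no column {by!r} in summary")
    rows = []
    for group, sub in summary.groupby(by, sort=True):
        periods = sub.loc[sub["is_rhythmic"], "first_peak_period"] / hours(1)
        rows.append(
            {
                by: group,
                "mean_period": periods.mean() if len(periods) else np.nan,
                "sd_period": periods.std(ddof=1) if len(periods) > 1 else np.nan,
                "percent_rhythmic": 100.0 * sub["is_rhythmic"].sum() / len(sub),
                "n_rhythmic": int(sub["is_rhythmic"].sum()),
                "n": len(sub),
            }
        )
    out = pd.DataFrame(rows)
    for col in ("mean_period", "sd_period", "percent_rhythmic"):
        out[col] = out[col].round(2)
    return out


# ---------------------------------------------------------------------------
# grouped binomial GLM
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LogitFit:
    """Two-group logistic regression fit (logit link, treatment coding).

    ``beta0`` is the log-odds of the outcome in the reference group,
    ``beta1`` the log-odds ratio of the second group versus the reference;
    ``se``, ``z`` and ``p`` are the expected-information Wald quantities.
    """

    beta0: float
    beta1: float
    se0: float
    se1: float

    @property
    def z0(self) -> float:
        return self.beta0 / self.se0

    @property
    def z1(self) -> float:
        return self.beta1 / self.se1

    @property
    def p0(self) -> float:
        return 2 * _stats.norm.sf(abs(self.z0))

    @property
    def p1(self) -> float:
        return 2 * _stats.norm.sf(abs(self.z1))

    def summary_frame(self, names=("(Intercept)", "group")) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "estimate": [self.beta0, self.beta1],
                "std_error": [self.se0, self.se1],
                "z_value": [self.z0, self.z1],
                "p_value": [self.p0, self.p1],
            },
            index=list(names),
        )


def two_group_logit_fit(k1: int, n1: int, k2: int, n2: int) -> LogitFit:
    """Binomial GLM with logit link on grouped two-sample data, in closed form.

    With ``k1`` successes of ``n1`` in the reference group and ``k2`` of
    ``n2`` in the other, the saturated two-group logistic MLE is

    ``beta0 = ln(k1/(n1-k1))``,
    ``beta1 = ln(k2/(n2-k2)) - beta0``,
    ``se0 = sqrt(1/k1 + 1/(n1-k1))``,
    ``se1 = sqrt(1/k1 + 1/(n1-k1) + 1/k2 + 1/(n2-k2))``.

    Complete separation (k = 0 or k = n in either group) makes the MLE
    infinite and raises.
    """
    for k, n, label in ((k1, n1, "group 1"), (k2, n2, "group 2")):
        if n <= 0 or k < 0 or k > n:
            raise ValueError(f"invalid counts for {label}: k={k}, n={n}")
        if k == 0 or k == n:
            raise ValueError(
                f"complete separation in {label} (k={k}, n={n}): logistic MLE is infinite"
            )
    beta0 = math.log(k1 / (n1 - k1))
    beta1 = math.log(k2 / (n2 - k2)) - beta0
    se0 = math.sqrt(1 / k1 + 1 / (n1 - k1))
    se1 = math.sqrt(1 / k1 + 1 / (n1 - k1) + 1 / k2 + 1 / (n2 - k2))
    return LogitFit(beta0=beta0, beta1=beta1, se0=se0, se1=se1)


def fit_rhythmicity_glm(summary: pd.DataFrame, by: str) -> LogitFit:
    """Fit is_rhythmic ~ group for a two-level grouping metavariable.

    The reference level is the first group in sorted order (matching
    treatment coding of a character covariate).
    """
    groups = sorted(summary[by].unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups in {by!r}, got {groups}")
    counts = []
    for g in groups:
        sub = summary.loc[summary[by] == g, "is_rhythmic"]
        counts.extend([int(sub.sum()), int(len(sub))])
    return two_group_logit_fit(*counts)
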