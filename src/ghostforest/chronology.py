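"""Detrending, site-chronology construction and chronology quality statistics.

Raw ring widths decline as a tree ages and its circumference grows, so each
series is standardized before averaging: an expected-growth curve
w(t) = a*exp(-b*t) + k is fit over cambial age t and the dimensionless
ring-width index is the ratio width/fitted. When the negative-exponential
fit is unusable the fit falls back to a non-positive-slope line, and
finally to the horizontal mean (the classic conservative detrending chain).

Quality statistics follow the standard dendrochronology definitions:

- mean sensitivity  MS = mean of |2(x_{t+1}-x_t)/(x_{t+1}+x_t)|
- interseries correlation: each series' Pearson r against the mean of all
  other series (a common-signal / crossdating quality summary)
- rbar: mean pairwise Pearson correlation among index series
- EPS = n*rbar / (1 + (n-1)*rbar),  SNR = n*rbar / (1 - rbar),
  linked by the identity EPS = SNR/(1+SNR).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .io import RingWidthSeries

__all__ = [
    "DetrendFit",
    "IndexSeries",
    "Chronology",
    "fit_detrend",
    "detrend",
    "mean_sensitivity",
    "interseries_correlation",
    "rbar_eps_snr",
    "eps_from_snr",
    "tukey_biweight_mean",
    "build_chronology",
]

NEGATIVE_EXPONENTIAL = "negative_exponential"
LINEAR_NONPOSITIVE = "linear_nonpositive"
HORIZONTAL_MEAN = "horizontal_mean"


@dataclass(frozen=True)
class DetrendFit:
    """A fitted expected-growth curve for one series.

    ``model`` records where the fallback chain stopped; ``fitted`` is the
    expected width (mm) per year, strictly positive so that ratio indexing
    is defined.
    """

    model: str
    params: dict
    fitted: np.ndarray

    def __post_init__(self):
        if np.any(np.asarray(self.fitted) <= 0):
            raise ValueError("fitted growth curve must be strictly positive")


@dataclass(frozen=True)
class IndexSeries:
    """A detrended, dimensionless ring-width index series."""

    series_id: str
    first_year: int
    index: np.ndarray
    tree_id: str = ""

    def __post_init__(self):
        idx = np.asarray(self.index, dtype=float)
        if np.any(idx < 0):
            raise ValueError(f"{self.series_id}: ring-width index must be >= 0")
        object.__setattr__(self, "index", idx)

    @property
    def last_year(self) -> int:
        return self.first_year + len(self.index) - 1

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.first_year, self.last_year + 1)

    def __len__(self) -> int:
        return len(self.index)


@dataclass
class Chronology:
    """Site-level mean index by year with sample depth and quality stats."""

    site_id: str
    years: np.ndarray
    values: np.ndarray
    depth: np.ndarray
    stats: dict = field(default_factory=dict)

    def __post_init__(self):
        self.years = np.asarray(self.years, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        self.depth = np.asarray(self.depth, dtype=int)
        if not (len(self.years) == len(self.values) == len(self.depth)):
            raise ValueError("years, values and depth must have equal length")

    @property
    def first_year(self) -> int:
        return int(self.years[0])

    @property
    def last_year(self) -> int:
        return int(self.years[-1])

    def value_at(self, year: int) -> float:
        pos = np.searchsorted(self.years, year)
        if pos >= len(self.years) or self.years[pos] != year:
            return float("nan")
        return float(self.values[pos])


def _negexp(t, a, b, k):
    return a * np.exp(-b * t) + k


def fit_detrend(series: RingWidthSeries) -> DetrendFit:
    """Fit the expected-growth curve with the conservative fallback chain.

    Tries w(t) = a*exp(-b*t) + k by least squares over cambial age
    t = 0,1,...; the fit is rejected (and the chain falls back to a linear
    fit, then to the horizontal mean) when it fails to converge, yields
    a <= 0, b <= 0, k < 0, or any non-positive fitted value. A linear fit
    with positive slope also falls through to the horizontal mean.
    """
    w = series.widths
    n = len(w)
    if n < 10:
        raise ValueError(f"{series.series_id}: need >= 10 rings to detrend, have {n}")
    if np.all(w == 0):
        raise ValueError(f"{series.series_id}: all-zero series has no positive level to fit")
    t = np.arange(n, dtype=float)

    if np.ptp(w) > 0:
        fit = _try_negexp(t, w)
        if fit is not None:
            return fit
        slope, intercept = np.polyfit(t, w, 1)
        fitted = slope * t + intercept
        if slope <= 0 and np.all(fitted > 0):
            return DetrendFit(
                LINEAR_NONPOSITIVE, {"slope": float(slope), "intercept": float(intercept)}, fitted
            )
    mean = float(np.mean(w))
    return DetrendFit(HORIZONTAL_MEAN, {"mean": mean}, np.full(n, mean))


def _try_negexp(t: np.ndarray, w: np.ndarray) -> DetrendFit | None:
    n = len(w)
    head = max(3, n // 10)
    k0 = max(float(np.mean(w[-head:])), 1e-6)
    a0 = float(np.mean(w[:head])) - k0
    if a0 <= 0:
        a0 = max(float(np.ptp(w)), 1e-3)
    for b0 in (3.0 / n, 10.0 / n, 0.5 / n):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", optimize.OptimizeWarning)
                popt, _ = optimize.curve_fit(
                    _negexp, t, w, p0=(a0, b0, k0), maxfev=20000, xtol=1e-12, ftol=1e-12
                )
        except (RuntimeError, optimize.OptimizeWarning):
            continue
        a, b, k = (float(v) for v in popt)
        fitted = _negexp(t, a, b, k)
        if a > 0 and b > 0 and k >= 0 and np.all(fitted > 0):
            return DetrendFit(NEGATIVE_EXPONENTIAL, {"a": a, "b": b, "k": k}, fitted)
    return None


def detrend(series: RingWidthSeries, fit: DetrendFit | None = None) -> IndexSeries:
    """Ratio-detrend a series: index = width / fitted expected width."""
    if fit is None:
        fit = fit_detrend(series)
    if len(fit.fitted) != len(series):
        raise ValueError("fit was computed for a series of different length")
    return IndexSeries(
        series_id=series.series_id,
        first_year=series.first_year,
        index=series.widths / fit.fitted,
        tree_id=series.tree_id,
    )


def mean_sensitivity(widths) -> float:
    """Average absolute relative difference between consecutive ring widths."""
    x = widths.widths if isinstance(widths, RingWidthSeries) else np.asarray(widths, dtype=float)
    if len(x) < 2:
        raise ValueError("mean sensitivity needs >= 2 rings")
    s = x[1:] + x[:-1]
    if np.any(s == 0):
        raise ValueError("consecutive pair of zero rings makes mean sensitivity undefined")
    return float(np.mean(np.abs(2.0 * (x[1:] - x[:-1]) / s)))


def _index_matrix(indices: list[IndexSeries]) -> tuple[np.ndarray, np.ndarray]:
    """Stack index series on the union of years; NaN where a series is absent."""
    lo = min(s.first_year for s in indices)
    hi = max(s.last_year for s in indices)
    years = np.arange(lo, hi + 1)
    mat = np.full((len(indices), len(years)), np.nan)
    for i, s in enumerate(indices):
        mat[i, s.first_year - lo : s.last_year - lo + 1] = s.index
    return years, mat


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xd = x - x.mean()
    yd = y - y.mean()
    denom = np.sqrt((xd**2).sum() * (yd**2).sum())
    if denom == 0:
        return float("nan")
    return float((xd * yd).sum() / denom)


def interseries_correlation(
    indices: list[IndexSeries], min_overlap: int = 20
) -> tuple[dict[str, float], float]:
    """Each series' Pearson r against the mean of all other series.

    Series overlapping the leave-one-out mean chronology by fewer than
    ``min_overlap`` years are flagged NaN and excluded from the site mean.
    """
    if len(indices) < 2:
        raise ValueError("interseries correlation needs >= 2 series")
    _, mat = _index_matrix(indices)
    per: dict[str, float] = {}
    for i, s in enumerate(indices):
        others = np.delete(mat, i, axis=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
            loo = np.nanmean(others, axis=0)
        ok = ~np.isnan(mat[i]) & ~np.isnan(loo)
        if ok.sum() < min_overlap:
            warnings.warn(
                f"{s.series_id}: only {int(ok.sum())} years overlap the leave-one-out mean "
                f"(< {min_overlap}); excluded from the site mean",
                stacklevel=2,
            )
            per[s.series_id] = float("nan")
            continue
        per[s.series_id] = _pearson(mat[i][ok], loo[ok])
    vals = [v for v in per.values() if not np.isnan(v)]
    return per, float(np.mean(vals)) if vals else float("nan")


def rbar_eps_snr(
    indices: list[IndexSeries],
    window: tuple[int, int] | None = None,
    min_pair_overlap: int = 20,
) -> tuple[float, float, float]:
    """Mean pairwise correlation and the derived EPS and SNR.

    rbar is the mean of all pairwise Pearson correlations over each pair's
    overlap within ``window``; pairs with fewer than ``min_pair_overlap``
    common years are skipped. With n contributing series,
    EPS = n*rbar/(1+(n-1)*rbar) and SNR = n*rbar/(1-rbar); rbar = 1 yields
    SNR = +inf (EPS = 1).
    """
    if len(indices) < 2:
        raise ValueError("rbar needs >= 2 series")
    years, mat = _index_matrix(indices)
    if window is not None:
        keep = (years >= window[0]) & (years <= window[1])
        mat = mat[:, keep]
    rs = []
    contributing: set[int] = set()
    for i in range(len(indices)):
        for j in range(i + 1, len(indices)):
            ok = ~np.isnan(mat[i]) & ~np.isnan(mat[j])
            if ok.sum() < min_pair_overlap:
                continue
            r = _pearson(mat[i][ok], mat[j][ok])
            if not np.isnan(r):
                rs.append(r)
                contributing.update((i, j))
    if not rs:
        raise ValueError("no series pair has sufficient overlap in the window")
    rbar = float(np.mean(rs))
    n = len(contributing)
    eps = n * rbar / (1.0 + (n - 1) * rbar)
    snr = float("inf") if rbar >= 1.0 else n * rbar / (1.0 - rbar)
    return rbar, float(eps), snr


def eps_from_snr(snr: float) -> float:
    """The algebraic identity EPS = SNR / (1 + SNR)."""
    if np.isinf(snr):
        return 1.0
    return snr / (1.0 + snr)


def tukey_biweight_mean(x: np.ndarray, c: float = 9.0) -> float:
    """Tukey's biweight robust mean with tuning constant ``c`` (one-step).

    Weights observations by (1-u^2)^2 with u = (x - median)/(c*MAD); points
    beyond c MADs get zero weight. Falls back to the median when MAD = 0.
    """
    x = np.asarray(x, dtype=float)
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        return float(med)
    u = (x - med) / (c * mad)
    w = np.where(np.abs(u) < 1, (1 - u**2) ** 2, 0.0)
    return float(np.sum(w * x) / np.sum(w))


def build_chronology(
    indices: list[IndexSeries],
    site_id: str = "",
    method: str = "biweight",
    truncate_start: int | None = None,
    biweight_min_depth: int = 6,
    raw_series: list[RingWidthSeries] | None = None,
    stats_window: tuple[int, int] | None = None,
) -> Chronology:
    """Average index series into a site chronology and attach quality stats.

    ``method`` is "mean" (arithmetic) or "biweight" (Tukey biweight robust
    mean, tuning constant 9, used in years with depth >= ``biweight_min_depth``,
    arithmetic mean otherwise). ``truncate_start`` drops all years before the
    given calendar year. Mean sensitivity is computed from ``raw_series``
    when provided (the conventional basis), else from the index series.
    """
    if method not in ("mean", "biweight"):
        raise ValueError(f"unknown aggregation method {method!r}")
    if not indices:
        raise ValueError("no index series supplied")
    years, mat = _index_matrix(indices)
    if truncate_start is not None:
        keep = years >= truncate_start
        years, mat = years[keep], mat[:, keep]
        if years.size == 0:
            raise ValueError(f"no data at or after truncate_start={truncate_start}")
    covered = ~np.all(np.isnan(mat), axis=0)
    years, mat = years[covered], mat[:, covered]
    depth = np.sum(~np.isnan(mat), axis=0)
    values = np.empty(len(years))
    for j in range(len(years)):
        col = mat[:, j]
        col = col[~np.isnan(col)]
        if method == "biweight" and len(col) >= biweight_min_depth:
            values[j] = tukey_biweight_mean(col)
        else:
            values[j] = col.mean()

    stats: dict = {"n_series": len(indices)}
    if stats_window is None:
        stats_window = (int(years[0]), int(years[-1]))
    if len(indices) >= 2:
        try:
            _, stats["interseries_r"] = interseries_correlation(indices)
        except ValueError:
            stats["interseries_r"] = float("nan")
        try:
            rbar, eps, snr = rbar_eps_snr(indices, window=stats_window)
            stats.update(rbar=rbar, eps=eps, snr=snr)
        except ValueError:
            stats.update(rbar=float("nan"), eps=float("nan"), snr=float("nan"))
    ms_source = raw_series if raw_series is not None else indices
    ms_vals = []
    for s in ms_source:
        x = s.widths if isinstance(s, RingWidthSeries) else s.index
        try:
            ms_vals.append(mean_sensitivity(x))
        except ValueError:
            pass
    stats["mean_sensitivity"] = float(np.mean(ms_vals)) if ms_vals else float("nan")

    return Chronology(site_id=site_id, years=years, values=values, depth=depth, stats=stats)
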