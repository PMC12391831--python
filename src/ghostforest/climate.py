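"""Lagged monthly climate-growth correlation analysis.

Ring formation integrates climate over more than the calendar year of
growth, so each window month of the previous and current year is paired
with the chronology value of the response year: the default 18-month
window runs previous-May through previous-December, then current-January
through current-October. Pearson correlations are computed per month with
significance from the exact two-sided t-test (default) or a stationary
bootstrap.
"""

from __future__ import annotations

import calendar
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .chronology import Chronology
from .io import ClimateTable

__all__ = [
    "PREVIOUS",
    "CURRENT",
    "LagWindow",
    "MonthCorrelation",
    "CorrelationResult",
    "align_lagged",
    "monthly_correlations",
    "split_period",
    "stationary_bootstrap_indices",
]

PREVIOUS = "previous"
CURRENT = "current"


@dataclass(frozen=True)
class LagWindow:
    """Ordered list of (year_offset, month) pairs defining the lag window."""

    months: tuple[tuple[str, int], ...] = tuple(
        [(PREVIOUS, m) for m in range(5, 13)] + [(CURRENT, m) for m in range(1, 11)]
    )

    def __post_init__(self):
        for off, m in self.months:
            if off not in (PREVIOUS, CURRENT):
                raise ValueError(f"year offset must be 'previous' or 'current', got {off!r}")
            if not 1 <= m <= 12:
                raise ValueError(f"month {m} outside 1..12")

    def __iter__(self):
        return iter(self.months)

    def __len__(self):
        return len(self.months)

    @staticmethod
    def label(offset: str, month: int) -> str:
        """Plot label: lowercase abbreviations for previous-year months, uppercase for current."""
        abbr = calendar.month_abbr[month]
        return abbr.lower() if offset == PREVIOUS else abbr.upper()


@dataclass(frozen=True)
class MonthCorrelation:
    offset: str
    month: int
    r: float
    p: float
    significant: bool
    n: int
    ci_low: float | None = None
    ci_high: float | None = None

    @property
    def label(self) -> str:
        return LagWindow.label(self.offset, self.month)


@dataclass
class CorrelationResult:
    """Per-month correlation coefficients between a chronology and one climate variable."""

    variable: str
    period: tuple[int, int]
    months: list[MonthCorrelation] = field(default_factory=list)
    method: str = "t_test"
    alpha: float = 0.05

    @property
    def n_years(self) -> int:
        return max((m.n for m in self.months), default=0)

    def __getitem__(self, key: tuple[str, int]) -> MonthCorrelation:
        for m in self.months:
            if (m.offset, m.month) == key:
                return m
        raise KeyError(key)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "variable": self.variable,
                "period_start": self.period[0],
                "period_end": self.period[1],
                "label": m.label,
                "year_offset": m.offset,
                "month": m.month,
                "r": m.r,
                "p": m.p,
                "significant": m.significant,
                "ci_low": m.ci_low,
                "ci_high": m.ci_high,
                "n": m.n,
            }
            for m in self.months
        ]
        return pd.DataFrame(rows)


def align_lagged(
    chronology: Chronology,
    climate: ClimateTable,
    window: LagWindow | None = None,
    period: tuple[int, int] | None = None,
) -> dict[tuple[str, int], tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Pair each window month's climate values with response-year chronology values.

    Previous-year months use year-1's climate; a year missing that month's
    climate value is dropped pairwise for that month only. Returns
    {(offset, month): (climate, chronology, response_years)}.
    """
    window = window or LagWindow()
    chron = pd.Series(chronology.values, index=chronology.years)
    years = chronology.years
    if period is not None:
        years = years[(years >= period[0]) & (years <= period[1])]
    overlap = [y for y in years if y in climate.data.index or (y - 1) in climate.data.index]
    if len(overlap) < 30:
        raise ValueError(
            f"chronology/climate overlap is {len(overlap)} years (< 30) "
            f"within period {period}"
        )
    out = {}
    resp = chron.reindex(years).to_numpy()
    for off, month in window:
        clim_years = years - 1 if off == PREVIOUS else years
        clim = climate.data[month].reindex(clim_years).to_numpy()
        ok = ~np.isnan(clim) & ~np.isnan(resp)
        out[(off, month)] = (clim[ok], resp[ok], years[ok])
    return out


def stationary_bootstrap_indices(n: int, mean_block: float, rng: np.random.Generator) -> np.ndarray:
    """One stationary-bootstrap resample of 0..n-1 (geometric block lengths)."""
    p = 1.0 / mean_block
    idx = np.empty(n, dtype=int)
    t = int(rng.integers(n))
    for i in range(n):
        idx[i] = t
        if rng.random() < p:
            t = int(rng.integers(n))  # start a new block
        else:
            t = (t + 1) % n
    return idx


def monthly_correlations(
    chronology: Chronology,
    climate: ClimateTable,
    window: LagWindow | None = None,
    period: tuple[int, int] | None = None,
    method: str = "t_test",
    alpha: float = 0.05,
    n_boot: int = 1000,
    mean_block: float = 4.0,
    seed: int = 0,
) -> CorrelationResult:
    """Pearson correlation per lag-window month with a significance flag.

    ``method="t_test"`` uses the exact two-sided t-test at level ``alpha``;
    ``method="stationary_bootstrap"`` resamples year-blocks (mean length
    ``mean_block``) ``n_boot`` times and flags months whose 95% percentile
    interval excludes zero. Zero-variance months get r = NaN.
    """
    if method not in ("t_test", "stationary_bootstrap"):
        raise ValueError(f"unknown significance method {method!r}")
    window = window or LagWindow()
    aligned = align_lagged(chronology, climate, window, period)
    if period is None:
        period = (int(chronology.years[0]), int(chronology.years[-1]))
    rng = np.random.default_rng(seed)
    result = CorrelationResult(variable=climate.variable, period=period, method=method, alpha=alpha)
    for off, month in window:
        clim, resp, _ = aligned[(off, month)]
        n = len(clim)
        if n < 3 or np.ptp(clim) == 0 or np.ptp(resp) == 0:
            result.months.append(
                MonthCorrelation(off, month, float("nan"), float("nan"), False, n)
            )
            continue
        r, p = sps.pearsonr(clim, resp)
        ci_low = ci_high = None
        if method == "t_test":
            significant = bool(p < alpha)
        else:
            reps = np.empty(n_boot)
            for b in range(n_boot):
                idx = stationary_bootstrap_indices(n, mean_block, rng)
                c, y = clim[idx], resp[idx]
                if np.ptp(c) == 0 or np.ptp(y) == 0:
                    reps[b] = 0.0
                else:
                    reps[b] = sps.pearsonr(c, y)[0]
            ci_low, ci_high = np.percentile(reps, [100 * alpha / 2, 100 * (1 - alpha / 2)])
            significant = bool(ci_low > 0 or ci_high < 0)
        result.months.append(
            MonthCorrelation(off, month, float(r), float(p), significant, n, ci_low, ci_high)
        )
    return result


def split_period(
    chronology: Chronology,
    climate: ClimateTable,
    window: LagWindow | None = None,
    breaks: tuple[int, int, int] = (1895, 1960, 2022),
    method: str = "t_test",
    split_inclusive_early: bool = True,
    **kwargs,
) -> tuple[CorrelationResult, CorrelationResult]:
    """Independent correlation analyses for an early and a late sub-period.

    With ``breaks = (b0, b1, b2)`` the early period is b0..b1 and the late
    b1+1..b2 (the split year belongs to the early half by default).
    """
    b0, b1, b2 = breaks
    early_period = (b0, b1)
    late_period = (b1 + 1, b2) if split_inclusive_early else (b1, b2)
    for name, (lo, hi) in (("early", early_period), ("late", late_period)):
        if hi - lo + 1 < 30:
            raise ValueError(f"{name} sub-period {lo}-{hi} is shorter than 30 years")
    early = monthly_correlations(chronology, climate, window, early_period, method, **kwargs)
    late = monthly_correlations(chronology, climate, window, late_period, method, **kwargs)
    return early, late
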