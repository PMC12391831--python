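"""Two procedures for detecting stress-related growth suppression.

Running-mean procedure (per tree, raw widths): a year is "suppressed" for a
tree when its raw ring width falls below ``threshold_frac`` (default 0.25)
of the tree's 20-year running mean; a year is a "widespread suppression"
year for the site when strictly more than ``widespread_threshold`` (default
75%) of the trees with a defined running mean are suppressed. Raw widths are
used because standardization can remove exactly the ecological signal the
procedure looks for.

Host/non-host procedure (per tree, standardized indices): the shared
climate signal is removed from each stressed-site ("host") tree by
subtracting the reference-site ("non-host") chronology's deviations scaled
by the host/non-host standard-deviation ratio:

    gsi[y] = h[y] - (sd_h / sd_c) * (c[y] - mean(c))

The normalized residual (ngsi, mean 0 / sd 1) flags host-specific
suppression: a maximal run of years with ngsi below an onset threshold
(default -1.28, the standard-normal 10th percentile), allowing single-year
interruptions, of at least ``min_duration`` years is a per-tree suppression
period; its severity comes from the minimum ngsi reached (minor >= -2,
moderate >= -3, severe < -3). Site-level events are maximal runs of years
in which at least ``min_proportion`` of trees are concurrently in a period.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chronology import Chronology, IndexSeries
from .io import RingWidthSeries, SeriesSet

__all__ = [
    "GsiSeries",
    "SuppressionFlags",
    "TreeSuppressionPeriod",
    "SuppressionEvent",
    "running_mean",
    "flag_suppression",
    "merge_cores",
    "site_suppression",
    "widespread_years",
    "correct_host",
    "detect_tree_events",
    "site_events",
    "detect_site_events",
]

MINOR = "minor"
MODERATE = "moderate"
SEVERE = "severe"


@dataclass
class SuppressionFlags:
    """Tree x year suppression flags with per-year site percentages."""

    tree_ids: list[str]
    years: np.ndarray
    flags: np.ndarray  # bool, trees x years
    defined: np.ndarray  # bool, running mean defined
    widespread_threshold: float = 0.75
    min_depth: int = 5

    @property
    def depth(self) -> np.ndarray:
        return self.defined.sum(axis=0)

    @property
    def percent(self) -> np.ndarray:
        """Per-year fraction of flagged trees among trees with a defined running mean."""
        d = self.depth
        with np.errstate(invalid="ignore"):
            return np.where(d > 0, self.flags.sum(axis=0) / np.maximum(d, 1), np.nan)

    @property
    def widespread_years(self) -> list[int]:
        return widespread_years(self, self.widespread_threshold, self.min_depth)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.flags.T, index=self.years, columns=self.tree_ids)


@dataclass(frozen=True)
class GsiSeries:
    """A host tree's climate-corrected growth index over the host/non-host overlap."""

    tree_id: str
    first_year: int
    gsi: np.ndarray
    ngsi: np.ndarray
    degenerate: bool = False  # sd(gsi) = 0: ngsi undefined

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.first_year, self.first_year + len(self.gsi))

    @property
    def last_year(self) -> int:
        return self.first_year + len(self.gsi) - 1


@dataclass(frozen=True)
class TreeSuppressionPeriod:
    tree_id: str
    start_year: int
    end_year: int
    min_ngsi: float
    severity: str

    @property
    def duration(self) -> int:
        return self.end_year - self.start_year + 1

    def covers(self, year: int) -> bool:
        return self.start_year <= year <= self.end_year


@dataclass
class SuppressionEvent:
    """A site-level multi-year suppression event."""

    start_year: int
    end_year: int
    trees_involved: list[str]
    max_proportion: float
    severities: dict[str, str] = field(default_factory=dict)

    @property
    def duration(self) -> int:
        return self.end_year - self.start_year + 1


# ---------------------------------------------------------------------------
# Running-mean procedure


def running_mean(
    series: RingWidthSeries, window: int = 20, min_years: int = 10
) -> tuple[np.ndarray, np.ndarray]:
    """Centered running mean of raw widths with edge handling.

    Interior years average the ``window`` years centered on the target
    (offsets -window//2 .. window - window//2 - 1). Where the window runs
    past a series edge it slides inward so that min(window, n) years are
    always used; series shorter than ``min_years`` raise.
    Returns (means, defined_mask).
    """
    w = series.widths
    n = len(w)
    if n < min_years:
        raise ValueError(f"{series.series_id}: series of {n} years is shorter than {min_years}")
    lo = window // 2
    hi = window - lo - 1
    rm = np.empty(n)
    for i in range(n):
        start, end = i - lo, i + hi
        if start < 0:
            end, start = end - start, 0
        if end > n - 1:
            start, end = max(0, start - (end - (n - 1))), n - 1
        rm[i] = w[start : end + 1].mean()
    return rm, np.ones(n, dtype=bool)


def flag_suppression(
    series: RingWidthSeries,
    rm: np.ndarray | None = None,
    defined: np.ndarray | None = None,
    threshold_frac: float = 0.25,
    window: int = 20,
) -> np.ndarray:
    """Flag years whose raw width is below ``threshold_frac`` x the running mean."""
    if rm is None:
        rm, defined = running_mean(series, window)
    if defined is None:
        defined = np.ones(len(rm), dtype=bool)
    return (series.widths < threshold_frac * rm) & defined


def merge_cores(series_set: SeriesSet) -> list[RingWidthSeries]:
    """Average each tree's cores into one per-tree width series.

    Trees (not cores) are the suppression unit; per year, the mean of the
    cores covering that year is used. Series without a tree_id stand alone.
    """
    groups: dict[str, list[RingWidthSeries]] = {}
    for s in series_set:
        groups.setdefault(s.tree_id or s.series_id, []).append(s)
    merged = []
    for tree_id, cores in groups.items():
        if len(cores) == 1:
            s = cores[0]
            merged.append(
                RingWidthSeries(tree_id, s.first_year, s.widths, tree_id=tree_id,
                                site_id=s.site_id, units_scale=s.units_scale)
            )
            continue
        lo = min(s.first_year for s in cores)
        hi = max(s.last_year for s in cores)
        acc = np.zeros(hi - lo + 1)
        cnt = np.zeros(hi - lo + 1)
        for s in cores:
            sl = slice(s.first_year - lo, s.last_year - lo + 1)
            acc[sl] += s.widths
            cnt[sl] += 1
        covered = cnt > 0
        first = int(np.argmax(covered))
        last = len(covered) - int(np.argmax(covered[::-1])) - 1
        if not covered[first : last + 1].all():
            raise ValueError(f"tree {tree_id}: cores leave an interior gap in coverage")
        widths = acc[first : last + 1] / cnt[first : last + 1]
        merged.append(
            RingWidthSeries(tree_id, lo + first, widths, tree_id=tree_id,
                            site_id=cores[0].site_id, units_scale=cores[0].units_scale)
        )
    return merged


def site_suppression(
    series_set: SeriesSet,
    window: int = 20,
    threshold_frac: float = 0.25,
    widespread_threshold: float = 0.75,
    min_depth: int = 5,
    min_years: int = 10,
) -> SuppressionFlags:
    """Run the running-mean procedure for every tree of a site."""
    trees = merge_cores(series_set)
    trees = [t for t in trees if len(t) >= min_years]
    if not trees:
        raise ValueError("no tree long enough for a running mean")
    lo = min(t.first_year for t in trees)
    hi = max(t.last_year for t in trees)
    years = np.arange(lo, hi + 1)
    flags = np.zeros((len(trees), len(years)), dtype=bool)
    defined = np.zeros_like(flags)
    for i, t in enumerate(trees):
        rm, mask = running_mean(t, window, min_years)
        f = flag_suppression(t, rm, mask, threshold_frac)
        sl = slice(t.first_year - lo, t.last_year - lo + 1)
        flags[i, sl] = f
        defined[i, sl] = mask
    return SuppressionFlags(
        tree_ids=[t.tree_id for t in trees],
        years=years,
        flags=flags,
        defined=defined,
        widespread_threshold=widespread_threshold,
        min_depth=min_depth,
    )


def widespread_years(
    flags: SuppressionFlags, widespread_threshold: float = 0.75, min_depth: int = 5
) -> list[int]:
    """Years in which strictly more than the threshold fraction of trees are suppressed."""
    pct = flags.percent
    depth = flags.depth
    ok = (depth >= min_depth) & ~np.isnan(pct) & (pct > widespread_threshold)
    return [int(y) for y in flags.years[ok]]


# ---------------------------------------------------------------------------
# Host/non-host procedure


def correct_host(host_index: IndexSeries, nonhost: Chronology, min_overlap: int = 30) -> GsiSeries:
    """Remove the shared (climate) signal from a host tree's index series.

    Over the host/non-host overlap, gsi = h - (sd_h/sd_c)*(c - mean(c));
    ngsi standardizes gsi to mean 0, sd 1. A degenerate result (sd(gsi)=0,
    e.g. host identical to the non-host chronology) is flagged and yields
    NaN ngsi, hence no events downstream.
    """
    lo = max(host_index.first_year, nonhost.first_year)
    hi = min(host_index.last_year, nonhost.last_year)
    if hi - lo + 1 < min_overlap:
        raise ValueError(
            f"{host_index.tree_id or host_index.series_id}: host/non-host overlap "
            f"{max(0, hi - lo + 1)} years < {min_overlap}"
        )
    h = host_index.index[lo - host_index.first_year : hi - host_index.first_year + 1]
    c = np.array([nonhost.value_at(y) for y in range(lo, hi + 1)])
    ok = ~np.isnan(c)
    if ok.sum() < min_overlap:
        raise ValueError("non-host chronology has too many gaps in the overlap")
    sd_c = float(np.std(c[ok], ddof=1))
    if sd_c == 0:
        raise ValueError("non-host chronology has zero variance over the overlap")
    sd_h = float(np.std(h[ok], ddof=1))
    gsi = np.where(ok, h - (sd_h / sd_c) * (c - np.nanmean(c[ok])), np.nan)
    valid = ~np.isnan(gsi)
    sd_g = float(np.std(gsi[valid], ddof=1))
    # perfect cancellation leaves only rounding noise: treat as degenerate
    if sd_g <= 1e-9 * max(sd_h, sd_c, 1e-30):
        ngsi = np.full_like(gsi, np.nan)
        degenerate = True
    else:
        ngsi = (gsi - np.nanmean(gsi[valid])) / sd_g
        degenerate = False
    return GsiSeries(
        tree_id=host_index.tree_id or host_index.series_id,
        first_year=lo,
        gsi=gsi,
        ngsi=ngsi,
        degenerate=degenerate,
    )


def _severity(min_ngsi: float) -> str:
    if min_ngsi < -3.0:
        return SEVERE
    if min_ngsi < -2.0:
        return MODERATE
    return MINOR


def detect_tree_events(
    g: GsiSeries,
    onset_threshold: float = -1.28,
    min_duration: int = 4,
    bridge_gap: int = 1,
) -> list[TreeSuppressionPeriod]:
    """Per-tree suppression periods from the normalized corrected index.

    A period is a maximal run of years with ngsi below ``onset_threshold``,
    bridging interruptions of up to ``bridge_gap`` consecutive years, kept
    when its start-to-end span reaches ``min_duration`` years.
    """
    if g.degenerate:
        return []
    below = g.ngsi < onset_threshold  # NaN compares False
    periods: list[TreeSuppressionPeriod] = []
    idx = np.flatnonzero(below)
    if idx.size == 0:
        return periods
    runs: list[list[int]] = [[int(idx[0]), int(idx[0])]]
    for i in idx[1:]:
        if i - runs[-1][1] - 1 <= bridge_gap:
            runs[-1][1] = int(i)
        else:
            runs.append([int(i), int(i)])
    for start, end in runs:
        if end - start + 1 < min_duration:
            continue
        min_ngsi = float(np.nanmin(g.ngsi[start : end + 1]))
        periods.append(
            TreeSuppressionPeriod(
                tree_id=g.tree_id,
                start_year=int(g.first_year + start),
                end_year=int(g.first_year + end),
                min_ngsi=min_ngsi,
                severity=_severity(min_ngsi),
            )
        )
    return periods


def site_events(
    tree_periods: list[TreeSuppressionPeriod],
    tree_spans: dict[str, tuple[int, int]],
    min_proportion: float = 0.25,
    min_trees: int = 3,
) -> list[SuppressionEvent]:
    """Combine per-tree periods into site-level suppression events.

    ``tree_spans`` maps every analyzed tree (with or without periods) to the
    (first_year, last_year) span over which its corrected index is defined;
    the per-year denominator counts trees whose span covers the year. An
    event is a maximal run of years with proportion >= ``min_proportion``.
    """
    if len(tree_spans) < min_trees:
        raise ValueError(f"need >= {min_trees} analyzed trees, have {len(tree_spans)}")
    if not tree_periods:
        return []
    lo = min(s[0] for s in tree_spans.values())
    hi = max(s[1] for s in tree_spans.values())
    years = np.arange(lo, hi + 1)
    active = np.zeros(len(years))
    depth = np.zeros(len(years))
    for (t0, t1) in tree_spans.values():
        depth[t0 - lo : t1 - lo + 1] += 1
    for p in tree_periods:
        active[p.start_year - lo : p.end_year - lo + 1] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        prop = np.where(depth > 0, active / np.maximum(depth, 1), 0.0)
    in_event = prop >= min_proportion
    events: list[SuppressionEvent] = []
    i = 0
    while i < len(years):
        if not in_event[i]:
            i += 1
            continue
        j = i
        while j + 1 < len(years) and in_event[j + 1]:
            j += 1
        start, end = int(years[i]), int(years[j])
        involved = sorted(
            {p.tree_id for p in tree_periods if p.start_year <= end and p.end_year >= start}
        )
        severities: dict[str, str] = {}
        rank = {MINOR: 0, MODERATE: 1, SEVERE: 2}
        for p in tree_periods:
            if p.start_year <= end and p.end_year >= start:
                cur = severities.get(p.tree_id)
                if cur is None or rank[p.severity] > rank[cur]:
                    severities[p.tree_id] = p.severity
        events.append(
            SuppressionEvent(
                start_year=start,
                end_year=end,
                trees_involved=involved,
                max_proportion=float(prop[i : j + 1].max()),
                severities=severities,
            )
        )
        i = j + 1
    return events


def detect_site_events(
    gsis: list[GsiSeries],
    onset_threshold: float = -1.28,
    min_duration: int = 4,
    bridge_gap: int = 1,
    min_proportion: float = 0.25,
    min_trees: int = 3,
) -> tuple[list[TreeSuppressionPeriod], list[SuppressionEvent]]:
    """Convenience wrapper: per-tree periods plus site events from corrected indices."""
    periods: list[TreeSuppressionPeriod] = []
    spans: dict[str, tuple[int, int]] = {}
    for g in gsis:
        spans[g.tree_id] = (int(g.first_year), int(g.last_year))
        periods.extend(detect_tree_events(g, onset_threshold, min_duration, bridge_gap))
    return periods, site_events(periods, spans, min_proportion, min_trees)
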