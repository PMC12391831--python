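"""Readers and writers for ring-width and tabular proxy data.

Ring-width measurements travel in the Tucson ("RWL") decadal format used by
the ITRDB: each line carries a series id, the calendar year of the first
value on the line, and up to ten integer widths; a stop marker (999 for
0.01 mm precision, -9999 for 0.001 mm) terminates each series. Climate,
microfossil-count and 137Cs tables are plain CSV.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .sediment import FORAM_TAXA, THECAMOEBIANS, CesiumProfile, MicrofossilProfile, MicrofossilSample

__all__ = [
    "RingWidthSeries",
    "SeriesSet",
    "ClimateTable",
    "RwlParseError",
    "read_rwl",
    "write_rwl",
    "read_climate_csv",
    "write_climate_csv",
    "read_microfossil_csv",
    "write_microfossil_csv",
    "read_cesium_csv",
    "write_cesium_csv",
]

CLIMATE_VARIABLES = ("PDSI", "TAVG", "PRCP")

#: stop markers by recorded precision (mm per integer unit)
_STOP_MARKERS = {0.01: 999, 0.001: -9999}


class RwlParseError(ValueError):
    """Malformed Tucson/RWL content; message names the offending line."""


@dataclass(frozen=True)
class RingWidthSeries:
    """One core's (or tree's) dated annual ring widths in millimetres.

    A ring's year is its formation year (CE); years are strictly consecutive
    from ``first_year``. A width of 0 encodes a locally absent ring and is
    retained as data.
    """

    series_id: str
    first_year: int
    widths: np.ndarray
    tree_id: str = ""
    site_id: str = ""
    units_scale: float = 0.001

    def __post_init__(self):
        w = np.asarray(self.widths, dtype=float)
        if w.ndim != 1 or w.size < 1:
            raise ValueError(f"{self.series_id}: widths must be a non-empty 1-d array")
        if np.any(w < 0) or np.any(~np.isfinite(w)):
            raise ValueError(f"{self.series_id}: widths must be finite and >= 0")
        if self.units_scale not in _STOP_MARKERS:
            raise ValueError(f"{self.series_id}: units_scale must be 0.01 or 0.001")
        object.__setattr__(self, "widths", w)

    @property
    def last_year(self) -> int:
        return self.first_year + len(self.widths) - 1

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.first_year, self.last_year + 1)

    def __len__(self) -> int:
        return len(self.widths)


@dataclass
class SeriesSet:
    """A collection of ring-width series from one site."""

    site_id: str
    series: list[RingWidthSeries] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        ids = [s.series_id for s in self.series]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate series_id values in set: {dupes}")

    def __len__(self) -> int:
        return len(self.series)

    def __iter__(self):
        return iter(self.series)

    def ids(self) -> list[str]:
        return [s.series_id for s in self.series]

    def get(self, series_id: str) -> RingWidthSeries:
        for s in self.series:
            if s.series_id == series_id:
                return s
        raise KeyError(series_id)

    def common_span(self) -> tuple[int, int] | None:
        """Intersection of all series' year ranges, or None if empty."""
        if not self.series:
            return None
        lo = max(s.first_year for s in self.series)
        hi = min(s.last_year for s in self.series)
        return (lo, hi) if lo <= hi else None


@dataclass
class ClimateTable:
    """A year x month grid of one monthly climate variable.

    ``data`` is indexed by calendar year with integer month columns 1..12;
    missing values are NaN. Every represented year carries all 12 slots.
    """

    variable: str
    data: pd.DataFrame
    units: str = ""

    def __post_init__(self):
        if self.variable not in CLIMATE_VARIABLES:
            raise ValueError(f"variable must be one of {CLIMATE_VARIABLES}, got {self.variable!r}")
        df = self.data.copy()
        df.columns = [int(c) for c in df.columns]
        if list(df.columns) != list(range(1, 13)):
            raise ValueError("ClimateTable needs exactly the 12 month columns 1..12")
        df.index = df.index.astype(int)
        df.index.name = "year"
        df = df.sort_index()
        self.data = df.astype(float)

    @property
    def years(self) -> np.ndarray:
        return self.data.index.to_numpy()

    def value(self, year: int, month: int) -> float:
        if year not in self.data.index:
            return float("nan")
        return float(self.data.at[year, month])

    def n_missing(self) -> int:
        return int(self.data.isna().to_numpy().sum())


# ---------------------------------------------------------------------------
# Tucson / RWL decadal format


def read_rwl(path, units_scale: float | None = None) -> SeriesSet:
    """Read a Tucson/RWL decadal file into a :class:`SeriesSet`.

    Precision is inferred per series from its stop marker (999 -> 0.01 mm,
    -9999 -> 0.001 mm) unless ``units_scale`` overrides it. Widths are
    returned in millimetres; zero widths (absent rings) are kept.
    """
    path = Path(path)
    text = path.read_text()
    series: list[RingWidthSeries] = []
    seen: set[str] = set()

    cur_id: str | None = None
    cur_first: int | None = None
    cur_vals: list[int] = []
    expected_year: int | None = None

    def finish(lineno: int):
        """Close the current series: the last value must be a stop marker.

        A value of 999 is only a marker at series end (in a 0.001 mm file it
        is a legitimate 0.999 mm ring mid-series), so the marker -- and with
        it the recorded precision -- is identified when the series ends.
        """
        nonlocal cur_id, cur_first, cur_vals, expected_year
        if cur_id is None:
            return
        if not cur_vals or cur_vals[-1] not in (-9999, 999):
            raise RwlParseError(f"line {lineno}: series {cur_id!r} has no stop marker")
        marker = cur_vals.pop()
        inferred = 0.001 if marker == -9999 else 0.01
        if cur_id in seen:
            raise RwlParseError(f"line {lineno}: duplicate series_id {cur_id!r}")
        seen.add(cur_id)
        scale = units_scale if units_scale is not None else inferred
        widths = np.asarray(cur_vals, dtype=float) * scale
        series.append(
            RingWidthSeries(cur_id, cur_first, widths, tree_id=cur_id, site_id=path.stem, units_scale=scale)
        )
        cur_id, cur_first, cur_vals, expected_year = None, None, [], None

    lineno = 0
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip()
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) < 2:
            raise RwlParseError(f"line {lineno}: expected series id, year and values, got {line!r}")
        sid = parts[0]
        try:
            year = int(parts[1])
            vals = [int(v) for v in parts[2:]]
        except ValueError as exc:
            raise RwlParseError(f"line {lineno}: non-integer field ({exc})") from None
        if sid != cur_id:
            finish(lineno - 1)
            cur_id, cur_first, expected_year = sid, year, year
        elif cur_vals and cur_vals[-1] == -9999:
            raise RwlParseError(f"line {lineno}: data after stop marker in series {sid!r}")
        if year != expected_year:
            raise RwlParseError(
                f"line {lineno}: non-consecutive decade line for {sid!r}: "
                f"expected year {expected_year}, got {year}"
            )
        for v in vals:
            if v < 0 and v != -9999:
                raise RwlParseError(f"line {lineno}: negative ring width {v}")
        if -9999 in vals and vals.index(-9999) != len(vals) - 1:
            raise RwlParseError(f"line {lineno}: data after stop marker")
        room = 10 - (year % 10)
        # the stop marker occupies the year slot after the last ring
        if len(vals) > room + (1 if vals and vals[-1] in (-9999, 999) else 0):
            raise RwlParseError(f"line {lineno}: more values than fit in the decade starting {year}")
        cur_vals.extend(vals)
        expected_year = year + len(vals)

    finish(lineno)
    return SeriesSet(site_id=path.stem, series=series)


def write_rwl(series_set: SeriesSet, path, units_scale: float | None = None) -> None:
    """Write a :class:`SeriesSet` in Tucson/RWL decadal layout.

    Each series is written at its recorded precision unless ``units_scale``
    forces one; 0.001 mm is the package default on newly simulated data.
    Round-trips exactly with :func:`read_rwl` at the recorded precision.
    """
    lines: list[str] = []
    for s in series_set:
        scale = units_scale if units_scale is not None else s.units_scale
        marker = _STOP_MARKERS[scale]
        ints = np.rint(s.widths / scale).astype(int)
        limit = 998 if scale == 0.01 else 99999
        if np.any(ints > limit):
            raise ValueError(
                f"{s.series_id}: width {ints.max() * scale:.3f} mm overflows the "
                f"{scale} mm integer field"
            )
        year = s.first_year
        vals: list[int] = []
        row_year = year
        for v in ints:
            vals.append(int(v))
            year += 1
            if year % 10 == 0:
                lines.append(_format_rwl_line(s.series_id, row_year, vals))
                vals = []
                row_year = year
        # stop marker occupies the slot of the year after the last ring
        vals.append(marker)
        lines.append(_format_rwl_line(s.series_id, row_year, vals))
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def _format_rwl_line(sid: str, year: int, vals: list[int]) -> str:
    if len(sid) > 8:
        raise ValueError(f"series_id {sid!r} longer than the 8-character RWL field")
    return f"{sid:<8}{year:>4}" + "".join(f"{v:>6d}" for v in vals)


# ---------------------------------------------------------------------------
# Climate CSV (wide: year + 12 month columns; long: year,month,value)


def read_climate_csv(path, variable: str, units: str = "") -> ClimateTable:
    """Read a monthly climate table from wide- or long-form CSV."""
    df = pd.read_csv(path, comment="#")
    df.columns = [str(c).strip().lower() for c in df.columns]
    if "month" in df.columns and "value" in df.columns:
        if df.duplicated(subset=["year", "month"]).any():
            dup = df[df.duplicated(subset=["year", "month"])].iloc[0]
            raise ValueError(f"duplicate (year, month) = ({int(dup['year'])}, {int(dup['month'])})")
        months = df["month"].astype(int)
        if (months < 1).any() or (months > 12).any():
            raise ValueError("month outside 1..12")
        grid = df.pivot(index="year", columns="month", values="value")
        grid = grid.reindex(columns=range(1, 13))
    else:
        if "year" not in df.columns:
            raise ValueError("climate CSV needs a 'year' column")
        month_cols = [c for c in df.columns if c != "year"]
        if len(month_cols) != 12:
            raise ValueError(f"wide-form climate CSV needs 12 month columns, found {len(month_cols)}")
        if df["year"].duplicated().any():
            raise ValueError(f"duplicate year {int(df['year'][df['year'].duplicated()].iloc[0])}")
        grid = df.set_index("year")[month_cols]
        grid.columns = range(1, 13)
    return ClimateTable(variable=variable, data=grid, units=units)


def write_climate_csv(table: ClimateTable, path) -> None:
    out = table.data.copy()
    out.columns = [f"m{m:02d}" for m in range(1, 13)]
    out.index.name = "year"
    out.to_csv(path)


# ---------------------------------------------------------------------------
# Microfossil count and 137Cs activity CSV

_MICRO_META = ("sample_id", "core_id", "depth_cm", "salinity_ppt", "volume_cm3")


def read_microfossil_csv(path) -> list[MicrofossilSample]:
    """Read a sample x taxon count table; non-metadata columns are taxa."""
    df = pd.read_csv(path, comment="#")
    samples = []
    taxa = [c for c in df.columns if c not in _MICRO_META]
    for _, row in df.iterrows():
        counts = {t: int(row[t]) for t in taxa if pd.notna(row[t])}
        depth = row.get("depth_cm")
        samples.append(
            MicrofossilSample(
                sample_id=str(row["sample_id"]),
                core_id=str(row.get("core_id", "")),
                counts=counts,
                depth_cm=None if pd.isna(depth) else float(depth),
                salinity_ppt=None if pd.isna(row.get("salinity_ppt")) else float(row["salinity_ppt"]),
                volume_cm3=float(row.get("volume_cm3", 2.0) if pd.notna(row.get("volume_cm3")) else 2.0),
            )
        )
    return samples


def write_microfossil_csv(samples: list[MicrofossilSample], path) -> None:
    taxa = list(FORAM_TAXA) + [THECAMOEBIANS]
    extra = sorted({t for s in samples for t in s.counts} - set(taxa))
    rows = []
    for s in samples:
        row = {
            "sample_id": s.sample_id,
            "core_id": s.core_id,
            "depth_cm": s.depth_cm,
            "salinity_ppt": s.salinity_ppt,
            "volume_cm3": s.volume_cm3,
        }
        for t in taxa + extra:
            row[t] = s.counts.get(t, 0)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_cesium_csv(path, core_id: str = "", detection_limit: float = 0.0) -> CesiumProfile:
    df = pd.read_csv(path, comment="#")
    df.columns = [str(c).strip().lower() for c in df.columns]
    return CesiumProfile(
        core_id=core_id or Path(path).stem,
        depth_cm=df["depth_cm"].to_numpy(dtype=float),
        activity=df["activity"].to_numpy(dtype=float),
        detection_limit=detection_limit,
    )


def write_cesium_csv(profile: CesiumProfile, path) -> None:
    pd.DataFrame({"depth_cm": profile.depth_cm, "activity": profile.activity}).to_csv(path, index=False)
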