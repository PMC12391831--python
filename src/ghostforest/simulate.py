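"""Seeded generators for every input the analysis consumes.

The generators emulate the statistical structure the pipeline assumes, with
the ground truth recorded so recovery can be tested end to end:

- monthly climate as seasonal means plus an AR(1) anomaly (drought index
  centered at zero, so negative drought years occur);
- tree growth as a negative-exponential age trend modulated by a lognormal
  combination of a summer-drought term, a site-level common signal, and
  tree-level noise, with optional implanted multi-year suppression events
  (a growth multiplier applied to a fraction of the trees);
- downcore microfossil counts as Poisson draws whose foraminiferal
  intensity follows a logistic ramp across a salinity-onset depth (or
  station), partitioned over the five marsh taxa by a mixing vector that
  shifts toward the high-salinity specialist at the saline end, with the
  thecamoebian intensity ramping oppositely;
- a 137Cs profile as background plus a Gaussian activity peak plus noise.

All draws flow from ``numpy.random.default_rng(seed)``; identical seed and
parameters give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io import ClimateTable, RingWidthSeries, SeriesSet
from .sediment import (
    FORAM_TAXA,
    THECAMOEBIANS,
    CesiumProfile,
    MicrofossilProfile,
    MicrofossilSample,
)

__all__ = [
    "MonthlyClimateParams",
    "GrowthParams",
    "ImplantedEvent",
    "SedimentTruth",
    "SimulationTruth",
    "default_climate_params",
    "simulate_climate",
    "simulate_site",
    "simulate_microfossil_profile",
    "simulate_surface_stations",
    "simulate_cesium",
]


@dataclass(frozen=True)
class MonthlyClimateParams:
    """Seasonal means plus AR(1) anomaly parameters for one monthly variable."""

    variable: str
    seasonal_means: tuple[float, ...]
    phi: float = 0.7
    innovation_sd: float = 1.0
    units: str = ""

    def __post_init__(self):
        if len(self.seasonal_means) != 12:
            raise ValueError("seasonal_means needs 12 entries")
        if abs(self.phi) >= 1:
            raise ValueError(f"AR(1) coefficient must satisfy |phi| < 1, got {self.phi}")


def default_climate_params() -> dict[str, MonthlyClimateParams]:
    """Parameters emulating monthly divisional climate for a humid subtropical coast.

    The drought index is centered at 0 (anomalies only, sd ~1.4 monthly);
    temperature follows a 8-27 degC seasonal cycle; precipitation a wetter
    summer. Anomaly persistence phi = 0.7 gives the multi-month memory a
    drought index exhibits.
    """
    tavg = (7.8, 9.4, 13.1, 17.4, 21.9, 25.8, 27.4, 26.9, 24.4, 18.9, 13.6, 9.5)
    prcp = (98, 88, 102, 77, 97, 132, 180, 177, 153, 89, 76, 91)
    return {
        "PDSI": MonthlyClimateParams("PDSI", (0.0,) * 12, phi=0.7, innovation_sd=1.0, units="index"),
        "TAVG": MonthlyClimateParams("TAVG", tavg, phi=0.5, innovation_sd=0.9, units="degC"),
        "PRCP": MonthlyClimateParams("PRCP", prcp, phi=0.2, innovation_sd=35.0, units="mm"),
    }


def simulate_climate(
    years: tuple[int, int],
    params: dict[str, MonthlyClimateParams] | None = None,
    seed: int = 0,
) -> dict[str, ClimateTable]:
    """Simulate monthly climate tables for the inclusive year range ``years``."""
    lo, hi = int(years[0]), int(years[1])
    n_years = hi - lo + 1
    if n_years < 30:
        raise ValueError(f"need >= 30 years of climate, got {n_years}")
    params = params or default_climate_params()
    rng = np.random.default_rng(seed)
    out = {}
    for var, p in params.items():
        n = n_years * 12
        innov = rng.normal(0.0, p.innovation_sd, n)
        anom = np.empty(n)
        # burn-in from the stationary distribution
        prev = rng.normal(0.0, p.innovation_sd / np.sqrt(1 - p.phi**2))
        for i in range(n):
            prev = p.phi * prev + innov[i]
            anom[i] = prev
        grid = anom.reshape(n_years, 12) + np.asarray(p.seasonal_means)
        if var == "PRCP":
            grid = np.clip(grid, 0.0, None)
        df = pd.DataFrame(grid, index=np.arange(lo, hi + 1), columns=range(1, 13))
        out[var] = ClimateTable(variable=var, data=df, units=p.units)
    return out


@dataclass(frozen=True)
class GrowthParams:
    """Stochastic growth-model parameters (log scale unless noted).

    The age trend a*exp(-b*age)+k is in mm; ``beta`` multiplies the mean
    summer (JJA) drought index; ``common_sd`` is the sd of the site-level
    shared noise and ``tree_sd`` of the tree-level noise, both lognormal.
    """

    a: float = 2.0
    b: float = 0.02
    k: float = 0.5
    beta: float = 0.09
    common_sd: float = 0.06
    tree_sd: float = 0.12
    summer_months: tuple[int, ...] = (6, 7, 8)


@dataclass(frozen=True)
class ImplantedEvent:
    """A multi-year growth-suppression event implanted at a site."""

    start_year: int
    end_year: int
    multiplier: float = 0.2
    fraction: float = 0.8

    def __post_init__(self):
        if self.multiplier <= 0:
            raise ValueError("event multiplier must be > 0")
        if not 0 < self.fraction <= 1:
            raise ValueError("affected fraction must be in (0, 1]")
        if self.end_year < self.start_year:
            raise ValueError("end_year before start_year")


@dataclass(frozen=True)
class SedimentTruth:
    onset_depth: float | None = 30.0
    peak_depth: float = 25.0
    collection_year: int = 2022


@dataclass
class SimulationTruth:
    """Everything needed to reproduce a simulated study, with its ground truth."""

    seed: int = 0
    climate_params: dict[str, MonthlyClimateParams] = field(default_factory=default_climate_params)
    growth_params: GrowthParams = field(default_factory=GrowthParams)
    events: list[ImplantedEvent] = field(default_factory=list)
    sediment: SedimentTruth = field(default_factory=SedimentTruth)

    def to_dict(self) -> dict:
        return asdict(self)


def _summer_pdsi(pdsi: ClimateTable, years: np.ndarray, months: tuple[int, ...]) -> np.ndarray:
    sub = pdsi.data.reindex(years)[list(months)]
    return sub.mean(axis=1).to_numpy()


def simulate_site(
    n_trees: int,
    years: tuple[int, int],
    pdsi: ClimateTable | None = None,
    growth: GrowthParams | None = None,
    events: list[ImplantedEvent] | None = None,
    seed: int = 0,
    site_id: str = "SIM",
    median_length: int | None = None,
    cores_per_tree: int = 1,
) -> tuple[SeriesSet, dict]:
    """Simulate a site's ring-width series with recorded per-tree truth.

    Per tree i and year t:
    width = (a*exp(-b*age) + k) * exp(beta*Psummer(t) + C(t) + eps_i(t)) * m_i(t)
    with C site-level noise, eps tree-level noise, and m_i the event
    multiplier when tree i is in the affected fraction. Tree start years are
    staggered so the median series length approaches ``median_length``
    (default: the full span). With ``cores_per_tree`` = 2 each tree yields
    two series sharing the tree signal plus small core-level noise.
    """
    if n_trees < 2:
        raise ValueError("need at least 2 trees")
    lo, hi = int(years[0]), int(years[1])
    span = hi - lo + 1
    growth = growth or GrowthParams()
    events = events or []
    rng = np.random.default_rng(seed)
    yr = np.arange(lo, hi + 1)

    if growth.beta != 0.0:
        if pdsi is None:
            raise ValueError("beta != 0 requires a drought-index ClimateTable")
        psummer = _summer_pdsi(pdsi, yr, growth.summer_months)
        if np.any(np.isnan(psummer)):
            raise ValueError("drought index does not cover the simulated years")
    else:
        psummer = np.zeros(span)

    common = rng.normal(0.0, growth.common_sd, span) if growth.common_sd > 0 else np.zeros(span)

    # stagger start years around a target median length
    if median_length is None or median_length >= span:
        lengths = np.full(n_trees, span)
    else:
        spread = max(4, median_length // 5)
        lengths = np.clip(
            np.rint(rng.normal(median_length, spread, n_trees)).astype(int), 30, span
        )
    start_years = hi - lengths + 1

    affected: dict[int, list[int]] = {}
    for e_idx, ev in enumerate(events):
        n_aff = int(round(ev.fraction * n_trees))
        chosen = rng.choice(n_trees, size=n_aff, replace=False)
        affected[e_idx] = sorted(int(c) for c in chosen)

    series: list[RingWidthSeries] = []
    truth_trees = []
    for i in range(n_trees):
        sy = int(start_years[i])
        m = hi - sy + 1
        age = np.arange(m, dtype=float)
        curve = growth.a * np.exp(-growth.b * age) + growth.k
        eps = rng.normal(0.0, growth.tree_sd, m) if growth.tree_sd > 0 else np.zeros(m)
        mult = np.ones(m)
        my_events = []
        for e_idx, ev in enumerate(events):
            if i in affected[e_idx]:
                s = max(ev.start_year, sy) - sy
                e = min(ev.end_year, hi) - sy
                if e >= s:
                    mult[s : e + 1] *= ev.multiplier
                    my_events.append(e_idx)
        sl = slice(sy - lo, hi - lo + 1)
        logmod = growth.beta * psummer[sl] + common[sl] + eps
        tree_width = curve * np.exp(logmod) * mult
        tree_id = f"{site_id}{i + 1:03d}"
        if cores_per_tree == 1:
            series.append(
                RingWidthSeries(tree_id, sy, tree_width, tree_id=tree_id, site_id=site_id)
            )
        else:
            for c in range(cores_per_tree):
                core_noise = np.exp(rng.normal(0.0, 0.05, m))
                series.append(
                    RingWidthSeries(
                        f"{tree_id}{chr(ord('a') + c)}", sy, tree_width * core_noise,
                        tree_id=tree_id, site_id=site_id,
                    )
                )
        truth_trees.append(
            {"tree_id": tree_id, "start_year": sy, "events": my_events}
        )
    truth = {
        "seed": seed,
        "site_id": site_id,
        "years": [lo, hi],
        "growth": asdict(growth),
        "events": [asdict(e) for e in events],
        "affected": {str(k): v for k, v in affected.items()},
        "trees": truth_trees,
    }
    return SeriesSet(site_id=site_id, series=series), truth


def _logistic_ramp(x: np.ndarray, onset: float | None, scale: float, increasing_with_x: bool) -> np.ndarray:
    if onset is None:
        return np.zeros_like(x, dtype=float)
    z = (x - onset) / scale
    return 1.0 / (1.0 + np.exp(z if not increasing_with_x else -z))


_LOW_SALINITY_MIX = {"M. fusca": 0.10, "A. crassus": 0.20, "A. inepta": 0.25,
                     "T. inflata": 0.15, "H. manilaensis": 0.30}
_HIGH_SALINITY_MIX = {"M. fusca": 0.45, "A. crassus": 0.20, "A. inepta": 0.10,
                      "T. inflata": 0.15, "H. manilaensis": 0.10}


def _draw_sample(rng, sample_id, core_id, depth, foram_intensity, theca_intensity, plateau):
    h = 0.0 if plateau == 0 else min(foram_intensity / plateau, 1.0)
    counts = {}
    for taxon in FORAM_TAXA:
        mix = (1 - h) * _LOW_SALINITY_MIX[taxon] + h * _HIGH_SALINITY_MIX[taxon]
        counts[taxon] = int(rng.poisson(foram_intensity * mix))
    counts[THECAMOEBIANS] = int(rng.poisson(theca_intensity))
    return MicrofossilSample(sample_id=sample_id, core_id=core_id, counts=counts, depth_cm=depth)


def simulate_microfossil_profile(
    depths: np.ndarray | None = None,
    onset: float | None = 30.0,
    plateau: float = 60.0,
    scale: float = 2.0,
    theca_max: float = 40.0,
    seed: int = 0,
    core_id: str = "SIMCORE",
) -> MicrofossilProfile:
    """Simulate a downcore microfossil profile with a salinity-onset depth.

    Foraminiferal intensity ramps logistically from ~0 below ``onset`` to
    ``plateau`` at the surface (``onset=None`` leaves the core barren of
    foraminifera); the thecamoebian intensity ramps oppositely. Counts are
    Poisson draws, partitioned across the five taxa by a salinity-dependent
    mixing vector.
    """
    if depths is None:
        depths = np.arange(0.0, 101.0, 5.0)
    depths = np.asarray(depths, dtype=float)
    if plateau < 0 or theca_max < 0:
        raise ValueError("intensities must be non-negative")
    rng = np.random.default_rng(seed)
    samples = []
    for d in depths:
        ramp = _logistic_ramp(np.array([d]), onset, scale, increasing_with_x=False)[0]
        samples.append(
            _draw_sample(
                rng, f"{core_id}-{int(d):03d}", core_id, float(d),
                plateau * ramp, theca_max * (1.0 - ramp), plateau,
            )
        )
    return MicrofossilProfile(core_id=core_id, samples=samples)


def simulate_surface_stations(
    n_stations: int = 12,
    onset_station: float | None = 8.0,
    plateau: float = 55.0,
    scale: float = 0.7,
    theca_max: float = 15.0,
    seed: int = 0,
) -> list[MicrofossilSample]:
    """Simulate surface samples along a creek's salinity gradient.

    Stations number upstream (1, fresh) to downstream (n, saline);
    foraminiferal intensity ramps up across ``onset_station``.
    """
    rng = np.random.default_rng(seed)
    samples = []
    for st in range(1, n_stations + 1):
        ramp = _logistic_ramp(np.array([float(st)]), onset_station, scale, increasing_with_x=True)[0]
        s = _draw_sample(
            rng, f"ST{st:02d}", "", None, plateau * ramp, theca_max * (1.0 - ramp), plateau
        )
        samples.append(s)
    return samples


def simulate_cesium(
    depths: np.ndarray | None = None,
    peak_depth: float = 25.0,
    peak_activity: float = 10.0,
    width: float = 4.0,
    background: float = 0.5,
    noise_frac: float = 0.10,
    seed: int = 0,
    core_id: str = "SIMCS",
    detection_limit: float | None = None,
) -> CesiumProfile:
    """Simulate a 137Cs activity profile with a single subsurface peak.

    activity = background + peak_activity*exp(-(d-peak)^2/(2 width^2)) +
    Gaussian noise (sd = ``noise_frac`` x peak_activity), floored at 0.
    """
    if depths is None:
        depths = np.arange(0.0, 101.0)
    depths = np.asarray(depths, dtype=float)
    if width <= 0:
        raise ValueError("peak width must be > 0")
    if not depths.min() <= peak_depth <= depths.max():
        raise ValueError("peak_depth outside the sampled depth range")
    rng = np.random.default_rng(seed)
    signal = background + peak_activity * np.exp(-((depths - peak_depth) ** 2) / (2 * width**2))
    noise = rng.normal(0.0, noise_frac * peak_activity, depths.size) if peak_activity > 0 else 0.0
    activity = np.clip(signal + noise, 0.0, None)
    return CesiumProfile(
        core_id=core_id,
        depth_cm=depths,
        activity=activity,
        detection_limit=background if detection_limit is None else detection_limit,
    )
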