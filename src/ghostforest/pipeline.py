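"""End-to-end orchestration of the analysis from a single YAML configuration.

Stages: per-site chronology (detrending + quality statistics), monthly
climate-growth correlations (full period and split), running-mean
suppression chronology, host/non-host suppression events, and the sediment
stage (microfossil classification, onset depth, 137Cs peak, age-depth
model). Each stage writes CSV/JSON outputs stamped with the run's seed and
a configuration hash so any file can be traced to the exact run that
produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as gfio
from .chronology import Chronology, build_chronology, detrend, fit_detrend
from .climate import LagWindow, monthly_correlations, split_period
from .sediment import (
    age_depth,
    classify_salinity,
    cs137_peak,
    first_occurrence_depth,
    onset_depth,
)
from .suppression import correct_host, detect_site_events, merge_cores, site_suppression

__all__ = ["PipelineConfig", "PipelineError", "validate_config", "run_pipeline"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""

    def __init__(self, stage: str, cause: Exception | str):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass
class PipelineConfig:
    """All inputs and parameters of one pipeline run.

    Parameter defaults follow the study design: truncation at 1850, climate
    period 1895-2022 split at 1960, the 25%-of-20-year-running-mean
    suppression rule with the 75% widespread threshold, a minimum of 20
    foraminiferal individuals for an interpretable assemblage, and the 1963
    fallout peak as the dated sediment horizon.
    """

    # inputs
    rwl_paths: dict[str, str] = field(default_factory=dict)  # site_id -> RWL path
    host_site: str | None = None
    nonhost_site: str | None = None
    climate_paths: dict[str, str] = field(default_factory=dict)  # variable -> CSV
    microfossil_paths: dict[str, str] = field(default_factory=dict)  # core_id -> CSV
    cesium_path: str | None = None
    # parameters
    truncate_start: int = 1850
    climate_period: tuple[int, int] = (1895, 2022)
    split_year: int = 1960
    chronology_method: str = "biweight"
    significance_method: str = "t_test"
    suppression_window: int = 20
    threshold_frac: float = 0.25
    widespread_threshold: float = 0.75
    min_depth: int = 5
    onset_threshold: float = -1.28
    min_duration: int = 4
    bridge_gap: int = 1
    min_proportion: float = 0.25
    min_trees: int = 3
    min_forams: int = 20
    peak_year: int = 1963
    collection_year: int = 2022
    # run control
    seed: int = 0
    output_dir: str = "ghostforest_out"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "climate_period" in raw:
            raw["climate_period"] = tuple(raw["climate_period"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.as_dict(), sort_keys=True))

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["climate_period"] = list(self.climate_period)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.as_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def validate_config(config: PipelineConfig) -> list[str]:
    """Return a list of problems (empty iff the config is runnable)."""
    problems: list[str] = []
    for site, p in config.rwl_paths.items():
        if not Path(p).exists():
            problems.append(f"rwl_paths[{site}]: file not found: {p}")
    for var, p in config.climate_paths.items():
        if var not in gfio.CLIMATE_VARIABLES:
            problems.append(f"climate_paths: unknown variable {var!r}")
        if not Path(p).exists():
            problems.append(f"climate_paths[{var}]: file not found: {p}")
    for core, p in config.microfossil_paths.items():
        if not Path(p).exists():
            problems.append(f"microfossil_paths[{core}]: file not found: {p}")
    if config.cesium_path and not Path(config.cesium_path).exists():
        problems.append(f"cesium_path: file not found: {config.cesium_path}")
    if config.host_site and config.host_site not in config.rwl_paths:
        problems.append(f"host_site {config.host_site!r} not among rwl_paths")
    if config.nonhost_site and config.nonhost_site not in config.rwl_paths:
        problems.append(f"nonhost_site {config.nonhost_site!r} not among rwl_paths")
    lo, hi = config.climate_period
    if lo >= hi:
        problems.append("climate_period: start must precede end")
    if not (lo < config.split_year < hi):
        problems.append(f"split_year {config.split_year} outside climate_period {lo}-{hi}")
    if not 0 < config.threshold_frac < 1:
        problems.append(f"threshold_frac must be in (0,1), got {config.threshold_frac}")
    if not 0 < config.widespread_threshold <= 1:
        problems.append(f"widespread_threshold must be in (0,1], got {config.widespread_threshold}")
    if config.suppression_window < 2:
        problems.append("suppression_window must be >= 2")
    if not 0 < config.min_proportion <= 1:
        problems.append(f"min_proportion must be in (0,1], got {config.min_proportion}")
    if config.onset_threshold >= 0:
        problems.append("onset_threshold must be negative")
    if config.min_duration < 1:
        problems.append("min_duration must be >= 1")
    if config.min_forams < 1:
        problems.append("min_forams must be >= 1")
    if config.collection_year <= config.peak_year:
        problems.append("collection_year must postdate peak_year")
    if config.chronology_method not in ("mean", "biweight"):
        problems.append(f"chronology_method must be 'mean' or 'biweight', got {config.chronology_method!r}")
    if config.significance_method not in ("t_test", "stationary_bootstrap"):
        problems.append(f"significance_method must be 't_test' or 'stationary_bootstrap'")
    return problems


def _stamp(config: PipelineConfig) -> str:
    return f"# seed={config.seed} config_sha={config.config_hash()}\n"


def _write_csv(df, path: Path, config: PipelineConfig, index=False) -> None:
    with open(path, "w") as fh:
        fh.write(_stamp(config))
        df.to_csv(fh, index=index)


def _write_json(obj: dict, path: Path, config: PipelineConfig) -> None:
    obj = {"seed": config.seed, "config_sha": config.config_hash(), **obj}
    path.write_text(json.dumps(obj, indent=2, default=_jsonable) + "\n")


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def _site_chronology(config: PipelineConfig, site: str) -> tuple[Chronology, dict]:
    sset = gfio.read_rwl(config.rwl_paths[site])
    trees = merge_cores(sset)
    indices = []
    for s in sset:
        try:
            indices.append(detrend(s, fit_detrend(s)))
        except ValueError as exc:
            warnings.warn(f"{site}: skipping series {s.series_id}: {exc}", stacklevel=2)
    chron = build_chronology(
        indices,
        site_id=site,
        method=config.chronology_method,
        truncate_start=config.truncate_start,
        raw_series=list(sset.series),
    )
    extras = {"series_set": sset, "trees": trees, "indices": indices}
    return chron, extras


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every configured stage; returns a report dict (also written to disk)."""
    problems = validate_config(config)
    if problems:
        raise PipelineError("validate", "; ".join(problems))
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"sites": {}, "stages": []}

    # --- chronologies -------------------------------------------------------
    chrons: dict[str, Chronology] = {}
    site_extras: dict[str, dict] = {}
    for site in config.rwl_paths:
        try:
            chron, extras = _site_chronology(config, site)
        except Exception as exc:
            raise PipelineError(f"chronology[{site}]", exc) from exc
        chrons[site] = chron
        site_extras[site] = extras
        df = pd.DataFrame({"year": chron.years, "value": chron.values, "depth": chron.depth})
        _write_csv(df, out / f"chronology_{site}.csv", config)
        _write_json({"site": site, "stats": chron.stats}, out / f"chronology_stats_{site}.json", config)
        report["sites"][site] = {"stats": chron.stats, "n_years": len(chron.years)}
    if chrons:
        report["stages"].append("chronology")

    # --- climate correlations ----------------------------------------------
    climates = {}
    for var, path in config.climate_paths.items():
        climates[var] = gfio.read_climate_csv(path, var)
    if climates and chrons:
        window = LagWindow()
        lo, hi = config.climate_period
        for site, chron in chrons.items():
            for var, table in climates.items():
                try:
                    full = monthly_correlations(
                        chron, table, window, (lo, hi), method=config.significance_method,
                        seed=config.seed,
                    )
                    early, late = split_period(
                        chron, table, window, (lo, config.split_year, hi),
                        method=config.significance_method, seed=config.seed,
                    )
                except Exception as exc:
                    raise PipelineError(f"climate[{site},{var}]", exc) from exc
                frames = [full.to_frame(), early.to_frame(), late.to_frame()]
                _write_csv(pd.concat(frames), out / f"correlations_{site}_{var}.csv", config)
        report["stages"].append("climate")

    # --- running-mean suppression ------------------------------------------
    for site in config.rwl_paths:
        try:
            flags = site_suppression(
                site_extras[site]["series_set"],
                window=config.suppression_window,
                threshold_frac=config.threshold_frac,
                widespread_threshold=config.widespread_threshold,
                min_depth=config.min_depth,
            )
        except Exception as exc:
            raise PipelineError(f"suppression[{site}]", exc) from exc
        _write_csv(flags.to_frame(), out / f"suppression_flags_{site}.csv", config, index=True)
        pct = pd.DataFrame({"year": flags.years, "percent": flags.percent, "depth": flags.depth})
        _write_csv(pct, out / f"suppression_percent_{site}.csv", config)
        _write_json(
            {"site": site, "widespread_years": flags.widespread_years},
            out / f"widespread_years_{site}.json", config,
        )
        report["sites"][site]["widespread_years"] = flags.widespread_years
    if config.rwl_paths:
        report["stages"].append("suppression")

    # --- host/non-host events ----------------------------------------------
    if config.host_site and config.nonhost_site and config.nonhost_site in chrons:
        try:
            nonhost_chron = chrons[config.nonhost_site]
            host_trees = site_extras[config.host_site]["trees"]
            gsis = []
            for tree in host_trees:
                try:
                    idx = detrend(tree, fit_detrend(tree))
                    gsis.append(correct_host(idx, nonhost_chron))
                except ValueError as exc:
                    warnings.warn(f"events: skipping tree {tree.tree_id}: {exc}", stacklevel=2)
            periods, events = detect_site_events(
                gsis,
                onset_threshold=config.onset_threshold,
                min_duration=config.min_duration,
                bridge_gap=config.bridge_gap,
                min_proportion=config.min_proportion,
                min_trees=config.min_trees,
            )
        except Exception as exc:
            raise PipelineError("events", exc) from exc
        ev_rows = [
            {
                "start_year": e.start_year,
                "end_year": e.end_year,
                "n_trees": len(e.trees_involved),
                "max_proportion": e.max_proportion,
                "n_minor": sum(1 for s in e.severities.values() if s == "minor"),
                "n_moderate": sum(1 for s in e.severities.values() if s == "moderate"),
                "n_severe": sum(1 for s in e.severities.values() if s == "severe"),
            }
            for e in events
        ]
        _write_csv(pd.DataFrame(ev_rows), out / "suppression_events.csv", config)
        per_rows = [
            {"tree_id": p.tree_id, "start_year": p.start_year, "end_year": p.end_year,
             "min_ngsi": p.min_ngsi, "severity": p.severity}
            for p in periods
        ]
        _write_csv(pd.DataFrame(per_rows), out / "tree_suppression_periods.csv", config)
        report["events"] = ev_rows
        report["stages"].append("events")
    elif config.host_site or config.nonhost_site:
        warnings.warn("event stage skipped: both host_site and nonhost_site are required", stacklevel=2)

    # --- sediment proxies ---------------------------------------------------
    sediment_report: dict = {}
    if config.microfossil_paths:
        from .sediment import MicrofossilProfile

        for core, path in config.microfossil_paths.items():
            try:
                samples = gfio.read_microfossil_csv(path)
                rows = []
                for s in samples:
                    rows.append(
                        {
                            "sample_id": s.sample_id,
                            "depth_cm": s.depth_cm,
                            "foram_total": s.foram_total,
                            "thecamoebians": s.thecamoebian_total,
                            "class": classify_salinity(s, config.min_forams),
                        }
                    )
                _write_csv(pd.DataFrame(rows), out / f"classification_{core}.csv", config)
                downcore = [s for s in samples if s.depth_cm is not None]
                core_info: dict = {}
                if len(downcore) >= 2:
                    profile = MicrofossilProfile(core_id=core, samples=downcore)
                    core_info["onset_depth_cm"] = onset_depth(profile, config.min_forams)
                    core_info["first_occurrence_depth_cm"] = first_occurrence_depth(profile)
                sediment_report[core] = core_info
            except Exception as exc:
                raise PipelineError(f"sediment[{core}]", exc) from exc
    if config.cesium_path:
        try:
            profile = gfio.read_cesium_csv(config.cesium_path)
            peak = cs137_peak(profile)
            model = age_depth(peak.depth_cm, config.collection_year, config.peak_year)
            horizons = {}
            for core, info in sediment_report.items():
                for key in ("onset_depth_cm", "first_occurrence_depth_cm"):
                    d = info.get(key)
                    if d is not None:
                        info[key.replace("_cm", "_year")] = float(model.year(d))
            sediment_report["cesium"] = {
                "peak_depth_cm": peak.depth_cm,
                "peak_at_edge": peak.at_edge,
                "rate_cm_per_yr": model.rate_cm_per_yr,
                "collection_year": config.collection_year,
                "peak_year": config.peak_year,
            }
        except Exception as exc:
            raise PipelineError("cesium", exc) from exc
    if sediment_report:
        _write_json(sediment_report, out / "sediment_report.json", config)
        report["sediment"] = sediment_report
        report["stages"].append("sediment")

    # --- run log ------------------------------------------------------------
    from . import __version__

    _write_json(
        {"version": __version__, "config": config.as_dict(), "stages": report["stages"]},
        out / "run_log.json", config,
    )
    return report
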