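# ghostforest

Tree-ring and sediment-proxy analysis of coastal **ghost-forest formation** —
the conversion of forested freshwater tidal wetlands into stands of dead
trees (snags) under saltwater intrusion.

The package is written for dendroecologists and coastal paleoenvironmental
researchers who want to combine two independent lines of evidence at a pair
of sites along a salinity gradient:

1. **Tree rings.** Annual ring-width series are standardized, averaged into
   site chronologies with the usual quality statistics, correlated month by
   month with climate, and screened for growth suppression with two
   procedures (a per-tree running-mean rule and host/non-host corrected-index
   event detection).
2. **Sediment cores.** Salt-tolerant agglutinated foraminifera versus
   freshwater thecamoebians track the salinization history downcore, and the
   1963 ¹³⁷Cs fallout maximum anchors a linear age–depth model that dates the
   salinity onset.

A fully seeded synthetic-data generator produces ring-width files (Tucson/RWL
format), monthly climate tables, microfossil count tables, and ¹³⁷Cs profiles
with recorded ground truth, so the entire pipeline is testable end to end
without field data.

## The statistics at the core

**Standardization.** Each series is ratio-detrended against a fitted
negative-exponential age trend, `w(t) = a·e^(−b·t) + k` over cambial age `t`
(falling back to a non-positive-slope line, then to the horizontal mean);
the ring-width index is `RWI = width / fitted`.

**Chronology quality.** With `n` series and mean pairwise correlation `r̄`
over a common window:

    EPS = n·r̄ / (1 + (n−1)·r̄)        SNR = n·r̄ / (1 − r̄)

linked by the identity `EPS = SNR/(1+SNR)`. Mean sensitivity is
`MS = mean |2(x_{t+1} − x_t)/(x_{t+1} + x_t)|`, and the interseries
correlation is each series' Pearson `r` against the mean of all others.

**Climate response.** Pearson correlations between the chronology and each
month of an 18-month lag window (previous May … current October), with
significance from the exact two-sided t-test or a stationary bootstrap.

**Suppression.** (a) A year is *suppressed* for a tree when its raw width is
below 25% of the tree's centered 20-year running mean; a site year with
suppression in strictly more than 75% of trees has *widespread suppression*.
(b) Host/non-host correction removes the shared climate signal from each
stressed-site tree:

    gsi[y] = h[y] − (σ_h/σ_c)·(c[y] − mean(c))

where `h` is the host tree's index and `c` the reference-site chronology;
the normalized residual (`ngsi`, mean 0 / sd 1) flags suppression periods
(runs below −1.28 lasting ≥ 4 years, single-year gaps bridged), classed
minor/moderate/severe at −2/−3.

**Sediment.** A sample with ≥ 20 foraminiferal individuals carries an
interpretable saline assemblage; the onset depth is the base of the
continuously saline upper core. The ¹³⁷Cs activity maximum (lightly smoothed,
shallow tie-break) dates to 1963, giving a constant sedimentation rate
`peak_depth / (collection_year − 1963)`.

## Worked example

```python
import ghostforest as gf

tables = gf.simulate_climate((1849, 2022), seed=1)
events = [gf.ImplantedEvent(1971, 1983, multiplier=0.2, fraction=0.8)]
high, _ = gf.simulate_site(12, (1850, 2022), pdsi=tables["PDSI"],
                           events=events, seed=2, site_id="HS")
low, _ = gf.simulate_site(12, (1850, 2022), pdsi=tables["PDSI"],
                          seed=3, site_id="LS")

nonhost = gf.build_chronology([gf.detrend(s) for s in low],
                              site_id="LS", truncate_start=1850)
print({k: round(v, 3) for k, v in nonhost.stats.items() if isinstance(v, float)})

gsis = [gf.correct_host(gf.detrend(t), nonhost) for t in gf.merge_cores(high)]
periods, evts = gf.detect_site_events(gsis)
for e in evts:
    print(f"suppression event {e.start_year}-{e.end_year}: "
          f"{len(e.trees_involved)} trees, peak proportion {e.max_proportion:.2f}")
```

prints

```
{'interseries_r': 0.71, 'rbar': 0.542, 'eps': 0.934, 'snr': 14.18, 'mean_sensitivity': 0.196}
suppression event 1971-1982: 10 trees, peak proportion 0.83
```

The reference-site chronology has a strong common signal (EPS 0.934 — above
the conventional 0.85 usability threshold, and equal to SNR/(1+SNR) exactly),
and the event detector recovers the implanted 1971–1983 suppression event to
within one year, involving 10 of the 12 trees (80% were implanted). On the
sediment side:

```python
peak = gf.cs137_peak(gf.simulate_cesium(peak_depth=25.0, seed=4))
model = gf.age_depth(peak.depth_cm, collection_year=2022)
print(f"137Cs peak at {peak.depth_cm:.0f} cm -> {model.rate_cm_per_yr:.3f} cm/yr; "
      f"30 cm dates to {model.year(30.0):.0f}")
```

```
137Cs peak at 25 cm -> 0.424 cm/yr; 30 cm dates to 1951
```

i.e. a 25-cm 1963 horizon implies ~0.42 cm/yr of accretion, dating a 30-cm
microfossil onset to the early 1950s (an extrapolation below the dated
anchor, and flagged as such by the model).

## Command line

```sh
ghostforest simulate --seed 1 --out study/     # synthetic two-site study + config.yaml
ghostforest run --config study/config.yaml     # full pipeline -> CSV/JSON outputs
ghostforest validate --config study/config.yaml
```

Every output file is stamped with the seed and a configuration hash.

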