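# Methods

This note documents the models, conventions and design choices behind the
package, in the order the pipeline applies them.

## Ring-width standardization

Raw ring widths carry a geometric/ontogenetic trend: as a tree ages and its
circumference grows, the same wood volume spreads over a larger ring, so
widths decline roughly exponentially toward an asymptote. Each series is
therefore fit with

    w(t) = a·e^(−b·t) + k,    t = 0, 1, … cambial-age index

by unconstrained nonlinear least squares (`scipy.optimize.curve_fit`,
initialized from the head/tail means, three fallback starting values for the
decay rate). The fit is accepted only when `a > 0`, `b > 0`, `k ≥ 0` and
every fitted value is positive; otherwise the fit falls back to a straight
line, accepted only with non-positive slope and positive fitted values, and
finally to the horizontal mean. This is the classic conservative detrending
chain: the fallbacks can only flatten, never amplify, low-frequency
variance. The ring-width index is the ratio `width / fitted`, which keeps
the index non-negative and makes detrending exactly scale-equivariant.

The cambial-age index starts at the first measured ring. Cores rarely hit
the pith, so true cambial age is underestimated by an unknown offset; with
no pith-offset data available the first-ring convention is the only
defensible default, and because the negative exponential is
translation-absorbing (a shift in t rescales `a`), the fitted curve shape is
barely affected.

## Chronology construction and quality statistics

Index series are averaged per year. The default aggregation is Tukey's
biweight robust mean (tuning constant 9, one step from the median/MAD) in
years with at least 6 contributing series, falling back to the arithmetic
mean at lower sample depth, where the biweight's breakdown advantage is not
worth its small-sample noise; a pure arithmetic mean is always available.
Chronologies are truncated at a configurable start year (default 1850, the
period over which estuary dredging could plausibly leave a signal).

Quality statistics use their standard definitions:

- **Mean sensitivity** `MS = (1/(n−1)) Σ |2(x_{t+1}−x_t)/(x_{t+1}+x_t)|`,
  computed on raw widths when they are available (the conventional basis)
  and averaged unweighted across series.
- **Interseries correlation**: each series' Pearson r against the arithmetic
  mean of all other series over their overlap (≥ 20 years, else the series
  is flagged and excluded from the site mean). Note this is a
  chronology-quality summary on the detrended series, *not* the
  segment-based, autoregressively whitened statistic a crossdating-QC
  program computes; dating-error detection is out of scope here and the two
  numbers are not interchangeable.
- **rbar** is the mean of all pairwise Pearson correlations over pairwise
  overlaps within the statistics window (pairs with < 20 common years are
  skipped as unstable); with n contributing series,
  `EPS = n·rbar/(1+(n−1)·rbar)` and `SNR = n·rbar/(1−rbar)`, so
  `EPS = SNR/(1+SNR)` holds identically. `rbar = 1` reports SNR as +inf.
- The statistics window defaults to the truncated (post-1850) span and is
  configurable.

## Climate–growth correlations

Ring formation integrates moisture and temperature over more than the
calendar year of growth, so the default lag window pairs each response year
with 18 months of climate: previous May–December and current
January–October. Pearson r is computed per month over a configurable period
(default 1895–2022); years missing a month's climate are dropped pairwise
for that month only, maximizing n per month. Significance is the exact
two-sided t-test at α = 0.05 by default; a stationary bootstrap (1000
replicates, geometric blocks of mean length 4 years, fixed seed, 95%
percentile interval excluding zero) is available for serially persistent
climate variables. The split-period analysis (default 1895–1960 vs
1961–2022, split year inclusive in the early half) simply runs the same
analysis on each sub-period; both halves must span ≥ 30 years.

## Suppression detection

**Running-mean rule (per tree, raw widths).** The reference level is a
centered 20-year running mean of raw widths (offsets −10…+9). At the series
edges the window slides inward so that min(20, series length) years are
always averaged; series shorter than 10 years are rejected. Raw widths are
used deliberately: standardization can remove exactly the ecological signal
this rule looks for. A year is *suppressed* for a tree when its width is
below 25% of the running mean — the rule is implemented literally
(`width < 0.25 × mean`), with the fraction configurable so the alternative
"25% below the mean" reading (0.75×) is one keyword away. Cores are averaged
to one series per tree before flagging, because suppression percentages
count trees. A site year has *widespread suppression* when strictly more
than 75% of the trees with a defined running mean are suppressed and at
least 5 trees have data.

**Host/non-host events (per tree, standardized indices).** Following the
outbreak-correction family of methods, the reference-site ("non-host")
chronology's deviations are scaled by the host/non-host standard-deviation
ratio and subtracted from each host tree's index over their overlap
(≥ 30 years):

    gsi[y] = h[y] − (σ_h/σ_c)·(c[y] − mean(c))

The residual is normalized to mean 0 / sd 1 (`ngsi`). A per-tree suppression
period is a maximal run of years with `ngsi < −1.28` (the standard-normal
10th percentile), bridging interruptions of up to 1 year, retained at ≥ 4
years; severity comes from the minimum `ngsi` (minor ≥ −2, moderate ≥ −3,
severe < −3). Site-level events are maximal runs of years in which ≥ 25% of
the trees with defined `ngsi` are concurrently inside a period; each event
reports its span, the trees involved, their worst severities and the peak
proportion. All thresholds are configuration keys.

Degenerate corrections (host identical to the reference chronology up to
rounding) are detected with a relative tolerance on sd(gsi) and yield no
events rather than amplified rounding noise.

*Known behaviour*: because growth noise is multiplicative, a genuinely
suppressed narrow ring formed in a shared drought year can be fully
"explained" by the climate correction, so event boundaries blur when several
dry years fall at an event's edge, and two or more consecutive shared dry
years inside an event can split it at the site level. This is intrinsic to
the linear correction, not an implementation artifact.

## Sediment proxies

Salinity classification is presence/absence based — no transfer function is
attempted, since the assemblages are used qualitatively. A sample with
≥ 20 foraminiferal individuals (five agglutinated marsh taxa) carries an
interpretable saline assemblage; zero foraminifera alongside thecamoebians
indicate freshwater; sparse or barren samples are indeterminate. The
20-individual rule is applied symmetrically to surface stations and downcore
samples. Two depths are reported rather than one: the *establishment* depth
(deepest depth at or above which every shallower sample classifies saline)
and the *first-occurrence* depth (deepest sample with any foraminifera),
because the two describe different stages of salinization.

The ¹³⁷Cs peak is located as the maximum of the activity profile after a
centered 5-point moving average (edge windows truncated; ties break toward
the shallower depth; a maximum on the first or last interval warns that the
true peak may lie outside the core). The smoothing bandwidth is about half
the typical fallout-peak width (~4 cm), small enough to leave the location
of a symmetric peak unbiased while suppressing the counting noise that
displaces a raw argmax between near-equal neighbouring slices; `smooth=1`
restores the raw maximum. The age–depth model is single-anchor linear:
depth 0 ↦ collection year and the peak depth ↦ 1963, with a constant
sedimentation rate, extrapolated (and flagged) below the peak. The ~1954
onset of detectable fallout is deliberately not used as a second anchor —
the peak is the robust horizon; onset depths serve as a consistency check.

## Synthetic-data generator

The generator emulates the study design, with ground truth recorded so every
stage can be tested for recovery.

- **Climate**: monthly values are seasonal means plus a continuous AR(1)
  anomaly. Defaults: drought index centered at 0 with φ = 0.7 and innovation
  sd 1.0 (monthly anomaly sd ≈ 1.4, so multi-year droughts with index values
  below −3 occur); temperature an 8–27 °C seasonal cycle, φ = 0.5;
  precipitation a wetter summer, φ = 0.2, floored at 0.
- **Tree growth**: per tree and year,
  `width = (a·e^(−b·age)+k) · exp(β·P̄_JJA + C(t) + ε_i(t)) · m_i(t)`
  with the age trend (a = 2 mm, b = 0.02 /yr, k = 0.5 mm), a summer (JJA)
  mean drought-index forcing, site-level lognormal common noise `C`,
  tree-level lognormal noise `ε`, and an event multiplier `m < 1` applied to
  a chosen fraction of trees during implanted events. Multiplicative noise
  is used because ring-width variability scales with level and widths must
  stay positive. Tree start years are staggered (normal spread around a
  target median length) to mimic targeted sampling of old trees.
- **Default noise mix** (β = 0.09 per index unit, common sd 0.06, tree sd
  0.12): chosen once so the simulated chronology statistics look like real
  bald-cypress chronologies — rbar ≈ 0.5, EPS > 0.9 at 12 trees, per-month
  summer drought correlations r ≈ 0.4–0.6. A much stronger climate share
  makes chronologies unrealistically climate-dominated and, because the
  host/non-host correction is linear while growth is multiplicative, buries
  event edges in "climate-explained" years.
- **Microfossils**: counts are Poisson draws whose foraminiferal intensity
  follows a logistic ramp (scale 2 cm) from ~0 below the onset depth to a
  plateau (default 60 per 2 cm³) at the surface, partitioned over the five
  taxa by a mixing vector that shifts toward the high-salinity specialist
  (*M. fusca*) at the saline end; thecamoebian intensity ramps oppositely.
  A station-gradient variant ramps across a creek's surface stations.
- **¹³⁷Cs**: background + Gaussian peak (default 25 cm deep, sd 4 cm, peak
  10 activity units over background 0.5) + Gaussian noise (sd = 10% of the
  peak), floored at 0; the detection limit defaults to the background level.

Everything flows from `numpy.random.default_rng(seed)`: identical seed and
parameters give bit-identical outputs.

**What the generator does *not* emulate** — and hence what passing tests do
not show about field data: crossdating error and locally absent rings
(series are perfectly dated by construction), age-dependent noise and
juvenile growth anomalies, autocorrelated growth noise (only the climate
forcing is persistent), disturbance signals other than the implanted events
(storms, logging, competition), sediment mixing/bioturbation and compaction
(the age–depth model is exactly linear in the synthetic cores), and
taphonomic loss of tests downcore.

## Numerical choices and degenerate inputs

- Detrending requires ≥ 10 rings; all-zero series are rejected (no positive
  level to fit). Zero widths (locally absent rings) yield index 0.
- Mean sensitivity is undefined over a consecutive zero-zero pair (division
  by zero) and raises rather than silently skipping.
- Pearson correlations on zero-variance vectors are reported as NaN and
  flagged non-significant rather than raising, so one degenerate month does
  not abort a window.
- The biweight mean falls back to the median when the MAD is 0.
- Pipeline problem sizes used by the test-suite and the acceptance script —
  12-tree sites over 1850–2022, 500 null correlation simulations, 50–100
  recovery seeds — were chosen to give stable Monte-Carlo rates (binomial
  se ≲ 1 percentage point at the checked thresholds).

## Known limitations

- The interseries correlation here is not comparable to segment-based
  crossdating statistics computed on whitened series (typically lower);
  published values from such programs should be compared qualitatively only.
- The host/non-host correction assumes the reference site shares the whole
  climate signal and none of the stressor; site-specific (non-climatic)
  common noise at either site leaks into `ngsi` and can produce occasional
  short spurious events when correcting against a *different* site's
  chronology.
- The single-anchor age–depth model assumes constant accretion; real marsh
  cores compact and accrete unevenly, so extrapolated ages below the 1963
  horizon carry unquantified error (they are flagged, not error-barred).
- Event spans printed by real-world analyses depend on the underlying raw
  measurement data; with different trees and noise, detected spans shift by
  a few years at the boundaries even when the same procedure is used.
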