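# Methods

## Overview

`isoclim` implements a bioclimatic workflow for climate-envelope habitat
analysis: (1) quality-control and gap-fill monthly station climate; (2)
compute the Rivas-Martínez bioclimatic parameters and indices from period
climatologies; (3) diagnose isobioclimates qualitatively; (4) project
station climate to a target year with an ensemble of robust linear trend
models; (5) interpolate index surfaces and apply rectilinear envelope logic
to map suitable (min–max) and optimal (Q1–Q3) areas and their
gain/unstable/stable change between periods.

## Station QC and imputation

A station is retained when its pooled missing-cell fraction over temperature
and precipitation is strictly below 10% (configurable). Pooling the two
variables into a single per-station gate is a deliberate choice: the
alternative (per-variable gates) yields stations usable for one variable
only, which the envelope stage cannot exploit. Missing cells are filled with
that station's long-term mean for the same calendar month; observed cells
are never altered, and a calendar month with no observation at all is an
error rather than a silent zero.

## Bioclimatic indices

From a 12-month climatology of mean temperature `Ti` (°C) and precipitation
`Pi` (mm):

- `Tavg` = mean of the twelve `Ti`; `Pavg` = annual precipitation total.
- `Tp = 10 · Σ{Ti : Ti > 0}` (tenths of °C), `Pp = Σ{Pi : Ti > 0}` (mm):
  sums restricted to months with mean temperature above freezing.
- `Tmax`, `Tmin`: warmest/coldest monthly means; `Ic = Tmax − Tmin`
  (simple continentality index).
- `It = 10 · (Tavg + 2·Tmin)` (thermicity); `Itc = It + C(Ic)` where the
  compensation `C` is a piecewise function of `Ic`: zero on [9, 18],
  `−10·(9 − Ic)` below 9, and increasingly steep positive segments above 18
  (5/unit to 21, then 10, 30, 60 per unit). The segment boundaries and
  slopes are configuration data (`CompensationTable`); the shipped defaults
  follow the 2011 worldwide classification system.
- `Io = 10 · Pp / Tp` (annual ombrothermic index). `Io` is NaN when
  `Tp ≤ 0` (no month above freezing) — an explicit "undefined" marker that
  propagates to classification as a beyond-table label and to suitability
  as absence; it is never coerced to zero.
- Summer ombrothermic indices over nested windows: `Ios1` (warmest summer
  month), `Ios2` (two hottest summer months), `Ios3` (summer quarter),
  `Ios4` (summer quarter plus the preceding month). Each is
  `ΣP / ΣT` over its window — the factors of ten in the formal definition
  cancel. The summer quarter defaults to the warmest three *consecutive*
  calendar months of the climatology (circular scan, earliest start on
  ties), which reduces to Jun–Aug for northern mid-latitudes and
  generalises to the southern hemisphere; a fixed-JJA/DJF mode is
  available. The two hottest months are chosen within the quarter, ties
  broken by calendar order.

`Ios1` is computed but excluded from envelopes by default: characterisation
practice reports `Ios2`–`Ios4`, and a single-month ratio is the noisiest of
the four.

## Qualitative diagnosis

The macrobioclimate test distinguishes Mediterranean from Temperate by
summer drought: Mediterranean iff two *consecutive* summer-quarter months
each satisfy `Pi < 2·Ti`. The alternative reading — the mean of the two
hottest months satisfying `P < 2T` — is implemented as a selectable mode;
the consecutive-months form is the default because it is the stricter and
more widely operationalised rule. Only these two macrobioclimates are
diagnosed; tropical belts are out of scope.

Thermotype, ombrotype, continentality and bioclimate are assigned from
threshold tables shipped as versioned YAML (`isoclim/data/thresholds.yaml`)
with values from the Rivas-Martínez 2011 system. All intervals are
lower-closed, upper-open; a value outside a table's span yields an explicit
`beyond-table` marker, never silence. Each class splits into two horizons
at its midpoint:

- thermotype: the *upper* horizon is the colder (lower It/Itc) half —
  upper belts sit higher upslope;
- ombrotype: the *upper* horizon is the wetter (higher Io) half;
- continentality: *weak*/*strong* are the lower/upper Ic halves.

Thermotype uses `Itc` when it is at or above a validity floor (default
120); below the floor the positive-temperature (`Tp`) sub-table applies —
cold-belt thermotypes (oro-, cryoro-) are defined on `Tp`. The Temperate
belt bounds ship as defaults from the same system family but, unlike the
Mediterranean, ombric and continentality tables, could not be
cross-checked against printed diagnoses, and should be treated as
configuration.

The submediterranean variant flags Temperate diagnoses whose summer-quarter
ombrothermic index `Ios3` falls below 2.0 (configurable): temperate
climates with a Mediterranean-like summer drought.

Species-level summaries rank the distinct isobioclimates of a species'
occurrences by frequency; entries at or below a 5% rarity share are marked
parenthetical (ad hoc occurrences), ties break by count then
lexicographically.

## Trend models and projection

Each complete station contributes 24 series (12 calendar months × 2
variables) of yearly values. Five linear models are fitted per series:

1. ordinary least squares (closed form);
2. Theil–Sen (median of pairwise slopes; intercept = median of
   `y − slope·x`);
3. Siegel repeated medians (median over points of each point's median
   pairwise slope; same intercept rule);
4. Huber M-estimator (IRLS, tuning constant 1.345, MAD scale);
5. an MM-type estimator: Theil–Sen initial fit, scale frozen at 1.4826 ×
   MAD of the initial residuals, then IRLS with Tukey's bisquare
   (c = 4.685). The high-breakdown initialisation gives the redescending
   M-step resistance to gross outliers; the procedure is fully
   deterministic (no subsampling).

The best model per series minimises a residual criterion on the observed
years. The default criterion is the **median absolute residual**, with
in-sample RMSE selectable. This choice is structural, not cosmetic: OLS
minimises in-sample RMSE by construction, so an RMSE criterion can never
prefer a robust fit and the five-model ensemble would degenerate to OLS
everywhere. The median absolute residual scores each fit by how well it
describes the majority of years, letting robust fits win exactly on the
contaminated series where they should. Ties break deterministically by
model order (ols, theil_sen, siegel, m_estimator, mm_estimator).

Projection evaluates the selected fit at the target year (default 2050);
projected precipitation is floored at 0 mm, temperature is not clamped.
Bioclimatic indices for the target year are recomputed from the projected
monthly climatology rather than trended directly — recomputation preserves
inter-index identities (`Ic = Tmax − Tmin`, homogeneity of the ombrothermic
family) that independent per-index trends would violate.

## Surfaces

Station values are interpolated onto a regular lon/lat grid (cell-centre
registration, row 0 northernmost, half-open cells) by ordinary kriging with
a spherical (default) or linear variogram fitted by least squares to the
binned empirical semivariogram; degenerate variograms or singular systems
fall back to inverse-distance weighting (power 2) with a warning. Both
interpolators are exact at data locations up to numeric tolerance. Point
sampling is nearest-cell with no inter-cell interpolation; points outside
the grid yield NaN.

Rasters persist as plain-text ESRI ASCII grids. The production-scale
1-km² statewide grid of operational use is a configuration, not a default;
default grids are coarse (tens of cells per side) so that the full pipeline
runs in seconds.

## Envelopes, suitability and change

A species envelope stores per-variable min/Q1/Q3/max over the occurrence
points' sampled values (quartiles by linear interpolation of order
statistics — numpy's default — pinned in configuration), plus the set of
soil orders observed at occurrences. The variable set is the 13 indices
plus elevation; soil order enters as set membership — together the "15
variables" of the analysis.

A cell is *suitable* when **every** continuous variable lies inside
[min, max] (inclusive bounds) and its soil order is admissible; *optimal*
uses [Q1, Q3]. The conjunction is a hard AND (soil toggleable). The CON
mask applies a numeric tolerance of 1e-6 at interval boundaries: envelope
bounds are themselves sampled surface values, so exact-boundary cells are
systematic, and ratio-valued indices (an Ios over a near-zero temperature
sum) can amplify last-bit float differences by orders of magnitude; 1e-6
remains far below cell-to-cell physical variation.

Change between the reference-period and future binary maps is coded per
cell: (0,0) never, (0,1) gain, (1,0) unstable, (1,1) stable. Percentages
are expressed relative to the current area (unstable + stable cells), so
stable% + unstable% = 100 and gain% can in principle exceed 100; a zero
current area yields NaN percentages rather than a fabricated zero.

## Synthetic data generator

The generator provides a known ground truth for every stage. It emulates a
Mediterranean mountain landscape observed 1980–2019:

- DEM: a north–south ridge plus a northward gradient and seeded smoothed
  noise, clamped to [0, 3000 m]; soil orders are elevation bands perturbed
  by noise (correlated with, not determined by, elevation).
- Temperature: sea-level baseline 17 °C at the southern edge, −0.8 °C per
  degree latitude northward, −6.5 °C/km lapse rate, and an annual sinusoid
  whose semi-amplitude (8 °C at the coast) grows 6% per degree inland —
  without this continentality gradient `Ic` is constant over the landscape
  and its envelope axis degenerates.
- Precipitation: 700 mm/yr at the coast, +30%/km orographic gain, −10% per
  degree inland, distributed over months with a winter-wet weighting that
  leaves summers dry enough to satisfy the two-consecutive-month `P < 2T`
  criterion at low elevations (the generator asserts this on its own
  output).
- Interannual structure: linear trends (+0.03 °C/yr; −0.2%/yr
  precipitation) plus independent Gaussian noise — 0.5 °C per monthly
  value; precipitation noise is proportional to the monthly normal (25%)
  and truncated at zero, since a flat absolute noise level would swamp the
  few-mm Mediterranean summer months. Noise is independent across months
  and years: the in-scope models are linear trends, and autocorrelation
  would only inflate their variance without changing the estimand.
- Optional gross contamination (outlier years per series) and missingness
  masks exercise the robust fits and the QC/imputation stages.
- Occurrences are sampled uniformly from cells whose *true* (noise-free)
  variable vector lies inside a prescribed box; junk records (duplicates,
  (0,0) coordinates, out-of-region points) can be injected for the
  cleaning stage.

All draws key on `(seed, stage tag)`, so each artifact is reproducible in
isolation and the full scenario is byte-reproducible.

What the generator does *not* emulate: spatially correlated noise fields,
GCM-style circulation changes, elevation-dependent trend magnitudes,
observation inhomogeneities (station moves, instrument changes), and
presence-only sampling bias in occurrences. Tests passing on this ground
truth therefore demonstrate correctness of the computational chain, not
skill on real networks.

## Numerical choices

- Index arithmetic in double precision; characterisation tables round to
  one decimal at the reporting layer only.
- Quantiles: linear interpolation of order statistics (numpy default).
- Model-selection ties: declared model order. Non-convergent robust fits
  fall back to OLS and are flagged.
- Interval classification: lower-closed, upper-open everywhere; boundary
  values belong to the upper interval.
- Degenerate inputs: all-equal years are a fitting error; an all-below-zero
  climatology yields NaN ombrothermic indices; a zero current area yields
  NaN change percentages.

## Problem sizes

Default test and demonstration scenarios use 25–100 stations on grids of
20×20 to 60×60 cells over 40 years, and 100–250 occurrences per species —
sizes chosen so the full pipeline and its verification run in seconds to a
couple of minutes while every statistical property under test (trend
recovery, envelope convergence, selection behaviour under contamination)
is already well-resolved. A `full_scale_config` preset scales the station
network to 177 stations over 40 years for end-to-end demonstrations.

## Known limitations

- The geostatistical step is ordinary kriging (or IDW): the
  simulation-based empirical Bayesian variants found in commercial GIS
  software are not reproducible from published settings, and this
  substitution is the pipeline's main deviation from common operational
  practice.
- Envelopes are rectilinear and conjunctive: no interactions between
  variables, no occurrence weighting, no dispersal or biotic constraints —
  suitability maps are climate-potential maps, not distribution forecasts.
- Trend projection is strictly linear per series; no uncertainty intervals
  accompany the 2050 values, and seasonal time-series models are out of
  scope.
- Temperate thermotype belt bounds are plausible defaults, not validated
  constants (see above).
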