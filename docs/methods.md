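# Methods

This note documents the models, conventions and design choices behind
`aquarisk`, in the order the pipeline runs them.

## Data model and descriptive statistics

A dataset is a list of replicate measurements (`WaterSample`) keyed by
location, district and source type (hand-dug well or borehole).  Canonical
units are µg/L for metals (mg/L columns are converted on ingest, because
reference doses are quoted in µg/kg·day), mg/L for TDS/Ca/Mg, µS/cm for EC.
Censoring follows the usual conventions: `ND` cells are non-detects and are
excluded; `<x` cells are below-detection with limit `x` and enter
descriptive statistics at `x/2`.  A metal that is entirely non-detected in a
stratum is excluded from risk simulation and flagged in the run manifest
("not screened"), not silently zeroed.

Guideline-violation percentages are location-level: triplicate measurements
are averaged to one value per location before comparison, so a stratum of 9
boreholes yields multiples of 1/9 (44.44%, 11.11%, ...).  The standard
deviation convention is the sample (n−1) estimator; `summarize` exposes
`ddof` because the population convention is the one under which statistics
are invariant to dataset self-concatenation.

Correlation strength classes follow the water-quality reporting convention:
|r| < 0.5 weak, 0.5 ≤ |r| < 0.7 moderate, |r| ≥ 0.7 strong, applied to the
magnitude with the sign reported separately.

## Distribution fitting from printed summaries

Two inversion routes cover the summary forms monitoring studies print:

- `fit_lognormal_from_summary(mean, sd)` — exact moment inversion,
  σ² = ln(1 + (sd/mean)²), µ = ln(mean) − σ²/2; the zero-sd limit returns a
  point mass.
- `fit_normal_from_percentiles(p_low, p_high)` — the two-quantile solve; for
  the symmetric (5%, 95%) pair this is the midpoint mean and
  sd = (p95 − p5)/3.2897.  A lognormal variant fits on the log scale for
  right-skewed quantities.

`fit_truncated_lognormal(mean, sd, lo, hi)` produces the generator's
concentration laws: it solves for (µ, σ) such that the *truncated* moments
match the targets, via a nested root search (inner: µ matching the
truncated mean at fixed σ; outer: σ matching the truncated sd).  Gaussian
CDF differences are evaluated through the survival function when the window
sits in a tail — the naive Φ(b) − Φ(a) form loses all precision there and
was observed to mislead the solver.  When the window genuinely cannot carry
the target spread (the achievable truncated sd saturates as σ grows), σ is
fixed at the untruncated moment fit and only the mean is matched: the mean
is the contract downstream recovery tests rely on.  The sd reported for
very narrow windows is additionally limited by cancellation in the
second-moment formula; bounds compliance is exact regardless, because
sampling is inverse-CDF through `scipy.stats.truncnorm` with a final clip.

## Synthetic study design

The generator emulates a two-district survey: per district, 9 wells and 9
boreholes, 3 replicates each (108 samples, 36 locations).  Default targets
are the published per-district ranges and means; where only a mean is
published the sd defaults to a 45% CV, the coefficient of variation of the
published Pb hazard-quotient output for the most-exposed stratum.  Two
generation levels separate sampling variance from measurement noise:
location means draw from the truncated lognormal above, replicates multiply
the location mean by unit-mean lognormal noise at 5% CV (triplicate
instrument scatter) and clip to the target range.  Cu and Cd are emitted as
non-detects everywhere, Cr in one district and in the other district's
boreholes, mirroring the detection pattern such surveys report.

One master seed drives everything; per-stratum substreams are derived by
hashing (district, source, parameter) labels into the `SeedSequence`
entropy, so datasets are byte-reproducible and adding a stratum never
perturbs another.

What the generator does *not* emulate: spatial autocorrelation between
locations, inter-parameter correlation inside a district (parameters are
independent given the stratum), temporal trends, and analytical bias.
Passing tests therefore demonstrate the pipeline's correctness and
calibration on data with the published marginal structure, not performance
on real aquifer chemistry.  One consequence of the published marginals is
worth noting: a range of 11.7–427.2 µg/L with mean 13 µg/L cannot carry a
45% CV under any truncated lognormal, so that stratum's realized spread is
narrower than the default CV suggests.

## Exposure and toxicity defaults

The exposure tables behind the source survey are not deposited; defaults
are back-calculated resident values and stay configurable: adult IR 2 L/day,
BW 70 kg, EF 350 days/year, ED 30 years; child IR 1 L/day, BW 15 kg, ED 6
years; dermal SA 18 000 cm² (adult) / 6 600 cm² (child), K_p 0.001 cm/h,
ET 0.58 h/day (adult) / 1 h/day (child), CF 0.001 L/cm³.  Averaging time is
ED × 365 days for hazard quotients (which makes the ingestion HQ
algebraically independent of ED) and 70 × 365 days for cancer risk.

Reference doses (µg/kg·day): Al 1000, Cr 1500, Fe 700, Mn 140, Ni 20.
Pb defaults to 1.4 µg/kg·day — the magnitude consistent with reported Pb
hazard quotients — with 140 selectable via a configuration flag, because
published RfD listings disagree at exactly this factor of 100.  The dermal
RfD falls back to the oral value unless a dermal-specific entry is
configured.  Oral slope factors ((mg/kg·day)⁻¹): Ni 1.7, Pb 0.0085, Cr 0.5.
The µg→mg conversion happens exactly once, inside `lifetime_cancer_risk`.

## Monte Carlo engine

Plain pseudo-random simulation (no variance reduction), default n = 10 000.
Each stochastic input gets its own substream in a fixed order, so declaring
a distribution for one factor does not shift another factor's draws.
Percentiles use sorted-sample linear interpolation (Hyndman–Fan type 7, the
spreadsheet default).  Exceedance uses strict inequality (ties have
probability zero under continuous laws).  The closed-form normal exceedance
1 − Φ((t − µ)/σ) serves as the independent oracle in tests; convergence to
it at the binomial 1/√n rate is asserted on a log–log slope.

Because only output summaries of the source survey are published, its
tables are reproduced by *output-distribution* fitting: a normal at the
printed (mean, SD) — the survey's own negative printed lower percentiles
show its summaries are normal fits — or, for the one strongly right-skewed
cancer-risk row, a lognormal through the printed 5th/95th band.  No input
distributions are guessed.

## Sensitivity shares

Contribution of input j = 100 · sign(ρ_j) · ρ_j²/Σρ_k², with ρ the Spearman
rank correlation against the risk output; magnitudes sum to 100%, monotone
input transforms leave shares unchanged, constant inputs report 0% with a
warning.  The squared normalization is the default (it matches tornado
reports with one negative body-weight bar); a |ρ| normalization is
available since published reports rarely state which is used.

## Source apportionment

"Principal factors" are computed as the eigen-decomposition of the Pearson
correlation matrix (unrotated), loadings scaled by √eigenvalue, with
retention by count, cumulative-variance threshold or the Kaiser rule.
Factor signs are fixed deterministically (largest-|loading| entry positive).
Variable contributions are loading²/eigenvalue and observation
contributions score²/Σscore², each summing to 100% per factor — the
quantities used to tie factors to parameters and to individual wells.
Standardization is implied by the correlation input, which also makes the
model scale-invariant.  No rotation is applied: published loadings from
rotated solutions are therefore comparable only qualitatively.

The planted-structure check uses a two-latent-source mixture (18
observations × 10 variables, half the variables per source at loading 0.9,
noise sd 0.5, one low-noise "marker" variable per source).  Two factors
retain well above 70% of variance at this size; the within-block dominance
ranking of the markers is only identifiable once the latent factors
decorrelate, so that claim is checked at 300 observations.

## IDW mapping

Cell value = Σ d⁻ᵖ v / Σ d⁻ᵖ over all points (optionally the k nearest),
default power 2, planar Euclidean distance; a cell within 10⁻⁹ × cellsize
of a data point takes its value exactly.  The interpolant is a convex
combination, hence bounded by the data range, and depends on distances
only (translation/rotation invariant).  Grids serialize to ESRI ASCII.
No kriging, basemaps or CRS handling.

## Pipeline

`run_full_assessment` composes the stages behind one configuration: data
(file or synthetic), descriptives with WHO/NSDWQ exceedance columns, risk
tables in the adult/child percentile layout, sensitivity tornado rows,
per-district factor CSVs, per-parameter `.asc` rasters, and a JSON manifest
carrying the config hash, seeds, row counts and machine-readable warnings.
Per-cell simulation seeds derive from the master seed and the cell labels,
so disabling one stage cannot change another's bytes.  Problem sizes used
throughout the tests (10³–10⁵ Monte Carlo draws, 900-location recovery
strata, 20×20 to 40×40 grids) were chosen as the smallest that leave
comfortable statistical margin for each check.
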