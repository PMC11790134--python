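# Methods

This note records the models implemented, the defaults and why, what the
synthetic generator does and does not emulate, and the numerical choices a
maintainer would want to know.

## Capacity and contamination indices

The environmental pollution capacity of a metal at a site is the residual
headroom between its concentration and the regulatory screening value,
expressed per hectare of soil: `Qi = 10⁻⁶·M·(Cs − Ci)` with
`M = 2.25×10⁶ kg/ha` by default (plough-layer mass of one hectare). The
total capacity `Qib` uses the background `Cb` in place of `Ci`, and the
capacity index `Pi = (Cs − Ci)/(Cs − Cb)` cancels `M`. The implementation
fixes the convention that `Qi` is measured-concentration-based and `Qib`
background-based, both relative to `Cs`; this is the only reading under
which `Pi = 1` at background, `Pi = 0` at the screening value and
`Pi < 0` beyond it, which is how the index is interpreted everywhere in
the literature this package follows.

Integration across metals is deliberately asymmetric between the two
index families. The Nemerow combination of concentration ratios uses the
classical max-emphasizing form `sqrt((mean² + max²)/2)` — a pollution
index must not let one extreme metal be averaged away. The integrated
capacity index instead range-normalizes each metal's `Pi` to [0, 1]
across the survey and combines with `sqrt((mean² + min²)/2)`: for a
*capacity* the scarce metal is the binding constraint, so the minimum is
emphasized. A metal whose `Pi` is constant across the survey carries no
ranking information; its normalized value is fixed at 0.5 by convention
(documented, tested). Both combinations are config-switchable.

Risk classes default to `Pi ≥ 0.7` safe, `0.4 ≤ Pi < 0.7` precautionary,
`0 ≤ Pi < 0.4` loaded, `Pi < 0` overloaded, with closed lower bounds on
the upper class; 0.7 is the one threshold the capacity literature prints
consistently, the others are round defaults and fully configurable.

### Reference constants

Background values are the FAO-style values shipped with the package
(Pb 50, Cr 100, Mn 2000, Cu 100, Zn 300, Co 50, Ni 100, As 20 mg/kg).
Method detection limits follow the analytical method (Pb 0.25, Zn 0.21,
Cr 0.16, Mn 0.15, Ni 0.54, Co 0.12, Cu 0.05 mg/kg; As 0.3 µg/kg stored
as 0.0003 mg/kg). Toxic-response factors are the standard Hakanson
literature values (Pb 5, Cr 2, Cu 5, Zn 1, Co 5, Ni 5, As 10, Mn 1).
Screening values are documented defaults drawn from agricultural-soil
screening standards where those exceed the background and otherwise set
above it — the invariant `Cs > Cb` is required for the capacity
denominator — and the standard limit `Sj` defaults to `Cs`. All constants
are overridable from a CSV; every result that depends on `Cs`, `Sj` or
`Tr` is parameterized by that table, and exact replication of any
specific study requires transcribing that study's constants.

## Land-use statistics

Per-stratum mean, unbiased SD and CV% = 100·sd/mean; Kolmogorov–Smirnov
normality with the Lilliefors correction (the normal's parameters are
estimated from the sample, so the uncorrected KS p-value would be
anti-conservative); Box–Cox (maximum-likelihood λ) applied only when
normality is rejected at α = 0.05; classical one-way ANOVA across land
uses with a mean-centred Levene pre-test routing the post-hoc family —
Tukey HSD under variance homogeneity, Games–Howell otherwise (the
homogeneous/heterogeneous metal lists are decided by the pre-test, not
hard-coded); Pearson correlations per stratum with two-tailed p-values.
Whether ANOVA runs on raw or Box–Cox-transformed values is a flag
(`use_boxcox`, default off). No multiple-testing correction is applied
beyond Tukey/Games–Howell family-wise control.

## Spatial interpolation and area detection

The variogram `γ(h) = nugget + (sill − nugget)(1 − exp(−h/range))`
(exponential; spherical available) is fitted to binned empirical
semivariances (12 bins to half the maximum pair distance) by weighted
least squares with Cressie weights `N(h)/γ_model(h)²`, iteratively
reweighted from a pair-count-weighted first pass. Plain pair-count
weighting systematically underestimated the range on single realizations;
the Cressie scheme emphasizes the short-lag bins that carry the range
information. `range` is the e-folding length (no factor-3 convention),
matching the synthetic generator's covariance. A constant field yields
`sill = 0`; collinear geometries warn but fit.

Ordinary kriging solves the standard BLUP system with the unbiasedness
constraint; duplicate sites are averaged (with a warning) and a
`1e-10·sill` diagonal jitter keeps near-singular systems solvable. With
zero nugget the predictor interpolates exactly; a pure-nugget model
collapses to the global mean.

The empirical-Bayesian-style predictor quantifies variogram-estimation
error: fit a base variogram, simulate K replicate datasets at the
observation locations from its Gaussian process, refit each, weight each
member variogram by the profile Gaussian likelihood of the *observed*
data under its covariance (normalized over members), and average the
member kriging surfaces by weight. `K = 1` reduces to ordinary kriging;
degenerate members are dropped and a vanished ensemble falls back to the
base fit with a warning. The subsetting of the data into overlapping
windows that commercial EBK implementations perform is deliberately
omitted at survey sizes of a few dozen sites: the full-data ensemble is
the appropriate scale.

Area detection rasterizes (default 100×100 cells over the padded bounding
box) and masks to the convex hull of the sites buffered by the median
nearest-neighbour distance — a proxy for the unavailable true study
polygon. "Combined interpolation" is the unweighted cellwise mean of the
kriging and IDW surfaces (the simplest faithful reading of a combined
predictor; either surface can be used alone). A cell or site is
contaminated when `Pi < 1` (equivalently `Ci > Cb`); the all-metals row
uses the integrated `Pi` against the precautionary boundary (0.4 by
default). An optional intermediate "unsafe" band between two thresholds
is available but disabled by default.

## SOM and cluster-count selection

Batch SOM on a rectangular grid (default ≈ 5√n units, aspect-balanced —
6×5 at n = 30) over column-standardized concentrations: per epoch, all
samples are assigned to their best-matching unit and every codebook
vector is replaced by the Gaussian-neighbourhood-weighted mean of the
data, with the neighbourhood radius shrinking linearly from
max(rows, cols)/2 to 1. Initialization is seeded-uniform over the data
range; training is fully deterministic given the seed. Codebook vectors
are clustered by k-means (10 restarts) for k = 2…10 and the
Davies–Bouldin index selects k (DBI is undefined at k = 1, so the scan
starts at 2); samples inherit their BMU's cluster. Rectangular topology
and z-score normalization are the documented defaults.

## PMF

Weighted nonnegative factorization by multiplicative updates with cell
weights `1/u²`: monotone in Q (asserted per iteration in the tests) and
nonnegativity-preserving. Defaults: 20 seeded restarts, `tol = 1e-6`
relative ΔQ, `max_iter = 5000`; the lowest-Q run is returned with the
per-run Q list. The second branch of the uncertainty equation carries the
square root — `u = sqrt((σⱼx)² + (MDL/2)²)` — since without it the units
are mg²/kg². σⱼ defaults to 0.1 for every metal and is the single most
result-sensitive unknown; it is configurable per metal. Below-detection
values are replaced by MDL/2 with `u = 5/6·MDL`. After fitting, G columns
are rescaled to mean 1 (F rows are then mean apportioned concentration
profiles); the reconstruction is unchanged. Factor contributions are
mass-based by default (share of total reconstructed mass), with a
mean-normalized-contribution basis available. A factor count `p` must
leave positive degrees of freedom (`p(n+m) < nm`). No robust
outlier down-weighting, bootstrap error estimation or rotational
(Fpeak-style) exploration is implemented.

## Synthetic generator

The survey generator reproduces the published study design: 30 sites in
five land-use strata (5/7/6/7/5) with per-stratum, per-metal mean/SD
matched exactly by moment-matched lognormals (right-skewed and positive,
consistent with data that need Box–Cox normalization). Each metal's
values are driven by a unit-variance Gaussian random field with
exponential covariance (range = 1/4 of the survey extent, nugget fraction
0.2) sampled at the site locations, so stratum moments hold marginally
while empirical variograms are non-degenerate. Concentrations are clamped
at half the detection limit. `corr_range_fraction = 0` is the documented
independent limit used for large Monte-Carlo checks of the moment
matching. The generator does *not* emulate the real geography, the
inter-metal correlation structure of the original data, or
below-detection censoring patterns; passing tests demonstrate correctness
of the algorithms under these controlled conditions, not field validity.

The receptor-model generator plants ground truth for recovery tests:
source-like profiles with disjoint dominant-metal blocks (loadings
0.6–1.0 on owned metals, 0.005–0.04 elsewhere, scaled to realistic
magnitudes), gamma-distributed contributions with three near-pure sites
per factor (sites dominated by a single source, as occurs next to point
sources), 5 % relative Gaussian noise truncated at zero, and an optional
prescribed mass split. The separability structure is what makes the
factorization identifiable at n = 30: with dense random profiles the
global optimum of Q can sit away from the planted truth, which is a
property of the model class, not of the solver.

## Problem sizes and determinism

Default analysis sizes are those of the emulated study (n = 30, m = 8,
p = 3–5, 100×100 rasters, 20 PMF restarts); recovery and cross-validation
tests use n = 45–200 fields and reduced ensembles (K = 8–30), and the
acceptance script averages three planted-dataset replicates for the
contribution recovery to keep Monte-Carlo error well inside the ±5-point
comparison band. Every stochastic stage takes an explicit seed; the
pipeline fans a single global seed out as seed + stage index, so a rerun
with the same survey, config and seed is byte-identical for every
deterministic artifact.

## Known limitations

- Screening values, standard limits and toxic-response factors ship as
  documented defaults, not as any specific study's constants; absolute
  `Pi`/`NPI`/`ER` levels move with them.
- The EBK-style ensemble quantifies variogram-estimation uncertainty
  only; it is not a reimplementation of any GIS vendor's EBK (no data
  subsetting, no vendor prior families).
- The study polygon is a buffered convex hull; with strongly non-convex
  basins the area fractions would differ.
- PMF factor-count selection is left to the diagnostics table; no
  automatic choice is made beyond the Q/Qexpected elbow.
- k-means inside the SOM clustering uses Lloyd restarts; for very small
  codebooks an exhaustive search would be cheaper and exact.
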