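# soilcap

Soil heavy-metal(loid) pollution assessment for small stratified surveys:
environmental-capacity and contamination indices, land-use statistics,
geostatistical delineation of contaminated area, self-organizing-map
pattern analysis, and uncertainty-weighted positive matrix factorization
(PMF) for source apportionment.

The package is aimed at environmental geochemists working with the typical
survey layout of a district-scale soil study: a few dozen composite
topsoil samples spread over land-use strata (residential, commercial,
educational, floodplain, agricultural), analysed for Pb, Cr, Mn, Cu, Zn,
Co, Ni and As. A calibrated synthetic-survey generator makes every stage
runnable and testable without field data.

## The indices

For a site concentration `Ci` with background `Cb`, screening value `Cs`,
standard limit `Sj` and Hakanson toxic-response factor `Tr`:

- contamination factor `CF = Ci / Cb`
- ecological risk `ER = Tr × CF`
- single-metal Nemerow ratio `NPI = Ci / Sj`, integrated per site as
  `sqrt((mean² + max²)/2)`
- environmental pollution capacity (EPC):
  `Qi = 10⁻⁶·M·(Cs − Ci)`, `Qib = 10⁻⁶·M·(Cs − Cb)`, and the capacity
  index `Pi = Qi/Qib = (Cs − Ci)/(Cs − Cb)`

`Pi` is 1 for background soil, 0 when the screening value is reached, and
negative beyond it; it is independent of the per-hectare soil mass `M`.
A site-level integrated `Pi` range-normalizes each metal's capacity over
the survey and combines with the *min*-emphasizing Nemerow form
`sqrt((mean² + min²)/2)`, weighting the metal with the least remaining
capacity. Risk classes default to `Pi ≥ 0.7` safe, `0.4–0.7`
precautionary, `0–0.4` loaded, `< 0` overloaded.

## Source apportionment and pattern analysis

PMF factorizes the `n × m` concentration matrix `X ≈ G·F` with
nonnegative site contributions `G` and source profiles `F`, minimizing the
uncertainty-scaled objective `Q = Σᵢⱼ((Xᵢⱼ − (GF)ᵢⱼ)/uᵢⱼ)²` by seeded
multistart multiplicative updates. Cell uncertainties follow the EPA
convention (`u = 5/6·MDL` below the detection limit with `MDL/2`
substitution, `u = sqrt((σⱼx)² + (MDL/2)²)` above it). Factor-count
diagnostics (Q/Qexpected elbow, scaled residuals, per-metal R²),
per-factor contribution percentages and per-metal species shares are
reported.

A batch self-organizing map trained on z-scored concentrations yields
component planes (per-metal codebook slices, whose correlations over units
expose source groupings) and a two-level clustering: k-means on the
codebook with the cluster count picked by the minimum Davies–Bouldin
index.

Interpolation of the capacity index uses ordinary kriging with a
weighted-least-squares exponential/spherical variogram fit, inverse
distance weighting, and an empirical-Bayesian-style variant that accounts
for variogram-estimation error by likelihood-weighting an ensemble of
simulate-and-refit variograms. Contaminated area is the fraction of cells
(inside the buffered convex hull of the sites) where the combined
kriging/IDW surface violates the contamination rule (`Pi < 1`,
equivalently `Ci > Cb`), compared with the plain per-site fraction.

## Worked example

```
$ soilcap simulate --out survey.csv --seed 1
wrote 30 sites to survey.csv
$ soilcap indices --survey survey.csv --out indices.csv
wrote indices for 30 sites to indices.csv
$ head -3 indices.csv
site,land_use,nemerow_integrated,integrated_pi,risk_class
S1,residential,0.3782,0.5058,precautionary
S2,residential,0.3972,0.4008,precautionary
$ soilcap map --survey survey.csv --out-prefix map --seed 3
wrote pollution-area table to map_areas.csv
$ head -4 map_areas.csv
metal,site_pct,interp_pct
Pb,100,100
Cr,56.67,94.03
Mn,0,0
```

The synthetic survey reproduces the published per-stratum means, so Pb —
whose stratum means (105–174 mg/kg) all exceed the 50 mg/kg background —
is contaminated at 100 % of sites and 100 % of the interpolated area,
while Mn (means ≈ 300 mg/kg against a 2000 mg/kg background) is clean.
For Cr, whose floodplain/agricultural distributions straddle the
background, interpolation upgrades the site fraction (56.67 %) to 94 % of
the area: the high-concentration strata dominate spatially. `S1`'s
integrated capacity of 0.51 places it in the precautionary class.

`soilcap run --survey survey.csv --out results/` executes every stage
(statistics, indices, mapping, SOM, PMF) and writes a JSON manifest with
input hashes and per-stage seeds; `soilcap pmf`, `soilcap som`,
`soilcap stats` run single stages.

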