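# Methods

`habisuit` implements a quality-aware habitat-suitability model for
medicinal plants, with *Schisandra sphenanthera* (its fruit lignan
schisantherin A indexing medicinal quality) as the reference organism.
Unlike presence/absence species-distribution models, the response being
modelled is a continuous quality signal: the metabolite content measured
at field sites.

## Model

**Standardization.** Observed contents (percent dry weight) are mapped to
membership degrees in [0, 1] by dividing by the maximum observed content
`c_max`; the best observed sample defines complete membership. A min–max
scaling was rejected because a low-but-nonzero content still indicates
partial suitability, not complete non-membership. `c_max` is stored in the
model file so external sites are scored on the same scale.

**Membership curves.** For each bioclimatic variable Bio1–Bio19 a fuzzy
membership function links the variable to the degree:

- Gaussian `A(x) = exp(−((x−a)/σ)²)` for variables with both lower and
  upper limiting boundaries; `A(a) = 1` exactly.
- Two-sided Gaussian (independent widths `σ_L`, `σ_R` about a shared
  optimum) where tolerance is asymmetric. This is the implementation of
  the "piecewise/subsection Gaussian" family: the simplest piecewise
  Gaussian consistent with an asymmetric threshold pair, continuous with
  value 1 at the optimum.
- Ramp `clip((x−z)/(o−z), 0, 1)` for variables with a single limiting
  boundary; the parameter order encodes orientation, so the descending
  variant needs no second formula. The textbook descending trapezoid is
  sometimes printed with denominator `(x−a)`, which is unbounded on
  `[a, b]`; only `(b−x)/(b−a)` satisfies `A(a)=1, A(b)=0` and the [0, 1]
  bound, so that form is used.

Curves are fitted per variable by bounded nonlinear least squares
(`scipy.optimize.least_squares`, relative tolerance 1e-8, ≤ 10 000
evaluations), initialized from the data: Gaussian optimum at the x of
maximum degree, width at half the data range; ramp endpoints at the data
extremes, ordered by the sign of the degree–variable correlation. When no
family is imposed, all three are fitted and the best **fitting degree**
wins, ties resolved fewest-assumptions-first (gaussian > two-sided >
ramp). Fitting degree is `100·(1 − RMSE)` of the membership residuals,
clipped to [0, 100] — residuals live on the bounded membership scale, so
this reproduces the conventional 0–100 report; R² is logged alongside.

**Entropy weights.** Variables are weighted objectively by Shannon
entropy of the membership-standardized site × variable matrix (column
normalization `p_ij = x_ij / Σ_i x_ij`, entropy `e_j = −Σ p ln p / ln m`
with `0·ln 0 = 0`, dispersion `d_j = 1 − e_j`, weights `w_j = d_j / Σ d`).
A constant column carries no discriminating information and gets weight 0
(dispersions below 1e-12 are snapped to zero — the mathematical value for
a constant column — so float roundoff cannot masquerade as signal); an
all-constant matrix is degenerate. Weights are computed on the training
split only.

**Aggregation, grading, areas.** The integrated ecological suitability
index of cell *i* is the weighted average `y_i = Σ_j w_j x_ij ∈ [0, 1]`.
It is classified with half-open bins — unsuitable [0, 0.3), marginally
[0.3, 0.5), moderately [0.5, 0.7), highly suitable [0.7, 1] — boundary
values going to the upper grade, directly per the `0.3 ≤ y` convention.
Area statistics count valid (non-nodata) cells and treat the ~1 km² cells
as equal-area, matching the grid-count style of 30-arc-second analyses;
no latitude weighting is applied.

**Validation.** Samples are partitioned once, 75 % training / 25 % test
(banker's rounding of the training count, seeded permutation; 307 sites
split 230/77). Skill is RMSE and R² of predicted index `P_i` (the model
evaluated at the test site's grid cell) against normalized content `Q_i`
— the only pairing on a common scale that makes an RMSE of a few
hundredths dimensionally coherent. R² is not clamped: out of sample it
can be negative for a predictor worse than the observed mean, and
reporting it as computed is more informative than forcing the nominal
[0, 1] range. The same routine scores external sites outside the
training window, which is the transferability protocol.

**Scenario projection.** The fitted model is applied unchanged to future
stacks, one per emission storyline (A1B, A2, B1) × GCM (BC, CC, MI) ×
period (2020s, 2050s, 2080s). Grade proportions are averaged
arithmetically across the GCMs of an emission × period cell and
renormalized to 100. Pooling all scenario runs (27 combinations), Pearson
correlations and OLS regressions relate climate summaries — means of
Bio1 (annual temperature) and Bio12 (annual precipitation) over valid
cells, chosen for linearity with the regression — to the highly-suitable
share; the regression's x-intercept `−intercept/slope` estimates the
climate value at which highly suitable habitat disappears, and is
flagged invalid when the slope is non-negative.

## Reference constants

`habisuit.reference` bundles the published per-variable summary for the
Qinling Mountains study system: family, optimum, printed threshold pair,
fitting degree and entropy weight for each of the 19 variables (fitting
degrees 76.20–96.93 %, mean 84.09 %; weights totalling 100.00 %). The
printed threshold pairs are used only to derive planted curve widths
(membership 0.5 at the threshold, `σ = halfwidth / √ln 2`) and as
evaluation fixtures, never as fit constraints. Documented quirks: Bio4's
pair is internally inconsistent (symmetric completion used), Bio19
prints a single threshold (symmetric width), and the Bio6/Bio8/Bio10
ramp orientations are ambiguous as printed — the generic
(zero-point, one-point) parameterization sidesteps the ambiguity, and
the planted defaults give L-types lower and R-types upper limiting
boundaries.

## The synthetic generator

Real inputs (WorldClim-style rasters, private field campaigns) are not
bundled; `habisuit.synthetic` generates structurally faithful stand-ins.

*Landscape.* A latent gradient `u` (affine trend in a random direction
plus moving-average-smoothed noise, min–max scaled) drives all layers:
layer *j* rescales `ρ·u + (1−ρ)·η_j` into its configured range, with
`η_j` variable-specific smoothed noise and cross-correlation `ρ = 0.9`.
Real bioclimatic variables co-vary strongly along elevation gradients;
this mixing reproduces that structure, and it is what makes parameter
recovery from aggregate content well-posed (see below). The identity
Bio7 = Bio5 − Bio6 holds by construction. Defaults: 48 × 64 cells of
0.05°, correlation length 3 cells (the smoothing window; short enough
that one landscape contains ~60 independent spatial patches, so the
value distribution of a single seed is not lumpy), a ~2 % nodata corner
block.

*Ranges and planted truth.* Each variable's membership-1 point sits at
quantile 0.4 of its range: most of the landscape is warmer and wetter
than optimal, the regime in which warming erodes highly suitable habitat
(the minority of cells below the optimum do gain — the synthetic analogue
of new upslope habitat). Gaussian ranges span 6 planted halfwidths so
both tails of the curve reach ≈ 0 inside the range; this matters because
the amplitude-pinned least-squares fit drags location estimates toward
any tail that stays high at the range edge. Temperature widths are
capped at a realistic 30 °C and precipitation clamped nonnegative, with
planted widths scaled alongside (`σ = width/5`, equal to the
printed-threshold σ when unclamped).

*Why recovery works, and its limits.* Observed degrees are the aggregate
`y`, not any single variable's membership. Because all optima align on
the latent gradient, `y` peaks where every variable is optimal and the
marginal relation of degrees to each variable traces that variable's own
curve — so curve *locations* are recoverable (the acceptance suite
demands 5 % of range on a 300-site study with content noise 0.05).
Widths are systematically distorted (each marginal fit absorbs the decay
of all other variables) and are not asserted. Weights are only weakly
identifiable from aggregate content: every fitted membership column
approximates the same aggregate signal, so the entropy method returns
near-uniform weights whatever vector generated the data. The planted
default is therefore uniform — the fixed point of the fit→weight loop —
and recovery is asserted within ±0.05 of it.

*Samples.* Sites are drawn at distinct valid cells (jittered within the
cell); content is `clip(y + ε, 0, 1)·c_max` with `ε ~ N(0, 0.05)` on the
membership scale and `c_max = 1.948 %`. The draw is repeated (≤ 100
attempts) until one content lies within 1 % of `c_max`, so the
content normalization is anchored; only as a last resort is a site moved
to the maximum-suitability cell (logged), keeping the noise distribution
unbiased on the common path.

*Scenarios.* Futures use the delta method: additive shifts on
absolute-temperature layers (Bio1, 5, 6, 8, 9, 10, 11), multiplicative
factors on precipitation amounts (Bio12, 13, 14, 16, 17, 18, 19);
range/seasonality measures (Bio2, 3, 4, 7, 15) are invariant under a
uniform shift, and the Bio7 identity is restored after perturbation. The
default suite warms by 0.8/1.8/3.2 °C (2020s/2050s/2080s) scaled per
storyline (A2 1.25 > A1B 1.15 > B1 0.8) with ±0.2 °C GCM offsets and
+4 % precipitation per degree.

*What the generator does not emulate:* real WorldClim spatial
covariance, anisotropy, elevation structure, or the geometry of any
actual mountain range; observation error in coordinates; spatial
sampling bias of field campaigns. Passing tests therefore demonstrate
correctness and statistical behaviour of the pipeline under controlled
conditions, not predictive skill on real landscapes.

## Numerical choices and degenerate inputs

- Optimizer: trust-region reflective least squares, `xtol = 1e-8`,
  ≤ 10 000 evaluations; widths bounded below by 1e-12.
- Grid convention: row 0 is the northernmost row; a point belongs to the
  cell containing it under half-open intervals `[x0, x0+dx)`; geographic
  coordinates throughout, no reprojection.
- Raster dialects: ESRI ASCII grid (full-precision `repr` floats, hence
  lossless round-trips) and single-band GeoTIFF with pixel-scale,
  tiepoint and nodata tags. A per-variable scale factor on read (default
  1.0) accommodates archives that store temperature as °C × 10.
- Degenerate inputs raise typed errors rather than returning NaN:
  all-zero contents, constant variables, constant observations,
  all-constant weight matrices, zero valid cells.
- GCM averaging renormalizes mean percentages to exactly 100 and keeps
  integer cell-count bookkeeping consistent after rounding.

## Problem sizes

Defaults are chosen so the full test suite (including two complete
fit–validate–project loops) runs in seconds on one CPU: 48 × 64 cells,
300 samples, 27-scenario suites; the CLI and generator scale to larger
grids linearly in cell count.

## Known limitations

- A single 75/25 split, as in the reference protocol; k-fold machinery
  is out of scope.
- Weights from aggregate content are near-uniform by construction (see
  above); on real data with weaker cross-correlation among variables the
  entropy weights would differentiate more.
- Equal-area cell counting ignores the cos(latitude) area factor
  (≈ 4 % variation across a 2.4° window).
- No dispersal, land-cover or human-pressure constraints: projections
  are climate-envelope statements only.
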