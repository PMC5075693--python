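# habisuit

Quality-aware habitat-suitability modelling for medicinal plants.

Classical species-distribution models predict where a plant can occur;
for a medicinal species the question is also *how good* the plant is
where it grows. `habisuit` models a continuous quality signal — the
content of a marker metabolite measured at field sites (the reference
system is *Schisandra sphenanthera*, whose fruit lignan schisantherin A
defines pharmacopoeial quality) — as a function of the 19 standard
bioclimatic variables (Bio1–Bio19), and projects the fitted model under
future-climate scenarios. It is aimed at ecologists and pharmacognosists
who have site-level chemistry plus climate rasters and want a
transparent, non-black-box suitability surface.

## Model

1. **Standardize** contents to membership degrees: `x = content / c_max`,
   so the best observed sample has degree 1.
2. **Fit fuzzy membership curves** per variable: Gaussian
   `A(x) = exp(−((x−a)/σ)²)` (optimum `a`, width `σ`), a two-sided
   Gaussian with asymmetric widths, or a trapezoidal ramp
   `clip((x−z)/(o−z), 0, 1)` for single-boundary responses. The family
   with the best fitting degree, `100·(1 − RMSE)`, is selected.
3. **Weight variables** by the entropy method:
   `p_ij = x_ij/Σ_i x_ij`, `e_j = −Σ_i p_ij ln p_ij / ln m`,
   `w_j = (1−e_j)/Σ_k (1−e_k)` — dispersion across sites, not expert
   opinion, sets the weights.
4. **Aggregate** per cell: `y_i = Σ_j w_j x_ij ∈ [0, 1]`, the integrated
   ecological suitability index; classify into four grades
   (`y < 0.3` unsuitable, `0.3 ≤ y < 0.5` marginal, `0.5 ≤ y < 0.7`
   moderate, `y ≥ 0.7` high) and report grade areas.
5. **Validate** on a held-out 25 % split with RMSE and R², and
   **project** onto future bioclim stacks (emission scenario × GCM ×
   period), averaging grade shares over GCMs and regressing the
   highly-suitable share on climate summaries to locate disappearance
   thresholds.

A seeded synthetic-data generator (`habisuit.synthetic`) produces
complete co-varying 19-layer landscapes, planted truth models and noisy
sample tables, so the entire pipeline runs and is tested without any
external downloads. See `docs/methods.md` for the model's assumptions
and the generator's design.

## Worked example

Generate a synthetic workspace, fit, validate and map:

```sh
habisuit simulate --out demo --seed 0 --n-samples 300
habisuit fit --stack-dir demo/stack --samples demo/samples.csv \
             --model demo/model.json --seed 0
```

```
fitted 19 membership curves; fitting degree 93.23-94.15 %
  Bio1: weight 5.18 %
  Bio2: weight 5.33 %
  ...
model written to demo/model.json
```

Each curve's fitting degree is the percent goodness-of-fit on the
membership scale; the entropy weights (printed as percentages) sum
to 100.

```sh
habisuit validate --stack-dir demo/stack --samples demo/samples.csv \
                  --model demo/model.json --seed 0
```

```json
{
  "rmse": 0.0581,
  "r_squared": 0.9578,
  "n_train": 225,
  "n_test": 75,
  "n_excluded": 0,
  "split_seed": 0
}
```

The hold-out RMSE of 0.058 on the 0–1 membership scale means predicted
suitability at the 75 test sites deviates from observed normalized
content by ~6 points of membership on average — consistent with the
planted content noise of 0.05.

```sh
habisuit assess   --stack-dir demo/stack --model demo/model.json --out demo/surface.asc
habisuit classify --surface demo/surface.asc --out demo/grades.asc
habisuit stats    --grades demo/grades.asc
```

```
unsuitable: 23.16 % (697 cells)
marginal: 17.18 % (517 cells)
moderate: 16.78 % (505 cells)
high: 42.87 % (1290 cells)
valid cells: 3009
```

42.9 % of the valid landscape scores `y ≥ 0.7`: climatically optimal for
both growth and metabolite accumulation. `habisuit project` re-applies
the model to a directory of future rasters for a chosen
emission/GCM/period and reports the shifted grade shares; in Python,
`habisuit.simulate_scenarios` runs the full 27-combination suite on
delta-perturbed stacks and `habisuit.threshold_regression` estimates the
climate values at which highly suitable habitat disappears.

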