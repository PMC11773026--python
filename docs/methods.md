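# Methods

## The model

A processive formin at a filament barbed end survives each
subunit-addition cycle with a fixed probability, so its run length
(subunits added before release) is geometric and, in the continuum
limit, its lifetime is exponential with hazard `k_off`. The package
treats the hazard as the fundamental quantity and moves between three
equivalent parameterizations:

- per-time rate `k_off_time` (s⁻¹), measured from lifetime survival
  curves;
- per-step rate `k_off_step = k_off_time / elongation rate` (step⁻¹),
  measured from run-length survival curves;
- per-increment probabilities `p_off = 1 − exp(−k·Δ)` with `Δ = 1` step
  or `Δ = dt` seconds, consumed by the simulator. The inverse
  `k = −ln(1 − p)/Δ` makes these conversions exact round trips.

Run length and lifetime are linked by `run time = subunits / elongation
rate`, with 370 subunits per μm of filament.

The delivery dependence of the hazard is piecewise linear in the
fraction `f` of polymerized subunits that arrive via FH1-mediated
profilin–actin delivery:

    k_off(f) = k_basal                          f ≤ θ
             = k_basal + s·(f − θ)              f > θ

with defaults `k_basal = 0.0039 s⁻¹`, `s = 0.02 s⁻¹` per unit fraction
and `θ = 2/3` stored as the exact rational (a literal `0.67` mode
replays rounded-legend arithmetic; the two differ by at most
`s/300 ≈ 7·10⁻⁵ s⁻¹`). The threshold coincides with the point where two
consecutive FH1 deliveries (probability `f²`) become as likely as not
(`0.67² ≈ 0.449`), the proposed destabilizing event. `fit_piecewise`
holds θ fixed: the slope comes from unconstrained OLS on points above θ
and the basal rate from the mean of points at or below it — the upper
line is deliberately *not* constrained through `(θ, k_basal)`, matching
how the measured rates were fitted; on model-generated points the two
constructions coincide.

## Binding equilibria

Two actin species (unlabeled and labeled, the label weakening profilin
binding ten-fold) compete for one profilin pool. The per-species
isotherm `PA = A·P_free/(K_d + P_free)` with `A` the species total is
already exact in the actin budget (free actin = `A − PA`), so the only
approximation in the classic calculation is `P_free ≈ P_total`.
`solve_shared_profilin` removes it by solving

    P + Σᵢ Aᵢ·P/(K_dᵢ + P) = P_total

for the free-profilin root (strictly monotone residual; Brent's method,
1e-10 μM). For the standard Sc mix (0.5/0.25 μM actin, 5 μM profilin)
the approximation overestimates total PA by ~3%. The per-species modes
(`solve_independent_species`, weak or quadratic isotherm) are retained
for comparison with the original analysis; the quadratic uses the
cancellation-stable root form `2AP/(b + √(b² − 4AP))`.

The labeled/unlabeled PA ratio feeds the fluorescence deconvolution:
`FH1_total = FH1_black·(1 + ratio)`. Because measurement noise can push
the normalized fluorescence above 1 or the summed fraction above 1,
out-of-range values are clamped into [0, 1] with a logged warning, the
components rescaled proportionally so the sum identity survives, and
the raw ratio kept in the result for audit.

## Survival fitting

The empirical survivor function is evaluated at the observed values (no
binning; histograms are display-only). The default estimator is
unweighted nonlinear least squares of `A·exp(−k·x)` with free
amplitude, mirroring the experimental analysis: under-detection of
short dim stretches pushes the fitted intercept above 1, which a fixed
`A = 1` fit would convert into rate bias. First-point omission defaults
on in the length domain (where that under-representation lives) and off
in the time domain; both are flags.

Confidence interval: the covariance matrix of the NLS fit is *not* used
for the reported CI. Survival-curve points are serially correlated, and
the regression covariance understates the sampling error of the rate
roughly ten-fold (measured coverage ~21% at n = 70). The package
reports the exponential information-bound interval
`k·(1 ± 1.96/√n)` instead, which covers the truth ~93% of the time at
n = 70 in simulation (mildly anticonservative at large n because the
NLS estimator is slightly less efficient than the MLE). The raw
covariance is retained on the fit result.

A censoring-aware MLE (`events / total observed time`, censored
exposure included) is provided as the preferred estimator whenever many
runs are censored — e.g. simulator output with per-filament time
budgets — since it is unbiased under any censoring schedule.

## Simulator

Each filament is an independent Bernoulli-increment chain: draw a
uniform, dissociate if it falls below `p_off`, otherwise elongate one
increment (1 subunit in `per_step` mode; `elongation rate × dt`
subunits in `per_time` mode, default `dt = 0.01 s`). The dissociation
test precedes elongation, so a first-increment failure records length
zero. The number of survived increments is geometric, so the default
fast path samples it by inversion from a single uniform; the literal
loop is retained and the two are distributionally indistinguishable
(two-sample KS across 20 seeds in the test suite). The literal loop at
the full published scale would draw ~1.4·10⁹ uniforms, hence the fast
path as default.

Populations follow the published bookkeeping: 12,000 filaments, 20%
present at t = 0 and the rest nucleating at 8 s⁻¹ (deterministic,
one per 1/8 s, since the schedule is described as a constant rate; a
Poisson-arrival option exists) over a 1200 s reaction. Every filament
draws from its own substream spawned from (seed, index), so output is
independent of iteration order and byte-identical across reruns.

Time budgets: by default every filament may run for the full reaction
duration, and filaments still bound at the end are counted (optionally
recorded) as censored. With `k ≈ 0.0035 s⁻¹` the 1200 s window spans
~4.2 mean lifetimes, so excluding the ~1.5–2% censored runs leaves a
mildly truncated exponential and the naive survival refit lands ~3%
above the input hazard — visible in the worked example and the
acceptance output, and removed entirely by lengthening the window or
using the censoring-aware MLE. The alternative `budget="remaining"`
truncates each filament at `duration − nucleation time`; that censors
late-nucleating filaments so heavily (~20% of the population) that
naive survival fits inflate by ~25%, which is why it is not the
default and why its output should be fitted with the MLE.

The FH1 sweep converts `predict_koff(f)` to `p_off_time` per cell and
simulates one population per (elongation rate, f) pair; the hazard per
cell is fixed, not re-drawn per subunit by delivery mode.

## Synthetic data

The generator treats the lifetime as the primitive exponential variable
and derives run length as `rate × lifetime` with per-filament Gaussian
elongation-rate noise (truncated positive by resampling), which links
the two fit domains exactly as the measurements do. Fluorescence is
generated by inverting the deconvolution at the true delivered fraction
with multiplicative Gaussian noise, so the analysis recovers the truth
exactly at zero noise and within ~3 noise SDs otherwise. An optional
detection filter drops uncensored runs below 500 subunits, reproducing
the above-unity fitted intercepts of the real curves.

What the generator does *not* emulate: photobleaching, spatial filament
interactions, stage drift, per-frame localization error, or any
dependence of the elongation rate on time. Passing recovery tests
therefore demonstrate correctness of the estimators under the assumed
statistical model, not robustness to those instrumental effects.

The preset condition grid spans the published reactions (Sc profilin at
0.75 and 1 μM actin, Hs profilin, and the FH1FH2 / PCPD-FH2 / FH1FH2-C
constructs). True per-condition elongation rates and delivered
fractions are published only as figure points, so presets use smooth
representative placeholder maps from the computed profilin–actin level
(5→25 subunits/s; f rising toward 0.95, reduced 40% for the
polyproline-dead construct) and basal rates in the published
0.0035–0.0039 s⁻¹ band; these are flagged non-authoritative in the
docstrings. Each preset's true `k_off` comes from the piecewise model,
so a fit across the grid is a closed-loop recovery test (it returns the
generating basal rate and slope within 10% at n = 12,000 over 10
seeds).

## Problem sizes and numerical choices

Default simulations use the published 12,000-filament scale, which runs
in well under a second via the fast path; validation suites that use the
literal loop or many replicates run at n = 2,000–4,000, sizes at which
the distributional tests retain their power. Root finding uses a
bracketed monotone residual (no convergence failures possible in exact
arithmetic); the binding quadratic uses the stable root form; fits are
seeded from the sample mean and bounded to positive rates; ties in the
survival curve collapse to single points with the correct step height;
degenerate inputs (fewer than 2 uncensored records, fewer than 4 curve
points, no events) raise data errors naming the problem.

## Known limitations

- The pipeline's model stage needs several conditions on both sides of
  the threshold; single-condition runs skip it.
- The information-bound CI is approximate for the NLS estimator (exact
  only for the MLE); at n ≳ 10³ its coverage drifts a few points below
  nominal.
- The simulator models hazard per increment only: no force dependence,
  no capping-protein competition, no two-color tracking within a
  filament, no spatial structure.
- Nucleation timing affects only bookkeeping and the `remaining`-budget
  mode; filament dynamics are otherwise exchangeable, so population
  summaries do not resolve time-dependent nucleation effects.
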