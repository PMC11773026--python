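# forminsim

Quantitative analysis of **formin processivity** — how long a formin such as
budding-yeast Bni1p stays attached to the growing barbed end of an actin
filament, and how profilin-mediated (FH1) delivery of subunits shortens that
association.

The package is aimed at single-molecule biophysicists analysing TIRF
measurements of formin-assembled filaments, and at modellers who want a
validated stochastic simulator of processive filament elongation. It provides:

- **Binding equilibria** (`forminsim.equilibria`) — profilin–actin (PA)
  concentrations for two-color reactions where unlabeled and labeled actin
  (Kd 2.9 vs 29 μM for *S. cerevisiae* profilin, 0.1 vs 1.0 μM for human
  profilin-1) compete for one profilin pool. Hyperbolic isotherm
  `[PA] = [A][P_free]/(K_d + [P_free])`, tight-binding quadratic, and an
  exact coupled-conservation solver.
- **Survival analysis** (`forminsim.survival`) — empirical survival curves of
  formin run lengths (subunits, 370 per μm) or run times
  (`t = subunits / elongation rate`), single-exponential fits
  `S(x) = A·e^(−k·x)` giving the dissociation rate `k_off` and mean run
  length `1/k`, plus the hazard↔probability conversions
  `p_off = 1 − e^(−k·Δ)` used by the simulator, and a censoring-aware MLE.
- **FH1-delivery deconvolution** (`forminsim.fh1`) — the fraction of subunits
  delivered by the FH1 domain from segment fluorescence:
  `FH1_black = 1 − F_formin/F_control`, `FH1_green = FH1_black · [PA_g]/[PA_b]`,
  total = sum.
- **Piecewise dissociation model** (`forminsim.dissociation`) —
  `k_off(f) = k_basal` for `f ≤ 2/3` and `k_basal + slope·(f − 2/3)` above,
  with published Bni1p values `k_basal = 0.0039 s⁻¹`, `slope = 0.02 s⁻¹`;
  fixed-breakpoint fitting and derived quantities.
- **Stochastic simulator** (`forminsim.simulate`) — populations of
  independent Bernoulli-increment filaments (per-step or per-Δt dissociation
  tests), the published nucleation schedule (2,400 initial + 8 filaments/s
  over 1200 s = 12,000), a geometric fast path equivalent to the literal
  loop, and the run-length sweep over FH1 fractions and elongation rates.
- **Synthetic data + pipeline** (`forminsim.synthetic`, `forminsim.pipeline`)
  — generators with known truth for every measured quantity, a staged
  analysis pipeline with checksummed manifests, and replicate
  parameter-recovery reports.

## Worked example

Simulate the published 5 μM-profilin condition and refit it
(`examples/05_population_simulation.py`):

```python
from forminsim import (SimulationConfig, p_off_time_from_rate,
                       simulate_population, summarize_population)

config = SimulationConfig(
    elongation_rate=18.55,                      # subunits/s
    p_off=p_off_time_from_rate(0.0035, 0.01),   # hazard 0.0035 s^-1, dt 0.01 s
    mode="per_time",
    seed=7,
)
result = simulate_population(config)
summary = summarize_population(result)
```

prints

```
nucleated 12000 filaments (11826 dissociated, 174 still bound at 1200 s)
fitted k_off        : 0.00362 s^-1 (input 0.0035)
fitted mean length  : 5131 subunits (expected ~5300)
10 replicates       : k_off 0.00363 +/- 0.000029 s^-1, length 5115 +/- 41 subunits
```

The survival refit recovers the input hazard to within a few percent (the
1200 s reaction truncates runs at ~4 mean lifetimes, which biases the naive
survival fit slightly high — see `docs/methods.md`), and the fitted mean
run length matches the closed form elongation rate / k_off ≈ 5300 subunits.

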