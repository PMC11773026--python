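"""Simulated run lengths across FH1-delivery fractions and growth rates.

For each (elongation rate, delivered fraction) the piecewise model sets
the hazard; populations are simulated and their mean run lengths
refitted.  Below the two-thirds threshold run length depends only on the
growth rate; above it, runs shorten and the rate curves converge.
"""

from forminsim import DissociationModel, SimulationConfig, simulate_fh1_sweep

config = SimulationConfig(
    elongation_rate=15.0,  # overridden per sweep cell
    p_off=0.0,  # overridden per sweep cell
    mode="per_time",
    n_filaments=3000,
    duration=5e4,
    nucleation_rate=0.0,
    initial_pool_fraction=1.0,
    seed=11,
)
table = simulate_fh1_sweep(
    elongation_rates=[5.0, 15.0, 25.0, 35.0],
    f_grid=[0.0, 0.3, 0.6, 0.8, 1.0],
    model=DissociationModel.bni1_default(),
    config=config,
)
pivot = table.pivot(index="f_fh1", columns="elongation_rate", values="mean_run_length")
print("mean run length (subunits) by FH1 fraction (rows) and sub/s (columns):")
print(pivot.round(0).to_string())

# Each column is flat up to f ~ 2/3 (constant basal hazard) and then
# drops; the 35 sub/s column starts ~7x the 5 sub/s one but the spread
# narrows as delivery dominates - the run-length convergence phenomenon.
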