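"""Stochastic population simulator: bookkeeping, determinism, distributions."""

import math

import numpy as np
import pytest
from scipy.stats import ks_2samp

from forminsim import (
    DissociationModel,
    SimulationConfig,
    simulate_fh1_sweep,
    simulate_filament,
    simulate_population,
    simulate_replicates,
    summarize_population,
)

P_5300 = 1 - math.exp(-1 / 5300)  # per-step probability for a 5300-subunit mean run


def quick_config(**overrides):
    """Small single-cohort config with censoring made negligible."""
    base = dict(
        elongation_rate=18.55,
        p_off=P_5300,
        mode="per_step",
        n_filaments=2000,
        duration=1e5,
        nucleation_rate=0.0,
        initial_pool_fraction=1.0,
        seed=0,
    )
    base.update(overrides)
    return SimulationConfig(**base)


class TestConfigValidation:
    def test_mismatched_pool_and_nucleation_warns(self):
        with pytest.warns(UserWarning, match="n_filaments"):
            SimulationConfig(
                elongation_rate=10.0, p_off=0.001, n_filaments=5000
            )  # 1000 + 9600 != 5000

    def test_paper_defaults_are_consistent(self, recwarn):
        cfg = SimulationConfig(elongation_rate=10.0, p_off=0.001)
        assert cfg.n_filaments == 12000
        assert not [w for w in recwarn if issubclass(w.category, UserWarning)]

    @pytest.mark.parametrize(
        "bad",
        [
            {"p_off": 1.0},
            {"p_off": -0.1},
            {"dt": 0.0},
            {"duration": -1.0},
            {"elongation_rate": 0.0},
            {"mode": "per_frame"},
        ],
    )
    def test_hard_invariants_raise(self, bad):
        kwargs = dict(elongation_rate=10.0, p_off=0.001)
        kwargs.update(bad)
        with pytest.raises(ValueError):
            SimulationConfig(**kwargs)


class TestSingleFilament:
    def test_near_certain_dissociation_is_immediate(self):
        rng = np.random.default_rng(0)
        rec = simulate_filament(0.999999, "per_step", 10.0, 0.01, 100.0, rng)
        assert rec.run_length_subunits <= 1
        assert not rec.censored

    def test_zero_p_off_censors_at_full_length(self):
        rng = np.random.default_rng(0)
        rec = simulate_filament(0.0, "per_time", 12.0, 0.01, 50.0, rng)
        assert rec.censored
        assert rec.run_length_subunits == pytest.approx(12.0 * 50.0)
        assert rec.run_time == pytest.approx(50.0)

    def test_geometric_mean_run_length(self):
        # sample mean of per-step runs ~ (1-p)/p ~ 5300 subunits
        result = simulate_population(quick_config(n_filaments=12000, seed=8))
        lengths = result.records["run_length_subunits"].to_numpy()
        expected = (1 - P_5300) / P_5300
        se = lengths.std(ddof=1) / np.sqrt(lengths.size)
        assert abs(lengths.mean() - expected) < 3 * se

    def test_invalid_arguments(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            simulate_filament(1.0, "per_step", 10.0, 0.01, 100.0, rng)
        with pytest.raises(ValueError):
            simulate_filament(0.1, "per_step", 10.0, 0.01, 0.0, rng)


class TestPopulation:
    def test_default_schedule_nucleates_twelve_thousand(self):
        cfg = SimulationConfig(elongation_rate=18.55, p_off=3.5e-5, seed=1)
        result = simulate_population(cfg)
        assert result.n_dissociated + result.n_censored == 12000
        # 20% initial pool, remainder at 8 filaments/s over 1200 s
        assert round(cfg.initial_pool_fraction * cfg.n_filaments) == 2400
        assert round(cfg.nucleation_rate * cfg.duration) == 9600

    def test_all_filaments_at_time_zero_without_nucleation(self):
        result = simulate_population(quick_config(n_filaments=100, record_censored=True))
        assert (result.records["nucleation_time_s"] == 0.0).all()

    def test_deterministic_for_fixed_seed(self):
        cfg = quick_config(n_filaments=500, seed=77)
        a = simulate_population(cfg).records
        b = simulate_population(cfg).records
        assert a.to_csv(index=False) == b.to_csv(index=False)

    def test_conservation_of_counts(self):
        for seed in range(5):
            cfg = quick_config(n_filaments=300, duration=2e5, seed=seed, mode="per_time",
                               p_off=1e-4, record_censored=True)
            res = simulate_population(cfg)
            assert res.n_dissociated + res.n_censored == cfg.n_filaments
            assert len(res.records) == cfg.n_filaments
            assert (res.records["run_length_subunits"] >= 0).all()

    def test_remaining_budget_mode_truncates_by_nucleation_time(self):
        cfg = SimulationConfig(
            elongation_rate=10.0,
            p_off=0.0,
            mode="per_time",
            n_filaments=100,
            duration=100.0,
            nucleation_rate=0.9,
            initial_pool_fraction=0.1,
            record_censored=True,
            budget="remaining",
        )
        res = simulate_population(cfg)
        slack = res.records["run_time_s"] + res.records["nucleation_time_s"]
        assert (slack <= cfg.duration + 1e-9).all()
        assert res.n_censored == cfg.n_filaments  # p_off = 0 never dissociates

    def test_censored_records_hidden_by_default(self):
        cfg = quick_config(n_filaments=200, p_off=0.0, mode="per_time")
        res = simulate_population(cfg)
        assert res.n_censored == 200
        assert len(res.records) == 0


class TestFastPathEquivalence:
    def test_fast_and_literal_distributions_match(self):
        # two-sample KS across 20 seeds; fast path must be statistically
        # indistinguishable from the literal increment-by-increment loop
        pvals, mean_ok = [], 0
        for seed in range(20):
            fast = simulate_population(quick_config(seed=seed, fast_path=True))
            lit = simulate_population(quick_config(seed=seed + 1000, fast_path=False))
            a = fast.records["run_length_subunits"].to_numpy()
            b = lit.records["run_length_subunits"].to_numpy()
            pvals.append(ks_2samp(a, b).pvalue)
            se = math.hypot(a.std(ddof=1) / math.sqrt(a.size), b.std(ddof=1) / math.sqrt(b.size))
            mean_ok += abs(a.mean() - b.mean()) < 3 * se
        assert sum(p > 0.01 for p in pvals) >= 18
        assert min(pvals) > 1e-3
        assert mean_ok >= 18


class TestPerTimeHazardRecovery:
    @pytest.mark.parametrize("k, seed", [(0.0035, 0), (0.0039, 1), (0.0105, 2)])
    def test_fitted_rate_within_ci_of_hazard(self, k, seed):
        p = 1 - math.exp(-k * 0.01)
        cfg = quick_config(
            mode="per_time", p_off=p, n_filaments=12000, duration=50 / k, seed=seed
        )
        summary = summarize_population(simulate_population(cfg))
        lo, hi = summary.fitted_k_off * (1 - 1.96 / math.sqrt(12000)), summary.fitted_k_off * (
            1 + 1.96 / math.sqrt(12000)
        )
        assert lo <= k <= hi


class TestSummaries:
    def test_replicate_summary_deterministic(self):
        cfg = quick_config(n_filaments=800, seed=9)
        s1 = summarize_population(simulate_replicates(cfg, 10))
        s2 = summarize_population(simulate_replicates(cfg, 10))
        assert s1.mean_run_length == s2.mean_run_length
        assert s1.sd_run_length == s2.sd_run_length
        assert s1.n_replicates == 10

    def test_single_replicate_has_no_sd(self):
        summary = summarize_population(simulate_population(quick_config(seed=2)))
        assert summary.sd_run_length is None
        assert summary.sd_k_off is None

    def test_replicate_mean_rate_near_truth(self):
        k = 0.0035
        cfg = quick_config(
            mode="per_time",
            p_off=1 - math.exp(-k * 0.01),
            n_filaments=3000,
            duration=50 / k,
            seed=13,
        )
        summary = summarize_population(simulate_replicates(cfg, 8))
        assert abs(summary.fitted_k_off - k) < 2 * summary.sd_k_off

    def test_too_few_events_rejected(self):
        cfg = quick_config(n_filaments=5, p_off=0.0, mode="per_time")
        with pytest.raises(ValueError, match="few"):
            summarize_population(simulate_population(cfg))


@pytest.fixture(scope="module")
def sweep_table():
    model = DissociationModel.bni1_default()
    cfg = SimulationConfig(
        elongation_rate=15.0,
        p_off=0.0,
        mode="per_time",
        n_filaments=3000,
        duration=5e4,
        nucleation_rate=0.0,
        initial_pool_fraction=1.0,
        seed=21,
    )
    return simulate_fh1_sweep([5.0, 35.0], [0.0, 0.3, 0.6, 0.5, 1.0], model, cfg)


class TestSweep:
    def test_flat_regime_below_threshold(self, sweep_table):
        sub = sweep_table[(sweep_table.elongation_rate == 35.0) & (sweep_table.f_fh1 <= 0.6)]
        means = sub["mean_run_length"].to_numpy()
        n = sub["n_dissociated"].to_numpy()
        se = np.hypot.reduce(means / np.sqrt(n))
        assert means.max() - means.min() < 3 * se

    def test_delivery_dominated_runs_are_shorter(self, sweep_table):
        at35 = sweep_table[sweep_table.elongation_rate == 35.0].set_index("f_fh1")
        ratio = at35.loc[1.0, "mean_run_length"] / at35.loc[0.5, "mean_run_length"]
        # hazard rises 0.0039 -> 0.0039 + 0.02/3 ~ 0.01057: lengths shrink accordingly
        expected = 0.0039 / (0.0039 + 0.02 * (1 - 2 / 3))
        assert ratio == pytest.approx(expected, rel=0.10)
        assert at35.loc[1.0, "mean_run_length"] < at35.loc[0.5, "mean_run_length"]

    def test_run_length_proportional_to_elongation_rate(self, sweep_table):
        at_half = sweep_table[sweep_table.f_fh1 == 0.5].set_index("elongation_rate")
        ratio = at_half.loc[35.0, "mean_run_length"] / at_half.loc[5.0, "mean_run_length"]
        assert ratio == pytest.approx(7.0, rel=0.05)

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError):
            simulate_fh1_sweep([0.0], [0.5], DissociationModel.bni1_default(),
                               quick_config(mode="per_time"))
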