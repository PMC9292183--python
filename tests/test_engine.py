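import numpy as np
import pytest

from tigrisim import (
    DemographyParams,
    Population,
    SimulationConfig,
    config_hash,
    initialize_population,
    make_deterministic_schedule,
    run_ensemble,
    run_realisation,
    step,
)


class TestConfig:
    def test_defaults_match_study_conditions(self):
        cfg = SimulationConfig(regime="deterministic", period=3)
        assert cfg.initial_n == 5000
        assert cfg.horizon == 150
        assert cfg.juvenile_to_adult_ratio == 25
        assert cfg.n_realisations == 100
        assert (cfg.mu_min, cfg.mu_max) == (0.02, 0.04)

    @pytest.mark.parametrize("kwargs", [
        {"regime": "weekly", "period": 3},
        {"regime": "deterministic", "period": 0},
        {"regime": "deterministic", "period": 3, "initial_n": 1},
        {"regime": "deterministic", "period": 3, "scale_factor": 0.0},
        {"regime": "deterministic", "period": 3, "scale_factor": 1.5},
        {"regime": "deterministic", "period": 3, "horizon": 0},
    ])
    def test_invariant_violations_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(**kwargs)

    def test_scale_factor_shrinks_population_and_density_constant(self):
        cfg = SimulationConfig(regime="deterministic", period=3, scale_factor=0.1)
        assert cfg.scaled_initial_n == 500
        assert cfg.scaled_dd_scale == 25_000

    def test_hash_stable_under_field_reordering(self):
        cfg = SimulationConfig(regime="stochastic", period=14, master_seed=5)
        d = cfg.to_dict()
        shuffled = dict(reversed(list(d.items())))
        assert config_hash(SimulationConfig.from_dict(shuffled)) == config_hash(cfg)


class TestInitialisation:
    def test_default_stage_structure(self, rng):
        cfg = SimulationConfig(regime="deterministic", period=3)
        pop = initialize_population(cfg, rng)
        assert pop.size == 5000
        assert pop.n_juvenile == 4808   # round(5000 * 25/26)
        assert pop.n_adult == 192

    def test_founder_traits_span_measured_ranges(self, rng):
        cfg = SimulationConfig(regime="deterministic", period=3)
        pop = initialize_population(cfg, rng)
        assert pop.mu.min() >= 0.02 and pop.mu.max() <= 0.04
        assert pop.f.min() >= 6.25 and pop.f.max() <= 12.50
        np.testing.assert_allclose(pop.f, 1.0 / (4.0 * pop.mu))
        assert np.all((pop.s >= 0) & (pop.s < 3.0))

    def test_same_seed_reproduces_founding_population(self):
        cfg = SimulationConfig(regime="deterministic", period=3, initial_n=200)
        a = initialize_population(cfg, np.random.default_rng(3))
        b = initialize_population(cfg, np.random.default_rng(3))
        np.testing.assert_array_equal(a.s, b.s)
        np.testing.assert_array_equal(a.mu, b.mu)


class TestStep:
    def test_empty_population_passes_through(self, small_config, rng):
        pop = Population(np.empty(0), np.empty(0), np.empty(0), t=0)
        sched = make_deterministic_schedule(3, 20)
        pop2, rec = step(pop, sched, small_config, rng)
        assert pop2.size == 0
        assert rec.births == rec.total_deaths == 0
        assert np.isnan(rec.mean_mu)

    def test_conservation_identity_every_step(self, small_config):
        sched = make_deterministic_schedule(small_config.period,
                                            small_config.horizon)
        rng = np.random.default_rng(11)
        pop = initialize_population(small_config, rng)
        for _ in range(small_config.horizon):
            n_before = pop.size
            pop, rec = step(pop, sched, small_config, rng)
            assert rec.n_total == n_before + rec.births - rec.total_deaths
            assert rec.n_total == rec.n_juvenile + rec.n_adult
            assert min(rec.births, rec.deaths_juvenile_hazard,
                       rec.deaths_adult_hazard, rec.deaths_density,
                       rec.deaths_age, rec.deaths_disturbance) >= 0

    def test_single_adult_births_match_fecundity(self, small_config):
        # Poisson(f) newborns per adult per day; disturbance-free day,
        # density dependence negligible at N ~ 1
        sched = make_deterministic_schedule(19, 20)
        rng = np.random.default_rng(21)
        births = []
        for _ in range(10_000):
            pop = Population(np.array([1.5]), np.array([0.0278]),
                             np.array([9.0]), t=0,
                             founding_mean_mu=0.03, founding_mean_f=8.66)
            _, rec = step(pop, sched, small_config, rng)
            births.append(rec.births)
        assert np.mean(births) == pytest.approx(9.0, abs=0.1)

    def test_adults_unaffected_by_disturbance(self, small_config, rng):
        sched = make_deterministic_schedule(1, 20)  # disturb every day
        pop = Population(np.array([1.2, 1.5, 2.0]), np.full(3, 1e-6),
                         np.full(3, 1e-6), t=0,
                         founding_mean_mu=0.03, founding_mean_f=8.66)
        _, rec = step(pop, sched, small_config, rng)
        assert rec.disturbed
        assert rec.deaths_disturbance == 0

    def test_newborn_same_day_hazard_knob_conserves(self):
        cfg = SimulationConfig(regime="deterministic", period=3, initial_n=100,
                               horizon=10, newborn_same_day_hazards=True)
        traj = run_realisation(cfg, 5)
        for prev, rec in zip(traj.records, traj.records[1:]):
            assert rec.n_total == prev.n_total + rec.births - rec.total_deaths


class TestRealisation:
    def test_record_count_and_reproducibility(self, small_config):
        a = run_realisation(small_config, 123)
        b = run_realisation(small_config, 123)
        assert len(a.records) == small_config.horizon + 1
        assert a.records == b.records
        np.testing.assert_array_equal(a.endpoint_mu, b.endpoint_mu)

    @pytest.mark.parametrize("period, expected_disturbed", [(3, 6), (7, 2)])
    def test_disturbed_flags_match_schedule(self, period, expected_disturbed):
        cfg = SimulationConfig(regime="deterministic", period=period,
                               initial_n=100, horizon=20)
        traj = run_realisation(cfg, 1)
        assert sum(r.disturbed for r in traj.records) == expected_disturbed

    def test_stochastic_and_deterministic_apply_equal_event_counts(self):
        for seed in range(5):
            det = run_realisation(SimulationConfig(
                regime="deterministic", period=14, initial_n=50, horizon=60), seed)
            stoch = run_realisation(SimulationConfig(
                regime="stochastic", period=14, initial_n=50, horizon=60), seed)
            assert (sum(r.disturbed for r in det.records)
                    == sum(r.disturbed for r in stoch.records)
                    == 60 // 14)

    def test_extinction_recorded_as_missing_not_zero(self):
        lethal = DemographyParams(juvenile_mort_coeff=60.0, adult_mort_coeff=0.5)
        cfg = SimulationConfig(regime="deterministic", period=2, initial_n=20,
                               horizon=80, demography=lethal)
        traj = run_realisation(cfg, 9)
        assert traj.extinct
        assert traj.extinction_time is not None
        assert traj.records[-1].n_total == 0
        assert np.isnan(traj.endpoint_var("mu"))
        assert np.isnan(traj.records[-1].var_mu)


class TestEnsemble:
    def test_size_and_distinctness(self, small_config):
        trajs = run_ensemble(small_config, n_realisations=5, master_seed=17)
        assert len(trajs) == 5
        finals = {tuple(t.records[-1].__dict__.items()) for t in trajs}
        assert len(finals) == 5  # derived seeds are disjoint

    def test_ensemble_reproducible_from_master_seed(self, small_config):
        a = run_ensemble(small_config, 3, master_seed=8)
        b = run_ensemble(small_config, 3, master_seed=8)
        for ta, tb in zip(a, b):
            assert ta.records == tb.records
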