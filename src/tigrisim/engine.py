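"""Time-stepping population simulator.

A realisation initialises a population of ~5000 individuals (25:1
juveniles:adults, founding maturation rates uniform on [0.02, 0.04]) and
advances it day by day for the configured horizon under one of four
disturbance regimes (deterministic/stochastic x Fast/Slow).  Within each
day the sub-steps run in a fixed order:

1. disturbance (if the new day is on the schedule) removes 30% of juveniles;
2. growth by ``mu`` per individual, with end-of-life deaths at s >= 3;
3. trait-linked hazard mortality (juveniles at rate 5*mu, adults at 0.001*f);
4. reproduction: each surviving adult appends Poisson(f) newborns at s = 0,
   which inherit parental traits plus a small Gaussian error;
5. density-dependent removal on the full post-birth roster.

Newborns are exempt from sub-steps 1-3 on the day of their birth (they
cannot die before existing for one full day) but are part of the end-of-day
census on which density dependence acts.  The ordering is centralised in
:func:`step` so alternatives can be probed; the one knob exposed is
``newborn_same_day_hazards``.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .demography import (
    DemographyParams,
    Individual,
    adult_mortality_prob,
    apply_disturbance,
    density_removal_count,
    juvenile_mortality_prob,
    mutate_traits,
    tradeoff_fecundity,
)
from .environment import (
    DETERMINISTIC,
    STOCHASTIC,
    DisturbanceSchedule,
    make_deterministic_schedule,
    make_stochastic_schedule,
)

__all__ = [
    "SimulationConfig",
    "Population",
    "StepRecord",
    "Trajectory",
    "initialize_population",
    "step",
    "run_realisation",
    "run_ensemble",
    "config_hash",
]


@dataclass(frozen=True)
class SimulationConfig:
    """All demographic and environmental constants of one study condition.

    ``scale_factor`` shrinks ``initial_n`` and the density scaling constant
    ``dd_scale`` proportionally, preserving per-capita density dependence at
    equal relative density; it exists so ensembles can be replicated at
    desk scale.
    """

    regime: str
    period: int
    initial_n: int = 5000
    juvenile_to_adult_ratio: float = 25.0
    horizon: int = 150
    n_realisations: int = 100
    master_seed: int = 0
    scale_factor: float = 1.0
    newborn_same_day_hazards: bool = False
    demography: DemographyParams = field(default_factory=DemographyParams)

    def __post_init__(self) -> None:
        if self.regime not in (DETERMINISTIC, STOCHASTIC):
            raise ValueError(
                f"regime must be '{DETERMINISTIC}' or '{STOCHASTIC}', "
                f"got {self.regime!r}")
        if self.period < 1:
            raise ValueError("period must be >= 1 day")
        if self.initial_n < 2:
            raise ValueError("initial_n must be >= 2")
        if self.horizon < 1:
            raise ValueError("horizon must be >= 1 day")
        if self.n_realisations < 1:
            raise ValueError("n_realisations must be >= 1")
        if not 0.0 < self.scale_factor <= 1.0:
            raise ValueError("scale_factor must lie in (0, 1]")
        if self.juvenile_to_adult_ratio <= 0:
            raise ValueError("juvenile_to_adult_ratio must be positive")

    @property
    def mu_min(self) -> float:
        return self.demography.mu_min

    @property
    def mu_max(self) -> float:
        return self.demography.mu_max

    @property
    def scaled_initial_n(self) -> int:
        return int(round(self.initial_n * self.scale_factor))

    @property
    def scaled_dd_scale(self) -> float:
        return self.demography.dd_scale * self.scale_factor

    def make_schedule(self, rng: np.random.Generator) -> DisturbanceSchedule:
        if self.regime == DETERMINISTIC:
            return make_deterministic_schedule(self.period, self.horizon)
        return make_stochastic_schedule(self.period, self.horizon, rng)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        demo = d.pop("demography", None)
        if demo is not None:
            d["demography"] = DemographyParams(**demo)
        return cls(**d)


def config_hash(config: SimulationConfig) -> str:
    """Short stable hash of a config (field-order independent)."""
    payload = json.dumps(config.to_dict(), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class Population:
    """The i-state configuration: one entry per living individual.

    Stored struct-of-arrays for speed; :meth:`individuals` offers the
    per-organism view.
    """

    s: np.ndarray
    mu: np.ndarray
    f: np.ndarray
    t: int = 0
    founding_mean_mu: float = np.nan
    founding_mean_f: float = np.nan

    @property
    def size(self) -> int:
        return self.s.size

    @property
    def n_juvenile(self) -> int:
        return int(np.count_nonzero(self.s < 1.0))

    @property
    def n_adult(self) -> int:
        return int(np.count_nonzero(self.s >= 1.0))

    def individuals(self) -> list[Individual]:
        return [Individual(float(s), float(m), float(fv))
                for s, m, fv in zip(self.s, self.mu, self.f)]

    def _keep(self, mask: np.ndarray) -> None:
        self.s, self.mu, self.f = self.s[mask], self.mu[mask], self.f[mask]


@dataclass(frozen=True)
class StepRecord:
    """Per-day population summary with death counts reconciled by cause."""

    t: int
    n_total: int
    n_juvenile: int
    n_adult: int
    mean_mu: float
    var_mu: float
    mean_f: float
    var_f: float
    births: int
    deaths_juvenile_hazard: int
    deaths_adult_hazard: int
    deaths_density: int
    deaths_age: int
    deaths_disturbance: int
    disturbed: bool

    @property
    def total_deaths(self) -> int:
        return (self.deaths_juvenile_hazard + self.deaths_adult_hazard
                + self.deaths_density + self.deaths_age
                + self.deaths_disturbance)


def _summarise(pop: Population, *, births: int = 0, d_juv: int = 0,
               d_adu: int = 0, d_dens: int = 0, d_age: int = 0,
               d_dist: int = 0, disturbed: bool = False) -> StepRecord:
    n = pop.size
    return StepRecord(
        t=pop.t,
        n_total=n,
        n_juvenile=pop.n_juvenile,
        n_adult=pop.n_adult,
        mean_mu=float(np.mean(pop.mu)) if n else np.nan,
        var_mu=float(np.var(pop.mu, ddof=1)) if n > 1 else np.nan,
        mean_f=float(np.mean(pop.f)) if n else np.nan,
        var_f=float(np.var(pop.f, ddof=1)) if n > 1 else np.nan,
        births=births,
        deaths_juvenile_hazard=d_juv,
        deaths_adult_hazard=d_adu,
        deaths_density=d_dens,
        deaths_age=d_age,
        deaths_disturbance=d_dist,
        disturbed=disturbed,
    )


def initialize_population(
    config: SimulationConfig, rng: np.random.Generator
) -> Population:
    """Found a population at the configured size and stage structure.

    Juveniles (25 of every 26 individuals by default) start at states
    uniform on [0, 1), adults uniform on [1, 3).  Founding maturation rates
    are independent uniform draws on [mu_min, mu_max] and fecundities
    follow the trade-off exactly; the founding trait means are recorded on
    the population because they set the inheritance-noise scale.
    """
    n = config.scaled_initial_n
    ratio = config.juvenile_to_adult_ratio
    n_juv = int(round(n * ratio / (ratio + 1.0)))
    n_adu = n - n_juv
    s = np.concatenate([rng.uniform(0.0, 1.0, n_juv),
                        rng.uniform(1.0, 3.0, n_adu)])
    mu = rng.uniform(config.mu_min, config.mu_max, n)
    f = tradeoff_fecundity(mu)
    return Population(
        s=s, mu=mu, f=np.asarray(f), t=0,
        founding_mean_mu=float(np.mean(mu)),
        founding_mean_f=float(np.mean(f)),
    )


def _effective_params(config: SimulationConfig, pop: Population) -> DemographyParams:
    params = config.demography
    if np.isfinite(pop.founding_mean_mu) and np.isfinite(pop.founding_mean_f):
        params = params.with_means(pop.founding_mean_mu, pop.founding_mean_f)
    if config.scale_factor != 1.0:
        params = replace(params, dd_scale=config.scaled_dd_scale)
    return params


def step(
    pop: Population,
    schedule: DisturbanceSchedule,
    config: SimulationConfig,
    rng: np.random.Generator,
    params: DemographyParams | None = None,
) -> tuple[Population, StepRecord]:
    """Advance the population by one day; returns the reconciled record.

    The record satisfies ``n_after = n_before + births - total_deaths``
    exactly, every step.  An empty population passes through unchanged.
    """
    if pop.t >= schedule.horizon:
        raise ValueError("population already at the schedule horizon")
    if params is None:
        params = _effective_params(config, pop)
    n_before = pop.size
    t_new = pop.t + 1
    pop = Population(pop.s, pop.mu, pop.f, t_new,
                     pop.founding_mean_mu, pop.founding_mean_f)

    # 1. juvenile-specific disturbance
    disturbed = t_new in schedule
    d_dist = 0
    if disturbed and pop.size:
        juv = np.flatnonzero(pop.s < params.maturity_threshold)
        removed = apply_disturbance(juv, rng, params.disturbance_fraction)
        d_dist = removed.size
        if d_dist:
            keep = np.ones(pop.size, dtype=bool)
            keep[removed] = False
            pop._keep(keep)

    # 2. growth and end-of-life deaths
    pop.s = pop.s + pop.mu
    alive = pop.s < params.end_of_life
    d_age = int(pop.size - np.count_nonzero(alive))
    pop._keep(alive)

    # 3. stage- and trait-linked hazard mortality
    d_juv = d_adu = 0
    if pop.size:
        is_juv = pop.s < params.maturity_threshold
        p_death = np.where(
            is_juv,
            juvenile_mortality_prob(pop.mu, coeff=params.juvenile_mort_coeff),
            adult_mortality_prob(pop.f, coeff=params.adult_mort_coeff),
        )
        died = rng.random(pop.size) < p_death
        d_juv = int(np.count_nonzero(died & is_juv))
        d_adu = int(np.count_nonzero(died & ~is_juv))
        pop._keep(~died)

    # 4. reproduction by surviving adults
    births = 0
    adults = pop.s >= params.maturity_threshold
    if adults.any():
        counts = rng.poisson(pop.f[adults])
        births = int(counts.sum())
        if births:
            parent_mu = np.repeat(pop.mu[adults], counts)
            parent_f = np.repeat(pop.f[adults], counts)
            child_mu, child_f = mutate_traits(parent_mu, parent_f, params, rng)
            if config.newborn_same_day_hazards:
                p = juvenile_mortality_prob(
                    child_mu, coeff=params.juvenile_mort_coeff)
                survive = rng.random(births) >= p
                d_juv += int(births - np.count_nonzero(survive))
                births_surviving = int(np.count_nonzero(survive))
                child_mu, child_f = child_mu[survive], child_f[survive]
            else:
                births_surviving = births
            pop.s = np.concatenate([pop.s, np.zeros(births_surviving)])
            pop.mu = np.concatenate([pop.mu, child_mu])
            pop.f = np.concatenate([pop.f, child_f])

    # 5. density-dependent removal on the post-birth roster
    d_dens = density_removal_count(pop.size, rng, params.dd_base, params.dd_scale)
    if d_dens:
        kill = rng.choice(pop.size, size=d_dens, replace=False)
        keep = np.ones(pop.size, dtype=bool)
        keep[kill] = False
        pop._keep(keep)

    record = _summarise(pop, births=births, d_juv=d_juv, d_adu=d_adu,
                        d_dens=d_dens, d_age=d_age, d_dist=d_dist,
                        disturbed=disturbed)
    assert record.n_total == n_before + record.births - record.total_deaths
    return pop, record


@dataclass
class Trajectory:
    """One realisation: per-day records plus the endpoint trait samples."""

    config_hash: str
    seed: int
    records: list[StepRecord]
    endpoint_mu: np.ndarray
    endpoint_f: np.ndarray
    extinct: bool
    extinction_time: int | None
    schedule: DisturbanceSchedule | None = None

    @property
    def horizon(self) -> int:
        return self.records[-1].t

    def endpoint_var(self, trait: str) -> float:
        """Intrapopulation variance of ``trait`` ('mu' or 'f') at the end;
        NaN for extinct or single-survivor populations."""
        values = self.endpoint_mu if trait == "mu" else self.endpoint_f
        return float(np.var(values, ddof=1)) if values.size > 1 else float("nan")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(r) for r in self.records])


def run_realisation(
    config: SimulationConfig,
    seed: int | np.random.SeedSequence,
) -> Trajectory:
    """Run one fresh realisation of the configured regime for the horizon.

    The schedule (for stochastic regimes), the founding population and all
    demographic randomness flow from the single seed, so identical
    ``(config, seed)`` pairs reproduce bit-identical trajectories.
    Extinction is handled gracefully: the run continues to the horizon with
    empty rosters and the trajectory is flagged.
    """
    seq = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(seq)
    schedule = config.make_schedule(rng)
    pop = initialize_population(config, rng)
    params = _effective_params(config, pop)
    records = [_summarise(pop)]
    extinction_time = None
    for _ in range(config.horizon):
        pop, rec = step(pop, schedule, config, rng, params)
        records.append(rec)
        if pop.size == 0 and extinction_time is None:
            extinction_time = rec.t
    seed_repr = seq.entropy if isinstance(seq.entropy, int) else -1
    return Trajectory(
        config_hash=config_hash(config),
        seed=int(seed_repr) if seed_repr is not None else -1,
        records=records,
        endpoint_mu=pop.mu.copy(),
        endpoint_f=pop.f.copy(),
        extinct=extinction_time is not None,
        extinction_time=extinction_time,
        schedule=schedule,
    )


def run_ensemble(
    config: SimulationConfig,
    n_realisations: int | None = None,
    master_seed: int | None = None,
) -> list[Trajectory]:
    """Run independent seeded realisations of one regime.

    Realisation seeds are spawned from the master seed through the
    numpy seed-sequence tree, so ensembles are reproducible and
    realisations statistically independent without seed collisions.
    """
    n = config.n_realisations if n_realisations is None else int(n_realisations)
    if n < 1:
        raise ValueError("n_realisations must be >= 1")
    master = config.master_seed if master_seed is None else int(master_seed)
    children = np.random.SeedSequence(master).spawn(n)
    return [run_realisation(config, child) for child in children]


def ensemble_endpoint_variances(
    trajectories: Sequence[Trajectory], trait: str
) -> np.ndarray:
    """Per-realisation endpoint trait variances, NaN where undefined."""
    return np.array([tr.endpoint_var(trait) for tr in trajectories])
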