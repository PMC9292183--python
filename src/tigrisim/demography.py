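"""Per-individual demographic kernels.

Each individual carries a continuous developmental state ``s`` on [0, 3]
(0 = newborn, [0, 1) = juvenile, [1, 3) = reproductive adult, 3 = end of
life) and two heritable life-history traits: maturation rate ``mu`` (state
units per day) and fecundity ``f`` (offspring per day).  The traits trade
off through f = 1/(4 mu), so the founding maturation-rate range
[0.02, 0.04] maps exactly onto the fecundity range [6.25, 12.50], and each
trait additionally raises the stage-specific mortality hazard of its
carrier: juveniles die at Poisson rate 5*mu, adults at rate 0.001*f.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Individual",
    "DemographyParams",
    "tradeoff_fecundity",
    "juvenile_mortality_prob",
    "adult_mortality_prob",
    "density_removal_count",
    "spawn_offspring",
    "grow",
    "apply_disturbance",
    "mutate_traits",
]

#: Stage boundaries of the developmental state.
MATURITY_THRESHOLD = 1.0
END_OF_LIFE = 3.0

#: Positivity floor for mutated offspring traits.
TRAIT_FLOOR = 1e-6


@dataclass(frozen=True)
class Individual:
    """One organism: developmental state plus its two heritable traits."""

    s: float
    mu: float
    f: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.s:
            raise ValueError(f"developmental state must be >= 0, got {self.s}")
        if self.mu <= 0:
            raise ValueError(f"maturation rate must be positive, got {self.mu}")
        if self.f <= 0:
            raise ValueError(f"fecundity must be positive, got {self.f}")

    @property
    def is_juvenile(self) -> bool:
        return self.s < MATURITY_THRESHOLD

    @property
    def is_adult(self) -> bool:
        return MATURITY_THRESHOLD <= self.s < END_OF_LIFE

    @property
    def is_dead_of_age(self) -> bool:
        return self.s >= END_OF_LIFE


@dataclass(frozen=True)
class DemographyParams:
    """Demographic constants, parameterised for *T. californicus*.

    ``mean_mu`` / ``mean_f`` are the global means of the founding trait
    sets; they set the scale of the inheritance noise and are filled in by
    the engine at initialisation.

    ``mutation_noise_interpretation`` selects how the stated noise scale
    ``0.01 * mean trait`` is read: as the standard deviation of the
    inheritance error (``"sd"``, default — a 1% error, small relative to
    the trait range) or literally as its variance (``"variance"``, which
    makes the error as wide as the whole trait range).
    """

    juvenile_mort_coeff: float = 5.0      # per-day hazard multiplier on mu
    adult_mort_coeff: float = 0.001       # per-day hazard multiplier on f
    dd_base: float = 0.001                # density-dependent baseline rate
    dd_scale: float = 250_000.0           # density scaling constant (10 L pool)
    disturbance_fraction: float = 0.3     # juveniles removed per event
    mutation_scale: float = 0.01          # noise scale relative to founding means
    mu_min: float = 0.02
    mu_max: float = 0.04
    maturity_threshold: float = MATURITY_THRESHOLD
    end_of_life: float = END_OF_LIFE
    mean_mu: float = 0.03
    mean_f: float = field(default=8.664)  # approx E[1/(4 mu)] over U[0.02, 0.04]
    mutation_noise_interpretation: str = "sd"

    def __post_init__(self) -> None:
        for name in ("juvenile_mort_coeff", "adult_mort_coeff", "dd_base",
                     "dd_scale", "mutation_scale"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.disturbance_fraction <= 1.0:
            raise ValueError("disturbance_fraction must lie in [0, 1]")
        if not self.mu_min < self.mu_max:
            raise ValueError("mu_min must be < mu_max")
        if not self.mu_min <= self.mean_mu <= self.mu_max:
            raise ValueError("mean_mu must lie in [mu_min, mu_max]")
        if self.mutation_noise_interpretation not in ("sd", "variance"):
            raise ValueError(
                "mutation_noise_interpretation must be 'sd' or 'variance'")

    @property
    def mutation_sd_mu(self) -> float:
        """Standard deviation of the inheritance error on mu."""
        scale = self.mutation_scale * self.mean_mu
        return scale if self.mutation_noise_interpretation == "sd" else np.sqrt(scale)

    @property
    def mutation_sd_f(self) -> float:
        """Standard deviation of the inheritance error on f."""
        scale = self.mutation_scale * self.mean_f
        return scale if self.mutation_noise_interpretation == "sd" else np.sqrt(scale)

    def with_means(self, mean_mu: float, mean_f: float) -> "DemographyParams":
        return replace(self, mean_mu=float(mean_mu), mean_f=float(mean_f))


def tradeoff_fecundity(mu):
    """Fecundity implied by the maturation-fecundity trade-off, f = 1/(4 mu).

    Strictly decreasing; maps mu in [0.02, 0.04] onto f in [6.25, 12.50]
    exactly.  Accepts scalars or arrays.
    """
    mu = np.asarray(mu, dtype=float)
    if np.any(mu <= 0):
        raise ValueError("maturation rate must be positive")
    f = 1.0 / (4.0 * mu)
    return float(f) if f.ndim == 0 else f


def juvenile_mortality_prob(mu, dt: float = 1.0, coeff: float = 5.0):
    """Per-step death probability of a juvenile, 1 - exp(-coeff*mu*dt).

    Exact discretisation of a Poisson mortality process with rate
    ``coeff * mu`` observed on a fixed grid of width ``dt`` days.
    """
    mu = np.asarray(mu, dtype=float)
    if np.any(mu < 0):
        raise ValueError("maturation rate must be non-negative")
    p = -np.expm1(-coeff * mu * dt)
    return float(p) if p.ndim == 0 else p


def adult_mortality_prob(f, dt: float = 1.0, coeff: float = 0.001):
    """Per-step death probability of an adult, 1 - exp(-coeff*f*dt)."""
    f = np.asarray(f, dtype=float)
    if np.any(f < 0):
        raise ValueError("fecundity must be non-negative")
    p = -np.expm1(-coeff * f * dt)
    return float(p) if p.ndim == 0 else p


def density_removal_count(
    n: int,
    rng: np.random.Generator,
    dd_base: float = 0.001,
    dd_scale: float = 250_000.0,
) -> int:
    """Number of random individuals excised by density-dependent mortality.

    The expected count is ``n * dd_base * (1 + n / dd_scale)``; the realised
    integer is its floor plus a Bernoulli draw on the fractional part, so a
    single realisation never differs from the expectation by more than one.
    """
    if n < 0:
        raise ValueError("population size must be non-negative")
    if n == 0:
        return 0
    expected = n * dd_base * (1.0 + n / dd_scale)
    base = int(expected)
    frac = expected - base
    count = base + int(rng.random() < frac)
    return min(count, n)


def mutate_traits(
    parent_mu: np.ndarray,
    parent_f: np.ndarray,
    params: DemographyParams,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Offspring traits: parental copies plus independent Gaussian errors.

    Each trait receives its own zero-mean Normal error (independent per
    offspring and per trait) whose scale is set by ``params``; results are
    floored at a small positive value so trait invariants always hold.
    Because both traits mutate independently, the founding trade-off
    f = 1/(4 mu) holds exactly only in generation zero and drifts after.
    """
    n = len(parent_mu)
    mu = parent_mu + rng.normal(0.0, params.mutation_sd_mu, size=n)
    f = parent_f + rng.normal(0.0, params.mutation_sd_f, size=n)
    return np.maximum(mu, TRAIT_FLOOR), np.maximum(f, TRAIT_FLOOR)


def spawn_offspring(
    parent: Individual,
    params: DemographyParams,
    rng: np.random.Generator,
) -> list[Individual]:
    """Reproduce one adult for one day: Poisson(f) newborns at s = 0.

    Offspring inherit the parent's traits with the inheritance error of
    :func:`mutate_traits`.
    """
    if not parent.is_adult:
        raise ValueError(
            f"only adults (s in [{MATURITY_THRESHOLD}, {END_OF_LIFE})) "
            f"reproduce; got s = {parent.s}")
    count = int(rng.poisson(parent.f))
    if count == 0:
        return []
    mus, fs = mutate_traits(
        np.full(count, parent.mu), np.full(count, parent.f), params, rng)
    return [Individual(s=0.0, mu=float(m), f=float(fv)) for m, fv in zip(mus, fs)]


def grow(ind: Individual) -> Individual:
    """Advance the developmental state by one day's increment mu.

    An individual whose state reaches 3.0 has completed its life cycle and
    dies of age (query ``is_dead_of_age`` on the result).
    """
    if ind.is_dead_of_age:
        raise ValueError("cannot grow an individual already at end of life")
    return Individual(s=ind.s + ind.mu, mu=ind.mu, f=ind.f)


def apply_disturbance(
    juvenile_indices: np.ndarray,
    rng: np.random.Generator,
    fraction: float = 0.3,
) -> np.ndarray:
    """Indices of juveniles removed by one disturbance event.

    Removes an exact ``round(fraction * n_juveniles)`` chosen uniformly
    without replacement — mirroring the discard of a fixed 30% volume of
    well-mixed medium — and never touches adults.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    juvenile_indices = np.asarray(juvenile_indices)
    n_remove = round(fraction * len(juvenile_indices))
    if n_remove == 0:
        return np.empty(0, dtype=juvenile_indices.dtype)
    return rng.choice(juvenile_indices, size=n_remove, replace=False)
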