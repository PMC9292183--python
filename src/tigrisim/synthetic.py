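"""Synthetic replicate-structured phenotype datasets.

Emulates the measurement design of the multi-generation selection
experiment: 3 treatments x 8 replicate populations x up to 30 gravid
females, with per-female fecundity derived from the mean interval between
successive clutches (clutch size held at the global constant 47.32
offspring) and maturation scored as the mean age at sexual maturity of a
female's offspring.  All times are recorded on a 0.5-day grid, matching
12-hour checks.

Latent (maturity age, clutch interval) pairs are drawn from treatment-level
lognormal distributions — positive and right-skewed like real interval and
age data — with optional replicate-level random effects, then quantised to
the measurement grid.  With all effect multipliers at one, treatment labels
are exchangeable, which is the null configuration used to calibrate the
permutation test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CLUTCH_SIZE_MEAN",
    "ExperimentDesign",
    "TreatmentEffect",
    "EffectConfig",
    "ExperimentDataset",
    "InsufficientSampleError",
    "generate_experiment_dataset",
    "simulate_endpoint_measurement",
]

#: Global mean clutch size (offspring per clutch) assumed for all females.
CLUTCH_SIZE_MEAN = 47.32

#: Baseline medians of the latent measurement distributions (days).  Age at
#: maturity spans roughly 25-50 days for maturation rates in [0.02, 0.04];
#: clutch intervals of 3.8-7.6 days reproduce fecundities in [6.25, 12.50].
BASE_MATURITY_DAYS = 35.0
BASE_INTERVAL_DAYS = 4.5
#: Baseline log-scale standard deviation (~15% coefficient of variation).
BASE_LOG_SD = 0.15

DEFAULT_TREATMENTS = ("deterministic_fast", "deterministic_slow", "stochastic_slow")


class InsufficientSampleError(ValueError):
    """Raised when an endpoint has too few survivors to measure — the
    in-silico analogue of a failed replicate."""


@dataclass(frozen=True)
class ExperimentDesign:
    """Shape and protocol constants of the measurement campaign."""

    treatments: tuple[str, ...] = DEFAULT_TREATMENTS
    replicates_per_treatment: int = 8
    females_per_replicate: int = 30
    clutch_size_mean: float = CLUTCH_SIZE_MEAN
    measurement_granularity: float = 0.5   # days (12-h checks)
    clutches_per_female: int = 3

    def __post_init__(self) -> None:
        if self.replicates_per_treatment < 2:
            raise ValueError("need >= 2 replicates per treatment")
        if self.females_per_replicate < 2:
            raise ValueError("need >= 2 females per replicate")
        if self.measurement_granularity <= 0:
            raise ValueError("measurement granularity must be positive")


@dataclass(frozen=True)
class TreatmentEffect:
    """Multiplicative shifts of one treatment's latent distributions.

    ``*_mean`` scales the lognormal median; ``*_var`` scales the log-scale
    variance (4.0 doubles the log-sd, roughly quadrupling the phenotypic
    variance).
    """

    maturity_mean: float = 1.0
    maturity_var: float = 1.0
    interval_mean: float = 1.0
    interval_var: float = 1.0

    def __post_init__(self) -> None:
        if min(self.maturity_mean, self.maturity_var,
               self.interval_mean, self.interval_var) <= 0:
            raise ValueError("effect multipliers must be positive")


@dataclass(frozen=True)
class EffectConfig:
    """Per-treatment effects plus the replicate random-effect scale.

    ``replicate_sd`` is the log-scale standard deviation of a shared
    replicate-level offset (0 = replicates exchangeable within treatment).
    """

    treatments: dict = field(default_factory=dict)
    replicate_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.replicate_sd < 0:
            raise ValueError("replicate_sd must be >= 0")
        for label, eff in self.treatments.items():
            if not isinstance(eff, TreatmentEffect):
                raise TypeError(f"effect for {label!r} must be a TreatmentEffect")

    def effect(self, treatment: str) -> TreatmentEffect:
        return self.treatments.get(treatment, TreatmentEffect())


_TRAIT_COLUMNS = {
    "fecundity": "fecundity",
    "f": "fecundity",
    "maturity_age": "maturity_age_days",
    "maturation_rate": "maturation_rate",
    "mu": "maturation_rate",
}


@dataclass
class ExperimentDataset:
    """Tidy per-female measurements: one row per scored female.

    Columns: treatment, replicate_id, female_id, maturity_age_days,
    clutch_interval_days, fecundity, maturation_rate.  Fecundity is
    clutch-size / clutch-interval, so it is exactly invertible back to the
    0.5-day interval grid; maturation rate is 1 / maturity age.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"treatment", "replicate_id", "female_id",
                    "maturity_age_days", "clutch_interval_days", "fecundity"}
        missing = required - set(self.df.columns)
        if missing:
            raise ValueError(f"dataset missing columns {sorted(missing)}")
        if "maturation_rate" not in self.df.columns:
            self.df = self.df.assign(
                maturation_rate=1.0 / self.df["maturity_age_days"])
        if (self.df["fecundity"] <= 0).any() or (self.df["maturity_age_days"] <= 0).any():
            raise ValueError("measured values must be positive")

    def __len__(self) -> int:
        return len(self.df)

    def replicate_measurements(self, treatment: str, trait: str) -> list[np.ndarray]:
        """Measurements of ``trait`` grouped by replicate, for the
        permutation test.  Trait aliases: 'f' -> fecundity, 'mu' ->
        maturation rate."""
        col = _TRAIT_COLUMNS.get(trait)
        if col is None:
            raise ValueError(f"unknown trait {trait!r}; "
                             f"expected one of {sorted(_TRAIT_COLUMNS)}")
        sub = self.df[self.df["treatment"] == treatment]
        if sub.empty:
            raise ValueError(f"no rows for treatment {treatment!r}")
        return [grp[col].to_numpy()
                for _, grp in sub.groupby("replicate_id", sort=True)]

    def to_long(self) -> pd.DataFrame:
        """Long format (treatment, replicate_id, individual_id, trait, value)
        — the schema the stats command line consumes."""
        rows = self.df.melt(
            id_vars=["treatment", "replicate_id", "female_id"],
            value_vars=["fecundity", "maturation_rate"],
            var_name="trait", value_name="value",
        ).rename(columns={"female_id": "individual_id"})
        rows["trait"] = rows["trait"].map(
            {"fecundity": "f", "maturation_rate": "mu"})
        return rows

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ExperimentDataset":
        return cls(pd.read_csv(path))


def _quantise(values: np.ndarray, grid: float) -> np.ndarray:
    """Snap to the measurement grid, never below one grid unit."""
    return np.maximum(np.round(values / grid) * grid, grid)


def generate_experiment_dataset(
    design: ExperimentDesign = ExperimentDesign(),
    effect_config: EffectConfig = EffectConfig(),
    rng: np.random.Generator | int | None = None,
) -> ExperimentDataset:
    """Draw a full synthetic measurement campaign.

    Per female, latent (maturity age, clutch interval) are lognormal with
    treatment-level median and log-sd multipliers and an optional shared
    replicate offset, then quantised to the 0.5-day grid and converted to
    fecundity via clutch-size / interval.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    grid = design.measurement_granularity
    frames = []
    for treatment in design.treatments:
        eff = effect_config.effect(treatment)
        for rep in range(design.replicates_per_treatment):
            n = design.females_per_replicate
            rep_shift_age = rng.normal(0.0, effect_config.replicate_sd) \
                if effect_config.replicate_sd else 0.0
            rep_shift_int = rng.normal(0.0, effect_config.replicate_sd) \
                if effect_config.replicate_sd else 0.0
            age = (BASE_MATURITY_DAYS * eff.maturity_mean
                   * np.exp(rng.normal(rep_shift_age,
                                       BASE_LOG_SD * np.sqrt(eff.maturity_var), n)))
            interval = (BASE_INTERVAL_DAYS * eff.interval_mean
                        * np.exp(rng.normal(rep_shift_int,
                                            BASE_LOG_SD * np.sqrt(eff.interval_var), n)))
            age_q = _quantise(age, grid)
            int_q = _quantise(interval, grid)
            frames.append(pd.DataFrame({
                "treatment": treatment,
                "replicate_id": f"{treatment}_r{rep + 1}",
                "female_id": np.arange(1, n + 1),
                "maturity_age_days": age_q,
                "clutch_interval_days": int_q,
                "fecundity": design.clutch_size_mean / int_q,
            }))
    return ExperimentDataset(pd.concat(frames, ignore_index=True))


def simulate_endpoint_measurement(
    endpoint_mu: np.ndarray,
    endpoint_f: np.ndarray,
    design: ExperimentDesign = ExperimentDesign(),
    rng: np.random.Generator | int | None = None,
    treatment: str = "simulated",
    n_replicates: int | None = None,
) -> ExperimentDataset:
    """Measure a simulation endpoint the way the lab protocol would.

    For each replicate, ``females_per_replicate`` survivors are subsampled
    without replacement from the endpoint trait sample; their implied
    maturity ages (1/mu) and clutch intervals (clutch-size/f) are recorded
    on the 0.5-day grid, and fecundity re-derived from the quantised
    interval.  Raises :class:`InsufficientSampleError` when fewer survivors
    than females are available — a failed replicate.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    endpoint_mu = np.asarray(endpoint_mu, dtype=float)
    endpoint_f = np.asarray(endpoint_f, dtype=float)
    n_fem = design.females_per_replicate
    if endpoint_mu.size < n_fem:
        raise InsufficientSampleError(
            f"endpoint has {endpoint_mu.size} survivors; "
            f"need >= {n_fem} to fill a replicate")
    n_reps = design.replicates_per_treatment if n_replicates is None else n_replicates
    grid = design.measurement_granularity
    frames = []
    for rep in range(n_reps):
        idx = rng.choice(endpoint_mu.size, size=n_fem, replace=False)
        age_q = _quantise(1.0 / endpoint_mu[idx], grid)
        int_q = _quantise(design.clutch_size_mean / endpoint_f[idx], grid)
        frames.append(pd.DataFrame({
            "treatment": treatment,
            "replicate_id": f"{treatment}_r{rep + 1}",
            "female_id": np.arange(1, n_fem + 1),
            "maturity_age_days": age_q,
            "clutch_interval_days": int_q,
            "fecundity": design.clutch_size_mean / int_q,
        }))
    return ExperimentDataset(pd.concat(frames, ignore_index=True))
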