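"""Variance statistics for simulation ensembles and replicate experiments.

Two inferential tools are provided:

* Welch's two-sample t-test on log-transformed per-realisation trait
  variances, for comparing simulation ensembles of unequal size and
  spread.

* A Monte Carlo permutation test for differences in intrapopulation
  variance between two treatments of a replicate-structured experiment.
  The null distribution is built from a "universal PDF": variances of
  groups of 30 individual-level measurements subsampled from the pooled
  dataset across all treatments and replicates.  N = a + b such group
  variances are drawn (a, b = replicate counts of the two treatments);
  the null mean-difference is then resampled from them 50,000 times, and
  the one-sided p-value is the proportion of null differences at least as
  large as the observed difference in mean replicate variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "VarianceSample",
    "PermutationResult",
    "trait_variances",
    "welch_log_variance_test",
    "permutation_variance_test",
]


@dataclass(frozen=True)
class VarianceSample:
    """Per-realisation (or per-replicate) intrapopulation variances.

    Missing values (NaN — e.g. extinct realisations) are tolerated and
    dropped before testing; at least two finite values must remain.
    """

    label: str
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))

    @property
    def finite(self) -> np.ndarray:
        v = self.values
        return v[np.isfinite(v)]


def trait_variances(trait_values) -> float:
    """Sample variance (n-1 denominator) of one population's trait values."""
    values = np.asarray(trait_values, dtype=float)
    if values.size < 2:
        raise ValueError(
            f"variance undefined for fewer than 2 values (got {values.size})")
    return float(np.var(values, ddof=1))


def welch_log_variance_test(
    sample_a: VarianceSample | Sequence[float],
    sample_b: VarianceSample | Sequence[float],
) -> tuple[float, float, float]:
    """Welch's t-test on log-transformed variances.

    Returns ``(t, df, p)`` with Welch-Satterthwaite degrees of freedom and
    a two-sided p-value.  The log transform requires strictly positive
    variances; non-finite entries are dropped first.
    """
    a = sample_a.finite if isinstance(sample_a, VarianceSample) else np.asarray(sample_a, float)
    b = sample_b.finite if isinstance(sample_b, VarianceSample) else np.asarray(sample_b, float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs >= 2 finite variance values")
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValueError("variances must be positive to log-transform")
    la, lb = np.log(a), np.log(b)
    res = sps.ttest_ind(la, lb, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


@dataclass(frozen=True)
class PermutationResult:
    """Outcome of the Monte Carlo permutation test on variance differences."""

    observed_difference: float
    universal_pdf: np.ndarray
    null_distribution: np.ndarray
    p_value: float
    group_size: int
    n_permutations: int
    seed: int | None = None
    label_a: str = "A"
    label_b: str = "B"

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value out of [0, 1]")
        if len(self.null_distribution) != self.n_permutations:
            raise ValueError("null distribution length != n_permutations")

    def to_dict(self) -> dict:
        return {
            "label_a": self.label_a,
            "label_b": self.label_b,
            "observed_difference": self.observed_difference,
            "p_value": self.p_value,
            "group_size": self.group_size,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
            "universal_pdf": [float(v) for v in self.universal_pdf],
        }


def _replicate_arrays(measurements) -> list[np.ndarray]:
    arrays = [np.asarray(rep, dtype=float) for rep in measurements]
    if any(rep.size < 1 for rep in arrays):
        raise ValueError("every replicate must supply >= 1 measurement")
    return arrays


def permutation_variance_test(
    measurements_a: Sequence[Sequence[float]],
    measurements_b: Sequence[Sequence[float]],
    pool: Sequence[Sequence[float]] | None = None,
    group_size: int = 30,
    n_permutations: int = 50_000,
    rng: np.random.Generator | int | None = None,
    pool_scope: str = "global",
    pdf_oversample: int = 1,
    redraw_universal_pdf: bool = False,
    label_a: str = "A",
    label_b: str = "B",
) -> PermutationResult:
    """Monte Carlo permutation test for an intrapopulation-variance difference.

    Parameters
    ----------
    measurements_a, measurements_b
        Individual-level measurements grouped by replicate (one inner
        sequence per replicate population); at least two replicates each.
    pool
        Measurements of further treatments included in the global pool
        (replicate-structured as above); ignored when
        ``pool_scope="pairwise"``.
    group_size
        Measurements per subsampled group whose variance enters the
        universal PDF (30, the number of females scored per replicate).
    n_permutations
        Resampling iterations forming the null distribution.
    rng
        numpy Generator or integer seed.
    pool_scope
        ``"global"`` pools all supplied data (both treatments plus
        ``pool``); ``"pairwise"`` restricts the pool to the two compared
        treatments.
    pdf_oversample
        Multiplier on the number of universal-PDF group variances (1
        reproduces the a+b-value PDF; larger values smooth the null).
    redraw_universal_pdf
        Redraw a fresh universal PDF on every permutation iteration
        instead of drawing it once up front.

    Returns
    -------
    PermutationResult
        The observed difference mean(replicate variances of B) -
        mean(replicate variances of A), the universal PDF, the null
        distribution, and the one-sided p-value P(null >= observed)
        oriented so that B is the hypothesised-larger treatment.
    """
    reps_a = _replicate_arrays(measurements_a)
    reps_b = _replicate_arrays(measurements_b)
    if len(reps_a) < 2 or len(reps_b) < 2:
        raise ValueError("each treatment needs >= 2 replicates")
    if pool_scope not in ("global", "pairwise"):
        raise ValueError("pool_scope must be 'global' or 'pairwise'")

    seed = rng if isinstance(rng, (int, np.integer)) else None
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)

    pooled_parts = reps_a + reps_b
    if pool is not None and pool_scope == "global":
        pooled_parts = pooled_parts + _replicate_arrays(pool)
    pooled = np.concatenate(pooled_parts)
    if group_size > pooled.size:
        raise ValueError(
            f"group_size {group_size} exceeds pooled dataset size {pooled.size}")

    a, b = len(reps_a), len(reps_b)
    n_groups = (a + b) * int(pdf_oversample)

    def draw_pdf() -> np.ndarray:
        # each group: subsample without replacement; independent across groups
        groups = np.stack([gen.choice(pooled, size=group_size, replace=False)
                           for _ in range(n_groups)])
        return groups.var(axis=1, ddof=1)

    universal_pdf = draw_pdf()
    if redraw_universal_pdf:
        null = np.empty(n_permutations)
        for i in range(n_permutations):
            pdf_i = draw_pdf()
            null[i] = (gen.choice(pdf_i, b, replace=True).mean()
                       - gen.choice(pdf_i, a, replace=True).mean())
    else:
        draws_b = gen.choice(universal_pdf, size=(n_permutations, b), replace=True)
        draws_a = gen.choice(universal_pdf, size=(n_permutations, a), replace=True)
        null = draws_b.mean(axis=1) - draws_a.mean(axis=1)

    # a single-measurement replicate has no defined variance; it still feeds
    # the pooled data above but cannot contribute to the observed difference
    var_a = np.array([np.var(rep, ddof=1) for rep in reps_a if rep.size > 1])
    var_b = np.array([np.var(rep, ddof=1) for rep in reps_b if rep.size > 1])
    if var_a.size < 2 or var_b.size < 2:
        raise ValueError(
            "each treatment needs >= 2 replicates with >= 2 measurements")
    observed = float(var_b.mean() - var_a.mean())
    p_value = float(np.mean(null >= observed))

    return PermutationResult(
        observed_difference=observed,
        universal_pdf=universal_pdf,
        null_distribution=null,
        p_value=p_value,
        group_size=group_size,
        n_permutations=n_permutations,
        seed=seed,
        label_a=label_a,
        label_b=label_b,
    )
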