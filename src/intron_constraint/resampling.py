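"""Permutation-style resampling tests.

The primary use is the 5'-UTR-intron mean-length test: are the UTR introns
longer than random same-sized subsets of the genome's CDS introns?  Subsets
are drawn without replacement, the comparison is one-sided (resampled mean >=
observed mean, ties counting as exceedances), and the p-value uses the add-one
convention p = (count + 1) / (reps + 1) so it can never be zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np


@dataclass(frozen=True)
class ResampleResult:
    observed_mean: float
    n_reps: int
    count_ge: int
    p_value: float
    max_resampled_mean: float
    seed: int


def subset_mean_test(
    population_lengths: Sequence[float],
    subset_lengths: Sequence[float],
    n_reps: int = 10_000,
    seed: int = 0,
) -> ResampleResult:
    """One-sided mean comparison of a subset against random resamples.

    Draws ``n_reps`` subsets of size ``len(subset_lengths)`` without
    replacement from the population and counts resampled means greater than or
    equal to the observed subset mean.  Deterministic under a fixed seed.
    """
    population = np.asarray(population_lengths, dtype=float)
    subset = np.asarray(subset_lengths, dtype=float)
    if subset.size == 0:
        raise ValueError("subset must be nonempty")
    if subset.size > population.size:
        raise ValueError(
            f"subset of {subset.size} larger than population of {population.size}"
        )
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")

    rng = np.random.default_rng(seed)
    observed = float(subset.mean())
    means = np.empty(n_reps, dtype=float)
    for rep in range(n_reps):
        means[rep] = population[
            rng.choice(population.size, size=subset.size, replace=False)
        ].mean()
    count_ge = int((means >= observed).sum())
    return ResampleResult(
        observed_mean=observed,
        n_reps=n_reps,
        count_ge=count_ge,
        p_value=(count_ge + 1) / (n_reps + 1),
        max_resampled_mean=float(means.max()),
        seed=seed,
    )
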