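"""Binomial model of the non-selected substitution burden.

The number of non-selected substitutions accumulated by one lineage over
``G`` generations is modelled as X ~ Binomial(n = L*G, p) — every site of a
genome of ``L`` base pairs is a trial in each of the ``G`` divisions, hit
with the per-site per-generation substitution rate ``p``.  Tail
probabilities P(X >= k) quantify how surprising a strain with k extra
mutations is under a constant mutation rate, and a one-sided binomial test
asks whether the number of strains carrying extra mutations exceeds that
expectation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import logsumexp

from .fluctuation import InputError

__all__ = ["BurstModel", "tail_prob", "strain_excess_test"]

#: Haploid yeast genome size (bp) and per-site substitution rate used for
#: the wild-type colony computations.
DEFAULT_GENOME_SIZE = 12_000_000
DEFAULT_PER_SITE_RATE = 3.3e-10
DEFAULT_GENERATIONS = 27


@dataclass(frozen=True)
class BurstModel:
    """Genome size L (bp), per-site per-generation rate, generations G."""

    genome_size_L: int = DEFAULT_GENOME_SIZE
    per_site_rate: float = DEFAULT_PER_SITE_RATE
    generations_G: int = DEFAULT_GENERATIONS

    def __post_init__(self):
        if self.genome_size_L < 1:
            raise InputError("genome_size_L must be >= 1")
        if not (0.0 <= self.per_site_rate <= 1.0):
            raise InputError("per_site_rate must be in [0, 1]")
        if self.generations_G < 1:
            raise InputError("generations_G must be >= 1")

    @property
    def n_trials(self) -> int:
        return int(self.genome_size_L) * int(self.generations_G)

    @property
    def mean_burden(self) -> float:
        """Expected substitutions per lineage, lambda = L*G*p."""
        return self.n_trials * self.per_site_rate


def _binomial_sf(k: int, n: int, p: float) -> float:
    """P(X >= k), X ~ Binomial(n, p), summed in log space.

    The tail is accumulated by log-sum-exp over log-pmf terms starting at k
    (never by subtracting CDFs near 1), so extreme tails like 1e-19 keep
    full relative precision.  Terms beyond the point where they stop
    contributing (45 nats below the running maximum) are dropped.
    """
    if k <= 0:
        return 1.0
    if k > n:
        return 0.0
    terms = []
    best = -math.inf
    j = k
    block = 512
    while j <= n:
        ks = np.arange(j, min(j + block, n + 1))
        lp = stats.binom.logpmf(ks, n, p)
        terms.append(lp)
        best = max(best, float(lp.max()))
        if float(lp[-1]) < best - 45.0:
            break
        j += block
    return float(np.exp(logsumexp(np.concatenate(terms))))


def tail_prob(model: BurstModel, k: int) -> float:
    """Probability of at least ``k`` non-selected substitutions in a lineage."""
    if k < 0:
        raise InputError(f"k must be non-negative, got {k}")
    return _binomial_sf(int(k), model.n_trials, model.per_site_rate)


def strain_excess_test(
    n_strains: int, n_with_extra: int, model: BurstModel
) -> tuple[float, float]:
    """Are more strains carrying extra mutations than the model expects?

    Each strain independently carries >= 1 non-selected substitution with
    probability ``tail_prob(model, 1)``.  Returns ``(expected_count,
    p_value)`` with the one-sided exact binomial tail
    P(Binomial(n_strains, tail_prob) >= n_with_extra).
    """
    if n_strains < 0 or not (0 <= n_with_extra <= n_strains):
        raise InputError(
            f"need 0 <= n_with_extra <= n_strains, got "
            f"{n_with_extra}/{n_strains}"
        )
    p1 = tail_prob(model, 1)
    expected = n_strains * p1
    p_value = _binomial_sf(n_with_extra, n_strains, p1)
    return expected, p_value
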