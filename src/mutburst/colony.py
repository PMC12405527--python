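"""Stochastic simulation of mutation accumulation during colony growth.

The colony starts from a single cell and doubles every generation for ``G``
generations (exponential growth, no death).  At each division every cell
produces one daughter; mutations of two independent types (channels 1 and 2,
e.g. the segmental-duplication *D* and canavanine-resistance *C* reporters)
appear only in daughters, never in mothers, and are never reverted.  A
daughter of a wild-type mother acquires channel-1 only, channel-2 only, or
both in the same division ("simultaneous" double, probability mu1*mu2);
a daughter of a single mutant that acquires the other mutation founds a
"sequential" double lineage.  Double-mutant cells permanently carry the
origin tag of their founding event.

Two model variants are provided:

* the **null model** (``simulate_null``): rates constant and identical for
  every cell in the colony;
* the **refined model** (``simulate_refined``): additionally, once per
  realization, ``S`` randomly picked cells enter a transient mutator state
  in which both rates are multiplied by a strength ``F`` for ``d``
  generations; the state is inherited by daughters during the episode and
  reverts synchronously afterwards.

Populations are propagated as integer class counts with exact multinomial
sampling (factorised into sequential binomials), which keeps 2^27-cell
colonies tractable; realizations are simulated in vectorised batches.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .fluctuation import (
    FluctuationDataset,
    InputError,
    RateEstimate,
    mle_rate,
)

__all__ = [
    "RateSet",
    "MutatorParams",
    "ColonyRealization",
    "ColonyBatch",
    "ModelRateEstimates",
    "OriginSummary",
    "simulate_null",
    "simulate_refined",
    "simulate_null_batch",
    "simulate_refined_batch",
    "estimate_model_rates",
    "classify_double_origins",
]

CLASS_NAMES = ("wt", "m1_only", "m2_only", "double_seq", "double_sim")

#: Printed single-mutation rates for the three reporter channels in wild-type
#: colonies (per cell per division): segmental duplication (D), canavanine
#: resistance (C), reciprocal translocation (T).
RATE_D = 3.3e-6
RATE_C = 1.6e-7
RATE_T = 1.8e-8
#: Observed double-mutant formation rates.
OBSERVED_RATE_DC = 1.8e-10
OBSERVED_RATE_DT = 1.1e-11
#: Generations of colony growth in the fluctuation experiments.
DEFAULT_GENERATIONS = 27


def _check_admissible(mu1: float, mu2: float) -> None:
    if mu1 < 0 or mu2 < 0:
        raise InputError("mutation rates must be non-negative")
    if mu1 + mu2 + mu1 * mu2 > 1.0 + 1e-12:
        raise InputError(
            f"rates inadmissible: mu1 + mu2 + mu1*mu2 = "
            f"{mu1 + mu2 + mu1 * mu2} > 1"
        )


@dataclass(frozen=True)
class RateSet:
    """Per-cell-per-division rates of the two mutation channels."""

    mu1: float
    mu2: float
    labels: tuple[str, str] = ("mu1", "mu2")

    def __post_init__(self):
        _check_admissible(self.mu1, self.mu2)

    def scaled(self, factor: float) -> "RateSet":
        """Rates multiplied by a mutator strength; validates admissibility."""
        return RateSet(self.mu1 * factor, self.mu2 * factor, self.labels)


@dataclass(frozen=True)
class MutatorParams:
    """One transient mutator episode.

    ``size_S`` cells enter the mutator state at onset generation ``g0``
    (sampled per ``onset_policy``), both rates are multiplied by
    ``strength_F`` for ``duration_d`` generations, and the state is
    inherited by daughters until it ends.  ``onset_policy`` is either
    ``"uniform"`` (g0 uniform on {ceil(log2 S), ..., G-1}, the first
    generations at which the population can hold S cells) or an integer
    fixing g0.
    """

    size_S: int
    strength_F: float
    duration_d: int
    onset_policy: str | int = "uniform"

    def __post_init__(self):
        if self.size_S < 1:
            raise InputError("mutator size_S must be >= 1")
        if self.strength_F < 1:
            raise InputError("mutator strength_F must be >= 1")
        if self.duration_d < 1:
            raise InputError("mutator duration_d must be >= 1")
        if isinstance(self.onset_policy, str) and self.onset_policy != "uniform":
            raise InputError(f"unknown onset policy {self.onset_policy!r}")

    @property
    def min_onset(self) -> int:
        return max(0, math.ceil(math.log2(self.size_S)))


@dataclass
class ColonyRealization:
    """One simulated colony: final class counts plus the event record.

    ``event_log`` rows are ``(generation, transition, cohort, n_new)`` —
    the generation at which ``n_new`` daughters first entered a mutant
    class (generation g means cells born in the g-th doubling).
    """

    generations_G: int
    wt: int
    m1_only: int
    m2_only: int
    double_seq: int
    double_sim: int
    seq_events: int
    sim_events: int
    g0: int  # mutator onset generation; -1 for the null model
    seed: int | None
    event_log: list = field(default_factory=list)

    @property
    def total(self) -> int:
        return self.wt + self.m1_only + self.m2_only + self.double_seq + self.double_sim

    @property
    def doubles(self) -> int:
        return self.double_seq + self.double_sim


class ColonyBatch:
    """A batch of realizations stored as per-realization arrays."""

    def __init__(self, G, rates, mutator, seed, counts, g0, seq_events,
                 sim_events, first_gen):
        self.G = G
        self.rates = rates
        self.mutator = mutator
        self.seed = seed
        self.counts = counts  # dict class -> (n,) int64 final counts
        self.g0 = g0
        self.seq_events = seq_events
        self.sim_events = sim_events
        self.first_gen = first_gen  # dict class -> (n,) int, -1 = never

    @property
    def n_realizations(self) -> int:
        return self.counts["wt"].size

    @property
    def total(self) -> np.ndarray:
        return sum(self.counts[c] for c in CLASS_NAMES)

    def channel_counts(self) -> dict[str, np.ndarray]:
        """Mutant-bearing cell counts per selective channel.

        A double mutant grows on either single-selective medium, so channel
        totals include the double classes.
        """
        dq, ds = self.counts["double_seq"], self.counts["double_sim"]
        return {
            "channel1": self.counts["m1_only"] + dq + ds,
            "channel2": self.counts["m2_only"] + dq + ds,
            "double": dq + ds,
        }

    def realization(self, i: int) -> ColonyRealization:
        c = {k: int(v[i]) for k, v in self.counts.items()}
        return ColonyRealization(
            generations_G=self.G,
            wt=c["wt"], m1_only=c["m1_only"], m2_only=c["m2_only"],
            double_seq=c["double_seq"], double_sim=c["double_sim"],
            seq_events=int(self.seq_events[i]),
            sim_events=int(self.sim_events[i]),
            g0=int(self.g0[i]), seed=None,
            event_log=[
                (int(self.first_gen[k][i]), k, "any", 1)
                for k in ("m1_only", "m2_only", "double_seq", "double_sim")
                if self.first_gen[k][i] >= 0
            ],
        )

    def to_dataframe(self) -> pd.DataFrame:
        """Tidy table: one row per realization."""
        data = {"realization": np.arange(self.n_realizations), "g0": self.g0}
        for k in CLASS_NAMES:
            data[k] = self.counts[k]
        data["seq_events"] = self.seq_events
        data["sim_events"] = self.sim_events
        for k in ("m1_only", "m2_only", "double_seq", "double_sim"):
            data[f"first_gen_{k}"] = self.first_gen[k]
        return pd.DataFrame(data)

    def manifest(self) -> dict:
        """Run manifest sufficient to reproduce the batch exactly."""
        man = {
            "model": "refined" if self.mutator is not None else "null",
            "mu1": self.rates.mu1, "mu2": self.rates.mu2,
            "generations": self.G, "n_realizations": self.n_realizations,
            "seed": self.seed,
        }
        if self.mutator is not None:
            man.update(
                mutator_size=self.mutator.size_S,
                mutator_strength=self.mutator.strength_F,
                mutator_duration=self.mutator.duration_d,
                onset_policy=self.mutator.onset_policy,
            )
        return man


def _as_generator(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    if not isinstance(seed, np.random.SeedSequence):
        seed = np.random.SeedSequence(seed)
    return np.random.Generator(np.random.PCG64(seed))


def _divide(rng, cohort, mu1, mu2, events):
    """One synchronous division round for one cohort (in place).

    ``cohort`` maps class name -> (n,) int64 counts; every cell produces one
    daughter, and daughters mutate with the cohort's rates.  The joint
    wild-type daughter fate {none, ch1, ch2, both} is the multinomial with
    probabilities {(1-mu1)(1-mu2), mu1(1-mu2), (1-mu1)mu2, mu1*mu2},
    factorised exactly as binomial(ch1) then binomial(ch2 | ch1 stratum).
    Returns the per-class numbers of newly founded mutant daughters.
    """
    wt, m1, m2 = cohort["wt"], cohort["m1_only"], cohort["m2_only"]
    a = rng.binomial(wt, mu1)            # wt daughters hit in channel 1
    ab = rng.binomial(a, mu2)            # ... and channel 2: simultaneous
    b = rng.binomial(wt - a, mu2)        # channel 2 only
    c1 = rng.binomial(m1, mu2)           # m1 daughters -> sequential double
    c2 = rng.binomial(m2, mu1)           # m2 daughters -> sequential double
    cohort["wt"] = 2 * wt - a - b
    cohort["m1_only"] = 2 * m1 - c1 + (a - ab)
    cohort["m2_only"] = 2 * m2 - c2 + b
    cohort["double_seq"] = 2 * cohort["double_seq"] + c1 + c2
    cohort["double_sim"] = 2 * cohort["double_sim"] + ab
    events["m1_only"] = a - ab
    events["m2_only"] = b
    events["double_seq"] = c1 + c2
    events["double_sim"] = ab
    return events


def _simulate_batch(rates, G, n, seed, mutator=None):
    if G < 1:
        raise InputError(f"G must be >= 1, got {G}")
    if G > 62:
        raise InputError("G > 62 would overflow 64-bit class counts")
    rng = _as_generator(seed)
    zeros = lambda: np.zeros(n, dtype=np.int64)
    basal = {k: zeros() for k in CLASS_NAMES}
    basal["wt"] += 1
    mut = {k: zeros() for k in CLASS_NAMES}

    g0 = np.full(n, -1, dtype=np.int64)
    mu1_f = mu2_f = None
    if mutator is not None:
        if mutator.size_S > 2 ** G:
            raise InputError("mutator size_S exceeds the final population")
        _check_admissible(rates.mu1 * mutator.strength_F,
                          rates.mu2 * mutator.strength_F)
        gmin = mutator.min_onset
        if isinstance(mutator.onset_policy, str):  # "uniform"
            if gmin > G - 1:
                raise InputError(
                    "population is smaller than size_S at every eligible "
                    "onset generation"
                )
            g0 = rng.integers(gmin, G, size=n)
        else:
            fixed = int(mutator.onset_policy)
            if not (gmin <= fixed <= G - 1):
                raise InputError(
                    f"fixed onset generation {fixed} not in [{gmin}, {G - 1}]"
                )
            g0 = np.full(n, fixed, dtype=np.int64)
        mu1_f = rates.mu1 * mutator.strength_F
        mu2_f = rates.mu2 * mutator.strength_F

    seq_events = zeros()
    sim_events = zeros()
    first_gen = {k: np.full(n, -1, dtype=np.int64)
                 for k in ("m1_only", "m2_only", "double_seq", "double_sim")}
    ev = {}

    for g in range(G):
        if mutator is not None:
            # episode end: fold the mutator cohort back into the basal one
            done = np.flatnonzero((g0 >= 0) & (g0 + mutator.duration_d == g))
            if done.size:
                for k in CLASS_NAMES:
                    basal[k][done] += mut[k][done]
                    mut[k][done] = 0
            # onset: draw S cells across classes proportionally to abundance
            start = np.flatnonzero(g0 == g)
            for i in start:
                colors = np.array([basal[k][i] for k in CLASS_NAMES])
                picked = rng.multivariate_hypergeometric(colors, mutator.size_S)
                for k, nk in zip(CLASS_NAMES, picked):
                    basal[k][i] -= nk
                    mut[k][i] += nk

        _divide(rng, basal, rates.mu1, rates.mu2, ev)
        new = {k: ev[k].copy() for k in ev}
        if mutator is not None:
            _divide(rng, mut, mu1_f, mu2_f, ev)
            for k in new:
                new[k] += ev[k]
        for k, delta in new.items():
            fresh = (delta > 0) & (first_gen[k] < 0)
            first_gen[k][fresh] = g + 1
        seq_events += new["double_seq"]
        sim_events += new["double_sim"]

    if mutator is not None:  # episodes still open at the final generation
        for k in CLASS_NAMES:
            basal[k] += mut[k]

    return ColonyBatch(G=G, rates=rates, mutator=mutator, seed=seed,
                       counts=basal, g0=g0, seq_events=seq_events,
                       sim_events=sim_events, first_gen=first_gen)


def simulate_null_batch(rates: RateSet, G: int, n_realizations: int,
                        seed) -> ColonyBatch:
    """Vectorised batch of null-model realizations."""
    return _simulate_batch(rates, G, n_realizations, seed)


def simulate_refined_batch(rates: RateSet, G: int, mutator: MutatorParams,
                           n_realizations: int, seed) -> ColonyBatch:
    """Vectorised batch of refined-model realizations (one episode each)."""
    return _simulate_batch(rates, G, n_realizations, seed, mutator=mutator)


def _single(batch: ColonyBatch, seed) -> ColonyRealization:
    r = batch.realization(0)
    r.seed = seed if isinstance(seed, int) else None
    return r


def simulate_null(rates: RateSet, G: int, seed) -> ColonyRealization:
    """One null-model colony (identical seeds give identical realizations)."""
    return _single(simulate_null_batch(rates, G, 1, seed), seed)


def simulate_refined(rates: RateSet, G: int, mutator: MutatorParams,
                     seed) -> ColonyRealization:
    """One refined-model colony with a single transient mutator episode."""
    return _single(simulate_refined_batch(rates, G, mutator, 1, seed), seed)


# ---------------------------------------------------------------------------
# Turning realizations into "theoretical" rates
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelRateEstimates:
    """Single- and double-channel rates re-estimated from simulated colonies."""

    rate1: float
    rate2: float
    double_rate: float
    estimate1: RateEstimate
    estimate2: RateEstimate
    estimate_double: RateEstimate


def _batch_from_realizations(realizations) -> ColonyBatch:
    reals = list(realizations)
    if not reals:
        raise InputError("need at least one realization")
    Gs = {r.generations_G for r in reals}
    if len(Gs) != 1:
        raise InputError("realizations must share a common G")
    counts = {k: np.array([getattr(r, k) for r in reals], dtype=np.int64)
              for k in CLASS_NAMES}
    return ColonyBatch(
        G=Gs.pop(), rates=None, mutator=None, seed=None, counts=counts,
        g0=np.array([r.g0 for r in reals], dtype=np.int64),
        seq_events=np.array([r.seq_events for r in reals], dtype=np.int64),
        sim_events=np.array([r.sim_events for r in reals], dtype=np.int64),
        first_gen={k: np.full(len(reals), -1, dtype=np.int64)
                   for k in ("m1_only", "m2_only", "double_seq", "double_sim")},
    )


def estimate_model_rates(
    realizations: "ColonyBatch | Iterable[ColonyRealization]",
    plating_fraction: float = 1.0,
    seed=None,
    censor_cap: int = 4096,
    compute_ci: bool = True,
) -> ModelRateEstimates:
    """Fluctuation-MLE rates from simulated colonies.

    Each realization's final mutant-bearing cell counts (channel 1, channel
    2, doubles) are treated as one fluctuation culture with Nt = 2^G, and
    ``mle_rate`` is applied per channel — the operation that turns model
    output into "theoretical" rates comparable with experimental ones.
    With ``plating_fraction`` < 1 the counts are binomially thinned (seeded)
    and the estimator applies the matching plating correction.
    """
    batch = (realizations if isinstance(realizations, ColonyBatch)
             else _batch_from_realizations(realizations))
    if batch.n_realizations < 2:
        raise InputError("need at least two realizations to estimate rates")
    nt = float(2 ** batch.G)
    channels = batch.channel_counts()
    if plating_fraction < 1.0:
        rng = _as_generator(seed)
        channels = {k: rng.binomial(v, plating_fraction)
                    for k, v in channels.items()}
    ests = {}
    for name, obs in channels.items():
        ds = FluctuationDataset(obs, cells_per_culture=nt,
                                plating_fraction=plating_fraction, label=name)
        ests[name] = mle_rate(ds, censor_cap=censor_cap, compute_ci=compute_ci)
    return ModelRateEstimates(
        rate1=ests["channel1"].rate, rate2=ests["channel2"].rate,
        double_rate=ests["double"].rate,
        estimate1=ests["channel1"], estimate2=ests["channel2"],
        estimate_double=ests["double"],
    )


@dataclass(frozen=True)
class OriginSummary:
    """Sequential-vs-simultaneous breakdown of double-mutant origins."""

    n_realizations: int
    n_with_doubles: int
    n_with_sequential: int
    n_with_simultaneous: int
    total_sequential_events: int
    total_simultaneous_events: int

    @property
    def sequential_fraction(self) -> float:
        """Pooled fraction of double lineages founded sequentially."""
        tot = self.total_sequential_events + self.total_simultaneous_events
        return self.total_sequential_events / tot if tot else math.nan

    @property
    def fraction_realizations_sequential(self) -> float:
        if not self.n_with_doubles:
            return math.nan
        return self.n_with_sequential / self.n_with_doubles

    @property
    def fraction_realizations_simultaneous(self) -> float:
        if not self.n_with_doubles:
            return math.nan
        return self.n_with_simultaneous / self.n_with_doubles


def classify_double_origins(
    realizations: "ColonyBatch | Iterable[ColonyRealization]",
) -> OriginSummary:
    """Summarise double-mutant origins over realizations.

    A double lineage founded by a wild-type daughter acquiring both
    mutations in one division is simultaneous; one founded by a
    single-mutant daughter is sequential.
    """
    batch = (realizations if isinstance(realizations, ColonyBatch)
             else _batch_from_realizations(realizations))
    dq = batch.counts["double_seq"]
    ds = batch.counts["double_sim"]
    return OriginSummary(
        n_realizations=batch.n_realizations,
        n_with_doubles=int(np.count_nonzero(dq + ds)),
        n_with_sequential=int(np.count_nonzero(dq)),
        n_with_simultaneous=int(np.count_nonzero(ds)),
        total_sequential_events=int(batch.seq_events.sum()),
        total_simultaneous_events=int(batch.sim_events.sum()),
    )
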