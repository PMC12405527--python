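"""Synthetic fluctuation-assay data with Luria–Delbrück structure.

Emulates the experimental design of the colony fluctuation assay: many
independent colonies grown to ~2^G cells, each plated on selective media
for channel-1 mutants, channel-2 mutants and double mutants.  Every culture
is one colony-simulator realization (null model, or refined model when a
transient mutator episode is embedded), so mutant counts carry the
jackpot-heavy distribution the estimators assume, and the three channel
counts of one culture come from the same realization — preserving the
within-colony correlation that makes double-mutant excess analyses
meaningful.  Observed counts are binomial thinnings of the true final
counts when only a fraction of each culture is plated.

A ground-truth manifest records the generating parameters for recovery
tests and exact re-runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .colony import (
    ColonyBatch,
    MutatorParams,
    RateSet,
    simulate_null_batch,
    simulate_refined_batch,
)
from .fluctuation import FluctuationDataset, InputError

__all__ = ["SynthSpec", "SyntheticExperiment", "make_fluctuation_table",
           "make_double_mutant_experiment"]


@dataclass(frozen=True)
class SynthSpec:
    """Generating parameters for a synthetic fluctuation experiment."""

    rates: RateSet
    n_cultures: int
    G: int = 27
    plating_fraction: float = 1.0
    mutator: MutatorParams | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_cultures < 1:
            raise InputError("n_cultures must be >= 1")
        if not (0.0 < self.plating_fraction <= 1.0):
            raise InputError("plating_fraction must be in (0, 1]")

    def manifest(self) -> dict:
        man = {
            "true_mu1": self.rates.mu1,
            "true_mu2": self.rates.mu2,
            "generations": self.G,
            "n_cultures": self.n_cultures,
            "plating_fraction": self.plating_fraction,
            "seed": self.seed,
            "model": "refined" if self.mutator is not None else "null",
        }
        if self.mutator is not None:
            man.update(
                mutator_size=self.mutator.size_S,
                mutator_strength=self.mutator.strength_F,
                mutator_duration=self.mutator.duration_d,
                onset_policy=self.mutator.onset_policy,
            )
        return man


@dataclass
class SyntheticExperiment:
    """Datasets per selective channel plus the generating ground truth."""

    datasets: dict[str, FluctuationDataset]
    batch: ColonyBatch
    manifest: dict


def _simulate(spec: SynthSpec) -> tuple[ColonyBatch, np.random.Generator]:
    ss = np.random.SeedSequence(spec.seed)
    sim_seed, thin_seed = ss.spawn(2)
    if spec.mutator is None:
        batch = simulate_null_batch(spec.rates, spec.G, spec.n_cultures, sim_seed)
    else:
        batch = simulate_refined_batch(
            spec.rates, spec.G, spec.mutator, spec.n_cultures, sim_seed
        )
    return batch, np.random.Generator(np.random.PCG64(thin_seed))


def _datasets(spec: SynthSpec, channels: tuple[str, ...]) -> SyntheticExperiment:
    batch, thin_rng = _simulate(spec)
    true_counts = batch.channel_counts()
    eps = spec.plating_fraction
    datasets = {}
    for name in channels:
        observed = true_counts[name]
        if eps < 1.0:
            observed = thin_rng.binomial(observed, eps)
        datasets[name] = FluctuationDataset(
            counts=observed,
            cells_per_culture=float(2 ** spec.G),
            plating_fraction=eps,
            label=name,
        )
    return SyntheticExperiment(datasets=datasets, batch=batch,
                               manifest=spec.manifest())


def make_fluctuation_table(spec: SynthSpec) -> SyntheticExperiment:
    """Single-channel fluctuation tables (one dataset per mutation channel)."""
    return _datasets(spec, ("channel1", "channel2"))


def make_double_mutant_experiment(spec: SynthSpec) -> SyntheticExperiment:
    """Three correlated datasets emulating the D / C / DC selection design.

    Channel-1, channel-2 and double-mutant counts are all read off the same
    realizations, mirroring one colony plated on three selective media.
    """
    return _datasets(spec, ("channel1", "channel2", "double"))
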