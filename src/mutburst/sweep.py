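"""Parameter-space sweep for the transient-mutator (refined) model.

The refined model has three free episode parameters: subpopulation size S
(cells), mutator strength F (fold increase over the basal rates) and
duration d (generations).  The sweep simulates a grid of (S, F, d)
combinations, re-estimates the single and double mutation rates from the
realizations with the fluctuation MLE, and flags the combinations that
recapitulate the experimentally observed rates:

* ``matches_double`` — the observed double-rate band and the simulated
  double-rate 95% profile CI overlap;
* ``matches_singles`` — both simulated single-rate point estimates fall
  inside the experimental 95% band (the "green" criterion).

Accepted points (both flags) are then summarised: pooled fraction of
simultaneously acquired doubles, onset-generation statistics split by the
regime of the resulting doubles, and per-realization single-mutant scatter
data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .colony import (
    OBSERVED_RATE_DC,
    RATE_C,
    RATE_D,
    ModelRateEstimates,
    MutatorParams,
    RateSet,
    estimate_model_rates,
    simulate_refined_batch,
)
from .fluctuation import InputError, expected_rate_band

__all__ = [
    "SweepGrid",
    "ObservedRates",
    "SweepPoint",
    "RegimeSummary",
    "FoldChange",
    "run_sweep",
    "accepted_points",
    "regime_summary",
    "fold_change",
    "points_to_dataframe",
    "realizations_to_dataframe",
    "double_distribution_ks",
]

#: Independent cultures behind the published wild-type D / C / DC rates.
N_CULTURES_D = 63
N_CULTURES_C = 104
N_CULTURES_DC = 550

#: Default sweep ranges: decade-spaced sizes and strengths, short durations.
DEFAULT_SIZES = (10, 100, 1_000, 10_000)
DEFAULT_STRENGTHS = (100.0, 1_000.0, 10_000.0)
DEFAULT_DURATIONS = (1, 5)


@dataclass(frozen=True)
class SweepGrid:
    """Grid of transient-mutator parameters to explore."""

    sizes: Sequence[int] = DEFAULT_SIZES
    strengths: Sequence[float] = DEFAULT_STRENGTHS
    durations: Sequence[int] = DEFAULT_DURATIONS
    G: int = 27
    rates: RateSet = field(default_factory=lambda: RateSet(RATE_D, RATE_C))
    n_realizations: int = 1000

    def __post_init__(self):
        if not (self.sizes and self.strengths and self.durations):
            raise InputError("sizes, strengths and durations must be non-empty")
        if self.n_realizations < 1:
            raise InputError("n_realizations must be >= 1")

    def combinations(self) -> list[tuple[int, float, int]]:
        return [(int(s), float(f), int(d))
                for s, f, d in product(self.sizes, self.strengths,
                                       self.durations)]


@dataclass(frozen=True)
class ObservedRates:
    """Experimentally measured rates with their 95% CI bands (per cell per
    division).  Bands are inputs (from the experiment or a config); the
    default ships the printed wild-type point rates with ±2-fold bands."""

    rate1: float
    rate1_band: tuple[float, float]
    rate2: float
    rate2_band: tuple[float, float]
    double_rate: float
    double_band: tuple[float, float]

    @classmethod
    def from_point_rates(cls, rate1: float, rate2: float, double_rate: float,
                         band_fold: float = 2.0) -> "ObservedRates":
        if min(rate1, rate2, double_rate) <= 0:
            raise InputError("observed rates must be positive")
        band = lambda r: (r / band_fold, r * band_fold)
        return cls(rate1, band(rate1), rate2, band(rate2),
                   double_rate, band(double_rate))

    @classmethod
    def from_designs(
        cls,
        rate1: float, n1: int,
        rate2: float, n2: int,
        double_rate: float, n_double: int,
        cells_per_culture: float = float(2 ** 27),
    ) -> "ObservedRates":
        """Bands from the experimental designs (rate + culture count).

        When only point rates and culture counts are published, the 95%
        likelihood-ratio CI band of each measurement is reconstructed from
        the expected Fisher information of the fluctuation likelihood at
        that design (see ``fluctuation.expected_rate_band``).
        """
        return cls(
            rate1, expected_rate_band(rate1, n1, cells_per_culture),
            rate2, expected_rate_band(rate2, n2, cells_per_culture),
            double_rate,
            expected_rate_band(double_rate, n_double, cells_per_culture),
        )

    @classmethod
    def wild_type_dc(cls) -> "ObservedRates":
        """Wild-type colony D / C / DC rates with 95% bands reconstructed
        from the published designs (63, 104 and 550 cultures)."""
        return cls.from_designs(RATE_D, N_CULTURES_D,
                                RATE_C, N_CULTURES_C,
                                OBSERVED_RATE_DC, N_CULTURES_DC)


@dataclass
class SweepPoint:
    """One (S, F, d) combination with re-estimated rates and flags."""

    size_S: int
    strength_F: float
    duration_d: int
    n_realizations: int
    estimates: ModelRateEstimates | None = None
    matches_double: bool = False
    matches_singles: bool = False
    skipped: bool = False
    skip_reason: str = ""
    # per-realization summaries used by regime_summary
    g0: np.ndarray | None = None
    m1_only: np.ndarray | None = None
    m2_only: np.ndarray | None = None
    has_sequential: np.ndarray | None = None
    has_simultaneous: np.ndarray | None = None
    sequential_events: int = 0
    simultaneous_events: int = 0

    @property
    def accepted(self) -> bool:
        return (not self.skipped) and self.matches_double and self.matches_singles

    @property
    def simultaneous_fraction(self) -> float:
        """Fraction of this point's double lineages founded simultaneously."""
        tot = self.sequential_events + self.simultaneous_events
        return self.simultaneous_events / tot if tot else math.nan


def _intervals_overlap(a: tuple[float, float], b: tuple[float, float]) -> bool:
    return a[0] <= b[1] and b[0] <= a[1]


def run_sweep(
    grid: SweepGrid,
    observed: ObservedRates,
    seed: int = 0,
    tolerance: float = 1.0,
    censor_cap: int = 4096,
) -> list[SweepPoint]:
    """Simulate and flag every grid point.

    Each point draws from its own child random stream (spawned from
    ``seed`` by grid position), so results do not depend on execution
    order.  ``tolerance`` (>= 1) widens the simulated double-rate CI before
    the overlap test; the default 1.0 is the plain CI-overlap rule.
    Infeasible points (S larger than any eligible population, or strengths
    pushing the rates past admissibility) are marked skipped, not fatal.
    """
    if tolerance < 1.0:
        raise InputError("tolerance multiplier must be >= 1")
    combos = grid.combinations()
    children = np.random.SeedSequence(seed).spawn(len(combos))
    points = []
    for (S, F, d), child in zip(combos, children):
        point = SweepPoint(size_S=S, strength_F=F, duration_d=d,
                           n_realizations=grid.n_realizations)
        try:
            mutator = MutatorParams(S, F, d)
            batch = simulate_refined_batch(grid.rates, grid.G, mutator,
                                           grid.n_realizations, child)
        except InputError as err:
            point.skipped = True
            point.skip_reason = str(err)
            points.append(point)
            continue
        est = estimate_model_rates(batch, censor_cap=censor_cap)
        dbl = est.estimate_double
        sim_ci = (dbl.ci_low / tolerance,
                  dbl.ci_high * tolerance if math.isfinite(dbl.ci_high)
                  else dbl.ci_high)
        point.estimates = est
        point.matches_double = _intervals_overlap(observed.double_band, sim_ci)
        point.matches_singles = (
            observed.rate1_band[0] <= est.rate1 <= observed.rate1_band[1]
            and observed.rate2_band[0] <= est.rate2 <= observed.rate2_band[1]
        )
        point.g0 = batch.g0.copy()
        point.m1_only = batch.counts["m1_only"].copy()
        point.m2_only = batch.counts["m2_only"].copy()
        point.has_sequential = batch.counts["double_seq"] > 0
        point.has_simultaneous = batch.counts["double_sim"] > 0
        point.sequential_events = int(batch.seq_events.sum())
        point.simultaneous_events = int(batch.sim_events.sum())
        points.append(point)
    return points


def accepted_points(points: Sequence[SweepPoint]) -> list[SweepPoint]:
    """Points recapitulating both the single and the double rates ("green")."""
    return [p for p in points if p.accepted]


@dataclass(frozen=True)
class RegimeSummary:
    """Accumulation-regime statistics pooled over accepted sweep points.

    All fields are NaN-marked when no double mutant supports them.
    """

    n_points: int
    n_realizations: int
    pooled_simultaneous_fraction: float
    point_simultaneous_min: float
    point_simultaneous_mean: float
    point_simultaneous_max: float
    onset_mean_sequential: float
    onset_sd_sequential: float
    n_sequential_realizations: int
    onset_mean_simultaneous: float
    onset_sd_simultaneous: float
    n_simultaneous_realizations: int
    fraction_no_double: float
    fraction_more_m1_than_m2: float
    scatter: pd.DataFrame

    def to_dict(self) -> dict:
        out = {k: getattr(self, k) for k in (
            "n_points", "n_realizations", "pooled_simultaneous_fraction",
            "point_simultaneous_min", "point_simultaneous_mean",
            "point_simultaneous_max", "onset_mean_sequential",
            "onset_sd_sequential", "n_sequential_realizations",
            "onset_mean_simultaneous", "onset_sd_simultaneous",
            "n_simultaneous_realizations", "fraction_no_double",
            "fraction_more_m1_than_m2",
        )}
        return {k: (None if isinstance(v, float) and math.isnan(v) else v)
                for k, v in out.items()}


def regime_summary(points: Sequence[SweepPoint]) -> RegimeSummary:
    """Summarise mutation-accumulation regimes over (accepted) points.

    Reports the pooled simultaneous fraction of double lineages with
    per-point spread, the mutator-onset generation split by whether the
    realization yielded sequential or simultaneous doubles, the fraction of
    double-free realizations, the fraction with more channel-1 than
    channel-2 single mutants, and the per-realization single-mutant scatter
    with double-mutant annotations.
    """
    pts = [p for p in points if not p.skipped]
    if not pts:
        raise InputError("need at least one non-skipped sweep point")
    seq_ev = sum(p.sequential_events for p in pts)
    sim_ev = sum(p.simultaneous_events for p in pts)
    per_point = [p.simultaneous_fraction for p in pts
                 if not math.isnan(p.simultaneous_fraction)]

    g0 = np.concatenate([p.g0 for p in pts])
    has_seq = np.concatenate([p.has_sequential for p in pts])
    has_sim = np.concatenate([p.has_simultaneous for p in pts])
    m1 = np.concatenate([p.m1_only for p in pts])
    m2 = np.concatenate([p.m2_only for p in pts])

    def _onset(mask):
        sel = g0[mask & (g0 >= 0)]
        if sel.size == 0:
            return math.nan, math.nan, 0
        return (float(sel.mean()),
                float(sel.std(ddof=1)) if sel.size > 1 else math.nan,
                int(sel.size))

    mean_seq, sd_seq, n_seq = _onset(has_seq)
    mean_sim, sd_sim, n_sim = _onset(has_sim)

    category = np.where(has_sim, "simultaneous",
                        np.where(has_seq, "sequential", "no_double"))
    # realizations with both kinds keep the rarer, simultaneous, tag
    scatter = pd.DataFrame({"m1_only": m1, "m2_only": m2, "category": category})

    n_tot = g0.size
    no_double = float(np.mean(~(has_seq | has_sim)))
    return RegimeSummary(
        n_points=len(pts),
        n_realizations=n_tot,
        pooled_simultaneous_fraction=(sim_ev / (seq_ev + sim_ev)
                                      if seq_ev + sim_ev else math.nan),
        point_simultaneous_min=min(per_point) if per_point else math.nan,
        point_simultaneous_mean=(float(np.mean(per_point))
                                 if per_point else math.nan),
        point_simultaneous_max=max(per_point) if per_point else math.nan,
        onset_mean_sequential=mean_seq,
        onset_sd_sequential=sd_seq,
        n_sequential_realizations=n_seq,
        onset_mean_simultaneous=mean_sim,
        onset_sd_simultaneous=sd_sim,
        n_simultaneous_realizations=n_sim,
        fraction_no_double=no_double,
        fraction_more_m1_than_m2=float(np.mean(m1 > m2)),
        scatter=scatter,
    )


@dataclass(frozen=True)
class FoldChange:
    """Observed/expected rate ratio with CI by interval propagation."""

    value: float
    ci_low: float = math.nan
    ci_high: float = math.nan
    infinite: bool = False


def fold_change(observed_rate: float, expected_rate: float,
                observed_ci: tuple[float, float] | None = None,
                expected_ci: tuple[float, float] | None = None) -> FoldChange:
    """Ratio observed/expected; CI bounds [obs_lo/exp_hi, obs_hi/exp_lo]."""
    if expected_rate < 0 or observed_rate < 0:
        raise InputError("rates must be non-negative")
    if expected_rate == 0:
        return FoldChange(value=math.inf, infinite=True)
    lo = hi = math.nan
    if observed_ci is not None and expected_ci is not None:
        lo = observed_ci[0] / expected_ci[1] if expected_ci[1] > 0 else math.inf
        hi = observed_ci[1] / expected_ci[0] if expected_ci[0] > 0 else math.inf
    return FoldChange(value=observed_rate / expected_rate, ci_low=lo, ci_high=hi)


def double_distribution_ks(simulated_counts: np.ndarray,
                           observed_counts: np.ndarray) -> tuple[float, float]:
    """Optional two-sample KS report comparing double-mutant count
    distributions (diagnostic only, not an acceptance gate)."""
    res = stats.ks_2samp(np.asarray(simulated_counts),
                         np.asarray(observed_counts))
    return float(res.statistic), float(res.pvalue)


def points_to_dataframe(points: Sequence[SweepPoint]) -> pd.DataFrame:
    """Per-point TSV-ready table."""
    rows = []
    for p in points:
        est = p.estimates
        rows.append({
            "size_S": p.size_S, "strength_F": p.strength_F,
            "duration_d": p.duration_d, "n_realizations": p.n_realizations,
            "rate1": est.rate1 if est else math.nan,
            "rate2": est.rate2 if est else math.nan,
            "double_rate": est.double_rate if est else math.nan,
            "double_ci_low": est.estimate_double.ci_low if est else math.nan,
            "double_ci_high": est.estimate_double.ci_high if est else math.nan,
            "matches_double": p.matches_double,
            "matches_singles": p.matches_singles,
            "accepted": p.accepted,
            "skipped": p.skipped,
            "skip_reason": p.skip_reason,
            "simultaneous_fraction": p.simultaneous_fraction,
            "sequential_events": p.sequential_events,
            "simultaneous_events": p.simultaneous_events,
        })
    return pd.DataFrame(rows)


def realizations_to_dataframe(points: Sequence[SweepPoint]) -> pd.DataFrame:
    """Per-realization table across points (for regime re-analysis)."""
    frames = []
    for idx, p in enumerate(points):
        if p.skipped:
            continue
        frames.append(pd.DataFrame({
            "point": idx, "size_S": p.size_S, "strength_F": p.strength_F,
            "duration_d": p.duration_d, "accepted": p.accepted,
            "g0": p.g0, "m1_only": p.m1_only, "m2_only": p.m2_only,
            "has_sequential": p.has_sequential,
            "has_simultaneous": p.has_simultaneous,
        }))
    if not frames:
        return pd.DataFrame()
    return pd.concat(frames, ignore_index=True)
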