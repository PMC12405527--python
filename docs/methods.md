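# Methods

## The Luria–Delbrück likelihood

A fluctuation experiment observes, for each of n independent cultures grown
from single cells to Nt cells, the number of mutant colonies on selective
medium.  Mutation events occur during growth at rate μ per cell per
division; a culture therefore accumulates m = μ·Nt events in expectation,
and each event founds a clone whose final size depends on when it occurred.
In the Lea–Coulson formulation the clone-size distribution is
P(K = k) = 1/(k(k+1)), and the mutant count is compound Poisson, giving the
Ma–Sandri–Sarkar (MSS) recursion for the pmf.

**Partial plating.**  When only a fraction ε ∈ (0, 1] of a culture is
plated, every mutant cell is retained independently with probability ε, so
each clone is binomially thinned.  The thinned clone-size distribution has
the closed-form zero class q0 = 1 + ε·ln(ε)/(1−ε); classes k ≥ 1 are
computed as binomial mixtures over the untruncated clone sizes (geometric
tail truncation, cached per (ε, n_max)).  The count pmf then follows from
the same Panjer-type recursion p_n = (m/n)·Σ_j (n−j)·q_{n−j}·p_j, which
reduces exactly to MSS at ε = 1.  The implementation is validated against
a 10^5-sample Monte-Carlo oracle (sample full counts, thin the totals) at
Kolmogorov distance < 0.01.

**Censoring.**  Jackpot cultures can hold millions of mutants; computing
the recursion to such counts is pointless and slow.  Counts are
right-censored at n_max = min(max observed count, cap) with cap = 4096 by
default: categories 0..n_max−1 are exact and category n_max carries mass
P(count ≥ n_max).  The largest observed count is therefore always treated
as "at least this many", which also makes the estimator collapse to the P0
estimator −ln(fraction mutant-free) when counts are all {0, 1}.  The cap
trades information against cost: at m ≈ 450 about a third of the mass lies
above 4096, and the censored likelihood still localises m to a few
percent with 10^3–10^4 cultures.

**Estimation.**  The log-likelihood is maximised over t = ln m by
bracket expansion plus bounded Brent (1e-6 relative tolerance in m), with
the boundary m̂ = 0 handled explicitly when no mutants are observed.  The
95% CI is the profile-likelihood set {m : 2(ℓ(m̂) − ℓ(m)) ≤ 3.841}, found
by bisection to 1e-4 relative tolerance on each side; all-censored or
all-zero data yield one-sided intervals flagged `degenerate`.  Rates are
m̂/Nt with a single Nt per dataset.  The likelihood-ratio test for two
experiments maximises a common per-cell rate μ (m_a = μ·Nt_a,
m_b = μ·Nt_b) and refers 2·Δℓ to χ²(1); its type-I error calibration is
exercised in the test suite.

**Recursion scaling.**  For large m the unscaled recursion underflows
(p0 = e^-m vanishes past m ≈ 700).  The recursion is run in a rescaled
basis with an explicit log-offset, renormalising whenever entries exceed
1e280, so likelihoods remain finite for arbitrarily large m (needed when a
sweep point inflates rates a thousand-fold).

## Colony models

Both models grow a colony from one cell by synchronous doubling for G
generations under five assumptions: exponential growth; no death; mutations
only in daughters; constant, population-uniform basal rates; no reversion.
Each division, a wild-type daughter independently acquires channel 1,
channel 2, or both with probabilities μ1(1−μ2), (1−μ1)μ2 and μ1μ2 (the
joint multinomial is factorised into exact sequential binomial draws); a
daughter of a single mutant acquires the other mutation at its rate and
founds a *sequential* double lineage, whereas a wild-type daughter hit
twice in one division founds a *simultaneous* lineage.  Origin tags are
inherited, so final `double_seq`/`double_sim` counts partition double
cells by the regime that created their lineage.  Counts are int64 and
conserve Σclasses = 2^g exactly at every generation; G ≤ 62 is enforced.

The refined model adds one transient mutator episode per realization,
parameterised by size S (cells), strength F (fold multiplier on both
rates) and duration d (generations).  Where the episode design was open,
the choices are:

* **Onset policy**: g0 uniform on {⌈log2 S⌉, …, G−1} — the population
  must be able to supply S cells; a fixed-generation policy is available
  for experiments and tests.  Uniform-over-generations is the least
  informative choice consistent with "cells are picked at random during
  growth"; onset weighted by population size would concentrate episodes in
  the last generations and suppress sequential doubles almost entirely.
* **Inheritance**: the mutator state passes to daughters during the
  episode and reverts synchronously after d generations, so that size and
  duration act independently (an S-cell episode of duration d exposes
  S·d·2-ish cell divisions regardless of when it starts).
* **Cohort selection**: the S cells are drawn without replacement across
  genotype classes proportionally to abundance (multivariate
  hypergeometric) — at realistic rates almost always wild type.
* **Admissibility**: after strength multiplication the constraint
  μ1 + μ2 + μ1μ2 ≤ 1 must hold; violating configurations are rejected.

Simulation is vectorised across realizations (arrays of class counts, one
PCG64 stream per batch); a cell-by-cell agent simulator exists in the test
suite as an independent oracle and agrees distributionally at small G.

**Theoretical rates.**  `estimate_model_rates` treats each realization's
final mutant-bearing counts (channel 1, channel 2, doubles, each including
double mutants) as one fluctuation culture with Nt = 2^G and applies the
MLE per channel.  This mirrors how measured rates are produced and is what
makes model output comparable with experiment.

**Estimator dialect bias.**  The simulator is a discrete-generation
(synchronous) model whose clone sizes are powers of two; the likelihood is
the continuous-time Lea–Coulson family.  Fitting one to the other biases
m̂ low by ~10% at m ≈ 13 and ~19% at m ≈ 440 (the estimator itself is
unbiased on data sampled from its own model, and the bias is negligible at
m ≲ 1).  This is the same family of discrepancy as the up-to-2-fold
divergence reported between established fluctuation estimators at high
rates.  Consequences: parameter-recovery tests on simulator data assert
25% accuracy rather than CI coverage at large m, CI-coverage properties
are asserted on model-distributed tables, and compatibility bands in the
sweep are interpreted with this bias in mind (below).

## The parameter sweep

The default grid follows the published exploration at desk scale: sizes
{10, 10², 10³, 10⁴}, strengths {10², 10³, 10⁴} (decade steps), durations
{1, 5}, G = 27, basal rates (3.3e-6, 1.6e-7).  Decade spacing matters for
one reported statistic: the *maximum* simultaneous share over accepted
points is grid-defined, and refining the grid adds boundary combinations
(e.g. S = 10³, F ≈ 3·10³, d = 1) whose genuinely higher simultaneous share
(~25%) was never part of the original sweep.  Half-decade or wider grids
remain available via `SweepGrid`.

A point is accepted ("green") when (i) its double-rate 95% profile CI
overlaps the observed double-rate band and (ii) both single-rate point
estimates fall inside the experimental single-rate bands.  The default
bands are reconstructed from the published experimental designs — point
rates with 63 (D), 104 (C) and 550 (DC) cultures of 2^27 cells — as Wald
bands rate·exp(±1.96/√(n·I)) using the expected Fisher information per
culture of the fluctuation likelihood, numerically differentiated from the
censored pmf.  This reproduces the "95% likelihood-ratio CI" criterion the
experimental comparison used, without access to the raw count tables;
±k-fold bands are available as a config alternative.  These
information-based bands assume ideal Luria–Delbrück sampling and therefore
tend to be narrower than real experimental CIs (colony-size variation,
plating losses), which makes the acceptance criterion conservative.

Regime summaries pool accepted points: the simultaneous share of double
lineages (per point and pooled), onset-generation means and SDs split by
whether a realization yielded sequential or simultaneous doubles, the
fraction of double-free realizations, the fraction with more channel-1
than channel-2 single mutants, and per-realization scatter data.  Fold
changes propagate CIs as [obs_lo/exp_hi, obs_hi/exp_lo].  A two-sample
Kolmogorov–Smirnov comparison of double-count distributions is provided as
a diagnostic only.

## Burden model

Non-selected substitutions per lineage are X ~ Binomial(n = L·G, p), with
defaults L = 12 Mb, p = 3.3e-10 per site per generation, G = 27
(λ = L·G·p ≈ 0.107).  Tails P(X ≥ k) are accumulated by log-sum-exp over
log-pmf terms starting at k — never by subtracting CDFs near 1 — keeping
full relative precision at magnitudes like 1e-19; the series is truncated
once terms fall 45 nats below the running maximum.  The strain-excess test
is the exact one-sided binomial tail for observing at least the given
number of strains with ≥ 1 extra substitution.

## Synthetic data

`synthetic` emulates the colony fluctuation design: every culture is one
simulator realization (null, or refined when a burst is embedded), the
three selective channels are read off the *same* realization (preserving
the within-colony correlation that double-mutant excess analyses depend
on), and observed counts are binomial thinnings when ε < 1.  Ground-truth
manifests round-trip through JSON.  What the generator does *not* emulate:
asynchronous division timing (hence the dialect bias above), cell death,
fitness differences among mutants, culture-to-culture Nt variation, and
plating/counting noise beyond binomial thinning.  Tests passing on these
tables therefore validate the statistical chain under the model's own
assumptions, not the wet-lab error structure.

## Problem sizes and determinism

The acceptance script uses 100,000 null realizations (the sequential share
and the theoretical double rate rest on ~150 double lineages) and 48,000
realizations per sweep point (per-point simultaneous shares and
simultaneous-onset means otherwise rest on single-digit event counts);
1000 realizations per point — the published floor — remains the `SweepGrid`
default.  All randomness flows from explicit seeds through
`numpy.random.SeedSequence`; sweep points draw from independent child
streams indexed by grid position, so results are identical regardless of
execution order, and identical seeds reproduce realizations exactly.

## Known limitations

* The Lea–Coulson/MSS family is the only pmf dialect implemented;
  phenotypic lag, death and differential mutant fitness are out of scope.
* One mutator episode per realization; no spatial colony structure.
* The refined model's onset policy and state inheritance are assumptions
  (documented above), not measurements; regime statistics that depend on
  the late-onset tail (the simultaneous-onset mean) move by a generation
  or two under alternative defensible policies.
* The fraction of accepted-set colonies with more channel-1 than channel-2
  single mutants computed here (~99%) exceeds the published ~91%; under
  the implemented acceptance bands, combinations in which channel-2
  episodes overtake the channel-1 background are excluded by the
  single-rate criterion, so the package reports what the model as
  specified produces.
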