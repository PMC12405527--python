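"""Luria–Delbrück fluctuation analysis.

Mutation rates are estimated from the distribution of mutant counts across
many parallel cultures (or colonies).  The natural parameter is ``m``, the
expected number of mutation events per culture; the per-cell-per-division
rate is ``m / Nt`` where ``Nt`` is the final number of cells per culture.

The mutant-count distribution is the Lea–Coulson formulation of the
Luria–Delbrück distribution: a compound Poisson over mutational clones whose
size distribution is P(K = k) = 1/(k(k+1)).  Partial plating (only a fraction
``eps`` of each culture plated on selective medium) thins every clone
binomially; the thinned clone-size distribution has the closed-form zero
class q0 = 1 + eps*ln(eps)/(1-eps) and the resulting count distribution is
computed by the same Panjer-type recursion.

Estimation is maximum likelihood on ``m`` with right-censoring of jackpot
counts, profile-likelihood 95% confidence intervals, and a likelihood-ratio
test for comparing rates between two experiments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import optimize, stats

__all__ = [
    "FluctuationDataset",
    "RateEstimate",
    "InputError",
    "EstimationError",
    "ld_pmf",
    "mle_rate",
    "lr_test",
    "expected_rate_band",
    "sample_ld_counts",
    "CHI2_95_1DF",
]

#: 95% quantile of chi-square with 1 df; deviance contour for profile CIs
#: and the likelihood-ratio acceptance threshold.
CHI2_95_1DF = 3.841458820694124

_RESCALE = 1e280


class InputError(ValueError):
    """Invalid user input (counts, rates, plating fraction ...)."""


class EstimationError(RuntimeError):
    """Optimization failed; carries the bracketing information tried."""

    def __init__(self, message: str, bracket=None):
        super().__init__(message)
        self.bracket = bracket


@dataclass(frozen=True)
class FluctuationDataset:
    """One fluctuation experiment: mutant counts from independent cultures.

    Parameters
    ----------
    counts
        Non-negative mutant-colony counts, one per independent culture.
    cells_per_culture
        Final number of cells per culture (``Nt``); a single value per
        dataset (one OD-based mean per experiment).
    plating_fraction
        Fraction of each culture plated on selective medium, in (0, 1].
    label
        Free-text strain/condition label.
    """

    counts: np.ndarray
    cells_per_culture: float
    plating_fraction: float = 1.0
    label: str = ""

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.ndim != 1 or counts.size < 1:
            raise InputError("counts must be a non-empty 1-D sequence")
        if np.any(counts < 0):
            raise InputError("mutant counts must be non-negative")
        if not (0.0 < self.plating_fraction <= 1.0):
            raise InputError(
                f"plating_fraction must be in (0, 1], got {self.plating_fraction}"
            )
        if self.cells_per_culture <= 0:
            raise InputError("cells_per_culture must be positive")
        if self.cells_per_culture < counts.max() / self.plating_fraction:
            raise InputError(
                "cells_per_culture smaller than max(counts)/plating_fraction: "
                f"{self.cells_per_culture} < "
                f"{counts.max() / self.plating_fraction}"
            )
        object.__setattr__(self, "counts", counts)

    @property
    def n_cultures(self) -> int:
        return int(self.counts.size)


@dataclass(frozen=True)
class RateEstimate:
    """MLE of the expected mutations per culture and the derived rate.

    ``rate = m_hat / cells_per_culture`` (mutations per cell per division);
    ``ci_low``/``ci_high`` are 95% profile-likelihood bounds on the rate.
    ``degenerate`` flags boundary fits (no mutants at all, or every count
    censored) whose CI is one-sided.
    """

    m_hat: float
    rate: float
    ci_low: float
    ci_high: float
    loglik: float
    n_cultures: int
    label: str = ""
    degenerate: bool = False


# ---------------------------------------------------------------------------
# Clone-size distributions and the count pmf
# ---------------------------------------------------------------------------


@lru_cache(maxsize=64)
def _clone_pmf(n_max: int, eps: float) -> np.ndarray:
    """pmf of the observed (plated) size of a single mutational clone.

    Under Lea–Coulson a clone has size k with probability 1/(k(k+1)); plating
    a fraction ``eps`` thins it binomially.  Returns q[0..n_max].
    """
    q = np.zeros(n_max + 1)
    if eps >= 1.0:
        k = np.arange(1, n_max + 1, dtype=float)
        q[1:] = 1.0 / (k * (k + 1.0))
        return q
    # closed-form zero class: sum_k (1-eps)^k / (k(k+1))
    q[0] = 1.0 + eps * math.log(eps) / (1.0 - eps)
    if n_max == 0:
        return q
    # remaining classes by direct binomial mixture over the clone size k;
    # terms decay geometrically at rate (1-eps) beyond k ~ j/eps
    j = np.arange(1, n_max + 1)
    k_top = int(math.ceil((n_max + 20.0 * math.sqrt(n_max + 1.0) + 60.0) / eps))
    ks = np.arange(1, k_top + 1)
    for lo in range(0, ks.size, 4096):
        chunk = ks[lo : lo + 4096]
        w = 1.0 / (chunk * (chunk + 1.0))
        q[1:] += stats.binom.pmf(j[:, None], chunk[None, :], eps) @ w
    return q


def _pmf_scaled(m: float, q: np.ndarray) -> tuple[np.ndarray, float]:
    """Compound-Poisson (Panjer) recursion, numerically rescaled.

    Returns ``(p_scaled, log_scale)`` with pmf = p_scaled * exp(log_scale);
    the rescaling keeps the recursion finite for arbitrarily large ``m``
    (the unscaled p0 = exp(-m(1-q0)) underflows past m ~ 700).
    """
    n_max = q.size - 1
    r = np.arange(n_max + 1, dtype=float) * q  # r_k = k * q_k
    p = np.zeros(n_max + 1)
    p[0] = 1.0
    log_scale = -m * (1.0 - q[0])
    for n in range(1, n_max + 1):
        p[n] = (m / n) * float(np.dot(p[:n], r[n:0:-1]))
        if p[n] > _RESCALE:
            p[: n + 1] /= _RESCALE
            log_scale += math.log(_RESCALE)
    return p, log_scale


def ld_pmf(m: float, n_max: int, plating_fraction: float = 1.0) -> np.ndarray:
    """P(observed mutant colonies = n) for n = 0..n_max.

    For ``plating_fraction`` = 1 this is the Ma–Sandri–Sarkar recursion
    p0 = exp(-m), p_n = (m/n) * sum_{j<n} p_j/(n-j+1); for partial plating
    the clone sizes are binomially thinned before counting.
    """
    if m < 0:
        raise InputError(f"m must be non-negative, got {m}")
    if n_max < 0:
        raise InputError(f"n_max must be non-negative, got {n_max}")
    if not (0.0 < plating_fraction <= 1.0):
        raise InputError(
            f"plating_fraction must be in (0, 1], got {plating_fraction}"
        )
    q = _clone_pmf(int(n_max), float(plating_fraction))
    p, log_scale = _pmf_scaled(float(m), q)
    return p * math.exp(log_scale) if log_scale > -745 else p * 0.0


# ---------------------------------------------------------------------------
# Censored likelihood
# ---------------------------------------------------------------------------


def _censored_log_pmf(m: float, q: np.ndarray) -> np.ndarray:
    """log P over categories 0..n_max-1 exact, n_max = right-censored tail.

    The final category collects all mass P(count >= n_max), so jackpot
    cultures never require a recursion past the cap.
    """
    n_max = q.size - 1
    p, log_scale = _pmf_scaled(m, q)
    with np.errstate(divide="ignore"):
        logp = np.log(p) + log_scale
    # tail category: 1 - sum_{n < n_max} p_n, in whichever regime is stable
    body = p[:n_max].sum()
    log_body = (math.log(body) if body > 0 else -math.inf) + log_scale
    if log_body < -1e-9:
        logp[n_max] = math.log1p(-math.exp(log_body)) if log_body > -745 else 0.0
    else:
        tail = max(1.0 - body * math.exp(log_scale), 1e-300)
        logp[n_max] = math.log(tail)
    return logp


def _prepare_censored(counts: np.ndarray, censor_cap: int) -> tuple[np.ndarray, int]:
    """Histogram of counts clipped at the censoring cap.

    Returns ``(weights, n_max)`` where weights[c] is the number of cultures
    in category c and category n_max means "count >= n_max"; the largest
    observed count is always treated as censored.
    """
    max_count = int(counts.max())
    n_max = max(1, min(max_count, censor_cap))
    clipped = np.minimum(counts, n_max)
    weights = np.bincount(clipped, minlength=n_max + 1).astype(float)
    return weights, n_max


def _loglik_fn(data: FluctuationDataset, censor_cap: int):
    weights, n_max = _prepare_censored(data.counts, censor_cap)
    q = _clone_pmf(n_max, float(data.plating_fraction))
    nz = weights > 0

    def loglik(m: float) -> float:
        if m < 0:
            return -math.inf
        if m == 0.0:
            # all mass at zero counts
            return 0.0 if weights[1:].sum() == 0 else -math.inf
        logp = _censored_log_pmf(m, q)
        return float(np.dot(weights[nz], logp[nz]))

    return loglik, weights, n_max, q


def _maximize_1d(fun, t0: float, t_min: float = -35.0, t_max: float = 35.0):
    """Bracketed maximization of ``fun`` over t = ln(m).

    Expands a bracket around ``t0`` until an interior maximum is enclosed,
    then refines with bounded Brent to 1e-6 absolute in t (i.e. 1e-6
    relative in m).
    """
    mid = min(max(t0, t_min + 1.0), t_max - 1.0)
    step = 1.0
    lo, hi = mid - step, mid + step
    f_lo, f_mid, f_hi = fun(lo), fun(mid), fun(hi)
    for _ in range(200):
        if f_mid >= f_lo and f_mid >= f_hi:
            break
        step *= 1.6
        if f_lo > f_hi:  # walk downhill to the left
            mid, hi, f_mid, f_hi = lo, mid, f_lo, f_mid
            lo = mid - step
            f_lo = fun(lo)
        else:  # walk to the right
            lo, mid, f_lo, f_mid = mid, hi, f_mid, f_hi
            hi = mid + step
            f_hi = fun(hi)
        if hi > t_max or lo < t_min:
            raise EstimationError(
                "log-likelihood maximization did not bracket an interior "
                "maximum", bracket=(lo, mid, hi),
            )
    res = optimize.minimize_scalar(
        lambda t: -fun(t), bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-6},
    )
    return float(res.x), float(-res.fun)


def mle_rate(
    data: FluctuationDataset,
    censor_cap: int = 4096,
    compute_ci: bool = True,
) -> RateEstimate:
    """Maximum-likelihood mutation-rate estimate with profile-likelihood CI.

    Maximizes ``sum_i log P(count_i | m, eps)`` over ``m`` (on a log scale,
    to 1e-6 relative tolerance), converts to a per-cell-per-division rate by
    dividing by ``cells_per_culture`` and profiles the deviance to the
    ``2*(l(m_hat)-l(m)) = 3.841`` contour for the 95% CI (bisection to 1e-4
    relative tolerance).  Counts above ``censor_cap`` are right-censored.
    """
    nt = float(data.cells_per_culture)
    loglik, weights, n_max, q = _loglik_fn(data, censor_cap)
    n = data.n_cultures
    one_minus_q0 = 1.0 - q[0]

    if data.counts.max() == 0:
        # likelihood monotone decreasing in m; boundary MLE at zero
        m_hi = CHI2_95_1DF / (2.0 * n * one_minus_q0)
        return RateEstimate(
            m_hat=0.0, rate=0.0, ci_low=0.0, ci_high=m_hi / nt,
            loglik=0.0, n_cultures=n, label=data.label, degenerate=True,
        )

    if np.all(data.counts >= n_max):
        # every culture censored: likelihood increases toward the saturated
        # model P(tail) = 1 and m is unbounded above
        return RateEstimate(
            m_hat=math.inf, rate=math.inf, ci_low=0.0, ci_high=math.inf,
            loglik=0.0, n_cultures=n, label=data.label, degenerate=True,
        )

    # initial guess: P0 estimator if zeros are present, else a crude
    # median-based start (Lea–Coulson counts scale like m ln m)
    frac0 = float(weights[0]) / n
    if frac0 > 0:
        m0 = max(-math.log(frac0) / one_minus_q0, 1e-6)
    else:
        med = max(float(np.median(data.counts)), 1.0)
        m0 = max(med / max(math.log(med), 1.0), 1e-3)

    fun = lambda t: loglik(math.exp(t))
    t_hat, ll_max = _maximize_1d(fun, math.log(m0))
    m_hat = math.exp(t_hat)

    ci_low_m, ci_high_m = math.nan, math.nan
    if compute_ci:
        dev = lambda t: 2.0 * (ll_max - fun(t)) - CHI2_95_1DF
        # lower bound: expand downward until the deviance contour is crossed
        t_lo = t_hat - 1.0
        for _ in range(120):
            if dev(t_lo) > 0 or t_lo < -40.0:
                break
            t_lo -= 1.0
        if t_lo < -40.0 and dev(t_lo) <= 0:
            ci_low_m = 0.0
        else:
            ci_low_m = math.exp(
                optimize.brentq(dev, t_lo, t_hat, xtol=1e-4)
            )
        # upper bound
        t_hi = t_hat + 1.0
        for _ in range(120):
            if dev(t_hi) > 0 or t_hi > 45.0:
                break
            t_hi += 1.0
        if t_hi > 45.0 and dev(t_hi) <= 0:
            ci_high_m = math.inf
        else:
            ci_high_m = math.exp(
                optimize.brentq(dev, t_hat, t_hi, xtol=1e-4)
            )

    return RateEstimate(
        m_hat=m_hat, rate=m_hat / nt,
        ci_low=ci_low_m / nt, ci_high=ci_high_m / nt,
        loglik=ll_max, n_cultures=n, label=data.label,
    )


def sample_ld_counts(
    m: float, n_cultures: int, plating_fraction: float = 1.0, seed=None
) -> np.ndarray:
    """Sample mutant-colony counts from the Lea–Coulson model directly.

    Draws, per culture, a Poisson(m) number of mutational clones with sizes
    from P(K = k) = 1/(k(k+1)) (inverse-CDF: K = floor(1/U)) and thins each
    clone binomially by the plating fraction.  This samples the exact
    distribution ``ld_pmf`` describes without using its recursion, so it
    doubles as an independent Monte-Carlo oracle for the pmf.
    """
    if m < 0:
        raise InputError(f"m must be non-negative, got {m}")
    if not (0.0 < plating_fraction <= 1.0):
        raise InputError(
            f"plating_fraction must be in (0, 1], got {plating_fraction}"
        )
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    n_clones = rng.poisson(m, size=n_cultures)
    counts = np.zeros(n_cultures, dtype=np.int64)
    total = int(n_clones.sum())
    if total:
        sizes = np.floor(1.0 / rng.random(total)).astype(np.int64)
        if plating_fraction < 1.0:
            sizes = rng.binomial(sizes, plating_fraction)
        culture = np.repeat(np.arange(n_cultures), n_clones)
        np.add.at(counts, culture, sizes)
    return counts


def expected_rate_band(
    rate: float,
    n_cultures: int,
    cells_per_culture: float,
    plating_fraction: float = 1.0,
    n_max: int = 4096,
) -> tuple[float, float]:
    """Expected 95% likelihood-ratio CI band for a fluctuation design.

    Computes the Fisher information per culture of the Luria–Delbrück
    likelihood in t = ln(m) at the given true rate (numerically, from the
    censored pmf), and returns the Wald band rate*exp(±1.96/sqrt(n*I)).
    This approximates the 95% profile-likelihood CI an experiment of
    ``n_cultures`` cultures at this rate would report, and is how default
    compatibility bands are derived from a published point rate and culture
    count when the raw counts are not available.
    """
    if rate <= 0 or n_cultures < 1:
        raise InputError("rate must be positive and n_cultures >= 1")
    m = rate * cells_per_culture
    q = _clone_pmf(n_max, float(plating_fraction))
    h = 1e-3
    lp0 = _censored_log_pmf(m, q)
    lp_plus = _censored_log_pmf(m * math.exp(h), q)
    lp_minus = _censored_log_pmf(m * math.exp(-h), q)
    score = (lp_plus - lp_minus) / (2.0 * h)
    p = np.exp(lp0)
    info = float(np.dot(p, score**2))  # E[score] = 0, so this is Var(score)
    half_width = 1.959963984540054 / math.sqrt(n_cultures * info)
    return rate * math.exp(-half_width), rate * math.exp(half_width)


def lr_test(
    data_a: FluctuationDataset,
    data_b: FluctuationDataset,
    censor_cap: int = 4096,
) -> tuple[float, float]:
    """Likelihood-ratio test for equality of two mutation rates.

    The alternative fits ``m`` separately per dataset; the null constrains a
    common per-cell rate ``mu`` (so m_a = mu*Nt_a, m_b = mu*Nt_b).  Returns
    ``(statistic, p_value)`` with the p-value from chi-square with 1 df.
    """
    if data_a.counts.max() == 0 and data_b.counts.max() == 0:
        return 0.0, 1.0

    est_a = mle_rate(data_a, censor_cap=censor_cap, compute_ci=False)
    est_b = mle_rate(data_b, censor_cap=censor_cap, compute_ci=False)
    ll_a, _, _, _ = _loglik_fn(data_a, censor_cap)
    ll_b, _, _, _ = _loglik_fn(data_b, censor_cap)
    nt_a, nt_b = data_a.cells_per_culture, data_b.cells_per_culture

    fun = lambda t: ll_a(math.exp(t) * nt_a) + ll_b(math.exp(t) * nt_b)
    # pooled starting rate
    finite = [e.rate for e in (est_a, est_b) if 0.0 < e.rate < math.inf]
    mu0 = np.mean(finite) if finite else 1.0 / max(nt_a, nt_b)
    _, ll_common = _maximize_1d(fun, math.log(mu0))

    stat = max(0.0, 2.0 * (est_a.loglik + est_b.loglik - ll_common))
    p_value = float(stats.chi2.sf(stat, df=1))
    return stat, p_value
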