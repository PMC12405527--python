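"""Independent oracles for the test suite.

These deliberately avoid the package's count-propagation engine and pmf
recursions: the colony oracle tracks every cell individually with per-cell
Bernoulli draws, and the thinning oracle samples full-plating mutant counts
from the (hand-verifiable) MSS pmf and thins the totals binomially.
"""

from __future__ import annotations

import numpy as np

# genotype codes
WT, M1, M2, DSEQ, DSIM = 0, 1, 2, 3, 4


def simulate_agent(mu1, mu2, G, rng, rate_schedule=None):
    """Cell-by-cell colony simulation; returns final class counts.

    Every cell is an array entry; at each division every cell emits one
    daughter whose mutations are independent per-cell Bernoulli draws.
    ``rate_schedule`` optionally maps generation index g (0-based division
    round) to (mu1, mu2), to emulate whole-population rate changes.
    """
    cells = np.zeros(1, dtype=np.int8)
    for g in range(G):
        m1g, m2g = (mu1, mu2) if rate_schedule is None else rate_schedule(g)
        daughters = cells.copy()
        u1 = rng.random(daughters.size) < m1g
        u2 = rng.random(daughters.size) < m2g
        new = daughters.copy()
        wt = daughters == WT
        new[wt & u1 & ~u2] = M1
        new[wt & ~u1 & u2] = M2
        new[wt & u1 & u2] = DSIM
        new[(daughters == M1) & u2] = DSEQ
        new[(daughters == M2) & u1] = DSEQ
        cells = np.concatenate([cells, new])
    return {
        "wt": int(np.sum(cells == WT)),
        "m1_only": int(np.sum(cells == M1)),
        "m2_only": int(np.sum(cells == M2)),
        "double_seq": int(np.sum(cells == DSEQ)),
        "double_sim": int(np.sum(cells == DSIM)),
    }


def p0_estimate(counts):
    """The P0 estimator of m: -ln(fraction of mutant-free cultures)."""
    counts = np.asarray(counts)
    frac0 = np.mean(counts == 0)
    return -np.log(frac0)


def thinned_counts_oracle(m, eps, n_samples, rng, pmf_full):
    """Monte-Carlo sample of plated counts: draw full-plating counts from
    the supplied eps=1 pmf (tail mass lumped in the last bin) and thin the
    totals binomially by eps."""
    p = pmf_full.copy()
    p[-1] += max(0.0, 1.0 - p.sum())
    full = rng.choice(p.size, size=n_samples, p=p / p.sum())
    return rng.binomial(full, eps)
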