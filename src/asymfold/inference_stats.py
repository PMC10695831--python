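"""Significance machinery: mean-difference permutation test and paired t-test.

The permutation test makes no distributional assumption — it only assumes
data exchangeability under the null.  The statistic is the difference in
group means; all distinct reassignments of the pooled values into the two
group sizes are enumerated exactly when feasible, otherwise sampled without
replacement.  Counting is inclusive (assignments with a statistic >= the
observed one, the observed labelling among them), so the smallest attainable
p for group sizes (m, n) is 1/C(m+n, m) one-sided and, for fully separated
data, 2/C(m+n, m) two-sided — e.g. 2/70 = 0.029 at four replicates each.
"""

from __future__ import annotations

import itertools
import random
from dataclasses import dataclass
from math import comb
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .errors import DomainError

__all__ = ["PermutationResult", "permutation_test", "paired_t_test"]

_TIE_REL = 1e-12  # relative tolerance treating float-equal statistics as ties


@dataclass(frozen=True)
class PermutationResult:
    p_value: float
    statistic_observed: float
    n_assignments_evaluated: int
    exhaustive: bool
    sided: str
    seed: Optional[int] = None


def _unrank_combination(rank: int, n: int, k: int) -> tuple:
    """Map a rank in [0, C(n,k)) to the combination of that rank.

    Combinations are ordered lexicographically over sorted index tuples
    (combinatorial number system).  Works with python bigints, so it is safe
    for totals far beyond 2**63.
    """
    out = []
    x = 0
    for remaining in range(k, 0, -1):
        while True:
            c = comb(n - x - 1, remaining - 1)
            if rank < c:
                out.append(x)
                x += 1
                break
            rank -= c
            x += 1
    return tuple(out)


def permutation_test(
    a: Sequence[float],
    b: Sequence[float],
    sided: str = "two",
    max_exhaustive: int = 1_000_000,
    n_samples: int = 100_000,
    seed: Optional[int] = None,
) -> PermutationResult:
    """Exact (or sampled-without-replacement) mean-difference permutation test.

    Parameters
    ----------
    a, b : the two replicate sets (each >= 2 values).
    sided : "two" uses |mean(a) − mean(b)|; "one" tests in the direction of
        the observed difference.
    max_exhaustive : enumerate all C(|a|+|b|, |a|) assignments when their
        count does not exceed this, else sample.
    n_samples : number of distinct assignments drawn when sampling; if it
        meets or exceeds the total count the test falls back to exhaustive.
    seed : seeds the rank sampler (required only on the sampled path).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise DomainError("each group needs at least 2 replicates")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise DomainError("non-finite replicate value")
    if sided not in ("two", "one"):
        raise DomainError("sided must be 'two' or 'one'")

    pool = np.concatenate([a, b])
    n_tot, n_a = pool.size, a.size
    total = comb(n_tot, n_a)

    d_obs = float(a.mean() - b.mean())
    sign = 1.0 if (sided == "two" or d_obs >= 0) else -1.0

    def stat(d: float) -> float:
        return abs(d) if sided == "two" else sign * d

    s_obs = stat(d_obs)
    tol = _TIE_REL * (abs(s_obs) + 1.0)

    pool_sum = pool.sum()
    exhaustive = total <= max_exhaustive or n_samples >= total

    if exhaustive:
        index_iter = itertools.combinations(range(n_tot), n_a)
        n_eval = total
        used_seed = None
    else:
        rng = random.Random(seed)
        ranks = set()
        while len(ranks) < n_samples:
            ranks.add(rng.randrange(total))
        index_iter = (_unrank_combination(r, n_tot, n_a) for r in sorted(ranks))
        n_eval = n_samples
        used_seed = seed

    count = 0
    for idx in index_iter:
        sa = pool[list(idx)].sum()
        d = sa / n_a - (pool_sum - sa) / (n_tot - n_a)
        if stat(d) >= s_obs - tol:
            count += 1
    if not exhaustive:
        # inclusive counting: ensure the observed labelling itself is counted
        count = max(count, 1)

    return PermutationResult(
        p_value=count / n_eval,
        statistic_observed=s_obs,
        n_assignments_evaluated=n_eval,
        exhaustive=exhaustive,
        sided=sided,
        seed=used_seed,
    )


def paired_t_test(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-tailed paired t-test p-value on the per-pair differences."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise DomainError("paired samples must have equal length")
    if x.size < 2:
        raise DomainError("need at least 2 pairs")
    d = x - y
    if np.all(d == d[0]):
        raise DomainError("zero variance of paired differences")
    return float(stats.ttest_rel(x, y).pvalue)
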