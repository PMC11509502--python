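"""Ranked-list gene-set enrichment by the minimum-hypergeometric statistic.

Given a ranked protein list and a binary membership vector for a set, the
mHG score is the smallest hypergeometric upper-tail probability over all
proper prefixes of the list.  Because the score minimizes over prefixes,
it is not itself a p-value; the exact p-value is computed by dynamic
programming over the (prefix length, member count) lattice, counting the
fraction of the C(N, K) equally likely arrangements whose mHG score is at
least as extreme.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from proteopair.io import GeneSetCollection

__all__ = [
    "EnrichmentResult",
    "hypergeometric_tail",
    "mhg_score",
    "mhg_pvalue",
    "enrich_ranked_list",
]

logger = logging.getLogger(__name__)

# Relative tolerance when comparing hypergeometric tails to the mHG score:
# both sides come from the same floating-point routine, so a hair of slack
# guards against spurious strict inequality.
_REL_TOL = 1e-9


@dataclass
class EnrichmentResult:
    term_id: str
    description: str
    N: int  # ranked-list length
    K: int  # set members present in the list
    n_opt: int  # optimal prefix length
    b_opt: int  # members within the optimal prefix
    mhg_score: float
    p_value: float
    q_value: float = math.nan


def hypergeometric_tail(N: int, K: int, n: int, b: int) -> float:
    """P(X >= b) for X ~ Hypergeometric(N, K, n).

    N balls, K of them marked, n drawn without replacement; the tail is the
    probability of drawing at least b marked balls.
    """
    if not (0 <= b <= n <= N and b <= K <= N):
        raise ValueError(f"invalid hypergeometric arguments N={N}, K={K}, n={n}, b={b}")
    if b == 0:
        return 1.0
    return float(stats.hypergeom.sf(b - 1, N, K, n))


def mhg_score(labels: Sequence[int]) -> tuple[float, int, int]:
    """Minimum hypergeometric tail over proper prefixes of a ranked list.

    `labels` is the binary membership vector in rank order (best rank
    first).  Returns (score, n_opt, b_opt) where n_opt is the smallest
    prefix length attaining the minimum; the full list (n = N) is excluded
    as uninformative.  K = 0 gives (1.0, 0, 0).
    """
    lab = np.asarray(labels, dtype=int)
    if lab.ndim != 1 or len(lab) < 1:
        raise ValueError("labels must be a non-empty 1-D vector")
    if not np.isin(lab, (0, 1)).all():
        raise ValueError("labels must be binary")
    N = len(lab)
    K = int(lab.sum())
    if K == 0 or N == 1:
        return (1.0, 0, 0)
    ns = np.arange(1, N)
    bs = np.cumsum(lab)[: N - 1]
    tails = stats.hypergeom.sf(bs - 1, N, K, ns)  # sf(-1) = 1 handles b = 0
    best = float(tails.min())
    if best >= 1.0:
        return (1.0, 0, 0)
    i = int(np.argmax(tails <= best * (1 + _REL_TOL)))  # smallest attaining n
    return (best, int(ns[i]), int(bs[i]))


def mhg_pvalue(score: float, N: int, K: int) -> float:
    """Exact p-value of an mHG score by lattice dynamic programming.

    Under the null every arrangement of K ones among N slots is equally
    likely.  Paths from (0, 0) to (N, K) in the (prefix length, ones seen)
    lattice are counted with exact integer arithmetic, zeroing every cell
    whose hypergeometric tail is <= score (i.e. arrangements whose own mHG
    would be at least as extreme); the p-value is the complementary
    fraction of surviving paths.
    """
    if not 0 <= score <= 1:
        raise ValueError("score must lie in [0, 1]")
    if not 0 <= K <= N or N < 1:
        raise ValueError(f"invalid N={N}, K={K}")
    if K == 0 or score >= 1.0:
        # K = 0 always scores 1; score 1 is matched by every arrangement.
        return 1.0
    cutoff = score * (1 + _REL_TOL)
    # counts[b] = number of paths to (n, b) avoiding the rejection region
    counts = [0] * (K + 1)
    counts[0] = 1
    for n in range(1, N + 1):
        b_lo = max(0, n - (N - K))
        b_hi = min(n, K)
        b_range = np.arange(b_lo, b_hi + 1)
        if n < N:  # the mHG minimization excludes the full list
            rejected = stats.hypergeom.sf(b_range - 1, N, K, n) <= cutoff
        else:
            rejected = np.zeros(len(b_range), dtype=bool)
        new = [0] * (K + 1)
        for b, rej in zip(b_range.tolist(), rejected.tolist()):
            if rej:
                continue
            c = counts[b]  # extend with a zero label
            if b > 0:
                c += counts[b - 1]  # extend with a one label
            new[b] = c
        counts = new
    surviving = counts[K]
    total = math.comb(N, K)
    return float((total - surviving) / total)


def enrich_ranked_list(
    ranked: Sequence[str],
    sets: GeneSetCollection,
    min_set_size: int = 3,
) -> list[EnrichmentResult]:
    """mHG enrichment of every gene set against a ranked protein list.

    Set members absent from the ranked list are ignored; sets retaining
    fewer than `min_set_size` members are skipped.  Results carry BH
    q-values across the reported terms and are sorted by ascending p-value
    (ties by term id).
    """
    from proteopair.paired_de import benjamini_hochberg

    ranked = list(ranked)
    if not ranked:
        raise ValueError("ranked list is empty")
    pos = {pid: i for i, pid in enumerate(ranked)}
    N = len(ranked)
    results: list[EnrichmentResult] = []
    for term, (desc, members) in sets:
        hit_positions = sorted(pos[m] for m in members if m in pos)
        K = len(hit_positions)
        if K < min_set_size:
            continue
        labels = np.zeros(N, dtype=int)
        labels[hit_positions] = 1
        score, n_opt, b_opt = mhg_score(labels)
        p = mhg_pvalue(score, N, K)
        results.append(
            EnrichmentResult(
                term_id=term,
                description=desc,
                N=N,
                K=K,
                n_opt=n_opt,
                b_opt=b_opt,
                mhg_score=score,
                p_value=p,
            )
        )
    if not results:
        logger.warning("no gene set passed the min_set_size=%d filter", min_set_size)
        return results
    results.sort(key=lambda r: (r.p_value, r.term_id))
    qs = benjamini_hochberg([r.p_value for r in results])
    for r, q in zip(results, qs):
        r.q_value = float(q)
    return results
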