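"""Benchmarking and comparison machinery for prioritized SNP lists.

Includes the median-rank permutation test (are known disease loci ranked
better by a score than random SNP sets of the same size?), greedy LD clumping
to independent signals, and thin wrappers over the standard rank-sum and
Spearman tests used to compare MAF/OR distributions between prioritization
strategies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .ldpanel import LDPanel, LDUndefinedError

__all__ = [
    "BenchmarkResult",
    "benchmark_rank_permutation",
    "prune_independent",
    "ranksum_test",
    "spearman",
]


@dataclass(frozen=True)
class BenchmarkResult:
    """Outcome of the median-rank permutation benchmark.

    Rank 1 is the best (top of the score-sorted list). The one-tailed p-value
    asks how often a random same-size SNP set achieves a median rank at least
    as good (<=) as the observed hits. In sampled mode the +1-corrected
    estimator p = (1 + #{null <= obs}) / (B + 1) is used, so p is never 0;
    in exhaustive mode p is the exact fraction over all subsets.
    """

    observed_median_rank: float
    null_medians: np.ndarray
    p_one_tailed: float
    B: int
    seed: int | None
    exhaustive: bool


def benchmark_rank_permutation(
    ranked_ids: Sequence[str],
    hit_ids: Sequence[str],
    B: int = 10_000,
    seed: int | None = None,
    max_exhaustive: int = 10_000,
) -> BenchmarkResult:
    """Test whether known hits sit higher in a ranked list than chance.

    ``ranked_ids`` is the full list sorted best-first; ``hit_ids`` must all be
    present in it. The statistic is the median (1-based) rank of the hits; the
    null distribution is the median rank of size-|hits| subsets drawn
    uniformly without replacement from the whole list. When C(n, k) <=
    ``max_exhaustive`` every subset is enumerated instead of sampled.
    """
    n = len(ranked_ids)
    k = len(hit_ids)
    if not (1 <= k <= n):
        raise ValueError("need 1 <= |hits| <= |ranked|")
    pos = {v: i + 1 for i, v in enumerate(ranked_ids)}
    missing = [h for h in hit_ids if h not in pos]
    if missing:
        raise ValueError(f"hits not present in ranked list: {missing}")
    observed = float(np.median([pos[h] for h in hit_ids]))

    if math.comb(n, k) <= max_exhaustive:
        null = np.array([float(np.median(c)) for c in combinations(range(1, n + 1), k)])
        p = float((null <= observed).sum() / null.size)
        return BenchmarkResult(observed, null, p, int(null.size), seed, exhaustive=True)

    rng = np.random.default_rng(seed)
    draws = np.argsort(rng.random((B, n)), axis=1)[:, :k] + 1
    null = np.median(draws, axis=1).astype(float)
    p = float((1 + (null <= observed).sum()) / (B + 1))
    return BenchmarkResult(observed, null, p, B, seed, exhaustive=False)


def prune_independent(
    ids: Sequence[str],
    scores: Mapping[str, float],
    panel: LDPanel,
    r2_max: float = 0.2,
    half_window_bp: int = 500_000,
) -> list[str]:
    """Greedy LD clumping: reduce a scored SNP list to independent signals.

    SNPs are visited by score descending (ties by id); a SNP is kept iff its
    r² with every already-kept SNP on the same chromosome within
    ``half_window_bp`` is strictly below ``r2_max``. LD beyond the window, on
    other chromosomes, or undefined in the panel is treated as 0.
    """
    order = sorted(ids, key=lambda i: (-scores[i], i))
    kept: list[str] = []
    for vid in order:
        if vid not in panel:
            kept.append(vid)
            continue
        v = panel.variant(vid)
        ok = True
        for kid in kept:
            if kid not in panel:
                continue
            u = panel.variant(kid)
            if u.chrom != v.chrom or abs(u.pos - v.pos) > half_window_bp:
                continue
            try:
                if panel.r2(vid, kid) >= r2_max:
                    ok = False
                    break
            except LDUndefinedError:
                continue
        if ok:
            kept.append(vid)
    return kept


def ranksum_test(
    x: Sequence[float], y: Sequence[float], alternative: str = "two-sided"
) -> tuple[float, float]:
    """Wilcoxon rank-sum test of two independent samples.

    Returns (W, p) where W is the rank-sum of ``x`` on pooled mid-ranks.
    The p-value is exact (full enumeration) for tie-free samples with
    |x| + |y| <= 12, otherwise the normal approximation with tie and
    continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (no_ties and pooled.size <= 12) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method, use_continuity=True)
    w = float(res.statistic + x.size * (x.size + 1) / 2)  # U -> rank-sum of x
    return w, float(res.pvalue)


def spearman(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation (Pearson correlation of pooled mid-ranks)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length samples of size >= 3")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValueError("correlation undefined for a constant vector")
    return float(stats.spearmanr(x, y).statistic)
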