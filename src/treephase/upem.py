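"""The UPEM objective (uniform probabilistic error minimization).

UPEM scores a k-way partition of reads as a sum of log p-values:

* per cluster, a one-sided binomial test of the cluster's error count
  against the expected miscall rate delta -- the number of trials is
  (D_i + S_i)/sigma and the observed "successes" D_i/sigma, where sigma is
  a dataset-specific normalizer (median read length / 25) that keeps this
  term from drowning out
* a chi-square goodness-of-fit p-value of the cluster sizes against the
  uniform expectation, encoding the assumption that the k haplotypes are
  covered evenly.

Higher is better; the score is always <= 0.  All p-values are computed in
log space.  The incremental :class:`ClusterCounts` structure keeps per-site
allele tallies per cluster so a single-read move re-scores in O(read
length) instead of O(cluster size * length).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Dict, List, Sequence, Tuple

from scipy import stats

from .fragments import Fragment, FragmentSet, Partition

#: Stand-in for log(0) so sums of log p-values stay finite.
LOG_FLOOR: float = -700.0


@dataclass(frozen=True)
class UpemParams:
    """delta: per-allele miscall probability; sigma: trial-count normalizer."""

    delta: float
    sigma: float

    def __post_init__(self) -> None:
        if not (0.0 < self.delta < 0.5):
            raise ValueError(f"delta must be in (0, 0.5), got {self.delta}")
        if self.sigma <= 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def binomial_log_tail(n_trials: int, p: float, threshold: int) -> float:
    """log P(X > threshold) for X ~ Binom(n_trials, p), exact, in log space.

    The strict tail P(X > t) is used; an empty tail (t >= n) returns the
    finite floor LOG_FLOOR instead of -inf.
    """
    if n_trials < 0:
        raise ValueError("n_trials must be >= 0")
    if not (0.0 < p < 1.0):
        raise ValueError(f"p must be in (0, 1), got {p}")
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if threshold >= n_trials:
        return LOG_FLOOR
    return _binom_logsf_cached(threshold, n_trials, p)


@lru_cache(maxsize=1 << 16)
def _binom_logsf_cached(threshold: int, n_trials: int, p: float) -> float:
    out = float(stats.binom.logsf(threshold, n_trials, p))
    if not math.isfinite(out):
        return LOG_FLOOR
    return out


def chi2_uniformity_logp(sizes: Sequence[int]) -> float:
    """log p-value of Pearson's chi-square of sizes vs. a uniform split.

    df = k - 1; perfectly equal sizes give statistic 0 and log p = 0.
    """
    k = len(sizes)
    if k < 2:
        raise ValueError("need at least 2 cluster sizes")
    total = float(sum(sizes))
    if total <= 0:
        raise ValueError("all cluster sizes are zero")
    return _chi2_logp_cached(tuple(sorted(sizes)))


@lru_cache(maxsize=1 << 16)
def _chi2_logp_cached(sizes: Tuple[int, ...]) -> float:
    k = len(sizes)
    expected = sum(sizes) / k
    stat = sum((x - expected) ** 2 for x in sizes) / expected
    out = float(stats.chi2.logsf(stat, k - 1))
    if not math.isfinite(out):
        return LOG_FLOOR
    return out


def upem_from_counts(
    ds_counts: Sequence[Tuple[int, int]],
    sizes: Sequence[int],
    params: UpemParams,
) -> float:
    """UPEM from per-cluster (D_i, S_i) pairs and cluster sizes.

    Clusters with no observations contribute nothing to the binomial term
    but their zero size still enters the uniformity term.
    """
    score = 0.0
    for D, S in ds_counts:
        n = _round_half_up((D + S) / params.sigma)
        t = _round_half_up(D / params.sigma)
        if n <= 0:
            continue
        score += binomial_log_tail(n, params.delta, t)
    score += chi2_uniformity_logp(sizes)
    return score


class ClusterCounts:
    """Per-cluster, per-site allele tallies supporting O(length) moves.

    D and S per cluster follow from the tallies alone: at each covered site
    the consensus allele is a maximizing allele, so S gains the column max
    and D the remainder -- no explicit consensus or tie-break needed.
    """

    def __init__(self, partition: Partition, fragments: FragmentSet) -> None:
        self.fragments = fragments
        self.k = partition.k
        # cluster -> site -> [count of allele 0..3]
        self._counts: List[Dict[int, List[int]]] = [{} for _ in range(self.k)]
        self._sizes: List[int] = [0] * self.k
        self._D: List[int] = [0] * self.k
        self._S: List[int] = [0] * self.k
        for i, cl in enumerate(partition.clusters):
            for fid in sorted(cl):
                self.add(fid, i)

    def sizes(self) -> List[int]:
        return list(self._sizes)

    def ds_counts(self) -> List[Tuple[int, int]]:
        return list(zip(self._D, self._S))

    def _apply(self, fragment: Fragment, cluster: int, sign: int) -> None:
        counts = self._counts[cluster]
        dD = dS = 0
        for j, a in fragment.alleles.items():
            col = counts.get(j)
            if col is None:
                col = counts[j] = [0, 0, 0, 0]
            tot_old = sum(col)
            max_old = max(col)
            col[a] += sign
            tot_new = tot_old + sign
            max_new = max(col)
            dS += max_new - max_old
            dD += (tot_new - max_new) - (tot_old - max_old)
            if tot_new == 0:
                del counts[j]
        self._D[cluster] += dD
        self._S[cluster] += dS
        self._sizes[cluster] += sign

    def add(self, fragment_id: str, cluster: int) -> None:
        self._apply(self.fragments[fragment_id], cluster, +1)

    def remove(self, fragment_id: str, cluster: int) -> None:
        self._apply(self.fragments[fragment_id], cluster, -1)

    def score(self, params: UpemParams) -> float:
        return upem_from_counts(self.ds_counts(), self._sizes, params)

    def move_delta(self, fragment_id: str, src: int, dst: int, params: UpemParams) -> float:
        """UPEM(after moving fragment src -> dst) - UPEM(before)."""
        before = self.score(params)
        self.remove(fragment_id, src)
        self.add(fragment_id, dst)
        after = self.score(params)
        self.remove(fragment_id, dst)
        self.add(fragment_id, src)
        return after - before


def upem(partition: Partition, fragments: FragmentSet, params: UpemParams) -> float:
    """UPEM score of a partition (k >= 2; empty clusters allowed)."""
    if partition.k < 2:
        raise ValueError("UPEM requires at least 2 clusters")
    counts = ClusterCounts(partition, fragments)
    return counts.score(params)
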