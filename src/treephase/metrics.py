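"""Phasing accuracy metrics.

All three metrics compare a candidate k x m haplotype matrix against the
truth and are invariant to a global relabeling of the candidate rows:

* Hamming error rate -- the best-permutation fraction of miscalled
  alleles, min over row permutations of sum d'(truth_i, cand_sigma(i)) / (m k),
  where d' counts a coordinate as an error when the alleles differ or
  exactly one side is uncalled ('-').
* switch error rate (SWER) -- the minimum number of changes of the
  truth-to-candidate row correspondence along the chromosome, divided by
  m; computed by dynamic programming over the per-column sets of
  allele-preserving permutations.
* q-block error rate -- the truth is cut into consecutive windows of q
  variants and the best-permutation Hamming rate is averaged over
  windows; it interpolates between switch-like behavior (q = 2) and the
  Hamming rate (q = m).
"""

from __future__ import annotations

import itertools
import math
from typing import Dict, List, Tuple

import numpy as np


def _check_shapes(truth: np.ndarray, candidate: np.ndarray) -> Tuple[int, int]:
    truth = np.asarray(truth)
    candidate = np.asarray(candidate)
    if truth.shape != candidate.shape or truth.ndim != 2:
        raise ValueError(
            f"haplotype matrices must share a (k, m) shape; got "
            f"{truth.shape} vs {candidate.shape}"
        )
    return truth.shape


def hamming_error_rate(truth: np.ndarray, candidate: np.ndarray) -> float:
    """Best-permutation Hamming error rate in [0, 1].

    A coordinate counts as an error when the two alleles differ, including
    when exactly one of them is '-'; two '-' agree.
    """
    k, m = _check_shapes(truth, candidate)
    if m == 0:
        return 0.0
    best = math.inf
    for perm in itertools.permutations(range(k)):
        errs = int(np.sum(truth != candidate[list(perm), :]))
        if errs < best:
            best = errs
    return best / (m * k)


def _column_permutations(
    truth_col: np.ndarray,
    cand_col: np.ndarray,
    perms: List[Tuple[int, ...]],
) -> Tuple[List[int], int]:
    """Indices of permutations consistent at this column.

    A permutation sigma is consistent when truth[j] == cand[sigma(j)] for
    every row j (under d'-style matching, so '-' only matches '-').  When
    no permutation is consistent the set relaxes to the permutations with
    the fewest mismatches and that mismatch count is reported.
    """
    mism = [
        int(np.sum(truth_col != cand_col[list(perm)])) for perm in perms
    ]
    best = min(mism)
    idxs = [i for i, x in enumerate(mism) if x == best]
    return idxs, best


def switch_error_details(
    truth: np.ndarray, candidate: np.ndarray
) -> Tuple[int, int, int]:
    """(minimal switch count, residual column mismatches, m).

    The DP tracks, per column, the cost of ending in each consistent
    permutation; a transition between different permutations at adjacent
    columns costs one switch.  Columns admitting no consistent permutation
    (possible with allele errors) relax to their minimum-mismatch
    permutations, and those mismatches accumulate in the second component.
    """
    k, m = _check_shapes(truth, candidate)
    perms = list(itertools.permutations(range(k)))
    if m == 0:
        return 0, 0, 0
    idxs, mismatches = _column_permutations(truth[:, 0], candidate[:, 0], perms)
    costs: Dict[int, int] = {i: 0 for i in idxs}
    for col in range(1, m):
        idxs, mm = _column_permutations(truth[:, col], candidate[:, col], perms)
        mismatches += mm
        best_prev = min(costs.values())
        costs = {
            i: min(costs.get(i, math.inf), best_prev + 1) for i in idxs
        }
    return int(min(costs.values())), mismatches, m


def switch_error_rate(truth: np.ndarray, candidate: np.ndarray) -> float:
    """Minimal switch count divided by the number of variants."""
    switches, _, m = switch_error_details(truth, candidate)
    if m == 0:
        return 0.0
    return switches / m


def q_block_error_rate(
    truth: np.ndarray, candidate: np.ndarray, q: int
) -> float:
    """Mean best-permutation Hamming rate over consecutive q-variant windows."""
    if q < 2:
        raise ValueError(f"q must be >= 2, got {q}")
    k, m = _check_shapes(truth, candidate)
    if m == 0:
        return 0.0
    rates = []
    for start in range(0, m, q):
        stop = min(start + q, m)
        rates.append(
            hamming_error_rate(truth[:, start:stop], candidate[:, start:stop])
        )
    return float(np.mean(rates))
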