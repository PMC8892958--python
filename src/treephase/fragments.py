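"""Variant-space read model.

Reads aligned to a chromosome are projected onto its ordered list of
heterozygous variants: a *fragment* records, for each variant a read covers,
which allele the read carries (codes 0-3; 0 is the reference allele).
Positions the read does not cover are simply absent, the classical ``-``
symbol of the minimum-error-correction (MEC) literature.

This module holds the fragment containers and the MEC-family quantities:
pairwise agreement/disagreement counts (s, d), the per-cluster consensus
haplotype, the per-cluster error counts (D, S) and the MEC score of a
partition of reads into ploidy-many clusters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np

#: Sentinel for the '-' symbol (position not covered / no call).
GAP: int = -1

#: Allowed allele codes: reference (0) plus up to three alternates.
ALLELE_CODES: Tuple[int, ...] = (0, 1, 2, 3)


@dataclass(frozen=True)
class Fragment:
    """One read in variant space.

    Parameters
    ----------
    id
        Unique read identifier.
    alleles
        Sparse map from 0-based variant index to allele code in {0,1,2,3}.
    qualities
        Optional map from variant index to per-call error probability in
        (0, 1).  Carried for file round-trips; the combinatorial scores use
        counts only.
    """

    id: str
    alleles: Mapping[int, int]
    qualities: Optional[Mapping[int, float]] = None

    def __post_init__(self) -> None:
        if not self.alleles:
            raise ValueError(f"fragment {self.id!r}: empty allele map")
        for j, a in self.alleles.items():
            if a not in ALLELE_CODES:
                raise ValueError(
                    f"fragment {self.id!r}: allele code {a} at index {j} "
                    f"outside {ALLELE_CODES}"
                )
        if self.qualities is not None and set(self.qualities) != set(self.alleles):
            raise ValueError(
                f"fragment {self.id!r}: quality keys do not match allele keys"
            )

    @property
    def first(self) -> int:
        """Smallest covered variant index."""
        return min(self.alleles)

    @property
    def last(self) -> int:
        """Largest covered variant index."""
        return max(self.alleles)

    @property
    def length(self) -> int:
        """Read length in variant space: last covered index minus first."""
        return self.last - self.first

    def __len__(self) -> int:
        return len(self.alleles)


@dataclass
class FragmentSet:
    """A set of fragments over ``m`` variant sites."""

    fragments: List[Fragment]
    m: int
    _by_id: Dict[str, Fragment] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        self._by_id = {}
        for fr in self.fragments:
            if fr.id in self._by_id:
                raise ValueError(f"duplicate fragment id {fr.id!r}")
            if fr.last >= self.m:
                raise ValueError(
                    f"fragment {fr.id!r} covers index {fr.last} >= m={self.m}"
                )
            self._by_id[fr.id] = fr

    def __len__(self) -> int:
        return len(self.fragments)

    def __iter__(self):
        return iter(self.fragments)

    def __getitem__(self, fragment_id: str) -> Fragment:
        return self._by_id[fragment_id]

    def __contains__(self, fragment_id: str) -> bool:
        return fragment_id in self._by_id

    def ids(self) -> List[str]:
        return [fr.id for fr in self.fragments]


# A haplotype is a dense array of length m over {GAP, 0, 1, 2, 3}.
Haplotype = np.ndarray


def empty_haplotype(m: int) -> Haplotype:
    return np.full(m, GAP, dtype=np.int8)


@dataclass
class Partition:
    """An ordered list of k disjoint fragment-id clusters."""

    clusters: List[Set[str]]

    def __post_init__(self) -> None:
        seen: Set[str] = set()
        for i, cl in enumerate(self.clusters):
            overlap = seen & cl
            if overlap:
                raise ValueError(
                    f"cluster {i} shares fragments with earlier clusters: "
                    f"{sorted(overlap)[:3]}..."
                )
            seen |= cl

    @property
    def k(self) -> int:
        return len(self.clusters)

    def sizes(self) -> List[int]:
        return [len(cl) for cl in self.clusters]

    def assigned_ids(self) -> Set[str]:
        out: Set[str] = set()
        for cl in self.clusters:
            out |= cl
        return out

    def copy(self) -> "Partition":
        return Partition([set(cl) for cl in self.clusters])

    def cluster_of(self, fragment_id: str) -> int:
        for i, cl in enumerate(self.clusters):
            if fragment_id in cl:
                return i
        raise KeyError(fragment_id)


def pair_diff_same(r1: Fragment, r2: Fragment) -> Tuple[int, int]:
    """Count differing (d) and agreeing (s) alleles on the shared sites.

    Only positions covered by *both* fragments contribute; disjoint
    fragments return ``(0, 0)``.  Symmetric in its arguments.
    """
    a1, a2 = r1.alleles, r2.alleles
    if len(a2) < len(a1):
        a1, a2 = a2, a1
    d = s = 0
    for j, allele in a1.items():
        other = a2.get(j)
        if other is None:
            continue
        if allele == other:
            s += 1
        else:
            d += 1
    return d, s


def consensus(
    cluster: Iterable[Fragment],
    interval: Optional[Tuple[int, int]] = None,
    m: Optional[int] = None,
) -> Haplotype:
    """Majority-vote consensus haplotype H(R_i) of a cluster of reads.

    At each variant index the most frequent allele among covering reads is
    taken; ties go to the smallest allele code, and sites covered by no read
    stay '-'.  ``interval`` (half-open, 0-based) restricts voting to a
    window; ``m`` sets the output length (defaults to max covered index + 1).
    """
    counts: Dict[int, np.ndarray] = {}
    lo, hi = (interval if interval is not None else (0, None))
    for fr in cluster:
        for j, a in fr.alleles.items():
            if j < lo or (hi is not None and j >= hi):
                continue
            col = counts.get(j)
            if col is None:
                col = counts[j] = np.zeros(4, dtype=np.int64)
            col[a] += 1
    if m is None:
        m = (max(counts) + 1) if counts else (hi if hi is not None else lo)
    hap = empty_haplotype(m)
    for j, col in counts.items():
        # np.argmax returns the first maximum -> smallest allele code on ties
        hap[j] = int(np.argmax(col))
    return hap


def cluster_error_counts(cluster: Sequence[Fragment]) -> Tuple[int, int]:
    """(D, S): disagreements and agreements of a cluster with its consensus.

    D(R_i) = sum_r d(H(R_i), r) and S(R_i) = sum_r s(H(R_i), r).  D + S
    equals the total number of allele observations in the cluster, since
    the consensus is defined at every covered site.
    """
    cluster = list(cluster)
    if not cluster:
        return 0, 0
    counts: Dict[int, np.ndarray] = {}
    for fr in cluster:
        for j, a in fr.alleles.items():
            col = counts.get(j)
            if col is None:
                col = counts[j] = np.zeros(4, dtype=np.int64)
            col[a] += 1
    D = S = 0
    for col in counts.values():
        tot = int(col.sum())
        best = int(col.max())
        S += best
        D += tot - best
    return D, S


def mec_score(partition: Partition, fragments: FragmentSet) -> int:
    """MEC score of a partition: total disagreement with cluster consensuses."""
    total = 0
    for cl in partition.clusters:
        members = []
        for fid in cl:
            if fid not in fragments:
                raise KeyError(f"unknown fragment id {fid!r}")
            members.append(fragments[fid])
        D, _ = cluster_error_counts(members)
        total += D
    return total
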