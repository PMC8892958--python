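"""Final haplotype construction from a read partition.

Without genotype information the output is simply each cluster's consensus
haplotype.  When a VCF supplies per-site allele dosages (how many of the k
haplotypes carry each allele), the output is constrained so the phased
column reproduces those dosages exactly: at every site all (cluster,
allele) calls are ranked by a confidence ratio

    c(i, j, a) = #{reads of cluster j with allele a at i}
                 / (#{reads of cluster j with a different allele at i} + 1)

and alleles are handed out greedily, never exceeding an allele's dosage
and never overwriting a haplotype already called at that site.  Because
every (cluster, allele) pair enters the ranking -- confidence 0 included --
each haplotype receives a call at every site and the column dosages match
the genotypes exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional

import numpy as np

from .fragments import ALLELE_CODES, GAP, FragmentSet, Partition, consensus


@dataclass
class GenotypeTable:
    """Per-variant allele dosages; dosages at each site sum to the ploidy."""

    ploidy: int
    dosages: List[Dict[int, int]]

    def __post_init__(self) -> None:
        for i, dm in enumerate(self.dosages):
            if any(c < 0 for c in dm.values()):
                raise ValueError(f"negative dosage at site {i}")
            if sum(dm.values()) != self.ploidy:
                raise ValueError(
                    f"dosages at site {i} sum to {sum(dm.values())}, "
                    f"expected ploidy {self.ploidy}"
                )

    @property
    def m(self) -> int:
        return len(self.dosages)

    def dosage(self, site: int, allele: int) -> int:
        return self.dosages[site].get(allele, 0)


def _cluster_site_counts(
    partition: Partition, fragments: FragmentSet
) -> List[Dict[int, np.ndarray]]:
    """Per cluster: site -> allele tally (length-4 vector)."""
    out: List[Dict[int, np.ndarray]] = []
    for cl in partition.clusters:
        counts: Dict[int, np.ndarray] = {}
        for fid in cl:
            for j, a in fragments[fid].alleles.items():
                col = counts.get(j)
                if col is None:
                    col = counts[j] = np.zeros(4, dtype=np.int64)
                col[a] += 1
        out.append(counts)
    return out


def allele_confidence(
    i: int,
    j: int,
    a: int,
    partition: Partition,
    fragments: FragmentSet,
) -> float:
    """Confidence ratio c(i, j, a); uncovered sites score 0."""
    agree = disagree = 0
    for fid in partition.clusters[j]:
        allele = fragments[fid].alleles.get(i)
        if allele is None:
            continue
        if allele == a:
            agree += 1
        else:
            disagree += 1
    return agree / (disagree + 1)


def unconstrained_haplotypes(
    partition: Partition, fragments: FragmentSet, m: Optional[int] = None
) -> np.ndarray:
    """Per-cluster consensus haplotypes as a (k, m) matrix."""
    if m is None:
        m = fragments.m
    rows = [
        consensus((fragments[fid] for fid in cl), m=m)
        for cl in partition.clusters
    ]
    return np.stack(rows) if rows else np.zeros((0, m), dtype=np.int8)


def constrained_haplotypes(
    partition: Partition,
    genotypes: GenotypeTable,
    fragments: FragmentSet,
) -> np.ndarray:
    """Genotype-constrained haplotypes: column dosages match the VCF exactly."""
    k = partition.k
    if genotypes.ploidy != k:
        raise ValueError(
            f"partition has {k} clusters but genotypes have ploidy "
            f"{genotypes.ploidy}"
        )
    m = genotypes.m
    counts = _cluster_site_counts(partition, fragments)
    matrix = np.full((k, m), GAP, dtype=np.int8)
    for i in range(m):
        entries = []
        for j in range(k):
            col = counts[j].get(i)
            tot = int(col.sum()) if col is not None else 0
            for a in ALLELE_CODES:
                agree = int(col[a]) if col is not None else 0
                conf = agree / (tot - agree + 1)
                entries.append((-conf, j, a))
        entries.sort()
        placed: Dict[int, int] = {}
        for _negconf, j, a in entries:
            if matrix[j, i] != GAP:
                continue
            if placed.get(a, 0) >= genotypes.dosage(i, a):
                continue
            matrix[j, i] = a
            placed[a] = placed.get(a, 0) + 1
        # dosages sum to k, so the greedy pass always fills the column;
        # guard against a malformed table anyway
        for j in range(k):
            if matrix[j, i] == GAP:
                remaining = {
                    a: genotypes.dosage(i, a) - placed.get(a, 0)
                    for a in ALLELE_CODES
                }
                a_fill = max(remaining, key=lambda a: (remaining[a], -a))
                matrix[j, i] = a_fill
                placed[a_fill] = placed.get(a_fill, 0) + 1
    return matrix
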