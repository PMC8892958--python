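"""Variant-space simulator for polyploid phasing experiments.

Generates k haplotypes over m bi-allelic SNPs with controlled dosage
structure, then samples long-read fragments directly in variant space:
every read covers a contiguous window of variants copied from one
haplotype, with each covered allele independently miscalled at rate
``error_rate``.  Coverage is uniform across haplotypes and the per-read
haplotype of origin is returned so accuracy metrics can be computed
against truth.

The simulator works purely in variant space -- no nucleotides, no
aligner -- because the phasing pipeline consumes fragments; read length is
measured in variants (last covered index minus first), matching the
pipeline's own length convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Mapping, Optional, Tuple

import numpy as np

from .fragments import Fragment, FragmentSet
from .haplotypes import GenotypeTable


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic instance.

    dosage_probs maps alternate-allele dosage (1..k-1; every site is
    heterozygous) to its probability; the default is uniform, which for
    triploids automatically excludes the impossible three-alternate case.
    Read lengths are drawn from a normal distribution (in variants) and
    clipped to [2, m]; coverage is the expected per-haplotype depth.
    """

    ploidy: int = 4
    sites: int = 200
    coverage: float = 10.0
    read_length_mean: float = 40.0
    read_length_sd: float = 10.0
    error_rate: float = 0.0
    dosage_probs: Optional[Mapping[int, float]] = None
    identical_haplotypes: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ploidy < 2:
            raise ValueError("ploidy must be >= 2")
        if self.sites < 1:
            raise ValueError("sites must be >= 1")
        if self.coverage <= 0:
            raise ValueError("coverage must be > 0")
        if not (0.0 <= self.error_rate < 0.5):
            raise ValueError("error_rate must be in [0, 0.5)")
        if self.dosage_probs is not None:
            probs = dict(self.dosage_probs)
            if not probs or abs(sum(probs.values()) - 1.0) > 1e-9:
                raise ValueError("dosage_probs must sum to 1")
            if any(not (1 <= d <= self.ploidy - 1) for d in probs):
                raise ValueError("dosages must lie in 1..ploidy-1")

    def resolved_dosage_probs(self) -> Dict[int, float]:
        if self.dosage_probs is not None:
            return dict(self.dosage_probs)
        ds = list(range(1, self.ploidy))
        return {d: 1.0 / len(ds) for d in ds}


def simulate_haplotypes(
    config: SimulationConfig,
) -> Tuple[np.ndarray, GenotypeTable]:
    """Draw k haplotypes over m heterozygous bi-allelic sites.

    At every site an alternate dosage is drawn from ``dosage_probs`` and
    the alternate allele is assigned to a uniformly random haplotype
    subset of that size.  The returned genotype table is exactly the
    column dosage of the matrix.
    """
    rng = np.random.default_rng(config.seed)
    k, m = config.ploidy, config.sites
    probs = config.resolved_dosage_probs()
    dosage_values = sorted(probs)
    pvec = np.array([probs[d] for d in dosage_values])
    matrix = np.zeros((k, m), dtype=np.int8)
    for i in range(m):
        dose = int(rng.choice(dosage_values, p=pvec))
        carriers = rng.choice(k, size=dose, replace=False)
        matrix[carriers, i] = 1
    if config.identical_haplotypes and k >= 2:
        matrix[1, :] = matrix[0, :]
    dosages = []
    for i in range(m):
        col = matrix[:, i]
        dm = {0: int(np.sum(col == 0)), 1: int(np.sum(col == 1))}
        dosages.append({a: c for a, c in dm.items() if c > 0})
    return matrix, GenotypeTable(ploidy=k, dosages=dosages)


def simulate_fragments(
    haplotypes: np.ndarray,
    config: SimulationConfig,
) -> Tuple[FragmentSet, Dict[str, int]]:
    """Sample reads uniformly over haplotypes and start positions.

    Start positions are uniform over the alignment positions of an
    infinite lattice and reads crossing a contig edge are truncated, so
    expected depth is uniform across all m sites (no coverage ramp at the
    ends); the read count is chosen so per-haplotype depth is
    ``coverage``.  Each covered allele is miscalled with probability
    ``error_rate`` to a uniformly chosen different code in {0,1,2,3}.
    """
    rng = np.random.default_rng(config.seed + 1)
    k, m = haplotypes.shape
    mean_len = config.read_length_mean
    n_reads = k * max(1, round(config.coverage * (m + mean_len - 1) / mean_len))
    fragments = []
    labels: Dict[str, int] = {}
    for idx in range(n_reads):
        hap = int(rng.integers(k))
        length = int(
            np.clip(
                round(rng.normal(config.read_length_mean, config.read_length_sd)),
                2,
                m,
            )
        )
        # uniform over all lattice placements covering >= 1 site, then
        # truncated to the contig -> every site sees the same start count
        start = int(rng.integers(-(length - 1), m))
        lo, hi = max(0, start), min(m, start + length)
        if hi - lo < 2:  # keep at least two covered variants
            if lo == 0:
                hi = 2
            else:
                lo, hi = m - 2, m
        alleles = {}
        for j in range(lo, hi):
            a = int(haplotypes[hap, j])
            if config.error_rate > 0 and rng.random() < config.error_rate:
                others = [c for c in (0, 1, 2, 3) if c != a]
                a = int(others[rng.integers(3)])
            alleles[j] = a
        fid = f"r{idx:06d}"
        fragments.append(Fragment(id=fid, alleles=alleles))
        labels[fid] = hap
    return FragmentSet(fragments=fragments, m=m), labels


def true_partition(labels: Mapping[str, int], k: int):
    """Group fragment ids by their haplotype of origin."""
    from .fragments import Partition

    clusters = [set() for _ in range(k)]
    for fid, hap in labels.items():
        clusters[hap].add(fid)
    return Partition(clusters=clusters)


def write_truth_bundle(
    directory,
    haplotypes: np.ndarray,
    genotypes: GenotypeTable,
    fragments: FragmentSet,
    labels: Mapping[str, int],
) -> Dict[str, Path]:
    """Write fragments, truth haplotypes, genotype VCF and labels to disk."""
    from . import io as tpio

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "fragments": directory / "fragments.txt",
        "haplotypes": directory / "truth_haplotypes.tsv",
        "genotypes": directory / "genotypes.vcf",
        "labels": directory / "labels.tsv",
    }
    tpio.write_fragment_file(fragments, paths["fragments"])
    tpio.write_haplotypes(haplotypes, paths["haplotypes"])
    tpio.write_vcf_genotypes(genotypes, paths["genotypes"])
    with open(paths["labels"], "w") as fh:
        fh.write("fragment_id\thaplotype\n")
        for fid in sorted(labels):
            fh.write(f"{fid}\t{labels[fid]}\n")
    return paths
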