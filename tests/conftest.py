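"""Shared generators for random phasing instances."""

from __future__ import annotations

from typing import Dict, List, Tuple

import numpy as np
import pytest

from treephase import Fragment, FragmentSet, Partition


def random_fragment_set(
    rng: np.random.Generator,
    n_fragments: int,
    m: int,
    n_alleles: int = 2,
    min_len: int = 2,
    max_len: int | None = None,
) -> FragmentSet:
    """Fragments with contiguous random windows and random alleles."""
    max_len = max_len or m
    fragments = []
    for i in range(n_fragments):
        length = int(rng.integers(min_len, max_len + 1))
        length = min(length, m)
        start = int(rng.integers(0, m - length + 1))
        alleles = {
            j: int(rng.integers(n_alleles)) for j in range(start, start + length)
        }
        fragments.append(Fragment(id=f"f{i:03d}", alleles=alleles))
    return FragmentSet(fragments=fragments, m=m)


def fully_overlapping_set(
    rng: np.random.Generator,
    n_fragments: int,
    n_sites: int,
    n_alleles: int = 2,
) -> FragmentSet:
    """All reads cover exactly the sites [0, n_sites)."""
    fragments = [
        Fragment(
            id=f"f{i:03d}",
            alleles={j: int(rng.integers(n_alleles)) for j in range(n_sites)},
        )
        for i in range(n_fragments)
    ]
    return FragmentSet(fragments=fragments, m=n_sites)


def random_partition(
    rng: np.random.Generator, fragment_ids: List[str], k: int
) -> Partition:
    """Random k-partition with every cluster non-empty (needs >= k ids)."""
    ids = list(fragment_ids)
    rng.shuffle(ids)
    clusters = [set() for _ in range(k)]
    for i, fid in enumerate(ids[:k]):
        clusters[i].add(fid)
    for fid in ids[k:]:
        clusters[int(rng.integers(k))].add(fid)
    return Partition(clusters)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
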