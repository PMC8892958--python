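"""File formats: fragment files, VCF genotypes, BAM extraction, haplotypes.

The fragment-file dialect is the whitespace-separated line grammar shared
by the H-PoP / AltHap / HapCUT family of phasers::

    <B> <read id> <start_1> <alleles_1> ... <start_B> <alleles_B> <quals>

where B is the number of contiguous pieces, each start is the 1-based
index of the piece's first variant, each alleles string is digits in
0-3, and the trailing quality string carries one offset-33 character per
allele (Q = ord(c) - 33, error probability 10^(-Q/10)).  Indices are
converted to 0-based internally.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Dict, List, Optional, Union

import numpy as np
import pysam

from .fragments import GAP, Fragment, FragmentSet
from .haplotypes import GenotypeTable

PathLike = Union[str, Path]

_DEFAULT_QUAL_CHAR = "?"  # Q30


def _prob_to_char(p: float) -> str:
    q = int(round(-10.0 * math.log10(max(p, 1e-10))))
    return chr(33 + min(93, max(0, q)))


def _char_to_prob(c: str) -> float:
    q = ord(c) - 33
    if q < 0:
        raise ValueError(f"invalid quality character {c!r}")
    return 10.0 ** (-q / 10.0)


class FragmentFileError(ValueError):
    """Malformed fragment file, annotated with the offending line number."""


def read_fragment_file(path: PathLike, m: Optional[int] = None) -> FragmentSet:
    """Parse a fragment file; ``m`` defaults to the largest index seen + 1."""
    fragments: List[Fragment] = []
    max_index = -1
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            fields = line.split()
            try:
                n_pieces = int(fields[0])
            except (ValueError, IndexError):
                raise FragmentFileError(
                    f"{path}:{lineno}: first field must be the piece count"
                )
            expected = 2 + 2 * n_pieces + 1
            if len(fields) != expected:
                raise FragmentFileError(
                    f"{path}:{lineno}: expected {expected} fields for "
                    f"{n_pieces} pieces, got {len(fields)}"
                )
            read_id = fields[1]
            alleles: Dict[int, int] = {}
            prev_end = -1
            for p in range(n_pieces):
                start_s, allele_s = fields[2 + 2 * p], fields[3 + 2 * p]
                try:
                    start1 = int(start_s)
                except ValueError:
                    raise FragmentFileError(
                        f"{path}:{lineno}: piece {p + 1} start {start_s!r} "
                        f"is not an integer"
                    )
                if start1 < 1:
                    raise FragmentFileError(
                        f"{path}:{lineno}: piece {p + 1} start must be >= 1 "
                        f"(file indices are 1-based)"
                    )
                start0 = start1 - 1
                if start0 <= prev_end:
                    raise FragmentFileError(
                        f"{path}:{lineno}: pieces overlap or are unsorted"
                    )
                for off, ch in enumerate(allele_s):
                    if ch not in "0123":
                        raise FragmentFileError(
                            f"{path}:{lineno}: allele {ch!r} outside 0-3"
                        )
                    alleles[start0 + off] = int(ch)
                prev_end = start0 + len(allele_s) - 1
            quals = fields[-1]
            if len(quals) != len(alleles):
                raise FragmentFileError(
                    f"{path}:{lineno}: quality string length {len(quals)} "
                    f"does not match {len(alleles)} alleles"
                )
            qualities = {
                j: _char_to_prob(quals[i])
                for i, j in enumerate(sorted(alleles))
            }
            fragments.append(
                Fragment(id=read_id, alleles=alleles, qualities=qualities)
            )
            max_index = max(max_index, prev_end)
    if m is None:
        m = max_index + 1 if max_index >= 0 else 1
    return FragmentSet(fragments=fragments, m=m)


def write_fragment_file(fragments: FragmentSet, path: PathLike) -> None:
    with open(path, "w") as fh:
        for fr in fragments:
            sites = sorted(fr.alleles)
            pieces: List[List[int]] = [[sites[0]]]
            for j in sites[1:]:
                if j == pieces[-1][-1] + 1:
                    pieces[-1].append(j)
                else:
                    pieces.append([j])
            parts = [str(len(pieces)), fr.id]
            for piece in pieces:
                parts.append(str(piece[0] + 1))
                parts.append("".join(str(fr.alleles[j]) for j in piece))
            if fr.qualities is not None:
                quals = "".join(_prob_to_char(fr.qualities[j]) for j in sites)
            else:
                quals = _DEFAULT_QUAL_CHAR * len(sites)
            parts.append(quals)
            fh.write(" ".join(parts) + "\n")


def write_haplotypes(
    matrix: np.ndarray, path: PathLike
) -> None:
    """Tab-separated haplotype matrix: header, then index + k allele columns."""
    matrix = np.asarray(matrix)
    k, m = matrix.shape
    with open(path, "w") as fh:
        fh.write(f"#ploidy={k}\tm={m}\n")
        for i in range(m):
            cells = [
                "-" if matrix[j, i] == GAP else str(int(matrix[j, i]))
                for j in range(k)
            ]
            fh.write(str(i) + "\t" + "\t".join(cells) + "\n")


def read_haplotypes(path: PathLike) -> np.ndarray:
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("#ploidy="):
            raise ValueError(f"{path}: missing '#ploidy=' header")
        fields = header[1:].split("\t")
        k = int(fields[0].split("=")[1])
        m = int(fields[1].split("=")[1])
        matrix = np.full((k, m), GAP, dtype=np.int8)
        for lineno, raw in enumerate(fh, start=2):
            line = raw.strip()
            if not line:
                continue
            cells = line.split("\t")
            if len(cells) != k + 1:
                raise ValueError(
                    f"{path}:{lineno}: expected {k + 1} columns, got {len(cells)}"
                )
            i = int(cells[0])
            for j in range(k):
                matrix[j, i] = GAP if cells[j + 1] == "-" else int(cells[j + 1])
    return matrix


_VCF_BASES = ["A", "T", "G", "C"]


def write_vcf_genotypes(
    table: GenotypeTable, path: PathLike, contig: str = "chr1"
) -> None:
    """Minimal single-sample VCF carrying the dosages as an unphased GT."""
    m = table.m
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={contig},length={m + 1}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsample\n"
        )
        for i, dm in enumerate(table.dosages):
            n_alleles = max(dm) + 1 if dm else 1
            ref = _VCF_BASES[0]
            alts = ",".join(_VCF_BASES[1:n_alleles]) if n_alleles > 1 else "."
            gt_alleles: List[str] = []
            for a in sorted(dm):
                gt_alleles.extend([str(a)] * dm[a])
            fh.write(
                f"{contig}\t{i + 1}\t.\t{ref}\t{alts}\t.\tPASS\t.\tGT\t"
                + "/".join(gt_alleles)
                + "\n"
            )


def read_vcf_genotypes(path: PathLike, ploidy: int) -> GenotypeTable:
    """Per-variant allele dosages from the first sample's GT field.

    Only SNPs with at most four alleles are retained (the fragment
    alphabet); skipped records are counted and logged.  The order of
    retained records defines the variant index space.
    """
    import logging

    log = logging.getLogger(__name__)
    dosages: List[Dict[int, int]] = []
    skipped = 0
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        if not samples:
            raise ValueError(f"{path}: VCF has no sample columns")
        for rec in vcf:
            alleles = rec.alleles
            if (
                alleles is None
                or len(alleles) > 4
                or any(a is None or len(a) != 1 for a in alleles)
            ):
                skipped += 1
                continue
            gt = rec.samples[samples[0]].get("GT")
            if gt is None or any(g is None for g in gt):
                raise ValueError(
                    f"{path}: missing GT at {rec.chrom}:{rec.pos}"
                )
            if len(gt) != ploidy:
                raise ValueError(
                    f"{path}: GT at {rec.chrom}:{rec.pos} has {len(gt)} "
                    f"alleles, expected ploidy {ploidy}"
                )
            dm: Dict[int, int] = {}
            for g in gt:
                dm[int(g)] = dm.get(int(g), 0) + 1
            dosages.append(dm)
    if skipped:
        log.info("skipped %d non-SNP or high-allelic records", skipped)
    return GenotypeTable(ploidy=ploidy, dosages=dosages)


def extract_fragments_from_bam(
    bam_path: PathLike, vcf_path: PathLike, min_snps: int = 2
) -> FragmentSet:
    """Project primary alignments onto the VCF's SNP index space.

    For each retained SNP covered by an alignment, the read base is looked
    up via the aligned pairs; a base matching one of the site's alleles
    becomes that allele's code, anything else (including deletions) stays
    '-'.  Reads covering fewer than ``min_snps`` SNPs are dropped;
    secondary and supplementary alignments are excluded.
    """
    # variant index space: retained SNPs in file order, grouped by contig
    sites_by_contig: Dict[str, List[Dict[str, object]]] = {}
    index = 0
    with pysam.VariantFile(str(vcf_path)) as vcf:
        for rec in vcf:
            alleles = rec.alleles
            if (
                alleles is None
                or len(alleles) > 4
                or any(a is None or len(a) != 1 for a in alleles)
            ):
                continue
            sites_by_contig.setdefault(rec.chrom, []).append(
                {
                    "pos0": rec.pos - 1,
                    "index": index,
                    "codes": {a.upper(): c for c, a in enumerate(alleles)},
                }
            )
            index += 1
    m = max(index, 1)
    by_pos: Dict[str, Dict[int, Dict[str, object]]] = {
        contig: {int(s["pos0"]): s for s in sites}
        for contig, sites in sites_by_contig.items()
    }
    fragments: List[Fragment] = []
    seen_ids: Dict[str, int] = {}
    with pysam.AlignmentFile(str(bam_path)) as bam:
        for aln in bam:
            if (
                aln.is_unmapped
                or aln.is_secondary
                or aln.is_supplementary
                or aln.query_sequence is None
            ):
                continue
            contig_sites = by_pos.get(aln.reference_name)
            if not contig_sites:
                continue
            alleles: Dict[int, int] = {}
            for qpos, rpos in aln.get_aligned_pairs(matches_only=True):
                site = contig_sites.get(rpos)
                if site is None:
                    continue
                base = aln.query_sequence[qpos].upper()
                code = site["codes"].get(base)  # type: ignore[union-attr]
                if code is not None:
                    alleles[int(site["index"])] = int(code)
            if len(alleles) < min_snps:
                continue
            name = aln.query_name or "read"
            count = seen_ids.get(name, 0)
            seen_ids[name] = count + 1
            fid = name if count == 0 else f"{name}.{count}"
            fragments.append(Fragment(id=fid, alleles=alleles))
    return FragmentSet(fragments=fragments, m=m)


def write_report(report: Dict[str, object], path: PathLike) -> None:
    """Machine-readable tab-separated key-value report."""
    with open(path, "w") as fh:
        for key, value in report.items():
            if isinstance(value, (list, tuple)):
                value = ",".join(str(v) for v in value)
            fh.write(f"{key}\t{value}\n")
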