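"""Breadth-of-coverage statistics over BGC genes from read alignments.

Confirmation of a candidate BGC rests on two statistics computed from a SAM
alignment of metagenomic reads against BGC gene sequences:

* **gene presence** — the fraction of a gene's length covered (depth >= 1)
  by mapped reads; the gene counts as present at or above a threshold
  (default 5%);
* **BGC coverage** — the fraction of the cluster's genes counted present;
  the cluster is confirmed at or above a second threshold.

"Covered" means breadth, not depth: overlapping reads are unioned and depth
beyond 1 does not increase coverage.  Only primary, mapped, non-supplementary
alignments are counted, so a multi-mapped read contributes at its single best
placement.  Paired mates contribute independently (no proper-pair
requirement).  SAM input coordinates are 1-based; internal intervals are
0-based half-open.

A minimal exact-seed/ungapped-extension aligner is included for fixtures and
benchmarks; production runs delegate alignment to an external SAM-producing
aligner via the command-template contract in :mod:`bgcprofiler.predict`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pysam
from intervaltree import IntervalTree

FLAG_UNMAPPED = 0x4
FLAG_SECONDARY = 0x100
FLAG_SUPPLEMENTARY = 0x800
FLAG_REVERSE = 0x10


class SamParseError(ValueError):
    pass


class CigarError(ValueError):
    pass


@dataclass(frozen=True)
class AlignmentRecord:
    query_id: str
    ref_id: str  # "bgc_id|gene_id"
    pos: int  # 1-based leftmost reference coordinate
    cigar: str
    flags: int
    mapq: int

    def __post_init__(self):
        if self.pos < 1:
            raise SamParseError(f"{self.query_id}: position {self.pos} < 1")


@dataclass
class SamStats:
    """Counters for records skipped while streaming a SAM file."""

    n_counted: int = 0
    n_unmapped: int = 0
    n_secondary: int = 0
    n_supplementary: int = 0
    n_unknown_ref: int = 0
    n_overhang: int = 0


@dataclass
class GeneCoverage:
    bgc_id: str
    gene_id: str
    gene_length: int
    covered_bases: int

    def __post_init__(self):
        if not 0 <= self.covered_bases <= self.gene_length:
            raise ValueError(
                f"{self.bgc_id}|{self.gene_id}: covered {self.covered_bases} "
                f"outside [0, {self.gene_length}]"
            )

    @property
    def presence_fraction(self) -> float:
        return self.covered_bases / self.gene_length


@dataclass
class BGCCoverage:
    bgc_id: str
    n_genes: int
    n_genes_present: int
    gene_details: list[GeneCoverage] = field(default_factory=list)

    @property
    def coverage_fraction(self) -> float:
        return self.n_genes_present / self.n_genes


# ---------------------------------------------------------------------------
# SAM streaming

_COUNTED_MASK = FLAG_UNMAPPED | FLAG_SECONDARY | FLAG_SUPPLEMENTARY


def parse_sam(
    source: str | Path | Iterable[str],
    counted_refs: set[str] | None = None,
    stats: SamStats | None = None,
) -> Iterator[AlignmentRecord]:
    """Stream counted alignment records from a SAM file or iterable of lines.

    Counted records are mapped, primary and non-supplementary; everything
    else (and any record whose reference is outside ``counted_refs``, when
    given) is skipped with a counter in ``stats``.
    """
    if stats is None:
        stats = SamStats()
    if isinstance(source, (str, Path)):
        lines: Iterable[str] = _sam_file_lines(source)
    else:
        lines = source
    for lineno, line in enumerate(lines, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("@"):
            continue
        fields = line.split("\t")
        if len(fields) < 11:
            raise SamParseError(f"SAM line {lineno}: {len(fields)} fields < 11")
        qname, flag_s, rname, pos_s, mapq_s, cigar = fields[:6]
        try:
            flag, pos, mapq = int(flag_s), int(pos_s), int(mapq_s)
        except ValueError as e:
            raise SamParseError(f"SAM line {lineno}: {e}") from None
        if flag & FLAG_UNMAPPED:
            stats.n_unmapped += 1
            continue
        if flag & FLAG_SECONDARY:
            stats.n_secondary += 1
            continue
        if flag & FLAG_SUPPLEMENTARY:
            stats.n_supplementary += 1
            continue
        if counted_refs is not None and rname not in counted_refs:
            stats.n_unknown_ref += 1
            continue
        stats.n_counted += 1
        yield AlignmentRecord(
            query_id=qname, ref_id=rname, pos=pos, cigar=cigar, flags=flag, mapq=mapq
        )


def _sam_file_lines(path: str | Path) -> Iterator[str]:
    # pysam validates the header and handles SAM/BAM uniformly; records are
    # re-emitted as text lines for the common parser above.
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for rec in fh:
            yield rec.to_string()


# ---------------------------------------------------------------------------
# CIGAR -> covered reference intervals

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")
_REF_CONSUMING = set("MDN=X")
_COVERING = set("M=X")


def covered_intervals(cigar: str, pos: int) -> list[tuple[int, int]]:
    """Reference intervals (0-based, half-open) covered by aligned bases.

    M/=/X bases cover reference positions; D and N consume reference without
    covering it; I/S/H/P consume no reference.  ``pos`` is the 1-based SAM
    leftmost coordinate.
    """
    if pos < 1:
        raise CigarError(f"position {pos} < 1")
    if cigar == "*":
        return []
    if _CIGAR_RE.sub("", cigar):
        raise CigarError(f"invalid CIGAR: {cigar!r}")
    intervals: list[tuple[int, int]] = []
    ref = pos - 1
    for length_s, op in _CIGAR_RE.findall(cigar):
        length = int(length_s)
        if op in _COVERING:
            if intervals and intervals[-1][1] == ref:
                intervals[-1] = (intervals[-1][0], ref + length)
            else:
                intervals.append((ref, ref + length))
            ref += length
        elif op in _REF_CONSUMING:  # D, N
            ref += length
    return intervals


# ---------------------------------------------------------------------------
# Coverage computation


def compute_gene_coverage(
    alignments: Iterable[AlignmentRecord],
    gene_lengths: Mapping[str, int],
    stats: SamStats | None = None,
) -> list[GeneCoverage]:
    """Union-breadth coverage per gene from a stream of counted alignments.

    ``gene_lengths`` maps reference names ("bgc_id|gene_id") to gene length.
    Alignments overhanging the gene end are clipped and counted once.  Every
    gene in ``gene_lengths`` appears in the result, uncovered genes with
    zero covered bases.
    """
    trees: dict[str, IntervalTree] = {ref: IntervalTree() for ref in gene_lengths}
    for aln in alignments:
        tree = trees.get(aln.ref_id)
        if tree is None:
            continue
        glen = gene_lengths[aln.ref_id]
        for start, end in covered_intervals(aln.cigar, aln.pos):
            if start >= glen:
                if stats is not None:
                    stats.n_overhang += 1
                continue
            if end > glen:
                if stats is not None:
                    stats.n_overhang += 1
                end = glen
            if end > start:
                tree.addi(start, end)
    out = []
    for ref_id in gene_lengths:
        tree = trees[ref_id]
        tree.merge_overlaps()
        covered = sum(iv.end - iv.begin for iv in tree)
        bgc_id, _, gene_id = ref_id.partition("|")
        out.append(
            GeneCoverage(
                bgc_id=bgc_id,
                gene_id=gene_id,
                gene_length=gene_lengths[ref_id],
                covered_bases=covered,
            )
        )
    return out


def compute_bgc_coverage(
    gene_covs: Sequence[GeneCoverage], gene_presence_threshold: float
) -> BGCCoverage:
    """Fraction of a cluster's genes present at the given presence threshold.

    ``gene_presence_threshold`` is a percent in (0, 100]; comparison is
    inclusive (a gene exactly at the threshold counts as present).
    """
    if not gene_covs:
        raise ValueError("empty gene list")
    if not 0 < gene_presence_threshold <= 100:
        raise ValueError(f"gene presence threshold {gene_presence_threshold} not in (0,100]")
    bgc_ids = {g.bgc_id for g in gene_covs}
    if len(bgc_ids) != 1:
        raise ValueError(f"gene coverages span multiple BGCs: {sorted(bgc_ids)}")
    thr = gene_presence_threshold / 100.0
    n_present = sum(1 for g in gene_covs if g.presence_fraction >= thr)
    return BGCCoverage(
        bgc_id=next(iter(bgc_ids)),
        n_genes=len(gene_covs),
        n_genes_present=n_present,
        gene_details=list(gene_covs),
    )


# ---------------------------------------------------------------------------
# Naive fixture aligner: exact 31-mer seed + ungapped full-length extension.

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def naive_map_reads(
    reads: Iterable[tuple[str, str]] | Sequence[str | Path],
    genes: Mapping[str, str] | str | Path,
    k: int = 31,
    min_identity: float = 0.76,
) -> str:
    """Map reads to gene sequences and return SAM text (one primary per read).

    Seeds are exact k-mers (both orientations); extension is ungapped over
    the full read, which must fit within the gene.  The single best-identity
    placement is reported (ties broken by lowest (ref_id, pos), forward
    orientation first); reads below ``min_identity`` are emitted unmapped.
    ``reads`` is either (read_id, sequence) pairs or FASTQ paths; ``genes``
    a {ref_id: sequence} mapping or a FASTA path.
    """
    from Bio import SeqIO

    if isinstance(genes, (str, Path)):
        genes = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(genes), "fasta")}
    ref_ids = sorted(genes)
    index: dict[str, list[tuple[int, int]]] = {}
    for ref_idx, rid in enumerate(ref_ids):
        seq = genes[rid]
        for i in range(len(seq) - k + 1):
            index.setdefault(seq[i : i + k], []).append((ref_idx, i))

    read_list = list(reads)

    def read_iter():
        if read_list and isinstance(read_list[0], (str, Path)):
            for p in read_list:  # FASTQ paths
                for rec in SeqIO.parse(str(p), "fastq"):
                    yield rec.id, str(rec.seq).upper()
        else:
            for rid, seq in read_list:
                yield rid, seq.upper()

    out = ["@HD\tVN:1.6\tSO:unsorted"]
    for rid in ref_ids:
        out.append(f"@SQ\tSN:{rid}\tLN:{len(genes[rid])}")

    for qname, seq in read_iter():
        L = len(seq)
        best = None  # (mismatches, orient_rank, ref_idx, start, oriented_seq)
        for orient_rank, oriented in enumerate((seq, revcomp(seq))):
            if L < k:
                break
            offsets = {0, (L - k) // 2, L - k}
            candidates: set[tuple[int, int]] = set()
            for off in offsets:
                for ref_idx, ref_pos in index.get(oriented[off : off + k], ()):
                    start = ref_pos - off
                    if start >= 0 and start + L <= len(genes[ref_ids[ref_idx]]):
                        candidates.add((ref_idx, start))
            for ref_idx, start in sorted(candidates):
                window = genes[ref_ids[ref_idx]][start : start + L]
                if window == oriented:
                    mism = 0
                else:
                    mism = sum(1 for a, b in zip(window, oriented) if a != b)
                key = (mism, orient_rank, ref_idx, start)
                if best is None or key < best[:4]:
                    best = (*key, oriented)
        if best is not None and (L - best[0]) / L >= min_identity:
            mism, orient_rank, ref_idx, start, oriented = best
            flag = FLAG_REVERSE if orient_rank == 1 else 0
            out.append(
                "\t".join(
                    [
                        qname,
                        str(flag),
                        ref_ids[ref_idx],
                        str(start + 1),
                        "60",
                        f"{L}M",
                        "*",
                        "0",
                        "0",
                        oriented,
                        "I" * L,
                    ]
                )
            )
        else:
            out.append(
                "\t".join([qname, str(FLAG_UNMAPPED), "*", "0", "0", "*", "*", "0", "0", seq, "I" * L])
            )
    return "\n".join(out) + "\n"
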