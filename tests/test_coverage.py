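"""Breadth-of-coverage statistics: CIGAR intervals, union coverage, SAM
filtering, and the naive fixture aligner."""

import re

import numpy as np
import pytest

from bgcprofiler.coverage import (
    AlignmentRecord,
    CigarError,
    SamParseError,
    SamStats,
    compute_bgc_coverage,
    compute_gene_coverage,
    covered_intervals,
    naive_map_reads,
    parse_sam,
    revcomp,
)


def per_base_oracle(alignments, gene_length):
    """Independent oracle: walk each CIGAR base by base over a boolean array."""
    covered = np.zeros(gene_length, dtype=bool)
    for cigar, pos in alignments:
        ref = pos - 1
        for n, op in re.findall(r"(\d+)([MIDNSHP=X])", cigar):
            n = int(n)
            if op in "M=X":
                for _ in range(n):
                    if 0 <= ref < gene_length:
                        covered[ref] = True
                    ref += 1
            elif op in "DN":
                ref += n
    return int(covered.sum())


class TestCoveredIntervals:
    @pytest.mark.parametrize(
        "cigar,pos,expected",
        [
            ("50M", 11, [(10, 60)]),
            ("20M5D20M", 1, [(0, 20), (25, 45)]),
            ("10S40M", 1, [(0, 40)]),
            ("5M3I5M", 1, [(0, 10)]),  # insertion consumes query only
            ("10M100N10M", 1, [(0, 10), (110, 120)]),
            ("3H20M2H", 5, [(4, 24)]),
        ],
    )
    def test_reference_consumption(self, cigar, pos, expected):
        assert covered_intervals(cigar, pos) == expected

    def test_invalid_cigar_token(self):
        with pytest.raises(CigarError):
            covered_intervals("10Q", 1)

    def test_unmapped_star_cigar_covers_nothing(self):
        assert covered_intervals("*", 1) == []


class TestParseSam:
    def _line(self, flag, rname="b1|g1", pos=1, cigar="10M"):
        return f"q1\t{flag}\t{rname}\t{pos}\t60\t{cigar}\t*\t0\t0\tACGTACGTAC\tIIIIIIIIII"

    @pytest.mark.parametrize(
        "flag,counter",
        [(0x4, "n_unmapped"), (0x100, "n_secondary"), (0x800, "n_supplementary")],
    )
    def test_uncounted_records_filtered(self, flag, counter):
        stats = SamStats()
        recs = list(parse_sam([self._line(flag)], stats=stats))
        assert recs == []
        assert getattr(stats, counter) == 1

    def test_primary_mapped_record_yielded(self):
        (rec,) = parse_sam([self._line(0)])
        assert rec == AlignmentRecord("q1", "b1|g1", 1, "10M", 0, 60)

    def test_unknown_reference_skipped_with_counter(self):
        stats = SamStats()
        recs = list(parse_sam([self._line(0, rname="zz|zz")], counted_refs={"b1|g1"}, stats=stats))
        assert recs == []
        assert stats.n_unknown_ref == 1

    def test_malformed_line_reports_line_number(self):
        with pytest.raises(SamParseError, match="line 2"):
            list(parse_sam([self._line(0), "q2\t0\tb1|g1\t1"]))

    def test_reads_sam_file_via_pysam(self, tmp_path):
        sam = "@HD\tVN:1.6\n@SQ\tSN:b1|g1\tLN:100\n" + self._line(0) + "\n"
        path = tmp_path / "t.sam"
        path.write_text(sam)
        (rec,) = parse_sam(path)
        assert rec.ref_id == "b1|g1"


class TestGeneCoverage:
    def test_single_read_fraction(self):
        covs = compute_gene_coverage(
            [AlignmentRecord("q", "b|g", 1, "50M", 0, 60)], {"b|g": 1000}
        )
        assert covs[0].presence_fraction == pytest.approx(0.05)

    def test_overlap_counts_once(self):
        alns = [
            AlignmentRecord("q1", "b|g", 1, "50M", 0, 60),
            AlignmentRecord("q2", "b|g", 26, "50M", 0, 60),
        ]
        (cov,) = compute_gene_coverage(alns, {"b|g": 1000})
        assert cov.covered_bases == 75

    def test_zero_alignments(self):
        (cov,) = compute_gene_coverage([], {"b|g": 500})
        assert cov.presence_fraction == 0.0

    def test_overhang_clipped_with_counter(self):
        stats = SamStats()
        (cov,) = compute_gene_coverage(
            [AlignmentRecord("q", "b|g", 91, "50M", 0, 60)], {"b|g": 100}, stats=stats
        )
        assert cov.covered_bases == 10
        assert stats.n_overhang == 1

    @pytest.mark.parametrize("case", range(200))
    def test_union_equals_per_base_oracle(self, case):
        rng = np.random.default_rng(case)
        gene_length = int(rng.integers(50, 2001))
        n_reads = int(rng.integers(0, 21))
        alns, pairs = [], []
        for i in range(n_reads):
            pos = int(rng.integers(1, gene_length + 1))
            parts = []
            for _ in range(int(rng.integers(1, 4))):
                op = rng.choice(["M", "D", "I", "S"], p=[0.7, 0.1, 0.1, 0.1])
                parts.append(f"{int(rng.integers(1, 60))}{op}")
            cigar = "".join(parts)
            if not any(op in "M" for op in cigar):
                cigar += "10M"
            alns.append(AlignmentRecord(f"q{i}", "b|g", pos, cigar, 0, 60))
            pairs.append((cigar, pos))
        (cov,) = compute_gene_coverage(alns, {"b|g": gene_length})
        assert cov.covered_bases == per_base_oracle(pairs, gene_length)

    def test_adding_alignment_never_decreases_presence(self):
        rng = np.random.default_rng(42)
        alns = [
            AlignmentRecord(f"q{i}", "b|g", int(rng.integers(1, 900)), "100M", 0, 60)
            for i in range(10)
        ]
        prev = 0.0
        for n in range(len(alns) + 1):
            (cov,) = compute_gene_coverage(alns[:n], {"b|g": 1000})
            assert cov.presence_fraction >= prev
            prev = cov.presence_fraction


class TestBGCCoverage:
    def _covs(self, fractions, length=100):
        from bgcprofiler.coverage import GeneCoverage

        return [
            GeneCoverage("b", f"g{i}", length, int(round(f * length)))
            for i, f in enumerate(fractions)
        ]

    def test_boundary_is_inclusive(self):
        covs = self._covs([0.05] + [0.0] * 9)
        bc = compute_bgc_coverage(covs, gene_presence_threshold=5)
        assert bc.n_genes_present == 1
        assert bc.coverage_fraction == pytest.approx(0.10)

    def test_hand_counted_mixture(self):
        bc = compute_bgc_coverage(self._covs([0.04, 0.05, 0.50, 1.0]), 5)
        assert bc.n_genes_present == 3
        assert bc.coverage_fraction == pytest.approx(0.75)

    def test_full_coverage_at_strictest_threshold(self):
        bc = compute_bgc_coverage(self._covs([1.0, 1.0, 1.0]), 100)
        assert bc.coverage_fraction == 1.0

    def test_raising_threshold_never_adds_present_genes(self):
        covs = self._covs([0.02, 0.05, 0.25, 0.6, 1.0])
        prev = len(covs) + 1
        for thr in (1, 5, 25, 60, 100):
            n = compute_bgc_coverage(covs, thr).n_genes_present
            assert n <= prev
            prev = n

    def test_empty_gene_list_is_error(self):
        with pytest.raises(ValueError, match="empty"):
            compute_bgc_coverage([], 5)

    def test_mixed_bgcs_rejected(self):
        from bgcprofiler.coverage import GeneCoverage

        covs = [GeneCoverage("a", "g", 10, 5), GeneCoverage("b", "g", 10, 5)]
        with pytest.raises(ValueError, match="multiple"):
            compute_bgc_coverage(covs, 5)


@pytest.fixture(scope="module")
def gene():
    rng = np.random.default_rng(5)
    return "".join(rng.choice(list("ACGT"), 500))


class TestNaiveMapReads:

    def test_verbatim_read_maps_at_source(self, gene):
        read = gene[100:200]
        sam = naive_map_reads([("r1", read)], {"bgcX|g1": gene})
        body = [l for l in sam.splitlines() if not l.startswith("@")]
        fields = body[0].split("\t")
        assert (fields[2], int(fields[3]), fields[5]) == ("bgcX|g1", 101, "100M")

    def test_foreign_read_unmapped(self, gene):
        rng = np.random.default_rng(99)
        read = "".join(rng.choice(list("ACGT"), 100))
        sam = naive_map_reads([("r1", read)], {"bgcX|g1": gene})
        body = [l for l in sam.splitlines() if not l.startswith("@")]
        assert int(body[0].split("\t")[1]) & 0x4

    def test_two_substitutions_still_map(self, gene):
        read = list(gene[100:200])
        read[10] = "A" if read[10] != "A" else "C"
        read[90] = "A" if read[90] != "A" else "C"
        read = "".join(read)
        sam = naive_map_reads([("r1", read)], {"bgcX|g1": gene})
        fields = [l for l in sam.splitlines() if not l.startswith("@")][0].split("\t")
        assert int(fields[1]) & 0x4 == 0
        assert int(fields[3]) == 101
        # brute-force sliding-window Hamming oracle agrees on the best locus
        best = min(
            range(len(gene) - 100 + 1),
            key=lambda s: sum(a != b for a, b in zip(gene[s : s + 100], read)),
        )
        assert int(fields[3]) == best + 1

    def test_reverse_complement_read_maps_with_flag(self, gene):
        read = revcomp(gene[100:200])
        sam = naive_map_reads([("r1", read)], {"bgcX|g1": gene})
        fields = [l for l in sam.splitlines() if not l.startswith("@")][0].split("\t")
        assert int(fields[1]) & 0x10
        assert int(fields[3]) == 101

    def test_low_identity_rejected(self, gene):
        # keep a single seed k-mer intact, scramble the rest of the read
        rng = np.random.default_rng(3)
        tail = "".join(rng.choice(list("ACGT"), 69))
        read = gene[100:131] + tail  # 31 matching + 69 random: identity ~ 0.4
        sam = naive_map_reads([("r1", read)], {"bgcX|g1": gene}, min_identity=0.76)
        assert int(sam.splitlines()[-1].split("\t")[1]) & 0x4
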