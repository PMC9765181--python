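"""Simulation and evaluation machinery: fixture worlds, communities, reads,
metrics, the threshold grid, and the method-comparison statistics."""

import math

import numpy as np
import pytest

from bgcprofiler.benchmark import (
    DEFAULT_GRID_VALUES,
    EvalMetrics,
    PreparedSample,
    allocate_pairs,
    build_mock_community,
    compare_methods,
    correlate,
    evaluate,
    generate_fixture_world,
    geometric_mean_abundance,
    grid_search,
    simulate_reads,
)
from bgcprofiler.coverage import revcomp


class TestFixtureWorld:
    def test_seeded_determinism(self):
        w1 = generate_fixture_world(n_species=6, n_bgc_harboring=2, seed=7)
        w2 = generate_fixture_world(n_species=6, n_bgc_harboring=2, seed=7)
        assert w1.genomes == w2.genomes
        assert [r.bgc_id for r in w1.records] == [r.bgc_id for r in w2.records]
        assert w1.markers == w2.markers

    def test_embedded_genes_are_exact_substrings(self, small_world):
        for rec in small_world.records:
            if rec.bgc_id in small_world.decoy_bgcs:
                continue
            (sp,) = rec.source_species
            genome = small_world.genomes[sp]
            for gene in rec.genes:
                assert gene.sequence in genome

    def test_recorded_loci_match_gene_sequences(self, small_world):
        for bgc_id, spans in small_world.bgc_loci.items():
            rec = next(r for r in small_world.records if r.bgc_id == bgc_id)
            for gene, (sp, start, end) in zip(rec.genes, spans):
                assert small_world.genomes[sp][start:end] == gene.sequence

    def test_markers_unique_across_genomes(self, small_world):
        # brute-force cross-scan: no marker (either orientation) occurs in
        # any genome other than its own species'
        for kmer, sp in small_world.markers.items():
            for other_sp, genome in small_world.genomes.items():
                if other_sp == sp:
                    continue
                assert kmer not in genome and revcomp(kmer) not in genome

    def test_decoy_genes_come_from_non_harboring_genomes(self, small_world):
        for bgc_id in small_world.decoy_bgcs:
            for sp, start, end in small_world.bgc_loci[bgc_id]:
                assert sp in small_world.non_harboring_species

    def test_too_small_genome_is_parameter_error(self):
        with pytest.raises(ValueError, match="too short"):
            generate_fixture_world(n_species=4, n_bgc_harboring=2, genome_length=3000, seed=0)


class TestMockCommunity:
    def test_template_abundances_assigned_as_permutation(self, small_world):
        c = build_mock_community(small_world, 3, abundance_template=[50, 30, 20], seed=5)
        assert sorted(m.relative_abundance for m in c.members) == [20, 30, 50]

    def test_abundances_sum_to_hundred(self, small_world):
        c = build_mock_community(small_world, 6, seed=9)
        assert sum(m.relative_abundance for m in c.members) == pytest.approx(100.0)

    def test_richness_exceeding_pool_rejected(self, small_world):
        with pytest.raises(ValueError, match="richness"):
            build_mock_community(small_world, 99, seed=0)

    def test_seeded_determinism(self, small_world):
        c1 = build_mock_community(small_world, 5, seed=11)
        c2 = build_mock_community(small_world, 5, seed=11)
        assert [(m.species, m.relative_abundance) for m in c1.members] == [
            (m.species, m.relative_abundance) for m in c2.members
        ]

    def test_truth_is_union_of_member_bgcs(self, small_world):
        c = build_mock_community(small_world, 6, seed=2, n_bgc_harboring=2)
        expected = set()
        for m in c.members:
            expected |= small_world.bgc_by_species.get(m.species, set())
        assert c.truth_bgcs == expected


class TestAllocatePairs:
    def test_even_split(self):
        assert allocate_pairs([50.0, 50.0], 1000) == [500, 500]

    @pytest.mark.parametrize("seed", range(20))
    def test_largest_remainder_oracle(self, seed):
        rng = np.random.default_rng(seed)
        weights = rng.random(int(rng.integers(2, 8))) + 0.01
        total = int(rng.integers(1, 5000))
        alloc = allocate_pairs(weights, total)
        assert sum(alloc) == total
        exact = total * weights / weights.sum()
        # every member within one pair of its exact share (largest-remainder property)
        assert all(math.floor(e) <= a <= math.ceil(e) for a, e in zip(alloc, exact))


class TestSimulateReads:
    def test_error_free_reads_are_genome_substrings(self, small_world):
        c = build_mock_community(small_world, 4, seed=1, n_bgc_harboring=1)
        mg = simulate_reads(c, 200, error_rate=0.0, seed=8)
        genomes = {m.species: m.genome for m in c.members}
        for name, r1, r2 in mg.pairs:
            sp = name.split("|")[0]
            assert r1 in genomes[sp]
            assert revcomp(r2) in genomes[sp]

    def test_library_size_exact(self, small_world):
        c = build_mock_community(small_world, 5, seed=2)
        mg = simulate_reads(c, 1234, seed=3)
        assert len(mg.pairs) == 1234

    def test_read_names_encode_provenance(self, small_world):
        c = build_mock_community(small_world, 3, seed=4)
        mg = simulate_reads(c, 50, error_rate=0.0, seed=5)
        genomes = {m.species: m.genome for m in c.members}
        for name, r1, _ in mg.pairs:
            sp, pos, serial = name.split("|")
            assert sp in genomes
            assert r1 == genomes[sp][int(pos) : int(pos) + len(r1)]
            int(serial)  # numeric serial

    def test_fastq_round_trip(self, small_world, tmp_path):
        from Bio import SeqIO

        c = build_mock_community(small_world, 3, seed=6)
        mg = simulate_reads(c, 20, seed=7)
        p1, p2 = mg.write_fastq(tmp_path)
        r1s = [str(r.seq) for r in SeqIO.parse(str(p1), "fastq")]
        assert r1s == [r1 for _, r1, _ in mg.pairs]

    def test_substitution_errors_at_requested_rate(self, small_world):
        c = build_mock_community(small_world, 3, seed=1)
        mg = simulate_reads(c, 3000, error_rate=0.01, seed=2)
        genomes = {m.species: m.genome for m in c.members}
        mismatches = bases = 0
        for name, r1, _ in mg.pairs:
            sp, pos, _ = name.split("|")
            ref = genomes[sp][int(pos) : int(pos) + len(r1)]
            mismatches += sum(a != b for a, b in zip(ref, r1))
            bases += len(r1)
        rate = mismatches / bases
        assert 0.005 < rate < 0.02  # loose band around the nominal 1%


class TestEvaluate:
    def test_perfect_prediction(self):
        m = evaluate({"a", "b"}, {"a", "b"})
        assert (m.precision, m.recall, m.f1) == (1.0, 1.0, 1.0)

    def test_hand_checked_counts(self):
        m = evaluate({"a", "b", "x"}, {"a", "b", "y"})
        assert (m.tp, m.fp, m.fn) == (2, 1, 1)
        assert m.precision == pytest.approx(2 / 3)
        assert m.recall == pytest.approx(2 / 3)
        assert m.f1 == pytest.approx(4 / 6)

    def test_empty_prediction_against_nonempty_truth(self):
        m = evaluate(set(), {"a"})
        assert m.recall == 0.0
        assert m.f1 == 0.0
        assert math.isnan(m.precision)

    def test_fully_degenerate_counts_are_na(self):
        m = evaluate(set(), set())
        assert math.isnan(m.f1) and math.isnan(m.precision)

    def test_ppv_equals_precision(self):
        m = evaluate({"a", "x"}, {"a"})
        assert m.ppv == m.precision

    @pytest.mark.parametrize("seed", range(5))
    def test_f1_algebraic_identity(self, seed):
        rng = np.random.default_rng(seed)
        tp, fp, fn = (int(x) for x in rng.integers(0, 50, 3))
        m = EvalMetrics(tp, fp, fn)
        if tp > 0:
            assert m.f1 == pytest.approx(2 * tp / (2 * tp + fp + fn))


class TestGridSearch:
    def test_default_grid_has_400_cells(self):
        sample = PreparedSample("s", {"a": [1.0]}, {"a"})
        result = grid_search([sample])
        assert len(result.grid) == 400
        assert set(result.grid) == {
            (gp, cov) for gp in DEFAULT_GRID_VALUES for cov in DEFAULT_GRID_VALUES
        }

    def test_lenient_corner_wins_for_partially_covered_truth(self):
        # one truth BGC with genes at 6% and 3% presence: recoverable only
        # at gene presence 5% and coverage <= 50%
        sample = PreparedSample("s", {"a": [0.06, 0.03]}, {"a"})
        result = grid_search([sample])
        # exhaustive independent oracle over the whole grid
        best_oracle = None
        for gp in DEFAULT_GRID_VALUES:
            for cov in DEFAULT_GRID_VALUES:
                present = sum(f >= gp / 100 for f in [0.06, 0.03])
                predicted = {"a"} if present / 2 >= cov / 100 else set()
                f1 = evaluate(predicted, {"a"}).f1
                if best_oracle is None or f1 > best_oracle[0]:
                    best_oracle = (f1, (gp, cov))
        assert result.best_pair == (5, 5)
        assert result.grid[result.best_pair] == best_oracle[0] == 1.0

    def test_best_cell_attains_maximum(self):
        samples = [
            PreparedSample("s1", {"a": [0.5, 0.04], "b": [0.2]}, {"a"}),
            PreparedSample("s2", {"b": [0.9, 0.9]}, {"b"}),
        ]
        result = grid_search(samples)
        best = result.grid[result.best_pair]
        assert all(best >= v for v in result.grid.values() if not math.isnan(v))

    def test_tie_break_prefers_smallest_thresholds(self):
        sample = PreparedSample("s", {"a": [1.0]}, {"a"})  # F1=1 everywhere
        result = grid_search([sample])
        assert result.best_pair == (5, 5)

    def test_confirmed_set_monotone_in_both_thresholds(self):
        rng = np.random.default_rng(0)
        fractions = {
            f"b{i}": [float(f) for f in rng.random(int(rng.integers(1, 8)))]
            for i in range(6)
        }
        sample = PreparedSample("s", fractions, set())
        for cov in DEFAULT_GRID_VALUES:
            sizes = [len(sample.confirmed_at(gp, cov)) for gp in DEFAULT_GRID_VALUES]
            assert sizes == sorted(sizes, reverse=True)
        for gp in DEFAULT_GRID_VALUES:
            sizes = [len(sample.confirmed_at(gp, cov)) for cov in DEFAULT_GRID_VALUES]
            assert sizes == sorted(sizes, reverse=True)

    def test_per_sample_best_reported(self):
        samples = [PreparedSample("s1", {"a": [0.06]}, {"a"})]
        result = grid_search(samples)
        (sid, pair, f1) = result.per_sample_best[0]
        assert sid == "s1" and f1 == 1.0 and pair == (5, 5)


class TestComparisonStatistics:
    def test_identical_distributions_not_significant(self):
        a = [0.5, 0.6, 0.7, 0.8, 0.5, 0.6, 0.7, 0.8]
        assert compare_methods(a, list(a)) > 0.8

    def test_fully_separated_groups_highly_significant(self):
        a = [float(i) for i in range(1, 11)]
        b = [x + 100 for x in a]
        assert compare_methods(a, b) < 0.001

    def test_too_few_scores_rejected(self):
        with pytest.raises(ValueError):
            compare_methods([1.0], [2.0, 3.0])

    def test_perfectly_monotone_pairs(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        y = [2.0, 4.0, 8.0, 16.0, 32.0]
        rho, _ = correlate(x, y)
        assert rho == pytest.approx(1.0)

    def test_geometric_mean_over_detected_harboring_species(self, small_world, small_db):
        from bgcprofiler.profiles import TaxonomicProfile

        harb = sorted(small_world.harboring_species)[:2]
        prof = TaxonomicProfile("s", [(harb[0], 4.0), (harb[1], 16.0), ("zz_zz", 1.0)])
        gm = geometric_mean_abundance(prof, small_db)
        assert gm == pytest.approx(8.0)  # sqrt(4 * 16); the non-db species is excluded
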