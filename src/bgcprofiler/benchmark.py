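"""Simulated-metagenome benchmarking and threshold optimization.

Everything needed to evaluate the predictor without external downloads lives
here: a synthetic *fixture world* (random genomes with BGCs embedded at known
loci, a species catalog, and species-unique k-mer markers for the test
profiler), mock-community assembly, a paired-end read simulator, the
TP/FP/FN -> precision/recall/F1/PPV evaluation, the 400-cell threshold grid
search, and the rank tests comparing taxonomy-guided against direct
detection.

The simulator draws read pairs from member genomes in proportion to
relative abundance x genome length (DNA-proportional shotgun sampling),
with normally distributed insert sizes and independent per-base substitution
errors; no indels are introduced, which is adequate for breadth-of-coverage
evaluation.  Ground truth for a sample is the union of BGCs embedded in its
member genomes.

Decoy records model the false-positive mode of direct detection: their
"genes" are verbatim slices of non-BGC-harboring community genomes,
attributed to a catalog species never placed in any community.  Reads from
those genomes fully cover the decoy genes, so direct mode confirms them,
while the taxonomy gate never proposes them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .coverage import naive_map_reads, revcomp
from .predict import (
    MODE_DIRECT,
    MODE_TAXONOMY,
    PredictionConfig,
    candidate_gene_lengths,
    confirm,
    confirmed_set,
    first_pass_candidates,
)
from .profiles import MARKER_K, KmerMarkerProfiler, TaxonomicProfile, match_species
from .refdb import (
    BGCRecord,
    GeneSequence,
    ReferenceDatabase,
    SpeciesCatalog,
    build_reference_database,
    normalize_species_name,
)

_BASES = np.frombuffer(b"ACGT", dtype="S1")

DEFAULT_GRID_VALUES = tuple(range(5, 101, 5))  # 5..100 % in steps of 5 -> 20x20 grid


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


# ---------------------------------------------------------------------------
# Fixture world


@dataclass
class FixtureWorld:
    """Synthetic genomes, BGC records, catalog and profiler markers."""

    genomes: dict[str, str]  # normalized species -> genome sequence
    records: list[BGCRecord]  # real + decoy records
    catalog: SpeciesCatalog
    markers: dict[str, str]  # k-mer (both orientations) -> species
    bgc_by_species: dict[str, set[str]]  # harboring species -> embedded bgc_ids
    decoy_bgcs: set[str]
    bgc_loci: dict[str, list[tuple[str, int, int]]]  # bgc -> (species, start, end) per gene
    seed: int

    @property
    def harboring_species(self) -> set[str]:
        return set(self.bgc_by_species)

    @property
    def non_harboring_species(self) -> set[str]:
        return set(self.genomes) - self.harboring_species

    def build_database(self) -> ReferenceDatabase:
        return build_reference_database(
            self.records, self.catalog, catalog_version=f"fixture-world-seed{self.seed}"
        )

    def profiler(self) -> KmerMarkerProfiler:
        return KmerMarkerProfiler(self.markers)


def generate_fixture_world(
    n_species: int = 20,
    n_bgc_harboring: int = 5,
    genome_length: int = 30_000,
    seed: int = 0,
    n_decoys: int = 0,
    markers_per_species: int = 20,
    genes_per_bgc: tuple[int, int] = (3, 15),
    gene_length: tuple[int, int] = (300, 2000),
) -> FixtureWorld:
    """Generate a deterministic synthetic world of genomes with embedded BGCs.

    Each of the first ``n_bgc_harboring`` species carries one synthetic BGC
    (``genes_per_bgc`` genes of ``gene_length`` bp, separated by short
    spacers) embedded verbatim at a recorded locus.  ``n_decoys`` additional
    records take their genes from non-harboring genomes but are attributed
    to species outside the world.  Species-unique 31-mer markers (checked
    against all genomes in both orientations) are recorded for the test
    profiler.
    """
    if n_bgc_harboring > n_species:
        raise ValueError("n_bgc_harboring exceeds n_species")
    if n_decoys and n_bgc_harboring >= n_species:
        raise ValueError("decoys need at least one non-BGC-harboring species")
    rng = np.random.default_rng(seed)
    species = [
        normalize_species_name(f"Fixturia species{i:03d}") for i in range(n_species)
    ]

    genomes: dict[str, str] = {sp: _random_dna(rng, genome_length) for sp in species}
    records: list[BGCRecord] = []
    bgc_by_species: dict[str, set[str]] = {}
    bgc_loci: dict[str, list[tuple[str, int, int]]] = {}

    class_pool = ("polyketide", "NRP", "RiPP", "saccharide", "terpene", "alkaloid", "other")
    for i, sp in enumerate(species[:n_bgc_harboring]):
        n_genes = int(rng.integers(genes_per_bgc[0], genes_per_bgc[1] + 1))
        genes = []
        cluster_parts = []
        gene_spans = []  # offsets within the cluster
        offset = 0
        for g in range(n_genes):
            glen = int(rng.integers(gene_length[0], gene_length[1] + 1))
            seq = _random_dna(rng, glen)
            genes.append(GeneSequence(gene_id=f"gene{g + 1:02d}", sequence=seq))
            cluster_parts.append(seq)
            gene_spans.append((offset, offset + glen))
            offset += glen
            spacer = _random_dna(rng, 50)
            cluster_parts.append(spacer)
            offset += len(spacer)
        cluster = "".join(cluster_parts)
        if len(cluster) + 2 * MARKER_K >= genome_length:
            raise ValueError(
                f"genome_length {genome_length} too short to embed a "
                f"{len(cluster)} bp cluster"
            )
        locus = int(rng.integers(0, genome_length - len(cluster)))
        genome = genomes[sp]
        genomes[sp] = genome[:locus] + cluster + genome[locus + len(cluster):]
        bgc_id = f"BGC_F{i + 1:03d}"
        n_classes = 1 + int(rng.random() < 0.25)
        classes = frozenset(rng.choice(class_pool, size=n_classes, replace=False).tolist())
        n_sms = 1 + int(rng.random() < 0.15)
        sms = tuple(f"fixturemycin_{i + 1}{chr(ord('a') + j)}" for j in range(n_sms))
        records.append(
            BGCRecord(
                bgc_id=bgc_id,
                classes=classes,
                sm_products=sms,
                source_species=frozenset({sp}),
                genes=tuple(genes),
            )
        )
        bgc_by_species.setdefault(sp, set()).add(bgc_id)
        bgc_loci[bgc_id] = [(sp, locus + a, locus + b) for a, b in gene_spans]

    # Decoys: genes sliced verbatim from non-harboring genomes, attributed to
    # catalog-only species that never appear in a community.
    decoy_bgcs: set[str] = set()
    decoy_species: list[str] = []
    non_harboring = species[n_bgc_harboring:]
    for d in range(n_decoys):
        host = non_harboring[d % len(non_harboring)]
        genome = genomes[host]
        n_genes = int(rng.integers(3, 7))
        genes = []
        spans = []
        pos = int(rng.integers(0, genome_length // 2))
        for g in range(n_genes):
            glen = int(rng.integers(400, 801))
            if pos + glen > len(genome):
                pos = 0
            genes.append(GeneSequence(gene_id=f"gene{g + 1:02d}", sequence=genome[pos : pos + glen]))
            spans.append((host, pos, pos + glen))
            pos += glen + 100
        sp_decoy = normalize_species_name(f"Decoyus species{d:03d}")
        decoy_species.append(sp_decoy)
        bgc_id = f"BGC_D{d + 1:03d}"
        decoy_bgcs.add(bgc_id)
        records.append(
            BGCRecord(
                bgc_id=bgc_id,
                classes=frozenset({"other"}),
                sm_products=(f"decoymycin_{d + 1}",),
                source_species=frozenset({sp_decoy}),
                genes=tuple(genes),
            )
        )
        bgc_loci[bgc_id] = spans

    markers = _pick_unique_markers(genomes, rng, markers_per_species)
    catalog = SpeciesCatalog(species=frozenset(species) | frozenset(decoy_species))
    return FixtureWorld(
        genomes=genomes,
        records=records,
        catalog=catalog,
        markers=markers,
        bgc_by_species=bgc_by_species,
        decoy_bgcs=decoy_bgcs,
        bgc_loci=bgc_loci,
        seed=seed,
    )


def _pick_unique_markers(
    genomes: Mapping[str, str], rng: np.random.Generator, per_species: int
) -> dict[str, str]:
    """Choose per-species 31-mers occurring exactly once across all genomes.

    Uniqueness is checked on canonical k-mers (lexicographic min of the two
    orientations) so reads from either strand identify only their species;
    the returned map carries both orientations.
    """
    from collections import Counter

    k = MARKER_K
    counts: Counter[str] = Counter()
    for seq in genomes.values():
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            counts[min(kmer, revcomp(kmer))] += 1

    markers: dict[str, str] = {}
    for sp in sorted(genomes):
        seq = genomes[sp]
        positions = rng.permutation(len(seq) - k + 1)
        chosen = 0
        for p in positions:
            kmer = seq[p : p + k]
            canon = min(kmer, revcomp(kmer))
            if counts[canon] == 1 and kmer not in markers and revcomp(kmer) not in markers:
                markers[kmer] = sp
                markers[revcomp(kmer)] = sp
                chosen += 1
                if chosen == per_species:
                    break
        if chosen < per_species:
            raise ValueError(f"could not find {per_species} unique markers for {sp}")
    return markers


# ---------------------------------------------------------------------------
# Mock communities


@dataclass
class CommunityMember:
    species: str
    genome: str
    relative_abundance: float  # percent
    harbors_bgcs: set[str]


@dataclass
class MockCommunity:
    members: list[CommunityMember]
    community_id: str = "community"

    def __post_init__(self):
        total = sum(m.relative_abundance for m in self.members)
        if abs(total - 100.0) > 1e-6:
            raise ValueError(f"abundances sum to {total}, expected 100")
        names = [m.species for m in self.members]
        if len(set(names)) != len(names):
            raise ValueError("duplicate species in community")

    @property
    def richness(self) -> int:
        return len(self.members)

    @property
    def truth_bgcs(self) -> set[str]:
        out: set[str] = set()
        for m in self.members:
            out |= m.harbors_bgcs
        return out


def build_mock_community(
    world: FixtureWorld,
    richness: int,
    abundance_template: Sequence[float] | None = None,
    seed: int = 0,
    lognormal_sigma: float = 1.0,
    n_bgc_harboring: int | None = None,
    community_id: str = "community",
) -> MockCommunity:
    """Sample a community from the world and assign relative abundances.

    Species are sampled without replacement; abundances come from a supplied
    rank-abundance template (renormalized to 100) or from a log-normal draw
    (``sigma`` in log space), and are assigned to the sampled species at
    random.  ``n_bgc_harboring`` forces the number of BGC-harboring species
    drawn (default: fully random sampling).
    """
    rng = np.random.default_rng(seed)
    pool = sorted(world.genomes)
    if richness > len(pool):
        raise ValueError(f"richness {richness} exceeds species pool {len(pool)}")
    if n_bgc_harboring is None:
        chosen = [str(s) for s in rng.choice(pool, size=richness, replace=False)]
    else:
        harb = sorted(world.harboring_species)
        non = sorted(world.non_harboring_species)
        if n_bgc_harboring > len(harb) or richness - n_bgc_harboring > len(non):
            raise ValueError("requested composition exceeds available species")
        chosen = [str(s) for s in rng.choice(harb, size=n_bgc_harboring, replace=False)] + [
            str(s) for s in rng.choice(non, size=richness - n_bgc_harboring, replace=False)
        ]

    if abundance_template is not None:
        if len(abundance_template) != richness:
            raise ValueError("abundance template length must equal richness")
        ab = np.asarray(abundance_template, dtype=float)
    else:
        ab = rng.lognormal(mean=0.0, sigma=lognormal_sigma, size=richness)
    ab = 100.0 * ab / ab.sum()
    rng.shuffle(chosen)

    members = [
        CommunityMember(
            species=sp,
            genome=world.genomes[sp],
            relative_abundance=float(a),
            harbors_bgcs=set(world.bgc_by_species.get(sp, set())),
        )
        for sp, a in zip(chosen, ab)
    ]
    return MockCommunity(members=members, community_id=community_id)


# ---------------------------------------------------------------------------
# Read simulation


@dataclass
class SimulatedMetagenome:
    community: MockCommunity
    library_size: int  # read pairs
    read_length: int
    pairs: list[tuple[str, str, str]]  # (name, mate1, mate2)
    truth_bgcs: set[str]
    seed: int

    def read_seqs(self) -> Iterable[str]:
        for _, r1, r2 in self.pairs:
            yield r1
            yield r2

    def read_pairs_named(self) -> Iterable[tuple[str, str]]:
        for name, r1, r2 in self.pairs:
            yield f"{name}/1", r1
            yield f"{name}/2", r2

    def write_fastq(self, out_dir: str | Path, prefix: str = "reads") -> tuple[Path, Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        p1, p2 = out_dir / f"{prefix}_R1.fastq", out_dir / f"{prefix}_R2.fastq"
        with open(p1, "w") as f1, open(p2, "w") as f2:
            for name, r1, r2 in self.pairs:
                f1.write(f"@{name}/1\n{r1}\n+\n{'I' * len(r1)}\n")
                f2.write(f"@{name}/2\n{r2}\n+\n{'I' * len(r2)}\n")
        return p1, p2


def allocate_pairs(weights: Sequence[float], total: int) -> list[int]:
    """Integer allocation proportional to weights, by largest remainder.

    Sums exactly to ``total``; ties in remainder go to the earlier member.
    """
    w = np.asarray(weights, dtype=float)
    if w.sum() <= 0:
        raise ValueError("weights must have positive sum")
    exact = total * w / w.sum()
    base = np.floor(exact).astype(int)
    short = total - int(base.sum())
    if short:
        remainders = exact - base
        order = np.argsort(-remainders, kind="stable")
        for idx in order[:short]:
            base[idx] += 1
    return base.tolist()


def simulate_reads(
    community: MockCommunity,
    library_size: int,
    read_length: int = 100,
    error_rate: float = 0.001,
    insert_mean: float = 300.0,
    insert_sd: float = 30.0,
    seed: int = 0,
) -> SimulatedMetagenome:
    """Simulate a paired-end shotgun metagenome from a mock community.

    Pairs are allocated across members proportional to
    abundance x genome length (largest-remainder rounding hits the library
    size exactly).  Fragments start uniformly; insert sizes are
    normal(insert_mean, insert_sd) truncated to [2 x read_length, genome
    length]; mate 2 is the reverse complement of the fragment end.
    Substitution errors are applied independently per base at
    ``error_rate``; no indels.  Read names encode provenance as
    "species|fragment_start|serial".
    """
    if library_size < 1:
        raise ValueError("library_size must be >= 1")
    rng = np.random.default_rng(seed)
    usable = [m for m in community.members if len(m.genome) >= read_length]
    skipped = [m.species for m in community.members if len(m.genome) < read_length]
    if skipped:
        import logging

        logging.getLogger(__name__).warning(
            "skipping members with genome shorter than the read length: %s", skipped
        )
    weights = [m.relative_abundance * len(m.genome) for m in usable]
    alloc = allocate_pairs(weights, library_size)

    pairs: list[tuple[str, str, str]] = []
    serial = 0
    for member, n_pairs in zip(usable, alloc):
        if n_pairs == 0:
            continue
        genome = member.genome
        L = len(genome)
        inserts = rng.normal(insert_mean, insert_sd, size=n_pairs)
        inserts = np.clip(np.rint(inserts), 2 * read_length, L).astype(int)
        starts = (rng.random(n_pairs) * (L - inserts + 1)).astype(int)
        n_err = rng.binomial(2 * read_length, error_rate, size=n_pairs)
        for j in range(n_pairs):
            start, ins = int(starts[j]), int(inserts[j])
            r1 = genome[start : start + read_length]
            r2 = revcomp(genome[start + ins - read_length : start + ins])
            if n_err[j]:
                r1, r2 = _apply_errors(rng, r1, r2, int(n_err[j]), read_length)
            serial += 1
            pairs.append((f"{member.species}|{start}|{serial}", r1, r2))
    return SimulatedMetagenome(
        community=community,
        library_size=library_size,
        read_length=read_length,
        pairs=pairs,
        truth_bgcs=community.truth_bgcs,
        seed=seed,
    )


_SUBS = {b: [c for c in "ACGT" if c != b] for b in "ACGT"}


def _apply_errors(
    rng: np.random.Generator, r1: str, r2: str, n_err: int, read_length: int
) -> tuple[str, str]:
    joint = list(r1 + r2)
    for pos in rng.choice(2 * read_length, size=n_err, replace=False):
        base = joint[pos]
        if base in _SUBS:
            joint[pos] = _SUBS[base][int(rng.integers(3))]
    s = "".join(joint)
    return s[:read_length], s[read_length:]


# ---------------------------------------------------------------------------
# Evaluation


@dataclass(frozen=True)
class EvalMetrics:
    """Confusion counts and derived scores for one sample.

    precision = TP/(TP+FP), recall = TP/(TP+FN), and F1 is their harmonic
    mean.  PPV is precision by definition.  Degenerate conventions: with no
    positive calls precision/PPV is NaN (excluded from means); F1 is NaN only
    when TP=FP=FN=0, and 0 when TP=0 with any FP or FN.
    """

    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else math.nan

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else math.nan

    @property
    def ppv(self) -> float:
        return self.precision

    @property
    def f1(self) -> float:
        if self.tp == 0:
            return math.nan if (self.fp == 0 and self.fn == 0) else 0.0
        return 2 / (1 / self.precision + 1 / self.recall)


def evaluate(predicted: set[str], truth: set[str]) -> EvalMetrics:
    """Score a predicted BGC set against the ground-truth set."""
    return EvalMetrics(
        tp=len(predicted & truth),
        fp=len(predicted - truth),
        fn=len(truth - predicted),
    )


def nanmean(values: Iterable[float]) -> float:
    vals = [v for v in values if not math.isnan(v)]
    return sum(vals) / len(vals) if vals else math.nan


# ---------------------------------------------------------------------------
# Prepared samples and the threshold grid search


@dataclass
class PreparedSample:
    """Per-sample gene presence fractions, reusable across all threshold pairs.

    Presence fractions are threshold-independent, so alignment (and
    profiling) happen once per sample; each grid cell then only re-counts
    genes against its thresholds.
    """

    sample_id: str
    fractions: dict[str, list[float]]  # candidate bgc_id -> per-gene presence fractions
    truth: set[str]

    def confirmed_at(self, gene_presence_pct: float, coverage_pct: float) -> set[str]:
        gp = gene_presence_pct / 100.0
        cov = coverage_pct / 100.0
        out = set()
        for bgc_id, fracs in self.fractions.items():
            present = sum(1 for f in fracs if f >= gp)
            if present / len(fracs) >= cov:
                out.add(bgc_id)
        return out


def prepare_sample(
    metagenome: SimulatedMetagenome,
    world: FixtureWorld,
    db: ReferenceDatabase,
    mode: str = MODE_TAXONOMY,
    profile: TaxonomicProfile | None = None,
) -> PreparedSample:
    """Profile (taxonomy mode), align with the internal aligner, and cache
    per-gene presence fractions for one simulated sample."""
    from .coverage import SamStats, compute_gene_coverage, parse_sam

    sample_id = metagenome.community.community_id
    if mode == MODE_TAXONOMY:
        if profile is None:
            profile = world.profiler().profile_reads(
                metagenome.read_seqs(), sample_id=sample_id
            )
        matched = match_species(profile, db)
        candidates = first_pass_candidates(matched, db)
    elif mode == MODE_DIRECT:
        candidates = {bgc_id: set() for bgc_id in db.bgcs}
    else:
        raise ValueError(f"unknown mode {mode!r}")

    fractions: dict[str, list[float]] = {}
    if candidates:
        gene_lengths = candidate_gene_lengths(db, candidates)
        gene_seqs = {
            f"{bid}|{g.gene_id}": g.sequence
            for bid in candidates
            for g in db.bgcs[bid].genes
        }
        sam_text = naive_map_reads(metagenome.read_pairs_named(), gene_seqs)
        alignments = parse_sam(sam_text.splitlines(), counted_refs=set(gene_lengths))
        gene_covs = compute_gene_coverage(alignments, gene_lengths)
        for gc in gene_covs:
            fractions.setdefault(gc.bgc_id, []).append(gc.presence_fraction)
    return PreparedSample(sample_id=sample_id, fractions=fractions, truth=set(metagenome.truth_bgcs))


@dataclass
class GridSearchResult:
    grid: dict[tuple[int, int], float]  # (gene presence %, coverage %) -> mean F1
    best_pair: tuple[int, int]
    per_sample_best: list[tuple[str, tuple[int, int], float]]

    @property
    def best_mean_f1(self) -> float:
        return self.grid[self.best_pair]


def grid_search(
    samples: Sequence[PreparedSample],
    gene_presence_values: Sequence[int] = DEFAULT_GRID_VALUES,
    coverage_values: Sequence[int] = DEFAULT_GRID_VALUES,
) -> GridSearchResult:
    """Mean F1 over samples for every threshold pair; argmax is the optimum.

    The default 5-100% step-5 ranges give a 400-cell grid.  Ties at the
    optimum break to the smallest gene-presence, then smallest coverage.
    Per-sample F1 values of NaN (no truth and no calls) are excluded from
    cell means; each sample's own best pair is reported alongside.
    """
    if not samples:
        raise ValueError("grid search needs at least one sample")
    grid: dict[tuple[int, int], float] = {}
    per_sample_f1: dict[tuple[int, int], list[float]] = {}
    for gp in gene_presence_values:
        for cov in coverage_values:
            f1s = [
                evaluate(s.confirmed_at(gp, cov), s.truth).f1 for s in samples
            ]
            per_sample_f1[(gp, cov)] = f1s
            grid[(gp, cov)] = nanmean(f1s)

    def cell_key(pair):
        mean = grid[pair]
        return (-(mean if not math.isnan(mean) else -math.inf), pair)

    best_pair = min(grid, key=cell_key)

    per_sample_best = []
    for i, s in enumerate(samples):
        best_for_sample = min(
            per_sample_f1,
            key=lambda pair: (
                -(per_sample_f1[pair][i] if not math.isnan(per_sample_f1[pair][i]) else -math.inf),
                pair,
            ),
        )
        per_sample_best.append((s.sample_id, best_for_sample, per_sample_f1[best_for_sample][i]))
    return GridSearchResult(grid=grid, best_pair=best_pair, per_sample_best=per_sample_best)


def grid_to_frame(result: GridSearchResult):
    import pandas as pd

    rows = [
        {"gene_presence": gp, "bgc_coverage": cov, "mean_f1": f1}
        for (gp, cov), f1 in sorted(result.grid.items())
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Method comparison statistics


def compare_methods(per_sample_a: Sequence[float], per_sample_b: Sequence[float]) -> float:
    """Two-sided Mann-Whitney U p-value comparing per-sample score lists.

    Exact for small samples without ties, normal approximation with tie
    correction otherwise (scipy's auto policy).
    """
    if len(per_sample_a) < 2 or len(per_sample_b) < 2:
        raise ValueError("need at least two scores per group")
    return float(
        sps.mannwhitneyu(per_sample_a, per_sample_b, alternative="two-sided").pvalue
    )


def correlate(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation (rho, p) between paired per-sample values."""
    if len(x) < 2 or len(x) != len(y):
        raise ValueError("need paired lists of length >= 2")
    res = sps.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def geometric_mean_abundance(profile: TaxonomicProfile, db: ReferenceDatabase) -> float:
    """Geometric mean relative abundance of detected BGC-harboring species.

    Computed over species present in both the profile and the database
    (zero-abundance species cannot be detected, so none enter the mean).
    """
    vals = [ab for sp, ab in profile.entries if sp in db.species_index and ab > 0]
    if not vals:
        return math.nan
    return float(np.exp(np.mean(np.log(vals))))


# ---------------------------------------------------------------------------
# Turnkey fixture benchmark


@dataclass
class BenchmarkRun:
    world: FixtureWorld
    db: ReferenceDatabase
    samples: list[SimulatedMetagenome]
    prepared: dict[str, list[PreparedSample]]  # mode -> per-sample
    metrics: dict[str, list[EvalMetrics]]  # mode -> per-sample metrics at mode defaults

    def mean_f1(self, mode: str) -> float:
        return nanmean(m.f1 for m in self.metrics[mode])

    def mean_ppv(self, mode: str) -> float:
        return nanmean(m.ppv for m in self.metrics[mode])


def run_fixture_benchmark(
    seed: int,
    n_communities: int = 10,
    library_size: int = 20_000,
    n_species: int = 20,
    n_bgc_harboring: int = 5,
    genome_length: int = 30_000,
    richness: int = 12,
    community_harboring: int = 3,
    error_rate: float = 0.0,
    n_decoys: int = 0,
    modes: Sequence[str] = (MODE_TAXONOMY, MODE_DIRECT),
) -> BenchmarkRun:
    """Generate a world, simulate communities, and score both prediction modes.

    Each mode is scored at its own default thresholds (5%/10%
    taxonomy-guided, 5%/90% direct) on the same simulated samples.
    """
    world = generate_fixture_world(
        n_species=n_species,
        n_bgc_harboring=n_bgc_harboring,
        genome_length=genome_length,
        seed=seed,
        n_decoys=n_decoys,
    )
    db = world.build_database()
    samples = []
    for i in range(n_communities):
        community = build_mock_community(
            world,
            richness=richness,
            seed=seed + 1000 + i,
            n_bgc_harboring=community_harboring,
            community_id=f"sim{i:02d}",
        )
        samples.append(
            simulate_reads(
                community, library_size, error_rate=error_rate, seed=seed + 2000 + i
            )
        )

    prepared: dict[str, list[PreparedSample]] = {}
    metrics: dict[str, list[EvalMetrics]] = {}
    for mode in modes:
        prepped = [prepare_sample(mg, world, db, mode=mode) for mg in samples]
        prepared[mode] = prepped
        config = PredictionConfig.default_for_mode(mode)
        metrics[mode] = [
            evaluate(
                p.confirmed_at(
                    config.gene_presence_threshold, config.bgc_coverage_threshold
                ),
                p.truth,
            )
            for p in prepped
        ]
    return BenchmarkRun(world=world, db=db, samples=samples, prepared=prepared, metrics=metrics)
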