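"""End-to-end BGC prediction: taxonomy gate plus in silico confirmation.

Taxonomy-guided mode runs the three-step pipeline: (1) take a species-level
taxonomic profile of the sample; (2) first-pass prediction — query the
detected species in the reference database to collect candidate BGCs;
(3) in silico confirmation — align the sample's reads against the candidate
BGC genes only and confirm each candidate whose gene-coverage fraction
reaches the coverage threshold (gene presence judged at the gene-presence
threshold).  Confirmed BGCs carry their known SM products from the database.

Direct mode skips the taxonomy gate and evaluates every database BGC by
read mapping against the full gene set.  Its optimal thresholds differ
(coverage 90% rather than 10%): without the taxonomy gate, shared gene
content across clusters makes lenient coverage cutoffs produce false
positives.

Restricting the alignment reference to candidate genes is what gives the
taxonomy-guided mode its positive-predictive-value advantage: reads from
unrelated genomes cannot accumulate on clusters whose source species are
absent from the sample.  Triggering species are reported as putative origins
only — gene elements of a BGC can also originate from other clusters or
species.
"""

from __future__ import annotations

import json
import logging
import shlex
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd

from . import __version__
from .coverage import (
    BGCCoverage,
    SamStats,
    compute_bgc_coverage,
    compute_gene_coverage,
    naive_map_reads,
    parse_sam,
)
from .profiles import TaxonomicProfile, match_species, parse_taxonomic_profile
from .refdb import ReferenceDatabase

logger = logging.getLogger(__name__)

MODE_TAXONOMY = "taxonomy_guided"
MODE_DIRECT = "direct"

#: Advisory floor below which prediction accuracy becomes library-size
#: sensitive; smaller inputs trigger a warning, never an error.
RECOMMENDED_MIN_READ_PAIRS = 10_000_000


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class PredictionConfig:
    """Thresholds (percent) and mode for one prediction run.

    Defaults are the optima found by grid search on simulated metagenomes:
    gene presence 5% with coverage 10% for taxonomy-guided mode, and gene
    presence 5% with coverage 90% for direct detection.
    """

    gene_presence_threshold: float = 5.0
    bgc_coverage_threshold: float = 10.0
    mode: str = MODE_TAXONOMY

    def __post_init__(self):
        for name, v in (
            ("gene_presence_threshold", self.gene_presence_threshold),
            ("bgc_coverage_threshold", self.bgc_coverage_threshold),
        ):
            if not 0 < v <= 100:
                raise ConfigurationError(f"{name}={v} not in (0, 100]")
        if self.mode not in (MODE_TAXONOMY, MODE_DIRECT):
            raise ConfigurationError(f"unknown mode {self.mode!r}")

    @classmethod
    def default_for_mode(cls, mode: str) -> "PredictionConfig":
        if mode == MODE_DIRECT:
            return cls(gene_presence_threshold=5.0, bgc_coverage_threshold=90.0, mode=mode)
        return cls(mode=MODE_TAXONOMY)


@dataclass
class BGCPrediction:
    bgc_id: str
    sm_products: list[str]
    classes: list[str]
    triggering_species: set[str]
    coverage: BGCCoverage
    confirmed: bool


# ---------------------------------------------------------------------------
# Aligner contract

AlignerFn = Callable[[Sequence[Path], Path], str]
#: An aligner is a callable (read FASTQ paths, reference FASTA path) -> SAM text.


class CommandTemplateAligner:
    """External aligner invoked through a shell command template.

    The template receives ``{reads1}``, ``{reads2}`` (empty for single-end),
    ``{ref}`` and ``{out}``; the command must write SAM to ``{out}`` or to
    stdout when ``{out}`` is absent from the template.  The external tool is
    run with its own defaults, which also decide identity/ambiguity policy.
    """

    def __init__(self, template: str):
        self.template = template

    def __call__(self, read_paths: Sequence[Path], ref_fasta: Path) -> str:
        reads1 = str(read_paths[0])
        reads2 = str(read_paths[1]) if len(read_paths) > 1 else ""
        with tempfile.TemporaryDirectory(prefix="bgcprofiler_aln_") as tmp:
            out = Path(tmp) / "out.sam"
            cmd = self.template.format(reads1=reads1, reads2=reads2, ref=str(ref_fasta), out=str(out))
            proc = subprocess.run(
                shlex.split(cmd), capture_output=True, text=True, check=True
            )
            if "{out}" in self.template:
                return out.read_text()
            return proc.stdout


def naive_aligner(read_paths: Sequence[Path], ref_fasta: Path) -> str:
    """The built-in exact-seed aligner exposed under the aligner contract."""
    return naive_map_reads(list(read_paths), ref_fasta)


# ---------------------------------------------------------------------------
# Pipeline steps


def first_pass_candidates(
    matched_species: Iterable[str], db: ReferenceDatabase
) -> dict[str, set[str]]:
    """Candidate BGCs from detected species: bgc_id -> triggering species.

    A cluster harbored by several species is a single candidate listing
    every detected source species.
    """
    candidates: dict[str, set[str]] = {}
    for sp in matched_species:
        for bgc_id in db.species_index.get(sp, ()):
            candidates.setdefault(bgc_id, set()).add(sp)
    return candidates


def candidate_gene_lengths(db: ReferenceDatabase, bgc_ids: Iterable[str]) -> dict[str, int]:
    """Reference-name ("bgc_id|gene_id") -> gene length for the candidate set."""
    out: dict[str, int] = {}
    for bgc_id in sorted(bgc_ids):
        for g in db.bgcs[bgc_id].genes:
            out[f"{bgc_id}|{g.gene_id}"] = g.length
    return out


def write_candidate_fasta(db: ReferenceDatabase, bgc_ids: Iterable[str], path: Path) -> Path:
    with open(path, "w") as fh:
        for bgc_id in sorted(bgc_ids):
            for g in db.bgcs[bgc_id].genes:
                fh.write(f">{bgc_id}|{g.gene_id}\n{g.sequence}\n")
    return path


def confirm(
    candidates: Mapping[str, set[str]],
    sam_source,
    db: ReferenceDatabase,
    config: PredictionConfig,
    stats: SamStats | None = None,
) -> list[BGCPrediction]:
    """Confirm candidates from read alignments against their gene set.

    A candidate is confirmed iff its gene-coverage fraction is at least the
    coverage threshold, with per-gene presence judged at the gene-presence
    threshold (both comparisons inclusive).  SAM records referencing genes
    outside the candidate set are skipped with a counter.
    """
    if stats is None:
        stats = SamStats()
    gene_lengths = candidate_gene_lengths(db, candidates)
    alignments = parse_sam(sam_source, counted_refs=set(gene_lengths), stats=stats)
    gene_covs = compute_gene_coverage(alignments, gene_lengths, stats=stats)
    by_bgc: dict[str, list] = {}
    for gc in gene_covs:
        by_bgc.setdefault(gc.bgc_id, []).append(gc)

    predictions = []
    cov_thr = config.bgc_coverage_threshold / 100.0
    for bgc_id in sorted(candidates):
        bcov = compute_bgc_coverage(by_bgc[bgc_id], config.gene_presence_threshold)
        rec = db.bgcs[bgc_id]
        predictions.append(
            BGCPrediction(
                bgc_id=bgc_id,
                sm_products=list(db.sm_index[bgc_id]),
                classes=sorted(rec.classes),
                triggering_species=set(candidates[bgc_id]),
                coverage=bcov,
                confirmed=bcov.coverage_fraction >= cov_thr,
            )
        )
    return predictions


def predict_sample(
    db: ReferenceDatabase,
    config: PredictionConfig,
    profile: TaxonomicProfile | str | Path | None = None,
    reads: Sequence[str | Path] | None = None,
    sam: str | Path | Iterable[str] | None = None,
    aligner: AlignerFn | None = None,
    sample_id: str = "sample",
) -> tuple[list[BGCPrediction], pd.DataFrame]:
    """Run the full prediction pipeline for one sample.

    Taxonomy-guided mode needs a profile (object or MetaPhlAn-style TSV
    path); both modes need either a precomputed SAM or reads plus an aligner
    under the contract.  In taxonomy-guided mode reads are aligned only
    against the pooled candidate gene set (one alignment pass per sample);
    direct mode aligns against every gene in the database.  Output is
    deterministic for fixed inputs.
    """
    if config.mode == MODE_TAXONOMY:
        if profile is None:
            raise ConfigurationError("taxonomy-guided mode requires a taxonomic profile")
        if not isinstance(profile, TaxonomicProfile):
            profile = parse_taxonomic_profile(Path(profile).read_text(), sample_id=sample_id)
        matched = match_species(profile, db)
        candidates = first_pass_candidates(matched, db)
    else:
        candidates = {bgc_id: set() for bgc_id in db.bgcs}

    if sam is None and reads is None:
        raise ConfigurationError("either a precomputed SAM or reads must be provided")

    predictions: list[BGCPrediction] = []
    stats = SamStats()
    if candidates:
        if sam is None:
            if aligner is None:
                raise ConfigurationError("reads given but no aligner configured")
            _warn_if_shallow(reads)
            with tempfile.TemporaryDirectory(prefix="bgcprofiler_ref_") as tmp:
                ref = write_candidate_fasta(db, candidates, Path(tmp) / "candidates.fasta")
                sam_text = aligner([Path(r) for r in reads], ref)
            sam = sam_text.splitlines()
        predictions = confirm(candidates, sam, db, config, stats=stats)
    if stats.n_unknown_ref:
        logger.info(
            "%s: skipped %d alignments to references outside the candidate set",
            sample_id,
            stats.n_unknown_ref,
        )

    report = predictions_report(predictions, sample_id)
    return predictions, report


def _warn_if_shallow(reads: Sequence[str | Path]) -> None:
    try:
        n_reads = 0
        for p in reads:
            with open(p) as fh:
                n_reads += sum(1 for _ in fh) // 4
    except OSError:
        return
    n_pairs = n_reads // 2 if len(reads) > 1 else n_reads
    if n_pairs < RECOMMENDED_MIN_READ_PAIRS:
        logger.warning(
            "library of %d read pairs is below the recommended minimum of %d; "
            "prediction accuracy may be library-size sensitive",
            n_pairs,
            RECOMMENDED_MIN_READ_PAIRS,
        )


REPORT_COLUMNS = [
    "sample_id",
    "bgc_id",
    "confirmed",
    "coverage_fraction",
    "n_genes",
    "n_genes_present",
    "sm_products",
    "classes",
    "triggering_species",
]


def predictions_report(predictions: Sequence[BGCPrediction], sample_id: str) -> pd.DataFrame:
    rows = []
    for p in sorted(predictions, key=lambda p: p.bgc_id):
        rows.append(
            {
                "sample_id": sample_id,
                "bgc_id": p.bgc_id,
                "confirmed": p.confirmed,
                "coverage_fraction": round(p.coverage.coverage_fraction, 6),
                "n_genes": p.coverage.n_genes,
                "n_genes_present": p.coverage.n_genes_present,
                "sm_products": ";".join(p.sm_products),
                "classes": ";".join(p.classes),
                "triggering_species": ";".join(sorted(p.triggering_species)),
            }
        )
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)


def confirmed_set(predictions: Sequence[BGCPrediction]) -> set[str]:
    return {p.bgc_id for p in predictions if p.confirmed}


def write_report(
    report: pd.DataFrame, path: str | Path, config: PredictionConfig, inputs: dict | None = None
) -> Path:
    """Write the report TSV plus a JSON provenance sidecar."""
    path = Path(path)
    report.to_csv(path, sep="\t", index=False)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(
        json.dumps(
            {
                "tool": "bgcprofiler",
                "version": __version__,
                "config": {
                    "mode": config.mode,
                    "gene_presence_threshold": config.gene_presence_threshold,
                    "bgc_coverage_threshold": config.bgc_coverage_threshold,
                },
                "inputs": inputs or {},
            },
            indent=2,
            sort_keys=True,
        )
        + "\n"
    )
    return path
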