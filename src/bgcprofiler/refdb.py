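"""Reference database of experimentally characterized biosynthetic gene clusters.

A BGC (biosynthetic gene cluster) record ties together four things: the
cluster's genes (nucleotide sequences, the units read mapping is scored
against), its biosynthetic class(es), the secondary metabolites (SMs) it is
known to produce, and the species it was characterized from.  The reference
database restricts a collection of such records to the species a taxonomic
profiler can recognize, and indexes them species -> BGCs and BGC -> SMs so a
per-sample species list can be turned into a candidate BGC set.

Records are parsed either from MIBiG-style inputs (a JSON metadata entry plus
a GenBank flat file carrying CDS features) or from a simplified TSV+FASTA
fixture dialect, so tests and benchmarks never need external downloads.
"""

from __future__ import annotations

import io
import json
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

# The six main biosynthetic classes; anything else folds into "other".
MAIN_CLASSES = ("alkaloid", "NRP", "polyketide", "RiPP", "saccharide", "terpene")
OTHER_CLASS = "other"
ALL_CLASSES = MAIN_CLASSES + (OTHER_CLASS,)

_CLASS_SYNONYMS = {
    "alkaloid": "alkaloid",
    "nrp": "NRP",
    "nrps": "NRP",
    "nonribosomal peptide": "NRP",
    "non-ribosomal peptide": "NRP",
    "polyketide": "polyketide",
    "pks": "polyketide",
    "ripp": "RiPP",
    "saccharide": "saccharide",
    "terpene": "terpene",
    "other": OTHER_CLASS,
}


class RecordParseError(ValueError):
    """A BGC record is missing a required field or has no usable genes."""


class DatabaseError(ValueError):
    """Database construction or (de)serialization failed."""


def normalize_species_name(name: str) -> str:
    """Collapse an organism string to a normalized binomial.

    Source organism strings are frequently strain-qualified
    ("Lactobacillus gasseri EV1461"); profiler clade names are underscored
    binomials.  Matching happens at species level: keep the first two
    whitespace tokens, lowercase them, and join with an underscore.
    """
    tokens = name.replace("_", " ").split()
    if len(tokens) < 2:
        raise ValueError(f"not a binomial species name: {name!r}")
    return f"{tokens[0].lower()}_{tokens[1].lower()}"


def normalize_class_label(label: str) -> str:
    """Map a free-form class label onto the seven-label scheme (unknown -> other)."""
    return _CLASS_SYNONYMS.get(label.strip().lower(), OTHER_CLASS)


@dataclass(frozen=True)
class GeneSequence:
    """One gene of a BGC; the unit over which read-mapping presence is scored."""

    gene_id: str
    sequence: str

    def __post_init__(self):
        if not self.gene_id:
            raise ValueError("gene_id must be nonempty")
        if not self.sequence:
            raise ValueError(f"gene {self.gene_id}: empty sequence")
        if not set(self.sequence) <= set("ACGTN"):
            raise ValueError(f"gene {self.gene_id}: sequence not over ACGTN")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class BGCRecord:
    """One experimentally characterized cluster.

    A BGC can be derived from multiple species, can encode multiple SMs,
    and can belong to multiple classes; summaries must count accordingly.
    """

    bgc_id: str
    classes: frozenset[str]
    sm_products: tuple[str, ...]
    source_species: frozenset[str]
    genes: tuple[GeneSequence, ...]

    def __post_init__(self):
        if not self.bgc_id:
            raise RecordParseError("missing BGC accession")
        if not self.classes:
            raise RecordParseError(f"{self.bgc_id}: no biosynthetic classes")
        if not self.sm_products:
            raise RecordParseError(f"{self.bgc_id}: no SM products")
        if not self.source_species:
            raise RecordParseError(f"{self.bgc_id}: no source species")
        if not self.genes:
            raise RecordParseError(
                f"{self.bgc_id}: no genes (a BGC with no genes cannot be confirmed)"
            )
        gene_ids = [g.gene_id for g in self.genes]
        if len(set(gene_ids)) != len(gene_ids):
            raise RecordParseError(f"{self.bgc_id}: duplicate gene_ids")


@dataclass(frozen=True)
class SpeciesCatalog:
    """Normalized binomials the taxonomic profiler can recognize."""

    species: frozenset[str]

    def __post_init__(self):
        if not self.species:
            raise ValueError("species catalog is empty")

    def __contains__(self, name: str) -> bool:
        return name in self.species


@dataclass
class ReferenceDatabase:
    """Catalog-restricted, bidirectionally indexed collection of BGC records."""

    bgcs: dict[str, BGCRecord]
    species_index: dict[str, set[str]]
    sm_index: dict[str, list[str]]
    catalog_version: str = ""

    @property
    def species(self) -> set[str]:
        return set(self.species_index)

    def __eq__(self, other) -> bool:
        if not isinstance(other, ReferenceDatabase):
            return NotImplemented
        return (
            self.bgcs == other.bgcs
            and self.species_index == other.species_index
            and self.sm_index == other.sm_index
            and self.catalog_version == other.catalog_version
        )


@dataclass
class DBSummary:
    """Counts and histograms describing a reference database."""

    n_species: int
    n_bgcs: int
    n_sm_total: int
    n_sm_unique: int
    per_class_bgc_counts: dict[str, int]
    per_class_species_counts: dict[str, int]
    species_bgc_histogram: dict[int, int]
    bgc_sm_histogram: dict[int, int]
    gene_count_histogram: dict[int, int]

    def per_class_bgc_pct(self) -> dict[str, float]:
        """Per-class shares of the BGC total, one-decimal percent."""
        return {
            c: class_share_pct(n, self.n_bgcs)
            for c, n in self.per_class_bgc_counts.items()
        }


def class_share_pct(count: int, total: int) -> float:
    """Share of a total as a percent rounded to one decimal (e.g. 338/953 -> 35.5)."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round(100.0 * count / total, 1)


# ---------------------------------------------------------------------------
# Parsing


def _extract_json_field(entry: dict, *keys):
    for k in keys:
        if k in entry and entry[k] not in (None, "", []):
            return entry[k]
    return None


def parse_bgc_record(json_text: str, genbank_text: str) -> BGCRecord:
    """Parse one MIBiG-style JSON metadata entry plus its GenBank flat file.

    The JSON supplies accession, compounds, biosynthetic classes and the
    organism; the GenBank file supplies CDS nucleotide sequences, which become
    the record's genes in file order (minus-strand features are
    reverse-complemented; pseudo-genes are kept — they are mapping targets
    regardless of translatability).
    """
    meta = json.loads(json_text)
    if "cluster" in meta and isinstance(meta["cluster"], dict):
        meta = meta["cluster"]

    accession = _extract_json_field(meta, "mibig_accession", "accession", "bgc_id")
    if not accession:
        raise RecordParseError("record JSON missing accession")

    compounds = _extract_json_field(meta, "compounds")
    if not compounds:
        raise RecordParseError(f"{accession}: record JSON missing compounds")
    sm_products = []
    for c in compounds:
        name = c.get("compound") if isinstance(c, dict) else c
        if name:
            sm_products.append(str(name))
    if not sm_products:
        raise RecordParseError(f"{accession}: no named compounds")

    raw_classes = _extract_json_field(meta, "biosyn_class", "classes") or []
    classes = frozenset(normalize_class_label(c) for c in raw_classes) or frozenset(
        {OTHER_CLASS}
    )

    organism = _extract_json_field(meta, "organism_name", "organism")
    if not organism:
        loci = meta.get("loci") or {}
        organism = loci.get("organism_name") if isinstance(loci, dict) else None
    if not organism:
        raise RecordParseError(f"{accession}: record JSON missing organism")
    species = frozenset({normalize_species_name(organism)})

    genes: list[GeneSequence] = []
    seen: set[str] = set()
    for seqrec in SeqIO.parse(io.StringIO(genbank_text), "genbank"):
        for feat in seqrec.features:
            if feat.type != "CDS":
                continue
            quals = feat.qualifiers
            gene_id = (
                (quals.get("locus_tag") or quals.get("gene") or quals.get("protein_id") or [None])[0]
            )
            if not gene_id or gene_id in seen:
                gene_id = f"cds_{len(genes) + 1}"
            seen.add(gene_id)
            seq = str(feat.extract(seqrec.seq)).upper()
            genes.append(GeneSequence(gene_id=gene_id, sequence=seq))
    if not genes:
        raise RecordParseError(f"{accession}: GenBank carries no CDS features")

    return BGCRecord(
        bgc_id=accession,
        classes=classes,
        sm_products=tuple(sm_products),
        source_species=species,
        genes=tuple(genes),
    )


def parse_fixture_records(tsv_text: str, fasta_text: str) -> list[BGCRecord]:
    """Parse the simplified fixture dialect: a metadata TSV plus one gene FASTA.

    TSV columns: bgc_id, classes (';'-joined), sm_products (';'-joined),
    source_species (';'-joined).  FASTA headers are "bgc_id|gene_id".
    """
    genes_by_bgc: dict[str, list[GeneSequence]] = {}
    for rec in SeqIO.parse(io.StringIO(fasta_text), "fasta"):
        if "|" not in rec.id:
            raise RecordParseError(f"gene FASTA header not 'bgc_id|gene_id': {rec.id}")
        bgc_id, gene_id = rec.id.split("|", 1)
        genes_by_bgc.setdefault(bgc_id, []).append(
            GeneSequence(gene_id=gene_id, sequence=str(rec.seq).upper())
        )

    records = []
    for i, line in enumerate(tsv_text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if fields[0] == "bgc_id":  # header row
            continue
        if len(fields) < 4:
            raise RecordParseError(f"fixture TSV line {i}: expected 4 columns")
        bgc_id, classes_s, sms_s, species_s = fields[:4]
        if bgc_id not in genes_by_bgc:
            raise RecordParseError(f"fixture TSV line {i}: no genes in FASTA for {bgc_id}")
        records.append(
            BGCRecord(
                bgc_id=bgc_id,
                classes=frozenset(normalize_class_label(c) for c in classes_s.split(";") if c),
                sm_products=tuple(s for s in sms_s.split(";") if s),
                source_species=frozenset(
                    normalize_species_name(s) for s in species_s.split(";") if s
                ),
                genes=tuple(genes_by_bgc[bgc_id]),
            )
        )
    return records


# ---------------------------------------------------------------------------
# Database construction


def build_reference_database(
    records: list[BGCRecord],
    catalog: SpeciesCatalog,
    catalog_version: str = "",
) -> ReferenceDatabase:
    """Restrict records to the profiler-recognizable catalog and index them.

    A record is retained iff at least one of its source species is in the
    catalog; the species index only lists catalog-intersected species, so a
    record sourced from both a catalog and a non-catalog species appears
    under the catalog species alone.  Multiple records per species are
    unioned under the species.
    """
    bgcs: dict[str, BGCRecord] = {}
    species_index: dict[str, set[str]] = {}
    sm_index: dict[str, list[str]] = {}
    for rec in records:
        kept = rec.source_species & catalog.species
        if not kept:
            continue
        if rec.bgc_id in bgcs:
            raise DatabaseError(f"duplicate BGC accession {rec.bgc_id}")
        bgcs[rec.bgc_id] = rec
        sm_index[rec.bgc_id] = list(rec.sm_products)
        for sp in kept:
            species_index.setdefault(sp, set()).add(rec.bgc_id)
    if not bgcs:
        raise DatabaseError(
            "no records retained: catalog shares no species with the records "
            "(check species-name normalization and catalog contents)"
        )
    return ReferenceDatabase(
        bgcs=bgcs,
        species_index=species_index,
        sm_index=sm_index,
        catalog_version=catalog_version,
    )


def summarize_database(db: ReferenceDatabase) -> DBSummary:
    """Count species, BGCs and SMs and build the rank/size histograms.

    Classes overlap (a BGC may be multi-class) so per-class counts need not
    sum to the BGC total; the unique-SM count deduplicates case-folded exact
    SM name strings across BGCs.
    """
    if not db.bgcs:
        raise DatabaseError("cannot summarize an empty database")
    n_bgcs = len(db.bgcs)
    n_species = len(db.species_index)

    per_class_bgc = Counter()
    per_class_species: dict[str, set[str]] = {c: set() for c in ALL_CLASSES}
    sm_total = 0
    sm_seen: set[str] = set()
    bgc_sm_hist = Counter()
    gene_hist = Counter()
    for rec in db.bgcs.values():
        for c in rec.classes:
            per_class_bgc[c] += 1
        sm_total += len(rec.sm_products)
        sm_seen.update(s.casefold() for s in rec.sm_products)
        bgc_sm_hist[len(rec.sm_products)] += 1
        gene_hist[len(rec.genes)] += 1
    for sp, ids in db.species_index.items():
        for bid in ids:
            for c in db.bgcs[bid].classes:
                per_class_species[c].add(sp)

    species_bgc_hist = Counter(len(ids) for ids in db.species_index.values())
    return DBSummary(
        n_species=n_species,
        n_bgcs=n_bgcs,
        n_sm_total=sm_total,
        n_sm_unique=len(sm_seen),
        per_class_bgc_counts={c: per_class_bgc.get(c, 0) for c in ALL_CLASSES},
        per_class_species_counts={c: len(s) for c, s in per_class_species.items()},
        species_bgc_histogram=dict(species_bgc_hist),
        bgc_sm_histogram=dict(bgc_sm_hist),
        gene_count_histogram=dict(gene_hist),
    )


# ---------------------------------------------------------------------------
# Serialization: a directory of per-BGC gene FASTA files + one metadata TSV.

_META_COLUMNS = ("bgc_id", "classes", "sm_products", "source_species", "indexed_species")


def write_database(db: ReferenceDatabase, path: str | Path) -> Path:
    """Serialize to a directory: metadata.tsv + genes/<bgc_id>.fasta."""
    root = Path(path)
    genes_dir = root / "genes"
    genes_dir.mkdir(parents=True, exist_ok=True)
    lines = ["\t".join(_META_COLUMNS) + f"\tcatalog_version={db.catalog_version}"]
    for bgc_id in sorted(db.bgcs):
        rec = db.bgcs[bgc_id]
        indexed = sorted(sp for sp, ids in db.species_index.items() if bgc_id in ids)
        lines.append(
            "\t".join(
                [
                    bgc_id,
                    ";".join(sorted(rec.classes)),
                    ";".join(rec.sm_products),
                    ";".join(sorted(rec.source_species)),
                    ";".join(indexed),
                ]
            )
        )
        with open(genes_dir / f"{bgc_id}.fasta", "w") as fh:
            for g in rec.genes:
                fh.write(f">{bgc_id}|{g.gene_id}\n{g.sequence}\n")
    (root / "metadata.tsv").write_text("\n".join(lines) + "\n")
    return root


def load_database(path: str | Path) -> ReferenceDatabase:
    """Load a database serialized by :func:`write_database` (round-trip identity)."""
    root = Path(path)
    meta_path = root / "metadata.tsv"
    if not meta_path.exists():
        raise DatabaseError(f"not a database directory (no metadata.tsv): {root}")
    lines = meta_path.read_text().splitlines()
    if not lines or not lines[0].startswith("\t".join(_META_COLUMNS)):
        raise DatabaseError(f"{meta_path}: line 1: bad or missing header")
    m = re.search(r"catalog_version=(.*)$", lines[0])
    catalog_version = m.group(1) if m else ""

    bgcs: dict[str, BGCRecord] = {}
    species_index: dict[str, set[str]] = {}
    sm_index: dict[str, list[str]] = {}
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != len(_META_COLUMNS):
            raise DatabaseError(
                f"{meta_path}: line {lineno}: expected {len(_META_COLUMNS)} columns, "
                f"got {len(fields)}"
            )
        bgc_id, classes_s, sms_s, species_s, indexed_s = fields
        fasta = root / "genes" / f"{bgc_id}.fasta"
        if not fasta.exists():
            raise DatabaseError(f"{meta_path}: line {lineno}: missing gene FASTA for {bgc_id}")
        genes = []
        for rec in SeqIO.parse(str(fasta), "fasta"):
            fid_bgc, _, gene_id = rec.id.partition("|")
            if fid_bgc != bgc_id or not gene_id:
                raise DatabaseError(f"{fasta}: header {rec.id!r} not '{bgc_id}|gene_id'")
            genes.append(GeneSequence(gene_id=gene_id, sequence=str(rec.seq).upper()))
        record = BGCRecord(
            bgc_id=bgc_id,
            classes=frozenset(classes_s.split(";")),
            sm_products=tuple(sms_s.split(";")),
            source_species=frozenset(species_s.split(";")),
            genes=tuple(genes),
        )
        bgcs[bgc_id] = record
        sm_index[bgc_id] = list(record.sm_products)
        for sp in indexed_s.split(";"):
            if sp:
                species_index.setdefault(sp, set()).add(bgc_id)
    return ReferenceDatabase(
        bgcs=bgcs,
        species_index=species_index,
        sm_index=sm_index,
        catalog_version=catalog_version,
    )
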