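"""Shared fixtures: a small synthetic world and MIBiG-style record texts.

All fixture data is generated programmatically; nothing is downloaded or
stored on disk.
"""

from __future__ import annotations

import json

import pytest

from bgcprofiler.benchmark import generate_fixture_world


@pytest.fixture(scope="session")
def small_world():
    """Deterministic world: 8 species, 3 BGC-harboring, 2 decoy records."""
    return generate_fixture_world(
        n_species=8,
        n_bgc_harboring=3,
        genome_length=30_000,
        seed=7,
        n_decoys=2,
    )


@pytest.fixture(scope="session")
def small_db(small_world):
    return small_world.build_database()


def make_genbank_text(genes: list[tuple[str, str, int]], name: str = "BGC_T001") -> str:
    """Build a GenBank flat file with CDS features from (gene_id, seq, strand).

    Genes are laid head-to-tail with 10 bp spacers; minus-strand genes are
    stored reverse-complemented in the contig so that extraction must
    reverse-complement them back.
    """
    from io import StringIO

    from Bio.Seq import Seq
    from Bio.SeqFeature import FeatureLocation, SeqFeature
    from Bio.SeqRecord import SeqRecord

    contig_parts: list[str] = []
    features = []
    pos = 0
    for gene_id, seq, strand in genes:
        stored = str(Seq(seq).reverse_complement()) if strand == -1 else seq
        features.append(
            SeqFeature(
                FeatureLocation(pos, pos + len(seq), strand=strand),
                type="CDS",
                qualifiers={"locus_tag": [gene_id]},
            )
        )
        contig_parts.append(stored)
        contig_parts.append("A" * 10)
        pos += len(seq) + 10
    record = SeqRecord(
        Seq("".join(contig_parts)),
        id=name,
        name=name,
        description="synthetic test cluster",
        annotations={"molecule_type": "DNA"},
    )
    record.features = features
    buf = StringIO()
    from Bio import SeqIO

    SeqIO.write(record, buf, "genbank")
    return buf.getvalue()


def make_mibig_json(
    accession: str = "BGC_T001",
    compounds: list[str] = ("toymycin",),
    classes: list[str] = ("Polyketide",),
    organism: str = "Streptomyces toyi",
) -> str:
    return json.dumps(
        {
            "cluster": {
                "mibig_accession": accession,
                "compounds": [{"compound": c} for c in compounds],
                "biosyn_class": list(classes),
                "organism_name": organism,
            }
        }
    )


@pytest.fixture
def genbank_3cds():
    genes = [
        ("tmy_A", "ATGAAACCCGGGTTTACGTACGTACGTTGA", 1),
        ("tmy_B", "ATGCCCAAATTTGGGCATCATCATCATTGA", -1),
        ("tmy_C", "ATGTTTGGGAAACCCGTAGTAGTAGTATGA", 1),
    ]
    return make_genbank_text(genes), genes
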