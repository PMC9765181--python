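"""Species-level taxonomic profiles: parsing, matching, and the test profiler.

The pipeline's first step is a species-level taxonomic profile of the sample
(MetaPhlAn-style TSV).  Profiled species are then matched against the
reference database to form the first-pass candidate BGC set.  Relative
abundances are carried along for reporting but never gate inclusion: any
detected species qualifies, however rare — prediction accuracy does not
depend on the abundance of the BGC-harboring species, and the profiler's own
detection limit is the implicit floor.

For download-free end-to-end tests a minimal k-mer profiler is included: it
detects a species when any of its unique 31-mer markers occurs in the reads.
It is a fixture standing behind the external-profiler contract, not a
production profiler.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, TYPE_CHECKING

from Bio import SeqIO

if TYPE_CHECKING:  # pragma: no cover
    from .refdb import ReferenceDatabase

logger = logging.getLogger(__name__)

_ABUNDANCE_SUM_TOL = 1e-6


class ProfileParseError(ValueError):
    pass


@dataclass
class TaxonomicProfile:
    """Species-level relative abundances (percent) for one sample."""

    sample_id: str
    entries: list[tuple[str, float]] = field(default_factory=list)

    def __post_init__(self):
        names = [n for n, _ in self.entries]
        if len(set(names)) != len(names):
            raise ProfileParseError(f"{self.sample_id}: duplicate species in profile")
        if any(a < 0 for _, a in self.entries):
            raise ProfileParseError(f"{self.sample_id}: negative abundance")
        total = sum(a for _, a in self.entries)
        if total > 100 + _ABUNDANCE_SUM_TOL:
            raise ProfileParseError(
                f"{self.sample_id}: abundances sum to {total:.6f} > 100"
            )

    @property
    def species(self) -> set[str]:
        return {n for n, _ in self.entries}

    def abundance(self, species: str) -> float:
        for n, a in self.entries:
            if n == species:
                return a
        raise KeyError(species)

    def to_tsv(self) -> str:
        lines = [f"#SampleID\t{self.sample_id}", "#clade_name\trelative_abundance"]
        for name, ab in self.entries:
            genus = name.split("_", 1)[0].capitalize()
            clade = f"k__|g__{genus}|s__{name.capitalize()}"
            lines.append(f"{clade}\t{ab:.6f}")
        return "\n".join(lines) + "\n"


def parse_taxonomic_profile(tsv_text: str, sample_id: str = "sample") -> TaxonomicProfile:
    """Parse a MetaPhlAn-style profile, keeping species-level rows only.

    Species rows contain an ``s__`` clade; strain-level ``t__`` rows (a rank
    below species) are excluded, as are comment lines.  The abundance is the
    last numeric column (profiles may carry an optional taxid-path column and
    trailing columns, which are ignored).
    """
    entries: list[tuple[str, float]] = []
    seen: set[str] = set()
    n_rows = 0
    for lineno, line in enumerate(tsv_text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        n_rows += 1
        fields = line.rstrip("\n").split("\t")
        clade = fields[0]
        if "s__" not in clade or "t__" in clade:
            continue
        species_token = next(
            part[len("s__"):] for part in clade.split("|") if part.startswith("s__")
        )
        name = species_token.strip().lower()
        if "_" not in name:
            raise ProfileParseError(f"line {lineno}: species clade not binomial: {clade!r}")
        abundance = None
        for f in fields[1:]:
            try:
                abundance = float(f)
            except ValueError:
                continue
        if abundance is None:
            raise ProfileParseError(f"line {lineno}: no parseable abundance in {line!r}")
        if name in seen:
            raise ProfileParseError(f"line {lineno}: duplicate species {name}")
        seen.add(name)
        entries.append((name, abundance))
    if not entries:
        logger.warning("profile %s: no species-level rows found", sample_id)
    return TaxonomicProfile(sample_id=sample_id, entries=entries)


def match_species(profile: TaxonomicProfile, db: "ReferenceDatabase") -> set[str]:
    """Species present in both the profile and the database species index.

    No abundance threshold is applied; detection alone qualifies a species.
    """
    return profile.species & set(db.species_index)


# ---------------------------------------------------------------------------
# Internal k-mer test profiler (fixture behind the external-profiler contract)

MARKER_K = 31


class KmerMarkerProfiler:
    """Detects species by exact hits to species-unique 31-mer markers.

    ``markers`` maps each marker k-mer to its species.  A species is reported
    as present if any of its markers occurs in any read; its relative
    abundance is estimated as its share of total marker-bearing reads,
    scaled to percent.
    """

    def __init__(self, markers: dict[str, str], k: int = MARKER_K):
        self.k = k
        self.markers = dict(markers)

    def profile_reads(
        self, read_seqs: Iterable[str], sample_id: str = "sample"
    ) -> TaxonomicProfile:
        from collections import Counter

        k = self.k
        markers = self.markers
        hits: Counter[str] = Counter()
        for seq in read_seqs:
            seq = seq.upper()
            found: set[str] = set()
            for i in range(len(seq) - k + 1):
                sp = markers.get(seq[i : i + k])
                if sp is not None:
                    found.add(sp)
            for sp in found:
                hits[sp] += 1
        total = sum(hits.values())
        entries = [
            (sp, 100.0 * n / total) for sp, n in sorted(hits.items(), key=lambda x: (-x[1], x[0]))
        ]
        return TaxonomicProfile(sample_id=sample_id, entries=entries)

    def profile_fastq(self, fastq_paths: Iterable[str | Path], sample_id: str = "sample"):
        def reads():
            for p in fastq_paths:
                for rec in SeqIO.parse(str(p), "fastq"):
                    yield str(rec.seq)

        return self.profile_reads(reads(), sample_id=sample_id)
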