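# Methods

## The prediction model

A sample is modelled as a mixture of species whose genomes may carry
experimentally characterized biosynthetic gene clusters (BGCs). Prediction
is a two-stage decision:

1. **Taxonomy gate.** The candidate set for a sample is the union of BGCs
   attributed (in the reference database) to any species detected in the
   sample's species-level taxonomic profile. Detection alone qualifies a
   species — no abundance floor is applied, because confirmation accuracy is
   governed by read coverage of the cluster genes, not by the profiled
   abundance, and the profiler's own detection limit already acts as an
   implicit floor. A cluster attributed to several species becomes a single
   candidate listing all detected source species; these are reported as
   putative origins only, since homologous gene content can also derive from
   other clusters or species.

2. **Breadth-of-coverage confirmation.** Sample reads are aligned against
   the pooled candidate gene sequences (one alignment pass per sample). For
   each gene, *presence* is the fraction of its length covered by at least
   one mapped read — breadth, never depth; overlapping reads are unioned via
   interval merging, so depth beyond 1 is ignored. For each cluster,
   *coverage* is the fraction of its genes whose presence reaches the
   gene-presence threshold. The cluster is confirmed when coverage reaches
   the BGC-coverage threshold. All comparisons are inclusive (`>=`),
   consistent with the thresholds being minima.

**Direct detection** is the ungated baseline: every database BGC is
evaluated by mapping reads against the full gene set. Shared gene content
then accumulates coverage on clusters whose source organisms are absent, so
its operating point must be much stricter on coverage (90 % vs 10 %) and it
still trades precision for the lost gate. The taxonomy-guided mode's
positive-predictive-value advantage comes precisely from aligning only
against candidate genes.

### Alignment accounting

Only mapped, primary, non-supplementary SAM records are counted; secondary
and supplementary alignments are excluded so a multi-mapped read contributes
breadth at a single best placement (the conservative reading; a flag-level
switch is easy to add at `parse_sam` if ambiguous placements are wanted).
Paired mates contribute intervals independently — no proper-pair
requirement, since the statistic is breadth, not fragment accounting. CIGAR
semantics: `M/=/X` cover reference positions, `D/N` consume reference
without covering, `I/S/H/P` consume none. SAM input is 1-based; internal
intervals are 0-based half-open. Alignments overhanging a gene end are
clipped and counted once, with a warning counter.

## Parameters

| parameter | default | units | rationale |
| --- | --- | --- | --- |
| gene presence threshold | 5 | % of gene length | grid-search optimum (taxonomy-guided and direct) |
| BGC coverage threshold | 10 (taxonomy-guided), 90 (direct) | % of genes present | grid-search optima per mode |
| grid ranges | 5–100 step 5, both axes | % | 400 threshold pairs |
| read length (simulator) | 100 | bp | paired-end short-read regime |
| insert size | normal(300, 30), truncated ≥ 2×read length | bp | typical shotgun library |
| substitution error rate | 0.001 | per base | Illumina-like; no indels |
| recommended library size | ≥ 10 million read pairs | pairs | below this, accuracy becomes library-size sensitive; smaller inputs warn, never fail |
| test profiler / aligner k | 31 | bp | exact-seed specificity at fixture scale |
| naive-aligner identity floor | 0.76 | fraction | mirrors the default-regime behaviour of production short-read mappers; production runs delegate identity policy to the external aligner |

Thresholds are user-overridable per run and validated into (0, 100].

## Reference database

Records carry genes (CDS nucleotide sequences, minus-strand features
reverse-complemented, pseudo-genes retained — they are mapping targets
regardless of translatability), biosynthetic classes, SM products, and
source species. Classes are normalized case-insensitively onto the seven
labels {alkaloid, NRP, polyketide, RiPP, saccharide, terpene, other};
synonyms like "nonribosomal peptide" fold into NRP and anything outside the
six main classes folds into "other". Organism strings are matched to the
profiler's vocabulary at species level: the first two whitespace tokens,
lowercased and underscore-joined ("Lactobacillus gasseri EV1461" →
`lactobacillus_gasseri`); strains of one species are unioned under the
species. A record is retained iff at least one source species is in the
catalog of profiler-recognizable species, and the species index lists only
catalog species. Summaries count a multi-class BGC once per class (so class
counts need not sum to the BGC total); the unique-SM count deduplicates
case-folded exact name strings — both the total and the unique count are
exposed, since different curation rules can legitimately disagree on the
dedup key.

Serialization is a directory: one metadata TSV plus one gene FASTA per BGC
with `bgc_id|gene_id` headers; loading is a strict round-trip with
line-numbered errors.

## The synthetic benchmark

The fixture world emulates the structure the method depends on, not real
genome content: i.i.d. random genomes (default 20 species of 30 kb), with
one synthetic BGC (3–15 genes of 300–2000 bp, 50 bp spacers) embedded
verbatim at a recorded locus in each of the first 5 species, and 20
species-unique 31-mers (checked against all genomes in both orientations)
recorded per species for the k-mer test profiler. Mock communities sample
species without replacement, draw relative abundances from a supplied
rank-abundance template or a log-normal (σ = 1), and assign them at random;
read pairs are allocated across members proportional to
abundance × genome length (DNA-proportional sequencing) with
largest-remainder rounding so the library size is hit exactly. Ground truth
for a sample is the union of clusters embedded in its member genomes.

**Decoy records** model the false-positive mechanism of direct detection:
their genes are verbatim slices of non-BGC-harboring community genomes,
attributed to a catalog species that is never placed in a community. Reads
from those genomes fully cover the decoy genes, so direct mode confirms
them; the taxonomy gate never proposes them. (Duplicating a real BGC's
genes would not work as a decoy under best-hit primary-only alignment — ties
route all reads to one copy — which is why content is shared with community
genomes instead of with other database records.)

What the fixtures deliberately do **not** model: real inter-species homology
and mosaic gene sharing between clusters, genome size variation, GC/repeat
structure, indel and quality-score error profiles, and profiler
mis-assignment. Passing benchmarks therefore demonstrate the correctness of
the machinery and the direction of the taxonomy-gate advantage — not
field-calibrated accuracy values; absolute F1/PPV on these clean fixtures
sit near the ceiling (taxonomy-guided recovery is exact at default
thresholds on error-free samples), whereas real metagenomes are far
messier.

Benchmark scale defaults were chosen once for desk-scale runs: ground-truth
recovery uses 3 communities × 100k pairs; the mode comparison uses 10
communities × 20k pairs with 4 decoys; communities of richness 12 with 3
BGC-harboring members. Full-scale parameters (community count, richness
40–100, library sizes into the tens of millions) remain ordinary function
arguments.

## Evaluation and statistics

Per sample, TP/FP/FN compare the confirmed set against truth;
precision = TP/(TP+FP), recall = TP/(TP+FN), F1 is their harmonic mean
(equivalently 2TP/(2TP+FP+FN)), PPV ≡ precision. Degenerate conventions,
documented rather than silently chosen: with no positive calls
precision/PPV is NA and excluded from means; F1 is NA only when
TP = FP = FN = 0 and is 0 when TP = 0 with any FP or FN. The grid search
computes alignment once per sample (presence fractions are
threshold-independent) and re-counts per cell; the optimum is the argmax of
mean F1 with ties broken to the smallest gene-presence, then smallest
coverage — a unique optimum is expected on realistic data, so the tie-break
only matters on fixtures. Mode comparison uses the two-sided Mann-Whitney U
test (exact for small untied samples, normal approximation with tie
correction otherwise) and Spearman rank correlation for the
abundance-vs-accuracy check; the geometric mean abundance of BGC-harboring
species is computed over detected species only (undetected species have no
abundance to contribute).

Association analysis builds a boolean samples × BGCs presence matrix
(samples with zero confirmed clusters keep all-false rows so prevalence
denominators stay honest) and runs two-sided Fisher's exact tests by the
point-probability rule. Multi-group contrasts are one-vs-rest per BGC per
group — the per-group-star reporting convention — with raw p-values and
tier symbols (ns ≥ 0.05 > * ≥ 0.01 > ** ≥ 0.001 > ***) by default; a
Benjamini–Hochberg q-value column is available but off by default, keeping
the default output faithful to raw-P reporting. Pairwise group contrasts
are available through `fisher_association` directly.

## Numerical and design notes

- Interval unions use an interval tree; coverage equals the per-base
  boolean-array definition exactly (property-tested against that oracle).
- The naive aligner is a *fixture*: exact 31-mer seeds (three offsets per
  orientation), ungapped full-read extension, best identity wins, ties to
  the lowest (reference, position) with forward orientation preferred.
  Reads must fit within a gene; boundary-straddling reads go unmapped,
  which only costs redundant depth at fixture coverage levels. Production
  alignment is delegated to any SAM-producing aligner via a command
  template (`{reads1} {reads2} {ref} {out}`), run with that tool's own
  defaults.
- One alignment pass per sample against the pooled candidate FASTA (rather
  than per-candidate re-alignment): cheaper, and best-hit placement across
  candidates is better-defined.
- All randomness flows through seeded `numpy` generators; identical seeds
  give byte-identical worlds, communities, reads and reports.
- Known limitations: no indel simulation; no BAM/CRAM beyond what pysam
  reads; no novel-BGC discovery (the method only predicts characterized
  clusters); abundance of a confirmed BGC is not quantified; taxid-based
  species matching is not implemented (name-based normalization only).
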