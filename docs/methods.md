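# Methods

## Model

A **superTranscript** is the intron-free exon-union sequence of a gene: the
merged union of all annotated exon intervals, ordered 5′→3′ in
transcriptional direction (ascending genomic order for `+` genes, descending
with reverse-complemented block sequences for `-` genes). It is built purely
from the annotation — a deterministic flattening of the GTF — not assembled
from read data. Each gene is flattened independently; overlapping genes are
not merged.

The **block map** is the ordered list of (genomic interval, superTranscript
interval) pairs produced by the flattening. Its invariants — exact tiling of
`[0, L)`, equal pairwise lengths, monotone genomic order per strand — make
genome↔superTranscript liftover exact and invertible on exonic positions.
Interval liftover returns the image of the exonic intersection; because a
contiguous genomic interval meets consecutive blocks, its image is a single
merged superTranscript interval.

A **fusion-superTranscript** for partners (g₅, g₃) is `ST(g₅) + ST(g₃)`.
Both genes are full length, so reads from unfused portions still align and
their expression remains visible. The **gene boundary** b = |ST(g₅)| is the
key annotation: a junction with start < b ≤ end is fusion-supporting.
Several caller rows on one gene pair (alternative fusion isoforms) collapse
to one reference sequence — the sequence is breakpoint-independent — with
every lifted breakpoint pair kept as metadata.

The reference also contains the superTranscripts of all *other* genes so
that reads from normal transcripts map competitively. Partner genes are
**excluded** from the normals: their sequence already exists inside the
fusion sequence, and keeping both copies would make every partner-gene read
multi-mapping, hiding unique coverage. This was a genuinely open design
point; exclusion is the only choice under which unique-mapping coverage of
the partners is observable.

## Breakpoint handling

Breakpoints are assigned to genes from the annotation, never from
caller-reported symbols (naming conventions vary too much across callers):
first by exon containment, then by gene-span containment, then by nearest
gene within a window (default 10 kb, configurable), with ties broken by
distance to the nearest exon and then symbol. Unassignable calls are skipped
and listed in the run manifest. Intronic breakpoints — absent from the
superTranscript by construction — are projected to the nearest exonic base
and flagged `projected` in the output metadata; this preserves the
visualization without inventing sequence. Same-gene events are built (they
resemble tandem duplications) with a warning.

## Filters and quantification

- **Flank filter.** A split read's gap is kept only if the aligned (M/=/X)
  bases between the gap and the neighboring gap or read end are ≥ 5 on
  *both* sides (the minimum side governs; deletions consume reference but do
  not count as anchor). Exactly 5 passes; the cutoff removes reads with
  *fewer than* 5 flanking bases. Default `min_flank = 5`, CLI-configurable.
- **Support threshold.** Junctions are keyed by exact (reference, start,
  end) — no fuzzy merging, since splice-aware aligners report exact gap
  edges and nearby isoform breakpoints must stay distinct. Junctions with
  support < 3 reads are excluded from figures but written to the raw table.
  Default `min_support = 3`, CLI-configurable.
- **Counting rules.** Only primary, non-supplementary, mapped alignments
  contribute to events, coverage, and the library size, so multimappers are
  counted once. The library size for RPM is the total primary mapped read
  count of the whole alignment file; `RPM = depth × 10⁶ / library_size`.
  Only split-read evidence is counted; read-pair (non-split spanning
  fragment) evidence is out of scope.
- **Motifs.** The donor/acceptor motif is read from the reference sequence
  at the gap edges (`seq[start:start+2] / seq[end-2:end]`); canonical
  splicing shows `GT/AG`.

## Simulator

The generator emulates the minimal situation the method operates on: a
single toy chromosome (~kb scale) with uniform-random sequence, multi-exon
genes on alternating strands, GT/AG motifs planted at intron edges (CT/AC on
the sense strand of `-` genes), one domain per gene spanning an exon
junction, two isoforms per gene (full-length and middle-exon-skipped), and a
fusion joining the first exon of gene 1 to the transcriptional start of
gene 2. Alignments are written directly as SAM with constructed gapped
CIGARs — left flank lengths drawn from a caller-specified profile, right
flank fixed at 30 bp — plus ungapped background reads, so every junction's
post-filter support is known in closed form and no external aligner is
needed (a FASTQ dump exists for optional integration with a real aligner).

What it does *not* emulate: sequencing error, base-quality structure,
realistic expression levels, multi-mapping ambiguity, or aligner behavior.
Passing tests therefore demonstrate the correctness of the reference
construction, liftover, filtering, counting, normalization and rendering
logic — not the end-to-end sensitivity of a real aligner on patient data.

## Numerical and rendering choices

Internal coordinates are uniformly 0-based half-open; GTF is converted on
read/write, BED used natively; JAFFA/STAR-Fusion positions (1-based) are
converted on parse while the package's own generic TSV dialect is 0-based.
Chromosome-name `chr`-prefix mismatches are reconciled against the genome
FASTA. Reference names are sanitized to SAM-safe characters with numeric
suffixes on collision. Figures use a fixed colorblind-safe (Okabe–Ito)
palette, fixed fonts and DPI, and PDF output omits the creation timestamp,
so rendering is byte-deterministic for a fixed bundle and spec; vector PDF
is the default with PNG as an alternative. Multi-sample overlays drop the
sashimi track and stack one coverage panel per sample over the shared
annotation tracks, with breakpoint lines colored by isoform group.

## Problem sizes

Tests and the acceptance script run on toy loci of 2–4 genes with 100 bp
exons and 200 bp introns, tens of reads per alignment file, 200+ random
gene layouts for the liftover oracle, and 20 simulation seeds for
end-to-end truth recovery; the whole suite completes in a few seconds.

## Limitations

- Fusion *calling* is out of scope; the package visualizes and quantifies
  events reported by an upstream caller, and two-partner events only.
- Read-pair spanning evidence is not counted, so support totals are
  split-read-only.
- No aligner is bundled or wrapped: align your reads to the built reference
  FASTA with any splice-aware aligner (relaxed stringency recommended, since
  the fusion is known *a priori*) and pass the SAM/BAM to `analyze`.
- Domain inputs are positional BED intervals; strand is ignored at liftover
  (domains are drawn as positions, not translated features), and no protein
  database is queried.
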