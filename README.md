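# fusionlens

Visualization and quantification of fusion genes detected in RNA-seq data,
built on superTranscript fusion references.

Fusion callers report candidate gene fusions with genomic breakpoints, but
inspecting the supporting reads against the genome is awkward: RNA-seq
coverage is sparse across introns, and a split-screen genome-browser view
loses the transcript context. `fusionlens` takes the breakpoints a caller
reports and builds, for each event, a *fusion-superTranscript*: the
intron-free exon-union sequence of the 5′ partner gene concatenated with
that of the 3′ partner, both oriented 5′→3′ in transcriptional direction.
Realigned against this compact reference, reads that span the fusion appear
as splice junctions crossing the *gene boundary* (the coordinate where the
3′ partner begins), and everything about the event — coverage over both full
genes, transcript isoforms, protein domains, alternative fusion breakpoints —
is visible on one linear axis. The reference also carries the
superTranscripts of all non-fused genes so reads from normal transcripts map
competitively instead of piling onto the fusion sequences.

It is intended for bioinformaticians and cancer genomics analysts who have
fusion calls (JAFFA, STAR-Fusion, or a generic table) and want to see and
quantify the evidence.

## Method

For a gene *g* with annotated exon set *E(g)*, the superTranscript is the
sequence of the merged union of *E(g)*, reverse-complemented for `-` genes; a
block map records the bijection between exonic genomic positions and
superTranscript offsets, giving exact liftover of transcripts, domains and
breakpoints. For a fusion with partners (*g₅*, *g₃*) the reference sequence
is `ST(g₅) + ST(g₃)` with boundary *b* = |ST(*g₅*)|.

Split-read support is computed from alignments against this reference:

- every primary mapped alignment whose CIGAR contains a reference skip (`N`)
  is a split read; a gap's *flanks* are the aligned bases on each side of it;
- reads with fewer than **5 bp** of flanking sequence on either side of any
  gap are filtered out (short anchors are the signature of misplaced split
  alignments);
- surviving gaps are grouped by exact coordinates into junctions; a junction
  with `start < b ≤ end` crosses the gene boundary and is fusion evidence,
  annotated with its donor/acceptor motif (e.g. `GT/AG`);
- junctions with fewer than **3** supporting reads are dropped from figures
  (kept in the raw tables);
- coverage is the per-base depth of aligned bases, normalized to reads per
  million: `RPM = depth × 10⁶ / library_size`.

## Worked example

Everything below runs on synthetic data generated by the built-in simulator
(no aligner or download needed):

```
fusionlens simulate --out demo --seed 3
fusionlens analyze --alignments demo/alignments.sam \
    --reference-dir demo/reference --out demo/analysis
fusionlens plot --reference-dir demo/reference \
    --analysis-dir demo/analysis --out demo/figures
```

`analyze` prints:

```
GENE1_GENE2: 5 spanning read(s) across the gene boundary
```

meaning five retained split reads support splicing from the 5′ partner into
the 3′ partner across the gene boundary of the `GENE1_GENE2` fusion
sequence. `demo/analysis/GENE1_GENE2/junctions.tsv` holds the junction
table:

```
refname      start  end  support  crosses_boundary  motif
GENE1_GENE2  100    300  5        True              AG/GC
```

one junction from superTranscript position 100 (the planted breakpoint after
the first exon of GENE1) to 300 (the boundary, i.e. the start of GENE2),
supported by 5 reads. `demo/figures/GENE1_GENE2.pdf` is the six-track
figure: scale axis, coverage, gene boundaries, protein domains, transcripts,
and a sashimi plot whose arcs are labeled with support counts; vertical
lines mark the expected breakpoints. Passing several `--analysis-dir`
options (one per sample) produces a multi-sample overlay with one coverage
panel per sample above the shared annotation tracks.

`fusionlens build` constructs the reference from your own inputs (`--fusions`
with `--dialect jaffa|star_fusion|generic`, `--gtf`, `--genome`, optional
`--domains` BED); its FASTA/BED/bedGraph outputs load directly in IGV.
`fusionlens run` chains build → analyze → plot. Thresholds are flags:
`--min-flank` (default 5) and `--min-support` (default 3).

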