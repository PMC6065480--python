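"""Synthetic fixtures: toy genome, annotation, domains, fusion calls, and
alignments with known truth.

The generator builds a small single-chromosome locus with multi-exon genes on
alternating strands (GT/AG splice motifs planted at intron edges), declares a
fusion between the first two genes at exon boundaries, and emits gapped SAM
alignments directly against the fusion reference so every planted junction's
post-filter support is known exactly.  Writing alignments rather than FASTQ
keeps the core test surface deterministic and aligner-free; a FASTQ mode is
available for integration tests with a real splice-aware aligner.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pysam

from fusionlens.annotation_io import (
    Breakpoint,
    DomainFeature,
    FusionCall,
    GeneModel,
    TranscriptModel,
    write_gtf,
)
from fusionlens.fusion_reference import FusionReference

CHROM = "chrT"
BASES = np.array(list("ACGT"))


@dataclass
class JunctionTruth:
    """Planted junction with its reads' flanks and expected filter outcome."""

    refname: str
    start: int
    end: int
    crosses_boundary: bool
    flanks: list[tuple[int, int]] = field(default_factory=list)
    min_flank: int = 5
    min_support: int = 3

    @property
    def n_reads(self) -> int:
        return len(self.flanks)

    @property
    def expected_support(self) -> int:
        """Reads surviving the flank filter (min side >= min_flank)."""
        return sum(1 for lf, rf in self.flanks if min(lf, rf) >= self.min_flank)

    @property
    def in_figure(self) -> bool:
        return self.expected_support >= self.min_support


@dataclass
class SimTruth:
    """Everything the simulator planted, for exact downstream verification."""

    chrom: str
    genome: str
    genes: list[GeneModel]
    domains: list[DomainFeature]
    calls: list[FusionCall]
    seed: int
    junctions: list[JunctionTruth] = field(default_factory=list)
    n_background: int = 0

    def to_json(self, path: str | Path) -> None:
        payload = {
            "chrom": self.chrom,
            "seed": self.seed,
            "n_background": self.n_background,
            "genes": [
                {
                    "gene_id": g.gene_id,
                    "symbol": g.symbol,
                    "strand": g.strand,
                    "transcripts": {
                        t.transcript_id: [list(iv) for iv in t.exons] for t in g.transcripts
                    },
                }
                for g in self.genes
            ],
            "junctions": [
                {
                    "refname": j.refname,
                    "start": j.start,
                    "end": j.end,
                    "crosses_boundary": j.crosses_boundary,
                    "flanks": [list(f) for f in j.flanks],
                    "n_reads": j.n_reads,
                    "expected_support": j.expected_support,
                    "in_figure": j.in_figure,
                    "min_flank": j.min_flank,
                    "min_support": j.min_support,
                }
                for j in self.junctions
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def _plant(seq: list[str], pos: int, motif: str) -> None:
    for i, base in enumerate(motif):
        seq[pos + i] = base


def make_toy_locus(
    n_genes: int = 2,
    exons_per_gene: int = 3,
    exon_len: int = 100,
    intron_len: int = 200,
    seed: int = 0,
    gene_gap: int = 500,
    margin: int = 100,
) -> SimTruth:
    """Generate a toy single-chromosome locus with known structure.

    Genes are laid out left to right with alternating strands ("+", "-",
    ...).  Each gene gets a full-length transcript and, when it has at least
    three exons, a second isoform skipping the middle exon.  GT/AG splice
    motifs are planted at intron edges.  One protein domain per gene spans an
    exon-exon junction (so its liftover splits).  A fusion call joins the 5'
    end of gene 1 to gene 2 at exon boundaries.  Deterministic per seed:
    different seeds change the sequence but not the structure.
    """
    if min(n_genes, exons_per_gene, exon_len, intron_len) < 1:
        raise ValueError("all sizes must be >= 1")
    rng = np.random.default_rng(seed)
    gene_span = exons_per_gene * exon_len + (exons_per_gene - 1) * intron_len
    total = margin + n_genes * gene_span + (n_genes - 1) * gene_gap + margin
    seq = list(rng.choice(BASES, size=total))

    genes: list[GeneModel] = []
    domains: list[DomainFeature] = []
    for i in range(n_genes):
        gstart = margin + i * (gene_span + gene_gap)
        exons = [
            (gstart + k * (exon_len + intron_len), gstart + k * (exon_len + intron_len) + exon_len)
            for k in range(exons_per_gene)
        ]
        strand = "+" if i % 2 == 0 else "-"
        for (s1, e1), (s2, _e2) in zip(exons, exons[1:]):
            if strand == "+":
                _plant(seq, e1, "GT")
                _plant(seq, s2 - 2, "AG")
            else:  # motifs on the sense strand of a "-" gene
                _plant(seq, e1, "CT")
                _plant(seq, s2 - 2, "AC")
        txs = [TranscriptModel(transcript_id=f"TX{i + 1}.1", exons=list(exons))]
        if exons_per_gene >= 3:
            skip = exons_per_gene // 2
            txs.append(
                TranscriptModel(
                    transcript_id=f"TX{i + 1}.2",
                    exons=[iv for k, iv in enumerate(exons) if k != skip],
                )
            )
        genes.append(
            GeneModel(
                gene_id=f"GENE{i + 1}",
                symbol=f"GENE{i + 1}",
                chrom=CHROM,
                strand=strand,
                transcripts=txs,
            )
        )
        if exons_per_gene >= 2 and exon_len >= 30:
            domains.append(
                DomainFeature(
                    name=f"DOM{i + 1}",
                    chrom=CHROM,
                    start=exons[0][1] - 30,
                    end=exons[1][0] + 30,
                    strand=strand,
                )
            )

    calls: list[FusionCall] = []
    if n_genes >= 2:
        g5, g3 = genes[0], genes[1]
        # donor: last transcriptional base of g5's first exon; acceptor: g3's
        # first transcriptional base
        e5 = g5.exons[0] if g5.strand == "+" else g5.exons[-1]
        donor_pos = e5[1] - 1 if g5.strand == "+" else e5[0]
        acceptor_pos = g3.exons[0][0] if g3.strand == "+" else g3.exons[-1][1] - 1
        calls.append(
            FusionCall(
                break5=Breakpoint(CHROM, donor_pos, g5.strand),
                break3=Breakpoint(CHROM, acceptor_pos, g3.strand),
                caller="simulated",
                sample="SIM1",
            )
        )

    return SimTruth(
        chrom=CHROM,
        genome="".join(seq),
        genes=genes,
        domains=domains,
        calls=calls,
        seed=seed,
    )


def write_locus(truth: SimTruth, outdir: str | Path) -> dict[str, Path]:
    """Write the locus as plain-text files: genome FASTA, GTF, domain BED,
    generic fusion TSV, and truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": outdir / "genome.fa",
        "gtf": outdir / "annotation.gtf",
        "domains": outdir / "domains.bed",
        "fusions": outdir / "fusions.tsv",
        "truth": outdir / "truth.json",
    }
    with open(paths["genome"], "w") as fh:
        fh.write(f">{truth.chrom}\n")
        for i in range(0, len(truth.genome), 60):
            fh.write(truth.genome[i : i + 60] + "\n")
    write_gtf(truth.genes, paths["gtf"])
    with open(paths["domains"], "w") as fh:
        for d in truth.domains:
            fh.write(f"{d.chrom}\t{d.start}\t{d.end}\t{d.name}\t0\t{d.strand}\n")
    with open(paths["fusions"], "w") as fh:
        fh.write("chrom1\tpos1\tstrand1\tchrom2\tpos2\tstrand2\tsample\n")
        for c in truth.calls:
            fh.write(
                f"{c.break5.chrom}\t{c.break5.pos}\t{c.break5.strand or '+'}\t"
                f"{c.break3.chrom}\t{c.break3.pos}\t{c.break3.strand or '+'}\t{c.sample}\n"
            )
    truth.to_json(paths["truth"])
    return paths


DEFAULT_RIGHT_FLANK = 30


def simulate_fusion_alignments(
    truth: SimTruth,
    reference: FusionReference,
    out_sam: str | Path,
    reads_per_junction: Optional[Sequence[int]] = None,
    flank_profile: Optional[Sequence[int]] = None,
    seed: int = 0,
    min_flank: int = 5,
    min_support: int = 3,
    n_background: int = 30,
    background_read_len: int = 50,
    sample: str = "SIM1",
) -> tuple[Path, SimTruth]:
    """Emit primary gapped alignments realizing each expected fusion junction.

    For every fusion sequence in `reference` and every expected breakpoint
    pair, a junction (gap) from donor+1 to acceptor is planted.
    `reads_per_junction[j]` reads are generated for junction j; read k's
    left flank (aligned bases before the gap) is `flank_profile[k % len]`
    (default 20) and its right flank is fixed at 30 bp, so the flank filter
    acts on the left flank.  Ungapped background reads are scattered over all
    reference sequences.  The returned truth records each junction's flanks
    and the support expected after filtering at `min_flank`/`min_support`.
    """
    out_sam = Path(out_sam)
    rng = np.random.default_rng(seed)
    sequences = reference.sequences()
    names = list(sequences)
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": name, "LN": len(sequences[name])} for name in names],
    }
    truth.junctions = []
    truth.n_background = n_background

    planted: list[tuple[str, int, int]] = []
    for fusion in reference.fusions:
        for ebp in fusion.breakpoints:
            planted.append((fusion.name, ebp.donor + 1, ebp.acceptor))

    if reads_per_junction is None:
        reads_per_junction = [5] * len(planted)
    if len(reads_per_junction) != len(planted):
        raise ValueError(
            f"reads_per_junction has {len(reads_per_junction)} entries "
            f"for {len(planted)} planted junctions"
        )

    with pysam.AlignmentFile(str(out_sam), "w", header=header) as sam:
        read_no = 0
        for j, ((refname, gstart, gend), n_reads) in enumerate(zip(planted, reads_per_junction)):
            refseq = sequences[refname]
            boundary = reference.boundary(refname)
            jt = JunctionTruth(
                refname=refname,
                start=gstart,
                end=gend,
                crosses_boundary=boundary is not None and gstart < boundary <= gend,
                min_flank=min_flank,
                min_support=min_support,
            )
            for k in range(n_reads):
                left = flank_profile[k % len(flank_profile)] if flank_profile else 20
                right = DEFAULT_RIGHT_FLANK
                if left < 1 or left > gstart:
                    raise ValueError(f"left flank {left} not realizable at gap start {gstart}")
                if gend + right > len(refseq):
                    right = len(refseq) - gend
                a = pysam.AlignedSegment()
                a.query_name = f"split_{j}_{k}_{read_no}"
                a.reference_id = names.index(refname)
                a.reference_start = gstart - left
                a.flag = 0
                a.mapping_quality = 60
                a.cigarstring = f"{left}M{gend - gstart}N{right}M"
                a.query_sequence = refseq[gstart - left : gstart] + refseq[gend : gend + right]
                a.query_qualities = pysam.qualitystring_to_array("I" * (left + right))
                sam.write(a)
                jt.flanks.append((left, right))
                read_no += 1
            truth.junctions.append(jt)

        for k in range(n_background):
            refname = names[int(rng.integers(len(names)))]
            refseq = sequences[refname]
            rlen = min(background_read_len, len(refseq))
            pos = int(rng.integers(0, len(refseq) - rlen + 1))
            a = pysam.AlignedSegment()
            a.query_name = f"bg_{k}"
            a.reference_id = names.index(refname)
            a.reference_start = pos
            a.flag = 0
            a.mapping_quality = 60
            a.cigarstring = f"{rlen}M"
            a.query_sequence = refseq[pos : pos + rlen]
            a.query_qualities = pysam.qualitystring_to_array("I" * rlen)
            sam.write(a)
    return out_sam, truth


def write_reads_fastq(sam_path: str | Path, fastq_path: str | Path) -> Path:
    """Dump simulated read sequences to FASTQ (for optional runs through a
    real splice-aware aligner)."""
    fastq_path = Path(fastq_path)
    with pysam.AlignmentFile(str(sam_path)) as sam, open(fastq_path, "w") as out:
        for aln in sam.fetch(until_eof=True):
            out.write(f"@{aln.query_name}\n{aln.query_sequence}\n+\n{'I' * len(aln.query_sequence)}\n")
    return fastq_path
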