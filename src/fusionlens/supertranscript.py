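"""superTranscript construction and genome <-> superTranscript liftover.

A superTranscript is the intron-free exon-union sequence of a gene, oriented
5'->3' in transcriptional direction: overlapping exons from all transcripts
are merged into maximal genomic blocks, the blocks are ordered in ascending
genomic order for "+" genes and descending for "-" genes, and the sequence of
a "-" block is reverse-complemented.  The :class:`BlockMap` records the
correspondence between genomic and superTranscript intervals and supports
exact position and interval liftover in both directions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from intervaltree import IntervalTree

from fusionlens.annotation_io import Breakpoint, DomainFeature, GeneModel, Genome

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of genomic intervals: sorted, maximal, non-touching blocks.

    Adjacent (touching) intervals are merged; a superTranscript block is a
    maximal run of exonic bases.
    """
    merged: list[tuple[int, int]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


@dataclass
class BlockMap:
    """Ordered (genomic interval, superTranscript interval) block pairs.

    Blocks tile [0, total_length) exactly.  For strand "+" genomic intervals
    ascend with superTranscript position; for "-" they descend, and within a
    "-" block position increases toward lower genomic coordinates.
    """

    blocks: list[tuple[tuple[int, int], tuple[int, int]]]
    strand: str
    chrom: str = ""

    @property
    def total_length(self) -> int:
        return self.blocks[-1][1][1] if self.blocks else 0

    @classmethod
    def from_exonic_union(
        cls, genomic_blocks: Sequence[tuple[int, int]], strand: str, chrom: str = ""
    ) -> "BlockMap":
        ordered = sorted(genomic_blocks, reverse=(strand == "-"))
        blocks = []
        offset = 0
        for gstart, gend in ordered:
            length = gend - gstart
            blocks.append(((gstart, gend), (offset, offset + length)))
            offset += length
        return cls(blocks=blocks, strand=strand, chrom=chrom)

    def genome_to_st(self, gpos: int) -> Optional[int]:
        """superTranscript offset of a genomic position, or None if not exonic."""
        for (gstart, gend), (sstart, _send) in self.blocks:
            if gstart <= gpos < gend:
                if self.strand == "+":
                    return sstart + (gpos - gstart)
                return sstart + (gend - 1 - gpos)
        return None

    def st_to_genome(self, spos: int) -> int:
        """Genomic position of a superTranscript offset (inverse of genome_to_st)."""
        if not (0 <= spos < self.total_length):
            raise IndexError(f"superTranscript position {spos} out of [0,{self.total_length})")
        for (gstart, gend), (sstart, send) in self.blocks:
            if sstart <= spos < send:
                if self.strand == "+":
                    return gstart + (spos - sstart)
                return gend - 1 - (spos - sstart)
        raise AssertionError("block tiling violated")  # unreachable by invariant

    def lift_interval(self, gstart: int, gend: int) -> list[tuple[int, int]]:
        """Image of a genomic interval in superTranscript space.

        Returns maximal superTranscript intervals sorted by start; intervals
        adjacent in superTranscript space are merged.  Empty when the input
        is fully intronic/intergenic.
        """
        pieces: list[tuple[int, int]] = []
        for (bgs, bge), (sstart, _send) in self.blocks:
            istart, iend = max(gstart, bgs), min(gend, bge)
            if istart >= iend:
                continue
            if self.strand == "+":
                pieces.append((sstart + (istart - bgs), sstart + (iend - bgs)))
            else:
                pieces.append((sstart + (bge - iend), sstart + (bge - istart)))
        pieces.sort()
        merged: list[tuple[int, int]] = []
        for s, e in pieces:
            if merged and s == merged[-1][1]:
                merged[-1] = (merged[-1][0], e)
            else:
                merged.append((s, e))
        return merged

    def project_to_exonic(self, gpos: int) -> tuple[int, bool]:
        """Lift a genomic position, projecting intronic/flanking positions to
        the nearest exonic base.  Returns (superTranscript offset, projected?)."""
        spos = self.genome_to_st(gpos)
        if spos is not None:
            return spos, False
        best = None
        for (gstart, gend), _ in self.blocks:
            for candidate in (gstart, gend - 1):
                dist = abs(gpos - candidate)
                if best is None or dist < best[0]:
                    best = (dist, candidate)
        assert best is not None
        result = self.genome_to_st(best[1])
        assert result is not None
        return result, True


@dataclass
class SuperTranscript:
    """A gene's flattened exon-union sequence plus liftover machinery."""

    gene: GeneModel
    sequence: str
    block_map: BlockMap
    lifted_transcripts: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    lifted_domains: list[tuple[str, int, int]] = field(default_factory=list)

    @property
    def total_length(self) -> int:
        return self.block_map.total_length

    @property
    def symbol(self) -> str:
        return self.gene.symbol


def build_supertranscript(
    gene: GeneModel,
    genome: Genome,
    domains: Sequence[DomainFeature] = (),
) -> SuperTranscript:
    """Flatten a gene into its superTranscript.

    The union of all annotated exons is computed (overlaps merged), ordered
    in transcriptional direction, and the sequence assembled from the genome
    (reverse-complemented for "-" genes).  Every transcript's exons and every
    overlapping domain are lifted into superTranscript coordinates; domain
    strand is ignored (domains are positional annotations).
    """
    exons = gene.exons
    if not exons:
        raise ValueError(f"gene {gene.gene_id} has no exons")
    chrom_len = genome.length(gene.chrom)
    if exons[-1][1] > chrom_len or exons[0][0] < 0:
        raise IndexError(
            f"gene {gene.gene_id}: exon outside chromosome {gene.chrom} (length {chrom_len})"
        )
    union = merge_intervals(exons)
    bm = BlockMap.from_exonic_union(union, gene.strand, gene.chrom)
    parts = []
    for (gstart, gend), _ in bm.blocks:
        seq = genome.fetch(gene.chrom, gstart, gend)
        parts.append(revcomp(seq) if gene.strand == "-" else seq)
    sequence = "".join(parts)

    lifted_tx: dict[str, list[tuple[int, int]]] = {}
    for tx in gene.transcripts:
        lifted: list[tuple[int, int]] = []
        for gstart, gend in tx.exons:
            ivs = bm.lift_interval(gstart, gend)
            assert len(ivs) == 1, "exon must lie within one block by construction"
            lifted.append(ivs[0])
        lifted_tx[tx.transcript_id] = sorted(lifted)

    lifted_domains: list[tuple[str, int, int]] = []
    for dom in domains:
        if dom.chrom != gene.chrom:
            continue
        for s, e in bm.lift_interval(dom.start, dom.end):
            lifted_domains.append((dom.name, s, e))

    return SuperTranscript(
        gene=gene,
        sequence=sequence,
        block_map=bm,
        lifted_transcripts=lifted_tx,
        lifted_domains=sorted(lifted_domains, key=lambda d: (d[1], d[2], d[0])),
    )


# ---------------------------------------------------------------------------
# breakpoint -> gene assignment


class UnassignableBreakpointError(LookupError):
    """No gene near the breakpoint within the assignment window."""

    def __init__(self, bp: Breakpoint, window: int):
        super().__init__(f"no gene within {window} bp of {bp.chrom}:{bp.pos}")
        self.breakpoint = bp


def _dist_to_interval(pos: int, start: int, end: int) -> int:
    if pos < start:
        return start - pos
    if pos >= end:
        return pos - end + 1
    return 0


class GeneIndex:
    """Interval index over gene spans and exons for breakpoint assignment."""

    def __init__(self, genes: Iterable[GeneModel], window: int = 10_000):
        self.window = window
        self.genes = list(genes)
        self._span_trees: dict[str, IntervalTree] = {}
        self._exon_trees: dict[str, IntervalTree] = {}
        for gene in self.genes:
            span = gene.span
            self._span_trees.setdefault(gene.chrom, IntervalTree()).addi(
                max(0, span[0] - window), span[1] + window, gene
            )
            for start, end in merge_intervals(gene.exons):
                self._exon_trees.setdefault(gene.chrom, IntervalTree()).addi(start, end, gene)

    def assign(self, bp: Breakpoint) -> GeneModel:
        """Deterministically pick the gene a breakpoint belongs to.

        Priority: (1) genes with an exon containing the position; (2) genes
        whose span contains it (intronic); (3) the nearest gene within the
        window.  Ties break by distance to the nearest exon, then by symbol.
        """
        exon_hits = {
            iv.data.gene_id: iv.data
            for iv in self._exon_trees.get(bp.chrom, IntervalTree())[bp.pos]
        }
        candidates = list(exon_hits.values())
        if not candidates:
            span_hits = {
                iv.data.gene_id: iv.data
                for iv in self._span_trees.get(bp.chrom, IntervalTree())[bp.pos]
            }
            in_span = [
                g for g in span_hits.values() if g.span[0] <= bp.pos < g.span[1]
            ]
            candidates = in_span or [
                g
                for g in span_hits.values()
                if _dist_to_interval(bp.pos, *g.span) <= self.window
            ]
        if not candidates:
            raise UnassignableBreakpointError(bp, self.window)

        def sort_key(gene: GeneModel):
            span_dist = _dist_to_interval(bp.pos, *gene.span)
            exon_dist = min(_dist_to_interval(bp.pos, s, e) for s, e in gene.exons)
            return (span_dist, exon_dist, gene.symbol)

        return min(candidates, key=sort_key)


def assign_gene(
    bp: Breakpoint, genes: Iterable[GeneModel] | GeneIndex, window: int = 10_000
) -> GeneModel:
    """Assign a breakpoint to a gene (see :meth:`GeneIndex.assign`)."""
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes, window=window)
    return index.assign(bp)
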