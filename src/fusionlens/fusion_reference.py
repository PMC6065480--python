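"""Assembly of the sample-specific fusion reference.

For each caller-reported event the two partner genes' superTranscripts are
concatenated, 5' partner first, into a fusion-superTranscript whose *gene
boundary* is the offset where the 3' gene begins.  Reads spanning the fusion
then align as splice junctions across that boundary.  The full reference also
carries the superTranscripts of all non-fused genes so that reads from normal
transcripts map competitively and are not spuriously attracted to the fusion
sequences; genes already embedded in a fusion-superTranscript are excluded
from the normals (keeping both copies would make every partner-gene read a
multi-mapper and hide unique coverage).
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from fusionlens.annotation_io import DomainFeature, FusionCall, GeneModel, Genome
from fusionlens.supertranscript import (
    GeneIndex,
    SuperTranscript,
    UnassignableBreakpointError,
    build_supertranscript,
)

logger = logging.getLogger(__name__)

FASTA_WIDTH = 60


@dataclass(frozen=True)
class ExpectedBreakpoint:
    """A caller breakpoint pair lifted into fusion-superTranscript coordinates.

    ``donor`` is the last expected 5'-gene base; ``acceptor`` the first
    expected 3'-gene base (offset by the boundary).  Intronic caller
    positions are projected to the nearest exonic base and flagged.
    """

    donor: int
    acceptor: int
    donor_projected: bool = False
    acceptor_projected: bool = False
    sample: str = ""
    caller_support: Optional[int] = None


@dataclass
class FusionSuperTranscript:
    """Concatenation of two superTranscripts with boundary and breakpoints."""

    name: str
    st5: SuperTranscript
    st3: SuperTranscript
    breakpoints: list[ExpectedBreakpoint] = field(default_factory=list)

    @property
    def boundary(self) -> int:
        return self.st5.total_length

    @property
    def sequence(self) -> str:
        return self.st5.sequence + self.st3.sequence

    @property
    def length(self) -> int:
        return self.st5.total_length + self.st3.total_length

    @property
    def gene_pair(self) -> tuple[str, str]:
        return (self.st5.gene.gene_id, self.st3.gene.gene_id)


@dataclass
class FusionReference:
    """The complete reference: fusion-superTranscripts plus normal genes."""

    fusions: list[FusionSuperTranscript] = field(default_factory=list)
    normals: list[SuperTranscript] = field(default_factory=list)
    skipped: list[dict] = field(default_factory=list)

    def sequences(self) -> dict[str, str]:
        out = {f.name: f.sequence for f in self.fusions}
        for st in self.normals:
            out[sanitize_name(st.symbol)] = st.sequence
        return out

    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences().items()}

    def boundary(self, refname: str) -> Optional[int]:
        for f in self.fusions:
            if f.name == refname:
                return f.boundary
        return None

    def get_fusion(self, refname: str) -> FusionSuperTranscript:
        for f in self.fusions:
            if f.name == refname:
                return f
        raise KeyError(f"no fusion sequence named {refname!r}")


def sanitize_name(name: str) -> str:
    """Make a reference name SAM/FASTA-safe (no whitespace or colons)."""
    return re.sub(r"[^A-Za-z0-9._-]", "_", name)


def make_fusion_st(
    call: FusionCall,
    genes: GeneIndex | Iterable[GeneModel],
    genome: Genome,
    domains: Sequence[DomainFeature] = (),
) -> FusionSuperTranscript:
    """Build the fusion-superTranscript for one caller event.

    Both partners are included full-length, 5' partner first, each oriented
    in transcriptional direction.  The caller breakpoints are lifted into
    fusion coordinates (intronic positions projected to the nearest exonic
    base and flagged).  A same-gene event is still built, with a warning.
    """
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    gene5 = index.assign(call.break5)
    gene3 = index.assign(call.break3)
    if gene5.gene_id == gene3.gene_id:
        logger.warning(
            "both breakpoints assign to %s; building a same-gene (tandem-duplication-like) event",
            gene5.symbol,
        )
    st5 = build_supertranscript(gene5, genome, domains)
    st3 = build_supertranscript(gene3, genome, domains)
    donor, donor_proj = st5.block_map.project_to_exonic(call.break5.pos)
    acceptor3, acc_proj = st3.block_map.project_to_exonic(call.break3.pos)
    name = f"{sanitize_name(st5.symbol)}_{sanitize_name(st3.symbol)}"
    fusion = FusionSuperTranscript(name=name, st5=st5, st3=st3)
    fusion.breakpoints.append(
        ExpectedBreakpoint(
            donor=donor,
            acceptor=st5.total_length + acceptor3,
            donor_projected=donor_proj,
            acceptor_projected=acc_proj,
            sample=call.sample,
            caller_support=call.caller_support,
        )
    )
    return fusion


def build_reference(
    calls: Sequence[FusionCall],
    genes: Mapping[str, GeneModel] | Iterable[GeneModel],
    genome: Genome,
    domains: Sequence[DomainFeature] = (),
    window: int = 10_000,
) -> FusionReference:
    """Assemble the full sample-specific reference from all calls.

    Distinct calls on the same gene pair collapse to one fusion sequence
    (the sequence is breakpoint-independent since both genes are full
    length); every expected breakpoint pair is kept as metadata.  Calls with
    an unassignable breakpoint are skipped and logged.  Every annotated gene
    not embedded in a fusion contributes a normal superTranscript.
    """
    gene_list = list(genes.values()) if isinstance(genes, Mapping) else list(genes)
    index = GeneIndex(gene_list, window=window)
    ref = FusionReference()
    by_pair: dict[tuple[str, str], FusionSuperTranscript] = {}
    if not calls:
        logger.warning("no fusion calls: building a normals-only reference")
    for call in calls:
        try:
            fusion = make_fusion_st(call, index, genome, domains)
        except UnassignableBreakpointError as exc:
            logger.warning("skipping call %s: %s", call, exc)
            ref.skipped.append({"call": repr(call), "reason": str(exc)})
            continue
        existing = by_pair.get(fusion.gene_pair)
        if existing is None:
            by_pair[fusion.gene_pair] = fusion
        else:
            existing.breakpoints.extend(fusion.breakpoints)

    # disambiguate name collisions (e.g. two gene pairs sharing symbols)
    name_counts: dict[str, int] = {}
    for fusion in by_pair.values():
        n = name_counts.get(fusion.name, 0)
        name_counts[fusion.name] = n + 1
        if n:
            fusion.name = f"{fusion.name}_{n + 1}"
        ref.fusions.append(fusion)

    fused_ids = {gid for f in ref.fusions for gid in f.gene_pair}
    for gene in gene_list:
        if gene.gene_id in fused_ids:
            continue
        ref.normals.append(build_supertranscript(gene, genome, domains))
    return ref


# ---------------------------------------------------------------------------
# writers


def write_reference_fasta(ref: FusionReference, path: str | Path) -> None:
    """Write the reference FASTA (60-column wrapped, SAM-safe names)."""
    sequences = ref.sequences()
    if not sequences:
        raise ValueError("empty reference: nothing to write")
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), FASTA_WIDTH):
                fh.write(seq[i : i + FASTA_WIDTH] + "\n")


def _bed12_row(
    refname: str,
    intervals: list[tuple[int, int]],
    name: str,
    offset: int = 0,
) -> str:
    ivs = sorted((s + offset, e + offset) for s, e in intervals)
    start, end = ivs[0][0], ivs[-1][1]
    sizes = ",".join(str(e - s) for s, e in ivs)
    starts = ",".join(str(s - start) for s, _ in ivs)
    return "\t".join(
        [
            refname,
            str(start),
            str(end),
            name,
            "0",
            "+",
            str(start),
            str(end),
            "0",
            str(len(ivs)),
            sizes,
            starts,
        ]
    )


def write_annotation_tracks(ref: FusionReference, outdir: str | Path) -> dict[str, Path]:
    """Write IGV-loadable annotation tracks in reference coordinates.

    Emits gene boundaries (BED4), transcripts (BED12 with exon blocks, the
    3'-partner rows offset by the gene boundary), domains (BED4, split
    features share their name), and expected breakpoints (1 bp BED rows).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "gene_boundaries": outdir / "gene_boundaries.bed",
        "transcripts": outdir / "transcripts.bed12",
        "domains": outdir / "domains.bed",
        "breakpoints": outdir / "breakpoints.bed",
    }
    with open(paths["gene_boundaries"], "w") as gb, open(
        paths["transcripts"], "w"
    ) as tx, open(paths["domains"], "w") as dom, open(paths["breakpoints"], "w") as bp:
        for fusion in ref.fusions:
            b, L = fusion.boundary, fusion.length
            gb.write(f"{fusion.name}\t0\t{b}\t{sanitize_name(fusion.st5.symbol)}\n")
            gb.write(f"{fusion.name}\t{b}\t{L}\t{sanitize_name(fusion.st3.symbol)}\n")
            for st, offset in ((fusion.st5, 0), (fusion.st3, b)):
                for tx_id, exons in st.lifted_transcripts.items():
                    tx.write(_bed12_row(fusion.name, exons, tx_id, offset) + "\n")
                for dname, s, e in st.lifted_domains:
                    dom.write(f"{fusion.name}\t{s + offset}\t{e + offset}\t{dname}\n")
            for i, ebp in enumerate(fusion.breakpoints, start=1):
                bp.write(f"{fusion.name}\t{ebp.donor}\t{ebp.donor + 1}\tdonor_{i}\n")
                bp.write(f"{fusion.name}\t{ebp.acceptor}\t{ebp.acceptor + 1}\tacceptor_{i}\n")
        for st in ref.normals:
            name = sanitize_name(st.symbol)
            gb.write(f"{name}\t0\t{st.total_length}\t{name}\n")
            for tx_id, exons in st.lifted_transcripts.items():
                tx.write(_bed12_row(name, exons, tx_id) + "\n")
            for dname, s, e in st.lifted_domains:
                dom.write(f"{name}\t{s}\t{e}\t{dname}\n")
    return paths


def write_manifest(ref: FusionReference, path: str | Path) -> None:
    """Serialize reference metadata (names, boundaries, lengths, tracks,
    expected breakpoints) to JSON so downstream steps can run without the
    genome or annotation."""
    payload = {
        "fusions": [
            {
                "name": f.name,
                "boundary": f.boundary,
                "length": f.length,
                "gene5": {"id": f.st5.gene.gene_id, "symbol": f.st5.symbol},
                "gene3": {"id": f.st3.gene.gene_id, "symbol": f.st3.symbol},
                "breakpoints": [
                    {
                        "donor": b.donor,
                        "acceptor": b.acceptor,
                        "donor_projected": b.donor_projected,
                        "acceptor_projected": b.acceptor_projected,
                        "sample": b.sample,
                        "caller_support": b.caller_support,
                    }
                    for b in f.breakpoints
                ],
                "transcripts": {
                    **{
                        tid: [[s, e] for s, e in exons]
                        for tid, exons in f.st5.lifted_transcripts.items()
                    },
                    **{
                        tid: [[s + f.boundary, e + f.boundary] for s, e in exons]
                        for tid, exons in f.st3.lifted_transcripts.items()
                    },
                },
                "domains": [
                    [name, s, e]
                    for name, s, e in f.st5.lifted_domains
                ]
                + [[name, s + f.boundary, e + f.boundary] for name, s, e in f.st3.lifted_domains],
            }
            for f in ref.fusions
        ],
        "normals": [
            {"name": sanitize_name(st.symbol), "length": st.total_length}
            for st in ref.normals
        ],
        "skipped": ref.skipped,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
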