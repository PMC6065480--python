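"""Split-read extraction, junction quantification, and coverage.

Against a fusion-superTranscript reference, a read spanning the fusion
breakpoint aligns with a reference skip (CIGAR ``N``) across the gene
boundary, so fusion support is measured exactly like splice-junction support:

1. every primary mapped alignment with >= 1 ``N`` operation yields one
   split-read event, with per-gap anchor ("flank") lengths computed from the
   CIGAR walk;
2. events with any gap flanked by fewer than ``min_flank`` aligned bases on
   either side are discarded (default 5 bp — short anchors are the signature
   of misplaced split alignments);
3. retained gaps are grouped by exact (reference, start, end) into junctions;
   junctions below ``min_support`` reads (default 3) are excluded from figure
   payloads but kept in the raw table;
4. per-base coverage from aligned (M/=/X) bases is optionally normalized to
   reads per million (RPM) using the total primary mapped read count.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
import pysam

logger = logging.getLogger(__name__)

# CIGAR op codes: M=0, I=1, D=2, N=3, S=4, H=5, P=6, ==7, X=8
_REF_CONSUMING = {0, 2, 3, 7, 8}
_ALIGNED = {0, 7, 8}  # ops that count as aligned bases (flanks, coverage)


@dataclass(frozen=True)
class SplitReadEvent:
    """One gapped primary alignment: its reference skips and their flanks."""

    read_id: str
    refname: str
    gaps: list[tuple[int, int]]
    flank_per_gap: list[tuple[int, int]]
    is_primary: bool = True

    def min_flank(self) -> int:
        return min(min(lf, rf) for lf, rf in self.flank_per_gap)


@dataclass(frozen=True)
class Junction:
    """A splice event keyed by exact gap coordinates, with read support."""

    refname: str
    start: int
    end: int
    support: int
    crosses_boundary: bool = False
    motif: str = "NN/NN"


@dataclass
class CoverageTrack:
    """Per-base read depth over one reference sequence."""

    refname: str
    values: np.ndarray
    scale: str = "raw"  # "raw" | "rpm"
    library_size: Optional[int] = None
    sample: str = ""


AlignmentSource = Union[str, Path, pysam.AlignmentFile]


def _iter_primary(alignments: AlignmentSource, refname: Optional[str] = None):
    own = False
    if not isinstance(alignments, pysam.AlignmentFile):
        alignments = pysam.AlignmentFile(str(alignments))
        own = True
    try:
        for aln in alignments.fetch(until_eof=True):
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            if refname is not None and aln.reference_name != refname:
                continue
            yield aln
    finally:
        if own:
            alignments.close()


def gaps_and_flanks(
    cigartuples: Sequence[tuple[int, int]], pos: int
) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """Walk a CIGAR from reference position `pos`, returning the gap intervals
    (N ops, 0-based half-open) and per-gap (left, right) flank lengths.

    A flank is the number of aligned (M/=/X) bases between the gap and the
    neighboring gap or read end on that side; deletions consume reference but
    do not count as flank.
    """
    ref = pos
    segments: list[int] = [0]  # aligned-base runs between gaps
    gaps: list[tuple[int, int]] = []
    for op, length in cigartuples:
        if op == 3:  # N
            gaps.append((ref, ref + length))
            ref += length
            segments.append(0)
        elif op in _ALIGNED:
            segments[-1] += length
            ref += length
        elif op in _REF_CONSUMING:  # D
            ref += length
    flanks = [(segments[i], segments[i + 1]) for i in range(len(gaps))]
    return gaps, flanks


def extract_split_reads(
    alignments: AlignmentSource, refname: Optional[str] = None
) -> list[SplitReadEvent]:
    """Extract one event per primary mapped alignment whose CIGAR contains at
    least one reference skip.  Records without a CIGAR are skipped with a
    warning."""
    events: list[SplitReadEvent] = []
    for aln in _iter_primary(alignments, refname):
        if aln.cigartuples is None:
            logger.warning("read %s has no CIGAR; skipped", aln.query_name)
            continue
        gaps, flanks = gaps_and_flanks(aln.cigartuples, aln.reference_start)
        if not gaps:
            continue
        events.append(
            SplitReadEvent(
                read_id=aln.query_name,
                refname=aln.reference_name,
                gaps=gaps,
                flank_per_gap=flanks,
            )
        )
    return events


def filter_split_reads(
    events: Iterable[SplitReadEvent], min_flank: int = 5
) -> list[SplitReadEvent]:
    """Retain events whose every gap has >= `min_flank` aligned bases on both
    sides.  Reads with fewer flanking bases (the default cutoff is 5 bp; a
    flank of exactly 5 passes) are removed as likely misalignments."""
    return [ev for ev in events if ev.min_flank() >= min_flank]


def count_junctions(
    events: Iterable[SplitReadEvent],
    refseq: Optional[str] = None,
    boundary: Optional[int] = None,
    min_support: int = 3,
) -> list[Junction]:
    """Group retained gap observations into junctions by exact coordinates.

    Returns *all* junctions (for the raw table), sorted by position, each
    annotated with its donor/acceptor motif (first and last two reference
    bases of the gap, e.g. "GT/AG") and whether it crosses the gene boundary
    (start < boundary <= end).  Use :func:`displayed_junctions` to apply the
    figure support threshold (`min_support` is carried for that purpose).
    """
    counter: Counter[tuple[str, int, int]] = Counter()
    for ev in events:
        for gap in ev.gaps:
            counter[(ev.refname, gap[0], gap[1])] += 1
    junctions = []
    for (refname, start, end), support in sorted(counter.items()):
        motif = "NN/NN"
        if refseq is not None and end <= len(refseq) and start + 2 <= end:
            motif = f"{refseq[start:start + 2]}/{refseq[end - 2:end]}"
        crosses = boundary is not None and start < boundary <= end
        junctions.append(
            Junction(
                refname=refname,
                start=start,
                end=end,
                support=support,
                crosses_boundary=crosses,
                motif=motif,
            )
        )
    return junctions


def displayed_junctions(junctions: Iterable[Junction], min_support: int = 3) -> list[Junction]:
    """Junctions meeting the figure display threshold (default 3 reads),
    filtering out low-support spurious splicing events."""
    return [j for j in junctions if j.support >= min_support]


def compute_coverage(
    alignments: AlignmentSource,
    refname: str,
    ref_length: Optional[int] = None,
    sample: str = "",
) -> CoverageTrack:
    """Per-base depth on one reference sequence from primary mapped reads.

    Aligned ops (M/=/X) add depth; skips (N) and deletions (D) do not.
    """
    own = False
    if not isinstance(alignments, pysam.AlignmentFile):
        alignments = pysam.AlignmentFile(str(alignments))
        own = True
    try:
        if ref_length is None:
            ref_length = alignments.get_reference_length(refname)
        depth = np.zeros(ref_length, dtype=np.int64)
        for aln in _iter_primary(alignments, refname):
            if aln.cigartuples is None:
                continue
            ref = aln.reference_start
            for op, length in aln.cigartuples:
                if op in _ALIGNED:
                    depth[ref : ref + length] += 1
                    ref += length
                elif op in _REF_CONSUMING:
                    ref += length
    finally:
        if own:
            alignments.close()
    return CoverageTrack(refname=refname, values=depth, scale="raw", sample=sample)


def count_library_size(alignments: AlignmentSource) -> int:
    """Total primary mapped reads in the whole alignment file (the RPM
    denominator: each read counted once)."""
    return sum(1 for _ in _iter_primary(alignments))


def normalize_rpm(track: CoverageTrack, library_size: int) -> CoverageTrack:
    """Scale raw depth to reads per million: value * 1e6 / library_size.

    RPM makes coverage comparable across samples with different sequencing
    depths.  Normalizing an already-RPM track is an error.
    """
    if track.scale != "raw":
        raise ValueError(f"track is already on scale {track.scale!r}")
    if library_size < 1:
        raise ValueError("library_size must be >= 1")
    return CoverageTrack(
        refname=track.refname,
        values=track.values.astype(float) * 1e6 / library_size,
        scale="rpm",
        library_size=library_size,
        sample=track.sample,
    )


def summarize_fusion_support(
    junctions: Iterable[Junction],
    breakpoints: Sequence[tuple[int, int]] = (),
) -> tuple[pd.DataFrame, int]:
    """Per-fusion support report for boundary-crossing junctions.

    `breakpoints` is the list of expected (donor, acceptor) positions from
    the caller, lifted into fusion coordinates.  Each boundary-crossing
    junction (a candidate fusion isoform) is matched to its nearest expected
    breakpoint pair.  Returns (table, total spanning-read support); an empty
    table with total 0 flags "no read support" for the fusion.
    """
    rows = []
    total = 0
    for j in junctions:
        if not j.crosses_boundary:
            continue
        total += j.support
        nearest, dist = None, None
        for donor, acceptor in breakpoints:
            # junction donor base is start-1, acceptor base is end
            d = abs((j.start - 1) - donor) + abs(j.end - acceptor)
            if dist is None or d < dist:
                nearest, dist = (donor, acceptor), d
        rows.append(
            {
                "refname": j.refname,
                "start": j.start,
                "end": j.end,
                "support": j.support,
                "motif": j.motif,
                "nearest_expected_donor": nearest[0] if nearest else pd.NA,
                "nearest_expected_acceptor": nearest[1] if nearest else pd.NA,
                "distance_to_expected": dist if dist is not None else pd.NA,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "refname",
            "start",
            "end",
            "support",
            "motif",
            "nearest_expected_donor",
            "nearest_expected_acceptor",
            "distance_to_expected",
        ],
    )
    if table.empty:
        logger.info("no read support: no boundary-crossing junctions")
    return table, total


# ---------------------------------------------------------------------------
# writers


def write_junction_table(junctions: Iterable[Junction], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "refname": j.refname,
                "start": j.start,
                "end": j.end,
                "support": j.support,
                "crosses_boundary": j.crosses_boundary,
                "motif": j.motif,
            }
            for j in junctions
        ],
        columns=["refname", "start", "end", "support", "crosses_boundary", "motif"],
    )
    df.to_csv(path, sep="\t", index=False)


def write_bedgraph(track: CoverageTrack, path: str | Path) -> None:
    """Write coverage as bedGraph (runs of equal depth collapsed)."""
    values = track.values
    with open(path, "w") as fh:
        if len(values) == 0:
            return
        run_start = 0
        for i in range(1, len(values) + 1):
            if i == len(values) or values[i] != values[run_start]:
                v = values[run_start]
                if v != 0:
                    out = f"{v:.6g}" if track.scale == "rpm" else str(int(v))
                    fh.write(f"{track.refname}\t{run_start}\t{i}\t{out}\n")
                run_start = i
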