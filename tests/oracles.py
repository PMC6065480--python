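"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the package's block/CIGAR arithmetic: liftover is
checked against a per-base rank table, and gap extraction against a per-base
interpretation of the CIGAR string.
"""

from __future__ import annotations

from typing import Sequence


def per_base_liftover_table(
    exonic_blocks: Sequence[tuple[int, int]], strand: str
) -> dict[int, int]:
    """Genomic position -> superTranscript offset by enumerating every exonic
    base in transcriptional order."""
    bases = [g for s, e in sorted(exonic_blocks) for g in range(s, e)]
    if strand == "-":
        bases.reverse()
    return {g: i for i, g in enumerate(bases)}


def per_base_cigar_gaps(
    cigartuples: Sequence[tuple[int, int]], pos: int
) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """Gap intervals and per-gap flanks from a per-base CIGAR expansion.

    Emits one label per reference-consuming base (M for aligned, D for
    deletion, N for skip), finds maximal N runs, and counts the M labels in
    each inter-run segment.
    """
    labels: list[tuple[str, int]] = []
    ref = pos
    for op, length in cigartuples:
        code = {0: "M", 7: "M", 8: "M", 2: "D", 3: "N"}.get(op)
        if code is None:
            continue  # I/S/H/P consume no reference
        for _ in range(length):
            labels.append((code, ref))
            ref += 1
    gaps: list[tuple[int, int]] = []
    segments: list[int] = [0]
    for code, refpos in labels:
        if code == "N":
            if gaps and gaps[-1][1] == refpos:
                gaps[-1] = (gaps[-1][0], refpos + 1)
            else:
                gaps.append((refpos, refpos + 1))
                segments.append(0)
        elif code == "M":
            segments[-1] += 1
    flanks = [(segments[i], segments[i + 1]) for i in range(len(gaps))]
    return gaps, flanks
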