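"""Readers for the standard inputs: GTF annotation, genome FASTA, domain BED,
and fusion-caller breakpoint tables.

All coordinates are 0-based half-open internally.  GTF (1-based inclusive) is
converted on read and write; BED is used natively.  Fusion-caller positions in
JAFFA- and STAR-Fusion-style files are 1-based and converted; the generic TSV
dialect defined here is already 0-based.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from pyfaidx import Fasta

logger = logging.getLogger(__name__)


class AnnotationError(ValueError):
    """Malformed or inconsistent annotation input."""


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class Breakpoint:
    """A genomic breakpoint: chromosome, 0-based position, optional strand."""

    chrom: str
    pos: int
    strand: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise AnnotationError("breakpoint chromosome must be non-empty")
        if self.pos < 0:
            raise AnnotationError(f"breakpoint position must be >= 0, got {self.pos}")


@dataclass(frozen=True)
class FusionCall:
    """One caller-reported fusion event: a 5' and a 3' genomic breakpoint."""

    break5: Breakpoint
    break3: Breakpoint
    caller: str = "generic"
    caller_support: Optional[int] = None
    sample: str = ""


@dataclass(frozen=True)
class DomainFeature:
    """A protein-domain interval in genomic coordinates (BED-style)."""

    name: str
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise AnnotationError(
                f"domain {self.name!r}: end ({self.end}) must exceed start ({self.start})"
            )


@dataclass
class TranscriptModel:
    """A transcript as an ordered list of disjoint exon intervals."""

    transcript_id: str
    exons: list[tuple[int, int]] = field(default_factory=list)

    def validate(self) -> None:
        prev_end = None
        for start, end in self.exons:
            if not (0 <= start < end):
                raise AnnotationError(
                    f"transcript {self.transcript_id}: invalid exon [{start},{end})"
                )
            if prev_end is not None and start < prev_end:
                raise AnnotationError(
                    f"transcript {self.transcript_id}: exons overlap or are unsorted"
                )
            prev_end = end

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]


@dataclass
class GeneModel:
    """A gene: identifier, display symbol, location, and its transcripts."""

    gene_id: str
    symbol: str
    chrom: str
    strand: str
    transcripts: list[TranscriptModel] = field(default_factory=list)

    def validate(self) -> None:
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        if not self.symbol:
            raise AnnotationError(f"gene {self.gene_id}: empty symbol")
        for tx in self.transcripts:
            tx.validate()

    @property
    def exons(self) -> list[tuple[int, int]]:
        """All exon intervals across transcripts, sorted by genomic start."""
        return sorted(iv for tx in self.transcripts for iv in tx.exons)

    @property
    def span(self) -> tuple[int, int]:
        ivs = self.exons
        return ivs[0][0], max(e for _, e in ivs)


# ---------------------------------------------------------------------------
# GTF

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_attributes(text: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(text))


def read_gtf(path: str | Path) -> dict[str, GeneModel]:
    """Parse a GTF file into gene models keyed by gene_id.

    Only ``exon`` features are used to build transcript structure.  GTF's
    1-based inclusive coordinates become 0-based half-open.  The display
    symbol is the ``gene_name`` attribute, falling back to ``gene_id``.
    Genes without any exon record are dropped with a warning.
    """
    genes: dict[str, GeneModel] = {}
    tx_index: dict[tuple[str, str], TranscriptModel] = {}
    seen_gene_ids: dict[str, int] = {}

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise AnnotationError(
                    f"{path}:{lineno}: expected 9 tab-separated fields, got {len(fields)}"
                )
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attrs_s = fields
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                raise AnnotationError(f"{path}:{lineno}: non-numeric coordinates") from None
            if end1 < start1:
                raise AnnotationError(f"{path}:{lineno}: end ({end1}) < start ({start1})")
            attrs = _parse_attributes(attrs_s)
            gene_id = attrs.get("gene_id")
            if gene_id is None:
                raise AnnotationError(f"{path}:{lineno}: missing gene_id attribute")
            seen_gene_ids.setdefault(gene_id, lineno)
            if feature != "exon":
                continue
            tx_id = attrs.get("transcript_id")
            if tx_id is None:
                raise AnnotationError(f"{path}:{lineno}: exon without transcript_id")
            symbol = attrs.get("gene_name") or gene_id
            gene = genes.get(gene_id)
            if gene is None:
                gene = GeneModel(gene_id=gene_id, symbol=symbol, chrom=chrom, strand=strand)
                genes[gene_id] = gene
            else:
                if chrom != gene.chrom:
                    raise AnnotationError(
                        f"{path}:{lineno}: gene {gene_id} spans chromosomes "
                        f"{gene.chrom} and {chrom}"
                    )
                if strand != gene.strand:
                    raise AnnotationError(
                        f"{path}:{lineno}: gene {gene_id} has transcripts on both strands"
                    )
            tx = tx_index.get((gene_id, tx_id))
            if tx is None:
                tx = TranscriptModel(transcript_id=tx_id)
                tx_index[(gene_id, tx_id)] = tx
                gene.transcripts.append(tx)
            tx.exons.append((start1 - 1, end1))  # to 0-based half-open

    for gene in genes.values():
        for tx in gene.transcripts:
            tx.exons.sort()
        gene.validate()

    dropped = set(seen_gene_ids) - set(genes)
    for gene_id in sorted(dropped):
        logger.warning("gene %s has no exon records; excluded", gene_id)
    return genes


def write_gtf(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene models back to GTF (round-trips with :func:`read_gtf`)."""
    with open(path, "w") as fh:
        for gene in genes:
            for tx in gene.transcripts:
                for start, end in tx.exons:
                    attrs = (
                        f'gene_id "{gene.gene_id}"; transcript_id "{tx.transcript_id}"; '
                        f'gene_name "{gene.symbol}";'
                    )
                    fh.write(
                        "\t".join(
                            [
                                gene.chrom,
                                "fusionlens",
                                "exon",
                                str(start + 1),
                                str(end),
                                ".",
                                gene.strand,
                                ".",
                                attrs,
                            ]
                        )
                        + "\n"
                    )


# ---------------------------------------------------------------------------
# genome FASTA


class Genome:
    """Random-access genome sequence source backed by a FASTA (+ .fai index)."""

    def __init__(self, path: str | Path):
        self._fasta = Fasta(str(path), sequence_always_upper=True, as_raw=True)

    @property
    def names(self) -> list[str]:
        return list(self._fasta.keys())

    def length(self, name: str) -> int:
        if name not in self._fasta:
            raise KeyError(f"unknown sequence {name!r}")
        return len(self._fasta[name])

    def fetch(self, name: str, start: int, end: int) -> str:
        """Return the subsequence [start, end) of `name`, uppercased."""
        if name not in self._fasta:
            raise KeyError(f"unknown sequence {name!r}")
        n = len(self._fasta[name])
        if start < 0 or end > n or start > end:
            raise IndexError(f"query [{start},{end}) out of bounds for {name} (length {n})")
        return str(self._fasta[name][start:end])


def open_genome(path: str | Path) -> Genome:
    """Open a FASTA for random access (builds a .fai index on first use)."""
    return Genome(path)


# ---------------------------------------------------------------------------
# fusion-caller tables

DIALECTS = ("generic", "jaffa", "star_fusion")


def _dedup(calls: list[FusionCall]) -> list[FusionCall]:
    seen: set[tuple] = set()
    out: list[FusionCall] = []
    for call in calls:
        key = (call.break5, call.break3, call.sample)
        if key in seen:
            logger.info("duplicate fusion row collapsed: %s", key)
            continue
        seen.add(key)
        out.append(call)
    return out


def _to_int(text: str, what: str) -> int:
    try:
        return int(text)
    except (TypeError, ValueError):
        raise AnnotationError(f"non-numeric {what}: {text!r}") from None


def _parse_generic(path: Path) -> list[FusionCall]:
    required = ["chrom1", "pos1", "strand1", "chrom2", "pos2", "strand2", "sample"]
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = [c for c in required if c not in (reader.fieldnames or [])]
        if missing:
            raise AnnotationError(f"generic fusion TSV missing columns: {missing}")
        calls = []
        for row in reader:
            calls.append(
                FusionCall(
                    break5=Breakpoint(row["chrom1"], _to_int(row["pos1"], "pos1"), row["strand1"]),
                    break3=Breakpoint(row["chrom2"], _to_int(row["pos2"], "pos2"), row["strand2"]),
                    caller="generic",
                    sample=row["sample"],
                )
            )
    return calls


def _parse_jaffa(path: Path) -> list[FusionCall]:
    with open(path) as fh:
        reader = csv.DictReader(fh)
        calls = []
        for row in reader:
            support = row.get("spanning reads")
            calls.append(
                FusionCall(
                    break5=Breakpoint(
                        row["chrom1"], _to_int(row["base1"], "base1") - 1, row.get("strand1")
                    ),
                    break3=Breakpoint(
                        row["chrom2"], _to_int(row["base2"], "base2") - 1, row.get("strand2")
                    ),
                    caller="jaffa",
                    caller_support=_to_int(support, "spanning reads") if support else None,
                    sample=row.get("sample", ""),
                )
            )
    return calls


def _parse_breakpoint_string(text: str, what: str) -> Breakpoint:
    parts = text.split(":")
    if len(parts) < 2:
        raise AnnotationError(f"malformed {what} breakpoint: {text!r}")
    strand = parts[2] if len(parts) > 2 and parts[2] in ("+", "-") else None
    return Breakpoint(parts[0], _to_int(parts[1], what) - 1, strand)


def _parse_star_fusion(path: Path) -> list[FusionCall]:
    with open(path) as fh:
        header = fh.readline().lstrip("#").rstrip("\n").split("\t")
        reader = csv.DictReader(fh, fieldnames=header, delimiter="\t")
        calls = []
        for row in reader:
            support = row.get("JunctionReadCount")
            calls.append(
                FusionCall(
                    break5=_parse_breakpoint_string(row["LeftBreakpoint"], "LeftBreakpoint"),
                    break3=_parse_breakpoint_string(row["RightBreakpoint"], "RightBreakpoint"),
                    caller="star_fusion",
                    caller_support=_to_int(support, "JunctionReadCount") if support else None,
                    sample=row.get("sample", ""),
                )
            )
    return calls


def parse_fusion_calls(path: str | Path, dialect: str = "generic") -> list[FusionCall]:
    """Read a fusion-caller breakpoint table.

    Supported dialects: ``generic`` (headered TSV with columns chrom1, pos1,
    strand1, chrom2, pos2, strand2, sample; 0-based positions), ``jaffa``
    (CSV with chrom1/base1/chrom2/base2, 1-based), and ``star_fusion`` (TSV
    with LeftBreakpoint/RightBreakpoint "chr:pos:strand" strings, 1-based).
    Duplicate rows (same breakpoints and sample) collapse to one call.  Any
    caller-reported gene symbols are ignored: gene identity is re-derived
    from the breakpoints against the annotation.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; choose from {DIALECTS}")
    path = Path(path)
    parser = {"generic": _parse_generic, "jaffa": _parse_jaffa, "star_fusion": _parse_star_fusion}[
        dialect
    ]
    return _dedup(parser(path))


# ---------------------------------------------------------------------------
# domain BED


def read_domain_bed(path: str | Path) -> list[DomainFeature]:
    """Read protein-domain intervals from a BED4+ file (0-based half-open).

    The name column (4th) is required.  Rows on chromosomes absent from the
    annotation are kept here and filtered later at liftover.
    """
    domains: list[DomainFeature] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise AnnotationError(
                    f"{path}:{lineno}: BED4 required (chrom, start, end, name)"
                )
            chrom, start_s, end_s, name = fields[:4]
            start = _to_int(start_s, "start")
            end = _to_int(end_s, "end")
            strand = fields[5] if len(fields) > 5 and fields[5] in ("+", "-") else "+"
            try:
                domains.append(DomainFeature(name=name, chrom=chrom, start=start, end=end, strand=strand))
            except AnnotationError as exc:
                raise AnnotationError(f"{path}:{lineno}: {exc}") from None
    return domains


# ---------------------------------------------------------------------------
# chromosome-name reconciliation


def match_chrom(name: str, known: Iterable[str]) -> str:
    """Reconcile a chromosome name against a known set by toggling the
    ``chr`` prefix; returns the matching known name or the input unchanged."""
    known = set(known)
    if name in known:
        return name
    alt = name[3:] if name.startswith("chr") else "chr" + name
    if alt in known:
        return alt
    return name
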