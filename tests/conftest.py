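from __future__ import annotations

from pathlib import Path

import pysam
import pytest

from fusionlens import annotation_io, fusion_reference, simulate
from fusionlens.annotation_io import Genome


class StringGenome:
    """In-memory sequence source with the same interface as Genome."""

    def __init__(self, sequences: dict[str, str]):
        self._seqs = {k: v.upper() for k, v in sequences.items()}

    @property
    def names(self):
        return list(self._seqs)

    def length(self, name: str) -> int:
        if name not in self._seqs:
            raise KeyError(name)
        return len(self._seqs[name])

    def fetch(self, name: str, start: int, end: int) -> str:
        if name not in self._seqs:
            raise KeyError(name)
        seq = self._seqs[name]
        if start < 0 or end > len(seq) or start > end:
            raise IndexError(f"[{start},{end}) out of bounds")
        return seq[start:end]


@pytest.fixture
def string_genome_factory():
    return StringGenome


def write_fasta(path: Path, sequences: dict[str, str]) -> Path:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
    return path


def write_sam(path: Path, lengths: dict[str, int], records: list[dict]) -> Path:
    """Write a SAM from record dicts: name, ref, pos, cigar, optional flag."""
    names = list(lengths)
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": n, "LN": lengths[n]} for n in names],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as sam:
        for rec in records:
            a = pysam.AlignedSegment()
            a.query_name = rec["name"]
            a.reference_id = names.index(rec["ref"])
            a.reference_start = rec["pos"]
            a.flag = rec.get("flag", 0)
            a.mapping_quality = rec.get("mapq", 60)
            a.cigarstring = rec["cigar"]
            qlen = sum(l for op, l in a.cigartuples or [] if op in (0, 1, 4, 7, 8))
            a.query_sequence = "A" * qlen
            sam.write(a)
    return path


@pytest.fixture
def sam_writer():
    return write_sam


@pytest.fixture
def fasta_writer():
    return write_fasta


@pytest.fixture
def toy_truth():
    return simulate.make_toy_locus(n_genes=4, exons_per_gene=3, seed=7)


@pytest.fixture
def toy_files(toy_truth, tmp_path):
    return simulate.write_locus(toy_truth, tmp_path / "locus")


@pytest.fixture
def toy_genome(toy_files) -> Genome:
    return annotation_io.open_genome(toy_files["genome"])


@pytest.fixture
def toy_genes(toy_files):
    return annotation_io.read_gtf(toy_files["gtf"])


@pytest.fixture
def toy_reference(toy_truth, toy_genes, toy_genome, toy_files):
    domains = annotation_io.read_domain_bed(toy_files["domains"])
    calls = annotation_io.parse_fusion_calls(toy_files["fusions"], "generic")
    return fusion_reference.build_reference(calls, toy_genes, toy_genome, domains)
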