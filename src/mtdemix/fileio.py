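"""File formats and run configuration.

FASTQ (plain or gzip) is read through pysam's fastx parser with Phred+33
quality decoding; SAM/BAM through pysam's alignment reader, recomputing each
record's Levenshtein distance from its sequence against the spanned reference
window rather than trusting aligner-specific tags.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import zip_longest
from pathlib import Path
from typing import Iterator

import edlib
import numpy as np
import pysam

from .deconvolve import DeconvolveConfig
from .phylo import KnownHaplotype, MitoReference, PhyloTree, parse_phylotree, parse_variant_token
from .preprocess import AlignmentRecord, Fragment, PreprocessConfig, PrimerSet, ReadPair

__all__ = [
    "ConfigError",
    "DataError",
    "RunConfig",
    "read_fastq_pair",
    "write_fastq_pair",
    "read_alignments",
    "fragments_from_sam",
    "load_reference",
    "load_tree",
    "load_primers",
    "load_knowns",
]


class ConfigError(Exception):
    """Invalid configuration (CLI exit code 2)."""


class DataError(Exception):
    """Malformed or inconsistent input data (CLI exit code 3)."""


def read_fastq_pair(path1: str | Path, path2: str | Path) -> Iterator[ReadPair]:
    """Lazily yield synchronized read pairs from two FASTQ files (gz transparent)."""
    with pysam.FastxFile(str(path1)) as f1, pysam.FastxFile(str(path2)) as f2:
        for i, (e1, e2) in enumerate(zip_longest(f1, f2)):
            if e1 is None or e2 is None:
                raise DataError(f"mate files desynchronized: record {i} missing in one file")
            if e1.quality is None or e2.quality is None:
                raise DataError(f"record {i} ({e1.name}): missing quality line")
            q1 = np.frombuffer(e1.quality.encode("ascii"), dtype=np.uint8) - 33
            q2 = np.frombuffer(e2.quality.encode("ascii"), dtype=np.uint8) - 33
            try:
                yield ReadPair(e1.name, e1.sequence.upper(), q1, e2.sequence.upper(), q2)
            except ValueError as exc:
                raise DataError(f"record {i}: {exc}") from exc


def write_fastq_pair(pairs: list[ReadPair], out_prefix: str | Path) -> tuple[Path, Path]:
    out1 = Path(f"{out_prefix}_R1.fastq")
    out2 = Path(f"{out_prefix}_R2.fastq")
    with open(out1, "w") as f1, open(out2, "w") as f2:
        for p in pairs:
            f1.write(f"@{p.read_id}\n{p.seq1}\n+\n{(p.qual1 + 33).tobytes().decode('ascii')}\n")
            f2.write(f"@{p.read_id}\n{p.seq2}\n+\n{(p.qual2 + 33).tobytes().decode('ascii')}\n")
    return out1, out2


def _window_lev(seq: str, ref_doubled: str, start: int, span: int) -> float:
    window = ref_doubled[start : start + span]
    if not window:
        return math.inf
    return float(edlib.align(seq, window, mode="NW", task="distance")["editDistance"])


def read_alignments(
    path: str | Path, reference: MitoReference, target: str = "mito"
) -> list[AlignmentRecord]:
    """Alignment records from SAM/BAM with recomputed Levenshtein distances.

    Soft-clipping is taken from the CIGAR; unmapped records carry the +inf
    distance sentinel. Secondary/supplementary lines are skipped.
    """
    records: list[AlignmentRecord] = []
    ref_doubled = reference.sequence + reference.sequence
    try:
        af = pysam.AlignmentFile(str(path), check_sq=False)
    except ValueError as exc:
        raise DataError(f"{path}: {exc}") from exc
    with af:
        for aln in af:
            if aln.is_secondary or aln.is_supplementary:
                continue
            if aln.is_unmapped:
                records.append(AlignmentRecord(aln.query_name, target, False, False, math.inf))
                continue
            if aln.reference_name is None:
                raise DataError(f"{path}: mapped record {aln.query_name} lacks a reference name")
            soft = any(op == 4 for op, _ in (aln.cigartuples or []))
            span = (aln.reference_end or aln.reference_start) - aln.reference_start
            seq = aln.query_alignment_sequence or aln.query_sequence or ""
            lev = _window_lev(seq, ref_doubled, aln.reference_start % len(reference), span)
            records.append(AlignmentRecord(aln.query_name, target, True, soft, lev))
    return records


def fragments_from_sam(path: str | Path) -> list[Fragment]:
    """Mapped primary records as fragments (BAM input mode, no pair merging)."""
    frags: list[Fragment] = []
    with pysam.AlignmentFile(str(path), check_sq=False) as af:
        for aln in af:
            if aln.is_secondary or aln.is_supplementary or aln.is_unmapped:
                continue
            seq = aln.query_sequence
            if not seq:
                continue
            if aln.query_qualities is not None:
                qual = np.asarray(aln.query_qualities, dtype=np.uint8)
            else:
                qual = np.full(len(seq), 30, dtype=np.uint8)
            frags.append(Fragment(aln.query_name, seq.upper(), qual))
    return frags


# ---------------------------------------------------------------------------
# reference / tree / primer / known loaders
# ---------------------------------------------------------------------------


def load_reference(path: str | Path, name: str | None = None) -> MitoReference:
    with pysam.FastxFile(str(path)) as fh:
        for entry in fh:
            return MitoReference(name=name or entry.name, sequence=entry.sequence.upper())
    raise DataError(f"{path}: no FASTA record found")


def load_fasta_sequence(path: str | Path) -> str:
    with pysam.FastxFile(str(path)) as fh:
        for entry in fh:
            return entry.sequence.upper()
    raise DataError(f"{path}: no FASTA record found")


def load_tree(path: str | Path, reference: MitoReference | None = None) -> PhyloTree:
    text = Path(path).read_text()
    return parse_phylotree(text, reference)


def load_primers(path: str | Path) -> PrimerSet:
    return PrimerSet.from_tsv(Path(path).read_text())


def load_knowns(path: str | Path) -> list[KnownHaplotype]:
    """Known haplotypes from TSV: sample_id <tab> space-separated variant tokens."""
    knowns: list[KnownHaplotype] = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        sample_id = fields[0].strip()
        tokens = fields[1].split() if len(fields) > 1 else []
        try:
            variants = tuple(parse_variant_token(t) for t in tokens)
            knowns.append(KnownHaplotype(sample_id=sample_id, variants=variants))
        except ValueError as exc:
            raise DataError(f"{path} line {lineno}: {exc}") from exc
    return knowns


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """End-to-end pipeline configuration (CLI and library entry point)."""

    tree_path: str
    mito_fasta: str
    outdir: str
    fastq1: str | None = None
    fastq2: str | None = None
    bam: str | None = None
    nuclear_fasta: str | None = None
    primers_path: str | None = None
    knowns_path: str | None = None
    seed: int = 0
    skip_preprocess: bool = False
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    deconvolve: DeconvolveConfig = field(default_factory=DeconvolveConfig)

    def validate(self) -> None:
        fastq_mode = self.fastq1 is not None or self.fastq2 is not None
        if fastq_mode and self.bam is not None:
            raise ConfigError("fastq and bam inputs are mutually exclusive")
        if fastq_mode and (self.fastq1 is None or self.fastq2 is None):
            raise ConfigError("paired input needs both --fastq1 and --fastq2")
        if not fastq_mode and self.bam is None:
            raise ConfigError("no input: provide --fastq1/--fastq2 or --bam")
        for label, p in (
            ("fastq1", self.fastq1),
            ("fastq2", self.fastq2),
            ("bam", self.bam),
            ("tree", self.tree_path),
            ("mito reference", self.mito_fasta),
            ("nuclear reference", self.nuclear_fasta),
            ("primers", self.primers_path),
            ("knowns", self.knowns_path),
        ):
            if p is not None and not Path(p).exists():
                raise ConfigError(f"{label} path does not exist: {p}")
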