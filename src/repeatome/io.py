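"""Readers/writers for the pipeline's on-disk formats and alignment ingestion.

FASTA/FASTQ parsing is delegated to Biopython, SAM ingestion to pysam, and
tabular matrices to pandas.  All internal coordinates are 0-based half-open;
SAM input is 1-based per the standard and converted at this boundary.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pysam
from Bio import SeqIO

__all__ = [
    "Read",
    "SampleEntry",
    "SampleManifest",
    "CoverageProfile",
    "ParseError",
    "read_sequences",
    "write_fasta",
    "write_fastq",
    "subsample_reads",
    "coverage_from_sam",
    "write_matrix_tsv",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N-preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


class ParseError(ValueError):
    """A sequence file failed to parse in the declared format."""


@dataclass(frozen=True)
class Read:
    """A sequencing read: the second vertex type of the incidence graph.

    ``qual`` is carried through from FASTQ but unused downstream (quality
    trimming is out of scope).
    """

    id: str
    seq: str
    qual: str | None = None

    def __post_init__(self) -> None:
        if len(self.seq) < 1:
            raise ValueError(f"read {self.id!r} has an empty sequence")
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise ValueError(f"read {self.id!r}: quality length != sequence length")


@dataclass(frozen=True)
class SampleEntry:
    sample_id: str
    species: str
    replicate: int
    path: str
    format: str  # "fasta" | "fastq"


@dataclass
class SampleManifest:
    """Maps sample ids to species/replicate labels and read files."""

    entries: list[SampleEntry]

    def __post_init__(self) -> None:
        ids = [e.sample_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("sample ids in a manifest must be unique")

    @property
    def sample_ids(self) -> list[str]:
        return [e.sample_id for e in self.entries]

    @property
    def sample_meta(self) -> dict[str, tuple[str, int]]:
        return {e.sample_id: (e.species, e.replicate) for e in self.entries}

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("sample_id\tspecies\treplicate\tpath\tformat\n")
            for e in self.entries:
                fh.write(f"{e.sample_id}\t{e.species}\t{e.replicate}\t{e.path}\t{e.format}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SampleManifest":
        entries = []
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            expected = ["sample_id", "species", "replicate", "path", "format"]
            if header != expected:
                raise ParseError(f"manifest header {header!r}, expected {expected!r}")
            for line in fh:
                if not line.strip():
                    continue
                sid, sp, rep, p, fmt = line.rstrip("\n").split("\t")
                entries.append(SampleEntry(sid, sp, int(rep), p, fmt))
        return cls(entries)


@dataclass
class CoverageProfile:
    """Per-position read depth over one reference sequence."""

    ref_id: str
    length: int
    depth: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.depth is None:
            self.depth = np.zeros(self.length, dtype=np.int64)
        else:
            self.depth = np.asarray(self.depth, dtype=np.int64)
        if len(self.depth) != self.length:
            raise ValueError(f"profile {self.ref_id!r}: depth length != reference length")
        if (self.depth < 0).any():
            raise ValueError(f"profile {self.ref_id!r}: negative depth")


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


_FORMATS = {"fasta", "fastq"}


def _infer_format(path: str | Path) -> str:
    name = Path(path).name
    if name.endswith(".gz"):
        name = name[:-3]
    suffix = Path(name).suffix.lower()
    if suffix in {".fa", ".fasta", ".fna"}:
        return "fasta"
    if suffix in {".fq", ".fastq"}:
        return "fastq"
    raise ValueError(f"cannot infer sequence format from {path!r}; pass format explicitly")


def read_sequences(path: str | Path, format: str | None = None) -> Iterator[Read]:
    """Yield reads from a FASTA/FASTQ file (plain or gzipped) in file order.

    Sequences are uppercased; ``N`` bases are preserved.  Malformed records
    raise :class:`ParseError`.
    """
    fmt = format or _infer_format(path)
    if fmt not in _FORMATS:
        raise ValueError(f"unknown sequence format {fmt!r}")
    with _open_text(path) as fh:
        try:
            for rec in SeqIO.parse(fh, fmt):
                qual = None
                if fmt == "fastq":
                    qual = "".join(
                        chr(q + 33) for q in rec.letter_annotations["phred_quality"]
                    )
                yield Read(rec.id, str(rec.seq).upper(), qual)
        except ValueError as exc:  # Biopython signals malformed records this way
            raise ParseError(f"{path}: {exc}") from exc


def write_fasta(records: Iterable, path: str | Path) -> None:
    """Write (id, seq) pairs or objects with ``.id``/``.seq`` as FASTA."""
    with open(path, "w") as fh:
        for rec in records:
            rid, seq = rec if isinstance(rec, tuple) else (rec.id, rec.seq)
            fh.write(f">{rid}\n{seq}\n")


def write_fastq(reads: Iterable[Read], path: str | Path) -> None:
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        for r in reads:
            qual = r.qual if r.qual is not None else "I" * len(r.seq)
            fh.write(f"@{r.id}\n{r.seq}\n+\n{qual}\n")


def subsample_reads(reads: Sequence[Read], target_bases: int, seed: int) -> list[Read]:
    """Uniform random subset of whole reads totalling at most ``target_bases``.

    Reads are visited in a seeded random permutation; a read that would push
    the running total past the target is skipped and scanning continues, so
    the selected total is the largest reachable value <= target for
    equal-length reads and within one read length of it otherwise.  The same
    seed always yields the same subset.
    """
    if target_bases < 0:
        raise ValueError("target_bases must be >= 0")
    reads = list(reads)
    total = sum(len(r.seq) for r in reads)
    if target_bases >= total:
        return reads
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(reads))
    chosen: list[int] = []
    acc = 0
    shortest = min((len(r.seq) for r in reads), default=0)
    for i in order:
        n = len(reads[i].seq)
        if acc + n <= target_bases:
            chosen.append(i)
            acc += n
            if target_bases - acc < shortest:
                break
    chosen.sort()  # preserve input order in the output
    return [reads[i] for i in chosen]


def coverage_from_sam(
    sam_path: str | Path, references: Mapping[str, int]
) -> dict[str, CoverageProfile]:
    """Per-reference coverage from a SAM file.

    Only primary alignments are counted (one alignment per read); depth is
    incremented at reference positions consumed by M/=/X CIGAR operations.
    Soft/hard clips and insertions do not increment.  Unmapped records are
    ignored.
    """
    profiles = {rid: CoverageProfile(rid, length) for rid, length in references.items()}
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as sam:
        for rid in sam.references:
            if rid not in references:
                raise ValueError(f"SAM reference {rid!r} missing from the reference map")
            if sam.get_reference_length(rid) != references[rid]:
                raise ValueError(
                    f"SAM header length for {rid!r} disagrees with the reference map"
                )
        for rec in sam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            rid = rec.reference_name
            if rid not in profiles:
                raise ValueError(f"alignment {rec.query_name!r} to unknown reference {rid!r}")
            prof = profiles[rid]
            if rec.reference_end > prof.length:
                raise ValueError(
                    f"alignment {rec.query_name!r} extends past the end of {rid!r}"
                )
            # get_blocks() returns 0-based half-open M/=/X blocks only.
            for start, end in rec.get_blocks():
                prof.depth[start:end] += 1
    return profiles


def write_matrix_tsv(matrix, path: str | Path) -> None:
    """Write an abundance matrix (anything with ``.to_tsv``) as TSV + sidecar."""
    matrix.to_tsv(path)
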