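"""Contaminant classification of the kChain library by k-mer containment.

Highly repetitive reads may come from the nuclear genome, from high-copy
organellar genomes (cpDNA/mtDNA), or from technical artifacts such as
leftover sequencing adapters.  Each kChain is classified by the fraction of
its canonical k-mers contained in user-supplied reference k-mer sets; the
downstream analysis consumes the "nuclear" bin, and the chloroplast bin can
be analyzed as its own abundance track.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .io import read_sequences
from .kchain import KChain, _read_kmer_set

__all__ = [
    "ContaminantIndex",
    "build_contaminant_index",
    "classify_kchain",
    "partition_library",
]

NUCLEAR = "nuclear"


@dataclass(frozen=True)
class ContaminantIndex:
    """Canonical k-mer set of one labeled contaminant reference collection."""

    label: str
    k: int
    kmers: frozenset[str]


def build_contaminant_index(
    refs: str | Path | Iterable[tuple[str, str]], label: str, k: int = 12
) -> ContaminantIndex:
    """Index a FASTA path or (id, seq) pairs as a canonical k-mer set."""
    if k < 8:
        raise ValueError("k must be >= 8")
    if isinstance(refs, (str, Path)):
        records = [(r.id, r.seq) for r in read_sequences(refs, "fasta")]
    else:
        records = list(refs)
    if not records:
        raise ValueError(f"no reference sequences for contaminant index {label!r}")
    kmers: set[str] = set()
    for _, seq in records:
        kmers |= _read_kmer_set(seq.upper(), k, use_canonical=True)
    if not kmers:
        warnings.warn(f"contaminant index {label!r}: all references shorter than k={k}")
    return ContaminantIndex(label, k, frozenset(kmers))


def containment(seq: str, index: ContaminantIndex) -> float:
    """Fraction of the sequence's canonical k-mers present in the index."""
    kmers = _read_kmer_set(seq.upper(), index.k, use_canonical=True)
    if not kmers:
        return 0.0
    return sum(1 for m in kmers if m in index.kmers) / len(kmers)


def classify_kchain(
    seq: str,
    indexes: Sequence[ContaminantIndex],
    containment_threshold: float = 0.5,
) -> tuple[str, float]:
    """Label of the highest-containment index meeting the threshold, else
    "nuclear".  Ties break by index order.  Returns (label, containment)."""
    if not 0.0 < containment_threshold <= 1.0:
        raise ValueError("containment_threshold must lie in (0, 1]")
    best_label, best_c = NUCLEAR, 0.0
    for idx in indexes:
        c = containment(seq, idx)
        if c >= containment_threshold and c > best_c:
            best_label, best_c = idx.label, c
    return best_label, best_c


def partition_library(
    kchains: Sequence[KChain],
    indexes: Sequence[ContaminantIndex],
    threshold: float = 0.5,
) -> dict[str, list[KChain]]:
    """Partition kChains into exactly one bin each; "nuclear" collects all
    chains below threshold for every index and is always present."""
    bins: dict[str, list[KChain]] = {NUCLEAR: []}
    for idx in indexes:
        bins.setdefault(idx.label, [])
    for chain in kchains:
        label, _ = classify_kchain(chain.seq, indexes, threshold)
        bins[label].append(chain)
    return bins
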