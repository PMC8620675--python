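"""Read-to-repeat mapping, abundance estimation, and matrix normalization.

Abundance of a repeat in a sample is the median (or mean) of per-position
read coverage over the repeat sequence.  The raw repeat x sample matrix is
filtered on a maximum-abundance threshold, natural-log transformed, and
quantile normalized before ordination and tree building.

The built-in mapper is a gapless local aligner (exact k-mer seeding on both
strands, best-segment extension under a running-identity constraint, one
alignment per read).  It stands in for an external local-mode aligner at
desk scale; production-size runs can ingest SAM instead via
:func:`repeatome.io.coverage_from_sam`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import CoverageProfile, Read, SampleManifest, revcomp

__all__ = [
    "AbundanceMatrix",
    "map_reads",
    "abundance",
    "build_matrix",
    "log_transform",
    "quantile_normalize",
    "filter_by_max",
]

_STATES = ("raw", "log", "quantile_normalized")


@dataclass(frozen=True)
class AbundanceMatrix:
    """Repeats x samples abundance values with sample metadata.

    ``state`` tracks the normalization stage and may only advance
    raw -> log -> quantile_normalized.
    """

    df: pd.DataFrame  # index: repeat ids, columns: sample ids
    state: str
    sample_meta: Mapping[str, tuple[str, int]]  # sample -> (species, replicate)

    def __post_init__(self) -> None:
        if self.state not in _STATES:
            raise ValueError(f"unknown state {self.state!r}")
        if self.df.index.duplicated().any() or self.df.columns.duplicated().any():
            raise ValueError("duplicated row or column ids")
        if self.state == "raw" and (self.df.values < 0).any():
            raise ValueError("raw abundances must be non-negative")

    @property
    def row_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def col_ids(self) -> list[str]:
        return list(self.df.columns)

    @property
    def values(self) -> np.ndarray:
        return self.df.to_numpy(dtype=float)

    def species_of(self, sample_id: str) -> str:
        return self.sample_meta[sample_id][0]

    def to_tsv(self, path: str | Path) -> None:
        """TSV with row ids in column 1 and sample ids in the header, plus a
        sidecar JSON recording state and sample metadata."""
        path = Path(path)
        self.df.to_csv(path, sep="\t", index_label="id", float_format="%.10g")
        sidecar = {
            "state": self.state,
            "sample_meta": {s: list(v) for s, v in self.sample_meta.items()},
        }
        with open(path.with_suffix(path.suffix + ".meta.json"), "w") as fh:
            json.dump(sidecar, fh, indent=2)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AbundanceMatrix":
        path = Path(path)
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        df.index.name = None
        meta_path = path.with_suffix(path.suffix + ".meta.json")
        if meta_path.exists():
            with open(meta_path) as fh:
                sidecar = json.load(fh)
            state = sidecar["state"]
            meta = {s: (v[0], int(v[1])) for s, v in sidecar["sample_meta"].items()}
        else:
            state, meta = "raw", {c: (c, 1) for c in df.columns}
        return cls(df, state, meta)


def _build_seed_index(references: Sequence[tuple[str, str]], seed_k: int):
    index: dict[int, list[tuple[int, int]]] = {}
    for ri, (_, seq) in enumerate(references):
        for i, code in _positional_kmer_codes(seq, seed_k):
            index.setdefault(code, []).append((ri, i))
    return index


def _positional_kmer_codes(seq: str, k: int) -> list[tuple[int, int]]:
    """(position, 2-bit code) for every N-free k-mer window of ``seq``."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    if len(arr) < k:
        return []
    codes = _kmer_lut[arr]
    pow4 = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    vals = np.lib.stride_tricks.sliding_window_view(codes, k).astype(np.int64) @ pow4
    bad = codes > 3
    if bad.any():
        invalid = np.convolve(bad.astype(np.int64), np.ones(k, dtype=np.int64), "valid") > 0
    else:
        invalid = np.zeros(len(vals), dtype=bool)
    ok = ~invalid
    return list(zip(np.nonzero(ok)[0].tolist(), vals[ok].tolist()))


_kmer_lut = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _kmer_lut[_b] = _i


def _best_segment(read: str, ref: str, offset: int, penalty: float):
    """Best-scoring gapless segment of the read against the reference at a
    fixed diagonal; score = matches - penalty * mismatches (Kadane)."""
    r0 = max(0, -offset)
    r1 = min(len(read), len(ref) - offset)
    best = 0.0
    best_span = None
    acc = 0.0
    start = r0
    for i in range(r0, r1):
        acc += 1.0 if read[i] == ref[i + offset] else -penalty
        if acc <= 0:
            acc = 0.0
            start = i + 1
        elif acc > best:
            best = acc
            best_span = (start, i + 1)
    return best, best_span


def map_reads(
    reads: Sequence[Read],
    references: Sequence[tuple[str, str]] | Mapping[str, str],
    seed_k: int = 12,
    min_identity: float = 0.9,
) -> dict[str, CoverageProfile]:
    """Map reads to repeat references and accumulate per-position coverage.

    Each read is assigned to at most one reference (the best-scoring gapless
    segment over all seeded diagonals on both strands; ties broken by
    reference order, then forward strand, then smallest offset), matching a
    local-mode aligner restricted to one alignment per read.
    """
    if isinstance(references, Mapping):
        refs = [(rid, seq.upper()) for rid, seq in references.items()]
    else:
        refs = [(rid, seq.upper()) for rid, seq in references]
    if not refs:
        raise ValueError("references must be non-empty")
    if not 0.5 < min_identity <= 1.0:
        raise ValueError("min_identity must lie in (0.5, 1]")
    penalty = min_identity / (1.0 - min_identity) if min_identity < 1.0 else np.inf
    index = _build_seed_index(refs, seed_k)
    profiles = {rid: CoverageProfile(rid, len(seq)) for rid, seq in refs}
    for read in reads:
        best = None  # (-score, ref_index, strand_rank, offset, span)
        for strand_rank, seq in enumerate((read.seq, revcomp(read.seq))):
            diagonals: set[tuple[int, int]] = set()
            for i, code in _positional_kmer_codes(seq, seed_k):
                hits = index.get(code)
                if not hits:
                    continue
                for ri, pos in hits:
                    diagonals.add((ri, pos - i))
            for ri, offset in sorted(diagonals):
                if penalty is np.inf:
                    score, span = _exact_segment(seq, refs[ri][1], offset)
                else:
                    score, span = _best_segment(seq, refs[ri][1], offset, penalty)
                if span is None:
                    continue
                key = (-score, ri, strand_rank, offset, span)
                if best is None or key < best:
                    best = key
        if best is None:
            continue
        _, ri, _, offset, span = best
        depth = profiles[refs[ri][0]].depth
        depth[span[0] + offset : span[1] + offset] += 1
    return profiles


def _exact_segment(read: str, ref: str, offset: int):
    """Longest exact match run on the diagonal (min_identity == 1 case)."""
    r0 = max(0, -offset)
    r1 = min(len(read), len(ref) - offset)
    best, best_span = 0, None
    run = 0
    for i in range(r0, r1):
        if read[i] == ref[i + offset]:
            run += 1
            if run > best:
                best = run
                best_span = (i + 1 - run, i + 1)
        else:
            run = 0
    return float(best), best_span


def abundance(profile: CoverageProfile, statistic: str = "median") -> float:
    """Summary abundance of one coverage profile (zeros included)."""
    if statistic == "median":
        return float(np.median(profile.depth))
    if statistic == "mean":
        return float(np.mean(profile.depth))
    raise ValueError(f"unknown statistic {statistic!r}")


def build_matrix(
    manifest: SampleManifest,
    references: Sequence[tuple[str, str]] | Sequence,
    profiles_by_sample: Mapping[str, Mapping[str, CoverageProfile]],
    statistic: str = "median",
) -> AbundanceMatrix:
    """Raw abundance matrix: rows follow the reference list, columns the
    manifest.  A reference absent from a sample's profiles scores zero."""
    ref_ids = [r[0] if isinstance(r, tuple) else r.id for r in references]
    if len(set(ref_ids)) != len(ref_ids):
        raise ValueError("duplicated reference ids")
    data = {}
    for entry in manifest.entries:
        profs = profiles_by_sample.get(entry.sample_id, {})
        data[entry.sample_id] = [
            abundance(profs[rid], statistic) if rid in profs else 0.0 for rid in ref_ids
        ]
    df = pd.DataFrame(data, index=ref_ids)
    return AbundanceMatrix(df, "raw", manifest.sample_meta)


def log_transform(matrix: AbundanceMatrix, pseudo: float = 1.0) -> AbundanceMatrix:
    """Elementwise natural log of (abundance + pseudo)."""
    if matrix.state != "raw":
        raise ValueError(f"log_transform requires state 'raw', got {matrix.state!r}")
    if pseudo <= 0:
        raise ValueError("pseudo must be > 0")
    return replace(matrix, df=np.log(matrix.df + pseudo), state="log")


def quantile_normalize(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Classic quantile normalization across sample columns.

    Each column is ranked; every value is replaced by the mean over columns
    of the values at its rank, with ties receiving the mean of their
    tied-rank targets.  Afterwards every column has the identical sorted
    value vector.
    """
    if matrix.state not in ("log", "quantile_normalized"):
        raise ValueError(f"quantile_normalize requires state 'log', got {matrix.state!r}")
    X = matrix.values
    if X.shape[1] < 2:
        raise ValueError("quantile normalization needs at least 2 columns")
    targets = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        col = X[:, j]
        order = np.argsort(col, kind="stable")
        assigned = np.empty(len(col))
        assigned[order] = targets
        # average targets over ties within the column
        _, inv = np.unique(col, return_inverse=True)
        sums = np.bincount(inv, weights=assigned)
        cnts = np.bincount(inv)
        out[:, j] = (sums / cnts)[inv]
    df = pd.DataFrame(out, index=matrix.df.index, columns=matrix.df.columns)
    return replace(matrix, df=df, state="quantile_normalized")


def filter_by_max(matrix: AbundanceMatrix, threshold: float) -> AbundanceMatrix:
    """Keep rows whose maximum over samples is strictly above ``threshold``."""
    keep = matrix.df.max(axis=1) > threshold
    return replace(matrix, df=matrix.df.loc[keep])
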