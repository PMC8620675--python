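"""Synthetic multi-species studies with planted repeat families.

The generator emulates the statistical structure the downstream analysis
assumes: each species genome is an i.i.d. uniform background into which
copies of shared repeat-family consensus sequences are inserted, with the
copy number varying by species (taxon-specific repeat amplification).
Whole-genome reads are drawn uniformly from both strands with independent
per-base substitution errors.  No indels, no quality model, no nesting:
the k-mer machinery under test tolerates substitutions naturally and none
of the defined computations exercise indel realism.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .io import Read, SampleEntry, SampleManifest, write_fastq

__all__ = [
    "RepeatFamilySpec",
    "StudySpec",
    "StudyData",
    "simulate_genome",
    "simulate_reads",
    "make_study",
    "write_study",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class RepeatFamilySpec:
    """A planted repeat family: one consensus, species-specific copy numbers.

    ``divergence`` is the per-copy, per-base substitution rate away from the
    consensus, applied independently to every planted copy.
    """

    family_id: str
    consensus_length: int
    copy_number_by_species: Mapping[str, int]
    divergence: float = 0.02

    def __post_init__(self) -> None:
        if self.consensus_length < 30:
            raise ValueError("consensus_length must be >= 30")
        if any(c < 0 for c in self.copy_number_by_species.values()):
            raise ValueError("copy numbers must be >= 0")
        if not 0.0 <= self.divergence <= 1.0:
            raise ValueError("divergence must lie in [0, 1]")


@dataclass(frozen=True)
class StudySpec:
    """Design of a synthetic multi-species sequencing study."""

    species: tuple[str, ...]
    replicates: int
    background_length: int
    families: tuple[RepeatFamilySpec, ...]
    read_length: int = 100
    depth: float = 20.0
    error_rate: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.depth <= 0:
            raise ValueError("depth must be > 0")
        if not 0.0 <= self.error_rate <= 0.2:
            raise ValueError("error_rate must lie in [0, 0.2]")

    @classmethod
    def from_config(cls, config: Mapping) -> "StudySpec":
        fams = tuple(
            RepeatFamilySpec(
                family_id=f["family_id"],
                consensus_length=int(f["consensus_length"]),
                copy_number_by_species={k: int(v) for k, v in f["copy_number_by_species"].items()},
                divergence=float(f.get("divergence", 0.02)),
            )
            for f in config["families"]
        )
        return cls(
            species=tuple(config["species"]),
            replicates=int(config["replicates"]),
            background_length=int(config["background_length"]),
            families=fams,
            read_length=int(config.get("read_length", 100)),
            depth=float(config.get("depth", 20.0)),
            error_rate=float(config.get("error_rate", 0.005)),
            seed=int(config["seed"]),
        )


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode()


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    if len(hits):
        # substitute with one of the three other bases
        shift = rng.integers(1, 4, size=len(hits))
        idx = np.searchsorted(_BASES, arr[hits])
        arr[hits] = _BASES[(idx + shift) % 4]
    return arr.tobytes().decode()


def family_consensi(spec: StudySpec) -> dict[str, str]:
    """Consensus sequence of every family, derived deterministically from the
    study seed so all species plant copies of the same consensus."""
    out = {}
    for i, fam in enumerate(spec.families):
        rng = np.random.default_rng([spec.seed, 7001, i])
        out[fam.family_id] = _random_seq(rng, fam.consensus_length)
    return out


def simulate_genome(
    spec: StudySpec, species: str, seed: int
) -> tuple[str, list[tuple[str, int, int]]]:
    """One species genome: uniform background with planted family copies.

    Copies (consensus mutated at each family's divergence rate) are spliced
    into the background at uniformly random positions, so inserts never
    overlap and the genome length equals background plus total insert
    length.  Returns the genome and truth intervals ``(family_id, start,
    end)`` in final 0-based half-open coordinates.
    """
    if species not in spec.species:
        raise ValueError(f"unknown species {species!r}")
    consensi = family_consensi(spec)
    copies: list[tuple[str, str]] = []
    rng = np.random.default_rng([seed, 11])
    total_insert = 0
    for fam in spec.families:
        n = fam.copy_number_by_species.get(species, 0)
        for _ in range(n):
            copies.append((fam.family_id, _mutate(rng, consensi[fam.family_id], fam.divergence)))
        total_insert += n * fam.consensus_length
    if total_insert > 0.5 * spec.background_length:
        raise ValueError(
            f"total insert length {total_insert} exceeds half the background "
            f"length {spec.background_length}; genome would be repeat-saturated"
        )
    background = _random_seq(rng, spec.background_length)
    # uniform insertion points into the background, applied left to right
    points = np.sort(rng.integers(0, spec.background_length + 1, size=len(copies)))
    order = rng.permutation(len(copies))
    parts: list[str] = []
    truth: list[tuple[str, int, int]] = []
    prev = 0
    out_len = 0
    for point, j in zip(points, order):
        parts.append(background[prev:point])
        out_len += point - prev
        fam_id, copy_seq = copies[j]
        truth.append((fam_id, out_len, out_len + len(copy_seq)))
        parts.append(copy_seq)
        out_len += len(copy_seq)
        prev = point
    parts.append(background[prev:])
    genome = "".join(parts)
    truth.sort(key=lambda t: t[1])
    return genome, truth


def simulate_reads(
    genome: str,
    read_length: int,
    depth: float,
    error_rate: float,
    seed: int,
    id_prefix: str = "r",
) -> list[Read]:
    """Uniform-coverage substitution-error reads from both strands.

    Read count is ``round(depth * len(genome) / read_length)``; start
    positions and strands are uniform; each base is substituted
    independently with probability ``error_rate``.
    """
    if read_length > len(genome):
        raise ValueError("read_length exceeds genome length")
    n_reads = int(round(depth * len(genome) / read_length))
    rng = np.random.default_rng([seed, 13])
    starts = rng.integers(0, len(genome) - read_length + 1, size=n_reads)
    strands = rng.integers(0, 2, size=n_reads)
    garr = np.frombuffer(genome.encode(), dtype=np.uint8)
    comp = np.zeros(256, dtype=np.uint8)
    for a, b in zip(b"ACGTN", b"TGCAN"):
        comp[a] = b
    reads: list[Read] = []
    for i in range(n_reads):
        s = int(starts[i])
        arr = garr[s : s + read_length]
        if strands[i]:
            arr = comp[arr][::-1]
        seq = arr.tobytes().decode()
        if error_rate > 0:
            seq = _mutate(rng, seq, error_rate)
        reads.append(Read(f"{id_prefix}_{i}", seq))
    return reads


@dataclass
class StudyData:
    """In-memory synthetic study: reads per sample plus ground truth."""

    spec: StudySpec
    manifest: SampleManifest
    reads: dict[str, list[Read]]  # sample_id -> reads
    truth: pd.DataFrame  # families x samples planted copy numbers
    consensi: dict[str, str]
    genomes: dict[str, str] = field(default_factory=dict)


def make_study(spec: StudySpec) -> StudyData:
    """Simulate one genome per species and one read set per replicate.

    The truth table records the planted copy number of every family in every
    sample (identical across replicates of a species, by construction).
    """
    consensi = family_consensi(spec)
    entries: list[SampleEntry] = []
    reads: dict[str, list[Read]] = {}
    genomes: dict[str, str] = {}
    truth_cols: dict[str, dict[str, int]] = {}
    for si, species in enumerate(spec.species):
        genome, _ = simulate_genome(spec, species, seed=int(spec.seed) * 1000 + si)
        genomes[species] = genome
        for rep in range(1, spec.replicates + 1):
            sample_id = f"{species}_rep{rep}"
            entries.append(SampleEntry(sample_id, species, rep, f"{sample_id}.fastq", "fastq"))
            reads[sample_id] = simulate_reads(
                genome,
                spec.read_length,
                spec.depth,
                spec.error_rate,
                seed=int(spec.seed) * 100000 + si * 100 + rep,
                id_prefix=sample_id,
            )
            truth_cols[sample_id] = {
                fam.family_id: fam.copy_number_by_species.get(species, 0)
                for fam in spec.families
            }
    truth = pd.DataFrame(truth_cols)
    truth = truth.loc[[f.family_id for f in spec.families], [e.sample_id for e in entries]]
    return StudyData(spec, SampleManifest(entries), reads, truth, consensi, genomes)


def write_study(study: StudyData, out_dir: str | Path) -> SampleManifest:
    """Materialize a study: FASTQ per sample, manifest TSV, truth TSV,
    family consensus FASTA, and the resolved spec as JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    for e in study.manifest.entries:
        path = out / f"{e.sample_id}.fastq"
        write_fastq(study.reads[e.sample_id], path)
        entries.append(SampleEntry(e.sample_id, e.species, e.replicate, str(path), "fastq"))
    manifest = SampleManifest(entries)
    manifest.to_tsv(out / "manifest.tsv")
    study.truth.to_csv(out / "truth_copy_number.tsv", sep="\t")
    with open(out / "family_consensus.fasta", "w") as fh:
        for fid, seq in study.consensi.items():
            fh.write(f">{fid}\n{seq}\n")
    spec = study.spec
    resolved = {
        "species": list(spec.species),
        "replicates": spec.replicates,
        "background_length": spec.background_length,
        "read_length": spec.read_length,
        "depth": spec.depth,
        "error_rate": spec.error_rate,
        "seed": spec.seed,
        "families": [
            {
                "family_id": f.family_id,
                "consensus_length": f.consensus_length,
                "copy_number_by_species": dict(f.copy_number_by_species),
                "divergence": f.divergence,
            }
            for f in spec.families
        ],
    }
    with open(out / "study_spec.json", "w") as fh:
        json.dump(resolved, fh, indent=2)
    return manifest
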