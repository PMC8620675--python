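"""End-to-end pipeline: subsample -> discover -> annotate -> quantify ->
normalize/filter -> ordinate -> tree, with every stage's randomness derived
from one config seed and the fully resolved config emitted beside the
outputs."""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from . import analyze, annotate, phylo, quantify
from .io import Read, SampleManifest, read_sequences, write_fasta
from .kchain import DiscoveryParams, KChain, discover

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """All stage parameters of one pipeline run."""

    # discovery
    k_values: tuple[int, ...] = (12, 15)
    discovery_fraction: float = 0.10
    min_density: float = 0.5
    min_kmers: int = 5
    min_reads: int = 10
    max_clusters: int = 10_000
    min_kmer_reads: int = 2
    min_length: int = 30
    # optional per-sample size normalization before anything else
    target_bases: int | None = None
    # annotation
    containment_k: int = 12
    containment_threshold: float = 0.5
    # quantification / normalization
    seed_k: int = 12
    min_identity: float = 0.9
    statistic: str = "median"
    pseudo: float = 1.0
    filter_threshold: float = 665.0  # kChain-path default; 150 for known-RE path
    filter_stage: str = "raw"  # "raw" | "normalized"
    # tree
    metric: str = "euclidean"
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, default=list)


@dataclass
class PipelineResult:
    out_dir: Path
    kchains: list[KChain]
    bins: dict[str, list[KChain]]
    matrices: dict[str, dict[str, quantify.AbundanceMatrix]] = field(default_factory=dict)
    trees: dict[str, str] = field(default_factory=dict)
    files: list[Path] = field(default_factory=list)


def _load_reads(manifest: SampleManifest) -> dict[str, list[Read]]:
    return {
        e.sample_id: list(read_sequences(e.path, e.format)) for e in manifest.entries
    }


def _analysis_track(
    label: str,
    refs: Sequence[KChain],
    reads_by_sample: Mapping[str, Sequence[Read]],
    manifest: SampleManifest,
    config: PipelineConfig,
    out: Path,
    result: PipelineResult,
) -> None:
    """Quantify one kChain bin across all samples and run the downstream
    ordination + tree if enough rows survive filtering."""
    ref_pairs = [(c.id, c.seq) for c in refs]
    profiles = {
        sid: quantify.map_reads(reads, ref_pairs, config.seed_k, config.min_identity)
        for sid, reads in reads_by_sample.items()
    }
    raw = quantify.build_matrix(manifest, ref_pairs, profiles, config.statistic)
    raw.to_tsv(out / f"{label}_abundance_raw.tsv")
    if config.filter_stage == "raw":
        raw_f = quantify.filter_by_max(raw, config.filter_threshold)
        norm = quantify.quantile_normalize(quantify.log_transform(raw_f, config.pseudo))
    else:
        norm = quantify.quantile_normalize(quantify.log_transform(raw, config.pseudo))
        norm = quantify.filter_by_max(norm, config.filter_threshold)
    norm.to_tsv(out / f"{label}_abundance_normalized.tsv")
    result.matrices[label] = {"raw": raw, "normalized": norm}
    result.files += [out / f"{label}_abundance_raw.tsv", out / f"{label}_abundance_normalized.tsv"]
    n_rows, n_cols = norm.df.shape
    if n_rows < 2 or n_cols < 2:
        logger.warning("%s: %d repeats after filtering; skipping ordination/tree", label, n_rows)
        return
    pca_res = analyze.pca(norm, n_components=min(2, n_rows, n_cols))
    pca_res.sample_scores.to_csv(out / f"{label}_pca_sample_scores.tsv", sep="\t")
    pca_res.repeat_coords.to_csv(out / f"{label}_pca_repeat_coords.tsv", sep="\t")
    with open(out / f"{label}_pca_variance.tsv", "w") as fh:
        fh.write("component\tvariance_fraction\n")
        for i, v in enumerate(pca_res.variance_fraction):
            fh.write(f"PC{i + 1}\t{v:.10g}\n")
    assignment = analyze.assign_max_species(norm)
    assignment.species.rename("species").to_csv(out / f"{label}_assignment.tsv", sep="\t")
    dm = phylo.abundance_distance(norm, config.metric)
    tree = phylo.neighbor_joining(dm)
    newick = phylo.write_newick(tree, out / f"{label}_tree.nwk")
    result.trees[label] = newick
    result.files += [
        out / f"{label}_pca_sample_scores.tsv",
        out / f"{label}_pca_repeat_coords.tsv",
        out / f"{label}_pca_variance.tsv",
        out / f"{label}_assignment.tsv",
        out / f"{label}_tree.nwk",
    ]


def run_pipeline(
    manifest: SampleManifest,
    config: PipelineConfig,
    out_dir: str | Path,
    contaminants: Mapping[str, str | Path] | None = None,
    reads_by_sample: Mapping[str, Sequence[Read]] | None = None,
) -> PipelineResult:
    """Run the full workflow and write all declared outputs to ``out_dir``.

    ``contaminants`` maps labels (e.g. "chloroplast") to reference FASTA
    paths; when given, the chloroplast bin gets its own analysis track in
    addition to the nuclear one.  ``reads_by_sample`` may inject already
    loaded reads (the simulator's in-memory studies); otherwise reads come
    from the manifest paths.
    """
    t0 = time.time()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result = PipelineResult(out, [], {})
    current = ["start"]

    def stage(name):
        current[0] = name
        logger.info("[%7.1fs] stage: %s", time.time() - t0, name)

    try:
        stage("load")
        if reads_by_sample is None:
            reads_by_sample = _load_reads(manifest)
        if config.target_bases is not None:
            from .io import subsample_reads

            reads_by_sample = {
                sid: subsample_reads(reads, config.target_bases, seed=config.seed)
                for sid, reads in reads_by_sample.items()
            }
        pooled: list[Read] = []
        for e in manifest.entries:
            pooled.extend(reads_by_sample[e.sample_id])

        stage("discover")
        params = DiscoveryParams(
            k_values=config.k_values,
            discovery_fraction=config.discovery_fraction,
            min_density=config.min_density,
            min_kmers=config.min_kmers,
            min_reads=config.min_reads,
            max_clusters=config.max_clusters,
            min_kmer_reads=config.min_kmer_reads,
            min_length=config.min_length,
            seed=config.seed,
        )
        kchains = discover(pooled, params)
        result.kchains = kchains
        write_fasta(kchains, out / "kchains.fasta")
        result.files.append(out / "kchains.fasta")
        logger.info("discovered %d kChains", len(kchains))

        stage("annotate")
        indexes = []
        for label, path in sorted((contaminants or {}).items()):
            indexes.append(
                annotate.build_contaminant_index(path, label, config.containment_k)
            )
        bins = annotate.partition_library(kchains, indexes, config.containment_threshold)
        result.bins = bins
        with open(out / "annotation.tsv", "w") as fh:
            fh.write("kchain_id\tlabel\tcontainment\n")
            for chain in kchains:
                label, c = annotate.classify_kchain(
                    chain.seq, indexes, config.containment_threshold
                )
                fh.write(f"{chain.id}\t{label}\t{c:.4f}\n")
        result.files.append(out / "annotation.tsv")

        tracks = [("nuclear", bins[annotate.NUCLEAR])]
        if contaminants and "chloroplast" in bins and bins["chloroplast"]:
            tracks.append(("chloroplast", bins["chloroplast"]))
        for label, refs in tracks:
            if not refs:
                logger.warning("no kChains in bin %r; skipping track", label)
                continue
            stage(f"quantify/{label}")
            _analysis_track(label, refs, reads_by_sample, manifest, config, out, result)

        with open(out / "pipeline_config.json", "w") as fh:
            fh.write(config.to_json())
        result.files.append(out / "pipeline_config.json")
        logger.info("pipeline finished in %.1fs", time.time() - t0)
        return result
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {current[0]!r}: {exc}") from exc
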