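"""PCA biplot of the normalized abundance matrix and repeat-species
association.

Repeats (rows) are the observations and samples (columns) the variables.
After column-mean centering, an exact SVD places repeats at their principal
coordinates (U*S) and samples at their singular-value-scaled loadings (V*S),
so both occupy the same plane: a repeat sits near the samples in which it is
most abundant.  Each repeat is additionally assigned to the species with the
highest replicate-mean abundance, and the assignment is validated
geometrically by the distance between the repeat and the sample centroid of
its species on the PC1-PC2 plane.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .quantify import AbundanceMatrix

__all__ = [
    "PCAResult",
    "SpeciesAssignment",
    "pca",
    "assign_max_species",
    "profile_summary",
    "biplot_association",
]


@dataclass(frozen=True)
class PCAResult:
    """Dual coordinates of repeats (rows) and samples (columns).

    ``sample_scores`` are singular-value-scaled loadings (V*S),
    ``repeat_coords`` principal coordinates (U*S), and ``loadings`` the
    unit-norm right singular vectors for display.  ``variance_fraction``
    entries are each component's share of the total centered variance, so
    they sum to 1 over all ``min(rows, cols)`` components.
    """

    sample_scores: pd.DataFrame  # samples x C
    repeat_coords: pd.DataFrame  # repeats x C
    loadings: pd.DataFrame  # samples x C, unit norm
    variance_fraction: np.ndarray  # length C


@dataclass(frozen=True)
class SpeciesAssignment:
    """Per-repeat argmax species with the per-species replicate means."""

    species: pd.Series  # repeat -> species
    max_mean: pd.Series  # repeat -> mean abundance in the assigned species
    species_means: pd.DataFrame  # repeats x species
    zero_rows: pd.Index  # repeats with all-zero profiles (flagged)


def pca(matrix: AbundanceMatrix, n_components: int = 2) -> PCAResult:
    """Exact SVD-based PCA of the (normalized) abundance matrix.

    Sign convention: each component's loading vector has its
    largest-magnitude entry positive, making the decomposition
    deterministic.
    """
    if matrix.state not in ("log", "quantile_normalized"):
        raise ValueError("pca expects a log or quantile-normalized matrix")
    X = matrix.values
    n_rows, n_cols = X.shape
    if n_components > min(n_rows, n_cols):
        raise ValueError("n_components exceeds min(rows, cols)")
    Xc = X - X.mean(axis=0, keepdims=True)
    if not np.any(Xc):
        raise ValueError("matrix is constant per column; no variance to decompose")
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    # fixed sign: largest-|.| loading entry positive per component
    for i in range(len(S)):
        j = int(np.argmax(np.abs(Vt[i])))
        if Vt[i, j] < 0:
            Vt[i] = -Vt[i]
            U[:, i] = -U[:, i]
    var = S**2
    var_frac = var / var.sum()
    C = n_components
    comps = [f"PC{i + 1}" for i in range(C)]
    rows, cols = matrix.df.index, matrix.df.columns
    return PCAResult(
        sample_scores=pd.DataFrame(Vt[:C].T * S[:C], index=cols, columns=comps),
        repeat_coords=pd.DataFrame(U[:, :C] * S[:C], index=rows, columns=comps),
        loadings=pd.DataFrame(Vt[:C].T, index=cols, columns=comps),
        variance_fraction=var_frac[:C],
    )


def _species_means(matrix: AbundanceMatrix) -> pd.DataFrame:
    meta = matrix.sample_meta
    groups: dict[str, list[str]] = {}
    for s in matrix.col_ids:
        groups.setdefault(meta[s][0], []).append(s)
    means = {sp: matrix.df[cols].mean(axis=1) for sp, cols in sorted(groups.items())}
    return pd.DataFrame(means)


def assign_max_species(
    matrix: AbundanceMatrix, sample_meta: Mapping[str, tuple[str, int]] | None = None
) -> SpeciesAssignment:
    """Assign each repeat to the species with the highest replicate-mean
    abundance; exact ties (including all-zero rows) go to the
    lexicographically first species."""
    if sample_meta is not None:
        matrix = AbundanceMatrix(matrix.df, matrix.state, sample_meta)
    means = _species_means(matrix)  # columns already sorted lexicographically
    assigned = means.idxmax(axis=1)  # first occurrence wins ties
    max_mean = means.max(axis=1)
    zero = matrix.df.index[(matrix.df == 0).all(axis=1)]
    return SpeciesAssignment(assigned, max_mean, means, zero)


def profile_summary(
    matrix: AbundanceMatrix, assignment: SpeciesAssignment, focus_species: str
) -> pd.Series:
    """Mean abundance, per sample, of the repeats assigned to one species.

    Reveals asymmetric sharing: repeats most abundant in one species may
    still be highly abundant in a sister species.
    """
    if focus_species not in assignment.species_means.columns:
        raise ValueError(f"unknown species {focus_species!r}")
    rows = assignment.species.index[assignment.species == focus_species]
    if len(rows) == 0:
        warnings.warn(f"no repeats assigned to {focus_species!r}; empty profile")
        return pd.Series(dtype=float)
    return matrix.df.loc[rows].mean(axis=0)


def biplot_association(
    pca_result: PCAResult, assignment: SpeciesAssignment, sample_meta: Mapping
) -> tuple[pd.Series, pd.DataFrame]:
    """Distance of each repeat to its assigned species' sample centroid on
    the PC1-PC2 plane, plus a per-species summary of mean distances.

    The per-species summary rows are assigned species; columns are the
    species whose sample centroid the distance is measured to, so the
    diagonal being columnwise-minimal expresses the repeat-species
    association the biplot shows.
    """
    if pca_result.sample_scores.shape[1] < 2:
        raise ValueError("biplot association needs at least 2 components")
    scores = pca_result.sample_scores[["PC1", "PC2"]]
    coords = pca_result.repeat_coords[["PC1", "PC2"]]
    centroids = {}
    for sample in scores.index:
        centroids.setdefault(sample_meta[sample][0], []).append(scores.loc[sample].to_numpy())
    centroids = {sp: np.mean(v, axis=0) for sp, v in sorted(centroids.items())}
    dist_own = pd.Series(index=coords.index, dtype=float)
    all_species = sorted(centroids)
    table = np.zeros((len(all_species), len(all_species)))
    counts = np.zeros(len(all_species))
    sp_pos = {sp: i for i, sp in enumerate(all_species)}
    for rid in coords.index:
        own = assignment.species.loc[rid]
        p = coords.loc[rid].to_numpy()
        dist_own.loc[rid] = float(np.linalg.norm(p - centroids[own]))
        i = sp_pos[own]
        counts[i] += 1
        for sp, c in centroids.items():
            table[i, sp_pos[sp]] += float(np.linalg.norm(p - c))
    with np.errstate(invalid="ignore"):
        table = table / counts[:, None]
    summary = pd.DataFrame(table, index=all_species, columns=all_species)
    return dist_own, summary
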