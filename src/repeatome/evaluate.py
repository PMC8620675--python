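"""Truth-based evaluation helpers for synthetic studies.

Used by the test suite and the reproduction script to compare pipeline
output against the planted ground truth: alignment identity of discovered
chains to family consensi (via edlib infix alignment), rank agreement of
raw abundance with planted copy number, species coherence of the PCA plane,
and monophyly of species in the abundance tree.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import edlib
import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .analyze import PCAResult
from .io import revcomp
from .kchain import KChain
from .phylo import is_monophyletic
from .quantify import AbundanceMatrix

__all__ = [
    "infix_identity",
    "family_recovery",
    "copy_number_spearman",
    "nearest_neighbor_species_fraction",
    "species_monophyly_fraction",
]


def infix_identity(query: str, target: str) -> float:
    """Best identity of the full query aligned anywhere inside the target
    (both strands): 1 - edit_distance / len(query)."""
    best = 0.0
    for q in (query, revcomp(query)):
        d = edlib.align(q, target, mode="HW", task="distance")["editDistance"]
        best = max(best, 1.0 - d / len(q))
    return best


def family_recovery(
    kchains: Sequence[KChain],
    consensi: Mapping[str, str],
    min_identity: float = 0.9,
    min_length: int = 30,
) -> pd.DataFrame:
    """Per family: the best identity achieved by any chain of at least
    ``min_length`` bp, the chain's id, and whether the family counts as
    recovered at the identity threshold."""
    rows = []
    for fam, consensus in consensi.items():
        best_id, best_chain = 0.0, None
        for chain in kchains:
            if chain.length < min_length:
                continue
            ident = infix_identity(chain.seq, consensus)
            if ident > best_id:
                best_id, best_chain = ident, chain.id
        rows.append(
            {
                "family_id": fam,
                "best_identity": best_id,
                "best_chain": best_chain,
                "recovered": best_id >= min_identity,
            }
        )
    return pd.DataFrame(rows).set_index("family_id")


def copy_number_spearman(raw_matrix: AbundanceMatrix, truth: pd.DataFrame) -> pd.Series:
    """Spearman correlation, per family, of planted copy number vs raw
    abundance across samples.  Row ids of the matrix must match the truth
    table's family ids (i.e. abundance quantified against the planted
    consensi)."""
    out = {}
    for fam in truth.index:
        if fam not in raw_matrix.df.index:
            out[fam] = np.nan
            continue
        cols = [c for c in truth.columns if c in raw_matrix.df.columns]
        rho, _ = spearmanr(truth.loc[fam, cols], raw_matrix.df.loc[fam, cols])
        out[fam] = float(rho)
    return pd.Series(out, name="spearman")


def nearest_neighbor_species_fraction(
    pca_result: PCAResult, sample_meta: Mapping[str, tuple[str, int]]
) -> float:
    """Fraction of samples whose nearest neighbor on the PC1-PC2 plane is a
    replicate of the same species."""
    scores = pca_result.sample_scores[["PC1", "PC2"]]
    samples = list(scores.index)
    X = scores.to_numpy()
    hits = 0
    for i, s in enumerate(samples):
        d = np.linalg.norm(X - X[i], axis=1)
        d[i] = np.inf
        j = int(np.argmin(d))
        if sample_meta[samples[j]][0] == sample_meta[s][0]:
            hits += 1
    return hits / len(samples)


def species_monophyly_fraction(tree, sample_meta: Mapping[str, tuple[str, int]]) -> float:
    """Fraction of species whose replicates form a monophyletic group."""
    groups: dict[str, list[str]] = {}
    for sample, (species, _) in sample_meta.items():
        groups.setdefault(species, []).append(sample)
    ok = sum(1 for labels in groups.values() if is_monophyletic(tree, labels))
    return ok / len(groups)
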