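"""Reaction-content comparison of metabolic models.

Models are reduced to binary presence/absence vectors over the union of
intracellular metabolic reactions in compartments shared by all models,
clustered under a sweep of dissimilarity measures and agglomerative linkage
methods, and the resulting dendrograms scored by the cophenetic correlation
coefficient (Pearson correlation between the original pairwise
dissimilarities and the dendrogram's merge-height distances). Clade support
counts in how many of the measure x method trees a given group of models
forms an exact clade.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cophenet, linkage, to_tree
from scipy.spatial.distance import pdist, squareform

from .model_core import ModelValidationError

__all__ = [
    "DISSIMILARITY_MEASURES",
    "LINKAGE_METHODS",
    "CopheneticResult",
    "build_reaction_matrix",
    "reaction_dissimilarity",
    "agglomerate",
    "cophenetic_correlation",
    "clade_support",
    "dendrogram_to_newick",
]

#: The 16 binary-profile dissimilarity measures of the comparison sweep.
DISSIMILARITY_MEASURES: tuple[str, ...] = (
    "jaccard", "dice", "hamming", "rogerstanimoto", "sokalsneath",
    "russellrao", "yule", "kulczynski1",
    "euclidean", "cityblock", "cosine", "correlation", "chebyshev",
    "canberra", "braycurtis", "sqeuclidean",
)

LINKAGE_METHODS: tuple[str, ...] = ("single", "complete", "average", "weighted", "ward")

_SHARED_COMPARTMENTS = ("c", "m", "x")  # cytosol, mitochondrion, peroxisome


def build_reaction_matrix(
    models: dict[str, "cobra.Model"],
    compartments: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Binary model x reaction presence matrix over shared compartments.

    Keeps intracellular metabolic reactions (no boundary reactions) whose
    metabolites all live in ``compartments`` (default: cytosol,
    mitochondrion and peroxisome intersected with the compartments every
    model actually has). Models must share a reaction id namespace.
    """
    if not models:
        raise ModelValidationError("no models given")
    if compartments is None:
        shared = set(_SHARED_COMPARTMENTS)
        for model in models.values():
            shared &= {m.compartment for m in model.metabolites}
        compartments = tuple(sorted(shared))
    if not compartments:
        raise ModelValidationError("models share no intracellular compartments")
    rows = {}
    for name, model in models.items():
        kept = set()
        for rxn in model.reactions:
            if len(rxn.metabolites) == 1:
                continue
            comps = {m.compartment for m in rxn.metabolites}
            if comps <= set(compartments):
                kept.add(rxn.id)
        rows[name] = kept
    reactions = sorted(set().union(*rows.values()))
    data = [[1 if rid in rows[name] else 0 for rid in reactions] for name in rows]
    return pd.DataFrame(data, index=list(rows), columns=reactions, dtype=int)


def _kulczynski1(matrix: np.ndarray) -> np.ndarray:
    """Kulczynski (1927) dissimilarity for boolean rows: (b + c) / a, with a
    the count of shared 1s and b, c the one-sided mismatches (removed from
    scipy 1.17)."""
    X = matrix.astype(bool)
    n = X.shape[0]
    out = np.zeros(n * (n - 1) // 2)
    idx = 0
    for i in range(n):
        for j in range(i + 1, n):
            a = np.sum(X[i] & X[j])
            bc = np.sum(X[i] ^ X[j])
            out[idx] = bc / a if a > 0 else np.inf
            idx += 1
    return out


def reaction_dissimilarity(matrix: pd.DataFrame, measure: str) -> pd.DataFrame:
    """Pairwise model dissimilarities under one registry measure.

    Returns a symmetric zero-diagonal DataFrame. Non-finite values (possible
    for ratio-based measures on degenerate profiles) are replaced by the
    largest finite distance observed, keeping downstream linkage defined.
    """
    if measure not in DISSIMILARITY_MEASURES:
        raise ModelValidationError(
            f"unknown measure {measure!r}; registry: {sorted(DISSIMILARITY_MEASURES)}"
        )
    X = matrix.values
    if measure == "kulczynski1":
        condensed = _kulczynski1(X)
    elif measure in ("jaccard", "dice", "hamming", "rogerstanimoto",
                     "sokalsneath", "russellrao", "yule"):
        condensed = pdist(X.astype(bool), metric=measure)
    else:
        condensed = pdist(X.astype(float), metric=measure)
    condensed = np.asarray(condensed, dtype=float)
    bad = ~np.isfinite(condensed)
    if bad.any():
        finite = condensed[~bad]
        condensed[bad] = finite.max() if finite.size else 1.0
    dist = squareform(condensed)
    return pd.DataFrame(dist, index=matrix.index, columns=matrix.index)


def agglomerate(distances: pd.DataFrame, method: str) -> np.ndarray:
    """Agglomerative linkage tree (scipy linkage matrix) from a square
    dissimilarity matrix. Ties follow scipy's deterministic lowest-index
    ordering."""
    if method not in LINKAGE_METHODS:
        raise ModelValidationError(
            f"unknown linkage method {method!r}; choose from {LINKAGE_METHODS}"
        )
    condensed = squareform(np.asarray(distances, dtype=float), checks=False)
    return linkage(condensed, method=method)


@dataclass
class CopheneticResult:
    ccc: float
    input_distances: pd.DataFrame
    cophenetic_distances: pd.DataFrame
    mean_input: float
    mean_cophenetic: float


def cophenetic_correlation(distances: pd.DataFrame, tree: np.ndarray) -> CopheneticResult:
    """Cophenetic correlation coefficient of a dendrogram.

    Pearson correlation between the strict upper triangles of the input
    dissimilarity matrix x(i,j) and the cophenetic (merge-height) matrix
    t(i,j). Degenerate variance in either raises an explicit error rather
    than propagating NaN.
    """
    x = squareform(np.asarray(distances, dtype=float), checks=False)
    if len(x) < 3:
        raise ModelValidationError("need at least 3 leaves")
    t = cophenet(tree)
    xc = x - x.mean()
    tc = t - t.mean()
    denom = np.sqrt((xc**2).sum() * (tc**2).sum())
    if denom <= 0:
        raise ModelValidationError("degenerate variance: CCC undefined")
    ccc = float((xc * tc).sum() / denom)
    labels = distances.index
    return CopheneticResult(
        ccc=ccc,
        input_distances=distances,
        cophenetic_distances=pd.DataFrame(squareform(t), index=labels, columns=labels),
        mean_input=float(x.mean()),
        mean_cophenetic=float(t.mean()),
    )


def _clades(tree: np.ndarray, labels: list[str]) -> set[frozenset[str]]:
    root = to_tree(tree)
    clades: set[frozenset[str]] = set()

    def leafset(node):
        if node.is_leaf():
            s = frozenset({labels[node.id]})
        else:
            s = leafset(node.left) | leafset(node.right)
        clades.add(s)
        return s

    leafset(root)
    return clades


def clade_support(
    matrix: pd.DataFrame,
    group: set[str],
    measures: tuple[str, ...] = DISSIMILARITY_MEASURES,
    methods: tuple[str, ...] = LINKAGE_METHODS,
) -> tuple[float, int, int]:
    """Fraction of measure x method trees in which ``group`` is an exact clade.

    Returns (fraction, supporting trees, total trees). Groups equal to a
    single leaf or to all models are clades in every tree by construction.
    """
    names = list(matrix.index)
    if not set(group) <= set(names):
        raise ModelValidationError("group contains unknown model names")
    target = frozenset(group)
    total = 0
    hits = 0
    for measure in measures:
        dist = reaction_dissimilarity(matrix, measure)
        for method in methods:
            tree = agglomerate(dist, method)
            total += 1
            if target in _clades(tree, names):
                hits += 1
    return hits / total, hits, total


def dendrogram_to_newick(tree: np.ndarray, labels: list[str]) -> str:
    """Newick string (with branch lengths from merge heights) for a linkage tree."""
    root = to_tree(tree)

    def render(node, parent_height):
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:g}"

    return render(root, root.dist) + ";"
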