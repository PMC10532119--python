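"""Interaction-matrix assembly, hierarchical clustering, bootstrap stability.

The strain-by-strain interaction matrix (one per growth parameter) is
symmetric with a zero diagonal.  Rows are clustered by complete-linkage
agglomeration on Euclidean distances between index profiles, and each
cluster's robustness is scored by its mean Jaccard similarity to the best
matching cluster across resampled re-clusterings (the clusterboot recipe):
``subset`` draws a fraction of strains without replacement, ``bootstrap``
resamples strains with replacement.  A mean Jaccard below 0.5 is
conventionally read as a dissolved (unstable) cluster.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .errors import AnalysisError, InputError

__all__ = [
    "InteractionMatrix",
    "ClusterStability",
    "build_matrix",
    "cluster_matrix",
    "bootstrap_stability",
    "linkage_to_newick",
]

DISSOLVED_THRESHOLD = 0.5


@dataclass(frozen=True)
class InteractionMatrix:
    """Symmetric strain x strain interaction-index matrix for one parameter."""

    parameter: str
    strains: tuple[str, ...]
    species: tuple[str, ...]
    values: np.ndarray
    significant: np.ndarray  # True where the outcome class is not A

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "significant", np.asarray(self.significant, dtype=bool))
        n = len(self.strains)
        if v.shape != (n, n):
            raise InputError(f"matrix shape {v.shape} does not match {n} strains")
        if not np.allclose(v, v.T, equal_nan=True):
            raise InputError("interaction matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise InputError("interaction matrix diagonal must be zero")

    @property
    def n(self) -> int:
        return len(self.strains)


@dataclass(frozen=True)
class ClusterStability:
    """Per-cluster mean Jaccard stability over resampled re-clusterings."""

    k: int
    assignments: dict[str, int]
    jaccard: dict[int, float]
    method: str
    B: int
    subset_fraction: float = 0.5

    def dissolved(self) -> list[int]:
        return [c for c, j in self.jaccard.items() if j < DISSOLVED_THRESHOLD]


def build_matrix(records, parameter: str) -> InteractionMatrix:
    """Assemble the symmetric index matrix from interaction records.

    Requires exactly one record per unordered strain pair; a missing or
    conflicting pair is an error.
    """
    recs = [r for r in records if r.parameter == parameter]
    if not recs:
        raise InputError(f"no interaction records for parameter {parameter!r}")
    strains = sorted({r.strain_1 for r in recs} | {r.strain_2 for r in recs})
    species = {}
    idx = {s: i for i, s in enumerate(strains)}
    n = len(strains)
    values = np.full((n, n), np.nan)
    np.fill_diagonal(values, 0.0)
    sig = np.zeros((n, n), dtype=bool)
    for r in recs:
        i, j = idx[r.strain_1], idx[r.strain_2]
        if not np.isnan(values[i, j]):
            raise InputError(f"duplicate interaction record for pair ({r.strain_1}, {r.strain_2})")
        values[i, j] = values[j, i] = r.index
        sig[i, j] = sig[j, i] = r.outcome != "A"
        species[r.strain_1] = r.species_1
        species[r.strain_2] = r.species_2
    missing = [(strains[i], strains[j]) for i in range(n) for j in range(i + 1, n) if np.isnan(values[i, j])]
    if missing:
        raise InputError(f"missing interaction records for pairs {missing[:5]}{'...' if len(missing) > 5 else ''}")
    return InteractionMatrix(parameter, tuple(strains), tuple(species.get(s, "") for s in strains), values, sig)


def _linkage(values: np.ndarray) -> np.ndarray:
    if len(values) < 2:
        raise AnalysisError("need at least 2 rows to cluster")
    return hierarchy.linkage(pdist(values, metric="euclidean"), method="complete")


def _canonical_labels(raw: np.ndarray, strains) -> dict[str, int]:
    """Renumber clusters 1..k in order of first appearance over sorted strains."""
    order = np.argsort(np.asarray(strains, dtype=object))
    mapping: dict[int, int] = {}
    for i in order:
        mapping.setdefault(int(raw[i]), len(mapping) + 1)
    return {s: mapping[int(raw[i])] for i, s in enumerate(strains)}


def cluster_matrix(matrix: InteractionMatrix, k: int):
    """Complete-linkage Euclidean clustering of index profiles, cut at ``k``.

    Returns ``(assignments, Z)`` where ``assignments`` maps strain to a
    cluster id in 1..k (ids ordered by lexicographic strain order) and
    ``Z`` is the scipy linkage matrix (the merge tree).
    """
    if k < 2 or k > matrix.n:
        raise AnalysisError(f"k must be in [2, {matrix.n}], got {k}")
    Z = _linkage(matrix.values)
    raw = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    return _canonical_labels(raw, matrix.strains), Z


def bootstrap_stability(matrix: InteractionMatrix, k: int, B: int, method: str = "subset",
                        seed: int = 0, subset_fraction: float = 0.5) -> ClusterStability:
    """Jaccard stability of each cluster under row resampling.

    Every resample is re-clustered at ``k`` (capped at the number of
    distinct resampled strains); each original cluster is scored by the
    maximum Jaccard similarity between its resampled members and any
    cluster of the resampled solution, averaged over all B iterations.
    A cluster with no member in a resample scores 0 for that iteration
    (it dissolved), following the reference bootmean convention — a
    singleton's stability is therefore capped near its resampling
    inclusion probability (~0.64 under bootstrap resampling of 15 rows),
    which is exactly why lone intermediate strains read as unstable.
    """
    if B < 1:
        raise AnalysisError(f"B must be >= 1, got {B}")
    if method not in ("subset", "bootstrap"):
        raise AnalysisError(f"unknown stability method {method!r}")
    assignments, _ = cluster_matrix(matrix, k)
    orig = {}
    for i, s in enumerate(matrix.strains):
        orig.setdefault(assignments[s], set()).add(i)

    rng = np.random.default_rng(seed)
    n = matrix.n
    sums = {c: 0.0 for c in orig}
    counts = {c: 0 for c in orig}
    for _ in range(B):
        if method == "bootstrap":
            idx = rng.integers(0, n, size=n)
        else:
            m = max(2, int(np.floor(subset_fraction * n)))
            idx = rng.choice(n, size=m, replace=False)
        uniq = sorted(set(int(i) for i in idx))
        if len(uniq) < 2:
            continue
        sub = matrix.values[idx]
        kk = min(k, len(uniq))
        raw = hierarchy.fcluster(_linkage(sub), t=kk, criterion="maxclust")
        new_clusters: dict[int, set[int]] = {}
        for pos, lab in enumerate(raw):
            new_clusters.setdefault(int(lab), set()).add(int(idx[pos]))
        drawn = set(uniq)
        for c, members in orig.items():
            inter = members & drawn
            if inter:
                sums[c] += max(len(inter & nc) / len(inter | nc) for nc in new_clusters.values())
            counts[c] += 1  # an absent cluster dissolved: scores 0
    jaccard = {c: (sums[c] / counts[c] if counts[c] else float("nan")) for c in orig}
    return ClusterStability(k=k, assignments=assignments, jaccard=jaccard,
                            method=method, B=B, subset_fraction=subset_fraction)


def linkage_to_newick(Z: np.ndarray, labels) -> str:
    """Export a scipy merge tree as a Newick string (heights as lengths)."""
    tree = hierarchy.to_tree(Z)

    def walk(node, parent_height):
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return walk(tree, tree.dist) + ";"
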