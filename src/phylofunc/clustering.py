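"""Functional dendrograms: hierarchical clustering of a distance matrix.

The dendrogram is exported as an ultrametric :class:`PhyloTree` whose node
heights are the merge heights (half the linkage merge distance), so the
tip-to-tip cophenetic distance on the exported tree equals the agglomerative
merge distance. The clustering method is selected by cophenetic correlation:
the Pearson correlation between the input distances and the distances implied
by the dendrogram, the standard yardstick for how faithfully a hierarchical
clustering represents the original dissimilarities.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
from scipy import stats
from scipy.cluster import hierarchy
from skbio import DistanceMatrix

from .tree import PhyloTree, cophenetic_matrix

__all__ = [
    "METHODS",
    "linkage",
    "cophenetic_correlation",
    "select_clustering",
    "ClusteringSelection",
]

#: Supported agglomeration methods, in tie-break priority order.
METHODS = ("single", "complete", "upgma", "wpgma", "ward")

_SCIPY_NAME = {
    "single": "single",
    "complete": "complete",
    "upgma": "average",
    "wpgma": "weighted",
    # Ward on a precomputed dissimilarity follows the Ward.D2 convention
    # (squared-distance objective), the scipy behaviour.
    "ward": "ward",
}


def linkage(dist: DistanceMatrix, method: str) -> PhyloTree:
    """Agglomerative clustering of ``dist``; returns an ultrametric tree.

    Tips sit at height 0; each merge creates an internal node at half the
    linkage merge distance, and every branch length is the height difference
    to the parent, so root-to-tip path lengths are all equal.
    """
    if method not in _SCIPY_NAME:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    condensed = dist.condensed_form()
    if np.isnan(condensed).any():
        raise ValueError("distance matrix contains NaN")
    z = hierarchy.linkage(condensed, method=_SCIPY_NAME[method])
    return _linkage_to_tree(z, list(dist.ids))


def _linkage_to_tree(z: np.ndarray, labels: list[str]) -> PhyloTree:
    n = len(labels)
    taxon_ns = dendropy.TaxonNamespace()
    nodes: list[dendropy.Node] = []
    heights: list[float] = []
    for lab in labels:
        nd = dendropy.Node()
        nd.taxon = taxon_ns.new_taxon(label=lab)
        nodes.append(nd)
        heights.append(0.0)
    for a, b, merge_dist, _count in z:
        h = float(merge_dist) / 2.0
        parent = dendropy.Node()
        for child_idx in (int(a), int(b)):
            child = nodes[child_idx]
            # clamp tiny negative slack from fp round-off on monotone methods
            child.edge.length = max(h - heights[child_idx], 0.0)
            parent.add_child(child)
        nodes.append(parent)
        heights.append(h)
    tree = dendropy.Tree(taxon_namespace=taxon_ns)
    tree.seed_node = nodes[-1]
    tree.seed_node.edge.length = 0.0
    return PhyloTree(tree)


def cophenetic_correlation(dist: DistanceMatrix, tree: PhyloTree) -> float:
    """Pearson r between input distances and the tree's cophenetic distances,
    over the n(n-1)/2 unordered tip pairs."""
    ids = sorted(dist.ids)
    if set(ids) != set(tree.tip_labels):
        raise ValueError("distance matrix and tree have different species sets")
    d1 = dist.filter(ids).condensed_form()
    d2 = cophenetic_matrix(tree).filter(ids).condensed_form()
    if np.ptp(d1) == 0 or np.ptp(d2) == 0:
        raise ValueError("zero variance in distances; correlation undefined")
    r, _ = stats.pearsonr(d1, d2)
    return float(r)


@dataclass(frozen=True)
class ClusteringSelection:
    """Outcome of clustering-method selection by cophenetic correlation."""

    method: str
    tree: PhyloTree
    correlations: dict[str, float]


def select_clustering(dist: DistanceMatrix,
                      methods=METHODS) -> ClusteringSelection:
    """Fit every method and keep the one with the highest cophenetic
    correlation; ties broken by the order of ``methods``.

    Correlations are rounded to 12 decimals before the argmax so that exact
    ties (e.g. an already-ultrametric input, where every method achieves
    r = 1) resolve by the declared order rather than fp noise.
    """
    if not methods:
        raise ValueError("need at least one clustering method")
    trees: dict[str, PhyloTree] = {}
    corr: dict[str, float] = {}
    for m in methods:
        trees[m] = linkage(dist, m)
        corr[m] = cophenetic_correlation(dist, trees[m])
    rounded = {m: round(corr[m], 12) for m in methods}
    best = max(methods, key=lambda m: (rounded[m], -list(methods).index(m)))
    return ClusteringSelection(method=best, tree=trees[best], correlations=corr)
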