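"""Species singularity: evolutionary distinctiveness (fair proportion).

Each branch's length is divided evenly among the tips descending from it;
a species' ED is the sum of its shares over every branch on its root path,
including its own terminal branch. The shares of all branches are fully
distributed, so ED summed over species equals the total tree length —
a conservation identity that holds for polytomies too.

Computed on the phylogeny this is the species' *phylogenetic singularity*
(PS); on the functional dendrogram, its *functional singularity* (FS).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .stats import TestResult, pearson_correlation_test
from .tree import PhyloTree

__all__ = [
    "SingularityScores",
    "evolutionary_distinctiveness",
    "singularity_correlation",
    "quartile_bins",
]


@dataclass(frozen=True)
class SingularityScores:
    tree_id: str
    scores: dict[str, float] = field(repr=False)

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(sorted(self.scores))

    def values(self, order=None) -> np.ndarray:
        order = self.species if order is None else order
        return np.array([self.scores[s] for s in order])


def evolutionary_distinctiveness(tree: PhyloTree, tree_id: str = "tree",
                                 exclude_root_edge: bool = False
                                 ) -> SingularityScores:
    """Fair-proportion ED per species.

    ``exclude_root_edge`` drops the root's own edge (relevant when the
    rooting is arbitrary, e.g. an MRP supertree); by default any root edge
    length is shared among all species.
    """
    if tree.n_tips < 2:
        raise ValueError("ED needs >= 2 tips")
    if tree.total_length <= 0:
        raise ValueError("ED undefined on a tree of total length 0")
    scores: dict[str, float] = {lab: 0.0 for lab in tree.tip_labels}
    below: dict[int, list[str]] = {}
    for node in tree.dendropy_tree.postorder_node_iter():
        if node.is_leaf():
            tips = [node.taxon.label]
        else:
            tips = [t for c in node.child_nodes() for t in below.pop(id(c))]
        below[id(node)] = tips
        if node.parent_node is None and exclude_root_edge:
            continue
        share = node.edge.length / len(tips)
        if share:
            for t in tips:
                scores[t] += share
    return SingularityScores(tree_id=tree_id, scores=scores)


def singularity_correlation(ps: SingularityScores,
                            fs: SingularityScores) -> TestResult:
    """Pearson correlation between phylogenetic and functional singularity,
    aligned by species label."""
    if set(ps.scores) != set(fs.scores):
        raise ValueError(
            "species sets differ between the two singularity scores"
        )
    order = ps.species
    return pearson_correlation_test(ps.values(order), fs.values(order))


def quartile_bins(scores: SingularityScores) -> dict[str, int]:
    """Bin species into empirical quartiles of their scores (1 = lowest).

    A value exactly on a quartile boundary goes to the lower bin, so a
    fully tied set of values lands entirely in bin 1.
    """
    species = scores.species
    if len(species) < 4:
        raise ValueError("quartile binning needs >= 4 species")
    vals = scores.values(species)
    qs = np.quantile(vals, [0.25, 0.5, 0.75])
    return {
        s: int(1 + np.sum(v > qs)) for s, v in zip(species, vals)
    }
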