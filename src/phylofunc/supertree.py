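"""Matrix representation with parsimony (MRP) supertrees.

Source topologies with overlapping taxon sets are combined by Baum-Ragan
coding: every internal (non-root) clade of every source tree becomes one
binary character, scored 1 for clade members, 0 for the other taxa of that
tree, and '?' for taxa the tree does not contain. A supertree is then any
topology of minimal parsimony score on the combined matrix; the score of a
character on a tree is the minimum number of state changes (Fitch counting,
with '?' free to take either state).

The search is heuristic: random-addition-order greedy starting trees refined
by nearest-neighbour-interchange hill climbing, best of several restarts,
fully deterministic given the seed. MRP yields topology only, so returned
supertrees carry unit branch lengths and an arbitrary rooting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .tree import PhyloTree, parse_newick

__all__ = ["MRPMatrix", "mrp_encode", "fitch_score", "mrp_supertree"]

# state masks: bit 0 = state 0, bit 1 = state 1; '?' may be either
_MASK = {0: 1, 1: 2, -1: 3}


@dataclass(frozen=True)
class MRPMatrix:
    """Baum-Ragan matrix: taxa x binary characters, -1 encoding '?'."""

    taxa: tuple[str, ...]
    data: np.ndarray = field(repr=False)  # int8, shape (n_taxa, n_chars)

    def __post_init__(self):
        if self.data.shape[0] != len(self.taxa):
            raise ValueError("matrix row count != taxon count")
        if not np.isin(self.data, (-1, 0, 1)).all():
            raise ValueError("MRP states must be 0, 1 or ? (-1)")

    @property
    def n_characters(self) -> int:
        return self.data.shape[1]

    def _rows(self):
        sym = {-1: "?", 0: "0", 1: "1"}
        for taxon, row in zip(self.taxa, self.data):
            yield taxon, "".join(sym[int(v)] for v in row)

    def to_phylip(self) -> str:
        """Relaxed PHYLIP: counts line then 'name<TAB>states' rows."""
        lines = [f"{len(self.taxa)} {self.n_characters}"]
        lines += [f"{t}\t{s}" for t, s in self._rows()]
        return "\n".join(lines) + "\n"

    def to_nexus(self) -> str:
        rows = "\n".join(f"    {t}  {s}" for t, s in self._rows())
        return (
            "#NEXUS\nBEGIN CHARACTERS;\n"
            f"  DIMENSIONS NTAX={len(self.taxa)} NCHAR={self.n_characters};\n"
            '  FORMAT DATATYPE=STANDARD SYMBOLS="01" MISSING=?;\n'
            f"  MATRIX\n{rows}\n  ;\nEND;\n"
        )


def mrp_encode(trees: list[PhyloTree]) -> MRPMatrix:
    """Encode source trees into one combined Baum-Ragan matrix.

    Each internal non-root clade with >= 2 members that is a proper subset
    of its tree's taxa contributes a character. Trees with fewer than 3 tips
    carry no internal structure and contribute nothing (with a warning).
    """
    if not trees:
        raise ValueError("need at least one source tree")
    taxa = tuple(sorted(set().union(*(set(t.tip_labels) for t in trees))))
    index = {t: i for i, t in enumerate(taxa)}
    columns = []
    for k, tree in enumerate(trees):
        tree_tips = set(tree.tip_labels)
        n_before = len(columns)
        for node in tree.dendropy_tree.preorder_internal_node_iter():
            if node.parent_node is None:
                continue
            clade = {lf.taxon.label for lf in node.leaf_iter()}
            if len(clade) < 2 or len(clade) >= len(tree_tips):
                continue
            col = np.full(len(taxa), -1, dtype=np.int8)
            for t in tree_tips:
                col[index[t]] = 1 if t in clade else 0
            columns.append(col)
        if len(columns) == n_before:
            warnings.warn(
                f"source tree {k} ({len(tree_tips)} tips) contributed no "
                "characters",
                stacklevel=2,
            )
    data = (np.column_stack(columns) if columns
            else np.zeros((len(taxa), 0), dtype=np.int8))
    return MRPMatrix(taxa=taxa, data=data)


# -- Fitch counting on arbitrary (possibly multifurcating) trees -----------


def _fitch_combine(child_masks: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Sequential Fitch combination of child state sets; returns the node's
    state-set masks and the per-character change counts incurred here."""
    cur = child_masks[0].copy()
    changes = np.zeros(cur.shape, dtype=np.int64)
    for m in child_masks[1:]:
        inter = cur & m
        union_needed = inter == 0
        changes += union_needed
        cur = np.where(union_needed, cur | m, inter)
    return cur, changes


def fitch_score(matrix: MRPMatrix, tree: PhyloTree) -> int:
    """Parsimony score of ``tree`` on ``matrix`` (sum of minimum changes).

    Tree tips absent from the matrix are treated as '?'. A matrix taxon
    absent from the tree is an error. The count is invariant to rerooting.
    """
    tips = set(tree.tip_labels)
    missing = set(matrix.taxa) - tips
    if missing:
        raise ValueError(f"matrix taxa absent from tree: {sorted(missing)}")
    row = {t: i for i, t in enumerate(matrix.taxa)}
    lookup = np.array([_MASK[s] for s in (-1, 0, 1)], dtype=np.uint8)
    nchar = matrix.n_characters
    total = np.zeros(nchar, dtype=np.int64)
    masks: dict[int, np.ndarray] = {}
    for node in tree.dendropy_tree.postorder_node_iter():
        if node.is_leaf():
            label = node.taxon.label
            if label in row:
                masks[id(node)] = lookup[matrix.data[row[label]] + 1]
            else:
                masks[id(node)] = np.full(nchar, 3, dtype=np.uint8)
        else:
            child = [masks.pop(id(c)) for c in node.child_nodes()]
            masks[id(node)], ch = _fitch_combine(child)
            total += ch
    return int(total.sum())


# -- heuristic search ------------------------------------------------------
# Search trees are nested 2-tuples of taxon indices (leaves are ints),
# rooted arbitrarily; scoring and moves respect unrooted semantics because
# Fitch counts are rerooting-invariant.


def _score_tuple(tree, tip_masks: np.ndarray) -> int:
    def rec(node):
        if isinstance(node, int):
            return tip_masks[node], 0
        lm, lc = rec(node[0])
        rm, rc = rec(node[1])
        inter = lm & rm
        add = inter == 0
        mask = np.where(add, lm | rm, inter)
        return mask, lc + rc + int(add.sum())

    return rec(tree)[1]


def _insertions(tree, leaf: int):
    """All trees obtained by grafting ``leaf`` onto each edge of ``tree``."""
    yield (tree, leaf)
    if not isinstance(tree, int):
        left, right = tree
        for sub in _insertions(left, leaf):
            yield (sub, right)
        for sub in _insertions(right, leaf):
            yield (left, sub)


def _nni_neighbors(tree):
    out = []

    def rec(node, rebuild):
        if isinstance(node, int):
            return
        a, b = node
        for child, sib in ((a, b), (b, a)):
            if not isinstance(child, int):
                c1, c2 = child
                for swapped in (((c1, sib), c2), ((c2, sib), c1)):
                    out.append(rebuild(swapped))
        rec(a, lambda s: rebuild((s, b)))
        rec(b, lambda s: rebuild((a, s)))

    rec(tree, lambda s: s)
    return out


def _tuple_to_newick(tree, taxa) -> str:
    def rec(node):
        if isinstance(node, int):
            return f"{taxa[node]}:1.0"
        return f"({rec(node[0])},{rec(node[1])}):1.0"

    if isinstance(tree, int):  # pragma: no cover - guarded upstream
        return f"({taxa[tree]}:1.0);"
    return f"({rec(tree[0])},{rec(tree[1])});"


def mrp_supertree(matrix: MRPMatrix, restarts: int = 10,
                  seed: int = 0) -> PhyloTree:
    """Heuristic maximum-parsimony supertree for an MRP matrix.

    Random taxon-addition order per restart, greedy best-edge insertion,
    then NNI hill climbing to a local optimum; the best-scoring tree over
    all restarts is returned (first found wins ties). Deterministic given
    ``seed``. The result is topology-only: unit branch lengths, arbitrary
    rooting.
    """
    ntax = len(matrix.taxa)
    if ntax < 4:
        raise ValueError("supertree search needs >= 4 taxa")
    lookup = np.array([_MASK[s] for s in (-1, 0, 1)], dtype=np.uint8)
    tip_masks = lookup[matrix.data + 1]  # (n_taxa, n_chars)
    rng = np.random.default_rng(seed)
    best_tree, best_score = None, None
    for _ in range(max(restarts, 1)):
        order = list(rng.permutation(ntax))
        tree = ((int(order[0]), int(order[1])), int(order[2]))
        for leaf in order[3:]:
            cands = list(_insertions(tree, int(leaf)))
            scores = [_score_tuple(c, tip_masks) for c in cands]
            tree = cands[int(np.argmin(scores))]
        score = _score_tuple(tree, tip_masks)
        improved = True
        while improved:
            improved = False
            for neigh in _nni_neighbors(tree):
                s = _score_tuple(neigh, tip_masks)
                if s < score:
                    tree, score = neigh, s
                    improved = True
                    break
        if best_score is None or score < best_score:
            best_tree, best_score = tree, score
    return parse_newick(_tuple_to_newick(best_tree, matrix.taxa))
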