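"""Phylogenetic tree container and core tree operations.

Trees are stored rooted (wrapping a :class:`dendropy.Tree`) but split-based
metrics use unrooted semantics: every bipartition is canonicalized as the side
that does *not* contain a fixed reference tip (the lexicographically smallest
label), so the artificial split at the root is never double-counted.

Branch lengths are non-negative reals in arbitrary units; a branch written
without a length in newick defaults to 1.0 (with a warning), because source
topologies (e.g. parsimony supertrees) often omit lengths while dendrograms
always carry heights.
"""

from __future__ import annotations

import warnings
from typing import Iterator

import dendropy
import numpy as np
from skbio import DistanceMatrix

__all__ = [
    "PhyloTree",
    "NewickParseError",
    "TreeValidationError",
    "parse_newick",
    "read_newick",
    "write_newick",
    "cophenetic_matrix",
    "normalize_tree",
    "bipartitions",
    "split_lengths",
]


class NewickParseError(ValueError):
    """Malformed newick input."""


class TreeValidationError(ValueError):
    """Tree violates a structural invariant (labels, branch lengths)."""


class PhyloTree:
    """A rooted phylogenetic tree with uniquely labeled tips.

    Parameters
    ----------
    tree:
        The underlying dendropy tree. Ownership passes to this object.
    default_branch_length:
        Length assigned to edges that carry none (the root edge gets 0).

    Invariants enforced at construction: unique non-empty tip labels, all
    branch lengths >= 0. Polytomies are allowed.
    """

    __slots__ = ("_tree",)

    def __init__(self, tree: dendropy.Tree, default_branch_length: float = 1.0):
        defaulted = 0
        for node in tree.preorder_node_iter():
            if node.parent_node is None:
                if node.edge.length is None:
                    node.edge.length = 0.0
            elif node.edge.length is None:
                node.edge.length = default_branch_length
                defaulted += 1
        if defaulted:
            warnings.warn(
                f"{defaulted} branch(es) had no length; defaulted to "
                f"{default_branch_length}",
                stacklevel=2,
            )
        labels = []
        for leaf in tree.leaf_node_iter():
            label = leaf.taxon.label if leaf.taxon is not None else None
            if not label:
                raise TreeValidationError("tree contains an unlabeled tip")
            labels.append(label)
        if len(set(labels)) != len(labels):
            dupes = sorted({x for x in labels if labels.count(x) > 1})
            raise TreeValidationError(f"duplicate tip labels: {dupes}")
        for node in tree.preorder_node_iter():
            if node.edge.length < 0:
                raise TreeValidationError(
                    f"negative branch length {node.edge.length}"
                )
        self._tree = tree

    # -- basic accessors ---------------------------------------------------

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def tip_labels(self) -> tuple[str, ...]:
        """Tip labels in sorted order (the canonical ordering for matrices)."""
        return tuple(sorted(l.taxon.label for l in self._tree.leaf_node_iter()))

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self._tree.leaf_node_iter())

    @property
    def total_length(self) -> float:
        """Sum of all branch lengths (the root edge contributes its length)."""
        return float(
            sum(nd.edge.length for nd in self._tree.preorder_node_iter())
        )

    def copy(self) -> "PhyloTree":
        return PhyloTree(self._tree.clone(depth=1))

    def prune_to(self, labels) -> "PhyloTree":
        """Return a copy restricted to ``labels`` (must be a subset of tips)."""
        keep = set(labels)
        missing = keep - set(self.tip_labels)
        if missing:
            raise TreeValidationError(
                f"labels not in tree: {sorted(missing)}"
            )
        clone = self._tree.clone(depth=1)
        taxa = [t for t in clone.taxon_namespace if t.label in keep]
        clone.retain_taxa(taxa)
        # retain_taxa can leave a unifurcating root; collapse it so the tree
        # stays a clean rooted tree with meaningful edge lengths.
        clone.suppress_unifurcations()
        return PhyloTree(clone)

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"PhyloTree(n_tips={self.n_tips}, total_length={self.total_length:.4g})"

    def as_ascii(self) -> str:  # pragma: no cover - debug aid
        return self._tree.as_ascii_plot()

    def write_newick(self) -> str:
        s = self._tree.as_string(schema="newick", suppress_rooting=True)
        return s.strip()


def parse_newick(text: str) -> PhyloTree:
    """Parse a single newick string into a :class:`PhyloTree`.

    Raises :class:`NewickParseError` (naming the character offset for
    unbalanced parentheses) and :class:`TreeValidationError` for duplicate
    or empty tip labels.
    """
    depth = 0
    in_quote = False
    for offset, ch in enumerate(text):
        if ch == "'":
            in_quote = not in_quote
        elif not in_quote:
            if ch == "(":
                depth += 1
            elif ch == ")":
                depth -= 1
                if depth < 0:
                    raise NewickParseError(
                        f"unbalanced ')' at character offset {offset}"
                    )
    if depth != 0:
        raise NewickParseError(
            f"unbalanced '(': {depth} unclosed at end of input "
            f"(length {len(text)})"
        )
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except TreeValidationError:
        raise
    except Exception as exc:  # dendropy raises several DataError subclasses
        if "Duplicate taxon labels" in str(exc):
            raise TreeValidationError(f"duplicate tip labels: {exc}") from exc
        raise NewickParseError(f"newick parse failed: {exc}") from exc
    return PhyloTree(tree)


def read_newick(path) -> PhyloTree:
    """Read the first tree from a newick file."""
    with open(path, "r", encoding="utf-8") as fh:
        return parse_newick(fh.read())


def read_newick_list(path) -> list[PhyloTree]:
    """Read every tree from a multi-newick file (one per ';')."""
    with open(path, "r", encoding="utf-8") as fh:
        text = fh.read()
    trees = []
    for chunk in text.split(";"):
        if chunk.strip():
            trees.append(parse_newick(chunk + ";"))
    return trees


def write_newick(tree: PhyloTree, path=None) -> str:
    """Serialize a tree; optionally also write it to ``path``."""
    s = tree.write_newick()
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(s + "\n")
    return s


# -- distances -------------------------------------------------------------


def cophenetic_matrix(tree: PhyloTree) -> DistanceMatrix:
    """Patristic (path-length) distances between every pair of tips.

    Entry (i, j) is the sum of branch lengths on the unique path joining
    tips i and j. Labels are sorted; the matrix is symmetric and hollow.
    """
    if tree.n_tips < 2:
        raise TreeValidationError("cophenetic matrix needs >= 2 tips")
    labels = tree.tip_labels
    index = {lab: k for k, lab in enumerate(labels)}
    # Per-leaf dict of {ancestor node id: distance from leaf to that ancestor}
    leaves = list(tree.dendropy_tree.leaf_node_iter())
    anc_dist = []
    for leaf in leaves:
        d = {}
        node, acc = leaf, 0.0
        while node is not None:
            d[id(node)] = acc
            acc += node.edge.length
            node = node.parent_node
        anc_dist.append(d)
    n = len(leaves)
    mat = np.zeros((n, n))
    for a in range(n):
        ia = index[leaves[a].taxon.label]
        da = anc_dist[a]
        for b in range(a + 1, n):
            ib = index[leaves[b].taxon.label]
            node, acc = leaves[b], 0.0
            while id(node) not in da:
                acc += node.edge.length
                node = node.parent_node
            dist = acc + da[id(node)]
            mat[ia, ib] = mat[ib, ia] = dist
    return DistanceMatrix(mat, ids=labels)


def normalize_tree(tree: PhyloTree) -> PhyloTree:
    """Rescale branch lengths so the total tree length equals 1."""
    total = tree.total_length
    if total <= 0:
        raise TreeValidationError("cannot normalize a tree of total length 0")
    out = tree.copy()
    for node in out.dendropy_tree.preorder_node_iter():
        node.edge.length = node.edge.length / total
    return out


# -- splits ----------------------------------------------------------------


def _canonical_side(below: frozenset, all_tips: frozenset, ref: str) -> frozenset:
    return frozenset(all_tips - below) if ref in below else below


def _clades(tree: PhyloTree) -> Iterator[tuple[frozenset, float]]:
    """Yield (tip set below edge, edge length) for every non-root edge."""
    below: dict[int, frozenset] = {}
    for node in tree.dendropy_tree.postorder_node_iter():
        if node.is_leaf():
            below[id(node)] = frozenset([node.taxon.label])
        else:
            acc = frozenset().union(
                *(below[id(c)] for c in node.child_nodes())
            )
            below[id(node)] = acc
        if node.parent_node is not None:
            yield below[id(node)], float(node.edge.length)


def bipartitions(tree: PhyloTree) -> set[frozenset]:
    """Non-trivial unrooted bipartitions, one per internal branch.

    Each split is represented by its canonical side (the side not containing
    the lexicographically smallest tip label). Trees with fewer than 4 tips
    have no non-trivial splits and yield the empty set. A fully binary
    unrooted tree of n tips yields exactly n - 3 splits.
    """
    all_tips = frozenset(tree.tip_labels)
    if len(all_tips) < 4:
        return set()
    ref = min(all_tips)
    out = set()
    for side, _length in _clades(tree):
        if 2 <= len(side) <= len(all_tips) - 2:
            out.add(_canonical_side(side, all_tips, ref))
    return out


def split_lengths(tree: PhyloTree) -> dict[frozenset, float]:
    """Map every split (trivial tip splits included) to its branch length.

    Splits are canonicalized as in :func:`bipartitions`; under the unrooted
    interpretation the two edges meeting at a degree-2 root describe the same
    split, so their lengths are summed.
    """
    all_tips = frozenset(tree.tip_labels)
    ref = min(all_tips)
    out: dict[frozenset, float] = {}
    for side, length in _clades(tree):
        if len(side) == len(all_tips):
            continue  # edge above a node spanning everything: no split
        key = _canonical_side(side, all_tips, ref)
        out[key] = out.get(key, 0.0) + length
    return out
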