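"""Tree-to-tree distance metrics on a shared tip set.

Three metrics are exposed:

* topological difference (TD) — the Penny-Hendy symmetric difference: the
  number of unrooted bipartitions present in exactly one of the two trees.
  For fully binary trees of n tips it ranges over even values in [0, 2n-6].
* relative topological difference (RTD) — TD / (2n - 6), in [0, 1] for
  binary trees (0 = identical topologies, 1 = no shared split). The 2n-6
  denominator is retained for multifurcating trees as well, so RTD can fall
  below 1 even when no splits are shared.
* branch length score (BLS) — the Kuhner-Felsenstein branch score: over the
  union of both trees' splits (trivial tip branches included), the square
  root of the sum of squared branch-length differences, a split absent from
  a tree contributing length 0. Both the square-root value and the raw
  squared sum are reported. With ``normalize=True`` both trees are first
  rescaled to total length 1, making the score unit-free; under that
  convention the square-root value cannot exceed sqrt(2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .tree import PhyloTree, bipartitions, normalize_tree, split_lengths

__all__ = [
    "TreeComparisonResult",
    "topological_difference",
    "rtd",
    "branch_length_score",
    "compare_trees",
]


def _check_same_tips(t1: PhyloTree, t2: PhyloTree) -> tuple[str, ...]:
    s1, s2 = set(t1.tip_labels), set(t2.tip_labels)
    if s1 != s2:
        raise ValueError(
            "tip sets differ: only in first "
            f"{sorted(s1 - s2)}, only in second {sorted(s2 - s1)}"
        )
    return t1.tip_labels


@dataclass(frozen=True)
class TreeComparisonResult:
    td: int
    rtd: float
    bls: float          # square-root (branch score distance) convention
    bls_squared: float  # raw sum of squared differences
    n: int


def topological_difference(t1: PhyloTree, t2: PhyloTree) -> int:
    """Symmetric difference of the two unrooted bipartition sets."""
    tips = _check_same_tips(t1, t2)
    if len(tips) < 4:
        raise ValueError("topological difference needs >= 4 shared tips")
    return len(bipartitions(t1) ^ bipartitions(t2))


def rtd(t1: PhyloTree, t2: PhyloTree) -> float:
    """Relative topological difference, TD / (2n - 6)."""
    n = len(_check_same_tips(t1, t2))
    if 2 * n - 6 <= 0:
        raise ValueError("RTD undefined for n < 4 (denominator 2n-6 <= 0)")
    return topological_difference(t1, t2) / (2 * n - 6)


def branch_length_score(t1: PhyloTree, t2: PhyloTree,
                        normalize: bool = True) -> tuple[float, float]:
    """Branch score between two trees on the same tips.

    Returns ``(sqrt_value, squared_sum)``. With ``normalize`` each tree is
    rescaled to total length 1 before comparison.
    """
    _check_same_tips(t1, t2)
    if normalize:
        t1, t2 = normalize_tree(t1), normalize_tree(t2)
    l1, l2 = split_lengths(t1), split_lengths(t2)
    sq = 0.0
    for split in set(l1) | set(l2):
        diff = l1.get(split, 0.0) - l2.get(split, 0.0)
        sq += diff * diff
    return math.sqrt(sq), sq


def compare_trees(t1: PhyloTree, t2: PhyloTree,
                  normalize: bool = True) -> TreeComparisonResult:
    """TD, RTD and BLS in one pass (the step-2 comparison battery)."""
    n = len(_check_same_tips(t1, t2))
    td = topological_difference(t1, t2)
    bls_sqrt, bls_sq = branch_length_score(t1, t2, normalize=normalize)
    return TreeComparisonResult(
        td=td, rtd=td / (2 * n - 6), bls=bls_sqrt, bls_squared=bls_sq, n=n
    )
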