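"""Phylogenetic signal of a quantitative "functional identity".

The functional identity of a species is a scalar summary of its position in
the functional dendrogram, obtained by simulating Brownian motion along that
dendrogram: closely clustered species receive correlated values. The signal
of those values on the *phylogeny* is then quantified with Moran's I
autocorrelation (inverse-patristic proximities) and Abouheif's C_mean
(Moran's I computed with the Abouheif tip proximity, which depends only on
topology). Both statistics are near -1/(n-1) in the absence of signal and
approach 1 when close relatives carry near-identical values; significance
comes from permuting values over tips.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .tree import PhyloTree, cophenetic_matrix

# permutation statistics within this distance of the observed value are
# counted as ties (symmetric tip permutations tie exactly in real
# arithmetic but differ in the last float bit across summation orders)
_TIE_TOL = 1e-12

__all__ = [
    "ProximityMatrix",
    "SignalResult",
    "brownian_simulate",
    "brownian_simulate_many",
    "proximity_matrix",
    "morans_i",
    "signal_test",
    "functional_identity_signal",
]


@dataclass(frozen=True)
class ProximityMatrix:
    """Row-normalized tip proximity weights for autocorrelation statistics."""

    ids: tuple[str, ...]
    weights: np.ndarray = field(repr=False)  # row-normalized, zero diagonal
    kind: str = "patristic_inverse"


@dataclass(frozen=True)
class SignalResult:
    statistic_name: str        # "moran_i" | "abouheif_cmean"
    observed: float            # mean over Brownian replicates
    p_value: float             # median per-replicate permutation p
    n_permutations: int
    seed: int | None
    n_replicates: int = 1
    per_replicate: tuple[float, ...] = ()
    per_replicate_p: tuple[float, ...] = ()

    def to_dict(self) -> dict:
        return {
            "statistic_name": self.statistic_name,
            "observed": self.observed,
            "p_value": self.p_value,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
            "n_replicates": self.n_replicates,
            "per_replicate": list(self.per_replicate),
            "per_replicate_p": list(self.per_replicate_p),
        }


# -- Brownian simulation ---------------------------------------------------


def brownian_simulate_many(tree: PhyloTree, sigma2: float = 1.0,
                           root_state: float = 0.0, seed: int | None = None,
                           n_replicates: int = 1):
    """Simulate Brownian motion along the tree, vectorized over replicates.

    Each node's state is its parent's state plus a Normal(0, sigma2 * branch
    length) increment, accumulated from the root (the root edge, if any,
    also evolves). Returns ``(labels, values)`` with values of shape
    (n_replicates, n_tips), columns in sorted label order.
    """
    if sigma2 <= 0:
        raise ValueError("sigma2 must be > 0")
    rng = np.random.default_rng(seed)
    states: dict[int, np.ndarray] = {}
    tip_vals: dict[str, np.ndarray] = {}
    for node in tree.dendropy_tree.preorder_node_iter():
        if node.parent_node is None:
            base = np.full(n_replicates, float(root_state))
        else:
            base = states[id(node.parent_node)]
        length = node.edge.length
        if length > 0:
            value = base + rng.normal(
                0.0, math.sqrt(sigma2 * length), size=n_replicates
            )
        else:
            value = base
        states[id(node)] = value
        if node.is_leaf():
            tip_vals[node.taxon.label] = value
    labels = tuple(sorted(tip_vals))
    values = np.column_stack([tip_vals[t] for t in labels])
    return labels, values


def brownian_simulate(tree: PhyloTree, sigma2: float = 1.0,
                      root_state: float = 0.0,
                      seed: int | None = None) -> dict[str, float]:
    """One Brownian draw: mapping species -> simulated tip state."""
    labels, values = brownian_simulate_many(
        tree, sigma2=sigma2, root_state=root_state, seed=seed, n_replicates=1
    )
    return {lab: float(v) for lab, v in zip(labels, values[0])}


# -- proximity matrices ----------------------------------------------------


def proximity_matrix(tree: PhyloTree, kind: str = "patristic_inverse") -> ProximityMatrix:
    """Tip proximity weights from a tree.

    ``patristic_inverse``: w_ij = 1 / patristic distance (branch-length
    aware). ``abouheif``: w_ij = 1 over the product, along the i->j path, of
    each internal node's number of direct descendants (topology-only).
    Both are symmetric before normalization; rows are then normalized to
    sum to 1.
    """
    if tree.n_tips < 3:
        raise ValueError("proximity matrix needs >= 3 tips")
    labels = tree.tip_labels
    n = len(labels)
    if kind == "patristic_inverse":
        d = cophenetic_matrix(tree).filter(labels).data
        off = ~np.eye(n, dtype=bool)
        if (d[off] == 0).any():
            raise ValueError("zero patristic distance between distinct tips")
        w = np.zeros((n, n))
        w[off] = 1.0 / d[off]
    elif kind == "abouheif":
        w = _abouheif_proximity(tree, labels)
    else:
        raise ValueError(f"unknown proximity kind {kind!r}")
    row_sums = w.sum(axis=1, keepdims=True)
    if (row_sums == 0).any():
        raise ValueError("a tip has zero total proximity")
    return ProximityMatrix(ids=labels, weights=w / row_sums, kind=kind)


def _abouheif_proximity(tree: PhyloTree, labels) -> np.ndarray:
    index = {lab: i for i, lab in enumerate(labels)}
    leaves = list(tree.dendropy_tree.leaf_node_iter())
    # ancestors of each leaf, nearest first, with node ids
    anc: list[list] = []
    for leaf in leaves:
        chain, node = [], leaf.parent_node
        while node is not None:
            chain.append(node)
            node = node.parent_node
        anc.append(chain)
    n_children = {}
    n = len(leaves)
    w = np.zeros((n, n))
    for a in range(n):
        ia = index[leaves[a].taxon.label]
        seen = {id(nd): k for k, nd in enumerate(anc[a])}
        for b in range(a + 1, n):
            ib = index[leaves[b].taxon.label]
            prod = 1.0
            for nd in anc[b]:
                if id(nd) in seen:
                    lca_pos = seen[id(nd)]
                    prod *= math.prod(
                        _deg(x, n_children) for x in anc[a][: lca_pos + 1]
                    )
                    break
                prod *= _deg(nd, n_children)
            w[ia, ib] = w[ib, ia] = 1.0 / prod
    return w


def _deg(node, cache) -> int:
    key = id(node)
    if key not in cache:
        cache[key] = node.num_child_nodes()
    return cache[key]


# -- Moran's I / C_mean ----------------------------------------------------


def _values_vector(values, ids) -> np.ndarray:
    missing = set(ids) - set(values)
    if missing:
        raise ValueError(f"values missing for species: {sorted(missing)}")
    return np.array([float(values[i]) for i in ids])


def morans_i(values, w: ProximityMatrix) -> float:
    """Moran's autocorrelation index of ``values`` under proximity ``w``.

    I = (n / S0) * sum_{i!=j} w_ij (x_i - mean)(x_j - mean) / sum (x - mean)^2
    with S0 the sum of off-diagonal weights. For row-normalized weights
    S0 = n. Equal off-diagonal weights give the null expectation -1/(n-1)
    for any non-constant x.
    """
    x = _values_vector(values, w.ids)
    return _morans_i_vec(x, w.weights)


def _morans_i_vec(x: np.ndarray, weights: np.ndarray) -> float:
    n = len(x)
    if n < 3:
        raise ValueError("Moran's I needs >= 3 values")
    xc = x - x.mean()
    ss = xc @ xc
    if ss == 0:
        raise ValueError("zero variance in values")
    s0 = weights.sum()
    return float((n / s0) * (xc @ weights @ xc) / ss)


def _moran_null(x: np.ndarray, weights: np.ndarray, n_perm: int,
                rng: np.random.Generator) -> np.ndarray:
    """Moran-type statistics for ``n_perm`` random tip shuffles, vectorized."""
    n = len(x)
    xc = x - x.mean()
    ss = xc @ xc
    s0 = weights.sum()
    perms = rng.permuted(np.tile(xc, (n_perm, 1)), axis=1)
    quad = np.einsum("pi,ij,pj->p", perms, weights, perms)
    return (n / s0) * quad / ss


def signal_test(values, w: ProximityMatrix, n_perm: int = 999,
                seed: int | None = None, exhaustive: bool = False,
                statistic_name: str = "moran_i") -> SignalResult:
    """Permutation test of Moran-type signal (one-sided, greater).

    The null shuffles values over tips. ``exhaustive=True`` enumerates all
    n! assignments (identity included). Uses the add-one p-value convention
    in sampled mode.
    """
    x = _values_vector(values, w.ids)
    observed = _morans_i_vec(x, w.weights)
    if exhaustive:
        null = np.array([
            _morans_i_vec(x[list(p)], w.weights)
            for p in itertools.permutations(range(len(x)))
        ])
        p_value = float(np.mean(null >= observed - _TIE_TOL))
        return SignalResult(statistic_name=statistic_name, observed=observed,
                            p_value=p_value, n_permutations=len(null),
                            seed=None, per_replicate=(observed,),
                            per_replicate_p=(p_value,))
    rng = np.random.default_rng(seed)
    null = _moran_null(x, w.weights, n_perm, rng)
    p_value = (1 + int((null >= observed - _TIE_TOL).sum())) / (1 + n_perm)
    return SignalResult(statistic_name=statistic_name, observed=observed,
                        p_value=p_value, n_permutations=n_perm, seed=seed,
                        per_replicate=(observed,), per_replicate_p=(p_value,))


def functional_identity_signal(phylo: PhyloTree, functree: PhyloTree,
                               n_replicates: int = 100, n_perm: int = 999,
                               seed: int | None = None,
                               sigma2: float = 1.0
                               ) -> tuple[SignalResult, SignalResult]:
    """Phylogenetic signal of Brownian functional identity.

    Per replicate: draw a Brownian identity on the functional tree (root 0;
    sigma2 is immaterial to the scale-invariant statistics), then score it
    on the phylogeny with Moran's I (inverse-patristic weights) and
    Abouheif's C_mean (Abouheif weights), each with a permutation p-value.
    Returns the two aggregated results (mean statistic, median p).
    """
    if set(phylo.tip_labels) != set(functree.tip_labels):
        raise ValueError("phylogeny and functional tree have different tips")
    w_pat = proximity_matrix(phylo, kind="patristic_inverse")
    w_abo = proximity_matrix(phylo, kind="abouheif")
    rng = np.random.default_rng(seed)
    bm_seed = int(rng.integers(2**31))
    labels, draws = brownian_simulate_many(
        functree, sigma2=sigma2, root_state=0.0, seed=bm_seed,
        n_replicates=n_replicates,
    )
    results = []
    for w, name in ((w_pat, "moran_i"), (w_abo, "abouheif_cmean")):
        # align Brownian draws (sorted labels) with the proximity ordering
        order = [labels.index(i) for i in w.ids]
        stats_r, ps = [], []
        for rep in range(n_replicates):
            x = draws[rep, order]
            obs = _morans_i_vec(x, w.weights)
            null = _moran_null(x, w.weights, n_perm, rng)
            stats_r.append(obs)
            ps.append((1 + int((null >= obs - _TIE_TOL).sum()))
                      / (1 + n_perm))
        results.append(SignalResult(
            statistic_name=name,
            observed=float(np.mean(stats_r)),
            p_value=float(np.median(ps)),
            n_permutations=n_perm,
            seed=seed,
            n_replicates=n_replicates,
            per_replicate=tuple(stats_r),
            per_replicate_p=tuple(ps),
        ))
    return results[0], results[1]
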