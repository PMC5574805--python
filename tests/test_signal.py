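"""Brownian simulation, proximity matrices, Moran's I / Abouheif's C_mean."""

import itertools
import subprocess

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phylofunc import (ProximityMatrix, brownian_simulate,
                       brownian_simulate_many, functional_identity_signal,
                       morans_i, parse_newick, proximity_matrix, signal_test,
                       simulate_yule_tree)


class TestBrownian:
    def test_zero_branch_lengths_keep_root_state(self):
        t = parse_newick("((a:0,b:0):0,c:0);")
        vals = brownian_simulate(t, sigma2=1.0, root_state=2.5, seed=0)
        assert all(v == 2.5 for v in vals.values())

    def test_deterministic_given_seed(self):
        t = simulate_yule_tree(8, seed=1)
        assert brownian_simulate(t, seed=7) == brownian_simulate(t, seed=7)

    def test_variance_and_covariance_calibration(self):
        t = simulate_yule_tree(8, seed=5)
        sigma2, reps = 1.7, 4000
        labels, draws = brownian_simulate_many(t, sigma2=sigma2, seed=3,
                                               n_replicates=reps)
        # independent expected (co)variances from node depths
        depth = {}
        for nd in t.dendropy_tree.preorder_node_iter():
            parent = nd.parent_node
            depth[id(nd)] = nd.edge.length + (depth[id(parent)] if parent
                                              else 0.0)
        leaf = {lf.taxon.label: lf for lf in t.dendropy_tree.leaf_node_iter()}

        def shared_depth(a, b):
            anc = set()
            nd = leaf[a]
            while nd is not None:
                anc.add(id(nd))
                nd = nd.parent_node
            nd = leaf[b].parent_node
            while id(nd) not in anc:
                nd = nd.parent_node
            return depth[id(nd)]

        for i, lab in enumerate(labels):
            expected = sigma2 * depth[id(leaf[lab])]
            observed = draws[:, i].var(ddof=1)
            se = expected * np.sqrt(2 / (reps - 1))
            assert abs(observed - expected) < 3 * se
        for i, j in [(0, 1), (2, 5), (3, 7)]:
            expected = sigma2 * shared_depth(labels[i], labels[j])
            vi = sigma2 * depth[id(leaf[labels[i]])]
            vj = sigma2 * depth[id(leaf[labels[j]])]
            observed = np.cov(draws[:, i], draws[:, j], ddof=1)[0, 1]
            se = np.sqrt((vi * vj + expected**2) / (reps - 1))
            assert abs(observed - expected) < 3 * se


class TestProximity:
    def test_abouheif_balanced_four(self, balanced_four):
        w = proximity_matrix(balanced_four, kind="abouheif").weights
        ids = proximity_matrix(balanced_four, kind="abouheif").ids
        i = {lab: k for k, lab in enumerate(ids)}
        # raw proximities 1/2 (cherry) and 1/8 (across root);
        # row-normalized: (1/2)/(3/4)=2/3 and (1/8)/(3/4)=1/6
        assert w[i["a"], i["b"]] == pytest.approx(2 / 3)
        assert w[i["a"], i["c"]] == pytest.approx(1 / 6)
        assert w[i["a"], i["d"]] == pytest.approx(1 / 6)

    def test_abouheif_star_tree(self):
        k = 5
        t = parse_newick("(" + ",".join(f"s{i}:1" for i in range(k)) + ");")
        w = proximity_matrix(t, kind="abouheif").weights
        off = w[~np.eye(k, dtype=bool)]
        np.testing.assert_allclose(off, 1 / (k - 1))

    def test_abouheif_ignores_branch_lengths(self):
        t1 = parse_newick("((a:1,b:1):1,(c:1,d:1):1);")
        t2 = parse_newick("((a:9,b:0.1):5,(c:2,d:7):0.3);")
        np.testing.assert_allclose(
            proximity_matrix(t1, "abouheif").weights,
            proximity_matrix(t2, "abouheif").weights,
        )

    def test_patristic_rows_sum_to_one(self):
        t = simulate_yule_tree(9, seed=3)
        w = proximity_matrix(t, "patristic_inverse").weights
        np.testing.assert_allclose(w.sum(axis=1), 1.0)
        assert np.all(np.diag(w) == 0)


class TestMoransI:
    def test_equal_weights_null_identity(self, rng):
        for n in (4, 7, 20):
            w = np.full((n, n), 1 / (n - 1))
            np.fill_diagonal(w, 0.0)
            prox = ProximityMatrix(ids=tuple(f"s{i}" for i in range(n)),
                                   weights=w, kind="equal")
            vals = {f"s{i}": v for i, v in enumerate(rng.normal(size=n))}
            assert morans_i(vals, prox) == pytest.approx(-1 / (n - 1),
                                                         abs=1e-12)

    @settings(max_examples=60, deadline=None, database=None,
              derandomize=True)
    @given(st.lists(st.integers(-1000, 1000), min_size=4, max_size=30,
                    unique=True))
    def test_equal_weights_closed_form_property(self, values):
        n = len(values)
        w = np.full((n, n), 1 / (n - 1))
        np.fill_diagonal(w, 0.0)
        prox = ProximityMatrix(ids=tuple(f"s{i}" for i in range(n)),
                               weights=w, kind="equal")
        vals = {f"s{i}": float(v) for i, v in enumerate(values)}
        assert morans_i(vals, prox) == pytest.approx(-1 / (n - 1), abs=1e-10)

    def test_clade_clustered_values_positive(self):
        t = parse_newick("((a:1,b:1,c:1):1,(d:1,e:1,f:1):1);")
        prox = proximity_matrix(t, "abouheif")
        vals = {"a": 1, "b": 1, "c": 1, "d": -1, "e": -1, "f": -1}
        assert morans_i(vals, prox) > 0

    def test_constant_values_error(self, balanced_four):
        prox = proximity_matrix(balanced_four, "abouheif")
        with pytest.raises(ValueError, match="variance"):
            morans_i({k: 1.0 for k in prox.ids}, prox)

    def test_affine_invariance(self, rng):
        t = simulate_yule_tree(10, seed=6)
        prox = proximity_matrix(t, "patristic_inverse")
        x = rng.normal(size=10)
        v1 = {k: float(val) for k, val in zip(prox.ids, x)}
        v2 = {k: float(3.5 * val - 7) for k, val in zip(prox.ids, x)}
        assert morans_i(v1, prox) == pytest.approx(morans_i(v2, prox))

    def test_matches_r_ape_moran(self, tmp_path, rng):
        t = simulate_yule_tree(8, seed=12)
        prox = proximity_matrix(t, "patristic_inverse")
        x = rng.normal(size=8)
        vals = {k: float(v) for k, v in zip(prox.ids, x)}
        mine = morans_i(vals, prox)
        np.savetxt(tmp_path / "w.csv", prox.weights, delimiter=",")
        np.savetxt(tmp_path / "x.csv", x, delimiter=",")
        script = (
            f"w <- as.matrix(read.csv('{tmp_path}/w.csv', header=FALSE));"
            f"x <- scan('{tmp_path}/x.csv');"
            "res <- ape::Moran.I(x, w);"
            "cat(sprintf('%.12f', res$observed))"
        )
        out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                             text=True, check=True)
        assert mine == pytest.approx(float(out.stdout), abs=1e-9)


class TestSignalTest:
    def test_exhaustive_matches_enumeration(self, rng):
        t = simulate_yule_tree(6, seed=9)
        prox = proximity_matrix(t, "abouheif")
        x = rng.normal(size=6)
        vals = {k: float(v) for k, v in zip(prox.ids, x)}
        res = signal_test(vals, prox, exhaustive=True)
        assert res.n_permutations == 720
        # independent enumeration with an explicit double-sum Moran formula
        w = prox.weights
        n = 6

        def moran(v):
            xc = v - v.mean()
            num = sum(w[i, j] * xc[i] * xc[j]
                      for i in range(n) for j in range(n) if i != j)
            return (n / w.sum()) * num / (xc @ xc)

        obs = moran(x)
        null = [moran(x[list(p)]) for p in
                itertools.permutations(range(n))]
        # ties within float round-off count, as in the implementation
        assert res.p_value == pytest.approx(
            np.mean([v >= obs - 1e-12 for v in null]))

    def test_brownian_power_and_shuffled_type_one(self):
        t = simulate_yule_tree(40, seed=21)
        prox = proximity_matrix(t, "abouheif")
        rng = np.random.default_rng(5)
        power = type1 = 0
        n_rep = 60
        for k in range(n_rep):
            labels, draws = brownian_simulate_many(
                t, seed=int(rng.integers(2**31)), n_replicates=1)
            x = draws[0]
            order = [labels.index(i) for i in prox.ids]
            vals = {i: float(v) for i, v in zip(prox.ids, x[order])}
            res = signal_test(vals, prox, n_perm=99,
                              seed=int(rng.integers(2**31)))
            power += res.p_value <= 0.05
            shuffled = rng.permutation(x[order])
            res0 = signal_test(
                {i: float(v) for i, v in zip(prox.ids, shuffled)},
                prox, n_perm=99, seed=int(rng.integers(2**31)))
            type1 += res0.p_value <= 0.05
        assert power / n_rep >= 0.8
        assert type1 / n_rep <= 0.15


class TestFunctionalIdentity:
    def test_identical_trees_strong_signal(self):
        t = simulate_yule_tree(30, seed=2)
        moran, cmean = functional_identity_signal(
            t, t, n_replicates=30, n_perm=99, seed=0)
        assert np.median(moran.per_replicate) > 0.1
        assert np.median(cmean.per_replicate) > 0.2

    def test_label_permuted_tree_no_signal(self):
        n = 30
        t = simulate_yule_tree(n, seed=2)
        shuffled = t.write_newick()
        rng = np.random.default_rng(8)
        perm = rng.permutation(n) + 1
        # consistent relabeling sp%04d -> zz%04d destroys the match
        for old, new in zip(range(1, n + 1), perm):
            shuffled = shuffled.replace(f"sp{old:04d}:", f"zz{new:04d}:")
        shuffled = shuffled.replace("zz", "sp")
        t2 = parse_newick(shuffled)
        moran, cmean = functional_identity_signal(
            t, t2, n_replicates=40, n_perm=49, seed=1)
        null = -1 / (n - 1)
        assert abs(moran.observed - null) < 0.1
        assert abs(cmean.observed - null) < 0.1

    def test_tip_mismatch_error(self):
        t1 = simulate_yule_tree(6, seed=1)
        t2 = simulate_yule_tree(7, seed=1)
        with pytest.raises(ValueError, match="tips"):
            functional_identity_signal(t1, t2, n_replicates=2, n_perm=9)
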