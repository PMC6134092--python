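"""Beta-diversity, PERMANOVA, Mantel, host distances and clade clustering."""

import numpy as np
import pandas as pd
import pytest
from skbio import DistanceMatrix
from skbio.stats.distance import mantel as skbio_mantel
from skbio.stats.distance import permanova as skbio_permanova

import ecoclade as ec
from ecoclade.errors import EcocladeError


class TestBrayCurtis:
    def test_identical_samples_zero(self):
        m = pd.DataFrame({"a": [1, 2], "b": [1, 2]}, index=["x", "y"])
        assert ec.bray_curtis(m)["a", "b"] == 0.0

    def test_disjoint_supports_one(self):
        m = pd.DataFrame({"a": [3, 0], "b": [0, 4]}, index=["x", "y"])
        assert ec.bray_curtis(m)["a", "b"] == 1.0

    def test_formula(self):
        m = pd.DataFrame({"a": [2, 0], "b": [1, 1]}, index=["x", "y"])
        assert ec.bray_curtis(m)["a", "b"] == pytest.approx(0.5)

    def test_binary_equals_weighted_on_binarized(self):
        rng = np.random.default_rng(0)
        m = pd.DataFrame(rng.integers(0, 5, (10, 6)),
                         columns=[f"s{i}" for i in range(6)])
        binar = (m > 0).astype(int)
        np.testing.assert_allclose(
            ec.bray_curtis(m, weighted=False).data,
            ec.bray_curtis(binar, weighted=True).data,
        )

    def test_all_zero_sample_error(self):
        m = pd.DataFrame({"a": [1, 0], "bad": [0, 0]}, index=["x", "y"])
        with pytest.raises(EcocladeError, match="bad"):
            ec.bray_curtis(m)


class TestShannon:
    @pytest.mark.parametrize(
        "counts,expected",
        [([1, 1, 1, 1], np.log(4)), ([5, 0, 0], 0.0), ([2, 1, 1], 1.0397208)],
    )
    def test_closed_forms(self, counts, expected):
        assert ec.shannon_entropy(counts) == pytest.approx(expected)

    def test_all_zero_error(self):
        with pytest.raises(EcocladeError):
            ec.shannon_entropy([0, 0])


def _random_dm(rng, n, ids=None):
    x = rng.random((n, 4))
    d = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(-1))
    return DistanceMatrix(d, ids=ids or [f"s{i}" for i in range(n)])


class TestPermanova:
    def test_perfect_separation(self):
        # zero within-group, positive between: R2 = 1, minimal p
        n, k = 24, 14
        d = np.zeros((n, n))
        d[:k, k:] = 1.0
        d[k:, :k] = 1.0
        dm = DistanceMatrix(d, ids=[f"s{i}" for i in range(n)])
        labels = ["a"] * k + ["b"] * (n - k)
        res = ec.permanova(dm, labels, n_perm=999, seed=0)
        assert res.extra["r2"] == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1 / 1000)

    def test_matches_gower_algebra(self):
        """R2 and pseudo-F agree with the Gower-centred matrix route."""
        rng = np.random.default_rng(4)
        dm = _random_dm(rng, 10)
        labels = np.array(["a"] * 5 + ["b"] * 5)
        res = ec.permanova(dm, labels, n_perm=99, seed=1)
        # Gower: G = -0.5 J A J with A = d^2; SSA = tr(HGH), SST = tr(G)
        A = -0.5 * dm.data ** 2
        n = 10
        J = np.eye(n) - np.ones((n, n)) / n
        G = J @ A @ J
        X = np.stack([(labels == g).astype(float) for g in ["a", "b"]], 1)
        H = X @ np.linalg.inv(X.T @ X) @ X.T
        ssa = np.trace(H @ G @ H)
        sst = np.trace(G)
        ssw = sst - ssa
        f = (ssa / 1) / (ssw / (n - 2))
        assert res.extra["r2"] == pytest.approx(ssa / sst)
        assert res.value == pytest.approx(f)

    def test_matches_skbio_statistic(self):
        rng = np.random.default_rng(5)
        dm = _random_dm(rng, 12)
        labels = ["a", "b", "c"] * 4
        res = ec.permanova(dm, labels, n_perm=99, seed=2)
        ref = skbio_permanova(dm, list(labels), permutations=99)
        assert res.value == pytest.approx(ref["test statistic"])

    def test_single_group_error(self):
        dm = _random_dm(np.random.default_rng(0), 5)
        with pytest.raises(EcocladeError):
            ec.permanova(dm, ["a"] * 5, n_perm=9)

    def test_null_calibration(self):
        """Structure-free distances give roughly uniform p-values."""
        rng = np.random.default_rng(6)
        ps = []
        for _ in range(40):
            dm = _random_dm(rng, 12)
            labels = rng.permutation(["a"] * 6 + ["b"] * 6)
            ps.append(ec.permanova(dm, labels, n_perm=99, seed=rng).p_value)
        assert 0.2 < np.mean(ps) < 0.8


class TestMantel:
    def test_perfect_correlation(self):
        rng = np.random.default_rng(1)
        d1 = _random_dm(rng, 8)
        d2 = DistanceMatrix(2 * d1.data, ids=d1.ids)
        res = ec.mantel(d1, d2, n_perm=999, seed=0)
        assert res.value == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1 / 1000)

    def test_hand_computed_r(self):
        d1 = DistanceMatrix(
            np.array([[0, 1, 2, 3], [1, 0, 4, 5], [2, 4, 0, 6],
                      [3, 5, 6, 0]], dtype=float))
        d2 = DistanceMatrix(
            np.array([[0, 2, 1, 4], [2, 0, 3, 6], [1, 3, 0, 5],
                      [4, 6, 5, 0]], dtype=float))
        res = ec.mantel(d1, d2, n_perm=99, seed=0)
        x = np.array([1, 2, 3, 4, 5, 6], dtype=float)
        y = np.array([2, 1, 4, 3, 6, 5], dtype=float)
        r_hand = np.corrcoef(x, y)[0, 1]
        assert res.value == pytest.approx(r_hand)

    def test_matches_skbio_r(self):
        rng = np.random.default_rng(2)
        d1, d2 = _random_dm(rng, 9), _random_dm(rng, 9)
        res = ec.mantel(d1, d2, n_perm=99, seed=1)
        r_ref, _, _ = skbio_mantel(d1, d2, permutations=0)
        assert res.value == pytest.approx(r_ref)

    def test_size_mismatch_error(self):
        rng = np.random.default_rng(3)
        with pytest.raises(EcocladeError):
            ec.mantel(_random_dm(rng, 5), _random_dm(rng, 6))


class TestHostDistance:
    def test_conspecific_zero_and_delegation(self):
        host = ec.parse_newick("((sp1:1,sp2:2):1,sp3:3);")
        meta = pd.DataFrame(
            {"host_species": ["sp1", "sp1", "sp3"]},
            index=["a", "b", "c"],
        )
        dm = ec.host_distance_matrix(host, meta, "host_species")
        assert dm["a", "b"] == 0.0
        assert dm["a", "c"] == pytest.approx(host.patristic_distance("sp1",
                                                                     "sp3"))

    def test_unmapped_species_listed(self):
        host = ec.parse_newick("(sp1:1,sp2:1);")
        meta = pd.DataFrame({"host_species": ["spX"]}, index=["a"])
        with pytest.raises(EcocladeError, match="spX"):
            ec.host_distance_matrix(host, meta, "host_species")

    def test_full_matrix_equals_expanded_tip_matrix(self):
        host = ec.simulate_tree(5, seed=3)
        species = host.tip_labels
        rng = np.random.default_rng(0)
        assign = rng.choice(species, size=12)
        meta = pd.DataFrame({"host_species": assign},
                            index=[f"s{i}" for i in range(12)])
        dm = ec.host_distance_matrix(host, meta, "host_species")
        base = host.patristic_matrix(species)
        for i, si in enumerate(meta.index):
            for j, sj in enumerate(meta.index):
                assert dm[si, sj] == pytest.approx(
                    base.loc[assign[i], assign[j]])


class TestCladeClustering:
    def test_self_null(self):
        """conserved == all internal nodes reproduces the null exactly."""
        tree = ec.simulate_tree(32, seed=0)
        res = ec.clade_clustering_test(tree, tree.clade_ids, n_boot=50,
                                       seed=1)
        assert res.value == pytest.approx(0.0)
        assert res.p_value > 0.05

    def test_planted_clustering_detected(self):
        tree = ec.simulate_tree(64, seed=17)
        sizes = {c: len(tree.clade_tips(c)) for c in tree.clade_ids}
        sub = min(sizes, key=lambda c: abs(sizes[c] - 8))
        conserved = [c for c in tree.clade_ids
                     if set(tree.clade_tips(c)) <= set(tree.clade_tips(sub))]
        res = ec.clade_clustering_test(tree, conserved, n_boot=1000, seed=2)
        assert res.p_value < 0.01
        assert res.extra["direction"] == "clustered"

    def test_single_clade_error(self):
        tree = ec.simulate_tree(16, seed=1)
        with pytest.raises(EcocladeError):
            ec.clade_clustering_test(tree, [tree.clade_ids[1]])

    def test_exclude_nested_drops_children(self):
        tree = ec.parse_newick("(((A:1,B:1):1,C:1):1,(D:1,E:1):1);")
        conserved = set(tree.clade_ids)  # every parent conserved too
        with pytest.raises(EcocladeError):
            # after exclusion only the root remains
            ec.clade_clustering_test(tree, conserved, exclude_nested=True)

    def test_invariant_to_sibling_order(self):
        tree = ec.simulate_tree(24, seed=5)
        import dendropy
        from test_tree import _shuffled_newick
        tree2 = ec.parse_newick(_shuffled_newick(tree.to_newick(), 7))
        picked = tree.clade_ids[2:8]
        a = ec.clade_clustering_test(tree, picked, n_boot=200, seed=3)
        b = ec.clade_clustering_test(tree2, picked, n_boot=200, seed=3)
        assert a.value == pytest.approx(b.value)
        assert a.p_value == pytest.approx(b.p_value)
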