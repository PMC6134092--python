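"""Permutation null, z test, FDR and the conservation scan."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy.stats import chisquare

import ecoclade as ec
from ecoclade.errors import EcocladeError


def exhaustive_null(tree, presence, clade_id, samples=None):
    """Exact null moments by enumerating every tip permutation."""
    tips = tree.tip_labels
    cols = samples or list(presence.columns)
    members = set(tree.clade_tips(clade_id))
    midx = [i for i, t in enumerate(tips) if t in members]
    P = presence.loc[tips, cols].to_numpy()
    prevs = []
    for perm in itertools.permutations(range(len(tips))):
        rows = P[list(perm)][midx]
        prevs.append(int((rows.sum(axis=0) > 0).sum()))
    prevs = np.asarray(prevs, dtype=float)
    return prevs.mean(), prevs.std(ddof=0)


class TestPermute:
    def test_single_row_identity(self):
        P = np.array([[1, 0, 1]])
        out = ec.permute_presence(P, rng=0)
        np.testing.assert_array_equal(out, P)

    def test_row_multiset_and_column_sums_preserved(self):
        rng = np.random.default_rng(2)
        P = rng.integers(0, 2, size=(12, 6))
        out = ec.permute_presence(P, rng=rng)
        assert sorted(map(tuple, out)) == sorted(map(tuple, P))
        np.testing.assert_array_equal(out.sum(axis=0), P.sum(axis=0))

    @settings(max_examples=50, derandomize=True)
    @given(
        P=arrays(np.int8, shape=st.tuples(st.integers(1, 10),
                                          st.integers(1, 6)),
                 elements=st.integers(0, 1)),
        seed=st.integers(0, 2**20),
    )
    def test_permutation_soundness_property(self, P, seed):
        """Any permuted matrix preserves the row multiset and every
        per-sample presence count."""
        out = ec.permute_presence(P, rng=seed)
        assert sorted(map(tuple, out)) == sorted(map(tuple, P))
        np.testing.assert_array_equal(out.sum(axis=0), P.sum(axis=0))

    def test_uniform_over_permutations(self, three_tip_presence):
        """All 6 permutations of 3 rows appear uniformly (chi-square)."""
        P = three_tip_presence.to_numpy()
        # make rows distinguishable for counting
        tagged = np.arange(3)
        rng = np.random.default_rng(7)
        counts = {p: 0 for p in itertools.permutations(range(3))}
        for _ in range(6000):
            idx = rng.permutation(3)
            counts[tuple(tagged[idx])] += 1
        stat, p = chisquare(list(counts.values()))
        assert p > 1e-3


class TestNullPrevalence:
    def test_all_tips_clade_degenerate(self, cherry_tree,
                                       three_tip_presence):
        null = ec.null_prevalence(cherry_tree, three_tip_presence, n_perm=50,
                                  rng=0)
        assert null.loc["node_0", "null_sd"] == 0.0
        assert null.loc["node_0", "null_mean"] == 2.0

    def test_exhaustive_oracle(self, cherry_tree, three_tip_presence):
        """Exact enumeration gives mean 5/3, sd sqrt(2/9) for clade {A,B}."""
        mean, sd = exhaustive_null(cherry_tree, three_tip_presence, "node_1")
        assert mean == pytest.approx(5 / 3)
        assert sd == pytest.approx(np.sqrt(2 / 9))

    def test_monte_carlo_consistency(self, cherry_tree, three_tip_presence):
        n_perm = 1000
        null = ec.null_prevalence(cherry_tree, three_tip_presence,
                                  n_perm=n_perm, rng=11)
        se = np.sqrt(2 / 9) / np.sqrt(n_perm)
        assert abs(null.loc["node_1", "null_mean"] - 5 / 3) < 3 * se

    def test_n_perm_validation(self, cherry_tree, three_tip_presence):
        with pytest.raises(EcocladeError):
            ec.null_prevalence(cherry_tree, three_tip_presence, n_perm=0)


class TestZTest:
    def test_closed_form(self):
        z, p = ec.z_test_prevalence(10, 4, 2)
        assert z == pytest.approx(3.0)
        assert p == pytest.approx(0.00135, abs=1e-5)

    def test_at_mean(self):
        z, p = ec.z_test_prevalence(5, 5, 1.5)
        assert z == 0.0 and p == 0.5

    def test_degenerate(self):
        assert ec.z_test_prevalence(4, 4, 0)[1] == 1.0
        assert ec.z_test_prevalence(5, 4, 0)[1] == 0.0
        assert ec.z_test_prevalence(3, 4, 0)[1] == 1.0


class TestBH:
    @staticmethod
    def stepup(p):
        """Direct order-statistics BH formula."""
        p = np.asarray(p, dtype=float)
        m = len(p)
        order = np.argsort(p, kind="stable")
        q = np.empty(m)
        prev = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            prev = min(prev, p[i] * m / rank)
            q[i] = prev
        return q

    def test_examples(self):
        np.testing.assert_allclose(ec.bh_fdr([0.01, 0.02, 0.03]),
                                   [0.03, 0.03, 0.03])
        assert ec.bh_fdr([0.2])[0] == pytest.approx(0.2)

    @pytest.mark.parametrize("seed", range(5))
    def test_random_vectors_match_stepup(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.random(50)
        q = ec.bh_fdr(p)
        np.testing.assert_allclose(q, self.stepup(p), atol=1e-12)
        assert (q >= p - 1e-12).all()

    @settings(max_examples=100, derandomize=True)
    @given(p=st.lists(st.floats(0, 1), min_size=1, max_size=60))
    def test_stepup_property(self, p):
        q = ec.bh_fdr(p)
        np.testing.assert_allclose(q, self.stepup(p), atol=1e-12)
        assert (q <= 1 + 1e-12).all() and (q >= np.asarray(p) - 1e-12).all()

    def test_invalid_p_error(self):
        with pytest.raises(EcocladeError):
            ec.bh_fdr([0.5, 1.5])


@pytest.fixture(scope="module")
def planted_cherry():
    config = ec.ScenarioConfig(
            n_tips=64, groups={"GroupA": 20},
            prevalence_alpha=4.0, prevalence_beta=16.0,
            planted=[ec.PlantSpec(clade_size=2, group="GroupA",
                                  prevalence=1.0)],
    )
    return ec.simulate_dataset(config, seed=42)


class TestScan:
    def test_planted_clade_recovered(self, planted_cherry):
        """A cherry planted at 100% prevalence is the top hit, q < 0.05."""
        ds = planted_cherry
        res = ec.test_conservation(ds.tree, ds.table, n_perm=500, seed=1)
        res = res.set_index("clade_id")
        planted = ds.truth["planted"][0]["clade_id"]
        informative = res[~res["degenerate_null"]]
        assert res.loc[planted, "p_value"] == informative["p_value"].min()
        assert res.loc[planted, "q_value"] < 0.05
        assert res.loc[planted, "conserved"]

    def test_root_never_conserved(self, planted_cherry):
        ds = planted_cherry
        res = ec.test_conservation(ds.tree, ds.table, n_perm=100, seed=5)
        root = res.set_index("clade_id").loc["node_0"]
        assert root["null_sd"] == 0.0
        assert root["observed_prevalence"] == root["null_mean"]
        assert not root["conserved"]
        assert root["degenerate_null"]

    def test_reproducible(self, planted_cherry):
        ds = planted_cherry
        a = ec.test_conservation(ds.tree, ds.table, n_perm=50, seed=9)
        b = ec.test_conservation(ds.tree, ds.table, n_perm=50, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_unknown_group_lists_available(self, planted_cherry):
        ds = planted_cherry
        with pytest.raises(EcocladeError, match="GroupA"):
            ec.test_conservation(ds.tree, ds.table, ds.metadata,
                                 "host_order", "Nope", n_perm=10, seed=0)

    def test_empirical_p_option(self, planted_cherry):
        ds = planted_cherry
        res = ec.test_conservation(ds.tree, ds.table, n_perm=99, seed=2,
                                   empirical_p=True)
        assert (res["p_value"] >= 1 / 100).all()
        planted = ds.truth["planted"][0]["clade_id"]
        assert res.set_index("clade_id").loc[planted, "p_value"] == \
            pytest.approx(1 / 100)

    def test_q_at_least_p(self, planted_cherry):
        ds = planted_cherry
        res = ec.test_conservation(ds.tree, ds.table, n_perm=50, seed=3)
        assert (res["q_value"] >= res["p_value"] - 1e-12).all()
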