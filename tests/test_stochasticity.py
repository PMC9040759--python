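import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chisquare

from ncycomm.stochasticity import (
    NullEnsemble,
    null_ensemble,
    randomize_community,
    run_stochasticity,
    stochastic_ratio,
)

from conftest import make_meta, make_table


def _ensemble_from(e, ids):
    return NullEnsemble(pd.DataFrame(e, index=ids, columns=ids), n_null=1)


def _sim_from(c, ids):
    return pd.DataFrame(c, index=ids, columns=ids)


class TestStochasticRatioFormulas:
    def test_equal_observed_and_expected_is_fully_stochastic(self):
        ids = ["a", "b", "c"]
        c = np.array([[1, 0.4, 0.7], [0.4, 1, 0.2], [0.7, 0.2, 1]])
        res = stochastic_ratio(_sim_from(c, ids), _ensemble_from(c, ids))
        assert res.st == pytest.approx(1.0, abs=1e-12)

    def test_branch_a_single_pair(self):
        ids = ["a", "b"]
        c = np.array([[1, 1.0], [1.0, 1]])
        e = np.array([[1, 0.5], [0.5, 1]])
        res = stochastic_ratio(_sim_from(c, ids), _ensemble_from(e, ids))
        assert res.st == pytest.approx(0.5, abs=1e-12)
        assert (res.n_a, res.n_b) == (1, 0)

    def test_branch_b_single_pair(self):
        ids = ["a", "b"]
        c = np.array([[1, 0.2], [0.2, 1]])
        e = np.array([[1, 0.6], [0.6, 1]])
        res = stochastic_ratio(_sim_from(c, ids), _ensemble_from(e, ids))
        # (1 - 0.6) / (1 - 0.2) = 0.5
        assert res.st == pytest.approx(0.5, abs=1e-12)
        assert (res.n_a, res.n_b) == (0, 1)

    def test_degenerate_pairs_contribute_one(self):
        ids = ["a", "b", "c"]
        c = np.array([[1, 0.0, 1.0], [0.0, 1, 0.5], [1.0, 0.5, 1]])
        e = np.array([[1, 0.0, 1.0], [0.0, 1, 0.5], [1.0, 0.5, 1]])
        res = stochastic_ratio(_sim_from(c, ids), _ensemble_from(e, ids))
        assert res.st == pytest.approx(1.0, abs=1e-12)

    def test_contributions_bounded_and_pooled(self):
        rng = np.random.default_rng(0)
        ids = [f"s{i}" for i in range(6)]
        c = rng.uniform(0.05, 0.95, (6, 6))
        c = (c + c.T) / 2
        np.fill_diagonal(c, 1)
        e = rng.uniform(0.05, 0.95, (6, 6))
        e = (e + e.T) / 2
        np.fill_diagonal(e, 1)
        res = stochastic_ratio(_sim_from(c, ids), _ensemble_from(e, ids))
        assert ((res.pairs["contribution"] >= 0) & (res.pairs["contribution"] <= 1)).all()
        assert res.n_a + res.n_b == 15
        assert res.st == pytest.approx(res.pairs["contribution"].mean(), abs=1e-12)

    def test_empty_pair_set_rejected(self):
        ids = ["a", "b"]
        c = np.eye(2)
        with pytest.raises(ValueError, match="pair"):
            stochastic_ratio(_sim_from(c, ids), _ensemble_from(c, ids), pair_subset=["a"])


class TestRandomizeCommunity:
    def _toy(self):
        rng = np.random.default_rng(3)
        x = rng.poisson(4, size=(8, 20)).astype(float)
        x[0, :15] = 0
        x[x.sum(axis=1) == 0, 0] = 1
        return make_table(x)

    def test_richness_and_totals_preserved(self):
        t = self._toy()
        rng = np.random.default_rng(0)
        for _ in range(20):
            null = randomize_community(t, rng)
            assert ((null.values() > 0).sum(1) == (t.values() > 0).sum(1)).all()
            assert np.allclose(null.values().sum(1), t.values().sum(1))

    def test_shuffle_allocation_preserves_value_multiset(self):
        t = self._toy()
        null = randomize_community(t, np.random.default_rng(1), allocation="shuffle")
        for i in range(t.shape[0]):
            obs = np.sort(t.values()[i][t.values()[i] > 0])
            got = np.sort(null.values()[i][null.values()[i] > 0])
            assert np.allclose(obs, got)

    def test_fixed_occupancy_selection_preserves_column_sums(self):
        t = self._toy()
        pres = (t.values() > 0).astype(int)
        null = randomize_community(t, np.random.default_rng(2), selection="fixed_occupancy")
        assert ((null.values() > 0).sum(0) == pres.sum(0)).all()

    def test_selection_frequency_proportional_to_occupancy(self):
        # richness-1 samples make inclusion probability exactly proportional
        # to occupancy: f0 occurs in 2 samples, f1 and f2 in 1 each
        t = make_table([[5, 0, 0], [7, 0, 0], [0, 3, 0], [0, 0, 2]])
        rng = np.random.default_rng(42)
        counts = np.zeros(3)
        n_draws = 10_000
        for _ in range(n_draws):
            counts += randomize_community(t, rng).values()[0] > 0
        expected = np.array([2, 1, 1]) / 4 * n_draws
        assert chisquare(counts, expected).pvalue > 0.01

    def test_richness_exceeding_pool_rejected(self):
        t = make_table([[1, 1], [1, 0]])
        bad = make_table([[1, 1, 1]])
        with pytest.raises(ValueError):
            randomize_community(bad, np.random.default_rng(0))
        randomize_community(t, np.random.default_rng(0))  # fine


class TestNullEnsemble:
    def test_single_draw_equals_one_randomization(self):
        t = TestRandomizeCommunity()._toy()
        from scipy.spatial.distance import pdist, squareform

        ens = null_ensemble(t, n_null=1, rng=7)
        null = randomize_community(t, np.random.default_rng(7))
        expect = squareform(1 - pdist(null.values(), "braycurtis"))
        np.fill_diagonal(expect, 1)
        got = ens.expected_similarity.to_numpy()
        np.fill_diagonal(got, 1)
        assert np.allclose(got, expect)

    def test_disjoint_seeds_converge(self):
        rng = np.random.default_rng(0)
        x = rng.integers(0, 20, size=(10, 12)).astype(float)
        x[x < 6] = 0
        x[x.sum(axis=1) == 0, 0] = 1
        t = make_table(x)
        e1 = null_ensemble(t, 1000, rng=1).expected_similarity.to_numpy()
        e2 = null_ensemble(t, 1000, rng=2).expected_similarity.to_numpy()
        assert np.abs(e1 - e2).max() < 0.02

    def test_identical_full_richness_samples_reproduce_observed(self):
        # continuous totals take the deterministic proportional allocation:
        # identical rows + full richness leave nothing to randomize
        t = make_table([[2.5, 1.5, 1.0]] * 4)
        ens = null_ensemble(t, n_null=5, rng=0)
        off_diag = ens.expected_similarity.to_numpy()[np.triu_indices(4, 1)]
        assert np.allclose(off_diag, 1.0, atol=1e-12)

    def test_expectation_matches_exhaustive_enumeration(self):
        """Brute-force oracle for E under the shuffle-allocation null.

        Enumerates every (feature subset, value assignment) state per
        sample with successive-sampling probabilities and averages the
        exact pairwise similarity; Monte-Carlo E at n_null=5000 must agree.
        """
        x = np.array([[3.0, 1, 0, 0], [0, 2, 2, 0], [4.0, 0, 0, 1]])
        t = make_table(x)
        occ = (x > 0).sum(axis=0).astype(float)

        def sample_states(row):
            vals = row[row > 0]
            k = len(vals)
            states = {}
            for seq in itertools.permutations(range(4), k):
                p = 1.0
                remaining = occ.sum()
                for f in seq:
                    p *= occ[f] / remaining
                    remaining -= occ[f]
                for assign in itertools.permutations(vals):
                    vec = np.zeros(4)
                    vec[list(seq)] = assign
                    key = tuple(vec)
                    # each of the k! assignments of values onto the *set* is
                    # equally likely; ordered seqs enumerate each set k! times
                    states[key] = states.get(key, 0.0) + p / math.factorial(k)
            total = sum(states.values())
            return [(np.array(v), p / total) for v, p in states.items()]

        states = [sample_states(row) for row in x]

        def bc_sim(u, v):
            return 1 - np.abs(u - v).sum() / (u + v).sum()

        exact = np.eye(3)
        for i, j in itertools.combinations(range(3), 2):
            e = sum(pi * pj * bc_sim(vi, vj)
                    for vi, pi in states[i] for vj, pj in states[j])
            exact[i, j] = exact[j, i] = e

        ens = null_ensemble(t, n_null=5000, rng=11, allocation="shuffle")
        got = ens.expected_similarity.to_numpy()
        np.fill_diagonal(got, 1)
        assert np.abs(got - exact).max() < 0.02


class TestRunStochasticity:
    def test_layer_subsets_use_their_own_pool(self):
        # feature f3 occurs only in MES samples: an SRF-only null can never
        # draw it because its occupancy in the SRF pool is zero
        x = np.array(
            [[3, 2, 0, 0], [1, 4, 0, 0], [2, 3, 0, 0],
             [0, 1, 2, 5], [1, 0, 3, 4], [0, 2, 1, 6]], dtype=float
        )
        t = make_table(x)
        srf = t.subset_samples(t.sample_ids[:3])
        rng = np.random.default_rng(0)
        for _ in range(50):
            null = randomize_community(srf, rng)
            assert (null.values()[:, 2:] == 0).all()

    def test_determinism_under_fixed_seed(self):
        t = TestRandomizeCommunity()._toy()
        meta = make_meta(
            np.arange(8.0), layer=["SRF"] * 3 + ["DCM"] * 2 + ["MES"] * 3
        )
        r1 = run_stochasticity(t, meta, n_null=20, rng=5)
        r2 = run_stochasticity(t, meta, n_null=20, rng=5)
        assert r1.keys() == r2.keys()
        for k in r1:
            assert r1[k].st == r2[k].st
            pd.testing.assert_frame_equal(r1[k].pairs, r2[k].pairs)

    def test_st_bounded_on_real_ensembles(self, community):
        _, meta, taxon, _, _ = community
        res = run_stochasticity(taxon, meta, n_null=30, rng=1, groups=("all", "SRF"))
        for r in res.values():
            assert 0.0 <= r.st <= 1.0
            assert ((r.pairs["contribution"] >= 0) & (r.pairs["contribution"] <= 1)).all()
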