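import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from ncycomm.assembly import (
    anosim,
    bh_adjust,
    compare_groups,
    environment_distance,
    factor_importance,
    mantel,
    mrpp,
    partial_mantel,
    permanova,
)

from conftest import make_meta, make_table


def _dm(arr):
    arr = np.asarray(arr, dtype=float)
    return DistanceMatrix(arr, ids=[f"s{i}" for i in range(arr.shape[0])])


def _random_dm(rng, n, p=4):
    return _dm(squareform(pdist(rng.normal(size=(n, p)))))


def _rank_toy():
    """6-sample matrix whose pair distances are the ranks 1..15.

    Within group A (samples 0-2): 1, 3, 5; within B (3-5): 7, 9, 11;
    between: 2, 4, 6, 8, 10, 12, 13, 14, 15.
    Hand evaluation: mean within rank = 6, mean between rank = 84/9,
    ANOSIM R = (84/9 - 6) / (6*5/4) = 4/9; MRPP delta = (3 + 9)/2 = 6.
    """
    d = np.zeros((6, 6))
    vals = {
        (0, 1): 1, (0, 2): 3, (1, 2): 5,
        (3, 4): 7, (3, 5): 9, (4, 5): 11,
        (0, 3): 2, (0, 4): 4, (0, 5): 6,
        (1, 3): 8, (1, 4): 10, (1, 5): 12,
        (2, 3): 13, (2, 4): 14, (2, 5): 15,
    }
    for (i, j), v in vals.items():
        d[i, j] = d[j, i] = v
    return _dm(d), ["A", "A", "A", "B", "B", "B"]


class TestPermanova:
    def test_statistic_matches_skbio(self):
        from skbio.stats.distance import permanova as sk_permanova

        rng = np.random.default_rng(0)
        d = _random_dm(rng, 12)
        groups = ["a"] * 6 + ["b"] * 6
        mine = permanova(d, groups, n_perm=99, rng=rng)
        ref = sk_permanova(d, groups, permutations=99)
        assert mine.statistic == pytest.approx(ref["test statistic"], abs=1e-9)

    def test_separated_clusters_reach_minimal_p(self):
        rng = np.random.default_rng(3)
        x = np.vstack([rng.normal(0, 0.1, (8, 3)), rng.normal(30, 0.1, (12, 3))])
        res = permanova(_dm(squareform(pdist(x))), ["a"] * 8 + ["b"] * 12,
                        n_perm=999, rng=rng)
        assert res.p_value == pytest.approx(1 / 1000)

    def test_permutation_p_matches_exhaustive_enumeration(self):
        # brute-force oracle: all distinct assignments of 2 + 3 labels
        rng = np.random.default_rng(5)
        d2 = _random_dm(rng, 5).data ** 2
        labels = np.array([0, 0, 1, 1, 1])

        def brute_f(codes):
            n = 5
            ss_t = d2[np.triu_indices(n, 1)].sum() / n
            ss_w = 0.0
            for g in (0, 1):
                idx = np.flatnonzero(codes == g)
                sub = d2[np.ix_(idx, idx)]
                ss_w += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
            return ((ss_t - ss_w) / 1) / (ss_w / 3)

        f_obs = brute_f(labels)
        perms = {tuple(p) for p in itertools.permutations(labels)}
        exact_p = np.mean([brute_f(np.array(p)) >= f_obs - 1e-12 for p in perms])
        mine = permanova(_dm(np.sqrt(d2)), labels, n_perm=999, rng=1)
        assert mine.statistic == pytest.approx(f_obs, abs=1e-9)
        assert abs(mine.p_value - exact_p) < 0.02

    def test_singleton_group_rejected(self):
        with pytest.raises(ValueError, match="singleton"):
            permanova(_random_dm(np.random.default_rng(0), 5), ["a"] + ["b"] * 4)


class TestAnosim:
    def test_perfect_separation_gives_r_of_one(self):
        d = np.zeros((6, 6))
        # all between-distances exceed all within-distances
        for i in range(6):
            for j in range(6):
                if i != j:
                    same = (i < 3) == (j < 3)
                    d[i, j] = 1 if same else 10
        res = anosim(_dm(d), ["A"] * 3 + ["B"] * 3, n_perm=99, rng=0)
        assert res.statistic == pytest.approx(1.0, abs=1e-12)

    def test_hand_computed_rank_toy(self):
        d, groups = _rank_toy()
        res = anosim(d, groups, n_perm=99, rng=0)
        assert res.statistic == pytest.approx(4 / 9, abs=1e-12)

    def test_random_labels_center_r_near_zero(self):
        rng = np.random.default_rng(2)
        d = _random_dm(rng, 14)
        stats = [
            anosim(d, rng.permutation(["a"] * 7 + ["b"] * 7), n_perm=49, rng=rng).statistic
            for _ in range(40)
        ]
        assert abs(np.mean(stats)) < 0.05

    def test_statistic_matches_skbio(self):
        from skbio.stats.distance import anosim as sk_anosim

        rng = np.random.default_rng(8)
        d = _random_dm(rng, 10)
        groups = ["a"] * 5 + ["b"] * 5
        mine = anosim(d, groups, n_perm=99, rng=rng)
        ref = sk_anosim(d, groups, permutations=99)
        assert mine.statistic == pytest.approx(ref["test statistic"], abs=1e-9)


class TestMrpp:
    def test_hand_computed_delta(self):
        d, groups = _rank_toy()
        res = mrpp(d, groups, n_perm=99, rng=0)
        assert res.extra["delta"] == pytest.approx(6.0, abs=1e-12)

    def test_zero_within_distances_give_a_of_one(self):
        d = np.zeros((6, 6))
        for i in range(6):
            for j in range(6):
                if i != j and (i < 3) != (j < 3):
                    d[i, j] = 5.0
        res = mrpp(_dm(d), ["A"] * 3 + ["B"] * 3, n_perm=199, rng=0)
        assert res.extra["delta"] == 0.0
        assert res.statistic == pytest.approx(1.0, abs=1e-12)

    def test_random_labels_center_a_near_zero(self):
        rng = np.random.default_rng(4)
        d = _random_dm(rng, 14)
        stats = [
            mrpp(d, rng.permutation(["a"] * 7 + ["b"] * 7), n_perm=99, rng=rng).statistic
            for _ in range(30)
        ]
        assert abs(np.mean(stats)) < 0.05


class TestMantel:
    def test_identity_gives_r_of_one(self):
        d = _random_dm(np.random.default_rng(0), 8)
        res = mantel(d, d, n_perm=99, rng=0)
        assert res.statistic == pytest.approx(1.0, abs=1e-12)

    def test_r_matches_skbio(self):
        from skbio.stats.distance import mantel as sk_mantel

        rng = np.random.default_rng(1)
        d1, d2 = _random_dm(rng, 10), _random_dm(rng, 10)
        for method in ("pearson", "spearman"):
            mine = mantel(d1, d2, n_perm=99, method=method, rng=rng)
            ref = sk_mantel(d1, d2, method=method, permutations=99)[0]
            assert mine.statistic == pytest.approx(float(ref), abs=1e-9)

    def test_null_r_centers_at_zero(self):
        rng = np.random.default_rng(9)
        rs = [
            mantel(_random_dm(rng, 10), _random_dm(rng, 10), n_perm=9, rng=rng).statistic
            for _ in range(60)
        ]
        assert abs(np.mean(rs)) < 0.05

    def test_permutation_p_matches_exhaustive_relabelings(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(5, 3))
        d1 = squareform(pdist(x))
        d2 = squareform(pdist(x + rng.normal(0, 0.2, x.shape)))
        iu = np.triu_indices(5, 1)
        r_obs = np.corrcoef(d1[iu], d2[iu])[0, 1]
        count = 0
        for perm in itertools.permutations(range(5)):
            dp = d1[np.ix_(perm, perm)]
            if np.corrcoef(dp[iu], d2[iu])[0, 1] >= r_obs - 1e-12:
                count += 1
        exact_p = count / 120
        mine = mantel(_dm(d1), _dm(d2), n_perm=999, rng=2)
        assert mine.statistic == pytest.approx(r_obs, abs=1e-12)
        assert abs(mine.p_value - exact_p) < 0.02


class TestPartialMantel:
    def test_fully_controlled_gives_zero(self):
        rng = np.random.default_rng(0)
        dB = _random_dm(rng, 8)
        dA = _random_dm(rng, 8)
        res = partial_mantel(dA, dB, dB, n_perm=49, rng=rng)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_uncorrelated_control_approaches_plain_mantel(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(40, 3))
        dA = _dm(squareform(pdist(x)))
        dB = _dm(squareform(pdist(x + rng.normal(0, 0.6, x.shape))))
        dC = _random_dm(rng, 40)
        r_plain = mantel(dA, dB, n_perm=9, rng=rng).statistic
        r_part = partial_mantel(dA, dB, dC, n_perm=9, rng=rng).statistic
        assert abs(r_part - r_plain) < 0.05

    def test_formula_oracle_on_toy(self):
        rng = np.random.default_rng(3)
        dA, dB, dC = (_random_dm(rng, 6) for _ in range(3))
        iu = np.triu_indices(6, 1)
        a, b, c = dA.data[iu], dB.data[iu], dC.data[iu]
        r_ab = np.corrcoef(a, b)[0, 1]
        r_ac = np.corrcoef(a, c)[0, 1]
        r_bc = np.corrcoef(b, c)[0, 1]
        expect = (r_ab - r_ac * r_bc) / np.sqrt((1 - r_ac**2) * (1 - r_bc**2))
        res = partial_mantel(dA, dB, dC, n_perm=9, rng=0)
        assert res.statistic == pytest.approx(expect, abs=1e-12)

    def test_control_identical_to_tested_matrix_gives_zero(self):
        # |r_BC| = 1 forces the numerator to zero too: the defined limit of
        # the partial correlation is 0 (everything is controlled away)
        d = _random_dm(np.random.default_rng(0), 6)
        res = partial_mantel(d, d, d, n_perm=9, rng=0)
        assert res.statistic == 0.0


class TestCompareGroups:
    def _meta(self):
        return make_meta(
            np.zeros(10),
            layer=["SRF"] * 5 + ["MES"] * 5,
        )

    def test_disjoint_ranges_reach_exact_rank_sum_p(self):
        t = make_table(
            np.column_stack([np.r_[1.0, 2, 3, 4, 5, 11, 12, 13, 14, 15]]),
            feature_ids=["pathway1"],
        )
        res = compare_groups(t, self._meta())
        assert res.loc["pathway1", "p_value"] == pytest.approx(2 / 252, abs=1e-12)
        assert res.loc["pathway1", "higher_in"] == "mesopelagic"

    def test_identical_distributions_not_significant(self):
        vals = np.r_[1.0, 2, 3, 4, 5, 1, 2, 3, 4, 5]
        t = make_table(np.column_stack([vals, vals[::-1]]), feature_ids=["p1", "p2"])
        res = compare_groups(t, self._meta())
        assert (res["p_adjusted"] > 0.9).all()

    def test_bh_adjustment_hand_example(self):
        adj = bh_adjust([0.01, 0.02, 0.03, 0.5])
        assert np.allclose(adj, [0.04, 0.04, 0.04, 0.5], atol=1e-12)


class TestFactorImportance:
    def test_planted_linear_factor_ranked_first(self):
        rng = np.random.default_rng(0)
        env = pd.DataFrame(rng.normal(size=(60, 5)),
                           columns=[f"v{i + 1}" for i in range(5)])
        y = 3.0 * env["v1"].to_numpy() + rng.normal(0, 0.1, 60)
        imp = factor_importance(y, env, n_trees=100, rng=1)
        assert imp.index[0] == "v1"
        assert imp.attrs["best_factor"] == "v1"
        assert imp["univariate_r2"].idxmax() == "v1"

    def test_near_duplicate_signal_pair_stays_above_noise(self):
        rng = np.random.default_rng(2)
        v1 = rng.normal(size=80)
        env = pd.DataFrame(
            {
                "v1": v1,
                "v1_dup": v1 + rng.normal(0, 0.05, 80),
                "n1": rng.normal(size=80),
                "n2": rng.normal(size=80),
            }
        )
        y = 2.0 * v1 + rng.normal(0, 0.1, 80)
        imp = factor_importance(y, env, n_trees=200, rng=3)
        noise_max = imp.loc[["n1", "n2"], "importance"].max()
        assert (imp.loc[["v1", "v1_dup"], "importance"] > noise_max).all()

    def test_pure_noise_importances_indistinguishable(self):
        # over independent noise datasets no column position should win the
        # top rank systematically
        winners = []
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            env = pd.DataFrame(rng.normal(size=(50, 4)), columns=list("abcd"))
            y = rng.normal(size=50)
            imp = factor_importance(y, env, n_trees=50, n_perm_repeats=5, rng=seed)
            winners.append(imp.index[0])
        counts = pd.Series(winners).value_counts()
        assert counts.iloc[0] <= 6

    def test_constant_response_rejected(self):
        env = pd.DataFrame(np.random.default_rng(0).normal(size=(20, 3)))
        with pytest.raises(ValueError, match="constant"):
            factor_importance(np.ones(20), env)


class TestEnvironmentDistance:
    def test_standardization_prevents_unit_dominance(self):
        meta = make_meta(
            np.zeros(4),
            temperature=[10.0, 11, 12, 13],
            nitrate=[1000.0, 2000, 3000, 4000],
        )
        d_std = environment_distance(meta).data
        d_raw = environment_distance(meta, standardize=False).data
        # raw distance is nitrate-dominated; after z-scoring both variables
        # contribute equally: step distance = sqrt(2) * (1 / sd of 0..3)
        assert d_raw[0, 1] > 100
        assert d_std[0, 1] == pytest.approx(np.sqrt(2) / np.std([0, 1, 2, 3]), abs=1e-9)
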