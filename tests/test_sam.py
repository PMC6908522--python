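"""SAM statistics against hand formulas, brute-force oracles and calibration."""

import itertools

import numpy as np
import pytest
from scipy import stats

from coexmeta.errors import StatisticsError
from coexmeta.normalization import glog_transform
from coexmeta.sam import (call_degs, estimate_s0, permutation_pvalues,
                          pooled_se, sam_analyze, sam_statistics, storey_q)
from coexmeta.simulate import SimulationConfig, gen_expression_study

from conftest import make_study


def two_group_study(case_rows, ctrl_rows):
    """Features x (ctrl then case) study from per-group row lists."""
    case = np.asarray(case_rows, dtype=float)
    ctrl = np.asarray(ctrl_rows, dtype=float)
    values = np.hstack([ctrl, case])
    groups = ["control"] * ctrl.shape[1] + ["case"] * case.shape[1]
    return make_study(values, groups)


class TestPooledSe:
    def test_zero_variance_gives_zero(self):
        s = pooled_se(np.array([[1.0, 1, 1, 3, 3, 3]]),
                      np.array([0, 0, 0, 1, 1, 1], bool))
        assert s[0] == 0.0

    def test_hand_computed_fixture(self):
        # case=[2,4], ctrl=[1,3]: s = sqrt(2); t (s0=0) = 1/sqrt(2)
        matrix = np.array([[1.0, 3.0, 2.0, 4.0]])
        mask = np.array([0, 0, 1, 1], bool)
        s = pooled_se(matrix, mask)
        assert s[0] == pytest.approx(np.sqrt(2), abs=1e-12)
        study = two_group_study([[2, 4]], [[1, 3]])
        d = sam_statistics(study, s0=0.0)["d"]
        assert d.iloc[0] == pytest.approx(0.70711, abs=1e-5)

    def test_equal_within_variance_gives_equal_s(self, rng):
        # all groups of size 2 with identical within-group deviations
        base = rng.normal(size=10)
        matrix = np.column_stack([base - 1, base + 1, base - 1, base + 1])
        mask = np.array([0, 0, 1, 1], bool)
        s = pooled_se(matrix, mask)
        np.testing.assert_allclose(s, s[0], atol=1e-12)

    def test_group_too_small_rejected(self):
        with pytest.raises(StatisticsError):
            pooled_se(np.ones((3, 3)), np.array([1, 0, 0], bool))

    def test_equals_pooled_t_when_s0_zero(self, rng):
        """With s0 = 0, d is exactly the classical pooled t statistic."""
        x = rng.normal(size=(1000, 14))
        study = make_study(x, ["control"] * 6 + ["case"] * 8)
        d = sam_statistics(study, s0=0.0)["d"].to_numpy()
        t = stats.ttest_ind(x[:, 6:], x[:, :6], axis=1, equal_var=True).statistic
        np.testing.assert_allclose(d, t, atol=1e-12)


class TestSamStatistics:
    def test_hand_fixture_with_fudge(self):
        study = two_group_study([[3, 3, 3]], [[1, 1, 1]])
        out = sam_statistics(study, s0=0.5)
        assert out["d"].iloc[0] == pytest.approx(4.0)
        assert out["direction"].iloc[0] == 1

    def test_identical_means_give_zero(self):
        study = two_group_study([[1, 2, 3]], [[3, 2, 1]])
        out = sam_statistics(study, s0=0.1)
        assert out["d"].iloc[0] == 0.0
        assert out["direction"].iloc[0] == 0

    def test_label_swap_antisymmetry(self, rng):
        x = rng.normal(size=(50, 10))
        a = make_study(x, ["control"] * 5 + ["case"] * 5)
        b = make_study(x, ["case"] * 5 + ["control"] * 5)
        da = sam_statistics(a, s0=0.3)
        db = sam_statistics(b, s0=0.3)
        np.testing.assert_allclose(da["d"], -db["d"], atol=1e-12)
        assert (da["direction"] == -db["direction"]).all()

    def test_zero_denominator_with_signal_rejected(self):
        study = two_group_study([[3, 3, 3]], [[1, 1, 1]])
        with pytest.raises(StatisticsError, match="zero denominator"):
            sam_statistics(study, s0=0.0)


class TestEstimateS0:
    def test_matches_brute_force_grid_oracle(self, rng):
        # Tusher-style data: mixture of variances plus some shifted genes
        m = 2000
        sd = rng.choice([0.2, 0.5, 1.0, 2.0], size=m)
        x = rng.normal(0, sd[:, None], size=(m, 12))
        x[:100, 6:] += 2.0
        mask = np.array([0] * 6 + [1] * 6, bool)
        s = pooled_se(x, mask)
        delta = x[:, mask].mean(axis=1) - x[:, ~mask].mean(axis=1)

        def oracle(delta, s):
            order = np.argsort(s, kind="stable")
            bins = np.array_split(order, 100)
            best, best_cv = None, np.inf
            for alpha in np.round(np.arange(0, 1.0001, 0.05), 2):
                s0 = np.quantile(s, alpha)
                d = delta / (s + s0)
                mads = np.array([1.4826 * np.median(np.abs(d[b] - np.median(d[b])))
                                 for b in bins])
                cv = mads.std(ddof=1) / mads.mean()
                if cv < best_cv - 1e-15:
                    best, best_cv = s0, cv
            return best

        s0, _ = estimate_s0(delta, s)
        assert s0 == pytest.approx(oracle(delta, s), abs=1e-12)

    def test_all_s_equal_returns_zero_with_warning(self, caplog):
        delta = np.array([1.0, -1.0, 2.0, 0.5] * 30)
        s = np.full(120, 0.7)
        with caplog.at_level("WARNING"):
            s0, alpha = estimate_s0(delta, s)
        assert s0 == 0.0
        assert any("identical" in r.message for r in caplog.records)


class TestPermutationPvalues:
    def test_constant_features_have_p_one(self):
        study = make_study(np.ones((5, 8)), ["control"] * 4 + ["case"] * 4)
        p, _, _ = permutation_pvalues(study, s0=0.0, B=50, seed=1)
        np.testing.assert_array_equal(p, 1.0)

    def test_matches_brute_force_enumeration(self, rng):
        """Exhaustive 3+3 design: p from an independent re-computation."""
        x = rng.normal(size=(4, 6))
        x[0, 3:] += 3
        study = make_study(x, ["control"] * 3 + ["case"] * 3)
        s0 = 0.2
        p, _, b_eff = permutation_pvalues(study, s0=s0, B=50, seed=5)
        assert b_eff == 19  # C(6,3) - identity

        # oracle: enumerate every non-identity case-assignment directly
        null = []
        for combo in itertools.combinations(range(6), 3):
            if combo == (3, 4, 5):
                continue
            mask = np.zeros(6, bool)
            mask[list(combo)] = True
            for j in range(4):
                c, u = x[j, mask], x[j, ~mask]
                ss = ((c - c.mean()) ** 2).sum() + ((u - u.mean()) ** 2).sum()
                s = np.sqrt(((1 / 3 + 1 / 3) / 4) * ss)
                null.append(abs((c.mean() - u.mean()) / (s + s0)))
        null = np.array(null)
        d_obs = sam_statistics(study, s0)["d"].abs().to_numpy()
        null = np.round(null, 12)
        p_oracle = np.array([(1 + (null >= round(d, 12)).sum()) / (1 + null.size)
                             for d in d_obs])
        np.testing.assert_allclose(p, p_oracle, atol=1e-12)

    def test_null_pvalues_uniform(self):
        cfg = SimulationConfig(n_genes=1000, samples_per_group=10,
                               effect_size=0.0, seed=9)
        study, _ = gen_expression_study(cfg, "LC", 9)
        norm = glog_transform(study)
        res = sam_analyze(norm, B=200, seed=9)
        ks = stats.kstest(res.table["p_perm"], "uniform").statistic
        assert ks <= 0.05

    def test_invariant_to_feature_order(self, rng):
        x = rng.normal(size=(30, 10))
        study = make_study(x, ["control"] * 5 + ["case"] * 5)
        perm = rng.permutation(30)
        shuffled = make_study(x[perm], ["control"] * 5 + ["case"] * 5,
                              features=[f"g{i}" for i in perm])
        p1, _, _ = permutation_pvalues(study, 0.1, B=100, seed=3)
        p2, _, _ = permutation_pvalues(shuffled, 0.1, B=100, seed=3)
        np.testing.assert_allclose(p1[perm], p2, atol=1e-12)


class TestStoreyQ:
    def test_single_p_formula(self):
        q, pi0 = storey_q(np.array([0.8]), lam=0.5)
        assert pi0 == 1.0
        assert q[0] == pytest.approx(0.8)

    def test_bh_equivalence_when_pi0_one(self):
        # p chosen so pi0 estimates to 1 is impossible at m=3; check the
        # step-up arithmetic directly with the pi0 the data imply
        p = np.array([0.01, 0.02, 0.03, 0.9, 0.8, 0.7])
        q, pi0 = storey_q(p, lam=0.5)
        assert pi0 == 1.0  # 3 of 6 above 0.5 -> 3/(6*0.5) = 1
        # BH: q = [0.06*... ] step-up of p*m/rank
        expected = np.array([0.06, 0.06, 0.06, 0.9, 0.9, 0.9])
        np.testing.assert_allclose(q, expected, atol=1e-12)

    def test_all_p_one(self):
        q, pi0 = storey_q(np.ones(10))
        assert pi0 == 1.0
        np.testing.assert_array_equal(q, 1.0)

    def test_monotone_in_p(self, rng):
        p = rng.uniform(size=500)
        q, _ = storey_q(p)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(q[order]) >= -1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(StatisticsError):
            storey_q(np.array([0.5, 1.2]))


class TestCallDegs:
    def test_empty_call_set_has_zero_fdr(self):
        cfg = SimulationConfig(n_genes=200, samples_per_group=5,
                               effect_size=0.0, seed=17)
        study, _ = gen_expression_study(cfg, "LC", 17)
        res = sam_analyze(glog_transform(study), B=100, seed=17)
        if int(res.table["called"].sum()) == 0:
            assert res.fdr_at_call == 0.0
            assert not res.fdr_flagged

    def test_gene_below_threshold_called(self, rng):
        x = rng.normal(size=(500, 20))
        x[0, 10:] += 5.0  # one overwhelming signal
        study = make_study(x, ["control"] * 10 + ["case"] * 10)
        res = sam_analyze(study, B=200, seed=2)
        row = res.table.iloc[0]
        assert row["q"] < 0.01 and bool(row["called"])

    def test_planted_signal_recall_and_fdp(self):
        """Mean FDP <= 0.15 and recall >= 0.8 on 10% non-null simulations."""
        fdps, recalls = [], []
        for rep in range(5):
            cfg = SimulationConfig(n_genes=1000, samples_per_group=10,
                                   effect_size=1.5, seed=13 + rep,
                                   n_winner_up=50, n_winner_down=50)
            study, truth = gen_expression_study(cfg, "LC", 13 + rep)
            res = sam_analyze(glog_transform(study), B=200, seed=13 + rep)
            called = set(res.table.index[res.table["called"]])
            planted = truth.planted_up | truth.planted_down
            if called:
                fdps.append(len(called - planted) / len(called))
            recalls.append(len(called & planted) / len(planted))
        assert np.mean(fdps) <= 0.15
        assert np.mean(recalls) >= 0.8
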