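import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from adjclust.errors import ArgumentError
from adjclust.io_prep import SampleMeta
from adjclust.stunting import (
    assign_groups,
    candidates,
    combine_pvalues,
    condition_filter,
    event_statistic,
    permutation_screen,
    pooled_sd,
    validate_marker,
    validate_pc1,
)
from adjclust.synthetic import simulate_screen_features


def _meta(sid, location, haz=None, condition="PMA-ionomycin"):
    return SampleMeta(
        sample_id=sid,
        donor_id=sid,
        location=location,
        week="53",
        condition=condition,
        haz=haz,
    )


class TestAssignGroups:
    def test_threshold_boundaries_and_american_imputation(self):
        metas = [
            _meta("b1", "Bangladesh", haz=-1.5),
            _meta("b2", "Bangladesh", haz=-1.49),
            _meta("b3", "Bangladesh", haz=-3.0),
            _meta("u1", "USA", haz=0.7),  # recorded HAZ ignored, imputed 0
        ]
        groups = assign_groups(metas)
        assert groups.group2 == ("b1", "b3")  # HAZ <= -1.5 inclusive
        assert groups.group1 == ("b2",)
        assert groups.group0 == ("u1",)
        assert groups.haz["u1"] == 0.0

    def test_missing_haz_excluded_with_warning(self):
        metas = [_meta("b1", "Bangladesh", haz=None), _meta("u1", "USA")]
        with pytest.warns(UserWarning, match="b1"):
            groups = assign_groups(metas)
        assert groups.group1 == () and groups.group2 == ()


class TestEventStatistic:
    def test_equal_means_never_fire_for_positive_theta(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=6)
        out = event_statistic(base, base + 0.0, base, theta=0.1)
        assert out["event"] is False
        assert out["d0"] == pytest.approx(0.0)

    def test_vacuous_threshold(self):
        rng = np.random.default_rng(1)
        out = event_statistic(
            rng.normal(size=4), rng.normal(size=4), rng.normal(size=4), theta=-100.0
        )
        assert out["event"] is True

    def test_hand_computed_pooled_sds_and_diffs(self):
        g0, g1, g2 = [2.0, 4.0], [0.0, 2.0], [3.0, 5.0]
        # all three groups have sample variance 2 -> pooled SDs sqrt(2)
        out = event_statistic(g0, g1, g2, theta=0.5)
        s = np.sqrt(2.0)
        assert out["s0"] == pytest.approx(s)
        assert out["s2"] == pytest.approx(s)
        assert out["d0"] == pytest.approx(2.0 / s)
        assert out["d2"] == pytest.approx(3.0 / s)
        assert out["event"] is True

    def test_zero_pooled_sd_is_undefined(self):
        out = event_statistic([1.0, 1.0], [1.0, 1.0], [1.0, 1.0], theta=0.0)
        assert out["event"] is None

    def test_translation_and_scale_invariance(self):
        rng = np.random.default_rng(2)
        g0, g1, g2 = rng.normal(size=(3, 5))
        a = event_statistic(g0, g1, g2, theta=0.3)
        b = event_statistic(g0 + 7, g1 + 7, g2 + 7, theta=0.3)
        c = event_statistic(g0 * 3, g1 * 3, g2 * 3, theta=0.3)
        assert a["d0"] == pytest.approx(b["d0"]) == pytest.approx(c["d0"])
        assert a["d2"] == pytest.approx(b["d2"]) == pytest.approx(c["d2"])

    def test_pooled_sd_formula(self):
        a = np.array([1.0, 2.0, 3.0])
        b = np.array([4.0, 8.0])
        expected = np.sqrt((2 * np.var(a, ddof=1) + 1 * np.var(b, ddof=1)) / 3)
        assert pooled_sd(a, b) == pytest.approx(expected)


class TestConditionFilter:
    def test_planted_mislabeled_sample_removed(self):
        rng = np.random.default_rng(3)
        stim = rng.normal(5.0, 0.3, size=(6, 4))
        unstim = rng.normal(0.0, 0.3, size=(6, 4))
        x = pd.DataFrame(np.vstack([stim, unstim]),
                         index=[f"s{i}" for i in range(12)])
        labels = pd.Series(
            ["stim"] * 6 + ["unstim"] * 6, index=x.index
        )
        labels.loc["s3"] = "unstim"  # stim profile declared unstim
        keep = condition_filter(x, labels, seed=0)
        assert "s3" not in keep
        assert len(keep) == 11

    def test_consistent_labels_keep_everything(self):
        rng = np.random.default_rng(4)
        x = pd.DataFrame(
            np.vstack([rng.normal(4, 0.2, (5, 3)), rng.normal(0, 0.2, (5, 3))]),
            index=[f"s{i}" for i in range(10)],
        )
        labels = pd.Series(["stim"] * 5 + ["unstim"] * 5, index=x.index)
        assert condition_filter(x, labels, seed=0) == list(x.index)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(5)
        x = pd.DataFrame(rng.normal(size=(10, 4)), index=[f"s{i}" for i in range(10)])
        labels = pd.Series(["stim", "unstim"] * 5, index=x.index)
        assert condition_filter(x, labels, seed=7) == condition_filter(x, labels, seed=7)

    def test_degenerate_identical_vectors_retained(self):
        x = pd.DataFrame(np.ones((4, 3)), index=list("abcd"))
        labels = pd.Series(["stim", "stim", "unstim", "unstim"], index=x.index)
        with pytest.warns(UserWarning, match="identical"):
            assert condition_filter(x, labels) == list("abcd")


class TestPermutationScreen:
    def test_null_discoveries_super_uniform(self):
        # under the null the observed grouping is exchangeable with the
        # permutations, so Pr(event observed AND its permutation rate <= a) <= a
        frac = []
        for seed in range(5):
            feats, groups = simulate_screen_features(n_features=60, seed=100 + seed)
            screen = permutation_screen(
                feats, groups, theta_grid=(0.0,), n_perm=400, seed=seed
            )
            hit = (screen["event"] == True) & (screen["perm_p"] <= 0.05)  # noqa: E712
            frac.append(hit.mean())
        n_tot = 5 * 60
        assert np.mean(frac) <= 0.05 + 1.96 * np.sqrt(0.05 * 0.95 / n_tot) + 0.01

    def test_planted_feature_recovered_as_candidate(self):
        feats, groups = simulate_screen_features(
            n_features=50, planted=(3, 11, 27, 40), effect_sd=2.0, seed=2
        )
        screen = permutation_screen(feats, groups, n_perm=500, seed=3)
        cand = candidates(screen)
        assert "feat03" in set(cand["feature"])

    def test_exchangeable_data_fdr_near_one(self):
        feats, groups = simulate_screen_features(n_features=40, seed=6)
        screen = permutation_screen(feats, groups, theta_grid=(0.0,), n_perm=300, seed=4)
        fired = screen[screen["event"] == True]  # noqa: E712
        if len(fired):
            assert fired["perm_fdr"].min() > 0.5

    def test_same_seed_identical_results(self):
        feats, groups = simulate_screen_features(n_features=20, seed=8)
        a = permutation_screen(feats, groups, theta_grid=(0.0, 0.5), n_perm=200, seed=9)
        b = permutation_screen(feats, groups, theta_grid=(0.0, 0.5), n_perm=200, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_tiny_group_rejected(self):
        feats, groups = simulate_screen_features(n0=1, seed=0)
        with pytest.raises(ArgumentError):
            permutation_screen(feats, groups, n_perm=100)


class TestValidatePc1:
    def test_single_column_reduces_to_one_sided_t(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=16)
        stunted = np.r_[np.zeros(8), np.ones(8)]
        x[8:] += 1.0
        share, p = validate_pc1(pd.DataFrame({"c": x}), stunted)
        assert share == 1.0
        t = sps.ttest_ind(x[8:], x[:8], equal_var=True, alternative="greater")
        assert p == pytest.approx(t.pvalue, rel=1e-9)

    def test_perfectly_correlated_columns_share_one(self):
        rng = np.random.default_rng(12)
        base = rng.normal(size=10)
        mat = pd.DataFrame({"a": base, "b": 2 * base, "c": -base})
        share, _ = validate_pc1(mat, np.r_[np.zeros(5), np.ones(5)])
        assert share == pytest.approx(1.0)

    def test_power_on_planted_shift_across_columns(self):
        rng = np.random.default_rng(13)
        hits = 0
        for rep in range(20):
            base = rng.normal(size=(16, 4)) + rng.normal(size=(16, 1))
            base[8:] += 2.0  # 2 SD shift in the stunted half
            _, p = validate_pc1(
                pd.DataFrame(base), np.r_[np.zeros(8), np.ones(8)]
            )
            hits += p < 0.05
        assert hits >= 18

    def test_validate_marker_combines_train_and_validation(self):
        rng = np.random.default_rng(14)
        train = pd.DataFrame(rng.normal(size=(16, 3)))
        valid = pd.DataFrame(rng.normal(size=(9, 2)))
        train.iloc[8:] += 1.5
        valid.iloc[5:] += 1.5
        res = validate_marker(
            "IL-8",
            train,
            np.r_[np.zeros(8), np.ones(8)],
            valid,
            np.r_[np.zeros(5), np.ones(4)],
        )
        assert res.p_combined == pytest.approx(
            combine_pvalues(res.p_train, res.p_valid)
        )
        assert res.p_combined < max(res.p_train, res.p_valid)


class TestCombinePvalues:
    def test_identity_at_one_and_chi2_value(self):
        assert combine_pvalues(1.0, 1.0) == pytest.approx(1.0)
        # -2(ln .05 + ln .05) = 11.98 -> chi2(4) tail ~ 0.0175
        assert combine_pvalues(0.05, 0.05) == pytest.approx(0.01752, abs=2e-4)

    def test_uniform_under_null(self):
        rng = np.random.default_rng(15)
        combined = [
            combine_pvalues(rng.uniform(), rng.uniform()) for _ in range(500)
        ]
        assert sps.kstest(combined, "uniform").pvalue > 0.01

    def test_zero_p_clipped_with_warning(self):
        with pytest.warns(UserWarning, match="clipped"):
            p = combine_pvalues(0.0, 0.5)
        assert 0 <= p < 1e-8
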