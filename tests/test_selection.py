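import numpy as np
import pytest
from scipy import stats

from momirf.forest import ForestParams
from momirf.imd import ImdProfile
from momirf.selection import (
    DEFAULT_TAU_GRID,
    ImdTScoreSelector,
    filter_support,
    select_filter,
    select_mixture,
    select_transformation,
)


def make_profile(imd_values, ntree=100, ids=None):
    imd_values = np.asarray(imd_values, float)
    n = len(imd_values)
    per_tree = np.tile(imd_values, (ntree, 1))
    rng = np.random.default_rng(0)
    per_tree = np.clip(per_tree + rng.normal(0, 0.01, size=per_tree.shape), 0, 1)
    per_tree[:, imd_values == 0] = 0.0
    fmean = per_tree.mean(axis=0)
    se = per_tree.std(axis=0, ddof=1) / np.sqrt(ntree)
    mu = fmean.mean()
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, (fmean - mu) / se, 0.0)
    return ImdProfile("predictor", ids or [f"v{i}" for i in range(n)],
                      per_tree, fmean, se, t, float(mu))


class TestFilterRule:
    def test_threshold_keeps_high_imd(self):
        prof = make_profile([0.3] * 5 + [0.0] * 45)
        mask = filter_support(prof, 1.0)
        assert mask[:5].all() and not mask[5:].any()

    def test_kept_set_shrinks_with_tau(self):
        rng = np.random.default_rng(2)
        prof = make_profile(rng.uniform(0, 0.4, 60))
        prev = None
        for tau in DEFAULT_TAU_GRID:
            mask = filter_support(prof, tau)
            if prev is not None:
                assert set(np.flatnonzero(mask)) <= set(np.flatnonzero(prev))
            prev = mask

    def test_tau_zero_keeps_all_positive(self):
        prof = make_profile([0.5, 0.2, 0.0, 0.1])
        mask = filter_support(prof, 0.0)
        assert mask.tolist() == [True, True, False, True]

    def test_full_procedure_recovers_constructed_signal(self, small_latent):
        # well-separated latent data: tuned filter keeps mostly true variables
        X = small_latent.datasets["omic1"].values
        Y = small_latent.datasets["omic2"].values
        res_x, res_y = select_filter(
            X, Y, ForestParams(ntree=40, seed=3),
            tau_grid=np.arange(0.2, 2.01, 0.2), k_repeats=2,
        )
        truth_y = small_latent.truth["omic2"]
        sel = res_y.selected_mask
        assert sel.sum() > 0
        # precision of the kept response set is high
        assert (sel & truth_y).sum() / sel.sum() > 0.6
        assert res_x.threshold == res_y.threshold
        assert "oob_curve" in res_x.diagnostics


class TestMixtureRule:
    def test_bimodal_profile_selects_upper_mode(self):
        rng = np.random.default_rng(4)
        low = np.clip(rng.normal(0.03, 0.01, 150), 0.001, 1)
        high = np.clip(rng.normal(0.5, 0.05, 30), 0, 1)
        prof = make_profile(np.concatenate([low, high, np.zeros(20)]))
        res = select_mixture(prof, pr=0.05)
        sel = res.selected_mask
        assert sel[150:180].all()
        assert not sel[:150].any() and not sel[180:].any()

    def test_pr_boundaries(self):
        rng = np.random.default_rng(5)
        vals = np.concatenate([np.clip(rng.normal(0.05, 0.01, 100), 0.001, 1),
                               np.clip(rng.normal(0.4, 0.05, 40), 0, 1), np.zeros(10)])
        prof = make_profile(vals)
        assert select_mixture(prof, pr=0.0).selected_mask.sum() == 0
        res = select_mixture(prof, pr=1.0)
        assert res.selected_mask.sum() == (vals > 0).sum()

    def test_zero_imd_never_selected(self):
        rng = np.random.default_rng(6)
        vals = np.concatenate([np.zeros(30), np.clip(rng.normal(0.2, 0.1, 100), 0.001, 1)])
        res = select_mixture(make_profile(vals), pr=1.0)
        assert not res.selected_mask[:30].any()


class TestTransformationRule:
    def test_threshold_value_matches_t_table(self):
        prof = make_profile(np.linspace(0, 0.5, 40))
        res = select_transformation(prof, alpha=0.05, ntree=100)
        assert res.threshold == pytest.approx(1.6604, abs=1e-3)

    def test_variable_at_mu_not_selected(self):
        # zero t-score (IMD exactly at the grand mean) never passes the cut
        vals = np.full(10, 0.2)
        prof = ImdProfile("predictor", list(range(10)), np.tile(vals, (100, 1)),
                          vals, np.zeros(10), np.zeros(10), 0.2)
        res = select_transformation(prof, alpha=0.05, ntree=100)
        assert res.selected_mask.sum() == 0

    def test_noise_only_calibration(self, rng):
        # null IMD profiles: selection fraction stays near alpha
        fracs = []
        for _ in range(10):
            per_tree = (rng.random((100, 200)) < 0.1) * rng.uniform(0.1, 0.3, (100, 200))
            fmean = per_tree.mean(axis=0)
            se = per_tree.std(axis=0, ddof=1) / 10
            mu = fmean.mean()
            t = np.where(se > 0, (fmean - mu) / se, 0.0)
            prof = ImdProfile("predictor", list(range(200)), per_tree, fmean, se, t, mu)
            res = select_transformation(prof, alpha=0.05, ntree=100)
            fracs.append(res.selected_mask.mean())
        assert np.mean(fracs) <= 0.10

    def test_lower_tail_variant_selects_more(self):
        rng = np.random.default_rng(8)
        prof = make_profile(rng.uniform(0, 0.3, 100))
        upper = select_transformation(prof, tail="upper").selected_mask.sum()
        lower = select_transformation(prof, tail="lower").selected_mask.sum()
        assert lower >= upper

    def test_df_requires_trees(self):
        prof = make_profile([0.1, 0.2], ntree=1)
        with pytest.raises(ValueError):
            select_transformation(prof, ntree=1)


class TestSelectorEstimators:
    def test_tscore_selector_fit_and_transform(self, small_latent, small_forest):
        X = small_latent.datasets["omic1"].values
        Y = small_latent.datasets["omic2"].values
        sel = ImdTScoreSelector(ntree=30, random_state=7).fit(X, Y, forest=small_forest)
        Xr = sel.transform(X)
        assert Xr.shape[1] == sel.get_support("predictor").sum()
        # sklearn param plumbing
        assert sel.get_params()["alpha"] == 0.05

    def test_selection_deterministic_given_forest(self, small_latent, small_forest):
        X = small_latent.datasets["omic1"].values
        Y = small_latent.datasets["omic2"].values
        a = ImdTScoreSelector().fit(X, Y, forest=small_forest).get_support("response")
        b = ImdTScoreSelector().fit(X, Y, forest=small_forest).get_support("response")
        np.testing.assert_array_equal(a, b)


def test_t_quantile_reference():
    # the transformation threshold for B=100 trees
    assert abs(stats.t.ppf(0.05, 99)) == pytest.approx(1.6604, abs=1e-3)
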