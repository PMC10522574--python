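"""Within-branch gradient analyses: screens, class correlations, letters,
isolation by distance, and position prediction."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from holopolyp import (
    class_gradient_correlations,
    feature_position_screen,
    isolation_by_distance,
    position_pair_dissimilarity,
    position_prediction_r2,
)
from holopolyp.gradient import compact_letter_display, ols_fit
from .conftest import make_table, polyp_meta


def _gradient_table(n_polyps=12, noise=0.0, seed=0):
    """One colony/branch, two features: one linear in position, one flat."""
    meta = polyp_meta(1, 1, n_polyps)
    pos = meta["position_mm"].to_numpy()
    rng = np.random.default_rng(seed)
    f1 = 0.002 * pos + 0.05 + noise * rng.normal(size=n_polyps)
    f2 = np.full(n_polyps, 0.3)
    return make_table(np.column_stack([np.abs(f1), f2]), meta)


class TestOls:
    def test_matches_scipy_linregress(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 100, 10)
        y = 0.3 * x + rng.normal(size=10)
        fit = ols_fit(x, y)
        ref = stats.linregress(x, y)
        assert fit["slope"] == pytest.approx(ref.slope, abs=1e-10)
        assert fit["intercept"] == pytest.approx(ref.intercept, abs=1e-10)
        assert fit["r_squared"] == pytest.approx(ref.rvalue**2, abs=1e-10)
        assert fit["p"] == pytest.approx(ref.pvalue, abs=1e-10)

    def test_vectorized_agrees_with_columnwise(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 10, 8)
        y = rng.normal(size=(8, 5))
        fit = ols_fit(x, y)
        for k in range(5):
            single = ols_fit(x, y[:, k])
            assert fit["slope"][k] == pytest.approx(single["slope"], abs=1e-12)
            assert fit["p"][k] == pytest.approx(single["p"], abs=1e-12)

    def test_adjusted_below_raw(self):
        rng = np.random.default_rng(3)
        fit = ols_fit(rng.uniform(size=9), rng.normal(size=9))
        assert fit["adj_r_squared"] <= fit["r_squared"]

    def test_constant_predictor_errors(self):
        with pytest.raises(ValueError):
            ols_fit(np.ones(5), np.arange(5.0))


class TestFeatureScreen:
    def test_exact_linear_feature_selected(self):
        res = feature_position_screen(_gradient_table())
        assert res.loc["F001", "r_squared"] == pytest.approx(1.0, abs=1e-9)
        assert bool(res.loc["F001", "selected"])
        assert res.loc["F002", "r_squared"] == 0.0
        assert not bool(res.loc["F002", "selected"])

    def test_selection_monotone_in_thresholds(self, small_norm):
        strict = feature_position_screen(small_norm, p_threshold=0.01, r2_threshold=0.2)
        loose = feature_position_screen(small_norm, p_threshold=0.05, r2_threshold=0.1)
        assert set(strict.index[strict.selected]) <= set(loose.index[loose.selected])

    def test_injected_gradients_recovered(self, small_norm):
        grad = small_norm.features["true_gradient_slope"] != 0
        res = feature_position_screen(small_norm)
        assert (res.selected & grad).sum() >= 6
        null_fp = (res.selected & ~grad).sum() / (~grad).sum()
        assert null_fp <= 0.05

    def test_few_positions_errors(self):
        meta = polyp_meta(1, 1, 2)
        t = make_table(np.ones((2, 2)), meta)
        with pytest.raises(ValueError):
            feature_position_screen(t)


class TestClassCorrelations:
    def test_perfect_class_gradient(self):
        t = _gradient_table()
        t.features["subclass_label"] = ["Sesquiterpenoids", "Carbamate esters"]
        res = class_gradient_correlations(t, level="SubClass")
        row = res.set_index("class_label").loc["Sesquiterpenoids"]
        assert row["pearson_r"] == pytest.approx(1.0, abs=1e-9)

    def test_bonferroni_arithmetic_and_monotonicity(self):
        # raw p = 0.01 with m = 20 classes -> adjusted 0.2, not significant
        assert min(1.0, 20 * 0.01) == pytest.approx(0.2)
        t = _gradient_table(noise=0.02, seed=5)
        t.features["subclass_label"] = ["Triterpenoids", "Hydroxysteroids"]
        res = class_gradient_correlations(t)
        assert (res["p_bonferroni"] >= res["p_raw"] - 1e-15).all()
        assert (res["p_bonferroni"] <= 1.0).all()

    def test_family_wise_error_controlled_under_null(self):
        """With all classes null, any family-wise rejection is rare."""
        rng = np.random.default_rng(10)
        fwe = 0
        n_runs = 200
        meta = polyp_meta(1, 2, 6)
        for _ in range(n_runs):
            x = np.abs(rng.normal(size=(12, 10)) + 3)
            t = make_table(x, meta)
            t.features["subclass_label"] = [f"cls{i % 5}" for i in range(10)]
            res = class_gradient_correlations(t)
            fwe += bool(res["significant"].any())
        assert fwe / n_runs <= 0.08

    def test_unknown_level_errors(self, small_norm):
        with pytest.raises(ValueError):
            class_gradient_correlations(small_norm, level="Kingdom")


class TestPositionPairs:
    def test_identical_samples_share_one_letter(self):
        meta = polyp_meta(1, 3, 4)
        t = make_table(np.tile([0.2, 0.3, 0.5], (12, 1)), meta)
        long, pmat, letters = position_pair_dissimilarity(t)
        assert (long["dissimilarity"] == 0).all()
        assert letters.nunique() == 1

    def test_gradient_increases_with_separation(self, small_norm):
        long, _, _ = position_pair_dissimilarity(small_norm)
        sep = long["pair"].str.split("-", expand=True).astype(int)
        long = long.assign(gap=(sep[1] - sep[0]).to_numpy())
        med = long.groupby("gap")["dissimilarity"].median()
        assert med.loc[5] > med.loc[1]

    def test_pair_count_combinatorics(self, small_norm):
        long, _, _ = position_pair_dissimilarity(small_norm)
        n_branches = small_norm.subset_role("polyp").samples["branch_id"].nunique()
        assert len(long) == n_branches * 15  # C(6,2) per branch


class TestLetterDisplay:
    def test_all_different(self):
        p = pd.DataFrame(np.zeros((3, 3)), index=list("abc"), columns=list("abc"))
        np.fill_diagonal(p.values, 1.0)
        letters = compact_letter_display(p)
        assert letters.nunique() == 3

    def test_chain_structure(self):
        """a~b and b~c non-significant but a vs c significant: b shares with both."""
        names = list("abc")
        p = pd.DataFrame(np.ones((3, 3)), index=names, columns=names)
        p.loc["a", "c"] = p.loc["c", "a"] = 0.001
        letters = compact_letter_display(p)
        assert set(letters["b"]) & set(letters["a"])
        assert set(letters["b"]) & set(letters["c"])
        assert not set(letters["a"]) & set(letters["c"])

    def test_same_distribution_shares_letter(self):
        rng = np.random.default_rng(6)
        shared = 0
        n_runs = 100
        for _ in range(n_runs):
            x, y = rng.normal(size=12), rng.normal(size=12)
            _, p = stats.kruskal(x, y)
            pm = pd.DataFrame([[1.0, p], [p, 1.0]], index=["g1", "g2"], columns=["g1", "g2"])
            letters = compact_letter_display(pm)
            shared += bool(set(letters["g1"]) & set(letters["g2"]))
        assert shared / n_runs >= 0.9


class TestIsolationByDistance:
    def test_proportional_dissimilarity_gives_high_r2(self):
        t = _gradient_table(n_polyps=6)
        per_branch, mean_adj = isolation_by_distance(t)
        assert per_branch["n_pairs"].iloc[0] == 15
        assert mean_adj > 0.8  # single monotone gradient drives dissimilarity

    def test_pure_noise_near_zero(self):
        rng = np.random.default_rng(14)
        vals = []
        for _ in range(30):
            meta = polyp_meta(2, 3, 6)
            x = np.abs(rng.normal(size=(36, 20)) + 5)
            _, mean_adj = isolation_by_distance(make_table(x, meta))
            vals.append(mean_adj)
        assert abs(np.mean(vals)) < 0.05

    def test_short_branch_skipped(self):
        meta = polyp_meta(1, 2, 6)
        keep = [s for s in meta.index if not s.startswith("C1B2") or s.endswith("P1") or s.endswith("P2")]
        meta = meta.loc[keep]
        t = make_table(np.abs(np.random.default_rng(0).normal(size=(len(keep), 4)) + 2), meta)
        with pytest.warns(UserWarning):
            per_branch, _ = isolation_by_distance(t)
        assert list(per_branch["branch_id"]) == ["C1B1"]


class TestPositionPrediction:
    def test_strong_gradient_predictable(self):
        """Many features tracking position, low noise: high out-of-sample R2."""
        rng = np.random.default_rng(20)
        meta = polyp_meta(4, 3, 6)
        pos = meta["position_mm"].to_numpy()
        x = np.abs(
            0.01 * pos[:, None] * rng.uniform(0.5, 1.5, 30)[None, :]
            + 0.02 * rng.normal(size=(72, 30))
            + 1.0
        )
        t = make_table(x, meta)
        r2 = position_prediction_r2(t, seed=0)
        assert r2 >= 0.8

    def test_shuffled_positions_unpredictable(self):
        rng = np.random.default_rng(21)
        meta = polyp_meta(4, 3, 6)
        meta["position_mm"] = rng.permutation(meta["position_mm"].to_numpy())
        x = np.abs(rng.normal(size=(72, 20)) + 3)
        t = make_table(x, meta)
        assert position_prediction_r2(t, seed=0) <= 0.1

    def test_deterministic_given_seed(self, small_norm):
        a = position_prediction_r2(small_norm, seed=3, folds=3, max_iter=150)
        b = position_prediction_r2(small_norm, seed=3, folds=3, max_iter=150)
        assert a == b

    def test_too_few_samples_errors(self):
        t = _gradient_table(n_polyps=6)
        with pytest.raises(ValueError):
            position_prediction_r2(t, folds=5)
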