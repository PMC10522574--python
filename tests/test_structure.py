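"""Bray-Curtis, ordination, PERMANOVA and discriminant classification."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from holopolyp import bray_curtis, discriminant, pca, permanova, permanova_two_factor
from holopolyp.structure import DistanceMatrix
from .conftest import make_table, polyp_meta


def _dm(values, labels=None):
    values = np.asarray(values, float)
    labels = labels or [f"S{i}" for i in range(len(values))]
    return DistanceMatrix(labels, values)


def brute_force_pseudo_f(d, labels):
    """Independent oracle: direct sums over the distance partition."""
    labels = np.asarray(labels)
    n = len(labels)
    groups = np.unique(labels)
    a = len(groups)
    ss_total = sum(d[i, j] ** 2 for i, j in combinations(range(n), 2)) / n
    ss_within = 0.0
    for g in groups:
        idx = np.flatnonzero(labels == g)
        ss_within += sum(d[i, j] ** 2 for i, j in combinations(idx, 2)) / len(idx)
    ss_between = ss_total - ss_within
    return (ss_between / (a - 1)) / (ss_within / (n - a))


class TestBrayCurtis:
    def test_identical_and_disjoint(self):
        meta = polyp_meta(1, 1, 3)
        t = make_table(np.array([[1.0, 0.0], [1.0, 0.0], [0.0, 1.0]]), meta)
        d = bray_curtis(t).to_frame()
        assert d.iloc[0, 1] == 0.0
        assert d.iloc[0, 2] == 1.0

    def test_hand_arithmetic(self):
        meta = polyp_meta(1, 1, 2)
        t = make_table(np.array([[1.0, 3.0], [2.0, 2.0]]), meta)
        d = bray_curtis(t).to_frame()
        assert d.iloc[0, 1] == pytest.approx(0.25, abs=1e-12)  # (1+1)/(4+4)

    def test_symmetry_and_range(self, small_norm):
        d = bray_curtis(small_norm)
        v = d.values
        assert np.allclose(v, v.T)
        assert v.min() >= 0 and v.max() <= 1
        assert np.allclose(np.diag(v), 0)

    def test_zero_sample_errors(self):
        meta = polyp_meta(1, 1, 2)
        t = make_table(np.array([[1.0, 1.0], [0.0, 0.0]]), meta)
        with pytest.raises(ValueError):
            bray_curtis(t)


class TestPca:
    def test_rank_one_explains_everything(self):
        meta = polyp_meta(1, 1, 3)
        base = np.array([1.0, 2.0, 3.0])
        t = make_table(np.outer([1.0, 2.0, 3.0], base), meta)
        with pytest.warns(UserWarning):
            scores, evr = pca(t, n_axes=3)
        assert evr[0] == pytest.approx(1.0, abs=1e-9)

    def test_explained_fractions_non_increasing(self, small_norm):
        _, evr = pca(small_norm, n_axes=5)
        assert np.all(np.diff(evr) <= 1e-12)
        assert evr.sum() <= 1 + 1e-9

    def test_scores_match_eigendecomposition(self):
        """Toy 3x2 matrix against a covariance eigen-decomposition oracle."""
        meta = polyp_meta(1, 1, 3)
        x = np.array([[1.0, 2.0], [3.0, 3.0], [4.0, 7.0]])
        t = make_table(x, meta)
        scores, evr = pca(t, n_axes=2)
        xc = x - x.mean(axis=0)
        w, v = np.linalg.eigh(xc.T @ xc)
        order = np.argsort(w)[::-1]
        w, v = w[order], v[:, order]
        expected = xc @ v
        # axes defined up to sign
        for k in range(2):
            col = scores.iloc[:, k].to_numpy()
            assert np.allclose(col, expected[:, k], atol=1e-9) or np.allclose(
                col, -expected[:, k], atol=1e-9
            )
        assert np.allclose(evr, w / w.sum(), atol=1e-9)


class TestPermanova:
    def test_pseudo_f_matches_brute_force(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(size=(6, 4))
        from scipy.spatial.distance import pdist, squareform

        d = squareform(pdist(x, "braycurtis"))
        labels = ["a", "a", "a", "b", "b", "b"]
        res = permanova(_dm(d), labels, n_permutations=9, seed=0)
        assert res.pseudo_f == pytest.approx(brute_force_pseudo_f(d, labels), abs=1e-10)

    def test_agrees_with_skbio(self):
        """Independent cross-check against scikit-bio's implementation."""
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import permanova as sk_permanova

        rng = np.random.default_rng(11)
        x = np.abs(rng.normal(size=(12, 8)))
        from scipy.spatial.distance import pdist, squareform

        d = squareform(pdist(x, "braycurtis"))
        labels = ["a"] * 4 + ["b"] * 4 + ["c"] * 4
        mine = permanova(_dm(d), labels, n_permutations=99, seed=1)
        theirs = sk_permanova(
            skbio.DistanceMatrix(d, [f"S{i}" for i in range(12)]), np.array(labels),
            permutations=99,
        )
        assert mine.pseudo_f == pytest.approx(theirs["test statistic"], abs=1e-10)

    def test_separated_clusters_minimum_p(self):
        # groups of 6 so a random permutation essentially never reproduces
        # the observed split (tie probability 2 / C(12,6) ~ 0.2%)
        x = np.vstack([np.zeros((6, 3)) + [1, 0, 0], np.zeros((6, 3)) + [0, 1, 0]])
        x += 0.01 * np.random.default_rng(0).uniform(size=x.shape)
        from scipy.spatial.distance import pdist, squareform

        d = squareform(pdist(x, "braycurtis"))
        res = permanova(_dm(d), ["a"] * 6 + ["b"] * 6, n_permutations=99, seed=0)
        assert res.p == pytest.approx(0.01)  # (1+0)/(1+99)

    def test_reproducible_given_seed(self, small_norm):
        d = bray_curtis(small_norm)
        colony = small_norm.subset_role("polyp").samples["colony_id"]
        r1 = permanova(d, colony, n_permutations=49, seed=5)
        r2 = permanova(d, colony, n_permutations=49, seed=5)
        assert (r1.pseudo_f, r1.p) == (r2.pseudo_f, r2.p)

    def test_p_floor(self):
        assert permanova.__doc__  # documented floor
        # p >= 1/(n_permutations+1) by construction of the +1 estimator

    def test_singleton_group_errors(self):
        d = np.zeros((3, 3))
        with pytest.raises(ValueError):
            permanova(_dm(d), ["a", "a", "b"], n_permutations=9)


class TestPermanovaTwoFactor:
    def test_identical_factors_error(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(size=(8, 3))
        from scipy.spatial.distance import pdist, squareform

        d = squareform(pdist(x, "braycurtis"))
        f = ["a"] * 4 + ["b"] * 4
        with pytest.raises(ValueError):
            permanova_two_factor(_dm(d), f, f, n_permutations=9)

    def test_signal_in_second_factor_detected(self):
        rng = np.random.default_rng(2)
        n = 24
        fb = np.repeat(["x", "y", "z"], 8)
        fa = list(np.tile(np.repeat(["p", "q"], 4), 3))
        x = rng.normal(size=(n, 6)) * 0.05 + 1.0
        x[fb == "y"] += [1, 0, 0, 0, 0, 0]
        x[fb == "z"] += [0, 1, 0, 0, 0, 0]
        from scipy.spatial.distance import pdist, squareform

        d = squareform(pdist(np.abs(x), "braycurtis"))
        res = permanova_two_factor(_dm(d), fa, list(fb), n_permutations=99, seed=0)
        assert res["factor_b"].p < 0.05
        assert res["factor_b"].p < res["factor_a"].p


class TestDiscriminant:
    def test_separated_clusters_perfect(self):
        rng = np.random.default_rng(4)
        meta = polyp_meta(2, 1, 6)
        x = rng.normal(size=(12, 10)) * 0.05
        x[:6] += 5.0
        t = make_table(np.abs(x), meta)
        res = discriminant(t, meta["colony_id"])
        assert res.misclassification_rate == 0.0
        assert res.canonical_scores.shape[1] <= 1  # k - 1 axes

    def test_shuffled_labels_near_chance(self):
        rng = np.random.default_rng(8)
        meta = polyp_meta(2, 2, 10)
        x = np.abs(rng.normal(size=(40, 12)) + 2)
        t = make_table(x, meta)
        labels = rng.permutation(np.repeat(["a", "b"], 20))
        res = discriminant(t, labels, mode="crossval", seed=0)
        assert res.misclassification_rate > 0.2  # ~ 1 - 1/k under the null

    def test_resubstitution_not_worse_than_crossval(self, small_norm):
        colony = small_norm.subset_role("polyp").samples["colony_id"]
        res_in = discriminant(small_norm, colony, mode="resubstitution")
        res_cv = discriminant(small_norm, colony, mode="crossval", seed=0)
        assert res_in.misclassification_rate <= res_cv.misclassification_rate + 1e-9

    def test_strong_colony_effects_classified_perfectly(self, small_norm):
        """Colony signatures dominate the simulated metabolome, so
        resubstitution classification by colony is perfect."""
        colony = small_norm.subset_role("polyp").samples["colony_id"]
        res = discriminant(small_norm, colony, mode="resubstitution")
        assert res.misclassification_rate == 0.0
        assert int(np.trace(res.confusion.to_numpy())) == len(colony)

    def test_single_sample_class_errors(self):
        meta = polyp_meta(1, 1, 3)
        t = make_table(np.ones((3, 4)) + np.eye(3, 4), meta)
        with pytest.raises(ValueError):
            discriminant(t, ["a", "a", "b"])
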