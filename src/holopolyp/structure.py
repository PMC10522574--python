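"""Distance-based and supervised community structure.

Bray-Curtis dissimilarities on relative abundances, PCA/PCoA ordination,
permutational multivariate ANOVA (PERMANOVA) with one factor or a
sequential two-factor partition, and high-dimensional linear discriminant
classification with misclassification rates.

The PERMANOVA pseudo-F follows the classic distance partition: with N
samples in a groups,

    SS_total = sum_{i<j} d_ij^2 / N
    SS_within = sum_g sum_{i<j in g} d_ij^2 / n_g
    F = (SS_between / (a-1)) / (SS_within / (N-a))

and the p value comes from label permutations, p = (1 + #{F* >= F}) /
(1 + n_permutations), reproducible given a seed.  The two-factor variant
partitions the Gower-centered inner-product matrix with sequential
(Type-I) hat-matrix traces so a second factor is assessed after the first.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.decomposition import PCA as _SKPCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .tables import FeatureTable

__all__ = [
    "DistanceMatrix",
    "PermanovaResult",
    "DiscriminantResult",
    "bray_curtis",
    "pca",
    "permanova",
    "permanova_two_factor",
    "discriminant",
]


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with sample labels."""

    labels: list
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0):
            raise ValueError("distance matrix diagonal must be zero")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def subset(self, labels) -> "DistanceMatrix":
        ix = [self.labels.index(l) for l in labels]
        return DistanceMatrix(list(labels), self.values[np.ix_(ix, ix)])


def bray_curtis(table: FeatureTable | pd.DataFrame, roles: tuple = ("polyp",)) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity, d(u,v) = sum|u-v| / sum(u+v).

    Computed on the (relative) abundance rows of the requested roles.  A
    sample with zero total makes the dissimilarity undefined and is an
    error.
    """
    if isinstance(table, FeatureTable):
        keep = table.samples["role"].isin(roles)
        ab = table.abundance.loc[keep.index[keep]]
    else:
        ab = table
    x = ab.to_numpy(float)
    if (x.sum(axis=1) == 0).any():
        bad = ab.index[x.sum(axis=1) == 0]
        raise ValueError(f"all-zero sample(s) make Bray-Curtis undefined: {list(bad)[:5]}")
    d = squareform(pdist(x, metric="braycurtis"))
    return DistanceMatrix(list(ab.index), d)


def pca(table: FeatureTable | pd.DataFrame, n_axes: int = 2, roles: tuple = ("polyp",)):
    """Centered PCA scores and explained-variance fractions.

    Returns ``(scores, explained)`` where scores is a samples x axes
    DataFrame.  ``n_axes`` beyond the matrix rank is truncated with a
    warning.
    """
    if isinstance(table, FeatureTable):
        keep = table.samples["role"].isin(roles)
        ab = table.abundance.loc[keep.index[keep]]
    else:
        ab = table
    if ab.shape[0] < 2:
        raise ValueError("PCA needs at least two samples")
    x = ab.to_numpy(float)
    rank = min(x.shape[0] - 1, x.shape[1])
    if n_axes > rank:
        warnings.warn(f"n_axes={n_axes} exceeds rank {rank}; truncating")
        n_axes = rank
    model = _SKPCA(n_components=n_axes)
    scores = model.fit_transform(x - x.mean(axis=0))
    cols = [f"PC{i + 1}" for i in range(n_axes)]
    return pd.DataFrame(scores, index=ab.index, columns=cols), model.explained_variance_ratio_


@dataclass
class PermanovaResult:
    """PERMANOVA term: pseudo-F, permutation p, and bookkeeping."""

    factor: str
    pseudo_f: float
    p: float
    n_permutations: int
    seed: int | None
    df_between: int
    df_within: int
    ss_between: float
    ss_within: float

    def as_dict(self) -> dict:
        return {
            "factor": self.factor,
            "pseudo_F": self.pseudo_f,
            "p": self.p,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
            "df_between": self.df_between,
            "df_within": self.df_within,
        }


def _check_groups(codes: np.ndarray) -> int:
    counts = np.bincount(codes)
    if len(counts) < 2:
        raise ValueError("PERMANOVA needs at least two groups")
    if (counts < 2).any():
        raise ValueError("PERMANOVA groups must each contain at least two samples")
    return len(counts)


def _pseudo_f(d2: np.ndarray, codes: np.ndarray, a: int) -> tuple[float, float, float]:
    n = len(codes)
    ss_total = d2.sum() / (2 * n)
    ss_within = 0.0
    for g in range(a):
        mask = codes == g
        ng = mask.sum()
        ss_within += d2[np.ix_(mask, mask)].sum() / (2 * ng)
    ss_between = ss_total - ss_within
    f = (ss_between / (a - 1)) / (ss_within / (n - a))
    return f, ss_between, ss_within


def permanova(
    dist: DistanceMatrix, labels, n_permutations: int = 999, seed: int | None = 0
) -> PermanovaResult:
    """One-factor PERMANOVA on a distance matrix.

    ``labels`` is a sequence or mapping (sample -> group) aligned with
    ``dist.labels``.  The p value is the proportion of label permutations
    whose pseudo-F meets or exceeds the observed one, with the +1
    small-sample correction, so p >= 1/(n_permutations + 1).
    """
    lab = _align_labels(dist, labels)
    codes = pd.Categorical(lab).codes.astype(int)
    a = _check_groups(codes)
    d2 = dist.values**2
    f_obs, ssb, ssw = _pseudo_f(d2, codes, a)
    rng = np.random.default_rng(seed)
    n = len(codes)
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        f_perm, _, _ = _pseudo_f(d2, codes[perm], a)
        if f_perm >= f_obs:
            exceed += 1
    p = (1 + exceed) / (1 + n_permutations)
    return PermanovaResult(
        factor="group",
        pseudo_f=float(f_obs),
        p=float(p),
        n_permutations=n_permutations,
        seed=seed,
        df_between=a - 1,
        df_within=n - a,
        ss_between=float(ssb),
        ss_within=float(ssw),
    )


def _align_labels(dist: DistanceMatrix, labels) -> np.ndarray:
    if isinstance(labels, pd.Series):
        return labels.loc[dist.labels].to_numpy()
    if isinstance(labels, dict):
        return np.array([labels[l] for l in dist.labels])
    labels = np.asarray(labels)
    if len(labels) != len(dist.labels):
        raise ValueError("labels length does not match the distance matrix")
    return labels


def _hat(x: np.ndarray) -> np.ndarray:
    q, _ = np.linalg.qr(x)
    # guard rank deficiency: keep columns with nonzero diagonal in R
    return q @ q.T


def _dummies(codes: np.ndarray) -> np.ndarray:
    return np.eye(codes.max() + 1)[codes]


def permanova_two_factor(
    dist: DistanceMatrix,
    factor_a,
    factor_b,
    n_permutations: int = 999,
    seed: int | None = 0,
) -> dict[str, PermanovaResult]:
    """Sequential (Type-I) two-factor PERMANOVA: factor_a, then factor_b.

    Sums of squares come from hat-matrix traces on the Gower-centered
    matrix; each term's pseudo-F uses the residual mean square after both
    factors, and p values come from whole-sample permutations.  Identical
    partitions for the two factors are rejected.
    """
    la = _align_labels(dist, factor_a)
    lb = _align_labels(dist, factor_b)
    ca = pd.Categorical(la).codes.astype(int)
    cb = pd.Categorical(lb).codes.astype(int)
    if _same_partition(ca, cb):
        raise ValueError("factor_a and factor_b induce identical partitions (confounded)")
    n = len(ca)
    d2 = dist.values**2
    j = np.eye(n) - np.ones((n, n)) / n
    g = -0.5 * j @ d2 @ j

    ones = np.ones((n, 1))
    xa = np.hstack([ones, _dummies(ca)])
    xab = np.hstack([ones, _dummies(ca), _dummies(cb)])
    ha, hab = _hat(xa), _hat(xab)
    df_a = np.linalg.matrix_rank(xa) - 1
    df_b = np.linalg.matrix_rank(xab) - np.linalg.matrix_rank(xa)
    if df_b == 0:
        raise ValueError("factor_b adds no information beyond factor_a")
    df_res = n - np.linalg.matrix_rank(xab)

    def terms(gmat: np.ndarray) -> tuple[float, float]:
        # gmat is double-centered, so the intercept contributes nothing to tr(H G)
        tr_tot = np.trace(gmat)
        ss_a = float(np.sum(ha * gmat))
        ss_ab = float(np.sum(hab * gmat))
        ss_res = tr_tot - ss_ab
        fa = (ss_a / df_a) / (ss_res / df_res)
        fb = ((ss_ab - ss_a) / df_b) / (ss_res / df_res)
        return fa, fb

    f_a, f_b = terms(g)
    rng = np.random.default_rng(seed)
    exc_a = exc_b = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        gp = g[np.ix_(perm, perm)]
        fa_p, fb_p = terms(gp)
        if fa_p >= f_a:
            exc_a += 1
        if fb_p >= f_b:
            exc_b += 1

    def result(name: str, f: float, exc: int, dfb: int) -> PermanovaResult:
        return PermanovaResult(
            factor=name,
            pseudo_f=float(f),
            p=float((1 + exc) / (1 + n_permutations)),
            n_permutations=n_permutations,
            seed=seed,
            df_between=dfb,
            df_within=df_res,
            ss_between=np.nan,
            ss_within=np.nan,
        )

    return {"factor_a": result("factor_a", f_a, exc_a, df_a), "factor_b": result("factor_b", f_b, exc_b, df_b)}


def _same_partition(ca: np.ndarray, cb: np.ndarray) -> bool:
    pairs = set(zip(ca.tolist(), cb.tolist()))
    return len({a for a, _ in pairs}) == len(pairs) == len({b for _, b in pairs})


@dataclass
class DiscriminantResult:
    """Linear discriminant fit on PCA-reduced scores."""

    canonical_scores: pd.DataFrame
    misclassification_rate: float
    confusion: pd.DataFrame
    mode: str
    n_components: int


def discriminant(
    table: FeatureTable | pd.DataFrame,
    labels,
    mode: str = "resubstitution",
    var_retained: float = 0.95,
    cv_folds: int = 5,
    seed: int | None = 0,
) -> DiscriminantResult:
    """Linear discriminant classification of samples by a design factor.

    Feature tables are wide (features >> samples), which makes a plain LDA
    singular, so samples are first projected onto the principal components
    retaining ``var_retained`` of the variance and the discriminant is fit
    on those scores.  ``mode="resubstitution"`` reports the training-set
    misclassification rate; ``"crossval"`` refits PCA+LDA per stratified
    fold and reports the held-out rate.  Canonical scores (up to
    n_classes - 1 axes) always come from the full-data fit.
    """
    if isinstance(table, FeatureTable):
        keep = table.samples["role"] == "polyp"
        ab = table.abundance.loc[keep.index[keep]]
    else:
        ab = table
    y = _align_series(labels, ab.index)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("discriminant analysis needs at least two classes")
    if (counts < 2).any():
        raise ValueError("every class needs at least two samples")

    x = ab.to_numpy(float)
    reducer = _SKPCA(n_components=min(x.shape[0] - 1, x.shape[1]))
    scores_full = reducer.fit_transform(x)
    ncomp = int(np.searchsorted(np.cumsum(reducer.explained_variance_ratio_), var_retained) + 1)
    ncomp = min(ncomp, scores_full.shape[1])
    z = scores_full[:, :ncomp]

    lda = LinearDiscriminantAnalysis()
    lda.fit(z, y)
    canon = lda.transform(z)
    canon_df = pd.DataFrame(
        canon, index=ab.index, columns=[f"Can{i + 1}" for i in range(canon.shape[1])]
    )

    if mode == "resubstitution":
        pred = lda.predict(z)
    elif mode == "crossval":
        from sklearn.model_selection import StratifiedKFold

        folds = min(cv_folds, counts.min())
        if folds < 2:
            raise ValueError("cross-validation needs at least two samples per class")
        pred = np.empty(len(y), dtype=object)
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        for train, test in skf.split(x, y):
            red = _SKPCA(n_components=min(len(train) - 1, x.shape[1]))
            zt = red.fit_transform(x[train])
            nc = int(np.searchsorted(np.cumsum(red.explained_variance_ratio_), var_retained) + 1)
            nc = min(nc, zt.shape[1])
            clf = LinearDiscriminantAnalysis().fit(zt[:, :nc], y[train])
            pred[test] = clf.predict(red.transform(x[test])[:, :nc])
    else:
        raise ValueError(f"unknown mode {mode!r}")

    rate = float(np.mean(pred != y))
    confusion = pd.crosstab(
        pd.Series(y, index=ab.index, name="true"), pd.Series(pred, index=ab.index, name="predicted")
    )
    return DiscriminantResult(
        canonical_scores=canon_df,
        misclassification_rate=rate,
        confusion=confusion,
        mode=mode,
        n_components=ncomp,
    )


def _align_series(labels, index) -> np.ndarray:
    if isinstance(labels, pd.Series):
        return labels.loc[index].to_numpy()
    if isinstance(labels, dict):
        return np.array([labels[i] for i in index])
    labels = np.asarray(labels)
    if len(labels) != len(index):
        raise ValueError("labels length does not match the table")
    return labels
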