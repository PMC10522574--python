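"""Within-branch spatial analyses of the polyp metabolome.

Everything here asks how composition changes with a polyp's distance from
the branch base (mm): per-feature ordinary-least-squares screens with
R-squared and p thresholds, class-level Pearson correlations with
Bonferroni control, Bray-Curtis dissimilarity grouped by polyp-position
pair with a compact letter display, isolation-by-distance regressions per
branch, and a cross-validated nonlinear position predictor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .structure import bray_curtis
from .tables import FeatureTable

__all__ = [
    "ols_fit",
    "feature_position_screen",
    "class_gradient_correlations",
    "position_pair_dissimilarity",
    "isolation_by_distance",
    "position_prediction_r2",
    "compact_letter_display",
]


def ols_fit(x: np.ndarray, y: np.ndarray) -> dict:
    """Simple-linear-regression summary of y on x (two-sided slope test).

    Vectorized over columns when ``y`` is 2-D (n x m): returns arrays of
    slope, intercept, r_squared, adj_r_squared and p per column.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    if n < 3:
        raise ValueError("regression needs at least three observations")
    xc = x - x.mean()
    sxx = float(xc @ xc)
    if sxx == 0:
        raise ValueError("constant predictor: positions do not vary")
    y2d = y[:, None] if y.ndim == 1 else y
    yc = y2d - y2d.mean(axis=0)
    sxy = xc @ yc
    slope = sxy / sxx
    intercept = y2d.mean(axis=0) - slope * x.mean()
    ss_tot = (yc**2).sum(axis=0)
    ss_res = ss_tot - slope * sxy
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(ss_tot > 0, 1 - ss_res / ss_tot, 0.0)
        adj = 1 - (1 - r2) * (n - 1) / (n - 2)
        se = np.sqrt(np.maximum(ss_res, 0) / (n - 2) / sxx)
        t = np.where(se > 0, slope / se, 0.0)
    p = 2 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where((ss_res <= 1e-300) & (slope != 0), 0.0, p)
    out = {
        "slope": slope,
        "intercept": intercept,
        "r_squared": r2,
        "adj_r_squared": adj,
        "p": p,
        "n": n,
    }
    if y.ndim == 1:
        out = {k: (float(v[0]) if isinstance(v, np.ndarray) else v) for k, v in out.items()}
    return out


def _polyp_positions(table: FeatureTable) -> tuple[pd.DataFrame, np.ndarray]:
    polyp = table.subset_role("polyp")
    pos = polyp.samples["position_mm"].to_numpy(float)
    if np.isnan(pos).any():
        raise ValueError("polyp samples missing position_mm")
    return polyp.abundance, pos


def feature_position_screen(
    table: FeatureTable, p_threshold: float = 0.05, r2_threshold: float = 0.10
) -> pd.DataFrame:
    """Regress every feature's relative abundance on distance from base.

    Polyps are pooled across branches and colonies.  A feature is
    ``selected`` when its two-sided slope p value is below ``p_threshold``
    and its R-squared exceeds ``r2_threshold`` — the screen used to flag
    biochemicals tracking position along the branch.
    """
    ab, pos = _polyp_positions(table)
    if len(np.unique(pos)) < 3:
        raise ValueError("need at least three distinct positions")
    fit = ols_fit(pos, ab.to_numpy(float))
    res = pd.DataFrame(
        {
            "slope": fit["slope"],
            "intercept": fit["intercept"],
            "r_squared": fit["r_squared"],
            "adj_r_squared": fit["adj_r_squared"],
            "p": fit["p"],
            "n": fit["n"],
        },
        index=ab.columns,
    )
    res["selected"] = (res["p"] < p_threshold) & (res["r_squared"] > r2_threshold)
    return res


def class_gradient_correlations(
    table: FeatureTable, level: str = "SubClass", alpha: float = 0.05
) -> pd.DataFrame:
    """Pearson correlation of class-summed relative abundance with position.

    Member features of each chemical class (``level`` = "Class" or
    "SubClass") are summed per sample; the class sum is correlated with
    distance from base and p values are Bonferroni-adjusted over the number
    of classes tested.  Classes whose members never appear are skipped with
    a warning.
    """
    col = {"Class": "class_label", "SubClass": "subclass_label"}.get(level)
    if col is None:
        raise ValueError(f"unknown annotation level {level!r}")
    if col not in table.features.columns:
        raise ValueError(f"feature annotations lack a {col!r} column")
    ab, pos = _polyp_positions(table)
    rows = []
    grouped = table.features.groupby(col, dropna=True)
    sums = {name: ab[g.index.intersection(ab.columns)].sum(axis=1) for name, g in grouped}
    sums = {k: v for k, v in sums.items() if len(v)}
    for name, s in sums.items():
        if (s == 0).all():
            warnings.warn(f"class {name!r} has all-zero summed abundance; skipped")
            continue
        if np.ptp(s.to_numpy(float)) == 0:  # constant sum: no association
            r, p = 0.0, 1.0
        else:
            r, p = stats.pearsonr(pos, s.to_numpy(float))
        rows.append({"class_label": name, "pearson_r": float(r), "p_raw": float(p), "n": len(s)})
    out = pd.DataFrame(rows)
    if len(out):
        m = len(out)
        out["p_bonferroni"] = np.minimum(1.0, m * out["p_raw"])
        out["significant"] = out["p_bonferroni"] < alpha
        out = out.sort_values("pearson_r", ascending=False).reset_index(drop=True)
    return out


def position_pair_dissimilarity(table: FeatureTable, alpha: float = 0.05):
    """Bray-Curtis dissimilarity between same-branch polyps, grouped by the
    unordered polyp-number pair.

    Returns ``(long, tests, letters)``: a long table of per-branch pair
    dissimilarities, the pairwise two-sample Kruskal-Wallis p matrix
    between pair groups, and a compact letter display in which groups
    sharing a letter are not significantly different at ``alpha``.
    """
    polyp = table.subset_role("polyp")
    dm = bray_curtis(polyp)
    dmat = dm.to_frame()
    meta = polyp.samples
    rows = []
    for branch, sub in meta.groupby("branch_id"):
        ids = list(sub.index)
        pn = sub["polyp_number"].astype(int)
        for s1, s2 in combinations(ids, 2):
            i, j = sorted((pn[s1], pn[s2]))
            rows.append(
                {"branch_id": branch, "pair": f"{i}-{j}", "dissimilarity": dmat.loc[s1, s2]}
            )
    long = pd.DataFrame(rows)
    groups = {k: g["dissimilarity"].to_numpy() for k, g in long.groupby("pair")}
    small = [k for k, v in groups.items() if len(v) < 2]
    for k in small:
        warnings.warn(f"position pair {k} has fewer than two values; excluded")
        del groups[k]
    names = sorted(groups)
    pmat = pd.DataFrame(np.ones((len(names), len(names))), index=names, columns=names)
    for a, b in combinations(names, 2):
        x, y = groups[a], groups[b]
        if np.ptp(np.concatenate([x, y])) == 0:
            p = 1.0
        else:
            _, p = stats.kruskal(x, y)
        pmat.loc[a, b] = pmat.loc[b, a] = p
    letters = compact_letter_display(pmat, alpha=alpha)
    return long, pmat, letters


def compact_letter_display(p_matrix: pd.DataFrame, alpha: float = 0.05) -> pd.Series:
    """Insert-and-absorb compact letter display from a pairwise p matrix.

    Groups sharing a letter are not significantly different (p >= alpha).
    Starts from one letter covering everything, splits it at each
    significant pair, absorbs redundant subsets, and assigns letters in
    alphabetical order of group name for a deterministic display.
    """
    names = sorted(p_matrix.index)
    letters: list[set] = [set(names)]
    for a, b in combinations(names, 2):
        if p_matrix.loc[a, b] < alpha:
            new = []
            for s in letters:
                if a in s and b in s:
                    new.extend([s - {a}, s - {b}])
                else:
                    new.append(s)
            # absorb: drop sets contained in another
            letters = [
                s for s in new if s and not any(s < t for t in new if s is not t)
            ]
            # deduplicate
            uniq = []
            for s in letters:
                if s not in uniq:
                    uniq.append(s)
            letters = uniq
    letters.sort(key=lambda s: sorted(s)[0])
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {n: "" for n in names}
    for i, s in enumerate(letters):
        for n in sorted(s):
            out[n] += alphabet[i % len(alphabet)]
    return pd.Series(out, name="letters")


def isolation_by_distance(table: FeatureTable, min_polyps: int = 3) -> tuple[pd.DataFrame, float]:
    """Per-branch regression of pairwise dissimilarity on physical distance.

    Within each branch, all polyp pairs contribute a (|delta position|,
    Bray-Curtis) point; the adjusted R-squared of the OLS fit summarizes
    isolation by distance on that branch.  Returns the per-branch table and
    the mean adjusted R-squared over branches.
    """
    polyp = table.subset_role("polyp")
    dm = bray_curtis(polyp).to_frame()
    meta = polyp.samples
    rows = []
    for branch, sub in meta.groupby("branch_id"):
        ids = list(sub.index)
        if len(ids) < min_polyps:
            warnings.warn(f"branch {branch} has fewer than {min_polyps} polyps; skipped")
            continue
        pos = sub["position_mm"]
        dx, dy = [], []
        for s1, s2 in combinations(ids, 2):
            dx.append(abs(pos[s1] - pos[s2]))
            dy.append(dm.loc[s1, s2])
        fit = ols_fit(np.array(dx), np.array(dy))
        rows.append(
            {
                "branch_id": branch,
                "adj_r_squared": fit["adj_r_squared"],
                "r_squared": fit["r_squared"],
                "slope": fit["slope"],
                "p": fit["p"],
                "n_pairs": len(dx),
            }
        )
    per_branch = pd.DataFrame(rows)
    mean_adj = float(per_branch["adj_r_squared"].mean()) if len(per_branch) else np.nan
    return per_branch, mean_adj


def position_prediction_r2(
    table: FeatureTable,
    seed: int = 0,
    folds: int = 5,
    hidden_layer_sizes: tuple = (32,),
    mode: str = "crossval",
    max_iter: int = 2000,
) -> float:
    """R-squared of a shallow neural network predicting position from the
    full metabolome.

    A single-hidden-layer feed-forward regressor is trained on standardized
    relative abundances.  ``crossval`` pools out-of-fold predictions over a
    seeded K-fold split (the honest generalization estimate);
    ``resubstitution`` scores the training data.  Deterministic given the
    seed.
    """
    from sklearn.metrics import r2_score
    from sklearn.model_selection import KFold
    from sklearn.neural_network import MLPRegressor
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import StandardScaler

    ab, pos = _polyp_positions(table)
    x = ab.to_numpy(float)
    if len(x) < 2 * folds:
        raise ValueError(f"need at least {2 * folds} samples for {folds}-fold CV")

    def model():
        return make_pipeline(
            StandardScaler(),
            MLPRegressor(
                hidden_layer_sizes=hidden_layer_sizes,
                random_state=seed,
                max_iter=max_iter,
                early_stopping=False,
            ),
        )

    if mode == "resubstitution":
        m = model().fit(x, pos)
        return float(r2_score(pos, m.predict(x)))
    if mode != "crossval":
        raise ValueError(f"unknown mode {mode!r}")
    pred = np.empty(len(pos))
    for train, test in KFold(n_splits=folds, shuffle=True, random_state=seed).split(x):
        m = model().fit(x[train], pos[train])
        pred[test] = m.predict(x[test])
    return float(r2_score(pos, pred))
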