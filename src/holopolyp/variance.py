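"""Per-feature dispersion at three organizational scales.

For every feature the relative-abundance standard deviation is computed at
three nested scales of the sampling design:

* ``within_branch`` — SD over the polyps of each branch, averaged over
  branches;
* ``between_branch`` — SD of branch-mean abundances within each colony,
  averaged over colonies (or, with ``aggregation="pooled"``, the SD over
  all samples of a colony);
* ``across_colony`` — SD of colony-mean abundances across colonies (pooled:
  SD over all samples).

The three per-feature SD distributions are then compared pairwise with
nonparametric tests.  This is a descriptive decomposition, not a fitted
random-effects model: with hierarchical effects injected at known
magnitudes it recovers their ordering, which is what the scale comparison
is used for.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .tables import FeatureTable

__all__ = ["VarianceDecomposition", "variance_decomposition", "compare_scales"]

SCALES = ("within_branch", "between_branch", "across_colony")


@dataclass
class VarianceDecomposition:
    """Per-feature SDs at the three scales plus summary means.

    ``per_feature`` has columns ``sd_within_branch``, ``sd_between_branch``,
    ``sd_across_colony``; ``scale_means`` are their column means, and
    ``scale_mean_variances`` the means of the squared SDs (both transforms
    are reported since either may be quoted as the scale summary).
    """

    per_feature: pd.DataFrame
    aggregation: str
    scale_means: dict = field(init=False)
    scale_mean_variances: dict = field(init=False)

    def __post_init__(self) -> None:
        self.scale_means = {s: float(self.per_feature[f"sd_{s}"].mean()) for s in SCALES}
        self.scale_mean_variances = {
            s: float((self.per_feature[f"sd_{s}"] ** 2).mean()) for s in SCALES
        }

    def compare_scales(self, method: str = "kruskal_wallis") -> pd.DataFrame:
        return compare_scales(self, method=method)


def _sd(x: np.ndarray, axis: int = 0) -> np.ndarray:
    """Sample SD with n-1 denominator; 0 for groups of size 1."""
    n = x.shape[axis]
    if n < 2:
        return np.zeros(x.shape[1 - axis] if x.ndim == 2 else ())
    return np.std(x, axis=axis, ddof=1)


def variance_decomposition(table: FeatureTable, aggregation: str = "means") -> VarianceDecomposition:
    """Compute per-feature SDs at the within-branch, between-branch and
    across-colony scales.

    ``aggregation="means"`` measures between-branch and across-colony
    dispersion on branch/colony mean profiles (dispersion of group
    centroids); ``"pooled"`` uses all samples of the grouping directly.
    """
    if aggregation not in ("means", "pooled"):
        raise ValueError(f"unknown aggregation {aggregation!r}")
    polyp = table.subset_role("polyp")
    meta = polyp.samples
    if meta[["colony_id", "branch_id"]].isna().any().any():
        raise ValueError("polyp samples missing colony/branch metadata")
    ab = polyp.abundance

    # within branch: SD over polyps per branch, averaged over branches
    within = ab.groupby(meta["branch_id"]).std(ddof=1).fillna(0.0).mean(axis=0)

    branch_means = ab.groupby(meta["branch_id"]).mean()
    branch_colony = meta.groupby("branch_id")["colony_id"].first().loc[branch_means.index]
    colony_means = ab.groupby(meta["colony_id"]).mean()

    if aggregation == "means":
        between = branch_means.groupby(branch_colony).std(ddof=1).fillna(0.0).mean(axis=0)
        across = colony_means.std(ddof=1).fillna(0.0)
    else:
        between = ab.groupby(meta["colony_id"]).std(ddof=1).fillna(0.0).mean(axis=0)
        across = ab.std(ddof=1).fillna(0.0)

    per_feature = pd.DataFrame(
        {
            "sd_within_branch": within,
            "sd_between_branch": between,
            "sd_across_colony": across,
        }
    )
    per_feature.index.name = "feature_id"
    return VarianceDecomposition(per_feature=per_feature, aggregation=aggregation)


def compare_scales(decomp: VarianceDecomposition, method: str = "kruskal_wallis") -> pd.DataFrame:
    """Pairwise tests between the three per-feature SD distributions.

    ``kruskal_wallis`` treats the two columns of each pair as independent
    samples; ``wilcoxon_paired`` respects that the three SDs are paired per
    feature.  Two-sided p values.
    """
    pf = decomp.per_feature
    if len(pf) < 2:
        raise ValueError("scale comparison needs at least two features")
    rows = []
    for a, b in combinations(SCALES, 2):
        x, y = pf[f"sd_{a}"].to_numpy(), pf[f"sd_{b}"].to_numpy()
        if np.array_equal(x, y) or (np.ptp(np.concatenate([x, y])) == 0):
            stat, p = 0.0, 1.0
        elif method == "kruskal_wallis":
            stat, p = stats.kruskal(x, y)
        elif method == "wilcoxon_paired":
            d = x - y
            if np.all(d == 0):
                stat, p = 0.0, 1.0
            else:
                stat, p = stats.wilcoxon(x, y)
        else:
            raise ValueError(f"unknown method {method!r}")
        rows.append({"scale_a": a, "scale_b": b, "statistic": float(stat), "p": float(p)})
    return pd.DataFrame(rows)
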