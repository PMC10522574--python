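"""Per-sample metabolome richness and Shannon entropy, with one-way ANOVAs.

Richness is the number of detected features (abundance > 0); entropy is
Shannon's H in nats over relative abundances.  Both are compared across
design factors — polyp number, colony, or branch within each colony — with
one-way fixed-effects ANOVA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .tables import FeatureTable

__all__ = ["richness", "shannon_entropy", "per_sample_diversity", "diversity_anova", "DiversityResult"]

FACTORS = ("polyp_number", "colony", "branch_within_colony")


def richness(abundances) -> int:
    """Number of features with abundance strictly greater than zero."""
    a = np.asarray(abundances, dtype=float)
    if (a < 0).any():
        raise ValueError("abundances must be non-negative")
    return int((a > 0).sum())


def shannon_entropy(abundances, base: float | None = None) -> float:
    """Shannon entropy over nonzero relative abundances (nats by default).

    Input is renormalized internally, so raw peak areas and relative
    abundances give the same answer.  ``base`` switches the logarithm (e.g.
    2 for bits); all-zero input is an error.
    """
    a = np.asarray(abundances, dtype=float)
    if (a < 0).any():
        raise ValueError("abundances must be non-negative")
    total = a.sum()
    if total == 0:
        raise ValueError("cannot compute entropy of an all-zero sample")
    p = a[a > 0] / total
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= np.log(base)
    return h


def per_sample_diversity(table: FeatureTable) -> pd.DataFrame:
    """Richness and entropy for every polyp sample, with design metadata."""
    polyp = table.subset_role("polyp")
    ab = polyp.abundance
    out = pd.DataFrame(
        {
            "richness": [richness(row) for row in ab.to_numpy()],
            "entropy": [shannon_entropy(row) for row in ab.to_numpy()],
        },
        index=ab.index,
    )
    return out.join(polyp.samples[["colony_id", "branch_id", "polyp_number", "position_mm"]])


@dataclass
class DiversityResult:
    """One-way ANOVA of a diversity metric across a design factor.

    ``anova`` holds one row per group set (a single row except for
    branch-within-colony, which runs one ANOVA per colony);
    ``n_significant`` counts group sets with p below alpha.
    """

    metric: str
    factor: str
    per_sample: pd.DataFrame
    anova: pd.DataFrame
    alpha: float = 0.05

    @property
    def n_significant(self) -> int:
        return int((self.anova["p"] < self.alpha).sum())


def _one_way(groups: list[np.ndarray]) -> tuple[float, float, tuple[int, int]]:
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least two groups")
    for g in groups:
        if len(g) < 2:
            raise ValueError("each ANOVA group needs at least two observations")
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f, p = stats.f_oneway(*groups)
    df = (len(groups) - 1, sum(len(g) for g in groups) - len(groups))
    if np.isnan(f):  # all observations equal: no variance at either scale
        f, p = 0.0, 1.0
    elif not np.isfinite(f):  # zero within-group variance, distinct means
        f, p = np.inf, 0.0
    return float(f), float(p), df


def diversity_anova(
    table: FeatureTable, metric: str = "richness", factor: str = "colony", alpha: float = 0.05
) -> DiversityResult:
    """One-way ANOVA of richness or entropy across a design factor.

    For ``branch_within_colony``, one ANOVA is run per colony (branches as
    groups) and the result table has one row per colony.
    """
    if metric not in ("richness", "entropy"):
        raise ValueError(f"unknown metric {metric!r}")
    if factor not in FACTORS:
        raise ValueError(f"unknown factor {factor!r}; choose from {FACTORS}")
    per_sample = per_sample_diversity(table)
    values = per_sample[metric]

    rows = []
    if factor == "branch_within_colony":
        for colony, sub in per_sample.groupby("colony_id", sort=True):
            groups = [values.loc[g.index].to_numpy(float) for _, g in sub.groupby("branch_id")]
            f, p, df = _one_way(groups)
            rows.append({"group_set": colony, "F": f, "p": p, "df_between": df[0], "df_within": df[1]})
    else:
        key = "polyp_number" if factor == "polyp_number" else "colony_id"
        groups = [values.loc[g.index].to_numpy(float) for _, g in per_sample.groupby(key)]
        f, p, df = _one_way(groups)
        rows.append({"group_set": factor, "F": f, "p": p, "df_between": df[0], "df_within": df[1]})

    return DiversityResult(
        metric=metric, factor=factor, per_sample=per_sample, anova=pd.DataFrame(rows), alpha=alpha
    )
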