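"""Host/symbiont source attribution for polyp metabolome features.

Polyp features are matched to features observed in two reference sample
sets — bleached coral (host-only tissue) and purified algal-symbiont
pellets — and labeled ``host`` if on average at least ``fold`` (default
10x) more abundant in the bleached references, ``symbiont`` if at least
``fold`` more abundant in the algal pellets, in both cases requiring a
significant Kruskal-Wallis enrichment between the two reference groups.
Matched features meeting neither rule are ``shared``; unmatched features
are ``unassigned``.  The summed relative abundance of each source class is
then regressed on the polyp's distance from the branch base to ask which
holobiont partner drives spatial structure.

Matching operates on feature tables, so reference features are paired to
polyp features by m/z (ppm window) and retention time rather than by MS/MS
spectral networking; synthetic tables sharing feature IDs can bypass
matching entirely with ``exact_ids=True``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .gradient import ols_fit
from .tables import FeatureTable

__all__ = ["match_reference_features", "assign_source", "source_sum_regression"]

SOURCES = ("host", "symbiont", "shared", "unassigned")


def match_reference_features(
    polyp_table: FeatureTable,
    reference_table: FeatureTable,
    mz_tol_ppm: float = 10.0,
    rt_tol_min: float = 0.1,
    exact_ids: bool = False,
) -> pd.Series:
    """Map each polyp feature to at most one reference feature.

    A reference feature is a candidate if it lies within ``mz_tol_ppm`` of
    the polyp feature's m/z and within ``rt_tol_min`` of its retention
    time; among candidates the smallest absolute ppm deviation wins.
    Returns a Series (polyp feature_id -> reference feature_id, NaN when
    unmatched).  ``exact_ids`` matches by identical feature IDs instead.
    """
    pf, rf = polyp_table.features, reference_table.features
    if exact_ids:
        return pd.Series(
            [fid if fid in rf.index else np.nan for fid in pf.index], index=pf.index, name="ref_id"
        )
    for df, name in ((pf, "polyp"), (rf, "reference")):
        for col in ("mz", "rt"):
            if col not in df.columns or df[col].isna().any():
                raise ValueError(f"{name} features missing {col} values")
    ref_mz = rf["mz"].to_numpy(float)
    ref_rt = rf["rt"].to_numpy(float)
    out = {}
    for fid, row in pf.iterrows():
        ppm = 1e6 * (ref_mz - row["mz"]) / row["mz"]
        ok = (np.abs(ppm) <= mz_tol_ppm) & (np.abs(ref_rt - row["rt"]) <= rt_tol_min)
        if not ok.any():
            out[fid] = np.nan
            continue
        cand = np.flatnonzero(ok)
        out[fid] = rf.index[cand[np.argmin(np.abs(ppm[cand]))]]
    return pd.Series(out, name="ref_id")


def _group_matrix(reference_table: FeatureTable, role: str) -> pd.DataFrame:
    ids = reference_table.samples.index[reference_table.samples["role"] == role]
    return reference_table.abundance.loc[ids]


def assign_source(
    polyp_table: FeatureTable,
    reference_table: FeatureTable,
    mapping: pd.Series | None = None,
    fold: float = 10.0,
    alpha: float = 0.05,
    agg: str = "mean",
    test: str = "kruskal",
) -> pd.DataFrame:
    """Label each polyp feature host / symbiont / shared / unassigned.

    For each matched feature the bleached-vs-algal fold change is computed
    on ``agg`` (mean or median) reference abundances, with a zero side
    replaced by half the smallest nonzero aggregate on that side, and the
    two reference groups are compared with a Kruskal-Wallis (or
    Mann-Whitney) test.  ``host`` requires fold >= ``fold`` and p <
    ``alpha``; ``symbiont`` the mirrored rule.
    """
    if fold <= 1:
        raise ValueError("fold threshold must exceed 1")
    bleached = _group_matrix(reference_table, "bleached_host")
    algal = _group_matrix(reference_table, "algal_pellet")
    if len(bleached) < 2 or len(algal) < 2:
        raise ValueError("need at least two bleached and two algal reference samples")
    if mapping is None:
        mapping = match_reference_features(polyp_table, reference_table)

    aggfun = {"mean": np.mean, "median": np.median}.get(agg)
    if aggfun is None:
        raise ValueError(f"unknown aggregation {agg!r}")

    b_agg = bleached.apply(aggfun, axis=0)
    a_agg = algal.apply(aggfun, axis=0)
    b_floor = 0.5 * b_agg[b_agg > 0].min() if (b_agg > 0).any() else 1.0
    a_floor = 0.5 * a_agg[a_agg > 0].min() if (a_agg > 0).any() else 1.0

    rows = []
    for fid in polyp_table.features.index:
        ref = mapping.get(fid, np.nan)
        if pd.isna(ref):
            rows.append(
                {"feature_id": fid, "source": "unassigned", "fold_change": np.nan,
                 "enrichment_p": np.nan, "matched": False}
            )
            continue
        bvals = bleached[ref].to_numpy(float)
        avals = algal[ref].to_numpy(float)
        num = b_agg[ref] if b_agg[ref] > 0 else b_floor
        den = a_agg[ref] if a_agg[ref] > 0 else a_floor
        fc = num / den
        if np.ptp(np.concatenate([bvals, avals])) == 0:
            p = 1.0
        elif test == "kruskal":
            _, p = stats.kruskal(bvals, avals)
        elif test == "mannwhitney":
            _, p = stats.mannwhitneyu(bvals, avals, alternative="two-sided")
        else:
            raise ValueError(f"unknown test {test!r}")
        if fc >= fold and p < alpha:
            source = "host"
        elif fc <= 1 / fold and p < alpha:
            source = "symbiont"
        else:
            source = "shared"
        rows.append(
            {"feature_id": fid, "source": source, "fold_change": float(fc),
             "enrichment_p": float(p), "matched": True}
        )
    return pd.DataFrame(rows).set_index("feature_id")


def source_sum_regression(
    polyp_table: FeatureTable, assignments: pd.DataFrame, sources: tuple = ("host", "symbiont")
) -> dict[str, dict | None]:
    """OLS of per-sample source-summed relative abundance on position.

    For each requested source class, member features' relative abundances
    are summed per polyp sample and regressed on distance from the branch
    base.  A source with no assigned features yields ``None`` (flagged
    absent) instead of a regression.
    """
    polyp = polyp_table.subset_role("polyp")
    pos = polyp.samples["position_mm"].to_numpy(float)
    out: dict[str, dict | None] = {}
    for source in sources:
        members = assignments.index[assignments["source"] == source]
        members = members.intersection(polyp.abundance.columns)
        if len(members) == 0:
            out[source] = None
            continue
        y = polyp.abundance[members].sum(axis=1).to_numpy(float)
        fit = ols_fit(pos, y)
        fit["n_features"] = int(len(members))
        out[source] = fit
    return out
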