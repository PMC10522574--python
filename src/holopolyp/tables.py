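"""Feature-table data model, CSV I/O, and the two preprocessing rules.

The central object is :class:`FeatureTable`: a samples x features matrix of
LC-MS peak areas joined to sample metadata (role and colony / branch /
polyp-position hierarchy) and feature metadata (m/z, retention time, class
annotations).  Preprocessing follows the standard untargeted-metabolomics
recipe: features must be on average ``ratio``-fold (default 3x) more
abundant in biological samples than in extraction blanks to be retained,
after which each sample is normalized to its total feature abundance,
yielding relative abundances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "SAMPLE_ROLES",
    "FeatureTable",
    "read_tables",
    "write_tables",
    "remove_blank_features",
    "normalize_total",
]

SAMPLE_ROLES = ("polyp", "blank", "bleached_host", "algal_pellet")

# MZmine FBMN quant-table export dialect.
_QUANT_ID = "row ID"
_QUANT_MZ = "row m/z"
_QUANT_RT = "row retention time"
_QUANT_AREA_SUFFIX = ".mzXML Peak area"

_SAMPLE_COLUMNS = ["sample_id", "role", "colony_id", "branch_id", "polyp_number", "position_mm"]
_FEATURE_COLUMNS = ["feature_id", "mz", "rt", "class_label", "subclass_label", "formula"]


@dataclass
class FeatureTable:
    """Abundance matrix plus sample and feature metadata.

    Parameters
    ----------
    abundance : pandas.DataFrame
        Samples (rows, indexed by sample_id) x features (columns, indexed by
        feature_id) matrix of non-negative peak areas or relative abundances.
    samples : pandas.DataFrame
        One row per sample, indexed by ``sample_id``, with at least a
        ``role`` column and, for polyp samples, ``colony_id``, ``branch_id``,
        ``polyp_number`` and ``position_mm``.
    features : pandas.DataFrame
        One row per feature, indexed by ``feature_id``, with ``mz``, ``rt``
        and optional annotation columns.
    normalized : bool
        True once rows are relative abundances summing to 1.
    """

    abundance: pd.DataFrame
    samples: pd.DataFrame
    features: pd.DataFrame
    normalized: bool = False

    def __post_init__(self) -> None:
        ab = self.abundance
        if ab.index.has_duplicates:
            raise ValueError("duplicate sample IDs in abundance matrix")
        if ab.columns.has_duplicates:
            raise ValueError("duplicate feature IDs in abundance matrix")
        missing_s = ab.index.difference(self.samples.index)
        if len(missing_s):
            raise ValueError(f"samples missing from metadata: {sorted(missing_s)[:5]}")
        missing_f = ab.columns.difference(self.features.index)
        if len(missing_f):
            raise ValueError(f"features missing from metadata: {sorted(missing_f)[:5]}")
        if (ab.to_numpy() < 0).any():
            raise ValueError("negative abundances are not allowed")
        # align metadata to matrix order
        self.samples = self.samples.loc[ab.index]
        self.features = self.features.loc[ab.columns]
        if self.normalized:
            polyp = self.polyp_mask()
            sums = ab.loc[polyp].sum(axis=1)
            if len(sums) and not np.allclose(sums, 1.0, atol=1e-9):
                raise ValueError("normalized flag set but polyp rows do not sum to 1")

    # -- convenience accessors -------------------------------------------------

    def polyp_mask(self) -> pd.Series:
        return self.samples["role"] == "polyp"

    def subset_role(self, role: str) -> "FeatureTable":
        """Restrict to samples of a single role."""
        keep = self.samples.index[self.samples["role"] == role]
        return replace(
            self,
            abundance=self.abundance.loc[keep],
            samples=self.samples.loc[keep],
        )

    @property
    def n_samples(self) -> int:
        return self.abundance.shape[0]

    @property
    def n_features(self) -> int:
        return self.abundance.shape[1]

    # -- preprocessing (method-style mirrors of the module functions) ----------

    def remove_blank_features(self, ratio: float = 3.0) -> "FeatureTable":
        return remove_blank_features(self, ratio=ratio)

    def normalize_total(self) -> "FeatureTable":
        return normalize_total(self)


def _area_col(sample_id: str) -> str:
    return f"{sample_id}{_QUANT_AREA_SUFFIX}"


def read_tables(quant_path, sample_meta_path, annotation_path=None) -> FeatureTable:
    """Read an MZmine-style quant CSV plus metadata CSVs into a FeatureTable.

    The quant table has columns ``row ID``, ``row m/z``, ``row retention
    time`` and one ``<sample>.mzXML Peak area`` column per sample.  Missing
    abundances are read as 0.  Sample IDs in the quant header must all be
    present in the sample-metadata table.
    """
    quant = pd.read_csv(quant_path)
    for col in (_QUANT_ID, _QUANT_MZ, _QUANT_RT):
        if col not in quant.columns:
            raise ValueError(f"quant table missing required column {col!r}")
    fids = quant[_QUANT_ID].astype(str)
    if fids.duplicated().any():
        dups = sorted(fids[fids.duplicated()].unique())
        raise ValueError(f"duplicate feature IDs in quant table: {dups[:5]}")

    area_cols = [c for c in quant.columns if c.endswith(_QUANT_AREA_SUFFIX)]
    sample_ids = [c[: -len(_QUANT_AREA_SUFFIX)] for c in area_cols]

    meta = pd.read_csv(sample_meta_path, dtype={"sample_id": str})
    meta = meta.set_index("sample_id")
    unmatched = [s for s in sample_ids if s not in meta.index]
    if unmatched:
        raise ValueError(f"quant-table samples absent from metadata: {unmatched}")

    abundance = quant[area_cols].fillna(0.0).astype(float)
    abundance.columns = sample_ids
    abundance.index = fids
    abundance = abundance.T  # samples x features
    abundance.index.name = "sample_id"
    abundance.columns.name = "feature_id"

    features = pd.DataFrame(
        {"mz": quant[_QUANT_MZ].to_numpy(float), "rt": quant[_QUANT_RT].to_numpy(float)},
        index=pd.Index(fids, name="feature_id"),
    )
    if annotation_path is not None:
        ann = pd.read_csv(annotation_path, dtype={"feature_id": str}).set_index("feature_id")
        features = features.join(ann, how="left")

    return FeatureTable(abundance=abundance, samples=meta.loc[sample_ids], features=features)


def write_tables(table: FeatureTable, quant_path, sample_meta_path, annotation_path=None) -> None:
    """Write a FeatureTable back to the CSV dialect :func:`read_tables` reads."""
    quant = pd.DataFrame(
        {
            _QUANT_ID: table.features.index,
            _QUANT_MZ: table.features["mz"].to_numpy(),
            _QUANT_RT: table.features["rt"].to_numpy(),
        }
    )
    mat = table.abundance.T  # features x samples
    for sid in table.abundance.index:
        quant[_area_col(sid)] = mat[sid].to_numpy()
    quant.to_csv(quant_path, index=False)

    table.samples.reset_index().to_csv(sample_meta_path, index=False)
    if annotation_path is not None:
        ann = table.features.drop(columns=["mz", "rt"], errors="ignore")
        ann.reset_index().to_csv(annotation_path, index=False)


def remove_blank_features(table: FeatureTable, ratio: float = 3.0) -> FeatureTable:
    """Drop features insufficiently enriched in samples over extraction blanks.

    A feature is retained iff its mean abundance over polyp samples is at
    least ``ratio`` times its mean over blank samples (boundary inclusive).
    Features never seen in any blank (blank mean 0) are always retained.
    Blank samples are dropped from the returned table.  With no blanks
    present the table is returned unchanged with a warning.
    """
    if ratio <= 0:
        raise ValueError(f"blank ratio must be positive, got {ratio}")
    if table.normalized:
        raise ValueError("blank filtering must precede normalization")
    roles = table.samples["role"]
    blank_ids = table.samples.index[roles == "blank"]
    if len(blank_ids) == 0:
        warnings.warn("no blank samples present; blank filtering skipped")
        return table
    polyp_ids = table.samples.index[roles == "polyp"]
    sample_mean = table.abundance.loc[polyp_ids].mean(axis=0)
    blank_mean = table.abundance.loc[blank_ids].mean(axis=0)
    keep = (blank_mean == 0) | (sample_mean >= ratio * blank_mean)
    keep_ids = table.abundance.columns[keep.to_numpy()]
    keep_samples = table.samples.index[roles != "blank"]
    return FeatureTable(
        abundance=table.abundance.loc[keep_samples, keep_ids],
        samples=table.samples.loc[keep_samples],
        features=table.features.loc[keep_ids],
        normalized=False,
    )


def normalize_total(table: FeatureTable) -> FeatureTable:
    """Total-abundance (TIC) normalization: divide each sample by its total.

    Every row of the result sums to 1.  Warns if blanks are still present
    (filtering is expected first); errors on an all-zero sample.
    """
    if (table.samples["role"] == "blank").any():
        warnings.warn("normalizing a table that still contains blank samples")
    totals = table.abundance.sum(axis=1)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"all-zero sample(s): {sorted(zero.index)[:5]}")
    return replace(table, abundance=table.abundance.div(totals, axis=0), normalized=True)
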