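"""Synthetic single-polyp metabolomics study generator.

Emulates a hierarchical coral-sampling campaign — colonies, three branches
per colony, six polyps per branch at defined distances from the branch base
— and simulates an LC-MS feature table over that design with known ground
truth: which features are host- vs symbiont-derived, which are extraction
contaminants, and which carry a true abundance gradient along the branch.

The sampling geometry follows the field protocol: polyp 1 sits 10 mm above
the branch base; polyps 2 and 3 are the next consecutive corallites (one
spacing step apart); polyp 4 is placed a quarter of the way from polyp 3 to
the branch tip, polyp 5 halfway, and polyp 6 at the tip.  Branch lengths
are drawn uniformly from ~8-15 cm.

Abundances are log-normal: additive colony, branch and residual effects on
the log scale, plus a per-mm slope for gradient features, exponentiated to
positive peak areas.  Extraction blanks carry only contaminant features;
bleached-coral references express host + shared features with only
residual-level bleed of the symbiont pool (1/``host_symbiont_fold`` of its
level), and algal-pellet references the mirror image, so the fold change
between the two reference sets equals ``host_symbiont_fold`` in
expectation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .tables import FeatureTable

__all__ = [
    "DesignSpec",
    "EffectSpec",
    "generate_design",
    "generate_feature_catalog",
    "simulate_abundances",
    "simulate_study",
]

#: Distance of polyp 1 from the branch base (mm): "1 cm above the base".
POLYP1_OFFSET_MM = 10.0

_CLASS_PALETTE = (
    "Prenol lipids",
    "Steroids and steroid derivatives",
    "Fatty Acyls",
    "Carboxylic acids and derivatives",
    "Organooxygen compounds",
)
_SUBCLASS_PALETTE = (
    "Triterpenoids",
    "Hydroxysteroids",
    "Sesquiterpenoids",
    "Amino acids and derivatives",
    "Organosulfonic acids and derivatives",
    "Carbamate esters",
)


@dataclass(frozen=True)
class DesignSpec:
    """Sampling design: how many colonies/branches/polyps and their geometry."""

    n_colonies: int = 19
    branches_per_colony: int = 3
    polyps_per_branch: int = 6
    branch_length_range_mm: tuple[float, float] = (80.0, 150.0)
    polyp_spacing_mm: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_colonies, self.branches_per_colony, self.polyps_per_branch) < 1:
            raise ValueError("all design counts must be >= 1")
        lo, hi = self.branch_length_range_mm
        if lo > hi:
            raise ValueError("branch_length_range_mm min must be <= max")
        if self.polyp_spacing_mm <= 0:
            raise ValueError("polyp spacing must be positive")


@dataclass(frozen=True)
class EffectSpec:
    """Effect sizes and composition of the simulated metabolome.

    Log-scale standard deviations place most variance at the colony level,
    then branch, then polyp residual, matching the organizational hierarchy
    the analysis is meant to recover.  The default gradient slope
    (log-abundance per mm) is sized so a gradient feature explains on the
    order of 20% of pooled between-sample variance against the combined
    colony+branch+residual noise over the ~10-115 mm position range.
    """

    baseline_log_mean: float = 13.0
    colony_sd: float = 1.0
    branch_sd: float = 0.5
    residual_sd: float = 0.25
    feature_log_sd: float = 0.0
    n_gradient_features: int = 7
    gradient_slope_per_mm: float = 0.015
    fraction_host: float = 0.4
    fraction_symbiont: float = 0.3
    fraction_contaminant: float = 0.1
    host_symbiont_fold: float = 20.0
    n_blanks: int = 3
    n_bleached: int = 4
    n_algal: int = 4
    blank_bleed: float = 0.0

    def __post_init__(self) -> None:
        if min(self.colony_sd, self.branch_sd, self.residual_sd, self.feature_log_sd) < 0:
            raise ValueError("effect standard deviations must be >= 0")
        fr = self.fraction_host + self.fraction_symbiont + self.fraction_contaminant
        if not (0 <= fr <= 1):
            raise ValueError("source fractions must be in [0, 1] and sum to <= 1")
        if self.host_symbiont_fold <= 1:
            raise ValueError("host_symbiont_fold must exceed 1")
        if not (0 <= self.blank_bleed < 1):
            raise ValueError("blank_bleed must be in [0, 1)")


def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _branch_positions(length: float, spacing: float) -> np.ndarray:
    """Positions (mm from base) of the six polyps on a branch of given length."""
    p1 = POLYP1_OFFSET_MM
    p2 = p1 + spacing
    p3 = p1 + 2 * spacing
    p4 = p3 + 0.25 * (length - p3)
    p5 = p3 + 0.50 * (length - p3)
    return np.array([p1, p2, p3, p4, p5, length])


def generate_design(spec: DesignSpec, seed=None, max_retries: int = 100) -> pd.DataFrame:
    """Generate one SampleRecord row per polyp over the full design.

    Returns a DataFrame indexed by sample_id with columns role, colony_id,
    branch_id, polyp_number and position_mm.  Branch lengths are drawn
    uniformly from ``spec.branch_length_range_mm``; a draw shorter than the
    polyp-3 position is rejected and redrawn (error after ``max_retries``).
    Deterministic given ``spec.seed`` (or an explicit ``seed``).
    """
    rng = _as_rng(spec.seed if seed is None else seed)
    lo, hi = spec.branch_length_range_mm
    p3 = POLYP1_OFFSET_MM + 2 * spec.polyp_spacing_mm
    rows = []
    for ci in range(1, spec.n_colonies + 1):
        colony = f"C{ci:02d}"
        for bi in range(1, spec.branches_per_colony + 1):
            branch = f"{colony}B{bi}"
            for _ in range(max_retries):
                length = rng.uniform(lo, hi)
                if length > p3:
                    break
            else:
                raise RuntimeError(
                    f"could not draw a branch length > polyp-3 position ({p3} mm) "
                    f"from range {spec.branch_length_range_mm} in {max_retries} tries"
                )
            positions = _branch_positions(length, spec.polyp_spacing_mm)
            for pn in range(1, spec.polyps_per_branch + 1):
                # branches shorter than 6 polyps take the first k positions
                pos = positions[pn - 1] if pn <= 6 else float(positions[-1])
                rows.append(
                    {
                        "sample_id": f"{branch}P{pn}",
                        "role": "polyp",
                        "colony_id": colony,
                        "branch_id": branch,
                        "polyp_number": pn,
                        "position_mm": float(pos),
                    }
                )
    return pd.DataFrame(rows).set_index("sample_id")


def generate_feature_catalog(
    n_features: int,
    effect: EffectSpec = EffectSpec(),
    seed=0,
    class_palette: Sequence[str] = _CLASS_PALETTE,
    subclass_palette: Sequence[str] = _SUBCLASS_PALETTE,
) -> pd.DataFrame:
    """Generate FeatureRecords: m/z, RT, class labels, and ground truth.

    Features are split into host / symbiont / contaminant / shared pools by
    the EffectSpec fractions.  Exactly ``effect.n_gradient_features``
    features carry a nonzero true gradient slope, all drawn from the host
    pool.  m/z is uniform over the 100-1500 scan range, RT over the 1-10 min
    acquisition window.  Deterministic given the seed.
    """
    rng = _as_rng(seed)
    n_host = int(round(n_features * effect.fraction_host))
    n_sym = int(round(n_features * effect.fraction_symbiont))
    n_con = int(round(n_features * effect.fraction_contaminant))
    if n_host + n_sym + n_con > n_features:
        raise ValueError("source fractions exceed the feature count")
    if effect.n_gradient_features > n_host:
        raise ValueError(
            f"host pool ({n_host}) smaller than n_gradient_features "
            f"({effect.n_gradient_features})"
        )
    n_shared = n_features - n_host - n_sym - n_con
    sources = np.array(
        ["host"] * n_host + ["symbiont"] * n_sym + ["contaminant"] * n_con + ["shared"] * n_shared
    )
    slopes = np.zeros(n_features)
    slopes[:effect.n_gradient_features] = effect.gradient_slope_per_mm  # host pool leads

    order = rng.permutation(n_features)
    feature_ids = [f"F{i + 1:04d}" for i in range(n_features)]
    cat = pd.DataFrame(
        {
            "mz": rng.uniform(100.0, 1500.0, n_features),
            "rt": rng.uniform(1.0, 10.0, n_features),
            "class_label": rng.choice(list(class_palette), n_features),
            "subclass_label": rng.choice(list(subclass_palette), n_features),
            "formula": "",
            "true_source": sources[order],
            "true_gradient_slope": slopes[order],
        },
        index=pd.Index(feature_ids, name="feature_id"),
    )
    return cat


def simulate_abundances(
    design: pd.DataFrame,
    catalog: pd.DataFrame,
    effect: EffectSpec = EffectSpec(),
    seed=0,
) -> FeatureTable:
    """Simulate peak areas for polyp samples plus blanks and reference samples.

    Log intensity of feature f in polyp sample s is
    ``baseline + colony_effect(c(s), f) + branch_effect(b(s), f) +
    slope(f) * position(s) + eps`` with independent normal effects, then
    exponentiated.  Contaminant features appear in blanks at sample-like
    intensity; other features are absent from blanks (or present at
    ``blank_bleed`` of baseline).  Bleached-coral references express
    host + shared (+ contaminant) features fully and the symbiont pool at
    1/``host_symbiont_fold``; algal-pellet references are the mirror image.
    """
    if len(design) == 0 or len(catalog) == 0:
        raise ValueError("design and catalog must be nonempty")
    rng = _as_rng(seed)
    n_feat = len(catalog)
    # per-feature baseline offsets emulate the orders-of-magnitude dynamic
    # range of LC-MS peak areas; shared by every sample block so the
    # blank-filter ratio is unaffected
    feat_base = rng.normal(0.0, effect.feature_log_sd, n_feat)
    source = catalog["true_source"].to_numpy()
    slope = catalog["true_gradient_slope"].to_numpy(float)
    log_fold = np.log(effect.host_symbiont_fold)

    colonies = design["colony_id"].to_numpy()
    branches = design["branch_id"].to_numpy()
    positions = design["position_mm"].to_numpy(float)
    uniq_col = pd.unique(colonies)
    uniq_br = pd.unique(branches)
    col_eff = rng.normal(0.0, effect.colony_sd, size=(len(uniq_col), n_feat))
    br_eff = rng.normal(0.0, effect.branch_sd, size=(len(uniq_br), n_feat))
    col_ix = pd.Categorical(colonies, categories=uniq_col).codes
    br_ix = pd.Categorical(branches, categories=uniq_br).codes

    is_con = source == "contaminant"
    # contamination is technical (reagents/instrument), so contaminant
    # features carry no biological colony/branch/gradient structure
    bio = (~is_con).astype(float)
    log_polyp = (
        effect.baseline_log_mean
        + feat_base
        + (col_eff[col_ix] + br_eff[br_ix] + np.outer(positions, slope)) * bio
        + rng.normal(0.0, effect.residual_sd, size=(len(design), n_feat))
    )
    polyp_ab = np.exp(log_polyp)

    def _reference(n: int, expressed: np.ndarray, suppressed: np.ndarray) -> np.ndarray:
        """Reference block: full level for expressed, 1/fold for suppressed pool."""
        log_ref = effect.baseline_log_mean + feat_base + rng.normal(
            0.0, effect.residual_sd, size=(n, n_feat)
        )
        log_ref = log_ref - log_fold * suppressed[None, :]
        ab = np.exp(log_ref)
        ab[:, ~(expressed | suppressed)] = 0.0
        return ab

    is_host = source == "host"
    is_sym = source == "symbiont"
    is_shared = source == "shared"

    blank_ab = np.zeros((effect.n_blanks, n_feat))
    if effect.n_blanks:
        log_blank = effect.baseline_log_mean + feat_base + rng.normal(
            0.0, effect.residual_sd, size=(effect.n_blanks, n_feat)
        )
        blank_ab = np.exp(log_blank)
        if effect.blank_bleed > 0:
            blank_ab[:, ~is_con] *= effect.blank_bleed
        else:
            blank_ab[:, ~is_con] = 0.0

    bleached_ab = _reference(effect.n_bleached, is_host | is_shared | is_con, is_sym)
    algal_ab = _reference(effect.n_algal, is_sym | is_shared | is_con, is_host)

    blocks, meta_rows = [polyp_ab], []
    for _, row in design.iterrows():
        meta_rows.append(dict(row))
    ids = list(design.index)

    def _add(prefix: str, role: str, ab: np.ndarray) -> None:
        if len(ab) == 0:
            return
        blocks.append(ab)
        for i in range(len(ab)):
            ids.append(f"{prefix}{i + 1}")
            meta_rows.append(
                {
                    "role": role,
                    "colony_id": np.nan,
                    "branch_id": np.nan,
                    "polyp_number": np.nan,
                    "position_mm": np.nan,
                }
            )

    _add("BLK", "blank", blank_ab)
    _add("BLH", "bleached_host", bleached_ab)
    _add("ALG", "algal_pellet", algal_ab)

    abundance = pd.DataFrame(
        np.vstack(blocks), index=pd.Index(ids, name="sample_id"), columns=catalog.index
    )
    samples = pd.DataFrame(meta_rows, index=abundance.index)
    return FeatureTable(abundance=abundance, samples=samples, features=catalog.copy())


def simulate_study(
    design_spec: DesignSpec = DesignSpec(),
    effect: EffectSpec = EffectSpec(),
    n_features: int = 617,
    seed: int | None = None,
) -> FeatureTable:
    """Full study in one call: design, catalog and abundances from one seed.

    The default feature count is sized so that removing the ~10%
    contaminant features during blank filtering leaves about 555 biological
    features, the scale of the real single-polyp dataset.
    """
    rng = _as_rng(design_spec.seed if seed is None else seed)
    design = generate_design(design_spec, seed=rng)
    catalog = generate_feature_catalog(n_features, effect, seed=rng)
    return simulate_abundances(design, catalog, effect, seed=rng)
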