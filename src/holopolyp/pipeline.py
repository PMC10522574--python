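"""End-to-end orchestration of the single-polyp metabolome analysis.

``run_pipeline`` drives every stage in order — simulate (or read) the
feature table, blank-filter and normalize, per-sample diversity with
ANOVAs, multi-scale variance decomposition, ordination + PERMANOVA +
discriminant classification, within-branch gradient analyses, and
host/symbiont source mapping — writing each stage's outputs as CSV/JSON
plus a reproducibility manifest (config, seed, package version, SHA-256
checksums).  All randomness flows from the single ``seed`` in the config,
so a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .diversity import diversity_anova
from .gradient import (
    class_gradient_correlations,
    feature_position_screen,
    isolation_by_distance,
    position_pair_dissimilarity,
    position_prediction_r2,
)
from .simulate import DesignSpec, EffectSpec, simulate_study
from .sourcemap import assign_source, match_reference_features, source_sum_regression
from .structure import bray_curtis, discriminant, pca, permanova, permanova_two_factor
from .tables import FeatureTable, normalize_total, read_tables, remove_blank_features
from .variance import variance_decomposition

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Pipeline configuration; defaults mirror the standard workflow rules."""

    # inputs: either the three CSV paths, or simulate=True
    quant_path: str | None = None
    sample_meta_path: str | None = None
    annotation_path: str | None = None
    simulate: bool = True
    n_features: int = 150
    design: dict = field(default_factory=dict)
    effect: dict = field(default_factory=dict)

    blank_ratio: float = 3.0
    fold: float = 10.0
    alpha: float = 0.05
    n_permutations: int = 999
    p_threshold: float = 0.05
    r2_threshold: float = 0.10
    class_level: str = "SubClass"
    run_position_nn: bool = True
    exact_ids: bool = True
    seed: int = 0
    out_dir: str = "holopolyp_out"

    def __post_init__(self) -> None:
        for name in ("alpha", "p_threshold", "r2_threshold"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if self.blank_ratio <= 0 or self.fold <= 1 or self.n_permutations < 1:
            raise ValueError("invalid blank_ratio / fold / n_permutations")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _dump_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonable) + "\n")


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON-serializable: {type(x)}")


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write outputs under ``config.out_dir``.

    Returns a summary dict (also written as ``manifest.json``).  Any stage
    failure is re-raised with the stage name attached.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    written: list[Path] = []

    def save_csv(df: pd.DataFrame, name: str, **kw) -> None:
        p = out / name
        df.to_csv(p, **kw)
        written.append(p)

    def save_json(obj, name: str) -> None:
        p = out / name
        _dump_json(obj, p)
        written.append(p)

    try:
        stage = "input"
        if config.simulate:
            table = simulate_study(
                DesignSpec(**{**config.design, "seed": config.seed}),
                EffectSpec(**config.effect),
                n_features=config.n_features,
                seed=config.seed,
            )
        else:
            if not (config.quant_path and config.sample_meta_path):
                raise ValueError("quant_path and sample_meta_path required when simulate=False")
            table = read_tables(config.quant_path, config.sample_meta_path, config.annotation_path)
        if config.class_level and "subclass_label" not in table.features.columns:
            raise ValueError("class analysis requested but annotations carry no class labels")

        stage = "preprocess"
        filtered = remove_blank_features(table, ratio=config.blank_ratio)
        norm = normalize_total(filtered)
        polyp = norm.subset_role("polyp")

        stage = "diversity"
        div_rows = []
        for metric in ("richness", "entropy"):
            for factor in ("polyp_number", "colony", "branch_within_colony"):
                res = diversity_anova(norm, metric=metric, factor=factor, alpha=config.alpha)
                for _, row in res.anova.iterrows():
                    div_rows.append({"metric": metric, "factor": factor, **row})
        save_csv(res.per_sample, "diversity_per_sample.csv")
        save_csv(pd.DataFrame(div_rows), "diversity_anova.csv", index=False)

        stage = "variance"
        decomp = variance_decomposition(norm)
        save_csv(decomp.per_feature, "variance_per_feature.csv")
        save_json(
            {
                "scale_mean_sd": decomp.scale_means,
                "scale_mean_variance": decomp.scale_mean_variances,
                "tests": decomp.compare_scales().to_dict(orient="records"),
            },
            "variance_scales.json",
        )

        stage = "structure"
        dm = bray_curtis(norm)
        save_csv(dm.to_frame(), "bray_curtis.csv")
        scores, evr = pca(norm, n_axes=2)
        save_csv(scores, "pca_scores.csv")
        colony = polyp.samples["colony_id"]
        polyp_no = polyp.samples["polyp_number"].astype(int).astype(str)
        perm_col = permanova(dm, colony, n_permutations=config.n_permutations, seed=config.seed)
        perm_pos = permanova(dm, polyp_no, n_permutations=config.n_permutations, seed=config.seed)
        perm_two = permanova_two_factor(
            dm, colony, polyp_no, n_permutations=config.n_permutations, seed=config.seed
        )
        disc = discriminant(norm, colony, mode="resubstitution")
        save_csv(disc.canonical_scores, "discriminant_scores.csv")
        save_json(
            {
                "pca_explained_variance_ratio": list(evr),
                "permanova_colony": perm_col.as_dict(),
                "permanova_polyp_number": perm_pos.as_dict(),
                "permanova_colony_then_polyp": {
                    "colony": perm_two["factor_a"].as_dict(),
                    "polyp_number": perm_two["factor_b"].as_dict(),
                },
                "discriminant_colony_misclassification": disc.misclassification_rate,
            },
            "structure_stats.json",
        )

        stage = "gradient"
        screen = feature_position_screen(
            norm, p_threshold=config.p_threshold, r2_threshold=config.r2_threshold
        )
        save_csv(screen, "gradient_feature_screen.csv")
        cls = class_gradient_correlations(norm, level=config.class_level, alpha=config.alpha)
        save_csv(cls, "gradient_class_correlations.csv", index=False)
        long, pmat, letters = position_pair_dissimilarity(norm, alpha=config.alpha)
        save_csv(long, "position_pair_dissimilarity.csv", index=False)
        save_csv(letters.to_frame(), "position_pair_letters.csv")
        ibd, mean_adj = isolation_by_distance(norm)
        save_csv(ibd, "isolation_by_distance.csv", index=False)
        grad_stats = {
            "n_selected_features": int(screen["selected"].sum()),
            "isolation_by_distance_mean_adj_r2": mean_adj,
        }
        if config.run_position_nn:
            grad_stats["position_prediction_r2"] = position_prediction_r2(norm, seed=config.seed)
        save_json(grad_stats, "gradient_stats.json")

        stage = "mapping"
        mapping = match_reference_features(norm, norm, exact_ids=config.exact_ids)
        assignments = assign_source(
            norm, norm, mapping=mapping, fold=config.fold, alpha=config.alpha
        )
        save_csv(assignments, "source_assignments.csv")
        sums = source_sum_regression(norm, assignments)
        save_json(
            {k: v for k, v in sums.items()},
            "source_sum_regressions.json",
        )

        stage = "manifest"
        manifest = {
            "version": __version__,
            "seed": config.seed,
            "config": dataclasses.asdict(config),
            "outputs": {p.name: _sha256(p) for p in sorted(written)},
        }
        _dump_json(manifest, out / "manifest.json")
        return manifest
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
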