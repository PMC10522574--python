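"""Recovery and calibration experiments over the synthetic study.

These are the package's standing validation experiments: each one
generates synthetic studies with known ground truth, runs the relevant
analysis stage, and measures how well the truth is recovered (or, for
null calibrations, that the test rejects at its nominal rate).  They are
used by the test suite and the results-reproduction script, and are also
useful for power analysis when adapting the pipeline to new designs.

All experiments are deterministic given their seed; replicate seeds are
derived from the base seed by offset.
"""

from __future__ import annotations

import numpy as np

from .simulate import DesignSpec, EffectSpec, simulate_study
from .sourcemap import assign_source, match_reference_features, source_sum_regression
from .structure import bray_curtis, permanova
from .gradient import feature_position_screen
from .tables import normalize_total, remove_blank_features
from .variance import variance_decomposition

__all__ = [
    "variance_ordering_recovery",
    "permanova_null_calibration",
    "gradient_and_source_recovery",
    "source_assignment_accuracy",
]


def _normalized_study(seed: int, effect: EffectSpec, n_features: int):
    table = simulate_study(DesignSpec(seed=seed), effect, n_features=n_features, seed=seed)
    return normalize_total(remove_blank_features(table))


def variance_ordering_recovery(
    n_seeds: int = 50,
    effect: EffectSpec = EffectSpec(),
    n_features: int = 120,
    base_seed: int = 0,
) -> float:
    """Fraction of replicate studies whose variance decomposition recovers
    the injected scale ordering within-branch < between-branch < across-colony.

    The default effect sizes place residual (0.25) < branch (0.5) < colony
    (1.0) SDs on the log scale, so a correct decomposition should order the
    three scale means accordingly in nearly every replicate.
    """
    hits = 0
    for k in range(n_seeds):
        norm = _normalized_study(base_seed + k, effect, n_features)
        m = variance_decomposition(norm).scale_means
        hits += m["within_branch"] < m["between_branch"] < m["across_colony"]
    return hits / n_seeds


def permanova_null_calibration(
    n_runs: int = 500,
    n_samples: int = 24,
    n_groups: int = 3,
    n_permutations: int = 99,
    base_seed: int = 0,
) -> float:
    """Type-I error of the PERMANOVA under random group labels.

    A single simulated community provides the distance matrix; each run
    assigns balanced labels at random (so the null holds by construction)
    and tests at alpha = 0.05.  A calibrated test rejects in ~5% of runs.
    """
    eff = EffectSpec(n_gradient_features=0)
    norm = _normalized_study(base_seed, eff, n_features=60)
    polyp = norm.subset_role("polyp")
    ids = list(polyp.abundance.index[:n_samples])
    dist = bray_curtis(polyp).subset(ids)
    base_labels = np.repeat(np.arange(n_groups), n_samples // n_groups)
    rng = np.random.default_rng(base_seed)
    rejections = 0
    for k in range(n_runs):
        labels = rng.permutation(base_labels)
        res = permanova(dist, labels, n_permutations=n_permutations, seed=int(rng.integers(2**31)))
        rejections += res.p < 0.05
    return rejections / n_runs


def gradient_and_source_recovery(
    n_reps: int = 10,
    effect: EffectSpec = EffectSpec(),
    n_features: int = 617,
    base_seed: int = 0,
    p_threshold: float = 0.05,
    r2_threshold: float = 0.10,
) -> dict:
    """Recovery of injected within-branch gradients and their host origin.

    For each replicate study the per-feature position screen is run at the
    standard thresholds (p < 0.05, R-squared > 0.10) and the host/symbiont
    source sums are regressed on position.  Returns means over replicates:

    * ``sensitivity`` — fraction of true gradient features selected;
    * ``false_positive_rate`` — fraction of non-gradient features selected;
    * ``host_r2`` / ``symbiont_r2`` — source-sum regression R-squared;
    * ``host_exceeds_symbiont`` — fraction of replicates with host > symbiont.
    """
    sens, fps, host_r2, sym_r2, wins = [], [], [], [], []
    for k in range(n_reps):
        norm = _normalized_study(base_seed + k, effect, n_features)
        screen = feature_position_screen(norm, p_threshold, r2_threshold)
        is_grad = norm.features["true_gradient_slope"] != 0
        sens.append((screen["selected"] & is_grad).sum() / max(1, is_grad.sum()))
        fps.append((screen["selected"] & ~is_grad).sum() / max(1, (~is_grad).sum()))
        assignments = assign_source(
            norm, norm, mapping=match_reference_features(norm, norm, exact_ids=True)
        )
        sums = source_sum_regression(norm, assignments)
        host_r2.append(sums["host"]["r_squared"])
        sym_r2.append(sums["symbiont"]["r_squared"])
        wins.append(sums["host"]["r_squared"] > sums["symbiont"]["r_squared"])
    return {
        "sensitivity": float(np.mean(sens)),
        "false_positive_rate": float(np.mean(fps)),
        "host_r2": float(np.mean(host_r2)),
        "symbiont_r2": float(np.mean(sym_r2)),
        "host_exceeds_symbiont": float(np.mean(wins)),
        "n_reps": n_reps,
    }


def source_assignment_accuracy(
    n_reps: int = 3,
    effect: EffectSpec = EffectSpec(host_symbiont_fold=20.0),
    n_features: int = 300,
    base_seed: int = 0,
    fold: float = 10.0,
    alpha: float = 0.05,
) -> float:
    """Mean accuracy of the 10x + enrichment rule on true host/symbiont
    features, with 20-fold true separation in the reference samples."""
    accs = []
    for k in range(n_reps):
        norm = _normalized_study(base_seed + k, effect, n_features)
        assignments = assign_source(
            norm,
            norm,
            mapping=match_reference_features(norm, norm, exact_ids=True),
            fold=fold,
            alpha=alpha,
        )
        truth = norm.features["true_source"]
        mask = truth.isin(["host", "symbiont"])
        accs.append((assignments.loc[mask[mask].index, "source"] == truth[mask]).mean())
    return float(np.mean(accs))
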