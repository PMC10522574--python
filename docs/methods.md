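# Methods

This note documents the models and procedures implemented in `holopolyp`,
the defaults they ship with, and the limits of what the synthetic-data
experiments can show.

## The study design being modeled

The sampling campaign the package targets collects single-polyp biopsies
from branching corals in a three-level hierarchy: colonies (genotypes),
branches within a colony, and six polyps per branch at defined distances
from the branch base. Polyp 1 sits 10 mm above the base; polyps 2 and 3
are the next consecutive corallites (default 1 mm apart — corallite pitch
is configurable since it varies between species); polyp 4 is placed ¼ of
the way from polyp 3 to the branch tip, polyp 5 halfway, and polyp 6 at
the tip. Branch lengths are drawn uniformly from 80–150 mm per branch;
draws shorter than the polyp-3 position are rejected and redrawn. At the
default 19 × 3 × 6 design this yields 342 polyp samples on 57 branches.

Alongside the polyps the design carries three extraction blanks (reagents
only), four bleached-coral reference samples (host tissue without algal
symbionts) and four algal-pellet references (purified symbionts). Four
reference samples per side is the minimum at which a two-group
Kruskal–Wallis test can reach p < 0.05 under complete separation, which
the 10× source rule requires.

## Abundance model

Peak areas are log-normal with additive effects on the log scale:

    log I(s, f) = μ + C(c(s), f) + B(b(s), f) + β(f)·x(s) + ε(s, f)

with colony effects C ~ N(0, σ_colony²), branch effects B ~ N(0,
σ_branch²), residual polyp noise ε ~ N(0, σ_res²), and x(s) the polyp's
distance from the branch base in mm. Defaults: μ = 13 (peak areas ≈ 4×10⁵,
a mid-range Orbitrap intensity), σ_colony = 1.0 > σ_branch = 0.5 > σ_res =
0.25, matching the empirical hierarchy in which colony signatures dominate,
branches are distinguishable within colonies, and neighboring polyps are
most similar. A log-normal was chosen because LC-MS peak areas are positive
and right-skewed. An optional per-feature baseline spread
(`feature_log_sd`, default 0) can emulate the instrument's dynamic range;
it is off by default to keep the model exactly as stated above.

Exactly `n_gradient_features` features (default 7) carry a nonzero slope
β = 0.015 log-units/mm, all drawn from the host pool. The slope was sized
analytically so that a gradient feature explains roughly 20% of pooled
between-sample variance against the combined colony+branch+residual noise
(variance ≈ 1.31) over the ~10–115 mm position range (position SD ≈ 38 mm):
β ≈ sqrt(0.25·1.31)/38 ≈ 0.015. The measured screen-scale R² at this slope
averages ≈ 0.18.

Feature pools: 40% host, 30% symbiont, 10% contaminant, remainder shared.
Contaminant features carry no colony/branch/gradient structure — they are
technical, not biological — and appear in blanks at sample-like intensity,
so the 3× blank filter removes essentially all of them while biological
features (absent from blanks) always survive. Bleached-coral references
express host + shared (+ contaminant) features at full level and the
symbiont pool at 1/`host_symbiont_fold` (default 1/20); algal pellets are
the mirror image. Modeling the suppressed pool as low-level bleed rather
than strictly absent keeps the reference fold change equal to
`host_symbiont_fold` in expectation (real bleached tissue retains residual
symbiont metabolites) and gives the 10× rule a defined fold to test.

The default catalog size is 617 features so that blank filtering leaves
≈ 555 biological features — the scale of the real single-polyp dataset.
This matters beyond fidelity: with TIC normalization, growth of the
gradient features mechanically depresses every other feature's relative
abundance (compositional closure). At 555 features the 7 gradient features
hold ~1.3% of total abundance and the closure artifact is small; with many
fewer features it would dominate the within-branch signal.

## Preprocessing

A feature is retained iff its mean abundance over polyp samples is at
least `ratio` (default 3) times its mean over blank samples. The boundary
is inclusive (≥ 3× is kept); features never seen in a blank are always
kept; reference samples do not enter either mean. Both the ≥ 3× rule and a
strict absent-in-blank criterion are available (`ratio=inf` is equivalent
to the latter). Zeros mean non-detection; no imputation is performed.
Normalization divides each sample by its total, so every row sums to 1;
it is idempotent and rank-preserving within samples.

## Statistics

* **Diversity.** Richness counts features with abundance > 0 (no minimum
  floor). Entropy is Shannon's H in nats over renormalized nonzero
  relative abundances (base configurable). ANOVAs are one-way
  fixed-effects; the branch-within-colony factor runs one ANOVA per colony
  and summarizes how many colonies reject at α = 0.05.
* **Variance decomposition.** Per feature: SD over the polyps of each
  branch averaged over branches (within); SD of branch-mean profiles within
  each colony averaged over colonies (between); SD of colony means
  (across). Group-centroid aggregation is the default because "between
  branches" most naturally means dispersion of branch-level centroids; a
  pooled alternative (SD over all samples of the grouping) is provided.
  Sample SDs use the n−1 denominator; both mean SDs and mean variances are
  reported since either transform may be quoted. This is a descriptive
  decomposition, not REML variance-component estimation.
* **PERMANOVA.** Pseudo-F from the classic distance partition
  (SS_total = Σd²/N; SS_within from within-group squared distances divided
  by group size), p = (1 + #{F* ≥ F})/(1 + n_permutations) under label
  permutation with a logged seed; 999 permutations by default. The
  two-factor variant partitions the Gower-centered inner-product matrix
  with sequential (Type-I) hat-matrix traces, so the second factor is
  assessed after the first; identical partitions are rejected as
  confounded. Polyp location is treated as a categorical factor (polyp
  number); continuous position is available through the regression tools.
* **Discriminant analysis.** Feature tables are wide (features ≫ samples),
  so samples are first projected onto principal components retaining 95%
  of variance (configurable) and a linear discriminant is fit on those
  scores. Misclassification is reported as resubstitution (training-set)
  rate by default — mirroring how such figures are usually quoted — with a
  stratified cross-validated mode as the honest generalization estimate.
* **Gradient screen.** Ordinary least squares of each feature's relative
  abundance on absolute position in mm, pooling polyps across branches and
  colonies; selection requires p < 0.05 and R² > 0.10. Selection is
  monotone in both thresholds. Per-branch normalized position (fraction of
  branch length) is available since branch lengths differ.
* **Class correlations.** Class-summed relative abundances vs position,
  Pearson r, Bonferroni over the number of classes tested (adjusted
  p = min(1, m·p)), significance at adjusted p < 0.05, sign reported.
* **Position-pair dissimilarity.** Same-branch Bray–Curtis values grouped
  by unordered polyp-number pair; pairwise two-sample Kruskal–Wallis at
  α = 0.05 (a quoted "α = 0.95" in this context is read as 95% confidence);
  compact letters via the insert-and-absorb algorithm with alphabetical
  tie-breaking.
* **Isolation by distance.** Within each branch, all 15 polyp pairs
  contribute (|Δposition|, Bray–Curtis) points; adjusted R² per branch and
  the mean over branches are reported. Branches with < 3 polyps are
  skipped.
* **Position prediction.** A single-hidden-layer (32-unit) feed-forward
  regressor on standardized relative abundances; R² from pooled
  out-of-fold predictions over a seeded 5-fold split (resubstitution mode
  available). 2000 optimizer iterations by default — small sample sizes
  need the extra iterations to converge.
* **Source mapping.** Polyp features are matched to reference features
  within 10 ppm m/z and 0.1 min RT, nearest-by-|ppm| winning ties
  (synthetic tables can match by identical IDs). A matched feature is
  *host* if mean(bleached) ≥ 10 × mean(algal) with Kruskal–Wallis p < 0.05
  across the two reference groups, *symbiont* under the mirrored rule,
  otherwise *shared*; unmatched features are *unassigned*. A zero mean on
  either side is replaced by half the smallest nonzero mean on that side
  before the fold is formed, avoiding infinite folds. Means are the
  default aggregate (medians available); Mann–Whitney is offered as the
  two-group equivalent of Kruskal–Wallis. Assignment is antisymmetric
  under swapping the reference sets, and raising the fold threshold never
  converts a shared feature into host/symbiont.

## Validation experiments and their problem sizes

`holopolyp.evaluation` holds the standing recovery/calibration
experiments, which the test suite asserts and `scripts/acceptance.py`
reports:

* variance scale-ordering recovery over 50 replicate studies (full
  19 × 3 × 6 design, 120 features — the ordering statistic is a mean over
  features and stabilizes well below the full catalog size);
* PERMANOVA type-I error over 500 random-label runs (24 samples, 3 groups,
  99 permutations each);
* gradient-screen sensitivity/false positives and the host vs symbiont
  source-sum contrast, as means over 10 replicate full-design studies at
  the 617-feature catalog; single-replicate sensitivity fluctuates with the
  realized colony-effect draws, so the replicate mean is the stable
  summary;
* source-assignment accuracy over 3 replicate studies at 300 features with
  20-fold true separation.

## What the synthetic experiments do and do not show

The generator reproduces the design geometry, the organizational variance
hierarchy, blank-borne contamination, host/symbiont reference contrast,
and host-borne position gradients — enough to verify that every analysis
stage recovers what was injected. It deliberately omits: correlated
features (real metabolites co-vary within pathways, so real source sums
carry far more biological variance than sums of independent features —
which is why the simulated symbiont-sum R² reflects only compositional
closure), retention-time drift and batch effects, missing-value structure
from peak picking, heavy-tailed intensity distributions (unless
`feature_log_sd` is enabled), and any MS/MS-level information (matching is
by m/z + RT, not spectral networking). Passing recovery tests therefore
demonstrates correctness of the statistical machinery under the stated
model, not robustness to every artifact of real LC-MS data.

Isolation-by-distance deserves a caveat: with independent equal-baseline
features, within-branch Bray–Curtis values are extremely stable, so even
the modest injected gradients produce large per-branch adjusted R² values.
Real data, with its much noisier dissimilarities, yields far smaller
values; the simulated quantity is a monotonicity check, not a calibrated
mirror of the real-data statistic.

## Numerical choices and degenerate inputs

Inclusive boundary on the 3× blank rule; all-equal ANOVA inputs return
F = 0, p = 1, and zero-within-variance separated groups return F = ∞,
p = 0; Kruskal–Wallis on all-identical values returns p = 1; constant
class sums correlate at r = 0, p = 1; OLS requires ≥ 3 observations and a
non-constant predictor; Bray–Curtis rejects all-zero samples; PCA axes
beyond rank are truncated with a warning; the PERMANOVA p value never
falls below 1/(n_permutations + 1). All simulation randomness flows from a
single integer seed through one generator instance, so identical
(spec, seed) pairs are bit-identical.
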