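# Methods

This note records the models implemented in `metaconn`, the defaults and
why they were chosen, what the synthetic generator does and does not
emulate, and the numerical conventions that matter for reproducibility.

## Connectivity estimation

**Static FC** is the pairwise Pearson correlation over the full record.
**dFC stream**: windows of `window_seconds` (default 20 s, converted to
frames by `round(w / TR)`) stepped by `step_frames` (default 2 TR). Frame
count follows `F = floor((T − w)/Δτ) + 1`; a single-frame stream is legal
(it equals the static FC) but meta-connectivity requires at least 3
frames. Each frame is stored in *vector format*: the `L = N(N−1)/2` unique
link values in the canonical order `(i, j), i < j`, lexicographic (the
order of `numpy.triu_indices`). Every array in the package — masks, graph
nodes, CPM features — indexes links by this one convention.

**Meta-connectivity** is the Pearson correlation between link time courses
across frames, kept as a compact `L × L` matrix. The redundant directed-pair
expansion (`M = N(N−1)`; 600 × 600 at N = 25) exists for reporting only:
each unique value occupies all four orientation combinations and their
transposes.

Zero-variance signals (constant ROI in a window, constant link course)
produce a correlation of **0 with a warning**, never NaN, so downstream
matrices stay valid. Constancy is detected with a relative tolerance
(`sd ≤ 1e−12 · max(1, |x|max)`) because the standard deviation of a
constant float column is rounding noise, not exactly zero.

**Significance mask.** Per unique entry, a one-sample t-test across
subjects against zero — on Fisher-z transformed values by default, which
stabilizes the variance of correlation estimates (a `fisher_z=False` knob
exists). Benjamini–Hochberg FDR at level `q` (default 0.05) runs over the
`L(L−1)/2` unique entries, and an entry must additionally pass the raw
threshold `alpha` (default 0.01). Note that under a *global* null BH
rejects almost nothing (the expected rejected fraction is near zero, not
`q`); the test suite asserts that correct calibration property.

**SSIM.** The default `global` mode computes the similarity from
whole-matrix means, variances and covariance with `C1 = (0.01R)²`,
`C2 = (0.03R)²`, `R` the dynamic range of the first argument (floor 1.0
when the matrix is constant). Windowed SSIM collapses inside flat blocks of
piecewise-constant matrices, which is exactly the structure of interest
here, so the global statistic is the default; a 7×7 uniform-window mode is
available for image-like comparisons.

## Synthetic cohorts

The generator emulates the phenomenon the pipeline is designed to detect:
**meta-modules**, groups of links whose coupling strengths co-fluctuate.

Mechanism. Each module `k` owns a slow latent `u_k(t)` (random-phase
sinusoid plus AR(1), unit variance, timescale `modulator_timescale`,
default 45 s). A link in module `k` mixes the shared latent with an
idiosyncratic one, `m_ℓ = √s·u_k + √(1−s)·ξ_ℓ`, where the share is
`s = min(0.98, 1.15 · within_strength)`. Instantaneous coupling is
`ρ_ℓ(t) = 0.3 + 0.65·tanh(3 m_ℓ(t))` — a near-bistable gate that keeps
correlations in (−0.35, 0.95) and mimics switching between high- and
low-coupling FC states. Between-module co-fluctuation is planted by
correlating module latents through a global component with weight
`between_strength / within_strength`. Samples are drawn per timepoint from
the nearest valid correlation matrix (eigenvalue clipping + diagonal
renormalization, then Cholesky), so the process is exactly consistent;
i.i.d. Gaussian measurement noise (`noise_sd`, default 0.2) is added on
top. `within_strength = between_strength = 0` means *no structure at all*:
independent ROI signals plus noise (a flat nonzero base correlation would
itself induce a common-factor MC floor).

Default module layout: ROIs are partitioned into `n_modules` contiguous
groups; within-group links form the modules and cross-group links are
unmodulated background. This community layout is exactly realizable as a
correlation process — an arbitrary link→module map with large planted
couplings generally is not (positive semi-definiteness couples the links),
and would be silently damped by the PSD projection.

**Calibration and honesty about magnitudes.** The realized within-module
MC is an *attenuated monotone transform* of `within_strength`: windowed
correlation estimates carry irreducible estimation noise (≈ (1−ρ²)/√(w−1)
per window) and the tanh gate compresses latent correlations. At the
default settings (20 s window, TR 2 s, 600 frames) a target of 0.8
realizes ≈ 0.6 and a target of 0.6 realizes ≈ 0.45, with between-module
MC ≈ 0. The constants (base 0.3, amplitude 0.65, saturation 3.0, share
gain 1.15) were fixed once, against the package's own estimator, to make
the planted contrast strong, monotone in the target, and near-zero under
the null. Tests therefore assert contrasts and orderings, not absolute MC
values.

Cohorts: the case group is generated at `within_strength`, controls at
`within_strength − group_effect`. Subjects are assigned round-robin to
sites; the second half of the sites receives an additive common nuisance
*signal* of amplitude `site_shift` (a constant offset would be invisible
to every correlation-based feature) and a global gain `site_scale`. Ages
are uniform on 6–40 years, sex is drawn 80/20 M/F — covariates, not
effects. Behavioral scores are linear in selected vectorized-MC features
plus Gaussian noise. Every subject draws from an independently spawned
random stream, so per-subject options never perturb other subjects.

What the generator does **not** emulate: hemodynamics, spatial smoothness,
head motion, physiological confounds, scanner drift beyond the single
nuisance signal, or heavy-tailed noise. Passing tests demonstrate that the
estimators and models recover structure of this planted form; they do not
certify performance on real multi-site data.

## Harmonization

Standard parametric ComBat: `y = α + Xβ + γ_site + δ_site·ε`. Features are
standardized by the covariate fit and pooled variance; per-site additive
effects shrink toward a normal prior and variance ratios toward an
inverse-gamma prior via method-of-moments empirical Bayes with iterative
conditional updates (tolerance 1e−4). Covariates are centered so the site
intercepts absorb the grand mean. A single-site fit is flagged as identity.
`combat_apply` refuses sites unseen at fit time; under leave-one-site-out
the evaluation layer therefore harmonizes the training sites and passes the
held-out site through untouched — the benefit comes from a cleaner training
set, and no information flows from test to train. Within any CV fold the
model is fit on training subjects only.

## Link graphs and the attention classifier

Nodes are the `L` unique links; an edge joins links `a, b` when the group
mask is true **and** `|MC[a,b]| ≥ edge_threshold` (default 0.1; experiments
in this repository use 0.25, which prunes the near-threshold bulk and cuts
training cost several-fold without hurting accuracy). Node features default
to the mean and SD of the link's dFC course (strength and volatility; the
masked MC row can be appended via `include_mc_row`); the edge feature is
the signed MC value. Depth-`d` neighborhood balls use a depth-limited DFS
that re-expands nodes reached with a larger remaining budget, making the
result identical to BFS hop distance.

The classifier applies bias-free linear transforms to node and edge
features, then per-node softmax attention with LeakyReLU scoring (negative
slope 0.2, a standard choice). The edge-attention score applies both
learnable vectors to the candidate edge's own transformed feature while
normalizing over all incident edges — implemented exactly as specified for
this architecture, although the destination term is plausibly intended to
vary with the competitor edge. Receptive field depth `d` (default 3) is
realized as `d` stacked node-attention layers, whose reach is exactly the
depth-`d` ball. Incident edge features are attention-aggregated per node,
concatenated with the final node representation, mixed by one linear
layer, mean-pooled over nodes, and classified by a two-layer MLP (ReLU,
dropout 0.2). Isolated nodes bypass attention and contribute a zero edge
summary. Hidden sizes (node/edge 32, final 64, MLP 32) are configurable;
the tests use 16/16/32/16.

Training: label smoothing `y(1−α) + α/K` with α = 0.1, cross-entropy with
a probability floor of 1e−12, an explicit `β‖W‖²` penalty (β = 1e−4) on
all linear-layer weight matrices (not biases or attention vectors), Adam
(0.9/0.999/1e−8). The literature defaults (learning rate 1e−4, batch 64,
100 epochs) are tuned for cohorts of ~1500 subjects; at desk scale a
30-subject cohort yields two optimizer steps per epoch and the prescribed
budget moves parameters by ~2% of their initialization scale, so the
package's experiments use learning rate 1e−3 with 100–150 epochs. All
randomness (init, shuffling, dropout) flows from one seeded generator;
fits are bitwise reproducible on one thread. Argmax ties resolve to class
0. The entire network — forward, analytic backward (verified against
numerical gradients to ~1e−10), Adam — is self-contained NumPy; message
passing uses CSR matrix products and `reduceat` segment reductions.

Ablations: uniform neighbor averaging (no attention), single linear
readout (no MLP), no significance filtering (all-true mask), no label
smoothing — all run on identical splits and seeds.

## Evaluation protocol

Stratified k-fold (stratification stabilizes small folds), stratified
holdout, or leave-one-site-out. Per fold, harmonization, the significance
mask, and the classifier are fit on training subjects only and frozen;
per-subject MC matrices are subject-local, so computing them once is
leakage-free. Metrics: accuracy, balanced accuracy, precision, recall, F1,
and AUC by the rank (Mann–Whitney) formulation; single-class test sets
report AUC as missing.

## Subtyping (rough fuzzy c-means)

Fuzzy memberships `μ_ij = 1/Σ_k (d_ij/d_kj)^{2/(m−1)}` with m = 2,
tolerance 0.005 (max |Δμ|), ≤ 1000 iterations, seeded k-means++
initialization, Euclidean distances. Rough regions: **core** (lower
approximation) μ ≥ 0.6, **boundary** 0.3 ≤ μ < 0.6; subjects below 0.3
everywhere join the boundary of their argmax cluster so every subject lies
in at least one upper approximation. Centroids combine the μ^m-weighted
core and boundary means with `w_low = 0.75` on the definite region; an
empty cluster is re-seeded from the farthest point. Cluster count is
chosen by the elbow of the dispersion curve `J(c) = Σ μ^m d²` — the
maximum second difference of **log J**, because raw-J curvature is
dominated by the largest absolute drop and systematically picks c = 2 on
well-separated data regardless of truth. Validity: silhouette and
Davies–Bouldin via scikit-learn (singleton-cluster silhouette is 0 by
convention; identical centroids flag a divergent DBI), Dunn index
(min inter-cluster point distance / max intra-cluster diameter) computed
directly.

## Severity prediction (CPM)

Training-set screening keeps features with `|r|` **strictly greater** than
`r_threshold` (0.4) and `p < 0.05`; the sign routes each edge to the
positive or negative network. Pearson is the default association
(Spearman and Huber-robust regression are available). Each subject's MC
values are summed per network and scores are fit by least squares on
`[1, pos_sum, neg_sum]` (a classic single-sum mode exists); a degenerate
summary column is dropped with a warning, and an empty selection
degenerates to the intercept (mean-score) model. Evaluation reports
Pearson r (missing for constant predictions) and RMSE. Test subjects never
influence selection or coefficients.

## Problem sizes

The suite and acceptance script run at desk scale, chosen to finish on one
CPU in minutes while leaving comfortable statistical margins: unit tests
use 6–10 ROIs and 200–600 frames; the cohort-recovery experiment uses 120
subjects × 25 ROIs × 600 frames (TR 2 s — the length of a concatenated
multi-run session); the robustness simulation uses the full 300-link block
matrix with 20 replicates per noise level.

## Known limitations

* The generator's realized MC magnitudes are attenuated relative to their
  targets (quantified above); only contrasts are calibrated.
* Edge-attention as printed scores each edge independently of its
  competitors' destination terms, so its softmax mainly re-weights by edge
  salience within a neighborhood.
* ComBat assumes features are Gaussian given site and covariates; MC
  entries near ±1 violate this mildly (Fisher-z is applied only in the
  significance mask, not before harmonization).
* RFCM follows the standard rough-fuzzy centroid scheme; other variants
  (e.g. possibilistic hybrids) are out of scope.
* No multi-head attention, GPU support, or baseline model zoo.
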