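# metaconn

Edge-centric **meta-connectivity** analysis of fMRI ROI time series, with a
node–edge attention graph classifier, multi-site harmonization, fuzzy
subtyping, and connectome-based severity prediction.

## The problem

Static functional connectivity (FC) — the Pearson correlation between two
regions' BOLD signals — discards how coupling strengths wax and wane over a
scan. Sliding-window dynamic FC (dFC) recovers that temporal dimension, and
*meta-connectivity* (MC) goes one step further: it treats every FC **link**
as a dynamic variable and correlates link time courses with each other. The
result is a link-by-link matrix whose block structure reveals *meta-modules*
— sets of connections that co-fluctuate — a higher-order signature that has
been used to separate clinical groups (e.g. autistic vs. typically
developing cohorts) where static FC fails.

`metaconn` implements that full analysis chain for small ROI sets (the
packaged atlas covers 25 regions of the salience, default-mode,
central-executive and theory-of-mind networks):

1. **Connectivity** — FC `FC_ij = corr(TS_i, TS_j)`; a windowed dFC stream
   `FC_ij(t_k)` over windows of `w` seconds stepped by `Δτ` frames (defaults
   20 s / 2 TR); meta-connectivity
   `MC_(ij),(kl) = corr(FC_ij(·), FC_kl(·))` stored compactly over the
   `L = N(N−1)/2` unique links, with the redundant `N(N−1) × N(N−1)`
   directed-pair expansion available (600 × 600 for 25 ROIs).
2. **Group statistics** — per-entry one-sample t-tests (Fisher-z) with
   Benjamini–Hochberg FDR to mask unreliable meta-links, plus Pearson/SSIM
   noise-robustness diagnostics.
3. **Harmonization** — ComBat-style empirical-Bayes removal of per-site
   location/scale effects from vectorized MC features.
4. **Classification** — each subject's masked MC becomes a *link graph*
   (nodes = FC links, edges = significant meta-links); a NumPy
   implementation of a graph attention network with explicit edge features
   (separate node/edge transforms, dual softmax attention, depth-`d`
   stacked layers, mean readout, label-smoothed cross-entropy + L2, Adam)
   classifies subjects. Cross-validation, leave-one-site-out, and an
   ablation suite are built in.
5. **Subtyping** — rough fuzzy c-means over MC features with lower/upper
   cluster approximations, elbow-based cluster-count selection, and
   silhouette / Davies–Bouldin / Dunn validity indices.
6. **Severity prediction** — connectome-based predictive modeling (CPM):
   screen MC entries by correlation with a behavioral score (|r| > 0.4,
   p < 0.05), sum the positive and negative networks, fit a linear model.
7. **Synthetic cohorts** — a generator that plants meta-module structure
   (slow latent modulators gating link couplings), group contrasts, site
   effects and linearly tied behavioral scores, so the entire chain is
   testable without any imaging data.

## Worked example

```python
from metaconn.synthetic import CohortSpec, gen_cohort
from metaconn.evaluation import PipelineConfig, make_splits, run_protocol
from metaconn.negat import NEGATConfig

spec = CohortSpec(n_subjects_per_group=15, n_rois=10, n_timepoints=400,
                  within_strength=0.9, group_effect=0.35, n_modules=2, seed=11)
ts_list, pheno = gen_cohort(spec)

cfg = PipelineConfig(edge_threshold=0.25,
                     negat=NEGATConfig(learning_rate=1e-3, epochs=150,
                                       node_hidden=16, edge_hidden=16,
                                       final_hidden=32, mlp_hidden=16))
plan = make_splits(pheno, "kfold", k=5, seed=0)
report = run_protocol(ts_list, pheno, plan, cfg)
print(report.summary().round(3))
```

Output:

```
                    mean     sd
accuracy           0.967  0.075
balanced_accuracy  0.967  0.075
precision          0.950  0.112
recall             1.000  0.000
f1                 0.971  0.064
auc                1.000  0.000
```

The cohort plants a within-meta-module MC contrast between the groups
(targets 0.9 vs. 0.55); with 30 subjects and 10 ROIs the attention
classifier separates the groups almost perfectly across the five folds
(one subject is misclassified in one fold). Setting `group_effect=0`
yields chance-level accuracy (≈ 0.5), confirming the pipeline carries no
leakage.

A thin CLI covers the common entry points:

```bash
metaconn simulate --config cohort.yaml --out cohort/
metaconn mc cohort/ mc_out/
metaconn mask mc_out/ mask.npz
metaconn evaluate cohort/ results.csv --scheme kfold --k 5
```

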