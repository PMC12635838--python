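"""Cross-validation schemes, metrics, the full classification pipeline,
and the ablation suite.

``run_protocol`` wires the whole chain per fold with no leakage: MC
features are computed once per subject (they depend on that subject only),
but harmonization, the group significance mask and the classifier are fit
on training subjects exclusively and then frozen for the test subjects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn import metrics as skmetrics
from sklearn.model_selection import StratifiedKFold, train_test_split

from . import negat
from .combat import combat_apply, combat_fit
from .connectivity import (
    MCMatrix,
    compute_dfc_stream,
    compute_mc,
    significance_mask,
)
from .linkgraph import build_link_graph
from .negat import NEGATConfig

__all__ = [
    "SplitPlan",
    "MetricsReport",
    "PipelineConfig",
    "make_splits",
    "classification_metrics",
    "compute_subject_features",
    "run_protocol",
    "ablation_suite",
]

GROUP_LABELS = {"control": 0, "case": 1}


@dataclass
class SplitPlan:
    scheme: str
    folds: list[tuple[np.ndarray, np.ndarray]]
    fold_names: list[str]
    seed: int


@dataclass
class MetricsReport:
    per_fold: pd.DataFrame

    def summary(self) -> pd.DataFrame:
        numeric = self.per_fold.drop(columns=["fold"])
        return pd.DataFrame({"mean": numeric.mean(), "sd": numeric.std()})

    def mean(self, metric: str) -> float:
        return float(self.per_fold[metric].mean())


@dataclass
class PipelineConfig:
    window_seconds: float = 20.0
    step_frames: int = 2
    alpha: float = 0.01
    q: float = 0.05
    edge_threshold: float = 0.1
    harmonize: bool = False
    significance_filtering: bool = True
    include_mc_row: bool = False
    negat: NEGATConfig = field(default_factory=NEGATConfig)


def make_splits(pheno: pd.DataFrame, scheme: str = "kfold", k: int = 5,
                seed: int = 0, test_fraction: float = 0.2) -> SplitPlan:
    """Stratified k-fold, stratified holdout, or leave-one-site-out folds."""
    y = pheno["group"].to_numpy()
    idx = np.arange(len(pheno))
    folds: list[tuple[np.ndarray, np.ndarray]] = []
    names: list[str] = []
    if scheme == "kfold":
        if k < 2:
            raise ValueError("k must be >= 2")
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        for f, (tr, te) in enumerate(skf.split(idx, y)):
            folds.append((tr, te))
            names.append(f"fold{f}")
    elif scheme == "holdout":
        tr, te = train_test_split(
            idx, test_size=test_fraction, stratify=y, random_state=seed
        )
        folds.append((np.sort(tr), np.sort(te)))
        names.append("holdout")
    elif scheme == "leave_one_site_out":
        sites = pheno["site_id"].to_numpy()
        roster = sorted(set(sites.tolist()))
        if len(roster) < 2:
            raise ValueError("leave-one-site-out needs >= 2 sites")
        for s in roster:
            te = idx[sites == s]
            if len(set(y[te].tolist())) < 2:
                warnings.warn(f"site {s} holds a single class; kept as test-only fold")
            folds.append((idx[sites != s], te))
            names.append(s)
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    return SplitPlan(scheme=scheme, folds=folds, fold_names=names, seed=seed)


def classification_metrics(y_true, y_pred, y_prob=None) -> dict[str, float]:
    """Accuracy, balanced accuracy, precision, recall, F1 and rank AUC."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("length mismatch")
    out = {
        "accuracy": float(skmetrics.accuracy_score(y_true, y_pred)),
        "balanced_accuracy": float(skmetrics.balanced_accuracy_score(y_true, y_pred)),
        "precision": float(skmetrics.precision_score(y_true, y_pred, zero_division=0)),
        "recall": float(skmetrics.recall_score(y_true, y_pred, zero_division=0)),
        "f1": float(skmetrics.f1_score(y_true, y_pred, zero_division=0)),
    }
    if y_prob is not None and len(set(y_true.tolist())) == 2:
        out["auc"] = float(skmetrics.roc_auc_score(y_true, np.asarray(y_prob)))
    else:
        out["auc"] = float("nan")
    return out


def compute_subject_features(ts_list, config: PipelineConfig | None = None):
    """Per-subject (dFC stream, MC matrix) pairs; subject-local, fold-safe."""
    cfg = config or PipelineConfig()
    out = []
    for ts in ts_list:
        stream = compute_dfc_stream(ts, cfg.window_seconds, cfg.step_frames)
        out.append((stream, compute_mc(stream)))
    return out


def _mc_feature_matrix(mcs: list[MCMatrix]) -> np.ndarray:
    iu = np.triu_indices(mcs[0].n_links, k=1)
    return np.stack([m.compact[iu] for m in mcs])


def _rebuild_mcs(features: np.ndarray, template: list[MCMatrix]) -> list[MCMatrix]:
    l = template[0].n_links
    iu = np.triu_indices(l, k=1)
    out = []
    for row, t in zip(features, template):
        m = np.eye(l)
        m[iu] = row
        m.T[iu] = row
        out.append(MCMatrix(compact=np.clip(m, -1, 1), link_index=t.link_index))
    return out


def run_protocol(ts_list, pheno: pd.DataFrame, plan: SplitPlan,
                 config: PipelineConfig | None = None,
                 features=None) -> MetricsReport:
    """Train/evaluate the link-graph classifier under a split plan.

    ``features`` may carry precomputed ``compute_subject_features`` output
    (subject-local, so sharing it across folds leaks nothing).
    """
    cfg = config or PipelineConfig()
    if features is None:
        features = compute_subject_features(ts_list, cfg)
    streams = [f[0] for f in features]
    mcs = [f[1] for f in features]
    y = pheno["group"].map(GROUP_LABELS).to_numpy()
    sites = pheno["site_id"].to_numpy()
    feat = _mc_feature_matrix(mcs)
    rows = []
    for name, (tr, te) in zip(plan.fold_names, plan.folds):
        if len(set(y[tr].tolist())) < 2:
            warnings.warn(f"fold {name}: training set has a single class; skipped")
            continue
        work = feat
        if cfg.harmonize and len(set(sites[tr].tolist())) >= 2:
            model = combat_fit(feat[tr], sites[tr])
            # subjects from sites unseen at fit time (the held-out site under
            # leave-one-site-out) pass through unchanged: the model refuses to
            # guess effects for sites it never saw, but the classifier still
            # benefits from a harmonized training set
            seen = np.isin(sites, model.sites)
            work = feat.copy()
            work[seen] = combat_apply(feat[seen], model, sites[seen])
        fold_mcs = _rebuild_mcs(work, mcs)
        if cfg.significance_filtering:
            mask = significance_mask([fold_mcs[i] for i in tr], cfg.alpha, cfg.q)
        else:
            mask = significance_mask([fold_mcs[i] for i in tr], alpha=1.0 + 1e-9, q=1.0)
            mask.values[:] = True
        graphs = [
            build_link_graph(
                fold_mcs[i], streams[i], mask, cfg.edge_threshold,
                cfg.include_mc_row, subject_id=str(pheno["subject_id"].iloc[i]),
                label=int(y[i]),
            )
            for i in range(len(ts_list))
        ]
        params, _ = negat.fit([graphs[i] for i in tr], y[tr], cfg.negat)
        preds = negat.predict([graphs[i] for i in te], params, cfg.negat)
        y_pred = np.array([p.label for p in preds])
        y_prob = np.array([p.probabilities[1] for p in preds])
        m = classification_metrics(y[te], y_pred, y_prob)
        m["fold"] = name
        rows.append(m)
    if not rows:
        raise ValueError("no usable folds")
    return MetricsReport(per_fold=pd.DataFrame(rows))


ABLATIONS = ("full", "no_attention", "no_mlp", "no_filtering", "no_label_smoothing")


def ablation_suite(ts_list, pheno: pd.DataFrame, plan: SplitPlan,
                   config: PipelineConfig | None = None,
                   variants=ABLATIONS, features=None) -> dict[str, MetricsReport]:
    """The model-component ablations, on identical splits and seeds."""
    cfg = config or PipelineConfig()
    if features is None:
        features = compute_subject_features(ts_list, cfg)
    out = {}
    for variant in variants:
        vcfg = replace(cfg, negat=replace(cfg.negat))
        if variant == "no_attention":
            vcfg.negat.attention = False
        elif variant == "no_mlp":
            vcfg.negat.mlp_head = False
        elif variant == "no_filtering":
            vcfg.significance_filtering = False
        elif variant == "no_label_smoothing":
            vcfg.negat.label_smoothing = 0.0
        elif variant != "full":
            raise ValueError(f"unknown ablation {variant!r}")
        out[variant] = run_protocol(ts_list, pheno, plan, vcfg, features=features)
    return out
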