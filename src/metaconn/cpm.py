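"""Connectome-based predictive modeling of symptom severity from MC features.

Classic CPM screening applied to edge-centric features: each vectorized MC
entry is correlated with the behavioral score across training subjects;
entries whose correlation magnitude strictly exceeds ``r_threshold`` at
``p < p_threshold`` form a positive and a negative edge set.  Each
subject's MC values are summed over both sets and a linear model
score ~ intercept + b1 * pos_sum + b2 * neg_sum is fit by least squares.
Test subjects never influence the edge sets or the coefficients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "CPMConfig",
    "CPMModel",
    "select_edges",
    "summarize_subject",
    "fit_cpm",
    "predict_scores",
    "evaluate_prediction",
]


@dataclass
class CPMConfig:
    correlation_method: str = "pearson"   # pearson | spearman | robust
    r_threshold: float = 0.4
    p_threshold: float = 0.05
    summary_mode: str = "separate_pos_neg"  # or "combined"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.r_threshold < 1:
            raise ValueError("r_threshold must be in (0, 1)")
        if not 0 < self.p_threshold < 1:
            raise ValueError("p_threshold must be in (0, 1)")
        if self.correlation_method not in ("pearson", "spearman", "robust"):
            raise ValueError(f"unknown correlation method {self.correlation_method!r}")
        if self.summary_mode not in ("separate_pos_neg", "combined"):
            raise ValueError(f"unknown summary mode {self.summary_mode!r}")


@dataclass
class CPMModel:
    positive_edges: np.ndarray
    negative_edges: np.ndarray
    coefficients: np.ndarray       # intercept first
    summary_mode: str
    edge_r: np.ndarray = field(default=None, repr=False)
    edge_p: np.ndarray = field(default=None, repr=False)
    train_r: float = float("nan")


def _edge_correlations(features: np.ndarray, scores: np.ndarray, method: str):
    n = len(scores)
    if method == "spearman":
        features = stats.rankdata(features, axis=0)
        scores = stats.rankdata(scores)
    if method in ("pearson", "spearman"):
        fc = features - features.mean(axis=0)
        sc = scores - scores.mean()
        denom = np.sqrt((fc**2).sum(axis=0) * (sc**2).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(denom > 0, fc.T @ sc / np.where(denom > 0, denom, 1.0), 0.0)
        r = np.clip(r, -1.0, 1.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = r * np.sqrt((n - 2) / np.maximum(1 - r**2, 1e-300))
        p = 2 * stats.t.sf(np.abs(t), df=n - 2)
        p = np.where(np.abs(r) >= 1.0, 0.0, p)
        return r, p
    # robust: iteratively reweighted (Huber) simple regression per edge,
    # expressed as a correlation through the standardized slope
    import statsmodels.api as sm

    r = np.empty(features.shape[1])
    p = np.empty(features.shape[1])
    z = (scores - scores.mean()) / (scores.std() + 1e-12)
    for k in range(features.shape[1]):
        x = features[:, k]
        sd = x.std()
        if sd == 0:
            r[k], p[k] = 0.0, 1.0
            continue
        xz = (x - x.mean()) / sd
        fitres = sm.RLM(z, sm.add_constant(xz), M=sm.robust.norms.HuberT()).fit()
        r[k] = float(np.clip(fitres.params[1], -1, 1))
        p[k] = float(fitres.pvalues[1])
    return r, p


def select_edges(mc_features: np.ndarray, scores: np.ndarray,
                 config: CPMConfig | None = None):
    """Screen features: keep |r| > r_threshold and p < p_threshold.

    Returns (positive index array, negative index array, r, p).
    """
    cfg = config or CPMConfig()
    x = np.asarray(mc_features, dtype=float)
    y = np.asarray(scores, dtype=float)
    if x.shape[0] < 4:
        raise ValueError("need at least 4 subjects")
    if not np.isfinite(y).all():
        raise ValueError("scores contain non-finite values")
    if y.std() == 0:
        raise ValueError("constant score vector")
    r, p = _edge_correlations(x, y, cfg.correlation_method)
    keep = (np.abs(r) > cfg.r_threshold) & (p < cfg.p_threshold)
    pos = np.where(keep & (r > 0))[0]
    neg = np.where(keep & (r < 0))[0]
    return pos, neg, r, p


def summarize_subject(mc_features: np.ndarray, model: CPMModel):
    """(pos_sum, neg_sum): sums of MC values over each selected edge set."""
    x = np.atleast_2d(np.asarray(mc_features, dtype=float))
    pos = x[:, model.positive_edges].sum(axis=1) if len(model.positive_edges) else np.zeros(len(x))
    neg = x[:, model.negative_edges].sum(axis=1) if len(model.negative_edges) else np.zeros(len(x))
    if x.shape[0] == 1:
        return float(pos[0]), float(neg[0])
    return pos, neg


def _design_matrix(pos, neg, mode):
    if mode == "combined":
        return np.stack([np.ones_like(pos), pos - neg], axis=1)
    return np.stack([np.ones_like(pos), pos, neg], axis=1)


def fit_cpm(train_features: np.ndarray, train_scores: np.ndarray,
            config: CPMConfig | None = None) -> CPMModel:
    """Screen edges on training data and fit the linear summary model."""
    cfg = config or CPMConfig()
    x = np.asarray(train_features, dtype=float)
    y = np.asarray(train_scores, dtype=float)
    if x.shape[0] < 4:
        raise ValueError("need at least 4 training subjects")
    pos_idx, neg_idx, r, p = select_edges(x, y, cfg)
    model = CPMModel(
        positive_edges=pos_idx, negative_edges=neg_idx,
        coefficients=np.array([y.mean()]), summary_mode=cfg.summary_mode,
        edge_r=r, edge_p=p,
    )
    if len(pos_idx) == 0 and len(neg_idx) == 0:
        return model  # intercept-only: mean-score predictor
    pos, neg = summarize_subject(x, model)
    design = _design_matrix(pos, neg, cfg.summary_mode)
    keep_cols = [0] + [c for c in range(1, design.shape[1]) if design[:, c].std() > 1e-12]
    if len(keep_cols) < design.shape[1]:
        warnings.warn("degenerate summary predictor dropped; single-predictor fit")
    coef_sub, *_ = np.linalg.lstsq(design[:, keep_cols], y, rcond=None)
    coef = np.zeros(design.shape[1])
    coef[keep_cols] = coef_sub
    model.coefficients = coef
    pred = design @ coef
    if pred.std() > 0:
        model.train_r = float(np.corrcoef(pred, y)[0, 1])
    return model


def predict_scores(test_features: np.ndarray, model: CPMModel) -> np.ndarray:
    """Evaluate the fitted linear model on test-set summary values."""
    x = np.atleast_2d(np.asarray(test_features, dtype=float))
    if len(model.coefficients) == 1:
        return np.full(len(x), model.coefficients[0])
    pos, neg = summarize_subject(x, model)
    pos = np.atleast_1d(pos)
    neg = np.atleast_1d(neg)
    return _design_matrix(pos, neg, model.summary_mode) @ model.coefficients


def evaluate_prediction(observed: np.ndarray, predicted: np.ndarray):
    """(pearson r, RMSE, paired values). r is NaN for constant predictions."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if len(obs) != len(pred) or len(obs) < 3:
        raise ValueError("need equal-length arrays of >= 3 values")
    rmse = float(np.sqrt(((obs - pred) ** 2).mean()))
    if pred.std() == 0 or obs.std() == 0:
        warnings.warn("zero-variance input; correlation undefined")
        r = float("nan")
    else:
        r = float(np.corrcoef(obs, pred)[0, 1])
    return r, rmse, np.stack([obs, pred], axis=1)
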