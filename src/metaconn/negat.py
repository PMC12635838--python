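"""Node-edge attention graph network for link-graph classification.

A self-contained NumPy implementation (forward pass, analytic backward
pass, Adam) of a graph attention classifier that attends over both node
features and explicit edge features:

* separate linear transforms (no bias) for node and edge features;
* per-node softmax attention over neighbors (node stream) and over
  incident edges (edge stream), with a LeakyReLU scoring function;
* ``depth`` stacked node-attention layers, so the receptive field of a
  node is its depth-d neighborhood ball;
* attention-weighted aggregation of incident edge features, concatenated
  with the final node representation and mixed by a linear layer;
* mean readout over nodes and a two-layer MLP head (ReLU, dropout 0.2)
  with softmax output;
* label-smoothed cross-entropy plus an explicit L2 penalty on the linear
  layer weights, optimized by Adam.

The edge attention score applies both learnable vectors to the candidate
edge's own transformed feature while normalizing over all incident edges,
mirroring the printed scoring rule this architecture follows.

Isolated nodes bypass attention and carry their transformed features
forward; their edge summary is zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .linkgraph import LinkGraph

__all__ = [
    "NEGATConfig",
    "NEGATParams",
    "Prediction",
    "TrainReport",
    "transform_features",
    "attention_coefficients",
    "propagate",
    "smooth_labels",
    "compute_loss",
    "forward",
    "fit",
    "predict",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class NEGATConfig:
    depth: int = 3
    node_hidden: int = 32
    edge_hidden: int = 32
    final_hidden: int = 64
    mlp_hidden: int = 32
    leaky_slope: float = 0.2
    dropout: float = 0.2
    learning_rate: float = 1e-4
    batch_size: int = 64
    epochs: int = 100
    l2_beta: float = 1e-4
    label_smoothing: float = 0.1
    n_classes: int = 2
    attention: bool = True   # False: uniform neighbor averaging (ablation)
    mlp_head: bool = True    # False: single linear readout (ablation)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.depth <= 5:
            raise ValueError("depth must be in [1, 5]")
        if not 0 <= self.label_smoothing < 1:
            raise ValueError("label_smoothing must be in [0, 1)")
        if min(self.learning_rate, self.batch_size, self.epochs) <= 0:
            raise ValueError("learning rate, batch size and epochs must be positive")


@dataclass
class Prediction:
    probabilities: np.ndarray
    label: int


@dataclass
class TrainReport:
    epoch_loss: list[float] = field(default_factory=list)


class NEGATParams(dict):
    """Flat name -> array container for all learnable weights."""

    @staticmethod
    def init(node_dim: int, edge_dim: int, cfg: NEGATConfig, rng: np.random.Generator) -> "NEGATParams":
        def glorot(shape):
            lim = np.sqrt(6.0 / (shape[0] + shape[1]))
            return rng.uniform(-lim, lim, size=shape)

        p = NEGATParams()
        f_in = node_dim
        for layer in range(cfg.depth):
            p[f"W_node{layer}"] = glorot((cfg.node_hidden, f_in))
            p[f"a_src{layer}"] = rng.uniform(-0.1, 0.1, cfg.node_hidden)
            p[f"a_dst{layer}"] = rng.uniform(-0.1, 0.1, cfg.node_hidden)
            f_in = cfg.node_hidden
        p["W_edge"] = glorot((cfg.edge_hidden, edge_dim))
        p["aE_src"] = rng.uniform(-0.1, 0.1, cfg.edge_hidden)
        p["aE_dst"] = rng.uniform(-0.1, 0.1, cfg.edge_hidden)
        p["W_final"] = glorot((cfg.final_hidden, cfg.node_hidden + cfg.edge_hidden))
        if cfg.mlp_head:
            p["M1"] = glorot((cfg.mlp_hidden, cfg.final_hidden))
            p["b1"] = np.zeros(cfg.mlp_hidden)
            p["M2"] = glorot((cfg.n_classes, cfg.mlp_hidden))
            p["b2"] = np.zeros(cfg.n_classes)
        else:
            p["M2"] = glorot((cfg.n_classes, cfg.final_hidden))
            p["b2"] = np.zeros(cfg.n_classes)
        return p

    def weight_names(self) -> list[str]:
        return [k for k in self if k.startswith(("W_", "M"))]


# ---------------------------------------------------------------- primitives

def transform_features(h: np.ndarray, e: np.ndarray, params: NEGATParams):
    """Bias-free linear transforms h' = W_node h, e' = W_edge e (layer 0)."""
    w_node, w_edge = params["W_node0"], params["W_edge"]
    if h.shape[-1] != w_node.shape[1] or e.shape[-1] != w_edge.shape[1]:
        raise ValueError("feature dimension does not match transform")
    return h @ w_node.T, e @ w_edge.T


def _leaky(x: np.ndarray, slope: float) -> np.ndarray:
    return np.where(x > 0, x, slope * x)


def attention_coefficients(
    feats: np.ndarray,
    a_src: np.ndarray,
    a_dst: np.ndarray,
    kind: str = "node",
    self_feat: np.ndarray | None = None,
    slope: float = 0.2,
) -> np.ndarray:
    """Softmax attention over one node's neighborhood.

    ``node`` kind scores neighbor j as LeakyReLU(a_src . h'_i + a_dst . h'_j)
    with ``self_feat`` = h'_i and ``feats`` the stacked neighbor h'_j.
    ``edge`` kind scores incident edge (i, k) as
    LeakyReLU(a_src . e'_ik + a_dst . e'_ik) with ``feats`` the stacked
    incident-edge features, normalizing over them.
    """
    feats = np.atleast_2d(feats)
    if feats.shape[0] == 0:
        raise ValueError("attention undefined for an empty neighbor set")
    if kind == "node":
        if self_feat is None:
            raise ValueError("node attention needs the center node's feature")
        scores = _leaky(a_src @ self_feat + feats @ a_dst, slope)
    elif kind == "edge":
        scores = _leaky(feats @ (a_src + a_dst), slope)
    else:
        raise ValueError(f"unknown attention kind {kind!r}")
    scores = scores - scores.max()
    ex = np.exp(scores)
    return ex / ex.sum()


def propagate(
    h_prime: np.ndarray,
    e_prime: np.ndarray,
    neighbors: list[np.ndarray],
    alpha_node: list[np.ndarray],
    alpha_edge: list[np.ndarray] | None = None,
):
    """Reference aggregation: h''_i = sum_j alpha_ij h'_j; e'' = alpha e'.

    ``e_prime``/``alpha_edge`` are organized per node over its incident
    edges (same order as ``neighbors``).  Isolated nodes keep h'.
    """
    h2 = h_prime.copy()
    e2 = None if alpha_edge is None else []
    for i, nbrs in enumerate(neighbors):
        if len(nbrs):
            h2[i] = alpha_node[i] @ h_prime[nbrs]
        if alpha_edge is not None:
            e2.append(alpha_edge[i][:, None] * e_prime[i] if len(nbrs) else np.zeros((0,)))
    return h2, e2


def smooth_labels(y: np.ndarray, alpha: float, n_classes: int) -> np.ndarray:
    """Label smoothing y_k (1 - alpha) + alpha / K for one-hot targets."""
    y = np.asarray(y, dtype=float)
    if not 0 <= alpha < 1:
        raise ValueError("alpha must be in [0, 1)")
    return y * (1 - alpha) + alpha / n_classes


def compute_loss(y_ls: np.ndarray, p: np.ndarray, params: NEGATParams | None, beta: float) -> float:
    """Label-smoothed cross-entropy plus beta * sum ||W||^2 over linear weights."""
    p = np.clip(np.asarray(p, dtype=float), 1e-12, None)
    ce = float(-(np.asarray(y_ls) * np.log(p)).sum())
    if params is not None and beta > 0:
        ce += beta * sum(float((params[k] ** 2).sum()) for k in params.weight_names())
    return ce


# ------------------------------------------------------------- graph caching

class _PreparedGraph:
    """Directed-edge arrays, sorted by aggregating node, for fast passing.

    Directed edges are lexsorted by (dst, src); per-destination segments are
    contiguous, so segment softmax and aggregation reduce to ``reduceat``
    calls, and scatter-to-source is a sparse transpose product.
    """

    def __init__(self, g: LinkGraph):
        from scipy import sparse

        self.h0 = np.asarray(g.node_features, dtype=float)
        self.e0 = np.asarray(g.edge_features, dtype=float)
        self.n = n = g.n_nodes
        if g.n_edges:
            a, b = g.edges[:, 0], g.edges[:, 1]
            dst = np.concatenate([a, b])
            src = np.concatenate([b, a])
            ue = np.concatenate([np.arange(g.n_edges), np.arange(g.n_edges)])
            order = np.lexsort((src, dst))
            self.dst, self.src, self.ue = dst[order], src[order], ue[order]
        else:
            self.dst = self.src = self.ue = np.empty(0, dtype=int)
        deg = np.bincount(self.dst, minlength=n).astype(float)
        self.deg = deg
        self.isolated = deg == 0
        # contiguous segments per destination node
        self.seg_nodes = np.unique(self.dst)
        self.seg_starts = np.searchsorted(self.dst, self.seg_nodes)
        self.seg_counts = deg[self.seg_nodes].astype(int)
        indptr = np.concatenate([[0], np.cumsum(deg).astype(int)])
        self._adj = sparse.csr_matrix(
            (np.ones(len(self.dst)), self.src, indptr), shape=(n, n)
        )
        self.label = g.label

    def expand(self, per_node_vals: np.ndarray) -> np.ndarray:
        """Per-present-segment values -> per-directed-edge values."""
        return np.repeat(per_node_vals, self.seg_counts)

    def aggregate(self, edge_weights: np.ndarray, node_vals: np.ndarray) -> np.ndarray:
        """out[i] = sum over incoming edges of weight * node_vals[src]."""
        self._adj.data = edge_weights
        return self._adj @ node_vals

    def scatter_to_src(self, edge_weights: np.ndarray, node_vals: np.ndarray) -> np.ndarray:
        """out[j] = sum over edges with src j of weight * node_vals[dst]."""
        self._adj.data = edge_weights
        return self._adj.T @ node_vals

    def segment_sum(self, edge_vals: np.ndarray) -> np.ndarray:
        """Per-destination-node sum of per-edge values (full length n)."""
        out = np.zeros(self.n)
        if len(edge_vals):
            out[self.seg_nodes] = np.add.reduceat(edge_vals, self.seg_starts)
        return out

    def segment_softmax(self, scores: np.ndarray | None, uniform: bool) -> np.ndarray:
        if uniform:
            return 1.0 / self.deg[self.dst]
        m = np.maximum.reduceat(scores, self.seg_starts)
        ex = np.exp(scores - self.expand(m))
        s = np.add.reduceat(ex, self.seg_starts)
        return ex / self.expand(s)


def _forward_graph(pg: _PreparedGraph, params: NEGATParams, cfg: NEGATConfig,
                   dropout_rng: np.random.Generator | None = None):
    """Full forward pass; returns (probabilities, cache for backward)."""
    cache = {"layers": []}
    x = pg.h0
    dst, src, n = pg.dst, pg.src, pg.n
    for layer in range(cfg.depth):
        w = params[f"W_node{layer}"]
        xp = x @ w.T
        if len(dst):
            if cfg.attention:
                s_src = xp @ params[f"a_src{layer}"]
                s_dst = xp @ params[f"a_dst{layer}"]
                score = s_src[dst] + s_dst[src]
                z = _leaky(score, cfg.leaky_slope)
            else:
                score = z = None
            alpha = pg.segment_softmax(z, uniform=not cfg.attention)
            out = pg.aggregate(alpha, xp)
            out[pg.isolated] = xp[pg.isolated]
        else:
            alpha = score = None
            out = xp
        cache["layers"].append({"x": x, "xp": xp, "score": score, "alpha": alpha})
        x = out
    # edge stream
    ep = pg.e0 @ params["W_edge"].T
    ebar = np.zeros((n, ep.shape[1]))
    if len(dst):
        if cfg.attention:
            e_score = ep @ (params["aE_src"] + params["aE_dst"])
            ez = _leaky(e_score[pg.ue], cfg.leaky_slope)
        else:
            e_score = ez = None
        e_alpha = pg.segment_softmax(ez, uniform=not cfg.attention)
        vals = e_alpha[:, None] * ep[pg.ue]
        ebar[pg.seg_nodes] = np.add.reduceat(vals, pg.seg_starts, axis=0)
    else:
        e_alpha = e_score = None
    cache["edge"] = {"ep": ep, "score": e_score, "alpha": e_alpha}
    hcat = np.hstack([x, ebar])
    f = hcat @ params["W_final"].T
    g = f.mean(axis=0)
    cache["hcat"], cache["g"] = hcat, g
    if cfg.mlp_head:
        u1 = params["M1"] @ g + params["b1"]
        r = np.maximum(u1, 0.0)
        if dropout_rng is not None and cfg.dropout > 0:
            mask = (dropout_rng.random(r.shape) >= cfg.dropout) / (1 - cfg.dropout)
        else:
            mask = np.ones_like(r)
        rd = r * mask
        logits = params["M2"] @ rd + params["b2"]
        cache.update(u1=u1, mask=mask, rd=rd)
    else:
        logits = params["M2"] @ g + params["b2"]
    logits = logits - logits.max()
    ex = np.exp(logits)
    probs = ex / ex.sum()
    cache["probs"] = probs
    return probs, cache


def _leaky_grad(score, slope):
    return np.where(score > 0, 1.0, slope)


def _backward_graph(pg, params, cfg, cache, y_ls, grads, scale):
    """Accumulate d(CE)/d(params) * scale into ``grads``."""
    dst, src, n = pg.dst, pg.src, pg.n
    dlogits = (cache["probs"] - y_ls) * scale
    if cfg.mlp_head:
        grads["M2"] += np.outer(dlogits, cache["rd"])
        grads["b2"] += dlogits
        drd = params["M2"].T @ dlogits
        dr = drd * cache["mask"]
        du1 = dr * (cache["u1"] > 0)
        grads["M1"] += np.outer(du1, cache["g"])
        grads["b1"] += du1
        dg = params["M1"].T @ du1
    else:
        grads["M2"] += np.outer(dlogits, cache["g"])
        grads["b2"] += dlogits
        dg = params["M2"].T @ dlogits
    grads["W_final"] += np.outer(dg, cache["hcat"].mean(axis=0))
    dhcat = np.tile((dg @ params["W_final"]) / n, (n, 1))
    h_dim = cfg.node_hidden
    dx = dhcat[:, :h_dim].copy()
    debar = dhcat[:, h_dim:]
    # edge stream backward
    ec = cache["edge"]
    ep, e_alpha = ec["ep"], ec["alpha"]
    dep = np.zeros_like(ep)
    if len(dst):
        gathered = debar[dst]
        dalpha = np.einsum("md,md->m", gathered, ep[pg.ue])
        vals = e_alpha[:, None] * gathered
        for k in range(ep.shape[1]):
            dep[:, k] += np.bincount(pg.ue, weights=vals[:, k], minlength=ep.shape[0])
        if cfg.attention:
            seg = pg.segment_sum(e_alpha * dalpha)
            dz = e_alpha * (dalpha - seg[dst])
            dscore_edge = dz * _leaky_grad(ec["score"][pg.ue], cfg.leaky_slope)
            dscore_per_ue = np.bincount(pg.ue, weights=dscore_edge, minlength=ep.shape[0])
            dvec = ep.T @ dscore_per_ue
            grads["aE_src"] += dvec
            grads["aE_dst"] += dvec
            dep += np.outer(dscore_per_ue, params["aE_src"] + params["aE_dst"])
    grads["W_edge"] += dep.T @ pg.e0
    # node stream backward through stacked layers
    for layer in reversed(range(cfg.depth)):
        lc = cache["layers"][layer]
        x, xp, alpha, score = lc["x"], lc["xp"], lc["alpha"], lc["score"]
        if len(dst):
            dxp = np.zeros_like(xp)
            dxp[pg.isolated] = dx[pg.isolated]
            dout = dx.copy()
            dout[pg.isolated] = 0.0
            dalpha = np.einsum("md,md->m", dout[dst], xp[src])
            dxp += pg.scatter_to_src(alpha, dout)
            if cfg.attention:
                seg = pg.segment_sum(alpha * dalpha)
                dz = alpha * (dalpha - seg[dst])
                dsc = dz * _leaky_grad(score, cfg.leaky_slope)
                ds_src = pg.segment_sum(dsc)
                ds_dst = np.bincount(src, weights=dsc, minlength=n)
                grads[f"a_src{layer}"] += xp.T @ ds_src
                grads[f"a_dst{layer}"] += xp.T @ ds_dst
                dxp += np.outer(ds_src, params[f"a_src{layer}"])
                dxp += np.outer(ds_dst, params[f"a_dst{layer}"])
        else:
            dxp = dx
        grads[f"W_node{layer}"] += dxp.T @ x
        dx = dxp @ params[f"W_node{layer}"]


# ----------------------------------------------------------------- training

def forward(graph: LinkGraph, params: NEGATParams, config: NEGATConfig) -> Prediction:
    """Eval-mode forward pass (dropout disabled)."""
    probs, _ = _forward_graph(_PreparedGraph(graph), params, config, dropout_rng=None)
    return Prediction(probabilities=probs, label=int(np.argmax(probs)))


def fit(
    graphs: list[LinkGraph],
    labels: np.ndarray | list[int],
    config: NEGATConfig | None = None,
) -> tuple[NEGATParams, TrainReport]:
    """Train with Adam on label-smoothed cross-entropy + L2.

    Deterministic given ``config.seed`` (initialization, shuffling and
    dropout all flow from one seeded generator).
    """
    cfg = config or NEGATConfig()
    labels = np.asarray(labels, dtype=int)
    if len(set(labels.tolist())) < 2:
        raise ValueError("training set contains a single class")
    rng = np.random.default_rng(cfg.seed)
    prepared = [_PreparedGraph(g) for g in graphs]
    params = NEGATParams.init(
        prepared[0].h0.shape[1], prepared[0].e0.shape[1], cfg, rng
    )
    onehot = np.eye(cfg.n_classes)[labels]
    y_ls = smooth_labels(onehot, cfg.label_smoothing, cfg.n_classes)
    m_state = {k: np.zeros_like(v) for k, v in params.items()}
    v_state = {k: np.zeros_like(v) for k, v in params.items()}
    b1m, b2m, eps = 0.9, 0.999, 1e-8
    step = 0
    report = TrainReport()
    n = len(prepared)
    for _ in range(cfg.epochs):
        perm = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, cfg.batch_size):
            batch = perm[start : start + cfg.batch_size]
            grads = {k: np.zeros_like(v) for k, v in params.items()}
            batch_ce = 0.0
            for idx in batch:
                probs, cache = _forward_graph(prepared[idx], params, cfg, dropout_rng=rng)
                batch_ce += compute_loss(y_ls[idx], probs, None, 0.0)
                _backward_graph(prepared[idx], params, cfg, cache, y_ls[idx], grads, 1.0 / len(batch))
            for k in params.weight_names():
                grads[k] += 2 * cfg.l2_beta * params[k]
            step += 1
            for k in params:
                m_state[k] = b1m * m_state[k] + (1 - b1m) * grads[k]
                v_state[k] = b2m * v_state[k] + (1 - b2m) * grads[k] ** 2
                mhat = m_state[k] / (1 - b1m**step)
                vhat = v_state[k] / (1 - b2m**step)
                params[k] -= cfg.learning_rate * mhat / (np.sqrt(vhat) + eps)
            penalty = cfg.l2_beta * sum(float((params[k] ** 2).sum()) for k in params.weight_names())
            epoch_losses.append(batch_ce / len(batch) + penalty)
        report.epoch_loss.append(float(np.mean(epoch_losses)))
    return params, report


def save_checkpoint(path, params: NEGATParams, config: NEGATConfig) -> None:
    """Write weights (array blob) and configuration (JSON) side by side."""
    import json
    from dataclasses import asdict

    np.savez_compressed(path, **params)
    Path(str(path) + ".json").write_text(json.dumps(asdict(config)))


def load_checkpoint(path) -> tuple[NEGATParams, NEGATConfig]:
    import json

    blob = np.load(path)
    params = NEGATParams({k: blob[k] for k in blob.files})
    cfg = NEGATConfig(**json.loads(Path(str(path) + ".json").read_text()))
    return params, cfg


def predict(graphs: list[LinkGraph], params: NEGATParams, config: NEGATConfig | None = None) -> list[Prediction]:
    """Eval-mode predictions; argmax labels, ties resolved to class 0."""
    cfg = config or NEGATConfig()
    out = []
    for g in graphs:
        pg = _PreparedGraph(g)
        if pg.h0.shape[1] != params["W_node0"].shape[1]:
            raise ValueError("node feature dimension does not match trained parameters")
        probs, _ = _forward_graph(pg, params, cfg, dropout_rng=None)
        out.append(Prediction(probabilities=probs, label=int(np.argmax(probs))))
    return out
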