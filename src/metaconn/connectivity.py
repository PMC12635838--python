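"""Static, dynamic, and meta-connectivity estimation.

Functional connectivity (FC) is the Pearson correlation between two ROI
time series over the full record.  A dynamic FC (dFC) *stream* re-estimates
FC inside a sliding window, producing one time course per link; the
meta-connectivity (MC) matrix is the link-by-link Pearson correlation of
those time courses, i.e. an edge-centric, higher-order connectome.

Link ordering convention used everywhere in this package: unique undirected
links (i, j) with i < j, sorted lexicographically — the order produced by
``numpy.triu_indices(n, k=1)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "FCMatrix",
    "DFCStream",
    "MCMatrix",
    "SignificanceMask",
    "RobustnessReport",
    "link_index",
    "compute_fc",
    "vectorize_fc",
    "devectorize",
    "compute_dfc_stream",
    "compute_mc",
    "expand_mc",
    "significance_mask",
    "ssim",
    "mc_noise_robustness",
    "snr_noise_robustness",
]


def link_index(n_rois: int) -> list[tuple[int, int]]:
    """Ordered list of unique links (i, j), i < j, lexicographic."""
    iu = np.triu_indices(n_rois, k=1)
    return list(zip(iu[0].tolist(), iu[1].tolist()))


def _corrcoef_safe(data: np.ndarray, what: str) -> np.ndarray:
    """Row-wise Pearson correlation with zero-variance rows mapped to 0.

    Degenerate (constant) rows produce a correlation of 0 off-diagonal and 1
    on the diagonal, with a warning, so downstream matrices stay valid.
    """
    sd = data.std(axis=1)
    # relative tolerance: a constant column's std is rounding noise, not 0
    bad = sd <= 1e-12 * np.maximum(1.0, np.abs(data).max(axis=1))
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} zero-variance {what}(s); correlations set to 0",
            stacklevel=3,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.corrcoef(data)
    c = np.atleast_2d(c)
    if bad.any():
        c[bad, :] = 0.0
        c[:, bad] = 0.0
    np.fill_diagonal(c, 1.0)
    return np.clip(c, -1.0, 1.0)


@dataclass
class FCMatrix:
    """Static functional-connectivity matrix (N x N, symmetric, unit diagonal)."""

    values: np.ndarray
    roi_names: list[str] | None = None

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]


@dataclass
class DFCStream:
    """Sliding-window FC stream in vector format (L links x F frames)."""

    values: np.ndarray
    window_frames: int
    step_frames: int
    link_index: list[tuple[int, int]]

    @property
    def n_links(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]


@dataclass
class MCMatrix:
    """Meta-connectivity: correlation between link dFC time courses.

    ``compact`` is the L x L working form over unique undirected links.  The
    redundant M x M directed-pair form (M = N(N-1)) is available through
    :func:`expand_mc`.
    """

    compact: np.ndarray
    link_index: list[tuple[int, int]]

    @property
    def n_links(self) -> int:
        return self.compact.shape[0]


@dataclass
class SignificanceMask:
    """Boolean L x L mask of group-significant meta-links."""

    values: np.ndarray
    alpha: float
    q: float


@dataclass
class RobustnessReport:
    """Per-noise-level similarity between clean and perturbed MC."""

    table: pd.DataFrame
    n_reps: int = field(default=1)


def compute_fc(ts) -> FCMatrix:
    """Pairwise Pearson FC over the full record of a ROI time-series table.

    Accepts a :class:`~metaconn.io.ROITimeSeries` or a bare (T x N) array.
    """
    data, names = _ts_data(ts)
    if data.shape[0] < 3:
        raise ValueError("need at least 3 timepoints to estimate FC")
    if not np.isfinite(data).all():
        raise ValueError("non-finite values in time series")
    return FCMatrix(values=_corrcoef_safe(data.T, "ROI column"), roi_names=names)


def _ts_data(ts) -> tuple[np.ndarray, list[str] | None]:
    if hasattr(ts, "data"):
        return np.asarray(ts.data, dtype=float), getattr(ts, "roi_names", None)
    return np.asarray(ts, dtype=float), None


def vectorize_fc(fc: FCMatrix | np.ndarray) -> np.ndarray:
    """Extract the L = N(N-1)/2 unique off-diagonal entries in link order."""
    m = fc.values if isinstance(fc, FCMatrix) else np.asarray(fc)
    iu = np.triu_indices(m.shape[0], k=1)
    return m[iu]


def devectorize(vec: np.ndarray, links: list[tuple[int, int]]) -> FCMatrix:
    """Inverse of :func:`vectorize_fc` (symmetric, unit diagonal)."""
    vec = np.asarray(vec, dtype=float)
    if len(vec) != len(links):
        raise ValueError(f"vector length {len(vec)} != number of links {len(links)}")
    n = max(j for _, j in links) + 1
    out = np.eye(n)
    for v, (i, j) in zip(vec, links):
        out[i, j] = out[j, i] = v
    return FCMatrix(values=out)


def compute_dfc_stream(
    ts,
    window_seconds: float = 20.0,
    step_frames: int = 2,
    tr_seconds: float | None = None,
) -> DFCStream:
    """Sliding-window Pearson FC stream in vector (L x F) format.

    Frame k covers samples [k*step, k*step + w) where the window length in
    frames is ``round(window_seconds / tr_seconds)``; the step is given
    directly in frames (TR units).  F = floor((T - w) / step) + 1.
    """
    data, _ = _ts_data(ts)
    if tr_seconds is None:
        tr_seconds = getattr(ts, "tr_seconds", 2.0)
    w = int(round(window_seconds / tr_seconds))
    if w < 3:
        raise ValueError(f"window of {w} frames is too short (need >= 3)")
    if step_frames < 1:
        raise ValueError("step must be >= 1 frame")
    t, n = data.shape
    n_frames = (t - w) // step_frames + 1
    if n_frames < 1:
        raise ValueError(
            f"record of {t} frames is shorter than the {w}-frame window"
        )
    links = link_index(n)
    iu = np.triu_indices(n, k=1)
    out = np.empty((len(links), n_frames))
    with warnings.catch_warnings():
        warnings.simplefilter("once")
        for k in range(n_frames):
            seg = data[k * step_frames : k * step_frames + w]
            out[:, k] = _corrcoef_safe(seg.T, "windowed ROI column")[iu]
    return DFCStream(values=out, window_frames=w, step_frames=step_frames, link_index=links)


def compute_mc(stream: DFCStream) -> MCMatrix:
    """Meta-connectivity: Pearson correlation between link dFC time courses."""
    if stream.n_frames < 3:
        raise ValueError("need at least 3 dFC frames to estimate MC")
    compact = _corrcoef_safe(stream.values, "link dFC time course")
    return MCMatrix(compact=compact, link_index=stream.link_index)


def expand_mc(mc: MCMatrix) -> np.ndarray:
    """Redundant M x M form over directed ROI pairs (M = N(N-1)).

    Directed pairs (i, j), i != j, are ordered lexicographically.  Each
    unique meta-link value appears at every combination of the two link
    orientations: MC[ij,kl] = MC[ji,kl] = MC[ij,lk] = MC[kl,ij].
    """
    n = max(j for _, j in mc.link_index) + 1
    directed = [(i, j) for i in range(n) for j in range(n) if i != j]
    lut = {}
    for a, (i, j) in enumerate(mc.link_index):
        lut[(i, j)] = a
        lut[(j, i)] = a
    rows = np.array([lut[p] for p in directed])
    return mc.compact[np.ix_(rows, rows)]


def significance_mask(
    mc_list: list[MCMatrix],
    alpha: float = 0.01,
    q: float = 0.05,
    fisher_z: bool = True,
) -> SignificanceMask:
    """Group-level mask of meta-links significantly different from zero.

    Per unique off-diagonal entry, a one-sample t-test across subjects
    (on Fisher-z transformed values by default) against 0, followed by
    Benjamini-Hochberg FDR over the L(L-1)/2 unique entries.  An entry is
    kept when it survives both the FDR step at level ``q`` and the raw
    threshold ``alpha``.  Zero-variance entries are never rejected.
    """
    if len(mc_list) < 3:
        raise ValueError("need at least 3 subjects for the group t-test")
    stack = np.stack([m.compact for m in mc_list])  # subjects x L x L
    iu = np.triu_indices(stack.shape[1], k=1)
    vals = stack[:, iu[0], iu[1]]  # subjects x n_entries
    if fisher_z:
        vals = np.arctanh(np.clip(vals, -1 + 1e-12, 1 - 1e-12))
    sd = vals.std(axis=0)
    pvals = np.ones(vals.shape[1])
    ok = sd > 0
    if ok.any():
        res = stats.ttest_1samp(vals[:, ok], popmean=0.0, axis=0)
        pvals[ok] = res.pvalue
    reject, _, _, _ = multipletests(pvals, alpha=q, method="fdr_bh")
    keep = reject & (pvals < alpha) & ok
    l = stack.shape[1]
    mask = np.zeros((l, l), dtype=bool)
    mask[iu] = keep
    mask |= mask.T
    np.fill_diagonal(mask, True)
    return SignificanceMask(values=mask, alpha=alpha, q=q)


def ssim(a: np.ndarray, b: np.ndarray, mode: str = "global") -> float:
    """Structural similarity between two matrices.

    ``global`` (default) uses whole-matrix means/variances/covariance with
    C1 = (0.01 R)^2, C2 = (0.03 R)^2 where R is the dynamic range of ``a``.
    ``windowed`` averages SSIM over 7x7 uniform windows (scikit-image).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    r = float(a.max() - a.min())
    if r == 0:
        r = 1.0
    if mode == "windowed":
        from skimage.metrics import structural_similarity

        return float(
            structural_similarity(
                a, b, win_size=7, data_range=r, gaussian_weights=False
            )
        )
    if mode != "global":
        raise ValueError(f"unknown SSIM mode {mode!r}")
    c1 = (0.01 * r) ** 2
    c2 = (0.03 * r) ** 2
    mu_a, mu_b = a.mean(), b.mean()
    var_a, var_b = a.var(), b.var()
    cov = ((a - mu_a) * (b - mu_b)).mean()
    lum = (2 * mu_a * mu_b + c1) / (mu_a**2 + mu_b**2 + c1)
    cs = (2 * cov + c2) / (var_a + var_b + c2)
    return float(lum * cs)


def perturb_mc(mc_values: np.ndarray, noise_sd: float, rng: np.random.Generator) -> np.ndarray:
    """Entrywise Gaussian perturbation, re-symmetrized, clamped, unit diagonal."""
    noisy = mc_values + rng.normal(0.0, noise_sd, size=mc_values.shape)
    noisy = (noisy + noisy.T) / 2.0
    noisy = np.clip(noisy, -1.0, 1.0)
    np.fill_diagonal(noisy, 1.0)
    return noisy


def _offdiag(m: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(m.shape[0], k=1)
    return m[iu]


def mc_noise_robustness(
    mc_truth: MCMatrix | np.ndarray,
    noise_sds: list[float],
    n_reps: int = 20,
    seed: int = 0,
) -> RobustnessReport:
    """Similarity of a ground-truth MC matrix to Gaussian-perturbed copies.

    For each noise SD: perturb every entry, re-symmetrize by averaging with
    the transpose, clamp to [-1, 1], restore the unit diagonal; report the
    mean Pearson correlation between the clean and noisy off-diagonals and
    the mean global SSIM across replicates.
    """
    clean = mc_truth.compact if isinstance(mc_truth, MCMatrix) else np.asarray(mc_truth)
    rng = np.random.default_rng(seed)
    rows = []
    for sd_level in noise_sds:
        pearsons, ssims = [], []
        for _ in range(n_reps):
            if sd_level == 0:
                noisy = clean.copy()
            else:
                noisy = perturb_mc(clean, sd_level, rng)
            pearsons.append(float(np.corrcoef(_offdiag(clean), _offdiag(noisy))[0, 1]))
            ssims.append(ssim(clean, noisy))
        rows.append(
            {"noise_sd": sd_level, "pearson": float(np.mean(pearsons)), "ssim": float(np.mean(ssims))}
        )
    return RobustnessReport(table=pd.DataFrame(rows), n_reps=n_reps)


def snr_noise_robustness(
    ts_list: list,
    snr_db_list: list[float],
    window_seconds: float = 20.0,
    step_frames: int = 2,
    n_reps: int = 3,
    seed: int = 0,
) -> RobustnessReport:
    """End-to-end robustness: noisy time series -> dFC -> MC vs clean MC.

    Gaussian noise is added to each subject's time series at the requested
    SNR (dB, relative to that subject's mean column variance), the full MC
    pipeline is re-run, and the Pearson/SSIM similarity to the noise-free
    MC is averaged over subjects and replicates.
    """
    rng = np.random.default_rng(seed)
    rows = []
    cleans = []
    for ts in ts_list:
        data, _ = _ts_data(ts)
        tr = getattr(ts, "tr_seconds", 2.0)
        stream = compute_dfc_stream(data, window_seconds, step_frames, tr)
        cleans.append((data, tr, compute_mc(stream).compact))
    for snr_db in snr_db_list:
        pearsons, ssims = [], []
        for data, tr, clean_mc in cleans:
            sig_power = float(data.var(axis=0).mean())
            noise_power = sig_power / (10.0 ** (snr_db / 10.0))
            for _ in range(n_reps):
                noisy = data + rng.normal(0.0, np.sqrt(noise_power), size=data.shape)
                stream = compute_dfc_stream(noisy, window_seconds, step_frames, tr)
                noisy_mc = compute_mc(stream).compact
                a, b = _offdiag(clean_mc), _offdiag(noisy_mc)
                if a.std() > 0 and b.std() > 0:
                    pearsons.append(float(np.corrcoef(a, b)[0, 1]))
                ssims.append(ssim(clean_mc, noisy_mc))
        rows.append(
            {
                "snr_db": snr_db,
                "pearson": float(np.mean(pearsons)) if pearsons else np.nan,
                "ssim": float(np.mean(ssims)),
            }
        )
    return RobustnessReport(table=pd.DataFrame(rows), n_reps=n_reps)
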