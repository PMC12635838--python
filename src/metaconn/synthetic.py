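"""Synthetic cohorts with planted meta-module structure.

The generator emulates the phenomenon meta-connectivity is designed to
detect: groups of FC links ("meta-modules") whose coupling strengths rise
and fall together.  Each module owns a slow latent modulator (random-phase
sinusoid plus AR(1) drift); every link in the module mixes that shared
modulator with an idiosyncratic one, and the mixture multiplicatively
gates the instantaneous ROI-ROI coupling.  Samples are drawn per timepoint
from the nearest valid (positive semi-definite) correlation matrix, so the
marginal FC is stationary while the windowed dFC stream carries the
planted co-fluctuation.

Because MC is estimated from finite, noisy windowed correlations, the
realized within-module MC is an attenuated monotone transform of the
requested ``within_strength`` (see docs/methods.md); the planted contrast
and its ordering are preserved exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .connectivity import MCMatrix, compute_dfc_stream, compute_mc, link_index
from .io import ROITimeSeries, packaged_roi_table

__all__ = [
    "MetaModuleSpec",
    "CohortSpec",
    "default_module_assignment",
    "gen_meta_module_timeseries",
    "gen_cohort",
    "gen_behavioral_scores",
    "module_contrast",
]

BACKGROUND = -1  # links with constant (unmodulated) coupling

# Coupling model rho(t) = RHO_BASE + AMP * tanh(SAT * m(t)); the modulator
# share given to the module latent is SHARE_GAIN * within_strength (capped),
# chosen so realized MC tracks the requested strength as closely as the
# windowed estimator permits.
RHO_BASE = 0.3
AMP = 0.65
SAT = 3.0
SHARE_GAIN = 1.15
SHARE_CAP = 0.98


@dataclass
class MetaModuleSpec:
    """Planted meta-module structure over FC links.

    ``module_assignment`` maps every link index (in the canonical i<j
    lexicographic link order) to a module id; id ``-1`` marks background
    links whose coupling stays constant.  ``within_strength`` is the target
    MC between links of the same module, ``between_strength`` between links
    of different modules; ``modulator_timescale`` (seconds) sets how slowly
    coupling states drift.
    """

    module_assignment: dict[int, int]
    within_strength: float = 0.8
    between_strength: float = 0.0
    modulator_timescale: float = 45.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.within_strength <= 1.0:
            raise ValueError("within_strength must be in [0, 1]")
        if not 0.0 <= self.between_strength <= 1.0:
            raise ValueError("between_strength must be in [0, 1]")
        if self.between_strength > self.within_strength:
            raise ValueError("between_strength must not exceed within_strength")
        if self.modulator_timescale <= 0:
            raise ValueError("modulator_timescale must be positive")

    @property
    def module_ids(self) -> list[int]:
        return sorted({m for m in self.module_assignment.values() if m != BACKGROUND})


def default_module_assignment(n_rois: int, n_modules: int) -> dict[int, int]:
    """Modules induced by a contiguous ROI partition.

    ROIs are split into ``n_modules`` groups; links inside group g form
    module g, links across groups are background.  This community layout is
    exactly realizable as a correlation process (arbitrary link->module
    maps generally are not).
    """
    if n_modules < 1 or n_modules > n_rois // 2:
        raise ValueError("need 1 <= n_modules <= n_rois // 2")
    bounds = np.linspace(0, n_rois, n_modules + 1).astype(int)
    roi_group = np.zeros(n_rois, dtype=int)
    for g in range(n_modules):
        roi_group[bounds[g] : bounds[g + 1]] = g
    out = {}
    for a, (i, j) in enumerate(link_index(n_rois)):
        out[a] = int(roi_group[i]) if roi_group[i] == roi_group[j] else BACKGROUND
    return out


def _slow_process(n: int, n_t: int, tr: float, tau: float, rng: np.random.Generator) -> np.ndarray:
    """n independent unit-variance slow latents: sinusoid + AR(1) drift."""
    t = np.arange(n_t) * tr
    freq = (1.0 / tau) * rng.uniform(0.8, 1.2, size=(n, 1))
    phase = rng.uniform(0, 2 * np.pi, size=(n, 1))
    sine = np.sqrt(2.0) * np.sin(2 * np.pi * freq * t[None, :] + phase)
    rho = float(np.exp(-tr / tau))
    eps = rng.normal(0.0, 1.0, size=(n, n_t))
    ar = np.empty_like(eps)
    ar[:, 0] = eps[:, 0]
    innov = np.sqrt(1 - rho**2)
    for k in range(1, n_t):
        ar[:, k] = rho * ar[:, k - 1] + innov * eps[:, k]
    out = (sine + ar) / np.sqrt(2.0)
    return (out - out.mean(axis=1, keepdims=True)) / (out.std(axis=1, keepdims=True) + 1e-12)


def _nearest_corr_chol(c: np.ndarray) -> np.ndarray:
    """Cholesky factor of the nearest valid correlation matrix (eigenclip)."""
    w, v = np.linalg.eigh(c)
    if w[0] < 1e-8:
        w = np.clip(w, 1e-8, None)
        c = (v * w) @ v.T
        d = np.sqrt(np.diag(c))
        c = c / np.outer(d, d)
    return np.linalg.cholesky(c)


def gen_meta_module_timeseries(
    spec: MetaModuleSpec,
    n_rois: int,
    n_timepoints: int,
    noise_sd: float = 0.2,
    seed: int | np.random.Generator = 0,
    tr_seconds: float = 2.0,
    subject_id: str = "sim",
) -> ROITimeSeries:
    """One subject's ROI time series with the planted meta-module structure."""
    links = link_index(n_rois)
    missing = set(range(len(links))) - set(spec.module_assignment)
    if missing:
        raise ValueError(f"module_assignment misses {len(missing)} link(s)")
    w_frames = int(round(20.0 / tr_seconds))
    if (n_timepoints - w_frames) // 2 + 1 < 5:
        raise ValueError(
            f"{n_timepoints} timepoints yield fewer than 5 dFC frames at the "
            "default 20 s window / 2-frame step; output would be unusable"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mods = spec.module_ids
    tau = spec.modulator_timescale

    # module latents, optionally correlated through a global component to
    # plant between-module co-fluctuation
    u = _slow_process(len(mods), n_timepoints, tr_seconds, tau, rng)
    g_between = 0.0 if spec.within_strength == 0 else spec.between_strength / spec.within_strength
    if g_between > 0 and len(mods) > 1:
        u0 = _slow_process(1, n_timepoints, tr_seconds, tau, rng)
        u = np.sqrt(g_between) * u0 + np.sqrt(1 - g_between) * u

    share = min(SHARE_CAP, SHARE_GAIN * spec.within_strength)
    modulated = spec.within_strength > 0 or spec.between_strength > 0
    xi = _slow_process(len(links), n_timepoints, tr_seconds, tau, rng)
    mod_row = {m: r for r, m in enumerate(mods)}
    # "no planted structure" means independent ROI signals: a flat nonzero
    # base correlation would itself induce a common-factor MC floor
    rho = np.full((len(links), n_timepoints), RHO_BASE if modulated else 0.0)
    if modulated:
        for a in range(len(links)):
            mid = spec.module_assignment[a]
            if mid == BACKGROUND:
                continue
            m = np.sqrt(share) * u[mod_row[mid]] + np.sqrt(1 - share) * xi[a]
            rho[a] = RHO_BASE + AMP * np.tanh(SAT * m)

    iu = np.triu_indices(n_rois, k=1)
    z = rng.normal(0.0, 1.0, size=(n_timepoints, n_rois))
    x = np.empty((n_timepoints, n_rois))
    c = np.eye(n_rois)
    for t in range(n_timepoints):
        c[iu] = rho[:, t]
        c.T[iu] = rho[:, t]
        x[t] = _nearest_corr_chol(c) @ z[t]
    if noise_sd > 0:
        x = x + rng.normal(0.0, noise_sd, size=x.shape)
    names = packaged_roi_table().names if n_rois == 25 else [f"roi{r}" for r in range(n_rois)]
    return ROITimeSeries(subject_id=subject_id, data=x, tr_seconds=tr_seconds, roi_names=names)


@dataclass
class CohortSpec:
    """Two-group cohort with planted MC contrast, site effects and scores.

    The case group is generated at ``within_strength``; the control group at
    ``within_strength - group_effect``.  Subjects are assigned round-robin
    to sites; the second half of the sites receives an additive common
    nuisance signal of amplitude ``site_shift`` (a constant offset would be
    invisible to every correlation-based feature) and a global gain of
    ``site_scale``.  ``score_coefficients`` maps vectorized-MC feature
    indices to linear weights for behavioral-score generation.
    """

    n_subjects_per_group: int
    n_rois: int = 25
    n_timepoints: int = 600
    tr_seconds: float = 2.0
    within_strength: float = 0.8
    between_strength: float = 0.0
    group_effect: float = 0.0
    n_modules: int = 3
    modulator_timescale: float = 45.0
    n_sites: int = 1
    site_shift: float = 0.0
    site_scale: float = 1.0
    score_coefficients: dict[int, float] = field(default_factory=dict)
    score_noise_sd: float = 0.0
    noise_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rois < 3:
            raise ValueError("n_rois must be >= 3")
        if self.site_scale <= 0:
            raise ValueError("site_scale must be positive")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        w_frames = int(round(20.0 / self.tr_seconds))
        if self.n_timepoints < 4 * w_frames:
            raise ValueError("n_timepoints must be >= 4 x window length in frames")
        if not 0 <= self.group_effect <= self.within_strength:
            raise ValueError("group_effect must lie in [0, within_strength]")


def gen_cohort(spec: CohortSpec):
    """Generate (time-series list, phenotype table) for a two-group cohort.

    Each subject draws from an independently spawned random stream, so site
    effects or other per-subject options never perturb another subject's
    realization; phenotype covariates come from a separate master stream.
    """
    rng = np.random.default_rng(spec.seed)
    n_total = 2 * spec.n_subjects_per_group
    subject_rngs = [np.random.default_rng(s) for s in np.random.SeedSequence(spec.seed).spawn(n_total)]
    assignment = default_module_assignment(spec.n_rois, spec.n_modules)
    strengths = {
        "case": spec.within_strength,
        "control": spec.within_strength - spec.group_effect,
    }
    ts_list: list[ROITimeSeries] = []
    rows = []
    idx = 0
    for group in ("case", "control"):
        mspec = MetaModuleSpec(
            module_assignment=assignment,
            within_strength=strengths[group],
            between_strength=min(spec.between_strength, strengths[group]),
            modulator_timescale=spec.modulator_timescale,
        )
        for _ in range(spec.n_subjects_per_group):
            sid = f"sub-{idx:04d}"
            site = idx % spec.n_sites
            sub_rng = subject_rngs[idx]
            ts = gen_meta_module_timeseries(
                mspec, spec.n_rois, spec.n_timepoints, spec.noise_sd, sub_rng,
                tr_seconds=spec.tr_seconds, subject_id=sid,
            )
            shifted_site = spec.n_sites > 1 and site >= spec.n_sites // 2
            if shifted_site and spec.site_shift != 0:
                nuisance = _slow_process(1, spec.n_timepoints, spec.tr_seconds, 40.0, sub_rng)[0]
                ts.data = ts.data + spec.site_shift * nuisance[:, None]
            if shifted_site and spec.site_scale != 1.0:
                ts.data = ts.data * spec.site_scale
            ts_list.append(ts)
            rows.append(
                {
                    "subject_id": sid,
                    "group": group,
                    "site_id": f"site{site}",
                    "age": float(rng.uniform(6, 40)),
                    "sex": "M" if rng.random() < 0.8 else "F",
                }
            )
            idx += 1
    pheno = pd.DataFrame(rows)
    if spec.score_coefficients:
        feats = np.stack([_mc_features(ts) for ts in ts_list])
        pheno["score_ADOS_total"] = gen_behavioral_scores(
            feats, spec.score_coefficients, spec.score_noise_sd, rng
        )
    return ts_list, pheno


def _mc_features(ts: ROITimeSeries) -> np.ndarray:
    stream = compute_dfc_stream(ts)
    mc = compute_mc(stream).compact
    iu = np.triu_indices(mc.shape[0], k=1)
    return mc[iu]


def gen_behavioral_scores(
    mc_features: np.ndarray,
    score_coefficients: dict[int, float],
    noise_sd: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Scores linearly tied to selected MC features, plus Gaussian noise."""
    mc_features = np.asarray(mc_features, dtype=float)
    n_feat = mc_features.shape[1]
    for k in score_coefficients:
        if not 0 <= k < n_feat:
            raise ValueError(f"coefficient key {k} outside feature range [0, {n_feat})")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    scores = np.zeros(mc_features.shape[0])
    for k, coef in score_coefficients.items():
        scores += coef * mc_features[:, k]
    if noise_sd > 0:
        scores = scores + rng.normal(0.0, noise_sd, size=scores.shape)
    return scores


def module_contrast(mc: MCMatrix | np.ndarray, assignment: dict[int, int]) -> tuple[float, float]:
    """(mean within-module MC, mean between-module MC) over non-background links."""
    m = mc.compact if isinstance(mc, MCMatrix) else np.asarray(mc)
    mods = np.array([assignment[a] for a in range(m.shape[0])])
    keep = mods != BACKGROUND
    idx = np.where(keep)[0]
    within, between = [], []
    for ai, a in enumerate(idx):
        for b in idx[ai + 1 :]:
            (within if mods[a] == mods[b] else between).append(m[a, b])
    return float(np.mean(within)), float(np.mean(between))
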