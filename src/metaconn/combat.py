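"""ComBat-style empirical-Bayes harmonization of multi-site features.

Model: y_ijv = alpha_v + X_ij' beta_v + gamma_iv + delta_iv * eps_ijv for
site i, subject j, feature v.  Features are standardized against the grand
mean, covariate effects and the pooled variance; per-site additive effects
gamma are shrunk toward a normal prior and multiplicative effects delta^2
toward an inverse-gamma prior by method-of-moments empirical Bayes with
iterative conditional updates.  Harmonized values remove (gamma*, delta*)
while restoring the covariate effects, so biology is preserved and site
location/scale is not.

Within a cross-validation fold the model is fit on training subjects only
and applied to test subjects with frozen parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["CombatModel", "combat_fit", "combat_apply"]


@dataclass
class CombatModel:
    sites: list[str]
    alpha: np.ndarray            # grand mean per feature
    beta: np.ndarray             # covariates x features (may be empty)
    var_pooled: np.ndarray       # pooled residual variance per feature
    gamma_star: np.ndarray       # sites x features, standardized units
    delta2_star: np.ndarray      # sites x features, variance ratios
    identity: bool = False       # single-site fit: harmonization is a no-op

    def site_row(self, site: str) -> int:
        try:
            return self.sites.index(site)
        except ValueError:
            raise KeyError(f"site {site!r} was not present at fit time") from None

    def additive_effect(self, site: str) -> np.ndarray:
        """Estimated per-feature additive site effect in original units."""
        return self.gamma_star[self.site_row(site)] * np.sqrt(self.var_pooled)

    def scale_effect(self, site: str) -> np.ndarray:
        """Estimated per-feature site scale relative to the pooled SD."""
        return np.sqrt(self.delta2_star[self.site_row(site)])


def _design(site_ids: np.ndarray, sites: list[str], covariates: np.ndarray | None):
    n = len(site_ids)
    site_dummies = np.zeros((n, len(sites)))
    for r, s in enumerate(sites):
        site_dummies[site_ids == s, r] = 1.0
    if covariates is None or covariates.size == 0:
        cov = np.empty((n, 0))
    else:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        cov = cov - cov.mean(axis=0)  # center so site intercepts absorb the mean
    return np.hstack([site_dummies, cov]), cov


# -- empirical-Bayes prior moments (method of moments) ----------------------

def _aprior(d2: np.ndarray) -> float:
    m, s2 = d2.mean(), d2.var()
    return (2 * s2 + m**2) / s2 if s2 > 0 else 100.0


def _bprior(d2: np.ndarray) -> float:
    m, s2 = d2.mean(), d2.var()
    return (m * s2 + m**3) / s2 if s2 > 0 else 1.0


def _it_sol(sdat, g_hat, d_hat, g_bar, t2, a, b, tol=1e-4, max_iter=500):
    """Iterative conditional EB updates for one site (standard parametric scheme)."""
    n = sdat.shape[0]
    g_old, d_old = g_hat.copy(), d_hat.copy()
    for _ in range(max_iter):
        g_new = (t2 * n * g_hat + d_old * g_bar) / (t2 * n + d_old)
        sum2 = ((sdat - g_new[None, :]) ** 2).sum(axis=0)
        d_new = (0.5 * sum2 + b) / (n / 2.0 + a - 1.0)
        change = max(
            np.abs(g_new - g_old).max() / (np.abs(g_old).max() + 1e-12),
            np.abs(d_new - d_old).max() / (np.abs(d_old).max() + 1e-12),
        )
        g_old, d_old = g_new, d_new
        if change < tol:
            break
    return g_old, d_old


def combat_fit(
    features: np.ndarray,
    site_ids,
    covariates: np.ndarray | None = None,
    eb: bool = True,
) -> CombatModel:
    """Fit location/scale site-effect model on a subjects x features matrix."""
    y = np.asarray(features, dtype=float)
    site_ids = np.asarray(site_ids)
    sites = sorted(set(site_ids.tolist()))
    if len(sites) < 2:
        n_feat = y.shape[1]
        return CombatModel(
            sites=sites,
            alpha=y.mean(axis=0),
            beta=np.empty((0, n_feat)),
            var_pooled=np.maximum(y.var(axis=0), 1e-12),
            gamma_star=np.zeros((len(sites), n_feat)),
            delta2_star=np.ones((len(sites), n_feat)),
            identity=True,
        )
    counts = np.array([(site_ids == s).sum() for s in sites])
    if (counts < 2).any():
        small = [s for s, c in zip(sites, counts) if c < 2]
        raise ValueError(f"each site needs >= 2 subjects; too few at {small}")
    x, cov = _design(site_ids, sites, covariates)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("rank-deficient design (collinear covariates or empty site)")
    n, n_feat = y.shape
    b_hat, *_ = np.linalg.lstsq(x, y, rcond=None)
    site_means = b_hat[: len(sites)]
    beta = b_hat[len(sites) :]
    alpha = (counts / n) @ site_means
    stand_mean = alpha[None, :] + cov @ beta
    var_pooled = np.maximum(((y - x @ b_hat) ** 2).mean(axis=0), 1e-12)
    sdat = (y - stand_mean) / np.sqrt(var_pooled)

    g_hat = np.stack([sdat[site_ids == s].mean(axis=0) for s in sites])
    d_hat = np.stack([sdat[site_ids == s].var(axis=0, ddof=1) for s in sites])
    if eb:
        g_star = np.empty_like(g_hat)
        d_star = np.empty_like(d_hat)
        for r, s in enumerate(sites):
            g_bar, t2 = g_hat[r].mean(), g_hat[r].var()
            if t2 == 0:
                t2 = 1e-12
            a, b = _aprior(d_hat[r]), _bprior(d_hat[r])
            g_star[r], d_star[r] = _it_sol(
                sdat[site_ids == s], g_hat[r], d_hat[r], g_bar, t2, a, b
            )
    else:
        g_star, d_star = g_hat, d_hat
    d_star = np.maximum(d_star, 1e-12)
    return CombatModel(
        sites=sites, alpha=alpha, beta=beta, var_pooled=var_pooled,
        gamma_star=g_star, delta2_star=d_star,
    )


def _rows(site_ids, sites):
    lut = {s: r for r, s in enumerate(sites)}
    return np.array([lut[s] for s in site_ids])


def combat_apply(
    features: np.ndarray,
    model: CombatModel,
    site_ids,
    covariates: np.ndarray | None = None,
) -> np.ndarray:
    """Remove fitted site effects: (y - a - Xb - g*)/d* * sd + a + Xb."""
    y = np.asarray(features, dtype=float)
    if model.identity:
        return y.copy()
    site_ids = np.asarray(site_ids)
    for s in set(site_ids.tolist()):
        model.site_row(s)  # raises on unseen site
    rows = _rows(site_ids, model.sites)
    if covariates is None or model.beta.shape[0] == 0:
        cov_term = 0.0
        if model.beta.shape[0] > 0:
            raise ValueError("model was fit with covariates; provide them at apply time")
    else:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        cov_term = (cov - cov.mean(axis=0)) @ model.beta
    stand_mean = model.alpha[None, :] + cov_term
    sdat = (y - stand_mean) / np.sqrt(model.var_pooled)
    adj = (sdat - model.gamma_star[rows]) / np.sqrt(model.delta2_star[rows])
    return adj * np.sqrt(model.var_pooled) + stand_mean
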