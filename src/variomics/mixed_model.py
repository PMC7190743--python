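"""Per-assay hierarchical model: genotype fixed effects, batch random intercept.

The model is y = X beta + Z u + eps with u ~ N(0, sigma_u^2 I_q) over
batches and eps ~ N(0, sigma_e^2 I_N).  Fitting is REML, profiled over the
variance ratio lambda = sigma_u^2 / sigma_e^2: given lambda, the GLS
fixed-effect estimate and the residual variance have closed forms, so the
optimization is a robust one-dimensional search.  Because the random term
is a single intercept per batch, all weighted cross-products are computed
with the Woodbury identity on per-batch sufficient statistics -- no N x N
matrix is ever formed.

Contrasts against a control genotype use the Satterthwaite approximation:
the effective degrees of freedom of a contrast are
2 f^2 / (grad f' A grad f), where f(theta) is the contrast variance as a
function of the variance components theta = (sigma_u^2, sigma_e^2), the
gradient is taken numerically, and A is the asymptotic covariance of
theta-hat from the finite-difference Hessian of the REML deviance.  When
the variance-ratio estimate hits the zero boundary the fit collapses
exactly to ordinary least squares on genotype means and inference falls
back to the classical pooled t test with N - p degrees of freedom.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class MixedModelFit:
    genotypes: list
    beta_hat: pd.Series
    se_beta: pd.Series
    sigma_u: float
    sigma_e: float
    loglik_reml: float
    residuals: np.ndarray
    adjusted_values: np.ndarray
    data: pd.DataFrame
    flagged: list = field(default_factory=list)
    n: int = 0
    p: int = 0
    _ss: "_SuffStats | None" = None


class _SuffStats:
    """Per-batch sufficient statistics for Woodbury-based weighted products."""

    def __init__(self, X: np.ndarray, y: np.ndarray, batch_idx: np.ndarray, q: int):
        self.X, self.y = X, y
        self.n, self.p = X.shape
        self.q = q
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)
        # S[b] = sum of x rows in batch b (p,), sy[b] = sum of y in batch b
        self.S = np.zeros((q, self.p))
        self.sy = np.zeros(q)
        self.nb = np.zeros(q)
        np.add.at(self.S, batch_idx, X)
        np.add.at(self.sy, batch_idx, y)
        np.add.at(self.nb, batch_idx, 1.0)
        self.batch_idx = batch_idx

    def weighted(self, lam: float):
        """(X'W^-1 X, X'W^-1 y, y'W^-1 y, log|W|) for W = I + lam ZZ'."""
        c = lam / (1.0 + lam * self.nb)  # (q,)
        XtWX = self.XtX - (self.S.T * c) @ self.S
        XtWy = self.Xty - self.S.T @ (c * self.sy)
        ytWy = self.yty - float(c @ (self.sy**2))
        logdetW = float(np.sum(np.log1p(lam * self.nb)))
        return XtWX, XtWy, ytWy, logdetW

    def gls(self, lam: float):
        XtWX, XtWy, ytWy, logdetW = self.weighted(lam)
        beta = np.linalg.solve(XtWX, XtWy)
        quad = ytWy - 2.0 * float(beta @ XtWy) + float(beta @ XtWX @ beta)
        quad = max(quad, 0.0)
        sign, logdetXtWX = np.linalg.slogdet(XtWX)
        return beta, quad, logdetW, logdetXtWX, XtWX

    def profiled_deviance(self, lam: float) -> float:
        beta, quad, logdetW, logdetXtWX, _ = self.gls(lam)
        npp = self.n - self.p
        s2e = quad / npp
        if s2e <= 0:
            return np.inf
        return npp * np.log(s2e) + logdetW + logdetXtWX + npp

    def deviance_theta(self, s2u: float, s2e: float) -> float:
        """REML deviance (-2 loglik, without the 2*pi constant) at
        unprofiled variance components."""
        if s2e <= 0 or s2u < 0:
            return np.inf
        lam = s2u / s2e
        beta, quad, logdetW, logdetXtWX, _ = self.gls(lam)
        npp = self.n - self.p
        return npp * np.log(s2e) + logdetW + logdetXtWX + quad / s2e

    def contrast_variance(self, c: np.ndarray, s2u: float, s2e: float) -> float:
        """f(theta) = c' (X'V^-1 X)^-1 c with V = s2u ZZ' + s2e I."""
        lam = s2u / s2e
        XtWX, _, _, _ = self.weighted(lam)
        return s2e * float(c @ np.linalg.solve(XtWX, c))


def _design(data: pd.DataFrame):
    genotypes = sorted(data["genotype"].astype(str).unique())
    batches = sorted(data["batch"].astype(str).unique())
    g_idx = data["genotype"].astype(str).map({g: i for i, g in enumerate(genotypes)}).to_numpy()
    b_idx = data["batch"].astype(str).map({b: i for i, b in enumerate(batches)}).to_numpy()
    n, p, q = len(data), len(genotypes), len(batches)
    X = np.zeros((n, p))
    X[np.arange(n), g_idx] = 1.0
    return genotypes, batches, X, g_idx, b_idx, q


def _confounded_genotypes(data: pd.DataFrame) -> list:
    """Genotypes confounded with a batch that contains only them."""
    flagged = []
    by_geno = data.groupby("genotype")["batch"].agg(set)
    by_batch = data.groupby("batch")["genotype"].agg(set)
    for g, bset in by_geno.items():
        if len(bset) == 1 and by_batch[next(iter(bset))] == {g}:
            flagged.append(str(g))
    return flagged


def fit_mixed_model(data: pd.DataFrame) -> MixedModelFit:
    """REML fit of genotype means with a batch random intercept.

    ``data`` needs columns genotype, batch, value (one assay at a time).
    With a single batch, or when the batch variance estimate hits zero,
    the fit reduces exactly to ordinary least squares on genotype means.
    """
    if "assay" in data.columns and data["assay"].nunique() > 1:
        raise ValueError("fit one assay at a time; got multiple assay labels")
    data = data.reset_index(drop=True)
    genotypes, batches, X, g_idx, b_idx, q = _design(data)
    if len(genotypes) < 2:
        raise ValueError("need at least two genotypes")
    y = data["value"].to_numpy(dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError("need more observations than genotypes")

    flagged = _confounded_genotypes(data)
    if flagged:
        warnings.warn(
            f"genotypes confounded with a single private batch: {', '.join(flagged)}",
            stacklevel=2,
        )

    ss = _SuffStats(X, y, b_idx, q)

    # OLS baseline (exact group means: X'X is diagonal under cell-means coding)
    counts = np.diag(ss.XtX)
    beta_ols = ss.Xty / counts
    rss_ols = ss.yty - float(beta_ols @ ss.Xty)
    scale = max(1.0, ss.yty / n)

    if rss_ols <= 1e-12 * scale or q == 1:
        lam_hat = 0.0
    else:
        grid = np.concatenate(([0.0], np.logspace(-8, 8, 81)))
        devs = np.array([ss.profiled_deviance(l) for l in grid])
        k = int(np.argmin(devs))
        lam_hat = grid[k]
        if 0 < k < len(grid) - 1:
            res = optimize.minimize_scalar(
                ss.profiled_deviance,
                bounds=(grid[k - 1], grid[k + 1]),
                method="bounded",
                options={"xatol": 1e-12},
            )
            if res.fun <= devs[k]:
                lam_hat = float(res.x)
        if ss.profiled_deviance(0.0) <= ss.profiled_deviance(lam_hat):
            lam_hat = 0.0

    npp = n - p
    if lam_hat == 0.0:
        beta = beta_ols
        quad = max(rss_ols, 0.0)
        s2e = quad / npp
        s2u = 0.0
        se_beta = np.sqrt(s2e / counts)
        u = np.zeros(q)
        if q > 1 and rss_ols > 1e-12 * scale:
            logging.getLogger("variomics").info(
                "batch variance estimate at the zero boundary; inference falls back to OLS"
            )
        dev = ss.deviance_theta(0.0, s2e) if s2e > 0 else -np.inf
    else:
        beta, quad, logdetW, logdetXtWX, XtWX = ss.gls(lam_hat)
        s2e = quad / npp
        s2u = lam_hat * s2e
        se_beta = np.sqrt(s2e * np.diag(np.linalg.inv(XtWX)))
        resid_fixed_b = ss.sy - ss.S @ beta  # per-batch sums of y - X beta
        u = (lam_hat / (1.0 + lam_hat * ss.nb)) * resid_fixed_b
        dev = ss.deviance_theta(s2u, s2e)

    fixed_pred = X @ beta
    zu = u[b_idx]
    residuals = y - fixed_pred - zu
    adjusted = fixed_pred + residuals
    loglik = -0.5 * (dev + npp * _LOG2PI) if np.isfinite(dev) else np.inf

    return MixedModelFit(
        genotypes=genotypes,
        beta_hat=pd.Series(beta, index=genotypes, name="beta"),
        se_beta=pd.Series(se_beta, index=genotypes, name="se"),
        sigma_u=float(np.sqrt(s2u)),
        sigma_e=float(np.sqrt(s2e)),
        loglik_reml=float(loglik),
        residuals=residuals,
        adjusted_values=adjusted,
        data=data,
        flagged=flagged,
        n=n,
        p=p,
        _ss=ss,
    )


def _satterthwaite_df(ss: _SuffStats, c: np.ndarray, s2u: float, s2e: float, npp: int) -> float:
    f0 = ss.contrast_variance(c, s2u, s2e)
    theta = np.array([s2u, s2e])
    h = np.maximum(1e-10, 1e-5 * np.maximum(theta, s2e))

    def cv(t):
        return ss.contrast_variance(c, max(t[0], 0.0), t[1])

    grad = np.zeros(2)
    for i in range(2):
        e = np.zeros(2)
        e[i] = h[i]
        grad[i] = (cv(theta + e) - cv(theta - e)) / (2 * h[i])

    def dev(t):
        return ss.deviance_theta(max(t[0], 0.0), t[1])

    H = np.zeros((2, 2))
    for i in range(2):
        for j in range(2):
            ei, ej = np.zeros(2), np.zeros(2)
            ei[i], ej[j] = h[i], h[j]
            H[i, j] = (
                dev(theta + ei + ej) - dev(theta + ei - ej) - dev(theta - ei + ej) + dev(theta - ei - ej)
            ) / (4 * h[i] * h[j])
    try:
        A = 2.0 * np.linalg.inv(H)  # asymptotic covariance of theta-hat
        denom = float(grad @ A @ grad)
        df = 2.0 * f0**2 / denom if denom > 0 else float(npp)
    except np.linalg.LinAlgError:
        df = float(npp)
    if not np.isfinite(df) or df <= 0:
        df = float(npp)
    return float(min(df, npp))


def contrast_pvalues(fit: MixedModelFit, contrast_group: str, alpha: float = 0.05) -> pd.DataFrame:
    """Two-sided contrasts of every genotype against ``contrast_group``.

    Returns a frame with genotype, contrast_group, estimate, se,
    df_satterthwaite and p_value.  In the zero-residual-variance limit the
    convention is p = 1 for an exactly-zero estimate and p = 0 otherwise.
    """
    if contrast_group not in fit.genotypes:
        raise ValueError(f"contrast group {contrast_group!r} was not fitted")
    ss = fit._ss
    npp = fit.n - fit.p
    s2u, s2e = fit.sigma_u**2, fit.sigma_e**2
    i_c = fit.genotypes.index(contrast_group)
    rows = []
    for g in fit.genotypes:
        if g == contrast_group:
            continue
        i_g = fit.genotypes.index(g)
        c = np.zeros(fit.p)
        c[i_g], c[i_c] = 1.0, -1.0
        est = float(fit.beta_hat.iloc[i_g] - fit.beta_hat.iloc[i_c])
        if s2e == 0.0:
            se, df = 0.0, float(npp)
            p = 1.0 if est == 0.0 else 0.0
        elif s2u == 0.0:
            var = ss.contrast_variance(c, 0.0, s2e)
            se, df = float(np.sqrt(var)), float(npp)
            p = 2.0 * stats.t.sf(abs(est) / se, df) if se > 0 else (1.0 if est == 0 else 0.0)
        else:
            var = ss.contrast_variance(c, s2u, s2e)
            se = float(np.sqrt(var))
            df = _satterthwaite_df(ss, c, s2u, s2e, npp)
            p = 2.0 * stats.t.sf(abs(est) / se, df)
        rows.append((g, contrast_group, est, se, df, float(p)))
    return pd.DataFrame(
        rows, columns=["genotype", "contrast_group", "estimate", "se", "df_satterthwaite", "p_value"]
    )


def adjust_for_random_effects(fit: MixedModelFit) -> np.ndarray:
    """Per-row adjusted values: fixed-effect prediction plus residual
    (the observed value with the estimated batch contribution removed)."""
    return fit.adjusted_values.copy()


def fit_summary(fit: MixedModelFit, wt_label: str, null_label: str) -> pd.DataFrame:
    """Per-genotype table: beta, se, n, p vs WT and p vs null."""
    counts = fit.data.groupby("genotype").size()
    p_wt = contrast_pvalues(fit, wt_label).set_index("genotype")["p_value"]
    p_null = contrast_pvalues(fit, null_label).set_index("genotype")["p_value"]
    out = pd.DataFrame(
        {
            "genotype": fit.genotypes,
            "beta": fit.beta_hat.to_numpy(),
            "se": fit.se_beta.to_numpy(),
            "n": [int(counts[g]) for g in fit.genotypes],
        }
    )
    out["p_vs_wt"] = [p_wt.get(g, np.nan) for g in fit.genotypes]
    out["p_vs_null"] = [p_null.get(g, np.nan) for g in fit.genotypes]
    return out
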