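"""Differential-expression engines.

Two engines are offered, selected by platform and user preference:

* a weighted least-squares linear model per gene with empirical-Bayes
  moderation of the residual variances (both platforms; on counts it is
  applied to precision-weighted log-CPM),
* a negative-binomial log-link GLM per gene with Cox-Reid adjusted
  profile-likelihood dispersion estimation and likelihood-ratio contrast
  tests (raw counts only).

Both report, per contrast and per gene: log2 fold change, average
expression, a test statistic, a p-value and a Benjamini-Hochberg adjusted
p-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy import optimize, special, stats

from .design import MODERATED_LM, NB_GLM, SampleDesign, build_contrasts, build_targets, validate_design
from .io import ExpressionMatrix, MICROARRAY, RNASEQ, ValidationError
from .normalize import NormalizedData, log_cpm, precision_weights, tmm_factors

RESULT_COLUMNS = ["logFC", "ave_expr", "stat", "pvalue", "adj_pvalue"]

#: IRLS controls for the NB GLM
IRLS_MAX_ITER = 50
IRLS_TOL = 1e-8
IRLS_RIDGE = 1e-6

#: floor on NB dispersions
PHI_FLOOR = 1e-6
#: prior weight for tagwise dispersion shrinkage, in residual-df equivalents
DISPERSION_PRIOR_DF = 10.0


@dataclass
class LinearFit:
    """Per-gene weighted least-squares fit summarized at the contrasts.

    ``coefficients`` are contrast estimates in log2 units;
    ``stdev_unscaled`` the corresponding unscaled standard errors
    (multiply by the residual sd to get a standard error); ``sigma2`` the
    residual variance; ``df_resid`` the shared residual degrees of freedom.
    """

    coefficients: pd.DataFrame
    stdev_unscaled: pd.DataFrame
    sigma2: pd.Series
    df_resid: float
    amean: pd.Series


@dataclass
class ModeratedStats:
    """Empirical-Bayes moderated statistics for a :class:`LinearFit`."""

    df_prior: float
    s2_prior: float
    s2_post: pd.Series
    t: pd.DataFrame
    pvalue: pd.DataFrame
    adj_pvalue: pd.DataFrame
    df_total: float


def fit_contrast_lm(
    norm: NormalizedData, design: pd.DataFrame, contrasts: pd.DataFrame
) -> LinearFit:
    """Gene-wise weighted least squares with contrast summaries.

    The design is a samples x classes indicator (or any full-rank model)
    matrix; contrasts map classes to tested combinations.  With no weights
    this reduces to ordinary least squares on class means.
    """
    y = norm.logexpr.to_numpy(dtype=float)
    X = design.to_numpy(dtype=float)
    n, p = X.shape
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        raise ValidationError("rank-deficient design matrix")
    df_resid = n - rank
    if df_resid < 1:
        raise ValidationError("no residual degrees of freedom")
    C = contrasts.reindex(design.columns).to_numpy(dtype=float)  # p x m

    G = y.shape[0]
    if norm.weights is None:
        xtx = X.T @ X
        xtx_inv = np.linalg.inv(xtx)
        beta = y @ X @ xtx_inv.T  # G x p
        resid = y - beta @ X.T
        sigma2 = (resid ** 2).sum(axis=1) / df_resid
        cov_c = np.sqrt(np.einsum("im,ij,jm->m", C, xtx_inv, C))  # m
        stdev = np.broadcast_to(cov_c, (G, C.shape[1])).copy()
    else:
        w = norm.weights.to_numpy(dtype=float)
        if (w <= 0).any():
            raise ValidationError("precision weights must be positive")
        A = np.einsum("ni,gn,nj->gij", X, w, X)  # G x p x p
        b = np.einsum("ni,gn->gi", X, w * y)
        beta = np.linalg.solve(A, b[..., None])[..., 0]
        resid = y - beta @ X.T
        sigma2 = (w * resid ** 2).sum(axis=1) / df_resid
        A_inv = np.linalg.inv(A)
        stdev = np.sqrt(np.einsum("im,gij,jm->gm", C, A_inv, C))

    est = beta @ C  # G x m, log2 units
    genes = norm.logexpr.index
    cols = list(contrasts.columns)
    return LinearFit(
        coefficients=pd.DataFrame(est, index=genes, columns=cols),
        stdev_unscaled=pd.DataFrame(stdev, index=genes, columns=cols),
        sigma2=pd.Series(sigma2, index=genes, name="sigma2"),
        df_resid=float(df_resid),
        amean=pd.Series(y.mean(axis=1), index=genes, name="ave_expr"),
    )


def trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        raise ValueError("trigamma inverse requires a positive argument")
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        step = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + step
        if abs(step) < 1e-10 * x:
            break
    return float(x)


def estimate_prior(sigma2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match the prior (df0, s0^2) of a scaled-F model for the
    gene-wise variances.

    Works on log variances: the excess of their observed spread over the
    chi-square sampling spread identifies the prior degrees of freedom via
    trigamma inversion.  If the observed spread does not exceed the
    sampling spread, the prior is infinite (all genes share one variance).
    """
    s2 = np.asarray(sigma2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        raise ValidationError("need >= 2 genes with positive residual variance")
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1)
    if evar < 1e-12:
        # degenerate: all variances numerically identical — the prior is a
        # point mass at that value and no sampling-bias correction applies
        return np.inf, float(np.exp(z.mean()))
    expected = special.polygamma(1, df / 2.0)
    excess = evar - expected
    if excess <= 0:
        return np.inf, float(np.exp(emean))
    df0 = 2.0 * trigamma_inverse(excess)
    s02 = np.exp(emean + special.digamma(df0 / 2.0) - np.log(df0 / 2.0))
    return float(df0), float(s02)


def moderate_ebayes(
    fit: LinearFit, prior: tuple[float, float] | None = None
) -> ModeratedStats:
    """Empirical-Bayes variance moderation and moderated t-statistics.

    Gene-wise residual variances are shrunk toward a common prior value
    estimated from all genes; the posterior variance is the
    degrees-of-freedom-weighted average (d0*s0^2 + d_g*s_g^2)/(d0 + d_g),
    and the moderated t is the contrast estimate over its posterior
    standard error, on d0 + d_g degrees of freedom.

    ``prior`` overrides the estimated ``(d0, s0^2)``; d0 -> 0 recovers the
    ordinary t-statistic and d0 = inf a pooled-variance z-like statistic.
    """
    s2 = fit.sigma2.to_numpy(dtype=float)
    if not (s2 > 0).any():
        raise ValidationError("all residual variances are zero; nothing to moderate")
    df0, s02 = prior if prior is not None else estimate_prior(s2, fit.df_resid)
    if np.isinf(df0):
        s2_post = np.full_like(s2, s02)
        df_total = np.inf
    else:
        s2_post = (df0 * s02 + fit.df_resid * s2) / (df0 + fit.df_resid)
        df_total = df0 + fit.df_resid

    se = fit.stdev_unscaled.to_numpy() * np.sqrt(s2_post)[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = fit.coefficients.to_numpy() / se
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    adj = np.column_stack([bh_adjust(p[:, j]) for j in range(p.shape[1])])

    genes, cols = fit.coefficients.index, fit.coefficients.columns
    return ModeratedStats(
        df_prior=df0,
        s2_prior=s02,
        s2_post=pd.Series(s2_post, index=genes, name="s2_post"),
        t=pd.DataFrame(t, index=genes, columns=cols),
        pvalue=pd.DataFrame(p, index=genes, columns=cols),
        adj_pvalue=pd.DataFrame(adj, index=genes, columns=cols),
        df_total=df_total,
    )


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    NaN entries are ignored (and returned as NaN).
    """
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    if ((pv < 0) | (pv > 1)).any():
        raise ValidationError("p-values must lie in [0, 1]")
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    res = np.empty(m)
    res[order] = adj
    out[ok] = res
    return out


def moderated_result(
    fit: LinearFit, mod: ModeratedStats
) -> dict[str, pd.DataFrame]:
    """Assemble per-contrast result tables from a moderated fit."""
    tables = {}
    for c in fit.coefficients.columns:
        tables[c] = pd.DataFrame(
            {
                "logFC": fit.coefficients[c],
                "ave_expr": fit.amean,
                "stat": mod.t[c],
                "pvalue": mod.pvalue[c],
                "adj_pvalue": mod.adj_pvalue[c],
            }
        )
    return tables


# ---------------------------------------------------------------------------
# negative-binomial GLM engine


def _nb_loglik(y: np.ndarray, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Per-gene NB log-likelihood (rows summed over samples); Poisson limit
    for tiny dispersions."""
    mu = np.maximum(mu, 1e-10)
    phi = np.broadcast_to(np.atleast_1d(phi), (y.shape[0],)).astype(float)
    ll = np.empty(y.shape[0])
    tiny = phi < 1e-8
    if tiny.any():
        yt, mt = y[tiny], mu[tiny]
        ll[tiny] = (yt * np.log(mt) - mt - special.gammaln(yt + 1.0)).sum(axis=1)
    if (~tiny).any():
        yn, mn = y[~tiny], mu[~tiny]
        r = (1.0 / phi[~tiny])[:, None]
        ll[~tiny] = (
            special.gammaln(yn + r)
            - special.gammaln(r)
            - special.gammaln(yn + 1.0)
            + r * np.log(r / (r + mn))
            + yn * np.log(mn / (r + mn))
        ).sum(axis=1)
    return ll


def _nb_irls(
    y: np.ndarray, X: np.ndarray, offset: np.ndarray, phi
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Fit log-link NB GLMs for all genes at once by IRLS.

    Returns (beta, mu, loglik, converged).  Singular steps are ridged;
    genes that fail to converge within the iteration cap are flagged.
    """
    G, n = y.shape
    p = X.shape[1]
    phi_vec = np.broadcast_to(np.atleast_1d(np.asarray(phi, dtype=float)), (G,))
    mu = np.maximum(y + 0.5, 0.5)
    eta = np.log(mu)
    ll = _nb_loglik(y, mu, phi_vec)
    beta = np.zeros((G, p))
    converged = np.zeros(G, dtype=bool)
    eye = np.eye(p)
    for _ in range(IRLS_MAX_ITER):
        active = ~converged
        if not active.any():
            break
        mu_a = mu[active]
        w = mu_a / (1.0 + phi_vec[active, None] * mu_a)
        z = (eta[active] - offset[None, :]) + (y[active] - mu_a) / mu_a
        A = np.einsum("ni,gn,nj->gij", X, w, X)
        b = np.einsum("ni,gn->gi", X, w * z)
        try:
            beta_new = np.linalg.solve(A, b[..., None])[..., 0]
        except np.linalg.LinAlgError:
            beta_new = np.linalg.solve(
                A + IRLS_RIDGE * eye[None, :, :], b[..., None]
            )[..., 0]
        bad = ~np.isfinite(beta_new).all(axis=1)
        if bad.any():
            beta_new[bad] = np.linalg.solve(
                A[bad] + IRLS_RIDGE * eye[None, :, :], b[bad][..., None]
            )[..., 0]
        eta_new = np.clip(offset[None, :] + beta_new @ X.T, -30.0, 30.0)
        mu_new = np.exp(eta_new)
        ll_new = _nb_loglik(y[active], mu_new, phi_vec[active])
        # step-halve genes whose likelihood got worse
        worse = ll_new < ll[active] - 1e-12
        if worse.any():
            half = beta_new.copy()
            for _h in range(8):
                if not worse.any():
                    break
                half[worse] = 0.5 * (half[worse] + beta[active][worse])
                eta_h = np.clip(offset[None, :] + half[worse] @ X.T, -30.0, 30.0)
                mu_h = np.exp(eta_h)
                ll_h = _nb_loglik(y[active][worse], mu_h, phi_vec[active][worse])
                idx = np.where(worse)[0]
                beta_new[idx] = half[idx]
                eta_new[idx] = eta_h
                mu_new[idx] = mu_h
                improved = ll_h >= ll[active][worse] - 1e-12
                ll_new[idx] = ll_h
                worse[idx[improved]] = False
        done = np.abs(ll_new - ll[active]) < IRLS_TOL * (np.abs(ll_new) + 1.0)
        beta[active] = beta_new
        eta[active] = eta_new
        mu[active] = mu_new
        ll[active] = ll_new
        conv_idx = np.where(active)[0][done]
        converged[conv_idx] = True
    return beta, mu, ll, converged


def _cr_adjustment(mu: np.ndarray, X: np.ndarray, phi) -> np.ndarray:
    """Cox-Reid adjustment 0.5 * logdet(X' W X) per gene."""
    phi_vec = np.broadcast_to(np.atleast_1d(np.asarray(phi, dtype=float)), (mu.shape[0],))
    w = mu / (1.0 + phi_vec[:, None] * mu)
    A = np.einsum("ni,gn,nj->gij", X, w, X)
    sign, logdet = np.linalg.slogdet(A + 1e-12 * np.eye(X.shape[1])[None])
    return 0.5 * logdet


def _apl(y: np.ndarray, X: np.ndarray, offset: np.ndarray, phi) -> np.ndarray:
    """Cox-Reid adjusted profile log-likelihood per gene at dispersion phi."""
    _, mu, ll, _ = _nb_irls(y, X, offset, phi)
    return ll - _cr_adjustment(mu, X, phi)


def nb_dispersion(
    counts: ExpressionMatrix,
    design: pd.DataFrame,
    factors: pd.Series | None = None,
) -> pd.Series:
    """Estimate per-gene NB dispersions.

    A common dispersion maximizes the Cox-Reid adjusted profile likelihood
    pooled over genes; per-gene dispersions are then shrunk toward it by
    weighted-likelihood averaging with a prior weight equivalent to
    ``DISPERSION_PRIOR_DF`` residual degrees of freedom.  Dispersions are
    floored at ``PHI_FLOOR``.
    """
    y = counts.values.to_numpy(dtype=float)
    X = design.to_numpy(dtype=float)
    n, p = X.shape
    df_resid = n - np.linalg.matrix_rank(X)
    if df_resid < 1:
        raise ValidationError(
            "dispersion estimation needs replication (residual df >= 1)"
        )
    lib = y.sum(axis=0)
    f = np.ones(n) if factors is None else factors.reindex(counts.sample_ids).to_numpy(dtype=float)
    offset = np.log(lib * f)

    # drop all-zero genes from estimation; they carry no information
    informative = y.sum(axis=1) > 0
    y_est = y[informative]
    if y_est.shape[0] == 0:
        raise ValidationError("all genes have zero counts")

    def neg_pooled(log10_phi: float) -> float:
        return -float(_apl(y_est, X, offset, 10.0 ** log10_phi).sum())

    res = optimize.minimize_scalar(
        neg_pooled, bounds=(-6.0, 0.7), method="bounded",
        options={"xatol": 1e-3},
    )
    common = max(10.0 ** res.x, PHI_FLOOR)

    # tagwise: weighted likelihood over a grid spanning the common value
    grid = np.clip(common * 2.0 ** np.linspace(-5, 5, 11), PHI_FLOOR, 10.0)
    apl_grid = np.column_stack([_apl(y_est, X, offset, g) for g in grid])
    prior_n = DISPERSION_PRIOR_DF / max(df_resid, 1)
    shared = apl_grid.mean(axis=0)
    wl = apl_grid + prior_n * shared[None, :]
    best = np.argmax(wl, axis=1)
    phi_est = grid[best]

    phi = np.full(y.shape[0], common)
    phi[informative] = phi_est
    return pd.Series(np.maximum(phi, PHI_FLOOR), index=counts.values.index, name="dispersion")


def nb_glm_test(
    counts: ExpressionMatrix,
    design: pd.DataFrame,
    contrasts: pd.DataFrame,
    dispersion: pd.Series,
    factors: pd.Series | None = None,
) -> dict[str, pd.DataFrame]:
    """Likelihood-ratio tests of each contrast under per-gene NB GLMs.

    Each contrast is tested by refitting with the contrast constrained to
    zero (the design projected on the contrast's null space) and comparing
    likelihoods on one degree of freedom.  log fold changes are reported in
    log2 units; p-values are BH-adjusted within each contrast.  Genes with
    zero counts across a contrast's classes, or that fail to converge, get
    NA statistics.
    """
    y = counts.values.to_numpy(dtype=float)
    X = design.to_numpy(dtype=float)
    n = X.shape[0]
    lib = y.sum(axis=0)
    f = np.ones(n) if factors is None else factors.reindex(counts.sample_ids).to_numpy(dtype=float)
    offset = np.log(lib * f)
    phi = dispersion.reindex(counts.values.index).to_numpy(dtype=float)

    beta_full, mu_full, ll_full, conv_full = _nb_irls(y, X, offset, phi)
    ave = log_cpm(counts, factors=factors).mean(axis=1)

    tables: dict[str, pd.DataFrame] = {}
    for cname in contrasts.columns:
        c = contrasts[cname].reindex(design.columns).to_numpy(dtype=float)
        N = sla.null_space(c[None, :])  # p x (p-1)
        Xr = X @ N
        _, _, ll_red, conv_red = _nb_irls(y, Xr, offset, phi)
        lr = 2.0 * (ll_full - ll_red)
        lr = np.maximum(lr, 0.0)
        logfc = (beta_full @ c) / np.log(2.0)

        involved = X[:, np.abs(c) > 0].sum(axis=1) > 0
        all_zero = y[:, involved].sum(axis=1) == 0
        bad = all_zero | ~conv_full | ~conv_red
        stat = np.where(bad, np.nan, lr)
        logfc = np.where(all_zero, np.nan, logfc)
        with np.errstate(invalid="ignore"):
            p = stats.chi2.sf(stat, df=1)
        adj = bh_adjust(p)
        tables[cname] = pd.DataFrame(
            {
                "logFC": logfc,
                "ave_expr": ave.to_numpy(),
                "stat": stat,
                "pvalue": p,
                "adj_pvalue": adj,
            },
            index=counts.values.index,
        )
    return tables


def run_differential(
    matrix: ExpressionMatrix, design: SampleDesign
) -> dict[str, pd.DataFrame]:
    """Full differential analysis: one result table per contrast
    (transcription plus each polysome fraction).

    * microarray -> moderated linear model on the values as given;
    * rnaseq + moderated_lm -> TMM factors, precision-weighted moderated
      linear model on log-CPM;
    * rnaseq + nb_glm -> TMM factors, NB dispersion, NB GLM
      likelihood-ratio tests.
    """
    validate_design(design, matrix)
    if design.engine == NB_GLM and design.platform != RNASEQ:
        raise ValidationError("the NB GLM engine requires RNA-seq counts")
    reordered, targets = build_targets(design, matrix)
    contrasts = build_contrasts(design)

    if design.platform == MICROARRAY:
        norm = NormalizedData(
            logexpr=reordered.values,
            weights=None,
            lib_sizes=pd.Series(1.0, index=reordered.sample_ids),
            factors=pd.Series(1.0, index=reordered.sample_ids),
        )
        fit = fit_contrast_lm(norm, targets, contrasts)
        return moderated_result(fit, moderate_ebayes(fit))

    factors = tmm_factors(reordered)
    if design.engine == MODERATED_LM:
        norm = precision_weights(reordered, targets, factors)
        fit = fit_contrast_lm(norm, targets, contrasts)
        return moderated_result(fit, moderate_ebayes(fit))
    dispersion = nb_dispersion(reordered, targets, factors)
    return nb_glm_test(reordered, targets, contrasts, dispersion, factors)
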