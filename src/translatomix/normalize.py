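"""Count filtering, scale-factor normalization, log-expression, precision
weights and MDS quality control.

RNA-seq counts are normalized by trimmed-mean-of-M-values (TMM) scale
factors and converted to log2 counts-per-million.  For the moderated
linear-model engine each observation additionally receives a precision
weight from the fitted mean-variance trend, so that the heteroscedastic
log-counts can be analysed with ordinary weighted least squares.
Microarray input is assumed background-corrected and log2-scale already:
no scaling, unit weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from statsmodels.nonparametric.smoothers_lowess import lowess

from .io import ExpressionMatrix, RNASEQ, ValidationError

# TMM trimming fractions: 30% on the log-ratios (M), 5% on absolute
# intensity (A); standard defaults for this scheme.
TRIM_M = 0.30
TRIM_A = 0.05

DEFAULT_PRIOR = 0.5
DEFAULT_MDS_TOP = 500
LOWESS_SPAN = 0.5


@dataclass
class NormalizedData:
    """log2 expression with optional precision weights and scaling metadata."""

    logexpr: pd.DataFrame
    weights: pd.DataFrame | None
    lib_sizes: pd.Series
    factors: pd.Series

    def __post_init__(self) -> None:
        if self.weights is not None and self.weights.shape != self.logexpr.shape:
            raise ValidationError("weights shape does not match logexpr")
        if (self.lib_sizes <= 0).any():
            raise ValidationError("library sizes must be positive")
        if (self.factors <= 0).any():
            raise ValidationError("scale factors must be positive")
        log_gm = np.log(self.factors.to_numpy(dtype=float)).mean()
        if abs(log_gm) > 1e-9:
            raise ValidationError(
                f"scale factors must have geometric mean 1 (got exp({log_gm:.2e}))"
            )


def filter_min_reads(
    counts: ExpressionMatrix, threshold: int = 256, subset: list[str] | None = None
) -> ExpressionMatrix:
    """Keep genes whose count strictly exceeds ``threshold`` in every
    ``subset`` sample.

    ``subset`` defaults to all samples; the pipeline passes the
    transcription (total RNA) samples.  Row order is preserved, so the
    operation is idempotent.
    """
    if counts.platform != RNASEQ:
        raise ValidationError("read filtering applies to RNA-seq counts only")
    if subset is None:
        subset = counts.sample_ids
    if not subset:
        raise ValidationError("subset must be nonempty")
    missing = [s for s in subset if s not in counts.values.columns]
    if missing:
        raise ValidationError(f"subset samples not in matrix: {missing}")
    keep = (counts.values[list(subset)] > threshold).all(axis=1)
    return counts.subset_genes(counts.values.index[keep])


def _tmm_pair(obs: np.ndarray, ref: np.ndarray, n_obs: float, n_ref: float) -> float:
    """Trimmed, precision-weighted mean of log2 ratios of one sample
    against the reference; returns the log2 scale factor."""
    keep = (obs > 0) & (ref > 0)
    obs, ref = obs[keep], ref[keep]
    if obs.size == 0:
        return 0.0
    p_obs = obs / n_obs
    p_ref = ref / n_ref
    m = np.log2(p_obs / p_ref)
    a = 0.5 * np.log2(p_obs * p_ref)
    # asymptotic (delta-method) variance of M: smaller for high counts
    w = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    finite = np.isfinite(m) & np.isfinite(a) & (w > 0)
    m, a, w = m[finite], a[finite], w[finite]
    n = m.size
    if n == 0:
        return 0.0
    lo_m = np.floor(n * TRIM_M) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * TRIM_A) + 1
    hi_a = n + 1 - lo_a
    rm = rankdata(m)
    ra = rankdata(a)
    keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if not keep.any():
        return 0.0
    f = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])
    if not np.isfinite(f):
        return 0.0
    return f


def tmm_factors(counts: ExpressionMatrix) -> pd.Series:
    """Per-sample TMM scale factors, rescaled to geometric mean 1.

    The reference sample is the column whose 75th percentile of
    library-size-scaled counts is closest to the mean of those percentiles.
    Each factor is 2 to the precision-weighted mean of the log2 ratios
    against the reference, after trimming the most extreme 30% of ratios
    and 5% of intensities on each side.
    """
    x = counts.values.to_numpy(dtype=float)
    lib = x.sum(axis=0)
    if (lib <= 0).any():
        bad = [s for s, l in zip(counts.sample_ids, lib) if l <= 0]
        raise ValidationError(f"samples with zero library size: {bad}")
    f75 = np.quantile(x / lib, 0.75, axis=0)
    ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    log_factors = np.array(
        [
            _tmm_pair(x[:, j], x[:, ref_idx], lib[j], lib[ref_idx])
            for j in range(x.shape[1])
        ]
    )
    log_factors -= log_factors.mean()  # geometric mean 1
    return pd.Series(2.0 ** log_factors, index=counts.sample_ids, name="tmm_factor")


def log_cpm(
    counts: ExpressionMatrix,
    factors: pd.Series | None = None,
    prior: float = DEFAULT_PRIOR,
) -> pd.DataFrame:
    """log2 counts-per-million with a prior count.

    value = log2( (count + prior) / (lib * factor + 2*prior) * 1e6 ).
    """
    x = counts.values.to_numpy(dtype=float)
    lib = x.sum(axis=0)
    if factors is None:
        f = np.ones(x.shape[1])
    else:
        f = factors.reindex(counts.sample_ids).to_numpy(dtype=float)
        if (f <= 0).any() or np.isnan(f).any():
            raise ValidationError("scale factors must be positive for all samples")
    eff = lib * f
    y = np.log2((x + prior) / (eff + 2.0 * prior) * 1e6)
    return pd.DataFrame(y, index=counts.values.index, columns=counts.values.columns)


def _interp_flat(x: np.ndarray, xp: np.ndarray, fp: np.ndarray) -> np.ndarray:
    """Linear interpolation with flat extrapolation beyond the data range."""
    return np.interp(x, xp, fp, left=fp[0], right=fp[-1])


def precision_weights(
    counts: ExpressionMatrix,
    design: pd.DataFrame,
    factors: pd.Series | None = None,
    prior: float = DEFAULT_PRIOR,
    span: float = LOWESS_SPAN,
) -> NormalizedData:
    """Mean-variance precision weights for log-CPM under a design.

    Fits gene-wise least-squares means of log-CPM under the design, fits a
    LOWESS trend of the square root of the residual standard deviation
    against average log2 count, and sets each observation's weight to the
    inverse fourth power of the trend's predicted sqrt-sd at the
    observation's fitted log-count.  High counts are measured more
    precisely and receive larger weights.
    """
    X = design.to_numpy(dtype=float)
    n, p = X.shape
    if n != counts.n_samples:
        raise ValidationError("design rows do not match matrix samples")
    rank = np.linalg.matrix_rank(X)
    if n - rank < 1:
        raise ValidationError("no residual degrees of freedom for the design")
    if n < p:
        raise ValidationError("fewer samples than design columns")

    if factors is None:
        f = np.ones(n)
    else:
        f = factors.reindex(counts.sample_ids).to_numpy(dtype=float)
    x = counts.values.to_numpy(dtype=float)
    lib = x.sum(axis=0)
    eff = lib * f + 1.0
    y = np.log2((x + prior) / eff * 1e6)

    beta, *_ = np.linalg.lstsq(X, y.T, rcond=None)  # p x G
    fitted = (X @ beta).T  # G x n
    resid = y - fitted
    df_resid = n - rank
    sigma = np.sqrt((resid ** 2).sum(axis=1) / df_resid)

    # average log2 count of each gene, on the count (not CPM) scale
    sx = y.mean(axis=1) + np.mean(np.log2(eff)) - np.log2(1e6)
    sy = np.sqrt(sigma)
    trend = lowess(sy, sx, frac=span, it=3, return_sorted=True)
    tx, ty = trend[:, 0], np.maximum(trend[:, 1], 1e-6)

    fitted_logcount = fitted + (np.mean(np.log2(eff)) - np.log2(1e6))
    pred_sqrt_sd = _interp_flat(fitted_logcount.ravel(), tx, ty)
    w = (pred_sqrt_sd ** -4).reshape(fitted.shape)
    if not np.isfinite(w).all() or (w <= 0).any():
        raise ValidationError("non-finite or non-positive precision weights")

    idx, cols = counts.values.index, counts.values.columns
    return NormalizedData(
        logexpr=pd.DataFrame(y, index=idx, columns=cols),
        weights=pd.DataFrame(w, index=idx, columns=cols),
        lib_sizes=pd.Series(lib, index=cols, name="lib_size"),
        factors=pd.Series(f / np.exp(np.mean(np.log(f))), index=cols, name="factor"),
    )


def leading_logfc_distances(logexpr: pd.DataFrame, top: int = DEFAULT_MDS_TOP) -> pd.DataFrame:
    """Pairwise leading log-fold-change distances between samples.

    The distance between two samples is the root-mean-square of the ``top``
    largest absolute log2 fold changes between them — a gene-selection that
    adapts per pair, so technically distinct samples are not diluted by the
    unchanged majority of the transcriptome.
    """
    if top < 1:
        raise ValidationError("top must be >= 1")
    y = logexpr.to_numpy(dtype=float)
    n = y.shape[1]
    top = min(top, y.shape[0])
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            diff2 = (y[:, i] - y[:, j]) ** 2
            largest = np.partition(diff2, len(diff2) - top)[-top:]
            d[i, j] = d[j, i] = np.sqrt(largest.mean())
    return pd.DataFrame(d, index=logexpr.columns, columns=logexpr.columns)


def mds_coordinates(
    logexpr: pd.DataFrame, top: int = DEFAULT_MDS_TOP, dims: int = 2
) -> pd.DataFrame:
    """Classical (metric) MDS of samples on leading-logFC distances.

    Returns a samples x dims coordinate table for QC plots; dimension 1
    captures the dominant axis of between-sample variation (in polysome
    experiments this is typically polysome vs total RNA).
    """
    if logexpr.shape[1] < dims + 1:
        raise ValidationError(
            f"need at least {dims + 1} samples for a {dims}-D MDS plot"
        )
    d = leading_logfc_distances(logexpr, top=top).to_numpy()
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:dims]
    coords = vecs[:, order] * np.sqrt(np.maximum(vals[order], 0.0))
    return pd.DataFrame(
        coords,
        index=logexpr.columns,
        columns=[f"dim{i + 1}" for i in range(dims)],
    )
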