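"""Translational efficiency (TE): condition-dependent change in translation
relative to transcription, per polysome fraction.

Two methods are offered:

* **ratio** — per replicate, the log2 ratio of polysome to total
  expression is formed (replicates paired by their order within class),
  grouped by condition, and the experiment-minus-control contrast of the
  ratios is tested with the moderated linear model (unit weights).
* **interaction** — the type (polysome vs total) x treatment (experiment
  vs control) interaction coefficient of a per-fraction linear model; on
  counts the model is fitted to precision-weighted log-CPM.

On noiseless balanced data both methods return the same TE log2 fold
change: (poly_exp - total_exp) - (poly_ctl - total_ctl).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .classify import Thresholds
from .design import (
    CONTROL,
    EXPERIMENT,
    SampleDesign,
    TRANSCRIPTION,
    build_te_design,
)
from .engines import fit_contrast_lm, moderate_ebayes, moderated_result
from .io import ExpressionMatrix, MICROARRAY, ValidationError
from .normalize import NormalizedData, log_cpm, precision_weights, tmm_factors

RATIO = "ratio"
INTERACTION = "interaction"


def _ordered_class_samples(
    logexpr_columns, design: SampleDesign, condition: str, fraction: int
) -> list[str]:
    """Samples of one class ordered by identifier (the pairing order)."""
    return sorted(
        s
        for s in logexpr_columns
        if design.assignment.get(s) == (condition, fraction)
    )


def ratio_matrix(
    logexpr: pd.DataFrame, design: SampleDesign, fraction: int
) -> pd.DataFrame:
    """Per-replicate log2 polysome/total ratios, control columns first.

    Replicates are paired by their order within class (polysome replicate i
    with total replicate i); unequal replicate counts between a condition's
    polysome and total classes cannot be paired implicitly and raise an
    error asking for an explicit pairing (subset the matrix columns).
    """
    cols = {}
    for cond in (CONTROL, EXPERIMENT):
        poly = _ordered_class_samples(logexpr.columns, design, cond, fraction)
        total = _ordered_class_samples(logexpr.columns, design, cond, TRANSCRIPTION)
        if len(poly) != len(total):
            raise ValidationError(
                f"cannot pair {len(poly)} polysome with {len(total)} total "
                f"replicates for condition {cond!r}; drop or duplicate "
                "samples to pair replicates explicitly"
            )
        label = design.label(cond)
        for i, (ps, ts) in enumerate(zip(poly, total), start=1):
            cols[f"{label}.ratio.{i}"] = logexpr[ps] - logexpr[ts]
    return pd.DataFrame(cols, index=logexpr.index)


def te_ratio_test(
    ratios: pd.DataFrame, design: SampleDesign, fraction: int
) -> pd.DataFrame:
    """Moderated test of experiment vs control log2 ratios for one fraction.

    Column membership is read from the column-name prefix produced by
    :func:`ratio_matrix`.  Requires at least one residual degree of
    freedom, i.e. more than one replicate in some condition.
    """
    ctl_cols = [c for c in ratios.columns if c.startswith(design.control_label + ".")]
    exp_cols = [c for c in ratios.columns if c.startswith(design.experiment_label + ".")]
    if not ctl_cols or not exp_cols:
        raise ValidationError("ratio matrix must contain both conditions")
    n = len(ctl_cols) + len(exp_cols)
    if n - 2 < 1:
        raise ValidationError(
            "a single replicate per condition leaves no residual degrees of "
            "freedom for the ratio test"
        )
    classes = [f"{design.control_label}.te", f"{design.experiment_label}.te"]
    targets = pd.DataFrame(0, index=list(ratios.columns), columns=classes, dtype=int)
    targets.loc[ctl_cols, classes[0]] = 1
    targets.loc[exp_cols, classes[1]] = 1
    contrasts = pd.DataFrame(
        {f"{classes[1]}-{classes[0]}": pd.Series([-1, 1], index=classes)}
    )
    norm = NormalizedData(
        logexpr=ratios,
        weights=None,
        lib_sizes=pd.Series(1.0, index=ratios.columns),
        factors=pd.Series(1.0, index=ratios.columns),
    )
    fit = fit_contrast_lm(norm, targets, contrasts)
    tables = moderated_result(fit, moderate_ebayes(fit))
    out = next(iter(tables.values()))
    out.attrs["method"] = RATIO
    out.attrs["fraction"] = fraction
    return out


def te_interaction_test(
    matrix: ExpressionMatrix, design: SampleDesign, fraction: int
) -> pd.DataFrame:
    """Interaction-model TE test for one polysome fraction.

    Fits ``type + treatment + type:treatment`` over the transcription
    samples plus the samples of the given fraction; the moderated statistic
    of the interaction coefficient is the TE test.  On counts the fit uses
    TMM factors and precision weights computed on this sample subset.
    """
    X, inter_idx = build_te_design(design, fraction)
    sub = matrix.subset_samples(list(X.index))
    if design.platform == MICROARRAY:
        norm = NormalizedData(
            logexpr=sub.values,
            weights=None,
            lib_sizes=pd.Series(1.0, index=sub.sample_ids),
            factors=pd.Series(1.0, index=sub.sample_ids),
        )
    else:
        factors = tmm_factors(sub)
        norm = precision_weights(sub, X, factors)
    contrast = pd.DataFrame(
        {"te_interaction": pd.Series(np.eye(4)[inter_idx], index=X.columns)}
    )
    fit = fit_contrast_lm(norm, X, contrast)
    tables = moderated_result(fit, moderate_ebayes(fit))
    out = next(iter(tables.values()))
    out.attrs["method"] = INTERACTION
    out.attrs["fraction"] = fraction
    return out


def run_te(
    matrix: ExpressionMatrix, design: SampleDesign, method: str = INTERACTION
) -> dict[int, pd.DataFrame]:
    """TE results for every polysome fraction by the chosen method."""
    if method not in (RATIO, INTERACTION):
        raise ValidationError(f"unknown TE method {method!r}")
    results: dict[int, pd.DataFrame] = {}
    if method == INTERACTION:
        for k in range(1, design.n_fractions + 1):
            results[k] = te_interaction_test(matrix, design, k)
        return results
    if design.platform == MICROARRAY:
        logexpr = matrix.values
    else:
        logexpr = log_cpm(matrix, factors=tmm_factors(matrix))
    for k in range(1, design.n_fractions + 1):
        ratios = ratio_matrix(logexpr, design, k)
        results[k] = te_ratio_test(ratios, design, k)
    return results


def te_heatmap_matrix(
    te: dict[int, pd.DataFrame],
    polysome_de: dict[int, pd.DataFrame],
    thresholds: Thresholds | None = None,
) -> pd.DataFrame:
    """Heatmap data for multi-fraction TE results.

    Rows are genes TE-significant in *any* fraction at the thresholds;
    values are the **polysome (translation) log2 fold changes** per
    fraction, not the TE fold changes — TE selects mRNAs whose translation
    changes beyond transcription, but the polysome fold change is the more
    biologically interpretable quantity to display.  Requires K >= 2
    fractions (a single fraction is shown as a volcano plot instead).
    """
    thresholds = thresholds or Thresholds()
    if len(te) < 2:
        raise ValidationError(
            "the TE heatmap needs >= 2 polysome fractions; use a volcano "
            "plot for a single fraction"
        )
    selected: set[str] = set()
    for k, table in te.items():
        pcol = "adj_pvalue" if thresholds.use_adjusted else "pvalue"
        sig = table[(table["logFC"].abs() > thresholds.lfc) & (table[pcol] < thresholds.p_cut)]
        selected.update(sig.index)
    fractions = sorted(polysome_de)
    genes = [g for g in polysome_de[fractions[0]].index if g in selected]
    data = {f"fraction_{k}": polysome_de[k].loc[genes, "logFC"] for k in fractions}
    return pd.DataFrame(data, index=pd.Index(genes, name="gene"))
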