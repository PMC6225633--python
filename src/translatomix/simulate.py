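"""Synthetic translatome studies with planted regulation.

The generator emulates the structure of a polysome-profiling experiment:
two conditions (control, experiment) x (one transcription fraction + K
polysome fractions) x n replicates.  RNA-seq counts are drawn from a
negative-binomial model whose per-sample means follow planted per-gene
log2 abundances and regulation effects; microarray studies draw Gaussian
log2 intensities around the same means.  Every gene belongs to one of the
five regulation categories, so classification, TE inference and power can
be evaluated against known truth.

Planted effects (applied in the experiment condition only):

* ``transcription_only`` (buffered): the transcription effect appears in
  the total RNA samples but the polysome samples do not move — the
  transcription shift is fully compensated at the level of translation.
* ``translation_only``: polysome samples shift, total RNA does not.
* ``both_same_direction``: concordant shifts in total and polysome.
* ``opposite``: total shifts one way, polysome the other.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import CATEGORIES
from .design import CONTROL, EXPERIMENT, MODERATED_LM, SampleDesign, TRANSCRIPTION
from .io import ExpressionMatrix, MICROARRAY, RNASEQ, ValidationError

DEFAULT_PROPORTIONS = {
    "not_regulated": 0.70,
    "transcription_only": 0.10,
    "translation_only": 0.10,
    "both_same_direction": 0.05,
    "opposite": 0.05,
}


@dataclass
class SimulationSpec:
    """Parameters of a synthetic translatome study.

    Defaults describe a mid-sized polysome-profiling experiment: 2000
    genes, 2 polysome fractions (heavy/light), 3 replicates per class,
    libraries of 0.5-1.5 million reads, NB dispersion 0.1 (squared
    biological CV ~ 0.1, typical for cell-line replicates) and 2-fold
    (|log2FC| = 2 would be 4-fold; here delta = 2 log2 units) planted
    effects.
    """

    n_genes: int = 2000
    n_fractions: int = 2
    n_replicates: int = 3
    platform: str = RNASEQ
    lib_size_range: tuple[float, float] = (5e5, 1.5e6)
    baseline_mean: float = 4.0
    baseline_sd: float = 2.0
    dispersion: float = 0.1
    residual_sd: float = 0.3
    proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PROPORTIONS)
    )
    tx_effect: float = 2.0
    tl_effect: float = 2.0
    seed: int = 0

    def validate(self) -> "SimulationSpec":
        if self.n_replicates < 2:
            raise ValidationError("need >= 2 replicates per class")
        props = [self.proportions.get(c, 0.0) for c in CATEGORIES]
        if any(p < 0 for p in props) or abs(sum(props) - 1.0) > 1e-9:
            raise ValidationError(
                "category proportions must be non-negative and sum to 1"
            )
        if not np.isfinite([self.tx_effect, self.tl_effect]).all():
            raise ValidationError("effect sizes must be finite")
        if self.platform not in (RNASEQ, MICROARRAY):
            raise ValidationError(f"unknown platform {self.platform!r}")
        return self


@dataclass
class SimulatedStudy:
    """A simulated matrix with its design and ground truth."""

    matrix: ExpressionMatrix
    design: SampleDesign
    truth: pd.DataFrame  # gene, category, tx_effect, tl_effect per fraction


def _plant_effects(
    spec: SimulationSpec, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Assign categories and signed effects; returns (category codes,
    total-RNA effect, polysome effect per fraction G x K)."""
    G, K = spec.n_genes, spec.n_fractions
    props = np.array([spec.proportions.get(c, 0.0) for c in CATEGORIES])
    cat_idx = rng.choice(len(CATEGORIES), size=G, p=props)
    sign = rng.choice([-1.0, 1.0], size=G)
    tx = np.zeros(G)
    tl = np.zeros((G, K))
    for g in range(G):
        cat = CATEGORIES[cat_idx[g]]
        if cat == "transcription_only":
            tx[g] = sign[g] * spec.tx_effect  # polysomes stay put: buffered
        elif cat == "translation_only":
            tl[g, :] = sign[g] * spec.tl_effect
        elif cat == "both_same_direction":
            tx[g] = sign[g] * spec.tx_effect
            tl[g, :] = sign[g] * spec.tl_effect
        elif cat == "opposite":
            tx[g] = sign[g] * spec.tx_effect
            tl[g, :] = -sign[g] * spec.tl_effect
    return cat_idx, tx, tl


def expected_means(
    spec: SimulationSpec, baseline: np.ndarray, tx: np.ndarray, tl: np.ndarray,
    lib_sizes: np.ndarray, sample_meta: list[tuple[str, int]],
) -> np.ndarray:
    """Expected counts per gene x sample under the planted model.

    mean = lib_scale_j * 2^(baseline_g + effect_gj), with the per-sample
    scale chosen so that an all-baseline sample totals the drawn library
    size.  The scale is fixed across samples (it does not re-normalize per
    sample), so planted effects translate directly into expected fold
    changes; realized library sizes drift slightly with the planted
    effects, as they do in a real experiment.
    """
    G = baseline.size
    base_total = (2.0 ** baseline).sum()
    mu = np.empty((G, len(sample_meta)))
    for j, (cond, frac) in enumerate(sample_meta):
        logab = baseline.copy()
        if cond == EXPERIMENT:
            if frac == TRANSCRIPTION:
                logab = logab + tx
            else:
                logab = logab + tl[:, frac - 1]
        mu[:, j] = lib_sizes[j] / base_total * 2.0 ** logab
    return mu


def simulate_study(spec: SimulationSpec) -> SimulatedStudy:
    """Draw a synthetic study; deterministic given ``spec.seed``."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    G, K, n = spec.n_genes, spec.n_fractions, spec.n_replicates

    cat_idx, tx, tl = _plant_effects(spec, rng)
    baseline = rng.normal(spec.baseline_mean, spec.baseline_sd, size=G)

    sample_meta: list[tuple[str, int]] = []
    sample_ids: list[str] = []
    for frac in range(K + 1):
        for cond in (CONTROL, EXPERIMENT):
            tag = "T" if frac == TRANSCRIPTION else f"F{frac}"
            lab = "ctl" if cond == CONTROL else "exp"
            for r in range(1, n + 1):
                sample_ids.append(f"R{r}_{lab}_{tag}")
                sample_meta.append((cond, frac))

    n_samples = len(sample_ids)
    lo, hi = spec.lib_size_range
    lib_sizes = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_samples))

    if spec.platform == RNASEQ:
        mu = expected_means(spec, baseline, tx, tl, lib_sizes, sample_meta)
        phi = spec.dispersion
        if phi < 1e-12:
            values = rng.poisson(mu).astype(float)
        else:
            shape = 1.0 / phi
            lam = rng.gamma(shape, mu / shape)
            values = rng.poisson(lam).astype(float)
    else:
        logmu = np.empty((G, n_samples))
        for j, (cond, frac) in enumerate(sample_meta):
            eff = np.zeros(G)
            if cond == EXPERIMENT:
                eff = tx if frac == TRANSCRIPTION else tl[:, frac - 1]
            logmu[:, j] = baseline + eff
        values = logmu + rng.normal(0.0, spec.residual_sd, size=logmu.shape)

    gene_ids = [f"gene{g + 1:05d}" for g in range(G)]
    matrix = ExpressionMatrix(
        values=pd.DataFrame(values, index=gene_ids, columns=sample_ids),
        platform=spec.platform,
    )
    design = SampleDesign(
        platform=spec.platform,
        engine=MODERATED_LM,
        control_label="ctl",
        experiment_label="exp",
        n_fractions=K,
        assignment={s: meta for s, meta in zip(sample_ids, sample_meta)},
    )
    truth = pd.DataFrame(
        {
            "category": [CATEGORIES[i] for i in cat_idx],
            "tx_effect": tx,
            **{f"tl_effect_{k + 1}": tl[:, k] for k in range(K)},
            **{f"te_effect_{k + 1}": tl[:, k] - tx for k in range(K)},
        },
        index=pd.Index(gene_ids, name="gene"),
    )
    return SimulatedStudy(matrix=matrix, design=design, truth=truth)


def recovery_report(
    truth: pd.DataFrame,
    calls: pd.DataFrame,
    te: dict[int, pd.DataFrame] | None = None,
) -> dict:
    """Score calls and TE estimates against the planted truth.

    Returns a dict with a 5x5 ``confusion`` matrix (truth rows x call
    columns), per-category ``sensitivity`` and ``specificity``, and — when
    TE tables are given — per-fraction ``te_bias`` and ``te_rmse`` of the
    estimated TE logFC against the planted TE effect.
    """
    common = truth.index.intersection(calls.index)
    if len(common) == 0:
        raise ValidationError("truth and calls share no genes")
    t = truth.loc[common, "category"]
    c = calls.loc[common, "category"]
    confusion = pd.crosstab(t, c).reindex(
        index=CATEGORIES, columns=CATEGORIES, fill_value=0
    )
    sens, spec_ = {}, {}
    for cat in CATEGORIES:
        tp = ((t == cat) & (c == cat)).sum()
        fn = ((t == cat) & (c != cat)).sum()
        fp = ((t != cat) & (c == cat)).sum()
        tn = ((t != cat) & (c != cat)).sum()
        sens[cat] = tp / (tp + fn) if (tp + fn) else float("nan")
        spec_[cat] = tn / (tn + fp) if (tn + fp) else float("nan")
    report = {
        "confusion": confusion,
        "sensitivity": pd.Series(sens),
        "specificity": pd.Series(spec_),
    }
    if te is not None:
        bias, rmse = {}, {}
        for k, table in te.items():
            genes = truth.index.intersection(table.index)
            err = (
                table.loc[genes, "logFC"].to_numpy()
                - truth.loc[genes, f"te_effect_{k}"].to_numpy()
            )
            err = err[np.isfinite(err)]
            bias[k] = float(err.mean())
            rmse[k] = float(np.sqrt((err ** 2).mean()))
        report["te_bias"] = pd.Series(bias)
        report["te_rmse"] = pd.Series(rmse)
    return report
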