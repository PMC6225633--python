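"""Five-way classification of translational regulation.

Comparing where a gene changes — transcription, translation, both or
neither — distinguishes biologically distinct modes of regulation:

* ``transcription_only`` — a transcription change not reflected in
  translation (translational buffering),
* ``translation_only`` — translation changes with stable mRNA levels,
* ``both_same_direction`` — a transcription change carried through to the
  polysomes,
* ``opposite`` — transcription and translation move in opposite
  directions,
* ``not_regulated`` — neither passes the significance gates.

Significance gates default to |log2FC| > 1 and raw p < 0.05 (strict
inequalities), matching the analysis modules' default sliders.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .io import ValidationError

CATEGORIES = [
    "not_regulated",
    "transcription_only",
    "translation_only",
    "both_same_direction",
    "opposite",
]


@dataclass(frozen=True)
class Thresholds:
    """Significance gates: |log2FC| > lfc and p (or adjusted p) < p_cut."""

    lfc: float = 1.0
    p_cut: float = 0.05
    use_adjusted: bool = False

    def __post_init__(self) -> None:
        if self.lfc < 0:
            raise ValidationError("lfc threshold must be >= 0")
        if not (0 < self.p_cut <= 1):
            raise ValidationError("p_cut must lie in (0, 1]")

    @property
    def p_column(self) -> str:
        return "adj_pvalue" if self.use_adjusted else "pvalue"


def select_significant(de: pd.DataFrame, thr: Thresholds | None = None) -> pd.DataFrame:
    """Genes passing |logFC| > thr.lfc and p < thr.p_cut (strict).

    Returns the subset of rows of the result table; genes with NA
    statistics never pass.  ``lfc=0`` disables the fold-change gate
    entirely (p-value-only selection), rather than excluding exact zeros.
    """
    thr = thr or Thresholds()
    mask = de[thr.p_column] < thr.p_cut
    if thr.lfc > 0:
        mask &= de["logFC"].abs() > thr.lfc
    else:
        mask &= de["logFC"].notna()
    return de[mask.fillna(False)]


def collapse_fractions(
    de_per_fraction: list[pd.DataFrame], thr: Thresholds | None = None
) -> pd.DataFrame:
    """Union of per-fraction significant gene sets with one representative
    log fold change per gene.

    The representative translation logFC is the logFC of largest magnitude
    among the fractions where the gene is significant (ties broken by the
    lowest fraction index).  Returns a table with columns ``tl_logFC``,
    ``tl_pvalue``, ``tl_adj_pvalue`` and ``fraction`` indexed by gene.
    """
    thr = thr or Thresholds()
    if not de_per_fraction:
        raise ValidationError("no translation result tables given")
    rows: dict[str, tuple[float, float, float, int]] = {}
    for k, de in enumerate(de_per_fraction, start=1):
        sig = select_significant(de, thr)
        for gene, row in sig.iterrows():
            prev = rows.get(gene)
            if prev is None or abs(row["logFC"]) > abs(prev[0]):
                rows[gene] = (row["logFC"], row["pvalue"], row["adj_pvalue"], k)
    out = pd.DataFrame.from_dict(
        rows, orient="index",
        columns=["tl_logFC", "tl_pvalue", "tl_adj_pvalue", "fraction"],
    )
    out.index.name = "gene"
    return out


def classify_regulation(
    tx: pd.DataFrame,
    tl_summary: pd.DataFrame,
    thr_tx: Thresholds | None = None,
    thr_tl: Thresholds | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Assign each gene one regulation category; return calls and counts.

    ``tx`` is the transcription result table; ``tl_summary`` the collapsed
    translation summary from :func:`collapse_fractions` (already gated at
    ``thr_tl``).  Classification runs on genes present in the transcription
    table; if the translation summary names genes missing from it, the
    universes differ (e.g. different upstream filtering) and a warning is
    issued before intersecting.
    """
    thr_tx = thr_tx or Thresholds()
    thr_tl = thr_tl or Thresholds()
    tx_sig = set(select_significant(tx, thr_tx).index)
    tl_only_extra = set(tl_summary.index) - set(tx.index)
    if tl_only_extra:
        warnings.warn(
            f"{len(tl_only_extra)} translation-significant genes are absent "
            "from the transcription table; classifying the intersection",
            UserWarning,
            stacklevel=2,
        )
    records = []
    for gene in tx.index:
        is_tx = gene in tx_sig
        is_tl = gene in tl_summary.index
        tx_lfc = tx.loc[gene, "logFC"]
        tl_lfc = tl_summary.loc[gene, "tl_logFC"] if is_tl else float("nan")
        if is_tx and is_tl:
            cat = "both_same_direction" if tx_lfc * tl_lfc >= 0 else "opposite"
        elif is_tx:
            cat = "transcription_only"
        elif is_tl:
            cat = "translation_only"
        else:
            cat = "not_regulated"
        records.append(
            {
                "gene": gene,
                "category": cat,
                "tx_logFC": tx_lfc,
                "tl_logFC": tl_lfc,
                "tx_pvalue": tx.loc[gene, thr_tx.p_column],
                "tl_pvalue": tl_summary.loc[gene, "tl_" + thr_tl.p_column] if is_tl else float("nan"),
            }
        )
    calls = pd.DataFrame.from_records(records).set_index("gene")
    counts = (
        calls["category"].value_counts().reindex(CATEGORIES, fill_value=0)
    )
    counts.name = "n_genes"
    return calls, counts
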