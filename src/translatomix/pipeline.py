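"""End-to-end orchestration: validate -> design -> normalize/QC ->
differential expression -> translational efficiency -> regulation
classification -> tables and figures.

The interactive threshold sliders of a GUI are replaced by re-runnable
stages taking explicit threshold arguments, so an analysis is a config
plus a seed and reruns are identical.
"""

from __future__ import annotations

import json
import platform as _platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .classify import Thresholds, classify_regulation, collapse_fractions
from .design import (
    NB_GLM,
    SampleDesign,
    TRANSCRIPTION,
    build_contrasts,
    build_targets,
    design_from_dict,
    validate_design,
)
from .efficiency import INTERACTION, run_te, te_heatmap_matrix
from .engines import run_differential
from .io import (
    ExpressionMatrix,
    MICROARRAY,
    RNASEQ,
    ValidationError,
    read_expression_table,
    validate_expression,
    write_results_table,
)
from .normalize import filter_min_reads, log_cpm, mds_coordinates, tmm_factors
from . import plots


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass
class ResultBundle:
    """Everything a pipeline run produces."""

    matrix: ExpressionMatrix
    design: SampleDesign
    factors: pd.Series | None
    mds: pd.DataFrame
    de: dict[str, pd.DataFrame]
    te: dict[int, pd.DataFrame]
    calls: pd.DataFrame
    counts: pd.Series
    tables: dict[str, Path] = field(default_factory=dict)
    figures: list[Path] = field(default_factory=list)


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc

    return wrap


def _combined_wide(de: dict[str, pd.DataFrame]) -> pd.DataFrame:
    parts = []
    for cname, table in de.items():
        part = table[["logFC", "stat", "pvalue", "adj_pvalue"]].copy()
        part.columns = [f"{cname}.{c}" for c in part.columns]
        parts.append(part)
    return pd.concat(parts, axis=1)


def run_pipeline(
    config: dict,
    matrix: ExpressionMatrix | None = None,
    out_dir: str | Path | None = None,
    render: bool = True,
) -> ResultBundle:
    """Run the full analysis described by ``config``.

    Config keys: ``matrix`` (path; ignored when a matrix object is passed),
    ``format``, ``design`` (see :func:`~translatomix.design.design_from_dict`),
    ``te_method`` (``ratio`` or ``interaction``), ``min_reads`` (optional
    count filter applied to the transcription samples), ``thresholds`` /
    ``te_thresholds`` (``lfc``, ``p_cut``, ``use_adjusted``), ``seed`` and
    ``out`` (output directory, overridable by ``out_dir``).

    Writes every result table (tab-delimited), the figures and a run log,
    and returns the in-memory bundle.
    """
    design = _stage("design")(
        lambda: config["design"] if isinstance(config["design"], SampleDesign)
        else design_from_dict(config["design"])
    )

    if matrix is None:
        matrix = _stage("input")(
            read_expression_table,
            config["matrix"],
            format=config.get("format"),
            platform=design.platform,
        )
    _stage("validation")(validate_expression, matrix)
    _stage("validation")(validate_design, design, matrix)

    min_reads = config.get("min_reads")
    if min_reads is not None:
        tx_samples = design.samples_in_class("control", TRANSCRIPTION) + \
            design.samples_in_class("experiment", TRANSCRIPTION)
        matrix = _stage("filter")(
            filter_min_reads, matrix, threshold=int(min_reads), subset=tx_samples
        )

    reordered, targets = _stage("design")(build_targets, design, matrix)
    contrasts = _stage("design")(build_contrasts, design)

    if design.platform == RNASEQ:
        factors = _stage("normalization")(tmm_factors, reordered)
        logexpr = _stage("normalization")(log_cpm, reordered, factors)
    else:
        factors = None
        logexpr = reordered.values
    mds = _stage("qc")(
        mds_coordinates, logexpr, top=int(config.get("mds_top", 500))
    )

    de = _stage("differential")(run_differential, matrix, design)
    te_method = config.get("te_method", INTERACTION)
    te = _stage("efficiency")(run_te, matrix, design, method=te_method)

    thr = Thresholds(**config.get("thresholds", {}))
    thr_te = Thresholds(**config.get("te_thresholds", config.get("thresholds", {})))
    tx_name = contrasts.columns[0]
    tl_tables = [de[contrasts.columns[k]] for k in range(1, design.n_fractions + 1)]
    tl_summary = _stage("classification")(collapse_fractions, tl_tables, thr)
    calls, counts = _stage("classification")(
        classify_regulation, de[tx_name], tl_summary, thr, thr
    )

    bundle = ResultBundle(
        matrix=matrix, design=design, factors=factors, mds=mds,
        de=de, te=te, calls=calls, counts=counts,
    )

    out = Path(out_dir or config.get("out", "translatomix_out"))
    out.mkdir(parents=True, exist_ok=True)
    tabdir = out / "tables"
    tabdir.mkdir(exist_ok=True)
    for cname, table in de.items():
        path = tabdir / f"de_{cname}.tsv"
        write_results_table(table, path)
        bundle.tables[f"de_{cname}"] = path
    wide = _combined_wide(de)
    write_results_table(wide, tabdir / "de_all_contrasts.tsv")
    bundle.tables["de_all_contrasts"] = tabdir / "de_all_contrasts.tsv"
    for k, table in te.items():
        path = tabdir / f"te_{te_method}_fraction_{k}.tsv"
        write_results_table(table, path)
        bundle.tables[f"te_fraction_{k}"] = path
    write_results_table(calls, tabdir / "regulation_calls.tsv")
    bundle.tables["regulation_calls"] = tabdir / "regulation_calls.tsv"
    write_results_table(mds, tabdir / "mds_coordinates.tsv")
    bundle.tables["mds_coordinates"] = tabdir / "mds_coordinates.tsv"

    if render:
        bundle.figures = _stage("figures")(
            render_figures, bundle, thr, thr_te, out / "figures"
        )

    from . import __version__ as pkg_version

    log = {
        "package_version": pkg_version,
        "python": _platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": config.get("seed"),
        "engine": design.engine,
        "te_method": te_method,
        "min_reads": min_reads,
        "thresholds": {"lfc": thr.lfc, "p_cut": thr.p_cut, "use_adjusted": thr.use_adjusted},
        "n_genes": matrix.n_genes,
        "n_samples": matrix.n_samples,
        "n_fractions": design.n_fractions,
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=2))
    return bundle


def render_figures(
    bundle: ResultBundle,
    thresholds: Thresholds,
    te_thresholds: Thresholds,
    fig_dir: str | Path,
) -> list[Path]:
    """Render the report figures for a result bundle.

    Volcano per contrast; translation and TE heatmaps when K >= 2 (volcano
    for a single fraction); transcription-vs-translation scatter colored by
    regulation category; category barplot; MDS QC plot.
    """
    fig_dir = Path(fig_dir)
    fig_dir.mkdir(parents=True, exist_ok=True)
    paths: list[Path] = []
    design = bundle.design
    contrasts = build_contrasts(design)

    for cname in contrasts.columns:
        paths += plots.volcano(
            bundle.de[cname], thresholds, fig_dir / f"volcano_{cname}", title=cname
        )

    tl_names = [contrasts.columns[k] for k in range(1, design.n_fractions + 1)]
    if design.n_fractions >= 2:
        tl_summary = collapse_fractions([bundle.de[c] for c in tl_names], thresholds)
        tl_heat = pd.DataFrame(
            {
                f"fraction_{k}": bundle.de[tl_names[k - 1]]["logFC"]
                for k in range(1, design.n_fractions + 1)
            }
        ).loc[[g for g in bundle.de[tl_names[0]].index if g in tl_summary.index]]
        paths += plots.fraction_heatmap(
            tl_heat, fig_dir / "translation_heatmap", title="translation log2FC"
        )
        poly_de = {k: bundle.de[tl_names[k - 1]] for k in range(1, design.n_fractions + 1)}
        te_heat = te_heatmap_matrix(bundle.te, poly_de, te_thresholds)
        paths += plots.fraction_heatmap(
            te_heat, fig_dir / "te_heatmap",
            title="polysome log2FC of TE-significant genes",
        )
    else:
        paths += plots.volcano(
            bundle.te[1], te_thresholds, fig_dir / "volcano_te_fraction_1",
            title="translational efficiency",
        )

    paths += plots.regulation_scatter(bundle.calls, fig_dir / "regulation_scatter")
    paths += plots.regulation_barplot(bundle.counts, fig_dir / "regulation_barplot")

    groups = pd.Series(
        {
            s: ("total" if design.assignment[s][1] == TRANSCRIPTION else "polysome")
            for s in bundle.mds.index
        },
        name="fraction_type",
    )
    paths += plots.mds_plot(bundle.mds, groups, fig_dir / "mds")
    return paths
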