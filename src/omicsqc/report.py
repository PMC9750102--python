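"""Report rendering: TSV bundle, figures and one self-contained HTML file.

Every number shown in the HTML is also written as a TSV (the TSVs are
written first and are the single source of truth); figures are static PNGs
embedded base64 in the HTML so the report is a single archivable file with
no JavaScript dependency.
"""

from __future__ import annotations

import base64
import html
import io as _io
import logging
from pathlib import Path
from string import Template

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .datatypes import OmicsQCError
from .pipeline import GROUPS, EvaluationReport, TableEvaluation

logger = logging.getLogger(__name__)

_PAGE = Template(
    """<!DOCTYPE html>
<html lang="en">
<head>
<meta charset="utf-8">
<title>omicsqc evaluation report</title>
<style>
body { font-family: sans-serif; margin: 2em auto; max-width: 70em; color: #222; }
h1 { border-bottom: 2px solid #444; }
h2 { border-bottom: 1px solid #aaa; margin-top: 2em; }
table { border-collapse: collapse; margin: 1em 0; }
th, td { border: 1px solid #999; padding: 0.3em 0.7em; text-align: right; }
th { background: #eee; }
td:first-child, th:first-child { text-align: left; }
.skipped { color: #8a6d3b; background: #fcf8e3; padding: 0.5em 1em; }
img { max-width: 100%; }
</style>
</head>
<body>
<h1>Omics data table quality evaluation</h1>
$body
</body>
</html>
"""
)


def _fig_to_html(fig: plt.Figure, alt: str) -> str:
    buf = _io.BytesIO()
    fig.savefig(buf, format="png", dpi=110, bbox_inches="tight")
    plt.close(fig)
    data = base64.b64encode(buf.getvalue()).decode("ascii")
    return f'<img alt="{html.escape(alt)}" src="data:image/png;base64,{data}">'


def _df_to_html(df: pd.DataFrame, max_rows: int = 30) -> str:
    shown = df.head(max_rows)
    note = ""
    if len(df) > max_rows:
        note = f"<p><em>first {max_rows} of {len(df)} rows shown</em></p>"
    return shown.to_html(float_format=lambda x: f"{x:.4g}", border=0) + note


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)


# ---------------------------------------------------------------------------
# TSV bundle
# ---------------------------------------------------------------------------

def write_result_tsvs(report: EvaluationReport, out_dir: Path) -> None:
    """Persist every figure's underlying numbers as TSV files."""
    summary = score_table(report)
    _write_tsv(summary, out_dir / "summary" / "scores.tsv")
    metrics = raw_metric_table(report)
    _write_tsv(metrics, out_dir / "summary" / "metrics.tsv")
    if report.overlap is not None:
        _write_tsv(report.overlap, out_dir / "summary" / "feature_overlap.tsv", index=False)

    for name, ev in report.tables.items():
        d = out_dir / "tables" / name
        if ev.depth:
            _write_tsv(
                ev.depth.per_sample_counts.to_frame("n_features"),
                d / "per_sample_feature_counts.tsv",
            )
            _write_tsv(
                ev.depth.missing_fraction_per_feature.to_frame("missing_fraction"),
                d / "missing_fraction_per_feature.tsv",
            )
        if ev.distribution:
            _write_tsv(ev.distribution.pairwise_auroc, d / "pairwise_auroc.tsv")
            _write_tsv(ev.distribution.per_sample_quartiles, d / "sample_quartiles.tsv")
        if ev.batch:
            _write_tsv(ev.batch.pca.coords, d / "pca_coordinates.tsv")
            _write_tsv(
                pd.DataFrame(
                    {"variance_fraction": ev.batch.pca.variance_fractions},
                    index=ev.batch.pca.coords.columns,
                ),
                d / "pca_variance_fractions.tsv",
            )
            _write_tsv(ev.batch.sample_correlation, d / "sample_correlation.tsv")
        if ev.complex_corr:
            n = ev.complex_corr.n_pairs
            _write_tsv(
                pd.DataFrame(
                    {
                        "intra_r": ev.complex_corr.intra_correlations[:n],
                        "inter_r": ev.complex_corr.inter_correlations[:n],
                    }
                ),
                d / "complex_pair_correlations.tsv",
                index=False,
            )
        if ev.function_pred and ev.function_pred.per_pathway_auroc:
            _write_tsv(
                pd.Series(ev.function_pred.per_pathway_auroc, name="auroc")
                .rename_axis("pathway")
                .to_frame(),
                d / "pathway_prediction_auroc.tsv",
            )
        if ev.class_pred:
            _write_tsv(
                ev.class_pred.out_of_fold_scores.rename_axis("sample").to_frame(),
                d / "class_prediction_scores.tsv",
            )
        if ev.clustering:
            _write_tsv(
                ev.clustering.cluster_labels.rename_axis("sample").to_frame(),
                d / "cluster_labels.tsv",
            )
        if ev.cv:
            _write_tsv(ev.cv.per_feature_cv.to_frame(), d / "qc_cv_per_feature.tsv")
        if ev.concordance:
            _write_tsv(
                ev.concordance.genewise_r.to_frame(), d / "genewise_correlation.tsv"
            )
            _write_tsv(
                ev.concordance.samplewise_r.to_frame(), d / "samplewise_correlation.tsv"
            )


def score_table(report: EvaluationReport) -> pd.DataFrame:
    """Radar scores, one row per table, one column per metric group."""
    rows = {
        name: {g: rs.scores.get(g) for g in GROUPS}
        for name, rs in report.radar.items()
    }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "table"
    return out


def raw_metric_table(report: EvaluationReport) -> pd.DataFrame:
    """Headline raw metrics, one row per table."""
    rows = {}
    for name, ev in report.tables.items():
        rows[name] = {
            "n_identified": ev.depth.n_identified if ev.depth else None,
            "n_quantifiable": ev.depth.n_quantifiable if ev.depth else None,
            "similarity_score": ev.distribution.similarity_score
            if ev.distribution
            else None,
            "asw_batch": ev.batch.asw_batch if ev.batch else None,
            "pcr_batch_r2": ev.batch.pcr_batch_r2 if ev.batch else None,
            "complex_separation_auroc": ev.complex_corr.separation_auroc
            if ev.complex_corr
            else None,
            "median_function_auroc": ev.function_pred.median_auroc
            if ev.function_pred
            else None,
            "class_cv_auroc": ev.class_pred.cv_auroc if ev.class_pred else None,
            "ari_vs_class": ev.clustering.ari_vs_class if ev.clustering else None,
            "ari_vs_batch": ev.clustering.ari_vs_batch if ev.clustering else None,
            "fraction_cv_below_threshold": ev.cv.fraction_below_threshold
            if ev.cv
            else None,
            "median_genewise_r": ev.concordance.median_genewise_r
            if ev.concordance
            else None,
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "table"
    return out


# ---------------------------------------------------------------------------
# figures
# ---------------------------------------------------------------------------

def radar_figure(report: EvaluationReport) -> plt.Figure:
    """One polygon per table over the available metric groups."""
    groups = [
        g
        for g in GROUPS
        if any(rs.scores.get(g) is not None for rs in report.radar.values())
    ]
    if not groups:
        groups = list(GROUPS)
    angles = np.linspace(0, 2 * np.pi, len(groups), endpoint=False)
    fig = plt.figure(figsize=(5.5, 5))
    ax = fig.add_subplot(111, polar=True)
    for name, rs in report.radar.items():
        vals = [rs.scores.get(g) for g in groups]
        vals = [0.0 if v is None else v for v in vals]
        closed_a = np.concatenate([angles, angles[:1]])
        closed_v = vals + vals[:1]
        ax.plot(closed_a, closed_v, label=name, linewidth=1.5)
        ax.fill(closed_a, closed_v, alpha=0.12)
    ax.set_xticks(angles)
    ax.set_xticklabels(groups)
    ax.set_ylim(0, 1)
    ax.legend(loc="upper right", bbox_to_anchor=(1.35, 1.1), fontsize=8)
    return fig


def _per_sample_counts_figure(report: EvaluationReport) -> plt.Figure:
    fig, ax = plt.subplots(figsize=(7, 3.2))
    order = report.annotation.table["order"]
    for name, ev in report.tables.items():
        if not ev.depth:
            continue
        counts = ev.depth.per_sample_counts
        if order.notna().all():
            x = order.loc[counts.index].to_numpy()
            xlabel = "run order"
        else:
            x = np.arange(len(counts))
            xlabel = "sample index"
        ax.scatter(x, counts.to_numpy(), s=14, label=name)
    ax.set_xlabel(xlabel)
    ax.set_ylabel("features observed")
    ax.legend(fontsize=8)
    return fig


def _boxplot_figure(ev: TableEvaluation) -> plt.Figure:
    q = ev.distribution.per_sample_quartiles
    s = ev.abundance_summary
    fig, ax = plt.subplots(figsize=(7, 3.2))
    x = np.arange(len(q))
    ax.vlines(x, s["min"], s["max"], color="#bbb", linewidth=0.8)
    ax.vlines(x, q["Q1"], q["Q3"], color="tab:blue", linewidth=4, alpha=0.7)
    ax.plot(x, q["median"], "k.", markersize=4)
    ax.set_xticks(x[:: max(1, len(x) // 25)])
    ax.set_xticklabels(q.index[:: max(1, len(x) // 25)], rotation=90, fontsize=6)
    ax.set_ylabel("abundance")
    ax.set_title(f"{ev.table_name}: per-sample abundance distribution")
    return fig


def _pca_figure(ev: TableEvaluation, report: EvaluationReport) -> plt.Figure:
    coords = ev.batch.pca.coords
    vf = ev.batch.pca.variance_fractions
    batches = report.annotation.batches.loc[coords.index]
    fig, ax = plt.subplots(figsize=(4.6, 4))
    for level in sorted(batches.unique()):
        sel = batches == level
        xy = coords.loc[sel.to_numpy()]
        y = xy.iloc[:, 1] if coords.shape[1] > 1 else np.zeros(len(xy))
        ax.scatter(xy.iloc[:, 0], y, s=16, label=str(level))
    ax.set_xlabel(f"PC1 ({vf[0] * 100:.1f}%)")
    if coords.shape[1] > 1:
        ax.set_ylabel(f"PC2 ({vf[1] * 100:.1f}%)")
    ax.legend(title="batch", fontsize=8)
    ax.set_title(f"{ev.table_name}: PCA")
    return fig


def _correlation_heatmap(ev: TableEvaluation) -> plt.Figure:
    corr = ev.batch.sample_correlation
    fig, ax = plt.subplots(figsize=(4.8, 4.2))
    im = ax.imshow(corr.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks([])
    ax.set_yticks([])
    fig.colorbar(im, ax=ax, shrink=0.8, label="Pearson r")
    ax.set_title(f"{ev.table_name}: sample correlation")
    return fig


def _complex_corr_figure(ev: TableEvaluation) -> plt.Figure:
    cc = ev.complex_corr
    fig, ax = plt.subplots(figsize=(5.2, 3.2))
    bins = np.linspace(-1, 1, 41)
    ax.hist(cc.intra_correlations, bins=bins, alpha=0.6, label="intra-complex")
    ax.hist(cc.inter_correlations, bins=bins, alpha=0.6, label="inter-complex")
    ax.set_xlabel("Pearson r")
    ax.set_ylabel("pairs")
    ax.legend(fontsize=8)
    ax.set_title(
        f"{ev.table_name}: complex pairs (separation AUROC "
        f"{cc.separation_auroc:.3f})"
    )
    return fig


def _cv_figure(ev: TableEvaluation) -> plt.Figure:
    cv = ev.cv
    fig, ax = plt.subplots(figsize=(5.2, 3.2))
    ax.hist(cv.per_feature_cv.clip(upper=1.0), bins=40, color="tab:green", alpha=0.8)
    ax.axvline(cv.threshold, color="k", linestyle="--", linewidth=1)
    ax.set_xlabel("CV (clipped at 1)")
    ax.set_ylabel("features")
    ax.set_title(
        f"{ev.table_name}: QC CVs ({cv.fraction_below_threshold * 100:.1f}% "
        f"below {cv.threshold:.0%})"
    )
    return fig


def _concordance_figure(ev: TableEvaluation) -> plt.Figure:
    con = ev.concordance
    fig, ax = plt.subplots(figsize=(5.2, 3.2))
    ax.hist(con.genewise_r, bins=np.linspace(-1, 1, 41), color="tab:purple", alpha=0.8)
    ax.axvline(con.median_genewise_r, color="k", linestyle="--", linewidth=1)
    ax.set_xlabel("gene-wise Spearman r")
    ax.set_ylabel("features")
    ax.set_title(
        f"{ev.table_name}: paired-omics concordance (median r "
        f"{con.median_genewise_r:.3f})"
    )
    return fig


def _overlap_figure(report: EvaluationReport) -> plt.Figure:
    ov = report.overlap
    names = [c for c in ov.columns if c != "count"]
    labels = [
        " & ".join(n for n in names if row[n]) for _, row in ov.iterrows()
    ]
    fig, ax = plt.subplots(figsize=(6.2, 3))
    ax.bar(range(len(ov)), ov["count"], color="tab:gray")
    ax.set_xticks(range(len(ov)))
    ax.set_xticklabels(labels, rotation=30, ha="right", fontsize=7)
    ax.set_ylabel("features")
    ax.set_title("exclusive feature-overlap patterns")
    return fig


# ---------------------------------------------------------------------------
# HTML assembly
# ---------------------------------------------------------------------------

def _skip_notice(reason: str) -> str:
    return f'<p class="skipped">skipped: {html.escape(reason)}</p>'


def render_report(report: EvaluationReport, out_dir: str | Path) -> Path:
    """Write the TSV bundle and the self-contained HTML report.

    The TSVs are persisted before any figure is rendered, so results
    survive a rendering failure.  Returns the path of the HTML file.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        probe = out / ".write_test"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise OmicsQCError(f"output directory {out} is not writable: {exc}") from exc

    write_result_tsvs(report, out)

    ann = report.annotation.table
    parts: list[str] = []

    # introduction
    parts.append("<h2>Introduction</h2>")
    intro = pd.DataFrame(
        {
            name: {
                "features": len(ev.depth.missing_fraction_per_feature)
                if ev.depth
                else None,
                "samples": len(ev.depth.per_sample_counts) if ev.depth else None,
            }
            for name, ev in report.tables.items()
        }
    ).T
    intro.index.name = "table"
    parts.append(_df_to_html(intro))
    klass = ann["class_label"].value_counts().rename_axis("class").to_frame("samples")
    batch = ann["batch"].value_counts().rename_axis("batch").to_frame("samples")
    parts.append("<p>Sample classes and batches:</p>")
    parts.append(_df_to_html(klass))
    parts.append(_df_to_html(batch))

    # overview
    parts.append("<h2>Overview</h2>")
    parts.append(_df_to_html(score_table(report)))
    parts.append(_df_to_html(raw_metric_table(report)))
    parts.append(_fig_to_html(radar_figure(report), "radar plot of metric-group scores"))

    # group 1: depth
    parts.append("<h2>Group 1 — data depth</h2>")
    depth_rows = {
        name: {
            "identified": ev.depth.n_identified,
            "quantifiable": ev.depth.n_quantifiable,
        }
        for name, ev in report.tables.items()
        if ev.depth
    }
    dt = pd.DataFrame.from_dict(depth_rows, orient="index")
    dt.index.name = "table"
    parts.append(_df_to_html(dt))
    parts.append(_fig_to_html(_per_sample_counts_figure(report), "features per sample"))
    if report.overlap is not None:
        parts.append(_fig_to_html(_overlap_figure(report), "feature overlap"))
        parts.append(_df_to_html(report.overlap))

    # group 2: normalization
    parts.append("<h2>Group 2 — normalization</h2>")
    for name, ev in report.tables.items():
        if ev.distribution:
            parts.append(
                f"<p><b>{html.escape(name)}</b>: distribution similarity score "
                f"{ev.distribution.similarity_score:.4f}</p>"
            )
            parts.append(_fig_to_html(_boxplot_figure(ev), f"{name} abundance boxplot"))

    # group 3: batch effect
    parts.append("<h2>Group 3 — batch effect</h2>")
    for name, ev in report.tables.items():
        if ev.batch:
            parts.append(
                f"<p><b>{html.escape(name)}</b>: batch ASW "
                f"{ev.batch.asw_batch:.4f}, PCR R&sup2; {ev.batch.pcr_batch_r2:.4f}</p>"
            )
            parts.append(_fig_to_html(_pca_figure(ev, report), f"{name} PCA"))
            parts.append(
                _fig_to_html(_correlation_heatmap(ev), f"{name} correlation heatmap")
            )

    # group 4: biological signal
    parts.append("<h2>Group 4 — biological signal</h2>")
    for name, ev in report.tables.items():
        parts.append(f"<h3>{html.escape(name)}</h3>")
        if ev.complex_corr:
            parts.append(_fig_to_html(_complex_corr_figure(ev), f"{name} complex pairs"))
        elif "complex_corr" in ev.skipped:
            parts.append(_skip_notice(ev.skipped["complex_corr"]))
        if ev.function_pred and ev.function_pred.median_auroc is not None:
            parts.append(
                f"<p>network function prediction: median AUROC "
                f"{ev.function_pred.median_auroc:.4f} over "
                f"{len(ev.function_pred.per_pathway_auroc)} pathway(s)</p>"
            )
        elif "function_pred" in ev.skipped:
            parts.append(_skip_notice(ev.skipped["function_pred"]))
        if ev.class_pred:
            parts.append(
                f"<p>class prediction CV AUROC: {ev.class_pred.cv_auroc:.4f}</p>"
            )
        elif "class_pred" in ev.skipped:
            parts.append(_skip_notice(ev.skipped["class_pred"]))
        if ev.clustering:
            parts.append(
                f"<p>clustering ARI vs class {ev.clustering.ari_vs_class:.4f}, "
                f"vs batch {ev.clustering.ari_vs_batch:.4f}</p>"
            )
        elif "clustering" in ev.skipped:
            parts.append(_skip_notice(ev.skipped["clustering"]))

    # group 5: reproducibility
    parts.append("<h2>Group 5 — platform reproducibility</h2>")
    for name, ev in report.tables.items():
        if ev.cv:
            parts.append(_fig_to_html(_cv_figure(ev), f"{name} QC CV distribution"))
        else:
            parts.append(
                f"<p><b>{html.escape(name)}</b></p>"
                + _skip_notice(ev.skipped.get("reproducibility", "not computed"))
            )

    # group 6: multi-omics concordance
    parts.append("<h2>Group 6 — multi-omics concordance</h2>")
    for name, ev in report.tables.items():
        if ev.concordance:
            parts.append(_fig_to_html(_concordance_figure(ev), f"{name} concordance"))
        else:
            parts.append(
                f"<p><b>{html.escape(name)}</b></p>"
                + _skip_notice(ev.skipped.get("concordance", "not computed"))
            )

    html_path = out / "report.html"
    html_path.write_text(_PAGE.substitute(body="\n".join(parts)), encoding="utf-8")
    logger.info("report written to %s", html_path)
    return html_path
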