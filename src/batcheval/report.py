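"""Multi-page static HTML report.

Structure mirrors the evaluation workflow: a main page with the per-variant
summary grid (k-BET accept rate, mean p-value, composite score), the
conclusion sentence and links; a raw-integration page with the statistical
tables, metric tables and visualization panels; and one page per correction
method. All assets are relative-path PNG/HTML so the report opens offline;
displayed numbers are rounded to 4 decimals while the JSON sidecar keeps
full precision.
"""

from __future__ import annotations

import html
import string
import warnings
from pathlib import Path

import numpy as np

_PAGE = string.Template("""<!DOCTYPE html>
<html lang="en">
<head>
<meta charset="utf-8">
<title>$title</title>
<style>
body { font-family: sans-serif; margin: 2em auto; max-width: 70em; color: #222; }
table { border-collapse: collapse; margin: 1em 0; }
th, td { border: 1px solid #999; padding: 0.35em 0.8em; text-align: right; }
th { background: #eee; }
td.name, th.name { text-align: left; }
.nav { position: fixed; top: 1em; left: 1em; }
.panels img { max-width: 30em; margin: 0.5em; border: 1px solid #ccc; }
.note { color: #666; font-size: 0.9em; }
h1, h2 { color: #113355; }
</style>
</head>
<body>
$nav
<h1>$title</h1>
$body
</body>
</html>
""")

_NAV = '<div class="nav"><a href="index.html">&#8592; Main page</a></div>'


def _fmt(x) -> str:
    if x is None:
        return "&mdash;"
    if isinstance(x, float):
        return f"{x:.4f}"
    return html.escape(str(x))


def _table(headers: list[str], rows: list[list], first_col_name=True) -> str:
    head = "".join(
        f'<th class="name">{html.escape(h)}</th>' if (i == 0 and first_col_name)
        else f"<th>{html.escape(h)}</th>"
        for i, h in enumerate(headers))
    body = []
    for row in rows:
        cells = "".join(
            f'<td class="name">{_fmt(c)}</td>' if (i == 0 and first_col_name)
            else f"<td>{_fmt(c)}</td>"
            for i, c in enumerate(row))
        body.append(f"<tr>{cells}</tr>")
    return f"<table><tr>{head}</tr>{''.join(body)}</table>"


# -- figures ----------------------------------------------------------------

def render_figure_panels(dataset, variant: str, outdir: str | Path,
                         seed: int = 0, max_points: int = 50_000) -> dict[str, str]:
    """Emit the visualization panels for one variant; returns panel->filename.

    Panels: (a) per-batch kernel density of totals, (b) per-batch CDF,
    (c) boxplot of totals, (d) gene mean vs variance scatter by batch,
    (e) PCA PC1/PC2 joint scatter with marginal densities, (f) UMAP scatter
    by batch, (g) pairwise Q-Q plots of totals. Panels whose prerequisites
    are missing are skipped (recorded as a placeholder), the rest proceed.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import seaborn as sns

    from .preprocess import per_cell_total_counts, per_gene_mean_variance

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    batch = np.asarray(dataset.batch).astype(str)
    names = sorted(set(batch))
    totals = per_cell_total_counts(dataset)
    panels: dict[str, str] = {}
    tag = variant.lower().replace(" ", "_")

    def save(fig, key):
        fname = f"{tag}_{key}.png"
        fig.savefig(outdir / fname, dpi=90, bbox_inches="tight")
        plt.close(fig)
        panels[key] = fname

    palette = dict(zip(names, sns.color_palette("tab10", len(names))))

    # (a) kernel density of totals
    fig, ax = plt.subplots(figsize=(5, 3.5))
    for b in names:
        sns.kdeplot(totals[batch == b], ax=ax, label=b, color=palette[b],
                    warn_singular=False)
    ax.set_xlabel("total counts per observation")
    ax.legend(title="batch")
    save(fig, "kde_totals")

    # (b) CDF of totals
    fig, ax = plt.subplots(figsize=(5, 3.5))
    for b in names:
        x = np.sort(totals[batch == b])
        ax.step(x, np.arange(1, len(x) + 1) / len(x), label=b, color=palette[b])
    ax.set_xlabel("total counts per observation")
    ax.set_ylabel("CDF")
    ax.legend(title="batch")
    save(fig, "cdf_totals")

    # (c) boxplot of totals
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.boxplot([totals[batch == b] for b in names], tick_labels=names)
    ax.set_ylabel("total counts per observation")
    save(fig, "box_totals")

    # (d) gene mean vs variance scatter per batch
    fig, ax = plt.subplots(figsize=(5, 3.5))
    for b, (mean, var) in per_gene_mean_variance(dataset, by_batch=True).items():
        ax.scatter(mean, var, s=6, alpha=0.5, label=b, color=palette[b])
    ax.set_xscale("symlog")
    ax.set_yscale("symlog")
    ax.set_xlabel("gene mean")
    ax.set_ylabel("gene variance")
    ax.legend(title="batch", markerscale=2)
    save(fig, "mean_variance")

    # (e) PCA joint plot
    if "pca" in dataset.embeddings:
        emb = dataset.embeddings["pca"]
        idx = np.arange(len(emb))
        if len(idx) > max_points:
            idx = np.sort(rng.choice(len(idx), size=max_points, replace=False))
        import pandas as pd

        df = pd.DataFrame({"PC1": emb[idx, 0], "PC2": emb[idx, 1],
                           "batch": batch[idx]})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            jg = sns.jointplot(data=df, x="PC1", y="PC2", hue="batch",
                               kind="scatter", height=4.5,
                               joint_kws={"s": 8, "alpha": 0.6})
        jg.figure.savefig(outdir / f"{tag}_pca_joint.png", dpi=90,
                          bbox_inches="tight")
        plt.close(jg.figure)
        panels["pca_joint"] = f"{tag}_pca_joint.png"
    else:
        panels["pca_joint"] = ""

    # (f) UMAP scatter
    if "umap" in dataset.embeddings:
        emb = dataset.embeddings["umap"]
        idx = np.arange(len(emb))
        if len(idx) > max_points:
            idx = np.sort(rng.choice(len(idx), size=max_points, replace=False))
        fig, ax = plt.subplots(figsize=(5, 4))
        for b in names:
            sel = idx[batch[idx] == b]
            ax.scatter(emb[sel, 0], emb[sel, 1], s=6, alpha=0.6, label=b,
                       color=palette[b])
        ax.set_xlabel("UMAP1")
        ax.set_ylabel("UMAP2")
        ax.legend(title="batch", markerscale=2)
        save(fig, "umap")
    else:
        panels["umap"] = ""

    # (g) pairwise Q-Q plots of totals
    if len(names) >= 2:
        from itertools import combinations

        pairs = list(combinations(names, 2))
        ncol = min(3, len(pairs))
        nrow = int(np.ceil(len(pairs) / ncol))
        fig, axes = plt.subplots(nrow, ncol, figsize=(3.2 * ncol, 3.2 * nrow),
                                 squeeze=False)
        q = np.linspace(0.01, 0.99, 99)
        for ax, (a, b) in zip(axes.flat, pairs):
            qa = np.quantile(totals[batch == a], q)
            qb = np.quantile(totals[batch == b], q)
            ax.scatter(qa, qb, s=8)
            lims = [min(qa.min(), qb.min()), max(qa.max(), qb.max())]
            ax.plot(lims, lims, "k--", lw=1)
            ax.set_xlabel(a)
            ax.set_ylabel(b)
        for ax in axes.flat[len(pairs):]:
            ax.axis("off")
        fig.suptitle("Q-Q plots of total counts per batch pair")
        save(fig, "qq_pairs")
    else:
        panels["qq_pairs"] = ""
    return panels


# -- HTML pages -------------------------------------------------------------

def _metric_tables(bundle) -> str:
    cl = bundle.classifier
    parts = [
        "<h2>Batch/domain estimate score</h2>",
        _table(["n_batch", "n_sample", "Train size", "DomainAcc", "Accept rate"],
               [[cl.n_batch, cl.n_sample, cl.train_size,
                 cl.domain_acc, cl.accept_rate]], first_col_name=False),
        "<h2>k-BET score</h2>",
        _table(["chi mean", "95% p value", "Accept rate", "Reject rate"],
               [[bundle.kbet.chi_mean, bundle.kbet.p_summary,
                 bundle.kbet.accept_rate, bundle.kbet.reject_rate]],
               first_col_name=False),
        "<h2>Local inverse Simpson&rsquo;s index</h2>",
        _table(["iLISI", "cLISI", "F1 score"],
               [[bundle.lisi.iLISI, bundle.lisi.cLISI, bundle.lisi.f1]],
               first_col_name=False),
        "<h2>Silhouette score</h2>",
        _table(["iSS", "cSS", "F1 score"],
               [[bundle.silhouette.iSS, bundle.silhouette.cSS,
                 bundle.silhouette.f1]], first_col_name=False),
        f'<p class="note">Type labels: {html.escape(bundle.types_source)}.</p>',
    ]
    return "\n".join(parts)


def _stat_tables(stat_bundle) -> str:
    if stat_bundle is None:
        return ""
    an = stat_bundle.anova
    parts = [
        "<h2>Statistical evaluation</h2>",
        _table(["Variation analysis", "n_batch", "n_sample", "F", "p value",
                f"F ref ({an.n_batch - 1}, {an.n_sample - an.n_batch})"],
               [["", an.n_batch, an.n_sample, an.F, an.p_value, an.F_ref]]),
        _table(["Kruskal-Wallis", "H", "p value"],
               [["", stat_bundle.kruskal.H, stat_bundle.kruskal.p_value]]),
        _table(["K-S test", "n_sample", "k-s stat", "p value"],
               [[f"{r.pair[0]}-{r.pair[1]}", r.n_sample, r.stat, r.p_value]
                for r in stat_bundle.ks_pairs]),
    ]
    if stat_bundle.association is not None:
        parts.append(_table(
            ["Cramer's test", "Pearson contingency coefficient", "Cramer's V coefficient"],
            [["", stat_bundle.association.pearson_c,
              stat_bundle.association.cramers_v]]))
    parts.append(
        f'<p class="note">Condition for the contingency analysis: '
        f"{html.escape(stat_bundle.condition_source)}.</p>")
    return "\n".join(parts)


def _panels_html(panels: dict[str, str]) -> str:
    imgs = []
    for key, fname in panels.items():
        if fname:
            imgs.append(f'<img src="{fname}" alt="{key}">')
        else:
            imgs.append(f'<p class="note">panel {html.escape(key)}: '
                        "prerequisite missing, skipped</p>")
    return '<h2>Visualization</h2><div class="panels">' + "\n".join(imgs) + "</div>"


def render_report(summary, stat_bundle=None, figures: dict[str, dict] | None = None,
                  outdir: str | Path = "report") -> Path:
    """Write index.html, raw.html and one page per method into ``outdir``.

    ``figures`` maps variant name -> panel dict as produced by
    :func:`render_figure_panels`; pages for variants without figures simply
    omit the panel section.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    figures = figures or {}
    variants = list(summary.bundles)
    page_of = {v: ("raw.html" if v == "Raw" else f"method_{_slug(v)}.html")
               for v in variants}

    # main page
    rows = [
        ["k-BET score"] + [summary.bundles[v].kbet.accept_rate for v in variants],
        ["95% p value"] + [summary.bundles[v].kbet.p_summary for v in variants],
        ["BatchEval score"] + [summary.bundles[v].summary.batcheval for v in variants],
    ]
    links = " | ".join(
        f'<a href="{page_of[v]}">{html.escape(v)}</a>' for v in variants)
    failed = "".join(
        f'<p class="note">method {html.escape(k)} failed: {html.escape(v)}</p>'
        for k, v in summary.failed.items())
    body = "\n".join([
        _table([""] + variants, rows),
        f"<p><b>Conclusion.</b> {html.escape(summary.conclusion)}</p>",
        f"<p>Detailed pages: {links}</p>",
        failed,
    ])
    (outdir / "index.html").write_text(
        _PAGE.substitute(title="BatchEval report", nav="", body=body))

    # per-variant pages
    for v in variants:
        parts = []
        if v == "Raw":
            parts.append(_stat_tables(stat_bundle))
        parts.append(_metric_tables(summary.bundles[v]))
        if v in figures:
            parts.append(_panels_html(figures[v]))
        title = "Raw integration evaluation" if v == "Raw" else f"Method: {v}"
        (outdir / page_of[v]).write_text(
            _PAGE.substitute(title=title, nav=_NAV, body="\n".join(parts)))
    return outdir


def _slug(name: str) -> str:
    return "".join(c if c.isalnum() else "_" for c in name.lower())


def rerender_from_json(metrics_json: str | Path, outdir: str | Path) -> Path:
    """Rebuild the HTML pages from an exported metrics JSON (figures are not
    regenerated; pages carry tables only)."""
    import json

    import pandas as pd

    from .benchmark import BenchmarkSummary
    from .classifier import ClassifierResult
    from .metrics import (KbetResult, LisiResult, MetricBundle,
                          SilhouetteResult, SummaryScore)
    from .stats import (AnovaResult, AssociationResult, KSResult, KWResult,
                        StatTestBundle)

    with open(metrics_json) as fh:
        data = json.load(fh)
    bundles = {}
    for name, d in data["variants"].items():
        bundles[name] = MetricBundle(
            classifier=ClassifierResult(**d["classifier"], loss_history=[]),
            kbet=KbetResult(**d["kbet"]),
            lisi=LisiResult(**d["lisi"]),
            silhouette=SilhouetteResult(**d["silhouette"]),
            summary=SummaryScore(**d["summary"]),
            types_source=d.get("types_source", "cell_type"),
        )
    summary = BenchmarkSummary(bundles=bundles, recommended=data["recommended"],
                               conclusion=data["conclusion"],
                               failed=data.get("failed", {}))
    stat_bundle = None
    st = data.get("stat_tests")
    if st is not None:
        assoc = None
        if st.get("association") is not None:
            a = st["association"]
            assoc = AssociationResult(table=pd.DataFrame(a.pop("table")), **a)
        stat_bundle = StatTestBundle(
            anova=AnovaResult(**st["anova"]),
            kruskal=KWResult(**st["kruskal"]),
            ks_pairs=[KSResult(pair=tuple(r.pop("pair")), **r)
                      for r in st["ks_pairs"]],
            association=assoc,
            condition_source=st.get("condition_source", "user"),
        )
    return render_report(summary, stat_bundle, None, outdir)
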