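"""Ready-made single-cell dashboard pages.

``add_sc_page`` adds one of seven page kinds to a dashboard from an
:class:`~dashweave.sc.dataset.SCDataset`. Every page is constructed purely
through the framework's public operations -- page/component/link mutation,
content dispatch, declarative figures -- which is exactly the template
mechanism the core is designed around: this module could live in a separate
package without losing any capability.

Page kinds
----------
``qc``
    Violin plots of the per-cell QC metrics (total counts, detected genes,
    percent mitochondrial), optionally stratified by a categorical, plus a
    per-level aggregate table.
``feature_selection``
    Mean-variance scatter with the selected highly variable genes
    highlighted, plus the HVG table.
``dimred_sample``
    2D embedding colored by a cell grouping, linked to a per-level count
    bar and a per-level aggregate bar (selection recomputes both).
``dimred_feature``
    Embedding + marker table + per-group expression violin; selecting a
    table row re-colors the embedding by that gene's expression.
``feature_grid``
    Static multi-panel figure: the embedding colored by each requested
    feature, with the figure (SVG) and the plotted values (CSV) downloadable.
``dimred_comparison``
    One embedding panel per supplied (label, parameters, coordinates)
    triple, on a tabset page.
``marker_heatmap``
    Heatmap of mean per-group expression of the top marker genes per group.
"""

from __future__ import annotations

import base64
import io

import numpy as np
import pandas as pd

from ..dispatch import Asset, ComponentFragment
from ..errors import OptionError
from ..figures import FigureSpec, Trace, render_figure
from ..linking import LinkSpec
from ..model import Dashboard
from .dataset import SCDataset
from .metrics import (
    aggregate_by_group,
    lognorm_cp10k,
    mean_variance_hvg,
    pca_embedding,
    qc_metrics,
    rank_markers,
)

__all__ = ["add_sc_page", "SC_PAGE_KINDS"]

SC_PAGE_KINDS = (
    "qc",
    "feature_selection",
    "dimred_sample",
    "dimred_feature",
    "feature_grid",
    "dimred_comparison",
    "marker_heatmap",
)

_HVG_COLORMAP = {"hvg": "#c44e52", "other": "#8c8c8c"}


def _require(options: dict, key: str, kind: str):
    if key not in options:
        raise OptionError(f"page kind {kind!r} requires option {key!r}")
    return options[key]


def _embedding(ds: SCDataset, options: dict, kind: str) -> tuple[str, np.ndarray]:
    """Resolve the embedding to draw: the named one, the only one, or the
    deterministic PCA fallback when the dataset carries none."""
    name = options.get("embedding")
    if name is not None:
        if name not in ds.embeddings:
            raise OptionError(
                f"unknown embedding {name!r}; available: "
                + (", ".join(sorted(ds.embeddings)) or "none")
            )
        return name, ds.embeddings[name]
    if len(ds.embeddings) == 1:
        name = next(iter(ds.embeddings))
        return name, ds.embeddings[name]
    if len(ds.embeddings) > 1:
        raise OptionError(
            f"page kind {kind!r} requires option 'embedding' to pick one of: "
            + ", ".join(sorted(ds.embeddings))
        )
    return "pca", pca_embedding(ds)


def _group_var(ds: SCDataset, options: dict) -> str:
    var = options.get("group_var", "group")
    if var not in ds.cell_meta.columns:
        raise OptionError(
            f"cell metadata has no column {var!r}; available: "
            + ", ".join(map(str, ds.cell_meta.columns))
        )
    return var


def _qc_page(db: Dashboard, ds: SCDataset, page_id: str, options: dict) -> None:
    stratify = options.get("stratify")
    if stratify is not None and stratify not in ds.cell_meta.columns:
        raise OptionError(f"stratify column {stratify!r} not in cell metadata")
    qc = qc_metrics(ds)
    strata = (
        ds.cell_meta[stratify].astype(str).to_numpy()
        if stratify
        else np.array(["all"] * ds.n_cells)
    )
    db.add_page(page_id, options.get("title", "Quality Metrics"), "grid_2x2", menu=options.get("menu"))
    for col, label in (
        ("total_counts", "Total counts"),
        ("detected_genes", "Detected genes"),
        ("pct_mito", "% mitochondrial"),
    ):
        fig = FigureSpec(
            traces=[Trace(kind="violin", x=list(strata), y=list(qc[col]))],
            title=label + (f" by {stratify}" if stratify else ""),
            xlabel=stratify or "",
            ylabel=label,
            colormap=options.get("colormap"),
        )
        db.add_component(page_id, fig, title=label)
    rows = []
    for col in ("total_counts", "detected_genes", "pct_mito"):
        agg = aggregate_by_group(qc[col], strata, fun=options.get("aggregate", "mean"))
        for _, r in agg.iterrows():
            rows.append({"metric": col, "level": r["level"], "value": float(r["value"])})
    db.add_component(page_id, rows, title=f"{options.get('aggregate', 'mean')} per level")


def _feature_selection_page(db: Dashboard, ds: SCDataset, page_id: str, options: dict) -> None:
    n_top = int(options.get("n_top", 50))
    hvg = mean_variance_hvg(ds, n_top=n_top, n_bins=int(options.get("n_bins", 20)))
    ok = (hvg["mean"] > 0) & (hvg["variance"] > 0)
    sub = hvg[ok]
    status = np.where(sub["hvg_flag"], "hvg", "other")
    if "hvg_status" not in db.colormaps:
        db.add_colormap("hvg_status", _HVG_COLORMAP)
    fig = FigureSpec(
        traces=[
            Trace(
                kind="scatter",
                x=list(np.log10(sub["mean"])),
                y=list(np.log10(sub["variance"])),
                color_by=list(status),
            )
        ],
        title=f"Mean-variance plot ({n_top} HVGs highlighted)",
        xlabel="log10 mean (CP10K/log1p)",
        ylabel="log10 variance",
        colormap="hvg_status",
    )
    db.add_page(page_id, options.get("title", "Feature Selection"), "focal_left", menu=options.get("menu"))
    db.add_component(page_id, fig, title="Mean-variance")
    table = hvg[hvg["hvg_flag"]].sort_values("residual", ascending=False)
    db.add_component(
        page_id,
        table[["gene_id", "mean", "variance", "residual"]],
        title=f"Top {n_top} highly variable genes",
    )


def _dimred_sample_page(db: Dashboard, ds: SCDataset, page_id: str, options: dict) -> None:
    name, coords = _embedding(ds, options, "dimred_sample")
    group_var = _group_var(ds, options)
    value_var = options.get("value_var", "pct_mito")
    agg_fun = options.get("aggregate", "mean")
    qc = qc_metrics(ds)
    values = (
        qc[value_var] if value_var in qc.columns else ds.cell_meta[value_var]
    ).to_numpy(dtype=float)
    levels = ds.cell_meta[group_var].astype(str)
    records = [
        {group_var: lv, value_var: float(v)} for lv, v in zip(levels, values)
    ]
    scatter = FigureSpec(
        traces=[Trace(kind="scatter", x=list(coords[:, 0]), y=list(coords[:, 1]), color_by=list(levels))],
        title=f"{name} embedding by {group_var}",
        xlabel=f"{name} 1",
        ylabel=f"{name} 2",
        colormap=options.get("colormap"),
        category_var=group_var,
        data=records,
    )
    counts = aggregate_by_group(np.ones(ds.n_cells), levels, fun="sum")
    count_bar = FigureSpec(
        traces=[Trace(kind="bar", x=list(counts["level"]), y=list(counts["value"]))],
        title=f"Cells per {group_var}",
        ylabel="cells",
        colormap=options.get("colormap"),
        category_var=group_var,
    )
    agg = aggregate_by_group(values, levels, fun=agg_fun)
    agg_bar = FigureSpec(
        traces=[Trace(kind="bar", x=list(agg["level"]), y=list(agg["value"]))],
        title=f"{agg_fun} {value_var} per {group_var}",
        ylabel=f"{agg_fun} {value_var}",
        colormap=options.get("colormap"),
        category_var=group_var,
        value_var=value_var,
    )
    db.add_page(page_id, options.get("title", "Cell Explorer"), "grid_2x2", menu=options.get("menu"))
    db.add_component(page_id, scatter, title="Embedding")
    db.add_component(page_id, count_bar, title=f"Cells per {group_var}")
    db.add_component(page_id, agg_bar, title=f"{agg_fun} {value_var}")
    c1, c2, c3 = (f"{page_id}-c{i}" for i in (1, 2, 3))
    db.add_link(page_id, LinkSpec(source=c1, target=c2, channel="subset_recompute",
                                  aggregate="count", variable=group_var))
    db.add_link(page_id, LinkSpec(source=c1, target=c3, channel="subset_recompute",
                                  aggregate=agg_fun, variable=value_var, by=group_var))


def _dimred_feature_page(db: Dashboard, ds: SCDataset, page_id: str, options: dict) -> None:
    name, coords = _embedding(ds, options, "dimred_feature")
    group_var = _group_var(ds, options)
    n_top = int(options.get("n_top", 10))
    markers = rank_markers(ds, group_var, n_top=n_top)
    Y = lognorm_cp10k(ds)
    genes = list(dict.fromkeys(markers["gene_id"]))  # unique, first-seen order
    top_gene = genes[0]
    expr = {g: Y[:, ds.gene_index(g)] for g in genes}
    cell_records = [
        {
            group_var: str(lv),
            **{g: round(float(expr[g][i]), 4) for g in genes},
        }
        for i, lv in enumerate(ds.cell_meta[group_var].astype(str))
    ]
    scatter = FigureSpec(
        traces=[
            Trace(kind="scatter", x=list(coords[:, 0]), y=list(coords[:, 1]),
                  color_by=list(expr[top_gene]))
        ],
        title=f"{name} embedding",
        xlabel=f"{name} 1",
        ylabel=f"{name} 2",
        value_var=top_gene,
        data=cell_records,
    )
    violin = FigureSpec(
        traces=[
            Trace(kind="violin", x=list(ds.cell_meta[group_var].astype(str)),
                  y=list(expr[top_gene]))
        ],
        title=f"{top_gene} by {group_var}",
        xlabel=group_var,
        ylabel="log1p CP10K",
        colormap=options.get("colormap"),
        value_var=top_gene,
        data=cell_records,
    )
    db.add_page(page_id, options.get("title", "Feature Explorer"), "grid_2x2", menu=options.get("menu"))
    db.add_component(page_id, scatter, title="Embedding (select a marker below)")
    db.add_component(page_id, markers, title=f"Top {n_top} markers per {group_var}")
    db.add_component(page_id, violin, title="Expression by group")
    c1, c2, c3 = (f"{page_id}-c{i}" for i in (1, 2, 3))
    # selecting a table row re-colors the embedding and re-labels the violin
    db.add_link(page_id, LinkSpec(source=c2, target=c1, channel="color_by_selection",
                                  variable="gene_id"))
    db.add_link(page_id, LinkSpec(source=c2, target=c3, channel="color_by_selection",
                                  variable="gene_id"))


def _panel_grid_svg(panels: list[str], ncols: int, panel_w: int, panel_h: int) -> str:
    """Compose rendered figure SVGs into one static multi-panel SVG."""
    nrows = (len(panels) + ncols - 1) // ncols
    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" '
        f'viewBox="0 0 {ncols * panel_w} {nrows * panel_h}" '
        f'width="{ncols * panel_w}" height="{nrows * panel_h}">'
    ]
    for i, svg in enumerate(panels):
        x, y = (i % ncols) * panel_w, (i // ncols) * panel_h
        positioned = svg.replace(
            'width="100%" preserveAspectRatio="xMidYMid meet">',
            f'x="{x}" y="{y}" width="{panel_w}" height="{panel_h}">',
            1,
        )
        parts.append(positioned)
    parts.append("</svg>")
    return "".join(parts)


def _feature_grid_page(db: Dashboard, ds: SCDataset, page_id: str, options: dict) -> None:
    features = list(_require(options, "features", "feature_grid"))
    name, coords = _embedding(ds, options, "feature_grid")
    ncols = int(options.get("ncols", 3))
    panel_w = int(options.get("panel_width", 320))
    panel_h = int(options.get("panel_height", 260))
    Y = lognorm_cp10k(ds)
    panels = []
    data = {f"{name}_1": coords[:, 0].round(4), f"{name}_2": coords[:, 1].round(4)}
    for feat in features:
        vals = Y[:, ds.gene_index(feat)]
        data[feat] = vals.round(4)
        fig = FigureSpec(
            traces=[Trace(kind="scatter", x=list(coords[:, 0]), y=list(coords[:, 1]),
                          color_by=list(vals))],
            title=feat,
        )
        panels.append(render_figure(fig, f"{page_id}-panel-{feat}", db.colormaps,
                                    width=panel_w, height=panel_h))
    svg = _panel_grid_svg(panels, ncols, panel_w, panel_h)
    csv_buf = io.StringIO()
    pd.DataFrame(data).to_csv(csv_buf, index=False)
    fragment = ComponentFragment(
        kind="image",
        title=f"Feature grid ({len(features)} features)",
        body=f"![Feature grid](asset:feature_grid.svg)",
        assets=[
            Asset("feature_grid.svg", "image/svg+xml",
                  base64.b64encode(svg.encode("utf-8")).decode("ascii")),
            Asset("feature_grid_data.csv", "text/csv",
                  base64.b64encode(csv_buf.getvalue().encode("utf-8")).decode("ascii")),
        ],
    )
    db.add_page(page_id, options.get("title", "Feature Grid"), "storyboard", menu=options.get("menu"))
    db.add_component(page_id, fragment, title=fragment.title)


def _dimred_comparison_page(db: Dashboard, ds: SCDataset, page_id: str, options: dict) -> None:
    comparisons = options.get("comparisons")
    if comparisons is None:
        if ds.embeddings:
            comparisons = [(nm, {}, nm) for nm in sorted(ds.embeddings)]
        else:
            comparisons = [("pca", {}, pca_embedding(ds))]
    group_var = _group_var(ds, options)
    levels = list(ds.cell_meta[group_var].astype(str))
    db.add_page(page_id, options.get("title", "Embedding Comparison"), "tabset", menu=options.get("menu"))
    for label, params, coords in comparisons:
        if isinstance(coords, str):
            if coords not in ds.embeddings:
                raise OptionError(f"unknown embedding {coords!r} in comparison {label!r}")
            coords = ds.embeddings[coords]
        coords = np.asarray(coords, dtype=float)
        param_str = ", ".join(f"{k}={v}" for k, v in sorted(dict(params).items()))
        title = label + (f" ({param_str})" if param_str else "")
        fig = FigureSpec(
            traces=[Trace(kind="scatter", x=list(coords[:, 0]), y=list(coords[:, 1]),
                          color_by=levels)],
            title=title,
            colormap=options.get("colormap"),
        )
        db.add_component(page_id, fig, title=title)


def _marker_heatmap_page(db: Dashboard, ds: SCDataset, page_id: str, options: dict) -> None:
    group_var = _group_var(ds, options)
    n_top = int(options.get("n_top", 10))
    markers = rank_markers(ds, group_var, n_top=n_top)
    Y = lognorm_cp10k(ds)
    groups = ds.cell_meta[group_var].astype(str).to_numpy()
    levels = sorted(set(groups))
    rows = list(markers["gene_id"])  # one row per (group, rank), group blocks in order
    z = []
    for gene in rows:
        gi = ds.gene_index(gene)
        z.append([float(Y[groups == lv, gi].mean()) for lv in levels])
    fig = FigureSpec(
        traces=[Trace(kind="heatmap", x=levels, y=rows, z=z)],
        title=f"Top {n_top} markers per {group_var} (mean log1p CP10K)",
        data=[
            {"group": r["group"], "gene_id": r["gene_id"],
             "score": round(float(r["score"]), 4), "rank": int(r["rank"])}
            for _, r in markers.iterrows()
        ],
    )
    db.add_page(page_id, options.get("title", "Marker Heatmap"), "storyboard", menu=options.get("menu"))
    db.add_component(page_id, fig, title=f"Top {n_top} marker genes")


_BUILDERS = {
    "qc": _qc_page,
    "feature_selection": _feature_selection_page,
    "dimred_sample": _dimred_sample_page,
    "dimred_feature": _dimred_feature_page,
    "feature_grid": _feature_grid_page,
    "dimred_comparison": _dimred_comparison_page,
    "marker_heatmap": _marker_heatmap_page,
}


def add_sc_page(
    db: Dashboard,
    ds: SCDataset,
    kind: str,
    options: dict | None = None,
) -> Dashboard:
    """Add a ready-made single-cell page of the given *kind* (see module
    docs). ``options`` tunes the page; common keys are ``page_id``,
    ``title``, ``menu``, ``embedding``, ``group_var``, ``colormap`` and
    ``n_top``; ``feature_grid`` additionally requires ``features``.

    Raises
    ------
    OptionError
        For an unknown kind or a missing/invalid required option.
    """
    if kind not in SC_PAGE_KINDS:
        raise OptionError(
            f"unknown sc page kind {kind!r}; valid kinds: {', '.join(SC_PAGE_KINDS)}"
        )
    options = dict(options or {})
    page_id = options.get("page_id", kind)
    _BUILDERS[kind](db, ds, page_id, options)
    return db
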