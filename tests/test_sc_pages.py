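import ast
import base64
import importlib
from pathlib import Path

import pytest

from dashweave import compile_wiring, create_dashboard
from dashweave.errors import OptionError
from dashweave.sc import add_sc_page


@pytest.fixture()
def db():
    return create_dashboard("sc test")


class TestQCPage:
    def test_stratified_violins_and_aggregate_table(self, db, small_sim):
        ds, _ = small_sim
        add_sc_page(db, ds, "qc", {"stratify": "condition"})
        page = db.pages["qc"]
        assert page.layout == "grid_2x2" and len(page.components) == 4
        violins = [c for c in page.components if c.figure is not None]
        assert len(violins) == 3
        # violin categories are the stratification levels
        strata = set(ds.cell_meta["condition"].astype(str))
        assert set(violins[0].figure.traces[0].x) == strata
        table = page.components[-1]
        assert table.kind == "table"
        metrics = {r["metric"] for r in table.data_payload}
        assert metrics == {"total_counts", "detected_genes", "pct_mito"}

    def test_unknown_stratifier_rejected(self, db, small_sim):
        ds, _ = small_sim
        with pytest.raises(OptionError, match="stratify"):
            add_sc_page(db, ds, "qc", {"stratify": "nope"})


class TestFeatureSelectionPage:
    def test_scatter_plus_hvg_table(self, db, small_sim):
        ds, _ = small_sim
        add_sc_page(db, ds, "feature_selection", {"n_top": 15})
        page = db.pages["feature_selection"]
        assert page.layout == "focal_left" and len(page.components) == 2
        scatter = page.components[0].figure
        assert scatter.colormap == "hvg_status" and "hvg_status" in db.colormaps
        assert scatter.traces[0].color_by.count("hvg") == 15
        assert len(page.components[1].data_payload) == 15


class TestDimredSamplePage:
    def test_grid_with_three_components_two_links(self, db, small_sim):
        ds, _ = small_sim
        add_sc_page(db, ds, "dimred_sample", {"embedding": "blob"})
        page = db.pages["dimred_sample"]
        assert page.layout == "grid_2x2"
        assert len(page.components) == 3 and len(page.links) == 2
        wiring = compile_wiring(page)
        assert [w.update for w in wiring] == ["recompute_bars", "recompute_bars"]
        assert wiring[0].aggregation["fun"] == "count"
        assert wiring[1].aggregation == {"fun": "mean", "variable": "pct_mito", "by": "group"}

    def test_payload_has_one_record_per_cell(self, db, small_sim):
        ds, _ = small_sim
        add_sc_page(db, ds, "dimred_sample", {"embedding": "blob"})
        assert len(db.pages["dimred_sample"].components[0].data_payload) == ds.n_cells


class TestDimredFeaturePage:
    def test_table_selection_recolors_embedding_and_violin(self, db, small_sim):
        ds, _ = small_sim
        add_sc_page(db, ds, "dimred_feature", {"embedding": "blob"})
        page = db.pages["dimred_feature"]
        assert len(page.components) == 3 and len(page.links) == 2
        wiring = compile_wiring(page)
        assert {w.update for w in wiring} == {"recolor"}
        assert {w.source for w in wiring} == {"dimred_feature-c2"}
        assert {w.target for w in wiring} == {"dimred_feature-c1", "dimred_feature-c3"}


class TestFeatureGridPage:
    def test_requires_features_option(self, db, small_sim):
        ds, _ = small_sim
        with pytest.raises(OptionError, match="features"):
            add_sc_page(db, ds, "feature_grid")

    def test_multipanel_svg_and_csv_export(self, db, small_sim):
        ds, _ = small_sim
        feats = list(ds.gene_ids[:3])
        add_sc_page(db, ds, "feature_grid",
                    {"features": feats, "ncols": 2, "embedding": "blob"})
        frag = db.pages["feature_grid"].components[0]
        assets = {a.asset_id: a for a in frag.assets}
        assert set(assets) == {"feature_grid.svg", "feature_grid_data.csv"}
        svg = base64.b64decode(assets["feature_grid.svg"].payload_b64).decode()
        assert svg.count("<svg") == 4  # outer + one panel per feature
        csv = base64.b64decode(assets["feature_grid_data.csv"].payload_b64).decode()
        header = csv.splitlines()[0].split(",")
        assert header == ["blob_1", "blob_2"] + feats
        assert len(csv.splitlines()) == ds.n_cells + 1


class TestDimredComparisonPage:
    def test_one_tab_per_triple(self, db, small_sim):
        ds, _ = small_sim
        import numpy as np

        comparisons = [
            ("umap", {"n_neighbors": 15}, "blob"),
            ("umap", {"n_neighbors": 30}, np.zeros((ds.n_cells, 2))),
            ("tsne", {"perplexity": 10}, "blob"),
        ]
        add_sc_page(db, ds, "dimred_comparison", {"comparisons": comparisons})
        page = db.pages["dimred_comparison"]
        assert page.layout == "tabset" and len(page.components) == 3
        assert "n_neighbors=15" in page.components[0].title

    def test_pca_fallback_without_embeddings(self, db, small_sim):
        ds, _ = small_sim
        from dashweave.sc.dataset import SCDataset

        bare = SCDataset(counts=ds.counts, cell_meta=ds.cell_meta, gene_meta=ds.gene_meta)
        add_sc_page(db, bare, "dimred_comparison")
        assert db.pages["dimred_comparison"].components[0].title.startswith("pca")


class TestMarkerHeatmapPage:
    def test_default_shows_ten_genes_per_group(self, db, small_sim):
        ds, _ = small_sim
        add_sc_page(db, ds, "marker_heatmap")
        frag = db.pages["marker_heatmap"].components[0]
        trace = frag.figure.traces[0]
        groups = sorted(set(ds.cell_meta["group"]))
        assert trace.x == groups
        assert len(trace.y) == 10 * len(groups)
        for group in groups:
            recs = [r for r in frag.data_payload if r["group"] == group]
            assert [r["rank"] for r in recs] == list(range(1, 11))


def test_unknown_kind_rejected(db, small_sim):
    ds, _ = small_sim
    with pytest.raises(OptionError, match="volcano"):
        add_sc_page(db, ds, "volcano")


# --- architecture: the extension uses only public operations -----------------

_CORE_MODULES = {
    "dashweave.model",
    "dashweave.dispatch",
    "dashweave.figures",
    "dashweave.linking",
    "dashweave.layouts",
    "dashweave.errors",
}
_ALLOWED_OTHER = {
    "dashweave.sc.dataset",
    "dashweave.sc.metrics",
    "dashweave.sc.pages",
    "dashweave.sc.demo",
    "dashweave.simulate",
    "numpy",
    "pandas",
    "base64",
    "io",
    "json",
    "__future__",
}


def _resolve(module: str | None, level: int, importer: str) -> str:
    if level == 0:
        return module or ""
    parts = importer.split(".")[: -level or None]
    base = ".".join(parts[: len(parts)])
    return f"{base}.{module}" if module else base


@pytest.mark.parametrize("modname", ["dashweave.sc.pages", "dashweave.sc.demo"])
def test_extension_imports_only_public_core_operations(modname):
    """The single-cell extension is a genuine template package: every core
    name it imports is part of the core modules' public (__all__) surface,
    and it never touches private attributes."""
    src = Path(importlib.import_module(modname).__file__).read_text()
    tree = ast.parse(src)
    for node in ast.walk(tree):
        if isinstance(node, ast.Import):
            for alias in node.names:
                assert alias.name in _ALLOWED_OTHER | _CORE_MODULES, alias.name
        elif isinstance(node, ast.ImportFrom):
            target = _resolve(node.module, node.level, modname)
            assert target in _ALLOWED_OTHER | _CORE_MODULES, target
            if target in _CORE_MODULES:
                public = importlib.import_module(target).__all__
                for alias in node.names:
                    assert alias.name in public, f"{target}.{alias.name} is not public"
        elif isinstance(node, ast.Attribute):
            assert not (
                node.attr.startswith("_") and not node.attr.startswith("__")
            ), f"private attribute access: {node.attr}"
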