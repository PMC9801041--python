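"""End-to-end demo: a full multi-page single-cell dashboard from a seeded
synthetic dataset. Used by the ``dashweave sc-demo`` command and throughout
the test suite as the canonical whole-pipeline fixture."""

from __future__ import annotations

from ..figures import DEFAULT_PALETTE
from ..model import Dashboard, create_dashboard
from .dataset import SCDataset
from .pages import add_sc_page

__all__ = ["build_demo_dashboard", "demo_dataset"]


def demo_dataset(seed: int, spec=None) -> SCDataset:
    """The demo's synthetic dataset: default simulation conditions plus a
    planted-blob 2D embedding named ``blob`` standing in for t-SNE/UMAP."""
    # imported lazily: the generator module itself consumes SCDataset
    from ..simulate import SimulationSpec, simulate_counts, simulate_embedding

    spec = spec or SimulationSpec(seed=seed)
    ds, _ = simulate_counts(spec)
    ds.embeddings["blob"] = simulate_embedding(
        ds.cell_meta["group"], separation=10.0, spread=1.0, seed=seed
    )
    return ds


def build_demo_dashboard(seed: int = 1, spec=None) -> Dashboard:
    """Build the complete demo dashboard (all seven page kinds) from one
    seeded synthetic dataset."""
    ds = demo_dataset(seed, spec)
    levels = sorted(set(ds.cell_meta["group"].astype(str)))
    db = create_dashboard(
        title="Single-cell demo dashboard",
        author="dashweave",
        theme="default",
    )
    db.add_colormap("group", {lv: DEFAULT_PALETTE[i % len(DEFAULT_PALETTE)]
                              for i, lv in enumerate(levels)})
    db.add_page("overview", "Overview", "storyboard")
    db.add_component(
        "overview",
        (
            "## Synthetic single-cell dataset\n\n"
            f"Negative-binomial counts for **{ds.n_cells} cells x {ds.n_genes} genes** "
            f"with {len(levels)} planted cell groups, group-specific marker genes, "
            "a planted high-dispersion gene set and a mitochondrial gene subset.\n\n"
            "Use the navigation bar to explore quality metrics, feature "
            "selection, linked embedding views, marker genes and embedding "
            "comparisons."
        ),
        title="About this demo",
    )
    db.add_to_sidebar(
        "**Demo dashboard** built programmatically from a seeded synthetic "
        "dataset; every figure derives from the same count matrix."
    )
    add_sc_page(db, ds, "qc", {"stratify": "condition", "menu": "QC"})
    add_sc_page(db, ds, "feature_selection", {"menu": "QC"})
    add_sc_page(db, ds, "dimred_sample",
                {"embedding": "blob", "colormap": "group", "menu": "Explore"})
    add_sc_page(db, ds, "dimred_feature",
                {"embedding": "blob", "colormap": "group", "menu": "Explore"})
    add_sc_page(db, ds, "marker_heatmap", {"menu": "Markers"})
    first_markers = [f"gene_{i + 1:04d}" for i in range(4)]
    add_sc_page(db, ds, "feature_grid",
                {"embedding": "blob", "features": first_markers, "ncols": 2, "menu": "Tools"})
    add_sc_page(db, ds, "dimred_comparison", {"menu": "Tools"})
    return db
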