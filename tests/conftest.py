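import base64

import numpy as np
import pandas as pd
import pytest

from dashweave.sc.dataset import SCDataset
from dashweave.simulate import SimulationSpec, simulate_counts, simulate_embedding

# 1x1 transparent PNG, for image-dispatch tests
PNG_1X1_B64 = (
    "iVBORw0KGgoAAAANSUhEUgAAAAEAAAABCAYAAAAfFcSJAAAADUlEQVR42mNkYPhfDwAChwGA"
    "60e6kgAAAABJRU5ErkJggg=="
)


@pytest.fixture()
def png_file(tmp_path):
    p = tmp_path / "fig.png"
    p.write_bytes(base64.b64decode(PNG_1X1_B64))
    return p


@pytest.fixture()
def tiny_ds():
    """3 cells x 3 genes with one mitochondrial gene; hand-checkable."""
    counts = np.array(
        [
            [1, 0, 3],  # total 4, detected 2, mito 3 -> 75%
            [0, 0, 0],  # all-zero cell
            [2, 2, 0],  # total 4, detected 2, mito 0
        ]
    )
    gene_meta = pd.DataFrame(
        {"gene_id": ["g1", "g2", "mt_g3"], "mito": [False, False, True]}
    )
    cell_meta = pd.DataFrame(
        {"cell_id": ["c1", "c2", "c3"], "group": ["a", "b", "a"]}
    )
    return SCDataset(counts=counts, cell_meta=cell_meta, gene_meta=gene_meta)


SMALL_SPEC = SimulationSpec(
    seed=7,
    n_cells=90,
    n_genes=150,
    k_groups=3,
    markers_per_group=3,
    n_hvg_planted=10,
)


@pytest.fixture(scope="session")
def small_sim():
    """Small simulated dataset with an embedding, shared across page tests."""
    ds, truth = simulate_counts(SMALL_SPEC)
    ds.embeddings["blob"] = simulate_embedding(
        ds.cell_meta["group"], separation=10.0, spread=1.0, seed=7
    )
    return ds, truth


@pytest.fixture(scope="session")
def demo_dashboard():
    from dashweave.sc import build_demo_dashboard

    return build_demo_dashboard(seed=1)
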