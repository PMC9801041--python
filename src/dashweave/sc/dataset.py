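"""Neutral single-cell dataset container and plain-text I/O.

:class:`SCDataset` replaces the rich R containers (SingleCellExperiment,
Seurat) with the minimal structure the dashboard page templates need: a
cells x genes count matrix, per-cell and per-gene metadata tables, and named
precomputed 2D embeddings. Readers accept MTX (+ genes/barcodes TSVs, 10x
convention: genes x cells, transposed on load) and dense TSV (cells x genes);
metadata and embeddings are CSV/TSV. All readers convert to the fixed
cells x genes orientation on load.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from ..errors import ConfigurationError

__all__ = [
    "SCDataset",
    "read_counts_mtx",
    "read_counts_tsv",
    "read_meta_table",
    "read_embedding_tsv",
    "write_dataset",
    "load_dataset",
    "from_anndata",
]

#: Gene-name prefix treated as mitochondrial by the load-time convenience
#: flagging (case-insensitive), the standard convention for human/mouse.
MITO_PREFIX = "mt-"


@dataclass
class SCDataset:
    """Counts (cells x genes) plus cell/gene metadata and 2D embeddings.

    ``gene_meta`` must carry unique gene ids in a ``gene_id`` column and a
    boolean ``mito`` flag; if the flag is absent it is derived from the
    ``MT-`` name prefix (case-insensitive).
    """

    counts: np.ndarray | sp.spmatrix
    cell_meta: pd.DataFrame
    gene_meta: pd.DataFrame
    embeddings: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n_cells, n_genes = self.counts.shape
        if len(self.cell_meta) != n_cells:
            raise ConfigurationError(
                f"cell_meta has {len(self.cell_meta)} rows but counts has {n_cells} cells"
            )
        if len(self.gene_meta) != n_genes:
            raise ConfigurationError(
                f"gene_meta has {len(self.gene_meta)} rows but counts has {n_genes} genes"
            )
        if "gene_id" not in self.gene_meta.columns:
            raise ConfigurationError("gene_meta requires a 'gene_id' column")
        ids = self.gene_meta["gene_id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise ConfigurationError(f"gene ids are not unique (e.g. {dup!r})")
        if "mito" not in self.gene_meta.columns:
            self.gene_meta = self.gene_meta.copy()
            self.gene_meta["mito"] = (
                ids.astype(str).str.lower().str.startswith(MITO_PREFIX)
            )
        self.gene_meta["mito"] = self.gene_meta["mito"].astype(bool)
        for name, coords in self.embeddings.items():
            coords = np.asarray(coords, dtype=float)
            if coords.shape != (n_cells, 2):
                raise ConfigurationError(
                    f"embedding {name!r} has shape {coords.shape}, expected ({n_cells}, 2)"
                )
            self.embeddings[name] = coords

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    @property
    def gene_ids(self) -> np.ndarray:
        return self.gene_meta["gene_id"].to_numpy()

    def counts_dense(self) -> np.ndarray:
        if sp.issparse(self.counts):
            return np.asarray(self.counts.todense(), dtype=float)
        return np.asarray(self.counts, dtype=float)

    def gene_index(self, gene_id: str) -> int:
        idx = np.flatnonzero(self.gene_ids == gene_id)
        if len(idx) == 0:
            raise ConfigurationError(f"unknown gene id {gene_id!r}")
        return int(idx[0])


def read_counts_mtx(mtx_path, genes_path, barcodes_path) -> tuple[sp.csr_matrix, pd.DataFrame, pd.DataFrame]:
    """Read a 10x-style MTX triplet (matrix genes x cells; transposed on load).

    Returns (counts cells x genes, gene table with ``gene_id``, barcode table
    with ``cell_id``)."""
    m = scipy.io.mmread(str(mtx_path)).tocsr().T.tocsr()
    genes = pd.read_csv(genes_path, sep="\t", header=None)
    genes = genes.rename(columns={0: "gene_id"})
    barcodes = pd.read_csv(barcodes_path, sep="\t", header=None, names=["cell_id"])
    if m.shape != (len(barcodes), len(genes)):
        raise ConfigurationError(
            f"MTX shape {m.shape} does not match {len(barcodes)} barcodes x {len(genes)} genes"
        )
    return m, genes, barcodes


def read_counts_tsv(path) -> tuple[np.ndarray, pd.DataFrame, pd.DataFrame]:
    """Read a dense TSV count matrix, cells x genes, with a header row of
    gene ids and the first column holding cell ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    genes = pd.DataFrame({"gene_id": df.columns.astype(str)})
    cells = pd.DataFrame({"cell_id": df.index.astype(str)})
    return df.to_numpy(dtype=float), genes, cells


def read_meta_table(path) -> pd.DataFrame:
    sep = "," if str(path).endswith(".csv") else "\t"
    return pd.read_csv(path, sep=sep)


def read_embedding_tsv(path) -> np.ndarray:
    """Read a per-cell 2D embedding from a TSV with columns x, y (extra
    columns are ignored)."""
    df = pd.read_csv(path, sep="\t")
    cols = [c for c in df.columns if c.lower() in ("x", "y")]
    if len(cols) != 2:
        df = df.select_dtypes("number").iloc[:, :2]
    else:
        df = df[sorted(cols, key=str.lower)]
    return df.to_numpy(dtype=float)


def load_dataset(
    counts_path,
    cell_meta_path=None,
    gene_meta_path=None,
    genes_path=None,
    barcodes_path=None,
    embeddings: dict[str, object] | None = None,
) -> SCDataset:
    """Assemble an :class:`SCDataset` from files.

    ``counts_path`` ending in ``.mtx`` requires ``genes_path`` and
    ``barcodes_path``; anything else is read as dense TSV. ``embeddings``
    maps names to TSV paths (or ready arrays).
    """
    counts_path = Path(counts_path)
    if counts_path.suffix == ".mtx":
        if genes_path is None or barcodes_path is None:
            raise ConfigurationError("MTX counts require genes_path and barcodes_path")
        counts, genes, cells = read_counts_mtx(counts_path, genes_path, barcodes_path)
    else:
        counts, genes, cells = read_counts_tsv(counts_path)
    cell_meta = read_meta_table(cell_meta_path) if cell_meta_path else cells
    gene_meta = read_meta_table(gene_meta_path) if gene_meta_path else genes
    emb = {}
    for name, src in (embeddings or {}).items():
        emb[name] = src if isinstance(src, np.ndarray) else read_embedding_tsv(src)
    return SCDataset(counts=counts, cell_meta=cell_meta, gene_meta=gene_meta, embeddings=emb)


def write_dataset(ds: SCDataset, out_dir) -> dict[str, Path]:
    """Write the MTX/TSV fixture files the ``sc-report`` CLI reads back:
    matrix.mtx (genes x cells), genes.tsv, barcodes.tsv, cell_meta.tsv,
    gene_meta.tsv and embedding_<name>.tsv per embedding."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    m = sp.coo_matrix(ds.counts).T  # write genes x cells (10x convention)
    paths["counts"] = out / "matrix.mtx"
    scipy.io.mmwrite(paths["counts"], m, field="integer")
    paths["genes"] = out / "genes.tsv"
    ds.gene_meta["gene_id"].to_csv(paths["genes"], sep="\t", header=False, index=False)
    paths["barcodes"] = out / "barcodes.tsv"
    cell_ids = (
        ds.cell_meta["cell_id"]
        if "cell_id" in ds.cell_meta.columns
        else pd.Series([f"cell_{i + 1}" for i in range(ds.n_cells)])
    )
    cell_ids.to_csv(paths["barcodes"], sep="\t", header=False, index=False)
    paths["cell_meta"] = out / "cell_meta.tsv"
    ds.cell_meta.to_csv(paths["cell_meta"], sep="\t", index=False)
    paths["gene_meta"] = out / "gene_meta.tsv"
    ds.gene_meta.to_csv(paths["gene_meta"], sep="\t", index=False)
    for name, coords in ds.embeddings.items():
        p = out / f"embedding_{name}.tsv"
        pd.DataFrame(coords, columns=["x", "y"]).to_csv(p, sep="\t", index=False)
        paths[f"embedding_{name}"] = p
    return paths


def from_anndata(adata) -> SCDataset:
    """Adapter from an AnnData object (optional dependency): X is taken as
    raw counts, obs/var as metadata, 2D obsm entries as embeddings."""
    counts = adata.X
    if hasattr(counts, "tocsr"):
        counts = counts.tocsr()
    else:
        counts = np.asarray(counts)
    gene_meta = adata.var.reset_index().rename(columns={adata.var.index.name or "index": "gene_id"})
    cell_meta = adata.obs.reset_index().rename(columns={adata.obs.index.name or "index": "cell_id"})
    emb = {
        key.removeprefix("X_"): np.asarray(val)[:, :2]
        for key, val in adata.obsm.items()
        if np.asarray(val).ndim == 2 and np.asarray(val).shape[1] >= 2
    }
    return SCDataset(counts=counts, cell_meta=cell_meta, gene_meta=gene_meta, embeddings=emb)
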