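"""Synthetic single-cell datasets with known ground truth.

Generates negative-binomial counts with planted cell groups, planted marker
genes (group-specific mean shifts), a planted high-dispersion gene set (the
"true" highly variable genes), and a mitochondria-flagged gene subset, so
every page template and every recovery property can be exercised without any
external download. Not a realistic scRNA-seq simulator: there is no
library-size confounding, no doublets and no ambient RNA -- just the
structure the visualized analyses assume.

The generator is fully seeded: a fixed :class:`SimulationSpec` reproduces
byte-identical output, and the sampling scheme below is part of the package
contract so fixtures stay stable across releases:

1. gene base means ~ log-uniform over ``nb_mean_range``; genes carrying
   planted structure (markers, planted HVGs) draw from the upper half of
   the range (log scale), because structure planted on near-zero genes is
   statistically invisible at realistic depth and the ground truth exists
   to be recoverable;
2. per-gene dispersion ``nb_dispersion``, multiplied by
   ``hvg_inflation_factor`` for the ``n_hvg_planted`` planted HVGs;
3. marker genes (disjoint blocks of ``markers_per_group`` per group) have
   their mean multiplied by ``2**marker_lfc`` within their group;
4. counts ~ Poisson(Gamma(1/dispersion, mean*dispersion)) (i.e. NB with
   variance mean + dispersion*mean^2);
5. cells are assigned round-robin to groups; batch and condition covariates
   are drawn uniformly.

Gene layout: markers first (one block per group), then planted HVGs, then
background genes; the mitochondrial flag is set on a trailing slice so it
never overlaps markers or planted HVGs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import SimulationError
from .sc.dataset import SCDataset

__all__ = ["SimulationSpec", "GroundTruth", "simulate_counts", "simulate_embedding"]


@dataclass(frozen=True)
class SimulationSpec:
    """Study conditions for one synthetic dataset.

    Defaults describe a small but structured experiment: 500 cells, 2000
    genes, three cell groups with five markers each at a log2 fold change of
    2, fifty genes at 4x inflated dispersion, 5% mitochondrial genes, two
    batches. ``seed`` is mandatory.
    """

    seed: int
    n_cells: int = 500
    n_genes: int = 2000
    k_groups: int = 3
    markers_per_group: int = 5
    marker_lfc: float = 2.0
    nb_mean_range: tuple[float, float] = (0.1, 20.0)
    nb_dispersion: float = 0.5
    hvg_inflation_factor: float = 4.0
    n_hvg_planted: int = 50
    pct_mito_genes: float = 0.05
    batch_levels: int = 2

    def validate(self) -> None:
        positive = {
            "n_cells": self.n_cells,
            "n_genes": self.n_genes,
            "k_groups": self.k_groups,
            "markers_per_group": self.markers_per_group,
            "nb_dispersion": self.nb_dispersion,
            "hvg_inflation_factor": self.hvg_inflation_factor,
            "batch_levels": self.batch_levels,
        }
        for name, v in positive.items():
            if v <= 0:
                raise SimulationError(f"{name} must be positive, got {v!r}")
        if self.n_hvg_planted < 0 or not (0.0 <= self.pct_mito_genes < 1.0):
            raise SimulationError(
                "n_hvg_planted must be >= 0 and pct_mito_genes in [0, 1)"
            )
        lo, hi = self.nb_mean_range
        if not (0 < lo <= hi):
            raise SimulationError(f"nb_mean_range must satisfy 0 < lo <= hi, got {self.nb_mean_range!r}")
        n_special = self.k_groups * self.markers_per_group + self.n_hvg_planted
        if n_special + int(self.pct_mito_genes * self.n_genes) > self.n_genes:
            raise SimulationError(
                f"n_genes={self.n_genes} too small for {n_special} marker/HVG genes "
                f"plus the mitochondrial subset"
            )
        if self.seed is None:
            raise SimulationError("seed is mandatory")


@dataclass(frozen=True)
class GroundTruth:
    """Planted structure of a simulated dataset."""

    group: np.ndarray  # per-cell group label
    marker_map: dict[str, list[str]] = field(default_factory=dict)  # group -> gene ids
    hvg_ids: list[str] = field(default_factory=list)


def _gene_ids(n: int) -> np.ndarray:
    width = max(4, len(str(n)))
    return np.array([f"gene_{i + 1:0{width}d}" for i in range(n)])


def simulate_counts(spec: SimulationSpec) -> tuple[SCDataset, GroundTruth]:
    """Draw one dataset from *spec*; returns the dataset and its truth."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n, g = spec.n_cells, spec.n_genes
    gene_ids = _gene_ids(g)

    lo, hi = spec.nb_mean_range
    base_mean = np.exp(rng.uniform(np.log(lo), np.log(hi), size=g))

    n_markers = spec.k_groups * spec.markers_per_group
    marker_idx = np.arange(n_markers)
    hvg_idx = np.arange(n_markers, n_markers + spec.n_hvg_planted)
    # planted-structure genes are expressed: log-uniform over the upper
    # half (log scale) of the mean range
    special = np.concatenate([marker_idx, hvg_idx])
    mid = np.sqrt(lo * hi)
    base_mean[special] = np.exp(rng.uniform(np.log(mid), np.log(hi), size=len(special)))
    dispersion = np.full(g, spec.nb_dispersion)
    dispersion[hvg_idx] *= spec.hvg_inflation_factor

    groups = np.array([f"group_{i % spec.k_groups + 1}" for i in range(n)])
    group_levels = [f"group_{i + 1}" for i in range(spec.k_groups)]
    marker_map = {
        level: list(
            gene_ids[marker_idx[i * spec.markers_per_group : (i + 1) * spec.markers_per_group]]
        )
        for i, level in enumerate(group_levels)
    }

    mean = np.tile(base_mean, (n, 1))
    fold = 2.0 ** spec.marker_lfc
    for i, level in enumerate(group_levels):
        block = marker_idx[i * spec.markers_per_group : (i + 1) * spec.markers_per_group]
        mean[np.ix_(groups == level, block)] *= fold

    lam = rng.gamma(shape=1.0 / dispersion, scale=mean * dispersion)
    counts = rng.poisson(lam).astype(np.int64)

    n_mito = int(round(spec.pct_mito_genes * g))
    mito = np.zeros(g, dtype=bool)
    if n_mito:
        mito[-n_mito:] = True
        gene_ids = gene_ids.astype(object)
        gene_ids[-n_mito:] = [f"mt_{gid}" for gid in gene_ids[-n_mito:]]

    gene_meta = pd.DataFrame({"gene_id": gene_ids, "mito": mito})
    cell_meta = pd.DataFrame(
        {
            "cell_id": [f"cell_{i + 1:0{max(4, len(str(n)))}d}" for i in range(n)],
            "group": groups,
            "batch": rng.integers(1, spec.batch_levels + 1, size=n).astype(str),
            "condition": rng.choice(["ctrl", "treated"], size=n),
        }
    )
    ds = SCDataset(counts=counts, cell_meta=cell_meta, gene_meta=gene_meta)
    truth = GroundTruth(
        group=groups,
        marker_map={k: [str(v) for v in vs] for k, vs in marker_map.items()},
        hvg_ids=[str(v) for v in gene_ids[hvg_idx]],
    )
    return ds, truth


def simulate_embedding(
    groups, separation: float = 10.0, spread: float = 1.0, seed: int = 0
) -> np.ndarray:
    """Per-cell 2D coordinates: one Gaussian blob per group.

    Blob centers sit equally spaced on a circle whose radius guarantees a
    pairwise center distance of at least *separation*; each cell scatters
    around its group center with standard deviation *spread*. Stands in for
    t-SNE/UMAP coordinates in fixtures and demos.
    """
    if separation <= 0 or spread <= 0:
        raise SimulationError("separation and spread must be positive")
    groups = np.asarray(groups)
    levels = sorted(set(groups.tolist()), key=str)
    k = len(levels)
    rng = np.random.default_rng(seed)
    if k == 1:
        centers = np.zeros((1, 2))
    else:
        radius = separation / (2.0 * np.sin(np.pi / k))
        angles = 2.0 * np.pi * np.arange(k) / k
        centers = radius * np.column_stack([np.cos(angles), np.sin(angles)])
    coords = np.empty((len(groups), 2))
    for i, level in enumerate(levels):
        mask = groups == level
        coords[mask] = centers[i] + rng.normal(0.0, spread, size=(int(mask.sum()), 2))
    return coords
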