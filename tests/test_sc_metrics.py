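import math

import numpy as np
import pandas as pd
import pytest

from dashweave.errors import ConfigurationError, OptionError
from dashweave.sc import (
    aggregate_by_group,
    lognorm_cp10k,
    mean_variance_hvg,
    pca_embedding,
    qc_metrics,
    rank_markers,
)
from dashweave.sc.dataset import SCDataset
from dashweave.simulate import SimulationSpec, simulate_counts


class TestQCMetrics:
    def test_hand_computed_cell(self, tiny_ds):
        qc = qc_metrics(tiny_ds)
        # counts [1,0,3], mito flags [F,F,T]
        assert qc.loc[0, "total_counts"] == 4
        assert qc.loc[0, "detected_genes"] == 2
        assert qc.loc[0, "pct_mito"] == 75.0

    def test_all_zero_cell_flagged(self, tiny_ds):
        qc = qc_metrics(tiny_ds)
        row = qc.loc[1]
        assert (row.total_counts, row.detected_genes, row.pct_mito) == (0, 0, 0.0)
        assert bool(row.zero_total)

    def test_total_counts_conservation(self, tiny_ds):
        qc = qc_metrics(tiny_ds)
        assert qc.total_counts.sum() == np.asarray(tiny_ds.counts).sum()

    def test_negative_counts_rejected(self, tiny_ds):
        bad = SCDataset(
            counts=np.array([[1, -1, 0], [0, 0, 0], [1, 1, 1]]),
            cell_meta=tiny_ds.cell_meta,
            gene_meta=tiny_ds.gene_meta,
        )
        with pytest.raises(ConfigurationError, match="negative"):
            qc_metrics(bad)


class TestAggregateByGroup:
    def test_mean_per_level(self):
        out = aggregate_by_group([1, 2, 3, 4], ["a", "a", "b", "b"], "mean")
        assert list(out.level) == ["a", "b"]
        assert list(out.value) == [1.5, 3.5]

    def test_sum_conserves_total(self):
        vals = [1.0, 2.5, 3.0, 0.5]
        out = aggregate_by_group(vals, ["a", "b", "a", "b"], "sum")
        assert out.value.sum() == pytest.approx(sum(vals))

    def test_unknown_function_lists_valid_names(self):
        with pytest.raises(OptionError, match="mean.*median.*sum"):
            aggregate_by_group([1], ["a"], "max")

    def test_length_mismatch(self):
        with pytest.raises(ConfigurationError):
            aggregate_by_group([1, 2], ["a"])


class TestMeanVarianceHVG:
    def _two_cell_ds(self):
        # two cells with equal totals: CP10K scaling is identical for both
        counts = np.array([[0, 4], [2, 2]])
        return SCDataset(
            counts=counts,
            cell_meta=pd.DataFrame({"cell_id": ["c1", "c2"]}),
            gene_meta=pd.DataFrame({"gene_id": ["gA", "gB"], "mito": [False, False]}),
        )

    def test_two_point_moments_match_hand_computation(self):
        ds = self._two_cell_ds()
        out = mean_variance_hvg(ds, n_top=1).set_index("gene_id")
        # gene gA counts (0, 2), totals both 4 -> scale 10000/4 = 2500
        v1, v2 = math.log1p(0.0), math.log1p(2 * 2500)
        assert out.loc["gA", "mean"] == pytest.approx((v1 + v2) / 2)
        assert out.loc["gA", "variance"] == pytest.approx(
            ((v1 - (v1 + v2) / 2) ** 2 + (v2 - (v1 + v2) / 2) ** 2) / 1  # ddof=1
        )

    def test_exactly_n_top_flagged_and_boundary(self, small_sim):
        ds, _ = small_sim
        out = mean_variance_hvg(ds, n_top=20)
        assert int(out.hvg_flag.sum()) == 20
        assert mean_variance_hvg(ds, n_top=ds.n_genes).hvg_flag.all()

    def test_n_top_above_gene_count_rejected(self, small_sim):
        ds, _ = small_sim
        with pytest.raises(OptionError):
            mean_variance_hvg(ds, n_top=ds.n_genes + 1)

    def test_recovers_planted_high_dispersion_genes(self):
        """50 genes at 4x inflated dispersion among 2000 (500 cells): the
        top-50 residuals recover >= 90% of the planted set."""
        ds, truth = simulate_counts(SimulationSpec(seed=1, marker_lfc=0.0))
        out = mean_variance_hvg(ds, n_top=50)
        selected = set(out.loc[out.hvg_flag, "gene_id"])
        assert len(selected & set(truth.hvg_ids)) / len(truth.hvg_ids) >= 0.9


class TestRankMarkers:
    def _exclusive_ds(self):
        # gene gA expressed only in group A
        counts = np.array([[5, 1], [5, 1], [0, 1], [0, 1]])
        return SCDataset(
            counts=counts,
            cell_meta=pd.DataFrame(
                {"cell_id": list("wxyz"), "group": ["A", "A", "B", "B"]}
            ),
            gene_meta=pd.DataFrame({"gene_id": ["gA", "gB"], "mito": [False] * 2}),
        )

    def test_exclusive_gene_ranks_first_with_signed_scores(self):
        mk = rank_markers(self._exclusive_ds(), "group", n_top=2)
        top_a = mk[(mk.group == "A") & (mk["rank"] == 1)].iloc[0]
        assert top_a.gene_id == "gA" and top_a.score > 0
        score_b = mk[(mk.group == "B") & (mk.gene_id == "gA")].iloc[0].score
        assert score_b < 0

    def test_default_n_top_is_ten(self, small_sim):
        ds, _ = small_sim
        mk = rank_markers(ds, "group")
        for _, grp in mk.groupby("group"):
            assert list(grp["rank"]) == list(range(1, 11))
            assert (grp.score.diff().dropna() <= 1e-12).all()  # non-increasing

    def test_single_level_grouping_rejected(self, tiny_ds):
        tiny_ds.cell_meta["mono"] = "only"
        with pytest.raises(OptionError, match="2 levels"):
            rank_markers(tiny_ds, "mono")

    def test_recovers_planted_markers_across_seeds(self):
        """Planted markers (lfc=2): per-group top-5 recovers >= 90% of the
        planted sets over 20 simulation seeds."""
        hit = tot = 0
        for seed in range(1, 21):
            ds, truth = simulate_counts(SimulationSpec(seed=seed))
            mk = rank_markers(ds, "group", n_top=5)
            for group, genes in truth.marker_map.items():
                top = set(mk.loc[mk.group == group, "gene_id"])
                hit += len(top & set(genes))
                tot += len(genes)
        assert hit / tot >= 0.9


def test_lognorm_scales_to_cp10k(tiny_ds):
    Y = lognorm_cp10k(tiny_ds)
    # cell 0: counts [1,0,3] of total 4 -> log1p([2500, 0, 7500])
    assert Y[0, 0] == pytest.approx(math.log1p(2500))
    assert (Y[1] == 0).all()  # all-zero cell stays zero


def test_pca_embedding_is_deterministic(small_sim):
    ds, _ = small_sim
    a, b = pca_embedding(ds), pca_embedding(ds)
    assert a.shape == (ds.n_cells, 2)
    np.testing.assert_array_equal(a, b)
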