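import collections
import random

import pytest

from dashweave import (
    FigureSpec,
    LinkSpec,
    Trace,
    apply_selection,
    compile_wiring,
    create_dashboard,
)
from dashweave.errors import LinkError
from dashweave.linking import resolve_color_variable


def _records(n=10, seed=0):
    rng = random.Random(seed)
    return [
        {"cell_type": rng.choice(["T", "B"]), "pct_mito": rng.uniform(0, 20)}
        for _ in range(n)
    ]


def _grid_page(records=None):
    db = create_dashboard("t").add_page("p", "P", "grid_2x2")
    records = _records() if records is None else records
    scatter = FigureSpec(
        traces=[Trace(kind="scatter", x=list(range(len(records))),
                      y=list(range(len(records))),
                      color_by=[r["cell_type"] for r in records])],
        category_var="cell_type",
        data=records,
    )
    bar = FigureSpec(traces=[Trace(kind="bar", x=["B", "T"], y=[1, 1])],
                     category_var="cell_type", value_var="pct_mito")
    db.add_component("p", scatter).add_component("p", bar)
    return db


class TestLinkValidation:
    def test_valid_link_on_grid_page(self):
        db = _grid_page()
        db.add_link("p", LinkSpec(source="p-c1", target="p-c2",
                                  aggregate="count", variable="cell_type"))
        assert len(db.pages["p"].links) == 1

    def test_storyboard_is_not_linkable(self):
        db = create_dashboard("t").add_page("s", "S", "storyboard")
        db.add_component("s", "one").add_component("s", "two")
        with pytest.raises(LinkError, match="not linkable"):
            db.add_link("s", LinkSpec(source="s-c1", target="s-c2",
                                      aggregate="count", variable="x"))

    def test_self_link_rejected(self):
        with pytest.raises(LinkError, match="self-link"):
            LinkSpec(source="c1", target="c1", aggregate="count", variable="x")

    def test_unknown_endpoint_rejected(self):
        db = _grid_page()
        with pytest.raises(LinkError, match="p-c9"):
            db.add_link("p", LinkSpec(source="p-c1", target="p-c9",
                                      aggregate="count", variable="x"))

    def test_subset_recompute_requires_aggregation(self):
        with pytest.raises(LinkError, match="aggregation"):
            LinkSpec(source="a", target="b", aggregate="max", variable="x")

    def test_links_up_to_k_times_k_minus_one(self):
        db = create_dashboard("t").add_page("p", "P", "grid_2x2")
        recs = _records(4)
        for _ in range(3):
            db.add_component(
                "p",
                FigureSpec(traces=[Trace(kind="scatter", x=[1], y=[1])], data=recs),
            )
        ids = db.pages["p"].component_ids
        n = 0
        for s in ids:
            for t in ids:
                if s != t:
                    db.add_link("p", LinkSpec(source=s, target=t,
                                              aggregate="count", variable="cell_type"))
                    n += 1
        assert n == 6 and len(compile_wiring(db.pages["p"])) == 6


class TestWiringCompilation:
    def test_one_entry_per_link(self):
        db = _grid_page()
        db.add_link("p", LinkSpec(source="p-c1", target="p-c2",
                                  aggregate="count", variable="cell_type"))
        db.add_link("p", LinkSpec(source="p-c1", target="p-c2",
                                  aggregate="mean", variable="pct_mito", by="cell_type"))
        wiring = compile_wiring(db.pages["p"])
        assert len(wiring) == 2
        assert {w.source for w in wiring} == {"p-c1"}
        assert wiring[0].aggregation == {"fun": "count", "variable": "cell_type", "by": "cell_type"}

    def test_source_without_payload_is_compile_error(self):
        db = create_dashboard("t").add_page("p", "P", "grid_2x2")
        db.add_component("p", FigureSpec(traces=[Trace(kind="scatter", x=[1], y=[1])]))
        db.add_component("p", FigureSpec(traces=[Trace(kind="bar", x=["a"], y=[1])]))
        db.add_link("p", LinkSpec(source="p-c1", target="p-c2",
                                  aggregate="count", variable="g"))
        with pytest.raises(LinkError, match="data payload"):
            compile_wiring(db.pages["p"])


class TestSelectionSemantics:
    def _count_entry(self, records):
        db = _grid_page(records)
        db.add_link("p", LinkSpec(source="p-c1", target="p-c2",
                                  aggregate="count", variable="cell_type"))
        return compile_wiring(db.pages["p"])[0]

    def test_three_of_ten_selected_counts_sum_to_three(self):
        records = _records(10, seed=1)
        entry = self._count_entry(records)
        out = apply_selection(entry, records, [0, 4, 7])
        # brute-force recount of the selected subset
        expect = collections.Counter(records[i]["cell_type"] for i in [0, 4, 7])
        assert sum(out.values()) == 3
        for level in {r["cell_type"] for r in records}:
            assert out[level] == expect.get(level, 0)

    def test_empty_selection_restores_full_view(self):
        records = _records(10, seed=2)
        entry = self._count_entry(records)
        full = collections.Counter(r["cell_type"] for r in records)
        for empty in (None, []):
            out = apply_selection(entry, records, empty)
            assert out == dict(full)

    def test_random_selections_match_brute_force(self):
        records = _records(40, seed=3)
        entry = self._count_entry(records)
        rng = random.Random(11)
        for _ in range(100):
            sel = rng.sample(range(40), rng.randint(1, 40))
            out = apply_selection(entry, records, sel)
            assert sum(out.values()) == len(sel)
            expect = collections.Counter(records[i]["cell_type"] for i in sel)
            assert out == {lv: expect.get(lv, 0)
                           for lv in sorted({r["cell_type"] for r in records})}

    @pytest.mark.parametrize("fun", ["mean", "median", "sum"])
    def test_numeric_aggregations_match_manual(self, fun):
        records = [
            {"cell_type": "T", "pct_mito": 1.0},
            {"cell_type": "T", "pct_mito": 3.0},
            {"cell_type": "B", "pct_mito": 10.0},
        ]
        db = _grid_page(records)
        db.add_link("p", LinkSpec(source="p-c1", target="p-c2", aggregate=fun,
                                  variable="pct_mito", by="cell_type"))
        entry = compile_wiring(db.pages["p"])[0]
        out = apply_selection(entry, records, [0, 1])
        assert out["T"] == {"mean": 2.0, "median": 2.0, "sum": 4.0}[fun]
        import math

        assert math.isnan(out["B"])  # level with no selected records


def test_color_by_selection_resolution():
    records = [{"gene_id": "g7", "score": 1.0}, {"gene_id": "g2", "score": 0.5}]
    db = create_dashboard("t").add_page("p", "P", "grid_2x2")
    db.add_component("p", records)  # table with payload
    db.add_component(
        "p",
        FigureSpec(traces=[Trace(kind="scatter", x=[1], y=[1])],
                   value_var="g7", data=[{"g7": 0.1, "g2": 0.3}]),
    )
    db.add_link("p", LinkSpec(source="p-c1", target="p-c2",
                              channel="color_by_selection", variable="gene_id"))
    entry = compile_wiring(db.pages["p"])[0]
    assert entry.update == "recolor" and entry.encoding == "g7"
    assert resolve_color_variable(entry, records, 1) == "g2"
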