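import logging

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dashweave import (
    CapacityError,
    ConfigurationError,
    assemble,
    create_dashboard,
)
from dashweave.figures import resolve_colors
from dashweave.layouts import capacity


def test_fresh_dashboard_is_empty():
    db = create_dashboard("QC report", "A. Author", "default", False)
    assert db.title == "QC report"
    assert len(db.pages) == 0 and not db.colormaps and not db.navbar_items
    # assembling it yields a front-matter-only document
    doc = assemble(db)
    text = doc.serialize()
    assert text.startswith("---\n") and '"QC report"' in text
    assert "# " not in text  # no page sections


def test_unknown_theme_names_valid_set():
    with pytest.raises(ConfigurationError, match="default.*dark.*light"):
        create_dashboard("x", theme="neon-disco")


def test_add_page_and_layout_validation():
    db = create_dashboard("t")
    db.add_page("overview", "Overview", "focal_left")
    assert list(db.pages) == ["overview"]
    with pytest.raises(ConfigurationError, match="storyboard"):
        db.add_page("p2", "P2", "diagonal")
    with pytest.raises(ConfigurationError, match="slug"):
        db.add_page("bad-id", "Bad", "storyboard")
    db.add_page("UPPER", "Upper", "storyboard")  # lowercased, not rejected
    assert "upper" in db.pages


def test_readd_replaces_page_with_warning(caplog):
    db = create_dashboard("t").add_page("overview", "Overview", "focal_left")
    db.add_component("overview", "text one")
    with caplog.at_level(logging.WARNING, logger="dashweave"):
        db.add_page("overview", "Overview v2", "focal_left")
    assert len(db.pages) == 1
    assert db.pages["overview"].components == []
    assert any("replaced" in r.message for r in caplog.records)


def test_storyboard_is_unbounded():
    db = create_dashboard("t").add_page("p1", "P1", "storyboard")
    for i in range(10):
        db.add_component("p1", f"component {i}")
    assert len(db.pages["p1"].components) == 10


@pytest.mark.parametrize("layout", ["focal_left", "grid_2x2"])
def test_capacity_overflow_names_layout_and_limit(layout):
    db = create_dashboard("t").add_page("p", "P", layout)
    cap = int(capacity(layout))
    for i in range(cap):
        db.add_component("p", f"c {i}")
    with pytest.raises(CapacityError, match=rf"{layout}.*{cap}"):
        db.add_component("p", "one too many")


def test_element_ids_are_ordinal_deterministic():
    db = create_dashboard("t").add_page("p1", "P", "storyboard")
    db.add_component("p1", "first").add_component("p1", "second")
    assert db.pages["p1"].component_ids == ["p1-c1", "p1-c2"]


def test_remove_page_drops_navbar_items(caplog):
    db = create_dashboard("t").add_page("overview", "O", "storyboard")
    db.add_navbar_item("Home", "overview")
    with caplog.at_level(logging.WARNING, logger="dashweave"):
        db.remove_page("overview")
    assert not db.pages and not db.navbar_items
    with caplog.at_level(logging.WARNING, logger="dashweave"):
        db.remove_page("ghost")  # no-op with warning
    assert any("ghost" in r.message for r in caplog.records)


def test_navbar_requires_existing_page_or_url():
    db = create_dashboard("t")
    with pytest.raises(ConfigurationError, match="unknown page"):
        db.add_navbar_item("Broken", "nowhere")
    db.add_navbar_item("Docs", "https://example.org/docs")  # URLs pass


class TestColormaps:
    def test_registration_and_shared_resolution(self):
        db = create_dashboard("t")
        db.add_colormap("Condition", {"A": "#FF0000", "B": "#00ff00"})
        # resolution is a pure lookup: identical on any page of the document
        c1 = resolve_colors(["A", "B"], db.colormaps["Condition"])
        c2 = resolve_colors(["B", "A"], db.colormaps["Condition"])
        assert c1 == c2 == {"A": "#ff0000", "B": "#00ff00"}

    def test_malformed_color_names_offender(self):
        db = create_dashboard("t")
        with pytest.raises(ConfigurationError, match="red-ish"):
            db.add_colormap("bad", {"A": "red-ish"})

    def test_reregistration_requires_removal(self):
        db = create_dashboard("t").add_colormap("Condition", {"A": "#ff0000"})
        with pytest.raises(ConfigurationError, match="remove"):
            db.add_colormap("Condition", {"A": "#0000ff"})
        db.remove_colormap("Condition").add_colormap("Condition", {"A": "#0000ff"})


_ops = st.lists(
    st.one_of(
        st.tuples(st.just("add_page"), st.sampled_from(["p1", "p2", "p3"]),
                  st.sampled_from(["storyboard", "tabset", "focal_left", "grid_2x2"])),
        st.tuples(st.just("remove_page"), st.sampled_from(["p1", "p2", "p3"]), st.none()),
        st.tuples(st.just("add_component"), st.sampled_from(["p1", "p2", "p3"]), st.none()),
    ),
    max_size=30,
)


@settings(max_examples=75, derandomize=True, deadline=None)
@given(_ops)
def test_invariants_hold_under_random_mutation_sequences(ops):
    """Capacity and id-uniqueness invariants survive arbitrary interleavings
    of page add/replace/remove and component additions."""
    db = create_dashboard("t")
    for op, pid, layout in ops:
        if op == "add_page":
            db.add_page(pid, pid.upper(), layout)
        elif op == "remove_page":
            db.remove_page(pid)
        else:
            if pid in db.pages:
                try:
                    db.add_component(pid, f"content for {pid}")
                except CapacityError:
                    pass
    assert len(set(db.pages)) == len(db.pages)
    all_ids = [f.element_id for p in db.pages.values() for f in p.components]
    assert len(all_ids) == len(set(all_ids))
    for p in db.pages.values():
        assert len(p.components) <= capacity(p.layout)
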