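"""Embedded stylesheet and client-side runtime for rendered dashboards.

Everything here is inlined into the single-file HTML output; there are no
external fetches. The runtime is one small data-driven script: it reads the
JSON wiring islands emitted per page and the JSON data islands emitted per
component, wires rectangle-drag selection on scatter SVGs and row selection
on tables, and applies the two update channels (bar recomputation over the
selected subset; color re-encoding of scatter points). Themes switch a
``data-theme`` attribute only.
"""

BASE_CSS = """
:root { --bg:#ffffff; --fg:#1c1e21; --accent:#2563eb; --panel:#f6f7f9; --border:#d7dbe0; }
[data-theme="dark"] { --bg:#15181d; --fg:#e6e8eb; --accent:#60a5fa; --panel:#1f242b; --border:#353c45; }
[data-theme="light"] { --bg:#fcfcfd; --fg:#24292f; --accent:#0969da; --panel:#f0f2f5; --border:#d0d7de; }
* { box-sizing:border-box; }
body { margin:0; font-family:system-ui,sans-serif; background:var(--bg); color:var(--fg); }
nav.dw-nav { display:flex; align-items:center; gap:0.25rem; padding:0.4rem 1rem; background:var(--panel); border-bottom:1px solid var(--border); flex-wrap:wrap; }
nav.dw-nav .dw-brand { font-weight:700; margin-right:1rem; }
nav.dw-nav a { color:var(--fg); text-decoration:none; padding:0.3rem 0.6rem; border-radius:5px; cursor:pointer; }
nav.dw-nav a.active, nav.dw-nav a:hover { background:var(--accent); color:#fff; }
nav.dw-nav details { position:relative; }
nav.dw-nav details summary { cursor:pointer; padding:0.3rem 0.6rem; border-radius:5px; list-style:none; }
nav.dw-nav details[open] summary { background:var(--accent); color:#fff; }
nav.dw-nav details .dw-menu { position:absolute; background:var(--panel); border:1px solid var(--border); border-radius:6px; padding:0.25rem; z-index:20; min-width:10rem; }
.dw-author { margin-left:auto; font-size:0.85rem; opacity:0.75; }
main { padding:0.75rem 1rem; }
section.dw-page { display:none; }
section.dw-page.active { display:block; }
.dw-page-body { display:flex; gap:0.75rem; align-items:flex-start; }
.dw-sidebar { flex:0 0 230px; background:var(--panel); border:1px solid var(--border); border-radius:8px; padding:0.6rem; font-size:0.9rem; }
.dw-slots { flex:1 1 auto; min-width:0; }
.dw-layout-focal_left { display:flex; gap:0.75rem; }
.dw-layout-focal_left .dw-col-focal { flex:2 1 0; }
.dw-layout-focal_left .dw-col-side { flex:1 1 0; display:flex; flex-direction:column; gap:0.75rem; }
.dw-layout-grid_2x2 { display:grid; grid-template-columns:1fr 1fr; gap:0.75rem; }
.dw-layout-storyboard { display:flex; flex-direction:column; gap:1rem; }
.dw-tabbar { display:flex; gap:0.25rem; border-bottom:2px solid var(--border); margin-bottom:0.6rem; flex-wrap:wrap; }
.dw-tabbar button { border:none; background:none; color:var(--fg); padding:0.35rem 0.7rem; cursor:pointer; border-radius:6px 6px 0 0; }
.dw-tabbar button.active { background:var(--accent); color:#fff; }
.dw-tabpane { display:none; } .dw-tabpane.active { display:block; }
.dw-component { background:var(--panel); border:1px solid var(--border); border-radius:8px; padding:0.6rem 0.8rem; overflow:auto; }
.dw-component h3 { margin:0 0 0.4rem; font-size:0.95rem; }
.dw-component table { border-collapse:collapse; font-size:0.85rem; }
.dw-component th, .dw-component td { border:1px solid var(--border); padding:0.2rem 0.5rem; }
.dw-component tr.dw-selected { outline:2px solid var(--accent); }
.dw-component tbody tr { cursor:default; }
.dw-linktable tbody tr { cursor:pointer; }
.dw-download { font-size:0.8rem; }
svg.dw-fig { background:transparent; }
svg.dw-fig .dw-plotbg { fill:var(--bg); stroke:var(--border); }
svg.dw-fig .dw-tick { stroke:var(--fg); stroke-width:1; }
svg.dw-fig .dw-ticklab, svg.dw-fig .dw-barlab { font:10px system-ui,sans-serif; fill:var(--fg); }
svg.dw-fig .dw-axlab, svg.dw-fig .dw-title { font:12px system-ui,sans-serif; fill:var(--fg); }
svg.dw-fig .dw-median { stroke:var(--fg); stroke-width:1.5; }
svg.dw-fig .dw-whisker { stroke:var(--fg); stroke-width:1; }
.dw-brushrect { fill:rgba(37,99,235,0.15); stroke:var(--accent); stroke-dasharray:4 3; }
footer.dw-footer { padding:0.5rem 1rem; font-size:0.8rem; opacity:0.7; border-top:1px solid var(--border); }
"""

RUNTIME_JS = r"""
(function () {
  "use strict";
  function qsa(sel, el) { return Array.prototype.slice.call((el || document).querySelectorAll(sel)); }
  function island(id) {
    var el = document.getElementById(id);
    return el ? JSON.parse(el.textContent) : null;
  }

  /* ---- navigation: one visible page at a time ---- */
  var pages = qsa("section.dw-page");
  function showPage(pid) {
    pages.forEach(function (p) { p.classList.toggle("active", p.id === "page-" + pid); });
    qsa("nav.dw-nav a[data-page]").forEach(function (a) {
      a.classList.toggle("active", a.getAttribute("data-page") === pid);
    });
    qsa("nav.dw-nav details").forEach(function (d) { d.removeAttribute("open"); });
  }
  qsa("nav.dw-nav a[data-page]").forEach(function (a) {
    a.addEventListener("click", function (ev) { ev.preventDefault(); showPage(a.getAttribute("data-page")); });
  });
  if (pages.length) showPage(pages[0].id.replace(/^page-/, ""));

  /* ---- tabsets ---- */
  qsa(".dw-tabbar").forEach(function (bar) {
    var panes = qsa(".dw-tabpane", bar.parentNode);
    qsa("button", bar).forEach(function (btn, i) {
      btn.addEventListener("click", function () {
        qsa("button", bar).forEach(function (b, j) { b.classList.toggle("active", i === j); });
        panes.forEach(function (p, j) { p.classList.toggle("active", i === j); });
      });
    });
  });

  /* ---- linked views ---- */
  var AGG = {
    count: function (v) { return v.length; },
    sum: function (v) { return v.reduce(function (a, b) { return a + b; }, 0); },
    mean: function (v) { return v.length ? AGG.sum(v) / v.length : NaN; },
    median: function (v) {
      if (!v.length) return NaN;
      var s = v.slice().sort(function (a, b) { return a - b; }), m = s.length >> 1;
      return s.length % 2 ? s[m] : (s[m - 1] + s[m]) / 2;
    }
  };
  function aggregate(records, idx, agg) {
    var subset = (idx && idx.length) ? idx.map(function (i) { return records[i]; }) : records;
    var levels = {};
    records.forEach(function (r) { if (r[agg.by] != null) levels[r[agg.by]] = true; });
    var out = {};
    Object.keys(levels).sort().forEach(function (lv) {
      var vals = subset.filter(function (r) { return String(r[agg.by]) === lv; })
                       .map(function (r) { return r[agg.variable]; });
      out[lv] = agg.fun === "count" ? vals.length
              : AGG[agg.fun](vals.filter(function (v) { return v != null; }).map(Number));
    });
    return out;
  }
  function updateBars(targetId, values) {
    var svg = document.getElementById(targetId + "-svg");
    if (!svg) return;
    var bars = qsa("rect.dw-bar", svg), scale = 0, base = 0;
    bars.forEach(function (b) {
      if (b._v0 === undefined) { b._v0 = +b.nextElementSibling.textContent; b._h0 = +b.getAttribute("height"); b._y0 = +b.getAttribute("y"); }
      base = Math.max(base, b._y0 + b._h0);
    });
    var vmax = Math.max.apply(null, Object.keys(values).map(function (k) { return values[k] || 0; }).concat([1e-9]));
    var hmax = Math.max.apply(null, bars.map(function (b) { return b._h0; }).concat([1]));
    scale = hmax / Math.max(vmax, Math.max.apply(null, bars.map(function (b) { return b._v0; })));
    bars.forEach(function (b) {
      var lv = b.getAttribute("data-level");
      var v = values[lv]; if (v === undefined || isNaN(v)) v = 0;
      var h = v * scale;
      b.setAttribute("height", h.toFixed(2));
      b.setAttribute("y", (base - h).toFixed(2));
      var lab = qsa('[data-level-label="' + lv.replace(/"/g, '\\"') + '"]', svg)[0];
      if (lab) { lab.textContent = +v.toFixed(3); lab.setAttribute("y", (base - h - 3).toFixed(2)); }
    });
  }
  var RAMP = ["#f7fbff", "#c6dbef", "#6baed6", "#2171b5", "#08306b"];
  function rampColor(t) {
    t = Math.min(Math.max(t, 0), 1);
    var pos = t * (RAMP.length - 1), i = Math.min(Math.floor(pos), RAMP.length - 2), f = pos - i;
    function hx(h) { return [parseInt(h.slice(1, 3), 16), parseInt(h.slice(3, 5), 16), parseInt(h.slice(5, 7), 16)]; }
    var a = hx(RAMP[i]), b = hx(RAMP[i + 1]);
    return "rgb(" + a.map(function (c, k) { return Math.round(c + (b[k] - c) * f); }).join(",") + ")";
  }
  function recolor(targetId, variable) {
    var svg = document.getElementById(targetId + "-svg");
    var records = island("data-" + targetId);
    if (!svg || !records) return;
    var pts = qsa("circle.dw-pt", svg);
    if (variable === null) {
      pts.forEach(function (p) { if (p._c0) p.setAttribute("fill", p._c0); });
      return;
    }
    var vals = records.map(function (r) { return Number(r[variable]); });
    var lo = Math.min.apply(null, vals), hi = Math.max.apply(null, vals), span = (hi - lo) || 1;
    pts.forEach(function (p) {
      if (!p._c0) p._c0 = p.getAttribute("fill");
      var v = vals[+p.getAttribute("data-i")];
      if (!isNaN(v)) p.setAttribute("fill", rampColor((v - lo) / span));
    });
    var title = qsa("text.dw-title", svg)[0];
    if (title) { if (!title._t0) title._t0 = title.textContent; title.textContent = title._t0 + " — " + variable; }
  }
  function applyEntries(entries, records, idx) {
    entries.forEach(function (e) {
      if (e.update === "recompute_bars") updateBars(e.target, aggregate(records, idx, e.aggregation));
    });
  }

  qsa("script.dw-wiring").forEach(function (w) {
    var entries = JSON.parse(w.textContent);
    var bySource = {};
    entries.forEach(function (e) { (bySource[e.source] = bySource[e.source] || []).push(e); });
    Object.keys(bySource).forEach(function (src) {
      var records = island("data-" + src);
      if (!records) return;
      var svg = document.getElementById(src + "-svg");
      if (svg && svg.getAttribute("data-kind") === "scatter") {
        brush(svg, records, function (idx) { applyEntries(bySource[src], records, idx); });
      }
      var tbl = document.getElementById(src + "-table");
      if (tbl) {
        tbl.classList.add("dw-linktable");
        qsa("tbody tr", tbl).forEach(function (tr, i) {
          tr.addEventListener("click", function () {
            var was = tr.classList.contains("dw-selected");
            qsa("tbody tr", tbl).forEach(function (t) { t.classList.remove("dw-selected"); });
            bySource[src].forEach(function (e) {
              if (e.update !== "recolor") return;
              if (was) { recolor(e.target, null); return; }
              tr.classList.add("dw-selected");
              recolor(e.target, String(records[i][e.aggregation.variable]));
            });
          });
        });
      }
    });
  });

  /* rectangle-drag selection on a scatter SVG; empty drag clears */
  function brush(svg, records, onSelect) {
    var rect = null, start = null;
    function pt(ev) {
      var p = svg.createSVGPoint(); p.x = ev.clientX; p.y = ev.clientY;
      return p.matrixTransform(svg.getScreenCTM().inverse());
    }
    svg.addEventListener("mousedown", function (ev) {
      start = pt(ev);
      rect = document.createElementNS("http://www.w3.org/2000/svg", "rect");
      rect.setAttribute("class", "dw-brushrect");
      svg.appendChild(rect);
      ev.preventDefault();
    });
    svg.addEventListener("mousemove", function (ev) {
      if (!rect) return;
      var p = pt(ev);
      rect.setAttribute("x", Math.min(p.x, start.x)); rect.setAttribute("y", Math.min(p.y, start.y));
      rect.setAttribute("width", Math.abs(p.x - start.x)); rect.setAttribute("height", Math.abs(p.y - start.y));
    });
    svg.addEventListener("mouseup", function (ev) {
      if (!rect) return;
      var p = pt(ev);
      var x0 = Math.min(p.x, start.x), x1 = Math.max(p.x, start.x);
      var y0 = Math.min(p.y, start.y), y1 = Math.max(p.y, start.y);
      svg.removeChild(rect); rect = null;
      var idx = [];
      if (x1 - x0 > 3 && y1 - y0 > 3) {
        qsa("circle.dw-pt", svg).forEach(function (c) {
          var cx = +c.getAttribute("cx"), cy = +c.getAttribute("cy");
          if (cx >= x0 && cx <= x1 && cy >= y0 && cy <= y1) idx.push(+c.getAttribute("data-i"));
        });
      }
      onSelect(idx); /* empty -> restore full-data view */
    });
  }
})();
"""
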