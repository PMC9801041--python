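# dashweave

Programmatic, iterative construction of multi-page interactive dashboards
from within omics analysis pipelines.

Analysis pipelines produce results incrementally — QC tables early,
embeddings and marker genes late — but report tooling usually wants the
whole layout up front. dashweave inverts this: a pipeline initializes an
empty dashboard object, adds pages and drops content onto them as results
become available, and finally renders everything into one deterministic,
self-contained HTML file that collaborators open in any browser, offline.
It is written for computational analysts and developers in sequencing /
bioinformatics facilities who need to hand interactive data views to
non-computational collaborators without running a server.

## Core model

The central object is the **dashboard document**: global metadata (title,
author, theme), an ordered set of **pages**, document-wide **colormaps** (a
named category → color mapping resolved identically everywhere), navigation
bar items and optional sidebars. Each page uses one of four **layouts**:

| layout       | capacity  | notes                                   |
|--------------|-----------|-----------------------------------------|
| `storyboard` | unlimited | sequential panels with commentary       |
| `tabset`     | unlimited | one tab per component                   |
| `focal_left` | 3         | one highlighted component; *linkable*   |
| `grid_2x2`   | 4         | row-major 2×2 grid; *linkable*          |

Content of heterogeneous kinds goes through one **generic dispatch**:
markdown strings, image paths (embedded base64), tables (DataFrames, record
lists or CSV/TSV paths), declarative figure specifications, and
zero-argument callables whose returned markup is injected verbatim. The
callable pathway is the extension mechanism: a template package builds whole
ready-made pages purely through these public operations.

On linkable layouts, components can be wired into **linked views**: a
rectangle selection of cells in one panel recomputes an aggregation
(count / mean / median / sum per category level) in another, or a table-row
selection re-colors an embedding by the chosen feature. Links compile to a
JSON wiring table consumed by one small embedded script — no server, no
network access, empty selection restores the full-data view.

## Single-cell extension

`dashweave.sc` provides the computations and page templates for a typical
scRNA-seq workflow, on a neutral dataset container (counts cells × genes +
cell/gene metadata + named 2D embeddings, read from MTX or TSV):

- **QC metrics** per cell: total counts, detected genes, % mitochondrial
  counts; violin plots optionally stratified by a categorical covariate.
- **Feature selection**: per-gene mean and variance of log1p CP10K
  expression; a rolling-median trend of log-variance vs log-mean over
  equal-count bins; the *n* genes with the largest residuals
  (log var − log trend) are flagged highly variable.
- **Marker ranking**: score(g, group) = mean log1p CP10K expression in the
  group − mean in all other cells; top-*n* per group (default 10).
- Linked embedding pages, a marker heatmap, a downloadable multi-panel
  feature grid, and an embedding-comparison tabset.

A bundled simulator generates negative-binomial counts with planted cell
groups, marker genes, high-dispersion genes and a mitochondrial subset, so
the whole stack is exercised end to end with known ground truth and no
external data.

## Worked example

```python
import dashweave as dw

db = dw.create_dashboard("QC report", author="A. Author")
db.add_page("overview", "Overview", "focal_left")
db.add_component("overview", "## Run summary\nAll 12 samples passed QC.")
db.add_component("overview",
                 [{"sample": "S1", "reads": 1.2e6}, {"sample": "S2", "reads": 0.9e6}],
                 title="Read counts")
doc = dw.assemble(db)
print(dw.render_html(doc, "mini.html"))
```

prints

```
{'bytes_written': 12895, 'page_count': 1, 'asset_count': 0}
```

— one page was rendered into a 12,895-byte self-contained HTML file with no
embedded binary assets (the text and table are inline). The full synthetic
single-cell demo comes from the command line:

```bash
dashweave sc-demo --seed 1 -o demo.html --keep-intermediate
# wrote demo.html: 8 page(s), 2 asset(s), 1342494 bytes
```

i.e. eight pages (overview, QC, feature selection, two linked embedding
pages, marker heatmap, feature grid, embedding comparison) and two embedded
downloadable assets (the feature-grid SVG and its CSV of plotted values) in
a ~1.3 MB single file; `--keep-intermediate` also writes the deterministic
markdown-dialect intermediate document. `dashweave build config.yaml` and
`dashweave sc-report --counts matrix.mtx ...` cover config-driven and
file-driven builds.

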