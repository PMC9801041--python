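# Methods

This note documents the models, conventions and numerical choices behind
dashweave, and what the synthetic fixtures do and do not demonstrate.

## Document model and determinism

A dashboard is a plain value: metadata, ordered pages, colormaps,
navigation items, sidebars. Every mutation is an explicit operation that
logs at info level; replacing an existing page id or removing a missing one
warns instead of raising, because in an iterative pipeline later stages
legitimately refine earlier pages. Capacity overflow, by contrast, is a
hard error — a layout silently dropping a component would corrupt a report
without anyone noticing.

Determinism is a design constraint, not an afterthought: component element
ids are ordinal (`<page>-c<k>`), front-matter keys and JSON islands are
emitted in fixed order with fixed float precision, line endings are
normalized, and no timestamp is emitted unless explicitly requested
(`build_info=True`). Consequently `assemble()` and `render_html()` are pure
functions of the dashboard value, and two builds of the same pipeline are
byte-identical — which makes report diffs meaningful and caching trivial.

## Layout geometry

Capacities are: storyboard and tabset unlimited, focal-left 3, 2×2 grid 4.
The focal component takes 2/3 of the page width with the remaining
components stacked equally in the right column, and the grid fills
row-major; both are fixed conventions recorded as constants in
`layouts.py`, so an alternate geometry is a one-line change. The sidebar is
not a slot-bearing layout: it is content attached to a page (local) or the
document (global) and occupies a fixed-width left rail at render time.

## Content dispatch

Dispatch converts heterogeneous content to a uniform fragment. Python has
no S4-style multiple dispatch, so the type rules are explicit: `str` is
markdown unless it names an existing file with a recognized extension;
`pathlib.Path` is always a file (missing → I/O error); DataFrames and
record lists are tables (body capped at 20 rows, full records kept in the
data payload); `FigureSpec` is the single declarative figure form;
callables are invoked exactly once, eagerly, at add-time — so a pipeline
failure surfaces at the line that caused it, with the pipeline's stack.

Figures are rendered server-side to inline SVG by a deterministic renderer
(trace kinds: scatter, bar, box, violin, heatmap; categorical colors from
document colormaps with a fixed fallback palette, numeric encodings on a
fixed sequential ramp; violin shapes from a Gaussian KDE, degrading to a
box when a group has fewer than 3 observations or no spread). Rendering
uses two-decimal coordinate formatting, so output is stable across
platforms.

## Linked views

Links are one-way, intra-page, and restricted to linkable layouts.
Only the `selection` event exists; hover/zoom are documented extension
points. Each link compiles to one row of a wiring table (source, event,
target, update function, aggregation descriptor) embedded as a JSON island;
one small embedded script interprets the table at view time. The same
semantics are implemented server-side in `apply_selection` /
`resolve_color_variable`, which is what the tests verify against
brute-force recomputation — the client script is a consumer of the same
compiled table, not a second specification.

Aggregation semantics: levels are those observed in the full data, sorted;
a level absent from the selection reports count 0 (mean/median: NaN,
rendered as an empty bar); an empty selection restores the full-data view.
The aggregation function is an explicit link field — a "% mitochondrial per
cell type" panel could defensibly update with either mean or median, so
the choice is never hidden in a default.

Known limitation: for a `color_by_selection` link whose target is a violin
panel, the embedded script updates the panel title to the selected feature
but does not re-draw the KDE shapes client-side; the embedding target is
fully re-colored. The server-side semantics (which feature is selected) are
identical for both targets.

## Single-cell computations

Normalization is one documented choice used everywhere: counts per 10,000
per cell, then log1p ("CP10K/log1p"). All-zero cells stay zero and are
flagged in QC rather than dropped — dropping cells is an analysis decision
that belongs to the pipeline, not the report layer.

HVG selection: per-gene mean and variance (ddof = 1) of normalized
expression; the trend is a rolling median of log-variance in 20
equal-count bins of log-mean, linearly interpolated between bin medians
with constant extrapolation. The residual is log-variance minus the fitted
log-trend; the top *n* residuals are flagged, ties broken by gene id so
selection is total-ordered. A median-based trend was chosen over a
parametric fit because it is robust to the very genes being selected; the
fit is isolated in `rolling_median_trend` so a different variance model can
be substituted in one place. Genes with zero mean or zero variance have no
defined residual and are flagged only after all informative genes.

Marker ranking scores each gene per group as mean normalized expression in
the group minus the mean over all other cells — a deliberately simple,
monotone score; it is not a differential-expression test and reports no
p-values. Default `n_top` is 10.

Embeddings are consumed, not computed: pages take named precomputed 2D
coordinate sets; when a dataset carries none, a deterministic fallback is
used — the top-2 principal directions of the normalized matrix, with each
direction's sign fixed so its largest-magnitude loading is positive.

## Synthetic data: what it shows and what it does not

The generator draws negative-binomial counts parameterized by (mean,
dispersion), variance = μ + αμ², via the gamma–Poisson mixture. Gene base
means are log-uniform over (0.1, 20) counts/cell — spanning the sparse bulk
of a UMI matrix up to well-expressed genes at a realistic library size of a
few thousand counts. Defaults: 500 cells × 2000 genes, 3 groups, 5 markers
per group at log2 fold change 2, 50 planted genes at 4× dispersion,
baseline dispersion 0.5, 5% mitochondrial genes, 2 batches; the seed is
mandatory and threaded through every draw.

Two fixture-design rules matter for interpreting the recovery tests:

1. **Planted structure sits on expressed genes.** Marker and
   high-dispersion genes draw their base means from the upper half (log
   scale) of the mean range. A dispersion change at a mean of ~0.1
   counts/cell is statistically invisible after log1p compression (it can
   even *lower* log-scale variance), so truth planted there would be
   unrecoverable by any mean–variance method at any realistic depth — and a
   ground-truth fixture exists to be recoverable in principle.
2. **Each recovery property is evaluated on a dataset planting only the
   structure under test.** Markers at lfc = 2 are genuinely highly variable
   and would legitimately occupy top HVG ranks, so the HVG-recovery check
   simulates with `marker_lfc = 0`; the marker-recovery check uses the
   stated lfc = 2. This keeps the two planted effects from confounding each
   other's oracle.

The simulator deliberately omits library-size confounding, doublets,
ambient RNA and zero-inflation. Passing recovery tests therefore shows the
selection and ranking machinery is correct under the stated model — not
that these simple statistics are competitive with model-based methods on
real data.

## Problem sizes

The test suite and the acceptance script use the default simulation size
(500 × 2000) for recovery checks — 20 independent simulations for marker
recovery — and a 90 × 150 dataset for page-structure tests; the full demo
dashboard builds in a couple of seconds and the whole suite in well under a
minute on one CPU. These sizes were chosen because the measured properties
(recovery rates, determinism, wiring semantics) are size-stable well below
real-data scale.

## Served mode

`interactive: true` renders the same static HTML plus a stub note, and
`dashweave serve` exits non-zero with an explanation. A reactive
server-backed mode duplicates what the static linked views already provide
client-side for the supported channels; the stub records the interface
without promising semantics that are not implemented.
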