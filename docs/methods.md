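# Methods

## Gating model

A gate is an ordered list of at least three finite vertices, implicitly
closed. Membership uses the even-odd (crossing-number) rule: a point is
inside iff a ray from it crosses the polygon boundary an odd number of
times. This rule is well defined for self-intersecting polygons, which
hand-drawn gates can easily be, and matches the default path-filling
convention of standard plotting libraries. No convexity or simplicity is
required; zero-area polygons are accepted with a warning and match only
boundary points.

Edge behaviour is a genuine design choice: the crossing-number rule alone
leaves points exactly on an edge ambiguous. Gates here are closed sets —
points within 1e-9 (Euclidean distance to the nearest edge segment) count as
inside — matching flow-cytometry convention where a gate boundary belongs to
the gate. The implementation computes the crossing parity with a half-open
vertical rule (`y1 > y != y2 > y`), which handles rays through vertices
consistently for off-boundary points, and then ORs in the explicit boundary
test.

Cells inside several gates receive the comma-joined names of all containing
gates, in drawing order (not alphabetical — drawing order is what the analyst
saw). Cells inside none receive the `outside_label`, `"rest"` by default;
this label is this package's convention, configurable per call. Default gate
names are `"0"`, `"1"`, ... in drawing order and can be renamed afterwards;
composite labels rename as whole strings.

## Axes contexts

Every polygon set is bound to the axes it was drawn in: either a named 2-D
embedding (UMAP, t-SNE, PCA — always inputs, never computed here) or a
feature-vs-feature scatter with a layer (`raw`/`normalized`) and per-axis
scale (`linear`/`log10`). Applying a session to a dataset that lacks the
referenced embedding, or to the wrong axes kind, is an error rather than a
guess — in particular a session drawn on one embedding cannot silently apply
to a recomputed embedding whose coordinates mean something else.

On log10 axes, polygons are interpreted in display space: gate vertices are
log10-transformed values. Zero counts, common in antibody-capture data,
would vanish from a log axis; they are placed at `log10(0.5)` (half a count,
configurable via `zero_pseudo`) so they remain visible and gateable below
every positive count. Negative values under a log axis raise a domain error.

## Region statistics

All abundance statistics use raw UMI counts, never the normalized layer,
under the assumption that one UMI is one detected transcript:

- `pct_cells`: 100 · n_label / n_total per distinct label; sums to 100.
- `pct_expressing`: percentage of a label's cells with raw count ≥ threshold
  (default 1 — "expressing" means at least one detected transcript; the
  threshold is exposed because antibody-capture backgrounds may warrant more).
- `tpm`: the gene's share of all UMIs in the region, × 10^6. Per region,
  TPM summed over all genes is exactly 10^6; a region with zero total UMIs
  yields NaN with a warning.
- `enrichment`: TPM inside the region over TPM in its complement (all cells
  not carrying the label). A gene absent outside but present inside gives
  +inf with a warning; absent everywhere gives NaN. `combined_enrichment`
  pools several labels into one region first.

Composite comma labels are atomic strings for all statistics; the
`label_contains` helper builds polygon-level masks ("every cell whose label
includes CCR7") when pooling across composites is wanted. Both variants are
exposed because region tables are sometimes needed per exact label and
sometimes per polygon. Percentages are never rounded internally; formatting
happens at print/CSV level.

## Gaussian mixture grouping

`fit_gmm` fits a K-component full-covariance Gaussian mixture in the 2-D
space of two marker genes, by default on the normalized layer (grouping is a
pattern-finding step, where library-size effects are nuisance), raw counts
via flag. Initialization is a k-means partition (k-means++ seeding, Lloyd
iterations to an assignment fixpoint or 300 iterations; emptied clusters
re-seed at the farthest point) converted to one-hot responsibilities. EM
then alternates closed-form M-steps with log-sum-exp E-steps; covariance
diagonals get a 1e-6 regularization floor; convergence is a relative change
in mean log-likelihood below 1e-6 or 200 iterations. These defaults mirror
the common choices of widespread mixture implementations. Components are
reordered by descending weight after fitting so repeated runs are
comparable; hard assignments (argmax responsibility) are written as string
labels usable by the region statistics exactly like gate labels.

EM guarantees a non-decreasing log-likelihood trace (asserted in tests to
1e-8 tolerance). On data without real structure — two components with
identical parameters — the maximum-likelihood fit does not collapse to
coincident means: it settles on a spurious split whose mean separation is on
the order of one component standard deviation (we measure ~0.7–1.5σ across
seeds, and an independent reference implementation started from the same
initialization behaves identically). What distinguishes real from spurious
structure is scale and confidence: genuinely distinct populations separated
by many σ are recovered with near-binary responsibilities, while the
spurious split stays near 1σ with responsibilities close to uniform. The
tests encode exactly this contrast.

## Synthetic data

The simulator emulates the statistical shape of droplet scRNA-seq with
optional antibody-capture features; its defaults are one fixed set of study
conditions, not tuning knobs:

- cluster of each cell ~ Categorical(weights), default 3 equal clusters;
- embedding coordinate ~ Normal(cluster center, sd·I); default centers on a
  circle of radius 10 with sd 1, i.e. well-separated blobs as a clean UMAP
  would show;
- counts ~ NegativeBinomial(mean, dispersion) — overdispersed relative to
  Poisson as UMI data are — with baseline mean 2 and dispersion 2, the mean
  multiplied by a fold factor f > 1 for marker genes in their clusters;
- independent dropout zeroes each entry with probability 0.1 by default;
- antibody-capture features are log-normal with cluster-specific log10
  location, spanning orders of magnitude, the regime where log-axis gating
  matters.

`reference_polygon` returns a regular 16-gon circumscribing the circle of
radius sd·√(χ²₀.₉₅(2)) around a cluster center, so its expected coverage of
that cluster's cells is known analytically (slightly above the quantile q).
`straddling_marker_dataset` builds the adversarial-for-clustering scenario:
two blobs at (±2, 0) with sd 1.2, and a marker elevated 40-fold inside the
disc of radius 1.5 around the origin — a high-expression zone that spans
both clusters, so block-cluster membership dilutes the marker signal while a
tight gate around the zone does not.

What the simulator does not emulate: batch effects, doublets, ambient RNA,
gene–gene correlation beyond cluster structure, and the mean–variance and
zero-inflation profiles of any particular chemistry. Passing tests therefore
demonstrate the correctness of the geometry, statistics and fitting
machinery under the stated generative model, not the biological validity of
any specific gating strategy on real data.

## Numerical and I/O choices

- Counts are integer CSR sparse internally; all I/O contracts are
  value-level. Matrix Market input requires an explicit orientation flag
  (cells-by-genes vs genes-by-cells) because both conventions circulate;
  nothing is guessed from shapes.
- The normalized layer, when absent and requested, is per-cell scaling to
  the median total count followed by log1p — the dominant convention — and
  is deliberately replaceable by supplying any non-negative matrix.
- CSV writers use `%.17g` floats and readers parse with round-trip
  precision, so embedding coordinates and annotations survive a disk round
  trip bit-exactly; session JSON stores vertices as decimal literals and
  reproduces them exactly.
- Cell order is the canonical index; annotations and embeddings align
  positionally and `cell_id` is used only for file joins, which fail loudly
  on unknown ids.

## Problem sizes in tests

The test suite and the acceptance script run entirely on simulated data at
sizes chosen to give the checks statistical teeth while staying quick:
10,000 polygon/point pairs for the geometry oracle, 100 random regions for
TPM conservation, n = 5000 for composite-label removal, 100 replicates of
n = 1500 for the gate-versus-cluster comparison, n = 2000 for mixture
recovery and 50 small datasets for EM monotonicity.

## Known limitations

- Interactive mouse capture is out of scope by design; gates enter
  programmatically (this is what makes the package testable headlessly).
- Embeddings are inputs; the `filter` step emits a reduced raw matrix for
  external re-embedding rather than recomputing coordinates.
- No spatial indexing: membership is O(n·k·vertices), ample for the gate
  counts and cell numbers this workflow sees.
- The mixture model is limited to two feature axes and a user-chosen K; no
  model selection is performed.
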