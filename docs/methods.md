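# Methods

## Connectivity model

Functional connectivity between two regions is the Pearson correlation
of their BOLD time courses ("full correlation"). Per subject the
package computes the ROI × ROI correlation matrix in atlas row order,
zeroes the diagonal, and clips negative coefficients to zero: the
neural interpretation of resting anti-correlations is contested and
they are typically near zero, so only nonnegative couplings are carried
forward. A constant (zero-variance) time course has no defined
correlation and raises an error naming the offending ROI.

Group matrices are the entrywise mean of the Fisher transform
z = arctanh(r), back-transformed with tanh. Averaging in z-space
stabilizes the variance of r across its range; cells that are zero in
every subject stay exactly zero. Correlations at or above 1 − 1e−12 are
clipped to 1 − 1e−12 before arctanh so duplicated series produce a
large finite z instead of infinity — the clip is silent by design,
since group aggregation routinely encounters exact 1.0 entries.

Thresholds are defined and applied on the r scale. An absolute cutoff
is used (default r > 0.5, with a sensitivity sweep over 0.40–0.50 in
steps of 0.01), never a proportional (fixed-cost) one: when one group
is globally hypo-connected, proportional thresholding back-fills weak,
likely spurious edges to keep the cost constant, and false positives
distort binary metrics more than false negatives. The inequality is
strict — an entry exactly at the cutoff is removed — which makes edge
sets nest monotonically across the sweep. The default thresholds the
group matrix; a per-subject option (`threshold_level: subject`)
thresholds before averaging, for users who want it, without any claim
the two orders are equivalent.

Connection counts are reported as nonzero off-diagonal cells of the
binary adjacency, i.e. ordered (directed) pairs, 2 × the undirected
edge count — the convention behind counts like "130 connections" over
12 nodes.

## Graph metric panel

On the binary undirected graph: node degree (row sums); clustering
coefficient C_i = 2·t_i / (k_i(k_i−1)) with C_i = 0 for k_i < 2; local
efficiency of node i as the global efficiency of the subgraph induced
by its neighbours; global efficiency as the mean of 1/d(i,j) over
ordered distinct pairs with 1/∞ = 0; characteristic path length (CPL)
as the mean shortest-path distance over *reachable* ordered pairs, with
the number of unreachable pairs reported alongside. High-threshold
brain graphs are routinely disconnected, so infinite distances must not
enter the CPL average; an edgeless graph has no defined CPL and is
flagged rather than given a sentinel value.

Nodal summaries report mean and sample (n−1) standard deviation. By
default isolated (degree-0) nodes are excluded before averaging
(`include_isolated=False`): group tables of sparse networks are only
arithmetically consistent with that convention, and for dense scopes
the two conventions coincide. Both the flag and the number of nodes
used are recorded in every output row so either convention can be
checked.

Distances come from scipy's csgraph BFS; the test suite verifies all
five metrics exactly against a pure-Python BFS/triangle-counting oracle
on 200 random graphs of up to 15 nodes, and cross-checks clustering and
global efficiency against networkx.

## Triangle-area segregation

Every unordered node triple within a scope defines a 3-cycle whose
sides are the three pairwise correlations; its Heron area summarizes
the intensity of mutual coupling. Enumeration covers *all* triples in
scope — admission is purely by area, not by graph-threshold edges; the
edge-restricted variant is available via `min_side` but makes no
fidelity claim. Triples with any zero side are skipped, and sides made
of correlations can violate the triangle inequality, in which case the
radicand is nonpositive and the triple is geometrically invalid; such
triples are excluded and counted in a diagnostics field rather than
erroring.

The admission threshold is the area of the hypothetical equilateral
triangle with side r = 0.6: A* = √(0.9·0.3³) ≈ 0.155885 (0.1559 at
4 dp). Admission uses ≥ with a 1e−12 slack so boundary triangles (all
sides exactly 0.6) are admitted — populated minimum-area columns equal
the rounded threshold itself, implying the boundary belongs in. Sides
are raw r, not Fisher z, because the side criterion is phrased in r.

Estimator rows report N, mean, median, skewness, sample SD, min, max of
the admitted areas. Skewness is moment-based Fisher–Pearson
g1 = m3/m2^1.5 (the bias-adjusted variant is an option); it is set to 0
for N ≤ 2, and for N = 0 only N is reported.

## Group statistics

Nodal metrics (degree, clustering, local efficiency) are compared
between the two *group* graphs with one observation per node — a
descriptive, not subject-level, convention. The two-sided rank-sum test
uses the tie-corrected normal approximation without continuity
correction; fully tied samples return (Z = 0, p = 1). BH-FDR is applied
within each metric × scope family (family size = number of metrics
compared in that scope) and adjusted p is never below raw p. Admitted
triangle counts are compared with the χ² goodness-of-fit test against
equal expected counts (df = k − 1); triangle area distributions with
the rank-sum test.

The normal approximation is checked against exhaustive permutation
enumeration at n = m = 4: agreement is within 0.02 in the rejection
region and order-consistent overall — at such sample sizes the exact
distribution is discrete and mid-range p-values can differ from the
approximation by up to ~0.1, a property of the approximation itself.

## Synthetic cohorts

The generator emulates the target study design: two groups (default
10 controls, 10 patients) of ROI × time matrices with T = 160
timepoints, the length of a standard six-and-a-half-minute resting
acquisition at TR = 2.5 s. Each group has a population correlation
matrix with unit diagonal, compound-symmetric blocks at a target r
within each resting-state network, and a background level elsewhere;
the patient visual-network block is multiplied by an attenuation
factor. Defaults: within-network r = 0.65 (comfortably above the 0.5
edge threshold and the 0.6 triangle side at T = 160 sampling noise),
background r = 0.2 (clearly sub-threshold), attenuation 0.5 (halved
patient visual coupling, far below threshold), noise_sd = 0 and AR
coefficient 0. The covariance is repaired by eigenvalue flooring and
diagonal rescaling if targets ever make it indefinite.

Subjects are i.i.d. multivariate-normal draws across time. Real BOLD is
band-limited, so an optional AR(1) coefficient imposes temporal
smoothness with unchanged marginal covariance (innovations scaled by
√(1−φ²)); with added white noise (noise_sd > 0) marginal correlations
shrink by 1/(1+noise_sd²), which is why the default keeps it at 0 so
the stated targets are exactly the marginal correlations. What the
generator does *not* emulate: hemodynamics, physiological/motion
artefacts, lesion geometry, spatial autocorrelation, or
between-subject heterogeneity of the correlation structure — passing
recovery tests therefore show the pipeline detects the modelled
group contrast, not that it is robust to real-data confounds.

Parameter recovery holds at the defaults: across 100 seeded replicates
of the full pipeline the control group shows more visual-network
connections, higher degree and clustering means, and more admitted
triangles than the attenuated patient group in at least 95 replicates
(in practice all 100), while with attenuation 1.0 the sign of the group
difference in mean visual-network correlation behaves like a fair coin.

## Pipeline and reporting

`run_pipeline` analyses every named network plus the union of networks
("RSNs") and the whole brain, per group: group matrix, connection
counts, density sweep (density = undirected edges / C(n, 2)), metric
table, triangle estimator table, and between-group comparisons. A scope
with no above-threshold edges yields a row flagged not computable; a
scope with fewer than 3 nodes is skipped with a warning. Every CSV
carries a provenance header (version, config hash excluding the output
directory, seed) and every convention flag and excluded-triple count is
logged, since several reporting conventions here are reconstructions;
re-running with the same config and inputs is byte-identical. BrainNet
Viewer exports write whitespace-separated `.node` (x y z color size
label) and `.edge` (N × N matrix) text files; the `.edge` round-trip
reproduces the matrix exactly.

## Numerical choices and limitations

- 0-based indices internally, 1-based atlas ids in files.
- Degenerate inputs: constant time series error; edgeless graphs flag
  CPL undefined; empty triangle sets report only N; all-tied rank-sum
  and all-zero χ² return their null values rather than erroring.
- The attentional-network membership follows the AAL-mappable region
  list (9 bilateral pairs, 18 nodes); "frontal eye fields" has no AAL
  label and is not included, so no claim is made that this AN matches
  any particular published node set beyond the listed regions.
- Analyses are descriptive at the group-matrix level; no subject-level
  inference, no network-based statistics, no weighted-graph metric
  variants, no community detection.
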