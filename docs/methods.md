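# Methods

## The model

A skull (or any articulated skeleton) is represented as a simple graph:
nodes are skeletal elements, links are physical contacts. The graph is
binary, undirected and unweighted — suture breadth, joint mobility and
bone geometry are deliberately outside the model. Cartilaginous elements
are simply absent from inputs. Isolated nodes are legal and meaningful
(e.g. ear ossicles that articulate with no other skull bone), so
disconnected graphs flow through every stage. Paired bones follow the
`L_`/`R_` prefix convention; midline bones carry no prefix.

## Descriptors

* **D = 2K / N(N−1)** — exact by construction.
* **C** — mean of local clustering coefficients over nodes with degree
  ≥ 2. Nodes with fewer than two neighbors have no neighbor pair to
  close; they are *excluded* from the average rather than counted as 0.
  This is the local-transitivity default of igraph/R, the toolchain this
  style of analysis is normally run in; counting them as zero would
  systematically deflate C for skulls with many pendant bones.
* **L** — mean shortest-path distance over *reachable* unordered pairs.
  Unreachable pairs are excluded, not treated as infinite or penalized:
  a skull with detached ossicles must still have a finite, comparable
  path length.
* **H** — sample (n−1 denominator) standard deviation of the degree
  sequence divided by its mean, again matching the default `sd()` of the
  statistical environment these analyses are traditionally run in.
  H = 0 exactly when all degrees are equal.

Degenerate inputs raise a typed error (`DegenerateNetworkError`) rather
than returning NaN: density needs N ≥ 2, path length and heterogeneity
need at least one link. A network whose nodes all have degree < 2 gets
C = 0 with a logged note.

## Topological overlap and clustering

`TO_ij = J(i,j) / min(k_i, k_j)` with `J` the pure common-neighbor count
(excluding i and j themselves, and *not* adding the direct i–j
adjacency). Pairs involving a degree-0 node get TO = 0; the diagonal is
defined as 1. Two variants exist for sensitivity analysis, both off by
default: `adjacency_correction=True` switches to the weighted-style
`(J + a_ij)/(min(k)+1−a_ij)` form, and `m > 1` expands neighborhoods to
all nodes within m links (generalized overlap). The defaults implement
the one-step, uncorrected formula because that is the form actually
printed for this analysis; the variants quantify how much the open
formula choices matter.

Clustering is plain agglomerative hierarchical clustering of `1 − TO`.
The linkage is selectable (average / single / complete); average
(UPGMA) is the default since no linkage is canonical for this analysis
and UPGMA is the common default of the clustering tools in this field.
The implementation is a direct O(N³) loop that recomputes cluster–
cluster dissimilarities from the original matrix at every step — trivial
at anatomical sizes (N ≤ ~60) — because it lets us fix a deterministic
tie-break the standard library routines do not guarantee: among merges
tied at the minimal height, the pair whose sorted label sets are
lexicographically smallest merges first. Dendrograms are therefore pure
functions of the input network. Heights are tied at an absolute
tolerance of 1e-12. On tie-free inputs the merge heights coincide with
`scipy.cluster.hierarchy.linkage` (verified in the tests).

## Q-modules

Modularity `Q = Σ_s [l_s/K − (d_s/2K)²]`. Only the N−1 horizontal cuts
of the dendrogram (plus the one-module root) are candidate partitions —
arbitrary subtree selections are not considered, matching how the
dendrogram cut is drawn and interpreted. Ties in Q (tolerance 1e-12)
resolve toward fewer modules. Isolated nodes stay in whatever cluster
the tree assigns them; with zero degree they cannot change Q.

The **jackknife error** of Q_max treats each link as an independent
observation: for every link, Q is recomputed on the network minus that
link under the *same* partition, and
`SE = sqrt((K−1)/K · Σ_e (Q_e − mean)²)`. The partition is deliberately
not re-estimated per replicate: re-clustering would measure the
stability of the partition-finding procedure, a different (and here
unspecified) quantity, whereas the link-jackknife quantifies sampling
noise of the Q statistic given the identified modules.

## S-modules

Each internal dendrogram node (except the root, which has no external
links) is tested: the vector of members' internal degrees against the
vector of their external degrees, with a two-sample Wilcoxon rank-sum
test, one-sided (`greater`) per the stated alternative; `two-sided` is
available behind a flag. The two vectors are paired by member, but the
test is the unpaired two-sample form, as named; a paired test would be a
different procedure.

p-values are computed exactly whenever feasible:

* tie-free samples of ≤ 25 each — the classical exact rank-sum null;
* tied samples with `C(n1+n2, n1) ≤ 20 000` — full enumeration of group
  assignments on midranks. Degree vectors are small integers, so ties
  are the rule, and the most interesting clusters (fully detached
  modules, whose external degrees are all zero) are *always* tied; the
  enumeration gives them their exact attainable minimum,
  `1/C(n1+n2, n1)` (0.05 at 3-vs-3 — meaning a 3-member module can never
  pass a strict p < 0.05 threshold, an honest floor of the test);
* otherwise — normal approximation with tie and continuity correction
  (the R `wilcox.test` behavior). Fully constant pooled data return
  p = 1.

S-module count = all clusters with p < 0.05, nested ones included, since
no flat counting rule is canonical for nested significant clusters; the
maximal (outermost) non-overlapping significant clusters are reported
separately. Note that with tight nested structure the outermost set can
legitimately contain unions of planted modules: a union of two dense
blocks is itself significantly more connected inside than outside. No
multiple-testing correction is applied — the tests are descriptive
annotations of one dendrogram, not a family of confirmatory hypotheses —
and the run log records how many tests were performed.

## Synthetic generator

The generator emulates the three structural features the analysis
relies on: planted modular blocks (within-block link probability `p_in`,
between-block `p_out`, drawn pair-by-pair in a fixed order from a seeded
`numpy` Generator), optional bilateral mirroring (one half drawn, copied
with `L_`/`R_` prefixes, joined by declared midline pairs so the L/R
swap is an exact graph automorphism), and detached chains. Defaults —
three blocks of 8, `p_in = 0.9`, `p_out = 0.05` — give strongly modular
graphs whose Q_max lands in the 0.3–0.7 band typical of clearly modular
networks, at sizes (24 plain, ~50 mirrored) comparable to real amniote
skull networks (34–63 bones).

What the generator does *not* emulate: developmental and geometric
constraints on which bones can touch (real contact graphs are roughly
planar and serially structured), degree–size correlations, and
left/right asymmetries. Passing the recovery tests therefore
demonstrates correctness of the machinery on graphs with known modular
signal, not detection power on any particular empirical skull.

## Validation design

Every stage is checked against an independent oracle written in a
different style: naive set-intersection TO, hand-rolled BFS path
lengths, triangle-enumeration clustering, `networkx` community
modularity, a literal leave-one-out jackknife, and full-enumeration
rank-sum p-values — across 200 seeded random graphs of up to 30 nodes,
plus closed-form fixtures (the two-triangle bridge with D = 7/15 and
Q = 5/14, path and star graphs, complete-graph jackknife SE = 0).
Planted-module recovery is measured as adjusted Rand ≥ 0.9 over 100
seeded draws. End-to-end runs are byte-identical across repeats. These
sizes keep the whole suite around ten seconds while covering the regime
(N ≤ 63) the method is used in.

## Known limitations

* The dendrogram constraint means Q_max is a maximum over N cuts, not
  over all partitions; a free community-detection algorithm may score
  higher Q on the same network by design.
* Exact rank-sum enumeration is capped at 20 000 assignments; very large
  tied clusters fall back to the normal approximation, whose p-values
  near the significance floor are approximate.
* The binary contact model carries no information about suture size or
  mobility; identical networks can represent mechanically very
  different skulls.
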