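# Methods

`tdafold` analyzes ensembles of Cα trajectories of a small fast-folding
protein by tracking the formation of loops — one-dimensional topological
features — rather than distances or dihedral angles.  This note records the
models, conventions and numerical choices behind each stage, what the
synthetic-data generator does and does not emulate, and the known
limitations.

## Persistent homology of a snapshot

Each snapshot is the point cloud p_1 … p_R of Cα positions (Å).  Balls of
radius r grown around the points induce the alpha filtration: the nested
family of subcomplexes of the Delaunay complex in which a simplex is present
once r reaches its entry radius.  Degree-1 persistent homology assigns every
loop a birth radius b (the loop closes) and a death radius d (the hole
fills); the lifetime d − b measures robustness against perturbation.

Conventions and numerics:

* **Radii, not squared radii.** Filtration values are ball radii in Å.
  Common alpha-complex implementations return squared radii; here the
  square root is taken at the source, so every downstream quantity
  (lifetimes, bag-of-simplices weights, NMF scores) carries Å units.
* **Entry radii.** A simplex whose circumball is empty of other points
  (Gabriel) enters at its circumradius; otherwise it enters with its
  earliest coface.  Values are assigned top-down from the maximal
  simplices, which makes the face-ordering invariant hold by construction.
* **Degenerate inputs.** A deterministic jitter of 1e-9 Å (seeded,
  recorded) is applied before triangulation to break exact cosphericity.
  Point sets of affine rank 2 — the planar polygons used as analytic test
  cases — are projected onto their best-fit plane and triangulated in 2D;
  collinear clouds raise an error, since no loop can exist.
* **Reduction.** Standard Z2 boundary-matrix reduction restricted to
  triangle columns over edge rows, with a pivot lookup table and bitset
  columns.  Zero-lifetime pairs (b = d) are discarded.  The tests verify
  the pairs against an independent, unoptimized full-matrix reduction.
* **Birth-radius guard.** `diagram_for_snapshot(max_birth=…)` optionally
  discards pairs born beyond a cap (the pipeline default is 20 Å).  A
  "loop" whose closing edges exceed tens of Å does not encode molecular
  structure; it is a boundary artifact of a nearly degenerate (for
  example almost straight) conformation, and such artifacts can carry
  lifetimes of hundreds of Å that would otherwise dominate every
  downstream weight.  Genuine Cα contact scales are an order of magnitude
  below the cap.

## Volume-optimal cycles

Birth and death alone cannot distinguish loops of similar size in different
parts of the chain, so each pair is assigned a representative: the boundary
of a minimal set Ω of triangles filling the hole.  Ω must contain the death
triangle, use only triangles present at radius d, and have a Z2 boundary
consisting solely of edges present at radius b.  Triangles already present
at radius b can only touch allowed edges, so the search is restricted to
entry values in (b, d] without loss.

The search is exact on three routes: a provable single-triangle shortcut;
exhaustive ascending-cardinality enumeration when at most 18 candidates
remain; and otherwise 0/1 integer programming (HiGHS through
`scipy.optimize.milp`) with the Z2 parity of each disallowed edge encoded by
an even-valued slack variable.  Before solving, candidates are pruned to the
death triangle's connected component of the forbidden-edge-sharing graph — a
minimal solution never contains a disconnected even-boundary cluster.  Ties
in |Ω| are broken deterministically by the lexicographically smallest tuple
of candidate ranks (candidates ranked by entry value, then vertex tuple),
applied identically on all routes.  When multiple minimal volumes exist the
chosen representative therefore depends on residue labeling; only uniqueness
of |Ω| and of the total weight is label-invariant.

## Bag-of-simplices vectorization

A snapshot's cycles are treated as a bag of edges: the weight of residue
pair (i, j) is the summed lifetime of all volume-optimal cycles whose edge
set contains (i, j).  This yields an R(R−1)/2-dimensional non-negative
vector (595 dimensions at R = 35) per snapshot, zero exactly when the
snapshot has no cycles — unfolded frames thus map near the origin.  Edge
coordinates are ordered lexicographically with 0-based indices in memory
and 1-based residue numbers on disk.  The exact conservation identity
Σ_ij s_ij = Σ_k |C_k| (d_k − b_k) is asserted in the tests at 1e-12.

## Non-negative matrix factorization

The N×M feature matrix V (columns = snapshots) is factored as V ≈ WH with
multiplicative updates minimizing the Frobenius objective from a seeded
random start.  The objective is recorded every iteration and is
non-increasing; iteration stops at a relative change below `tol` (default
1e-6) or `max_iter` (default 2000).  After the fit each basis column is
rescaled to unit Euclidean norm with its H row scaled inversely — WH is
unchanged, the diagonal scale ambiguity is removed, and the scores h_ji
inherit Å units.  The residual permutation ambiguity is irrelevant
downstream because components are identified by correlation, not index.
`sklearn.decomposition.NMF` is used in the tests as an independent
cross-check of the attained objective, never as the implementation.

Two rank-selection procedures are provided, both on a seeded column
subsample (default 10,000, clamped with a warning):

* **RSS inflection.**  RSS(L) = ‖V_sub − WH‖²_F is fitted per rank; the
  selected rank maximizes the drop ratio D(L)/D(L+1) where
  D(L) = RSS(L−1) − RSS(L), i.e. the last steep drop before the plateau.
  If no ratio exceeds 5 the curve is declared effectively linear and no
  rank is selected — a legitimate outcome on unstructured data, reported,
  not raised.  (A sign-change rule on second differences was tried first
  and discarded: near the elbow both neighboring second differences are
  noise-dominated and the rule flips between adjacent ranks.)
* **Cophenetic coefficient (consensus clustering).**  Per rank, `n_runs`
  (default 30) fits from distinct seeds assign each sample to its
  largest-coefficient basis (lowest index on ties); the consensus matrix
  holds co-clustering fractions; the coefficient is the cophenetic
  correlation between 1 − consensus distances and their average-linkage
  dendrogram, defined as exactly 1 when all distances are equal (perfectly
  stable clustering).  Selected rank = argmax, smallest on ties.  The
  number of runs and the linkage are not canonical; 30 runs and average
  linkage are the package defaults and are logged.

## Flow fields and path classification

Each trajectory becomes a sequence of L-dimensional score vectors.  The
velocity at frame t is score(t+1) − score(t) (Å per frame interval, 250 ps
by default), attributed to the earlier frame's grid cell, never spanning
trajectory boundaries; this is the simplest estimator consistent with a
per-cell mean velocity and is the package's own choice, as is binning over
the data's min–max range.  Cells with at most `min_count` samples (strict
inequality, default 100) report counts but no velocity.  Because a cell
mean can cancel opposing motions, the velocity distribution within a
rectangular region is exposed separately.

`classify_paths` is a derived statistic, not a field-standard quantity: a
trajectory is labeled by which of two selected components first exceeds a
threshold.  The pipeline selects the two components by optimal one-to-one
matching between components and planted contact sets, maximizing the
correlation between score rows and the summed feature weights of each
set's edges (the same correlation used to interpret bases).  The default
threshold is half the pooled 95th-percentile score of the two components:
well above the near-zero unfolded noise floor, well below the plateau a
formed loop produces.

## Synthetic trajectory generator

The generator emulates the statistical structure the analysis assumes
about a 35-residue three-helix fast folder, with geometry only — no force
field, no excluded volume, no thermodynamics:

* **Native state**: three ideal helices (rise 1.5 Å/residue, radius
  2.3 Å, twist 100°/residue — the canonical 3.8 Å Cα spacing) packed as a
  bundle in which two planted contact sets are satisfied: set 1 bridges
  helices 1↔3 (residue pairs (6,28), (9,32), 0-based), set 2 bridges
  helices 1↔2 ((6,16), (5,17)).  Linkers and tails are interpolated or
  extrapolated; the seed adds a 0.05 Å jitter, with bounded retries if a
  contact breaks.
* **Folding kinematics**: frame 0 is a straight extended chain at 3.8 Å
  spacing; a collapse stage (first 30% of progress) blends it into a
  splayed bundle whose outer helices are hinged open (110°, helix 2
  additionally translated outward since a pure hinge cannot clear the
  contact threshold for so short a helix); each arm then docks over a
  window ending at its contact set's activation fraction.  Plans A and B
  differ only in the order of the two docking windows (fractions 0.55 and
  0.85).  Linkers re-interpolate every frame so the chain stays connected.
  At progress 1 the conformation equals the native input exactly; i.i.d.
  Gaussian noise (default σ = 0.25 Å) is added per frame, keeping the
  final RMSD well below the 1.0 Å folded criterion.
* **Non-folding trajectories**: a persistent-random-walk coil that
  diffuses smoothly, regenerated from derived seeds until every frame is
  ≥ 3 Å RMSD from native.
* **Frozen tails**: appended frames with all residues at one point
  (default (22.5, 22.5, 22.5)), emulating a distributed-computing merge
  artifact.
* **Planted matrices** for factorization benchmarks: `planted_factor_matrix`
  (sparse gamma factors, multiplicative noise) and `planted_block_matrix`
  (five archetypes with exclusive feature bands — separation holds at
  every seed — plus shared background, cross-archetype mixing that makes
  over-ranked clusterings initialization-dependent, and additive noise).

What passing tests show: that the pipeline recovers planted structure —
contact-formation order, factor bases, block counts — under the generator's
idealized kinematics and noise.  What they do not show: performance on real
MD data, whose unfolded ensembles are far more heterogeneous, whose loops
form and break reversibly, and whose noise is not isotropic Gaussian.

## Preprocessing

RMSD uses Cα-only clouds and proper rotations only (Kabsch via SVD with a
reflection correction; residuals are evaluated explicitly rather than
through the singular-value identity, which loses precision to cancellation
for near-identical clouds).  A frame is degenerate when its per-axis
coordinate variance is ≤ 1e-12 Å² on all three axes; the rule is applied to
all frames, not only trailing ones — simpler and strictly stronger than the
observed tail artifact, and the removed count is reported per trajectory.
A trajectory is kept iff its minimum frame-wise RMSD to native is strictly
below the cutoff (default 1.0 Å); ties at the cutoff are excluded.

## Problem sizes used by the test suite and acceptance script

Persistence analytics use 3–9-point planar and spatial clouds with known
closed-form diagrams; oracle equivalence uses 50 seeded 8-point clouds;
NMF recovery uses planted rank-5 factors at 595×2000 with 5% noise over 5
seeds; rank selection uses a 5-block, 300-sample matrix with 30 runs per
rank over ranks 3–8; the end-to-end experiment runs 100 trajectories (50
per plan, 40 frames each, default noise) through every stage and requires
≥ 90% planted-path recovery.  These sizes were chosen so the planted
effects are comfortably identifiable while the whole suite completes in a
few minutes on one CPU.

## Known limitations

* The hinge-and-blend kinematics make early collapse frames geometrically
  loose (linker spacings transiently exceed bonded Cα distances).
* Volume-optimal-cycle representatives are label-dependent when multiple
  minimal volumes exist (any deterministic tie-break is).
* The alpha filtration of near-collinear conformations produces
  boundary-artifact loops; the pipeline's 20 Å birth cap removes them but
  is a heuristic, not a theorem.
* Multiplicative updates converge slowly near the optimum; the exact-fit
  floor reachable in 2000 iterations is ~1e-5 relative, not machine
  precision.
* `classify_paths` assumes exactly two path hypotheses expressed through
  two score components; trajectories crossing neither threshold are
  labeled "unresolved" rather than forced into a class.
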