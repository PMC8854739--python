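# tdafold

Topological data analysis of protein-folding trajectories: degree-1
persistent homology with volume-optimal cycles, "bag of simplices"
vectorization, non-negative matrix factorization with principled rank
selection, and flow-field analysis of folding dynamics in the reduced
space.

## The problem

Molecular-dynamics folding ensembles of small proteins such as the
35-residue villin headpiece subdomain contain millions of snapshots, and
the interesting question — *in which order does the tertiary structure
form, and along how many distinct routes?* — is poorly served by linear
coordinates like Cartesian PCA.  Loops are a natural alternative: the
closing of an inter-helix contact creates a one-dimensional cycle in the
Cα point cloud, a nonlocal feature defined by many residues at once, and
unfolded states are simply states without stable loops.

`tdafold` implements that analysis as a tested, reusable pipeline for
anyone studying folding ensembles of small helical proteins, together with
a synthetic bead-chain trajectory generator so every stage is verifiable
without external data.

## The method

For each snapshot with Cα positions p_1 … p_R, grow balls of radius r and
track the alpha filtration of the Delaunay complex.  Each loop is a triple
(b, d, C): birth radius, death radius, and its **volume-optimal cycle** C —
the boundary of a minimal set of triangles filling the hole, which
localizes the loop on specific residue pairs.  Snapshots are vectorized by
the **bag of simplices**

    s_ij = Σ_{C_k ∋ (i,j)} (d_k − b_k),

the summed lifetimes of all cycles containing edge (i, j), giving an
R(R−1)/2-dimensional non-negative vector (595 for R = 35).  The stacked
matrix V is factored as V ≈ WH with W, H ≥ 0 minimizing ‖V − WH‖_F, basis
columns rescaled to ‖w_j‖ = 1 so the scores h_ji carry Å units; the rank L
is chosen by the residual-sum-of-squares inflection and by the cophenetic
correlation of consensus clusterings over repeated fits.  Finally, the
per-frame score displacements are binned on a grid to estimate the mean
velocity field in the reduced space, and trajectories are classified into
folding paths by the order in which selected score components first
activate.

Preprocessing follows the standard conventions: trajectories are kept only
if their minimum Kabsch RMSD (Cα, proper rotations) to the native state is
below 1.0 Å, and frames in which every atom sits at one identical
coordinate triple — a known distributed-computing merge artifact — are
removed.

## Worked example

```python
import numpy as np
from tdafold import (make_native, plan_a, simulate_folding_trajectory,
                     diagram_for_snapshot, bag_of_simplices, feature_dimension)
from tdafold.preprocess import kabsch_rmsd

native = make_native(seed=0)
traj = simulate_folding_trajectory(native, plan_a(), n_frames=40, seed=1)
print("min RMSD to native: %.3f A" % min(kabsch_rmsd(f, native) for f in traj.frames))

cycles = diagram_for_snapshot(traj.frames[-1].coords, max_birth=20.0)
top = max(cycles, key=lambda c: c.lifetime)
print("most persistent loop: birth %.2f A, death %.2f A, %d edges, volume %d triangles"
      % (top.birth, top.death, len(top.cycle), top.optimal_volume_size))
vec = bag_of_simplices(cycles, 35)
print("feature vector: dimension %d, %d nonzero, total weight %.2f A"
      % (feature_dimension(35), (vec.weights > 0).sum(), vec.weights.sum()))
```

prints

```
min RMSD to native: 0.404 A
most persistent loop: birth 2.12 A, death 3.32 A, 9 edges, volume 7 triangles
feature vector: dimension 595, 113 nonzero, total weight 50.60 A
```

The trajectory folds (minimum RMSD 0.404 Å < 1.0 Å, so the preprocessing
filter keeps it).  The final frame's most robust loop closes at ball
radius 2.12 Å and fills at 3.32 Å; its volume-optimal cycle runs through 9
residue-pair edges, so those pairs receive its 1.2 Å lifetime in the
595-dimensional feature vector, whose 113 nonzero entries summarize the
frame's loop structure.

The full pipeline — simulate an ensemble with two planted folding paths,
filter it, compute persistence diagrams and feature vectors for every
frame, factorize, and classify each trajectory's path from the reduced
scores — runs from a config:

```sh
tdafold run-all --config config.yaml      # or per-stage subcommands:
tdafold simulate --out runs/sim --n-per-plan 5
tdafold preprocess --in runs/sim --native runs/sim/native.xyz --out report.csv
```

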