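# Methods

## Problem and approach

Membrane transporters with a conserved α-helical core (the LeuT fold is the
motivating case: two inverted five-TM repeats, canonically divided into a
bundle, a hash and two arms) change conformation by moving groups of helices
relative to one another. Comparing those conformations by structural
superposition forces a choice of reference frame that biases the result.
`ddmotion` instead works from internal coordinates:

1. **Distance difference matrix (DDM).** For two conformations A and B of
   one protein, with Cα–Cα distances `d_ij`, the DDM is `d_ij(B) − d_ij(A)`
   over the residues resolved in both structures. It is exactly invariant
   under rigid transforms of either structure and antisymmetric under
   swapping A and B. Positive entries mark residue pairs that move apart,
   negative entries pairs that approach.
2. **Helix-only and helix-binned DDMs.** Restricting to the residues of a
   curated set of helix segments gives the ho-DDM; collapsing each
   segment-pair block into a root-mean-squared distance difference,

       RMSDD(h1, h2) = sqrt( (1/N) Σ_{i∈h1} Σ_{j∈h2} (d_ij(B) − d_ij(A))² ),
       N = |h1|·|h2|,

   gives the hb-DDM, a fixed-size fingerprint (14×14 for the LeuT-fold
   segmentation 1a, 1b, 2, 3, 4, 5a, 5b, 6a, 6b, 7, 8, 9, 10a, 10b) that is
   directly comparable across distant homologs. The diagonal holds
   intrasegment RMSDDs (helix flexing) and is not forced to zero.
3. **Rigid bodies.** Segments that keep their mutual distances through a
   transition have small inter-segment RMSDD, so UPGMA (average-linkage)
   clustering of the hb-DDM — with the diagonal zeroed to make it a proper
   dissimilarity — groups segments that move as one rigid body. The merge
   tree is reported in full; a flat cut height is a user parameter because
   no single threshold is privileged.
4. **Sparse motion decomposition.** A set of hb-DDMs (one per conformational
   comparison) is flattened row-major into k² features (196 for k=14; both
   symmetric copies and the diagonal are kept, which double-weights
   off-diagonal terms in the loss — a deliberate fidelity choice) and
   factored by sparse PCA: L1-penalized components, LARS-lasso solver,
   features centered on the dataset mean. Simple rigid motions touch few
   segment pairs, so the sparse components isolate individual building-block
   motions. Components are sign-fixed to nonnegative entry sum, symmetrized,
   clipped at zero, and ordered by total weight over the training set.
   Projections are shifted by the projection of the all-zero matrix so that
   "no motion" is the origin; the resulting rescaled weights are empirically
   nonnegative on fingerprint datasets and read as motion amplitudes. A
   cross-check solves the same regression under a hard nonnegativity
   constraint (NNLS with components fixed) and reports the cosine similarity
   between the two weight sets.
5. **Superposition geometry.** Where a frame *is* wanted, a Kabsch
   least-squares fit (SVD, with the determinant sign correction so the
   rotation is always proper) superposes structures on a chosen segment
   selection. A rigid-body rotation angle is measured by aligning on one
   selection and fitting the residual rotation of another
   (`θ = arccos((tr R − 1)/2)`). Membrane-plane tilt θ uses three points per
   leaflet (e.g. OPM/PPM dummy atoms): normals `v = (p2−p1) × (p3−p1)`,
   angle `arccos(v_O·v_I / (‖v_O‖‖v_I‖))`, folded into [0°, 90°] because a
   plane normal's sign is arbitrary.
6. **Conformation annotation.** For proteins with many deposited structures,
   pairwise Cα RMSD after superposition forms a matrix whose rows are
   clustered by k-means (fixed seed, 10 restarts, clusters renumbered by
   size then lexicographically smallest member for stable output).
   Literature-derived anchor labels propagate to cluster members within
   0.5 Å of an anchor; anything farther is flagged unresolved rather than
   guessed. Representatives per state are chosen lexicographically: same
   organism as the reference; not atypical (RMSD to the state medoid above
   the 90th percentile); best resolution; disordered-core structures
   replaced by the next best; alphabetical PDB-ID tie-break.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| sparsity `alpha` | 2.0 | L1 penalty on sparse components; larger → sparser, more isolated motions |
| `n_components` | 6 | number of building-block motions; chosen from the error-vs-n elbow (`component_scan`) |
| `ridge_alpha` | 0.01 | ridge term in the projection step (sklearn convention); 0 gives exact least squares for fixed bases |
| propagation threshold | 0.5 Å | max RMSD to an anchor for label inheritance |
| k-means seed / restarts | 0 / 10 | reproducibility of state clustering |
| UPGMA cut height | none | flat rigid bodies only on request; the full tree is the primary output |

All residue bookkeeping uses author numbering as printed in the structure
file; helix boundaries are consumed as a tab-delimited table in the same
numbering. Residues unresolved in one structure are dropped from the DDM
(with per-segment counts logged) and `N` in the RMSDD always counts residue
pairs actually compared. Alternate locations keep the highest-occupancy Cα
(ties by altloc id); model 1 is used for multi-model files; insertion-coded
residues sort with their base number and ranges apply to base numbers.

## Synthetic data: what it emulates and what it does not

The generators provide ground truth that real structures cannot:

- `make_ideal_helix` / `make_toy_protein`: Cα traces of ideal α-helices
  (radius 2.3 Å, rise 1.5 Å/residue, 100°/residue — textbook values giving
  ~3.8 Å consecutive-Cα spacing), one helix per segment, placed on a circle
  or grid with ≥ 6 Å inter-segment clearance. Default scheme: 14 segments ×
  8 residues.
- `apply_motion`: scripted rotations about arbitrary axes/pivots plus
  translations of chosen segment subsets, so true rotation angles and rigid
  bodies are known exactly.
- `make_hbddm_dataset`: fingerprints as nonnegative mixtures of known
  sparse components plus symmetric Gaussian noise clipped at zero
  (clipping bias negligible at the default σ = 0.05 Å). The recovery
  experiments use 22 mixtures of 3 disjoint-support components — a dataset
  size typical of a transporter-family comparison set.

These fixtures have no side chains, no packing constraints, no membrane,
no disorder, and their motions are perfectly rigid. Passing tests therefore
demonstrate the correctness of the *computations* (invariances, oracle
equivalences, recovery of programmed ground truth), not that any particular
biological dataset decomposes into few motions; applying the pipeline to
experimental structure sets requires the structures and a curated helix
boundary table as inputs.

## Numerical choices

- DDM comparisons refuse traces from different proteins; ortholog
  comparisons need an explicit residue mapping upstream.
- The intra/inter RMSDD summary pools diagonal values and the unique
  off-diagonal triangle; SD is population (ddof = 0) and the convention is
  recorded in the output.
- Kabsch uses SVD with `d = sign(det)` on the smallest singular direction;
  degenerate (collinear) point sets raise rather than return an arbitrary
  frame. Angles are clamped to [−1, 1] before `arccos`.
- UPGMA ties break deterministically via scipy's linkage on the condensed
  matrix with segments in scheme order; flat-cluster labels are renumbered
  by first-appearing segment so they are stable under input permutation.
- For the membrane angle we use the standard product-of-norms cosine. The
  folding of θ into [0°, 90°] makes the result independent of leaflet point
  ordering.
- Sparse PCA is deterministic for fixed input order and seed; fitted
  components on symmetric-feature data are symmetric up to solver
  tolerance, and the symmetrization step averages the two triangles before
  clipping.
- The decomposition's reconstruction error is reported both as the mean
  squared error over all matrices and features (Å²) and as its square root
  (Å): both conventions circulate, so outputs label the two explicitly.

## Known limitations

- DDMs require the same protein (or an explicit mapping); cross-protein
  comparison of single conformations via plain distance matrices is out of
  scope.
- Angle-difference matrices, NMR multi-model ensembles beyond model 1,
  curved membranes, and membrane-position prediction itself are not
  handled; membrane planes are consumed as produced by OPM/PPM.
- The choice of k for state clustering is per protein and user-specified;
  `dispersion_scan` reports inertia across k to guide it, but no automatic
  criterion is imposed.
- With heavily disordered helices a segment can lose most of its residues;
  selections drop unresolved residues silently (logged), which biases
  RMSDDs toward the resolved part of the helix.
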