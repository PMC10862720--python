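"""Cluster structures into conformational states and propagate labels.

Simulates six structures of one protein: three near an open state, three
near a closed state (0.1 A coordinate jitter within a state, a 25-degree
bundle rotation between states).  k-means on the pairwise-RMSD matrix
splits them, and two literature-style anchors label every member within
0.5 A of an anchor.
"""

import numpy as np

import ddmotion as dm

scheme = dm.default_scheme(8)
rng = np.random.default_rng(0)
base = dm.make_toy_protein(scheme)
other = dm.apply_motion(
    base, scheme,
    dm.MotionScript.single(("1a", "1b", "2"), axis=(0, 1, 0), angle_deg=25.0))

traces = []
for g, anchor in enumerate((base, other)):
    for i in range(3):
        coords = anchor.coords + rng.normal(scale=0.1, size=anchor.coords.shape)
        traces.append(dm.CaTrace("toy", f"G{g}S{i}", "A",
                                 anchor.residue_numbers, coords))

matrix = dm.pairwise_rmsd_matrix(traces)
print("pairwise Ca RMSD matrix (A):")
print(matrix.to_frame().round(2))

labeling = dm.kmeans_conformations(matrix, k=2, seed=0)
labeled = dm.propagate_labels(
    labeling, {"G0S0": "O_op", "G1S0": "I_op"}, matrix, threshold=0.5)
print("\nstructure assignments (anchors: G0S0=O_op, G1S0=I_op):")
print(labeled.to_frame().to_string(index=False))
print("\nwithin-state RMSDs (~0.14 A) sit far below the between-state")
print("RMSDs, so the two conformations separate cleanly and every member")
print("lies within 0.5 A of its anchor, inheriting the anchor's label.")
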