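"""Measure rigid-body rotation angles and the membrane-plane angle theta.

Scripts a 20-degree bundle rock of a toy protein, recovers the angle by
hash-frame superposition, then tilts the bundle together with a membrane
plane and recovers the plane rotation theta.
"""

import numpy as np

import ddmotion as dm

scheme = dm.default_scheme(8)
hash_sel = ["3", "4", "8", "9"]
bundle = ("1a", "1b", "2", "6a", "6b", "7")

trace_o = dm.make_toy_protein(scheme, structure_id="O")
trace_i = dm.apply_motion(
    trace_o, scheme,
    dm.MotionScript.single(bundle, axis=(0, 1, 0), angle_deg=20.0),
    structure_id="I")

fit = dm.superpose(trace_i, trace_o, scheme, hash_sel)
print(f"hash superposition: RMSD = {fit.rmsd:.3f} A over {fit.n_atoms} Ca atoms")
angle = dm.rigid_body_rotation_angle(trace_o, trace_i, scheme,
                                     hash_sel, list(bundle))
print(f"bundle rotation in the hash frame: {angle:.2f} degrees "
      "(the scripted 20)")

# membrane-plane rotation: tilt bundle + plane by 10 degrees, hash fixed
tilt = dm.Move(bundle, axis=(1, 0, 0), angle_deg=10.0, pivot=(0, 0, 0))
tilted = dm.apply_motion(trace_o, scheme, dm.MotionScript((tilt,)))
plane_o = dm.MembranePlane([[0, 0, -15], [30, 0, -15], [0, 30, -15.0]])
R = dm.synthetic._rotation_about_axis(np.array([1.0, 0, 0]), 10.0)
plane_i = dm.MembranePlane(plane_o.points @ R.T)
theta = dm.membrane_rotation_workflow(trace_o, plane_o, tilted, plane_i,
                                      scheme, hash_sel)
print(f"membrane-plane angle theta (hash-based superposition): {theta:.2f} "
      "degrees — how much the membrane rotates when the hash is held fixed")
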