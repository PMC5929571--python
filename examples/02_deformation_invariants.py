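"""Tissue-deformation invariants on analytic flows.

Advects a point cloud under known affine velocity fields and shows that
the pipeline — finite-difference velocities, local affine fits, tensor
invariants — recovers the prescribed deformation: the volume change rate
P = tr(A), the rotation discriminant D (> 0 only for spiralling flow)
and the distortion rate Q_d (volume-preserving rearrangement).
"""

import numpy as np

import trajkit as tk

cases = {
    "isotropic expansion k=0.1": (tk.expansion(0.1), "P -> 0.3"),
    "rigid rotation w=0.2": (tk.rotation(0.2), "D -> w^6 = 6.4e-5"),
    "pure shear g=0.5": (tk.shear(0.5), "Q_d -> sqrt(2)*g = 0.707"),
    "translation v=(2,0,0)": (tk.translation([2, 0, 0]), "speed -> 2, rest -> 0"),
}

for name, (flow, expect) in cases.items():
    forest, A, b = tk.sample_field(flow, n_points=60, n_frames=11, seed=0)
    table = tk.deformation_table(forest, radius=1e6)
    frames = table.index.get_level_values("frame")
    interior = table[(frames > 0) & (frames < 10) & table["valid"]]
    print(f"{name:28s} ({expect})")
    print(f"    P {interior['P'].median(): .6f}   D {interior['D'].median(): .3e}   "
          f"Q_d {interior['Q_d'].median(): .6f}   speed {interior['speed'].median(): .3f}")
# Each printed median should match its closed form to ~1e-6: the sampler
# is built so central differences reproduce the field exactly at
# interior frames.
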