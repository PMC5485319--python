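"""Simulate sinusoidal breathing on a cardiac phantom.

The heart translates superiorly by up to 7 mm following a sinusoidal
breathing curve (bottom of the curve = full inhale); each readout of
the acquisition is taken from the k-space of the heart position at
that moment.  More breathing cycles per acquisition means more k-space
inconsistency: wave-like artefacts form around the moving region.
"""

import numpy as np

from kmotion import (
    RespiratoryModel,
    make_cardiac_phantom,
    make_cartesian_trajectory,
    simulate_respiratory_artefact,
)
from kmotion.features import compute_roi

N = 128
volume, mask = make_cardiac_phantom(seed=1, shape=(N, N, 64))
trajectory = make_cartesian_trajectory(N, N)
roi = compute_roi([mask], (N, N))
rs = roi.slices()
print(f"heart ROI: {roi.height}x{roi.width} pixels (mask bounding box + 10%)")

for cycles in (0, 1, 4, 8):
    model = RespiratoryModel(n_cycles=cycles, max_displacement_mm=7.0, n_states=8)
    clean, corrupted = simulate_respiratory_artefact(volume, mask, trajectory, model)
    roi_energy = np.linalg.norm(corrupted.data[rs] - clean.data[rs])
    print(f"{cycles} breathing cycle(s): artefact energy in heart ROI = {roi_energy:.3f}")
print("0 cycles is exactly artefact-free; any breathing injects a clearly")
print("non-zero artefact, while its energy varies only mildly with the rate")
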