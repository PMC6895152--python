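"""Axial circular statistics of an orientation map.

Orientation is axial (ϕ and ϕ+180° are identical), so dispersion uses
angle doubling.  The polar histogram duplicates every orientation by
central symmetry, as orientation data are shown on polar plots.
"""
import numpy as np

from shgpol import (AxialSample, axial_circular_mean, axial_circular_std,
                    polar_histogram)
from shgpol.simulate import generate_field

for mode in ("foetal_homogeneous", "foetal_random", "adult"):
    truth = generate_field(mode, shape=(128, 128), seed=1)
    s = AxialSample(truth.phi)
    h = polar_histogram(s, bin_width_deg=10.0)
    peak = h.bin_edges_deg[np.argmax(h.counts)]
    print(f"{mode:18s}  circ mean={axial_circular_mean(s):7.2f} deg  "
          f"circ std={axial_circular_std(s):5.1f} deg  "
          f"modal bin={peak:5.0f} deg")

print("\nThe circular std separates the tissue classes: tightly aligned "
      "foetal fields (~26 deg),\nadult fascicle mosaics (~32 deg), "
      "disordered foetal fields (~37 deg).")
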