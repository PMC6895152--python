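"""Per-pixel fibril orientation mapping on a synthetic adult field.

Simulates an adult meniscus field (fascicle clusters separated by thick
fibers), renders its 18-angle polarization series at a 10^4-count photon
budget, inverts it with the FFT estimator and compares the recovered
orientation map with the ground truth.
"""
import numpy as np

from shgpol import fit_orientation
from shgpol.simulate import generate_field, render_pstack

truth = generate_field("adult", shape=(128, 128), seed=1)
stack = render_pstack(truth, photons=1e4, seed=2)
result = fit_orientation(stack)

d = np.angle(np.exp(2j * (result.phi - truth.phi))) / 2.0  # axial difference
rmse = np.degrees(np.sqrt(np.nanmean(d[result.valid] ** 2)))
print(f"valid pixels: {100 * result.valid.mean():.1f}%")
print(f"orientation RMSE vs truth: {rmse:.2f} deg")
print(f"median recovered rho: {np.nanmedian(result.rho[result.valid]):.2f} "
      f"(truth median {np.median(truth.rho):.2f})")
print("\nSub-degree RMSE at this photon budget: the harmonic phases carry "
      "the orientation\nalmost losslessly; rho is noisier since it rides on "
      "the coefficient ratio.")
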