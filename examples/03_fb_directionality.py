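"""Forward/backward SHG ratios and thick-fiber segmentation.

Simulates foetal-like and adult-like fields, renders forward/backward
frame triplets, calibrates the pixel-wise F/B ratio (efficiency ratio
c = 0.4) and segments thick fibers with the Yen threshold on the backward
channel.  Maturation shows up as a higher inter-fibrillar F/B and a
larger fiber area.
"""
from shgpol import analyze_fb
from shgpol.simulate import generate_field, render_fb

for mode in ("foetal_random", "adult"):
    truth = generate_field(mode, shape=(128, 128), seed=1)
    res = analyze_fb(render_fb(truth, seed=2))
    print(f"{mode:16s}  F/B whole={res.median_whole:6.2f}  "
          f"F/B interfib={res.median_interfib:6.2f}  "
          f"interfib area={100 * res.interfib_fraction:5.1f}% "
          f"(truth {100 * truth.interfib_fraction:.1f}%)")

print("\nAdult inter-fibrillar tissue emits far more forward (large, "
      "ordered fibrils);\nits thick-fiber network occupies ~10% of the "
      "field against ~2% in the foetus.")
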