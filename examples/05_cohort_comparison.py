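"""Two-group comparison of per-sample metrics (5 foetal vs 6 adult).

Builds a small cohort of simulated samples, summarizes each with the
F/B and segmentation metrics, and runs the exact Wilcoxon-Mann-Whitney
comparison with SEM summaries — the across-sample statistics layer.
"""
import pandas as pd

from shgpol import analyze_fb, compare_all_metrics
from shgpol.circstats import AxialSample, axial_circular_std
from shgpol.simulate import generate_field, render_fb

rows = []
for group, mode, seeds in [("foetal", "foetal_random", range(5)),
                           ("adult", "adult", range(5, 11))]:
    for seed in seeds:
        truth = generate_field(mode, shape=(96, 96), seed=seed)
        res = analyze_fb(render_fb(truth, seed=seed + 100))
        rows.append({
            "sample_id": f"{group}-{seed}", "group": group,
            "fb_median_whole": res.median_whole,
            "fb_median_interfib": res.median_interfib,
            "interfib_fraction": res.interfib_fraction,
            "circ_std_deg": axial_circular_std(AxialSample(truth.phi))})

table = compare_all_metrics(pd.DataFrame(rows))
print(table.round(4).to_string(index=False))
print("\nAll four metrics separate the groups; with clean separation the "
      "exact test\nreaches its attainable minimum p = 2/C(11,5) = 0.0043.")
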