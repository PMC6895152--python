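"""End-to-end orchestration: configuration, file runs and cohort reports.

Each ``run_*`` function composes the library modules on files (or on
in-memory objects), writes its artifacts into an output directory and
returns the summary it wrote.  Everything downstream of fixed inputs and
configuration is deterministic; stochastic steps consume the config seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import circstats, cohort, directionality, io, orientation

log = logging.getLogger("shgpol")

__all__ = ["RunConfig", "run_pshg", "run_fb", "run_cohort"]


@dataclass(frozen=True)
class RunConfig:
    """Pipeline constants: calibration, validity gates, reporting knobs."""

    calibration_c: float = 0.4
    noise_floor: float = 2.0
    intensity_floor: float = 2.0
    residual_ceiling: float = 0.3
    kleinman_limit: float = 1.1
    bin_width_deg: float = 5.0
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("calibration_c", "noise_floor", "intensity_floor",
                     "residual_ceiling", "kleinman_limit", "bin_width_deg"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:12]


def _provenance(out_dir: Path, config: RunConfig, inputs: dict) -> None:
    (out_dir / "provenance.json").write_text(json.dumps(
        {"config": asdict(config), "config_sha256": config.digest(),
         "seed": config.seed, "inputs": inputs}, indent=1))


def run_pshg(stack_path, out_dir, config: RunConfig | None = None,
             sidecar_path=None, kleinman: bool = False) -> pd.Series:
    """Orientation-map a polarization stack file; write maps + summaries.

    Emits ϕ/ρ/validity TIFFs, the centrosymmetric polar histogram CSV and
    a one-row summary CSV (mean α0, % valid, circular mean/std of ϕ over
    valid pixels).  Deterministic given inputs and config.
    """
    config = config or RunConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stack = io.read_polarization_stack(stack_path, sidecar_path)
    result = orientation.fit_orientation(
        stack, kleinman=kleinman, kleinman_limit=config.kleinman_limit,
        intensity_floor=config.intensity_floor,
        residual_ceiling=config.residual_ceiling)
    io.write_orientation_maps(out_dir, result)

    coeffs = orientation.fourier_coefficients(stack)
    sample = circstats.AxialSample(result.phi[result.valid])
    hist = circstats.polar_histogram(sample, config.bin_width_deg)
    pd.DataFrame({"bin_start_deg": hist.bin_edges_deg[:-1],
                  "count": hist.counts}).to_csv(
        out_dir / "polar_histogram.csv", index=False)

    summary = pd.Series({
        "n_valid": int(result.valid.sum()),
        "pct_valid": 100.0 * result.valid.mean(),
        "mean_alpha0": float(coeffs.alpha0.mean()),
        "circ_mean_deg": circstats.axial_circular_mean(sample),
        "circ_std_deg": circstats.axial_circular_std(sample),
    })
    summary.to_frame().T.to_csv(out_dir / "summary.csv", index=False)
    _provenance(out_dir, config, {"stack": str(stack_path)})
    log.info("run_pshg %s: %.1f%% valid, circ std %.2f deg (config %s)",
             stack_path, summary["pct_valid"], summary["circ_std_deg"],
             config.digest())
    return summary


def run_fb(forward_path, backward_path, out_dir,
           config: RunConfig | None = None, sidecar_path=None) -> pd.Series:
    """Calibrated F/B analysis of a forward/backward file pair.

    Emits the corrected ratio map, the fiber mask and a one-row summary
    CSV {median_whole, median_fiber, median_interfib, interfib_fraction}.
    """
    config = config or RunConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pair, notes = io.read_fb_pair(forward_path, backward_path, sidecar_path,
                                  default_calibration_c=config.calibration_c)
    for key, msg in notes.items():
        log.warning("%s: %s", key, msg)
    res = directionality.analyze_fb(pair, noise_floor=config.noise_floor)

    import tifffile
    tifffile.imwrite(out_dir / "fb_ratio.tif",
                     res.ratio_map.astype(np.float32))
    tifffile.imwrite(out_dir / "fiber_mask.tif",
                     res.fiber_mask.astype(np.uint8) * 255)
    summary = pd.Series({
        "median_whole": res.median_whole,
        "median_fiber": res.median_fiber,
        "median_interfib": res.median_interfib,
        "interfib_fraction": res.interfib_fraction,
    })
    summary.to_frame().T.to_csv(out_dir / "summary.csv", index=False)
    _provenance(out_dir, config, {"forward": str(forward_path),
                                  "backward": str(backward_path)})
    return summary


def run_cohort(summaries: pd.DataFrame | str | Path, out_dir,
               config: RunConfig | None = None) -> pd.DataFrame:
    """Group comparison of per-sample metric rows (CSV path or DataFrame).

    Requires ≥ 2 samples in each of the two groups; emits a comparison
    CSV and a markdown report (one row per metric).  No multiple-testing
    correction is applied across metrics.
    """
    config = config or RunConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = pd.read_csv(summaries) if isinstance(summaries, (str, Path)) \
        else summaries
    counts = rows["group"].value_counts()
    if len(counts) < 2 or counts.min() < 2:
        raise ValueError("cohort needs >= 2 samples in each of two groups")
    table = cohort.compare_all_metrics(rows, alpha=config.alpha)
    table.to_csv(out_dir / "comparisons.csv", index=False)

    lines = ["# Cohort comparison", "",
             "| metric | n1 | n2 | mean1 ± SEM | mean2 ± SEM | U | p | sig |",
             "|---|---|---|---|---|---|---|---|"]
    for _, r in table.iterrows():
        lines.append(
            f"| {r.metric} | {r.n1} | {r.n2} "
            f"| {r.mean1:.4g} ± {r.sem1:.2g} | {r.mean2:.4g} ± {r.sem2:.2g} "
            f"| {r.U:.1f} | {r.p:.4g} | {'yes' if r.significant else 'NS'} |")
    lines += ["", f"Rank-sum test, two-sided, alpha = {config.alpha}; "
              "Shapiro-Wilk p-values in comparisons.csv. "
              "No multiple-testing correction across metrics."]
    (out_dir / "report.md").write_text("\n".join(lines) + "\n")
    _provenance(out_dir, config, {"summaries": str(summaries)[:200]})
    return table
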