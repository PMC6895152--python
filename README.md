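# shgpol

Quantitative analysis of fibrillar collagen architecture from second
harmonic generation (SHG) microscopy, built around two complementary
measurements:

- **Polarization-resolved SHG (P-SHG).** Collagen's SHG intensity under a
  rotating linear polarization follows a two-harmonic law
  `I(θ) = a0 + a2·cos 2(θ−ϕ) + a4·cos 4(θ−ϕ)`, where ϕ is the in-plane
  fibril orientation and the coefficients are algebraic functions of the
  susceptibility anisotropy ρ = χ33/χ31 (tilted out of plane by δ,
  ρ = ρ0·cos²δ + 3·sin²δ) and a scale K:
  `a0 = K/2·[1+((ρ−1)/2)² + 2((ρ+1)/2)²]`, `a2 = K(ρ²−1)/2`,
  `a4 = K/8·(ρ−3)(ρ+1)`. A per-pixel DFT along the angle axis yields the
  harmonic phases; ϕ is the β-weighted blend of the second- and
  fourth-harmonic phase estimates (β = α2²/(α2²+4α4²)), ρ follows in
  closed form from the signed harmonic ratio, and an optional nonlinear
  fit relaxes the Kleinman assumption A = χ31/χ15 = 1, discarding pixels
  with |A| ≥ 1.1.
- **Forward/backward directionality (F/B).** The ratio of forward- to
  backward-detected SHG grows with the axial size and order of the
  emitting structures. After dividing by the detection-efficiency ratio
  measured on an isotropic reference (c = 0.4), the pixel-wise median F/B
  separates thin immature fibrils from mature thick fibers; Yen
  thresholding of the backward channel segments the thick-fiber network
  and gives the inter-fibrillar area fraction.

Downstream, axial (period-π) circular statistics summarize orientation
maps, and a nonparametric cohort layer (Shapiro-Wilk screen, exact
Wilcoxon-Mann-Whitney, SEM error bars) compares sample groups — e.g.
foetal versus adult meniscus, where maturation raises the inter-fibrillar
F/B from ≈4.5 to ≈28 and shrinks the inter-fibrillar area from ≈98% to
≈90%.

Because such tissue images are rarely shareable, `shgpol.simulate`
generates seeded ground-truth fields of three tissue classes
(homogeneous foetal, random foetal, adult fascicle/thick-fiber mosaics)
and renders their polarization series and F/B frame sets with shot and
read noise, so the entire pipeline runs — and is tested — end to end
without instrument data.

## Worked example

```sh
python examples/03_fb_directionality.py
```

```
foetal_random     F/B whole=  4.51  F/B interfib=  4.50  interfib area= 97.7% (truth 98.0%)
adult             F/B whole= 27.83  F/B interfib= 28.01  interfib area= 89.4% (truth 90.0%)
```

Each line is one simulated 128×128 sample: the calibrated median F/B over
the whole field and over the inter-fibrillar mask, and the Yen-segmented
inter-fibrillar area against the generator's label map. The adult field
shows the maturation signature — a six-fold higher inter-fibrillar F/B
and a five-fold larger thick-fiber area. The other `examples/` scripts
walk through the forward model, orientation mapping (`02` prints a
0.09° recovery RMSE at a 10⁴-count budget), circular statistics and the
cohort comparison.

A thin CLI wraps the same pipeline for shell use:

```sh
shgpol simulate --mode adult --shape 256x256 --seed 1 --out fixture/
shgpol fit fixture/pstack.tif out/        # ϕ/ρ maps + summaries
shgpol fb fixture/forward.tif fixture/backward.tif out-fb/
```

## Layout

- `src/shgpol/model.py` — the two-harmonic intensity law and tensor types
- `src/shgpol/orientation.py` — per-pixel DFT inversion, Kleinman fit, masks
- `src/shgpol/directionality.py` — F/B calibration, Yen segmentation
- `src/shgpol/circstats.py` — axial circular statistics, polar histograms
- `src/shgpol/cohort.py` — Shapiro-Wilk + rank-sum group comparisons
- `src/shgpol/simulate.py` — ground-truth fields and noisy renders
- `src/shgpol/io.py`, `pipeline.py`, `cli.py` — files, orchestration, CLI
- `docs/methods.md` — models, calibration choices, limitations
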