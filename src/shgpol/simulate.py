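"""Seeded generator of ground-truth collagen fields and rendered SHG data.

Three tissue classes are emulated, matching the architectures seen in
foetal and adult meniscus:

``foetal_homogeneous``
    one orientation over the whole field (horizontal fibrils) plus
    wrapped-normal jitter, with a sparse thin-fiber skeleton (2% area);
``foetal_random``
    orientation patches (Voronoi cells) whose axes are drawn uniformly
    over a solved arc — a non-organized, more random arrangement — again
    with a 2% thin-fiber skeleton;
``adult``
    Voronoi fascicle clusters of homogeneous orientation separated by a
    thick-fiber network (10% area) following the cluster boundaries, the
    fiber axis along the boundary tangent.

Dispersion defaults are calibrated so the axial circular std of the field
matches the tissue-class values (≈26°, ≈37°, ≈32°); the generator solves
the non-fiber dispersion analytically from the target given the realized
fiber-tangent resultant, and assigns cluster orientations by area-weighted
stratified (inverse-CDF) sampling so even a 256×256 field represents its
nominal dispersion.  F/B contrast defaults: inter-fibrillar 4.5 (foetal) /
28 (adult), thick fibers 5 in both (their F/B does not mature).

All randomness flows from one integer seed through named generators; the
same (mode, shape, seed, params) reproduces every array bit-exactly.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage, optimize
from scipy.spatial import cKDTree
from scipy.special import ndtri

from .directionality import FBPair
from .model import coeffs_from_rho, rho_from_tilt
from .orientation import PolarizationStack, wrap_axial

__all__ = [
    "REGION_INTERFIB",
    "REGION_FIBER",
    "FieldParams",
    "GroundTruthField",
    "FixtureBundle",
    "generate_field",
    "render_pstack",
    "render_fb",
    "make_fixture",
    "write_fixture",
    "read_fixture",
]

REGION_INTERFIB = 0
REGION_FIBER = 1

#: Default polarization grid: 18 states spaced by 10° over one half-turn.
DEFAULT_ANGLES_DEG = np.arange(18) * 10.0


@dataclass(frozen=True)
class FieldParams:
    """Tissue-class parameters of the ground-truth field generator.

    ``cluster_area_px`` is the expected Voronoi cell area for orientation
    patches (None = a single homogeneous domain); ``fiber_cell_area_px``
    the cell area of the Voronoi tessellation whose boundaries seed the
    thick-fiber skeleton (None = reuse the orientation tessellation, as in
    adult tissue where fibers separate the fascicles).  The cluster scale
    is a free parameter of the emulation — no spatial statistics constrain
    it — and is recorded in every manifest.
    """

    mode: str
    base_phi_deg: float = 0.0
    target_circ_std_deg: float = 32.0
    within_jitter_deg: float | None = 4.0
    cluster_dist: str = "normal"  # "normal" | "uniform_arc"
    cluster_area_px: float | None = 1600.0
    fiber_cell_area_px: float | None = None
    fiber_fraction: float = 0.10
    rho0_range: tuple[float, float] = (1.3, 2.0)
    fb_interfib: float = 28.0
    fb_fiber: float = 5.0
    K_interfib: float = 1.0
    K_fiber: float = 1.8
    K_texture_sigma: float = 0.15
    bwd_fiber_gain: float = 3.0
    tilt_patch_frac: float = 0.0
    tilt_delta_deg: float = 45.0
    pixel_size_um: float = 2.0


_MODE_DEFAULTS = {
    "foetal_homogeneous": dict(
        target_circ_std_deg=26.0, within_jitter_deg=None, cluster_area_px=None,
        fiber_cell_area_px=14400.0, fiber_fraction=0.02,
        fb_interfib=4.5),
    "foetal_random": dict(
        target_circ_std_deg=37.0, within_jitter_deg=5.0,
        cluster_dist="uniform_arc", cluster_area_px=1600.0,
        fiber_cell_area_px=14400.0, fiber_fraction=0.02,
        fb_interfib=4.5),
    "adult": dict(
        target_circ_std_deg=32.0, within_jitter_deg=4.0,
        cluster_dist="normal", cluster_area_px=1600.0,
        fiber_cell_area_px=None, fiber_fraction=0.10,
        fb_interfib=28.0),
}


@dataclass
class GroundTruthField:
    """Per-pixel ground truth of one simulated tissue field."""

    phi: np.ndarray
    rho0: np.ndarray
    delta: np.ndarray
    K: np.ndarray
    region: np.ndarray
    fb_ratio: np.ndarray
    meta: dict

    @property
    def fiber_mask(self) -> np.ndarray:
        return self.region == REGION_FIBER

    @property
    def fiber_fraction(self) -> float:
        return float(self.fiber_mask.mean())

    @property
    def interfib_fraction(self) -> float:
        return float(1.0 - self.fiber_mask.mean())

    @property
    def rho(self) -> np.ndarray:
        """Effective anisotropy after out-of-plane tilt."""
        return rho_from_tilt(self.rho0, self.delta)


@dataclass
class FixtureBundle:
    """A ground-truth field with its rendered acquisitions and manifest."""

    truth: GroundTruthField
    pstack: PolarizationStack
    fbpair: FBPair
    manifest: dict


def _voronoi_labels(shape, n_cells, rng) -> np.ndarray:
    h, w = shape
    pts = np.column_stack([rng.uniform(0, h, n_cells),
                           rng.uniform(0, w, n_cells)])
    zz, yy = np.mgrid[0:h, 0:w]
    grid = np.column_stack([zz.ravel(), yy.ravel()])
    _, lab = cKDTree(pts).query(grid)
    return lab.reshape(shape)


def _boundary_mask(labels: np.ndarray) -> np.ndarray:
    b = np.zeros(labels.shape, dtype=bool)
    b[:-1, :] |= labels[:-1, :] != labels[1:, :]
    b[:, :-1] |= labels[:, :-1] != labels[:, 1:]
    return b


def _stratified_uniform(n, rng) -> np.ndarray:
    """n scrambled stratified quantiles in (0, 1)."""
    return rng.permutation((np.arange(n) + rng.uniform(size=n)) / n)


def _area_midpoint_quantiles(areas, rng) -> np.ndarray:
    """Midpoint quantiles of area-weighted strata, in random cluster order.

    Cluster i receives the quantile at the middle of its own area share,
    so the area-weighted empirical distribution of the assigned values
    tracks the nominal law even for a few tens of clusters.
    """
    n = areas.size
    order = rng.permutation(n)
    frac = areas[order] / areas.sum()
    cum = np.concatenate([[0.0], np.cumsum(frac)])
    mid = (cum[:-1] + cum[1:]) / 2.0
    q = np.empty(n)
    q[order] = mid
    return q


def _solve_uniform_arc(r_needed: float) -> float:
    """Half-width Δ of a uniform axial arc with doubled-angle resultant r.

    2ϕ ~ U(−2Δ, 2Δ) has R = sin(2Δ)/(2Δ); solved on (0, π/2]."""
    if r_needed >= 1.0:
        return 0.0
    if r_needed <= 0.0:
        return np.pi / 2.0
    f = lambda x: np.sin(x) / x - r_needed  # noqa: E731
    return float(optimize.brentq(f, 1e-9, np.pi)) / 2.0


def generate_field(mode: str, shape=(256, 256), seed=0,
                   params: FieldParams | None = None,
                   **overrides) -> GroundTruthField:
    """Generate one ground-truth collagen field of the given tissue class.

    ``seed`` may be an int or a numpy Generator.  Keyword overrides patch
    individual :class:`FieldParams` fields.
    """
    if mode not in _MODE_DEFAULTS:
        raise ValueError(f"unknown mode {mode!r}; choose from "
                         f"{sorted(_MODE_DEFAULTS)}")
    if min(shape) < 64:
        raise ValueError("field must be at least 64x64")
    if params is None:
        params = FieldParams(mode=mode, **_MODE_DEFAULTS[mode])
    if overrides:
        params = replace(params, **overrides)
    rng = seed if isinstance(seed, np.random.Generator) else \
        np.random.default_rng(seed)
    h, w = shape
    npix = h * w
    base = np.deg2rad(params.base_phi_deg)

    # orientation clusters
    if params.cluster_area_px is None:
        labels = np.zeros(shape, dtype=int)
        n_clusters = 1
    else:
        n_clusters = max(1, int(round(npix / params.cluster_area_px)))
        labels = _voronoi_labels(shape, n_clusters, rng)

    # thick-fiber skeleton along (its own or the cluster) Voronoi boundaries
    if params.fiber_cell_area_px is None:
        fiber_labels = labels
    else:
        n_fc = max(2, int(round(npix / params.fiber_cell_area_px)))
        fiber_labels = _voronoi_labels(shape, n_fc, rng)
    dist = ndimage.distance_transform_edt(~_boundary_mask(fiber_labels))
    k = int(round(params.fiber_fraction * npix))
    order = np.argsort(dist.ravel() + rng.uniform(0, 1e-9, npix))
    fiber = np.zeros(npix, dtype=bool)
    fiber[order[:k]] = True
    fiber = fiber.reshape(shape)

    # fiber orientation follows the boundary tangent
    smooth = ndimage.gaussian_filter(dist, 3.0)
    gz, gy = np.gradient(smooth)
    tangent = wrap_axial(np.arctan2(gy, gz) + np.pi / 2.0)

    # ---- dispersion calibration ------------------------------------------
    # |f·R_j·C_f·e^(−2i·base) + (1−f)·R_j·R_c| = R_target, solved for the
    # unknown dispersion given the realized fiber-tangent resultant C_f.
    s_t = np.deg2rad(params.target_circ_std_deg)
    r_t = float(np.exp(-2.0 * s_t**2))
    f = k / npix
    c_f = (np.exp(2j * tangent[fiber]).mean() * np.exp(-2j * base)
           if k else 0.0 + 0.0j)

    if params.within_jitter_deg is None:
        # homogeneous mode: all dispersion is per-pixel jitter
        denom = abs(f * c_f + (1.0 - f))
        r_j = min(r_t / max(denom, 1e-12), 1.0)
        sigma_j = float(np.sqrt(-np.log(r_j) / 2.0)) if r_j < 1.0 else 0.0
        r_c = 1.0
    else:
        sigma_j = float(np.deg2rad(params.within_jitter_deg))
        r_j = float(np.exp(-2.0 * sigma_j**2))
        t = r_t / r_j
        disc = max(t**2 - np.imag(f * c_f) ** 2, 0.0)
        r_c = (-np.real(f * c_f) + np.sqrt(disc)) / (1.0 - f)
        r_c = float(np.clip(r_c, 0.0, 1.0))

    # cluster orientations
    if n_clusters == 1:
        cluster_phi = np.array([base])
    else:
        areas = np.bincount(labels.ravel(), minlength=n_clusters).astype(float)
        q = _area_midpoint_quantiles(areas, rng)
        if params.cluster_dist == "uniform_arc":
            delta_arc = _solve_uniform_arc(r_c)
            cluster_phi = base + delta_arc * (2.0 * q - 1.0)
        elif params.cluster_dist == "normal":
            sigma_c = float(np.sqrt(-np.log(max(r_c, 1e-12)) / 2.0)) \
                if r_c < 1.0 else 0.0
            cluster_phi = base + sigma_c * ndtri(q)
        else:
            raise ValueError(f"unknown cluster_dist {params.cluster_dist!r}")

    phi = cluster_phi[labels]
    phi = np.where(fiber, tangent, phi)
    if sigma_j > 0:
        phi = phi + rng.normal(0.0, sigma_j, shape)
    phi = wrap_axial(phi)

    # anisotropy, tilt, brightness, directionality
    lo, hi = params.rho0_range
    rho0 = rng.uniform(lo, hi, n_clusters)[labels]
    delta = np.zeros(shape)
    if params.tilt_patch_frac > 0:
        r_patch = np.sqrt(params.tilt_patch_frac * npix / np.pi)
        cz, cy = rng.uniform(0, h), rng.uniform(0, w)
        zz, yy = np.mgrid[0:h, 0:w]
        patch = (zz - cz) ** 2 + (yy - cy) ** 2 <= r_patch**2
        delta[patch] = np.deg2rad(params.tilt_delta_deg)
    sig = params.K_texture_sigma
    texture = np.exp(rng.normal(0.0, sig, shape) - sig**2 / 2.0)
    K = np.where(fiber, params.K_fiber, params.K_interfib) * texture
    fb_ratio = np.where(fiber, params.fb_fiber, params.fb_interfib)
    region = np.where(fiber, REGION_FIBER, REGION_INTERFIB).astype(np.uint8)

    meta = {"mode": mode, "shape": list(shape),
            "seed": None if isinstance(seed, np.random.Generator) else int(seed),
            "params": asdict(params), "n_clusters": n_clusters,
            "fiber_fraction_realized": f,
            "jitter_sigma_rad": sigma_j, "cluster_resultant": r_c}
    return GroundTruthField(phi=phi, rho0=rho0, delta=delta, K=K,
                            region=region, fb_ratio=fb_ratio, meta=meta)


def render_pstack(truth: GroundTruthField, angles_deg=None,
                  photons: float = 1e4, read_sigma: float = 1.0,
                  repeats: int = 3, seed=0) -> PolarizationStack:
    """Render the polarization series of a ground-truth field.

    Per pixel and angle the expected count is the two-harmonic intensity
    at the pixel's (ϕ, ρ, K), normalized so the θ-average equals
    ``photons``·K.  Finite photon budgets add Poisson shot noise plus
    Gaussian read noise and quantize to integer counts; ``photons=inf``
    renders the analytic model exactly (amplitude K, no noise).
    """
    if photons < 0:
        raise ValueError("photon budget must be nonnegative")
    angles_deg = DEFAULT_ANGLES_DEG if angles_deg is None else \
        np.asarray(angles_deg, dtype=float)
    theta = np.deg2rad(angles_deg)
    rng = seed if isinstance(seed, np.random.Generator) else \
        np.random.default_rng(seed)

    rho = truth.rho
    c = coeffs_from_rho(rho, 1.0)
    u = theta[:, None, None] - truth.phi[None, :, :]
    unit = (c.a0[None] + c.a2[None] * np.cos(2 * u)
            + c.a4[None] * np.cos(4 * u)) / c.a0[None]

    if np.isinf(photons):
        frames = truth.K[None] * unit
        raw = np.repeat(frames[:, None], repeats, axis=1)
    else:
        lam = photons * truth.K[None] * unit
        raw = rng.poisson(lam[:, None], size=(theta.size, repeats)
                          + truth.phi.shape).astype(float)
        if read_sigma > 0:
            raw += rng.normal(0.0, read_sigma, raw.shape)
        np.clip(np.rint(raw), 0, None, out=raw)
    return PolarizationStack.from_repeats(
        raw, angles_deg,
        pixel_size_um=truth.meta["params"].get("pixel_size_um", 2.0))


def render_fb(truth: GroundTruthField, base_backward: float = 200.0,
              calibration_c: float = 0.4, repeats: int = 3, seed=0,
              noiseless: bool = False) -> FBPair:
    """Render forward/backward frame sets of a ground-truth field.

    Backward expectation = ``base_backward``·K (thick fibers boosted by
    ``bwd_fiber_gain``: they dominate the backward channel); forward
    expectation = backward · fb_ratio · calibration_c, so the calibrated
    pixel ratio recovers ``truth.fb_ratio`` in expectation (exactly when
    ``noiseless``).
    """
    if base_backward <= 0:
        raise ValueError("base_backward must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else \
        np.random.default_rng(seed)
    gain = truth.meta["params"].get("bwd_fiber_gain", 1.0)
    bwd_exp = base_backward * truth.K * np.where(truth.fiber_mask, gain, 1.0)
    fwd_exp = bwd_exp * truth.fb_ratio * calibration_c
    if noiseless:
        fwd = np.repeat(fwd_exp[None], repeats, axis=0)
        bwd = np.repeat(bwd_exp[None], repeats, axis=0)
    else:
        fwd = rng.poisson(fwd_exp[None], size=(repeats,) + fwd_exp.shape
                          ).astype(float)
        bwd = rng.poisson(bwd_exp[None], size=(repeats,) + bwd_exp.shape
                          ).astype(float)
    return FBPair(fwd, bwd, calibration_c=calibration_c)


def make_fixture(mode: str, shape=(256, 256), seed=0, photons: float = 1e4,
                 read_sigma: float = 1.0, base_backward: float = 200.0,
                 calibration_c: float = 0.4, repeats: int = 3,
                 **field_overrides) -> FixtureBundle:
    """Generate field + polarization stack + F/B pair from one master seed.

    Child seeds for the field, the polarization render and the F/B render
    are spawned from ``seed`` so the three stages are independent streams
    yet jointly reproducible from the manifest.
    """
    ss = np.random.SeedSequence(seed)
    s_field, s_pol, s_fb = (np.random.default_rng(c) for c in ss.spawn(3))
    truth = generate_field(mode, shape=shape, seed=s_field, **field_overrides)
    truth.meta["seed"] = int(seed)
    pstack = render_pstack(truth, photons=photons, read_sigma=read_sigma,
                           repeats=repeats, seed=s_pol)
    fbpair = render_fb(truth, base_backward=base_backward,
                       calibration_c=calibration_c, repeats=repeats,
                       seed=s_fb)
    manifest = {
        "mode": mode, "shape": list(shape), "seed": int(seed),
        "photons": photons, "read_sigma": read_sigma,
        "base_backward": base_backward, "calibration_c": calibration_c,
        "repeats": repeats, "field_overrides": field_overrides,
        "field_meta": {k: v for k, v in truth.meta.items()
                       if k not in ("shape", "seed")},
        "angles_deg": pstack.angles_deg.tolist(),
    }
    return FixtureBundle(truth=truth, pstack=pstack, fbpair=fbpair,
                         manifest=manifest)


def _write_tiff(path: Path, array: np.ndarray) -> np.ndarray:
    """Write pages as uint16 when lossless, else float32; return as stored."""
    import tifffile

    a = np.asarray(array)
    if (np.issubdtype(a.dtype, np.floating)
            and np.all(a == np.rint(a)) and a.min() >= 0 and a.max() < 2**16):
        a = a.astype(np.uint16)
    elif np.issubdtype(a.dtype, np.floating):
        a = a.astype(np.float32)
    tifffile.imwrite(path, a, photometric="minisblack")
    return a


def write_fixture(bundle: FixtureBundle, directory) -> Path:
    """Write the fixture to ``directory`` (TIFFs + JSON manifest).

    The polarization stack is one multi-page TIFF with angle-major page
    order (page = angle_index·repeats + repeat_index); forward/backward
    channels hold one page per repeat; truth maps are float32 (region as
    uint8).  Returns the manifest path.  A read-back reproduces every
    array bit-exactly, and re-running :func:`make_fixture` with the
    manifest's seed and parameters regenerates the fixture.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    import tifffile

    raw = bundle.pstack.raw
    if raw is None:
        raw = np.moveaxis(bundle.pstack.frames, -1, 0)[:, None]
    pages = raw.reshape((-1,) + raw.shape[2:])
    _write_tiff(directory / "pstack.tif", pages)
    (directory / "pstack.json").write_text(json.dumps({
        "angles_deg": bundle.pstack.angles_deg.tolist(),
        "pixel_size_um": bundle.pstack.pixel_size_um,
        "repeats": int(raw.shape[1])}, indent=1))

    _write_tiff(directory / "forward.tif", bundle.fbpair.forward_frames)
    _write_tiff(directory / "backward.tif", bundle.fbpair.backward_frames)
    (directory / "fb.json").write_text(json.dumps({
        "calibration_c": bundle.fbpair.calibration_c,
        "noise_floor": 2.0}, indent=1))

    t = bundle.truth
    for name, arr in [("truth_phi", t.phi), ("truth_rho0", t.rho0),
                      ("truth_delta", t.delta), ("truth_K", t.K),
                      ("truth_fb_ratio", t.fb_ratio)]:
        tifffile.imwrite(directory / f"{name}.tif", arr.astype(np.float32))
    tifffile.imwrite(directory / "truth_region.tif",
                     t.region.astype(np.uint8))

    manifest_path = directory / "manifest.json"
    manifest = dict(bundle.manifest)
    manifest["files"] = sorted(p.name for p in directory.glob("*.tif"))
    manifest_path.write_text(json.dumps(manifest, indent=1, default=float))
    return manifest_path


def read_fixture(directory) -> dict:
    """Read back a written fixture as {name: array} plus its manifest."""
    import tifffile

    directory = Path(directory)
    out = {"manifest": json.loads((directory / "manifest.json").read_text())}
    for p in sorted(directory.glob("*.tif")):
        out[p.stem] = tifffile.imread(p)
    for p in ("pstack.json", "fb.json"):
        out[p.replace(".json", "_sidecar")] = json.loads(
            (directory / p).read_text())
    return out
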