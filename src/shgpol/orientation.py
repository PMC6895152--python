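"""Per-pixel inversion of polarization stacks into fibril orientation maps.

The measured intensity at each pixel, as a function of the incident linear
polarization angle θ sampled on a uniform grid over one half-turn, follows
the two-harmonic law of :mod:`shgpol.model`.  A DFT along the angle axis
yields the harmonic magnitudes (α0, α2, α4) and two independent estimates
of the fibril orientation: ϕ2 from the 2nd-harmonic phase (unique over the
axial half-turn) and ϕ4 from the 4th-harmonic phase (unique only modulo
π/4).  The two are merged with the variance-optimal weight
β = α2²/(α2² + 4α4²) after lifting ϕ4 by mπ/4 (m ∈ {−2…2}) onto the branch
nearest ϕ2.  The effective anisotropy ρ follows in closed form from the
signed harmonic ratio, and an optional per-pixel nonlinear fit relaxes the
Kleinman assumption A = χ31/χ15 = 1, flagging pixels with |A| ≥ 1.1.

Angles are radians internally; ϕ maps live in [−π/2, π/2) (axial data:
fibril polarity is not observable).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import coeffs_from_rho

__all__ = [
    "PolarizationStack",
    "FourierCoeffMap",
    "OrientationResult",
    "wrap_axial",
    "fourier_coefficients",
    "combine_phi",
    "estimate_rho",
    "kleinman_fit",
    "validity_mask",
    "fit_orientation",
]


def wrap_axial(phi):
    """Wrap angles into the axial half-turn [−π/2, π/2)."""
    return (np.asarray(phi, dtype=float) + np.pi / 2.0) % np.pi - np.pi / 2.0


@dataclass
class PolarizationStack:
    """An H×W×Nθ polarization series with its angle grid and metadata.

    ``frames`` holds the (repeat-averaged) intensity in counts; ``raw``
    optionally keeps the individual acquisitions with shape (Nθ, R, H, W).
    The angle grid must be θ_k = k·(180/Nθ)° — uniformly spaced from 0,
    spanning exactly one half-turn.
    """

    frames: np.ndarray
    angles_deg: np.ndarray
    pixel_size_um: float = 2.0
    repeats: int = 1
    raw: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.angles_deg = np.asarray(self.angles_deg, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[-1] != self.angles_deg.size:
            raise ValueError("frames must be H×W×Nθ matching the angle list")
        if np.any(self.frames < 0):
            raise ValueError("intensities must be nonnegative")
        _check_angle_grid(self.angles_deg)

    @classmethod
    def from_repeats(cls, raw: np.ndarray, angles_deg, **kw) -> "PolarizationStack":
        """Build a stack from raw acquisitions shaped (Nθ, R, H, W).

        The R repeat frames per angle are mean-averaged before any fitting.
        """
        raw = np.asarray(raw, dtype=float)
        if raw.ndim != 4:
            raise ValueError("raw must be (Nθ, repeats, H, W)")
        frames = np.moveaxis(raw.mean(axis=1), 0, -1)
        return cls(frames, np.asarray(angles_deg, dtype=float),
                   repeats=raw.shape[1], raw=raw, **kw)

    @property
    def n_angles(self) -> int:
        return int(self.angles_deg.size)

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[:2]


def _check_angle_grid(angles_deg: np.ndarray) -> None:
    n = angles_deg.size
    if n < 9:
        raise ValueError("need at least 9 polarization angles (Nyquist for the "
                         "4th harmonic over a half-turn)")
    expected = np.arange(n) * (180.0 / n)
    if not np.allclose(angles_deg, expected, atol=1e-6):
        raise ValueError(
            "polarization angles must be k*(180/N) degrees, k=0..N-1 "
            f"(got {angles_deg.tolist()})")


@dataclass
class FourierCoeffMap:
    """Per-pixel harmonic decomposition of a polarization stack.

    ``alpha0/2/4`` are the harmonic magnitudes (counts); ``phi2`` ∈
    [−π/2, π/2) and ``phi4`` ∈ (−π/8, π/8] the phase-derived orientation
    estimates; ``beta`` the 2nd-harmonic weight α2²/(α2²+4α4²).  ``c1`` and
    ``c2`` keep the complex harmonics (2·F_m/Nθ) so signed amplitudes can be
    recovered by projection at a known orientation.
    """

    alpha0: np.ndarray
    alpha2: np.ndarray
    alpha4: np.ndarray
    phi2: np.ndarray
    phi4: np.ndarray
    beta: np.ndarray
    c1: np.ndarray = field(repr=False, default=None)
    c2: np.ndarray = field(repr=False, default=None)


@dataclass
class OrientationResult:
    """Per-pixel orientation inversion output.

    ``phi`` (radians, axial) and ``rho`` are NaN where undefined; ``valid``
    marks pixels passing all gates; ``m`` is the π/4-branch index used to
    lift ϕ4; ``A`` is present only after a Kleinman (non-symmetric) fit.
    """

    phi: np.ndarray
    rho: np.ndarray
    valid: np.ndarray
    m: np.ndarray
    A: np.ndarray | None = None


def fourier_coefficients(stack: PolarizationStack) -> FourierCoeffMap:
    """DFT of the angle axis → per-pixel harmonic magnitudes and phases.

    With θ_k = kπ/N the harmonic cos 2(θ−ϕ) lives in DFT bin 1 and
    cos 4(θ−ϕ) in bin 2:  F_m = Σ_k I_k e^(−2πi·m·k/N) gives
    α0 = F_0/N, c_m = 2F_m/N with Arg(c1) = −2ϕ (for a2 > 0).
    ϕ2 = −Arg(c1)/2 lands in [−π/2, π/2) directly (two-argument
    arctangent); ϕ4 uses the single-argument arctangent of tan(Arg(c2))
    so the unknown sign of a4 cannot fold it out of (−π/8, π/8].
    """
    n = stack.n_angles
    F = np.fft.fft(stack.frames, axis=-1)
    alpha0 = F[..., 0].real / n
    c1 = 2.0 * F[..., 1] / n
    c2 = 2.0 * F[..., 2] / n
    alpha2 = np.abs(c1)
    alpha4 = np.abs(c2)
    phi2 = -np.angle(c1) / 2.0
    phi4 = -np.arctan(np.tan(np.angle(c2))) / 4.0
    denom = alpha2**2 + 4.0 * alpha4**2
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = np.where(denom > 0, alpha2**2 / np.where(denom > 0, denom, 1.0),
                        np.nan)
    return FourierCoeffMap(alpha0, alpha2, alpha4, phi2, phi4, beta, c1, c2)


def combine_phi(coeffs: FourierCoeffMap) -> tuple[np.ndarray, np.ndarray]:
    """Merge ϕ2 and ϕ4 into the final orientation map.

    ϕ4 is defined only modulo π/4; the branch index m ∈ {−2,…,2} minimizing
    the circular (period-π) distance between ϕ2 and ϕ4 + mπ/4 is selected,
    then ϕ = β·ϕ2 + (1−β)·(ϕ4 + mπ/4) on the branch nearest ϕ2 (so the
    blend never averages across the ±90° wrap), wrapped back into
    [−π/2, π/2).  Pixels with α2 = α4 = 0 have no orientation: ϕ = NaN.
    """
    base = coeffs.phi2 - coeffs.phi4
    best_d = np.full(base.shape, np.inf)
    best_m = np.zeros(base.shape, dtype=np.int8)
    for m in (0, 1, -1, 2, -2):  # ties (m = ±2 differ by π) go to small |m|
        d = wrap_axial(base - m * np.pi / 4.0)
        better = np.abs(d) < np.abs(best_d) - 1e-15
        best_d = np.where(better, d, best_d)
        best_m = np.where(better, np.int8(m), best_m)
    phi = wrap_axial(coeffs.phi2 - (1.0 - coeffs.beta) * best_d)
    undefined = (coeffs.alpha2 == 0) & (coeffs.alpha4 == 0)
    phi = np.where(undefined, np.nan, phi)
    return phi, best_m


def estimate_rho(coeffs: FourierCoeffMap, phi: np.ndarray,
                 denom_tol: float = 1e-6) -> np.ndarray:
    """Closed-form effective anisotropy from the signed harmonic ratio.

    Projecting the complex harmonics at the known orientation gives the
    signed amplitudes a2 = Re(c1·e^(2iϕ)), a4 = Re(c2·e^(4iϕ)); with
    r = a4/a2 the coefficient equations invert to ρ = (4r−3)/(4r−1).
    Pixels with a2 ≈ 0 or |4r−1| ≤ ``denom_tol`` are NaN (singular).
    The branch is reported as the closed form returns it — no physical
    clipping, so estimator pathologies stay visible.
    """
    a2 = np.real(coeffs.c1 * np.exp(2j * phi))
    a4 = np.real(coeffs.c2 * np.exp(4j * phi))
    scale = np.maximum(coeffs.alpha0, 1.0)
    bad = ~np.isfinite(phi) | (np.abs(a2) <= 1e-12 * scale)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(bad, np.nan, a4 / np.where(bad, 1.0, a2))
        den = 4.0 * r - 1.0
        rho = np.where(np.abs(den) <= denom_tol, np.nan,
                       (4.0 * r - 3.0) / den)
    return rho


# ---------------------------------------------------------------------------
# Kleinman-relaxed per-pixel fit


def _nk_model_and_jac(theta, K, A, B, phi):
    """Model K[(A sin²u + B cos²u)² + sin²2u] and its Jacobian, batched.

    Shapes: parameters (P, 1), theta (N,) → model (P, N), jac (P, N, 4).
    """
    u = theta[None, :] - phi
    s2 = np.sin(u) ** 2
    c2 = np.cos(u) ** 2
    sin2u = np.sin(2.0 * u)
    sin4u = np.sin(4.0 * u)
    q = A * s2 + B * c2
    m = K * (q**2 + sin2u**2)
    dK = q**2 + sin2u**2
    dA = 2.0 * K * q * s2
    dB = 2.0 * K * q * c2
    dphi = -K * (2.0 * q * (A - B) * sin2u + 2.0 * sin4u)
    return m, np.stack([dK, dA, dB, dphi], axis=-1)


def kleinman_fit(stack: PolarizationStack, init: OrientationResult,
                 kleinman_limit: float = 1.1, max_iter: int = 200,
                 tol: float = 1e-10) -> OrientationResult:
    """Per-pixel least squares of the Kleinman-relaxed intensity model.

    Fits (K, A, B, ϕ) of I(θ) = K[(A sin²(θ−ϕ) + B cos²(θ−ϕ))² +
    sin²2(θ−ϕ)] by a batched Levenberg–Marquardt, initialized at A = 1,
    B = ρ̂, ϕ = ϕ̂ from the harmonic inversion.  A pixel is valid when the
    fit converged, the signal is modulated (ϕ identifiable), and the
    Kleinman condition |A| < ``kleinman_limit`` holds — the paper-style
    validity filter.  ρ is updated to B/A where defined.
    """
    theta = np.deg2rad(stack.angles_deg)
    coeffs = fourier_coefficients(stack)
    h, w = stack.shape
    I = stack.frames.reshape(-1, theta.size)

    phi0 = init.phi.reshape(-1).copy()
    rho0 = init.rho.reshape(-1).copy()
    alpha0 = coeffs.alpha0.reshape(-1)
    mod = np.sqrt(coeffs.alpha2**2 + 4.0 * coeffs.alpha4**2).reshape(-1)
    identifiable = np.isfinite(phi0) & (mod > 1e-6 * np.maximum(alpha0, 1.0))

    rho0 = np.where(np.isfinite(rho0), rho0, 1.5)
    rho0 = np.clip(rho0, -0.9, 2.95)
    a0_unit = coeffs_from_rho(rho0, 1.0).a0
    K0 = np.where(alpha0 > 0, alpha0 / a0_unit, 1.0)

    idx = np.flatnonzero(identifiable)
    p = np.stack([K0[idx], np.ones(idx.size), rho0[idx], phi0[idx]], axis=1)
    data = I[idx]
    lam = np.full(idx.size, 1e-3)
    converged = np.zeros(idx.size, dtype=bool)
    active = np.ones(idx.size, dtype=bool)

    def cost_of(params):
        m, _ = _nk_model_and_jac(theta, params[:, 0:1], params[:, 1:2],
                                 params[:, 2:3], params[:, 3:4])
        r = m - data
        return r, (r**2).sum(axis=1)

    _, cost = cost_of(p)
    for _ in range(max_iter):
        if not active.any():
            break
        ai = np.flatnonzero(active)
        pa = p[ai]
        m, J = _nk_model_and_jac(theta, pa[:, 0:1], pa[:, 1:2],
                                 pa[:, 2:3], pa[:, 3:4])
        r = m - data[ai]
        g = np.einsum("pnk,pn->pk", J, r)
        H = np.einsum("pnk,pnl->pkl", J, J)
        diag = np.maximum(np.einsum("pkk->pk", H), 1e-12)
        Hd = H + lam[ai, None, None] * diag[:, :, None] * np.eye(4)
        try:
            step = -np.linalg.solve(Hd, g[..., None])[..., 0]
        except np.linalg.LinAlgError:
            step = -np.linalg.solve(
                Hd + 1e-8 * np.eye(4), g[..., None])[..., 0]
        p_new = pa + step
        mn, _ = _nk_model_and_jac(theta, p_new[:, 0:1], p_new[:, 1:2],
                                  p_new[:, 2:3], p_new[:, 3:4])
        cost_new = ((mn - data[ai]) ** 2).sum(axis=1)
        improved = cost_new <= cost[ai]
        # relative residual change gate (guard the all-zero-cost pixel)
        denom = np.maximum(cost[ai], 1e-300)
        rel = np.abs(cost[ai] - cost_new) / denom
        done = improved & ((rel < tol) | (cost_new < 1e-300))
        p[ai[improved]] = p_new[improved]
        cost[ai[improved]] = cost_new[improved]
        lam[ai[improved]] = np.maximum(lam[ai[improved]] * 0.3, 1e-12)
        lam[ai[~improved]] = np.minimum(lam[ai[~improved]] * 10.0, 1e12)
        converged[ai[done]] = True
        active[ai[done]] = False
        # pixels whose damping exploded cannot improve further
        stuck = ~improved & (lam[ai] >= 1e12)
        active[ai[stuck]] = False

    n = h * w
    K_m = np.full(n, np.nan)
    A_m = np.full(n, np.nan)
    B_m = np.full(n, np.nan)
    phi_m = np.full(n, np.nan)
    ok = np.zeros(n, dtype=bool)
    K_m[idx], A_m[idx], B_m[idx] = p[:, 0], p[:, 1], p[:, 2]
    phi_m[idx] = wrap_axial(p[:, 3])
    ok[idx] = converged & (np.abs(A_m[idx]) < kleinman_limit)

    with np.errstate(invalid="ignore", divide="ignore"):
        rho_m = np.where(np.abs(A_m) > 1e-12, B_m / A_m, np.nan)
    return OrientationResult(
        phi=phi_m.reshape(h, w), rho=rho_m.reshape(h, w),
        valid=ok.reshape(h, w), m=init.m, A=A_m.reshape(h, w))


def validity_mask(stack: PolarizationStack, coeffs: FourierCoeffMap,
                  fit: OrientationResult | None = None,
                  intensity_floor: float = 2.0,
                  residual_ceiling: float = 0.3) -> np.ndarray:
    """Pixels with enough signal and a harmonic-law-shaped response.

    A pixel is valid when α0 ≥ ``intensity_floor``, the relative RMS
    residual of the two-harmonic reconstruction is ≤ ``residual_ceiling``
    (pure noise has no harmonic structure and fails this gate), and — when
    a Kleinman-relaxed fit is supplied — its own validity flag holds.
    """
    n = stack.n_angles
    k = np.arange(n)
    recon = (coeffs.alpha0[..., None]
             + np.real(coeffs.c1[..., None] * np.exp(2j * np.pi * k / n))
             + np.real(coeffs.c2[..., None] * np.exp(4j * np.pi * k / n)))
    resid = np.sqrt(np.mean((stack.frames - recon) ** 2, axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = np.where(coeffs.alpha0 > 0,
                       resid / np.where(coeffs.alpha0 > 0, coeffs.alpha0, 1.0),
                       np.inf)
    mask = (coeffs.alpha0 >= intensity_floor) & (rel <= residual_ceiling)
    if fit is not None:
        mask &= fit.valid
    return mask


def fit_orientation(stack: PolarizationStack, *, kleinman: bool = False,
                    kleinman_limit: float = 1.1,
                    intensity_floor: float = 2.0,
                    residual_ceiling: float = 0.3) -> OrientationResult:
    """Full harmonic inversion: ϕ, ρ and the validity mask in one call.

    With ``kleinman=True`` the per-pixel nonlinear fit refines (ϕ, ρ) and
    applies the |A| < ``kleinman_limit`` filter on top of the signal gates.
    """
    coeffs = fourier_coefficients(stack)
    phi, m = combine_phi(coeffs)
    rho = estimate_rho(coeffs, phi)
    res = OrientationResult(phi=phi, rho=rho,
                            valid=np.isfinite(phi), m=m)
    fit = None
    if kleinman:
        fit = kleinman_fit(stack, res, kleinman_limit=kleinman_limit)
        res = fit
    mask = validity_mask(stack, coeffs, fit=fit,
                         intensity_floor=intensity_floor,
                         residual_ceiling=residual_ceiling)
    res.valid = mask & np.isfinite(res.phi)
    return res
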