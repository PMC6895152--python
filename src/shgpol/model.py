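"""Forward physical model of polarization-resolved SHG from fibrillar collagen.

Collagen fibrils are treated as cylindrically symmetric (C∞) scatterers with
non-chiral second-order susceptibility components χ33, χ31, χ15.  For an
incident linear polarization at angle θ (measured from the laboratory Z axis,
counter-clockwise positive) and a fibril whose in-plane axis lies at angle ϕ,
the total SHG intensity follows a two-harmonic law

    I(θ) = a0 + a2·cos 2(θ−ϕ) + a4·cos 4(θ−ϕ)

whose coefficients are algebraic functions of the effective anisotropy
ρ = χ33/χ31 (tilted out of plane by δ, ρ = ρ0·cos²δ + 3·sin²δ) and an overall
scale K.  All angles are radians here; user-facing layers convert to degrees.

Everything in this module is a pure, vectorized function of its arguments;
the simulator renders through it and the estimators invert it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TensorParams",
    "HarmonicCoeffs",
    "intensity_components",
    "total_intensity",
    "nonkleinman_intensity",
    "coeffs_from_rho",
    "rho_from_tilt",
]


@dataclass(frozen=True)
class TensorParams:
    """Susceptibility-tensor description of one fibril population.

    Parameters
    ----------
    chi15:
        χ15 component (arbitrary units, > 0).
    A:
        Tensor ratio χ31/χ15; A = 1 under Kleinman symmetry.
    B:
        Effective ratio combining χ33/χ15 and the out-of-plane tilt.  B is
        stored as given: the pipeline never separates χ33/χ15 from δ.
    rho0:
        Anisotropy parameter χ33/χ31 at zero tilt.
    delta:
        Out-of-plane tilt in radians (0 = in the imaging plane).
    rho:
        Effective anisotropy of the tilted fibril.
    K:
        Overall intensity scale (counts), ≥ 0.
    """

    chi15: float = 1.0
    A: float = 1.0
    B: float | None = None
    rho0: float | None = None
    delta: float = 0.0
    rho: float | None = None
    K: float = 1.0

    def __post_init__(self) -> None:
        if self.chi15 <= 0:
            raise ValueError("chi15 must be > 0")
        if self.K < 0:
            raise ValueError("K must be >= 0")
        if self.rho is None and self.rho0 is not None:
            object.__setattr__(self, "rho", rho_from_tilt(self.rho0, self.delta))


@dataclass(frozen=True)
class HarmonicCoeffs:
    """Harmonic coefficients (a0, a2, a4) of the polarization response.

    a2 and a4 are signed; a0 ≥ |a2| + |a4| for any physical response since
    the intensity is nonnegative at every θ.
    """

    a0: float
    a2: float
    a4: float


def rho_from_tilt(rho0, delta):
    """Effective anisotropy of a fibril tilted out of plane by ``delta``.

    ρ = ρ0·cos²δ + 3·sin²δ; tilt drags the apparent anisotropy toward 3.
    """
    rho0 = np.asarray(rho0, dtype=float)
    delta = np.asarray(delta, dtype=float)
    out = rho0 * np.cos(delta) ** 2 + 3.0 * np.sin(delta) ** 2
    return out if out.ndim else float(out)


def intensity_components(theta, phi, params: TensorParams):
    """Z and Y intensity components for polarization angle ``theta``.

    IZ ∝ |χ15 cosδ [A sin²(θ−ϕ) + B cos²(θ−ϕ)]|²,
    IY ∝ |χ15 A cosδ sin 2(θ−ϕ)|².

    The sin 2(θ−ϕ) form on IY (degeneracy factor 2 relative to
    sinu·cosu) is the one consistent with the harmonic coefficients of
    :func:`coeffs_from_rho`: at A = 1, B = ρ the component sum equals
    :func:`total_intensity` with K = χ15²cos²δ.
    """
    if params.B is None:
        raise ValueError("TensorParams.B required for intensity_components")
    u = np.asarray(theta, dtype=float) - np.asarray(phi, dtype=float)
    cd = np.cos(params.delta)
    iz = (params.chi15 * cd) ** 2 * (
        params.A * np.sin(u) ** 2 + params.B * np.cos(u) ** 2
    ) ** 2
    iy = (params.chi15 * params.A * cd) ** 2 * np.sin(2.0 * u) ** 2
    return iz, iy


def nonkleinman_intensity(theta, phi, K, A, B):
    """Total SHG intensity for a fibril that may violate Kleinman symmetry.

    I(θ) = K[(A sin²(θ−ϕ) + B cos²(θ−ϕ))² + sin² 2(θ−ϕ)]

    This is the χ15-normalized total intensity: the sin²2u term carries no
    tensor ratio, so (K, |A|, B·sign(A)) is identifiable from a single
    polarization sweep — the property the Kleinman validity filter relies
    on.  At A = 1, B = ρ it coincides with :func:`total_intensity`.
    """
    u = np.asarray(theta, dtype=float) - np.asarray(phi, dtype=float)
    return np.asarray(K, dtype=float) * (
        (A * np.sin(u) ** 2 + B * np.cos(u) ** 2) ** 2 + np.sin(2.0 * u) ** 2
    )


def coeffs_from_rho(rho, K=1.0) -> HarmonicCoeffs:
    """Harmonic coefficients of the Kleinman (A=1) response at anisotropy ρ.

    a0 = K/2·[1 + ((ρ−1)/2)² + 2((ρ+1)/2)²]
    a2 = K·(ρ²−1)/2
    a4 = K/8·(ρ−3)(ρ+1)
    """
    rho = np.asarray(rho, dtype=float)
    K = np.asarray(K, dtype=float)
    a0 = K / 2.0 * (1.0 + ((rho - 1.0) / 2.0) ** 2 + 2.0 * ((rho + 1.0) / 2.0) ** 2)
    a2 = K * (rho**2 - 1.0) / 2.0
    a4 = K / 8.0 * (rho - 3.0) * (rho + 1.0)
    if a0.ndim == 0:
        return HarmonicCoeffs(float(a0), float(a2), float(a4))
    return HarmonicCoeffs(a0, a2, a4)


def total_intensity(theta, phi, rho, K=1.0):
    """Total SHG intensity I(θ) = a0 + a2 cos2(θ−ϕ) + a4 cos4(θ−ϕ).

    Vectorized over every argument (broadcasting).  Nonnegative for ρ in
    the physical range [−1, 3].
    """
    c = coeffs_from_rho(rho, K)
    u = np.asarray(theta, dtype=float) - np.asarray(phi, dtype=float)
    return c.a0 + c.a2 * np.cos(2.0 * u) + c.a4 * np.cos(4.0 * u)
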