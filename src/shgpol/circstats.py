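"""Axial (period-π) circular statistics for fibril-orientation maps.

Fibril orientation has no polarity: ϕ and ϕ+180° are the same physical
state, so the data are axial with period π.  Statistics therefore use the
standard angle-doubling device — work with ψ = 2ϕ on the full circle, then
halve the resulting mean and dispersion.  Without it, ±90° would spuriously
count as opposite directions.

Means and standard deviations are returned in degrees (reporting units);
input angles are radians, as produced by the orientation maps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "AxialSample",
    "PolarHistogram",
    "axial_circular_std",
    "axial_circular_mean",
    "polar_histogram",
]

#: Mean resultant lengths below this are treated as exactly zero
#: (uniform axial data: dispersion unbounded, mean undefined).
_R_EPS = 1e-12


@dataclass
class AxialSample:
    """Axial orientations (radians, wrapped to [−π/2, π/2)) with weights."""

    angles: np.ndarray
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        a = np.asarray(self.angles, dtype=float).ravel()
        a = a[np.isfinite(a)]
        if a.size == 0:
            raise ValueError("empty axial sample")
        self.angles = (a + np.pi / 2.0) % np.pi - np.pi / 2.0
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=float).ravel()
            if w.size != a.size:
                raise ValueError("weights must match angles")
            if np.any(w < 0):
                raise ValueError("weights must be nonnegative")
            self.weights = w


@dataclass
class PolarHistogram:
    """Centrosymmetric full-circle histogram of axial orientations."""

    bin_edges_deg: np.ndarray
    counts: np.ndarray


def _resultant(sample: AxialSample) -> tuple[float, float]:
    """Mean resultant length and argument of the doubled angles."""
    z = np.exp(2j * sample.angles)
    if sample.weights is None:
        m = z.mean()
    else:
        wsum = sample.weights.sum()
        if wsum <= 0:
            raise ValueError("weights sum to zero")
        m = (sample.weights * z).sum() / wsum
    return float(np.abs(m)), float(np.angle(m))


def axial_circular_std(sample: AxialSample) -> float:
    """Axial circular standard deviation in degrees.

    std = (1/2)·√(−2 ln R) with R the mean resultant length of the doubled
    angles.  R → 0 (e.g. half the mass at 0°, half at 90°) returns +inf:
    the dispersion of axially uniform data is unbounded.
    """
    r, _ = _resultant(sample)
    if r < _R_EPS:
        return float("inf")
    return float(np.degrees(0.5 * np.sqrt(-2.0 * np.log(min(r, 1.0)))))


def axial_circular_mean(sample: AxialSample) -> float:
    """Axial circular mean in degrees, wrapped to [−90, 90).

    Undefined (raises) when the resultant vanishes.
    """
    r, ang = _resultant(sample)
    if r < _R_EPS:
        raise ValueError("resultant is zero: axial mean undefined")
    mean_deg = np.degrees(ang / 2.0)
    return float((mean_deg + 90.0) % 180.0 - 90.0)


def polar_histogram(sample: AxialSample, bin_width_deg: float = 5.0
                    ) -> PolarHistogram:
    """Full-circle histogram with every orientation duplicated at +180°.

    The duplication makes the histogram exactly centrosymmetric
    (count(b) = count(b+180°)) and doubles the total count, mirroring how
    axial orientation data are displayed on polar plots.  ``bin_width_deg``
    must divide 180 so that the +180° copy lands a whole number of bins
    away (an odd bin count cannot be centrosymmetric).
    """
    nbins = 360.0 / bin_width_deg
    if abs(nbins - round(nbins)) > 1e-9 or abs(180.0 / bin_width_deg
                                               - round(180.0 / bin_width_deg)) > 1e-9:
        raise ValueError("bin width must divide 180 degrees")
    nbins = int(round(nbins))
    deg = np.degrees(sample.angles) % 360.0
    idx = np.floor(deg / bin_width_deg).astype(int) % nbins
    # the central-symmetry duplicate lands exactly nbins/2 bins away
    idx = np.concatenate([idx, (idx + nbins // 2) % nbins])
    counts = np.bincount(idx, minlength=nbins)
    edges = np.arange(nbins + 1) * bin_width_deg
    return PolarHistogram(bin_edges_deg=edges, counts=counts)
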