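"""Optical characterization statistics: axial profiles, attenuation, power law.

Axial resolution is measured by scanning a thin fluorescent layer through
focus: the per-plane two-photon signal is the background-subtracted sum of
pixel intensities within a circular ROI around the spot, and the reported
axial confinement is the FWHM of the resulting axial profile (linear
interpolation at half maximum).

Depth performance is summarized by the attenuation length ``l_e`` of the 2P
signal through overlying tissue, ``S = S0 * exp(-2 z / l_e)`` (the factor 2
reflects the quadratic dependence on the attenuated illumination), and
depths are compared across preparations after normalizing ``z / l_e``.

The quadratic character of the excitation itself is verified by the slope
of ``ln(Fl)`` against ``ln(P)``: a pure two-photon signal with constant
pulse width has slope 2; self-phase-modulation pulse broadening would bend
it below 2 at high power.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import tifffile

from .errors import DegenerateFitError, InvalidConfigurationError

__all__ = [
    "ZStack",
    "AxialProfile",
    "AttenuationFit",
    "PowerSeries",
    "axial_profile",
    "fwhm_of_profile",
    "fit_attenuation",
    "normalized_depth",
    "power_law_exponent",
]


@dataclass
class ZStack:
    """A z-stack of frames with a circular analysis ROI.

    ``frames`` is (n_z, ny, nx); ``z_positions`` in um, strictly monotone;
    ``roi`` is (center_y, center_x, radius) in pixels.
    """

    frames: np.ndarray
    z_positions: np.ndarray
    roi: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.z_positions = np.asarray(self.z_positions, dtype=float)
        dz = np.diff(self.z_positions)
        if not (np.all(dz > 0) or np.all(dz < 0)):
            raise InvalidConfigurationError("z_positions must be strictly monotone")
        if self.frames.shape[0] != self.z_positions.size:
            raise InvalidConfigurationError("frames and z_positions disagree")
        cy, cx, r = self.roi
        ny, nx = self.frames.shape[1:]
        if r <= 0 or cy - r < 0 or cx - r < 0 or cy + r > ny - 1 or cx + r > nx - 1:
            raise InvalidConfigurationError("roi must lie inside the frame")

    @classmethod
    def from_tiff(
        cls, path: str, z_positions: np.ndarray, roi: tuple[float, float, float]
    ) -> "ZStack":
        return cls(frames=tifffile.imread(path), z_positions=z_positions, roi=roi)

    def to_tiff(self, path: str) -> None:
        tifffile.imwrite(path, self.frames.astype(np.float32))


@dataclass
class AxialProfile:
    """Integrated ROI signal per plane."""

    z: np.ndarray  # um
    signal: np.ndarray
    fwhm: float | None = None  # um, filled by fwhm_of_profile


def axial_profile(stack: ZStack) -> AxialProfile:
    """Per-plane background-subtracted ROI-integrated intensity.

    The background is the median of the pixels outside the ROI of each
    plane, subtracted before summation.
    """
    cy, cx, r = stack.roi
    ny, nx = stack.frames.shape[1:]
    Y, X = np.ogrid[:ny, :nx]
    inside = (Y - cy) ** 2 + (X - cx) ** 2 <= r**2
    signal = np.empty(stack.frames.shape[0])
    for i, frame in enumerate(stack.frames):
        bg = np.median(frame[~inside]) if (~inside).any() else 0.0
        signal[i] = (frame[inside] - bg).sum()
    return AxialProfile(z=stack.z_positions.copy(), signal=signal)


def fwhm_of_profile(profile: AxialProfile) -> float:
    """FWHM (um) of an axial profile by linear interpolation at half maximum.

    The half level is ``baseline + (peak - baseline) / 2`` with the baseline
    the profile minimum; the peak must be interior (a monotone profile has
    no measurable width).
    """
    z = np.asarray(profile.z, dtype=float)
    s = np.asarray(profile.signal, dtype=float)
    if s.size < 3:
        raise DegenerateFitError("profile too short for a FWHM")
    ipk = int(np.argmax(s))
    if ipk == 0 or ipk == s.size - 1:
        raise DegenerateFitError("profile peak lies on the boundary (no interior peak)")
    baseline = float(s.min())
    half = baseline + (s[ipk] - baseline) / 2.0

    def cross(idx_range, reverse):
        rng = idx_range[::-1] if reverse else idx_range
        for i in rng:
            if s[i] <= half:
                j = i + 1 if reverse else i - 1
                # linear interpolation between i (below) and j (above)
                frac = (half - s[i]) / (s[j] - s[i])
                return z[i] + frac * (z[j] - z[i])
        raise DegenerateFitError("profile does not cross half maximum on both sides")

    left = cross(range(0, ipk), reverse=True)
    right = cross(range(ipk + 1, s.size), reverse=False)
    profile.fwhm = abs(right - left)
    return profile.fwhm


@dataclass
class AttenuationFit:
    """Exponential attenuation of 2P signal with overlying tissue thickness."""

    s0: float
    attenuation_length: float  # um; inf when non-attenuating
    depths: np.ndarray
    signals: np.ndarray
    attenuating: bool = True


def fit_attenuation(depths: np.ndarray, signals: np.ndarray) -> AttenuationFit:
    """Least-squares fit of ``S = S0 * exp(-2 z / l_e)`` on log signal.

    Non-positive signals are excluded with a warning; a non-negative slope
    is flagged as non-attenuating (``l_e = inf``).
    """
    z = np.asarray(depths, dtype=float)
    s = np.asarray(signals, dtype=float)
    good = s > 0
    if not good.all():
        warnings.warn(
            f"excluding {int((~good).sum())} non-positive signal(s) from the "
            "attenuation fit",
            stacklevel=2,
        )
    z, s = z[good], s[good]
    if np.unique(z).size < 2:
        raise DegenerateFitError("need >= 2 distinct thicknesses to fit attenuation")
    slope, intercept = np.polyfit(z, np.log(s), 1)
    if slope >= 0:
        return AttenuationFit(
            s0=float(np.exp(intercept)),
            attenuation_length=float("inf"),
            depths=z,
            signals=s,
            attenuating=False,
        )
    return AttenuationFit(
        s0=float(np.exp(intercept)),
        attenuation_length=float(-2.0 / slope),
        depths=z,
        signals=s,
    )


def normalized_depth(z: np.ndarray | float, attenuation_length: float):
    """Penetration depth in units of the attenuation length, ``z / l_e``."""
    if attenuation_length <= 0:
        raise InvalidConfigurationError("attenuation_length must be > 0")
    return np.asarray(z, dtype=float) / attenuation_length


@dataclass
class PowerSeries:
    """Fluorescence signal vs excitation power."""

    powers: np.ndarray  # mW
    signals: np.ndarray


def power_law_exponent(series: PowerSeries) -> float:
    """Slope of ``ln(Fl)`` vs ``ln(P)`` by least squares.

    2.0 for a pure two-photon signal with power-independent pulse width.
    Requires >= 3 power levels spanning more than a 2x range.
    """
    p = np.asarray(series.powers, dtype=float)
    s = np.asarray(series.signals, dtype=float)
    if np.any(p <= 0) or np.any(s <= 0):
        raise InvalidConfigurationError("powers and signals must be positive")
    if p.size < 3 or p.max() / p.min() <= 2.0:
        raise InvalidConfigurationError(
            "need >= 3 power levels spanning more than a 2x range"
        )
    slope, _ = np.polyfit(np.log(p), np.log(s), 1)
    return float(slope)
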