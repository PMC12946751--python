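"""Phase-mask synthesis for multiplexed two-photon photostimulation.

A liquid-crystal spatial light modulator (LC-SLM) in a Fourier plane of the
sample shapes the photostimulation beam.  The propagation model used
throughout is a single unitary discrete Fourier transform between the SLM
plane and the sample plane (ideal lens conjugation); the mapping from SLM
pixels to sample-plane micrometres is set by the addressable field size.

Three synthesis strategies are implemented:

* ``gerchberg_saxton`` — iterative projection phase retrieval for arbitrary
  target intensities (extended shapes).  Holographic extended spots carry
  speckle, quantified here as the standard deviation / mean of intensity
  within the target support.
* ``multiplexed_gaussian_spots`` — the phase of a coherent sum of tilted
  Gaussian beamlets, one prism per target position.  Reconstructed spots are
  smooth (speckle-free), which is why somata are targeted this way rather
  than with holographic disks.
* ``zernike_phase`` — Noll-indexed Zernike aberration-correction phases on
  the SLM pupil.

Position-dependent diffraction efficiency of the pixelated SLM is modeled
as a separable sinc^2 falloff of the deflection angle and compensated by
reweighting spots; extended shapes are power-normalized to a constant
excitation density (power per unit area).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidConfigurationError

__all__ = [
    "SLMSpec",
    "PropagationModel",
    "Spot",
    "TargetPattern",
    "PhaseMask",
    "ReconstructedField",
    "GSResult",
    "SpotMultiplex",
    "propagate",
    "backpropagate",
    "angular_spectrum_propagate",
    "gerchberg_saxton",
    "multiplexed_gaussian_spots",
    "diffraction_efficiency",
    "diffraction_efficiency_compensation",
    "shape_power_normalization",
    "zernike_phase",
    "zernike_noll",
    "speckle_contrast",
    "reconstruct",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))
TWO_PI = 2.0 * math.pi


@dataclass(frozen=True)
class SLMSpec:
    """Physical SLM panel: resolution (nx, ny), pixel size (um), wavelength (nm)."""

    resolution: tuple[int, int] = (1272, 1024)
    pixel_size: float = 12.5
    wavelength: float = 1030.0

    def __post_init__(self) -> None:
        if min(self.resolution) <= 0 or self.pixel_size <= 0 or self.wavelength <= 0:
            raise InvalidConfigurationError("SLM dimensions must be positive")


@dataclass(frozen=True)
class PropagationModel:
    """Discrete Fourier conjugation between SLM and sample planes.

    ``grid`` is the square computational grid (the SLM phase is addressed on
    it), ``field_um`` the addressable sample-plane field of view; one
    sample-plane pixel is ``field_um / grid``.
    """

    grid: int = 512
    field_um: float = 480.0

    @property
    def sample_pixel(self) -> float:
        return self.field_um / self.grid

    def coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Sample-plane coordinate arrays (um), centered."""
        c = (np.arange(self.grid) - self.grid / 2) * self.sample_pixel
        return np.meshgrid(c, c, indexing="ij")


@dataclass(frozen=True)
class Spot:
    """A Gaussian photostimulation spot at (x, y) um with 2P FWHM ``fwhm`` um."""

    x: float
    y: float
    fwhm: float = 10.0
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.fwhm <= 0 or self.weight <= 0:
            raise InvalidConfigurationError("fwhm and weight must be > 0")


@dataclass
class TargetPattern:
    """Photostimulation targets: Gaussian spots and/or binary shape masks."""

    spots: list[Spot] = field(default_factory=list)
    shapes: list[np.ndarray] = field(default_factory=list)
    shape_pitch_um: float = 1.0  # pixel pitch of the shape masks
    excitation_density: float | None = None  # mW / um^2


@dataclass
class PhaseMask:
    """SLM phase in radians, wrapped to [0, 2*pi)."""

    phase: np.ndarray

    def __post_init__(self) -> None:
        self.phase = np.mod(self.phase, TWO_PI)


@dataclass
class ReconstructedField:
    """Sample-plane intensity with per-target diagnostics."""

    intensity: np.ndarray
    per_target_power: np.ndarray | None = None
    speckle: np.ndarray | None = None


def propagate(field: np.ndarray) -> np.ndarray:
    """SLM plane -> sample plane: unitary centered 2D DFT."""
    return np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(field), norm="ortho"))


def backpropagate(field: np.ndarray) -> np.ndarray:
    """Sample plane -> SLM plane (inverse of :func:`propagate`)."""
    return np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(field), norm="ortho"))


def angular_spectrum_propagate(
    field: np.ndarray, dz: float, wavelength: float, pixel: float
) -> np.ndarray:
    """Free-space propagation by ``dz`` (m) via the angular-spectrum method.

    ``wavelength`` and ``pixel`` in meters; evanescent components are
    discarded.
    """
    n = field.shape[0]
    k = 2.0 * np.pi * np.fft.fftfreq(n, pixel)
    KX, KY = np.meshgrid(k, k, indexing="ij")
    kz2 = (2.0 * np.pi / wavelength) ** 2 - KX**2 - KY**2
    H = np.where(kz2 > 0, np.exp(1j * np.sqrt(np.maximum(kz2, 0.0)) * dz), 0.0)
    return np.fft.ifft2(np.fft.fft2(field) * H)


# ---------------------------------------------------------------------------
# Gerchberg-Saxton


@dataclass
class GSResult:
    mask: PhaseMask
    errors: np.ndarray  # RMS amplitude error per iteration
    n_iter: int = 0


def gerchberg_saxton(
    target_intensity: np.ndarray,
    model: PropagationModel | None = None,
    n_iter: int = 50,
    seed: int | None = 0,
    tol: float = 1e-4,
) -> GSResult:
    """Retrieve an SLM phase whose far-field intensity approximates a target.

    Alternating projections between the (uniform-amplitude) SLM constraint
    and the target-amplitude constraint; the RMS error between the achieved
    and target far-field amplitudes is non-increasing over iterations.
    Stops early when the relative error change drops below ``tol``.
    """
    target_intensity = np.asarray(target_intensity, dtype=float)
    if target_intensity.min() < 0:
        raise InvalidConfigurationError("target intensity must be non-negative")
    total = target_intensity.sum()
    if total == 0:
        raise InvalidConfigurationError("target intensity is identically zero")
    amp_target = np.sqrt(target_intensity / total)

    n = target_intensity.shape[0]
    rng = np.random.default_rng(seed)
    pupil_amp = np.full(target_intensity.shape, 1.0 / n)  # unit total power
    phase = rng.uniform(0.0, TWO_PI, size=target_intensity.shape)

    errors = []
    for it in range(n_iter):
        far = propagate(pupil_amp * np.exp(1j * phase))
        err = float(np.sqrt(np.mean((np.abs(far) - amp_target) ** 2)))
        errors.append(err)
        constrained = amp_target * np.exp(1j * np.angle(far))
        phase = np.angle(backpropagate(constrained))
        if it > 0 and errors[-2] > 0:
            if abs(errors[-2] - errors[-1]) / errors[-2] < tol:
                break
    return GSResult(mask=PhaseMask(phase), errors=np.array(errors), n_iter=len(errors))


# ---------------------------------------------------------------------------
# Multiplexed Gaussian spots


def _check_in_field(spots: list[Spot], model: PropagationModel) -> None:
    half = model.field_um / 2.0
    offenders = [
        (i, s.x, s.y)
        for i, s in enumerate(spots)
        if abs(s.x) >= half or abs(s.y) >= half
    ]
    if offenders:
        raise InvalidConfigurationError(
            "spots outside the addressable field "
            f"(+-{half:g} um): {offenders}"
        )


@dataclass
class SpotMultiplex:
    """Phase mask plus the matched incident Gaussian envelope on the SLM."""

    mask: PhaseMask
    incident: np.ndarray  # amplitude envelope on the SLM grid, unit power
    model: PropagationModel


def multiplexed_gaussian_spots(
    spots: list[Spot],
    model: PropagationModel | None = None,
    n_refine: int = 20,
    rel_tol: float = 0.05,
) -> SpotMultiplex:
    """Phase of the coherent sum of tilted Gaussian beamlets, one per spot.

    Each spot contributes a beamlet whose sample-plane field is a weighted
    Gaussian at the requested position; the SLM phase is the argument of the
    back-propagated sum.  Displayed on an incident Gaussian beam matched to
    the spot size, the reconstruction is a set of smooth (speckle-free)
    Gaussian spots.  All spots must share one FWHM: the incident beam fixes
    the beamlet envelope.

    Discarding the amplitude of the beamlet sum (the SLM is phase-only)
    compresses the dynamic range of unequal weights, so the beamlet weights
    are refined closed-loop (damped multiplicative updates, at most
    ``n_refine`` iterations) until the delivered per-spot powers match the
    requested ``weight**2`` within ``rel_tol``.  The loop stops as soon as
    the tolerance is met: near the tolerance the phase-only response to
    weight changes is steep and further feedback would amplify
    discretization noise.
    """
    model = model or PropagationModel()
    if not spots:
        raise InvalidConfigurationError("at least one spot is required")
    fwhms = {s.fwhm for s in spots}
    if max(fwhms) - min(fwhms) > 1e-9:
        raise InvalidConfigurationError(
            "multiplexed spots must share a single FWHM (one incident beam)"
        )
    _check_in_field(spots, model)
    X, Y = model.coords()
    # amplitude sigma: intensity FWHM = fwhm * sqrt(2) (illumination profile
    # of a 2P spot), amplitude falls as the square root of intensity
    sigma_i = spots[0].fwhm * math.sqrt(2.0) * _FWHM_TO_SIGMA
    beamlets = np.stack(
        [
            np.exp(-(((X - s.x) ** 2 + (Y - s.y) ** 2) / (4.0 * sigma_i**2)))
            for s in spots
        ]
    )
    centered = np.exp(-((X**2 + Y**2) / (4.0 * sigma_i**2)))
    incident = np.abs(backpropagate(centered.astype(complex)))
    incident /= np.sqrt((incident**2).sum())

    target = np.array([s.weight**2 for s in spots], dtype=float)
    target /= target.sum()
    w = np.sqrt(target)
    windows = [
        ((X - s.x) ** 2 + (Y - s.y) ** 2) <= (1.5 * s.fwhm) ** 2 for s in spots
    ]
    phase = None
    for _ in range(max(1, n_refine)):
        sample = np.tensordot(w, beamlets, axes=(0, 0))
        phase = np.angle(backpropagate(sample))
        if len(spots) == 1 or n_refine == 0:
            break
        intensity = np.abs(propagate(incident * np.exp(1j * phase))) ** 2
        got = np.array([intensity[win].sum() for win in windows])
        got /= got.sum()
        if np.max(np.abs(got / target - 1.0)) < rel_tol:
            break
        w = w * (target / np.maximum(got, 1e-12)) ** 0.25
        w /= np.linalg.norm(w)
    return SpotMultiplex(mask=PhaseMask(phase), incident=incident, model=model)


def reconstruct(
    mask: PhaseMask,
    incident: np.ndarray | None = None,
    model: PropagationModel | None = None,
    spots: list[Spot] | None = None,
) -> ReconstructedField:
    """Propagate ``incident * exp(i phase)`` to the sample plane.

    With ``spots`` given, integrates the delivered power within 1.5 FWHM of
    each spot and computes the per-spot speckle contrast (sigma/mean of
    intensity within the FWHM support).
    """
    model = model or PropagationModel()
    n = mask.phase.shape[0]
    if incident is None:
        incident = np.full(mask.phase.shape, 1.0 / n)
    out = propagate(incident * np.exp(1j * mask.phase))
    intensity = np.abs(out) ** 2
    per_power = speckle = None
    if spots:
        X, Y = model.coords()
        per_power = np.empty(len(spots))
        speckle = np.empty(len(spots))
        for i, s in enumerate(spots):
            r2 = (X - s.x) ** 2 + (Y - s.y) ** 2
            per_power[i] = intensity[r2 <= (1.5 * s.fwhm) ** 2].sum()
            speckle[i] = speckle_contrast(intensity, r2 <= (0.5 * s.fwhm) ** 2)
    return ReconstructedField(
        intensity=intensity, per_target_power=per_power, speckle=speckle
    )


def speckle_contrast(intensity: np.ndarray, support: np.ndarray) -> float:
    """sigma / mean of intensity within a boolean support mask."""
    vals = intensity[support]
    if vals.size == 0 or vals.mean() == 0:
        raise InvalidConfigurationError("empty or dark speckle support")
    return float(vals.std() / vals.mean())


# ---------------------------------------------------------------------------
# Diffraction efficiency and shape power


def diffraction_efficiency(
    x: np.ndarray | float, y: np.ndarray | float, model: PropagationModel | None = None
) -> np.ndarray:
    """Separable sinc^2 efficiency of a pixelated SLM vs deflection.

    The field edge (``+- field_um / 2``) corresponds to the Nyquist
    deflection of the SLM (two-pixel grating), where the per-axis efficiency
    is ``sinc^2(1/2) ~ 0.41``.
    """
    model = model or PropagationModel()
    u = np.asarray(x, dtype=float) / model.field_um
    v = np.asarray(y, dtype=float) / model.field_um
    return (np.sinc(u) ** 2) * (np.sinc(v) ** 2)


def diffraction_efficiency_compensation(
    spots: list[Spot],
    model: PropagationModel | None = None,
    floor: float = 0.1,
) -> np.ndarray:
    """Per-spot weights proportional to 1 / efficiency, center weight 1."""
    model = model or PropagationModel()
    _check_in_field(spots, model)
    eta = np.array([diffraction_efficiency(s.x, s.y, model) for s in spots])
    bad = [i for i, e in enumerate(eta) if e < floor]
    if bad:
        raise InvalidConfigurationError(
            f"spots {bad} sit where diffraction efficiency < {floor}: "
            f"{eta[bad].tolist()}"
        )
    return 1.0 / eta


def shape_power_normalization(
    shapes: list[np.ndarray],
    excitation_density: float,
    pitch_um: float = 1.0,
) -> np.ndarray:
    """Per-shape power (mW) giving every shape the same excitation density.

    ``power_i = density * area_i`` with the area counted from the binary
    mask at ``pitch_um`` sampling.
    """
    if excitation_density <= 0:
        raise InvalidConfigurationError("excitation_density must be > 0")
    powers = []
    for i, mask in enumerate(shapes):
        area = float(np.count_nonzero(mask)) * pitch_um**2
        if area == 0:
            raise InvalidConfigurationError(f"shape {i} is an empty mask")
        powers.append(excitation_density * area)
    return np.array(powers)


# ---------------------------------------------------------------------------
# Zernike aberration phases


def _noll_to_nm(j: int) -> tuple[int, int, bool]:
    """Noll index -> (n, |m|, is_cosine)."""
    if j < 1:
        raise InvalidConfigurationError("Noll index must be >= 1")
    n = int(math.sqrt(2 * j - 1) + 0.5) - 1
    if n % 2 == 0:
        m = 2 * int((2 * j + 1 - n * (n + 1)) // 4)
    else:
        m = 2 * int((2 * (j + 1) - n * (n + 1)) // 4) - 1
    return n, m, (j % 2 == 0)


def zernike_noll(j: int, rho: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Noll-normalized Zernike polynomial Z_j on (rho, theta), rho <= 1."""
    n, m, cosine = _noll_to_nm(j)
    R = np.zeros_like(rho)
    for k in range((n - m) // 2 + 1):
        c = (
            (-1) ** k
            * math.factorial(n - k)
            / (
                math.factorial(k)
                * math.factorial((n + m) // 2 - k)
                * math.factorial((n - m) // 2 - k)
            )
        )
        R += c * rho ** (n - 2 * k)
    if m == 0:
        return math.sqrt(n + 1.0) * R
    norm = math.sqrt(2.0 * (n + 1.0))
    ang = np.cos(m * theta) if cosine else np.sin(m * theta)
    return norm * R * ang


def zernike_phase(
    coefficients: dict[int, float],
    model: PropagationModel | None = None,
    pupil_radius: float | None = None,
) -> PhaseMask:
    """Sum of Noll-indexed Zernike phases (radians) on the SLM pupil.

    ``coefficients`` maps Noll index -> coefficient in radians RMS; the
    phase is zero outside the pupil and wrapped to [0, 2*pi).
    """
    model = model or PropagationModel()
    n = model.grid
    c = np.arange(n) - n / 2
    X, Y = np.meshgrid(c, c, indexing="ij")
    radius = pupil_radius if pupil_radius is not None else n / 2
    rho = np.sqrt(X**2 + Y**2) / radius
    theta = np.arctan2(Y, X)
    phase = np.zeros((n, n))
    inside = rho <= 1.0
    for j, cj in coefficients.items():
        if cj == 0.0:
            continue
        phase[inside] += cj * zernike_noll(int(j), rho[inside], theta[inside])
    return PhaseMask(phase)
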