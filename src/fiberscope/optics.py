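"""Design calculator for fiber-bundle two-photon endoscopes.

A fiber-bundle endoscope relays a scanned (or holographically shaped)
excitation beam through an imaging fiber of thousands of cores onto a distal
focal element (GRIN lens or miniaturized objective) of magnification ``M``.
Two closed-form quantities characterize a configuration:

* the maximum field of view, ``FOV_max = phi_fiber / M``, set by the bundle's
  quality-area diameter;
* the lateral resolution, the inter-core distance divided by ``M``, since the
  core lattice — not diffraction — samples the image.

The module also models how a focused spot distributes power over the core
lattice.  A spot is specified by the FWHM of its two-photon excitation
profile (``fwhm_2p``); the underlying Gaussian illumination profile is
``sqrt(2)`` wider because two-photon signal scales with intensity squared.
The number of illuminated cores is the illumination-FWHM square footprint
divided by the effective inter-core area, and the per-core power assumes 50%
of total beam power falls within the FWHM of a Gaussian.  Keeping per-core
power below the self-phase-modulation (SPM) threshold (~10 mW/core at
920 nm, 130 fs, 80 MHz) preserves the pulse width and hence the quadratic
power law of the two-photon signal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import yaml

from .errors import InvalidConfigurationError

__all__ = [
    "FiberBundleSpec",
    "FocalElementSpec",
    "EndoscopeConfiguration",
    "SpotSpec",
    "LaserSpec",
    "CoreIllumination",
    "SPMCheck",
    "compute_fov_max",
    "compute_lateral_resolution",
    "n_illuminated_cores",
    "power_per_core",
    "scanning_from_static_power",
    "snr_matched_power",
    "check_spm",
    "load_presets",
    "bundle_preset",
    "focal_element_preset",
    "laser_preset",
]


@dataclass(frozen=True)
class FiberBundleSpec:
    """An imaging fiber bundle.

    Parameters
    ----------
    quality_area_diameter : float
        Diameter of the usable core area, in mm.
    inter_core_distance : float
        Core lattice pitch, in um.
    length : float
        Bundle length, in m.
    bending_radius : float
        Minimum bending radius, in mm (flexibility figure of merit).
    """

    name: str
    quality_area_diameter: float
    n_cores: int
    inter_core_distance: float
    length: float = 1.0
    bending_radius: float = 5.0

    def __post_init__(self) -> None:
        if self.quality_area_diameter <= 0:
            raise InvalidConfigurationError("quality_area_diameter must be > 0")
        if self.n_cores <= 0:
            raise InvalidConfigurationError("n_cores must be > 0")
        if self.inter_core_distance <= 0:
            raise InvalidConfigurationError("inter_core_distance must be > 0")


@dataclass(frozen=True)
class FocalElementSpec:
    """Distal focal element (GRIN lens or mini-objective)."""

    name: str
    magnification: float
    working_distance: float = 0.0  # mm
    diameter: float = 0.0  # mm

    def __post_init__(self) -> None:
        if self.magnification <= 0:
            raise InvalidConfigurationError("magnification must be > 0")


def compute_fov_max(bundle: FiberBundleSpec, element: FocalElementSpec) -> float:
    """Maximum field of view in um, rounded to the nearest 10 um.

    ``FOV_max = phi_fiber / M``: the bundle quality-area diameter demagnified
    by the distal element.
    """
    fov_um = 1000.0 * bundle.quality_area_diameter / element.magnification
    return round(fov_um / 10.0) * 10.0


def compute_lateral_resolution(
    bundle: FiberBundleSpec, element: FocalElementSpec
) -> float:
    """Lateral resolution in um (inter-core distance / M), rounded to 0.1 um."""
    return round(bundle.inter_core_distance / element.magnification, 1)


@dataclass(frozen=True)
class EndoscopeConfiguration:
    """A bundle + focal element pair with its derived optical quantities."""

    bundle: FiberBundleSpec
    element: FocalElementSpec
    fov_max: float  # um
    lateral_resolution: float  # um
    effective_intercore: float  # um, unrounded inter-core distance / M
    field_curvature: float | None = None  # um, measured Df, optional

    @classmethod
    def from_specs(
        cls,
        bundle: FiberBundleSpec,
        element: FocalElementSpec,
        field_curvature: float | None = None,
    ) -> "EndoscopeConfiguration":
        return cls(
            bundle=bundle,
            element=element,
            fov_max=compute_fov_max(bundle, element),
            lateral_resolution=compute_lateral_resolution(bundle, element),
            effective_intercore=bundle.inter_core_distance / element.magnification,
            field_curvature=field_curvature,
        )


@dataclass(frozen=True)
class SpotSpec:
    """An excitation spot, sized by the FWHM of its two-photon profile (um).

    ``fwhm_gauss`` is the FWHM of the underlying Gaussian illumination
    intensity, wider by sqrt(2) because the two-photon signal is the square
    of the illumination intensity.
    """

    fwhm_2p: float
    fwhm_gauss: float = field(init=False)

    def __post_init__(self) -> None:
        if self.fwhm_2p <= 0:
            raise InvalidConfigurationError("fwhm_2p must be > 0")
        object.__setattr__(self, "fwhm_gauss", self.fwhm_2p * math.sqrt(2.0))


@dataclass(frozen=True)
class LaserSpec:
    """Excitation laser: wavelength (nm), pulse width (fs), rep rate (MHz)."""

    name: str
    wavelength: float
    pulse_width: float
    rep_rate: float
    max_power: float  # W
    spm_threshold: float | None = None  # mW/core; only meaningful per laser

    def __post_init__(self) -> None:
        for attr in ("wavelength", "pulse_width", "rep_rate", "max_power"):
            if getattr(self, attr) <= 0:
                raise InvalidConfigurationError(f"{attr} must be > 0")


def n_illuminated_cores(spot: SpotSpec, effective_intercore: float) -> int:
    """Number of cores covered by a spot.

    The footprint is the squared Gaussian illumination FWHM
    (= ``fwhm_2p * sqrt(2)``) divided by the squared effective inter-core
    distance at the sample plane, rounded to the nearest integer.
    """
    if effective_intercore <= 0:
        raise InvalidConfigurationError("effective_intercore must be > 0")
    return int(round(spot.fwhm_gauss**2 / effective_intercore**2))


def power_per_core(p_total: float, n_cores: int) -> float:
    """Average power per illuminated core, in mW.

    50% of a Gaussian beam's total power falls within its FWHM, shared
    equally over the illuminated cores.
    """
    if n_cores < 1:
        raise InvalidConfigurationError("n_cores must be >= 1 for a valid spot")
    if p_total < 0:
        raise InvalidConfigurationError("p_total must be >= 0")
    return 0.5 * p_total / n_cores


def scanning_from_static_power(
    p_static: float, transmission_fraction: float = 0.65
) -> float:
    """Average power delivered while scanning, from the static-spot power.

    The circular iris crop and the removal of mirror-turnaround dwell leave a
    measured ~65% of the static power on the sample; the fraction is a
    calibration constant of the scan engine, not a geometric ratio.
    """
    if not 0 < transmission_fraction <= 1:
        raise InvalidConfigurationError("transmission_fraction must be in (0, 1]")
    if p_static < 0:
        raise InvalidConfigurationError("p_static must be >= 0")
    return p_static * transmission_fraction


def snr_matched_power(p0: float, f0: float, fi: float) -> float:
    """Imaging power keeping the per-frame 2P signal constant across frame rates.

    The two-photon signal per frame scales as ``P^2 / f_frame``; holding it
    constant when moving from frame rate ``f0`` to ``fi`` requires
    ``P_i = P_0 * sqrt(f_i / f_0)``.
    """
    if f0 <= 0 or fi <= 0:
        raise InvalidConfigurationError("frame rates must be > 0")
    return p0 * math.sqrt(fi / f0)


@dataclass(frozen=True)
class SPMCheck:
    below: bool
    margin: float  # mW; threshold - p_core


def check_spm(p_core: float, threshold: float = 10.0) -> SPMCheck:
    """Whether a per-core power stays below the SPM pulse-broadening threshold."""
    if p_core < 0:
        raise InvalidConfigurationError("p_core must be >= 0")
    return SPMCheck(below=p_core < threshold, margin=threshold - p_core)


@dataclass(frozen=True)
class CoreIllumination:
    """Power distribution of a spot over the core lattice."""

    n_cores_illuminated: int
    power_per_core: float  # mW
    spm_threshold: float = 10.0  # mW/core
    below_spm: bool = field(init=False)

    def __post_init__(self) -> None:
        if self.power_per_core < 0:
            raise InvalidConfigurationError("power_per_core must be >= 0")
        object.__setattr__(
            self, "below_spm", self.power_per_core < self.spm_threshold
        )

    @classmethod
    def from_spot(
        cls,
        spot: SpotSpec,
        p_total: float,
        effective_intercore: float,
        spm_threshold: float = 10.0,
    ) -> "CoreIllumination":
        n = n_illuminated_cores(spot, effective_intercore)
        return cls(
            n_cores_illuminated=n,
            power_per_core=power_per_core(p_total, n),
            spm_threshold=spm_threshold,
        )


# ---------------------------------------------------------------------------
# Presets


def load_presets(path: str | None = None) -> dict:
    """Load bundle / focal-element / laser presets from YAML.

    Without ``path``, the presets shipped with the package (the three
    characterized bundles and both focal elements) are returned.
    """
    if path is None:
        text = (
            resources.files("fiberscope").joinpath("data/presets.yaml").read_text()
        )
    else:
        with open(path) as fh:
            text = fh.read()
    return yaml.safe_load(text)


def bundle_preset(name: str, presets: dict | None = None) -> FiberBundleSpec:
    presets = presets or load_presets()
    try:
        cfg = presets["bundles"][name]
    except KeyError as exc:
        raise InvalidConfigurationError(f"unknown bundle preset {name!r}") from exc
    return FiberBundleSpec(name=name, **cfg)


def focal_element_preset(name: str, presets: dict | None = None) -> FocalElementSpec:
    presets = presets or load_presets()
    try:
        cfg = presets["focal_elements"][name]
    except KeyError as exc:
        raise InvalidConfigurationError(
            f"unknown focal element preset {name!r}"
        ) from exc
    return FocalElementSpec(name=name, **cfg)


def laser_preset(name: str, presets: dict | None = None) -> LaserSpec:
    presets = presets or load_presets()
    try:
        cfg = presets["lasers"][name]
    except KeyError as exc:
        raise InvalidConfigurationError(f"unknown laser preset {name!r}") from exc
    return LaserSpec(name=name, **cfg)
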