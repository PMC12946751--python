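"""Green's-function simulation of tissue heating under a scanned 2P beam.

The tissue is modeled as a homogeneous, isotropic, infinite medium with
thermal diffusivity ``D = kappa / (rho c)``.  An instantaneous point deposit
of energy ``E`` at the origin produces, after a time ``t``, the temperature
rise

    dT(r, t) = E / (rho c) * (4 pi D t)^(-3/2) * exp(-r^2 / (4 D t)),

and because the heat equation is linear, the temperature under scanned
illumination is the superposition of such kernels over every past position
of the beam.  The beam raster-scans a circular field of view with a
triangular (constant-speed) waveform; light is absorbed along depth
following Beer-Lambert attenuation (absorption above the tissue surface is
not modeled), and each absorbed parcel of energy acts as a Gaussian-smeared
deposit matching the illumination spot profile.  The probed quantity is the
time-resolved temperature rise at the center of the field of view at the
imaging depth — the hottest point of the scanned volume — relative to the
steady-state brain temperature.

Default tissue constants are brain gray-matter values from the optogenetics
heating literature: conductivity 0.527 W/(m K), volumetric heat capacity
3.796e6 J/(m^3 K), and an absorption coefficient at 920 nm of 13 1/m
(0.13 1/cm, water-dominated).  Heat deposition is truncated at 1 mm depth,
beyond which the ballistic Beer-Lambert column is no longer a meaningful
description of light transport in scattering tissue.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidConfigurationError

__all__ = [
    "TissueThermalModel",
    "IlluminationProtocol",
    "ScanTrajectory",
    "AbsorbedProfile",
    "TemperatureTrace",
    "BRAIN_GRAY_MATTER",
    "greens_point_source",
    "build_scan_trajectory",
    "absorbed_power_density",
    "simulate_temperature_rise",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


@dataclass(frozen=True)
class TissueThermalModel:
    """Thermal and optical constants of the tissue.

    Parameters
    ----------
    thermal_diffusivity : float
        ``D`` in m^2/s.
    volumetric_heat_capacity : float
        ``rho c`` in J/(m^3 K).
    absorption_coefficient : float
        ``mu_a`` in 1/m at the illumination wavelength.
    scattering_length : float, optional
        ``l_s`` in m; required by the beam-propagation (scattering) mode.
    """

    thermal_diffusivity: float
    volumetric_heat_capacity: float
    absorption_coefficient: float
    scattering_length: float | None = None

    def __post_init__(self) -> None:
        for attr in ("thermal_diffusivity", "volumetric_heat_capacity"):
            if getattr(self, attr) <= 0:
                raise InvalidConfigurationError(f"{attr} must be > 0")
        if self.absorption_coefficient < 0:
            raise InvalidConfigurationError("absorption_coefficient must be >= 0")
        if self.scattering_length is not None and self.scattering_length <= 0:
            raise InvalidConfigurationError("scattering_length must be > 0")

    @classmethod
    def from_conductivity(
        cls,
        conductivity: float,
        volumetric_heat_capacity: float,
        absorption_coefficient: float,
        scattering_length: float | None = None,
    ) -> "TissueThermalModel":
        """Build from conductivity kappa (W/(m K)); D = kappa / (rho c)."""
        return cls(
            thermal_diffusivity=conductivity / volumetric_heat_capacity,
            volumetric_heat_capacity=volumetric_heat_capacity,
            absorption_coefficient=absorption_coefficient,
            scattering_length=scattering_length,
        )


#: Brain gray matter at 920 nm (kappa = 0.527 W/m/K, rho c = 3.796e6 J/m^3/K,
#: mu_a = 13 1/m water-dominated, l_s = 170 um).
BRAIN_GRAY_MATTER = TissueThermalModel.from_conductivity(
    conductivity=0.527,
    volumetric_heat_capacity=3.796e6,
    absorption_coefficient=13.0,
    scattering_length=170e-6,
)


@dataclass(frozen=True)
class IlluminationProtocol:
    """Scan parameters of an imaging acquisition.

    Lengths in um, power in mW, rates in Hz (user-facing units; the
    simulation converts to SI internally).
    """

    fov_diameter: float  # um
    frame_rate: float  # Hz
    spot_fwhm: float  # um, FWHM of the 2P profile
    scanning_power: float  # mW, average power delivered while scanning
    depth: float = 120.0  # um, probe depth below the surface
    n_frames: int = 16

    def __post_init__(self) -> None:
        if self.fov_diameter <= 0:
            raise InvalidConfigurationError("fov_diameter must be > 0")
        if self.frame_rate <= 0:
            raise InvalidConfigurationError("frame_rate must be > 0")
        if self.n_frames < 1:
            raise InvalidConfigurationError("n_frames must be >= 1")
        if self.scanning_power < 0:
            raise InvalidConfigurationError("scanning_power must be >= 0")


@dataclass
class ScanTrajectory:
    """Successive beam positions within one acquisition.

    ``positions`` are (x, y) in meters relative to the FOV center,
    ``dwell_times`` in seconds, ``frame_index`` the frame each sample
    belongs to, and ``times`` the absolute time of each sample.
    """

    positions: np.ndarray  # (n, 2) m
    dwell_times: np.ndarray  # (n,) s
    frame_index: np.ndarray  # (n,) int
    times: np.ndarray  # (n,) s


def greens_point_source(r: float, t_elapsed: float, tissue: TissueThermalModel) -> float:
    """Temperature rise per unit deposited energy (K/J) at distance r, time t.

    Free-space Green's function of the heat equation for an instantaneous
    point deposit in an infinite homogeneous medium.
    """
    if t_elapsed <= 0:
        raise InvalidConfigurationError("t_elapsed must be > 0")
    D = tissue.thermal_diffusivity
    rhoc = tissue.volumetric_heat_capacity
    return (1.0 / rhoc) * (4.0 * math.pi * D * t_elapsed) ** -1.5 * math.exp(
        -(r**2) / (4.0 * D * t_elapsed)
    )


def build_scan_trajectory(
    protocol: IlluminationProtocol,
    lines_per_frame: int = 100,
    samples_per_frame: int = 10_000,
) -> ScanTrajectory:
    """Triangular raster over the FOV bounding square, cropped to the circle.

    The scan runs at constant speed (triangular waveform on the fast axis,
    linear slow axis), matching an iris-cropped galvo scan; samples outside
    the inscribed circle are discarded, and the per-frame time budget
    ``1 / frame_rate`` is spread uniformly over the retained samples.
    """
    if lines_per_frame < 2:
        raise InvalidConfigurationError("lines_per_frame must be >= 2")
    if protocol.fov_diameter <= 0:
        raise InvalidConfigurationError("fov_diameter must be > 0")
    fov = protocol.fov_diameter * 1e-6
    s = (np.arange(samples_per_frame) + 0.5) / samples_per_frame
    line_pos = s * lines_per_frame
    line_idx = np.floor(line_pos).astype(int)
    frac = line_pos - line_idx
    tri = np.where(line_idx % 2 == 0, frac, 1.0 - frac)
    x = (tri - 0.5) * fov
    y = ((line_idx + 0.5) / lines_per_frame - 0.5) * fov
    keep = x**2 + y**2 <= (fov / 2.0) ** 2
    x, y = x[keep], y[keep]
    n = x.size
    if n == 0:
        raise InvalidConfigurationError("no scan samples retained inside the FOV")
    frame_period = 1.0 / protocol.frame_rate
    dwell = np.full(n * protocol.n_frames, frame_period / n)
    pos = np.tile(np.column_stack([x, y]), (protocol.n_frames, 1))
    frame_index = np.repeat(np.arange(protocol.n_frames), n)
    t_local = (np.arange(n) + 0.5) / n * frame_period
    times = (frame_index * frame_period) + np.tile(t_local, protocol.n_frames)
    return ScanTrajectory(
        positions=pos, dwell_times=dwell, frame_index=frame_index, times=times
    )


@dataclass
class AbsorbedProfile:
    """Depth discretization of the absorbed power.

    ``z`` are slab centroids (m, below the surface), ``weight`` the fraction
    of the incident beam power absorbed in each slab, ``sigma_z`` a Gaussian
    smearing matching the slab extent, and ``sigma_xy`` the transverse
    Gaussian sigma of the deposit at each depth.
    """

    z: np.ndarray
    weight: np.ndarray
    sigma_z: np.ndarray
    sigma_xy: np.ndarray
    ballistic: np.ndarray | None = None  # bpm mode: ballistic intensity vs z


def _slab_edges(z_max: float, n_slabs: int, depth: float) -> np.ndarray:
    """Slab edges refined around the probe depth, coarsening to z_max."""
    fine_top = min(2.5 * depth, z_max)
    n_fine = max(2, int(n_slabs * 0.55))
    edges = np.linspace(0.0, fine_top, n_fine + 1)
    if fine_top < z_max:
        coarse = np.geomspace(fine_top, z_max, n_slabs - n_fine + 1)[1:]
        edges = np.concatenate([edges, coarse])
    return edges


def absorbed_power_density(
    protocol: IlluminationProtocol,
    tissue: TissueThermalModel,
    mode: str = "beer-lambert",
    *,
    z_max: float = 1e-3,
    n_slabs: int = 24,
    seed: int | None = None,
    n_draws: int = 20,
    grid: int = 64,
    grid_extent: float = 160e-6,
    wavelength: float = 920e-9,
) -> AbsorbedProfile:
    """Depth profile of absorbed power for one beam position.

    ``beer-lambert`` (default, deterministic): Gaussian transverse profile
    attenuated as ``exp(-mu_a z)``; the transverse width is the illumination
    Gaussian of the spot at every depth.

    ``bpm``: forward-scattering beam propagation through random phase
    screens whose variance per step reproduces the ballistic attenuation
    ``exp(-z / l_s)``; the screens are unitary, so energy is conserved
    before absorption.  Returns ensemble-averaged per-slab absorption and
    transverse widths, plus the ballistic (coherent) intensity decay.
    """
    mu_a = tissue.absorption_coefficient
    # illumination (one-photon) Gaussian is sqrt(2) wider than the 2P FWHM
    sigma_spot = protocol.spot_fwhm * 1e-6 * math.sqrt(2.0) * _FWHM_TO_SIGMA
    edges = _slab_edges(z_max, n_slabs, protocol.depth * 1e-6)
    zc = 0.5 * (edges[:-1] + edges[1:])
    sigma_z = np.diff(edges) / math.sqrt(12.0)

    if mode == "beer-lambert":
        weight = np.exp(-mu_a * edges[:-1]) - np.exp(-mu_a * edges[1:])
        sigma_xy = np.full_like(zc, sigma_spot)
        return AbsorbedProfile(z=zc, weight=weight, sigma_z=sigma_z, sigma_xy=sigma_xy)

    if mode != "bpm":
        raise InvalidConfigurationError(f"unknown absorption mode {mode!r}")
    if tissue.scattering_length is None:
        raise InvalidConfigurationError("bpm mode requires tissue.scattering_length")

    rng = np.random.default_rng(seed)
    ls = tissue.scattering_length
    px = grid_extent / grid
    xs = (np.arange(grid) - grid / 2) * px
    X, Y = np.meshgrid(xs, xs, indexing="ij")
    field0 = np.exp(-(X**2 + Y**2) / (4.0 * sigma_spot**2))  # amplitude
    field0 /= np.sqrt((np.abs(field0) ** 2).sum())

    kx = 2.0 * np.pi * np.fft.fftfreq(grid, px)
    KX, KY = np.meshgrid(kx, kx, indexing="ij")
    k0 = 2.0 * np.pi / wavelength
    kz2 = k0**2 - KX**2 - KY**2
    dz_steps = np.diff(edges)
    sq = np.sqrt(np.maximum(kz2, 0.0))

    mean_I = np.zeros((len(zc), grid, grid))
    mean_field = np.zeros((len(zc), grid, grid), dtype=complex)
    weight = np.zeros(len(zc))
    for _ in range(n_draws):
        f = field0.astype(complex)
        power = 1.0
        for k, dz in enumerate(dz_steps):
            # unitary scattering screen: variance dz/ls -> ballistic e^{-dz/ls}
            sigma_phi = math.sqrt(dz / ls)
            phase = rng.standard_normal((grid, grid))
            # correlate over ~2 px to keep scattering forward-peaked
            phase = np.fft.ifft2(
                np.fft.fft2(phase) * np.exp(-0.5 * (KX**2 + KY**2) * (2 * px) ** 2)
            ).real
            phase *= sigma_phi / max(phase.std(), 1e-30)
            f = f * np.exp(1j * phase)
            H = np.exp(1j * sq * dz) * (kz2 > 0)
            f = np.fft.ifft2(np.fft.fft2(f) * H)
            absorbed = power * (1.0 - math.exp(-mu_a * dz))
            weight[k] += absorbed / n_draws
            power -= absorbed
            f *= math.exp(-0.5 * mu_a * dz)
            mean_I[k] += np.abs(f) ** 2 / n_draws
            mean_field[k] += f / n_draws
    # transverse width of the ensemble-average fluence per slab
    r2 = X**2 + Y**2
    tot = mean_I.sum(axis=(1, 2))
    sigma_xy = np.sqrt(
        (mean_I * r2).sum(axis=(1, 2)) / np.maximum(tot, 1e-300) / 2.0
    )
    ballistic = (np.abs(mean_field) ** 2).sum(axis=(1, 2))
    return AbsorbedProfile(
        z=zc, weight=weight, sigma_z=sigma_z, sigma_xy=sigma_xy, ballistic=ballistic
    )


@dataclass
class TemperatureTrace:
    """Temperature rise at the probe point over time."""

    times: np.ndarray  # s
    delta_t: np.ndarray  # K
    peak: float = field(init=False)
    equilibrated: bool = False
    frame_peaks: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.peak = float(self.delta_t.max()) if self.delta_t.size else 0.0


def simulate_temperature_rise(
    protocol: IlluminationProtocol,
    tissue: TissueThermalModel = BRAIN_GRAY_MATTER,
    *,
    lines_per_frame: int = 100,
    samples_per_frame: int = 10_000,
    times_per_frame: int = 10,
    mode: str = "beer-lambert",
    seed: int | None = None,
    z_max: float = 1e-3,
    n_slabs: int = 24,
    equilibrium_tol: float = 0.01,
) -> TemperatureTrace:
    """Temperature rise at the FOV center, ``protocol.depth`` below the surface.

    Superposes the anisotropic Gaussian heat kernels of every past deposit
    along the scan trajectory: a deposit with initial variances
    ``(sigma_xy^2, sigma_xy^2, sigma_z^2)`` evaluated at age ``tau`` has
    variance ``sigma_d^2 + 2 D tau`` along each axis.  The ``equilibrated``
    flag is set when the per-frame peak grows by less than
    ``equilibrium_tol`` (relative) between the last two frames.
    """
    traj = build_scan_trajectory(protocol, lines_per_frame, samples_per_frame)
    profile = absorbed_power_density(
        protocol, tissue, mode, z_max=z_max, n_slabs=n_slabs, seed=seed
    )
    D = tissue.thermal_diffusivity
    rhoc = tissue.volumetric_heat_capacity
    power = protocol.scanning_power * 1e-3  # W
    frame_period = 1.0 / protocol.frame_rate
    n_out = protocol.n_frames * times_per_frame
    t_out = (np.arange(n_out) + 1.0) / times_per_frame * frame_period

    if power == 0.0:
        trace = TemperatureTrace(times=t_out, delta_t=np.zeros(n_out))
        trace.equilibrated = True
        trace.frame_peaks = np.zeros(protocol.n_frames)
        return trace

    energy = power * traj.dwell_times  # J per deposit (before absorption split)
    rho2 = traj.positions[:, 0] ** 2 + traj.positions[:, 1] ** 2
    dz2 = (profile.z - protocol.depth * 1e-6) ** 2  # (K,)
    w = profile.weight
    sz2 = profile.sigma_z**2
    sxy2 = profile.sigma_xy**2

    delta_t = np.zeros(n_out)
    for j, t in enumerate(t_out):
        age = t - traj.times
        m = age > 0
        if not m.any():
            continue
        tau = age[m][:, None]  # (n, 1)
        vxy = sxy2[None, :] + 2.0 * D * tau
        vz = sz2[None, :] + 2.0 * D * tau
        g = (
            w[None, :]
            * np.exp(-rho2[m][:, None] / (2.0 * vxy) - dz2[None, :] / (2.0 * vz))
            / (2.0 * np.pi * vxy * np.sqrt(2.0 * np.pi * vz))
        )
        delta_t[j] = (energy[m][:, None] * g).sum() / rhoc

    trace = TemperatureTrace(times=t_out, delta_t=delta_t)
    frame_peaks = delta_t.reshape(protocol.n_frames, times_per_frame).max(axis=1)
    trace.frame_peaks = frame_peaks
    if protocol.n_frames >= 2 and frame_peaks[-1] > 0:
        rel = (frame_peaks[-1] - frame_peaks[-2]) / frame_peaks[-1]
        trace.equilibrated = bool(rel < equilibrium_tol)
    else:
        trace.equilibrated = False
    return trace
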