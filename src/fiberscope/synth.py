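"""Synthetic-data generators with exported ground truth.

Every input the analysis modules consume can be generated here with known
hidden parameters, so each statistic has an end-to-end recovery test:

* fiber-bundle-sampled fluorescence images — a hexagonal core lattice
  inside a circular aperture, per-core transmission drawn with a
  configurable coefficient of variation (near zero for leached-style
  bundles with homogeneous cores, larger for stochastically inhomogeneous
  ones).  Two-photon excitation makes the imaged signal scale with the
  squared transmission, so a transmission CV of ``c`` appears as a
  core-to-core intensity CV of about ``2 c``.
* slow-indicator calcium traces with photostimulation-evoked responses —
  targeted cells respond to each pulse train; non-targeted cells respond as
  Bernoulli draws with probability ``p0 * exp(-d / k_true)`` of the
  distance to the nearest spot, emulating off-target dendritic excitation.
  The camera gating of the paradigm (200 ms ON / 50 ms OFF) is modeled by
  the 4 Hz frame clock: frames fall in the ON periods only.
* thin-fluorescent-layer z-stacks with a known axial FWHM and a quadratic
  field-curvature shift of the focal plane toward the FOV edge.
* home-cage random-walk trajectories with speeds drawn from a known
  distribution (held constant within 200 ms blocks) and wall reflection.

All generators are deterministic given (parameters, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .behavior import Trajectory
from .characterization import ZStack
from .errors import InvalidConfigurationError
from .stim import StimSchedule, TraceSet, distance_to_nearest_spot

__all__ = [
    "BundleModel",
    "SceneModel",
    "SyntheticGroundTruth",
    "BundleImage",
    "CalciumExperiment",
    "hex_lattice",
    "generate_bundle_image",
    "make_schedule",
    "generate_calcium_movie",
    "generate_activation_outcomes",
    "generate_zstack",
    "generate_trajectory",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


@dataclass
class SyntheticGroundTruth:
    """Hidden parameters a generator used, for recovery testing."""

    seed: int | None = None
    responders: np.ndarray | None = None
    k_true: float | None = None
    axial_fwhm: float | None = None
    field_curvature: float | None = None
    speed_distribution: str | None = None
    amplitude: float | None = None


# ---------------------------------------------------------------------------
# Fiber-bundle images


@dataclass(frozen=True)
class BundleModel:
    """Core lattice of a fiber bundle: hexagonal, inside a circular aperture.

    ``inhomogeneity_cv`` is the coefficient of variation of the per-core
    transmission (~0 for leached bundles with constant cores, larger for
    bundles manufactured with stochastic core inhomogeneity).
    """

    n_cores: int = 18000
    inter_core: float = 11.6  # um
    inhomogeneity_cv: float = 0.0

    def __post_init__(self) -> None:
        if self.n_cores <= 0 or self.inter_core <= 0:
            raise InvalidConfigurationError("n_cores and inter_core must be > 0")
        if self.inhomogeneity_cv < 0:
            raise InvalidConfigurationError("inhomogeneity_cv must be >= 0")

    @property
    def aperture_radius(self) -> float:
        """Radius (um) of the circle holding ``n_cores`` at the lattice density."""
        area_per_core = math.sqrt(3.0) / 2.0 * self.inter_core**2
        return math.sqrt(self.n_cores * area_per_core / math.pi)


def hex_lattice(radius: float, pitch: float) -> np.ndarray:
    """(n, 2) hexagonal lattice points within a circle of ``radius``."""
    dy = pitch * math.sqrt(3.0) / 2.0
    n_rows = int(radius / dy) + 1
    pts = []
    for row in range(-n_rows, n_rows + 1):
        y = row * dy
        x_off = (row % 2) * pitch / 2.0
        n_cols = int(radius / pitch) + 1
        for col in range(-n_cols, n_cols + 1):
            x = col * pitch + x_off
            if x * x + y * y <= radius * radius:
                pts.append((x, y))
    return np.array(pts)


@dataclass
class BundleImage:
    """Rendered bundle-sampled image plus its per-core quantities."""

    image: np.ndarray | None
    core_positions: np.ndarray  # (n, 2) um
    core_signals: np.ndarray  # imaged (2P) signal per core
    transmissions: np.ndarray
    um_per_px: float


def generate_bundle_image(
    bundle: BundleModel,
    scene: Callable[[np.ndarray, np.ndarray], np.ndarray] | None = None,
    seed: int | None = 0,
    um_per_px: float = 4.0,
    background: float = 0.0,
    render: bool = True,
) -> BundleImage:
    """Sample a scene through the core lattice and render the bundle image.

    The scene intensity is evaluated at each core position and scaled by
    the squared per-core transmission (two-photon excitation); cores are
    rendered as Gaussian spots of sigma = pitch / 3.  Deterministic per
    seed.
    """
    rng = np.random.default_rng(seed)
    cores = hex_lattice(bundle.aperture_radius, bundle.inter_core)
    cv = bundle.inhomogeneity_cv
    if cv > 0:
        sigma_ln = math.sqrt(math.log(1.0 + cv**2))
        trans = rng.lognormal(mean=-0.5 * sigma_ln**2, sigma=sigma_ln, size=len(cores))
    else:
        trans = np.ones(len(cores))
    if scene is None:
        intensity = np.ones(len(cores))
    else:
        intensity = np.asarray(scene(cores[:, 0], cores[:, 1]), dtype=float)
    signals = intensity * trans**2

    if not render:
        return BundleImage(
            image=None,
            core_positions=cores,
            core_signals=signals,
            transmissions=trans,
            um_per_px=um_per_px,
        )
    half = bundle.aperture_radius
    n_px = int(2 * half / um_per_px) + 1
    img = np.full((n_px, n_px), float(background))
    sigma_px = bundle.inter_core / 3.0 / um_per_px
    cx = (cores[:, 0] + half) / um_per_px
    cy = (cores[:, 1] + half) / um_per_px
    span = max(1, int(3 * sigma_px))
    for (px, py, s) in zip(cx, cy, signals):
        ix, iy = int(px), int(py)
        sl_y = slice(max(iy - span, 0), min(iy + span + 1, n_px))
        sl_x = slice(max(ix - span, 0), min(ix + span + 1, n_px))
        yy = np.arange(sl_y.start, sl_y.stop)[:, None]
        xx = np.arange(sl_x.start, sl_x.stop)[None, :]
        img[sl_y, sl_x] += s * np.exp(
            -((yy - py) ** 2 + (xx - px) ** 2) / (2.0 * sigma_px**2)
        )
    return BundleImage(
        image=img,
        core_positions=cores,
        core_signals=signals,
        transmissions=trans,
        um_per_px=um_per_px,
    )


# ---------------------------------------------------------------------------
# Calcium traces with photostimulation


@dataclass
class SceneModel:
    """Cells and signal/noise model for synthetic calcium data.

    ``crosstalk_slope`` adds a slow activation ramp at acquisition onset
    proportional to the imaging power above ``crosstalk_threshold``
    (emulating opsin cross-activation by the imaging laser); it is zero at
    or below the threshold.
    """

    cell_positions: np.ndarray  # (n, 2) um
    rise_time: float = 0.5  # s, indicator rise
    decay_time: float = 1.5  # s, indicator decay
    noise_sd: float = 0.05  # dF/F additive noise per frame
    amplitude: float = 0.5  # dF/F peak of an evoked transient
    spontaneous_rate: float = 0.0  # events / s / cell
    crosstalk_slope: float = 0.0  # dF/F per mW above threshold
    crosstalk_threshold: float = 97.5  # mW
    imaging_power: float = 65.0  # mW

    def __post_init__(self) -> None:
        self.cell_positions = np.atleast_2d(
            np.asarray(self.cell_positions, dtype=float)
        )
        if self.rise_time <= 0 or self.decay_time <= 0:
            raise InvalidConfigurationError("kinetic times must be > 0")


def make_schedule(
    targeted_cells: np.ndarray,
    spot_positions: np.ndarray,
    n_repetitions: int = 4,
    first_onset: float = 10.0,
    interval: float = 30.0,
) -> StimSchedule:
    """Standard four-repetition paradigm with the default pulse/gating timing."""
    onsets = first_onset + interval * np.arange(n_repetitions)
    return StimSchedule(
        repetition_onsets=onsets,
        targeted_cells=np.asarray(targeted_cells, dtype=int),
        spot_positions=spot_positions,
    )


def _transient_kernel(t: np.ndarray, rise: float, decay: float) -> np.ndarray:
    """Difference-of-exponentials transient, unit peak, zero for t < 0."""
    k = (1.0 - np.exp(-np.maximum(t, 0.0) / rise)) * np.exp(
        -np.maximum(t, 0.0) / decay
    )
    t_pk = rise * math.log(1.0 + decay / rise)
    pk = (1.0 - math.exp(-t_pk / rise)) * math.exp(-t_pk / decay)
    return np.where(t >= 0.0, k / pk, 0.0)


@dataclass
class CalciumExperiment:
    """Synthetic photostimulation acquisition."""

    traces: TraceSet
    schedule: StimSchedule
    truth: SyntheticGroundTruth
    movie: np.ndarray | None = None


def generate_calcium_movie(
    scene: SceneModel,
    schedule: StimSchedule,
    k_true: float = 18.4,
    p0: float = 1.0,
    seed: int | None = 0,
    tail: float = 10.0,
) -> CalciumExperiment:
    """Generate dF/F traces for a photostimulation paradigm.

    Targeted cells respond to every pulse train with the scene amplitude;
    non-targeted cells are responders with probability
    ``p0 * exp(-d / k_true)`` where ``d`` is their distance to the nearest
    photostimulation spot (the draw is made once per cell and exported as
    ground truth).  Frames run at the camera-gated 4 Hz clock, centered in
    the camera-ON periods.
    """
    if k_true <= 0:
        raise InvalidConfigurationError("k_true must be > 0")
    rng = np.random.default_rng(seed)
    n_cells = scene.cell_positions.shape[0]
    duration = schedule.repetition_onsets[-1] + schedule.train_duration + tail
    period = schedule.camera_on + schedule.camera_off
    n_frames = int(duration / period)
    frame_times = np.arange(n_frames) * period + schedule.camera_on / 2.0

    d = distance_to_nearest_spot(scene.cell_positions, schedule.spot_positions)
    targeted = np.zeros(n_cells, dtype=bool)
    targeted[schedule.targeted_cells] = True
    p_resp = np.where(targeted, 1.0, p0 * np.exp(-d / k_true))
    responders = rng.uniform(size=n_cells) < p_resp

    dff = rng.normal(0.0, scene.noise_sd, size=(n_cells, n_frames))
    # evoked transients start at the train onset and build over the train
    for onset in schedule.repetition_onsets:
        kern = _transient_kernel(
            frame_times - onset - schedule.fifth_pulse_offset / 2.0,
            scene.rise_time + schedule.fifth_pulse_offset / 2.0,
            scene.decay_time,
        )
        dff[responders] += scene.amplitude * kern
    # spontaneous activity
    if scene.spontaneous_rate > 0:
        lam = scene.spontaneous_rate * duration
        for i in range(n_cells):
            for t_ev in rng.uniform(0.0, duration, size=rng.poisson(lam)):
                dff[i] += scene.amplitude * _transient_kernel(
                    frame_times - t_ev, scene.rise_time, scene.decay_time
                )
    # imaging-laser crosstalk ramp at acquisition onset
    excess = max(0.0, scene.imaging_power - scene.crosstalk_threshold)
    if scene.crosstalk_slope > 0 and excess > 0:
        dff += scene.crosstalk_slope * excess * (1.0 - np.exp(-frame_times / 5.0))

    snr = np.where(
        responders, scene.amplitude / max(scene.noise_sd, 1e-12), 1.0
    )
    traces = TraceSet(
        dff=dff,
        frame_times=frame_times,
        cell_positions=scene.cell_positions,
        snr=snr,
    )
    truth = SyntheticGroundTruth(
        seed=seed,
        responders=responders,
        k_true=k_true,
        amplitude=scene.amplitude,
    )
    return CalciumExperiment(traces=traces, schedule=schedule, truth=truth)


def generate_activation_outcomes(
    n_cells: int = 2000,
    k_true: float = 18.4,
    p0: float = 1.0,
    d_max: float = 100.0,
    seed: int | None = 0,
) -> tuple[np.ndarray, np.ndarray, SyntheticGroundTruth]:
    """Bernoulli off-target activation outcomes vs distance.

    Cells sit at uniform random distances in [0, d_max] um from their
    nearest spot and respond with probability ``p0 * exp(-d / k_true)``.
    Returns (distances, responded, truth).
    """
    if k_true <= 0:
        raise InvalidConfigurationError("k_true must be > 0")
    rng = np.random.default_rng(seed)
    d = rng.uniform(0.0, d_max, size=n_cells)
    responded = rng.uniform(size=n_cells) < p0 * np.exp(-d / k_true)
    return d, responded, SyntheticGroundTruth(seed=seed, k_true=k_true)


# ---------------------------------------------------------------------------
# Thin-layer z-stacks


def generate_zstack(
    fwhm_true: float = 9.0,
    field_curvature: float = 0.0,
    seed: int | None = 0,
    z_range: tuple[float, float] = (-15.0, 15.0),
    dz: float = 0.5,
    spot_positions: tuple[tuple[float, float], ...] = ((0.0, 0.0),),
    spot_fwhm: float = 10.0,
    fov_radius: float = 240.0,
    um_per_px: float = 2.0,
    photon_scale: float = 200.0,
    background: float = 2.0,
    noise: bool = True,
) -> tuple[ZStack, SyntheticGroundTruth]:
    """Z-stack of static spots exciting a thin fluorescent layer.

    Each spot (positions in um from the FOV center) produces a Gaussian
    transverse profile whose integrated signal follows a Gaussian axial
    response of FWHM ``fwhm_true``; the best-focus plane of a spot shifts
    quadratically with its radial position, reaching ``field_curvature`` at
    the FOV edge (``fov_radius``).  Poisson-like photon noise on top of a
    flat background is applied when ``noise`` is true.  The stack's ROI is
    a disk around the first spot.
    """
    if fwhm_true <= 0:
        raise InvalidConfigurationError("fwhm_true must be > 0")
    rng = np.random.default_rng(seed)
    zs = np.arange(z_range[0], z_range[1] + dz / 2.0, dz)
    sigma_z = fwhm_true * _FWHM_TO_SIGMA
    sigma_xy = spot_fwhm * _FWHM_TO_SIGMA  # transverse 2P profile of the spot
    half = fov_radius + 4.0 * sigma_xy
    n_px = int(2 * half / um_per_px) + 1
    Y, X = np.mgrid[:n_px, :n_px]
    xs = X * um_per_px - half
    ys = Y * um_per_px - half
    ideal = np.full((zs.size, n_px, n_px), float(background))
    for (sx, sy) in spot_positions:
        z_pk = field_curvature * (sx**2 + sy**2) / fov_radius**2
        transverse = np.exp(
            -(((xs - sx) ** 2 + (ys - sy) ** 2) / (2.0 * sigma_xy**2))
        )
        axial = photon_scale * np.exp(-((zs - z_pk) ** 2) / (2.0 * sigma_z**2))
        ideal += axial[:, None, None] * transverse[None, :, :]
    frames = rng.poisson(ideal).astype(float) if noise else ideal
    cx0 = (spot_positions[0][0] + half) / um_per_px
    cy0 = (spot_positions[0][1] + half) / um_per_px
    roi = (cy0, cx0, 2.0 * spot_fwhm / um_per_px)
    stack = ZStack(frames=frames, z_positions=zs, roi=roi)
    truth = SyntheticGroundTruth(
        seed=seed, axial_fwhm=fwhm_true, field_curvature=field_curvature
    )
    return stack, truth


# ---------------------------------------------------------------------------
# Trajectories


def generate_trajectory(
    speed_sampler: Callable[[np.random.Generator, int], np.ndarray],
    cage: tuple[float, float] = (37.0, 21.0),
    duration: float = 60.0,
    fps: float = 30.0,
    seed: int | None = 0,
    block: float = 0.2,
    turn_sd: float = 0.6,
) -> tuple[Trajectory, SyntheticGroundTruth]:
    """Random walk with speeds from ``speed_sampler`` and wall reflection.

    The speed is held constant within ``block``-second blocks (matching the
    smoothing window of the speed analysis); the heading diffuses with
    per-frame standard deviation ``turn_sd`` radians.
    """
    rng = np.random.default_rng(seed)
    n = int(duration * fps)
    frames_per_block = max(1, int(round(block * fps)))
    n_blocks = -(-n // frames_per_block)
    speeds = np.repeat(speed_sampler(rng, n_blocks), frames_per_block)[:n]
    heading = np.cumsum(rng.normal(0.0, turn_sd, size=n))
    w, h = cage
    pos = np.empty((n, 2))
    pos[0] = (w / 2.0, h / 2.0)
    step = speeds / fps
    for i in range(1, n):
        x = pos[i - 1, 0] + step[i] * math.cos(heading[i])
        y = pos[i - 1, 1] + step[i] * math.sin(heading[i])
        # reflect at the walls (fold back, preserving step length)
        if x < 0:
            x = -x
        elif x > w:
            x = 2 * w - x
        if y < 0:
            y = -y
        elif y > h:
            y = 2 * h - y
        pos[i] = (min(max(x, 0.0), w), min(max(y, 0.0), h))
    traj = Trajectory(
        times=np.arange(n) / fps, positions=pos, fps=fps, cage=cage
    )
    truth = SyntheticGroundTruth(seed=seed, speed_distribution="sampler")
    return traj, truth
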