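"""Photostimulation-response statistics for dF/F trace sets.

An all-optical experiment repeats a photostimulation paradigm (a train of
10 pulses of 20 ms at 4 Hz, interleaved with the camera gating: 200 ms ON,
50 ms OFF) four times during one acquisition.  Analysis proceeds on the
repetition-averaged dF/F trace of each cell:

* baseline = mean over the 2 s before the train onset;
* response = mean over the 2 s after the 5th pulse (the middle of the
  photostimulation period);
* a cell responds when ``response - baseline > 3 * sd(baseline window)``.

Cells are cross-tabulated into targeted/responding classes (T/R, T/nR,
nT/R, nT/nR).  Off-target activation is quantified by binning the
probability of responding against the distance to the nearest
photostimulation spot and fitting a single exponential decay
``A * exp(-x / k)``; ``k`` is the characteristic off-target decay distance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import DegenerateFitError, InvalidConfigurationError

__all__ = [
    "TraceSet",
    "StimSchedule",
    "ResponseResult",
    "DecayFit",
    "DisplacementRecord",
    "average_over_repetitions",
    "classify_responses",
    "distance_to_nearest_spot",
    "activation_probability_fit",
    "count_components_above_snr",
    "mean_frame_displacement",
]

LABELS = ("T/R", "T/nR", "nT/R", "nT/nR")


@dataclass
class TraceSet:
    """Per-cell dF/F traces with cell positions.

    ``dff`` is (n_cells, n_frames); ``frame_times`` in s, strictly
    increasing; ``cell_positions`` (n_cells, 2) in um; ``snr`` optional
    per-cell signal-to-noise values (externally computed or synthetic).
    """

    dff: np.ndarray
    frame_times: np.ndarray
    cell_positions: np.ndarray
    snr: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dff = np.asarray(self.dff, dtype=float)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        self.cell_positions = np.asarray(self.cell_positions, dtype=float)
        if not np.all(np.isfinite(self.dff)):
            raise InvalidConfigurationError("dff contains non-finite values")
        if np.any(np.diff(self.frame_times) <= 0):
            raise InvalidConfigurationError("frame_times must be strictly increasing")
        if self.dff.shape[1] != self.frame_times.size:
            raise InvalidConfigurationError("dff and frame_times disagree in length")

    @property
    def n_cells(self) -> int:
        return self.dff.shape[0]

    def to_csv(self, path: str) -> None:
        """cell_id, x, y, then one column per frame."""
        df = pd.DataFrame(self.dff, columns=[f"f{t:.3f}" for t in self.frame_times])
        df.insert(0, "y", self.cell_positions[:, 1])
        df.insert(0, "x", self.cell_positions[:, 0])
        df.insert(0, "cell_id", np.arange(self.n_cells))
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str) -> "TraceSet":
        df = pd.read_csv(path)
        times = np.array([float(c[1:]) for c in df.columns[3:]])
        return cls(
            dff=df.iloc[:, 3:].to_numpy(),
            frame_times=times,
            cell_positions=df[["x", "y"]].to_numpy(),
        )


@dataclass
class StimSchedule:
    """Timing of the photostimulation paradigm and the targeted pattern."""

    repetition_onsets: np.ndarray  # s, onset of each pulse train
    targeted_cells: np.ndarray  # indices into the trace set
    spot_positions: np.ndarray  # (n_spots, 2) um
    pulses_per_train: int = 10
    pulse_duration: float = 0.020  # s
    pulse_rate: float = 4.0  # Hz
    camera_off: float = 0.050  # s
    camera_on: float = 0.200  # s

    def __post_init__(self) -> None:
        self.repetition_onsets = np.atleast_1d(
            np.asarray(self.repetition_onsets, dtype=float)
        )
        self.targeted_cells = np.asarray(self.targeted_cells, dtype=int)
        self.spot_positions = np.atleast_2d(
            np.asarray(self.spot_positions, dtype=float)
        )
        # pulses must fit inside the camera-off gaps
        if self.pulse_duration > self.camera_off:
            raise InvalidConfigurationError(
                "pulse_duration exceeds the camera-off gap"
            )
        if abs(1.0 / self.pulse_rate - (self.camera_on + self.camera_off)) > 1e-9:
            raise InvalidConfigurationError(
                "pulse rate inconsistent with camera gating "
                "(one pulse per ON+OFF cycle)"
            )

    @property
    def frame_rate(self) -> float:
        return 1.0 / (self.camera_on + self.camera_off)

    @property
    def fifth_pulse_offset(self) -> float:
        """Time from train onset to the 5th pulse (4 inter-pulse intervals)."""
        return 4.0 / self.pulse_rate

    @property
    def train_duration(self) -> float:
        return self.pulses_per_train / self.pulse_rate


def average_over_repetitions(
    traces: TraceSet,
    schedule: StimSchedule,
    window: tuple[float, float] = (-3.0, 5.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Mean peri-stimulus dF/F over the repetitions of the paradigm.

    Returns ``(rel_times, averaged)`` where ``rel_times`` (s, relative to
    train onset) is the frame grid of the window and ``averaged`` is
    (n_cells, n_window_frames).
    """
    dt = np.median(np.diff(traces.frame_times))
    n_pre = int(round(-window[0] / dt))
    n_post = int(round(window[1] / dt))
    segments = []
    for r, onset in enumerate(schedule.repetition_onsets):
        i0 = int(np.searchsorted(traces.frame_times, onset))
        lo, hi = i0 - n_pre, i0 + n_post
        if lo < 0 or hi > traces.frame_times.size:
            raise InvalidConfigurationError(
                f"repetition {r} (onset {onset:g} s) window falls outside the recording"
            )
        segments.append(traces.dff[:, lo:hi])
    rel_times = (np.arange(-n_pre, n_post) + 0.5) * dt
    return rel_times, np.mean(segments, axis=0)


@dataclass
class ResponseResult:
    """Per-cell repetition-averaged photostimulation response."""

    mean_before: np.ndarray
    mean_after: np.ndarray
    amplitude: np.ndarray  # mean_after - mean_before
    baseline_sd: np.ndarray
    responding: np.ndarray  # bool
    targeted: np.ndarray  # bool
    label: np.ndarray  # one of LABELS per cell

    def counts(self) -> dict[str, int]:
        return {lab: int((self.label == lab).sum()) for lab in LABELS}


def classify_responses(
    traces: TraceSet,
    schedule: StimSchedule,
    baseline_window: float = 2.0,
    response_window: float = 2.0,
    sigma_factor: float = 3.0,
) -> ResponseResult:
    """3-sigma response classification on the repetition-averaged trace.

    ``amplitude = <dF/F>_after - <dF/F>_before`` with the before window the
    2 s preceding the train onset and the after window the 2 s following the
    5th pulse; a cell responds when the amplitude exceeds
    ``sigma_factor * sd`` of the baseline window.
    """
    t5 = schedule.fifth_pulse_offset
    rel, avg = average_over_repetitions(
        traces,
        schedule,
        window=(-baseline_window - 0.5, t5 + response_window + 0.5),
    )
    before = (rel >= -baseline_window) & (rel < 0.0)
    after = (rel >= t5) & (rel < t5 + response_window)
    if before.sum() < 2 or after.sum() < 1:
        raise InvalidConfigurationError(
            "baseline/response windows contain too few frames"
        )
    mean_before = avg[:, before].mean(axis=1)
    mean_after = avg[:, after].mean(axis=1)
    amplitude = mean_after - mean_before
    baseline_sd = avg[:, before].std(axis=1, ddof=1)
    responding = amplitude > sigma_factor * baseline_sd
    targeted = np.zeros(traces.n_cells, dtype=bool)
    targeted[schedule.targeted_cells] = True
    label = np.where(
        targeted,
        np.where(responding, "T/R", "T/nR"),
        np.where(responding, "nT/R", "nT/nR"),
    )
    return ResponseResult(
        mean_before=mean_before,
        mean_after=mean_after,
        amplitude=amplitude,
        baseline_sd=baseline_sd,
        responding=responding,
        targeted=targeted,
        label=label,
    )


def distance_to_nearest_spot(
    cell_positions: np.ndarray, spot_positions: np.ndarray
) -> np.ndarray:
    """Euclidean distance from each cell to its nearest photostimulation spot."""
    cells = np.atleast_2d(np.asarray(cell_positions, dtype=float))
    spots = np.atleast_2d(np.asarray(spot_positions, dtype=float))
    if spots.shape[0] == 0:
        raise InvalidConfigurationError("at least one spot is required")
    d = np.linalg.norm(cells[:, None, :] - spots[None, :, :], axis=2)
    return d.min(axis=1)


@dataclass
class DecayFit:
    """Exponential decay fit A * exp(-x / k) of activation probability."""

    A: float
    k: float  # um
    A_se: float
    k_se: float
    bin_edges: np.ndarray
    bin_centers: np.ndarray
    probabilities: np.ndarray
    counts: np.ndarray


def _bin_probabilities(
    distances: np.ndarray,
    responded: np.ndarray,
    bin_width: float,
    min_count: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    edges = np.arange(0.0, distances.max() + bin_width, bin_width)
    if edges.size < 2:
        edges = np.array([0.0, bin_width])
    idx = np.clip(np.digitize(distances, edges) - 1, 0, edges.size - 2)
    centers, probs, counts = [], [], []
    # merge sparse bins forward until min_count is reached
    acc_n = acc_r = acc_d = 0.0
    for b in range(edges.size - 1):
        sel = idx == b
        acc_n += sel.sum()
        acc_r += responded[sel].sum()
        acc_d += distances[sel].sum()
        if acc_n >= min_count:
            centers.append(acc_d / acc_n)
            probs.append(acc_r / acc_n)
            counts.append(acc_n)
            acc_n = acc_r = acc_d = 0.0
    if acc_n > 0 and centers:
        # fold the trailing remainder into the last kept bin
        counts[-1] += acc_n
        probs[-1] = (probs[-1] * (counts[-1] - acc_n) + acc_r) / counts[-1]
    return edges, np.array(centers), np.array(probs), np.array(counts, dtype=int)


def activation_probability_fit(
    distances: np.ndarray,
    responded: np.ndarray,
    bin_width: float = 10.0,
    min_count: int = 5,
) -> DecayFit:
    """Bin response outcomes by distance and fit ``A * exp(-x / k)``.

    Nonlinear least squares on the per-bin response probabilities; standard
    errors come from the fit covariance.  Degenerate data (all bins at the
    same probability, or fewer than 3 usable bins) raise
    :class:`DegenerateFitError`.
    """
    distances = np.asarray(distances, dtype=float)
    responded = np.asarray(responded, dtype=bool)
    edges, centers, probs, counts = _bin_probabilities(
        distances, responded, bin_width, min_count
    )
    if centers.size < 3:
        raise DegenerateFitError("fewer than 3 distance bins with data")
    if np.ptp(probs) == 0.0:
        raise DegenerateFitError("activation probabilities carry no decay signal")

    def model(x, A, k):
        return A * np.exp(-x / k)

    p0 = (max(probs.max(), 1e-3), max(centers[probs > probs.max() / 2].max(), 1.0))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        popt, pcov = curve_fit(
            model,
            centers,
            probs,
            p0=p0,
            bounds=([0.0, 1e-6], [np.inf, np.inf]),
            maxfev=10_000,
        )
    perr = np.sqrt(np.diag(pcov))
    return DecayFit(
        A=float(popt[0]),
        k=float(popt[1]),
        A_se=float(perr[0]),
        k_se=float(perr[1]),
        bin_edges=edges,
        bin_centers=centers,
        probabilities=probs,
        counts=counts,
    )


def count_components_above_snr(snr: np.ndarray, threshold: float = 2.0) -> int:
    """Number of components with SNR strictly above the threshold."""
    snr = np.asarray(snr, dtype=float)
    return int((snr > threshold).sum())


@dataclass
class DisplacementRecord:
    """Per-frame displacement summary over motion-correction patches."""

    d: np.ndarray  # (frames, patches) total displacement per patch
    mean_d: np.ndarray  # (frames,) mean over non-excluded patches
    excluded_patches: np.ndarray  # flat indices of excluded (corner) patches


def mean_frame_displacement(
    dx: np.ndarray,
    dy: np.ndarray,
    grid_shape: tuple[int, int],
    exclude_corners: bool = True,
) -> DisplacementRecord:
    """Mean per-frame displacement ``sqrt(dx^2 + dy^2)`` over patches.

    ``dx`` and ``dy`` are (frames, patches) with patches in row-major order
    on ``grid_shape``.  Corner patches are excluded — they cover areas
    outside the fiber bundle that stay static during acquisition.  Grids too
    small for the exclusion are computed without it (with a warning).
    """
    dx = np.asarray(dx, dtype=float)
    dy = np.asarray(dy, dtype=float)
    rows, cols = grid_shape
    if dx.shape != dy.shape or dx.shape[1] != rows * cols:
        raise InvalidConfigurationError("dx/dy shapes inconsistent with grid_shape")
    d = np.hypot(dx, dy)
    excluded = np.array([], dtype=int)
    if exclude_corners:
        if rows >= 2 and cols >= 2:
            excluded = np.array(
                [0, cols - 1, (rows - 1) * cols, rows * cols - 1], dtype=int
            )
        else:
            warnings.warn(
                "patch grid too small for corner exclusion; using all patches",
                stacklevel=2,
            )
    keep = np.setdiff1d(np.arange(rows * cols), excluded)
    return DisplacementRecord(
        d=d, mean_d=d[:, keep].mean(axis=1), excluded_patches=excluded
    )
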