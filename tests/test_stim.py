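"""Photostimulation-response statistics and their recovery from synthetic data."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fiberscope.errors import DegenerateFitError, InvalidConfigurationError
from fiberscope.stim import (
    LABELS,
    StimSchedule,
    TraceSet,
    activation_probability_fit,
    average_over_repetitions,
    classify_responses,
    count_components_above_snr,
    distance_to_nearest_spot,
    mean_frame_displacement,
)
from fiberscope.synth import (
    SceneModel,
    generate_activation_outcomes,
    generate_calcium_movie,
    make_schedule,
)


def _simple_experiment(n_cells=20, n_targets=5, amplitude=0.8, noise_sd=0.05,
                       p0=0.0, k_true=18.4, seed=0):
    rng = np.random.default_rng(seed)
    pos = rng.uniform(-200.0, 200.0, size=(n_cells, 2))
    sched = make_schedule(np.arange(n_targets), pos[:n_targets])
    scene = SceneModel(cell_positions=pos, amplitude=amplitude, noise_sd=noise_sd)
    return generate_calcium_movie(scene, sched, k_true=k_true, p0=p0, seed=seed)


# ---------------------------------------------------------------------------
# schedule and averaging


def test_schedule_rejects_pulse_longer_than_gap():
    with pytest.raises(InvalidConfigurationError):
        StimSchedule(
            repetition_onsets=[10.0],
            targeted_cells=[0],
            spot_positions=[[0.0, 0.0]],
            pulse_duration=0.08,
        )


def test_fifth_pulse_offset():
    s = make_schedule([0], [[0.0, 0.0]])
    assert s.fifth_pulse_offset == pytest.approx(1.0)  # 4 intervals at 4 Hz
    assert s.frame_rate == pytest.approx(4.0)


def test_averaging_identical_repetitions_is_identity():
    frame_times = np.arange(200) * 0.25
    sched = make_schedule([0], [[0.0, 0.0]], first_onset=10.0, interval=10.0)
    period = np.zeros(200)
    # the same deterministic bump after every onset
    for onset in sched.repetition_onsets:
        sel = (frame_times >= onset) & (frame_times < onset + 2.0)
        period[sel] = 1.0
    traces = TraceSet(
        dff=period[None, :], frame_times=frame_times, cell_positions=[[0.0, 0.0]]
    )
    rel, avg = average_over_repetitions(traces, sched, window=(-2.0, 4.0))
    single = period[(frame_times >= 8.0) & (frame_times < 14.0)]
    np.testing.assert_allclose(avg[0], single)


def test_averaging_reduces_noise_by_factor_two(rng):
    frame_times = np.arange(600) * 0.25
    sched = make_schedule([0], [[0.0, 0.0]], first_onset=20.0, interval=30.0)
    noise = rng.normal(0.0, 1.0, size=(200, 600))
    traces = TraceSet(
        dff=noise,
        frame_times=frame_times,
        cell_positions=np.zeros((200, 2)),
    )
    _, avg = average_over_repetitions(traces, sched)
    # four-repetition average halves the noise sd
    assert avg.std() == pytest.approx(0.5, rel=0.05)


def test_averaging_out_of_range_names_repetition():
    frame_times = np.arange(40) * 0.25  # 10 s recording
    sched = make_schedule([0], [[0.0, 0.0]], first_onset=8.0, interval=30.0)
    traces = TraceSet(
        dff=np.zeros((1, 40)), frame_times=frame_times, cell_positions=[[0.0, 0.0]]
    )
    with pytest.raises(InvalidConfigurationError, match="repetition 0"):
        average_over_repetitions(traces, sched)


# ---------------------------------------------------------------------------
# classification


def test_flat_trace_not_responding():
    exp = _simple_experiment(noise_sd=1e-6, amplitude=0.0)
    res = classify_responses(exp.traces, exp.schedule)
    assert np.all(res.amplitude == pytest.approx(0.0, abs=1e-5))


def test_clean_step_above_threshold_is_tr():
    """A targeted cell stepping by 4 baseline sds classifies as T/R."""
    frame_times = np.arange(400) * 0.25
    sched = make_schedule([0], [[0.0, 0.0]], first_onset=20.0, interval=20.0)
    base = np.tile([0.01, -0.01], 200)  # deterministic baseline wiggle
    sd = np.std(base[:8], ddof=1)
    dff = base.copy()
    for onset in sched.repetition_onsets:
        dff[(frame_times >= onset) & (frame_times < onset + 4.0)] += 4.0 * sd
    traces = TraceSet(
        dff=dff[None, :], frame_times=frame_times, cell_positions=[[0.0, 0.0]]
    )
    res = classify_responses(traces, sched)
    assert res.label[0] == "T/R"


def test_high_effect_pattern_fully_recovered():
    """10 targets, high amplitude, no off-target: 10/10 T/R and 0 nT/R."""
    exp = _simple_experiment(n_cells=28, n_targets=10, amplitude=1.0, noise_sd=0.05)
    res = classify_responses(exp.traces, exp.schedule)
    counts = res.counts()
    assert counts["T/R"] == 10
    assert counts["T/nR"] == 0
    assert counts["nT/R"] == 0


def test_labels_partition_cells():
    exp = _simple_experiment(n_cells=40, p0=0.5)
    res = classify_responses(exp.traces, exp.schedule)
    assert sum(res.counts().values()) == 40
    assert set(res.label) <= set(LABELS)


@given(c=st.floats(0.05, 50.0))
@settings(derandomize=True, max_examples=25, deadline=None)
def test_threshold_scale_equivariance(c):
    """Scaling dF/F by c > 0 leaves every label unchanged."""
    exp = _simple_experiment(n_cells=15, n_targets=4, amplitude=0.3, noise_sd=0.08,
                             seed=7)
    res1 = classify_responses(exp.traces, exp.schedule)
    scaled = TraceSet(
        dff=c * exp.traces.dff,
        frame_times=exp.traces.frame_times,
        cell_positions=exp.traces.cell_positions,
    )
    res2 = classify_responses(scaled, exp.schedule)
    assert np.array_equal(res1.label, res2.label)


def test_off_target_responders_cluster_near_targets():
    """nT/R cells lie closer to targets than nT/nR cells (median distance)."""
    exp = _simple_experiment(n_cells=400, n_targets=10, amplitude=1.0,
                             noise_sd=0.05, p0=1.0, k_true=30.0, seed=2)
    res = classify_responses(exp.traces, exp.schedule)
    d = distance_to_nearest_spot(
        exp.traces.cell_positions, exp.schedule.spot_positions
    )
    ntr = (res.label == "nT/R")
    ntnr = (res.label == "nT/nR")
    assert ntr.sum() >= 5 and ntnr.sum() >= 5
    assert np.median(d[ntr]) < np.median(d[ntnr])


# ---------------------------------------------------------------------------
# distances


def test_distance_trivial_cases():
    d = distance_to_nearest_spot([[3.0, 4.0], [0.0, 0.0]], [[0.0, 0.0]])
    assert d[0] == pytest.approx(5.0)
    assert d[1] == 0.0


def test_distance_matches_brute_force(rng):
    cells = rng.uniform(-100, 100, size=(50, 2))
    spots = rng.uniform(-100, 100, size=(7, 2))
    d = distance_to_nearest_spot(cells, spots)
    brute = np.array(
        [min(np.hypot(*(c - s)) for s in spots) for c in cells]
    )
    np.testing.assert_allclose(d, brute)


# ---------------------------------------------------------------------------
# decay fit


def test_decay_fit_noiseless_recovery():
    """Outcomes laid exactly on A=1, k=20 recover (1, 20)."""
    m = 2000
    distances, responded = [], []
    for x in np.arange(5.0, 96.0, 10.0):
        p = np.exp(-x / 20.0)
        k = int(round(m * p))
        distances += [x] * m
        responded += [True] * k + [False] * (m - k)
    fit = activation_probability_fit(np.array(distances), np.array(responded))
    assert fit.A == pytest.approx(1.0, abs=0.02)
    assert fit.k == pytest.approx(20.0, rel=0.02)


def test_decay_fit_degenerate_flagged():
    d = np.linspace(1.0, 90.0, 200)
    with pytest.raises(DegenerateFitError):
        activation_probability_fit(d, np.zeros(200, dtype=bool))
    with pytest.raises(DegenerateFitError):
        activation_probability_fit(d, np.ones(200, dtype=bool))


def test_decay_constant_recovery_within_two_se():
    d, r, truth = generate_activation_outcomes(2000, k_true=18.4, seed=0)
    fit = activation_probability_fit(d, r)
    assert abs(fit.k - truth.k_true) <= 2.0 * fit.k_se


def test_decay_estimator_unbiased_over_replicates():
    """Over 200 seeded replicates at n=2000 the estimator is unbiased to 5%."""
    ks = []
    for seed in range(200):
        d, r, _ = generate_activation_outcomes(2000, k_true=18.4, seed=seed)
        ks.append(activation_probability_fit(d, r).k)
    assert np.mean(ks) == pytest.approx(18.4, rel=0.05)


# ---------------------------------------------------------------------------
# SNR counting and displacement


@pytest.mark.parametrize(
    "values, expected",
    [([], 0), ([1.0, 2.0, 3.0], 1), ([2.0001, 5.0, 0.1], 2)],
)
def test_count_components_above_snr(values, expected):
    assert count_components_above_snr(np.array(values)) == expected


def test_displacement_zero_and_pythagoras():
    dx = np.zeros((3, 12))
    dy = np.zeros((3, 12))
    rec = mean_frame_displacement(dx, dy, (3, 4))
    assert np.all(rec.mean_d == 0.0)
    rec2 = mean_frame_displacement(dx + 3.0, dy + 4.0, (3, 4))
    np.testing.assert_allclose(rec2.mean_d, 5.0)


def test_displacement_corner_exclusion():
    rng = np.random.default_rng(0)
    dx = rng.normal(size=(5, 12))
    dy = rng.normal(size=(5, 12))
    base = mean_frame_displacement(dx, dy, (3, 4))
    corrupted_dx = dx.copy()
    corrupted_dy = dy.copy()
    for p in base.excluded_patches:
        corrupted_dx[:, p] = 1e6
        corrupted_dy[:, p] = 1e6
    rec = mean_frame_displacement(corrupted_dx, corrupted_dy, (3, 4))
    np.testing.assert_allclose(rec.mean_d, base.mean_d)


def test_displacement_small_grid_warns():
    dx = np.ones((2, 2))
    dy = np.ones((2, 2))
    with pytest.warns(UserWarning):
        rec = mean_frame_displacement(dx, dy, (1, 2))
    np.testing.assert_allclose(rec.mean_d, np.sqrt(2.0))
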