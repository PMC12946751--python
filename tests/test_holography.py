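"""Phase-mask synthesis: projection, symmetry and speckle properties."""

import numpy as np
import pytest

from fiberscope.errors import InvalidConfigurationError
from fiberscope.holography import (
    PropagationModel,
    Spot,
    angular_spectrum_propagate,
    backpropagate,
    diffraction_efficiency,
    diffraction_efficiency_compensation,
    gerchberg_saxton,
    multiplexed_gaussian_spots,
    propagate,
    reconstruct,
    shape_power_normalization,
    speckle_contrast,
    zernike_noll,
    zernike_phase,
)

MODEL = PropagationModel(grid=256, field_um=480.0)


@pytest.fixture(scope="module")
def model():
    return MODEL


# ---------------------------------------------------------------------------
# propagation model


def test_propagation_is_unitary(rng):
    field = rng.standard_normal((128, 128)) + 1j * rng.standard_normal((128, 128))
    out = propagate(field)
    assert np.abs(out).sum() != np.abs(field).sum()  # not trivially identical
    assert (np.abs(out) ** 2).sum() == pytest.approx(
        (np.abs(field) ** 2).sum(), rel=1e-12
    )
    back = backpropagate(out)
    np.testing.assert_allclose(back, field, atol=1e-10)


# ---------------------------------------------------------------------------
# Gerchberg-Saxton


def _disk_target(model, radius_um, center=(0.0, 0.0)):
    X, Y = model.coords()
    return (((X - center[0]) ** 2 + (Y - center[1]) ** 2) <= radius_um**2).astype(
        float
    )


def test_gs_error_non_increasing(model):
    for seed in (0, 1, 2):
        res = gerchberg_saxton(_disk_target(model, 5.0), model, n_iter=50, seed=seed)
        assert np.all(np.diff(res.errors) <= 1e-14)
        assert res.errors[-1] < res.errors[0]


def test_gs_point_target_is_prism(model):
    """A single off-center point target reconstructs at its position +-1 px."""
    target = np.zeros((model.grid, model.grid))
    target[160, 96] = 1.0
    res = gerchberg_saxton(target, model, n_iter=10, seed=0)
    rec = reconstruct(res.mask, None, model)
    peak = np.unravel_index(np.argmax(rec.intensity), rec.intensity.shape)
    assert abs(peak[0] - 160) <= 1 and abs(peak[1] - 96) <= 1
    # a pure prism is a linear phase: its unwrapped row differences are constant
    d = np.diff(np.unwrap(res.mask.phase[128]))
    assert np.std(d) < 0.05 * (np.abs(np.mean(d)) + 1e-12) + 1e-6


def test_gs_rejects_zero_target(model):
    with pytest.raises(InvalidConfigurationError):
        gerchberg_saxton(np.zeros((64, 64)), model)


def test_gs_multispot_uniform_after_efficiency_weighting(model):
    """10 point targets pre-weighted by 1/eta deliver uniform power x eta."""
    rng = np.random.default_rng(3)
    spots = [
        Spot(x, y, 10.0)
        for x, y in rng.uniform(-180.0, 180.0, size=(10, 2))
    ]
    w = diffraction_efficiency_compensation(spots, model)
    target = np.zeros((model.grid, model.grid))
    for s, wi in zip(spots, w):
        i = int(round(s.x / model.sample_pixel)) + model.grid // 2
        j = int(round(s.y / model.sample_pixel)) + model.grid // 2
        target[i, j] = wi
    res = gerchberg_saxton(target, model, n_iter=60, seed=0)
    rec = reconstruct(res.mask, None, model, spots=spots)
    delivered = rec.per_target_power * np.array(
        [diffraction_efficiency(s.x, s.y, model) for s in spots]
    )
    assert delivered.max() / delivered.min() < 1.2 / 0.8


# ---------------------------------------------------------------------------
# multiplexed Gaussian spots


def test_single_spot_flat_phase_and_fwhm(model):
    mux = multiplexed_gaussian_spots([Spot(0.0, 0.0, 10.0)], model)
    sig = mux.incident > 1e-3 * mux.incident.max()
    ph = np.angle(np.exp(1j * mux.mask.phase[sig]))
    assert np.ptp(ph) < 1e-6  # flat up to piston where the beam has power
    rec = reconstruct(mux.mask, mux.incident, model)
    # intensity second moment of a Gaussian spot: sigma = FWHM_illum / 2.355
    X, Y = model.coords()
    I = rec.intensity
    sx = np.sqrt((I * X**2).sum() / I.sum())
    fwhm_illum = 2.3548 * sx
    assert fwhm_illum == pytest.approx(10.0 * np.sqrt(2.0), rel=0.10)


def test_two_symmetric_spots_equal_power(model):
    spots = [Spot(-60.0, 0.0, 10.0), Spot(60.0, 0.0, 10.0)]
    mux = multiplexed_gaussian_spots(spots, model)
    rec = reconstruct(mux.mask, mux.incident, model, spots=spots)
    p = rec.per_target_power
    assert abs(p[0] - p[1]) / p.mean() < 0.05


def test_spot_positions_reproduced(model):
    spots = [Spot(-100.0, 40.0, 10.0), Spot(80.0, -120.0, 10.0), Spot(0.0, 150.0, 10.0)]
    mux = multiplexed_gaussian_spots(spots, model)
    rec = reconstruct(mux.mask, mux.incident, model)
    I = rec.intensity.copy()
    px = model.sample_pixel
    for s in spots:
        i = int(round(s.x / px)) + model.grid // 2
        j = int(round(s.y / px)) + model.grid // 2
        window = I[i - 6 : i + 7, j - 6 : j + 7]
        pk = np.unravel_index(np.argmax(window), window.shape)
        assert abs(pk[0] - 6) <= 1 and abs(pk[1] - 6) <= 1


def test_multiplexed_uniform_after_efficiency_weighting(model):
    """Efficiency-compensated 10-spot pattern: delivered power within 20%."""
    rng = np.random.default_rng(0)
    spots = [Spot(x, y, 10.0) for x, y in rng.uniform(-180.0, 180.0, size=(10, 2))]
    w = diffraction_efficiency_compensation(spots, model)
    weighted = [
        Spot(s.x, s.y, s.fwhm, weight=np.sqrt(wi)) for s, wi in zip(spots, w)
    ]
    mux = multiplexed_gaussian_spots(weighted, model)
    rec = reconstruct(mux.mask, mux.incident, model, spots=spots)
    delivered = rec.per_target_power * np.array(
        [diffraction_efficiency(s.x, s.y, model) for s in spots]
    )
    assert np.all(np.abs(delivered / delivered.mean() - 1.0) < 0.2)


def test_spot_outside_field_rejected(model):
    with pytest.raises(InvalidConfigurationError):
        multiplexed_gaussian_spots([Spot(500.0, 0.0, 10.0)], model)


def test_multiplexed_spot_smoother_than_gs_disk(model):
    """Speckle contrast: multiplexed Gaussian spot < GS holographic disk."""
    mux = multiplexed_gaussian_spots([Spot(0.0, 0.0, 10.0)], model)
    rec_mux = reconstruct(mux.mask, mux.incident, model)
    support = _disk_target(model, 5.0) > 0
    c_mux = speckle_contrast(rec_mux.intensity, support)

    res = gerchberg_saxton(_disk_target(model, 5.0), model, n_iter=50, seed=0)
    rec_gs = reconstruct(res.mask, None, model)
    c_gs = speckle_contrast(rec_gs.intensity, support)
    assert c_mux < c_gs


# ---------------------------------------------------------------------------
# diffraction efficiency and shape power


def test_efficiency_center_weight_one(model):
    w = diffraction_efficiency_compensation([Spot(0.0, 0.0)], model)
    assert w[0] == pytest.approx(1.0)


def test_efficiency_mirror_symmetry(model):
    w = diffraction_efficiency_compensation(
        [Spot(-120.0, 80.0), Spot(120.0, -80.0)], model
    )
    assert w[0] == pytest.approx(w[1])


def test_efficiency_weights_increase_with_distance(model):
    xs = np.linspace(0.0, 220.0, 12)
    w = diffraction_efficiency_compensation([Spot(x, 0.0) for x in xs], model)
    assert np.all(np.diff(w) > 0)


def test_efficiency_floor_refused():
    # at a tight floor, far-corner spots must be refused with a diagnostic
    with pytest.raises(InvalidConfigurationError, match="efficiency"):
        diffraction_efficiency_compensation(
            [Spot(230.0, 230.0)], MODEL, floor=0.5
        )


def test_shape_power_scaling():
    a = np.ones((10, 30), dtype=bool)  # 300 um^2 at 1 um pitch
    b = np.ones((20, 30), dtype=bool)
    p = shape_power_normalization([a, b], excitation_density=0.1)
    assert p[0] == pytest.approx(30.0)
    assert p[1] / p[0] == pytest.approx(2.0)
    assert p.sum() == pytest.approx(0.1 * (300 + 600))


def test_shape_power_empty_mask_rejected():
    with pytest.raises(InvalidConfigurationError):
        shape_power_normalization([np.zeros((5, 5), dtype=bool)], 0.1)


# ---------------------------------------------------------------------------
# Zernike


def test_zernike_zero_coefficients_flat(model):
    mask = zernike_phase({4: 0.0, 11: 0.0}, model)
    assert np.all(mask.phase == 0.0)


@pytest.mark.parametrize("j1, j2", [(2, 3), (4, 5), (4, 11), (6, 7)])
def test_zernike_orthogonality(j1, j2):
    n = 256
    c = (np.arange(n) - n / 2 + 0.5) / (n / 2)
    X, Y = np.meshgrid(c, c, indexing="ij")
    rho = np.sqrt(X**2 + Y**2)
    th = np.arctan2(Y, X)
    ins = rho <= 1.0
    z1 = zernike_noll(j1, rho[ins], th[ins])
    z2 = zernike_noll(j2, rho[ins], th[ins])
    # disk-sampled inner products: distinct modes ~0, self ~1 (Noll norm)
    assert abs((z1 * z2).mean()) < 5e-3
    assert (z1 * z1).mean() == pytest.approx(1.0, abs=0.02)


def test_zernike_invalid_index():
    with pytest.raises(InvalidConfigurationError):
        zernike_noll(0, np.array([0.5]), np.array([0.0]))


def test_defocus_shifts_best_focus_plane(model):
    """Pure defocus moves the plane of peak intensity, sign following c."""
    mux = multiplexed_gaussian_spots([Spot(0.0, 0.0, 10.0)], model)
    px = model.sample_pixel * 1e-6
    lam = 1.03e-6
    dzs = np.linspace(-600e-6, 600e-6, 25)

    def best_focus(c):
        zmask = zernike_phase({4: c}, model)
        samp = propagate(mux.incident * np.exp(1j * zmask.phase))
        peaks = [
            (np.abs(angular_spectrum_propagate(samp, dz, lam, px)) ** 2).max()
            for dz in dzs
        ]
        return dzs[int(np.argmax(peaks))]

    assert best_focus(0.0) == pytest.approx(0.0, abs=1e-9)
    assert best_focus(3.0) > 0.0
    assert best_focus(-3.0) < 0.0
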