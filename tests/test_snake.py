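"""Level-set primitives and the localized active contour."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import integrate

from otomsi import metrics
from otomsi.snake import (ContourParams, LevelSetField, evolve_contour, local_means,
                          mask_boundary, sdf_from_mask, smoothed_dirac,
                          smoothed_heaviside)

# ---------------------------------------------------------------------------
# smoothed Heaviside / Dirac


@pytest.mark.parametrize(
    "phi,eps,expected",
    [
        (-2.0, 1.0, 1.0),            # deep interior
        (2.0, 1.0, 0.0),             # deep exterior
        (0.0, 1.0, 0.5),             # midpoint of the smooth branch
        (-1.0, 1.0, 1.0),            # continuous at the band edge
        (1.0, 1.0, 0.0),
        (-0.5, 1.0, 0.5 * (1.5 + np.sin(np.pi / 2) / np.pi)),  # ≈ 0.909
    ],
)
def test_heaviside_values(phi, eps, expected):
    assert smoothed_heaviside(phi, eps) == pytest.approx(expected, abs=1e-12)


def test_heaviside_scales_with_epsilon():
    # the band edge moves with epsilon
    assert smoothed_heaviside(-2 * 3.0, 3.0) == 1.0
    assert smoothed_heaviside(2 * 3.0, 3.0) == 0.0


@given(st.floats(-10, 10), st.floats(-10, 10), st.floats(0.1, 5))
def test_heaviside_monotone_and_bounded(p1, p2, eps):
    h1, h2 = smoothed_heaviside(p1, eps), smoothed_heaviside(p2, eps)
    assert 0.0 <= h1 <= 1.0
    if p1 <= p2:
        assert h1 >= h2 - 1e-12


@pytest.mark.parametrize(
    "phi,eps,expected",
    [
        (2.0, 1.0, 0.0),
        (-2.0, 1.0, 0.0),
        (1.0, 1.0, 0.0),     # cos(pi) = -1 at the band edge
        (-1.0, 1.0, 0.0),
        (0.0, 1.0, 1.0),     # 1/epsilon at the contour
        (0.0, 2.0, 0.5),
    ],
)
def test_dirac_values(phi, eps, expected):
    assert smoothed_dirac(phi, eps) == pytest.approx(expected, abs=1e-12)


def test_dirac_integrates_to_one():
    val, _ = integrate.quad(lambda p: smoothed_dirac(p, 1.5), -1.5, 1.5)
    assert val == pytest.approx(1.0, abs=1e-6)


def test_dirac_is_heaviside_derivative_magnitude():
    eps, h = 1.5, 1e-5
    phis = np.linspace(-2.5, 2.5, 401)
    dH = (smoothed_heaviside(phis + h, eps) - smoothed_heaviside(phis - h, eps)) / (2 * h)
    assert np.abs(np.abs(dH) - smoothed_dirac(phis, eps)).max() < 1e-4


@pytest.mark.parametrize("func", [smoothed_heaviside, smoothed_dirac])
def test_band_functions_reject_nonpositive_epsilon(func):
    with pytest.raises(ValueError):
        func(0.0, 0.0)


# ---------------------------------------------------------------------------
# signed distance field


def test_sdf_single_center_pixel():
    mask = np.zeros((3, 3), dtype=bool)
    mask[1, 1] = True
    phi = sdf_from_mask(mask).phi
    assert phi[1, 1] == pytest.approx(-1.0)
    for r, c in ((0, 1), (1, 0), (1, 2), (2, 1)):
        assert phi[r, c] == pytest.approx(1.0)
    for r, c in ((0, 0), (0, 2), (2, 0), (2, 2)):
        assert phi[r, c] == pytest.approx(np.sqrt(2))


def _brute_force_sdf(mask):
    ins = np.argwhere(mask).astype(float)
    outs = np.argwhere(~mask).astype(float)
    pts = np.indices(mask.shape).reshape(2, -1).T.astype(float)
    d_in = np.sqrt(((pts[:, None, :] - ins[None]) ** 2).sum(-1)).min(1)
    d_out = np.sqrt(((pts[:, None, :] - outs[None]) ** 2).sum(-1)).min(1)
    return (d_in - d_out).reshape(mask.shape)


def test_sdf_matches_brute_force_on_random_masks():
    rng = np.random.default_rng(0)
    for _ in range(20):
        mask = rng.random((8, 8)) < 0.4
        if mask.all() or not mask.any():
            continue
        phi = sdf_from_mask(mask).phi
        assert np.allclose(phi, _brute_force_sdf(mask))
        assert np.array_equal(phi < 0, mask)


def test_sdf_complement_negates_within_discretization():
    rng = np.random.default_rng(1)
    for _ in range(20):
        mask = rng.random((8, 8)) < 0.5
        if mask.all() or not mask.any():
            continue
        phi = sdf_from_mask(mask).phi
        phic = sdf_from_mask(~mask).phi
        # the discrete transform is asymmetric by up to one pixel across the interface
        assert np.abs(phi + phic).max() <= 1.0 + 1e-9


@pytest.mark.parametrize("mask", [np.ones((4, 4), bool), np.zeros((4, 4), bool)])
def test_sdf_rejects_single_phase(mask):
    with pytest.raises(ValueError):
        sdf_from_mask(mask)


def test_sdf_gradient_magnitude_near_unity():
    mask = np.zeros((40, 40), bool)
    yy, xx = np.mgrid[0:40, 0:40]
    mask[(yy - 20) ** 2 + (xx - 20) ** 2 <= 100] = True
    phi = sdf_from_mask(mask).phi
    gy, gx = np.gradient(phi)
    mag = np.hypot(gx, gy)
    # exclude the interface (central differences straddle the sign change)
    # and the medial axis (where the true distance gradient is undefined)
    ring = (np.abs(phi) > 3) & (np.abs(phi) < 7)
    assert np.abs(mag[ring] - 1.0).max() < 0.15


# ---------------------------------------------------------------------------
# local means


def test_local_means_constant_image():
    img = np.full((11, 11), 0.7)
    mask = np.zeros((11, 11), bool)
    mask[4:8, 4:8] = True
    field = sdf_from_mask(mask)
    lm = local_means(img, field, (5, 5), 4)
    assert not lm.interior_empty and not lm.exterior_empty
    assert lm.interior_mean == pytest.approx(0.7, abs=1e-6)
    assert lm.exterior_mean == pytest.approx(0.7, abs=1e-6)


def test_local_means_two_phase_oracle():
    img = np.where(np.arange(11)[None, :] < 6, 0.2, 0.9) * np.ones((11, 1))
    mask = np.zeros((11, 11), bool)
    mask[:, :6] = True  # interior = left phase
    field = sdf_from_mask(mask)
    lm = local_means(img, field, (5, 5), 3)
    # independent weighted-mean oracle over the same window
    h = smoothed_heaviside(field.phi[2:9, 2:9], field.epsilon)
    patch = img[2:9, 2:9]
    mu_in = (h * patch).sum() / h.sum()
    mu_out = ((1 - h) * patch).sum() / (1 - h).sum()
    assert lm.interior_mean == pytest.approx(mu_in, abs=1e-9)
    assert lm.exterior_mean == pytest.approx(mu_out, abs=1e-9)
    # and the means recover the phases up to the Heaviside band blur
    assert lm.interior_mean == pytest.approx(0.2, abs=0.1)
    assert lm.exterior_mean == pytest.approx(0.9, abs=0.1)


def test_local_means_flags_empty_side():
    mask = np.zeros((15, 15), bool)
    mask[2:13, 2:13] = True
    field = sdf_from_mask(mask)
    lm = local_means(np.ones((15, 15)), field, (7, 7), 2)  # ball deep inside interior
    assert lm.exterior_empty and not lm.interior_empty


def test_local_means_rejects_bad_inputs():
    mask = np.zeros((5, 5), bool)
    mask[2, 2] = True
    field = sdf_from_mask(mask)
    with pytest.raises(ValueError):
        local_means(np.ones((5, 5)), field, (2, 2), 0)
    with pytest.raises(ValueError):
        local_means(np.ones((5, 5)), field, (9, 2), 2)


# ---------------------------------------------------------------------------
# mask boundary


def test_boundary_of_block():
    mask = np.zeros((5, 5), bool)
    mask[1:4, 1:4] = True
    pts = {tuple(p) for p in mask_boundary(mask)}
    expected = {(r, c) for r in range(1, 4) for c in range(1, 4) if not (r == 2 and c == 2)}
    assert pts == expected


def test_boundary_single_pixel_and_idempotence():
    mask = np.zeros((4, 4), bool)
    mask[2, 1] = True
    assert [tuple(p) for p in mask_boundary(mask)] == [(2, 1)]
    # one-pixel-thick ring: boundary of the ring is the ring itself
    ring = np.zeros((7, 7), bool)
    ring[1:6, 1:6] = True
    ring[2:5, 2:5] = False
    ring_pts = {tuple(p) for p in mask_boundary(ring)}
    assert ring_pts == {tuple(p) for p in np.argwhere(ring)}


def test_boundary_rejects_empty_mask():
    with pytest.raises(ValueError):
        mask_boundary(np.zeros((3, 3), bool))


# ---------------------------------------------------------------------------
# contour evolution


def _disc(shape, center, radius):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2


SMALL_PARAMS = ContourParams(local_radius=8, max_iters=300)


def test_recovers_noiseless_disc():
    truth = _disc((64, 64), (32, 32), 15)
    img = np.where(truth, 0.8, 0.2)
    init = _disc((64, 64), (35, 30), 19)  # offset, covering
    res = evolve_contour(img, init, SMALL_PARAMS)
    assert metrics.dice(res.mask, truth) >= 0.99


def test_truth_init_is_near_fixed_point():
    truth = _disc((64, 64), (32, 32), 15)
    img = np.where(truth, 0.8, 0.2)
    res = evolve_contour(img, truth, SMALL_PARAMS)
    assert metrics.dice(res.mask, truth) >= 0.99


def test_constant_image_curvature_only_shrinks():
    # zero data force: the motion is pure curvature flow, which shrinks a
    # convex interior (curve-shortening); it must terminate without error
    img = np.full((64, 64), 0.5)
    init = _disc((64, 64), (32, 32), 18)
    res = evolve_contour(img, init, SMALL_PARAMS)
    assert res.converged
    assert res.mask.any()
    assert res.mask.sum() <= init.sum()
    # short runs only shave the boundary
    short = evolve_contour(img, init, ContourParams(local_radius=8, max_iters=8))
    assert short.mask.sum() <= init.sum()
    assert metrics.dice(short.mask, init) > 0.9


def test_evolution_is_deterministic():
    truth = _disc((48, 48), (24, 24), 12)
    rng = np.random.default_rng(3)
    img = np.clip(np.where(truth, 0.8, 0.2) + 0.05 * rng.normal(size=(48, 48)), 0, 1)
    init = _disc((48, 48), (25, 23), 15)
    r1 = evolve_contour(img, init, SMALL_PARAMS)
    r2 = evolve_contour(img, init, SMALL_PARAMS)
    assert np.array_equal(r1.mask, r2.mask)
    assert r1.iterations_run == r2.iterations_run
    assert r1.energy_trace == r2.energy_trace


def test_evolution_input_contracts():
    img = np.full((16, 16), 0.5)
    with pytest.raises(ValueError):
        evolve_contour(img, np.zeros((16, 16), bool), SMALL_PARAMS)
    with pytest.raises(ValueError):
        evolve_contour(img, np.ones((8, 8), bool), SMALL_PARAMS)


def test_params_validation():
    with pytest.raises(ValueError):
        ContourParams(epsilon=0.0)
    with pytest.raises(ValueError):
        ContourParams(convergence_tol=1.5)
    with pytest.raises(ValueError):
        ContourParams(curvature_weight=-0.1)


def test_levelset_field_interior_property():
    mask = np.zeros((6, 6), bool)
    mask[2:4, 2:4] = True
    field = sdf_from_mask(mask)
    assert isinstance(field, LevelSetField)
    assert np.array_equal(field.interior, mask)


def test_segmentation_on_small_phantom_red(small_phantom):
    """On a quarter-scale phantom the red channel segments the TM closely."""
    from otomsi.pipeline import make_init_mask
    from otomsi.snake import default_contour_params

    _, init = make_init_mask(small_phantom, jitter_seed=5)
    shape = small_phantom.gt_tm_mask.shape
    res = evolve_contour(small_phantom.channels["red"], init, default_contour_params(shape))
    rec = metrics.evaluate(res.mask, small_phantom.gt_tm_mask)
    assert rec.dice > 0.97
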