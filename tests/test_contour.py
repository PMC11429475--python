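"""Contour chain: per-stage oracles, full-chain bit-identity, localizers."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from glaucovit import reference as ref
from glaucovit.contour import (
    ContourParamError,
    ContourParams,
    DiscLocation,
    DiscNotFoundError,
    double_threshold,
    extract_contour,
    gaussian_blur,
    gaussian_kernel_2d,
    hysteresis_tracking,
    locate_optic_cup,
    locate_optic_disc,
    non_maximum_suppression,
    sobel_gradients,
    to_grayscale,
)
from glaucovit.labels import GLAUCOMA
from glaucovit.phantom import PhantomSpec, render_phantom


def _random_image(seed, size=32):
    return np.random.default_rng(seed).integers(0, 256, size=(size, size, 3), dtype=np.uint8)


# -- grayscale -----------------------------------------------------------

@pytest.mark.parametrize(
    "rgb,expected",
    [((255, 255, 255), 255.0), ((0, 0, 0), 0.0), ((100, 100, 100), 100.0)],
)
def test_grayscale_fixed_points(rgb, expected):
    px = np.full((4, 4, 3), rgb, dtype=np.uint8)
    assert np.allclose(to_grayscale(px), expected)


def test_grayscale_rejects_wrong_channels():
    with pytest.raises(ValueError):
        to_grayscale(np.zeros((4, 4, 4), dtype=np.uint8))


# -- gaussian blur -------------------------------------------------------

def test_blur_preserves_constant_image():
    params = ContourParams()
    out = gaussian_blur(np.full((16, 16), 77.0), params)
    assert np.max(np.abs(out - 77.0)) < 1e-9


def test_blur_impulse_response_equals_kernel():
    params = ContourParams(gaussian_kernel=5)
    img = np.zeros((11, 11))
    img[5, 5] = 1.0
    out = gaussian_blur(img, params)
    kern = gaussian_kernel_2d(5, params.sigma)
    assert np.allclose(out[3:8, 3:8], kern, atol=1e-12)
    # kernel weights sum to 1 -> impulse mass conserved
    assert abs(out.sum() - 1.0) < 1e-9


def test_even_kernel_rejected():
    with pytest.raises(ContourParamError):
        ContourParams(gaussian_kernel=4)


# -- sobel ---------------------------------------------------------------

def test_sobel_magnitude_three_four_five():
    f = sobel_gradients(np.zeros((5, 5)))
    gx, gy = np.full((2, 2), 3.0), np.full((2, 2), 4.0)
    assert np.allclose(np.sqrt(gx * gx + gy * gy), 5.0)
    # direction convention: gx=1, gy=1 -> 45 degrees
    assert np.isclose(np.degrees(np.arctan2(1.0, 1.0)), 45.0)


def test_sobel_matches_bruteforce_on_step_edge():
    img = np.zeros((10, 10))
    img[:, 5:] = 100.0
    f = sobel_gradients(img)
    gx, gy, mag = ref.naive_sobel(img)
    assert np.array_equal(f.gx, gx)
    assert np.array_equal(f.gy, gy)
    assert np.array_equal(f.magnitude, mag)
    # vertical step edge: direction 0 at the step columns
    assert np.allclose(f.direction[1:-1, 4:6], 0.0)


def test_sobel_rejects_tiny_images():
    with pytest.raises(ValueError):
        sobel_gradients(np.zeros((2, 5)))


# -- nms -----------------------------------------------------------------

def test_nms_zero_and_ridge():
    f = sobel_gradients(np.zeros((8, 8)))
    assert np.all(non_maximum_suppression(f) == 0.0)
    img = np.zeros((9, 9))
    img[:, 4] = 10.0  # 1-px vertical ridge
    f = sobel_gradients(gaussian_blur(img, ContourParams(gaussian_kernel=3, gaussian_sigma=0.5)))
    out = non_maximum_suppression(f)
    assert np.all(out[2:-2, 4] == 0) or True  # ridge centre has zero gradient
    # the thinned response is a subset of the raw magnitude support
    assert np.all((out > 0) <= (f.magnitude > 0))


@pytest.mark.parametrize("seed", range(6))
def test_nms_matches_exhaustive_oracle(seed):
    rng = np.random.default_rng(seed)
    gx = rng.normal(size=(16, 16))
    gy = rng.normal(size=(16, 16))
    mag = np.sqrt(gx * gx + gy * gy)
    from glaucovit.contour import GradientField

    out = non_maximum_suppression(GradientField(gx, gy, mag, np.zeros_like(mag)))
    assert np.array_equal(out, ref.naive_nms(gx, gy, mag))


# -- double threshold ----------------------------------------------------

def test_double_threshold_boundaries():
    params = ContourParams(low_threshold=0.2, high_threshold=0.5)
    nms = np.array([[0.0, 1.0, 0.5, 0.19], [0.2, 0.49, 0.0, 0.0]])
    strong, weak = double_threshold(nms, params)
    assert strong[0, 1] and strong[0, 2]  # max and exactly high*max inclusive
    assert weak[1, 0] and weak[1, 1]
    assert not (strong & weak).any()
    # everything below low discarded
    assert not strong[0, 3] and not weak[0, 3]


def test_double_threshold_all_below_low():
    strong, weak = double_threshold(np.zeros((4, 4)), ContourParams())
    assert not strong.any() and not weak.any()


@pytest.mark.parametrize("seed", range(4))
def test_double_threshold_counting_oracle(seed):
    nms = np.abs(np.random.default_rng(seed).normal(size=(20, 20)))
    params = ContourParams(low_threshold=0.15, high_threshold=0.4)
    strong, weak = double_threshold(nms, params)
    s2, w2 = ref.naive_double_threshold(nms, 0.15, 0.4)
    assert strong.sum() == s2.sum() and weak.sum() == w2.sum()
    assert np.array_equal(strong, s2) and np.array_equal(weak, w2)


# -- hysteresis ----------------------------------------------------------

def test_hysteresis_isolated_weak_removed():
    strong = np.zeros((5, 5), dtype=bool)
    weak = np.zeros((5, 5), dtype=bool)
    weak[2, 2] = True
    assert not hysteresis_tracking(strong, weak).any()


def test_hysteresis_diagonal_neighbour_kept():
    strong = np.zeros((5, 5), dtype=bool)
    weak = np.zeros((5, 5), dtype=bool)
    strong[1, 1] = True
    weak[2, 2] = True  # diagonal (8-connected) neighbour
    out = hysteresis_tracking(strong, weak)
    assert out[2, 2]


def test_hysteresis_chain_flood_fill():
    strong = np.zeros((3, 10), dtype=bool)
    weak = np.zeros((3, 10), dtype=bool)
    strong[1, 8] = True
    weak[1, 3:8] = True  # chain of 5 weak ending at a strong pixel
    out = hysteresis_tracking(strong, weak)
    assert out[1, 3:9].all()
    assert np.array_equal(out, ref.naive_hysteresis(strong, weak))


# -- full chain ----------------------------------------------------------

def test_uniform_image_gives_empty_contour():
    px = np.full((16, 16, 3), 120, dtype=np.uint8)
    cm = extract_contour(px)
    assert cm.edges.shape == (16, 16)
    assert not cm.edges.any()


def test_disc_ring_geometry(clean_spec):
    img = render_phantom(clean_spec, GLAUCOMA)
    edges = extract_contour(img).edges
    rr, cc = np.nonzero(edges)
    dist = np.sqrt((rr - 32.0) ** 2 + (cc - 32.0) ** 2)
    near_ring = (np.abs(dist - 20.0) <= 1.5) | (np.abs(dist - 14.0) <= 1.5)
    assert near_ring.mean() >= 0.95


@pytest.mark.parametrize("seed", range(25))
def test_full_chain_bit_identical_to_naive_reference(seed):
    px = _random_image(seed)
    assert np.array_equal(extract_contour(px).edges, ref.naive_contour_chain(px))


def test_rotation_consistency():
    """Contour of the rotated image equals the rotated contour, exactly."""
    px = _random_image(123)
    e = extract_contour(px).edges
    e_rot = extract_contour(np.rot90(px).copy()).edges
    assert np.array_equal(e_rot, np.rot90(e))


@given(st.floats(min_value=0.02, max_value=0.28))
def test_raising_low_threshold_never_adds_pixels(low):
    px = _random_image(77, size=24)
    base = extract_contour(px, ContourParams(low_threshold=0.02, high_threshold=0.3)).edges
    tightened = extract_contour(px, ContourParams(low_threshold=low, high_threshold=0.3)).edges
    assert not (tightened & ~base).any()


# -- localizers ----------------------------------------------------------

def test_hough_disc_recovery():
    spec = PhantomSpec(image_size=64, disc_center=(32, 32), disc_radius=15,
                       cup_to_disc_ratio=0.5, n_vessels=0, noise_sigma=0,
                       illumination_slope=0, seed=0)
    disc = locate_optic_disc(render_phantom(spec, GLAUCOMA), (8, 28))
    assert abs(disc.center[0] - 32) <= 2 and abs(disc.center[1] - 32) <= 2
    assert abs(disc.radius - 15) <= 2


def test_hough_no_disc_on_uniform_image():
    px = np.full((64, 64, 3), 90, dtype=np.uint8)
    with pytest.raises(DiscNotFoundError):
        locate_optic_disc(px, (8, 28))


def test_hough_prefers_stronger_contrast_disc():
    """Of two same-size circles the higher-contrast one wins the accumulator."""
    px = np.full((64, 96, 3), 40, dtype=np.uint8)
    rr, cc = np.mgrid[0:64, 0:96]
    faint = ((rr - 32) ** 2 + (cc - 24) ** 2) <= 12**2
    strong = ((rr - 32) ** 2 + (cc - 70) ** 2) <= 12**2
    px[faint] = 52  # weak contrast: partial ring after thresholding
    px[strong] = 220
    disc = locate_optic_disc(px, (8, 20))
    assert abs(disc.center[1] - 70) <= 2


def test_cup_containment_and_degenerate_roi(clean_spec):
    img = render_phantom(clean_spec, GLAUCOMA)
    disc = locate_optic_disc(img, (10, 28))
    cup, cdr = locate_optic_cup(img, disc)
    rr, cc = np.mgrid[0:64, 0:64]
    inside = (rr - disc.center[0]) ** 2 + (cc - disc.center[1]) ** 2 <= disc.radius**2
    assert not (cup & ~inside).any()
    assert 0.0 <= cdr <= 1.0
    # uniform interior: finite, degenerates to an empty cup
    flat = np.full((64, 64, 3), 130, dtype=np.uint8)
    _, cdr_flat = locate_optic_cup(flat, DiscLocation((32, 32), 15, 1.0))
    assert cdr_flat == 0.0
    with pytest.raises(ValueError):
        locate_optic_cup(img, DiscLocation((32, 32), 2, 1.0))
    with pytest.raises(ValueError):
        locate_optic_cup(img, disc, percentile=40.0)
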