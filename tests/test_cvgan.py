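"""Conditional GAN: loss algebra against transcription oracles, gradient-
penalty closed forms, contracts of encode/generate/sample, training progress."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from glaucovit import nn
from glaucovit.cvgan import (
    CVGANState,
    LossWeights,
    aux_class_loss,
    discriminator_loss,
    encoder_generator_loss,
    entropy_monitor,
    gradient_penalty,
    interpolate_gp_sample,
    tiny_config,
    total_objective,
    train_cvgan,
)
from glaucovit.labels import GLAUCOMA, NORMAL
from glaucovit.phantom import PhantomSpec, generate_dataset

finite = st.floats(min_value=-100, max_value=100, allow_nan=False)
weight = st.floats(min_value=0, max_value=10, allow_nan=False)


# -- interpolation -------------------------------------------------------

def test_interpolation_endpoints_and_midpoint():
    x = np.zeros((2, 3))
    x_gen = np.full((2, 3), 2.0)
    assert np.array_equal(interpolate_gp_sample(x, x_gen, 1.0), x)
    assert np.array_equal(interpolate_gp_sample(x, x_gen, 0.0), x_gen)
    assert np.array_equal(interpolate_gp_sample(x, x_gen, 0.5), np.ones((2, 3)))
    with pytest.raises(ValueError):
        interpolate_gp_sample(x, x_gen, 1.5)


# -- loss algebra --------------------------------------------------------

@given(finite, finite, st.floats(min_value=0, max_value=100), st.floats(min_value=0, max_value=20), weight)
def test_discriminator_loss_transcription(ds_fake, ds_real, gp, lcel, lam2):
    w = LossWeights(lam2=lam2)
    expected = (ds_fake - ds_real) + gp - lam2 * lcel
    assert abs(discriminator_loss(ds_fake, ds_real, gp, lcel, w) - expected) < 1e-9


@given(finite, finite, st.floats(min_value=0, max_value=100),
       st.floats(min_value=0, max_value=20), weight, weight)
def test_encoder_generator_loss_transcription(ds_fake, cls, l1, lcel, lam4, lam5):
    w = LossWeights(lam4=lam4, lam5=lam5)
    expected = ds_fake + lam4 * cls - lam5 * l1 - lcel
    assert abs(encoder_generator_loss(ds_fake, cls, l1, lcel, w) - expected) < 1e-9


def test_loss_fixed_examples():
    w = LossWeights()
    assert discriminator_loss(1.0, 1.0, 0.0, 0.0, w) == 0.0
    assert abs(discriminator_loss(2.0, 1.0, 10.0, 1.6094, w) - 9.3906) < 1e-9
    assert abs(encoder_generator_loss(1.0, -0.1, 0.5, 0.2, w) - 0.2) < 1e-9
    # perfect reconstruction and vanished class terms leave the critic score
    assert encoder_generator_loss(3.7, 0.0, 0.0, 0.0, w) == 3.7
    assert abs(total_objective(0.2, 9.3906) - 9.5906) < 1e-9
    assert total_objective(0.0, 0.0) == 0.0
    assert total_objective(1.5, -2.5) == total_objective(-2.5, 1.5)


@given(finite, st.floats(min_value=0, max_value=5))
def test_discriminator_loss_linear_in_real_score(ds_real, delta):
    w = LossWeights()
    base = discriminator_loss(1.0, ds_real, 2.0, 0.5, w)
    shifted = discriminator_loss(1.0, ds_real + delta, 2.0, 0.5, w)
    assert abs((base - shifted) - delta) < 1e-9


@given(st.floats(min_value=0, max_value=5), st.floats(min_value=0, max_value=4))
def test_eg_loss_linear_in_l1(l1, delta):
    w = LossWeights(lam5=1.0)
    base = encoder_generator_loss(1.0, 0.0, l1, 0.0, w)
    worse = encoder_generator_loss(1.0, 0.0, l1 + delta, 0.0, w)
    assert abs((base - worse) - delta) < 1e-9


# -- auxiliary classifier loss -------------------------------------------

def test_aux_class_loss_closed_forms():
    # true-class probability 1 -> 0
    logits = np.array([100.0, 0.0, 0.0, 0.0, 0.0])
    assert aux_class_loss(logits, GLAUCOMA).item() < 1e-12
    # uniform probabilities -> ln 5
    assert abs(aux_class_loss(np.zeros(5), NORMAL).item() - np.log(5.0)) < 1e-9
    with pytest.raises(ValueError):
        aux_class_loss(np.zeros(5), np.array([7]))


@pytest.mark.parametrize("seed", range(5))
def test_aux_class_loss_matches_softmax_log_oracle(seed):
    rng = np.random.default_rng(seed)
    logits = rng.normal(size=(6, 5)) * 3.0
    codes = rng.integers(0, 5, size=6)
    z = logits - logits.max(axis=1, keepdims=True)
    p = np.exp(z) / np.exp(z).sum(axis=1, keepdims=True)
    expected = -np.mean(np.log(p[np.arange(6), codes]))
    got = aux_class_loss(nn.Tensor(logits), codes).item()
    assert abs(got - expected) < 1e-9


def test_entropy_monitor_uniform_is_ln5():
    assert abs(entropy_monitor(np.zeros((3, 5))) - np.log(5.0)) < 1e-9


# -- gradient penalty ----------------------------------------------------

def test_gradient_penalty_closed_forms(rng):
    lam1 = LossWeights().lam1
    assert lam1 == 10.0
    w = rng.normal(size=(16, 1))
    w /= np.linalg.norm(w)
    x_hat = nn.Tensor(rng.normal(size=(5, 16)), requires_grad=True)

    def linear_critic(scale):
        return lambda t: nn.matmul(t, nn.Tensor(scale * w))

    # unit-norm linear critic: gradient norm 1 everywhere -> penalty 0
    assert abs(gradient_penalty(linear_critic(1.0), x_hat, lam1).item()) < 1e-6
    # constant critic: zero gradient -> (0-1)^2 -> lam1
    const = lambda t: nn.mul(nn.tsum(t, axis=1, keepdims=True), 0.0)
    assert abs(gradient_penalty(const, x_hat, lam1).item() - 10.0) < 1e-5
    # doubled critic: (2-1)^2 -> lam1
    assert abs(gradient_penalty(linear_critic(2.0), x_hat, lam1).item() - 10.0) < 1e-5


# -- model contracts -----------------------------------------------------

@pytest.fixture(scope="module")
def gan_state():
    return CVGANState(tiny_config(seed=0))


@pytest.fixture(scope="module")
def phantom16():
    spec = PhantomSpec(image_size=16, disc_center=(8, 8), disc_radius=5,
                       cup_to_disc_ratio=0.5, n_vessels=0, noise_sigma=2.0,
                       illumination_slope=0.0)
    _, imgs = generate_dataset({GLAUCOMA: 16, NORMAL: 16}, spec, seed=11)
    return imgs


def test_encoder_output_contracts(gan_state, phantom16):
    out = gan_state.encode(phantom16[0].pixels)
    assert abs(out.class_probs.sum() - 1.0) < 1e-6
    assert np.all(out.class_probs >= 0)
    assert out.latent.shape == (gan_state.cfg.latent_dim,)
    out2 = gan_state.encode(phantom16[0].pixels)
    assert np.array_equal(out.class_probs, out2.class_probs)
    assert np.array_equal(out.latent, out2.latent)
    with pytest.raises(ValueError):
        gan_state.encode(np.zeros((8, 8, 3), dtype=np.uint8))


def test_generator_output_contracts(gan_state, rng):
    z = rng.standard_normal(gan_state.cfg.latent_dim)
    img = gan_state.generate(z, GLAUCOMA)
    assert img.shape == (3, 16, 16)
    assert np.array_equal(img, gan_state.generate(z, GLAUCOMA))
    for _ in range(20):
        out = gan_state.generate(rng.standard_normal(gan_state.cfg.latent_dim), NORMAL)
        assert out.min() >= -1.0 and out.max() <= 1.0
    with pytest.raises(ValueError):
        gan_state.generate(np.full(gan_state.cfg.latent_dim, np.nan), GLAUCOMA)
    with pytest.raises(ValueError):
        gan_state.generate(z, "glaucoma")


def test_sample_synthetic_counts_and_determinism(gan_state):
    imgs, rows = gan_state.sample_synthetic({GLAUCOMA: 7}, seed=3)
    assert len(imgs) == 7
    assert all(im.label == GLAUCOMA and im.source == "generated" for im in imgs)
    imgs2, _ = gan_state.sample_synthetic({GLAUCOMA: 7}, seed=3)
    assert all(np.array_equal(a.pixels, b.pixels) for a, b in zip(imgs, imgs2))
    with pytest.raises(ValueError):
        gan_state.sample_synthetic({GLAUCOMA: -1}, seed=0)


def test_training_short_run_stable_and_deterministic(phantom16):
    hist_a = train_cvgan(CVGANState(tiny_config(seed=5)), phantom16, n_steps=12)
    assert all(np.isfinite(list(rec.values())).all() for rec in hist_a)
    hist_b = train_cvgan(CVGANState(tiny_config(seed=5)), phantom16, n_steps=12)
    for ra, rb in zip(hist_a, hist_b):
        assert ra == rb


@pytest.mark.timeout(1500)
def test_conditional_fidelity_and_reconstruction_path():
    """After training on noiseless two-level phantoms (CDR 0.3 vs 0.7), the
    CDR probe on generated samples ranks the glaucoma condition higher in
    most seeds, and the reconstruction path G(E(x), y) ends with a lower
    mean L1 to x than at initialization in every seed."""
    from glaucovit.contour import DiscLocation, locate_optic_cup

    spec = PhantomSpec(image_size=16, disc_center=(8, 8), disc_radius=5,
                       noise_sigma=0.0, n_vessels=0, illumination_slope=0.0)
    disc = DiscLocation((8, 8), 5, 1.0)
    fidelity_wins = 0
    for seed in (0, 1, 2):
        _, imgs = generate_dataset({GLAUCOMA: 24, NORMAL: 24}, spec,
                                   seed=50 + seed, jitter=False)
        state = CVGANState(tiny_config(seed=seed))
        probe = np.stack([state.to_model_range(im.pixels) for im in imgs[:16]])
        l1_init = state.reconstruction_l1(probe)
        train_cvgan(state, imgs, n_steps=1000)
        assert state.reconstruction_l1(probe) < l1_init  # per-seed improvement
        medians = {}
        for lab in (GLAUCOMA, NORMAL):
            gen, _ = state.sample_synthetic({lab: 50}, seed=seed + 1)
            medians[lab] = np.median([locate_optic_cup(g.pixels, disc)[1] for g in gen])
        fidelity_wins += medians[GLAUCOMA] > medians[NORMAL]
    assert fidelity_wins >= 2


def test_checkpoint_roundtrip(tmp_path, phantom16):
    state = CVGANState(tiny_config(seed=2))
    train_cvgan(state, phantom16, n_steps=3)
    path = tmp_path / "ck.npz"
    state.save(path)
    fresh = CVGANState(tiny_config(seed=9))
    fresh.load(path)
    z = np.zeros(state.cfg.latent_dim)
    assert np.array_equal(state.generate(z, GLAUCOMA), fresh.generate(z, GLAUCOMA))
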