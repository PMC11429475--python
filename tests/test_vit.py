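"""Transformer classifier: alignment algebra, weighted cross-entropy
identities, backbone contracts, weight sharing, attention export."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from glaucovit import nn
from glaucovit.labels import ALL_LABELS, GLAUCOMA, NORMAL
from glaucovit.vit import (
    Backbone,
    BackboneConfig,
    ClassifierState,
    align_features,
    backbone_forward,
    class_weights_from_counts,
    export_attention_maps,
    export_features,
    load_classifier,
    predict,
    save_classifier,
    train_classifier,
    weighted_cross_entropy,
)

TINY = BackboneConfig(image_size=32, patch_size=8, hidden=32, n_encoder_layers=1,
                      n_decoder_layers=1, n_heads=2, n_queries=4, dropout=0.0)


@pytest.fixture(scope="module")
def tiny_backbone():
    return Backbone(TINY, seed=0)


def _img(seed, n=1, size=32):
    return np.random.default_rng(seed).integers(0, 256, size=(n, size, size, 3), dtype=np.uint8)


# -- alignment -----------------------------------------------------------

def test_align_additive_identity_and_commutativity():
    a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    b = np.array([5.0, 4.0, 3.0, 2.0, 1.0])
    assert np.array_equal(align_features(a, np.zeros(5)), a)
    assert np.array_equal(align_features(a, b), align_features(b, a))
    assert np.array_equal(align_features(a, b), np.full(5, 6.0))
    with pytest.raises(ValueError):
        align_features(a, np.zeros(4))


# -- class weights -------------------------------------------------------

def test_class_weights_formula():
    balanced = {lab: 100 for lab in ALL_LABELS}
    assert np.allclose(class_weights_from_counts(balanced), 1.0)
    counts = dict(zip(ALL_LABELS, (100, 100, 100, 100, 600)))
    w = class_weights_from_counts(counts)
    assert np.allclose(w, [2.0, 2.0, 2.0, 2.0, 1.0 / 3.0])
    with pytest.raises(ValueError):
        class_weights_from_counts({GLAUCOMA: 10, NORMAL: 0})


@given(st.lists(st.integers(min_value=1, max_value=500), min_size=5, max_size=5))
def test_class_weights_conservation_identity(ns):
    """sum_j w_j n_j = N for inverse-frequency weights."""
    counts = dict(zip(ALL_LABELS, ns))
    w = class_weights_from_counts(counts)
    assert abs(sum(w[l.code] * n for l, n in counts.items()) - sum(ns)) < 1e-9


# -- weighted cross-entropy ----------------------------------------------

def test_weighted_ce_closed_forms():
    p = np.zeros((1, 5))
    p[0, 2] = 1.0
    assert weighted_cross_entropy(p, [2], np.ones(5)) == 0.0
    p = np.full((1, 5), 0.125)
    p[0, 1] = 0.5
    w = np.ones(5)
    w[1] = 2.0
    assert abs(weighted_cross_entropy(p, [1], w) - 2.0 * np.log(2.0)) < 1e-12


@pytest.mark.parametrize("seed", range(5))
def test_weighted_ce_double_loop_oracle(seed):
    rng = np.random.default_rng(seed)
    probs = rng.dirichlet(np.ones(5), size=8)
    codes = rng.integers(0, 5, size=8)
    w = rng.uniform(0.2, 3.0, size=5)
    expected = 0.0
    for i in range(8):  # naive transcription: -(1/N) sum_i sum_j w_j 1(y_i=j) log p_ij
        for j in range(5):
            if codes[i] == j:
                expected -= w[j] * np.log(probs[i, j])
    expected /= 8
    assert abs(weighted_cross_entropy(probs, codes, w) - expected) < 1e-9
    # unit weights reduce to the unweighted cross-entropy
    unweighted = -np.mean(np.log(probs[np.arange(8), codes]))
    assert abs(weighted_cross_entropy(probs, codes, np.ones(5)) - unweighted) < 1e-9
    # batch-mean form times N equals the sum form
    assert abs(8 * weighted_cross_entropy(probs, codes, w) - 8 * expected) < 1e-9


def test_weighted_ce_zero_probability_clamped():
    p = np.zeros((1, 5))
    p[0, 0] = 1.0
    with pytest.warns(UserWarning):
        val = weighted_cross_entropy(p, [3], np.ones(5))
    assert np.isfinite(val) and val > 0


def test_weighted_ce_tensor_and_numpy_agree(rng):
    probs = rng.dirichlet(np.ones(5), size=6)
    codes = rng.integers(0, 5, size=6)
    w = rng.uniform(0.5, 2.0, size=5)
    a = weighted_cross_entropy(probs, codes, w)
    b = weighted_cross_entropy(nn.Tensor(probs), codes, w).item()
    assert abs(a - b) < 1e-12


# -- backbone ------------------------------------------------------------

def test_backbone_output_shape_and_determinism(tiny_backbone):
    x = _img(0, n=3)
    out = backbone_forward(tiny_backbone, x)
    assert out.shape == (3, 5)
    assert np.array_equal(out, backbone_forward(tiny_backbone, x))


def test_backbone_batch_independence(tiny_backbone):
    x = _img(1, n=4)
    batched = backbone_forward(tiny_backbone, x)
    single = np.concatenate([backbone_forward(tiny_backbone, x[i : i + 1]) for i in range(4)])
    assert np.max(np.abs(batched - single)) < 1e-5


def test_backbone_rejects_wrong_resolution(tiny_backbone):
    with pytest.raises(ValueError):
        backbone_forward(tiny_backbone, _img(0, n=1, size=16))


def test_config_validation():
    with pytest.raises(ValueError):
        BackboneConfig(hidden=30, n_heads=4)
    with pytest.raises(ValueError):
        BackboneConfig(image_size=100, patch_size=32)


# -- prediction ----------------------------------------------------------

def test_predict_contract(tiny_backbone):
    state = ClassifierState(tiny_backbone, TINY, np.ones(5), trained=False)
    with pytest.warns(UserWarning):
        p = predict(state, _img(3)[0])
    assert abs(p.scores.sum() - 1.0) < 1e-6
    assert p.label.code == int(np.argmax(p.scores))


def test_predict_never_touches_contour_pipeline(tiny_backbone, monkeypatch):
    import glaucovit.contour as contour_mod

    calls = {"n": 0}

    def spy(*a, **k):
        calls["n"] += 1
        raise AssertionError("contour pipeline invoked at inference")

    monkeypatch.setattr(contour_mod, "extract_contour", spy)
    state = ClassifierState(tiny_backbone, TINY, np.ones(5), trained=True)
    predict(state, _img(4)[0])
    assert calls["n"] == 0


# -- training ------------------------------------------------------------

def _training_triples(n_per_class=8):
    from glaucovit.contour import contour_to_image, extract_contour
    from glaucovit.labels import SUSPECT
    from glaucovit.phantom import PhantomSpec, generate_dataset

    spec = PhantomSpec(image_size=32, disc_center=(16, 16), disc_radius=7, noise_sigma=2.0)
    _, imgs = generate_dataset(
        {GLAUCOMA: n_per_class, NORMAL: n_per_class, SUSPECT: n_per_class}, spec, seed=21
    )
    x = np.stack([im.pixels for im in imgs])
    c = np.stack([contour_to_image(extract_contour(im)) for im in imgs])
    y = np.array([im.label.code for im in imgs])
    return x, c, y


def test_training_deterministic_and_loss_decreases():
    x, c, y = _training_triples()
    cfg = BackboneConfig(image_size=32, patch_size=8, hidden=32, n_encoder_layers=1,
                         n_decoder_layers=1, n_heads=2, n_queries=4, dropout=0.1, lr=3e-4)
    _, h1 = train_classifier(x, c, y, cfg, seed=3, epochs=3, batch_size=12)
    _, h2 = train_classifier(x, c, y, cfg, seed=3, epochs=3, batch_size=12)
    assert h1 == h2  # bit-identical loss history under a fixed seed
    assert h1[-1]["train_loss"] <= h1[0]["train_loss"]


def test_training_requires_paired_contours():
    x, c, y = _training_triples(4)
    with pytest.raises(ValueError):
        train_classifier(x, c[:-1], y, TINY, seed=0, epochs=1)


def test_shared_backbone_weights():
    """Both branches of the alignment use the very same parameter objects."""
    x, c, y = _training_triples(4)
    state, _ = train_classifier(x, c, y, TINY, seed=0, epochs=1, batch_size=12)
    # one Backbone instance serves both branches: predicting from the contour
    # input uses the identical parameters as predicting from the image input
    assert predict(state, x[0]).scores.shape == predict(state, c[0]).scores.shape
    assert len({id(p) for p in state.backbone.parameters()}) == len(state.backbone.parameters())


def test_resume_reproduces_uninterrupted_run(tmp_path):
    """Stopping after epoch 2 and resuming yields the exact epoch-3 record
    of an uninterrupted run (optimizer and generator state round-trip)."""
    from glaucovit.vit import ClassifierTrainer

    x, c, y = _training_triples(6)
    cfg = BackboneConfig(image_size=32, patch_size=8, hidden=32, n_encoder_layers=1,
                         n_decoder_layers=1, n_heads=2, n_queries=4, dropout=0.1, lr=3e-4)
    straight = ClassifierTrainer(x, c, y, cfg, seed=7, batch_size=9)
    straight.run(3)

    first = ClassifierTrainer(x, c, y, cfg, seed=7, batch_size=9)
    first.run(2)
    path = tmp_path / "trainer.npz"
    first.save(path)
    resumed = ClassifierTrainer(x, c, y, cfg, seed=7, batch_size=9)
    resumed.resume(path)
    resumed.run(1)
    assert resumed.history[-1] == straight.history[-1]


def test_checkpoint_roundtrip(tmp_path):
    x, c, y = _training_triples(4)
    state, _ = train_classifier(x, c, y, TINY, seed=1, epochs=1, batch_size=12)
    path = tmp_path / "clf.npz"
    save_classifier(state, path)
    loaded = load_classifier(path)
    a = predict(state, x[0]).scores
    b = predict(loaded, x[0]).scores
    assert np.allclose(a, b, atol=1e-12)
    with pytest.raises(ValueError):
        bad = tmp_path / "bad.npz"
        np.savez_compressed(bad, junk=np.zeros(3))
        load_classifier(bad)


# -- attention and features ----------------------------------------------

def test_attention_maps_normalized(tiny_backbone):
    state = ClassifierState(tiny_backbone, TINY, np.ones(5), trained=True)
    pre, up = export_attention_maps(state, _img(5)[0])
    assert pre.shape == (TINY.n_decoder_layers, TINY.n_heads, TINY.n_tokens)
    assert up.shape == (TINY.n_decoder_layers, TINY.n_heads, 32, 32)
    assert np.allclose(pre.sum(axis=-1), 1.0, atol=1e-6)
    # constant input: near-uniform attention for an untrained net
    flat = np.full((32, 32, 3), 128, dtype=np.uint8)
    pre_flat, _ = export_attention_maps(state, flat)
    assert (pre_flat.max() / pre_flat.min()) < 10.0


def test_export_features_consistency(tiny_backbone):
    state = ClassifierState(tiny_backbone, TINY, np.ones(5), trained=True)
    x = np.concatenate([_img(6, n=2), _img(6, n=2)])
    feats = export_features(state, x)
    assert feats.shape == (4, TINY.hidden)
    assert np.allclose(feats[:2], feats[2:], atol=1e-12)  # identical inputs
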