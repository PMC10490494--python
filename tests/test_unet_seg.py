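"""U-Net / FCN construction, softmax head, training and tiled prediction."""

import numpy as np
import pytest

from histoseg import nn
from histoseg.errors import (
    InvalidParameterError,
    InvalidSpecError,
    StateError,
    ValidationError,
)
from histoseg.unet_seg import (
    FCN,
    SegNetworkSpec,
    UNet,
    build_fcn,
    build_unet,
    load_segmenter,
    n_parameters,
    pixel_softmax,
    predict_mask,
    save_segmenter,
    train_segmenter,
)

SMALL = SegNetworkSpec(depth=2, base_filters=4, convs_per_block=2, input_size=16)


def test_pixel_softmax_closed_forms():
    out = pixel_softmax(np.zeros((1, 1, 2)))
    assert np.allclose(out, 0.5)
    out = pixel_softmax(np.array([[[1.0, 0.0]]]))
    e = np.e
    assert out[0, 0, 0] == pytest.approx(e / (e + 1))
    assert out[0, 0, 1] == pytest.approx(1 / (e + 1))


def test_pixel_softmax_properties(rng):
    acts = rng.normal(size=(6, 5, 3)) * 50
    probs = pixel_softmax(acts)
    assert np.abs(probs.sum(axis=2) - 1).max() < 1e-6
    shifted = pixel_softmax(acts + 17.3)
    assert np.allclose(probs, shifted, atol=1e-10)
    with pytest.raises(ValidationError):
        pixel_softmax(np.array([[[np.inf, 0.0]]]))
    with pytest.raises(ValidationError):
        pixel_softmax(np.zeros((3, 3, 1)))


def test_spec_validation():
    with pytest.raises(InvalidSpecError):
        SegNetworkSpec(depth=3, input_size=30).validate()
    with pytest.raises(InvalidSpecError):
        SegNetworkSpec(n_classes=1).validate()
    SegNetworkSpec().validate()


def test_unet_output_contract(rng):
    model = build_unet(SMALL, seed=0)
    x = rng.uniform(size=(2, 3, 16, 16)).astype(np.float32)
    logits = model.forward(x, train=False)
    assert logits.shape == (2, 2, 16, 16)
    probs = nn.softmax_probs(logits)
    assert np.abs(probs.sum(axis=1) - 1).max() < 1e-6
    assert model.n_skip_connections == SMALL.depth


def test_improved_blocks_add_parameters():
    classic = build_unet(SegNetworkSpec(depth=2, base_filters=4, convs_per_block=2))
    improved = build_unet(SegNetworkSpec(depth=2, base_filters=4, convs_per_block=3))
    assert n_parameters(improved) > n_parameters(classic)


def test_fcn_contract_matches_unet(rng):
    fcn = build_fcn(SMALL, seed=0)
    assert fcn.n_skip_connections == 0
    x = rng.uniform(size=(2, 3, 16, 16)).astype(np.float32)
    logits = fcn.forward(x, train=False)
    assert logits.shape == (2, 2, 16, 16)
    probs = nn.softmax_probs(logits)
    assert np.abs(probs.sum(axis=1) - 1).max() < 1e-6


def _toy_pairs(rng, n=8, size=16):
    """Dark blobs on light background with exact masks."""
    pairs = []
    for _ in range(n):
        mask = np.zeros((size, size), dtype=np.uint8)
        r, c = rng.integers(2, size - 6, 2)
        mask[r : r + 5, c : c + 5] = 1
        img = np.full((size, size, 3), 0.9)
        img[mask == 1] = 0.2
        img = np.clip(img + rng.normal(0, 0.02, img.shape), 0, 1)
        pairs.append((img, mask))
    return pairs


def test_training_reduces_loss_and_records_history(rng):
    pairs = _toy_pairs(rng)
    model = build_unet(SMALL, seed=0)
    model, hist = train_segmenter(model, pairs, epochs=5, batch_size=4, seed=0)
    assert len(hist.losses) == 5 and len(hist.accuracies) == 5
    assert all(l >= 0 for l in hist.losses)
    assert hist.losses[-1] < hist.losses[0]
    assert model.trained


def test_training_validation_errors(rng):
    model = build_unet(SMALL, seed=0)
    with pytest.raises(InvalidParameterError):
        train_segmenter(model, [], epochs=1, seed=0)
    bad_mask = [(np.zeros((16, 16, 3)), np.full((16, 16), 2))]
    with pytest.raises(ValidationError):
        train_segmenter(model, bad_mask, epochs=1, seed=0)


def test_predict_untrained_raises(rng):
    model = build_unet(SMALL, seed=0)
    with pytest.raises(StateError):
        predict_mask(model, rng.uniform(size=(16, 16, 3)), 16, 16)


class _ConstantHead:
    """Stub whose head always emits activations (0, 10) -> class 1."""

    def __init__(self):
        self.spec = SegNetworkSpec(depth=1, base_filters=1, input_size=16)
        self.trained = True

    def forward(self, x, train=False):
        logits = np.zeros((x.shape[0], 2, 16, 16), dtype=np.float32)
        logits[:, 1] = 10.0
        return logits


def test_forced_argmax_gives_all_ones(rng):
    mask = predict_mask(_ConstantHead(), rng.uniform(size=(30, 20, 3)), 16, 16)
    assert mask.shape == (30, 20)
    assert np.all(mask == 1)


class _TieHead(_ConstantHead):
    def forward(self, x, train=False):
        return np.zeros((x.shape[0], 2, 16, 16), dtype=np.float32)


def test_probability_half_tie_goes_foreground(rng):
    mask = predict_mask(_TieHead(), rng.uniform(size=(16, 16, 3)), 16, 16)
    assert np.all(mask == 1)


def test_overlapping_and_disjoint_strides_agree_for_constant_model(rng):
    image = rng.uniform(size=(32, 32, 3))
    a = predict_mask(_ConstantHead(), image, 16, 16)
    b = predict_mask(_ConstantHead(), image, 16, 8)
    assert np.array_equal(a, b)


@pytest.fixture(scope="module")
def trained_small():
    rng = np.random.default_rng(7)
    pairs = _toy_pairs(rng, n=12)
    model = build_unet(SMALL, seed=0)
    model, _ = train_segmenter(model, pairs, epochs=25, batch_size=4, seed=0)
    return model, pairs


def test_predict_is_deterministic_and_learns_blobs(trained_small, rng):
    model, pairs = trained_small
    image, mask = pairs[0]
    a = predict_mask(model, image, 16, 16)
    b = predict_mask(model, image, 16, 16)
    assert np.array_equal(a, b)
    # training pair should be mostly recovered
    assert (a == mask).mean() > 0.9


def test_all_zero_masks_drive_foreground_down(rng):
    pairs = [(img, np.zeros_like(mask)) for img, mask in _toy_pairs(rng, n=6)]
    model = build_unet(SMALL, seed=0)
    model, _ = train_segmenter(model, pairs, epochs=10, batch_size=4, seed=0)
    pred = predict_mask(model, pairs[0][0], 16, 16)
    assert pred.mean() < 0.05


def test_segmenter_checkpoint_round_trip(trained_small, tmp_path):
    model, pairs = trained_small
    save_segmenter(model, tmp_path / "seg")
    model2 = load_segmenter(tmp_path / "seg")
    assert model2.trained and isinstance(model2, UNet)
    image = pairs[1][0]
    assert np.array_equal(
        predict_mask(model, image, 16, 16), predict_mask(model2, image, 16, 16)
    )


def test_fcn_trains_with_same_interface(rng):
    pairs = _toy_pairs(rng, n=6)
    fcn = build_fcn(SMALL, seed=0)
    fcn, hist = train_segmenter(fcn, pairs, epochs=3, batch_size=3, seed=0)
    assert len(hist.losses) == 3
    assert isinstance(fcn, FCN)
    pred = predict_mask(fcn, pairs[0][0], 16, 16)
    assert pred.shape == (16, 16)
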