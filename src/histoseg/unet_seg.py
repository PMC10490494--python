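"""Supervised segmentation: improved U-Net and an FCN baseline.

The U-Net is an encoder-decoder. Encoder blocks (conv3x3 -> batch-norm
-> ReLU, repeated ``convs_per_block`` times, then 2x2 max-pool) trade
spatial extent for feature depth; the decoder recovers resolution with
2x2 up-convolutions and concatenates the matching encoder feature map
at every level (skip connections). The head is a 1x1 convolution to
``n_classes`` channels followed by a per-pixel channel softmax

    p_k(x) = exp(a_k(x)) / sum_k' exp(a_k'(x))

trained with pixel-wise cross-entropy against one-hot masks. The
classic architecture uses two convolutions per block; the improved
variant deepens every block (default three), which is the only
difference between the two and is exposed as ``convs_per_block``.

The FCN baseline follows the AlexNet-style recipe: a convolutional
encoder with a large-kernel first layer and no skip connections, a 1x1
classifier, and stacked transposed convolutions to upscale the coarse
score map back to input resolution.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import nn
from .cae_cluster import TrainingHistory
from .errors import (
    InvalidParameterError,
    InvalidSpecError,
    StateError,
    ValidationError,
)
from .patching import extract_patches


@dataclasses.dataclass
class SegNetworkSpec:
    """Hyperparameters shared by the U-Net and the FCN baseline."""

    depth: int = 3
    base_filters: int = 8
    convs_per_block: int = 3  # 2 = classic U-Net block; >=3 = improved
    n_classes: int = 2
    input_size: int = 64

    def validate(self) -> None:
        if self.depth < 1 or self.base_filters < 1 or self.convs_per_block < 1:
            raise InvalidSpecError("depth, base_filters, convs_per_block must be >= 1")
        if self.n_classes < 2:
            raise InvalidSpecError("n_classes must be >= 2")
        if self.input_size % (2**self.depth) != 0:
            raise InvalidSpecError(
                f"input_size {self.input_size} not divisible by 2^{self.depth}"
            )


def pixel_softmax(activations: np.ndarray) -> np.ndarray:
    """Per-pixel channel softmax of an (H, W, K) activation map.

    Stabilized by subtracting the per-pixel maximum, to which the result
    is invariant. Channel sums are 1 up to floating-point rounding.
    """
    activations = np.asarray(activations, dtype=np.float64)
    if activations.ndim != 3 or activations.shape[2] < 2:
        raise ValidationError(f"expected (H, W, K>=2) activations, got {activations.shape}")
    if not np.isfinite(activations).all():
        raise ValidationError("activations must be finite")
    shifted = activations - activations.max(axis=2, keepdims=True)
    exp = np.exp(shifted)
    return exp / exp.sum(axis=2, keepdims=True)


def _conv_block(in_ch: int, out_ch: int, n_convs: int, rng) -> nn.Sequential:
    layers: list[nn.Layer] = []
    for j in range(n_convs):
        layers += [
            nn.Conv2d(in_ch if j == 0 else out_ch, out_ch, 3, rng),
            nn.BatchNorm2d(out_ch),
            nn.ReLU(),
        ]
    return nn.Sequential(*layers)


class UNet:
    """Encoder-decoder with skip connections and a softmax head."""

    kind = "unet"

    def __init__(self, spec: SegNetworkSpec, seed: int = 0):
        spec.validate()
        self.spec = spec
        self.trained = False
        rng = np.random.default_rng(seed)
        d, f, m = spec.depth, spec.base_filters, spec.convs_per_block
        enc_ch = [f * 2**i for i in range(d)]  # per-level feature width
        self.enc_blocks, self.pools = [], []
        in_ch = 3
        for ch in enc_ch:
            self.enc_blocks.append(_conv_block(in_ch, ch, m, rng))
            self.pools.append(nn.MaxPool2d())
            in_ch = ch
        self.bottleneck = _conv_block(enc_ch[-1], f * 2**d, m, rng)
        self.ups, self.dec_blocks = [], []
        up_in = f * 2**d
        for ch in reversed(enc_ch):
            self.ups.append(nn.ConvTranspose2d(up_in, ch, rng))
            self.dec_blocks.append(_conv_block(2 * ch, ch, m, rng))
            up_in = ch
        self.head = nn.Conv2d(enc_ch[0], spec.n_classes, 1, rng)
        self.root = nn.Sequential(
            *self.enc_blocks, self.bottleneck, *self.ups, *self.dec_blocks, self.head
        )
        self._enc_ch = enc_ch

    @property
    def n_skip_connections(self) -> int:
        return self.spec.depth

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        skips = []
        h = x
        for block, pool in zip(self.enc_blocks, self.pools):
            h = block.forward(h, train=train)
            skips.append(h)
            h = pool.forward(h, train=train)
        h = self.bottleneck.forward(h, train=train)
        for up, dec, skip in zip(self.ups, self.dec_blocks, reversed(skips)):
            h = up.forward(h, train=train)
            h = np.concatenate([skip, h], axis=1)
            h = dec.forward(h, train=train)
        return self.head.forward(h, train=train)

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        dh = self.head.backward(dlogits)
        dskips = []
        # decoder levels were applied deepest-first; undo shallowest-first
        for up, dec, ch in zip(
            reversed(self.ups), reversed(self.dec_blocks), self._enc_ch
        ):
            dcat = dec.backward(dh)
            dskips.append(dcat[:, :ch])
            dh = up.backward(dcat[:, ch:])
        dh = self.bottleneck.backward(dh)
        for block, pool, dskip in zip(
            reversed(self.enc_blocks), reversed(self.pools), reversed(dskips)
        ):
            dh = pool.backward(dh)
            dh = dh + dskip
            dh = block.backward(dh)
        return dh


class FCN:
    """AlexNet-style fully convolutional baseline: no skip connections."""

    kind = "fcn"
    n_skip_connections = 0

    def __init__(self, spec: SegNetworkSpec, seed: int = 0):
        spec.validate()
        self.spec = spec
        self.trained = False
        rng = np.random.default_rng(seed)
        f, d, k = spec.base_filters, spec.depth, spec.n_classes
        kernels = [7, 5] + [3] * max(d - 2, 0)  # large first kernel, shrinking
        layers: list[nn.Layer] = []
        in_ch = 3
        for level in range(d):
            out_ch = f * 2 ** min(level, 2)
            layers += [
                nn.Conv2d(in_ch, out_ch, kernels[level], rng),
                nn.BatchNorm2d(out_ch),
                nn.ReLU(),
                nn.MaxPool2d(),
            ]
            in_ch = out_ch
        # 1x1 "fully connected" classifier stage, then learned upsampling
        layers += [nn.Conv2d(in_ch, in_ch, 1, rng), nn.ReLU()]
        for _level in range(d):
            out_ch = max(in_ch // 2, k)
            layers += [nn.ConvTranspose2d(in_ch, out_ch, rng), nn.ReLU()]
            in_ch = out_ch
        layers.append(nn.Conv2d(in_ch, k, 1, rng))
        self.root = nn.Sequential(*layers)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return self.root.forward(x, train=train)

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        return self.root.backward(dlogits)


def build_unet(spec: SegNetworkSpec, seed: int = 0) -> UNet:
    return UNet(spec, seed=seed)


def build_fcn(spec: SegNetworkSpec, seed: int = 0) -> FCN:
    return FCN(spec, seed=seed)


def n_parameters(model) -> int:
    return sum(p.size for layer in nn.iter_layers(model.root) for p in layer.params.values())


def _dataset_to_arrays(dataset, input_size: int) -> tuple[np.ndarray, np.ndarray]:
    if len(dataset) == 0:
        raise InvalidParameterError("empty training dataset")
    images, masks = [], []
    for image, mask in dataset:
        image = np.asarray(image, dtype=np.float32)
        mask = np.asarray(mask)
        if image.shape[:2] != (input_size, input_size) or image.shape[2] != 3:
            raise ValidationError(
                f"image patch shape {image.shape} != ({input_size}, {input_size}, 3)"
            )
        if mask.shape != (input_size, input_size):
            raise ValidationError(f"mask patch shape {mask.shape} mismatches image")
        if not np.isin(mask, (0, 1)).all():
            raise ValidationError("mask values must be 0 or 1")
        images.append(image.transpose(2, 0, 1))
        masks.append(mask.astype(np.int64))
    return np.stack(images), np.stack(masks)


def train_segmenter(
    model,
    dataset: Sequence[tuple[np.ndarray, np.ndarray]],
    epochs: int = 200,
    learning_rate: float = 1e-3,
    batch_size: int = 8,
    seed: int = 0,
) -> tuple[object, TrainingHistory]:
    """Train a U-Net or FCN with pixel-wise softmax cross-entropy (Adam).

    ``dataset`` is a sequence of (image patch, binary mask patch) pairs
    matching the model's input size. The history records per-epoch mean
    loss and training pixel accuracy.
    """
    if epochs < 1:
        raise InvalidParameterError("epochs must be >= 1")
    x, y = _dataset_to_arrays(dataset, model.spec.input_size)
    rng = np.random.default_rng(seed)
    opt = nn.Adam(model.root, lr=learning_rate)
    losses, accs = [], []
    for _epoch in range(epochs):
        perm = rng.permutation(len(x))
        total, correct, n_seen, n_pix = 0.0, 0, 0, 0
        for start in range(0, len(x), batch_size):
            idx = perm[start : start + batch_size]
            xb, yb = x[idx], y[idx]
            opt.zero_grad()
            logits = model.forward(xb, train=True)
            loss, grad = nn.softmax_cross_entropy(logits, yb)
            model.backward(grad)
            opt.step()
            total += loss * len(xb)
            n_seen += len(xb)
            correct += int((logits.argmax(axis=1) == yb).sum())
            n_pix += yb.size
        losses.append(total / n_seen)
        accs.append(correct / n_pix)
    model.trained = True
    return model, TrainingHistory(losses=losses, seed=seed, epochs=epochs, accuracies=accs)


def predict_mask(
    model, image: np.ndarray, patch_size: int = 64, stride: int = 64
) -> np.ndarray:
    """Tile, forward, and stitch a binary mask for an arbitrary-size image.

    The image is cut as in training (reflect-padded grid), each tile's
    class probabilities are computed, overlapping tiles are averaged per
    pixel, and the mask is the per-pixel argmax with the tie at
    probability 0.5 resolved to foreground.
    """
    if not getattr(model, "trained", False):
        raise StateError("model has not been trained; call train_segmenter first")
    if patch_size != model.spec.input_size:
        raise ValidationError(
            f"patch_size {patch_size} != model input size {model.spec.input_size}"
        )
    grid = extract_patches(image, patch_size=patch_size, stride=stride)
    k = model.spec.n_classes
    prob_sum = np.zeros((k, grid.padded_height, grid.padded_width))
    cover = np.zeros((grid.padded_height, grid.padded_width))
    patches_nchw = np.asarray(grid.patches, dtype=np.float32).transpose(0, 3, 1, 2)
    probs = []
    for start in range(0, len(patches_nchw), 64):
        logits = model.forward(patches_nchw[start : start + 64], train=False)
        probs.append(nn.softmax_probs(logits))
    probs = np.concatenate(probs, axis=0)
    for p, (r, c) in zip(probs, grid.coords):
        prob_sum[:, r : r + patch_size, c : c + patch_size] += p
        cover[r : r + patch_size, c : c + patch_size] += 1
    avg = prob_sum / cover[None]
    # argmax with ties resolved to the higher class index (0.5 -> foreground)
    pred = (k - 1) - np.argmax(avg[::-1], axis=0)
    return pred[: grid.source_height, : grid.source_width].astype(np.uint8)


def save_segmenter(model, path_prefix) -> None:
    """Write ``<prefix>.npz`` weights and a JSON sidecar (spec, kind, trained)."""
    prefix = Path(path_prefix)
    nn.save_weights(model.root, prefix.with_suffix(".npz"))
    sidecar = {
        "kind": model.kind,
        "trained": bool(model.trained),
        "spec": dataclasses.asdict(model.spec),
    }
    prefix.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_segmenter(path_prefix):
    prefix = Path(path_prefix)
    sidecar = json.loads(prefix.with_suffix(".json").read_text())
    spec = SegNetworkSpec(**sidecar["spec"])
    model = UNet(spec) if sidecar["kind"] == "unet" else FCN(spec)
    nn.load_weights(model.root, prefix.with_suffix(".npz"))
    model.trained = sidecar["trained"]
    return model


def write_history_csv(history: TrainingHistory, path) -> None:
    """Training curve as CSV (epoch, loss[, accuracy]) for loss/accuracy plots."""
    lines = ["epoch,loss,accuracy"]
    for i, loss in enumerate(history.losses):
        acc = "" if history.accuracies is None else f"{history.accuracies[i]}"
        lines.append(f"{i},{loss},{acc}")
    Path(path).write_text("\n".join(lines) + "\n")
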