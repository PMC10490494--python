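"""Checkpointing: weights as .npz, architecture/metadata as a JSON sidecar."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .layers import Layer, iter_layers


def state_dict(root: Layer) -> dict[str, np.ndarray]:
    out: dict[str, np.ndarray] = {}
    for i, layer in enumerate(iter_layers(root)):
        for name, arr in layer.params.items():
            out[f"layer{i:03d}.{name}"] = arr
        for name, arr in layer.buffers().items():
            out[f"layer{i:03d}.{name}"] = arr
    return out


def save_weights(root: Layer, path) -> None:
    np.savez(Path(path), **state_dict(root))


def load_weights(root: Layer, path) -> None:
    """Copy stored arrays into an already-built layer tree (shapes must match)."""
    with np.load(Path(path)) as data:
        for i, layer in enumerate(iter_layers(root)):
            for name, arr in layer.params.items():
                arr[...] = data[f"layer{i:03d}.{name}"]
            for name, arr in layer.buffers().items():
                arr[...] = data[f"layer{i:03d}.{name}"]
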