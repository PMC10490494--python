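"""Unsupervised segmentation: convolutional autoencoder + K-means in latent space.

The pipeline is sequential. A convolutional autoencoder (CAE) is trained
to reconstruct image patches under mean-squared error; once the
reconstruction loss is minimized, the encoder is assumed to hold a
faithful compressed description of each patch in its latent space Z.
Patch codes are then partitioned by K-means with K=2 (tumor / non-tumor).
Clustering alone cannot say which cluster is which class, so a separate
mapping step resolves the cluster-to-class correspondence: against
reference masks when they are available, otherwise by the stain
heuristic that hematoxylin-stained nuclei are darker than the eosin
background. Segmenting an image then amounts to encoding its patches,
assigning each code to its nearest centroid, mapping clusters to
classes, and broadcasting each patch's class to its pixels.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from sklearn.cluster import KMeans

from . import nn
from .errors import (
    DegenerateInputError,
    InvalidParameterError,
    InvalidSpecError,
    StateError,
    ValidationError,
)
from .patching import PatchGrid, assemble_mask, extract_patches

LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])


@dataclasses.dataclass
class NetworkSpec:
    """Autoencoder hyperparameters: N encoder levels, C base filters, Z latent units.

    Each encoder level halves the spatial extent, so ``input_size`` must be
    divisible by ``2**depth_N``. Defaults (N=3, C=16, Z=64 on 32x32 patches)
    put the bottleneck (64) far below the input dimensionality (32*32*3).
    """

    depth_N: int = 3
    base_filters_C: int = 16
    latent_Z: int = 64
    input_size: int = 32

    def validate(self) -> None:
        if self.depth_N < 1 or self.base_filters_C < 1 or self.latent_Z < 1:
            raise InvalidSpecError("depth_N, base_filters_C and latent_Z must be >= 1")
        if self.input_size % (2**self.depth_N) != 0:
            raise InvalidSpecError(
                f"input_size {self.input_size} not divisible by 2^{self.depth_N}"
            )


@dataclasses.dataclass
class TrainingHistory:
    """Per-epoch mean losses (and, for classifiers, pixel accuracies)."""

    losses: list[float]
    seed: int
    epochs: int
    accuracies: Optional[list[float]] = None


@dataclasses.dataclass
class LatentMatrix:
    """Per-patch latent codes aligned with the grid they came from."""

    codes: np.ndarray  # (n_patches, latent_Z)
    grid: Optional[PatchGrid] = None


@dataclasses.dataclass
class ClusterModel:
    """Fitted 2-cluster model plus the cluster->class mapping (once set)."""

    centroids: np.ndarray  # (2, latent_Z)
    inertia: float
    class_of_cluster: Optional[dict[int, int]] = None  # {cluster: 0|1}


class ConvAutoencoder:
    """Encoder: N x [conv3x3 -> batch-norm -> ReLU -> max-pool 2x2] with filters
    doubling from C, then a dense bottleneck of Z units. Decoder mirrors with
    2x2 up-convolutions; a final sigmoid keeps reconstructions in [0, 1]."""

    def __init__(self, spec: NetworkSpec, seed: int = 0, batch_norm: bool = True):
        spec.validate()
        self.spec = spec
        rng = np.random.default_rng(seed)
        n, c, z, s = spec.depth_N, spec.base_filters_C, spec.latent_Z, spec.input_size
        channels = [3] + [c * 2**i for i in range(n)]
        enc: list[nn.Layer] = []
        for i in range(n):
            enc.append(nn.Conv2d(channels[i], channels[i + 1], 3, rng))
            if batch_norm:
                enc.append(nn.BatchNorm2d(channels[i + 1]))
            enc += [nn.ReLU(), nn.MaxPool2d()]
        bottom = s // 2**n
        feat = channels[-1] * bottom * bottom
        enc += [nn.Flatten(), nn.Linear(feat, z, rng)]
        self.encoder = nn.Sequential(*enc)

        dec: list[nn.Layer] = [
            nn.Linear(z, feat, rng),
            nn.ReLU(),
            nn.Reshape((channels[-1], bottom, bottom)),
        ]
        for i in reversed(range(n)):
            out_ch = channels[i + 1] if i == 0 else channels[i]
            dec.append(nn.ConvTranspose2d(channels[i + 1], out_ch, rng))
            dec.append(nn.Conv2d(out_ch, out_ch, 3, rng))
            if batch_norm:
                dec.append(nn.BatchNorm2d(out_ch))
            dec.append(nn.ReLU())
        dec += [nn.Conv2d(channels[1], 3, 3, rng), nn.Sigmoid()]
        self.decoder = nn.Sequential(*dec)
        self.root = nn.Sequential(self.encoder, self.decoder)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return self.root.forward(x, train=train)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return self.root.backward(dy)


def _patches_to_nchw(patches, input_size: int) -> np.ndarray:
    arr = np.asarray(patches, dtype=np.float32)
    if arr.ndim != 4 or arr.shape[1:3] != (input_size, input_size) or arr.shape[3] != 3:
        raise ValidationError(
            f"expected (n, {input_size}, {input_size}, 3) patches, got {arr.shape}"
        )
    return arr.transpose(0, 3, 1, 2)


def build_cae(spec: NetworkSpec, seed: int = 0, batch_norm: bool = True) -> ConvAutoencoder:
    """Construct a CAE with deterministic (seeded) initialization."""
    return ConvAutoencoder(spec, seed=seed, batch_norm=batch_norm)


def train_cae(
    model: ConvAutoencoder,
    patches,
    epochs: int = 20,
    learning_rate: float = 1e-3,
    batch_size: int = 32,
    seed: int = 0,
) -> tuple[ConvAutoencoder, TrainingHistory]:
    """Minimize mean-squared reconstruction error with Adam.

    Returns the model and the per-epoch mean loss history; a fixed seed
    makes shuffling (and hence the history) reproducible.
    """
    if epochs < 1:
        raise InvalidParameterError("epochs must be >= 1")
    x = _patches_to_nchw(patches, model.spec.input_size)
    if len(x) == 0:
        raise InvalidParameterError("no patches to train on")
    rng = np.random.default_rng(seed)
    opt = nn.Adam(model.root, lr=learning_rate)
    losses = []
    for _epoch in range(epochs):
        perm = rng.permutation(len(x))
        total, n_seen = 0.0, 0
        for start in range(0, len(x), batch_size):
            batch = x[perm[start : start + batch_size]]
            opt.zero_grad()
            recon = model.forward(batch, train=True)
            loss, grad = nn.mse_loss(recon, batch)
            model.backward(grad)
            opt.step()
            total += loss * len(batch)
            n_seen += len(batch)
        losses.append(total / n_seen)
    return model, TrainingHistory(losses=losses, seed=seed, epochs=epochs)


def encode(model: ConvAutoencoder, patches, grid: Optional[PatchGrid] = None) -> LatentMatrix:
    """Run the encoder in inference mode: one Z-vector per patch."""
    x = _patches_to_nchw(patches, model.spec.input_size)
    codes = []
    for start in range(0, len(x), 256):  # bounded memory
        codes.append(model.encoder.forward(x[start : start + 256], train=False))
    return LatentMatrix(codes=np.concatenate(codes, axis=0), grid=grid)


def _lloyd_from(codes: np.ndarray, centers: np.ndarray, max_iter: int = 100):
    """Plain Lloyd iterations from explicit initial centers."""
    for _ in range(max_iter):
        d = ((codes[:, None, :] - centers[None]) ** 2).sum(-1)
        labels = d.argmin(axis=1)
        new = centers.copy()
        for k in (0, 1):
            if (labels == k).any():
                new[k] = codes[labels == k].mean(axis=0)
        if np.allclose(new, centers, rtol=0, atol=0):
            break
        centers = new
    d = ((codes[:, None, :] - centers[None]) ** 2).sum(-1)
    inertia = float(d.min(axis=1).sum())
    return centers, inertia


def fit_kmeans2(latents, n_restarts: int = 10, seed: int = 0) -> ClusterModel:
    """2-means on latent codes: Lloyd iterations from k-means++ starts,
    best of ``n_restarts`` by inertia. The class mapping is left unset.

    On small inputs (at most 64 distinct codes) the stochastic restarts are
    supplemented by deterministic Lloyd runs seeded from every distinct pair
    of points; with K=2 the optimal partition is itself a Lloyd fixed point,
    so dense seeding makes the tiny-sample optimum reliably attainable.
    """
    codes = latents.codes if isinstance(latents, LatentMatrix) else np.asarray(latents)
    codes = codes.astype(np.float64)
    if len(np.unique(codes, axis=0)) < 2:
        raise DegenerateInputError("all latent codes are identical; cannot form 2 clusters")
    km = KMeans(
        n_clusters=2,
        n_init=n_restarts,
        init="k-means++",
        algorithm="lloyd",
        random_state=seed % (2**31),
    ).fit(codes)
    best_centers, best_inertia = km.cluster_centers_, float(km.inertia_)
    unique = np.unique(codes, axis=0)
    if len(unique) <= 64:
        for i in range(len(unique)):
            for j in range(i + 1, len(unique)):
                centers, inertia = _lloyd_from(codes, unique[[i, j]].copy())
                if inertia < best_inertia:
                    best_centers, best_inertia = centers, inertia
    return ClusterModel(centroids=best_centers, inertia=best_inertia)


def assign_clusters(cluster_model: ClusterModel, codes: np.ndarray) -> np.ndarray:
    """Nearest-centroid assignment; ties go to the lower centroid index."""
    d = ((codes[:, None, :].astype(np.float64) - cluster_model.centroids[None]) ** 2).sum(-1)
    return d.argmin(axis=1)


def map_clusters_to_classes(
    cluster_model: ClusterModel,
    assignments: np.ndarray,
    patches,
    reference_masks: Optional[Sequence[np.ndarray]] = None,
) -> ClusterModel:
    """Resolve the cluster->class correspondence.

    With ``reference_masks`` (evaluation mode) the bijection maximizing
    pixel accuracy against the references is chosen; a tie keeps cluster 0
    as non-tumor. Without references (deployment mode) the cluster whose
    member patches are darker in mean luminance is called tumor — nuclei
    take up hematoxylin and are darker than eosin-stained background.
    """
    patches = np.asarray(patches, dtype=np.float64)
    assignments = np.asarray(assignments)
    if len(assignments) != len(patches):
        raise ValidationError("assignments and patches must align")
    if reference_masks is not None:
        refs = np.asarray(reference_masks)
        if len(refs) != len(patches):
            raise ValidationError("reference_masks and patches must align")
        best_map, best_correct = None, -1
        for mapping in ({0: 0, 1: 1}, {0: 1, 1: 0}):
            labels = np.array([mapping[int(a)] for a in assignments])
            correct = int((refs == labels[:, None, None]).sum())
            if correct > best_correct:  # strict: tie keeps the identity mapping
                best_map, best_correct = mapping, correct
        return dataclasses.replace(cluster_model, class_of_cluster=best_map)
    luma = patches @ LUMA_WEIGHTS  # (n, h, w)
    mean_luma = [
        luma[assignments == k].mean() if (assignments == k).any() else np.inf
        for k in (0, 1)
    ]
    dark = int(np.argmin(mean_luma))
    return dataclasses.replace(
        cluster_model, class_of_cluster={dark: 1, 1 - dark: 0}
    )


def segment_unsupervised(
    image: np.ndarray,
    cae_model: ConvAutoencoder,
    cluster_model: ClusterModel,
    patch_size: int = 32,
    stride: int = 32,
) -> np.ndarray:
    """Segment one image with the trained encoder + fitted cluster model.

    Patches are encoded, assigned to their nearest centroid, mapped to
    tumor/non-tumor, and each patch's class is broadcast to its pixels
    (overlapping strides resolve by per-pixel majority vote).
    """
    if cluster_model.class_of_cluster is None:
        raise StateError("cluster model has no class mapping; run map_clusters_to_classes")
    grid = extract_patches(image, patch_size=patch_size, stride=stride)
    latents = encode(cae_model, grid.patches, grid=grid)
    assignments = assign_clusters(cluster_model, latents.codes)
    labels = [cluster_model.class_of_cluster[int(a)] for a in assignments]
    return assemble_mask(labels, grid)


def save_cae(model: ConvAutoencoder, cluster_model: Optional[ClusterModel], path_prefix) -> None:
    """Write ``<prefix>.npz`` (weights) and ``<prefix>.json`` (spec + clusters)."""
    prefix = Path(path_prefix)
    nn.save_weights(model.root, prefix.with_suffix(".npz"))
    sidecar = {"network_spec": dataclasses.asdict(model.spec)}
    if cluster_model is not None:
        sidecar["cluster_model"] = {
            "centroids": cluster_model.centroids.tolist(),
            "inertia": cluster_model.inertia,
            "class_of_cluster": (
                None
                if cluster_model.class_of_cluster is None
                else {str(k): v for k, v in cluster_model.class_of_cluster.items()}
            ),
        }
    prefix.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_cae(path_prefix) -> tuple[ConvAutoencoder, Optional[ClusterModel]]:
    prefix = Path(path_prefix)
    sidecar = json.loads(prefix.with_suffix(".json").read_text())
    spec = NetworkSpec(**sidecar["network_spec"])
    model = ConvAutoencoder(spec, seed=0)
    nn.load_weights(model.root, prefix.with_suffix(".npz"))
    cluster_model = None
    if "cluster_model" in sidecar:
        cm = sidecar["cluster_model"]
        mapping = cm["class_of_cluster"]
        cluster_model = ClusterModel(
            centroids=np.array(cm["centroids"]),
            inertia=cm["inertia"],
            class_of_cluster=None if mapping is None else {int(k): v for k, v in mapping.items()},
        )
    return model, cluster_model
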