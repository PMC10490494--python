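"""Self-contained synthetic benchmarks exercising both segmentation branches.

Each runner builds its inputs from the synthetic generator, executes one
pipeline end to end at desk scale, and returns the measured quantities.
The three benchmark conditions:

* CAE learning — the default autoencoder (N=3, C=16, Z=64) fit to 200
  32x32 patches cut from high-contrast 128x128 images, 20 epochs.
* Unsupervised recovery — 20 easy 128x128 images (8 nuclei of radius
  14-22 px, noise sd 0.02); a 16x16-patch CAE (N=2, C=16, Z=32) is
  trained for 15 epochs, codes are 2-means clustered, clusters mapped
  against ground truth, and each image segmented with stride 4 so the
  per-pixel majority vote smooths patch-block boundaries.
* Supervised benchmark — improved U-Net (depth 3, base 8 filters, 3
  convs per block) and the FCN baseline, each trained 30 epochs on 64
  easy 64x64 images and scored on 16 held-out images.

``seed`` drives every random stage (data draw, weight init, shuffling,
clustering restarts); a fixed seed reproduces results bit-identically.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .cae_cluster import (
    NetworkSpec,
    TrainingHistory,
    assign_clusters,
    build_cae,
    encode,
    fit_kmeans2,
    map_clusters_to_classes,
    segment_unsupervised,
    train_cae,
)
from .evaluation import MetricReport, compute_metrics, confusion_counts
from .nn import mse_loss
from .patching import extract_mask_patches, extract_patches
from .synthetic import SyntheticParams, generate_dataset
from .unet_seg import (
    SegNetworkSpec,
    build_fcn,
    build_unet,
    predict_mask,
    train_segmenter,
)

# High-contrast "easy" conditions: nucleus/background colors at the package
# defaults, mild noise, nuclei large relative to the patch grid.
EASY_PATCH_PARAMS = SyntheticParams(
    image_height=128,
    image_width=128,
    n_nuclei=8,
    radius_range=(14.0, 22.0),
    noise_sd=0.02,
    seed=7,
)

EASY_UNSUP_PARAMS = SyntheticParams(
    image_height=128,
    image_width=128,
    n_nuclei=8,
    radius_range=(14.0, 22.0),
    noise_sd=0.02,
    seed=11,
)

EASY_SUP_PARAMS = SyntheticParams(
    image_height=64,
    image_width=64,
    n_nuclei=4,
    radius_range=(8.0, 14.0),
    noise_sd=0.02,
    seed=21,
)


def _sub_seeds(seed: int, n: int) -> list[int]:
    """Deterministic sub-seeds below 2^31 derived from one master seed."""
    return [int(s) % (2**31 - 1) for s in np.random.SeedSequence(seed).generate_state(n)]


def run_cae_learning(seed: int = 0) -> tuple[float, TrainingHistory]:
    """Train the default CAE on 200 synthetic 32x32 patches for 20 epochs.

    Returns the reconstruction MSE of the freshly initialized model and the
    training history, so callers can measure the loss reduction.
    """
    data_seed, net_seed = _sub_seeds(seed, 2)
    params = dataclasses.replace(EASY_PATCH_PARAMS, seed=data_seed)
    ds = generate_dataset(13, params)
    patches = []
    for item in ds:
        patches.extend(list(extract_patches(item.image, 32, 32).patches))
    patches = np.asarray(patches[:200])
    model = build_cae(NetworkSpec(), seed=net_seed)
    x = patches.astype(np.float32).transpose(0, 3, 1, 2)
    init_loss, _ = mse_loss(model.forward(x, train=False), x)
    model, history = train_cae(model, patches, epochs=20, seed=net_seed)
    return init_loss, history


def run_unsupervised_pipeline(
    seed: int = 0,
) -> tuple[list[MetricReport], TrainingHistory, list[np.ndarray]]:
    """Full unsupervised branch on the easy 20-image set.

    Returns per-image metric reports, the CAE training history, and the
    predicted masks.
    """
    data_seed, net_seed = _sub_seeds(seed, 2)
    params = dataclasses.replace(EASY_UNSUP_PARAMS, seed=data_seed)
    ds = generate_dataset(20, params)
    spec = NetworkSpec(depth_N=2, base_filters_C=16, latent_Z=32, input_size=16)
    patches, mask_patches = [], []
    for item in ds:
        patches.extend(list(extract_patches(item.image, 16, 16).patches))
        mask_patches.extend(list(extract_mask_patches(item.mask, 16, 16).patches))
    patches = np.asarray(patches)
    mask_patches = np.asarray(mask_patches)
    model = build_cae(spec, seed=net_seed)
    model, history = train_cae(model, patches, epochs=15, seed=net_seed)
    latents = encode(model, patches)
    cmodel = fit_kmeans2(latents, seed=net_seed)
    assignments = assign_clusters(cmodel, latents.codes)
    cmodel = map_clusters_to_classes(
        cmodel, assignments, patches, reference_masks=mask_patches
    )
    reports, masks = [], []
    for item in ds:
        pred = segment_unsupervised(item.image, model, cmodel, patch_size=16, stride=4)
        masks.append(pred)
        reports.append(compute_metrics(confusion_counts(pred, item.mask)))
    return reports, history, masks


def run_supervised_benchmark(
    seed: int = 0,
) -> tuple[list[MetricReport], list[MetricReport], TrainingHistory, list[np.ndarray]]:
    """Improved U-Net vs FCN: 64 training and 16 held-out easy images.

    Returns held-out metric reports for both models, the U-Net training
    history, and the U-Net's predicted masks.
    """
    data_seed, net_seed = _sub_seeds(seed, 2)
    params = dataclasses.replace(EASY_SUP_PARAMS, seed=data_seed)
    ds = generate_dataset(80, params)
    train, held_out = ds[:64], ds[64:]
    pairs = [(d.image, d.mask) for d in train]
    spec = SegNetworkSpec(depth=3, base_filters=8, convs_per_block=3, input_size=64)
    unet = build_unet(spec, seed=net_seed)
    unet, history = train_segmenter(unet, pairs, epochs=30, batch_size=8, seed=net_seed)
    fcn = build_fcn(spec, seed=net_seed)
    fcn, _ = train_segmenter(fcn, pairs, epochs=30, batch_size=8, seed=net_seed)
    unet_reports, fcn_reports, unet_masks = [], [], []
    for item in held_out:
        pu = predict_mask(unet, item.image, 64, 64)
        pf = predict_mask(fcn, item.image, 64, 64)
        unet_masks.append(pu)
        unet_reports.append(compute_metrics(confusion_counts(pu, item.mask)))
        fcn_reports.append(compute_metrics(confusion_counts(pf, item.mask)))
    return unet_reports, fcn_reports, history, unet_masks


def mean_metric(reports: list[MetricReport], name: str) -> float:
    values = [getattr(r, name) for r in reports if getattr(r, name) is not None]
    return float(np.mean(values))
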