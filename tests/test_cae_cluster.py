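"""CAE training, latent clustering, cluster->class mapping and segmentation."""

import itertools

import numpy as np
import pytest

from histoseg import nn
from histoseg.cae_cluster import (
    ClusterModel,
    NetworkSpec,
    assign_clusters,
    build_cae,
    encode,
    fit_kmeans2,
    load_cae,
    map_clusters_to_classes,
    save_cae,
    segment_unsupervised,
    train_cae,
)
from histoseg.errors import (
    DegenerateInputError,
    InvalidParameterError,
    InvalidSpecError,
    StateError,
)

TINY = NetworkSpec(depth_N=2, base_filters_C=4, latent_Z=8, input_size=8)


def _patches(rng, n, size=8):
    return rng.uniform(size=(n, size, size, 3))


def test_spec_validation():
    with pytest.raises(InvalidSpecError):
        NetworkSpec(depth_N=2, input_size=30).validate()
    with pytest.raises(InvalidSpecError):
        NetworkSpec(latent_Z=0).validate()
    NetworkSpec().validate()


def test_shape_contracts(rng):
    model = build_cae(NetworkSpec(depth_N=2, base_filters_C=8, latent_Z=16, input_size=32))
    patches = _patches(rng, 4, 32)
    codes = encode(model, patches).codes
    assert codes.shape == (4, 16)
    recon = model.forward(np.asarray(patches, np.float32).transpose(0, 3, 1, 2), train=False)
    assert recon.shape == (4, 3, 32, 32)
    assert recon.min() >= 0.0 and recon.max() <= 1.0  # sigmoid output


def test_encoder_halves_spatial_dims_per_level(rng):
    model = build_cae(NetworkSpec(depth_N=2, base_filters_C=8, latent_Z=16, input_size=32))
    x = np.asarray(_patches(rng, 2, 32), np.float32).transpose(0, 3, 1, 2)
    sizes = []
    h = x
    for layer in model.encoder.layers:
        h = layer.forward(h, train=False)
        if isinstance(layer, nn.MaxPool2d):
            sizes.append(h.shape[-1])
    assert sizes == [16, 8]


def test_training_reduces_loss_on_constant_patches():
    """Any gradient method must reduce error on a constant target."""
    patches = np.full((50, 8, 8, 3), 0.3)
    model = build_cae(TINY, seed=0)
    model, hist = train_cae(model, patches, epochs=15, seed=0)
    assert len(hist.losses) == 15
    assert all(l >= 0 for l in hist.losses)
    assert hist.losses[-1] < hist.losses[0]


def test_training_epoch_one_history_and_empty_errors(rng):
    model = build_cae(TINY, seed=0)
    _, hist = train_cae(model, _patches(rng, 4), epochs=1, seed=0)
    assert hist.epochs == 1 and len(hist.losses) == 1
    with pytest.raises(InvalidParameterError):
        train_cae(build_cae(TINY), np.zeros((0, 8, 8, 3)), epochs=1, seed=0)


def test_encode_deterministic_and_separates_extremes():
    patches = np.concatenate([np.zeros((10, 8, 8, 3)), np.ones((10, 8, 8, 3))])
    model = build_cae(TINY, seed=1)
    model, _ = train_cae(model, patches, epochs=10, seed=1)
    a = encode(model, patches).codes
    b = encode(model, patches).codes
    assert np.array_equal(a, b)
    assert np.linalg.norm(a[0] - a[-1]) > 0  # all-0 vs all-1 patch codes differ


def _brute_force_sse(points):
    """Optimal 2-partition sum of squared errors by exhaustive enumeration."""
    n = len(points)
    best = np.inf
    for bits in itertools.product([0, 1], repeat=n):
        if 0 < sum(bits) < n:
            sse = 0.0
            for k in (0, 1):
                group = points[np.array(bits) == k]
                sse += ((group - group.mean(axis=0)) ** 2).sum()
            best = min(best, sse)
    return best


def test_kmeans_matches_exhaustive_partition_oracle(rng):
    for _ in range(5):
        points = rng.normal(size=(8, 3))
        cm = fit_kmeans2(points, n_restarts=10, seed=0)
        assert cm.inertia == pytest.approx(_brute_force_sse(points), rel=1e-9)


def test_kmeans_separated_blobs_and_degenerate(rng):
    blob_a = rng.normal(0.0, 0.1, size=(4, 2))
    blob_b = rng.normal(10.0, 0.1, size=(4, 2))
    points = np.vstack([blob_a, blob_b])
    cm = fit_kmeans2(points, seed=0)
    a = assign_clusters(cm, points)
    assert len(set(a[:4])) == 1 and len(set(a[4:])) == 1 and a[0] != a[-1]
    # two distinct points: each its own centroid, inertia 0
    cm2 = fit_kmeans2(np.array([[0.0, 0.0], [1.0, 1.0]]), seed=0)
    assert cm2.inertia == pytest.approx(0.0, abs=1e-12)
    with pytest.raises(DegenerateInputError):
        fit_kmeans2(np.ones((5, 3)), seed=0)


def test_mapping_reference_mode_picks_higher_accuracy():
    # cluster 0 patches are foreground in the references -> mapping {0:1,1:0}
    patches = np.zeros((4, 2, 2, 3))
    assignments = np.array([0, 0, 1, 1])
    refs = np.array([np.ones((2, 2)), np.ones((2, 2)), np.zeros((2, 2)), np.zeros((2, 2))])
    cm = ClusterModel(centroids=np.zeros((2, 3)), inertia=0.0)
    mapped = map_clusters_to_classes(cm, assignments, patches, reference_masks=refs)
    assert mapped.class_of_cluster == {0: 1, 1: 0}


def test_mapping_luminance_mode_dark_cluster_is_tumor():
    dark = np.full((3, 2, 2, 3), 0.2)
    light = np.full((3, 2, 2, 3), 0.9)
    patches = np.concatenate([dark, light])
    assignments = np.array([1, 1, 1, 0, 0, 0])  # dark patches in cluster 1
    cm = ClusterModel(centroids=np.zeros((2, 3)), inertia=0.0)
    mapped = map_clusters_to_classes(cm, assignments, patches)
    assert mapped.class_of_cluster == {1: 1, 0: 0}


def test_mapping_tie_keeps_cluster0_as_background():
    # both bijections score identically -> identity mapping retained
    patches = np.zeros((2, 2, 2, 3))
    assignments = np.array([0, 1])
    # references half-right under either bijection -> exact tie
    refs = np.array([np.ones((2, 2)), np.ones((2, 2))])
    cm = ClusterModel(centroids=np.zeros((2, 3)), inertia=0.0)
    m1 = map_clusters_to_classes(cm, assignments, patches, reference_masks=refs)
    assert m1.class_of_cluster == {0: 0, 1: 1}


@pytest.fixture(scope="module")
def trained_unsup():
    """Tiny CAE + clusters trained on high-contrast 8x8 patches."""
    rng = np.random.default_rng(0)
    dark = np.clip(rng.normal(0.3, 0.02, (40, 8, 8, 3)), 0, 1)
    light = np.clip(rng.normal(0.85, 0.02, (40, 8, 8, 3)), 0, 1)
    patches = np.concatenate([dark, light])
    refs = np.concatenate([np.ones((40, 8, 8)), np.zeros((40, 8, 8))])
    model = build_cae(TINY, seed=0)
    model, _ = train_cae(model, patches, epochs=10, seed=0)
    lat = encode(model, patches)
    cm = fit_kmeans2(lat, seed=0)
    a = assign_clusters(cm, lat.codes)
    cm = map_clusters_to_classes(cm, a, patches, reference_masks=refs)
    return model, cm


def test_segment_contract_and_unmapped_error(trained_unsup, rng):
    model, cm = trained_unsup
    image = rng.uniform(size=(24, 24, 3))
    mask = segment_unsupervised(image, model, cm, patch_size=8, stride=8)
    assert mask.shape == (24, 24)
    assert set(np.unique(mask)) <= {0, 1}
    with pytest.raises(StateError):
        segment_unsupervised(
            image, model, ClusterModel(cm.centroids, cm.inertia), patch_size=8, stride=8
        )


def test_segment_pure_background_is_all_zero(trained_unsup):
    model, cm = trained_unsup
    image = np.full((16, 16, 3), 0.85)
    assert segment_unsupervised(image, model, cm, 8, 8).sum() == 0


def test_segment_invariant_under_cluster_relabeling(trained_unsup, rng):
    model, cm = trained_unsup
    image = rng.uniform(size=(16, 16, 3))
    flipped = ClusterModel(
        centroids=cm.centroids[::-1].copy(),
        inertia=cm.inertia,
        class_of_cluster={0: cm.class_of_cluster[1], 1: cm.class_of_cluster[0]},
    )
    a = segment_unsupervised(image, model, cm, 8, 8)
    b = segment_unsupervised(image, model, flipped, 8, 8)
    assert np.array_equal(a, b)


def test_checkpoint_round_trip(trained_unsup, tmp_path, rng):
    model, cm = trained_unsup
    save_cae(model, cm, tmp_path / "ckpt")
    model2, cm2 = load_cae(tmp_path / "ckpt")
    image = rng.uniform(size=(16, 16, 3))
    assert np.array_equal(
        segment_unsupervised(image, model, cm, 8, 8),
        segment_unsupervised(image, model2, cm2, 8, 8),
    )
    assert cm2.class_of_cluster == cm.class_of_cluster
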