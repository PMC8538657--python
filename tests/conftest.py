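"""Shared fixtures: small phantoms and (expensive) trained artifacts.

The heavyweight fixtures are session-scoped so the trained scaled-down
U-Net is shared between the segmentation benchmark and the end-to-end
pipeline test.
"""

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from renodce import coarse_seg, fine_seg
from renodce.coarse_seg import TrainConfig, UNetConfig
from renodce.phantom import PhantomConfig, make_phantom


@pytest.fixture(scope="session")
def small_phantom():
    """Noiseless small phantom: exact ground truth for oracle tests."""
    return make_phantom(PhantomConfig(shape=(192, 192, 6), noise_sigma=0.0, seed=11))


@pytest.fixture(scope="session")
def noisy_phantom():
    """Default-noise (3% Gaussian) small phantom."""
    return make_phantom(PhantomConfig(shape=(192, 192, 6), noise_sigma=0.03, seed=12))


@pytest.fixture(scope="session")
def classification_phantoms():
    """Two training subjects + one held-out subject for the voxel-classification
    benchmark: 3% noise with 15% within-compartment PK dispersion."""
    cfg = dict(shape=(192, 192, 6), noise_sigma=0.03, pk_dispersion=0.15)
    train = {f"train{i}": make_phantom(PhantomConfig(seed=10 + i, **cfg)) for i in range(2)}
    test = make_phantom(PhantomConfig(seed=77, **cfg))
    return train, test


@pytest.fixture(scope="session")
def classification_artifacts(classification_phantoms):
    """PCA + balanced features fitted on the training subjects only."""
    train, _ = classification_phantoms
    sets = [
        fine_seg.extract_time_courses(ph.series, ph.labels.data > 0, ph.labels, subject=name)
        for name, ph in train.items()
    ]
    tcs = fine_seg.concat_time_courses(sets)
    pca = fine_seg.fit_pca(tcs, k=20)
    features = fine_seg.transform_pca(pca, tcs)
    bal_x, bal_y = fine_seg.balance_classes(features, tcs.labels, seed=0)
    return dict(pca=pca, features=bal_x, labels=bal_y, subjects=sorted(train), tcs=tcs)


@pytest.fixture(scope="session")
def segmentation_phantoms():
    """Noiseless phantoms for the scaled-down U-Net benchmark (2 train + 1 test)."""
    train = {
        f"train{i}": make_phantom(PhantomConfig(shape=(192, 192, 8), noise_sigma=0.0, seed=i + 1))
        for i in range(2)
    }
    test = make_phantom(PhantomConfig(shape=(192, 192, 8), noise_sigma=0.0, seed=99))
    return train, test


@pytest.fixture(scope="session")
def trained_unet(segmentation_phantoms):
    """Scaled-down U-Net (base filters 16, 10 epochs, ~250 patches) trained on
    the noiseless training phantoms; shared by benchmark and pipeline tests."""
    train, _ = segmentation_phantoms
    sets = []
    for name, ph in train.items():
        frames = coarse_seg.select_enhancement_frames(ph.series)
        for f in frames:
            sets.append(
                coarse_seg.extract_patches(
                    ph.series.frame(f), ph.labels.data > 0,
                    vertical_offsets=3, seed=f, subject=name, frame_index=f,
                )
            )
    patches = coarse_seg.concat_patch_sets(sets)
    net, history = coarse_seg.train_unet(
        patches,
        UNetConfig(base_filters=16, seed=0),
        TrainConfig(epochs=10, batch_size=8, seed=0),
    )
    return net, history, len(patches)
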