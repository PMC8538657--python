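"""Stage 1: coarse whole-kidney segmentation.

A U-Net classifies each pixel of a 96x96 single-kidney patch as kidney
or background.  The stage covers: selecting the enhancement frames used
for training/inference, extracting and augmenting patches (vertical
offsets + horizontal mirroring), building and training the network, and
predicting full-grid masks refined by largest-connected-component
filtering.

Frame selection at inference cannot use tissue labels, so the frame of
maximal cortical enhancement is located by a label-free surrogate: the
frame maximizing the 95th percentile of baseline-subtracted signal
within the central third of image rows (the band that brackets the
kidneys).  The peak frame plus its immediate neighbours are returned.

Patches are split by image side: a 192-pixel-wide in-plane matrix is
divided into two 96-pixel halves, each covering one kidney.  Inputs
with a different in-plane matrix are center-cropped/padded to 192.
Each patch is min-max normalized to [0, 1] before entering the network.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from . import nn
from .dataio import DynamicSeries, KidneyMask
from .errors import (
    ConfigurationError,
    NoEnhancementError,
    ParameterError,
    ShapeError,
)
from .metrics import iou
from .nn import bce_loss

logger = logging.getLogger(__name__)

__all__ = [
    "PatchSet",
    "UNetConfig",
    "TrainConfig",
    "select_enhancement_frames",
    "extract_patches",
    "count_base_patches",
    "binary_cross_entropy",
    "build_unet",
    "train_unet",
    "predict_mask",
    "largest_component",
]

PATCH = 96
INPLANE = 192


@dataclass
class UNetConfig:
    """Architecture of the segmentation network."""

    depth: int = 4
    base_filters: int = 64
    dropout: float = 0.2
    batch_norm: bool = True
    seed: int = 0

    @property
    def bottleneck_filters(self) -> int:
        return self.base_filters * 2**self.depth

    def validate(self) -> None:
        if not 0 <= self.dropout < 1:
            raise ConfigurationError("dropout must lie in [0, 1)")
        if self.depth < 1 or self.base_filters < 1:
            raise ConfigurationError("depth and base_filters must be positive")


@dataclass
class TrainConfig:
    """Optimization settings for U-Net training."""

    learning_rate: float = 0.01
    momentum: float = 0.99
    epochs: int = 50
    val_fraction: float = 1.0 / 3.0
    batch_size: int = 16
    seed: int = 0
    bce_eps: float = 1e-7

    def validate(self) -> None:
        if self.learning_rate <= 0:
            raise ConfigurationError("learning rate must be positive")
        if not 0 < self.val_fraction < 1:
            raise ConfigurationError("validation fraction must lie in (0, 1)")


@dataclass
class PatchSet:
    """Training or inference patches with full provenance."""

    patches: np.ndarray            # (n, 96, 96) float32, min-max normalized
    masks: np.ndarray | None       # (n, 96, 96) bool (None at inference)
    provenance: pd.DataFrame       # subject, session, side, slice_index, frame_index, vertical_offset, mirrored
    training: bool = True

    def __post_init__(self) -> None:
        self.patches = np.asarray(self.patches, dtype=np.float32)
        if self.patches.ndim != 3:
            raise ShapeError("patches must be (n, h, w)")
        if self.masks is not None:
            self.masks = np.asarray(self.masks, dtype=bool)
            if self.masks.shape != self.patches.shape:
                raise ShapeError("patch and mask stacks must have equal shapes")
            if self.training and self.masks.size and not self.masks.any(axis=(1, 2)).all():
                raise ShapeError("every training patch must contain at least one kidney pixel")
        if len(self.provenance) != len(self.patches):
            raise ShapeError("provenance must have one row per patch")

    def __len__(self) -> int:
        return len(self.patches)

    @property
    def subjects(self) -> np.ndarray:
        return self.provenance["subject"].to_numpy()


def count_base_patches(
    n_exams: int = 20,
    kidneys_per_exam: int = 2,
    frames_per_exam: int = 3,
    slices_per_kidney: int = 12,
) -> int:
    """Base (pre-augmentation) training-patch count from per-exam factors."""
    return n_exams * kidneys_per_exam * frames_per_exam * slices_per_kidney


# ---------------------------------------------------------------------------
# frame selection
# ---------------------------------------------------------------------------

def select_enhancement_frames(series: DynamicSeries, n: int = 3) -> list[int]:
    """Indices of the perfusion-phase frames: peak cortical enhancement plus neighbours.

    The peak is located without labels: per frame, take the 95th
    percentile of (signal - baseline mean) over the central third of
    image rows; the maximizing post-baseline frame is the center of the
    returned window of ``n`` consecutive frames.
    """
    t0 = series.n_baseline_frames
    n_post = series.n_frames - t0
    if n < 1 or n > n_post:
        raise ParameterError(f"cannot select {n} frames from {n_post} post-baseline frames")
    ny = series.shape[1]
    band = slice(ny // 3, 2 * ny // 3)
    base = series.baseline_mean()[:, band, :]
    post = series.data[:, band, :, t0:]
    enh = post - base[..., None]
    score = np.percentile(enh.reshape(-1, n_post), 95, axis=0)
    if score.max() <= 0.02 * float(base.mean()):
        raise NoEnhancementError("no enhancement detected in the dynamic series")
    k = t0 + int(np.argmax(score))
    half = n // 2
    lo = min(max(k - half, t0), series.n_frames - n)
    return list(range(lo, lo + n))


# ---------------------------------------------------------------------------
# patch extraction
# ---------------------------------------------------------------------------

def _fit_inplane(volume: np.ndarray) -> np.ndarray:
    """Center-crop/pad the in-plane (x, y) matrix to 192x192."""
    out = volume
    for axis in (0, 1):
        size = out.shape[axis]
        if size > INPLANE:
            lo = (size - INPLANE) // 2
            out = np.take(out, np.arange(lo, lo + INPLANE), axis=axis)
        elif size < INPLANE:
            pad = INPLANE - size
            widths = [(0, 0)] * out.ndim
            widths[axis] = (pad // 2, pad - pad // 2)
            out = np.pad(out, widths)
    return out


def _normalize(patch: np.ndarray) -> np.ndarray:
    lo, hi = patch.min(), patch.max()
    if hi > lo:
        return ((patch - lo) / (hi - lo)).astype(np.float32)
    return np.zeros_like(patch, dtype=np.float32)


_SIDE_SLICES = {"left": slice(0, PATCH), "right": slice(PATCH, INPLANE)}


def extract_patches(
    volume: np.ndarray,
    mask: np.ndarray | None = None,
    vertical_offsets: int = 10,
    mirror: bool = True,
    min_kidney_fraction: float = 0.2,
    seed: int = 0,
    subject: str = "",
    session: str = "",
    frame_index: int = -1,
) -> PatchSet:
    """Extract 96x96 single-kidney patches from one 3D frame.

    Training mode (``mask`` given): per slice and side, up to
    ``vertical_offsets`` vertical patch positions each retaining at
    least ``min_kidney_fraction`` of that slice's kidney pixels, each
    randomly mirrored horizontally with probability 1/2.  Slices
    without kidney pixels are skipped.  Inference mode (``mask`` None):
    exactly one centrally located patch per side per slice.
    """
    volume = _fit_inplane(np.asarray(volume, dtype=float))
    training = mask is not None
    if training:
        mask = _fit_inplane(np.asarray(mask)).astype(bool)
        if mask.shape != volume.shape:
            raise ShapeError("mask and volume must share the same grid")
    rng = np.random.default_rng(seed)
    ny, nz = volume.shape[1], volume.shape[2]
    patches, targets, rows = [], [], []
    center_y = (ny - PATCH) // 2
    for z in range(nz):
        for side, xs in _SIDE_SLICES.items():
            img = volume[xs, :, z]
            if training:
                kid = mask[xs, :, z]
                n_pix = int(kid.sum())
                if n_pix == 0:
                    logger.debug("slice %d side %s has no kidney pixels; skipped", z, side)
                    continue
                candidates = [
                    y0 for y0 in range(ny - PATCH + 1)
                    if kid[:, y0 : y0 + PATCH].sum() >= min_kidney_fraction * n_pix
                ]
                chosen = rng.choice(
                    candidates, size=min(vertical_offsets, len(candidates)), replace=False
                )
            else:
                chosen = [center_y]
            for y0 in chosen:
                patch = _normalize(img[:, y0 : y0 + PATCH])
                target = mask[xs, y0 : y0 + PATCH, z] if training else None
                mirrored = bool(mirror and training and rng.random() < 0.5)
                if mirrored:
                    patch = patch[::-1]
                    target = target[::-1]
                patches.append(patch)
                if training:
                    targets.append(target)
                rows.append(
                    dict(subject=subject, session=session, side=side, slice_index=z,
                         frame_index=frame_index, vertical_offset=int(y0), mirrored=mirrored)
                )
    return PatchSet(
        patches=np.array(patches, dtype=np.float32).reshape(-1, PATCH, PATCH),
        masks=np.array(targets, dtype=bool).reshape(-1, PATCH, PATCH) if training else None,
        provenance=pd.DataFrame(
            rows, columns=["subject", "session", "side", "slice_index",
                           "frame_index", "vertical_offset", "mirrored"],
        ),
        training=training,
    )


def concat_patch_sets(sets: list[PatchSet]) -> PatchSet:
    """Concatenate patch sets (e.g. several subjects/frames) preserving provenance."""
    return PatchSet(
        patches=np.concatenate([s.patches for s in sets]),
        masks=None if sets[0].masks is None else np.concatenate([s.masks for s in sets]),
        provenance=pd.concat([s.provenance for s in sets], ignore_index=True),
        training=sets[0].training,
    )


# ---------------------------------------------------------------------------
# loss / network
# ---------------------------------------------------------------------------

def binary_cross_entropy(y, p, eps: float = 1e-7) -> float:
    """Mean binary cross-entropy, probabilities clipped to [eps, 1-eps]."""
    return bce_loss(y, p, eps)


def build_unet(config: UNetConfig | None = None) -> nn.UNet:
    """Instantiate the (untrained) segmentation network from its config."""
    config = config or UNetConfig()
    config.validate()
    return nn.UNet(
        in_channels=1,
        base_filters=config.base_filters,
        depth=config.depth,
        dropout=config.dropout,
        batch_norm=config.batch_norm,
        seed=config.seed,
    )


def _predict_patches(net: nn.UNet, patches: np.ndarray, batch_size: int = 16) -> np.ndarray:
    out = []
    for i in range(0, len(patches), batch_size):
        x = patches[i : i + batch_size][:, None]
        out.append(net.forward(x, training=False)[:, 0])
    return np.concatenate(out) if out else np.empty((0, PATCH, PATCH), dtype=np.float32)


def _mean_iou(pred_probs: np.ndarray, masks: np.ndarray) -> float:
    scores = []
    for p, m in zip(pred_probs >= 0.5, masks):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            scores.append(iou(p, m))
    return float(np.mean(scores)) if scores else float("nan")


def _split_train_val(patch_set: PatchSet, val_fraction: float, rng) -> tuple[np.ndarray, np.ndarray]:
    """Validation split by subject when provenance allows, else by patch."""
    subjects = np.unique(patch_set.subjects)
    n = len(patch_set)
    if len(subjects) > 1:
        n_val = max(1, int(round(len(subjects) * val_fraction)))
        val_subjects = rng.choice(subjects, size=n_val, replace=False)
        val_idx = np.isin(patch_set.subjects, val_subjects)
    else:
        perm = rng.permutation(n)
        n_val = max(1, int(round(n * val_fraction)))
        val_idx = np.zeros(n, dtype=bool)
        val_idx[perm[:n_val]] = True
    if val_idx.all() or not val_idx.any():
        raise ConfigurationError("validation split is empty (or swallowed all patches)")
    return ~val_idx, val_idx


def train_unet(
    patch_set: PatchSet,
    unet_config: UNetConfig | None = None,
    train_config: TrainConfig | None = None,
) -> tuple[nn.UNet, pd.DataFrame]:
    """Train the U-Net with SGD + momentum on binary cross-entropy.

    Returns the network restored to the epoch of minimum validation
    loss, together with a per-epoch history (train/val loss and IoU).
    """
    if patch_set.masks is None:
        raise ConfigurationError("training requires target masks")
    train_config = train_config or TrainConfig()
    train_config.validate()
    net = build_unet(unet_config)
    rng = np.random.default_rng(train_config.seed)
    tr, va = _split_train_val(patch_set, train_config.val_fraction, rng)
    x_tr, y_tr = patch_set.patches[tr], patch_set.masks[tr]
    x_va, y_va = patch_set.patches[va], patch_set.masks[va]
    opt = nn.SGD(net.params(), lr=train_config.learning_rate, momentum=train_config.momentum)
    history = []
    best = (np.inf, None)
    for epoch in range(train_config.epochs):
        order = rng.permutation(len(x_tr))
        losses, iou_scores = [], []
        for i in range(0, len(order), train_config.batch_size):
            idx = order[i : i + train_config.batch_size]
            losses.append(net.train_step(x_tr[idx][:, None], y_tr[idx], opt, eps=train_config.bce_eps))
            iou_scores.append(_mean_iou(net._probs[:, 0], y_tr[idx]))
        p_va = _predict_patches(net, x_va, train_config.batch_size)
        val_loss = bce_loss(y_va, p_va, train_config.bce_eps)
        history.append(
            dict(epoch=epoch, train_loss=float(np.mean(losses)), val_loss=val_loss,
                 train_iou=float(np.mean(iou_scores)), val_iou=_mean_iou(p_va, y_va))
        )
        if val_loss < best[0]:
            best = (val_loss, net.get_weights())
    if best[1] is not None:
        net.set_weights(best[1])
    net.trained = True
    return net, pd.DataFrame(history)


# ---------------------------------------------------------------------------
# prediction and refinement
# ---------------------------------------------------------------------------

def predict_mask(net: nn.UNet, series: DynamicSeries, frame_index: int) -> tuple[KidneyMask, KidneyMask]:
    """Predict left/right whole-kidney masks on one frame of a series.

    One central patch per side per slice is classified and thresholded
    at probability 0.5, then reassembled onto the full grid.
    """
    net.require_trained()
    if not 0 <= frame_index < series.n_frames:
        raise ParameterError(f"frame index {frame_index} outside series")
    volume = series.frame(frame_index)
    patches = extract_patches(volume, mask=None)
    probs = _predict_patches(net, patches.patches)
    fitted_shape = _fit_inplane(volume).shape
    ny = fitted_shape[1]
    y0 = (ny - PATCH) // 2
    masks = {side: np.zeros(fitted_shape, dtype=bool) for side in ("left", "right")}
    for row, prob in zip(patches.provenance.itertuples(), probs):
        masks[row.side][_SIDE_SLICES[row.side], y0 : y0 + PATCH, row.slice_index] = prob >= 0.5
    return KidneyMask(masks["left"], "left"), KidneyMask(masks["right"], "right")


def largest_component(mask, connectivity_3d: bool = True):
    """Keep only the largest connected component (26-connected in 3D).

    Accepts a :class:`KidneyMask` or a boolean array (3D, or 2D with
    8-connectivity).  Empty input is returned unchanged with a warning;
    ties are broken toward the component containing the lowest
    flat-index voxel (logged).
    """
    is_mask = isinstance(mask, KidneyMask)
    data = mask.data if is_mask else np.asarray(mask, dtype=bool)
    if not data.any():
        warnings.warn("largest_component received an empty mask", stacklevel=2)
        return mask
    structure = np.ones((3,) * data.ndim) if connectivity_3d or data.ndim == 2 else None
    labeled, n = ndimage.label(data, structure=structure)
    counts = np.bincount(labeled.ravel())
    counts[0] = 0
    winners = np.flatnonzero(counts == counts.max())
    if len(winners) > 1:
        flat = labeled.ravel()
        first_index = [np.flatnonzero(flat == w)[0] for w in winners]
        keep = winners[int(np.argmin(first_index))]
        logger.info("largest_component tie between %d components; keeping lowest-coordinate one", len(winners))
    else:
        keep = winners[0]
    out = labeled == keep
    return KidneyMask(out, mask.side) if is_mask else out
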