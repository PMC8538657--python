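"""Data containers and on-disk formats.

The in-memory objects every pipeline stage consumes live here:
:class:`DynamicSeries` (the 4D contrast-enhanced acquisition),
:class:`KidneyMask`, :class:`CompartmentLabelMap` and :class:`AIFCurve`.

On disk, volumes are NIfTI-1 (via nibabel) with acquisition metadata
(frame times, TR/TE, flip angle, number of baseline frames) in a JSON
sidecar rather than squeezed into NIfTI header fields — the sidecar is
bit-exact and self-describing.  Curves and tables are CSV, configuration
is YAML, fitted model artifacts are joblib bundles stamped with the
package version, the seed and a hash of the configuration that produced
them.

Conventions: coordinates are 0-based with axis order (x, y, z, t).  The
"left"/"right" side tags refer to image halves; whether the image left
half is the subject's anatomical left or right is governed by the
``orientation`` flag (``radiological`` means the subject's left kidney
appears in the image right half).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, FormatError, ShapeError

__all__ = [
    "DynamicSeries",
    "KidneyMask",
    "CompartmentLabelMap",
    "AIFCurve",
    "ModelArtifact",
    "read_series",
    "write_series",
    "read_labels",
    "write_labels",
    "read_mask",
    "write_mask",
    "read_aif",
    "write_aif",
    "load_config",
    "validate_config",
    "save_model",
    "load_model",
    "config_hash",
]

VALID_LABEL_CODES = (0, 1, 2, 3)
LABEL_NAMES = {0: "background", 1: "cortex", 2: "medulla", 3: "pelvis"}

#: required keys (and types) of a segmentation-training configuration
SEG_TRAIN_SCHEMA = {
    "patch_size": int,
    "base_filters": int,
    "epochs": int,
    "learning_rate": float,
    "momentum": float,
}


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class DynamicSeries:
    """A 4D dynamic contrast-enhanced series.

    Attributes
    ----------
    data : ndarray, shape (x, y, z, t)
        Signal intensity in arbitrary scanner units (non-negative).
    spacing : tuple of float
        Voxel spacing in mm, (dx, dy, dz).
    frame_times : ndarray, shape (t,)
        Acquisition time of each frame in seconds, strictly increasing.
    tr_ms, te_ms : float
        Repetition / echo time of the spoiled gradient echo sequence (ms).
    flip_angle_deg : float
        Excitation flip angle (degrees).
    n_baseline_frames : int
        Number of pre-contrast frames at the start of the series.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    frame_times: np.ndarray
    tr_ms: float
    te_ms: float
    flip_angle_deg: float
    n_baseline_frames: int

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.data.ndim != 4:
            raise ShapeError(f"DynamicSeries data must be 4D (x,y,z,t); got {self.data.ndim}D")
        if self.frame_times.shape != (self.data.shape[3],):
            raise ShapeError(
                f"frame_times length {self.frame_times.size} != number of frames {self.data.shape[3]}"
            )
        if np.any(np.diff(self.frame_times) <= 0):
            raise FormatError("frame_times must be strictly increasing")
        if any(s <= 0 for s in self.spacing):
            raise FormatError("voxel spacing must be positive")
        if np.any(self.data < 0):
            raise FormatError("signal intensities must be non-negative")
        if not 0 <= self.n_baseline_frames < self.data.shape[3]:
            raise FormatError("n_baseline_frames must be < number of frames")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]

    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.spacing)) / 1000.0

    def baseline_mean(self) -> np.ndarray:
        """Per-voxel mean over the pre-contrast frames."""
        return self.data[..., : self.n_baseline_frames].mean(axis=3)

    def frame(self, index: int) -> np.ndarray:
        return self.data[..., index]


@dataclass
class KidneyMask:
    """Boolean 3D kidney mask with a side tag ('left' or 'right' image half)."""

    data: np.ndarray
    side: str

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 3:
            raise ShapeError(f"KidneyMask must be 3D; got {self.data.ndim}D")
        if self.side not in ("left", "right"):
            raise FormatError(f"unknown side tag {self.side!r}; expected 'left' or 'right'")

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


@dataclass
class CompartmentLabelMap:
    """Integer 3D map: 0 background, 1 cortex, 2 medulla, 3 pelvis."""

    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ShapeError(f"CompartmentLabelMap must be 3D; got {self.data.ndim}D")
        codes = np.unique(self.data)
        bad = [int(c) for c in codes if c not in VALID_LABEL_CODES]
        if bad:
            raise FormatError(f"unknown label codes {bad}; valid codes are {VALID_LABEL_CODES}")
        self.data = self.data.astype(np.uint8)

    def support(self, code: int) -> int:
        return int(np.count_nonzero(self.data == code))


@dataclass
class AIFCurve:
    """Arterial input function: plasma concentration (mmol/L) versus time (s)."""

    times: np.ndarray
    concentration: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.concentration = np.asarray(self.concentration, dtype=float)
        if self.times.shape != self.concentration.shape or self.times.ndim != 1:
            raise ShapeError("AIF times and concentration must be 1D arrays of equal length")
        if np.any(np.diff(self.times) < 0):
            raise FormatError("AIF times must be non-decreasing")
        if np.any(self.concentration < 0):
            raise FormatError("AIF concentration must be non-negative")


@dataclass
class ModelArtifact:
    """A persisted fitted model plus the provenance needed to reproduce it."""

    payload: object
    version: str
    seed: int | None
    config_hash: str
    config: dict | None = field(default=None)


# ---------------------------------------------------------------------------
# NIfTI volumes
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def _affine(spacing) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def write_series(series: DynamicSeries, path) -> Path:
    """Write a 4D series as NIfTI-1 plus a JSON metadata sidecar."""
    path = Path(path)
    img = nib.Nifti1Image(series.data, _affine(series.spacing))
    nib.save(img, str(path))
    sidecar = {
        "frame_times_s": series.frame_times.tolist(),
        "tr_ms": series.tr_ms,
        "te_ms": series.te_ms,
        "flip_angle_deg": series.flip_angle_deg,
        "n_baseline_frames": series.n_baseline_frames,
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


def read_series(path) -> DynamicSeries:
    """Read a 4D series written by :func:`write_series`."""
    path = Path(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 4:
        raise FormatError(f"expected a 4D NIfTI series; {path.name} has {data.ndim} dimensions")
    sc_path = _sidecar_path(path)
    if not sc_path.exists():
        raise FormatError(f"missing JSON sidecar {sc_path.name} for series {path.name}")
    sidecar = json.loads(sc_path.read_text())
    for key in ("frame_times_s", "tr_ms", "te_ms", "flip_angle_deg", "n_baseline_frames"):
        if key not in sidecar:
            raise FormatError(f"sidecar {sc_path.name} is missing required field '{key}'")
    spacing = tuple(float(abs(img.affine[i, i])) for i in range(3))
    return DynamicSeries(
        data=data,
        spacing=spacing,
        frame_times=np.asarray(sidecar["frame_times_s"], dtype=float),
        tr_ms=float(sidecar["tr_ms"]),
        te_ms=float(sidecar["te_ms"]),
        flip_angle_deg=float(sidecar["flip_angle_deg"]),
        n_baseline_frames=int(sidecar["n_baseline_frames"]),
    )


def write_labels(labels: CompartmentLabelMap, path, spacing=(1.0, 1.0, 1.0)) -> Path:
    path = Path(path)
    nib.save(nib.Nifti1Image(labels.data.astype(np.uint8), _affine(spacing)), str(path))
    return path


def read_labels(path) -> CompartmentLabelMap:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"expected a 3D label map; got {data.ndim}D")
    return CompartmentLabelMap(np.rint(data).astype(np.int64))


def write_mask(mask: KidneyMask, path, spacing=(1.0, 1.0, 1.0)) -> Path:
    path = Path(path)
    nib.save(nib.Nifti1Image(mask.data.astype(np.uint8), _affine(spacing)), str(path))
    return path


def read_mask(path, side: str) -> KidneyMask:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"expected a 3D mask; got {data.ndim}D")
    return KidneyMask(data > 0.5, side=side)


# ---------------------------------------------------------------------------
# curves, configuration, model artifacts
# ---------------------------------------------------------------------------

def write_aif(aif: AIFCurve, path) -> Path:
    path = Path(path)
    pd.DataFrame({"time_s": aif.times, "concentration_mmol_l": aif.concentration}).to_csv(
        path, index=False
    )
    return path


def read_aif(path) -> AIFCurve:
    df = pd.read_csv(path)
    for col in ("time_s", "concentration_mmol_l"):
        if col not in df.columns:
            raise FormatError(f"AIF CSV is missing required column '{col}'")
    conc = df["concentration_mmol_l"].to_numpy(dtype=float)
    if np.any(conc < 0):
        raise FormatError("AIF CSV contains negative concentration values")
    return AIFCurve(times=df["time_s"].to_numpy(dtype=float), concentration=conc)


def validate_config(config: dict, schema: dict) -> dict:
    """Check required keys/types; raise :class:`ConfigurationError` naming the key."""
    for key, typ in schema.items():
        if key not in config:
            raise ConfigurationError(f"configuration is missing required key '{key}'")
        value = config[key]
        if typ is float and isinstance(value, int):
            value = float(value)
        if not isinstance(value, typ):
            raise ConfigurationError(
                f"configuration key '{key}' must be of type {typ.__name__}, got {type(value).__name__}"
            )
    return config


def load_config(path, schema: dict | None = None) -> dict:
    """Load a YAML configuration file, optionally validated against a schema."""
    with open(path) as fh:
        config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise ConfigurationError("configuration file must contain a YAML mapping")
    if schema is not None:
        validate_config(config, schema)
    return config


def config_hash(config) -> str:
    """Stable sha256 of a (nested, JSON-serialisable) configuration."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


def save_model(path, payload, *, seed: int | None = None, config: dict | None = None) -> Path:
    """Persist a fitted model with version + seed + config-hash metadata."""
    from . import __version__

    path = Path(path)
    artifact = ModelArtifact(
        payload=payload,
        version=__version__,
        seed=seed,
        config_hash=config_hash(config or {}),
        config=config,
    )
    joblib.dump(artifact, path)
    return path


def load_model(path) -> ModelArtifact:
    artifact = joblib.load(path)
    if not isinstance(artifact, ModelArtifact):
        raise FormatError("file does not contain a renodce model artifact")
    return artifact
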