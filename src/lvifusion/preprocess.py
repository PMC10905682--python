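"""From a case to the 19-channel network input, plus split and augmentation.

The network consumes a ``(19, 32, 32, 32)`` tensor: three VOI-centered cubic
patches (one per modality, intensity-normalized to [0, 1] on the whole volume
before cropping) stacked with 16 spatially constant planes, each filled with
one min-max-scaled prior clinico-radiological feature.  Volumes are assumed
resampled to 1 mm isotropic so a 32 mm cube is a 32-voxel cube.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import Case, PRIOR_FEATURE_NAMES

__all__ = [
    "PATCH_SIZE",
    "InputTensor",
    "SplitConfig",
    "normalize_intensity",
    "crop_voi_patch",
    "PriorFeatureScaler",
    "scale_prior_features",
    "encode_prior_planes",
    "assemble_input",
    "flip_tensor",
    "random_flip",
    "stratified_split",
    "case_to_input",
]

PATCH_SIZE = 32


@dataclass
class InputTensor:
    """Stacked network input: channels 0-2 are image patches, 3-18 (when
    present) are constant prior planes in the fixed feature order."""

    data: np.ndarray  # (19, s, s, s) or (3, s, s, s) float32, values in [0, 1]
    case_id: str = ""
    flipped_axes: tuple[int, ...] = ()


@dataclass
class SplitConfig:
    train_fraction: float = 0.7
    seed: int = 0
    allocation_rule: str = "floor_validation"  # or "largest_remainder"

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie strictly in (0, 1)")
        if self.allocation_rule not in ("floor_validation", "largest_remainder"):
            raise ValueError(f"unknown allocation_rule {self.allocation_rule!r}")


def normalize_intensity(volume: np.ndarray) -> np.ndarray:
    """Clip negatives to zero, then scale by the per-volume maximum.

    An all-zero (after clipping) volume is returned unchanged; idempotent.
    """
    volume = np.asarray(volume)
    if not np.all(np.isfinite(volume)):
        raise ValueError("volume contains NaN or Inf voxels")
    clipped = np.clip(volume, 0.0, None)
    m = float(clipped.max(initial=0.0))
    if m == 0.0:
        return clipped.astype(np.float32)
    return (clipped / m).astype(np.float32)


def crop_voi_patch(volume: np.ndarray, center: Sequence[int], size: int = PATCH_SIZE) -> np.ndarray:
    """VOI-centered cubic patch over the half-open window [c-size//2, c+size//2).

    Voxels falling outside the volume are zero-filled (zero is background
    after intensity normalization).
    """
    volume = np.asarray(volume)
    if volume.ndim != 3:
        raise ValueError("expected a 3D volume")
    center = tuple(int(c) for c in center)
    if not all(0 <= c < s for c, s in zip(center, volume.shape)):
        raise IndexError(f"VOI center {center} outside volume of shape {volume.shape}")
    half = size // 2
    patch = np.zeros((size,) * 3, dtype=volume.dtype)
    src, dst = [], []
    for c, s in zip(center, volume.shape):
        lo, hi = c - half, c - half + size
        src.append(slice(max(lo, 0), min(hi, s)))
        dst.append(slice(max(lo, 0) - lo, min(hi, s) - lo))
    patch[tuple(dst)] = volume[tuple(src)]
    return patch


@dataclass
class PriorFeatureScaler:
    """Per-feature min-max scaling to [0, 1], fitted on training rows only.

    Validation values are clipped into [0, 1]; a feature constant on the
    training set maps to 0.
    """

    mins: pd.Series | None = None
    ranges: pd.Series | None = None
    columns: list[str] = field(default_factory=list)

    def fit(self, table: pd.DataFrame) -> "PriorFeatureScaler":
        if len(table) == 0:
            raise ValueError("cannot fit scaler on an empty training set")
        self.columns = list(table.columns)
        self.mins = table.min(axis=0).astype(float)
        self.ranges = (table.max(axis=0) - table.min(axis=0)).astype(float)
        return self

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        if self.mins is None:
            raise ValueError("scaler has not been fitted")
        table = table[self.columns]
        out = {}
        for col in self.columns:
            rng = self.ranges[col]
            if rng == 0.0:
                out[col] = np.zeros(len(table))
            else:
                out[col] = np.clip((table[col].to_numpy(float) - self.mins[col]) / rng, 0.0, 1.0)
        return pd.DataFrame(out, index=table.index)

    def to_dict(self) -> dict:
        return {
            "columns": self.columns,
            "mins": {c: float(self.mins[c]) for c in self.columns},
            "ranges": {c: float(self.ranges[c]) for c in self.columns},
        }


def scale_prior_features(
    train_table: pd.DataFrame, table: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, PriorFeatureScaler]:
    """Fit min-max scaling on ``train_table`` and transform ``table``
    (defaults to the training table itself)."""
    scaler = PriorFeatureScaler().fit(train_table)
    return scaler.transform(train_table if table is None else table), scaler


def encode_prior_planes(values: Sequence[float], size: int = PATCH_SIZE) -> np.ndarray:
    """16 spatially constant planes, one per scaled prior feature."""
    vals = np.asarray(values, dtype=np.float32)
    if vals.ndim != 1 or vals.shape[0] != len(PRIOR_FEATURE_NAMES):
        raise ValueError(f"expected {len(PRIOR_FEATURE_NAMES)} scaled feature values")
    if np.any(vals < 0.0) or np.any(vals > 1.0):
        raise ValueError("prior features must be scaled to [0, 1] before plane encoding")
    return np.broadcast_to(vals[:, None, None, None], (len(vals), size, size, size)).copy()


def assemble_input(
    patches: Sequence[np.ndarray], planes: np.ndarray | None = None
) -> np.ndarray:
    """Stack 3 image patches (and, unless ablated, 16 prior planes) into the
    channel-first network input."""
    patches = [np.asarray(p, dtype=np.float32) for p in patches]
    shape = patches[0].shape
    if any(p.shape != shape for p in patches):
        raise ValueError("all patches must share one cubic shape")
    chans = list(patches)
    if planes is not None:
        planes = np.asarray(planes, dtype=np.float32)
        if planes.shape[1:] != shape:
            raise ValueError("plane shape does not match patch shape")
        chans.extend(planes)
    return np.stack(chans, axis=0)


def flip_tensor(x: np.ndarray, mask: Sequence[bool]) -> np.ndarray:
    """Reverse the spatial axes selected by ``mask``; all channels together."""
    axes = tuple(i + 1 for i, m in enumerate(mask) if m)
    return np.flip(x, axis=axes).copy() if axes else x.copy()


def random_flip(
    x: np.ndarray, rng: int | np.random.Generator
) -> tuple[np.ndarray, tuple[bool, bool, bool]]:
    """Each spatial axis independently reversed with probability 1/2.

    Constant planes are unchanged by construction; returns the flipped tensor
    and the flip mask for provenance.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    mask = tuple(bool(b) for b in rng.random(3) < 0.5)
    return flip_tensor(x, mask), mask


def _labels_of(cases) -> np.ndarray:
    if len(cases) == 0:
        raise ValueError("cannot split an empty cohort")
    if hasattr(cases[0], "lvi_label"):
        return np.asarray([c.lvi_label for c in cases])
    return np.asarray(cases)


def stratified_split(cases, cfg: SplitConfig) -> tuple[np.ndarray, np.ndarray]:
    """Label-stratified random partition into train and validation indices.

    Per-stratum validation counts follow ``cfg.allocation_rule``:
    ``floor_validation`` floors each stratum's validation quota (remainder to
    training); ``largest_remainder`` apportions the rounded total validation
    size across strata by largest fractional remainder.
    """
    labels = _labels_of(cases)
    n = len(labels)
    strata = [np.flatnonzero(labels == v) for v in np.unique(labels)]
    if any(len(s) == 0 for s in strata) or len(strata) < 1:
        raise ValueError("every label stratum must be non-empty")
    val_frac = 1.0 - cfg.train_fraction
    quotas = [len(s) * val_frac for s in strata]
    n_val = [int(np.floor(q)) for q in quotas]
    if cfg.allocation_rule == "largest_remainder":
        total = int(round(n * val_frac))
        remainders = [q - f for q, f in zip(quotas, n_val)]
        order = np.argsort(remainders)[::-1]
        for k in order:
            if sum(n_val) >= total:
                break
            n_val[k] += 1
    rng = np.random.default_rng(cfg.seed)
    train_idx, val_idx = [], []
    for s, nv in zip(strata, n_val):
        perm = rng.permutation(s)
        val_idx.append(perm[:nv])
        train_idx.append(perm[nv:])
    train = np.sort(np.concatenate(train_idx))
    val = np.sort(np.concatenate(val_idx))
    assert len(train) + len(val) == n
    return train, val


def case_to_input(
    case: Case,
    scaled_features: Sequence[float] | None,
    size: int = PATCH_SIZE,
) -> InputTensor:
    """Normalize each volume, crop the VOI patch, and stack with the prior
    planes (pass ``scaled_features=None`` for the image-only ablation)."""
    patches = [
        crop_voi_patch(normalize_intensity(case.volumes[m]), case.voi_center, size)
        for m in range(case.volumes.shape[0])
    ]
    planes = None if scaled_features is None else encode_prior_planes(scaled_features, size)
    return InputTensor(data=assemble_input(patches, planes), case_id=case.case_id)
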