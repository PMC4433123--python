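"""Volume input/output and conversion between volume space and voxel features.

All volumes are NIfTI-1 (``.nii`` / ``.nii.gz``) handled through nibabel.
Inputs must already be co-registered: every channel and the brain mask of a
study share the same grid and (within tolerance) the same affine.  No
resampling is performed.

Voxel ordering is always lexicographic over 0-based array coordinates
``(i, j, k)``, which makes the flat feature representation deterministic and
invertible.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

#: Channel names a study must provide, in canonical order.
CHANNELS = ("T1", "T1c", "T2", "Flair")

AFFINE_ATOL = 1e-5


class CoregistrationError(ValueError):
    """Raised when volumes that must share a grid/affine do not."""


@dataclass
class MultiChannelStudy:
    """One patient's aligned multi-channel MR volumes plus brain mask.

    Attributes
    ----------
    channels : dict
        Maps channel name (``T1``, ``T1c``, ``T2``, ``Flair``) to a 3-D
        float array.
    brain_mask : numpy.ndarray
        3-D boolean array; True inside the brain.
    affine : numpy.ndarray
        4x4 voxel-to-world transform shared by all volumes.
    """

    channels: dict[str, np.ndarray]
    brain_mask: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.brain_mask.shape)

    def __post_init__(self) -> None:
        self.brain_mask = np.asarray(self.brain_mask) > 0
        if self.brain_mask.ndim != 3:
            raise ValueError("brain mask must be 3-D")
        if not self.brain_mask.any():
            raise ValueError("brain mask has no foreground voxels")
        self.affine = np.asarray(self.affine, dtype=float)
        for name, vol in self.channels.items():
            vol = np.asarray(vol, dtype=float)
            if vol.shape != self.brain_mask.shape:
                raise CoregistrationError(
                    f"channel {name!r} shape {vol.shape} != mask shape "
                    f"{self.brain_mask.shape}"
                )
            if not np.isfinite(vol[self.brain_mask]).all():
                raise ValueError(f"channel {name!r} has non-finite values inside the mask")
            self.channels[name] = vol

    @property
    def n_voxels(self) -> int:
        """Number of in-mask voxels."""
        return int(self.brain_mask.sum())


@dataclass
class FeatureMatrix:
    """Per-voxel feature vectors restricted to in-mask voxels.

    ``values[n]`` is the feature vector of the voxel at array coordinates
    ``index_map[n]``; rows are ordered lexicographically by coordinate.
    """

    values: np.ndarray          # (N, D)
    index_map: np.ndarray       # (N, 3) integer voxel coordinates
    shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.index_map = np.asarray(self.index_map)
        if self.values.ndim != 2:
            raise ValueError("values must be an N x D matrix")
        if len(self.index_map) != len(self.values):
            raise ValueError("index_map length must equal number of rows")
        if not np.isfinite(self.values).all():
            raise ValueError("feature values must be finite")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]


@dataclass
class LabelVolume:
    """Integer label volume: 0 = background/everything-else, >0 = classes."""

    labels: np.ndarray
    legend: dict[int, str] = field(default_factory=dict)
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            rounded = np.rint(self.labels)
            if not np.allclose(self.labels, rounded):
                raise ValueError("label volume must be integer-valued")
            self.labels = rounded.astype(np.int32)

    def present_labels(self) -> list[int]:
        return [int(v) for v in np.unique(self.labels) if v > 0]


def read_volume(path: str | os.PathLike) -> tuple[np.ndarray, np.ndarray]:
    """Read a 3-D NIfTI volume.

    Returns ``(data, affine)`` with data promoted to float64.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such volume: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D image, got {data.ndim}-D")
    return data.astype(np.float64), np.asarray(img.affine, dtype=float)


def write_volume(volume: np.ndarray, affine: np.ndarray, path: str | os.PathLike) -> None:
    """Write a 3-D volume as NIfTI.

    Integer-typed (or boolean) arrays are written with an integer dtype so
    that label volumes round-trip exactly; everything else is float64.
    """
    volume = np.asarray(volume)
    if volume.ndim != 3 or 0 in volume.shape:
        raise ValueError(f"expected a non-empty 3-D volume, got shape {volume.shape}")
    if volume.dtype == bool or np.issubdtype(volume.dtype, np.integer):
        out = volume.astype(np.int16)
    else:
        out = volume.astype(np.float64)
    nib.save(nib.Nifti1Image(out, np.asarray(affine, dtype=float)), str(path))


def assemble_study(channel_paths: dict[str, str | os.PathLike],
                   mask_path: str | os.PathLike) -> MultiChannelStudy:
    """Load the four channels and the brain mask into a validated study.

    All inputs must share shape and affine (tolerance 1e-5 on the affine);
    the mask is binarized at > 0.
    """
    missing = [c for c in CHANNELS if c not in channel_paths]
    if missing:
        raise ValueError(f"missing channel(s): {', '.join(missing)}")
    mask, affine = read_volume(mask_path)
    channels = {}
    for name in CHANNELS:
        vol, aff = read_volume(channel_paths[name])
        if vol.shape != mask.shape:
            raise CoregistrationError(
                f"channel {name!r} shape {vol.shape} != mask shape {mask.shape}")
        if not np.allclose(aff, affine, atol=AFFINE_ATOL):
            raise CoregistrationError(f"channel {name!r} affine differs from mask affine")
        channels[name] = vol
    return MultiChannelStudy(channels=channels, brain_mask=mask > 0, affine=affine)


def flatten_to_features(stack: list[np.ndarray] | np.ndarray,
                        mask: np.ndarray) -> FeatureMatrix:
    """Stack volumes into an N x D feature matrix over in-mask voxels.

    Row ``n`` holds the values of all ``D`` volumes at the n-th in-mask
    voxel in lexicographic coordinate order.
    """
    mask = np.asarray(mask) > 0
    stack = [np.asarray(v, dtype=float) for v in stack]
    if len(stack) == 0:
        raise ValueError("empty volume stack")
    for v in stack:
        if v.shape != mask.shape:
            raise ValueError("stack volume shape does not match mask")
    if not mask.any():
        raise ValueError("empty mask")
    idx = np.argwhere(mask)  # lexicographic by construction
    values = np.column_stack([v[mask] for v in stack])
    return FeatureMatrix(values=values, index_map=idx, shape=tuple(mask.shape))


def scatter_labels(assignment: np.ndarray, index_map: np.ndarray,
                   shape: tuple[int, int, int],
                   legend: dict[int, str] | None = None,
                   affine: np.ndarray | None = None) -> LabelVolume:
    """Scatter a per-voxel integer assignment back into a label volume.

    Voxels not listed in ``index_map`` are 0.
    """
    assignment = np.asarray(assignment)
    index_map = np.asarray(index_map)
    if len(assignment) != len(index_map):
        raise ValueError(
            f"assignment length {len(assignment)} != index_map length {len(index_map)}")
    labels = np.zeros(shape, dtype=np.int32)
    labels[index_map[:, 0], index_map[:, 1], index_map[:, 2]] = assignment
    return LabelVolume(labels=labels, legend=dict(legend or {}),
                       affine=np.eye(4) if affine is None else affine)


def scatter_values(values: np.ndarray, index_map: np.ndarray,
                   shape: tuple[int, int, int], fill: float = 0.0) -> np.ndarray:
    """Scatter a per-voxel scalar quantity into a float volume (inverse of flatten)."""
    values = np.asarray(values, dtype=float)
    index_map = np.asarray(index_map)
    if len(values) != len(index_map):
        raise ValueError("length mismatch between values and index_map")
    vol = np.full(shape, fill, dtype=float)
    vol[index_map[:, 0], index_map[:, 1], index_map[:, 2]] = values
    return vol
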