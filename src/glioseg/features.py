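"""First-order texture feature stack and PCA dimensionality reduction.

Starting from the four MR contrasts (T1, T1c, T2, Flair) a fifth derived
image T1d = |T1c - T1| is built; it highlights contrast-enhancing tissue.
For each of the five base images the mean, skewness and kurtosis of the
voxel values in a local (2r+1)^3 neighbourhood are computed, giving a stack
of 20 images per study (5 bases + 3 moments x 5 bases).

The stack is flattened over in-mask voxels, each feature standardized, and
reduced with PCA keeping the smallest number of leading components whose
cumulative explained variance reaches at least 99%.

Conventions
-----------
* Neighbourhoods are clipped at the volume border and restricted to in-mask
  voxels; no padding values ever enter a moment.
* Skewness is the third standardized moment, kurtosis the plain (non-excess)
  fourth standardized moment (Gaussian => 3).  A neighbourhood with zero
  variance (or fewer than 2 in-mask voxels) yields (mean, 0, 0).
* Moments are computed from mask-weighted running sums of powers via
  separable box filters; the volume is shifted by its global in-mask mean
  first, which leaves all three outputs unchanged mathematically but keeps
  the power sums well conditioned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from sklearn.decomposition import PCA

from .volume_io import FeatureMatrix, MultiChannelStudy, flatten_to_features

#: Base image names in canonical order.
BASES = ("T1", "T1c", "T2", "Flair", "T1d")

#: Moment prefixes: mu = local mean, gamma = skewness, kappa = kurtosis.
MOMENT_PREFIXES = ("mu", "gamma", "kappa")

DEFAULT_RADIUS = 2  # 5 x 5 x 5 neighbourhood

_VAR_EPS = 1e-12  # relative zero-variance cutoff


@dataclass
class FeatureStack:
    """Ordered 20-image stack: 5 bases then mu/gamma/kappa of each base."""

    images: list[np.ndarray]
    names: list[str]
    neighbourhood_radius: int = DEFAULT_RADIUS

    def __post_init__(self) -> None:
        if len(self.images) != len(self.names):
            raise ValueError("images and names length mismatch")
        shapes = {im.shape for im in self.images}
        if len(shapes) > 1:
            raise ValueError("stack images must share one shape")


@dataclass
class PcaModel:
    """Fitted standardize-then-PCA reduction.

    ``explained_fractions`` holds the full 20-long spectrum (non-increasing,
    sums to 1); ``k`` is the smallest count whose cumulative sum reaches the
    variance threshold.
    """

    mean: np.ndarray            # (D0,)
    scale: np.ndarray           # (D0,)
    components: np.ndarray      # (K, D0)
    explained_fractions: np.ndarray
    k: int
    variance_threshold: float = 0.99

    def transform(self, x: np.ndarray) -> np.ndarray:
        z = (np.asarray(x, dtype=float) - self.mean) / self.scale
        return z @ self.components.T


def compute_t1d(t1c: np.ndarray, t1: np.ndarray) -> np.ndarray:
    """Derived image |T1c - T1| (non-negative; highlights enhancement)."""
    t1c = np.asarray(t1c, dtype=float)
    t1 = np.asarray(t1, dtype=float)
    if t1c.shape != t1.shape:
        raise ValueError(f"shape mismatch: {t1c.shape} vs {t1.shape}")
    return np.abs(t1c - t1)


def _box_sum(volume: np.ndarray, size: int) -> np.ndarray:
    """Sum over the clipped (size^3) box at each voxel (zeros outside)."""
    return ndimage.uniform_filter(volume, size=size, mode="constant", cval=0.0) * size**3


def local_first_order_moments(volume: np.ndarray, mask: np.ndarray,
                              radius: int = DEFAULT_RADIUS
                              ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Local mean, skewness and kurtosis over in-mask neighbourhood voxels.

    Returns three volumes, zero outside the mask.
    """
    if radius < 1:
        raise ValueError("radius must be >= 1")
    volume = np.asarray(volume, dtype=float)
    mask = np.asarray(mask) > 0
    if volume.shape != mask.shape:
        raise ValueError("volume and mask shapes differ")
    if not mask.any():
        raise ValueError("empty mask")
    size = 2 * radius + 1
    m = mask.astype(float)
    shift = float(volume[mask].mean())
    v = np.where(mask, volume - shift, 0.0)

    cnt = _box_sum(m, size)
    cnt = np.rint(cnt)
    s1 = _box_sum(v, size)
    s2 = _box_sum(v * v, size)
    s3 = _box_sum(v ** 3, size)
    s4 = _box_sum(v ** 4, size)

    with np.errstate(divide="ignore", invalid="ignore"):
        n = np.where(cnt > 0, cnt, 1.0)
        mu = s1 / n
        m2 = s2 / n - mu**2
        m3 = s3 / n - 3 * mu * s2 / n + 2 * mu**3
        m4 = s4 / n - 4 * mu * s3 / n + 6 * mu**2 * s2 / n - 3 * mu**4
        # zero-variance convention: skew = kurt = 0; scale-relative cutoff
        ref = s2 / n + mu**2  # mean of squares, local magnitude reference
        degenerate = (cnt < 2) | (m2 <= _VAR_EPS * np.maximum(ref, 1.0))
        m2s = np.where(degenerate, 1.0, m2)
        skew = np.where(degenerate, 0.0, m3 / m2s**1.5)
        kurt = np.where(degenerate, 0.0, m4 / m2s**2)

    mean = np.where(mask, mu + shift, 0.0)
    skew = np.where(mask, skew, 0.0)
    kurt = np.where(mask, kurt, 0.0)
    return mean, skew, kurt


def build_feature_stack(study: MultiChannelStudy,
                        radius: int = DEFAULT_RADIUS) -> FeatureStack:
    """Build the ordered 20-image stack for a study.

    Order: T1, T1c, T2, Flair, T1d, then mu/gamma/kappa blocks, each block
    over the five bases in that same order.
    """
    base_images = {name: study.channels[name] for name in BASES[:4]}
    base_images["T1d"] = compute_t1d(study.channels["T1c"], study.channels["T1"])

    images = [base_images[b] for b in BASES]
    names = list(BASES)
    moments = {b: local_first_order_moments(base_images[b], study.brain_mask, radius)
               for b in BASES}
    for i, prefix in enumerate(MOMENT_PREFIXES):
        for b in BASES:
            images.append(moments[b][i])
            names.append(f"{prefix}_{b}")
    return FeatureStack(images=images, names=names, neighbourhood_radius=radius)


def reduce_dimensionality(stack: FeatureStack, mask: np.ndarray,
                          variance_threshold: float = 0.99,
                          standardize: bool = True
                          ) -> tuple[PcaModel, FeatureMatrix]:
    """Standardize in-mask features and project onto the leading PCs.

    The retained dimensionality K is the smallest integer whose cumulative
    explained-variance fraction reaches ``variance_threshold``.  Features
    with zero variance are centred but not scaled.
    """
    full = flatten_to_features(stack.images, mask)
    x = full.values
    n, d = x.shape
    if n <= d:
        raise ValueError(f"need more in-mask voxels ({n}) than features ({d})")

    mean = x.mean(axis=0)
    if standardize:
        scale = x.std(axis=0)
        scale = np.where(scale > 0, scale, 1.0)
    else:
        scale = np.ones(d)
    z = (x - mean) / scale

    pca = PCA(n_components=None, svd_solver="full")
    projected = pca.fit_transform(z)
    fractions = pca.explained_variance_ratio_
    k = int(np.searchsorted(np.cumsum(fractions), variance_threshold - 1e-12) + 1)
    k = min(k, d)

    model = PcaModel(mean=mean, scale=scale, components=pca.components_[:k],
                     explained_fractions=fractions, k=k,
                     variance_threshold=variance_threshold)
    reduced = FeatureMatrix(values=projected[:, :k], index_map=full.index_map,
                            shape=full.shape)
    return model, reduced
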