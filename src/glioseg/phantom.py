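"""Synthetic multi-channel brain phantoms with ground truth.

The phantom is a nested-ellipsoid brain: a GM shell around a WM interior,
a CSF (ventricle) ellipsoid inside the WM, and a four-compartment tumour —
necrotic core, enhancing rim, non-enhancing region and edema halo — nested
inside the WM, disjoint from the CSF.  Channel intensities (T1, T1c, T2,
Flair) are drawn per tissue from Gaussians; by default each tissue has two
intensity modes (a 2-component mixture), mirroring the modelling assumption
that every brain tissue needs a mixture of two Gaussians, so the default
14-class clustering is identifiable.

Contrast relations are built in: the enhancing rim has the largest
T1c - T1 difference, edema the brightest Flair, the necrotic core the
darkest T1c among tumour compartments — exactly the cues the BRATS code
mapping relies on.

Tissue probability maps are smoothed indicators of the HEALTHY geometry:
the tumour region is attributed to the tissue that encloses it (WM), as a
population atlas warped onto a lesioned brain would be.  This makes the
lesion correction step of the isolation stage do real work.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .isolation import EDEMA, ENHANCING, NECROSIS, NON_ENHANCING, TISSUES, TissueProbabilityMaps
from .volume_io import CHANNELS, LabelVolume, MultiChannelStudy

#: Internal tissue names in label order 1..7.
TISSUE_NAMES = ("CSF", "GM", "WM", "necrosis", "edema", "non-enhancing", "enhancing")

#: Ground-truth label codes: BRATS codes for tumour, 5..7 for normal tissue.
TRUTH_CODES = {"necrosis": NECROSIS, "edema": EDEMA,
               "non-enhancing": NON_ENHANCING, "enhancing": ENHANCING,
               "CSF": 5, "GM": 6, "WM": 7}

# Per-tissue channel means, channels ordered (T1, T1c, T2, Flair).
# The values encode the contrast assumptions the pipeline relies on:
# tumour tissue is hyperintense vs normal tissue in Flair (edema most) and,
# for the enhancing rim, in T1c; post-contrast T1c shows little GM/WM
# contrast, so the in-brain T1c histogram is tight and only enhancement
# exceeds median + std; necrosis is the darkest tumour tissue on T1c.
DEFAULT_MEANS = {
    "CSF": (20.0, 22.0, 90.0, 25.0),
    "GM": (62.0, 64.0, 55.0, 55.0),
    "WM": (72.0, 66.0, 45.0, 45.0),
    "edema": (55.0, 56.0, 75.0, 92.0),
    "necrosis": (32.0, 30.0, 70.0, 62.0),
    "non-enhancing": (52.0, 56.0, 65.0, 72.0),
    "enhancing": (66.0, 110.0, 60.0, 66.0),
}


@dataclass
class Ellipsoid:
    center: tuple[float, float, float]
    radii: tuple[float, float, float]

    def mask(self, shape: tuple[int, int, int]) -> np.ndarray:
        grids = np.ogrid[tuple(slice(0, s) for s in shape)]
        acc = np.zeros(shape)
        for g, c, r in zip(grids, self.center, self.radii):
            acc = acc + ((g - c) / r) ** 2
        return acc <= 1.0


@dataclass
class PhantomSpec:
    """Geometry, intensity and noise parameters of one synthetic study."""

    name: str = "custom"
    shape: tuple[int, int, int] = (64, 64, 64)
    brain: Ellipsoid = field(default_factory=lambda: Ellipsoid((32, 32, 32), (26, 24, 22)))
    wm: Ellipsoid = field(default_factory=lambda: Ellipsoid((32, 32, 32), (20, 18, 17)))
    csf: Ellipsoid = field(default_factory=lambda: Ellipsoid((19, 35, 34), (4, 4, 4)))
    tumour_center: tuple[float, float, float] = (38.0, 33.0, 32.0)
    #: nested tumour radii, innermost first: necrotic core, enhancing rim,
    #: non-enhancing region, edema halo (each a spherical boundary)
    tumour_radii: tuple[float, float, float, float] = (5.0, 7.0, 9.0, 11.0)
    channel_means: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: {k: v for k, v in DEFAULT_MEANS.items()})
    channel_stds: dict[str, float] | float = 2.0
    #: Per-tissue two-mode intensity split: each tissue is a 2-component
    #: mixture at mean +- offset vector (per channel).  Normal-tissue
    #: heterogeneity (deep vs superficial GM/WM) shows in the precontrast
    #: T1/T2 channels and leaves T1c and Flair unimodal, so the Flair/T1c
    #: hyperintensity cues stay sharp; tumour modes are mild so same-tissue
    #: modes remain statistically similar (mergeable).  A scalar is
    #: shorthand for that same pattern scaled.
    mode_offsets: float | dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: {
            "CSF": (0.0, 0.0, 0.0, 0.0),
            "GM": (2.3, 0.5, -2.3, -2.3),
            "WM": (2.3, 0.5, -2.3, -2.3),
            "necrosis": (1.0, 0.0, 1.0, 0.0),
            "edema": (2.0, 0.0, 2.0, 0.0),
            "non-enhancing": (1.0, 0.0, 1.0, 0.0),
            "enhancing": (1.0, 0.0, 1.0, 0.0),
        })
    noise_seed: int = 0
    #: Gaussian sigma (voxels) of the atlas-prior smoothing; a dict gives
    #: per-tissue sigmas (ventricular CSF priors are diffuse in population
    #: atlases, cortical GM/WM priors comparatively sharp)
    prob_map_smoothing: float | dict[str, float] = field(
        default_factory=lambda: {"WM": 1.2, "GM": 1.2, "CSF": 2.5})

    def smoothing_of(self, tissue: str) -> float:
        if isinstance(self.prob_map_smoothing, dict):
            return float(self.prob_map_smoothing[tissue])
        return float(self.prob_map_smoothing)

    def mode_offset_of(self, tissue: str) -> np.ndarray:
        if isinstance(self.mode_offsets, dict):
            return np.asarray(self.mode_offsets[tissue], dtype=float)
        scale = float(self.mode_offsets)
        base = {"CSF": (0, 0, 0, 0), "GM": (1, 0, 1, 0), "WM": (1, 0, 1, 0)}
        return scale * np.asarray(base.get(tissue, (0.25, 0.0, 0.25, 0.0)),
                                  dtype=float)

    def std_of(self, tissue: str) -> float:
        if isinstance(self.channel_stds, dict):
            return float(self.channel_stds[tissue])
        return float(self.channel_stds)


def _tumour_masks(spec: PhantomSpec, shape) -> dict[str, np.ndarray]:
    r = spec.tumour_radii
    if not all(r[i] < r[i + 1] for i in range(3)):
        raise ValueError("tumour radii must be strictly increasing")
    balls = [Ellipsoid(spec.tumour_center, (x, x, x)).mask(shape) for x in r]
    return {
        "necrosis": balls[0],
        "enhancing": balls[1] & ~balls[0],
        "non-enhancing": balls[2] & ~balls[1],
        "edema": balls[3] & ~balls[2],
    }


def _truth_labels(spec: PhantomSpec) -> np.ndarray:
    shape = spec.shape
    brain = spec.brain.mask(shape)
    wm = spec.wm.mask(shape) & brain
    csf = spec.csf.mask(shape)
    tumour = _tumour_masks(spec, shape)
    tumour_all = np.zeros(shape, dtype=bool)
    for m in tumour.values():
        tumour_all |= m
    if not (tumour_all <= wm).all():
        raise ValueError("tumour compartments must lie inside the WM ellipsoid")
    if (tumour_all & csf).any():
        raise ValueError("tumour compartments overlap the CSF ellipsoid")
    if not (csf <= wm).all():
        raise ValueError("CSF ellipsoid must lie inside the WM ellipsoid")

    labels = np.zeros(shape, dtype=np.int32)
    labels[brain] = TRUTH_CODES["GM"]
    labels[wm] = TRUTH_CODES["WM"]
    labels[csf] = TRUTH_CODES["CSF"]
    for name, m in tumour.items():
        labels[m] = TRUTH_CODES[name]
    return labels


def generate_phantom(spec: PhantomSpec
                     ) -> tuple[MultiChannelStudy, LabelVolume, TissueProbabilityMaps]:
    """Generate one study, its ground-truth labels and aligned tissue maps.

    Deterministic given ``spec.noise_seed``.
    """
    labels = _truth_labels(spec)
    brain = labels > 0
    rng = np.random.default_rng(spec.noise_seed)

    channels = {name: np.zeros(spec.shape) for name in CHANNELS}
    for tissue in TISSUE_NAMES:
        sel = labels == TRUTH_CODES[tissue]
        n = int(sel.sum())
        if n == 0:
            continue
        means = np.asarray(spec.channel_means[tissue], dtype=float)
        std = spec.std_of(tissue)
        offset = spec.mode_offset_of(tissue)
        # two intensity modes per tissue (a 2-Gaussian mixture)
        mode = rng.integers(0, 2, size=n) * 2 - 1
        for j, name in enumerate(CHANNELS):
            vals = means[j] + offset[j] * mode + std * rng.standard_normal(n)
            channels[name][sel] = vals

    study = MultiChannelStudy(channels=channels, brain_mask=brain, affine=np.eye(4))
    truth = LabelVolume(labels=labels,
                        legend={v: k for k, v in TRUTH_CODES.items()},
                        affine=np.eye(4))

    # healthy-geometry probability maps: tumour region filled with WM
    healthy = labels.copy()
    tumour_all = (labels >= 1) & (labels <= 4)
    healthy[tumour_all] = TRUTH_CODES["WM"]
    maps = {}
    for t in TISSUES:
        ind = (healthy == TRUTH_CODES[t]).astype(float)
        maps[t] = ndimage.gaussian_filter(ind, sigma=spec.smoothing_of(t))
    total = sum(maps.values())
    for t in TISSUES:
        m = np.zeros(spec.shape)
        np.divide(maps[t], total, out=m, where=total > 1e-12)
        m[~brain] = 0.0
        maps[t] = m
    tpm = TissueProbabilityMaps(maps=maps, corrected=False)
    return study, truth, tpm


def default_specs() -> dict[str, PhantomSpec]:
    """Named presets: low-noise, moderate-noise, thin-enhancing-rim.

    * ``low-noise`` — default geometry, per-channel std 2.0; the smallest
      inter-tissue mean separation (WM vs GM, Euclidean ~31.6) is over
      5x the noise std.
    * ``moderate-noise`` — same geometry, std 5.0.
    * ``thin-enhancing-rim`` — large necrotic core with an enhancing rim
      at most 2 voxels thick and reduced rim brightness, the configuration
      reported hardest for strongly smoothed models.
    """
    low = PhantomSpec(name="low-noise", channel_stds=2.0)
    moderate = replace(low, name="moderate-noise", channel_stds=5.0)
    thin_means = {k: v for k, v in DEFAULT_MEANS.items()}
    thin_means["enhancing"] = (66.0, 90.0, 60.0, 64.0)  # low-brightness rim
    thin = replace(low, name="thin-enhancing-rim",
                   tumour_radii=(6.0, 8.0, 9.5, 11.0),
                   channel_means=thin_means)
    return {"low-noise": low, "moderate-noise": moderate,
            "thin-enhancing-rim": thin}
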