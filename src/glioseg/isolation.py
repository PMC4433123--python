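"""Automatic tumour-class isolation.

An unsupervised segmentation assigns no semantics to its classes.  This
module turns a C-class labelling into at most four tumour classes carrying
BRATS codes, in three steps mirroring how a neuro-radiology pipeline would
post-process such a segmentation:

1. **Identify and remove normal-tissue classes.**  WM/GM/CSF probability
   maps (warped atlas priors) are first corrected inside a rough lesion
   mask — voxels brighter than median + std of the in-brain Flair or T1c
   histogram, hole-filled, minus the brain perimeter — by setting every
   tissue probability there to a small epsilon.  For each tissue t the
   share of its probability mass explained by each class,
   p(c|t,S) = sum_{v: S(v)=c} p(t|v) / sum_v p(t|v),
   is sorted descending and cumulatively summed; classes past the point
   where the cumulative sum exceeds a confidence threshold tau explain
   almost none of t.  The intersection over the three tissues gives the
   pathological set Z.
2. **Remove outlier classes**: connected components lying mostly (> 50%)
   in a dilated brain-perimeter shell, then classes occupying < 1% of the
   remaining labelled voxels.
3. **Merge by distribution similarity**: per-class kernel density
   estimates in feature space, pairwise Jensen-Shannon divergences
   (base 2), average-link agglomeration forced down to at most 4 classes,
   and a contrast-based mapping of the merged classes to BRATS codes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.stats import gaussian_kde

from .volume_io import LabelVolume, MultiChannelStudy

logger = logging.getLogger(__name__)

TISSUES = ("WM", "GM", "CSF")

DEFAULT_TAU = 0.8
DEFAULT_EPSILON = 1e-6
DEFAULT_MIN_FRACTION = 0.01
DEFAULT_MAX_CLASSES = 4
DEFAULT_MERGE_THRESHOLD = 0.1  # bits
PERIMETER_EROSION = 2
# The outlier perimeter mask must reach past the cortical band plus the
# texture-feature support (moment radius 2 blurs boundary signatures ~2
# voxels inward), so it is dilated wider than the detection shell.
PERIMETER_DILATION = 4
KDE_GRID_POINTS = 256

#: BRATS label codes.
NECROSIS, EDEMA, NON_ENHANCING, ENHANCING = 1, 2, 3, 4
BRATS_NAMES = {NECROSIS: "necrosis", EDEMA: "edema",
               NON_ENHANCING: "non-enhancing", ENHANCING: "enhancing"}


@dataclass
class TissueProbabilityMaps:
    """Per-voxel WM/GM/CSF probabilities warped into patient space."""

    maps: dict[str, np.ndarray]
    corrected: bool = False

    def __post_init__(self) -> None:
        missing = [t for t in TISSUES if t not in self.maps]
        if missing:
            raise ValueError(f"missing tissue map(s): {missing}")
        for t in TISSUES:
            m = np.asarray(self.maps[t], dtype=float)
            if (m < -1e-9).any() or (m > 1 + 1e-6).any():
                raise ValueError(f"{t} probabilities must lie in [0, 1]")
            self.maps[t] = m

    @property
    def shape(self):
        return self.maps[TISSUES[0]].shape


@dataclass
class AttributionTable:
    """p(c|t,S) with the per-tissue sorted vectors and selected sets."""

    class_ids: list[int]
    p_ct: np.ndarray                     # (C, 3) columns ordered as TISSUES
    sorted_classes: dict[str, list[int]]  # per-tissue class order (descending p)
    sorted_probs: dict[str, np.ndarray]
    cumsums: dict[str, np.ndarray]
    z_sets: dict[str, set[int]]
    z: set[int]
    tau: float
    rule: str = "exclusive"

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame(self.p_ct, index=self.class_ids, columns=list(TISSUES))


@dataclass
class ClassDensity:
    """Per-class, per-feature-dimension KDE on one shared grid."""

    class_ids: list[int]
    grid: np.ndarray                 # (D, G) evaluation points
    densities: dict[int, np.ndarray]  # class -> (D, G), each row integrates to 1
    bandwidths: dict[int, np.ndarray] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# step 1: normal-tissue class removal


def brain_perimeter_shell(brain_mask: np.ndarray,
                          erosion_radius: int = PERIMETER_EROSION) -> np.ndarray:
    """Brain mask minus its erosion: the outermost in-brain shell."""
    mask = np.asarray(brain_mask) > 0
    eroded = ndimage.binary_erosion(mask, iterations=erosion_radius)
    return mask & ~eroded


def compute_lesion_mask(study: MultiChannelStudy,
                        perimeter_radius: int = PERIMETER_EROSION) -> np.ndarray:
    """Rough lesion mask from Flair/T1c hyper-intensity.

    A voxel enters the mask if, in Flair or T1c, its intensity exceeds the
    median plus one standard deviation of the in-brain histogram of that
    channel.  Holes are filled in 3-D, then voxels in the brain-perimeter
    shell are removed.
    """
    mask = study.brain_mask
    if not mask.any():
        raise ValueError("empty brain mask")
    lesion = np.zeros(mask.shape, dtype=bool)
    for name in ("Flair", "T1c"):
        vals = study.channels[name][mask]
        thr = float(np.median(vals) + vals.std())
        lesion |= mask & (study.channels[name] > thr)
    lesion = ndimage.binary_fill_holes(lesion)
    lesion &= ~brain_perimeter_shell(mask, perimeter_radius)
    lesion &= mask
    return lesion


def correct_tissue_maps(maps: TissueProbabilityMaps, lesion: np.ndarray,
                        epsilon: float = DEFAULT_EPSILON) -> TissueProbabilityMaps:
    """Set every tissue probability to epsilon inside the lesion mask."""
    if not 0 <= epsilon < 1:
        raise ValueError("epsilon must lie in [0, 1)")
    lesion = np.asarray(lesion) > 0
    if lesion.shape != maps.shape:
        raise ValueError("lesion mask shape does not match tissue maps")
    out = {}
    for t in TISSUES:
        m = maps.maps[t].copy()
        m[lesion] = epsilon
        out[t] = m
    return TissueProbabilityMaps(maps=out, corrected=True)


def attribute_classes(label_volume: LabelVolume, maps: TissueProbabilityMaps,
                      brain_mask: np.ndarray, tau: float = DEFAULT_TAU,
                      rule: str = "exclusive") -> AttributionTable:
    """Attribute segmentation classes to normal tissues and isolate Z.

    For each tissue t, classes are sorted by descending p(c|t,S) (ties to
    the lower class id) and the cumulative sum S_t computed.  With
    ``rule="literal"`` Z_t contains the classes at sorted positions whose
    cumulative sum strictly exceeds tau (this includes the crossing class);
    with the default ``rule="exclusive"`` Z_t contains the classes strictly
    after the crossing position, i.e. those that together explain less than
    1 - tau of the tissue.  Z is the intersection over WM, GM and CSF.
    """
    if not 0 < tau < 1:
        raise ValueError("tau must lie in (0, 1)")
    if rule not in ("literal", "exclusive"):
        raise ValueError("rule must be 'literal' or 'exclusive'")
    labels = label_volume.labels
    mask = np.asarray(brain_mask) > 0
    class_ids = [int(c) for c in np.unique(labels[mask]) if c > 0]
    if not class_ids:
        raise ValueError("segmentation has no positive classes inside the mask")
    n_classes = len(class_ids)

    in_mask_labels = np.where(mask, labels, 0)
    p_ct = np.zeros((n_classes, len(TISSUES)))
    sorted_classes, sorted_probs, cumsums, z_sets = {}, {}, {}, {}
    for j, t in enumerate(TISSUES):
        pt = np.where(mask & (in_mask_labels > 0), maps.maps[t], 0.0)
        total = float(pt.sum())
        if total <= 0:
            warnings.warn(f"tissue {t} has zero probability mass; "
                          "its constraint is vacuous", stacklevel=2)
            p_ct[:, j] = 0.0
            sorted_classes[t] = list(class_ids)
            sorted_probs[t] = np.zeros(n_classes)
            cumsums[t] = np.zeros(n_classes)
            z_sets[t] = set(class_ids)
            continue
        sums = ndimage.sum_labels(pt, labels=in_mask_labels, index=class_ids)
        p = np.asarray(sums, dtype=float) / total
        p_ct[:, j] = p
        order = np.lexsort((class_ids, -p))  # descending p, ties -> lower id
        cs = np.cumsum(p[order])
        sorted_classes[t] = [class_ids[i] for i in order]
        sorted_probs[t] = p[order]
        cumsums[t] = cs
        exceed = cs > tau
        if rule == "literal":
            sel = np.flatnonzero(exceed)
        else:
            first = int(exceed.argmax()) if exceed.any() else n_classes
            sel = np.arange(first + 1, n_classes)
        z_sets[t] = {sorted_classes[t][i] for i in sel}
        if rule == "literal" and exceed.all():
            warnings.warn(
                f"tissue {t}: top class alone exceeds tau; the literal rule "
                "marks every class pathological for this tissue", stacklevel=2)

    z = set(class_ids)
    for t in TISSUES:
        z &= z_sets[t]
    return AttributionTable(class_ids=class_ids, p_ct=p_ct,
                            sorted_classes=sorted_classes,
                            sorted_probs=sorted_probs, cumsums=cumsums,
                            z_sets=z_sets, z=z, tau=tau, rule=rule)


def keep_classes(label_volume: LabelVolume, keep: set[int]) -> LabelVolume:
    """Erase every class not in ``keep`` (set to 0)."""
    labels = label_volume.labels.copy()
    labels[~np.isin(labels, sorted(keep)) & (labels > 0)] = 0
    legend = {c: n for c, n in label_volume.legend.items() if c in keep}
    return LabelVolume(labels=labels, legend=legend, affine=label_volume.affine)


# ---------------------------------------------------------------------------
# step 2: outlier classes


def remove_perimeter_classes(label_volume: LabelVolume, brain_mask: np.ndarray,
                             dilation_radius: int = PERIMETER_DILATION,
                             erosion_radius: int = PERIMETER_EROSION) -> LabelVolume:
    """Erase 26-connected class components lying mostly on the brain perimeter.

    The perimeter mask is the dilated brain-boundary shell; a component is
    erased when strictly more than 50% of its voxels fall inside it.
    """
    shell = brain_perimeter_shell(brain_mask, erosion_radius)
    perimeter = ndimage.binary_dilation(shell, iterations=dilation_radius)
    labels = label_volume.labels.copy()
    structure = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity
    for c in label_volume.present_labels():
        comp, n_comp = ndimage.label(labels == c, structure=structure)
        for i in range(1, n_comp + 1):
            sel = comp == i
            inside = int((sel & perimeter).sum())
            if inside * 2 > int(sel.sum()):
                labels[sel] = 0
    return LabelVolume(labels=labels, legend=dict(label_volume.legend),
                       affine=label_volume.affine)


def remove_low_rate_classes(label_volume: LabelVolume,
                            min_fraction: float = DEFAULT_MIN_FRACTION) -> LabelVolume:
    """Erase classes occupying less than ``min_fraction`` of labelled voxels.

    Fractions are computed once, before any deletion.
    """
    if not 0 <= min_fraction < 1:
        raise ValueError("min_fraction must lie in [0, 1)")
    labels = label_volume.labels
    present = label_volume.present_labels()
    if not present:
        raise ValueError("no classes left to filter")
    counts = {c: int((labels == c).sum()) for c in present}
    total = sum(counts.values())
    keep = {c for c in present if counts[c] / total >= min_fraction}
    if not keep:
        raise ValueError("low-rate filtering removed every class; "
                         "review min_fraction")
    return keep_classes(label_volume, keep)


# ---------------------------------------------------------------------------
# step 3: merge by distribution similarity


def estimate_class_densities(features: np.ndarray, assignment: np.ndarray,
                             classes: list[int],
                             grid_points: int = KDE_GRID_POINTS) -> ClassDensity:
    """Per-dimension Gaussian KDE (Silverman bandwidth) on one shared grid.

    The grid spans the pooled per-dimension range of the listed classes'
    members with 5% padding; each density is renormalized on the grid.
    """
    x = np.asarray(features, dtype=float)
    assignment = np.asarray(assignment)
    members = {c: x[assignment == c] for c in classes}
    for c, m in members.items():
        if len(m) < 2:
            raise ValueError(f"class {c} has fewer than 2 member voxels")
    pooled = np.vstack([members[c] for c in classes])
    lo, hi = pooled.min(axis=0), pooled.max(axis=0)
    pad = 0.05 * np.maximum(hi - lo, 1e-12)
    d = x.shape[1]
    grid = np.stack([np.linspace(lo[j] - pad[j], hi[j] + pad[j], grid_points)
                     for j in range(d)])
    densities, bandwidths = {}, {}
    for c in classes:
        dens = np.empty((d, grid_points))
        bw = np.empty(d)
        for j in range(d):
            vals = members[c][:, j]
            if vals.std() <= 1e-12 * max(1.0, abs(vals.mean())):
                # degenerate class dimension: unit mass at the nearest grid point
                dens[j] = 0.0
                k = int(np.abs(grid[j] - vals.mean()).argmin())
                step = grid[j, 1] - grid[j, 0]
                dens[j, k] = 1.0 / step
                bw[j] = 0.0
                continue
            kde = gaussian_kde(vals, bw_method="silverman")
            dens[j] = kde(grid[j])
            bw[j] = float(kde.factor * vals.std(ddof=1))
        # renormalize on the grid (trapezoid)
        for j in range(d):
            area = np.trapezoid(dens[j], grid[j])
            if area > 0:
                dens[j] = dens[j] / area
        densities[c] = dens
        bandwidths[c] = bw
    return ClassDensity(class_ids=list(classes), grid=grid,
                        densities=densities, bandwidths=bandwidths)


def js_divergence(p: np.ndarray, q: np.ndarray) -> float:
    """Jensen-Shannon divergence, base 2, averaged over feature dimensions.

    ``p`` and ``q`` are (D, G) or (G,) density evaluations on the same
    grid; each dimension is normalized to a discrete distribution first.
    0 <= JSD <= 1, zero iff equal, 1 on disjoint supports.
    """
    p = np.atleast_2d(np.asarray(p, dtype=float))
    q = np.atleast_2d(np.asarray(q, dtype=float))
    if p.shape != q.shape:
        raise ValueError("densities must share one grid shape")

    def _kl(a, b):  # sum a*log2(a/b), 0*log0 := 0
        sel = a > 1e-300  # guards denormal underflow in the ratio
        return float((a[sel] * np.log2(a[sel] / b[sel])).sum())

    total = 0.0
    for j in range(p.shape[0]):
        pj = p[j] / p[j].sum()
        qj = q[j] / q[j].sum()
        mj = 0.5 * (pj + qj)
        total += 0.5 * _kl(pj, mj) + 0.5 * _kl(qj, mj)
    return total / p.shape[0]


def jsd_matrix(density: ClassDensity) -> np.ndarray:
    ids = density.class_ids
    n = len(ids)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = js_divergence(density.densities[ids[i]],
                                                  density.densities[ids[j]])
    return mat


def merge_similar_classes(density: ClassDensity,
                          max_classes: int = DEFAULT_MAX_CLASSES,
                          merge_threshold: float = DEFAULT_MERGE_THRESHOLD
                          ) -> dict[int, int]:
    """Average-link (UPGMA) agglomeration on the pairwise JSD matrix.

    Merging continues while the next smallest average-link distance is
    below ``merge_threshold`` or more than ``max_classes`` groups remain.
    Ties are broken by the lowest pair of class ids.  Returns a map from
    original class id to merged group id (1..K, ordered by each group's
    smallest member id).
    """
    ids = list(density.class_ids)
    if not ids:
        raise ValueError("no classes to merge")
    dist = jsd_matrix(density)
    groups: list[list[int]] = [[i] for i in range(len(ids))]  # indices into ids

    def avg_link(a: list[int], b: list[int]) -> float:
        return float(np.mean([dist[i, j] for i in a for j in b]))

    while len(groups) > 1:
        best = None
        for gi in range(len(groups)):
            for gj in range(gi + 1, len(groups)):
                d = avg_link(groups[gi], groups[gj])
                key = (d, min(ids[k] for k in groups[gi] + groups[gj]),
                       gi, gj)
                if best is None or key < best[0]:
                    best = (key, gi, gj)
        (d, *_), gi, gj = best
        if d >= merge_threshold and len(groups) <= max_classes:
            break
        groups[gi] = groups[gi] + groups[gj]
        del groups[gj]

    groups.sort(key=lambda g: min(ids[k] for k in g))
    mapping = {}
    for new_id, g in enumerate(groups, start=1):
        for k in g:
            mapping[ids[k]] = new_id
    return mapping


def apply_merge(label_volume: LabelVolume, mapping: dict[int, int]) -> LabelVolume:
    """Relabel a volume through an old-class -> merged-class map."""
    labels = label_volume.labels
    out = np.zeros_like(labels)
    for old, new in mapping.items():
        out[labels == old] = new
    return LabelVolume(labels=out, legend={}, affine=label_volume.affine)


def assign_brats_labels(merged: LabelVolume, study: MultiChannelStudy,
                        ) -> LabelVolume:
    """Map <= 4 merged classes to BRATS codes by their channel contrasts.

    Priority order: the class with the highest mean T1d becomes enhancing
    (4); among the rest, highest mean Flair becomes edema (2); among the
    rest, lowest mean T1c becomes necrosis (1); anything left becomes
    non-enhancing (3).  Ties break to the lower class id.  The chosen
    mapping is logged and recorded in the legend.
    """
    classes = merged.present_labels()
    if not classes:
        raise ValueError("no classes to map to BRATS codes")
    if len(classes) > 4:
        raise ValueError("BRATS mapping requires at most 4 classes")
    t1d = np.abs(study.channels["T1c"] - study.channels["T1"])
    stats = {}
    for c in classes:
        sel = merged.labels == c
        stats[c] = {"T1d": float(t1d[sel].mean()),
                    "Flair": float(study.channels["Flair"][sel].mean()),
                    "T1c": float(study.channels["T1c"][sel].mean())}
    remaining = list(classes)

    def _pick(key: str, largest: bool) -> int:
        vals = [(stats[c][key], c) for c in remaining]
        # ties break to the lower class id in both directions
        best = max(vals, key=lambda t: (t[0], -t[1])) if largest else min(vals)
        remaining.remove(best[1])
        return best[1]

    code_of = {}
    code_of[_pick("T1d", largest=True)] = ENHANCING
    if remaining:
        code_of[_pick("Flair", largest=True)] = EDEMA
    if remaining:
        code_of[_pick("T1c", largest=False)] = NECROSIS
    for c in remaining:
        code_of[c] = NON_ENHANCING
    logger.info("BRATS code mapping: %s (class stats: %s)", code_of, stats)

    out = np.zeros_like(merged.labels)
    for c, code in code_of.items():
        out[merged.labels == c] = code
    legend = {code: BRATS_NAMES[code] for code in sorted(set(code_of.values()))}
    vol = LabelVolume(labels=out, legend=legend, affine=merged.affine)
    vol.legend_mapping = dict(code_of)
    return vol
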