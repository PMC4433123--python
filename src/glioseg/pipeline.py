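"""End-to-end orchestration: features -> clustering -> isolation -> BRATS codes.

`run_pipeline` drives the whole segmentation for one study and optionally
scores it against a reference labelling.  Every stage decision (thresholds,
radii, selected classes, merge map, BRATS mapping) is recorded in the run
manifest so a run is fully auditable and, given the same seed and config,
bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np

from . import clustering, features, isolation, metrics, volume_io
from .isolation import AttributionTable, TissueProbabilityMaps
from .volume_io import LabelVolume, MultiChannelStudy

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything a segmentation run depends on."""

    algorithm: str = "gmm"
    n_classes: int = clustering.DEFAULT_N_CLASSES
    n_inits: int = 100
    keep: int = 10
    beta: float = clustering.DEFAULT_BETA
    tau: float = isolation.DEFAULT_TAU
    attribution_rule: str = "exclusive"
    epsilon: float = isolation.DEFAULT_EPSILON
    max_classes: int = isolation.DEFAULT_MAX_CLASSES
    merge_threshold: float = isolation.DEFAULT_MERGE_THRESHOLD
    min_fraction: float = isolation.DEFAULT_MIN_FRACTION
    moment_radius: int = features.DEFAULT_RADIUS
    variance_threshold: float = 0.99
    tol: float = clustering.DEFAULT_TOL
    max_iter: int = clustering.DEFAULT_MAX_ITER
    icm_sweeps: int = clustering.DEFAULT_ICM_SWEEPS
    seed: int = 0

    def validate(self) -> None:
        if self.algorithm not in clustering.ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if not 1 <= self.keep <= self.n_inits:
            raise ValueError("need 1 <= keep <= n_inits")


@dataclass
class PipelineResult:
    """Final labelling plus every intermediate object worth inspecting."""

    segmentation: LabelVolume
    config: PipelineConfig
    pca_model: features.PcaModel
    cluster_model: clustering.ClusterModel
    raw_labelling: clustering.Labelling
    attribution: AttributionTable
    merge_map: dict[int, int]
    report: metrics.CompartmentReport | None
    manifest: dict = field(default_factory=dict)


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


def run_pipeline(study: MultiChannelStudy, tissue_maps: TissueProbabilityMaps,
                 config: PipelineConfig | None = None,
                 reference: LabelVolume | None = None,
                 out_dir: str | os.PathLike | None = None) -> PipelineResult:
    """Segment one study and (optionally) score it against a reference.

    Stages: 20-image feature stack -> standardize + PCA (>= 99% variance)
    -> K-means++ multi-start clustering -> normal-tissue removal via
    corrected atlas attribution -> outlier removal -> JSD/UPGMA merge ->
    BRATS code mapping.  Deterministic given ``config.seed``.
    """
    config = config or PipelineConfig()
    config.validate()
    t0 = time.time()
    manifest: dict = {"config": dataclasses.asdict(config), "stages": {}}

    stack = _stage("features")(features.build_feature_stack)(
        study, radius=config.moment_radius)
    pca_model, feats = _stage("pca")(features.reduce_dimensionality)(
        stack, study.brain_mask, variance_threshold=config.variance_threshold)
    manifest["stages"]["features"] = {
        "n_images": len(stack.images), "n_voxels": feats.n,
        "pca_components": pca_model.k,
        "explained_fraction": float(
            np.cumsum(pca_model.explained_fractions)[pca_model.k - 1]),
    }

    mrf = None
    if config.algorithm == "ghmrf":
        mrf = clustering.mrf_from_mask(study.brain_mask, beta=config.beta)
    fit_kwargs = dict(max_iter=config.max_iter, tol=config.tol)
    if config.algorithm == "ghmrf":
        fit_kwargs["icm_sweeps"] = config.icm_sweeps
    model, labelling = _stage("clustering")(clustering.run_multistart)(
        feats, config.n_classes, config.algorithm, n_inits=config.n_inits,
        keep=config.keep, rng_seed=config.seed, mrf=mrf, **fit_kwargs)
    manifest["stages"]["clustering"] = {
        "algorithm": config.algorithm, "n_classes": config.n_classes,
        "objective": model.nll, "n_iter": model.n_iter,
        "candidate_scores": model.extras.get("candidate_scores"),
    }

    raw_volume = volume_io.scatter_labels(labelling.assignment, feats.index_map,
                                          feats.shape, affine=study.affine)

    # isolation step 1: normal-tissue classes
    lesion = _stage("lesion-mask")(isolation.compute_lesion_mask)(study)
    corrected = isolation.correct_tissue_maps(tissue_maps, lesion, config.epsilon)
    attribution = _stage("attribution")(isolation.attribute_classes)(
        raw_volume, corrected, study.brain_mask, tau=config.tau,
        rule=config.attribution_rule)
    if not attribution.z:
        raise RuntimeError("pipeline stage 'attribution' failed: "
                           "no pathological classes survive the tau rule")
    tumour_volume = isolation.keep_classes(raw_volume, attribution.z)
    manifest["stages"]["attribution"] = {
        "tau": config.tau, "rule": config.attribution_rule,
        "lesion_voxels": int(lesion.sum()),
        "pathological_classes": sorted(attribution.z),
    }

    # isolation step 2: outlier classes
    tumour_volume = isolation.remove_perimeter_classes(tumour_volume, study.brain_mask)
    tumour_volume = _stage("low-rate-filter")(isolation.remove_low_rate_classes)(
        tumour_volume, min_fraction=config.min_fraction)
    survivors = tumour_volume.present_labels()
    manifest["stages"]["outliers"] = {"surviving_classes": survivors}

    # isolation step 3: merge and map to BRATS codes
    surviving_assignment = tumour_volume.labels[
        feats.index_map[:, 0], feats.index_map[:, 1], feats.index_map[:, 2]]
    density = _stage("kde")(isolation.estimate_class_densities)(
        feats.values, surviving_assignment, survivors)
    merge_map = isolation.merge_similar_classes(
        density, max_classes=config.max_classes,
        merge_threshold=config.merge_threshold)
    merged = isolation.apply_merge(tumour_volume, merge_map)
    final = _stage("brats-mapping")(isolation.assign_brats_labels)(merged, study)
    manifest["stages"]["merge"] = {
        "merge_map": {str(k): v for k, v in merge_map.items()},
        "final_classes": final.present_labels(),
        "brats_mapping": {str(k): v for k, v in
                          getattr(final, "legend_mapping", {}).items()},
    }

    report = None
    if reference is not None:
        report = metrics.evaluate_segmentation(final, reference)
        manifest["evaluation"] = report.as_flat_dict()
    manifest["runtime_seconds"] = round(time.time() - t0, 3)

    result = PipelineResult(segmentation=final, config=config, pca_model=pca_model,
                            cluster_model=model, raw_labelling=labelling,
                            attribution=attribution, merge_map=merge_map,
                            report=report, manifest=manifest)
    if out_dir is not None:
        _write_outputs(result, study, out_dir)
    return result


def _write_outputs(result: PipelineResult, study: MultiChannelStudy,
                   out_dir: str | os.PathLike) -> None:
    os.makedirs(out_dir, exist_ok=True)
    volume_io.write_volume(result.segmentation.labels, study.affine,
                           os.path.join(out_dir, "segmentation.nii.gz"))
    result.attribution.to_frame().to_csv(os.path.join(out_dir, "attribution.csv"))
    model = result.cluster_model
    sidecar = {
        "model_kind": model.model_kind,
        "n_classes": model.n_classes,
        "means": model.means.tolist(),
        "covariances": model.covariances.tolist(),
        "priors": model.priors.tolist(),
        "objective": model.nll,
        "objective_trace": model.objective_trace.tolist(),
    }
    with open(os.path.join(out_dir, "model.json"), "w") as fh:
        json.dump(sidecar, fh, indent=2)
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(result.manifest, fh, indent=2)
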