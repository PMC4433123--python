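# glioseg

Unsupervised multiparametric MRI brain-tumour segmentation: first-order
texture features + PCA, four unsupervised voxel classifiers (K-means,
fuzzy K-means, Gaussian mixture EM, Gaussian hidden Markov random field),
a K-means++ multi-start fitting protocol, and an atlas-guided postprocess
that automatically isolates the tumour classes.

## Who this is for

Glioblastoma delineation pipelines are usually supervised, which ties
them to the annotation protocol of their training set.  `glioseg`
implements the alternative: build a patient-specific unsupervised model
from the patient's own co-registered T1/T1c/T2/Flair volumes, then use
population-atlas tissue priors (WM/GM/CSF probability maps warped to the
patient) to decide *which* of the anonymous clusters are pathological.
It is aimed at researchers studying unsupervised and structured
segmentation models — every stage is a plain, seeded, inspectable
function, and a built-in phantom generator makes the whole pipeline
testable without any clinical data.

## The model in brief

Voxels carry 20 features — T1, T1c, T2, Flair, T1d = |T1c − T1| and the
local mean/skewness/kurtosis of each over a 5×5×5 neighbourhood —
standardized and reduced by PCA to the smallest K components explaining
≥ 99% of variance.  Classification maximizes, over labellings Y and
Gaussian parameters, either a mixture likelihood (K-means and fuzzy
K-means as constrained special cases, full-covariance GMM via EM) or the
structured posterior

    p(X, Y) ∝ exp( − Σₙ −log N(xₙ | μ_{yₙ}, Σ_{yₙ}) − β Σ_{(n,m)∈Q} [yₙ ≠ y_m] )

with Q the 6-connected in-mask voxel pairs (GHMRF; hard EM with ICM
labelling).  Each fit takes the best of 10 pre-selected K-means++
seedings out of 100.  Isolation then computes, per normal tissue t,
p(c|t,S) = Σ_{v:S(v)=c} p(t|v) / Σ_v p(t|v) on lesion-corrected priors,
removes the classes that explain the normal tissues (cumulative-sum rule
at τ = 0.8), deletes perimeter and sub-1% outlier classes, merges the
survivors by average-link clustering of Jensen–Shannon divergences down
to ≤ 4 classes, and assigns BRATS codes (1 necrosis, 2 edema, 3
non-enhancing, 4 enhancing) from channel contrasts.

## Worked example

Generate a synthetic study and segment it:

```sh
glioseg phantom --preset low-noise --seed 1 --out-dir data/
glioseg segment --t1 data/t1.nii.gz --t1c data/t1c.nii.gz \
    --t2 data/t2.nii.gz --flair data/flair.nii.gz --mask data/mask.nii.gz \
    --wm data/wm.nii.gz --gm data/gm.nii.gz --csf data/csf.nii.gz \
    --algorithm gmm --seed 1 --out-dir run/
glioseg evaluate --segmentation run/segmentation.nii.gz \
    --reference data/truth.nii.gz
```

or, from Python:

```python
from glioseg.phantom import default_specs, generate_phantom
from glioseg.pipeline import PipelineConfig, run_pipeline

study, truth, tissue_maps = generate_phantom(default_specs()["low-noise"])
result = run_pipeline(study, tissue_maps,
                      PipelineConfig(algorithm="gmm", seed=1),
                      reference=truth)
print(result.report.as_flat_dict())
```

which prints (numbers from this exact invocation):

```
{'complete_dice': 0.9949, 'complete_ppv': 1.0, 'complete_sensitivity': 0.9898,
 'core_dice': 0.8605, 'core_ppv': 0.7661, 'core_sensitivity': 0.9814,
 'enhancing_dice': 1.0, 'enhancing_ppv': 1.0, 'enhancing_sensitivity': 1.0,
 'kappa': 0.9948}
```

Complete tumour (all four labels) is recovered with Dice 0.99 against the
phantom ground truth; the enhancing rim — the most distinctive contrast —
is exact, while the core score reflects boundary voxels traded between
neighbouring compartments during merging.  `run/` additionally holds
the attribution table (CSV), the fitted Gaussian model (JSON) and a full
run manifest recording every threshold and mapping the run used.

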