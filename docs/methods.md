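# Methods

## Overview

`glioseg` segments multiparametric brain MRI (T1, T1c, T2, Flair) into
tumour compartments without any training labels.  The pipeline has four
stages:

1. **Feature extraction.**  A derived image T1d = |T1c − T1| highlights
   contrast enhancement.  For each of the five base images, first-order
   texture images are computed: the local mean (μ), skewness (γ) and
   kurtosis (κ) of the voxel values in a 5×5×5 neighbourhood restricted to
   in-mask voxels, giving 20 images per study.
2. **Dimensionality reduction.**  The 20 features are standardized over
   in-mask voxels and reduced by PCA, retaining the smallest number of
   leading components that explain at least 99% of the variance.
3. **Unsupervised voxel classification.**  One of four classifiers —
   K-means, fuzzy K-means, a full-covariance Gaussian mixture fit by EM, or
   a Gaussian hidden Markov random field (Ising pairwise prior, hard EM
   with ICM) — partitions the in-mask voxels into C classes (default
   C = 14: seven brain tissues, each allotted a two-Gaussian mixture).
   Every fit uses a multi-start protocol: 100 K-means++ seedings, the 10
   most promising retained by the mean nearest-seed squared distance, each
   fitted, and the best solution selected (distance objective for the
   K-means variants, mixture negative log-likelihood for GMM/GHMRF).
4. **Automatic tumour-class isolation.**  Atlas tissue probability maps
   (WM/GM/CSF), corrected to a small ε inside a rough hyperintensity-based
   lesion mask, attribute each segmentation class to the normal tissues;
   classes explaining almost none of any normal tissue are kept as
   pathological.  Spurious classes on the brain perimeter or below 1%
   occurrence are removed; the survivors are merged by average-link
   clustering of Jensen–Shannon divergences between per-class kernel
   density estimates, capped at four classes, and mapped to BRATS codes by
   their channel contrasts.

## Model details and conventions

### Texture moments

Moments are computed from mask-weighted running sums of powers obtained
with separable box filters; the volume is shifted by its global in-mask
mean first, which leaves mean/skewness/kurtosis unchanged but keeps the
power sums well conditioned.  Neighbourhoods are clipped at volume borders
and restricted to the brain mask — no padding value ever enters a moment.
Kurtosis is the plain fourth standardized moment (Gaussian ⇒ 3).  A
neighbourhood with fewer than two in-mask voxels or zero variance yields
(mean, 0, 0).  The "local histogram" is taken to be the empirical
distribution of the raw neighbourhood values; no binning is performed,
since a bin count would be an extra free parameter and the binned moments
converge to the unbinned ones anyway.

### PCA

Features are standardized before the decomposition (zero mean, unit
variance; zero-variance features are centred only).  Raw channels, local
means, and kurtosis images live on incommensurate scales, and the 99%
retention rule is scale-sensitive, so standardization is the default; a
raw-scale mode is available (`standardize=False`).

### Classifiers

* **K-means** reports identity covariances and uniform priors — its
  reading as a Gaussian mixture with shared spherical covariance.  An
  emptied cluster is re-seeded at the point farthest from its assigned
  centroid.
* **Fuzzy K-means** uses the exact alternating minimizer of
  Σₙ Σ_c u_nc^m ‖xₙ − μ_c‖²: u_nc = 1/Σⱼ (d²_nc/d²_nj)^{1/(m−1)} with
  squared distances, i.e. the textbook update with plain norms and
  exponent 2/(m−1).  A point coincident with a centroid takes membership
  1 there (the limit convention).  Note this convention makes seeds that
  sit exactly on data points absorbing for very large m; the m→∞
  uniform-membership limit is observed from off-data starts.
* **GMM** initializes means from the seeds, covariances from the global
  data covariance and priors uniformly.  Each M-step adds a relative
  ridge 1e-6·trace(Σ)/D to the covariance diagonal (guarding collapse on
  quantized intensities); a covariance that is singular despite the ridge
  raises an error naming the class.  Convergence: relative NLL change
  below 1e-6 (default), cap 200 iterations.
* **GHMRF** models p(X,Y) ∝ exp(−U(X|Y) − U(Y)) with Gaussian emissions
  U(X|Y) = Σₙ −log N(xₙ|μ_{yₙ}, Σ_{yₙ}) and the Ising penalty
  U(Y) = β·Σ_{(n,m)∈Q} [yₙ ≠ y_m] over 6-connected in-mask pairs (β = 1
  by default).  The partition function is never needed for MAP labelling
  or hard EM and is not computed.  The labelling step runs ICM sweeps in a
  fixed lexicographic visit order with ties broken to the lowest label —
  the total energy is non-increasing per sweep; the parameter step is the
  ML Gaussian update from the hard assignment, with the same ridge.  ICM
  was chosen over graph-cut solvers deliberately: it preserves the
  contract that matters (deterministic, energy-non-increasing labelling)
  with no extra dependencies, and the solver is a small, replaceable
  function.  The inner sweep is compiled with numba.

### Multi-start protocol

Seeding-score pre-selection (keep the 10 seedings with the lowest mean
point-to-nearest-seed squared distance) is a heuristic: it correlates
with, but does not guarantee, the best final objective.  On tiny
structureless instances the optimal basin can rank outside the kept set;
on clusterable data (the intended regime) the protocol reliably attains
the enumerable global optimum at N ≤ 8.  Duplicate seed-sets — which occur
when the data has few distinct rows — collapse to a single candidate
before ranking.  "Average intra-cluster sums" is implemented as the mean
per point, which is monotone-equivalent to the total for fixed N.

### Attribution rule

For tissue t, p(c|t,S) = Σ_{v:S(v)=c} p(t|v) / Σ_v p(t|v) is sorted
descending (ties to the lower class id) and cumulatively summed.  Two
readings of the selection rule are implemented:

* `rule="literal"`: classes at sorted positions whose cumulative sum
  strictly exceeds τ — this includes the crossing class itself.
* `rule="exclusive"` (default): classes strictly after the crossing
  position, i.e. those jointly explaining less than 1 − τ of the tissue.

The literal reading has a degenerate regime: whenever a tissue's top class
alone exceeds τ, every class of the segmentation lands in that tissue's
set, and with a 50/50 split the second-largest class of a tissue — half
the tissue — is marked pathological.  The exclusive reading matches the
stated intent (classes with very low probability of explaining the normal
tissue) and is the default; the literal rule is kept selectable and
triggers a warning in its degenerate case.  τ defaults to 0.8; the
pathological set shrinks (weakly) as τ grows.

### Outlier removal and merging

The brain-perimeter shell is the mask minus its erosion by 2 voxels; the
outlier perimeter mask dilates that shell by 4 voxels, wide enough to
reach past the cortical band plus the ~2-voxel blur the 5×5×5 texture
support imprints on boundary signatures.  A 26-connected component of a
surviving class is erased when strictly more than half of it lies in the
perimeter mask.  Classes under 1% occurrence (fractions computed once,
before any deletion) are erased next.

Class similarity is measured in the reduced PCA feature space:
per-dimension Gaussian KDEs (Silverman bandwidth, shared 256-point grid
with 5% padding, renormalized), base-2 Jensen–Shannon divergence averaged
over dimensions, average-link (UPGMA) agglomeration.  Merging proceeds
while the next merge distance is below 0.1 bits or more than four groups
remain; ties break to the lowest pair of class ids.  The BRATS code
mapping is a contrast heuristic (highest mean T1d → enhancing; then
highest Flair → edema; then lowest T1c → necrosis; remainder →
non-enhancing), recorded in the run manifest — the semantic mapping of
unsupervised classes is not defined by the model itself, so the heuristic
is deliberately simple, logged, and overridable.

### Evaluation

Dice is the standard overlap 2TP/(P+P̂) (the accuracy-like variant
2(TP+TN)/(P+N+P̂+N̂) found in some write-ups is available behind a flag
for auditability but is never reported).  PPV = TP/(TP+FP),
sensitivity = TP/(TP+FN), and Cohen's kappa uses
P_A = (TP+TN)/(P+N) and
P_E = (P/(P+N))·(P̂/(P̂+N̂)) + (N/(P+N))·(N̂/(P̂+N̂)).  Compartments
follow the BRATS convention: complete = {1,2,3,4}, core = {1,3,4},
enhancing = {4}.  Kappa is computed on the binary complete-tumour masks.
Empty-set conventions (both masks empty ⇒ Dice/PPV/sensitivity = 1;
P_E = 1 ⇒ kappa = 0) are logged when triggered.

## The phantom: what it emulates, and what it does not

The phantom realizes the statistical structure the classifiers assume:
per-tissue Gaussian channel intensities (each tissue a two-mode mixture,
honouring the "two Gaussians per tissue" modelling budget that sets
C = 14), spatially coherent nested-ellipsoid anatomy (GM shell, WM
interior, ventricular CSF, and a four-compartment tumour: necrotic core,
enhancing rim, non-enhancing region, edema halo), and atlas-style tissue
probability maps built from the *healthy* geometry — the tumour volume is
attributed to the enclosing WM, exactly as a population atlas warped onto
a lesioned brain would be, so the lesion-correction step does real work.

Design choices worth making explicit:

* **Contrast layout.**  Tumour tissue is hyperintense against normal
  tissue precisely where the lesion-mask rule looks: edema has the
  brightest Flair, the enhancing rim by far the brightest T1c, and
  post-contrast GM/WM T1c values are kept close so that the in-brain T1c
  histogram is tight and only enhancement exceeds median + std.  Necrosis
  is the darkest tumour tissue on T1c; the mapping heuristic's three cues
  are therefore all realized.
* **Tissue bimodality** is placed in the precontrast channels (T1/T2)
  and kept out of T1c and Flair, so tissue heterogeneity does not blur
  the hyperintensity cues.  The normal-tissue mode axis is aligned with
  the GM→WM contrast direction, so the texture gradation across the
  cortical interface runs through the mode chain instead of opening a
  separate feature-space band.  Tumour modes are mild (±1, edema ±2) so
  same-compartment classes remain statistically similar — mergeable by
  the JSD stage — while the compartments stay mutually distinct.
* **Atlas prior sharpness** is per-tissue: cortical GM/WM priors are
  relatively sharp (σ = 1.2 voxels) while the small ventricular CSF prior
  is diffuse (σ = 2.5), as in real population atlases.  This matters for
  the attribution stage: the diffuse CSF prior spreads enough mass onto
  the periventricular rim that rim classes rank inside CSF's protected
  prefix, while sharp GM/WM priors keep each tissue's mass concentrated
  in its own classes.
* **Geometry.**  The tumour (outer radius 11 voxels) is wholly inside the
  WM ellipsoid with clearance from both the cortical band and the
  ventricle, so the texture-gradation band at the tumour boundary is a
  single-tissue (WM) structure that the attribution stage can rank and
  remove, rather than an unattributable multi-tissue mixture.

What the phantom does **not** model: MR physics, bias fields, Rician
noise, partial-volume mixing at tissue interfaces, and anatomical
variability.  Passing the phantom suite therefore demonstrates the
correctness and internal consistency of the pipeline — oracle equivalence,
monotone optimization, faithful attribution arithmetic, end-to-end
label flow — under the model's own assumptions; it does not certify
performance on clinical data, where preprocessing residue and
partial-volume effects dominate the error budget.

A genuine limitation surfaced by the phantom and worth knowing about: the
5×5×5 texture support imprints graded feature signatures on every tissue
interface, and with a full-covariance mixture these boundary bands can
claim their own classes.  Bands at normal/normal interfaces carry enough
tissue mass to be recognized as normal; the band at the tumour/WM
interface is removed or kept depending on where it falls against the τ
crossing, which is the main driver of the few-percent spread in
complete-tumour Dice between otherwise identical runs.

## Problem sizes and determinism

The shipped test suite and the acceptance script run the full pipelines
on the 64³ low-noise phantom (~57 000 brain voxels, C = 14, 100/10
multi-start) and smaller derived phantoms (48³) for determinism checks —
sizes chosen to exercise every stage at realistic class counts while
keeping a complete run in minutes on one CPU.  All randomness flows
from explicit integer seeds through `numpy.random.default_rng`; two runs
with the same configuration and seed are bit-identical, including the
final label volume.
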