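# Methods

## Problem and approach

Quantitative MRI analysis of rodent brain-tumor models needs two nested
segmentations: the tumor-bearing brain extracted from the whole
head/neck volume (skull stripping), and the tumor extracted from the
brain. `rodentseg` implements this as a stepwise cascade of two 3D
U-Nets sharing one architecture. Model 1 maps the three-channel stack
(T1WI, T2WI, CE-T1WI) of the head to a brain-probability map; model 2
maps the same stack with all voxels outside the predicted brain zeroed
to a tumor-probability map. Predicted tumor is intersected with the
predicted brain, so `tumor ⊆ brain` holds by construction and
contralateral tissue is available as `brain − tumor`.

## Network

The encoder applies, per level, two 3×3×3 convolutions with ReLU
followed by 2× max-pooling; the decoder mirrors it with 2×
nearest-neighbor up-sampling and concatenation of the matching encoder
feature map; a final 1×1×1 convolution and sigmoid produce one
foreground-probability channel. Default depth is 3 levels with channel
widths doubling from `base_filters` (8 at desk scale; 32 is a sensible
full-scale width). Input patches are 64³ voxels; any larger grid is
tiled into non-overlapping 64³ patches and predictions are reassembled
without blending, so no cross-patch context is used at inference — the
same independence that patch-wise training imposes.

The engine is written directly in numpy: each 3×3×3 convolution is
evaluated as 27 shifted GEMMs, with analytic backward passes for every
layer and loss. This keeps training bitwise reproducible from a single
seed and dependency-free; it is deliberately a desk-scale engine (one
CPU, minutes per model), not a GPU trainer.

## Objective

Training minimizes

    L = λ · L_dice + (1 − λ) · L_focal,        λ = 0.5 by default

with the soft dice loss `1 − (2Σpg + ε)/(Σp + Σg + ε)` (ε = 1e-6) and a
class-weighted focal loss, mean over voxels of
`−w · (1 − p_t)^γ · log(p_t)`, where `p_t` is the predicted probability
of the true class and `w` is 0.75 on ROI voxels and 0.25 on background
voxels. The 0.75/0.25 weights address the small ROI volume and are
interpreted as per-class voxel weights inside the focal term (a literal
reading of "weights on ROI and non-ROI voxels"), not as the dice/focal
mixing weight. γ defaults to 2.0 and λ to 0.5; both are exposed in
`TrainConfig` since no stated values exist for them. Optimization is
Adam; the stated learning rate 1e-4 is the package default.
Probability maps are binarized at 0.5 (configurable; no stated value).

## Preprocessing

Images are intensity-normalized (z-score per volume for network input;
min-max to 0–255 for the noise protocol, which specifies that range),
resampled to isotropic 0.5 mm by cubic B-spline interpolation
(`scipy.ndimage.map_coordinates`, order 3; output dimension
`round(dim · spacing / 0.5)` per axis), centrally cropped or
zero-padded to a patch-divisible matrix, and stacked channels-first.
Masks follow the same geometric chain with nearest-neighbor resampling
to preserve binarity (linear + 0.5 threshold available as a flag).
Under these rules the coronal rat lattice (80×192×192 at
0.43×0.29×0.29 mm) becomes 69×111×111 and is cropped/padded to
64×128×128 (4 patches); the transverse mouse lattice is brought to
64×64×64 and fed natively.

Augmentation draws uniformly from the group generated by in-plane
90°-rotations and vertical/horizontal flips — exact lattice
permutations, applied identically to all channels and masks. The
multiplicity is unstated upstream; the default is one random group
element per training sample per epoch.

## Synthetic phantoms

The phantom generator provides controllable, license-free inputs that
emulate the two acquisition styles: `leuven_like` (80×192×192,
0.43×0.29×0.29 mm, whole head, default SNR 12) and `tcia_like`
(30×256×256, 0.50×0.12×0.12 mm, truncated z-coverage emulating scans
that miss the posterior brain, default SNR 6). Geometry is procedural:
an ellipsoidal soft-tissue head, a brighter skull shell around an
ellipsoidal brain, a spherical tumor in one hemisphere, an optional
concentric necrotic core, optional enlarged CSF-bright lateral
ventricles (ventriculomegaly), and an optional midline shift
implemented as a contralateral translation of the brain geometry with
the skull fixed, clipped at the skull interior.

Region mean intensities per modality are fixed, documented constants
chosen to reproduce the radiological contrast contract: tumor
hyperintense on T2WI and (when well-enhanced) on CE-T1WI, hypointense
on T1WI; the necrotic core suppresses CE-T1WI enhancement. A 1-voxel
Gaussian smoothing creates soft tissue ramps; additive Gaussian noise
is scaled so that brain-tissue mean over background SD equals the
requested `base_snr` (air is exactly zero-mean before noise, which
makes this SNR definition operational). The per-style default SNRs
encode only the ordering "rat scans cleaner than mouse scans"; they are
package choices, not measured values.

What the phantoms do **not** model: anatomy beyond nested
ellipsoids/spheres, MRI physics (bias fields, k-space artifacts,
Rician noise), partial-volume mixtures, or inter-subject variability.
Consequently, passing desk-scale tests demonstrates that the pipeline,
losses, metrics and protocols are implemented correctly and that the
cascade can recover geometry from realistic contrast — it does not
certify performance on real rodent MRI.

## Evaluation metrics

Four measures per prediction/truth pair, computed in physical mm by
default (a voxel-unit mode exists because surface distances are not
comparable across differing matrix sizes):

- DSC = 2|P∩G| / (|P|+|G|) by integer voxel counts;
- RV(seg1, seg2) = V1/V2 with physical volumes, reported as
  prediction/truth;
- MSD = (Σ_p d(p,S′) + Σ_p′ d(p′,S)) / (n_S + n_S′);
- HD = max{sup_x d(x,Y), sup_y d(X,y)}, exact (no HD95 variant).

Surfaces are centers of foreground voxels with at least one background
6-neighbor, the grid border counting as background — the simplest
testable convention, since no extraction rule is stated upstream.
Distances use a k-d tree and are validated against an exhaustive
all-pairs oracle on small masks (HD exact, MSD to 1e-9). Conventions
for degenerate inputs: DSC is 1 when both masks are empty, 0 when
exactly one is; RV and surface metrics are flagged undefined (NaN,
never silently propagated) when their denominators or surfaces vanish.

## Noise robustness protocol

Gaussian white noise with σ ∈ {1,…,15} (step 1) is added after min-max
normalization to 0–255, independently per modality with one seed stream
per modality. Outputs are not re-clipped by default: clipping would
bias the background SD and break the additive-variance identity
SD_after = √(SD₀² + σ²) used as a self-check (a `clip` flag exists).
SNR is measured on T2WI as tissue mean over background SD, with
tissue = brain − tumor and background = air eroded by 2 voxels to
avoid skull bleed — mirroring manually drawn ROIs without manual work.
The challenge re-runs the cascade per case × σ × seed and emits a tidy
table for metric-vs-SNR curves.

## Inter-observer analysis

Disparity between two observers is the same four-metric report applied
to their masks; batches are summarized as mean ± SEM with no hypothesis
tests (a one-liner for users, and outside the method's scope).
Synthetic observers displace the truth boundary by a smooth random
field: signed Euclidean distance to the boundary thresholded against
Gaussian-filtered white noise scaled to an RMS amplitude in mm.
Assisted observers use a smaller amplitude than manual ones (defaults
0.2 vs 0.5 mm), encoding that corrections of a shared model prediction
diverge less than independent de novo delineations. Segmentation time
is an input field (minutes) only.

## Desk-scale preset and problem sizes

The demo pipeline, the acceptance script and the training tests use one
frozen preset: 20 easy phantoms (large well-enhanced tumors, isotropic
64³ at 0.5 mm, SNR 15), 16/4 train/validation split, `base_filters` 8,
3 levels, Adam lr 1e-3, batch size 1, no augmentation, 4 epochs for
model 1 and 5 for model 2, best-validation-IoU weight selection. The
learning rate is raised from the 1e-4 default because a ~60-step run on
a tiny cohort needs proportionally larger steps to converge — the
standard small-data adjustment; augmentation is disabled because at
this cohort size it slows convergence more than it regularizes. Both
choices apply to the desk preset only; `TrainConfig` defaults remain
lr 1e-4 with augmentation on. With this preset the held-out cascade
reaches brain DSC ≈ 0.99 and tumor DSC ≈ 0.99 on phantoms, and each
model trains in minutes on one CPU.

## Numerical choices and degenerate inputs

- Probabilities are clipped to [1e-7, 1−1e-7] inside the focal term;
  the dice smoothing constant is 1e-6.
- Weight init is He-normal scaled by fan-in, seeded; the final 1×1×1
  layer's bias starts at −2.0 so the initial foreground probability sits
  near a background prior (~0.12) — the standard prior-initialization
  trick that keeps the focal term from saturating the sigmoid in the
  first steps. Gradients are clipped to a global norm of 5.0
  (`TrainConfig.max_grad_norm`; 0 disables). All randomness
  (init, split, shuffling, augmentation, noise, observers) derives from
  explicit integer seeds, and every demo-level seed is derived from one
  global seed via `SeedSequence`.
- Max-pool backward routes gradient to the argmax (first on ties);
  up-sampling backward sums over each 2³ block.
- Crop/pad centers per axis independently; odd differences put the
  extra voxel on the high-index side.
- z-scoring a constant volume is an error for network input but yields
  an all-zero volume (warned) in `segment_stepwise`, so an all-zero
  stack degrades to an empty brain prediction plus warning rather than
  a crash.
- NIfTI affines with rotation/shear are rejected at load; the whole
  pipeline assumes axis-aligned lattices in (z, y, x) order.
- Mask resampling cannot create labels outside {0, 1}; nonzero values
  on ingestion are coerced to 1 with a warning.

## Known limitations

- CNN predictions are translation- but not flip/rotation-equivariant;
  near-equivariance on phantoms is an empirical property of training,
  checked approximately, never exactly.
- The numpy engine trains small nets on small cohorts; full-scale
  training (base_filters 32, dozens of real cases, augmentation on)
  would need hours to days on CPU and is out of the package's intended
  range.
- Real-data performance figures (for example brain DSC ≈ 0.85–0.87 on
  rat/mouse cohorts) require the original scans and trained weights and
  are not reproducible here; the package reproduces the method, the
  protocols and their internal consistency, not those numbers.
- `run_noise_challenge` measures SNR from ground-truth-derived regions;
  on real data without masks the regions must be supplied.
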