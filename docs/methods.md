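# Methods

This note records the models, parameter choices, and numerical decisions
behind `tractfa`, and what the synthetic validation does and does not show.

## The phantom and what it emulates

The generator stands in for a two-center PPA imaging study. Its default
configuration *is* the study condition set, not a tuning surface:

| parameter | default | meaning |
|---|---|---|
| grid | 40×48×40 voxels, 2 mm isotropic | desk-scale stand-in for 2.0/2.5 mm protocols |
| tract diffusivities | λ∥ = 1.7·10⁻³, λ⊥ = 0.3·10⁻³ mm²/s | typical white-matter tensor, FA ≈ 0.80 |
| background | isotropic, MD = 0.767·10⁻³ mm²/s | non-fibre tissue |
| groups | control 39, nfPPA 29, svPPA 27 | study cohort sizes; ages 57.9±11.6, 60.4±5.0, 62.4±10.4 y |
| centers | A: 31 directions; B: 65 directions; both b = 1000 s/mm² | two protocol variants; controls mostly at B, patients mostly at A |
| center effect | +0.05 FA (additive, center B) | planted site offset the harmonization must remove |
| age effect | −0.001 FA/year inside tracts | linear decline around reference age 60 |
| lesions | ΔFA = 0.10 over a 40 mm span; cc_ii for nfPPA, left ILF for svPPA | ground truth for the group contrasts |
| severity | per-subject uniform 0.5–1.5 multiplier | inter-patient heterogeneity; drives score coupling |
| follow-up | 10 nfPPA + 6 svPPA at +12 months; depth and span +30% | lesion progression |
| scores | sob = 40·depth + 0.5 + N(0, 1.18), controls 0 | designed FA–score correlation ≈ −0.7 at lesion voxels |
| subject FA level | per-subject N(0, 0.01) offset inside tracts | biological between-subject variability; without it, tract means are unrealistically precise and group tests flag harmonization rounding |
| atrophy | ×0.85 GM in left frontal (nfPPA) / left temporal (svPPA) | volumetric ground truth; lost GM becomes CSF so ICV is conserved |
| noise | FA maps: σ = 0.03 per voxel; DWI: σ = 33 at S₀ = 1000 (SNR ≈ 30) | measurement noise |

Lesions are implemented as trace-preserving shrinkage of the eigenvalue
deviator: for target FA f the deviatoric norm is rescaled to
u = f·√3·λ̄ / √(1.5 − f²), which hits the requested FA decrement exactly
(closed form, no iteration). Overlapping tubes resolve by the
nearest-centreline rule; tubes that leave the grid are rejected.

Two routes produce observed FA maps. The *DWI route* simulates
S = S₀·exp(−b·gᵀDg) per gradient, adds Gaussian noise, fits tensors by
log-linear least squares, and computes FA; it is exact on noiseless input
and is exercised in the pipeline's `dwi_route` mode and the tensor tests.
The *direct route* adds the subject's age/center offsets and white voxel
noise straight onto the ground-truth FA map. The replicated Monte-Carlo
validations (50–200 cohorts) use the direct route; one replicate of the
full cross-sectional analysis takes ~2 s that way, which keeps 350+
replicate cohorts inside a few minutes on one CPU. The two routes agree on
tube FA to within the simulated measurement noise (see
`analysis/02_fit_and_harmonize.py`).

Noise is additive Gaussian on the magnitude signal, not Rician: the
subject of validation is the downstream statistics, not signal modelling.
The phantom has no anatomy, no partial-volume or crossing-fibre geometry,
no motion or susceptibility artifacts, and its subjects are already
grid-aligned. Consequently, passing tests demonstrate that the statistical
machinery recovers known effects under controlled conditions — they do not
certify performance on real, misregistered, artifact-laden data.

## Analysis parameters

All fixed analysis constants are logged at run start and verified
behaviourally in the acceptance suite: FA threshold 0.2 (analysis mask and
tracking floor), smoothing 8 mm FWHM (σ = FWHM/(2√(2 ln 2)) ≈ 3.397 mm,
converted to voxels per axis), BH FDR at α = 0.05, cluster extent
256 voxels, template-correlation stopping rule 0.7, forest hyperparameters
(100 trees, Gini, depth 4, min split 2, min leaf 1, sqrt features,
bootstrap, fixed random state).

The cluster-extent threshold is expressed in voxels; on this 2 mm grid
256 voxels correspond to 2048 mm³ (the 1:1 voxel/mm³ equivalence holds
only on a 1 mm³ normalized grid). The analysis scripts at full phantom
scale produce lesion clusters of ~420 voxels, comfortably above it; the
end-to-end demo configuration uses 64 voxels because its cohort is
smaller — both values flow from the same configuration field.

## Design choices where the method was open

- **Registration model**: 12-parameter affine (translation, rotation,
  log-scale, shear) maximizing normalized correlation, Powell optimizer,
  two-level multi-resolution. Rigid-only is insufficient for inter-subject
  normalization; nonlinear warping is out of scope. Halfway alignment uses
  the principal matrix square root via logm/expm of the homogeneous
  transform, so neither timepoint is interpolated more than the other.
- **Tensor interpolation**: trilinear on the six components;
  nearest-neighbour for masks and labels. Reorientation uses the
  finite-strain rotation (polar decomposition of the linear part).
- **Normalization iterations**: first pass on b0, later passes on FA
  (higher contrast), stop at correlation > 0.7, at most 4 iterations;
  subjects that never reach the threshold are flagged rather than
  silently accepted, mirroring quality-control exclusion. Because the
  phantom emits grid-aligned maps, the default pipeline run skips
  inter-subject registration (`normalize` is exercised on warped inputs in
  the test suite); real data would route through it.
- **Center correction**: "linear first-order" is read as per-voxel
  gain + offset moment matching (gain = sd_A/sd_B,
  offset = mean_A − gain·mean_B), which removes an additive site offset
  exactly on the fitting controls; a pure-offset mode is available. Gains
  fall back to 1 where sd_B < 10⁻⁶ FA units. Age correction runs first,
  per center, to the control reference age.

  Moment matching has a side effect worth naming: it pins the corrected
  center-B controls to the center-A *sample* moments, so the corrected
  control group carries the sampling error of the smaller center-A control
  pool. When the groups' center composition is unbalanced, that error does
  not cancel from patient–control contrasts and mildly inflates group-test
  statistics. The replicated recovery conditions therefore use a
  center-balanced cohort (equal A/B fractions in every group), where the
  correction error is common mode and cancels; the full-scale analysis
  scripts keep the study's unbalanced composition, where the single-run
  results remain clean but this caveat applies.
- **Tracking**: the "neighbourhood-aware" modification is implemented as
  averaging the trilinearly interpolated tensor with its six grid
  neighbours before eigenvector extraction; the probabilistic element is a
  uniform angular perturbation bounded by 10°. Step 1 mm, max angle 45°,
  5 seeds/voxel, max length 200 mm; none of these have authoritative
  values, all are configuration. A launch integrates both eigenvector
  polarities and is retained once either reaches the target.
- **TFAS** averages subject FA over visited voxels (voxel-level
  definition, invariant to streamline order and duplication), not over
  per-streamline profiles.
- **WBSS sidedness**: two-sided Welch tests with signed cluster reporting,
  since both FA decreases and increases are of interest. Clustering uses
  26-connectivity by default (6-connectivity by flag) and runs on
  FDR-surviving voxels. The analysis mask is computed from the unsmoothed
  corrected maps so that it tracks true fibre support rather than the
  smoothing halo.
- **Longitudinal cluster matching** is by maximal voxel overlap between
  same-sign clusters; peak-proximity matching proved brittle when the peak
  drifts along an extended lesion.
- **Volumetry**: ICV = integrated GM+WM+CSF; atrophy in the generator
  converts GM to CSF so that ICV standardization does not leak the atrophy
  into unaffected structures. Group tests are Welch (the test behind the
  reference tables is unstated); longitudinal change uses a paired t-test.
- **Classification**: the documented 80/20 split and fivefold CV are
  reconciled as stratified 5-fold CV (each fold is the 20% validation).
  Elimination drops the feature with the lowest fold-averaged Gini
  importance and keeps the reduced set iff mean accuracy does not fall
  (tolerance 0 by default); importances are reported fold-averaged. The
  forest itself is scikit-learn's; folding, elimination, and reporting are
  implemented here.

## Numerical notes and degenerate inputs

- Eigenvalues are clamped at zero before FA; all-zero voxels get FA 0, so
  FA never leaves [0, 1].
- Welch voxels with zero variance in both groups return t = 0, p = 1 and
  are counted; constant score vectors make the correlation map flagged
  and null rather than raising.
- Age-model slopes are zeroed for degenerate regressors (all ages equal or
  fewer than 3 controls). Corrections clip FA to [0, 1].
- Smoothing uses zero padding; inside a mask it renormalizes by the
  smoothed mask to avoid edge dilution. The impulse-response FWHM is
  verified numerically to 8 mm ± half a voxel.
- All randomness is keyed on explicit seeds (phantom seed + CRC of the
  subject id + a purpose salt), making every artifact bit-reproducible;
  run manifests content-hash each stage's outputs to prove it.

## Problem sizes used in validation

The replicated checks run 200 false-discovery simulations (24³ mixture
phantom, 15 subjects/group), 50 lesion-recovery cohorts (n = 25/group),
100 correlation cohorts (n = 29 patients), 100 longitudinal cohorts
(10 patients, 25 controls), and 100–150 classifier simulations (n = 60,
10 features). These sizes give binomial standard errors of 3–5% on the
reported success fractions. The analysis scripts run once at the full
study size (39/29/27).

## Known limitations

- All validation evidence is synthetic; no patient-data results (cluster
  tables, R values, accuracies from real cohorts) are reproduced here, and
  the desk-scale effects are deliberately stronger than clinical reality so
  that recovery is unambiguous.
- Linear registration only; no diffeomorphic refinement, no real MNI
  atlas — "template space" is the phantom grid and reported coordinates
  are world mm in that space.
- Single-shell tensor model only; no multi-shell, kurtosis, or spherical
  deconvolution; no crossing fibres in the phantom, so the tracker's
  behaviour at fibre crossings is untested.
- The bounded-angle uniform perturbation is a stand-in for the original
  probabilistic sampler, whose exact perturbation law is not public.
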