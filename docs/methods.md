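# Methods

## The harmonization model

Single-shell diffusion-weighted MRI measures, per voxel, the attenuation
S(g)/S0 along unit gradient directions g. Because the signal is antipodally
symmetric, it admits an expansion in the real, even-order spherical-harmonic
(SH) basis,

    S(g)/S0 = sum_{l even} sum_{m=-l..l} c_lm Y_lm(g),

and the per-order energies

    E_l = sum_m c_lm^2

are invariant to rotations of the gradient frame (RISH features). E_0 carries
the orientation-averaged attenuation, E_2 the leading anisotropy, E_4 finer
angular structure.

Scanner- and protocol-related differences between two sites act, to good
approximation, multiplicatively on these energies. Given groups of controls
at a reference and a target site matched for age and sex — so that their
*biological* diffusion profiles agree in expectation — voxelwise scale maps

    Delta_l(v) = sqrt( (E_ref,l(v) + eps) / (E_tar,l(v) + eps) )

are learned from the groups' expected (sample-mean) RISH features, and every
target-site scan is harmonized by scaling its coefficients, c'_lm(v) =
Delta_l(v) c_lm(v), then reconstructing the signal at the subject's own
directions. The mapping is linear in the SH domain and nonlinear in the
signal domain. Energies transform exactly: E'_l = Delta_l^2 E_l.

Harmonizing several target sites to one reference also harmonizes the
targets against each other (transitivity), which is what makes pooled
multi-site analyses possible.

### Noise-debiased expected energies

A least-squares coefficient estimate carries noise, and the *measured*
energy is biased upward by it: E[Ê_l] = E_l + sigma^2 tr[(M M')_ll], where M
is the fitting matrix. The bias depends on the number of gradient
directions, so two sites with different schemes have different noise
energies even with identical tissue. The ratio of raw measured energies
therefore maps one site's noise energy onto the other's; at SNR 30 with 45-
vs 32-direction schemes this leaves a small but systematic anisotropy shift
in harmonized data (about 0.0015 in skeleton-mean FA here). By default the
expected RISH features are debiased before the ratio, using the per-voxel
residual variance of the SH fit and the per-order trace of the coefficient
covariance; `noise_correct=False` restores the plain ratio.

### Common representation for comparisons

Reconstruction from a band-limited SH fit removes the signal content the
basis cannot represent, including part of the noise. A comparison between
raw reference data and reconstructed target data therefore confounds the
*representation* with the *site*: the reconstruction alone shifts tensor
metrics (roughly +0.002 FA at SNR 30) and changes the dispersion that PSMD
summarizes. The pipeline consequently evaluates both arms in the common
representation by default: reference scans, and the pre-harmonization arm,
are projected through the same order-4 fit with identity scaling
(`project_reference` / `project_before`), so before/after differences
isolate the learned inter-site transformation. Both flags can be switched
off to reproduce the raw-data convention.

## B-value mapping

Sites acquire at slightly different b-values (1000–1200 s/mm^2). Under
monoexponential decay S/S0 = exp(-b g'Dg), mapping to a common b is a power
law on the attenuation, (S/S0)^(b_target/b_source) — a linear scaling of the
log-attenuation. It is exact for Gaussian diffusion and validated only for
closely spaced b-values around 1000 s/mm^2; attenuations are clamped to
[1e-6, 1] first (values above 1 arise from noise). Mapping precedes SH
fitting in the pipeline.

## Tensor metrics

FA and MD come from a weighted log-linear least-squares tensor fit (weights
= squared signals, the first-order variance stabilization for log-
transformed data); voxels with non-positive signals or negative eigenvalues
are flagged, not clamped. This differs from nonlinear fitting routines by
small numeric amounts. PSMD is the 95th-minus-5th percentile of MD over the
white-matter skeleton mask, with linear interpolation between order
statistics (PSMD is sensitive to the percentile rule, so it is pinned).
The skeleton is a supplied mask: tract-skeletonization itself is out of
scope, and the synthetic phantom emits its own ground-truth skeleton.

## Key parameters

| parameter | default | notes |
|---|---|---|
| `l_max` | 4 (auto-reduced if directions are few; configurable to 8) | orders 0/2/4 carry the harmonization; 15 coefficients need >= 15 directions |
| `reg_lambda` (Laplace–Beltrami) | 0.0 | shrinkage at 0.006 biases l=2 energy by 6–9% depending on direction count, which surfaces as a spurious site effect when the reference stays raw; the LS fit at order 4 with >= 30 directions needs no stabilization |
| `eps` | 1e-8 | guards the energy ratio in background/CSF voxels |
| `clip` | [0.1, 10] | bounds Delta so near-zero-energy voxels cannot amplify noise |
| `smoothing_fwhm` | 4 mm | smooths expected RISH maps so individual anatomy does not leak through residual misregistration into the scale maps; set to 0 in the synthetic studies, whose subjects share one voxel-aligned grid |
| `noise_correct` | on | see above |
| common b-value | 1000 s/mm^2 | the shell all sites are mapped to |
| b0 threshold | 50 s/mm^2 | volumes below count as non-diffusion-weighted |
| permutations | 1000 | voxelwise max-statistic FWER null |

## Evaluation statistics

Site differences in controls are tested three ways: age/sex-adjusted
Cohen's d of skeleton means between sites, one-way ANOVA across sites, and
voxelwise two-sample t-tests with max-statistic permutation FWER control
(a permutation-based alternative to cluster-enhancement pipelines; the
family-wise null is exact for exchangeable groups and the readout — are
site differences present? — is the same). Disease sensitivity uses the
linear model `metric ~ group + age + sex`, with d = group coefficient /
residual SD — with no covariates this is exactly classical pooled-SD
Cohen's d — and the large-sample CI d ± 1.96 sqrt((n1+n2)/(n1 n2) +
d^2/(2(n1+n2))). WMH associations regress z-scored skeleton metrics on
z-scored Box-Cox-transformed WMH volume (% of intracranial volume) plus age
and sex, in patients; lambda is chosen by profile likelihood on a grid over
[-2, 2] in steps of 0.01. Age is centered and sex coded as a 0/1 indicator.

## The synthetic cohort generator

No public multi-site SVD dMRI cohort exists, so validation runs on a
digital phantom with known ground truth.

**Geometry.** A 32x32x16 grid at 2 mm isotropic: an ellipsoidal brain with
two crossing white-matter bundles (along x and along y, a two-tensor
mixture where they overlap), isotropic grey matter (0.8e-3 mm^2/s) and CSF
(3.0e-3 mm^2/s), and a ground-truth skeleton along the single-fiber bundle
cores. The crossing is excluded from the skeleton: PSMD-style analyses mask
their skeleton conservatively, and in the crossing the tensor model itself
is biased, which would add a severity-tracking mode to the skeleton MD
histogram. A fixed smooth anatomical profile (+-10%) modulates radial
diffusivity identically for every subject, giving the skeleton the static
along-tract MD spread real data has — without it PSMD is noise-dominated.

**Subjects.** Controls carry a global radial-diffusivity multiplier with SD
0.055 plus a small age slope, yielding mean-skeleton FA SD ~ 0.018 and MD SD
~ 2.3% across controls, within the spread elderly control groups show.
Patients add (a) a diffuse radial increase proportional to 0.18 + 0.15 x
(standardized log WMH burden + noise), spatially weighted by a fixed smooth
severity field in [0.5, 1.5], and (b) focal lesions (axial 1.3e-3, radial
0.9e-3 mm^2/s — higher MD, lower FA by construction) grown as spheres in
white matter outside the skeleton core until their volume matches the
subject's WMH burden to the voxel. The noise SD of the diffuse effect is
set so the population R^2 between Box-Cox WMH volume and skeleton MD equals
a configured target (0.6 by default; verified at 0.602 by direct Monte
Carlo of the generator equations). WMH burdens are log-normal in patients
(median 1% of intracranial volume) and near zero in controls.

**Designed cohorts.** Patient WMH burdens and the latent severity noise are
drawn by stratified (Latin-hypercube) sampling per site, with the noise
orthogonalized against the design variable and pinned to its nominal SD. A
cohort of 60 then carries the declared population variances; i.i.d. draws
of that size would fluctuate by far more (SD of R-hat^2 ~ 0.086) than the
calibration being tested. Training-control ages and sexes are shared across
sites — matched by construction, as a real study would match them.

**Site effects.** Each site multiplies the order-l SH coefficients by a
smooth field gamma_l(v) = base_l (1 + amp f(v)) (default amp 5%), then adds
Rician noise (magnitude of a complex Gaussian) at the site's b0 SNR
(default 30). Injecting the effect in the SH domain makes recovery an
internal-consistency test — it is exactly the space the method corrects;
the five default site presets mirror a 1000–1200 s/mm^2, 30–61-direction
multi-site study. Determinism is total under a master seed: subject
generators are seeded by (seed, site index, subject index), site fields by
(seed, 777, site index).

**What the generator does not emulate.** Real anatomy, registration error,
eddy/motion/susceptibility artifacts, multi-shell acquisitions, or
free-form (signal-domain) site effects — an injected-in-SH effect is
exactly correctable by construction, so passing tests show internal
consistency and statistical calibration, not robustness to arbitrary
scanner physics.

## Study scenarios and problem sizes

The validation experiments run at desk scale: site-difference removal with
20 controls/site and a gamma_2 = 0.8 target; transitivity with three sites
at 15 controls each; effect-size preservation with 40 controls + 60
patients per site under a mild near-uniform site effect
(gamma = (1.01, 0.96, 0.97), field amplitude 1%, 12 mm expected-map
smoothing — for a near-uniform effect heavy spatial pooling suppresses
training-sample noise in the scale maps without biasing them); association
recovery and pooling with 60 patients/site under the strong effect. A
strong, spatially structured site effect genuinely alters within-site PSMD
contrasts (its removal is site-effect removal, not method damage), which is
why preservation is quantified on the mild pair.

## Known limitations

* Scale maps assume co-registered data on one grid; the template/warping
  machinery real studies need is out of scope.
* Single shell only; the b-value mapping degrades for widely separated
  b-values or strongly non-Gaussian regimes.
* The log-linear WLS tensor fit and the pinned percentile rule can differ
  from other implementations in the last digits.
* PSMD depends on skeleton masking conventions; with a user-supplied
  skeleton the published tool's exact masking is only approximated.
* With groups smaller than ~15 training controls the expected RISH features
  absorb individual anatomy; the pipeline warns below that size.
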