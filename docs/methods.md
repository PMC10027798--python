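# Methods

This note documents the models behind `tandemspect`, the defaults and why
they were chosen, what the synthetic data do and do not emulate, and the
numerical decisions that affect results.

## Imaging problem

A dual-head gamma camera with a high-energy collimator acquires, at 24 h
after simultaneous administration of ~1000 MBq ¹⁷⁷Lu- and ~8 MBq
²²⁵Ac-labelled PSMA ligand, the 208 keV photopeak of ¹⁷⁷Lu (15 % width, with
170 keV/15 % and 240 keV/10 % scatter windows) and the 440 keV gamma of the
²²⁵Ac progeny ²¹³Bi (20 % total width, with one adjacent lower scatter
window of 44 keV). 16 views per head are taken at 3.5 min per view
(128² detector pixels of 4.7952 mm). At 48 h a ¹⁷⁷Lu-only scan follows with
64 views per head at 5 s. The 440 keV channel runs at ~26 cps — an extreme
low-count regime. The ²²¹Fr 218 keV line sits inside the 208 keV window but
contributes < 1 % at the 8:1000 activity ratio (computed analytically from
the emission probabilities, 11.4 % vs 10.41 %); it is neglected, and the
package provides the calculator that justifies this.

## Forward model

The projector is rotation-based. Per view the volume is rotated about the
scanner axis by a sparse bilinear operator; the forward direction uses the
*splat* (transpose of the bilinear gather), which conserves total activity
exactly, so view totals are independent of object position. Attenuation
factors `exp(-Δy·(Σ μ beyond the voxel + μ/2))` are precomputed per view
from the rotated μ-map (water mass-attenuation at the window energy, scaled
by CT density). Each constant-distance plane is convolved (batched FFT) with
the PSF kernel of its source-to-collimator distance, then planes are summed
and scaled by `voxel volume × sensitivity [cps/MBq] × time per view`.
Because rotation is an explicit sparse matrix and the kernels are exactly
centrosymmetric, the adjoint used by MLEM is the exact transpose of the
forward operator (verified to < 10⁻⁶ relative; in practice exact to
rounding).

**Collimator-detector response.** Two regimes:

- `gaussian` (¹⁷⁷Lu, 208 keV): isotropic Gaussians with
  `FWHM(d) = sqrt(intrinsic² + (slope·d)²)`; defaults intrinsic 4.0 mm,
  slope 0.09 mm/mm — a high-energy collimator resolution curve.
- `high_energy` (440 keV): the same Gaussian core carrying (1−p) of the
  counts plus 2k exponential-decay star arms carrying fraction p, emulating
  septal penetration through a hexagonal-bore collimator. Defaults:
  p = 0.25, k = 3 arm pairs at 60°, arm decay length 40 mm. The stack holds
  150 kernels for distances up to 600 mm. These are analytic stand-ins with
  the correct qualitative anatomy (distance-dependent core, star-shaped
  tails); no Monte Carlo transport is performed.

**Scatter.** A parametric emulation sufficient to test the correction
algebra: the measured photopeak is `primary + s_f · B(primary)` with B an
80 mm FWHM blur; each adjacent window records a fraction of the same blurred
component chosen so that the window-based estimate
`S = Σ (C_w / w_w) · w_p / 2` recovers the injected scatter exactly in
expectation. Defaults `s_f` = 0.3 (208 keV) and 0.5 (440 keV) — downscatter
is heavier in the high-energy window. Counting noise is per-pixel Poisson;
low-count acquisitions divide the time per view (factor 30 for the LC
phantom) before drawing.

## Reconstruction

(OS-)MLEM with the same system operator; the scatter estimate is added to
the expected data in the EM denominator (preserves Poisson statistics and
nonnegativity; pre-subtraction is not used). Schedules follow clinical
practice: ¹⁷⁷Lu 20 iterations with 16-projection subsets; ²²⁵Ac 60
iterations with all views per update (at 26 cps, subsets are too sparse).
Negative window-estimate pixels are clamped at zero. Voxels with subset
sensitivity below 10⁻⁶ of the maximum are frozen at zero. The system matrix
is built with unit sensitivity, so reconstructed values carry the true
calibration factor as a constant; `calibrate_to_concentration` divides it
out. `derive_calibration_factor` implements the cylinder procedure as mean
view count rate over known activity; its closed loop is exact for an
attenuation-free acquisition, so the bundled calibration simulates the
cylinder without attenuation (an attenuated acquisition would fold the
object's self-absorption into the factor).

A quadratic smoothing prior exists behind the plain-MLEM default only as a
config hook; all results here use the uniform prior (the clinical
algorithm's prior is not public, and the schedules above are honored as the
operative description).

## Synthetic data

**Phantom.** A 101 mm × 110 mm water cylinder (3.53 l) with three sphere
inserts of 200/45/20 ml at 120° spacing, background 0.9 kBq/ml and inserts
at 6.4:1 (5.76 kBq/ml), total ≈ 4.4 MBq — the high-count condition; the
low-count condition divides acquisition time by 30. Five 100 ml background
rods (17.8 mm × 100 mm) sit between and around the inserts, clear of every
insert, and provide the SNR noise reference. Insert shapes are spheres (the
physical phantom's insert geometry is not dimensioned); masks use
voxel-center inclusion.

**Patients.** A water torso cylinder holds two kidney ellipsoids and
`n_lesions` spheres placed uniformly at random without overlap (bounded
retries, then error). Draws per structure:

- ¹⁷⁷Lu SUV ~ truncated normal: kidneys 2.1 ± 0.9, lesions 2.1 ± 1.5.
- ²²⁵Ac SUV = ¹⁷⁷Lu SUV × (1 + r) with r normal around the ratio of the
  cohort means (kidneys 2.5/2.1 − 1 ≈ +0.19, sd 0.23; lesions
  1.8/2.1 − 1 ≈ −0.14, sd 0.32). Centring the ratio on the ratio of the
  means (rather than on the mean per-patient ratio, +21 %) makes the
  sd-zero cohort reproduce the printed SUV means exactly; the two centres
  differ because a mean of ratios is not a ratio of means.
- ¹⁷⁷Lu effective half-lives ~ moment-matched log-normal: kidneys 31 ± 17 h,
  lesions 51 ± 39 h (positive, right-skewed: sd ≈ mean), clipped below the
  ¹⁷⁷Lu physical half-life. ²²⁵Ac half-lives follow by the shared-biology
  conversion.
- Lesion volumes ~ truncated normal 21 ± 13 ml.
- A lesion is generated with *increasing* 24→48 h uptake with probability
  7/26 (the cohort's seven non-evaluable lesions out of 26); such lesions
  cannot be fitted by a decaying mono-exponential and must be excluded and
  counted by the pipeline.
- Non-VOI body background: SUV 0.3 with a 25 h effective half-life — a
  nonzero background exercises scatter and segmentation realistically.

SUV convention on both the generator and measurement side: concentration
over decay-corrected injected activity per gram body mass, tissue density
1 g/ml. Using one convention on both sides is required for the recovery
contracts to be meaningful.

What the generator does **not** emulate: anatomy (XCAT-style organs, bone,
bladder), respiratory/patient motion, intra-VOI heterogeneity, non-mono-
exponential kinetics, free-daughter redistribution (a hook exists for a
²¹³Bi kidney excess factor), and registration error between time points
(all maps share one grid). Passing tests therefore demonstrate the
correctness and self-consistency of the algorithms under the stated count
levels and geometry — not clinical accuracy on real patients.

## Dosimetry

Kinetics: two-point mono-exponential fit between 24 h and 48 h VOI means;
a VOI whose later uptake is not lower is flagged excluded. Effective
half-lives convert between nuclides through `1/T_bio = 1/T_eff − 1/T_phys`
(physical half-lives: ¹⁷⁷Lu 6.647 d, ²²⁵Ac 9.920 d). The voxel
time-integrated activity applies the closed form
`TIA = A(t*)·exp(ln2·t*/T½)·T½/ln2` — the 0→∞ integral of the
mono-exponential extrapolated through the measurement; it slightly
overestimates if the true uptake phase is still rising before t*.

Voxel S-value kernels are analytic and energy-conserving by construction
(Σ kernel × voxel mass = energy per decay, reference density 1.0 g/ml):
²²⁵Ac deposits the full 27.6 MeV chain energy in the source voxel (alpha
ranges ≪ voxel size; full local deposition of all daughters is assumed, as
in the clinical comparison this mirrors); ¹⁷⁷Lu spreads its 0.147 MeV mean
electron energy over an exponential shell of 0.6 mm scale, so the
self-fraction tends to 1 as voxels grow. Dose maps are weighted voxel-wise
by `ρ_ref/ρ(x)`; the reference density of the weighting must equal the
density the kernel was derived for (here 1.0), otherwise a constant bias
enters. Kernel spill-out past the body contour (dose to air) is discarded
before weighting. RBE weighting multiplies by 5 for ²²⁵Ac and 1 for ¹⁷⁷Lu;
reports normalize to Sv_RBE=5/MBq (²²⁵Ac) and Sv_RBE=1/GBq (¹⁷⁷Lu).

## Harmonization and segmentation

Cross-isotope comparability is achieved by Gaussian post-filtering: the
²²⁵Ac image is fixed at 30 mm FWHM and the ¹⁷⁷Lu filter is searched over
20–50 mm (5 mm steps) for the closest kidney SNR match (ties break toward
the smaller width). SNR is defined as VOI mean over the pooled
background-VOI voxel sd (the five rods in the phantom, the non-VOI body in
patients); whether the clinical analysis used background or insert-internal
sd is not documented, so this is an explicit config-level definition.
Lesion uptake is read from an 80 % isocontour: hill-climb (26-neighborhood)
from the seed to the local maximum, threshold at 0.8 × max, keep the
connected component containing the maximum.

## Numerical choices and problem sizes

- Desk-scale phantom studies run on a 64×64×24 grid at the clinical
  4.7952 mm pitch (307 mm field of view around the 202 mm phantom); the
  96×96×64 grid remains the pipeline default for larger runs. SNR at these
  count levels is count-limited, not grid-limited.
- The "ideal" imaging mode of the patient study is the perfect-imaging
  limit (measured maps equal true maps, no harmonization filtering): it
  isolates the kinetics/dosimetry chain for recovery contracts. The
  "realistic" mode runs the full simulate/reconstruct chain and shows the
  expected negative partial-volume bias on kidney dose.
- FFT-based plane convolutions can produce round-off below zero; projections
  clip at zero, dose maps clamp after convolution.
- MLEM convergence: with heavy 440 keV blur the inverse problem is
  ill-conditioned and converged recovery exceeds the measured-phantom
  values (a matched-model simulation has no model mismatch). Recovery
  reference bands are therefore asserted at the clinical 30 mm post-filter
  operating point; identity-style contracts (scatter-oracle equivalence,
  uniform-cylinder recovery) are asserted on well-conditioned
  configurations (delta or mild PSF) where the ML fixed point is unique.
- All randomness flows from a single integer seed through
  `numpy.random.SeedSequence` spawning; reruns are byte-identical.
- Run configs are validated eagerly (unknown keys and invalid values are
  rejected before any computation); every output carries the config hash
  and seed.

## Known limitations

- The PSF stack and scatter model are parametric emulations, not photon
  transport; absolute septal-penetration magnitudes are plausible defaults,
  not measured ones.
- The calibration-factor values (22.7 and 7.0 cps/MBq) anchor simulated
  count levels to the clinical system but are inputs, not derived camera
  properties.
- Single-compartment mono-exponential kinetics only; no biologically
  effective dose; no organ-level S-value phantoms.
- DICOM ingestion, image registration and resampling are out of scope;
  volumes are exchanged as NIfTI-1 with JSON sidecars on a common grid.
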