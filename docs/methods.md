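# Methods

`freecine` is a desk-scale, fully synthetic re-creation of a free-running 5D
cardiac cine MRI study: a beating, breathing digital phantom is sampled along
a self-gated 3D radial trajectory, the motion is recovered blindly, the data
are binned and reconstructed by compressed sensing, and left-ventricular (LV)
volumes from the result are compared against a simulated breath-held 2D cine
reference with the usual method-agreement statistics.  Every stage has known
ground truth, so the whole chain can be validated quantitatively.

## The phantom

The LV is a pair of concentric ellipsoids inside a static torso ellipsoid.
Contraction scales the endocardial short semi-axes by a smooth periodic curve

    s(phi) = 1 - cf * sin^2(pi * phi / (2 * phi_ES)),   phi <= phi_ES,

mirrored back to 1 at phi = 1 (C1-continuous at end-systole and at the wrap);
the long axis uses half the fractional shortening `cf`.  The cavity volume is
therefore closed-form at every phase, `V(phi) = (4/3) pi a b c s^2 s_long`,
and the ejection fraction depends only on `cf`:
`EF = 1 - (1 - cf)^2 (1 - cf/2)`.  `anatomy_for_volumes(edv, ef)` inverts
this relation, so a subject can be prescribed exact EDV/EF.

Defaults describe a healthy adult: EDV 160 mL, EF 61%, wall thickness 10 mm,
long axis tilted 15 degrees from superior-inferior (SI), bright-blood
contrast blood:myocardium:background = 1 : 0.35 : 0.15.  Respiration
translates the heart along SI as `A * sin^4(pi t / T)`, which dwells near
zero far longer than at peak inspiration — the end-expiratory plateau of
natural breathing that makes "equally populated" amplitude states have very
unequal dwell times.  RR intervals are Gaussian around `60000 / HR` ms
(resampled if a draw falls at or below 300 ms).  Coils are eight smooth
complex Gaussian lobes around the torso.

Voxelisation is binary (no partial volume); the voxelised cavity volume
converges to the closed form as the grid is refined (within 2% at 64^3) and
this discretisation error is part of every downstream tolerance.

What the phantom deliberately omits: bSSFP signal physics (contrast is
prescribed, not simulated), right ventricle and atria, papillary muscles,
through-plane cardiac motion, non-rigid respiratory deformation (pure SI
translation), arrhythmia.  Passing tests therefore show the *pipeline*
recovers prescribed motion and volumes from its own forward model; they do
not certify performance on in-vivo data.

## Acquisition model

Radial readout endpoints follow the spiral phyllotaxis rule: endpoint m of N
has polar angle `(pi/2) sqrt(m/N)` and azimuth `m * 137.51 deg`; interleave i
takes every `n_interleaves`-th endpoint, giving smooth pole-to-equator arms.
Each interleave is 22 TRs (TR 3.53 ms): one SI self-gating (SG) readout plus
21 imaging readouts, so SG samples arrive every 77.66 ms (~13 Hz, enough for
cardiac/respiratory rates up to 360 per minute).  The preset interleave
counts for the 1..6-minute acquisitions are {762, 1516, 2322, 3058, 3833,
4621}.  Each readout samples a full k-space diameter with `n_samples = grid`
points.

The simulator renders the phantom at each readout's motion state (10 ms
physio lookup; states quantised to 1/64 cycle and 1/4 voxel so repeated
states share one render and FFT), multiplies by the coil maps and evaluates
the radial line with the gridding NUFFT; complex Gaussian noise (default sd
0.05 against a blood-signal scale of ~1) is added per sample.

The NUFFT is a Kaiser-Bessel gridding transform (oversampling 1.5, kernel
width 3, Beatty shape parameter), accurate to ~2% against the exact DFT, with
an adjoint that is the exact algebraic transpose (inner-product test at
machine precision).  Because the simulator and the reconstruction share this
operator, reconstruction sees data exactly consistent with its forward model;
the residual inconsistencies are the physiological ones (intra-bin motion,
beat-to-beat variability), which is the effect under study.

The 2D cine reference is rendered analytically at end-expiration: a
short-axis stack with 8 mm slabs (averaged over 5 sub-planes), 2 mm gaps,
25 phases, 1.7 mm pixels — geometry matching a clinical breath-held protocol.

## Self-gating

SG spokes are inverse-Fourier-transformed to per-coil SI projections; the
magnitude profiles (one row per interleave, linearly detrended per column)
form the SG matrix.  PCA whitens it to 8 components; SOBI then jointly
diagonalises time-lagged covariances (lags 1..25, i.e. ~0.08-1.9 s) by Jacobi
rotations.  Sources are assigned to physiology by periodogram power fractions
in 0.08-0.5 Hz (respiratory) and 0.5-3 Hz (cardiac); selection fails loudly
if the best in-band fraction is under 0.4.  Cardiac triggers are refined
peaks of the band-passed cardiac source; the fiducial point is arbitrary but
constant, which the 50 ms binning tolerates (ED/ES are later found as curve
extrema, not assumed at bin 0).  Respiratory states are rank quartiles of the
interpolated respiratory source; end-expiration (state 0) is the dense end of
the amplitude distribution, located by the sample skewness — a robust proxy
for dwell time that resolves the blind-source polarity without a sign
convention.

## Binning and reconstruction

Each imaging readout is binned independently: cardiac bin =
`floor((t - T_prev) / 50 ms)` (readouts outside the trigger span or beyond
`floor(median RR / 50 ms)` bins are discarded rather than folded), crossed
with its respiratory state.  A ~800 ms RR thus yields ~16 cardiac bins x 4
states ≈ 64 bins.

The 5D image is reconstructed by ADMM with exactly 10 outer iterations,

    sum_b 1/(2L) || W^1/2 (A_b S x_b - y_b) ||^2
      + lambda_c ||D_c x||_1 + lambda_r ||D_r x||_1,

with `W` the radial density compensation (r^2 law; used as the standard
preconditioner for this family), `L` a power-iteration estimate of the data
term's largest eigenvalue, `D_c` circular and `D_r` mirrored first
differences, split variables soft-thresholded, and the x-update solved by 5
warm-started CG iterations.  Coil data are SVD-compressed to 4 virtual
channels (an exact restriction of the model; >99% of the energy of the
smooth synthetic coils).

Two normalisation conventions needed fixing that the printed settings do not
determine:

* **Intensity calibration.** The zero-filled initialisation weights the
  adjoint by exact radial shell volumes (the r^2 law mis-weights the centre
  sample, which all spokes share, by 3x) so reconstructed intensities match
  the object's scale.  A single-pass gridding adjoint of the binary phantom
  still carries ~0.3 NRMSE — spectral energy outside the sampled k-ball plus
  off-grid spectral leakage — while the CG-solved system reaches ~0.1.
* **Regularisation scale.** The soft-threshold is
  `lambda * 1.25 * R_b * max|x_zf|`, where `R_b` is the mean per-bin radial
  undersampling factor relative to the Nyquist spoke count `(pi/2) N^2`.  A
  framework whose data term grows with the number of acquired readouts
  weakens its *relative* regularisation automatically as sampling increases;
  the spectral normalisation used here removes that scaling, so it is
  restored explicitly.  The constant 1.25 was calibrated once on the default
  phantom (EF fidelity at the 1- and 6-minute presets simultaneously) and is
  not a per-run dial; the published weight 0.001 remains the user-facing
  default for both dimensions.

The end-expiratory cine is the magnitude of the state-0 subvolume across all
cardiac bins.

## Volumetry

The cine is reformatted onto the same short-axis geometry as the 2D reference
(trilinear sampling, 10 mm slice spacing, 8 mm slab averaged over 5
sub-planes, 2.5 mm pixels).  The blood pool is segmented per slice by
thresholding plus the connected component containing the projected LV-centre
seed; a slice contributes to Simpson's volume
(`sum areas * spacing`) exactly when its seeded component exists — no human
valve-plane judgement is modelled.  ED and ES are the volume-curve extrema;
`EF = 100 (EDV - ESV) / EDV`.

The pipeline uses one threshold per dataset: the half-maximum between the
blood plateau (median of a 5x5 seed window at the brightest phase, resistant
to Gibbs overshoot) and the nominal myocardial level (0.35 of blood, the
phantom's bright-blood contrast).  The half-maximum cut is the
area-preserving boundary for a blurred bright object, and anchoring both
levels to the measured plateau keeps it independent of how much background or
streak signal a particular reconstruction contains — class-based (Otsu)
thresholds proved unstable on heavily undersampled reconstructions.  A
stand-alone three-class Otsu segmentation (`blood_threshold`) is also
provided.

## Study orchestration and statistics

A study draws `n_subjects` phantoms from configured population ranges
(EDV 130-190 mL, EF 56-64%, HR 55-85 bpm with 10-35 ms RR jitter,
respiration 10-18 /min with 10-16 mm SI excursion — healthy-adult ranges),
simulates one independent acquisition per duration (fresh physiology per
duration, mirroring separate randomized scans) plus the 2D reference, and
aggregates per-duration Bland-Altman bias and 1.96-SD limits of agreement,
Shapiro-Wilk-gated paired tests (paired t if the differences pass normality
at p >= 0.05, Wilcoxon otherwise), and the acquisition-efficiency table
(free-running sampling time over sampling time + 60 s planning overhead; the
2D row uses the protocol's typical 112 s of sampling in a 869 s exam).  The
ICC is the single-measure two-way mixed-model coefficient for absolute
agreement, `(MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))`, classified
poor/moderate/good/excellent at 0.40/0.60/0.80 (boundaries resolved as
0.40 -> moderate, 0.80 -> good, matching ">0.80" for excellent).  All
randomness derives from one master seed through `numpy.random.SeedSequence`.

## Problem sizes

The validation study runs 3 subjects at a 32^3 grid (220 mm FOV, ~6.9 mm
voxels) over the 1- and 6-minute presets — the package's desk-scale profile,
chosen so a full study completes in tens of minutes on one CPU core.  The
study profile also drops the gridding oversampling to 1.25 (from the library
default 1.5); simulation and reconstruction share the operator, so the
inverse problem remains self-consistent while the FFT grids shrink by ~40%.  Grid,
subject count and durations are configuration; the phantom and method are
resolution-independent.  At this scale a 6-minute acquisition is roughly
Nyquist-sampled per bin while the 1-minute acquisition is ~6x undersampled,
reproducing the regime contrast the duration sweep is about.

## Known limitations

* Binary voxelisation and the coarse desk-scale grid dominate the volume
  error budget; absolute EDV/ESV from the free-running arm run ~10-15% low
  at the 1-minute preset (blur pulls the half-max contour inward), while EF,
  a volume ratio, is recovered within a few percentage points.
* The automated reader is deliberately simple; observer variability (the
  paper's intra/inter-observer analyses) is out of scope — the ICC machinery
  is provided and tested, but no human-like reading noise is simulated.
* Trigger fiducials are arbitrary; metrics relying on absolute cardiac
  timing (not used here) would need alignment.
* With fewer than ~3 breaths or ~10 s of data the source selection refuses
  to run rather than guessing.
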