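# Methods

`pemfdose` computes the electromagnetic dose delivered to an ischemic
brain lesion by a pulsed electromagnetic field (PEMF) applicator, and
relates pre/post-treatment lesion volumetrics to that dose.  This note
records the models, the numerical choices, and what the synthetic
validation does and does not establish.

## Physical model

**Source.** The clinical applicator is a 240-turn rectangular solenoid
driven by a pulsed current generator.  It is modelled, as is standard
for such sources, as a single planar rectangular turn of 0.14 x
0.106 m (the mean winding size) carrying the full equivalent current,
with a peak of 240 A.  The magnetic flux density **B** and the
magnetic vector potential **A** are evaluated with the exact analytic
finite-segment expressions for straight wires, summed over the four
sides — no numerical quadrature is involved, so subdividing the sides
changes nothing beyond round-off.  A closed form anchors the oracle:
at the loop center `|B| = (mu0 I / pi) sqrt(a^2 + b^2) / (a b)` with
half-sides `a, b`, giving 2.2719 mT at 240 A.

**Drive signal.** The published device parameters are peak current
(240 A), active-phase duration (1.3 ms) and repetition rate (75 Hz);
the pulse shape itself is not published.  The default is a trapezoid
whose rise/fall ramps are 10% of the active phase (130 us).  That
choice makes the pulse consistent with the premise of the
frequency-domain method: the analysis band up to 7.5 kHz then carries
99.98% of the signal energy, so the band-limited reconstruction
recovers the waveform to 1.3% in L2 and its peak to 1.2%.  (With 5%
ramps the Gibbs ripple of the truncated series exceeds 5% at the flat
top — such a pulse could not be faithfully represented by the stated
band.)  Raised-cosine and exponential-decay shapes are available as
alternatives.

**Harmonic decomposition.** A 75 Hz-periodic pulse has spectral lines
only at multiples of 75 Hz.  Two frequency grids are supported: the
*native* grid (75 Hz multiples up to 7.5 kHz, 100 components — the
default), and a *replication* grid of 50 Hz spacing over [50, 7500] Hz
(150 components) matching the solve schedule used with commercial
quasistatic solvers.  Amplitudes on any grid are Fourier-series
coefficients of the periodic waveform; grid frequencies that are not
multiples of the repetition rate are orthogonal to the signal over the
common period and receive exactly zero.  The DC Fourier term is kept
separately: a one-sided pulse has a substantial mean (~22 A here), and
**B**, being linear and in phase with the current, includes it in its
time course, while the induced current density **J** has no response
at omega = 0.

**Induced fields.** At these frequencies the head is electrically
small and conduction dominates: the magneto-quasistatic approximation
applies, the head does not perturb **B**, and the induced electric
field is `E = -j omega A - grad(phi)` with the scalar potential
enforcing `div(sigma* E) = 0` inside the conductor and an insulating
boundary (`J.n = 0`) at the air interface.  Tissue admittance is the
complex conductivity `sigma* = sigma + j omega eps0 eps_r`; the
displacement part is retained rather than assumed negligible (a test
measures its effect: below 10% of |J| for a representative
permittivity at 1 kHz).

## Discretization and solver

The scalar-potential finite-difference (impedance-method) scheme:
potentials on voxel nodes, `sigma*` per voxel, each node-to-node edge
carrying the mean `sigma*` of the up-to-four voxels sharing it (air
counts as zero, which builds the insulating boundary into the
operator).  Rows of the resulting complex-symmetric system sum to zero
by construction, and its residual *is* the net nodal current
imbalance, so the stopping rule directly bounds discrete `div J`.

The solve uses a Jacobi-preconditioned conjugate-orthogonal CG (COCG)
written for the complex-symmetric case; for a real operator it reduces
exactly to preconditioned CG.  A hand-rolled iteration was preferred
over library Krylov solvers because those target Hermitian or general
systems, while COCG exploits complex symmetry and keeps the solve
deterministic (zero initial guess, fixed stopping rule: relative
residual below 1e-9 in both the 2-norm and max-norm, verified on the
true residual).  The pure-Neumann system is singular up to an additive
constant; the right-hand side is consistent by construction (each edge
contributes equal and opposite nodal currents) and only potential
*gradients* enter the fields.

`E` is evaluated at voxel centers from face-averaged nodal potentials
plus the local `-j omega A` term, and `J = sigma* E`.  Verification
against the closed-form eddy-current solution of a homogeneous sphere
in a uniform axial field (`|J| = sigma pi f B rho`, exact because the
azimuthal current is everywhere tangent to the surface) gives a
maximum relative error of 2.9% at 2 mm voxels, excluding a fixed 4 mm
surface layer where the voxel staircase dominates and voxels below 20%
of peak |J| where the relative metric blows up; the RMS error falls
monotonically (1.4% -> 0.4% -> 0.09%) over 4/2/1 mm grids.  The
divergence metric `max |nodal current| / (max|J| h^2)` stays below
1e-8 on every solve.

Default grid resolution is 2 mm isotropic.  That is the desk-scale
operating point of this package: it resolves the layered phantom and
the lesions while keeping a 12-frequency dispersive band solve on a
full head to about 1.5 minutes on one CPU.  Resolution is fully
configurable; clinical workflows with sub-millimetre anatomical models
would use finer grids and the same code path.

A *fast mode* covers the non-dispersive case: with frequency-
independent real conductivity the operator is fixed and the source is
linear in omega, so one solve scales analytically across the band
(verified against per-frequency solves to 1e-6).  It refuses to run on
dispersive phantoms.

## Synthetic phantom and ground-truth lesion evolution

The phantom generator replaces everything a clinical study takes from
patients and licensed anatomical models.

* **Layered head.** Concentric (optionally ellipsoidal) shells —
  skin 4 mm, skull 7 mm, CSF 3 mm, grey matter 15 mm, white-matter
  core — of default radius 80 mm at 2 mm voxels.  Shell volumes match
  the analytic shell formulas to a few percent at this resolution.
* **Tissue properties.** A built-in table of representative
  low-frequency conductivities and permittivities for the five tissues
  over [50, 7500] Hz, log-linearly interpolated, and fully overridable
  via CSV — published low-frequency dielectric data differ enough
  between sources that pinning exact values inside the code would be
  false precision.  The lesion is edema: sigma = 1.7 S/m at all
  frequencies with grey-matter permittivity.
* **Lesions.** Ellipsoids with band-limited radial noise whose
  correlation length tracks the lesion (not the phantom) size, clipped
  to brain labels, deterministic per seed.  With zero irregularity the
  voxelized volume matches (4/3) pi a b c within 5% at 2 mm.
* **MRI-like volume.** Piecewise-constant label intensities with the
  lesion strictly hyperintense, plus Gaussian noise; rendered on an
  anisotropic grid (thick slices along one axis) so the segmentation
  chain has a real resampling problem to solve.
* **Evolution under a known law.** Each lesion voxel exposed above a
  floor survives independently with probability
  `min(1, (M_true/100) exp(a_true |B|_mT))`; sub-floor voxels persist
  and grow into neighbouring sub-floor brain tissue at a configured
  expected rate.  The Bernoulli law has an exactly computable
  expectation, which the tests check against binomial standard errors.
  Morphological closing of the post mask is available but off by
  default, because closing adds voxels and would bias that exact
  expectation.

## Segmentation

Seeded region growing (iterative dilation restricted to the
supra-threshold set, 6- or 26-connectivity) extracts exactly the
connected supra-threshold component containing the seed; a brute-force
breadth-first flood fill reproduces it voxel-for-voxel on randomized
volumes.  Masks are packed as unitary-valued NIfTI volumes with
lossless round-trip.  Grid adaptation converts the mask to a signed
distance field in millimetres, interpolates it linearly at the target
voxel centers, optionally Gaussian-smooths it iteratively, and
re-thresholds at zero; the smoothing-induced volume drift is bounded
(default 5%, configurable) and violations raise rather than warn.
Manual edge editing of the clinical workflow is out of scope; optional
morphological opening/closing with a logged structuring element
replaces it.

## Exposure analysis and the dose-response fit

Exposure is the per-voxel peak over one reconstructed signal period:
for **B** this is `|b_unit| x max|i(t)|` of the band-limited current;
for **J** the per-voxel maximum of the recomposed harmonic sum.
Volumes are voxel counts times voxel volume at voxel centers — no
partial-volume weighting, matching the binary-mask resolution.

The analysis reproduces the study's post-processing: exposure
histograms over the lesion (0.05 mT bins, anchored edges; the mode is
the robustness metric for coil-misplacement checks), slicing of both
lesions along the coil d/f/t frame at 5 mm spacing, volume-ratio
tables over exposure ranges (default B edges 1/1.3/1.7/2 mT and an
open top range; undefined ranges marked like the table "slash"),
lower-bound-threshold ratio curves, and a pooled exponential fit
`f(x) = M exp(a x)` by nonlinear least squares seeded from a
log-linear regression (deterministic given data).  The fit is exposed
as a model/results pair (`DoseResponseModel.fit()` returning
estimates, covariance, standard errors and a `summary()` table).
Two exact identities are enforced against brute-force enumeration:
per-range pre-volumes sum to the pre-volume inside the outer edges,
and the threshold curve equals the tail sums of the range table at
aligned edges.

**Why recovery needs several cases.** The threshold ratio at x equals
`(M/100) E[exp(a B) | B >= x]`, not `(M/100) exp(a x)`: fitting the
exponential to a *single* lesion spanning a wide exposure range
recovers a slope attenuated by the conditional-mean excess
`delta(x) = E[B | B >= x] - x` (about a factor 2 too shallow in a
representative wide-lesion configuration).  Pooling several cases
whose individual exposure ranges are narrow but mutually offset — the
multi-patient design — identifies the slope from between-case
variation.  The canonical recovery experiment therefore uses three
lesions (large mid-depth, small shallow, small deep; ~10,000 voxels at
2 mm) evolved under the pure law (floor 0, no untreated growth), a
0.1 mT threshold grid per case up to its 90th exposure percentile, and
20 stochastic replicates.  Median recovery errors are ~9% for M and
~8-13% for a across seeds; the residual bias (~9% on M, ~5% on a) is
the structural delta(x) effect, not noise, and is inherent to the
threshold-ratio estimator.

## What the synthetic validation does and does not show

Passing tests establish that the chain — coil field, harmonic
superposition, SPFD solve, volumetrics, fit — is internally correct
against closed forms, brute-force enumeration, and a known generator
law.  They do not validate anatomical realism: the phantom has no
cortical folding, no conductivity anisotropy, and rigid coil placement
(the conformable applicator is approximated by a planar coil with a
configurable standoff; the supported robustness check is the +-1 cm
shift analysis).  Patient-level numbers from the motivating study
(per-patient exposure extremes, its fitted M = 79.38, a = -0.1 per mT)
depend on real lesions inside a licensed anatomical model and are not
reproducible here; they serve as generator defaults and qualitative
patterns only.  One further caution carried over from that context: a
fitted decaying exponential with M near 79 and a near -0.1 per mT
implies ~69% at 1.4 mT, so statements pairing "50% reduction" with
"about 1.4 mT" are not consistent with that parameterization; this
package reports fitted curves and their covariance and leaves such
readings to the user.

## Numerical details and edge cases

* World coordinates are millimetres (matching NIfTI affines); field
  kernels convert to SI metres internally.  Voxel centers sit at
  integer grid coordinates, 0-based.
* Field evaluation within 1e-6 m of the wire raises a singularity
  error naming the offending point.
* The histogram mode may sit up to half a bin outside the raw value
  range because bin edges are anchored at multiples of the bin width
  (so histograms of shifted coils share a grid).
* Thresholds whose pre-treatment tail volume is zero are dropped with
  a log note; ratio-table rows with pre-volume zero but post-volume
  nonzero report infinity, and rows empty on both sides report the
  undefined marker.
* The coil-shift robustness metric is quantized by the histogram bin;
  at 0.05 mT bins on the wide demonstration lesion it reports ~6%
  variation for +-1 cm shifts.
* All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); repeat runs of the pipeline are
  byte-identical, which the suite asserts on the emitted CSV/NIfTI.
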