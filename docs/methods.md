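# Methods

## Coil-field model and GNL tensor

Each gradient coil axis a ∈ {x, y, z} produces a field expanded in real
solid harmonics,

f_a(r) = Σ C_{n,m} · N_{nm} · rⁿ P_nᵐ(cos θ) {cos, sin}(mφ) / R0ⁿ⁻¹,

with Schmidt semi-normalized associated Legendre functions P̄_nᵐ (no
Condon-Shortley phase) and dimensionless coefficients; R0 (mm) is the
reference radius of the expansion.  The field is normalized by the nominal
gradient, which fixes the otherwise convention-dependent normalization
through a single invariant: ∇f_a(0) = ê_a.  Models violating that
invariant (or containing non-finite coefficients) are rejected at load
time, so the choice of harmonic convention cannot change any downstream
number.

Harmonic terms are assembled symbolically as Cartesian polynomials in
(x, y, z) and lambdified to numpy, so the GNL tensor
L_ab(r) = ∂f_a/∂x_b is *analytic* — no finite differencing anywhere in the
production path.  The finite-difference Jacobian exists only as an
independent test oracle (agreement to 1e-6 at 100 random in-FOV points).

The truncated expansion diverges far outside the coil; evaluations are
limited to a validity radius of 1.5·R0.  Points beyond it are flagged NaN
(or raise), never silently extrapolated, and b-map grids that leave the
validity region raise an error that lists the offending magnet-frame
extent.

### The shipped representative model

Scanner spherical-harmonic coefficient sets are proprietary, so the package
ships a representative whole-body 3T model (`data/coil_representative.yaml`)
with the ideal linear term plus odd orders 3 and 5 per coil and
R0 = 250 mm.  Its coefficients were calibrated once, analytically, so that
the trace b-value bias c̄ − 1:

* reaches about −10% at 200 mm superior-inferior offset,
* reaches about +8.5% at 200 mm right-left offset,
* decreases monotonically along S-I and increases along R-L within the
  400 mm field of view,
* vanishes at the isocenter (L(0) = I by construction).

This reproduces the bias *regime* reported for torso-size DWI on clinical
systems; it is not any vendor's actual gradient design.  The 5th-order
transverse term makes the S-I curve turn around near 262 mm — outside the
FOV the model is calibrated for, which is why the monotonicity contract is
stated for the FOV only.

## b-maps, correction, and coordinate conventions

Coordinates are a right-handed magnet frame in mm: origin at isocenter,
+x patient-left, +y posterior→anterior, +z superior; volumes sample voxel
centers.  Station grids live in a patient/table frame; the magnet-frame
position of a voxel is its grid coordinate plus the station table-offset
vector (a scalar offset means S-I).  A fixed anatomy point therefore maps
to the same magnet position through either station, which is why b-maps of
two stations covering the same anatomy agree voxelwise — the behaviour the
multi-station offset bookkeeping is designed to guarantee.

b-maps follow the on-scanner DICOM convention: dimensionless c̄ stored as
integers scaled to 1E4 at the isocenter (`v = round(1E4·c̄)`), percent bias
β = 100·((v/1E4) − 1).  All downstream arithmetic uses v/1E4, giving
bit-exact parity with an integer-stored product.  A consequence worth
knowing: the integer quantization bounds the correction at half a quantum
(5e-5 relative), so "noiseless round trip restores truth exactly" holds to
1e-6 relative only through the *unquantized* corrector; through the stored
b-map it holds to ~5e-5 relative.  Tests pin both statements separately.

The b = 0 image carries no diffusion gradients and is treated as
bias-free; only the DW b-value is modulated.  Correction is applied at
trace level (division by c̄), which is exact for isotropic diffusion — the
bone-marrow assumption here.  ADC fitting is the two-point inversion
ADC = ln(S0/S_b)/b in μm²/ms, with non-positive signals excluded from the
validity mask (counted and logged) and S_b ≥ S0 voxels floored at zero and
flagged rather than reported negative.

## Synthetic data

### Phantom

A uniform gel ellipsoid (semi-axes 90 × 60 × 180 mm) with true diffusivity
2.13 μm²/ms (room-temperature sodium-polyacrylate preset), imaged as a
3-slice coronal slab with a 400 (S-I) × 200 (R-L) mm² FOV at 2 mm.  The
per-direction DW signal is S0·exp(−b·c_k(r)·D), so the geometric-mean trace
image carries exactly the c̄ modulation the correction must remove.

### Virtual cohort

Subjects carry ellipsoidal bone-site ROIs at anthropomorphic offsets in an
L3-centered patient frame: trochanters ±102 mm R-L and 120 mm inferior,
ilia ±52 mm R-L, vertebral bodies on the midline at 32 mm S-I pitch.
Default ellipsoid volumes match typical segmentations (trochanter
≈ 88 cm³, ilium ≈ 72 cm³, vertebra ≈ 22 cm³); specs outside a factor-3
band of those defaults, overlapping ROIs, or mis-ordered vertebrae are
rejected.  Two stations (lumbar spine; pelvis/femur) with table offsets
10 and 130 mm (120 mm separation, within the 12-23 cm range such protocols
use) place edge vertebrae in the negative-bias S-I lobe and trochanters in
the positive R-L lobe — the sign structure the analysis expects.

Truth model: site-level true-ADC bases are the corrected group means of
the MF population this generator emulates (T 0.519, I 0.628, MV 0.577,
EV 0.591 μm²/ms); each subject adds a common N(0, 0.10) offset (the
between-subject heterogeneity that drives inter-site ADC correlation) and
N(0, 0.03) per-site scatter, and ilium ADC carries a
0.05 μm²/ms-per-grade fibrosis slope so grade correlations are
recoverable.  Ilium fat fraction is drawn from a low (0.04-0.38) or high
(0.46-0.73) band with a configurable low-band count, mirroring the
FF < 40% selection rule downstream; per-site FF scales by 1.3 (trochanter)
and 0.8 (vertebrae).

Water signal is scaled by (1 − FF) before Rician noise — implemented as
the magnitude of a complex Gaussian perturbation per direction image
before geometric-mean trace formation — so high-FF sites genuinely lose
contrast-to-noise and show the low-ADC histogram truncation seen in vivo.
The default b = 0 SNR of 150 (before fat scaling) represents averaged
fat-suppressed EPI at 3T; at FF < 40% it keeps the Rician floor on ADC an
order of magnitude below the 2·SEM recovery band.

Repositioning: each timepoint draws a jitter of σ = 8/6/12 mm
(R-L/A-P/S-I) around the subject's base position, plus a ±32 mm
(one-vertebra) S-I landmark shift with probability 0.5 — emulating the
vertebra-miscounting that multi-month longitudinal scans exhibit.  These
defaults produce test-retest bias limits of agreement of roughly ±3%
under the shipped coil model; they are tunable study parameters, not
ground truth.

### What the generator does *not* emulate

Real EPI distortion, eddy currents, imaging-gradient cross terms,
anisotropic or non-mono-exponential marrow diffusion, partial-volume and
segmentation error, fat-suppression failure, or biological change between
timepoints.  Passing tests therefore demonstrate correctness of the
*bias-and-correction arithmetic and the statistical machinery* under the
stated signal model — not robustness to those confounds in vivo.  In
particular, test-retest ADC differences here are pure
(repositioning × bias) + noise, which is exactly why the corrected LOA
must shrink.

## Analysis conventions

* ROI statistics use voxels with matching label, a validity mask, and
  (for ADC) a strict > 0.01 μm²/ms floor; absent sites yield absent
  entries, not zeros, so variable vertebra coverage propagates honestly.
* Histograms are left-closed, right-open, anchored at 0 (bin edges k·Δ),
  so binning is reproducible regardless of data range; bias histograms use
  0.5% bins normalized to total ROI volume, ADC histograms 0.05 μm²/ms
  bins normalized to total count.
* Intra-subject nonuniformity is max − min of per-site mean bias;
  heterogeneity is 100·SD/mean (CV) across site means; both require ≥ 2
  sites and raise otherwise.
* Trend-deviation flags use strict inequalities with exact-tie exclusion
  (ties are measure-zero on real data and make synthetic runs
  deterministic); a missing group leaves its flag undefined rather than
  counted.
* Bland-Altman limits of agreement are exactly 1.96·SD(difference) with
  the n−1 denominator; p-values come from the t distribution throughout
  (cohorts are small); Bonferroni thresholds are exact α/k (0.05/6 =
  0.00833…, reported elsewhere rounded to 0.008).
* The paired t-test returns p = 1 with a warning on zero-variance
  differences rather than NaN.
* The 3-point median filter (sequential 3-tap medians along the in-plane
  axes, replicate edges) is a display aid only and is never applied before
  statistics.

## Problem sizes and numerical choices

Default grids are 2 mm for the phantom slab (~60k voxels) and 3 mm for
station volumes (~0.5M voxels each); the 20-subject × 2-timepoint cohort
analysis runs in well under a minute on one core because station grids and
table offsets are fixed, so coil-field evaluations are memoized across
scans.  Signals are stored float32 (ADC error ~1e-7 relative, negligible
against the 5e-5 b-map quantization); correctors and statistics are
float64.  Seeds thread explicitly through every random draw: identical
spec + seed reproduce cohorts bit for bit, and per-scan seeds are derived
from the cohort master seed.

## Known limitations

The representative coil model is a stand-in with the right magnitude and
symmetry, not a measured gradient design, so per-site bias *values* are
study-shaped rather than scanner-accurate (e.g. trochanter bias here is
+1-2%, at the low end of the +1-10% range such sites show on real
systems, because the model's transverse lobe grows more slowly than some
real coils at mid-radius).  Geometric (warping) distortion correction,
vendor DICOM scaling dialects beyond generic rescale slope/intercept, and
PDFF map reconstruction are out of scope; fat fraction enters only as a
scalar per site.
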