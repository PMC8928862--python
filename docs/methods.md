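# Methods

## Signal model

Each voxel's complex multi-echo gradient-echo signal is modelled as a
water resonance plus an eight-resonance triglyceride spectrum:

    S(t) = [ W + F f Σₘ αₘ Eₘ(t) ] e^{Ψt},    Eₘ(t) = e^{iωₘt},
    Ψ = i2πψ − R2*.

The resonance groups A–H sit at 5.28, 4.22, 2.75, 2.25, 2.02, 1.57, 1.30
and 0.90 ppm (water reference 4.70 ppm); angular frequencies are
ωₘ = 2π(δₘ − δ_w)·γ·B0 with γ = 42.577 MHz/T and B0 = 3 T by default, so
resonances below water rotate with negative frequency. The proton
amplitudes are linear in the composition parameters:

    α = (2·ndb, 4, 2·nmidb, 6, 4(ndb − nmidb), 6,
         6(cl − 4) − 8·ndb + 2·nmidb, 9)

with the chain length fixed at cl = 17.3, giving the bulk-methylene
constant 6(cl − 4) = 79.8 and the identity Σα = 104.8 − 2·ndb. Fixing cl
removes one poorly conditioned degree of freedom; interpersonal chain
length variation in human adipose tissue is small. f = 1/Σα normalises
the spectrum so that S extrapolated to t = 0 equals W + F.

Collecting terms gives the linearised form

    S(t) = [ W + A₀ P_F(t) + A₁ P_ndb(t) + A₂ P_nmidb(t) ] e^{Ψt}

with A₀ = Ff, A₁ = Ff·ndb, A₂ = Ff·nmidb and basis waveforms
P_F = 4E_B + 6E_D + 6E_F + 79.8E_G + 9E_H, P_ndb = 2E_A + 4E_E − 8E_G,
P_nmidb = 2E_C − 4E_E + 2E_G. Some printed accounts of P_F carry an extra
bare E_A term; it is inconsistent with the amplitude table (α_A = 2·ndb
has no constant part) and breaks S(0) = W + F, so it is omitted. The
literal variant remains available through `include_constant_ea` for
comparison. Whether ndb/nmidb are per-triglyceride or per-fatty-acid
averages does not affect any derived fraction; the code treats them as
abstract model parameters.

Out of model scope: T1/flip-angle steady-state weighting, eddy-current
phase, bipolar-readout corrections, and resonance lineshape broadening.

## Estimation

At fixed (ψ, R2*) the model is linear in the four complex amplitudes, so
the fit eliminates them by variable projection: the design matrix is the
basis {1, P_F, P_ndb, P_nmidb} modulated by e^{Ψt}, the amplitudes follow
from exact least squares on the unweighted acquired signal, and the
subfit residual is the objective of the outer two-parameter search.

The residual landscape in ψ is periodic with period 1/ΔTE and multimodal
(the water–fat swap ambiguity), so the outer search is multi-start: a
coarse grid of 64 field-map values across the aliasing interval
(±1/(2ΔTE) ≈ ±320 Hz at ΔTE = 1.56 ms) crossed with 6 decay rates in
[0, 300] s⁻¹ is scored for every voxel at once via precomputed orthonormal
design spans, the best 3 local minima of the per-voxel ψ-profile seed
trust-region refinements of (ψ, R2*), and the lowest refined residual
wins. A candidate whose grid residual exceeds ten times the best refined
residual is skipped. Refinement works on scaled offsets from the start
(a start exactly at ψ = 0 or on the R2* bound would otherwise open the
trust region with a vanishing radius) with R2* bounded in [0, 500] s⁻¹
and tolerances 1e−8. ψ is reported folded into (−1/(2ΔTE), 1/(2ΔTE)];
the global signal phase is absorbed into the complex amplitudes and
magnitudes are reported.

The amplitude ratios are then inverted: ndb = Re(A₁/A₀) clipped to ≥ 0,
nmidb = Re(A₂/A₀) clipped to [0, ndb], with a further clip onto the
feasible set 8·ndb − 2·nmidb ≤ 6(cl − 4) that keeps every resonance
amplitude non-negative; clipping is flagged rather than enforced inside
the linear solve, so the subproblem stays exact and constraint activity
observable. F = |A₀|·Σα(ndb, nmidb). Voxels whose peak magnitude falls
below 5% of the image peak are marked invalid (NaN plus a validity mask).
Fitting is voxel-wise independent, complex-valued throughout, and
deterministic; R2* is estimated jointly with ψ rather than sequentially,
and W and F carry independent phases (both points are open in the source
description; joint complex fitting is the simplest self-consistent
choice).

Noiseless identifiability: on phantoms the fit recovers all six
parameters to ~1e−13 relative; the test suite asserts 1e−6. Precision
under noise is acquisition-limited: at SNR 50 (noise σ per real channel =
peak magnitude / 50), 12 echoes and fat fraction 0.95, the Cramér–Rao
bound for the median absolute per-voxel error is ≈ 0.12 for ndb and
≈ 0.14 for nmidb, and the estimator sits at that bound (measured ≈ 0.12
and ≈ 0.13). Per-voxel maps are therefore noisy in ndb/nmidb at realistic
SNR; depot summaries average over ROIs of hundreds of voxels, which is
where the method's statistical power comes from.

## Derived maps and ROIs

fSFA = 1 − (ndb − nmidb)/3, fMUFA = (ndb − 2·nmidb)/3, fPUFA = nmidb/3
(valid under the at-most-two-double-bonds assumption; raw values outside
[0, 1] are clipped and flagged). Fractions are computed voxel-wise and
averaged over ROIs; because the formulas are linear this equals applying
them to ROI-mean ndb/nmidb, asserted in the tests. Fat fraction is
F/(W+F) on magnitudes; T2* = 1/R2* with an infinity sentinel at R2* = 0.

Segmentation conventions: subcutaneous fat is the 4-connected component
of voxels with FF ≥ 0.5 (configurable) grown from a seed in the
subcutaneous ring; the visceral depot is the manually drawn cavity
polygon minus the subcutaneous mask, with pixel-centre, half-open,
even-odd rasterisation in 0-based (row, col) index space; the
deep/superficial split uses only the lower (posterior, supine) half of
the image rows, classifying voxels above the fascia polyline as deep.
Analysis ROIs apply strict thresholds FF > 0.9 and T2* > 20 ms, plus an
upper FF cap of 1.1 that is inert for magnitude-derived fractions and
kept only as a numerical guard. ROI voxels are pooled per depot across
slices into one ROI per subject.

## Synthetic data

The phantom emulates one axial abdominal slice on a 96 × 128 grid (here
down-scaled versions are used in tests; sizes are stated in each test):
an elliptical body with a subcutaneous fat ring (default FF 0.95,
ndb 2.40, nmidb 0.36, R2* 35 s⁻¹), a lean cavity (FF 0.10), a circular
visceral depot (FF 0.93, R2* 40 s⁻¹) and a posterior spine wedge excluded
from the visceral label; a smooth quadratic field map (tens of Hz); and
i.i.d. complex Gaussian noise with σ = peak magnitude / SNR per real
channel (default SNR 50). Tissue values are homogeneous within a region.
The phantom does not emulate organs, bone marrow, k-space effects,
motion, coil combination or the left–right readout-direction artifact
seen in vivo, so passing round-trip tests demonstrates correctness of the
estimator under the model, not robustness to un-modelled physics.

Cohorts draw per-subject, per-depot (ndb, nmidb) from group-level
independent normals matched by median and IQR (σ = IQR/1.349) to the
reference two-group study (group sizes 23 and 15), rejection-truncated to
0 ≤ nmidb ≤ ndb with non-negative amplitudes; truncation shifts the
sample medians by ≪ 0.01 at the default spreads. Per-subject substreams
derive from the master seed by integer counter, so cohorts are
reproducible bit for bit across platforms.

## Statistics

Group contrasts use the two-sided Wilcoxon rank-sum test, within-group
depot contrasts (SAT vs VAT, sSAT vs dSAT) the two-sided Wilcoxon
signed-rank test on pairwise-complete subjects; zero differences are
dropped. Combined samples of at most 12 without ties use the exact null
distribution, larger or tied samples the normal approximation with tie
and continuity corrections; the method used is reported per comparison.
Summaries are medians with linear-interpolation quartiles; the group
difference column is the difference of group medians. p-values are
reported raw — no multiple-testing adjustment is applied, and the output
schema deliberately carries no adjusted-p column. Type-I error of the
rank-sum path is verified by simulation to sit at 5% ± 2% for
n = 23 vs 15.

## Numerical and design notes

- Determinism: identical input and configuration give bit-identical
  outputs; all randomness flows from integer seeds.
- Degenerate inputs: all-zero images yield empty (all-invalid) maps;
  noise-only voxels fit without error and are flagged by magnitude
  thresholding; |A₀| at numerical-noise scale yields a fat-free estimate
  instead of a division.
- Echo times are uniform by default (monopolar readout); arbitrary
  strictly increasing echo-time vectors are accepted, in which case no
  field-map folding is applied.
- NIfTI is used for all raster I/O (complex data as a real/imag pair in a
  5-D volume with a JSON echo-time sidecar); DICOM ingestion is out of
  scope. Every output embeds a SHA-256 hash of the producing
  configuration.
- Configuration is validated before any computation; unknown keys are
  rejected. Validation uses plain dataclasses with explicit invariant
  checks.
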