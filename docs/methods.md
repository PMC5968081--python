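# Methods

This note documents the models implemented by `hippodmri`, the scenario
choices behind its synthetic phantom, and the numerical decisions that a
user extending or auditing the package should know about.

## Acquisition calibration

The PGSE b value uses the rectangular-pulse approximation
b = (γGδ)²(Δ − δ/3) = q²τ, with γ = 2.6752218744×10⁸ rad s⁻¹ T⁻¹ (water
proton; overridable) and SI-to-conventional conversion to s/mm². No
trapezoid or ramp correction is applied; consequently, inverting the formula
for the three-shell timings (δ = 4.3 ms, Δ = 14.4 ms, b = 4500 s/mm²) gives
G ≈ 512 mT/m. Hardware-effective gradient definitions can differ from this
by a constant factor, and the package makes no attempt to model them.

The usable-protocol bounds split a total signal floor F (default 0.05)
equally over the relaxation and diffusion decays: TE_max = −T2·ln√F and
b_max = −ln√F / D. Reported integers follow the protocol convention of
rounding TE to the nearest ms and flooring b. For the study conditions
(T2 = 46 ms grey matter, D = 0.16×10⁻³ mm²/s) these are 69 ms and
9361 s/mm². The product identity e^(−TE_max/T2)·e^(−b_max·D) = F holds to
1e−9 and is property-tested.

## T2 relaxometry and inter-shell compensation

The mono-exponential fit excludes (rather than clamps) nonpositive samples
before the log-linear initialization — unbiased at high SNR and the only
option that keeps the log defined. A voxel is invalid when fewer than two
usable echoes remain or when the decay rate estimate is nonpositive or
implies T2 beyond 50× the echo-time range (a non-decaying voxel has an
unbounded T2; reporting a finite huge number would be misleading).
Refinement uses Levenberg–Marquardt on the exponential model.

Histogram modes use a Gaussian KDE with Silverman's bandwidth on a 512-point
grid; modes are local density maxima (two-point plateaus from symmetric
samples are collapsed to one mode). A KDE mode is a far noisier estimator
than a sample mean: across seeds, the mode of a unimodal Gaussian sample of
n = 20000 deviates by up to ≈ 0.15 SD, which is the basis of the 0.2 SD
test bound. Well-separated bimodal T2 samples (36.3/46.4 ms components,
SD 1.5 ms) are resolved to better than ±1 ms.

Compensation multiplies all volumes of a shell by e^(+ΔTE/T2(v)), ΔTE being
the shell's echo-time excess over the lowest-TE (b = 4500) shell. On a
noiseless simulation this inverts the applied T2 weighting exactly; voxels
with invalid T2 are left unchanged and keep their flag.

## Local models

DTI uses weighted linear least squares on the log signal with one
reweighting pass (weights = squared predicted signal), per-voxel exclusion
of nonpositive samples, and a 7-usable-measurement validity threshold.
Eigenvalues are clamped to ≥ 0 at metric time with clamp events logged.
FA/MD use the standard invariant forms; the color-encoded direction map is
|e1|·FA per channel (x→red, y→green, z→blue).

The analytical Q-ball implementation follows the original Funk–Radon
formulation: real symmetric spherical harmonics (even degrees, ascending l
then m; m<0 ↦ √2·Re Y_l^|m|, m=0 ↦ Y_l⁰, m>0 ↦ √2·Im Y_l^m), signal
coefficients c = (BᵀB + λL)⁻¹Bᵀs with L = diag((l(l+1))²) and λ = 0.006,
ODF coefficients 2π·P_l(0)·c_l, scaled so the ODF integrates to 1. With
λ = 0 an order-8 band-limited signal is reproduced to 1e−9
(interpolation exactness), and the reconstruction is rotation-equivariant
within tessellation resolution.

Peak extraction evaluates the ODF on an antipodally symmetric icosphere
(2562 vertices) and takes strict local maxima over the neighbor graph. The
relative threshold applies to baseline-subtracted amplitudes: at ex vivo
contrast the Funk–Radon ODF rides on a large orientation-independent
baseline, so raw-amplitude ratios are always ≈ 1 and lobe height above the
per-voxel minimum is the discriminating quantity. Greedy selection enforces
a 25° minimum separation, merges antipodes, and returns at most 3 peaks.

Angular resolution is contrast-limited, not implementation-limited: by the
exact (truncation-free) Funk–Radon integral, two equal sticks 60° apart
merge into a single bisector peak when b·d ≲ 2. At the grey-matter contrast
of this protocol (b·d∥ = 4500 × 0.16×10⁻³ = 0.72) a 60° crossing is
therefore unresolvable in principle, while 90° still resolves. The crossing
validation scenarios use a white-matter-like stick diffusivity of
1.0×10⁻³ mm²/s (b·d = 4.5) on the 500-direction b = 4500 scheme, where the
order-8 reconstruction recovers both 90° and 60° crossings within 10°.

## Four-compartment ex vivo NODDI

Nested parametrization (f_iso, f'_stat, f*_ic) with global fractions
f_stat = (1−f_iso)f'_stat, f_ic = (1−f_iso)(1−f'_stat)f*_ic,
f_ec = (1−f_iso)(1−f'_stat)(1−f*_ic); closure to 1 is exact by
construction and asserted to 1e−12. Orientation dispersion uses the Watson
distribution with ODI = (2/π)·arctan(1/κ); maps are stored as ODI.

The Watson-stick kernel ∫W(u)·e^(−b·d∥(gᵀu)²)du is computed without
sampling: the exponent is a rank-2 quadratic form κμμᵀ − b·d∥·ggᵀ whose
eigenvalues come from a closed-form 2×2 problem; the sphere integral of
e^(uᵀAu) is then evaluated with the azimuthal part integrated exactly
(Bessel I₀, via the exponentially scaled i0e for stability) and 64-point
Gauss–Legendre quadrature over the polar angle. This matches a 10⁶-sample
Monte-Carlo rejection oracle to ≲ 1e−3 relative and reaches the κ→∞ stick
and κ=0 isotropic limits. The extra-cellular tensor is the standard
dispersion-averaged cylindrical tensor with tortuosity d⊥ = d∥(1 − f*_ic)
and orientation moment τ₁ = E[(uᵀμ)²] from the same quadrature. Kernels
are diffusion-time independent (Gaussian compartments); only b enters.

Fitting is voxelwise with no spatial coupling: S0 = mean b = 0 signal,
attenuations formed by division; μ initialized from the DTI principal
eigenvector; a coarse grid over (f_iso, f'_stat, f*_ic) ∈ {0, 0.1, …, 1}³
× ODI ∈ {0.04, 0.16, 0.36, 0.64, 0.84} (precomputed kernels make this
cheap) selects the sum-of-squares optimum; bounded trust-region-reflective
least squares then refines all six values (three fractions, ODI, two
spherical angles), with diagnostics (residual norm, evaluations,
convergence flag) stored per voxel. Optimizer failures fall back to the
grid optimum and are flagged. Single-shell input triggers an explicit
warning: the isotropic and stationary fractions are then poorly identified.

Noiseless recovery on the three-shell protocol is numerically exact
(validated over a 3⁴ ground-truth grid × 5 orientations, 405 voxels: max
fraction error < 1e−3, orientation < 0.1°). Under the measured shell SNRs
(9.9/7.6/4.2, Rician), the attainable voxelwise precision is limited by a
flat likelihood valley: at b·d∥ = 0.72–1.6 the stick, tortuous-tensor, and
stationary kernels are only weakly distinguishable, and a Monte-Carlo pilot
(fits reaching lower residual than the ground truth, so the limitation is
statistical, not algorithmic) gives a median |f̂_ic − f_ic| ≈ 0.15, scaling
to 0.1 only near SNR 50. The noisy-recovery regression test therefore
asserts the pilot-derived 0.2 bound; per-shell SNR weighting was evaluated
and improves the median only to ≈ 0.13, so the simpler unweighted objective
is kept.

## Tractography

Both trackers step bidirectionally at 70 µm with candidate directions
restricted to a 30° half-angle cone around the incoming direction and an
inertial blend dir ← normalize(0.3·incoming + 0.7·chosen) (the
"regularized" low-pass; weight exposed in the config). SRD takes the
highest-amplitude admissible candidate; SRP samples candidates with
probability proportional to the min–max normalized ODF amplitude. The
normalization matters: the raw ODF's isotropic baseline carries no
orientation information, and sampling it would turn tracking into an
undirected random walk. Tensor fields expose a single candidate axis
(principal eigenvector) with FA as its amplitude. SH coefficients / tensor
components are interpolated trilinearly (continuity of the direction
field); peaks are never interpolated. Streamlines terminate on mask exit,
absence of admissible candidates above the 0.1 relative amplitude cutoff,
or the 100 mm cap (half per direction); those outside 0.5–100 mm are
discarded. SRP derives one RNG substream per seed from (seed of run, seed
index), making tractograms bit-reproducible.

## Connectomics

A streamline increments exactly one cell, chosen by its two endpoint voxel
labels (strict containment, no search radius); same-label or unlabeled
endpoints contribute nothing, making the matrix symmetric with a zero
diagonal by construction (asserted on every build). Streamlines traversing
more than two labels still count only their endpoint pair — the
conservative reading of counting "connections linking" two regions.
Length normalization (division by log mean streamline length per cell) is
implemented but off by default: a small, internally connected structure
with short fibers does not need the short-fiber overweighting correction
used in whole-brain studies. Bundle filtering keeps streamlines with one
endpoint in the start set and the other in the end set, traversing every
waypoint set and no exclusion voxel; it is idempotent.

## The phantom

The phantom is a stylized layered slab sharing the study's salient features
— not an anatomically faithful hippocampus. Its 24×24×48 voxel grid at
0.3 mm carries a 1-voxel free-water rim (f_iso = 1), and an interior
partitioned along the long (z) axis into head/body/tail and along y into
laminar compartments: a coherent white sheet (f*_ic 0.6, ODI 0.04, fibers
along z; split into alveus/fimbria in body and tail), a pyramidal-like
layer (f*_ic 0.1, f'_stat 0.4, the stationary-rich low-density layer), a
moderate CA2/CA3 band containing a 90° two-population crossing block
(weights 0.55/0.45 so the DTI principal direction there is deterministic),
a strongly dispersed molecular-like layer (f*_ic 0.3, ODI 0.6), dentate-
and subicular-like bands, with the full 22-region subfield legend reused so
downstream connectomics code paths run unchanged. Layer values are scenario
choices, not measured values. Grey-matter labels carry a linear
anterior→posterior f*_ic gradient (default 0.02 per mm; positive slope
means the anterior end is denser). T2 is bimodal by tissue class
(36.3 ms white / 46.4 ms grey, 1.5 ms within-class jitter; 200 ms rim).

Acquisition simulation uses the same four-compartment forward model as the
fitter (two-population voxels superpose attenuations linearly by weight),
optional per-volume e^(−TE/T2) weighting, and Rician noise with per-shell
σ = (shell's own mean b = 0 signal)/SNR, the default SNRs being the
measured 9.9/7.6/4.2. What the phantom does not emulate: anatomically
curved geometry, susceptibility/eddy distortions (the PGSE data are
distortion-free), partial-volume mixtures beyond two populations, spatially
correlated noise, and B1 inhomogeneity. Passing recovery tests therefore
demonstrate correctness of the estimation chain under the model's own
assumptions, not robustness to out-of-model effects in real tissue.

Separate stick-only phantoms (straight 10×10×40 bundle; two orthogonal
bars crossing at the center) with the white-matter-like d = 1.0×10⁻³ mm²/s
drive the tractography validation: ≥95% of SRP streamlines seeded centrally
in the straight bundle connect its end faces; seeded in the crossing block,
Q-ball SRP reaches both arms while DTI-based tracking loses the
non-dominant one.

## Problem sizes and defaults

Validation runs use 405 noiseless + 200 noisy voxels for the NODDI loop,
500-direction single-voxel reconstructions for crossing resolution, a
10×24×18 phantom for the relaxometry round trip, and a few hundred
streamlines per tracking scenario; these sizes make the full suite run in
a couple of minutes on one CPU while leaving every statistical conclusion
unchanged at larger n (the pilot scans above were run at several sizes).

## Known limitations

- The aQBI variant is the original Funk–Radon ODF, not the solid-angle
  variant; at low b·d the ODF baseline is large.
- Voxelwise NODDI at the study SNRs has the f_ic precision floor described
  above; spatially regularized or dictionary-based fitting would improve
  it but is out of scope.
- The tracker interprets "maximum solid angle 30°" as a 30° half-angle
  cone, and implements "regularized" streamlining as an inertial low-pass;
  the cited algorithm's exact regularizer is not public.
- Endpoint labelling uses strict voxel containment; no endpoint dilation.
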