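# Methods

## Forward model (the digital phantom)

The phantom inverts the reconstruction chain on a single transverse slice.
A circular "spinal canal" of radius R (default 2.35 mm) is placed in a
64 × 64 grid of 0.47 × 0.47 mm voxels (slice 3.1 mm). The true velocity
field is separable,

    v(x, y, k) = p(r) · c(k),

with a spatial profile p(r) that is either *plug* (1 inside the lumen) or
*parabolic* (Poiseuille-like, 1 − (r/R)², the default — no measured profile
is available for this geometry, and a blunted laminar profile is the
standard assumption for slow oscillatory CSF flow), and a centreline time
course c(k) built from harmonics A·sin(2π f k/N + φ₀) of the cardiac cycle
(frequency 0 encodes the DC mean-flow term). The acquisition defaults are
VENC 10 cm/s, N = 40 cardiac phases, 453 ms nominal cycle; cardiac phases
are uniformly spaced samples of one cycle (retrospective gating;
within-scan R–R variability is not modelled).

The default waveform is DC + three harmonics whose coefficients were
calibrated **once, offline** so that the ROI-integrated flow of the default
phantom reproduces the canonical cervical-canal profile: caudal lobe
90 mm³/s × phase, cranial lobe 225 (net 135), with the caudal→cranial
reversal at fractional phase 6.5 of 40. The frozen constants live in
`phantom.DEFAULT_HARMONICS`; nothing is fitted at run time. Peak
centreline velocity is ≈ 0.15 cm/s, far below VENC, so the default phantom
never aliases; aliasing studies pass explicit high-amplitude harmonics.

Corruption terms: a static background phase b(x, y) = b₀ + r_x·x + r_y·y
(rad; an eddy-current-like offset plus in-plane ramp), additive Gaussian
phase noise (SD in rad), and Rician magnitude noise (Gaussian noise on the
two complex channels of a bright-lumen/dim-tissue magnitude image). The
emitted phase is wrap(π v/VENC + b + noise) with wrap to the half-open
interval [−π, π); +π maps to −π, matching two's-complement scanner
storage, so v = +VENC encodes as −π. Ground truth carries the noiseless
velocity field, its ROI-integrated waveform (exactly the mask-summed,
area-scaled field) and the six metric values.

No k-space or sequence-level simulation is attempted (no gradient-echo
signal model, no Maxwell terms, no eddy-current fields beyond the linear
ramp); the phantom models the *reconstructed* image pair, which is what the
pipeline consumes.

## Reconstruction

1. **Temporal unwrapping.** Per voxel, successive differences along the
   cardiac-phase axis are re-wrapped into (−π, π] and cumulatively summed
   from an anchor sample (default phase 0) that is assumed unaliased; the
   anchor is configurable for waveforms that start near peak systole. The
   choice of *temporal* rather than spatial unwrapping reflects the
   geometry: the flow region is a few voxels wide but the time series is
   smooth, so aliasing appears as >π inter-phase jumps. Voxels whose
   unwrapped peak-to-peak excursion exceeds 4π (configurable) are flagged
   unreliable and reported via a warning — never silently altered. The
   operation is idempotent on smooth series and only ever changes values by
   multiples of 2π.
2. **Decoding.** v = φ·VENC/π, elementwise (linear, sign-preserving).
3. **Background correction.** A polynomial in voxel indices — order 1
   (plane) by default, order 0 and 2 available — is least-squares fitted to
   the *time-averaged* velocity over a static-tissue mask and subtracted
   from every cardiac phase. Correction happens on velocity (after
   unwrapping), not on phase, so the fitted surface has physical units and
   aliased voxels have already been repaired. The static mask is
   user-supplied or auto-derived (velocity temporal SD below the 25th
   percentile, magnitude above its median) — the auto mask may legitimately
   include canal-rim voxels whose parabolic-profile velocity is ~0.

On noiseless phantoms the full chain reproduces ground-truth metrics to
~1e-16 relative; with 1.5 × VENC aliasing plus an injected background plane
it stays at machine precision after unwrapping and plane subtraction
(validated in the acceptance suite at 1e-9 / 1e-6 tolerances).

## Flow metrics

q[k] = Σ_voxels v·10·A_vox (per-voxel summation, robust to partial-lumen
masks). The six metrics are defined as the minimal set consistent with
their names: cranial/caudal volumes are the positive/negative phase-sums,
net = cranial − caudal, absolute = cranial + caudal, amplitude is
peak-to-peak max(q) − min(q) (no harmonic fit is assumed), and peak is
max |q| regardless of direction (a flag restricts it to the cranial lobe).
Volume metrics are reported both as raw phase-sums (mm³/s × cardiac phase,
the conventional unit for gated reporting) and as time-integrated volumes
(× dt in s → mm³), because published values do not always state which
convention they use. Note that peak ≤ amplitude only holds for waveforms
spanning zero (a constant waveform has amplitude 0); amplitude ≤ 2·peak
holds always. No temporal smoothing is applied by default; an optional
cyclic moving average (window 3) exists behind a flag and is off in all
validation runs. Flow reversals are located as sign changes between
cyclically adjacent phases with linear interpolation of the fractional
crossing.

## Synthetic cohort

The generator emulates a small aging-primate cohort: age ~ Uniform(10, 27)
years; a latent flow variable L = b₀ + β_age·age + ε_L; six metric columns
as affine transforms of L with small independent measurement noise (caudal
volume decreasing in L, the others increasing; net and absolute stroke are
derived as cranial ∓ caudal so the row-wise identities hold); a CSF
Aβ42/40 ratio with a direct age effect plus an effect of ε_L — the
age-*independent* component of flow, which is exactly what a partial
correlation on age should recover; Aβ40 independent of age and flow, with
Aβ42 = ratio × Aβ40; and null biomarkers independent of flow given age.
CSF nulls (pTau181, NfL, GFAP) keep realistic age trends; plasma analogues
carry *no* age trend, because any age slope would leak a marginal
plasma–flow correlation through the shared age pathway, whereas the
emulated panel is marginally null.

Calibration is analytic and happens before any data are drawn. Targets are
population Spearman values (defaults: ρ(age, flow) = −0.75, age-adjusted
ρ(flow, ratio) = +0.70, ρ(age, ratio) = −0.50). For the age–flow link the
noise SD is solved from the exact population Spearman of a linear model
with a uniform regressor, ρ_S = 6·P[(X₁−X₂)(Y₁−Y₃) > 0] − 3 reduced to a
2-D quadrature (the Gaussian-copula formula is noticeably biased when the
regressor is uniform); for the Gaussian residual pair (flow residual,
ratio) the copula conversion ρ_P = 2 sin(π ρ_S/6) is used. Setting any
slope or noise field explicitly (e.g. `beta_flow_ratio = 0` for null
experiments) overrides the target-derived value. Monte-Carlo checks at
n = 5000 recover the targets within ±0.03; at n = 16 over 500 replicates
the qualitative pattern (sign of every age–metric and metric–ratio cell,
non-significance of every plasma cell) is recovered in ≥ 90% of replicates
per cell.

What the generator does **not** emulate: partial-volume and segmentation
error at the canal boundary, biomarker assay batch effects, non-uniform
age sampling, and any nonlinearity in the age–flow relationship. Passing
tests therefore demonstrate correctness of the computations and
calibration of the statistics under this idealised data-generating process,
not robustness to those real-data effects.

## Statistics

Spearman ρ is the Pearson correlation of mid-ranks (average ties);
p-values use the t approximation t = r√((n−2)/(1−r²)) — the conventional
choice at n ≈ 16 — with an exact-permutation option (full enumeration) for
n ≤ 8. Pairwise/triple-wise complete-case deletion throughout; any cell
with fewer than 4 complete cases is reported missing, never zero, and
n_used is always recorded. Significance is p < 0.05 two-sided, uncorrected
by default (Benjamini–Hochberg available but off).

Partial correlation is computed by **both** routes — the closed form and
the correlation of OLS residuals on the control — and the two are asserted
to agree within 1e-10 on every call; df = n − 3. Collinearity with the
control (|r| = 1) is reported as undefined, not as a number.

Residualization regresses the biomarker on [1, age, e] where e is the
age-residualized metric, reporting e's slope, SE, t and p on n − 3 df.
Because e ⊥ age, this slope equals the metric's multiple-regression
coefficient (Frisch–Waugh) and its t-statistic is algebraically identical
to the Pearson partial-correlation t — the reason partial-correlation and
residualization columns print identical p-values on the same data. A
two-stage variant that drops age from stage 2 (df = n − 2) would break
this identity whenever the biomarker loads on age; retaining age is
therefore the package's convention, verified numerically to 1e-8 over
random tables. In the assembled report the age-adjusted table uses Pearson
(raw-scale slopes, mirroring an `lm` on raw data) while the correlation
matrix defaults to Spearman; both are switchable.

Under a Gaussian null at n = 16 the Pearson partial-correlation test's
type-I error is 0.05 within Monte-Carlo error (5000 replicates in the
acceptance suite).

## Noise-bias characterisation

At a waveform signal-to-noise ratio of 5 (phase-noise SD chosen so that
the ROI-summed flow noise SD is one fifth of the true peak flow; for the
default 80-voxel phantom this is ≈ 0.04 rad), 100 noise realisations show
the absolute stroke volume biased upward by rectification of noise at
near-zero-flow phases (≈ +7 on a true 315, several SEM above zero), while
the net stroke volume is unbiased but with an SD of ≈ 16 phase-sum units —
quantifying why net stroke is the least reliable of the six metrics in
low-SNR acquisitions.

## Validation problem sizes

The acceptance experiments use: 10⁵ velocities for the encode/decode
round-trip; 64 × 64 × 40 phantoms for recovery checks; 1000 random
waveforms for metric identities; 100 random n = 16 tables for the
route-equivalence and twin-t checks; 5000 Monte-Carlo replicates for
type-I calibration; one n = 5000 cohort plus 500 n = 16 cohorts for
parameter and sign-pattern recovery; and 100 noise seeds for the SNR-5
bias study. These sizes make every experiment reproducible in seconds on a
single core while keeping Monte-Carlo error well inside the asserted
bands.

## Files and interfaces

Image series travel as 4-D NIfTI (x, y, 1, cardiac-phase) with voxel
geometry in the header; NIfTI has no cardiac-phase semantics, so cycle
duration lives in the YAML config and JSON sidecars. Phase files may be
floating-point radians or scanner-style integers mapped linearly onto
[−π, π). Header/config geometry disagreements warn and the config wins.
Every pipeline run writes a manifest (config echo, SHA-256 checksums,
stage timings, collected warnings); analytic outputs are byte-reproducible
from config + seed. DICOM ingestion and scanner integration are out of
scope.
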