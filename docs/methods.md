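# Methods

This note documents the models, estimators, and numerical choices behind
`oxibold`, and what the synthetic study does and does not demonstrate.

## The measurement problem

Oxygen extraction fraction (OEF) and the cerebral metabolic rate of oxygen
(CMRO2) vary regionally and with age. The constrained qBOLD approach infers
voxelwise venous oxygen saturation Yv from the reversible transverse
relaxation signature of deoxyhemoglobin in a multi-echo steady-state
acquisition, stabilized by independently measured priors, and combines the
resulting OEF with an arterial-spin-labeling CBF map through Fick's
principle:

    CMRO2 = CBF · Ca · SaO2 · OEF,     Ca = Hct · C_rbc

with C_rbc = 19.93 µmol O2/mL, SaO2 = 0.98, hematocrit a per-subject scalar
(finger-prick measurement in practice), and OEF = (SaO2 − Yv)/SaO2 so that
Ca·SaO2·OEF is the arteriovenous oxygen content difference.

## Forward model

The acquisition alternates SSFP-FID and SSFP-ECHO multi-echo components
(defaults: 17 echoes, 1.5 ms spacing, first TEs 1.6/2.2 ms, TR 30 ms). In
the static dephasing regime the extravascular signal around randomly
oriented venous vessels decays reversibly as exp(−DBV·fc(δω·t)), with

    fc(x) = (1/3) ∫₀¹ (2+u)·√(1−u)·(1 − J0(1.5·x·u))/u² du
    δω = (4π/3)·γ·B0·Δχ_do·Hct·(1−Yv)

fc is quadratic (0.3 x²) at short times and rises with unit slope
asymptotically, so the late-time reversible rate is DBV·δω. The full per-voxel
magnitudes are

    FID(t)  = A_F·exp(−R2·t)·exp(−DBV·fc(δω·t))·exp(−R2'nh·t)
    ECHO(t) = A_E·exp(−R2·t)·exp(−DBV·fc(δω·(TR−t)))·exp(−R2'nh·(TR−t))

The echo component refocuses at TR, reproducing the effective decay rates
R2 + R2' (FID) and R2 − R2' (ECHO) with R2' = DBV·δω + R2'nh. A_F and A_E are
free per-voxel scales: the SSFP steady-state amplitude model (flip-angle and
T1 dependence) is deliberately outside the contract, so the simulator and
fitter form an exactly self-consistent pair without it. Phase accrues as
γ·B0·ΔB0·t on the FID (referenced to TR on the ECHO).

Susceptibility bookkeeping uses one convention throughout: the 4π/3 sphere
factor is folded once into the deoxy-blood scale (Δχ_do = 0.27 ppm/Hct, so
the effective scale is 4π/3 · 0.27 ppm). The voxel susceptibility aggregates
four pools:

    Ψ = CBVa·[χ_oxy + Hct·Δχ_eff·(1−SaO2)]
      + CBVv·[χ_oxy + Hct·Δχ_eff·(1−Yv)]
      + (1−CBVa−CBVv)·χ_nb

CBVa is fixed by configuration (default 0.01) and not estimated; the
susceptibility zero reference (water) is a configurable offset.

`fc` is evaluated by adaptive quadrature; values are cached on a dense grid
(801 points on [0, 2], 1400 on [2, 60]) and linearly interpolated, with a
unit-slope extension beyond x = 60. Table-vs-quadrature agreement is better
than 1e−4 relative; the cache is what makes the voxelwise fitter affordable.

## Digital phantom

No real volumes ship with the package; the phantom is the ground-truth
substrate. Geometry is synthetic nested solids — a CSF rind, a cortical
shell partitioned into frontal/parietal/occipital/temporal sectors, a white
matter core, and box-shaped subcortical structures (medial temporal lobe
containing hippocampus and amygdala, thalamus, striatum) — carrying the same
11-region label battery the cohort statistics use. Parameters are piecewise
constant per region (optional multiplicative within-region jitter), with
regional Yv derived from young-adult OEF group means and CBF from the
corresponding perfusion means. The macroscopic background field is a smooth
second-order polynomial (peak 0.05 ppm); the total field adds the dipole
field of the voxelwise Ψ map, so the phase pathway (field map → background
removal → dipole inversion) is exercised end to end.

What the phantom does **not** emulate: realistic anatomy, partial-volume
mixtures at boundaries, motion/physiological artifacts, k-space effects,
diffusion narrowing, intravascular signal. Recovery results on the phantom
demonstrate estimator correctness under the model, not robustness to these
real-data effects.

Noise is additive circularly-symmetric complex Gaussian, per-quadrature
standard deviation `noise_sd`, seeded and bit-reproducible. "SNR 100" in the
tests means A_F/σ = 100 on the AUSFIDE data; the labeling scans use smaller
noise (VS-VSL 0.2, pCASL 0.5 on a 100-scale M0), chosen as representative of
averaged difference images.

## Prior estimation

* **R2/R2'/R2\***: per-voxel log-linear fits of |FID| and |ECHO| vs TE with
  |S|¹ weights; R2 = (rate_FID + rate_ECHO)/2, R2' = (rate_FID − rate_ECHO)/2.
  Magnitude weighting down-weights noisy late echoes without concentrating
  all leverage on the earliest echoes, where fc curvature biases a
  monoexponential fit most; the residual R2' prior bias is ~9–12 % low for
  physiological δω, which is exactly the curvature the constrained fit
  corrects. Negative R2' is clipped to zero with a flag, never silently.
* **ΔB0**: temporal phase unwrapping across FID echoes, magnitude²-weighted
  linear fit, slope converted to ppm; voxels whose inter-echo increment
  reaches π are flagged as aliased.
* **Δχ**: polynomial background removal (order 2 by default, matching the
  phantom's polynomial background; pluggable) followed by Tikhonov-regularized
  dipole deconvolution, χ = IFFT[conj(D)·FFT(f)/(D² + reg)] with
  D = 1/3 − kz²/|k|² and the k = 0 term zeroed. Tikhonov inversion of
  compact objects loses the spectral content near the kernel's zero cone
  (~15 % of a uniform sphere's energy), an inherent limitation shared by all
  closed-form QSM; streak-suppressed iterative QSM is out of scope.
* **CBVv**: (control − tag)/(2·κ·M0b) with κ = exp(−TI/T1b). The
  velocity-selective labeling signal model is this self-consistent pair; the
  sequence-level model is not reproduced.
* **CBF**: consensus single-compartment quantification,
  CBF = 6000·λ·ΔM·exp(PLD/T1b)/(2·α·T1b·(1 − exp(−τ/T1b))·M0), defaults
  λ = 0.9 mL/g, T1b = 1.65 s, α = 0.85, τ = 1.8 s, PLD = 2 s. The label
  duration and quantification constants are consensus conventions exposed in
  the configuration (the acquisition protocol pins only PLD and the 6
  control/tag pairs). No partial-volume correction is applied.

## Constrained inversion

Per voxel, Θ = {Yv, DBV, R2'nh, χ_nb} solves a bounded nonlinear least
squares on the stacked residual: the FID/ECHO magnitude misfit, plus
√w·(Δχ_prior − Ψ(Θ)) and √p·(R2'_prior − Y(Θ)) with Y = DBV·δω + R2'nh.
Implementation choices:

* **Variable projection**: A_F, A_E are profiled out by an exact linear
  solve at every iterate, so the search runs over four parameters.
* **Bounds**: Yv ∈ [0.30, 0.98], DBV ∈ [0.001, 0.1], R2'nh ∈ [0, 20] s⁻¹,
  χ_nb ∈ [−0.2, 0.2] ppm (physiological ranges, configurable).
* **Initialization**: DBV⁰ = CBVv prior, R2'nh⁰ = 0.2·R2' prior, Yv⁰ from
  inverting Y at those values, χ_nb⁰ = Δχ prior. Optional multistart over a
  Yv grid keeps the lowest objective (ties broken toward lower DBV, so the
  result is deterministic).
* **Role of CBVv**: venous volume inside Ψ and the DBV initializer; DBV
  itself stays free in the data term and Y (a hard DBV = CBVv switch is
  available).
* **R2**: fixed from its prior during each solve, then refined in up to 4
  outer self-consistency iterations — an exact weighted log-linear
  re-estimate of the common slope of both components once the current
  reversible terms are removed, followed by a warm-restarted solve. The
  refinement contracts at ~0.1/iteration and removes the ~0.2 s⁻¹ curvature
  bias of the monoexponential R2 prior, which would otherwise map to ~3
  percentage points of OEF bias. `refine_r2 = 0` restores a strictly fixed
  R2.
* **Automatic penalty weights** (`w = p = "auto"`): each penalty is first
  balanced so its value at the initializer equals the data term divided by
  the echo count (with characteristic mismatch floors of 0.05 ppm and
  2 s⁻¹ preventing degenerate scaling when the initializer already satisfies
  a penalty); after the first solve the weights are rebalanced against the
  converged per-echo data misfit — effectively the noise level — and the
  solve is repeated once. Noiseless self-consistent data therefore drive the
  penalties to ~0 (no prior-bias leakage), while noisy data keep them at the
  noise scale. Fits on noiseless phantoms recover all four parameters to
  machine precision with exact priors, and OEF to < 0.2 pp end-to-end with
  estimated priors.
* **Magnitude fitting**: the data term uses echo magnitudes; ΔB0 is handled
  in the phase pathway only (an optional through-slab magnitude correction is
  deliberately disabled by default).

### Precision at realistic SNR

The voxelwise OEF precision of this acquisition is intrinsically limited: a
Cramér–Rao analysis of the 34-echo magnitude model at per-echo SNR 100 gives
a lower bound of roughly 10–20 percentage points per voxel even with exact
priors, because the split of R2' into DBV·δω and R2'nh is identified only by
the weak curvature of fc over the echo range. The estimator measures
~16 pp voxelwise RMSE with near-zero bias under those conditions. Usable
precision comes from regional aggregation — a few hundred voxels bring the
ROI mean's standard error below 1 pp — which is exactly how the analysis
battery consumes the maps. Voxelwise maps at this SNR should be read as
noisy estimates to be pooled, not as per-voxel measurements.

## Cohort simulator

One row per subject: age uniform within group ranges (23–35 and 50–87
years), sex Bernoulli (P(male) = 0.735), hematocrit Gaussian (0.436 ± 0.045,
clipped to [0.25, 0.60]). Regional OEF and CBF follow linear-in-age means
anchored at the group reference ages (the range midpoints, so simulated
group means match the configured anchors in expectation) with Gaussian
residuals; the default anchors, residual SDs, and age slopes are the
young/old regional group statistics and regression coefficients of the
source study (whole-brain OEF slope +0.150 %/year, CBF −0.207
mL/100 g/min/year). CMRO2 is always computed from the subject's own CBF,
Hct, and OEF via Fick — never drawn independently — so simulated CMRO2 group
means are a consequence of the other draws rather than separately matched
targets. Hemispheric values are exactly symmetric by default (LI = 0), with
configurable fractional asymmetry offsets; published laterality indices
derive from unavailable subject-level data and are not baked into defaults.
CSF volume (needed for ICV) is not tabulated in the source; defaults
(280 ± 40 / 340 ± 55 mL young/old) were chosen once as physiologically
plausible for ICV ≈ 1.4–1.5 L with age-related CSF expansion.

Because the group anchors are configured independently of the slopes, the
default cohort's full-age-range regression estimand differs slightly from
the configured slope (the between-group offset is not exactly on the
within-group line). `consistent_anchor_config` places the old anchors
exactly on the young line extended by the slope; generative-recovery and
CI-coverage checks use that variant so the estimand equals the configured
value.

## Statistics battery

* **ROI summaries**: within each ROI, values are filtered to finite,
  strictly positive ("physiologically plausible"), then trimmed to the
  within-ROI [P5, P95] interval using linear-interpolation percentiles
  (Hyndman–Fan type 7) with inclusive retention at both bounds; 90 of 100
  distinct values survive.
* **Group comparisons**: Shapiro–Wilk at α = 0.05 per group gates a
  two-sided equal-variance Student t-test (not Welch — matching the study's
  stated test; Welch available) vs a Mann–Whitney U with the normal
  approximation and tie correction. Degenerate zero-variance comparisons
  return p = 1 with a flag.
* **Region vs whole brain**: paired t vs Wilcoxon signed-rank (zeros
  dropped) on d = region − global, with Cohen's dz = mean(d)/sd(d).
* **FDR**: Benjamini–Hochberg step-up, implemented directly and tested
  against an O(m²) brute-force oracle. The correction family is the 11
  regions within one metric within one table (m = 11), the family size that
  reproduces the study's worked q-values (0.121, 0.425, 0.222); the family
  for the regression table is configurable because the published regression
  q-values imply a smaller family that the study does not specify.
* **Regression**: OLS of metric on age, sex (male = 1, female = 0), and
  ICV-normalized volume (the region's own volume where simulated, otherwise
  whole-brain), with t-based 95 % CIs, standardized coefficients, residual
  normality and Breusch–Pagan diagnostics, and a condition-number guard
  (> 1e8 → error naming the covariates).
* **Volumetrics**: ICV = GM + WM + CSF; volumes as %ICV; GM/WB and WM/WB
  with WB = GM + WM. (Published whole-brain volume exceeds GM + WM,
  implying unlisted tissue in that definition; the phantom defines
  WB = GM + WM and documents the difference here.)
* **Laterality**: LI = (R − L)/(R + L) per subject, one-sample t or Wilcoxon
  against zero, Cohen's dz; subjects with R + L = 0 are excluded and counted.
* **Sex balance**: Pearson chi-square without continuity correction
  (df = 1); the worked sex table gives χ² = 0.001, p = 0.982, confirming
  the no-correction convention.
* **"<0.001" printed p-values** are treated as the 0.001 upper bound when
  used as inputs to FDR worked examples.

## Workflow

Internal units are seconds, s⁻¹, tesla, ppm, and fractions; percent appears
only at reporting boundaries. Volumes are NIfTI-1 (complex series as
magnitude/phase pairs), tables TSV, configuration TOML, reports TSV + JSON.
Every pipeline run writes a provenance file with the resolved configuration
and library versions; stages are resumable from saved artifacts and a rerun
with the same seed reproduces the report byte-identically. The default demo
problem sizes (16³ phantom grids, cohorts of tens to a few hundred subjects,
20-replicate coverage checks) were chosen so the full suite runs comfortably
on a single CPU; all sizes scale through configuration.

## Known limitations

* Voxelwise OEF at realistic SNR is information-limited (see above);
  only ROI-level conclusions should be drawn at SNR ≲ 100.
* Tikhonov dipole inversion underestimates compact sources near the kernel
  cone; the susceptibility prior inherits that bias, which the rebalanced
  penalty weighting keeps out of Yv for well-fit data.
* The phantom's geometric regularity makes background-field removal easier
  than in vivo (polynomial backgrounds by construction).
* No spatial regularization across voxels, no partial-volume modeling, no
  intravascular compartment, no B1/flip-angle dependence of the SSFP
  amplitudes.
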