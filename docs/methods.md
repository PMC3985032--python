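# Methods

## Forward model of the ASL acquisition

A tag/control series is simulated on an (x, y, slice) grid with strictly
alternating labels (control first; 36 control + 36 tag by default,
TR = 4.5 s, TE = 44 ms). The control-frame signal at an in-brain voxel is

    S_control(k) = M0 · (1 + drift_slope·k + bold_amplitude·hrf(t_k)) + ε_k

and tag frames are additionally reduced by ΔM. ΔM is obtained by inverting
the single-compartment quantification equation at the voxel's ground-truth
CBF and its slice's 1-based acquisition index n:

    ΔM = CBF · M0 / [ 6000/(λ·T1) · exp((w + T_slc·(n−1))/T1) · exp(TE/T2) ]

so that quantification recovers the generating CBF *exactly* when noise is
absent. ΔM is a constant offset per tag frame: no transit-time kinetics are
modeled, matching the steady-state assumption of a labeling scheme that tags
immediately adjacent to the imaging slab. Motion is represented only by its
variance effect — designated "spike" frames receive extra zero-mean noise of
SD `spike_sd`; there are no rigid-body transforms, no k-space or
pulse-sequence physics, no slice-timing effects, and no spatial noise
correlations (thermal noise is i.i.d. Gaussian). Consequences for test
interpretation: passing tests demonstrate correctness of the estimation
chain under its own forward model, not robustness to spatially correlated
physiological noise, realignment errors, or partial-volume mixing.

Defaults: M0 = 1000 (arbitrary units), noise_sd = 5 (0.5% of M0, a
realistic ASL SNR regime where ΔM/M0 ≈ 1%), drift_slope = 0 and
bold_amplitude = 0. Drift and BOLD amplitude are exposed for robustness
experiments but default to zero because the four-regressor design contains
no drift column and the analysis of interest is baseline perfusion;
non-zero drift would bias every fit by construction.

`T_slc` (per-slice readout time) defaults to 0.06 s — a typical EPI readout
window divided evenly over six slices; it is not a literature constant and
is exposed in both the acquisition and quantification configs. The two must
agree for exact round trips.

### Masks

Tissue masks are geometric: white matter is a central in-plane disk, gray
matter the surrounding annulus, and the anterior/posterior halves of the
grid define "frontal" and "parietal" subregions. By construction
`gray = frontal_gray ⊔ parietal_gray` and likewise for white, so every
voxel's ground-truth CBF is defined by exactly one leaf region and regional
means are exactly recoverable. Global gray/white ground-truth values are
voxel-count-weighted means of their leaves.

## Synthetic cohort

Ages are drawn from a truncated normal (reject-and-redraw) with mean 69.15,
SD 8.31, range 55–85; n = 41 by default. The generative path structure is

    eCRF_i = 6.80 + a·(age_i − 69.15) + ε_i,            ε ~ N(0, σ_e²)
    CBF_ri = μ_r + b_r·(eCRF_i − mean) + c′_r·(age_i − mean) + η_ri

per leaf region r, with gray regions sharing (b, c′) = (2.24, 0) and white
regions (0, 0) by default — i.e., gray-matter perfusion is fully mediated by
fitness, white matter carries null paths. Baseline perfusion μ_r: 58/62
(frontal/parietal gray) and 23/21 (white), mL/100 g/min.

Fitness covariates (BMI ~ N(26.5, 4²), resting heart rate ~ N(66, 9²),
blood pressures matching an older-adult sample) are drawn independently and
the self-reported activity score is **back-solved** from the eCRF estimating
equation, so the equation reproduces the generative eCRF exactly. The
back-solved score is continuous, not the ordinal categories of the original
self-report instrument — a deliberate divergence, documented here, that
keeps the equation an exact identity on synthetic cohorts. Gender is a
0/1 code (default convention: female = 1, the sex receiving the equation's
+2.77 offset; the published source of the equation does not state the
coding, so it is configurable) and, in the default generator, affects no
other variable; all analyses residualize gender regardless.

### Noise calibration

σ_e = 1.44 and per-leaf-region σ_η = 4.74 are not free knobs but derived
from the reference sample's reported statistics at n = 41:

* with a = −0.08 eCRF/yr and age SD 8.31, σ_e = |a|·σ_age·√(1/r² − 1)
  reproduces an age–eCRF correlation of r ≈ −0.42;
* the total age effect on *global* gray CBF (c = a·b ≈ −0.18 per year) then
  has r ≈ −0.31, i.e. t ≈ −2.0 at n = 41 — a marginal two-tailed p ≈ 0.05,
  the knife-edge regime the reference analysis reports. Global gray CBF
  averages two leaf regions, so per-leaf σ_η = √2 × the implied global
  residual SD (3.35).

These constraints cannot simultaneously match every printed correlation
(the implied eCRF–CBF partial correlation, ≈0.7, is stronger than the
reported ≈0.46; the printed values are mutually over-determined). The
age-path constraints were prioritized because the mediation logic hinges on
them. Volumes are generated as ICV-proportional baselines weakly coupled to
regional CBF (100 mm³ per mL/100 g/min) with 2000 mm³ residual SD, enough
to exercise the ICV-normalization and volume-correlation code paths.

## Estimation chain

**Design.** Columns: canonical double-gamma HRF convolved with the task
blocks (six 18-s breath-holds separated by 36 s of rest, by default absent —
baseline-only analysis); the perfusion waveform coded +0.5 on control and
−0.5 on tag frames; the perfusion waveform gated to task-on frames; and an
all-ones baseline. With ±0.5 coding the perfusion coefficient *is* the
tag-control difference ΔM. Because that makes the baseline coefficient the
tag/control mid-level, the reported M0 map is `baseline + ΔM/2` — the
fitted control-frame (static tissue) level, which is what the
quantification equation's M0 denotes. All-zero columns (no task) are
retained for shape stability and receive zero coefficients; rank deficiency
among non-zero columns is an error.

**rWLS.** Per-frame variance is the mean squared residual over in-brain
voxels at that frame (volume-wise, not voxel-wise); weights are its inverse;
fit–reweight is iterated twice by default (a third pass changes weights
negligibly on simulated data). Weights are reported normalized to mean 1;
WLS is invariant to global weight rescaling. A frame with numerically zero
residual variance would get infinite weight; weights are capped at 1e12 ×
the smallest positive-variance weight with a warning, and a fully constant
(noise-free, zero-perfusion) series falls back to equal weights. Frames are
never deleted — "soft" exclusion only.

**Quantification.** Internal canonical time unit is seconds everywhere
(the printed constants arrive in ms; `cbfmed.config.ms` converts at the
boundary — the 6000 factor presumes min/s consistency, and unit mixing is
the likeliest implementation bug, so it is centralized). Slice index n is
1-based exactly as in the (n−1) decay-correction term; a `slice_order`
permutation maps geometric slices to acquisition order (default ascending).
Voxels with |M0| below 5% of the in-mask median |M0| are set to NaN and
excluded from regional means (the reference analysis does not state its
low-signal handling; this floor is a package default, not a literature
claim). No partial-volume correction and no CBF ceiling are applied.

## Statistics

* **Partial correlation** is computed by residualizing both variables on
  the covariates (OLS with intercept) and correlating residuals, with
  df = n − 2 − k; this equals the closed-form partial-correlation formula
  and is cross-checked against an independent implementation in the tests.
  One-tailed p-values are reported where directional hypotheses exist;
  mediation testing is two-tailed throughout.
* **Mediation** fits the three regressions m~x, y~x, y~x+m. The identity
  c = c′ + a·b holds to machine precision and is asserted. Classification:
  prerequisites are significant a and c; "full" requires b significant and
  c′ non-significant; "partial" keeps c′ significant; "none" otherwise.
  When a bootstrap CI is computed, a significant indirect effect
  additionally requires the CI to exclude zero (combined evidence standard).
  A "marginal" band (0.05 < p ≤ 0.10) is reported in labels only; it never
  affects classification.
* **Bootstrap** resamples subjects (cases, not residuals) with replacement,
  10,000 resamples and a 95% percentile CI by default. The resample core is
  a vectorized closed-form two-predictor OLS, verified against statsmodels.
  Degenerate resamples (zero predictor/mediator variance) are redrawn and
  counted; inputs that are collinear in the original sample raise
  immediately, since every resample would inherit the degeneracy. The
  percentile CI is known to be slightly anticonservative when one path is
  null and the other strong (measured type-I ≈ 6% at nominal 5%, n = 41);
  a bias-corrected variant is deliberately not the default.
* **Outlier exclusion** is a single pass: column means/SDs from the full
  sample, removal if any designated MRI measure deviates by > 3 SD.
* **ICV normalization** subtracts the OLS slope times centered ICV
  (covariance approach), leaving adjusted volumes uncorrelated with ICV.
* **Stratified sensitivity**: the sample is split by gender, then at the
  median age within gender (ties go to the younger stratum); stratum means
  are subtracted and pooled residuals correlated — a regression-free control
  for gender and coarse age.

Degrees of freedom are always computed from the data at hand; no attempt is
made to reproduce any particular historical df bookkeeping.

## Orchestration and reproducibility

`run_study` executes generate → simulate → fit (rWLS) → quantify →
aggregate → exclude outliers → fitness indices → statistics. One study seed
fans out via `numpy.random.SeedSequence` to child seeds for cohort
generation, per-subject imaging, and each bootstrap, so any stage can be
re-run in isolation. The JSON report for a fixed config+seed is
byte-identical across runs (no timestamps inside hashed content); the
config hash and package version are recorded as provenance. Mediation in
the pipeline operates on gender-residualized age/eCRF/CBF (residualized
once, before resampling). Degenerate sub-analyses in extreme configs
(constant white-matter CBF under zero noise, strata too small to center)
degrade to NaN entries or an empty table with a logged warning rather than
failing the study.

Default problem sizes — 32×32×6 voxel grids, 72 frames, 41 subjects,
10,000 resamples; simulation-based checks use 100–500 replicate cohorts at
n = 41–200 with 1,000 resamples — chosen so the full suite runs on a
laptop-class single core in well under a minute while keeping Monte-Carlo
error far below the effect sizes being asserted.

## Known limitations

* The ΔM injection is kinetics-free; multi-delay or transit-time-sensitive
  acquisitions are out of scope.
* No realignment, slice-timing, smoothing, or autocorrelation modeling —
  the simulated data are pre-aligned by construction and the GLM assumes
  white noise.
* The activity score is continuous in synthetic cohorts; applying the
  pipeline to real cohorts with ordinal scores is supported but the
  generator does not emulate the discreteness.
* Mediation here is the classical regression-based kind: no counterfactual
  estimands, no sensitivity analysis for unmeasured confounding, and no
  multiple-testing correction anywhere.
* White-matter "CBF" in real data mixes perfusion with degeneration-related
  signal; the generator's null white-matter paths encode an assumption, not
  a physiological fact.
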