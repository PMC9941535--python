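# Methods

`uafc` implements a resting-state fMRI analysis chain that links a blood
biomarker (serum uric acid, UA) to whole-brain functional hubness, selects
a biomarker-guided connectivity feature set, and predicts a clinical
outcome (the UPDRS-III motor improvement rate after subthalamic deep brain
stimulation) with a support-vector regression. Because no patient data of
this structure are publicly deposited, the package ships a synthetic-cohort
generator with planted, ground-truth-known effects; every stage is
validated by recovering what was planted.

## The analysis chain

1. **QC.** A subject is excluded iff maximum |translation| > 3.0 mm or
   maximum |rotation| > 3.0° across retained frames (strict inequality:
   exactly 3.0 is retained). Subjects whose image grid differs from the
   cohort mode, or with no motion file, are excluded with explicit reason
   codes.
2. **Denoising.** The first 10 of 242 volumes are discarded
   (equilibration). Per subject: 6 mm FWHM mask-normalized Gaussian
   smoothing (σ = FWHM/(2√(2 ln 2)) per axis, in voxel units); linear
   detrend plus ideal 0.01–0.08 Hz band-pass; regression of the Friston-24
   motion expansion ([R_t, R_{t−1}, R_t², R_{t−1}²]) and mean white-matter
   and CSF signals. The band-pass is implemented as one orthogonal
   projection onto span(in-band Fourier components) ∩ {constant, linear
   trend}⊥, which makes it exactly idempotent, annihilates out-of-band
   bins exactly, and leaves zero mean. Confound columns are band-passed
   with the same projection before regression (toggle
   `filter_confounds=False` restores regression on raw confounds); columns
   made exactly collinear by that projection are dropped, which leaves the
   residuals unchanged. Global-signal regression and scrubbing are
   deliberately absent, matching the modeled protocol.
3. **Degree centrality (DC).** Every in-mask voxel is a node; the edge
   weight is the Pearson correlation between voxel time series. Weighted
   DC(i) = Σ_{j≠i} r_ij over r_ij ≥ 0.25 (positive supra-threshold
   correlations only; a binary-degree option exists). The voxel×voxel
   matrix is streamed in row blocks and never materialized; the result is
   block-size-invariant and equal to the dense computation. Maps are
   divided by their in-mask mean, so the normalized map has mean 1.
4. **UA screening.** Serum UA is correlated (Pearson) with ROI-mean
   normalized DC over the PD group, one test per effective atlas region.
   Default selection is **uncorrected p < 0.05**; a BH-FDR mode exists
   (`screening_correction="bh"`). The uncorrected default is deliberate:
   screening is exploratory feature reduction, and the reference
   screening table's largest selected p (0.049) could not survive BH
   across 164 regions. Every report prints which mode was used.
5. **Edge selection.** Mean BOLD time series per screened ROI → pairwise
   Pearson r → Fisher z (arctanh, |r| clipped at 1−1e−12 with a warning,
   diagonal fixed at 0). Each lower-triangle edge is compared between
   PD and HC with a pooled-variance Student t (df = n₁+n₂−2; Welch
   optional); the k(k−1)/2 raw p-values are BH-FDR corrected
   (rejection at adjusted q ≤ 0.05, the textbook step-up boundary).
6. **Outcome prediction.** Improvement rate = (pre-op med-off −
   post-op med-on) / pre-op med-off, chosen because the reference cohort
   means (57.29, 19.34) reproduce the reported 0.66 under exactly this
   formula; it may be negative for worsening and is not clipped in
   analysis. Selected-edge zFC values are the features. Features and
   label are min–max scaled to [−1, 1]; an RBF ε-SVR is grid searched
   over C ∈ 2^{−5..25}, γ ∈ 2^{−25..3} (step 2 on the exponent),
   ε ∈ {0.1..0.5}, each triple evaluated by full leave-one-out CV; the
   triple minimizing LOOCV MSE (normalized scale) wins, ties broken
   toward smaller C, then γ, then ε. Reported metrics are the LOOCV
   Pearson r (with two-tailed p) and MSE on both the normalized and the
   original scale. Two scaling modes: `"full-sample"` (scalers fit on all
   subjects — the common published LIBSVM workflow, optimistically biased)
   and `"leakage-safe"` (scalers refit inside each training fold, so the
   held-out subject's data never touch its own prediction). The whole
   procedure is deterministic; libsvm iterations are capped at 20 000
   (pathological corners such as C = 2^25 with mid-range γ otherwise cost
   ~200 ms per fit; the optimum region converges far below the cap).

The chain is exposed statsmodels-style: `DBSOutcomeModel` (from a cohort
directory or an in-memory synthetic cohort) → `.fit()` →
`DBSOutcomeResults` with `summary()`, per-stage tables, a filter-count
ledger (enrolled → included → ROIs screened → selected → edges tested →
selected → folds), and `save_report()`. A thin `uafc` CLI wraps it.

## The synthetic cohort generator

Defaults mirror the modeled study design: 32 PD + 31 HC analysable
subjects, TR = 2 s, 242 volumes of which 10 carry a decaying equilibration
transient, serum UA ~ N(288.45, 87.05²) μmol/L in PD and N(327.36, 10.57²)
in HC, improvement rate mean 0.66 / sd 0.21, a toy 20-ROI atlas (two
regions flagged "undefined", mirroring atlas regions that vanish under
resampling; the effective count is therefore 18) plus WM and CSF
compartments. The atlas partitions an ellipsoidal brain into *compact*
3D parcels by nearest-centroid assignment — compactness matters because
spatial smoothing mixes parcel borders, and sliver-shaped parcels would
leak their neighbours' signals everywhere.

Per subject, all temporal sources are unit-variance band-limited
(0.01–0.08 Hz) Gaussian series:

* **Region latents.** ROI k's latent is
  `L_k = w·η_k + g·G + Σ_e w_e·E_e`, with `η_k` idiosyncratic, `G` a
  global signal with subject-varying strength g (clipped at 0.5), `E_e`
  shared components on designated edges, and `w` chosen so Var(L_k)=1.
  The global signal is included because the modeled protocol does not
  regress it out; its subject-to-subject variability makes connectivity
  edges positively dependent, as in real connectomes.
* **Within-region coherence (the hub mechanism).** Voxel v of region k is
  `x_v = √coh_k·L_k + √(1−coh_k)·idio_v + noise`, where the idiosyncratic
  field is built from zero-spatial-mean plane-wave modes at two spatial
  scales (wavelengths ≈ 6 and ≈ 2.2 voxels, 16 modes each by default,
  every mode carrying its own band-limited series). `coh_k` is the mean
  pairwise voxel correlation of the region. The modes cancel exactly in
  the ROI average, so ROI-level connectivity equals the latent
  correlation structure; the smooth scale survives Gaussian smoothing, and
  the fine scale emulates the fine-grained physiological variance real
  BOLD keeps after smoothing — without it, smoothing leaves voxel
  cross-region correlations ≈ coh·g², which can cross the DC threshold
  and flood the degree map.
* **UA–DC coupling.** Per coupled region, a hub factor
  h = ±ρ·z_UA + √(1−ρ²)·η shifts the coherence linearly
  (coh = 0.5 + 0.25·h, clipped to [0.12, 0.8]); positive-coupled regions
  use +ρ, negative-coupled −ρ. Degree centrality is monotone in
  coherence, so corr(UA, ROI-mean DC) ≈ ρ up to estimation attenuation.
  Infeasible requests (|ρ| ≥ 0.95, or voxel noise large enough to swamp
  the hub signal, or variance budgets g² + Σw_e² ≥ 1) raise an explicit
  error rather than silently clipping.
* **Group-difference edges.** Four designated (disjoint) edges among the
  coupled regions carry shared-component weight 0.6 in HC but only
  0.1 + 0.15·u_s in PD (u_s a per-subject factor), planting PD < HC
  connectivity differences.
* **Outcome link.** Each PD subject's improvement rate is
  mean + sd·(β·z_s + √(1−β²)·ε) clipped to [0, 1] (the observed quantity
  is a proportion), where z_s is the standardized *true* outcome-edge
  coupling, arctanh(g² + w²) averaged over the designated edges — the
  quantity the measured zFC estimates. β defaults to 0.75. UPDRS-III
  scores are then generated consistently (post-op med-on =
  pre-op med-off × (1 − rate)).
* **Motion.** A smooth random walk per subject; a configurable fraction
  receives a > 3 mm/3° spike so QC exclusion is exercised (0 by default;
  the within-scan motion distribution is a stated convenience, not an
  inference from data).

The config seed fully determines every array and file; per-subject BOLD is
generated lazily from spawned child seeds, and written cohorts
(uncompressed NIfTI + motion text + TSV + JSON ground-truth ledger) have
reproducible SHA-256 manifests.

### Calibration

The generator was calibrated — as its contract requires — so the planted
effects are *recoverable by the pipeline*, not merely present in the
latents: the coherence-mode mechanism replaced two earlier designs
(amplitude gain, phase dispersion) that smoothing and band-pass filtering
rendered unreadable; the global-signal clip (0.5) keeps coherence×g²
below the 0.25 degree threshold so high-g subjects cannot flood the degree
map; the two-scale modes keep that margin after smoothing. Residual
attenuation is dominated by DC estimation noise: with 232 frames of
0.01–0.08 Hz signal there are only ~68 temporal degrees of freedom, so
ROI-mean DC has split-half reliability ≈ 0.7 and a planted ρ = 0.6 is
recovered at ≈ 0.48 on average. That ceiling is a property of the scan
length, not of the estimator.

## Parameter-recovery protocol (`uafc.validation`)

Recovery runs use `fwhm_mm = 0`. At desk scale the toy parcels are ~5
voxels across, barely 2.5× the kernel FWHM, so 6 mm smoothing leaks
neighbouring parcels into each other far more than it would with real
atlas parcels (which are many kernel widths across); the leak both
attenuates the DC–coherence readout and creates small true group biases
on null edges between adjacent parcels. The unsmoothed protocol measures
the method rather than that scale artifact; the smoothing operator itself
is validated separately against a brute-force convolution oracle, and the
default configuration for real data keeps 6 mm.

Problem sizes: UA–DC recovery uses 20 seeds × 60 PD subjects at low voxel
noise (the regime where the coupling contract is stated); edge recovery
uses 20 seeds at the default 32 + 31 design on the designated 8-ROI
panel; outcome recovery uses 7 seeds with a compact SVR grid (4×3×2
triples). The planted-outcome check uses the full-sample (protocol)
scaling mode; the null check uses the leakage-safe mode, because the
protocol itself carries two documented optimisms on null data — scaling
before cross-validation, and reporting r at the LOOCV-MSE-selected grid
point — that a null sanity check should not inherit (a dedicated test
demonstrates the full-sample optimism explicitly).

## Numerical choices and degenerate inputs

* Correlations are computed on mean-removed, unit-norm series; |r| is
  clipped to [−1, 1] against floating-point overshoot.
* Zero-variance in-mask voxels are an error instructing re-masking (the
  default mask keeps nonzero-temporal-variance voxels ∩ atlas support).
* A scan too short for the band/confound model — fewer pass-band
  dimensions than nuisance regressors, which would leave numerically zero
  residuals — is refused with an explicit error (at TR = 2 s and the
  default 27-column design this needs roughly 140 retained frames).
* BH-FDR handles ties through the running minimum; rejection uses the
  textbook ≤ boundary.
* Grid-search ties are broken deterministically toward the smallest C,
  then γ, then ε; all randomness anywhere flows from a single integer
  seed.
* Mismatched affine/grid between BOLD and atlas is an error, never an
  automatic resample.

## What passing tests do and do not show

The synthetic cohorts have band-limited Gaussian sources, piecewise-
homogeneous parcels, no hemodynamic response function, no scanner
artifacts, no anatomical variability, and linear planted links. Passing
recovery tests therefore shows the *pipeline* is correct and calibrated —
that it finds exactly what was planted at realistic sample sizes — not
that the biological effects exist or that the published effect sizes
would replicate. The published headline result (LOOCV r = 0.487 on 32
patients) depends on undeposited patient data and is explicitly outside
what the synthetic validation can or does claim.

## Known limitations

* The toy atlas has 20 regions, not 170; exclusion-list handling is
  emulated by flags rather than by resampling anatomy.
* LOOCV r at the grid-selected hyperparameters is optimistically biased
  (≈ +0.1–0.2 at n = 32 under the null even leakage-safe); nested
  cross-validation would remove this but is out of scope.
* ROI screening at uncorrected p < 0.05 admits ≈ α·(#regions) false
  regions by construction; the design relies on the downstream FDR edge
  stage for error control.
* Welch/binary-degree/BH-screening options are provided but the defaults
  follow the modeled protocol.
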