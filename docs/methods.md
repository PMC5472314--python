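# Methods

This note documents the models, parameter choices and limitations of
`gaitdrift` — what the synthetic data emulate, how the classifiers are
formulated, how the evaluation designs and the statistical layer are defined,
and where genuinely open design choices were resolved.

## The synthetic-data generator

### What it emulates

The generator reproduces the *statistical structure* of a within-day
multi-session gait study, not its physics: 9 subjects, 6 sessions at start
times (0, 10, 40, 50, 140, 150) minutes — the unique schedule consistent
with rest gaps of 10/30/10/90/10 minutes — and 15 stride trials per session.
Each trial is a multichannel curve set: 6 GRF channels (2 foot contacts x
3 force directions, body-weight units scaled to Newtons by a per-subject
mass drawn from N(73.2, 13.3²) kg) or 18 joint-angle channels (2 legs x
3 joints x 3 planes, degrees), each with 100 samples per stride.

A trial's joined vector is

    x = template + subject_offset + Bᵀ·θ(t_session) + Bᵀ·η_trial

where **B** is a rank-`basis_rank` orthonormal smooth basis over the joined
feature vector (cosine modes per channel, QR-orthonormalised), **θ** follows
a Gaussian random walk over session start times with increment variance
`drift_scale² · Δt` per coordinate, and **η** is i.i.d. N(0, `noise_scale²`)
per coordinate.  Orthonormality of B makes the separation identity exact in
curve space:

    E ‖drift(sᵢ) − drift(sⱼ)‖² = basis_rank · drift_scale² · |tᵢ − tⱼ|.

A Brownian walk was chosen over a mean-reverting (Ornstein–Uhlenbeck)
process because it is the simplest process whose expected separation grows
with elapsed time — the qualitative signature the analysis detects — without
imposing a reversion time-scale that nothing in the emulated design
constrains.

### Parameters and calibration

| parameter | default | meaning |
| --- | --- | --- |
| `basis_rank` | 8 | dimensionality of the smooth drift/noise subspace |
| `noise_scale` | 0.05 | trial-to-trial (stride-to-stride) noise, BW units per basis coordinate |
| `drift_scale` | 0.0125 | session drift per √minute, BW units per basis coordinate |
| `subject_scale` | 0.2 | between-subject template perturbation |

No quantitative drift magnitude is available for real gait, so `drift_scale`
is a **calibration of this package**, not an empirical constant.  The
Gaussian-discrimination approximation d² ≈ basis_rank · drift_scale² · Δt /
noise_scale² locates the workable region, and the default was fixed on a
small pilot run so that pairwise session classification rates fall in the
73–100% band reported for real within-day data (≈80% at 10 min rising to
≈100% at 150 min, six-session rates ≈70%).  Both modalities use the same
mechanism and scales; consequently the synthetic kinematic data are *not*
systematically easier to classify than the kinetic data, unlike real
recordings — a deliberate simplification.

### What passing tests do not show

The generator produces smooth, stationary-noise curves in a low-rank
subspace.  Real stride waveforms have richer structure: heteroscedastic
noise, stride-time warping, autocorrelated within-session drift,
subject-specific noise levels and marker/soft-tissue artefacts.  Tests
passing on synthetic data therefore validate the *pipeline machinery*
(preprocessing contracts, solver correctness, harness logic, statistical
arithmetic) and the qualitative time-scale trend, not field performance on
laboratory data.

## Preprocessing

The chain is: stride segmentation (10 N threshold on vertical GRF, right
heel strike to left toe off) → zero-phase 2nd-order Butterworth low-pass at
18 Hz (angles only) → body-weight normalisation (GRF only) → linear time
normalisation to 100 points → z-transform → [-1, 1] scaling → joined matrix.

Two conventions deserve explanation:

* **z-transform scope.**  Kinematic trials are standardised per trial across
  their own 1800 features; kinetic features are standardised per feature
  column across the subject's 90 trials.  Standardisation is never pooled
  across subjects — the analysis is strictly intra-individual.
* **Scaling scope.**  The [-1, 1] map is per feature column across the
  subject's trials (constant columns map to 0).  Per-variable scaling is the
  only reading that serves its purpose of preventing variables with larger
  numeric ranges from dominating the kernel.

Because the column-wise stages (global z, scaling) are defined across all 90
trials, the implementation joins trials into a matrix first and then
standardises/scales; the per-row and per-column scopes are unchanged by this
ordering.  Fitting the column statistics on the full matrix before
cross-validation leaks a small amount of held-out information; this mirrors
the conventional processing order and its effect is negligible here, but a
fold-safe variant (statistics re-fitted on each training fold) is available
via `loocv_rate(..., fold_safe=True)` and the `--fold-safe-scaling` flag.

Linear interpolation is used for time normalisation: it is the
minimal-assumption choice, exact on linear segments, and its error on the
smooth templates is < 1e-3 at 100 points.

## Classifiers

### KBDR

Kernel-based discriminant regression is implemented as **kernel
least-squares regression of ±1 class indicators with a ridge penalty**: with
training kernel matrix K, the dual coefficients per class solve

    (KᵀK + αI) c = Kᵀ y.

This normal-equation form treats the kernel columns as a design matrix and
is well posed even when the kernel matrix is indefinite — which matters
because the **signed polynomial kernel**

    k(x, z) = sign(s) · |s|^exp,   s = x·z + β

is used with possibly fractional `exp`, and [-1, 1]-scaled features admit
negative s.  The signed power is the continuous odd extension of s^exp and
reduces to the standard polynomial kernel for s > 0.  β is the kernel's
additive offset and α the ridge regulariser — the only assignment consistent
with the magnitudes of their search grids (α spans 10⁻⁷–10⁻³, a typical
ridge scale).

Two solvers are provided and contract-tested to agree within 1e-6:

* **direct**: Cholesky solve of the normal equations (least-squares fallback
  if rounding on badly scaled kernels defeats the factorisation);
* **proximal_point**: c⁽ᵗ⁺¹⁾ = (KᵀK + (α+λ)I)⁻¹(Kᵀy + λc⁽ᵗ⁾) from c⁽⁰⁾ = 0,
  stopping when the successive max-norm change falls below `tol` (default
  1e-9).  Its fixed point satisfies the normal equations for any λ > 0;
  the default step λ = 0.01 keeps the contraction factor λ/(λ+α+σ²ₘᵢₙ) small
  so convergence is fast.  Non-convergence raises with the residual.

Multiclass uses one-versus-all: per class c, f_c(x) = Σᵢ cᵢ k(xᵢ, x), with
argmax prediction and ties broken to the lowest class index in sorted class
order (deterministic by construction).

**Hyperparameter grids.**  exp ∈ {0.1, 0.3, 1, 3}, α ∈ {10⁻⁷ … 10⁻³},
β ∈ {0.01, 0.03, 0.1, 0.3, 1, 3, 10}.  The exp and β grids follow the same
1–3-per-decade convention, which for exp is also forced by behaviour: on
[-1, 1]-scaled features the linear gram has entries of order ±200, and the
signed fractional power warps such values so strongly that LOOCV rates
collapse for non-integer degrees; a grid that includes degree 1 (and reaches
its endpoint 3) keeps the method usable on its own design.

### Linear SVM

L2-regularised L2-loss (squared hinge) support vector classification,

    min_w ½‖w‖² + C Σᵢ max(0, 1 − yᵢ w·x̃ᵢ)²,

with the bias handled by augmenting each x with a constant 1 (the bias is
regularised, matching common primal L2L2 implementations; stated explicitly
because formulations differ).  The objective is convex and C¹; it is
minimised by L-BFGS, optimising over the span of the training rows when
n ≤ d (lossless for this objective and much cheaper at d = 600/1800).
C ∈ {2⁻⁵, 2⁻⁴·⁷⁵, …, 2¹⁵} (81 values).  An independent reference optimiser
is used in the test suite to verify objective values to 1e-4 relative.

## Evaluation designs

* **LOOCV**: each trial predicted by a model fitted on all remaining trials
  of the design; rate = 100 · correct/total.  The harness is contract-tested
  to agree *exactly* with a naive per-fold refit oracle.  Designs with any
  class below 2 trials are rejected.
* **Grid search**: non-nested by default — one setting maximising the LOOCV
  rate of the full design matrix, ties broken to the first point in
  documented grid order (exp → α → β; ascending C).  A nested mode (inner
  LOOCV per training fold) is available for honest generalisation estimates.
  Selection is run once per subject x modality x classifier on the
  six-session design and reused for the 15 pairwise designs.
* **Intervals**: pairwise session gaps map to T1 = {10}, T2 = [30, 50],
  T3 = [90, 110], T4 = [130, 150] minutes — sizes (3, 4, 4, 4) for the
  default schedule; a gap outside every interval signals a schedule
  mismatch.

## Statistical layer

For the subjects x conditions table (e.g. 9 x 4 interval means):

* **Shapiro–Wilk gate** at α = 0.05 per condition routes to the parametric
  or nonparametric path (any rejection, or a constant sample, →
  nonparametric) and sets the descriptive convention (mean ± sd vs median
  (Q1–Q3)).
* **rm-ANOVA**: within-subject F with df (k−1, (k−1)(n−1)); Mauchly's test
  on the orthonormal-contrast covariance gates the Greenhouse–Geisser
  correction (ε multiplies both df).  Partial η² = F·df1/(F·df1 + df2) is
  computed from the *uncorrected* df — the only definition consistent with
  published (F, df, η²) triplets for this design — also when corrected df
  are reported.  Post-hoc paired t-tests use Bonferroni m = C(6,2) = 15 for
  the six-session family.
* **Friedman** via average ranks with tie correction (the all-tied table
  returns statistic 0, p = 1); its chi-square reference deviates from the
  exact discrete permutation null by a few percent at n = 9, which the
  permutation-oracle test allows for.
* **Wilcoxon signed-rank**: zero differences dropped; exact two-sided p by
  sign-assignment enumeration (subset-sum convolution over doubled ranks)
  for ≤ 25 non-zero pairs, tie-corrected normal approximation without
  continuity correction above.  Z is reported in either case and
  r = Z/√n with n = the total number of pairs (the number-of-subjects
  convention; the non-zero-pair alternative can be requested via
  `n_for_r`).  Post-hoc Wilcoxon p values are Bonferroni-adjusted with
  m = C(4,2) = 6; the exact nine-concordant-pairs p (2/2⁹ ≈ 0.0039) times 6
  gives ≈ 0.023, matching the convention of reporting *adjusted* post-hoc
  p values.

## Reproduction script

`scripts/acceptance.py` runs nine subjects x both modalities x both
classifiers from a single seed: per-subject grid search on the six-session
design (full KBDR grid; the SVM cost grid thinned to 5 of its 81 points to
keep the run to a few minutes on one CPU), all LOOCV designs, interval
means, the Friedman omnibus over the KBDR/GRF interval table, and a
permuted-label chance-level control.  Every reported number is computed at
run time; nothing is looked up.

## Known limitations

* The generator's drift is homogeneous across channels and modalities; real
  kinematic/kinetic asymmetries (angles drifting faster than forces) are not
  emulated, so modality comparisons on synthetic data are uninformative.
* Non-nested hyperparameter selection is optimistically biased; the nested
  mode exists but is markedly slower and is not the default.
* The KBDR formulation is this package's own minimal reading of
  "discriminant regression with a proximal-point solver and polynomial
  kernel"; other formulations (e.g. LDA-style scatter-matrix objectives)
  would differ in detail.
* Exact Wilcoxon enumeration is O(n · Σranks) per test — fine for n ≤ 25,
  by design not used above.
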