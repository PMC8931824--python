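# Methods

## The measurement problem

The package treats decision-making style as a latent individual trait that
leaves a signature in facial kinematics during speech. The observable is a
30 Hz capture of P = 1347 facial landmarks in camera coordinates (meters);
the target is the five GDMS dimension scores, each an integer sum of five
1–5 Likert items (range 5–25). The mapping is learned by supervised
regression; nothing in the pipeline assumes which facial regions carry the
signal — landmark selection is purely variance-driven.

## Pipeline stages and the choices inside them

**Coordinate shift.** The reference landmark ("vertex", index
`reference_point`, default 0 since the mesh carries no anatomical labels) is
subtracted *per frame* by default. The alternative single-offset reading
(`shift_mode="first_frame"`) subtracts only the frame-0 position and so
retains head translation. Per-frame subtraction is the stricter
normalization — it removes rigid head translation entirely, leaving only
motion relative to the face — and is what the screening and feature stages
assume. The shift is idempotent and translation-invariant.

**Mean filter.** A centered moving average of width W ∈ {3, 5}. At the
boundaries the window is truncated to the frames that exist and the average
is taken over those (e.g. (1,2,3,4,5) at W=3 → (1.5, 2, 3, 4, 4.5)); this
keeps the frame count unchanged without letting padding values leak into
the series. A centered rather than forward window avoids a half-window
phase shift; the subsequent 150-frame trim discards the boundary frames
anyway, so end handling never reaches the features.

**Trim and standardize.** `round(trim_seconds · rate)` frames are dropped
from each end (150 at 5 s / 30 Hz) to remove the unsettled start and the
capture-stop tail, then the *first* `retained_frames` (2112) of the
remainder are kept. 2112 is a protocol constant, not derived: it equals
66·32 and makes the 128/64 sliding-window grid come out to exactly 32
windows. Captures left shorter are flagged discarded — never padded — and
every discard is logged with its frame count.

**Screening.** For each sample the inter-frame Euclidean displacement
matrix D ((N−1) × P) is reduced to per-landmark sample variances (ddof = 1;
the variance formula is implemented as the standard two-pass sample
variance), stacked across the corpus, averaged per column, and ranked
descending. Ties break toward the lower landmark index so the ranking is a
total order. Screening uses the whole preprocessed corpus by default
(matching the protocol's corpus-level matrix); restricting it to training
samples is possible by screening a subset, but the default is the
corpus-level reading.

**Spectral features.** Windows are rectangular (no taper): each 128-frame
block gets an unnormalized forward DFT, and the window's two features are
the mean and the sample variance (ddof = 1) of the 128 coefficient moduli.
The population/sample normalization of this variance is not fixed by the
protocol text; ddof = 1 was chosen for consistency with the screening
variance. The feature layout is deterministic — point-major (in screening
rank order), then axis x/y/z, then window in time order, then
mean/variance — so feature matrices are bit-reproducible and column names
(`p012_y_w07_variance`) identify their provenance.

**Dimensionality reduction and regression.** PCA is fitted on training rows
only (refitted inside every CV fold) to avoid leakage; the permissive
fit-on-everything reading is not provided. The 80-component default targets
the >98% explained-variance design point; the achieved fraction is logged
and a warning is emitted below 0.98. PCA scores are standardized to unit
variance before every regressor. This is a numerical choice: raw features
are in meters (~10⁻³), so unscaled component scores would make the fixed
SVR budget (C = 1) collapse the fit into its ε-tube and would leave the
ridge penalty grid (13 log-spaced values, 10⁻³…10³) dimensionally
meaningless. OLS predictions are invariant to this scaling, so it changes
nothing for the reference algorithm. SVR uses a linear kernel with
ε = 0.1·SD(training scores); ridge selects its penalty by efficient
leave-one-out GCV; Bayesian ridge uses scikit-learn's evidence-maximized
conjugate hyperpriors.

**Splitting and evaluation.** The stratified split sorts by score
(descending, ties by subject id), cuts four contiguous strata (remainder
samples go to the high-score strata), and draws round(0.8·size) of each
stratum for training with a seeded generator. Each dimension gets its own
split by default — the protocol is ambiguous on whether one split served
all five — and a shared-split mode reproduces the other reading. Metrics
are plain Pearson r (NaN with a warning when either vector is constant) and
RMSE in raw score points. Ten-fold CV shuffles with the config seed and
refits the entire PCA+regressor inside each fold.

**Split-half reliability.** Re-using the full-length model on half-length
captures is impossible — the window grid, and hence the feature
dimensionality, changes — so reliability is computed with two parallel
pipelines: odd-index and even-index frames form two 1056-frame
half-captures, the FFT window and hop are halved (preserving the
32-windows-per-axis grid), both pipelines are trained on the training half
and their validation predictions are correlated per dimension.
Spearman–Brown correction (2r/(1+r)) is available but off by default, since
the two halves are not independent administrations in the questionnaire
sense.

## The synthetic cohort generator

The generator is the package's stand-in for the unreleased capture corpus
and defines the study conditions the tests run under: 240 subjects, 2500
raw frames at 30 Hz, 1347 landmarks of which 100 carry signal (a "toy"
preset scales to 60/20 for fast runs), oscillation base amplitude 2 mm,
measurement noise SD 0.3 mm, head drift 5 mm below 0.2 Hz.

Per subject, five latent traits z ~ N(0, I) generate both outputs:

* **Scores**: `round(mean_d + sd_d · z_d)` clipped to [5, 25]. Defaults are
  the published per-gender norms pooled with 130 female / 110 male weights
  (pooled means 16.0–18.9, SDs 3.0–4.7); per-gender generation is available
  by overriding `score_means`/`score_sds`.
* **Motion**: each signal landmark oscillates as a sum of 2–4 sinusoids
  with frequencies drawn from (0.5, 8) Hz — inside the resolvable band of a
  128-frame window at 30 Hz — along fixed random 3D directions, with
  amplitude `base_amplitude · (1 + coupling · ⟨w_j, z⟩)` floored at 0.05.

The weight vectors w_j are one-hot (landmark j carries dimension j mod 5)
with scale 0.2. A dense random w_j at coupling ≥ 1 would drive roughly half
the cohort's amplitude factors negative, destroying the monotone
feature→score relationship the recovery tests rely on; the one-hot design
keeps factors positive for |z| ≤ 3 at coupling 1.5 while still exercising
all five dimensions. Cohort-level structure (base positions, signal set,
weights, frequencies, directions) is drawn once from the seed and shared by
all subjects; phases, head placement, drift and noise come from per-subject
child seeds, so subject *i* is bit-identical regardless of cohort size.

What the generator does **not** emulate: facial anatomy and mesh topology,
expression semantics, nonstationary speech dynamics, frame drops, sensor
quantization, and any nonlinear or non-spectral trait coding. Passing
recovery tests therefore demonstrates that the pipeline faithfully extracts
linear spectral-amplitude structure — not that real faces carry such
structure, which only the original kind of data could show.

## Problem sizes used by tests and the acceptance script

Simulation-backed checks run at deliberately chosen scales: the
planted-signal recovery and reliability check uses the full 240-subject
cohort at toy landmark resolution (60 landmarks, 2500 frames, top 50
selected, 80 PCA components); the null-distribution comparison uses 20
no-coupling cohorts of 80 subjects at a reduced grid (900 frames, 64/32
windows); the score-discreteness reproduction uses 120 subjects with
5-fold CV across all four algorithms; protocol arithmetic is measured on
two full-resolution (1347-landmark) captures. These sizes keep every check
fast enough to re-run routinely while leaving each conclusion's effect size
far above its sampling noise.

## Numerical notes and edge cases

* All variances are sample variances (ddof = 1) unless a closed form says
  otherwise; the displacement-variance and modulus-variance conventions
  match by construction.
* Pearson r on a constant vector is NaN-with-warning, not an exception, so
  batch evaluations never abort on a degenerate fold.
* `round()` (banker's rounding) is used for trim frames and stratum
  training counts; at the protocol constants no half-way cases arise.
* Sequences must be dense: a landmark CSV with missing (frame, point)
  pairs is rejected, never imputed.
* Determinism: all randomness flows through `numpy` `SeedSequence` children
  of the config seeds; same seed ⇒ bit-identical features, splits and
  simulated cohorts.

## Known limitations

* The GDMS item→dimension key and reverse-keying are not standardized here;
  item scoring accepts any partition key, and simulated cohorts generate
  dimension scores directly.
* `retained_frames`, window and hop must satisfy the exact divisibility the
  window grid needs; arbitrary capture lengths require choosing compatible
  constants.
* The four regressors are linear in the PCA scores by design; no
  nonlinear models are provided.
* Reliability and accuracy estimates on synthetic cohorts are upper bounds
  relative to real captures, whose noise structure is richer than i.i.d.
  Gaussian jitter.
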