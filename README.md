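# facekin

Automatic recognition of decision-making style from facial kinematics.

People's habitual decision styles are usually measured with the General
Decision-Making Style questionnaire (GDMS): 25 Likert items summed into five
dimension scores — *spontaneous*, *avoidant*, *rational*, *dependent* and
*intuition*, each in [5, 25]. Questionnaires are slow and need a trained
administrator. `facekin` implements an alternative instrument for
behavioral-phenotyping researchers: predict the five scores directly from a
short 30 Hz capture of 1347 3D facial landmarks (the Kinect HD-face mesh)
recorded while the subject speaks.

## Method

For a capture `p[i, j] ∈ ℝ³` (frame *i*, landmark *j*):

1. **Face-local shift** — subtract a reference landmark per frame:
   `p'[i, j] = p[i, j] − p[i, ref]`, removing camera placement and rigid
   head translation.
2. **Mean filter** — centered moving average of width W ∈ {3, 5} on every
   coordinate series, suppressing sensor noise.
3. **Trim/standardize** — drop the first and last 5 s (150 frames), keep the
   first 2112 frames; shorter captures are discarded.
4. **Landmark screening** — per sample, inter-frame Euclidean displacements
   `d[i, j] = ‖p'[i+1, j] − p'[i, j]‖` form an (N−1)×1347 matrix; landmarks
   are ranked by the corpus-mean of the per-sample column variances σⱼ and
   the top 100 are kept.
5. **Spectral features** — each axis series of each kept landmark is cut
   into 128-frame windows with a 64-frame hop (32 windows); per window, the
   moduli `|F_k|` of the unnormalized DFT give two features (mean, sample
   variance), for 100 × 3 × 32 × 2 = **19200 features per sample**.
6. **Model** — PCA to 80 components (fitted on training rows; >98%
   variance), standardized scores, then one of four regressors per
   dimension: OLS (`lr`), linear-kernel SVR (`svr`), ridge with
   generalized-cross-validated penalty (`ridgecv`), Bayesian ridge (`br`).
7. **Evaluation** — score-stratified 8:2 holdout (four score-quartile strata
   of 60; 48/12 each; 192/48 overall at n = 240), Pearson r and RMSE,
   10-fold cross-validation, and odd/even-frame split-half reliability.

Because the original capture corpus is not public, the package ships a
first-class **synthetic cohort generator**: latent standard-normal traits
`z` per subject drive both the GDMS scores (`round(mean_d + sd_d·z_d)`,
calibrated to published gender-pooled norms) and the spectral amplitudes of
designated signal landmarks (`A_j = A₀(1 + c·⟨w_j, z⟩)`). Recovering the
planted coupling end-to-end is the package's accuracy check.

## Worked example

```python
import facekin as fk

sim = fk.SimulationConfig.toy(n_subjects=40, coupling_strength=1.5,
                              noise_sd_m=0.0, seed=3)
cfg = fk.PipelineConfig.toy(pca_components=15, seed=3)
seqs, records, _ = fk.simulate_cohort(sim)
result = fk.run_pipeline(seqs, records, cfg, with_reliability=False)
print(result.report.pivot("pearson_r").round(3))
```

prints

```
dimension    spontaneous  avoidant  rational  dependent  intuition
algorithm W
br        3        0.999     0.994     0.998      0.992      0.995
lr        3        0.999     0.994     0.998      0.992      0.995
ridgecv   3        0.999     0.994     0.998      0.992      0.995
svr       3        0.999     0.994     0.996      0.993      0.993
```

Each cell is the Pearson correlation between predicted and actual scores on
the stratified validation set. Values near 1 mean the pipeline recovered
the trait→motion coupling the simulator planted; on this noiseless cohort
anything far below 1 would indicate a defect in preprocessing, screening,
feature extraction or modeling. `examples/` contains one short script per
capability (simulation, preprocessing, screening/features, model
evaluation, reliability).

A thin CLI wraps the same functions:

```sh
facekin simulate --out data --preset toy --n-subjects 16 --coupling 1.5 --seed 7
facekin run-all --data-dir data --out results --seed 7
```

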