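# Methods

## The consistency model

The analysis assumes only that a voxel activated by the task produces a
*similar* time course in every repetition (run) of the same experiment — not
that the response follows any hemodynamic model, arrives on time, or has a
particular sign or shape. Each voxel's "model" is therefore its own time
course in another run.

For a session of N co-registered runs with identical task timing, every
unordered pair of runs (j, k), j < k, contributes an ordinary least-squares
regression per voxel i:

    s_ik(t) = a + beta_ijk * s_ij(t) + e(t),     t = beta / SE(beta),

with residual degrees of freedom T − 2 (T volumes). The model includes an
intercept even though detrended data are near zero mean: with the intercept
the t value is exactly symmetric in (j, k) and equals the correlation form
r·sqrt(T−2)/sqrt(1−r²), matching the unordered use of the pairs. All
N(N−1)/2 pairwise fits form the triangular beta and t half-matrices per
voxel.

Downstream quantities:

* **Subject t map** — one-sample t of the pairwise betas over the P
  selected pairs: t = mean(beta)·sqrt(P)/sd(beta), P ≥ 2.
* **Bad-run exclusion** — iterative. Each pass: (1) subject t map over the
  current good runs; (2) an activation mask of its top 1 percentile,
  Gaussian-smoothed (FWHM 2 voxels) and re-binarized at 0.5 — smoothing
  discards isolated supra-percentile voxels while keeping contiguous foci;
  (3) for every candidate run n, a one-sided Welch test of whether the
  in-mask t values of the leave-n-out map exceed those of the all-runs map;
  (4) Bonferroni correction by the number of runs tested in the pass;
  (5) if several runs are flagged, only the one with the smallest mean
  in-mask t over the pairs involving it is excluded, and the pass repeats.
  Testing stops when nothing is flagged or when only two good runs would
  remain.
* **Reliability map** — the final result: the percentage of good-run pairs
  whose pairwise t exceeds the upper-tail Student quantile at uncorrected
  p < 0.001 (t ≈ 3.25 at dof 54). Only the positive tail counts: consistent
  responses of either BOLD sign produce positive inter-run slopes, whereas
  negative slopes indicate anti-correlated, i.e. inconsistent, behaviour.
  With N_g good runs the map takes values 100·m/(N_g(N_g−1)/2); with two
  runs the only levels are 0 and 100.
* **Mean beta map** — the average pairwise slope over good pairs, useful
  for separating true activation (slopes near 1) from artefacts when N is
  small.

Because a global circular shift of all runs permutes every pair of time
courses identically, all pairwise sums of squares — hence beta, t, and the
reliability map — are mathematically invariant under consistent timing
offsets. A GLM fitted against a fixed regressor is not; this asymmetry is
what the shift-sensitivity experiment measures.

## Reference GLM and fit-quality comparison

The reference GLM uses a single regressor: the task boxcar convolved with
the canonical double-gamma HRF (SPM convention — gamma shapes 6 and 16,
unit scales, undershoot ratio 1/6, 32 s support, peak normalised; built on
a 0.1 s grid for onset accuracy and sampled at the volume times), plus an
intercept. It is fitted per run to the *same* polynomial-detrended data the
consistency analysis uses, and beta/t/R² are averaged across good runs;
this keeps residual dof comparable with the pairwise fits and avoids
conflating preprocessing differences with model differences. Only positive
t values are reported on output maps.

Voxelwise goodness of fit uses R² = 1 − SSres/SStot. For the consistency
analysis R² is the mean over good pairs of each pairwise fit's R² (a pooled
variant combining sums of squares across pairs is available behind a flag;
the mean keeps each pair equally weighted regardless of its total
variance). The comparison map

    r_UG = (R²_consistency − R²_GLM) / (R²_consistency + R²_GLM)

is 0 where both methods fit equally, positive where run-to-run consistency
explains signal the canonical model cannot (delayed or transient
responses), and defined as 0 where both R² vanish. Positive-r_UG clusters
are 26-connected components above a minimum size, and cubic 5×5×5-voxel
ROIs centred on them provide average time courses for visual comparison
against the regressor.

Note an inherent asymmetry at finite SNR: the consistency "model" is itself
noisy, so for a perfectly model-conform response R²_consistency ≈ rho² and
R²_GLM ≈ rho, where rho = sigma_s²/(sigma_s² + sigma_n²) is the inter-run
correlation. r_UG for canonical responses is therefore slightly negative
unless sigma_s >> sigma_n; it approaches 0 from below as SNR grows. The
modified-response experiment runs at 5 % signal change, tSNR 100
(sigma_s ≈ 2.5·sigma_n), where canonical r_UG ≈ −0.05.

## Preprocessing

Scanner drift is removed by subtracting the least-squares second-order
polynomial per voxel time series, independently per run, with the volume
index as the time variable (the polynomial span, and hence the residual, is
invariant to time units). The same detrended data feed both analyses.
Temporal shifts used by the evaluation experiments are circular (the final
n volumes move to the front for positive n), applied after detrending so
every shifted analysis sees the same samples in permuted order.

## Synthetic sessions

The generator emulates the two block designs the method targets:

| design | blocks | TR | volumes |
|---|---|---|---|
| `motor_ababab` | 3 × 20 s task, ABABABA | 2.5 s | 56 |
| `visuomotor` | 10 s rest, then 5 × (10 s task + 20 s rest) | 1.0 s | 160 |

Brain voxels (an ellipsoid in the grid) carry a baseline of 1000 arbitrary
units. Regions add a response template in percent signal change: canonical
(boxcar ⊛ HRF), delayed (onsets shifted), transient onset/offset (short
impulses at block edges ⊛ HRF), negative, or none. Each run adds an
independent random second-order polynomial drift (coefficient sds
(10, 20, 20) units over normalised time, i.e. up to ~2–3 % of baseline) and
white Gaussian noise with sd = baseline/tSNR (an optional AR(1) coefficient
exists for robustness checks and defaults to 0). Runs designated "bad" are
generated with zero task amplitude — the analogue of a run in which no task
was performed. A single seed drives a per-run seed tree, so sessions are
bit-reproducible and region edits do not perturb noise streams.

Default study conditions, chosen once from typical 7 T values: tSNR 100
(mid-range gray matter at ~2 mm voxels), amplitudes 3–5 % (motor/visual
cortex block responses at ultra-high field). The low-contrast scenarios
(1 %, tSNR 50) probe the detection floor, see below.

What the generator does **not** emulate: physiological (cardiac or
respiratory) noise, motion and stimulus-correlated motion, spatially
correlated noise, EPI distortion or ghosting, and between-run registration
error. Passing tests therefore demonstrate the statistical behaviour of the
method under its own assumptions, not robustness to the full artefact
spectrum of acquired data.

## Detectability: what contrast the method needs

For an active voxel the inter-run correlation is
rho = sigma_s²/(sigma_s² + sigma_n²), where sigma_s is the temporal sd of
the response template (≈ 0.43 × amplitude for the ABABABA design) and
sigma_n the noise sd. The pairwise t is noncentral around
rho·sqrt(T−2)/sqrt(1−rho²):

* Reliability ≥ 90 in ≥ 95 % of active voxels needs a per-pair
  supra-threshold probability ≈ 0.995, i.e. pairwise t ≈ 6, rho ≈ 0.6 —
  at 1 % signal change this means tSNR ≈ 300. The recovery test runs at
  tSNR 400.
* At 1 % / tSNR 50, rho ≈ 0.05: the subject-level t of true foci (≈ 1.7
  over 45 pairs) sits *below* the top-1-percentile cut of the noise
  (≈ 2.6), so the activation mask cannot isolate the foci and the Welch
  exclusion test loses its footing entirely — compounded by the
  leave-one-out map's sqrt(36/45) scale handicap against the all-runs map.
  This is a floor of the method itself, not of the implementation: run
  exclusion presupposes clearly detectable activation, which matches its
  intended presurgical-mapping use. At 3 % / tSNR 100 the correct bad run
  is excluded in 20/20 seeded sessions with no false exclusions in 20
  all-good sessions.
* The Welch test's power also grows with the activation-mask voxel count
  (top 1 % of the brain): acquired brains contribute thousands of mask
  voxels, desk-scale phantoms tens to hundreds. The low-contrast scenarios
  use a 40×40×16 grid to keep the mask realistically sized.

## Numerical choices and degenerate inputs

* Zero-variance predictor or response in any regression: beta = t = 0.
* Zero-residual (perfect) fits: t clamped to ±1e6 so percentiles and Welch
  statistics stay finite; same clamp for zero-spread one-sample t.
* Welch test on two identical constant samples returns (t = 0, p = 0.5).
* Percentiles use the linear-interpolation quantile with a strict
  inequality at the cut; if the strict set is empty (constant map), ties at
  the cut are included.
* Count-matched GLM thresholds break ties at the cut by lexicographic voxel
  index, so split-half tables are deterministic.
* Dice of two empty masks is defined as 1 and flagged, keeping threshold
  tables total.
* Non-finite voxels in loaded NIfTI data are zero-filled and logged; ROI
  cubes are clipped at volume boundaries and logged.

## Open design points, resolved

* Among multiply-flagged runs, "the one with the smallest t value" is read
  as the smallest mean in-mask subject-level t computed from only the pairs
  involving that run (`selection="run_mean_t"`); selecting by largest Welch
  statistic is available (`selection="welch"`) and agrees on clear cases.
* The subject-level one-sample test feeds run exclusion unthresholded; its
  p = 0.05 level gates nothing upstream of the Welch test.
* Within-half bad-run exclusion is off by default in the split-half
  experiment so both halves keep matched pair counts.
* Odd/even split is by 1-based acquisition position (runs 1, 3, 5, … vs
  2, 4, 6, …).

## Problem sizes

Test and reproduction runs use grids of 16×16×6 to 40×40×16 voxels with
2,500–15,000 brain voxels, 2–20 runs of 56 volumes, and 20-seed Monte
Carlo loops for the exclusion experiments; the full suite and the
reproduction script each complete in well under five minutes on one core.

## Limitations

Multi-run designs with identical timing are required; the method cannot
separate several tasks in one session, and consistency is lost if response
dynamics change across runs (learning, fatigue, changed strategy).
Task-correlated motion produces consistent artefacts that score as reliable;
the mean-beta map helps flag them but does not remove them. Reliability
resolution is limited to multiples of 100/(N_g(N_g−1)/2).
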