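# Methods

This note records the models, parameter choices and numerical conventions
behind `segusim`, and what its synthetic experiments do and do not show.

## GrowCut automaton

The segmentation engine is a two-class seeded cellular automaton on the
image grid with Moore (8-neighbor) connectivity. Each cell carries a label
(none / background / foreground), a strength θ ∈ [0, 1] and its scalar
intensity c. Seeds start at θ = 1, everything else unlabeled at θ = 0. At
each synchronous step a cell e is conquered by the neighbor f maximizing
the attack strength θ_f · g(c_e, c_f), provided that product *strictly*
exceeds θ_e, where g(c_e, c_f) = 1 − |c_e − c_f| / max_pairwise, clamped to
[0, 1]. The denominator is computed once per image as (max − min) intensity;
a uniform image degenerates to g ≡ 1. Cells with label *none* never attack.
A per-cell counter h accumulates label flips (not strength-only updates);
it is the uncertainty signal consumed by the seed-suggestion strategies.

Conventions the underlying automaton formulation leaves open, fixed here:

* **Schedule** — fully synchronous (all cells read t, write t+1). Attacker
  ties at equal strength resolve by a fixed scan order N, NE, E, SE, S, SW,
  W, NW.
* **Termination** — strengths are per-cell non-decreasing and bounded by 1,
  so a fixed point is reached in finitely many steps; convergence is
  declared when an iteration changes nothing, with a cap of w·h iterations.
* **Seeds** — a strength-1 cell can never be strictly exceeded, so seed
  labels are invariant without special-casing.

The vectorized implementation is checked for exact fixed-point agreement
(labels, strengths and counters) against an independently coded per-pixel
simulator on random instances up to 7×7.

## Seed suggestion

*Guided*: the two cells with the largest h from the previous run
(row-major tie-break); if h is identically zero, the fallback is flagged.

*Joint*: an influence map M = norm(|∇I|) + (17/12)·norm(h) + norm(D).
Gradients use central differences with replicated borders. D = 1/(1 + d),
where d is the Euclidean distance to the nearest contour pixel of the
current mask, so *proximity* to the boundary scores high; an empty mask
contributes D ≡ 0. Each component is min–max normalized to [0, 1] before
the weighted sum (the three raw maps have incommensurable units, and
normalizing first makes the 17/12 weight meaningful); consequently M is
invariant under affine intensity rescaling. J = 20 seeds are picked
greedily in descending map order with a Chebyshev separation of
max(3, ⌈0.03·min(w, h)⌉) pixels to avoid local clusters, and auto-labeled
by the current mask (inside → foreground).

## Prototype engines and robot users

All three engines start from background seeds spaced along the image
border (the object is assumed interior). The guided engine additionally
places one foreground seed at the ground-truth centroid — the smallest
fixed interior initialization that yields a non-empty, nonzero-Dice
starting segmentation, which the guided paradigm requires; the other two
start at Dice 0.

The robot user targets the largest connected error component (current
labels vs. ground truth, 8-connected): the semi-manual robot scribbles up
to 6 component pixels nearest its centroid with the component's
ground-truth label; the guided robot picks the option matching ground
truth at the two proposed locations; the joint robot toggles every
proposal whose automatic label disagrees with ground truth and
occasionally long-presses in the error component. Faults are injected with
a per-interaction mislabel probability ε, Gaussian placement jitter σ, and
an undo probability. Sessions stop at Dice ≥ 0.99, when no error component
has ≥ 4 pixels, or at the interaction budget.

Timing model: interaction times are lognormal(μ, σ=0.35) seconds;
computation time is 2 ms per automaton iteration; wall-clock advances by
their sum plus a 0.2 s orientation pause, so the three time channels exist
and correlate positively with effort, as the ratio features require.

Every event is logged with its seed payload, so logs replay exactly: the
suite asserts recomputed per-interaction Dice equals the recorded values
for every simulated log.

## Synthetic cohort

The generator emulates the two-study design: study 1 has 10 subjects
segmenting all m = 3 recorded images with both the semi-manual and guided
prototypes in randomized order; study 2 has 11 subjects with the joint
prototype; 2·10 + 11 = 31 subject-prototype samples. A practice image of
moderate complexity is segmented first and excluded from the recorded logs
(configurable). Images are 40×40 radial star domains whose boundary
carries Fourier perturbations; the amplitude of high-frequency terms
scales with a roughness knob in [0, 1], giving a monotone, box-counting
measurable proxy for boundary fractal dimension (recorded images use
roughness 0.15–0.75, the practice image 0.4). Foreground/background
contrast is 0.30 with pixel noise SD 0.10 — chosen so that sessions need
multiple corrective interactions rather than converging after one seed,
while staying solvable within realistic budgets. The problem size (40×40,
m = 3, ≤ 12 interactions) keeps a full cohort simulation in tens of
seconds while preserving every structural property of the pipeline.

Each sample draws a latent usability u ~ U(0, 1) that monotonically drives
both behavior (mislabel ε = 0.05 + 0.35(1−u), jitter σ = 0.3 + 1.2(1−u),
interaction-time log-mean −0.3 + 0.9(1−u), budget 5 + ⌈7(1−u)⌉, undo rate)
and questionnaire items: SUS items express agreement v = 0.10 + 0.80u plus
item noise (SD 0.06, negatively keyed items reversed), AttrakDiff-2 groups
load on u with weights 0.9 (PQ), 0.8 (ATT), 0.7 (HQ-I), 0.6 (HQ-S) mapped
to the 1–7 scale. With zero item noise the scores are deterministic
monotone functions of u. Across 200 samples, u correlates with mean final
Dice at r ≈ 0.6.

What this does *not* show: the robot is a stationary rule follower — it
has no learning curve, fatigue, aesthetic judgment or inter-subject
strategy variance, and the questionnaire link is monotone by construction.
Passing tests demonstrate that the pipeline recovers a learnable signal
end to end, not that human questionnaire scores are predictable at any
particular accuracy.

## Questionnaires

SUS scoring follows the alternating-key formula; the adjective mapping
classifies by the nearest of the published per-adjective mean scores
(12.5, 20.3, 35.7, 50.9, 71.4, 85.5, 90.9 for worst imaginable … best
imaginable), which reproduces the anchors 88/82 → excellent, 67 → good.
The anchors are configurable. AttrakDiff-2 presentation randomizes pair
order and polarity; de-randomization maps flipped responses x → 8 − x and
is an exact inverse. The portfolio uses two-sided t confidence intervals
and the conventional 3×3 partition of [1, 7]² with cuts at 3 and 5; the
seven conventional labels leave two cells unnamed ((mid PQ, low HQ) and
(low PQ, mid HQ)), which map to "neutral"; the field geometry is
configurable.

## Feature catalogue

The 22 per-segmentation scalars are: #Interactions, #Undos, #Seeds,
#FG_seeds, #BG_seeds, #Label_toggles, Σctime, Σitime, Σwtime, Med_ctime,
Med_itime, Med_wtime, Final_Dice_score, Final_Jaccard, Final_Rand_index,
ROC_AUC, RAVD, MSE, LOG, OBJ_TPR, OBJ_TNR, Dice_trajectory_AUC. OBJ_TPR /
OBJ_TNR are the foreground true-positive and background true-negative
rates. The soft map for ROC_AUC and LOG is derived from automaton
strengths: p(foreground) = θ for foreground cells, 1 − θ for background,
0.5 for unlabeled; log-loss probabilities are clipped at 10⁻⁶.

Base features (48) = 4 relative seed-position statistics (median and SD of
user-placed seed x/(w−1), y/(h−1), pooled over the sample's logs; imputed
0.5/0 when no user seeds exist) + mean and median of each scalar over the
sample's segmentations. Composites to 216: each seed-position feature
divided by each of the six time summaries (24); each mean-aggregated
feature by each mean time summary (66); each median-aggregated feature by
each median time summary (66); and 12 time-relation ratios — ordered pairs
within the mean and within the median time summaries, named with a ':'
separator so all 216 column names stay unique (their arithmetic overlaps
six ratio columns; the redundancy is harmless and keeps the registry
counts at 48 base / 156 ratio / 12 time-relation). Division by zero and
undefined metrics impute 0. PCA augmentation standardizes the 216 columns
(constant columns are excluded from the fit but retained), appends
⌈0.1·216⌉ = 22 component scores, and persists the fitted transform for
test-time application.

## Prediction

The regressor is a stochastic gradient-boosted regression forest with
Huber loss (LightGBM backend): per-stage row subsampling plus per-tree
feature subsetting (30%) are the stochastic ingredients. The full search
grid is 8 × 8 × 8 × 8 × 5 = 20,480 combinations over boosting stages
{25…400}, learning rate {0.005…0.3}, tree depth {1…8}, subsample fraction
{0.4…1.0} and minimum leaf size {1,2,3,5,8}; a 256-combination demo grid
(4 × 4 × 4 × 2 × 2 over the same axes) ships for fast end-to-end runs and
still exceeds the 205-estimator voting pool. Model selection uses
eight-fold cross-validation on a random 4:1 train/test split; the CV score
is the held-out Huber deviance with transition point δ = 1 on raw
residuals. The SUS pipeline takes the 205 lowest-deviance configurations,
votes feature importances (fold-averaged, per-estimator normalized gain)
weighted by 1/loss, keeps the top 25 features, and repeats the grid search
on the reduced table. Predictions are clipped to [0, 100] (SUS) or [1, 7].
Relative absolute prediction error uses the true label as denominator;
zero-label samples are excluded.

On a 200-sample synthetic cohort (fixed seeds), held-out median relative
errors are ≤ 15% for all six labels with the demo grid — the end-to-end
recovery the acceptance suite asserts.

## Known limitations

* Two-class segmentation on 2-D grids only; no multi-label or 3-D support.
* The automaton re-segments from scratch after every interaction; on
  uniform regions the background/foreground frontier depends on wave
  arrival order, so adding redundant seeds can shift it.
* The robot user's error model is i.i.d. per interaction; real users make
  spatially and temporally correlated mistakes.
* The feature catalogue is one consistent reconstruction of the stated
  stage cardinalities; it is isolated behind the column registry so
  alternatives can be swapped.
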