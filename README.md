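# segusim

Semi-automated usability evaluation for interactive image segmentation.

Interactive segmentation systems (ISS) are judged not only by the masks
they produce but by how it *feels* to produce them — a property normally
measured with user studies and questionnaires, which are expensive to run.
`segusim` implements the full evaluation stack needed to study this
question on the desk:

* a seeded **GrowCut** segmentation engine — a cellular automaton in which
  labeled cells conquer Moore neighbors when the attack strength
  `θ_f · g(c_e, c_f)` exceeds the defender's strength, with
  `g(c_e, c_f) = 1 − ‖c_e − c_f‖ / max_{j,k}‖c_j − c_k‖` — extended with a
  per-cell counter `h` of label flips that marks where the automaton was
  uncertain;
* three headless **prototype engines** mirroring distinct interaction
  paradigms: free scribbling (*semi-manual*), forced choice among the four
  labelings of two system-proposed uncertain locations (*guided*), and
  toggling of J ≈ 20 auto-labeled seed proposals ranked by an influence map
  `norm(|∇I|) + (17/12)·norm(h) + norm(D)` with contour-proximity `D`
  (*joint*), each driven by a rule-based robot user that emits replayable,
  timestamped interaction logs;
* **questionnaire scoring**: the System Usability Scale,
  `sus(x) = (2.5/S) Σ_s [Σ_{odd i} x_{s,i} + Σ_{even i} (4 − x_{s,i})]`,
  with the Bangor adjective mapping, and AttrakDiff-2 group scores
  `attrakdiff(x, g) = 1/(7S) Σ_s Σ_i x^g_{s,i}` for PQ / ATT / HQ-I / HQ-S
  with `HQ = (HQ-I + HQ-S)/2` and the PQ-vs-HQ portfolio with 95%
  confidence rectangles;
* a deterministic **feature pipeline** turning each subject-prototype pair's
  logs into 48 base features, 216 log-derived features and 238 columns after
  PCA augmentation; and
* six **gradient-boosted regression forests** (Huber loss, exhaustive
  hyperparameter grid of 20,480 combinations, eight-fold cross-validation on
  a 4:1 split) predicting ATT, HQ, HQ-I, HQ-S, PQ and SUS from the logs
  alone, with a two-stage SUS feature selection: the best 1% (205) of
  grid-search estimators vote with 1/loss-weighted importances, the table is
  reduced to the 25 winning features, and the grid search is repeated.

A synthetic-cohort generator reproduces the two-study design (10 subjects ×
2 prototypes + 11 subjects × 1 prototype = 31 samples over m = 3 recorded
images plus a practice image) with a latent per-sample usability that
drives both robot behavior and questionnaire responses, so the prediction
task is well-posed and measurable end to end.

## Worked example

```python
from segusim import make_synthetic_image, sus_score, sus_adjective
from segusim.session import run_semi_manual, policy_from_usability
from segusim.questionnaires import SusResponse

image, truth = make_synthetic_image(shape_complexity=0.5, noise_sd=0.10,
                                    size=(40, 40), rng_seed=7, contrast=0.3)
log = run_semi_manual(image, truth, policy_from_usability(0.8, rng_seed=1))
print("final Dice: %.3f" % log.final_dice)
score = sus_score([SusResponse("s01", [4, 1, 3, 0, 4, 1, 4, 1, 3, 0])])
print("SUS = %.1f -> %s" % (score, sus_adjective(score)))
```

prints

```
final Dice: 0.986
SUS = 87.5 -> excellent
```

The robot user needed three scribble interactions (Dice trajectory 0.973,
0.973, 0.986) to satisfy its stopping rule; the SUS response pattern scores
87.5 of 100, which the adjective anchors classify as an *excellent* system.

The same pipeline is scriptable from the shell:

```sh
segusim pipeline --seed 0 --out runs/demo
```

which simulates the cohort, writes JSON-lines interaction logs, the feature
CSV with its column registry, the questionnaire/portfolio report, and the
relative-error table of the six trained estimators.

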