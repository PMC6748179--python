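"""Headless prototype engines, robot users, and cohort simulation.

Three interaction paradigms are simulated against a known ground truth:

* *semi-manual* — the user free-hand scribbles foreground/background seeds,
  each scribble followed by a GrowCut re-segmentation;
* *guided* — the system proposes the two most label-uncertain locations and
  renders the four possible labelings; the user picks one;
* *joint* — the system proposes J auto-labeled seeds from an influence map;
  the user toggles wrong labels, optionally long-presses to add a seed, and
  commits the batch.

A rule-based robot user drives each engine: it targets the largest
connected error component of the current segmentation, with configurable
scribble length, placement jitter, mislabeling rate, undo rate, timing
distribution and interaction budget.  Every recognized interaction is
logged with wall-clock, interaction and computation times plus the Dice
score after the update, yielding replayable JSON-lines interaction logs.

``simulate_cohort`` reproduces the two-study design: study-1 subjects
segment all images with both the semi-manual and guided prototypes, study-2
subjects with the joint prototype (defaults 10 and 11 subjects, m = 3
recorded images plus one practice image, giving 31 subject-prototype
samples).  A per-sample latent usability ``u`` drives both the robot's
efficiency and synthetic questionnaire responses through monotone links, so
questionnaire scores are learnable from the logs alone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .growcut import (LABEL_BACKGROUND, LABEL_FOREGROUND, SegmentationResult,
                      segment)
from .imaging import make_synthetic_image
from .metrics import dice
from .questionnaires import (AttrakDiffResponse, SusResponse,
                             attrakdiff_scores, sus_score)
from .seeds import (ScribbleSet, SeedPoint, border_background_seeds,
                    influence_map, max_change_locations, suggest_seeds,
                    long_press_seed)

__all__ = [
    "InteractionEvent",
    "InteractionLog",
    "RobotUserPolicy",
    "guided_options",
    "run_semi_manual",
    "run_guided",
    "run_joint",
    "replay_log",
    "simulate_cohort",
    "CohortResult",
    "policy_from_usability",
    "questionnaires_from_usability",
    "log_to_jsonl",
    "log_from_jsonl",
]

#: Seconds of (simulated) computation per GrowCut iteration.
COMPUTE_TIME_PER_ITER = 0.002
#: Fixed pause between interactions (orientation, hand movement), seconds.
PAUSE_TIME = 0.2
#: Session stops once Dice reaches this value.
STOP_DICE = 0.99
#: ... or once no connected error component has at least this many pixels.
MIN_ERROR_COMPONENT = 4


@dataclass
class InteractionEvent:
    wall_clock_time: float
    event_type: str  # add_scribble|choose_option|toggle_label|long_press|new_points|undo|finish
    payload: dict = field(default_factory=dict)
    computation_time: float = 0.0
    interaction_time: float = 0.0
    dice_after: float | None = None  # set on events that re-segment


@dataclass
class InteractionLog:
    subject_id: str
    prototype: str  # semi_manual|guided|joint
    image_id: str
    events: list[InteractionEvent] = field(default_factory=list)
    initial_dice: float = 0.0
    final_result: SegmentationResult | None = None
    image: np.ndarray | None = None        # reference data, not serialized
    ground_truth: np.ndarray | None = None

    @property
    def final_dice(self) -> float:
        for ev in reversed(self.events):
            if ev.dice_after is not None:
                return ev.dice_after
        return self.initial_dice


@dataclass
class RobotUserPolicy:
    """Rule-based user model parameters."""

    scribble_len: int = 6
    jitter_sigma: float = 0.5
    mislabel_prob: float = 0.0
    time_mu: float = 0.0       # lognormal log-mean of interaction time (s)
    time_sigma: float = 0.35
    undo_prob: float = 0.0
    long_press_prob: float = 0.2
    budget: int = 12
    rng_seed: int = 0

    def __post_init__(self):
        for p in (self.mislabel_prob, self.undo_prob, self.long_press_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.budget < 1:
            raise ValueError("budget must be >= 1")


class _Session:
    """Shared engine state: cumulative scribbles, current segmentation,
    undo history, event log and the simulated clock."""

    def __init__(self, image, gt, scribbles: ScribbleSet, log: InteractionLog,
                 rng: np.random.Generator, policy: RobotUserPolicy):
        self.image = image
        self.gt = gt.astype(bool)
        self.scribbles = scribbles
        self.rng = rng
        self.policy = policy
        self.log = log
        self.clock = 0.0
        self.result = segment(image, scribbles)
        self.history: list[tuple[ScribbleSet, SegmentationResult]] = []
        log.initial_dice = dice(self.result.foreground, self.gt)

    def emit(self, event_type: str, payload: dict, itime: float,
             ctime: float = 0.0, dice_after: float | None = None) -> None:
        self.clock += itime + ctime + PAUSE_TIME
        self.log.events.append(InteractionEvent(
            wall_clock_time=self.clock, event_type=event_type, payload=payload,
            computation_time=ctime, interaction_time=itime, dice_after=dice_after))

    def draw_itime(self, scale: float = 1.0) -> float:
        return float(scale * self.rng.lognormal(self.policy.time_mu, self.policy.time_sigma))

    def commit(self, new_seeds: list[SeedPoint]) -> tuple[SegmentationResult, float, float]:
        """Add seeds, re-segment, push undo history; returns
        (result, computation_time, dice)."""
        self.history.append((self.scribbles, self.result))
        self.scribbles = self.scribbles.add(new_seeds)
        self.result = segment(self.image, self.scribbles)
        ctime = COMPUTE_TIME_PER_ITER * self.result.iterations_run
        return self.result, ctime, dice(self.result.foreground, self.gt)

    def undo(self) -> None:
        """Reverse the latest committed interaction (no-op on empty history)."""
        if self.history:
            self.scribbles, self.result = self.history.pop()
            d = dice(self.result.foreground, self.gt)
            self.emit("undo", {}, self.draw_itime(0.4), 0.0, dice_after=d)
        else:
            self.emit("undo", {"noop": True}, self.draw_itime(0.4), 0.0)

    def error_component(self) -> tuple[np.ndarray | None, bool]:
        """Largest connected component of the current error, and whether it
        is a false negative (missing foreground)."""
        err = self.result.foreground ^ self.gt
        lab, n = ndimage.label(err, structure=np.ones((3, 3), dtype=int))
        if n == 0:
            return None, False
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=range(1, n + 1))
        biggest = int(np.argmax(sizes)) + 1
        comp = lab == biggest
        is_missing_fg = bool(self.gt[comp].any() and not self.result.foreground[comp].any()) \
            or bool(self.gt[comp].sum() > (~self.gt[comp]).sum())
        return comp, is_missing_fg

    def should_stop(self) -> bool:
        if dice(self.result.foreground, self.gt) >= STOP_DICE:
            return True
        comp, _ = self.error_component()
        return comp is None or comp.sum() < MIN_ERROR_COMPONENT


def _component_scribble(comp: np.ndarray, gt: np.ndarray, policy: RobotUserPolicy,
                        rng: np.random.Generator, n: int) -> list[SeedPoint]:
    """Scribble of up to ``scribble_len`` pixels inside an error component,
    labeled by the ground truth there, with placement jitter and a
    mislabeling fault."""
    ys, xs = np.nonzero(comp)
    cy, cx = ys.mean(), xs.mean()
    order = np.argsort((ys - cy) ** 2 + (xs - cx) ** 2, kind="stable")
    picks = order[:policy.scribble_len]
    # gt label of the component majority decides the scribble label
    want_fg = gt[ys, xs].mean() > 0.5
    label = LABEL_FOREGROUND if want_fg else LABEL_BACKGROUND
    if rng.uniform() < policy.mislabel_prob:
        label = LABEL_FOREGROUND + LABEL_BACKGROUND - label
    h, w = comp.shape
    out = []
    for i in picks:
        y = int(np.clip(round(ys[i] + rng.normal(0, policy.jitter_sigma)), 0, h - 1))
        x = int(np.clip(round(xs[i] + rng.normal(0, policy.jitter_sigma)), 0, w - 1))
        out.append(SeedPoint(y, x, label, origin="user_scribble", n=n))
    return out


def run_semi_manual(image: np.ndarray, gt: np.ndarray, policy: RobotUserPolicy,
                    subject_id: str = "s0", image_id: str = "img0") -> InteractionLog:
    """Simulate a free-scribbling session.

    Starts from border background seeds (Dice 0); per interaction the robot
    scribbles inside the largest error component with the ground-truth
    label, then the image is re-segmented.
    """
    rng = np.random.default_rng(policy.rng_seed)
    log = InteractionLog(subject_id, "semi_manual", image_id,
                         image=image, ground_truth=gt.astype(bool))
    sess = _Session(image, gt, border_background_seeds(image, spacing=2), log, rng, policy)
    for n in range(1, policy.budget + 1):
        if sess.should_stop():
            break
        if sess.history and rng.uniform() < policy.undo_prob:
            sess.undo()
        comp, _ = sess.error_component()
        if comp is None:
            break
        new_seeds = _component_scribble(comp, sess.gt, policy, rng, n)
        _, ctime, d = sess.commit(new_seeds)
        itime = sess.draw_itime(1.0 + 0.1 * len(new_seeds))
        sess.emit("add_scribble", {"seeds": [s.to_json() for s in new_seeds]},
                  itime, ctime, dice_after=d)
    sess.emit("finish", {}, sess.draw_itime(0.3))
    log.final_result = sess.result
    return log


def guided_options(image: np.ndarray, s_prev: ScribbleSet,
                   p1: tuple[int, int], p2: tuple[int, int],
                   n: int = 0) -> list[tuple[tuple[int, int], SegmentationResult]]:
    """The four alternative segmentations for two proposed seed locations.

    One GrowCut run per labeling of ``(p1, p2)``, in the fixed order
    (bg, bg), (bg, fg), (fg, bg), (fg, fg).  Returns ``[(labels, result)]``.
    """
    if tuple(p1) == tuple(p2):
        raise ValueError("the two proposed locations must differ")
    options = []
    for l1 in (LABEL_BACKGROUND, LABEL_FOREGROUND):
        for l2 in (LABEL_BACKGROUND, LABEL_FOREGROUND):
            trial = s_prev.add([SeedPoint(*p1, l1, origin="system_suggested", n=n),
                                SeedPoint(*p2, l2, origin="system_suggested", n=n)])
            options.append(((l1, l2), segment(image, trial)))
    return options


def _guided_init_seeds(image: np.ndarray, gt: np.ndarray) -> ScribbleSet:
    """Fixed initial seeds for the guided prototype: border background seeds
    plus one foreground seed at (the gt pixel nearest to) the centroid."""
    s0 = border_background_seeds(image, spacing=2)
    ys, xs = np.nonzero(gt)
    cy, cx = ys.mean(), xs.mean()
    i = int(np.argmin((ys - cy) ** 2 + (xs - cx) ** 2))
    return s0.add([SeedPoint(int(ys[i]), int(xs[i]), LABEL_FOREGROUND,
                             origin="border_init", n=0)])


def run_guided(image: np.ndarray, gt: np.ndarray, policy: RobotUserPolicy,
               subject_id: str = "s0", image_id: str = "img0") -> InteractionLog:
    """Simulate a guided session: forced choice among four labelings of two
    system-proposed, maximally label-uncertain locations.

    The initial seed set yields a non-empty segmentation, so Dice is
    already positive before the first interaction.  The robot picks the
    ground-truth-consistent option with probability 1 − mislabel_prob.
    """
    rng = np.random.default_rng(policy.rng_seed)
    gt = gt.astype(bool)
    log = InteractionLog(subject_id, "guided", image_id, image=image, ground_truth=gt)
    sess = _Session(image, gt, _guided_init_seeds(image, gt), log, rng, policy)
    for n in range(1, policy.budget + 1):
        if sess.should_stop():
            break
        (p1, p2), _ = max_change_locations(sess.result.changes, k=2)
        if p1 == p2:
            break
        correct = (LABEL_FOREGROUND if gt[p1] else LABEL_BACKGROUND,
                   LABEL_FOREGROUND if gt[p2] else LABEL_BACKGROUND)
        combos = [(l1, l2) for l1 in (LABEL_BACKGROUND, LABEL_FOREGROUND)
                  for l2 in (LABEL_BACKGROUND, LABEL_FOREGROUND)]
        if rng.uniform() < policy.mislabel_prob:
            wrong = [c for c in combos if c != correct]
            chosen = wrong[rng.integers(len(wrong))]
        else:
            chosen = correct
        new_seeds = [SeedPoint(*p1, chosen[0], origin="system_suggested", n=n),
                     SeedPoint(*p2, chosen[1], origin="system_suggested", n=n)]
        _, ctime, d = sess.commit(new_seeds)
        # the engine computed 4 alternatives; the user inspected and chose one
        ctime *= 4.0
        sess.emit("choose_option", {"option": combos.index(chosen),
                                    "seeds": [s.to_json() for s in new_seeds]},
                  sess.draw_itime(1.2), ctime, dice_after=d)
    sess.emit("finish", {}, sess.draw_itime(0.3))
    log.final_result = sess.result
    return log


def run_joint(image: np.ndarray, gt: np.ndarray, policy: RobotUserPolicy,
              J: int = 20, subject_id: str = "s0", image_id: str = "img0") -> InteractionLog:
    """Simulate a joint session: J influence-ranked, auto-labeled seed
    proposals per round; the robot toggles ground-truth-inconsistent labels
    (each toggle logged), occasionally long-presses inside the largest error
    component, then commits the batch with *new points*."""
    rng = np.random.default_rng(policy.rng_seed)
    gt = gt.astype(bool)
    log = InteractionLog(subject_id, "joint", image_id, image=image, ground_truth=gt)
    sess = _Session(image, gt, border_background_seeds(image, spacing=2), log, rng, policy)
    for n in range(1, policy.budget + 1):
        if sess.should_stop():
            break
        imap = influence_map(image, sess.result.changes, sess.result.foreground)
        proposed, _ = suggest_seeds(imap, sess.result.foreground, J=J, n=n)
        batch = []
        for i, s in enumerate(proposed):
            gt_label = LABEL_FOREGROUND if gt[s.y, s.x] else LABEL_BACKGROUND
            label = s.label
            if label != gt_label:
                # robot toggles a wrong label; with probability eps it fails
                if rng.uniform() >= policy.mislabel_prob:
                    label = gt_label
                    sess.emit("toggle_label", {"index": i, "y": s.y, "x": s.x},
                              sess.draw_itime(0.3))
            elif rng.uniform() < policy.mislabel_prob:
                label = LABEL_FOREGROUND + LABEL_BACKGROUND - label
                sess.emit("toggle_label", {"index": i, "y": s.y, "x": s.x},
                          sess.draw_itime(0.3))
            batch.append(replace(s, label=label))
        if rng.uniform() < policy.long_press_prob:
            comp, _ = sess.error_component()
            if comp is not None:
                ys, xs = np.nonzero(comp)
                j = int(np.argmin((ys - ys.mean()) ** 2 + (xs - xs.mean()) ** 2))
                lp = long_press_seed(sess.result.foreground, (int(ys[j]), int(xs[j])), n=n)
                batch.append(lp)
                sess.emit("long_press", {"y": lp.y, "x": lp.x}, sess.draw_itime(0.6))
        _, ctime, d = sess.commit(batch)
        sess.emit("new_points", {"seeds": [s.to_json() for s in batch]},
                  sess.draw_itime(0.4), ctime, dice_after=d)
    sess.emit("finish", {}, sess.draw_itime(0.3))
    log.final_result = sess.result
    return log


_INIT_SEEDS = {
    "semi_manual": lambda img, gt: border_background_seeds(img, spacing=2),
    "guided": _guided_init_seeds,
    "joint": lambda img, gt: border_background_seeds(img, spacing=2),
}


def replay_log(log: InteractionLog) -> list[float]:
    """Re-run a log's events through the engine and return the recomputed
    per-interaction Dice values (same order as the recorded ``dice_after``
    values)."""
    if log.image is None or log.ground_truth is None:
        raise ValueError("log carries no image/ground-truth reference to replay against")
    scribbles = _INIT_SEEDS[log.prototype](log.image, log.ground_truth)
    stack = [scribbles]
    out = []
    for ev in log.events:
        if ev.event_type in ("add_scribble", "choose_option", "new_points"):
            seeds = [SeedPoint.from_json(d) for d in ev.payload["seeds"]]
            stack.append(stack[-1].add(seeds))
            res = segment(log.image, stack[-1])
            out.append(dice(res.foreground, log.ground_truth))
        elif ev.event_type == "undo" and not ev.payload.get("noop"):
            stack.pop()
            res = segment(log.image, stack[-1])
            out.append(dice(res.foreground, log.ground_truth))
    return out


# ---------------------------------------------------------------------------
# JSON-lines serialization

def log_to_jsonl(log: InteractionLog) -> str:
    header = {"subject": log.subject_id, "prototype": log.prototype,
              "image": log.image_id, "initial_dice": log.initial_dice}
    lines = [json.dumps(header)]
    for ev in log.events:
        lines.append(json.dumps({
            "t": ev.wall_clock_time, "type": ev.event_type, "payload": ev.payload,
            "ctime": ev.computation_time, "itime": ev.interaction_time,
            "dice": ev.dice_after}))
    return "\n".join(lines)


def log_from_jsonl(text: str) -> InteractionLog:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    head = json.loads(lines[0])
    log = InteractionLog(head["subject"], head["prototype"], head["image"],
                         initial_dice=head.get("initial_dice", 0.0))
    for ln in lines[1:]:
        d = json.loads(ln)
        log.events.append(InteractionEvent(
            wall_clock_time=d["t"], event_type=d["type"], payload=d["payload"],
            computation_time=d["ctime"], interaction_time=d["itime"],
            dice_after=d["dice"]))
    return log


# ---------------------------------------------------------------------------
# Cohort simulation with a latent-usability generative model

def policy_from_usability(u: float, rng_seed: int) -> RobotUserPolicy:
    """Map latent usability u in [0, 1] to robot-user parameters.

    Higher usability means fewer mistakes, steadier placement, faster
    interactions and earlier task completion — the monotone link that makes
    questionnaire scores learnable from the logs.
    """
    u = float(np.clip(u, 0.0, 1.0))
    return RobotUserPolicy(
        scribble_len=6,
        jitter_sigma=0.3 + 1.2 * (1.0 - u),
        mislabel_prob=0.05 + 0.35 * (1.0 - u),
        time_mu=-0.3 + 0.9 * (1.0 - u),
        time_sigma=0.35,
        undo_prob=0.01 + 0.05 * (1.0 - u),
        long_press_prob=0.2,
        budget=5 + int(round(7 * (1.0 - u))),
        rng_seed=rng_seed,
    )


def questionnaires_from_usability(u: float, subject: str, rng: np.random.Generator,
                                  item_noise: float = 0.06
                                  ) -> tuple[SusResponse, AttrakDiffResponse]:
    """Draw questionnaire item responses from latent usability.

    Each SUS item expresses agreement ``v = 0.10 + 0.80 u`` plus item noise
    (even-indexed statements are negatively keyed, so their raw response is
    ``1 − v``).  AttrakDiff-2 groups load on u with decreasing weights
    (PQ strongest, HQ-S weakest), mapped to the 1–7 scale.  With zero item
    noise the resulting scores are deterministic monotone functions of u.
    """
    sus_items = []
    for i in range(1, 11):
        v = np.clip(0.10 + 0.80 * u + rng.normal(0.0, item_noise), 0.0, 1.0)
        if i % 2 == 1:
            sus_items.append(int(round(4 * v)))
        else:
            sus_items.append(int(round(4 * (1.0 - v))))
    sus = SusResponse(subject, sus_items)

    weights = {"PQ": 0.9, "ATT": 0.8, "HQ-I": 0.7, "HQ-S": 0.6}
    groups = {}
    for g, w in weights.items():
        items = []
        for _ in range(7):
            v = np.clip(w * u + (1.0 - w) * 0.5 + rng.normal(0.0, item_noise), 0.0, 1.0)
            items.append(int(np.clip(round(1 + 6 * v), 1, 7)))
        groups[g] = items
    att = AttrakDiffResponse(subject, groups)
    return sus, att


@dataclass
class CohortResult:
    logs: list[InteractionLog]
    sus_responses: dict[tuple[str, str], SusResponse]
    attrakdiff_responses: dict[tuple[str, str], AttrakDiffResponse]
    labels: pd.DataFrame     # per (subject, prototype): ATT, HQ, HQ-I, HQ-S, PQ, SUS
    latent: pd.Series        # latent usability per sample
    manifest: pd.DataFrame   # one row per recorded log

    @property
    def sample_keys(self) -> list[tuple[str, str]]:
        return list(self.labels.index)


def simulate_cohort(n_subjects_A: int = 10, n_subjects_B: int = 11,
                    m_images: int = 3, image_size: tuple[int, int] = (40, 40),
                    rng_seed: int = 0, item_noise: float = 0.06,
                    noise_sd: float = 0.10, contrast: float = 0.30,
                    record_practice: bool = False,
                    simulate_practice: bool = True) -> CohortResult:
    """Simulate the two-study design and synthetic questionnaire responses.

    Study 1: ``n_subjects_A`` subjects segment all ``m_images`` recorded
    images with both the semi-manual and guided prototypes, in randomized
    task order.  Study 2: ``n_subjects_B`` subjects use the joint
    prototype.  A practice image of moderate complexity is segmented first
    with each prototype but excluded from the recorded logs by default.
    Each (subject, prototype) sample carries a latent usability drawn
    uniformly, which shapes both the robot's behavior and the sample's
    questionnaire responses.

    Defaults give ``2 * n_A + n_B = 31`` samples.
    """
    if m_images < 1:
        raise ValueError("at least one recorded image is required")
    rng = np.random.default_rng(rng_seed)

    complexities = np.linspace(0.15, 0.75, m_images)
    images = [make_synthetic_image(c, noise_sd=noise_sd, size=image_size,
                                   rng_seed=int(rng.integers(2 ** 31)),
                                   contrast=contrast)
              for c in complexities]
    practice = make_synthetic_image(0.4, noise_sd=noise_sd, size=image_size,
                                    rng_seed=int(rng.integers(2 ** 31)),
                                    contrast=contrast)

    runners = {"semi_manual": run_semi_manual, "guided": run_guided, "joint": run_joint}
    tasks = []  # (subject, prototype)
    for a in range(n_subjects_A):
        subj = f"A{a:02d}"
        for proto in ("semi_manual", "guided"):
            tasks.append((subj, proto))
    for b in range(n_subjects_B):
        tasks.append((f"B{b:02d}", "joint"))

    logs, manifest_rows = [], []
    sus_resp, att_resp, label_rows, latents = {}, {}, [], {}
    for subj, proto in tasks:
        u = float(rng.uniform())
        latents[(subj, proto)] = u
        policy = policy_from_usability(u, rng_seed=int(rng.integers(2 ** 31)))
        run = runners[proto]
        if simulate_practice:
            plog = run(practice[0], practice[1], replace(
                policy, rng_seed=int(rng.integers(2 ** 31))),
                subject_id=subj, image_id="practice")
            if record_practice:
                logs.append(plog)
                manifest_rows.append((subj, proto, "practice", plog.final_dice))
        order = rng.permutation(m_images)  # randomized task order
        for k in order:
            img, gt = images[k]
            lg = run(img, gt, replace(policy, rng_seed=int(rng.integers(2 ** 31))),
                     subject_id=subj, image_id=f"img{k}")
            logs.append(lg)
            manifest_rows.append((subj, proto, f"img{k}", lg.final_dice))
        sus, att = questionnaires_from_usability(u, subj, rng, item_noise=item_noise)
        sus_resp[(subj, proto)] = sus
        att_resp[(subj, proto)] = att
        scores = attrakdiff_scores([att])
        label_rows.append({"subject": subj, "prototype": proto,
                           "ATT": scores.att, "HQ": scores.hq,
                           "HQ-I": scores.hq_i, "HQ-S": scores.hq_s,
                           "PQ": scores.pq, "SUS": sus_score([sus])})

    labels = pd.DataFrame(label_rows).set_index(["subject", "prototype"])
    latent = pd.Series(latents, name="usability")
    manifest = pd.DataFrame(manifest_rows,
                            columns=["subject", "prototype", "image", "final_dice"])
    return CohortResult(logs, sus_resp, att_resp, labels, latent, manifest)
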