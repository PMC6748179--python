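"""Seeded GrowCut segmentation as a cellular automaton with change counting.

Each pixel is an automaton cell with a label (none / background /
foreground), a strength in ``[0, 1]`` and a scalar intensity feature.  At
every synchronous step each cell may be conquered by the Moore neighbor
whose attack strength ``theta_f * g(c_e, c_f)`` strictly exceeds the cell's
own strength, where

    g(c_e, c_f) = 1 - |c_e - c_f| / max_pairwise_distance

is the intensity-similarity weight.  Seeds start at strength 1 and can never
be conquered (attack strength is bounded by 1 and conquest requires a strict
increase), so seed labels are invariant.  A per-cell counter ``h`` records
how often the cell's label flipped during the run; high counts mark regions
where the automaton was uncertain, which downstream seed suggestion exploits.

Strengths are monotonically non-decreasing per cell and bounded by 1, so the
automaton reaches a fixed point in finitely many steps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LABEL_NONE",
    "LABEL_BACKGROUND",
    "LABEL_FOREGROUND",
    "AutomatonState",
    "SegmentationResult",
    "transition_weight",
    "initialize_state",
    "step",
    "segment",
]

LABEL_NONE = 0
LABEL_BACKGROUND = 1
LABEL_FOREGROUND = 2

# Moore-neighbor scan order used for attacker tie-breaks: N, NE, E, SE, S,
# SW, W, NW as (dy, dx) offsets.  The first direction in this order wins
# among equal attack strengths.
_MOORE_OFFSETS = [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]


@dataclass
class AutomatonState:
    """Per-cell GrowCut state on the image grid."""

    labels: np.ndarray      # int8, {none, background, foreground}
    strengths: np.ndarray   # float64 in [0, 1]
    features: np.ndarray    # float64 intensities
    changes: np.ndarray     # int32 label-change counters h
    max_pairwise: float     # denominator of the similarity weight

    def copy(self) -> "AutomatonState":
        return AutomatonState(self.labels.copy(), self.strengths.copy(),
                              self.features, self.changes.copy(), self.max_pairwise)


@dataclass
class SegmentationResult:
    labels: np.ndarray       # final label matrix
    strengths: np.ndarray    # final strength matrix
    changes: np.ndarray      # final change-count matrix h
    iterations_run: int
    converged: bool

    @property
    def foreground(self) -> np.ndarray:
        """Binary foreground mask of the final labeling."""
        return self.labels == LABEL_FOREGROUND

    def probability_map(self) -> np.ndarray:
        """Soft foreground confidence derived from cell strengths.

        ``p = theta`` for foreground cells, ``1 - theta`` for background
        cells and ``0.5`` for unlabeled cells.
        """
        p = np.full(self.labels.shape, 0.5)
        fg = self.labels == LABEL_FOREGROUND
        bg = self.labels == LABEL_BACKGROUND
        p[fg] = self.strengths[fg]
        p[bg] = 1.0 - self.strengths[bg]
        return p


def transition_weight(c_e: float, c_f: float, max_pairwise: float) -> float:
    """Similarity weight g between two intensities, clamped to [0, 1].

    A degenerate (uniform) image has ``max_pairwise == 0``; every pair is
    then maximally similar and the weight is 1.
    """
    if max_pairwise < 0:
        raise ValueError("max_pairwise must be non-negative")
    if max_pairwise == 0:
        return 1.0
    return float(np.clip(1.0 - abs(c_e - c_f) / max_pairwise, 0.0, 1.0))


def initialize_state(image: np.ndarray, seeds) -> AutomatonState:
    """Build the initial automaton state from an image and labeled seeds.

    ``seeds`` is any iterable of objects with ``y``, ``x`` and ``label``
    attributes (see :mod:`segusim.seeds`) or ``(y, x, label)`` tuples.
    Seeds get strength 1; all other cells start unlabeled at strength 0
    with a zero change counter.
    """
    image = np.asarray(image, dtype=np.float64)
    labels = np.zeros(image.shape, dtype=np.int8)
    strengths = np.zeros(image.shape, dtype=np.float64)
    changes = np.zeros(image.shape, dtype=np.int32)
    n_seeds = 0
    for s in seeds:
        y, x, lab = (s.y, s.x, s.label) if hasattr(s, "y") else s
        if not (0 <= y < image.shape[0] and 0 <= x < image.shape[1]):
            raise ValueError(f"seed position ({y}, {x}) outside image {image.shape}")
        labels[y, x] = lab
        strengths[y, x] = 1.0
        n_seeds += 1
    if n_seeds == 0:
        raise ValueError("at least one seed is required")
    max_pairwise = float(image.max() - image.min())
    return AutomatonState(labels, strengths, image, changes, max_pairwise)


def step(state: AutomatonState) -> tuple[AutomatonState, bool]:
    """One synchronous automaton update.

    All cells read the time-t state and write t+1.  Among neighbors whose
    attack strength strictly exceeds the defender's, the maximal attacker
    wins; ties go to the first direction in the fixed scan order.  Returns
    the new state and whether anything changed.
    """
    labels, strengths, feats = state.labels, state.strengths, state.features
    h, w = labels.shape
    mp = state.max_pairwise

    best_strength = strengths.copy()          # defender strength = bar to beat
    new_labels = labels.copy()
    new_strengths = strengths.copy()
    conquered = np.zeros(labels.shape, dtype=bool)

    for dy, dx in _MOORE_OFFSETS:
        # Valid defender window and the matching attacker window.
        y0, y1 = max(0, -dy), min(h, h - dy)
        x0, x1 = max(0, -dx), min(w, w - dx)
        def_sl = (slice(y0, y1), slice(x0, x1))
        atk_sl = (slice(y0 + dy, y1 + dy), slice(x0 + dx, x1 + dx))

        atk_labels = labels[atk_sl]
        if mp == 0:
            g = 1.0
        else:
            g = 1.0 - np.abs(feats[def_sl] - feats[atk_sl]) / mp
            np.clip(g, 0.0, 1.0, out=g)
        attack = strengths[atk_sl] * g
        # "none" never attacks; strict > keeps earlier directions on ties.
        wins = (atk_labels != LABEL_NONE) & (attack > best_strength[def_sl])
        if not wins.any():
            continue
        best_strength[def_sl] = np.where(wins, attack, best_strength[def_sl])
        new_labels[def_sl] = np.where(wins, atk_labels, new_labels[def_sl])
        new_strengths[def_sl] = np.where(wins, attack, new_strengths[def_sl])
        conquered[def_sl] |= wins

    changed = bool(conquered.any())
    new_changes = state.changes + (new_labels != labels)
    return AutomatonState(new_labels, new_strengths, feats, new_changes, mp), changed


def segment(image: np.ndarray, seeds, max_iters: int | None = None) -> SegmentationResult:
    """Run GrowCut to its fixed point (or ``max_iters``, default w*h)."""
    state = initialize_state(image, seeds)
    if max_iters is None:
        max_iters = int(image.shape[0] * image.shape[1])
    converged = False
    it = 0
    for it in range(1, max_iters + 1):
        state, changed = step(state)
        if not changed:
            converged = True
            break
    if not converged and it >= 1:
        # One extra probe: if the last allowed iteration was also a fixed
        # point we still count as converged.
        probe, changed = step(state)
        if not changed:
            converged = True
    return SegmentationResult(state.labels, state.strengths, state.changes,
                              iterations_run=it, converged=converged)
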