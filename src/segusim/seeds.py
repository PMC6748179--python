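"""Seed-point model and system-side seed suggestion.

A seed is a labeled pixel position; a scribble set is the ordered,
cumulative collection of seeds over the interactions of one session.  Two
suggestion strategies are provided:

* *guided*: pick the k cells with the most label flips (the change counter
  ``h``) in the previous GrowCut run — the automaton's uncertainty hotspots;
* *joint*: rank cells by an influence map — a weighted sum of the image's
  gradient magnitude, the change counter (weighted 17/12) and proximity to
  the current segmentation contour — and greedily pick J well-separated
  maxima, labeled automatically by the current mask.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage

from .growcut import LABEL_BACKGROUND, LABEL_FOREGROUND

__all__ = [
    "SeedPoint",
    "ScribbleSet",
    "InfluenceMap",
    "border_background_seeds",
    "max_change_locations",
    "influence_map",
    "suggest_seeds",
    "long_press_seed",
]

#: Empirical weight of the change-counter component in the influence map.
CHANGE_WEIGHT = 17.0 / 12.0


@dataclass(frozen=True)
class SeedPoint:
    """One labeled seed: position, label, provenance, interaction index."""

    y: int
    x: int
    label: int  # LABEL_BACKGROUND or LABEL_FOREGROUND
    origin: str = "user_scribble"  # user_scribble|system_suggested|long_press|border_init
    n: int = 0

    def to_json(self) -> dict:
        return asdict(self)

    @classmethod
    def from_json(cls, d: dict) -> "SeedPoint":
        return cls(**d)


@dataclass
class ScribbleSet:
    """Ordered, cumulative seed collection S^0 ⊆ S^1 ⊆ … over interactions."""

    points: list[SeedPoint] = field(default_factory=list)

    def __iter__(self):
        return iter(self.points)

    def __len__(self) -> int:
        return len(self.points)

    def add(self, seeds) -> "ScribbleSet":
        """Return a new set extended by ``seeds``; duplicates within the new
        interaction (same position and label) are dropped."""
        existing = {(s.y, s.x, s.label) for s in self.points}
        fresh = []
        for s in seeds:
            key = (s.y, s.x, s.label)
            if key not in existing:
                existing.add(key)
                fresh.append(s)
        return ScribbleSet(self.points + fresh)

    def user_placed(self) -> list[SeedPoint]:
        return [s for s in self.points if s.origin != "border_init"]

    def dumps(self) -> str:
        return "\n".join(json.dumps(s.to_json()) for s in self.points)

    @classmethod
    def loads(cls, text: str) -> "ScribbleSet":
        pts = [SeedPoint.from_json(json.loads(line)) for line in text.splitlines() if line.strip()]
        return cls(pts)


@dataclass
class InfluenceMap:
    """Combined seed-location score with its component maps retained."""

    values: np.ndarray
    gradient: np.ndarray
    change: np.ndarray
    contour: np.ndarray


def border_background_seeds(image: np.ndarray, spacing: int = 1, n: int = 0) -> ScribbleSet:
    """Background seeds along the image border at the given spacing (S^0).

    The border is walked clockwise from the top-left corner; a spacing
    larger than the perimeter degenerates to the four corners.
    """
    if spacing < 1:
        raise ValueError("spacing must be >= 1")
    h, w = image.shape[:2]
    # Clockwise border walk starting at (0, 0).
    path = [(0, x) for x in range(w)]
    path += [(y, w - 1) for y in range(1, h)]
    path += [(h - 1, x) for x in range(w - 2, -1, -1)]
    path += [(y, 0) for y in range(h - 2, 0, -1)]
    chosen = {path[i] for i in range(0, len(path), spacing)}
    chosen |= {(0, 0), (0, w - 1), (h - 1, 0), (h - 1, w - 1)}
    pts = [SeedPoint(y, x, LABEL_BACKGROUND, origin="border_init", n=n)
           for (y, x) in sorted(chosen)]
    return ScribbleSet(pts)


def max_change_locations(h: np.ndarray, k: int = 2) -> tuple[list[tuple[int, int]], bool]:
    """The k positions with the largest change counts, row-major tie-break.

    Returns ``(positions, fallback)``.  If ``h`` is identically zero there
    is no uncertainty signal; positions then fall back to the first k cells
    in row-major order and ``fallback`` is True.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    h = np.asarray(h)
    flat = h.ravel()
    fallback = not np.any(flat > 0)
    # stable sort on negated values keeps row-major order among ties
    order = np.argsort(-flat, kind="stable")[:k]
    pos = [tuple(map(int, np.unravel_index(i, h.shape))) for i in order]
    return pos, fallback


def _minmax(a: np.ndarray) -> np.ndarray:
    lo, hi = float(a.min()), float(a.max())
    if hi - lo == 0:
        return np.zeros_like(a, dtype=np.float64)
    return (a - lo) / (hi - lo)


def _contour_pixels(mask: np.ndarray) -> np.ndarray:
    """Boundary pixels of the foreground: set members with a non-member
    4-neighbor."""
    mask = mask.astype(bool)
    eroded = ndimage.binary_erosion(mask, structure=ndimage.generate_binary_structure(2, 1),
                                    border_value=0)
    return mask & ~eroded


def influence_map(image: np.ndarray, h: np.ndarray, current_mask: np.ndarray) -> InfluenceMap:
    """Score candidate seed locations for the joint prototype.

    ``M = norm(|grad I|) + (17/12) * norm(h) + norm(D)`` where each
    component is min-max normalized to ``[0, 1]`` (all-zero components stay
    zero) and ``D = 1 / (1 + d)`` scores proximity to the current contour
    (``d`` = Euclidean distance to the nearest contour pixel).  An empty
    mask has no contour, so ``D`` is identically zero.  Min-max
    normalization makes the map invariant under affine rescaling of the
    image intensities.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.shape != np.asarray(h).shape or image.shape != np.asarray(current_mask).shape:
        raise ValueError("image, h and mask shapes must agree")
    gy, gx = np.gradient(image)  # central differences, replicated borders
    grad = _minmax(np.hypot(gy, gx))
    change = _minmax(np.asarray(h, dtype=np.float64))

    contour = _contour_pixels(np.asarray(current_mask))
    if contour.any():
        dist = ndimage.distance_transform_edt(~contour)
        proximity = _minmax(1.0 / (1.0 + dist))
    else:
        proximity = np.zeros_like(image)

    values = grad + CHANGE_WEIGHT * change + proximity
    return InfluenceMap(values=values, gradient=grad, change=change, contour=proximity)


def suggest_seeds(imap: InfluenceMap | np.ndarray, current_mask: np.ndarray,
                  J: int = 20, min_separation: int | None = None,
                  n: int = 0) -> tuple[list[SeedPoint], bool]:
    """Greedy pick of J well-separated influence maxima, auto-labeled.

    Positions are taken in descending map value (row-major tie-break),
    skipping any candidate within ``min_separation`` (Chebyshev distance)
    of an already chosen one.  Each seed is labeled foreground iff it lies
    inside the current mask.  Returns ``(seeds, shortfall)`` where
    ``shortfall`` flags fewer than J admissible positions.
    """
    if J < 1:
        raise ValueError("J must be >= 1")
    values = imap.values if isinstance(imap, InfluenceMap) else np.asarray(imap)
    mask = np.asarray(current_mask).astype(bool)
    if min_separation is None:
        min_separation = max(3, int(np.ceil(0.03 * min(values.shape))))

    order = np.argsort(-values.ravel(), kind="stable")
    chosen: list[tuple[int, int]] = []
    for idx in order:
        y, x = np.unravel_index(idx, values.shape)
        y, x = int(y), int(x)
        if any(max(abs(y - cy), abs(x - cx)) < min_separation for cy, cx in chosen):
            continue
        chosen.append((y, x))
        if len(chosen) == J:
            break
    seeds = [SeedPoint(y, x, LABEL_FOREGROUND if mask[y, x] else LABEL_BACKGROUND,
                       origin="system_suggested", n=n)
             for y, x in chosen]
    return seeds, len(seeds) < J


def long_press_seed(current_mask: np.ndarray, position: tuple[int, int], n: int = 0) -> SeedPoint:
    """Seed from a long-press: label inverts the mask's label at that spot."""
    y, x = position
    mask = np.asarray(current_mask).astype(bool)
    if not (0 <= y < mask.shape[0] and 0 <= x < mask.shape[1]):
        raise ValueError("long-press position outside image")
    label = LABEL_BACKGROUND if mask[y, x] else LABEL_FOREGROUND
    return SeedPoint(int(y), int(x), label, origin="long_press", n=n)
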