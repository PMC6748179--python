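"""SUS and AttrakDiff-2 questionnaire scoring, adjective mapping, portfolio.

The System Usability Scale (SUS) is ten alternating positively / negatively
keyed statements answered on a five-point Likert scale coded 0–4.  The
score over S subjects is

    sus(x) = (2.5 / S) * sum_s [ sum_{odd i} x_{s,i} + sum_{even i} (4 - x_{s,i}) ]

which ranges 0–100; an all-neutral respondent (all 2) scores 50.  A single
score maps to a seven-step adjective scale (worst imaginable … best
imaginable) by proximity to published per-adjective mean anchors.

AttrakDiff-2 is 28 bipolar adjective pairs on a 1–7 scale, seven pairs per
group: pragmatic quality (PQ), attractiveness (ATT), hedonic identity
(HQ-I) and hedonic stimulus (HQ-S).  Each group scores the mean over
subjects and items,

    attrakdiff(x, g) = 1 / (7 S) * sum_s sum_i x^g_{s,i}

and HQ is the mean of HQ-I and HQ-S.  Presentation randomizes both pair
order and pair polarity; de-randomization restores the canonical order,
mapping flipped responses x -> 8 - x.  The portfolio representation places
a system at (PQ, HQ) with a 95% t-based confidence rectangle inside a
partition of the [1,7]^2 plane into named character fields.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy import stats

__all__ = [
    "SusResponse",
    "AttrakDiffResponse",
    "UsabilityScores",
    "sus_score",
    "sus_adjective",
    "attrakdiff_scores",
    "randomize_presentation",
    "de_randomize",
    "portfolio",
    "Portfolio",
    "attrakdiff_pairs",
    "SUS_ADJECTIVE_ANCHORS",
    "ATTRAKDIFF_GROUPS",
]

ATTRAKDIFF_GROUPS = ("PQ", "ATT", "HQ-I", "HQ-S")

#: Published mean SUS score per adjective (Bangor et al.'s 959-survey
#: calibration); classification is by nearest anchor.  Configurable.
SUS_ADJECTIVE_ANCHORS: dict[str, float] = {
    "worst imaginable": 12.5,
    "awful": 20.3,
    "poor": 35.7,
    "OK": 50.9,
    "good": 71.4,
    "excellent": 85.5,
    "best imaginable": 90.9,
}

#: Conventional 3x3 partition of the (PQ, HQ) plane with cut points 3 and 5.
#: Cells are keyed (pq_band, hq_band) with bands 0=low, 1=mid, 2=high; the
#: two cells the seven conventional labels leave unnamed map to "neutral".
PORTFOLIO_FIELDS: dict[tuple[int, int], str] = {
    (2, 2): "desired",
    (2, 1): "task-oriented",
    (2, 0): "too task-oriented",
    (1, 2): "self-oriented",
    (0, 2): "too self-oriented",
    (1, 1): "neutral",
    (0, 0): "superfluous",
    (1, 0): "neutral",
    (0, 1): "neutral",
}


@dataclass
class SusResponse:
    """One subject's ten SUS item responses, each in {0, ..., 4}."""

    subject: str
    items: list[int]

    def __post_init__(self):
        if len(self.items) != 10:
            raise ValueError("SUS requires exactly 10 items")
        if any(not 0 <= int(v) <= 4 for v in self.items):
            raise ValueError("SUS items must lie in {0,...,4}")


@dataclass
class AttrakDiffResponse:
    """One subject's 28 AttrakDiff-2 item responses, 7 per group in {1..7}.

    ``presentation`` optionally records the randomized pair order and
    per-pair polarity flips used during administration.
    """

    subject: str
    groups: dict[str, list[int]]
    presentation: dict | None = None

    def __post_init__(self):
        if set(self.groups) != set(ATTRAKDIFF_GROUPS):
            raise ValueError(f"groups must be exactly {ATTRAKDIFF_GROUPS}")
        for g, items in self.groups.items():
            if len(items) != 7:
                raise ValueError(f"group {g} must have exactly 7 items")
            if any(not 1 <= int(v) <= 7 for v in items):
                raise ValueError("AttrakDiff items must lie in {1,...,7}")


@dataclass
class UsabilityScores:
    sus: float | None = None
    pq: float | None = None
    att: float | None = None
    hq_i: float | None = None
    hq_s: float | None = None

    @property
    def hq(self) -> float | None:
        if self.hq_i is None or self.hq_s is None:
            return None
        return (self.hq_i + self.hq_s) / 2.0

    def as_dict(self) -> dict[str, float | None]:
        return {"ATT": self.att, "HQ": self.hq, "HQ-I": self.hq_i,
                "HQ-S": self.hq_s, "PQ": self.pq, "SUS": self.sus}


def sus_score(responses: list[SusResponse]) -> float:
    """SUS score over all subjects, in [0, 100].

    Odd-indexed (1-based) statements are positively keyed and contribute
    their raw value; even-indexed statements are negatively keyed and
    contribute ``4 - x``.
    """
    if not responses:
        raise ValueError("at least one response is required")
    total = 0.0
    for r in responses:
        for i, x in enumerate(r.items, start=1):
            total += x if i % 2 == 1 else 4 - x
    return 2.5 * total / len(responses)


def sus_adjective(score: float,
                  anchors: dict[str, float] = SUS_ADJECTIVE_ANCHORS) -> str:
    """Map a SUS score to the adjective with the nearest anchor mean."""
    if not 0.0 <= score <= 100.0:
        raise ValueError("SUS score must lie in [0, 100]")
    return min(anchors, key=lambda a: (abs(score - anchors[a]), anchors[a]))


def attrakdiff_scores(responses: list[AttrakDiffResponse]) -> UsabilityScores:
    """Mean score per group over subjects and items; HQ = (HQ-I + HQ-S)/2."""
    if not responses:
        raise ValueError("at least one response is required")
    means = {}
    for g in ATTRAKDIFF_GROUPS:
        total = sum(sum(r.groups[g]) for r in responses)
        means[g] = total / (7.0 * len(responses))
    return UsabilityScores(pq=means["PQ"], att=means["ATT"],
                           hq_i=means["HQ-I"], hq_s=means["HQ-S"])


# ---------------------------------------------------------------------------
# Presentation randomization

def attrakdiff_pairs() -> list[dict]:
    """The 28 canonical adjective pairs with their group and in-group index."""
    with resources.files("segusim.data").joinpath("attrakdiff_pairs.csv").open() as fh:
        return list(csv.DictReader(fh))


def randomize_presentation(rng_seed: int, n_pairs: int = 28) -> dict:
    """Random pair order and per-pair polarity flips for administration."""
    rng = np.random.default_rng(rng_seed)
    return {"order": [int(i) for i in rng.permutation(n_pairs)],
            "flips": [bool(b) for b in rng.integers(0, 2, size=n_pairs)]}

def de_randomize(presented: list[int], presentation: dict) -> list[int]:
    """Invert a presentation: restore canonical pair order and polarity.

    ``presented[j]`` is the response to the pair shown at position j;
    a flipped pair's response maps ``x -> 8 - x``.
    """
    order, flips = presentation["order"], presentation["flips"]
    if len(presented) != len(order):
        raise ValueError("response length does not match presentation")
    canonical = [0] * len(order)
    for j, idx in enumerate(order):
        x = presented[j]
        canonical[idx] = 8 - x if flips[idx] else x
    return canonical


def apply_randomization(canonical: list[int], presentation: dict) -> list[int]:
    """Forward map: canonical responses to their presented order/polarity."""
    order, flips = presentation["order"], presentation["flips"]
    return [8 - canonical[idx] if flips[idx] else canonical[idx] for idx in order]


# ---------------------------------------------------------------------------
# Portfolio representation

@dataclass
class Portfolio:
    pq_mean: float
    hq_mean: float
    pq_halfwidth: float | None
    hq_halfwidth: float | None
    n: int
    confidence: float
    fields: list[str] = field(default_factory=list)

    @property
    def dominant_field(self) -> str | None:
        return self.fields[0] if len(self.fields) == 1 else None

    def overlaps(self, other: "Portfolio", dimension: str) -> bool:
        """Whether the two rectangles overlap in the given 1-D projection
        ('PQ' or 'HQ') — overlapping projections mean the difference in
        that dimension is not significant."""
        if dimension == "PQ":
            a = (self.pq_mean, self.pq_halfwidth or 0.0)
            b = (other.pq_mean, other.pq_halfwidth or 0.0)
        elif dimension == "HQ":
            a = (self.hq_mean, self.hq_halfwidth or 0.0)
            b = (other.hq_mean, other.hq_halfwidth or 0.0)
        else:
            raise ValueError("dimension must be 'PQ' or 'HQ'")
        return abs(a[0] - b[0]) <= a[1] + b[1]

    def as_dict(self) -> dict:
        return {"pq_mean": self.pq_mean, "hq_mean": self.hq_mean,
                "pq_halfwidth": self.pq_halfwidth, "hq_halfwidth": self.hq_halfwidth,
                "n": self.n, "confidence": self.confidence, "fields": self.fields}


def _band(v: float, cuts: tuple[float, float] = (3.0, 5.0)) -> int:
    return 0 if v < cuts[0] else (1 if v < cuts[1] else 2)


def portfolio(samples: list[UsabilityScores], confidence: float = 0.95,
              field_map: dict[tuple[int, int], str] = PORTFOLIO_FIELDS) -> Portfolio:
    """Portfolio rectangle from per-subject PQ/HQ scores.

    Mean and two-sided t-based confidence half-width per dimension; the
    rectangle is labeled with the single field containing it entirely, or
    with every field it overlaps.  A single subject yields an undefined
    (None) half-width.
    """
    pq = np.array([s.pq for s in samples], dtype=float)
    hq = np.array([s.hq for s in samples], dtype=float)
    if pq.size == 0:
        raise ValueError("at least one sample is required")
    n = pq.size
    if n >= 2:
        tcrit = stats.t.ppf(0.5 + confidence / 2.0, df=n - 1)
        half_pq = float(tcrit * pq.std(ddof=1) / np.sqrt(n))
        half_hq = float(tcrit * hq.std(ddof=1) / np.sqrt(n))
    else:
        half_pq = half_hq = None

    hp, hh = half_pq or 0.0, half_hq or 0.0
    corners_pq = (pq.mean() - hp, pq.mean() + hp)
    corners_hq = (hq.mean() - hh, hq.mean() + hh)
    touched = sorted({field_map[(_band(p), _band(h))]
                      for p in corners_pq for h in corners_hq})
    return Portfolio(float(pq.mean()), float(hq.mean()), half_pq, half_hq,
                     n=n, confidence=confidence, fields=touched)


def plot_portfolio(portfolios: dict[str, Portfolio], path) -> None:
    """Static PQ-vs-HQ portfolio figure with confidence rectangles."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Rectangle

    fig, ax = plt.subplots(figsize=(5, 5))
    for c in (3.0, 5.0):
        ax.axhline(c, color="0.8", lw=0.8)
        ax.axvline(c, color="0.8", lw=0.8)
    colors = plt.rcParams["axes.prop_cycle"].by_key()["color"]
    for (name, p), col in zip(portfolios.items(), colors):
        hp, hh = p.pq_halfwidth or 0.0, p.hq_halfwidth or 0.0
        ax.add_patch(Rectangle((p.pq_mean - hp, p.hq_mean - hh), 2 * hp, 2 * hh,
                               alpha=0.3, color=col))
        ax.plot([p.pq_mean], [p.hq_mean], "o", color=col, label=name)
    ax.set_xlim(1, 7)
    ax.set_ylim(1, 7)
    ax.set_xlabel("Pragmatic quality (PQ)")
    ax.set_ylabel("Hedonic quality (HQ)")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
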