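"""Deterministic feature extraction from interaction logs.

One sample is one (subject, prototype) pair.  The pipeline has three
stages with fixed cardinalities:

1. **48 base features** — 4 relative seed-position statistics (median and
   standard deviation of user-placed seed x and y, normalized by image
   size, pooled over the sample's logs) plus the mean and the median of
   each of 22 per-segmentation scalars across the sample's recorded
   segmentations.
2. **216 log-derived features** — the 48 base features, 156 ratio
   composites (base feature divided by a mean or median time summary) and
   12 time-relation ratios among the three time summaries themselves.
3. **238 features** — the 216 plus 22 principal-component scores of the
   standardized table (10% of 216, rounded up), fitted once and persisted
   for test-time application.

Extraction is a pure function of the logs; re-extraction is bit-identical.
Undefined values (division by zero, degenerate metrics) are imputed with 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler

from . import metrics
from .growcut import LABEL_FOREGROUND
from .session import InteractionLog

__all__ = [
    "PER_SEGMENTATION_FEATURES",
    "SEED_POSITION_FEATURES",
    "per_segmentation_features",
    "base_features",
    "composite_features",
    "build_feature_table",
    "pca_augment",
    "PcaTransform",
    "column_registry",
    "group_logs_by_sample",
]

#: The 22 per-segmentation scalars (fixed catalogue).
PER_SEGMENTATION_FEATURES = [
    "#Interactions", "#Undos", "#Seeds", "#FG_seeds", "#BG_seeds",
    "#Label_toggles", "Σctime", "Σitime", "Σwtime", "Med_ctime", "Med_itime",
    "Med_wtime", "Final_Dice_score", "Final_Jaccard", "Final_Rand_index",
    "ROC_AUC", "RAVD", "MSE", "LOG", "OBJ_TPR", "OBJ_TNR",
    "Dice_trajectory_AUC",
]

SEED_POSITION_FEATURES = [
    "Med(Relative_Seed_Coord_W)", "Med(Relative_Seed_Coord_H)",
    "Std(Relative_Seed_Coord_W)", "Std(Relative_Seed_Coord_H)",
]

#: Shorthand used in composite column names (mirrors how the final-mask
#: metrics are commonly abbreviated in feature listings).
_SHORT = {"Final_Dice_score": "Dice", "Final_Jaccard": "Jaccard",
          "Final_Rand_index": "Rand_index"}

_TIME_SUMS = ["Σctime", "Σitime", "Σwtime"]


def _finite(x: float) -> float:
    """Imputation rule: non-finite values (0/0, x/0) become 0."""
    x = float(x)
    return x if np.isfinite(x) else 0.0


def per_segmentation_features(log: InteractionLog) -> dict[str, float]:
    """The 22 per-segmentation scalars of one interaction log."""
    if log.final_result is None or log.ground_truth is None:
        raise ValueError("log must carry its final result and ground truth")
    events = log.events
    n_undo = sum(1 for e in events if e.event_type == "undo")
    n_toggle = sum(1 for e in events if e.event_type == "toggle_label")
    n_inter = sum(1 for e in events if e.event_type != "finish")

    seeds = []
    for e in events:
        seeds.extend(e.payload.get("seeds", []))
    n_fg = sum(1 for s in seeds if s["label"] == LABEL_FOREGROUND)

    itimes = [e.interaction_time for e in events]
    ctimes = [e.computation_time for e in events]
    walls = [e.wall_clock_time for e in events]
    wdeltas = np.diff([0.0] + walls) if walls else np.array([0.0])

    pred = log.final_result.foreground
    gt = log.ground_truth
    prob = log.final_result.probability_map()
    traj = metrics.dice_trajectory(log)

    def safe(fn, *args):
        try:
            return _finite(fn(*args))
        except metrics.UndefinedMetricError:
            return 0.0

    return {
        "#Interactions": float(n_inter),
        "#Undos": float(n_undo),
        "#Seeds": float(len(seeds)),
        "#FG_seeds": float(n_fg),
        "#BG_seeds": float(len(seeds) - n_fg),
        "#Label_toggles": float(n_toggle),
        "Σctime": _finite(np.sum(ctimes)) if ctimes else 0.0,
        "Σitime": _finite(np.sum(itimes)) if itimes else 0.0,
        "Σwtime": _finite(walls[-1]) if walls else 0.0,
        "Med_ctime": _finite(np.median(ctimes)) if ctimes else 0.0,
        "Med_itime": _finite(np.median(itimes)) if itimes else 0.0,
        "Med_wtime": _finite(np.median(wdeltas)),
        "Final_Dice_score": safe(metrics.dice, pred, gt),
        "Final_Jaccard": safe(metrics.jaccard, pred, gt),
        "Final_Rand_index": safe(metrics.rand_index, pred, gt),
        "ROC_AUC": safe(metrics.roc_auc, prob, gt),
        "RAVD": safe(metrics.ravd, pred, gt),
        "MSE": safe(metrics.mse, pred, gt),
        "LOG": safe(metrics.log_loss, prob, gt),
        "OBJ_TPR": safe(metrics.obj_tpr, pred, gt),
        "OBJ_TNR": safe(metrics.obj_tnr, pred, gt),
        "Dice_trajectory_AUC": _finite(metrics.trajectory_auc(traj)),
    }


def base_features(logs: list[InteractionLog]) -> dict[str, float]:
    """The 48 base features of one sample (its recorded logs pooled)."""
    if not logs:
        raise ValueError("a sample needs at least one log")
    xs, ys = [], []
    for lg in logs:
        h, w = lg.ground_truth.shape
        for e in lg.events:
            for s in e.payload.get("seeds", []):
                xs.append(s["x"] / (w - 1))
                ys.append(s["y"] / (h - 1))
    out: dict[str, float] = {}
    if xs:
        out["Med(Relative_Seed_Coord_W)"] = _finite(np.median(xs))
        out["Med(Relative_Seed_Coord_H)"] = _finite(np.median(ys))
        out["Std(Relative_Seed_Coord_W)"] = _finite(np.std(xs))
        out["Std(Relative_Seed_Coord_H)"] = _finite(np.std(ys))
    else:  # no user-placed seeds: neutral position, zero spread
        out["Med(Relative_Seed_Coord_W)"] = 0.5
        out["Med(Relative_Seed_Coord_H)"] = 0.5
        out["Std(Relative_Seed_Coord_W)"] = 0.0
        out["Std(Relative_Seed_Coord_H)"] = 0.0

    per_seg = pd.DataFrame([per_segmentation_features(lg) for lg in logs])
    for name in PER_SEGMENTATION_FEATURES:
        col = per_seg[name].to_numpy()
        out[f"Mean({_SHORT.get(name, name)})"] = _finite(col.mean())
        out[f"Med({_SHORT.get(name, name)})"] = _finite(np.median(col))
    return out


def composite_features(base: dict[str, float]) -> dict[str, float]:
    """Extend 48 base features to the full 216 log-derived features.

    Adds 156 ratios (seed-position and aggregated features divided by time
    summaries) and 12 time-relation ratios.  Division by zero imputes 0.
    """
    out = dict(base)

    def ratio(a: float, b: float) -> float:
        return _finite(a / b) if b != 0 else 0.0

    mean_times = [f"Mean({t})" for t in _TIME_SUMS]
    med_times = [f"Med({t})" for t in _TIME_SUMS]

    # (a) 4 seed-position features / 6 time summaries = 24
    for sp in SEED_POSITION_FEATURES:
        for ts in mean_times + med_times:
            out[f"{sp}/{ts}"] = ratio(base[sp], base[ts])
    # (b) 22 mean-aggregated features / 3 mean time summaries = 66
    # (c) 22 median-aggregated features / 3 median time summaries = 66
    for name in PER_SEGMENTATION_FEATURES:
        short = _SHORT.get(name, name)
        for ts in mean_times:
            out[f"Mean({short})/{ts}"] = ratio(base[f"Mean({short})"], base[ts])
        for ts in med_times:
            out[f"Med({short})/{ts}"] = ratio(base[f"Med({short})"], base[ts])
    # (d) 12 time relations: ordered pairs within the mean and within the
    # median time summaries.  Named with ':' so they stay distinct from the
    # ratio columns of stage (b)/(c) that share the same arithmetic.
    for group in (mean_times, med_times):
        for a in group:
            for b in group:
                if a != b:
                    out[f"{a}:{b}"] = ratio(base[a], base[b])
    return out


def group_logs_by_sample(logs: list[InteractionLog]) -> dict[tuple[str, str], list[InteractionLog]]:
    grouped: dict[tuple[str, str], list[InteractionLog]] = {}
    for lg in logs:
        grouped.setdefault((lg.subject_id, lg.prototype), []).append(lg)
    return grouped


def build_feature_table(logs: list[InteractionLog]) -> pd.DataFrame:
    """216-column feature table, one row per (subject, prototype) sample."""
    rows = {}
    for key, sample_logs in group_logs_by_sample(logs).items():
        rows[key] = composite_features(base_features(sample_logs))
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index = pd.MultiIndex.from_tuples(rows.keys(), names=["subject", "prototype"])
    return table


@dataclass
class PcaTransform:
    """Persisted standardization + PCA for test-time application."""

    columns: list[str]          # non-constant input columns used for the fit
    scaler: StandardScaler
    pca: PCA
    n_components: int
    capped: bool                # fewer components than requested

    def apply(self, table: pd.DataFrame) -> pd.DataFrame:
        z = self.scaler.transform(table[self.columns].to_numpy())
        scores = self.pca.transform(z)
        pcs = pd.DataFrame(scores, index=table.index,
                           columns=[f"PCA_VAL_{i}" for i in range(self.n_components)])
        return pd.concat([table, pcs], axis=1)


def pca_augment(table: pd.DataFrame, fraction: float = 0.1
                ) -> tuple[pd.DataFrame, PcaTransform]:
    """Append ceil(fraction * n_columns) principal-component score columns.

    Columns are standardized to zero mean / unit variance first; constant
    columns are dropped from the fit but retained in the table.  With 216
    input columns the default adds 22 components for a 238-column table
    (capped, and flagged, when the sample count cannot support them).
    """
    n_req = int(np.ceil(fraction * table.shape[1]))
    values = table.to_numpy(dtype=float)
    nonconst = table.columns[values.std(axis=0) > 0].tolist()
    n_comp = min(n_req, len(nonconst), max(1, table.shape[0] - 1))
    scaler = StandardScaler().fit(table[nonconst].to_numpy())
    pca = PCA(n_components=n_comp, svd_solver="full").fit(
        scaler.transform(table[nonconst].to_numpy()))
    transform = PcaTransform(columns=nonconst, scaler=scaler, pca=pca,
                             n_components=n_comp, capped=n_comp < n_req)
    return transform.apply(table), transform


def column_registry(columns: list[str]) -> pd.Series:
    """Provenance of each feature column: base | ratio | time_relation | pca."""
    out = {}
    for c in columns:
        if c.startswith("PCA_VAL_"):
            out[c] = "pca"
        elif ":" in c:
            out[c] = "time_relation"
        elif "/" in c:
            out[c] = "ratio"
        else:
            out[c] = "base"
    return pd.Series(out, name="provenance")
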