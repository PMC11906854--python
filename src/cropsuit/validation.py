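"""Presence/absence validation of suitability maps.

Absences are drawn uniformly at random over eligible cells — excluding the
highly-suitable class (S1), nodata, and (by default) constraint-masked
non-cropland cells, so pseudo-absences stay comparable to mapped
suitability.  Suitability scores are extracted at presence and absence
coordinates and summarized as the area under the ROC curve, which equals the
probability that a random presence outscores a random absence
(Mann–Whitney, midrank ties).  AUROC > 0.9 is read as very high accuracy,
0.7–0.9 as high, < 0.7 as low.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve

from .errors import SuitabilityError
from .grids import CategoricalGrid, Grid
from .overlay import NONCROPLAND_CODE

log = logging.getLogger(__name__)

S1_CODE = 1

PRESENCE = "presence"
ABSENCE = "absence"


@dataclass
class RocResult:
    """ROC curve, AUROC and the accuracy band it falls in."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auroc: float
    n_presence: int
    n_absence: int

    @property
    def band(self) -> str:
        if self.auroc > 0.9:
            return "very high"
        if self.auroc >= 0.7:
            return "high"
        return "low"

    def to_dict(self) -> dict:
        return {
            "auroc": self.auroc,
            "band": self.band,
            "n_presence": self.n_presence,
            "n_absence": self.n_absence,
        }

    def curve_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"threshold": self.thresholds, "fpr": self.fpr, "tpr": self.tpr}
        )


def dedupe_points(points: pd.DataFrame) -> pd.DataFrame:
    """Drop exact-coordinate duplicates within each label."""
    return points.drop_duplicates(subset=["x", "y", "label"]).reset_index(drop=True)


def sample_absences(
    classes: CategoricalGrid,
    n: int,
    seed: int,
    allow_noncropland: bool = False,
) -> pd.DataFrame:
    """``n`` absence points, uniform over eligible cells (seeded).

    Eligible cells exclude S1, nodata, and — unless ``allow_noncropland`` —
    cells masked as non-cropland.  Points are placed at cell centers, at most
    one per cell, so coordinates never repeat.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    eligible = classes.mask & (classes.codes != S1_CODE)
    if not allow_noncropland:
        eligible &= classes.codes != NONCROPLAND_CODE
    rows, cols = np.nonzero(eligible)
    if len(rows) < n:
        raise SuitabilityError(
            f"only {len(rows)} eligible cells for {n} absence points"
        )
    rng = np.random.default_rng(seed)
    pick = rng.choice(len(rows), size=n, replace=False)
    xy = np.array([classes.cell_center(r, c) for r, c in zip(rows[pick], cols[pick])])
    return pd.DataFrame({"x": xy[:, 0], "y": xy[:, 1], "label": ABSENCE})


def extract(index: Grid, points: pd.DataFrame) -> pd.DataFrame:
    """Per-point (score, label) from the index grid.

    Points on nodata cells are dropped with a logged count; an all-nodata
    point set is an error.  Points must lie inside the grid extent.
    """
    scores = []
    keep = []
    for _, row in points.iterrows():
        r, c = index.point_to_index(float(row["x"]), float(row["y"]))
        ok = bool(index.mask[r, c])
        keep.append(ok)
        scores.append(index.values[r, c] if ok else np.nan)
    dropped = len(points) - sum(keep)
    if dropped:
        log.info("extract: dropped %d point(s) on nodata cells", dropped)
    out = points.loc[keep, ["x", "y", "label"]].copy()
    out["score"] = [s for s, k in zip(scores, keep) if k]
    if out.empty:
        raise SuitabilityError("all points fall on nodata cells")
    return out.reset_index(drop=True)


def auroc(scored: pd.DataFrame) -> RocResult:
    """ROC/AUROC from a (score, label) frame with midrank tie handling."""
    labels = scored["label"].to_numpy()
    scores = scored["score"].to_numpy(dtype=float)
    y = labels == PRESENCE
    n1, n0 = int(y.sum()), int((~y).sum())
    if n1 == 0 or n0 == 0:
        raise SuitabilityError(
            f"AUROC needs both classes (got {n1} presences, {n0} absences)"
        )
    auc = float(roc_auc_score(y, scores))
    fpr, tpr, thresholds = roc_curve(y, scores)
    return RocResult(
        thresholds=thresholds, fpr=fpr, tpr=tpr, auroc=auc,
        n_presence=n1, n_absence=n0,
    )


def area_correlation(predicted, observed) -> float:
    """Pearson R between predicted and observed per-district areas."""
    x = np.asarray(predicted, dtype=float)
    y = np.asarray(observed, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("predicted and observed must be 1-D and paired")
    if len(x) < 3:
        raise SuitabilityError("correlation needs at least 3 paired districts")
    if np.std(x) == 0 or np.std(y) == 0:
        raise SuitabilityError("zero variance in one of the area vectors")
    return float(stats.pearsonr(x, y).statistic)
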