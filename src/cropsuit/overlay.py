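"""Weighted overlay, equal-interval classification, constraint masking, areas.

The suitability index is the weighted overlay

    S(cell) = Σ_i W_i · w_i(cell)

with W_i the criterion weight from the AHP audit and w_i(cell) the subclass
weight the cell's value falls in for criterion i.  The index is split into
four classes (S1 highly, S2 moderately, S3 marginally, N not suitable) at
equal intervals of the observed index range, then cells whose land cover
bars cultivation are recoded ``non-cropland``, and class areas are tabulated
in hectares.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import DomainError, SuitabilityError
from .grids import CategoricalGrid, Grid, check_aligned

#: Class codes for the 4-class suitability legend (S1 best).
CLASS_LEGEND = {1: "S1", 2: "S2", 3: "S3", 4: "N"}
NONCROPLAND_CODE = 0
MASKED_LEGEND = {NONCROPLAND_CODE: "non-cropland", **CLASS_LEGEND}


@dataclass
class ConstraintMap:
    """LULC grid plus the cropland / non-cropland partition of its legend."""

    lulc: CategoricalGrid
    cropland: frozenset
    noncropland: frozenset

    def __post_init__(self) -> None:
        legend_labels = set(self.lulc.legend.values())
        if self.cropland & self.noncropland:
            raise ValueError("cropland and non-cropland sets overlap")
        missing = legend_labels - (self.cropland | self.noncropland)
        if missing:
            raise DomainError(f"LULC classes not assigned to a partition side: {sorted(missing)}")

    def noncropland_mask(self) -> np.ndarray:
        codes = {c for c, lbl in self.lulc.legend.items() if lbl in self.noncropland}
        return np.isin(self.lulc.codes, list(codes)) & self.lulc.mask


@dataclass
class SuitabilityResult:
    """Everything one overlay run produces."""

    index: Grid
    classes: CategoricalGrid
    masked_classes: CategoricalGrid
    areas_before: pd.DataFrame
    areas_after: pd.DataFrame
    breaks: tuple[float, float, float]


def weighted_overlay(
    weight_layers: Mapping[str, Grid], criterion_weights: Mapping[str, float]
) -> Grid:
    """Cellwise Σ_i W_i · w_i; nodata in any layer propagates."""
    missing = set(criterion_weights) - set(weight_layers)
    if missing:
        raise SuitabilityError(f"missing criterion layer(s): {sorted(missing)}")
    extra = set(weight_layers) - set(criterion_weights)
    if extra:
        raise SuitabilityError(f"layer(s) without a criterion weight: {sorted(extra)}")
    total = sum(criterion_weights.values())
    if abs(total - 1.0) > 1e-6:
        raise SuitabilityError(f"criterion weights sum to {total}, expected 1 ± 1e-6")
    check_aligned(dict(weight_layers))
    names = sorted(criterion_weights)
    tpl = weight_layers[names[0]]
    acc = np.zeros(tpl.shape)
    valid = np.ones(tpl.shape, dtype=bool)
    for name in names:
        layer = weight_layers[name]
        valid &= layer.mask
        acc += criterion_weights[name] * np.where(layer.mask, layer.values, 0.0)
    return tpl.copy_with(np.where(valid, acc, -9999.0), nodata=-9999.0, units="suitability index")


def equal_interval_breaks(vmin: float, vmax: float, n_classes: int = 4) -> tuple[float, ...]:
    """Interior break values min + k·(max − min)/n, k = 1..n−1."""
    if not vmax > vmin:
        raise SuitabilityError(
            f"degenerate classification: index range [{vmin}, {vmax}] has zero width; "
            "an equal-interval split needs a non-constant index"
        )
    width = (vmax - vmin) / n_classes
    return tuple(vmin + k * width for k in range(1, n_classes))


def equal_interval_classify(index: Grid, n_classes: int = 4) -> CategoricalGrid:
    """Classify the index into S1..N at equal intervals of its observed range.

    The highest interval becomes S1; a value exactly on an interior break
    goes to the upper (more suitable) class, and the maximum goes to S1.
    """
    if n_classes != 4:
        raise ValueError("the suitability legend is defined for 4 classes")
    vals = index.valid_values()
    if vals.size == 0:
        raise SuitabilityError("index has no valid cells")
    vmin, vmax = float(vals.min()), float(vals.max())
    breaks = equal_interval_breaks(vmin, vmax, n_classes)
    width = (vmax - vmin) / n_classes
    k = np.floor((index.values - vmin) / width).astype(int)  # 0 = lowest interval
    k = np.clip(k, 0, n_classes - 1)
    codes = np.where(index.mask, n_classes - k, -1).astype(np.int32)
    return CategoricalGrid(codes, dict(CLASS_LEGEND), transform=index.transform, nodata=-1)


def apply_constraint(classes: CategoricalGrid, constraint: ConstraintMap) -> CategoricalGrid:
    """Recode cells whose land cover bars cultivation as ``non-cropland``."""
    check_aligned({"classes": classes, "lulc": constraint.lulc})
    blocked = constraint.noncropland_mask()
    codes = np.where(blocked & classes.mask, NONCROPLAND_CODE, classes.codes)
    return CategoricalGrid(
        codes.astype(np.int32), dict(MASKED_LEGEND), transform=classes.transform,
        nodata=classes.nodata,
    )


def tabulate_areas(classes: CategoricalGrid) -> pd.DataFrame:
    """Hectares and percent per legend class (rows for every class, even zero)."""
    cell_ha = classes.cell_size**2 / 10_000.0
    valid = classes.mask
    total = int(valid.sum())
    rows = []
    # S1..N first, non-cropland (code 0) last, mirroring the published tables
    order = sorted(classes.legend, key=lambda c: (c == NONCROPLAND_CODE, c))
    for code in order:
        count = int(((classes.codes == code) & valid).sum())
        rows.append(
            {
                "class": classes.legend[code],
                "area_ha": count * cell_ha,
                "area_pct": 100.0 * count / total if total else 0.0,
            }
        )
    return pd.DataFrame(rows, columns=["class", "area_ha", "area_pct"])
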