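"""Packaged judgment matrices, classification schemes, and the LULC partition.

These encode the published rice and coconut suitability setups for coastal
agro-ecosystems: the two 9-criterion pairwise comparison matrices, the
per-criterion subclass bins and weights (with their consistency footers), and
the ESRI-style 8-class land-cover legend with its cropland / non-cropland
partition used for constraint masking.

Criterion keys are canonical short names: ``rainfall``, ``temperature``,
``drainage``, ``depth``, ``texture``, ``slope``, ``elevation``, ``soc``,
``ph``.
"""

from __future__ import annotations

from math import inf

import numpy as np

from .ahp import PairwiseMatrix
from .reclass import ClassificationScheme, Footer

CROPS = ("rice", "coconut")

# -- criterion judgment matrices ------------------------------------------

_RICE_LABELS = (
    "rainfall", "temperature", "drainage", "depth", "texture",
    "slope", "elevation", "soc", "ph",
)
_RICE_MATRIX = np.array([
    [1.00, 8.00, 1.00, 5.00, 3.00, 6.00, 6.00, 7.00, 9.00],
    [0.13, 1.00, 0.13, 0.20, 0.17, 0.33, 0.33, 0.50, 2.00],
    [1.00, 8.00, 1.00, 3.00, 2.00, 5.00, 5.00, 7.00, 9.00],
    [0.20, 5.00, 0.33, 1.00, 0.50, 3.00, 3.00, 4.00, 7.00],
    [0.33, 6.00, 0.50, 2.00, 1.00, 4.00, 4.00, 5.00, 7.00],
    [0.17, 3.00, 0.20, 0.33, 0.25, 1.00, 1.00, 2.00, 5.00],
    [0.17, 3.00, 0.20, 0.33, 0.25, 1.00, 1.00, 2.00, 5.00],
    [0.14, 2.00, 0.14, 0.25, 0.20, 0.50, 0.50, 1.00, 3.00],
    [0.11, 0.50, 0.11, 0.14, 0.14, 0.20, 0.20, 0.33, 1.00],
])

_COCONUT_LABELS = (
    "elevation", "slope", "depth", "texture", "drainage",
    "rainfall", "temperature", "ph", "soc",
)
_COCONUT_MATRIX = np.array([
    [1.00, 0.50, 0.20, 0.33, 0.25, 0.14, 0.17, 2.00, 3.00],
    [2.00, 1.00, 0.25, 0.50, 0.33, 0.17, 0.20, 3.00, 5.00],
    [5.00, 4.00, 1.00, 3.00, 2.00, 0.33, 0.50, 6.00, 7.00],
    [3.00, 2.00, 0.33, 1.00, 0.50, 0.20, 0.25, 4.00, 5.00],
    [4.00, 3.00, 0.50, 2.00, 1.00, 0.25, 0.33, 5.00, 7.00],
    [7.00, 6.00, 3.00, 5.00, 4.00, 1.00, 2.00, 8.00, 9.00],
    [6.00, 5.00, 2.00, 4.00, 3.00, 0.50, 1.00, 7.00, 8.00],
    [0.50, 0.33, 0.17, 0.25, 0.20, 0.13, 0.14, 1.00, 2.00],
    [0.33, 0.20, 0.14, 0.20, 0.14, 0.11, 0.13, 0.50, 1.00],
])


def rice_matrix() -> PairwiseMatrix:
    """The published 9×9 rice criterion judgment matrix."""
    return PairwiseMatrix(_RICE_MATRIX.copy(), _RICE_LABELS)


def coconut_matrix() -> PairwiseMatrix:
    """The published 9×9 coconut criterion judgment matrix."""
    return PairwiseMatrix(_COCONUT_MATRIX.copy(), _COCONUT_LABELS)


def crop_matrix(crop: str) -> PairwiseMatrix:
    if crop == "rice":
        return rice_matrix()
    if crop == "coconut":
        return coconut_matrix()
    raise ValueError(f"unknown crop {crop!r}; expected one of {CROPS}")


#: Criterion weights as printed in the source tables (2-decimal, metadata
#: only; each column famously sums to 1.02 from rounding).  Pipelines use
#: full-precision weights from :func:`cropsuit.ahp.derive_weights`.
PRINTED_WEIGHTS = {
    "rice": {
        "rainfall": 0.29, "temperature": 0.03, "drainage": 0.25, "depth": 0.11,
        "texture": 0.16, "slope": 0.06, "elevation": 0.06, "soc": 0.04, "ph": 0.02,
    },
    "coconut": {
        "elevation": 0.04, "slope": 0.06, "depth": 0.15, "texture": 0.08,
        "drainage": 0.11, "rainfall": 0.31, "temperature": 0.22, "ph": 0.03, "soc": 0.02,
    },
}

# -- canonical categorical layers -----------------------------------------

#: Soil depth classes (cm ranges as surveyed), deepest first.
DEPTH_CLASSES = (
    "very deep",          # > 125 cm
    "deep",               # 100–125 cm
    "moderately deep",    # 75–100 cm
    "moderately shallow", # 50–75 cm
    "shallow",            # 25–50 cm
    "very shallow",       # 10–25 cm
    "extremely shallow",  # < 10 cm
)

DRAINAGE_CLASSES = (
    "imperfect", "very poor", "poor",
    "moderately well drained", "well drained", "excessive",
)

#: ESRI-style 8-class land-cover legend.
LULC_CLASSES = (
    "water", "trees", "flooded vegetation", "crops",
    "built area", "bare ground", "snow/ice", "rangeland",
)
LULC_LEGEND = dict(enumerate(LULC_CLASSES))

#: Constraint partition: classes where cultivation is possible vs barred.
CROPLAND_CLASSES = frozenset({"flooded vegetation", "crops", "bare ground", "rangeland"})
NONCROPLAND_CLASSES = frozenset({"water", "trees", "built area", "snow/ice"})


# -- subclass classification schemes --------------------------------------

def _interval(criterion, units, bins, footer, crop):
    """bins: list of (label, lo, hi, weight) in ascending edge order."""
    labels = tuple(b[0] for b in bins)
    weights = tuple(b[3] for b in bins)
    edges = tuple(b[1] for b in bins) + (bins[-1][2],)
    return ClassificationScheme(
        criterion=criterion, units=units, kind="interval",
        labels=labels, weights=weights, edges=edges,
        footer=Footer(*footer),
        criterion_weight=PRINTED_WEIGHTS[crop][criterion],
    )


def _categorical(criterion, units, bins, footer, crop):
    """bins: list of (label, category set, weight)."""
    return ClassificationScheme(
        criterion=criterion, units=units, kind="categorical",
        labels=tuple(b[0] for b in bins),
        weights=tuple(b[2] for b in bins),
        categories=tuple(frozenset(b[1]) for b in bins),
        footer=Footer(*footer),
        criterion_weight=PRINTED_WEIGHTS[crop][criterion],
    )


def rice_scheme() -> dict[str, ClassificationScheme]:
    """Subclass bins, weights and consistency footers for rice."""
    c = "rice"
    return {
        "elevation": _interval("elevation", "m", [
            ("<100", -inf, 100, 0.58),
            ("100-500", 100, 500, 0.26),
            ("500-1000", 500, 1000, 0.12),
            (">1000", 1000, inf, 0.05),
        ], (4, 4.140, 0.047, 0.900, 0.052), c),
        "slope": _interval("slope", "%", [
            ("<1", -inf, 1, 0.51),
            ("1-3", 1, 3, 0.24),
            ("3-10", 3, 10, 0.14),
            ("10-15", 10, 15, 0.06),
            (">15", 15, inf, 0.04),
        ], (5, 5.326, 0.081, 1.12, 0.073), c),
        "depth": _categorical("depth", "cm class", [
            ("very deep", {"very deep"}, 0.28),
            ("deep", {"deep"}, 0.28),
            ("moderately deep", {"moderately deep"}, 0.20),
            ("moderately shallow", {"moderately shallow"}, 0.12),
            ("shallow", {"shallow"}, 0.06),
            ("very shallow", {"very shallow"}, 0.03),
            ("extremely shallow", {"extremely shallow"}, 0.02),
        ], (7, 7.409, 0.068, 1.32, 0.052), c),
        "texture": _categorical("texture", "USDA class", [
            ("clayey", {"clay", "silty clay", "clay loam", "silty clay loam", "sandy clay"}, 0.52),
            ("loam", {"sandy clay loam", "silt loam", "loam", "silt"}, 0.22),
            ("sandy loam", {"sandy loam"}, 0.11),
            ("loamy sand", {"loamy sand"}, 0.10),
            ("sand", {"sand"}, 0.04),
        ], (5, 5.108, 0.027, 1.12, 0.024), c),
        "drainage": _categorical("drainage", "class", [
            ("imperfect", {"imperfect"}, 0.39),
            ("very poor", {"very poor"}, 0.28),
            ("poor", {"poor"}, 0.18),
            ("moderately well drained", {"moderately well drained"}, 0.08),
            ("well drained", {"well drained"}, 0.05),
            ("excessive", {"excessive"}, 0.03),
        ], (6, 6.293, 0.059, 1.24, 0.047), c),
        "soc": _interval("soc", "%", [
            ("<0.25", -inf, 0.25, 0.04),
            ("0.25-0.50", 0.25, 0.50, 0.07),
            ("0.50-0.75", 0.50, 0.75, 0.14),
            ("0.75-1.00", 0.75, 1.00, 0.31),
            (">1.00", 1.00, inf, 0.43),
        ], (5, 5.133, 0.033, 1.12, 0.030), c),
        "ph": _interval("ph", "pH", [
            ("strongly acidic (<4.5)", -inf, 4.5, 0.09),
            ("moderately acidic (4.5-5.5)", 4.5, 5.5, 0.20),
            ("slightly acidic (5.5-6.5)", 5.5, 6.5, 0.46),
            ("neutral (6.5-7.5)", 6.5, 7.5, 0.20),
            ("slightly alkaline (7.5-8.5)", 7.5, 8.5, 0.04),
        ], (5, 5.222, 0.055, 1.12, 0.049), c),
        "rainfall": _interval("rainfall", "mm", [
            ("<750", -inf, 750, 0.06),
            ("750-900", 750, 900, 0.11),
            ("900-1100", 900, 1100, 0.29),
            (">1100", 1100, inf, 0.54),
        ], (4, 4.009, 0.003, 0.900, 0.003), c),
        "temperature": _interval("temperature", "degC", [
            ("<15", -inf, 15, 0.04),
            ("15-20", 15, 20, 0.06),
            ("20-25", 20, 25, 0.15),
            ("25-30", 25, 30, 0.27),
            (">30", 30, inf, 0.48),
        ], (5, 5.239, 0.060, 1.12, 0.053), c),
    }


def coconut_scheme() -> dict[str, ClassificationScheme]:
    """Subclass bins, weights and consistency footers for coconut."""
    c = "coconut"
    return {
        "elevation": _interval("elevation", "m", [
            ("<100", -inf, 100, 0.58),
            ("100-600", 100, 600, 0.26),
            ("600-900", 600, 900, 0.12),
            (">900", 900, inf, 0.05),
        ], (4, 4.140, 0.047, 0.900, 0.052), c),
        "slope": _interval("slope", "%", [
            ("<4", -inf, 4, 0.51),
            ("4-8", 4, 8, 0.24),
            ("8-15", 8, 15, 0.14),
            ("15-30", 15, 30, 0.06),
            (">30", 30, inf, 0.04),
        ], (5, 5.326, 0.081, 1.12, 0.073), c),
        "depth": _categorical("depth", "cm class", [
            (">100", {"very deep", "deep"}, 0.52),
            ("75-100", {"moderately deep"}, 0.30),
            ("50-75", {"moderately shallow"}, 0.12),
            ("<50", {"shallow", "very shallow", "extremely shallow"}, 0.06),
        ], (4, 4.118, 0.039, 0.900, 0.044), c),
        "texture": _categorical("texture", "USDA class", [
            ("loam",
             {"clay loam", "loam", "sandy clay loam", "sandy clay", "silty clay loam", "silt loam"},
             0.67),
            ("SL, SiC, Si", {"sandy loam", "silty clay", "silt"}, 0.24),
            ("S, C, LS", {"sand", "clay", "loamy sand"}, 0.09),
        ], (3, 3.014, 0.007, 0.58, 0.012), c),
        "drainage": _categorical("drainage", "class", [
            ("well drained", {"well drained"}, 0.49),
            ("moderately well drained", {"moderately well drained"}, 0.24),
            ("imperfect", {"imperfect"}, 0.12),
            ("excessive", {"excessive"}, 0.10),
            ("poorly drained", {"poor", "very poor"}, 0.04),
        ], (5, 5.371, 0.093, 1.12, 0.083), c),
        "soc": _interval("soc", "%", [
            ("<0.25", -inf, 0.25, 0.04),
            ("0.25-0.50", 0.25, 0.50, 0.07),
            ("0.50-0.75", 0.50, 0.75, 0.14),
            ("0.75-1.00", 0.75, 1.00, 0.31),
            (">1.00", 1.00, inf, 0.43),
        ], (5, 5.133, 0.033, 1.12, 0.030), c),
        # four weighted groups; the split 6.5-7.5 / 4.5-5.0 (and 7.5-8.5 /
        # 4.0-4.5) pairs share a label and weight
        "ph": _interval("ph", "pH", [
            ("<4.0", -inf, 4.0, 0.05),
            ("7.5-8.5, 4.0-4.5", 4.0, 4.5, 0.11),
            ("6.5-7.5, 4.5-5.0", 4.5, 5.0, 0.27),
            ("5.0-6.5", 5.0, 6.5, 0.57),
            ("6.5-7.5, 4.5-5.0", 6.5, 7.5, 0.27),
            ("7.5-8.5, 4.0-4.5", 7.5, 8.5, 0.11),
        ], (4, 4.191, 0.064, 0.900, 0.071), c),
        "rainfall": _interval("rainfall", "mm", [
            ("<500", -inf, 500, 0.06),
            ("500-1000", 500, 1000, 0.11),
            ("1000-1500", 1000, 1500, 0.29),
            (">1500", 1500, inf, 0.54),
        ], (4, 4.009, 0.003, 0.900, 0.003), c),
        "temperature": _interval("temperature", "degC", [
            ("<26", -inf, 26, 0.25),
            ("26-29", 26, 29, 0.75),
        ], (2, 2.000, 0.00, 0.0, 0.00), c),
    }


def crop_scheme(crop: str) -> dict[str, ClassificationScheme]:
    if crop == "rice":
        return rice_scheme()
    if crop == "coconut":
        return coconut_scheme()
    raise ValueError(f"unknown crop {crop!r}; expected one of {CROPS}")
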