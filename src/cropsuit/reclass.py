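"""Reclassification of environmental layers into subclass-weight layers.

Each criterion has a :class:`ClassificationScheme`: ordered bins (value
intervals or category sets) with one AHP subclass weight per bin plus the
consistency footer (n, λ_max, CI, RI, CR) of the judgment matrix the weights
came from.  Reclassification is exhaustive and exclusive — every in-domain
cell maps to exactly one bin, values outside the declared domain raise
:class:`~cropsuit.errors.DomainError` rather than being clamped.

Interval bins are lower-inclusive / upper-exclusive; the extreme bins absorb
their boundary (the topmost finite edge is inclusive, so pH 8.5 still falls
in the 7.5–8.5 bin).

Also here: the soil pre-processing steps that feed the texture and soil
criteria — depth-weighted 0–15 cm averaging and USDA texture-triangle
classing with the crop-specific texture groupings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from . import ahp
from .errors import DomainError, SuitabilityError
from .grids import CategoricalGrid, Grid, check_aligned


@dataclass(frozen=True)
class Footer:
    """Consistency metadata of the subclass judgment matrix behind a scheme."""

    n: int
    lambda_max: float
    ci: float
    ri: float
    cr: float


@dataclass(frozen=True)
class ClassificationScheme:
    """Ordered bins with subclass weights for one criterion.

    ``kind="interval"``: ``edges`` has ``len(labels) + 1`` ascending entries
    (±inf allowed at the ends); bin i covers ``[edges[i], edges[i+1])``.
    ``kind="categorical"``: ``categories[i]`` is the set of input category
    labels mapping to bin i.

    Grouped bins (e.g. a pH scheme where two disjoint intervals share one
    suitability group) repeat the label and weight across bins; weight-sum
    validation is over unique labels.
    """

    criterion: str
    units: str
    kind: str  # "interval" | "categorical"
    labels: tuple[str, ...]
    weights: tuple[float, ...]
    footer: Footer
    edges: tuple[float, ...] | None = None
    categories: tuple[frozenset, ...] | None = None
    criterion_weight: float | None = None  # printed table weight, metadata only

    def __post_init__(self) -> None:
        if self.kind not in ("interval", "categorical"):
            raise ValueError(f"unknown scheme kind {self.kind!r}")
        if len(self.labels) != len(self.weights):
            raise ValueError("labels and weights length mismatch")
        if self.kind == "interval":
            if self.edges is None or len(self.edges) != len(self.labels) + 1:
                raise ValueError("interval scheme needs len(labels)+1 edges")
            if any(a >= b for a, b in zip(self.edges, self.edges[1:])):
                raise ValueError("edges must be strictly ascending")
        else:
            if self.categories is None or len(self.categories) != len(self.labels):
                raise ValueError("categorical scheme needs one category set per bin")
        unique = {lbl: w for lbl, w in zip(self.labels, self.weights)}
        total = sum(unique.values())
        if abs(total - 1.0) > 0.02:
            raise ValueError(
                f"{self.criterion}: subclass weights sum to {total:.3f}, expected 1 ± 0.02"
            )

    @property
    def n_bins(self) -> int:
        return len(self.labels)

    def domain(self) -> tuple[float, float] | frozenset:
        if self.kind == "interval":
            return (self.edges[0], self.edges[-1])
        return frozenset().union(*self.categories)

    def bin_of_value(self, value: float) -> int:
        """Bin index for one scalar (interval schemes)."""
        idx = self._bin_indices(np.asarray([value], dtype=float))
        return int(idx[0])

    def _bin_indices(self, values: np.ndarray) -> np.ndarray:
        lo, hi = self.edges[0], self.edges[-1]
        out = (values < lo) | (values > hi)
        if out.any():
            bad = float(values[out].flat[0])
            raise DomainError(
                f"{self.criterion}: value {bad} outside scheme domain [{lo}, {hi}]"
            )
        idx = np.digitize(values, self.edges[1:-1], right=False)
        # topmost finite edge is inclusive: digitize already puts hi in the last bin
        return idx

    def bin_of_category(self, label: str) -> int:
        for i, cats in enumerate(self.categories):
            if label in cats:
                return i
        raise DomainError(
            f"{self.criterion}: category {label!r} not in scheme domain {sorted(self.domain())}"
        )

    def audit_footer(self) -> tuple[float, float]:
        """Recompute (CI, CR) from the footer's printed λ_max, n and RI."""
        ci = ahp.consistency_index(self.footer.lambda_max, self.footer.n)
        cr = ahp.consistency_ratio(ci, self.footer.ri)
        return ci, cr

    def to_dict(self) -> dict:
        d = {
            "criterion": self.criterion,
            "units": self.units,
            "kind": self.kind,
            "labels": list(self.labels),
            "weights": list(self.weights),
            "footer": vars(self.footer).copy(),
            "criterion_weight": self.criterion_weight,
        }
        if self.kind == "interval":
            d["edges"] = [None if math.isinf(e) else e for e in self.edges]
        else:
            d["categories"] = [sorted(c) for c in self.categories]
        return d


def reclassify(
    layer: Grid | CategoricalGrid, scheme: ClassificationScheme
) -> tuple[CategoricalGrid, Grid]:
    """Map a layer through a scheme → (bin grid, subclass-weight grid)."""
    if scheme.kind == "interval":
        if not isinstance(layer, Grid):
            raise SuitabilityError(
                f"{scheme.criterion}: interval scheme requires a continuous grid"
            )
        valid = layer.mask
        idx = np.zeros(layer.shape, dtype=np.int32)
        idx[valid] = scheme._bin_indices(layer.values[valid])
    else:
        if not isinstance(layer, CategoricalGrid):
            raise SuitabilityError(
                f"{scheme.criterion}: categorical scheme requires a categorical grid"
            )
        valid = layer.mask
        code_to_bin = {
            code: scheme.bin_of_category(label) for code, label in layer.legend.items()
        }
        idx = np.zeros(layer.shape, dtype=np.int32)
        for code, b in code_to_bin.items():
            idx[(layer.codes == code) & valid] = b

    weights = np.asarray(scheme.weights, dtype=float)
    wgrid = np.where(valid, weights[idx], -9999.0)
    bins = np.where(valid, idx, -1).astype(np.int32)
    legend = dict(enumerate(scheme.labels))
    return (
        CategoricalGrid(bins, legend, transform=layer.transform, nodata=-1),
        Grid(wgrid, transform=layer.transform, nodata=-9999.0, units="subclass weight"),
    )


# -- soil pre-processing ---------------------------------------------------

#: The 12 USDA texture-triangle classes.
USDA_CLASSES = (
    "sand",
    "loamy sand",
    "sandy loam",
    "loam",
    "silt loam",
    "silt",
    "sandy clay loam",
    "clay loam",
    "silty clay loam",
    "sandy clay",
    "silty clay",
    "clay",
)


def usda_texture(sand, silt, clay):
    """USDA texture-triangle class from sand/silt/clay percentages.

    Accepts scalars or equally-shaped arrays; fractions are renormalized to
    sum to 100 when within ±1, otherwise an error is raised.  Returns a class
    label (scalar input) or an object array of labels.
    """
    sand = np.asarray(sand, dtype=float)
    silt = np.asarray(silt, dtype=float)
    clay = np.asarray(clay, dtype=float)
    if (sand < 0).any() or (silt < 0).any() or (clay < 0).any():
        raise ValueError("texture fractions must be non-negative")
    total = sand + silt + clay
    if (np.abs(total - 100.0) > 1.0).any():
        bad = float(total[np.abs(total - 100.0) > 1.0].flat[0])
        raise ValueError(f"sand+silt+clay must sum to 100 ± 1 (got {bad:.3f})")
    sand, silt, clay = (100.0 * f / total for f in (sand, silt, clay))

    # USDA/NRCS flowchart, evaluated as a first-match cascade
    rules = [
        ("sand", silt + 1.5 * clay < 15),
        ("loamy sand", silt + 2.0 * clay < 30),
        ("sandy loam", ((clay >= 7) & (clay < 20) & (sand > 52)) | ((clay < 7) & (silt < 50))),
        ("loam", (clay >= 7) & (clay < 27) & (silt >= 28) & (silt < 50) & (sand <= 52)),
        ("silt loam", (silt >= 50) & (((clay >= 12) & (clay < 27)) | ((silt < 80) & (clay < 12)))),
        ("silt", (silt >= 80) & (clay < 12)),
        ("sandy clay loam", (clay >= 20) & (clay < 35) & (silt < 28) & (sand > 45)),
        ("clay loam", (clay >= 27) & (clay < 40) & (sand > 20) & (sand <= 45)),
        ("silty clay loam", (clay >= 27) & (clay < 40) & (sand <= 20)),
        ("sandy clay", (clay >= 35) & (sand > 45)),
        ("silty clay", (clay >= 40) & (silt >= 40)),
        ("clay", np.ones_like(sand, dtype=bool)),
    ]
    out = np.full(sand.shape, None, dtype=object)
    undecided = np.ones(sand.shape, dtype=bool)
    for label, cond in rules:
        hit = undecided & np.asarray(cond)
        out[hit] = label
        undecided &= ~hit
    if out.ndim == 0:
        return out.item()
    return out


def usda_texture_grid(sand: Grid, silt: Grid, clay: Grid) -> CategoricalGrid:
    """Per-cell USDA texture class grid from three fraction grids."""
    check_aligned({"sand": sand, "silt": silt, "clay": clay})
    valid = sand.mask & silt.mask & clay.mask
    labels = usda_texture(
        np.where(valid, sand.values, 33.0),
        np.where(valid, silt.values, 33.0),
        np.where(valid, clay.values, 34.0),
    )
    code_of = {c: i for i, c in enumerate(USDA_CLASSES)}
    codes = np.full(sand.shape, -1, dtype=np.int32)
    for label, code in code_of.items():
        codes[(labels == label) & valid] = code
    return CategoricalGrid(
        codes, dict(enumerate(USDA_CLASSES)), transform=sand.transform, nodata=-1
    )


#: Crop-specific texture groupings of the 12 USDA classes.
TEXTURE_GROUPS: dict[str, dict[str, frozenset]] = {
    "rice": {
        "clayey": frozenset({"clay", "silty clay", "clay loam", "silty clay loam", "sandy clay"}),
        "loam": frozenset({"sandy clay loam", "silt loam", "loam", "silt"}),
        "sandy loam": frozenset({"sandy loam"}),
        "loamy sand": frozenset({"loamy sand"}),
        "sand": frozenset({"sand"}),
    },
    "coconut": {
        "loam": frozenset(
            {"clay loam", "loam", "sandy clay loam", "sandy clay", "silty clay loam", "silt loam"}
        ),
        "SL, SiC, Si": frozenset({"sandy loam", "silty clay", "silt"}),
        "S, C, LS": frozenset({"sand", "clay", "loamy sand"}),
    },
}


def texture_group(texture_class: str, crop: str) -> str:
    """Crop-specific grouped texture label for a USDA class."""
    if crop not in TEXTURE_GROUPS:
        raise ValueError(f"unknown crop {crop!r}; expected one of {sorted(TEXTURE_GROUPS)}")
    if texture_class not in USDA_CLASSES:
        raise ValueError(f"unknown USDA texture class {texture_class!r}")
    for group, members in TEXTURE_GROUPS[crop].items():
        if texture_class in members:
            return group
    raise AssertionError("texture groups must partition the USDA classes")


def depth_weighted_average(layer_0_5: Grid, layer_5_15: Grid) -> Grid:
    """Depth-weighted 0–15 cm soil value: (5·v₀₋₅ + 10·v₅₋₁₅) / 15."""
    check_aligned({"0-5cm": layer_0_5, "5-15cm": layer_5_15})
    valid = layer_0_5.mask & layer_5_15.mask
    avg = (5.0 * layer_0_5.values + 10.0 * layer_5_15.values) / 15.0
    return layer_0_5.copy_with(np.where(valid, avg, layer_0_5.nodata))
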