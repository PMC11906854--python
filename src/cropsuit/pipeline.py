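"""The end-to-end suitability pipeline.

Composition, in order: AHP audit of the criterion matrix (with a CR < 0.1
gate) → per-criterion reclassification into subclass-weight layers →
weighted overlay → equal-interval 4-class classification → land-cover
constraint masking → area tabulation.  Grids must arrive co-registered; the
pipeline checks and fails loudly rather than resampling.  A JSON manifest
records weights, consistency numbers, class breaks, seed and version so a
run is a pure function of its inputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from . import __version__, ahp, climate, overlay, presets, reclass
from .errors import ConsistencyGateError, SuitabilityError
from .grids import CategoricalGrid, Grid, check_aligned

log = logging.getLogger(__name__)

#: Rice uses the Jun–Sep growing-season temperature; coconut the annual mean.
SEASON_MONTHS = {"rice": (6, 7, 8, 9), "coconut": tuple(range(1, 13))}


@dataclass
class RunConfig:
    """File-driven run description (used by the CLI)."""

    crop: str
    layer_dir: Path
    out_dir: Path
    matrix_csv: Path | None = None
    seed: int = 0
    force: bool = False
    estimator: str = "max"


def prepare_criterion_layers(bundle: Mapping, crop: str) -> dict[str, Grid | CategoricalGrid]:
    """Derive the nine criterion layers a crop's scheme needs from a bundle.

    The bundle is keyed as produced by :func:`cropsuit.synthetic.generate_layers`
    (or loaded from disk in the same shape): monthly climate stacks are
    aggregated (seasonal/annual temperature mean, annual rainfall sum) and
    sand/silt/clay fractions are classed into USDA textures.
    """
    if crop not in presets.CROPS:
        raise ValueError(f"unknown crop {crop!r}")
    required = ("elevation", "slope", "ph", "soc", "depth", "drainage")
    missing = [k for k in required if k not in bundle]
    for k in ("temperature_stack", "rainfall_stack"):
        if k not in bundle:
            missing.append(k)
    if not {"sand", "silt", "clay"} <= set(bundle) and "texture" not in bundle:
        missing.append("texture (or sand/silt/clay)")
    if missing:
        raise SuitabilityError(f"bundle is missing layer(s): {missing}")

    layers: dict[str, Grid | CategoricalGrid] = {
        k: bundle[k] for k in required
    }
    layers["temperature"] = climate.season_mean(
        bundle["temperature_stack"], SEASON_MONTHS[crop]
    )
    layers["rainfall"] = climate.annual_precip(bundle["rainfall_stack"])
    if "texture" in bundle:
        layers["texture"] = bundle["texture"]
    else:
        layers["texture"] = reclass.usda_texture_grid(
            bundle["sand"], bundle["silt"], bundle["clay"]
        )
    return layers


def run_suitability(
    layers: Mapping[str, Grid | CategoricalGrid],
    crop: str = "rice",
    lulc: CategoricalGrid | None = None,
    matrix: ahp.PairwiseMatrix | None = None,
    force: bool = False,
    estimator: str = "max",
) -> tuple[overlay.SuitabilityResult, dict]:
    """Score, classify, mask and tabulate; returns (result, manifest).

    ``layers`` maps the nine criterion names to co-registered grids (already
    aggregated — see :func:`prepare_criterion_layers`).  ``lulc`` enables the
    constraint-masking stage; without it the masked outputs equal the
    unmasked ones.  Raises :class:`ConsistencyGateError` when the criterion
    matrix has CR ≥ 0.1 and ``force`` is not set.
    """
    matrix = matrix if matrix is not None else presets.crop_matrix(crop)
    report = ahp.analyze(matrix, estimator=estimator)
    if not report.accepted and not force:
        raise ConsistencyGateError(
            f"criterion matrix CR = {report.cr:.4f} >= 0.1; refusing to overlay "
            "(pass force=True to override)"
        )

    scheme = presets.crop_scheme(crop)
    missing = set(scheme) - set(layers)
    if missing:
        raise SuitabilityError(f"missing criterion layer(s): {sorted(missing)}")
    check_aligned(dict(layers))

    weight_layers = {}
    for name, sch in scheme.items():
        _, wgrid = reclass.reclassify(layers[name], sch)
        weight_layers[name] = wgrid

    weights = report.weights_by_label()
    index = overlay.weighted_overlay(weight_layers, weights)
    classes = overlay.equal_interval_classify(index)
    vals = index.valid_values()
    breaks = overlay.equal_interval_breaks(float(vals.min()), float(vals.max()))

    if lulc is not None:
        constraint = overlay.ConstraintMap(
            lulc, presets.CROPLAND_CLASSES, presets.NONCROPLAND_CLASSES
        )
        masked = overlay.apply_constraint(classes, constraint)
    else:
        masked = CategoricalGrid(
            classes.codes.copy(), dict(overlay.MASKED_LEGEND),
            transform=classes.transform, nodata=classes.nodata,
        )
    result = overlay.SuitabilityResult(
        index=index,
        classes=classes,
        masked_classes=masked,
        areas_before=overlay.tabulate_areas(classes),
        areas_after=overlay.tabulate_areas(masked),
        breaks=tuple(breaks),
    )
    manifest = {
        "crop": crop,
        "version": __version__,
        "estimator": estimator,
        "criterion_weights": weights,
        "lambda_max": report.lambda_max,
        "ci": report.ci,
        "ri": report.ri,
        "cr": report.cr,
        "accepted": report.accepted,
        "forced": bool(not report.accepted and force),
        "index_range": [float(vals.min()), float(vals.max())],
        "breaks": [float(b) for b in breaks],
        "masked": lulc is not None,
    }
    if not report.accepted:
        log.warning("inconsistent matrix (CR = %.4f) used under force", report.cr)
    return result, manifest


def write_bundle(bundle: Mapping, out_dir: str | Path) -> Path:
    """Write a layer bundle to a directory of .asc/.csv files."""
    from .grids import write_ascii, write_categorical

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name in ("elevation", "slope", "ph", "soc", "sand", "silt", "clay"):
        if name in bundle:
            write_ascii(bundle[name], out / f"{name}.asc")
    for name in ("depth", "drainage", "lulc"):
        if name in bundle:
            write_categorical(bundle[name], out / f"{name}.asc")
    for stack_name, prefix in (("temperature_stack", "temperature"), ("rainfall_stack", "rainfall")):
        if stack_name in bundle:
            for m in range(1, 13):
                write_ascii(bundle[stack_name][m], out / f"{prefix}_{m:02d}.asc")
    return out


def load_bundle(in_dir: str | Path) -> dict:
    """Load a layer bundle written by :func:`write_bundle`."""
    from .grids import read_ascii, read_categorical

    src = Path(in_dir)
    bundle: dict = {}
    for name in ("elevation", "slope", "ph", "soc", "sand", "silt", "clay"):
        p = src / f"{name}.asc"
        if p.exists():
            bundle[name] = read_ascii(p)
    for name in ("depth", "drainage", "lulc"):
        p = src / f"{name}.asc"
        if p.exists():
            bundle[name] = read_categorical(p)
    for stack_name, prefix, units in (
        ("temperature_stack", "temperature", "degC"),
        ("rainfall_stack", "rainfall", "mm"),
    ):
        paths = [src / f"{prefix}_{m:02d}.asc" for m in range(1, 13)]
        if all(p.exists() for p in paths):
            bundle[stack_name] = climate.MonthlyStack(
                tuple(read_ascii(p, units=units) for p in paths), prefix, units
            )
    if not bundle:
        raise SuitabilityError(f"no bundle layers found in {src}")
    return bundle


def write_outputs(result: overlay.SuitabilityResult, manifest: dict, out_dir: str | Path) -> dict:
    """Write index/class grids, area tables and the manifest; returns paths."""
    from .grids import write_ascii, write_categorical

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "index": write_ascii(result.index, out / "index.asc"),
        "classes": write_categorical(result.classes, out / "classes.asc"),
        "masked_classes": write_categorical(result.masked_classes, out / "masked_classes.asc"),
    }
    result.areas_before.to_csv(out / "areas_before_masking.csv", index=False)
    result.areas_after.to_csv(out / "areas_after_masking.csv", index=False)
    paths["areas_before"] = out / "areas_before_masking.csv"
    paths["areas_after"] = out / "areas_after_masking.csv"
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    paths["manifest"] = manifest_path
    return paths
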