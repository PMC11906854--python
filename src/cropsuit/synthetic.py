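"""Seeded generator of a miniature coastal landscape.

Produces the full layer inventory the suitability pipeline consumes — a
smooth DEM with derived percent-rise slope, spatially autocorrelated soil
and climate fields on a common square grid, categorical soil depth /
drainage / land-cover layers, and presence points whose probability
increases with a supplied suitability index — with no external data.

Random fields are smoothed white noise (separable Gaussian filter), chosen
for simplicity over geostatistical fidelity.  Generated ranges are clipped
to the packaged classification-scheme domains so reclassification never
faults.  One global seed drives independent per-layer substreams, so adding
a layer does not perturb the others.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.special import log_expit

from .climate import MonthlyStack
from .grids import CategoricalGrid, Grid, Transform
from .presets import DEPTH_CLASSES, DRAINAGE_CLASSES, LULC_CLASSES, LULC_LEGEND
from .validation import PRESENCE

#: Monsoon-heavy monthly rainfall fractions (sum to 1), peaking in Jun–Sep.
MONSOON_FRACTIONS = (
    0.01, 0.01, 0.02, 0.03, 0.06, 0.15, 0.22, 0.20, 0.14, 0.09, 0.05, 0.02,
)

#: Spatially-coherent class proportions for the categorical soil layers,
#: patterned on coastal survey compositions (deepest/most common first).
DEPTH_PROPORTIONS = (0.24, 0.26, 0.11, 0.06, 0.13, 0.11, 0.09)
DRAINAGE_PROPORTIONS = (0.17, 0.07, 0.09, 0.13, 0.40, 0.14)


@dataclass
class LandscapeConfig:
    """Knobs of the synthetic coastal landscape."""

    shape: tuple[int, int] = (64, 64)
    cell_size: float = 250.0  # m
    seed: int = 0
    relief: float = 1200.0  # m, maximum elevation; coast floor is -5 m
    corr_length: float = 8.0  # cells, Gaussian smoothing radius
    rain_base: float = 1300.0  # mm, annual total at the coast
    rain_gradient: float = 40.0  # mm per km inland (west -> east)
    rain_noise_sd: float = 180.0  # mm
    lapse_rate: float = 0.65  # degC per 100 m elevation
    temp_base: float = 27.5  # degC, annual sea-level mean
    temp_amplitude: float = 3.0  # degC, seasonal half-range
    temp_noise_sd: float = 0.25  # degC
    ph_mean: float = 6.3
    ph_sd: float = 0.9
    soc_mean: float = 1.1
    soc_sd: float = 0.6
    lulc_proportions: dict = field(
        default_factory=lambda: {
            "water": 0.08, "trees": 0.20, "flooded vegetation": 0.05, "crops": 0.40,
            "built area": 0.07, "bare ground": 0.05, "snow/ice": 0.0, "rangeland": 0.15,
        }
    )
    occ_intercept: float = -14.0  # a in logistic(a + b * standardized index)
    occ_slope: float | None = 10.0  # b, log-odds per index sd; None must be supplied

    def __post_init__(self) -> None:
        if self.shape[0] < 8 or self.shape[1] < 8:
            raise ValueError("landscape must be at least 8x8")
        if self.cell_size <= 0:
            raise ValueError("cell size must be positive")
        total = sum(self.lulc_proportions.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"LULC proportions sum to {total}, expected 1")
        unknown = set(self.lulc_proportions) - set(LULC_CLASSES)
        if unknown:
            raise ValueError(f"unknown LULC classes {sorted(unknown)}")

    @property
    def transform(self) -> Transform:
        return (0.0, 0.0, self.cell_size)

    def rng(self, stream: str) -> np.random.Generator:
        """Independent, named, seed-derived substream."""
        return np.random.default_rng([self.seed, zlib.crc32(stream.encode())])


def _smooth_field(config: LandscapeConfig, stream: str) -> np.ndarray:
    """Standardized Gaussian-smoothed white noise (zero mean, unit sd)."""
    z = config.rng(stream).standard_normal(config.shape)
    f = gaussian_filter(z, sigma=config.corr_length, mode="reflect")
    sd = f.std()
    return (f - f.mean()) / (sd if sd > 0 else 1.0)


def _quantile_classes(latent: np.ndarray, proportions, labels) -> np.ndarray:
    """Threshold a latent field at rank quantiles -> spatially clumped codes."""
    flat = latent.ravel()
    order = np.argsort(flat, kind="stable")
    codes = np.empty(flat.size, dtype=np.int32)
    start = 0
    cum = 0.0
    for i, p in enumerate(proportions):
        cum += p
        stop = flat.size if i == len(proportions) - 1 else int(round(cum * flat.size))
        codes[order[start:stop]] = i
        start = stop
    return codes.reshape(latent.shape)


def generate_dem(config: LandscapeConfig) -> Grid:
    """Smoothed random DEM in [−5 m, relief] with a low-lying coastal west edge."""
    f = _smooth_field(config, "dem")
    ncols = config.shape[1]
    inland = np.linspace(0.0, 1.0, ncols)[None, :]  # 0 at the west (coast) edge
    h = 0.55 * inland + 0.45 * (f - f.min()) / max(np.ptp(f), 1e-12)
    t = (h - h.min()) / max(np.ptp(h), 1e-12)
    dem = -5.0 + (config.relief + 5.0) * t**3  # cubic skew: mostly low-lying
    return Grid(dem, transform=config.transform, units="m")


def derive_slope(dem: Grid) -> Grid:
    """Percent-rise slope by Horn's 3×3 stencil (one-sided at the edges)."""
    if dem.shape[0] < 3 or dem.shape[1] < 3:
        raise ValueError("slope needs at least a 3x3 DEM")
    z = np.pad(dem.values, 1, mode="reflect", reflect_type="odd")
    cs = dem.cell_size
    # Horn weights; odd reflection makes the edge columns exact one-sided
    # differences for a planar surface
    dzdx = (
        (z[:-2, 2:] + 2 * z[1:-1, 2:] + z[2:, 2:])
        - (z[:-2, :-2] + 2 * z[1:-1, :-2] + z[2:, :-2])
    ) / (8 * cs)
    dzdy = (
        (z[2:, :-2] + 2 * z[2:, 1:-1] + z[2:, 2:])
        - (z[:-2, :-2] + 2 * z[:-2, 1:-1] + z[:-2, 2:])
    ) / (8 * cs)
    pct = 100.0 * np.hypot(dzdx, dzdy)
    return Grid(pct, transform=dem.transform, units="%")


def generate_lulc(config: LandscapeConfig) -> CategoricalGrid:
    """Spatially clumped 8-class land-cover map at the configured proportions."""
    latent = _smooth_field(config, "lulc")
    props = [config.lulc_proportions.get(cls, 0.0) for cls in LULC_CLASSES]
    codes = _quantile_classes(latent, props, LULC_CLASSES)
    return CategoricalGrid(codes, dict(LULC_LEGEND), transform=config.transform)


def generate_layers(config: LandscapeConfig, dem: Grid) -> dict:
    """Full co-registered layer bundle keyed by canonical layer name.

    Keys: ``elevation``, ``slope``, ``ph``, ``soc``, ``sand``/``silt``/
    ``clay``, ``depth``, ``drainage``, ``lulc``, ``temperature_stack``,
    ``rainfall_stack``.
    """
    tf = config.transform
    bundle: dict = {"elevation": dem, "slope": derive_slope(dem)}

    # temperature: seasonal cycle - lapse * elevation + smooth noise
    months = []
    lapse_term = config.lapse_rate * dem.values / 100.0
    for m in range(1, 13):
        seasonal = config.temp_amplitude * np.cos(2 * np.pi * (m - 6) / 12.0)
        noise = _smooth_field(config, f"temp_{m:02d}") * config.temp_noise_sd
        months.append(
            Grid(config.temp_base + seasonal - lapse_term + noise, transform=tf, units="degC")
        )
    bundle["temperature_stack"] = MonthlyStack(tuple(months), "temperature", "degC")

    # rainfall: annual total with inland gradient, split by monsoon fractions
    ncols = config.shape[1]
    x_km = (np.arange(ncols) + 0.5) * config.cell_size / 1000.0
    annual = (
        config.rain_base
        + config.rain_gradient * x_km[None, :]
        + _smooth_field(config, "rain") * config.rain_noise_sd
    )
    annual = np.clip(annual, 350.0, None)
    bundle["rainfall_stack"] = MonthlyStack(
        tuple(
            Grid(annual * frac, transform=tf, units="mm") for frac in MONSOON_FRACTIONS
        ),
        "precipitation",
        "mm",
    )

    # continuous soil fields, clipped to the scheme domains
    ph = config.ph_mean + _smooth_field(config, "ph") * config.ph_sd
    bundle["ph"] = Grid(np.clip(ph, 3.5, 8.5), transform=tf, units="pH")
    soc = config.soc_mean + _smooth_field(config, "soc") * config.soc_sd
    bundle["soc"] = Grid(np.clip(soc, 0.05, 3.0), transform=tf, units="%")

    # sand/silt/clay on the simplex via a softmax of smooth fields
    logits = np.stack([_smooth_field(config, f"texture_{c}") for c in ("sand", "silt", "clay")])
    e = np.exp(1.2 * logits)
    fracs = 100.0 * e / e.sum(axis=0)
    for i, name in enumerate(("sand", "silt", "clay")):
        bundle[name] = Grid(fracs[i], transform=tf, units="%")

    # spatially coherent categorical soil layers
    bundle["depth"] = CategoricalGrid(
        _quantile_classes(_smooth_field(config, "depth"), DEPTH_PROPORTIONS, DEPTH_CLASSES),
        dict(enumerate(DEPTH_CLASSES)),
        transform=tf,
    )
    bundle["drainage"] = CategoricalGrid(
        _quantile_classes(
            _smooth_field(config, "drainage"), DRAINAGE_PROPORTIONS, DRAINAGE_CLASSES
        ),
        dict(enumerate(DRAINAGE_CLASSES)),
        transform=tf,
    )
    bundle["lulc"] = generate_lulc(config)
    return bundle


def generate_landscape(config: LandscapeConfig | None = None) -> dict:
    """Convenience: DEM plus the full bundle in one call."""
    config = config or LandscapeConfig()
    return generate_layers(config, generate_dem(config))


def generate_occurrences(
    index: Grid, config: LandscapeConfig, n: int, seed: int | None = None
) -> pd.DataFrame:
    """``n`` presence points with sampling weight ∝ logistic(a + b·z).

    ``z`` is the suitability index standardized to zero mean and unit sd
    across valid cells, so ``b`` reads as log-odds per index standard
    deviation.  Keep ``a`` negative enough that ``a + b·z`` stays below ~0
    for most cells: in that regime the logistic is an exponential tilt
    ``exp(b·z)`` and the planted signal scales cleanly with ``b`` (a large
    ``a`` saturates the logistic and flattens the signal).  ``b = 0`` gives
    uniform presence locations.  Seeded and duplicate-free (at most one
    point per cell, placed at cell centers).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if config.occ_slope is None:
        raise ValueError("occ_slope (b) must be specified to generate occurrences")
    rows, cols = np.nonzero(index.mask)
    if len(rows) < n:
        raise ValueError(f"only {len(rows)} valid cells for {n} presences")
    vals = index.values[rows, cols]
    z = (vals - vals.mean()) / max(vals.std(), 1e-12)
    # sampling weights ∝ expit(a + b·z), computed in log-space so deeply
    # negative logits stay proportional instead of underflowing to zero
    logw = log_expit(config.occ_intercept + config.occ_slope * z)
    p = np.exp(logw - logw.max())
    p = p / p.sum()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    pick = rng.choice(len(rows), size=n, replace=False, p=p)
    xy = np.array([index.cell_center(r, c) for r, c in zip(rows[pick], cols[pick])])
    return pd.DataFrame({"x": xy[:, 0], "y": xy[:, 1], "label": PRESENCE})
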