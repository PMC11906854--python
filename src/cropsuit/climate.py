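"""Climate layer derivation: monthly climatology, seasonal/annual aggregates,
and inverse-distance-weighted (IDW) downscaling with cross-validated power.

The IDW prediction at a target location is the convex combination

    v(x) = Σ_i v_i · d_i^(−p) / Σ_i d_i^(−p)

over the k nearest sample points; a target coincident with a sample returns
that sample's value exactly.  The interpolation power p is chosen by bounded
scalar minimization of the leave-one-out RMSE over the samples (the same IDW
implementation is used inside the objective).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.spatial import cKDTree

from .errors import SuitabilityError
from .grids import Grid, check_aligned

log = logging.getLogger(__name__)

MONTHS = tuple(range(1, 13))


@dataclass
class MonthlyStack:
    """Twelve co-registered grids, one per calendar month."""

    grids: tuple[Grid, ...]
    variable: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        if len(self.grids) != 12:
            raise ValueError(f"a monthly stack needs 12 grids, got {len(self.grids)}")
        check_aligned({f"month {m}": g for m, g in zip(MONTHS, self.grids)})

    def __getitem__(self, month: int) -> Grid:
        """Grid for calendar month 1–12."""
        if month not in MONTHS:
            raise KeyError(f"month must be 1..12, got {month}")
        return self.grids[month - 1]

    @property
    def template(self) -> Grid:
        return self.grids[0]

    def _stacked(self) -> tuple[np.ndarray, np.ndarray]:
        """(12, r, c) value cube and combined validity mask."""
        cube = np.stack([g.values for g in self.grids])
        valid = np.all([g.mask for g in self.grids], axis=0)
        return cube, valid


def climatology(series: Sequence[Sequence[Grid]], variable: str = "", units: str = "") -> MonthlyStack:
    """Cellwise mean per calendar month across years.

    ``series[y][m]`` is the grid of month ``m+1`` in year ``y``; every year
    must provide all 12 months.
    """
    if not series:
        raise ValueError("climatology needs at least one year of data")
    for y, year in enumerate(series):
        if len(year) != 12:
            raise ValueError(f"year {y} has {len(year)} months; 12 required")
    months = []
    for m in range(12):
        grids = [year[m] for year in series]
        check_aligned(grids)
        valid = np.all([g.mask for g in grids], axis=0)
        mean = np.mean([g.values for g in grids], axis=0)
        tpl = grids[0]
        months.append(tpl.copy_with(np.where(valid, mean, tpl.nodata)))
    return MonthlyStack(tuple(months), variable=variable, units=units)


def season_mean(stack: MonthlyStack, months: Iterable[int]) -> Grid:
    """Cellwise mean over the listed calendar months (all 12 = annual mean)."""
    months = sorted(set(months))
    if not months:
        raise ValueError("month set must be non-empty")
    if not set(months) <= set(MONTHS):
        raise ValueError(f"months must be within 1..12, got {months}")
    grids = [stack[m] for m in months]
    valid = np.all([g.mask for g in grids], axis=0)
    mean = np.mean([g.values for g in grids], axis=0)
    tpl = stack.template
    return tpl.copy_with(np.where(valid, mean, tpl.nodata))


def annual_mean(stack: MonthlyStack) -> Grid:
    return season_mean(stack, MONTHS)


def annual_precip(stack: MonthlyStack) -> Grid:
    """Cellwise sum of the 12 monthly precipitation grids (mm)."""
    cube, valid = stack._stacked()
    tpl = stack.template
    return tpl.copy_with(np.where(valid, cube.sum(axis=0), tpl.nodata), units="mm")


# -- point samples and IDW -------------------------------------------------


@dataclass
class PointSamples:
    """Scattered (x, y, value) observations in grid coordinate units."""

    xy: np.ndarray  # (n, 2)
    values: np.ndarray  # (n,)

    def __post_init__(self) -> None:
        self.xy = np.atleast_2d(np.asarray(self.xy, dtype=float))
        self.values = np.asarray(self.values, dtype=float)
        if self.xy.shape[0] != self.values.shape[0]:
            raise ValueError("xy and values length mismatch")
        if not np.isfinite(self.xy).all() or not np.isfinite(self.values).all():
            raise ValueError("samples must be finite")
        if len(np.unique(self.xy, axis=0)) != len(self.xy):
            raise ValueError("duplicate sample coordinates")

    def __len__(self) -> int:
        return len(self.values)

    @classmethod
    def from_csv(cls, path: str | Path) -> "PointSamples":
        df = pd.read_csv(path)
        return cls(df[["x", "y"]].to_numpy(), df["value"].to_numpy())

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"x": self.xy[:, 0], "y": self.xy[:, 1], "value": self.values}).to_csv(
            path, index=False
        )


def grid_to_samples(grid: Grid) -> PointSamples:
    """Cell centers of a (coarse) grid as IDW source nodes."""
    rows, cols = np.nonzero(grid.mask)
    xll, yll, cs = grid.transform
    ytop = yll + grid.shape[0] * cs
    x = xll + (cols + 0.5) * cs
    y = ytop - (rows + 0.5) * cs
    return PointSamples(np.column_stack([x, y]), grid.values[rows, cols])


def _idw_at_points(
    samples: PointSamples, targets: np.ndarray, power: float, k: int | None
) -> np.ndarray:
    n = len(samples)
    kq = n if k is None else min(k, n)
    tree = cKDTree(samples.xy)
    d, idx = tree.query(targets, k=kq)
    d = np.atleast_2d(d.reshape(len(targets), kq))
    idx = np.atleast_2d(idx.reshape(len(targets), kq))
    vals = samples.values[idx]
    out = np.empty(len(targets))
    exact = d[:, 0] == 0.0  # exact hit short-circuits to the sample value
    out[exact] = vals[exact, 0]
    rest = ~exact
    if rest.any():
        w = d[rest] ** (-power)
        out[rest] = (w * vals[rest]).sum(axis=1) / w.sum(axis=1)
    return out


def idw(
    samples: PointSamples, target: Grid, power: float, k: int | None = 12
) -> Grid:
    """IDW-interpolate samples onto the cell centers of ``target``.

    ``k`` limits the neighborhood to the k nearest samples (``None`` = all).
    Nodata cells of the template stay nodata.
    """
    if len(samples) < 1:
        raise SuitabilityError("IDW needs at least one sample")
    if power <= 0:
        raise ValueError("IDW power must be positive")
    rows, cols = np.nonzero(target.mask) if not target.mask.all() else np.nonzero(
        np.ones(target.shape, dtype=bool)
    )
    xll, yll, cs = target.transform
    ytop = yll + target.shape[0] * cs
    pts = np.column_stack([xll + (cols + 0.5) * cs, ytop - (rows + 0.5) * cs])
    vals = _idw_at_points(samples, pts, power, k)
    out = np.full(target.shape, target.nodata, dtype=float)
    out[rows, cols] = vals
    return target.copy_with(out)


def loo_rmse(samples: PointSamples, power: float, k: int | None = 12) -> float:
    """Leave-one-out RMSE of IDW predictions at the sample locations."""
    n = len(samples)
    if n < 3:
        raise SuitabilityError("leave-one-out requires at least 3 samples")
    errs = np.empty(n)
    for i in range(n):
        keep = np.arange(n) != i
        sub = PointSamples(samples.xy[keep], samples.values[keep])
        pred = _idw_at_points(sub, samples.xy[i : i + 1], power, k)[0]
        errs[i] = pred - samples.values[i]
    return float(np.sqrt(np.mean(errs**2)))


def optimize_power(
    samples: PointSamples,
    bounds: tuple[float, float] = (0.5, 20.0),
    k: int | None = 12,
) -> tuple[float, float]:
    """Power minimizing the leave-one-out RMSE, by bounded scalar search.

    Returns ``(power, loo_rmse)``.
    """
    low, high = bounds
    if not 0 < low < high:
        raise ValueError(f"bounds must satisfy 0 < low < high, got {bounds}")
    if len(samples) < 3:
        raise SuitabilityError("power optimization requires at least 3 samples")
    res = minimize_scalar(
        lambda p: loo_rmse(samples, p, k), bounds=(low, high), method="bounded",
        options={"xatol": 1e-3},
    )
    log.info("IDW power optimization: p = %.3f, LOO RMSE = %.4g", res.x, res.fun)
    return float(res.x), float(res.fun)
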