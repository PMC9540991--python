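"""Landscape and climate covariates over expansion zones and trap buffers.

Eight zone-level summaries are computed for each species-trap expansion
zone: proportional cover of broadleaf/mixed woodland, coniferous woodland,
suburban land and protected areas, plus the mean and variance of growing
degree-days above 5 degC (GDD5) and of elevation.  Trap-level summaries are
proportional covers within a 1-km radius circle around the trap, evaluated
on the 25-m landcover grid by the center-in-circle rule.

Zone proportions are computed from the 1-km fractional-cover rasters, which
are exact block aggregates of the 25-m landcover, so zone cover is
area-exact.  Variances are population variances by default (zones are
exhaustively enumerated, not sampled).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .expansion import TrapWindow, ZoneGrid
from .grids import Raster

#: Calendar month lengths of a 365-day year, used to convert monthly mean
#: temperature exceedance (degC) into degree-days.
MONTH_DAYS = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])


@dataclass(frozen=True)
class ZoneMetrics:
    """Covariate summaries over one expansion zone."""

    prop_broadleaf: float
    prop_conifer: float
    prop_suburban: float
    prop_protected: float
    gdd5_mean: float
    gdd5_var: float
    elev_mean: float
    elev_var: float

    def as_dict(self) -> dict[str, float]:
        return {
            "zone_broadleaf": self.prop_broadleaf,
            "zone_conifer": self.prop_conifer,
            "zone_suburban": self.prop_suburban,
            "zone_protected": self.prop_protected,
            "zone_gdd5_mean": self.gdd5_mean,
            "zone_gdd5_var": self.gdd5_var,
            "zone_elev_mean": self.elev_mean,
            "zone_elev_var": self.elev_var,
        }


@dataclass(frozen=True)
class BufferMetrics:
    """Proportional landcover within a small circle around a trap."""

    prop_woodland: float
    prop_broadleaf: float
    prop_conifer: float
    prop_suburban: float

    def as_dict(self) -> dict[str, float]:
        return {
            "buffer_woodland": self.prop_woodland,
            "buffer_broadleaf": self.prop_broadleaf,
            "buffer_conifer": self.prop_conifer,
            "buffer_suburban": self.prop_suburban,
        }


def gdd5(monthly_temp: Sequence[Raster], base: float = 5.0) -> Raster:
    """Annual growing degree-days above ``base`` degC from 12 monthly means.

    Per cell, ``GDD = sum_m max(0, T_m - base) * days_m`` with calendar month
    lengths of a 365-day year.  Monotone non-decreasing in every monthly
    temperature.
    """
    if len(monthly_temp) != 12:
        raise ValueError("need 12 monthly temperature rasters")
    ref = monthly_temp[0]
    for r in monthly_temp[1:]:
        if not ref.same_grid(r):
            raise ValueError("monthly temperature rasters are not co-registered")
    acc = np.zeros_like(ref.data, dtype=float)
    for days, r in zip(MONTH_DAYS, monthly_temp):
        acc += np.maximum(0.0, r.data - base) * days
    return Raster(acc, ref.x0, ref.y0, ref.cell)


def _zone_mask_1km(zone: ZoneGrid, raster: Raster) -> np.ndarray:
    """Boolean mask of the raster's cells whose centers fall inside member
    10-km cells of the zone.  Cells of the zone lying outside the raster
    footprint are ignored (synthetic landscapes are finite; the zone ellipse
    may overhang the mapped area)."""
    if len(zone) == 0:
        raise ValueError("empty zone")
    ox, oy = zone.origin
    member = {
        (int(np.floor((cx - ox) / zone.cell)), int(np.floor((cy - oy) / zone.cell)))
        for cx, cy in zone.cells
    }
    X, Y = raster.center_grids()
    ix = np.floor((X - ox) / zone.cell).astype(int)
    iy = np.floor((Y - oy) / zone.cell).astype(int)
    mask = np.zeros(raster.data.shape, dtype=bool)
    for i, j in member:
        mask |= (ix == i) & (iy == j)
    return mask


def zone_summary(
    zone: ZoneGrid,
    habitat: dict[str, Raster],
    gdd5_raster: Raster,
    elevation: Raster,
    sample_variance: bool = False,
) -> ZoneMetrics:
    """Summarise the eight landscape/climate covariates over one zone.

    ``habitat`` maps class names (``broadleaf``, ``conifer``, ``suburban``,
    ``protected``) to 1-km fractional-cover rasters co-registered with
    ``gdd5_raster`` and ``elevation``.
    """
    ref = elevation
    for r in list(habitat.values()) + [gdd5_raster]:
        if not ref.same_grid(r):
            raise ValueError("zone summary rasters are not co-registered")
    mask = _zone_mask_1km(zone, ref)
    n = int(mask.sum())
    if n == 0:
        raise ValueError(
            f"zone {zone.species_id}/{zone.trap_id} lies outside the raster extent"
        )
    ddof = 1 if sample_variance else 0

    def prop(name: str) -> float:
        return float(habitat[name].data[mask].mean())

    g = gdd5_raster.data[mask]
    e = elevation.data[mask]
    return ZoneMetrics(
        prop_broadleaf=prop("broadleaf"),
        prop_conifer=prop("conifer"),
        prop_suburban=prop("suburban"),
        prop_protected=prop("protected"),
        gdd5_mean=float(g.mean()),
        gdd5_var=float(g.var(ddof=ddof)),
        elev_mean=float(e.mean()),
        elev_var=float(e.var(ddof=ddof)),
    )


def buffer_cell_mask(landcover: Raster, x: float, y: float, radius: float) -> np.ndarray:
    """Mask of landcover cells whose centers lie within ``radius`` km of (x, y)."""
    xmin, ymin, xmax, ymax = landcover.extent
    if not (xmin <= x - radius and x + radius <= xmax and ymin <= y - radius and y + radius <= ymax):
        raise ValueError(f"buffer around ({x}, {y}) extends outside the raster")
    # window of candidate rows/cols to avoid touching the full 25-m grid
    c0 = max(0, int(np.floor((x - radius - landcover.x0) / landcover.cell)) - 1)
    c1 = min(landcover.nx, int(np.ceil((x + radius - landcover.x0) / landcover.cell)) + 1)
    r0 = max(0, int(np.floor((y - radius - landcover.y0) / landcover.cell)) - 1)
    r1 = min(landcover.ny, int(np.ceil((y + radius - landcover.y0) / landcover.cell)) + 1)
    mask = np.zeros(landcover.data.shape, dtype=bool)
    xs = landcover.x0 + (np.arange(c0, c1) + 0.5) * landcover.cell
    ys = landcover.y0 + (np.arange(r0, r1) + 0.5) * landcover.cell
    DX, DY = np.meshgrid(xs - x, ys - y)
    mask[r0:r1, c0:c1] = DX**2 + DY**2 <= radius**2
    return mask


def trap_buffer_summary(
    trap: TrapWindow,
    landcover: Raster,
    class_codes: dict[str, int],
    radius: float = 1.0,
) -> BufferMetrics:
    """Proportional cover of each class among 25-m cells whose centers lie
    within ``radius`` km of the trap."""
    mask = buffer_cell_mask(landcover, trap.x, trap.y, radius)
    values = landcover.data[mask]
    n = values.size

    def prop(name: str) -> float:
        return float(np.count_nonzero(values == class_codes[name]) / n)

    broadleaf = prop("broadleaf")
    conifer = prop("conifer")
    return BufferMetrics(
        prop_woodland=broadleaf + conifer,
        prop_broadleaf=broadleaf,
        prop_conifer=conifer,
        prop_suburban=prop("suburban"),
    )
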