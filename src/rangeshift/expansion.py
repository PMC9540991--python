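"""Expansion-zone geometry: analysable species-trap pairs, zones, distances.

A species' *baseline distribution* is the set of occupied 1-km cells during a
reference period; a monitoring trap outside that range is a potential
colonisation target.  A species-trap pair enters the analysis only if the
trap is well outside the baseline range (at least ``MIN_PAIR_DISTANCE_KM``
from any record).  For every valid pair an *expansion zone* is constructed:
the set of 10-km grid cells whose centers ``c`` satisfy

    d(c, nearest record) + d(c, trap) < 100 km + D_min,

where ``D_min`` is the minimum trap-record distance.  For a single record
this is the interior of an ellipse with the record and the trap as foci; for
scattered records the zone flexes around the baseline range margin.  The
zone is the region a colonising population most plausibly crosses, over
which landscape covariates are summarised.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

#: A pair is analysable only if the trap is at least this far (km) from every
#: baseline record (boundary inclusive).
MIN_PAIR_DISTANCE_KM = 20.0

#: Slack added to D_min in the zone inclusion inequality (km).
ZONE_BUFFER_KM = 100.0


@dataclass(frozen=True)
class OccurrenceSet:
    """Baseline records of one species as occupied 1-km cell centers (km).

    Duplicate cells are collapsed: multiple records in the same 1-km cell
    count once.
    """

    species_id: str
    cells: np.ndarray

    def __post_init__(self) -> None:
        c = np.atleast_2d(np.asarray(self.cells, dtype=float))
        if c.size == 0:
            c = c.reshape(0, 2)
        if c.shape[1] != 2:
            raise ValueError("cells must be an (n, 2) array of km coordinates")
        object.__setattr__(self, "cells", np.unique(c, axis=0))

    def __len__(self) -> int:
        return len(self.cells)

    @classmethod
    def from_points(cls, species_id: str, points: np.ndarray, cell: float = 1.0) -> "OccurrenceSet":
        """Snap raw record locations to the centers of their 1-km cells."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        centers = (np.floor(p / cell) + 0.5) * cell
        return cls(species_id, centers)


@dataclass(frozen=True)
class TrapWindow:
    """A continuously operating trap with its observation window (years)."""

    trap_id: str
    x: float
    y: float
    start_year: int
    end_year: int

    def __post_init__(self) -> None:
        if self.end_year < self.start_year:
            raise ValueError(
                f"trap {self.trap_id}: end_year < start_year"
            )

    @property
    def location(self) -> np.ndarray:
        return np.array([self.x, self.y])

    @property
    def length_years(self) -> int:
        """Years of operation, inclusive of both endpoint years."""
        return self.end_year - self.start_year + 1


@dataclass(frozen=True)
class ZoneGrid:
    """The 10-km cells of one species-trap expansion zone (cell centers, km)."""

    species_id: str
    trap_id: str
    cells: np.ndarray
    cell: float = 10.0
    d_min: float = float("nan")
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        c = np.atleast_2d(np.asarray(self.cells, dtype=float))
        if c.size == 0:
            c = c.reshape(0, 2)
        object.__setattr__(self, "cells", c)

    def __len__(self) -> int:
        return len(self.cells)


def min_trap_distance(occ: OccurrenceSet, trap: TrapWindow) -> float:
    """Minimum Euclidean distance (km) from the trap to any baseline cell."""
    if len(occ) == 0:
        raise ValueError(f"species {occ.species_id}: empty occurrence set")
    return float(np.min(np.hypot(*(occ.cells - trap.location).T)))


def valid_pairs(
    occurrences: list[OccurrenceSet],
    traps: list[TrapWindow],
    min_distance: float = MIN_PAIR_DISTANCE_KM,
) -> list[tuple[str, str]]:
    """Species-trap pairs where the trap is clearly outside the baseline range.

    A pair is valid iff the trap is at least ``min_distance`` km (inclusive)
    from every baseline record of the species.
    """
    pairs = []
    for occ in occurrences:
        for trap in traps:
            if min_trap_distance(occ, trap) >= min_distance:
                pairs.append((occ.species_id, trap.trap_id))
    return pairs


def build_zone(
    occ: OccurrenceSet,
    trap: TrapWindow,
    cell: float = 10.0,
    origin: tuple[float, float] = (0.0, 0.0),
    buffer_km: float = ZONE_BUFFER_KM,
) -> ZoneGrid:
    """Construct the expansion zone for a valid species-trap pair.

    Membership is evaluated at 10-km cell centers on a grid aligned to
    ``origin``; the inclusion inequality is strict (<).  Every member cell
    center lies within ``buffer_km + d_min`` of the trap, which bounds the
    search window.
    """
    d_min = min_trap_distance(occ, trap)
    bound = buffer_km + d_min

    ox, oy = origin
    # candidate cell centers within `bound` of the trap
    lo_i = int(np.floor((trap.x - bound - ox) / cell))
    hi_i = int(np.floor((trap.x + bound - ox) / cell))
    lo_j = int(np.floor((trap.y - bound - oy) / cell))
    hi_j = int(np.floor((trap.y + bound - oy) / cell))
    xs = ox + (np.arange(lo_i, hi_i + 1) + 0.5) * cell
    ys = oy + (np.arange(lo_j, hi_j + 1) + 0.5) * cell
    X, Y = np.meshgrid(xs, ys)
    centers = np.column_stack([X.ravel(), Y.ravel()])

    d_trap = np.hypot(centers[:, 0] - trap.x, centers[:, 1] - trap.y)
    near = d_trap <= bound  # necessary condition; cheap pre-filter
    centers = centers[near]
    d_trap = d_trap[near]
    d_rec = cdist(centers, occ.cells).min(axis=1)
    member = (d_rec + d_trap) < bound
    return ZoneGrid(
        species_id=occ.species_id,
        trap_id=trap.trap_id,
        cells=centers[member],
        cell=cell,
        d_min=d_min,
        origin=origin,
    )


def distance_covariate(
    occ: OccurrenceSet,
    trap: TrapWindow,
    k: int = 3,
    unit_km: float = 100.0,
) -> float:
    """Mean distance from the trap to its ``k`` nearest distinct baseline
    cells, expressed in units of ``unit_km`` (default 100 km)."""
    if len(occ) < k:
        raise ValueError(
            f"species {occ.species_id}: needs >= {k} distinct baseline cells, "
            f"has {len(occ)}"
        )
    d = np.sort(np.hypot(*(occ.cells - trap.location).T))
    return float(d[:k].mean() / unit_km)
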