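"""Habitat-network conductance: the landscape-configuration covariate.

Habitat cells (1-km resolution, area ``A_i`` km^2) are nodes of a network in
which every pair of nodes is linked by a per-generation colonisation rate

    k_ij = C * A_i * A_j * exp(-d_ij / alpha),    alpha = delta / 2,

where ``d_ij`` is the center-to-center distance and ``delta`` the mean
per-generation dispersal distance of a negative-exponential 2-D kernel
(whose mean displacement is twice its scale parameter).  Edges are truncated
at ``5 * delta``, discarding under 0.7% of kernel mass, to keep the network
sparse; the truncation is configurable and can be disabled.

Treating the rates as electrical conductances, the *effective conductance*
between a source region (the baseline range margin) and a target (a
monitoring trap) summarises, in one number, how fast a species can spread
across the intervening landscape over multiple generations: it integrates
habitat amount, patch sizes and their spatial arrangement, and is obtained
by merging all source nodes into one terminal and solving the network
Laplacian for the two-terminal current at unit potential difference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import spsolve
from scipy.spatial import cKDTree

from .expansion import OccurrenceSet, TrapWindow, min_trap_distance
from .grids import Raster

#: Records up to this many km farther than the closest record are part of
#: the source terminal (boundary inclusive).
SOURCE_BUFFER_KM = 100.0

#: A record or target not sitting on a habitat node attaches to the nearest
#: node within this distance (km); otherwise it is dropped.
DEFAULT_SNAP_KM = 10.0


@dataclass(frozen=True)
class ConductanceVariant:
    """One of the tested conductance settings: mean dispersal distance
    (5, 10 or 20 km per generation) x habitat definition (broadleaf/mixed
    woodland alone, or with coniferous woodland included)."""

    dispersal_km: float = 5.0
    include_conifer: bool = False

    @property
    def habitat_classes(self) -> tuple[str, ...]:
        return ("broadleaf", "conifer") if self.include_conifer else ("broadleaf",)

    @property
    def label(self) -> str:
        woods = "allwood" if self.include_conifer else "broadleaf"
        return f"{woods}_d{self.dispersal_km:g}"


@dataclass(frozen=True)
class HabitatNetwork:
    """Habitat cells as nodes with symmetric per-generation colonisation rates.

    ``rates`` is a symmetric sparse matrix with zero diagonal; nodes with
    zero habitat area are absent by construction.
    """

    coords: np.ndarray           # (n, 2) cell centers, km
    areas: np.ndarray            # (n,) habitat area per node, km^2
    rates: sparse.csr_matrix     # (n, n) symmetric, zero diagonal
    dispersal_km: float
    rate_constant: float
    truncation_km: float

    @property
    def n_nodes(self) -> int:
        return len(self.areas)

    def nearest_node(self, point, max_dist: float | None = None) -> int | None:
        """Index of the node nearest to ``point``, or None if the network is
        empty or the nearest node is farther than ``max_dist``."""
        if self.n_nodes == 0:
            return None
        d = np.hypot(self.coords[:, 0] - point[0], self.coords[:, 1] - point[1])
        i = int(np.argmin(d))
        if max_dist is not None and d[i] > max_dist:
            return None
        return i


def habitat_raster(habitat: dict[str, Raster], classes) -> Raster:
    """Combined fractional-cover raster for the requested habitat classes."""
    rasters = [habitat[c] for c in classes]
    ref = rasters[0]
    total = sum(r.data for r in rasters)
    return Raster(np.asarray(total, dtype=float), ref.x0, ref.y0, ref.cell)


def build_habitat_network(
    habitat: Raster,
    dispersal_km: float,
    rate_constant: float = 1.0,
    truncation_factor: float | None = 5.0,
    min_area: float = 0.0,
) -> HabitatNetwork:
    """Build the colonisation-rate network from a fractional-cover raster.

    Nodes are cells with habitat area strictly greater than ``min_area``
    (km^2); ``truncation_factor=None`` keeps every pairwise edge (dense,
    for oracle comparisons on small landscapes).
    """
    if dispersal_km <= 0:
        raise ValueError("dispersal distance must be positive")
    frac = habitat.data
    rows, cols = np.nonzero(frac > min_area)
    areas = frac[rows, cols] * habitat.cell**2
    xs = habitat.x0 + (cols + 0.5) * habitat.cell
    ys = habitat.y0 + (rows + 0.5) * habitat.cell
    coords = np.column_stack([xs, ys])
    n = len(areas)

    alpha = dispersal_km / 2.0
    trunc = np.inf if truncation_factor is None else truncation_factor * dispersal_km
    if n == 0:
        rates = sparse.csr_matrix((0, 0))
        return HabitatNetwork(coords, areas, rates, dispersal_km, rate_constant, trunc)

    if np.isinf(trunc):
        i, j = np.triu_indices(n, k=1)
    else:
        tree = cKDTree(coords)
        pairs = tree.query_pairs(r=trunc * (1 + 1e-12), output_type="ndarray")
        i, j = (pairs[:, 0], pairs[:, 1]) if len(pairs) else (np.array([], int), np.array([], int))
    d = np.hypot(coords[i, 0] - coords[j, 0], coords[i, 1] - coords[j, 1])
    k = rate_constant * areas[i] * areas[j] * np.exp(-d / alpha)
    rates = sparse.coo_matrix(
        (np.concatenate([k, k]), (np.concatenate([i, j]), np.concatenate([j, i]))),
        shape=(n, n),
    ).tocsr()
    return HabitatNetwork(coords, areas, rates, dispersal_km, rate_constant, trunc)


def build_network_from_bundle(bundle, variant: ConductanceVariant, **kwargs) -> HabitatNetwork:
    """Convenience wrapper: network for one conductance variant of a
    synthetic landscape bundle."""
    hab = habitat_raster(bundle.habitat, variant.habitat_classes)
    return build_habitat_network(hab, variant.dispersal_km, **kwargs)


def select_sources(
    occ: OccurrenceSet,
    trap: TrapWindow,
    network: HabitatNetwork,
    snap_km: float = DEFAULT_SNAP_KM,
    buffer_km: float = SOURCE_BUFFER_KM,
) -> np.ndarray:
    """Source nodes for the circuit calculation.

    All baseline records within ``D_min + buffer_km`` of the trap (boundary
    inclusive) qualify; each is attached to the habitat node containing it
    or the nearest node within ``snap_km``, and records with no such node
    are dropped.
    """
    d_min = min_trap_distance(occ, trap)
    d = np.hypot(*(occ.cells - trap.location).T)
    qualifying = occ.cells[d <= d_min + buffer_km]
    if len(qualifying) == 0:
        raise ValueError("no qualifying baseline record for source selection")
    nodes = {
        idx
        for pt in qualifying
        if (idx := network.nearest_node(pt, max_dist=snap_km)) is not None
    }
    if not nodes:
        raise ValueError(
            f"no habitat node within {snap_km} km of any qualifying record"
        )
    return np.array(sorted(nodes))


def effective_conductance(network: HabitatNetwork, sources, target: int) -> float:
    """Two-terminal effective conductance from the merged sources to the target.

    All source nodes are contracted into one terminal held at unit potential,
    the target is grounded, and the interior potentials solve the reduced
    graph Laplacian; the returned value is the total current into the target.
    Returns 0.0 when the target is in a different connected component from
    every source, and +inf when the target is itself a source node.
    """
    sources = np.atleast_1d(np.asarray(sources, dtype=int))
    if len(sources) == 0:
        raise ValueError("sources must be nonempty")
    if network.n_nodes == 0:
        return 0.0
    if target < 0 or target >= network.n_nodes:
        raise ValueError(f"target node {target} not in network")
    if target in set(sources.tolist()):
        return float("inf")

    n_comp, labels = connected_components(network.rates, directed=False)
    if not np.any(labels[sources] == labels[target]):
        return 0.0
    comp = np.where(labels == labels[target])[0]
    pos = {node: k for k, node in enumerate(comp)}
    K = network.rates[comp][:, comp].tocsr()
    src = np.array(sorted({pos[s] for s in sources if labels[s] == labels[target]}))
    tgt = pos[target]

    m = len(comp)
    is_terminal = np.zeros(m, dtype=bool)
    is_terminal[src] = True
    is_terminal[tgt] = True
    interior = np.where(~is_terminal)[0]

    # current into the target from the sources directly
    k_ts = np.asarray(K[tgt].toarray()).ravel()[src].sum()
    if len(interior) == 0:
        return float(k_ts)

    deg = np.asarray(K.sum(axis=1)).ravel()
    L = sparse.diags(deg) - K
    L_ii = L[interior][:, interior].tocsc()
    K_int = K[interior]
    b = np.asarray(K_int[:, src].sum(axis=1)).ravel()  # source potential = 1
    v = spsolve(L_ii, b)
    k_ti = np.asarray(K[tgt].toarray()).ravel()[interior]
    return float(k_ts + k_ti @ v)


def conductance_covariate(
    value: float,
    floor: float = 1e-12,
) -> float:
    """Regression covariate: natural log of effective conductance, floored at
    a tiny positive value so disconnected (zero-conductance) pairs stay
    finite."""
    return float(np.log(max(value, floor)))
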