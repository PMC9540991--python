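"""Synthetic landscapes, species baselines, traps and arrival times.

Every downstream stage of the pipeline is testable against known ground
truth generated here:

* landscapes — a categorical 25-m landcover raster (broadleaf/mixed
  woodland, coniferous woodland, suburban, other) built by thresholding
  smoothed Gaussian random fields, so habitat *amount* and *clumpiness* are
  controlled independently; a protected-area overlay; 1-km elevation and
  monthly-temperature rasters with a north-south gradient and an
  elevation lapse; and 1-km fractional-cover rasters aggregated exactly
  from the 25-m landcover;
* species — woodland/farmland affiliation flags, a northern range limit,
  a per-species frailty (log-time offset), and baseline occurrences drawn
  from suitable 1-km cells south of the limit;
* arrival times — for each species-trap row, a constant-hazard
  (exponential) arrival time with mean ``exp(x' beta + b_s)``, right-
  censored at the end of the trap's operating window; and
* mechanistic spread — a stochastic per-generation lattice colonisation
  process on a habitat network, used to check that effective conductance
  predicts multi-generation spread speed.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .conductance import HabitatNetwork
from .expansion import OccurrenceSet, TrapWindow
from .grids import Raster, aggregate_fraction

#: Landcover class codes on the 25-m raster.
CLASS_CODES = {"other": 0, "broadleaf": 1, "conifer": 2, "suburban": 3}

#: UK-like monthly mean temperatures (degC) at mean elevation, Jan..Dec.
DEFAULT_MONTH_MEANS = (4.0, 4.2, 6.0, 8.2, 11.3, 14.2, 16.4, 16.2, 13.8, 10.6, 6.9, 4.8)


@dataclass(frozen=True)
class LandscapeConfig:
    """Parameters of the synthetic landscape generator.

    Cover fractions are realized exactly (cells are assigned by ranking a
    smoothed random field, so the target count of 25-m cells per class is
    hit deterministically).  ``clump_km`` is the Gaussian correlation length
    of the landcover fields: larger values give fewer, larger patches at the
    same cover fraction.
    """

    extent_km: int = 50
    fine_cell: float = 0.025           # 25-m landcover grain
    coarse_cell: float = 1.0           # 1-km climate/habitat grain
    frac_broadleaf: float = 0.08       # GB-like woodland cover ~10% total
    frac_conifer: float = 0.04
    frac_suburban: float = 0.06
    frac_protected: float = 0.07
    clump_km: float = 2.0
    elev_mean: float = 120.0           # m
    elev_sd: float = 60.0
    elev_clump_km: float = 8.0
    month_means: tuple = DEFAULT_MONTH_MEANS
    north_gradient: float = -0.006     # degC per km northing
    lapse_rate: float = -0.006         # degC per m elevation
    temp_noise_sd: float = 0.3
    temp_clump_km: float = 10.0

    def validate(self) -> None:
        fracs = (self.frac_broadleaf, self.frac_conifer, self.frac_suburban, self.frac_protected)
        if any(f < 0 or f > 1 for f in fracs):
            raise ValueError("cover fractions must lie in [0, 1]")
        if self.frac_broadleaf + self.frac_conifer + self.frac_suburban > 1:
            raise ValueError("class fractions sum to more than 1")
        if self.extent_km <= 0:
            raise ValueError("extent must be positive")
        ratio = self.coarse_cell / self.fine_cell
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("coarse cell must be a multiple of the fine cell")
        if self.extent_km % self.coarse_cell:
            raise ValueError("extent must be a whole number of coarse cells")


@dataclass(frozen=True)
class LandscapeBundle:
    """Co-registered rasters of one synthetic landscape.

    ``landcover`` and ``protected`` are at 25-m grain; ``elevation``,
    ``monthly_temp`` and the fractional-cover rasters in ``habitat`` (keys
    ``broadleaf``, ``conifer``, ``suburban``, ``protected``) are at 1-km
    grain on the same origin.
    """

    landcover: Raster
    protected: Raster
    elevation: Raster
    monthly_temp: tuple
    habitat: dict[str, Raster]
    config: LandscapeConfig

    @property
    def extent_km(self) -> int:
        return self.config.extent_km


@dataclass(frozen=True)
class SpeciesSpec:
    """Attributes of one synthetic species."""

    species_id: str
    woodland: bool                # reportedly associated with woodland
    farmland: bool                # associated with anthropogenic habitats
    range_limit_km: float         # northing of the baseline range margin
    frailty: float                # b_s, log-time offset
    occupancy_p: float            # occupancy probability in suitable cells


@dataclass(frozen=True)
class SpeciesConfig:
    n_species: int = 12
    p_woodland: float = 0.6       # flags drawn independently: a species may
    p_farmland: float = 0.5       # be both, either, or neither
    occupancy_p: float = 0.3
    frailty_sd: float = 0.5
    range_limit_frac: tuple = (0.25, 0.55)  # limit ~ U(frac) * extent
    woodland_min_fraction: float = 0.05     # suitability threshold, 1-km cells
    min_occupied: int = 3

    def validate(self) -> None:
        if self.n_species < 1:
            raise ValueError("need at least one species")
        for p in (self.p_woodland, self.p_farmland, self.occupancy_p):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")


@dataclass(frozen=True)
class SyntheticTruth:
    """The data-generating survival model, recorded exactly as simulated.

    ``beta`` maps covariate names (plus ``Intercept``) to coefficients on
    the log-mean-time scale; ``frailties`` maps species ids to their
    log-time offsets b_s, drawn N(0, frailty_sd^2).
    """

    beta: dict[str, float]
    frailty_sd: float
    frailties: dict[str, float] = field(default_factory=dict)


def _smooth_field(rng: np.random.Generator, shape, sigma_cells: float) -> np.ndarray:
    """Standardized smoothed Gaussian random field (float32 to bound memory)."""
    z = rng.standard_normal(shape).astype(np.float32)
    if sigma_cells > 0:
        z = gaussian_filter(z, sigma=sigma_cells, mode="reflect")
    sd = z.std()
    if sd > 0:
        z = (z - z.mean()) / sd
    return z


def generate_landscape(config: LandscapeConfig, seed: int) -> LandscapeBundle:
    """Generate one landscape; bit-identical for the same (config, seed)."""
    config.validate()
    rng = np.random.default_rng(seed)
    n25 = int(round(config.extent_km / config.fine_cell))
    sigma25 = config.clump_km / config.fine_cell

    landcover = np.zeros((n25, n25), dtype=np.int8)
    unassigned = np.ones((n25, n25), dtype=bool)
    total = n25 * n25
    for name in ("broadleaf", "conifer", "suburban"):
        frac = getattr(config, f"frac_{name}")
        count = int(round(frac * total))
        if count == 0:
            _ = _smooth_field(rng, (n25, n25), sigma25)  # keep stream aligned
            continue
        fld = _smooth_field(rng, (n25, n25), sigma25)
        fld[~unassigned] = -np.inf
        flat = fld.ravel()
        idx = np.argpartition(flat, -count)[-count:]
        sel = np.zeros(total, dtype=bool)
        sel[idx] = True
        sel = sel.reshape(n25, n25)
        landcover[sel] = CLASS_CODES[name]
        unassigned &= ~sel

    prot_count = int(round(config.frac_protected * total))
    prot = np.zeros((n25, n25), dtype=bool)
    if prot_count > 0:
        fld = _smooth_field(rng, (n25, n25), sigma25)
        idx = np.argpartition(fld.ravel(), -prot_count)[-prot_count:]
        prot.ravel()[idx] = True

    n1 = int(round(config.extent_km / config.coarse_cell))
    elev_z = _smooth_field(rng, (n1, n1), config.elev_clump_km / config.coarse_cell)
    elevation = np.maximum(0.0, config.elev_mean + config.elev_sd * elev_z.astype(float))

    anomaly = _smooth_field(rng, (n1, n1), config.temp_clump_km / config.coarse_cell)
    y_centers = (np.arange(n1) + 0.5) * config.coarse_cell
    north = (y_centers - config.extent_km / 2.0)[:, None] * np.ones((1, n1))
    monthly = tuple(
        Raster(
            m
            + config.north_gradient * north
            + config.lapse_rate * (elevation - config.elev_mean)
            + config.temp_noise_sd * anomaly.astype(float),
            cell=config.coarse_cell,
        )
        for m in config.month_means
    )

    lc = Raster(landcover, cell=config.fine_cell)
    prot_r = Raster(prot, cell=config.fine_cell)
    habitat = {
        name: aggregate_fraction(lc, CLASS_CODES[name], config.coarse_cell)
        for name in ("broadleaf", "conifer", "suburban")
    }
    habitat["protected"] = aggregate_fraction(
        Raster(prot.astype(np.int8), cell=config.fine_cell), 1, config.coarse_cell
    )
    return LandscapeBundle(
        landcover=lc,
        protected=prot_r,
        elevation=Raster(elevation, cell=config.coarse_cell),
        monthly_temp=monthly,
        habitat=habitat,
        config=config,
    )


def generate_species_and_baseline(
    config: SpeciesConfig,
    landscape: LandscapeBundle,
    seed: int,
) -> tuple[list[SpeciesSpec], list[OccurrenceSet]]:
    """Draw species attributes and their baseline occupied 1-km cells.

    Suitable cells for woodland species are 1-km cells whose combined
    woodland fraction reaches ``woodland_min_fraction``; other species can
    occupy any cell.  Cells south of (northing not exceeding) the species'
    range limit are occupied independently with probability ``occupancy_p``;
    if fewer than ``min_occupied`` cells result, the southernmost suitable
    cells are force-occupied so every species supports the three-nearest
    distance covariate.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    hab = landscape.habitat
    woodfrac = hab["broadleaf"].data + hab["conifer"].data
    ref = hab["broadleaf"]
    X, Y = ref.center_grids()
    lo, hi = config.range_limit_frac

    specs: list[SpeciesSpec] = []
    occs: list[OccurrenceSet] = []
    for i in range(config.n_species):
        sid = f"sp{i:02d}"
        woodland = rng.random() < config.p_woodland
        farmland = rng.random() < config.p_farmland
        limit = float(rng.uniform(lo, hi) * landscape.extent_km)
        frailty = float(rng.normal(0.0, config.frailty_sd)) if config.frailty_sd > 0 else 0.0
        suitable = woodfrac >= config.woodland_min_fraction if woodland else np.ones_like(woodfrac, bool)
        south = Y <= limit
        eligible = suitable & south
        occupied = eligible & (rng.random(eligible.shape) < config.occupancy_p)
        if occupied.sum() < config.min_occupied:
            ys = np.where(eligible.ravel() & ~occupied.ravel())[0]
            need = config.min_occupied - int(occupied.sum())
            # southernmost eligible cells first (row-major => ascending northing)
            occupied.ravel()[ys[:need]] = True
        cells = np.column_stack([X[occupied], Y[occupied]])
        specs.append(SpeciesSpec(sid, woodland, farmland, limit, frailty, config.occupancy_p))
        occs.append(OccurrenceSet(sid, cells))
    return specs, occs


def generate_traps(
    landscape: LandscapeBundle,
    n_traps: int,
    seed: int,
    start_year: int = 0,
    n_years: int = 27,
    p_continuous: float = 0.45,
    margin_km: float = 2.0,
    y_min_frac: float = 0.5,
) -> list[TrapWindow]:
    """Place traps uniformly in the northern part of the landscape.

    A fraction ``p_continuous`` of traps operate for the whole study period;
    the rest cease at a uniform year, producing right-censored rows.
    """
    rng = np.random.default_rng(seed)
    ext = landscape.extent_km
    traps = []
    for i in range(n_traps):
        x = float(rng.uniform(margin_km, ext - margin_km))
        y = float(rng.uniform(max(margin_km, y_min_frac * ext), ext - margin_km))
        if rng.random() < p_continuous:
            end = start_year + n_years - 1
        else:
            end = int(rng.integers(start_year + 5, start_year + n_years - 1))
        traps.append(TrapWindow(f"trap{i:02d}", x, y, start_year, end))
    return traps


def simulate_arrivals(
    truth: SyntheticTruth,
    design: pd.DataFrame,
    windows: list[TrapWindow],
    seed: int,
    year_resolution: bool = False,
) -> pd.DataFrame:
    """Simulate right-censored arrival times for each species-trap row.

    For each row the mean time is ``mu = exp(x' beta + b_s)`` and the
    arrival time T is exponential with mean ``mu``; the row is an event if
    T falls within the trap's operating window, else right-censored at the
    window end.  With ``year_resolution`` the event times are floored to
    whole years and first-year arrivals assigned 0.5 years (avoids
    zero-exposure rows).
    """
    lengths = {t.trap_id: t.length_years for t in windows}
    for t in windows:
        if t.length_years <= 0:
            raise ValueError(f"trap {t.trap_id}: non-positive window length")
    missing = set(design["trap_id"]) - set(lengths)
    if missing:
        raise ValueError(f"design rows reference unknown traps: {sorted(missing)}")

    rng = np.random.default_rng(seed)
    eta = np.full(len(design), truth.beta.get("Intercept", 0.0), dtype=float)
    for name, coef in truth.beta.items():
        if name == "Intercept":
            continue
        eta += coef * design[name].to_numpy(dtype=float)
    b = design["species_id"].map(lambda s: truth.frailties.get(s, 0.0)).to_numpy(dtype=float)
    mu = np.exp(eta + b)
    T = rng.exponential(mu)
    L = design["trap_id"].map(lengths).to_numpy(dtype=float)
    event = T <= L
    time = np.where(event, T, L)
    if year_resolution:
        yr = np.floor(time)
        yr[(yr == 0) & event] = 0.5
        time = np.where(event, yr, L)

    out = design.copy()
    out["time"] = time
    out["event"] = event.astype(int)
    return out


def simulate_spread(
    network: HabitatNetwork,
    sources,
    target: int,
    max_generations: int,
    seed: int,
) -> int | None:
    """Stochastic per-generation colonisation on a habitat network.

    Each generation, an empty node j becomes occupied with probability
    ``1 - exp(-sum_i occupied k_ij)``.  Returns the first generation at
    which the target is occupied, or None if still empty after
    ``max_generations`` (censored).
    """
    if network.n_nodes == 0:
        raise ValueError("empty network")
    if not (0 <= target < network.n_nodes):
        raise ValueError(f"target node {target} not in network")
    sources = np.atleast_1d(np.asarray(sources, dtype=int))
    if len(sources) == 0:
        raise ValueError("sources must be nonempty")

    rng = np.random.default_rng(seed)
    occupied = np.zeros(network.n_nodes, dtype=bool)
    occupied[sources] = True
    if occupied[target]:
        return 0
    for gen in range(1, max_generations + 1):
        pressure = network.rates @ occupied.astype(float)
        p = 1.0 - np.exp(-pressure)
        new = (~occupied) & (rng.random(network.n_nodes) < p)
        if not new.any():
            continue
        occupied |= new
        if occupied[target]:
            return gen
    return None
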