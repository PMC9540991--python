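"""End-to-end assembly of the species-trap analysis table.

Chains the pipeline stages: valid species-trap pairs, expansion-zone
construction, landscape/climate summaries, trap-buffer summaries, the
distance covariate and the habitat-network conductance covariate, producing
one row per analysable species-trap pair ready for survival modelling.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .conductance import (
    ConductanceVariant,
    build_network_from_bundle,
    conductance_covariate,
    effective_conductance,
    select_sources,
)
from .expansion import (
    OccurrenceSet,
    TrapWindow,
    build_zone,
    distance_covariate,
    valid_pairs,
)
from .metrics import gdd5, trap_buffer_summary, zone_summary
from .synthetic import CLASS_CODES, LandscapeBundle, SpeciesSpec


def assemble_covariate_table(
    bundle: LandscapeBundle,
    specs: list[SpeciesSpec],
    occurrences: list[OccurrenceSet],
    traps: list[TrapWindow],
    variant: ConductanceVariant | None = None,
    min_pair_distance: float | None = None,
) -> pd.DataFrame:
    """One covariate row per valid species-trap pair.

    Columns: species flags (``woodland``, ``farmland``), ``distance`` (mean
    distance to the three nearest baseline cells, 100-km units), the eight
    zone summaries, the trap-buffer covers and, if a conductance variant is
    given, ``conductance``/``log_conductance`` of the woodland network.
    """
    occ_by_id = {o.species_id: o for o in occurrences}
    spec_by_id = {s.species_id: s for s in specs}
    trap_by_id = {t.trap_id: t for t in traps}
    kwargs = {} if min_pair_distance is None else {"min_distance": min_pair_distance}
    pairs = valid_pairs(occurrences, traps, **kwargs)

    gdd = gdd5(bundle.monthly_temp)
    network = None
    if variant is not None:
        network = build_network_from_bundle(bundle, variant)

    rows = []
    for sid, tid in pairs:
        occ, trap, spec = occ_by_id[sid], trap_by_id[tid], spec_by_id[sid]
        if len(occ) < 3:
            continue  # cannot form the three-nearest distance covariate
        zone = build_zone(occ, trap)
        zm = zone_summary(zone, bundle.habitat, gdd, bundle.elevation)
        bm = trap_buffer_summary(trap, bundle.landcover, CLASS_CODES)
        row = {
            "species_id": sid,
            "trap_id": tid,
            "woodland": float(spec.woodland),
            "farmland": float(spec.farmland),
            "distance": distance_covariate(occ, trap),
            **zm.as_dict(),
            **bm.as_dict(),
        }
        if network is not None:
            cond = 0.0
            tgt = network.nearest_node(trap.location, max_dist=10.0)
            if tgt is not None:
                try:
                    sources = select_sources(occ, trap, network)
                except ValueError:
                    sources = None
                if sources is not None and tgt not in set(sources.tolist()):
                    cond = effective_conductance(network, sources, tgt)
            row["conductance"] = cond
            row["log_conductance"] = conductance_covariate(cond)
        rows.append(row)
    return pd.DataFrame(rows)
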