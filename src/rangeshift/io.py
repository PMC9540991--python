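"""CSV serialization of occurrences, traps, zones and survival tables."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .expansion import OccurrenceSet, TrapWindow, ZoneGrid


def write_occurrences(occurrences: list[OccurrenceSet], path: str | Path) -> None:
    rows = [
        {"species_id": occ.species_id, "x_km": x, "y_km": y}
        for occ in occurrences
        for x, y in occ.cells
    ]
    pd.DataFrame(rows, columns=["species_id", "x_km", "y_km"]).to_csv(path, index=False)


def read_occurrences(path: str | Path) -> list[OccurrenceSet]:
    df = pd.read_csv(path)
    return [
        OccurrenceSet(str(sid), sub[["x_km", "y_km"]].to_numpy())
        for sid, sub in df.groupby("species_id", sort=True)
    ]


def write_traps(traps: list[TrapWindow], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"trap_id": t.trap_id, "x_km": t.x, "y_km": t.y,
             "start_year": t.start_year, "end_year": t.end_year}
            for t in traps
        ]
    ).to_csv(path, index=False)


def read_traps(path: str | Path) -> list[TrapWindow]:
    df = pd.read_csv(path)
    return [
        TrapWindow(str(r.trap_id), float(r.x_km), float(r.y_km),
                   int(r.start_year), int(r.end_year))
        for r in df.itertuples()
    ]


def write_zone(zone: ZoneGrid, path: str | Path) -> None:
    pd.DataFrame(zone.cells, columns=["x_km", "y_km"]).to_csv(path, index=False)


def write_survival_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def read_survival_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def load_archived_table(path: str | Path) -> pd.DataFrame:
    """Load the study's archived derived analysis table (one species-trap row
    with covariates, time at risk and event flag).

    The archive is distributed separately (Dryad, doi:10.5061/dryad.dr7sqvb1k)
    and is not bundled with this package; download it and pass its local
    path.  Column names are normalized to lower case.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(
            f"archived analysis table not found at {path}; download the Dryad "
            "deposit (doi:10.5061/dryad.dr7sqvb1k) and place it there"
        )
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    return df
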