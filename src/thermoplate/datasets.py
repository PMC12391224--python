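"""Packaged reference data: the published 48 h chondrocyte experiment.

The fixture carries the 32 per-well integrated total-heat values
(uJ/cell) of the published four-group, eight-replicate run — no-cell
controls, cells without supplemental carbon, glucose-fed and
glutamine-fed chondrocytes at 150,000 cells per hydrogel — together
with the cartridge layout that produced them (samples in rows B-E,
references in rows A and F, groups in column pairs).

Note the source table reports the No Cells group in uJ/cell even though
those wells contain no cells; the values are reproduced verbatim without
reinterpreting the divisor.
"""

from __future__ import annotations

import pandas as pd

from .io import PlateLayout, WellAssignment

__all__ = [
    "GROUPS",
    "CELLS_PER_GEL",
    "load_heat_per_cell",
    "reference_layout",
]

GROUPS = ("No Cells", "Cells Only", "Cells + Glucose", "Cells + Glutamine")
CELLS_PER_GEL = 150_000

# per-well integrated total heat, uJ/cell, column-major within each group
_HEAT_PER_CELL = {
    # No Cells: columns 1-2
    "B1": 0.25, "C1": 0.03, "D1": 0.31, "E1": 0.66,
    "B2": 0.74, "C2": 0.56, "D2": 0.18, "E2": 0.25,
    # Cells Only: columns 3-4
    "B3": 3.26, "C3": 2.83, "D3": 3.00, "E3": 2.76,
    "B4": 3.45, "C4": 3.97, "D4": 3.00, "E4": 1.99,
    # Cells + Glucose: columns 5-6
    "B5": 1.54, "C5": 2.08, "D5": 3.03, "E5": 3.11,
    "B6": 2.65, "C6": 4.34, "D6": 2.61, "E6": 2.98,
    # Cells + Glutamine: columns 7-8
    "B7": 1.42, "C7": 0.68, "D7": 2.37, "E7": 2.23,
    "B8": 1.82, "C8": 1.77, "D8": 2.07, "E8": 2.83,
}

_GROUP_COLUMNS = {
    "No Cells": (1, 2),
    "Cells Only": (3, 4),
    "Cells + Glucose": (5, 6),
    "Cells + Glutamine": (7, 8),
}


def _group_of(well_id: str) -> str:
    col = int(well_id[1:])
    for group, cols in _GROUP_COLUMNS.items():
        if col in cols:
            return group
    raise KeyError(well_id)


def load_heat_per_cell() -> pd.DataFrame:
    """The 32 published per-well total-heat values.

    Returns a DataFrame with columns ``well_id``, ``group`` and
    ``heat_per_cell_uJ``, ordered column-major (B1, C1, ..., E8).
    """
    wells = sorted(_HEAT_PER_CELL, key=lambda w: (int(w[1:]), w[0]))
    return pd.DataFrame(
        {
            "well_id": wells,
            "group": [_group_of(w) for w in wells],
            "heat_per_cell_uJ": [_HEAT_PER_CELL[w] for w in wells],
        }
    )


def reference_layout() -> PlateLayout:
    """The published 48-well cartridge layout.

    Rows A and F hold the 16 cell-free references; rows B-E hold the 32
    sample gels, one group per column pair.  No-cell control wells carry
    ``cell_count = 0``; every other sample well carries 150,000 cells.
    """
    wells: list[WellAssignment] = []
    for col in range(1, 9):
        group = _group_of(f"B{col}")
        for row in "ABCDEF":
            wid = f"{row}{col}"
            if row in "AF":
                wells.append(WellAssignment(wid, "reference"))
            else:
                cells = 0 if group == "No Cells" else CELLS_PER_GEL
                wells.append(WellAssignment(wid, "sample", group=group, cell_count=cells))
    return PlateLayout(wells=tuple(wells))
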