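"""Plate layouts, thermogram files, and result tables.

A 48-well microcalorimeter cartridge is organised as 6 rows (A-F) by 8
columns.  Each well holds a hermetically sealed titanium capsule and is
either a *sample* well or a cell-free *reference* well; the instrument
compares every sample against the references loaded in the same column,
so any column that carries samples must also carry at least one
reference.  The conventional loading puts the 16 references in the top
and bottom rows, but any declared row is accepted.

File dialects
-------------
Thermogram files are delimited text (comma or tab, auto-detected) in
either a *wide* dialect (``time_s`` plus one power column per well id)
or a *long* dialect (``time_s, well_id, power_uW``).  Layout files are
YAML with ``n_rows``, ``n_cols`` and a ``wells`` list of
``{id, role, group, cells}`` entries.  All times are seconds from the
start of recording and all powers are microwatts, so that a time
integral is directly in microjoules (1 uW * s = 1 uJ).
"""

from __future__ import annotations

import re
import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "WellAssignment",
    "PlateLayout",
    "Thermogram",
    "ThermogramSet",
    "LayoutError",
    "ThermogramError",
    "parse_well_id",
    "read_layout",
    "read_thermograms",
    "write_heat_table",
    "read_heat_table",
    "HEAT_TABLE_COLUMNS",
]

HEAT_TABLE_COLUMNS = ["well_id", "group", "total_heat_uJ", "cells", "heat_per_cell_uJ"]

_WELL_RE = re.compile(r"^([A-Za-z])(\d{1,2})$")


class LayoutError(ValueError):
    """A plate layout violates the cartridge's structural rules."""


class ThermogramError(ValueError):
    """A thermogram file or trace is malformed."""


def parse_well_id(well_id: str) -> tuple[int, int]:
    """Parse ``"D6"`` into 0-based ``(row, column)`` indices."""
    m = _WELL_RE.match(well_id.strip())
    if m is None:
        raise LayoutError(f"malformed well id {well_id!r}")
    row = string.ascii_uppercase.index(m.group(1).upper())
    col = int(m.group(2)) - 1
    if col < 0:
        raise LayoutError(f"malformed well id {well_id!r}: column must be >= 1")
    return row, col


def well_sort_key(well_id: str) -> tuple[int, int]:
    """Column-major ordering key (B1, C1, ... E1, B2, ...)."""
    row, col = parse_well_id(well_id)
    return col, row


@dataclass(frozen=True)
class WellAssignment:
    """One well's role on the cartridge.

    ``group`` is an experimental-group label for sample wells and may be
    None for references.  ``cell_count`` is the number of cells embedded
    in the well's hydrogel (0 for cell-free references and no-cell
    controls).
    """

    well_id: str
    role: str  # "sample" | "reference"
    group: str | None = None
    cell_count: int = 0

    def __post_init__(self) -> None:
        parse_well_id(self.well_id)  # validates
        if self.role not in ("sample", "reference"):
            raise LayoutError(
                f"well {self.well_id}: role must be 'sample' or 'reference', got {self.role!r}"
            )
        if self.cell_count < 0:
            raise LayoutError(f"well {self.well_id}: negative cell_count")
        if self.role == "reference" and self.cell_count != 0:
            raise LayoutError(f"reference well {self.well_id} must have cell_count 0")

    @property
    def row(self) -> int:
        return parse_well_id(self.well_id)[0]

    @property
    def column(self) -> int:
        return parse_well_id(self.well_id)[1]


@dataclass(frozen=True)
class PlateLayout:
    """Validated assignment of every used well on a cartridge."""

    wells: tuple[WellAssignment, ...]
    n_rows: int = 6
    n_cols: int = 8

    def __post_init__(self) -> None:
        object.__setattr__(self, "wells", tuple(self.wells))
        seen: set[tuple[int, int]] = set()
        for w in self.wells:
            pos = (w.row, w.column)
            if w.row >= self.n_rows or w.column >= self.n_cols:
                raise LayoutError(f"well {w.well_id} outside {self.n_rows}x{self.n_cols} plate")
            if pos in seen:
                raise LayoutError(f"duplicate well id {w.well_id}")
            seen.add(pos)
        # every column with samples must have a reference to subtract
        for col in sorted({w.column for w in self.wells if w.role == "sample"}):
            if not any(w.role == "reference" and w.column == col for w in self.wells):
                raise LayoutError(
                    f"column {col + 1} contains sample wells but no reference well"
                )

    @property
    def sample_wells(self) -> tuple[WellAssignment, ...]:
        return tuple(
            sorted(
                (w for w in self.wells if w.role == "sample"),
                key=lambda w: well_sort_key(w.well_id),
            )
        )

    @property
    def reference_wells(self) -> tuple[WellAssignment, ...]:
        return tuple(
            sorted(
                (w for w in self.wells if w.role == "reference"),
                key=lambda w: well_sort_key(w.well_id),
            )
        )

    def references_for_column(self, col: int) -> tuple[WellAssignment, ...]:
        return tuple(w for w in self.reference_wells if w.column == col)

    def __getitem__(self, well_id: str) -> WellAssignment:
        for w in self.wells:
            if w.well_id.upper() == well_id.upper():
                return w
        raise KeyError(well_id)

    def __contains__(self, well_id: str) -> bool:
        try:
            self[well_id]
        except KeyError:
            return False
        return True


@dataclass
class Thermogram:
    """One well's uniformly sampled heat-flow trace (seconds, microwatts)."""

    well_id: str
    times: np.ndarray
    powers: np.ndarray
    sampling_rate_hz: float = 1.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.powers = np.asarray(self.powers, dtype=float)
        if self.times.shape != self.powers.shape or self.times.ndim != 1:
            raise ThermogramError(
                f"well {self.well_id}: times and powers must be 1-D and the same length"
            )
        if self.sampling_rate_hz <= 0:
            raise ThermogramError(f"well {self.well_id}: sampling rate must be positive")
        if self.times.size >= 2:
            dt = np.diff(self.times)
            if np.any(dt <= 0):
                raise ThermogramError(f"well {self.well_id}: times must be strictly increasing")
            nominal = 1.0 / self.sampling_rate_hz
            if np.any(dt > 2.0 * nominal):
                i = int(np.argmax(dt > 2.0 * nominal))
                raise ThermogramError(
                    f"well {self.well_id}: sampling gap of {dt[i]:.3g} s at "
                    f"t={self.times[i]:.1f} s exceeds twice the nominal interval "
                    f"({nominal:.3g} s); gaps are not interpolated"
                )

    def __len__(self) -> int:
        return self.times.size


@dataclass
class ThermogramSet:
    """A plate layout plus one trace per used well, on a shared time grid."""

    layout: PlateLayout
    traces: dict[str, Thermogram] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [w.well_id for w in self.layout.sample_wells if w.well_id not in self.traces]
        if missing:
            raise ThermogramError(
                f"{len(missing)} sample wells have no trace: {', '.join(missing)}"
            )
        grids = {t.times.tobytes() for t in self.traces.values()}
        if len(grids) > 1:
            raise ThermogramError("traces do not share a common time grid")

    def __getitem__(self, well_id: str) -> Thermogram:
        return self.traces[well_id]

    @property
    def times(self) -> np.ndarray:
        return next(iter(self.traces.values())).times


# ---------------------------------------------------------------------------
# layout I/O


def _layout_from_mapping(doc: Mapping) -> PlateLayout:
    if "wells" not in doc:
        raise LayoutError("layout file has no 'wells' list")
    wells = []
    for entry in doc["wells"] or []:
        try:
            wells.append(
                WellAssignment(
                    well_id=str(entry["id"]),
                    role=str(entry["role"]),
                    group=entry.get("group"),
                    cell_count=int(entry.get("cells", 0)),
                )
            )
        except KeyError as exc:
            raise LayoutError(f"well entry {entry!r} is missing key {exc}") from exc
    return PlateLayout(
        wells=tuple(wells),
        n_rows=int(doc.get("n_rows", 6)),
        n_cols=int(doc.get("n_cols", 8)),
    )


def read_layout(path: str | Path) -> PlateLayout:
    """Read and validate a YAML plate-layout file."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, Mapping):
        raise LayoutError(f"{path}: layout file must be a mapping with a 'wells' list")
    return _layout_from_mapping(doc)


def write_layout(layout: PlateLayout, path: str | Path) -> None:
    doc = {
        "n_rows": layout.n_rows,
        "n_cols": layout.n_cols,
        "wells": [
            {"id": w.well_id, "role": w.role, "group": w.group, "cells": w.cell_count}
            for w in layout.wells
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# thermogram I/O


def _sniff_sep(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if header.count("\t") > header.count(",") else ","


def read_thermograms(path: str | Path, layout: PlateLayout) -> ThermogramSet:
    """Read a wide- or long-dialect thermogram file against a layout.

    The dialect is detected from the header: a ``well_id`` column means
    long format, otherwise every non-time column is taken to be a well.
    Traces are trimmed to the intersection of their time grids so the
    set shares a common grid.
    """
    path = Path(path)
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep)
    if "time_s" not in df.columns:
        raise ThermogramError(f"{path}: no 'time_s' column")

    if "well_id" in df.columns:  # long dialect
        if "power_uW" not in df.columns:
            raise ThermogramError(f"{path}: long dialect requires a 'power_uW' column")
        wide = df.pivot(index="time_s", columns="well_id", values="power_uW")
        wide = wide.sort_index()
    else:  # wide dialect
        wide = df.set_index("time_s").sort_index()

    unknown = [c for c in wide.columns if c not in layout]
    if unknown:
        raise ThermogramError(f"{path}: well ids not in layout: {', '.join(map(str, unknown))}")

    if wide.isna().any().any():
        # long files may cover different windows per well; keep rows shared by all
        wide = wide.dropna()
    if wide.empty:
        raise ThermogramError(f"{path}: no time points shared by all wells")

    times = wide.index.to_numpy(dtype=float)
    rate = 1.0 / float(np.median(np.diff(times))) if times.size >= 2 else 1.0
    traces = {
        str(col): Thermogram(str(col), times, wide[col].to_numpy(dtype=float), rate)
        for col in wide.columns
    }
    return ThermogramSet(layout=layout, traces=traces)


def write_thermograms(traces: Mapping[str, Thermogram], path: str | Path) -> None:
    """Write traces in the wide dialect (shared grid required)."""
    ids = sorted(traces, key=well_sort_key)
    times = traces[ids[0]].times
    data = {"time_s": times}
    for wid in ids:
        data[wid] = traces[wid].powers
    pd.DataFrame(data).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# heat table I/O


def write_heat_table(summaries: Iterable, path: str | Path) -> None:
    """Write per-well heat summaries as CSV in stable column-major order.

    The header is exactly ``well_id,group,total_heat_uJ,cells,heat_per_cell_uJ``.
    ``heat_per_cell_uJ`` is empty for wells with no cells.
    """
    rows = sorted(summaries, key=lambda s: well_sort_key(s.well_id))
    if not rows:
        raise ValueError("no heat summaries to write")
    df = pd.DataFrame(
        {
            "well_id": [s.well_id for s in rows],
            "group": [s.group for s in rows],
            "total_heat_uJ": [s.total_heat_uJ for s in rows],
            "cells": [s.cell_count for s in rows],
            "heat_per_cell_uJ": [s.heat_per_cell_uJ for s in rows],
        }
    )
    df.to_csv(path, index=False, float_format="%.6g")


def read_heat_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in HEAT_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df
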