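"""Data model and I/O for 384-well viability screening plates.

The screening substrate is a resazurin viability readout of 384-well
plates: 320 test compounds per plate, with negative (DMSO) and positive
(bortezomib) controls confined to the external columns 1, 2, 23 and 24.
This module provides well addressing, plate layouts, measurement records
and table round-tripping; normalization and scoring live in
:mod:`mbscreen.hitcall`.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from ._errors import FormatError, QCError, ValidationError

ROWS = "ABCDEFGHIJKLMNOP"  # 16 rows of a 384-well plate
N_COLUMNS = 24
CONTROL_COLUMNS = (1, 2, 23, 24)

_WELL_RE = re.compile(r"^([A-P])(\d{1,2})$")


@dataclass(frozen=True, order=True)
class WellAddress:
    """A well position, row letter A–P plus 1-based column 1–24."""

    row: str
    column: int

    def __post_init__(self) -> None:
        if self.row not in ROWS:
            raise ValidationError(f"row {self.row!r} outside A–{ROWS[-1]}")
        if not 1 <= self.column <= N_COLUMNS:
            raise ValidationError(f"column {self.column} outside 1–{N_COLUMNS}")

    @classmethod
    def parse(cls, text: str) -> "WellAddress":
        m = _WELL_RE.match(str(text).strip().upper())
        if not m:
            raise ValidationError(f"unparseable well address {text!r}")
        return cls(m.group(1), int(m.group(2)))

    def __str__(self) -> str:
        return f"{self.row}{self.column:02d}"


class WellRole(str, enum.Enum):
    TEST = "test"
    NEG_CONTROL = "neg_control"
    POS_CONTROL = "pos_control"
    EMPTY = "empty"


Layout = Mapping[WellAddress, WellRole]


def default_layout() -> dict[WellAddress, WellRole]:
    """The default 384-well screening layout ("default384").

    Columns 1, 2, 23 and 24 hold controls, negative (DMSO) and positive
    (bortezomib) alternating by row so that both appear 32 times per
    plate; columns 3–22 are the 320 test wells.
    """
    layout: dict[WellAddress, WellRole] = {}
    for i, row in enumerate(ROWS):
        for col in range(1, N_COLUMNS + 1):
            if col in CONTROL_COLUMNS:
                role = WellRole.NEG_CONTROL if i % 2 == 0 else WellRole.POS_CONTROL
            else:
                role = WellRole.TEST
            layout[WellAddress(row, col)] = role
    return layout


def read_layout(spec: str | Path | Layout) -> dict[WellAddress, WellRole]:
    """Resolve a layout spec: the preset name "default384", a CSV of
    well,role pairs, or an already-built mapping."""
    if isinstance(spec, Mapping):
        return dict(spec)
    if str(spec) == "default384":
        return default_layout()
    df = pd.read_csv(spec)
    cols = {c.lower() for c in df.columns}
    if not {"well", "role"} <= cols:
        raise FormatError(f"layout file {spec} needs columns well,role")
    df.columns = [c.lower() for c in df.columns]
    return {
        WellAddress.parse(r.well): WellRole(r.role) for r in df.itertuples(index=False)
    }


@dataclass(frozen=True)
class Measurement:
    """One well-level fluorescence reading (arbitrary units, >= 0)."""

    plate_id: str
    well: WellAddress
    compound_id: str | None
    dose: float | None  # µM; None for control/empty wells
    replicate: int
    raw_signal: float

    def __post_init__(self) -> None:
        import math

        if self.replicate < 1:
            raise ValidationError(f"replicate {self.replicate} < 1")
        if not math.isfinite(self.raw_signal) or self.raw_signal < 0:
            raise ValidationError(
                f"raw_signal {self.raw_signal!r} must be finite and >= 0"
            )


@dataclass
class PlateSet:
    """All measurements for one cell model under one layout.

    ``condition`` distinguishes the chemo-naïve ("sensitive") from the
    resistance-selected ("resistant") counterpart of the same model.
    """

    measurements: list[Measurement]
    layout: dict[WellAddress, WellRole] = field(default_factory=default_layout)
    cell_model: str = "unknown"
    condition: str = "sensitive"
    min_controls: int = 8

    def __post_init__(self) -> None:
        if self.condition not in ("sensitive", "resistant"):
            raise ValidationError(f"condition {self.condition!r}")
        self.validate()

    def validate(self) -> None:
        for m in self.measurements:
            if m.well not in self.layout:
                raise ValidationError(
                    f"well {m.well} on plate {m.plate_id} not in layout"
                )
        counts = (
            self.to_frame()
            .groupby(["plate_id", "role"], observed=True)["well"]
            .count()
            .unstack(fill_value=0)
        )
        for role in (WellRole.NEG_CONTROL.value, WellRole.POS_CONTROL.value):
            if role in counts:
                bad = counts.index[counts[role] < self.min_controls]
            else:
                bad = counts.index
            if len(bad):
                raise QCError(
                    f"plates {list(bad)} have fewer than {self.min_controls} "
                    f"{role} wells"
                )

    def to_frame(self) -> pd.DataFrame:
        """Long-format view: one row per measurement, with its layout role."""
        return pd.DataFrame(
            {
                "plate_id": [m.plate_id for m in self.measurements],
                "well": [str(m.well) for m in self.measurements],
                "role": [self.layout[m.well].value for m in self.measurements],
                "compound_id": [m.compound_id for m in self.measurements],
                "dose": [m.dose for m in self.measurements],
                "replicate": [m.replicate for m in self.measurements],
                "signal": [m.raw_signal for m in self.measurements],
            }
        )

    @property
    def plate_ids(self) -> list[str]:
        return sorted({m.plate_id for m in self.measurements})

    def n_wells(self, role: WellRole) -> int:
        return sum(1 for m in self.measurements if self.layout[m.well] is role)


REQUIRED_COLUMNS = ("plate_id", "well", "compound_id", "dose", "replicate", "signal")


def read_plate_table(
    path: str | Path,
    layout: str | Path | Layout = "default384",
    cell_model: str = "unknown",
    condition: str = "sensitive",
    min_controls: int = 8,
) -> PlateSet:
    """Read a long-format plate table (CSV or TSV, sniffed by extension).

    Expected columns: plate_id, well, compound_id, dose, replicate, signal.
    Rows whose well lies outside the layout raise a ValidationError naming
    the offending row.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","
    try:
        df = pd.read_csv(path, sep=sep)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file") from exc
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    lay = read_layout(layout)
    measurements = []
    for i, row in enumerate(df.itertuples(index=False)):
        well = WellAddress.parse(row.well)
        if well not in lay:
            raise ValidationError(f"{path} row {i}: well {row.well} not in layout")
        compound = None if pd.isna(row.compound_id) else str(row.compound_id)
        dose = None if pd.isna(row.dose) else float(row.dose)
        measurements.append(
            Measurement(
                plate_id=str(row.plate_id),
                well=well,
                compound_id=compound,
                dose=dose,
                replicate=int(row.replicate),
                raw_signal=float(row.signal),
            )
        )
    return PlateSet(
        measurements,
        layout=lay,
        cell_model=cell_model,
        condition=condition,
        min_controls=min_controls,
    )


def write_plate_table(plates: PlateSet, path: str | Path) -> None:
    """Write the long-format table read back by :func:`read_plate_table`."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","
    plates.to_frame().drop(columns="role").to_csv(path, sep=sep, index=False)


def layout_counts(layout: Layout) -> dict[str, int]:
    """Number of wells per role; the four roles partition the plate."""
    counts = {role.value: 0 for role in WellRole}
    for role in layout.values():
        counts[role.value] += 1
    return counts


def wells_by_role(layout: Layout, role: WellRole) -> list[WellAddress]:
    return sorted(w for w, r in layout.items() if r is role)


def iter_plates(plates: PlateSet) -> Iterable[tuple[str, pd.DataFrame]]:
    """Yield (plate_id, frame) pairs in sorted plate order."""
    df = plates.to_frame()
    for pid, sub in df.groupby("plate_id", sort=True):
        yield str(pid), sub
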