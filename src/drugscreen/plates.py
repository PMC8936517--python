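"""Plate data model and delimited-table I/O for 384-well drug screens.

The canonical long-format plate table has one row per well with columns

    plate_id, well, sample_id, drug1, conc1_nM, drug2, conc2_nM,
    drug3, conc3_nM, role, signal

Concentrations are always nanomolar; files are UTF-8 CSV with a mandatory
header.  Well labels accept both ``A1`` and ``A01``; the emitted form is
zero-padded.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

ROWS = "ABCDEFGHIJKLMNOP"  # 16 rows x 24 columns = 384 wells
N_COLS = 24

ROLES = ("negative_control", "positive_control", "treated")

PLATE_TABLE_COLUMNS = [
    "plate_id", "well", "sample_id",
    "drug1", "conc1_nM", "drug2", "conc2_nM", "drug3", "conc3_nM",
    "role", "signal",
]

_WELL_RE = re.compile(r"^([A-Pa-p])0?([1-9]|1[0-9]|2[0-4])$")


class PlateError(ValueError):
    """Malformed plate data; the message names the offending plate/well."""


def parse_well_label(label: str) -> tuple[str, int]:
    """Split ``A01`` or ``A1`` into ``("A", 1)``; reject anything off-grid."""
    m = _WELL_RE.match(str(label).strip())
    if not m:
        raise PlateError(f"malformed well label {label!r}")
    return m.group(1).upper(), int(m.group(2))


def format_well_label(row: str, col: int) -> str:
    return f"{row}{col:02d}"


@dataclass(frozen=True)
class Treatment:
    """What a well received: up to three drug/concentration pairs, or a control role."""

    drugs: tuple[tuple[str, float], ...] = ()
    role: str = "treated"

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise PlateError(f"unknown well role {self.role!r}")
        if self.role == "treated" and not self.drugs:
            raise PlateError("treated well must list at least one drug")
        if self.role != "treated" and self.drugs:
            raise PlateError(f"{self.role} well must not list drugs")
        if len(self.drugs) > 3:
            raise PlateError("at most three drugs per well")
        names = [d for d, _ in self.drugs]
        if len(set(names)) != len(names):
            raise PlateError(f"duplicate drug names in treatment: {names}")
        for name, conc in self.drugs:
            if not name:
                raise PlateError("empty drug name")
            if not (conc > 0 and conc < float("inf")):
                raise PlateError(f"concentration for {name!r} must be finite and > 0, got {conc}")

    @property
    def label(self) -> str:
        """Canonical treatment label, e.g. ``bortezomib@4+dexamethasone@10``."""
        if self.role != "treated":
            return self.role
        return "+".join(f"{d}@{c:g}" for d, c in self.drugs)

    @property
    def drug_names(self) -> tuple[str, ...]:
        return tuple(d for d, _ in self.drugs)


@dataclass
class Well:
    plate_id: str
    position: tuple[str, int]  # (row letter A-P, column 1-24)
    sample_id: str
    treatment: Treatment
    raw_signal: float
    qc_flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        row, col = self.position
        if row not in ROWS or not 1 <= col <= N_COLS:
            raise PlateError(
                f"plate {self.plate_id}: position {row}{col} off the 384-well grid")
        s = float(self.raw_signal)
        if not (s >= 0 and s < float("inf")):
            raise PlateError(
                f"plate {self.plate_id} well {self.label}: raw signal must be "
                f"finite and non-negative, got {self.raw_signal}")
        self.raw_signal = s

    @property
    def label(self) -> str:
        return format_well_label(*self.position)


@dataclass
class Plate:
    plate_id: str
    sample_id: str
    wells: list[Well] = field(default_factory=list)
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[tuple[str, int]] = set()
        for w in self.wells:
            if w.position in seen:
                raise PlateError(
                    f"plate {self.plate_id}: duplicate well {w.label}")
            seen.add(w.position)

    def wells_with_role(self, role: str) -> list[Well]:
        return [w for w in self.wells if w.treatment.role == role]

    @property
    def usable_for_normalization(self) -> bool:
        """Needs at least two wells of each control role."""
        return (len(self.wells_with_role("negative_control")) >= 2
                and len(self.wells_with_role("positive_control")) >= 2)


def _parse_row(rec: dict, idx: int) -> Well:
    plate_id = str(rec["plate_id"])
    well = str(rec["well"])
    where = f"plate {plate_id} well {well} (row {idx})"
    try:
        position = parse_well_label(well)
    except PlateError as e:
        raise PlateError(f"{where}: {e}") from None
    role = str(rec["role"]).strip()
    drugs: list[tuple[str, float]] = []
    for i in (1, 2, 3):
        name = rec.get(f"drug{i}")
        conc = rec.get(f"conc{i}_nM")
        name = "" if name is None or pd.isna(name) else str(name).strip()
        has_conc = conc is not None and not pd.isna(conc) and str(conc).strip() != ""
        if name and not has_conc:
            raise PlateError(f"{where}: drug{i} {name!r} has no concentration")
        if has_conc and not name:
            raise PlateError(f"{where}: conc{i}_nM set but drug{i} empty")
        if name:
            drugs.append((name, float(conc)))
    try:
        treatment = Treatment(drugs=tuple(drugs), role=role)
        signal = float(rec["signal"])
        return Well(plate_id=plate_id, position=position,
                    sample_id=str(rec["sample_id"]), treatment=treatment,
                    raw_signal=signal)
    except (PlateError, ValueError) as e:
        raise PlateError(f"{where}: {e}") from None


def wells_to_frame(wells: Iterable[Well]) -> pd.DataFrame:
    """Flatten wells into the canonical long-format table."""
    rows = []
    for w in wells:
        rec = {
            "plate_id": w.plate_id, "well": w.label, "sample_id": w.sample_id,
            "drug1": "", "conc1_nM": "", "drug2": "", "conc2_nM": "",
            "drug3": "", "conc3_nM": "",
            "role": w.treatment.role, "signal": w.raw_signal,
        }
        for i, (name, conc) in enumerate(w.treatment.drugs, start=1):
            rec[f"drug{i}"] = name
            rec[f"conc{i}_nM"] = conc
        rows.append(rec)
    return pd.DataFrame(rows, columns=PLATE_TABLE_COLUMNS)


def read_plate_table(path: str | Path) -> list[Plate]:
    """Read the canonical CSV plate table into one :class:`Plate` per plate_id."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in PLATE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise PlateError(f"{path}: missing columns {missing}")
    plates: dict[str, Plate] = {}
    for idx, rec in enumerate(df.to_dict("records")):
        well = _parse_row(rec, idx)
        plate = plates.get(well.plate_id)
        if plate is None:
            plate = Plate(plate_id=well.plate_id, sample_id=well.sample_id)
            plates[well.plate_id] = plate
        if well.position in {w.position for w in plate.wells}:
            raise PlateError(
                f"plate {well.plate_id}: duplicate well {well.label}")
        plate.wells.append(well)
    return list(plates.values())


def write_plate_table(plates: Sequence[Plate], path: str | Path) -> None:
    frames = [wells_to_frame(p.wells) for p in plates]
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=PLATE_TABLE_COLUMNS)
    write_results(out, path)


def write_results(records, path: str | Path) -> None:
    """Write any result table as CSV with >= 6 significant digits on floats.

    Accepts a DataFrame or an iterable of dataclass-like records (anything
    pandas can turn into rows).  Column order is preserved as given.
    """
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        df = pd.DataFrame([r.__dict__ if hasattr(r, "__dict__") else r
                           for r in records])
    df.to_csv(path, index=False, float_format="%.8g")


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
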