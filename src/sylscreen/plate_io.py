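"""Data model and CSV readers/writers for plate-based screen measurements.

The on-disk exchange format is long-format, comma-separated UTF-8 with a
required header. One row describes one well of a 96-well viability plate:

    plate_id,row,col,cell_line,sirna_id,gene,role,reading

Well addressing follows the 96-well convention (row letters A-H, columns
1-12) and is stored verbatim. Control wells are identified by the ``role``
column, never by their position, so any plate layout is supported.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from sylscreen.errors import FormatError, IntegrityError

ROLES = ("sample", "neg_control", "pos_control", "death_control", "empty")

#: canonical column order of the screen-well schema
WELL_COLUMNS = ("plate_id", "row", "col", "cell_line", "sirna_id", "gene", "role", "reading")

ROW_LETTERS = tuple("ABCDEFGH")


@dataclass(frozen=True)
class WellMeasurement:
    """A single screen well: identity, role and raw viability reading.

    ``sirna_id`` and ``gene`` are empty strings for control/empty wells;
    ``reading`` is a non-negative absorbance in arbitrary units.
    """

    plate_id: str
    row: str
    col: int
    cell_line: str
    sirna_id: str
    gene: str
    role: str
    reading: float

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise IntegrityError(f"unknown well role {self.role!r}")
        if self.role == "sample" and (not self.sirna_id or not self.gene):
            raise IntegrityError(
                f"sample well {self.plate_id}/{self.row}{self.col} lacks sirna_id or gene"
            )
        if self.reading < 0:
            raise IntegrityError(
                f"negative reading at {self.plate_id}/{self.row}{self.col}: {self.reading}"
            )


@dataclass
class ScreenDataset:
    """All wells of a screen plus the siRNA library index.

    ``wells`` is a long-format DataFrame with the columns of
    :data:`WELL_COLUMNS`; ``library_index`` maps each screened gene to the
    ordered list of its siRNA identifiers. Equality is order-insensitive:
    two datasets are equal when they contain the same wells.
    """

    wells: pd.DataFrame
    cell_lines: frozenset = field(default_factory=frozenset)
    library_index: Mapping[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wells = self.wells.reset_index(drop=True)
        if not self.cell_lines:
            self.cell_lines = frozenset(self.wells["cell_line"].unique())
        if not self.library_index:
            self.library_index = _build_library_index(self.wells)

    def _canonical(self) -> pd.DataFrame:
        return (
            self.wells[list(WELL_COLUMNS)]
            .sort_values(["cell_line", "plate_id", "row", "col"], kind="mergesort")
            .reset_index(drop=True)
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ScreenDataset):
            return NotImplemented
        return self._canonical().equals(other._canonical())

    @property
    def n_plates(self) -> int:
        return self.wells["plate_id"].nunique()

    @property
    def sample_wells(self) -> pd.DataFrame:
        return self.wells[self.wells["role"] == "sample"]

    def to_records(self) -> list[WellMeasurement]:
        return [WellMeasurement(**rec) for rec in self.wells[list(WELL_COLUMNS)].to_dict("records")]


def _build_library_index(wells: pd.DataFrame) -> dict[str, list[str]]:
    samples = wells[wells["role"] == "sample"]
    index: dict[str, list[str]] = {}
    for gene, grp in samples.groupby("gene", sort=True):
        index[gene] = sorted(grp["sirna_id"].unique())
    return index


def _validate_wells(wells: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in WELL_COLUMNS if c not in wells.columns]
    if missing:
        raise FormatError(f"missing required column(s): {', '.join(missing)}")
    wells = wells[list(WELL_COLUMNS)].copy()
    for col in ("plate_id", "row", "cell_line", "sirna_id", "gene", "role"):
        wells[col] = wells[col].fillna("").astype(str)
    wells["col"] = wells["col"].astype(int)
    wells["reading"] = wells["reading"].astype(float)

    bad_role = set(wells["role"]) - set(ROLES)
    if bad_role:
        raise FormatError(f"unknown role value(s): {sorted(bad_role)}")
    dup = wells.duplicated(subset=["plate_id", "row", "col"])
    if dup.any():
        first = wells.loc[dup.idxmax()]
        raise IntegrityError(
            f"duplicate well address {first.plate_id}/{first.row}{int(first.col)}"
        )
    if (wells["reading"] < 0).any():
        first = wells.loc[(wells["reading"] < 0).idxmax()]
        raise IntegrityError(
            f"negative reading at {first.plate_id}/{first.row}{int(first.col)}"
        )
    samples = wells["role"] == "sample"
    incomplete = samples & ((wells["sirna_id"] == "") | (wells["gene"] == ""))
    if incomplete.any():
        first = wells.loc[incomplete.idxmax()]
        raise IntegrityError(
            f"sample well {first.plate_id}/{first.row}{int(first.col)} lacks sirna_id or gene"
        )
    return wells


def read_screen_table(source) -> ScreenDataset:
    """Read a long-format screen-well CSV into a validated :class:`ScreenDataset`.

    ``source`` may be a path, a file object or a text stream. Unknown columns
    are ignored; row order never affects downstream results.

    Raises
    ------
    FormatError
        if a required column is absent.
    IntegrityError
        on duplicate (plate, row, col) addresses or negative readings.
    """
    wells = pd.read_csv(source, dtype={"row": str})
    return ScreenDataset(wells=_validate_wells(wells))


def dataset_from_records(records: Iterable[WellMeasurement]) -> ScreenDataset:
    """Build a dataset from in-memory :class:`WellMeasurement` records."""
    wells = pd.DataFrame([r.__dict__ for r in records], columns=list(WELL_COLUMNS))
    return ScreenDataset(wells=_validate_wells(wells))


def validate_controls(ds: ScreenDataset) -> pd.DataFrame:
    """Per-plate QC report: well count of each role, fatal flag when a plate
    has no negative-control wells (it could not be normalized).

    Always returns one row per (cell_line, plate_id); never raises.
    """
    rows = []
    for (line, plate), grp in ds.wells.groupby(["cell_line", "plate_id"], sort=True):
        counts = grp["role"].value_counts()
        entry = {"cell_line": line, "plate_id": plate}
        for role in ROLES:
            entry[f"n_{role}"] = int(counts.get(role, 0))
        entry["fatal"] = entry["n_neg_control"] == 0
        rows.append(entry)
    return pd.DataFrame(rows)


def write_table(records, sink) -> None:
    """Write any pipeline output table as CSV at full float precision.

    ``records`` may be a DataFrame, a ScreenDataset, or an iterable of
    dataclass records. Round-trips exactly: ``read(write(x)) == x`` for every
    pipeline record type (floats serialized via ``repr``).
    """
    if isinstance(records, ScreenDataset):
        frame = records.wells[list(WELL_COLUMNS)]
    elif isinstance(records, pd.DataFrame):
        frame = records
    else:
        records = list(records)
        frame = pd.DataFrame([r.__dict__ for r in records])
    if isinstance(sink, (str, Path)):
        Path(sink).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(sink, index=False)


def read_table(source) -> pd.DataFrame:
    """Read back any table written by :func:`write_table`."""
    return pd.read_csv(source)


def dataset_to_csv_string(ds: ScreenDataset) -> str:
    buf = io.StringIO()
    write_table(ds, buf)
    return buf.getvalue()
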