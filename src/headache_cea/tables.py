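"""Published results-table fixture: costs, HLYs and ICERs as printed.

The package ships the printed provider-perspective results for the three
case-study countries (Luxembourg, Russia, Spain), three headache types and
two horizons -- 18 cells in all -- as a small CSV. Cost-saving cells are
encoded as a negative ``additional_cost_provider`` together with the
sentinel ``cost_saving`` in the ICER column (the tables print
"(cost saved)" and "n/a").

The fixture is the internal-consistency oracle for the ICER arithmetic:
for every numeric-ICER cell, the printed cost divided by the printed HLYs,
rounded to the nearest euro, must equal the printed ICER.
"""
from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from .model import canonical_headache_type

__all__ = [
    "TableCell",
    "Table123Fixture",
    "FixtureError",
    "packaged_fixture_path",
    "load_table_fixture",
    "write_table_fixture",
]

#: Sentinel used in the ICER column for "(cost saved)" / "n/a" cells.
COST_SAVING_SENTINEL = "cost_saving"

_COLUMNS = (
    "country_id",
    "headache_type",
    "horizon_years",
    "n_patients",
    "additional_cost_provider",
    "hlys_gained",
    "icer_printed",
)

_EXPECTED_COUNTRIES = ("Luxembourg", "Russia", "Spain")
_EXPECTED_TYPES = ("migraine", "tth", "moh")
_EXPECTED_HORIZONS = (1, 5)


class FixtureError(ValueError):
    """Raised when the results-table fixture is missing cells or malformed."""


@dataclass(frozen=True)
class TableCell:
    """One printed cell: a (country, headache type, horizon) result row."""

    country_id: str
    headache_type: str
    horizon_years: int
    n_patients: int
    additional_cost_provider: float
    hlys_gained: float
    icer_printed: int | None  # None for "(cost saved)" cells

    @property
    def cost_saving(self) -> bool:
        return self.icer_printed is None

    def key(self) -> tuple[str, str, int]:
        return (self.country_id, self.headache_type, self.horizon_years)


@dataclass(frozen=True)
class Table123Fixture:
    """All 18 printed cells (3 countries x 3 headache types x 2 horizons)."""

    rows: tuple[TableCell, ...]

    def cell(self, country_id: str, headache_type: str, horizon_years: int) -> TableCell:
        key = (country_id, canonical_headache_type(headache_type), int(horizon_years))
        for row in self.rows:
            if row.key() == key:
                return row
        raise KeyError(f"no fixture cell {key}")


def packaged_fixture_path() -> Path:
    """Path of the CSV fixture shipped inside the package."""
    return Path(resources.files("headache_cea") / "data" / "tables123.csv")


def _parse_row(raw: dict[str, str], line_no: int) -> TableCell:
    where = f"fixture row {line_no} ({raw.get('country_id')!r}, {raw.get('headache_type')!r}, horizon {raw.get('horizon_years')!r})"
    try:
        horizon = int(raw["horizon_years"])
        cell = TableCell(
            country_id=raw["country_id"].strip(),
            headache_type=canonical_headache_type(raw["headache_type"]),
            horizon_years=horizon,
            n_patients=int(raw["n_patients"]),
            additional_cost_provider=float(raw["additional_cost_provider"]),
            hlys_gained=float(raw["hlys_gained"]),
            icer_printed=(
                None
                if raw["icer_printed"].strip() == COST_SAVING_SENTINEL
                else int(raw["icer_printed"])
            ),
        )
    except (KeyError, ValueError) as exc:
        raise FixtureError(f"malformed {where}: {exc}") from exc
    if cell.horizon_years not in _EXPECTED_HORIZONS:
        raise FixtureError(f"{where}: horizon must be 1 or 5")
    if cell.hlys_gained <= 0:
        raise FixtureError(f"{where}: hlys_gained must be > 0 in every printed cell")
    if cell.icer_printed is not None and cell.additional_cost_provider <= 0:
        raise FixtureError(
            f"{where}: a numeric ICER requires a positive additional cost"
        )
    if cell.icer_printed is None and cell.additional_cost_provider >= 0:
        raise FixtureError(
            f"{where}: a cost-saving cell requires a negative additional cost"
        )
    return cell


def load_table_fixture(path: str | Path | None = None) -> Table123Fixture:
    """Load the results-table fixture, validating every cell.

    With no ``path`` the packaged fixture is used. Missing files, malformed
    rows, invariant violations and missing cells raise :class:`FixtureError`
    naming the offending or first missing cell.
    """
    path = packaged_fixture_path() if path is None else Path(path)
    if not path.exists():
        raise FixtureError(f"fixture file not found: {path}")
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or tuple(reader.fieldnames) != _COLUMNS:
            raise FixtureError(
                f"fixture columns {reader.fieldnames} do not match {_COLUMNS}"
            )
        rows = [_parse_row(raw, i) for i, raw in enumerate(reader, start=2)]

    seen = {row.key() for row in rows}
    if len(seen) != len(rows):
        raise FixtureError("fixture contains duplicate cells")
    for country in _EXPECTED_COUNTRIES:
        for headache_type in _EXPECTED_TYPES:
            for horizon in _EXPECTED_HORIZONS:
                key = (country, headache_type, horizon)
                if key not in seen:
                    raise FixtureError(f"fixture is missing cell {key}")
    return Table123Fixture(rows=tuple(rows))


def write_table_fixture(fixture: Table123Fixture, path: str | Path) -> None:
    """Serialize a fixture back to CSV (exact round trip of the loader)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_COLUMNS)
        for row in fixture.rows:
            writer.writerow(
                [
                    row.country_id,
                    # preserve the upper-case labels used in print
                    row.headache_type if row.headache_type == "migraine" else row.headache_type.upper(),
                    row.horizon_years,
                    row.n_patients,
                    _format_number(row.additional_cost_provider),
                    _format_number(row.hlys_gained),
                    COST_SAVING_SENTINEL if row.icer_printed is None else row.icer_printed,
                ]
            )


def _format_number(value: float) -> str:
    return str(int(value)) if float(value).is_integer() else str(value)
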