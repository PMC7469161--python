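"""Canonical data model for the field study.

The sampling unit is the butterfly *nest*: a gregarious batch of larvae
from one egg clutch, collected at one of nine fortnightly sampling
occasions per site and year.  Each :class:`NestRecord` carries the counts
from which every downstream quantity is derived: larvae collected, larvae
that yielded the focal parasitoid, and parasitoid adults that emerged
from their cocoons in the laboratory.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import SchemaError, UndefinedStatisticError, ValidationError

HOSTS = ("A_urticae", "A_io", "A_levana")
#: Hosts native to the study area (the third is a recent arrival).
NATIVE_HOSTS = ("A_urticae", "A_io")
REGIONS = ("north", "south")

_MANDATORY_COLUMNS = (
    "site_id", "region", "year", "week", "host", "nest_id",
    "instar", "n_larvae", "n_parasitized",
)
_OPTIONAL_COLUMNS = ("n_emerged_adults", "x", "y", "calendar_week")


@dataclass
class NestRecord:
    """One sampled butterfly nest with its parasitism counts.

    Parameters
    ----------
    site_id : str
        Field-site identifier.
    region : str
        ``"north"`` or ``"south"``.
    year : int
        Sampling year.
    week : int
        Fortnightly sampling occasion, 1-9 within the season.
    host : str
        Host butterfly species (``A_urticae``, ``A_io`` or ``A_levana``).
    nest_id : str
        Unique nest identifier.
    instar : int
        Larval instar (1-5) at collection.
    n_larvae : int
        Larvae collected from the nest.
    n_parasitized : int
        Larvae that yielded the focal parasitoid.
    n_emerged_adults : int
        Parasitoid adults that emerged from their cocoon.
    x, y : float, optional
        Planar nest coordinates in meters.
    calendar_week : int, optional
        ISO calendar week, kept as metadata only; analyses index by
        sampling occasion.
    """

    site_id: str
    region: str
    year: int
    week: int
    host: str
    nest_id: str
    instar: int
    n_larvae: int
    n_parasitized: int
    n_emerged_adults: int = 0
    x: float | None = None
    y: float | None = None
    calendar_week: int | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.region not in REGIONS:
            raise ValidationError(f"unknown region {self.region!r}")
        if self.host not in HOSTS:
            raise ValidationError(f"unknown host {self.host!r}")
        if not 1 <= self.week <= 9:
            raise ValidationError(f"week {self.week} outside sampling occasions 1-9")
        if not 1 <= self.instar <= 5:
            raise ValidationError(f"instar {self.instar} outside 1-5")
        if self.n_larvae < 0:
            raise ValidationError("n_larvae must be non-negative")
        if not 0 <= self.n_parasitized <= self.n_larvae:
            raise ValidationError(
                f"n_parasitized ({self.n_parasitized}) must be in [0, n_larvae={self.n_larvae}]"
            )
        if not 0 <= self.n_emerged_adults <= self.n_parasitized:
            raise ValidationError(
                f"n_emerged_adults ({self.n_emerged_adults}) must be in "
                f"[0, n_parasitized={self.n_parasitized}]"
            )


def read_nest_records(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
) -> list[NestRecord]:
    """Read nest records from a CSV file.

    Parameters
    ----------
    path : path-like
        CSV file with a header row; comma-separated, UTF-8.
    schema : mapping, optional
        Column-rename map ``{file column -> canonical column}`` applied
        before validation.

    Returns
    -------
    list of NestRecord
        In file row order.

    Raises
    ------
    SchemaError
        If a mandatory column is absent (the message names it).
    ValidationError
        If a row violates a count invariant (the message carries the
        1-based data row number).
    """
    df = pd.read_csv(path)
    if schema:
        df = df.rename(columns=dict(schema))
    for col in _MANDATORY_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"missing mandatory column {col!r} in {path}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        kwargs = {col: getattr(row, col) for col in _MANDATORY_COLUMNS}
        for col in _OPTIONAL_COLUMNS:
            if col in df.columns:
                val = getattr(row, col)
                if pd.isna(val):
                    val = 0 if col == "n_emerged_adults" else None
                kwargs[col] = val
        for col in ("year", "week", "instar", "n_larvae", "n_parasitized"):
            kwargs[col] = int(kwargs[col])
        kwargs["n_emerged_adults"] = int(kwargs.get("n_emerged_adults", 0))
        if kwargs.get("calendar_week") is not None:
            kwargs["calendar_week"] = int(kwargs["calendar_week"])
        for col in ("site_id", "region", "host", "nest_id"):
            kwargs[col] = str(kwargs[col])
        try:
            records.append(NestRecord(**kwargs))
        except ValidationError as exc:
            raise ValidationError(f"row {i}: {exc}") from exc
    return records


def write_nest_records(records: Iterable[NestRecord], path: str | Path) -> None:
    """Write nest records to CSV; a later :func:`read_nest_records` round-trips."""
    df = records_to_frame(records)
    df.to_csv(path, index=False)


def records_to_frame(records: Iterable[NestRecord]) -> pd.DataFrame:
    """Tabulate records as a DataFrame, one row per nest."""
    return pd.DataFrame([dataclasses.asdict(r) for r in records])


_CELL_FIELDS = ("n_reared", "n_nests_parasitized", "n_larvae_total", "n_nests_total")


@dataclass(frozen=True)
class CellCounts:
    """Aggregated counts for one (year, region, host) cell."""

    n_reared: int = 0
    n_nests_parasitized: int = 0
    n_larvae_total: int = 0
    n_nests_total: int = 0

    def __add__(self, other: "CellCounts") -> "CellCounts":
        return CellCounts(*(getattr(self, f) + getattr(other, f) for f in _CELL_FIELDS))


class SummaryTable:
    """Parasitism counts aggregated by (year, region, host).

    Each cell holds, in order: parasitoid individuals reared, nests
    parasitized, host larvae collected, nests collected.  Marginal totals
    are exact sums over cells.
    """

    def __init__(self, cells: Mapping[tuple[int, str, str], CellCounts]):
        self._cells = dict(cells)

    def cell(self, year: int, region: str, host: str) -> CellCounts:
        return self._cells.get((year, region, host), CellCounts())

    def total(
        self,
        year: int | None = None,
        region: str | None = None,
        host: str | None = None,
    ) -> CellCounts:
        """Marginal total over all cells matching the given keys."""
        out = CellCounts()
        for (y, r, h), counts in self._cells.items():
            if (year is None or y == year) and (region is None or r == region) \
                    and (host is None or h == host):
                out = out + counts
        return out

    @property
    def years(self) -> tuple[int, ...]:
        return tuple(sorted({y for y, _, _ in self._cells}))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"year": y, "region": r, "host": h, **dataclasses.asdict(c)}
            for (y, r, h), c in sorted(self._cells.items())
        ]
        return pd.DataFrame(rows, columns=["year", "region", "host", *_CELL_FIELDS])


def summarize_counts(records: Sequence[NestRecord]) -> SummaryTable:
    """Aggregate nest records into a (year, region, host) summary table.

    Cell values are exact sums over records; permutation-invariant.
    """
    cells: dict[tuple[int, str, str], list[int]] = {}
    for rec in records:
        key = (rec.year, rec.region, rec.host)
        cell = cells.setdefault(key, [0, 0, 0, 0])
        cell[0] += rec.n_parasitized
        cell[1] += 1 if rec.n_parasitized > 0 else 0
        cell[2] += rec.n_larvae
        cell[3] += 1
    return SummaryTable({k: CellCounts(*v) for k, v in cells.items()})


def percent_change(a: float, b: float) -> float:
    """Signed percentage change from baseline ``a`` to ``b``: ``100*(b-a)/a``.

    Raises
    ------
    UndefinedStatisticError
        If the baseline ``a`` is not positive.
    """
    if a <= 0:
        raise UndefinedStatisticError("percent change undefined for non-positive baseline")
    return 100.0 * (b - a) / a


def emergence_rate(records: Sequence[NestRecord]) -> float:
    """Proportion of reared parasitoids whose adult emerged from the cocoon."""
    parasitized = sum(r.n_parasitized for r in records)
    if parasitized == 0:
        raise UndefinedStatisticError("emergence rate undefined: no parasitized larvae")
    return sum(r.n_emerged_adults for r in records) / parasitized


def read_climate(path: str | Path) -> pd.DataFrame:
    """Read a daily climate series CSV with columns date, t_mean, precip.

    Dates must be strictly increasing without duplicates.
    """
    df = pd.read_csv(path, parse_dates=["date"])
    for col in ("date", "t_mean"):
        if col not in df.columns:
            raise SchemaError(f"missing mandatory column {col!r} in {path}")
    if not df["date"].is_monotonic_increasing or df["date"].duplicated().any():
        raise ValidationError("climate dates must be strictly increasing without duplicates")
    return df
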