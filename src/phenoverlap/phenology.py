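"""Weekly phenology distributions and the parasitoid-host overlap index.

The overlap index OPH between the parasitoid and one host at a given site
and year is

    OPH = sum_k min(P_k, H_k),    k = 1..9 sampling occasions,

where P_k is the proportion of all parasitoid individuals reared at that
site-year that came from occasion k, and H_k the proportion of the host's
nests collected at occasion k.  OPH is 0 when the two phenologies are
disjoint and 1 when they coincide exactly.  Parasitoid abundance counts
reared *individuals* while host abundance counts *nests*; the mixed units
are intentional and match the index's definition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .errors import ContractError, GapError, NoWindowError
from .field_data import NestRecord

N_OCCASIONS = 9


def standardize(counts: Sequence[float]) -> np.ndarray:
    """Convert occasion counts to proportions of the season total.

    Returns a vector summing to 1, or an all-NaN vector flagging an
    undefined distribution when the total count is zero (never a silent
    zero vector).
    """
    arr = np.asarray(counts, dtype=float)
    if arr.ndim != 1:
        raise ContractError("counts must be a 1-D vector")
    if (arr < 0).any():
        raise ContractError("counts must be non-negative")
    total = arr.sum()
    if total == 0:
        return np.full(arr.shape, np.nan)
    return arr / total


def is_defined(proportions: np.ndarray) -> bool:
    """True when a standardized vector is usable (not the NaN flag)."""
    return not np.isnan(proportions).any()


def compute_oph(p: Sequence[float], h: Sequence[float]) -> float:
    """Overlap index: sum of element-wise minima of two standardized vectors.

    Both arguments must each sum to 1 (proportions from :func:`standardize`).
    The result lies in [0, 1]; it equals 1 iff ``p == h`` elementwise and 0
    iff their supports are disjoint.
    """
    p = np.asarray(p, dtype=float)
    h = np.asarray(h, dtype=float)
    if p.shape != h.shape:
        raise ContractError("p and h must have the same length")
    for name, v in (("p", p), ("h", h)):
        if np.isnan(v).any():
            raise ContractError(f"{name} is flagged undefined")
        if abs(v.sum() - 1.0) > 1e-9:
            raise ContractError(f"{name} is not standardized (sums to {v.sum():.6g})")
    return float(np.minimum(p, h).sum())


@dataclass(frozen=True)
class OverlapResult:
    """Overlap index for one (site, year, host) combination."""

    site_id: str
    year: int
    host: str
    oph: float


def phenology_counts(
    records: Sequence[NestRecord],
    n_occasions: int = N_OCCASIONS,
) -> dict[tuple[str, int], dict[str, np.ndarray]]:
    """Per site-year occasion counts: host nests per species, parasitoid individuals.

    Returns a mapping ``(site, year) -> {"parasitoid": counts, host: counts, ...}``
    where parasitoid counts are reared individuals summed over all hosts and
    host counts are numbers of nests.
    """
    out: dict[tuple[str, int], dict[str, np.ndarray]] = {}
    for rec in records:
        key = (rec.site_id, rec.year)
        tables = out.setdefault(key, {})
        host_counts = tables.setdefault(rec.host, np.zeros(n_occasions))
        host_counts[rec.week - 1] += 1
        para = tables.setdefault("parasitoid", np.zeros(n_occasions))
        para[rec.week - 1] += rec.n_parasitized
    return out


def overlap_table(
    records: Sequence[NestRecord],
    parasitoid_records: Sequence[NestRecord] | None = None,
) -> list[OverlapResult]:
    """Compute OPH for every (site, year, host) where both species were sampled.

    Host phenology counts nests of that species per occasion; parasitoid
    phenology counts reared individuals (from ``parasitoid_records`` when
    given, else from ``records`` themselves).  Combinations where either
    total is zero are absent from the output, not zero-filled.
    """
    host_tables = phenology_counts(records)
    para_tables = host_tables if parasitoid_records is None \
        else phenology_counts(parasitoid_records)
    results = []
    for (site, year), tables in sorted(host_tables.items()):
        para_counts = para_tables.get((site, year), {}).get("parasitoid")
        if para_counts is None or para_counts.sum() == 0:
            continue
        p = standardize(para_counts)
        for host, counts in sorted(tables.items()):
            if host == "parasitoid" or counts.sum() == 0:
                continue
            results.append(OverlapResult(site, year, host, compute_oph(p, standardize(counts))))
    return results


def overlap_frame(results: Sequence[OverlapResult]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results], columns=["site_id", "year", "host", "oph"])


@dataclass(frozen=True)
class OccurrenceWindow:
    """First and last sampling occasion with a focal-parasitoid rearing."""

    scope: tuple
    first_week: int
    last_week: int

    def __contains__(self, week: int) -> bool:
        return self.first_week <= week <= self.last_week


Scope = Literal["region_year", "site_year"]


def occurrence_window(
    records: Sequence[NestRecord],
    scope: Scope = "region_year",
) -> dict[tuple, OccurrenceWindow]:
    """Parasitoid occurrence windows per region-year (default) or site-year.

    A scope's window spans the first to last occasion with at least one
    focal-parasitoid rearing.  Scopes without any occurrence are absent
    from the result; asking for a single absent scope raises
    :class:`NoWindowError` via :func:`window_for`.
    """
    weeks: dict[tuple, list[int]] = {}
    for rec in records:
        if rec.n_parasitized == 0:
            continue
        key = (rec.region, rec.year) if scope == "region_year" else (rec.site_id, rec.year)
        weeks.setdefault(key, []).append(rec.week)
    return {
        key: OccurrenceWindow(key, min(ws), max(ws))
        for key, ws in sorted(weeks.items())
    }


def window_for(windows: dict[tuple, OccurrenceWindow], key: tuple) -> OccurrenceWindow:
    try:
        return windows[key]
    except KeyError:
        raise NoWindowError(f"no parasitoid occurrence in scope {key}") from None


def gdd13(
    series: pd.DataFrame,
    start: str | pd.Timestamp,
    end: str | pd.Timestamp,
    base: float = 13.0,
) -> float:
    """Cumulative growing degree-days above a base temperature.

    Sums ``max(0, t_mean - base)`` over every calendar day in
    ``[start, end]`` (daily means, simple truncation).  The series must
    cover the interval without gaps.

    Raises
    ------
    GapError
        Listing the missing dates if any day of the interval is absent.
    """
    start = pd.Timestamp(start)
    end = pd.Timestamp(end)
    sub = series[(series["date"] >= start) & (series["date"] <= end)]
    expected = pd.date_range(start, end, freq="D")
    missing = expected.difference(sub["date"])
    if len(missing):
        raise GapError(missing.date)
    return float(np.maximum(0.0, sub["t_mean"].to_numpy() - base).sum())
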