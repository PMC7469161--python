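"""Shared fixtures: printed-table reconstruction and a simulated study."""

from __future__ import annotations

import pytest

from phenoverlap.field_data import NestRecord
from phenoverlap.synthetic import SimulationConfig, simulate_field_season

#: Published per-cell counts (year, region, host) ->
#: (parasitoids reared, nests parasitized, larvae collected, nests collected).
PUBLISHED_CELLS = {
    (2017, "north", "A_urticae"): (65, 22, 374, 57),
    (2017, "north", "A_io"): (81, 30, 589, 70),
    (2017, "south", "A_urticae"): (82, 34, 612, 68),
    (2017, "south", "A_io"): (27, 10, 605, 45),
    (2017, "south", "A_levana"): (2, 1, 712, 69),
    (2018, "north", "A_urticae"): (6, 4, 598, 58),
    (2018, "north", "A_io"): (11, 3, 379, 26),
    (2018, "south", "A_urticae"): (78, 23, 669, 66),
    (2018, "south", "A_io"): (76, 19, 685, 63),
    (2018, "south", "A_levana"): (0, 0, 871, 98),
}
#: Parasitoid adults that emerged from their cocoon, study-wide.
TOTAL_EMERGED = 124


def records_from_cell(year, region, host, reared, n_par_nests, larvae, nests):
    """Expand one aggregated cell into per-nest records with exact sums.

    Larvae and reared parasitoids are spread as evenly as integer counts
    allow; only the first ``n_par_nests`` nests carry parasitized larvae.
    """
    base = larvae // nests
    extra = larvae - base * nests
    larvae_alloc = [base + 1 if i < extra else base for i in range(nests)]
    par_alloc = [0] * nests
    if n_par_nests:
        q, r = divmod(reared, n_par_nests)
        for i in range(n_par_nests):
            par_alloc[i] = q + (1 if i < r else 0)
    out = []
    for i in range(nests):
        assert par_alloc[i] <= larvae_alloc[i]
        out.append(NestRecord(
            site_id=f"{region}-site", region=region, year=year,
            week=i % 9 + 1, host=host, nest_id=f"{year}-{region}-{host}-{i}",
            instar=i % 5 + 1, n_larvae=larvae_alloc[i],
            n_parasitized=par_alloc[i],
        ))
    return out


@pytest.fixture(scope="session")
def published_records():
    """Per-nest records whose cell sums equal the published summary table."""
    records = []
    for (year, region, host), cell in PUBLISHED_CELLS.items():
        records.extend(records_from_cell(year, region, host, *cell))
    remaining = TOTAL_EMERGED
    for rec in records:
        take = min(remaining, rec.n_parasitized)
        rec.n_emerged_adults = take
        remaining -= take
    assert remaining == 0
    return records


@pytest.fixture(scope="session")
def sim_study():
    """One seeded realization of the full synthetic study."""
    return simulate_field_season(SimulationConfig(seed=42))
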