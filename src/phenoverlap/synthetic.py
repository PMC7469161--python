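"""Synthetic field, climate, landscape, and molecular data generators.

The generators emulate the structure of a two-year, two-region field
study of butterfly-nest parasitism: 19 sites (10 south, 9 north) sampled
at 9 fortnightly occasions per season, host-specific phenology curves, a
parasitoid whose attack activity spans roughly one calendar week (about
half a fortnightly occasion), attack probability peaking at larval
instars 3-4, and molecular samples with few, closely related haplotypes
and mostly monomorphic dominant markers.

All randomness flows from a single seeded :class:`numpy.random.Generator`
carried by the configuration; module functions never touch global random
state.  Ground-truth parameters are returned alongside every dataset so
parameter-recovery tests can compare refitted estimates against the
values that generated the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from .errors import ConfigError
from .field_data import NestRecord
from .landscape import DEFAULT_LEGEND, LandCoverGrid
from .popgen import AFLPMatrix, Alignment

HOST_SPECIES = ("A_urticae", "A_io", "A_levana")


@dataclass
class HostPhenology:
    """Gaussian-shaped seasonal nest-abundance curve for one host.

    ``peak`` and ``spread`` are in sampling-occasion units (1-9);
    ``intensity`` is the expected number of nests collected per site at
    the peak occasion.
    """

    peak: float
    spread: float = 1.5
    intensity: float = 4.0


def default_phenologies() -> dict[tuple[str, str, int], HostPhenology]:
    """Study-like phenology table per (species, region, year).

    The first-brood peaks sit mid-season, the univoltine host slightly
    later than the bivoltine one; the second year advances the northern
    curves toward spring (a warm-spring season), which is what erodes the
    parasitoid-host overlap there.  The recent-arrival host occurs only
    in the south at lower intensity.
    """
    table: dict[tuple[str, str, int], HostPhenology] = {}
    for year in (2017, 2018):
        advance = 1.5 if year == 2018 else 0.0
        table[("A_urticae", "south", year)] = HostPhenology(peak=4.0, spread=1.8, intensity=4.0)
        table[("A_io", "south", year)] = HostPhenology(peak=5.0, spread=1.4, intensity=3.5)
        table[("A_levana", "south", year)] = HostPhenology(peak=5.5, spread=1.8, intensity=3.0)
        table[("A_urticae", "north", year)] = HostPhenology(peak=4.5 - advance, spread=1.5, intensity=3.5)
        table[("A_io", "north", year)] = HostPhenology(peak=5.0 - advance, spread=1.3, intensity=3.0)
    return table


@dataclass
class SimulationConfig:
    """Parameters of the simulated study; defaults mirror the study design.

    Attack-model log-odds are on the per-larva logit scale: the
    probability that a larva in a nest sampled at occasion k is
    parasitized is ``activity_k * expit(eta)`` where ``activity_k`` is
    the parasitoid activity curve integrated over occasion k (normalized
    to 1 at its peak, hence exactly 0 for occasions outside the attack
    season) and ``eta`` sums the baseline with host, instar, region-year
    and optional land-cover effects.
    """

    seed: int
    n_sites_south: int = 10
    n_sites_north: int = 9
    years: tuple[int, ...] = (2017, 2018)
    n_occasions: int = 9
    phenology: Mapping[tuple[str, str, int], HostPhenology] = dc_field(
        default_factory=default_phenologies)
    #: sd (occasions) of the parasitoid activity curve; one week of a
    #: fortnightly grid is about half an occasion.
    attack_window_width: float = 0.5
    #: center of the attack activity curve per (region, year); defaults track
    #: the first-brood host peak, advanced less than the hosts in the warm year
    #: so the northern overlap drops.
    attack_peak: Mapping[tuple[str, int], float] = dc_field(default_factory=lambda: {
        ("south", 2017): 4.0, ("south", 2018): 4.0,
        ("north", 2017): 4.5, ("north", 2018): 4.0,
    })
    mean_larvae_per_nest: float = 10.0
    larvae_dispersion: float = 5.0
    baseline_attack_logodds: float = -1.2
    host_logodds: Mapping[str, float] = dc_field(default_factory=lambda: {
        "A_urticae": 0.41, "A_io": 0.0, "A_levana": -3.5})
    #: instar-at-collection effects (log-odds), peaking at instars 3-4
    instar_logodds: Mapping[int, float] = dc_field(default_factory=lambda: {
        1: -0.8, 2: -0.8, 3: 0.4, 4: 0.6, 5: -0.5})
    instar_probs: tuple[float, ...] = (0.05, 0.25, 0.30, 0.25, 0.15)
    year_logodds: float = -1.2
    region_logodds: float = 0.0
    #: south × second-year interaction (the southern rate rises while the
    #: northern falls)
    region_year_interaction: float = 1.04
    #: per-percentage-point land-cover effects at the 100 m buffer
    artificial_nest_logodds: float = -0.0467
    artificial_larva_logodds: float = 0.026
    deciduous_larva_logodds: float = 0.018
    emergence_prob: float = 0.29
    #: landscape grid
    grid_shape: tuple[int, int] = (200, 200)
    grid_cell_size: float = 10.0
    class_proportions: Mapping[int, float] = dc_field(default_factory=lambda: {
        1: 0.35, 2: 0.35, 3: 0.15, 4: 0.10, 5: 0.05})
    blob_scale: float = 8.0
    #: molecular defaults: few, closely related haplotypes; mostly
    #: monomorphic dominant markers
    haplotype_freqs: tuple[float, ...] = (0.85, 0.07, 0.04, 0.03, 0.01)
    haplotype_steps: tuple[int, ...] = (1, 1, 2, 3)
    sequence_length: int = 613
    aflp_n_loci: int = 82
    aflp_n_polymorphic: int = 15

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigError("seed is mandatory")
        if abs(sum(self.class_proportions.values()) - 1.0) > 1e-9:
            raise ConfigError("land-cover class proportions must sum to 1")
        self.rng = np.random.default_rng(self.seed)

    @property
    def sites(self) -> list[tuple[str, str]]:
        south = [(f"S{i+1:02d}", "south") for i in range(self.n_sites_south)]
        north = [(f"N{i+1:02d}", "north") for i in range(self.n_sites_north)]
        return south + north


@dataclass
class SimulatedStudy:
    """A generated dataset bundle with its ground-truth parameters."""

    records: list[NestRecord]
    climate: Mapping[int, pd.DataFrame]
    landcover: LandCoverGrid
    alignments: Mapping[str, Alignment]
    aflp: Mapping[str, AFLPMatrix]
    ground_truth: dict


def activity_curve(cfg: SimulationConfig, region: str, year: int) -> np.ndarray:
    """Parasitoid attack activity integrated over each occasion.

    A Gaussian activity curve (sd = ``attack_window_width`` occasions) is
    integrated over each unit occasion interval and normalized by the
    integral over the peak-centered interval, so values lie in [0, 1] and
    an attack season disjoint from the sampled occasions yields zeros.
    """
    mu = cfg.attack_peak[(region, year)]
    sd = cfg.attack_window_width
    k = np.arange(1, cfg.n_occasions + 1, dtype=float)
    mass = norm.cdf(k + 0.5, mu, sd) - norm.cdf(k - 0.5, mu, sd)
    peak_mass = norm.cdf(mu + 0.5, mu, sd) - norm.cdf(mu - 0.5, mu, sd)
    return mass / peak_mass


def _nest_sizes(cfg: SimulationConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    """Truncated negative-binomial larvae counts (min 1), mean ~ configured."""
    r = cfg.larvae_dispersion
    mean = cfg.mean_larvae_per_nest - 1.0
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size=n) + 1


def simulate_field_season(cfg: SimulationConfig) -> SimulatedStudy:
    """Generate a full two-year field study from the configuration.

    Nest counts per site-occasion are Poisson around the discretized
    phenology curve; per-larva parasitism follows the attack model
    described on :class:`SimulationConfig`.  Reproducible for a fixed
    seed.
    """
    rng = cfg.rng
    total_intensity = sum(p.intensity for p in cfg.phenology.values())
    if total_intensity == 0:
        raise ConfigError("degenerate phenology: zero intensity everywhere")

    grid = simulate_landcover(cfg, rng=rng)
    extent_x = grid.ncols * grid.cell_size
    extent_y = grid.nrows * grid.cell_size

    records: list[NestRecord] = []
    nest_counter = 0
    for site_id, region in cfg.sites:
        for year in cfg.years:
            act = activity_curve(cfg, region, year)
            south = region == "south"
            late = year == max(cfg.years)
            for species in HOST_SPECIES:
                phen = cfg.phenology.get((species, region, year))
                if phen is None:
                    continue
                k = np.arange(1, cfg.n_occasions + 1, dtype=float)
                weights = np.exp(-0.5 * ((k - phen.peak) / phen.spread) ** 2)
                lam = phen.intensity * weights
                n_nests = rng.poisson(lam)
                for occ, count in enumerate(n_nests, start=1):
                    sizes = _nest_sizes(cfg, count, rng)
                    instars = rng.choice(
                        np.arange(1, 6), size=count, p=cfg.instar_probs)
                    for size, instar in zip(sizes, instars):
                        eta = (
                            cfg.baseline_attack_logodds
                            + cfg.host_logodds[species]
                            + cfg.instar_logodds[int(instar)]
                            + (cfg.year_logodds if late else 0.0)
                            + (cfg.region_logodds if south else 0.0)
                            + (cfg.region_year_interaction if (south and late) else 0.0)
                        )
                        p = act[occ - 1] * expit(eta)
                        n_par = int(rng.binomial(int(size), p))
                        n_emerged = int(rng.binomial(n_par, cfg.emergence_prob))
                        nest_counter += 1
                        records.append(NestRecord(
                            site_id=site_id,
                            region=region,
                            year=year,
                            week=occ,
                            host=species,
                            nest_id=f"nest{nest_counter:05d}",
                            instar=int(instar),
                            n_larvae=int(size),
                            n_parasitized=n_par,
                            n_emerged_adults=n_emerged,
                            x=float(rng.uniform(0, extent_x)),
                            y=float(rng.uniform(0, extent_y)),
                        ))

    climate = {y: simulate_climate(y, warm=(y == max(cfg.years)), rng=rng)
               for y in cfg.years}
    alignments = {
        "parasitoid": simulate_sequences(
            cfg.haplotype_freqs, cfg.haplotype_steps, cfg.sequence_length,
            n=88, rng=rng),
    }
    aflp = {"parasitoid": simulate_aflp(_default_band_freqs(cfg, rng), n=39, rng=rng)}

    ground_truth = {
        "baseline_attack_logodds": cfg.baseline_attack_logodds,
        "host_logodds": dict(cfg.host_logodds),
        "instar_logodds": dict(cfg.instar_logodds),
        "year_logodds": cfg.year_logodds,
        "region_year_interaction": cfg.region_year_interaction,
        "attack_window_width": cfg.attack_window_width,
        "attack_peak": {f"{region}:{year}": peak
                        for (region, year), peak in cfg.attack_peak.items()},
        "emergence_prob": cfg.emergence_prob,
        "seed": cfg.seed,
    }
    return SimulatedStudy(records, climate, grid, alignments, aflp, ground_truth)


def simulate_climate(
    year: int,
    warm: bool = False,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Daily temperature/precipitation for one calendar year.

    A sinusoidal seasonal mean with day-to-day noise; ``warm`` shifts the
    whole series up by 2 °C and reduces rainfall, mimicking an
    exceptionally warm, dry season.
    """
    rng = rng or np.random.default_rng(0)
    dates = pd.date_range(f"{year}-01-01", f"{year}-12-31", freq="D")
    doy = dates.dayofyear.to_numpy(dtype=float)
    t_mean = 5.0 + 12.0 * np.sin(2 * np.pi * (doy - 105) / 365.25)
    t_mean = t_mean + (2.0 if warm else 0.0) + rng.normal(0, 2.0, len(doy))
    precip = rng.gamma(0.6, 3.0 if not warm else 1.5, len(doy))
    return pd.DataFrame({"date": dates, "t_mean": t_mean, "precip": precip})


def simulate_landcover(
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> LandCoverGrid:
    """Blob-structured categorical land-cover grid.

    A Gaussian-smoothed noise field is thresholded at the quantiles of
    the requested class proportions, so realized proportions match the
    request to within one cell while retaining spatially coherent blobs.
    """
    from scipy.ndimage import gaussian_filter

    props = dict(cfg.class_proportions)
    if abs(sum(props.values()) - 1.0) > 1e-9:
        raise ConfigError("class proportions must sum to 1")
    nrows, ncols = cfg.grid_shape
    if nrows <= 0 or ncols <= 0:
        raise ConfigError("grid dimensions must be positive")
    rng = rng or cfg.rng
    noise = rng.normal(size=(nrows, ncols))
    fld = gaussian_filter(noise, sigma=cfg.blob_scale)
    flat = fld.ravel()
    order = np.argsort(flat, kind="stable")
    codes = np.empty(flat.shape, dtype=int)
    start = 0
    items = sorted(props.items())
    for idx, (code, prop) in enumerate(items):
        stop = flat.size if idx == len(items) - 1 else start + int(round(prop * flat.size))
        codes[order[start:stop]] = code
        start = stop
    legend = {c: DEFAULT_LEGEND.get(c, f"class_{c}") for c in props}
    return LandCoverGrid(codes.reshape(nrows, ncols), cfg.grid_cell_size, (0.0, 0.0), legend)


_BASES = np.array(list("ACGT"))


def simulate_sequences(
    freqs: Sequence[float],
    steps: Sequence[int],
    length: int,
    n: int,
    rng: np.random.Generator | int | None = None,
) -> Alignment:
    """Sample an alignment from a constructed haplotype pool.

    ``freqs`` are haplotype frequencies (summing to 1); haplotype ``i+1``
    differs from the first (reference) haplotype by ``steps[i]`` fresh
    mutations, so pairwise divergences are controlled by construction.
    ``n`` sequences are drawn with replacement (multinomial counts).
    """
    if not np.isclose(sum(freqs), 1.0):
        raise ConfigError("haplotype frequencies must sum to 1")
    if len(steps) != len(freqs) - 1:
        raise ConfigError("need one step count per non-reference haplotype")
    if sum(steps) > length:
        raise ConfigError("more required polymorphic sites than sequence length")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    ref = rng.choice(_BASES, size=length)
    haplotypes = [ref.copy()]
    free_sites = list(rng.permutation(length))
    for step in steps:
        hap = ref.copy()
        for _ in range(step):
            site = free_sites.pop()
            current = hap[site]
            hap[site] = rng.choice([b for b in "ACGT" if b != current])
        haplotypes.append(hap)
    draws = rng.choice(len(freqs), size=n, p=np.asarray(freqs, dtype=float))
    ids = [f"seq{i+1:03d}" for i in range(n)]
    seqs = ["".join(haplotypes[d]) for d in draws]
    return Alignment(ids, seqs)


def _default_band_freqs(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Mostly fixed loci with a minority polymorphic, per the configured counts."""
    freqs = np.ones(cfg.aflp_n_loci)
    freqs[: cfg.aflp_n_loci // 2] = 0.0
    freqs[: cfg.aflp_n_polymorphic] = rng.uniform(0.1, 0.9, cfg.aflp_n_polymorphic)
    return freqs


def simulate_aflp(
    band_freqs: Sequence[float],
    n: int,
    rng: np.random.Generator | int | None = None,
) -> AFLPMatrix:
    """Bernoulli band presence/absence draws per individual × locus."""
    freqs = np.asarray(band_freqs, dtype=float)
    if ((freqs < 0) | (freqs > 1)).any():
        raise ConfigError("band frequencies must lie in [0, 1]")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    data = (rng.uniform(size=(n, len(freqs))) < freqs).astype(float)
    return AFLPMatrix(data)


def simulate_glm_dataset(
    n_nests: int,
    rng: np.random.Generator | int | None = None,
    level: str = "larva",
    baseline: float = -1.0,
    host_effect: float = 0.41,
    region_year_interaction: float = 1.04,
    year_effect: float = -0.6,
    region_effect: float = 0.2,
    instar_effects: Mapping[str, float] | None = None,
    artificial_effect: float = 0.0,
    deciduous_effect: float = 0.0,
    week_effect: float = 0.0,
    week_sq_effect: float = 0.0,
    noise_covariates: int = 0,
    mean_larvae: float = 10.0,
) -> pd.DataFrame:
    """Draw a nest- or larva-level binomial dataset from an explicit design.

    Covariates (host, region, year, pooled instar class, centered week,
    land-cover percentages, optional standard-normal noise columns) are
    drawn independently; the response is binomial with success
    probability ``expit(eta)`` where ``eta`` is linear in the stated
    effects.  Because the generating model is exactly the fitted model,
    refits are unbiased and the stated effects are recoverable — this is
    the workhorse of the parameter-recovery tests.  At larva level, nests
    with zero parasitized larvae are dropped (as in the study design,
    which models larvae-per-nest only for parasitized nests); with
    study-like nest sizes this truncation is negligible.

    Returns a DataFrame directly usable with
    :class:`~phenoverlap.glm.ModelFrame`.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    if instar_effects is None:
        instar_effects = {"1-2": 0.0, "3": 0.5, "4": 0.7, "5": -0.3}
    host = rng.choice(["A_urticae", "A_io"], size=n_nests)
    region = rng.choice(["north", "south"], size=n_nests)
    year = rng.choice(["2017", "2018"], size=n_nests)
    instar = rng.choice(list(instar_effects), size=n_nests)
    week_c = rng.uniform(-2.5, 2.5, size=n_nests)
    artificial = rng.uniform(0, 40, size=n_nests)
    deciduous = rng.uniform(0, 60, size=n_nests)
    eta = (
        baseline
        + host_effect * (host == "A_urticae")
        + region_effect * (region == "south")
        + year_effect * (year == "2018")
        + region_year_interaction * ((region == "south") & (year == "2018"))
        + np.array([instar_effects[i] for i in instar])
        + artificial_effect * artificial
        + deciduous_effect * deciduous
        + week_effect * week_c
        + week_sq_effect * week_c ** 2
    )
    df = pd.DataFrame({
        "host": host, "region": region, "year": year, "instar_class": instar,
        "week_c": week_c, "artificial_100": artificial, "deciduous_100": deciduous,
    })
    for j in range(noise_covariates):
        df[f"noise{j+1}"] = rng.normal(size=n_nests)
    p = expit(eta)
    if level == "nest":
        df["trials"] = 1
        df["successes"] = rng.binomial(1, p)
    else:
        trials = _nest_sizes_simple(mean_larvae, n_nests, rng)
        df["trials"] = trials
        df["successes"] = rng.binomial(trials, p)
        df = df[df["successes"] > 0].reset_index(drop=True)
    return df


def _nest_sizes_simple(mean: float, n: int, rng: np.random.Generator) -> np.ndarray:
    r = 5.0
    m = mean - 1.0
    return rng.negative_binomial(r, r / (r + m), size=n) + 1
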