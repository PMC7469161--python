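# phenoverlap

Tools for analysing parasitism of gregarious butterfly larvae by a
specialist parasitoid wasp: a phenological-overlap index, binomial-logit
parasitism models with likelihood-ratio backward elimination, land-cover
buffer metrics, and barcode/dominant-marker diversity summaries — plus a
synthetic-data generator that emulates the field design so the whole
pipeline is testable without field or sequence data.

It is aimed at ecologists working with host–parasitoid field surveys:
nest-level collection records (larvae collected, larvae yielding the
parasitoid), daily climate series, a categorical land-cover raster, and
optionally aligned CO1 barcode sequences and AFLP presence/absence
matrices.

## The core quantities

**Overlap index.** For site *j*, year *i*, and a given host,

```
OPH_ij = Σ_{k=1..9} min(P_ijk, H_ijk)
```

where `P_ijk` is the share of parasitoid individuals reared from occasion
*k* (of the site-year total) and `H_ijk` the share of the host's nests
collected at occasion *k*. OPH is 0 for disjoint phenologies and 1 for
identical ones, and is computed only where both species were sampled.

**Parasitism models.** Nest-level (is a nest parasitized?) and larva-level
(how many larvae in a parasitized nest?) responses are binomial with a
logit link. Covariates: host, region, year, pooled instar class, centered
week and overlap with quadratics, nest density, and two-way interactions.
Model selection is backward elimination on Type-II likelihood-ratio tests
at α = 0.05, respecting marginality. Land-cover covariates are summarized
by the gain in deviance-based pseudo-R².

**Diversity statistics.** Haplotype diversity `Hd = n(1 − Σ p_i²)/(n − 1)`
(Nei's unbiased estimator), nucleotide diversity π (mean pairwise
differences per analyzed site, complete deletion of gap/N sites),
segregating and parsimony-informative sites, percentage of variable
dominant markers and band-state gene diversity, and a median-joining
haplotype network.

## Worked example

Simulate a study, compute overlaps, and fit the larva-level model:

```python
import numpy as np
from phenoverlap import (SimulationConfig, simulate_field_season, overlap_table,
                         occurrence_window, build_frames, backward_eliminate,
                         summarize_counts)
from phenoverlap.glm import DEFAULT_LARVA_TERMS

study = simulate_field_season(SimulationConfig(seed=42))
t = summarize_counts(study.records).total()
print(f"reared={t.n_reared} nests_parasitized={t.n_nests_parasitized} "
      f"larvae={t.n_larvae_total}")

ov = overlap_table(study.records)
print(f"overlap rows={len(ov)} mean OPH={np.mean([o.oph for o in ov]):.3f}")

windows = occurrence_window(study.records)            # region-year scope
nest_frame, larva_frame = build_frames(study.records, ov, windows)
res = backward_eliminate(larva_frame, DEFAULT_LARVA_TERMS, alpha=0.05)
print("retained terms:", ", ".join(res.terms))
print(f"host coef = {res.fit.coef('host[A_urticae]'):+.3f}")
```

which prints:

```
reared=756 nests_parasitized=330 larvae=12212
overlap rows=96 mean OPH=0.446
retained terms: host, region, year, instar_class, week_c, week_c^2, nest_density, host:nest_density, region:year
host coef = +0.740
```

756 parasitoid individuals were reared from 330 of the simulated nests;
96 (site, year, host) combinations had both species sampled, with a mean
phenological overlap of 0.446. Backward elimination kept the host effect
(the simulation gives one host a higher per-larva attack log-odds) along
with season-shape terms; the positive `host coef` is the log-odds contrast
of the preferred host against the other, conditional on the retained
interaction. Coefficients for week and overlap are on the centered scale
recorded in `larva_frame.centers`.

The same steps run from the shell:

```
phenoverlap simulate --seed 42 --outdir sim/
phenoverlap oph --nests sim/nests.csv --out oph.csv
phenoverlap glm --level larva --nests sim/nests.csv --out fit.json
phenoverlap landcover --grid sim/landcover.asc --nests sim/nests.csv --out metrics.csv
```

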