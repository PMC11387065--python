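# dietshift

Body size modulates how strongly large mammalian herbivores switch their
diets between seasons. `dietshift` is a Python library for testing that
allometry from two data streams:

1. **herd-level dietary DNA metabarcoding tables** — read counts of plant
   taxa (trnL-P6 marker) per pooled faecal sample, with species, season and
   herd metadata;
2. **GPS telemetry** — fixes from collared animals, converted into 72 h
   pre-sampling movement windows and habitat-use summaries on 30 m
   elevation and land-cover grids.

It is written for community ecologists who want the full pipeline — count
table in, allometric hypothesis tests out — with every statistical step
testable in isolation, plus a synthetic-data generator that emulates a
five-species ungulate community (pronghorn 48 kg, bighorn sheep 75 kg,
mule deer 85 kg, elk 241 kg, bison 625 kg) for power analysis and
validation.

## The analysis

Samples are filtered (< 1000 reads dropped) and rarefied without
replacement to a common depth (1453 reads). To balance unequal sampling,
the seasonal comparison draws the minimum cell size (*n* = 4 herds per
species–season) 100 times; each replicate yields five indicators:

| indicator | definition |
|---|---|
| turnover | mean Bray–Curtis dissimilarity Σ\|x−y\|/Σ(x+y) over summer × winter sample pairs within a species |
| herd richness | mean number of plant taxa per sample |
| TNW | total niche width: incidence-based expected richness S(t) standardized to t = 8 sampling units (Chao2-family interpolation/extrapolation from the Q₁, Q₂ incidence frequencies) |
| herd d′ | mean Blüthgen d′ of a species' samples — the standardized Kullback–Leibler divergence d = Σⱼ pⱼ ln(pⱼ/qⱼ) of a herd's diet shares p from the network-wide availability q |
| species d′ | d′ of the species' mean seasonal profile among species |

Turnover is regressed on log₁₀ body mass (g); the other indicators enter
Type III ANCOVAs (`indicator ~ log mass × season`, sum-to-zero coding,
centred covariate) simplified by likelihood-ratio tests. Community-level
structure is tested with perMANOVA (sequential SS, 999 free permutations),
betadisper-style multivariate dispersion with bias adjustment, Mantel
tests of diet against habitat-use dissimilarity, and NMDS for
visualization. Movement windows are buffered by 400 m into use polygons
(area, mean elevation, habitat richness, cover proportions).

## Worked example

```bash
python examples/01_simulate_community.py
```

prints, for the default seeded community:

```
183 herd samples x 229 plant taxa
every sample holds exactly 1453 reads (rarefied depth)

species         mass kg  summer-winter BC   richness s/w
pronghorn            48             0.918    36.7/23.0
bighorn_sheep        75             0.918    39.4/25.8
mule_deer            85             0.905    40.3/27.0
elk                 241             0.868    47.5/33.8
bison               625             0.845    53.4/39.8
```

Cross-season Bray–Curtis falls with body mass (the smallest species switch
diets almost completely; bison retain more of their winter diet) while
per-sample richness rises with mass and is higher in summer.
`examples/02_seasonality_indicators.py` then recovers the allometry:

```
turnover ~ log10 mass(g): slope = -0.0744, R^2 = 0.988, p = 0.0006
```

The other examples run the perMANOVA/dispersion/NMDS battery and the
GPS-window habitat summaries. A thin CLI wraps the same functions:

```bash
dietshift simulate --seed 7 --out data/
dietshift prepare  --counts data/counts.tsv --meta data/meta.tsv --out prep/
dietshift analyze  --counts data/counts.tsv --meta data/meta.tsv \
                   --masses data/masses.tsv --seed 7 --out results/
dietshift habitat  --fixes data/fixes.tsv --dem data/elevation.asc \
                   --cover data/cover.asc --sample-times data/sample_times.tsv \
                   --out habitat/
```

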