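# nanomcr

Design and analysis toolkit for **nanoscale multicomponent-reaction (MCR)
library campaigns** run on acoustic liquid handlers.

Modern library synthesis can run many chemistries at once: sixteen
isocyanide-based MCR scaffolds, each designed for 96 products, fit on four
384-well destination plates (1536 reactions) fed by a single 384-well
source plate of classed building-block stocks, with every transfer made as
2.5 nL acoustic droplets. Because each scheme samples only a sliver of its
combinatorial space (1536 of ~16.4 million combinations is ~0.1 per mille),
the design is a *sparse matrix*: a seeded uniform draw of building-block
combinations without replacement. `nanomcr` is for chemists and
automation engineers who want to design such campaigns, generate the
instrument picklists, aggregate the resulting per-well outcome calls, and
profile the virtual library chemoinformatically.

The package provides:

* **building-block banks** — classed reagents (amidine, aldehyde, ketone,
  isocyanide, carboxylic acid, 1°/2° amine, fixed reagents) with stock
  tiers (0.5/0.25/0.16 M) and transporter solvents, plus a deterministic
  synthetic-bank generator so everything is testable without stock lists;
* **reaction schemes** — 16 slot-typed reaction-SMARTS templates
  (Groebke–Blackburn–Bienaymé, Passerini, Ugi and variants,
  Ugi–Pictet–Spengler, van Leusen, Orru, tetrazolo-lactams...), virtual
  product enumeration with skipped-combination bookkeeping, and exact
  combinatorial-space arithmetic;
* **plate design** — source layout, per-scheme sparse sampling,
  droplet-rounded transfer volumes (V = scale/concentration, rounded up to
  2.5 nL multiples), byte-stable picklist CSV export, and the bijective
  4×384 → 1536 quadrant interleave;
* **outcome statistics** — validation and aggregation of three-level MS
  calls (`none`/`medium`/`major`) into ranked per-scheme success rates,
  per-building-block performance and plate heatmaps;
* **chemoinformatic profiling** — descriptors, Lipinski/Ghose/Muegge
  filters, the CNS MPO desirability score (six piecewise-linear
  components, 0–6), NPR shape-triangle classification with a KDE
  barycenter, pairwise Kolmogorov–Smirnov comparison matrices, PCA and
  fingerprint similarity matrices.

## Worked example

```python
from nanomcr import (default_campaign_bank, builtin_registry, build_campaign,
                     export_picklist, generate_outcomes, ingest_calls,
                     scheme_success_rates)

bank = default_campaign_bank(seed=1)          # 316 variable blocks + 20 reagents
registry = builtin_registry()                 # the 16 scheme definitions
campaign = build_campaign(list(registry), bank, n_per_scheme=96, seed=1)

print(len(campaign.wells), len(campaign.destination_plates), len(campaign.transfers))
# 1536 4 5472

print(export_picklist(campaign).splitlines()[:2])
# ['Source Plate Name,Source Well,Destination Plate Name,Destination Well,Transfer Volume',
#  'Source[1],G1,Destination[1],A1,2000']

calls = generate_outcomes(campaign, seed=2)   # synthetic three-level MS calls
stats = scheme_success_rates(ingest_calls(calls, campaign))
print(stats[["scheme_id", "pct_major", "pct_medium", "pct_none", "pct_success"]]
      .head(3).to_string(index=False))
#  scheme_id  pct_major  pct_medium  pct_none  pct_success
#          3         51          31        18           82
#          8         29          44        27           73
#          9         29          39        32           68
```

The campaign occupies 1536 wells on four destination plates with 5472
acoustic transfers; the statistics table ranks the sixteen chemistries by
the fraction of wells showing any product (here scheme 3, an Ugi
four-component reaction, leads with 82% success, 51% of wells giving the
major product).

The same workflow is available from a shell:

```bash
nanomcr generate-bank --out bank/ --seed 1
nanomcr design --bank bank/ --n 96 --seed 1 --out design/
nanomcr analyze --campaign design/campaign.csv --calls calls.csv --out analysis/
nanomcr profile --library products.smi --out profile/
```

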