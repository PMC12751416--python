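# bacfilter

Quantitative microbial community analysis for granular activated carbon
(GAC) biofilters — the biologically active filters used in drinking-water
treatment. Most amplicon studies of such filters describe the community in
relative abundances only; `bacfilter` implements the absolute-abundance
workflow needed to say whether taxa actually grow or decline: ATP-based
biomass quantitation, 16S-qPCR anchoring of ASV tables, a whole-filter
cell mass balance, dominant/rare dynamics, occupancy–abundance
core-microbiome selection, and Sloan neutral-community-model (NCM)
classification of taxa as advantaged, neutral or disadvantaged by the
filter environment. A synthetic experiment generator with a full truth
bundle makes every stage testable without sequencing data.

Intended users: microbial ecologists and environmental engineers analysing
time- and depth-resolved biofilter (or similar biofilm reactor) datasets.

## The quantities at the core

**ATP → cells.** Luminescence is converted to ATP concentration through a
linear calibration and to cell equivalents with a fixed cellular ATP
content *F* = 8.9 × 10⁻¹⁷ g ATP/cell: `cells = m_ATP / F`.

**Absolute abundance.** Per sample *s* and taxon *i*,
`A[i,s] = rel[i,s] · qPCR[s]` (16S copies per g wet GAC); columns conserve
the qPCR total exactly.

**Cell mass balance.** Over a takedown interval, with influent/effluent
total cell counts TCC (cells/mL, held constant between measurements) and
flow *Q*:

    net_input = ∫ (TCC_in − TCC_eff) · Q dt
    stock     = Σ_f M_f · q_f            (bed-section wet mass × cells/g)
    Δ_cells   = (stock_end − stock_start) − net_input

Positive Δ means net growth in the bed, negative net decay; the
transformation rate is Δ divided by the interval length (cells/day).

**Core microbiome.** Taxa are ranked by a composite index (mean of
time-specific occupancy and replication consistency); the Bray–Curtis
contribution curve tracks, per ranking prefix, the fraction of mean
pairwise community similarity the prefix captures; the curve's elbow
(maximum chord distance) defines the core set.

**Neutral model.** A taxon with source abundance *p* is detected with
frequency `1 − I_d(N·m·p, N·m·(1−p))` (regularised incomplete beta);
migration *m* is fitted by bounded least squares, and each taxon is
classified against a Wilson 95% band around its predicted frequency:
above = advantaged, below = disadvantaged.

## Worked example

```python
from bacfilter.pipeline import run_pipeline

bundle = run_pipeline({"seed": 1})   # default synthetic experiment
for b in bundle["mass_balance"]["budgets"]:
    print(f"day {b['t_start']:>3.0f}-{b['t_end']:>3.0f}:  "
          f"rate {b['rate_cells_per_day']:+.3g} cells/day  ({b['phase']})")
print(bundle["ncm"]["summary"])
```

prints

```
day   0- 34:  rate -2.51e+08 cells/day  (decay)
day  34- 62:  rate +2.17e+08 cells/day  (growth)
day  62- 83:  rate -4.38e+08 cells/day  (decay)
day  83-162:  rate -1.62e+09 cells/day  (decay)
Sloan neutral community model fit
============================================
taxa (fitted/total)         300/300
samples                     24
community size N            19721
detection limit d           3.515e-05
migration m                 0.1264 (SE 0.0063)
R-squared                   0.8426
prediction band             Wilson, level 0.95
--------------------------------------------
above                       57 (19.0%)
neutral                     233 (77.7%)
below                       10 (3.3%)
```

The mass balance recovers the scripted start-up dynamics of the synthetic
filter — early net decay while the virgin bed is colonised, a growth phase
(days 34–62), then decay phases in which the standing stock still rises
but more slowly than the water phase delivers cells. The NCM fit on the
top-of-bed community estimates the migration parameter and flags taxa
whose occupancy cannot be explained by dispersal alone (the generator
plants advantaged and disadvantaged taxa; the truth bundle
`experiment.truth` records which). The same pipeline runs on real data via
`run_pipeline({"mode": "files", "inputs": {...}})` or the CLI:

```bash
bacfilter simulate --seed 1 --out sim/        # write synthetic input files
bacfilter run --seed 1 --out results/         # full pipeline + report.md
bacfilter ncm --counts sim/asv_counts.tsv --out ncm.json
```

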