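# Methods

This note documents the models, conventions and numerical choices behind
`bacfilter`, and what the synthetic-data generator does and does not
emulate. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Biomass quantitation

ATP luminescence is calibrated against standards by ordinary least squares
on the raw (not log) scale — luciferase output is linear in ATP over the
working range (~0.005–1 µM) and an intercept absorbs instrument
background. The calibration refuses to extrapolate silently: queries
mapping outside the standards' concentration range carry an explicit flag.
ATP mass is converted to cell equivalents with a fixed cellular ATP
content of 8.9 × 10⁻¹⁷ g/cell; the conversion is a pure division, hence
linear and scale-equivariant.

Absolute ASV abundances are relative abundances multiplied by the
sample's total 16S copy number from qPCR. Two deliberate conventions:

* qPCR copies are **not** divided by 16S copies per genome; outputs are
  gene copies per g wet GAC, not genomes. This mirrors common practice and
  is a documented limitation (taxa with many rRNA operons are
  over-weighted).
* input proportions are re-normalised per column before anchoring, so the
  conservation invariant (column sums equal qPCR totals) holds to float
  tolerance even for slightly off-normalised inputs.

Replicate aggregation everywhere is the arithmetic mean. The ATP–qPCR
agreement check is a Pearson correlation on raw values by default
(`log10=True` available); across a depth-stratified bed the correlation is
dominated by the ~order-of-magnitude depth gradient, so values near 0.97
indicate proxy agreement, not small per-sample noise.

## Cell mass balance

The filter is one control volume. Influent and effluent total cell counts
are step functions (left-hold between measurements) integrated against
the volumetric flow; the standing stock at a takedown is the sum over bed
sections of wet GAC mass times ATP-derived cells per gram. The balance
attributes the residual to biology:

    delta = (stock_end − stock_start) − net_input,

positive = net growth. The algebraically flipped convention
(`eq1_literal=True`, delta = net_input − stock change) is retained for
comparability but the interpretive convention is the default because it
is the one under which reported growth/decay phases carry their usual
signs. The first interval starts from zero stock (virgin GAC). Flow is
stored internally as mL/day; the loader accepts mL/min, mL/h and mL/day
because published operating tables and methods sections sometimes
disagree (e.g. 63.7 mL/h vs 1 mL/min ≈ 60 mL/h) — the parsed source
string is recorded on the `FlowSpec`.

Budgets are per consecutive takedown pair (the transformation rate's
denominator is the interval length), not cumulative from start-up;
per-interval budgets sum to the cumulative one by the additivity of the
step integral, which is property-tested.

Sensitivity: the delta is a difference of large numbers. With per-replicate
measurement CVs around 10% and triplicate averaging, per-interval rates on
the default synthetic experiment carry relative errors of tens of percent;
the *sign* (phase), which has a much larger margin, is the robust output.
This is intrinsic to the method, not an implementation artefact.

## Dominant/rare partition and dynamics

Taxa are ranked by the unweighted mean relative abundance across samples
(matching the per-sample framing of the occupancy analyses); the top 20
are "dominant", the rest "rare". The alternative ≥0.5% mean-abundance
rule is tracked as a diagnostic and a warning reports any disagreement
with the top-n rule. Ties break lexicographically by taxon id so the
partition is reproducible and invariant to sample order. Group totals are
mass-weighted bed totals (per-gram densities via `per_gram=True`);
fold/percent changes are exact ratios, rounded only in the rendered
report. Depth stratification reports the mass-weighted biomass share
above a section boundary and the top:bottom per-gram density ratio.

## Core microbiome

Per taxon we compute occupancy, time-specific occupancy (mean over time
groups of within-group occupancy) and replication consistency (fraction
of time groups with detection in *every* sample of the group); the
composite ranking index is their arithmetic mean — the two components are
the established ingredients of occupancy-abundance core selection and
equal weighting is the neutral choice absent a stated combination.
Detection is count ≥ 1 on a table the caller has typically rarefied to
minimum depth (rarefaction is applied in the pipeline's core/NCM branch
but not in the absolute-abundance branch, where it would distort qPCR
anchoring).

The contribution curve: for the top-n ranked taxa, each sample pair
contributes `2·Σ_{i≤n} min(x_i, y_i) / Σ_all (x_i + y_i)` — the shared
abundance of the prefix over the full-table denominator — averaged over
pairs and normalised by its value at the full ranking. With the full
denominator the curve is non-decreasing in n and ends at exactly 1; using
the restricted table in the denominator as well would break monotonicity
and make "elbow" ill-defined. A pair of all-zero restricted vectors is
assigned similarity 1 (shared absence is not penalised).

The elbow defaults to the maximum-perpendicular-distance-to-chord rule
(ties → smallest n; an exactly linear or flat curve returns n = 1 with a
degenerate-curve warning). A `last-gain` rule (largest n whose marginal
gain exceeds a fraction, default 2%, of the curve's range) is provided
for sensitivity analysis; the method used is recorded in the selection's
metadata. Sample ids are sorted internally before computing occupancy
statistics and pair means so the selection is exactly invariant to input
column order (including floating-point summation order).

## Neutral community model

Local relative abundance of a taxon with source abundance p follows
Beta(N·m·p, N·m·(1−p)); predicted detection frequency is the beta mass
above a detection limit d. N defaults to the mean reads per sample.

**Detection limit.** d defaults to ln2/N rather than the single-read
convention 1/N. Reads are a binomial thinning of the underlying
composition: a taxon at abundance x yields at least one read with
probability 1−(1−x)^N, which is ½ at x = ln2/N. A step-function detection
model placed at 1/N systematically under-predicts detection of taxa just
below the single-read line, and fitting then inflates the migration
estimate — on read-thinned simulations at m = 0.1, N = 1000 the bias is
about +23% with d = 1/N and about −3% with d = ln2/N. Pass `d = 1/N`
explicitly to reproduce the older convention.

**Fitting.** m is estimated by bounded least squares on (1e−6, 1] with a
deterministic multi-start (m₀ ∈ {0.01, 0.1, 0.5}) to avoid boundary
traps; no randomness is involved, so fits are exactly reproducible and
permutation-invariant. R² = 1 − SSE/SST over taxa entering the fit; taxa
with p = 0 or undefined frequency are excluded from fitting but retained
as `not_evaluated`. All observed frequencies equal is a degenerate fit
(SST = 0) and raises. The standard error on m comes from the 1-D
Gauss–Newton approximation at the optimum.

**Classification.** The 95% band is the Wilson score interval around the
predicted frequency at the realised sample count (the common published
implementation; exact binomial bounds differ negligibly at these n).
Observed frequency strictly above the upper bound → `above` (advantaged),
strictly below the lower → `below` (disadvantaged); on-bound → neutral.
By default the model uses the dataset's own mean relative abundances; an
external source-community vector can be supplied (used when asking
whether a downstream community assembled neutrally *from* a measured
source, e.g. seeding influent water).

**Statistical power.** A 95% band at ~30 samples is wide. A closed-form
binomial power calculation (in-band upper limit vs the odds-tilted
detection probability) shows that a 2× detection-odds shift can *never*
be flagged with 0.9 recall at 30 samples, whatever the taxon's occupancy,
and that a 4× shift reaches that power only for neutral detection
probabilities ≈ 0.22–0.64. Classification results on few-sample datasets
should therefore be read as detecting strong selection only. This
calculation drove the generator's selection design (below).

## Synthetic experiment generator

The generator emulates the statistical structure of a six-month,
depth-stratified lab biofilter experiment; it contains no hydraulic,
adsorption or nutrient mechanics.

* **Anchoring.** Four takedowns (days 34, 62, 83, 162) with true total
  standing stocks 5.3 × 10¹⁰, 1.2 × 10¹¹, 1.307 × 10¹¹ (interpolated) and
  1.8 × 10¹¹ cells — magnitudes a lab-scale drinking-water filter
  reaches. Influent/effluent cell counts default to a surface-water step
  profile (1.5 × 10⁶ → 1.9 × 10⁶ cells/mL at day 83; effluent
  2.925 × 10⁵) at 1 mL/min; under these defaults the noise-free balance
  gives one early-decay, one growth and two decay phases with rates of
  order +6.5 × 10⁸ to −1.7 × 10⁹ cells/day.
* **Depth profile.** Section biomass weights decay exponentially with
  section midpoint depth; the decay constant is calibrated (Brent root
  find) so the mass-weighted share above 15 cm hits the configured target
  (default 0.79). The profile is a shape stand-in, not a mechanism; a
  single exponential cannot simultaneously match an arbitrary top-share
  and an arbitrary top:bottom ratio.
* **Abundance hierarchy.** The source community has a 20-taxon abundant
  head (55% of the source; a uniform floor mixed with a lognormal spread
  so the weakest member keeps ≥ 2.5% of the head), a 10-taxon persistent
  rare shelf (4%), and a lognormal tail capped per-taxon at the shelf
  share with excess redistributed. The cap is what keeps the designed
  dominant taxa on top of the *mean relative abundance* ranking even
  after the rare fraction grows to most of the biomass — real rare
  fractions spread their mass over thousands of taxa, which a 300-taxon
  simulation must imitate by bounding individual tail shares.
* **Dynamics.** The abundant group's absolute bed total is constant
  across takedowns (the persistent-coloniser phenotype); the rare
  fraction carries the growing remainder of the anchored stock
  trajectory, so its total strictly increases. Within-sample lognormal
  noise (CV 0.10 abundant, 0.30 rare) plus measurement noise (qPCR CV
  0.10, ATP CV 0.12, TCC CV 0.05) are mean-one multiplicative. Per-taxon
  abundant stability is therefore CV ≈ 0.07 on bed totals (the group mean
  is tested against the 0.10 design bound; individual worst-case taxa can
  exceed it through noise alone).
* **Neutral occupancy and selection.** Rare-taxon presence per sample
  follows the Sloan detection process (beta draw, binomial thinning,
  detection = ≥1 read) with per-taxon detection-odds multipliers; the
  tilt is realised by flipping the exact deficit/excess fraction of
  detections, so the realised occupancy matches s·π/(1−π+s·π) while
  conditional abundances are untouched. Defaults plant 20 advantaged
  (8×) and 20 disadvantaged (0.25×) taxa inside the informative
  occupancy windows from the power calculation above; outside those
  windows selection is statistically invisible at ~30 samples and
  planting it there would only document the band's known limits.
* **Reproducibility.** All randomness flows from one seed through named
  `SeedSequence` spawns (source, selection, occupancy, counts,
  measurement, TCC, water), so outputs are bit-identical given the seed
  and sub-streams are independently stable.

The truth bundle records per-taxon roles and selection labels, per-sample
true totals and sequencing depths, the noise-free phase ledger and the
engineered high-occupancy core (abundant + persistent taxa).

What passing tests on this generator do **not** show about real data:
taxonomy-dependent effects (the generator carries no taxonomy), relic-DNA
inflation of qPCR signals, depth-dependent composition shifts beyond
total biomass, non-exponential depth profiles, backwashing or other
operational disturbances, and rare-taxon dynamics other than the smooth
growth stand-in.

## Problem sizes and runtime choices

Default experiments use 300 taxa, 4 takedowns × 5 sections × 3 replicates
(60 filter samples) at ~20 000 reads per sample; neutral-model studies use
500 taxa × 30 samples at N = 1000 with 20 replicate seeds. These sizes
give stable medians and recalls while keeping the full test suite and the
acceptance script in the seconds-to-minutes range.

## Known limitations

* Gene copies ≠ genomes ≠ active cells; both biomass proxies include
  extracellular/relic DNA and dormant cells.
* The NCM fit assumes a single community size N and a well-mixed source;
  depth-pooled fits blur genuine depth structure (the pipeline fits the
  top-of-bed subset for this reason).
* The elbow of a contribution curve is a heuristic; the chord rule is
  reproducible but, like every elbow rule, sensitive to the curve's tail
  length. The alternative `last-gain` rule is provided to check
  robustness of a core set.
* Transformation-rate magnitudes are noise-sensitive (difference of large
  numbers); phases are the robust output.
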