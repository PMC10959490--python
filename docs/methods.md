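# Methods

## Experimental design model

A design is a set of treatments (chemical × stress schedule), each evolved in
`populations_per_treatment` isolated populations carrying
`barcodes_per_population` barcoded lineages, for `days` daily 1:`dilution_factor`
transfer cycles. Stress is expressed as a fraction of the ancestral lethal
limit (20 g/l NaCl, 8 µM CuSO₄), so salt and copper share all schedule logic.
Constant schedules hold one fraction; alternating schedules switch daily
between two, starting on the first-listed (lower) level on day 1 — the naming
convention `EH0_40` lists levels in that order, and no other convention is
implied by the treatment labels. Generations per cycle are computed as
log₂(dilution factor) = 9.9658 for 1:1000, which rounds to the conventional
9.97; it is treated as global rather than per-treatment (optical-density-based
per-treatment estimates would differ only in the third digit and the analysis
nowhere depends on it).

The full layout is 7 treatments × 2 chemicals × 16 populations × 2 barcodes =
448 lineages in 224 populations. One ancestral plate layout of
`treatments × populations-per-plate × 2` strains is copied onto
`plates_per_chemical = 2` microplates per chemical: barcodes are unique within
a plate but shared between plates, so lineage identity is (plate, barcode) and
a single Day-0 template pool serves all plates.

## Synthetic-data generator

The generator emulates the measurement process the analysis assumes, not the
evolutionary dynamics that produced it: truth is specified directly as Day-0
and Day-50 endpoints (Day-0 relative fitness is 1 everywhere; barcoded
ancestors are fitness-equivalent to the reference). Per-day mutation dynamics,
clonal interference, and de novo mutation spectra are deliberately out of
scope — the downstream analysis only ever sees the two endpoints.

**True effects.** For a lineage whose history spent time fraction τ(e) at
assay environment e, the mean Day-50 effect is

* antagonistic pleiotropy: `home_gain·τ(e) − away_loss·(1 − τ(e))`
* conditional neutrality: `home_gain·τ(e)`
* complementary: `home_gain·(0.5 + mean schedule fraction)`, equal across
  environments.

The complementary surface is intentionally asymmetric: a symmetric home/away
model can only ever tilt the EH0–EH80 connecting line one way (both treatment
points mirror across the diagonal, slope −1), whereas generalist gains that
grow with stress history let one treatment dominate the other in both
environments and produce the positive cross-environment slopes seen under
that regime. Lineage deviations around the mean surface are multivariate
normal across assay environments with exchangeable correlation
`cross_env_rho` and marginal s.d. `effect_sd`; the two barcodes co-inhabiting
a population are independent by default (`within_population_rho = 0`), since
nothing in the assay couples them. Defaults `home_gain = 0.05`,
`away_loss = 0.03`, `effect_sd = 0.02` (all on the w scale, i.e. 5/3/2
percentage points) put typical fitness changes in the few-percent range that
50-day yeast evolution produces, straddling the 2.163 pp detection limit.

**Assays.** Each (pool, environment) assay starts from frequencies
f₀ (reference at 0.70, lineages equal shares of the rest) and grows
deterministically for G = 20 generations by the replicator update
`f48_i ∝ f0_i · w_i^G` (reference w = 1); both timepoints are multinomial
draws at the configured depth. Quintuplicate 0-hour and quadruplicate 48-hour
samples are separate sequencing samples. Optional per-replicate lognormal
noise on realized w (`replicate_noise_sd`, default 0) models biological
assay-to-assay variability; the default keeps the estimator-consistency tests
exact. An `exact=True` mode emits rounded expectations at a given depth for
noise-free checks. Default full-scale depth is 2,000,000 reads/sample, which
reproduces the observed ≈5,600 reads per nonreference barcode per sample;
scaled-down validation runs use 10⁴–10⁵.

**Contamination.** A binomial fraction ≈`rate` of a sample's reads is
reassigned uniformly to library barcodes neither expected in the sample nor
the reference. Because every pool contains every library barcode, injection
is a no-op in competition samples — exactly why dedicated sentinel wells
(seeded with one barcode pair) are needed to measure it. Contamination that
lands on expected barcodes in real pools is thereby not modeled; at the
sub-percent rates involved its effect on log-ratio fitness is far below
sampling noise.

**Reads.** FASTQ records are
`[fwd index (9–12 bp)][8 bp anchor][20 bp barcode][8 bp anchor][rev index (9–12 bp)]`
with constant placeholder qualities and seed-shuffled order. The anchors
stand in for the constant amplicon sequence; writer and parser share the one
layout table (`barfit.layout`). No sequencing-error model is included: the
perfect-match rule means errors only reduce depth, which the depth parameter
already controls.

All randomness descends from one integer seed through spawned numpy
generators; identical configs and seeds give byte-identical outputs.

## Counting rules

Index matching is position-fixed (per-sample index lengths are known from the
sample sheet), with no mismatch tolerance anywhere in index, anchor, or
barcode — matching the perfect-match retention rule. Reads whose index pair
matches but whose 20-mer is not in the library count as discarded, not as
contamination (the contamination metric counts library barcodes only).
`retained + discarded = total` holds for every parse. Entries with
≤ 20 reads become missing (NA), and missingness propagates: any fitness value
touching a missing count is missing, never zero. A single declared strand
orientation is used; there is no reverse-complement handling.

## Fitness estimation

G is fixed at 20 for 48-hour assays rather than recomputed per sample. Each
48-hour replicate is paired with the mean of the quintuplicate 0-hour
measures (per-replicate pairing is available as `pairing="per_replicate"`).
Δw is mean-then-subtract — replicate w values are averaged per day before
differencing — with a `per_replicate=True` variant producing one Δw per
48-hour replicate for the mixed model. Δw is reported in percentage points of
Wrightian fitness so that the detection limits apply on a single scale. If
the reference barcode is missing in a sample, every fitness value from that
sample is missing (logged). The two barcodes of a population are analyzed as
separate lineages.

## Statistics

* **Detection limits.** `min_detectable_effect` inverts the exact
  noncentral-t power function by root-finding (normal limit used above
  df ≈ 10³ where the noncentral t is numerically fragile). The configured
  limits (2.163 / 0.634 / 0.306 pp at 80% power, α = 0.05, RMSE 2.419) are
  treated as constants of the `PowerSpec` config, not derived values, because
  the replication n behind them is not part of the design description; with
  the RMSE of 2.419 pp, n = 11 gives 2.27 pp and n = 12 gives 2.15 pp.
* **Classification.** increased iff Δw ≥ limit, decreased iff Δw ≤ −limit
  (the limit is two-sided and symmetric), else unchanged; missing Δw is
  unclassified.
* **Treatment effects.** `Δw ~ treatment + 0` with a random intercept per
  line, via statsmodels MixedLM (REML); p-values use a t-approximation with
  residual-based degrees of freedom. Singular or failed fits fall back to OLS
  on line means, logged. With an intercept, terms are contrasts against the
  first treatment.
* **Slopes.** The cross-environment genetic correlation for an environment
  pair is the slope of the segment joining the two constant-treatment mean Δw
  points; inference, when wanted, is by nonparametric bootstrap over lineages
  (percentile interval), since slope uncertainty has no standard closed form
  here.
* **No-cost line.** The line joins the EH0 and EH80 mean points in the
  (Δw at 0%, Δw at 80%) plane. Its unit normal points to the benefit side
  (positive dot product with (1,1); ties broken by positive x-component).
  Costs are signed *orthogonal* distances — a vertical-distance variant is
  easy to derive from the returned line but is not used, as orthogonal
  distance treats the two environments symmetrically. Category: cost iff
  distance ≤ −limit, benefit iff ≥ +limit, else no-cost, with 2.163 pp for
  single lineages and 0.634 pp for treatment means.

## Numerical notes and limitations

* Estimator consistency is exact: on noise-free expected counts the
  Malthusian estimator returns ln(w) to machine precision; the rounded
  infinite-depth simulator mode is accurate to ~10⁻⁶ (rounding of 10⁹-read
  expectations).
* Degenerate inputs fail loudly: empty pools, non-normalized frequencies,
  coincident no-cost anchor points, equal slope x-coordinates, and invalid
  rates all raise with messages rather than returning NaN silently.
* w50 draws are floored at 0.01 to keep true fitness positive in extreme
  noise draws; at default parameters the floor is ~50 s.d. away and inert.
* Validation on synthetic data shows the estimator and classification
  machinery recover known truth (Δw RMSE ≈ 0.15 pp at depth 10⁵; slope signs
  recovered in 100/100 seeded runs per mode). This demonstrates correctness
  of the pipeline, not of the biological model: real data add batch effects,
  uneven depth, frequency-dependent selection, and sequencing error, none of
  which the generator emulates.
* Problem sizes in the test suite and acceptance script (4 populations per
  treatment, depths of 10⁴–10⁵) are scaled-down versions of the full design,
  chosen so the whole validation campaign runs in minutes on one core while
  keeping every rate and threshold at its study value.
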