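# Methods

## Model

A lineage is the set of descendants of one barcoded founder stem cell.  Its
state is an integer vector `(s, a, n)` of symmetrically dividing S-cells,
asymmetrically dividing A-cells and non-proliferating N-cells.  Six event
types act independently per cell with piecewise-constant daily rates:
`S → S S`, `S → ∅` (removal), `S → A`, `S → N`, `A → A N`, `A → N`.  The
exact single-lineage law is the master equation implemented (truncated) in
`master_equation.py`; averaging over lineages gives the linear ODE system

    ds/dt = (r_SS − r_∅ − r_SA − r_SN) s
    da/dt = r_SA s − r_AN a
    dn/dt = r_SN s + (r_AAN + r_AN) a

solved exactly per constant-rate interval as the matrix exponential of the
3×3 lower-triangular generator (`deterministic.py`).  No time stepping is
involved; a generic LSODA integration is kept only as a test oracle.

The packaged default rate schedule (`data/map_rates.yaml`) carries the
maximum-a-posteriori rates for a 40-day cerebral-organoid culture over four
protocol phases — days 0–3 (removal 0.35/d, S→N 0.15/d), 3–6 (S→SS 0.6,
S→N 0.15), 6–11 (S→SS 0.94, S→N 1.14) and 11–40 (S→SS 1.68, S→A 1.69,
A→AN 0.71, A→N 0.07).  Rate intervals are half-open `[t_start, t_end)`:
a change at day *d* applies from *d* onward.  The initial condition is
30,000 lineages of one S-cell each (the calibrated founder count, which
absorbs multiple-labelling and sequencing artefacts in the real assay).

A caveat that matters when comparing against published point values: the
packaged table prints rates rounded to two digits, which puts the day 11–40
net S rate at −0.01/day instead of the unrounded −0.022/day.  Day-40
quantities that compound this difference over 29 days (total day-40 S-cell
count, day-40 S-lineage count) are therefore systematically a little higher
than values derived from unrounded rates.  We keep the printed table as-is
rather than inventing unpublished digits.

## Stochastic simulation

`simulate_ensemble` advances all lineages in Poisson tau-leaping steps: the
number of cells undergoing event *e* in a step is
`Poisson(rate_e · count · Δt)`.  The step size solves
`1 − e^(−rΔt)(1 + rΔt) = ε` at the schedule's maximum per-cell total rate
`r`, bounding the probability of a double event per cell and step by
`ε = 1e-3` (default); an all-zero schedule uses a 0.1-day cap.  The time grid
is split at rate-interval boundaries and at recording days, so every step
lies inside one constant-rate interval.

Removal draws can (rarely) exceed the available cells; the offending draws
are thinned by a multivariate hypergeometric sample so that exactly the
available cells are consumed, preserving relative event proportions.  The
per-run count of thinned steps is reported on the ensemble.  The S-cell
extinction time `T_S` is recorded inline as the midpoint of the step in
which `s` reached zero — sub-step timing is unresolved at tau-leap
resolution — and `inf` marks survival past the horizon.

Lineages are simulated in blocks (default 50,000) with per-block substreams
spawned from `SeedSequence(seed)`, so any lineage can be reproduced in
isolation by re-simulating only its block.  Bit-exact reproduction of a
single lineage *without* its block is not supported; the tests check that
block partitioning leaves all marginals unchanged.

Validation is three-fold: marginals against the truncated master equation
(total-variation check), ensemble means against the closed-form ODE, and the
whole tau-leap pipeline against an exact event-by-event Gillespie simulator
(`simulate_exact`, intentionally slow, test-only).  Halving Δt changes
day-40 summaries by less than Monte-Carlo error.

## Sequencing readout

Each cell contributes one template molecule; every molecule is amplified
through a Galton–Watson PCR in which each copy duplicates with probability
`E` (default 0.35, the day-0 estimate) per cycle for `n_cycles = 30` cycles.
The per-lineage copy total is simulated directly by iterating
`X ← X + Binomial(X, E)` from `X = l_i`.  Reads are Poisson with mean
proportional to the post-PCR copies, normalized so the expected reads of
lineage *i* are `W·l_i/Σl_j` for library size `W`.  Because the normalized
family-size distribution converges with cycle number, results are
insensitive to `n_cycles ≳ 20`.  For `E = 1` amplification is deterministic
and reads are exactly Poisson; for `E < 1` they are over-dispersed.
Detection is `reads ≥ 1` by default (error correction and barcode filtering
are upstream concerns, out of scope).  Back-normalization divides reads by
`W / total_cells` and is unbiased by construction.

Real count tables are normalized instead by the *mode* of the log read-count
distribution (Gaussian KDE, Silverman bandwidth), anchoring the most common
lineage size at one cell.  On synthetic readouts this recovers total cell
counts to roughly 10–15%; the residual error is an upward bias of the KDE
mode on the discrete, PCR-over-dispersed read distribution.  Samples with
fewer than 30 lineages fall back to library-size normalization
(`reads · total_cells / W`).

## Power-law statistics

`pareto_mle` implements the closed-form estimator `m̂ = min l_i`,
`α̂ = n / Σ log(l_i/m̂)` (natural log) and refuses all-equal samples.  The
fast/slow threshold anchors the Zipf line `log10 L(r) = d − (1/ᾱ) log10 r`
at the smallest lineage, finds the first rank whose observed size reaches
the line, fits an unweighted log–log OLS line to the ranks above it (a
single qualifying rank gets slope zero), and intersects the two lines.
Ranks are 1-based; ties keep stable input order.

`emergent_zipf_alpha` measures the predicted index-1/2 regime on simulated
data.  The prediction is asymptotic: the final-size law
`L(ΔT) = (s₀ΔT/3 + r_SS ΔT²/4)·r_SA(1 + r_AAN/r_AN)` generates Pareto(1/2)
sizes only where its quadratic term dominates, i.e. past the crossover
`ΔT* = 4s₀/(3 r_SS)` (≈4 days at the default rates).  The measurement
therefore keeps lineages with `T_S ≥ t_ref + 2ΔT*` (≈ day 19.5) and sizes at
or below the fast/slow threshold.  Because `m̂` is an extreme statistic, the
single-ensemble estimate scatters with sd ≈ 0.04 at 10⁵ lineages; headline
numbers average over five independent ensembles.

## Rate inference

The six estimable rates (S→SS and S→N for days 6–11; S→SS, S→A, A→AN, A→N
for days 11–40) carry independent uniform priors on [0, 4] events/cell/day;
the day 0–6 rates are fixed calibration inputs.  Observations are log-scale
replicate means/SDs of total organoid sizes (deterministic prediction) and
of ranked lineage sizes on days 11 and 40 (stochastic prediction through one
simulated ensemble, optionally passed through the readout model).  The
log-likelihood is the sum of standardized Gaussian quadratic terms with
constants dropped, so a perfect fit scores 0 and each one-σ miss costs −0.5.
Replicate SDs of zero are floored at 0.05 in log space.  Ranks exceeding a
sample's lineage count are excluded rather than imputed; a rank observed in
the data but missing in the prediction is a hard reject.

Sampling is pseudo-marginal Metropolis–Hastings: a Gaussian random-walk
proposal (scale 0.1 per coordinate, tunable), a fresh noisy likelihood
estimate per proposal, and — essential for correctness — the current state's
estimate is never refreshed, which keeps the exact posterior invariant.
Many short chains are run from over-dispersed uniform starts; each chain's
final accepted state is the retained posterior draw, and full accepted-move
traces feed the Gelman–Rubin diagnostic (second halves; point estimate plus
an F-quantile upper bound), computed per rate and for the derived net S rate
`r_SS − r_SA`.  The MAP estimate is the highest-density mode of the retained
draws found by Gaussian mean-shift with per-dimension Silverman bandwidths.
Chains that fail to reach their accept quota inside a proposal budget are
flagged and kept as partial traces.

Test-scale settings (hundreds of lineages per likelihood ensemble, ~10
chains × tens of accepts, ε = 1e-2) are deliberately far below a
production-scale run (30,000 lineages, 1,000 chains × 1,000 accepts);
the tests verify prior recovery, net-S parameter recovery, pseudo-marginal
invariance to ensemble size, and diagnostics, not publication-grade
posteriors.

`sensitivity_analysis` perturbs each rate by ±2 posterior SDs (plus a
coupled S→SS/S→A shift that keeps the net S rate fixed), clips negatives to
zero with a warning, and returns deterministic size curves plus one
simulated rank-size curve per variant.

## Neutral-competition theory

With `r_SS = r_SA = λ/2` the S-count follows the critical diffusion
`ds = √(λs) dW`.  Conditioned on extinction ΔT days after the reference day,
the most probable S-trajectory is the parabola
`s_ext(t) = s₀(1 − t/ΔT)(1 + ρt/ΔT)` with `ρ = 3λΔT/(4s₀) − 1`; its integral
times the per-S A/N output `r_SA(1 + r_AAN/r_AN)` gives the closed-form
final size `L(ΔT)` above (the integral identity is verified symbolically and
numerically in the tests, and `L` is cross-checked against stratified
simulation medians — agreement within a factor 1.5 across all well-populated
strata).  The extinction-time law `exp(−2s₀/(λt))` is implemented as the
probability of extinction *by* time t: it increases to one and its
derivative matches the tail density `2s₀t⁻²/λ`, which makes it the CDF even
though source texts sometimes print it as a survival probability.  Inverting
`L` recovers per-lineage extinction days from final sizes; inverted days
below the first or past the last histogram edge are clipped into the first
bin or dropped, respectively.  `bd_extinction_prob` supplies the classical
linear birth–death extinction probability (with the `rt/(1+rt)` critical
form) used to cross-validate simulated survival counts.

## What the synthetic data does and does not emulate

The generator pipeline (simulator + readout) reproduces the study
conditions: 30,000 single-S-cell founders, the four-phase rate table, PCR
efficiency 0.35, library-size-scaled Poisson reads, mode normalization.  It
does *not* model sequencing errors, barcode collisions, UMI structure,
cell-cycle-correlated division times, spatial effects or inter-lineage
interactions.  Passing tests therefore demonstrate internal consistency of
the method under the model's assumptions, not the fidelity of those
assumptions to any particular wet-lab dataset.

## Numerical choices and limitations

* ε = 1e-3 double-event tolerance; results insensitive to halving Δt.
* Tau-leap clamping bias is O(ε) and logged per run.
* The master-equation oracle refuses lattices whose lost-plus-boundary mass
  exceeds 1e-6.
* Mean-shift convergence tolerance 1e-8 with a 500-iteration cap.
* Day-40 point values inherit the rounded-rates caveat above (~150–160
  S-containing lineages rather than the coarser "≈200" sometimes quoted).
* The deterministic solver covers only times inside the schedule; querying
  beyond it is an error, not an extrapolation.
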