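# Methods

## The model

The package implements a two-level Poisson description of lifetime cancer
incidence, the "np" model.

**Population level.** In a period with `n` cell turnovers (nucleated-cell
replications) and per-turnover transformation probability `p`, the number
of transforming events is Poisson with mean λ = n·p, so

    P(health) = e^(−n·p),    P(cancer) = 1 − e^(−n·p).

The didactic *simple aggregate model* applies this to an unconstrained
exponentially growing clone: after `x` doublings there are n = 2^x cells,
and P(cancer) = 1 − exp(−2^x·p). For any p > 0 this S-curve tends to 1 —
with p = 1e-15 per division it first reaches 50% at generation 50 —
which is the model's statement that cancer in a proliferating system is
ultimately inevitable.

**Cell level.** The per-turnover probability splits into a constant
background `p_c` and an accumulation term `p_a`. Cells collect "effective
mutations" by i.i.d. Poisson deposition, one per division generation on
average, and a cell transforms once its accumulated count reaches an
integer threshold `q`. If a bracket's cells have reached mean generation
λ_Pa, the probability that a cell's count has crossed the threshold is the
upper cumulative Poisson tail

    Q(λ_Pa) = P(X ≥ q),  X ~ Poisson(λ_Pa).

The tail is **inclusive at q**. This is a deliberate convention: with
q = 118 and mean 45 the inclusive tail is 1.175e-19 while the exclusive
tail P(X > q) is ~2.6× smaller; only the inclusive form reproduces the
reference chain Q(45) = 1.18e-19, Q(46) = 5.86e-19. The Monte-Carlo bead
simulator uses the same ≥ q rule.

For the first age bracket, p_a is Q(λ_Pa) itself — the cohort arrives at
birth already carrying its in-utero divisions. For later brackets, p_a is
the probability of *newly* crossing the threshold, conditional on not
having crossed before:

    p_a = (Q(λ_new) − Q(λ_old)) / (1 − Q(λ_old)).

At the human magnitudes (Q ~ 1e-19) the plain difference Q_new − Q_old
agrees with the conditional form to more than ten significant figures; the
difference form is selectable (`mode="difference"`) and is what the
reference arithmetic used. When the tail is large (Q > 0.5) the
implementation switches to lower-tail CDF differences, which are the small
quantities in that regime, to avoid catastrophic cancellation; the 0/0
case of a fully transformed population is defined as p_a = 0.

**Age structure.** A `Schedule` is a contiguous sequence of half-open
5-year brackets `[start, start+5)`, each carrying the mean division
generation λ_Pa reached and the annual turnover n for that bracket; both
apply uniformly to each of the bracket's five years. Generations are
non-decreasing and clamped at a configurable cap (default 55, the
Hayflick division limit) with a logged warning rather than an error, so
user schedules that overshoot are corrected transparently.

The forward chain per bracket is: tail → p_a → p = p_c + p_a → λ = n·p →
annual P(cancer) = 1 − e^(−λ) → 5-year percentage
100·(1 − (1 − annual)^5). All intermediates are kept unrounded;
`expm1`/`log1p` are used throughout so the survival identity
1 − annual = e^(−λ) holds to machine precision and log-survival is
additive across years.

## Default parameters

| parameter | default | units | origin |
|---|---|---|---|
| `n_base` | 4.2e13 | turnovers/year | 0.116 trillion nucleated-cell replications/day (red cells excluded) |
| `p_c` | 2.38e-18 | per turnover | inverted from early-life incidence (below) |
| `q` | 118 | effective mutations | grid-search calibration (below) |
| generation cap | 55 | generations | Hayflick limit |
| brackets | 19 × 5 years | ages 0–95 | packaged UK schedule |

The packaged schedule (`data/uk_schedule.csv`) carries generations 45, 46,
47, then +0.5 per bracket capped at 55; turnover 4.2e13/year through the
30–35 bracket, then a 25% decline per bracket to age 75, 35% to 85, 40%
to 90 and 50% beyond; and the observed UK 5-year incidence percentages.
The turnover values are stored as printed (3 significant figures); the
parametric profile in `synthetic.make_synthetic_schedule` regenerates them
by exact compounding and agrees within 0.4%.

## Calibration

**p_c** is deduced from early-life incidence, where accumulation is
negligible. The observed rate is read as 0.05% per *5 years*; dividing by
5 gives an annual probability of 1e-4, and inverting the survival identity
gives p_c = −ln(1 − 1e-4)/4.2e13 = 2.38e-18. The per-year reading of the
same 0.05% figure would give a p_c five times larger and is inconsistent
with the downstream table; the per-5-year reading is the one that is
self-consistent, and is the documented convention (logged in every CLI run
header).

**q** is fitted by exhaustive grid search (default 100..140): for each
candidate the forward model is run over the schedule and scored against
the observed 5-year percentages with

    R² = 1 − RSS/TSS,  RSS = Σ(obs − model)²,  TSS = Σ(model)².

TSS here is the sum of squared *theoretical* incidence — not the centred
observed sum of squares of textbook R². The nonstandard normalisation is
implemented verbatim because it is the score under which the grid selects
q = 118 on the packaged table; the formula-fidelity property test pins it
against an independent arithmetic oracle. Ties break to the smallest q
(ties are practically impossible: the deep tail changes ~2.4× per unit q).
An optional `max_age` restricts scoring to brackets ending by that age
(e.g. 35, the constant-turnover range); the default fits all brackets,
which is fully determined by the packaged inputs.

**Turnover deduction** inverts the forward map: observed 5-year incidence
→ annual probability via 1 − (1 − P₅)^(1/5) → n = −ln(1 − annual)/p_total
with p_total from the generation schedule. Brackets with zero observed
incidence are non-invertible and flagged (turnover `None`) rather than
erroring. Per-5-year percent changes are reported raw; on the UK observed
column with the calibrated parameters the 35–75 declines average ≈ −22%,
consistent with the ~25%/5yr narrative given the noise in observed rates.

**Log-log slope** regresses log10(annual cancer probability) on
log10(bracket upper-bound age) by ordinary least squares over brackets
whose upper bound lies in the requested range. Annual probability (not
the 5-year percentage) and upper-bound age are the conventions that
reproduce the classic multistage power-law slope of ≈5.8 over ages 25–75
at constant turnover; both axes choices are logged in the run header.

## Projection

Cumulative cancerization compounds yearly hazards from birth on an
integer-age grid: each year uses its bracket's annual probability, and
cumulative incidence at age t is 1 − Π(1 − annual) over the t elapsed
years, accumulated as Σ log1p(−annual) in log space (agrees with the
naive product to 1e-14 relative over 100-year horizons). The onset age is
reported as the first integer age at which the curve reaches the
threshold (default 50%); a linearly interpolated crossing is also
available since the reduced-turnover crossing falls between integer ages
(interpolated ≈ 87.1, first integer crossing 88). Extending the horizon
beyond the schedule's end persists the last bracket's parameters.

## Synthetic data and the bead simulator

`generate_observed_incidence` attaches a noisy observed column to a
parametric schedule: model percentage × exp(ε), ε ~ Normal(−cv²/2, cv)
per bracket. Multiplicative log-normal noise was chosen because incidence
is positive and spans three orders of magnitude across brackets; the
−cv²/2 shift makes the noise mean-preserving, so Monte-Carlo means
converge to the model value. cv = 0 returns the forward model exactly,
which is what the pipeline-closure tests (exact q recovery, exact
turnover round-trip) exploit. The generator emulates the *structure* of
an age-specific incidence table — 5-year brackets, monotone generation
profile, declining turnover, positive multiplicative noise — but not
registry artefacts of real data (finite population counts, age-standard
isation, cohort effects, reporting changes), so passing recovery tests
demonstrate internal consistency of the estimators, not robustness to
registry data quirks.

`scaled_config(q)` builds a ground truth at any threshold in the
*identifiable* regime. The tail Q(q, mean) swings by orders of magnitude
with q, so simply changing q under the human profile saturates the
incidence (for q ≲ 60, mean 45–55 puts essentially the whole population
over threshold in the first bracket and every candidate q fits equally
badly). The scaling keeps the dimensionless ratios fixed: generations
scale by q/118 and the baseline turnover is rescaled so the first
bracket's accumulation hazard n·Q matches the human configuration, with
p_c rescaled inversely to preserve the background hazard n·p_c.

`simulate_raining_beads` realises the mutation-accumulation picture
directly: each cell gains Poisson(μ) effective mutations per generation
and transforms once its total reaches q (inclusive). Desk-scale defaults
(1e5 cells, q = 5, 10 generations, μ = 1) are used because the calibrated
human tail (~1e-19 at q = 118) is unreachable by naive Monte Carlo; the
simulator/analytic agreement is checked where the tail is estimable, at
3-binomial-SE tolerance.

## Numerical and design notes

- Poisson tail and CDF come from `scipy.stats.poisson` (regularized
  incomplete gamma underneath), stable to ~1e-22 — no hand-rolled
  summation in the production path; brute-force pmf sums appear only as
  test oracles.
- The simple-model crossing uses ≥ threshold, so a curve that lands
  exactly on the threshold (λ = ln 2 giving exactly 0.5) counts as
  crossed; this does not affect the p = 1e-15 crossing at generation 50.
- Grid search is fully deterministic; the only randomness in the package
  is the seeded `numpy.random.default_rng` in the synthetic generators.
- Schedule CSVs are read and written with pandas; numeric columns
  round-trip at full double precision (shortest-representation
  formatting).
- Problem sizes in the test suite (≤1e5 simulated cells, 20-seed noise
  studies, 41-point q grids) were chosen as the smallest sizes at which
  each statistical check is sharp.

## Limitations

- One compartment: no tissue-specific sub-models, no competing mortality
  — the projection is pure cancerization probability, so late-life
  cumulative incidence exceeds what a registry (with competing deaths)
  would record.
- `q` and the "effective mutation" are internal parameters; the package
  deliberately offers no mapping to physical driver-mutation counts.
- No uncertainty quantification on fitted q or deduced n(t); the
  calibration data provide no replication to support it.
- Children's turnover is held at the adult baseline before age 35 for
  lack of data; the early-bracket fit absorbs any error through p_c.
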