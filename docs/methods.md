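# Methods

This note documents the models, conventions and design choices behind
`cviscreen`: what is computed, under which assumptions, and what the
synthetic cohorts do and do not establish.

## The screener and its decision rule

The screener is a five-level card-matching task; level *l* shows `2l + 2`
cards of which *l* form true pairs (the two endpoints — 4 cards/1 pair and
12 cards/5 pairs — are fixed by the instrument; the intermediate counts
6/8/10 follow the arithmetic progression between them). Three variables are
recorded per run: overall time across the five levels, per-level accuracy
(a level is accurate when every matched pair is a true pair), and dwell
time (time to the first pair at each level). Each child ideally completes
both the multi-colored and single-colored versions.

Normative cutoffs are estimated per (age band × version) cell from a
reference cohort: the 85th percentile of overall time and of mean dwell
time for ages 5–8 (whose distributions are much wider), the 95th for ages
9–12 and 13–18. Percentiles use linear interpolation between closest ranks,
`h = (n−1)·p/100 + 1` — the numpy/R type-7 default — and the convention is
written into the threshold provenance, because cutoff values are always an
artifact of the supplied reference cohort and must be reproducible
bit-for-bit. The accuracy cutoff (fewer than 4 accurate rounds) is fixed
across bands. Each cell requires a configurable minimum of 20 runs.

A child is flagged when **any one** of the six thresholds (2 versions × 3
variables) is met. Time comparisons are strict (`value > cutoff`): a child
exactly at the normative percentile is not flagged. This makes the boundary
testable and errs against flagging at the estimation point itself. A child
with only one version on file is screened on that version and marked
*partial* rather than rejected. The rule is deliberately permissive — CVI
presents heterogeneously, and the screener's purpose is referral for
further assessment, not diagnosis.

`NormativeScreener` packages estimation + rule as a scikit-learn estimator
(`fit`/`predict`, `get_params`, fitted attributes `thresholds_`,
`n_children_`), so it composes with sklearn tooling; the underlying
functions (`estimate_thresholds`, `evaluate_run`, `screen_child`) remain
the library surface for non-estimator use.

## Age trend

`fit_age_trend` is ordinary least squares of overall time on age in years
(statsmodels), reporting slope, intercept, F with (1, n−2) degrees of
freedom, R², and the two-sided slope p-value. It requires at least three
distinct ages. The cohort-level trend is linear by construction in the
simulator (below); on real data the linearity is an approximation adequate
for choosing age bands, not a growth model.

## The cohort simulator

No child-level data from the screener studies is public, so the test
substrate is a generative model chosen to be the *simplest mechanism that
reproduces all three measured variables*:

* **Serial self-terminating search.** At each level a child inspects cards
  one at a time. Finding the next pair among `R` remaining cards costs
  `1 + Poisson(rate·(R−2))` inspections (`rate` default 0.5/card; the `−2`
  discounts the found pair itself), each inspection taking a lognormal time
  (σ = 0.5). Dwell time is the first pair's search time; level time is the
  sum over pairs — so dwell ≤ level time and dwell > 0 hold by
  construction.
* **Age calibration.** The expected overall time is analytically
  `E[N]·median·exp(σ²/2)` with `E[N] = 15 + 70·rate` inspections. Ages act
  as a multiplicative speed factor chosen so that the cohort-level expected
  overall time is *linear* in age with the configured slope (−3.34 s/yr
  single, −2.83 s/yr multi), anchored at the expectation implied by the
  per-card inspection median (0.85 s) at age 10 — about 48 s, which places
  the simulated age-band ranges (e.g. ≈16–170 s for 5–8-year-olds on the
  single-colored version) in line with the spreads reported for the
  instrument. Because the calibration is exact in expectation, OLS on a
  typical-only cohort recovers the configured slope up to sampling noise.
* **Between-child variation.** Each child carries a lognormal latent speed
  factor (σ = 0.35, mean 1) shared by both versions. This is both the
  realistic overdispersion (within-run averaging would otherwise shrink
  spread to a few percent) and the model of within-child correlation
  between versions — the correlation is not separately asserted, it
  emerges from the shared factor.
* **The deficit.** A latent severity in [0, 1] multiplies search times by
  `1 + severity·(multiplier − 1)` (multiplier 2.0: full-severity children
  take twice as long in expectation at matched age) and shifts the per-pair
  mismatch probability. Mismatch probability is logistic in card count and
  severity: about 1% per pair at 4 cards and 2.6% at 12 cards for typical
  children (so typical accurate-round counts concentrate at 4–5), rising to
  roughly 18–37% at full severity (`deficit_mismatch_boost` = 0.25 is the
  probability increment at the mid card count). Simulated cohorts default
  to the age composition of the 724-child normative sample.

Times are rounded to milliseconds; derived fields (overall time, mean
dwell, accurate rounds) are stored redundantly in the cohort CSV and
re-validated on every read — a mismatch is an error, not a silent fix.

**What passing tests show — and don't.** The simulator demonstrates that
the pipeline is correct and well-calibrated *under its own assumptions*:
thresholds recover nominal tail fractions, the screening rule reaches high
sensitivity for full-severity profiles, OLS recovers the configured slope.
Real children differ in ways the model omits: distraction and frustration
behaviors, non-stationary strategies, floor/ceiling effects on particular
levels, measurement artifacts of the touchscreen, and deficit profiles that
affect accuracy without slowing (or vice versa). Screening performance on
simulated cohorts is therefore a property of the generative model, not an
estimate of field performance.

## Cancellation tests

**Teddy-bear cancellation (ages 5–8).** Sheets carry 15 targets and 60
distractors distributed proportionally over five columns (3 + 12 per
column), vertical order randomized. Scoring: omissions `O`; `LO_S` = sum of
column nominal values (−1, −1, 0, +1, +1 left to right) over omitted
targets (empty sum 0); `START_S` = the same sum over the first three
*marked targets* — "the first three teddy bears crossed out" is read
literally, so wrongly marked distractors do not count toward the three.
Out of norm iff `O ≥ 1`. Responses are taken as complete as recorded (the
test ends when the child says they are finished); nothing is imputed. The
published instrument's exact pseudo-random layout is not public; generated
sheets preserve the counts and column structure only.

The response model marks each target independently with omission
probability `base + severity·gain` (defaults 0.02 / 0.25), optionally
skewed laterally: a rightward attentional bias multiplies omission
probability by `1 − bias·nominal(column)`, concentrating omissions in the
negative-valued left columns so E[LO-S] < 0. Marking order is a noisy
column-wise scan from a start column whose leftward preference flattens
with severity.

**Six-letter cancellation (ages 9+).** A 22×14 grid of uniformly random
letters with six designated targets, worked for 90 s. Net = total −
wrong cancellations; duplicate marks on one cell are rejected at the type
level rather than guessed into the "wrong" count. The decision rule follows
the instrument's wording "at the 5th percentile or less" as a *value*
comparison: out of norm iff net ≤ the reference band's 5th percentile
(closest-ranks interpolation). The midpoint-corrected rank percentile
(fraction strictly below + half the ties) is reported alongside as
`percentile_in_reference`; with a degenerate all-equal reference the value
rule still behaves correctly (equal net is out of norm), where a
midpoint-percentile rule would not. The two can disagree only under heavy
ties at the cutoff; the flag always follows the value rule.

The reference is pluggable: published per-age tables load from JSON;
otherwise a reference is built from simulated typical responses and its
provenance is explicitly labelled synthetic. The response model scans cells
in reading order at a lognormal per-cell pace (median 0.5 s at age 12,
slower when younger by 5%/year, doubled at full severity), marks targets
with probability 1 − miss and non-targets with a small severity-dependent
confusion probability, and stops at the time budget. In the
infinite-speed, error-free limit the net score equals the number of
target-letter cells.

## Agreement statistics

For a 2×2 reference-vs-index table, `po = (a+d)/n`, `pe` = sum of products
of marginal proportions, `κ = (po − pe)/(1 − pe)`. The null-hypothesis test
uses the marginal-based (Fleiss) null variance

    se0 = sqrt(pe + pe² − Σᵢ pᵢ₊ p₊ᵢ (pᵢ₊ + p₊ᵢ)) / ((1 − pe)·√n)

with `z = κ/se0` and a two-sided normal p-value, no continuity correction.
This formula was adopted after verifying it reproduces the validation
study's printed p-values (0.347, <0.001, 0.032) from the printed counts.
When both margins are degenerate (`pe = 1`), κ is defined as 1 for perfect
observed agreement and 0 otherwise, flagged `degenerate` with an undefined
SE. Interpretation bands follow Landis–Koch (≤0.20 slight, ≤0.40 fair,
≤0.60 moderate, ≤0.80 substantial, else almost perfect; negative poor).

Sensitivity `a/(a+b)` and specificity `d/(c+d)` carry Wald intervals
`p ± z·√(p(1−p)/m)` with z = 1.96. Wald — not Wilson or Clopper–Pearson —
because it is what the validation study computed: it reproduces every
printed interval to three decimals, including the upper bound 1.151 that
exceeds 1. Bounds are therefore reported *unclipped*, with a note attached
to machine-readable reports. A rate whose reference margin is empty is
returned as an explicit undefined status (None) rather than an exception,
so degenerate tables still yield the defined rate.

One inconsistency in the published record is documented rather than
reconciled: the κ and n values printed for the known-condition comparison
do not match recomputation from that comparison's own 2×2 counts — each
printed κ matches a *neighboring* age group's table (recomputed 0.339 at
n=34, 0.571 at n=36, 0.475 at n=16 for the 5–8 / 9–12 / 13–18 tables) —
while the printed sensitivities and specificities do match their tables.
This package always computes from the counts.

The 11-question parental inventory flags a total score strictly over 15
(configurable). The published follow-up table contains one child at exactly
15, which is why the study's "eight out of ten" tally is reproduced only
under a ≥ 15 reading; the strict reading is implemented and the discrepancy
is asserted in a test rather than resolved.

## Problem sizes and numerical choices

Simulation-based checks use cohorts of 400–724 children (100 replicates of
n = 700 for slope recovery, 500 per arm for the deficit/typical time ratio,
200 + 600 for screening sensitivity); these sizes put Monte-Carlo error
well inside the asserted bands while keeping the whole suite fast. All
randomness flows through `numpy.random.default_rng` seeds; identical
config + seed reproduces cohorts and pipeline outputs byte-for-byte (no
timestamps are written into any report). Stored times carry millisecond
resolution; derived-field validation uses a 1 ms tolerance.

## Known limitations

* The simulator is a single-latent-cause model; it cannot represent
  dissociations between speed and accuracy deficits, attentional lapses, or
  version-specific effects (color helping some children and distracting
  others).
* Normative cutoffs from simulated references are not transferable to real
  children; the pipeline is designed so a real cohort CSV drops in without
  code changes.
* The six-letter reference built synthetically is a stand-in for the
  published normative tables, which are not reprinted in the public record;
  its provenance says so.
* Wald intervals behave poorly at extreme proportions and small n (point
  intervals at p ∈ {0, 1}, bounds outside [0, 1]); they are kept for
  fidelity to the validation arithmetic, not recommended for new studies.
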