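# Methods

## The single-subject loop

The package models self-management of a chronic recurrent condition as a
two-stage N-of-1 cycle. During a **baseline phase** the subject logs, once
per calendar day, a binary outcome (did an episode occur?) and one or more
binary candidate triggers (was the subject exposed?). Screening ranks
candidate triggers by the strength of their association with the outcome.
The subject then picks one suspect, changes behaviour (the **intervention
phase**), and the episode rate per logged day is compared across phases.

Three data conventions carry the whole design:

* **A day is the unit of analysis.** Within-day multiplicity is out of
  model; an outcome that recurs several times a day is a day with value 1.
* **An unlogged day is not a zero.** Absence of a row means no
  information. All analyses are pairwise-complete over logged values, and
  phase comparisons divide events by *logged* days only. Nothing is
  imputed: missingness in this setting is plausibly informative and any
  imputation model would be unvalidatable from a single subject's data.
* **Dates are ISO calendar dates; gaps are allowed.** Lag-1 pairing
  requires two entries on *consecutive calendar days* — a stricter and
  safer rule than "consecutive entries", which would pair a Friday
  exposure with a Monday episode after a weekend of silence.

## Screening statistic

For outcome series `o` and factor series `f`, the 2×2 table at lag ℓ
counts complete pairs `(f_t, o_{t+ℓ})`, ℓ ∈ {0, 1}. The phi coefficient

    phi = (n11·n00 − n10·n01) / √(r1·r0·c1·c0)

equals the Pearson correlation of the expanded 0/1 vectors (property-tested
to 1e−12). phi is *undefined* when any marginal is zero — a constant
series carries no correlation information — and the result carries a
machine-readable reason (`no variation in factor`, …) instead of a number;
undefined results always sort after defined ones. Longer lags are rejected
rather than silently computed: with diary-scale data every extra lag is
another multiple-comparisons bite, and next-day action is the only delayed
mechanism the daily-binary design can meaningfully resolve.

Results are ranked by |phi| (ties: more supporting pairs, then factor
name, then lag). Each result carries a confidence tier driven by the
number of complete pairs *n*:

| tier | pairs | rationale |
|---|---|---|
| insufficient | n < 3 | below the minimum the screening runs at; phi withheld |
| low | 3–13 | sign only; SE(phi) ≳ 0.28 even at independence |
| moderate | 14–29 | |phi| ≳ 0.5 distinguishable from 0 (1/√n ≈ 0.26) |
| high | ≥ 30 | conventional threshold for a stable 2×2 correlation |

The tiers give the qualitative fact "accuracy grows with data" a testable
form; the cutpoints are package conventions, configurable via
`TierThresholds`. The default report surfaces raw correlations (mirroring
how an interactive tracker presents them, and because the subject treats
the ranking as a shortlist, not an inference); `analyze(...,
with_pvalues=True, bonferroni=True)` attaches exact-test p-values with a
Bonferroni factor equal to the number of screened (outcome, factor, lag)
triples for research use.

## Phase comparison

`compare_phases` forms the phase × episode-day table over logged days and
reports rates, their difference (intervention − baseline), and a
two-sided exact-test p. Entries outside any declared phase span default
to baseline, so a diary without phase bookkeeping is a pure baseline
diary. The span boundary is taken literally; no washout is modelled — a
documented limitation, since a trigger with carry-over will dilute the
contrast near the boundary.

## Exact tests

Both tests condition on the margins and use the probability-ordering
two-sided rule (the `fisher.test` convention): p is the total conditional
probability of tables no more probable than the observed one.

* **2×2**: hypergeometric enumeration with exact integer weights
  `C(r1,k)·C(r0,c1−k)`, so probability ties are resolved exactly. A zero
  margin admits a single table; p = 1.
* **R×C**: the Fisher–Yates multivariate hypergeometric. The lattice of
  margin-preserving tables is enumerated lazily; past a cap (default 10⁵
  tables) the p-value switches to Monte Carlo over margin-preserving
  samples (Patefield's algorithm, via `scipy.stats.random_table`, which
  serves purely as the sampler) with the add-one estimator
  `(1 + hits)/(reps + 1)` and a reported `method` flag. Float probability
  comparisons use a 1e−7 relative tie tolerance so arithmetic order cannot
  flip a tie.

Chi-square approximations, continuity corrections and mid-p variants are
deliberately out of scope: diary-scale and survey-block tables are small
enough for exact computation.

## Simulator

`simulate_diary` draws, for a scenario with horizon `n_days`:
exposures `x_f(t) ~ Bernoulli(q_f)` independent across factors and days;
outcome `o(t) ~ Bernoulli(clip(p0 + Σ_f δ_f·x_f(t − ℓ_f), 0, 1))`; and a
logging indicator `Bernoulli(adherence)` per day (an unlogged day is
absent entirely — missing rows, never NaN cells). Draw order is fixed, so
a scenario + seed reproduces the diary byte-for-byte through the CSV
writer. Effects are risk differences by default — the most transparent
scale for testing — with an odds-ratio mode (`effect_scale="odds_ratio"`)
multiplying the baseline odds per exposed factor. Validation requires
`p0 + δ_f ∈ [0,1]` per factor; simultaneous exposures may still clip,
which is reported behaviour, not an error. An optional intervention phase
forces chosen factors to zero exposure from a given day, emulating a
subject acting on a suspected trigger.

Base-rate presets mirror the recurrence-frequency categories reported by
prospective users of diary trackers: multiple/day → 0.95, daily → 0.80,
weekly → 1/7, monthly → 1/30, every few months → 1/90, less → 1/240. The
first preset deliberately collapses within-day multiplicity to a
near-saturated daily probability: a diary that reads 1 almost every day
has almost no contrast, and the harness should *surface* that detection is
nearly impossible there rather than hide it. These presets emulate the
reported recurrence of the underlying conditions, not guaranteed
diary-visible rates.

### Power harness and what it shows

`estimate_power` replays a scenario (replicate streams spawned from the
scenario seed), runs the screening, and reports the fraction of replicates
in which a `DetectionCriterion` flags the true factor at its true lag —
default: defined phi with |phi| ≥ 0.3, tier at least `moderate`, top rank.
The criterion is a package convention, not a recommendation;
`calibrate_phi_threshold` produces a threshold with a chosen type-I rate
by taking the upper-α quantile of the null |phi| distribution on an
independent run.

A property worth knowing when reading power grids: under a *fixed* |phi|
threshold, detection is signal-driven only when the true phi clears the
threshold. For weaker effects, short-horizon "detections" are noise
crossings of the threshold, and their rate *falls* as the diary grows —
measured here as 0.18 at 30 days shrinking to 0.07 at 60 days for a 0.1
risk difference against a 0.3 threshold. Power is therefore monotone
non-decreasing in horizon, adherence and effect size on grids whose
effects reach the threshold, and the acceptance grid is chosen in that
regime (risk differences 0.2–0.4 against a 0.2 threshold, horizons 30–90
days, adherence 0.5–1.0).

### What the generator does not emulate

Missingness is completely at random, whereas real users plausibly skip
logging *because* of a bad day; exposures are i.i.d. across days with no
weekly periodicity, autocorrelation, or co-occurrence between factors;
effects are constant over time; there is no measurement error in either
series. Passing simulation tests therefore demonstrate the statistical
machinery under the stated model, not robustness to these real-data
features.

## Survey fixtures

The survey module packages the summary counts of a 180-participant
feasibility pilot of a diary tracker (demographics, tracked conditions,
recurrence frequencies, technology habits, follow-up and 3-month adoption
by demographic category) and recomputes every printed percentage from the
raw counts. Rounding is half-away-from-zero, verified cell-by-cell
against the printed values (banker's rounding is rejected: it would turn
5/8 into 62 rather than the printed 63). Block denominators follow each
table's stated n, including internal inconsistencies, which are preserved
verbatim and flagged in `KNOWN_DISCREPANCIES` — one education cell prints
a percentage consistent with the overall cohort denominator rather than
the block's own n.

The follow-up association p-values are recomputed with the package's
exact R×C test. Two blocks (age, ethnicity) reproduce the printed values;
two (education, race) do not under any standard exact or chi-square
variant we tried — the software and variant behind the printed values is
unstated — so those recomputations are reported alongside the printed
values as a soft comparison, never gated on.

## Numerical and interface conventions

* Diary CSV is bit-exact under write→read (property-tested over generated
  diaries with gaps, missing cells and phases); phase spans and roles
  serialize as `#`-directives so that reconstruction needs no inference.
* All CLI randomness flows from `--seed`; reruns are byte-identical.
  Logs go to stderr, data to stdout or `-o`. Exit codes: 0 success, 1
  domain error, 2 usage error.
* Problem sizes in the test suite and acceptance script (500 Monte Carlo
  replicates for rate estimates, 300 per power-grid cell, 90-day horizons,
  10⁵ Monte Carlo draws for large exact tests) were chosen so Monte Carlo
  standard errors are small relative to the tolerances asserted (2–3 MC
  SE), which they satisfy with margin.
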