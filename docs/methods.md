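# Methods

## Counting model

The unit of analysis is the distinct (report, term) pair. A deduplicated
report mentioning a PT twice contributes one pair; `n` is the total number
of pairs in the database at the chosen level (PT or SOC). This matches the
"adverse events" totals of spontaneous-report studies, which exceed their
report totals several-fold. Report-level counting (`unit="REPORT"`, where
`n` is the number of reports) is available; the choice is recorded in
`run_metadata.json` because published tables rarely state it. SOC-level
tables are recounted from reports — a report with two PTs of one SOC
contributes a single (report, SOC) pair — and SOC-level `d` derives from
the SOC-level `n`, keeping each level internally consistent rather than
forcing the two levels to share margins.

Deduplication keeps, per `caseid`, the row with the highest `caseversion`,
breaking ties by latest receipt date and then largest `primaryid`; caseids
on an FDA-style deleted-case list are dropped entirely. Source data rarely
document their exact rule beyond "deduplication", so ours is fixed,
documented, and idempotent by construction. Only the post-2012Q4 FAERS
schema is supported; the legacy ISR-keyed layout is out of scope.

Drug matching is case-insensitive substring search over both the verbatim
drug name and the active-ingredient field after whitespace folding, with a
configurable synonym list (default: TERIPARATIDE, FORTEO, FORSTEO,
BONSITY). FAERS verbatims are noisy enough that exact matching (available
via `match_mode="exact"`) loses reports to trade dress.

## Disproportionality statistics

ROR and PRR use Wald intervals on the log scale with z = 1.96. The χ²
statistic is Pearson's with the Yates continuity correction by default
(the convention of the PRR screening rule in the pharmacovigilance
literature), floored at zero when |ad − bc| ≤ n/2; the uncorrected form is
a flag away. When any cell is zero, ROR/PRR/χ² are computed on the
Haldane–Anscombe table (all cells + 0.5) and the adjustment is recorded;
an all-zero table yields NaN markers, which never classify as signals.

### BCPNN

The information component model places independent Beta posteriors on the
joint and the two marginal reporting probabilities, with the joint prior
scale chosen so the prior IC is centred on independence (margin priors
α₁ = β₁ = 1 over totals α = β = 2, joint γ₁₁ = 1). Two evaluation modes:

* `exact` (default): E(IC) and V(IC) from digamma/trigamma — the exact
  posterior moments under this model. These agree with a Monte-Carlo
  sampler of the three Beta posteriors to within sampling error at any
  table size.
* `approx`: the classic closed-form log-of-posterior-mean expressions. The
  approximation error is O(1/count) — about 0.03 bits at a = 10 —
  negligible for the large-count rows of published SOC tables but visible
  at small counts.

IC025 is the moment bound E(IC) − 2√V(IC) in both modes, not an exact
posterior quantile; this is the form most screening rules assume.

### MGPS

Cell counts follow a ~ Poisson(λE) with
λ ~ p·Gamma(α₁, β₁) + (1−p)·Gamma(α₂, β₂). The marginal of a is a
two-component negative-binomial mixture; the five hyperparameters are
fitted by maximising the summed log marginal over all drug–event cells of
the database (zero-observation cells of the drug × term cross-product
included — omitting them biases the prior upward). Numerics:

* optimisation on transformed parameters (log for the four positives,
  logit for p) with L-BFGS-B, bounded at ±20 to prevent overflow;
* starting point (0.2, 0.1, 2, 4, 1/3) plus four jittered restarts
  (Gaussian σ = 0.7 on the transformed scale, seeded); best log-likelihood
  wins, `converged` reflects optimiser status;
* identical (a, E) cells are grouped with multiplicity weights — an exact
  rewriting of the likelihood that makes grid-like inputs cheap. A
  count-stratified approximate "squashing" is *not* applied;
* a likelihood conditioned on a ≥ 1 is available (`truncated=True`) for
  databases where zero cells are unobservable;
* components are relabelled so component 1 has the smaller prior mean,
  making p identifiable for recovery tests;
* an input with every a = 0 raises an error rather than fitting a
  degenerate prior.

The posterior for one cell is a two-component gamma mixture with weight Q
from the component marginals. EBGM is the posterior geometric mean
exp(E[ln λ|a]) evaluated via digamma (matching the estimator's name); the
arithmetic posterior mean is reported alongside for diagnostics. EBGM05 and
EBGM95 are found by Brent root-finding on the mixture CDF, bracketed by the
component quantiles (the bracket is widened by 10⁻⁹ relatively, because
when Q ≈ 0 or 1 the root can sit numerically on a bracket endpoint).

### Thresholds

Defaults: ROR lower 95% bound > 1 with a ≥ 3; PRR ≥ 2 with Yates χ² ≥ 4 and
a ≥ 3; IC025 > 0 (strict, so an IC025 of exactly 0 is not a signal);
EBGM05 ≥ 2. The combined flag requires all four (`combine="ALL"`); `ANY`
and `PER_ALGORITHM` are available. All cutoffs are configurable and echoed
into `run_metadata.json` so results are auditable.

## Descriptive summary

Percentages are rounded half-up to two decimals (decimal arithmetic, not
binary floats). Denominators: total reports for year, gender, age,
reporter, country, route and indications; outcome *records* for the
outcome section (a report with two outcomes contributes twice — this is
the convention under which published outcome percentages sum to 100 on a
denominator smaller than the report count); and, for time to onset, the
reports carrying any therapy-start or event date (the "Unknown" bucket
holds those whose gap is incomputable — missing counterpart, partial
precision, or negative). Age bands are half-open at 18/45/65/75; onset
bands half-open at 7/28/60 days. Time to onset is the whole-day difference
between the event date and the earliest therapy start among matching
primary-suspect entries, and requires day-precision on both dates: FAERS
dates arrive as YYYYMMDD, YYYYMM or YYYY, and partial dates are kept but
flagged imprecise. Reports with missing age fail age-restricted subgroup
predicates (they are excluded, not imputed).

## Synthetic data

The generator emulates: multi-drug multi-PT reports with one designated
primary suspect; Zipf-like background frequency simplexes over drugs and
PTs; planted (drug, PT) associations applied multiplicatively to the PT
selection probability when that drug is the primary suspect — i.e. planted
on the same relative reporting rate λ that MGPS estimates; an elderly,
predominantly female demographic (age ~ N(70, 12²) clipped to [18, 100],
90% female among non-missing); consumer-dominated reporter occupations;
therapy/event/receipt dates with a log-normal onset gap (median 40 days,
σ = 1.5); FAERS age-unit codes (YR/DEC/MON); configurable missingness for
sex (2%), age (30%) and dates (35%, with 10% of event dates degraded to
month precision); duplicate follow-up versions for 5% of cases; and an FDA
deleted-case list covering 1%. Default planted pairs sit on mid-rank PTs so
that the post-renormalisation selection probability stays close to rr ×
background; planting on the most common PTs would saturate and realize a
smaller rate than nominal. All draws come from one `numpy` generator seeded
from the config, and files are written with fixed field and row order, so
identical configs are byte-identical.

Not emulated: drug-name misspellings and free-text verbatims, reporting
trends over calendar time, correlated polypharmacy, event-dependent
reporting (notoriety effects), and country-specific coding habits. Passing
the recovery tests therefore shows the pipeline's counting and statistics
are correct under the stated generative model — not that real-FAERS
confounding, duplication-by-rewording, or masking effects are handled.

## Problem sizes

The test suite exercises a 3,000-report corpus for unit/pipeline checks, a
50,000-report corpus with four pairs planted at rr = 10 for end-to-end
recovery, a 20,000-report all-null corpus for calibration of the PRR rule
(share of E ≥ 5 cells flagged), and 10 replicates of a 20,000-cell
simulation for MGPS mixture-weight recovery (target ±0.05). The acceptance
script reruns the same designs from a caller-supplied seed. These sizes
were chosen as the smallest at which the stochastic properties under test
are stable across seeds.

## Known limitations

* Disproportionality measures association within a reporting database, not
  risk; no confounder adjustment or multiple-testing correction is applied
  (per-pair thresholds only, as is standard for these screening rules).
* The PT → SOC map is single-axis (one primary SOC per PT); MedDRA
  multi-axiality, versioning and LLT coding are out of scope, and MedDRA
  content must be supplied by the licensee.
* The BCPNN IC025 is a moment approximation, not a posterior quantile.
* MGPS hyperparameter fitting is a non-convex 5-parameter problem; the
  jittered multistart makes label-consistent convergence reliable in our
  tests but a global optimum is not guaranteed.
* Year-stratified expectations (as used by some MGPS deployments) and
  drug–drug interaction screening are not implemented.
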