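# Methods

`pvsignal` implements the standard spontaneous-report signal-detection
chain used in FAERS pharmacovigilance studies: quarterly ASCII ingest with
the FDA-recommended deduplication rule, primary-suspect cohort selection,
four disproportionality algorithms combined into a single positive-signal
rule, Weibull time-to-onset modelling, and demographic subgroup
contingency tests. A synthetic FAERS-like generator with full ground-truth
bookkeeping makes every stage testable without access to the real
database.

## Data model and deduplication

FAERS distributes each quarter as five dollar-delimited text tables
(DEMO, DRUG, REAC, OUTC, THER) linked by a primary ID. A case may be
submitted repeatedly; successive versions share a Case ID but carry new
primary IDs and FDA receipt dates. The cleaning rule keeps, per Case ID,
the version that maximises `(FDA_DT, primaryid)` lexicographically — the
latest receipt date, ties broken by the highest primary ID. The rule is
idempotent and never invents rows; on synthetic data the surviving set is
checked to equal the generator's canonical bookkeeping exactly.

Cohort selection matches drug names exactly after normalisation
(case-fold, trim, collapse internal whitespace) against a synonym list,
restricted to a role filter (default: primary suspect only). Exact
matching rather than substring matching avoids capturing combination
products. Ages are normalised to years (`YR` as-is, `DEC` ×10, `MON` ÷12,
`WK` ÷52.18, `DY` ÷365.25, `HR` ÷8766; results above 120 years are set
missing with a warning), weights to kg (1 lb = 0.45359 kg). Events are
counted as unique (report, PT) pairs — a PT repeated within one report
counts once — and at SOC level a report contributes at most once per SOC
regardless of how many of its PTs map there. The PT→SOC mapping is a
user-supplied two-column TSV because MedDRA is licensed and cannot be
bundled; unmapped PTs route to a sentinel `UNMAPPED` SOC and are logged.
A miniature 30-PT/5-SOC dictionary ships with the synthetic generator as
a stand-in for tests.

## Disproportionality statistics

For each event the 2×2 cell is

|                  | event | other events |
|------------------|-------|--------------|
| target drug      | a     | b            |
| all other drugs  | c     | d            |

with N = a+b+c+d and independence expectation E = (a+b)(a+c)/N.

**ROR** = ad/bc with the Woolf (log-normal) interval
exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d)).
**PRR** = [a/(a+b)]/[c/(c+d)] with the Pearson χ² of the 2×2, no
continuity correction by default (a switch enables Yates). The
uncorrected statistic is the one that reproduces published demographic
χ² values exactly (see below), so it is also the default here for
consistency.
**Zero cells** make ROR (any zero) and PRR (c = 0) *undefined* rather
than silently corrected; a configuration switch enables the Haldane +0.5
correction. Undefined statistics never satisfy a flag.

**BCPNN information component.** The gamma-Poisson shrinkage variant:
a | λ ~ Poisson(λE) with the Jeffreys-type prior λ ~ Gamma(½, ½) gives
the posterior λ | a ~ Gamma(a+½, E+½), and

    IC    = log2((a + ½)/(E + ½))
    IC025 = [ψ(a+½) − 1.96·√ψ′(a+½)]/ln 2 − log2(E + ½)

i.e. the 2.5th posterior percentile via a normal approximation to
log λ. This variant was chosen over the original three-Beta formulation
because it is the dominant form in the recent FAERS literature and its
normal approximation tracks the exact posterior quantile more closely
(within 0.05 of a 10⁵-draw Monte-Carlo quantile on reference cells,
which a test enforces; the three-Beta normal approximation misses that
band at moderate counts).

**MGPS / EBGM.** Empirical Bayes under a two-component gamma mixture
prior on the rate ratio λ: P(λ) = w·Γ(α₁,β₁) + (1−w)·Γ(α₂,β₂). The
marginal of each observed count is then a two-component negative-binomial
mixture; the five hyperparameters are fitted by maximising the summed
marginal log-likelihood over all cells with a quasi-Newton optimiser on
log/logit-transformed parameters from three fixed starting points (a
diffuse classic start; one concentrated at λ = 1; a bimodal null+signal
mix), making the fit deterministic. The posterior is again a two-gamma
mixture with data-dependent weight;

    EBGM   = exp(E[ln λ | a])       (posterior geometric mean)
    EBGM05 = 5th posterior percentile, root-found on the mixture CDF
             to 1e-6.

Tests verify EBGM against direct numerical integration of the posterior
and the hyperparameter fit against simulations with known mixtures.
Note that EBGM, being a geometric mean, sits slightly below the
arithmetic posterior mean (Jensen), and under a fitted mixture a cell
can be pulled toward the signal component's mean; the classic
"shrinkage never overshoots the observation" statement therefore holds
for the arithmetic posterior mean under a unit-mean prior, which is the
form the property test asserts.

**Combined rule.** An event is a positive signal only when all four
criteria hold simultaneously (each threshold configurable):

| algorithm | default criterion           |
|-----------|-----------------------------|
| ROR       | a ≥ 3 and ROR lower 95% > 1 |
| PRR       | a ≥ 3, PRR ≥ 2, χ² ≥ 4      |
| BCPNN     | IC025 > 0                   |
| MGPS      | EBGM05 > 2                  |

On synthetic null data (all rate ratios 1, 1,000 events, 50,000 reports)
fewer than 1% of events are flagged; every planted pair with RR ≥ 5 and
expected count ≥ 10 is recovered.

## Time to onset

Onset lag is the number of days from the earliest target-drug therapy
start to the report's event date; one value per report. Missing dates or
negative lags are excluded and counted; same-day onsets are kept at 0.5
days rather than dropped, because the Weibull support is positive and
dropping the earliest events would bias the shape upward. Median and
quartiles use linear interpolation of order statistics.

The Weibull shape β and scale η are maximum-likelihood estimates: β
solves the standard one-dimensional profile score equation (bracketed
Brent root, tolerance 1e-10; the sum of powers is rescaled by the sample
maximum for overflow safety) and η = (mean tᵝ)^(1/β). The default 95% CI
for β uses the observed Fisher information with the delta method on
log β; a seeded percentile bootstrap (2,000 resamples) is available.
The hazard classification is the usual trichotomy on the CI: *early
failure* if the whole CI is below 1, *wear-out* if above 1, *random*
otherwise. Simulation at n = 2,000 recovers a true shape of 0.58 with
mean error ≤ 0.02 and ≥ 90% CI coverage over 200 replicates. There is no
censoring model — spontaneous reports carry no at-risk denominator, so
only observed events enter, which is a stated limitation of this class
of analysis, not of the implementation. Day-level rounding of simulated
lags coarsens the smallest onsets, which biases the fitted shape upward
by a few hundredths at scale 30 days; the recovery test uses continuous
lags for this reason.

## Subgroup analysis

Descriptive characterisation reports per-category counts and two-decimal
percentages (sex; age bins <18 / 18–64 / 65–85 / >85, plus the FDA
antidepressant-warning binning ≤24 / 25–64 / ≥65 with 24.0 in the lower
bin; weight bins <50 / 50–100 / >100 kg; top-k countries; reporter;
outcomes; reporting year), with missingness always shown as its own row.
Association between suicide-related labelling (a report carrying at
least one PT from the suicide list) and a factor is tested on the r×2
table of non-missing categories: uncorrected Pearson χ² by default,
switching to Fisher's exact test when any expected count is below 5
(2×2: hypergeometric; r×2: a seeded Monte-Carlo resampling exact test,
20,000 resamples). Missing categories are excluded from tests but kept
in descriptive output. The uncorrected χ² reproduces the published
demographic tables of the motivating cohort to ±0.01 (48.77 for sex,
30.17 for age, 0.88 with p = 0.64 for weight), which fixes both the
no-continuity-correction default and the missing-excluded convention.

## Synthetic data generator

Each simulated report has one primary-suspect drug (plus one concomitant
row); events are drawn independently per PT with probability
(mean events per report) × (baseline PT frequency) × (planted relative
rate for the report's suspect drug), capped at 0.95, so the empirical
frequency ratio of a planted pair converges to its planted value while
unlisted pairs stay at 1. Demographics follow the missingness pattern of
real antidepressant cohorts (≈50% missing age, ≈80% missing weight,
female-skewed sex); a few percent of ages and weights are emitted in
non-default units to exercise conversion. Therapy start dates fall in the
report's quarter; event date = start + a Weibull(0.58, 30 d) lag rounded
to whole days; FDA receipt follows within 45 days. A configurable
fraction of cases is re-emitted in 2–3 versions with later (occasionally
tied) FDA dates, demographics held fixed, so only the deduplication rule
is under test. The generator emits the exact dialect the ingest code
reads (round-trip identity is a test) and a JSON ground-truth sidecar
(per-case canonical version, suspect drug, event set, onset lag).

Deliberately not emulated: reporter-country effects, dose and
indication, concomitant-drug interaction structure, masking/competition
bias, correlated events within reports, and secular reporting trends.
Passing tests therefore demonstrate correctness of the computational
chain under known ground truth, not robustness to those real-data
phenomena.

## Problem sizes and determinism

The bundled analyses and tests use 4,000–50,000 simulated reports, 30 to
1,000 event terms, 200 Weibull replicates at n = 2,000, and 10⁵-draw
Monte-Carlo oracles — sizes at which every law-of-large-numbers check has
comfortable margin while the whole suite stays fast. All randomness flows
through explicit seeds (`numpy.random.default_rng`); a pipeline re-run
with the same inputs, configuration and seed is byte-identical across all
output tables.

## Known limitations

- Disproportionality measures reporting associations, not risk;
  confounding by indication (depression itself carries suicidality) is
  inherent to the design and cannot be adjusted away here.
- The MGPS fit maximises the marginal likelihood jointly; no stratified
  (age/sex) expected counts are implemented.
- The r×2 exact test is Monte-Carlo based (seeded), not a full network
  enumeration; at 20,000 resamples its p-values are stable to ~0.005.
- The published disproportionality values of the motivating study depend
  on the full FAERS background and are not reproducible from bundled
  inputs; the package instead validates its algorithms against planted
  ground truth and independent numerical oracles.
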