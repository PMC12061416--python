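# Methods

## Data model

One row per fish (`fish.csv`): tagging and return years, trap-measured
smolt length (0.1 cm), adult length (0.1 cm) and weight (0.01 kg), sex,
and — when both parents were genetically identified — the parents'
return year. True sea-age is `return_year − smolt_year`; true
freshwater age is `smolt_year − parent_return_year − 1` (offspring
hatch the year after spawning) and is simply unknown when no parent
pair is recorded. Each of R readers contributes one age call per fish
(`reads.csv`) and one set of scale-radius measurements (`radii.csv`,
0.001 mm): total radius, the radius at the smolt mark, and the ordered
annulus radii. An abstention is an empty cell on disk and `None` in
memory — never 0 or −1, because abstentions are informative and must
stay distinguishable from numeric ages.

## Precision statistics

**PE / agreement.** `PE = 100/n · #{estimate ≠ truth}` over readable
(true, estimate) pairs; agreement is its complement. Unreadable reads
are excluded from numerator *and* denominator: the statistic describes
accuracy among produced estimates. The headline value pools
reader×fish pairs (denominator = total readable pairs); per-reader
values are always reported alongside, and pooled PE is algebraically
the read-count-weighted mean of per-reader PEs.

**Bootstrap CIs.** 95% percentile intervals from B = 1000 resamples
(configurable), resampling *fish* with replacement so that the
correlation between a fish's reads (same scale image) is preserved.
Empirical quantiles use linear interpolation (Hyndman–Fan type 7,
numpy's default); the method is fixed and recorded in the report. A
resample on which the statistic is undefined (e.g. all drawn reads
unreadable) is redrawn, with a hard cap (default 100 consecutive
failures) before erroring.

**CV / APE.** For repeated length measurements, Chang's CV is the mean
over fish of `sd_j / ref_j` (sd with the r−1 denominator), ×100; APE
replaces the sd with the mean absolute deviation. `ref_j` is the true
(trap-measured) length when available and the reader mean otherwise;
fish with fewer than two readings are excluded. Per-fish ratios are
averaged — variances are never pooled across fish.

**Classwise misclassification** reports, per age class, the number of
fish with at least one wrong readable read over all fish in the class,
as an exact fraction.

## Symmetry tests

Reader bias (systematic under- or over-ageing) is tested on the
true-vs-estimated table with three chi-square statistics of symmetry:
McNemar (all above- vs all below-diagonal mass, df 1), Bowker (one term
per symmetric cell pair with mass, df = number of such pairs), and a
distance-pooled variant that sums `(A_d − B_d)²/(A_d + B_d)` over
off-diagonal distances d with mass. When errors never exceed ±1 year
the distance-pooled variant has df 1 while Bowker's df equals the
number of adjacent age pairs involved; published analyses are not
always explicit about which convention they used, so all three are
computed side by side. No continuity correction is applied. The test
is undefined on a table with no off-diagonal mass, and readers are
pooled into one table by default with per-reader tables on request.

## Back-calculation and bias

Lea-Dahl assumes body length proportional to scale radius:
`L_t = L_c · S_t / S_c`. It is applied at the smolt mark and every
annulus; an unreadable smolt mark yields a missing back-calculated
smolt length while the fish remains in the age analyses. Bias of
back-calculated vs measured smolt length is assessed three ways on the
per-fish reader means (per-reader analyses are also emitted):

1. paired t-test of the mean difference against 0;
2. sign chi-square `(n_under − E)²/E + (n_over − E)²/E`, `E` the mean of
   the two counts, df 1 — equivalently `2(n_under − n̄)²/n̄`; exact ties
   are excluded from the counts and reported (when *all* pairs tie the
   sign statistic carries no information and is reported as NaN rather
   than failing the whole analysis);
3. OLS of back-calculated (response) on measured (predictor) with
   `t = (slope − 1)/se` on n−2 df; the slope-vs-0 statistic is reported
   too, since published slope t-values are sometimes computed against 0.
   A perfect fit (zero residual SE) reports t = 0 when the slope equals
   the null value exactly.

## Misclassification GLMs

Response per fish: 1 if at least one reader produced a readable wrong
age, 0 if all readable reads were correct — abstentions are not errors
(the models describe misclassification among produced estimates). True
ages are aggregated into two classes (sea: 1SW vs MSW; freshwater: 1–2
vs 3–5 years) because older fish are scarce. Candidate covariates: age
class, smolt year (categorical, dummy-coded against the earliest year),
smolt length, adult length (sea model only), sex. Binomial logit fits
use IRLS to relative tolerance 1e-8 within 100 iterations; perfect or
quasi-separation is flagged (`degenerate`) rather than silently
reported. All-subsets selection enumerates every admissible term
subset, respects marginality (an age-class × adult-length interaction —
available behind a flag, off by default because its definition in the
motivating analysis is ambiguous — requires both mains), excludes
failed or degenerate fits from the ranking, minimises
AIC = 2k − 2·loglik (an identity asserted on every fit), and breaks
ties within 1e-9 toward fewer coefficients. Reported p-values are
two-sided; one-sided tests can be derived by halving.

## Synthetic cohort generator

The generator emulates the river-trap study design; defaults are the
published cohort's summary statistics.

| parameter | default | note |
|---|---|---|
| n_fish | 254 | returning adults |
| smolt length | trunc. normal μ 13.73 cm, σ 1.08, bounds 11.5–17.0 | σ chosen so the untruncated 5%/95% quantiles hit 12.00/15.56 cm; the published table gives quantiles, not an sd |
| sea-age pmf | {1: 126/254, 2: 105/254, 3: 19/254, 4: 4/254} | the 23 fish of age ≥ 3 split 19/4 so the pmf mean equals the published 1.61; the split itself is not published |
| fw-age pmf | {1,4,5: 1/81 each, 2: 38/81, 3: 40/81} | only the age-2 and age-3 counts are published |
| fw truth known | Bernoulli(81/254) | parent pair identified |
| adult length by sea-age | N(56.5, 4), N(78.5, 5), N(93, 6), N(103, 6), N(108, 5) cm, truncated to [40, 120] | means chosen so the mixture mean ≈ 69.1 cm and the range matches 45.5–108 cm |
| weight | 1e-5 · L³ · lognormal(0.1) kg | maps mean length 69 cm near the published mean 3.38 kg |
| reader sea error | 1SW 1%, MSW 5% per reader, ±1 yr | reproduces order-of-magnitude published totals (6–9 errors per reader; errors never exceed one year) |
| reader fw error | 23% / 33% per reading reader | per-reader accuracies 76.9% / 66.7%; the third reader abstains from freshwater age entirely |
| fw abstention | 1/3 for the two fw readers | ≈ published abstention share |
| smolt-mark abstention | 8/248, 61/248, 111/248 | published per-reader counts |
| geometry | L0 = 9 cm, β = 0.04 mm/cm, κ lognormal sd 0.08 | see below |

Error direction is symmetric (+1/−1 equally likely) because the
motivating study found no directional bias; at true age 1 the error is
forced to +1 since age 0 is impossible for a returning adult — this
floor is a genuine asymmetry of the error process at the age boundary,
which is why the nominal-size check of the symmetry test uses ages
bounded away from 1.

**Scale geometry.** Radii follow `S(L) = κ · β · (L − L0)` with a
per-fish lognormal factor κ. Winter marks sit on a piecewise-linear
latent growth path: freshwater winters interpolate from L0 to the smolt
length, sea winters from the smolt length to the adult length, in equal
per-winter increments (the simplest trajectory consistent with strictly
increasing annuli; the fraction of the final increment completed at
capture is configurable). Reader measurement noise multiplies each
radius *increment* by an independent lognormal factor, preserving
annulus order and the total-radius bound by construction. With L0 = 0
and zero noise the whole back-calculation pipeline is an exact identity
on smolt length; with L0 > 0 and zero noise the back-calculated smolt
length is `L_c(L_s − L0)/(L_c − L0)` in closed form, so the regression
slope on measured length exceeds 1 — the slope-type bias seen in real
back-calculation studies. The default L0 = 9 cm produces a clearly
detectable slope ≈ 1.15–1.18. Note what this mechanism does *not*
emulate: the published bias has a near-zero mean difference (−0.27 cm)
with slope 1.26, which a pure formation-length offset cannot reproduce
within L0 < min smolt length; in real data reader mark-placement
conventions offset the level. Passing tests therefore demonstrate the
machinery detects a slope-type bias of the right form, not that the
generator replicates the published effect sizes.

**Latent freshwater ages.** Freshwater truth exists only for the
parent-identified subset. Fish without truth still need annulus counts
and reader calls, so the radii and read simulators draw an independent
latent age from the same pmf for them; those fish are excluded from
every freshwater analysis downstream, so the draw shapes only nuisance
structure. For the same reason a reader's annulus count is not coupled
to that reader's (possibly wrong) age call.

## Numerical and design conventions

- All randomness flows from explicit integer seeds; the pipeline
  expands one top-level seed into fixed-label per-stage streams
  (SeedSequence children, masked below 2³¹), so stages are independently
  reproducible and a report is byte-identical across runs of the same
  config and seed.
- CSV round trips preserve integers exactly and measurements at their
  stated precision (0.1 cm, 0.01 kg, 0.001 mm).
- Radii validation allows equality at the scale edge (last annulus =
  total radius) within 1e-12 relative slack.
- Bias analyses require ≥ 3 fish and nonconstant measured lengths;
  per-scale back-calculation problems are collected and logged, never
  fatal to the cohort.
- Simulation-based checks in the test suite use 200–500 replicates and
  cohorts of 254 fish with B = 1000 bootstrap resamples — large enough
  that binomial Monte-Carlo error is a few percent of the quantities
  checked, which the assertion bands reflect.

## Known limitations

- No mechanistic growth model (temperature, circuli deposition): winter
  lengths are linear interpolations.
- No reader random-effects (mixed) models; readers enter only through
  pooling or per-reader stratification.
- No alternative back-calculation models (Fraser–Lee, body-proportional)
  and no post-hoc correction factor for Lea-Dahl bias; the pooled
  per-fish reader mean is the only aggregation for the headline bias
  analysis.
- The symmetry tests are asymptotic chi-square; no exact/permutation
  small-sample version is provided.
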