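# Methods

This note documents the models, conventions and design choices behind the
package, in the order a cohort flows through it.

## Scoring

**Averaging and rounding.** The four aliquot counts are averaged
arithmetically and rounded *half-up* to an integer before any category
lookup; the same rounded value decides elevated vs. not elevated (so a draw
averaging 4.75 counts as elevated and is scored with markers). Published
descriptions of the assay reference protocol rounding rules without
printing them; half-up applied uniformly is this package's convention, and
whether the enumeration brackets were applied to the raw or rounded average
in the original assay is unknown. Both choices matter only for averages
within 0.5 of a bracket edge.

**Enumeration brackets** are closed on both ends as printed (5–10 → 1
point, 11–100 → 3, >100 → 4); marker positivity categories are 0% exactly,
(0, 10], and (10, 100].

**The default point table.** The per-marker Bio-Point values come from a
supplementary table that is not publicly printed. The shipped default —

| marker | 0% | 1–10% | >10% |
|--------|----|-------|------|
| ER     | 4  | 2     | 0    |
| BCL2   | 2  | 1     | 0    |
| HER2   | 0  | 2     | 3    |
| Ki67   | 0  | 1     | 3    |

— is a deliberate stand-in constrained to reproduce every structural fact
the published algorithm states: maxima summing to 12 so the total tops out
at 16, sensitivity markers non-increasing and resistance markers
non-decreasing in positivity, and ER weighted at least as heavily as any
other marker. `validate_point_table` checks exactly these constraints, so
alternative weightings can be swapped in (YAML/JSON serializable) and
audited the same way. Results that depend on the specific default values —
e.g. which elevated-CTC marker profiles land in the low category — are
properties of this stand-in, not recovered trial facts.

**Undetermined results.** A panel whose status is not `ok` (QNS,
pre-analytic error, technical failure), or an elevated draw missing any of
the four marker percentages, yields an undetermined score, mirroring the
protocol notion of an unsuccessful determination; undetermined panels are
excluded from score-based groupings.

## Synthetic cohorts

The generator emulates the statistical structure of a 120-patient,
12-month serial-sampling trial; it is the test bed for every downstream
stage, not a model of any real cohort.

- **Baseline elevation** is Bernoulli(0.36). Elevated patients draw a
  patient-level mean count λ from a log-normal with median 15 and sigma 0.9
  (floored at 5); non-elevated patients draw λ ~ Exponential(0.8). Aliquot
  counts are conditionally Poisson(λ), *rejection-sampled* so the rounded
  four-aliquot average always agrees with the patient's elevation flag —
  this makes prevalence statements exact rather than almost-sure and is the
  one place the generator departs from a pure hierarchical draw.
- **Latent endocrine state** (sensitive/resistant) is drawn conditionally
  on elevation (P(resistant) = 0.80 if elevated, 0.15 otherwise). Marker
  percentages come from zero-inflated Beta priors conditional on that state
  (defaults in `synthetic.DEFAULT_MARKER_PRIORS`): sensitive patients tend
  to high ER/BCL2 and absent HER2/Ki67, resistant patients the reverse. No
  published marker-percentage distributions exist; these priors are free
  parameters chosen to give all three score categories non-trivial mass,
  and nothing downstream assumes their specific shape.
- **PFS** is exponential with median equal to the configured value for the
  patient's *baseline* score category (defaults 6.9 / 8.5 / 2.8 months for
  low / intermediate / high), administratively censored at 12 months.
  Median-parameterization uses hazard = ln 2 / median. 10% of events are
  deaths, 85% of those attributed to metastatic breast cancer.
- **Follow-up draws** exist only strictly before the event/censoring time;
  elevation persists with probability 0.85 for resistant patients and
  decays geometrically for sensitive ones, and per-visit independent
  missingness (defaults 5% at M1–M3, 30% at M12) thins the remaining
  panels. 3-month reimaging is missing with probability 0.11.

What the generator does **not** emulate: inter-laboratory and
inter-operator variation, staining-intensity distributions (percent
positivity is drawn directly), correlated marker panels beyond the single
latent state, non-exponential hazards, informative censoring or
visit-missingness linked to disease state. Tests passing on this generator
therefore certify the *analysis machinery* — estimators, exact tests,
bookkeeping — not clinical conclusions about any real population.

## Survival analysis

Kaplan–Meier estimation is delegated to lifelines; at tied times events
precede censorings (the standard convention). The k-sample logrank
machinery (observed-minus-expected vector and hypergeometric covariance) is
computed in-package because the 1-df *trend* statistic needs the covariance
explicitly: with scores $s$ (default 0, 1, 2), $z = s^\top(O-E) /
\sqrt{s^\top V s}$, two-sided normal p. The k−1-df heterogeneity chi-square
built from the same machinery is exposed separately (`logrank_test`) and is
verified against lifelines in the tests. The trial literature describes its
trend test as "2 degrees of freedom", which conflicts with the conventional
1-df trend statistic; both readings are available — `trend_test` (1 df) and
`logrank_test` (k−1 df) — and reports include both.

**Landmarking.** PFS is capped at the 12-month horizon *before*
re-anchoring; a landmark at time $t_0$ keeps patients with a usable sample
at that visit and capped PFS strictly beyond $t_0$, and subtracts $t_0$
from their times. Zero or negative re-anchored times (event on the sample
date) are excluded, as are patients whose score is undeterminable at the
visit.

## Rapid progression and exact statistics

RP is progression, or death attributed to metastatic breast cancer, within
3.0 months. A qualifying event settles the endpoint by itself; otherwise
3-month reimaging is required to call no-RP, and without it the patient is
unassessable and omitted. A non-MBC death inside the window is *not* RP.

- **Fisher 2×2**: scipy's implementation (probability-mass two-sided rule);
  a zero margin returns p = 1 with an undefined odds ratio.
- **Freeman–Halton r×c**: full enumeration of tables with the observed
  margins; p sums multivariate-hypergeometric probabilities no greater than
  the observed table's (relative tolerance 1e-9 on log-probabilities to
  absorb float noise). The r×2 case is vectorized; a configurable
  enumeration bound raises with advice to fall back to Monte-Carlo rather
  than silently running forever. The headline high-vs-low comparison is a
  2×2; the 3×2 across all categories is also reported, since published
  phrasing leaves ambiguous which test produced the quoted p-value.
- **Clopper–Pearson** intervals come from Beta quantiles. For whole-percent
  report formatting the bounds are rounded half-up to one decimal and then
  half-up to an integer — i.e. as read off a one-decimal intermediate
  table. This two-stage convention reproduces all ten published interval
  bounds checked (e.g. a lower bound of 28.467% prints as 29); a single
  half-up rounding does not.
- **Cochran–Armitage trend** over ordered categories with scores 0, 1, 2:
  $z = \sum_i s_i(x_i - n_i\bar p) / \sqrt{\bar p(1-\bar p)(\sum s_i^2 n_i
  - (\sum s_i n_i)^2/N)}$, two-sided normal p; degenerate pooled rates
  return (0, 1).

## Two-stage design and power

Each of the two sequential 32-sample analytical-validity analyses is an
exact binomial test of p ≤ 0.60 (unacceptable) against p ≥ 0.80 (desired):
reject the null when successes ≥ cutoff. α = P(X ≥ cutoff | p₀) and
β = P(X ≤ cutoff−1 | p₁) are exact tails; at the published cutoff 24/32
they are 0.0575 and 0.1746. `find_cutoff` returns the smallest cutoff
meeting the α target (which, α being decreasing and β increasing in the
cutoff, minimizes β among admissible cutoffs) when its β also meets the β
target. The stages are treated independently; no error spending is
combined.

Power for the clinical design draws, per replicate, category RP counts
Binomial(36, 0.20), Binomial(48, 0.34), Binomial(36, 0.75) — sizes are
round(fraction × 120) — and applies the 3×2 Freeman–Halton test at
two-sided α = 0.05. 2000 replicates give a Monte-Carlo standard error
under 1.2 percentage points near the null and far less at the design
alternative (power ≈ 100%); the acceptance script uses exactly this size.
Logrank-based power is deliberately not bundled: the design's hazard
assumptions for it are unpublished, so it is only computable from
user-supplied hazards via the survival module.

## Retraining ensemble

Eligibility: RP-assessable patients with a baseline rounded average ≥ 5 CTC
and all four markers determined. Each of 500 splits partitions the
eligible set into training (22) and validation (10), inflates the training
part to 500 by sampling with replacement, fits one model on five
predictors (average CTC, four marker percentages), and scores its
validation set; each patient's predicted probabilities are averaged over
the splits where they fell in validation, and the ROC/AUC is computed from
those means. Splits are drawn independently (not forced distinct).

Unstated details fixed here: trees are Gini-impurity CART with 3 features
considered per split (⌈√5⌉), minimum leaf 5 on the inflated scale and
unlimited depth, all configurable; "most important variable" is the
largest total impurity decrease; single-class training multisets fall back
to a constant class-frequency predictor with a logged warning; logistic
fits are unpenalized (separation on 22-point training sets is expected and
silenced at the ensemble level, but the univariate follow-up fits detect
complete separation and refuse to report a diverging estimate). A patient
who never lands in validation is excluded from the ROC with a warning; an
all-one-outcome validated set makes the AUC undefined and raises.

## Numerical and interface conventions

All times are months (days convert at 30.4375 days/month); no calendar
dates are used anywhere. Cohorts serialize to CSV one row per
patient-visit with empty fields for undetermined markers and full float
round-tripping; configs and point tables are YAML (JSON accepted). Every
stochastic component threads a single integer seed through
`numpy.random.default_rng`, and the missingness operator uses a seed
stream derived from the same seed so generation and thinning compose
deterministically. CLI exit codes: 0 success, 1 user error, 2 internal
error.

## Problem sizes used in the test suite

Parameter-recovery checks run at 5000 patients (prevalence) and ~5000
records per score category (KM median recovery; the cohort is sized up
because the intermediate category holds only ~5% of patients). Exact tests
are verified against brute-force enumeration at n ≤ 15 and against
permutation oracles (5000–20000 permutations) on fixed seeded instances;
the power simulation is verified at 400–500 replicates in tests and 2000
in the acceptance script.

## Known limitations

The default point table and marker priors are stand-ins (above), so
absolute score distributions and retraining AUCs on synthetic cohorts are
illustrative only. The Freeman–Halton enumeration is exact but exponential
in table size; beyond the configured bound a Monte-Carlo p-value is the
intended escape hatch and is not implemented in-package. Asymptotic p-values
(logrank, trend) are compared to permutation references only at moderate
sizes; at very small n they share the usual chi-square approximation error.
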