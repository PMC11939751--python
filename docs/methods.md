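# Methods

`brskit` implements a rule-set analysis of ordinal survey data: which
*combinations* of respondent characteristics predict high job satisfaction,
when no single variable does. The positive class is described by an
OR-of-ANDs rule set — e.g. *(health medium-or-high AND autonomy high AND
work time low) OR (age high AND sleep quality medium-or-high AND work time
low)* — selected by maximizing a Bayesian posterior over subsets of a mined
candidate pool, with bootstrap resampling to separate stable rules from
artifacts of a single sample.

## Data model and preparation

A survey table holds respondents × variables in the questionnaire's
original codings. The default instrument has 18 variables: ordinal 1–4/1–5
attitude and health items, a 1–10 social-class ladder, continuous weekly
work hours (0–84), weekday sleep hours (6–12), one-way commute minutes,
age (18–65), yearly income (≥ 0, heavily right-skewed), and three binary
demographics. Three items (job satisfaction, autonomy, sleep quality) are
reverse-coded in the raw instrument and flipped during preparation so that
higher always means more of the construct: v′ = (max level + 1) − v.

Preparation order: reverse coding → drop variables with more than a
threshold fraction of missing values (default 10%; 5% as a robustness
variant; the outcome may never be dropped) → remove rows with implausible
work time (> 84 h/week, i.e. ≥ 12 h × 7 days; exactly 84 is retained) →
listwise deletion of remaining incomplete rows → discretization and
binarization. The transform log records every step with row/variable
counts, so a prepared table documents its own provenance.

The outcome is dichotomized at mean + 1 sample SD: respondents strictly
above the cutoff form the high-satisfaction class.

Every predictor is reduced to three ordered bins. Continuous variables are
cut at their empirical 1/3 and 2/3 quantiles (linear-interpolation "type 7";
values tied with a cutpoint go to the lower bin; degenerate cutpoints warn).
Ordinal variables are cut by splitting their rating levels into three
contiguous, near-equal groups with the remainder assigned to the lower
groups: a 4-level item bins as {1,2}/{3}/{4} and a 5-level item as
{1,2}/{3,4}/{5}. Each three-bin variable then yields four *overlapping*
binary features — `low` (bottom bin), `low_or_med` (bottom or middle),
`med_or_high` (middle or top), `high` (top) — plus an exact `NOT_`
complement column for each; binary variables yield their indicator and its
complement. The overlap is what lets a conjunction of at most three
literals express one-sided threshold conditions in either direction.
Note that under this scheme the complement columns of a three-bin variable
duplicate other overlapping columns (`NOT_low` ≡ `med_or_high`, etc.); they
are emitted for completeness, and the miner collapses duplicate columns to
their first, positively-named occurrence so reported literals are canonical.

## Candidate rule mining

A rule is a conjunction of 1–3 feature columns (negations are ordinary
`NOT_` columns). The pool contains every conjunction with support —
fraction of *all* rows covered — of at least 5% (`ceil(0.05 · n)` rows),
found by a level-wise search using support anti-monotonicity for pruning.
Conjunctions pairing a feature with its complement are excluded. Rules
whose in-sample cover is identical to an earlier-enumerated rule's cover
(a literal that excludes no additional row, or two features that coincide
in this sample) are dropped by default (`drop_dominated`), keeping the
shortest, earliest representative: such duplicates are empirically
indistinguishable and only create exact ties downstream. Cover identity is
detected by comparing support, true-positive count, and two weighted-row-sum
fingerprints, which avoids materializing covers for long conjunctions. If
the pool exceeds 5,000 rules it is truncated by information gain of the
rule's cover with respect to the class labels, deterministically.

## The Bayesian rule set model

A rule set A is scored by the unnormalized posterior
p(A|S) ∝ π(A) · p(S|A).

**Prior.** π(A) = Poisson(|A|; λ) · Π_rules w(length). λ penalizes the
number of rules and the length weights (default uniform over 1..3) penalize
their complexity. `PriorParams` defaults to λ = 3 (rule sets of two or
three rules are the expected regime), but the pipeline and bootstrap use a
*pool-scaled* prior by default, λ = expected_rules / pool_size
(`pool_scaled_prior`): a count-only Poisson(3) makes the (k+1)-th rule
essentially free, while picking one specific conjunction out of thousands
should cost about log(pool size). Folding the selection cost into λ keeps
noise-chasing rules out of the MAP set; a genuinely predictive rule gains
far more likelihood than the ≈ log(5000/3) ≈ 7.4 it pays.

**Likelihood.** The rule set splits rows into a covered stratum (predicted
positive) and an uncovered stratum (predicted negative). Each stratum's
labels are modelled Beta-Binomially:

log p(S|A) = log B(TP+α⁺, FP+β⁺) − log B(α⁺, β⁺)
           + log B(TN+α⁻, FN+β⁻) − log B(α⁻, β⁻),

with B the Beta function. Defaults α⁺ = 100, β⁺ = 1, α⁻ = 1, β⁻ = 100
encode a strong prior that covered rows are positive and uncovered rows
negative — i.e. that a good rule set is precise and complete. The data
enter only through the confusion counts, so scoring is O(n) per update and
exchangeable over rows.

**Search.** The MAP rule set is found by multi-chain simulated annealing
over pool subsets (default 10 chains × 10,000 iterations; scaled-down
settings are used inside the bootstrap, see below). Moves add, remove, or
replace one rule; the temperature decays geometrically from 1.0 to 0.01 and
a move is accepted with probability exp(Δ log-posterior / T). Proposals
are guided: with probability 0.8 an add targets a rule covering a randomly
chosen false-negative row (weighted by rule precision²), and a removal
targets a rule covering a false positive. After the chains finish, the
best state found is polished by deterministic best-improvement local search
over single additions, removals, and one-for-one swaps until no move
improves the posterior; the swap moves matter because a near-equivalent
rule substitution is a two-step path through a worse state that annealing
rarely crosses late in the schedule. This is a stochastic MAP search, not
a posterior sampler; the guided, asymmetric proposals are chosen for
optimization quality, and reproducibility comes from seeding (per-chain
seeds are spawned from the master seed). On pools of ≤ 4 rules the search
is verified against exhaustive enumeration of all 2⁴ subsets.

## Bootstrap stability

B resamples (default 100) are drawn with replacement; mining and fitting
are redone on each. For every rule that ever enters a resample's MAP set:
*prevalence* is the fraction of resamples selecting it (exact literal-set
identity); *coverage* is decomposed into covered true positives (reported
positive) and covered false positives (reported negative), evaluated
in-bag on the resample that produced the rule (an out-of-bag option
exists); the 2.5th/97.5th percentiles of signed coverage (TP − FP) across
selecting resamples give a 95% interval. The aggregated rule set keeps
rules with prevalence ≥ 5% (at least 5 appearances in 100 resamples).
Per-row confusion labels (TP/FP/TN/FN) and a variable co-occurrence edge
list over the aggregated rules are exported for external embedding/chord
rendering; no plots are produced here.

## Synthetic surveys with planted rules

The generator emulates the instrument's marginals (categorical
probabilities and truncated-normal/log-normal laws approximating the
published descriptive statistics: work time mean ≈ 48.4 h, SD ≈ 17;
sleep quality mean ≈ 2.0 on the raw 1–4 scale; income log-normal with mean
≈ 79k and SD ≈ 129k; education recoded to 5 bands with the published
composition) and plants OR-of-ANDs truth: a respondent satisfying any
planted rule reports high satisfaction with probability 1 − noise_rate,
everyone else with probability noise_rate. Rules are planted on the same
discretized categories the pipeline mines, so recovery can be judged
literal-for-literal.

Three generator mechanisms deserve note:

- **Support forcing.** Under independent marginals a 3-literal rule's
  support is often below the 5% mining floor, so each planted rule may
  declare a `target_support`. Level-coded literals are forced by
  resampling the variable inside its category (level-defined bins give no
  feedback); continuous literals are forced by *swapping* values with donor
  rows, which preserves the column's marginal — and hence its tercile
  cutpoints — exactly. Donors are screened so a swap never accidentally
  completes another planted rule. Infeasible targets (e.g. a lone tercile
  literal, whose support is pinned at ~1/3) raise an error naming the rule.
- **Near-miss contrast.** For each literal of a forced rule the generator
  ensures at least `contrast_fraction × target_support` (default 1/3)
  near-miss rows satisfying every other literal but not that one. Without
  them, a literal that is marginally almost always true (medium-or-high
  health holds for ~93% of respondents under the declared marginals) is
  statistically indistinguishable from its absence, and the planted
  3-literal rule is unidentifiable from its 2-literal sub-rule. Naturally
  abundant near-miss sets are left untouched; only actively forced rows are
  protected from later reuse.
- **Outcome construction.** Positives report the top satisfaction level;
  negatives draw from a distribution concentrated just below the neutral
  midpoint (default (0.05, 0.30, 0.65) over aligned levels 1–3), chosen so
  that the mean + 1 SD cutoff lands between the top negative level and the
  top level for any positive rate from 0 to ~0.45. The pipeline's
  dichotomization then reproduces the planted labels exactly, which is what
  makes end-to-end recovery tests sharp. Configurations violating this
  (e.g. extreme positive rates) fail fast with a clear message.

Missingness injection is MCAR per variable; outlier injection replaces a
fraction of work-time values with infeasible weekly totals (96–168 h).

**What the generator does not emulate:** survey sampling weights, household
clustering, and realistic inter-variable dependence beyond what planted
rules and near-misses induce (covariates are otherwise independent). A
passing recovery test therefore shows the pipeline recovers rule structure
it is designed for under calibrated noise — not that the instrument's real
correlation structure would yield the same rules.

## Propensity, weighting, and mediation extension

To move from description toward adjusted effects, a core variable defines a
treatment contrast (high group = value > mean + 1 SD). A logistic
propensity model p_i = P(T=1 | W_i) supports (a) greedy 1:1 nearest-
neighbour matching without replacement (treated processed in descending
score order, distance ties to the lower control index), caliper matching
(default caliper 0.2 × SD of the logit of the score), or radius matching;
and (b) inverse probability weighting w = 1/p (treated), 1/(1−p)
(controls), with weights above the 99th percentile flagged. Perfect
separation aborts with the separating covariate named.

Each aggregated rule becomes an indicator column, and three OLS equations
are fitted: the mediator on treatment, controls, and rule indicators; the
outcome on treatment, mediator, and controls; and the outcome on all of
them jointly. The indirect effect of rule r through the mediator is the
product of its mediator-equation coefficient and the joint-equation
mediator coefficient, with a delta-method standard error
(se² ≈ λr²·var(λ2) + λ2²·var(λr)); the direct effect is the rule's
joint-equation coefficient. Without treatment grouping the treatment terms
are simply omitted. Diagnostics: variance inflation factors for the joint
design, a rule-overlap (Jaccard) matrix, rank-deficiency errors that name
the collinear columns, and a LASSO-based rule filter using 5-fold
cross-validation with the one-standard-error rule (the largest penalty
within one SE of the CV minimum), which zeroes pure-noise indicators
instead of letting them ride at the error-minimizing penalty.

## Baselines

Three standard interpretable baselines are included for comparison: LASSO
over all products of up to three binary features (complement products
excluded; a width budget guards the combinatorial design) with an OLS refit
on the selected support and 5%-level flags (no multiplicity correction —
matching the enumeration-style reporting this mirrors, a documented
caveat); rules read off the positive leaves of a leaf-capped decision tree
(left branch contributes the complement column, so the extracted rule set
reproduces the tree's predictions exactly on binary inputs); and
impurity-decrease random-forest importances, normalized and ranked.

## Pipeline and reproducibility

`run_pipeline` executes simulate/ingest → prep → mine → fit → bootstrap →
optional mediation/baselines, writing every artifact (CSV/TSV/JSON) and a
manifest with per-stage row/feature counts into a run directory. All
stage seeds are spawned deterministically from one master seed, so reruns
are byte-identical; `compare_runs` reports the Jaccard overlap of two runs'
aggregated rule sets plus a side-by-side prevalence table, which is how the
5%-vs-10% missingness robustness variant is assessed. The `brskit` CLI
exposes each stage (`simulate`, `prep`, `mine`, `fit`, `bootstrap`,
`mediate`, `baselines`, `run`, `compare`).

## Problem sizes and default study conditions

The reference recovery study uses n = 1000 respondents, the two headline
planted rules (target supports 0.12 and 0.10), 10% label noise, and B = 50
bootstrap resamples with 2 chains × 1,500 iterations per resample — chosen
so the full study runs in minutes on one core while the search still
reaches the enumerated optimum on every tested pool. Single definitive
fits use more chains and iterations (the 10 × 10,000 default). Search
verification uses 50-row fixtures with 4-rule pools where exhaustive
enumeration is exact; parameter-recovery checks use n = 5000 (logistic
propensity, ±0.1) and n = 2000 (mediation, 2 SE).

## Known limitations

- The real-world counterpart of the synthetic instrument — the CGSS 2021
  resident questionnaire — is restricted-access; analyses of it
  (sample counts after filtering, descriptive statistics) are supported by
  the ingest path (`RunConfig.input_csv` + a variable-spec YAML) but cannot
  be validated here.
- MAP search is heuristic; optimality is only guaranteed where enumeration
  is feasible. The polish step makes results locally optimal and, in our
  fixtures, globally optimal, but pathological posteriors can defeat it.
- Rule-indicator regressions inherit the usual caveats of linearly summing
  overlapping OR-logic indicators; the overlap matrix and VIFs are provided
  precisely so users notice when coefficients become uninterpretable.
- Cover-duplicate pruning is sample-relative: a literal dropped as
  redundant in one resample may be informative in another, which is one
  reason prevalence, not a single fit, drives the aggregated set.
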