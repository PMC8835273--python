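# Methods

## Scope and object of study

`parksocial` re-implements, as a tested pipeline, an observational analysis
of how the built structure of community sports parks shapes social
interaction. The study system is three parks in Chongqing divided into 35
spatial study units of three space types (fitness-equipment spaces, paths,
sports courts). Social interaction is measured on two bespoke scales — a
behavior-mapping *crowds-congregate index* and a questionnaire
*engagement-with-the-park score* — and the dependence of these outcomes on
spatial, activity and individual-difference variables is modeled with one
discrete Bayesian belief network (BBN) per space type. The original field
records are not publicly deposited, so the package ships a synthetic-data
generator with known ground truth; every quantitative claim the tests make
is about the method's behavior under those generated conditions, not about
the original survey data.

## Interaction metrics

For one observation session in a unit of area S (m², S > 1), with N people
present, person i belonging to a congregate group of size B_i for T_i
minutes (1 ≤ T_i ≤ 60; the observation window caps congregate time at 60
minutes, and longer stays are an upstream recording error rather than
silently clamped):

    R = Σ_i (B_i / A) · ln T_i  /  (N · log10 S),      A = (A_start + A_end) / 2

A is the session-level average crowd total from the start/end head counts
(each person assumed counted once). The published formula typesets the
grouping ambiguously; we read the numerator as the sum of per-person terms
(B_i/A)·ln T_i and the denominator as the area/size normalizer N·log10 S,
the only grouping under which the denominator acts as the described
normalization. "lg" is base-10, "ln" natural. Solitary visitors enter with
B = 1 — the sum runs over all N present people by definition of N. R ≥ 0,
strictly increasing in every T_i and decreasing in S.

Engagement is the mean of three 1–7 questionnaire items (participation
intensity, preference for the space, visit frequency), so it lies in [1, 7].

Spatial indicators are plain ratio computations on measured primitives
(enclosure L1/L, tree cover S1/S, 125°-panorama percentages, Shannon–Wiener
diversity −Σ p ln p in nats); photo segmentation and CAD work are out of
scope and their outputs are inputs here.

## Variable inventory and discretization

The packaged fixture holds 19 variables: 12 spatial, 2 activity, 3
individual-difference, 2 interaction outcomes. Category systems follow the
published conditional-probability tables. Numeric bins use a half-open
[lower, upper) convention with the last bin closed, which resolves two
ambiguities in the printed category systems: touching integer bins
("0–10" / "11–20") get the cut at the upper bin's lower bound, and the
vegetation-diversity bins "1.3–1.8" / "1.8–2.1", which overlap at 1.8,
assign 1.8 to the higher bin. Count variables with a textual gap at exactly
3 ("more than three" vs "one or two") assign 3 to the top category, keeping
the ordinal scale contiguous. Out-of-domain measurements raise an error
rather than clamping.

The two interaction outcomes have no published numeric edges, so their 5-
and 3-level systems default to equal-frequency (quantile) bins fitted on
training values and frozen, with unbounded outer bins so held-out values
always discretize; explicit edges can be supplied instead. MISSING is a
storage-layer sentinel (empty CSV cell), never a modeled category.

## Belief-network engine

A network is a DAG over the categorical variables plus one CPT per node.
Inference is exact variable elimination with a min-fill ordering and
lexicographic tie-breaks (nets here have ≤ ~20 nodes and ≤ 7 states, so
approximate inference is unnecessary and deliberately unimplemented).
Posteriors, evidence probabilities and record likelihoods (missing cells
marginalized) all come from this engine; held-out evaluation uses a
vectorized fast path for the common case where everything but the target is
observed, in which only the target's own CPT and its children's CPTs enter.

Parameters are fit by EM. Expected family counts are exact: families fully
observed in a record are tallied vectorized, families with missing members
get their posterior mass from variable elimination given the record's
evidence. The M-step normalizes counts with a Dirichlet pseudo-count
(default 1, preventing zero rows, in the spirit of experience-table
smoothing; the exact smoothing of the commercial tool the original analysis
used is proprietary, so this default is a documented stand-in, not a
bit-compatibility claim). Initialization is a seeded uniform-Dirichlet
draw; convergence is a relative log-likelihood change below 1e-6 with a cap
of 500 iterations. On complete data the first M-step already equals the
smoothed relative frequencies. With pseudo-count 0 the log-likelihood trace
is the EM objective and is non-decreasing; with smoothing, the monotone
objective is the penalized likelihood, so monotonicity tests run unsmoothed.
Parent configurations with zero expected count fall back to uniform rows.

A statistical note on parameter recovery: entry-wise CPT recovery within
±0.03 needs on the order of a thousand effective observations per parent
configuration. At n = 5,000 that holds for small families (≤ ~4 parent
configurations) and is what the recovery tests check; the generator's
largest engagement families (100+ configurations) would need two orders of
magnitude more data for the same bound, which is a property of the
estimand, not of the estimator.

## Structure learning

The search mirrors a three-step procedure: (1) a draft DAG from a-priori
knowledge — either the full published mechanism edges ("priors" mode) or
only a tier ordering spatial/individual → activity → interaction that
forbids edges pointing upstream; (2) candidate generation by seeded random
walks of geometric length (mean 4 moves) over legal single-edge
add/remove/reverse mutations, deduplicated, default 200 candidates, max 4
parents per node, required edges immutable; (3) EM fitting on a 70/30
train/test split and held-out scoring per interaction target: log loss
(mean −log probability of the observed state, floored at 1e-9) and argmax
accuracy (ties to the lowest state index).

Selection supports two rules. The default ranks by mean target accuracy
with log-loss tie-break, mirroring the original "highest accuracy"
phrasing. The recovery experiments select by log loss instead: argmax
accuracy is blind to a parent that shifts probability mass without flipping
the modal state (the published physical-activity and gender slices are
nearly collinear, so exactly this happens), whereas log loss is a strictly
proper score and separates the structures cleanly. An optional iterated
mode (`rounds > 1`) re-drafts from the current best and repeats — a
stochastic local search that stays within the random-mutation scheme; note
that because selection uses the same held-out split every round, many
rounds could overfit that split, so the default is 1 and the experiments
use 2.

Known a-priori edges are *not* required in the recovery experiments: the
draft there is edgeless under tier constraints only, so finding the
generating edge is a genuine discovery, not a constraint artifact.

## Sensitivity analysis

For a target variable, every other node is ranked by mutual information
I(target; variable) under the fitted joint, computed from exact two-variable
marginals — the expected entropy reduction upon observing the variable.
Entropy and MI are reported in bits (log base 2) together with the percent
of target entropy, which is scale-free; the original study reports
sensitivity magnitudes whose units are unstated and exceed the 5-state
entropy bound, so those published values are context, not comparison
targets.
Sensitivity is evaluated at the prior by default, with optional evidence
conditioning.

## Synthetic-data generator

One ground-truth network is packaged per space type, with edges shaped like
the published influence mechanisms (e.g. for fitness-equipment spaces:
{green view, accessibility, visual obstacles, fitness equipment} → physical
activity → crowds congregate; seats density → leisure activity →
engagement; children's play equipment, age, social relationship →
engagement; gender → crowds congregate). CPT rows combine the published
child-given-single-parent percentage slices across parents by normalized
product; slices never published are Dirichlet(1) draws from a fixed
name-fingerprint seed, so the packaged nets are deterministic. Root
marginals are uniform over the fixture bins (the real joint distribution of
spatial variables across the 35 units is unknown). An `effect_strength`
temperature β sharpens rows (p^β, renormalized); β = 4 puts the
physical-activity effect on crowds congregate above 0.3 total-variation
distance between rows — the strong-effect regime the recovery experiments
require.

Records are ancestral samples from these nets with missing cells injected
completely at random (no informative missingness mechanism is modeled).
Sessions are built so the congregate index is controllable: group sizes and
unit areas are drawn from per-type ranges (120 sessions per type, matching
~10 units observed over four days with three daily windows), a mean-one
lognormal noise factor (σ = 0.3) sets each session's index target around
the configured per-type mean (0.550 sports court, 0.503 path, 0.426
fitness equipment — the published ranking values, used here as generator
settings), and the implied log-time budget is split across groups with
random Dirichlet weights, water-filling any excess over the 60-minute
ceiling so the cap introduces no systematic downward bias. A session whose
groups are all at the ceiling tops out at R = ln 60 · ΣB²/(N² log₁₀S) — an
intrinsic feasibility bound that makes singleton-heavy sessions in large
areas unable to reach high index values, which is why the path scenario
observes moderate-length segments (80–300 m²) rather than whole paths.
Questionnaire items are integer-rounded draws around configured per-type
means (4.69 / 4.42 / 4.27). Park assignment of units to questionnaire
tallies (124 + 133 + 96 = 353) follows the packaged unit fixture, whose
unit-to-park mapping is a documented convention because the source map is
not machine-readable; subtype membership of all 35 units is exact.

What the generator does *not* emulate: spatial autocorrelation between
units, seasonal/diurnal usage structure, informative missingness, and any
dependence among the spatial variables themselves. Passing tests therefore
demonstrate correctness of the machinery and recoverability under the
stated conditions, not claims about the original field data — in
particular, the published data-dependent accuracies (74%, 76%, …) and
sensitivity values (1.23, 7.12, …) are not reproducible without the raw
records and are not targets anywhere in the package.

## Problem sizes

The verification suite and the acceptance script size their experiments for
a desk-scale run: 1,000 random sessions for the index oracle check, 200
(tests) / 60 (script) random nets for the inference-vs-enumeration sweep, 50
missing-data EM scenarios, n = 5,000 records with 10 seeded replicates for
the edge-recovery and ranking-recovery experiments (75 candidates × 2
rounds per replicate), and a three-space-type pipeline demo at smaller
candidate counts. These sizes were chosen as the smallest at which the
stochastic claims (≥ 9/10 seeds, ±0.03 recovery) are statistically
meaningful.

## Interfaces

The analysis-project layout is deliberate: the numbered scripts under
`analysis/` are the command surface (simulate → metrics → learn →
sensitivity), each a thin driver over the library, and `run_pipeline`
exposes the same chain as a single call. Networks interchange as JSON
(nodes, states, edges, row-major CPTs); datasets as CSV with empty cell =
missing; CPT exports as percent tables (rows summing to 100 ± 0.1) matching
the layout of the published conditional-probability tables.
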