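# Methods

## Model and assumptions

The pipeline models ten discrete variables describing a hospitalized
hereditary-angioedema admission: Age {≤17, 18-39, 40-64, ≥65}, Race
{White, Black, Hispanic, Other}, Income {Q1..Q4}, Payer {Medicare,
Medicaid, Private, Other}, Region {Northeast, Midwest, South, West},
Hypertension {no, yes}, Autoimmune {no, yes}, Diabetes {no, yes},
APR-DRG Severity {minor, moderate, major, extreme}, and the binary
outcome MortalityRisk {low, high}.  "Other" race absorbs Asian, Native
American, other and missing; "Other" payer absorbs self-pay and other
sources.  Sex is deliberately not a node.  The joint distribution
factorizes along an expert DAG; edges encode statistical dependence, not
causation, and the structure is knowledge-specified — no structure search
is performed.

The default edge set routes Age into the three comorbidities and the
outcome; Race, Income, Payer and Region directly into the outcome; the
comorbidities into Severity; and Severity into the outcome.  The published
figure of the structure is not machine-readable, so this reconstruction
follows the narrative rationale, and the JSON model config is the single
source of truth: users can swap in any alternative structure without code
changes.  Note the choice is consequential: with six parents the outcome
CPT has 4,096 rows, which drives the smoothing behaviour discussed under
Limitations.

## Parameter estimation

Counts N_ijk are exact cross-tabulations (zero rows kept for unobserved
parent configurations).  Each CPT row is the symmetric-Dirichlet posterior
mean θ̂_ijk = (N_ijk + α)/(N_ij + kα); the estimator is the posterior
mean, not the MAP mode, so α = 1 users get add-one smoothing and
unobserved rows fall back to the uniform prior mean.  α is per-category
and configurable; α = 0 is an MLE fallback permitted only when every
parent configuration was observed.  Parent configurations enumerate
lexicographically over declared category orders, making the JSON
serialization bit-stable (floats use shortest round-trip representation).

## Inference

Two engines compute every posterior.  The reference is brute-force
enumeration of the full joint (a plain Python loop, kept independent of
the factor code).  The production engine is factor-based variable
elimination with a min-degree ordering and declaration-order tie-breaks;
the test suite requires agreement to 1e-9 on hundreds of randomized
(network, evidence) instances.  Soft evidence is Pearl virtual evidence —
a nonnegative likelihood vector entered as a unit-scope factor — rather
than Jeffrey conditioning, which would pin the conditioned node's
posterior marginal exactly.  Virtual evidence matches the intended
semantics of observations that are "treated probabilistically": a flat
vector is vacuous, a one-hot vector reproduces hard evidence, and the
update interacts with the network's priors.  Scenario queries relax a
hard observation to strength s (default 0.9) on the observed state with
(1−s)/(k−1) on the rest; disjunctive observations (e.g. payer is
Medicare or Medicaid) are likelihood vectors with 1 on each admissible
state.  Evidence with zero posterior mass raises a distinct
impossible-evidence error instead of propagating NaN.

## Synthetic cohort generator

The generator stands in for licensed discharge data.  Root nodes take
fixed marginals; the published cohort frequencies pin White 58%, age
40-64 39%, private payer 40%, South 37% and West 23%, and the remaining
entries of each probability vector are chosen once as realistic
inpatient values (e.g. Age ≤17 8%, 18-39 27%, ≥65 26%; Medicare 26%,
Medicaid 19%; income quartiles near-uniform with Q3 highest at 28%).
Non-root nodes start from hand-specified log-odds effect tables in the
directions the published conditioning analysis reports — comorbidity
prevalence rising with age; risk rising with age, Black/Other race,
lower income, Medicare/private payer, Midwest/West residence and
severity, with severity the dominant term — and a single scalar intercept
per calibrated node (Hypertension 48%, Diabetes 21%, MortalityRisk
38.7%) is solved with Brent's method against the node's *exact* marginal,
computed by factor products over the full joint.  A final audit
re-enumerates all targets and raises a calibration error naming any node
off by more than 0.5 percentage points.  Autoimmune disease has no
published marginal; its age-graded prevalences (4-16%, overall 12.6%)
were fixed once.  The published prevalence of high risk appears as both
38.7% and 38.8% in different places; the generator targets 38.7%.

Cohorts are drawn by vectorized ancestral sampling in topological order
from `numpy.random.default_rng(seed)`, so identical (truth, n, seed) give
bit-identical CSVs.  The default cohort size is 441, matching the study
scale and hence the sparsity regime the Dirichlet smoothing addresses.
The generator emits complete cases only and the reader rejects missing
values ("missing" race is already folded into Other).  What it does not
emulate: survey weights, hospital clustering, within-region correlation,
or the real cohort's joint distribution beyond the calibrated margins and
the DAG's dependency structure — so passing tests demonstrate correctness
of the machinery, not epidemiological fidelity of any particular number.

## Validation stage

70/30 train/test split, stratified by outcome by default (floor of the
train fraction per stratum, remainder to test); with ~440 records and
~39% positives an unstratified split can destabilize the panel, and the
flag can be turned off to mimic a plain split.  Posterior probabilities
are thresholded at 0.5 with ties predicted high (conservative toward
detecting at-risk patients; configurable).  The eight-metric panel is
computed so its identities hold exactly: balanced accuracy =
(sensitivity+specificity)/2, detection rate = TP/N, detection prevalence
= (TP+FP)/N.  Degenerate denominators yield NaN, never a coerced value.
AUC is computed in two modes, always both: probability mode (standard ROC
over scores, trapezoid area, equal to the Mann-Whitney pairwise
probability) and label mode (the two-point ROC of the thresholded
classifier, a straight-line curve with area exactly
(sensitivity+specificity)/2, mirroring discrete-prediction reporting).

## Problem sizes and numerical choices

Exact inference is cheap at this scale (65,536 joint states), so no
approximate engine is used.  Tests exercise oracle equivalence on ~200
random networks of 3-7 nodes, marginal convergence at n up to 50,000,
parameter recovery on a compact truth network at n = 200,000 (chosen so
every CPT cell has roughly 3-sigma support inside a 0.02 entrywise band),
and validation behaviour at n = 5,000.  Probability-vector sanity is
enforced at 1e-9; elimination-vs-enumeration agreement at 1e-9;
calibration at 0.5 percentage points.

## Limitations

* With the default structure the outcome CPT has 4,096 parent
  configurations.  At study scale (n = 441) most configurations are
  unobserved, so the α = 1 posterior mean sits at 0.5 in most cells and
  the fitted no-evidence baseline is pulled noticeably above the 38.7%
  truth marginal (typically ~0.47-0.49); even n = 50,000 leaves ~12
  observations per cell, far too few for tight entrywise recovery of that
  one table.  This attenuation is an inherent property of
  Dirichlet-smoothed estimation at this sample-to-table ratio, shrinks as
  n grows, and vanishes for the other nodes (≤ 8 parent rows each).
  Users who need a calibrated study-scale baseline should use a sparser
  outcome parent set.
* The soft-evidence strength of the original scenario analyses is not
  recoverable, so scenario probabilities computed here characterize the
  synthetic truth, not the licensed cohort.
* Deltas are associational; the DAG licenses no causal or counterfactual
  reading.
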