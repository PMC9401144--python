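# Methods

This note documents the models behind `carenet`, the choices made where the
design was genuinely open, and what the synthetic test bed does and does
not establish. No empirical number appears here that the test suite or
`scripts/acceptance.py` does not itself compute.

## Episode construction and D^in

Claims of one patient are linked into per-fracture episodes by two
thresholds. Inpatient rule: a stay whose admission falls within
τ₁ days of a previous discharge continues the same episode (default
τ₁ = 10 d). Outpatient rule: a visit within τ₂ days of an admission,
discharge, or already-linked visit date belongs to the episode (default
τ₂ = 35 d). Both rules are closed transitively; the implementation is a
union-find sweep whose result equals, by a randomized test, the connected
components of the brute-force rule graph. Three readings of the rules were
open and are fixed as follows:

- **Day counting.** D^in = (last discharge) − (first admission) as a plain
  date difference, not the inclusive (+1) count; a same-day stay has
  D^in = 0. The case filter keeps D^in = 400 and drops 401 ("exceeding"
  the cap is exclusive).
- **Visit chaining.** The τ₂ rule anchors on visits already in the episode,
  so visit chains at ≤ τ₂ spacing extend it. A
  `LinkageParams(transitive_visits=False)` flag restricts anchors to
  admission/discharge dates for sensitivity analyses.
- **Overlapping stays.** Overlapping inpatient stays at different providers
  are merged into one episode with a logged warning; real claims contain
  such overlaps and no rule favors either stay.

Case age is age at the episode's first admission. Analyzable cases must
contain surgery, use only giant-component hospitals, and have D^in ≤ 400 d.

## Provider network

The usage matrix has B[i, j] = 1 iff patient j has at least one claim
(inpatient or outpatient) at provider i; multiplicity is deliberately
discarded. Edge weights are cosine similarities of provider rows, so a
provider's size cannot inflate its weights: duplicating patients leaves
weights in (0, 1]. Zero-weight pairs get no edge; self-loops are removed.
A flag restricts B to inpatient claims for sensitivity runs. Structural
features use standard definitions (networkx): unweighted shortest-path
distance averaged over ordered pairs (identical either way for a symmetric
metric), local clustering with C_i = 0 when degree < 2, and degree–degree
Pearson assortativity over edge endpoints in both orientations, undefined
(NaN, with a warning) on degree-regular graphs.

## node2vec

Second-order walks: from `cur` with predecessor `prev`, neighbor x is
drawn with unnormalized probability α·w, where α is 1/p if x = prev, 1 if
x neighbors prev, 1/q otherwise; the first step is weight-proportional.
Per-(prev, cur) distributions are cached; correctness is checked by a
Monte-Carlo walk-law test. `t` walks of `l` nodes start from every node.

The skip-gram maximizes Σ over (center u, context c) pairs of
v_u·v_c − log Z_u with the exact softmax normalizer Z_u = Σ_v exp(v_u·v_v)
over all nodes — affordable at the few-hundred-node scale of provider
networks, and the analytic gradient is verified against finite
differences. Contexts are the w positions before and after each walk
position. Training is minibatch stochastic gradient ascent on the mean
batch gradient, learning rate decaying linearly to 1% (default 0.5, 5
epochs, uniform ±0.5/d initialization, all seeded and exposed). These
optimizer settings are package choices for stable convergence on toy
corpora, not claims about any reference implementation.

Default hyperparameters are (t, l, w, d, p, q) = (7, 60, 13, 75, 16, 1/32);
the grid search re-draws the embedding per iteration, scores each (p, q)
cell by the mean over iterations of 5-fold cross-validated linear-model
RMSE (RMSE = √(mean squared error)), and returns the full surface plus the
argmin. Desk-scale studies in the tests use reduced sizes
(d = 16, w = 5, t = 5, l = 20, 2–6 iterations) to keep runtimes in minutes.

## Regression models

- **μ_G(s)** is the geometric mean of strength over a case's hospitals,
  computed in the log domain (strengths must be positive); the arithmetic
  mean is provided for comparison.
- **OLS** (statsmodels) reports per-coefficient t tests, the overall F
  test, R² and adjusted R². A constant response defines R² = 0. Rank
  deficiency raises an error naming the collinear columns.
- **Cross-validated R²** pools out-of-fold predictions over k folds (same
  folds across models) and scores them against y; repeats average over
  reshuffles. The adjusted CV R² uses the pooled n.
- **Trees.** Greedy SSE-minimizing binary regression trees with `m_try`
  features drawn per node, minimum leaf size `n_min`, a tree-wide split
  budget `s_max`, and leaf values equal to training means. Split ties break
  toward the lower feature index, then the lower threshold, for
  determinism. Random forest averages `M` trees fit on n-out-of-n bootstrap
  resamples. LSBoost starts from mean(y) and adds η-scaled trees fit to
  residuals; under squared loss the leaf constants are exactly the leaf
  residual means, so training loss is non-increasing.
- **Hyperparameter search.** `optimize_ensemble` is a seeded random search
  over {random forest, LSBoost} × (M, n_min, s_max, m_try, η) minimizing
  5-fold CV RMSE. The configuration space is small enough at desk scale
  that a surrogate-model (Bayesian) layer buys little; the search is the
  package's budgeted stand-in for that stage and the budget is a parameter.
- **Model comparison** reports Models 1–4 on identical folds; Models 3–4
  add mean and best rows over a configurable number of independent
  embedding re-draws (default 20; tests use 2–3).

## Map-equation communities

For a weighted undirected graph the ergodic walk gives node visit rates
p_α = s_α/2W. A community's exit probability is q_c = cut(c)/2W, and

L = q H(Q) + Σ_c p_c↻ H(P_c),  q = Σ_c q_c,  p_c↻ = q_c + Σ_{α∈c} p_α,

in bits. These flow definitions are the standard ones for undirected
networks; the implementation evaluates L through the collected plogp form
and is tested against an independent straight-from-entropy evaluator and
closed forms (a single-community 4-cycle costs exactly 2 bits). Detection
is a Louvain-style greedy search, two levels only: seeded node sweeps that
move a node to the neighboring community with the largest decrease in L
(ties keep the current assignment), alternating with merges of connected
community pairs, to a local optimum. On two-clique toys it attains the
exhaustive minimum over all partitions in ≥ 95% of seeds.

Per-community features use the induced subgraph; μ_G(s) uses full-network
strengths (cooperation is a property of the node in the whole system),
over all members and over in-prefecture members separately; both
conventions are exposed. The structure-vs-cooperation analysis regresses
μ_G(s) on ⟨d⟩/N, ⟨C⟩ and r across communities.

## The synthetic test bed

The generator emulates the statistical regime of prefecture-level femoral
neck fracture claims: a mostly female cohort centered on age 83; fracture
recurrence with exponential inter-fracture gaps of mean 126 days (every
drawn gap is recorded in the ground truth, so the distribution is testable
without censoring), recurrence starting after the post-fracture care tail
plus a 35-day quiet window so distinct fractures rarely chain through the
τ₂ rule; acute→recovery transfers with probability 0.19 starting within
τ₁-compatible gaps (~77–81% single-provider cases at defaults); weekly
outpatient lattices before and after hospitalization with occasional
±1-day jitter; a small no-surgery fraction and a rare lognormal long-stay
tail so every case filter removes rows; and five "medical administration
areas" on a ring, with providers and patients at 2-D locations and
distance-decayed provider choice, which makes patient sharing
geographically clustered and the areas the planted communities.

Cooperation is a positive latent per provider: an area-level mean plus a
smooth low-frequency spatial field plus a small provider residual. Two
mechanisms tie it to the observable network: the number of distinct
outpatient partners per case grows with the admitting hospital's
cooperation, and provider choice favors cooperative providers — so
realized strength correlates with planted cooperation. The realized stay is

D = stay_base + age_effect·(age − 83.2) + coop_effect·g(x) + noise,

with x the mean standardized log-cooperation over the case's hospitals.
In the linear regime g(x) = x; with `nonlinearity=True`, g saturates
(tanh) and planted per-community offsets (scaled to |coop_effect|) plus an
offset×cooperation interaction make the effect multi-dimensional, which is
what separates the embedding models from the scalar-strength models.

Default sizes (1800 patients, 220 providers, rate 1.2 over a 2014–2019
horizon) give roughly two thousand analyzable cases — the scale used by
the parameter-recovery study. The model-ordering and walk-strategy studies
use a sparser documented configuration (200 providers with tight hospital
catchments, within-area probability 0.98) at 900 and 400 patients
respectively: embedding-based models need enough cases per dimension,
while the depth-first-vs-breadth-first sampling contrast is a property of
sparse networks and fades as case volume densifies the projection. Sizes
were chosen so each study runs in minutes on one CPU. In the ordering
study Model 4 runs its budgeted hyperparameter search per embedding draw,
as the method prescribes.

What passing tests show — and what they do not: the pipeline recovers
planted effects (sign and significance of the cooperation slope, the
ordering of model classes, area-aligned communities) from data *generated
under this model*. Real claims differ in ways the generator does not
attempt: diagnosis coding and eligibility churn, comorbidity-driven stay
variation, non-exponential re-admission mixtures, provider entry/exit over
the horizon, and true geography. Results on synthetic data validate the
machinery, not the epidemiology.

## Numerical choices and limitations

- Exact-softmax skip-gram scales as O(N²d) per epoch; beyond a few
  thousand nodes a sampling-based approximation would be needed (out of
  scope here).
- The greedy map-equation search is a local optimizer; seeds change the
  sweep order and can change the local optimum on ambiguous graphs. L is
  always reported from the final assignment, so partitions are comparable.
- Cosine projection materializes only nonzero co-usage pairs (sparse
  product), exact to 1e-12 against the dense double loop.
- CSV outputs round floats to 12 significant digits; pipeline reruns under
  a fixed config+seed are hash-identical.
- Episode linkage treats dates as whole days; claims with identical dates
  are ordered by record type and provider id for determinism.
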