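# Methods

## The EES metric and its practical rules

EES integrates enantioresolution (Rs) and the retention factor of the
more-retained enantiomer (k₂) into one decision-oriented number:

    EES = Rs − p · max(0, k₂ − k₂ˡⁱᵐ)

Evaluation order matters and is fixed: (1) round Rs and k₂ to one decimal
(half away from zero); (2) cap Rs at `rs_cap` = 6 and truncate k₂ at
`k2_cap` = 30; (3) apply the formula with `p` = 45 and `k2lim` = 20;
(4) floor the result at −1. Whenever the rounded k₂ is within the limit,
EES equals the capped Rs. A separation is acceptable when EES ≥ 1.3.
All of these are fields of `EESParameters` and individually configurable.

Internally the computation runs on integer multiples of the rounding step,
so grid comparisons such as `EES ≥ 1.3` are exact in floating point — the
3-in-18 361 false-positive count below is an exact integer result, not a
tolerance artifact.

### Choice of the penalty factor

A *false positive* is an input scored acceptable although k₂ exceeds the
limit. The simulation that selects `p` evaluates, by default, **every**
one-decimal pair with Rs ∈ [0, 6] and k₂ ∈ [0, 30] exactly once
(61 × 301 = 18 361 cells); a uniform Monte-Carlo mode over the same grids
exists for cross-checking and converges to the enumerated rate. At p = 45
exactly 3 cells are false positives (0.0163 %, printed as 0.02 %), and 45
is the smallest integer in [1, 100] whose rate is ≤ 0.02 % (p = 44 gives
4/18 361 = 0.0218 %). The boundary k₂ = 20.0 is not penalized and is not a
false positive. The enumeration domain follows directly from the rounding
and truncation rules; a distribution-based simulation would add assumptions
the rules themselves do not impose.

## Quality metrics and the search objective

For each of the training (Tr), validation (Va) and internal-test (IT)
subsets, predictions are compared with targets on the back-transformed EES
scale (where the error thresholds below are meaningful):

* `Q = R·|R| − |1 − b₁| − |b₀|`, with R the Pearson correlation and
  (b₁, b₀) the OLS slope/intercept of predictions regressed on targets.
  Q = 1 only for a perfect, unbiased fit. If either vector is constant the
  correlation is undefined; such candidates receive Q = −3 (below any
  attainable real value) so the search can still compare them. Q is
  computed over all compound × mobile-phase cells of the subset.
* `pQ = 100 · (mQ − pOverfit · sQ)` with mQ, sQ the mean and sample
  standard deviation of the three subset Q values and pOverfit = 2;
  subset-to-subset instability is a symptom of overfitting and is punished.
* `pE` grades each cell's absolute error into Level 1 (0.2 < |e| < 0.4),
  Level 2 (0.4 ≤ |e| < 0.6) or Level 3 (|e| ≥ 0.6) and weights the counts:
  0.1·(Tr1+Va1+IT1) + 0.2·Tr2 + 0.3·Tr3 + 1·Va2 + 1.5·Va3 + 2·IT2 + 3·IT3.
  Errors ≤ 0.2 EES units cost nothing. Counting is per **cell**
  (compound × mobile phase): each compound contributes nine graded errors,
  which is the only reading under which the level thresholds act on
  individual predictions; a per-compound reading would discard information.
* `Fobj = W·pQ − (1−W)·pE` with W = 0.5. pE enters **negatively**: it is a
  penalty, and the optimizer maximizes Fobj. The additive variant
  (`ObjectiveWeights(literal_pe_sign=True)`) is retained for comparison but
  contradicts the intended optimization direction and is not the default.

## Network training

Networks are deliberately small: one or two tanh hidden layers with at most
30 neurons each (n₂ = 0 selects a single layer) and a linear output over
the nine mobile phases. Training minimizes MSE on the Tr rows by full-batch
Adam (learning rate 0.02) with Glorot-uniform seeded initialization;
after every epoch the Va MSE is evaluated and training stops once it has
failed to improve for `patience` = 20 epochs (or at `max_epochs` = 500),
restoring the best-Va weights. IT rows never influence fitting. Defaults
suit nets of this size on ≤ 100 rows, where full-batch gradients are cheap
and convergence is fast; both are configurable. Training is bit-for-bit
reproducible from its seed.

Autoscaling (column z-score with the sample n−1 standard deviation) is
fitted on the **full** compound set before splitting, matching the global
preprocessing convention of wrapper-selection workflows; note this leaks
distributional information across subsets, which is acceptable here because
subset membership is itself a search variable. Constant columns record a
scale of 0, map to zeros, and back-transform to the constant exactly.
Predictions are back-transformed to EES units; user-facing profiles are
clipped to [−1, 6], while objective evaluation uses unclipped values so the
regression diagnostics in Q stay linear.

## Solution encoding and the search

A candidate is a vector in [0,1]⁷⁴ (for 62 descriptors): genes 1–10 are
split slots (first 7 → Va, next 3 → IT, remainder Tr), genes 11–12 the
topology (n₁ = 1 + round(g·29), n₂ = round(g·30)), genes 13–74 descriptor
switches binarized at 0.8. Decoding is *total*: split slots map through
floor(g·n) with forward-cyclic collision repair, so any genome yields a
valid disjoint 7/3/66 partition, and an all-below-cutoff switch block is
repaired by forcing the single highest gene on. The 7-then-3 slot order and
the linear topology mapping are this package's conventions.

The optimizer is population-based with a chaotic perturbation: offspring
are built around the incumbent best (best + F·(x_r1 − x_r2), F = 0.8),
perturbed by a logistic-map signal (rate 4) whose amplitude anneals
geometrically from 0.3 to 0.01 over the run, recombined gene-wise with the
parent (crossover rate 0.7), and compete with their parents — the worse of
each pair is discarded. The worst 10 % of the population is regenerated
each iteration around the best with the same annealed amplitude, which
doubles as local refinement late in the run. Elitism is on by default, so
the best-so-far trajectory is monotone (a tested invariant). These update
constants were fixed by benchmarking the search on an analytic sphere
surrogate and on the synthetic feature-recovery task; the objective
interface is pluggable, so an alternative metaheuristic can be swapped in
without touching candidate evaluation. Reference-scale settings are
population 250, 500 iterations and 70 independent runs; tests and examples
use reduced scales (population 8–30, 3–30 iterations, 3–5 runs) that finish
in seconds to a few minutes on one CPU while exercising identical code.

Within one run the network-training seed is derived from the run seed, so a
genome always maps to the same Fobj (the objective is deterministic within
a run, noisy across runs — by design, since runs are meant to explore
different basins).

## Consensus

Archived models are ranked by misclassification count against EES = 1.3
(ascending), ties broken by Fobj (descending), then pE (ascending), then
model id. Selection among candidate models is often aided by visual
inspection of validation plots; the deterministic tiebreak chain replaces
that step for reproducibility.
The top k = 5 models (k is a user parameter; no automatic gap detection)
form the consensus: per compound and mobile phase the member predictions
reduce to their median (midpoint for even k) and MADe = 1.4826·MAD, the
consistency-scaled robust standard-deviation estimate. A phase is feasible
when the median reaches 1.3; among feasible phases the one with maximal
median EES is nominated, ties to the lowest acetonitrile content.

## The synthetic benchmark

The generator fabricates datasets with the geometry of a real screening
campaign (default 76 compounds × 62 descriptors) and a planted truth:

* descriptors mix small-integer counts, binary flags and continuous values;
  the first 5 columns (continuous) carry all signal;
* latent retention and chiral-recognition scores are linear in the
  informative columns; retention decays exponentially with acetonitrile
  fraction (log k₂ = 4 + r − 6·f<sub>ACN</sub>, plus noise), spanning
  impractically retained cases (k₂ > 20) at 30 % ACN down to near-void
  retention at 98 %;
* resolution is amp·softplus(c)·hump(k₂) for compounds whose recognition
  score passes a population-quantile gate (default 30 % pass), where the
  hump envelope vanishes at zero retention and peaks at moderate k₂;
  gated-off compounds get near-zero Rs everywhere. Rs and k₂ are rounded
  to one decimal, and k₁ ≤ k₂ is stored for completeness though nothing
  consumes it.

This emulates the class structure that matters to the framework — a
majority of flat profiles, a minority of peaked ones, retention-penalty
floors at low ACN — and supports exact ground-truth checks (which
descriptors are informative; realized separable fraction within ±0.1 of the
target at n = 200). It does **not** emulate real descriptor correlations,
possible biphasic retention on cellulose phases, or the EES distribution of
any particular dataset, so passing tests demonstrate that the machinery
recovers structure it is pointed at, not chromatographic accuracy on real
compounds.

## Numerical choices and degenerate inputs

* Rounding is half-away-from-zero, as in everyday chromatographic
  reporting; EES arithmetic is exact on the rounded grid (see above).
* Early stopping improvements must exceed 1e−12 to reset patience.
* Constant prediction/target vectors → Q = −3 (flagged, not fatal).
* Split decoding rejects datasets with ≤ 10 compounds (the slots could not
  be distinct).
* Even-sized consensus memberships use the midpoint median; MADe of fully
  agreeing members is exactly 0.
* Pipeline manifests carry a wall-clock timestamp; reproducibility checks
  therefore hash every artifact except `manifest.json`.

## Known limitations

* The chaotic-search constants are this package's own, benchmarked on
  surrogates, not a reimplementation of any particular published variant's
  constants.
* The network trainer is defined by its contract (MSE on Tr, early stop on
  Va, seeded determinism), not by parity with any particular toolbox's
  training algorithm (e.g. Levenberg–Marquardt); different optimizers
  satisfying the contract yield different weights but the same framework
  semantics.
* MADe is the only uncertainty measure; no formal prediction intervals.
* Applicability is bounded by the training chemotype/condition space: a
  consensus trained on one column and solvent system says nothing about
  others.
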