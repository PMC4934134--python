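# Methods

## The problem

In randomness-perception experiments, participants rate binary strings
(e.g. X/O sequences) for how random they look, or classify them as
random/non-random.  The normative yardstick is the second-order entropy of
the string, which is maximal when the probability of alternation
P(A) = (r − 1)/(n − 1) equals 0.5; observed ratings instead peak around
P(A) ≈ 0.6–0.7 (the overalternating bias).  This package scores sequences
with symmetric (Shannon, Rényi) and asymmetric (Marcellin) entropies, fits
the free parameters of the latter two to mean rating curves, and validates
fitted measures by correlation against observed judgments.

## Sequence statistics

A sequence of length n over {X, O} has r runs and n − 1 overlapping
digrams in four categories, ordered throughout the package as
(XX, OO, XO, OX) — uniform pairs first, alternating pairs second.  Two
identities tie these together and are enforced as exact invariants:
c_XO + c_OX = r − 1, and P(A) = (c_XO + c_OX)/(n − 1).  Digrams are linear
(no wraparound): this is the only reading under which the digram count and
the alternation identity are mutually consistent.

For a *stimulus level* rather than a concrete string, the analytic digram
distribution splits the alternating mass pa equally between XO and OX and
the uniform mass 1 − pa equally between XX and OO.  Within any single
linear string |c_XO − c_OX| ≤ 1, and the fitted weight constraints force
the corresponding weights to be nearly equal, so a finer split would change
the second-order entropy negligibly; the symmetric split is deterministic
and reproducible.

## Entropy families

All logs are base 2.  Conventions: 0·log(1/0) := 0; 0^α := 0; the support
size for Rényi α = 0 counts strictly positive masses; α = ∞ is an explicit
sentinel (`math.inf`), never inferred from magnitude.

- Shannon: H(P) = Σ pᵢ log₂(1/pᵢ).
- Rényi: H_α(P) = (1/(1−α)) log₂ Σ pᵢ^α, with the Shannon limit at α → 1
  taken by an explicit branch at |α − 1| < 1e−12.
- Marcellin: H_W(P) = Σ pᵢ(1−pᵢ)/((1−2wᵢ)pᵢ + wᵢ²), each wᵢ strictly in
  (0, 1).  The denominator is linear in pᵢ and positive at both endpoints
  (wᵢ² and (1−wᵢ)²), so the measure is non-negative on the whole simplex;
  it is zero at point masses and equals N when P = W.  W is a free
  parameter vector, not a distribution — the fitted four-weight vector
  sums to about 2.

### Second-order entropy

H2 is defined as digram entropy minus first-order entropy.  Two
formulations are provided because the four-category Marcellin digram term
and the two-category symbol term can be combined in more than one
defensible way:

- `difference` (default): F(digram) − F(first-order).  Marcellin applies
  the four digram weights to the first term and a separate two-component
  worst distribution to the second, default (0.5, 0.5) — the first-order
  distribution of the stimulus designs is nearly constant (11/21 vs
  10/21), so this term shifts the curve by a near-constant and its worst
  distribution is not fitted.
- `conditional`: Σ_s p(s)·F(next | s), weighting by the digram
  first-symbol marginal; Marcellin uses the conditional worst pairs
  (w_XX, w_XO) given X and (w_OO, w_OX) given O.  For Shannon the two
  formulations coincide exactly by the chain rule (when the first-order
  term is the digram marginal); for Rényi α ≠ 1 and Marcellin they
  genuinely differ.  The fitted weight pairs nearly summing to 1 per
  conditioning symbol hints that the conditional reading is almost proper,
  but `difference` remains the default and the fitting target.

For the same reason, Rényi's α is applied to both terms of the difference.

## Model curve and fitness

`model_curve` evaluates H2 at each P(A) level of the design.  The default
`analytic` mode scores the level's idealized digram distribution with a
symmetric (0.5, 0.5) symbol marginal (which is also the exact first-symbol
marginal of that distribution), making the curve deterministic; a
`stimuli` mode instead averages per-sequence H2 over generated stimulus
sets, which tracks the analytic curve up to the 11/10 marginal and
sampling noise.

Ratings live on a 0–10 scale while entropies are in bits, so the Euclidean
fitness between a model curve and a target curve requires an alignment
choice.  The default, `minmax_both`, min–max normalizes both vectors to
[0, 1] over the evaluated levels — a pure shape comparison, the only
option that is well defined without committing to a rating-scale
calibration.  `ratings_div_scale` (ratings divided by the scale maximum,
model divided by its own peak) and `none` are provided as alternatives.
Reported fitness magnitudes depend directly on this choice.

## Difficulty Predictor

DP is the minimum of (#uniform segments) + 2·(#alternating segments) over
all partitions of the string, where uniform segments are constant and
alternating segments have every adjacent pair unequal and length ≥ 3.  A
length-2 alternating fragment would cost exactly the same as its two runs,
so the ≥ 3 rule removes pure ties without changing any score — verified
exhaustively against the brute-force oracle on every string up to length
12.  The dynamic program is O(n²); the score is unique, and among minimal
partitions the reported one prefers fewer alternating blocks, then longer
segments.  A length-1 string has DP = 1.  DP deliberately reproduces the
measure's known length insensitivity (a long and a short uniform run cost
the same); no normalization is added.

## Differential Evolution

Classic DE/rand/1/bin: population N = 20, mutant v_m = v₁ + F·(v₂ − v₃),
binomial crossover at rate CR with one forced mutant component (standard
rule; a toggle), greedy one-to-one selection with ties going to the trial.
Mutants are clipped to bounds component-wise (a toggle).  Donor vectors
are drawn from the current, in-place-updated population.  Defaults
F = 0.6, CR = 0.9, 100 generations — the best cell of the tuning grid for
this fitting problem.

Constraints are feasibility rules of the form 2|xᵢ − xⱼ|/(xᵢ + xⱼ) ≤ 0.1
on the (XX, OO) and (XO, OX) weight pairs: infeasible trial vectors are
discarded and regenerated (fresh donors and crossover) up to
`max_retries` = 100 times, after which the target member survives the
duel — guaranteeing termination; at tolerance 0.1 exhaustion is rare after
the first generations.  Initial members are rejection-sampled until
feasible.

A run *converges* when its best fitness falls below the best fitness over
all runs of the batch plus 1%.  The F × CR tuning grid spans F = 0.1…2.0
and CR = 0.1…0.9 in steps of 0.1 (180 cells), scoring each cell by
convergence percentage and mean generations to converge.  Note the
criterion is relative: on objectives whose optimum is exactly 0 the
threshold collapses, so benchmark objectives with a positive fitness floor
(e.g. 1 + Σx²) — matching real fitting problems, where the best fitness is
strictly positive — make the criterion meaningful.

Fitting bounds: Marcellin weights in [0.001, 0.999]⁴ (the measure requires
wᵢ strictly inside (0, 1)); Rényi α in (0, 10] by default — the upper end
is far beyond the regime where the second-order curve still changes
appreciably, and it is configurable.  Runs are exactly reproducible from
their seed, and `fit_entropy(n_runs=k)` reports the best of k
independently seeded runs, mirroring the usual practice of reporting the
best of a batch of search-algorithm runs.

## Synthetic data

`generate_fk_set` emulates the classic design: replicate sets of
21-symbol strings, one per P(A) level 0.1…1.0, with the run count
r = 20·pa + 1 enforced *exactly* (not in expectation) and the 11/10 symbol
split alternating across levels.  Run lengths are uniform random
compositions (stars and bars) of each symbol's count into its runs; the
starting symbol alternates across levels and sets where the run structure
permits (at P(A) = 1.0 the majority symbol must start).  What it does not
emulate: individual raters, response noise, sequence-position or order
effects — passing recovery tests shows the fitting machinery is correct,
not that real raters behave like the generator.

`synth_rating_curve` rescales a model curve to [0, 10] by min–max and adds
i.i.d. Gaussian noise (sd in rating units), clipped to the scale.  The
noise model is a plain stand-in for mean-rating variability; real mean
ratings have level-dependent variance and correlated deviations.

## Parameter recovery: what to expect

Noiseless curves: best-of-3 DE runs recover all four Marcellin weights to
within 0.05 (and Rényi's α to well under 0.1) in ≥ 9 of 10 replicates;
single runs occasionally land in a local minimum, which is why the
experiment reports the best of a small batch.

Noisy curves (sd 0.25 rating units): the typical (median) component error
stays well under 0.15, but the objective is weakly identified along one
direction — in roughly one replicate in ten to twenty, the *global*
minimum of the noisy shape-distance jumps to a second mode with
alternating weights near 0.4 and component errors around 0.3.  This is a
property of shape-only fitting of this model at 10 points, not an
optimizer failure (the second mode fits the noisy curve strictly better
than the generating weights do).  Conclusions about individual weights
from noisy 10-point curves should therefore be drawn from replicated
fits, not a single curve.

## Known limitations

- Only two-symbol alphabets; no two-dimensional grid stimuli.
- The published best/worst fitness values for real rating data cannot be
  checked here because the underlying mean ratings are not public; the
  pipeline ingests such data via CSV when available.
- The uniform/alternating weight pairs are individually only weakly
  identified (their within-pair ordering is exchangeable up to the
  constraint), so per-component intervals tighter than the constraint
  width are not meaningful.
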