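# Methods

## Additive model and normalization

Global values are additive over criteria: `v(a) = Σ kᵢ · uᵢ(xₐᵢ)` with
scale constants on the unit simplex. All criteria are treated as benefit
type (more is better); cost criteria are out of scope. Per-criterion value
functions are affine min–max maps over the *observed* column range of the
consequence matrix: the worst observed raw score maps to 0 and the best to
1, so every column of the normalized matrix spans [0, 1]. Alternatives to
this choice (score/maximum scaling, global fixed ranges) were considered
and rejected because only the observed-range min–max map reproduces the
case study's printed value maxima (SET 0.6667 over the ranked space) and
its final value (SET 0.5847 at the final scale constants). A criterion
whose column is constant carries no information; it raises an explicit
degenerate-criterion error rather than being silently dropped.

Weight vectors supplied by callers must be non-negative and sum to 1
within a tolerance (default 1e-9, configurable per call).

## Questionnaire aggregation

The criterion-level consequence matrix is built from a two-level criteria
tree (criteria with ordered subcriteria) and a specialist's 0–5 score per
(alternative, subcriterion) pair: each matrix entry is the plain sum of
the alternative's scores over the criterion's subcriteria. The packaged
triage fixtures reproduce the study's published matrix cell-for-cell under
this rule, which is why the sum (not the mean) is the default. Nurse-panel
Likert relevance means (1–5) are packaged and exposed, but intentionally do
not enter the matrix numerically: in the study they informed the
specialist's scoring qualitatively. A `leaf_weights` hook turns the sum
into a weighted sum for studies that want relevance-weighted aggregation;
it defaults off. Display rounding is decimal half-up to 2 places; internal
values are never rounded.

Tree validation prunes the subcriteria a decision group rejects and drops
criteria left without leaves. The packaged tree is the validated one
(4 criteria, 27 subcriteria); the two subcriteria removed during the
study's validation step are not identified in the source material, so
tests model them as synthetic extra leaves.

## Weight space and linear programming

The ranked weight polytope and all statement cuts are kept as an explicit
list of linear constraints; every query is a HiGHS LP
(`scipy.optimize.linprog`, deterministic for fixed inputs):

- **value maximum** of an alternative: maximize `u·k`;
- **weight bounds**: min/max of each `kᵢ` (2n LPs);
- **potential optimality**: maximize a slack `s` subject to
  `v(alt, k) ≥ v(b, k) + s` for every rival `b` — the alternative survives
  iff the optimum is ≥ 0;
- **ratio bounds** `k_j/kᵢ`: a Charnes–Cooper transformed LP
  (`y = k/kᵢ`, `s = 1/kᵢ`), exact in one solve per side; valid because the
  ranking keeps `kᵢ` strictly positive.

Strict inequalities are closed with an epsilon `δ` (default 1e-6,
configurable): additively for the ranking (`k_r ≥ k_{r+1} + δ`) and
multiplicatively for statement cuts (`k_j ≤ kᵢ(v − δ)` rather than
`kᵢv − δ`). The multiplicative form shifts the feasible ratio interval by
exactly δ regardless of the magnitude of `kᵢ`; an additive epsilon shifts
it by δ/kᵢ, which can exceed the remaining interval width late in a
session when low-ranked weights are small, and was therefore rejected.
Indifference answers add a two-sided band of the same relative form
(±1e-6, configurable) instead of a hard equality, keeping the polytope
full-dimensional for subsequent LPs.

Elimination is conservative: an alternative is excluded only when its
optimal slack falls below −1e-7, so boundary ties always keep it and the
true best cannot be lost to rounding. For δ = 0 the ranked polytope's
vertices are the equal-weight prefixes `(1/m, …, 1/m, 0, …, 0)`; this
closed form serves as an independent enumeration oracle in the tests,
alongside a dense simplex-grid search.

## Elicitation loop

Questions oppose a hypothetical intermediate level on a higher-ranked
criterion (worst elsewhere) to the best level on a lower-ranked criterion
(worst elsewhere); the pair need not be rank-adjacent. The default
bisection strategy asks about the ranked pair whose feasible ratio
interval is widest, at the interval midpoint, halving it per answer. Pairs
whose interval is narrower than `min_ratio_width` (default 1e-5, floored
at 8δ so the δ-closed cuts stay feasible) are considered resolved. The
loop stops at a single survivor, an exhausted answer source, an
uninformative question set, or a question cap (default 50). With several
survivors at termination the recommendation is the survivor with the
highest LP maximum value, ties broken lexicographically by id.

Scripted replays fix the pair sequence from the recorded session and let
bisection choose the levels, since the original on-screen levels were not
published. On the packaged case study this replay not only ends in the
recorded recommendation (SET, sole survivor after seven answers) but lands
on the published final scale constants and weight limits to all four
printed decimals — evidence the original tool used the same midpoint rule.
The recorded answer notation is ambiguous about which consequence was
labelled A versus B on screen; the fixture adopts A = hypothetical on the
higher-ranked criterion, per the model's constraint derivation, and says
so in its header.

Inconsistent answers (a cut that empties the polytope) raise an error
carrying the offending statement and the session log accumulated so far.

## Synthetic data and what it shows

The generator draws integer consequence matrices uniformly per cell
(default 5 alternatives × 4 criteria on 0–30, echoing the case study's
summed 0–5 subcriterion scores; constant columns are redrawn) and true
weights uniformly from the ranked simplex (Dirichlet(1,…,1) sorted
descending). The simulated decision-maker answers by comparing `kᵢ·v`
with `k_j` under its true weights, with a symmetric indifference band
(default 0 — a perfectly consistent answerer).

The recovery experiment reports the fraction of replicates in which the
session recommends the true-best alternative. Replicates whose top two
alternatives tie exactly under the true weights are redrawn, since "the"
best is undefined there. With a zero band and a generous question budget
(200), recovery is complete over 200 replicates at the default problem
size; the mean session length is about 4–5 questions. What this does and
does not show: the simulated answerer is perfectly self-consistent and
stationary, so these runs validate the geometry of the method (the true
best is never cut off, intervals contract), not robustness to human
inconsistency, fatigue, or preference drift — real sessions can
contradict themselves, which the engine surfaces as an error rather than
resolving.

## Problem sizes and numerical defaults

Test and acceptance runs use 5×4 problems (the case-study scale), 200
statement-sequence and recovery replicates, a 0.01-step grid oracle on 50
random problems, and LP tolerances as above; the whole suite completes in
a few minutes on one core. Key defaults: δ = 1e-6, indifference tolerance
1e-6, elimination slack −1e-7, weight-sum tolerance 1e-9, max 50 questions
interactively and 200 in simulations.

## Known limitations

- Only additive value models with affine per-criterion value functions;
  no outranking, multiplicative, or nonlinear forms.
- Weights are the only imprecise quantity; consequences and value
  functions are taken as exact.
- Strictness epsilons mean weight vectors within δ of a cut can be
  classified either way; reported bounds are accurate to solver tolerance
  (~1e-7), not exact rational geometry.
- Single decision-maker (or a group answering jointly); no aggregation of
  conflicting answer streams.
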