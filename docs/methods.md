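# Methods

## Scope and model class

`symobs` treats autonomous ODE systems ẋ_i = f_i(x₁, …, x_d) whose
right-hand sides are rational functions of the state variables; any free
name not declared a state variable is a constant parameter and never
takes part in symbol classification. Transcendental couplings (exp,
non-integer powers of a state, …) are rejected with an explicit error:
the four-symbol calculus is defined for polynomial and rational couplings
only, and silently approximating anything else would corrupt every
downstream quantity.

## Symbol classification

Each Jacobian entry ∂f_i/∂x_j is brought to a canonical ratio of
polynomials (`sympy.together` followed by `sympy.cancel`) before
classification:

* identically zero → `0`;
* constant in every state variable → `1`;
* x_j present in the canonical denominator → `1̄̄`;
* otherwise (non-constant polynomial, or rational whose denominator does
  not involve x_j) → `1̄`.

Cancellation before the denominator test matters: an entry like
x₂·(1 − x₁₂)/(K + 1 − x₁₂) differentiated with respect to x₂ keeps its
denominator but loses the x₂ dependence *in* it, and must classify as
`1̄`, not `1̄̄`. Classification is invariant under scaling by nonzero
parameters, which the test suite asserts.

Products and sums of symbols follow explicit rewrite tables (the more
severe symbol wins; zero annihilates products). The tables are stored
verbatim as the source of truth; their equivalence with the max-severity
shortcut is asserted exhaustively in tests.

## Observability matrix

A measurement configuration assigns each sensor a coordinate count c_i ≥ 1
(the variable plus its first c_i − 1 derivatives) with Σ c_i = d. Each
sensor contributes a block of rows: the unit row e_i, then the sensor's
symbolic Jacobian row, then repeated propagation v ↦ (⊕_k v_k ⊗ J_kj)_j of
the previous row. Blocks are emitted in ascending variable order; the
determinant summary below is invariant under any row permutation (tested),
so block order is immaterial.

## Determinant summary and coefficient

The symbolic determinant is the multiset of nonzero permutation products
with **no sign bookkeeping, no cancellation, and no deduplication of
identical rows**: each of the T surviving permutations contributes d
symbols, tallied into occurrence totals N₁, N̄, N̄̄. This convention — rather
than, say, symbol-algebra reduction of the expanded determinant — is the
one that reproduces the published benchmark coefficients (0.17, 0.30,
0.48, 0.70, 0.86, 0.93 and all exact 1.00/0.00 cases) on the bundled
models.

Two equivalent implementations exist deliberately: a d! brute-force
enumeration (refused above d = 8, used as the independent oracle) and a
permanent-style dynamic programme over used-column bitmasks that
aggregates (term count, occurrence totals) per state. Rows are processed
sparsest-first, which keeps the state space tiny for observability
matrices (their many unit rows admit only one column choice each); the
worst case is O(d · 2ᵈ) states, comfortable up to d ≈ 20. Both agree on
500 random matrices per test run.

The coefficient is computed in exact rational arithmetic
(`fractions.Fraction`):

    if N̄ = 0 and N̄̄ > 0:  N̄ ← N̄̄        (rational-system condition)
    D = max(1, N₁) + N̄ + N̄̄
    η = N₁/D + N̄/D² + N̄̄/D³            (η = 0 when T = 0)

The rational-system condition is stated here with the overbars restored:
purely rational nonlinearity must be penalised at the quadratic level as
well, otherwise none of the published rational-model values is
reproducible. Rounding to the conventional two decimals happens only at
reporting and is half-away-from-zero, so that exact values such as
163/343 ≈ 0.4752 print as 0.48 deterministically.

### Known edge case

For the 5D circadian model the published univariate values η(x₂⁵) = 0.08,
η(x₃⁵) = 0.02 and η(x₄⁵) = 0.09 are *not* reproduced by this
construction, which yields 0.18, 0.12 and 0.18. All three configurations
involve repeated, fully saturated all-`1̄̄` Lie rows, whose multiplicity
convention the published procedure does not pin down. The discrepancy is
documented rather than patched — every multivariate and every other
univariate benchmark value is reproduced exactly — and these three values
are excluded from the acceptance checks.

## Graph criteria and preselection

* σ_out^lin(i) counts rows j ≠ i with J̃_ji = 1. Zero means no other
  variable sees x_i linearly, so x_i is essential (must be measured).
* σ_in^nm(i) sums severity weights (1/2/3 for linear/polynomial/rational)
  of couplings J̃_ik received from the candidate non-measured set, which
  is the **full removable set before any pair is resolved** — the
  convention calibrated against the 9D walkthrough values (3, 3, 5, 5, 4).
* An exclusive pair {i, j} has J̃_ij = J̃_ji = 1 with both out-strengths
  exactly 1: the two variables are linearly seen only by each other, so
  one must be measured. The member with the larger σ_in^nm is removed;
  exact ties are not broken arbitrarily but enumerated as branches (the
  13D model's {x₁, x₈} tie is genuinely unresolved by the criteria).
* Every removed variable must appear in at least one measured variable's
  equation (reachability); a variable failing the check is retained. The
  check uses the pre-retention sensor set, which is conservative: it can
  only retain more, never remove more.

### Fixture discrepancies

The bundled 9D convection Jacobian is derived by differentiation of the
equations. A historically published symbol matrix for the same system
differs in six entries ((6,6), (7,6), (8,5), (8,6), (8,8), (9,5)); it is
exposed as `jacobian_variant="printed"` with the differences recorded in
the fixture metadata. The derived matrix is the default because the
published out-strength walkthrough (σ_out^lin(6) = 0) is consistent with
it only. Likewise σ_out^lin(9) computes to 2 on either variant (x₉ enters
the equations of both x₂ and x₄ linearly) although a published
walkthrough quotes 1; the definition is applied as stated.

## Search

Configurations are enumerated canonically (by m, then measured subset,
then coordinate composition); the count obeys Σ_m C(d, m)·C(d−1, m−1)
with default range m = 1 … d−1, excluding the trivial all-variables
measurement — the convention matching the published counts 125 and
24 309. Ranking is η descending, then fewer sensors, then the canonical
configuration string, so identical inputs give byte-identical outputs.
Large spaces are streamed lazily with optional progress logging and a
per-configuration callback rather than materialised. The reduced search
filters the stream to configurations containing every essential variable
and at least one member of each exclusive pair; tie branches are thereby
merged. The default reporting threshold η ≥ 0.75 is the conventional
"good observability" cutoff.

Problem sizes used in the bundled checks: the 5D exhaustive space (125
configurations), the m = 6 slice of the 9D space, the full 13 × 12
leave-one-out scan of the 13D model, and the m = 9 preselection-reduced
slice of the 13D space (990 configurations) — each a few seconds at most;
the full 5.2 × 10⁶-configuration 13D space is only counted, exactly as a
practitioner would before committing to the reduced search.

## Synthetic systems

The generator draws a symbol matrix with configurable off-diagonal
density and a mixture over the three nonzero classes; the diagonal is
always nonzero, mirroring the damping/decay terms every benchmark
equation carries. Defaults (density 0.3, equal mixture weights) keep the
matrices in the sparsity range of the bundled models. `realize_odes`
converts a symbol matrix into an actual rational vector field: linear
entries become c·x_j, polynomial entries c·x_j² (the squared form is
chosen over a cross-term c·x_j·x_k because a cross term's ∂/∂x_k would
inject a spurious polynomial coupling into column k and break the exact
round trip), rational entries c·x_j/(K + x_j), all with fresh positive
parameters. The central property — classification of the realised system
recovers the symbol matrix exactly, 200 seeded cases per test run —
exercises differentiation, cancellation and classification against known
ground truth.

What synthetic systems do **not** emulate: dynamical realism (stability,
attractors, conserved quantities), parameter magnitudes, or the block
structure of real reaction networks. Passing the round-trip suite
therefore validates the symbolic calculus, not any claim about the
dynamics of real models; the three bundled fixtures carry that weight.

## Limitations

* Reconstruction spaces larger than d (delay/Takens-style embeddings with
  2d + 1 coordinates) are out of scope.
* The coefficient is a structural summary: it cannot see parameter-value
  coincidences, e.g. two nonlinear terms cancelling numerically in the
  true determinant.
* The analytic (computer-algebra) determinant of the observability matrix
  is not computed; the symbolic summary replaces it by design.
* For repeated saturated univariate blocks the term-multiplicity
  convention affects η (see the known edge case above).
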