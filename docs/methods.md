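# Methods

This note documents the statistical model, the estimation and inference
machinery, the synthetic-data generator, and the numerical and design
choices behind `fslmm`.  It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Model and likelihoods

The linear mixed model is `Y = Xβ + Zb + ε` with `ε ~ N(0, σ²Iₙ)` and
`b ~ N(0, σ²D)`.  Random effects are organized by `r` crossed factors;
factor `k` groups `q_k` effects over `l_k` levels, contributing columns
`Z_(k) = [Z_(k,1) … Z_(k,l_k)]` to `Z` (within a factor, columns are
ordered by level and then by effect; `Z_(k,j)` is zero on every row not
assigned to level `j`).  The covariance is `D = ⊕ₖ (I_{l_k} ⊗ D_k)` with
one symmetric `q_k × q_k` block per factor; the residual covariance is
fixed at `σ²I` (no weighting or heteroscedasticity).

Log-likelihoods drop additive constants: reported values differ from
normalized log-densities by `n·log(2π)/2`-type terms, under both the ML
criterion

`l = −½(n log σ² + σ⁻²e'V⁻¹e + log|V|)`,  `V = I + ZDZ'`,  `e = Y − Xβ`,

and the restricted criterion `l_R = l + ½(p log σ² − log|X'V⁻¹X|)`.

## Product forms

All computation passes through `P=X'X, Q=X'Y, R=X'Z, S=Y'Y, T=Z'Y,
U=Z'Z`.  With one LU factorization of `A = I_q + DU` (where `D` is applied
blockwise, never materialized except as a `q×q` temporary for solves):

- `Z'V⁻¹Z = U A⁻¹` (using `A⁻¹DU = I − A⁻¹`), `X'V⁻¹Z = R A⁻¹`,
- `X'V⁻¹X = P − R·A⁻¹D·R'`, `Z'V⁻¹Y = T − U·A⁻¹D·T`, and the β-dependent
  contractions `Z'V⁻¹e`, `X'V⁻¹e`, `e'V⁻¹e` by substitution,
- `log|V| = log det(I_q + DU)` (matrix-determinant identity); the sign of
  the determinant is checked and a non-positive value raises a
  covariance-blow-up error that the optimizers treat as a failed step.

The single `q`-column solve (for `Z'V⁻¹Z`) is lazy, so likelihood-only
evaluations during step-halving cost one LU plus thin solves.  After the
product forms are built, nothing downstream allocates an `n`-sized object.

Per-level sums `Σⱼ Mⱼ ⊗ Mⱼ` in the information matrices are computed by
the block-vectorization identity: reshape the blocked matrix into rows of
`vec(block)'`, form one small cross-product, and permute
`vec(H̃'G̃)` with a cached index vector representing
`(I_{n₂} ⊗ K_{n₁,n₂} ⊗ I_{n₁})`.  Permutations are always stored as index
vectors and applied by gather.  Structural matrices (duplication,
elimination, commutation, symmetrizer) are dense 0/1 arrays cached per
dimension — the dimensions involved are `q_k`, which is small by the
model's design.

A note on the generalized vectorization operator: `vec_m` stacks the
`m`-column partitions of a matrix vertically, so `vec_1` coincides with
ordinary column-stacking `vec` and a single partition is the identity.
The cross-product identity used for sums `Σᵢ AᵢBᵢ'` of stacked
`(m₁ × m₂)` blocks is `vec_{m₁}(A')' vec_{m₁}(B')` — the partition width
is the block *row* count, which is the only dimensionally consistent
reading; the test suite pins it against a loop oracle.

## Scores and expected information

Closed forms (half representation; `Dup` the duplication matrix):

- `dl/dβ = σ⁻²X'V⁻¹e`, `dl/dσ² = −n/(2σ²) + e'V⁻¹e/(2σ⁴)`,
- `dl/dvech(D_k) = ½ Dup' vec(Σⱼ Z_(k,j)'V⁻¹(ee'/σ² − V)V⁻¹Z_(k,j))`,
  expanded so that `ee'` is never formed: the summand becomes
  `(Z'V⁻¹e)(Z'V⁻¹e)'/σ²` minus diagonal blocks of `Z'V⁻¹Z`.
- Information: `I_β = σ⁻²X'V⁻¹X`; β cross-blocks vanish exactly;
  `I_{σ²} = n/(2σ⁴)`;
  `I_{vech(D_{k₁}),vech(D_{k₂})} = ½ Dup'[Σᵢⱼ Bᵢⱼ⊗Bᵢⱼ]Dup` with
  `Bᵢⱼ = Z_(k₁,i)'V⁻¹Z_(k₂,j)`.

The full representation treats symmetric elements as distinct (partial
derivatives, no duplication matrices); its information is rank-deficient
by a symmetrizer factor, so updates use the invertible scoring-matrix
surrogate `F` (the same blocks without the symmetrizer), which is
algebraically equivalent to the Moore–Penrose-inverse update.  The
Cholesky representation chains through the Jacobian
`J = L(Λ'⊗I)(I+K)L'` (elimination matrix `L`, commutation `K`), stored so
that `dl/dvech(Λ) = J·dl/dvech(D)` and `I^c = J I^h J'`; `J` equals the
transposed numeric Jacobian of `vech(Λ) ↦ vech(ΛΛ')`.

ReML adds `½p/σ²` to the σ² score and
`½Dup'vec(Σⱼ Z_(k,j)'V⁻¹X(X'V⁻¹X)⁻¹X'V⁻¹Z_(k,j))` to each covariance
score.  The expected information is kept at its ML form *except* the σ²
diagonal, which becomes `(n−p)/(2σ⁴)` — the restricted likelihood's own
curvature, consistent with the adjusted score's stationarity point
`σ² = e'V⁻¹e/(n−p)`.  This choice makes the Satterthwaite machinery exact
in the no-random-effect limit (below); using the unadjusted `n/(2σ⁴)`
there would give `v = n` instead of `n − p`.

## The five fitting algorithms

Common scaffolding: OLS starting values `β₀ = (X'X)⁻¹X'Y`,
`σ₀² = e₀'e₀/n`, and a moment-style start for each `D_k` obtained by
substituting `V → I` in the full-representation update (a per-factor Gram
system in `U`'s diagonal blocks), then symmetrizing and projecting onto
the PSD cone; a singular Gram system falls back to `D_k = 0` with a
warning.  Each iteration proposes a step at unit step size and halves up
to 10 times if the criterion does not increase, accepting a zero step
with a warning otherwise (the step-size policy is a standard scoring
safeguard; the scalar step size itself is part of the update rule).
`D_k` is projected onto the PSD cone (eigenvalue clipping — the Frobenius
projection) after every accepted update, except under `csfs`, whose
Cholesky construction is PSD by definition.  Convergence is declared when
successive log-likelihoods differ by less than `tol` (default `1e-6`);
`max_iter` defaults to 200, far above the ≤ 40 iterations observed in the
benchmark harness.  Whether projection should occur every iteration or
only at convergence is not prescribed anywhere authoritative; every
iteration was chosen as the safer interpretation.

`fs`/`ffs` update all parameters jointly (β decouples because its
information cross-blocks are exactly zero).  `sfs`/`fsfs`/`csfs` first
apply the GLS updates `β ← (X'V⁻¹X)⁻¹X'V⁻¹Y`, `σ² ← e'V⁻¹e/n` (ML) or
`/(n−p)` (ReML), then one scoring step per factor, all factors sharing
one step-halving line search; after convergence one final GLS pass
refreshes `(β, σ²)` at the final covariance.  `csfs` starts from the
Cholesky factor of the projected initial `D_k`; rank-deficient starts are
re-triangularized via QR of the eigendecomposition square root, and
near-zero diagonal entries are nudged off the boundary (a zero diagonal
freezes its entire column — the gradient coordinate vanishes identically
there).  Singular information blocks anywhere trigger a pseudo-inverse
fallback (relative singular-value cutoff `1e-12`) with a warning.
σ² is floored at `1e-10` during evaluation and fits that touch the floor
are flagged.

## Constrained covariance and the ACE model

A constraint supplies, per factor, a reconstruction `vecu(D_k) ↦ D_k` and
Jacobian `C_k = ∂vec(D_k)/∂vecu(D_k)` (rows indexed by the free
parameters).  Scores and information map as `C_k·∂l/∂vec(D_k)` and
`C_{k₁}F C_{k₂}'`; because constrained reconstructions are symmetric, the
symmetrizer drops out and the scoring-matrix form can be used throughout.
Built-ins: `diagonal`, `compound_symmetry`, `identity_scaled`, the
vech-identity (which reduces exactly to the unconstrained half
representation), and explicit user matrices; AR(1)/Toeplitz structures
are expressible through the explicit form.  Shared mode drives all
factors from one parameter vector; the ACE twin model uses
`ρ = [τ_a, τ_c]'` with `D_k = τ_a²K^a_k + τ_c²K^c_k` and Jacobian
`(1_{(1,r)} ⊗ diag(2τ_a, 2τ_c))·⊕ₖ[vec(K^a_k)'; vec(K^c_k)']`.  Kinship
(`K^a`) and shared-environment (`K^c`) matrices are user inputs; the
package does not derive them from pedigrees.  Fitting alternates GLS and
constrained scoring with the same safeguards as `sfs`.  Constrained
reconstructions are *not* PSD-projected (each constraint defines its own
manifold; ACE is PSD whenever the K matrices are).  Initial constrained
parameters are extracted from the unconstrained moment start by least
squares; for ACE the squared τ values are floored at `1e-6` before the
square root.  Note that `τ = 0` is a stationary point of the
τ-parameterization (the score carries a factor `2τ`), so small-sample
fits can legitimately settle on the boundary when the data prefer it.

## Satterthwaite inference

For a `1×p` contrast `L`: `T = Lβ̂/√S²`, `S² = σ̂²L(X'V̂⁻¹X)⁻¹L'`,
`v = 2(S²)²/Var(S²)`, `Var(S²) ≈ g'I(η̂)⁻¹g` with
`η̂ = (σ̂², vech(D̂₁), …)`, `I(η̂)` the covariance sub-block of the expected
information (β rows excluded — exactly orthogonal), and the closed-form
gradient `dS²/dσ² = L(X'V̂⁻¹X)⁻¹L'`,
`dS²/dvech(D̂_k) = σ̂²Dup'Σⱼ B_(k,j)⊗B_(k,j)`,
`B_(k,j) = Z_(k,j)'V̂⁻¹X(X'V̂⁻¹X)⁻¹L'`.  Constrained fits map the gradient
through `C` and use the constrained information.  p-values are two-sided
with no multiplicity handling (single contrasts only; multi-row F-type
contrasts are a documented extension point).  `v < 1` is clamped to 1
with a warning.  With `D̂ = 0` and η restricted to σ² under ReML,
`v = n − p` exactly.

Inference uses whatever criterion the fit used, warning on ML: ML's
downward-biased variance estimates distort `S²`, and — because `v(η)` is
decreasing in the covariance blocks while ML shrinks them — the plug-in
dof at the ML estimate sits *above* the ReML-based value (the test suite
pins this ordering).  ReML is the recommended criterion for testing.

## Synthetic data generator

`generate_dataset` emulates a standard simulation design: first X column
and first per-factor random effect are intercepts; all other fixed and
random covariates i.i.d. standard normal; level assignment uniform at
random (redrawn — up to 100 times — if any level is empty, since an empty
level makes its covariance block unidentifiable); `b ~ N(0, σ²D)`,
`ε ~ N(0, σ²I)`.  Three preset designs, all `n = 1000`: `r=1, q=(2),
l=(50)`; `r=2, q=(3,2), l=(100,50)`; `r=3, q=(4,3,2), l=(100,50,10)`.

The generating truth defaults to documented stand-ins:
`β = (0.5, −0.3, 0.8, 0)` (the trailing zero provides the truly-null
effect that the degrees-of-freedom and type-I-error harnesses require),
`σ² = 1`, and fixed PSD blocks with a mixture of zero and nonzero
off-diagonals (`[[1,.5],[.5,.8]]` for q=2, a 3×3 with one correlated pair,
a 4×4 with a correlated chain).  These magnitudes give signal-to-noise
ratios typical of the designs the model targets; any other truth can be
passed explicitly.  What the generator does *not* emulate: unbalanced or
structured level assignment, non-Gaussian noise, missingness, or
covariate correlation — passing tests therefore demonstrate correctness
of the estimation machinery under the stated sampling model, not
robustness to real-data pathologies.

`generate_twin_dataset` builds ACE data: factors are family-structure
types, each family contributes one identity block to `Z`, and the
within-family covariance is `σ_e²(τ_a²K^a + τ_c²K^c)`.  The recovery
studies use two trio types (MZ pair + full sibling, DZ pair + full
sibling; kinship coefficients 1 and 0.5, shared environment all-ones)
with 55 families each (330 subjects), `τ_a = 0.8, τ_c = 0.5, σ_e² = 1` —
a small but realistic twin study in which the MZ/DZ contrast identifies
the additive component.  ACE fits cost `O(n³)` here because `Z = Iₙ`
makes `q = n`; this sets the replicate counts below.

Benchmark harnesses spawn one child RNG stream per replicate from a
parent `SeedSequence`, so all methods within a replicate see identical
data and streams are never reused.  MAE and MRD between a vector `a` and
reference `b` are `mean|aᵢ−bᵢ|` and `mean|aᵢ−bᵢ| / mean((|aᵢ|+|bᵢ|)/2)`,
computed separately for β and for the elements of the variance product
σ²D.  The degrees-of-freedom harness fixes one random design, redraws
`(b, ε)` per replicate, ReML-fits with `fsfs`, and forms a
moment-matching truth: per-replicate numerators `2(S²)²` averaged over an
empirical `Var(S²)` estimated from a separate larger run.

## Problem sizes in the shipped studies

Chosen so the whole suite runs in minutes on one CPU: cross-method
agreement on 50/50/25 replicates of the three presets (at a tightened
`1e-8` convergence tolerance, so estimates are compared at the optimum);
iteration-count means on 200/50 replicates (settings 1–2) at the standard
`1e-6` tolerance; degrees-of-freedom benchmark on 100 response replicates
with a 1000-replicate truth run (setting 1); lme4 cross-checks on four
exported datasets; ACE recovery on 200 replicates; type-I error on 1000
null replicates.  `scripts/acceptance.py` re-runs the same studies at
comparable sizes and writes every number it computes.

## Known limitations

- Dense `q × q` algebra: designs with very large `Σ q_k l_k` (including
  large ACE studies, where `q = n`) scale cubically; sparse methods are
  out of scope by design.
- Residual covariance is `σ²I`; no weighting, serial correlation or
  missing-data handling.
- Variance-component hypothesis tests (boundary problems) are not
  provided; the t-test covers fixed effects only, one contrast at a time.
- ML-based Satterthwaite dof are systematically larger than ReML-based
  ones (see above); use ReML for inference.
- The scoring iteration count of the simplified methods depends on the
  curvature of the likelihood around the truth, hence on the generating
  covariance values; reproduction of published per-method iteration means
  is exact only where the stand-in truth matches; the reproduction script
  reports every computed mean so the differences stay visible.
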