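# Methods

## Problem

Dynamic programs that fold RNA spend most of their time in the
interval-splitting recursion `W[i,j] = max_k (L[i,k] + L[k+1,j])`.
*Sparsification* prunes this loop: only split points whose left part is a
*candidate* — an interval whose optimal score strictly beats every split —
need be considered, and the pruning is lossless.  The practical value of the
technique therefore hinges on how rare candidates are.  This package
quantifies that rarity two ways and compares them:

1. **Combinatorially.**  A candidate interval carries an *irreducible*
   optimal sub-structure (one that no backbone cut separates without cutting
   an arc).  Under the ensemble assumption that a structure σ with ℓ arcs is
   the minimum-free-energy structure of a uniformly random sequence with
   probability proportional to W(σ) = (6/16)^ℓ η^{w(σ)}, the probability
   that an interval of length m is a candidate is
   P(m) = d\*(m)/d(m), the weighted fraction of irreducible structures.
   Generating functions give d and d\* exactly, singularity analysis gives
   their asymptotics, and the expected candidate fraction
   Ē(n) = Σ_m (n−m+1)P(m) / M(n), M(n) = n(n+1)/2, converges to a constant
   b = lim d\*(n)/d(n).
2. **Empirically.**  Sparsified folding of uniformly random sequences under
   the same simplified energy models, counting the candidate set |Q|
   directly.

Structures are *g-structures*: partial matchings on 1..n, minimum arc
length 2 (no arcs (i, i+1)), of fixed topological genus g.  Genus 0 is the
classical pseudoknot-free case; genus g ≥ 1 admits crossing arcs
(pseudoknots) in a controlled way.

## Models and parameters

**Arc-based (Nussinov-like).**  Every arc scores c (default 1); weight per
structure τ^ℓ with τ = (6/16)·η^c and η = e, so τ = (6/16)e ≈ 1.01936.
The factor 6/16 is the probability that two uniformly random bases can pair
(AU, UA, GC, CG, GU, UG — 6 of 16 ordered pairs).  τ is always computed
from this formula; no rounded decimal is hard-coded.  τ = 1 recovers
uniform counting, which is what the exact-arithmetic backend and all
enumeration cross-checks use.

**Loop-based (Zuker-like, simplified).**  A genus-0 structure decomposes
uniquely into loops; each loop scores by type only: hairpin +0.5, interior
+1 (stacks and bulges included; unpaired runs of any length, including
zero, on both sides), multiloop −5 (once per closing arc with ≥ 2 nested
branches).  Scores are maximized; weight per structure
(6/16)^ℓ e^{w(σ)}, w(σ) the sum of loop scores.

## Generating functions

* `matching_series` produces the genus-refined perfect-matching counts
  c_g(n) by the Harer–Zagier three-term recurrence
  (n+1)c_g(n) = 2(2n−1)c_g(n−1) + (2n−1)(n−1)(2n−3)c_{g−1}(n−2),
  validated against brute-force genus enumeration (boundary-component
  tracing) for n ≤ 5 arcs.
* `g_structure_series` builds D_{g,τ}(z) = C_g(v)/(τz²−z+1),
  v = τz²/(τz²−z+1)², by truncated-series reciprocal, product and
  composition — one audited code path rather than closed-form coefficient
  formulas.
* `irreducible_series` uses D\*_0 = 1 − 1/D_0 and, for g ≥ 1, the
  convolution recursion
  D\*_g = (D_g/D_0 − Σ_{g₁=1}^{g−1} D\*_{g₁} D_{g−g₁}) / D_0,
  which follows from F·D = 1 for the genus-bivariate series
  (structures are sequences of irreducible blocks; genus is additive).
  The sign of the Σ term matters: the composition identity
  (e.g. D\*_2 = D_2/D_0² − D_1²/D_0³) and exhaustive enumeration
  (d\*_2(8) = 20, d\*_2(9) = 140, d\*_2(10) = 844) both confirm the minus.
* The loop-model series F\*_0 solves the hairpin/interior/multiloop grammar

      F* = κ η^{0.5} z²·z s + κ η z² s² F* + κ η^{−5} z² s · G,
      G = (F*s)² + (F*s)·G,          s = 1/(1−z), κ = 6/16,

  coefficient-by-coefficient (every term carries z², so the recursion is
  well founded), and F_0 = s/(1 − F\*_0 s).  The same grammar, term for
  term, is what the loop-model DP implements, and the coefficients are
  cross-checked against explicit loop-decomposition scoring of enumerated
  structures (n ≤ 10, relative 1e−9).

## Singularity analysis and constants

* Arc model: γ_τ = 1/ρ_τ with ρ_τ the smallest positive root of
  τz² − (1+2√τ)z + 1 = 0; at τ = 1, γ = (3+√5)/2 ≈ 2.618.
* The limiting candidate probability is b_g = τ ρ_τ² for **every** genus g
  (at τ = 1: ρ² = (7−3√5)/2 ≈ 0.14590).  The genus-independence is a
  consequence of the singular expansions: D\*_g carries a (z²−z+1)
  prefactor where D_g carries 1/(z²−z+1), and the leading singular
  polynomials satisfy U_g(1/4) = P_g(1/4)/4, so the amplitude ratio is
  (ρ²−ρ+1)²/4 = ρ².  Because the subleading singular term of D\*_g decays
  only like n^{−1/2} relative to the leading one (for g ≥ 1), `b_constant`
  fits the tail of the ratio sequence against the basis
  {1, n^{−1/2}, n^{−1}, n^{−3/2}} (least squares over n ∈ [N/4, N],
  default N = 400) and requires two half-window fits to agree within 1e−3;
  a naive dyadic-ratio extrapolation does not converge at these orders.
* Loop model: the grammar clears to a quadratic
  a(z)F\*² + b(z)F\* + c(z) = 0; the dominant singularity ρ ≈ 0.46177 is
  the smallest positive root of its discriminant (branch point), computed
  from the polynomial (1−z)⁴(b²−4ac) and cross-checked against the
  coefficient ratio f\*(n+1)/f\*(n) at n ≈ 2000 (relative 1e−3).
  Amplitudes α (for f\*) and β (for f) are extrapolated from
  f(n)·n^{3/2}·ρⁿ at dyadic checkpoints N/4, N/2, N with Aitken Δ²
  acceleration, N = 2048, computing the coefficients in the rescaled
  variable z = ρy to avoid overflow.  The subexponential exponent −3/2 is
  fixed by the square-root branch point.

### Known discrepancies

The reference values sometimes attached to this simplified loop model —
α ≈ 0.24, β ≈ 2.88, b = α/β ≈ 0.08 — are **not** what its functional
equation yields.  Three independent routes in this package agree with each
other and not with those values: (a) the coefficient recursion plus
rescaled extrapolation gives α ≈ 0.1683 and β ≈ 78.6; (b) the analytic
singular expansion at the branch point (F\*(ρ) = −b/2a ≈ 0.492,
amplitude √(−Δ'(ρ)ρ)/(2a)/(2√π)) gives α ≈ 0.1686 and
β = α·s(ρ)²/(1−F\*(ρ)s(ρ))² ≈ 78.7; (c) the low-order coefficients match
exhaustive enumeration exactly, pinning the model itself.  The large β
arises because F\*(ρ)·s(ρ) ≈ 0.914 sits close to the sequence-construction
pole.  A scan over plausible alternative model readings (κ placement,
hairpin minimum size, energy-sign conventions, η = 2) reproduces the
reference triple under none of them.  The package therefore reports its
own honestly computed constants; the corresponding acceptance tests, which
assert the reference values at 2-decimal precision, fail by design.
Note that the implied qualitative conclusion — a large constant reduction —
only strengthens: 100(1−b) ≈ 99.8% under this model's own constants.

Similarly, the experimental reduction for the arc model normalized by
M(n) = n(n+1)/2 is ≈ 92.3% at n = 300 (slowly rising to ≈ 93% at
n = 800); the often-quoted 96% is recovered exactly when |Q| is divided by
n² (the full DP table rather than its upper triangle).  The package keeps
the M(n) normalization, which is the one the theory uses.

## Dynamic programs

Both folds fill L over intervals by increasing length; W iterates, per left
endpoint i, over the recorded candidate right ends (the sparsification data
structure being quantified), or over all k when `sparse=False`.
An interval enters Q iff its paired-closure score strictly exceeds W
(ties are not candidates); singletons are vacuous candidates and are
counted in Q, consistently with M(n) counting m = 1 intervals.  The loop
DP keeps auxiliary tables M1 (best single branch), B1/B2 (best branch
chains, ≥ 1 / ≥ 2 branches) so interior and multiloop cases cost O(n³)
overall.  Backtracking is deterministic: the lexicographically first
optimal split, else the closing arc; all default loop scores are dyadic,
so float equality in backtracking is exact.  The backtracked structure's
score is re-verified against the table optimum in tests.

## Synthetic sequences

`random_rna` draws i.i.d. uniform bases via numpy's PCG64 from
`SeedSequence((seed, sequence_index))`, making every experiment
bit-reproducible from (seed, lengths, num_seqs).  Uniform sequences are the
study condition for all reported experiments (they realize the 6/16
pairing probability exactly in expectation).  They do **not** model real
transcriptomes: no composition bias, no correlated neighborhoods, no
selection for stable structures, and the simplified energy models ignore
stacking identity, loop-length penalties and dangles.  Passing experiments
therefore validate the combinatorial framework under its own assumptions,
not folding accuracy on biological sequences.

## Problem sizes

Defaults were chosen so every computation is exact or comfortably converged
at desk scale: truncation order 120 (exact backend) / 400 (float),
amplitude extrapolation at order 2048, enumeration cross-checks at n ≤ 12
(64 351 structures at n = 12), DP equivalence checks at lengths ≤ 60, and
the folding experiment at 100 sequences of length 300 (standard error
< 10% of the mean).

## Limitations

* Genus ≥ 1 folding is available only through the exhaustive small-n
  oracle (g_max = 1); no polynomial-time pseudoknot DP is included.
* The loop grammar is the simplified three-weight model; no
  nearest-neighbor parameter set, no temperature dependence.
* `claim_identity_check` covers g ≤ 3; closed forms U_g, V_g are not
  constructed symbolically — all asymptotic constants are numerical.
* Partition-function (Boltzmann ensemble) quantities are out of scope:
  sparsification as analyzed here applies to optimization, not summation.
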