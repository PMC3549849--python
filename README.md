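# rnasparse

Combinatorics of candidate-list **sparsification** for RNA secondary- and
pseudoknot-structure folding.

Folding DPs spend their time splitting intervals:
`W[i,j] = max_k (L[i,k] + L[k+1,j])`.  Sparsification restricts the split
points to *candidates* — intervals whose optimal score strictly beats every
split — without changing the optimum.  How much that buys depends on how
rare candidates are.  This package answers that question for structures of
fixed topological genus g (g = 0 is the classical pseudoknot-free case)
under two simplified energy models, from two directions:

* **Theory** — truncated-power-series machinery for the genus-filtered
  generating functions D_{g,τ}(z) of structures and D\*_{g,τ}(z) of
  *irreducible* structures (those no backbone cut separates), built from
  the Harer–Zagier matching counts; an interval of length m hosts a
  candidate with probability P_g(m) = d\*_g(m)/d_g(m), so the expected
  candidate fraction is Ē_g(n) = Σ_m (n−m+1)P_g(m) / M(n) with
  M(n) = n(n+1)/2, converging to b_g = lim d\*_g(n)/d_g(n).
  For the loop-based model the analogous pair (F_0, F\*_0) solves a
  hairpin/interior/multiloop grammar and a quadratic singularity analysis
  yields growth rate γ = 1/ρ and amplitudes α, β.
* **Experiment** — sparsified Nussinov-like and Zuker-like DPs over seeded
  uniform random sequences, tracking the candidate set Q exactly, plus
  exhaustive enumeration oracles (all structures with genus and
  irreducibility at n ≤ 16, brute-force folding at n ≤ 14) that pin every
  series coefficient and every DP table at small n.

See `docs/methods.md` for the model definitions, the singularity analysis,
numerical choices, and a frank account of which reference constants the
model's own equations do and do not reproduce.

## Worked example

```python
>>> import rnasparse as rs
>>> seq = rs.random_rna(40, 7)                     # seeded uniform ACGU
>>> res = rs.fold(seq, rs.LoopEnergyModel())       # sparsified loop-model DP
>>> seq
'UGGUGUUAACCUUACUAUACUCCCGCUCCGGGGUUUGGCU'
>>> res.structure.to_dot_bracket()
'.((((((((..)))..))))).(((.)..))((((.))))'
>>> res.mfe, len(res.candidates), rs.expected_candidate_entries(40)
(13.5, 134, 820)
```

The fold maximizes the simplified loop score (hairpin +0.5, interior +1,
multiloop −5): this structure realizes 13.5.  Of the 820 intervals the
split rule would examine, only 134 (16%) are candidates — and the fraction
keeps falling with length:

```python
>>> stats = rs.candidate_experiment([300], num_seqs=100, seed=1,
...                                 model=rs.ArcEnergyModel())
>>> round(stats.normalized[0], 4), round(stats.reduction_percent(), 1)
(0.079, 92.1)
```

i.e. folding 100 random length-300 sequences under the arc model, 92.1% of
the split-rule entries are pruned.  The theory side predicts the limiting
candidate fraction from the series alone:

```python
>>> rs.b_constant(0, rs.ArcEnergyModel().tau).ratio_limit
0.1471410610082603
```

— the closed form is τρ_τ² (≈ 0.1459 at τ = 1), independent of the genus.

A CLI mirrors the library: `rnasparse gf-arc`, `gf-loop`, `enum`, `fold`,
`experiment`, `report` (CSV/JSON out, logging to stderr; see
`rnasparse --help`).

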