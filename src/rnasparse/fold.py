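"""Sparsified dynamic-programming folding with candidate-set tracking.

The decomposition rule quantified here splits an interval [i, j] into two
subsequent intervals [i, k], [k+1, j].  An interval is a *candidate* when
its optimal score strictly beats every such split; the sparsified recursion
only iterates over splits whose left part is a recorded candidate — a
lossless pruning, because a non-candidate left part can itself be split and
re-associated.  The size of the candidate set Q relative to the number of
intervals M(n) = n(n+1)/2 is the quantity the combinatorial theory predicts.

Two energy models are implemented:

* arc-based (Nussinov-like): each compatible arc scores ``c`` (default 1),
  minimum arc length 2, no other constraint;
* simplified loop-based (Zuker-like): hairpin +0.5, interior loop +1
  (unbounded unpaired runs on both sides, zero allowed — stacks), multiloop
  -5 once per closing arc with >= 2 nested branches.  Scores are maximized.

Both DPs can be run unsparsified (identical tables, used in tests).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence, Union

import numpy as np

from .enumeration import COMPATIBLE_PAIRS, Structure
from .genus import ArcEnergyModel, expected_candidate_entries
from .loops import LoopEnergyModel

EnergyModel = Union[ArcEnergyModel, LoopEnergyModel]

NEG = float("-inf")

BASES = "ACGU"


def random_rna(n: int, seed) -> str:
    """Uniform i.i.d. sequence over {A, C, G, U}; deterministic given seed.

    ``seed`` may be an int or a tuple (experiment seed, sequence index) —
    the documented child-seed scheme used by :func:`candidate_experiment`.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    return "".join(BASES[k] for k in rng.integers(0, 4, size=n))


@dataclass
class FoldResult:
    """Tables and candidate set of one folding run (1-based intervals)."""

    n: int
    L: np.ndarray                      # optimal score over [i, j]
    V: np.ndarray                      # score with (i, j) paired (-inf else)
    candidates: set                    # Q: intervals (i, j), singletons incl.
    mfe: float
    structure: Structure

    @property
    def normalized_candidates(self) -> float:
        return len(self.candidates) / expected_candidate_entries(self.n)


def _compat_matrix(seq: str) -> np.ndarray:
    n = len(seq)
    mat = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 2, n):
            mat[i, j] = (seq[i], seq[j]) in COMPATIBLE_PAIRS
    return mat


def _check_sequence(seq: str) -> str:
    seq = seq.upper().replace("T", "U")
    if not seq or any(b not in BASES for b in seq):
        raise ValueError("sequence must be a nonempty string over A, C, G, U")
    return seq


# ---------------------------------------------------------------------------
# arc-based model
# ---------------------------------------------------------------------------
def fold_arc_sparse(seq: str, model: ArcEnergyModel | None = None,
                    sparse: bool = True) -> FoldResult:
    """Maximum arc-score folding with candidate tracking.

    V[i,j] = L[i+1,j-1] + c for a compatible pair (j - i >= 2), W[i,j] the
    best split; L = max(V, W); (i, j) enters Q iff V > W (singletons are
    vacuous candidates).  ``sparse=False`` runs the full split loop instead
    of the candidate list; the tables are identical either way.
    """
    seq = _check_sequence(seq)
    model = model or ArcEnergyModel()
    n = len(seq)
    compat = _compat_matrix(seq)
    c = model.c
    L = np.zeros((n, n))
    V = np.full((n, n), NEG)
    Q = set()
    cand_left = [[] for _ in range(n)]   # k-lists: [i, k] is a candidate
    for i in range(n):
        Q.add((i + 1, i + 1))
        cand_left[i].append(i)
    for span in range(2, n + 1):
        for i in range(0, n - span + 1):
            j = i + span - 1
            v = NEG
            if compat[i, j]:
                inner = L[i + 1, j - 1] if j - 1 >= i + 1 else 0.0
                v = inner + c
            V[i, j] = v
            w = NEG
            if sparse:
                for k in cand_left[i]:
                    if k >= j:
                        break
                    cur = L[i, k] + L[k + 1, j]
                    if cur > w:
                        w = cur
            else:
                for k in range(i, j):
                    cur = L[i, k] + L[k + 1, j]
                    if cur > w:
                        w = cur
            if v > w:
                L[i, j] = v
                Q.add((i + 1, j + 1))
                cand_left[i].append(j)
            else:
                L[i, j] = w
    arcs = _backtrack_arc(L, V, compat, n)
    structure = Structure(n, arcs)
    return FoldResult(n=n, L=L, V=V, candidates=Q, mfe=float(L[0, n - 1]),
                      structure=structure)


def _backtrack_arc(L, V, compat, n) -> list[tuple[int, int]]:
    """Deterministic backtrack: the lexicographically first optimal split is
    taken when one attains the score; otherwise the interval is a candidate
    and its closing arc is taken.  All model scores are dyadic, so float
    equality is exact."""
    arcs = []
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j:
            continue
        for k in range(i, j):
            if L[i, j] == L[i, k] + L[k + 1, j]:
                stack.append((i, k))
                stack.append((k + 1, j))
                break
        else:
            # no split attains L, hence L = V: close the arc
            arcs.append((i + 1, j + 1))
            if j - 1 >= i + 1:
                stack.append((i + 1, j - 1))
    return arcs


# ---------------------------------------------------------------------------
# loop-based model
# ---------------------------------------------------------------------------
def fold_loop_sparse(seq: str, model: LoopEnergyModel | None = None,
                     sparse: bool = True) -> FoldResult:
    """Zuker-style maximum-score folding under the simplified loop model.

    States (0-based, inclusive):
      V[i,j]   best score with (i, j) paired: max of hairpin (all inner
               unpaired), interior (one branch, any unpaired runs, +w_int),
               multiloop (>= 2 branches, +w_multi once);
      M1[i,j]  best single branch V[p,q] with [p,q] within [i,j];
      B1[i,j]  best sum over >= 1 disjoint branches within [i,j];
      B2[i,j]  best sum over >= 2 disjoint branches within [i,j];
      L[i,j]   optimal score; split loop sparsified over candidate lists.
    """
    seq = _check_sequence(seq)
    model = model or LoopEnergyModel()
    n = len(seq)
    compat = _compat_matrix(seq)
    wh, wi, wm = model.w_hairpin, model.w_interior, model.w_multi
    V = np.full((n, n), NEG)
    M1 = np.full((n, n), NEG)
    B1 = np.full((n, n), NEG)
    B2 = np.full((n, n), NEG)
    L = np.zeros((n, n))
    Q = set()
    cand_left = [[] for _ in range(n)]
    for i in range(n):
        Q.add((i + 1, i + 1))
        cand_left[i].append(i)
    for span in range(1, n + 1):
        for i in range(0, n - span + 1):
            j = i + span - 1
            if span == 1:
                M1[i, j] = NEG
                B1[i, j] = NEG
                B2[i, j] = NEG
                continue
            # --- V ---
            v = NEG
            if span >= 3 and compat[i, j]:
                v = wh                                    # hairpin
                if j - 1 >= i + 1:
                    m1_in = M1[i + 1, j - 1]
                    if m1_in > NEG:
                        v = max(v, wi + m1_in)            # interior
                    b2_in = B2[i + 1, j - 1]
                    if b2_in > NEG:
                        v = max(v, wm + b2_in)            # multiloop
            V[i, j] = v
            # --- M1 ---
            m1 = max(M1[i + 1, j] if i + 1 <= j else NEG,
                     M1[i, j - 1] if i <= j - 1 else NEG,
                     v)
            M1[i, j] = m1
            # --- B1 / B2: last branch ends at j, or j unpaired ---
            b1 = B1[i, j - 1] if i <= j - 1 else NEG
            b2 = B2[i, j - 1] if i <= j - 1 else NEG
            # branch (p, j), prefix [i, p-1] holds 0/>=1 branches
            ps = np.arange(i, j - 1)                      # p <= j - 2
            if ps.size:
                vcol = V[ps, j]
                ok = vcol > NEG
                if ok.any():
                    prefix0 = np.zeros(ps.size)           # empty prefix
                    prefix1 = np.full(ps.size, NEG)
                    if ps.size > 1:
                        prefix1[1:] = B1[i, ps[1:] - 1]
                    best_any = np.maximum(prefix0, prefix1)
                    b1 = max(b1, np.max(np.where(ok, vcol + best_any, NEG)))
                    with np.errstate(invalid="ignore"):
                        cand2 = np.where(ok & (prefix1 > NEG),
                                         vcol + prefix1, NEG)
                    if cand2.size:
                        b2 = max(b2, float(np.max(cand2)))
            B1[i, j] = b1
            B2[i, j] = b2
            # --- L ---
            w = NEG
            if sparse:
                for k in cand_left[i]:
                    if k >= j:
                        break
                    cur = L[i, k] + L[k + 1, j]
                    if cur > w:
                        w = cur
            else:
                for k in range(i, j):
                    cur = L[i, k] + L[k + 1, j]
                    if cur > w:
                        w = cur
            if v > w:
                L[i, j] = v
                Q.add((i + 1, j + 1))
                cand_left[i].append(j)
            else:
                L[i, j] = w
    arcs = _backtrack_loop(model, L, V, M1, B1, B2, n)
    structure = Structure(n, arcs)
    return FoldResult(n=n, L=L, V=V, candidates=Q, mfe=float(L[0, n - 1]),
                      structure=structure)


def _backtrack_loop(model, L, V, M1, B1, B2, n) -> list[tuple[int, int]]:
    """Recover one optimal structure; deterministic first-match order.
    All scores are sums of dyadic loop weights, so float equality is exact
    for the default model."""
    wh, wi, wm = model.w_hairpin, model.w_interior, model.w_multi
    arcs: list[tuple[int, int]] = []
    stack: list[tuple[str, int, int]] = [("L", 0, n - 1)]
    while stack:
        state, i, j = stack.pop()
        if i > j:
            continue
        if state == "L":
            if i == j:
                continue
            split = False
            for k in range(i, j):
                if L[i, j] == L[i, k] + L[k + 1, j]:
                    stack.append(("L", i, k))
                    stack.append(("L", k + 1, j))
                    split = True
                    break
            if not split:
                stack.append(("V", i, j))
        elif state == "V":
            arcs.append((i + 1, j + 1))
            if V[i, j] == wh:
                continue
            if j - 1 >= i + 1 and V[i, j] == wi + M1[i + 1, j - 1]:
                stack.append(("M1", i + 1, j - 1))
                continue
            stack.append(("B2", i + 1, j - 1))
        elif state == "M1":
            if i + 1 <= j and M1[i, j] == M1[i + 1, j]:
                stack.append(("M1", i + 1, j))
            elif i <= j - 1 and M1[i, j] == M1[i, j - 1]:
                stack.append(("M1", i, j - 1))
            else:
                stack.append(("V", i, j))
        elif state == "B1":
            if i <= j - 1 and B1[i, j] == B1[i, j - 1]:
                stack.append(("B1", i, j - 1))
                continue
            for p in range(i, j - 1):
                if V[p, j] == NEG:
                    continue
                if B1[i, j] == V[p, j]:
                    stack.append(("V", p, j))
                    break
                if p >= i + 1 and B1[i, p - 1] > NEG and \
                        B1[i, j] == V[p, j] + B1[i, p - 1]:
                    stack.append(("V", p, j))
                    stack.append(("B1", i, p - 1))
                    break
        elif state == "B2":
            if i <= j - 1 and B2[i, j] == B2[i, j - 1]:
                stack.append(("B2", i, j - 1))
                continue
            for p in range(i + 1, j - 1):
                if V[p, j] == NEG or B1[i, p - 1] == NEG:
                    continue
                if B2[i, j] == V[p, j] + B1[i, p - 1]:
                    stack.append(("V", p, j))
                    stack.append(("B1", i, p - 1))
                    break
    return arcs


def fold(seq: str, model: EnergyModel | None = None,
         sparse: bool = True) -> FoldResult:
    """Dispatch on the model type (arc-based by default)."""
    if model is None or isinstance(model, ArcEnergyModel):
        return fold_arc_sparse(seq, model, sparse=sparse)
    return fold_loop_sparse(seq, model, sparse=sparse)


# ---------------------------------------------------------------------------
# Monte-Carlo candidate experiment
# ---------------------------------------------------------------------------
@dataclass
class CandidateStats:
    """Mean candidate-set sizes over random sequences, per length."""

    lengths: list[int]
    mean_candidates: list[float]
    normalized: list[float]
    stderr: list[float]
    per_m_counts: dict
    num_seqs: int
    seed: int
    model: str

    def reduction_percent(self, idx: int = -1) -> float:
        """100 (1 - mean|Q|/M(n)) for the idx-th length."""
        return 100.0 * (1.0 - self.normalized[idx])


def candidate_experiment(lengths: Sequence[int], num_seqs: int, seed: int,
                         model: EnergyModel | None = None) -> CandidateStats:
    """Fold ``num_seqs`` uniform random sequences at each length and record
    mean |Q| and mean |Q|/M(n).  Child seeds are (seed, global sequence
    index), making every run bit-reproducible."""
    if num_seqs < 1:
        raise ValueError("num_seqs must be >= 1")
    model = model or ArcEnergyModel()
    means, norms, errs = [], [], []
    per_m: dict[int, np.ndarray] = {}
    idx = 0
    for n in lengths:
        counts = np.zeros(num_seqs)
        m_hist = np.zeros(n + 1)
        for r in range(num_seqs):
            seq = random_rna(n, (seed, idx))
            idx += 1
            res = fold(seq, model)
            counts[r] = len(res.candidates)
            for (a, b) in res.candidates:
                m_hist[b - a + 1] += 1
        M = expected_candidate_entries(n)
        means.append(float(counts.mean()))
        norms.append(float(counts.mean() / M))
        errs.append(float(counts.std(ddof=1) / math.sqrt(num_seqs) / M
                          if num_seqs > 1 else 0.0))
        per_m[n] = m_hist / num_seqs
    name = "arc" if isinstance(model, ArcEnergyModel) else "loop"
    return CandidateStats(lengths=list(lengths), mean_candidates=means,
                          normalized=norms, stderr=errs, per_m_counts=per_m,
                          num_seqs=num_seqs, seed=seed, model=name)
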