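"""Exhaustive enumeration of diagrams with genus and irreducibility.

This module is the package's ground truth at small n: every generating
function and every dynamic program is validated against direct enumeration
of structures (partial matchings on 1..n, 1-based, arc length >= 2), with

* genus computed by boundary-component tracing of the chord diagram's
  fatgraph (chi = v - e + r, g = 1 - chi/2, which reduces to
  g = (ell + 1 - r)/2 for a matching with ell arcs and r boundary cycles);
* irreducibility: a structure is irreducible iff no backbone cut point
  leaves every arc entirely on one side (the single vertex is irreducible);
* Assumption-1 weighting W(sigma) = kappa^ell * eta^{w(sigma)} and the
  induced probability distribution, for both energy models;
* a brute-force folding oracle that scores every interval of a sequence by
  exhaustive search and extracts the candidate set by definition (the
  optimal score strictly beats every split).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Iterator, Sequence, Union

from .genus import ArcEnergyModel
from .loops import LoopEnergyModel

EnergyModel = Union[ArcEnergyModel, LoopEnergyModel]

MAX_ENUM_VERTICES = 16
MAX_BRUTE_FORCE_LENGTH = 14

#: ordered base pairs that may form an arc (Watson-Crick + wobble): 6 of 16
COMPATIBLE_PAIRS = frozenset(
    {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")})


@dataclass(frozen=True)
class Structure:
    """A diagram over vertices 1..n: disjoint arcs (i, j), j - i >= 2."""

    n: int
    arcs: tuple[tuple[int, int], ...]

    def __post_init__(self):
        object.__setattr__(self, "arcs", tuple(sorted(self.arcs)))
        seen = set()
        for i, j in self.arcs:
            if not (1 <= i < j <= self.n):
                raise ValueError(f"arc ({i},{j}) outside 1..{self.n}")
            if j - i < 2:
                raise ValueError(f"1-arc ({i},{j}) not allowed")
            if i in seen or j in seen:
                raise ValueError("vertex in more than one arc")
            seen.update((i, j))

    @property
    def ell(self) -> int:
        return len(self.arcs)

    @property
    def genus(self) -> int:
        return diagram_genus(self)

    @property
    def irreducible(self) -> bool:
        return is_irreducible(self)

    # -- notation ------------------------------------------------------
    def to_dot_bracket(self) -> str:
        """Dot-bracket string; crossing arcs (genus >= 1) use the extended
        families ()[]{}<>, assigned greedily."""
        families = "()[]{}<>"
        out = ["."] * self.n
        assignment = {}
        for i, j in sorted(self.arcs):
            for fam in range(4):
                if all(not (oi < i < oj < j) for oi, oj in assignment
                       if assignment[(oi, oj)] == fam):
                    assignment[(i, j)] = fam
                    break
            else:
                raise ValueError("structure needs more than 4 bracket families")
        for (i, j), fam in assignment.items():
            out[i - 1] = families[2 * fam]
            out[j - 1] = families[2 * fam + 1]
        return "".join(out)


def diagram_genus(s: Structure) -> int:
    """Genus by boundary tracing of the induced chord diagram (isolated
    vertices deleted; genus is insensitive to them)."""
    if not s.arcs:
        return 0
    points = sorted(p for arc in s.arcs for p in arc)
    index = {p: k for k, p in enumerate(points)}
    m = len(points)
    partner = [0] * m
    for i, j in s.arcs:
        partner[index[i]] = index[j]
        partner[index[j]] = index[i]
    seen = [False] * m
    r = 0
    for start in range(m):
        if seen[start]:
            continue
        r += 1
        x = start
        while not seen[x]:
            seen[x] = True
            x = (partner[x] + 1) % m
    ell = len(s.arcs)
    g2 = ell + 1 - r
    assert g2 % 2 == 0 and g2 >= 0
    return g2 // 2


def is_irreducible(s: Structure) -> bool:
    """True iff no backbone cut 1 <= k < n leaves all arcs on one side."""
    if s.n == 1:
        return True
    for k in range(1, s.n):
        if not any(i <= k < j for i, j in s.arcs):
            return False
    return True


# ---------------------------------------------------------------------------
# enumeration
# ---------------------------------------------------------------------------
def _matchings_over(points: tuple[int, ...],
                    allowed=None) -> Iterator[tuple[tuple[int, int], ...]]:
    """Perfect matchings of ``points`` with arc length >= 2 (first point
    always paired), optionally restricted to ``allowed`` pairs."""
    if not points:
        yield ()
        return
    i = points[0]
    rest = points[1:]
    for j in rest:
        if j - i < 2:
            continue
        if allowed is not None and (i, j) not in allowed:
            continue
        sub = tuple(p for p in rest if p != j)
        for tail in _matchings_over(sub, allowed):
            yield ((i, j),) + tail


def enumerate_structures(n: int, g_max: int | None = None,
                         allowed=None) -> list[Structure]:
    """All structures on n vertices with genus <= g_max, in deterministic
    lexicographic order (by paired-vertex subset, then arcs)."""
    if n > MAX_ENUM_VERTICES:
        raise ValueError(
            f"n={n} exceeds the enumeration guard ({MAX_ENUM_VERTICES})")
    out = []
    verts = tuple(range(1, n + 1))
    for k in range(0, n // 2 + 1):
        for subset in itertools.combinations(verts, 2 * k):
            for arcs in _matchings_over(subset, allowed):
                s = Structure(n, arcs)
                if g_max is None or diagram_genus(s) <= g_max:
                    out.append(s)
    return out


# ---------------------------------------------------------------------------
# loop decomposition and Assumption-1 weighting
# ---------------------------------------------------------------------------
def loop_decomposition(s: Structure) -> list[str]:
    """Loop types closed by each arc of a genus-0 structure: 'hairpin' (no
    nested branch), 'interior' (one branch, incl. stacks/bulges), 'multi'
    (>= 2 branches)."""
    if diagram_genus(s) != 0:
        raise ValueError("loop decomposition requires a genus-0 structure")
    kinds = []
    for i, j in s.arcs:
        children = 0
        inner = sorted(a for a in s.arcs if i < a[0] and a[1] < j)
        # count maximal arcs strictly inside (i, j)
        reach = i
        for a, b in inner:
            if a > reach:
                children += 1
                reach = b
        kinds.append("hairpin" if children == 0
                     else "interior" if children == 1 else "multi")
    return kinds


def structure_energy(s: Structure, model: LoopEnergyModel) -> float:
    """w(sigma) = sum over loops of w(loop type)."""
    w = {"hairpin": model.w_hairpin, "interior": model.w_interior,
         "multi": model.w_multi}
    return sum(w[k] for k in loop_decomposition(s))


def structure_weight(s: Structure, model: EnergyModel):
    """Assumption-1 weight W(sigma) = kappa^ell * eta^{w(sigma)}."""
    if isinstance(model, ArcEnergyModel):
        return model.tau ** s.ell
    return float(model.kappa) ** s.ell * model.eta ** structure_energy(s, model)


@dataclass
class WeightedEnsemble:
    structures: list[Structure]
    weights: list[float]
    probabilities: list[float] = field(default_factory=list)

    def __post_init__(self):
        total = sum(self.weights)
        if not self.probabilities:
            self.probabilities = [w / total for w in self.weights]


def assumption1_distribution(structures: Sequence[Structure],
                             model: EnergyModel) -> WeightedEnsemble:
    """P(sigma) = W(sigma) / sum W(sigma'), the model's stand-in for which
    structure is the minimum-free-energy structure of a random sequence."""
    structures = list(structures)
    if not structures:
        raise ValueError("empty ensemble")
    weights = [structure_weight(s, model) for s in structures]
    return WeightedEnsemble(structures, weights)


# ---------------------------------------------------------------------------
# brute-force folding oracle
# ---------------------------------------------------------------------------
def _score(s: Structure, model: EnergyModel) -> float:
    if isinstance(model, ArcEnergyModel):
        return model.c * s.ell
    return structure_energy(s, model)


def _compatible_arcs(seq: str) -> set[tuple[int, int]]:
    n = len(seq)
    return {(i, j) for i in range(1, n + 1) for j in range(i + 2, n + 1)
            if (seq[i - 1], seq[j - 1]) in COMPATIBLE_PAIRS}


def brute_force_fold(seq: str, model: EnergyModel,
                     g_max: int = 0) -> tuple[float, set[tuple[int, int]]]:
    """Score every interval [i, j] (1-based, inclusive) of ``seq`` by
    exhaustive enumeration of sequence-compatible structures of genus
    <= g_max, and return (mfe over the full sequence, candidate set).

    An interval is a candidate iff its optimal score strictly exceeds every
    split L[i,k] + L[k+1,j]; single positions are vacuously candidates.
    """
    seq = seq.upper()
    n = len(seq)
    if n > MAX_BRUTE_FORCE_LENGTH:
        raise ValueError(f"sequence longer than {MAX_BRUTE_FORCE_LENGTH}")
    if any(b not in "ACGU" for b in seq):
        raise ValueError("sequence must be over A, C, G, U")
    allowed = _compatible_arcs(seq)
    L = {}
    for i in range(1, n + 1):
        L[(i, i)] = 0.0
    for m in range(2, n + 1):
        for i in range(1, n - m + 2):
            j = i + m - 1
            best = 0.0
            verts = tuple(range(i, j + 1))
            for k in range(1, m // 2 + 1):
                for subset in itertools.combinations(verts, 2 * k):
                    for arcs in _matchings_over(subset, allowed):
                        s = Structure(n, arcs)
                        if diagram_genus(s) <= g_max:
                            best = max(best, _score(s, model))
            L[(i, j)] = best
    candidates = {(i, i) for i in range(1, n + 1)}
    for m in range(2, n + 1):
        for i in range(1, n - m + 2):
            j = i + m - 1
            best_split = max(L[(i, k)] + L[(k + 1, j)] for k in range(i, j))
            if L[(i, j)] > best_split:
                candidates.add((i, j))
    return L[(1, n)] if n else 0.0, candidates


# ---------------------------------------------------------------------------
# FASTA input
# ---------------------------------------------------------------------------
def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """(id, sequence) records; T is transcribed to U."""
    from Bio import SeqIO

    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append((rec.id, str(rec.seq).upper().replace("T", "U")))
    return records
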