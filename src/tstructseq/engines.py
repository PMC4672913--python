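"""Folding engines behind a common interface.

Two engines are provided:

* :class:`BuiltinEngine` — a self-contained Zuker-style minimum-free-energy
  dynamic program over the nearest-neighbor parameters embedded in
  :mod:`tstructseq.params`. It implements the chemical-modification
  constraint exactly: a flagged nucleotide may not occupy a Watson-Crick
  pair flanked on both sides by Watson-Crick pairs. Integer energies make
  it bit-reproducible and directly comparable to exhaustive enumeration.

* :class:`ViennaEngine` — an adapter over the ViennaRNA (RNAfold) Turner-model
  bindings, used for thermodynamic scans and unconstrained folding / energy
  evaluation at 37 degC. ViennaRNA's constraint language cannot express the
  flanked-pair modification rule, so this adapter refuses non-empty
  modification constraint sets rather than silently approximating them.

Exhaustive enumeration over all nested structures (`enumerate_structures`,
`exhaustive_mfe`) is included as an independent reference for short
sequences; it shares only the loop-wise evaluator with the DP engine.
"""

from __future__ import annotations

from typing import Iterable, Iterator, Protocol

import numpy as np

from . import params
from .params import (
    INF,
    MIN_HAIRPIN,
    MULTI_BRANCH,
    MULTI_OFFSET,
    MULTI_UNPAIRED,
    SCALE,
    STACK,
    bulge_energy,
    hairpin_energy,
    internal_energy,
    pair_type,
)
from .structures import FoldConstraintSet, SecondaryStructure, StructureError


class EngineError(RuntimeError):
    pass


class EngineCapabilityError(EngineError):
    pass


class FoldingEngine(Protocol):
    name: str

    def mfe_fold(self, seq: str, constraints: FoldConstraintSet | None = None) -> SecondaryStructure:
        ...

    def energy_of(self, seq: str, structure: SecondaryStructure) -> float:
        ...


def _clean(seq: str) -> str:
    s = seq.upper().replace("T", "U")
    bad = set(s) - set("ACGU")
    if bad:
        raise ValueError(f"sequence contains non-ACGU characters: {sorted(bad)}")
    return s


# ---------------------------------------------------------------------------
# loop-wise evaluation (shared by energy_of and the enumeration reference)
# ---------------------------------------------------------------------------

def _loop_energy_int(seq: str, pairs: Iterable[tuple[int, int]]) -> int:
    """Total energy (0.01 kcal/mol) of a nested structure by loop decomposition."""
    plist = sorted(pairs)
    partner = {}
    for i, j in plist:
        partner[i] = j
        partner[j] = i
    total = 0
    # children of each pair (and of the exterior loop, which costs nothing)
    for i, j in plist:
        children = []
        k = i + 1
        while k < j:
            if k in partner and partner[k] > k:
                children.append((k, partner[k]))
                k = partner[k] + 1
            else:
                k += 1
        if not children:
            total += hairpin_energy(j - i - 1)
        elif len(children) == 1:
            k, l = children[0]
            n1, n2 = k - i - 1, j - l - 1
            if n1 == 0 and n2 == 0:
                total += STACK[(seq[i - 1] + seq[j - 1], seq[k - 1] + seq[l - 1])]
            elif n1 == 0 or n2 == 0:
                total += bulge_energy(n1 + n2)
            else:
                total += internal_energy(n1 + n2)
        else:
            unpaired = (j - i - 1) - sum(l - k + 1 for k, l in children)
            total += MULTI_OFFSET + MULTI_BRANCH * (1 + len(children)) + MULTI_UNPAIRED * unpaired
    return total


def _forbidden_by_constraints(seq: str, pair_set: frozenset[tuple[int, int]],
                              modified: frozenset[int]) -> bool:
    """True iff some modified nucleotide sits in a WC pair flanked by WC pairs."""
    for i, j in pair_set:
        if i not in modified and j not in modified:
            continue
        if pair_type(seq[i - 1], seq[j - 1]) != 1:
            continue
        outer = (i - 1, j + 1)
        inner = (i + 1, j - 1)
        if outer in pair_set and inner in pair_set \
                and pair_type(seq[outer[0] - 1], seq[outer[1] - 1]) == 1 \
                and pair_type(seq[inner[0] - 1], seq[inner[1] - 1]) == 1:
            return True
    return False


# ---------------------------------------------------------------------------
# exhaustive enumeration reference (short sequences)
# ---------------------------------------------------------------------------

def enumerate_structures(seq: str) -> Iterator[frozenset[tuple[int, int]]]:
    """Yield every nested canonical pair set on `seq` (min hairpin loop 3)."""
    s = _clean(seq)
    n = len(s)

    def rec(i: int, j: int) -> list[frozenset[tuple[int, int]]]:
        if j - i < MIN_HAIRPIN + 1:
            return [frozenset()]
        out = list(rec(i + 1, j))  # i unpaired
        for l in range(i + MIN_HAIRPIN + 1, j + 1):
            if pair_type(s[i - 1], s[l - 1]) == 0:
                continue
            for inner in rec(i + 1, l - 1):
                for rest in rec(l + 1, j):
                    out.append(inner | rest | {(i, l)})
        return out

    yield from rec(1, n)


def exhaustive_mfe(seq: str, constraints: FoldConstraintSet | None = None
                   ) -> tuple[frozenset[tuple[int, int]], float]:
    """Brute-force MFE over all nested structures; independent of the DP path."""
    s = _clean(seq)
    modified = frozenset(constraints.positions) if constraints else frozenset()
    best: frozenset[tuple[int, int]] = frozenset()
    best_e = 0
    for pair_set in enumerate_structures(s):
        if modified and _forbidden_by_constraints(s, pair_set, modified):
            continue
        e = _loop_energy_int(s, pair_set)
        if e < best_e or (e == best_e and sorted(pair_set) < sorted(best)):
            best, best_e = pair_set, e
    return best, best_e / SCALE


# ---------------------------------------------------------------------------
# built-in Zuker-style DP engine
# ---------------------------------------------------------------------------

try:  # numba accelerates the O(n^3)-O(n^4) fill; pure-Python fallback below
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*a, **k):  # type: ignore
        def deco(f):
            return f
        return deco(a[0]) if a and callable(a[0]) else deco


@njit(cache=True)
def _fill(n, ptype, mod, stE, HE, BE, IE, a, b, c, inf):  # pragma: no cover - jit
    V = np.full((n, n), inf, dtype=np.int64)
    Vns = np.full((n, n), inf, dtype=np.int64)
    M = np.full((n, n), inf, dtype=np.int64)
    M1 = np.full((n, n), inf, dtype=np.int64)
    for d in range(1, n):
        for i in range(0, n - d):
            j = i + d
            if d > MIN_HAIRPIN and ptype[i, j] > 0:
                # hairpin
                best = HE[d - 1]
                # internal / bulge loops (child pair (k, l) != (i+1, j-1))
                for k in range(i + 1, j - MIN_HAIRPIN - 1):
                    for l in range(k + MIN_HAIRPIN + 1, j):
                        n1 = k - i - 1
                        n2 = j - l - 1
                        if n1 + n2 == 0:
                            continue
                        if ptype[k, l] == 0 or V[k, l] >= inf:
                            continue
                        loop = BE[n1 + n2] if (n1 == 0 or n2 == 0) else IE[n1 + n2]
                        e = loop + V[k, l]
                        if e < best:
                            best = e
                # multibranch loop: >= 2 branches inside (i, j)
                for k in range(i + 2, j - 1):
                    if M[i + 1, k - 1] < inf and M1[k, j - 1] < inf:
                        e = a + b + M[i + 1, k - 1] + M1[k, j - 1]
                        if e < best:
                            best = e
                Vns[i, j] = best
                # helix stack on the immediate inner pair
                if d - 2 > MIN_HAIRPIN and ptype[i + 1, j - 1] > 0:
                    restricted = (
                        ptype[i, j] == 1
                        and ptype[i + 1, j - 1] == 1
                        and (mod[i + 1] or mod[j - 1])
                    )
                    if restricted and ptype[i + 2, j - 2] == 1:
                        T = Vns[i + 1, j - 1]
                    else:
                        T = V[i + 1, j - 1]
                    if T < inf:
                        e = stE[i, j] + T
                        if e < best:
                            best = e
                V[i, j] = best
            # multiloop helper arrays
            m1 = inf
            if ptype[i, j] > 0 and V[i, j] < inf:
                m1 = V[i, j] + b
            if j - 1 >= i and M1[i, j - 1] < inf:
                e = M1[i, j - 1] + c
                if e < m1:
                    m1 = e
            M1[i, j] = m1
            m = inf
            if M[i + 1, j] < inf:
                m = M[i + 1, j] + c
            if j - 1 >= i and M[i, j - 1] < inf:
                e = M[i, j - 1] + c
                if e < m:
                    m = e
            if ptype[i, j] > 0 and V[i, j] < inf:
                e = V[i, j] + b
                if e < m:
                    m = e
            for k in range(i + 1, j):
                if M[i, k - 1] < inf and ptype[k, j] > 0 and V[k, j] < inf:
                    e = M[i, k - 1] + V[k, j] + b
                    if e < m:
                        m = e
            M[i, j] = m
    return V, Vns, M, M1


class BuiltinEngine:
    """Self-contained nearest-neighbor MFE folder with modification constraints."""

    name = "builtin"
    supports_constraints = True
    temperature = 37.0

    def _tables(self, s: str, modified: frozenset[int]):
        n = len(s)
        ptype = np.zeros((n, n), dtype=np.int8)
        stE = np.zeros((n, n), dtype=np.int64)
        for i in range(n):
            for j in range(i + MIN_HAIRPIN + 1, n):
                ptype[i, j] = pair_type(s[i], s[j])
                if ptype[i, j] and j - i - 2 > MIN_HAIRPIN and pair_type(s[i + 1], s[j - 1]):
                    stE[i, j] = STACK[(s[i] + s[j], s[i + 1] + s[j - 1])]
        mod = np.zeros(n, dtype=np.bool_)
        for p in modified:
            mod[p - 1] = True
        HE = np.array([hairpin_energy(k) if k >= MIN_HAIRPIN else INF for k in range(n + 1)],
                      dtype=np.int64)
        BE = np.array([bulge_energy(k) if k >= 1 else INF for k in range(n + 1)], dtype=np.int64)
        IE = np.array([internal_energy(k) if k >= 2 else INF for k in range(n + 1)], dtype=np.int64)
        return ptype, mod, stE, HE, BE, IE

    def mfe_fold(self, seq: str, constraints: FoldConstraintSet | None = None) -> SecondaryStructure:
        s = _clean(seq)
        n = len(s)
        modified = frozenset(constraints.positions) if constraints else frozenset()
        if constraints:
            constraints.check_bounds(n)
        if n <= MIN_HAIRPIN + 1:
            return SecondaryStructure(name="", length=n, pairs=(), energy=0.0)
        ptype, mod, stE, HE, BE, IE = self._tables(s, modified)
        V, Vns, M, M1 = _fill(n, ptype, mod, stE, HE, BE, IE,
                              MULTI_OFFSET, MULTI_BRANCH, MULTI_UNPAIRED, INF)
        # exterior loop (no penalty for exterior unpaired bases or branches)
        W = np.zeros(n + 1, dtype=np.int64)  # W[j] = MFE of prefix 1..j (1-based)
        Wtrace = np.zeros(n + 1, dtype=np.int64)  # 0 => j unpaired; k>0 => pair (k, j)
        for j in range(1, n + 1):
            best = W[j - 1]
            arg = 0
            for k in range(1, j):
                if ptype[k - 1, j - 1] > 0 and V[k - 1, j - 1] < INF:
                    e = W[k - 1] + V[k - 1, j - 1]
                    if e < best:
                        best, arg = e, k
            W[j] = best
            Wtrace[j] = arg
        pairs = self._traceback(s, ptype, mod, stE, V, Vns, M, M1, Wtrace, n)
        pairs = tuple(sorted((int(i), int(j)) for i, j in pairs))
        return SecondaryStructure(name="", length=n, pairs=pairs, energy=float(W[n]) / SCALE)

    def _traceback(self, s, ptype, mod, stE, V, Vns, M, M1, Wtrace, n):
        pairs: list[tuple[int, int]] = []
        stack: list[tuple[str, int, int, bool]] = []
        j = n
        while j >= 1:
            k = Wtrace[j]
            if k == 0:
                j -= 1
            else:
                stack.append(("V", k - 1, j - 1, False))
                j = k - 1
        while stack:
            kind, i, j, no_stack = stack.pop()
            if kind == "M1":
                while M1[i, j] == M1[i, j - 1] + MULTI_UNPAIRED and M1[i, j - 1] < INF:
                    j -= 1
                stack.append(("V", i, j, False))
                continue
            if kind == "M":
                val = M[i, j]
                if M[i + 1, j] < INF and val == M[i + 1, j] + MULTI_UNPAIRED:
                    stack.append(("M", i + 1, j, False))
                    continue
                if j - 1 >= i and M[i, j - 1] < INF and val == M[i, j - 1] + MULTI_UNPAIRED:
                    stack.append(("M", i, j - 1, False))
                    continue
                if ptype[i, j] > 0 and V[i, j] < INF and val == V[i, j] + MULTI_BRANCH:
                    stack.append(("V", i, j, False))
                    continue
                found = False
                for k in range(i + 1, j):
                    if (M[i, k - 1] < INF and ptype[k, j] > 0 and V[k, j] < INF
                            and val == M[i, k - 1] + V[k, j] + MULTI_BRANCH):
                        stack.append(("M", i, k - 1, False))
                        stack.append(("V", k, j, False))
                        found = True
                        break
                if not found:  # pragma: no cover - internal consistency
                    raise EngineError("traceback failed in multiloop array")
                continue
            # kind == "V"
            val = Vns[i, j] if no_stack else V[i, j]
            pairs.append((i + 1, j + 1))
            # stack case first (matches fill order preference for helices)
            if not no_stack and j - i - 2 > MIN_HAIRPIN and ptype[i + 1, j - 1] > 0:
                restricted = (ptype[i, j] == 1 and ptype[i + 1, j - 1] == 1
                              and (mod[i + 1] or mod[j - 1]))
                child_ns = bool(restricted and ptype[i + 2, j - 2] == 1)
                T = Vns[i + 1, j - 1] if child_ns else V[i + 1, j - 1]
                if T < INF and val == stE[i, j] + T:
                    stack.append(("V", i + 1, j - 1, child_ns))
                    continue
            if val == hairpin_energy(j - i - 1):
                continue
            found = False
            for k in range(i + 1, j - MIN_HAIRPIN - 1):
                for l in range(k + MIN_HAIRPIN + 1, j):
                    n1, n2 = k - i - 1, j - l - 1
                    if n1 + n2 == 0 or ptype[k, l] == 0 or V[k, l] >= INF:
                        continue
                    loop = bulge_energy(n1 + n2) if (n1 == 0 or n2 == 0) else internal_energy(n1 + n2)
                    if val == loop + V[k, l]:
                        stack.append(("V", k, l, False))
                        found = True
                        break
                if found:
                    break
            if found:
                continue
            for k in range(i + 2, j - 1):
                if (M[i + 1, k - 1] < INF and M1[k, j - 1] < INF
                        and val == MULTI_OFFSET + MULTI_BRANCH + M[i + 1, k - 1] + M1[k, j - 1]):
                    stack.append(("M", i + 1, k - 1, False))
                    stack.append(("M1", k, j - 1, False))
                    found = True
                    break
            if not found:  # pragma: no cover - internal consistency
                raise EngineError(f"traceback failed at pair ({i + 1},{j + 1})")
        return pairs

    def energy_of(self, seq: str, structure: SecondaryStructure) -> float:
        s = _clean(seq)
        if structure.length != len(s):
            raise StructureError("structure length does not match sequence")
        bad = [(i, j) for i, j in structure.pairs if pair_type(s[i - 1], s[j - 1]) == 0]
        if bad:
            raise StructureError(f"non-complementary pairs: {bad}")
        return _loop_energy_int(s, structure.pairs) / SCALE


class ViennaEngine:
    """Turner-model adapter over the ViennaRNA (RNAfold) python bindings."""

    name = "vienna"
    supports_constraints = False
    temperature = 37.0

    def __init__(self) -> None:
        try:
            import RNA  # type: ignore
        except ImportError as exc:  # pragma: no cover
            raise EngineError(
                "the ViennaRNA adapter requires the RNA python bindings "
                "(install ViennaRNA); use engine='builtin' otherwise"
            ) from exc
        self._RNA = RNA
        self._md = RNA.md()
        self._md.temperature = self.temperature

    def mfe_fold(self, seq: str, constraints: FoldConstraintSet | None = None) -> SecondaryStructure:
        if constraints and len(constraints) > 0:
            raise EngineCapabilityError(
                "the ViennaRNA adapter cannot express the chemical-modification "
                "(flanked Watson-Crick pair) constraint; use engine='builtin' "
                "or an external Turner-model folder with modification constraints"
            )
        s = _clean(seq)
        fc = self._RNA.fold_compound(s, self._md)
        db, energy = fc.mfe()
        return SecondaryStructure.from_dotbracket(db, energy=float(energy))

    def energy_of(self, seq: str, structure: SecondaryStructure) -> float:
        s = _clean(seq)
        if structure.length != len(s):
            raise StructureError("structure length does not match sequence")
        bad = [(i, j) for i, j in structure.pairs if pair_type(s[i - 1], s[j - 1]) == 0]
        if bad:
            raise StructureError(f"non-complementary pairs: {bad}")
        fc = self._RNA.fold_compound(s, self._md)
        return float(fc.eval_structure(structure.dotbracket))


def get_engine(name: str = "auto") -> FoldingEngine:
    """Resolve an engine by name: 'builtin', 'vienna', or 'auto' (vienna if available)."""
    if name == "builtin":
        return BuiltinEngine()
    if name == "vienna":
        return ViennaEngine()
    if name == "auto":
        try:
            return ViennaEngine()
        except EngineError:
            return BuiltinEngine()
    raise EngineError(f"unknown folding engine {name!r}")
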