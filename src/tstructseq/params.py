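"""Embedded nearest-neighbor energy parameters for the built-in folding engine.

All energies are stored as integers in units of 0.01 kcal/mol (37 degC) so
that dynamic programming, exhaustive enumeration, and loop-wise evaluation
agree exactly, with no floating-point drift.

The table is a compact classic nearest-neighbor set: Watson-Crick stacking
free energies plus a category rule for wobble-containing stacks, logarithmic
Jacobson-Stockmayer loop-size extrapolation, and an affine multibranch-loop
penalty. No dangling ends, no coaxial stacking, minimum hairpin loop of 3.
"""

from __future__ import annotations

import math

#: canonical pairs; GU/UG are wobble, the rest Watson-Crick
WC_PAIRS = frozenset({"AU", "UA", "GC", "CG"})
WOBBLE_PAIRS = frozenset({"GU", "UG"})
CANONICAL_PAIRS = WC_PAIRS | WOBBLE_PAIRS

#: minimum number of unpaired nucleotides in a hairpin loop
MIN_HAIRPIN = 3

#: scale: integer energy units per kcal/mol
SCALE = 100

INF = 1 << 40

# 1.75 * R * T at 310.15 K, in 0.01 kcal/mol, for loop-size extrapolation
_LOOP_EXTRAP = 107.856


def _rev(pair: str) -> str:
    return pair[::-1]


# Watson-Crick / Watson-Crick stacks, keyed (outer pair, inner pair) where the
# outer pair is (i, j) and the inner pair is (i+1, j-1); units 0.01 kcal/mol.
_WC_STACK_SEED = {
    ("AU", "AU"): -90,
    ("AU", "UA"): -90,
    ("UA", "AU"): -110,
    ("CG", "AU"): -180,
    ("CG", "UA"): -170,
    ("GC", "AU"): -230,
    ("GC", "UA"): -210,
    ("CG", "GC"): -200,
    ("GC", "GC"): -290,
    ("GC", "CG"): -340,
}


def _build_stack_table() -> dict[tuple[str, str], int]:
    table: dict[tuple[str, str], int] = {}
    # reversal symmetry: a helix has the same energy read from either strand
    for (p, q), e in _WC_STACK_SEED.items():
        table[(p, q)] = e
        table[(_rev(q), _rev(p))] = e
    # wobble-containing stacks by pair-strength category (symmetric by
    # construction since the rule depends only on the unordered categories)
    for p in CANONICAL_PAIRS:
        for q in CANONICAL_PAIRS:
            if (p, q) in table:
                continue
            n_wobble = (p in WOBBLE_PAIRS) + (q in WOBBLE_PAIRS)
            if n_wobble == 0:
                continue  # already seeded
            if n_wobble == 2:
                e = -50
            else:
                strong = p if q in WOBBLE_PAIRS else q
                e = -150 if strong in ("GC", "CG") else -100
            table[(p, q)] = e
    return table


#: stacking energies, (outer, inner) pair strings -> 0.01 kcal/mol
STACK: dict[tuple[str, str], int] = _build_stack_table()


def hairpin_energy(size: int) -> int:
    """Hairpin-loop penalty for `size` unpaired nucleotides (size >= 3)."""
    if size < MIN_HAIRPIN:
        return INF
    return 540 + int(round(_LOOP_EXTRAP * math.log(size / 3.0)))


def bulge_energy(size: int) -> int:
    """Bulge-loop penalty (one side of the loop has zero unpaired nt)."""
    if size < 1:
        return INF
    return 390 + int(round(_LOOP_EXTRAP * math.log(size)))


def internal_energy(size: int) -> int:
    """Internal-loop penalty for total unpaired count `size` (>= 2)."""
    if size < 2:
        return INF
    return 410 + int(round(_LOOP_EXTRAP * math.log(size / 2.0)))


#: multibranch loop: offset + per-branch (closing pair included) + per-unpaired
MULTI_OFFSET = 340
MULTI_BRANCH = 40
MULTI_UNPAIRED = 10


def pair_type(a: str, b: str) -> int:
    """0 = not pairable, 1 = Watson-Crick, 2 = wobble."""
    p = a + b
    if p in WC_PAIRS:
        return 1
    if p in WOBBLE_PAIRS:
        return 2
    return 0
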