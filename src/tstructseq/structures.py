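"""Secondary-structure containers and dot-bracket / CT text formats.

Coordinates are 1-based throughout; pairs are stored as ``(i, j)`` with
``i < j``. Structures must be pseudoknot-free (properly nested), each
position may occur in at most one pair, and the minimum hairpin loop is
3 unpaired nucleotides (``j - i >= 4``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .params import CANONICAL_PAIRS, MIN_HAIRPIN


class StructureError(ValueError):
    pass


def _validate_pairs(pairs: Sequence[tuple[int, int]], length: int) -> list[tuple[int, int]]:
    seen: set[int] = set()
    out = []
    for i, j in pairs:
        if not (1 <= i < j <= length):
            raise StructureError(f"pair ({i},{j}) out of bounds for length {length}")
        if j - i <= MIN_HAIRPIN:
            raise StructureError(f"pair ({i},{j}) violates minimum hairpin loop of {MIN_HAIRPIN}")
        if i in seen or j in seen:
            raise StructureError(f"position in more than one pair at ({i},{j})")
        seen.update((i, j))
        out.append((i, j))
    out.sort()
    # nestedness: no two pairs may interleave
    stack: list[tuple[int, int]] = []
    for i, j in out:
        while stack and stack[-1][1] < i:
            stack.pop()
        if stack and not (stack[-1][0] < i and j < stack[-1][1]):
            raise StructureError(f"pseudoknot: ({i},{j}) crosses ({stack[-1][0]},{stack[-1][1]})")
        stack.append((i, j))
    return out


@dataclass(frozen=True)
class SecondaryStructure:
    """A nested RNA secondary structure on a transcript or fragment."""

    name: str
    length: int
    pairs: tuple[tuple[int, int], ...]
    energy: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "pairs", tuple(_validate_pairs(self.pairs, self.length)))

    @property
    def dotbracket(self) -> str:
        db = ["."] * self.length
        for i, j in self.pairs:
            db[i - 1] = "("
            db[j - 1] = ")"
        return "".join(db)

    @property
    def pair_set(self) -> frozenset[tuple[int, int]]:
        return frozenset(self.pairs)

    def partner(self) -> dict[int, int]:
        d: dict[int, int] = {}
        for i, j in self.pairs:
            d[i] = j
            d[j] = i
        return d

    @classmethod
    def from_dotbracket(cls, db: str, name: str = "", energy: float | None = None) -> "SecondaryStructure":
        stack: list[int] = []
        pairs: list[tuple[int, int]] = []
        for pos, ch in enumerate(db, start=1):
            if ch == "(":
                stack.append(pos)
            elif ch == ")":
                if not stack:
                    raise StructureError(f"unbalanced ')' at position {pos}")
                pairs.append((stack.pop(), pos))
            elif ch != ".":
                raise StructureError(f"unexpected character {ch!r} at position {pos}")
        if stack:
            raise StructureError(f"unbalanced '(' at position {stack[-1]}")
        return cls(name=name, length=len(db), pairs=tuple(pairs), energy=energy)

    # ----- CT format (standard 6-column) -----

    def to_ct(self, sequence: str) -> str:
        if len(sequence) != self.length:
            raise StructureError("sequence length does not match structure length")
        partner = self.partner()
        header = f"{self.length}"
        if self.energy is not None:
            header += f"  ENERGY = {self.energy:.2f}"
        header += f"  {self.name}"
        lines = [header]
        for i, base in enumerate(sequence, start=1):
            nxt = i + 1 if i < self.length else 0
            lines.append(f"{i}\t{base}\t{i - 1}\t{nxt}\t{partner.get(i, 0)}\t{i}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_ct(cls, text: str, name: str | None = None) -> tuple["SecondaryStructure", str]:
        """Parse a CT file; returns (structure, sequence)."""
        lines = [ln for ln in text.splitlines() if ln.strip()]
        head = lines[0].split()
        n = int(head[0])
        energy = None
        if "ENERGY" in lines[0].upper():
            toks = lines[0].replace("=", " ").split()
            for k, tok in enumerate(toks):
                if tok.upper().startswith("ENERGY"):
                    energy = float(toks[k + 1])
                    break
        title = name if name is not None else " ".join(head[1:]) or ""
        seq = []
        pairs = []
        for ln in lines[1 : n + 1]:
            f = ln.split()
            i, base, j = int(f[0]), f[1], int(f[4])
            seq.append(base)
            if j > i:
                pairs.append((i, j))
        struct = cls(name=title, length=n, pairs=tuple(pairs), energy=energy)
        return struct, "".join(seq)


def read_dotbracket(path: str | Path) -> tuple[str, SecondaryStructure]:
    """Read a (possibly FASTA-headed) dot-bracket file: sequence line then structure line."""
    lines = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    name = ""
    if lines and lines[0].startswith(">"):
        name = lines[0][1:].strip()
        lines = lines[1:]
    if len(lines) < 2:
        raise StructureError(f"{path}: expected a sequence line and a structure line")
    seq = lines[0].upper().replace("T", "U")
    db = lines[1].split()[0]
    energy = None
    rest = lines[1][len(db):].strip().strip("()")
    if rest:
        try:
            energy = float(rest)
        except ValueError:
            pass
    return seq, SecondaryStructure.from_dotbracket(db, name=name, energy=energy)


def write_dotbracket(path: str | Path, sequence: str, structure: SecondaryStructure) -> None:
    with open(path, "w") as fh:
        fh.write(f">{structure.name}\n{sequence}\n{structure.dotbracket}")
        if structure.energy is not None:
            fh.write(f" ({structure.energy:.2f})")
        fh.write("\n")


@dataclass(frozen=True)
class FoldConstraintSet:
    """Positions flagged as chemically modified (1-based, on the folded fragment).

    Semantics at fold time: a flagged nucleotide may not sit in a Watson-Crick
    pair that is flanked on both sides by Watson-Crick pairs (a helix-interior
    position). Helix-terminal pairing, wobble pairing, and remaining unpaired
    are all allowed.
    """

    positions: frozenset[int] = field(default_factory=frozenset)

    def __init__(self, positions: Iterable[int] = ()) -> None:
        object.__setattr__(self, "positions", frozenset(int(p) for p in positions))

    def __len__(self) -> int:
        return len(self.positions)

    def __iter__(self):
        return iter(sorted(self.positions))

    def __contains__(self, p: int) -> bool:
        return p in self.positions

    def check_bounds(self, length: int) -> None:
        bad = [p for p in self.positions if not (1 <= p <= length)]
        if bad:
            raise StructureError(f"constraint positions out of bounds: {sorted(bad)}")

    def to_text(self) -> str:
        """Plain position-list export, one 1-based position per line."""
        return "\n".join(str(p) for p in sorted(self.positions)) + ("\n" if self.positions else "")

    def to_rnastructure_con(self) -> str:
        """Chemical-modification constraint dialect used by Turner-model folders."""
        lines = ["DS:", "-1", "SS:", "-1", "Mod:"]
        lines += [str(p) for p in sorted(self.positions)]
        lines += ["-1", "Pairs:", "-1 -1", "FMN:", "-1", "Forbids:", "-1 -1"]
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "FoldConstraintSet":
        return cls(int(t) for t in text.split())


def is_canonical(a: str, b: str) -> bool:
    return (a + b) in CANONICAL_PAIRS
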