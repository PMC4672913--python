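"""Base-pair conservation and mutation classes over a multiple alignment.

A structure model built on a reference sequence is mapped through the
alignment columns of the reference row; each model pair is then scored per
species as canonical (AU/UA/GC/CG plus GU/UG wobble), non-canonical, or
gapped (gaps count as non-canonical in the conservation fraction). Mutation
classes are assessed per species against the reference:

* consistent  — exactly one of the two residues differs and the species pair
  is still canonical (single point mutation preserving pairing);
* compensatory — both residues differ and the species pair is canonical
  (double point mutation preserving pairing).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .structures import SecondaryStructure, is_canonical

log = logging.getLogger(__name__)

STATUS_CANONICAL = "canonical"
STATUS_NONCANONICAL = "non-canonical"
STATUS_GAPPED = "gapped"


class AlignmentBlock:
    """Named aligned sequences over {A, C, G, U, -} with a designated reference row."""

    def __init__(self, rows: dict[str, str] | Sequence[tuple[str, str]], reference: str) -> None:
        items = list(rows.items()) if isinstance(rows, dict) else list(rows)
        self.names = [name for name, _ in items]
        self.rows = {name: seq.upper().replace("T", "U") for name, seq in items}
        widths = {len(s) for s in self.rows.values()}
        if len(widths) != 1:
            raise ValueError("alignment rows have unequal lengths")
        self.width = widths.pop()
        if reference not in self.rows:
            raise ValueError(f"reference row {reference!r} not in alignment")
        self.reference = reference
        # reference (ungapped) position -> alignment column, both 1-based
        self._ref_to_col: list[int] = [
            col for col, ch in enumerate(self.rows[reference], start=1) if ch != "-"
        ]

    @property
    def reference_length(self) -> int:
        return len(self._ref_to_col)

    def ref_to_column(self, position: int) -> int:
        if not (1 <= position <= self.reference_length):
            raise IndexError(f"reference position {position} beyond ungapped length "
                             f"{self.reference_length}")
        return self._ref_to_col[position - 1]

    def residue(self, name: str, column: int) -> str:
        return self.rows[name][column - 1]

    def subset(self, names: Sequence[str]) -> "AlignmentBlock":
        """Row-subset view (the reference row is always retained)."""
        keep = list(dict.fromkeys([self.reference, *names]))
        return AlignmentBlock([(n, self.rows[n]) for n in keep], reference=self.reference)

    @classmethod
    def from_file(cls, path: str | Path, reference: str, fmt: str | None = None) -> "AlignmentBlock":
        """Read an aligned FASTA or Clustal file (format inferred from suffix)."""
        from Bio import AlignIO

        if fmt is None:
            suffix = Path(path).suffix.lower()
            fmt = "clustal" if suffix in (".aln", ".clustal", ".clu") else "fasta"
        aln = AlignIO.read(str(path), fmt)
        return cls([(rec.id, str(rec.seq)) for rec in aln], reference=reference)


@dataclass
class PairConservation:
    """Scores for a single model pair across the alignment."""

    i: int  # reference coordinates
    j: int
    column_i: int
    column_j: int
    status: dict[str, str] = field(default_factory=dict)  # species -> status
    canonical_fraction: float = 0.0
    consistent_species: tuple[str, ...] = ()
    compensatory_species: tuple[str, ...] = ()

    @property
    def has_consistent(self) -> bool:
        return bool(self.consistent_species)

    @property
    def has_compensatory(self) -> bool:
        return bool(self.compensatory_species)


@dataclass
class PairConservationReport:
    """Per-pair conservation plus model-level summary (Table-style row)."""

    pairs: list[PairConservation]
    n_species: int

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def mean_conservation_pct(self) -> float:
        if not self.pairs:
            return float("nan")
        return 100.0 * sum(p.canonical_fraction for p in self.pairs) / len(self.pairs)

    @property
    def n_pairs_with_consistent(self) -> int:
        return sum(p.has_consistent for p in self.pairs)

    @property
    def n_pairs_with_compensatory(self) -> int:
        return sum(p.has_compensatory for p in self.pairs)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("i\tj\tcolumn_i\tcolumn_j\tcanonical_fraction\t"
                     "n_consistent_species\tn_compensatory_species\t"
                     "has_consistent\thas_compensatory\n")
            for p in self.pairs:
                fh.write(f"{p.i}\t{p.j}\t{p.column_i}\t{p.column_j}\t"
                         f"{p.canonical_fraction:.4f}\t{len(p.consistent_species)}\t"
                         f"{len(p.compensatory_species)}\t{int(p.has_consistent)}\t"
                         f"{int(p.has_compensatory)}\n")

    def summary_row(self) -> dict:
        return {
            "bps": self.n_pairs,
            "conservation_pct": self.mean_conservation_pct,
            "consistent": self.n_pairs_with_consistent,
            "compensatory": self.n_pairs_with_compensatory,
        }


def map_pairs(structure: SecondaryStructure, aln: AlignmentBlock) -> list[tuple[int, int]]:
    """Map model pairs (reference coordinates) to alignment column pairs."""
    cols = []
    for i, j in structure.pairs:
        cols.append((aln.ref_to_column(i), aln.ref_to_column(j)))
    return cols


def score_pair_conservation(aln: AlignmentBlock, column_pairs: Sequence[tuple[int, int]],
                            ref_pairs: Sequence[tuple[int, int]] | None = None
                            ) -> PairConservationReport:
    """Canonical fraction per pair over all rows (reference included).

    A species pair is canonical iff both residues are present (no gap) and
    form AU/UA/GC/CG/GU/UG; gapped pairs count as non-canonical.
    """
    records = []
    for idx, (ci, cj) in enumerate(column_pairs):
        if not (1 <= ci <= aln.width and 1 <= cj <= aln.width):
            raise IndexError(f"column pair ({ci},{cj}) outside alignment width {aln.width}")
        ri, rj = ref_pairs[idx] if ref_pairs else (0, 0)
        rec = PairConservation(i=ri, j=rj, column_i=ci, column_j=cj)
        n_canon = 0
        for name in aln.names:
            a, b = aln.residue(name, ci), aln.residue(name, cj)
            if a == "-" or b == "-":
                rec.status[name] = STATUS_GAPPED
            elif is_canonical(a, b):
                rec.status[name] = STATUS_CANONICAL
                n_canon += 1
            else:
                rec.status[name] = STATUS_NONCANONICAL
        rec.canonical_fraction = n_canon / len(aln.names)
        records.append(rec)
    return PairConservationReport(pairs=records, n_species=len(aln.names))


def classify_mutations(aln: AlignmentBlock, column_pairs: Sequence[tuple[int, int]],
                       ref_pairs: Sequence[tuple[int, int]] | None = None
                       ) -> PairConservationReport:
    """Flag consistent and compensatory mutations per pair (vs the reference row)."""
    report = score_pair_conservation(aln, column_pairs, ref_pairs)
    ref = aln.reference
    for rec in report.pairs:
        ra, rb = aln.residue(ref, rec.column_i), aln.residue(ref, rec.column_j)
        consistent, compensatory = [], []
        for name in aln.names:
            if name == ref:
                continue
            a, b = aln.residue(name, rec.column_i), aln.residue(name, rec.column_j)
            if a == "-" or b == "-" or not is_canonical(a, b):
                continue
            n_diff = (a != ra) + (b != rb)
            if n_diff == 1:
                consistent.append(name)
            elif n_diff == 2:
                compensatory.append(name)
        rec.consistent_species = tuple(consistent)
        rec.compensatory_species = tuple(compensatory)
    return report


def conservation_report(aln: AlignmentBlock, structure: SecondaryStructure
                        ) -> PairConservationReport:
    """Map a model through the alignment and score conservation and mutations."""
    cols = map_pairs(structure, aln)
    return classify_mutations(aln, cols, ref_pairs=list(structure.pairs))
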