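"""Reactivity-constrained structure modeling and bootstrap support.

Strongly DMS-reactive nucleotides (P_DMS >= 0.8% by default) become
chemical-modification folding constraints: such a nucleotide may not occupy
a Watson-Crick pair flanked on both sides by Watson-Crick pairs. Bootstrap
support refolds the fragment many times with random constraint subsets and
reports, per base pair, the fraction of replicates containing it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .engines import FoldingEngine
from .reactivity import STRONG_THRESHOLD, ReactivityProfile
from .structures import FoldConstraintSet, SecondaryStructure

log = logging.getLogger(__name__)


def make_constraints(profile: ReactivityProfile, threshold: float = STRONG_THRESHOLD,
                     region: tuple[int, int] | None = None) -> FoldConstraintSet:
    """Positions with P_DMS >= threshold and adequate coverage.

    With ``region=(start, end)`` (transcript coordinates, 1-based inclusive)
    positions are re-indexed to the folded fragment (fragment position 1 is
    transcript position ``start``). Undefined positions are never constrained.
    """
    ok = profile.coverage_ok.copy()
    with np.errstate(invalid="ignore"):
        hits = np.flatnonzero(ok & (profile.p_dms >= threshold))
    if region is None:
        return FoldConstraintSet(int(i) for i in hits)
    start, end = region
    return FoldConstraintSet(int(i) - start + 1 for i in hits if start <= i <= end)


def mfe_fold(seq: str, constraints: FoldConstraintSet | None,
             engine: FoldingEngine, name: str = "") -> SecondaryStructure:
    """Minimum-free-energy structure under modification constraints (37 degC)."""
    if constraints is not None:
        constraints.check_bounds(len(seq))
    structure = engine.mfe_fold(seq, constraints)
    if name:
        structure = SecondaryStructure(name=name, length=structure.length,
                                       pairs=structure.pairs, energy=structure.energy)
    return structure


def energy_of(seq: str, structure: SecondaryStructure, engine: FoldingEngine) -> float:
    """Thermodynamic evaluation of a given (possibly hand-built) structure."""
    return engine.energy_of(seq, structure)


@dataclass
class BootstrapSupport:
    """Per-pair support frequencies from constraint-subset refolding."""

    support: dict[tuple[int, int], float]
    n_replicates: int
    fraction: float
    seed: int
    full_structure: SecondaryStructure
    consensus: tuple[tuple[int, int], ...] = field(default=())

    def __post_init__(self) -> None:
        self.consensus = tuple(sorted(p for p, f in self.support.items() if f > 0.5))

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# n_replicates={self.n_replicates}\tfraction={self.fraction}\t"
                     f"seed={self.seed}\n")
            fh.write("i\tj\tsupport\tin_full_model\tconsensus\n")
            full = self.full_structure.pair_set
            for (i, j), f in sorted(self.support.items()):
                fh.write(f"{i}\t{j}\t{f:.4f}\t{int((i, j) in full)}\t{int(f > 0.5)}\n")


def bootstrap_support(seq: str, constraints: FoldConstraintSet, engine: FoldingEngine,
                      n: int = 1000, fraction: float = 0.5, seed: int = 0) -> BootstrapSupport:
    """Refold ``n`` times with random constraint subsets (sampled without
    replacement, ``ceil(fraction * |constraints|)`` per replicate) and report
    per-pair support frequencies; consensus pairs exceed 0.5.
    """
    if n < 1:
        raise ValueError("bootstrap requires at least one replicate")
    rng = np.random.default_rng(seed)
    full = mfe_fold(seq, constraints, engine)
    positions = sorted(constraints.positions)
    k = int(np.ceil(fraction * len(positions)))
    counts: dict[tuple[int, int], int] = {}
    if not positions:
        # no resampling variance: every replicate is the unconstrained MFE
        for pair in full.pairs:
            counts[pair] = n
    else:
        cache: dict[frozenset[int], tuple[tuple[int, int], ...]] = {}
        for _ in range(n):
            subset = frozenset(rng.choice(positions, size=k, replace=False).tolist())
            pairs = cache.get(subset)
            if pairs is None:
                pairs = mfe_fold(seq, FoldConstraintSet(subset), engine).pairs
                cache[subset] = pairs
            for pair in pairs:
                counts[pair] = counts.get(pair, 0) + 1
    support = {pair: c / n for pair, c in counts.items()}
    return BootstrapSupport(support=support, n_replicates=n, fraction=fraction,
                            seed=seed, full_structure=full)
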