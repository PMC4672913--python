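"""Sliding-window thermodynamic z-score scan and structured-region calling.

For each window the native minimum free energy is compared with the MFE
distribution of shuffled sequences of identical composition:

    z = (dG_native - mean(dG_shuffled)) / sd(dG_shuffled)

Strongly negative z indicates the native sequence is more stable than
composition alone explains, a signature of evolved structure. Overlapping
windows below a cutoff (by default one standard deviation below the
transcript-wide mean window z) are merged into structured regions.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .engines import FoldingEngine

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class WindowScore:
    start: int  # 1-based inclusive
    end: int
    dg_native: float  # kcal/mol
    dg_random_mean: float
    dg_random_sd: float
    z: float  # NaN when sd == 0 or the engine failed
    n_shuffles: int


@dataclass(frozen=True)
class StructuredRegion:
    start: int
    end: int
    mean_z: float
    min_z: float
    mean_dg: float
    min_dg: float
    n_windows: int


def shuffle_sequence(seq: str, rng: np.random.Generator) -> str:
    """Uniformly random permutation of the sequence (composition preserved)."""
    if not seq:
        raise ValueError("cannot shuffle an empty sequence")
    chars = np.array(list(seq))
    return "".join(rng.permutation(chars))


def dinucleotide_shuffle(seq: str, rng: np.random.Generator, max_tries: int = 200) -> str:
    """Shuffle preserving dinucleotide composition (random Eulerian walk on the
    doublet graph, rejection-sampled until every edge is consumed)."""
    if len(seq) < 3:
        return seq
    edges: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    n_edges = len(seq) - 1
    for _ in range(max_tries):
        pool = {k: list(v) for k, v in edges.items()}
        for v in pool.values():
            rng.shuffle(v)
        walk = [seq[0]]
        while pool.get(walk[-1]):
            walk.append(pool[walk[-1]].pop())
        if len(walk) == n_edges + 1:
            return "".join(walk)
    log.warning("dinucleotide shuffle failed to cover the doublet graph; "
                "falling back to mononucleotide shuffle")
    return shuffle_sequence(seq, rng)


def _window_rng(seed: int, start: int) -> np.random.Generator:
    # independent per-window streams so scans parallelize deterministically
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(start)]))


def scan(seq: str, engine: FoldingEngine, window: int = 150, step: int = 10,
         n_shuffles: int = 25, seed: int = 0, shuffle: str = "mono") -> list[WindowScore]:
    """Score every full window (strict sliding scheme; trailing partial dropped)."""
    seq = seq.upper().replace("T", "U")
    if len(seq) < window:
        raise ValueError(f"sequence length {len(seq)} shorter than window {window}")
    shuffler = shuffle_sequence if shuffle == "mono" else dinucleotide_shuffle
    scores: list[WindowScore] = []
    for start in range(1, len(seq) - window + 2, step):
        frag = seq[start - 1 : start - 1 + window]
        rng = _window_rng(seed, start)
        try:
            dg_native = engine.mfe_fold(frag).energy
            dgs = np.array([engine.mfe_fold(shuffler(frag, rng)).energy
                            for _ in range(n_shuffles)])
        except Exception as exc:  # engine failure: mark window NA, keep scanning
            log.warning("engine failed on window %d-%d: %s", start, start + window - 1, exc)
            scores.append(WindowScore(start, start + window - 1, math.nan, math.nan,
                                      math.nan, math.nan, n_shuffles))
            continue
        mean = float(dgs.mean())
        sd = float(dgs.std(ddof=0))
        z = (dg_native - mean) / sd if sd > 0 else math.nan
        scores.append(WindowScore(start, start + window - 1, float(dg_native),
                                  mean, sd, z, n_shuffles))
    return scores


def auto_cutoff(scores: Sequence[WindowScore]) -> float:
    """One standard deviation below the mean window z (population sd)."""
    zs = np.array([w.z for w in scores if not math.isnan(w.z)])
    if zs.size == 0:
        raise ValueError("all windows are NA; no cutoff can be derived")
    return float(zs.mean() - zs.std(ddof=0))


def call_regions(scores: Sequence[WindowScore], cutoff: float | str = "auto",
                 gap_join: int = 0) -> list[StructuredRegion]:
    """Merge overlapping below-cutoff windows into structured regions.

    Windows with z < cutoff whose intervals share at least one nucleotide are
    merged by interval union; ``gap_join > 0`` additionally merges regions
    separated by at most that many nucleotides (off by default).
    """
    zs = [w.z for w in scores if not math.isnan(w.z)]
    if not zs:
        warnings.warn("all windows are NA; no regions called", stacklevel=2)
        return []
    cut = auto_cutoff(scores) if cutoff == "auto" else float(cutoff)
    hits = sorted((w for w in scores if not math.isnan(w.z) and w.z < cut),
                  key=lambda w: w.start)
    regions: list[StructuredRegion] = []
    group: list[WindowScore] = []

    def flush() -> None:
        if not group:
            return
        regions.append(StructuredRegion(
            start=group[0].start,
            end=max(w.end for w in group),
            mean_z=float(np.mean([w.z for w in group])),
            min_z=float(min(w.z for w in group)),
            mean_dg=float(np.mean([w.dg_native for w in group])),
            min_dg=float(min(w.dg_native for w in group)),
            n_windows=len(group),
        ))

    for w in hits:
        cur_end = max(g.end for g in group) if group else 0
        overlap = group and w.start <= cur_end  # shares >= 1 nt
        joinable = group and gap_join > 0 and (w.start - cur_end - 1) <= gap_join
        if overlap or joinable:
            group.append(w)
        else:
            flush()
            group = [w]
    flush()
    return regions


def windows_to_tsv(scores: Sequence[WindowScore], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("start\tend\tdG_native\tdG_random_mean\tdG_random_sd\tz\tn_shuffles\n")
        for w in scores:
            fh.write(f"{w.start}\t{w.end}\t{w.dg_native:.2f}\t{w.dg_random_mean:.4f}\t"
                     f"{w.dg_random_sd:.4f}\t{w.z:.4f}\t{w.n_shuffles}\n")


def regions_to_tsv(regions: Sequence[StructuredRegion], path: str | Path) -> None:
    """Region table (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("start\tend\tmean_z\tmin_z\tmean_dG\tmin_dG\tn_windows\n")
        for r in regions:
            fh.write(f"{r.start}\t{r.end}\t{r.mean_z:.4f}\t{r.min_z:.4f}\t"
                     f"{r.mean_dg:.2f}\t{r.min_dg:.2f}\t{r.n_windows}\n")
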