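"""Per-base DMS reactivity from termination counts.

The reactivity estimator is a background-subtracted termination rate:

    P_term(i)  = n_T(i) / r_T(i)        (treated sample)
    P_spont(i) = n_U(i) / r_U(i)        (untreated control)
    P_DMS(i)   = P_term(i) - P_spont(i)

where n counts RT stops at position i and r counts reads reading through i.
Positions lacking read-through coverage in either condition are undefined
(NaN, coverage flag set). Negative P_DMS values are retained.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from .readproc import PrimerPanel, TerminationCounts, TranscriptRef

log = logging.getLogger(__name__)

#: classification thresholds on P_DMS (unitless probabilities)
STRONG_THRESHOLD = 0.008   # >= 0.8%
MODERATE_THRESHOLD = 0.004  # strict lower bound: 0.4% < P_DMS < 0.8%

#: sentinel used only when exporting plots/tables, never in computation
NA_PLOT_SENTINEL = -0.01

CLASS_NA, CLASS_LOW, CLASS_MODERATE, CLASS_STRONG = "NA", "low", "moderate", "strong"


@dataclass
class ReactivityProfile:
    """Per-position DMS reactivity on one transcript (arrays indexed 1..length)."""

    transcript: str
    length: int
    p_term: np.ndarray = field(repr=False, default=None)
    p_spont: np.ndarray = field(repr=False, default=None)
    p_dms: np.ndarray = field(repr=False, default=None)
    coverage_ok: np.ndarray = field(repr=False, default=None)
    classification: np.ndarray = field(repr=False, default=None)
    n_primers: np.ndarray = field(repr=False, default=None)
    # per-primer provenance (set by compute_pdms)
    primer: str | None = None
    primer_start: int | None = None
    r_treated: np.ndarray | None = field(repr=False, default=None)
    r_untreated: np.ndarray | None = field(repr=False, default=None)

    def __post_init__(self) -> None:
        size = self.length + 1
        if self.p_term is None:
            self.p_term = np.full(size, np.nan)
        if self.p_spont is None:
            self.p_spont = np.full(size, np.nan)
        if self.p_dms is None:
            self.p_dms = np.full(size, np.nan)
        if self.coverage_ok is None:
            self.coverage_ok = np.zeros(size, dtype=bool)
        if self.classification is None:
            self.classification = np.full(size, CLASS_NA, dtype=object)
        if self.n_primers is None:
            self.n_primers = np.zeros(size, dtype=int)

    def defined_positions(self) -> np.ndarray:
        return np.flatnonzero(self.coverage_ok)

    def to_tsv(self, path: str | Path, transcript: TranscriptRef | None = None) -> None:
        with open(path, "w") as fh:
            fh.write("transcript\tposition\tbase\tP_term\tP_spont\tP_DMS\tn_primers\tclass\n")
            for i in range(1, self.length + 1):
                base = transcript.base(i) if transcript is not None else "N"
                fh.write(f"{self.transcript}\t{i}\t{base}\t{self.p_term[i]:.6g}\t"
                         f"{self.p_spont[i]:.6g}\t{self.p_dms[i]:.6g}\t"
                         f"{self.n_primers[i]}\t{self.classification[i]}\n")


@dataclass
class QCReport:
    """Quality metrics: A+C specificity by rank and inter-profile agreement."""

    ac_fraction: dict[int, float] = field(default_factory=dict)
    pearson_r: float = float("nan")
    slope: float = float("nan")
    n_positions: int = 0


def compute_pdms(treated: TerminationCounts, untreated: TerminationCounts) -> ReactivityProfile:
    """Background-subtracted termination rate for one primer."""
    if treated.transcript != untreated.transcript:
        raise ValueError(f"transcript mismatch: {treated.transcript!r} vs {untreated.transcript!r}")
    if treated.length != untreated.length:
        raise ValueError("treated and untreated counts have different lengths")
    prof = ReactivityProfile(transcript=treated.transcript, length=treated.length)
    ok = (treated.r > 0) & (untreated.r > 0)
    ok[0] = False
    with np.errstate(divide="ignore", invalid="ignore"):
        p_term = np.where(treated.r > 0, treated.n / np.where(treated.r > 0, treated.r, 1), np.nan)
        p_spont = np.where(untreated.r > 0, untreated.n / np.where(untreated.r > 0, untreated.r, 1),
                           np.nan)
    prof.p_term = np.where(ok, p_term, np.nan)
    prof.p_spont = np.where(ok, p_spont, np.nan)
    prof.p_dms = prof.p_term - prof.p_spont
    prof.coverage_ok = ok
    prof.n_primers = ok.astype(int)
    prof.primer = treated.primer
    prof.r_treated = treated.r.copy()
    prof.r_untreated = untreated.r.copy()
    return prof


def combine_primers(per_primer: Sequence[ReactivityProfile], panel: PrimerPanel,
                    window: tuple[int, int] = (100, 380),
                    min_readthrough: float = 1000.0) -> ReactivityProfile:
    """Average per-primer reactivities over eligible primers at each position.

    A primer is eligible at position i when i lies ``window`` nt (inclusive)
    from its annealing site and its read-through exceeds ``min_readthrough``
    in both conditions at i. Positions with no eligible primer are undefined.
    """
    if not per_primer:
        raise ValueError("no per-primer profiles supplied")
    lengths = {p.length for p in per_primer}
    names = {p.transcript for p in per_primer}
    if len(lengths) != 1 or len(names) != 1:
        raise ValueError("per-primer profiles disagree on transcript name or length")
    length = lengths.pop()
    lo, hi = window
    out = ReactivityProfile(transcript=names.pop(), length=length)
    total = np.zeros(length + 1)
    count = np.zeros(length + 1, dtype=int)
    pos = np.arange(length + 1)
    for prof in per_primer:
        if prof.primer is None or prof.r_treated is None:
            raise ValueError("combine_primers requires profiles from compute_pdms")
        entry = panel[prof.primer]
        dist = entry.start - pos  # positions 5' of the annealing site
        eligible = (
            (dist >= lo) & (dist <= hi)
            & prof.coverage_ok
            & (prof.r_treated > min_readthrough)
            & (prof.r_untreated > min_readthrough)
        )
        total[eligible] += prof.p_dms[eligible]
        count[eligible] += 1
    ok = count > 0
    with np.errstate(invalid="ignore"):
        out.p_dms = np.where(ok, total / np.where(ok, count, 1), np.nan)
    out.coverage_ok = ok
    out.n_primers = count
    return out


def classify_reactivity(profile: ReactivityProfile, strong: float = STRONG_THRESHOLD,
                        moderate: float = MODERATE_THRESHOLD) -> ReactivityProfile:
    """Partition defined positions into strong / moderate / low reactivity.

    strong: P_DMS >= strong threshold; moderate: moderate < P_DMS < strong
    (strict bounds); low: everything else defined; NA: insufficient coverage.
    """
    cls = np.full(profile.length + 1, CLASS_NA, dtype=object)
    ok = profile.coverage_ok
    v = profile.p_dms
    with np.errstate(invalid="ignore"):
        cls[ok & (v >= strong)] = CLASS_STRONG
        cls[ok & (v > moderate) & (v < strong)] = CLASS_MODERATE
        cls[ok & (v <= moderate)] = CLASS_LOW
    profile.classification = cls
    return profile


def rank_positions(profile: ReactivityProfile) -> np.ndarray:
    """Defined positions sorted by descending P_DMS, ties broken by position."""
    pos = profile.defined_positions()
    order = np.lexsort((pos, -profile.p_dms[pos]))
    return pos[order]


def ac_specificity(profile: ReactivityProfile, transcript: TranscriptRef,
                   ranks: Sequence[int]) -> QCReport:
    """Fraction of A/C bases among the top-ranked positions at each rank cutoff."""
    if transcript.length != profile.length:
        raise ValueError("transcript and profile lengths differ")
    ranked = rank_positions(profile)
    is_ac = np.array([transcript.base(int(i)) in "AC" for i in ranked])
    report = QCReport()
    for k in ranks:
        k = int(k)
        if k < 1 or k > len(ranked):
            report.ac_fraction[k] = float("nan")
        else:
            report.ac_fraction[k] = float(np.mean(is_ac[:k]))
    return report


def compare_profiles(p1: ReactivityProfile, p2: ReactivityProfile) -> QCReport:
    """Pearson correlation and least-squares slope over co-defined non-zero positions."""
    if p1.transcript != p2.transcript or p1.length != p2.length:
        raise ValueError("profiles are not on the same transcript")
    ok = p1.coverage_ok & p2.coverage_ok
    with np.errstate(invalid="ignore"):
        ok &= (p1.p_dms != 0) & (p2.p_dms != 0)
        ok &= ~np.isnan(p1.p_dms) & ~np.isnan(p2.p_dms)
    x = p1.p_dms[ok]
    y = p2.p_dms[ok]
    report = QCReport(n_positions=int(ok.sum()))
    if len(x) < 3:
        warnings.warn("fewer than 3 co-defined non-zero positions; agreement undefined",
                      stacklevel=2)
        return report
    report.pearson_r = float(stats.pearsonr(x, y).statistic)
    slope, _ = np.polyfit(x, y, 1)
    report.slope = float(slope)
    return report
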