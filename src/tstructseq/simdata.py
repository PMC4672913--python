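"""Synthetic targeted RT-stop probing experiments with known ground truth.

The simulator emulates the chemistry the pipeline analyzes: a transcript
with a planted secondary structure is "treated" so that accessible
(unpaired) A and C bases carry a per-encounter termination hazard, and
reverse transcription is modeled as a 3'->5' walk from each primer in which
the polymerase halts at position i with probability

    h(i) = p_spont + modification_probability(i)     (treated)
    h(i) = p_spont                                   (untreated)

so the read starts at i + 1 and the inferred RT stop is exactly i. Products
shorter than a minimum recovered length are discarded, mimicking library
size selection. Because termination is a per-position hazard, the n/r
estimator's expectation is analytically p_spont + p_mod(i) at covered
positions, which makes recovery tests exact up to binomial noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .readproc import AlignedRead, PrimerEntry, PrimerPanel, TranscriptRef
from .structures import SecondaryStructure
from .params import pair_type

log = logging.getLogger(__name__)

TREATED, UNTREATED = "treated", "untreated"


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic experiment.

    Default rates are scaled to the regime the estimator targets in real
    probing data: reactivities (P_DMS) of a few tenths of a percent up to a
    few percent at accessible bases, spontaneous drop-off giving ~250 nt
    median product length, and ten thousand reads per primer.
    """

    length: int = 600
    sequence: str | None = None
    structure: SecondaryStructure | None = None
    p_hit: float = 0.02          # termination prob. at accessible A/C (treated)
    p_bg: float = 0.0005         # termination prob. at protected positions (treated)
    p_spont: float = 0.004       # per-nt spontaneous drop-off (both conditions)
    ac_only: bool = True         # modification confined to A and C bases
    min_recovered_length: int = 100
    reads_per_primer: int = 10_000
    primer_spacing: int = 200
    primer_width: int = 20
    dose_scale: float = 1.0
    mismatch_rate: float = 0.0   # optional uniform mismatch injection
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_hit", "p_bg", "p_spont", "mismatch_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.min_recovered_length >= self.primer_spacing:
            raise ValueError("min_recovered_length must be smaller than primer spacing")


@dataclass
class GroundTruth:
    """What the simulator planted: per-position modification probabilities."""

    transcript: TranscriptRef
    structure: SecondaryStructure
    accessible: frozenset[int]          # unpaired A/C positions
    mod_prob: np.ndarray = field(repr=False, default=None)  # index 1..length
    panel: PrimerPanel = None

    def to_tsv(self, path: str | Path) -> None:
        paired = {p for ij in self.structure.pairs for p in ij}
        with open(path, "w") as fh:
            fh.write("position\tbase\tpaired\taccessible\tmod_prob\n")
            for i in range(1, self.transcript.length + 1):
                fh.write(f"{i}\t{self.transcript.base(i)}\t{int(i in paired)}\t"
                         f"{int(i in self.accessible)}\t{self.mod_prob[i]:.6g}\n")


_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}


def _plant_hairpins(length: int, rng: np.random.Generator,
                    stem: int = 8, loop: int = 6, spacing: int = 60
                    ) -> tuple[str, list[tuple[int, int]]]:
    """Random sequence with Watson-Crick hairpins written in every `spacing` nt."""
    seq = list(rng.choice(list("ACGU"), size=length))
    pairs: list[tuple[int, int]] = []
    unit = 2 * stem + loop
    start = 10
    while start + unit - 1 <= length - 10:
        # A/C-rich loop so accessible positions are informative for reactivity
        for k in range(loop):
            seq[start - 1 + stem + k] = rng.choice(list("ACAC"))
        for k in range(stem):
            i = start + k
            j = start + unit - 1 - k
            seq[j - 1] = _COMPLEMENT[seq[i - 1]]
            pairs.append((i, j))
        start += spacing
    return "".join(seq), sorted(pairs)


def default_panel(length: int, spacing: int = 200, width: int = 20) -> PrimerPanel:
    """Primers every `spacing` nt along the transcript, 3'-most first omitted
    edge effects aside; annealing intervals are `width` nt wide."""
    entries = []
    k = 1
    start = spacing
    while start + width - 1 <= length:
        entries.append(PrimerEntry(name=f"P{k:02d}", start=start, end=start + width - 1,
                                   pool=f"pool{(k - 1) % 3 + 1}"))
        start += spacing
        k += 1
    if not entries:
        raise ValueError(f"transcript of length {length} too short for primer spacing {spacing}")
    return PrimerPanel(entries, transcript_length=length, min_pool_spacing=0)


def make_transcript(cfg: SimConfig, rng: np.random.Generator | None = None) -> GroundTruth:
    """Build the transcript, planted structure, and modification probabilities."""
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    if cfg.sequence is not None:
        seq = cfg.sequence.upper().replace("T", "U")
        if cfg.structure is not None:
            structure = cfg.structure
            for i, j in structure.pairs:
                if pair_type(seq[i - 1], seq[j - 1]) == 0:
                    raise ValueError(f"planted pair ({i},{j}) is not complementary "
                                     f"({seq[i - 1]}:{seq[j - 1]})")
        else:
            structure = SecondaryStructure(name="planted", length=len(seq), pairs=())
    else:
        seq, pairs = _plant_hairpins(cfg.length, rng)
        structure = SecondaryStructure(name="planted", length=len(seq), pairs=tuple(pairs))
    transcript = TranscriptRef(name="sim_transcript", sequence=seq)
    paired = {p for ij in structure.pairs for p in ij}
    accessible = frozenset(
        i for i in range(1, transcript.length + 1)
        if i not in paired and transcript.base(i) in "AC"
    )
    mod = np.zeros(transcript.length + 1)
    for i in range(1, transcript.length + 1):
        if i in accessible:
            mod[i] = cfg.p_hit * cfg.dose_scale
        elif cfg.ac_only and transcript.base(i) not in "AC":
            mod[i] = 0.0
        else:
            mod[i] = cfg.p_bg * cfg.dose_scale
    mod = np.clip(mod, 0.0, 1.0)
    panel = default_panel(transcript.length, cfg.primer_spacing, cfg.primer_width)
    return GroundTruth(transcript=transcript, structure=structure,
                       accessible=accessible, mod_prob=mod, panel=panel)


def simulate_reads(truth: GroundTruth, cfg: SimConfig, condition: str,
                   rng: np.random.Generator) -> list[AlignedRead]:
    """Draw reads per primer from the exact termination distribution of the
    3'->5' hazard walk (categorical sampling over stop positions)."""
    if condition not in (TREATED, UNTREATED):
        raise ValueError(f"condition must be {TREATED!r} or {UNTREATED!r}")
    reads: list[AlignedRead] = []
    hazard_base = np.full(truth.transcript.length + 1, cfg.p_spont)
    if condition == TREATED:
        hazard_base = np.clip(hazard_base + truth.mod_prob, 0.0, 1.0)
    for entry in truth.panel:
        first = entry.start - 1  # first template position copied after the primer
        if first < 1:
            continue
        h = hazard_base[: first + 1].copy()  # hazard at positions 0..first (0 unused)
        # P(stop at t) = h(t) * prod_{k>t} (1 - h(k)); t = 0 collects run-off
        surv = np.cumprod(1.0 - h[1 : first + 1][::-1])[::-1]  # survival through t+1..first
        probs = np.zeros(first + 1)
        probs[1:first] = h[1:first] * surv[1:]
        probs[first] = h[first]
        probs[0] = surv[0]  # read off the 5' end
        probs /= probs.sum()
        stops = rng.choice(first + 1, size=cfg.reads_per_primer, p=probs)
        for idx, t in enumerate(stops):
            a = int(t) + 1
            b = first
            if b - a + 1 < cfg.min_recovered_length:
                continue
            mm = 0
            if cfg.mismatch_rate > 0:
                mm = int(rng.binomial(b - a + 1, cfg.mismatch_rate))
            reads.append(AlignedRead(
                read_id=f"{condition}:{entry.name}:{idx}",
                transcript=truth.transcript.name,
                start=a, end=b, aligned_length=b - a + 1,
                mismatches=mm, weight=1.0, primer=entry.name))
    return reads


def reads_to_sam(reads: list[AlignedRead], truth: GroundTruth, path: str | Path) -> None:
    """Write simulated alignments as plain-text SAM (NM and NH tags included)."""
    import pysam

    header = {"HD": {"VN": "1.6", "SO": "unsorted"},
              "SQ": [{"SN": truth.transcript.name, "LN": truth.transcript.length}]}
    dna = truth.transcript.sequence.replace("U", "T")
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for read in reads:
            a = pysam.AlignedSegment(fh.header)
            a.query_name = read.read_id
            a.reference_id = 0
            a.reference_start = read.start - 1
            a.mapping_quality = 42
            seq = dna[read.start - 1: read.end]
            a.query_sequence = seq
            a.cigarstring = f"{len(seq)}M"
            a.flag = 0
            a.set_tag("NM", read.mismatches or 0)
            a.set_tag("NH", 1)
            fh.write(a)


def reads_to_fastq(reads: list[AlignedRead], truth: GroundTruth, path: str | Path,
                   prefix: str = "NNN") -> None:
    """Raw-read export: cDNA sequences with the random trinucleotide prefix,
    for exercising the pre-alignment clipping step."""
    dna = truth.transcript.sequence.replace("U", "T")
    comp = str.maketrans("ACGT", "TGCA")
    with open(path, "w") as fh:
        for read in reads:
            template = dna[read.start - 1: read.end]
            cdna = template.translate(comp)[::-1]
            seq = prefix + cdna
            fh.write(f"@{read.read_id}\n{seq}\n+\n{'I' * len(seq)}\n")


def run_experiment(cfg: SimConfig) -> tuple[GroundTruth, list[AlignedRead], list[AlignedRead]]:
    """Convenience wrapper: transcript plus treated and untreated read sets."""
    rng = np.random.default_rng(cfg.seed)
    truth = make_transcript(cfg, rng)
    treated = simulate_reads(truth, cfg, TREATED, rng)
    untreated = simulate_reads(truth, cfg, UNTREATED, rng)
    return truth, treated, untreated
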