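"""From sequencing reads to per-position termination and read-through counts.

The RT-stop convention: reverse transcription proceeds 3'->5' along the RNA
template, so a cDNA whose alignment starts at transcript position ``a``
implies the polymerase failed to copy position ``t = a - 1`` (the position
where it would have added the next base). ``t = 0`` means the read ran off
the 5' end of the transcript and contributes no termination event.

All transcript coordinates are 1-based and inclusive.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

log = logging.getLogger(__name__)

#: 5' adaptor carried by every RT primer in the panel
DEFAULT_ADAPTOR = "CAGACGTGTGCTCT"


@dataclass(frozen=True)
class TranscriptRef:
    """A probed RNA: name plus sequence over {A, C, G, U} (1-based positions)."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper().replace("T", "U")
        bad = set(seq) - set("ACGU")
        if bad:
            raise ValueError(f"transcript {self.name!r} has non-ACGU characters: {sorted(bad)}")
        object.__setattr__(self, "sequence", seq)

    @property
    def length(self) -> int:
        return len(self.sequence)

    def base(self, i: int) -> str:
        return self.sequence[i - 1]

    @classmethod
    def from_fasta(cls, path: str | Path, name: str | None = None) -> "TranscriptRef":
        from Bio import SeqIO

        for rec in SeqIO.parse(str(path), "fasta"):
            if name is None or rec.id == name:
                return cls(name=rec.id, sequence=str(rec.seq))
        raise ValueError(f"transcript {name!r} not found in {path}")


@dataclass(frozen=True)
class PrimerEntry:
    """One RT primer: its annealing interval on the transcript and pool label."""

    name: str
    start: int  # annealing interval, 1-based inclusive
    end: int
    pool: str = ""
    adaptor: str = DEFAULT_ADAPTOR

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"primer {self.name!r}: bad annealing interval [{self.start},{self.end}]")

    def distance_to(self, position: int) -> int:
        """Distance from a transcript position to the read-proximal (5') edge
        of the annealing site; 0 for positions inside the annealing interval."""
        if position < self.start:
            return self.start - position
        if position > self.end:
            return position - self.end
        return 0


class PrimerPanel:
    """An ordered collection of RT primers targeting one transcript."""

    def __init__(self, entries: Sequence[PrimerEntry], transcript_length: int | None = None,
                 min_pool_spacing: int = 500) -> None:
        self.entries = list(entries)
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("duplicate primer names in panel")
        if transcript_length is not None:
            for e in self.entries:
                if e.end > transcript_length:
                    raise ValueError(
                        f"primer {e.name!r} interval [{e.start},{e.end}] exceeds "
                        f"transcript length {transcript_length}")
        by_pool: dict[str, list[PrimerEntry]] = {}
        for e in self.entries:
            by_pool.setdefault(e.pool, []).append(e)
        for pool, group in by_pool.items():
            group = sorted(group, key=lambda e: e.start)
            for prev, nxt in zip(group, group[1:]):
                if nxt.start - prev.end < min_pool_spacing:
                    warnings.warn(
                        f"primers {prev.name!r} and {nxt.name!r} in pool {pool!r} are "
                        f"{nxt.start - prev.end} nt apart (< {min_pool_spacing} nt)",
                        stacklevel=2)

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, name: str) -> PrimerEntry:
        for e in self.entries:
            if e.name == name:
                return e
        raise KeyError(name)

    @classmethod
    def from_tsv(cls, path: str | Path, transcript_length: int | None = None) -> "PrimerPanel":
        import pandas as pd

        df = pd.read_csv(path, sep="\t", dtype={"name": str, "pool": str})
        entries = [
            PrimerEntry(name=row["name"], start=int(row["start"]), end=int(row["end"]),
                        pool=str(row.get("pool", "")),
                        adaptor=str(row.get("adaptor", DEFAULT_ADAPTOR)))
            for _, row in df.iterrows()
        ]
        return cls(entries, transcript_length=transcript_length)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("name\tstart\tend\tpool\tadaptor\n")
            for e in self.entries:
                fh.write(f"{e.name}\t{e.start}\t{e.end}\t{e.pool}\t{e.adaptor}\n")


@dataclass(frozen=True)
class AlignedRead:
    """A local alignment of one cDNA read to the transcript."""

    read_id: str
    transcript: str
    start: int  # 1-based inclusive, 5'-most aligned transcript position
    end: int
    aligned_length: int
    mismatches: int | None = None
    weight: float = 1.0  # 1/k for a read reported at k alignment sites
    primer: str | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"read {self.read_id!r}: start > end")
        if not (0.0 < self.weight <= 1.0):
            raise ValueError(f"read {self.read_id!r}: weight {self.weight} outside (0, 1]")

    @property
    def termination(self) -> int:
        """Inferred RT-stop position (0 = full-length run-off past position 1)."""
        return self.start - 1


def infer_termination(read: AlignedRead) -> int:
    """RT-stop position for a read: the transcript base the RT failed to copy."""
    return read.termination


@dataclass
class TerminationCounts:
    """Weighted RT-stop (n) and read-through (r) tallies for one primer/condition."""

    transcript: str
    condition: str
    primer: str
    length: int
    n: np.ndarray = field(repr=False, default=None)  # index 1..length; [0] unused
    r: np.ndarray = field(repr=False, default=None)
    excluded: np.ndarray = field(repr=False, default=None)  # primer-proximal mask
    total_weight: float = 0.0

    def __post_init__(self) -> None:
        if self.n is None:
            self.n = np.zeros(self.length + 1)
        if self.r is None:
            self.r = np.zeros(self.length + 1)
        if self.excluded is None:
            self.excluded = np.zeros(self.length + 1, dtype=bool)

    def __add__(self, other: "TerminationCounts") -> "TerminationCounts":
        if (self.transcript, self.condition, self.primer, self.length) != (
                other.transcript, other.condition, other.primer, other.length):
            raise ValueError("cannot add counts from different transcript/condition/primer")
        out = TerminationCounts(self.transcript, self.condition, self.primer, self.length)
        out.n = self.n + other.n
        out.r = self.r + other.r
        out.excluded = self.excluded | other.excluded
        out.total_weight = self.total_weight + other.total_weight
        return out


# ---------------------------------------------------------------------------
# raw-read clipping
# ---------------------------------------------------------------------------

def clip_reads(records: Iterable, n_clip: int = 3) -> tuple[list, int]:
    """Remove the fixed NNN prefix (random trinucleotide) from raw reads.

    Accepts Bio.SeqRecord objects or (id, seq, qual) tuples; reads shorter
    than ``n_clip + 1`` are skipped. Returns (clipped records, skip count).
    """
    out = []
    skipped = 0
    for rec in records:
        if isinstance(rec, tuple):
            rid, seq, qual = rec
            if len(seq) < n_clip + 1:
                skipped += 1
                continue
            out.append((rid, seq[n_clip:], qual[n_clip:] if qual is not None else None))
        else:
            if len(rec.seq) < n_clip + 1:
                skipped += 1
                continue
            out.append(rec[n_clip:])  # SeqRecord slicing clips qualities in lockstep
    if skipped:
        log.info("clip_reads: skipped %d reads shorter than %d nt", skipped, n_clip + 1)
    return out, skipped


def clip_fastq(in_path: str | Path, out_path: str | Path, n_clip: int = 3) -> int:
    """Clip a FASTQ file on disk; returns the number of skipped reads."""
    from Bio import SeqIO

    records = SeqIO.parse(str(in_path), "fastq")
    clipped, skipped = clip_reads(records, n_clip=n_clip)
    SeqIO.write(clipped, str(out_path), "fastq")
    return skipped


# ---------------------------------------------------------------------------
# alignment ingestion and filtering
# ---------------------------------------------------------------------------

def read_sam(path: str | Path, transcript: str | None = None) -> list[AlignedRead]:
    """Load local alignments from SAM/BAM into AlignedRead records.

    Aligned length is the reference span minus deletions (soft clips never
    count); mismatches come from the NM tag; multi-mapping weight is 1/NH
    when the NH tag is present, otherwise the read is treated as unique.
    """
    import pysam

    reads: list[AlignedRead] = []
    n_untagged = 0
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for aln in fh:
            # secondary records are kept: each alignment site of a multi-mapped
            # read receives weight 1/NH so the read's total weight stays 1
            if aln.is_unmapped:
                continue
            if transcript is not None and aln.reference_name != transcript:
                continue
            match_len = sum(l for op, l in (aln.cigartuples or ()) if op in (0, 7, 8))
            nm = aln.get_tag("NM") if aln.has_tag("NM") else None
            if aln.has_tag("NH"):
                k = int(aln.get_tag("NH"))
            else:
                k = 1
                n_untagged += 1
            reads.append(AlignedRead(
                read_id=aln.query_name,
                transcript=aln.reference_name,
                start=aln.reference_start + 1,
                end=aln.reference_end,  # pysam end is 0-based exclusive == 1-based inclusive
                aligned_length=match_len,
                mismatches=int(nm) if nm is not None else None,
                weight=1.0 / k,
            ))
    if n_untagged:
        log.debug("read_sam: %d alignments without NH tag treated as unique", n_untagged)
    return reads


def filter_alignments(reads: Iterable[AlignedRead], min_len: int = 60,
                      max_mismatch: int = 2, tally: Counter | None = None) -> list[AlignedRead]:
    """Keep reads with aligned length >= min_len and <= max_mismatch mismatches.

    Reads with no mismatch information are discarded under their own tally.
    Pass a Counter as ``tally`` to collect per-reason discard counts.
    """
    kept: list[AlignedRead] = []
    counts = tally if tally is not None else Counter()
    for read in reads:
        if read.mismatches is None:
            counts["missing_mismatch_field"] += 1
        elif read.aligned_length < min_len:
            counts["too_short"] += 1
        elif read.mismatches > max_mismatch:
            counts["too_many_mismatches"] += 1
        else:
            kept.append(read)
    if tally is None and counts:
        log.info("filter_alignments: discarded %s", dict(counts))
    return kept


def assign_primers(reads: Iterable[AlignedRead], panel: PrimerPanel,
                   slack: int = 5) -> tuple[list[AlignedRead], int]:
    """Assign each read to the primer whose annealing interval its 3'-cDNA
    (high-coordinate) end overlaps or abuts within ``slack`` nt.

    Unassignable reads are off-target and dropped. Returns (assigned, dropped).
    """
    assigned: list[AlignedRead] = []
    dropped = 0
    for read in reads:
        best: PrimerEntry | None = None
        best_d = slack + 1
        for entry in panel:
            # read end should sit just 5' of (or within) the annealing site
            if read.end > entry.end + slack:
                continue
            d = max(0, entry.start - 1 - read.end)
            if d < best_d:
                best, best_d = entry, d
        if best is None:
            dropped += 1
        else:
            assigned.append(AlignedRead(
                read_id=read.read_id, transcript=read.transcript, start=read.start,
                end=read.end, aligned_length=read.aligned_length,
                mismatches=read.mismatches, weight=read.weight, primer=best.name))
    if dropped:
        log.info("assign_primers: dropped %d off-target reads", dropped)
    return assigned, dropped


def accumulate_counts(reads: Iterable[AlignedRead], primer: PrimerEntry, condition: str,
                      transcript_length: int, primer_exclusion: int = 25,
                      transcript: str = "") -> TerminationCounts:
    """Tally weighted termination (n) and read-through (r) events for one primer.

    ``n(i)`` sums read weights with RT stop at i; ``r(i)`` sums weights of reads
    covering i, restricted to positions strictly more than ``primer_exclusion``
    nt from the primer annealing site (closer positions are flagged and zeroed).
    Reads extending outside the transcript are discarded with a tally.
    """
    tc = TerminationCounts(transcript=transcript, condition=condition,
                           primer=primer.name, length=transcript_length)
    # mask of positions too close to (or inside) the annealing site
    pos = np.arange(transcript_length + 1)
    dist = np.where(pos < primer.start, primer.start - pos,
                    np.where(pos > primer.end, pos - primer.end, 0))
    tc.excluded = dist <= primer_exclusion
    tc.excluded[0] = True
    n_oob = 0
    for read in reads:
        if read.start < 1 or read.end > transcript_length:
            n_oob += 1
            continue
        t = read.termination
        if t >= 1:
            tc.n[t] += read.weight
        cover = slice(read.start, read.end + 1)
        tc.r[cover] += read.weight
        tc.total_weight += read.weight
    tc.r[tc.excluded] = 0.0
    if n_oob:
        log.info("accumulate_counts: discarded %d reads outside transcript bounds", n_oob)
    return tc


def counts_to_tsv(counts: Iterable[TerminationCounts], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("transcript\tposition\tcondition\tprimer\tn\tr\texcluded_flag\n")
        for tc in counts:
            for i in range(1, tc.length + 1):
                fh.write(f"{tc.transcript}\t{i}\t{tc.condition}\t{tc.primer}\t"
                         f"{tc.n[i]:.6g}\t{tc.r[i]:.6g}\t{int(tc.excluded[i])}\n")
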