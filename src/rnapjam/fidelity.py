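"""Mismatch-rate pipeline for estimating transcription fidelity from reads.

The cascade mirrors a conservative RNA-seq error-counting protocol:

1. reject raw reads containing homopolymer runs of five or more;
2. trim 20 nt from each end (135-nt reads become 95-nt cores);
3. reject reads on quality (mean phred >= 25, minimum phred >= 15);
4. map survivors to the reference with an exhaustive ungapped mapper that
   keeps only unique best placements with at most 6 mismatches;
5. tally every aligned base against the reference, position by position.

The headline metric is the per-base mismatch percentage; because real
reads mix transcription, reverse-transcription and sequencing errors the
pipeline reports per-read means and the fraction of reads carrying at
least one mismatch as well, so either convention can be compared.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO

__all__ = [
    "Read",
    "Alignment",
    "MismatchReport",
    "Mapper",
    "filter_homopolymer",
    "trim_reads",
    "quality_filter",
    "map_reads",
    "tally_mismatches",
    "run_pipeline",
    "read_fastq",
    "read_fasta",
]

logger = logging.getLogger(__name__)

_LUT = np.zeros(256, np.uint8)
for _i, _b in enumerate(b"ACGTN"):
    _LUT[_b] = _i  # A..T -> 0..3, N -> 4
_N = 4


@dataclass(frozen=True)
class Read:
    """A sequencing read: DNA over {A,C,G,T,N} plus per-base phred scores."""

    id: str
    sequence: str
    qualities: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError(f"read {self.id}: sequence/quality length mismatch")
        if any(q < 0 for q in self.qualities):
            raise ValueError(f"read {self.id}: negative phred score")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def codes(self) -> np.ndarray:
        return _LUT[np.frombuffer(self.sequence.encode(), dtype=np.uint8)]


@dataclass(frozen=True)
class Alignment:
    """Ungapped placement of a read on the reference (0-based start)."""

    read_id: str
    ref_start: int
    strand: str  # '+' or '-'
    n_mismatches: int
    mismatch_read_positions: tuple[int, ...]  # 1-based positions in the read
    aligned_bases: int  # read length minus N-excluded positions


@dataclass
class MismatchReport:
    """Aggregate mismatch statistics plus per-stage read accounting."""

    total_aligned_bases: int
    total_mismatches: int
    per_base_rate: float  # percent
    per_read_mean: float  # mean mismatches per aligned read
    reads_with_mismatch_fraction: float  # percent
    n_aligned_reads: int
    stage_counts: dict[str, int] = field(default_factory=dict)

    def to_tsv(self, path) -> None:
        lines = ["metric\tvalue"]
        for k in (
            "total_aligned_bases",
            "total_mismatches",
            "per_base_rate",
            "per_read_mean",
            "reads_with_mismatch_fraction",
            "n_aligned_reads",
        ):
            lines.append(f"{k}\t{getattr(self, k)}")
        for stage, count in self.stage_counts.items():
            lines.append(f"reads_after_{stage}\t{count}")
        Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# filters


def _longest_run(seq: str) -> int:
    best = run = 1
    prev = ""
    for c in seq:
        run = run + 1 if c == prev else 1
        prev = c
        best = max(best, run)
    return best if seq else 0


def filter_homopolymer(reads: list[Read], max_run: int = 4) -> list[Read]:
    """Reject reads whose longest single-nucleotide run is ``max_run + 1``
    or more (default: runs of five or more, e.g. TTTTT).  Applied to the
    raw, untrimmed sequence."""
    return [r for r in reads if _longest_run(r.sequence) <= max_run]


def trim_reads(
    reads: list[Read],
    head: int = 20,
    tail: int = 20,
    expect_len: int | None = 95,
) -> list[Read]:
    """Trim ``head``/``tail`` bases off sequence and qualities alike.

    Reads too short to leave at least one base are dropped (and counted in
    the pipeline's stage log); a warning is emitted when a trimmed length
    differs from ``expect_len``.
    """
    out = []
    oddballs = 0
    for r in reads:
        if len(r) <= head + tail:
            continue
        t = Read(r.id, r.sequence[head : len(r) - tail], r.qualities[head : len(r) - tail])
        if expect_len is not None and len(t) != expect_len:
            oddballs += 1
        out.append(t)
    if oddballs:
        warnings.warn(
            f"{oddballs} reads trimmed to a length != {expect_len}", stacklevel=2
        )
    return out


def quality_filter(reads: list[Read], min_mean_q: float = 25, min_q: int = 15) -> list[Read]:
    """Keep reads with mean phred >= ``min_mean_q`` and min phred >= ``min_q``."""
    return [
        r
        for r in reads
        if np.mean(r.qualities) >= min_mean_q and min(r.qualities) >= min_q
    ]


# ---------------------------------------------------------------------------
# mapping


class Mapper:
    """Exhaustive ungapped mapper over a small reference.

    Scores every placement on both strands by mismatch count (N positions
    on either side are wildcards) and reports a read only when a single
    best placement with at most ``max_mismatches`` exists; ties are
    discarded as ambiguous.  Correctness over speed: intended for
    synthetic references up to ~100 kb.
    """

    def __init__(self, reference: str, max_mismatches: int = 6):
        if not reference:
            raise ValueError("empty reference")
        self.reference = reference.upper()
        self.max_mismatches = max_mismatches
        self._ref = _LUT[np.frombuffer(self.reference.encode(), dtype=np.uint8)]
        self._windows: dict[int, np.ndarray] = {}
        self._ref_is_n = self._ref == _N

    def _window_view(self, read_len: int) -> np.ndarray:
        if read_len not in self._windows:
            if read_len > self._ref.size:
                raise ValueError("reference shorter than read")
            self._windows[read_len] = np.lib.stride_tricks.sliding_window_view(
                self._ref, read_len
            )
        return self._windows[read_len]

    def _scan(self, codes: np.ndarray) -> np.ndarray:
        win = self._window_view(codes.size)
        informative = (codes != _N) & (win != _N)
        return ((win != codes) & informative).sum(axis=1)

    def map(self, read: Read) -> Alignment | None:
        codes = read.codes
        # reverse complement in code space; N stays N
        rc = np.where(codes[::-1] == _N, _N, 3 - codes[::-1])
        mm_fwd = self._scan(codes)
        mm_rev = self._scan(rc)
        best_f, best_r = int(mm_fwd.min()), int(mm_rev.min())
        best = min(best_f, best_r)
        if best > self.max_mismatches:
            return None
        n_ties = int((mm_fwd == best).sum()) + int((mm_rev == best).sum())
        if n_ties != 1:
            return None
        if best_f <= best_r:
            start = int(np.argmin(mm_fwd))
            aligned = codes
            strand = "+"
        else:
            start = int(np.argmin(mm_rev))
            aligned = rc
            strand = "-"
        win = self._ref[start : start + codes.size]
        informative = (aligned != _N) & (win != _N)
        mism = np.nonzero((win != aligned) & informative)[0]
        if strand == "+":
            read_pos = tuple(int(p) + 1 for p in mism)
        else:
            read_pos = tuple(int(codes.size - p) for p in mism[::-1])
        return Alignment(
            read_id=read.id,
            ref_start=start,
            strand=strand,
            n_mismatches=int(mism.size),
            mismatch_read_positions=read_pos,
            aligned_bases=int(informative.sum()),
        )


def map_reads(
    reads: list[Read], reference: str, max_mismatches: int = 6
) -> tuple[list[Alignment], int]:
    """Map reads; returns (alignments, number discarded as unmapped/ambiguous)."""
    mapper = Mapper(reference, max_mismatches)
    alignments = []
    dropped = 0
    for r in reads:
        a = mapper.map(r)
        if a is None:
            dropped += 1
        else:
            alignments.append(a)
    return alignments, dropped


# ---------------------------------------------------------------------------
# tallying and the full cascade


def tally_mismatches(
    alignments: list[Alignment],
    reference: str | None = None,
    stage_counts: dict[str, int] | None = None,
) -> MismatchReport:
    """Aggregate per-base and per-read mismatch statistics.

    N bases were excluded from both numerator and denominator at mapping
    time (``aligned_bases``); ``reference`` is accepted for interface
    symmetry but the counts are carried on the alignments.
    """
    bases = sum(a.aligned_bases for a in alignments)
    mism = sum(a.n_mismatches for a in alignments)
    n_reads = len(alignments)
    with_mm = sum(1 for a in alignments if a.n_mismatches > 0)
    return MismatchReport(
        total_aligned_bases=bases,
        total_mismatches=mism,
        per_base_rate=100.0 * mism / bases if bases else float("nan"),
        per_read_mean=mism / n_reads if n_reads else float("nan"),
        reads_with_mismatch_fraction=100.0 * with_mm / n_reads if n_reads else float("nan"),
        n_aligned_reads=n_reads,
        stage_counts=dict(stage_counts or {}),
    )


def run_pipeline(
    reads: list[Read],
    reference: str,
    max_run: int = 4,
    head: int = 20,
    tail: int = 20,
    expect_len: int | None = 95,
    min_mean_q: float = 25,
    min_q: int = 15,
    max_mismatches: int = 6,
) -> tuple[MismatchReport, list[Read]]:
    """Full cascade: homopolymer filter -> trim -> quality filter -> map ->
    tally.  Returns the report and the filtered (pre-mapping) reads."""
    counts = {"input": len(reads)}
    kept = filter_homopolymer(reads, max_run=max_run)
    counts["homopolymer_filter"] = len(kept)
    kept = trim_reads(kept, head=head, tail=tail, expect_len=expect_len)
    counts["trim"] = len(kept)
    kept = quality_filter(kept, min_mean_q=min_mean_q, min_q=min_q)
    counts["quality_filter"] = len(kept)
    alignments, dropped = map_reads(kept, reference, max_mismatches=max_mismatches)
    counts["mapped"] = len(alignments)
    for stage, n in counts.items():
        logger.info("stage %s: %d reads", stage, n)
    if dropped:
        logger.info("unmapped/ambiguous: %d reads", dropped)
    report = tally_mismatches(alignments, reference, stage_counts=counts)
    if report.total_aligned_bases == 0:
        warnings.warn("no aligned bases survive the cascade; rates undefined", stacklevel=2)
    return report, kept


# ---------------------------------------------------------------------------
# I/O


def read_fastq(path) -> list[Read]:
    return [
        Read(rec.id, str(rec.seq).upper(), tuple(rec.letter_annotations["phred_quality"]))
        for rec in SeqIO.parse(str(path), "fastq")
    ]


def read_fasta(path) -> str:
    recs = list(SeqIO.parse(str(path), "fasta"))
    if not recs:
        raise ValueError(f"no sequences in {path}")
    return str(recs[0].seq).upper()


def write_fastq(reads: list[Read], path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    recs = []
    for r in reads:
        rec = SeqRecord(Seq(r.sequence), id=r.id, description="")
        rec.letter_annotations["phred_quality"] = list(r.qualities)
        recs.append(rec)
    SeqIO.write(recs, str(path), "fastq")
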