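"""Quality trimming and best-single-placement read mapping.

The mapping contract mirrors the study's use of a short-read mapper plus SAM
post-filtering: all transcripts are indexed simultaneously, each read is
assigned to at most one transcript (its single highest-scoring ungapped
placement), placements shorter than ``min_mapped_length`` aligned bases
(default 12) or above ``max_mismatch_rate`` are rejected, and reverse-strand
placements are recorded with the read bases already complemented into
transcript orientation.

Candidate placements are found by exact ``seed_kmer`` matches on both strands
and extended without gaps over the whole read (the simulator emits no
indels). Scores are matches minus mismatches; ties break to the lowest
transcript identifier, then the lowest start, then the forward strand.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pysam

from ._util import phred_error_probs, revcomp, seq_to_array
from .synth import Read


@dataclass(frozen=True)
class TrimConfig:
    """Quality-trim settings: maximum tolerated per-base error probability."""

    error_probability_threshold: float = 0.001

    def __post_init__(self) -> None:
        if not 0.0 < self.error_probability_threshold < 1.0:
            raise ValueError("error_probability_threshold must lie in (0, 1)")


@dataclass(frozen=True)
class MappingRecord:
    """Placement of one read on exactly one transcript.

    ``start`` is a 0-based transcript offset; ``aligned_bases`` is the read
    segment in transcript orientation (reverse-strand reads complemented),
    clipped to the transcript, so ``aligned_bases`` lines up with
    ``transcript[start : start + mapped_length]``. ``read_offset`` is where
    that segment begins within the oriented read.
    """

    read_id: str
    transcript_id: str
    start: int
    strand: str  # '+' or '-'
    mapped_length: int
    mismatches: int
    score: int
    read_offset: int
    aligned_bases: str


@dataclass
class MappingResult:
    records: list[MappingRecord]
    n_unmapped: int

    @property
    def n_mapped(self) -> int:
        return len(self.records)


def quality_trim(read: Read, trim_config: TrimConfig) -> Read | None:
    """Longest contiguous segment whose bases all meet the error threshold.

    Ties break leftmost; a read with no acceptable base is discarded (None).
    """
    if len(read.quality) != len(read.sequence):
        raise ValueError("quality string length differs from sequence length")
    good = phred_error_probs(read.quality) <= trim_config.error_probability_threshold
    if good.all():
        return read
    best_start, best_len, run_start = 0, 0, None
    for i, ok in enumerate(np.append(good, False)):
        if ok and run_start is None:
            run_start = i
        elif not ok and run_start is not None:
            if i - run_start > best_len:
                best_start, best_len = run_start, i - run_start
            run_start = None
    if best_len == 0:
        return None
    return Read(
        read.read_id,
        read.sequence[best_start : best_start + best_len],
        read.quality[best_start : best_start + best_len],
    )


class _Index:
    """Exact k-mer index over the forward strand of all transcripts."""

    def __init__(self, transcripts: dict[str, str], k: int):
        self.k = k
        self.ids = sorted(transcripts)
        self.seqs = [transcripts[t] for t in self.ids]
        self.arrays = [seq_to_array(s) for s in self.seqs]
        self.lookup: dict[str, list[tuple[int, int]]] = {}
        for ti, seq in enumerate(self.seqs):
            for pos in range(len(seq) - k + 1):
                self.lookup.setdefault(seq[pos : pos + k], []).append((ti, pos))


def map_reads(
    reads: Iterable[Read],
    transcripts: dict[str, str],
    min_mapped_length: int = 12,
    seed_kmer: int = 16,
    max_mismatch_rate: float = 0.10,
) -> MappingResult:
    """Map each read to its single best transcript placement, or nowhere."""
    if not transcripts:
        raise ValueError("no transcripts to map against")
    index = _Index(transcripts, seed_kmer)
    k = seed_kmer
    records: list[MappingRecord] = []
    n_unmapped = 0
    for read in reads:
        oriented = {"+": read.sequence, "-": revcomp(read.sequence)}
        arrays = {s: seq_to_array(q) for s, q in oriented.items()}
        lr = len(read.sequence)
        candidates: set[tuple[int, int, str]] = set()
        if lr >= k:
            seed_offs = list(range(0, lr - k + 1, k))
            if seed_offs[-1] != lr - k:
                seed_offs.append(lr - k)
            for strand, seq in oriented.items():
                for soff in seed_offs:
                    for ti, tpos in index.lookup.get(seq[soff : soff + k], ()):
                        candidates.add((ti, tpos - soff, strand))
        best: tuple[tuple, MappingRecord] | None = None
        for ti, diag, strand in candidates:
            tarr = index.arrays[ti]
            a = max(0, diag)
            b = min(len(tarr), diag + lr)
            mapped_length = b - a
            if mapped_length < min_mapped_length:
                continue
            rarr = arrays[strand][a - diag : b - diag]
            mism = int(np.count_nonzero(tarr[a:b] != rarr))
            if mism > max_mismatch_rate * mapped_length:
                continue
            score = mapped_length - 2 * mism
            rec = MappingRecord(
                read_id=read.read_id,
                transcript_id=index.ids[ti],
                start=a,
                strand=strand,
                mapped_length=mapped_length,
                mismatches=mism,
                score=score,
                read_offset=a - diag,
                aligned_bases=oriented[strand][a - diag : b - diag],
            )
            key = (-score, index.ids[ti], a, strand == "-")
            if best is None or key < best[0]:
                best = (key, rec)
        if best is None:
            n_unmapped += 1
        else:
            records.append(best[1])
    return MappingResult(records=records, n_unmapped=n_unmapped)


def write_sam(
    result: MappingResult,
    transcripts: dict[str, str],
    path: str,
    unmapped_reads: Sequence[Read] = (),
) -> None:
    """Write mappings as SAM with soft-clips for transcript-edge overhangs."""
    ids = sorted(transcripts)
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": t, "LN": len(transcripts[t])} for t in ids],
    }
    tid_of = {t: i for i, t in enumerate(ids)}
    with pysam.AlignmentFile(path, "w", header=header) as sam:
        for rec in result.records:
            a = pysam.AlignedSegment(sam.header)
            a.query_name = rec.read_id
            a.flag = 16 if rec.strand == "-" else 0
            a.reference_id = tid_of[rec.transcript_id]
            a.reference_start = rec.start
            a.mapping_quality = 255
            # the stored sequence is the aligned (clipped, oriented) segment
            a.query_sequence = rec.aligned_bases
            a.cigar = [(0, rec.mapped_length)]
            a.set_tag("NM", rec.mismatches)
            a.set_tag("AS", rec.score)
            sam.write(a)
        for read in unmapped_reads:
            a = pysam.AlignedSegment(sam.header)
            a.query_name = read.read_id
            a.flag = 4
            a.query_sequence = read.sequence
            a.query_qualities = pysam.qualitystring_to_array(read.quality)
            sam.write(a)


def read_sam(path: str) -> MappingResult:
    """Read a SAM produced by :func:`write_sam` back into mapping records."""
    records: list[MappingRecord] = []
    n_unmapped = 0
    with pysam.AlignmentFile(path, "r", check_sq=False) as sam:
        for a in sam:
            if a.is_unmapped:
                n_unmapped += 1
                continue
            mapped_length = sum(ln for op, ln in a.cigartuples if op == 0)
            offset = 0
            records.append(
                MappingRecord(
                    read_id=a.query_name,
                    transcript_id=a.reference_name,
                    start=a.reference_start,
                    strand="-" if a.is_reverse else "+",
                    mapped_length=mapped_length,
                    mismatches=int(a.get_tag("NM")) if a.has_tag("NM") else 0,
                    score=int(a.get_tag("AS")) if a.has_tag("AS") else 0,
                    read_offset=offset,
                    aligned_bases=a.query_sequence[offset : offset + mapped_length],
                )
            )
    return MappingResult(records=records, n_unmapped=n_unmapped)
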