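"""Six-frame ORF prediction and GC-content classification.

Assembled transcripts are 5'/3'-truncated, so an ORF is defined stop-to-stop
(no start codon required): the longest stop-free stretch across all six
reading frames, measured in nucleotides. GC content at or above 48% marks a
transcript as predominantly protein-coding; restricting the hypothesis
statistics to that subset is a robustness check against non-coding
transcripts.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq

from ._util import revcomp

GC_THRESHOLD = 0.48


@dataclass(frozen=True)
class CodingAssessment:
    transcript_id: str
    gc_fraction: float
    longest_orf_length: int
    orf_fraction: float
    passes_gc: bool


def gc_content(sequence: str) -> float:
    """(G+C)/(A+C+G+T); ambiguity codes excluded from both counts."""
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper()
    gc = seq.count("G") + seq.count("C")
    at = seq.count("A") + seq.count("T")
    if gc + at == 0:
        raise ValueError("sequence contains no unambiguous bases")
    return gc / (gc + at)


def _longest_stop_free(seq: str, frame: int) -> int:
    """Longest stop-free codon run in nucleotides for one forward frame (0-2)."""
    sub = seq[frame:]
    sub = sub[: len(sub) - len(sub) % 3]
    if not sub:
        return 0
    protein = str(Seq(sub).translate())
    best = max((len(run) for run in protein.split("*")), default=0)
    return 3 * best


def longest_orf(sequence: str) -> tuple[int, int]:
    """Length (nt) and frame (+1..+3 / -1..-3) of the longest stop-to-stop ORF.

    Ties break in frame order +1, +2, +3, -1, -2, -3.
    """
    seq = sequence.upper()
    rc = revcomp(seq)
    best_len, best_frame = 0, 1
    for strand in (1, -1):
        for frame in range(3):
            length = _longest_stop_free(seq if strand == 1 else rc, frame)
            if length > best_len:
                best_len, best_frame = length, strand * (frame + 1)
    return best_len, best_frame


def assess(
    transcripts: dict[str, str], gc_threshold: float = GC_THRESHOLD
) -> list[CodingAssessment]:
    """CodingAssessment for every transcript, sorted by identifier."""
    out = []
    for tid in sorted(transcripts):
        seq = transcripts[tid]
        gc = gc_content(seq)
        orf_len, _ = longest_orf(seq)
        out.append(
            CodingAssessment(
                transcript_id=tid,
                gc_fraction=gc,
                longest_orf_length=orf_len,
                orf_fraction=orf_len / len(seq) if seq else 0.0,
                passes_gc=gc >= gc_threshold,
            )
        )
    return out


def coding_subset(assessments: list[CodingAssessment]) -> set[str]:
    """Identifiers of transcripts passing the GC threshold."""
    return {a.transcript_id for a in assessments if a.passes_gc}
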