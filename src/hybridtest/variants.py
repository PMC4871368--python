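"""Pileups, frequency-threshold SNP calling, and per-locus SNP rates.

A SNP is called at a position where enough reads cover it and the most
frequent non-reference base reaches the minimum variant frequency (default
10%, the conservative evidence threshold for two alleles being present).
The number of calls per transcript, normalized by transcript length, gives
the SNP rate per nucleotide; a transcript with no calls is SNP-free.

No strand-bias filter is applied, but forward/reverse variant read counts
are recorded for diagnostics. Positions are reported 1-based; internal
arithmetic is 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np

from ._util import BASES, base_index_array
from .mapping import MappingRecord


class DataIntegrityError(ValueError):
    """A record refers to data that does not fit the references given."""


@dataclass
class PileupColumn:
    transcript_id: str
    position: int  # 1-based
    base_counts: dict[str, int]
    coverage: int


@dataclass
class TranscriptPileup:
    """Per-base read counts over one transcript, split by strand."""

    transcript_id: str
    forward: np.ndarray  # (4, L) counts
    reverse: np.ndarray  # (4, L) counts

    @property
    def counts(self) -> np.ndarray:
        return self.forward + self.reverse

    @property
    def coverage(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def columns(self) -> Iterator[PileupColumn]:
        counts = self.counts
        coverage = counts.sum(axis=0)
        for pos in np.nonzero(coverage)[0]:
            yield PileupColumn(
                transcript_id=self.transcript_id,
                position=int(pos) + 1,
                base_counts={
                    BASES[b]: int(counts[b, pos]) for b in range(4) if counts[b, pos]
                },
                coverage=int(coverage[pos]),
            )


@dataclass(frozen=True)
class SnpCall:
    """One called variant position.

    ``primary`` is the reference (transcript) base and ``variant`` the most
    frequent non-reference base; ``variant_frequency`` is variant reads over
    total coverage, so a cross-mapped divergent site where nearly all reads
    disagree with the reference approaches frequency 1.
    """

    transcript_id: str
    position: int  # 1-based
    primary: str
    variant: str
    coverage: int
    variant_frequency: float
    variant_forward: int = 0
    variant_reverse: int = 0


@dataclass(frozen=True)
class LocusDiversity:
    transcript_id: str
    length: int
    n_snps: int
    snp_rate: float
    snp_free: bool
    low_coverage: bool = False


def pileup(
    records: list[MappingRecord],
    transcripts: dict[str, str],
) -> dict[str, TranscriptPileup]:
    """Accumulate per-position base counts from mapping records.

    Reverse-strand records already carry complemented bases (mapping module
    contract). Every transcript gets a pileup, covered or not.
    """
    piles = {
        tid: TranscriptPileup(
            tid,
            np.zeros((4, len(seq)), dtype=np.int32),
            np.zeros((4, len(seq)), dtype=np.int32),
        )
        for tid, seq in transcripts.items()
    }
    for rec in records:
        pile = piles.get(rec.transcript_id)
        if pile is None:
            raise DataIntegrityError(f"unknown transcript {rec.transcript_id}")
        length = pile.forward.shape[1]
        if rec.start + rec.mapped_length > length:
            raise DataIntegrityError(
                f"{rec.read_id} extends past end of {rec.transcript_id}"
            )
        idx = base_index_array(rec.aligned_bases)
        valid = idx < 4
        positions = rec.start + np.nonzero(valid)[0]
        target = pile.forward if rec.strand == "+" else pile.reverse
        np.add.at(target, (idx[valid], positions), 1)
    return piles


def call_snps(
    piles: dict[str, TranscriptPileup],
    transcripts: dict[str, str],
    min_variant_frequency: float = 0.10,
    min_coverage: int = 8,
    min_variant_reads: int = 2,
) -> list[SnpCall]:
    """Emit one call per position passing coverage and frequency thresholds.

    Only the single most frequent non-reference base is reported per
    position; further alleles are ignored.
    """
    if not 0 < min_variant_frequency <= 1:
        raise ValueError("min_variant_frequency must lie in (0, 1]")
    calls: list[SnpCall] = []
    for tid in sorted(piles):
        pile = piles[tid]
        ref = base_index_array(transcripts[tid])
        counts = pile.counts
        coverage = counts.sum(axis=0)
        length = counts.shape[1]
        cols = np.arange(length)
        nonref = counts.copy()
        ok_ref = ref < 4
        nonref[ref[ok_ref], cols[ok_ref]] = 0
        vcount = nonref.max(axis=0)
        vidx = nonref.argmax(axis=0)
        passing = (
            ok_ref
            & (coverage >= min_coverage)
            & (vcount >= min_variant_reads)
            & (vcount >= min_variant_frequency * coverage)
        )
        for pos in np.nonzero(passing)[0]:
            v = int(vidx[pos])
            calls.append(
                SnpCall(
                    transcript_id=tid,
                    position=int(pos) + 1,
                    primary=BASES[int(ref[pos])],
                    variant=BASES[v],
                    coverage=int(coverage[pos]),
                    variant_frequency=float(vcount[pos] / coverage[pos]),
                    variant_forward=int(pile.forward[v, pos]),
                    variant_reverse=int(pile.reverse[v, pos]),
                )
            )
    return calls


def locus_diversity(
    calls: list[SnpCall],
    transcripts: dict[str, str],
    piles: dict[str, TranscriptPileup] | None = None,
    min_coverage: int = 8,
) -> list[LocusDiversity]:
    """Per-transcript SNP count and rate; zero-SNP transcripts included.

    With pileups supplied, transcripts whose median coverage falls below
    ``min_coverage`` are flagged low_coverage (they stay in all denominators).
    """
    per_tid: dict[str, int] = {tid: 0 for tid in transcripts}
    for call in calls:
        if call.transcript_id not in per_tid:
            raise DataIntegrityError(f"call on unknown transcript {call.transcript_id}")
        per_tid[call.transcript_id] += 1
    out: list[LocusDiversity] = []
    for tid in sorted(transcripts):
        length = len(transcripts[tid])
        n = per_tid[tid]
        low = False
        if piles is not None and tid in piles:
            low = float(np.median(piles[tid].coverage)) < min_coverage
        out.append(
            LocusDiversity(
                transcript_id=tid,
                length=length,
                n_snps=n,
                snp_rate=n / length,
                snp_free=(n == 0),
                low_coverage=low,
            )
        )
    return out


def write_vcf(calls: list[SnpCall], transcripts: dict[str, str], path: str) -> None:
    """Minimal VCF: CHROM/POS/REF/ALT plus DP and AF in INFO."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=hybridtest\n")
        for tid in sorted(transcripts):
            fh.write(f"##contig=<ID={tid},length={len(transcripts[tid])}>\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(
            '##INFO=<ID=AF,Number=1,Type=Float,Description="Variant frequency">\n'
        )
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c in sorted(calls, key=lambda c: (c.transcript_id, c.position)):
            fh.write(
                f"{c.transcript_id}\t{c.position}\t.\t{c.primary}\t{c.variant}\t.\t.\t"
                f"DP={c.coverage};AF={c.variant_frequency:.4f}\n"
            )


def read_vcf(path: str) -> list[SnpCall]:
    """Read a minimal VCF written by :func:`write_vcf`."""
    calls: list[SnpCall] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            chrom, pos, _, ref, alt, _, _, info = line.rstrip("\n").split("\t")[:8]
            fields = dict(kv.split("=") for kv in info.split(";") if "=" in kv)
            dp = int(fields.get("DP", 0))
            af = float(fields.get("AF", 0.0))
            calls.append(
                SnpCall(
                    transcript_id=chrom,
                    position=int(pos),
                    primary=ref,
                    variant=alt,
                    coverage=dp,
                    variant_frequency=af,
                )
            )
    return calls
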