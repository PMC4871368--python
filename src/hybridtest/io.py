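"""FASTA/FASTQ/TSV readers and writers used at module boundaries."""

from __future__ import annotations

import csv
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .synth import HaplotypeSet, Read


def read_fasta(path: str) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def write_fasta(sequences: dict[str, str], path: str) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sequences.items()
    ]
    SeqIO.write(records, path, "fasta")


def read_fastq(path: str) -> list[Read]:
    reads = []
    for rec in SeqIO.parse(path, "fastq"):
        qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        reads.append(Read(rec.id, str(rec.seq).upper(), qual))
    return reads


def write_fastq(reads: Iterable[Read], path: str) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{r.quality}\n")


def write_truth_table(loci: list[HaplotypeSet], path: str) -> None:
    """TSV of ground-truth variable sites (1-based positions)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(
            ["locus_id", "position", "major_base", "minor_base", "minor_copies",
             "expected_fraction"]
        )
        for locus in loci:
            for site in locus.truth_table:
                writer.writerow(
                    [
                        locus.locus_id,
                        site.position,
                        site.major_base,
                        site.minor_base,
                        ",".join(str(c) for c in site.minor_copies),
                        f"{site.expected_fraction:.6f}",
                    ]
                )
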