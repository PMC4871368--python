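"""Synthetic two-taxon generator with known ground truth.

Emulates the study design: a diploid paternal taxon with low expressed
heterozygosity, and a triploid hybrid whose genome combines one paternal-like
copy with two copies of a divergent maternal haplotype. Also emulates the two
artefacts the curation pipeline must cope with: assembler-style consensus
transcripts that collapse allelic variation to the majority base, and
redundant overlapping/contained contig sets as produced by a k-mer-sweep
assembly.

Every stage is driven by ``numpy.random.default_rng`` seeded from the config,
so identical configs produce byte-identical FASTA/FASTQ output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import ConfigurationError, SimulationConfig
from ._util import BASES, array_to_seq, phred_char, revcomp

_IDX_TO_BASE = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class TruthSite:
    """Ground-truth variable site within one locus.

    position is 1-based; expected_fraction is the expected read fraction of
    the minor allele under copy-proportional expression, i.e.
    (copies carrying the minor base) / ploidy.
    """

    position: int
    major_base: str
    minor_base: str
    minor_copies: tuple[int, ...]
    expected_fraction: float


@dataclass
class HaplotypeSet:
    """All genome copies of one locus plus its truth table."""

    locus_id: str
    haplotypes: list[str]
    truth_table: list[TruthSite] = field(default_factory=list)

    def __post_init__(self) -> None:
        lengths = {len(h) for h in self.haplotypes}
        if len(lengths) > 1:
            raise ValueError(f"{self.locus_id}: haplotypes differ in length")

    @property
    def length(self) -> int:
        return len(self.haplotypes[0])

    @property
    def ploidy(self) -> int:
        return len(self.haplotypes)


@dataclass(frozen=True)
class Read:
    """One simulated single-end read with its provenance in the id."""

    read_id: str
    sequence: str
    quality: str


def _rng(config_seed: int, stage: int, extra: int = 0) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config_seed, stage, extra]))


def _draw_lengths(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    mean, sd = config.locus_length_mean, config.locus_length_sd
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    lengths = np.exp(rng.normal(mu, np.sqrt(sigma2), size=config.n_loci))
    return np.maximum(np.round(lengths).astype(int), config.min_locus_length)


def _mutate(hap: np.ndarray, mask: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Substitute masked sites uniformly over the three alternative bases."""
    out = hap.copy()
    n = int(mask.sum())
    if n:
        out[mask] = (hap[mask] + 1 + rng.integers(0, 3, size=n)) % 4
    return out


def _truth_from_copies(copies: np.ndarray) -> list[TruthSite]:
    """Truth table from the realized copy-by-site base matrix (indices 0-3)."""
    ploidy, length = copies.shape
    counts = np.stack([(copies == b).sum(axis=0) for b in range(4)])  # (4, L)
    variable = (counts > 0).sum(axis=0) > 1
    sites: list[TruthSite] = []
    for pos in np.nonzero(variable)[0]:
        col = counts[:, pos]
        # majority base; ties resolved toward the first-listed (paternal) copy
        top = col.max()
        major = int(copies[0, pos]) if col[copies[0, pos]] == top else int(col.argmax())
        minor_counts = col.copy()
        minor_counts[major] = 0
        minor = int(minor_counts.argmax())
        carriers = tuple(int(c) for c in np.nonzero(copies[:, pos] == minor)[0])
        sites.append(
            TruthSite(
                position=int(pos) + 1,
                major_base=BASES[major],
                minor_base=BASES[minor],
                minor_copies=carriers,
                expected_fraction=len(carriers) / ploidy,
            )
        )
    return sites


def _hap_matrix(hap_set: HaplotypeSet) -> np.ndarray:
    lookup = np.zeros(128, dtype=np.int8)
    for i, b in enumerate(BASES):
        lookup[ord(b)] = i
    return np.stack(
        [lookup[np.frombuffer(h.encode(), dtype=np.uint8)] for h in hap_set.haplotypes]
    )


def simulate_parent(config: SimulationConfig) -> list[HaplotypeSet]:
    """Simulate the diploid parent: two haplotypes per locus.

    Each site is independently heterozygous with probability
    ``parent_heterozygosity``; the second haplotype carries a uniformly chosen
    alternative base there, so every truth-table entry has expected minor-read
    fraction 1/2.
    """
    rng = _rng(config.seed, 1)
    lengths = _draw_lengths(config, rng)
    loci: list[HaplotypeSet] = []
    for i, length in enumerate(lengths):
        hap1 = rng.integers(0, 4, size=length, dtype=np.int8)
        het = rng.random(length) < config.parent_heterozygosity
        hap2 = _mutate(hap1, het, rng)
        copies = np.stack([hap1, hap2])
        loci.append(
            HaplotypeSet(
                locus_id=f"locus{i:04d}",
                haplotypes=[_indices_to_seq(hap1), _indices_to_seq(hap2)],
                truth_table=_truth_from_copies(copies),
            )
        )
    return loci


def _indices_to_seq(idx: np.ndarray) -> str:
    return array_to_seq(_IDX_TO_BASE[idx.astype(np.intp)])


def derive_maternal(
    parent_loci: list[HaplotypeSet], divergence: float, seed: int
) -> dict[str, str]:
    """Derive one maternal haplotype per locus from the first paternal one.

    Substitutions occur independently at rate ``divergence`` and never yield
    the original base.
    """
    if not 0.0 <= divergence <= 0.5:
        raise ConfigurationError("divergence must lie in [0, 0.5]")
    rng = _rng(seed, 2)
    out: dict[str, str] = {}
    for locus in parent_loci:
        hap = _hap_matrix(locus)[0]
        mask = rng.random(len(hap)) < divergence
        out[locus.locus_id] = _indices_to_seq(_mutate(hap, mask, rng))
    return out


def make_hybrid(
    parent_locus: HaplotypeSet,
    maternal_haplotype: str,
    composition: tuple[int, int] = (1, 2),
) -> HaplotypeSet:
    """Assemble the hybrid copy set for one locus.

    The ``n_paternal`` copies cycle over the parent's haplotypes (first-listed
    first), so composition (3, 0) is the autopolyploid control whose only
    variable sites are the parent's heterozygous ones; the ``n_maternal``
    copies replicate the maternal haplotype. At a paternal/maternal difference
    site the truth table records the minor allele at fraction
    min(n_pat, n_mat) / ploidy.
    """
    n_pat, n_mat = composition
    if n_pat < 0 or n_mat < 0 or n_pat + n_mat < 2:
        raise ConfigurationError("composition must sum to ploidy >= 2")
    if len(maternal_haplotype) != parent_locus.length:
        raise ValueError("maternal haplotype length mismatch")
    paternal = [parent_locus.haplotypes[i % 2] for i in range(n_pat)]
    copies = paternal + [maternal_haplotype] * n_mat
    hyb = HaplotypeSet(locus_id=parent_locus.locus_id, haplotypes=copies)
    hyb.truth_table = _truth_from_copies(_hap_matrix(hyb))
    return hyb


def emit_consensus_transcripts(loci: list[HaplotypeSet]) -> dict[str, str]:
    """Majority-base consensus per locus, mimicking assembler output.

    Ties go to the first-listed (paternal) haplotype, so a diploid
    heterozygous site is written with the paternal base while a (1,2) triploid
    difference site is written with the maternal base (2/3 majority). Real
    allelic diversity is thereby collapsed, as in de novo transcript assembly.
    """
    out: dict[str, str] = {}
    for locus in loci:
        copies = _hap_matrix(locus)
        counts = np.stack([(copies == b).sum(axis=0) for b in range(4)])
        best = counts.max(axis=0)
        consensus = counts.argmax(axis=0)
        first_wins = counts[copies[0], np.arange(copies.shape[1])] == best
        consensus[first_wins] = copies[0][first_wins]
        out[locus.locus_id] = _indices_to_seq(consensus)
    return out


def emit_redundant_contigs(
    loci: list[HaplotypeSet],
    n_fragments: int = 6,
    seed: int = 0,
) -> tuple[dict[str, str], list[tuple[str, str]]]:
    """Fragment each locus consensus into a redundant, overlapping contig set.

    Mimics a k-mer-sweep assembly, whose contigs for one transcript are
    near-identical and vary mainly at their ends: fragments are the locus
    consensus with random end trims. The first fragment keeps the 5' end and
    the second keeps the 3' end (guaranteeing full coverage of the locus and
    one overlapping-but-not-contained pair); with ``n_fragments >= 3`` the
    third is strictly contained in the first (guaranteeing a contained pair).

    Returns the contig dict and the ground-truth containment relations
    (inner_id, outer_id), established by brute-force substring tests on both
    strands.
    """
    if n_fragments < 1:
        raise ConfigurationError("n_fragments must be >= 1")
    rng = _rng(seed, 3)
    consensus = emit_consensus_transcripts(loci)
    contigs: dict[str, str] = {}
    for locus in loci:
        seq = consensus[locus.locus_id]
        frags = _fragment_one(seq, n_fragments, rng)
        for j, frag in enumerate(frags):
            contigs[f"{locus.locus_id}_frag{j}"] = frag
    relations = containment_relations(contigs)
    return contigs, relations


def _fragment_one(seq: str, n_fragments: int, rng: np.random.Generator) -> list[str]:
    length = len(seq)
    if n_fragments == 1:
        return [seq]

    def trim() -> int:
        return int(rng.integers(10, max(11, length // 6)))

    e = trim()
    s = e
    if seq[: length - e] == seq[s:]:  # degenerate periodic sequence
        s += 1
    frags = [seq[: length - e], seq[s:]]
    if n_fragments >= 3:
        # strictly inside the first fragment
        a = int(rng.integers(1, max(2, length // 8)))
        b = len(frags[0]) - int(rng.integers(1, max(2, length // 8)))
        frags.append(frags[0][a:b])
    while len(frags) < n_fragments:
        frags.append(seq[trim() : length - trim()])
    return frags


def containment_relations(contigs: dict[str, str]) -> list[tuple[str, str]]:
    """All (inner, outer) pairs where inner is a substring of outer on either strand."""
    rels: list[tuple[str, str]] = []
    items = sorted(contigs.items())
    for iid, iseq in items:
        irc = revcomp(iseq)
        for oid, oseq in items:
            if iid == oid or len(iseq) > len(oseq):
                continue
            if iseq in oseq or irc in oseq:
                rels.append((iid, oid))
    return rels


def simulate_reads(
    loci: list[HaplotypeSet],
    config: SimulationConfig,
    seed_stage: int = 4,
) -> list[Read]:
    """Simulate uniform-coverage single-end reads from all genome copies.

    Read counts per locus are Poisson with mean coverage * L / read_length;
    the source copy is uniform over copies (expression proportional to
    dosage), the start uniform over valid positions, the strand random.
    Per-base errors at ``error_rate`` substitute a uniformly chosen other
    base; the constant quality string encodes ``error_rate`` in phred+33.
    """
    if config.coverage <= 0:
        raise ConfigurationError("coverage must be positive")
    r = config.read_length
    qual = phred_char(config.error_rate) * r
    rng = _rng(config.seed, seed_stage)
    reads: list[Read] = []
    for locus in loci:
        mat = _hap_matrix(locus)
        ploidy, length = mat.shape
        if r > length:
            raise ConfigurationError("read_length exceeds locus length")
        n = int(rng.poisson(config.coverage * length / r))
        if n == 0:
            continue
        copy = rng.integers(0, ploidy, size=n)
        start = rng.integers(0, length - r + 1, size=n)
        strand = rng.integers(0, 2, size=n)
        positions = start[:, None] + np.arange(r)[None, :]
        bases = mat[copy[:, None], positions]  # (n, r) indices
        err = rng.random((n, r)) < config.error_rate
        n_err = int(err.sum())
        if n_err:
            bases[err] = (bases[err] + 1 + rng.integers(0, 3, size=n_err)) % 4
        rev = strand == 1
        bases[rev] = 3 - bases[rev, ::-1]  # reverse complement (A<->T, C<->G)
        seqs = _IDX_TO_BASE[bases.astype(np.intp)]
        for k in range(n):
            reads.append(
                Read(
                    read_id=(
                        f"{locus.locus_id}:c{copy[k]}:p{start[k]}"
                        f":{'-' if strand[k] else '+'}:{k}"
                    ),
                    sequence=seqs[k].tobytes().decode("ascii"),
                    quality=qual,
                )
            )
    return reads
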