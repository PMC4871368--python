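"""End-to-end synthetic scenario: simulate, curate, map, call, test.

``run_scenario`` chains every stage for the two taxa ("parent" and
"hybrid"), computes all four reciprocal mapping combinations, the ploidy
signatures, the no-shared-ancestry null, and the hybrid-origin verdict.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from . import contigs as contigs_mod
from . import hypothesis as hyp
from . import mapping as mapping_mod
from . import variants as variants_mod
from ._util import BASES
from .config import SimulationConfig
from .synth import (
    HaplotypeSet,
    Read,
    derive_maternal,
    emit_consensus_transcripts,
    emit_redundant_contigs,
    make_hybrid,
    simulate_parent,
    simulate_reads,
)

logger = logging.getLogger("hybridtest")

PARENT = "parent"
HYBRID = "hybrid"


@dataclass
class CombinationData:
    """One read-source x transcript-source mapping/calling run."""

    combination: hyp.Combination
    mapping: mapping_mod.MappingResult
    calls: list[variants_mod.SnpCall]
    diversity: list[variants_mod.LocusDiversity]


@dataclass
class ScenarioResult:
    config: SimulationConfig
    loci: dict[str, list[HaplotypeSet]]
    transcripts: dict[str, dict[str, str]]  # taxon -> {transcript_id: seq}
    reads: dict[str, list[Read]]
    combinations: dict[hyp.Combination, CombinationData]
    reciprocal: dict[hyp.Combination, hyp.ReciprocalResult]
    signatures: dict[str, hyp.PloidySignature]
    null_cross: hyp.NullCross
    verdict: hyp.HybridVerdict
    curation: dict[str, list[contigs_mod.Cluster]] = field(default_factory=dict)


def simulate_taxa(
    config: SimulationConfig,
) -> tuple[dict[str, list[HaplotypeSet]], dict[str, list[Read]]]:
    """Simulate haplotypes and reads for the parent and hybrid taxa."""
    parent_loci = simulate_parent(config)
    maternal = derive_maternal(parent_loci, config.maternal_divergence, config.seed)
    hybrid_loci = [
        make_hybrid(p, maternal[p.locus_id], config.hybrid_composition)
        for p in parent_loci
    ]
    reads = {
        PARENT: simulate_reads(parent_loci, config, seed_stage=4),
        HYBRID: simulate_reads(hybrid_loci, config, seed_stage=5),
    }
    return {PARENT: parent_loci, HYBRID: hybrid_loci}, reads


def curate_taxon(
    loci: list[HaplotypeSet],
    n_fragments: int = 6,
    seed: int = 0,
) -> tuple[dict[str, str], list[contigs_mod.Cluster]]:
    """Fragment each locus into a redundant contig set, then curate it back."""
    frags, _ = emit_redundant_contigs(loci, n_fragments=n_fragments, seed=seed)
    # fragments of the shortest loci drop below the 200 b assembler floor;
    # the curation floor is set beneath the fragment lengths instead
    return contigs_mod.curate(frags, min_length=60)


def run_combination(
    combination: hyp.Combination,
    reads: list[Read],
    transcripts: dict[str, str],
    trim_threshold: float = 0.01,
    min_mapped_length: int = 12,
    min_variant_frequency: float = 0.10,
    min_coverage: int = 8,
    min_variant_reads: int = 2,
) -> CombinationData:
    trim = mapping_mod.TrimConfig(trim_threshold)
    trimmed = [r for r in (mapping_mod.quality_trim(r, trim) for r in reads) if r]
    result = mapping_mod.map_reads(
        trimmed, transcripts, min_mapped_length=min_mapped_length
    )
    piles = variants_mod.pileup(result.records, transcripts)
    calls = variants_mod.call_snps(
        piles,
        transcripts,
        min_variant_frequency=min_variant_frequency,
        min_coverage=min_coverage,
        min_variant_reads=min_variant_reads,
    )
    diversity = variants_mod.locus_diversity(
        calls, transcripts, piles, min_coverage=min_coverage
    )
    logger.info(
        "%s reads on %s transcripts: %d mapped, %d unmapped, %d SNPs",
        combination[0], combination[1], result.n_mapped, result.n_unmapped, len(calls),
    )
    return CombinationData(combination, result, calls, diversity)


def simulate_null_cross(config: SimulationConfig, seed: int) -> hyp.NullCross:
    """No-shared-ancestry null: parent reads mapped onto transcripts of an
    independent lineage at divergence 2 * maternal_divergence.

    Consensus transcripts are used directly (curation of error-free
    fragments reproduces them).
    """
    null_cfg = replace(config, seed=seed)
    parent_loci = simulate_parent(null_cfg)
    divergence = min(0.5, 2.0 * config.maternal_divergence)
    other_hap1 = derive_maternal(parent_loci, divergence, seed + 1)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 17]))
    other_loci = []
    for locus in parent_loci:
        hap1 = other_hap1[locus.locus_id]
        arr = np.frombuffer(hap1.encode(), dtype=np.uint8).copy()
        het = rng.random(len(arr)) < config.parent_heterozygosity
        idx = np.nonzero(het)[0]
        lookup = {ord(b): i for i, b in enumerate(BASES)}
        for i in idx:
            b = lookup[int(arr[i])]
            arr[i] = ord(BASES[(b + 1 + int(rng.integers(0, 3))) % 4])
        other_loci.append(
            HaplotypeSet(locus.locus_id, [hap1, arr.tobytes().decode("ascii")])
        )
    transcripts = emit_consensus_transcripts(other_loci)
    reads = simulate_reads(parent_loci, null_cfg, seed_stage=4)
    data = run_combination((PARENT, "null"), reads, transcripts)
    free = sum(1 for d in data.diversity if d.snp_free)
    return hyp.NullCross(
        snp_free_loci=free,
        total_loci=len(data.diversity),
        snp_rates=np.array([d.snp_rate for d in data.diversity]),
    )


def mean_called_variant_frequency(
    seed: int,
    composition: tuple[int, int] | None = (1, 2),
    locus_length: int = 2500,
    coverage: float = 600.0,
    divergence: float = 0.02,
    heterozygosity: float = 0.002,
    error_rate: float = 0.002,
    read_length: int = 100,
    min_variant_frequency: float = 0.10,
) -> tuple[float, int]:
    """Mean called variant frequency on one deep-coverage locus.

    Simulates a single locus, maps its own reads back onto its consensus
    transcript and calls SNPs at the minimum variant frequency. With a
    ``composition`` the locus is a hybrid (a (1, 2) triploid carries the
    paternal allele at expected frequency 1/3); with ``composition=None`` it
    is the diploid parent (heterozygous alleles at 1/2). Returns
    (mean frequency, number of calls).
    """
    config = SimulationConfig(
        n_loci=1,
        locus_length_mean=locus_length,
        locus_length_sd=0.0,
        parent_heterozygosity=heterozygosity if composition is None else 0.002,
        maternal_divergence=divergence,
        coverage=coverage,
        read_length=read_length,
        error_rate=error_rate,
        seed=seed,
    )
    parent_loci = simulate_parent(config)
    if composition is None:
        loci = parent_loci
        seed_stage = 4
    else:
        maternal = derive_maternal(parent_loci, divergence, config.seed)
        loci = [
            make_hybrid(p, maternal[p.locus_id], composition) for p in parent_loci
        ]
        seed_stage = 5
    transcripts = emit_consensus_transcripts(loci)
    reads = simulate_reads(loci, config, seed_stage=seed_stage)
    result = mapping_mod.map_reads(reads, transcripts)
    piles = variants_mod.pileup(result.records, transcripts)
    calls = variants_mod.call_snps(
        piles, transcripts, min_variant_frequency=min_variant_frequency
    )
    if not calls:
        return float("nan"), 0
    return float(np.mean([c.variant_frequency for c in calls])), len(calls)


def run_scenario(
    config: SimulationConfig,
    n_fragments: int = 6,
    use_curation: bool = True,
    min_coverage_for_signature: int = 8,
    alpha: float = 1e-4,
    symmetry_tolerance: float = 0.20,
) -> ScenarioResult:
    """Run the full two-taxon pipeline and evaluate the hybrid hypothesis.

    With ``use_curation`` the per-taxon transcript sets come from the
    fragment-and-curate path (redundant contigs, containment removal,
    clustering, consensus); otherwise the locus consensus sequences are used
    directly.
    """
    logger.info(
        "scenario: seed=%d n_loci=%d coverage=%g composition=%s h=%g d=%g "
        "alpha=%g symmetry_tolerance=%g",
        config.seed, config.n_loci, config.coverage, config.hybrid_composition,
        config.parent_heterozygosity, config.maternal_divergence,
        alpha, symmetry_tolerance,
    )
    loci, reads = simulate_taxa(config)
    transcripts: dict[str, dict[str, str]] = {}
    curation: dict[str, list[contigs_mod.Cluster]] = {}
    for offset, taxon in enumerate((PARENT, HYBRID)):
        if use_curation:
            tx, clusters = curate_taxon(
                loci[taxon], n_fragments=n_fragments, seed=config.seed + offset
            )
            transcripts[taxon] = tx
            curation[taxon] = clusters
        else:
            transcripts[taxon] = emit_consensus_transcripts(loci[taxon])

    combinations: dict[hyp.Combination, CombinationData] = {}
    for read_taxon in (PARENT, HYBRID):
        for ref_taxon in (PARENT, HYBRID):
            combo = (read_taxon, ref_taxon)
            combinations[combo] = run_combination(
                combo, reads[read_taxon], transcripts[ref_taxon]
            )

    reciprocal = hyp.reciprocal_snp_stats(
        {combo: data.diversity for combo, data in combinations.items()}
    )
    signatures = {
        taxon: hyp.ploidy_signature(
            combinations[(taxon, taxon)].calls,
            min_coverage_for_signature=min_coverage_for_signature,
        )
        for taxon in (PARENT, HYBRID)
    }
    null_cross = simulate_null_cross(config, seed=config.seed + 104729)
    verdict = hyp.evaluate_hybrid_hypothesis(
        reciprocal,
        signatures=signatures,
        null_cross=null_cross,
        hybrid=HYBRID,
        parent=PARENT,
        alpha=alpha,
        symmetry_tolerance=symmetry_tolerance,
    )
    return ScenarioResult(
        config=config,
        loci=loci,
        transcripts=transcripts,
        reads=reads,
        combinations=combinations,
        reciprocal=reciprocal,
        signatures=signatures,
        null_cross=null_cross,
        verdict=verdict,
        curation=curation,
    )
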