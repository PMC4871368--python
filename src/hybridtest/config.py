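"""Simulation configuration.

The defaults define the study conditions emulated by the synthetic generator:
a diploid paternal taxon with low heterozygosity, and a triploid hybrid
carrying one paternal-like genome copy plus two copies of a maternal genome
that diverged from the paternal lineage. Expression is copy-proportional, so
allele dosage maps directly onto expected read fractions (1/2 for a diploid
het, 1/3 for the minor allele of a (1,2) triploid).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import json


class ConfigurationError(ValueError):
    """Raised for invalid simulation parameters."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic two-taxon scenario.

    Parameters
    ----------
    n_loci:
        Number of independent loci (transcripts) per taxon.
    locus_length_mean, locus_length_sd:
        Mean and standard deviation, in bases, of the lognormal locus length
        distribution. Lengths are truncated below at max(200, read_length).
    parent_heterozygosity:
        Per-site probability that the diploid parent is heterozygous.
    maternal_divergence:
        Per-site substitution probability between the paternal and maternal
        haplotypes.
    hybrid_composition:
        (n_paternal_copies, n_maternal_copies); the sum is the hybrid ploidy.
        (1, 2) is the triploid-hybrid default; (3, 0) is the autopolyploid
        control in which the copies cycle over the parent's two haplotypes.
    coverage:
        Mean read depth per locus.
    read_length:
        Read length in bases (single-end).
    error_rate:
        Per-base sequencing error probability.
    seed:
        Root seed; the same config and seed yield byte-identical output.
    """

    n_loci: int = 200
    locus_length_mean: float = 600.0
    locus_length_sd: float = 300.0
    parent_heterozygosity: float = 0.002
    maternal_divergence: float = 0.02
    hybrid_composition: tuple[int, int] = (1, 2)
    coverage: float = 20.0
    read_length: int = 100
    error_rate: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_loci <= 0:
            raise ConfigurationError("n_loci must be positive")
        if self.locus_length_mean <= 0 or self.locus_length_sd < 0:
            raise ConfigurationError("locus length parameters must be positive")
        for name in ("parent_heterozygosity", "maternal_divergence", "error_rate"):
            p = getattr(self, name)
            if not 0.0 <= p <= 0.5:
                raise ConfigurationError(f"{name} must lie in [0, 0.5]")
        n_pat, n_mat = self.hybrid_composition
        if n_pat < 0 or n_mat < 0 or n_pat + n_mat < 2:
            raise ConfigurationError("hybrid_composition must sum to ploidy >= 2")
        if self.coverage <= 0:
            raise ConfigurationError("coverage must be positive")
        if self.read_length <= 0:
            raise ConfigurationError("read_length must be positive")

    @property
    def ploidy(self) -> int:
        return sum(self.hybrid_composition)

    @property
    def min_locus_length(self) -> int:
        # read_length <= shortest locus, and the assembler floor of 200 b
        return max(200, self.read_length)

    def to_json(self) -> str:
        d = asdict(self)
        d["hybrid_composition"] = list(self.hybrid_composition)
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SimulationConfig":
        d = json.loads(text)
        if "hybrid_composition" in d:
            d["hybrid_composition"] = tuple(d["hybrid_composition"])
        return cls(**d)
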