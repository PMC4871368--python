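"""Reciprocal-mapping statistics and the hybrid-origin verdict.

A hybrid origin makes two testable predictions:

1. the putative hybrid carries greater allelic diversity than the putative
   parent (fewer SNP-free loci when each taxon's reads are mapped onto its
   own transcript assemblies);
2. the parent's alleles co-occur in (are nested within) the hybrid genome.

Prediction 2 is a verbal argument in the source literature of this field;
here it is operationalized as three measurable conditions (see
:func:`evaluate_hybrid_hypothesis`): the parent's reads must be closer to
the hybrid's transcripts than a no-shared-ancestry null allows, within- and
between-genome divergence must be symmetric (the heat-map symmetry), and the
hybrid's reads must reveal a divergent allele class against the parent's
transcripts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

Combination = tuple[str, str]  # (read_source_taxon, transcript_source_taxon)


class IntegrityError(ValueError):
    """Reciprocal combinations do not share matched transcript sets."""


@dataclass
class ReciprocalResult:
    """SNP-free summary for one read-source x transcript-source combination."""

    combination: Combination
    total_loci: int
    snp_free_loci: int
    snp_free_proportion: float
    snp_rates: pd.Series  # per-locus SNP rate, indexed by transcript id

    def rates_excluding_snp_free(self) -> pd.Series:
        """Per-locus rates with SNP-free loci removed (density-plot view)."""
        return self.snp_rates[self.snp_rates > 0]


@dataclass
class ChiSquareContrast:
    counts: np.ndarray  # 2x2: rows = combinations, cols = (snp_free, not)
    statistic: float
    p_value: float


@dataclass
class PloidySignature:
    variant_frequency_histogram: np.ndarray  # counts per 0.05-wide bin
    bin_edges: np.ndarray
    modal_frequency: float
    dosage_class: str  # 'diploid-like' | 'triploid-like' | 'ambiguous'
    n_calls: int = 0


@dataclass
class NullCross:
    """Cross-mapping summary under the no-shared-ancestry null simulation."""

    snp_free_loci: int
    total_loci: int
    snp_rates: np.ndarray

    @property
    def snp_free_proportion(self) -> float:
        return self.snp_free_loci / self.total_loci if self.total_loci else 0.0


@dataclass
class HybridVerdict:
    prediction1_supported: bool
    prediction2_supported: bool
    statistics: dict = field(default_factory=dict)
    narrative: str = ""


def reciprocal_snp_stats(
    diversities: dict[Combination, list],
) -> dict[Combination, ReciprocalResult]:
    """Summarize the four mapping combinations into SNP-free statistics.

    Combinations sharing a transcript source must cover identical transcript
    sets (they were mapped against the same references).
    """
    by_ref: dict[str, set[str]] = {}
    results: dict[Combination, ReciprocalResult] = {}
    for combo, divs in diversities.items():
        ids = {d.transcript_id for d in divs}
        ref = combo[1]
        if ref in by_ref and by_ref[ref] != ids:
            raise IntegrityError(
                f"transcript sets differ across combinations mapped onto {ref!r}"
            )
        by_ref.setdefault(ref, ids)
        rates = pd.Series(
            {d.transcript_id: d.snp_rate for d in divs}, dtype=float
        ).sort_index()
        total = len(divs)
        free = sum(1 for d in divs if d.snp_free)
        results[combo] = ReciprocalResult(
            combination=combo,
            total_loci=total,
            snp_free_loci=free,
            snp_free_proportion=free / total if total else 0.0,
            snp_rates=rates,
        )
    return results


def two_proportion_chi2(
    count_a: int, total_a: int, count_b: int, total_b: int
) -> ChiSquareContrast:
    """Pearson chi-squared (1 df, no continuity correction) on a 2x2 table."""
    if total_a <= 0 or total_b <= 0:
        raise ValueError("totals must be positive")
    if count_a > total_a or count_b > total_b:
        raise ValueError("counts cannot exceed totals")
    table = np.array(
        [[count_a, total_a - count_a], [count_b, total_b - count_b]], dtype=float
    )
    if np.any(table.sum(axis=0) == 0):
        # a degenerate margin carries no information; proportions are equal
        return ChiSquareContrast(counts=table, statistic=0.0, p_value=1.0)
    stat, p, _, _ = stats.chi2_contingency(table, correction=False)
    return ChiSquareContrast(counts=table, statistic=float(stat), p_value=float(p))


def ploidy_signature(
    snp_calls: list,
    min_coverage_for_signature: int = 50,
    bin_width: float = 0.05,
) -> PloidySignature:
    """Classify allele dosage from the variant-frequency spectrum.

    Frequencies are binned at ``bin_width`` with bin centers on the round
    frequencies (0.30, 0.35, 0.50, ...); the modal bin center, folded onto
    (0, 0.5] (a 2/3 signal is the complement of a 1/3 signal), is assigned
    to the nearer of 1/3 (triploid-like) or 1/2 (diploid-like), or
    'ambiguous' when it falls within 0.04 of the midpoint 5/12.
    """
    freqs = np.array(
        [c.variant_frequency for c in snp_calls if c.coverage >= min_coverage_for_signature]
    )
    edges = np.arange(-bin_width / 2, 1.0 + bin_width, bin_width)
    if freqs.size == 0:
        return PloidySignature(
            variant_frequency_histogram=np.zeros(len(edges) - 1, dtype=int),
            bin_edges=edges,
            modal_frequency=float("nan"),
            dosage_class="ambiguous",
            n_calls=0,
        )
    hist, _ = np.histogram(freqs, bins=edges)
    mode_bin = int(hist.argmax())
    modal = float((edges[mode_bin] + edges[mode_bin + 1]) / 2)
    folded = min(modal, 1.0 - modal)
    if abs(folded - 5.0 / 12.0) < 0.04:
        dosage = "ambiguous"
    elif abs(folded - 1.0 / 3.0) < abs(folded - 0.5):
        dosage = "triploid-like"
    else:
        dosage = "diploid-like"
    return PloidySignature(
        variant_frequency_histogram=hist,
        bin_edges=edges,
        modal_frequency=modal,
        dosage_class=dosage,
        n_calls=int(freqs.size),
    )


def heatmap_matrix(
    rates_x: pd.Series, rates_y: pd.Series, n_bins: int = 20
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """2D per-locus SNP-rate histogram (the heat-map view of reciprocal data).

    Both series must be indexed by the same transcript set; the matrix counts
    sum to the number of shared loci.
    """
    if set(rates_x.index) != set(rates_y.index):
        raise IntegrityError("rate series are indexed by different transcript sets")
    rates_y = rates_y.reindex(rates_x.index)
    top = max(float(rates_x.max()), float(rates_y.max()), 1e-9)
    edges = np.linspace(0.0, top * (1 + 1e-9), n_bins + 1)
    matrix, _, _ = np.histogram2d(rates_x.values, rates_y.values, bins=(edges, edges))
    return matrix.astype(int), edges, edges


def evaluate_hybrid_hypothesis(
    reciprocal: dict[Combination, ReciprocalResult],
    signatures: dict[str, PloidySignature] | None = None,
    null_cross: NullCross | None = None,
    hybrid: str = "hybrid",
    parent: str = "parent",
    alpha: float = 1e-4,
    symmetry_tolerance: float = 0.20,
) -> HybridVerdict:
    """Evaluate the two hybrid-origin predictions.

    Prediction 1 is supported when the hybrid's self-mapping shows a
    significantly smaller SNP-free proportion than the parent's self-mapping.

    Prediction 2 (allelic nesting) is supported when all of:
      (a) per-locus SNP rates of parent reads on hybrid transcripts sit
          significantly below the no-shared-ancestry null (one-sided
          Mann-Whitney): the parent is closer to the hybrid's subgenome than
          an unrelated lineage would be. Skipped if no null is provided.
          (SNP-free proportions saturate at high divergence, so the contrast
          is measured on rates; the proportions are still reported.);
      (b) within-hybrid and parent-vs-hybrid divergence are symmetric:
          median per-locus SNP rates (SNP-free loci excluded) differ by at
          most ``symmetry_tolerance`` relative to their mean;
      (c) hybrid reads on parent transcripts show significantly fewer
          SNP-free loci than the parent's self-mapping (the divergent allele
          class is actually present in the hybrid).
    """
    required = [(hybrid, hybrid), (parent, parent), (parent, hybrid), (hybrid, parent)]
    for combo in required:
        if combo not in reciprocal:
            raise IntegrityError(f"missing combination {combo}")
    hh, pp = reciprocal[(hybrid, hybrid)], reciprocal[(parent, parent)]
    ph, hp = reciprocal[(parent, hybrid)], reciprocal[(hybrid, parent)]

    stats_out: dict = {
        "snp_free_proportions": {
            f"{c[0]}_reads_on_{c[1]}_transcripts": r.snp_free_proportion
            for c, r in reciprocal.items()
        }
    }

    c1 = two_proportion_chi2(
        hh.snp_free_loci, hh.total_loci, pp.snp_free_loci, pp.total_loci
    )
    prediction1 = (
        hh.snp_free_proportion < pp.snp_free_proportion and c1.p_value < alpha
    )
    stats_out["prediction1"] = {
        "hybrid_self_snp_free": hh.snp_free_proportion,
        "parent_self_snp_free": pp.snp_free_proportion,
        "chi2": c1.statistic,
        "p_value": c1.p_value,
    }

    # (a) cross-mapping rates vs the no-shared-ancestry null
    if null_cross is not None:
        obs = ph.snp_rates.to_numpy(dtype=float)
        null_rates = np.asarray(null_cross.snp_rates, dtype=float)
        if np.any(obs > 0) or np.any(null_rates > 0):
            u = stats.mannwhitneyu(obs, null_rates, alternative="less")
            p_a = float(u.pvalue)
        else:
            p_a = 1.0
        cond_a = (
            float(np.median(obs)) <= float(np.median(null_rates)) and p_a < alpha
        )
        stats_out["prediction2_null_contrast"] = {
            "parent_on_hybrid_median_rate": float(np.median(obs)),
            "null_median_rate": float(np.median(null_rates)),
            "parent_on_hybrid_snp_free": ph.snp_free_proportion,
            "null_snp_free": null_cross.snp_free_proportion,
            "p_value": p_a,
        }
    else:
        cond_a = True
        stats_out["prediction2_null_contrast"] = None

    # (b) heat-map symmetry of divergence medians
    m_within = float(np.median(hh.rates_excluding_snp_free())) if (
        hh.rates_excluding_snp_free().size
    ) else 0.0
    m_cross = float(np.median(ph.rates_excluding_snp_free())) if (
        ph.rates_excluding_snp_free().size
    ) else 0.0
    if m_within > 0 and m_cross > 0:
        rel = abs(m_within - m_cross) / ((m_within + m_cross) / 2)
        cond_b = rel <= symmetry_tolerance
    else:
        rel = float("nan")
        cond_b = False
    stats_out["prediction2_symmetry"] = {
        "median_within_hybrid_rate": m_within,
        "median_parent_on_hybrid_rate": m_cross,
        "relative_difference": rel,
        "tolerance": symmetry_tolerance,
    }

    # (c) the divergent allele class shows against the parent reference
    cc = two_proportion_chi2(
        hp.snp_free_loci, hp.total_loci, pp.snp_free_loci, pp.total_loci
    )
    cond_c = hp.snp_free_proportion < pp.snp_free_proportion and cc.p_value < alpha
    stats_out["prediction2_nesting_contrast"] = {
        "hybrid_on_parent_snp_free": hp.snp_free_proportion,
        "parent_self_snp_free": pp.snp_free_proportion,
        "chi2": cc.statistic,
        "p_value": cc.p_value,
    }

    prediction2 = cond_a and cond_b and cond_c
    if signatures:
        stats_out["dosage_classes"] = {
            taxon: sig.dosage_class for taxon, sig in signatures.items()
        }

    narrative = (
        f"Self-mapping SNP-free proportions: {hybrid} "
        f"{hh.snp_free_proportion:.1%}, {parent} {pp.snp_free_proportion:.1%}. "
        f"Prediction 1 (greater allelic diversity in the {hybrid}): "
        f"{'supported' if prediction1 else 'not supported'}. "
        f"Prediction 2 (parental alleles nested in the {hybrid}): "
        f"{'supported' if prediction2 else 'not supported'}."
    )
    return HybridVerdict(
        prediction1_supported=prediction1,
        prediction2_supported=prediction2,
        statistics=stats_out,
        narrative=narrative,
    )
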