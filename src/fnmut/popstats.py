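"""Diversity statistics and spontaneous-mutation expectations.

θπ is pairwise nucleotide diversity per site, computed with the unbiased
per-site heterozygosity 2·p·(1−p)·n/(n−1) summed over variant sites and
averaged over all L sites (monomorphic sites contribute zero).  For inbred
lines the sample is treated as haploid.  Expected spontaneous mutation
counts per line multiply a per-site per-generation rate by an explicit
site-generations total — the diploid/fixation accounting is a parameter,
not an assumption, because different conventions are defensible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from fnmut.variants import Variant, nonref_allele_count

#: per-site per-generation rates from plant mutation-accumulation studies
DEFAULT_SNP_RATE = 6.53e-9
DEFAULT_INDEL_RATE = 0.47e-9


@dataclass
class MutationRateModel:
    """Spontaneous mutation model for expected per-line counts.

    generation_weighting:
      - ``site_generations``: E = rate × L × (g_pre + selfing) × ploidy_factor
      - ``fixed_factor``: E = rate × site_generations_override (the caller
        supplies the site-generations total directly)
    """

    snp_rate: float = DEFAULT_SNP_RATE
    indel_rate: float = DEFAULT_INDEL_RATE
    pre_treatment_generations: int = 10
    genome_length: float = 966e6
    generation_weighting: str = "site_generations"
    ploidy_factor: float = 1.0
    site_generations_override: float | None = None

    def __post_init__(self) -> None:
        if self.snp_rate < 0 or self.indel_rate < 0:
            raise ValueError("rates must be non-negative")
        if self.pre_treatment_generations < 0:
            raise ValueError("pre-treatment generations must be non-negative")
        if self.genome_length <= 0:
            raise ValueError("genome length must be positive")
        if self.generation_weighting not in ("site_generations", "fixed_factor"):
            raise ValueError(f"unknown weighting {self.generation_weighting!r}")


def expected_spontaneous_count(
    model: MutationRateModel, rate_kind: str, selfing_generations: int = 0
) -> float:
    """Expected spontaneous mutations per line for ``rate_kind`` ("snp" or "indel")."""
    if selfing_generations < 0:
        raise ValueError("negative generations")
    rate = {"snp": model.snp_rate, "indel": model.indel_rate}[rate_kind]
    if model.generation_weighting == "fixed_factor":
        if model.site_generations_override is None:
            raise ValueError("fixed_factor weighting requires site_generations_override")
        return rate * model.site_generations_override
    site_generations = (
        model.genome_length
        * (model.pre_treatment_generations + selfing_generations)
        * model.ploidy_factor
    )
    return rate * site_generations


@dataclass
class DiversityEstimate:
    theta_pi: float  # per site
    n: int  # haploid sample size
    S: int  # variant sites used
    L: float  # total sites (monomorphic + polymorphic)


def theta_pi(
    variant_allele_counts: Iterable[int], n: int, L: float
) -> DiversityEstimate:
    """Pairwise diversity per site from per-site non-reference allele counts.

    θπ = Σ_sites 2·p·(1−p)·n/(n−1) / L with p = count/n.
    """
    if n < 2:
        raise ValueError("need haploid sample size n >= 2")
    if L <= 0:
        raise ValueError("L must be positive")
    counts = np.asarray(list(variant_allele_counts), dtype=float)
    if counts.size and (counts.min() < 1 or counts.max() > n - 1):
        raise ValueError("allele counts must lie in [1, n-1]")
    p = counts / n
    total = float(np.sum(2.0 * p * (1.0 - p)) * n / (n - 1))
    return DiversityEstimate(theta_pi=total / L, n=n, S=int(counts.size), L=L)


def windowed_pi(
    sites: Sequence[tuple[str, int, int]],
    n: int,
    window_bp: int,
    contig_lengths: dict[str, int],
) -> pd.DataFrame:
    """Per-window θπ track over non-overlapping windows.

    ``sites`` are (chrom, pos, allele_count) triples.  The genome-wide value
    equals the length-weighted mean of window values.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    rows = []
    by_chrom: dict[str, list[tuple[int, int]]] = {c: [] for c in contig_lengths}
    for chrom, pos, ac in sites:
        by_chrom.setdefault(chrom, []).append((pos, ac))
    for chrom, length in contig_lengths.items():
        site_list = sorted(by_chrom.get(chrom, []))
        for start in range(0, length, window_bp):
            end = min(start + window_bp, length)
            counts = [ac for pos, ac in site_list if start < pos <= end]
            est = theta_pi(counts, n, end - start)
            rows.append(
                {
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "n_sites": est.S,
                    "theta_pi": est.theta_pi,
                }
            )
    return pd.DataFrame(rows)


def observed_heterozygosity(variants: Sequence[Variant]) -> pd.DataFrame:
    """Per-sample fraction of called genotypes that are heterozygous."""
    called: dict[str, int] = {}
    het: dict[str, int] = {}
    for v in variants:
        for s, gt in (v.genotypes or {}).items():
            called.setdefault(s, 0)
            het.setdefault(s, 0)
            if None in gt:
                continue
            called[s] += 1
            if gt[0] != gt[1]:
                het[s] += 1
    rows = []
    for s in sorted(called):
        rows.append(
            {
                "sample": s,
                "n_called": called[s],
                "n_het": het[s],
                "het_fraction": het[s] / called[s] if called[s] else float("nan"),
                "flag": "" if called[s] else "no_called_genotypes",
            }
        )
    return pd.DataFrame(rows)


def pooled_allele_counts(variants: Sequence[Variant]) -> list[tuple[str, int, int]]:
    """(chrom, pos, nonref allele count) per variant, for diversity tracks."""
    return [(v.chrom, v.pos, nonref_allele_count(v)) for v in variants]
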