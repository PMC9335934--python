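"""Isolation of de novo mutations in treatment lines.

The filter chain removes, in order: variants matching the parental line or
the diversity panel (standing variation), variants in masked regions
(parental deletions relative to the reference, where de novo calls cannot be
ascertained), low-quality calls, and variants whose carrier pattern is
inconsistent with a fixed de novo mutation in an inbred line — i.e. anything
that is not a homozygous singleton (shared variants are heterogeneity of the
seed stock, heterozygous calls are segregating or erroneous).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from fnmut.variants import (
    MaskSet,
    Variant,
    VariantClass,
    classify_variant,
    nonref_allele_count,
    read_line_meta,
    read_variants,
)

# removal reasons, keyed by the filter that owns them
REASON_KNOWN = "known_variant"
REASON_MASKED = "masked_region"
REASON_LOW_QUAL = "low_qual"
REASON_LOW_DEPTH = "low_depth"
REASON_NO_CARRIER = "no_carrier"
REASON_SHARED = "shared_heterogeneity"
REASON_HET = "het_call"
REASON_UNCALLED = "uncalled_noncarrier"


@dataclass
class FilterConfig:
    """Thresholds and carrier rules for de novo isolation.

    min_depth/min_qual are QC defaults, deliberately config-exposed.
    max_other_lines_carrying = 0 enforces strict singletons;
    allow_family_sharing permits sharing restricted to one family id
    (siblings derived from the same mutagenized plant).
    """

    min_depth: int = 5
    min_qual: float = 30.0
    max_other_lines_carrying: int = 0
    require_homozygous: bool = True
    allow_family_sharing: bool = False
    require_noncarriers_called: bool = False

    def __post_init__(self) -> None:
        if self.min_depth < 0 or self.min_qual < 0:
            raise ValueError("min_depth and min_qual must be non-negative")


@dataclass
class DeNovoRecord:
    variant: Variant
    line: str
    vclass: VariantClass
    flags: tuple[str, ...] = ()


@dataclass
class DeNovoSet:
    """Variants surviving the filter chain, with per-filter provenance."""

    records: list[DeNovoRecord] = field(default_factory=list)
    removed: Counter = field(default_factory=Counter)
    removal_log: list[tuple[tuple, str]] = field(default_factory=list)  # (variant.key, reason)
    lines: list[str] = field(default_factory=list)

    def variants(self) -> list[Variant]:
        return [r.variant for r in self.records]

    def per_line_counts(self) -> pd.DataFrame:
        rows = {line: {"snps": 0, "indels": 0} for line in self.lines}
        for r in self.records:
            rows.setdefault(r.line, {"snps": 0, "indels": 0})
            if r.vclass.label == "SNP":
                rows[r.line]["snps"] += 1
            elif r.vclass.label in ("insertion", "deletion"):
                rows[r.line]["indels"] += 1
        df = pd.DataFrame.from_dict(rows, orient="index").rename_axis("sample")
        df["total"] = df["snps"] + df["indels"]
        return df.sort_index()

    def outlier_report(self, factor: float = 3.0) -> pd.DataFrame:
        """Lines whose totals exceed ``factor`` × cohort median (possible contamination)."""
        counts = self.per_line_counts()
        med = counts["total"].median()
        return counts[counts["total"] > factor * max(med, 1)]


def apply_masks(
    variants: list[Variant], masks: MaskSet
) -> tuple[list[Variant], list[Variant]]:
    """Split variants into (kept, removed) by mask overlap of the REF span."""
    kept, removed = [], []
    for v in variants:
        (removed if masks.overlaps_variant(v) else kept).append(v)
    return kept, removed


@dataclass
class SubtractResult:
    kept: list[Variant]
    removed: list[Variant]
    flagged_position_collisions: set[tuple[str, int]]


def subtract_known(
    treatment_variants: list[Variant],
    parental_variants: list[Variant],
    panel_variants: list[Variant],
) -> SubtractResult:
    """Remove treatment variants identical (chrom, pos, ref, alt) to known ones.

    Position-only collisions with different alleles are retained but flagged,
    so a stricter position-level subtraction is one config switch away.
    """
    known_keys = {v.key for v in parental_variants} | {v.key for v in panel_variants}
    known_pos = {(k[0], k[1]) for k in known_keys}
    kept, removed, flagged = [], [], set()
    for v in treatment_variants:
        if v.key in known_keys:
            removed.append(v)
        else:
            kept.append(v)
            if (v.chrom, v.pos) in known_pos:
                flagged.add((v.chrom, v.pos))
    return SubtractResult(kept, removed, flagged)


def _carriers(v: Variant) -> list[str]:
    if not v.genotypes:
        return []
    return [s for s, gt in v.genotypes.items() if any(a == 1 for a in gt)]


def isolate_de_novo(
    treatment_variants: list[Variant],
    parental_variants: list[Variant],
    panel_variants: list[Variant],
    masks: MaskSet,
    line_meta: pd.DataFrame,
    config: FilterConfig | None = None,
) -> DeNovoSet:
    """Run the full de novo filter chain over a multi-sample treatment call set.

    Chain: subtract known → apply masks → QUAL ≥ min_qual → carrier rule
    (non-reference in exactly one line, or family-restricted sharing when
    allowed; homozygous when required; carrier depth ≥ min_depth).
    """
    config = config or FilterConfig()
    samples = _treatment_samples(treatment_variants)
    if samples:
        missing = set(samples) - set(line_meta.index)
        if missing:
            raise ValueError(f"metadata missing for samples: {sorted(missing)}")
        if not set(samples) & set(line_meta.index):
            raise ValueError("no samples shared between VCF and metadata")
    family = line_meta["family"].to_dict() if "family" in line_meta else {}

    result = DeNovoSet(lines=sorted(samples))
    sub = subtract_known(treatment_variants, parental_variants, panel_variants)
    _log(result, sub.removed, REASON_KNOWN)
    flagged_pos = sub.flagged_position_collisions

    unmasked, masked = apply_masks(sub.kept, masks)
    _log(result, masked, REASON_MASKED)

    for v in unmasked:
        if v.qual is not None and v.qual < config.min_qual:
            _log(result, [v], REASON_LOW_QUAL)
            continue
        carriers = _carriers(v)
        if not carriers:
            _log(result, [v], REASON_NO_CARRIER)
            continue
        if len(carriers) > 1 + config.max_other_lines_carrying:
            fams = {family.get(s) for s in carriers}
            family_ok = (
                config.allow_family_sharing
                and len(fams) == 1
                and next(iter(fams)) not in (None, "", float("nan"))
                and not pd.isna(next(iter(fams)))
            )
            if not family_ok:
                _log(result, [v], REASON_SHARED)
                continue
        if config.require_homozygous and any(
            v.genotypes[s] != (1, 1) for s in carriers
        ):
            _log(result, [v], REASON_HET)
            continue
        depths = v.depths or {}
        if any(
            depths.get(s) is not None and depths[s] < config.min_depth
            for s in carriers
        ):
            _log(result, [v], REASON_LOW_DEPTH)
            continue
        noncarriers = [s for s in (v.genotypes or {}) if s not in carriers]
        n_uncalled = sum(1 for s in noncarriers if v.genotypes[s] == (None, None))
        if config.require_noncarriers_called and n_uncalled:
            _log(result, [v], REASON_UNCALLED)
            continue
        flags = []
        if (v.chrom, v.pos) in flagged_pos:
            flags.append("position_collision_with_known")
        if n_uncalled:
            flags.append(f"uncalled_noncarriers={n_uncalled}")
        for s in carriers:
            result.records.append(
                DeNovoRecord(v, s, classify_variant(v.ref, v.alt), tuple(flags))
            )
    return result


def isolate_de_novo_from_paths(
    treatment_vcf,
    parental_vcf,
    panel_vcf,
    mask_bed,
    meta_tsv,
    reference,
    config: FilterConfig | None = None,
) -> DeNovoSet:
    """Path-based convenience wrapper around :func:`isolate_de_novo`."""
    return isolate_de_novo(
        read_variants(treatment_vcf, reference),
        read_variants(parental_vcf, reference),
        read_variants(panel_vcf, reference),
        MaskSet.from_bed(mask_bed),
        read_line_meta(meta_tsv),
        config,
    )


def partition_by_frequency(
    panel_variants: list[Variant],
) -> tuple[list[Variant], list[Variant]]:
    """Partition standing variants into (rare, common) by non-reference allele count.

    Rare: allele count 1–2; common: 3 or higher; count 0 excluded from both.
    """
    rare, common = [], []
    for v in panel_variants:
        ac = nonref_allele_count(v)
        if ac == 0:
            continue
        (rare if ac <= 2 else common).append(v)
    return rare, common


def _treatment_samples(variants: list[Variant]) -> set[str]:
    samples: set[str] = set()
    for v in variants:
        if v.genotypes:
            samples.update(v.genotypes)
    return samples


def _log(result: DeNovoSet, variants: list[Variant], reason: str) -> None:
    result.removed[reason] += len(variants)
    for v in variants:
        result.removal_log.append((v.key, reason))
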