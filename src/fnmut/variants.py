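"""Readers, writers and normalization for the standard formats the pipeline touches.

Coordinate conventions: variants are VCF-style 1-based inclusive; mask
intervals are BED-style 0-based half-open.  The two conventions meet only in
:meth:`MaskSet.overlaps_variant` and the BED reader/writer.

Indels are represented VCF-style with a shared anchor base and left-aligned
on read, so identical events compare equal across call sets — the filter
chain subtracts known variants by exact (chrom, pos, ref, alt) identity and
needs a canonical representation.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import pysam

log = logging.getLogger(__name__)

_ACGT = frozenset("ACGT")
Genotype = tuple  # (allele, allele) with None for missing

MISSING_GT: Genotype = (None, None)


class ReferenceMismatchError(ValueError):
    """REF allele disagrees with the reference sequence — wrong reference build."""


@dataclass
class Variant:
    """One normalized, biallelic variant record.

    ``genotypes`` maps sample name to an (a, b) pair of allele indices in
    {0, 1, None}; ``depths`` maps sample name to read depth or None.
    Both are optional (site-only records have neither).
    """

    chrom: str
    pos: int  # 1-based position of the first reference base
    ref: str
    alt: str
    qual: float | None = None
    genotypes: dict[str, Genotype] | None = None
    depths: dict[str, int | None] | None = None
    info: dict = field(default_factory=dict)

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def span(self) -> tuple[int, int]:
        """0-based half-open interval covered by the REF allele."""
        return (self.pos - 1, self.pos - 1 + len(self.ref))

    def __post_init__(self) -> None:
        if not self.ref or not self.alt:
            raise ValueError(f"empty allele at {self.chrom}:{self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt at {self.chrom}:{self.pos}")


@dataclass(frozen=True)
class VariantClass:
    """Variant type label with the signed length change (alt − ref)."""

    label: str  # SNP | insertion | deletion | other
    signed_length: int


@dataclass(frozen=True)
class LineMeta:
    sample: str
    dosage_gy: int
    selfing_generations: int
    family: str | None = None


def classify_variant(ref: str, alt: str) -> VariantClass:
    """Classify normalized alleles as SNP / insertion / deletion / other."""
    if not ref or not alt:
        raise ValueError("empty allele string")
    if len(ref) == 1 and len(alt) == 1:
        return VariantClass("SNP", 0)
    delta = len(alt) - len(ref)
    if delta > 0 and alt.startswith(ref):
        return VariantClass("insertion", delta)
    if delta < 0 and ref.startswith(alt):
        return VariantClass("deletion", delta)
    return VariantClass("other", 0)


def nonref_allele_count(variant: Variant) -> int:
    """Count alt-allele copies across all called genotypes (missing → 0)."""
    if not variant.genotypes:
        return 0
    return sum(
        1 for gt in variant.genotypes.values() for a in gt if a is not None and a > 0
    )


# ---------------------------------------------------------------------------
# reference access


def get_contig(reference, chrom: str) -> str:
    """Uppercase sequence of one contig from a pyfaidx.Fasta or a plain mapping."""
    seq = reference[chrom]
    if not isinstance(seq, str):
        seq = str(seq[:])  # pyfaidx FastaRecord
    return seq.upper()


class _RefCache:
    """Memoize full-contig strings; random per-base pyfaidx access is slow."""

    def __init__(self, reference):
        self._ref = reference
        self._cache: dict[str, str] = {}

    def __getitem__(self, chrom: str) -> str:
        if chrom not in self._cache:
            self._cache[chrom] = get_contig(self._ref, chrom)
        return self._cache[chrom]

    def __contains__(self, chrom: str) -> bool:
        try:
            self[chrom]
        except KeyError:
            return False
        return True


# ---------------------------------------------------------------------------
# normalization


def normalize_allele_pair(chrom_seq: str, pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Left-align and trim an allele pair against the contig sequence.

    Standard parsimony/left-alignment: trim shared trailing bases (extending
    left through the reference when an allele would empty), then trim shared
    leading bases.  Returns (pos, ref, alt) in 1-based coordinates.
    """
    ref, alt = ref.upper(), alt.upper()
    while True:
        if ref[-1] == alt[-1] and len(ref) > 1 and len(alt) > 1:
            ref, alt = ref[:-1], alt[:-1]
        elif ref[-1] == alt[-1] and pos > 1:
            prev = chrom_seq[pos - 2]
            ref, alt = prev + ref[:-1], prev + alt[:-1]
            pos -= 1
        else:
            break
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def _is_symbolic(alt: str) -> bool:
    return any(c in alt for c in "<>[]*.") or not set(alt.upper()) <= _ACGT


# ---------------------------------------------------------------------------
# VCF I/O


def read_variants(vcf_path, reference, normalize: bool = True) -> list[Variant]:
    """Read a VCF into normalized biallelic :class:`Variant` records.

    Multiallelic records are split into one record per alt, each inheriting
    the original QUAL; in split records, genotype alleles belonging to a
    different alt are set missing.  Symbolic/structural alleles are excluded
    with a logged count.  Every REF allele is verified against the reference;
    a mismatch is fatal (it signals the wrong reference build).
    """
    vcf_path = str(vcf_path)
    if not Path(vcf_path).exists():
        raise FileNotFoundError(vcf_path)
    ref_cache = _RefCache(reference)
    out: list[Variant] = []
    n_symbolic = 0
    with pysam.VariantFile(vcf_path) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            try:
                chrom_seq = ref_cache[rec.chrom]
            except KeyError:
                raise KeyError(f"contig {rec.chrom!r} absent from reference")
            alts = rec.alts or ()
            for ai, alt in enumerate(alts, start=1):
                if alt is None or _is_symbolic(alt):
                    n_symbolic += 1
                    continue
                pos, ref, alt_n = rec.pos, rec.ref.upper(), alt.upper()
                fasta_ref = chrom_seq[pos - 1 : pos - 1 + len(ref)]
                if fasta_ref != ref:
                    raise ReferenceMismatchError(
                        f"{rec.chrom}:{pos} REF {ref!r} != reference {fasta_ref!r}"
                    )
                if normalize:
                    pos, ref, alt_n = normalize_allele_pair(chrom_seq, pos, ref, alt_n)
                genotypes = None
                depths = None
                if samples:
                    genotypes, depths = {}, {}
                    for s in samples:
                        sample = rec.samples[s]
                        gt = sample.get("GT", MISSING_GT) or MISSING_GT
                        mapped = tuple(
                            None if a is None else (1 if a == ai else (0 if a == 0 else None))
                            for a in gt
                        )
                        if len(mapped) != 2:
                            mapped = MISSING_GT
                        genotypes[s] = mapped
                        depths[s] = sample.get("DP", None)
                out.append(
                    Variant(rec.chrom, pos, ref, alt_n, rec.qual, genotypes, depths)
                )
    if n_symbolic:
        log.info("excluded %d symbolic/structural alleles from %s", n_symbolic, vcf_path)
    return out


def write_variants(
    path,
    variants: Sequence[Variant],
    samples: Sequence[str] | None = None,
    contig_lengths: Mapping[str, int] | None = None,
    info_fields: Sequence[tuple[str, str, str]] = (),
) -> None:
    """Write variants as a plain-text VCF 4.2.

    ``info_fields`` lists extra INFO declarations as (ID, Type, Description);
    values are taken from each variant's ``info`` dict.
    """
    if samples is None:
        seen: dict[str, None] = {}
        for v in variants:
            if v.genotypes:
                for s in v.genotypes:
                    seen.setdefault(s)
        samples = list(seen)
    lines = ["##fileformat=VCFv4.2"]
    if contig_lengths:
        for c, ln in contig_lengths.items():
            lines.append(f"##contig=<ID={c},length={ln}>")
    for fid, ftype, desc in info_fields:
        lines.append(f'##INFO=<ID={fid},Number=1,Type={ftype},Description="{desc}">')
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER"]
    header += ["INFO", "FORMAT"] + list(samples) if samples else ["INFO"]
    lines.append("\t".join(header))
    for v in sorted(variants, key=lambda x: (x.chrom, x.pos, x.ref, x.alt)):
        qual = "." if v.qual is None else f"{v.qual:g}"
        info = (
            ";".join(f"{k}={val}" for k, val in v.info.items()) if v.info else "."
        )
        row = [v.chrom, str(v.pos), ".", v.ref, v.alt, qual, "PASS", info]
        if samples:
            row.append("GT:DP")
            for s in samples:
                gt = (v.genotypes or {}).get(s, MISSING_GT)
                gts = "/".join("." if a is None else str(a) for a in gt)
                dp = (v.depths or {}).get(s)
                row.append(f"{gts}:{'.' if dp is None else dp}")
        lines.append("\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# masks


class MaskSet:
    """Per-contig sorted, merged 0-based half-open intervals."""

    def __init__(self, intervals: Mapping[str, Iterable[tuple[int, int]]] | None = None):
        self._ivals: dict[str, list[tuple[int, int]]] = {}
        if intervals:
            for chrom, ivs in intervals.items():
                self._ivals[chrom] = self._merge(ivs)

    @staticmethod
    def _merge(ivs: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
        out: list[tuple[int, int]] = []
        for s, e in sorted(ivs):
            if s >= e:
                raise ValueError(f"empty/inverted interval ({s}, {e})")
            if out and s <= out[-1][1]:
                out[-1] = (out[-1][0], max(out[-1][1], e))
            else:
                out.append((s, e))
        return out

    @classmethod
    def from_bed(cls, path) -> "MaskSet":
        ivals: dict[str, list[tuple[int, int]]] = {}
        for line in Path(path).read_text().splitlines():
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end = line.split("\t")[:3]
            ivals.setdefault(chrom, []).append((int(start), int(end)))
        return cls(ivals)

    def to_bed(self, path) -> None:
        rows = [
            f"{c}\t{s}\t{e}"
            for c in sorted(self._ivals)
            for s, e in self._ivals[c]
        ]
        Path(path).write_text("\n".join(rows) + ("\n" if rows else ""))

    def intervals(self, chrom: str) -> list[tuple[int, int]]:
        return list(self._ivals.get(chrom, []))

    def contigs(self) -> list[str]:
        return list(self._ivals)

    def total_length(self) -> int:
        return sum(e - s for ivs in self._ivals.values() for s, e in ivs)

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        """True if [start, end) (0-based half-open) intersects any interval."""
        ivs = self._ivals.get(chrom)
        if not ivs:
            return False
        i = bisect_right(ivs, (start, float("inf"))) - 1
        if i >= 0 and ivs[i][1] > start:
            return True
        return i + 1 < len(ivs) and ivs[i + 1][0] < end

    def overlaps_variant(self, variant: Variant) -> bool:
        s, e = variant.span
        return self.overlaps(variant.chrom, s, e)

    def __len__(self) -> int:
        return sum(len(v) for v in self._ivals.values())


# ---------------------------------------------------------------------------
# metadata


META_COLUMNS = ["sample", "dosage_gy", "selfing_generations", "family"]


def read_line_meta(path) -> pd.DataFrame:
    """Read the per-line metadata TSV (sample, dosage_gy, selfing_generations, family)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "family": str})
    missing = set(META_COLUMNS[:3]) - set(df.columns)
    if missing:
        raise ValueError(f"metadata missing columns: {sorted(missing)}")
    if "family" not in df.columns:
        df["family"] = None
    if df["sample"].duplicated().any():
        raise ValueError("duplicate sample rows in metadata")
    return df.set_index("sample", drop=False)


def write_line_meta(path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False, columns=META_COLUMNS)
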