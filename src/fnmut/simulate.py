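"""Synthetic inputs with planted truth for the whole pipeline.

The generator emulates the statistical structure the analysis assumes:
a ~34% GC reference; a parental line differing from the reference at
realistic SNP/indel densities, with deletion masks covering ~3.8% of the
genome; a diversity panel whose allele-frequency spectrum follows a
truncated neutral 1/i law, spanning rare (allele count ≤ 2) and common
(≥ 3) strata; a treatment cohort of inbred lines carrying homozygous
singleton de novo SNPs drawn from a configurable 6-class strand-collapsed
spectrum with a CpG-conditional boost for C>T*, and de novo indels with a
deletion-skewed, 1-bp-dominated signed length law and an A/T bias for 1-bp
events; and optional genotype-level noise layers (heterozygous calls,
low-depth calls, shared heterogeneity variants), each the exact signature
one filter of the de novo chain is designed to remove.  Everything planted
is recorded in a truth table.  All outputs are byte-deterministic under a
fixed seed.

Default sizes mirror the study design the analysis targets (27 treatment
lines, per-line SNP mean ≈ 53 and indel mean ≈ 32, dosages 8/16/32 Gy,
3–8 selfing generations, two 3-sibling families) on a desk-scale 2 × 2 Mb
genome.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from fnmut.spectrum import COLLAPSED_CLASSES, COMPLEMENT
from fnmut.variants import (
    MaskSet,
    Variant,
    classify_variant,
    normalize_allele_pair,
    write_line_meta,
    write_variants,
)

STOP_CODONS = ("TAA", "TAG", "TGA")
_NONSTOP = tuple(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOP_CODONS and a + b + c != "ATG"
)

DEFAULT_CLASS_PROBS = {
    "C>T*": 0.458,
    "A>G*": 0.240,
    "C>A*": 0.100,
    "C>G*": 0.055,
    "A>T*": 0.080,
    "A>C*": 0.067,
}


@dataclass
class GenomeConfig:
    contigs: tuple[tuple[str, int], ...] = (("chr1", 2_000_000), ("chr2", 2_000_000))
    gc_fraction: float = 0.34


@dataclass
class ParentalConfig:
    snp_per_kb: float = 1.5
    indel_per_kb: float = 0.25
    masked_fraction: float = 0.038
    mask_interval_mean_bp: int = 5_000


@dataclass
class PanelConfig:
    n_lines: int = 30
    site_per_kb: float = 2.0
    snp_fraction: float = 0.85
    insertion_fraction: float = 0.468
    mean_depth: float = 14.0


@dataclass
class CohortConfig:
    n_lines: int = 27
    snp_mean: float = 53.0
    indel_mean: float = 32.0
    class_probs: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_PROBS))
    cpg_boost: float = 3.0
    deletion_fraction: float = 0.715
    length_geom_p: float = 0.55
    max_indel: int = 279
    at_bias_1bp: float = 0.8
    dosages: tuple[int, ...] = (8, 16, 32)
    selfing_range: tuple[int, int] = (3, 8)
    n_families: int = 2
    family_size: int = 3
    mean_depth: float = 27.0

    def __post_init__(self) -> None:
        total = sum(self.class_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class probabilities sum to {total}, not 1")


@dataclass
class NoiseConfig:
    het_per_line: float = 0.0  # Poisson mean of spurious heterozygous calls
    lowdepth_per_line: float = 0.0  # Poisson mean of low-depth artefact calls
    n_heterogeneity: int = 0  # variants shared hom-alt by >=2 non-sibling lines


@dataclass
class SimConfig:
    seed: int = 0
    genome: GenomeConfig = field(default_factory=GenomeConfig)
    parental: ParentalConfig = field(default_factory=ParentalConfig)
    panel: PanelConfig = field(default_factory=PanelConfig)
    cohort: CohortConfig = field(default_factory=CohortConfig)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    n_genes: int = 12

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SimResult:
    config: SimConfig
    reference: dict[str, str]
    transcripts: list
    parental_variants: list[Variant]
    masks: MaskSet
    panel_variants: list[Variant]
    cohort_variants: list[Variant]
    meta: pd.DataFrame
    truth: pd.DataFrame

    @property
    def contig_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.reference.items()}


# ---------------------------------------------------------------------------
# reference and gene models


def generate_reference(config: GenomeConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """i.i.d. reference bases with P(G) + P(C) = gc_fraction, as uint8 arrays."""
    gc = config.gc_fraction
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    codes = np.frombuffer(b"ACGT", dtype=np.uint8)
    return {
        name: codes[rng.choice(4, size=length, p=probs)]
        for name, length in config.contigs
    }


def reference_to_strings(ref_arrays: dict[str, np.ndarray]) -> dict[str, str]:
    return {c: a.tobytes().decode() for c, a in ref_arrays.items()}


def generate_gene_models(
    ref_arrays: dict[str, np.ndarray], n_genes: int, rng: np.random.Generator
):
    """Plant non-overlapping multi-exon genes, rewriting the reference so every
    CDS translates as a valid ORF (ATG start, single terminal stop).

    Returns :class:`fnmut.consequence.Transcript` models.  Must run before
    variant planting: it mutates the reference arrays in place.
    """
    from fnmut.consequence import Transcript

    transcripts = []
    if n_genes == 0:
        return transcripts
    chroms = list(ref_arrays)
    per_chrom = {c: [] for c in chroms}
    for gi in range(n_genes):
        per_chrom[chroms[gi % len(chroms)]].append(gi)
    for chrom, gids in per_chrom.items():
        seq = ref_arrays[chrom]
        cursor = int(rng.integers(2_000, 10_000))
        for gi in gids:
            strand = "+" if rng.random() < 0.5 else "-"
            utr_left = int(rng.integers(60, 200))
            utr_right = int(rng.integers(60, 200))
            n_ex = int(rng.integers(2, 5))
            coding_lens = [int(rng.integers(90, 400)) for _ in range(n_ex)]
            coding_lens[-1] += (3 - sum(coding_lens) % 3) % 3
            introns = [int(rng.integers(30, 120)) for _ in range(n_ex - 1)]
            total = utr_left + sum(coding_lens) + sum(introns) + utr_right
            start = cursor
            end = start + total - 1
            if end + 2_000 > len(seq):
                raise ValueError(f"genome too small to place gene {gi} on {chrom}")
            # left-to-right layout: [utr][cds1][intron][cds2]...[utr]
            exons, cds = [], []
            p = start + utr_left
            for i, cl in enumerate(coding_lens):
                cds.append((p, p + cl - 1))
                p += cl
                if i < n_ex - 1:
                    p += introns[i]
            exons.append((start, cds[0][1]))
            exons.extend(cds[1:-1])
            exons.append((cds[-1][0], end))
            if n_ex == 2:
                exons = [(start, cds[0][1]), (cds[-1][0], end)]
            _write_orf(seq, cds, strand, rng)
            tid = f"gene{gi + 1:03d}.t1"
            transcripts.append(
                Transcript(
                    tid=tid,
                    gene_id=f"gene{gi + 1:03d}",
                    chrom=chrom,
                    strand=strand,
                    start=start,
                    end=end,
                    exons=exons,
                    cds=cds,
                )
            )
            cursor = end + int(rng.integers(12_000, 40_000))
    return transcripts


def _write_orf(seq: np.ndarray, cds: list[tuple[int, int]], strand: str, rng) -> None:
    n_codons = sum(e - s + 1 for s, e in cds) // 3
    body = "".join(
        [_NONSTOP[i] for i in rng.integers(0, len(_NONSTOP), size=n_codons - 2)]
    )
    orf = "ATG" + body + STOP_CODONS[int(rng.integers(0, 3))]
    if strand == "-":
        orf = "".join(COMPLEMENT[b] for b in reversed(orf))
    flat = np.frombuffer(orf.encode(), dtype=np.uint8)
    offset = 0
    for s, e in cds:
        seq[s - 1 : e] = flat[offset : offset + (e - s + 1)]
        offset += e - s + 1


def write_gff3(path, transcripts, contig_lengths: dict[str, int]) -> None:
    lines = ["##gff-version 3"]
    for c, ln in contig_lengths.items():
        lines.append(f"##sequence-region {c} 1 {ln}")
    for t in sorted(transcripts, key=lambda t: (t.chrom, t.start)):
        gid = t.gene_id
        lines.append(
            f"{t.chrom}\tfnmut\tgene\t{t.start}\t{t.end}\t.\t{t.strand}\t.\tID={gid}"
        )
        lines.append(
            f"{t.chrom}\tfnmut\tmRNA\t{t.start}\t{t.end}\t.\t{t.strand}\t.\t"
            f"ID={t.tid};Parent={gid}"
        )
        for i, (s, e) in enumerate(t.exons, 1):
            lines.append(
                f"{t.chrom}\tfnmut\texon\t{s}\t{e}\t.\t{t.strand}\t.\t"
                f"ID={t.tid}.exon{i};Parent={t.tid}"
            )
        cds_in_order = t.cds if t.strand == "+" else list(reversed(t.cds))
        cum = 0
        for i, (s, e) in enumerate(cds_in_order, 1):
            phase = (3 - cum % 3) % 3
            cum += e - s + 1
            lines.append(
                f"{t.chrom}\tfnmut\tCDS\t{s}\t{e}\t.\t{t.strand}\t{phase}\t"
                f"ID={t.tid}.cds;Parent={t.tid}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# planting machinery


class _Planter:
    """Places variants at non-overlapping, unmasked sites on a frozen reference."""

    def __init__(self, reference: dict[str, str], masks: MaskSet | None, rng):
        self.ref = reference
        self.rng = rng
        self.chroms = list(reference)
        self.lengths = np.array([len(reference[c]) for c in self.chroms], dtype=float)
        self.weights = self.lengths / self.lengths.sum()
        self.occupied = {
            c: np.zeros(len(reference[c]), dtype=bool) for c in self.chroms
        }
        self.masks = masks
        self.n_resampled = 0
        if masks is not None:
            for c in self.chroms:
                for s, e in masks.intervals(c):
                    self.occupied[c][s:e] = True

    def random_pos(self) -> tuple[str, int]:
        ci = int(self.rng.choice(len(self.chroms), p=self.weights))
        chrom = self.chroms[ci]
        pos = int(self.rng.integers(1, len(self.ref[chrom]) + 1))
        return chrom, pos

    def claim(self, chrom: str, span: tuple[int, int], pad: int = 1) -> bool:
        s = max(0, span[0] - pad)
        e = min(len(self.ref[chrom]), span[1] + pad)
        if self.occupied[chrom][s:e].any():
            return False
        self.occupied[chrom][s:e] = True
        return True

    # --- SNPs -------------------------------------------------------------

    def plant_snp(self, cls_probs: dict[str, float], cpg_boost: float,
                  max_tries: int = 10_000):
        """One SNP drawn from the collapsed-class law with CpG boost for C>T*.

        Returns (chrom, pos, ref, alt, collapsed_class, is_cpg).
        """
        classes = list(cls_probs)
        probs = np.array([cls_probs[c] for c in classes])
        cls = classes[int(self.rng.choice(len(classes), p=probs))]
        canon_ref, canon_alt = cls[0], cls[2]
        want = {canon_ref, COMPLEMENT[canon_ref]}
        for _ in range(max_tries):
            chrom, pos = self.random_pos()
            base = self.ref[chrom][pos - 1]
            if base not in want:
                continue
            cpg = self._is_cpg(chrom, pos, base)
            if cls == "C>T*" and cpg_boost > 1 and not cpg:
                if self.rng.random() >= 1.0 / cpg_boost:
                    continue
            if not self.claim(chrom, (pos - 1, pos)):
                self.n_resampled += 1
                continue
            alt = canon_alt if base == canon_ref else COMPLEMENT[canon_alt]
            return chrom, pos, base, alt, cls, cpg
        raise RuntimeError("genome too small to place requested SNPs")

    def plant_uniform_snp(self, max_tries: int = 10_000):
        """SNP with uniform alt among the three non-reference bases."""
        for _ in range(max_tries):
            chrom, pos = self.random_pos()
            base = self.ref[chrom][pos - 1]
            if not self.claim(chrom, (pos - 1, pos)):
                self.n_resampled += 1
                continue
            alts = [b for b in "ACGT" if b != base]
            return chrom, pos, base, alts[int(self.rng.integers(0, 3))]
        raise RuntimeError("genome too small to place requested SNPs")

    def _is_cpg(self, chrom: str, pos: int, base: str) -> bool:
        seq = self.ref[chrom]
        if base == "C":
            return pos < len(seq) and seq[pos] == "G"
        if base == "G":
            return pos > 1 and seq[pos - 2] == "C"
        return False

    # --- indels -----------------------------------------------------------

    def plant_indel(self, deletion_fraction: float, geom_p: float, max_len: int,
                    at_bias_1bp: float, max_tries: int = 20_000):
        """One indel: signed length from a deletion-skewed geometric law,
        1-bp events with an A/T base bias.

        Returns (chrom, pos, ref, alt, signed_length).
        """
        is_del = self.rng.random() < deletion_fraction
        length = min(int(self.rng.geometric(geom_p)), max_len)
        biased_base = None
        if length == 1:
            if self.rng.random() < at_bias_1bp:
                biased_base = "AT"[int(self.rng.integers(0, 2))]
            else:
                biased_base = "CG"[int(self.rng.integers(0, 2))]
        for _ in range(max_tries):
            chrom, pos = self.random_pos()
            seq = self.ref[chrom]
            if is_del:
                if pos + length > len(seq) or pos < 1:
                    continue
                if biased_base is not None and seq[pos] != biased_base:
                    continue
                ref = seq[pos - 1 : pos + length]
                alt = seq[pos - 1]
            else:
                anchor = seq[pos - 1]
                if biased_base is not None:
                    ins = biased_base
                else:
                    ins = "".join(
                        "ACGT"[i] for i in self.rng.integers(0, 4, size=length)
                    )
                ref = anchor
                alt = anchor + ins
            npos, nref, nalt = normalize_allele_pair(seq, pos, ref, alt)
            span = (npos - 1, npos - 1 + len(nref))
            if not self.claim(chrom, span):
                self.n_resampled += 1
                continue
            signed = len(nalt) - len(nref)
            return chrom, npos, nref, nalt, signed
        raise RuntimeError("genome too small to place requested indels")


# ---------------------------------------------------------------------------
# parental, panel, cohort


def generate_masks(
    reference: dict[str, str], config: ParentalConfig, rng: np.random.Generator
) -> MaskSet:
    """Deletion masks covering ``masked_fraction`` of the genome, merged/sorted."""
    genome_len = sum(len(s) for s in reference.values())
    target = config.masked_fraction * genome_len
    ivals: dict[str, list[tuple[int, int]]] = {c: [] for c in reference}
    chroms = list(reference)
    lengths = np.array([len(reference[c]) for c in chroms], dtype=float)
    weights = lengths / lengths.sum()
    covered = 0.0
    taken: dict[str, np.ndarray] = {c: np.zeros(len(reference[c]), bool) for c in chroms}
    while covered < target:
        c = chroms[int(rng.choice(len(chroms), p=weights))]
        ln = max(200, int(rng.exponential(config.mask_interval_mean_bp)))
        ln = int(min(ln, target - covered + 200))
        start = int(rng.integers(0, len(reference[c]) - ln))
        if taken[c][start : start + ln].any():
            continue
        taken[c][start : start + ln] = True
        ivals[c].append((start, start + ln))
        covered += ln
    return MaskSet(ivals)


def generate_parental(
    reference: dict[str, str],
    config: ParentalConfig,
    rng: np.random.Generator,
    planter: _Planter | None = None,
    masks: MaskSet | None = None,
) -> tuple[list[Variant], MaskSet, _Planter]:
    """Parental-line differences from the reference plus deletion masks.

    Returns (variants, masks, planter); the planter carries site occupancy
    forward so later planting stays disjoint from parental sites and masks.
    """
    if masks is None:
        masks = generate_masks(reference, config, rng)
    if planter is None:
        planter = _Planter(reference, masks, rng)
    genome_kb = sum(len(s) for s in reference.values()) / 1_000
    n_snp = int(rng.poisson(config.snp_per_kb * genome_kb))
    n_indel = int(rng.poisson(config.indel_per_kb * genome_kb))
    variants: list[Variant] = []
    for _ in range(n_snp):
        chrom, pos, ref, alt = planter.plant_uniform_snp()
        variants.append(
            Variant(chrom, pos, ref, alt, 200.0, {"PARENT": (1, 1)}, {"PARENT": 60})
        )
    for _ in range(n_indel):
        chrom, pos, ref, alt, _ = planter.plant_indel(0.5, 0.5, 50, 0.6)
        variants.append(
            Variant(chrom, pos, ref, alt, 200.0, {"PARENT": (1, 1)}, {"PARENT": 60})
        )
    return variants, masks, planter


def generate_panel(
    reference: dict[str, str],
    config: PanelConfig,
    cohort: CohortConfig,
    rng: np.random.Generator,
    planter: _Planter,
) -> list[Variant]:
    """Diversity panel with allele counts from a truncated neutral 1/i law.

    Allele counts span 1..n_lines−1; the configured copies are assigned to
    haplotypes uniformly, so both rare (AC ≤ 2) and common (AC ≥ 3) strata
    are populated at defaults.
    """
    n = config.n_lines
    samples = [f"P{i + 1:03d}" for i in range(n)]
    genome_kb = sum(len(s) for s in reference.values()) / 1_000
    n_sites = int(rng.poisson(config.site_per_kb * genome_kb))
    if n >= 2:
        ac_support = np.arange(1, n)
        ac_probs = (1.0 / ac_support) / (1.0 / ac_support).sum()
    variants: list[Variant] = []
    for _ in range(n_sites):
        if rng.random() < config.snp_fraction:
            chrom, pos, ref, alt = planter.plant_uniform_snp()
        else:
            chrom, pos, ref, alt, _ = planter.plant_indel(
                1 - config.insertion_fraction, 0.5, 50, cohort.at_bias_1bp
            )
        ac = int(rng.choice(ac_support, p=ac_probs)) if n >= 2 else 1
        hap_idx = rng.choice(2 * n, size=ac, replace=False)
        gts = {s: [0, 0] for s in samples}
        for h in hap_idx:
            gts[samples[h // 2]][h % 2] = 1
        genotypes = {s: tuple(g) for s, g in gts.items()}
        depths = {s: max(2, int(rng.poisson(config.mean_depth))) for s in samples}
        variants.append(Variant(chrom, pos, ref, alt, 150.0, genotypes, depths))
    return variants


def generate_line_meta(config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Cohort metadata: dosages, selfing generations, sibling families."""
    rows = []
    li = 0
    for f in range(config.n_families):
        dosage = int(rng.choice(config.dosages))
        selfing = int(rng.integers(config.selfing_range[0], config.selfing_range[1] + 1))
        for _ in range(config.family_size):
            rows.append((f"FN{li + 1:02d}", dosage, selfing, f"F{f + 1}"))
            li += 1
    while li < config.n_lines:
        dosage = int(rng.choice(config.dosages))
        selfing = int(rng.integers(config.selfing_range[0], config.selfing_range[1] + 1))
        rows.append((f"FN{li + 1:02d}", dosage, selfing, ""))
        li += 1
    df = pd.DataFrame(rows, columns=["sample", "dosage_gy", "selfing_generations", "family"])
    return df.set_index("sample", drop=False)


def generate_fn_cohort(
    reference: dict[str, str],
    config: CohortConfig,
    noise: NoiseConfig,
    rng: np.random.Generator,
    planter: _Planter,
    meta: pd.DataFrame | None = None,
) -> tuple[list[Variant], pd.DataFrame, pd.DataFrame]:
    """Treatment cohort: per-line Poisson SNP/indel counts planted hom-alt at
    unmasked, non-parental, mutually non-overlapping sites, plus noise layers.

    Returns (multi-sample variants, metadata, truth table).
    """
    if meta is None:
        meta = generate_line_meta(config, rng)
    samples = list(meta.index)
    truth_rows = []
    variants: list[Variant] = []

    def make_record(chrom, pos, ref, alt, carriers, gt, depth_override=None):
        genotypes = {s: (0, 0) for s in samples}
        depths = {
            s: max(10, int(rng.poisson(config.mean_depth))) for s in samples
        }
        for s in carriers:
            genotypes[s] = gt
            if depth_override is not None:
                depths[s] = depth_override
        qual = float(rng.uniform(60, 200))
        variants.append(Variant(chrom, pos, ref, alt, qual, genotypes, depths))

    for line in samples:
        for _ in range(int(rng.poisson(config.snp_mean))):
            chrom, pos, ref, alt, cls, cpg = planter.plant_snp(
                config.class_probs, config.cpg_boost
            )
            make_record(chrom, pos, ref, alt, [line], (1, 1))
            truth_rows.append(
                (chrom, pos, ref, alt, line, "SNP", cls, 0, cpg, "planted")
            )
        for _ in range(int(rng.poisson(config.indel_mean))):
            chrom, pos, ref, alt, signed = planter.plant_indel(
                config.deletion_fraction,
                config.length_geom_p,
                config.max_indel,
                config.at_bias_1bp,
            )
            kind = "insertion" if signed > 0 else "deletion"
            make_record(chrom, pos, ref, alt, [line], (1, 1))
            truth_rows.append(
                (chrom, pos, ref, alt, line, kind, "", signed, False, "planted")
            )

    # --- noise layers, each tagged with the filter designed to remove it
    for line in samples:
        for _ in range(int(rng.poisson(noise.het_per_line))):
            chrom, pos, ref, alt = planter.plant_uniform_snp()
            make_record(chrom, pos, ref, alt, [line], (0, 1))
            truth_rows.append(
                (chrom, pos, ref, alt, line, "SNP", "", 0, False, "noise_het")
            )
        for _ in range(int(rng.poisson(noise.lowdepth_per_line))):
            chrom, pos, ref, alt = planter.plant_uniform_snp()
            make_record(
                chrom, pos, ref, alt, [line], (1, 1),
                depth_override=int(rng.integers(1, 5)),
            )
            truth_rows.append(
                (chrom, pos, ref, alt, line, "SNP", "", 0, False, "noise_lowdepth")
            )
    families = meta["family"].fillna("").to_dict()
    for _ in range(noise.n_heterogeneity):
        chrom, pos, ref, alt = planter.plant_uniform_snp()
        while True:  # carriers must span more than one family
            k = int(rng.integers(2, 5))
            carriers = [samples[i] for i in rng.choice(len(samples), size=k, replace=False)]
            fams = {families.get(s) or s for s in carriers}
            if len(fams) > 1:
                break
        make_record(chrom, pos, ref, alt, carriers, (1, 1))
        for s in carriers:
            truth_rows.append(
                (chrom, pos, ref, alt, s, "SNP", "", 0, False, "noise_heterogeneity")
            )

    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "chrom", "pos", "ref", "alt", "line", "kind",
            "collapsed_class", "signed_length", "cpg", "tag",
        ],
    )
    return variants, meta, truth


# ---------------------------------------------------------------------------
# orchestration


def simulate(config: SimConfig | None = None) -> SimResult:
    """Generate every pipeline input in memory with planted truth."""
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed)
    ref_arrays = generate_reference(config.genome, rng)
    transcripts = generate_gene_models(ref_arrays, config.n_genes, rng)
    reference = reference_to_strings(ref_arrays)
    parental, masks, planter = generate_parental(reference, config.parental, rng)
    panel = generate_panel(reference, config.panel, config.cohort, rng, planter)
    cohort, meta, truth = generate_fn_cohort(
        reference, config.cohort, config.noise, rng, planter
    )
    return SimResult(
        config=config,
        reference=reference,
        transcripts=transcripts,
        parental_variants=parental,
        masks=masks,
        panel_variants=panel,
        cohort_variants=cohort,
        meta=meta,
        truth=truth,
    )


def write_fasta(path, reference: dict[str, str], width: int = 60) -> None:
    lines = []
    for chrom, seq in reference.items():
        lines.append(f">{chrom}")
        lines.extend(seq[i : i + width] for i in range(0, len(seq), width))
    Path(path).write_text("\n".join(lines) + "\n")


def simulate_all(config: SimConfig | None = None, outdir=".") -> dict[str, Path]:
    """Run :func:`simulate` and write all standard-format outputs to ``outdir``."""
    import pyfaidx

    config = config or SimConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    res = simulate(config)
    paths = {
        "reference": outdir / "reference.fa",
        "parental": outdir / "parental.vcf",
        "mask": outdir / "mask.bed",
        "panel": outdir / "panel.vcf",
        "fn_lines": outdir / "fn_lines.vcf",
        "meta": outdir / "meta.tsv",
        "genes": outdir / "genes.gff3",
        "truth": outdir / "truth.tsv",
    }
    clen = res.contig_lengths
    write_fasta(paths["reference"], res.reference)
    pyfaidx.Faidx(str(paths["reference"]))  # build .fai
    write_variants(paths["parental"], res.parental_variants, ["PARENT"], clen)
    res.masks.to_bed(paths["mask"])
    panel_samples = [f"P{i + 1:03d}" for i in range(config.panel.n_lines)]
    write_variants(paths["panel"], res.panel_variants, panel_samples, clen)
    write_variants(paths["fn_lines"], res.cohort_variants, list(res.meta.index), clen)
    write_line_meta(paths["meta"], res.meta)
    write_gff3(paths["genes"], res.transcripts, clen)
    res.truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths
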