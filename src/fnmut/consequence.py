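"""Indel length spectra and a minimal gene-model-based consequence classifier.

The classifier emits one label per (variant, transcript) pair using the
standard effect-predictor vocabulary (frameshift, missense, synonymous,
splice_region, UTR, intron, upstream/downstream, intergenic...), with
precedence frameshift/stop_gained/stop_lost/start_lost > inframe > missense
> splice_region > synonymous > UTR > intron.  A frameshift is an indel whose
CDS-overlapping length change is not a multiple of 3; an indel straddling a
CDS boundary counts only its CDS-overlapping bases.  It is deliberately not
a full effect-predictor replacement: no regulatory features, no protein
domains, no known-variant lookup.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.Seq import Seq

from fnmut.variants import Variant, VariantClass, classify_variant, _RefCache

CODING_CLASSES = (
    "stop_gained",
    "frameshift",
    "stop_lost",
    "start_lost",
    "inframe_insertion",
    "inframe_deletion",
    "protein_altering",
    "missense",
    "synonymous",
    "start_retained",
    "stop_retained",
    "coding_sequence",
)

ALL_LABELS = CODING_CLASSES + (
    "splice_region",
    "5_prime_UTR",
    "3_prime_UTR",
    "intron",
    "upstream",
    "downstream",
    "intergenic",
)


@dataclass
class Transcript:
    """One transcript model: 1-based inclusive exon and CDS intervals, sorted."""

    tid: str
    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]]

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons)
        self.cds = sorted(self.cds)
        for name, ivs in (("exons", self.exons), ("cds", self.cds)):
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                if s2 <= e1:
                    raise ValueError(f"overlapping {name} in {self.tid}")
        for s, e in self.cds:
            if not any(xs <= s and e <= xe for xs, xe in self.exons):
                raise ValueError(f"CDS outside exons in {self.tid}")

    def cds_sequence(self, chrom_seq: str) -> str:
        """Spliced coding sequence in translation (5'→3') orientation."""
        parts = [chrom_seq[s - 1 : e] for s, e in self.cds]
        seq = "".join(parts)
        if self.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        return seq

    def cds_index_of(self, pos: int) -> int | None:
        """0-based index of a genomic position within the spliced CDS, or None."""
        offset = 0
        for s, e in self.cds:
            if s <= pos <= e:
                idx = offset + (pos - s)
                if self.strand == "-":
                    total = sum(e2 - s2 + 1 for s2, e2 in self.cds)
                    return total - 1 - idx
                return idx
            offset += e - s + 1
        return None


def load_gene_models(gff3_path) -> list[Transcript]:
    """Parse a GFF3 into :class:`Transcript` models (via gffutils)."""
    import gffutils

    db = gffutils.create_db(
        str(gff3_path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    out: list[Transcript] = []
    for mrna in db.features_of_type("mRNA"):
        exons = [(f.start, f.end) for f in db.children(mrna, featuretype="exon")]
        cds = [(f.start, f.end) for f in db.children(mrna, featuretype="CDS")]
        gene_id = mrna.attributes.get("Parent", [mrna.id])[0]
        out.append(
            Transcript(
                tid=mrna.id,
                gene_id=gene_id,
                chrom=mrna.seqid,
                strand=mrna.strand,
                start=mrna.start,
                end=mrna.end,
                exons=exons or [(mrna.start, mrna.end)],
                cds=cds,
            )
        )
    return out


@dataclass(frozen=True)
class ConsequenceRecord:
    variant_key: tuple
    transcript_id: str | None
    label: str


# ---------------------------------------------------------------------------
# indel spectra


@dataclass
class IndelLengthSpectrum:
    """Signed-length histogram (insertions > 0, deletions < 0) for one cohort."""

    cohort: str
    histogram: dict[int, int]

    def __post_init__(self) -> None:
        if not self.histogram:
            raise ValueError("empty indel set")
        if any(l == 0 for l in self.histogram):
            raise ValueError("length 0 is not an indel")

    @property
    def n_insertions(self) -> int:
        return sum(c for l, c in self.histogram.items() if l > 0)

    @property
    def n_deletions(self) -> int:
        return sum(c for l, c in self.histogram.items() if l < 0)

    @property
    def insertion_fraction(self) -> float:
        return self.n_insertions / (self.n_insertions + self.n_deletions)

    def to_frame(self, display_cap: int | None = None) -> pd.DataFrame:
        items = sorted(self.histogram.items())
        if display_cap is not None:
            items = [(l, c) for l, c in items if abs(l) <= display_cap]
        return pd.DataFrame(items, columns=["signed_length", "count"]).assign(
            cohort=self.cohort
        )


def indel_length_spectrum(
    variants: Iterable[Variant], cohort_label: str, display_cap: int = 20
) -> IndelLengthSpectrum:
    """Histogram of signed indel lengths; the display cap only affects plotting."""
    hist: Counter = Counter()
    for v in variants:
        vc = classify_variant(v.ref, v.alt)
        if vc.label not in ("insertion", "deletion"):
            raise ValueError(f"non-indel variant {v.key}")
        hist[vc.signed_length] += 1
    return IndelLengthSpectrum(cohort_label, dict(hist))


def insertion_fraction_from_counts(n_insertions: int, n_deletions: int) -> float:
    """Insertion share of an indel set given direction totals."""
    if n_insertions + n_deletions == 0:
        raise ValueError("empty indel set")
    return n_insertions / (n_insertions + n_deletions)


def single_bp_identity(variants: Iterable[Variant]) -> pd.DataFrame:
    """Tally the non-anchor base of 1-bp indels per direction.

    Returns a deleted/inserted × A/C/G/T count table.
    """
    counts = pd.DataFrame(0, index=["inserted", "deleted"], columns=list("ACGT"))
    n = 0
    for v in variants:
        vc = classify_variant(v.ref, v.alt)
        if abs(vc.signed_length) != 1 or vc.label == "other":
            raise ValueError(f"not a 1-bp indel: {v.key}")
        if vc.label == "insertion":
            counts.loc["inserted", v.alt[-1]] += 1
        else:
            counts.loc["deleted", v.ref[-1]] += 1
        n += 1
    if n == 0:
        raise ValueError("empty input")
    return counts


# ---------------------------------------------------------------------------
# consequence classification

_SEVERITY = {label: i for i, label in enumerate([
    "frameshift", "stop_gained", "stop_lost", "start_lost",
    "inframe_insertion", "inframe_deletion",
    "missense", "splice_region", "synonymous",
    "5_prime_UTR", "3_prime_UTR", "intron",
])}


def _pick(labels: set[str]) -> str:
    return min(labels, key=lambda l: _SEVERITY[l])


def _overlap_len(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]) + 1)


def classify_consequence(
    variant: Variant,
    gene_models: Sequence[Transcript],
    reference,
    flank_bp: int = 5000,
    splice_exonic: int = 3,
    splice_intronic: int = 8,
    _ref_cache: _RefCache | None = None,
) -> list[ConsequenceRecord]:
    """Label one variant against every transcript within ``flank_bp``.

    Returns one record per (variant, transcript) pair — the same accounting
    an effect predictor uses when reporting affected-transcript counts — or
    a single intergenic record when nothing is in range.
    """
    cache = _ref_cache or _RefCache(reference)
    vc = classify_variant(variant.ref, variant.alt)
    records: list[ConsequenceRecord] = []
    # affected genomic interval, 1-based inclusive
    if vc.label == "deletion":
        affected = (variant.pos + len(variant.alt), variant.pos + len(variant.ref) - 1)
    elif vc.label == "insertion":
        affected = (variant.pos, variant.pos + 1)  # insertion point between the two
    else:
        affected = (variant.pos, variant.pos + len(variant.ref) - 1)
    for t in gene_models:
        if t.chrom != variant.chrom:
            continue
        if affected[1] < t.start - flank_bp or affected[0] > t.end + flank_bp:
            continue
        if affected[1] < t.start or affected[0] > t.end:
            before = affected[1] < t.start
            if t.strand == "+":
                label = "upstream" if before else "downstream"
            else:
                label = "downstream" if before else "upstream"
            records.append(ConsequenceRecord(variant.key, t.tid, label))
            continue
        records.append(
            ConsequenceRecord(
                variant.key,
                t.tid,
                _label_within(variant, vc, affected, t, cache[t.chrom],
                              splice_exonic, splice_intronic),
            )
        )
    if not records:
        records.append(ConsequenceRecord(variant.key, None, "intergenic"))
    return records


def _label_within(
    variant: Variant,
    vc: VariantClass,
    affected: tuple[int, int],
    t: Transcript,
    chrom_seq: str,
    splice_exonic: int,
    splice_intronic: int,
) -> str:
    labels: set[str] = set()
    cds_overlap = sum(_overlap_len(affected, c) for c in t.cds)
    if vc.label in ("insertion", "deletion"):
        if vc.label == "insertion":
            inside_cds = any(s <= variant.pos < e for s, e in t.cds)
            coding_change = vc.signed_length if inside_cds else 0
        else:
            coding_change = -cds_overlap
        if coding_change != 0:
            if coding_change % 3 != 0:
                labels.add("frameshift")
            else:
                labels.add(
                    "inframe_insertion" if vc.label == "insertion" else "inframe_deletion"
                )
    elif vc.label == "SNP" and cds_overlap:
        labels.add(_snp_coding_label(variant, t, chrom_seq))
    if _near_splice(affected, t, splice_exonic, splice_intronic):
        labels.add("splice_region")
    if not labels or labels == {"splice_region"}:
        in_exon = any(_overlap_len(affected, x) for x in t.exons)
        if in_exon and not cds_overlap:
            labels.add(_utr_side(affected, t))
        elif not in_exon and not cds_overlap:
            labels.add("intron")
    return _pick(labels)


def _snp_coding_label(variant: Variant, t: Transcript, chrom_seq: str) -> str:
    idx = t.cds_index_of(variant.pos)
    if idx is None:
        return "splice_region"  # unreachable under cds_overlap, defensive
    cds = t.cds_sequence(chrom_seq)
    alt = variant.alt if t.strand == "+" else str(Seq(variant.alt).reverse_complement())
    codon_i = idx // 3
    codon = cds[codon_i * 3 : codon_i * 3 + 3]
    mutated = codon[: idx % 3] + alt + codon[idx % 3 + 1 :]
    if len(codon) < 3:  # malformed/truncated model tail
        return "coding_sequence"
    aa_old = str(Seq(codon).translate())
    aa_new = str(Seq(mutated).translate())
    if codon_i == 0 and aa_old == "M" and aa_new != "M":
        return "start_lost"
    if aa_old == "*" and aa_new != "*":
        return "stop_lost"
    if aa_new == "*" and aa_old != "*":
        return "stop_gained"
    return "synonymous" if aa_old == aa_new else "missense"


def _near_splice(
    affected: tuple[int, int], t: Transcript, splice_exonic: int, splice_intronic: int
) -> bool:
    """Within ``splice_exonic`` exonic / ``splice_intronic`` intronic bases of an
    internal exon–intron junction (donor/acceptor folded into splice_region)."""
    for i, (s, e) in enumerate(t.exons):
        junctions = []
        if i > 0:
            junctions.append(("acceptor", s))
        if i < len(t.exons) - 1:
            junctions.append(("donor", e))
        for _, j in junctions:
            if j == s:  # exon start: exonic side right, intronic side left
                exonic = (s, min(e, s + splice_exonic - 1))
                intronic = (s - splice_intronic, s - 1)
            else:  # exon end
                exonic = (max(s, e - splice_exonic + 1), e)
                intronic = (e + 1, e + splice_intronic)
            if _overlap_len(affected, exonic) or _overlap_len(affected, intronic):
                return True
    return False


def _utr_side(affected: tuple[int, int], t: Transcript) -> str:
    if not t.cds:
        return "5_prime_UTR"  # non-coding model: arbitrary but stable
    cds_start, cds_end = t.cds[0][0], t.cds[-1][1]
    before = affected[1] < cds_start
    if t.strand == "+":
        return "5_prime_UTR" if before else "3_prime_UTR"
    return "3_prime_UTR" if before else "5_prime_UTR"


def consequence_summary(
    records: Iterable[ConsequenceRecord], cohort_label: str = ""
) -> pd.DataFrame:
    """Aggregate records to label counts and proportions (affected-transcript table)."""
    counts = Counter(r.label for r in records)
    total = sum(counts.values())
    rows = [
        {"label": l, "count": counts.get(l, 0),
         "proportion_pct": 100 * counts.get(l, 0) / total if total else 0.0}
        for l in ALL_LABELS
    ]
    return pd.DataFrame(rows).assign(cohort=cohort_label)


def frameshift_fraction_of_coding(summary: Mapping[str, int] | pd.DataFrame) -> float:
    """Frameshift share of coding-class records, as a percentage."""
    if isinstance(summary, pd.DataFrame):
        summary = dict(zip(summary["label"], summary["count"]))
    norm = {str(k).strip().lower(): v for k, v in summary.items()}
    coding = sum(norm.get(c, 0) for c in CODING_CLASSES)
    if coding == 0:
        raise ValueError("zero coding denominator")
    return 100.0 * norm.get("frameshift", 0) / coding
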