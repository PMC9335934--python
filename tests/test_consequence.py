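"""Indel spectra, 1-bp base identity and the gene-model consequence classifier."""

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

from fnmut.consequence import (
    Transcript,
    classify_consequence,
    consequence_summary,
    frameshift_fraction_of_coding,
    indel_length_spectrum,
    insertion_fraction_from_counts,
    single_bp_identity,
)
from fnmut.variants import Variant, classify_variant


# ---------------------------------------------------------------------------
# hand-built single-gene fixture
#
# chr layout (1-based):  1..10 upstream, 11..13 5'UTR, gene CDS split over
# two exons: CDS1 = 14..25 (12 bp), intron 26..55 (30 bp), CDS2 = 56..73
# (18 bp), 3'UTR 74..76, downstream from 77.
CDS1 = "ATGGCTTCTCGT"  # M A S R
CDS2 = "GGGACCTTAGAACTGTGA"  # G T L E L *
SEQ = "TTTTTTTTTT" + "CCC" + CDS1 + ("T" * 30) + CDS2 + "GGG" + ("A" * 6000)
REF = {"c1": SEQ}

GENE = Transcript(
    tid="t1",
    gene_id="g1",
    chrom="c1",
    strand="+",
    start=11,
    end=76,
    exons=[(11, 25), (56, 76)],
    cds=[(14, 25), (56, 73)],
)


def label_of(variant, **kw):
    recs = classify_consequence(variant, [GENE], REF, **kw)
    assert len(recs) == 1
    return recs[0].label


class TestClassifier:
    def test_cds_translates_in_fixture(self):
        assert str(Seq(GENE.cds_sequence(SEQ)).translate()) == "MASRGTLEL*"

    def test_synonymous_snp(self):
        # codon 2 GCT→GCC, both Ala (pos 19 T→C)
        assert label_of(Variant("c1", 19, "T", "C")) == "synonymous"

    def test_missense_snp(self):
        # codon 2 GCT→GTT: Ala→Val (pos 18 C→T)
        assert label_of(Variant("c1", 18, "C", "T")) == "missense"

    def test_stop_gained(self):
        # codon 3 TCT→TGA needs 2 changes; use codon 4 CGT→TGT? Arg→Cys is
        # missense; TCT(Ser)→TAA? use pos 23: TCT codon at 20..22 — switch
        # codon 8 TTA in CDS2: TTA(Leu) at CDS idx 21..23 → genome 65..67?
        # simpler: codon 2 of CDS2 ACC: genome 59..61; TAA not reachable in
        # one change. Use Leu codon TTA at genome 62..64 → TAA via T62A? that
        # codon is CDS idx: 56..73 maps CDS idx 12.. so genome 62 is idx 18,
        # codon 7 (idx 18..20) = TTA. T→A at its first base: still checks
        # aa: TTA→ATA (Ile) missense. Second base T→A: TAA stop.
        assert label_of(Variant("c1", 63, "T", "A")) == "stop_gained"

    def test_stop_lost(self):
        # terminal codon TGA at genome 71..73; TGA→TGC = Cys
        assert label_of(Variant("c1", 73, "A", "C")) == "stop_lost"

    def test_start_lost(self):
        assert label_of(Variant("c1", 14, "A", "C")) == "start_lost"

    def test_one_bp_deletion_in_cds_is_frameshift(self):
        assert label_of(Variant("c1", 17, "GC", "G")) == "frameshift"

    def test_three_bp_deletion_in_cds_is_inframe(self):
        assert label_of(Variant("c1", 16, "GGCT", "G")) == "inframe_deletion"

    def test_three_bp_insertion_in_cds_is_inframe(self):
        assert label_of(Variant("c1", 16, "G", "GAAA")) == "inframe_insertion"

    def test_intron_snp(self):
        assert label_of(Variant("c1", 40, "T", "C")) == "intron"

    def test_splice_region_intronic(self):
        # within 8 intronic bases of the donor junction at exon1 end (25)
        assert label_of(Variant("c1", 27, "T", "C")) == "splice_region"

    def test_utr_labels(self):
        assert label_of(Variant("c1", 12, "C", "T")) == "5_prime_UTR"
        assert label_of(Variant("c1", 75, "G", "T")) == "3_prime_UTR"

    def test_upstream_downstream_by_strand(self):
        assert label_of(Variant("c1", 5, "T", "C")) == "upstream"
        assert label_of(Variant("c1", 100, "A", "C")) == "downstream"
        minus = Transcript("t2", "g2", "c1", "-", GENE.start, GENE.end,
                           GENE.exons, GENE.cds)
        rec = classify_consequence(Variant("c1", 5, "T", "C"), [minus], REF)
        assert rec[0].label == "downstream"

    def test_intergenic_beyond_flank(self):
        assert label_of(Variant("c1", 5, "T", "C"), flank_bp=3) == "intergenic"
        # ~6 kb past the gene end with default 5 kb flank
        assert label_of(Variant("c1", 6070, "A", "C")) == "intergenic"

    def test_variant_on_contig_without_models_is_intergenic(self):
        recs = classify_consequence(Variant("c2", 5, "A", "C"), [GENE], {"c2": "A" * 10})
        assert recs[0].label == "intergenic"

    def test_deletion_straddling_cds_boundary_counts_cds_bases(self):
        # deletion of 74..76 (3'UTR, 3 bp) plus 72..73 (CDS, 2 bp): anchor 71
        v = Variant("c1", 71, SEQ[70:76], SEQ[70])
        assert label_of(v) == "frameshift"  # 2 CDS bases lost, 2 % 3 != 0


class TestStrandMirror:
    def test_mirror_fixture_gives_identical_labels(self):
        """Reverse-complementing genome and coordinates preserves labels."""
        from fnmut.spectrum import revcomp

        L = len(SEQ)
        mirror_seq = revcomp(SEQ)
        mt = Transcript(
            "t1m", "g1m", "c1", "-",
            L + 1 - GENE.end, L + 1 - GENE.start,
            [(L + 1 - e, L + 1 - s) for s, e in GENE.exons],
            [(L + 1 - e, L + 1 - s) for s, e in GENE.cds],
        )
        cases = [(19, "T", "C"), (18, "C", "T"), (63, "T", "A"), (14, "A", "C"),
                 (40, "T", "C"), (12, "C", "T"), (75, "G", "T")]
        for pos, ref, alt in cases:
            fwd = label_of(Variant("c1", pos, ref, alt))
            mv = Variant("c1", L + 1 - pos, revcomp(ref), revcomp(alt))
            rev = classify_consequence(mv, [mt], {"c1": mirror_seq})[0].label
            assert fwd == rev, (pos, ref, alt)


class TestTranslationOracle:
    def test_labels_match_translate_and_compare_oracle(self, sim_default):
        """Coding SNP/indel labels equal a splice-translate-compare oracle."""
        rng = np.random.default_rng(99)
        transcripts = sim_default.transcripts
        reference = sim_default.reference
        n_checked = 0
        for t in transcripts:
            seq = reference[t.chrom]
            cds_seq = t.cds_sequence(seq)
            for _ in range(15):
                # variant fully inside one CDS interval, clear of junctions
                # and of the first/last codon
                s, e = t.cds[int(rng.integers(0, len(t.cds)))]
                lo, hi = s + 4, e - 6
                if hi <= lo:
                    continue
                pos = int(rng.integers(lo, hi))
                if rng.random() < 0.5:
                    ref = seq[pos - 1]
                    alt = "ACGT"[int(rng.integers(0, 4))]
                    if alt == ref:
                        continue
                    v = Variant(t.chrom, pos, ref, alt)
                else:
                    ln = int(rng.integers(1, 5))
                    if rng.random() < 0.5:
                        v = Variant(t.chrom, pos, seq[pos - 1 : pos + ln], seq[pos - 1])
                    else:
                        ins = "".join(rng.choice(list("ACGT"), ln))
                        v = Variant(t.chrom, pos, seq[pos - 1], seq[pos - 1] + ins)
                got = classify_consequence(v, [t], reference)[0].label
                expect = _oracle_label(v, t, seq, cds_seq)
                if expect is None:
                    continue
                assert got == expect, (t.tid, v.key)
                n_checked += 1
        assert n_checked >= 100


def _oracle_label(v, t, seq, cds_seq):
    """Independent oracle: apply the variant to the spliced CDS and compare
    the translated proteins (skips start/stop codons; indel frameshift ⟺
    mod-3 length change within CDS)."""
    vc = classify_variant(v.ref, v.alt)
    if vc.label in ("insertion", "deletion"):
        return "frameshift" if vc.signed_length % 3 else (
            "inframe_insertion" if vc.label == "insertion" else "inframe_deletion"
        )
    idx = t.cds_index_of(v.pos)
    if idx is None or idx < 3 or idx >= len(cds_seq) - 3:
        return None
    alt = v.alt if t.strand == "+" else str(Seq(v.alt).reverse_complement())
    mutated = cds_seq[:idx] + alt + cds_seq[idx + 1 :]
    p_old = str(Seq(cds_seq).translate())
    p_new = str(Seq(mutated).translate())
    if p_old == p_new:
        return "synonymous"
    i = next(j for j, (a, b) in enumerate(zip(p_old, p_new)) if a != b)
    return "stop_gained" if p_new[i] == "*" else "missense"


class TestIndelSpectrum:
    def test_insertion_fraction_from_histogram(self):
        vs = (
            [Variant("c1", 1, "AT", "A")] * 3
            + [Variant("c1", 5, "ACG", "A")]
            + [Variant("c1", 9, "A", "AG")]
        )
        spec = indel_length_spectrum(vs, "x")
        assert spec.histogram == {-1: 3, -2: 1, 1: 1}
        assert spec.insertion_fraction == pytest.approx(0.2)

    def test_insertion_fraction_from_counts(self):
        assert insertion_fraction_from_counts(756_095, 860_649) * 100 == pytest.approx(
            46.8, abs=0.05
        )

    def test_histogram_matches_brute_force_recount(self, sim_default):
        truth = sim_default.truth
        indels = truth[truth.kind.isin(["insertion", "deletion"])]
        vs = [Variant(r.chrom, r.pos, r.ref, r.alt) for r in indels.itertuples()]
        spec = indel_length_spectrum(vs, "fn")
        brute = {}
        for v in vs:
            l = len(v.alt) - len(v.ref)
            brute[l] = brute.get(l, 0) + 1
        assert spec.histogram == brute

    def test_display_cap_only_affects_frame(self):
        vs = [Variant("c1", 1, "A", "A" + "G" * 25), Variant("c1", 5, "AT", "A")]
        spec = indel_length_spectrum(vs, "x")
        assert 25 in spec.histogram
        assert 25 not in set(spec.to_frame(display_cap=20)["signed_length"])

    def test_non_indel_rejected(self):
        with pytest.raises(ValueError):
            indel_length_spectrum([Variant("c1", 1, "A", "G")], "x")

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            indel_length_spectrum([], "x")


class TestSingleBpIdentity:
    def test_direction_and_base(self):
        counts = single_bp_identity(
            [Variant("c1", 1, "AT", "A"), Variant("c1", 5, "A", "AG")]
        )
        assert counts.loc["deleted", "T"] == 1
        assert counts.loc["inserted", "G"] == 1

    def test_multibase_rejected(self):
        with pytest.raises(ValueError):
            single_bp_identity([Variant("c1", 1, "ATT", "A")])

    def test_recovers_planted_at_bias(self, sim_default):
        from scipy.stats import binom

        truth = sim_default.truth
        one_bp = truth[truth.signed_length.abs() == 1]
        vs = [Variant(r.chrom, r.pos, r.ref, r.alt) for r in one_bp.itertuples()]
        counts = single_bp_identity(vs)
        at = int(counts[["A", "T"]].sum().sum())
        n = int(counts.sum().sum())
        lo, hi = binom.interval(0.99, n, sim_default.config.cohort.at_bias_1bp)
        assert lo <= at <= hi


class TestFrameshiftFraction:
    def test_all_frameshift_toy(self):
        assert frameshift_fraction_of_coding({"frameshift": 7}) == 100.0

    def test_mixed_with_noncoding_ignored(self):
        summary = {"frameshift": 1, "missense": 2, "synonymous": 1, "intron": 50}
        assert frameshift_fraction_of_coding(summary) == pytest.approx(25.0)

    def test_zero_coding_denominator(self):
        with pytest.raises(ValueError):
            frameshift_fraction_of_coding({"intron": 10})

    def test_summary_frame_accepted(self):
        df = pd.DataFrame({"label": ["frameshift", "missense"], "count": [1, 3]})
        assert frameshift_fraction_of_coding(df) == pytest.approx(25.0)


def test_consequence_summary_counts_records():
    recs = classify_consequence(Variant("c1", 19, "T", "C"), [GENE], REF)
    recs += classify_consequence(Variant("c1", 40, "T", "C"), [GENE], REF)
    df = consequence_summary(recs, "fn")
    assert df.set_index("label").loc["synonymous", "count"] == 1
    assert df.set_index("label").loc["intron", "count"] == 1
    assert df["count"].sum() == 2
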