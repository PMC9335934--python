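"""Flank extraction, null resampling, relative-entropy profiles, k-mer counts."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fnmut.context import (
    BASES,
    ContextConfig,
    ContextWindow,
    extract_context_windows,
    extract_flanks,
    kmer_composition,
    relative_entropy_profile,
    sample_null_windows,
)
from fnmut.variants import Variant

REF = {"c1": "AACGT"}


def win(ref="C", alt="T", up="A", down="G", flipped=False, cls=None):
    return ContextWindow(ref, alt, up, down, flipped, cls)


class TestExtractFlanks:
    def test_plus_strand_window(self):
        v = Variant("c1", 3, "C", "T")
        w = extract_flanks(v, REF, ContextConfig(k=1))
        assert (w.up, w.ref, w.down, w.strand_flipped) == ("A", "C", "G", False)

    def test_g_ref_is_strand_flipped(self):
        v = Variant("c1", 4, "G", "A")
        w = extract_flanks(v, REF, ContextConfig(k=1))
        # raw window C|G|T reverse-complements to A|C|G, central change C>T
        assert (w.ref, w.alt) == ("C", "T")
        assert (w.up, w.down) == ("A", "G")
        assert w.strand_flipped

    def test_edge_window_excluded(self):
        v = Variant("c1", 1, "A", "G")
        assert extract_flanks(v, REF, ContextConfig(k=2)) is None

    def test_indel_rejected(self):
        v = Variant("c1", 3, "CG", "C")
        with pytest.raises(ValueError, match="indel"):
            extract_flanks(v, REF, ContextConfig(k=1))

    def test_ref_mismatch_fatal(self):
        v = Variant("c1", 3, "A", "T")
        with pytest.raises(ValueError, match="mismatch"):
            extract_flanks(v, REF, ContextConfig(k=1))

    def test_window_containing_other_variant_excluded(self):
        vs = [Variant("c1", 3, "C", "T"), Variant("c1", 4, "G", "A")]
        windows, excluded = extract_context_windows(vs, REF, ContextConfig(k=1))
        assert not windows
        assert excluded["overlaps_variant"] == 2

    @given(st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None)
    def test_strand_flip_is_involutive(self, seed):
        rng = np.random.default_rng(seed)
        b = list("ACGT")
        w = ContextWindow(
            ref=b[rng.integers(0, 4)],
            alt=None,
            up="".join(rng.choice(b, 2)),
            down="".join(rng.choice(b, 2)),
            strand_flipped=False,
            cls=None,
        )
        assert w.flipped().flipped() == w


class TestNullSampling:
    def test_forced_draw_when_single_eligible_site(self):
        ref = {"c1": "CTTTTTTTCA"}  # focal C at 1; only other C at 9
        v = Variant("c1", 1, "C", "T")
        nulls, skipped = sample_null_windows([v], ref, ContextConfig(k=1, window=20, seed=0))
        assert len(nulls) == 1
        assert nulls[0].pos == 9
        assert nulls[0].cls == "C>T*"

    def test_no_eligible_site_counted(self):
        ref = {"c1": "CTTTTTTTTA"}
        v = Variant("c1", 1, "C", "T")
        nulls, skipped = sample_null_windows([v], ref, ContextConfig(k=1, window=9, seed=0))
        assert not nulls and skipped["no_eligible_position"] == 1

    def test_same_seed_identical(self, sim_small):
        truth = sim_small.truth
        snps = truth[(truth.kind == "SNP")].head(50)
        vs = [Variant(r.chrom, r.pos, r.ref, r.alt) for r in snps.itertuples()]
        cfg = ContextConfig(k=2, seed=42)
        a, _ = sample_null_windows(vs, sim_small.reference, cfg)
        b, _ = sample_null_windows(vs, sim_small.reference, cfg)
        assert a == b

    def test_draws_uniform_over_eligible_sites(self, rng):
        """Empirical pick distribution matches the uniform law (χ² p > 0.001)."""
        from scipy.stats import chisquare

        seq = "".join(rng.choice(list("ACGT"), 101))
        seq = seq[:50] + "C" + seq[51:]
        ref = {"c1": seq}
        v = Variant("c1", 51, "C", "T")
        cfg = ContextConfig(k=1, window=40, seed=5, n_null_per_variant=10_000)
        nulls, _ = sample_null_windows([v], ref, cfg)
        eligible = [
            p for p in range(11, 92)
            if p != 51 and seq[p - 1] == "C"
        ]
        picks = [w.pos for w in nulls]
        counts = [picks.count(p) for p in eligible]
        assert sum(counts) == len(picks)
        _, p_val = chisquare(counts)
        assert p_val > 0.001


class TestRelativeEntropy:
    def test_identical_sets_zero_re(self):
        ws = [win(up=u, down=d) for u in "ACGT" for d in "ACGT"]
        prof = relative_entropy_profile(ws, list(ws))
        assert np.allclose(prof.re_bits.to_numpy(), 0.0)

    def test_point_mass_vs_uniform_two_bits(self):
        obs = [win(up="A", down="A") for _ in range(4)]
        null = [win(up=b, down=b) for b in "ACGT"]
        prof = relative_entropy_profile(obs, null, pseudocount=0.0)
        assert prof.re_bits.loc[-1] == pytest.approx(2.0)
        assert prof.re_bits.loc[1] == pytest.approx(2.0)

    def test_matches_hand_computation_on_small_fixture(self):
        obs = [win(up=u, down=d) for u, d in
               [("A", "G"), ("A", "G"), ("C", "G"), ("A", "T"),
                ("G", "G"), ("A", "C"), ("C", "G"), ("T", "G")]]
        null = [win(up=u, down=d) for u, d in
                [("A", "A"), ("C", "G"), ("G", "C"), ("T", "T"),
                 ("A", "G"), ("C", "C"), ("G", "T"), ("T", "A")]]
        prof = relative_entropy_profile(obs, null, pseudocount=0.5)
        # independent spreadsheet-style recomputation
        for offset, getter in ((-1, lambda w: w.up), (1, lambda w: w.down)):
            expected = 0.0
            for b in BASES:
                p = (sum(1 for w in obs if getter(w) == b) + 0.5) / (len(obs) + 2.0)
                q = (sum(1 for w in null if getter(w) == b) + 0.5) / (len(null) + 2.0)
                expected += p * math.log2(p / q)
            assert prof.re_bits.loc[offset] == pytest.approx(expected, abs=1e-12)

    def test_re_nonnegative_with_full_support(self):
        rng = np.random.default_rng(3)
        b = list("ACGT")
        obs = [win(up="".join(rng.choice(b, 2)), down="".join(rng.choice(b, 2))) for _ in range(100)]
        null = [win(up="".join(rng.choice(b, 2)), down="".join(rng.choice(b, 2))) for _ in range(100)]
        prof = relative_entropy_profile(obs, null)
        assert (prof.re_bits >= 0).all()
        assert np.allclose(prof.observed.sum(axis=1), 1.0)
        assert np.allclose(prof.null.sum(axis=1), 1.0)

    def test_empty_after_class_filter(self):
        with pytest.raises(ValueError):
            relative_entropy_profile([win(cls="C>T*")], [win(cls="C>T*")], "A>G*")


class TestKmerComposition:
    def test_small_examples(self):
        df = kmer_composition({"c1": "ACGC"}, 2).set_index("kmer")
        assert df.loc["AC", "count"] == 1
        assert df.loc["CG", "count"] == 1
        assert df.loc["GC", "count"] == 1
        assert df.loc["AC", "frequency"] == pytest.approx(1 / 3)
        assert df["frequency"].sum() == pytest.approx(1.0)

    def test_mononucleotide(self):
        df = kmer_composition({"c1": "AAAA"}, 1).set_index("kmer")
        assert df.loc["A", "frequency"] == 1.0

    def test_k1_counts_equal_base_totals(self, sim_small):
        df = kmer_composition(sim_small.reference, 1).set_index("kmer")
        seq = "".join(sim_small.reference.values())
        for b in "ACGT":
            assert df.loc[b, "count"] == seq.count(b)

    def test_n_windows_skipped(self):
        df = kmer_composition({"c1": "ACNGT"}, 2)
        assert df["count"].sum() == 2  # AC and GT only

    def test_k_longer_than_contigs(self):
        with pytest.raises(ValueError):
            kmer_composition({"c1": "ACG"}, 5)

    def test_uniform_sequence_cg_frequency(self, rng):
        """CG dinucleotide frequency ≈ 1/16 on a uniform-composition sequence."""
        seq = "".join(rng.choice(list("ACGT"), 200_000))
        df = kmer_composition({"c1": seq}, 2).set_index("kmer")
        n = df["count"].sum()
        se = math.sqrt((1 / 16) * (15 / 16) / n)
        assert abs(df.loc["CG", "frequency"] - 1 / 16) < 2.576 * se
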