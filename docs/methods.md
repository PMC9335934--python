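# Methods

## The de novo isolation model

A fixed de novo mutation in a selfed inbred line has a precise signature:
homozygous non-reference in exactly one line of the cohort, absent from the
parental line, absent from standing variation, and located where the
parental genome is actually ascertainable against the reference. The filter
chain applies these conditions in order:

1. **Subtraction of known variants.** Treatment variants identical in
   normalized `(chrom, pos, ref, alt)` to any parental or panel variant are
   removed. Identity requires allele match; a treatment variant at a known
   position but with a different allele is retained and flagged
   (`position_collision_with_known`), so the stricter position-level rule is
   a one-line change for users who want it. Normalization (multiallelic
   splitting, left alignment with anchor bases, trimming) happens at read
   time so identical events compare equal across call sets — without it,
   the same deletion in a homopolymer run can legitimately be written at
   several positions and subtraction silently fails.
2. **Deletion masks.** Variants whose reference span intersects a masked
   interval (BED, 0-based half-open) are removed. Masks model regions
   deleted in the parental line relative to the reference, where
   reference-based calling cannot see de novo events.
3. **Quality control.** QUAL ≥ `min_qual` (default 30) and carrier depth ≥
   `min_depth` (default 5). These defaults are deliberately config-exposed
   conventions, not measured constants.
4. **Carrier rule.** Non-reference in exactly one line (strict singleton
   default). Sharing is permitted only when `allow_family_sharing` is set
   and all carriers belong to one named sibling family. Heterozygous
   carriers are removed under `require_homozygous` (default): a true
   mutation fixed by selfing should be homozygous, and residual
   heterozygosity is indistinguishable from segregating seed-stock
   heterogeneity at the single-line level. Missing genotypes in
   non-carrier lines do not veto singleton status but are counted; a
   conservative `require_noncarriers_called` switch inverts that.

Every removed variant is logged with the reason that removed it, which is
what the provenance tests assert against: each synthetic noise layer must
be eliminated by precisely the filter built for it, not accidentally by
another one.

Per-line totals far above the cohort median (the signature of sample
contamination or unintended outcrossing) are surfaced by
`DeNovoSet.outlier_report`, but no automatic exclusion is performed — that
is a judgment call for the analyst.

## Spectrum and association statistics

The 12 ordered single-base changes collapse 2-to-1 into six classes; the
canonical representative takes reference base A or C (so G>A reports as
C>T\*). Ts/Tv = (C>T\* + A>G\*) / (other four). A cohort with zero
transversions reports Ts/Tv = ∞ with a `degenerate` flag rather than
raising.

Per-line summaries report both the sample SD (ddof = 1, the primary
convention) and the population SD (ddof = 0), because published per-line
dispersion figures for cohorts of this type are frequently population SDs;
reporting both avoids silent convention mismatches.

The association block computes Pearson r² between per-line SNP and indel
counts, a paired two-sided *t*-test on the same pairs, and a two-way ANOVA
of totals on dosage and selfing generations. Both factors are treated as
categorical and sums of squares are type II: the designs this package
targets are unbalanced (unequal lines per dosage), where type I sums would
depend on factor order. Degenerate inputs (constant columns, identical
pairs) return flagged results.

## Flanking-context relative entropy

Context windows take the 2k+1 reference bases around each SNP (k = 2 by
default, where essentially all context signal concentrates). Windows whose
central reference base is G or T are reverse-complemented whole, swapping
upstream and downstream offsets, so all windows share the A/C-reference
orientation of the collapsed classes. Windows truncated by contig edges,
containing non-ACGT bases, or containing another variant position are
excluded and counted.

The null asks: what do flanks look like around bases *of the same kind*
that did not mutate for context-specific reasons? For each focal SNP, one
position (configurable) is drawn uniformly from the ±W window (default
W = 50 bp) among positions whose reference base equals the focal pre-flip
reference base, excluding the focal site and all other variant sites. The
draw is seeded; identical seeds give identical nulls. W is a modelling
default, not an inferred value — the profile is insensitive to it on
synthetic data, and it is config-exposed.

Frequencies use an add-0.5 pseudocount per base so that small observed
sets (a few hundred windows for a single class in a modest cohort) never
produce log(0); raw counts are reported alongside so users can recompute
without it. Per-base signed contributions p·log₂(p/q) convey direction:
positive = overrepresented, negative = underrepresented. Total RE_j is
non-negative whenever the null has full support.

K-mer composition counts overlapping k-mers on the forward strand with
N-containing windows skipped, vectorized by integer base coding.

## Consequence classification

The classifier emits one record per (variant, transcript) pair for every
transcript within 5 kb (the customary effect-predictor flank), or a single
intergenic record. Precedence within a transcript:
frameshift / stop_gained / stop_lost / start_lost > inframe > missense >
splice_region > synonymous > UTR > intron.

- Indels: the CDS-overlapping length change decides. An insertion counts
  its full length if the insertion point lies inside a CDS interval; a
  deletion counts only the deleted bases that fall inside CDS (so events
  straddling a CDS boundary are judged by their coding footprint).
  Change mod 3 ≠ 0 ⟹ frameshift.
- SNPs: the affected codon is located through a genome→CDS coordinate map
  (strand-aware), mutated and translated; start_lost/stop_lost/stop_gained
  are decided before the missense/synonymous comparison.
- splice_region covers 3 exonic / 8 intronic bases around internal exon
  junctions; donor/acceptor sites are folded into splice_region because
  the synthetic gene models do not constrain splice dinucleotides
  (separate labels would claim precision the fixtures cannot support).

Full effect-predictor edge-case parity is explicitly not promised; the
correctness claim is oracle equivalence — labels match a
splice-mutate-translate-compare oracle over randomized gene/variant
fixtures — plus strand-mirror invariance.

## Diversity and expectation

θπ uses the unbiased per-site estimator 2p(1−p)·n/(n−1), summed over
variant sites and divided by total site count L; for S singletons this
reduces to S·(2/n)/L exactly, and for any configuration it equals the
direct O(S·n²) average pairwise difference (asserted in tests). Inbred
lines are treated as a haploid sample.

Expected spontaneous counts are E = μ × site-generations. The
generation/ploidy accounting (how pre-treatment seed-increase generations,
selfing generations and diploidy-with-fixation combine into
site-generations) is an explicit parameter with two modes —
`site_generations` (L × (g_pre + g_self) × ploidy_factor) and
`fixed_factor` (caller-supplied total) — because more than one convention
is defensible and published SNP and indel expectations are not mutually
consistent under any single factor. Defaults: μ_SNP = 6.53×10⁻⁹ and
μ_indel = 0.47×10⁻⁹ per site per generation (plant mutation-accumulation
estimates), g_pre = 10 generations of seed maintenance before treatment.
Dosage in Gy is carried as metadata only; no dose-response model is
fitted.

## The synthetic-data generator

The generator's defaults *are* the study conditions the analysis targets:
27 treatment lines, per-line Poisson means λ_SNP = 53 and λ_indel = 32,
dosages {8, 16, 32} Gy, 3–8 selfing generations, two 3-sibling families, a
30-line diversity panel, 34% GC reference, 3.8% of the genome masked,
class probabilities led by C>T\* at 0.458, CpG boost 3×, deletion fraction
0.715 of indels, geometric length decay from 1 bp (cap 279 bp), and an
A/T probability of 0.8 for 1-bp indel identity. The genome is scaled to
2 × 2 Mb so a full simulate–filter–analyze cycle runs in seconds on one
CPU; all statistical structure is preserved at that scale because every
law is per-site or per-event.

Mechanics worth knowing:

- All planted variants (parental, panel, de novo) occupy disjoint,
  unmasked sites, and planted alleles are normalized at planting time, so
  truth comparison is exact-key and unambiguous; rejection-resampled
  collisions are counted.
- SNP classes are drawn first, then a site with a compatible reference
  base is rejection-sampled; for C>T\*, non-CpG candidate sites are
  accepted with probability 1/boost, giving CpG-context sites exactly
  `cpg_boost`-fold relative weight.
- 1-bp deletions sample their target base first and then a site whose
  deleted base matches, since a deletion's base identity is dictated by
  the reference.
- Panel allele counts follow P(c) ∝ 1/c over 1..n−1 (the neutral
  frequency law), with copies assigned uniformly to the 2n haplotypes.
- Gene models are planted *before* variants and rewrite the reference so
  every CDS is a valid ORF (ATG, no internal stop, terminal stop,
  length ≡ 0 mod 3, introns ≥ 20 bp).
- Noise layers are the exact negatives the filter chain must reject:
  heterozygous calls (→ homozygosity filter), depths below threshold
  (→ depth filter), and hom-alt variants shared by ≥ 2 non-sibling lines
  (→ singleton filter). They are tagged in the truth table so removal
  provenance can be asserted per variant.

What the generator does **not** emulate: read-level error processes,
mapping artefacts, repetitive or low-complexity sequence, linkage between
sites, real allele-frequency spectra shaped by selection and demography,
structural variants, and genotype-likelihood uncertainty. Passing tests
therefore demonstrate that the analysis is correct *given* well-formed
calls with these statistical properties — not that any particular caller's
output on real data satisfies them.

## Numerical choices and degenerate inputs

- Tolerances in tests are closed-form where possible; stochastic recovery
  checks use exact binomial/multinomial 99% intervals at the generated n,
  never asymptotic approximations.
- Ts/Tv with zero transversions, correlation of a constant column, SD of a
  single line, and a paired *t* on identical columns all return flagged
  results instead of raising; empty variant sets raise `ValueError` where
  an empty result would be semantically meaningless (spectrum, RE profile,
  indel spectrum).
- RE contributions define p·log₂(p/q) = 0 at p = 0 (its limit), which only
  matters when users disable the pseudocount.
- Multiallelic splitting maps a sample's other-alt alleles to missing
  rather than reference, which preserves alt-copy totals across splits
  without inventing reference calls.
- The acceptance script reports θπ to two significant figures, matching
  the precision at which such genome-wide estimates are conventionally
  printed.

## Known limitations

- The consequence classifier handles one variant at a time; compound
  effects of nearby variants on the same codon are not modelled.
- `partition_by_frequency` uses raw allele counts, not frequencies; with
  very small panels the rare/common boundary (2 vs 3 copies) is coarse.
- The windowed π track uses non-overlapping windows only.
- The CLI reads uncompressed or bgzipped VCF through pysam but always
  writes plain text.
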