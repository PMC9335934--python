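"""Strand-collapsed mutational spectrum and per-line association statistics.

Because resequencing cannot distinguish the strand of origin, the 12 ordered
single-nucleotide changes collapse into 6 classes, each pooling a change
with its reverse complement (e.g. C>T* = C>T plus G>A).  The canonical
representative has reference base A or C.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from fnmut.variants import Variant

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: the six strand-collapsed classes, transitions first
COLLAPSED_CLASSES = ("C>T*", "A>G*", "C>A*", "C>G*", "A>T*", "A>C*")
TRANSITION_CLASSES = frozenset({"C>T*", "A>G*"})


def revcomp(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


def collapse_class(ref_base: str, alt_base: str) -> str:
    """Map an ordered base change to its strand-collapsed class label."""
    ref_base, alt_base = ref_base.upper(), alt_base.upper()
    if ref_base not in COMPLEMENT or alt_base not in COMPLEMENT:
        raise ValueError(f"non-ACGT base in ({ref_base}, {alt_base})")
    if ref_base == alt_base:
        raise ValueError("identical bases are not a mutation")
    if ref_base in "GT":
        ref_base, alt_base = COMPLEMENT[ref_base], COMPLEMENT[alt_base]
    return f"{ref_base}>{alt_base}*"


@dataclass
class SpectrumTable:
    """Counts and fractions per collapsed class for one cohort, with Ts/Tv."""

    cohort: str
    counts: dict[str, int]
    degenerate: bool = False  # Ts/Tv undefined (no transversions)

    def __post_init__(self) -> None:
        for cls in COLLAPSED_CLASSES:
            self.counts.setdefault(cls, 0)
        if self.total == 0:
            raise ValueError("empty spectrum")
        if self.transversions == 0:
            self.degenerate = True

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def fractions(self) -> dict[str, float]:
        t = self.total
        return {c: self.counts[c] / t for c in COLLAPSED_CLASSES}

    @property
    def transitions(self) -> int:
        return sum(self.counts[c] for c in COLLAPSED_CLASSES if c in TRANSITION_CLASSES)

    @property
    def transversions(self) -> int:
        return sum(
            self.counts[c] for c in COLLAPSED_CLASSES if c not in TRANSITION_CLASSES
        )

    @property
    def ts_tv(self) -> float:
        if self.transversions == 0:
            return math.inf
        return self.transitions / self.transversions

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "class": COLLAPSED_CLASSES,
                "count": [self.counts[c] for c in COLLAPSED_CLASSES],
                "fraction": [self.fractions[c] for c in COLLAPSED_CLASSES],
            }
        ).assign(cohort=self.cohort)


def spectrum_table(
    snvs: Iterable[Variant] | Mapping[str, int], cohort_label: str
) -> SpectrumTable:
    """Build a :class:`SpectrumTable` from SNP variants or a counts mapping."""
    if isinstance(snvs, Mapping):
        return SpectrumTable(cohort_label, dict(snvs))
    counts: dict[str, int] = {}
    for v in snvs:
        if len(v.ref) != 1 or len(v.alt) != 1:
            raise ValueError(f"non-SNP variant in spectrum input: {v.key}")
        cls = collapse_class(v.ref, v.alt)
        counts[cls] = counts.get(cls, 0) + 1
    return SpectrumTable(cohort_label, counts)


@dataclass
class CohortSummary:
    per_line: pd.DataFrame
    mean: dict[str, float]
    sd: dict[str, float]  # sample SD (n−1 denominator)
    sd_pop: dict[str, float]  # population SD (n denominator)
    flags: tuple[str, ...] = ()


def per_line_summary(
    counts: pd.DataFrame, line_meta: pd.DataFrame | None = None
) -> CohortSummary:
    """Per-line SNP/indel/total counts with cohort mean and SD.

    ``counts`` must have columns ``snps`` and ``indels`` indexed by sample
    (the shape :meth:`DeNovoSet.per_line_counts` produces, or a published
    per-line table fed in directly).  Both the sample SD (n−1) and the
    population SD are reported.
    """
    df = counts.copy()
    if "total" not in df.columns:
        df["total"] = df["snps"] + df["indels"]
    if line_meta is not None:
        missing = set(df.index) - set(line_meta.index)
        if missing:
            raise ValueError(f"lines without metadata: {sorted(missing)}")
        df = df.join(line_meta[["dosage_gy", "selfing_generations", "family"]])
    cols = ["snps", "indels", "total"]
    flags = []
    if len(df) < 2:
        flags.append("sd_undefined")
    return CohortSummary(
        per_line=df,
        mean={c: float(df[c].mean()) for c in cols},
        sd={c: float(df[c].std(ddof=1)) for c in cols},
        sd_pop={c: float(df[c].std(ddof=0)) for c in cols},
        flags=tuple(flags),
    )


@dataclass
class AssociationResult:
    """Association between per-line SNP and indel counts, plus design factors."""

    r_squared: float
    t_statistic: float
    t_pvalue: float
    anova: pd.DataFrame | None
    flags: tuple[str, ...] = ()


def snp_indel_association(
    per_line: pd.DataFrame, line_meta: pd.DataFrame | None = None
) -> AssociationResult:
    """Pearson r² of per-line SNP vs indel counts, paired t-test, two-way ANOVA.

    The ANOVA models total counts on dosage (Gy) and selfing generations,
    both categorical, with type II sums of squares (the design is
    unbalanced).  Degenerate inputs (constant columns) are flagged, never a
    crash.
    """
    df = per_line.copy()
    if line_meta is not None:
        df = df.join(line_meta[["dosage_gy", "selfing_generations"]], how="left")
    if "total" not in df.columns:
        df["total"] = df["snps"] + df["indels"]
    if len(df) < 3:
        raise ValueError("need at least 3 lines")
    snps, indels = df["snps"].to_numpy(float), df["indels"].to_numpy(float)
    flags = []
    if np.ptp(snps) == 0 or np.ptp(indels) == 0:
        flags.append("constant_column")
        r2 = math.nan
    else:
        r, _ = stats.pearsonr(snps, indels)
        r2 = r * r
    if np.ptp(snps - indels) == 0:
        flags.append("degenerate_paired_t")
        t_stat, t_p = 0.0, 1.0
    else:
        t = stats.ttest_rel(snps, indels)
        t_stat, t_p = float(t.statistic), float(t.pvalue)
    anova = None
    if {"dosage_gy", "selfing_generations"} <= set(df.columns) and not (
        df["dosage_gy"].isna().any() or df["selfing_generations"].isna().any()
    ):
        anova = _two_way_anova(df)
    return AssociationResult(r2, t_stat, t_p, anova, tuple(flags))


def _two_way_anova(df: pd.DataFrame) -> pd.DataFrame:
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    d = df.rename(columns={"dosage_gy": "dosage", "selfing_generations": "selfing"})
    model = ols("total ~ C(dosage) + C(selfing)", data=d).fit()
    return sm.stats.anova_lm(model, typ=2)
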