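"""Flanking-sequence context of SNPs and relative-entropy profiles.

Each SNP contributes a strand-normalized window of 2k+1 reference bases
(after normalization the central reference base is A or C; windows on the
other strand are reverse-complemented, which swaps upstream and downstream
offsets).  Context informativeness at each flanking offset is the relative
entropy (KL divergence, bits) between observed base frequencies and a null
built from nearby positions of the same reference base, sampled uniformly
within a ±W window around each focal SNP.  Per-base signed contributions
p·log2(p/q) convey over- (positive) and under-representation (negative).

Indels are rejected: their local context is not directly observable because
multiple equiprobable alignments of the event are possible.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from fnmut.spectrum import collapse_class, revcomp
from fnmut.variants import Variant, _RefCache

BASES = ("A", "C", "G", "T")


@dataclass
class ContextConfig:
    k: int = 2  # flank width in bases
    window: int = 50  # null-sampling half-width W
    seed: int = 0
    n_null_per_variant: int = 1

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.window <= self.k:
            raise ValueError("null window W must exceed k")


@dataclass(frozen=True)
class ContextWindow:
    """Strand-normalized flanks around a SNP (or a null position).

    ``up``/``down`` are the bases at offsets −k..−1 / +1..+k in 5′→3′
    orientation after strand normalization.  ``cls`` is the collapsed class
    of the originating SNP (null windows inherit the focal SNP's class).
    """

    ref: str
    alt: str | None
    up: str
    down: str
    strand_flipped: bool
    cls: str | None
    chrom: str = ""
    pos: int = 0

    @property
    def k(self) -> int:
        return len(self.up)

    def bases_at(self, offset: int) -> str:
        if offset < 0:
            return self.up[offset + self.k]
        if offset > 0:
            return self.down[offset - 1]
        return self.ref

    def flipped(self) -> "ContextWindow":
        """Reverse-complement the whole window, swapping up/downstream."""
        return ContextWindow(
            ref=revcomp(self.ref),
            alt=None if self.alt is None else revcomp(self.alt),
            up=revcomp(self.down),
            down=revcomp(self.up),
            strand_flipped=not self.strand_flipped,
            cls=self.cls,
            chrom=self.chrom,
            pos=self.pos,
        )


def _window_at(
    chrom_seq: str, chrom: str, pos: int, alt: str | None, k: int
) -> ContextWindow | None:
    """Raw (unflipped) window, or None when truncated by an edge or containing N."""
    if pos - k < 1 or pos + k > len(chrom_seq):
        return None
    seq = chrom_seq[pos - 1 - k : pos + k]
    if set(seq) - set(BASES):
        return None
    ref = seq[k]
    cls = collapse_class(ref, alt) if alt is not None else None
    return ContextWindow(ref, alt, seq[:k], seq[k + 1 :], False, cls, chrom, pos)


def _normalize(win: ContextWindow) -> ContextWindow:
    return win.flipped() if win.ref in "GT" else win


def extract_flanks(
    variant: Variant, reference, config: ContextConfig, chrom_seq: str | None = None
) -> ContextWindow | None:
    """Strand-normalized context window of one SNP; None if excluded (edge/N)."""
    if len(variant.ref) != 1 or len(variant.alt) != 1:
        raise ValueError(f"context undefined for indel {variant.key}")
    if chrom_seq is None:
        chrom_seq = _RefCache(reference)[variant.chrom]
    if chrom_seq[variant.pos - 1] != variant.ref:
        raise ValueError(
            f"REF mismatch at {variant.chrom}:{variant.pos}: "
            f"{variant.ref} vs {chrom_seq[variant.pos - 1]}"
        )
    win = _window_at(chrom_seq, variant.chrom, variant.pos, variant.alt, config.k)
    return None if win is None else _normalize(win)


def extract_context_windows(
    snvs: Sequence[Variant], reference, config: ContextConfig
) -> tuple[list[ContextWindow], Counter]:
    """Windows for all SNPs; exclusions (edge/N/overlapping another variant) counted."""
    cache = _RefCache(reference)
    positions = {(v.chrom, v.pos) for v in snvs}
    windows: list[ContextWindow] = []
    excluded: Counter = Counter()
    for v in snvs:
        win = extract_flanks(v, reference, config, cache[v.chrom])
        if win is None:
            excluded["edge_or_N"] += 1
            continue
        if any(
            (v.chrom, v.pos + off) in positions
            for off in range(-config.k, config.k + 1)
            if off != 0
        ):
            excluded["overlaps_variant"] += 1
            continue
        windows.append(win)
    return windows, excluded


def sample_null_windows(
    snvs: Sequence[Variant],
    reference,
    config: ContextConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[ContextWindow], Counter]:
    """Null windows from nearby same-base positions, one per focal SNP by default.

    For each focal SNP, positions within ±W whose reference base equals the
    focal (pre-flip) reference base are eligible, excluding the focal site
    and any other variant site; ``n_null_per_variant`` draws are made
    uniformly.  The null window inherits the focal SNP's collapsed class and
    is strand-normalized by the same rule.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    cache = _RefCache(reference)
    positions = {(v.chrom, v.pos) for v in snvs}
    windows: list[ContextWindow] = []
    skipped: Counter = Counter()
    for v in snvs:
        chrom_seq = cache[v.chrom]
        lo = max(1, v.pos - config.window)
        hi = min(len(chrom_seq), v.pos + config.window)
        eligible = [
            p
            for p in range(lo, hi + 1)
            if p != v.pos
            and chrom_seq[p - 1] == v.ref
            and (v.chrom, p) not in positions
        ]
        if not eligible:
            skipped["no_eligible_position"] += 1
            continue
        cls = collapse_class(v.ref, v.alt)
        for p in rng.choice(eligible, size=config.n_null_per_variant, replace=True):
            win = _window_at(chrom_seq, v.chrom, int(p), None, config.k)
            if win is None:
                skipped["null_edge_or_N"] += 1
                continue
            win = _normalize(win)
            windows.append(
                ContextWindow(
                    win.ref, None, win.up, win.down, win.strand_flipped, cls,
                    win.chrom, win.pos,
                )
            )
    return windows, skipped


@dataclass
class REProfile:
    """Per-offset observed/null base frequencies and relative entropy in bits."""

    offsets: tuple[int, ...]
    observed: pd.DataFrame  # index offset, columns BASES: frequencies p
    null: pd.DataFrame  # frequencies q
    contributions: pd.DataFrame  # signed p*log2(p/q)
    observed_counts: pd.DataFrame
    null_counts: pd.DataFrame
    n_observed: int
    n_null: int
    pseudocount: float

    @property
    def re_bits(self) -> pd.Series:
        return self.contributions.sum(axis=1).rename("RE_bits")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for off in self.offsets:
            for b in BASES:
                rows.append(
                    {
                        "offset": off,
                        "base": b,
                        "p_observed": self.observed.loc[off, b],
                        "q_null": self.null.loc[off, b],
                        "contribution_bits": self.contributions.loc[off, b],
                        "n_observed": self.observed_counts.loc[off, b],
                        "n_null": self.null_counts.loc[off, b],
                    }
                )
        return pd.DataFrame(rows)


def _base_counts(windows: Sequence[ContextWindow], offsets: Sequence[int]) -> pd.DataFrame:
    counts = pd.DataFrame(0, index=list(offsets), columns=list(BASES))
    for w in windows:
        for off in offsets:
            counts.loc[off, w.bases_at(off)] += 1
    return counts


def relative_entropy_profile(
    observed_windows: Sequence[ContextWindow],
    null_windows: Sequence[ContextWindow],
    class_filter: str | None = None,
    pseudocount: float = 0.5,
) -> REProfile:
    """Relative-entropy profile of observed vs null flanking base composition.

    Frequencies use an add-``pseudocount`` per base (default 0.5) so small
    observed sets never hit log(0); raw counts are reported alongside so the
    profile can be recomputed without it.
    """
    if class_filter is not None:
        observed_windows = [w for w in observed_windows if w.cls == class_filter]
        null_windows = [w for w in null_windows if w.cls == class_filter]
    if not observed_windows or not null_windows:
        raise ValueError("empty window set after class filtering")
    k = observed_windows[0].k
    offsets = tuple(list(range(-k, 0)) + list(range(1, k + 1)))
    obs_counts = _base_counts(observed_windows, offsets)
    null_counts = _base_counts(null_windows, offsets)
    p = (obs_counts + pseudocount).div(
        (obs_counts + pseudocount).sum(axis=1), axis=0
    )
    q = (null_counts + pseudocount).div(
        (null_counts + pseudocount).sum(axis=1), axis=0
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        contrib = p * np.log2(p / q)
    contrib = contrib.where(p > 0, 0.0)  # lim p→0 of p·log2(p/q) is 0
    return REProfile(
        offsets=offsets,
        observed=p,
        null=q,
        contributions=contrib,
        observed_counts=obs_counts,
        null_counts=null_counts,
        n_observed=len(observed_windows),
        n_null=len(null_windows),
        pseudocount=pseudocount,
    )


def write_windows_fasta(path, windows: Iterable[ContextWindow]) -> None:
    """FASTA of context windows, one 2k+1-base sequence per window."""
    lines = []
    for w in windows:
        lines.append(f">{w.chrom}:{w.pos}:{w.cls or 'null'}")
        lines.append(w.up + w.ref + w.down)
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def kmer_composition(reference, k: int, contigs: Sequence[str] | None = None) -> pd.DataFrame:
    """Overlapping k-mer counts and frequencies over the reference (one strand).

    Windows containing a non-ACGT base are skipped.  Vectorized by encoding
    bases as integers and summing positional codes.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    cache = _RefCache(reference)
    if contigs is None:
        if hasattr(reference, "keys"):
            contigs = list(reference.keys())
        else:
            contigs = [rec.name for rec in reference]
    lut = np.full(256, -1, dtype=np.int64)
    for i, b in enumerate(BASES):
        lut[ord(b)] = i
    total = np.zeros(4**k, dtype=np.int64)
    any_long_enough = False
    for chrom in contigs:
        seq = cache[chrom]
        if len(seq) < k:
            continue
        any_long_enough = True
        codes = lut[np.frombuffer(seq.encode(), dtype=np.uint8)]
        valid = codes >= 0
        window_code = np.zeros(len(seq) - k + 1, dtype=np.int64)
        window_valid = np.ones(len(seq) - k + 1, dtype=bool)
        for j in range(k):
            window_code = window_code * 4 + codes[j : j + len(window_code)]
            window_valid &= valid[j : j + len(window_code)]
        total += np.bincount(window_code[window_valid], minlength=4**k)
    if not any_long_enough:
        raise ValueError(f"k={k} longer than every contig")
    kmers = ["".join(BASES[(i >> (2 * (k - 1 - j))) & 3] for j in range(k)) for i in range(4**k)]
    n = total.sum()
    return pd.DataFrame(
        {"kmer": kmers, "count": total, "frequency": total / n if n else 0.0}
    )
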