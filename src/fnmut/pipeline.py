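"""End-to-end orchestration: simulate → filter → analyze → report.

``run_pipeline`` chains the de novo filter, spectrum, context, consequence
and diversity stages over a synthetic cohort (or pre-simulated inputs) and
writes per-stage TSVs plus one JSON summary.  ``summarize_counts`` is the
summary-only entry point: it accepts a per-line counts table and an
affected-transcript consequence table directly, so published worked
examples run without any VCF.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from fnmut import consequence as cq
from fnmut import context as ctx
from fnmut import popstats, spectrum
from fnmut.denovo import FilterConfig, isolate_de_novo, partition_by_frequency
from fnmut.simulate import SimConfig, SimResult, simulate
from fnmut.variants import nonref_allele_count


@dataclass
class RunConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    filter: FilterConfig = field(default_factory=FilterConfig)
    context: ctx.ContextConfig = field(default_factory=ctx.ContextConfig)
    rates: popstats.MutationRateModel | None = None
    outdir: str | Path | None = None


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict(orient="list"))
    if isinstance(obj, float) and (obj != obj):
        return None
    return obj


def run_pipeline(config: RunConfig, sim_result: SimResult | None = None) -> dict:
    """Execute every analysis stage over a synthetic cohort; return the summary.

    When ``config.outdir`` is set, per-stage TSVs and ``summary.json`` are
    written there.
    """
    res = sim_result if sim_result is not None else simulate(config.sim)
    stage = "denovo_filter"
    try:
        denovo = isolate_de_novo(
            res.cohort_variants,
            res.parental_variants,
            res.panel_variants,
            res.masks,
            res.meta,
            config.filter,
        )
        per_line = denovo.per_line_counts()
        cohort_summary = spectrum.per_line_summary(per_line, res.meta)
        assoc = spectrum.snp_indel_association(per_line, res.meta)

        stage = "spectrum"
        rare, common = partition_by_frequency(res.panel_variants)
        fn_snvs = [r.variant for r in denovo.records if r.vclass.label == "SNP"]
        fn_indels = [
            r.variant
            for r in denovo.records
            if r.vclass.label in ("insertion", "deletion")
        ]
        spectra = {}
        for label, snvs in (
            ("fn", fn_snvs),
            ("rare", [v for v in rare if len(v.ref) == len(v.alt) == 1]),
            ("common", [v for v in common if len(v.ref) == len(v.alt) == 1]),
        ):
            if snvs:
                spectra[label] = spectrum.spectrum_table(snvs, label)

        stage = "context"
        re_summary = None
        if fn_snvs:
            windows, excluded = ctx.extract_context_windows(
                fn_snvs, res.reference, config.context
            )
            nulls, skipped = ctx.sample_null_windows(
                fn_snvs, res.reference, config.context
            )
            if any(w.cls == "C>T*" for w in windows) and any(
                w.cls == "C>T*" for w in nulls
            ):
                prof = ctx.relative_entropy_profile(windows, nulls, "C>T*")
                re_summary = {
                    "class": "C>T*",
                    "offsets": list(prof.offsets),
                    "re_bits": [float(x) for x in prof.re_bits],
                    "plus1_contributions": {
                        b: float(prof.contributions.loc[1, b]) for b in ctx.BASES
                    },
                    "n_observed": prof.n_observed,
                    "n_null": prof.n_null,
                    "excluded": dict(excluded),
                    "null_skipped": dict(skipped),
                }

        stage = "consequence"
        indel_stats = {}
        cons_summary_df = None
        frameshift_pct = None
        if fn_indels:
            spec = cq.indel_length_spectrum(fn_indels, "fn")
            one_bp = [
                v for v in fn_indels if abs(len(v.alt) - len(v.ref)) == 1
            ]
            indel_stats = {
                "insertion_fraction": spec.insertion_fraction,
                "n_insertions": spec.n_insertions,
                "n_deletions": spec.n_deletions,
                "single_bp_identity": cq.single_bp_identity(one_bp).to_dict()
                if one_bp
                else None,
            }
        if res.transcripts:
            records = []
            cache = None
            for r in denovo.records:
                records.extend(
                    cq.classify_consequence(
                        r.variant, res.transcripts, res.reference
                    )
                )
            cons_summary_df = cq.consequence_summary(records, "fn")
            try:
                frameshift_pct = cq.frameshift_fraction_of_coding(cons_summary_df)
            except ValueError:
                frameshift_pct = None

        stage = "popstats"
        n_hap = config.sim.cohort.n_lines
        L = sum(res.contig_lengths.values())
        singleton_counts = [1] * len(fn_snvs)
        div = popstats.theta_pi(singleton_counts, n_hap, L) if fn_snvs else None
        rates = config.rates or popstats.MutationRateModel(genome_length=L)
        expected = {
            "snp_per_line": popstats.expected_spontaneous_count(
                rates, "snp", int(res.meta["selfing_generations"].mean())
            ),
            "indel_per_line": popstats.expected_spontaneous_count(
                rates, "indel", int(res.meta["selfing_generations"].mean())
            ),
        }
        het = popstats.observed_heterozygosity(res.cohort_variants)
    except Exception as exc:  # pragma: no cover - error context passthrough
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    summary = {
        "seed": config.sim.seed,
        "n_lines": len(res.meta),
        "per_line": per_line.reset_index().to_dict(orient="list"),
        "cohort_mean": cohort_summary.mean,
        "cohort_sd": cohort_summary.sd,
        "association": {
            "r_squared": assoc.r_squared,
            "t_statistic": assoc.t_statistic,
            "t_pvalue": assoc.t_pvalue,
            "anova_pvalues": dict(assoc.anova["PR(>F)"].dropna())
            if assoc.anova is not None
            else None,
            "flags": list(assoc.flags),
        },
        "spectra": {
            label: {
                "counts": tbl.counts,
                "fractions": tbl.fractions,
                "ts_tv": tbl.ts_tv if not tbl.degenerate else None,
                "degenerate": tbl.degenerate,
            }
            for label, tbl in spectra.items()
        },
        "re_profile": re_summary,
        "indels": indel_stats,
        "consequences": cons_summary_df,
        "frameshift_pct_of_coding": frameshift_pct,
        "theta_pi": div.theta_pi if div else None,
        "expected_spontaneous": expected,
        "mean_het_fraction": float(het["het_fraction"].mean()) if len(het) else None,
        "filter_removed": dict(denovo.removed),
    }
    summary = _jsonable(summary)

    if config.outdir is not None:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        per_line.to_csv(outdir / "per_line_counts.tsv", sep="\t")
        if spectra:
            pd.concat([t.to_frame() for t in spectra.values()]).to_csv(
                outdir / "spectrum.tsv", sep="\t", index=False
            )
        if cons_summary_df is not None:
            cons_summary_df.to_csv(outdir / "consequences.tsv", sep="\t", index=False)
        het.to_csv(outdir / "heterozygosity.tsv", sep="\t", index=False)
        (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary


def summarize_counts(
    per_line: pd.DataFrame,
    consequences: pd.DataFrame | None = None,
    n_haploid: int | None = None,
    genome_length: float | None = None,
) -> dict:
    """Summary statistics from a per-line counts table alone (no VCFs).

    ``per_line`` needs columns ``snps`` and ``indels`` (plus ``dosage_gy``
    and ``selfing_generations`` for the ANOVA); ``consequences`` is an
    affected-transcript table with ``label`` and one count column per
    cohort.
    """
    cohort_summary = spectrum.per_line_summary(per_line)
    assoc = spectrum.snp_indel_association(per_line)
    out = {
        "cohort_mean": cohort_summary.mean,
        "cohort_sd": cohort_summary.sd,
        "cohort_sd_pop": cohort_summary.sd_pop,
        "association": {
            "r_squared": assoc.r_squared,
            "t_statistic": assoc.t_statistic,
            "t_pvalue": assoc.t_pvalue,
            "anova_pvalues": dict(assoc.anova["PR(>F)"].dropna())
            if assoc.anova is not None
            else None,
        },
    }
    if consequences is not None:
        counts_cols = [c for c in consequences.columns if c != "label"]
        out["frameshift_pct_of_coding"] = {
            c: cq.frameshift_fraction_of_coding(
                dict(zip(consequences["label"], consequences[c]))
            )
            for c in counts_cols
        }
    if n_haploid and genome_length:
        snp_total = int(per_line["snps"].sum())
        out["theta_pi"] = popstats.theta_pi(
            [1] * snp_total, n_haploid, genome_length
        ).theta_pi
    return _jsonable(out)
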