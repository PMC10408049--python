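"""Pipeline orchestration, FDR control, odds-ratio conversion and output files.

``run_pipeline`` executes the whole analysis from a declarative run
configuration: instrument selection in the configured gene regions, LD
clumping, winner's-curse correction, per-outcome harmonization and
cross-source meta-analysis of the variant-outcome associations, the
correlated-variant IVW estimate with its sensitivity suite, and
Benjamini-Hochberg FDR control across the primary outcome analyses.
Sensitivity analyses never enter the FDR family.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from statsmodels.stats.multitest import multipletests

from . import __version__
from .gwas_io import harmonize, read_ld_matrix, read_summary_stats
from .instruments import (
    DEFAULT_REGIONS,
    clump,
    fiqt_adjust,
    instrument_strength,
    select_region_snps,
)
from .meta import cochran_q, fixed_effect_meta, random_effects_meta
from .models import (
    GeneRegion,
    HarmonizedSet,
    HetResult,
    LDMatrix,
    MREstimate,
    ORRecord,
    SelectionConfig,
    StrengthReport,
    SummarySet,
)
from .mr_core import correlated_ivw, lead_snp_analysis, leave_one_out, per_gene_estimates

__all__ = [
    "ORRecord",
    "SourceSpec",
    "OutcomeSpec",
    "RunConfig",
    "OutcomeResult",
    "ResultBundle",
    "bh_fdr",
    "to_odds_ratio",
    "run_pipeline",
    "write_results",
]


def bh_fdr(pvals: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, capped at one."""
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        return []
    if np.any((p <= 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1].tolist()


def to_odds_ratio(est: MREstimate, outcome: str = "", p_fdr: float | None = None) -> ORRecord:
    """Exponentiate a log-odds-per-SD slope into an odds ratio per SD."""
    return ORRecord(
        outcome=outcome or est.label,
        or_=float(np.exp(est.beta)),
        ci_low=float(np.exp(est.ci_low)),
        ci_high=float(np.exp(est.ci_high)),
        pval=est.pval,
        p_fdr=est.pval if p_fdr is None else p_fdr,
        n_variants=est.n_variants,
    )


@dataclass(frozen=True)
class SourceSpec:
    """One variant-outcome summary-statistics file."""

    path: str
    label: str
    column_map: Mapping[str, str] | None = None


@dataclass(frozen=True)
class OutcomeSpec:
    name: str
    sources: tuple[SourceSpec, ...]

    def __post_init__(self) -> None:
        if not self.sources:
            raise ValueError(f"outcome {self.name!r} has no sources")


@dataclass
class RunConfig:
    """Declarative description of one full pipeline run."""

    exposure_path: str
    ld_path: str
    outcomes: tuple[OutcomeSpec, ...]
    regions: tuple[GeneRegion, ...] = DEFAULT_REGIONS
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    eaf_ambiguity_band: float = 0.08
    apply_fiqt: bool = True
    leads: tuple[str, ...] = ()
    exposure_column_map: Mapping[str, str] | None = None
    exposure_trait: str = "exposure"
    seed: int = 0

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        regions = tuple(
            GeneRegion(
                name=r["name"],
                chrom=str(r["chrom"]),
                start=int(r["start"]),
                end=int(r["end"]),
                flank=int(r.get("flank", 0)),
            )
            for r in d.get("regions", [])
        ) or DEFAULT_REGIONS
        sel = d.get("selection", {})
        selection = SelectionConfig(
            p_threshold=float(sel.get("p_threshold", 5e-5)),
            clump_r2=float(sel.get("clump_r2", 0.3)),
            clump_window_kb=float(sel.get("clump_window_kb", 10_000)),
            m_total=sel.get("m_total"),
        )
        outcomes = tuple(
            OutcomeSpec(
                name=o["name"],
                sources=tuple(
                    SourceSpec(
                        path=s["path"],
                        label=s.get("label", Path(s["path"]).stem),
                        column_map=s.get("column_map"),
                    )
                    for s in o["sources"]
                ),
            )
            for o in d["outcomes"]
        )
        exp = d["exposure"]
        return cls(
            exposure_path=exp["path"],
            exposure_column_map=exp.get("column_map"),
            exposure_trait=exp.get("trait", "exposure"),
            ld_path=d["ld"],
            outcomes=outcomes,
            regions=regions,
            selection=selection,
            eaf_ambiguity_band=float(d.get("eaf_ambiguity_band", 0.08)),
            apply_fiqt=bool(d.get("fiqt", True)),
            leads=tuple(d.get("leads", ())),
            seed=int(d.get("seed", 0)),
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def echo(self) -> dict:
        d = dataclasses.asdict(self)
        d["regions"] = [dataclasses.asdict(r) for r in self.regions]
        d["selection"] = dataclasses.asdict(self.selection)
        d["outcomes"] = [
            {
                "name": o.name,
                "sources": [dataclasses.asdict(s) for s in o.sources],
            }
            for o in self.outcomes
        ]
        return d


@dataclass
class OutcomeResult:
    """All analyses of one outcome."""

    name: str
    primary: MREstimate
    or_record: ORRecord
    per_source: dict[str, MREstimate]
    source_het: HetResult | None
    source_re_meta: MREstimate | None
    per_gene: dict[str, MREstimate]
    gene_het: HetResult | None
    loo: list[MREstimate]
    lead: MREstimate | None
    exclusions: list[tuple[str, str, str]]  # (source, rsid, reason)


@dataclass
class ResultBundle:
    """Everything one pipeline run produced."""

    outcomes: list[OutcomeResult]
    instruments: SummarySet
    strength: StrengthReport
    selection_m_total: int
    config_echo: dict
    seed: int


def _harmonized_meta(
    instruments: SummarySet,
    source_sets: Mapping[str, SummarySet],
    band: float,
) -> tuple[HarmonizedSet, list[tuple[str, str, str]]]:
    """Harmonize each source then fixed-effect meta-analyze per variant.

    A variant covered by only some sources is pooled over the sources that
    measured it, mirroring per-outcome coverage differences in real GWAS.
    """
    per_source = {
        label: harmonize(instruments, sset, eaf_ambiguity_band=band)
        for label, sset in source_sets.items()
    }
    exclusions = [
        (label, rsid, reason)
        for label, h in per_source.items()
        for rsid, reason in h.exclusions
    ]
    pairs = {}
    for rsid in instruments.rsids:
        recs = [h.pairs[rsid][1] for h in per_source.values() if rsid in h.pairs]
        if not recs:
            exclusions.append(("meta", rsid, "missing in every source"))
            continue
        pairs[rsid] = (
            instruments[rsid],
            recs[0] if len(recs) == 1 else fixed_effect_meta(recs),
        )
    h_meta = HarmonizedSet(
        pairs=pairs,
        gene_assignment={
            r: instruments[r].region for r in pairs if instruments[r].region
        },
    )
    return h_meta, exclusions


def _sensitivity_suite(
    name: str,
    h_meta: HarmonizedSet,
    per_source_h: Mapping[str, HarmonizedSet],
    ld: LDMatrix,
    leads: Sequence[str],
) -> OutcomeResult:
    primary = correlated_ivw(h_meta, ld, label="primary")
    per_source_est = {
        label: correlated_ivw(h, ld, label=f"source:{label}")
        for label, h in per_source_h.items()
        if len(h) > 0
    }
    source_het = source_re = None
    if len(per_source_est) >= 2:
        ests = [(e.beta, e.se) for e in per_source_est.values()]
        source_het = cochran_q(ests)
        source_re = random_effects_meta(ests, label="source-re-meta")
    per_gene: dict[str, MREstimate] = {}
    gene_het = None
    if len(set(h_meta.gene_assignment.values())) >= 2:
        per_gene, gene_het = per_gene_estimates(h_meta, ld)
    loo = leave_one_out(h_meta, ld) if len(h_meta) >= 2 else []
    lead_est = None
    leads_present = [r for r in leads if r in h_meta.pairs]
    if leads_present:
        lead_est = lead_snp_analysis(h_meta, ld, leads_present)
    return OutcomeResult(
        name=name,
        primary=primary,
        or_record=to_odds_ratio(primary, outcome=name),  # p_fdr filled later
        per_source=per_source_est,
        source_het=source_het,
        source_re_meta=source_re,
        per_gene=per_gene,
        gene_het=gene_het,
        loo=loo,
        lead=lead_est,
        exclusions=[],
    )


def run_pipeline(config: RunConfig) -> ResultBundle:
    """Execute the full cis-MR analysis described by ``config``.

    Deterministic given the configuration: file reading, selection,
    clumping, FIQT, harmonization, per-variant cross-source meta-analysis,
    correlated IVW plus sensitivity analyses per outcome, and BH-FDR across
    the primary estimates of all outcomes.
    """
    exposure = read_summary_stats(
        config.exposure_path,
        column_map=config.exposure_column_map,
        trait=config.exposure_trait,
        trait_type="continuous",
        units="SD",
        source="exposure",
    )
    ld = read_ld_matrix(config.ld_path)

    in_region = [
        rec
        for rec in exposure
        if any(r.contains(rec.variant.chrom, rec.variant.pos) for r in config.regions)
    ]
    m_total = (
        config.selection.m_total
        if config.selection.m_total is not None
        else len(in_region)
    )

    try:
        selected = select_region_snps(exposure, config.regions, config.selection)
        clumped = clump(selected, ld, config.selection)
        instruments = (
            fiqt_adjust(clumped, m_total=m_total) if config.apply_fiqt else clumped
        )
    except (ValueError, KeyError) as exc:
        raise RuntimeError(f"instrument selection stage failed: {exc}") from exc

    strength = instrument_strength(instruments, ld)

    results: list[OutcomeResult] = []
    for spec in config.outcomes:
        source_sets = {
            s.label: read_summary_stats(
                s.path,
                column_map=s.column_map,
                trait=spec.name,
                trait_type="binary",
                units="log-odds",
                source=s.label,
            )
            for s in spec.sources
        }
        try:
            h_meta, exclusions = _harmonized_meta(
                instruments, source_sets, config.eaf_ambiguity_band
            )
            per_source_h = {
                label: harmonize(
                    instruments, sset, eaf_ambiguity_band=config.eaf_ambiguity_band
                )
                for label, sset in source_sets.items()
            }
            res = _sensitivity_suite(spec.name, h_meta, per_source_h, ld, config.leads)
        except (ValueError, KeyError, ZeroDivisionError) as exc:
            raise RuntimeError(f"outcome stage failed for {spec.name!r}: {exc}") from exc
        res.exclusions = exclusions
        results.append(res)

    p_fdr = bh_fdr([r.primary.pval for r in results])
    for res, pf in zip(results, p_fdr):
        res.or_record = to_odds_ratio(res.primary, outcome=res.name, p_fdr=pf)

    return ResultBundle(
        outcomes=results,
        instruments=instruments,
        strength=strength,
        selection_m_total=m_total,
        config_echo=config.echo(),
        seed=config.seed,
    )


def _est_row(outcome: str, analysis: str, est: MREstimate, p_fdr: float | None = None) -> dict:
    return {
        "outcome": outcome,
        "analysis": analysis,
        "n_variants": est.n_variants,
        "beta": est.beta,
        "se": est.se,
        "ci_low": est.ci_low,
        "ci_high": est.ci_high,
        "pval": est.pval,
        "p_fdr": p_fdr,
        "q": est.q,
        "phi": est.phi,
        "or": round(float(np.exp(est.beta)), 3),
        "or_ci_low": round(float(np.exp(est.ci_low)), 3),
        "or_ci_high": round(float(np.exp(est.ci_high)), 3),
    }


def write_results(bundle: ResultBundle, out_dir) -> list[str]:
    """Serialize a bundle as stable TSV tables plus run metadata JSON.

    Emits estimates.tsv, loo.tsv, heterogeneity.tsv, instruments.tsv,
    exclusions.tsv and run.json; returns the manifest. Identical bundles
    produce byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    est_rows, loo_rows, het_rows, excl_rows = [], [], [], []
    for res in bundle.outcomes:
        est_rows.append(_est_row(res.name, "primary", res.primary, res.or_record.p_fdr))
        for label, e in res.per_source.items():
            est_rows.append(_est_row(res.name, f"source:{label}", e))
        for label, e in res.per_gene.items():
            est_rows.append(_est_row(res.name, f"gene:{label}", e))
        if res.source_re_meta is not None:
            est_rows.append(_est_row(res.name, "source-re-meta", res.source_re_meta))
        if res.lead is not None:
            est_rows.append(_est_row(res.name, "lead-snp", res.lead))
        for e in res.loo:
            loo_rows.append(
                {
                    "outcome": res.name,
                    "omitted_rsid": e.label,
                    "n_variants": e.n_variants,
                    "beta": e.beta,
                    "se": e.se,
                    "ci_low": e.ci_low,
                    "ci_high": e.ci_high,
                    "pval": e.pval,
                }
            )
        for scope, het in (("sources", res.source_het), ("genes", res.gene_het)):
            if het is not None:
                het_rows.append(
                    {
                        "outcome": res.name,
                        "scope": scope,
                        "q": het.q,
                        "df": het.df,
                        "i2": het.i2,
                        "p_het": het.p_het,
                    }
                )
        for source, rsid, reason in res.exclusions:
            excl_rows.append(
                {"outcome": res.name, "source": source, "rsid": rsid, "reason": reason}
            )

    loo_cols = ["outcome", "omitted_rsid", "n_variants", "beta", "se",
                "ci_low", "ci_high", "pval"]
    het_cols = ["outcome", "scope", "q", "df", "i2", "p_het"]
    excl_cols = ["outcome", "source", "rsid", "reason"]
    est_cols = ["outcome", "analysis", "n_variants", "beta", "se", "ci_low",
                "ci_high", "pval", "p_fdr", "q", "phi", "or", "or_ci_low",
                "or_ci_high"]

    def _write(df: pd.DataFrame, cols: list[str], name: str) -> None:
        df.reindex(columns=cols).to_csv(
            out / name, sep="\t", index=False, float_format="%.10g"
        )

    _write(pd.DataFrame(est_rows), est_cols, "estimates.tsv")
    _write(pd.DataFrame(loo_rows), loo_cols, "loo.tsv")
    _write(pd.DataFrame(het_rows), het_cols, "heterogeneity.tsv")
    _write(pd.DataFrame(excl_rows), excl_cols, "exclusions.tsv")
    inst_df = bundle.instruments.to_dataframe()
    inst_df.to_csv(out / "instruments.tsv", sep="\t", index=False, float_format="%.10g")

    run_meta = {
        "cismr_version": __version__,
        "seed": bundle.seed,
        "m_total": bundle.selection_m_total,
        "mean_f": bundle.strength.mean_f,
        "mean_f_marginal": bundle.strength.mean_f_marginal,
        "approx_relative_bias": bundle.strength.approx_relative_bias,
        "config": bundle.config_echo,
    }
    with open(out / "run.json", "w") as fh:
        json.dump(run_meta, fh, indent=2, sort_keys=True)
        fh.write("\n")

    return [
        "estimates.tsv",
        "loo.tsv",
        "heterogeneity.tsv",
        "instruments.tsv",
        "exclusions.tsv",
        "run.json",
    ]
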