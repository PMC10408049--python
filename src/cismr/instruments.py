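"""Instrument selection and post-processing for cis-MR.

Selection keeps variants that pass a significance threshold inside flanked
gene regions; greedy LD clumping prunes correlated variants; the FIQT
(FDR inverse quantile transformation) shrinks selected effect sizes to
counter winner's curse; and a decorrelated mean F statistic quantifies
instrument strength.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np
from scipy.stats import norm

from .models import (
    AssocRecord,
    GeneRegion,
    LDMatrix,
    SelectionConfig,
    StrengthReport,
    SummarySet,
)

__all__ = [
    "GeneRegion",
    "SelectionConfig",
    "StrengthReport",
    "DEFAULT_REGIONS",
    "select_region_snps",
    "clump",
    "fiqt_adjust",
    "instrument_strength",
]

logger = logging.getLogger(__name__)

#: Caffeine-metabolism gene regions (GRCh37, Ensembl coordinates) with the
#: conventional 100 kb flank used for cis-instrument selection.
DEFAULT_REGIONS = (
    GeneRegion(name="AHR", chrom="7", start=17_338_246, end=17_385_776, flank=100_000),
    GeneRegion(name="CYP1A2", chrom="15", start=75_041_185, end=75_048_543, flank=100_000),
)


def select_region_snps(
    exposure: SummarySet,
    regions: Sequence[GeneRegion] = DEFAULT_REGIONS,
    config: SelectionConfig | None = None,
) -> SummarySet:
    """Keep records with p below threshold inside a flanked region.

    Boundaries are inclusive on both ends; a variant falling in several
    regions is assigned to the first region listed.
    """
    config = config or SelectionConfig()
    kept: list[AssocRecord] = []
    for rec in exposure:
        if rec.pval is None or rec.pval >= config.p_threshold:
            continue
        v = rec.variant
        for region in regions:
            if region.contains(v.chrom, v.pos):
                kept.append(dataclasses.replace(rec, region=region.name))
                break
    if not kept:
        raise ValueError(
            "no variants pass the significance threshold inside the regions; "
            "check the p threshold, the region coordinates and the build"
        )
    return exposure.replace_records(kept)


def clump(
    selected: SummarySet,
    ld: LDMatrix,
    config: SelectionConfig | None = None,
) -> SummarySet:
    """Greedy LD clumping by ascending p-value.

    Repeatedly keeps the not-yet-removed variant with the smallest p
    (ties broken by rsid, for determinism) and removes every other variant
    with r^2 above ``clump_r2`` within ``clump_window_kb``. Variants on
    different chromosomes never exclude each other. The retained set is
    returned in the input order.
    """
    config = config or SelectionConfig()
    missing = [r for r in selected.rsids if r not in ld]
    if missing:
        raise KeyError(f"rsids absent from the LD matrix: {missing}")
    window_bp = config.clump_window_kb * 1000.0
    order = sorted(
        selected,
        key=lambda rec: (rec.pval if rec.pval is not None else 1.0, rec.rsid),
    )
    removed: set[str] = set()
    kept: set[str] = set()
    for rec in order:
        if rec.rsid in removed:
            continue
        kept.add(rec.rsid)
        for other in order:
            if other.rsid in kept or other.rsid in removed:
                continue
            if other.variant.chrom != rec.variant.chrom:
                continue
            if abs(other.variant.pos - rec.variant.pos) > window_bp:
                continue
            if ld.r2(rec.rsid, other.rsid) > config.clump_r2:
                removed.add(other.rsid)
    return selected.replace_records([r for r in selected if r.rsid in kept])


def _bh_adjust_with_total(pvals: np.ndarray, m_total: int) -> np.ndarray:
    """BH step-up adjusted p-values using ``m_total`` as the test count.

    Matches R's p.adjust(p, "BH", n = m_total) for a subset of a larger
    family: adj_(i) = min_{j>=i} p_(j) * m_total / j, capped at 1.
    """
    p = np.asarray(pvals, dtype=float)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m_total / np.arange(1, len(p) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = np.minimum(adj, 1.0)
    return out


def fiqt_adjust(selected: SummarySet, m_total: int | None = None) -> SummarySet:
    """Winner's-curse correction by FDR inverse quantile transformation.

    Two-sided p-values are BH-adjusted against ``m_total`` tests (default:
    the number of records supplied), mapped back to z-scores via the normal
    quantile, and multiplied by the standard error to give shrunken betas:

        z_adj = sign(z) * Phi^-1(1 - p_BH / 2),  beta_adj = z_adj * se.

    The original beta is kept in ``beta_raw``; se and pval are untouched.
    An adjusted p of 1 or more maps to beta 0 (warned).
    """
    records = list(selected)
    if any(r.pval is None for r in records):
        raise ValueError("FIQT needs a p-value on every record")
    m_total = m_total if m_total is not None else len(records)
    if m_total < len(records):
        raise ValueError("m_total cannot be smaller than the record count")
    p_adj = _bh_adjust_with_total(
        np.array([r.pval for r in records]), m_total
    )
    adjusted: list[AssocRecord] = []
    for rec, pa in zip(records, p_adj):
        if pa >= 1.0:
            logger.warning("%s: adjusted p >= 1; shrinking beta to 0", rec.rsid)
            z_adj = 0.0
        else:
            z_adj = float(np.sign(rec.z) * norm.isf(pa / 2.0))
        adjusted.append(
            dataclasses.replace(rec, beta=z_adj * rec.se, beta_raw=rec.beta)
        )
    return selected.replace_records(adjusted)


def instrument_strength(
    selected: SummarySet, ld: LDMatrix, decorrelate: bool = True
) -> StrengthReport:
    """Mean F statistic of the instrument set, accounting for LD.

    With z_j = beta_j / se_j the decorrelated mean F is (z' R^-1 z) / J;
    its reciprocal approximates the relative weak-instrument bias of the
    IVW estimate. The plain mean of z_j^2 is also reported.
    """
    rsids = selected.rsids
    missing = [r for r in rsids if r not in ld]
    if missing:
        raise KeyError(f"rsids absent from the LD matrix: {missing}")
    z = np.array([selected[r].z for r in rsids])
    r_sub = ld.subset(rsids).r
    marginal = float(np.mean(z**2))
    if decorrelate:
        try:
            decorr = float(z @ np.linalg.solve(r_sub, z)) / len(z)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                "LD matrix is singular over the instrument set"
            ) from exc
        mean_f = decorr
    else:
        mean_f = marginal
    return StrengthReport(
        mean_f=mean_f,
        approx_relative_bias=1.0 / mean_f if mean_f > 0 else float("inf"),
        per_variant_z=dict(zip(rsids, z.tolist())),
        mean_f_marginal=marginal,
    )
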