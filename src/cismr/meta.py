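"""Meta-analysis machinery.

Fixed-effect inverse-variance pooling is used to combine per-variant
outcome associations across cohorts; DerSimonian-Laird additive random
effects combine MR estimates across sources; Cochran's Q and I-squared
quantify heterogeneity.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy.stats import chi2, norm

from .models import AssocRecord, HetResult, MREstimate

__all__ = [
    "HetResult",
    "fixed_effect_meta",
    "cochran_q",
    "random_effects_meta",
]


def fixed_effect_meta(per_source: Sequence[AssocRecord]) -> AssocRecord:
    """Inverse-variance-weighted fixed-effect pooling of one variant.

    All records must describe the same variant with the same effect allele.
    The pooled record carries source label "meta" and a recomputed
    two-sided normal p-value.
    """
    if not per_source:
        raise ValueError("no records to meta-analyze")
    first = per_source[0]
    for rec in per_source[1:]:
        if rec.variant.rsid != first.variant.rsid or (
            rec.variant.effect_allele,
            rec.variant.other_allele,
        ) != (first.variant.effect_allele, first.variant.other_allele):
            raise ValueError(
                f"records for {first.rsid} are not allele-aligned across sources"
            )
    b = np.array([r.beta for r in per_source])
    w = np.array([1.0 / r.se**2 for r in per_source])
    beta = float(np.sum(w * b) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    pval = float(2.0 * norm.sf(abs(beta) / se))
    ns = [r.n for r in per_source if r.n is not None]
    return dataclasses.replace(
        first,
        beta=beta,
        se=se,
        pval=max(pval, np.finfo(float).tiny),
        n=sum(ns) if ns else None,
        source="meta",
    )


def cochran_q(estimates: Sequence[tuple[float, float]]) -> HetResult:
    """Cochran's Q against the fixed-effect pooled mean, with I-squared.

    I^2 = max(0, (Q - df) / Q); its floor at zero matches the convention
    of reporting "0%" when Q does not exceed its degrees of freedom.
    """
    if len(estimates) < 2:
        raise ValueError("heterogeneity needs at least 2 estimates")
    b = np.array([e[0] for e in estimates], dtype=float)
    s = np.array([e[1] for e in estimates], dtype=float)
    if np.any(s <= 0):
        raise ValueError("standard errors must be positive")
    w = 1.0 / s**2
    pooled = np.sum(w * b) / np.sum(w)
    q = float(np.sum(w * (b - pooled) ** 2))
    df = len(estimates) - 1
    i2 = max(0.0, (q - df) / q) if q > 0 else 0.0
    return HetResult(q=q, df=df, i2=i2, p_het=float(chi2.sf(q, df)))


def random_effects_meta(
    estimates: Sequence[tuple[float, float]], label: str = "random-effects meta"
) -> MREstimate:
    """DerSimonian-Laird additive random-effects pooling.

    tau^2 = max(0, (Q - df) / (sum w - sum w^2 / sum w)) with fixed-effect
    weights w = 1/se^2; pooling then uses w* = 1/(se^2 + tau^2).
    """
    if len(estimates) < 2:
        raise ValueError("random-effects meta needs at least 2 estimates")
    b = np.array([e[0] for e in estimates], dtype=float)
    s = np.array([e[1] for e in estimates], dtype=float)
    w = 1.0 / s**2
    het = cochran_q(estimates)
    denom = np.sum(w) - np.sum(w**2) / np.sum(w)
    tau2 = max(0.0, (het.q - het.df) / denom) if denom > 0 else 0.0
    w_star = 1.0 / (s**2 + tau2)
    beta = float(np.sum(w_star * b) / np.sum(w_star))
    se = float(np.sum(w_star) ** -0.5)
    pval = float(2.0 * norm.sf(abs(beta) / se))
    return MREstimate(
        beta=beta,
        se=se,
        ci_low=beta - 1.96 * se,
        ci_high=beta + 1.96 * se,
        pval=max(pval, np.finfo(float).tiny),
        n_variants=len(estimates),
        q=het.q,
        phi=1.0,
        label=label,
    )
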