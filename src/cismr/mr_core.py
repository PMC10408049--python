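"""Causal estimation: Wald ratios and the correlated-variant IVW estimator.

The pooled slope is estimated by generalized least squares of the outcome
associations on the exposure associations through the origin,

    beta = (g' O^-1 g)^-1 g' O^-1 G,   O_jk = se(G_j) se(G_k) r_jk,

with a multiplicative random-effects variance inflation
phi = max(1, Q / (J - 1)) absorbing residual heterogeneity without moving
the point estimate. With an identity LD matrix this reduces to the
standard IVW of Wald ratios under first-order weights; with one variant it
is exactly the Wald ratio. Exposure uncertainty is deliberately ignored in
the weights (first-order IVW), which is what the 1/F weak-instrument bias
approximation presupposes.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import norm

from .meta import cochran_q
from .models import HarmonizedSet, HetResult, LDMatrix, MREstimate, RatioEstimate

__all__ = [
    "RatioEstimate",
    "MREstimate",
    "wald_ratio",
    "correlated_ivw",
    "leave_one_out",
    "per_gene_estimates",
    "lead_snp_analysis",
]


def wald_ratio(exposure_beta: float, exposure_se: float,
               outcome_beta: float, outcome_se: float,
               rsid: str = "") -> RatioEstimate:
    """Per-variant causal estimate: outcome beta over exposure beta.

    The standard error is first-order (delta method in the outcome only):
    se(theta) = se(Gamma) / |gamma|.
    """
    if exposure_beta == 0:
        raise ZeroDivisionError(f"{rsid}: zero exposure beta")
    return RatioEstimate(
        rsid=rsid,
        theta=outcome_beta / exposure_beta,
        se_theta=outcome_se / abs(exposure_beta),
    )


def correlated_ivw(h: HarmonizedSet, ld: LDMatrix, label: str = "primary") -> MREstimate:
    """Multiplicative random-effects IVW accounting for LD between variants.

    The LD matrix must be signed and aligned to the harmonized effect
    alleles; ``ld`` may cover a superset of the harmonized variants.
    """
    if len(h) == 0:
        raise ValueError("no variants to estimate from")
    gamma, _, Gamma, se_Gamma = h.arrays()
    if np.any(gamma == 0):
        raise ZeroDivisionError("zero exposure beta among instruments")
    J = len(gamma)
    r_sub = ld.subset(h.rsids).r
    omega = np.outer(se_Gamma, se_Gamma) * r_sub
    try:
        oi_g = np.linalg.solve(omega, gamma)
        oi_G = np.linalg.solve(omega, Gamma)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError("singular weighting matrix Omega") from exc
    v = 1.0 / float(gamma @ oi_g)
    beta = v * float(gamma @ oi_G)
    resid = Gamma - beta * gamma
    q = float(resid @ np.linalg.solve(omega, resid))
    q = max(q, 0.0)  # guards tiny negative round-off at exact fit
    phi = max(1.0, q / (J - 1)) if J >= 2 else 1.0
    se = float(np.sqrt(v * phi))
    pval = float(2.0 * norm.sf(abs(beta) / se))
    return MREstimate(
        beta=beta,
        se=se,
        ci_low=beta - 1.96 * se,
        ci_high=beta + 1.96 * se,
        pval=max(pval, np.finfo(float).tiny),
        n_variants=J,
        q=q,
        phi=phi,
        label=label,
    )


def leave_one_out(h: HarmonizedSet, ld: LDMatrix) -> list[MREstimate]:
    """Re-estimate the slope omitting each variant in turn.

    Each result is labelled by the omitted rsid. The LD submatrix is taken
    from the already-repaired full matrix without re-repair, so results are
    deterministic functions of the full-set inputs.
    """
    if len(h) < 2:
        raise ValueError("leave-one-out needs at least 2 variants")
    out = []
    for omit in h.rsids:
        keep = [r for r in h.rsids if r != omit]
        out.append(correlated_ivw(h.subset(keep), ld, label=omit))
    return out


def per_gene_estimates(
    h: HarmonizedSet, ld: LDMatrix
) -> tuple[dict[str, MREstimate], HetResult]:
    """Slope per gene region plus heterogeneity across the region slopes."""
    if set(h.gene_assignment) != set(h.rsids):
        missing = set(h.rsids) - set(h.gene_assignment)
        raise ValueError(f"variants without a region assignment: {sorted(missing)}")
    regions: dict[str, list[str]] = {}
    for rsid in h.rsids:
        regions.setdefault(h.gene_assignment[rsid], []).append(rsid)
    if len(regions) < 2:
        raise ValueError("gene-level heterogeneity needs at least 2 regions")
    estimates = {
        name: correlated_ivw(h.subset(rsids), ld, label=name)
        for name, rsids in regions.items()
    }
    het = cochran_q([(e.beta, e.se) for e in estimates.values()])
    return estimates, het


def lead_snp_analysis(
    h: HarmonizedSet, ld: LDMatrix, leads: list[str]
) -> MREstimate:
    """Replicate the analysis using only the lead variant per region."""
    missing = [r for r in leads if r not in h.pairs]
    if missing:
        raise KeyError(f"lead variants absent from harmonized set: {missing}")
    return correlated_ivw(h.subset(leads), ld, label="lead-snp")
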