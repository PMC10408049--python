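"""Reading, validating and harmonizing GWAS summary statistics and LD matrices.

Summary statistics are delimited text with a header (TSV by default; comma
detected automatically). The canonical column names are

    rsid, chr, pos, ea, oa, eaf, beta, se, pval, n

and any file can be mapped onto them with a ``column_map``. LD matrices are
TSV with rsids as both the header row and the first column, cells holding the
signed correlation r.
"""

from __future__ import annotations

import logging
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .models import (
    AssocRecord,
    HarmonizedSet,
    LDMatrix,
    SummarySet,
    Variant,
)

__all__ = [
    "Variant",
    "AssocRecord",
    "SummarySet",
    "LDMatrix",
    "HarmonizedSet",
    "CANONICAL_COLUMNS",
    "read_summary_stats",
    "write_summary_stats",
    "read_ld_matrix",
    "write_ld_matrix",
    "ld_from_dosages",
    "psd_repair",
    "harmonize",
]

logger = logging.getLogger(__name__)

CANONICAL_COLUMNS = ("rsid", "chr", "pos", "ea", "oa", "eaf", "beta", "se", "pval", "n")

#: |z| vs p disagreement tolerated before a warn-only consistency note.
_PVAL_Z_LOG10_TOL = 1.0


def _sniff_sep(path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "," if ("," in header and "\t" not in header) else "\t"


def read_summary_stats(
    path,
    column_map: Mapping[str, str] | None = None,
    trait: str = "",
    trait_type: str = "continuous",
    units: str = "",
    source: str | None = None,
) -> SummarySet:
    """Read a delimited summary-statistics file into a validated SummarySet.

    ``column_map`` maps canonical field names to the file's column names
    (identity for any field omitted). Rows failing validation (non-positive
    se, out-of-range p or eaf, identical alleles, malformed numbers) are
    dropped and logged with the row number and reason; alleles are
    upper-cased on read.
    """
    column_map = dict(column_map or {})
    df = pd.read_csv(path, sep=_sniff_sep(path))
    for canon in ("rsid", "chr", "pos", "ea", "oa", "beta", "se"):
        col = column_map.get(canon, canon)
        if col not in df.columns:
            raise ValueError(f"{path}: required column {col!r} not found")

    def get(row, canon, default=None):
        col = column_map.get(canon, canon)
        if col not in df.columns:
            return default
        val = row[col]
        return default if pd.isna(val) else val

    records: list[AssocRecord] = []
    seen: set[str] = set()
    for i, row in df.iterrows():
        rsid = str(get(row, "rsid"))
        if rsid in seen:
            raise ValueError(f"{path}: duplicate rsid {rsid}")
        try:
            eaf = get(row, "eaf")
            variant = Variant(
                rsid=rsid,
                chrom=str(get(row, "chr")),
                pos=int(get(row, "pos")),
                effect_allele=str(get(row, "ea")).upper(),
                other_allele=str(get(row, "oa")).upper(),
                eaf=None if eaf is None else float(eaf),
            )
            se = float(get(row, "se"))
            if se <= 0:
                raise ValueError("nonpositive se")
            pval = get(row, "pval")
            n = get(row, "n")
            rec = AssocRecord(
                variant=variant,
                beta=float(get(row, "beta")),
                se=se,
                pval=None if pval is None else float(pval),
                n=None if n is None else float(n),
                source=source if source is not None else trait,
            )
        except (ValueError, TypeError) as exc:
            logger.warning("%s row %d (%s) dropped: %s", path, i + 2, rsid, exc)
            continue
        if rec.pval is not None:
            z_implied = _z_from_p(rec.pval)
            z_obs = abs(rec.z)
            if z_obs > 0.5 and z_implied > 0.5:
                if abs(np.log10(z_obs) - np.log10(z_implied)) > _PVAL_Z_LOG10_TOL:
                    warnings.warn(
                        f"{rsid}: reported p inconsistent with |beta/se|",
                        stacklevel=2,
                    )
        seen.add(rsid)
        records.append(rec)

    if not records:
        raise ValueError(f"{path}: no rows survived validation")
    return SummarySet.from_records(
        records, trait=trait or str(path), trait_type=trait_type, units=units
    )


def _z_from_p(p: float) -> float:
    from scipy.stats import norm

    return float(norm.isf(min(max(p, 1e-300), 1.0) / 2.0))


def write_summary_stats(sset: SummarySet, path) -> None:
    """Write a SummarySet to canonical-column TSV."""
    df = sset.to_dataframe()
    df[[c for c in CANONICAL_COLUMNS if c in df.columns]].to_csv(
        path, sep="\t", index=False
    )


def psd_repair(r: np.ndarray, min_eig: float = 1e-10) -> tuple[np.ndarray, bool]:
    """Clip negative eigenvalues and rescale the diagonal to one.

    Returns the repaired matrix and whether a repair was actually applied.
    """
    eigval, eigvec = np.linalg.eigh(r)
    if eigval.min() >= -1e-8:
        return r, False
    eigval = np.clip(eigval, min_eig, None)
    fixed = eigvec @ np.diag(eigval) @ eigvec.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return fixed, True


def read_ld_matrix(path) -> LDMatrix:
    """Read a signed LD correlation matrix from TSV.

    The matrix is symmetrized as (M + M')/2, the diagonal forced to one and,
    if the smallest eigenvalue is below -1e-8, repaired by eigenvalue
    clipping (logged).
    """
    df = pd.read_csv(path, sep=_sniff_sep(path), index_col=0)
    header = [str(c) for c in df.columns]
    rows = [str(i) for i in df.index]
    if len(header) != len(rows):
        raise ValueError(f"{path}: LD matrix is not square")
    if header != rows:
        raise ValueError(f"{path}: rsid mismatch between header and rows")
    m = df.to_numpy(dtype=float)
    if np.abs(m).max() > 1.0 + 1e-6:
        raise ValueError(f"{path}: |r| entries exceed 1")
    m = (m + m.T) / 2.0
    np.fill_diagonal(m, 1.0)
    m = np.clip(m, -1.0, 1.0)
    m, repaired = psd_repair(m)
    if repaired:
        logger.warning("%s: LD matrix was not PSD; eigenvalue-clip repair applied", path)
    return LDMatrix(rsids=rows, r=m)


def write_ld_matrix(ld: LDMatrix, path) -> None:
    pd.DataFrame(ld.r, index=ld.rsids, columns=ld.rsids).to_csv(path, sep="\t")


def ld_from_dosages(dosages: pd.DataFrame | np.ndarray, rsids: Sequence[str] | None = None) -> LDMatrix:
    """Signed LD from a variants-by-samples dosage table (Pearson r of rows).

    A small stand-in for estimating LD from a reference panel such as the
    1000 Genomes European subsample.
    """
    if isinstance(dosages, pd.DataFrame):
        rsids = [str(i) for i in dosages.index]
        mat = dosages.to_numpy(dtype=float)
    else:
        mat = np.asarray(dosages, dtype=float)
        rsids = list(rsids) if rsids is not None else [f"v{i}" for i in range(mat.shape[0])]
    if mat.shape[1] < 2:
        raise ValueError("need at least 2 samples to estimate LD")
    if np.any(mat.std(axis=1) == 0):
        bad = [rsids[i] for i in np.where(mat.std(axis=1) == 0)[0]]
        raise ValueError(f"constant dosage rows (zero variance): {bad}")
    r = np.corrcoef(mat)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return LDMatrix(rsids=rsids, r=r)


def _alignment(exp_v: Variant, out_v: Variant) -> str:
    """'same', 'swap', or 'mismatch' for an outcome variant vs exposure."""
    if (out_v.effect_allele, out_v.other_allele) == (exp_v.effect_allele, exp_v.other_allele):
        return "same"
    if (out_v.effect_allele, out_v.other_allele) == (exp_v.other_allele, exp_v.effect_allele):
        return "swap"
    return "mismatch"


def harmonize(
    exposure: SummarySet,
    outcome: SummarySet,
    eaf_ambiguity_band: float = 0.08,
    gene_assignment: Mapping[str, str] | None = None,
) -> HarmonizedSet:
    """Align outcome records to the exposure effect alleles.

    Variants present in only one set are excluded ("missing in other set").
    Swapped alleles flip the outcome beta and complement its eaf. Palindromic
    (A/T, C/G) variants are kept only when both allele frequencies fall
    outside 0.5 +/- ``eaf_ambiguity_band`` and agree in direction after
    alignment; a missing eaf on a palindromic variant excludes it. Other
    allele mismatches are excluded.
    """
    pairs: dict[str, tuple[AssocRecord, AssocRecord]] = {}
    exclusions: list[tuple[str, str]] = []
    exp_ids = set(exposure.rsids)
    out_ids = set(outcome.rsids)
    for rsid in exposure.rsids:
        if rsid not in out_ids:
            exclusions.append((rsid, "missing in other set"))
    for rsid in outcome.rsids:
        if rsid not in exp_ids:
            exclusions.append((rsid, "missing in other set"))

    for rsid in exposure.rsids:
        if rsid not in out_ids:
            continue
        e, o = exposure[rsid], outcome[rsid]
        align = _alignment(e.variant, o.variant)
        if align == "mismatch":
            exclusions.append((rsid, "allele mismatch"))
            continue
        if align == "swap":
            # flipped() swaps alleles and complements eaf when known
            o = AssocRecord(
                variant=o.variant.flipped(),
                beta=-o.beta,
                se=o.se,
                pval=o.pval,
                n=o.n,
                source=o.source,
            )
        if e.variant.is_palindromic:
            band_lo, band_hi = 0.5 - eaf_ambiguity_band, 0.5 + eaf_ambiguity_band
            e_eaf, o_eaf = e.variant.eaf, o.variant.eaf
            if e_eaf is None or o_eaf is None:
                exclusions.append((rsid, "palindromic, frequency-ambiguous"))
                continue
            if band_lo <= e_eaf <= band_hi or band_lo <= o_eaf <= band_hi:
                exclusions.append((rsid, "palindromic, frequency-ambiguous"))
                continue
            if (e_eaf > 0.5) != (o_eaf > 0.5):
                exclusions.append((rsid, "palindromic, frequency-ambiguous"))
                continue
        pairs[rsid] = (e, o)

    if not pairs and not exclusions:
        raise ValueError("no overlapping variants between exposure and outcome")
    assignment = {
        rsid: (gene_assignment or {}).get(rsid) or (exposure[rsid].region or "")
        for rsid in pairs
    }
    return HarmonizedSet(
        pairs=pairs,
        exclusions=exclusions,
        gene_assignment={k: v for k, v in assignment.items() if v},
    )
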