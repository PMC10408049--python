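"""Shared dataclasses for the cis-MR pipeline.

Each type is re-exported from the stage module it belongs to
(:mod:`cismr.gwas_io`, :mod:`cismr.instruments`, ...); this module only
exists so that the stage modules can share types without circular imports.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Variant",
    "AssocRecord",
    "SummarySet",
    "LDMatrix",
    "HarmonizedSet",
    "GeneRegion",
    "SelectionConfig",
    "StrengthReport",
    "HetResult",
    "RatioEstimate",
    "MREstimate",
    "ORRecord",
    "PALINDROMIC_PAIRS",
]

#: Allele pairs that read the same on both strands (strand-ambiguous SNPs).
PALINDROMIC_PAIRS = (frozenset({"A", "T"}), frozenset({"C", "G"}))


@dataclass(frozen=True)
class Variant:
    """A biallelic variant with its effect-allele orientation.

    Coordinates are 1-based GRCh37. ``eaf`` is the effect-allele frequency
    and may be ``None`` when the source file does not report it.
    """

    rsid: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float | None = None

    def __post_init__(self) -> None:
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.rsid}: effect and other allele identical")
        if self.pos < 1:
            raise ValueError(f"{self.rsid}: position must be >= 1")
        if self.eaf is not None and not (0.0 < self.eaf < 1.0):
            raise ValueError(f"{self.rsid}: eaf must lie in (0, 1)")

    @property
    def is_palindromic(self) -> bool:
        return frozenset({self.effect_allele, self.other_allele}) in PALINDROMIC_PAIRS

    def flipped(self) -> "Variant":
        """Same variant with the effect/other alleles swapped."""
        return dataclasses.replace(
            self,
            effect_allele=self.other_allele,
            other_allele=self.effect_allele,
            eaf=None if self.eaf is None else 1.0 - self.eaf,
        )


@dataclass(frozen=True)
class AssocRecord:
    """One variant-trait association (beta in SD units or log-odds).

    ``beta_raw`` holds the pre-shrinkage estimate after winner's-curse
    correction; it is ``None`` for unadjusted records. ``region`` is filled
    in by gene-region selection.
    """

    variant: Variant
    beta: float
    se: float
    pval: float | None = None
    n: float | None = None
    source: str = ""
    region: str | None = None
    beta_raw: float | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.beta):
            raise ValueError(f"{self.rsid}: non-finite beta")
        if not (np.isfinite(self.se) and self.se > 0):
            raise ValueError(f"{self.rsid}: se must be positive")
        if self.pval is not None and not (0.0 < self.pval <= 1.0):
            raise ValueError(f"{self.rsid}: pval must lie in (0, 1]")

    @property
    def rsid(self) -> str:
        return self.variant.rsid

    @property
    def z(self) -> float:
        return self.beta / self.se


@dataclass
class SummarySet:
    """Per-variant association records for one trait in one cohort."""

    records: dict[str, AssocRecord]
    trait: str
    trait_type: str = "continuous"  # "continuous" | "binary"
    units: str = ""

    def __post_init__(self) -> None:
        if self.trait_type not in ("continuous", "binary"):
            raise ValueError(f"unknown trait_type {self.trait_type!r}")
        if not self.records:
            raise ValueError(f"SummarySet for {self.trait!r} is empty")
        for rsid, rec in self.records.items():
            if rec.rsid != rsid:
                raise ValueError(f"record keyed {rsid} has rsid {rec.rsid}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[AssocRecord]:
        return iter(self.records.values())

    def __contains__(self, rsid: str) -> bool:
        return rsid in self.records

    def __getitem__(self, rsid: str) -> AssocRecord:
        return self.records[rsid]

    @property
    def rsids(self) -> list[str]:
        return list(self.records)

    @classmethod
    def from_records(
        cls,
        records: Sequence[AssocRecord],
        trait: str,
        trait_type: str = "continuous",
        units: str = "",
    ) -> "SummarySet":
        keyed: dict[str, AssocRecord] = {}
        for rec in records:
            if rec.rsid in keyed:
                raise ValueError(f"duplicate rsid {rec.rsid}")
            keyed[rec.rsid] = rec
        return cls(records=keyed, trait=trait, trait_type=trait_type, units=units)

    def replace_records(self, records: Sequence[AssocRecord]) -> "SummarySet":
        """New set with the same trait metadata but different records."""
        return SummarySet.from_records(
            records, trait=self.trait, trait_type=self.trait_type, units=self.units
        )

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for rec in self:
            v = rec.variant
            rows.append(
                {
                    "rsid": v.rsid,
                    "chr": v.chrom,
                    "pos": v.pos,
                    "ea": v.effect_allele,
                    "oa": v.other_allele,
                    "eaf": v.eaf,
                    "beta": rec.beta,
                    "se": rec.se,
                    "pval": rec.pval,
                    "n": rec.n,
                    "source": rec.source,
                    "region": rec.region,
                    "beta_raw": rec.beta_raw,
                }
            )
        return pd.DataFrame(rows)


@dataclass
class LDMatrix:
    """Signed correlation matrix over named variants.

    The single source of both r (estimation) and r-squared (clumping).
    """

    rsids: list[str]
    r: np.ndarray

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        if self.r.ndim != 2 or self.r.shape[0] != self.r.shape[1]:
            raise ValueError("LD matrix must be square")
        if len(self.rsids) != self.r.shape[0]:
            raise ValueError("rsid count does not match matrix dimension")
        if len(set(self.rsids)) != len(self.rsids):
            raise ValueError("duplicate rsids in LD matrix")
        self._index = {rsid: i for i, rsid in enumerate(self.rsids)}

    def __contains__(self, rsid: str) -> bool:
        return rsid in self._index

    def __len__(self) -> int:
        return len(self.rsids)

    def index(self, rsid: str) -> int:
        return self._index[rsid]

    def subset(self, rsids: Sequence[str]) -> "LDMatrix":
        """Submatrix over ``rsids`` in the given order (no re-repair)."""
        idx = [self._index[r] for r in rsids]
        return LDMatrix(rsids=list(rsids), r=self.r[np.ix_(idx, idx)])

    def r2(self, a: str, b: str) -> float:
        return float(self.r[self._index[a], self._index[b]] ** 2)

    def flip(self, rsids: Sequence[str]) -> "LDMatrix":
        """Negate the rows/columns of ``rsids`` (allele relabelling)."""
        signs = np.ones(len(self.rsids))
        for rsid in rsids:
            signs[self._index[rsid]] = -1.0
        return LDMatrix(rsids=list(self.rsids), r=self.r * np.outer(signs, signs))


@dataclass
class HarmonizedSet:
    """Exposure/outcome records aligned to a common effect allele.

    ``pairs`` maps rsid -> (exposure record, outcome record); every input
    variant not retained appears in ``exclusions`` with a reason.
    """

    pairs: dict[str, tuple[AssocRecord, AssocRecord]]
    exclusions: list[tuple[str, str]] = field(default_factory=list)
    gene_assignment: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def rsids(self) -> list[str]:
        return list(self.pairs)

    def subset(self, rsids: Sequence[str]) -> "HarmonizedSet":
        missing = [r for r in rsids if r not in self.pairs]
        if missing:
            raise KeyError(f"rsids not in harmonized set: {missing}")
        return HarmonizedSet(
            pairs={r: self.pairs[r] for r in rsids},
            exclusions=[],
            gene_assignment={
                r: self.gene_assignment[r] for r in rsids if r in self.gene_assignment
            },
        )

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(gamma, se_gamma, Gamma, se_Gamma) in rsid order."""
        exp = [p[0] for p in self.pairs.values()]
        out = [p[1] for p in self.pairs.values()]
        return (
            np.array([r.beta for r in exp]),
            np.array([r.se for r in exp]),
            np.array([r.beta for r in out]),
            np.array([r.se for r in out]),
        )


@dataclass(frozen=True)
class GeneRegion:
    """A gene region with a symmetric flank, 1-based inclusive bounds."""

    name: str
    chrom: str
    start: int
    end: int
    flank: int = 0

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.name}: start > end")
        if self.flank < 0:
            raise ValueError(f"{self.name}: negative flank")

    def contains(self, chrom: str, pos: int) -> bool:
        return (
            str(chrom) == str(self.chrom)
            and self.start - self.flank <= pos <= self.end + self.flank
        )


@dataclass
class SelectionConfig:
    """Thresholds for instrument selection, clumping and FIQT."""

    p_threshold: float = 5e-5
    clump_r2: float = 0.3
    clump_window_kb: float = 10_000.0
    m_total: int | None = None  # FIQT test count; None -> region variant count

    def __post_init__(self) -> None:
        if not (0.0 < self.p_threshold < 1.0):
            raise ValueError("p_threshold must lie in (0, 1)")
        if not (0.0 < self.clump_r2 <= 1.0):
            raise ValueError("clump_r2 must lie in (0, 1]")
        if self.clump_window_kb <= 0:
            raise ValueError("clump_window_kb must be positive")


@dataclass
class StrengthReport:
    """Instrument-strength diagnostics.

    ``mean_f`` is the LD-decorrelated mean F statistic z' R^-1 z / J;
    ``mean_f_marginal`` the plain mean of squared z-scores; 1/F
    approximates the relative weak-instrument bias of the IVW estimate.
    """

    mean_f: float
    approx_relative_bias: float
    per_variant_z: dict[str, float]
    mean_f_marginal: float


@dataclass
class HetResult:
    """Cochran's Q heterogeneity summary."""

    q: float
    df: int
    i2: float
    p_het: float


@dataclass
class RatioEstimate:
    """Per-variant Wald ratio (log-odds per SD) with first-order SE."""

    rsid: str
    theta: float
    se_theta: float


@dataclass
class MREstimate:
    """Pooled causal slope on the log-odds-per-SD scale."""

    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_variants: int
    q: float = 0.0
    phi: float = 1.0
    label: str = ""

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValueError("se must be positive")
        if not (self.ci_low <= self.beta <= self.ci_high):
            raise ValueError("CI must bracket the point estimate")
        if self.phi < 1.0:
            raise ValueError("overdispersion factor cannot shrink the CI")


@dataclass
class ORRecord:
    """Odds ratio per SD of exposure, with FDR-adjusted p-value."""

    outcome: str
    or_: float
    ci_low: float
    ci_high: float
    pval: float
    p_fdr: float
    n_variants: int
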