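import numpy as np
import pytest

from cismr.models import AssocRecord, LDMatrix, SummarySet, Variant


def make_variant(rsid="rs1", chrom="15", pos=75_000_000, ea="C", oa="T", eaf=0.3):
    return Variant(rsid=rsid, chrom=chrom, pos=pos, effect_allele=ea,
                   other_allele=oa, eaf=eaf)


def make_record(rsid="rs1", beta=0.1, se=0.02, pval=None, source="x", **variant_kw):
    from scipy.stats import norm

    if pval is None:
        pval = max(float(2 * norm.sf(abs(beta / se))), 1e-300)
    return AssocRecord(
        variant=make_variant(rsid=rsid, **variant_kw),
        beta=beta, se=se, pval=pval, source=source,
    )


def make_set(records, trait="exposure", trait_type="continuous"):
    return SummarySet.from_records(records, trait=trait, trait_type=trait_type)


def random_correlation(rng, n):
    """A random well-conditioned correlation matrix."""
    a = rng.standard_normal((n, n + 3))
    c = a @ a.T + n * np.eye(n)
    d = np.sqrt(np.diag(c))
    r = c / np.outer(d, d)
    np.fill_diagonal(r, 1.0)
    return r


@pytest.fixture
def rng():
    return np.random.default_rng(20230808)


@pytest.fixture
def identity_ld():
    def _make(rsids):
        return LDMatrix(rsids=list(rsids), r=np.eye(len(rsids)))

    return _make
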