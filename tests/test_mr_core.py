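"""Wald ratios and the correlated-variant IVW estimator with its sensitivity suite."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cismr.models import AssocRecord, HarmonizedSet, LDMatrix
from cismr.mr_core import (
    correlated_ivw,
    lead_snp_analysis,
    leave_one_out,
    per_gene_estimates,
    wald_ratio,
)

from conftest import make_record, make_variant, random_correlation


def _hset(gamma, se_g, Gamma, se_G, chroms=None, regions=None):
    pairs = {}
    assignment = {}
    for j in range(len(gamma)):
        rsid = f"rs{j}"
        chrom = (chroms or ["15"] * len(gamma))[j]
        exp = make_record(rsid, beta=gamma[j], se=se_g[j], chrom=chrom,
                          pos=75_000_000 + 1000 * j, source="exp")
        out = make_record(rsid, beta=Gamma[j], se=se_G[j], chrom=chrom,
                          pos=75_000_000 + 1000 * j, source="out")
        pairs[rsid] = (exp, out)
        if regions:
            assignment[rsid] = regions[j]
    return HarmonizedSet(pairs=pairs, gene_assignment=assignment)


def _independent_ivw(gamma, Gamma, se_G):
    """Oracle: inverse-variance-weighted mean of Wald ratios, first-order weights."""
    theta = np.asarray(Gamma) / np.asarray(gamma)
    w = (np.asarray(gamma) / np.asarray(se_G)) ** 2
    beta = float(np.sum(w * theta) / np.sum(w))
    return beta, float(np.sum(w) ** -0.5)


class TestWaldRatio:
    def test_zero_outcome_beta_gives_zero_ratio(self):
        est = wald_ratio(0.2, 0.02, 0.0, 0.01, rsid="rs1")
        assert est.theta == 0.0
        assert est.se_theta == pytest.approx(0.05)

    def test_hand_arithmetic(self):
        est = wald_ratio(0.2, 0.02, 0.02, 0.01)
        assert est.theta == pytest.approx(0.1)
        assert est.se_theta == pytest.approx(0.05)

    def test_zero_exposure_beta_raises(self):
        with pytest.raises(ZeroDivisionError):
            wald_ratio(0.0, 0.02, 0.02, 0.01)

    def test_negative_exposure_beta_keeps_se_positive(self):
        est = wald_ratio(-0.2, 0.02, 0.02, 0.01)
        assert est.theta == pytest.approx(-0.1)
        assert est.se_theta == pytest.approx(0.05)


class TestCorrelatedIVW:
    def test_single_variant_reduces_to_wald_ratio(self):
        h = _hset([0.2], [0.02], [0.02], [0.01])
        est = correlated_ivw(h, LDMatrix(rsids=["rs0"], r=np.eye(1)))
        ref = wald_ratio(0.2, 0.02, 0.02, 0.01)
        assert est.beta == pytest.approx(ref.theta, rel=1e-12)
        assert est.se == pytest.approx(ref.se_theta, rel=1e-12)
        assert est.phi == 1.0

    def test_two_variant_gls_by_hand(self):
        # both ratios exactly 0.1 so Q = 0, phi = 1, se = sqrt(v) = 0.05
        h = _hset([0.2, 0.1], [0.02, 0.02], [0.02, 0.01], [0.01, 0.01])
        ld = LDMatrix(rsids=["rs0", "rs1"], r=np.array([[1.0, 0.5], [0.5, 1.0]]))
        est = correlated_ivw(h, ld)
        assert est.beta == pytest.approx(0.1, rel=1e-12)
        assert est.q == pytest.approx(0.0, abs=1e-12)
        assert est.phi == 1.0
        assert est.se == pytest.approx(0.05, rel=1e-12)

    @settings(max_examples=60, deadline=None)
    @given(st.integers(min_value=0, max_value=100_000),
           st.integers(min_value=2, max_value=8))
    def test_identity_ld_matches_independent_ivw_oracle(self, seed, J):
        rng = np.random.default_rng(seed)
        gamma = rng.uniform(0.05, 0.3, J) * rng.choice([-1, 1], J)
        se_g = rng.uniform(0.005, 0.03, J)
        Gamma = rng.normal(0, 0.05, J)
        se_G = rng.uniform(0.005, 0.05, J)
        h = _hset(gamma, se_g, Gamma, se_G)
        est = correlated_ivw(h, LDMatrix(rsids=h.rsids, r=np.eye(J)))
        beta_o, se_o = _independent_ivw(gamma, Gamma, se_G)
        assert est.beta == pytest.approx(beta_o, rel=1e-10)
        theta = Gamma / gamma
        w = (gamma / se_G) ** 2
        q_o = float(np.sum(w * (theta - beta_o) ** 2))
        assert est.q == pytest.approx(q_o, rel=1e-8, abs=1e-12)
        phi_o = max(1.0, q_o / (J - 1))
        assert est.se == pytest.approx(se_o * np.sqrt(phi_o), rel=1e-10)

    @settings(max_examples=40, deadline=None)
    @given(st.integers(min_value=0, max_value=100_000),
           st.floats(min_value=0.1, max_value=10.0))
    def test_scale_equivariance_in_exposure(self, seed, c):
        rng = np.random.default_rng(seed)
        J = 5
        gamma = rng.uniform(0.05, 0.3, J)
        se_g = rng.uniform(0.005, 0.03, J)
        Gamma = rng.normal(0, 0.05, J)
        se_G = rng.uniform(0.005, 0.05, J)
        ld = LDMatrix(rsids=[f"rs{j}" for j in range(J)],
                      r=random_correlation(rng, J))
        est1 = correlated_ivw(_hset(gamma, se_g, Gamma, se_G), ld)
        est2 = correlated_ivw(_hset(c * gamma, c * se_g, Gamma, se_G), ld)
        assert est2.beta == pytest.approx(est1.beta / c, rel=1e-9)
        assert est2.se == pytest.approx(est1.se / c, rel=1e-9)

    def test_allele_relabelling_invariance(self, rng):
        J = 4
        gamma = rng.uniform(0.05, 0.3, J)
        se_g = rng.uniform(0.005, 0.03, J)
        Gamma = rng.normal(0, 0.05, J)
        se_G = rng.uniform(0.005, 0.05, J)
        ld = LDMatrix(rsids=[f"rs{j}" for j in range(J)],
                      r=random_correlation(rng, J))
        base = correlated_ivw(_hset(gamma, se_g, Gamma, se_G), ld)
        # flip variant 2: both betas change sign, LD row/column sign flips
        gamma2, Gamma2 = gamma.copy(), Gamma.copy()
        gamma2[2] *= -1
        Gamma2[2] *= -1
        flipped = correlated_ivw(_hset(gamma2, se_g, Gamma2, se_G),
                                 ld.flip(["rs2"]))
        assert flipped.beta == pytest.approx(base.beta, rel=1e-10)
        assert flipped.se == pytest.approx(base.se, rel=1e-10)

    def test_exact_proportionality_gives_phi_one(self, rng):
        J = 6
        gamma = rng.uniform(0.05, 0.3, J)
        Gamma = 0.07 * gamma
        ld = LDMatrix(rsids=[f"rs{j}" for j in range(J)],
                      r=random_correlation(rng, J))
        est = correlated_ivw(
            _hset(gamma, [0.02] * J, Gamma, rng.uniform(0.005, 0.05, J)), ld
        )
        assert est.beta == pytest.approx(0.07, rel=1e-10)
        assert est.q == pytest.approx(0.0, abs=1e-10)
        assert est.phi == 1.0

    def test_empty_set_raises(self):
        with pytest.raises(ValueError):
            correlated_ivw(HarmonizedSet(pairs={}), LDMatrix(rsids=[], r=np.eye(0)))


class TestLeaveOneOut:
    def test_two_variants_reduce_to_single_wald_ratios(self):
        h = _hset([0.2, 0.1], [0.02, 0.02], [0.02, 0.03], [0.01, 0.01])
        ld = LDMatrix(rsids=["rs0", "rs1"], r=np.array([[1.0, 0.4], [0.4, 1.0]]))
        results = leave_one_out(h, ld)
        assert [r.label for r in results] == ["rs0", "rs1"]
        # omitting rs0 leaves rs1's ratio 0.03 / 0.1 = 0.3
        assert results[0].beta == pytest.approx(0.3, rel=1e-12)
        assert results[1].beta == pytest.approx(0.1, rel=1e-12)

    def test_homogeneous_ratios_leave_estimate_unchanged(self, rng):
        J = 5
        gamma = rng.uniform(0.05, 0.3, J)
        ld = LDMatrix(rsids=[f"rs{j}" for j in range(J)],
                      r=random_correlation(rng, J))
        h = _hset(gamma, [0.02] * J, 0.1 * gamma, rng.uniform(0.01, 0.03, J))
        full = correlated_ivw(h, ld)
        for res in leave_one_out(h, ld):
            assert res.beta == pytest.approx(full.beta, rel=1e-9)

    def test_omitting_planted_outlier_moves_estimate_to_common_ratio(self):
        gamma = np.array([0.2, 0.15, 0.25, 0.2])
        Gamma = 0.1 * gamma
        Gamma[3] += 0.08  # the outlier
        ld = LDMatrix(rsids=[f"rs{j}" for j in range(4)], r=np.eye(4))
        h = _hset(gamma, [0.02] * 4, Gamma, [0.01] * 4)
        full = correlated_ivw(h, ld)
        loo = {r.label: r for r in leave_one_out(h, ld)}
        assert abs(loo["rs3"].beta - 0.1) < abs(full.beta - 0.1)
        assert loo["rs3"].beta == pytest.approx(0.1, rel=1e-9)

    def test_single_variant_raises(self):
        h = _hset([0.2], [0.02], [0.02], [0.01])
        with pytest.raises(ValueError):
            leave_one_out(h, LDMatrix(rsids=["rs0"], r=np.eye(1)))


class TestPerGeneEstimates:
    def test_shared_slope_gives_zero_i2(self):
        gamma = np.array([0.2, 0.15, 0.25, 0.2])
        regions = ["AHR", "AHR", "CYP1A2", "CYP1A2"]
        h = _hset(gamma, [0.02] * 4, 0.1 * gamma, [0.01] * 4,
                  chroms=["7", "7", "15", "15"], regions=regions)
        ld = LDMatrix(rsids=h.rsids, r=np.eye(4))
        ests, het = per_gene_estimates(h, ld)
        assert set(ests) == {"AHR", "CYP1A2"}
        assert ests["AHR"].beta == pytest.approx(0.1, rel=1e-10)
        assert het.q == pytest.approx(0.0, abs=1e-10)
        assert het.i2 == 0.0

    def test_offset_region_produces_heterogeneity(self):
        gamma = np.array([0.2, 0.15, 0.25, 0.2])
        Gamma = 0.1 * gamma
        Gamma[2:] += 0.05 * gamma[2:]  # CYP1A2 slope 0.15 instead of 0.1
        h = _hset(gamma, [0.02] * 4, Gamma, [0.01] * 4,
                  chroms=["7", "7", "15", "15"],
                  regions=["AHR", "AHR", "CYP1A2", "CYP1A2"])
        ld = LDMatrix(rsids=h.rsids, r=np.eye(4))
        _, het = per_gene_estimates(h, ld)
        assert het.q > 0

    def test_single_region_raises(self):
        h = _hset([0.2, 0.1], [0.02] * 2, [0.02, 0.01], [0.01] * 2,
                  regions=["AHR", "AHR"])
        with pytest.raises(ValueError):
            per_gene_estimates(h, LDMatrix(rsids=h.rsids, r=np.eye(2)))


class TestLeadSnpAnalysis:
    def test_all_variants_as_leads_equals_full_estimate(self, rng):
        J = 4
        gamma = rng.uniform(0.05, 0.3, J)
        ld = LDMatrix(rsids=[f"rs{j}" for j in range(J)],
                      r=random_correlation(rng, J))
        h = _hset(gamma, [0.02] * J, 0.1 * gamma + rng.normal(0, 0.005, J),
                  rng.uniform(0.01, 0.03, J))
        full = correlated_ivw(h, ld)
        lead = lead_snp_analysis(h, ld, h.rsids)
        assert lead.beta == pytest.approx(full.beta, rel=1e-12)

    def test_cross_chromosome_leads_equal_independent_ivw(self):
        gamma = [0.2, 0.15]
        Gamma = [0.025, 0.012]
        se_G = [0.01, 0.012]
        h = _hset(gamma, [0.02] * 2, Gamma, se_G, chroms=["7", "15"])
        ld = LDMatrix(rsids=h.rsids, r=np.eye(2))
        lead = lead_snp_analysis(h, ld, h.rsids)
        beta_o, se_o = _independent_ivw(gamma, Gamma, se_G)
        assert lead.beta == pytest.approx(beta_o, rel=1e-12)

    def test_lead_only_ci_is_wider_on_dense_instruments(self):
        from cismr.synthetic_data import SimConfig, simulate_region, run_sim_pipeline
        from cismr.gwas_io import harmonize
        from cismr.meta import fixed_effect_meta
        from cismr.models import HarmonizedSet

        cfg = SimConfig(seed=5)
        exposure, outcomes, ld, truth = simulate_region(cfg)
        est, instruments = run_sim_pipeline(exposure, outcomes, ld, cfg)
        hs = [harmonize(instruments, o) for o in outcomes.values()]
        pairs = {
            r: (instruments[r],
                fixed_effect_meta([h.pairs[r][1] for h in hs if r in h.pairs]))
            for r in instruments.rsids
        }
        h = HarmonizedSet(pairs=pairs,
                          gene_assignment={r: instruments[r].region for r in pairs})
        leads = [r for r in truth.lead_rsids.values() if r in h.pairs]
        if len(leads) >= 1 and len(leads) < len(h):
            lead = lead_snp_analysis(h, ld, leads)
            full = correlated_ivw(h, ld)
            assert lead.se > 0
            # less information cannot produce a narrower base variance;
            # compare on the phi-free scale to isolate the information content
            assert lead.se / np.sqrt(lead.phi) >= full.se / np.sqrt(full.phi) * 0.999

    def test_absent_lead_raises(self):
        h = _hset([0.2], [0.02], [0.02], [0.01])
        with pytest.raises(KeyError):
            lead_snp_analysis(h, LDMatrix(rsids=["rs0"], r=np.eye(1)), ["rs99"])
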