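import math

import pytest
from hypothesis import given, settings, strategies as st
from pydantic import ValidationError

from mixsel import (
    IndexWeights,
    MixtureGeneticParams,
    SpeciesGeneticParams,
    derive_components,
    design_heritability,
    load_params,
    sgma_criterion_variance,
    srma_criterion_variance,
)
from mixsel.experiments import default_designs, make_params

ONES = IndexWeights(alpha_1=1.0, alpha_2=1.0)


def _params(**kw):
    defaults = dict(
        species1=SpeciesGeneticParams(var_direct=1.0, var_associate=0.5, rho_va=-0.5),
        species2=SpeciesGeneticParams(var_direct=1.0, var_associate=0.5, rho_va=-0.5),
        var_va_12=0.25,
        var_va_21=0.25,
        rho_va12_va21=-0.5,
        var_plot_error_mixture=2.0,
    )
    defaults.update(kw)
    return MixtureGeneticParams(**defaults)


class TestDeriveComponents:
    def test_gma_variance_from_correlation(self):
        # sigma_g^2 = 1 + 0.5 + 2*(-0.5)*sqrt(0.5)
        d = derive_components(_params())
        assert d.var_gma_1 == pytest.approx(1.5 - math.sqrt(0.5), rel=1e-12)

    def test_sma_variance(self):
        # 0.25 + 0.25 + 2*(-0.5)*0.25
        d = derive_components(_params())
        assert d.var_sma == pytest.approx(0.25, rel=1e-12)

    def test_zero_variance_forces_zero_covariance(self):
        sp = SpeciesGeneticParams(var_direct=1.0, var_associate=0.0, rho_va=-0.9)
        p = _params(species1=sp)
        d = derive_components(p)
        assert d.cov_v1_a1 == 0.0
        assert d.var_gma_1 == 1.0

    def test_contribution_components(self):
        d = derive_components(_params())
        assert d.var_Gx1 == pytest.approx(1.0 + 0.5 + 0.25)
        cov = 2 * (-0.5 * math.sqrt(0.5)) + (-0.5 * 0.25)
        assert d.cov_Gx1_Gx2 == pytest.approx(cov, rel=1e-12)
        assert abs(d.cov_Gx1_Gx2) <= math.sqrt(d.var_Gx1 * d.var_Gx2)


class TestCriterionVariances:
    def test_srma_worked_value(self):
        expected = 2 * (1.5 - math.sqrt(0.5)) + 0.25 + 2.0 / 3.0
        got = srma_criterion_variance(_params(), ONES, replicates=3)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_unit_weights_reduce_to_performance_variance(self):
        p = _params()
        d = derive_components(p)
        got = srma_criterion_variance(p, ONES, replicates=3)
        assert got == pytest.approx(
            d.var_gma_1 + d.var_gma_2 + d.var_sma + 2.0 / 3.0, rel=1e-12
        )

    @pytest.mark.parametrize("c", [0.5, 2.0, 7.3])
    def test_quadratic_scaling_in_weights(self, c):
        p = _params()
        base = srma_criterion_variance(p, ONES, 3)
        scaled = srma_criterion_variance(
            p, IndexWeights(alpha_1=c, alpha_2=c), 3
        )
        assert scaled == pytest.approx(c * c * base, rel=1e-12)

    def test_sgma_worked_value(self):
        got = sgma_criterion_variance(_params(), ONES, 3, focal_species=1)
        assert got == pytest.approx(1.5 - math.sqrt(0.5) + 2.0 / 3.0, rel=1e-12)

    def test_sgma_error_term_vanishes_with_many_replicates(self):
        p = _params()
        got = sgma_criterion_variance(p, ONES, 10**9, 1)
        assert got == pytest.approx(1.5 - math.sqrt(0.5), rel=1e-6)

    def test_sgma_own_contribution_index(self):
        # weights (1, 0): variance of the family-mean own contribution
        p = _params()
        w = IndexWeights(alpha_1=1.0, alpha_2=0.0)
        ve1, _, _ = p.error_split()
        assert sgma_criterion_variance(p, w, 3, 1) == pytest.approx(
            1.0 + ve1 / 3.0, rel=1e-12
        )

    def test_degenerate_model_rejected(self):
        p = _params(
            species1=SpeciesGeneticParams(var_direct=0.0, var_associate=0.0),
            species2=SpeciesGeneticParams(var_direct=0.0, var_associate=0.0),
            var_va_12=0.0,
            var_va_21=0.0,
            var_plot_error_mixture=0.0,
        )
        with pytest.raises(ValueError, match="degenerate"):
            srma_criterion_variance(p, ONES, 3)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(
        sv=st.floats(0.1, 5.0),
        sa=st.floats(0.0, 5.0),
        rho=st.floats(-1.0, 1.0),
        sva=st.floats(0.0, 2.0),
        rho12=st.floats(-1.0, 1.0),
        eps=st.floats(0.0, 10.0),
        m=st.integers(1, 10),
    )
    def test_unit_weight_identity_holds_generally(
        self, sv, sa, rho, sva, rho12, eps, m
    ):
        sp = SpeciesGeneticParams(var_direct=sv, var_associate=sa, rho_va=rho)
        p = MixtureGeneticParams(
            species1=sp,
            species2=sp,
            var_va_12=sva,
            var_va_21=sva,
            rho_va12_va21=rho12,
            var_plot_error_mixture=eps,
        )
        d = derive_components(p)
        expected = d.var_gma_1 + d.var_gma_2 + d.var_sma + eps / m
        if expected <= 0:
            return
        got = srma_criterion_variance(p, ONES, m)
        assert got == pytest.approx(expected, rel=1e-12)


class TestDesignHeritability:
    def test_worked_example_two_schemes(self):
        p = make_params(0.5, 0.5, -0.5)
        designs = default_designs()
        assert round(design_heritability(p, designs["srma"], "srma"), 2) == 0.73
        assert round(design_heritability(p, designs["sgma"], "sgma"), 2) == 0.54

    def test_no_plot_error_gives_unit_heritability(self):
        p = make_params(0.5, 0.5, -0.5, var_plot_error=0.0)
        designs = default_designs()
        assert design_heritability(p, designs["srma"], "srma") == pytest.approx(1.0)
        assert design_heritability(p, designs["sgma"], "sgma") == pytest.approx(1.0)


class TestValidation:
    def test_negative_variance_rejected(self):
        with pytest.raises(ValidationError, match="var_direct"):
            SpeciesGeneticParams(var_direct=-1.0, var_associate=0.5)

    def test_out_of_range_correlation_rejected(self):
        with pytest.raises(ValidationError, match="rho_va"):
            SpeciesGeneticParams(var_direct=1.0, var_associate=0.5, rho_va=1.5)

    def test_inconsistent_error_split_rejected(self):
        with pytest.raises(ValidationError, match="error split"):
            _params(var_e1=2.0, var_e2=2.0, rho_e1_e2=0.5)

    def test_partial_error_split_rejected(self):
        with pytest.raises(ValidationError, match="together"):
            _params(var_e1=2.0)

    def test_default_error_split(self):
        ve1, ve2, cov = _params().error_split()
        assert (ve1, ve2) == (2.0, 2.0)
        assert cov == pytest.approx(-1.0)

    def test_unknown_config_key_rejected(self, tmp_path):
        cfg = tmp_path / "p.json"
        cfg.write_text(
            '{"species1": {"var_direct": 1, "var_associate": 0.5},'
            ' "species2": {"var_direct": 1, "var_associate": 0.5},'
            ' "rho_va21_va12": -0.5}'
        )
        with pytest.raises(ValidationError, match="rho_va21_va12"):
            load_params(cfg)

    def test_load_params_roundtrip(self, tmp_path):
        cfg = tmp_path / "p.json"
        cfg.write_text(
            '{"species1": {"var_direct": 1, "var_associate": 0.5, "rho_va": -0.5},'
            ' "species2": {"var_direct": 1, "var_associate": 0.5, "rho_va": -0.5},'
            ' "var_plot_error_mixture": 2.0,'
            ' "design": {"total_plots": 900, "replicates": 3, "selection_rate": 0.1}}'
        )
        p = load_params(cfg)
        assert p.species1.var_associate == 0.5
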