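import math

import pytest

from mixsel import (
    IndexWeights,
    MixtureGeneticParams,
    ResponseRatioTarget,
    SpeciesGeneticParams,
    derive_components,
    selection_intensity,
    solve_srma_index,
    srma_criterion_variance,
    srma_responses_after,
    srma_responses_before,
)
from mixsel.experiments import make_params


class TestResponsesAfter:
    def test_symmetric_parameters_give_equal_contributions(
        self, worked_params, designs, ones
    ):
        r = srma_responses_after(worked_params, designs["srma"], ones)
        assert r.dG_x1 == pytest.approx(r.dG_x2, rel=1e-12)
        assert r.dG_total == pytest.approx(r.dG_x1 + r.dG_x2, rel=1e-12)

    def test_collapses_to_two_trait_direct_selection(self, designs, ones):
        # no associate effects, no interactions: classic direct response
        sp = SpeciesGeneticParams(var_direct=1.0, var_associate=0.0)
        p = MixtureGeneticParams(
            species1=sp, species2=sp, var_plot_error_mixture=2.0
        )
        r = srma_responses_after(p, designs["srma"], ones)
        i = selection_intensity(0.10)
        sigma = math.sqrt(2.0 + 2.0 / 3.0)
        assert r.dG_total == pytest.approx(i * 2.0 / sigma, rel=1e-12)

    def test_interactions_dilute_but_do_not_contribute(self, designs, ones):
        # adding interaction variance inflates sigma_I, shrinking the response
        lean = make_params(0.5, 0.5, 0.0, interaction_rule=False)
        rich = make_params(0.5, 0.5, 0.0, interaction_rule=True)
        r_lean = srma_responses_after(lean, designs["srma"], ones)
        r_rich = srma_responses_after(rich, designs["srma"], ones)
        assert r_rich.dG_total < r_lean.dG_total
        ratio = srma_criterion_variance(lean, ones, 3) / srma_criterion_variance(
            rich, ones, 3
        )
        assert r_rich.dG_total == pytest.approx(
            r_lean.dG_total * math.sqrt(ratio), rel=1e-12
        )


class TestResponsesBefore:
    def test_gap_identity_under_plain_selection(
        self, worked_params, designs, ones
    ):
        # (before - after) mixture response = i * sigma_d^2 / sigma_y
        before = srma_responses_before(worked_params, designs["srma"], ones)
        after = srma_responses_after(worked_params, designs["srma"], ones)
        i = selection_intensity(0.10)
        d = derive_components(worked_params)
        sigma_y = math.sqrt(srma_criterion_variance(worked_params, ones, 3))
        assert before.dG_total - after.dG_total == pytest.approx(
            i * d.var_sma / sigma_y, rel=1e-12
        )

    def test_per_species_gap_identities(self, designs, ones):
        p = make_params(0.5, 0.1, -0.5)
        before = srma_responses_before(p, designs["srma"], ones)
        after = srma_responses_after(p, designs["srma"], ones)
        i = selection_intensity(0.10)
        d = derive_components(p)
        sigma_y = math.sqrt(srma_criterion_variance(p, ones, 3))
        assert before.dG_x1 - after.dG_x1 == pytest.approx(
            i * (p.var_va_12 + d.cov_va12_va21) / sigma_y, rel=1e-12
        )
        assert before.dG_x2 - after.dG_x2 == pytest.approx(
            i * (p.var_va_21 + d.cov_va12_va21) / sigma_y, rel=1e-12
        )

    def test_no_interactions_means_no_gap(self, designs, ones):
        p = make_params(0.5, 0.5, -0.5, interaction_rule=False)
        before = srma_responses_before(p, designs["srma"], ones)
        after = srma_responses_after(p, designs["srma"], ones)
        assert before.dG_x1 == pytest.approx(after.dG_x1, rel=1e-12)
        assert before.dG_x2 == pytest.approx(after.dG_x2, rel=1e-12)

    def test_symmetric_parameters(self, worked_params, designs, ones):
        r = srma_responses_before(worked_params, designs["srma"], ones)
        assert r.dG_x1 == pytest.approx(r.dG_x2, rel=1e-12)


class TestScaleInvariance:
    @pytest.mark.parametrize("c", [0.1, 2.0, 13.7])
    def test_joint_positive_rescaling_cancels(self, worked_params, designs, c):
        w = IndexWeights(alpha_1=1.0, alpha_2=0.4)
        cw = IndexWeights(alpha_1=c, alpha_2=0.4 * c)
        for fn in (srma_responses_after, srma_responses_before):
            base = fn(worked_params, designs["srma"], w)
            scaled = fn(worked_params, designs["srma"], cw)
            assert scaled.dG_x1 == pytest.approx(base.dG_x1, rel=1e-12)
            assert scaled.dG_x2 == pytest.approx(base.dG_x2, rel=1e-12)


class TestIndexSolver:
    def test_diagonal_system(self, designs):
        # uncorrelated contributions: weights are k / variance
        sp = SpeciesGeneticParams(var_direct=1.0, var_associate=0.5)
        p = MixtureGeneticParams(
            species1=sp,
            species2=SpeciesGeneticParams(var_direct=2.0, var_associate=0.5),
            var_plot_error_mixture=2.0,
        )
        d = derive_components(p)
        w = solve_srma_index(p, ResponseRatioTarget(k1=1.0, k2=2.0))
        assert w.alpha_1 == pytest.approx(1.0 / d.var_Gx1, rel=1e-9)
        assert w.alpha_2 == pytest.approx(2.0 / d.var_Gx2, rel=1e-9)

    def test_round_trip_ratio(self, designs):
        # tuned index meets the before-recombination target ratio exactly
        p = make_params(0.5, 0.1, -0.5, rho_e=-0.5)
        target = ResponseRatioTarget(k1=1.0, k2=1.0)
        w = solve_srma_index(p, target)
        before = srma_responses_before(p, designs["srma"], w)
        assert before.dG_x1 / before.dG_x2 == pytest.approx(1.0, rel=1e-9)
        after = srma_responses_after(p, designs["srma"], w)
        # interactions asymmetric: after-recombination ratio departs slightly
        assert after.dG_x1 / after.dG_x2 != pytest.approx(1.0, rel=1e-9)

    def test_symmetric_target_gives_equal_weights(self, worked_params):
        w = solve_srma_index(worked_params, ResponseRatioTarget(k1=1.0, k2=1.0))
        assert w.alpha_1 == pytest.approx(w.alpha_2, rel=1e-12)

    def test_symmetric_interactions_keep_after_ratio_exact(self, designs):
        # equal interaction variances (symmetric model): the transmission gap
        # is the same for both species, so the after ratio stays 1
        p = make_params(0.5, 0.5, -0.25, rho_e=-0.5)
        w = solve_srma_index(p, ResponseRatioTarget(k1=1.0, k2=1.0))
        after = srma_responses_after(p, designs["srma"], w)
        assert after.dG_x1 / after.dG_x2 == pytest.approx(1.0, rel=1e-9)

    def test_singular_system_rejected(self):
        # perfectly correlated contributions: rho = 1 everywhere, matched
        # variances make the 2x2 covariance matrix rank one
        sp = SpeciesGeneticParams(var_direct=1.0, var_associate=1.0, rho_va=1.0)
        p = MixtureGeneticParams(
            species1=sp,
            species2=sp,
            var_va_12=0.0,
            var_va_21=0.0,
            var_plot_error_mixture=2.0,
        )
        with pytest.raises(ValueError, match="singular|unsolvable"):
            solve_srma_index(p, ResponseRatioTarget(k1=1.0, k2=1.0))

    def test_zero_target_rejected(self):
        with pytest.raises(Exception):
            ResponseRatioTarget(k1=0.0, k2=0.0)
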