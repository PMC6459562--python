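"""Sigma rule, critical ratios, pairwise reduction and coefficient counts."""

import math

import numpy as np
import pytest

from edgegames import (
    DegreeProfile,
    additive_tensor,
    coefficient_count,
    critical_dol,
    critical_ratio,
    dol_tensor,
    marginal_sigma,
    ndol_tensor,
    pairwise_condition,
    pairwise_tensor,
    per_s_tensor,
    sigma_rule_lhs,
    sigma_table,
    verdict,
    volunteers_table,
    weighted_tables,
)


def donation_matrices(B, C):
    return [(b - c, -c, b, 0.0) for b, c in zip(B, C)]


class TestSigmaRuleLhs:
    def test_constant_game_is_neutral(self, profile32):
        t = pairwise_tensor([(1.0, 1.0, 1.0, 1.0)] * 2, profile32)
        table = sigma_table(profile32)
        assert sigma_rule_lhs(table, t) == pytest.approx(0.0, abs=1e-12)

    def test_donation_neutral_at_mean_ratio_k(self, profile32):
        # Bbar/Cbar = k = 5 with unequal per-type entries
        B, C = [7.0, 2.0], [1.2, 0.7]
        k = 5
        scale = k * sum(g * c for g, c in zip((3, 2), C)) / sum(
            g * b for g, b in zip((3, 2), B)
        )
        t = pairwise_tensor(donation_matrices([b * scale for b in B], C), profile32)
        assert sigma_rule_lhs(sigma_table(profile32), t) == pytest.approx(
            0.0, abs=1e-9
        )

    def test_volunteers_dilemma_closed_form(self, profile33):
        """lhs of n identical VDs equals n (Bv sigma~_g - Cv)."""
        Bv, Cv = 4.0, 1.0
        t = additive_tensor([volunteers_table(3, Bv, Cv)] * 2, profile33)
        table = sigma_table(profile33)
        tilde_g = marginal_sigma(table, mode="first")[-1]
        assert sigma_rule_lhs(table, t) == pytest.approx(
            2 * (Bv * tilde_g - Cv), abs=1e-12
        )

    def test_profile_mismatch(self, profile32, profile33):
        t = additive_tensor([volunteers_table(3, 2, 1)] * 2, profile33)
        with pytest.raises(ValueError, match="mismatch"):
            sigma_rule_lhs(sigma_table(profile32), t)


class TestVerdict:
    def test_sign_and_linearity_in_omega(self, profile33, vd_mixture_tensor):
        table = sigma_table(profile33)
        v1 = verdict(table, vd_mixture_tensor, 0.01)
        v2 = verdict(table, vd_mixture_tensor, 0.02)
        assert v1.favored == ("A" if v1.lhs > 0 else "B")
        assert v2.predicted_difference == pytest.approx(
            2 * v1.predicted_difference
        )

    def test_vd_above_critical_favors_A(self, profile33):
        table = sigma_table(profile33)
        tilde_g = marginal_sigma(table, mode="first")[-1]
        crit = 1.0 / tilde_g
        above = additive_tensor([volunteers_table(3, 1.1 * crit, 1.0)] * 2, profile33)
        below = additive_tensor([volunteers_table(3, 0.9 * crit, 1.0)] * 2, profile33)
        assert verdict(table, above, 0.01).favored == "A"
        assert verdict(table, below, 0.01).favored == "B"

    def test_rejects_nonpositive_omega(self, profile33, vd_mixture_tensor):
        with pytest.raises(ValueError):
            verdict(sigma_table(profile33), vd_mixture_tensor, 0.0)


class TestCriticalRatio:
    def test_volunteers_dilemma_inverse_marginal(self, profile33):
        table = sigma_table(profile33)
        fam = lambda B: additive_tensor(
            [volunteers_table(3, B, 1.0)] * 2, profile33
        )
        tilde_g = marginal_sigma(table, mode="first")[-1]
        assert critical_ratio(fam, table) == pytest.approx(1.0 / tilde_g, abs=1e-9)

    def test_root_resubstitution(self, profile32):
        table = sigma_table(profile32)
        fam = lambda B: dol_tensor(profile32, B, 1.0, accumulative=False)
        star = critical_ratio(fam, table)
        assert sigma_rule_lhs(table, fam(star)) == pytest.approx(0.0, abs=1e-9)

    def test_benefit_independent_family_rejected(self, profile32):
        table = sigma_table(profile32)
        fam = lambda B: pairwise_tensor([(1, 1, 1, 1)] * 2, profile32)
        with pytest.raises(ValueError, match="independent"):
            critical_ratio(fam, table)


class TestCriticalDol:
    @pytest.mark.parametrize("accumulative", [True, False])
    def test_formula_agrees_with_tensor_route(self, accumulative):
        p = DegreeProfile((3, 5))
        table = sigma_table(p)
        via_formula = critical_dol(8, 3, 5, True, accumulative)
        via_tensor = critical_ratio(
            lambda B: dol_tensor(p, B, 1.0, accumulative), table
        )
        assert via_formula == pytest.approx(via_tensor, abs=1e-9)

    @pytest.mark.parametrize("accumulative", [True, False])
    def test_single_threshold_agrees_with_tensor_route(self, accumulative):
        p = DegreeProfile((8,))
        table = sigma_table(p)
        via_formula = critical_dol(8, labor_division=False, accumulative=accumulative)
        via_tensor = critical_ratio(
            lambda B: per_s_tensor(*ndol_tensor(8, B, 1.0, accumulative), p), table
        )
        assert via_formula == pytest.approx(via_tensor, abs=1e-9)

    def test_requires_consistent_roles(self):
        with pytest.raises(ValueError):
            critical_dol(8, 3, 4, labor_division=True)


class TestPairwiseReduction:
    def test_all_equal_entries_neutral(self, profile32):
        v = pairwise_condition([(2.0, 2.0, 2.0, 2.0)] * 2, profile32)
        assert v.favored == "neutral"

    def test_donation_threshold_at_k(self):
        p = DegreeProfile((3, 1))
        above = pairwise_condition(donation_matrices([4.5, 4.5], [1, 1]), p)
        below = pairwise_condition(donation_matrices([3.5, 3.5], [1, 1]), p)
        assert above.favored == "A" and below.favored == "B"

    @pytest.mark.parametrize("g", [(2, 1), (3, 1), (2, 3)])
    def test_exact_proportionality_to_full_rule(self, g, rng):
        """Full sigma-rule lhs = (k-1)/2 times the simplified condition."""
        p = DegreeProfile(g)
        table = sigma_table(p)
        for _ in range(25):
            mats = [tuple(rng.normal(size=4)) for _ in range(p.n)]
            full = sigma_rule_lhs(table, pairwise_tensor(mats, p))
            simple = pairwise_condition(mats, p)
            assert full == pytest.approx(simple.lhs * (p.k - 1) / 2, abs=1e-9)
            assert simple.predicted_difference == pytest.approx(
                simple.omega * full, abs=1e-12
            )


class TestCoefficientCount:
    def test_counts(self):
        assert coefficient_count(DegreeProfile((6,)), "general") == 7  # k+1
        assert coefficient_count(DegreeProfile((3, 3)), "general") == math.comb(5, 2)
        assert coefficient_count(DegreeProfile((3, 2, 1)), "general") == 4 * 3 * 2
        assert coefficient_count(DegreeProfile((3, 2, 1)), "diverse-additive") == 9
        assert coefficient_count(DegreeProfile((3, 3)), "diverse-additive") == 4
        # repeated sizes collapse in the additive count
        assert coefficient_count(DegreeProfile((2, 2, 3)), "diverse-additive") == 7


class TestWeightInvariance:
    def test_critical_ratio_unaffected_by_weights(self, profile33, rng):
        table = sigma_table(profile33)
        ref = critical_ratio(
            lambda B: additive_tensor([volunteers_table(3, B, 1.0)] * 2, profile33),
            table,
        )
        for _ in range(5):
            zeta = tuple(rng.uniform(0.2, 5.0, size=2))
            fam = lambda B, z=zeta: additive_tensor(
                weighted_tables([volunteers_table(3, B, 1.0)] * 2, z), profile33
            )
            assert critical_ratio(fam, table) == pytest.approx(ref, abs=1e-9)

    def test_lhs_scales_with_mean_weight(self, profile33):
        table = sigma_table(profile33)
        base = [volunteers_table(3, 5.0, 1.0)] * 2
        l1 = sigma_rule_lhs(table, additive_tensor(base, profile33))
        l2 = sigma_rule_lhs(
            table, additive_tensor(weighted_tables(base, (2.0, 2.0)), profile33)
        )
        assert l2 == pytest.approx(2 * l1, abs=1e-12)
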