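import math

import numpy as np
import pytest

from plastburst.core_io import FamilyCounts, parse_newick
from plastburst.turnover import (
    ModelSelection,
    TurnoverFit,
    TurnoverRates,
    ancestral_marginals,
    classify_family,
    compare_models,
    family_loglik,
    fit_turnover,
    root_prior_vector,
    transition_matrix,
    transition_prob,
)
from plastburst.synthetic import sim_family_counts

from _oracles import enumerate_loglik_3leaf, expm_transition


class TestTransitionLaw:
    def test_zero_start_zero_gain_stays_zero(self):
        assert transition_prob(0, 0, 5.0, 0.0, 1.0) == 1.0

    def test_pure_death_half_life(self):
        assert abs(transition_prob(1, 0, math.log(2), 0.0, 1.0) - 0.5) < 1e-12

    def test_matches_generator_exponential(self):
        p = transition_prob(2, 1, 1.0, 0.3, 0.5)
        assert abs(p - expm_transition(2, 1, 1.0, 0.3, 0.5)) < 1e-10

    def test_negative_arguments_rejected(self):
        with pytest.raises(ValueError):
            transition_prob(1, 1, -1.0, 0.1, 0.1)
        with pytest.raises(ValueError):
            transition_prob(1, 1, 1.0, 0.1, 0.0)

    @pytest.mark.parametrize("gamma,delta", [(0.0, 1.0), (0.3, 0.5), (2.0, 0.8)])
    @pytest.mark.parametrize("t", [0.0, 0.1, 1.0, 10.0])
    def test_rows_sum_to_one(self, gamma, delta, t):
        for i in range(0, 11, 2):
            cap = i + 40 + int(10 * gamma / delta * t if delta * t < 1 else 10 * gamma / delta)
            total = sum(transition_prob(i, j, t, gamma, delta) for j in range(cap + 1))
            assert abs(total - 1.0) < 1e-9

    def test_long_time_limit_is_stationary_poisson(self):
        gamma, delta = 0.4, 0.8
        t = 500.0 / delta
        lam = gamma / delta
        for i in (0, 3, 7):
            for j in range(12):
                pois = math.exp(-lam) * lam**j / math.factorial(j)
                assert abs(transition_prob(i, j, t, gamma, delta) - pois) < 1e-6

    def test_matrix_agrees_with_scalar_form(self):
        P = transition_matrix(0.3, 0.5, np.array([0.7]), 20)[0]
        for i in (0, 2, 5):
            for j in (0, 1, 4, 9):
                assert abs(P[i, j] - transition_prob(i, j, 0.7, 0.3, 0.5)) < 1e-12


class TestFamilyLoglik:
    def test_all_zero_counts_certain_under_zero_gain(self):
        tree = parse_newick("(A:1,B:1);")
        rates = TurnoverRates({"background": (0.0, 1.0)})
        ll = family_loglik(tree, {"A": 0, "B": 0}, rates, root_prior=("fixed", 0))
        assert abs(ll[0]) < 1e-12

    @pytest.mark.parametrize("counts", [(1, 1, 2), (0, 2, 1), (3, 0, 0)])
    def test_matches_exhaustive_enumeration(self, counts):
        gamma, delta, cap = 0.3, 0.5, 15
        tree = parse_newick("((A:1,B:1):1,C:2);")
        rates = TurnoverRates({"background": (gamma, delta)})
        ll = family_loglik(
            tree, dict(zip("ABC", counts)), rates, max_count=cap
        )
        prior = root_prior_vector("stationary", rates, cap)
        oracle = enumerate_loglik_3leaf(
            (1.0, 1.0, 1.0, 2.0), counts, gamma, delta, prior, cap, transition_prob
        )
        assert abs(ll[0] - oracle) < 1e-8

    def test_truncation_stability(self):
        tree = parse_newick("((A:1,B:1):1,C:2);")
        rates = TurnoverRates({"background": (0.3, 0.5)})
        counts = {"A": 1, "B": 1, "C": 2}
        l1 = family_loglik(tree, counts, rates, max_count=20)[0]
        l2 = family_loglik(tree, counts, rates, max_count=40)[0]
        assert abs(l1 - l2) < 1e-8

    def test_invariant_to_leaf_ordering(self):
        rates = TurnoverRates({"background": (0.2, 0.4)})
        a = family_loglik(parse_newick("((A:1,B:1):1,C:2);"), {"A": 1, "B": 2, "C": 0}, rates)
        b = family_loglik(parse_newick("((B:1,A:1):1,C:2);"), {"A": 1, "B": 2, "C": 0}, rates)
        c = family_loglik(parse_newick("(C:2,(B:1,A:1):1);"), {"C": 0, "B": 2, "A": 1}, rates)
        assert abs(a[0] - b[0]) < 1e-12 and abs(a[0] - c[0]) < 1e-12

    def test_species_mismatch_rejected(self):
        tree = parse_newick("(A:1,B:1);")
        rates = TurnoverRates({"background": (0.2, 0.4)})
        with pytest.raises(ValueError):
            family_loglik(tree, {"A": 1, "X": 1}, rates)


class TestFitting:
    def test_all_zero_table_drives_gain_to_boundary(self):
        tree = parse_newick("(A:10,B:10);")
        fc = FamilyCounts(["f1", "f2"], ["A", "B"], np.zeros((2, 2), dtype=int))
        fit = fit_turnover(tree, fc, "global", seed=0, allow_absent_families=True)
        gamma, _ = fit.rates.rates["background"]
        assert gamma < 1e-6

    def test_absent_families_rejected_by_default(self):
        tree = parse_newick("(A:10,B:10);")
        fc = FamilyCounts(["f1"], ["A", "B"], np.zeros((1, 2), dtype=int))
        with pytest.raises(ValueError, match="untestable"):
            fit_turnover(tree, fc, "global", seed=0)

    def test_global_recovery_on_simulated_families(self, species_tree):
        truth = TurnoverRates({"background": (0.005, 0.004)})
        fc, _ = sim_family_counts(species_tree, truth, 400, seed=5)
        fit = fit_turnover(species_tree, fc, "global", seed=1, allow_absent_families=True)
        g, d = fit.rates.rates["background"]
        assert abs(g / 0.005 - 1) < 0.25
        assert abs(d / 0.004 - 1) < 0.25

    def test_branch_fit_agrees_between_classes_under_global_truth(self, species_tree):
        truth = TurnoverRates({"background": (0.01, 0.01)})
        fc, _ = sim_family_counts(species_tree, truth, 300, seed=9)
        fit = fit_turnover(
            species_tree, fc, "branch", foreground="Mob", seed=2, allow_absent_families=True
        )
        g_bg, d_bg = fit.rates.rates["background"]
        g_fg, d_fg = fit.rates.rates["foreground"]
        # one 93-Myr terminal branch: loose agreement is all that is expected
        assert 0.1 < g_fg / g_bg < 10
        assert fit.n_params == 4

    def test_branch_fit_does_not_mutate_input_tree(self, species_tree):
        before = [n.branch_class for n in species_tree.postorder()]
        fit_turnover(
            species_tree,
            FamilyCounts(["f1"], sorted(species_tree.leaf_names()),
                         np.ones((1, 11), dtype=int)),
            "branch", foreground="Mob", n_restarts=1, seed=0,
        )
        after = [n.branch_class for n in species_tree.postorder()]
        assert before == after


def _fit_with_aic(aic, n_params, model="global"):
    lnl = n_params - aic / 2.0
    return TurnoverFit(
        model=model,
        rates=TurnoverRates({"background": (0.1, 0.1)}),
        loglik=lnl,
        n_params=n_params,
        aic=aic,
        family_logliks=np.array([lnl]),
        converged=True,
        n_restarts=5,
        max_count=10,
    )


class TestModelSelection:
    def test_delta_aic_two_is_significant(self):
        sel = compare_models([_fit_with_aic(100, 2), _fit_with_aic(102, 4)])
        assert abs(sel.evidence_ratio - math.e) < 1e-12
        assert sel.significant

    def test_delta_aic_one_is_not_significant(self):
        sel = compare_models([_fit_with_aic(100, 2), _fit_with_aic(101, 4)])
        assert abs(sel.evidence_ratio - math.exp(0.5)) < 1e-12
        assert not sel.significant

    def test_tie_prefers_fewer_parameters(self):
        sel = compare_models([_fit_with_aic(100, 4, "branch"), _fit_with_aic(100, 2)])
        assert sel.best.n_params == 2
        assert sel.evidence_ratio == 1.0
        assert not sel.significant


class TestClassification:
    def _branch_fit(self, foreground="M", fg_rates=(0.001, 0.01), bg_rates=(0.01, 0.002)):
        rates = TurnoverRates({"background": bg_rates, "foreground": fg_rates})
        lnl = -1.0
        return TurnoverFit(
            model="branch", rates=rates, loglik=lnl, n_params=4,
            aic=8 - 2 * lnl, family_logliks=np.array([lnl]), converged=True,
            n_restarts=5, max_count=20, foreground=foreground,
        )

    def test_loss_of_all_genes_is_contraction(self):
        tree = parse_newick("((M:10,A:10):5,B:15);")
        fit = self._branch_fit(fg_rates=(1e-6, 0.5))
        call, lost = classify_family(fit, tree, {"M": 0, "A": 4, "B": 4})
        assert call == "contracted" and lost

    def test_foreground_excess_is_expansion(self):
        tree = parse_newick("((M:10,A:10):5,B:15);")
        fit = self._branch_fit(fg_rates=(2.0, 0.05), bg_rates=(0.02, 0.01))
        call, lost = classify_family(fit, tree, {"M": 45, "A": 3, "B": 3})
        assert call == "expanded" and not lost

    def test_match_with_reconstruction_is_stable(self):
        tree = parse_newick("((M:10,A:10):5,B:15);")
        fit = self._branch_fit(fg_rates=(0.01, 0.002), bg_rates=(0.01, 0.002))
        marg = ancestral_marginals(tree, {"M": 2, "A": 2, "B": 2}, fit.rates)
        fg_parent = next(l for l in tree.leaves() if l.name == "M").parent
        recon = int(np.argmax(marg[fg_parent]))
        call, lost = classify_family(fit, tree, {"M": recon, "A": 2, "B": 2})
        assert call == "stable" and not lost

    def test_marginals_are_distributions(self):
        tree = parse_newick("((M:10,A:10):5,B:15);")
        rates = TurnoverRates({"background": (0.05, 0.02)})
        marg = ancestral_marginals(tree, {"M": 1, "A": 2, "B": 0}, rates)
        for post in marg.values():
            assert abs(post.sum() - 1.0) < 1e-9
            assert (post >= 0).all()
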