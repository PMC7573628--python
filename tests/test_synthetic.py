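import numpy as np
import pytest
from scipy import stats

from plastburst.core_io import parse_newick
from plastburst.ks_engine import CODONS, transition_matrix_codon
from plastburst.synthetic import (
    angiosperm_timetree,
    sim_codon_pair,
    sim_family_counts,
    sim_family_tree_with_ks,
    sim_ks_mixture,
    sim_nupt_genome,
    split_seed,
    t_for_ds,
)
from plastburst.turnover import TurnoverRates, transition_prob

UNIFORM = np.full(len(CODONS), 1.0 / len(CODONS))


class TestDeterminism:
    def test_same_seed_reproduces_every_generator(self):
        tree = angiosperm_timetree()
        rates = TurnoverRates({"background": (0.01, 0.01)})
        a, _ = sim_family_counts(tree, rates, 50, seed=3)
        b, _ = sim_family_counts(tree, rates, 50, seed=3)
        assert (a.counts == b.counts).all()
        p1, _ = sim_codon_pair(50, 0.3, 2.0, 0.2, seed=3)
        p2, _ = sim_codon_pair(50, 0.3, 2.0, 0.2, seed=3)
        assert p1.seq1 == p2.seq1 and p1.seq2 == p2.seq2
        x1, _ = sim_ks_mixture([(1.0, 1.0, 0.2)], 100, seed=3)
        x2, _ = sim_ks_mixture([(1.0, 1.0, 0.2)], 100, seed=3)
        assert np.array_equal(x1, x2)
        g1 = sim_nupt_genome(20_000, 5_000, 5, seed=3)
        g2 = sim_nupt_genome(20_000, 5_000, 5, seed=3)
        assert g1[0] == g2[0] and g1[2] == g2[2]

    def test_seed_splitting_is_stable_and_stage_specific(self):
        assert split_seed(1, "ks") == split_seed(1, "ks")
        assert split_seed(1, "ks") != split_seed(1, "peaks")
        assert 0 <= split_seed(123456, "anything") < 2**31


class TestFamilyCounts:
    def test_zero_gain_from_empty_root_stays_empty(self):
        tree = angiosperm_timetree()
        rates = TurnoverRates({"background": (0.0, 0.01)})
        fc, _ = sim_family_counts(tree, rates, 100, root_prior=("fixed", 0), seed=0)
        assert (fc.counts == 0).all()

    def test_long_branch_reaches_stationary_poisson(self):
        gamma, delta = 0.6, 0.3
        tree = parse_newick(f"(A:{1000/delta});")
        rates = TurnoverRates({"background": (gamma, delta)})
        fc, _ = sim_family_counts(tree, rates, 5000, root_prior=("fixed", 3), seed=1)
        counts = fc.counts.ravel()
        lam = gamma / delta
        kmax = 8
        obs = np.bincount(np.minimum(counts, kmax), minlength=kmax + 1)
        probs = stats.poisson.pmf(np.arange(kmax), lam)
        probs = np.append(probs, 1 - probs.sum())
        chi = stats.chisquare(obs, probs * counts.size)
        assert chi.pvalue > 0.01

    def test_single_branch_law_matches_transition_prob(self):
        gamma, delta, t, start = 0.4, 0.5, 1.3, 2
        tree = parse_newick(f"(A:{t});")
        rates = TurnoverRates({"background": (gamma, delta)})
        fc, _ = sim_family_counts(tree, rates, 20_000, root_prior=("fixed", start), seed=2)
        counts = fc.counts.ravel()
        for j in range(8):
            p = transition_prob(start, j, t, gamma, delta)
            obs = (counts == j).mean()
            se = np.sqrt(p * (1 - p) / counts.size)
            assert abs(obs - p) <= 3 * max(se, 1e-4)


class TestCodonPairs:
    def test_zero_time_gives_identical_pair(self):
        pair, truth = sim_codon_pair(200, 0.0, 2.0, 0.2, seed=0)
        assert pair.seq1 == pair.seq2
        assert truth.items["true_dS"] == 0.0

    def test_neutral_model_has_equal_site_and_flux_fractions(self):
        _, truth = sim_codon_pair(50, 0.3, 1.0, 1.0, seed=0)
        assert abs(truth.items["rho_S"] - truth.items["f_S"]) < 1e-12

    def test_observed_difference_fraction_matches_expectation(self):
        t = t_for_ds(0.5, 2.0, 0.2, UNIFORM)
        P = transition_matrix_codon(UNIFORM, 2.0, 0.2, t / 2)
        q_same = float((UNIFORM[:, None] * P * P).sum())  # P(child1 == child2)
        n, reps = 500, 12
        fracs = []
        for i in range(reps):
            pair, _ = sim_codon_pair(n, t, 2.0, 0.2, seed=100 + i)
            diff = sum(
                pair.seq1[k : k + 3] != pair.seq2[k : k + 3] for k in range(0, 3 * n, 3)
            )
            fracs.append(diff / n)
        expect = 1 - q_same
        se = np.sqrt(expect * (1 - expect) / (n * reps))
        assert abs(np.mean(fracs) - expect) <= 3 * se


class TestKsMixture:
    def test_degenerate_component_collapses_to_mean(self):
        x, _ = sim_ks_mixture([(1.0, 1.3, 1e-6)], 200, seed=0)
        assert np.allclose(x, 1.3, atol=1e-4)

    def test_component_proportions_recovered(self):
        comps = [(0.15, 0.17, 0.05), (0.55, 1.62, 0.30), (0.30, 2.53, 0.30)]
        x, _ = sim_ks_mixture(comps, 2000, seed=9)
        means = np.array([c[1] for c in comps])
        assign = np.argmin(np.abs(x[:, None] - means[None, :]), axis=1)
        props = np.bincount(assign, minlength=3) / x.size
        assert np.abs(props - [0.15, 0.55, 0.30]).max() < 0.04

    def test_window_exclusion_lowers_acceptance(self):
        comps = [(0.5, 1.0, 0.05), (0.5, 10.0, 0.05)]
        _, truth = sim_ks_mixture(comps, 500, window=(0.05, 5.0), seed=1)
        assert truth.items["acceptance_rate"] < 0.6


class TestFamilyTrees:
    def test_noiseless_ks_is_twice_node_age(self):
        tree, ks, truth = sim_family_tree_with_ks(10, ks_noise_sd=0.0, seed=5)
        ages = sorted(truth.items["node_ages"])
        for (a, b), v in ks.items():
            assert any(abs(v - 2 * age) < 1e-12 for age in ages)

    def test_deep_nodes_are_split_off(self):
        from plastburst.ks_weighting import split_by_ks

        tree, ks, truth = sim_family_tree_with_ks(
            8, node_ages=[0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 3.0], ks_noise_sd=0.0, seed=2
        )
        clades = split_by_ks(tree, ks, threshold=5.0)
        assert len(clades) == 2  # root (age 3 -> Ks 6) split, nothing else


class TestNuptGenome:
    def test_zero_divergence_insertions_found_verbatim(self):
        nuc, plastid, placed, _ = sim_nupt_genome(
            60_000, 20_000, 10, divergence=(0.0, 0.0), seed=4
        )
        for s, e, d in placed:
            assert d == 0.0
            frag = nuc[s:e]
            from plastburst.nupt import revcomp

            assert frag in plastid or revcomp(frag) in plastid

    def test_truth_intervals_do_not_overlap(self):
        _, _, placed, _ = sim_nupt_genome(100_000, 30_000, 50, seed=5)
        for (s1, e1, _), (s2, e2, _) in zip(placed, placed[1:]):
            assert e1 <= s2

    def test_empty_genome_has_no_spurious_hits(self):
        from plastburst.nupt import toy_local_align

        nuc, plastid, placed, _ = sim_nupt_genome(100_000, 20_000, 0, seed=3)
        assert placed == []
        assert toy_local_align(plastid, nuc) == []
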