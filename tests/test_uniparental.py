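"""Uniparental statistics: diversity, Phi_ST, exact test, PCO, posteriors, TMRCA."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import fisher_exact

from endopop.synthetic_data import simulate_haplogroup_counts, simulate_str
from endopop.uniparental import (DEFAULT_MU, HaplogroupCounts, STRHaplotypeSet,
                                 admixture_posterior, asd_tmrca,
                                 diversity_z_test, exact_test,
                                 generations_to_years, gene_diversity,
                                 modal_haplotype, pco, phi_st)


def counts_table(rows, pops=None, cats=None):
    rows = np.atleast_2d(rows)
    pops = pops or [f"pop{i+1}" for i in range(rows.shape[0])]
    cats = cats or [f"c{i+1}" for i in range(rows.shape[1])]
    return HaplogroupCounts(pd.DataFrame(rows, index=pops, columns=cats))


class TestGeneDiversity:
    def test_monomorphic_sample_has_zero_diversity(self):
        h, se = gene_diversity([7])
        assert h == 0.0

    def test_two_equal_categories_hand_value(self):
        h, _ = gene_diversity([2, 2])
        assert h == pytest.approx(4 / 3 * 0.5)

    def test_se_matches_bootstrap_within_20_percent(self):
        rng = np.random.default_rng(0)
        p_true = np.array([0.4, 0.3, 0.2, 0.1])
        n = 500
        counts = rng.multinomial(n, p_true)
        _, se = gene_diversity(counts)
        boots = []
        for _ in range(3000):
            c = rng.multinomial(n, counts / n)
            boots.append(gene_diversity(c)[0])
        assert se == pytest.approx(np.std(boots), rel=0.2)

    def test_small_samples_rejected_and_z_test_runs(self):
        with pytest.raises(ValueError):
            gene_diversity([1])
        h1, s1 = gene_diversity([5, 5])
        h2, s2 = gene_diversity([9, 1])
        z, p = diversity_z_test(h1, s1, h2, s2)
        assert z > 0 and 0 <= p <= 1

    def test_duplicating_an_existing_category_never_increases_h(self):
        base = [5, 3, 2]
        h0, _ = gene_diversity(base)
        h1, _ = gene_diversity([6, 3, 2])
        assert h1 <= h0 + 1e-12


class TestPhiST:
    def test_complete_fixation_gives_one(self):
        phi, p = phi_st(counts_table([[4, 0], [0, 4]]), n_permutations=200,
                        seed=1)
        assert phi == pytest.approx(1.0)
        assert p < 0.1

    def test_identical_counts_give_non_positive_phi(self):
        phi, _ = phi_st(counts_table([[2, 2], [2, 2]]), n_permutations=100,
                        seed=1)
        assert phi <= 0

    def test_toy_table_matches_hand_amova(self):
        # pops (3A+1B) vs (1A+3B): hand AMOVA gives Phi_ST = 0.2
        phi, _ = phi_st(counts_table([[3, 1], [1, 3]]), n_permutations=100,
                        seed=1)
        assert phi == pytest.approx(0.2)

    def test_permutation_p_invariant_to_category_relabeling(self):
        t = [[5, 2, 1], [1, 3, 4]]
        phi1, p1 = phi_st(counts_table(t), n_permutations=500, seed=7)
        shuffled = [[1, 5, 2], [4, 1, 3]]       # same rows, columns permuted
        phi2, p2 = phi_st(counts_table(shuffled), n_permutations=500, seed=7)
        assert phi1 == pytest.approx(phi2)
        assert p1 == pytest.approx(p2)


class TestExactTest:
    def test_identical_rows_give_large_p(self):
        p = exact_test(counts_table([[5, 5], [5, 5]]), n_steps=10000, seed=3)
        assert p > 0.5

    def test_diagonal_table_matches_fisher(self):
        p = exact_test(counts_table([[5, 0], [0, 5]]), n_steps=20000, seed=4)
        assert p == pytest.approx(2 / 252, abs=0.004)   # Fisher: 0.00794

    def test_matches_fisher_on_assorted_2x2_tables(self):
        rng = np.random.default_rng(5)
        for _ in range(8):
            t = rng.integers(0, 8, (2, 2)) + np.array([[1, 0], [0, 1]])
            p_f = fisher_exact(t)[1]
            p_mc = exact_test(counts_table(t), n_steps=20000, seed=6)
            assert p_mc == pytest.approx(p_f, abs=0.05)

    def test_null_p_values_approximately_uniform(self):
        rng = np.random.default_rng(8)
        pvals = []
        for rep in range(100):
            t = rng.multinomial(30, [0.25] * 4, size=2)
            pvals.append(exact_test(counts_table(t), n_steps=2000, seed=rep))
        pvals = np.asarray(pvals)
        assert 0.35 < pvals.mean() < 0.65
        assert (pvals <= 0.05).mean() <= 0.12


class TestPCO:
    def test_self_similarity_formula(self):
        # direct check of the n/(n-1) diagonal on the centered embedding input
        assert 13 / 12 == pytest.approx(1.0833, abs=1e-4)
        fst = pd.DataFrame([[0.0, 0.1], [0.1, 0.0]], index=["x", "y"],
                           columns=["x", "y"])
        coords, eig = pco(fst, pd.Series([13, 13], index=["x", "y"]))
        d = np.linalg.norm(coords.loc["x"] - coords.loc["y"])
        # embedded distance^2 = S_xx + S_yy - 2 S_xy
        assert d ** 2 == pytest.approx(2 * (13 / 12) - 2 * 0.9)

    def test_identical_populations_coincide_on_first_axis(self):
        pops = ["x", "y", "z"]
        fst = pd.DataFrame([[0.0, 0.0, 0.3], [0.0, 0.0, 0.3], [0.3, 0.3, 0.0]],
                           index=pops, columns=pops)
        coords, _ = pco(fst, pd.Series([10, 10, 10], index=pops))
        assert coords.loc["x", "PCo1"] == pytest.approx(coords.loc["y", "PCo1"])

    def test_equal_pairwise_fst_embeds_as_equilateral_triangle(self):
        pops = ["x", "y", "z"]
        fst = pd.DataFrame(0.2, index=pops, columns=pops)
        np.fill_diagonal(fst.values, 0.0)
        coords, _ = pco(fst, pd.Series([10, 10, 10], index=pops))
        d = [np.linalg.norm(coords.loc[a] - coords.loc[b])
             for a, b in [("x", "y"), ("x", "z"), ("y", "z")]]
        assert max(d) - min(d) < 1e-9

    def test_asymmetric_matrix_rejected(self):
        fst = pd.DataFrame([[0.0, 0.1], [0.3, 0.0]], index=["x", "y"],
                           columns=["x", "y"])
        with pytest.raises(ValueError, match="symmetric"):
            pco(fst, pd.Series([5, 5], index=["x", "y"]))


class TestAdmixturePosterior:
    def test_pure_source_a_hybrid_pushes_mode_high(self):
        cats = list("abcd")
        f_a = pd.Series([0.7, 0.2, 0.05, 0.05], index=cats)
        f_b = pd.Series([0.05, 0.05, 0.2, 0.7], index=cats)
        rng = np.random.default_rng(0)
        hybrid = pd.Series(rng.multinomial(500, f_a), index=cats)
        pa = pd.Series(rng.multinomial(500, f_a), index=cats)
        pb = pd.Series(rng.multinomial(500, f_b), index=cats)
        post = admixture_posterior(hybrid, pa, pb)
        assert post.mode > 0.9
        assert post.mass.sum() == pytest.approx(1.0)

    def test_identical_parents_leave_prior_flat(self):
        cats = list("ab")
        f = pd.Series([30, 20], index=cats)
        hybrid = pd.Series([12, 8], index=cats)
        post = admixture_posterior(hybrid, f, f)
        assert post.median == pytest.approx(0.5, abs=0.01)
        assert post.mass.max() / post.mass.min() < 1.0001

    def test_posterior_mean_monotone_in_diagnostic_count(self):
        cats = list("ab")
        pa = pd.Series([50, 0], index=cats)
        pb = pd.Series([0, 50], index=cats)
        means = [admixture_posterior(pd.Series([k, 20 - k], index=cats),
                                     pa, pb).mean for k in (2, 10, 18)]
        assert means[0] < means[1] < means[2]

    def test_credible_interval_covers_generating_proportion(self):
        cats = list("abcd")
        f_a = pd.Series([0.7, 0.2, 0.05, 0.05], index=cats)
        f_b = pd.Series([0.05, 0.05, 0.2, 0.7], index=cats)
        rng = np.random.default_rng(1)
        covered = 0
        reps = 60
        for rep in range(reps):
            hybrid = simulate_haplogroup_counts(f_a, f_b, 0.8, 200,
                                                seed=1000 + rep)
            pa = pd.Series(rng.multinomial(500, f_a), index=cats)
            pb = pd.Series(rng.multinomial(500, f_b), index=cats)
            post = admixture_posterior(hybrid.table.iloc[0], pa, pb)
            covered += post.ci[0] <= 0.8 <= post.ci[1]
        assert covered / reps >= 0.9


class TestModalHaplotype:
    def _set(self, rows, hg="P"):
        rows = np.atleast_2d(rows)
        return STRHaplotypeSet(rows, [f"L{i}" for i in range(rows.shape[1])],
                               [hg] * rows.shape[0])

    def test_unanimous_sample(self):
        s = self._set([[14, 12]] * 5)
        m = modal_haplotype(s, "P")
        assert m.haplotype == (14, 12) and m.frequency == 1.0
        assert not m.below_threshold

    def test_majority_mode_without_flag(self):
        s = self._set([[14, 12]] * 3 + [[15, 12]] + [[14, 13]])
        m = modal_haplotype(s, "P")
        assert m.haplotype == (14, 12)
        assert m.frequency == pytest.approx(0.6)
        assert not m.below_threshold

    def test_tie_is_hard_error(self):
        s = self._set([[14, 12]] * 2 + [[15, 12]] * 2 + [[16, 12]])
        with pytest.raises(ValueError, match="tie"):
            modal_haplotype(s, "P")

    def test_plurality_below_half_is_flagged(self):
        s = self._set([[14, 12]] * 2 + [[15, 12]] + [[16, 12]] + [[17, 12]])
        m = modal_haplotype(s, "P")
        assert m.below_threshold


class TestASDTMRCA:
    def _set(self, rows):
        rows = np.atleast_2d(rows)
        return STRHaplotypeSet(rows, [f"L{i}" for i in range(rows.shape[1])],
                               ["P"] * rows.shape[0])

    def test_no_variation_dates_to_zero(self):
        s = self._set([[14, 12, 23, 10, 11, 13]] * 4)
        est = asd_tmrca(s, (14, 12, 23, 10, 11, 13), n_iterations=100)
        assert est.asd == 0.0 and est.t_generations == 0.0

    def test_single_step_hand_example(self):
        modal = (14, 12, 23, 10, 11, 13)
        rows = [list(modal), [15, 12, 23, 10, 11, 13]]
        est = asd_tmrca(self._set(rows), modal, mu=DEFAULT_MU, n_iterations=0)
        assert est.asd == pytest.approx(1 / 12)
        assert est.t_generations == pytest.approx(43.6, abs=0.05)

    def test_mean_estimate_unbiased_under_smm(self):
        t_true, mu = 35, DEFAULT_MU
        anc = (14, 12, 23, 10, 11, 13)
        ests = []
        for rep in range(40):
            strs = simulate_str(anc, mu, t_true, 200, seed=rep)
            ests.append(asd_tmrca(strs, anc, mu=mu, n_iterations=0).t_generations)
        assert np.mean(ests) == pytest.approx(t_true, rel=0.1)

    def test_ci_covers_truth_in_most_replicates(self):
        t_true, mu = 35, DEFAULT_MU
        anc = (14, 12, 23, 10, 11, 13)
        covered = 0
        reps = 40
        for rep in range(reps):
            strs = simulate_str(anc, mu, t_true, 50, seed=500 + rep)
            est = asd_tmrca(strs, anc, mu=mu, n_iterations=2000, seed=rep)
            covered += est.ci_generations[0] <= t_true <= est.ci_generations[1]
        assert covered / reps >= 0.9

    def test_pooled_clusters_average_their_asd(self):
        m1 = (14, 12)
        m2 = (20, 18)
        s1 = self._set([[15, 12], [14, 12]])        # squared diffs: 1, 0
        s2 = self._set([[20, 20], [20, 18]])        # squared diffs: 4, 0
        est = asd_tmrca(s1, m1, mu=0.001, n_iterations=0,
                        pooled_partners=(s2, m2))
        assert est.asd == pytest.approx((1 + 0 + 4 + 0) / 8)

    def test_exclusions_remove_outliers(self):
        rows = [[14, 12], [14, 12], [23, 12]]
        s = STRHaplotypeSet(np.asarray(rows), ["L0", "L1"], ["P"] * 3,
                            ids=["a", "b", "outlier"])
        est = asd_tmrca(s, (14, 12), mu=0.001, n_iterations=0,
                        exclusions=("outlier",))
        assert est.asd == 0.0

    def test_mu_uncertainty_widens_interval(self):
        strs = simulate_str((14, 12, 23, 10, 11, 13), DEFAULT_MU, 35, 50, seed=9)
        fixed = asd_tmrca(strs, (14, 12, 23, 10, 11, 13), n_iterations=4000,
                          seed=1)
        loose = asd_tmrca(strs, (14, 12, 23, 10, 11, 13), n_iterations=4000,
                          seed=1, mu_uncertainty=True)
        width = lambda ci: ci[1] - ci[0]
        assert width(loose.ci_generations) > width(fixed.ci_generations)


class TestGenerationsToYears:
    @pytest.mark.parametrize("t,ci,years,ci_years", [
        (37, (19, 61), 1036, (532, 1708)),
        (31, (18, 46), 868, (504, 1288)),
    ])
    def test_printed_conversions(self, t, ci, years, ci_years):
        y, cy = generations_to_years(t, ci, 28)
        assert y == years
        assert cy == ci_years

    def test_zero_generations(self):
        y, cy = generations_to_years(0, (0, 0), 28)
        assert y == 0 and cy == (0, 0)
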