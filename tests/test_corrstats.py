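import math

import numpy as np
import pytest
from scipy.stats import chi2_contingency

from protdna_korr.alignments import AA_INDEX, NT_INDEX
from protdna_korr.corrstats import (
    DegenerateColumnError,
    chi2_summands,
    column_information_content,
    column_pair_stats,
    correlation_matrix,
    joint_frequency,
    mutual_information,
    positional_frequency,
    weighted_counts,
)
from protdna_korr.substitution import blosum_transition_probs, identity_model

from conftest import make_set, random_set


def brute_force_counts(pset, i, j):
    """Independent double-loop oracle for the weighted counts."""
    N_ij = np.zeros((20, 4))
    n_eff = 0.0
    for r in pset.records:
        a, n = r.tf_row[i], r.site_row[j]
        if a == "-" or n == "-":
            continue
        N_ij[AA_INDEX[a], NT_INDEX[n]] += r.weight
        n_eff += r.weight
    return N_ij, n_eff


def brute_force_mi(f_ij, f_i, f_j):
    """Plain double-sum evaluation of the MI definition."""
    total = 0.0
    for a in range(f_ij.shape[0]):
        for n in range(f_ij.shape[1]):
            if f_ij[a, n] > 0:
                total += f_ij[a, n] * math.log(f_ij[a, n] / (f_i[a] * f_j[n]))
    return total


class TestWeightedCounts:
    def test_uniform_weights_equal_raw_cooccurrence(self):
        pset = make_set([("K", "C"), ("K", "C"), ("E", "T")])
        N_ij, N_i, N_j, n_eff = weighted_counts(pset, 0, 0)
        assert N_ij[AA_INDEX["K"], NT_INDEX["C"]] == 2.0
        assert N_ij[AA_INDEX["E"], NT_INDEX["T"]] == 1.0
        assert n_eff == 3.0

    def test_weights_sum_into_cells(self):
        pset = make_set([("K", "C"), ("K", "C")], weights=[1.0, 0.5])
        N_ij, *_ = weighted_counts(pset, 0, 0)
        assert N_ij[AA_INDEX["K"], NT_INDEX["C"]] == pytest.approx(1.5)

    def test_gapped_records_excluded_per_pair(self):
        pset = make_set([("K-", "C"), ("KE", "-"), ("KE", "T")])
        _, _, _, n_eff0 = weighted_counts(pset, 0, 0)
        assert n_eff0 == 2.0  # record 2 gapped at the site column
        _, _, _, n_eff1 = weighted_counts(pset, 1, 0)
        assert n_eff1 == 1.0  # records 1 and 2 gapped at one of the columns

    def test_matches_brute_force_on_random_weighted_sets(self):
        rng = np.random.default_rng(21)
        for _ in range(10):
            pset = random_set(rng, n_records=15, gap_rate=0.15)
            i = int(rng.integers(pset.n_protein_cols))
            j = int(rng.integers(pset.n_site_cols))
            N_ij, N_i, N_j, n_eff = weighted_counts(pset, i, j)
            exp_ij, exp_eff = brute_force_counts(pset, i, j)
            np.testing.assert_allclose(N_ij, exp_ij, atol=1e-12)
            assert n_eff == pytest.approx(exp_eff)
            np.testing.assert_allclose(N_i, exp_ij.sum(axis=1), atol=1e-12)
            np.testing.assert_allclose(N_j, exp_ij.sum(axis=0), atol=1e-12)


class TestFrequencies:
    def test_kappa_zero_reduces_to_plain_frequencies(self):
        model = identity_model(kappa=0.0)
        N = np.zeros(20)
        N[AA_INDEX["K"]] = 3
        N[AA_INDEX["E"]] = 1
        f = positional_frequency(N, 4.0, model, "aa")
        assert f[AA_INDEX["K"]] == pytest.approx(0.75)
        assert f.sum() == pytest.approx(1.0)

    def test_identity_substitution_cancels_pseudocounts(self):
        model = identity_model(kappa=0.5)
        N = np.zeros(20)
        N[AA_INDEX["K"]] = 3
        N[AA_INDEX["E"]] = 1
        f = positional_frequency(N, 4.0, model, "aa")
        assert f[AA_INDEX["K"]] == pytest.approx(0.75)

    def test_blosum_pseudocount_matches_direct_formula(self):
        model = blosum_transition_probs("BLOSUM45", kappa=0.5)
        N = np.zeros(20)
        N[AA_INDEX["K"]] = 3
        N[AA_INDEX["E"]] = 1
        f = positional_frequency(N, 4.0, model, "aa")
        # direct scalar evaluation of the pseudocounted frequency formula
        for a in range(20):
            pseudo = sum(N[b] * model.P[b, a] for b in range(20))
            expected = (N[a] + 0.5 * pseudo) / (4.0 * 1.5)
            assert f[a] == pytest.approx(expected, abs=1e-12)
        assert f.sum() == pytest.approx(1.0, abs=1e-9)

    def test_nucleotide_pseudocount_is_uniform(self):
        model = identity_model(kappa=0.5)
        N = np.array([4.0, 0.0, 0.0, 0.0])
        f = positional_frequency(N, 4.0, model, "nt")
        # kappa*N/4 = 0.5 pseudo-observations per base over N(1+kappa) = 6
        np.testing.assert_allclose(f, [4.5 / 6, 0.5 / 6, 0.5 / 6, 0.5 / 6])

    def test_joint_marginalizes_to_positional(self):
        rng = np.random.default_rng(33)
        model = blosum_transition_probs("BLOSUM45", kappa=0.5)
        for _ in range(20):
            pset = random_set(rng, n_records=10, gap_rate=0.1)
            i = int(rng.integers(pset.n_protein_cols))
            j = int(rng.integers(pset.n_site_cols))
            N_ij, N_i, N_j, n_eff = weighted_counts(pset, i, j)
            if n_eff == 0:
                continue
            f_ij = joint_frequency(N_ij, N_i, n_eff, model)
            f_i = positional_frequency(N_i, n_eff, model, "aa")
            f_j = positional_frequency(N_j, n_eff, model, "nt")
            assert f_ij.sum() == pytest.approx(1.0, abs=1e-9)
            np.testing.assert_allclose(f_ij.sum(axis=1), f_i, atol=1e-9)
            np.testing.assert_allclose(f_ij.sum(axis=0), f_j, atol=1e-9)

    def test_six_record_toy_against_hand_evaluation(self):
        model = blosum_transition_probs("BLOSUM45", kappa=0.5)
        pset = make_set(
            [("K", "C"), ("K", "C"), ("K", "T"), ("E", "T"), ("E", "T"), ("E", "T")]
        )
        N_ij, N_i, N_j, n_eff = weighted_counts(pset, 0, 0)
        f_ij = joint_frequency(N_ij, N_i, n_eff, model)
        K, E, C, T = AA_INDEX["K"], AA_INDEX["E"], NT_INDEX["C"], NT_INDEX["T"]
        kap = 0.5

        def expected(a, n):
            obs = N_ij[a, n]
            pseudo = sum(model.P[b, a] * N_i[b] for b in range(20)) / 4.0
            return (obs + kap * pseudo) / (6.0 * (1 + kap))

        for a, n in [(K, C), (K, T), (E, C), (E, T)]:
            assert f_ij[a, n] == pytest.approx(expected(a, n), abs=1e-12)

    def test_degenerate_column_raises(self):
        model = identity_model()
        with pytest.raises(DegenerateColumnError):
            positional_frequency(np.zeros(20), 0.0, model, "aa")


class TestMutualInformation:
    def test_constant_protein_column_gives_zero(self):
        model = identity_model(kappa=0.0)
        pset = make_set([("K", "C"), ("K", "T"), ("K", "C")])
        stats = column_pair_stats(pset, 0, 0, model)
        assert stats.I == pytest.approx(0.0, abs=1e-12)

    def test_perfect_binary_association_is_ln2(self):
        model = identity_model(kappa=0.0)
        pset = make_set([("K", "C"), ("K", "C"), ("E", "T"), ("E", "T")])
        stats = column_pair_stats(pset, 0, 0, model)
        assert stats.I == pytest.approx(math.log(2), abs=1e-12)

    def test_six_record_hand_value(self):
        model = identity_model(kappa=0.0)
        pset = make_set(
            [("K", "C"), ("K", "C"), ("K", "T"), ("E", "T"), ("E", "T"), ("E", "T")]
        )
        stats = column_pair_stats(pset, 0, 0, model)
        # (1/3)ln2 + (1/6)ln(1/2) + (1/2)ln(3/2) = 0.31825...
        assert stats.I == pytest.approx(0.3182570841474064, abs=1e-12)

    @pytest.mark.parametrize("kappa", [0.0, 0.5])
    def test_matches_brute_force_double_sum(self, kappa):
        model = blosum_transition_probs("BLOSUM45", kappa=kappa)
        rng = np.random.default_rng(55)
        for _ in range(30):
            pset = random_set(rng, n_records=12, gap_rate=0.1)
            i = int(rng.integers(pset.n_protein_cols))
            j = int(rng.integers(pset.n_site_cols))
            N_ij, N_i, N_j, n_eff = weighted_counts(pset, i, j)
            if n_eff == 0:
                continue
            f_ij = joint_frequency(N_ij, N_i, n_eff, model)
            f_i = positional_frequency(N_i, n_eff, model, "aa")
            f_j = positional_frequency(N_j, n_eff, model, "nt")
            assert mutual_information(f_ij, f_i, f_j) == pytest.approx(
                brute_force_mi(f_ij, f_i, f_j), abs=1e-10
            )

    def test_nonnegative_up_to_tolerance(self):
        rng = np.random.default_rng(77)
        model = blosum_transition_probs("BLOSUM45", kappa=0.5)
        I, ok = correlation_matrix(random_set(rng, n_records=20), model)
        assert np.all(I[ok] >= -1e-12)


class TestChi2:
    def test_zero_when_observed_equals_expected(self):
        N_ij = np.outer(np.arange(20.0), np.array([1.0, 2, 3, 4])) / 10.0
        summ, sign, hi = chi2_summands(N_ij, N_ij.sum(1), N_ij.sum(0), N_ij.sum())
        np.testing.assert_allclose(summ, 0.0, atol=1e-12)

    def test_single_cell_arithmetic(self):
        # O = 10, E = 10*10/50 = 2 -> (10-2)^2/2 = 32, overrepresented
        N_ij = np.zeros((20, 4))
        N_ij[0, 0] = 10.0
        N_ij[1, 1] = 40.0
        N_i, N_j, n = N_ij.sum(1), N_ij.sum(0), N_ij.sum()
        summ, sign, hi = chi2_summands(N_ij, N_i, N_j, n)
        assert summ[0, 0] == pytest.approx(32.0)
        assert sign[0, 0] == 1 and sign[0, 1] == -1
        assert bool(hi[0, 0]) is False  # default cutoff 50
        summ2, _, hi2 = chi2_summands(N_ij, N_i, N_j, n, cutoff=30.0)
        assert bool(hi2[0, 0]) is True

    def test_total_matches_scipy_pearson_statistic(self):
        rng = np.random.default_rng(100)
        counts = rng.integers(1, 20, size=(4, 4)).astype(float)
        N_ij = np.zeros((20, 4))
        N_ij[:4] = counts
        summ, *_ = chi2_summands(N_ij, N_ij.sum(1), N_ij.sum(0), N_ij.sum())
        stat = chi2_contingency(counts, correction=False).statistic
        assert summ.sum() == pytest.approx(stat, rel=1e-12)


class TestInformationContent:
    def test_uniform_nucleotide_column_is_zero_bits(self):
        assert column_information_content(np.full(4, 0.25)) == pytest.approx(0.0)

    def test_single_residue_column_is_log2_20(self):
        f = np.zeros(20)
        f[3] = 1.0
        assert column_information_content(f) == pytest.approx(math.log2(20))

    def test_half_half_two_nucleotides_is_one_bit(self):
        assert column_information_content(np.array([0.5, 0.5, 0, 0])) == pytest.approx(1.0)


class TestCorrelationMatrix:
    def test_shape_and_consistency_with_per_pair_route(self):
        rng = np.random.default_rng(13)
        pset = random_set(rng, n_records=15, n_prot=6, n_site=5, gap_rate=0.1)
        model = blosum_transition_probs("BLOSUM45", kappa=0.5)
        I, ok = correlation_matrix(pset, model)
        assert I.shape == (5, 6)
        for j in range(5):
            for i in range(6):
                N_ij, N_i, N_j, n_eff = weighted_counts(pset, i, j)
                if n_eff == 0:
                    assert not ok[j, i]
                    continue
                stats = column_pair_stats(pset, i, j, model)
                assert I[j, i] == pytest.approx(stats.I, abs=1e-10)

    def test_identity_model_cancels_in_protein_marginal(self):
        """With P = identity the protein pseudocount reproduces the observed
        counts, so f_i is kappa-free; the joint and nucleotide marginals keep
        their uniform 1/4 pseudocount regardless of P."""
        rng = np.random.default_rng(17)
        pset = random_set(rng, n_records=10)
        for j, i in [(0, 0), (2, 3)]:
            _, N_i, _, n_eff = weighted_counts(pset, i, j)
            f_k = positional_frequency(N_i, n_eff, identity_model(0.8), "aa")
            f_0 = positional_frequency(N_i, n_eff, identity_model(0.0), "aa")
            np.testing.assert_allclose(f_k, f_0, atol=1e-12)

    def test_vanishing_kappa_converges_to_plain_mi(self):
        rng = np.random.default_rng(17)
        pset = random_set(rng, n_records=10)
        I1, _ = correlation_matrix(pset, identity_model(kappa=1e-9))
        I0, _ = correlation_matrix(pset, identity_model(kappa=0.0))
        np.testing.assert_allclose(I1, I0, atol=1e-6)

    def test_mean_mi_shrinks_with_sample_size(self):
        """Finite-sample MI bias: independent columns give small positive MI
        that decreases as records accumulate."""
        model = identity_model(kappa=0.0)
        means = []
        for n in (10, 40, 160):
            vals = []
            for seed in range(5):
                rng = np.random.default_rng(1000 + seed)
                pset = random_set(rng, n_records=n, weighted=False)
                I, ok = correlation_matrix(pset, model)
                vals.append(I[ok].mean())
            means.append(np.mean(vals))
        assert means[0] > means[1] > means[2]
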