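import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from adsigkit.deg import (NBConfig, SAMConfig, adjust_bh, call_degs,
                          filter_by_tpm, nb_exact_test, qvalues, sam_test,
                          tmm_factors)
from adsigkit.io_model import ExpressionMatrix, ValidationError
from adsigkit.synthetic_data import MouseSimConfig, SimulationConfig, \
    simulate_mouse_study

from conftest import make_counts, make_log_matrix


# ---------------------------------------------------------------------------
# TPM filter
# ---------------------------------------------------------------------------


class TestFilterByTpm:
    def test_strict_inequality_at_threshold(self):
        counts = make_counts([[4, 4], [2, 2], [1, 1]], ["A", "B"])
        tpm = ExpressionMatrix(
            pd.DataFrame([[2.0, 2.0], [1.0, 1.0], [0.5, 0.5]],
                         index=counts.gene_ids, columns=counts.sample_ids),
            "tpm", counts.samples)
        out = filter_by_tpm(counts, tpm, 1.0)
        assert list(out.gene_ids) == ["g0"]

    def test_zero_threshold_keeps_all_positive_genes(self):
        counts = make_counts([[4, 4], [2, 2]], ["A", "B"])
        tpm = ExpressionMatrix(counts.values.astype(float), "tpm",
                               counts.samples)
        out = filter_by_tpm(counts, tpm, 0.0)
        assert list(out.gene_ids) == list(counts.gene_ids)

    def test_survivors_match_brute_force(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            vals = rng.uniform(0, 3, (40, 6))
            counts = make_counts(np.ones((40, 6), dtype=int), ["A"] * 3 + ["B"] * 3)
            tpm = ExpressionMatrix(
                pd.DataFrame(vals, index=counts.gene_ids,
                             columns=counts.sample_ids), "tpm", counts.samples)
            cutoff = rng.uniform(0.5, 2)
            out = filter_by_tpm(counts, tpm, cutoff)
            brute = sum(1 for i in range(40) if np.mean(vals[i]) > cutoff)
            assert len(out.gene_ids) == brute

    def test_id_mismatch_rejected(self):
        counts = make_counts([[1, 1]], ["A", "B"])
        tpm = ExpressionMatrix(pd.DataFrame([[1.0, 1.0]], index=["other"],
                                            columns=counts.sample_ids),
                               "tpm", counts.samples)
        with pytest.raises(ValidationError):
            filter_by_tpm(counts, tpm, 1.0)


# ---------------------------------------------------------------------------
# TMM
# ---------------------------------------------------------------------------


def _tmm_oracle(y, ref, trim_m=0.3, trim_a=0.05):
    """Independent re-implementation of the trimmed weighted mean of M."""
    n_y, n_r = y.sum(), ref.sum()
    keep = (y > 0) & (ref > 0)
    y, ref = y[keep].astype(float), ref[keep].astype(float)
    m = np.log2((y / n_y) / (ref / n_r))
    a = 0.5 * np.log2((y / n_y) * (ref / n_r))
    w = (n_y - y) / (n_y * y) + (n_r - ref) / (n_r * ref)
    n = len(m)
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rm, ra = stats.rankdata(m), stats.rankdata(a)
    keep2 = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    return 2 ** (np.sum(m[keep2] / w[keep2]) / np.sum(1 / w[keep2]))


class TestTmmFactors:
    def test_identical_samples_give_unit_factors(self):
        counts = make_counts([[10, 10], [20, 20], [5, 5]], ["A", "B"])
        np.testing.assert_allclose(tmm_factors(counts), 1.0)

    def test_pure_depth_difference_gives_unit_factors(self):
        base = np.array([10, 20, 5, 40, 3, 17])
        counts = make_counts(np.column_stack([base, 2 * base]), ["A", "B"])
        np.testing.assert_allclose(tmm_factors(counts), 1.0)

    def test_matches_independent_trimmed_mean_oracle(self):
        rng = np.random.default_rng(11)
        y = rng.poisson(50, size=(30, 3)) + 1
        counts = make_counts(y, ["A", "A", "B"])
        f = tmm_factors(counts, ref_sample="s0")
        expected = np.array([1.0,
                             _tmm_oracle(y[:, 1], y[:, 0]),
                             _tmm_oracle(y[:, 2], y[:, 0])])
        expected /= np.exp(np.mean(np.log(expected)))
        np.testing.assert_allclose(f.to_numpy(), expected, atol=1e-10)

    def test_all_zero_sample_rejected(self):
        counts = make_counts([[1, 0], [2, 0]], ["A", "B"])
        with pytest.raises(ValidationError):
            tmm_factors(counts)


# ---------------------------------------------------------------------------
# NB exact test
# ---------------------------------------------------------------------------


def _binomial_split_oracle(y_a, total, n_a, n_b):
    """Poisson-limit conditional p: enumerate every split of the total."""
    prob = n_a / (n_a + n_b)
    pmf = np.array([stats.binom.pmf(a, total, prob)
                    for a in range(total + 1)])
    return pmf[pmf <= pmf[y_a] * (1 + 1e-12)].sum()


class TestNBExactTest:
    def test_identical_groups_give_p_one_and_zero_lfc(self):
        vals = np.array([[5, 7, 5, 7], [30, 10, 30, 10], [3, 3, 3, 3]])
        counts = make_counts(vals, ["A", "A", "B", "B"])
        table = nb_exact_test(counts, "A", "B", NBConfig(dispersion=0.1))
        np.testing.assert_allclose(table["p"], 1.0)
        np.testing.assert_allclose(table["log2fc"], 0.0, atol=1e-12)

    def test_poisson_limit_matches_full_enumeration(self):
        # constant background genes pin the TMM factors at exactly 1 and a
        # filler row equalizes library sizes, so pseudo-counts = raw counts
        test_rows = np.array([[3, 1, 9, 2],
                              [5, 6, 1, 7],
                              [2, 3, 0, 1],
                              [4, 4, 4, 4]])
        background = np.full((40, 4), 10)
        stack = np.vstack([test_rows, background])
        filler = stack.sum(axis=0).max() - stack.sum(axis=0)
        vals = np.vstack([stack, filler])
        counts = make_counts(vals, ["A", "A", "B", "B"])
        table = nb_exact_test(counts, "A", "B", NBConfig(dispersion=0.0))
        for i in range(4):
            y_a = int(vals[i, :2].sum())
            total = int(vals[i].sum())
            assert total <= 20
            oracle = _binomial_split_oracle(y_a, total, 2, 2)
            assert table["p"].iloc[i] == pytest.approx(oracle, abs=1e-10)

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(5)
        vals = rng.poisson(40, (20, 6))
        counts = make_counts(vals, ["A"] * 3 + ["B"] * 3)
        fwd = nb_exact_test(counts, "A", "B", NBConfig(dispersion=0.05))
        rev = nb_exact_test(counts, "B", "A", NBConfig(dispersion=0.05))
        np.testing.assert_allclose(fwd["p"], rev["p"], atol=1e-12)
        np.testing.assert_allclose(fwd["log2fc"], -rev["log2fc"], atol=1e-12)

    def test_planted_fold_changes_recovered(self):
        cfg = SimulationConfig(
            n_genes=400, seed=3,
            mouse=MouseSimConfig(n_shared_per_direction=15,
                                 n_model_specific=0, n_discordant=0,
                                 n_low_expressed=0))
        counts, tpm, truth = simulate_mouse_study(cfg)
        table = nb_exact_test(counts, "VT", "CHS")
        table = call_degs(table, 0.05, 2.0)
        planted = set(truth.mouse_shared_up) | set(truth.mouse_shared_down)
        hit = sum(1 for g in planted if table.loc[g, "call"] != "none")
        assert hit / len(planted) >= 0.9
        # planted genes dominate the smallest p-values
        top = set(table.nsmallest(len(planted), "p").index)
        assert len(top & planted) / len(planted) >= 0.8

    def test_single_group_rejected(self):
        counts = make_counts([[1, 2]], ["A", "A"])
        with pytest.raises(ValidationError):
            nb_exact_test(counts, "A", "B")


# ---------------------------------------------------------------------------
# SAM
# ---------------------------------------------------------------------------


class TestSamTest:
    def test_identical_group_means_give_zero_d(self):
        vals = np.array([[5.0, 6.0, 5.0, 6.0], [8.0, 7.0, 8.0, 7.0]])
        m = make_log_matrix(vals, ["A", "A", "B", "B"])
        table = sam_test(m, "A", "B", SAMConfig(n_perm=10, s0=0.0))
        np.testing.assert_allclose(table["statistic"], 0.0, atol=1e-12)

    def test_d_matches_hand_formula_3v3(self):
        rng = np.random.default_rng(9)
        vals = rng.normal(8, 1, (5, 6))
        m = make_log_matrix(vals, ["A"] * 3 + ["B"] * 3)
        table = sam_test(m, "A", "B", SAMConfig(n_perm=20, s0=0.1))
        for i in range(5):
            a, b = vals[i, :3], vals[i, 3:]
            pooled = (np.sum((a - a.mean()) ** 2) + np.sum((b - b.mean()) ** 2)) / 4
            s = math.sqrt((1 / 3 + 1 / 3) * pooled)
            d = (b.mean() - a.mean()) / (s + 0.1)
            assert table["statistic"].iloc[i] == pytest.approx(d, abs=1e-12)

    def test_d_with_zero_s0_equals_pooled_t(self):
        rng = np.random.default_rng(13)
        vals = rng.normal(0, 1, (8, 9))
        m = make_log_matrix(vals, ["A"] * 4 + ["B"] * 5)
        table = sam_test(m, "A", "B", SAMConfig(n_perm=10, s0=0.0))
        t = stats.ttest_ind(vals[:, 4:], vals[:, :4], axis=1, equal_var=True)
        np.testing.assert_allclose(table["statistic"], t.statistic,
                                   atol=1e-12)

    def test_4v4_enumerates_70_permutations_exactly(self):
        rng = np.random.default_rng(21)
        vals = rng.normal(8, 1, (6, 8))
        m = make_log_matrix(vals, ["A"] * 4 + ["B"] * 4)
        table = sam_test(m, "A", "B", SAMConfig(n_perm=1000, s0=0.05))
        # exhaustive oracle over all C(8,4)=70 label assignments
        combos = list(itertools.combinations(range(8), 4))
        assert len(combos) == 70
        for i in range(6):
            x = vals[i]
            def d_of(mask_b):
                b = x[list(mask_b)]
                a = x[[j for j in range(8) if j not in mask_b]]
                pooled = (np.sum((a - a.mean()) ** 2)
                          + np.sum((b - b.mean()) ** 2)) / 6
                s = math.sqrt((1 / 4 + 1 / 4) * pooled)
                return (b.mean() - a.mean()) / (s + 0.05)
            d_obs = d_of((4, 5, 6, 7))
            perm_d = np.array([d_of(c) for c in combos])
            oracle_p = np.mean(np.abs(perm_d) >= abs(d_obs) - 1e-12)
            assert table["p"].iloc[i] == pytest.approx(oracle_p, abs=1e-10)
        # full enumeration: p are exact multiples of 1/70
        np.testing.assert_allclose((table["p"] * 70) % 1, 0, atol=1e-9)

    def test_permutation_p_bounds_with_random_draws(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(0, 1, (30, 12))
        m = make_log_matrix(vals, ["A"] * 6 + ["B"] * 6)
        table = sam_test(m, "A", "B", SAMConfig(n_perm=99, seed=4))
        assert (table["p"] >= 1 / 100 - 1e-12).all()
        assert (table["p"] <= 1.0).all()

    def test_needs_two_samples_per_group(self):
        m = make_log_matrix([[1.0, 2.0, 3.0]], ["A", "B", "B"])
        with pytest.raises(ValidationError):
            sam_test(m, "A", "B")


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------


def _storey_oracle(p, lambda_grid):
    """Loop-based second implementation of the q-value estimator."""
    p = np.asarray(p)
    m = len(p)
    if m < 100:
        pi0 = min(1.0, 2.0 * p.mean())
    else:
        pi0_l = [(p > lam).mean() / (1 - lam) for lam in lambda_grid]
        coef = np.polyfit(lambda_grid, pi0_l, 3)
        pi0 = min(1.0, max(float(np.polyval(coef, max(lambda_grid))), 1e-8))
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    prev = np.inf
    for rank in range(m - 1, -1, -1):
        i = order[rank]
        val = min(prev, pi0 * p[i] * m / (rank + 1))
        q[i] = min(val, 1.0)
        prev = val
    return q


class TestMultipleTesting:
    def test_all_ones_stay_one(self):
        np.testing.assert_allclose(adjust_bh([1.0] * 5), 1.0)
        np.testing.assert_allclose(qvalues([1.0] * 5), 1.0)

    def test_bh_step_up_arithmetic(self):
        np.testing.assert_allclose(adjust_bh([0.01, 0.02, 0.03, 0.04]), 0.04)

    @pytest.mark.parametrize("n,seed", [(50, 0), (500, 1), (2000, 2)])
    def test_qvalues_match_independent_storey_oracle(self, n, seed):
        rng = np.random.default_rng(seed)
        p = np.concatenate([rng.uniform(0, 1, n - n // 5),
                            rng.uniform(0, 0.01, n // 5)])
        grid = np.arange(0.05, 0.96, 0.05)
        np.testing.assert_allclose(qvalues(p, grid), _storey_oracle(p, grid),
                                   atol=1e-12)

    def test_qvalues_are_pi0_scaled_bh(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(0, 1, 500)
        q = qvalues(p)
        bh = adjust_bh(p)
        assert (q <= 1.0 + 1e-12).all()
        # with one pi0 estimate the q-value is exactly pi0 * BH wherever
        # neither hits the cap at 1
        free = (q < 1) & (bh < 1) & (bh > 0)
        ratio = q[free] / bh[free]
        assert ratio.max() - ratio.min() < 1e-9
        assert 0 < ratio.min() <= 1 + 1e-12

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValidationError):
            qvalues([0.5, 1.2])
        with pytest.raises(ValidationError):
            adjust_bh([-0.1])


class TestCallDegs:
    @pytest.mark.parametrize("fdr,log2fc,expected", [
        (0.04, 1.5, "up"),     # passes both cutoffs
        (0.06, 3.0, "none"),   # FDR is strict
        (0.01, -0.9, "none"),  # |log2fc| <= 1 fails FC > 2
        (0.01, -1.5, "down"),
    ])
    def test_threshold_rules(self, fdr, log2fc, expected):
        table = pd.DataFrame({"log2fc": [log2fc], "statistic": [0.0],
                              "p": [fdr], "fdr": [fdr], "call": ["none"]},
                             index=["g"])
        out = call_degs(table, 0.05, 2.0)
        assert out["call"].iloc[0] == expected

    def test_call_direction_consistent_with_sign(self):
        rng = np.random.default_rng(1)
        table = pd.DataFrame({
            "log2fc": rng.normal(0, 2, 100), "statistic": 0.0,
            "p": rng.uniform(0, 1, 100), "fdr": rng.uniform(0, 1, 100),
            "call": "none"}, index=[f"g{i}" for i in range(100)])
        out = call_degs(table, 0.1, 1.5)
        assert (out.loc[out["call"] == "up", "log2fc"] > 0).all()
        assert (out.loc[out["call"] == "down", "log2fc"] < 0).all()
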