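"""Tests for the paired left/right expression screen."""

import numpy as np
import pandas as pd
import pytest

from asymscreen.screen import (CountMatrix, apply_thresholds,
                               classify_background, coexpression_fraction,
                               compute_flags, consensus_union, ma_statistics,
                               normalize_to_mean_coverage, p50_filter,
                               paired_lr_test, relative_expression_ddct)
from asymscreen.synthetic import CountSimParams, simulate_paired_counts
from conftest import make_count_matrix


class TestCountMatrix:
    def test_pairing_enforced(self):
        values = pd.DataFrame({"s1": [1], "s2": [2]},
                              index=pd.Index(["g0"], name="gene"))
        samples = pd.DataFrame([
            {"sample_id": "s1", "embryo_id": "e1", "side": "L", "stage": "x"},
            {"sample_id": "s2", "embryo_id": "e2", "side": "L", "stage": "x"},
        ])
        with pytest.raises(ValueError, match="unpaired"):
            CountMatrix(values, samples)

    def test_negative_counts_rejected(self):
        arr = np.array([[1.0, -2.0]])
        with pytest.raises(ValueError, match="nonnegative"):
            make_count_matrix(arr, n_pairs=1)


class TestNormalizeToMeanCoverage:
    def test_hand_arithmetic(self):
        # totals (100, 300): gene with raw (10, 30) -> (20, 20)
        arr = np.array([[10.0, 30.0], [90.0, 270.0]])
        norm = normalize_to_mean_coverage(make_count_matrix(arr, n_pairs=1))
        assert norm.values.iloc[0].tolist() == pytest.approx([20.0, 20.0])
        assert norm.normalized

    def test_equal_totals_unchanged(self):
        arr = np.array([[10.0, 20.0], [30.0, 20.0]])
        norm = normalize_to_mean_coverage(make_count_matrix(arr, n_pairs=1))
        assert np.allclose(norm.values.to_numpy(), arr)

    def test_column_sums_equal_mean_total(self, rng):
        arr = rng.integers(0, 500, size=(40, 8)).astype(float)
        arr[0] += 1  # no zero-total columns
        raw = make_count_matrix(arr, n_pairs=4)
        norm = normalize_to_mean_coverage(raw)
        target = arr.sum(axis=0).mean()
        assert np.allclose(norm.values.sum(axis=0), target, rtol=1e-9)

    def test_grand_total_conserved(self, rng):
        arr = rng.integers(1, 100, size=(25, 6)).astype(float)
        norm = normalize_to_mean_coverage(make_count_matrix(arr, n_pairs=3))
        assert norm.values.to_numpy().sum() == pytest.approx(arr.sum())

    def test_zero_total_sample_named(self):
        arr = np.zeros((3, 2))
        arr[:, 0] = 5.0
        with pytest.raises(ValueError, match="embryo_1_R"):
            normalize_to_mean_coverage(make_count_matrix(arr, n_pairs=1))


class TestFlagsAndFilters:
    def test_boundary_inclusive(self):
        arr = np.array([[20.0, 19.999]])
        norm = make_count_matrix(arr, n_pairs=1, normalized=True)
        flags = compute_flags(norm)
        assert flags.iloc[0].tolist() == [1, 0]

    def test_all_zero_gene(self):
        arr = np.zeros((1, 4))
        flags = compute_flags(make_count_matrix(arr, n_pairs=2, normalized=True))
        assert flags.iloc[0].sum() == 0

    def test_flags_equal_brute_force(self, rng):
        arr = rng.uniform(0, 60, size=(50, 8))
        norm = make_count_matrix(arr, n_pairs=4, normalized=True)
        flags = compute_flags(norm)
        assert np.array_equal(flags.to_numpy(), (arr >= 20).astype(int))

    @pytest.mark.parametrize("s,n_flagged,kept", [
        (8, 4, True), (8, 3, False), (7, 4, True), (7, 3, False)])
    def test_p50_ceil_rule(self, s, n_flagged, kept):
        flags = pd.DataFrame([[1] * n_flagged + [0] * (s - n_flagged)],
                             index=["g0"])
        assert (("g0" in p50_filter(flags)) is kept)

    def test_p50_idempotent_and_brute_force(self, rng):
        flags = pd.DataFrame(rng.integers(0, 2, size=(60, 8)),
                             index=[f"g{i}" for i in range(60)])
        keep = p50_filter(flags)
        brute = {g for g in flags.index if flags.loc[g].sum() >= 4}
        assert keep == brute

    def test_threshold_boundaries_inclusive(self):
        res = pd.DataFrame({"fold_change": [1.2, 1.19], "p_value": [0.05, 0.001]},
                           index=["a", "b"])
        assert apply_thresholds(res) == {"a"}

    def test_thresholds_equal_brute_force(self, rng):
        res = pd.DataFrame({"fold_change": rng.uniform(1, 2, 200),
                            "p_value": rng.uniform(0, 0.2, 200)},
                           index=[f"g{i}" for i in range(200)])
        kept = apply_thresholds(res)
        brute = {g for g in res.index
                 if res.at[g, "fold_change"] >= 1.2 and res.at[g, "p_value"] <= 0.05}
        assert kept == brute

    def test_consensus_union(self):
        assert consensus_union([{"a", "b"}, {"b", "c"}]) == {"a", "b", "c"}
        assert consensus_union([{"a"}]) == {"a"}
        assert len(consensus_union([{"a"}, {"b"}, {"c"}])) == 3
        with pytest.raises(ValueError):
            consensus_union([])


class TestPairedLrTest:
    def test_equal_sides_null(self):
        arr = np.tile(np.array([[30.0, 30.0]]), (1, 4))
        norm = make_count_matrix(arr, n_pairs=4, normalized=True)
        res = paired_lr_test(norm)
        assert res["mean_log2_ratio"].iloc[0] == 0
        assert res["p_value"].iloc[0] == pytest.approx(1.0)

    def test_classical_t_oracle(self, rng):
        # moderation disabled -> classical paired t on the log differences
        from scipy import stats as sps
        arr = rng.integers(10, 300, size=(30, 8)).astype(float)
        norm = make_count_matrix(arr, n_pairs=4, normalized=True)
        res = paired_lr_test(norm, prior_df=0)
        d = np.log2(arr[:, 0::2] + 0.5) - np.log2(arr[:, 1::2] + 0.5)
        t_ref = d.mean(axis=1) / np.sqrt(d.var(axis=1, ddof=1) / 4)
        p_ref = 2 * sps.t.sf(np.abs(t_ref), 3)
        assert res["t_statistic"].to_numpy() == pytest.approx(t_ref)
        assert res["p_value"].to_numpy() == pytest.approx(p_ref)

    def test_missing_side_rejected(self):
        values = pd.DataFrame({"s1": [1.0], "s2": [2.0]},
                              index=pd.Index(["g0"], name="gene"))
        samples = pd.DataFrame([
            {"sample_id": "s1", "embryo_id": "e1", "side": "L", "stage": "x"},
            {"sample_id": "s2", "embryo_id": "e1", "side": "R", "stage": "x"},
        ])
        cm = CountMatrix(values, samples, normalized=True)
        with pytest.raises(ValueError, match="at least 2"):
            paired_lr_test(cm)

    def test_true_positives_rank_ahead_of_nulls(self):
        # asymmetric genes get systematically smaller p in every seed
        for seed in range(20):
            m, truth = simulate_paired_counts(CountSimParams(
                n_genes=500, n_pairs=4, n_asym=25, asym_fold=2.0,
                baseline_mean=200, log_sd=0.5, dispersion=0.05, seed=seed))
            res = paired_lr_test(normalize_to_mean_coverage(m))
            true = res.index.isin(truth["asym_genes"])
            assert (np.median(res.loc[true, "p_value"])
                    < np.median(res.loc[~true, "p_value"]))

    def test_bh_column_monotone_in_sorted_p(self, rng):
        arr = rng.integers(5, 400, size=(80, 8)).astype(float)
        res = paired_lr_test(make_count_matrix(arr, n_pairs=4, normalized=True))
        srt = res.sort_values("p_value")
        assert np.all(np.diff(srt["bh_adjusted_p"]) >= -1e-12)
        assert np.all(srt["bh_adjusted_p"] >= srt["p_value"] - 1e-12)
        assert np.all(res["fold_change"] >= 1.0)

    def test_sensitivity_monotone_in_n_pairs(self):
        sens = []
        for n_pairs in (3, 6):
            hits = total = 0
            for seed in range(3):
                m, truth = simulate_paired_counts(CountSimParams(
                    n_genes=400, n_pairs=n_pairs, n_asym=40, asym_fold=1.6,
                    baseline_mean=80, log_sd=0.5, dispersion=0.15, seed=seed))
                res = paired_lr_test(normalize_to_mean_coverage(m))
                kept = apply_thresholds(res)
                hits += len(kept & set(truth["asym_genes"]))
                total += len(truth["asym_genes"])
            sens.append(hits / total)
        assert sens[1] >= sens[0]


class TestMAStatistics:
    def test_constant_gene(self):
        arr = np.full((1, 8), 12.0)
        ma = ma_statistics(make_count_matrix(arr, n_pairs=4, normalized=True))
        assert ma["A"].iloc[0] == pytest.approx(np.log2(12.5))
        assert ma["M"].iloc[0] == 0

    def test_exact_doubling(self, rng):
        right = rng.uniform(10, 100, size=(20, 4))
        arr = np.empty((20, 8))
        arr[:, 0::2] = 2 * right
        arr[:, 1::2] = right
        ma = ma_statistics(make_count_matrix(arr, n_pairs=4, normalized=True),
                           pseudocount=0.0)
        assert ma["M"].to_numpy() == pytest.approx(np.ones(20))
        assert len(ma) == 20


class TestUtilities:
    def test_background_boundary(self):
        labels = classify_background([5.6, 5.599, 0.0, 100.0])
        assert labels.tolist() == [False, True, True, False]

    def test_background_brute_force(self, rng):
        v = rng.uniform(0, 12, size=200)
        assert np.array_equal(classify_background(v), v < 5.6)

    def test_coexpression_printed_counts(self):
        # 309 A-positive cells, 234 of them B-positive
        expr = pd.DataFrame({
            "A": [1.0] * 309 + [0.0] * 41,
            "B": [1.0] * 234 + [0.0] * (309 - 234) + [1.0] * 41,
        })
        n_a, n_both, frac = coexpression_fraction(expr, "A", "B")
        assert (n_a, n_both) == (309, 234)
        assert frac == pytest.approx(234 / 309)

    def test_coexpression_edges(self):
        expr = pd.DataFrame({"A": [1.0, 2.0], "B": [0.0, 0.0]})
        assert coexpression_fraction(expr, "A", "B")[2] == 0.0
        expr = pd.DataFrame({"A": [1.0, 2.0], "B": [3.0, 1.0]})
        assert coexpression_fraction(expr, "A", "B")[2] == 1.0
        expr = pd.DataFrame({"A": [0.0], "B": [1.0]})
        with pytest.raises(ZeroDivisionError):
            coexpression_fraction(expr, "A", "B")

    def test_ddct(self):
        records = pd.DataFrame({
            "sample_id": ["cal", "s1"],
            "ct_target": [22.0, 20.0],
            "ct_reference": [20.0, 19.0],
        })
        rel = relative_expression_ddct(records, "cal")
        assert rel["cal"] == pytest.approx(1.0)
        # sample dCt = 1, calibrator dCt = 2 -> 2^(1) = 2
        assert rel["s1"] == pytest.approx(2.0)

    def test_ddct_cycle_shift_halves(self):
        records = pd.DataFrame({
            "sample_id": ["cal", "s1", "s2"],
            "ct_target": [20.0, 21.0, 22.0],
            "ct_reference": [20.0, 20.0, 20.0],
        })
        rel = relative_expression_ddct(records, "cal")
        assert rel["s2"] == pytest.approx(rel["s1"] / 2.0)

    def test_ddct_missing_calibrator(self):
        records = pd.DataFrame({"sample_id": ["s1"], "ct_target": [20.0],
                                "ct_reference": [19.0]})
        with pytest.raises(KeyError):
            relative_expression_ddct(records, "cal")
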