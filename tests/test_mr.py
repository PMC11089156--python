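"""MR estimators against hand arithmetic and brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pharmsignal import mr
from pharmsignal.synthetic import GwasSimConfig, simulate_gwas_pair


def make_instr(ratios, weights=None, beta_x=None, se_x=1e-8):
    """Instrument frame with prescribed Wald ratios and IVW weights.

    beta_x defaults to 1 so beta_y equals the ratio; se_y is chosen so
    that 1/ratio_se^2 equals the requested weight.
    """
    ratios = np.asarray(ratios, float)
    n = len(ratios)
    bx = np.ones(n) if beta_x is None else np.asarray(beta_x, float)
    w = np.ones(n) if weights is None else np.asarray(weights, float)
    se_y = np.abs(bx) / np.sqrt(w)
    by = ratios * bx
    return pd.DataFrame({
        "snp": [f"s{j}" for j in range(n)],
        "beta_x": bx, "se_x": se_x, "beta_y": by, "se_y": se_y,
        "wald_ratio": by / bx, "ratio_se": se_y / np.abs(bx),
    })


class TestSelectInstruments:
    def test_threshold_filters(self):
        df = pd.DataFrame({"snp": list("abcde"),
                           "pval": [1e-9, 1e-3, 4e-8, 0.5, 1e-10]})
        out = mr.select_instruments(df, p_threshold=5e-8)
        assert sorted(out["snp"]) == ["a", "c", "e"]

    def test_no_positions_warns_and_keeps_all(self, caplog):
        df = pd.DataFrame({"snp": ["a", "b"], "pval": [1e-9, 1e-9]})
        with caplog.at_level("WARNING"):
            out = mr.select_instruments(df)
        assert len(out) == 2
        assert any("not distance-pruned" in r.getMessage() for r in caplog.records)

    def test_zero_survivors_is_hard_error(self):
        df = pd.DataFrame({"snp": ["a"], "pval": [0.9]})
        with pytest.raises(ValueError, match="threshold"):
            mr.select_instruments(df)

    def test_recovers_generator_truth(self, gwas_fixture):
        out = mr.select_instruments(gwas_fixture["exposure"])
        assert sorted(out["snp"]) == sorted(gwas_fixture["truth"]["significant_snps"])

    def test_distance_pruning_keeps_best_per_window(self):
        df = pd.DataFrame({
            "snp": ["a", "b", "c"], "chr": [1, 1, 1],
            "pos": [100_000, 600_000, 5_000_000],
            "pval": [1e-10, 1e-9, 1e-9],
        })
        out = mr.select_instruments(df, prune_window_kb=1000)
        assert sorted(out["snp"]) == ["a", "c"]  # b within 1Mb of the better a


class TestHarmonize:
    def _frame(self, snp, ea, oa, beta, se=0.1, pval=1e-9):
        return pd.DataFrame({"snp": [snp], "effect_allele": [ea],
                             "other_allele": [oa], "beta": [beta],
                             "se": [se], "pval": [pval]})

    def test_swapped_alleles_flip_outcome_beta(self):
        instr = mr.harmonize(self._frame("rs1", "A", "G", 0.1),
                             self._frame("rs1", "G", "A", -0.2))
        assert instr["beta_y"].iloc[0] == pytest.approx(0.2)
        assert instr["wald_ratio"].iloc[0] == pytest.approx(2.0)

    def test_palindromic_dropped_by_default(self):
        instr = mr.harmonize(self._frame("rs1", "A", "T", 0.1),
                             self._frame("rs1", "A", "T", 0.2))
        assert instr.empty

    def test_strand_complement_accepted(self):
        instr = mr.harmonize(self._frame("rs1", "A", "G", 0.1),
                             self._frame("rs1", "T", "C", 0.2))
        assert instr["beta_y"].iloc[0] == pytest.approx(0.2)

    def test_irreconcilable_alleles_dropped_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            instr = mr.harmonize(self._frame("rs1", "A", "G", 0.1),
                                 self._frame("rs1", "A", "C", 0.2))
        assert instr.empty

    def test_negative_exposure_beta_reoriented(self):
        instr = mr.harmonize(self._frame("rs1", "A", "G", -0.1),
                             self._frame("rs1", "A", "G", 0.2))
        assert instr["beta_x"].iloc[0] == pytest.approx(0.1)
        assert instr["beta_y"].iloc[0] == pytest.approx(-0.2)
        assert instr["wald_ratio"].iloc[0] == pytest.approx(-2.0)

    def test_generated_swaps_all_undone(self, gwas_fixture):
        exp, out = gwas_fixture["exposure"], gwas_fixture["outcome"]
        truth = gwas_fixture["truth"]
        instr = mr.harmonize(exp, out)
        assert len(instr) == len(exp)  # nothing lost, swaps resolved
        swapped = set(truth["swapped_snps"])
        unswapped_by = np.where(out["snp"].isin(swapped), -out["beta"], out["beta"])
        expected_ratio = unswapped_by / exp["beta"].to_numpy()
        got = instr.set_index("snp")["wald_ratio"]
        for snp, exp_r in zip(exp["snp"], expected_ratio):
            assert got[snp] == pytest.approx(exp_r, rel=1e-12)


class TestIvw:
    def test_single_instrument_is_wald_ratio(self):
        res = mr.ivw(make_instr([2.0], weights=[1.0]))
        assert res.beta == pytest.approx(2.0)
        assert res.se == pytest.approx(1.0)

    def test_two_instrument_hand_arithmetic(self):
        instr = make_instr([2.0, 4.0], weights=[1.0, 0.25])
        res = mr.ivw(instr)
        assert res.beta == pytest.approx(2.4)
        assert res.se == pytest.approx(1 / np.sqrt(1.25))  # Q/df < 1: fixed SE
        q = mr.cochran_q(instr, "ivw")
        assert q.q == pytest.approx(0.8)
        assert q.q_df == 1

    def test_orientation_flip_invariance(self):
        rng = np.random.default_rng(0)
        instr = make_instr(rng.normal(0.5, 0.2, 10), weights=rng.uniform(0.5, 2, 10),
                           beta_x=rng.uniform(0.1, 0.3, 10))
        flipped = instr.copy()
        flipped.loc[::2, ["beta_x", "beta_y"]] *= -1
        flipped["wald_ratio"] = flipped["beta_y"] / flipped["beta_x"]
        flipped["ratio_se"] = flipped["se_y"] / flipped["beta_x"].abs()
        assert mr.ivw(flipped).beta == pytest.approx(mr.ivw(instr).beta, rel=1e-12)

    def test_matches_egger_through_origin(self):
        """IVW equals the no-intercept weighted regression of beta_y on
        beta_x with weights 1/se_y^2 (multiplicative-weights identity)."""
        rng = np.random.default_rng(5)
        bx = rng.uniform(0.05, 0.3, 20)
        by = 0.5 * bx + rng.normal(0, 0.02, 20)
        sy = rng.uniform(0.01, 0.05, 20)
        instr = pd.DataFrame({"snp": range(20), "beta_x": bx, "se_x": 1e-8,
                              "beta_y": by, "se_y": sy,
                              "wald_ratio": by / bx, "ratio_se": sy / bx})
        w = 1 / sy**2
        slope = np.sum(w * bx * by) / np.sum(w * bx**2)
        assert mr.ivw(instr, model="fixed").beta == pytest.approx(slope, abs=1e-9)


class TestEgger:
    def test_exact_linear_fit(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        by = 0.5 + 1.5 * bx
        instr = pd.DataFrame({"snp": range(4), "beta_x": bx, "se_x": 1e-8,
                              "beta_y": by, "se_y": 0.1,
                              "wald_ratio": by / bx, "ratio_se": 0.1 / bx})
        est, pleio = mr.mr_egger(instr)
        assert est.beta == pytest.approx(1.5, abs=1e-9)
        assert pleio.intercept == pytest.approx(0.5, abs=1e-9)
        assert mr.cochran_q(instr, "egger").q == pytest.approx(0.0, abs=1e-12)

    def test_against_normal_equations_oracle(self):
        """Slope/intercept/SEs match an explicit weighted normal-equations
        solve (with the residual-scale floor at 1) to 1e-10."""
        bx = np.array([0.10, 0.15, 0.22, 0.31])
        by = np.array([0.04, 0.09, 0.05, 0.18])
        sy = np.array([0.02, 0.03, 0.025, 0.04])
        instr = pd.DataFrame({"snp": range(4), "beta_x": bx, "se_x": 1e-8,
                              "beta_y": by, "se_y": sy,
                              "wald_ratio": by / bx, "ratio_se": sy / bx})
        est, pleio = mr.mr_egger(instr)

        # oracle: beta = (X'WX)^-1 X'Wy ; cov = max(1, sigma^2) (X'WX)^-1
        X = np.column_stack([np.ones(4), bx])
        W = np.diag(1 / sy**2)
        xtwx_inv = np.linalg.inv(X.T @ W @ X)
        beta_hat = xtwx_inv @ X.T @ W @ by
        resid = by - X @ beta_hat
        sigma2 = (resid @ W @ resid) / (4 - 2)
        cov = max(1.0, sigma2) * xtwx_inv
        assert pleio.intercept == pytest.approx(beta_hat[0], abs=1e-10)
        assert est.beta == pytest.approx(beta_hat[1], abs=1e-10)
        assert pleio.se == pytest.approx(np.sqrt(cov[0, 0]), abs=1e-10)
        assert est.se == pytest.approx(np.sqrt(cov[1, 1]), abs=1e-10)

    def test_too_few_instruments_errors(self):
        with pytest.raises(ValueError, match="3"):
            mr.mr_egger(make_instr([1.0, 2.0]))


class TestWeightedMedian:
    def test_equal_weights_is_plain_median(self):
        res = mr.weighted_median(make_instr([1.0, 2.0, 3.0]), n_boot=50)
        assert res.beta == pytest.approx(2.0)

    def test_hand_interpolation(self):
        res = mr.weighted_median(make_instr([1.0, 2.0, 10.0],
                                            weights=[0.25, 0.25, 0.5]), n_boot=50)
        assert res.beta == pytest.approx(2 + 8 * (0.5 - 0.375) / (0.75 - 0.375))

    def test_identical_ratios_zero_se(self):
        instr = make_instr([3.0, 3.0, 3.0], weights=[1e16, 1e16, 1e16])
        res = mr.weighted_median(instr, n_boot=100, seed=0)
        assert res.beta == pytest.approx(3.0)
        assert res.se < 1e-6

    def test_equal_weights_match_sample_median_odd_n(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            ratios = rng.normal(0, 1, 7)
            res = mr.weighted_median(make_instr(ratios), n_boot=10)
            assert res.beta == pytest.approx(np.median(ratios), abs=1e-12)

    def test_against_interpolated_quantile_oracle(self):
        """Point estimate equals a from-scratch cumulative-midpoint quantile
        interpolation on random weighted sets."""
        rng = np.random.default_rng(4)
        for _ in range(50):
            ratios = rng.normal(0.5, 1.0, 9)
            weights = rng.uniform(0.1, 2.0, 9)
            got = mr.weighted_median(make_instr(ratios, weights), n_boot=10).beta
            order = np.argsort(ratios)
            r, w = ratios[order], weights[order] / weights.sum()
            p = np.cumsum(w) - 0.5 * w
            assert got == pytest.approx(np.interp(0.5, p, r), abs=1e-12)


class TestModes:
    def test_dominant_cluster_is_simple_mode(self):
        simple, _ = mr.mode_estimators(make_instr([2.0, 2.0, 2.0, 5.0]), n_boot=50)
        assert simple.beta == pytest.approx(2.0, abs=0.05)

    def test_against_grid_search_oracle(self):
        """Mode equals a dense independent grid search over the same
        weighted normal-kernel density, to grid resolution."""
        ratios = np.array([0.2, 0.5, 0.55, 0.6, 1.4])
        weights = np.array([1.0, 2.0, 2.0, 2.0, 1.0])
        instr = make_instr(ratios, weights)
        simple, weighted = mr.mode_estimators(instr, n_boot=10)

        def oracle(r, w):
            s = np.std(r, ddof=1)
            mad = np.median(np.abs(r - np.median(r))) / 0.6745
            h = 0.9 * min(s, mad if mad > 0 else s) * len(r) ** (-0.2)
            grid = np.linspace(r.min() - 3 * h, r.max() + 3 * h, 200_001)
            dens = sum(wj * stats.norm.pdf(grid, rj, h) for rj, wj in zip(r, w))
            return grid[np.argmax(dens)]

        assert simple.beta == pytest.approx(oracle(ratios, np.ones(5)), abs=2e-3)
        assert weighted.beta == pytest.approx(oracle(ratios, weights), abs=2e-3)

    def test_weight_concentration_flips_weighted_mode(self):
        """IVW weights piled on the minority cluster move the weighted mode
        there while the simple mode stays with the majority."""
        ratios = [1.0, 1.01, 0.99, 5.0, 5.01]
        weights = [0.1, 0.1, 0.1, 50.0, 50.0]
        simple, weighted = mr.mode_estimators(make_instr(ratios, weights), n_boot=10)
        assert simple.beta == pytest.approx(1.0, abs=0.2)
        assert weighted.beta == pytest.approx(5.0, abs=0.2)


class TestDiagnostics:
    def test_homogeneous_ratios_q_zero(self):
        q = mr.cochran_q(make_instr([2.0, 2.0, 2.0]), "ivw")
        assert q.q == pytest.approx(0.0, abs=1e-18)
        assert q.q_pval == pytest.approx(1.0)

    def test_leave_one_out_identical_instruments(self):
        loo = mr.leave_one_out(make_instr([2.0, 2.0, 2.0]))
        assert loo["beta"].nunique() == 1
        assert not loo["flips_sign"].any()

    def test_leave_one_out_flags_outlier(self):
        instr = make_instr([0.5, 0.52, 0.48, 0.51, 5.0])
        loo = mr.leave_one_out(instr)
        full = mr.ivw(instr).beta
        deltas = (loo["beta"] - full).abs()
        assert deltas.idxmax() == 4  # dropping the outlier moves the estimate most

    def test_two_instruments_give_single_wald_ratios(self):
        loo = mr.leave_one_out(make_instr([2.0, 6.0]))
        assert sorted(loo["beta"]) == [2.0, 6.0]

    def test_funnel_scatter_schema_and_symmetry(self):
        # symmetric ratios about 1.0 with equal weights
        instr = make_instr([0.6, 0.8, 1.2, 1.4])
        fits = {"ivw": mr.ivw(instr, model="fixed")}
        scatter, lines, funnel = mr.funnel_scatter_data(instr, fits)
        assert list(scatter.columns) == ["snp", "beta_x", "se_x", "beta_y", "se_y"]
        assert set(lines.columns) == {"method", "intercept", "slope"}
        assert {"snp", "wald_ratio", "precision", "ivw_beta"} <= set(funnel.columns)
        centred = funnel["wald_ratio"] - funnel["ivw_beta"]
        assert centred.sum() == pytest.approx(0.0, abs=1e-12)

    def test_or_consistency(self):
        res = mr.ivw(make_instr([2.0, 4.0], weights=[1.0, 0.25]))
        assert res.or_ == pytest.approx(np.exp(res.beta))


class TestEndToEnd:
    def test_noiseless_limit_recovers_truth(self):
        cfg = GwasSimConfig(se_y=1e-6, se_x=1e-8, pleiotropy_mean=0,
                            pleiotropy_sd=0, het_sd=0, swap_fraction=0.3, seed=5)
        exp, out, truth = simulate_gwas_pair(cfg)
        instr = mr.harmonize(exp, out)
        res = mr.ivw(instr)
        assert res.beta == pytest.approx(truth["true_beta"], abs=1e-3)

    def test_bootstrap_seed_reproducibility(self, gwas_fixture):
        instr = mr.harmonize(gwas_fixture["exposure"], gwas_fixture["outcome"])
        a = mr.weighted_median(instr, n_boot=200, seed=42)
        b = mr.weighted_median(instr, n_boot=200, seed=42)
        assert a.se == b.se
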