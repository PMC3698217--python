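import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from stimdur.de import (
    TimecourseDE,
    WindowError,
    WindowModelFit,
    bh_adjust,
    estimate_prior,
    fit_window_model,
    moderated_f,
)
from tests.conftest import make_ratio_dataset


def bh_oracle(p):
    """Brute-force Benjamini-Hochberg step-up."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        adj[i] = running
    return adj


class TestWindowModel:
    def test_identical_arms_give_zero_contrasts(self):
        rng = np.random.default_rng(0)
        matrix, sheet = make_ratio_dataset(20, (6.0, 8.0, 10.0), 2, rng, sigma_per_gene=0.0)
        fit = fit_window_model(matrix, sheet, "main")
        assert np.abs(fit.beta.to_numpy()).max() <= 1e-12
        assert np.abs(fit.s2).max() <= 1e-24

    def test_exact_unit_shift_recovered_noiselessly(self):
        rng = np.random.default_rng(1)
        times = (6.0, 8.0, 10.0)
        signal = {("transient", t): pd.Series(1.0, index=[f"g{i:04d}" for i in range(10)])
                  for t in times}
        matrix, sheet = make_ratio_dataset(10, times, 2, rng,
                                           sigma_per_gene=0.0, signal=signal)
        fit = fit_window_model(matrix, sheet, "main")
        assert np.allclose(fit.beta.to_numpy(), 1.0, atol=1e-12)
        assert np.abs(fit.s2).max() <= 1e-24

    def test_matches_brute_force_ols(self):
        # 3 genes, 2 shared times, 2 replicates, noisy: compare against
        # normal equations assembled by hand, observation by observation
        rng = np.random.default_rng(2)
        times = (6.0, 8.0)
        matrix, sheet = make_ratio_dataset(3, times, 2, rng, sigma_per_gene=0.5)
        fit = fit_window_model(matrix, sheet, "main")

        meta = sheet.set_index("sample_id")
        cells = sorted({(c, t) for c, t in zip(meta.condition, meta.time_h)
                        if c != "untreated"})
        for g in matrix.index:
            rows, ys = [], []
            for c, t in cells:
                for rep in (1, 2):
                    treated = f"{c}:t{t:g}:r{rep}"
                    ref = f"untreated:t{t:g}:r{rep}"
                    x = np.zeros(len(cells))
                    x[cells.index((c, t))] = 1.0
                    rows.append(x)
                    ys.append(matrix.loc[g, treated] - matrix.loc[g, ref])
            x = np.array(rows)
            y = np.array(ys)
            coef = np.linalg.solve(x.T @ x, x.T @ y)
            resid = y - x @ coef
            df = len(y) - len(coef)
            s2 = resid @ resid / df
            for k, t in enumerate(times):
                expect = coef[cells.index(("transient", t))] - coef[cells.index(("sustained", t))]
                assert abs(fit.beta.loc[g, t] - expect) <= 1e-9
            assert abs(fit.s2[g] - s2) <= 1e-9
            assert fit.df == df

    def test_window_errors_name_the_window(self):
        rng = np.random.default_rng(3)
        matrix, sheet = make_ratio_dataset(5, (6.0, 8.0), 2, rng)
        with pytest.raises(WindowError, match="early"):
            fit_window_model(matrix, sheet, "early")
        matrix1, sheet1 = make_ratio_dataset(5, (6.0, 8.0), 1, rng)
        with pytest.raises(WindowError, match="main"):
            fit_window_model(matrix1, sheet1, "main")  # zero residual df


class TestPriorEstimation:
    def test_recovers_scaled_inv_chisq_parameters(self):
        rng = np.random.default_rng(42)
        d0_true, s0_true, d = 4.0, 0.05, 6
        sigma2 = s0_true * d0_true / rng.chisquare(d0_true, size=2000)
        s2 = sigma2 * rng.chisquare(d, size=2000) / d
        d0, s0 = estimate_prior(s2, d)
        assert abs(d0 - d0_true) / d0_true <= 0.25
        assert abs(s0 - s0_true) / s0_true <= 0.10

    def test_matches_limma_fitFDist(self):
        rng = np.random.default_rng(42)
        sigma2 = 0.05 * 4.0 / rng.chisquare(4.0, size=200)
        s2 = sigma2 * rng.chisquare(6, size=200) / 6
        d0, s0 = estimate_prior(s2, 6)
        rcode = (
            "suppressMessages(library(limma)); s2 <- c(%s); "
            "f <- limma:::fitFDist(s2, df1=6); cat(f$df2, f$scale, sep='\\n')"
            % ",".join("%.17g" % v for v in s2)
        )
        out = subprocess.run(["Rscript", "-e", rcode],
                             capture_output=True, text=True, check=True)
        d0_ref, s0_ref = (float(x) for x in out.stdout.split())
        assert abs(d0 - d0_ref) / d0_ref <= 1e-5
        assert abs(s0 - s0_ref) / s0_ref <= 1e-5

    def test_constant_variances_flag_infinite_d0(self):
        d0, s0 = estimate_prior(np.full(50, 0.3), 6)
        assert np.isinf(d0)
        assert s0 == pytest.approx(0.3, abs=1e-12)

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValueError, match=">= 10"):
            estimate_prior(np.array([0.1] * 5), 6)

    def test_all_zero_variances_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            estimate_prior(np.zeros(50), 6)


def _toy_fit(beta, cov_unscaled, s2, df, times=None):
    beta = np.atleast_2d(beta)
    times = times if times is not None else list(range(beta.shape[1]))
    return WindowModelFit(
        window="main", times=times,
        beta=pd.DataFrame(beta, index=[f"g{i}" for i in range(beta.shape[0])],
                          columns=times),
        s2=pd.Series(np.atleast_1d(s2), index=[f"g{i}" for i in range(beta.shape[0])]),
        df=df, cov_unscaled=np.atleast_2d(cov_unscaled),
    )


class TestModeratedF:
    def test_d0_zero_reduces_to_ordinary_f(self):
        rng = np.random.default_rng(7)
        n, k, df = 40, 3, 5
        beta = rng.normal(size=(n, k))
        a = rng.normal(size=(k, k))
        cov = a @ a.T + np.eye(k)
        s2 = rng.chisquare(df, size=n) / df
        fit = _toy_fit(beta, cov, s2, df)
        tab = moderated_f(fit, (0.0, 1.0))
        ci = np.linalg.inv(cov)
        f_ord = np.einsum("gi,ij,gj->g", beta, ci, beta) / k / s2
        assert np.abs(tab["F"].to_numpy() - f_ord).max() <= 1e-9
        p_ord = stats.f.sf(f_ord, k, df)
        assert np.abs(tab["p"].to_numpy() - p_ord).max() <= 1e-9

    def test_infinite_d0_matches_chi2_tail(self):
        rng = np.random.default_rng(8)
        beta = rng.normal(size=(20, 2))
        fit = _toy_fit(beta, np.eye(2), rng.chisquare(4, 20) / 4, 4)
        tab = moderated_f(fit, (np.inf, 1.0))
        quad = (beta ** 2).sum(axis=1)
        p_chi = stats.chi2.sf(quad, 2)
        assert np.abs(tab["p"].to_numpy() - p_chi).max() <= 1e-9

    def test_hand_computed_single_gene(self):
        # k=1, beta=2, unscaled var 0.5, posterior s2=1, total df 10 -> F=8
        fit = _toy_fit([[2.0]], [[0.5]], [1.0], 6)
        tab = moderated_f(fit, (4.0, 1.0))
        assert abs(tab["F"].iloc[0] - 8.0) <= 1e-12
        assert abs(tab["p"].iloc[0] - stats.f.sf(8.0, 1, 10)) <= 1e-12

    def test_moderation_shrinks_toward_prior(self):
        rng = np.random.default_rng(9)
        s2 = rng.chisquare(4, 100) / 4
        fit = _toy_fit(rng.normal(size=(100, 2)), np.eye(2), s2, 4)
        d0, s0 = 3.0, 0.8
        tab = moderated_f(fit, (d0, s0))
        assert (np.abs(tab["s2_post"] - s0) <= np.abs(tab["s2"] - s0) + 1e-12).all()
        lo = np.minimum(tab["s2"], s0)
        hi = np.maximum(tab["s2"], s0)
        assert ((tab["s2_post"] >= lo - 1e-12) & (tab["s2_post"] <= hi + 1e-12)).all()


class TestBH:
    def test_hand_computed_step_up(self):
        p = [0.01, 0.02, 0.03, 0.04, 0.05]
        assert np.allclose(bh_adjust(p), [0.05] * 5)

    @pytest.mark.parametrize("p,expected", [
        ([0.2], [0.2]),
        ([1.0, 1.0, 1.0], [1.0, 1.0, 1.0]),
    ])
    def test_boundary_cases(self, p, expected):
        assert np.allclose(bh_adjust(p), expected)

    def test_exhaustive_small_lists_match_oracle(self):
        grid = [0.0, 0.01, 0.04, 0.2, 0.5, 0.8, 1.0]
        from itertools import product
        for n in (1, 2, 3):
            for combo in product(grid, repeat=n):
                assert np.allclose(bh_adjust(list(combo)), bh_oracle(combo)), combo

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=8))
    def test_random_lists_match_oracle_and_order_invariance(self, p):
        adj = bh_adjust(p)
        assert np.allclose(adj, bh_oracle(p))
        perm = np.random.default_rng(0).permutation(len(p))
        adj_perm = bh_adjust(np.asarray(p)[perm])
        assert np.allclose(adj_perm, adj[perm])

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestCallDifferential:
    def test_identical_arms_yield_no_calls(self):
        rng = np.random.default_rng(12)
        times = (1.5, 2.0, 3.0, 4.0, 6.0, 8.0, 10.0, 14.0)
        matrix, sheet = make_ratio_dataset(300, times, 2, rng, sigma_per_gene=0.15)
        res = TimecourseDE(matrix, sheet).fit(alpha=0.05)
        # null data: expected false calls ~ alpha-level; loose 3x bound
        assert res.significant.sum() <= 0.05 * 300 * 3

    def test_alpha_zero_calls_nothing(self):
        rng = np.random.default_rng(13)
        matrix, sheet = make_ratio_dataset(50, (2.0, 3.0, 6.0, 8.0), 2, rng)
        res = TimecourseDE(matrix, sheet).fit(alpha=0.0)
        assert res.significant.sum() == 0

    def test_late_signal_called_lower_in_transient(self):
        rng = np.random.default_rng(14)
        times = (1.5, 2.0, 3.0, 4.0, 6.0, 8.0, 10.0, 14.0)
        genes = [f"g{i:04d}" for i in range(100)]
        # first 20 genes induced late in sustained only
        signal = {("sustained", t): pd.Series([2.0] * 20 + [0.0] * 80, index=genes)
                  for t in times if t >= 6}
        matrix, sheet = make_ratio_dataset(100, times, 2, rng,
                                           sigma_per_gene=0.1, signal=signal)
        res = TimecourseDE(matrix, sheet).fit(alpha=0.05)
        hits = res.significant[:20]
        assert hits.all()
        assert (res.direction[:20] == "lower_in_transient").all()
        assert res.significant[20:].sum() <= 5

    def test_summary_has_per_window_columns(self):
        rng = np.random.default_rng(15)
        matrix, sheet = make_ratio_dataset(60, (2.0, 3.0, 6.0, 8.0), 2, rng)
        res = TimecourseDE(matrix, sheet).fit()
        cols = res.summary().columns
        for c in ("F_early", "fdr_early", "F_main", "fdr_main",
                  "significant", "direction"):
            assert c in cols

    def test_null_p_values_are_calibrated(self):
        # moderated-F p-values on hierarchical null data are uniform
        rng = np.random.default_rng(16)
        d0_true, s0_true = 4.0, 0.04
        sigma = np.sqrt(s0_true * d0_true / rng.chisquare(d0_true, size=800)) / np.sqrt(2)
        matrix, sheet = make_ratio_dataset(800, (6.0, 8.0, 10.0, 14.0), 2, rng,
                                           sigma_per_gene=sigma, shared_refs=False)
        res = TimecourseDE(matrix, sheet, windows={"main": (6.0, 14.0)}).fit()
        p = res.stats["main"]["p"].to_numpy()
        for x in (0.01, 0.05, 0.1):
            half = 2.576 * np.sqrt(x * (1 - x) / len(p))
            assert abs((p < x).mean() - x) <= half + 1e-12
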