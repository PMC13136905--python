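"""Unit and property tests for the IRLS deconvolution engine."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from celldecon import (
    CellSizeVector,
    cap_weights,
    compute_weights,
    fit_disturbance_terms,
    initial_mixture,
    irls_deconvolve,
    normalize_cp10k,
    select_beta_and_cap,
    solve_weighted,
)
from celldecon.containers import SignatureMatrix

from conftest import toy_signature


class TestNormalizeCP10K:
    def test_vector(self):
        np.testing.assert_allclose(
            normalize_cp10k(np.array([1.0, 1.0, 2.0])), [2500, 2500, 5000]
        )
        np.testing.assert_allclose(
            normalize_cp10k(np.array([0.0, 0.0, 5.0])), [0, 0, 1e4]
        )

    def test_idempotent(self):
        v = normalize_cp10k(np.array([3.0, 9.0, 1.0]))
        np.testing.assert_allclose(normalize_cp10k(v), v)

    def test_matrix_columns_and_zero_error(self):
        m = normalize_cp10k(np.array([[1.0, 0.0], [1.0, 2.0]]))
        np.testing.assert_allclose(m.sum(axis=0), [1e4, 1e4])
        with pytest.raises(ValueError, match="all-zero"):
            normalize_cp10k(np.zeros(3))


class TestDisturbanceInit:
    def test_closed_forms(self):
        S = SignatureMatrix(
            values=pd.DataFrame(
                {"A": [100.0, 200.0, 1.0], "B": [1.0, 1.0, 50.0]},
                index=["g0", "g1", "g2"],
            ),
            marker_sets={"A": ["g0", "g1"], "B": ["g2"]},
        )
        y = pd.Series([50.0, 100.0, 25.0], index=S.genes)
        u = fit_disturbance_terms(y, S, min_markers=1)
        assert u["A"] == pytest.approx(np.log(0.5))
        assert u["B"] == pytest.approx(np.log(0.5))

    def test_mean_of_log_ratios(self):
        S = SignatureMatrix(
            values=pd.DataFrame({"A": [10.0, 100.0, 1000.0]}, index=list("abc")),
            marker_sets={"A": list("abc")},
        )
        y = pd.Series([20.0, 50.0, 4000.0], index=list("abc"))
        u = fit_disturbance_terms(y, S, min_markers=1)
        assert u["A"] == pytest.approx(np.log(4) / 3)

    def test_few_markers_means_absent(self):
        S = toy_signature(K=2)
        y = pd.Series(0.0, index=S.genes)
        y.iloc[:3] = [10.0, 10.0, 10.0]  # only t0 markers present
        with pytest.warns(UserWarning, match="usable markers"):
            u = fit_disturbance_terms(y, S)
        assert np.isneginf(u["t1"])
        delta, _ = initial_mixture(u, S)
        assert delta["t1"] == 0.0

    def test_softmax(self):
        S = toy_signature(K=3)
        u = pd.Series([0.0, np.log(2), np.log(5)], index=S.cell_type_names)
        delta, y_star = initial_mixture(u, S)
        np.testing.assert_allclose(delta.to_numpy(), [1 / 8, 2 / 8, 5 / 8])
        np.testing.assert_allclose(
            y_star.to_numpy(), S.values.to_numpy() @ delta.to_numpy()
        )
        u2 = pd.Series([0.0, 0.0, -np.inf], index=S.cell_type_names)
        delta2, _ = initial_mixture(u2, S)
        np.testing.assert_allclose(delta2.to_numpy(), [0.5, 0.5, 0.0])
        with pytest.raises(ValueError, match="-inf"):
            initial_mixture(pd.Series(-np.inf, index=S.cell_type_names), S)


class TestWeights:
    @pytest.mark.parametrize(
        "beta,expected", [(1.0, 0.25), (0.0, 1.0), (0.5, 0.5)]
    )
    def test_closed_forms(self, beta, expected):
        w = compute_weights(np.array([3.0]), np.array([1.0]), beta)
        assert w[0] == pytest.approx(expected)

    def test_finite_at_exact_fit(self):
        w = compute_weights(np.array([2.0]), np.array([2.0]), 1.0)
        assert np.isfinite(w[0]) and w[0] > 0

    def test_cap_examples(self):
        np.testing.assert_allclose(
            cap_weights(np.array([1.0, 5.0, 10.0]), 0.5), [1, 5, 5]
        )
        w = np.array([1.0, 2.0, 3.0, 4.0])
        np.testing.assert_allclose(cap_weights(w, 1.0), w)
        np.testing.assert_allclose(cap_weights(w, 0.5), [1, 2, 2.5, 2.5])

    @given(st.integers(0, 2**31 - 1), st.floats(0.05, 1.0))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_cap_monotone(self, seed, tau):
        w = np.random.default_rng(seed).lognormal(size=20)
        capped = cap_weights(w, tau)
        assert (capped <= w + 1e-15).all()


class TestSolveWeighted:
    def test_orthogonal_recovery(self):
        S = SignatureMatrix(
            values=pd.DataFrame({"A": [10.0, 0.0], "B": [0.0, 10.0]}, index=["g0", "g1"]),
            marker_sets={"A": ["g0"], "B": ["g1"]},
        )
        y = S.values.to_numpy() @ np.array([0.3, 0.7])
        x = solve_weighted(y, S, np.array([1.0, 1.0]), np.ones(2))
        np.testing.assert_allclose(x.to_numpy(), [0.3, 0.7], atol=1e-10)

    def test_cell_size_unmixing(self):
        S = toy_signature(K=2)
        c = np.array([2.0, 1.0])
        x_true = np.array([0.25, 0.75])
        y = S.values.to_numpy() @ (c * x_true)
        x = solve_weighted(y, S, c, np.ones(len(S.genes)))
        np.testing.assert_allclose(x.to_numpy(), x_true, atol=1e-8)

    def test_orthogonal_mixture_error(self):
        S = SignatureMatrix(
            values=pd.DataFrame({"A": [1.0, 0.0], "B": [2.0, 0.0]}, index=["g0", "g1"]),
            marker_sets={"A": ["g0"], "B": ["g0"]},
        )
        y = np.array([0.0, 5.0])
        with pytest.raises(ValueError, match="orthogonal"):
            solve_weighted(y, S, np.array([1.0, 1.0]), np.ones(2))

    def test_matches_simplex_grid_search(self):
        # brute-force oracle on the 2-simplex at step 0.01
        rng = np.random.default_rng(5)
        S = toy_signature(K=3, n_per_type=20, seed=5)
        Sarr = S.values.to_numpy()
        c = np.array([1.5, 1.0, 0.7])
        y = Sarr @ (c * np.array([0.3, 0.45, 0.25])) + rng.normal(0, 5, 60)
        y = np.clip(y, 0, None)
        w = rng.lognormal(size=60)

        def objective(x):
            return float(w @ (y - Sarr @ (c * x)) ** 2)

        x_hat = solve_weighted(y, S, c, w).to_numpy()
        best = np.inf
        for i in range(101):
            for j in range(101 - i):
                x = np.array([i, j, 100 - i - j]) / 100.0
                best = min(best, objective(x))
        assert objective(x_hat) <= best + 1e-8


class TestIRLS:
    def test_exact_recovery_with_sizes(self, small_signature):
        S = small_signature
        x_true = np.array([0.2, 0.5, 0.3])
        c = CellSizeVector(
            c=pd.Series([2.0, 1.0, 0.5], index=S.cell_type_names), method="ercc"
        )
        y = S.values.to_numpy() @ (c.c.to_numpy() * x_true)
        fit = irls_deconvolve(pd.Series(y, index=S.genes), S, c, beta=0.5)
        assert np.abs(fit.proportions.to_numpy() - x_true).max() < 1e-4
        assert fit.converged and fit.n_iter <= 5
        assert fit.score == pytest.approx(1.0)

    def test_single_type(self):
        S = toy_signature(K=2).restrict_types(["t0"])
        y = pd.Series([5.0, 1.0, 2.0], index=S.genes)
        fit = irls_deconvolve(y, S)
        assert fit.proportions.to_list() == [1.0]
        assert fit.n_iter == 1

    def test_gene_permutation_invariance(self, small_signature):
        S = small_signature
        rng = np.random.default_rng(3)
        y = pd.Series(
            S.values.to_numpy() @ rng.dirichlet(np.ones(3))
            * rng.lognormal(0, 0.2, len(S.genes)),
            index=S.genes,
        )
        fit = irls_deconvolve(y, S, beta=1.0)
        perm = rng.permutation(len(S.genes))
        S2 = type(S)(
            values=S.values.iloc[perm],
            marker_sets=S.marker_sets,
            top_n=S.top_n,
        )
        fit2 = irls_deconvolve(y.iloc[perm], S2, beta=1.0)
        np.testing.assert_allclose(
            fit.proportions.to_numpy(), fit2.proportions.to_numpy(), atol=1e-10
        )

    def test_scale_invariance_through_normalization(self, small_signature):
        S = small_signature
        rng = np.random.default_rng(4)
        raw = pd.Series(rng.lognormal(2, 1, len(S.genes)), index=S.genes)
        f1 = irls_deconvolve(normalize_cp10k(raw), S, beta=0.5)
        f2 = irls_deconvolve(normalize_cp10k(raw * 37.5), S, beta=0.5)
        np.testing.assert_allclose(
            f1.proportions.to_numpy(), f2.proportions.to_numpy(), atol=1e-12
        )

    @given(st.integers(0, 2**31 - 1), st.sampled_from([0.0, 0.5, 1.0]))
    @settings(max_examples=15, deadline=None, derandomize=True)
    def test_simplex_output(self, seed, beta):
        rng = np.random.default_rng(seed)
        S = toy_signature(K=3, n_per_type=5, seed=seed % 100)
        y = pd.Series(
            np.clip(rng.lognormal(1, 1, len(S.genes)), 0.01, None), index=S.genes
        )
        c = CellSizeVector(
            c=pd.Series(rng.uniform(0.5, 3, 3), index=S.cell_type_names),
            method="computational",
        )
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = irls_deconvolve(y, S, c, beta=beta)
        x = fit.proportions.to_numpy()
        assert (x >= -1e-12).all()
        assert x.sum() == pytest.approx(1.0, abs=1e-8)


class TestBetaAndCapSelection:
    def test_beta_grid_membership(self, small_signature):
        S = small_signature
        rng = np.random.default_rng(9)
        y = pd.Series(
            S.values.to_numpy() @ rng.dirichlet(np.ones(3))
            * rng.lognormal(0, 0.3, len(S.genes)),
            index=S.genes,
        )
        fit = select_beta_and_cap(y, S, enable_cap=False)
        assert fit.beta in (0.0, 0.5, 1.0)
        assert fit.cap_quantile is None

    def test_full_cap_equals_uncapped(self, small_signature):
        S = small_signature
        rng = np.random.default_rng(10)
        y = pd.Series(
            S.values.to_numpy() @ rng.dirichlet(np.ones(3))
            * rng.lognormal(0, 0.3, len(S.genes)),
            index=S.genes,
        )
        f_pl = irls_deconvolve(y, S, beta=1.0)
        f_cp = irls_deconvolve(y, S, beta=1.0, tau_q=1.0)
        np.testing.assert_allclose(
            f_pl.proportions.to_numpy(), f_cp.proportions.to_numpy(), atol=1e-10
        )

    def test_noiseless_selects_perfect_score(self, small_signature):
        S = small_signature
        y = pd.Series(
            S.values.to_numpy() @ np.array([0.4, 0.35, 0.25]), index=S.genes
        )
        fit = select_beta_and_cap(y, S)
        assert fit.score == pytest.approx(1.0, abs=1e-9)
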