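"""AMMI core: double-centering, SVD scaling, Gollob tests, invariants."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ammistab import (
    CellMeansMatrix,
    cell_means,
    double_center,
    fit_ammi,
    generate_met,
    gollob_df,
    gollob_test,
    partition_means,
)

from conftest import random_means


def flip_axis(fit, n):
    """A copy of the fit with axis n's (1-based) signs flipped on both sides."""
    g = fit.genotype_scores.copy()
    e = fit.environment_scores.copy()
    g.iloc[:, n - 1] *= -1
    e.iloc[:, n - 1] *= -1
    return dataclasses.replace(fit, genotype_scores=g, environment_scores=e)


class TestDoubleCenter:
    def test_constant_matrix(self):
        means = CellMeansMatrix(pd.DataFrame(np.full((3, 3), 4.0)))
        dc = double_center(means)
        assert dc.mu == pytest.approx(4.0)
        assert np.allclose(dc.alpha, 0) and np.allclose(dc.beta, 0)
        assert np.allclose(dc.centered, 0)

    def test_additive_matrix_centers_to_zero(self, rng):
        a = rng.standard_normal(5)
        b = rng.standard_normal(4)
        means = CellMeansMatrix(pd.DataFrame(10 + a[:, None] + b[None, :]))
        assert np.allclose(double_center(means).centered, 0, atol=1e-12)

    def test_two_by_two_by_hand(self):
        means = CellMeansMatrix(pd.DataFrame([[1.0, 0.0], [0.0, 1.0]]))
        dc = double_center(means)
        assert dc.mu == pytest.approx(0.5)
        assert np.allclose(dc.centered, [[0.5, -0.5], [-0.5, 0.5]])

    def test_rows_and_columns_sum_to_zero(self, rng):
        means = random_means(rng, 6, 4)
        c = double_center(means).centered
        assert np.allclose(c.sum(axis=0), 0, atol=1e-12)
        assert np.allclose(c.sum(axis=1), 0, atol=1e-12)


class TestFitAmmi:
    def test_full_reconstruction_of_centered_matrix(self, rng):
        means = random_means(rng, 6, 4)
        fit = fit_ammi(means, n_axes="all")
        recon = fit.genotype_scores.to_numpy() @ fit.environment_scores.to_numpy().T
        assert np.allclose(recon, double_center(means).centered, atol=1e-9)
        assert np.allclose(fit.residual, 0, atol=1e-9)

    def test_score_columns_orthogonal_and_zero_sum(self, rng):
        fit = fit_ammi(random_means(rng, 7, 5), n_axes="all")
        for scores in (fit.genotype_scores.to_numpy(), fit.environment_scores.to_numpy()):
            assert np.allclose(scores.sum(axis=0), 0, atol=1e-9)
            gram = scores.T @ scores
            assert np.allclose(gram - np.diag(np.diag(gram)), 0, atol=1e-9)

    def test_symmetric_sqrt_scaling(self, rng):
        fit = fit_ammi(random_means(rng, 7, 5), n_axes="all")
        for scores in (fit.genotype_scores, fit.environment_scores):
            assert np.allclose(
                (scores.to_numpy() ** 2).sum(axis=0), fit.singular_values, atol=1e-9
            )
        assert np.all(np.diff(fit.singular_values) <= 1e-12)

    def test_axis_ss_sums_to_interaction_ss(self, rng):
        means = random_means(rng, 6, 5, r=3)
        fit = fit_ammi(means, n_axes="all")
        ss_ge = partition_means(means).table.loc["gxe", "ss"]
        assert fit.axis_ss.sum() == pytest.approx(ss_ge, rel=1e-9)

    def test_planted_rank_one_interaction(self):
        trial, truth = generate_met(
            G=6, E=4, r=2, singular_values=(2.5,), block_sd=0.0, error_sd=0.0, seed=11
        )
        fit = fit_ammi(cell_means(trial), n_axes="all")
        assert fit.singular_values[0] == pytest.approx(2.5, abs=1e-9)
        assert np.allclose(fit.singular_values[1:], 0, atol=1e-9)
        assert fit.explained_pct[0] == pytest.approx(100.0)
        assert fit.n_axes_available == 1

    def test_orientation_rule_makes_extreme_environment_positive(self, rng):
        fit = fit_ammi(random_means(rng, 8, 5), n_axes="all", orient="max_env")
        e = fit.environment_scores.to_numpy()
        for n in range(e.shape[1]):
            assert e[np.abs(e[:, n]).argmax(), n] >= 0

    def test_axis_count_selection(self, maize):
        assert fit_ammi(maize.means).n_axes == 2  # no error info -> biplot default
        assert fit_ammi(maize.means, n_axes="all").n_axes == 4
        assert fit_ammi(maize.means, n_axes=3).n_axes == 3
        with pytest.raises(ValueError):
            fit_ammi(maize.means, n_axes=5)

    def test_too_small_table_rejected(self, rng):
        with pytest.raises(ValueError, match="3 x 3"):
            fit_ammi(random_means(rng, 2, 4))

    def test_environment_score_norm_consistent_with_axis_ss(self, maize_fit):
        # printed per-axis SS and printed environment scores are coherent:
        # sum of squared axis-1 environment scores = sqrt(plot SS / r)
        norm_sq = (maize_fit.environment_scores["IPCA1"] ** 2).sum()
        expected = np.sqrt(maize_fit.axis_ss[0] / maize_fit.replicate_count)
        assert norm_sq == pytest.approx(expected, rel=1e-9)

    def test_sign_flip_leaves_reconstruction_and_ss_invariant(self, maize_fit):
        flipped = flip_axis(maize_fit, 1)
        orig = maize_fit.genotype_scores.to_numpy() @ maize_fit.environment_scores.to_numpy().T
        new = flipped.genotype_scores.to_numpy() @ flipped.environment_scores.to_numpy().T
        assert np.allclose(orig, new, atol=1e-12)
        assert np.allclose(flipped.axis_ss, maize_fit.axis_ss)
        assert np.allclose(flipped.explained_pct, maize_fit.explained_pct)


class TestGollob:
    @pytest.mark.parametrize(
        "n,G,E,expected", [(1, 69, 5, 71), (2, 69, 5, 69), (3, 69, 5, 67), (1, 3, 3, 3)]
    )
    def test_df_formula(self, n, G, E, expected):
        assert gollob_df(n, G, E) == expected

    @pytest.mark.parametrize("n", [0, 5])
    def test_df_out_of_range(self, n):
        with pytest.raises(ValueError):
            gollob_df(n, 69, 5)

    def test_f_matches_hand_formula(self, rng):
        means = random_means(rng, 6, 5, r=3)
        fit = fit_ammi(means, n_axes="all")
        res = gollob_test(fit, error_ms=0.5, error_df=40)
        r, d = 3, fit.singular_values
        for k in range(len(d)):
            expected = (r * d[k] ** 2 / gollob_df(k + 1, 6, 5)) / 0.5
            assert res.table["f"].iloc[k] == pytest.approx(expected, rel=1e-12)
            assert res.table["p"].iloc[k] == pytest.approx(
                stats.f.sf(expected, gollob_df(k + 1, 6, 5), 40), rel=1e-12
            )

    def test_zero_axis_not_significant(self):
        trial, _ = generate_met(
            G=5, E=4, r=2, singular_values=(), block_sd=0.0, error_sd=0.0, seed=4
        )
        fit = fit_ammi(cell_means(trial), n_axes="all")
        res = gollob_test(fit, error_ms=1.0, error_df=20)
        assert np.allclose(res.table["f"], 0.0, atol=1e-18)
        assert not res.table["significant"].any()
        assert res.recommended_n == 0

    def test_recommended_n_counts_leading_significant_axes(self, maize_fit):
        res = gollob_test(maize_fit)
        # every axis of the maize fit is significant at the published error MS
        assert res.recommended_n == 4
        assert res.table["significant"].all()

    def test_invalid_error_arguments(self, maize_fit):
        with pytest.raises(ValueError):
            gollob_test(maize_fit, error_ms=0.0, error_df=10)
        with pytest.raises(ValueError):
            gollob_test(maize_fit, error_ms=1.0, error_df=0)
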