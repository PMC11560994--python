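"""Biplot coordinates, fitted values, per-environment selections."""

import numpy as np
import pytest

from ammistab import (
    ammi1_coords,
    ammi2_coords,
    cell_means,
    fit_ammi,
    fitted_matrix,
    generate_met,
    per_environment_selections,
    selection_scan,
)

from conftest import random_means
from test_ammi import flip_axis


@pytest.fixture
def noisy_fit(rng):
    return fit_ammi(random_means(rng, 8, 5, r=2), n_axes="all")


@pytest.fixture
def additive_fit():
    trial, _ = generate_met(
        G=6, E=4, r=2, singular_values=(), block_sd=0.0, error_sd=0.0, seed=21
    )
    return fit_ammi(cell_means(trial), n_axes="all")


class TestAmmi1:
    def test_maize_reference_line_is_grand_mean(self, maize_fit):
        coords = ammi1_coords(maize_fit)
        assert coords.references["grand_mean"] == pytest.approx(13.18, abs=0.01)

    def test_smolice_has_extreme_environment_score(self, maize_fit):
        coords = ammi1_coords(maize_fit)
        envs = coords.points[coords.points["role"] == "environment"]
        extreme = envs.loc[envs["y"].abs().idxmax(), "label"]
        assert extreme == "Smolice"

    def test_additive_data_lies_on_zero_line(self, additive_fit):
        coords = ammi1_coords(additive_fit)
        # scores scale as sqrt(d); machine-zero singular values leave
        # sqrt(eps)-sized coordinates
        assert np.allclose(coords.points["y"], 0, atol=1e-6)
        assert additive_fit.n_axes_available == 0

    def test_genotype_x_coordinates_average_to_grand_mean(self, noisy_fit):
        coords = ammi1_coords(noisy_fit)
        genos = coords.points[coords.points["role"] == "genotype"]
        assert genos["x"].mean() == pytest.approx(noisy_fit.mu, rel=1e-12)


class TestAmmi2:
    def test_maize_extreme_positive_genotype(self, maize_fit):
        # orient axis 1 as published (Smolice positive); the largest
        # positive genotype score then belongs to SMH_16129
        coords = ammi2_coords(maize_fit)
        genos = coords.points[coords.points["role"] == "genotype"].set_index("label")
        sign = np.sign(coords.points.set_index("label").loc["Smolice", "x"])
        oriented = sign * genos["x"]
        assert oriented.idxmax() == "SMH_16129"
        assert oriented.max() == pytest.approx(0.630, abs=0.02)

    def test_maize_all_four_quadrants_populated(self, maize_fit):
        coords = ammi2_coords(maize_fit)
        genos = coords.points[coords.points["role"] == "genotype"]
        assert set(genos["quadrant"]) == {"Q1", "Q2", "Q3", "Q4"}

    def test_zero_coordinate_assigned_to_positive_side(self, maize_fit):
        from ammistab.biplot import _quadrant

        assert _quadrant(np.array([0.0]), np.array([0.0]))[0] == "Q1"
        assert _quadrant(np.array([0.0]), np.array([-1.0]))[0] == "Q4"

    def test_requires_two_axes(self, additive_fit):
        trial, _ = generate_met(
            G=5, E=4, r=2, singular_values=(1.0,), block_sd=0.0, error_sd=0.0, seed=3
        )
        fit = fit_ammi(cell_means(trial), n_axes="all")
        # structurally 3 axes exist, so coordinates are defined; a 1-column
        # score matrix must be rejected
        import dataclasses

        crippled = dataclasses.replace(
            fit,
            genotype_scores=fit.genotype_scores.iloc[:, :1],
            environment_scores=fit.environment_scores.iloc[:, :1],
        )
        with pytest.raises(ValueError, match="two interaction axes"):
            ammi2_coords(crippled)

    def test_sign_flip_is_an_isometry_of_environment_vectors(self, noisy_fit):
        def pairwise_dots(fit):
            e = fit.environment_scores.iloc[:, :2].to_numpy()
            return e @ e.T

        assert np.allclose(
            pairwise_dots(noisy_fit), pairwise_dots(flip_axis(noisy_fit, 2)), atol=1e-12
        )


class TestFittedMatrix:
    def test_all_axes_reproduce_cell_means(self, rng):
        means = random_means(rng, 6, 4, r=2)
        fit = fit_ammi(means, n_axes="all")
        assert np.allclose(
            fitted_matrix(fit, n_axes=fit.genotype_scores.shape[1]),
            means.values, atol=1e-9,
        )

    def test_zero_axes_is_purely_additive(self, noisy_fit):
        fitted = fitted_matrix(noisy_fit, n_axes=0).to_numpy()
        expected = (
            noisy_fit.mu
            + noisy_fit.alpha.to_numpy()[:, None]
            + noisy_fit.beta.to_numpy()[None, :]
        )
        assert np.allclose(fitted, expected, atol=1e-12)

    def test_one_axis_matches_termwise_formula(self, rng):
        means = random_means(rng, 5, 4)
        fit = fit_ammi(means, n_axes="all")
        fitted = fitted_matrix(fit, n_axes=1)
        for i, g in enumerate(fit.genotypes):
            for j, e in enumerate(fit.environments):
                expected = (
                    fit.mu + fit.alpha.iloc[i] + fit.beta.iloc[j]
                    + fit.genotype_scores.iloc[i, 0] * fit.environment_scores.iloc[j, 0]
                )
                assert fitted.iloc[i, j] == pytest.approx(expected, abs=1e-12)

    def test_residual_norm_decreases_with_axes(self, noisy_fit):
        centered = (
            noisy_fit.genotype_scores.to_numpy()
            @ noisy_fit.environment_scores.to_numpy().T
        )
        norms = []
        for n in range(noisy_fit.genotype_scores.shape[1] + 1):
            recon = (
                noisy_fit.genotype_scores.iloc[:, :n].to_numpy()
                @ noisy_fit.environment_scores.iloc[:, :n].to_numpy().T
            )
            norms.append(np.linalg.norm(centered - recon))
        assert all(a >= b - 1e-12 for a, b in zip(norms, norms[1:]))

    def test_out_of_range_axes_rejected(self, noisy_fit):
        with pytest.raises(ValueError):
            fitted_matrix(noisy_fit, n_axes=99)


class TestSelections:
    def test_additive_data_gives_identical_orderings(self, additive_fit):
        sel = per_environment_selections(additive_fit, top_k=6)
        orderings = {
            env: tuple(grp.sort_values("rank")["genotype"])
            for env, grp in sel.groupby("environment")
        }
        assert len(set(orderings.values())) == 1
        # and that common ordering is the genotype main-effect order
        expected = tuple(additive_fit.alpha.sort_values(ascending=False).index)
        assert next(iter(orderings.values())) == expected

    def test_top_k_full_is_a_permutation(self, noisy_fit):
        sel = per_environment_selections(noisy_fit, top_k=len(noisy_fit.genotypes))
        for _, grp in sel.groupby("environment"):
            assert sorted(grp["genotype"]) == sorted(noisy_fit.genotypes)

    def test_invariant_to_axis_sign_flips(self, noisy_fit):
        sel = per_environment_selections(noisy_fit, top_k=4)
        sel_flipped = per_environment_selections(flip_axis(noisy_fit, 1), top_k=4)
        assert sel["genotype"].tolist() == sel_flipped["genotype"].tolist()

    def test_scan_covers_requested_axis_range(self, maize_fit):
        scan = selection_scan(maize_fit, top_k=4)
        assert set(scan) == {0, 1, 2, 3, 4}
        for table in scan.values():
            assert len(table) == 4 * 5

    def test_top_k_exceeding_genotypes_rejected(self, noisy_fit):
        with pytest.raises(ValueError):
            per_environment_selections(noisy_fit, top_k=1000)
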