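"""Tests of the synthetic survey generator: design geometry, scale
conservation, cross-scale correlation and response calibration."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import stageniche as sn
from stageniche import synthetic
from stageniche.glm import FamilySpec, fit_glm


def dense_design(n, spacing=1.0, extent=(400.0, 400.0)):
    """Single-location design for large-n Monte-Carlo checks."""
    return synthetic.SurveyDesignSpec(
        n_locations=1, n_points_per_location=n,
        habitat_types={"A": list(synthetic.HABITATS_A)},
        habitat_allocation={"A": list(synthetic.DEFAULT_ALLOCATION_A)},
        min_point_spacing=spacing, area_extent={"A": extent},
        min_larvae_threshold_per_location={"A": 5},
        fine_scale_points_cap={"A": 10})


class TestDesignGeometry:
    def test_default_design_yields_240_points(self, survey):
        assert len(survey.points) == 240
        assert survey.points.groupby("location").size().tolist() == [120, 120]

    def test_minimum_spacing_respected(self, survey):
        for _, sub in survey.points.groupby("location"):
            xy = sub[["x", "y"]].to_numpy()
            d = np.sqrt(((xy[:, None] - xy[None]) ** 2).sum(-1))
            np.fill_diagonal(d, np.inf)
            assert d.min() >= 5.5

    def test_habitat_allocation_proportional(self, survey):
        sub = survey.points[survey.points.location == "A"]
        counts = sub.habitat_type.value_counts()
        expect = dict(zip(synthetic.HABITATS_A,
                          synthetic._proportional_counts(
                              synthetic.DEFAULT_ALLOCATION_A, 120)))
        assert counts.to_dict() == {k: v for k, v in expect.items() if v}

    def test_infeasible_spacing_raises(self):
        design = dense_design(200, spacing=50.0, extent=(100.0, 100.0))
        truth = synthetic.SyntheticTruth(seed=0)
        with pytest.raises(RuntimeError, match="min_point_spacing"):
            synthetic.generate_covariates(design, truth)

    def test_invalid_allocation_rejected(self):
        with pytest.raises(ValueError, match="sums to"):
            synthetic.SurveyDesignSpec(
                habitat_allocation={"A": [0.5, 0.2], "B": [1.0]})


class TestCovariates:
    def test_percentage_covers_bounded(self, survey):
        for base in synthetic.catalog.COVER_BASES:
            for s in ("25", "50", "1"):
                col = survey.points[f"{base}_{s}"]
                assert (col >= 0).all() and (col <= 100).all()

    def test_degenerate_cross_scale_rho_gives_identical_scales(self):
        design = dense_design(50)
        truth = synthetic.SyntheticTruth(seed=3, cross_scale_rho=1.0)
        sv = synthetic.generate_covariates(design, truth)
        for s in ("25", "50"):
            np.testing.assert_allclose(sv.points[f"BARESOIL_{s}"],
                                       sv.points["BARESOIL_1"])

    def test_cross_scale_spearman_matches_parameter(self):
        # Monte-Carlo check of the generator against its own parameter
        design = dense_design(2000)
        truth = synthetic.SyntheticTruth(seed=11, cross_scale_rho=0.8)
        sv = synthetic.generate_covariates(design, truth)
        rho = stats.spearmanr(sv.points["BARESOIL_25"],
                              sv.points["BARESOIL_1"]).statistic
        assert abs(rho - 0.8) < 0.05


class TestResponses:
    def test_zero_model_gives_half_prevalence(self):
        # inverse-logit(0) = 0.5
        design = dense_design(2000)
        truth = synthetic.SyntheticTruth(seed=7)
        truth.stage_models["adult_PA"] = synthetic.StageModel(0.0, {})
        truth.stage_models["adult_AB"] = synthetic.StageModel(0.0, {})
        sv = synthetic.simulate_survey(design, truth)
        # adult_PA is drawn before the abundance reconciliation touches it
        assert abs(sv.points["adult_PA"].mean() - 0.5) < 0.03

    def test_large_k_reaches_poisson_limit(self):
        # NB variance = mean + mean^2/k -> mean as k -> infinity
        rng = np.random.default_rng(0)
        mean = np.full(5000, 3.0)
        y = synthetic._nb_draw(rng, mean, k=1e6)
        assert abs(y.var() / y.mean() - 1.0) < 0.1
        y_small_k = synthetic._nb_draw(rng, mean, k=0.5)
        assert y_small_k.var() / y_small_k.mean() > 3.0

    def test_generating_effect_recovered_by_univariate_glm(self, survey):
        # strong positive coefficient on bare soil must be detectable:
        # positive, p < 0.05 univariate fits in >= 95/100 response redraws
        pts = survey.points[["BARESOIL_1"]].copy()
        model = synthetic.StageModel(-2.5, {"BARESOIL_1": 0.06})
        hits = 0
        rng = np.random.default_rng(99)
        from scipy.special import expit
        for _ in range(100):
            pts["y"] = rng.binomial(1, expit(model.eta(pts)))
            m = fit_glm(pts, "y", ["BARESOIL_1"], FamilySpec("binomial"))
            null = fit_glm(pts, "y", [], FamilySpec("binomial"))
            p = stats.chi2.sf(null.deviance - m.deviance, 1)
            if m.params["BARESOIL_1"] > 0 and p < 0.05:
                hits += 1
        assert hits >= 95

    def test_conservation_across_scales(self, survey, datasets):
        # 16-cell sum = 1x1 m abundance; central 2x2 = 50x50 cm abundance
        pts = survey.points.set_index(["location", "point_id"])
        for key, cmap in survey.cell_maps.items():
            assert cmap.counts.sum() == pts.loc[key, "larva_AB"]
        for ds_id in (5, 6):
            df = datasets[ds_id]
            for _, row in df.iterrows():
                cmap = survey.cell_maps[(row.location, row.point_id)]
                assert row.larva_AB == cmap.central_total

    def test_instars_sum_to_total(self, survey):
        pts = survey.points
        total = pts[["larva1_AB", "larva2_AB", "larva3_AB"]].sum(axis=1)
        assert (total == pts["larva_AB"]).all()


class TestNeighbourGeometry:
    def test_neighbour_set_sizes(self):
        # corner cells border 3 quadrats, edges 5, interior 8
        sizes = {synthetic.neighbour_set_size((r, c))
                 for r in range(4) for c in range(4)}
        assert sizes == {3, 5, 8}
        assert synthetic.neighbour_set_size((0, 0)) == 3
        assert synthetic.neighbour_set_size((0, 1)) == 5
        assert synthetic.neighbour_set_size((1, 1)) == 8

    def test_all_zero_map(self):
        z = np.zeros((4, 4), dtype=int)
        assert synthetic.neighbour_count(z, "central") == 0
        assert all(synthetic.neighbour_count(z, (r, c)) == 0
                   for r in range(4) for c in range(4))

    def test_uniform_map_counts(self):
        # ring around the central 2x2 block has 16 - 4 = 12 cells
        u = np.ones((4, 4), dtype=int)
        assert synthetic.neighbour_count(u, "central") == 12
        assert synthetic.neighbour_count(u, (0, 0)) == 3
        assert synthetic.neighbour_count(u, (2, 0)) == 5
        assert synthetic.neighbour_count(u, (2, 2)) == 8

    def test_focal_outside_grid_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            synthetic.neighbour_count(np.zeros((4, 4)), (4, 0))


class TestAssembly:
    def test_fine_scale_row_counts(self, datasets):
        # caps of 10 and 11 points, 16 cells each
        assert len(datasets[7]) == 160
        assert len(datasets[8]) == 176

    def test_no_threshold_no_cap_keeps_all_cells(self, survey):
        import copy
        sv = copy.copy(survey)
        sv.design = synthetic.SurveyDesignSpec(
            min_larvae_threshold_per_location={"A": 0, "B": 0},
            fine_scale_points_cap={"A": None, "B": None})
        ds = synthetic.assemble_datasets(sv)
        assert len(ds[7]) == 16 * 120
        assert len(ds[8]) == 16 * 120

    def test_fine_scale_selection_deterministic(self, survey):
        a = synthetic._select_fine_points(survey, "A")
        b = synthetic._select_fine_points(survey, "A")
        assert a == b
        totals = [survey.cell_maps[("A", pid)].total for pid in a]
        assert totals == sorted(totals, reverse=True)
        assert min(totals) >= 5

    def test_same_seed_bit_identical(self):
        design = dense_design(40)
        s1 = sn.simulate_survey(design, synthetic.SyntheticTruth(seed=77))
        s2 = sn.simulate_survey(dense_design(40),
                                synthetic.SyntheticTruth(seed=77))
        pd.testing.assert_frame_equal(s1.points, s2.points)
        for k in s1.cell_maps:
            np.testing.assert_array_equal(s1.cell_maps[k].counts,
                                          s2.cell_maps[k].counts)

    def test_all_columns_registered(self, datasets):
        from stageniche import catalog
        for df in datasets.values():
            catalog.validate_columns(df.columns)
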