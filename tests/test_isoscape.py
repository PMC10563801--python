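import math

import numpy as np
import pytest

from paleoscape import isoscape as iso
from paleoscape.core import CoreSample, CoreSite, DepthInterval, EraBin
from paleoscape.isoscape import (
    FAMILIES,
    GridSpec,
    VariogramModel,
    build_isoscapes,
    empirical_variogram,
    fit_variogram,
    krige,
    select_variogram,
)
from paleoscape.synthetic import FieldParams, ScenarioConfig, gen_true_field


def naive_kriging_solve(points, values, model, target, drift_order=0):
    """Independent loop-assembled dense solve of the kriging equations."""
    n = len(points)

    def basis(p):
        x, y = p
        cols = [1.0]
        if drift_order >= 1:
            cols += [x, y]
        if drift_order >= 2:
            cols += [x * y, x**2, y**2]
        return cols

    p = len(basis(points[0]))
    a = np.zeros((n + p, n + p))
    for i in range(n):
        for j in range(n):
            if i != j:
                h = math.dist(points[i], points[j])
                a[i, j] = float(model.gamma(h))
        for k, b in enumerate(basis(points[i])):
            a[i, n + k] = b
            a[n + k, i] = b
    rhs = np.zeros(n + p)
    for i in range(n):
        rhs[i] = float(model.gamma(math.dist(points[i], target)))
    for k, b in enumerate(basis(target)):
        rhs[n + k] = b
    sol = np.linalg.solve(a, rhs)
    w = sol[:n]
    pred = float(w @ values)
    var = float(w @ rhs[:n] + sol[n:] @ rhs[n:])
    return pred, var, w


class TestEmpiricalVariogram:
    def test_two_point_semivariance(self):
        emp = empirical_variogram(np.array([[0.0, 0.0], [100.0, 0.0]]),
                                  np.array([0.0, 2.0]), n_bins=1, max_lag=200.0)
        assert emp.semivariance[0] == pytest.approx(2.0)  # (2^2)/(2*1)
        assert emp.counts[0] == 1

    def test_constant_field_all_zero(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(0, 1000, (30, 2))
        emp = empirical_variogram(pts, np.full(30, 3.3))
        assert np.allclose(emp.semivariance, 0.0)

    def test_coincident_points_error(self):
        with pytest.raises(iso.VariogramError):
            empirical_variogram(np.zeros((5, 2)), np.arange(5.0))

    def test_grf_sample_tracks_true_model_at_small_lags(self):
        # empirical semivariance of generator GRFs vs configured model,
        # averaged over 20 seeds
        fp = FieldParams(0.0, 0.0, range_m=1200.0, sill=1.0)
        cfg = ScenarioConfig(
            n_sites=60, channel_length=3000.0, grid_spacing=100.0,
            channel_width=1000.0,
            field_params={"d15N": {e.label: fp for e in ScenarioConfig().eras}},
        )
        era = cfg.eras[0].label
        gam_sum = None
        for seed in range(20):
            fld = gen_true_field(cfg, "d15N", era, seed=seed)
            emp = empirical_variogram(fld.points, fld.grf, n_bins=8)
            gam_sum = emp.semivariance if gam_sum is None else gam_sum + emp.semivariance
        gam = gam_sum / 20
        model = VariogramModel("spherical", 0.0, 1.0, 1200.0)
        expect = model.gamma(emp.centers)
        # small lags: Monte-Carlo agreement within 25%
        assert np.all(np.abs(gam[:4] - expect[:4]) < 0.25 * np.maximum(expect[:4], 0.2))


class TestFitVariogram:
    def test_recovers_exact_spherical_curve(self):
        truth = VariogramModel("spherical", 0.1, 1.5, 800.0)
        h = np.linspace(50, 1400, 12)
        emp = iso.EmpiricalVariogram(h, truth.gamma(h), np.full(12, 50), 1400.0, 112.5)
        fit = fit_variogram(emp, "spherical")
        assert fit.partial_sill == pytest.approx(1.5, rel=0.05)
        assert fit.range_m == pytest.approx(800.0, rel=0.05)

    def test_constant_zero_semivariance_gives_zero_sill(self):
        emp = iso.EmpiricalVariogram(
            np.array([100.0, 200.0, 300.0]), np.zeros(3), np.full(3, 10), 300.0, 100.0
        )
        fit = fit_variogram(emp, "spherical")
        assert fit.nugget == 0.0 and fit.partial_sill == 0.0

    def test_gamma_zero_at_origin_with_nugget_jump(self):
        m = VariogramModel("exponential", 0.3, 1.0, 500.0)
        assert m.gamma(0.0) == 0.0
        assert m.gamma(1e-9) >= 0.3

    @pytest.mark.parametrize("family", ["spherical", "circular", "exponential",
                                        "gaussian"])
    def test_gamma_nondecreasing(self, family):
        m = VariogramModel(family, 0.1, 1.0, 700.0)
        h = np.linspace(0, 2000, 500)
        assert (np.diff(m.gamma(h)) >= -1e-12).all()


class TestKrige:
    def _random_config(self, rng, n):
        pts = rng.uniform(0, 1000, (n, 2))
        vals = rng.normal(0, 1, n) + 0.002 * pts[:, 0]
        return pts, vals

    def test_exact_interpolation_at_data_point_with_zero_nugget(self):
        rng = np.random.default_rng(1)
        pts, vals = self._random_config(rng, 8)
        model = VariogramModel("spherical", 0.0, 1.0, 600.0)
        preds, var = krige(pts, vals, model, pts[2][None, :])
        assert preds[0] == pytest.approx(vals[2], abs=1e-8)
        assert var[0] == pytest.approx(0.0, abs=1e-8)

    def test_constant_data_predicts_constant(self):
        rng = np.random.default_rng(2)
        pts = rng.uniform(0, 1000, (10, 2))
        for family in ("spherical", "exponential", "gaussian"):
            model = VariogramModel(family, 0.2, 1.0, 500.0)
            preds, _ = krige(pts, np.full(10, 4.2), model,
                             rng.uniform(0, 1000, (5, 2)))
            np.testing.assert_allclose(preds, 4.2, atol=1e-8)

    def test_three_point_agrees_with_hand_assembled_system(self):
        pts = np.array([[0.0, 0.0], [100.0, 0.0], [0.0, 100.0]])
        vals = np.array([1.0, 2.0, 4.0])
        model = VariogramModel("spherical", 0.05, 1.0, 300.0)
        target = np.array([40.0, 30.0])
        preds, var = krige(pts, vals, model, target[None, :])
        pred_o, var_o, _ = naive_kriging_solve(pts, vals, model, target)
        assert preds[0] == pytest.approx(pred_o, abs=1e-8)
        assert var[0] == pytest.approx(var_o, abs=1e-8)

    def test_ordinary_weights_sum_to_one(self):
        rng = np.random.default_rng(3)
        pts, vals = self._random_config(rng, 12)
        model = VariogramModel("exponential", 0.1, 0.8, 400.0)
        targets = rng.uniform(0, 1000, (20, 2))
        _, _, w = krige(pts, vals, model, targets, return_weights=True)
        np.testing.assert_allclose(w.sum(axis=1), 1.0, atol=1e-10)

    def test_universal_drift_reproduces_plane_exactly(self):
        rng = np.random.default_rng(4)
        pts = rng.uniform(0, 1000, (15, 2))
        vals = 2.0 + 0.01 * pts[:, 0] - 0.005 * pts[:, 1]  # exact plane
        model = VariogramModel("linear_drift1", 0.0, 1.0, 1000.0)
        targets = rng.uniform(0, 1000, (6, 2))
        preds, _ = krige(pts, vals, model, targets)
        expect = 2.0 + 0.01 * targets[:, 0] - 0.005 * targets[:, 1]
        np.testing.assert_allclose(preds, expect, atol=1e-6)

    def test_duplicates_averaged_before_solving(self):
        pts = np.array([[0.0, 0.0], [0.0, 0.0], [100.0, 0.0], [0.0, 100.0]])
        vals = np.array([1.0, 3.0, 5.0, 7.0])
        model = VariogramModel("spherical", 0.0, 1.0, 300.0)
        preds, _ = krige(pts, vals, model, np.array([[0.0, 0.0]]))
        assert preds[0] == pytest.approx(2.0, abs=1e-8)  # mean of 1 and 3

    def test_variance_nonnegative_everywhere(self):
        rng = np.random.default_rng(5)
        pts, vals = self._random_config(rng, 15)
        model = VariogramModel("gaussian", 0.1, 1.0, 400.0)
        _, var = krige(pts, vals, model, rng.uniform(-200, 1200, (50, 2)))
        assert (var >= 0).all()


class TestSelectVariogram:
    def test_same_seed_identical_holdout_and_table(self):
        rng = np.random.default_rng(6)
        pts = rng.uniform(0, 2000, (40, 2))
        vals = 0.003 * pts[:, 0] + rng.normal(0, 0.3, 40)
        a = select_variogram(pts, vals, seed=5)
        b = select_variogram(pts, vals, seed=5)
        np.testing.assert_array_equal(a.holdout_idx, b.holdout_idx)
        assert a.rmse == b.rmse and a.best_family == b.best_family

    def test_constant_field_ties_break_to_spherical(self):
        rng = np.random.default_rng(7)
        pts = rng.uniform(0, 2000, (30, 2))
        sel = select_variogram(pts, np.full(30, 2.0), seed=0)
        assert sel.best_family == "spherical"
        for fam, rmse in sel.rmse.items():
            if not math.isnan(rmse):
                assert rmse == pytest.approx(0.0, abs=1e-8)

    def test_too_few_points_rejected(self):
        pts = np.random.default_rng(0).uniform(0, 100, (4, 2))
        with pytest.raises(iso.VariogramError):
            select_variogram(pts, np.arange(4.0), seed=0)


class TestBuildIsoscapes:
    def _inputs(self, n_sites=12, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        sites = [
            CoreSite(f"s{i}", float(200 * (i % 6)), float(200 * (i // 6)))
            for i in range(n_sites)
        ]
        era = EraBin("old", 1800, 1900)
        samples = []
        dated = {}
        for s in sites:
            val = 1.0 + 0.004 * s.x + 0.002 * s.y + rng.normal(0, noise)
            smp = CoreSample(s.site_id, DepthInterval(0, 10), d15N=val,
                             c_pct=2.0, n_pct=0.2)
            samples.append(smp)
            dated[(s.site_id, 0.0, 10.0)] = (1850.0, era)
        return samples, dated, sites, [era]

    def test_linear_gradient_reproduced_at_sites(self):
        samples, dated, sites, eras = self._inputs()
        maps = build_isoscapes(samples, dated, sites, eras, "d15N",
                               force_family="spherical", cell=50.0)
        assert len(maps) == 1
        m = maps[0]
        site_xy = np.array([[s.x, s.y] for s in sites])
        preds, _ = iso.krige(site_xy, np.array([m.site_values[s.site_id]
                                                for s in sites]),
                             m.model, site_xy)
        expect = [m.site_values[s.site_id] for s in sites]
        np.testing.assert_allclose(preds, expect, atol=1e-6)

    def test_era_with_too_few_sites_skipped(self):
        samples, dated, sites, eras = self._inputs(n_sites=3)
        maps = build_isoscapes(samples, dated, sites, eras, "d15N",
                               force_family="spherical")
        assert maps == []

    def test_masked_predictions_finite_and_variance_nonnegative(self):
        samples, dated, sites, eras = self._inputs(noise=0.2, seed=2)
        maps = build_isoscapes(samples, dated, sites, eras, "d15N",
                               force_family="spherical", cell=100.0)
        m = maps[0]
        assert np.isfinite(m.predictions[m.mask]).all()
        assert (m.variances[m.mask] >= 0).all()

    def test_ascii_grid_written_with_sidecar(self, tmp_path):
        samples, dated, sites, eras = self._inputs()
        maps = build_isoscapes(samples, dated, sites, eras, "d15N",
                               force_family="spherical", cell=100.0)
        path = tmp_path / "iso.asc"
        iso.write_ascii_grid(maps[0], path)
        text = path.read_text().splitlines()
        assert text[0].startswith("ncols") and text[1].startswith("nrows")
        import json

        sidecar = json.loads((tmp_path / "iso.asc.json").read_text())
        assert sidecar["family"] == "spherical" and sidecar["era"] == "old"
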