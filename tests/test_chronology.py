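import math

import numpy as np
import pytest

from paleoscape import chronology as chron
from paleoscape.chronology import (
    AgeDepthPosterior,
    CompositeChronology,
    MarkerDate,
    RadionuclideProfile,
    apply_chronology,
    composite_chronology,
    crs_ages,
    derive_era_bins,
    detect_markers,
    fit_age_depth,
    MCMCConfig,
)
from paleoscape.core import DepthInterval, EraBin, DEFAULT_ERAS
from paleoscape.synthetic import ScenarioConfig, gen_radionuclide_profile


def _noiseless_profile():
    cfg = ScenarioConfig(pb210_noise_cv=0.0)
    return cfg, *gen_radionuclide_profile(cfg, 0)


class TestDetectMarkers:
    def test_noiseless_profile_markers_at_true_depths(self):
        cfg, prof, truth = _noiseless_profile()
        markers = {m.kind: m for m in detect_markers(prof)}
        assert markers["surface"].calendar_year == 2010
        # basal Cs at slab bottom, peak at slab midpoint; within one slab of truth
        assert abs(markers["cs_basal_1953"].depth - truth["depth_1953"]) <= 2.0
        assert abs(markers["cs_peak_1963"].depth - truth["depth_1963"]) <= 1.0
        assert abs(markers["pb_peak_1974"].depth - truth["depth_1974"]) <= 1.0

    def test_all_zero_cs_gives_surface_and_pb_only(self):
        cfg, prof, _ = _noiseless_profile()
        prof.cs137[:] = 0.0
        kinds = {m.kind for m in detect_markers(prof)}
        assert "cs_basal_1953" not in kinds and "cs_peak_1963" not in kinds
        assert "surface" in kinds and "pb_peak_1974" in kinds

    def test_tied_cs_maxima_choose_shallower(self):
        n = 10
        cs = np.zeros(n)
        cs[3] = cs[6] = 5.0  # two equal maxima
        prof = RadionuclideProfile(
            top=np.arange(n) * 2.0,
            bottom=np.arange(1, n + 1) * 2.0,
            pb210_total=np.ones(n),
            pb210_sd=np.full(n, 0.1),
            cs137=cs,
            pb_total_ppm=np.zeros(n),
        )
        markers = {m.kind: m for m in detect_markers(prof)}
        assert markers["cs_peak_1963"].depth == pytest.approx(7.0)  # shallower slab

    def test_flat_pb_profile_gives_no_pb_marker(self):
        cfg, prof, _ = _noiseless_profile()
        prof.pb_total_ppm[:] = 10.0
        kinds = {m.kind for m in detect_markers(prof)}
        assert "pb_peak_1974" not in kinds


class TestCRS:
    def test_surface_age_zero(self):
        cfg, prof, _ = _noiseless_profile()
        crs = crs_ages(prof, supported_level=cfg.supported_pb210)
        assert crs.ages[0] == pytest.approx(0.0, abs=1e-9)

    def test_half_inventory_is_one_halflife(self):
        # constructed: I(z) = I(0)/2 exactly -> age 22.3 yr
        cfg, prof, _ = _noiseless_profile()
        crs = crs_ages(prof, supported_level=cfg.supported_pb210)
        i0 = crs.inventory_surface
        # interpolate depth where cumulative-below crosses i0/2 via ages array
        idx = np.nanargmin(np.abs(crs.ages - 22.3))
        assert crs.ages[idx] == pytest.approx(22.3, rel=0.1)

    def test_noiseless_constant_accretion_recovery(self):
        cfg, prof, truth = _noiseless_profile()
        crs = crs_ages(prof, supported_level=cfg.supported_pb210)
        true_ages = truth["age_at_depth"](crs.depths)
        ok = crs.valid & (true_ages <= 4 * 22.3) & (true_ages > 0)
        rel = np.abs(crs.ages[ok] - true_ages[ok]) / true_ages[ok]
        assert np.nanmax(rel) < 0.02

    def test_nonpositive_inventory_flagged_not_extrapolated(self):
        prof = RadionuclideProfile(
            top=np.array([0.0, 2.0, 4.0]),
            bottom=np.array([2.0, 4.0, 6.0]),
            pb210_total=np.array([5.0, 1.0, 1.0]),
            pb210_sd=np.full(3, 0.1),
            cs137=np.zeros(3),
            pb_total_ppm=np.zeros(3),
        )
        crs = crs_ages(prof, supported_level=1.0, tail_correction=False)
        assert not crs.valid[-1]
        assert math.isnan(crs.ages[-1])


class TestFitAgeDepth:
    def test_markers_only_two_point_slope(self):
        # {0 cm -> 2010 (tight), 25 cm -> 1963} => accretion ~ 25/47 cm/yr
        prof = RadionuclideProfile(
            top=np.arange(0.0, 30.0, 2.0),
            bottom=np.arange(2.0, 32.0, 2.0),
            pb210_total=np.full(15, 1.0),  # uninformative flat profile
            pb210_sd=np.full(15, 10.0),  # huge errors: markers dominate
            cs137=np.zeros(15),
            pb_total_ppm=np.zeros(15),
            collection_year=2010,
        )
        markers = [
            MarkerDate(0.0, 2010.0, 0.01, "surface"),
            MarkerDate(25.0, 1963.0, 1.0, "cs_peak_1963"),
        ]
        priors = chron.AgeDepthPriors(acc_mean=47.0 / 25.0, acc_shape=2.0,
                                      memory_sd=0.2)
        post = fit_age_depth(prof, markers, priors=priors,
                             mcmc=MCMCConfig(iterations=3000), seed=0)
        assert post.accretion_draws.mean() == pytest.approx(25.0 / 47.0, rel=0.10)

    def test_posterior_draws_monotone_and_mean_in_envelope(self):
        cfg = ScenarioConfig()
        prof, _ = gen_radionuclide_profile(cfg, 3)
        post = fit_age_depth(prof, detect_markers(prof),
                             mcmc=MCMCConfig(iterations=1500), seed=3)
        assert (np.diff(post.draws, axis=1) <= 1e-12).all()  # years fall with depth
        lo, hi = post.ci
        assert ((lo - 1e-9 <= post.mean_year) & (post.mean_year <= hi + 1e-9)).all()

    def test_nonconvergence_flag_not_exception(self):
        cfg = ScenarioConfig()
        prof, _ = gen_radionuclide_profile(cfg, 1)
        post = fit_age_depth(prof, detect_markers(prof),
                             mcmc=MCMCConfig(iterations=200, adapt=False), seed=0)
        assert isinstance(post, AgeDepthPosterior)  # flags may warn, never raise

    def test_posterior_persistence(self, tmp_path):
        cfg = ScenarioConfig()
        prof, _ = gen_radionuclide_profile(cfg, 2)
        post = fit_age_depth(prof, detect_markers(prof),
                             mcmc=MCMCConfig(iterations=600), seed=2)
        post.save(tmp_path / "core1")
        assert (tmp_path / "core1.draws.csv").exists()
        assert (tmp_path / "core1.summary.json").exists()


def _linear_posterior(accretion_cm_yr: float, n_draws: int = 200,
                      depth_max: float = 40.0, jitter: float = 0.0,
                      seed: int = 0) -> AgeDepthPosterior:
    """Synthetic posterior with exactly linear age-depth draws."""
    rng = np.random.default_rng(seed)
    depths = np.linspace(0, depth_max, 21)
    base = 2010.0 - depths / accretion_cm_yr
    draws = np.tile(base, (n_draws, 1))
    if jitter > 0:
        draws = draws + rng.normal(0, jitter, (n_draws, 1))
    alpha = np.full((n_draws, 20), 1.0 / accretion_cm_yr)
    return AgeDepthPosterior(
        depth_grid=depths,
        draws=draws,
        accretion_draws=np.full(n_draws, accretion_cm_yr),
        alpha_draws=alpha,
        influx_draws=np.ones(n_draws),
        supported_draws=np.ones(n_draws),
        acceptance_rate=0.3,
    )


class TestComposite:
    def test_composite_of_identical_posteriors_equals_each(self):
        p = _linear_posterior(0.25)
        comp = composite_chronology([p, p, p])
        np.testing.assert_allclose(comp.mean_year, 2010.0 - comp.depth_grid / 0.25,
                                   atol=1e-9)

    def test_two_linear_chronologies_pool_to_pointwise_mean(self):
        pa = _linear_posterior(0.2)
        pb = _linear_posterior(0.5)
        comp = composite_chronology([pa, pb])
        expect = 0.5 * ((2010 - comp.depth_grid / 0.2) + (2010 - comp.depth_grid / 0.5))
        np.testing.assert_allclose(comp.mean_year, expect, atol=1e-9)

    def test_pooled_ci_at_least_as_wide_where_cores_disagree(self):
        pa = _linear_posterior(0.2, jitter=2.0, seed=1)
        pb = _linear_posterior(0.5, jitter=2.0, seed=2)
        comp = composite_chronology([pa, pb])
        pooled_width = comp.hi95 - comp.lo95
        for p in (pa, pb):
            lo, hi = p.ci
            own = np.interp(comp.depth_grid, p.depth_grid, hi - lo)
            deep = comp.depth_grid > 10
            assert (pooled_width[deep] >= own[deep] - 1e-9).all()

    def test_requested_grid_outside_range_truncated_with_flag(self):
        p = _linear_posterior(0.25, depth_max=40.0)
        comp = composite_chronology([p], depth_grid=np.linspace(0, 80, 41))
        assert comp.depth_grid[-1] <= 40.0
        assert "coverage_truncated" in comp.flags

    def test_monotone_mean_enforced(self):
        p = _linear_posterior(0.25)
        comp = composite_chronology([p])
        assert (np.diff(comp.mean_year) <= 1e-12).all()


class TestApplyChronology:
    def _chron(self, accretion=0.25):
        depths = np.linspace(0, 50, 51)
        years = 2010.0 - depths / accretion
        return CompositeChronology(depths, years, years - 5, years + 5, 1)

    def test_interval_age_arithmetic(self):
        # 0-10 cm at 0.25 cm/yr from a 2010 surface -> midpoint 5 cm -> 1990
        out = apply_chronology(self._chron(), [DepthInterval(0, 10)], DEFAULT_ERAS)
        assert out[0].mean_year == pytest.approx(1990.0)

    def test_era_membership(self):
        # mean year 1975 falls in the 1963-1981 era
        c = self._chron()
        iv = DepthInterval(8.0, 9.5)  # midpoint 8.75 cm -> 1975
        out = apply_chronology(c, [iv], DEFAULT_ERAS)
        assert out[0].mean_year == pytest.approx(1975.0)
        assert out[0].era.label == "1963-1981"

    def test_out_of_range_interval_flagged_and_excluded(self):
        out = apply_chronology(self._chron(), [DepthInterval(60, 70)], DEFAULT_ERAS)
        assert not out[0].in_range and out[0].era is None

    def test_era_assignment_stable_under_grid_refinement(self):
        acc = 0.25
        coarse = np.linspace(0, 50, 26)
        fine = np.linspace(0, 50, 51)
        intervals = [DepthInterval(t, t + 10) for t in (0.0, 10.0, 20.0, 30.0)]
        results = []
        for grid in (coarse, fine):
            years = 2010.0 - grid / acc
            c = CompositeChronology(grid, years, years - 5, years + 5, 1)
            results.append(apply_chronology(c, intervals, DEFAULT_ERAS))
        for a, b in zip(*results):
            assert abs(a.mean_year - b.mean_year) < 0.5
            assert a.era.label == b.era.label


class TestDeriveEraBins:
    def test_bins_span_sections_and_merge_deepest(self):
        c = CompositeChronology(
            np.linspace(0, 100, 101),
            2010.0 - np.linspace(0, 100, 101) / 0.25,
            2010.0 - np.linspace(0, 100, 101) / 0.25 - 5,
            2010.0 - np.linspace(0, 100, 101) / 0.25 + 5,
            1,
        )
        eras = derive_era_bins(c, [0, 10, 20, 30, 40, 50, 75, 100], max_bins=6,
                               collection_year=2010)
        assert len(eras) == 6
        assert eras[0].start_year == pytest.approx(1610)
        assert eras[-1].end_year == pytest.approx(2011)
        # contiguous
        for a, b in zip(eras, eras[1:]):
            assert a.end_year == b.start_year
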