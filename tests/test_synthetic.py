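import numpy as np
import pandas as pd
import pytest

from retscat.config import ConfigurationError, OpticalConfig
from retscat.correlation import angular_to_correlation, azimuthal_integrate, fit_slope
from retscat.layers import segment_layers
from retscat.synthetic import (CohortSpec, MediumSpec, cs_noise, generate_cohort,
                               inject_specular, location_layout, make_angular_plane,
                               make_bscan)


def _recover_alpha(plane, cfg):
    return fit_slope(azimuthal_integrate(angular_to_correlation(plane, cfg))).alpha


class TestAngularPlane:
    def test_plane_is_real_nonnegative_finite(self, cfg):
        p = make_angular_plane(MediumSpec(alpha_true=1.2, seed=3), cfg)
        assert p.shape == (cfg.n_theta_x, cfg.n_theta_y)
        assert np.all(np.isfinite(p)) and np.all(p >= 0)

    def test_seed_determinism_bit_identical(self, cfg):
        spec = MediumSpec(alpha_true=0.7, seed=42)
        p1 = make_angular_plane(spec, cfg)
        p2 = make_angular_plane(spec, cfg)
        assert np.array_equal(p1, p2)
        p3 = make_angular_plane(MediumSpec(alpha_true=0.7, seed=43), cfg)
        assert not np.array_equal(p1, p3)

    def test_flat_target_recovers_zero_slope(self, cfg):
        # alpha_true = 0: constant correlation energy across the window
        vals = [_recover_alpha(make_angular_plane(
            MediumSpec(alpha_true=0.0, seed=s), cfg), cfg) for s in range(5)]
        assert abs(np.mean(vals)) < 0.05

    def test_closed_loop_recovery_unit_slope(self, cfg):
        vals = [_recover_alpha(make_angular_plane(
            MediumSpec(alpha_true=1.0, seed=s), cfg), cfg) for s in range(20)]
        assert 0.9 <= np.mean(vals) <= 1.1

    def test_noise_free_recovery_is_exact(self, cfg):
        p = make_angular_plane(MediumSpec(alpha_true=1.3, seed=0, noise_sigma=0.0), cfg)
        assert _recover_alpha(p, cfg) == pytest.approx(1.3, abs=1e-9)

    def test_unrealizable_window_raises_configuration_error(self):
        tiny = OpticalConfig(n_theta_x=16, n_theta_y=16)  # r_max = 8 um
        with pytest.raises(ConfigurationError, match="r_max"):
            make_angular_plane(MediumSpec(alpha_true=1.0, outer_scale=120.0), tiny)

    @pytest.mark.parametrize("kwargs", [dict(alpha_true=3.5), dict(alpha_true=-0.1),
                                        dict(alpha_true=1.0, inner_scale=5.0,
                                             outer_scale=2.0)])
    def test_invalid_medium_spec(self, kwargs):
        with pytest.raises(ValueError):
            MediumSpec(**kwargs)


class TestInjectSpecular:
    def test_unit_gain_is_identity(self, cfg, rng):
        p = rng.random((32, 32))
        out, fp = inject_specular(p, (16, 16), 3, gain=1.0)
        assert np.array_equal(out, p)

    def test_disc_pixels_exceed_threshold_exactly(self):
        p = np.ones((40, 40))
        out, fp = inject_specular(p, (20, 20), 3, gain=10.0)
        assert np.array_equal(out > 5 * np.median(out), fp)
        assert fp.sum() == np.sum(
            (np.arange(40)[:, None] - 20) ** 2 + (np.arange(40)[None, :] - 20) ** 2 <= 9)

    def test_masking_footprint_restores_moments(self, cfg):
        p = make_angular_plane(MediumSpec(alpha_true=0.8, seed=5), cfg)
        out, fp = inject_specular(p, (60, 60), 4, gain=12.0)
        for moment in (np.mean, np.var):
            assert moment(out[~fp]) == pytest.approx(moment(p[~fp]), rel=1e-12)

    def test_disc_outside_plane_rejected(self):
        with pytest.raises(ValueError):
            inject_specular(np.ones((16, 16)), (1, 1), 3, gain=2.0)


class TestBscan:
    def test_nfl_row_count_forced_by_pixel_size(self, cfg):
        # 18 um at 2 um/px -> 9 rows
        _, truth = make_bscan({"NFL": 18.0, "OPL": 15.0, "RPE": 15.0}, cfg)
        top, bottom = truth.boundaries["NFL"]
        assert bottom - top == 9

    def test_noiseless_segmentation_recovers_truth(self, cfg):
        img, truth = make_bscan({"NFL": 18.0, "OPL": 15.0, "RPE": 15.0}, cfg,
                                speckle_level=0.0)
        seg = segment_layers(img, oct_axial_pixel=cfg.oct_axial_pixel)
        assert seg.boundaries == truth.boundaries

    def test_thinner_nfl_changes_only_its_row_count(self, cfg):
        _, t16 = make_bscan({"NFL": 16.0, "OPL": 15.0, "RPE": 15.0}, cfg)
        _, t18 = make_bscan({"NFL": 18.0, "OPL": 15.0, "RPE": 15.0}, cfg)
        rows = lambda t, l: t.boundaries[l][1] - t.boundaries[l][0]
        assert rows(t18, "NFL") - rows(t16, "NFL") == 1
        for layer in ("OPL", "RPE"):
            assert rows(t16, layer) == rows(t18, layer)

    def test_speckle_is_mean_preserving(self, cfg):
        img0, _ = make_bscan({"NFL": 18.0, "OPL": 15.0, "RPE": 15.0}, cfg)
        img1, _ = make_bscan({"NFL": 18.0, "OPL": 15.0, "RPE": 15.0}, cfg,
                             speckle_level=1.0, seed=0)
        assert img1.mean() == pytest.approx(img0.mean(), rel=0.05)

    def test_nonpositive_thickness_rejected(self, cfg):
        with pytest.raises(ValueError):
            make_bscan({"NFL": 0.0, "OPL": 15.0, "RPE": 15.0}, cfg)


class TestCohort:
    def test_default_design_counts(self, cfg):
        ds = generate_cohort(CohortSpec(seed=0), cfg, mode="table")
        assert len(ds.records) == 184  # (10 + 13) eyes x 8 locations
        assert sum(r.group == "WT" for r in ds.records) == 80
        assert len(ds.truth) == 184 * 3  # one truth entry per record per layer

    def test_determinism(self, cfg):
        d1 = generate_cohort(CohortSpec(seed=5), cfg, mode="table")
        d2 = generate_cohort(CohortSpec(seed=5), cfg, mode="table")
        pd.testing.assert_frame_equal(d1.truth, d2.truth)

    def test_volume_records_are_reproducible(self, small_cfg, small_cohort_spec):
        d1 = generate_cohort(small_cohort_spec, small_cfg, mode="volumes")
        d2 = generate_cohort(small_cohort_spec, small_cfg, mode="volumes")
        assert np.array_equal(d1.records[0].bscan, d2.records[0].bscan)
        assert np.array_equal(d1.records[0].volume.intensity,
                              d2.records[0].volume.intensity)

    def test_quadrant_layout_follows_axes(self):
        layout = location_layout(8)
        quads = [q for _, q in layout]
        assert quads.count("superior") == quads.count("inferior") == 2
        for (dx, dy), q in layout:
            if q == "superior":
                assert dy > 0 and dx == 0
            if q == "temporal":
                assert dx < 0 and dy == 0
        assert {abs(dx) + abs(dy) for (dx, dy), _ in layout} == {500.0, 1000.0}

    def test_null_cohort_group_means_agree(self, cfg):
        # no group effects: group means of true alpha within 2 pooled SEs
        spec = CohortSpec.null_design(n_wt_eyes=200, n_ad_eyes=200, seed=3)
        tt = generate_cohort(spec, cfg, mode="table").truth_table()
        sub = tt[(tt.metric == "alpha") & (tt.layer == "NFL")]
        eye_means = sub.groupby("eye").agg(group=("group", "first"),
                                           value=("value", "mean"))
        wt = eye_means[eye_means.group == "WT"].value
        ad = eye_means[eye_means.group == "AD"].value
        se = np.sqrt(wt.var(ddof=1) / len(wt) + ad.var(ddof=1) / len(ad))
        assert abs(wt.mean() - ad.mean()) <= 2 * se

    def test_compound_symmetry_correlation_recovered(self, cfg):
        # empirical within-eye correlation of location residuals at rho = 0.5
        spec = CohortSpec.null_design(n_wt_eyes=250, n_ad_eyes=250, n_locations=8,
                                      within_eye_rho=0.5, seed=9)
        tt = generate_cohort(spec, cfg, mode="table").truth_table()
        sub = tt[(tt.metric == "alpha") & (tt.layer == "NFL")]
        wide = sub.pivot(index="eye", columns="location", values="value").to_numpy()
        wide = wide - wide.mean(axis=0)
        cov = wide.T @ wide / (len(wide) - 1)
        off = cov[~np.eye(8, dtype=bool)].mean()
        diag = np.diag(cov).mean()
        assert 0.45 <= off / diag <= 0.55

    def test_cs_noise_moments(self, rng):
        draws = np.array([cs_noise(8, -0.14, rng) for _ in range(4000)])
        assert np.allclose(draws.mean(axis=0), 0.0, atol=0.06)
        assert np.allclose(draws.var(axis=0), 1.0, atol=0.08)

    def test_inadmissible_rho_rejected(self):
        with pytest.raises(ValueError, match="within_eye_rho"):
            CohortSpec(within_eye_rho=-0.2)  # below -1/7 for 8 locations

    def test_superior_only_mean_effect_is_confined(self, cfg):
        spec = CohortSpec(seed=2)  # default: AD intensity level raised in superior only
        tt = generate_cohort(spec, cfg, mode="table").truth_table()
        sub = tt[(tt.metric == "intensity_mean") & (tt.layer == "NFL")]
        ad = sub[sub.group == "AD"]
        wt = sub[sub.group == "WT"]
        sup_diff = ad[ad.quadrant == "superior"].value.mean() - \
            wt[wt.quadrant == "superior"].value.mean()
        inf_diff = ad[ad.quadrant == "inferior"].value.mean() - \
            wt[wt.quadrant == "inferior"].value.mean()
        assert sup_diff > 1.0
        assert abs(inf_diff) < 0.5
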