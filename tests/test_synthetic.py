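"""Generator determinism, calibration and truth-recovery round trips."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

import antheridyn as ad
from antheridyn.exceptions import CalibrationError, InputError


def test_template_satisfies_invariants(template, scenario):
    g = template.geometry
    cells = ad.extract_cells(g)
    assert len(cells) == 2 * scenario.n_cells_side + 2
    cavity_ref = g.points[g.structure == "cavity"].mean(axis=0)
    for cell in cells:
        # every cell chains into a simple polygon (checked on construction)
        # and its inner wall bulges toward the cavity
        assert ad.wall_curvature(cell.inner, cavity_ref) > 0


def test_template_is_deterministic(scenario):
    a = ad.make_antheridium_template(scenario)
    b = ad.make_antheridium_template(scenario)
    np.testing.assert_array_equal(a.geometry.points, b.geometry.points)


def test_calibration_hits_all_three_means_exactly(scenario):
    mix = ad.calibrate_cell_factors(scenario)
    (w1, l1), (w2, l2) = mix["components"]
    assert (w1 + w2) / 2 == pytest.approx(scenario.width_factor_mean, abs=1e-12)
    assert (l1 + l2) / 2 == pytest.approx(scenario.length_factor_mean, abs=1e-12)
    assert (w1 / l1 + w2 / l2) / 2 == pytest.approx(
        scenario.ratio_factor_mean, abs=1e-12
    )
    # positive covariance is required because ratio-of-means > mean-of-ratios
    assert (w1 - w2) * (l1 - l2) > 0


def test_calibration_degenerates_to_constant_pairs():
    sc = replace(
        ad.BurstScenario(), width_factor_mean=1.2, length_factor_mean=0.96,
        ratio_factor_mean=1.2 / 0.96,
    )
    factors, mix = ad.sample_cell_factors(sc, 50, seed=0)
    assert mix["delta_w"] == 0.0 and mix["delta_l"] == 0.0
    assert np.ptp(factors[:, 0]) == 0.0 and np.ptp(factors[:, 1]) == 0.0


def test_calibration_infeasible_triple_raises():
    # W >= 2*R*L drives the low-length component non-positive
    sc = replace(
        ad.BurstScenario(), width_factor_mean=1.0, length_factor_mean=1.0,
        ratio_factor_mean=0.4,
    )
    with pytest.raises(CalibrationError):
        ad.calibrate_cell_factors(sc)


def test_factor_sampler_montecarlo_means(scenario):
    factors, _ = ad.sample_cell_factors(scenario, 100_000, seed=123)
    w, l = factors[:, 0], factors[:, 1]
    assert w.mean() == pytest.approx(scenario.width_factor_mean, rel=0.005)
    assert l.mean() == pytest.approx(scenario.length_factor_mean, rel=0.005)
    assert (w / l).mean() == pytest.approx(scenario.ratio_factor_mean, rel=0.005)


def test_factor_sampler_is_seed_deterministic(scenario):
    a, _ = ad.sample_cell_factors(scenario, 20, seed=9)
    b, _ = ad.sample_cell_factors(scenario, 20, seed=9)
    np.testing.assert_array_equal(a, b)


def test_identity_deformation_returns_template(template):
    sc = replace(
        ad.BurstScenario(),
        width_factor_mean=1.0, length_factor_mean=1.0, ratio_factor_mean=1.0,
        organ_area_factor=1.0, organ_width_factor=1.0, cavity_area_factor=1.0,
        curvature_gain=1.0, noise_sigma_um=0.0,
    )
    tpl = ad.make_antheridium_template(sc)
    after, truth = ad.apply_burst_deformation(tpl, sc, seed=1)
    np.testing.assert_allclose(after.points, tpl.geometry.points, atol=1e-9)
    np.testing.assert_allclose(truth.displacement, 0.0, atol=1e-9)


def test_noise_free_deformation_recovers_drawn_factors(template, quiet_scenario):
    """Pipeline-vs-truth round trip: measured per-cell width/length changes
    equal the drawn factors to 1e-9, organ/cavity factors exactly."""
    g = template.geometry
    after, truth = ad.apply_burst_deformation(template, quiet_scenario, seed=17)
    cells_b = {c.cell_id: c for c in ad.extract_cells(g)}
    cells_a = {c.cell_id: c for c in ad.extract_cells(after)}
    for row in truth.cell_factors.itertuples():
        wb, lb, _ = ad.cell_width_length(cells_b[row.cell_id])
        wa, la, _ = ad.cell_width_length(cells_a[row.cell_id])
        assert wa / wb == pytest.approx(row.width_factor, abs=1e-9)
        assert la / lb == pytest.approx(row.length_factor, abs=1e-9)
        area_fac = ad.cell_area_extension(
            cells_b[row.cell_id], cells_a[row.cell_id]
        )
        assert area_fac == pytest.approx((row.area_factor - 1) * 100, abs=1e-9)

    def outline(geom, tag):
        return geom.points[geom.structure == tag]

    assert ad.polygon_area(outline(after, "organ_outline")) / ad.polygon_area(
        outline(g, "organ_outline")
    ) == pytest.approx(quiet_scenario.organ_area_factor, abs=1e-12)
    assert np.ptp(outline(after, "organ_outline")[:, 0]) / np.ptp(
        outline(g, "organ_outline")[:, 0]
    ) == pytest.approx(quiet_scenario.organ_width_factor, abs=1e-12)
    assert ad.polygon_area(outline(after, "cavity")) / ad.polygon_area(
        outline(g, "cavity")
    ) == pytest.approx(quiet_scenario.cavity_area_factor, abs=1e-12)


def test_deformation_strictly_increases_inner_curvature(template, quiet_scenario):
    g = template.geometry
    after, truth = ad.apply_burst_deformation(template, quiet_scenario, seed=4)
    cavity_ref = g.points[g.structure == "cavity"].mean(axis=0)
    cells_b = {c.cell_id: c for c in ad.extract_cells(g)}
    cells_a = {c.cell_id: c for c in ad.extract_cells(after)}
    for cid in cells_b:
        kb = ad.wall_curvature(cells_b[cid].inner, cavity_ref)
        ka = ad.wall_curvature(cells_a[cid].inner, cavity_ref)
        assert ka > kb > 0
        assert ka / kb == pytest.approx(quiet_scenario.curvature_gain, abs=1e-6)


def test_deformation_displacement_truth_matches_field(template, quiet_scenario):
    after, truth = ad.apply_burst_deformation(template, quiet_scenario, seed=6)
    np.testing.assert_allclose(
        truth.displacement, after.points - template.geometry.points, atol=1e-12
    )
    # inner walls displace much more than the anchored outer walls
    g = template.geometry
    mags = np.linalg.norm(truth.displacement, axis=1)
    inner = mags[(g.structure == "cell") & (g.wall == "inner")].mean()
    outer = mags[(g.structure == "cell") & (g.wall == "outer")].mean()
    assert inner > 3 * outer


def test_rigid_jitter_roundtrip_and_determinism(template):
    g = template.geometry
    moved, truth = ad.rigid_jitter(g, max_tilt_deg=60.0, seed=31)
    again, _ = ad.rigid_jitter(g, max_tilt_deg=60.0, seed=31)
    np.testing.assert_array_equal(moved.points, again.points)
    assert abs(truth.transform["tilt_deg"]) <= 60.0
    np.testing.assert_allclose(
        ad.normalize_geometry(moved).normalized.points,
        ad.normalize_geometry(g).normalized.points,
        atol=1e-9,
    )
    same, truth0 = ad.rigid_jitter(g, max_tilt_deg=0.0, seed=31)
    assert truth0.transform["tilt_deg"] == 0.0
    with pytest.raises(InputError):
        ad.rigid_jitter(g, max_tilt_deg=80.0, seed=1)


def test_landmark_noise_moments_and_identity(template):
    g = template.geometry
    assert ad.add_landmark_noise(g, 0.0, seed=1).points is not g.points
    np.testing.assert_array_equal(ad.add_landmark_noise(g, 0.0, 1).points, g.points)
    big = ad.LandmarkGeometry(
        specimen_id="noise", frame=1, time_s=0.0,
        points=np.random.default_rng(0).uniform(0, 100, (5000, 2)),
        structure=["organ_outline"] * 5000,
        anchor_left=0, anchor_right=1,
    )
    sigma = 0.05
    noisy = ad.add_landmark_noise(big, sigma, seed=2)
    resid = (noisy.points - big.points).ravel()
    assert resid.std() == pytest.approx(sigma, rel=0.05)
    np.testing.assert_array_equal(
        ad.add_landmark_noise(big, sigma, seed=2).points, noisy.points
    )


def test_apex_series_roundtrip(quiet_scenario):
    walls, times, truth = ad.make_apex_series(quiet_scenario)
    lengths, pct, elapsed = ad.apex_extension_series(walls, times)
    assert pct == pytest.approx(truth.apex_growth_percent, abs=1e-9)
    assert elapsed == pytest.approx(truth.apex_duration_s, abs=1e-12)
    np.testing.assert_allclose(lengths, truth.apex_lengths, atol=1e-9)
    assert np.all(np.diff(lengths) > 0)  # monotone growth to the burst
    flat = replace(quiet_scenario, apex_growth=0.0)
    _, pct0, _ = ad.apex_extension_series(*ad.make_apex_series(flat)[:2])
    assert pct0 == 0.0


def test_sperm_mass_track_roundtrip(quiet_scenario):
    profile_c = np.array([30.0, 25.0, 20.0, 16.0, 12.0])
    profile_r = np.array([18.0, 15.0, 11.0, 8.0, 5.0])
    track, truth = ad.make_sperm_mass_track(
        profile_c, profile_r, duration_s=5 / 15, time_step=1 / 15, noise=0.0, seed=0
    )
    raw = ad.raw_mass_speeds(track)
    np.testing.assert_allclose(raw.center, truth.center_speeds, atol=1e-9)
    np.testing.assert_allclose(raw.radius, truth.radius_speeds, atol=1e-9)
    np.testing.assert_allclose(raw.end, truth.end_speeds, atol=1e-9)
    still, _ = ad.make_sperm_mass_track(0.0, 0.0, 1.0, 0.1, noise=0.0, seed=0)
    raw_still = ad.raw_mass_speeds(still)
    assert np.all(raw_still.end == 0.0)


def test_sperm_track_recovery(quiet_scenario):
    straight, truth = ad.make_sperm_track(450.0, 0.0, 0.5, 1 / 15, seed=3)
    assert ad.initial_sperm_speed(straight) == pytest.approx(450.0, abs=1e-9)
    wobbly, truth = ad.make_sperm_track(450.0, 30.0, 0.5, 1 / 15, seed=3)
    est = ad.initial_sperm_speed(wobbly)
    assert abs(est - truth.sperm_speed) / truth.sperm_speed < 0.05
    again, _ = ad.make_sperm_track(450.0, 30.0, 0.5, 1 / 15, seed=3)
    np.testing.assert_array_equal(wobbly.positions, again.positions)


def test_dataset_determinism_and_layout(scenario):
    a, ta = ad.simulate_burst_dataset(scenario, 3, seed=5)
    b, tb = ad.simulate_burst_dataset(scenario, 3, seed=5)
    for sa, sb in zip(a, b):
        for ga, gb in zip(sa.frames, sb.frames):
            np.testing.assert_array_equal(ga.points, gb.points)
    assert all(t1.cell_factors.equals(t2.cell_factors) for t1, t2 in zip(ta, tb))
    assert all(len(s) == 2 for s in a)


def test_statistical_roundtrip_of_population_means(scenario):
    """With landmark noise and 50 specimens the recovered population means
    of the three per-cell effect sizes fall within 2 standard errors of
    the scenario truth in at least 90% of seeds (20 seeds checked)."""
    targets = {
        "cell_width_change": (scenario.width_factor_mean - 1) * 100,
        "cell_length_change": (scenario.length_factor_mean - 1) * 100,
        "cell_ratio_change": (scenario.ratio_factor_mean - 1) * 100,
    }
    hits = {k: 0 for k in targets}
    n_seeds = 20
    for seed in range(n_seeds):
        series, _ = ad.simulate_burst_dataset(scenario, 50, seed=seed)
        metrics = ad.dataset_metrics(series)
        for name, target in targets.items():
            v = metrics.loc[metrics.metric == name, "value"]
            se = v.std(ddof=1) / np.sqrt(len(v))
            hits[name] += abs(v.mean() - target) <= 2 * se
    for name, count in hits.items():
        assert count >= 0.9 * n_seeds, f"{name}: only {count}/{n_seeds} seeds in band"
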