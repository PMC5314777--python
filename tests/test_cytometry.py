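"""Gating pipeline and noise estimators."""

import numpy as np
import pandas as pd
import pytest

from capscaffold.cytometry import (
    GateConfig,
    cv,
    cv_vs_radius,
    density_centre,
    dual_reporter_noise,
    noise_pipeline,
    plateau_cv,
    radial_gate,
    scatter_gate,
    trim_time,
)
from capscaffold.simulate import FlowSimConfig, simulate_events


def make_events(n=1000, time=None, fsc=50_000.0, ssc=50_000.0, gfp=100.0):
    t = np.arange(n) * 0.1 if time is None else np.asarray(time, dtype=float)
    return pd.DataFrame({
        "time": t,
        "fsc": np.broadcast_to(fsc, t.shape).copy(),
        "ssc": np.broadcast_to(ssc, t.shape).copy(),
        "gfp": np.broadcast_to(gfp, t.shape).copy(),
    })


class TestTrim:
    def test_trim_window_arithmetic(self):
        # 120 events at 0.1 s spacing over [0, 11.9]: keep (1.0, 11.7]
        ev = make_events(120)
        kept = trim_time(ev, 1.0, 0.2)
        assert len(kept) == 107
        assert kept["time"].min() > 1.0
        assert kept["time"].max() <= 11.7 + 1e-9

    def test_zero_trims_identity(self):
        ev = make_events(50)
        assert len(trim_time(ev, 0.0, 0.0)) == 50

    def test_everything_trimmed_raises(self):
        ev = make_events(5)  # spans 0.4 s only
        with pytest.raises(ValueError, match="empty after trim"):
            trim_time(ev, 1.0, 0.2)

    def test_unsorted_rejected(self):
        ev = make_events(10, time=np.linspace(1, 0, 10))
        with pytest.raises(ValueError, match="time-sorted"):
            trim_time(ev, 0.0, 0.0)


class TestScatterGate:
    def test_inside_kept_outside_removed(self):
        ev = pd.DataFrame({"time": [0.0, 0.1], "fsc": [50_000.0, 30_000.0],
                           "ssc": [50_000.0, 50_000.0], "gfp": [1.0, 1.0]})
        kept = scatter_gate(ev)
        assert len(kept) == 1 and kept["fsc"].iloc[0] == 50_000.0

    def test_uniform_retention_fraction(self):
        rng = np.random.default_rng(0)
        n = 20_000
        ev = pd.DataFrame({"time": np.linspace(0, 10, n),
                           "fsc": rng.uniform(0, 150_000, n),
                           "ssc": rng.uniform(0, 150_000, n),
                           "gfp": np.ones(n)})
        frac = len(scatter_gate(ev)) / n
        expected = (60 / 150) * (80 / 150)
        assert abs(frac - expected) < 4 * np.sqrt(expected * (1 - expected) / n)


class TestDensityCentre:
    def test_point_mass(self):
        ev = make_events(200, fsc=50_000.0, ssc=40_000.0)
        cf, cs = density_centre(ev)
        assert abs(cf - 50_000.0) <= 1_250.0 and abs(cs - 40_000.0) <= 1_250.0

    def test_bivariate_normal_mode(self):
        rng = np.random.default_rng(7)
        n = 50_000
        ev = pd.DataFrame({"time": np.linspace(0, 10, n),
                           "fsc": rng.normal(60_000, 8_000, n),
                           "ssc": rng.normal(30_000, 6_000, n),
                           "gfp": np.ones(n)})
        cf, cs = density_centre(ev, bin_width=2_500.0)
        assert abs(cf - 60_000) <= 2_500.0
        assert abs(cs - 30_000) <= 2_500.0

    def test_tie_break_deterministic(self):
        half = make_events(100, fsc=40_000.0, ssc=40_000.0)
        other = make_events(100, fsc=80_000.0, ssc=80_000.0)
        ev = pd.concat([half, other]).sort_values("time").reset_index(drop=True)
        centres = {density_centre(ev, 2_500.0) for _ in range(3)}
        assert len(centres) == 1

    def test_too_few_events(self):
        with pytest.raises(ValueError, match="at least 100"):
            density_centre(make_events(50))


class TestRadialGate:
    def test_345_triangle_boundary_kept(self):
        centre = (50_000.0, 50_000.0)
        ev = make_events(2, fsc=53_000.0, ssc=54_000.0)  # distance exactly 5000
        assert len(radial_gate(ev, centre, 5_000.0)) == 2
        with pytest.raises(ValueError, match="empty"):
            radial_gate(ev, centre, 4_999.0)

    def test_radius_zero_keeps_only_centre(self):
        ev = pd.DataFrame({"time": [0.0, 0.1], "fsc": [50_000.0, 50_001.0],
                           "ssc": [50_000.0, 50_000.0], "gfp": [1.0, 1.0]})
        assert len(radial_gate(ev, (50_000.0, 50_000.0), 0.0)) == 1

    def test_large_radius_identity(self):
        ev = make_events(100)
        assert len(radial_gate(ev, (0.0, 0.0), 1e9)) == 100


class TestCV:
    def test_examples(self):
        assert cv([10, 10, 10]) == 0.0
        assert cv([1, 2, 3]) == pytest.approx(0.5)

    def test_scale_invariance(self):
        v = np.array([3.0, 5.0, 9.0, 11.0])
        assert cv(7.3 * v) == pytest.approx(cv(v))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            cv([1.0])
        with pytest.raises(ValueError, match="non-positive"):
            cv([-1.0, 1.0])


class TestCvVsRadius:
    def test_flat_curve_without_extrinsic_component(self):
        ev = simulate_events(FlowSimConfig(n_events=30_000, extrinsic_cv=0.0,
                                           intrinsic_cv={"gfp": 0.12},
                                           debris_fraction=0.0, seed=21))
        centre = density_centre(ev)
        curve = cv_vs_radius(ev, centre, GateConfig().radii)
        plateau, stable = plateau_cv(curve)
        total = cv(ev["gfp"])
        assert abs(plateau - total) / total < 0.05
        assert stable

    def test_shuffled_radii_rejected(self):
        ev = make_events(500)
        with pytest.raises(ValueError, match="must increase"):
            cv_vs_radius(ev, (50_000.0, 50_000.0), [5_000.0, 1_000.0])

    def test_insufficient_events(self):
        ev = make_events(500, fsc=50_000.0)
        with pytest.raises(ValueError, match="insufficient"):
            cv_vs_radius(ev, (0.0, 0.0), [10.0, 20.0], min_events=200)


class TestDualReporter:
    def test_identical_channels_zero(self):
        x = np.array([1.0, 2.0, 3.0])
        assert dual_reporter_noise(x, x) == 0.0

    def test_antisymmetric_example(self):
        assert dual_reporter_noise([2.0, 0.0], [0.0, 2.0]) == pytest.approx(2.0)

    def test_symmetry_and_common_rescaling(self):
        rng = np.random.default_rng(4)
        g = rng.uniform(1, 5, 1_000)
        m = rng.uniform(1, 5, 1_000)
        assert dual_reporter_noise(g, m) == pytest.approx(dual_reporter_noise(m, g))
        assert dual_reporter_noise(3.0 * g, 3.0 * m) == pytest.approx(
            dual_reporter_noise(g, m))

    def test_normalization_equalizes_brightness(self):
        rng = np.random.default_rng(5)
        g = rng.lognormal(0, 0.1, 10_000)
        assert dual_reporter_noise(g, 0.5 * g) == pytest.approx(0.0)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError, match="paired"):
            dual_reporter_noise([1.0, 2.0], [1.0])


def test_pipeline_is_deterministic():
    ev = simulate_events(FlowSimConfig(n_events=20_000, seed=3))
    s1 = noise_pipeline(ev)
    s2 = noise_pipeline(ev.copy())
    assert s1.total_cv == s2.total_cv
    assert s1.plateau_cv == s2.plateau_cv
    assert s1.centre == s2.centre


def test_plateau_closer_to_intrinsic_than_total_across_seeds():
    """Radial gating strictly improves on the total CV as an intrinsic-noise
    estimate whenever an extrinsic component is present."""
    intrinsic = 0.10
    for seed in range(3):
        ev = simulate_events(FlowSimConfig(
            n_events=30_000, extrinsic_cv=0.20,
            intrinsic_cv={"gfp": intrinsic}, seed=seed))
        s = noise_pipeline(ev)
        assert abs(s.plateau_cv - intrinsic) < abs(s.total_cv - intrinsic)
        assert s.plateau_cv <= s.total_cv
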