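"""Generator-level properties: arrival statistics, the dwell law, timing,
bleaching/titration series and determinism."""

import numpy as np
import pandas as pd
import pytest

from capgrad import synthetic_data as sd
from capgrad.binding_kinetics import bleach_model


def test_config_validation_rejects_bad_parameters():
    with pytest.raises(ValueError):
        sd.SimulationConfig(v_g=-1.0)
    with pytest.raises(ValueError):
        sd.SimulationConfig(tau_tip=0.0)
    with pytest.raises(ValueError):
        sd.SimulationConfig(p_blink_off=1.5)
    with pytest.raises(ValueError):
        sd.SimulationConfig(exposure=0.1, frame_interval=0.06)
    with pytest.raises(ValueError):
        sd.SimulationConfig(n_frames=0)
    with pytest.raises(ValueError):
        sd.SimulationConfig(v_g=float("nan"))


def test_zero_on_rate_gives_empty_outputs():
    cfg = sd.SimulationConfig(on_rate_density=0.0, n_frames=100, seed=1)
    locs, truth, trace = sd.simulate_cap_events(cfg)
    assert len(locs) == 0
    assert len(truth.events) == 0
    assert len(trace.frames) == 100


def test_tip_trace_is_linear_with_slope_vg():
    cfg = sd.SimulationConfig(v_g=59.8, n_frames=500, on_rate_density=0.0, seed=0)
    _, _, trace = sd.simulate_cap_events(cfg)
    t = trace.frames * cfg.frame_interval
    fit = np.polyfit(t, trace.tip_s_nm, 1)
    assert fit[0] == pytest.approx(59.8, rel=1e-12)
    resid = trace.tip_s_nm - np.polyval(fit, t)
    assert np.max(np.abs(resid)) < 1e-6


def test_same_seed_reproducibility_all_generators():
    cfg = sd.SimulationConfig(on_rate_density=0.5, n_frames=500, seed=42)
    a = sd.simulate_cap_events(cfg)
    b = sd.simulate_cap_events(cfg)
    assert a[0].to_csv() == b[0].to_csv()
    assert a[1].events.to_csv() == b[1].events.to_csv()
    t1 = sd.simulate_titration("hyperbolic", {"A": 1, "K_d": 40}, [2, 5, 10], 0.1, 3, seed=7)
    t2 = sd.simulate_titration("hyperbolic", {"A": 1, "K_d": 40}, [2, 5, 10], 0.1, 3, seed=7)
    assert t1.to_csv() == t2.to_csv()
    b1 = sd.simulate_bleach_series(0.01, 0.02, [0.06, 0.1], 0.055, 100, 0.02, seed=5)
    b2 = sd.simulate_bleach_series(0.01, 0.02, [0.06, 0.1], 0.055, 100, 0.02, seed=5)
    assert all(np.array_equal(x.F, y.F) for x, y in zip(b1, b2))


def test_uniform_affinity_limit_dwell_independent_of_position():
    # lambda -> inf: mean dwell in [0,1) um and [3,4) um behind the tip agree
    cfg = sd.SimulationConfig(
        lambda_cap=float("inf"), tau_tip=1.0, on_rate_density=3.0,
        n_frames=3000, mt_length0=6000.0, seed=3,
    )
    _, truth, _ = sd.simulate_cap_events(cfg)
    ev = truth.events
    near = ev[(ev.distance_nm >= 0) & (ev.distance_nm < 1000)]["dwell_s"]
    far = ev[(ev.distance_nm >= 3000) & (ev.distance_nm < 4000)]["dwell_s"]
    assert len(near) >= 500 and len(far) >= 500
    sem = np.sqrt(near.var() / len(near) + far.var() / len(far))
    assert abs(near.mean() - far.mean()) < 3 * sem


def test_dwell_law_recovery_in_narrow_distance_bins():
    # empirical mean dwell at distance d matches tau_tip*exp(-d/lambda)
    cfg = sd.SimulationConfig(
        lambda_cap=450.0, tau_tip=2.0, on_rate_density=40.0,
        n_frames=2000, k_bleach=0.0, seed=4,
    )
    _, truth, _ = sd.simulate_cap_events(cfg)
    ev = truth.events
    for d0 in (200.0, 600.0, 1000.0):
        sub = ev[np.abs(ev.distance_nm - d0) < 150]["dwell_s"]
        assert len(sub) >= 1000
        expect = 2.0 * np.exp(-d0 / 450.0)
        sem = sub.std() / np.sqrt(len(sub))
        assert abs(sub.mean() - expect) < 3 * sem


def test_event_conservation_truth_vs_localizations():
    cfg = sd.SimulationConfig(on_rate_density=0.5, n_frames=2000, seed=8)
    locs, truth, _ = sd.simulate_cap_events(cfg)
    detected_ids = set(locs["track_truth_id"].unique())
    ev = truth.events
    assert detected_ids == set(ev[ev.detected]["event_id"])
    assert len(ev) == ev.detected.sum() + (~ev.detected).sum()
    # every emitted localization maps to exactly one truth event
    assert locs["track_truth_id"].isin(ev["event_id"]).all()


def test_expected_event_count_matches_simulation():
    cfg = sd.SimulationConfig(on_rate_density=0.5, n_frames=5000, seed=0)
    expect = sd.expected_event_count(cfg)
    counts = []
    for seed in range(8):
        _, truth, _ = sd.simulate_cap_events(sd.SimulationConfig(
            on_rate_density=0.5, n_frames=5000, seed=100 + seed))
        counts.append(truth.events.detected.sum())
    assert np.mean(counts) == pytest.approx(expect, rel=0.15)


def test_calibrated_tau_tip_reproduces_target_measured_mean():
    tau = sd.calibrate_tau_tip(0.88, 450.0, 0.06, 0.055, 1.0 / 45.0)
    got = sd.expected_measured_mean_dwell(tau, 450.0, 0.06, 0.055, 1.0 / 45.0)
    assert got == pytest.approx(0.88, abs=1e-4)
    # truth-level check: measured frame spans of detected events
    cfg = sd.wildtype_config(seed=5, on_rate_density=0.5, n_frames=5000)
    locs, _, _ = sd.simulate_cap_events(cfg)
    g = locs.groupby("track_truth_id")["frame"]
    spans = (g.max() - g.min() + 1) * cfg.frame_interval
    assert spans.mean() == pytest.approx(0.88, rel=0.10)


# ---------------------------------------------------------------------------
# titration and bleach series


def test_titration_noiseless_points_lie_on_model():
    E = [2, 5, 10, 25, 50, 100, 200, 500]  # the wildtype titration grid
    t = sd.simulate_titration("hyperbolic", {"A": 2.0, "K_d": 40.0}, E, 0.0, 2, seed=0)
    expect = 2.0 * t["E_nM"] / (40.0 + t["E_nM"])
    assert np.allclose(t["I"], expect)
    with pytest.raises(ValueError):
        sd.simulate_titration("cubic", {}, E, 0.1, 1, seed=0)


def test_isotherm_models_vanish_at_zero_concentration():
    from capgrad.binding_kinetics import hyperbolic_model, quadratic_model

    assert hyperbolic_model(0.0, 1.0, 40.0) == 0.0
    assert quadratic_model(0.0, 1.0, 8.0, 2.1) == pytest.approx(0.0)


def test_bleach_series_limits_and_validation():
    # no bleaching -> constant 1
    s = sd.simulate_bleach_series(0.01, 0.0, [0.06, 0.1], 0.055, 50, 0.0, seed=0)
    assert np.allclose(s[0].F, 1.0)
    # continuous illumination, no unbinding -> pure exponential bleaching
    s = sd.simulate_bleach_series(0.0, 0.1, [0.055], 0.055, 100, 0.0, seed=0)
    assert np.allclose(s[0].F, np.exp(-0.1 * s[0].times), rtol=1e-10)
    # the experimental interval set is a valid input
    s = sd.simulate_bleach_series(1 / 300, 1 / 45, [0.06, 0.1, 0.2], 0.055, 20, 0.02, seed=1)
    assert len(s) == 3 and all(x.F[0] == 1.0 for x in s)
    with pytest.raises(ValueError):
        sd.simulate_bleach_series(0.01, 0.02, [0.04, 0.1], 0.055, 20, 0.0, seed=0)


def test_bleach_series_follows_duty_cycle_model():
    s = sd.simulate_bleach_series(1 / 300, 1 / 45, [0.06, 0.2], 0.055, 200, 0.0, seed=0)
    for series in s:
        k_b_eff = (1 / 45) * series.exposure / series.frame_interval
        assert np.allclose(series.F, bleach_model(series.times, 1 / 300, k_b_eff))


# ---------------------------------------------------------------------------
# rendering


def test_render_movie_background_only_without_emitters():
    cfg = sd.SimulationConfig(n_frames=3, seed=0)
    empty = pd.DataFrame(columns=sd.LOCALIZATION_COLUMNS)
    movie = sd.render_movie(empty, cfg, shape=(16, 16), background=100.0,
                            poisson_noise=False)
    assert movie.shape == (3, 16, 16)
    assert (movie == 100).all()


def test_render_movie_centroid_matches_emitter_position():
    cfg = sd.SimulationConfig(n_frames=1, seed=0)
    locs = pd.DataFrame({
        "frame": [0], "x_nm": [7 * 120.0], "y_nm": [5 * 120.0],
        "photons": [5000.0], "sigma_nm": [0.0], "track_truth_id": [0],
    })
    movie = sd.render_movie(locs, cfg, shape=(12, 16), background=0.0,
                            poisson_noise=False)
    img = movie[0].astype(float)
    yy, xx = np.mgrid[0:12, 0:16]
    cx = (img * xx).sum() / img.sum()
    cy = (img * yy).sum() / img.sum()
    assert abs(cx - 7.0) < 0.01 and abs(cy - 5.0) < 0.01


def test_render_movie_warns_on_out_of_frame_emitters():
    cfg = sd.SimulationConfig(n_frames=1, seed=0)
    locs = pd.DataFrame({
        "frame": [0], "x_nm": [1e6], "y_nm": [0.0], "photons": [1000.0],
        "sigma_nm": [0.0], "track_truth_id": [0],
    })
    with pytest.warns(UserWarning, match="outside"):
        sd.render_movie(locs, cfg, shape=(8, 8), poisson_noise=False)
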