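"""Linking, dwell records, survival fitting, the spatial gradient and MSD."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from capgrad import synthetic_data as sd
from capgrad.dwell_analysis import (
    comet_lifetime,
    dwell_records,
    fit_monoexp,
    hydrolysis_rate,
    link_events,
    local_dwell_profile,
    merge_colocated_tracks,
    msd_diffusion,
    survival,
)
from capgrad.end_tracking import EndTrace
from tests.conftest import run_cap_pipeline


# ---------------------------------------------------------------------------
# linking


def brute_force_link(locs, max_dist_nm=120.0, max_gap_frames=30):
    """Independent naive implementation of the linking rules: per frame, per
    localization in row order, scan every track ever opened and apply the
    eligibility rules directly."""
    tracks = []  # list of dicts: last_frame, last_x, last_y, updated_this_frame
    out = np.full(len(locs), -1, dtype=int)
    rows = list(locs.itertuples(index=False))
    current_frame = None
    for idx, row in enumerate(rows):
        f = row.frame
        if f != current_frame:
            for t in tracks:
                t["pending"] = None
            current_frame = f
        best = None
        best_d = None
        for tid, t in enumerate(tracks):
            if t["claimed_frame"] == f:
                continue
            if t["last_frame"] >= f:
                continue
            if f - t["last_frame"] > max_gap_frames:
                continue
            d = np.hypot(row.x_nm - t["last_x"], row.y_nm - t["last_y"])
            if d > max_dist_nm:
                continue
            if best is None or d < best_d:
                best, best_d = tid, d
        if best is None:
            tracks.append({"last_frame": f, "last_x": row.x_nm, "last_y": row.y_nm,
                           "claimed_frame": f, "pending": None})
            out[idx] = len(tracks) - 1
        else:
            t = tracks[best]
            t["claimed_frame"] = f
            t["pending"] = (f, row.x_nm, row.y_nm)
            out[idx] = best
        # apply pending updates when the frame advances
        if idx + 1 == len(rows) or rows[idx + 1].frame != f:
            for t in tracks:
                if t["pending"] is not None:
                    t["last_frame"], t["last_x"], t["last_y"] = t["pending"]
                    t["pending"] = None
    return out


def _random_locs(rng, n):
    frames = np.sort(rng.integers(0, 60, size=n))
    return pd.DataFrame({
        "frame": frames,
        "x_nm": rng.uniform(0, 600, size=n),
        "y_nm": rng.uniform(0, 300, size=n),
    })


@pytest.mark.parametrize("seed", range(30))
def test_greedy_linker_matches_brute_force_oracle(seed):
    rng = np.random.default_rng(seed)
    locs = _random_locs(rng, int(rng.integers(1, 51)))
    locs = locs.drop_duplicates(subset=["frame", "x_nm", "y_nm"]).reset_index(drop=True)
    linked = link_events(locs)
    oracle = brute_force_link(locs)
    assert np.array_equal(linked["track_id"].to_numpy(), oracle)


def test_link_basic_examples():
    # 50 nm apart in consecutive frames -> one track of dwell 2 frames
    locs = pd.DataFrame({"frame": [0, 1], "x_nm": [0.0, 50.0], "y_nm": [0.0, 0.0]})
    linked = link_events(locs)
    assert linked["track_id"].nunique() == 1
    # 200 nm apart -> two tracks
    locs = pd.DataFrame({"frame": [0, 1], "x_nm": [0.0, 200.0], "y_nm": [0.0, 0.0]})
    assert link_events(locs)["track_id"].nunique() == 2


def test_link_gap_threshold_inclusive_at_30_frames():
    locs = pd.DataFrame({"frame": [0, 30], "x_nm": [0.0, 0.0], "y_nm": [0.0, 0.0]})
    assert link_events(locs)["track_id"].nunique() == 1
    locs = pd.DataFrame({"frame": [0, 31], "x_nm": [0.0, 0.0], "y_nm": [0.0, 0.0]})
    assert link_events(locs)["track_id"].nunique() == 2


def test_link_rejects_unsorted_and_deduplicates():
    locs = pd.DataFrame({"frame": [1, 0], "x_nm": [0.0, 0.0], "y_nm": [0.0, 0.0]})
    with pytest.raises(ValueError, match="sorted"):
        link_events(locs)
    locs = pd.DataFrame({"frame": [0, 0], "x_nm": [5.0, 5.0], "y_nm": [0.0, 0.0]})
    with pytest.warns(UserWarning, match="duplicate"):
        linked = link_events(locs)
    assert len(linked) == 1


def test_merge_colocated_tracks_rejoins_noise_split_event():
    # one molecule: a > 120 nm noise jump at frame 5 splits off a second
    # track that then runs interleaved with the first at the same spot
    frames = np.arange(12)
    x = np.array([980.0, 1000.0, 1020.0, 1000.0, 990.0, 1111.0,
                  1000.0, 1090.0, 1010.0, 1080.0, 1000.0, 1010.0])
    locs = pd.DataFrame({"frame": frames, "x_nm": x, "y_nm": 0.0})
    linked = link_events(locs)
    assert linked["track_id"].nunique() == 2
    merged = merge_colocated_tracks(linked)
    assert merged["track_id"].nunique() == 1


def test_merge_preserves_separated_molecules():
    locs = pd.DataFrame({
        "frame": [0, 0, 1, 1], "x_nm": [0.0, 5000.0, 10.0, 5010.0],
        "y_nm": [0.0, 0.0, 0.0, 0.0],
    })
    merged = merge_colocated_tracks(link_events(locs))
    assert merged["track_id"].nunique() == 2


# ---------------------------------------------------------------------------
# dwell records


def _trace(n=100, tip0=5000.0, v=60.0, dt=0.06):
    return EndTrace(np.arange(n), tip0 + v * np.arange(n) * dt, dt)


def test_dwell_record_distance_frozen_at_first_frame():
    trace = _trace()
    # molecule binds 1 um behind the tip at frame 10 and stays put
    locs = pd.DataFrame({
        "frame": np.arange(10, 40), "x_nm": trace.tip_at(10) - 1000.0, "y_nm": 0.0,
    })
    linked = link_events(locs)
    recs = dwell_records(linked, trace)
    assert len(recs) == 1
    assert recs.iloc[0]["distance_nm"] == pytest.approx(1000.0)
    assert recs.iloc[0]["dwell_s"] == pytest.approx(30 * 0.06)
    assert not recs.iloc[0]["censored"]


def test_dwell_record_at_tip_and_censoring_flags():
    trace = _trace()
    locs = pd.DataFrame({
        "frame": [0, 1, 2, 98, 99],
        "x_nm": [float(trace.tip_at(0))] * 3 + [3000.0, 3000.0],
        "y_nm": 0.0,
    })
    recs = dwell_records(link_events(locs), trace)
    assert recs.iloc[0]["distance_nm"] == pytest.approx(0.0)
    assert bool(recs.iloc[0]["censored"])  # touches movie start
    assert bool(recs.iloc[1]["censored"])  # touches movie end


def test_pipeline_distances_match_truth(wt_records=None):
    cfg = sd.wildtype_config(seed=21, on_rate_density=0.05)
    locs, truth, trace = sd.simulate_cap_events(cfg)
    from capgrad.end_tracking import mask_localizations

    masked = mask_localizations(locs, trace)
    linked = merge_colocated_tracks(link_events(masked.kept.reset_index(drop=True)))
    recs = dwell_records(linked, trace)
    # match each track to its dominant truth event and compare distances
    truth_of = linked.groupby("track_id")["track_truth_id"].agg(
        lambda s: s.value_counts().index[0]
    )
    ev = truth.events.set_index("event_id")
    matched = recs.join(truth_of.rename("truth_id"), on="event_id")
    d_true = ev.loc[matched["truth_id"], "distance_nm"].to_numpy()
    close = np.abs(matched["distance_nm"].to_numpy() - d_true) < 4 * cfg.sigma_loc
    assert close.mean() >= 0.95


# ---------------------------------------------------------------------------
# survival + mono-exponential fits


def test_survival_definition_on_three_dwells():
    recs = pd.DataFrame({"dwell_s": [0.06, 0.12, 0.18], "censored": False})
    c = survival(recs)
    assert np.allclose(c.t, [0.06, 0.12, 0.18])
    assert np.allclose(c.S, [1.0, 2 / 3, 1 / 3])


def test_survival_step_function_for_equal_dwells():
    recs = pd.DataFrame({"dwell_s": [0.5] * 10, "censored": False})
    c = survival(recs)
    assert np.array_equal(c.t, [0.5]) and np.array_equal(c.S, [1.0])


def test_survival_all_censored_raises():
    recs = pd.DataFrame({"dwell_s": [1.0], "censored": True})
    with pytest.raises(ValueError):
        survival(recs)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.floats(min_value=0.01, max_value=100.0), min_size=1, max_size=200))
def test_survival_monotone_from_one(dwells):
    recs = pd.DataFrame({"dwell_s": dwells, "censored": False})
    c = survival(recs)
    assert c.S[0] == 1.0
    assert np.all(np.diff(c.S) <= 0)
    assert np.all(c.S >= 0)


def test_monoexp_fit_exact_quantile_sample():
    tau = 0.7
    q = (np.arange(500) + 0.5) / 500
    dwells = -tau * np.log(1 - q)
    recs = pd.DataFrame({"dwell_s": dwells, "censored": False})
    fit = fit_monoexp(survival(recs), n_boot=20, mc_test=False)
    assert fit.tau == pytest.approx(tau, rel=0.01)


def test_monoexp_fit_recovers_wildtype_mean_dwell():
    """2000 exponential draws at the wildtype mean dwell (0.88 s),
    quantized to the 60 ms frame grid."""
    rng = np.random.default_rng(12)
    dwells = np.ceil(rng.exponential(0.88, 2000) / 0.06) * 0.06
    recs = pd.DataFrame({"dwell_s": dwells, "censored": False})
    fit = fit_monoexp(survival(recs), n_boot=50, mc_test=True, rng=rng)
    assert fit.tau == pytest.approx(0.88, rel=0.10)
    assert fit.mono_exponential
    # sample mean and tau agree within 10% when mono-exponentiality holds
    assert np.mean(dwells) == pytest.approx(fit.tau, rel=0.10)


def test_monoexp_fit_flags_two_component_mixture():
    rng = np.random.default_rng(3)
    dwells = np.concatenate([
        rng.exponential(0.12, 1500), rng.exponential(2.5, 700)
    ])
    dwells = np.ceil(dwells / 0.06) * 0.06
    recs = pd.DataFrame({"dwell_s": dwells, "censored": False})
    fit = fit_monoexp(survival(recs), n_boot=20, mc_test=True, rng=rng)
    assert not fit.mono_exponential


def test_monoexp_fit_degenerate_input_raises():
    recs = pd.DataFrame({"dwell_s": [0.06] * 5, "censored": False})
    with pytest.raises(ValueError):
        fit_monoexp(survival(recs))


def test_censored_inclusion_biases_dwell_estimate_upward():
    """Events still bound at the movie boundary are length-biased toward the
    long-dwell (near-tip) states: the probability of being caught alive is
    proportional to the dwell.  For a single exponential the truncation
    exactly cancels the length bias (memorylessness), but for the spatial
    dwell mixture the bias tilts the included-events mean upward, which is
    why censored events are excluded from fits by default."""
    records, _ = run_cap_pipeline(sd.wildtype_config, 300, seed=31, n_frames=700)
    assert records["censored"].sum() >= 5
    mean_excl = survival(records, exclude_censored=True).mean_dwell
    mean_incl = survival(records, exclude_censored=False).mean_dwell
    assert mean_incl >= mean_excl


# ---------------------------------------------------------------------------
# spatial gradient


def test_local_profile_flat_data_reports_no_gradient():
    rng = np.random.default_rng(5)
    n = 3000
    recs = pd.DataFrame({
        "dwell_s": np.ceil(rng.exponential(1.0, n) / 0.06) * 0.06,
        "distance_nm": rng.uniform(0, 3000, n),
        "censored": False,
    })
    prof = local_dwell_profile(recs, min_events=100)
    assert not prof.gradient_detected
    assert prof.lambda_nm > 10000  # effectively unbounded


def test_local_profile_too_few_bins_raises():
    recs = pd.DataFrame({
        "dwell_s": [0.06, 0.12, 0.18] * 20, "distance_nm": 100.0, "censored": False,
    })
    with pytest.raises(ValueError, match="bins"):
        local_dwell_profile(recs)


def test_gradient_recovery_across_seeds():
    """Full pipeline recovers the decay length and tip dwell within 15%
    at >= 1500 events, across independent seeds."""
    true_tau = sd.wildtype_config().tau_tip
    for seed in (101, 202, 303, 404, 505):
        records, _ = run_cap_pipeline(sd.wildtype_config, 1500, seed=seed)
        assert len(records) >= 1200
        prof = local_dwell_profile(records)
        assert prof.gradient_detected
        assert prof.lambda_nm == pytest.approx(450.0, rel=0.15)
        assert prof.tau_tip == pytest.approx(true_tau, rel=0.15)


# ---------------------------------------------------------------------------
# derived rates


def test_rate_and_lifetime_arithmetic():
    assert comet_lifetime(500.0, 50.0) == pytest.approx(10.0)
    assert hydrolysis_rate(500.0, 50.0) == pytest.approx(0.1)
    assert hydrolysis_rate(500.0, 100.0) == pytest.approx(0.2)  # linear in v_g
    with pytest.raises(ValueError):
        hydrolysis_rate(500.0, 0.0)
    with pytest.raises(ValueError):
        comet_lifetime(500.0, 0.0)


# ---------------------------------------------------------------------------
# MSD


def _tracks_from_positions(pos_list, dt=0.06):
    rows = []
    for tid, pos in enumerate(pos_list):
        for f, x in enumerate(pos):
            rows.append({"frame": f, "x_nm": x, "y_nm": 0.0, "track_id": tid})
    return pd.DataFrame(rows)


def test_msd_stationary_noiseless_gives_zero_D():
    tracks = _tracks_from_positions([np.full(30, 1000.0)] * 20)
    with pytest.raises(ValueError):
        # zero scatter -> no valid sem weights anywhere
        msd_diffusion(tracks, 0.06)


def test_msd_recovers_diffusion_coefficient():
    rng = np.random.default_rng(7)
    dt, D, sig = 0.06, 1e-3, 30.0
    step = np.sqrt(2 * D * 1e6 * dt)
    pos = []
    for _ in range(250):
        x = 1000.0 + np.cumsum(step * rng.standard_normal(15))
        pos.append(x + sig * rng.standard_normal(15))
    res = msd_diffusion(_tracks_from_positions(pos), dt)
    assert res.D_um2_per_s == pytest.approx(D, rel=0.25)
    assert res.diffusive
    lo, hi = res.sampling_range_nm(8.0)
    assert hi == pytest.approx(np.sqrt(2) * lo)


def test_msd_flags_drift_as_non_diffusive():
    rng = np.random.default_rng(8)
    v = 500.0  # nm/s drift
    pos = [1000.0 + v * 0.06 * np.arange(15) + 5.0 * rng.standard_normal(15)
           for _ in range(100)]
    res = msd_diffusion(_tracks_from_positions(pos), 0.06)
    assert not res.diffusive


def test_msd_requires_long_tracks():
    tracks = _tracks_from_positions([np.full(5, 0.0)])
    with pytest.raises(ValueError, match="track spans"):
        msd_diffusion(tracks, 0.06)
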