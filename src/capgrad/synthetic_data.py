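"""Synthetic single-molecule data with the statistical structure of
TIRF imaging of EB proteins at growing microtubule ends.

The generator emulates one growing microtubule per call: the tip advances at
a constant speed ``v_g``; molecules associate as a Poisson process uniformly
over the whole lattice behind the tip; the dwell time of an event is
exponential with a mean that decays e-fold every ``lambda_cap`` nanometers of
distance behind the tip, frozen at the distance at the moment of binding;
bound molecules diffuse along the lattice; emitters bleach per illuminated
frame, optionally blink, and are localized with Gaussian noise once per frame
(point sampling at the frame time).  The observed density gradient behind the
tip therefore emerges purely from the unbinding gradient — the association
rate itself carries no positional structure.

The module also provides the generative inverses of the titration and
steady-state bleaching experiments, a renderer producing TIFF-compatible
movies from localization tables, and closed-form helpers
(:func:`expected_measured_mean_dwell`, :func:`calibrate_tau_tip`,
:func:`expected_event_count`) that connect generator parameters to what the
analysis pipeline measures, so that study-level conditions ("ensemble mean
dwell of 880 ms", "~2425 events") can be imposed without trial simulation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .binding_kinetics import BleachSeries, bleach_model, hyperbolic_model, quadratic_model
from .comet_analysis import emg_profile
from .end_tracking import EndTrace, Kymograph

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "simulate_cap_events",
    "simulate_titration",
    "simulate_bleach_series",
    "render_movie",
    "render_comet_kymograph",
    "detection_probability",
    "expected_measured_mean_dwell",
    "calibrate_tau_tip",
    "expected_event_count",
    "microtubules_for_events",
    "wildtype_config",
    "e254d_config",
    "lattice_config",
]

LOCALIZATION_COLUMNS = ["frame", "x_nm", "y_nm", "photons", "sigma_nm", "track_truth_id"]


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth parameters of one simulated microtubule movie.

    Parameters
    ----------
    v_g : tip growth speed, nm/s.
    lambda_cap : decay length of the dwell-time gradient, nm (inf = uniform
        affinity, i.e. a lattice with no gradient).
    tau_tip : mean dwell at zero distance behind the tip, s.
    on_rate_density : association events per µm of lattice per second; the
        default corresponds to the picomolar single-molecule imaging regime
        of a few detected events per 10-minute microtubule movie, sparse
        enough that distinct binding events practically never fall within
        the linking thresholds of each other.
    D_lattice : 1-D diffusion coefficient of bound molecules, µm²/s.
    k_bleach : bleaching rate per illuminated second, 1/s.
    p_blink_off, p_blink_on : per-frame blink transition probabilities
        (on→off and off→on); blinking is off by default.
    sigma_loc : localization noise s.d., nm.
    pixel_nm : camera pixel size, nm.
    frame_interval, exposure : frame timing, s (exposure <= interval).
    n_frames : movie length in frames.
    mt_length0 : microtubule length at t = 0, nm (tip starts here).
    seed : RNG seed; the same seed and config give byte-identical output.
    """

    v_g: float = 59.8
    lambda_cap: float = 450.0
    tau_tip: float = 1.5
    on_rate_density: float = 0.004
    D_lattice: float = 1e-3
    k_bleach: float = 1.0 / 45.0
    p_blink_off: float = 0.0
    p_blink_on: float = 1.0
    sigma_loc: float = 30.0
    pixel_nm: float = 120.0
    frame_interval: float = 0.060
    exposure: float = 0.055
    n_frames: int = 10000
    mt_length0: float = 6000.0
    seed: int = 0

    def __post_init__(self):
        for name in (
            "v_g", "tau_tip", "on_rate_density", "D_lattice", "k_bleach",
            "sigma_loc", "pixel_nm", "frame_interval", "exposure", "mt_length0",
        ):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and non-negative, got {v}")
        if not (self.lambda_cap > 0):  # inf allowed
            raise ValueError("lambda_cap must be > 0 (inf allowed)")
        if self.tau_tip <= 0:
            raise ValueError("tau_tip must be > 0")
        for name in ("p_blink_off", "p_blink_on"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.exposure > self.frame_interval:
            raise ValueError("exposure cannot exceed the frame interval")
        if self.frame_interval <= 0 or self.pixel_nm <= 0:
            raise ValueError("frame_interval and pixel_nm must be > 0")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1 (zero-frame movies are empty)")


@dataclass
class SimulationTruth:
    """Ground truth for one simulated microtubule.

    ``events`` has one row per binding event (also undetected ones, flagged
    ``detected=False``); ``trajectories`` holds the true per-frame positions
    of every emitted localization, keyed by ``event_id``.
    """

    config: SimulationConfig
    events: pd.DataFrame = field(repr=False)
    trajectories: pd.DataFrame = field(repr=False)


def _dwell_mean(tau_tip: float, lambda_cap: float, d):
    d = np.asarray(d, dtype=float)
    if np.isinf(lambda_cap):
        return np.full_like(d, tau_tip)
    return tau_tip * np.exp(-d / lambda_cap)


def simulate_cap_events(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, SimulationTruth, EndTrace]:
    """Simulate one growing microtubule and its single-molecule events.

    Returns ``(localizations, truth, end_trace)``.  The localization table
    has the canonical schema (frame, x_nm, y_nm, photons, sigma_nm,
    track_truth_id); the filament lies along the x axis with the minus end at
    x = 0 and y = 0, so the arc-length coordinate equals x.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    dt = cfg.frame_interval
    T = cfg.n_frames * dt
    frames = np.arange(cfg.n_frames)
    tip_per_frame = cfg.mt_length0 + cfg.v_g * frames * dt
    end_trace = EndTrace(frames, tip_per_frame, dt)

    # --- arrivals: Poisson over (time x lattice), uniform per unit length
    rate_nm = cfg.on_rate_density / 1000.0  # events per nm per s
    Lint = cfg.mt_length0 * T + 0.5 * cfg.v_g * T * T  # integral of length over time
    n_arr = rng.poisson(rate_nm * Lint)
    if n_arr == 0:
        empty_locs = pd.DataFrame(columns=LOCALIZATION_COLUMNS)
        empty_events = pd.DataFrame(
            columns=[
                "event_id", "t_bind_s", "x_bind_nm", "distance_nm", "dwell_s",
                "n_frames_emitted", "detected", "censored_end", "bleach_censored",
            ]
        )
        truth = SimulationTruth(
            cfg, empty_events, pd.DataFrame(columns=["event_id", "frame", "x_true_nm"])
        )
        return empty_locs, truth, end_trace
    u = rng.uniform(size=n_arr)
    if cfg.v_g > 0:
        t_bind = (
            -cfg.mt_length0
            + np.sqrt(cfg.mt_length0**2 + 2.0 * cfg.v_g * u * Lint)
        ) / cfg.v_g
    else:
        t_bind = u * T
    length_at = cfg.mt_length0 + cfg.v_g * t_bind
    x_bind = rng.uniform(0.0, length_at)
    d_bind = length_at - x_bind  # distance behind the tip, frozen at binding
    m = _dwell_mean(cfg.tau_tip, cfg.lambda_cap, d_bind)
    dwell = rng.exponential(m)
    t_unbind = t_bind + dwell

    f0 = np.ceil(t_bind / dt).astype(int)  # first frame sampled while bound
    f_last = np.floor(t_unbind / dt).astype(int)
    censored_end = f_last >= cfg.n_frames - 1
    f_last = np.minimum(f_last, cfg.n_frames - 1)
    n_vis = f_last - f0 + 1  # frames the dwell covers (may be <= 0)

    # bleaching: survives frame k (1-based among illuminated frames) while
    # (k-1)*exposure < illumination budget
    if cfg.k_bleach > 0:
        budget = rng.exponential(1.0 / cfg.k_bleach, size=n_arr)
        max_ill = np.floor(budget / cfg.exposure).astype(int) + 1
    else:
        max_ill = np.full(n_arr, np.iinfo(np.int64).max // 2)

    step_sd_nm = math.sqrt(2.0 * cfg.D_lattice * 1e6 * dt)
    blinking = cfg.p_blink_off > 0.0

    loc_rows = []
    traj_rows = []
    n_emitted = np.zeros(n_arr, dtype=int)
    bleach_censored = np.zeros(n_arr, dtype=bool)
    for i in np.nonzero(n_vis >= 1)[0]:
        k_dwell = int(n_vis[i])
        # blink / bleach schedule over candidate frames
        if blinking:
            on = True
            ill = 0
            emit_idx = []
            for k in range(k_dwell):
                if on:
                    if ill >= max_ill[i]:
                        bleach_censored[i] = True
                        break
                    emit_idx.append(k)
                    ill += 1
                    if rng.uniform() < cfg.p_blink_off:
                        on = False
                else:
                    if rng.uniform() < cfg.p_blink_on:
                        on = True
                        if ill >= max_ill[i]:
                            bleach_censored[i] = True
                            break
                        emit_idx.append(k)
                        ill += 1
            emit_idx = np.asarray(emit_idx, dtype=int)
        else:
            k_obs = min(k_dwell, int(max_ill[i]))
            bleach_censored[i] = max_ill[i] < k_dwell
            emit_idx = np.arange(k_obs)
        if len(emit_idx) == 0:
            continue
        k_span = int(emit_idx.max()) + 1
        # true 1-D positions at the frame times f0..f0+k_span-1
        delta_first = f0[i] * dt - t_bind[i]
        stds = np.full(k_span, step_sd_nm)
        stds[0] = math.sqrt(2.0 * cfg.D_lattice * 1e6 * max(delta_first, 0.0))
        x_true = x_bind[i] + np.cumsum(stds * rng.standard_normal(k_span))
        x_emit = x_true[emit_idx]
        fr = f0[i] + emit_idx
        n_emitted[i] = len(emit_idx)
        x_obs = x_emit + cfg.sigma_loc * rng.standard_normal(len(emit_idx))
        y_obs = cfg.sigma_loc * rng.standard_normal(len(emit_idx))
        for k in range(len(emit_idx)):
            loc_rows.append((int(fr[k]), x_obs[k], y_obs[k], 3000.0, cfg.sigma_loc, i))
            traj_rows.append((i, int(fr[k]), x_emit[k]))

    locs = pd.DataFrame(loc_rows, columns=LOCALIZATION_COLUMNS)
    if len(locs):
        locs = locs.sort_values(["frame", "track_truth_id"], kind="stable").reset_index(
            drop=True
        )
    events = pd.DataFrame(
        {
            "event_id": np.arange(n_arr),
            "t_bind_s": t_bind,
            "x_bind_nm": x_bind,
            "distance_nm": d_bind,
            "dwell_s": dwell,
            "n_frames_emitted": n_emitted,
            "detected": n_emitted > 0,
            "censored_end": censored_end,
            "bleach_censored": bleach_censored,
        }
    )
    truth = SimulationTruth(
        cfg, events, pd.DataFrame(traj_rows, columns=["event_id", "frame", "x_true_nm"])
    )
    return locs, truth, end_trace


# ---------------------------------------------------------------------------
# closed-form properties of the generator + observation model


def detection_probability(m, frame_interval: float):
    """Probability that an exponential dwell of mean ``m`` covers at least one
    frame sampling instant (binding time uniform within the frame cycle)."""
    m = np.asarray(m, dtype=float)
    return (m / frame_interval) * (1.0 - np.exp(-frame_interval / m))


def _geometric_ratio(m, cfg_dt, k_bleach, exposure):
    """Per-frame survival ratio of the observed span: dwell survival times
    bleach survival per illuminated frame."""
    return np.exp(-cfg_dt / np.asarray(m, dtype=float)) * math.exp(
        -k_bleach * exposure
    )


def expected_measured_mean_dwell(
    tau_tip: float,
    lambda_cap: float,
    frame_interval: float,
    exposure: float,
    k_bleach: float = 0.0,
    d_max_nm: float | None = None,
) -> float:
    """Expected ensemble mean of *measured* dwell times (inclusive frame span
    × frame interval) over all detected events, for uniform association over
    the lattice behind the tip.

    Detection weighting, frame quantization and per-frame bleaching are all
    accounted for, so this is the quantity the survival pipeline's sample
    mean estimates.  Only meaningful for finite ``lambda_cap``.
    """
    if not np.isfinite(lambda_cap):
        raise ValueError("closed-form mean requires a finite decay length")
    if d_max_nm is None:
        d_max_nm = 40.0 * lambda_cap
    d = np.linspace(0.0, d_max_nm, 20000)
    m = _dwell_mean(tau_tip, lambda_cap, d)
    p = detection_probability(m, frame_interval)
    rho = _geometric_ratio(m, frame_interval, k_bleach, exposure)
    q = frame_interval / (1.0 - rho)  # E[measured dwell | detected]
    return float(np.trapezoid(p * q, d) / np.trapezoid(p, d))


def calibrate_tau_tip(
    target_mean_s: float,
    lambda_cap: float,
    frame_interval: float,
    exposure: float,
    k_bleach: float = 0.0,
) -> float:
    """Tip dwell ``tau_tip`` such that the expected measured ensemble mean
    dwell equals ``target_mean_s`` under the generator's observation model."""

    def f(tau):
        return (
            expected_measured_mean_dwell(
                tau, lambda_cap, frame_interval, exposure, k_bleach
            )
            - target_mean_s
        )

    return float(brentq(f, 1.05 * frame_interval, 200.0, xtol=1e-6))


def expected_event_count(config: SimulationConfig) -> float:
    """Expected number of *detected* binding events for one simulated
    microtubule (events emitting at least one localization)."""
    cfg = config
    T = cfg.n_frames * cfg.frame_interval
    if np.isinf(cfg.lambda_cap):
        mean_len = cfg.mt_length0 + 0.5 * cfg.v_g * T
        p = float(detection_probability(cfg.tau_tip, cfg.frame_interval))
        return cfg.on_rate_density / 1000.0 * T * mean_len * p
    d_hi = min(40.0 * cfg.lambda_cap, cfg.mt_length0)
    d = np.linspace(0.0, d_hi, 20000)
    p = detection_probability(
        _dwell_mean(cfg.tau_tip, cfg.lambda_cap, d), cfg.frame_interval
    )
    ell_det_nm = float(np.trapezoid(p, d))  # effective detection zone length
    return cfg.on_rate_density / 1000.0 * T * ell_det_nm


def microtubules_for_events(config: SimulationConfig, target_events: int) -> int:
    """Number of identically configured microtubules needed so the expected
    total detected-event count reaches ``target_events``."""
    per_mt = expected_event_count(config)
    if per_mt <= 0:
        raise ValueError("configuration yields no detectable events")
    return max(1, int(round(target_events / per_mt)))


# ---------------------------------------------------------------------------
# study-condition configurations


def wildtype_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Wildtype-like growing end: v_g = 59.8 nm/s, dwell gradient decay
    length 450 nm, tip dwell calibrated so the measured ensemble mean dwell
    is 880 ms at 60 ms frames; 30 nm localization noise, 45 s bleaching
    time."""
    base = dict(
        v_g=59.8, lambda_cap=450.0, frame_interval=0.060, exposure=0.055,
        k_bleach=1.0 / 45.0, sigma_loc=30.0, seed=seed,
    )
    base.update(overrides)
    if "tau_tip" not in overrides:
        base["tau_tip"] = calibrate_tau_tip(
            0.880, base["lambda_cap"], base["frame_interval"], base["exposure"],
            base["k_bleach"],
        )
    return SimulationConfig(**base)


def e254d_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Slow-hydrolysis (E254D-like) growing end: v_g = 58.5 nm/s and an
    extended gradient with decay length 850 nm.  The tip dwell is kept at
    the wildtype-calibrated value — the mutation slows cap maturation, not
    the affinity of the freshly formed GTP site at the tip."""
    wt = wildtype_config()
    base = dict(
        v_g=58.5, lambda_cap=850.0, tau_tip=wt.tau_tip, frame_interval=0.060,
        exposure=0.055, k_bleach=1.0 / 45.0, sigma_loc=30.0, seed=seed,
    )
    base.update(overrides)
    return SimulationConfig(**base)


def lattice_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Static, uniform-affinity lattice (hydrolysis-blocked, E254A-like):
    no growth, no dwell gradient, long dwells — the regime used for lattice
    diffusion (MSD) and steady-state bleaching measurements."""
    base = dict(
        v_g=0.0, lambda_cap=float("inf"), tau_tip=10.0, mt_length0=20000.0,
        frame_interval=0.060, exposure=0.055, k_bleach=1.0 / 45.0,
        sigma_loc=30.0, on_rate_density=0.02, n_frames=5000, seed=seed,
    )
    base.update(overrides)
    return SimulationConfig(**base)


# ---------------------------------------------------------------------------
# titration and bleaching series


def simulate_titration(
    model: str,
    params: dict,
    concentrations,
    noise_frac: float = 0.1,
    n_rep: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Equilibrium titration intensities with multiplicative Gaussian noise.

    ``model`` is ``"hyperbolic"`` (params A, K_d) or ``"quadratic"``
    (params A, K_d, T).  Returns a table (E_nM, I, replicate); intensities
    are clipped at zero.
    """
    E = np.asarray(concentrations, dtype=float)
    if np.any(E <= 0):
        raise ValueError("concentrations must be strictly positive")
    if np.any(np.diff(E) <= 0):
        raise ValueError("concentrations must be sorted and strictly increasing")
    if model == "hyperbolic":
        I0 = hyperbolic_model(E, params["A"], params["K_d"])
    elif model == "quadratic":
        I0 = quadratic_model(E, params["A"], params["K_d"], params["T"])
    else:
        raise ValueError(f"unknown titration model '{model}'")
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(n_rep):
        I = I0 * (1.0 + noise_frac * rng.standard_normal(len(E)))
        rows.append(pd.DataFrame({"E_nM": E, "I": np.clip(I, 0.0, None), "replicate": rep}))
    return pd.concat(rows, ignore_index=True)


def simulate_bleach_series(
    k_off: float,
    k_bleach: float,
    intervals,
    exposure: float,
    n_frames: int,
    noise_frac: float = 0.02,
    seed: int = 0,
) -> list[BleachSeries]:
    """Steady-state bleaching decays at several frame intervals.

    Per interval Δt the normalized ensemble intensity follows
    ``bleach_model(frame·Δt, k_off, k_bleach·exposure/Δt)`` — bleaching acts
    only during the illuminated exposure — times multiplicative noise, then
    renormalized to the first frame.
    """
    if k_off < 0 or k_bleach < 0:
        raise ValueError("rates must be non-negative")
    intervals = [float(dt) for dt in intervals]
    if any(dt <= 0 for dt in intervals):
        raise ValueError("frame intervals must be > 0")
    if exposure > min(intervals):
        raise ValueError("exposure cannot exceed the shortest frame interval")
    rng = np.random.default_rng(seed)
    series = []
    for dt in intervals:
        frames = np.arange(n_frames)
        k_b_eff = k_bleach * exposure / dt
        F = bleach_model(frames * dt, k_off, k_b_eff)
        F = F * (1.0 + noise_frac * rng.standard_normal(n_frames))
        F = F / F[0]
        series.append(BleachSeries(frame_interval=dt, exposure=exposure, frames=frames, F=F))
    return series


# ---------------------------------------------------------------------------
# rendering


def render_movie(
    localizations: pd.DataFrame,
    config: SimulationConfig,
    shape: tuple[int, int] | None = None,
    psf_sigma_px: float = 1.2,
    background: float = 100.0,
    photons: float | None = None,
    poisson_noise: bool = True,
    offset_nm: tuple[float, float] = (0.0, 0.0),
    seed: int | None = None,
) -> np.ndarray:
    """Render a localization table as a 16-bit TIRF-like movie.

    Each emitter becomes a 2-D Gaussian PSF of s.d. ``psf_sigma_px`` pixels
    integrated to its photon count, on a constant background, with optional
    Poisson shot noise.  ``offset_nm`` shifts all emitters (e.g. to center a
    filament that lies on y = 0).  Emitters outside the frame are clipped
    with a warning.  Returns an array of shape (n_frames, H, W), uint16.
    """
    px = config.pixel_nm
    if shape is None:
        if len(localizations):
            w = int(np.ceil((localizations["x_nm"].max() + offset_nm[0]) / px)) + 8
            h = int(np.ceil((localizations["y_nm"].max() + offset_nm[1]) / px)) + 8
            shape = (max(h, 16), max(w, 16))
        else:
            shape = (32, 32)
    H, W = shape
    movie = np.full((config.n_frames, H, W), float(background))
    half = int(np.ceil(4 * psf_sigma_px))
    clipped = 0
    for row in localizations.itertuples(index=False):
        f = int(row.frame)
        if not 0 <= f < config.n_frames:
            clipped += 1
            continue
        cx = (row.x_nm + offset_nm[0]) / px
        cy = (row.y_nm + offset_nm[1]) / px
        if not (0 <= cx < W and 0 <= cy < H):
            clipped += 1
            continue
        nph = float(photons if photons is not None else getattr(row, "photons", 3000.0))
        x0, x1 = max(int(cx) - half, 0), min(int(cx) + half + 1, W)
        y0, y1 = max(int(cy) - half, 0), min(int(cy) + half + 1, H)
        xs = np.arange(x0, x1)
        ys = np.arange(y0, y1)
        gx = np.exp(-((xs - cx) ** 2) / (2 * psf_sigma_px**2))
        gy = np.exp(-((ys - cy) ** 2) / (2 * psf_sigma_px**2))
        psf = np.outer(gy, gx)
        psf *= nph / (2 * np.pi * psf_sigma_px**2)
        movie[f, y0:y1, x0:x1] += psf
    if clipped:
        warnings.warn(f"{clipped} emitters fell outside the rendered frame")
    if poisson_noise:
        rng = np.random.default_rng(config.seed if seed is None else seed)
        movie = rng.poisson(movie).astype(float)
    return np.clip(movie, 0, 65535).astype(np.uint16)


def render_comet_kymograph(
    n_frames: int,
    n_px: int,
    v_g: float,
    tip0_nm: float,
    profile: Callable[[np.ndarray], np.ndarray] | dict,
    pixel_nm: float = 120.0,
    frame_interval: float = 0.2,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[Kymograph, EndTrace]:
    """Synthetic kymograph of a comet riding on an advancing tip.

    ``profile`` maps distance behind the tip (nm, positive into the lattice)
    to intensity; a dict of EMG parameters (A, x_c, sigma, and optionally B)
    is also accepted.  Intensity ahead of the tip falls off through the same
    profile.  Returns the kymograph and the true end trace.
    """
    if isinstance(profile, dict):
        p = dict(profile)

        def profile_fn(d):
            return emg_profile(d, p["A"], p["x_c"], p["sigma"], 0.0, p.get("B", 0.0))
    else:
        profile_fn = profile
    rng = np.random.default_rng(seed)
    s = np.arange(n_px) * pixel_nm
    frames = np.arange(n_frames)
    tip = tip0_nm + v_g * frames * frame_interval
    data = np.empty((n_frames, n_px))
    for f in frames:
        data[f] = profile_fn(tip[f] - s)
    if noise_sd > 0:
        data = data + noise_sd * rng.standard_normal(data.shape)
    poly = np.array([[0.0, 0.0], [n_px * pixel_nm, 0.0]])
    kymo = Kymograph(
        data=data, s_nm=s, polyline=poly, pixel_nm=pixel_nm,
        frame_interval=frame_interval,
    )
    return kymo, EndTrace(frames, tip, frame_interval)
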