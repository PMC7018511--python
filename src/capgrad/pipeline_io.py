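"""Pipeline orchestration, run configuration and file formats.

All files use a single unit convention — nanometers, seconds, nanomolar —
with the units carried in the column names, because the upstream literature
mixes nm/µm and ms/s and silent unit mistakes are the dominant failure mode
in this kind of analysis.  Tables are plain CSV with fixed headers; movies
are 16-bit multi-page TIFF; configs and reports are JSON.

:func:`run_all` executes the selected stages end-to-end — simulate →
mask → link → dwell/MSD, plus titration and bleaching fits — with every
random choice derived from a single seed, so that two runs with the same
config produce byte-identical data artifacts.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .binding_kinetics import BleachSeries, fit_bleach_global, fit_hyperbolic, fit_quadratic
from .dwell_analysis import (
    DWELL_COLUMNS,
    dwell_records,
    fit_monoexp,
    link_events,
    local_dwell_profile,
    merge_colocated_tracks,
    msd_diffusion,
    survival,
)
from .end_tracking import EndTrace, mask_localizations
from .synthetic_data import (
    LOCALIZATION_COLUMNS,
    SimulationConfig,
    microtubules_for_events,
    simulate_bleach_series,
    simulate_cap_events,
    simulate_titration,
)

__all__ = [
    "RunConfig",
    "run_all",
    "child_seed",
    "read_localizations",
    "write_localizations",
    "read_end_trace",
    "write_end_trace",
    "read_dwell_records",
    "write_dwell_records",
    "read_titration",
    "write_titration",
    "read_bleach_series",
    "write_bleach_series",
    "read_movie",
    "write_movie",
]

END_TRACE_COLUMNS = ["frame", "tip_s_nm"]
TITRATION_COLUMNS = ["E_nM", "I", "replicate"]
BLEACH_COLUMNS = ["interval_s", "frame", "F"]


# ---------------------------------------------------------------------------
# seeding


def child_seed(seed: int, index: int) -> int:
    """Deterministic sub-seed (< 2^31) for the index-th independent stream."""
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(index,))
    return int(ss.generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# CSV schemas


def _read_csv_checked(path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in required:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column '{col}'")
        bad = df[col].isna()
        if bad.any():
            rows = (np.nonzero(bad.to_numpy())[0] + 2).tolist()[:5]
            raise ValueError(f"{path}: column '{col}' has missing values at rows {rows}")
    return df


def write_localizations(df: pd.DataFrame, path) -> None:
    cols = [c for c in LOCALIZATION_COLUMNS if c in df.columns]
    df.to_csv(path, index=False, columns=cols)


def read_localizations(path) -> pd.DataFrame:
    return _read_csv_checked(path, ["frame", "x_nm", "y_nm", "photons", "sigma_nm"])


def write_end_trace(trace: EndTrace, path) -> None:
    trace.to_frame().to_csv(path, index=False)


def read_end_trace(path, frame_interval: float = 0.06) -> EndTrace:
    df = _read_csv_checked(path, END_TRACE_COLUMNS)
    return EndTrace(df["frame"].to_numpy(), df["tip_s_nm"].to_numpy(), frame_interval)


def write_dwell_records(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=DWELL_COLUMNS)


def read_dwell_records(path) -> pd.DataFrame:
    return _read_csv_checked(path, DWELL_COLUMNS)


def write_titration(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=TITRATION_COLUMNS)


def read_titration(path) -> pd.DataFrame:
    return _read_csv_checked(path, ["E_nM", "I"])


def write_bleach_series(series: list[BleachSeries], path) -> None:
    pd.concat([s.to_frame() for s in series], ignore_index=True).to_csv(path, index=False)


def read_bleach_series(path, exposure: float) -> list[BleachSeries]:
    df = _read_csv_checked(path, BLEACH_COLUMNS)
    out = []
    for dt, grp in df.groupby("interval_s", sort=True):
        out.append(
            BleachSeries(
                frame_interval=float(dt), exposure=exposure,
                frames=grp["frame"].to_numpy(), F=grp["F"].to_numpy(),
            )
        )
    return out


def write_movie(movie: np.ndarray, path) -> None:
    tifffile.imwrite(path, movie.astype(np.uint16))


def read_movie(path) -> np.ndarray:
    movie = tifffile.imread(path)
    if movie.ndim == 2:
        movie = movie[None]
    return movie


# ---------------------------------------------------------------------------
# run configuration


_STAGES = ("dwell", "msd", "titration", "bleach")


@dataclass
class RunConfig:
    """Parameters of an end-to-end run.

    ``simulation`` holds overrides for :class:`SimulationConfig`; the number
    of simulated microtubules is either explicit (``n_microtubules``) or
    derived from a target detected-event count.  Unknown keys anywhere in a
    loaded JSON config are rejected.
    """

    seed: int = 0
    stages: list = field(default_factory=lambda: ["dwell"])
    simulation: dict = field(default_factory=dict)
    n_microtubules: int | None = 3
    target_events: int | None = None
    max_dist_nm: float = 120.0
    max_gap_frames: int = 30
    lateral_tol_nm: float = 240.0
    bin_width_nm: float = 590.0
    min_events: int = 30
    max_lag_frames: int = 10
    titration: dict = field(default_factory=dict)
    bleach: dict = field(default_factory=dict)
    out_dir: str | None = None

    def __post_init__(self):
        for s in self.stages:
            if s not in _STAGES:
                raise ValueError(f"unknown stage '{s}'; valid stages: {_STAGES}")

    @classmethod
    def from_json(cls, path_or_dict) -> "RunConfig":
        if isinstance(path_or_dict, dict):
            data = path_or_dict
        else:
            data = json.loads(Path(path_or_dict).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        sim_known = {f.name for f in dataclasses.fields(SimulationConfig)}
        sim_unknown = set(data.get("simulation", {})) - sim_known
        if sim_unknown:
            raise ValueError(f"unknown simulation keys: {sorted(sim_unknown)}")
        return cls(**data)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))


# ---------------------------------------------------------------------------
# orchestration


def _simulation_config(cfg: RunConfig, seed: int) -> SimulationConfig:
    params = dict(cfg.simulation)
    params["seed"] = seed
    return SimulationConfig(**params)


def run_all(config: RunConfig) -> dict:
    """Execute the selected stages and return the run report.

    The report echoes every parameter, reconciles record counts across
    stages, and contains the fit results with standard errors.  When
    ``out_dir`` is set, all data artifacts (localizations, dwell records,
    survival curves, fit reports) are written there.
    """
    cfg = config
    out = Path(cfg.out_dir) if cfg.out_dir else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "software": {"name": "capgrad", "version": __version__},
        "seed": cfg.seed,
        "config": dataclasses.asdict(cfg),
        "stages": {},
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }

    if "dwell" in cfg.stages or "msd" in cfg.stages:
        base = _simulation_config(cfg, seed=0)
        if cfg.target_events is not None:
            n_mt = microtubules_for_events(base, cfg.target_events)
        else:
            n_mt = cfg.n_microtubules or 1
        all_records = []
        all_tracks = []
        counts = {
            "n_microtubules": n_mt, "n_truth_events": 0, "n_localizations": 0,
            "n_masked_out": 0, "n_tracks": 0,
        }
        v_gs = []
        for i in range(n_mt):
            sim_cfg = _simulation_config(cfg, seed=child_seed(cfg.seed, i))
            locs, truth, trace = simulate_cap_events(sim_cfg)
            masked = mask_localizations(
                locs, trace, polyline=None, lateral_tol_nm=cfg.lateral_tol_nm
            )
            assert len(masked.kept) + len(masked.removed) == len(locs)
            if len(masked.kept) == 0:
                continue
            linked = link_events(
                masked.kept.reset_index(drop=True),
                max_dist_nm=cfg.max_dist_nm, max_gap_frames=cfg.max_gap_frames,
            )
            linked = merge_colocated_tracks(linked, max_dist_nm=cfg.max_dist_nm)
            records = dwell_records(linked, trace, sim_cfg.frame_interval)
            counts["n_truth_events"] += len(truth.events)
            counts["n_localizations"] += len(locs)
            counts["n_masked_out"] += len(masked.removed)
            counts["n_tracks"] += linked["track_id"].nunique()
            linked = linked.copy()
            linked["track_id"] = linked["track_id"] + sum(
                t["track_id"].nunique() for t in all_tracks
            )
            all_tracks.append(linked)
            all_records.append(records)
            if sim_cfg.v_g > 0:
                v_gs.append(trace.v_g)
        records = pd.concat(all_records, ignore_index=True) if all_records else pd.DataFrame(columns=DWELL_COLUMNS)
        tracks = pd.concat(all_tracks, ignore_index=True) if all_tracks else None
        counts["n_records"] = len(records)
        counts["n_censored"] = int(records["censored"].sum()) if len(records) else 0
        stage: dict = {"counts": counts, "simulation": dataclasses.asdict(base)}
        if "dwell" in cfg.stages and len(records):
            curve = survival(records)
            fit = fit_monoexp(curve, n_boot=50, n_mc=100)
            stage["n_events"] = int(curve.n_events)
            stage["mean_dwell_s"] = curve.mean_dwell
            stage["tau_s"] = fit.tau
            stage["tau_se_s"] = fit.tau_se
            stage["mono_exponential"] = fit.mono_exponential
            stage["v_g_nm_per_s"] = float(np.mean(v_gs)) if v_gs else 0.0
            try:
                profile = local_dwell_profile(
                    records, bin_width_nm=cfg.bin_width_nm, min_events=cfg.min_events
                )
                stage["lambda_nm"] = profile.lambda_nm
                stage["lambda_se_nm"] = profile.lambda_se
                stage["tau_tip_s"] = profile.tau_tip
                stage["gradient_detected"] = profile.gradient_detected
            except ValueError as err:
                stage["lambda_nm"] = None
                stage["gradient_note"] = str(err)
            if out is not None:
                write_dwell_records(records, out / "dwell_records.csv")
                curve.to_frame().to_csv(out / "survival.csv", index=False)
        if "msd" in cfg.stages and tracks is not None:
            msd = msd_diffusion(tracks, base.frame_interval, cfg.max_lag_frames)
            stage["msd"] = {
                "D_um2_per_s": msd.D_um2_per_s, "D_se": msd.D_se,
                "offset_um2": msd.offset_um2, "diffusive": msd.diffusive,
            }
        report["stages"]["dwell"] = stage

    if "titration" in cfg.stages:
        t = dict(cfg.titration)
        model = t.pop("model", "hyperbolic")
        params = t.pop("params", {"A": 1.0, "K_d": 40.0})
        concentrations = t.pop("concentrations", [2, 5, 10, 25, 50, 100, 200, 500])
        noise_frac = t.pop("noise_frac", 0.1)
        n_rep = t.pop("n_rep", 5)
        if t:
            raise ValueError(f"unknown titration keys: {sorted(t)}")
        series = simulate_titration(
            model, params, concentrations, noise_frac, n_rep,
            seed=child_seed(cfg.seed, 1001),
        )
        if model == "hyperbolic":
            fit = fit_hyperbolic(series)
            result = {"K_d_nM": fit.K_d, "K_d_se": fit.K_d_se, "A": fit.A}
        else:
            fit = fit_quadratic(series, T_fixed=params.get("T"))
            result = {"K_d_nM": fit.K_d, "K_d_se": fit.K_d_se, "A": fit.A, "T_nM": fit.T}
        report["stages"]["titration"] = {"model": model, "fit": result, "n": len(series)}
        if out is not None:
            write_titration(series, out / "titration.csv")

    if "bleach" in cfg.stages:
        b = dict(cfg.bleach)
        k_off = b.pop("k_off", 1.0 / 300.0)
        k_bleach = b.pop("k_bleach", 1.0 / 45.0)
        intervals = b.pop("intervals", [0.06, 0.1, 0.2])
        exposure = b.pop("exposure", 0.055)
        n_frames = b.pop("n_frames", 3000)
        noise_frac = b.pop("noise_frac", 0.02)
        if b:
            raise ValueError(f"unknown bleach keys: {sorted(b)}")
        series = simulate_bleach_series(
            k_off, k_bleach, intervals, exposure, n_frames, noise_frac,
            seed=child_seed(cfg.seed, 2001),
        )
        fit = fit_bleach_global(series)
        report["stages"]["bleach"] = {
            "k_off_per_s": fit.k_off, "k_b_per_s": fit.k_b,
            "bleaching_time_s": fit.bleaching_time,
            "k_off_se": fit.k_off_se, "k_b_se": fit.k_b_se,
        }
        if out is not None:
            write_bleach_series(series, out / "bleach.csv")

    if out is not None:
        (out / "run_report.json").write_text(json.dumps(report, indent=2, default=float))
    return report
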