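"""Kymograph construction, growing-end tracing and spatial masking.

A microtubule trajectory is a polyline drawn over the field of view (nm
coordinates).  A kymograph samples the movie along that polyline, one row per
frame.  The growing-end position per frame (the "end trace") defines, together
with a lateral tolerance around the trajectory, the admissible region for
single-molecule localizations: points on the microtubule up to the growing
end in each frame.  Localizations beyond the tip or off the trajectory are
removed before linking, with the removal reason logged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates, median_filter

__all__ = [
    "Kymograph",
    "EndTrace",
    "MaskResult",
    "build_kymograph",
    "trace_end",
    "mask_localizations",
    "project_onto_polyline",
]


@dataclass
class Kymograph:
    """Space-time intensity image along one trajectory.

    ``data`` has shape (n_frames, n_arc_samples); ``s_nm`` is the arc-length
    coordinate of each column measured from the start of the polyline.
    """

    data: np.ndarray
    s_nm: np.ndarray
    polyline: np.ndarray  # (N, 2) x,y in nm
    pixel_nm: float
    frame_interval: float  # s


@dataclass
class EndTrace:
    """Per-frame tip position along a trajectory.

    ``tip_s_nm`` is the arc-length position of the growing end; frames are
    0-based and must be contiguous for the frames analyzed.  ``flags`` marks
    frames where the position was interpolated rather than traced.
    """

    frames: np.ndarray
    tip_s_nm: np.ndarray
    frame_interval: float  # s
    flags: np.ndarray = field(default=None)

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=int)
        self.tip_s_nm = np.asarray(self.tip_s_nm, dtype=float)
        if self.flags is None:
            self.flags = np.zeros(len(self.frames), dtype=bool)
        if len(self.frames) != len(self.tip_s_nm):
            raise ValueError("frames and tip positions must have equal length")
        if not np.all(np.isfinite(self.tip_s_nm)):
            raise ValueError("tip positions must be finite")

    @property
    def v_g(self) -> float:
        """Growth speed (nm/s) from a least-squares line through the trace."""
        t = self.frames * self.frame_interval
        if len(t) < 2:
            raise ValueError("need >= 2 frames to estimate a growth speed")
        return float(np.polyfit(t, self.tip_s_nm, 1)[0])

    def tip_at(self, frames) -> np.ndarray:
        """Tip arc-length at the given frames (nan outside the trace)."""
        frames = np.asarray(frames, dtype=float)
        out = np.interp(frames, self.frames, self.tip_s_nm)
        out = np.where(
            (frames >= self.frames.min()) & (frames <= self.frames.max()), out, np.nan
        )
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"frame": self.frames, "tip_s_nm": self.tip_s_nm})


def _polyline_geometry(polyline: np.ndarray):
    poly = np.asarray(polyline, dtype=float)
    if poly.ndim != 2 or poly.shape[0] < 2 or poly.shape[1] != 2:
        raise ValueError("trajectory polyline needs >= 2 (x, y) points")
    seg = np.diff(poly, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    if np.any(seg_len == 0):
        raise ValueError("degenerate polyline segment of zero length")
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    return poly, seg, seg_len, cum


def build_kymograph(
    movie: np.ndarray,
    polyline,
    width_px: int = 5,
    pixel_nm: float = 120.0,
    frame_interval: float = 0.06,
    reduce: str = "max",
) -> Kymograph:
    """Sample a movie along a trajectory polyline, one row per frame.

    The intensity at (frame, arc position) is the max (or mean) over
    ``width_px`` samples taken perpendicular to the trajectory, which makes
    the kymograph robust to a microtubule lying a pixel off the drawn line.
    Arc positions are spaced by one pixel.
    """
    if movie.ndim != 3:
        raise ValueError("movie must be a (frames, y, x) stack")
    if reduce not in ("max", "mean"):
        raise ValueError("reduce must be 'max' or 'mean'")
    poly, seg, seg_len, cum = _polyline_geometry(polyline)
    total = cum[-1]
    s = np.arange(0.0, total + 0.5 * pixel_nm, pixel_nm)
    # point and unit normal at each arc position
    seg_idx = np.clip(np.searchsorted(cum, s, side="right") - 1, 0, len(seg) - 1)
    frac = (s - cum[seg_idx]) / seg_len[seg_idx]
    pts = poly[seg_idx] + frac[:, None] * seg[seg_idx]
    tang = seg[seg_idx] / seg_len[seg_idx, None]
    normal = np.stack([-tang[:, 1], tang[:, 0]], axis=1)
    offsets = (np.arange(width_px) - (width_px - 1) / 2.0) * pixel_nm
    # sample coordinates in pixel units, shape (width, n_s, 2)
    coords = (pts[None, :, :] + offsets[:, None, None] * normal[None, :, :]) / pixel_nm
    rows_px = coords[..., 1].ravel()
    cols_px = coords[..., 0].ravel()
    out = np.empty((movie.shape[0], len(s)), dtype=float)
    for f in range(movie.shape[0]):
        samples = map_coordinates(
            movie[f].astype(float), [rows_px, cols_px], order=1, mode="nearest"
        ).reshape(width_px, len(s))
        out[f] = samples.max(axis=0) if reduce == "max" else samples.mean(axis=0)
    return Kymograph(
        data=out, s_nm=s, polyline=poly, pixel_nm=pixel_nm,
        frame_interval=frame_interval,
    )


def trace_end(
    kymograph: Kymograph | None = None,
    method: str = "threshold",
    trace_file=None,
    smooth_frames: int = 5,
) -> EndTrace:
    """Locate the growing end in each kymograph frame.

    ``method='file'`` loads a manually traced CSV (columns frame, tip_s_nm),
    the analogue of tracing the end by hand.  ``method='threshold'`` is an
    automated stand-in: per frame, the farthest arc position whose intensity
    exceeds half of the comet plateau, median-smoothed over
    ``smooth_frames`` frames.  Frames with no suprathreshold pixel are
    linearly interpolated and flagged.
    """
    if method == "file":
        df = pd.read_csv(trace_file) if not isinstance(trace_file, pd.DataFrame) else trace_file
        for col in ("frame", "tip_s_nm"):
            if col not in df.columns:
                raise ValueError(f"trace file missing required column '{col}'")
        dt = kymograph.frame_interval if kymograph is not None else 1.0
        return EndTrace(df["frame"].to_numpy(), df["tip_s_nm"].to_numpy(), dt)
    if method != "threshold":
        raise ValueError(f"unknown tracing method '{method}'")
    data = kymograph.data
    lo = float(np.percentile(data, 5))
    hi = float(np.percentile(data, 95))
    if hi <= lo:
        raise ValueError("kymograph has no visible edge (flat intensity)")
    thresh = lo + 0.5 * (hi - lo)
    n_frames = data.shape[0]
    tip = np.full(n_frames, np.nan)
    for f in range(n_frames):
        above = np.nonzero(data[f] >= thresh)[0]
        if len(above):
            tip[f] = kymograph.s_nm[above[-1]]
    flags = ~np.isfinite(tip)
    if flags.all():
        raise ValueError("no suprathreshold pixels in any frame")
    if flags.any():
        frames_all = np.arange(n_frames)
        tip[flags] = np.interp(frames_all[flags], frames_all[~flags], tip[~flags])
    if smooth_frames > 1:
        tip = median_filter(tip, size=smooth_frames, mode="nearest")
    return EndTrace(np.arange(n_frames), tip, kymograph.frame_interval, flags=flags)


def project_onto_polyline(points: np.ndarray, polyline) -> tuple[np.ndarray, np.ndarray]:
    """Arc-length and lateral distance of x-y points relative to a polyline.

    Returns ``(s_nm, lateral_nm)`` where ``s`` is the arc-length of the
    closest point on the polyline and ``lateral`` the unsigned distance to
    it.  Used both to mask localizations onto a microtubule and to assign a
    1-D coordinate along the filament axis.
    """
    poly, seg, seg_len, cum = _polyline_geometry(polyline)
    pts = np.asarray(points, dtype=float)
    best_d2 = np.full(len(pts), np.inf)
    best_s = np.zeros(len(pts))
    for i in range(len(seg)):
        rel = pts - poly[i]
        t = np.clip((rel @ seg[i]) / (seg_len[i] ** 2), 0.0, 1.0)
        proj = poly[i] + t[:, None] * seg[i]
        d2 = np.sum((pts - proj) ** 2, axis=1)
        better = d2 < best_d2
        best_d2[better] = d2[better]
        best_s[better] = cum[i] + t[better] * seg_len[i]
    return best_s, np.sqrt(best_d2)


@dataclass
class MaskResult:
    """Localizations retained by the microtubule mask plus the removal log."""

    kept: pd.DataFrame  # with added s_nm, lateral_nm columns
    removed: pd.DataFrame  # same + 'reason' column


def mask_localizations(
    localizations: pd.DataFrame,
    end_trace: EndTrace,
    polyline=None,
    lateral_tol_nm: float = 240.0,
) -> MaskResult:
    """Keep localizations on the microtubule up to the traced growing end.

    A localization survives if it lies within ``lateral_tol_nm`` of the
    trajectory and its arc-length does not exceed the traced tip position in
    its frame (boundary inclusive).  Localizations in frames not covered by
    the trace are dropped with a warning.  ``polyline=None`` treats the
    filament as the x axis (s = x, lateral = |y|), the geometry produced by
    the synthetic generator.

    Row conservation holds by construction: every input row lands in either
    ``kept`` or ``removed``.
    """
    locs = localizations.copy()
    for col in ("frame", "x_nm", "y_nm"):
        if col not in locs.columns:
            raise ValueError(f"localization table missing required column '{col}'")
    if len(locs) == 0:
        empty = locs.assign(s_nm=pd.Series(dtype=float), lateral_nm=pd.Series(dtype=float))
        return MaskResult(kept=empty, removed=empty.assign(reason=pd.Series(dtype=str)))
    if polyline is None:
        s = locs["x_nm"].to_numpy(float)
        lateral = np.abs(locs["y_nm"].to_numpy(float))
    else:
        s, lateral = project_onto_polyline(
            locs[["x_nm", "y_nm"]].to_numpy(float), polyline
        )
    locs["s_nm"] = s
    locs["lateral_nm"] = lateral
    tip = end_trace.tip_at(locs["frame"].to_numpy())
    no_trace = ~np.isfinite(tip)
    if no_trace.any():
        warnings.warn(
            f"{int(no_trace.sum())} localizations in frames without an end "
            "trace were dropped"
        )
    off_axis = lateral > lateral_tol_nm
    beyond_tip = np.zeros(len(locs), dtype=bool)
    covered = ~no_trace
    beyond_tip[covered] = s[covered] > tip[covered]
    reason = np.where(
        no_trace, "no_trace_frame", np.where(off_axis, "off_trajectory",
                                             np.where(beyond_tip, "beyond_tip", ""))
    )
    drop = no_trace | off_axis | beyond_tip
    removed = locs[drop].copy()
    removed["reason"] = reason[drop]
    return MaskResult(kept=locs[~drop].copy(), removed=removed)
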