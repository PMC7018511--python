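"""Equilibrium binding isotherms and steady-state photobleaching kinetics.

Two isotherm models are provided for titrations of a fluorescent
microtubule-binding protein (EB3) against microtubules:

* the hyperbolic (Langmuir) isotherm ``I = A·E/(K_d + E)``, valid when the
  ligand is in large excess over binding sites, and
* the quadratic ligand-depletion isotherm, used when the total binding-site
  concentration ``T`` is comparable to the dissociation constant, so that
  binding depletes the free ligand pool.

The steady-state bleaching model separates photobleaching (proportional to
illumination time) from unbinding (proportional to real time) by imaging the
same steady state at several frame intervals with a fixed exposure.  Bound
molecules bleach at a rate ``k_b`` per illuminated second and unbind at
``k_off`` per real second; with exchange from an unbleached solution pool the
ensemble fluorescence relaxes as::

    F(t) = (k_off + k_b_eff · exp(-k_T t)) / k_T,      k_T = k_off + k_b_eff

where ``k_b_eff = k_b · exposure / interval`` is the duty-cycle-scaled
bleaching rate on the real-time axis.  A global fit over several intervals
with shared ``k_off`` makes the two rates separately identifiable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit, least_squares

__all__ = [
    "HyperbolicFit",
    "QuadraticFit",
    "BleachSeries",
    "BleachFit",
    "hyperbolic_model",
    "quadratic_model",
    "fit_hyperbolic",
    "fit_quadratic",
    "bleach_model",
    "fit_bleach_global",
    "dwell_bias_correction",
]


# ---------------------------------------------------------------------------
# isotherm models


def hyperbolic_model(E, A, K_d):
    """Langmuir isotherm ``I = A·E/(K_d + E)`` (ligand excess limit)."""
    E = np.asarray(E, dtype=float)
    return A * E / (K_d + E)


def quadratic_model(E, A, K_d, T):
    """Ligand-depletion isotherm.

    ``I = A·[(T + E + K_d) - sqrt((T + E + K_d)^2 - 4·T·E)]``

    ``T`` is the total binding-site concentration (nM) and ``E`` the total
    ligand concentration (nM).  The conventional factor of 1/2 in the bound
    fraction is absorbed into the free amplitude ``A``, which leaves ``K_d``
    unaffected.  The discriminant is clipped at zero against round-off.
    """
    E = np.asarray(E, dtype=float)
    s = T + E + K_d
    disc = s * s - 4.0 * T * E
    if np.any(disc < 0):
        warnings.warn("quadratic isotherm discriminant < 0; clipping at 0")
    return A * (s - np.sqrt(np.clip(disc, 0.0, None)))


@dataclass
class HyperbolicFit:
    """Result of a hyperbolic isotherm fit."""

    K_d: float
    A: float
    K_d_se: float
    A_se: float
    n_points: int
    unbounded: bool = False  # no curvature in data; K_d not determined


@dataclass
class QuadraticFit:
    """Result of a quadratic ligand-depletion fit."""

    K_d: float
    A: float
    T: float
    K_d_se: float
    A_se: float
    T_se: float  # 0 when T was held fixed
    T_fixed: bool
    n_points: int


def _extract_titration(series) -> tuple[np.ndarray, np.ndarray]:
    """Accept a DataFrame with E_nM/I columns or an (E, I) pair."""
    if isinstance(series, pd.DataFrame):
        for col in ("E_nM", "I"):
            if col not in series.columns:
                raise ValueError(f"titration table missing required column '{col}'")
        return series["E_nM"].to_numpy(float), series["I"].to_numpy(float)
    E, I = series
    return np.asarray(E, dtype=float), np.asarray(I, dtype=float)


def _titration_sigma(I: np.ndarray, weighting: str) -> np.ndarray | None:
    """Per-point sigma for isotherm fits.

    Fluorescence intensities carry noise roughly proportional to the signal,
    so the default weighting uses sigma ~ I (floored at 5% of the maximum to
    avoid zero weights near E = 0); ``weighting='none'`` falls back to
    ordinary least squares.
    """
    if weighting == "none":
        return None
    if weighting != "proportional":
        raise ValueError(f"unknown weighting '{weighting}'")
    scale = float(np.max(np.abs(I))) or 1.0
    return np.clip(np.abs(I), 0.05 * scale, None)


def fit_hyperbolic(series, weighting: str = "proportional") -> HyperbolicFit:
    """Least-squares fit of the hyperbolic isotherm.

    Parameters
    ----------
    series : DataFrame with columns ``E_nM``, ``I`` (one row per replicate
        measurement), or a tuple ``(E, I)`` of arrays.
    weighting : ``'proportional'`` (default; sigma ~ I, matching
        signal-proportional intensity noise) or ``'none'``.

    Returns
    -------
    HyperbolicFit. ``unbounded`` is set when the data show no curvature so
    that only the ratio A/K_d is constrained.
    """
    E, I = _extract_titration(series)
    if len(np.unique(E)) < 3:
        raise ValueError("hyperbolic fit requires >= 3 distinct concentrations")
    if np.any(E <= 0):
        raise ValueError("concentrations must be strictly positive")
    A0 = float(np.max(I)) or 1.0
    K0 = float(np.median(E))
    popt, pcov = curve_fit(
        hyperbolic_model, E, I, p0=[A0, K0], bounds=([0, 1e-12], [np.inf, np.inf]),
        sigma=_titration_sigma(I, weighting), maxfev=20000,
    )
    se = np.sqrt(np.diag(pcov))
    unbounded = bool(popt[1] > 50 * E.max() or not np.isfinite(se[1]) or se[1] > popt[1])
    return HyperbolicFit(
        K_d=float(popt[1]), A=float(popt[0]), K_d_se=float(se[1]), A_se=float(se[0]),
        n_points=len(E), unbounded=unbounded,
    )


def fit_quadratic(
    series, T_fixed: float | None = None, weighting: str = "proportional"
) -> QuadraticFit:
    """Least-squares fit of the quadratic depletion isotherm.

    With ``T_fixed`` given (nM), only the amplitude and ``K_d`` float; this is
    the standard situation where the site concentration was measured
    independently.  Otherwise ``T`` floats as a third parameter.  Weighting
    as in :func:`fit_hyperbolic`.
    """
    E, I = _extract_titration(series)
    if len(np.unique(E)) < 4:
        raise ValueError("quadratic fit requires >= 4 distinct concentrations")
    if T_fixed is not None and T_fixed <= 0:
        raise ValueError("total site concentration T must be > 0")
    sigma = _titration_sigma(I, weighting)
    A0 = float(np.max(I)) / max(2.0 * (T_fixed or 1.0), 1e-9)
    K0 = float(np.median(E)) / 2.0
    if T_fixed is not None:
        popt, pcov = curve_fit(
            lambda E, A, K: quadratic_model(E, A, K, T_fixed),
            E, I, p0=[A0, K0], bounds=([0, 1e-12], [np.inf, np.inf]),
            sigma=sigma, maxfev=20000,
        )
        se = np.sqrt(np.diag(pcov))
        return QuadraticFit(
            K_d=float(popt[1]), A=float(popt[0]), T=float(T_fixed),
            K_d_se=float(se[1]), A_se=float(se[0]), T_se=0.0,
            T_fixed=True, n_points=len(E),
        )
    T0 = float(np.median(E)) / 2.0
    popt, pcov = curve_fit(
        quadratic_model, E, I, p0=[A0, K0, T0],
        bounds=([0, 1e-12, 1e-12], [np.inf, np.inf, np.inf]),
        sigma=sigma, maxfev=20000,
    )
    se = np.sqrt(np.diag(pcov))
    return QuadraticFit(
        K_d=float(popt[1]), A=float(popt[0]), T=float(popt[2]),
        K_d_se=float(se[1]), A_se=float(se[0]), T_se=float(se[2]),
        T_fixed=False, n_points=len(E),
    )


# ---------------------------------------------------------------------------
# steady-state bleaching


def bleach_model(t, k_off: float, k_b: float):
    """Relative unbleached fraction at real time ``t``.

    ``F(t) = (k_off + k_b·exp(-k_T·t)) / k_T`` with ``k_T = k_off + k_b``.
    ``k_b`` here is the bleaching rate on the same time axis as ``t``
    (apply duty-cycle scaling before calling if ``t`` is real time and the
    illumination is stroboscopic).  Both rates must be >= 0; when both are 0
    the fraction is identically 1.
    """
    if k_off < 0 or k_b < 0:
        raise ValueError("rates must be non-negative")
    t = np.asarray(t, dtype=float)
    k_T = k_off + k_b
    if k_T == 0:
        return np.ones_like(t)
    return (k_off + k_b * np.exp(-k_T * t)) / k_T


@dataclass
class BleachSeries:
    """One normalized ensemble-intensity decay at a fixed frame interval.

    ``F`` is the mean field intensity per frame normalized to the first
    frame; the time axis is ``frames * frame_interval`` (real time).
    """

    frame_interval: float  # s
    exposure: float  # s
    frames: np.ndarray  # frame indices, 0-based
    F: np.ndarray  # normalized intensity, F[0] == 1

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=int)
        self.F = np.asarray(self.F, dtype=float)
        if len(self.frames) != len(self.F):
            raise ValueError("frames and F must have equal length")
        if self.exposure > self.frame_interval:
            raise ValueError("exposure cannot exceed the frame interval")

    @property
    def times(self) -> np.ndarray:
        return self.frames * self.frame_interval

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"interval_s": self.frame_interval, "frame": self.frames, "F": self.F}
        )


@dataclass
class BleachFit:
    """Global steady-state bleaching fit with shared unbinding rate."""

    k_off: float  # 1/s, shared across series
    k_b: float  # 1/s per illuminated second
    k_off_se: float
    k_b_se: float
    per_interval: pd.DataFrame = field(repr=False)  # interval_s, k_b_eff, k_T_eff

    @property
    def k_T(self) -> float:
        return self.k_off + self.k_b

    @property
    def bleaching_time(self) -> float:
        """1/k_b in seconds of illumination."""
        return np.inf if self.k_b == 0 else 1.0 / self.k_b


def fit_bleach_global(series: list[BleachSeries]) -> BleachFit:
    """Jointly fit several bleach decays recorded at distinct frame intervals.

    Per series the model is ``bleach_model(frame·Δt, k_off, k_b·exposure/Δt)``:
    unbinding runs on real time while bleaching runs on illuminated time only.
    ``k_off`` and ``k_b`` are shared; with a single interval they are only
    jointly identifiable, which raises an error.
    """
    if len(series) < 2:
        raise ValueError("global bleach fit needs >= 2 series")
    intervals = [s.frame_interval for s in series]
    if len(set(np.round(intervals, 12))) < 2:
        raise ValueError(
            "k_off and k_b are not separately identifiable from a single "
            "frame interval; provide series at >= 2 distinct intervals"
        )

    def residuals(p):
        k_off, k_b = p
        res = []
        for s in series:
            k_b_eff = k_b * s.exposure / s.frame_interval
            res.append(bleach_model(s.times, k_off, k_b_eff) - s.F)
        return np.concatenate(res)

    # rates are bounded by the illumination timescale; the finite upper bound
    # also collapses the degenerate ridge (k_off -> inf) of bleach-free data
    # onto k_b = 0
    sol = least_squares(
        residuals, x0=[0.01, 0.03], bounds=([0.0, 0.0], [100.0, 100.0]),
        xtol=1e-14, ftol=1e-14,
    )
    n = sum(len(s.F) for s in series)
    dof = max(n - 2, 1)
    s2 = 2.0 * sol.cost / dof
    JTJ = sol.jac.T @ sol.jac
    try:
        cov = s2 * np.linalg.inv(JTJ)
        se = np.sqrt(np.diag(cov))
    except np.linalg.LinAlgError:
        se = np.full(2, np.nan)
    k_off, k_b = sol.x
    per = pd.DataFrame(
        {
            "interval_s": intervals,
            "exposure_s": [s.exposure for s in series],
            "k_b_eff": [k_b * s.exposure / s.frame_interval for s in series],
        }
    )
    per["k_T_eff"] = per["k_b_eff"] + k_off
    return BleachFit(
        k_off=float(k_off), k_b=float(k_b),
        k_off_se=float(se[0]), k_b_se=float(se[1]), per_interval=per,
    )


@dataclass
class CorrectedDwell:
    tau_corrected: float  # s; nan when non-physical
    physical: bool


def dwell_bias_correction(tau_observed: float, k_b_effective: float) -> CorrectedDwell:
    """Remove the bleaching contribution from an apparent mean dwell time.

    The observed unbinding rate is the sum of the true unbinding rate and the
    effective bleaching rate, so ``1/tau_corr = 1/tau_obs - k_b_eff``.  When
    bleaching accounts for the whole observed rate the correction is
    non-physical and flagged.
    """
    if tau_observed <= 0 or k_b_effective < 0:
        raise ValueError("tau_observed must be > 0 and k_b_effective >= 0")
    rate = 1.0 / tau_observed - k_b_effective
    if rate <= 0:
        return CorrectedDwell(tau_corrected=float("nan"), physical=False)
    return CorrectedDwell(tau_corrected=1.0 / rate, physical=True)
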