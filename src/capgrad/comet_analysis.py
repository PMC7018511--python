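"""End-aligned comet profiles and exponentially modified Gaussian fits.

Fluorescent end-binding proteins decorate the growing microtubule end as a
"comet": a profile that decays roughly exponentially with distance behind the
tip, convolved with the microscope point-spread function.  The model fitted
here is the exponentially modified Gaussian (EMG)

    I(x) = B + (A/2) · exp(σ²/(2 x_c²) − (x − μ)/x_c)
               · erfc(σ/(√2 x_c) − (x − μ)/(√2 σ))

with ``x`` increasing from the tip into the lattice, comet decay length
``x_c`` (nm), PSF width ``σ`` (nm), tip offset ``μ`` (nm), amplitude ``A``
and background ``B``.  Dividing ``x_c`` by the growth speed ``v_g`` gives the
mean lifetime ``t_c = x_c/v_g`` of the high-affinity binding sites, i.e. the
cap lifetime.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.special import erfcx

from .binding_kinetics import HyperbolicFit, fit_hyperbolic

__all__ = [
    "CometProfile",
    "CometFit",
    "emg_profile",
    "average_comet",
    "fit_emg",
    "comet_kd",
]


def emg_profile(x, A, x_c, sigma, mu=0.0, B=0.0):
    """Exponentially modified Gaussian comet model.

    Evaluated in the overflow-safe form
    ``B + (A/2)·erfcx(z)·exp(−(x−μ)²/(2σ²))`` with
    ``z = σ/(√2 x_c) − (x−μ)/(√2 σ)``, which is algebraically identical to
    the exp·erfc product but never overflows ahead of the tip.
    """
    x = np.asarray(x, dtype=float)
    u = x - mu
    if sigma <= 0:
        # PSF-free limit: one-sided exponential decay into the lattice
        return B + np.where(u >= 0, A * np.exp(-np.clip(u, 0, None) / x_c), 0.0)
    z = sigma / (np.sqrt(2.0) * x_c) - u / (np.sqrt(2.0) * sigma)
    gauss = np.exp(-(u * u) / (2.0 * sigma * sigma))
    with np.errstate(invalid="ignore", over="ignore"):
        out = 0.5 * A * erfcx(z) * gauss
    # far behind the tip z is very negative and erfcx(z)*gauss overflows to
    # inf*0; use erfcx(z) = 2 exp(z^2) - erfcx(-z), whose leading term turns
    # the product into the pure exponential tail
    deep = z < -6.0
    if np.any(deep):
        out = np.asarray(out, dtype=float)
        tail = A * np.exp(sigma**2 / (2.0 * x_c**2) - u[deep] / x_c)
        out[deep] = tail - 0.5 * A * erfcx(-z[deep]) * gauss[deep]
    return B + out


@dataclass
class CometProfile:
    """Time-averaged, end-aligned spatial intensity profile.

    ``x_nm`` is distance relative to the traced tip, positive into the
    lattice (behind the tip).  ``mean`` is averaged over frames and
    microtubules; ``sd``/``n`` allow the standard error per position.
    """

    x_nm: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    n: np.ndarray  # samples averaged per position
    n_frames: int
    n_microtubules: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"x_nm": self.x_nm, "mean": self.mean, "sd": self.sd, "n": self.n}
        )


@dataclass
class CometFit:
    x_c: float  # comet decay length, nm
    sigma_psf: float  # nm
    A: float
    B: float
    mu: float  # tip offset, nm
    x_c_se: float
    sigma_se: float
    at_bounds: bool

    def t_c(self, v_g: float) -> float:
        """Cap lifetime x_c/v_g (s) given the growth speed (nm/s)."""
        if v_g <= 0:
            raise ValueError("growth speed must be > 0")
        return self.x_c / v_g


def average_comet(
    kymographs,
    end_traces,
    x_range_nm: tuple[float, float] = (-2000.0, 6000.0),
    step_nm: float | None = None,
) -> CometProfile:
    """Align kymograph rows on the traced tip and average.

    Each kymograph row (one frame) is re-centered so the traced tip sits at
    ``x = 0`` and resampled by linear interpolation onto a common grid; rows
    are averaged over frames and then pooled over microtubules.  The spatial
    resolution of the result is set by the tracing, about 1-2 pixels.

    Parameters
    ----------
    kymographs : list of Kymograph (see :mod:`capgrad.end_tracking`).
    end_traces : list of EndTrace, frame-matched to the kymographs.
    """
    if len(kymographs) == 0:
        raise ValueError("need at least one kymograph")
    if len(kymographs) != len(end_traces):
        raise ValueError("kymographs and end traces must pair up")
    step = step_nm if step_nm is not None else kymographs[0].pixel_nm
    grid = np.arange(x_range_nm[0], x_range_nm[1] + 0.5 * step, step)
    total = np.zeros_like(grid)
    total2 = np.zeros_like(grid)
    counts = np.zeros_like(grid)
    n_frames = 0
    for kymo, trace in zip(kymographs, end_traces):
        if kymo.data.shape[0] != len(trace.frames):
            raise ValueError("trace length does not match kymograph frames")
        for row, tip in zip(kymo.data, trace.tip_s_nm):
            # x positive behind the tip
            x_rel = tip - kymo.s_nm
            order = np.argsort(x_rel)
            vals = np.interp(grid, x_rel[order], row[order], left=np.nan, right=np.nan)
            ok = np.isfinite(vals)
            total[ok] += vals[ok]
            total2[ok] += vals[ok] ** 2
            counts[ok] += 1
            n_frames += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = total / counts
        var = total2 / counts - mean**2
    sd = np.sqrt(np.clip(var, 0.0, None))
    keep = counts > 0
    return CometProfile(
        x_nm=grid[keep], mean=mean[keep], sd=sd[keep], n=counts[keep],
        n_frames=n_frames, n_microtubules=len(kymographs),
    )


def fit_emg(profile: CometProfile, fix_sigma: float | None = None) -> CometFit:
    """Least-squares EMG fit of an averaged comet profile.

    Initialization by moments: the peak position seeds ``μ``, the half-width
    of the rising edge seeds ``σ``, and the tail log-slope seeds ``x_c``.
    ``fix_sigma`` (nm) pins the PSF width, useful when it is known from bead
    calibration.  Raises on flat profiles and flags fits where ``x_c`` ran
    into its bounds.
    """
    x = np.asarray(profile.x_nm, dtype=float)
    y = np.asarray(profile.mean, dtype=float)
    span = x.max() - x.min()
    B0 = float(np.percentile(y, 5))
    amp = float(y.max() - B0)
    if amp <= 0 or (y.std() < 1e-12 * max(abs(y.mean()), 1.0)):
        raise ValueError("flat profile: no comet signal above background")
    i_pk = int(np.argmax(y))
    mu0 = float(x[i_pk])
    # tail log-slope for x_c seed
    tail = (x > mu0) & (y > B0 + 0.05 * amp)
    if tail.sum() >= 3:
        slope = np.polyfit(x[tail], np.log(y[tail] - B0 + 1e-12 * amp), 1)[0]
        xc0 = -1.0 / slope if slope < 0 else span / 4.0
    else:
        xc0 = span / 4.0
    xc0 = float(np.clip(xc0, 10.0, span))
    sig0 = fix_sigma if fix_sigma is not None else max(xc0 / 3.0, 50.0)

    lo_xc, hi_xc = 1.0, 10.0 * span
    if fix_sigma is not None:
        def model(x, A, x_c, mu, B):
            return emg_profile(x, A, x_c, fix_sigma, mu, B)
        starts = [[amp, xc0, mu0, B0]]
        bounds = (
            [0, lo_xc, x.min() - span / 4, -np.inf],
            [np.inf, hi_xc, x.max(), np.inf],
        )
    else:
        def model(x, A, x_c, sigma, mu, B):
            return emg_profile(x, A, x_c, sigma, mu, B)
        # several PSF-width starts: a pure-exponential profile (sigma -> 0)
        # and a strongly blurred one occupy different basins
        starts = [[amp, xc0, s0, mu0, B0] for s0 in (sig0, 20.0, span / 8.0)]
        bounds = (
            [0, lo_xc, 1.0, x.min() - span / 4, -np.inf],
            [np.inf, hi_xc, span, x.max(), np.inf],
        )
    best = None
    last_err = None
    for p0 in starts:
        try:
            popt_i, pcov_i = curve_fit(model, x, y, p0=p0, bounds=bounds, maxfev=40000)
        except RuntimeError as err:
            last_err = err
            continue
        ssr = float(np.sum((y - model(x, *popt_i)) ** 2))
        if best is None or ssr < best[0]:
            best = (ssr, popt_i, pcov_i)
    if best is None:
        raise RuntimeError(f"EMG fit did not converge: {last_err}")
    _, popt, pcov = best
    se = np.sqrt(np.diag(pcov))
    if fix_sigma is not None:
        A, x_c, mu, B = popt
        sigma, sigma_se = float(fix_sigma), 0.0
        x_c_se = float(se[1])
    else:
        A, x_c, sigma, mu, B = popt
        sigma_se = float(se[2])
        x_c_se = float(se[1])
    at_bounds = bool(x_c <= lo_xc * 1.01 or x_c >= hi_xc * 0.99)
    return CometFit(
        x_c=float(x_c), sigma_psf=float(sigma), A=float(A), B=float(B),
        mu=float(mu), x_c_se=x_c_se, sigma_se=sigma_se, at_bounds=at_bounds,
    )


def comet_kd(series) -> HyperbolicFit:
    """K_d from maximal comet intensities vs ligand concentration.

    Thin delegate to the hyperbolic isotherm fit: at growing ends the ligand
    is in large excess over the transient binding sites, so depletion is
    negligible and the Langmuir form applies.
    """
    return fit_hyperbolic(series)
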