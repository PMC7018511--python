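# Methods

## The model

A growing microtubule is represented as a 1-D lattice along its axis, with
the minus end at the origin and the plus-end tip advancing at constant speed
`v_g` (nm/s). Fluorescent end-binding (EB) molecules associate with the
lattice as a Poisson process that is **uniform per unit length** over the
whole filament behind the tip; the spatial structure of the comet emerges
entirely from unbinding. An event that binds at distance `d` behind the tip
draws an exponential dwell time with mean

    tau(d) = tau_tip * exp(-d / lambda_cap)

where `tau_tip` (s) is the mean dwell of a freshly formed, GTP-like site at
the tip and `lambda_cap` (nm) is the decay length of the affinity gradient
produced by GTP hydrolysis. The distance is **frozen at the moment of
binding**: the analysis assigns each event a single distance measured in its
first frame, so the generator does not let the maturing lattice shorten an
ongoing dwell. A continuous-maturation mode is deliberately out of scope.

While bound, molecules diffuse along the lattice with 1-D coefficient
`D_lattice` (µm²/s). Observation is by point sampling: a molecule is
localized in frame `f` if it is bound at time `f·frame_interval`, with
Gaussian localization noise `sigma_loc` added independently per frame and
axis. Bleaching consumes an exponential illumination budget at rate
`k_bleach` per *illuminated* second, i.e. per frame the survival probability
is `exp(-k_bleach·exposure)`. Blinking is a two-state per-frame Markov chain
and is off by default — the analysis absorbs short dark periods through its
30-frame gap-closing allowance.

Because hydrolysis converts position behind the tip into time since
incorporation, the fitted decay length yields a maturation (hydrolysis) rate
`v_g / lambda`, and a comet of length `x_c` corresponds to a cap lifetime
`t_c = x_c / v_g`.

## Default parameters and why

| parameter | default | rationale |
|---|---|---|
| `v_g` | 59.8 nm/s (wildtype-like), 58.5 (slow-hydrolysis-like) | measured growth speeds of the two imaging conditions being emulated |
| `lambda_cap` | 450 nm / 850 nm | fitted decay lengths of the two conditions |
| `tau_tip` | calibrated at runtime (≈ 4.3 s) | see calibration below |
| `frame_interval`, `exposure` | 60 ms, 55 ms | single-molecule acquisition timing |
| `sigma_loc` | 30 nm | upper end of the stated sub-pixel localization precision |
| `pixel_nm` | 120 nm | camera pixel size |
| `k_bleach` | 1/45 s⁻¹ per illuminated s | measured bleaching time of the fluorophore |
| `on_rate_density` | 0.004 µm⁻¹s⁻¹ | reproduces the picomolar single-molecule regime of ≈ 4–5 detected events per 10-min movie (≈ 2425 events over ≈ 550 microtubules); sparse enough that two molecules essentially never co-occur within a linking radius |
| `n_frames` | 10 000 | 10 min at 60 ms |
| `D_lattice` | 10⁻³ µm²/s | measured lattice diffusion of bound EB3 |

`wildtype_config()`, `e254d_config()` and `lattice_config()` bundle these
conditions; `lattice_config` is the static, uniform-affinity,
hydrolysis-blocked regime (no growth, `lambda_cap = inf`, long dwells) used
for diffusion and bleaching measurements.

### Calibration of `tau_tip`

The tip dwell is not directly observable; what is reported is the ensemble
mean of *measured* dwell times over all detected events (880 ms for the
wildtype-like condition). Under the generator's observation model this mean
has a closed form: an event with true mean dwell `m` is detected with
probability `(m/Δt)(1 − e^(−Δt/m))` (binding phase uniform within the frame
cycle), and its measured inclusive frame span is geometric with per-frame
ratio `ρ = e^(−Δt/m)·e^(−k_bleach·exposure)`, giving expected measured dwell
`Δt/(1−ρ)`. Integrating both over the uniform-association distance
distribution yields the expected ensemble mean as a function of `tau_tip`;
`calibrate_tau_tip` inverts it by root finding. The slow-hydrolysis
configuration reuses the wildtype-calibrated `tau_tip`: the mutation slows
cap maturation (larger `lambda_cap`), not the affinity of the fresh
GTP site at the tip, for which no separate ensemble mean is available.

## Analysis pipeline choices

- **Masking** keeps localizations within 240 nm (2 px) lateral tolerance of
  the trajectory and arc length ≤ traced tip, boundary inclusive. Distances
  use the *traced* tip, not the generator truth.
- **Linking** is greedy and frame-ordered: each localization joins the
  nearest open track within 120 nm whose last frame is within 30 frames
  (both inclusive); ties break by distance then track age; one localization
  per track per frame. The algorithm is intentionally simple enough to be
  verified against an exhaustive brute-force implementation in the tests.
- **Track merging.** A hard 120 nm radius with 30 nm noise means a
  between-frame displacement exceeds the radius with probability ≈ 2% per
  step, splitting one molecule into two interleaved tracks that both span
  most of the event and would double-count long dwells. In the low-density
  regime assumed throughout (no two simultaneous binders within a pixel),
  tracks that overlap in time with median positions within the linking
  radius are the same molecule; `merge_colocated_tracks` merges them
  transitively. This is a separate, documented step after linking.
- **Dwell time** is the inclusive frame span × frame interval; single-frame
  events count one frame and are kept (filterable via `t_min`). Events
  touching the first or last traced frame are flagged censored and excluded
  from fits by default. Censored events are *length-biased* toward
  long-dwell states; for a single exponential the truncation cancels the
  bias exactly (memorylessness) but the spatial mixture tilts the
  included-events mean upward — the tests document this direction.
- **Survival fits** use `S(t) = A·exp(−t/τ)` with a **free amplitude**.
  With dwells quantized to the frame grid, S at the first grid point is 1
  by construction and a fixed-amplitude fit is biased by about half a
  frame; with the amplitude free, τ equals the geometric decay per frame
  and stays unbiased even when τ is below the frame interval, which the
  far distance bins require. A bootstrap gives the standard error, and a
  Monte-Carlo residual test (refits of synthetic mono-exponential samples
  of the same size and quantization) flags non-mono-exponential
  distributions at p < 0.01.
- **Spatial binning** uses contiguous 0.59 µm bins from distance zero (the
  printed experimental bins lie on this grid), requiring ≥ 30 uncensored
  events per bin; bins whose dwell distribution is degenerate (all events
  one frame) drop out. The gradient fit `tau(d) = tau0·exp(−g·d)` is
  parameterized by the decay **rate** `g = 1/λ ≥ 0`, weighted by per-bin
  standard errors, so the flat-profile limit is an interior point; "no
  gradient" is reported when `g` is within two standard errors of zero.
- **Isotherm fits** default to weights σ ∝ I (floored at 5% of the maximum)
  because fluorescence intensities carry signal-proportional noise;
  unweighted least squares is available. The printed form of the depletion
  isotherm absorbs the conventional factor ½ into the free amplitude, which
  leaves K_d unaffected. The discriminant is clipped at zero against
  round-off.
- **Bleaching global fit** shares `k_off` and `k_b` across series, with the
  per-series effective bleaching rate `k_b·exposure/Δt` on the real-time
  axis. This duty-cycle convention is the only one under which varying the
  frame interval at fixed exposure separates the two rates, and the
  generator mirrors it. Rates are bounded above at 100 s⁻¹, which also
  collapses the degenerate ridge (`k_off → ∞`) of bleach-free data onto
  `k_b = 0`. Series are normalized to their first frame before fitting.
- **MSD** uses 1-D displacements along the filament axis,
  `MSD(t) = 2Dt + offset`, weighted by per-lag standard errors over lags
  2–10; the offset absorbs static localization noise (2σ²) and lag 1, the
  point most distorted by noise correlation, is excluded. A reduced-χ²
  threshold of 5 flags non-diffusive (drifting) motion. Because the
  dimensionality convention for the lattice-sampling range is ambiguous,
  `MSDResult.sampling_range_nm` reports both `sqrt(2Dτ)` and `sqrt(4Dτ)`.
- **EMG comet fit** initializes by moments (peak → μ, rise width → σ, tail
  log-slope → x_c) and restarts from several PSF widths, keeping the lowest
  residual, because the pure-exponential (σ → 0) and strongly blurred
  regimes occupy different basins. The profile is evaluated through
  `erfcx`, with the identity `exp(z²−u²/2σ²) = exp(σ²/2x_c² − u/x_c)`
  removing all overflow, and an asymptotic branch for the deep tail.
- The hydrolysis rate can be estimated two ways — from the comet lifetime
  (`1/t_c`) or from the dwell decay length (`v_g/λ`); both are provided and
  neither is privileged, as they probe slightly different observables.

## What the generator does and does not emulate

It reproduces the statistical structure the analysis relies on: Poisson
association, exponential position-dependent dwells, tip advance, frame
quantization, detection loss of sub-frame events, localization noise,
lattice diffusion, duty-cycled bleaching, optional blinking, and movie
rendering with Gaussian PSFs and shot noise. It does **not** simulate
catastrophes or dynamic instability, nucleation, microtubule wiggling or
drift, a structured on-rate within the cap (an explicit assumption: the
observed density gradient then derives purely from the unbinding gradient),
the short EB-free zone at the very tip, or 3-D/astigmatic optics. Passing
recovery tests therefore demonstrates the correctness and calibration of
the analysis chain under these idealized-but-realistic conditions, not
robustness to every imaging pathology of real data.

## Problem sizes

Recovery runs use the study-scale event counts (≈ 2425 wildtype-like and
≈ 1834 slow-hydrolysis-like events, pooled over several hundred simulated
microtubules; ≥ 200 tracks for diffusion; 3 × 3000-frame bleaching series;
8-concentration titrations with 5 replicates). At these sizes the decay
length recovers to within a few percent, the ensemble mean dwell to ~5%,
and the isotherm, bleaching and diffusion constants to within their
stochastic scatter; each full dataset simulates and analyzes in seconds.

## Known limitations

- The greedy linker is order-dependent by construction; its behavior is
  pinned by the brute-force equivalence tests rather than by a global
  assignment optimum.
- Track merging assumes the low-density regime; at high labeling densities
  it would fuse genuinely distinct molecules.
- Per-bin dwell fits treat events within a bin as one exponential although
  the mean varies e-fold over `bin_width/λ`; the resulting bin-center bias
  largely cancels in the ratio between adjacent bins and is well below the
  recovery tolerances at the default bin width.
- The automated threshold end-tracer is a stand-in for manual kymograph
  tracing; its 5-frame median smoothing is a declared choice, and noisy
  kymographs should use `method="file"` with an externally drawn trace.
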