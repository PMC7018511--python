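# capgrad

Spatially resolved single-molecule analysis of the microtubule **GTP cap**.

Growing microtubules are protected by a cap of GTP-bound tubulin that is
consumed by GTP hydrolysis. End-binding proteins (EB1/EB3) bind the cap
region with high affinity and mark it as a fluorescent "comet" in TIRF
microscopy. `capgrad` quantifies the cap from single-molecule and comet
imaging data:

- **Dwell-time gradient** — single EB molecules are localized, masked onto
  the microtubule up to the traced growing end, linked into binding events
  (≤ 120 nm, ≤ 30 frames), and summarized as survival functions
  S(t) = 1 − CDF. Binning events by distance *d* behind the tip and fitting
  each bin mono-exponentially yields local mean dwell times that decay as
  τ(d) = τ_tip·exp(−d/λ). The decay length λ measures the conformational
  gradient left by hydrolysis, and v_g/λ estimates the hydrolysis rate.
- **Comet profiles** — end-aligned, time-averaged intensity profiles are
  fitted with an exponentially modified Gaussian
  I(x) = B + (A/2)·exp(σ²/2x_c² − (x−μ)/x_c)·erfc(σ/√2x_c − (x−μ)/√2σ),
  giving the comet length x_c and cap lifetime t_c = x_c/v_g.
- **Binding isotherms** — hyperbolic I = A·E/(K_d + E) for ligand-excess
  titrations, and the quadratic ligand-depletion isotherm
  I = A·[(T+E+K_d) − √((T+E+K_d)² − 4TE)] when the site concentration T is
  comparable to K_d.
- **Steady-state photobleaching** — decays recorded at several frame
  intervals with fixed exposure are fitted globally with
  F(t) = (k_off + k_b·e^(−k_T t))/k_T, k_T = k_off + k_b (bleaching scaled
  by the duty cycle), separating unbinding from bleaching.
- **Lattice diffusion** — a time-and-ensemble-averaged MSD with a
  localization-noise offset, MSD = 2Dt + 2σ², gives the 1-D diffusion
  coefficient of bound molecules.

A first-class synthetic-data generator reproduces the statistical structure
of this kind of TIRF data (advancing tip, exponential dwells with a spatial
gradient frozen at binding, lattice diffusion, bleaching, blinking, ~30 nm
localization noise, 120 nm pixels), so every analysis stage is verifiable by
parameter recovery against known ground truth. It can also render movies
(Gaussian PSF + Poisson noise) to exercise the localization stage.

## Worked example

Recover the wildtype-like cap gradient from ~2400 simulated binding events
(growth speed 59.8 nm/s, decay length 450 nm, 60 ms frames):

```python
import pandas as pd
from capgrad import synthetic_data as sd
from capgrad.end_tracking import mask_localizations
from capgrad.dwell_analysis import (link_events, merge_colocated_tracks,
                                    dwell_records, survival,
                                    local_dwell_profile, hydrolysis_rate)
from capgrad.pipeline_io import child_seed

records = []
n_mt = sd.microtubules_for_events(sd.wildtype_config(), 2425)
for i in range(n_mt):
    cfg = sd.wildtype_config(seed=child_seed(1, i))
    locs, truth, trace = sd.simulate_cap_events(cfg)
    kept = mask_localizations(locs, trace).kept
    if not len(kept):
        continue
    linked = merge_colocated_tracks(link_events(kept.reset_index(drop=True)))
    records.append(dwell_records(linked, trace, cfg.frame_interval))
records = pd.concat(records, ignore_index=True)

curve = survival(records)
profile = local_dwell_profile(records, bin_width_nm=590.0)
print(f"events analyzed      : {curve.n_events}")
print(f"mean dwell           : {1000 * curve.mean_dwell:.0f} ms")
print(f"dwell decay length   : {profile.lambda_nm:.0f} +/- {profile.lambda_se:.0f} nm")
print(f"tip dwell time       : {profile.tau_tip:.2f} s")
print(f"hydrolysis rate      : {hydrolysis_rate(profile.lambda_nm, cfg.v_g):.2f} 1/s")
```

prints

```
events analyzed      : 2510
mean dwell           : 864 ms
dwell decay length   : 455 +/- 9 nm
tip dwell time       : 4.37 s
hydrolysis rate      : 0.13 1/s
```

The pipeline recovers the generator's 450 nm decay length within its
standard error from realistically noisy, frame-quantized, bleach-shortened
observations; the mean dwell of the detected events lands close to the
880 ms the generator was calibrated to produce, and the implied hydrolysis
rate is v_g/λ.

The same stages are scriptable from the shell:

```sh
capgrad simulate --seed 1 --out run/ --render
capgrad localize run/movie.tif --out run/locs.csv
capgrad link run/locs.csv --trace run/end_trace.csv --out run/linked.csv
capgrad dwell run/linked.csv --trace run/end_trace.csv --out run/records.csv
capgrad run-all --config run.json --out run/
```

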