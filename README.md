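# flaglen

Quantitative analysis of flagellar length regulation by balanced
IFT-mediated assembly and kinesin-13-mediated disassembly, built around
the *Giardia lamblia* trophozoite — a cell that maintains eight flagella
in four pairs, each pair at its own equilibrium length.

The package is aimed at quantitative cell biologists and biophysicists
working on organelle size control. It provides, as a single tested stack:

- **Synthetic live-cell data** with the measured statistical structure —
  per-pair flagellar length distributions, Poisson IFT train injection,
  kymographs of constant-speed trains, strip-bleach FRAP recoveries, cosh
  kinesin-13 tip gradients, linear total-IFT-intensity-vs-length data,
  and Taxol/knockdown length-shift scenarios — so every analysis stage is
  testable end to end without any raw-image download.
- **FRAP fitting**: strip-bleach effective diffusion
  `I(t) = I0·(1 − ω/√(ω² + 4πDt))`, the early-linear pore law with a
  retrograde-flux term, and a mobile-fraction-bounded tip variant.
- **Kymograph analysis**: Fourier quadrant filtering into anterograde and
  retrograde traffic, peak linking into train tracks (speed, intensity,
  injection time), and exponential waiting-time (injection-rate)
  estimation by maximum likelihood.
- **The kinesin-13 transport model**: steady-state tip gradient
  `c(x) = c0·cosh(x/λ)` with decay length `λ = √(D/k_on) = R`, the
  finite-reservoir tip concentration
  `c(L) = c_init·e^{L/λ}/(1 + v·e^{L/λ})`, and cosh tip-profile fitting.
- **Balance-point length control**:
  `dL/dt = I·(N − L) − k⁻·c(L)` with steady states, stability, and
  trajectory integration.

Fitted quantities follow a statsmodels-style pattern: a model object
built from data whose `fit()` returns a `FitResult` carrying estimates,
95% confidence intervals, diagnostics and a `summary()` table.

## Worked example

Simulate one 26-s anterograde kymograph for the anterior flagellum under
the packaged `wbc6` conditions, recover train speeds and the injection
rate, fit a pore FRAP recovery, and solve the balance-point length:

```python
import numpy as np
from flaglen import get_scenario
from flaglen.datatypes import (FlagellarGeometry, FrapModelParams,
                               LengthControlParams, TransportParams)
from flaglen.synthetic import (simulate_injection_process, render_kymograph,
                               simulate_frap_trace)
from flaglen.kymograph import (directional_filter, extract_tracks,
                               injection_intervals, fit_injection_rate)
from flaglen.frap import fit_strip_frap
from flaglen.length_control import LengthControlModel

wbc6 = get_scenario("wbc6")
ps = wbc6.pair_stats("anterior")
geom = FlagellarGeometry(pair="anterior", membrane_length=ps.membrane_mean,
                         cytoplasmic_length=ps.cytoplasmic_mean)

events = simulate_injection_process(ps.injection_mean_interval, 330 / 13,
                                    seed=11, speed=wbc6.train_speed_anterograde)
kymo = render_kymograph(events, geom, noise_sd=10.0, seed=12)
antero, retro = directional_filter(kymo)
tracks = extract_tracks(antero, min_intensity=20.0)
print(f"{len(tracks)} anterograde tracks, "
      f"mean speed {np.mean([t.speed for t in tracks]):.2f} um/s")
print(fit_injection_rate(injection_intervals(tracks)).summary())

params = FrapModelParams(**wbc6.frap["pore"])
trace = simulate_frap_trace("pore", params, 300, 1.0, noise_sd=0.05, seed=3)
print(fit_strip_frap(trace, bootstrap=200, seed=4).summary())

lc = LengthControlParams(inj_flux=0.01, pool=25.0, k_minus=0.17,
                         transport=TransportParams(lambda_=0.25, v=1e-3,
                                                   c_init=1e-3))
L_star, stable = LengthControlModel(lc).steady_state_length()
print(f"L* = {L_star:.3f} um (stable={stable})")
```

Output:

```
24 anterograde tracks, mean speed 3.10 um/s
injection-rate results
==============================================
parameter         estimate    [0.025    0.975]
----------------------------------------------
mean_interval        1.017     0.702     1.604
rate                0.9836    0.6235     1.425
----------------------------------------------
nobs = 23   RSS = 21.49   converged = True
mean_interval_histogram_fit = 1.0564156077514468
bin_width = 0.2
low_confidence = False
strip-FRAP results
==============================================
parameter         estimate    [0.025    0.975]
----------------------------------------------
I0                   1.011    0.9947     1.027
D                  0.04657    0.0417   0.05142
----------------------------------------------
nobs = 301   RSS = 0.7554   converged = True
L* = 8.000 um (stable=True)
```

The 24 tracks at 3.10 µm/s recover the generating anterograde speed;
the fitted mean injection interval (1.02 s from a single 26-s
acquisition, wide CI at n = 23) recovers the anterior flagellum's 1.0-s
Poisson mean; the FRAP fit recovers the pore's effective diffusion
constant (0.047 vs the generating 0.049 µm²/s at SNR 20); and the
balance-point model places the high-kinesin-13-load flagellum at a stable
8 µm equilibrium.

A `flaglen` console script exposes the same stages
(`flaglen simulate|frap|kymo|model|lengthctl|profile ...`); see
`flaglen --help`.

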