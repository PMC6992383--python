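# Methods

`flaglen` models how a cell maintains several flagella of different
equilibrium lengths, using *Giardia lamblia* trophozoites — eight flagella
in four pairs, each pair with its own stable length — as the reference
system. The package has two halves: a synthetic-data generator that
reproduces the statistical structure of the live-cell measurements, and
the analysis/modelling stack that estimates the biophysical parameters
back from such data. Every analysis stage is validated by parameter
recovery on its paired generator.

## Geometry of the system

Each *Giardia* axoneme has a cytoplasmic region (basal body → flagellar
pore) and a membrane-bound region (pore → tip); their sum is the total
axoneme length. The flagellar pore acts as the diffusion barrier where IFT
(intraflagellar transport) trains are assembled and injected. Packaged
scenario `wbc6` carries the measured per-pair summary statistics:
membrane-bound lengths 12.8 / 8.1 / 8.7 / 13.7 µm (anterior / caudal /
posteriolateral / ventral) and total axoneme lengths 19.1 / 20.5 / 16.2 /
16.8 µm. Published dispersions are 95% CIs of the mean over n = 35
flagella; per-cell sds are back-computed as `ci_halfwidth·√35/1.96` and
stored explicitly. Lengths are drawn from normals truncated at zero — the
simplest model consistent with a reported mean ± CI. Perturbation
scenarios shift the membrane-bound means only: `taxol-1h` multiplies by
1.19 / 1.27 / 1.61 (anterior / posteriolateral / caudal), `taxol-5h` adds
4.1 / 4.3 / 5.4 / 4.5 µm, and `k13kd` (kinesin-13 CRISPRi knockdown) adds
1.1 / 0.9 / 3.1 / 1.6 µm.

## FRAP: strip-bleach effective diffusion

Recovery of a bleached strip of width ω refilled by effective 1-D
diffusion follows

    I(t) = I0 · (1 − ω/√(ω² + 4πD t)),

with the short-time limit I(t) ≈ I0·2πD t/ω². `FrapRecoveryModel` fits
(I0, D) by trust-region nonlinear least squares (initial guesses: I0 from
the trace tail, D = ω²/(4π·t_half) from the observed half-recovery time);
95% CIs come from a parametric bootstrap (200 refits on model + residual-sd
noise). D ≥ 0 is enforced by bounds. An identically-zero trace is
degenerate and returned with `converged=False` rather than raising.

For the flagellar-pore region the retrograde IFT flux adds a linear term
to the early recovery:

    I_FP(t) = I0 · (2πD/ω_CA² + λ0C0·v/ω_FP) · t,

where λ0C0 is the relative membrane-vs-cytoplasmic integrated intensity, v
the retrograde train speed and ω_CA, ω_FP the two strip widths. The
predicted pore/axoneme initial-slope ratio is
`(2πD/ω_CA² + λ0C0·v/ω_FP)/(2πD/ω_CA²)`; the diffusive term retains ω_CA
throughout. Strip widths are not published; the scenarios fix
ω_CA = ω_FP = 2 µm and λ0C0 = 0.0354, which together with v = 3.2 µm/s
gives the canonical predicted ratio of 3. Pore recoveries themselves are
generated and fitted with the strip law at the pore's effective
D = 0.049 µm²/s (the cytoplasmic region uses 0.018 µm²/s), matching how
the effective diffusion constants are measured; the early-linear pore law
is available separately (`simulate_frap_trace(..., early_linear=True)`)
for initial-slope studies. `fit_initial_linear` is plain OLS over a user
window; choose the window inside t < 0.01·ω²/(4πD) so the strip law is
within 1% of linear.

Kinesin-13 tip recoveries plateau far below prebleach (most tip
kinesin-13 is immobile on the FRAP timescale). Because the plateau and
the prebleach level cannot be separated within one trace, the bounded
model I(t) = f_mobile·I0·(1 − ω/√(ω² + 4πDt)) fixes I0 at the trace's
recorded prebleach intensity and reports f_mobile = plateau/prebleach.
The tip scenario uses f_mobile = 0.30, ω = 1 µm and an effective
D = 0.01 µm²/s; the tip D is a free generator parameter (no published
value), chosen to give minute-scale recovery as observed.

Trace correction follows the standard normalisation: subtract background,
divide by the background-subtracted reference rescaled to its initial
value (photobleach correction), then map the prebleach level to 1 and the
post-bleach floor to 0. Ensemble averaging rescales each trace by its own
bleach depth before averaging.

## Kymographs: rendering, directional filtering, tracking

Synthetic kymographs are rows = time (row 0 = t = 0), columns = position
from the flagellar base (column 0 = pore), 0.1 µm pixels, 330 frames at
13 fps (≈26 s). Each train is a 1-pixel-σ Gaussian along position —
a diffraction-limited spot without explicit optics — integrated over the
frame exposure in 8 sub-steps (a 3 µm/s train moves >2 pixels per 77 ms
exposure, so the smear is physical and, incidentally, keeps the train's
spectral energy in its own direction quadrants). Intensities attenuate by
`exp(−bleach_rate·t)`; noise is additive i.i.d. Gaussian, the conventional
camera surrogate at these intensities. Noise conventions throughout: SNR =
(signal amplitude)/(noise sd), where the amplitude is the nominal train
intensity for kymographs and the recovered plateau for FRAP traces.

Directional separation works in the 2-D Fourier plane: a line x = vt with
v > 0 (anterograde, base → tip) has energy where temporal and spatial
frequencies have opposite signs. The filter zeroes the complementary
quadrants, the zero-frequency (static) bands, and the Nyquist rows/columns
— the latter are direction-ambiguous, and excluding them keeps the masks
Hermitian-symmetric so both outputs are exactly real and energy
bookkeeping is exact (anterograde + retrograde + discarded = input).

Track extraction detects per-frame peaks above a user threshold
(sub-pixel parabolic refinement), links them frame-to-frame by nearest
predicted position (velocity-extrapolated; ties to the brighter peak)
within a jump limit of `speed_max`·frame_interval (default speed_max
8 µm/s), and allows 2-frame gaps. Tracks need ≥8 anchors and a line-fit
R² ≥ 0.8; speed is the absolute least-squares slope of position vs time,
and the injection time is the extrapolated intercept at the entry boundary
(base for anterograde, tip for retrograde) — robust to missed early
frames. With 0.1 µm pixels at 13 fps the quantization bound is
1.3 µm/s per frame step, but regression over ~50 anchors recovers speeds
to ~1%.

Injection statistics: anterograde start times are differenced;
waiting times are fitted as a single exponential. The authoritative
estimator is the MLE (τ̂ = sample mean) with the exact χ²(2n) confidence
interval; a least-squares fit of (1/τ)e^(−t/τ) to the normalised interval
histogram (default bin 0.2 s) is also reported for comparability with
histogram-based practice. Fewer than 20 intervals flags the result
low-confidence. Scenario injection means: 1.0 s anterior, 1.3 s caudal,
1.2 s posteriolateral; the ventral pair mirrors the posteriolateral value
because ventral IFT is unmeasurable in vivo (the flagella keep beating)
— it is generator plumbing, not a measurement.

## Kinesin-13 transport model

Free kinesin-13 diffuses in the flagellum and is captured by anterograde
trains at first-order rate k_on, giving dc/dt = D c'' − k_on c with steady
state c(x) = c0·cosh(x/λ), λ = √(D/k_on). Taking the capture time as the
time to diffuse the flagellar radius R gives k_on = D/R² and λ = R
(≈0.25 µm) — a decay length independent of flagellar length, which is the
model's signature prediction. With a finite reservoir the tip
concentration is c(L) = c_init·e^(L/λ)/(1 + v·e^(L/λ)), computed in the
algebraically identical overflow-free form c_init/(v + e^(−L/λ)); v is
the λ-stretch-to-reservoir volume ratio (≈10⁻³, giving a 10³ tip
enhancement and half-saturation at λ·ln(1/v) ≈ 1.7 µm). Boundary
conditions are implicit in the closed form; correctness is verified by a
finite-difference residual oracle rather than by re-deriving flux
conditions. Concentrations are arbitrary fluorescence-proportional units;
only ratios are meaningful.

Measured tip line scans are fitted with I(x) = I0·cosh((w − x)/λ) over a
window w = 1.2 µm from the tip (overridable); λ > 0 is enforced and a
flat profile is flagged non-identifiable (λ → ∞) instead of fitted.

## Balance-point length control

Length dynamics follow dL/dt = I·(N − L) − k⁻·c(L): assembly from a
depleting precursor pool (N, expressed in µm of assemblable length; I in
1/s) minus kinesin-13-mediated tip disassembly. k⁻ absorbs the
depolymerisation step size so k⁻·c has µm/s units (conversion constant 1;
no molar calibration exists). Assembly falls linearly in L, disassembly
rises (saturating) in L, so the balance point L* = N − k⁻·c(L*)/I is
unique and always stable (linearised rate −I − k⁻·c'(L*) < 0); longer
flagella carry less kinesin-13 at their tips. Steady states are found by
bracketing root search (Brent, xtol 1e-8 µm), stability by central
difference; trajectories by adaptive RK45 (atol 1e-8), clamped
non-negative. Dynamics are deterministic mean-field; no stochastic
single-molecule simulation is attempted.

The illustrative two-length parameter set (scenario constants
`LENGTH_CONTROL_FIG7`) uses the order-of-magnitude transport estimates
λ = R = 0.25 µm, v = 10⁻³ with I = 0.01 s⁻¹, N = 25 µm, k⁻ = 0.17 and two
kinesin-13 loads c_init = 1.0e-3 / 7.06e-4, which place the two stable
lengths at ≈8 and ≈13 µm (caudal- and anterior-like). It is illustrative,
not fitted — no length time courses exist to fit. Whether pairs share one
pool or own equivalent pools is biologically open; the model takes
per-flagellum parameters, so either reading can be configured.

## Line-scan statistics

Ensemble mean profiles resample each scan to 200 points on a normalised
[0, 1] axis (flagella differ in length) and report the pointwise mean with
Student-t 95% bands, no multiplicity correction — matching shaded-band
presentation. A single profile yields a mean only. Total integrated
intensity is the trapezoidal AUC. Intensity-vs-length regression is OLS
with R²; the generator draws AUC = ρ·L + ε with the noise sd computed
analytically from the pooled length mixture variance so the *population*
R² equals the scenario target (0.89) — calibrated by closed form, not by
tuning to a fit outcome. Full-axoneme generator scans exist only for the
anterior and posteriolateral pairs (cytoplasmic scans of the other pairs
are unmeasurable in vivo), with a Gaussian accumulation at the pore whose
parameters are free generator choices.

## What the generator does and does not emulate

Emulated: per-pair truncated-normal length distributions; exponential
inter-injection waiting times; constant train speeds with
truncated-normal intensities; exposure smear, acquisition photobleach and
Gaussian camera noise in kymographs; strip-law/bounded FRAP recoveries;
cosh tip gradients; linear AUC-vs-length structure; Taxol/knockdown
length shifts. Not emulated: optics beyond the 1-pixel PSF, 3-D cell
geometry, stage drift (synthetic data are drift-free), beating-flagella
motion artifacts, molecule-count calibration of fluorescence, and
correlated (non-Gaussian) camera noise. Passing recovery tests therefore
demonstrates the estimators are correct and well-calibrated under the
stated noise model at realistic SNR; they do not certify performance
under drift, non-Gaussian noise, or segmentation error in real
micrographs.

## Problem sizes and numerical choices

Default validation sizes: 10⁴ draws for distributional recoveries, 19–25
traces per FRAP ensemble, 10–20 kymographs per tracking ensemble, 100
seeded replicates for coverage/unbiasedness properties, bootstrap 100–200
refits for CIs. All randomness flows through `numpy.random.default_rng`
with explicit integer seeds (sub-seeds spawned via `SeedSequence`);
identical (config, seed) gives byte-identical output. Fits use
trust-region least squares with tolerances 1e-12 so noise-free round
trips recover generating parameters to ≤1e-6. Degenerate inputs (zero
trace, flat profile, single track, <20 intervals) return flagged results
instead of raising wherever the flagged result is scientifically
interpretable.
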