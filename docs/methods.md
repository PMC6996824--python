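# Methods

## Physical model of the synthetic traces

The generator treats the eye (or phantom) as a thin spherical membrane of
radius `R` and areal density `μ = ρh` under internal pressure `P`. Laplace's
law for a spherical shell gives the in-plane tension `T = P R / 2`, and the
transverse wave on an ideal tensioned membrane travels at `c = √(T/μ)`, so

```
c(P) = √(P R / 2 μ).
```

The spark fires at `t = 0`; the shock front crosses the air gap `d_air` at a
fixed speed `c_shock` and the membrane wave then covers the surface arc `s`
to the pickup point, so the arrival time is

```
t_arr(P) = d_air / c_shock + s / √(P R / 2 μ).
```

The surface term scales as `P^(-1/2)`, which is the entire pressure
dependence: fitting `IOP = a·TOF^b` to air-delay-corrected arrivals must
recover `b = −2`, and this is the pipeline's main self-consistency check.

This is deliberately the *simplest* model consistent with the observed
behaviour of such systems — a pressure-controlled wave speed of the right
magnitude (~5 m/s on an eye in the clinical pressure range) and a
monotonically falling TOF. It has no flexural stiffness, no dispersion, no
viscoelasticity and no fluid loading; the shock is reduced to a fixed
air-path speed. Consequences: synthetic packets keep their shape across
pressures (real corneal packets broaden and change shape), the
carrier-to-envelope relation is fixed, and inter-eye geometric variability
(the dominant real-world bias) appears only if the caller varies the
geometry. Passing tests therefore demonstrate correctness of the *analysis
chain*, not fidelity of corneal mechanics.

A known internal tension of the measured system is that a quoted ~8 mm
surface wavelength is inconsistent with speed/frequency ≈ 5 m/s / 2.4 kHz ≈
2 mm; the simulator follows the speed and the centre frequency and ignores
the wavelength figure.

### Packet shape

The detected wave packet is a Gaussian-windowed cosine,

```
x(t) = A · exp(−(t − t_arr)² / 2σ²) · cos(2π f₀ (t − t_arr)),
```

with `σ = n_cycles / (4 f₀)` (the ±2σ core of the envelope spans `n_cycles`
carrier periods). Defaults: `f₀ = 2.4 kHz` (eye) or `3.4 kHz` (phantom) and
`n_cycles = 4`. Four cycles is chosen so that exactly five positive peaks
clear the third-peak picker's 5 %-of-maximum prominence gate (peak heights
`exp(−8k²/n²)` for `k = 0, ±1, ±2` are above 5 %, `k = ±3` below), which
puts the *third* positive peak at the packet centre — the feature the
phantom-branch timing method presumes. With three cycles only three peaks
qualify and the third-peak time would sit one full carrier period late. An
optional spark artifact (decaying exponential, τ = 10 µs) marks the trigger.

### Noise and seeding

Noise is white Gaussian, the neutral default in the absence of a measured
noise spectrum. Its standard deviation is set from the clean-trace RMS so
that `20·log10(RMS_signal/RMS_noise) = snr_db`; with zero signal amplitude a
unit-RMS noise-only trace is emitted and flagged in the metadata. All
randomness flows through `numpy.random.default_rng(seed)`; sweep generation
spawns per-trace child seeds from the config seed, so equal configurations
are bit-identical and traces within a sweep are independent.

### Default study conditions

| quantity | default | why |
|---|---|---|
| eye radius `R` | 12 mm | porcine globe |
| eye areal density `μ` | 1.05 kg/m² | ≈1 mm cornea at 1050 kg/m³; gives c = 5 m/s at ~33 mmHg |
| phantom membrane | 50 µm, μ = 0.06 kg/m² | thin polyurethane film |
| air gap / shock speed | 15 mm / 412 m/s | source distance; Mach 1.2 front |
| surface arc | 10 mm (eye), 25 mm (phantom) | footprint-to-zenith path |
| pressure range | 10–70 mmHg | clinically relevant sweep |
| sample rate | 2 MS/s default | desk-scale; the acquisition-hardware rates (100–200 MS/s) are supported and used only for rate-scaling of filter windows |
| trace duration | 6 ms (eye) | contains the slowest packet (10 mmHg) with 3σ margin |
| mmHg↔Pa | 133.322 Pa/mmHg | fixed conversion |

## Time-of-flight extraction

Both branches start with Savitzky–Golay smoothing (polynomial order 3 by
default — the order is a free choice — window 2000 points *at the reference
200 MS/s rate*). Window lengths are specified in points, as acquisition
software does; `FilterSpec.scaled_to(rate)` rescales them to preserve
physical duration at other rates, keeping the SG window odd and above the
polynomial order. Edges are mirror-padded; envelope samples within half a
window of an edge are flagged unreliable.

- **Phantom branch** — third positive local maximum, scanning forward, with
  prominence ≥ 5 % of the trace maximum (the prominence floor is a policy
  choice; the qualitative rule is "a clearly distinguishable peak").
- **Eye branch** — envelope pipeline: rectification (|x|, required for a
  meaningful envelope), 200-point moving median, 120-point sliding mean,
  then an IIR Butterworth low-pass. The published constraint "−50 dB at
  5 kHz" under-determines the filter, so the order is fixed (4) and the
  −3 dB corner solved from `f_c = f_a / (10^(A/10) − 1)^(1/2n)` ≈ 1.19 kHz;
  the filter is applied forward–backward so zero group delay biases the
  peak time. Negative ringing is clipped at zero. TOF = envelope maximum
  (ties to the earliest sample); the energy centroid
  `Σ t x² / Σ x²` over the signal window and the highest smoothed peak are
  selectable alternatives — published descriptions of this branch name both
  the envelope peak and the energy centroid, so both are first-class.
- **QC** — SNR is `20·log10(RMS_signal-window / RMS_noise-window)` with a
  pre-arrival noise window (default [0, 0.5] ms) and half-open window
  semantics; estimates below 6 dB (a policy default — only the observed
  rejection fraction of such studies is documented, not the threshold) are
  rejected, and batch extraction reports the rejection fraction. Manual
  corrections come from an overrides table and are flagged
  `manually_corrected`, never silently merged.

## Calibration

Linear calibration is OLS of IOP on TOF with a teaching/validation split;
`evaluate_validation` refuses any overlap between teaching and validation
ids (the blinding protocol). The power model `IOP = a·TOF^b` is fitted by
nonlinear least squares in original units, initialized from the log–log OLS
fit (tolerance 1e-10, ≤ 200 iterations); fitting in original units rather
than log space keeps the residuals in mmHg. The air-path delay is
subtracted before power fitting by default, since only the surface term
carries pressure dependence; `subtract_air_delay` guards against
over-subtraction. Sensitivity is the secant slope of the *inverse* model
(TOF per IOP) in µs/mmHg; for any `b < 0` its magnitude falls with IOP,
which is why agreement with a reference tonometer is heteroscedastic —
poorer in mmHg terms at high pressure.

## Agreement statistics

Bland–Altman differences use the `n−1` SD denominator; `RPC = 1.96·SD`,
limits of agreement = bias ± RPC. Pooling across repeated sweeps within one
eye is the default (ids let callers stratify); no repeated-measures
correction is applied. Because the unit convention of a published "SSE in
mmHg" is ambiguous, `residual_summary` reports both the SSE (mmHg²) and the
RMS residual (mmHg).

The end-to-end agreement study (in `experiments`) runs
simulate → extract → calibrate, then perturbs the extracted TOFs with
seeded jitter sized through the fitted model's inverse slope so the induced
IOP error is ~2.5 mmHg RMS at every pressure (scatter in time grows where
sensitivity shrinks, as in real recordings), and reports the Bland–Altman
comparison of predictions against reference pressures. This reproduces the
~5 mmHg RPC *regime* qualitatively; it is not a reanalysis of any measured
data set.

## Safety physics

All closed forms: `E = CV²/2`; worst case ozone assumes every joule
dissociates O₂ (498 kJ/mol) and each O atom forms one O₃, so
`n_O₃ = 2E/498000`; room air from the ideal gas law (R = 8.314 J/mol·K);
concentration in ppb is the molar ratio ×10⁹. The peak pressure behind the
shock uses the Rankine–Hugoniot normal-shock jump, which gives 1.51 bar at
Mach 1.2 — an isentropic stagnation estimate would give ~2.4 bar, and the
normal-shock static jump is the physically appropriate quantity for a
passing front. The Mach number from camera footage is the least-squares
slope of front position against frame time divided by `√(γ R_s T)`
(343.2 m/s at 20 °C). The membrane-bulge artifact bound divides the bulge
distance by either the ambient sound speed (3 mm → 8.7 µs) or the shock
speed (3 mm → 7.3 µs); both conventions are exposed because either could be
meant by an order-of-magnitude figure of ~8 µs.

## Numerical choices and degenerate inputs

- Peak ties break to the earliest time everywhere.
- Zero noise RMS ⇒ SNR = +∞ (accepted); zero signal RMS ⇒ −∞ (rejected).
- Windows are half-open `[start, end)` so adjacent windows partition a
  trace exactly.
- A packet whose ±3σ core would leave the trace raises a configuration
  error instead of silently truncating.
- Constant-TOF calibration sets, non-positive data in power fits, and
  non-invertible models raise typed errors (`FitError`, `ParameterError`,
  `ProtocolError`).
- Trace files must have a uniform time grid to 1 ppm of the sample period
  and finite samples; seeds recorded in sidecars keep runs reproducible.

## Problem sizes

The reference studies use 20 pressures × 3 repeats (exponent recovery) and
13 × 3 × 3 seeds (agreement) at 2 MS/s and 6 ms per trace — about 240
traces, a few seconds in total. These sizes give the fitted exponent a
seed-to-seed spread well inside ±0.01 noiseless and ±0.05 at 20 dB SNR.

## Known limitations

- No dispersion or viscoelasticity: TOF methods agree to within half a
  carrier period on synthetic packets, which overstates their agreement on
  real corneal signals.
- The simulator's noise is white; narrowband interference or drift would
  stress the SNR gate differently.
- Published sensitivities of such systems (order −100 µs/mmHg at low IOP,
  −20 µs/mmHg at high IOP) depend on the specific fitted geometry and are
  reproduced qualitatively (sign and decreasing magnitude), not numerically.
- The safety chain is a worst-case paper calculation, not a plasma
  chemistry model; in reality most of the stored energy dissipates as heat.
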