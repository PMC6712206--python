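# Methods notes

This note records the scientific and numerical choices behind the package:
what the procedures assume, which parameters matter, what the synthetic
generator does and does not emulate, and where the design was genuinely
open.

## Conductance decomposition

The decomposition assumes (i) an ideal somatic voltage clamp (V_m equals
the command potential; series-resistance and space-clamp errors are not
modelled), (ii) only two synaptic conductance classes with known,
time-invariant reversal potentials (defaults 0 and −70 mV), and (iii) a
current/voltage relation that is linear across the clamped potentials at
every timepoint. Under these assumptions the per-timepoint OLS slope a(t)
equals the total synaptic conductance and the intercept b(t) carries the
weighted reversal information; the reconstruction is exact for noise-free
data with any ≥2 distinct potentials (verified to <1e−9 nS in the tests).

Choices where the procedure was underdetermined:

- **Repeats are averaged before the fit** (the acquisition protocol is
  organized that way); fitting per repeat and averaging conductances would
  give the same expectation but noisier traces.
- **Unweighted OLS** across potentials: nothing suggests heteroscedastic
  weighting, and with equal noise per sweep OLS is efficient.
- **Negative conductance estimates are reported unclipped** by default
  with an optional clip-and-flag mode. Clipping is a nonlinearity that
  would break the additivity of the estimator; downstream summation fits
  tolerate small negative excursions.
- **r² convention:** where the current is identical across potentials the
  flat line fits perfectly; r² is recorded as 1 rather than NaN so QC
  statistics stay defined pre-stimulus.
- **Linearity QC:** a sweep set passes if the median r² over the response
  window is ≥0.9 (configurable), mirroring the inclusion rule that only
  cells with linear I/V relations enter the analysis.
- **Analysis grid:** [0, 100] ms at 0.1 ms. Raw 100 kHz acquisitions are
  decimated by boxcar mean; the boxcar is unbiased for band-limited
  signals and suppresses noise by √factor.

G_m is measured as ΔI_steady/ΔV from a small voltage step (plateau means;
windows configurable). With the default 111 MΩ input resistance this gives
9.0 nS; the interneuron default (104 MΩ) gives 9.6 nS.

## Summation fit

The fit minimizes Σ w(t)²·(DUO − α·(AiP+LA))² with w(t) = exp(−t/τ),
τ = 20 ms, over [0, 100] ms, constrained to α ≥ 0. Two points were not
derivable from the original description and are fixed here explicitly:

- **Weight application:** w enters as a per-point weight of the residual
  (so w² multiplies the squared residual) — ordinary weighted least
  squares. With the stated τ the first 40 ms carry ~86% of the total
  weight, which is the stated intent of the weighting.
- **Non-negativity** is on by default (the original fit used a
  non-negative solver); an unconstrained mode exists for diagnostics. The
  closed form max(0, Σw²sd/Σw²s²) is the exact NNLS solution for a single
  regressor, cross-checked against scipy's NNLS in the tests.

Classification uses tol = 0 per cell (α strictly above/below 1); whether a
*population* summates linearly is decided by the Z test against 1, not by
per-cell tolerance.

## Detection

The 8×SD onset rule uses a two-sided threshold on |signal − baseline mean|
by default, because inward synaptic currents are negative-going while
PSPs are positive-going; a one-sided mode exists. The first 0.5 ms after
the stimulus are blanked (stimulus artifact; configurable — the original
artifact handling is unspecified). The baseline window defaults to
[−100, 0] ms, shared with background subtraction. With a noiseless
baseline the threshold degenerates to zero and any deviation counts; a
completely flat zero trace raises instead of returning an arbitrary
answer. Spike detection is scipy's local-maximum search with prominence
20 mV and minimum peak −10 mV (the classic peak-detector parametrization).

## VSD processing

All stages are linear; the chain is verified linear to 1e−10. Specifics:

- **Spatial filter:** "kernel width of one inter-diode distance" is read
  as σ = 150 µm (not FWHM). Because the diode array is hexagonally packed
  (irregular grid), the filter is a distance-based Gaussian kernel over
  diode coordinates, row-normalized so constants pass unchanged — no
  interpolation onto a square grid, hence no interpolation artifacts.
- **Temporal filter:** centered 5 ms running average with truncated
  (shrinking) windows at the edges, preserving DC. It trims the peak of
  the default response kernel by <1%.
- **First positive deflection:** deflections are maximal runs of positive
  samples in the search window (default [0, 200] ms); the response is the
  first run whose peak exceeds 8× the pre-stimulus SD of the ROI trace,
  which skips brief noise blips while reducing to "first positive run"
  for noiseless data. The undershoot after the deflection is not
  analyzed.
- The acquisition-side 0.2 Hz high-pass is assumed already applied to
  input data. Time-varying Amax (re-measured during long sessions) is
  supported by passing per-repeat recordings; the generator uses a single
  Amax per diode.

## Statistics

The one-sample Z test plugs the sample SD into a normal reference:
z = (mean − µ0)/(SD/√n). With the SD estimated from n = 18–28 cells this
is anti-conservative relative to a t test (effective size ≈0.066 at
n = 18 for nominal 0.05); the calibration test therefore checks the 5%
type-I error at n = 100 per replicate, where the plug-in approximation is
accurate. "Pearson's coefficient" skewness is the moment coefficient
g1 = m3/m2^{3/2} (biased population-moment form — the reported values are
small and unlabelled); the median-based second coefficient is available
via `variant="median"`. Pointwise trace comparisons are per-timepoint
paired t tests at uncorrected p < 0.05, exactly as in the figure
conventions they reproduce — no multiple-testing correction is applied,
so isolated significant timepoints must be interpreted with care.

## Synthetic data: what it emulates, what it does not

The generator states the world the analysis was designed for:

- **Kernels:** difference-of-exponentials conductance transients with the
  measured pathway defaults (AiP: exc 2.94 nS at 5.95 ms, inh 8.89 nS at
  7.67 ms; LA: exc 0.75 nS at 5.55 ms, inh 3.22 nS at 6.72 ms). Rise and
  decay time constants are **not** reported anywhere and are package
  defaults (τ_rise = 1 ms, τ_decay = 10 ms, plausible for AMPA/GABA_A
  mixtures at near-physiological temperature). Kernels are normalized so
  the maximum **on the evaluated grid** equals the requested peak exactly
  (analytic-peak normalization would undershoot on a discrete grid).
- **Voltage clamp:** ideal clamp, passive leak from the measured membrane
  parameters (111 MΩ, −62.8 mV for principal cells), additive white
  Gaussian current noise (default SD 10 pA), 5 holding potentials from
  −90 to −50 mV, 3 repeats differing only in noise.
- **LIF current clamp:** forward Euler at dt = 0.01 ms (≥10× below the
  ~2.4 ms membrane time constant; larger dt raises an error), threshold
  −37.3/−36.1 mV, reset to rest, 2 ms refractory period, stylized
  one-sample spike peaks at +30 mV rendered for detector testing. The
  internal spike log is the ground truth. Interneuron synaptic drive is
  derived from the measured current peaks at −70 mV (1416 pA AiP, 322 pA
  LA → 20.2/4.6 nS over the 70 mV driving force).
- **DUO construction:** exactly α·(AiP + LA), optionally passed through a
  tanh saturation for robustness fixtures.
- **Diode array:** 464 hexagonally packed diodes at 150 µm pitch, 1 kHz
  sampling, per-diode Amax drawn uniformly in [800, 1200] (arbitrary
  12-bit-scale light levels), fractional noise SD 0.002. The default
  response is a spatial Gaussian of σ = 1.5 mm — broad relative to the
  pitch, as a deep-layer population depolarization is — times a
  difference-of-exponentials time course of fractional amplitude 0.0741.
  A narrow wave (σ comparable to the pitch) would be visibly attenuated
  by the 150 µm spatial filter; that attenuation is filter physics, not
  an artifact.
- **Population scenarios:** per-cell kernel peaks jittered lognormally
  (σ_log = 0.3) and latencies normally (SD 0.5 ms), true α drawn from the
  configured normal distribution (defaults 0.77 ± 0.1786 for excitation,
  0.94 ± 0.2785 for inhibition, n = 18). The measured between-cell peak
  dispersion is larger (CV ≈ 0.8), but at that dispersion a noticeable
  fraction of cells have near-zero kernels and degenerate per-cell fits;
  0.3 keeps every synthetic cell analyzable while preserving realistic
  heterogeneity.

Not emulated: series-resistance/space-clamp errors, voltage-dependent or
kinetically filtered synaptic currents, dye bleaching, optical point
spread, correlated (line/synaptic background) noise. A green test
therefore establishes correctness of the estimators under the stated
model, not robustness to those artifacts.

## Determinism

Every generator is a pure function of its seed; the pipeline derives
per-stage, per-cell child seeds from the master seed via SHA-256 (kept
below 2³¹), so runs are bit-identical across machines and stage order.
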