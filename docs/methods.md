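# Methods

## Decay model and discretization

The donor population is a two-state mixture: free donors (lifetime
τ_free, default 2.6 ns) and donors undergoing FRET (τ_FRET, default
1.1 ns; FRET strictly shortens the lifetime). The continuous decay is

F(t) = F0 (P_free e^(−t/τ_free) + P_FRET e^(−t/τ_FRET)),

with P_free + P_FRET = 1 held structurally (P_FRET is derived, never
stored). The default lifetimes are fixture/calibration choices for the
simulator and the fixed-lifetime fit mode, not measured constants.

Time is circular over the 12.5 ns laser period (80 MHz pulse train):
photons emitted more than one period after their pulse appear in the next
period's histogram. Expected channel contents are therefore built from the
*wrapped* exponential (geometric pile-up of previous pulses), and IRF
convolution is periodic; a truncation mode exists for tests. Channels are
0-based, channel i covers [iΔ, (i+1)Δ) with center (i+0.5)Δ.

Expected counts are **bin integrals** of the wrapped decay, not point
samples at channel centers. This matters for the offset arrival time t0: a
sub-channel shift of a point-sampled exponential is exactly equivalent to
rescaling each component (the likelihood is flat in t0 within a channel),
whereas bin integration moves edge mass between the two channels
straddling the rise, keeping t0 identifiable to well below one channel.

## Offset estimation and fitting

t0 is estimated once per field of view from the pooled (high-count)
histogram by maximizing the Poisson likelihood of the IRF-reconvolved
model with t0 free and the amplitude fraction and scale profiled out
(coarse grid at a quarter channel, then bounded scalar refinement). ROIs
and pixels then reuse that t0; per-ROI refitting of t0 is deliberately not
done.

ROI fits minimize the Poisson deviance (correct noise model for photon
counting at low counts); the overall scale is profiled in closed form
(MLE scale matches the observed total), so the default fixed-lifetime mode
is a 1-D optimization over P_FRET in [0, 1], started at 0.3 with
multi-start at {0.1, 0.5, 0.9} on non-convergence; ties break to the
lowest deviance, then the lowest P_FRET. Convergence: relative deviance
change < 1e-8 or 500 iterations. A full mode frees both lifetimes and t0
(Nelder-Mead on the profiled deviance) for calibration work, and a
weighted-least-squares loss is available as a cross-check. Histograms
under 100 photons are rejected for fitting; the same threshold masks map
pixels.

Fitted P's are treated as amplitude (species) fractions. The *photon*
fraction of the FRET species,
P_FRET τ_FRET / (P_free τ_free + P_FRET τ_FRET), is exposed as a derived
quantity; it is strictly smaller than the amplitude fraction because the
FRET species emits fewer photons per molecule. Reported ΔP_FRET time
courses use the photon fraction; Δlifetime uses the empirical mean
lifetime by default (the fitted-model photon-weighted lifetime is
switchable).

## Empirical mean lifetime and the period-truncation correction

The raw count-weighted mean of (channel center − t0), with pre-t0 photons
wrapped forward one period, is a model-free lifetime proxy — but over a
12.5 ns period it underestimates a 2.6 ns lifetime by ~0.10 ns, because
the slow tail wraps: the circular mean of a wrapped exponential is
τ − P/(e^(P/τ) − 1), not τ. Since the pipeline fixes the two calibration
lifetimes anyway, the estimator optionally applies a closed-form two-state
unwrap: the circular mean is affine in the component photon weights, so
the weights — and from them the analytic photon-weighted mean lifetime and
the amplitude fraction — are recovered exactly in the expected-counts
limit, with no fitting. The constants are computed on the same discrete
bin-integrated grid as the forward model, making the round trip exact to
float precision for a delta IRF. Lifetime maps use this corrected fast
path (after subtracting the IRF's mean convolution delay); the slow path
fits each pixel. Raw circular means remain available.

## Synthetic data

The generator emulates the statistical structure the analysis assumes,
with ground truth always returned beside the data and every randomness
source behind an explicit seed (identical seeds give bit-identical
output).

- **Histograms**: per-channel Poisson draws (or exact-total multinomial)
  from the bin-integrated, IRF-convolved, offset-shifted expected curve.
- **Reporter kinetics**: dp/dt = k_PKA(1−p) − k_phosphatase·p integrated
  in closed form per drug epoch; the reporter relaxes with rate
  (k_PKA + k_phos), so lifetime deliberately *lags* step changes in the
  underlying activity — the known reporter-lag caveat, made testable.
- **p → P_FRET mapping**: affine between endpoint free-donor fractions
  0.85 (dephosphorylated) and 0.45 (fully phosphorylated) — a large but
  plausible biosensor dynamic range, chosen once; the kinetics module's
  interpolation inverts it exactly, which is the pipeline's core
  end-to-end identity.
- **Drug epochs**: baseline (k_PKA=0.001/s, k_phos=0.05/s; ~2%
  phosphorylated), forskolin (k_PKA=0.15/s; relaxes to 75% phosphorylated
  with ~5 s time constant), H89 (k_PKA=0; decays to 0 with 20 s time
  constant). The agonist scenario gives the nucleus tenfold slower rates
  than the cytoplasm at the same steady-state target, so the nuclear
  response is slower — compartmentalized kinetics.
- **Frame budget**: 1e5 photons per ROI frame every 10 s (neither budget
  nor frame rate is a measured constant; 1e5 gives a fixed-lifetime fit
  sd on P_FRET well under 0.01, pinned by the calibration tests).
- **FRAP**: baseline 1.0, instantaneous step to 1 − bleach_frac at t = 0,
  exponential recovery to a plateau (full recovery by default — a small
  bleached region exchanging with a large cytoplasmic pool). Defaults are
  the standard operating band: 40% bleach (within the 30–50% target),
  2% Gaussian noise on normalized fluorescence (traces are line-scan
  averages; a Poisson mode exists), 2 ms sampling, 1 s pre / 10 s post,
  4 acquisitions.

What the simulator does **not** model: spatial diffusion of the reporter
within a frame, photobleaching during FLIM acquisition, autofluorescence
spectra (background pixels are simply dark), pH effects on the donor
(optionally representable as a lifetime offset confound), detector
afterpulsing, and multi-FRET or triplet photophysics. Passing recovery
tests therefore demonstrate estimator correctness under the stated noise
model, not robustness to every artifact of real tissue.

## Kinetics conversions

f_pAKAR is the affine, order-reversing interpolation between calibration
endpoints; excursions outside [0, 1] up to 0.05 absolute are clipped with
a warning (fit noise near an endpoint), larger ones raise (they mean the
endpoints do not bracket the data). The steady-state ratio
k_phosphatase/k_PKA = (1−f)/f is reported as +inf at f = 0 and only
interpreted for windows that pass a steadiness check: an OLS line over the
window is flagged steady when the 95% CI on its slope contains zero (the
criterion and level are configurable; a perfectly constant window is
steady by convention). Only the ratio is identified at steady state, never
the individual rates. Condition comparisons use unpaired Welch t-tests
(Welch–Satterthwaite df, two-sided) against a reference group with
Bonferroni-corrected per-comparison alpha.

## FRAP numerical choices

Fits use only post-bleach samples; the first post-bleach sample defines
t = 0 of recovery, excluding the (finite-width) bleach pulse. The plateau
is free — no assumption of return to baseline. τ is initialized from the
63%-of-span crossing time and bounded to [1 ms, 10 s]; fits with amplitude
below twice the residual sd (or τ at a bound, or optimizer failure) are
flagged unidentifiable and excluded-but-counted in summaries. Per-class
summaries report mean, SEM (undefined for n = 1, reported as missing) and
the empirical CDF.

## Problem sizes

Defaults are desk-scale: 64-channel histograms, 1e5-photon ROI frames,
16×16-pixel phantoms at a few thousand photons per pixel, tens of frames
per scenario, and FRAP ensembles of 16–22 regions × 4 acquisitions. The
whole test suite and the acceptance script each run in seconds on one
core.
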