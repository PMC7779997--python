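# Methods

`dcsmc` separates cerebral from scalp blood flow in multi-distance diffuse
correlation spectroscopy (DCS) by fitting measured intensity
autocorrelations against a layered Monte Carlo forward model.  This note
records the models, the numerical choices, what the synthetic data do and
do not emulate, and the known limitations.

## Models

### Semi-infinite analytical model

The homogeneous reference model is the correlation-diffusion solution for
a semi-infinite medium with an extrapolated boundary:

    G1(rho, tau) ∝ exp(-K r1)/r1 - exp(-K r2)/r2
    K^2          = 3 mu_a mu_s' + mu_s'^2 k0^2 alpha <dr^2(tau)>
    <dr^2(tau)>  = 6 BFi tau

with `r1 = sqrt(rho^2 + z0^2)`, `r2 = sqrt(rho^2 + (z0 + 2 zb)^2)`,
`z0 = 1/mu_s'`, `zb = 1.76/mu_s'` (tissue refractive index 1.37) and the
in-medium wavenumber `k0 = 2 pi n / lambda`.  The moving-scatterer
fraction `alpha` is not separable from the diffusion coefficient in this
parameterisation; the fitted quantity is `alpha*Db`, reported as BFi in
mm^2/s.  The measured intensity autocorrelation follows from the Siegert
relation `g2 = 1 + beta g1^2`.

Default bulk properties for 850-nm forehead fitting are `mu_a = 0.015`,
`mu_s' = 0.85` mm^-1.  A second, tabulated property set (0.020/0.800 at
850 nm, with the -1.5 power-law scattering scaling to 767 and 785 nm) is
shipped in the configuration; the two sets coexist deliberately — the
fitting defaults come from frequency-domain NIRS group averages, the table
from the instrument-wavelength bookkeeping — and either can be selected.

### Layered Monte Carlo model

Photon transport is simulated once through a finely layered medium (1-mm
layers; 21 over a semi-infinite terminal medium for the slab, 22 on an
80-mm-radius sphere for the curved surrogate).  For every detected photon
the per-layer pathlength `L_i` and accumulated momentum transfer
`Y_i = sum(1 - cos(theta))` are recorded.  The field autocorrelation for a
layered flow state is then

    G1(tau) = (1/Np) sum_n exp(-(k0^2/3) sum_i Y_ni * 6 BFi_i tau)
                         * exp(-sum_i mu_a_i L_ni)

Because absorption enters only through static per-photon weights, one
history serves any absorption setting; and because the fine layers are
concatenated into coarse scalp/skull/[CSF/]brain layers in
post-processing, one history serves the entire thickness grid (18
two-layer and 70 three-layer versions).  A scattering change invalidates
the history and requires a new transport run.

Transport choices:

- Scattering is isotropic at the reduced rate mu_s' (similarity relation),
  so the expected momentum transfer per event is 1 and per unit path is
  mu_s'.  Henyey-Greenstein sampling is deliberately not emulated; the
  similarity relation is the standard choice when only mu_s' is known.
- Absorption is excluded from transport (applied in post-processing).
- The top surface uses unpolarised Fresnel reflection/refraction with
  n_tissue = 1.37 against air; this matches the extrapolation length used
  by the analytical model.
- Detectors are annuli (default centres 5, 25, 30 mm, half-width 1 mm),
  exploiting rotational symmetry.  The symmetric radial average across an
  annulus biases g1 only at second order (<0.2%).
- Photons are terminated at 60 mm depth, 70 mm lateral radius, or a
  1200-mm total pathlength.  Paths beyond these bounds carry absorption
  weights below 1e-5 at any tissue-like mu_a and contribute nothing
  detectable; enlarging the domain was verified to leave g1 unchanged
  within Monte Carlo noise.
- The default desk-scale budget is 1e7 launched photons (a few minutes on
  one core); the count is a config knob and all stochastic test
  tolerances are stated at that default.

### Agreement between the two models

For a uniform medium the history-derived g1 at 25 mm agrees with the
analytical solution to within 0.05 on the normalised curve everywhere
g1 >= 0.1, and within a few percent relative over the main decay
(g1 >= 0.35).  The relative deviation grows systematically as g1 falls
(about 13% at g1 = 0.1): the deep tail of g1 is carried by the shortest,
earliest-arriving photon paths, exactly the regime where the diffusion
approximation behind the analytical model fails.  This deviation is a
property of the model pair — it is independent of photon count, seed, and
domain size — and is the quantitative reason Monte Carlo fitting is
preferred over the analytical model at short separations.

## Inverse fits

All fits minimise summed squared g2 residuals over the delay window
[1e-6, 1e-2] s (the full decay region; restricting to the upper part of
the curve is known to inflate fit variance).  `beta` enters `g2 - 1`
linearly in `g1^2`, so for any trial BFi the optimal beta has the closed
form `sum((g2-1) g1^2)/sum(g1^4)`, clipped to [1e-3, 0.6].  Profiling
beta out reduces every fit to a bounded scalar minimisation over
log10(BFi) in [1e-12, 1e-3] mm^2/s — the same optimum as a joint bounded
least squares, but robust and fast enough for 70-candidate grid searches.
Standard errors come from the curvature of the profiled objective at the
optimum (delta method back to linear BFi).

Timecourse fitting uses a two-pass beta scheme for hypercapnia sessions:
pass 1 fits (BFi, beta) per timepoint, pass 2 refits BFi with beta held at
the per-detector median of pass 1.  Pressure-modulation sessions use the
single-pass fit, since probe pressure genuinely moves beta.

The layered fit holds the scalp-layer BFi to the 5-mm analytical fit at
the same timepoint, the skull layer to 2e-8 mm^2/s, and (four-layer
models) the CSF layer to 5e-8 mm^2/s, the centre of the 1e-8 to 9e-8
band around the biological zero of the blood flow index; the only free
flow parameter is the brain BFi (initial guess 5x the scalp constraint, a
physiological-ratio prior).  Per-layer absorption defaults are
0.010/0.033/0.004/0.023 mm^-1 for scalp/skull/CSF/brain.

Two consequences of the constraint design deserve emphasis:

- **The long-separation curves form the objective.**  The 5-mm curve's
  information is consumed by the scalp constraint; re-including it in the
  least-squares objective lets analytical/Monte-Carlo model mismatch at
  short separation leak into the brain estimate (a measured +48% bias on
  synthetic sessions, versus +3% with long-separation-only objectives).
- **Absolute CBFi carries a model-transfer bias; relative changes do
  not.**  In a layered medium the semi-infinite 5-mm fit reads about
  0.85x the true scalp flow, and the brain-flow tail of the
  multi-distance g2 is so sensitive to the scalp constraint that this
  deflates/inflates absolute CBFi by tens of percent (an overstated scalp
  constraint drives the fitted brain flow down hard, because the slow
  tail of g2 is carried by shallow, scalp-weighted photons).  The bias is
  stable across a session, so the reported quantity — the relative
  timecourse DrCBFi(%) — is recovered to a few percent.  Absolute CBFi
  values should be interpreted with this in mind.

## Model selection

The thickness grid is fitted on a pressure-modulation session (probe
pressure occludes scalp flow; brain flow is unaffected).  Each candidate
gets (a) a stability score — the RMS fractional deviation of the fitted
CBFi from its baseline mean over the whole timecourse — and (b) the
baseline brain-to-scalp flow ratio (baseline-mean brain fit over
baseline-mean scalp constraint).  Candidates with ratio outside [3, 8]
are rejected; among the rest the smallest stability score wins, ties
breaking towards the thinnest extracerebral total so selection is
order-independent.  If no candidate is in band the selection returns a
structured "no model" diagnosis, the signature of a measurement with
little brain sensitivity.  By default, out-of-band candidates skip the
full-timecourse fit (their score is reported as NaN); window weighting of
the stability score is uniform.

## Synthetic data

The generator emulates the two protocols with known per-layer ground
truth, forward-modelled through the same layered history machinery used
for fitting:

- Pressure modulation: 20/30/10 s phases, 3-s bins; scalp drops by a
  seed-drawn 50-90% during pressure with 3-s raised-cosine edges; brain
  constant.
- Hypercapnia: 60/120/120 s phases, 10-s bins; brain follows a smoothed
  trapezoid peaking +30-40% (45-s edges, tracking the end-tidal CO2
  stimulus) with full recovery; in the *contaminated* scenario the scalp
  ramps later to +20-50% and stays 10-25% above baseline at the session
  end; *clean* keeps the scalp flat; *low-sensitivity* suppresses the
  brain response.

Baseline flows are scalp 1.0e-6 and brain 3.5e-6 mm^2/s (true ratio 3.5).
The baselines were calibrated once so that the *measured* brain-to-scalp
ratio — the quantity the selection band [3, 8] filters on, and the
quantity reported for real subjects — sits mid-band: the pipeline's two
analytical-transfer factors (scalp constraint ~0.85x truth, brain fit
inflated correspondingly) raise the measured ratio about 1.7x above the
true ratio.

Noise is zero-mean Gaussian with the g2-shaped standard deviation

    sigma(tau) = sigma0 (1 + beta - g2(tau) + c) (T_bin/T_ref)^(-1/2)

(sigma0 = 0.01, c = 0.05, T_ref = 10 s): largest where the curve has
decayed, scaling with the inverse square root of the integration time.
This is a transparency-first stand-in for a full correlation-noise model;
it reproduces the qualitative structure (tail-heavy, bin-width scaling)
but not the inter-tau correlations of real correlator noise, so recovery
tolerances demonstrated here do not automatically transfer to hardware
data.  sigma0 is set so that recovery tests are nontrivial, not from a
measured instrument.

Physiological waveforms: a 1-kHz capnograph with 0.25-Hz breathing
(sigmoid-gated between an inspired floor of 3 mmHg and an end-tidal
plateau of 36 mmHg stepping +10 mmHg during CO2 with ~50-s physiological
edges), and 100-Hz Doppler velocities constructed from the capnograph's
upper envelope, advanced by a 5-s lag and mapped through
`slope*dPETCO2 + intercept` (defaults 3.2, -0.4), with multiplicative
1-Hz cardiac pulsatility (10-12%) and 0.2% white noise.  The velocities
are tied to the *measurable* envelope rather than the latent plateau so
the constructed relation is recoverable by the processing chain.

## Physiological processing

- Envelopes interpolate local extrema separated by at least one
  oscillation cycle (2 s breathing, 0.5 s cardiac), with a prominence
  floor of 5% of the trace range so that noise riding on the opposite
  phase of the cycle does not enter the envelope support.
- The Doppler chain lowpasses the envelopes at 0.01 Hz with a zero-phase
  (forward-backward) second-order Butterworth — zero-phase so the lag
  search is not corrupted — normalises by the baseline mean and averages
  all available envelopes into one percent-change timecourse.
- The lag search shifts the end-tidal change by 1..10 s (1-s steps) and
  regresses the Doppler percent change on it over 60-250 s.  The shifted
  regressor is passed through the same 0.01-Hz zero-phase filter before
  the regression: a filtered response regressed on an unfiltered
  regressor is an inconsistent estimator (any 5-minute protocol has
  signal in the filter's transition band, and the measured slope drops
  ~12% without matching).  The best unfiltered lag is retained as a
  diagnostic.
- Group averaging drops the single highest and lowest value per timepoint
  before computing mean, standard error and quartiles (linear
  interpolation between order statistics).
- Screening gates: count rate >= 5000/s per fibre at 30 mm; baseline
  coefficient of variation strictly below 25%; a >20% scalp increase
  sustained for >= 30 consecutive seconds after CO2 ends; and a
  long-separation profile distinct from the 5-mm one (peak times >= 10 s
  apart or end-of-session recovery >= 10 percentage points apart).  The
  persistence and distinctness thresholds are concrete defaults for
  criteria that are usually applied by eye; all are configuration.

## Degenerate inputs and tie-breaks

A flat g2 (no coherent signal) drives the profiled beta to its lower
bound and the fit is flagged unconverged rather than raising.  Timepoints
missing their 5-mm scalp constraint are flagged, never interpolated.
A zero-lag construction selects the 1-s boundary of the lag grid (the
grid deliberately starts at 1 s).  Selection ties break to the thinnest
extracerebral total, then lexicographically by plan.

## Problem sizes

Stochastic validations run at 1e7 launched photons for the homogeneous
cross-check, 25 synthetic hypercapnia sessions for brain-flow recovery,
and 20 pressure sessions for thickness-selection recovery (grid fits use
histories subsampled to 1500 photons per detector; session forward
models use 6000 per detector).  `scripts/acceptance.py` re-runs the same
pipelines at 4e6 photons and 8/6 seeds, sizes chosen as representative
desk-scale runs.

## Limitations

- The curved geometry is a concentric-shell surrogate, not an
  MRI-derived head; it captures curvature, not cortical folding, and
  layer thicknesses map to depth along the sphere normal.
- The scattering similarity relation is assumed; anisotropy is not
  sampled explicitly.
- Absolute CBFi inherits the analytical scalp-constraint transfer bias
  discussed above; relative timecourses are the validated output.
- The noise generator is uncorrelated across delay bins; real correlator
  noise is not.
- No motion artifacts, probe decoupling or afterpulsing are simulated.
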