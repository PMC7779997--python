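# dcsmc

Multi-layer Monte Carlo modelling and fitting for diffuse correlation
spectroscopy (DCS) measurements of cerebral blood flow.

DCS infers microvascular blood flow from the temporal autocorrelation of
multiply scattered coherent near-infrared light.  In adults, measurements
taken on the forehead are contaminated by scalp blood flow: systemic
responses (for example during a hypercapnia challenge) drive the scalp and
skin, and the standard homogeneous semi-infinite analytical fit mixes that
superficial signal into the cerebral blood flow index (CBFi).  `dcsmc`
implements the layered alternative: a Monte Carlo photon-transport forward
model whose per-photon, per-layer pathlengths `L` and momentum transfers
`Y` yield the field autocorrelation

    G1(tau) = (1/Np) * sum_n exp(-(k0^2/3) sum_i Y_ni <dr^2(tau)>_i)
                           * exp(-sum_i mu_a,i L_ni),
    <dr^2(tau)>_i = 6 BFi_i tau,      g2 = 1 + beta g1^2,

so that a constrained multi-distance inverse fit (scalp flow held to the
5-mm analytical fit, skull flow to 2e-8 mm^2/s) extracts the brain-layer
BFi free of scalp cross-talk.  One fine-layered transport run serves an
entire grid of scalp/skull thickness hypotheses (18 two-layer and 70
three-layer versions) by summing fine layers in post-processing; the
optimal thicknesses are chosen on a pressure-modulation measurement (probe
pressure occludes scalp flow) as the most pressure-stable candidate whose
baseline brain-to-scalp flow ratio is physiological (3–8).  Supporting
pipelines process end-tidal CO2 and transcranial Doppler waveforms and
calibrate the expected Doppler response `eTCD = 3.2 * dPETCO2 - 0.4`.

The package is intended for researchers in diffuse optical neuromonitoring
who want a self-contained, testable implementation of layered MC fitting —
including a synthetic-session generator with known ground truth, so every
stage can be validated without instrument data.

## Worked example

Simulate a layered slab, generate a synthetic contaminated hypercapnia
session with known truth, and fit it both ways:

```python
import numpy as np
from dcsmc import (LayeredGeometry, McConfig, simulate, concatenate_layers,
                   OpticalProperties, generate_flow_truth, generate_session,
                   fit_timecourse_two_pass, fit_layered_timecourse,
                   relative_change, HYPERCAPNIA)

props = OpticalProperties(wavelength_nm=850, mu_a=0.015, mu_sp=0.85)
history = simulate(LayeredGeometry(kind="slab", n_fine_layers=21, mu_s=0.85),
                   McConfig(photons_launched=2_000_000, rng_seed=303))

truth = generate_flow_truth(HYPERCAPNIA, "contaminated", seed=1)
session = generate_session(truth, history, props)

# homogeneous analytical fits per separation (two-pass beta)
ana = fit_timecourse_two_pass(
    {rho: session.curves_at(rho) for rho in (5.0, 25.0, 30.0)},
    props, two_pass=True)

# layered fit: scalp held to the 5-mm fit, brain free
t = ana.timestamps[5.0]
mc = fit_layered_timecourse(
    [c for c in session.curves if c.rho_mm > 10],
    concatenate_layers(history, (3, 7, 11)),      # scalp/skull/brain, mm
    props, dict(zip(t, ana.bfi[5.0])), beta_policy="two-pass")

base = (t >= 0) & (t <= 60)
print("end-of-session relative change (%):")
print(f"  scalp truth     {relative_change(truth.scalp_bfi, base)[-1]:6.1f}")
print(f"  brain truth     {relative_change(truth.brain_bfi, base)[-1]:6.1f}")
print(f"  analytical 30mm {relative_change(ana.bfi[30.0], base)[-1]:6.1f}")
print(f"  MC 3-layer      {mc.relative_change_pct((0, 60))[-1]:6.1f}")
```

Output:

```
end-of-session relative change (%):
  scalp truth       12.2
  brain truth        0.0
  analytical 30mm    8.1
  MC 3-layer         2.0
```

The generated brain flow has returned to baseline at the session end while
the scalp remains +12% elevated.  The homogeneous 30-mm analytical fit
ends at +8% — scalp cross-talk it cannot remove — whereas the layered fit
with the correct thicknesses ends within 2% of the brain truth.

The same pipelines are available from the shell:

```
dcsmc simulate --geometry slab --photons 10000000 --seed 0 --out hist.h5
dcsmc synth --protocol hypercapnia --scenario contaminated --seed 7 \
      --history hist.h5 --out session/
dcsmc select-model --pressure-session pressure_g2.csv --history hist.h5 \
      --plan 3layer --out selection.json
dcsmc run --hypercapnia session/g2.csv --history hist.h5 \
      --petco2 session/petco2.csv --scalp-mm 3 --skull-mm 7 --out results/
dcsmc physio-calibrate --tcd lmca.csv rmca.csv --petco2 petco2.csv \
      --interval 60 250 --out calib.json
```

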