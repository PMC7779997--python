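"""Synthetic test sessions with known ground truth.

Two protocols are emulated.  Pressure modulation: 20 s baseline, 30 s of
light probe pressure (scalp flow drops 50-90%, brain flow unchanged), 10 s
recovery, binned at 3 s.  Hypercapnia: 60 s baseline, 120 s of CO2-enriched
breathing, 120 s recovery, binned at 10 s; the brain flow follows a smooth
trapezoid peaking 30-40% above baseline with full recovery (tracking the
end-tidal CO2 stimulus), while in the *contaminated* scenario the scalp
flow ramps up later (+20-50%) and stays elevated at the end — the systemic
cross-talk the layered fit is designed to remove.

Sessions are produced by the same layered forward model used for fitting:
per bin and detector the noiseless g2 is computed from a photon history via
the per-layer autocorrelation model and the Siegert relation, then
zero-mean Gaussian noise with standard deviation

    sigma(tau) = sigma0 * (1 + beta - g2(tau) + c) * (T_bin / T_ref)^(-1/2)

is added (g2-shaped: larger where the curve has decayed, scaling with the
inverse square root of the integration time).  Every artefact records its
ground truth and seed; regeneration with the same seed is bit-identical.

Raw physiological waveforms are generated alongside: a 1-kHz capnograph
trace with 0.25-Hz breathing oscillations whose end-tidal plateau steps up
by +10 mmHg during the CO2 phase, and 100-Hz Doppler velocity traces with
multiplicative 1-Hz cardiac pulsatility constructed from the shifted
end-tidal trajectory through a known affine relation and lag.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .analytical import g2_siegert
from .data import G2Curve, PhotonHistorySet
from .layered import SKULL_BFI, CSF_BFI_DEFAULT, g1_from_history, layer_mu_a
from .optics import OpticalProperties
from .physio import PhysioTrace
from .transport import concatenate_layers

__all__ = [
    "ProtocolTemplate",
    "PRESSURE",
    "HYPERCAPNIA",
    "NoiseModel",
    "GroundTruth",
    "Session",
    "multitau_grid",
    "generate_flow_truth",
    "generate_session",
    "generate_physio",
    "PhysioTruth",
]


@dataclass(frozen=True)
class ProtocolTemplate:
    """Phase layout and binning of a measurement protocol."""

    name: str
    phases_s: tuple[float, float, float]     # baseline, intervention, recovery
    bin_width_s: float

    def __post_init__(self) -> None:
        if any(p <= 0 for p in self.phases_s) or self.bin_width_s <= 0:
            raise ValueError("phases and bin width must be positive")

    @property
    def total_s(self) -> float:
        return float(sum(self.phases_s))

    @property
    def baseline_window(self) -> tuple[float, float]:
        return (0.0, self.phases_s[0])

    @property
    def intervention_window(self) -> tuple[float, float]:
        return (self.phases_s[0], self.phases_s[0] + self.phases_s[1])

    def bin_centres(self) -> np.ndarray:
        n = int(round(self.total_s / self.bin_width_s))
        return (np.arange(n) + 0.5) * self.bin_width_s


PRESSURE = ProtocolTemplate("pressure", (20.0, 30.0, 10.0), 3.0)
HYPERCAPNIA = ProtocolTemplate("hypercapnia", (60.0, 120.0, 120.0), 10.0)


@dataclass(frozen=True)
class NoiseModel:
    """g2-shaped Gaussian noise with integration-time scaling."""

    sigma0: float = 0.01
    c: float = 0.05
    t_ref_s: float = 10.0

    def sigma(self, g2: np.ndarray, beta: float, t_bin_s: float) -> np.ndarray:
        return self.sigma0 * (1.0 + beta - g2 + self.c) \
            * (t_bin_s / self.t_ref_s) ** -0.5


def multitau_grid(tau_min: float = 1e-6, tau_max: float = 1e-2,
                  points_per_octave: int = 3) -> np.ndarray:
    """Quasi-logarithmic delay grid in the style of a multi-tau correlator."""
    n_oct = np.log2(tau_max / tau_min)
    n = int(np.ceil(n_oct * points_per_octave)) + 1
    return tau_min * 2.0 ** (np.arange(n) / points_per_octave)


def _smoothstep(t: np.ndarray, t0: float, width: float) -> np.ndarray:
    """Raised-cosine step from 0 to 1 over [t0, t0 + width]."""
    x = np.clip((t - t0) / max(width, 1e-9), 0.0, 1.0)
    return 0.5 * (1.0 - np.cos(np.pi * x))


def trapezoid(t: np.ndarray, on_s: float, off_s: float,
              rise_s: float, fall_s: float, amplitude: float) -> np.ndarray:
    """Smoothed trapezoid: 0 before ``on_s``, ``amplitude`` on the plateau."""
    return amplitude * (_smoothstep(t, on_s, rise_s)
                        - _smoothstep(t, off_s, fall_s))


@dataclass
class GroundTruth:
    """Per-layer BFi truth for one synthetic session."""

    protocol: ProtocolTemplate
    scenario: str
    scalp_mm: int
    skull_mm: int
    times: np.ndarray                         # bin centres, s
    scalp_bfi: np.ndarray                     # mm^2/s per bin
    brain_bfi: np.ndarray
    skull_bfi: float
    beta: dict[float, float]                  # rho -> coherence factor
    noise: NoiseModel
    seed: int

    def layer_flows(self, i: int) -> np.ndarray:
        """(scalp, skull, brain) flow vector at bin ``i``."""
        return np.array([self.scalp_bfi[i], self.skull_bfi, self.brain_bfi[i]])


#: Baseline layer flows (mm^2/s).  Scalp 1e-6 is the standard adult value;
#: brain 3.5e-6 puts the true brain-to-scalp ratio at 3.5, which the
#: measurement pipeline (whose scalp constraint and brain estimate carry
#: opposite analytical-transfer factors) reports in the middle of the
#: physiological 3-8 screening band.
SCALP_BFI_BASE = 1.0e-6
BRAIN_BFI_BASE = 3.5e-6
DEFAULT_BETA = {5.0: 0.50, 25.0: 0.50, 30.0: 0.50}


def generate_flow_truth(
    protocol: ProtocolTemplate,
    scenario: str,
    seed: int,
    scalp_mm: int = 3,
    skull_mm: int = 7,
    scalp_base: float = SCALP_BFI_BASE,
    brain_base: float = BRAIN_BFI_BASE,
    noise: NoiseModel = NoiseModel(),
    beta: dict[float, float] | None = None,
) -> GroundTruth:
    """Draw a ground-truth flow timecourse for a scenario.

    Scenarios: ``"clean"`` (scalp flat during hypercapnia), ``"contaminated"``
    (scalp ramp with sustained end elevation) and ``"low-sensitivity"``
    (no brain response; the scalp still reacts).  Pressure-modulation truth
    always drops the scalp by 50-90% during the pressure window and keeps
    the brain constant.
    """
    if scenario not in ("clean", "contaminated", "low-sensitivity"):
        raise ValueError(f"unknown scenario {scenario!r}")
    rng = np.random.default_rng(seed)
    t = protocol.bin_centres()
    on, off = protocol.intervention_window

    if protocol.name == "pressure":
        drop = rng.uniform(0.5, 0.9)
        scalp = scalp_base * (1.0 - trapezoid(t, on, off, 3.0, 3.0, drop))
        brain = np.full_like(t, brain_base)
    else:
        brain_peak = rng.uniform(0.30, 0.40)
        brain_resp = trapezoid(t, on + 5.0, off + 5.0, 45.0, 45.0, brain_peak)
        brain = brain_base * (1.0 + brain_resp)
        if scenario == "low-sensitivity":
            brain = np.full_like(t, brain_base)
        if scenario == "clean":
            scalp = scalp_base * np.ones_like(t)
        else:
            scalp_peak = rng.uniform(0.20, 0.50)
            end_frac = min(rng.uniform(0.10, 0.25), scalp_peak)
            # slow ramp peaking ~40 s after the CO2 phase ends, decaying only
            # partially: sustained elevation at the session end
            ramp_up = _smoothstep(t, on + 20.0, (off - on) + 40.0)
            decay = 1.0 - (1.0 - end_frac / scalp_peak) \
                * _smoothstep(t, off + 40.0, 70.0)
            scalp = scalp_base * (1.0 + scalp_peak * ramp_up * decay)
    return GroundTruth(
        protocol=protocol, scenario=scenario, scalp_mm=scalp_mm,
        skull_mm=skull_mm, times=t, scalp_bfi=scalp, brain_bfi=brain,
        skull_bfi=SKULL_BFI, beta=dict(beta or DEFAULT_BETA),
        noise=noise, seed=seed,
    )


@dataclass
class Session:
    """A generated multi-distance g2 session with its embedded truth."""

    curves: list[G2Curve]
    truth: GroundTruth
    seed: int

    def curves_at(self, rho_mm: float) -> list[G2Curve]:
        return sorted((c for c in self.curves if abs(c.rho_mm - rho_mm) < 0.25),
                      key=lambda c: c.timestamp_s)

    @property
    def rhos(self) -> list[float]:
        return sorted({c.rho_mm for c in self.curves})


#: Nominal per-fibre detected count rates (Hz) by separation, used as
#: session metadata for the screening gates.
DEFAULT_COUNT_RATES = {5.0: 180_000.0, 25.0: 25_000.0, 30.0: 12_000.0}


def generate_session(
    truth: GroundTruth,
    history: PhotonHistorySet,
    props: OpticalProperties,
    seed: int | None = None,
    detectors: Sequence[float] = (5.0, 25.0, 30.0),
    tau: np.ndarray | None = None,
    mu_a: np.ndarray | None = None,
    csf_bfi: float = CSF_BFI_DEFAULT,
    count_rates: dict[float, float] | None = None,
) -> Session:
    """Forward-model a session from ground truth through a photon history.

    ``history`` may be fine (it is concatenated to the truth's geometry) or
    already coarse with a matching layer count.  The same history can then
    be used by the inverse fit, making noiseless round-trips exact.
    """
    if history.has_terminal:
        groups = (truth.scalp_mm, truth.skull_mm,
                  history.n_layers - truth.scalp_mm - truth.skull_mm)
        coarse = concatenate_layers(history, groups)
    else:
        coarse = history
    n_layers = coarse.n_columns
    mu_a_vec = layer_mu_a(n_layers) if mu_a is None else np.asarray(mu_a, float)
    seed = truth.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    tau = multitau_grid() if tau is None else np.asarray(tau, float)
    rates = dict(DEFAULT_COUNT_RATES, **(count_rates or {}))
    t_bin = truth.protocol.bin_width_s
    k0 = props.k0

    det_ids = {rho: coarse.detector_for_rho(rho, atol=0.51) for rho in detectors}
    curves: list[G2Curve] = []
    for i, t_c in enumerate(truth.times):
        if n_layers == 3:
            flows = truth.layer_flows(i)
        elif n_layers == 4:
            flows = np.array([truth.scalp_bfi[i], truth.skull_bfi,
                              csf_bfi, truth.brain_bfi[i]])
        elif n_layers == 2:
            flows = np.array([truth.scalp_bfi[i], truth.brain_bfi[i]])
        else:
            raise ValueError(f"unsupported layer count {n_layers}")
        g1 = g1_from_history(coarse, mu_a_vec, flows, k0, tau,
                             detectors=list(det_ids.values()))
        for rho in detectors:
            beta = truth.beta[rho]
            g2 = g2_siegert(g1[det_ids[rho]], beta)
            sigma = truth.noise.sigma(g2, beta, t_bin)
            g2_noisy = g2 + rng.normal(0.0, 1.0, size=g2.shape) * sigma
            curves.append(G2Curve(
                tau=tau.copy(), g2=g2_noisy, rho_mm=rho,
                integration_time_s=t_bin,
                count_rate_hz=rates.get(rho), timestamp_s=float(t_c)))
    return Session(curves=curves, truth=truth, seed=seed)


@dataclass
class PhysioTruth:
    """Construction parameters of a synthetic physiological recording."""

    lag_s: float
    slope: float
    intercept: float
    co2_step_mmhg: float
    baseline_mmhg: float
    seed: int


def generate_physio(
    seed: int,
    lag_s: float = 5.0,
    slope: float = 3.2,
    intercept: float = -0.4,
    co2_step_mmhg: float = 10.0,
    baseline_mmhg: float = 36.0,
    protocol: ProtocolTemplate = HYPERCAPNIA,
    noise_pct: float = 0.2,
    mcav_base_cms: float = 60.0,
) -> tuple[PhysioTrace, PhysioTrace, PhysioTrace, PhysioTruth]:
    """Generate raw capnograph and Doppler waveforms with a known relation.

    The end-tidal plateau steps up by ``co2_step_mmhg`` during the CO2 phase
    with slow (~50 s) physiological edges, breathing oscillations at 0.25 Hz
    ride on top, and the Doppler velocities lead the end-tidal trace by
    ``lag_s`` through the affine relation ``slope * dPETCO2 + intercept``
    (as percent change from baseline velocity) with multiplicative 1-Hz
    cardiac pulsatility.  Returns (petco2, lmca, rmca, truth).
    """
    rng = np.random.default_rng(seed)
    on, off = protocol.intervention_window
    total = protocol.total_s

    # --- capnograph, 1 kHz ---
    fs_co2 = 1000.0
    t1 = np.arange(0.0, total, 1.0 / fs_co2)
    plateau = baseline_mmhg + trapezoid(t1, on + 2.0, off, 50.0, 50.0,
                                        co2_step_mmhg)
    breath = 1.0 / (1.0 + np.exp(-8.0 * np.sin(2.0 * np.pi * 0.25 * t1)))
    inspired = 3.0
    petco2_raw = inspired + (plateau - inspired) * breath \
        + rng.normal(0.0, 0.05, t1.size)
    petco2 = PhysioTrace(t1, petco2_raw, fs_co2, "PETCO2")

    # --- Doppler MCAV, 100 Hz, both sides ---
    # the velocities are tied to the *measurable* end-tidal trajectory: the
    # upper envelope of the capnograph (minus its baseline mean), advanced
    # by the lag, scaled through the affine relation
    from .physio import envelope as _envelope

    env = _envelope(petco2, "upper", min_cycle_s=2.0)
    dpet_env = env.values - env.values[env.time <= on].mean()
    fs_tcd = 100.0
    t2 = np.arange(0.0, total, 1.0 / fs_tcd)
    dpet_lead = np.interp(t2 + lag_s, env.time, dpet_env)   # advanced by lag
    gate = _smoothstep(t2, protocol.phases_s[0], 2.0)   # affine relation active
    pct = (slope * dpet_lead + intercept) * gate        # after the baseline
    traces = []
    for side, amp in (("LMCA", 0.10), ("RMCA", 0.12)):
        phase = rng.uniform(0.0, 2.0 * np.pi)
        ripple = 1.0 + amp * np.sin(2.0 * np.pi * 1.0 * t2 + phase)
        v = mcav_base_cms * (1.0 + pct / 100.0) * ripple \
            * (1.0 + rng.normal(0.0, noise_pct / 100.0, t2.size))
        traces.append(PhysioTrace(t2, v, fs_tcd, side))
    truth = PhysioTruth(lag_s=lag_s, slope=slope, intercept=intercept,
                        co2_step_mmhg=co2_step_mmhg,
                        baseline_mmhg=baseline_mmhg, seed=seed)
    return petco2, traces[0], traces[1], truth
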