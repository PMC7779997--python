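"""Layered field-autocorrelation model from photon histories and the
constrained multi-layer inverse fit for cerebral blood flow.

For a coarse history with ``Nt`` tissue layers the field autocorrelation at
a detector is

    G1(tau) = (1/Np) sum_n exp(-(k0^2/3) sum_i Y_ni <dr^2(tau)>_i)
                      * exp(-sum_i mu_a_i L_ni),

with ``<dr^2(tau)>_i = 6 BFi_i tau`` per layer, i.e. each photon decays at
the rate ``2 k0^2 sum_i Y_ni BFi_i`` and carries a static absorption weight
``exp(-sum_i mu_a_i L_ni)``.  Because absorption enters only through the
static weights, histories can be reweighted for new absorption settings
without re-running the transport.

The inverse fit holds the scalp-layer BFi to the value obtained from the
5-mm analytical fit at the same timepoint, the skull layer to
2e-8 mm^2/s, and (for 4-layer models) the CSF layer to a configurable
pseudo-diffusion value (default 5e-8 mm^2/s, the middle of the 1e-8 to
9e-8 range); the only free flow parameter is the brain BFi, with the
coherence factor beta per detector either profiled out in closed form or
held fixed (two-pass scheme for hypercapnia sessions).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from ._kernels import g1_eval
from .analytical import BETA_BOUNDS, FIT_WINDOW, _profiled_beta
from .data import G2Curve, PhotonHistorySet
from .optics import OpticalProperties

__all__ = [
    "SKULL_BFI",
    "CSF_BFI_DEFAULT",
    "g1_from_history",
    "absorption_weights",
    "reweight_absorption",
    "LayeredDCSModel",
    "LayeredDCSResults",
    "fit_layered_timecourse",
    "LayeredTimecourseFit",
]

#: Skull blood flow constraint, mm^2/s (about 1% of typical head BFi values).
SKULL_BFI = 2e-8
#: CSF pseudo-diffusion default, mm^2/s (centre of the 1e-8..9e-8 band
#: around the biological zero of the blood flow index).
CSF_BFI_DEFAULT = 5e-8

BRAIN_BFI_BOUNDS = (1e-12, 1e-3)
#: Absorption (mm^-1) for scalp / skull / CSF / brain used by the MC models.
MC_MU_A = {"scalp": 0.010, "skull": 0.033, "csf": 0.004, "brain": 0.023}


def layer_mu_a(n_layers: int) -> np.ndarray:
    """Default per-layer absorption for 2-, 3- or 4-layer models."""
    if n_layers == 2:
        names = ["scalp", "brain"]
    elif n_layers == 3:
        names = ["scalp", "skull", "brain"]
    elif n_layers == 4:
        names = ["scalp", "skull", "csf", "brain"]
    else:
        raise ValueError(f"unsupported layer count {n_layers}")
    return np.array([MC_MU_A[k] for k in names])


def absorption_weights(history: PhotonHistorySet, mu_a: np.ndarray) -> np.ndarray:
    """Static per-photon weights ``exp(-sum_i mu_a_i L_ni)``."""
    mu_a = np.asarray(mu_a, dtype=float)
    if np.any(mu_a < 0):
        raise ValueError("absorption coefficients must be non-negative")
    if mu_a.shape != (history.n_columns,):
        raise ValueError(
            f"mu_a must have one entry per layer ({history.n_columns}), "
            f"got {mu_a.shape}")
    return np.exp(-history.L.astype(np.float64) @ mu_a)


def reweight_absorption(weights: np.ndarray, history: PhotonHistorySet,
                        old_mu_a: np.ndarray, new_mu_a: np.ndarray) -> np.ndarray:
    """Update cached static weights for a change of absorption.

    Multiplies each photon's weight by ``exp(-(new - old) . L_n)``; identical
    to recomputing :func:`absorption_weights` at the new absorption.
    """
    old = np.asarray(old_mu_a, dtype=float)
    new = np.asarray(new_mu_a, dtype=float)
    if np.any(new < 0):
        raise ValueError("absorption coefficients must be non-negative")
    return weights * np.exp(-history.L.astype(np.float64) @ (new - old))


def g1_from_history(
    history: PhotonHistorySet,
    mu_a: np.ndarray,
    flows: np.ndarray,
    k0: float,
    tau: np.ndarray,
    detectors: Sequence[int] | None = None,
) -> dict[int, np.ndarray]:
    """Normalised g1(tau) per detector from a coarse photon history.

    ``flows`` is the per-layer BFi vector (mm^2/s) matching the history's
    layer count.  Photons are pooled within each detector annulus.
    """
    flows = np.asarray(flows, dtype=float)
    if np.any(flows < 0):
        raise ValueError("layer BFi values must be non-negative")
    if flows.shape != (history.n_columns,):
        raise ValueError(
            f"flows must have one entry per layer ({history.n_columns}), "
            f"got {flows.shape}")
    tau = np.asarray(tau, dtype=float)
    w_all = absorption_weights(history, mu_a)
    rate_all = 2.0 * k0 ** 2 * (history.Y.astype(np.float64) @ flows)
    out: dict[int, np.ndarray] = {}
    dets = range(len(history.annuli)) if detectors is None else detectors
    for det in dets:
        idx = history.detector_indices(det)
        if idx.size == 0:
            raise ValueError(f"detector {det} has no detected photons")
        w = w_all[idx]
        g1 = (w[:, None] * np.exp(-np.outer(rate_all[idx], tau))).sum(axis=0)
        out[det] = g1 / w.sum()
    return out


@dataclass
class LayeredDCSResults:
    """Constrained multi-layer fit at one timepoint."""

    brain_bfi: float
    beta: dict[float, float]           # rho -> beta
    residual: float
    converged: bool
    brain_bfi_stderr: float | None
    constraints: dict[str, float]
    rhos: tuple[float, ...]
    n_layers: int

    def summary(self) -> str:
        lines = [
            f"Layered MC DCS fit ({self.n_layers} layers)",
            "=" * 46,
            f"brain BFi (CBFi)     {self.brain_bfi:10.3e} mm^2/s",
        ]
        if self.brain_bfi_stderr is not None:
            lines.append(f"brain BFi std err    {self.brain_bfi_stderr:10.3e} mm^2/s")
        for name, val in self.constraints.items():
            lines.append(f"{name:<20s} {val:10.3e} mm^2/s (held)")
        for rho, b in self.beta.items():
            lines.append(f"beta @ {rho:4.0f} mm        {b:10.4f}")
        lines += [
            f"residual (SSR)       {self.residual:10.3e}",
            f"converged            {str(self.converged):>10s}",
        ]
        return "\n".join(lines)


class _DetectorBlock:
    """Precomputed arrays for one detector's photons and tau window."""

    __slots__ = ("rho", "tau", "y", "w", "rate_fixed", "y_brain")

    def __init__(self, rho, tau, y, w, rate_fixed, y_brain):
        self.rho = rho
        self.tau = tau
        self.y = y
        self.w = w
        self.rate_fixed = rate_fixed
        self.y_brain = y_brain


class LayeredDCSModel:
    """Constrained multi-layer model for one timepoint's multi-distance data.

    Parameters
    ----------
    curves : sequence of G2Curve
        Curves at one timepoint; separations are matched to the history's
        detector annuli.  At least one long separation (25/30 mm) must be
        present alongside the 5-mm scalp constraint.
    history : PhotonHistorySet
        Coarse (concatenated) history whose deepest layer is the brain.
    props : OpticalProperties
        Supplies the in-medium wavenumber k0.
    scalp_bfi : float
        Scalp-layer BFi held from the 5-mm analytical fit (mm^2/s).
    skull_bfi, csf_bfi : float
        Fixed skull / CSF flows for 3- and 4-layer models.
    mu_a : array, optional
        Per-layer absorption; defaults to the standard scalp/skull/CSF/brain
        values.
    """

    def __init__(
        self,
        curves: Sequence[G2Curve],
        history: PhotonHistorySet,
        props: OpticalProperties,
        scalp_bfi: float,
        skull_bfi: float = SKULL_BFI,
        csf_bfi: float = CSF_BFI_DEFAULT,
        mu_a: np.ndarray | None = None,
        fit_window: tuple[float, float] = FIT_WINDOW,
    ) -> None:
        if history.has_terminal:
            raise ValueError("fit requires a coarse (concatenated) history")
        if scalp_bfi < 0:
            raise ValueError("scalp BFi constraint must be non-negative")
        nl = history.n_columns
        if nl not in (2, 3, 4):
            raise ValueError(f"unsupported layer count {nl}")
        self.history = history
        self.props = props
        self.n_layers = nl
        self.mu_a = layer_mu_a(nl) if mu_a is None else np.asarray(mu_a, float)
        self.constraints = {"scalp_bfi": scalp_bfi}
        fixed = np.zeros(nl)
        fixed[0] = scalp_bfi
        if nl >= 3:
            fixed[1] = skull_bfi
            self.constraints["skull_bfi"] = skull_bfi
        if nl == 4:
            fixed[2] = csf_bfi
            self.constraints["csf_bfi"] = csf_bfi
        self.fixed_flows = fixed
        self.fit_window = fit_window

        k0 = props.k0
        self._k2 = 2.0 * k0 ** 2
        w_all = absorption_weights(history, self.mu_a)
        rate_fixed_all = self._k2 * (history.Y.astype(np.float64) @ fixed)
        y_brain_all = self._k2 * history.Y[:, -1].astype(np.float64)
        self.blocks: list[_DetectorBlock] = []
        if not curves:
            raise ValueError("no curves supplied")
        for c in curves:
            det = history.detector_for_rho(c.rho_mm, atol=0.51)
            idx = history.detector_indices(det)
            if idx.size == 0:
                raise ValueError(
                    f"detector at rho={c.rho_mm} mm has no detected photons")
            tau, g2 = c.window(*fit_window)
            if tau.size == 0:
                raise ValueError("no delay points inside the fit window")
            self.blocks.append(_DetectorBlock(
                c.rho_mm, tau, g2 - 1.0,
                np.ascontiguousarray(w_all[idx]),
                np.ascontiguousarray(rate_fixed_all[idx]),
                np.ascontiguousarray(y_brain_all[idx])))
        if not any(b.rho >= 20.0 for b in self.blocks):
            raise ValueError("at least one long separation (>= 20 mm) is required")

    def _g1_block(self, block: _DetectorBlock, brain_bfi: float) -> np.ndarray:
        return g1_eval(block.w, block.rate_fixed, block.y_brain,
                       block.tau, brain_bfi)

    def _objective(self, log_bfi: float,
                   fixed_beta: Mapping[float, float] | None) -> tuple[float, dict[float, float]]:
        b = 10.0 ** log_bfi
        ssr = 0.0
        betas: dict[float, float] = {}
        for blk in self.blocks:
            g1sq = self._g1_block(blk, b) ** 2
            if fixed_beta is None:
                beta = _profiled_beta(g1sq, blk.y, BETA_BOUNDS)
            else:
                beta = fixed_beta[blk.rho]
            r = blk.y - beta * g1sq
            ssr += float(np.dot(r, r))
            betas[blk.rho] = beta
        return ssr, betas

    def fit(self, beta_mode: str = "free",
            fixed_beta: Mapping[float, float] | None = None) -> LayeredDCSResults:
        """Fit the brain BFi (beta per detector free or fixed)."""
        if beta_mode == "fixed":
            if fixed_beta is None:
                raise ValueError("beta_mode='fixed' requires fixed_beta per rho")
        elif beta_mode != "free":
            raise ValueError(f"unknown beta_mode {beta_mode!r}")
        fb = fixed_beta if beta_mode == "fixed" else None
        lo, hi = math.log10(BRAIN_BFI_BOUNDS[0]), math.log10(BRAIN_BFI_BOUNDS[1])
        # physiological prior: brain flow a few-fold above scalp flow
        res = minimize_scalar(lambda x: self._objective(x, fb)[0],
                              bounds=(lo, hi), method="bounded",
                              options={"xatol": 1e-7})
        ssr, betas = self._objective(float(res.x), fb)
        stderr = self._stderr(float(res.x), fb, ssr)
        return LayeredDCSResults(
            brain_bfi=10.0 ** float(res.x),
            beta=betas, residual=ssr, converged=bool(res.success),
            brain_bfi_stderr=stderr, constraints=dict(self.constraints),
            rhos=tuple(b.rho for b in self.blocks), n_layers=self.n_layers,
        )

    def _stderr(self, x: float, fb, ssr: float) -> float | None:
        h = 5e-4
        fm = self._objective(x - h, fb)[0]
        fp = self._objective(x + h, fb)[0]
        d2 = (fp - 2.0 * ssr + fm) / h ** 2
        npts = sum(b.tau.size for b in self.blocks)
        nfree = 1 + (len(self.blocks) if fb is None else 0)
        dof = max(npts - nfree, 1)
        if d2 <= 0:
            return None
        var_x = 2.0 * (ssr / dof) / d2
        return 10.0 ** x * math.log(10.0) * math.sqrt(var_x)


@dataclass
class LayeredTimecourseFit:
    """Brain-BFi timecourse from the constrained layered fit."""

    table: pd.DataFrame           # timestamp_s, brain_bfi, scalp_bfi, beta_*, ...
    median_beta: dict[float, float]
    two_pass: bool

    @property
    def timestamps(self) -> np.ndarray:
        return self.table["timestamp_s"].to_numpy()

    @property
    def brain_bfi(self) -> np.ndarray:
        return self.table["brain_bfi"].to_numpy()

    def relative_change_pct(self, baseline_window: tuple[float, float]) -> np.ndarray:
        from .physio import relative_change

        mask = ((self.timestamps >= baseline_window[0])
                & (self.timestamps <= baseline_window[1]))
        return relative_change(self.brain_bfi, mask)

    def plot(self, ax=None, baseline_window=None, label="MC CBFi"):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        y = (self.relative_change_pct(baseline_window)
             if baseline_window is not None else self.brain_bfi)
        ax.plot(self.timestamps, y, label=label)
        ax.set_xlabel("time (s)")
        ax.set_ylabel("$\\Delta$rCBFi (%)" if baseline_window is not None
                      else "CBFi (mm$^2$/s)")
        ax.legend()
        return ax


def fit_layered_timecourse(
    curves: Sequence[G2Curve],
    history: PhotonHistorySet,
    props: OpticalProperties,
    scalp_bfi_series: Mapping[float, float],
    beta_policy: str = "two-pass",
    skull_bfi: float = SKULL_BFI,
    csf_bfi: float = CSF_BFI_DEFAULT,
    mu_a: np.ndarray | None = None,
    fit_window: tuple[float, float] = FIT_WINDOW,
) -> LayeredTimecourseFit:
    """Fit the brain-BFi timecourse across session bins.

    ``curves`` are the long-separation curves of a whole session (any number
    of separations per timepoint); ``scalp_bfi_series`` maps timestamps to
    the 5-mm analytical scalp constraint.  ``beta_policy`` is ``"two-pass"``
    (hypercapnia: refit with beta fixed at the per-detector median of pass 1)
    or ``"single"`` (pressure modulation).  Timepoints lacking a scalp
    constraint are flagged, not interpolated.
    """
    if beta_policy not in ("two-pass", "single"):
        raise ValueError(f"unknown beta policy {beta_policy!r}")
    by_time: dict[float, list[G2Curve]] = {}
    for c in curves:
        by_time.setdefault(c.timestamp_s, []).append(c)
    times = sorted(by_time)

    def one_pass(fixed_beta: Mapping[float, float] | None):
        rows = []
        betas_seen: dict[float, list[float]] = {}
        for t in times:
            scalp = scalp_bfi_series.get(t)
            if scalp is None:
                rows.append({"timestamp_s": t, "brain_bfi": np.nan,
                             "scalp_bfi": np.nan, "residual": np.nan,
                             "converged": False})
                continue
            model = LayeredDCSModel(by_time[t], history, props, scalp,
                                    skull_bfi=skull_bfi, csf_bfi=csf_bfi,
                                    mu_a=mu_a, fit_window=fit_window)
            if fixed_beta is None:
                fit = model.fit(beta_mode="free")
            else:
                fit = model.fit(beta_mode="fixed", fixed_beta=fixed_beta)
            row = {"timestamp_s": t, "brain_bfi": fit.brain_bfi,
                   "scalp_bfi": scalp, "residual": fit.residual,
                   "converged": fit.converged}
            for rho, b in fit.beta.items():
                row[f"beta_rho{rho:g}"] = b
                betas_seen.setdefault(rho, []).append(b)
            rows.append(row)
        return pd.DataFrame(rows), betas_seen

    table, betas_seen = one_pass(None)
    med = {rho: float(np.median(v)) for rho, v in betas_seen.items()}
    two_pass = beta_policy == "two-pass"
    if two_pass and med:
        table, _ = one_pass(med)
    return LayeredTimecourseFit(table=table, median_beta=med, two_pass=two_pass)
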