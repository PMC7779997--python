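"""Semi-infinite homogeneous correlation-diffusion model and BFi fitting.

The field autocorrelation of multiply scattered coherent light in a
homogeneous semi-infinite medium is

    G1(rho, tau) ∝ exp(-K r1)/r1 - exp(-K r2)/r2,
    K^2 = 3 mu_a mu_s' + mu_s'^2 k0^2 alpha <dr^2(tau)>,
    <dr^2(tau)> = 6 BFi tau,

with the image-source distances ``r1 = sqrt(rho^2 + z0^2)`` and
``r2 = sqrt(rho^2 + (z0 + 2 zb)^2)`` built from the extrapolated-boundary
lengths.  The measured intensity autocorrelation follows from the Siegert
relation ``g2 = 1 + beta g1^2``.  The moving-scatterer fraction ``alpha``
is folded into the blood flow index: the fitted quantity is ``alpha Db``,
reported as BFi in mm^2/s.

Fitting uses a profiled objective: for any trial BFi the coherence factor
``beta`` that minimises the summed squared g2 residual has the closed form
``beta* = sum((g2-1) g1^2) / sum(g1^4)`` (clipped to its bounds), so the fit
reduces to a bounded one-dimensional minimisation over log10(BFi).  This is
the same optimum as a joint bounded least-squares over (BFi, beta) but is
considerably more robust and fast enough for grid searches.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import minimize_scalar

from .data import G2Curve
from .optics import OpticalProperties, extrapolation_lengths

__all__ = [
    "g1_semi_infinite",
    "g2_siegert",
    "SemiInfiniteDCSModel",
    "SemiInfiniteDCSResults",
    "fit_semi_infinite",
    "fit_timecourse_two_pass",
    "TimecourseFit",
]

FIT_WINDOW = (1e-6, 1e-2)      # s; full decay region
BFI_BOUNDS = (1e-12, 1e-3)     # mm^2/s
BETA_BOUNDS = (1e-3, 0.6)
MIN_WINDOW_POINTS = 10


def g1_semi_infinite(
    rho_mm: float,
    tau: np.ndarray,
    props: OpticalProperties,
    bfi: float,
    alpha: float = 1.0,
) -> np.ndarray:
    """Normalised field autocorrelation g1(tau) at separation ``rho_mm``.

    Normalised so that g1(0) = 1; for ``bfi == 0`` the curve is identically 1.
    """
    if rho_mm <= 0:
        raise ValueError("rho must be positive (source singularity at rho=0)")
    if bfi < 0:
        raise ValueError("BFi must be non-negative")
    tau = np.asarray(tau, dtype=float)
    z0, zb = extrapolation_lengths(props)
    r1 = math.hypot(rho_mm, z0)
    r2 = math.hypot(rho_mm, z0 + 2.0 * zb)
    k0 = props.k0

    def unnorm(t: np.ndarray) -> np.ndarray:
        ksq = 3.0 * props.mu_a * props.mu_sp \
            + props.mu_sp ** 2 * k0 ** 2 * alpha * 6.0 * bfi * t
        k = np.sqrt(ksq)
        return np.exp(-k * r1) / r1 - np.exp(-k * r2) / r2

    g0 = unnorm(np.zeros(1))[0]
    return unnorm(tau) / g0


def g2_siegert(g1: np.ndarray, beta: float) -> np.ndarray:
    """Siegert relation ``g2 = 1 + beta g1^2``."""
    if not 0.0 <= beta <= 1.0:
        raise ValueError(f"beta must be in [0, 1], got {beta}")
    return 1.0 + beta * np.asarray(g1, dtype=float) ** 2


def _profiled_beta(g1sq: np.ndarray, y: np.ndarray,
                   bounds: tuple[float, float]) -> float:
    denom = float(np.dot(g1sq, g1sq))
    if denom <= 0:
        return bounds[0]
    return float(np.clip(np.dot(y, g1sq) / denom, *bounds))


@dataclass
class SemiInfiniteDCSResults:
    """Fit results for one g2 curve under the semi-infinite model."""

    bfi: float
    beta: float
    residual: float            # sum of squared g2 residuals over the window
    converged: bool
    bfi_stderr: float | None
    curve: G2Curve
    props: OpticalProperties
    fixed_beta: bool = False
    n_points: int = 0

    def predict(self, tau: np.ndarray | None = None) -> np.ndarray:
        tau = self.curve.tau if tau is None else np.asarray(tau, float)
        g1 = g1_semi_infinite(self.curve.rho_mm, tau, self.props, self.bfi)
        return g2_siegert(g1, self.beta)

    def summary(self) -> str:
        lines = [
            "Semi-infinite DCS fit",
            "=" * 42,
            f"rho                 {self.curve.rho_mm:10.1f} mm",
            f"BFi                 {self.bfi:10.3e} mm^2/s",
        ]
        if self.bfi_stderr is not None:
            lines.append(f"BFi std err         {self.bfi_stderr:10.3e} mm^2/s")
        lines += [
            f"beta                {self.beta:10.4f}" + ("  (fixed)" if self.fixed_beta else ""),
            f"residual (SSR)      {self.residual:10.3e}",
            f"n tau points        {self.n_points:10d}",
            f"converged           {str(self.converged):>10s}",
        ]
        return "\n".join(lines)


class SemiInfiniteDCSModel:
    """Semi-infinite homogeneous model for a single autocorrelation curve.

    Parameters
    ----------
    curve : G2Curve
        Measured curve; fitting is restricted to ``fit_window``.
    props : OpticalProperties
        Assumed bulk optical properties of the medium.
    fit_window : (float, float)
        Delay-time window in seconds, default [1e-6, 1e-2] covering the
        whole decay region.
    """

    def __init__(
        self,
        curve: G2Curve,
        props: OpticalProperties,
        fit_window: tuple[float, float] = FIT_WINDOW,
    ) -> None:
        self.curve = curve
        self.props = props
        self.fit_window = fit_window
        self._tau, self._g2 = curve.window(*fit_window)
        if self._tau.size == 0:
            raise ValueError("no delay points inside the fit window")
        if self._tau.size < MIN_WINDOW_POINTS:
            raise ValueError(
                f"need >= {MIN_WINDOW_POINTS} delay points in the fit window, "
                f"got {self._tau.size}")

    def _objective(self, log_bfi: float, fixed_beta: float | None) -> tuple[float, float]:
        g1 = g1_semi_infinite(self.curve.rho_mm, self._tau, self.props, 10.0 ** log_bfi)
        g1sq = g1 * g1
        y = self._g2 - 1.0
        beta = fixed_beta if fixed_beta is not None \
            else _profiled_beta(g1sq, y, BETA_BOUNDS)
        r = y - beta * g1sq
        return float(np.dot(r, r)), beta

    def fit(self, fixed_beta: float | None = None) -> SemiInfiniteDCSResults:
        """Fit BFi (and beta unless ``fixed_beta`` is given)."""
        if fixed_beta is not None and not 0.0 <= fixed_beta <= 1.0:
            raise ValueError("fixed_beta must be in [0, 1]")
        lo, hi = math.log10(BFI_BOUNDS[0]), math.log10(BFI_BOUNDS[1])
        res = minimize_scalar(
            lambda x: self._objective(x, fixed_beta)[0],
            bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-7},
        )
        ssr, beta = self._objective(res.x, fixed_beta)
        bfi = 10.0 ** float(res.x)
        converged = bool(res.success) and beta > BETA_BOUNDS[0] * 1.0001
        stderr = self._bfi_stderr(float(res.x), fixed_beta, ssr)
        return SemiInfiniteDCSResults(
            bfi=bfi, beta=beta, residual=ssr, converged=converged,
            bfi_stderr=stderr, curve=self.curve, props=self.props,
            fixed_beta=fixed_beta is not None, n_points=self._tau.size,
        )

    def _bfi_stderr(self, x: float, fixed_beta: float | None,
                    ssr: float) -> float | None:
        """Delta-method standard error from the curvature of the profile SSR."""
        h = 5e-4
        try:
            fm = self._objective(x - h, fixed_beta)[0]
            f0 = ssr
            fp = self._objective(x + h, fixed_beta)[0]
        except ValueError:
            return None
        d2 = (fp - 2.0 * f0 + fm) / h ** 2
        dof = max(self._tau.size - (1 if fixed_beta is not None else 2), 1)
        if d2 <= 0:
            return None
        var_x = 2.0 * (ssr / dof) / d2
        return 10.0 ** x * math.log(10.0) * math.sqrt(var_x)


def fit_semi_infinite(
    curve: G2Curve,
    props: OpticalProperties,
    fit_beta: bool = True,
    fixed_beta: float | None = None,
    fit_window: tuple[float, float] = FIT_WINDOW,
) -> SemiInfiniteDCSResults:
    """Convenience wrapper: build the model and fit one curve."""
    if not fit_beta and fixed_beta is None:
        raise ValueError("fixed_beta must be supplied when fit_beta=False")
    return SemiInfiniteDCSModel(curve, props, fit_window).fit(
        fixed_beta=None if fit_beta else fixed_beta)


@dataclass
class TimecourseFit:
    """Per-detector BFi/beta timecourses from a (possibly two-pass) fit."""

    timestamps: dict[float, np.ndarray]          # rho -> times
    bfi: dict[float, np.ndarray]                 # rho -> BFi(t)
    beta: dict[float, np.ndarray]                # rho -> beta(t)
    converged: dict[float, np.ndarray]           # rho -> flags
    median_beta: dict[float, float] = field(default_factory=dict)
    two_pass: bool = False

    def series(self, rho: float) -> tuple[np.ndarray, np.ndarray]:
        return self.timestamps[rho], self.bfi[rho]


def fit_timecourse_two_pass(
    curves_by_detector: Mapping[float, Sequence[G2Curve]],
    props: OpticalProperties,
    two_pass: bool = True,
    fit_window: tuple[float, float] = FIT_WINDOW,
) -> TimecourseFit:
    """Fit BFi(t), beta(t) per detector with the optional two-pass beta scheme.

    Pass 1 fits (BFi, beta) at every timepoint.  When ``two_pass`` is true
    (used for hypercapnia sessions, where beta is stable), BFi is re-fitted
    with beta held at the per-detector median of pass 1; pressure-modulation
    sessions use the single-pass fit (beta moves under probe pressure).
    """
    out = TimecourseFit({}, {}, {}, {}, {}, two_pass=two_pass)
    for rho, curves in curves_by_detector.items():
        if len(curves) < 3:
            raise ValueError(
                f"need >= 3 timepoints per detector for a timecourse fit "
                f"(rho={rho} mm has {len(curves)})")
        curves = sorted(curves, key=lambda c: c.timestamp_s)
        first = [SemiInfiniteDCSModel(c, props, fit_window).fit() for c in curves]
        betas = np.array([f.beta for f in first])
        med_beta = float(np.median(betas))
        out.median_beta[rho] = med_beta
        if two_pass:
            fits = [SemiInfiniteDCSModel(c, props, fit_window).fit(fixed_beta=med_beta)
                    for c in curves]
        else:
            fits = first
        out.timestamps[rho] = np.array([c.timestamp_s for c in curves])
        out.bfi[rho] = np.array([f.bfi for f in fits])
        out.beta[rho] = np.array([f.beta for f in fits])
        out.converged[rho] = np.array([f.converged for f in fits])
    return out
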