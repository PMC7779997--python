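"""Core in-memory containers: intensity-autocorrelation curves and photon
histories.

``G2Curve`` carries one measured (or synthesised) normalised intensity
autocorrelation ``g2(tau)`` at a single source-detector separation and
timepoint.  ``PhotonHistorySet`` carries the per-detected-photon, per-layer
pathlengths ``L`` and accumulated momentum transfers ``Y`` produced by the
Monte Carlo transport step, which are the sufficient statistics for the
layered field-autocorrelation model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any, Sequence

import numpy as np

__all__ = ["G2Curve", "PhotonHistorySet", "average_curves"]

HISTORY_SCHEMA_VERSION = 1


@dataclass
class G2Curve:
    """Normalised intensity autocorrelation at one separation and timepoint.

    Parameters
    ----------
    tau : array
        Delay-time grid in seconds, strictly increasing.
    g2 : array
        Normalised intensity autocorrelation values (dimensionless, finite).
    rho_mm : float
        Source-detector separation in mm (> 0).
    integration_time_s : float
        Correlator integration time used to form the curve.
    count_rate_hz : float, optional
        Detected photon count rate, used by measurement screening.
    timestamp_s : float
        Time of the bin centre from session start.
    """

    tau: np.ndarray
    g2: np.ndarray
    rho_mm: float
    integration_time_s: float = 1.0
    count_rate_hz: float | None = None
    timestamp_s: float = 0.0

    def __post_init__(self) -> None:
        self.tau = np.asarray(self.tau, dtype=float)
        self.g2 = np.asarray(self.g2, dtype=float)
        if self.tau.ndim != 1 or self.tau.shape != self.g2.shape:
            raise ValueError("tau and g2 must be 1-d arrays of equal length")
        if self.tau.size >= 2 and not np.all(np.diff(self.tau) > 0):
            raise ValueError("tau grid must be strictly increasing")
        if not np.all(np.isfinite(self.g2)):
            raise ValueError("g2 values must be finite")
        if self.rho_mm <= 0:
            raise ValueError(f"rho must be positive, got {self.rho_mm}")

    def window(self, tau_min: float, tau_max: float) -> tuple[np.ndarray, np.ndarray]:
        """Return (tau, g2) restricted to the closed window [tau_min, tau_max]."""
        mask = (self.tau >= tau_min) & (self.tau <= tau_max)
        return self.tau[mask], self.g2[mask]


def average_curves(curves: Sequence[G2Curve]) -> G2Curve:
    """Average bundled-fibre curves recorded at the same separation.

    Curves must share the same tau grid and rho; g2 values are averaged and
    count rates summed (bundled fibres feed one logical detector).
    """
    if not curves:
        raise ValueError("no curves to average")
    first = curves[0]
    for c in curves[1:]:
        if c.tau.shape != first.tau.shape or not np.allclose(c.tau, first.tau):
            raise ValueError("curves must share a common tau grid")
        if c.rho_mm != first.rho_mm:
            raise ValueError("curves must share the same separation")
    g2 = np.mean([c.g2 for c in curves], axis=0)
    rates = [c.count_rate_hz for c in curves if c.count_rate_hz is not None]
    return G2Curve(
        tau=first.tau.copy(),
        g2=g2,
        rho_mm=first.rho_mm,
        integration_time_s=first.integration_time_s,
        count_rate_hz=float(np.sum(rates)) if rates else None,
        timestamp_s=first.timestamp_s,
    )


@dataclass
class PhotonHistorySet:
    """Per-detected-photon, per-layer pathlength and momentum transfer.

    ``L[n, i]`` is the pathlength (mm) of photon ``n`` in layer ``i`` and
    ``Y[n, i]`` its accumulated momentum transfer ``sum(1 - cos(theta))``
    over the scattering events in that layer.  ``detector_id[n]`` indexes
    into ``annuli`` (detector annulus centres/half-widths, mm).

    A *fine* history (``has_terminal=True``) has one column per 1-mm fine
    layer plus a trailing column for the semi-infinite terminal medium; a
    *coarse* history produced by layer concatenation has one column per
    tissue layer and no terminal column.
    """

    L: np.ndarray
    Y: np.ndarray
    detector_id: np.ndarray
    annuli: list[tuple[float, float]]
    photons_launched: int
    seed: int
    fine_layer_thickness_mm: float = 1.0
    has_terminal: bool = True
    geometry_hash: str = ""
    layer_groups: tuple[int, ...] | None = None
    version: int = HISTORY_SCHEMA_VERSION
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.L = np.asarray(self.L)
        self.Y = np.asarray(self.Y)
        self.detector_id = np.asarray(self.detector_id, dtype=np.int32)
        if self.L.shape != self.Y.shape:
            raise ValueError("L and Y must have the same shape")
        if self.L.ndim != 2:
            raise ValueError("L and Y must be 2-d (photons x layers)")
        if self.detector_id.shape[0] != self.L.shape[0]:
            raise ValueError("detector_id length must match photon count")

    @property
    def n_photons(self) -> int:
        return self.L.shape[0]

    @property
    def n_columns(self) -> int:
        return self.L.shape[1]

    @property
    def n_layers(self) -> int:
        """Number of tissue layers (terminal medium counted with the last)."""
        return self.n_columns - 1 if self.has_terminal else self.n_columns

    def detector_indices(self, detector: int) -> np.ndarray:
        return np.nonzero(self.detector_id == detector)[0]

    def detector_for_rho(self, rho_mm: float, atol: float = 1e-6) -> int:
        """Detector id whose annulus centre matches ``rho_mm``."""
        for k, (centre, _hw) in enumerate(self.annuli):
            if abs(centre - rho_mm) <= atol:
                return k
        raise ValueError(f"no detector annulus centred at rho={rho_mm} mm "
                         f"(available: {[a[0] for a in self.annuli]})")

    def select_photons(self, index: np.ndarray) -> "PhotonHistorySet":
        return replace(
            self,
            L=self.L[index],
            Y=self.Y[index],
            detector_id=self.detector_id[index],
            meta=dict(self.meta, subset_of=self.n_photons),
        )

    def subsample(self, per_detector: int, seed: int) -> "PhotonHistorySet":
        """Randomly keep at most ``per_detector`` photons per detector.

        Used to bound the cost of grid fits; the subsample is reproducible
        for a fixed seed.
        """
        rng = np.random.default_rng(seed)
        keep: list[np.ndarray] = []
        for k in range(len(self.annuli)):
            idx = self.detector_indices(k)
            if idx.size > per_detector:
                idx = rng.choice(idx, size=per_detector, replace=False)
                idx.sort()
            keep.append(idx)
        return self.select_photons(np.concatenate(keep))
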