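"""Layered-medium Monte Carlo photon transport.

One transport run through a finely layered medium (1-mm fine layers by
default) records, for every detected photon, the pathlength and accumulated
momentum transfer per fine layer.  Because scattering is uniform across
layers in the default configuration and absorption is applied only during
post-processing, a single photon history can be concatenated into any
coarse layering (scalp / skull / [CSF /] brain) and reweighted for any
absorption setting — one simulation serves the whole model grid.

Two geometries are provided: a plane-parallel slab (21 fine layers over a
semi-infinite terminal medium) and a concentric-spherical-shell surrogate
for a curved head (22 fine layers on an 80-mm-radius sphere), which captures
surface curvature while remaining rotationally symmetric so that annular
detectors can pool photons efficiently.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from ._kernels import transport_shell, transport_slab
from .data import PhotonHistorySet

__all__ = [
    "LayeredGeometry",
    "McConfig",
    "simulate",
    "concatenate_layers",
    "build_model_variants",
    "two_layer_plans",
    "three_layer_plans",
    "four_layer_plans",
]

DEFAULT_ANNULI = [(5.0, 1.0), (25.0, 1.0), (30.0, 1.0)]


@dataclass(frozen=True)
class LayeredGeometry:
    """Fine-layered medium for the transport step.

    Parameters
    ----------
    kind : {"slab", "shell"}
        Plane-parallel slab or concentric-spherical-shell (curved) geometry.
    n_fine_layers : int
        Number of fine layers above the semi-infinite terminal medium
        (21 for the slab, 22 for the shell by default).
    fine_layer_thickness_mm : float
        Fine layer thickness, default 1 mm.
    mu_s : float or sequence
        Reduced scattering coefficient(s) in mm^-1; a scalar applies to all
        fine layers and the terminal medium, a sequence must have
        ``n_fine_layers + 1`` entries (terminal last).
    n_tissue, n_external : float
        Refractive indices for the Fresnel surface boundary.
    shell_outer_radius_mm : float
        Outer radius of the shell geometry (ignored for slabs).
    domain_depth_mm, domain_radius_mm : float
        Absorbing bounds terminating deep or far-wandering photons.
    """

    kind: str = "slab"
    n_fine_layers: int = 21
    fine_layer_thickness_mm: float = 1.0
    mu_s: float | tuple[float, ...] = 0.85
    n_tissue: float = 1.37
    n_external: float = 1.0
    shell_outer_radius_mm: float = 80.0
    domain_depth_mm: float = 60.0
    domain_radius_mm: float = 70.0

    def __post_init__(self) -> None:
        if self.kind not in ("slab", "shell"):
            raise ValueError(f"unknown geometry kind {self.kind!r}")
        if self.n_fine_layers < 1:
            raise ValueError("need at least one fine layer")
        if self.fine_layer_thickness_mm <= 0:
            raise ValueError("fine layer thickness must be positive")
        if self.kind == "shell":
            depth = self.n_fine_layers * self.fine_layer_thickness_mm
            if self.shell_outer_radius_mm <= depth:
                raise ValueError("shell outer radius must exceed the layered depth")

    def mu_s_array(self) -> np.ndarray:
        n = self.n_fine_layers + 1
        arr = np.broadcast_to(np.asarray(self.mu_s, dtype=float), (n,)).copy() \
            if np.ndim(self.mu_s) else np.full(n, float(self.mu_s))
        if arr.shape != (n,):
            raise ValueError(f"mu_s must be scalar or length {n} (fine layers + terminal)")
        if np.any(arr <= 0):
            raise ValueError("all scattering coefficients must be positive")
        return arr

    def content_hash(self) -> str:
        key = repr((self.kind, self.n_fine_layers, self.fine_layer_thickness_mm,
                    tuple(np.round(self.mu_s_array(), 12)), self.n_tissue,
                    self.n_external, self.shell_outer_radius_mm,
                    self.domain_depth_mm, self.domain_radius_mm))
        return hashlib.md5(key.encode()).hexdigest()[:16]


@dataclass(frozen=True)
class McConfig:
    """Transport run configuration."""

    photons_launched: int = 10_000_000
    rng_seed: int = 0
    annuli: tuple[tuple[float, float], ...] = tuple(DEFAULT_ANNULI)
    max_total_pathlength_mm: float = 1200.0

    def __post_init__(self) -> None:
        if self.photons_launched <= 0:
            raise ValueError("photons_launched must be positive")
        edges = sorted((c - hw, c + hw) for c, hw in self.annuli)
        for (lo1, hi1), (lo2, hi2) in zip(edges, edges[1:]):
            if hi1 > lo2:
                raise ValueError("detector annuli must not overlap")


_CHUNK = 1_000_000


def simulate(geometry: LayeredGeometry, config: McConfig) -> PhotonHistorySet:
    """Run the transport simulation and collect the photon history.

    Deterministic for a fixed configuration: the run is processed in fixed
    chunks, each seeded from ``config.rng_seed`` and its chunk index.
    """
    mus = geometry.mu_s_array()
    dz = geometry.fine_layer_thickness_mm
    n_fine = geometry.n_fine_layers
    ann = np.asarray(config.annuli, dtype=float)
    ann_lo = ann[:, 0] - ann[:, 1]
    ann_hi = ann[:, 0] + ann[:, 1]
    if np.any(ann_lo < 0):
        raise ValueError("annulus extends below zero separation")

    L_parts: list[np.ndarray] = []
    Y_parts: list[np.ndarray] = []
    det_parts: list[np.ndarray] = []
    remaining = config.photons_launched
    chunk_idx = 0
    while remaining > 0:
        n = min(remaining, _CHUNK)
        seed = (config.rng_seed + 0x9E3779B1 * chunk_idx) % (2 ** 32)
        cap = max(20_000, n // 5)
        while True:
            L_out = np.zeros((cap, n_fine + 1), dtype=np.float32)
            Y_out = np.zeros((cap, n_fine + 1), dtype=np.float32)
            det_out = np.full(cap, -1, dtype=np.int32)
            if geometry.kind == "slab":
                count, overflow = transport_slab(
                    n, seed, mus, dz, n_fine, geometry.domain_depth_mm,
                    geometry.domain_radius_mm, geometry.n_tissue,
                    geometry.n_external, config.max_total_pathlength_mm,
                    ann_lo, ann_hi, L_out, Y_out, det_out)
            else:
                count, overflow = transport_shell(
                    n, seed, mus, dz, n_fine, geometry.domain_depth_mm,
                    geometry.shell_outer_radius_mm, geometry.n_tissue,
                    geometry.n_external, config.max_total_pathlength_mm,
                    ann_lo, ann_hi, L_out, Y_out, det_out)
            if overflow == 0:
                break
            cap = cap * 2 + overflow  # rerun the chunk with room for everything
        L_parts.append(L_out[:count])
        Y_parts.append(Y_out[:count])
        det_parts.append(det_out[:count])
        remaining -= n
        chunk_idx += 1

    L = np.concatenate(L_parts) if L_parts else np.zeros((0, n_fine + 1), np.float32)
    Y = np.concatenate(Y_parts) if Y_parts else np.zeros((0, n_fine + 1), np.float32)
    det = np.concatenate(det_parts) if det_parts else np.zeros(0, np.int32)
    history = PhotonHistorySet(
        L=L, Y=Y, detector_id=det,
        annuli=[tuple(a) for a in config.annuli],
        photons_launched=config.photons_launched,
        seed=config.rng_seed,
        fine_layer_thickness_mm=dz,
        has_terminal=True,
        geometry_hash=geometry.content_hash(),
        meta={"kind": geometry.kind},
    )
    if history.n_photons == 0:
        import warnings

        warnings.warn("no photons detected (check scattering/annuli settings)")
    return history


def concatenate_layers(history: PhotonHistorySet,
                       groups: Sequence[int]) -> PhotonHistorySet:
    """Sum fine-layer columns into coarse tissue layers.

    ``groups`` are fine-layer counts (mm at the default thickness) summing to
    the number of fine layers; for a fine history, the terminal medium is
    folded into the last group.  Per-photon totals of L and Y are preserved
    exactly.
    """
    groups = tuple(int(g) for g in groups)
    if any(g <= 0 for g in groups):
        raise ValueError("group sizes must be positive")
    n_units = history.n_layers
    if sum(groups) != n_units:
        raise ValueError(
            f"group sizes {groups} sum to {sum(groups)}, expected {n_units}")
    edges = np.cumsum((0,) + groups)
    ncols = history.n_columns
    L = np.empty((history.n_photons, len(groups)), dtype=np.float64)
    Y = np.empty_like(L)
    for j in range(len(groups)):
        lo, hi = edges[j], edges[j + 1]
        if j == len(groups) - 1:
            hi = ncols  # terminal column (if any) joins the deepest layer
        L[:, j] = history.L[:, lo:hi].sum(axis=1, dtype=np.float64)
        Y[:, j] = history.Y[:, lo:hi].sum(axis=1, dtype=np.float64)
    return replace(
        history, L=L, Y=Y, detector_id=history.detector_id.copy(),
        has_terminal=False, layer_groups=groups,
    )


def two_layer_plans(max_extracerebral_mm: int = 18) -> list[tuple[int, ...]]:
    """Extracerebral thickness 1..18 mm -> 18 two-layer plans."""
    return [(e,) for e in range(1, max_extracerebral_mm + 1)]


def three_layer_plans(scalp_range: Iterable[int] = range(1, 8),
                      skull_range: Iterable[int] = range(4, 14)) -> list[tuple[int, ...]]:
    """All scalp (1-7 mm) x skull (4-13 mm) combinations -> 70 plans."""
    return [(s, k) for s in scalp_range for k in skull_range]


def four_layer_plans(base_combo: tuple[int, int],
                     csf_mm: Iterable[int] = (1, 2)) -> list[tuple[int, ...]]:
    """CSF layers carved out of the skull of a chosen three-layer combo."""
    scalp, skull = base_combo
    plans = []
    for c in csf_mm:
        if c >= skull:
            raise ValueError(f"CSF thickness {c} mm leaves no skull (skull={skull} mm)")
        plans.append((scalp, skull - c, c))
    return plans


def _plan_to_groups(plan: tuple[int, ...], n_fine: int) -> tuple[int, ...]:
    used = sum(plan)
    if used >= n_fine:
        raise ValueError(
            f"thickness combination {plan} uses {used} mm, exceeding the "
            f"{n_fine} available fine layers (brain layer would be empty)")
    return plan + (n_fine - used,)


def build_model_variants(
    history: PhotonHistorySet,
    plan_kind: str,
    base_combo: tuple[int, int] | None = None,
) -> dict[tuple[int, ...], PhotonHistorySet]:
    """Concatenate one fine history into every model of a thickness grid.

    ``plan_kind`` is ``"2layer"`` (18 variants), ``"3layer"`` (70 variants)
    or ``"4layer"`` (CSF carved from the skull of ``base_combo``).  Keys are
    the extracerebral thickness combinations in mm; values are coarse
    histories whose deepest layer is the brain.
    """
    if not history.has_terminal:
        raise ValueError("model variants must be built from a fine history")
    if plan_kind in ("2layer", "2L"):
        plans = two_layer_plans()
    elif plan_kind in ("3layer", "3L"):
        plans = three_layer_plans()
    elif plan_kind in ("4layer", "4L"):
        if base_combo is None:
            raise ValueError("4-layer plans need a base (scalp, skull) combo")
        plans = four_layer_plans(base_combo)
    else:
        raise ValueError(f"unknown plan kind {plan_kind!r}")
    n_fine = history.n_layers
    return {plan: concatenate_layers(history, _plan_to_groups(plan, n_fine))
            for plan in plans}
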