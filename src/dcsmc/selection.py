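"""Thickness-grid enumeration and pressure-modulation model selection.

The layered fit needs scalp and skull thicknesses that are not directly
measurable without imaging.  The selection strategy runs the constrained
fit for every thickness combination of a model grid on a pressure-
modulation session (brief probe pressure occludes scalp flow while brain
flow is unaffected) and keeps the combinations for which (a) the fitted
brain flow stays most constant before, during and after the pressure
window, and (b) the baseline brain-to-scalp BFi ratio lies in the
physiological band 3-8.  The winner is the in-band candidate with the
smallest stability score (root-mean-square fractional deviation of CBFi
from its baseline mean).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .analytical import FIT_WINDOW, SemiInfiniteDCSModel
from .data import G2Curve, PhotonHistorySet
from .layered import CSF_BFI_DEFAULT, SKULL_BFI, LayeredDCSModel
from .optics import OpticalProperties
from .transport import build_model_variants

__all__ = [
    "ModelCandidate",
    "enumerate_grid",
    "pressure_stability_metric",
    "select_model",
    "evaluate_candidates",
    "GridEvaluation",
]

RATIO_RANGE = (3.0, 8.0)


@dataclass
class ModelCandidate:
    """A thickness combination with its selection metrics."""

    plan: tuple[int, ...]               # (scalp, skull[, csf]) or (extracerebral,)
    stability_metric: float | None = None
    baseline_ratio: float | None = None
    selected: bool = False

    @property
    def total_extracerebral_mm(self) -> int:
        return int(sum(self.plan))


def enumerate_grid(plan_kind: str,
                   base_combo: tuple[int, int] | None = None) -> list[ModelCandidate]:
    """Enumerate the 2-layer (18), 3-layer (70) or 4-layer candidate grids."""
    from .transport import four_layer_plans, three_layer_plans, two_layer_plans

    if plan_kind in ("2layer", "2L"):
        plans = two_layer_plans()
    elif plan_kind in ("3layer", "3L"):
        plans = three_layer_plans()
    elif plan_kind in ("4layer", "4L"):
        if base_combo is None:
            raise ValueError("4-layer grids need a base (scalp, skull) combo")
        plans = four_layer_plans(base_combo)
    else:
        raise ValueError(f"unknown plan kind {plan_kind!r}")
    return [ModelCandidate(plan=p) for p in plans]


def pressure_stability_metric(cbfi: np.ndarray,
                              baseline_mask: np.ndarray) -> float:
    """RMS fractional deviation of CBFi from its baseline mean.

    Zero for a perfectly flat timecourse; lower is more stable.  The mean is
    taken over the whole timecourse (baseline, pressure and recovery alike).
    """
    cbfi = np.asarray(cbfi, float)
    baseline_mask = np.asarray(baseline_mask, bool)
    if not baseline_mask.any():
        raise ValueError("empty baseline window")
    finite = np.isfinite(cbfi)
    if not finite.all():
        cbfi = cbfi[finite]
        baseline_mask = baseline_mask[finite]
        if not baseline_mask.any() or cbfi.size == 0:
            raise ValueError("no finite CBFi samples in the baseline window")
    base = cbfi[baseline_mask].mean()
    if base <= 0:
        raise ValueError("baseline CBFi mean must be positive")
    frac = cbfi / base - 1.0
    return float(np.sqrt(np.mean(frac ** 2)))


def select_model(
    candidates: Sequence[ModelCandidate],
    ratio_range: tuple[float, float] = RATIO_RANGE,
) -> tuple[ModelCandidate | None, dict]:
    """Pick the most pressure-stable candidate with a physiological ratio.

    Among candidates whose baseline brain-to-scalp ratio lies inside
    ``ratio_range``, returns the one with the smallest stability metric;
    ties break towards the smallest total extracerebral thickness (then the
    thinnest scalp) so the choice is order-independent.  If no candidate is
    in range, returns ``(None, diagnosis)`` — typically a sign of low brain
    sensitivity in the measurement.
    """
    if not candidates:
        raise ValueError("empty candidate list")
    lo, hi = ratio_range
    in_range = [c for c in candidates
                if c.baseline_ratio is not None
                and c.stability_metric is not None
                and np.isfinite(c.stability_metric)
                and lo <= c.baseline_ratio <= hi]
    if not in_range:
        ratios = [c.baseline_ratio for c in candidates if c.baseline_ratio is not None]
        diagnosis = {
            "selected": None,
            "reason": "no candidate with baseline brain-to-scalp ratio in "
                      f"[{lo}, {hi}]; possible low brain sensitivity",
            "n_candidates": len(candidates),
            "ratio_min": float(np.nanmin(ratios)) if ratios else None,
            "ratio_max": float(np.nanmax(ratios)) if ratios else None,
        }
        return None, diagnosis
    best = min(in_range, key=lambda c: (c.stability_metric,
                                        c.total_extracerebral_mm,
                                        c.plan))
    for c in candidates:
        c.selected = c is best
    return best, {"selected": best.plan, "stability_metric": best.stability_metric,
                  "baseline_ratio": best.baseline_ratio}


@dataclass
class GridEvaluation:
    """Full report of a grid evaluation on a pressure-modulation session."""

    candidates: list[ModelCandidate]
    selected: ModelCandidate | None
    diagnosis: dict
    scalp_bfi_series: dict[float, float] = field(default_factory=dict)

    def as_records(self) -> list[dict]:
        return [{"plan": list(c.plan),
                 "stability_metric": c.stability_metric,
                 "baseline_ratio": c.baseline_ratio,
                 "selected": c.selected} for c in self.candidates]


def evaluate_candidates(
    curves: Sequence[G2Curve],
    fine_history: PhotonHistorySet,
    props: OpticalProperties,
    plan_kind: str = "3layer",
    base_combo: tuple[int, int] | None = None,
    baseline_window: tuple[float, float] = (0.0, 20.0),
    ratio_range: tuple[float, float] = RATIO_RANGE,
    skull_bfi: float = SKULL_BFI,
    csf_bfi: float = CSF_BFI_DEFAULT,
    subsample_per_detector: int | None = 1500,
    prefilter_ratio: bool = True,
    fit_window: tuple[float, float] = FIT_WINDOW,
) -> GridEvaluation:
    """Fit every grid candidate on a pressure session and select the model.

    The 5-mm curves are fitted analytically (single pass, beta free) to
    obtain the scalp constraint per bin; every candidate's coarse history is
    then fitted across the session.  With ``prefilter_ratio`` the baseline
    bins are fitted first and candidates whose brain-to-scalp ratio falls
    outside ``ratio_range`` skip the rest of the timecourse (their
    stability metric is reported as NaN).  Detected photons may be
    subsampled per detector to bound the grid cost.
    """
    short = sorted((c for c in curves if c.rho_mm <= 10.0),
                   key=lambda c: c.timestamp_s)
    long_by_time: dict[float, list[G2Curve]] = {}
    for c in curves:
        if c.rho_mm > 10.0:
            long_by_time.setdefault(c.timestamp_s, []).append(c)
    if not short or not long_by_time:
        raise ValueError("session must contain 5-mm and long-separation curves")

    scalp_series: dict[float, float] = {}
    for c in short:
        scalp_series[c.timestamp_s] = SemiInfiniteDCSModel(c, props, fit_window).fit().bfi

    history = fine_history
    if subsample_per_detector is not None:
        history = history.subsample(subsample_per_detector,
                                    seed=fine_history.seed + 1)
    variants = build_model_variants(history, plan_kind, base_combo)

    times = sorted(long_by_time)
    t_arr = np.array(times)
    base_mask = (t_arr >= baseline_window[0]) & (t_arr <= baseline_window[1])
    base_times = [t for t, m in zip(times, base_mask) if m]
    rest_times = [t for t, m in zip(times, base_mask) if not m]
    scalp_base = np.mean([scalp_series[t] for t in base_times])

    def fit_at(t: float, variant: PhotonHistorySet) -> float:
        model = LayeredDCSModel(long_by_time[t], variant, props,
                                scalp_bfi=scalp_series[t],
                                skull_bfi=skull_bfi, csf_bfi=csf_bfi,
                                fit_window=fit_window)
        return model.fit(beta_mode="free").brain_bfi

    candidates: list[ModelCandidate] = []
    for plan, variant in variants.items():
        cand = ModelCandidate(plan=plan)
        brain_base = np.array([fit_at(t, variant) for t in base_times])
        cand.baseline_ratio = float(brain_base.mean() / scalp_base)
        in_range = ratio_range[0] <= cand.baseline_ratio <= ratio_range[1]
        if in_range or not prefilter_ratio:
            brain_rest = np.array([fit_at(t, variant) for t in rest_times])
            cbfi = np.empty(len(times))
            cbfi[base_mask] = brain_base
            cbfi[~base_mask] = brain_rest
            cand.stability_metric = pressure_stability_metric(cbfi, base_mask)
        else:
            cand.stability_metric = float("nan")
        candidates.append(cand)

    selected, diagnosis = select_model(candidates, ratio_range)
    return GridEvaluation(candidates=candidates, selected=selected,
                          diagnosis=diagnosis, scalp_bfi_series=scalp_series)
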