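"""End-to-end orchestration of the two measurement workflows.

A session is processed in the order the protocols are acquired: the
pressure-modulation measurement drives model selection (thickness grid +
stability/ratio criteria), after which the hypercapnia measurement is
fitted with the selected layered model to produce the cerebral blood flow
timecourse, alongside the per-detector analytical fits, the screening
report and (when a capnograph trace is supplied) the expected-Doppler
overlay.  Every output table carries the configuration hash and seeds so
that equal inputs reproduce byte-equal results.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .analytical import fit_timecourse_two_pass
from .config import config_hash, load_config
from .data import G2Curve, PhotonHistorySet
from .layered import fit_layered_timecourse
from .optics import OpticalProperties
from .physio import (PhysioTrace, process_petco2, relative_change,
                     screen_measurement, synthesize_etcd)
from .selection import evaluate_candidates
from .synth import HYPERCAPNIA, PRESSURE
from .transport import concatenate_layers

__all__ = ["run_workflow", "WorkflowError"]

log = logging.getLogger("dcsmc.workflow")


class WorkflowError(RuntimeError):
    """A stage-localised workflow failure with an actionable message."""

    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _split_by_rho(curves: Sequence[G2Curve]) -> dict[float, list[G2Curve]]:
    out: dict[float, list[G2Curve]] = {}
    for c in curves:
        out.setdefault(c.rho_mm, []).append(c)
    for v in out.values():
        v.sort(key=lambda c: c.timestamp_s)
    return out


def run_workflow(
    hypercapnia_curves: Sequence[G2Curve],
    fine_history: PhotonHistorySet,
    props: OpticalProperties,
    out_dir: str | Path,
    pressure_curves: Sequence[G2Curve] | None = None,
    thickness_override: tuple[int, int] | None = None,
    petco2: PhysioTrace | None = None,
    config: Mapping | None = None,
    config_overrides_path: str | Path | None = None,
) -> dict:
    """Run screening, selection and the layered CBFi fit; write result tables.

    Returns a dict with the key results and the paths written.  Raises
    :class:`WorkflowError` naming the failing stage.
    """
    cfg = dict(config) if config is not None else load_config(config_overrides_path)
    chash = config_hash(cfg)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    provenance = {"config_hash": chash,
                  "history_seed": int(fine_history.seed),
                  "history_photons": int(fine_history.photons_launched)}
    for key, val in cfg.items():
        log.info("config %s = %r", key, val)

    by_rho = _split_by_rho(hypercapnia_curves)
    if 5.0 not in by_rho:
        raise WorkflowError("analytical", "no 5-mm curves in the hypercapnia session")
    long_rhos = sorted(r for r in by_rho if r > 10.0)
    if not long_rhos:
        raise WorkflowError("analytical", "no long-separation curves present")

    # --- analytical fits (two-pass beta for hypercapnia) ---
    ana = fit_timecourse_two_pass(by_rho, props, two_pass=True)
    base_win = HYPERCAPNIA.baseline_window
    times5 = ana.timestamps[5.0]
    base_mask5 = (times5 >= base_win[0]) & (times5 <= base_win[1])
    ana_rows = {"timestamp_s": times5}
    for rho in sorted(by_rho):
        mask = (ana.timestamps[rho] >= base_win[0]) & (ana.timestamps[rho] <= base_win[1])
        ana_rows[f"bfi_rho{rho:g}"] = ana.bfi[rho]
        ana_rows[f"d_rbfi_pct_rho{rho:g}"] = relative_change(ana.bfi[rho], mask)
    ana_df = pd.DataFrame(ana_rows)
    ana_df.attrs.update(provenance)

    # --- screening ---
    rho_long = max(long_rhos)
    c30 = by_rho[rho_long][0]
    base5 = ana.bfi[5.0][base_mask5]
    cov = float(np.std(base5, ddof=1) / np.mean(base5)) if base5.size > 1 else 0.0
    screen = screen_measurement(
        count_rate_30mm_hz=c30.count_rate_hz or 0.0,
        baseline_cov=cov,
        time_s=times5,
        drbfi_5mm_pct=ana_df["d_rbfi_pct_rho5"].to_numpy(),
        drbfi_long_pct=ana_df[f"d_rbfi_pct_rho{rho_long:g}"].to_numpy(),
        co2_end_s=HYPERCAPNIA.intervention_window[1],
        min_count_rate_hz=cfg["screening"]["min_count_rate_hz"],
        max_baseline_cov=cfg["screening"]["max_baseline_cov"],
        scalp_drift_pct=cfg["screening"]["scalp_drift_pct"],
        persist_s=cfg["screening"]["persist_s"],
    )

    # --- model selection (pressure session) or explicit thickness ---
    selection_report: dict
    if thickness_override is not None:
        plan = tuple(int(x) for x in thickness_override)
        selection_report = {"selected": list(plan), "source": "override"}
    else:
        if pressure_curves is None:
            raise WorkflowError(
                "selection",
                "a layered fit needs layer thicknesses: provide a pressure-"
                "modulation session for model selection or an explicit "
                "thickness override (--scalp-mm/--skull-mm)")
        evaluation = evaluate_candidates(
            pressure_curves, fine_history, props,
            plan_kind="3layer",
            baseline_window=PRESSURE.baseline_window,
            ratio_range=tuple(cfg["selection"]["ratio_range"]),
            subsample_per_detector=cfg["selection"]["subsample_per_detector"])
        if evaluation.selected is None:
            raise WorkflowError("selection", evaluation.diagnosis["reason"])
        plan = evaluation.selected.plan
        selection_report = {"selected": list(plan), "source": "pressure-modulation",
                            "candidates": evaluation.as_records(),
                            "diagnosis": evaluation.diagnosis}

    # --- layered CBFi fit on the hypercapnia session ---
    n_fine = fine_history.n_layers
    groups = plan + (n_fine - sum(plan),)
    coarse = concatenate_layers(fine_history, groups)
    scalp_series = dict(zip(times5.tolist(), ana.bfi[5.0].tolist()))
    long_curves = [c for c in hypercapnia_curves if c.rho_mm > 10.0]
    mc = fit_layered_timecourse(
        long_curves, coarse, props, scalp_series, beta_policy="two-pass",
        skull_bfi=cfg["fitting"]["skull_bfi"], csf_bfi=cfg["fitting"]["csf_bfi"])
    mc_table = mc.table.copy()
    mc_table["d_rcbfi_pct"] = mc.relative_change_pct(base_win)

    # --- expected Doppler overlay ---
    etcd_df = None
    if petco2 is not None:
        dpet = process_petco2(petco2, baseline_window=base_win)
        etcd = synthesize_etcd(dpet.values,
                               slope=cfg["physio"]["etcd"]["slope"],
                               intercept=cfg["physio"]["etcd"]["intercept"])
        etcd_df = pd.DataFrame({"time_s": dpet.time, "dpetco2_mmhg": dpet.values,
                                "etcd_pct": etcd})

    # --- write outputs ---
    paths = {}
    header = f"# config_hash={chash} history_seed={fine_history.seed}\n"
    for name, df in [("analytical_fits.csv", ana_df), ("cbfi.csv", mc_table)] \
            + ([("etcd.csv", etcd_df)] if etcd_df is not None else []):
        p = out_dir / name
        with open(p, "w") as f:
            f.write(header)
            df.to_csv(f, index=False)
        paths[name] = str(p)
    for name, payload in [("selection.json", selection_report),
                          ("screening.json", {"passed": screen.passed,
                                              "flags": screen.flags,
                                              "reasons": screen.reasons,
                                              "baseline_cov": cov})]:
        p = out_dir / name
        with open(p, "w") as f:
            json.dump({"provenance": provenance, **payload}, f, indent=2)
        paths[name] = str(p)

    return {"plan": plan, "analytical": ana_df, "cbfi": mc_table,
            "screening": screen, "selection": selection_report,
            "etcd": etcd_df, "paths": paths, "config_hash": chash}
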