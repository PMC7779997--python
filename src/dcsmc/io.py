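"""Readers and writers for the package's file formats.

g2 sessions travel as long-format delimited tables (one row per delay
point) with an explicit header; photon histories as HDF5 containers with a
mandatory schema version; physiological traces as two-column delimited time
series; configuration and manifests as YAML.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd
import yaml

from .data import G2Curve, PhotonHistorySet, HISTORY_SCHEMA_VERSION
from .physio import PhysioTrace

__all__ = [
    "write_g2_table",
    "read_g2_table",
    "write_session_hdf5",
    "read_session_hdf5",
    "write_history",
    "read_history",
    "write_physio_trace",
    "read_physio_trace",
    "load_manifest",
]

G2_COLUMNS = ["timestamp_s", "rho_mm", "tau_s", "g2",
              "integration_time_s", "count_rate_hz"]


def write_g2_table(path: str | Path, curves: Sequence[G2Curve]) -> None:
    """Write curves to a long-format CSV with one row per delay point."""
    rows = []
    for c in curves:
        rate = np.nan if c.count_rate_hz is None else c.count_rate_hz
        for t, g in zip(c.tau, c.g2):
            rows.append((c.timestamp_s, c.rho_mm, t, g,
                         c.integration_time_s, rate))
    pd.DataFrame(rows, columns=G2_COLUMNS).to_csv(path, index=False)


def read_g2_table(path: str | Path) -> list[G2Curve]:
    """Read a long-format g2 CSV back into curves (grouped by time and rho)."""
    df = pd.read_csv(path)
    missing = [c for c in G2_COLUMNS[:5] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    curves = []
    for (ts, rho), grp in df.groupby(["timestamp_s", "rho_mm"], sort=True):
        tau = grp["tau_s"].to_numpy()
        if tau.size >= 2 and not np.all(np.diff(tau) > 0):
            bad = int(grp.index[np.argmin(np.diff(tau) > 0)]) + 2  # header row
            raise ValueError(
                f"{path}: non-monotone tau in curve (t={ts}, rho={rho}) "
                f"near file row {bad}")
        rate = grp["count_rate_hz"].iloc[0] if "count_rate_hz" in grp else np.nan
        curves.append(G2Curve(
            tau=tau, g2=grp["g2"].to_numpy(), rho_mm=float(rho),
            integration_time_s=float(grp["integration_time_s"].iloc[0]),
            count_rate_hz=None if pd.isna(rate) else float(rate),
            timestamp_s=float(ts)))
    return curves


def write_session_hdf5(path: str | Path, curves: Sequence[G2Curve]) -> None:
    """Write a whole session to a grouped HDF5 container.

    One group per (timestamp, rho) curve; complements the portable CSV
    format for large sessions.
    """
    with h5py.File(path, "w") as f:
        f.attrs["n_curves"] = len(curves)
        for i, c in enumerate(curves):
            g = f.create_group(f"curve_{i:05d}")
            g.attrs["timestamp_s"] = c.timestamp_s
            g.attrs["rho_mm"] = c.rho_mm
            g.attrs["integration_time_s"] = c.integration_time_s
            g.attrs["count_rate_hz"] = (np.nan if c.count_rate_hz is None
                                        else c.count_rate_hz)
            g.create_dataset("tau_s", data=c.tau)
            g.create_dataset("g2", data=c.g2)


def read_session_hdf5(path: str | Path) -> list[G2Curve]:
    curves = []
    with h5py.File(path, "r") as f:
        for name in sorted(f.keys()):
            g = f[name]
            rate = float(g.attrs["count_rate_hz"])
            curves.append(G2Curve(
                tau=g["tau_s"][...], g2=g["g2"][...],
                rho_mm=float(g.attrs["rho_mm"]),
                integration_time_s=float(g.attrs["integration_time_s"]),
                count_rate_hz=None if np.isnan(rate) else rate,
                timestamp_s=float(g.attrs["timestamp_s"])))
    return curves


def write_history(path: str | Path, history: PhotonHistorySet) -> None:
    """Write a photon history to an HDF5 container (schema-versioned)."""
    with h5py.File(path, "w") as f:
        f.attrs["version"] = history.version
        f.attrs["photons_launched"] = history.photons_launched
        f.attrs["seed"] = history.seed
        f.attrs["fine_layer_thickness_mm"] = history.fine_layer_thickness_mm
        f.attrs["has_terminal"] = history.has_terminal
        f.attrs["geometry_hash"] = history.geometry_hash
        f.attrs["annuli"] = json.dumps(history.annuli)
        if history.layer_groups is not None:
            f.attrs["layer_groups"] = json.dumps(list(history.layer_groups))
        f.attrs["meta"] = json.dumps(history.meta, default=str)
        f.create_dataset("L", data=history.L, compression="gzip", shuffle=True)
        f.create_dataset("Y", data=history.Y, compression="gzip", shuffle=True)
        f.create_dataset("detector_id", data=history.detector_id)


def read_history(path: str | Path) -> PhotonHistorySet:
    with h5py.File(path, "r") as f:
        version = int(f.attrs["version"])
        if version > HISTORY_SCHEMA_VERSION:
            raise ValueError(
                f"{path}: unsupported history schema version {version} "
                f"(this build reads <= {HISTORY_SCHEMA_VERSION})")
        groups = f.attrs.get("layer_groups")
        return PhotonHistorySet(
            L=f["L"][...], Y=f["Y"][...],
            detector_id=f["detector_id"][...],
            annuli=[tuple(a) for a in json.loads(f.attrs["annuli"])],
            photons_launched=int(f.attrs["photons_launched"]),
            seed=int(f.attrs["seed"]),
            fine_layer_thickness_mm=float(f.attrs["fine_layer_thickness_mm"]),
            has_terminal=bool(f.attrs["has_terminal"]),
            geometry_hash=str(f.attrs["geometry_hash"]),
            layer_groups=tuple(json.loads(groups)) if groups is not None else None,
            version=version,
            meta=json.loads(f.attrs["meta"]),
        )


def write_physio_trace(path: str | Path, trace: PhysioTrace) -> None:
    """Two-column delimited time series with a channel/units header."""
    df = pd.DataFrame({"time_s": trace.time, trace.channel or "value": trace.values})
    df.to_csv(path, index=False)


def read_physio_trace(path: str | Path, channel: str | None = None) -> PhysioTrace:
    df = pd.read_csv(path)
    if df.shape[1] < 2 or "time_s" not in df.columns:
        raise ValueError(f"{path}: expected columns time_s,<channel>")
    value_col = channel or [c for c in df.columns if c != "time_s"][0]
    time = df["time_s"].to_numpy(float)
    fs = 1.0 / float(np.median(np.diff(time))) if time.size > 1 else 1.0
    return PhysioTrace(time, df[value_col].to_numpy(float), fs, value_col)


def load_manifest(path: str | Path) -> dict:
    """Load a session manifest (YAML) and check that referenced files exist."""
    path = Path(path)
    with open(path) as f:
        manifest = yaml.safe_load(f)
    if not isinstance(manifest, dict):
        raise ValueError(f"{path}: manifest must be a mapping")
    files = manifest.get("files", {})
    for key, rel in files.items():
        p = path.parent / rel
        if not p.exists():
            raise FileNotFoundError(f"{path}: referenced {key} file missing: {p}")
    return manifest
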