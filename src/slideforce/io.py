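"""Delimited-text readers and writers for traces, scans and tracks.

All files are tab-separated with a header row; scalar metadata travels in
``# key = json-value`` comment lines at the top so a single text file is
self-describing.  Physical units are fixed: pN, nm, s, K.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
import yaml

from .friction import FVScan, FVSegment
from .motility import FilamentTrack
from .traces import ForceTrace

PathLike = Union[str, Path]


def _write_header(fh, meta: dict) -> None:
    for key, value in meta.items():
        fh.write(f"# {key} = {json.dumps(value)}\n")


def _read_header(path: Path) -> dict:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, raw = line[1:].partition("=")
            meta[key.strip()] = json.loads(raw.strip())
    return meta


def write_trace(trace: ForceTrace, path: PathLike) -> None:
    path = Path(path)
    cols = {"time_s": trace.time, "fx_pN": trace.force_x, "fy_pN": trace.force_y}
    if trace.stage_x is not None:
        cols["stage_x_nm"] = trace.stage_x
    if trace.stage_y is not None:
        cols["stage_y_nm"] = trace.stage_y
    meta = {"trap_stiffness_pN_per_nm": trace.trap_stiffness, **trace.metadata}
    with open(path, "w") as fh:
        _write_header(fh, meta)
        pd.DataFrame(cols).to_csv(fh, sep="\t", index=False, float_format="%.10g")


def read_trace(path: PathLike) -> ForceTrace:
    path = Path(path)
    meta = _read_header(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    k = meta.pop("trap_stiffness_pN_per_nm")
    return ForceTrace(
        time=df["time_s"].to_numpy(),
        force_x=df["fx_pN"].to_numpy(),
        force_y=df["fy_pN"].to_numpy(),
        trap_stiffness=k,
        stage_x=df["stage_x_nm"].to_numpy() if "stage_x_nm" in df else None,
        stage_y=df["stage_y_nm"].to_numpy() if "stage_y_nm" in df else None,
        metadata=meta,
    )


def write_scan(scan: FVScan, path: PathLike) -> None:
    rows = [
        {
            "mode": s.mode,
            "setpoint": s.setpoint,
            "response": s.response,
            "quality_weight": s.quality_weight,
            "duration_s": s.duration,
        }
        for s in scan.segments
    ]
    meta = {
        "pair_id": scan.pair_id,
        "unloaded_velocity_nm_s": scan.unloaded_velocity,
        **scan.metadata,
    }
    with open(Path(path), "w") as fh:
        _write_header(fh, meta)
        pd.DataFrame(rows).to_csv(fh, sep="\t", index=False, float_format="%.10g")


def read_scan(path: PathLike) -> FVScan:
    path = Path(path)
    meta = _read_header(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    segments = [
        FVSegment(
            mode=row["mode"],
            setpoint=float(row["setpoint"]),
            response=float(row["response"]),
            quality_weight=float(row["quality_weight"]),
            duration=float(row["duration_s"]),
        )
        for _, row in df.iterrows()
    ]
    return FVScan(
        segments=segments,
        unloaded_velocity=meta.pop("unloaded_velocity_nm_s"),
        pair_id=str(meta.pop("pair_id", "")),
        metadata=meta,
    )


def write_tracks(tracks: list[FilamentTrack], path: PathLike) -> None:
    """Long-format table: one row per (filament, frame)."""
    rows = []
    for tr in tracks:
        for t, p in zip(tr.frame_times, tr.positions):
            rows.append(
                {
                    "filament_id": tr.filament_id,
                    "frame_time_s": t,
                    "position_nm": p,
                    "length_nm": tr.filament_length,
                    "mode": tr.mode,
                }
            )
    pd.DataFrame(rows).to_csv(Path(path), sep="\t", index=False, float_format="%.10g")


def read_tracks(path: PathLike) -> list[FilamentTrack]:
    df = pd.read_csv(Path(path), sep="\t", comment="#")
    tracks = []
    for fid, grp in df.groupby("filament_id", sort=False):
        grp = grp.sort_values("frame_time_s")
        tracks.append(
            FilamentTrack(
                frame_times=grp["frame_time_s"].to_numpy(),
                positions=grp["position_nm"].to_numpy(),
                filament_length=float(grp["length_nm"].iloc[0]),
                mode=str(grp["mode"].iloc[0]),
                filament_id=str(fid),
            )
        )
    return tracks


def load_config(path: PathLike) -> dict:
    """Flat key-value run configuration (YAML)."""
    with open(Path(path)) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config file must contain a mapping")
    return cfg


def write_json(obj: dict, path: PathLike) -> None:
    def _default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(Path(path), "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_default)
        fh.write("\n")
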