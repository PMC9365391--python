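"""Readers and writers for the pipeline's on-disk formats.

Trajectories and event tables are plain CSV (comma-separated, header row,
dot decimal, UTF-8); kymographs are 16-bit grayscale TIFF with a JSON
sidecar carrying calibration metadata (never TIFF tags, for bit-exact
portability).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .simulate import BindingEventSet, ForceExtensionCurve, GroundTruth
from .tracking import Kymograph, Trajectory

__all__ = [
    "write_trajectories_csv",
    "read_trajectories_csv",
    "write_kymograph_tiff",
    "read_kymograph_tiff",
    "write_ground_truth_csv",
    "write_binding_events_csv",
    "read_binding_events_csv",
    "write_force_extension_csv",
    "read_force_extension_csv",
    "write_json",
]

FLOAT_FMT = "%.9g"


def write_trajectories_csv(path: str | Path, trajectories: list[Trajectory]) -> None:
    rows = []
    for k, tr in enumerate(trajectories):
        tid = tr.source or str(k)
        for frame, (t, x, flag) in enumerate(
            zip(tr.times_s, tr.positions_um, tr.interpolated)
        ):
            rows.append(
                {
                    "trace_id": tid,
                    "frame": frame,
                    "time_s": t,
                    "x_um": x,
                    "interpolated": int(flag),
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False, float_format=FLOAT_FMT)


def read_trajectories_csv(path: str | Path) -> list[Trajectory]:
    df = pd.read_csv(path)
    out: list[Trajectory] = []
    for tid, grp in df.groupby("trace_id", sort=False):
        grp = grp.sort_values("frame")
        t = grp["time_s"].to_numpy()
        dt = float(np.median(np.diff(t))) if len(t) > 1 else 1.0
        out.append(
            Trajectory(
                positions_um=grp["x_um"].to_numpy(),
                frame_interval_s=dt,
                t0_s=float(t[0]),
                source=str(tid),
                interpolated=grp["interpolated"].to_numpy().astype(bool),
            )
        )
    return out


def write_kymograph_tiff(
    path: str | Path, kymo: Kymograph, extra_meta: dict | None = None
) -> None:
    """16-bit TIFF (rows = pixels, columns = scan lines) + JSON sidecar."""
    path = Path(path)
    tifffile.imwrite(path, kymo.counts.astype(np.uint16))
    meta = {
        "pixel_size_um": kymo.pixel_size_um,
        "line_time_s": kymo.line_time_s,
        "n_pixels": kymo.n_pixels,
        "n_lines": kymo.n_lines,
    }
    if extra_meta:
        meta.update(extra_meta)
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def read_kymograph_tiff(path: str | Path) -> tuple[Kymograph, dict]:
    path = Path(path)
    counts = tifffile.imread(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    return (
        Kymograph(
            counts=counts,
            pixel_size_um=meta["pixel_size_um"],
            line_time_s=meta["line_time_s"],
        ),
        meta,
    )


def write_ground_truth_csv(path: str | Path, gt: GroundTruth) -> None:
    pd.DataFrame(
        {
            "frame": np.arange(gt.times_s.size),
            "time_s": gt.times_s,
            "x_um": gt.positions_um,
            "alive": gt.alive.astype(int),
        }
    ).to_csv(path, index=False, float_format=FLOAT_FMT)


def write_binding_events_csv(path: str | Path, events: BindingEventSet) -> None:
    pd.DataFrame(
        {
            "molecule_id": np.arange(events.t_first_s.size),
            "t_first_s": events.t_first_s,
            "first_censored": events.first_censored.astype(int),
            "dwell_s": events.dwell_s,
            "dwell_censored": events.dwell_censored.astype(int),
        }
    ).to_csv(path, index=False, float_format=FLOAT_FMT)


def read_binding_events_csv(
    path: str | Path, concentration_m: float, dna_length_bp: int
) -> BindingEventSet:
    df = pd.read_csv(path)
    return BindingEventSet(
        t_first_s=df["t_first_s"].to_numpy(),
        first_censored=df["first_censored"].to_numpy().astype(bool),
        dwell_s=df["dwell_s"].to_numpy(),
        dwell_censored=df["dwell_censored"].to_numpy().astype(bool),
        concentration_m=concentration_m,
        dna_length_bp=dna_length_bp,
    )


def write_force_extension_csv(path: str | Path, curve: ForceExtensionCurve) -> None:
    pd.DataFrame(
        {"force_pN": curve.force_pn, "distance_um": curve.distance_um}
    ).to_csv(path, index=False, float_format=FLOAT_FMT)


def read_force_extension_csv(path: str | Path) -> ForceExtensionCurve:
    df = pd.read_csv(path)
    return ForceExtensionCurve(
        force_pn=df["force_pN"].to_numpy(), distance_um=df["distance_um"].to_numpy()
    )


def write_json(path: str | Path, obj: dict) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default))


def _json_default(o):
    if isinstance(o, np.bool_):
        return bool(o)
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
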