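"""File formats: trajectory CSV, parameter/rig JSON, matrices, config YAML.

All writers round-trip losslessly through their readers.  Trajectories are
plain CSV with columns ``frame,t_s,x_mm,y_mm,z_mm`` (missing coordinates
allowed on read); parameters and camera rigs are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import InputError
from .simulate import MovementParams, TankGeometry
from .tagloc import CameraRig, EllipseObservation

__all__ = [
    "TRAJECTORY_COLUMNS",
    "read_trajectory",
    "write_trajectory",
    "read_movement_params",
    "write_movement_params",
    "read_rig",
    "write_rig",
    "read_ellipses",
    "write_ellipses",
    "write_matrix",
    "read_matrix",
    "load_config",
    "tank_from_spec",
]

TRAJECTORY_COLUMNS = ("frame", "t_s", "x_mm", "y_mm", "z_mm")

_FLOAT_FMT = "%.10g"


def read_trajectory(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in TRAJECTORY_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"{path}: trajectory CSV lacks columns {missing}")
    return df.loc[:, list(TRAJECTORY_COLUMNS)]


def write_trajectory(traj: pd.DataFrame, path) -> None:
    missing = [c for c in TRAJECTORY_COLUMNS if c not in traj.columns]
    if missing:
        raise InputError(f"trajectory lacks columns {missing}")
    traj.loc[:, list(TRAJECTORY_COLUMNS)].to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


def read_movement_params(path) -> MovementParams:
    with open(path) as fh:
        return MovementParams.from_dict(json.load(fh))


def write_movement_params(params: MovementParams, path) -> None:
    with open(path, "w") as fh:
        json.dump(params.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_rig(path) -> CameraRig:
    with open(path) as fh:
        return CameraRig.from_dict(json.load(fh))


def write_rig(rig: CameraRig, path) -> None:
    with open(path, "w") as fh:
        json.dump(rig.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")


_ELLIPSE_COLUMNS = ("frame", "cx_px", "cy_px", "semi_major_px", "semi_minor_px", "orientation_rad")


def read_ellipses(path) -> list[tuple[int, EllipseObservation]]:
    df = pd.read_csv(path)
    missing = [c for c in _ELLIPSE_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"{path}: ellipse CSV lacks columns {missing}")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            (
                int(row.frame),
                EllipseObservation(
                    center=np.array([row.cx_px, row.cy_px]),
                    semi_major=float(row.semi_major_px),
                    semi_minor=float(row.semi_minor_px),
                    orientation=float(row.orientation_rad),
                ),
            )
        )
    return out


def write_ellipses(observations: list[tuple[int, EllipseObservation]], path) -> None:
    rows = [
        {
            "frame": f,
            "cx_px": obs.center[0],
            "cy_px": obs.center[1],
            "semi_major_px": obs.semi_major,
            "semi_minor_px": obs.semi_minor,
            "orientation_rad": obs.orientation,
        }
        for f, obs in observations
    ]
    pd.DataFrame(rows, columns=list(_ELLIPSE_COLUMNS)).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


def write_matrix(D: np.ndarray, ids, path) -> None:
    """Square matrix as CSV with fish-ID header row and index column."""
    pd.DataFrame(np.asarray(D, dtype=float), index=list(ids), columns=list(ids)).to_csv(
        path, float_format=_FLOAT_FMT
    )


def read_matrix(path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, index_col=0)
    return df.to_numpy(dtype=float), [str(c) for c in df.columns]


def load_config(path) -> dict:
    """YAML configuration (tank dimensions, timestep, pipeline thresholds)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise InputError(f"{path}: config must be a YAML mapping")
    return cfg


def tank_from_spec(spec: str | dict | None) -> TankGeometry:
    """Tank from 'default', 'top,base,depth' (mm) or a mapping."""
    if spec is None or spec == "default":
        return TankGeometry()
    if isinstance(spec, dict):
        return TankGeometry(**{k: float(v) for k, v in spec.items()})
    parts = [float(v) for v in str(spec).split(",")]
    if len(parts) != 3:
        raise InputError("tank spec must be 'default' or 'top_radius,base_radius,depth'")
    return TankGeometry(top_radius=parts[0], base_radius=parts[1], depth=parts[2])
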