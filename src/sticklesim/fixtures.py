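"""Seeded synthetic fixture bundles for development and testing.

Everything here is generated by the package's own simulator and synthetic
camera-scene oracle; no external data are involved.  The default movement
regimes span the slow/medium/fast range of per-fish behaviour: gamma mean
steps of roughly 1, 4 and 10 mm with rank autocorrelations 0.75-0.88, and
turning power laws under which concentration and ellipticity both grow
with step length.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from . import io as sio
from .simulate import DEFAULT_TANK, MovementParams, PowerLaw, simulate_path, simulate_unnatural_path
from .stepproc import GammaParams
from .tagloc import default_rig, synth_tag_scene

__all__ = ["REGIME_PARAMS", "make_fixtures"]


def _regimes() -> dict[str, MovementParams]:
    return {
        "slow": MovementParams(
            gamma=GammaParams(shape=1.5, rate=1.0),
            rho_s=0.75,
            kappa_law=PowerLaw(k=2.5, d=0.9),
            beta_law=PowerLaw(k=0.8, d=1.0),
        ),
        "medium": MovementParams(
            gamma=GammaParams(shape=2.0, rate=0.5),
            rho_s=0.81,
            kappa_law=PowerLaw(k=2.0, d=1.0),
            beta_law=PowerLaw(k=0.7, d=1.1),
        ),
        "fast": MovementParams(
            gamma=GammaParams(shape=2.5, rate=0.4),
            rho_s=0.85,
            kappa_law=PowerLaw(k=3.0, d=0.8),
            beta_law=PowerLaw(k=1.0, d=0.9),
        ),
    }


#: Three per-fish parameter sets spanning slow, medium and fast movers.
REGIME_PARAMS = _regimes()

#: Near-immobile outlier: sub-0.05 mm median steps.
_OUTLIER_PARAMS = MovementParams(
    gamma=GammaParams(shape=1.0, rate=50.0),
    rho_s=0.5,
    kappa_law=PowerLaw(k=2.0, d=1.0),
    beta_law=PowerLaw(k=0.7, d=1.1),
)


def make_fixtures(out_dir, seed: int, n_steps: int = 36000) -> dict:
    """Write a deterministic fixture bundle and return its manifest.

    Contents: one trajectory CSV + params JSON per movement regime, a
    near-immobile outlier trajectory, an unnatural (two-point step)
    trajectory, a synthetic tag scene (edge points CSV + rig JSON + ground
    truth JSON) and ``manifest.json``.  Re-running with the same seed
    reproduces the files byte for byte.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(seed)
    files: list[dict] = []

    def _note(name: str, kind: str) -> None:
        files.append({"name": name, "kind": kind})

    streams = root.spawn(len(REGIME_PARAMS) + 3)
    for (name, params), ss in zip(REGIME_PARAMS.items(), streams):
        rng = np.random.default_rng(ss)
        traj = simulate_path(params, DEFAULT_TANK, n_steps, rng)
        sio.write_trajectory(traj, out / f"traj_{name}.csv")
        sio.write_movement_params(params, out / f"params_{name}.json")
        _note(f"traj_{name}.csv", "trajectory")
        _note(f"params_{name}.json", "movement_params")

    rng = np.random.default_rng(streams[-3])
    traj = simulate_path(_OUTLIER_PARAMS, DEFAULT_TANK, n_steps, rng)
    sio.write_trajectory(traj, out / "traj_outlier.csv")
    _note("traj_outlier.csv", "trajectory")

    rng = np.random.default_rng(streams[-2])
    traj = simulate_unnatural_path(
        REGIME_PARAMS["medium"], DEFAULT_TANK, min(n_steps, 1200), rng
    )
    sio.write_trajectory(traj, out / "traj_unnatural.csv")
    _note("traj_unnatural.csv", "trajectory")

    rng = np.random.default_rng(streams[-1])
    rig = default_rig()
    edge_px, truth = synth_tag_scene(
        np.array([30.0, -40.0, 50.0]), rig, pixel_noise_sd=0.25, rng=rng
    )
    np.savetxt(
        out / "tag_scene_edges.csv",
        edge_px,
        delimiter=",",
        header="u_px,v_px",
        comments="",
        fmt="%.10g",
    )
    sio.write_rig(rig, out / "tag_scene_rig.json")
    with open(out / "tag_scene_truth.json", "w") as fh:
        json.dump(
            {
                "center_mm": [float(v) for v in truth["center"]],
                "normal": [float(v) for v in truth["normal"]],
                "diameter_mm": truth["diameter"],
            },
            fh,
            indent=2,
            sort_keys=True,
        )
        fh.write("\n")
    _note("tag_scene_edges.csv", "edge_points")
    _note("tag_scene_rig.json", "camera_rig")
    _note("tag_scene_truth.json", "tag_truth")

    manifest = {"seed": int(seed), "n_steps": int(n_steps), "files": files}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
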