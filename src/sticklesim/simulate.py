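"""Generative model of individual 3D fish movement in a tapered circular tank.

At each 0.1 s timestep the fish draws a step length from an autocorrelated
gamma process and a new heading from a Kent distribution whose mean axis is
the previous heading and whose concentration and ellipticity are power-law
functions of the drawn step length (fast fish turn little; slow fish
reorient freely).  The position update is

    c(t) = c(t - tau) + v(t) * s(t)

A look-ahead boundary rule keeps the path inside the tank: if the position
three timesteps ahead (same heading, same step length) would leave the
tank, both step length and direction are redrawn until it would not.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .directional import (
    HeadingFrame,
    KentParams,
    _kent_draw_canonical,
    frame_from_heading,
    kent_sample,
)
from .errors import InputError, ParameterError, SimulationError
from .stepproc import (
    CorrelatedGammaChain,
    GammaParams,
    TWO_POINT_MAX_STEP,
    sample_two_point_steps,
)

__all__ = [
    "PowerLaw",
    "MovementParams",
    "TankGeometry",
    "DEFAULT_TANK",
    "DEFAULT_TAU",
    "kent_params_for_step",
    "tank_contains",
    "sample_initial_state",
    "simulate_path",
    "simulate_unnatural_path",
    "trajectory_from_positions",
    "n_steps_for_duration",
]

#: Sampling interval of the empirical data collection, in seconds.
DEFAULT_TAU = 0.1

#: Timesteps looked ahead by the boundary rule.
_LOOKAHEAD = 3


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


@dataclass(frozen=True)
class PowerLaw:
    """Power function g(s) = k * s**d mapping step length to a Kent parameter."""

    k: float
    d: float

    def __post_init__(self):
        if not (np.isfinite(self.k) and self.k > 0):
            raise ParameterError(f"power-law coefficient must be > 0, got {self.k}")
        if not np.isfinite(self.d):
            raise ParameterError("power-law exponent must be finite")

    def __call__(self, s):
        s = np.asarray(s, dtype=float)
        if np.any(s < 0):
            raise InputError("step length must be >= 0")
        with np.errstate(divide="ignore"):
            out = self.k * np.power(s, self.d)
        # k * 0**d: zero for d > 0 (rest implies uniform turning); k at d == 0
        if np.any(~np.isfinite(out)):
            raise ParameterError(
                f"power law k={self.k}, d={self.d} diverges at step length 0"
            )
        return float(out) if out.ndim == 0 else out

    def to_dict(self) -> dict:
        return {"k": float(self.k), "d": float(self.d)}

    @classmethod
    def from_dict(cls, d: dict) -> "PowerLaw":
        return cls(float(d["k"]), float(d["d"]))


@dataclass(frozen=True)
class MovementParams:
    """Per-fish generative movement parameters.

    gamma : marginal step-length distribution (shape, rate 1/mm).
    rho_s : lag-1 Spearman autocorrelation of step length, in [0, 1).
    kappa_law, beta_law : power laws giving Kent concentration/ellipticity
        as functions of step length (mm).
    tau : timestep in seconds.
    """

    gamma: GammaParams
    rho_s: float
    kappa_law: PowerLaw
    beta_law: PowerLaw
    tau: float = DEFAULT_TAU

    def __post_init__(self):
        if not (0.0 <= self.rho_s < 1.0):
            raise ParameterError(f"rho_s must lie in [0, 1), got {self.rho_s}")
        if not (np.isfinite(self.tau) and self.tau > 0):
            raise ParameterError(f"tau must be > 0, got {self.tau}")

    def to_dict(self) -> dict:
        return {
            "gamma": self.gamma.to_dict(),
            "rho_s": float(self.rho_s),
            "kappa_law": self.kappa_law.to_dict(),
            "beta_law": self.beta_law.to_dict(),
            "tau_s": float(self.tau),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MovementParams":
        return cls(
            gamma=GammaParams.from_dict(d["gamma"]),
            rho_s=float(d["rho_s"]),
            kappa_law=PowerLaw.from_dict(d["kappa_law"]),
            beta_law=PowerLaw.from_dict(d["beta_law"]),
            tau=float(d.get("tau_s", DEFAULT_TAU)),
        )


@dataclass(frozen=True)
class TankGeometry:
    """Tapered circular tank: radius shrinks linearly from surface to floor.

    Defaults are a 30 cm diameter tank tapering to 27.5 cm at the base with
    8 cm of water, in mm.
    """

    top_radius: float = 150.0
    base_radius: float = 137.5
    depth: float = 80.0

    def __post_init__(self):
        ok = (
            np.isfinite(self.top_radius)
            and np.isfinite(self.base_radius)
            and np.isfinite(self.depth)
            and self.top_radius > 0
            and self.base_radius > 0
            and self.depth > 0
            and self.top_radius >= self.base_radius
        )
        if not ok:
            raise ParameterError("invalid tank geometry")

    def radius_at(self, z):
        """Tank radius (mm) at depth z below the surface."""
        z = np.asarray(z, dtype=float)
        r = self.top_radius - (self.top_radius - self.base_radius) * z / self.depth
        return float(r) if r.ndim == 0 else r


DEFAULT_TANK = TankGeometry()


def tank_contains(pos, tank: TankGeometry = DEFAULT_TANK):
    """True where position(s) lie inside the tank (boundary inclusive)."""
    p = np.asarray(pos, dtype=float)
    single = p.ndim == 1
    p = np.atleast_2d(p)
    z = p[:, 2]
    r = np.hypot(p[:, 0], p[:, 1])
    ok = (z >= 0.0) & (z <= tank.depth) & (r <= tank.radius_at(z) + 1e-12)
    return bool(ok[0]) if single else ok


def sample_initial_state(tank: TankGeometry, rng) -> tuple[np.ndarray, np.ndarray]:
    """Uniform random start: position in the inscribed cylinder, heading on S^2.

    The cylinder of radius ``base_radius`` and height ``depth`` is wholly
    inside the tapered tank, so the start is always contained.
    """
    rng = _as_rng(rng)
    r = tank.base_radius * math.sqrt(rng.random())
    ang = 2.0 * math.pi * rng.random()
    z = tank.depth * rng.random()
    pos = np.array([r * math.cos(ang), r * math.sin(ang), z])
    while True:
        h = rng.standard_normal(3)
        n = np.linalg.norm(h)
        if n > 1e-12:
            return pos, h / n


def kent_params_for_step(s: float, p: MovementParams, frame: HeadingFrame) -> KentParams:
    """Kent turning kernel for a drawn step length.

    kappa and beta come from the fitted power laws; beta is clipped to
    kappa/2 where the laws would violate the ellipticity constraint.  Axes
    are taken from the heading frame: mean = previous heading, major =
    lateral, minor = dorsoventral.
    """
    if s < 0:
        raise InputError(f"step length must be >= 0, got {s}")
    kappa = float(p.kappa_law(s))
    beta = min(float(p.beta_law(s)), kappa / 2.0)
    return KentParams(kappa, beta, frame.heading, frame.lateral, frame.dorsoventral)


def trajectory_from_positions(positions: np.ndarray, tau: float = DEFAULT_TAU) -> pd.DataFrame:
    """Wrap an (n, 3) position array as a trajectory table.

    Columns: ``frame`` (index), ``t_s`` (seconds), ``x_mm, y_mm, z_mm``.
    """
    P = np.atleast_2d(np.asarray(positions, dtype=float))
    if P.shape[1] != 3:
        raise InputError("positions must be an (n, 3) array")
    n = P.shape[0]
    frames = np.arange(n)
    return pd.DataFrame(
        {
            "frame": frames,
            "t_s": frames * tau,
            "x_mm": P[:, 0],
            "y_mm": P[:, 1],
            "z_mm": P[:, 2],
        }
    )


def n_steps_for_duration(duration_s: float, tau: float = DEFAULT_TAU) -> int:
    """Number of samples recorded over ``duration_s`` at interval ``tau``."""
    return int(round(duration_s / tau))


def simulate_path(
    p: MovementParams,
    tank: TankGeometry = DEFAULT_TANK,
    n_steps: int = 1200,
    rng=None,
    init: tuple | None = None,
    *,
    unnatural: bool = False,
    redraw_cap: int = 10000,
) -> pd.DataFrame:
    """Simulate one fish for ``n_steps`` sampled positions.

    The returned trajectory has ``n_steps`` rows (frame 0 is the initial
    position, so ``n_steps - 1`` displacement draws are made); 36,000 rows
    correspond to 60 min at the default 0.1 s timestep.  ``init`` may supply
    a ``(position, heading)`` pair; otherwise both are drawn uniformly.

    Boundary rule: a proposed move is accepted only if the position three
    timesteps ahead along the proposed heading, at the proposed step length,
    is still inside the tank; otherwise step length and direction are
    redrawn (the latent step-length chain advances on every redraw).  More
    than ``redraw_cap`` consecutive redraws raises :class:`SimulationError`.
    """
    if n_steps < 1:
        raise InputError("n_steps must be >= 1")
    rng = _as_rng(rng)

    if init is None:
        pos, heading = sample_initial_state(tank, rng)
    else:
        pos = np.asarray(init[0], dtype=float).reshape(3).copy()
        heading = np.asarray(init[1], dtype=float).reshape(3)
        heading = heading / np.linalg.norm(heading)
        if not tank_contains(pos, tank):
            raise InputError("initial position lies outside the tank")

    if unnatural:
        mean_step = p.gamma.mean
        if mean_step > TWO_POINT_MAX_STEP:
            raise ParameterError(
                f"mean step {mean_step:.3g} mm exceeds the two-point support "
                f"[0, {TWO_POINT_MAX_STEP}]"
            )

        def draw_step() -> float:
            return float(sample_two_point_steps(mean_step, 1, rng)[0])

    else:
        chain = CorrelatedGammaChain(p.gamma, p.rho_s, rng)
        draw_step = chain.draw

    positions = np.empty((n_steps, 3))
    positions[0] = pos

    # Scalar state for the hot loop (same maths as the public frame/Kent
    # helpers, without per-step dataclass validation).
    frame0 = frame_from_heading(heading)
    hx, hy, hz = frame0.heading
    lx, ly, lz = frame0.lateral
    dx, dy, dz = frame0.dorsoventral
    px, py, pz = (float(v) for v in pos)
    kk, kd = p.kappa_law.k, p.kappa_law.d
    bk, bd = p.beta_law.k, p.beta_law.d
    top_r, depth = tank.top_radius, tank.depth
    slope = (tank.top_radius - tank.base_radius) / tank.depth

    for t in range(1, n_steps):
        for _attempt in range(redraw_cap):
            s = draw_step()
            kappa = kk * s**kd if s > 0.0 else (kk if kd == 0.0 else 0.0)
            beta = bk * s**bd if s > 0.0 else (bk if bd == 0.0 else 0.0)
            if 2.0 * beta > kappa:
                beta = 0.5 * kappa
            x1, x2, x3 = _kent_draw_canonical(kappa, beta, rng)
            vx = x1 * hx + x2 * lx + x3 * dx
            vy = x1 * hy + x2 * ly + x3 * dy
            vz = x1 * hz + x2 * lz + x3 * dz
            nrm = math.sqrt(vx * vx + vy * vy + vz * vz)
            vx, vy, vz = vx / nrm, vy / nrm, vz / nrm
            look = _LOOKAHEAD * s
            fx, fy, fz = px + look * vx, py + look * vy, pz + look * vz
            if 0.0 <= fz <= depth and math.hypot(fx, fy) <= top_r - slope * fz + 1e-12:
                break
        else:
            raise SimulationError(
                f"boundary redraw cap ({redraw_cap}) exceeded at timestep {t}"
            )
        px, py, pz = px + s * vx, py + s * vy, pz + s * vz
        positions[t] = (px, py, pz)
        # advance the heading frame: lateral = heading x up = (-vy, vx, 0)
        hx, hy, hz = vx, vy, vz
        hor = math.hypot(vx, vy)
        if hor > 1e-8:
            lx, ly, lz = -vy / hor, vx / hor, 0.0
        else:
            # near-vertical heading: carry the previous lateral axis,
            # re-orthogonalised against the new heading
            dot = lx * hx + ly * hy + lz * hz
            cx, cy, cz = lx - dot * hx, ly - dot * hy, lz - dot * hz
            cn = math.sqrt(cx * cx + cy * cy + cz * cz)
            lx, ly, lz = cx / cn, cy / cn, cz / cn
        # dorsoventral = heading x lateral
        dx = hy * lz - hz * ly
        dy = hz * lx - hx * lz
        dz = hx * ly - hy * lx

    return trajectory_from_positions(positions, p.tau)


def simulate_unnatural_path(
    p: MovementParams,
    tank: TankGeometry = DEFAULT_TANK,
    n_steps: int = 1200,
    rng=None,
    init: tuple | None = None,
    redraw_cap: int = 10000,
) -> pd.DataFrame:
    """Simulate the stilted two-point-step variant (turns as in the main model).

    Step lengths are 0 or 20 mm with the mean matched to the gamma mean a/b.
    """
    return simulate_path(
        p, tank, n_steps, rng, init, unnatural=True, redraw_cap=redraw_cap
    )
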