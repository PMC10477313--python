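"""Directional statistics on the unit sphere: the Kent (FB5) family.

The Kent distribution is the elliptical analogue of the von Mises-Fisher
distribution on S^2.  Its density at a unit vector ``x`` is

    f(x) = c(kappa, beta)^{-1} *
           exp{ kappa * g1.x + beta * [(g2.x)^2 - (g3.x)^2] }

where ``kappa >= 0`` controls concentration, ``beta`` (with
``0 <= 2*beta <= kappa``) controls ellipticity, and ``g1, g2, g3`` are
orthonormal mean, major and minor axes.  Turn directions of a swimming fish
are modelled with this family: the mean axis is the previous heading, the
major axis the fish's lateral (horizontal) axis and the minor axis its
dorsoventral axis, so that spread is wider side-to-side than up-and-down.

Conventions
-----------
World coordinates are (x, y, z) in mm with z the *depth* below the water
surface, so "up" (toward the surface) is -z.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, special

from .errors import DegenerateDataError, InputError, ParameterError

__all__ = [
    "UP",
    "KentParams",
    "HeadingFrame",
    "as_unit_vector",
    "kent_log_norm_const",
    "kent_norm_const",
    "kent_log_density",
    "kent_fit",
    "kent_sample",
    "frame_from_heading",
]

#: Unit vector pointing toward the water surface (z is depth, increasing down).
UP = np.array([0.0, 0.0, -1.0])

_UNIT_TOL = 1e-9
_AXIS_TOL = 1e-8


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def as_unit_vector(v, tol: float = 1e-6, name: str = "vector") -> np.ndarray:
    """Validate and return ``v`` as a unit 3-vector (renormalised exactly)."""
    v = np.asarray(v, dtype=float).reshape(3)
    if not np.all(np.isfinite(v)):
        raise InputError(f"{name} has non-finite components")
    n = float(np.linalg.norm(v))
    if abs(n - 1.0) > tol:
        raise InputError(f"{name} is not unit length (|v| = {n:.6g})")
    return v / n


def _check_kent_domain(kappa: float, beta: float) -> None:
    if not (np.isfinite(kappa) and np.isfinite(beta)):
        raise ParameterError("kappa and beta must be finite")
    if kappa < 0:
        raise ParameterError(f"kappa must be >= 0 (got {kappa})")
    if beta < -_UNIT_TOL or 2.0 * beta > kappa + _UNIT_TOL:
        raise ParameterError(
            f"ellipticity constraint 0 <= 2*beta <= kappa violated "
            f"(kappa={kappa}, beta={beta})"
        )


@dataclass(frozen=True)
class KentParams:
    """Parameters of a Kent (FB5) distribution.

    Attributes
    ----------
    kappa : concentration (>= 0, dimensionless).
    beta : ellipticity, constrained by ``0 <= 2*beta <= kappa``.
    gamma1, gamma2, gamma3 : orthonormal right-handed mean/major/minor axes.
    """

    kappa: float
    beta: float
    gamma1: np.ndarray
    gamma2: np.ndarray
    gamma3: np.ndarray

    def __post_init__(self):
        _check_kent_domain(self.kappa, self.beta)
        g1 = as_unit_vector(self.gamma1, name="gamma1")
        g2 = as_unit_vector(self.gamma2, name="gamma2")
        g3 = as_unit_vector(self.gamma3, name="gamma3")
        G = np.vstack([g1, g2, g3])
        if not np.allclose(G @ G.T, np.eye(3), atol=1e-6):
            raise ParameterError("Kent axes are not orthonormal")
        if np.linalg.det(G) < 0:
            raise ParameterError("Kent axes are not right-handed")
        object.__setattr__(self, "gamma1", g1)
        object.__setattr__(self, "gamma2", g2)
        object.__setattr__(self, "gamma3", g3)

    @property
    def axes(self) -> np.ndarray:
        """Axes stacked as rows: ``[gamma1; gamma2; gamma3]``."""
        return np.vstack([self.gamma1, self.gamma2, self.gamma3])

    def to_dict(self) -> dict:
        return {
            "kappa": float(self.kappa),
            "beta": float(self.beta),
            "axes": [float(v) for v in self.axes.ravel()],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "KentParams":
        axes = np.asarray(d["axes"], dtype=float).reshape(3, 3)
        return cls(float(d["kappa"]), float(d["beta"]), axes[0], axes[1], axes[2])


# ---------------------------------------------------------------------------
# Normalisation constant
# ---------------------------------------------------------------------------

_LOG_4PI = math.log(4.0 * math.pi)


def kent_log_norm_const(kappa: float, beta: float) -> float:
    """Log of the Kent normalisation constant c(kappa, beta).

    Uses the series

        c = 2*pi * sum_{j>=0} G(j+1/2)/G(j+1) * beta^(2j)
                   * (2/kappa)^(2j+1/2) * I_{2j+1/2}(kappa)

    evaluated with exponentially scaled Bessel functions for stability at
    large kappa, truncated adaptively.  Reduces to ``4*pi*sinh(k)/k`` at
    ``beta = 0`` and to ``log(4*pi)`` at ``kappa = 0``.
    """
    _check_kent_domain(kappa, beta)
    if kappa < 1e-12:
        return _LOG_4PI
    beta = max(0.0, min(beta, kappa / 2.0))
    log_2_over_k = math.log(2.0 / kappa)
    log_beta = math.log(beta) if beta > 0 else -math.inf
    log_terms: list[float] = []
    best = -math.inf
    for j in range(2000):
        nu = 2 * j + 0.5
        iv = special.ive(nu, kappa)
        if iv <= 0.0:
            break
        logt = (
            math.lgamma(j + 0.5)
            - math.lgamma(j + 1.0)
            + (2 * j + 0.5) * log_2_over_k
            + math.log(iv)
        )
        if j > 0:
            if beta == 0.0:
                break
            logt += 2 * j * log_beta
        log_terms.append(logt)
        best = max(best, logt)
        if j > 3 and logt < best - 36.0:
            break
    else:  # pragma: no cover - series always terminates for valid params
        raise ParameterError("normalisation series did not converge")
    return kappa + math.log(2.0 * math.pi) + special.logsumexp(log_terms)


def kent_norm_const(kappa: float, beta: float) -> float:
    """Kent normalisation constant c(kappa, beta) (may overflow for kappa >~ 700)."""
    return float(np.exp(kent_log_norm_const(kappa, beta)))


def kent_log_density(x, p: KentParams) -> np.ndarray | float:
    """Log density of the Kent distribution at unit vector(s) ``x``.

    ``x`` may be a single 3-vector or an (n, 3) array of unit vectors.
    """
    X = np.asarray(x, dtype=float)
    single = X.ndim == 1
    X = np.atleast_2d(X)
    if X.shape[1] != 3:
        raise InputError("x must be a 3-vector or an (n, 3) array")
    norms = np.linalg.norm(X, axis=1)
    if not np.allclose(norms, 1.0, atol=1e-6):
        raise InputError("x must contain unit vectors")
    logc = kent_log_norm_const(p.kappa, p.beta)
    t1 = X @ p.gamma1
    t2 = X @ p.gamma2
    t3 = X @ p.gamma3
    out = p.kappa * t1 + p.beta * (t2**2 - t3**2) - logc
    return float(out[0]) if single else out


# ---------------------------------------------------------------------------
# Estimation
# ---------------------------------------------------------------------------


def _orthonormal_complement(g1: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Any orthonormal pair spanning the plane perpendicular to ``g1``."""
    ref = np.zeros(3)
    ref[int(np.argmin(np.abs(g1)))] = 1.0
    u = np.cross(g1, ref)
    u /= np.linalg.norm(u)
    w = np.cross(g1, u)
    return u, w


def kent_fit(samples, method: str = "mle") -> KentParams:
    """Fit a Kent distribution to unit-vector samples.

    Axes are estimated by Kent's moment method: the mean direction gives the
    mean axis, and the eigenvectors of the second-moment matrix of the
    tangent-plane components give the major/minor axes.  With
    ``method="mle"`` (default) kappa and beta are then found by maximising
    the exact likelihood (axes held fixed); ``method="moment"`` keeps the
    large-concentration moment estimators.
    """
    X = np.atleast_2d(np.asarray(samples, dtype=float))
    if X.ndim != 2 or X.shape[1] != 3:
        raise InputError("samples must be an (n, 3) array of unit vectors")
    n = X.shape[0]
    if n < 10:
        raise InputError(f"need at least 10 samples, got {n}")
    norms = np.linalg.norm(X, axis=1)
    if not np.allclose(norms, 1.0, atol=1e-6):
        raise InputError("samples must be unit vectors")
    X = X / norms[:, None]
    if float(np.max(np.ptp(X, axis=0))) < 1e-12:
        raise DegenerateDataError("all samples identical; axes undefined")

    xbar = X.mean(axis=0)
    rbar = float(np.linalg.norm(xbar))
    if rbar > 1e-12:
        g1 = xbar / rbar
    else:
        # No mean direction (antipodally balanced data): fall back to the
        # principal axis of the scatter matrix.
        _, vecs = np.linalg.eigh(X.T @ X / n)
        g1 = vecs[:, -1]

    u, w = _orthonormal_complement(g1)
    C = X @ np.column_stack([u, w])
    M = C.T @ C / n
    evals, evecs = np.linalg.eigh(M)
    # eigh returns ascending order; the major axis has the larger eigenvalue
    v_major = evecs[:, 1]
    w1, w2 = float(evals[1]), float(evals[0])
    g2 = v_major[0] * u + v_major[1] * w
    g2 /= np.linalg.norm(g2)
    g3 = np.cross(g1, g2)

    r2 = w1 - w2
    denom_minus = max(2.0 - 2.0 * rbar - r2, 1e-10)
    denom_plus = max(2.0 - 2.0 * rbar + r2, 1e-10)
    kappa0 = 1.0 / denom_minus + 1.0 / denom_plus
    beta0 = 0.5 * (1.0 / denom_minus - 1.0 / denom_plus)
    kappa0 = float(np.clip(kappa0, 1e-8, 1e6))
    beta0 = float(np.clip(beta0, 0.0, 0.5 * kappa0 * (1.0 - 1e-9)))

    if method == "moment":
        return KentParams(kappa0, beta0, g1, g2, g3)
    if method != "mle":
        raise InputError(f"unknown method {method!r}")

    # Sufficient statistics for the exact likelihood with fixed axes.
    m1 = float(np.mean(X @ g1))
    m2 = float(np.mean((X @ g2) ** 2))
    m3 = float(np.mean((X @ g3) ** 2))

    def nll(theta):
        k, e = theta
        b = 0.5 * e * k
        return kent_log_norm_const(k, b) - (k * m1 + b * (m2 - m3))

    e0 = float(np.clip(2.0 * beta0 / kappa0, 0.0, 1.0 - 1e-9))
    res = optimize.minimize(
        nll,
        x0=[kappa0, e0],
        bounds=[(1e-8, 1e6), (0.0, 1.0 - 1e-9)],
        method="L-BFGS-B",
    )
    kappa_hat = float(res.x[0])
    beta_hat = 0.5 * float(res.x[1]) * kappa_hat
    return KentParams(kappa_hat, beta_hat, g1, g2, g3)


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------


def _acg_envelope_b(c2: float, c3: float) -> float:
    """Solve sum_i 1/(b + c_i) = 1 with c = (0, c2, c3); root lies in (0, 3]."""
    if c2 <= 0.0 and c3 <= 0.0:
        return 3.0

    def f(b):
        return 1.0 / b + 1.0 / (b + c2) + 1.0 / (b + c3) - 1.0

    return float(optimize.brentq(f, 1e-12, 3.0, xtol=1e-12))


def kent_sample(p: KentParams, n: int, rng) -> np.ndarray:
    """Draw ``n`` i.i.d. unit vectors from a Kent distribution.

    Exact rejection sampling: the Fisher (linear) part of the exponent is
    bounded by a Bingham density via ``exp(k*x1) <= e^k * exp(-k(1-x1^2)/2)``,
    and the resulting Bingham proposal is simulated by rejection from an
    angular central Gaussian with ``Omega = I + 2*Lambda/b``.  Both rejection
    stages are folded into a single acceptance probability, so no burn-in or
    approximation is involved.
    """
    if n < 1:
        raise InputError("n must be >= 1")
    rng = _as_rng(rng)
    kappa, beta = p.kappa, p.beta
    lam2 = kappa / 2.0 - beta
    lam3 = kappa / 2.0 + beta
    b = _acg_envelope_b(2.0 * lam2, 2.0 * lam3)
    omega = np.array([1.0, 1.0 + 2.0 * lam2 / b, 1.0 + 2.0 * lam3 / b])
    sqrt_omega = np.sqrt(omega)
    # sup of exp(-s) * (1 + 2s/b)^{3/2} over s >= 0 is attained at s=(3-b)/2
    log_m = -(3.0 - b) / 2.0 + 1.5 * math.log(3.0 / b)

    out = np.empty((n, 3))
    got = 0
    while got < n:
        m = max(16, int(2.5 * (n - got)) + 8)
        z = rng.standard_normal((m, 3)) / sqrt_omega
        x = z / np.linalg.norm(z, axis=1, keepdims=True)
        s = lam2 * x[:, 1] ** 2 + lam3 * x[:, 2] ** 2
        log_acc = (
            -s
            + 1.5 * np.log1p(2.0 * s / b)
            - log_m
            - kappa * (1.0 - x[:, 0]) ** 2 / 2.0
        )
        u = rng.random(m)
        keep = np.log(u) < log_acc
        k = int(np.count_nonzero(keep))
        take = min(k, n - got)
        out[got : got + take] = x[keep][:take]
        got += take
    world = out @ p.axes
    world /= np.linalg.norm(world, axis=1, keepdims=True)
    return world


def _envelope_b_scalar(c2: float, c3: float) -> float:
    """Newton solve of 1/b + 1/(b+c2) + 1/(b+c3) = 1 from the left; b in (0, 3]."""
    if c2 <= 0.0 and c3 <= 0.0:
        return 3.0
    b = 3.0 / (3.0 + c2 + c3)  # g(b) > 0 here, left of the root
    for _ in range(60):
        g = 1.0 / b + 1.0 / (b + c2) + 1.0 / (b + c3) - 1.0
        if abs(g) < 1e-12:
            break
        gp = -(1.0 / (b * b) + 1.0 / ((b + c2) ** 2) + 1.0 / ((b + c3) ** 2))
        b -= g / gp
    return b


def _kent_draw_canonical(kappa: float, beta: float, rng: np.random.Generator):
    """One Kent draw in the canonical frame (gamma1 = pole), as 3 floats.

    Identical rejection scheme to :func:`kent_sample`, written in scalar form
    for the simulator's per-timestep loop.
    """
    lam2 = 0.5 * kappa - beta
    lam3 = 0.5 * kappa + beta
    c2, c3 = 2.0 * lam2, 2.0 * lam3
    b = _envelope_b_scalar(c2, c3)
    so2 = math.sqrt(1.0 + c2 / b)
    so3 = math.sqrt(1.0 + c3 / b)
    log_m = -(3.0 - b) / 2.0 + 1.5 * math.log(3.0 / b)
    while True:
        e = rng.standard_normal(3)
        x, y, z = float(e[0]), float(e[1]) / so2, float(e[2]) / so3
        nrm = math.sqrt(x * x + y * y + z * z)
        x1, x2, x3 = x / nrm, y / nrm, z / nrm
        sv = lam2 * x2 * x2 + lam3 * x3 * x3
        log_acc = (
            -sv
            + 1.5 * math.log1p(2.0 * sv / b)
            - log_m
            - 0.5 * kappa * (1.0 - x1) ** 2
        )
        if math.log(rng.random()) < log_acc:
            return x1, x2, x3


# ---------------------------------------------------------------------------
# Heading frames
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HeadingFrame:
    """Right-handed orthonormal frame attached to a fish's heading.

    Rows of ``matrix`` are the frame axes in world coordinates:
    axis 1 the previous heading (local pole), axis 2 the lateral
    (horizontal) axis, axis 3 the dorsoventral axis.
    """

    matrix: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.matrix, dtype=float).reshape(3, 3)
        if not np.allclose(R @ R.T, np.eye(3), atol=_AXIS_TOL):
            raise InputError("heading frame is not orthonormal")
        if np.linalg.det(R) < 0:
            raise InputError("heading frame is not right-handed")
        object.__setattr__(self, "matrix", R)

    @property
    def heading(self) -> np.ndarray:
        return self.matrix[0]

    @property
    def lateral(self) -> np.ndarray:
        return self.matrix[1]

    @property
    def dorsoventral(self) -> np.ndarray:
        return self.matrix[2]

    def to_local(self, v) -> np.ndarray:
        """World coordinates -> fish-local coordinates."""
        return self.matrix @ np.asarray(v, dtype=float)

    def to_world(self, v) -> np.ndarray:
        """Fish-local coordinates -> world coordinates."""
        return self.matrix.T @ np.asarray(v, dtype=float)


_VERTICAL_TOL = 1.0 - 1e-8
_FALLBACK_LATERAL = np.array([0.0, 1.0, 0.0])


def frame_from_heading(prev_heading, prev_lateral=None) -> HeadingFrame:
    """Construct the fish-local frame implied by the previous heading.

    The lateral axis is the horizontal unit vector ``heading x up``
    (up = -z since z is depth), and the dorsoventral axis completes the
    right-handed triad.  For near-vertical headings the lateral axis is
    undefined by this rule; ``prev_lateral`` (the lateral axis of the
    preceding frame) is then reused to keep frames continuous, falling back
    to a fixed horizontal reference if none is supplied.
    """
    h = np.asarray(prev_heading, dtype=float).reshape(3)
    nh = float(np.linalg.norm(h))
    if not np.isfinite(nh) or nh < 1e-12:
        raise InputError("heading must be a nonzero vector")
    h = h / nh
    if abs(h[2]) > _VERTICAL_TOL:
        ref = _FALLBACK_LATERAL if prev_lateral is None else np.asarray(prev_lateral, float)
        lat = ref - (ref @ h) * h
        nl = float(np.linalg.norm(lat))
        if nl < 1e-12:  # pragma: no cover - reference never parallel to ~vertical h
            lat = np.array([1.0, 0.0, 0.0]) - h[0] * h
            nl = float(np.linalg.norm(lat))
        lat /= nl
    else:
        lat = np.cross(h, UP)
        lat /= np.linalg.norm(lat)
    dv = np.cross(h, lat)
    return HeadingFrame(np.vstack([h, lat, dv]))
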