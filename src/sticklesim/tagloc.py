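"""Refraction-aware monocular 3D localization of a circular dorsal tag.

A single overhead camera images a circular tag (default 7 mm diameter)
attached to a fish swimming below the air-water interface.  The tag's
perspective projection is an ellipse; the two image points at the extremes
of the semimajor axis correspond to diametrically opposite points on the
tag, whose world separation equals the tag diameter regardless of tag
orientation.  Casting a ray through each endpoint, refracting both at the
water surface (Snell's law, n1 sin(th1) = n2 sin(th2)) and finding the
depth at which the two refracted rays are exactly one tag diameter apart
recovers the tag's 3D position with a single camera.

World frame: (x, y, z) mm with z the depth below the water surface
(surface z = 0, camera at negative z).  The camera is an ideal pinhole
(lens distortion is assumed already removed from the edge coordinates).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .errors import GeometryError, InputError, LocalizationError, ParameterError

__all__ = [
    "CameraRig",
    "EllipseObservation",
    "Ray",
    "default_rig",
    "fit_ellipse",
    "pinhole_project",
    "pixel_to_water_surface",
    "refract",
    "ray_point_at_depth",
    "endpoint_separation",
    "localize_tag",
    "project_world_point",
    "synth_tag_scene",
    "rmse_experiment",
    "RmseResult",
]

#: Water-surface normal pointing into the air (z is depth, so up is -z).
_SURFACE_NORMAL = np.array([0.0, 0.0, -1.0])


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


@dataclass(frozen=True)
class CameraRig:
    """Ideal pinhole camera above the water plus interface constants.

    ``rotation``/``translation`` map world to camera coordinates
    (``X_cam = R @ X_world + t``); the camera looks along +z_cam toward the
    water.  ``focal`` is in pixels, ``principal_point`` is (cx, cy).
    """

    rotation: np.ndarray
    translation: np.ndarray
    focal: float
    principal_point: np.ndarray
    n_air: float = 1.0
    n_water: float = 1.333
    tag_diameter: float = 7.0
    max_depth: float = 80.0
    image_size: tuple[float, float] = (1920.0, 1080.0)

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        pp = np.asarray(self.principal_point, dtype=float).reshape(2)
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8) or np.linalg.det(R) < 0:
            raise ParameterError("rotation must be orthonormal with det +1")
        if not (self.n_water >= self.n_air >= 1.0):
            raise ParameterError("require n_water >= n_air >= 1")
        if self.tag_diameter <= 0 or self.focal <= 0 or self.max_depth <= 0:
            raise ParameterError("focal, tag diameter and max depth must be > 0")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        object.__setattr__(self, "principal_point", pp)

    @property
    def camera_center(self) -> np.ndarray:
        """Centre of projection in world coordinates."""
        return -self.rotation.T @ self.translation

    def to_dict(self) -> dict:
        return {
            "rotation": [float(v) for v in self.rotation.ravel()],
            "translation": [float(v) for v in self.translation],
            "focal_px": float(self.focal),
            "principal_point_px": [float(v) for v in self.principal_point],
            "n_air": float(self.n_air),
            "n_water": float(self.n_water),
            "tag_diameter_mm": float(self.tag_diameter),
            "max_depth_mm": float(self.max_depth),
            "image_size_px": [float(v) for v in self.image_size],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CameraRig":
        return cls(
            rotation=np.asarray(d["rotation"], dtype=float).reshape(3, 3),
            translation=np.asarray(d["translation"], dtype=float),
            focal=float(d["focal_px"]),
            principal_point=np.asarray(d["principal_point_px"], dtype=float),
            n_air=float(d.get("n_air", 1.0)),
            n_water=float(d.get("n_water", 1.333)),
            tag_diameter=float(d.get("tag_diameter_mm", 7.0)),
            max_depth=float(d.get("max_depth_mm", 80.0)),
            image_size=tuple(d.get("image_size_px", (1920.0, 1080.0))),
        )


def default_rig(
    height_mm: float = 800.0,
    focal_px: float = 1100.0,
    tilt_deg: float = 0.0,
) -> CameraRig:
    """Overhead camera ``height_mm`` above the tank centre, optionally tilted
    about the world x axis by ``tilt_deg``."""
    c, s = math.cos(math.radians(tilt_deg)), math.sin(math.radians(tilt_deg))
    R = np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])
    center = np.array([0.0, 0.0, -height_mm])
    t = -R @ center
    return CameraRig(
        rotation=R,
        translation=t,
        focal=focal_px,
        principal_point=np.array([960.0, 540.0]),
    )


@dataclass(frozen=True)
class EllipseObservation:
    """Fitted ellipse of the tag's image: centre, semiaxes, orientation (rad)."""

    center: np.ndarray
    semi_major: float
    semi_minor: float
    orientation: float

    def __post_init__(self):
        c = np.asarray(self.center, dtype=float).reshape(2)
        if not (self.semi_major >= self.semi_minor > 0):
            raise InputError(
                f"require semi_major >= semi_minor > 0 "
                f"(got {self.semi_major}, {self.semi_minor})"
            )
        object.__setattr__(self, "center", c)

    @property
    def major_endpoints(self) -> tuple[np.ndarray, np.ndarray]:
        """The two pixel points at the extremes of the semimajor axis."""
        d = self.semi_major * np.array(
            [math.cos(self.orientation), math.sin(self.orientation)]
        )
        return self.center + d, self.center - d


@dataclass(frozen=True)
class Ray:
    """Half-line with unit direction, in world coordinates (mm)."""

    origin: np.ndarray
    direction: np.ndarray

    def __post_init__(self):
        o = np.asarray(self.origin, dtype=float).reshape(3)
        d = np.asarray(self.direction, dtype=float).reshape(3)
        n = float(np.linalg.norm(d))
        if n < 1e-12:
            raise InputError("ray direction must be nonzero")
        object.__setattr__(self, "origin", o)
        object.__setattr__(self, "direction", d / n)


# ---------------------------------------------------------------------------
# Ellipse fitting (direct least squares with the ellipse constraint)
# ---------------------------------------------------------------------------


def _conic_to_geometric(coef: np.ndarray) -> tuple[np.ndarray, float, float, float]:
    A, B, C, D, E, F = coef
    den = B * B - 4 * A * C
    if den >= 0:
        raise InputError("fitted conic is not an ellipse")
    cx = (2 * C * D - B * E) / den
    cy = (2 * A * E - B * D) / den
    # evaluate conic at centre to get the scale term
    Fc = A * cx * cx + B * cx * cy + C * cy * cy + D * cx + E * cy + F
    M = np.array([[A, B / 2], [B / 2, C]])
    evals, evecs = np.linalg.eigh(M)
    axes2 = -Fc / evals  # semiaxis^2 along each eigenvector
    if np.any(axes2 <= 0):
        raise InputError("degenerate ellipse")
    axes = np.sqrt(axes2)
    i_maj = int(np.argmax(axes))
    a, b = float(axes[i_maj]), float(axes[1 - i_maj])
    v = evecs[:, i_maj]
    theta = math.atan2(v[1], v[0])
    return np.array([cx, cy]), a, b, theta


def fit_ellipse(edge_points) -> EllipseObservation:
    """Direct least-squares ellipse fit to edge points (Fitzgibbon constraint).

    Uses the numerically stable partitioned formulation of the
    constrained conic fit (4AC - B^2 = 1), which always returns an ellipse
    when one exists.  Requires at least 6 points in general position.
    """
    P = np.atleast_2d(np.asarray(edge_points, dtype=float))
    if P.ndim != 2 or P.shape[1] != 2:
        raise InputError("edge points must be an (n, 2) array")
    if P.shape[0] < 6:
        raise InputError(f"need >= 6 edge points, got {P.shape[0]}")
    mean = P.mean(axis=0)
    x, y = (P - mean).T  # centre for conditioning
    if float(np.ptp(x)) < 1e-12 and float(np.ptp(y)) < 1e-12:
        raise InputError("edge points are degenerate")
    D1 = np.column_stack([x * x, x * y, y * y])
    D2 = np.column_stack([x, y, np.ones_like(x)])
    S1 = D1.T @ D1
    S2 = D1.T @ D2
    S3 = D2.T @ D2
    try:
        T = -np.linalg.solve(S3, S2.T)
    except np.linalg.LinAlgError as exc:
        raise InputError(f"degenerate edge-point configuration: {exc}") from exc
    M = S1 + S2 @ T
    # apply inverse constraint matrix C1^{-1} for 4AC - B^2
    M = np.vstack([M[2] / 2.0, -M[1], M[0] / 2.0])
    evals, evecs = np.linalg.eig(M)
    cond = 4 * evecs[0] * evecs[2] - evecs[1] ** 2
    ok = np.isreal(evals) & (np.real(cond) > 0)
    if not np.any(ok):
        raise InputError("no elliptical solution (collinear or degenerate points)")
    a1 = np.real(evecs[:, np.nonzero(ok)[0][0]])
    a2 = T @ a1
    coef = np.concatenate([a1, a2])
    center, a, b, theta = _conic_to_geometric(coef)
    return EllipseObservation(center + mean, a, b, theta)


# ---------------------------------------------------------------------------
# Rays and refraction
# ---------------------------------------------------------------------------


def pinhole_project(rig: CameraRig, world_point) -> np.ndarray:
    """Project a world point (above or on the water surface) to pixels."""
    X = np.asarray(world_point, dtype=float).reshape(3)
    Xc = rig.rotation @ X + rig.translation
    if Xc[2] <= 1e-9:
        raise GeometryError("point is behind the camera")
    return rig.focal * Xc[:2] / Xc[2] + rig.principal_point


def pixel_ray(rig: CameraRig, pixel) -> Ray:
    """Back-project a pixel to a world-frame ray from the camera centre."""
    px = np.asarray(pixel, dtype=float).reshape(2)
    d_cam = np.array(
        [
            (px[0] - rig.principal_point[0]) / rig.focal,
            (px[1] - rig.principal_point[1]) / rig.focal,
            1.0,
        ]
    )
    d_world = rig.rotation.T @ d_cam
    return Ray(rig.camera_center, d_world)


def pixel_to_water_surface(pixel, rig: CameraRig) -> tuple[np.ndarray, Ray]:
    """Intersect a pixel's back-projected ray with the water plane z = 0."""
    ray = pixel_ray(rig, pixel)
    dz = ray.direction[2]
    if abs(dz) < 1e-12:
        raise GeometryError("pixel ray is parallel to the water surface")
    lam = -ray.origin[2] / dz
    if lam <= 0:
        raise GeometryError("pixel ray does not reach the water surface")
    return ray.origin + lam * ray.direction, ray


def refract(ray: Ray, surface_normal, n1: float, n2: float) -> Ray:
    """Refract a ray at an interface with indices n1 (incident) and n2.

    Vector form of Snell's law; the returned ray keeps the incident ray's
    origin (place it at the surface point before calling).  Raises
    :class:`GeometryError` on total internal reflection.
    """
    n = np.asarray(surface_normal, dtype=float).reshape(3)
    n = n / np.linalg.norm(n)
    d = ray.direction
    cos_i = -float(n @ d)
    if cos_i < 0:  # normal given on the far side; flip
        n = -n
        cos_i = -cos_i
    eta = n1 / n2
    sin2_t = eta * eta * (1.0 - cos_i * cos_i)
    if sin2_t > 1.0:
        raise GeometryError("total internal reflection")
    cos_t = math.sqrt(1.0 - sin2_t)
    d_out = eta * d + (eta * cos_i - cos_t) * n
    return Ray(ray.origin, d_out)


def ray_point_at_depth(ray: Ray, z: float) -> np.ndarray:
    """Point on the ray at world depth ``z`` (ray parameterised by depth)."""
    dz = ray.direction[2]
    if abs(dz) < 1e-12:
        raise GeometryError("ray does not advance in depth")
    t = (z - ray.origin[2]) / dz
    return ray.origin + t * ray.direction


def _refracted_endpoint_rays(obs: EllipseObservation, rig: CameraRig) -> tuple[Ray, Ray]:
    rays = []
    for px in obs.major_endpoints:
        surf, incident = pixel_to_water_surface(px, rig)
        ray = refract(Ray(surf, incident.direction), _SURFACE_NORMAL, rig.n_air, rig.n_water)
        if ray.direction[2] <= 0:
            raise GeometryError("refracted ray does not travel into the water")
        rays.append(ray)
    return rays[0], rays[1]


def endpoint_separation(obs: EllipseObservation, rig: CameraRig, z: float) -> float:
    """Distance (mm) between the two refracted endpoint rays at depth ``z``."""
    r1, r2 = _refracted_endpoint_rays(obs, rig)
    return float(np.linalg.norm(ray_point_at_depth(r1, z) - ray_point_at_depth(r2, z)))


#: A noisy observation of a surface tag may overshoot the diameter at z=0
#: (the depth solve amplifies endpoint noise); overshoots beyond half a tag
#: diameter are treated as non-physical.
_SURFACE_OVERSHOOT_MM = 3.5


def localize_tag(obs: EllipseObservation, rig: CameraRig) -> np.ndarray:
    """3D tag position from one ellipse observation.

    Casts rays through the semimajor-axis endpoints, refracts them at the
    surface, and bisects for the depth at which the rays are exactly one
    tag diameter apart (separation grows monotonically with depth for
    diverging rays); the tag centre is the midpoint of the two ray points
    at that depth.
    """
    r1, r2 = _refracted_endpoint_rays(obs, rig)

    def sep(z: float) -> float:
        return float(
            np.linalg.norm(ray_point_at_depth(r1, z) - ray_point_at_depth(r2, z))
        )

    z_hi = rig.max_depth + 5.0
    grid = np.linspace(0.0, z_hi, 9)
    seps = np.array([sep(z) for z in grid])
    if np.any(np.diff(seps) <= -1e-9):
        raise GeometryError("endpoint rays converge with depth; observation non-physical")

    D = rig.tag_diameter
    if seps[0] >= D:
        if seps[0] - D <= _SURFACE_OVERSHOOT_MM:
            z_star = 0.0
        else:
            raise LocalizationError(
                f"apparent size at the surface ({seps[0]:.2f} mm) exceeds the tag "
                f"diameter by more than {_SURFACE_OVERSHOOT_MM} mm (non-physical)"
            )
    else:
        # Observation noise can push the root slightly past the nominal
        # bottom margin for floor-depth tags; extend the bracket a bounded
        # number of times rather than fail on a physically sound scene.
        z_cap = 3.0 * rig.max_depth
        while sep(z_hi) < D and z_hi < z_cap:
            z_hi = min(2.0 * z_hi, z_cap)
        if sep(z_hi) < D:
            raise LocalizationError(
                f"ray separation never reaches the tag diameter within depth {z_hi} mm"
            )
        z_star = float(optimize.brentq(lambda z: sep(z) - D, 0.0, z_hi, xtol=1e-9))
    p1 = ray_point_at_depth(r1, z_star)
    p2 = ray_point_at_depth(r2, z_star)
    return 0.5 * (p1 + p2)


# ---------------------------------------------------------------------------
# Synthetic scene oracle
# ---------------------------------------------------------------------------


def project_world_point(rig: CameraRig, P) -> np.ndarray:
    """Project a world point to pixels, tracing through the water surface.

    Points below the surface (z > 0) are traced water -> air: the surface
    crossing point is found by solving Snell's law along the vertical plane
    containing the camera and the point, then projected by the pinhole.
    """
    P = np.asarray(P, dtype=float).reshape(3)
    if P[2] <= 1e-12:
        return pinhole_project(rig, P)
    C = rig.camera_center
    if C[2] >= 0:
        raise GeometryError("camera must be above the water surface")
    h = -C[2]
    delta = P[:2] - C[:2]
    d = float(np.hypot(*delta))
    if d < 1e-12:
        S = np.array([C[0], C[1], 0.0])
        return pinhole_project(rig, S)

    zp = P[2]

    def snell_mismatch(xs: float) -> float:
        sin1 = xs / math.hypot(xs, h)
        sin2 = (d - xs) / math.hypot(d - xs, zp)
        return rig.n_air * sin1 - rig.n_water * sin2

    xs = float(optimize.brentq(snell_mismatch, 0.0, d, xtol=1e-12))
    S = np.array([C[0] + xs / d * delta[0], C[1] + xs / d * delta[1], 0.0])
    return pinhole_project(rig, S)


def _tag_boundary(center: np.ndarray, normal: np.ndarray, diameter: float, n: int) -> np.ndarray:
    normal = normal / np.linalg.norm(normal)
    ref = np.zeros(3)
    ref[int(np.argmin(np.abs(normal)))] = 1.0
    u = np.cross(normal, ref)
    u /= np.linalg.norm(u)
    w = np.cross(normal, u)
    ang = 2 * np.pi * np.arange(n) / n
    r = diameter / 2.0
    return center + r * (np.outer(np.cos(ang), u) + np.outer(np.sin(ang), w))


def synth_tag_scene(
    tag_center,
    rig: CameraRig,
    normal=(0.0, 0.0, -1.0),
    n_boundary_points: int = 72,
    pixel_noise_sd: float = 0.0,
    rng=None,
) -> tuple[np.ndarray, dict]:
    """Synthetic edge points of a submerged tag, with ground truth.

    Samples the tag's circular boundary, traces every point through the
    refracting surface to the camera, projects to pixels and adds isotropic
    Gaussian pixel noise.  Returns ``(edge_points, truth)`` where ``truth``
    records the tag centre, normal and diameter.  Synthetic stand-in for an
    imaged tag; the refracted image is only approximately elliptical.
    """
    center = np.asarray(tag_center, dtype=float).reshape(3)
    if not (0.0 <= center[2] <= rig.max_depth):
        raise InputError(f"tag depth {center[2]} mm outside [0, {rig.max_depth}]")
    rng = _as_rng(rng)
    pts3d = _tag_boundary(center, np.asarray(normal, dtype=float), rig.tag_diameter, n_boundary_points)
    if np.any(pts3d[:, 2] < -1e-9) or np.any(pts3d[:, 2] > rig.max_depth + 1e-9):
        raise InputError("tag is not fully submerged")
    px = np.array([project_world_point(rig, p) for p in np.clip(pts3d, [-np.inf, -np.inf, 0.0], None)])
    W, H = rig.image_size
    if np.any(px[:, 0] < 0) or np.any(px[:, 0] > W) or np.any(px[:, 1] < 0) or np.any(px[:, 1] > H):
        raise GeometryError("tag image falls outside the field of view")
    if pixel_noise_sd > 0:
        px = px + pixel_noise_sd * rng.standard_normal(px.shape)
    truth = {
        "center": center.copy(),
        "normal": np.asarray(normal, dtype=float) / np.linalg.norm(normal),
        "diameter": rig.tag_diameter,
    }
    return px, truth


@dataclass(frozen=True)
class RmseResult:
    """Localization accuracy summary of the synthetic grid experiment."""

    overall: float
    per_depth: dict
    n_scenes: int


def _grid_locations(n: int, radius: float) -> np.ndarray:
    """Sunflower (Fibonacci) layout: n points roughly uniform over a disc."""
    i = np.arange(n) + 0.5
    r = radius * np.sqrt(i / n)
    theta = i * math.pi * (3.0 - math.sqrt(5.0))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta)])


def rmse_experiment(
    rig: CameraRig,
    pixel_noise_sd: float = 0.0,
    rng=None,
    n_locations: int = 32,
    depths=(0.0, 40.0, 80.0),
    grid_radius: float = 110.0,
    n_boundary_points: int = 72,
) -> RmseResult:
    """Localization error over a grid of known tag positions.

    Places horizontal tags at ``n_locations`` xy positions (approximately
    uniform over a disc) at each depth, images them synthetically with the
    given pixel noise, runs the full ellipse-fit + depth-solve pipeline and
    reports the root-mean-square position error overall and per depth.
    """
    rng = _as_rng(rng)
    xy = _grid_locations(n_locations, grid_radius)
    per_depth: dict[float, float] = {}
    all_sq: list[float] = []
    for z in depths:
        sq = []
        for x, y in xy:
            center = np.array([x, y, float(z)])
            px, truth = synth_tag_scene(
                center,
                rig,
                n_boundary_points=n_boundary_points,
                pixel_noise_sd=pixel_noise_sd,
                rng=rng,
            )
            obs = fit_ellipse(px)
            est = localize_tag(obs, rig)
            sq.append(float(np.sum((est - truth["center"]) ** 2)))
        per_depth[float(z)] = math.sqrt(float(np.mean(sq)))
        all_sq.extend(sq)
    return RmseResult(
        overall=math.sqrt(float(np.mean(all_sq))),
        per_depth=per_depth,
        n_scenes=len(all_sq),
    )
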