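"""Inverse pipeline: trajectories -> movement statistics -> model parameters.

Raw tracked positions are cleaned (cubic-spline imputation of missing
frames, zero-phase Butterworth smoothing), converted to step lengths and
relative turn vectors, and the generative parameters are re-estimated:
gamma marginal (with an AIC comparison against competitor families), lag-1
rank autocorrelation with a randomisation test, per-step-length-bin Kent
fits and power laws for concentration and ellipticity with bootstrap
confidence intervals.

Population-level comparison utilities operate on per-fish empirical
distributions: Hellinger dissimilarity matrices, classical (Torgerson)
multidimensional scaling, and distance-matrix regression with a matrix
permutation test.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import interpolate, optimize, signal

from .directional import UP, KentParams, kent_fit
from .errors import DegenerateDataError, FitError, InputError, QualityError
from .simulate import DEFAULT_TAU, MovementParams, PowerLaw
from .stepproc import (
    GammaParams,
    aic_model_comparison,
    autocorr_randomisation_test,
    fit_gamma,
    lag1_spearman,
)

__all__ = [
    "TurnSamples",
    "BinnedKentFit",
    "PowerLawFit",
    "CharacterizeConfig",
    "impute_positions",
    "smooth_positions",
    "steps_and_turns",
    "binned_kent_fits",
    "fit_power_laws",
    "fit_movement_params",
    "hellinger_distance",
    "step_histograms",
    "turn_histograms",
    "dissimilarity_matrices",
    "classical_mds",
    "distance_matrix_regression",
    "MRMResult",
    "size_distance_matrix",
]

_COORDS = ("x_mm", "y_mm", "z_mm")


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def _positions(traj: pd.DataFrame) -> np.ndarray:
    try:
        return traj.loc[:, list(_COORDS)].to_numpy(dtype=float)
    except KeyError as exc:
        raise InputError(f"trajectory lacks coordinate columns {_COORDS}") from exc


def _tau_of(traj: pd.DataFrame) -> float:
    if "t_s" not in traj.columns or len(traj) < 2:
        return DEFAULT_TAU
    dt = np.diff(traj["t_s"].to_numpy(dtype=float))
    return float(np.median(dt))


# ---------------------------------------------------------------------------
# Cleaning
# ---------------------------------------------------------------------------


def impute_positions(traj: pd.DataFrame, max_missing_frac: float = 0.2) -> pd.DataFrame:
    """Fill missing coordinates by cubic spline interpolation.

    Interior gaps are splined through the observed frames; leading and
    trailing gaps (outside the spline's support) are filled with the nearest
    observed value.  Observed values are left untouched.  More than
    ``max_missing_frac`` missing frames in any coordinate raises
    :class:`QualityError` (tracking losses in practice are a few percent).
    """
    P = _positions(traj)
    n = P.shape[0]
    out = P.copy()
    for j in range(3):
        col = P[:, j]
        good = np.isfinite(col)
        n_missing = int(n - good.sum())
        if n_missing == 0:
            continue
        if n_missing / n > max_missing_frac:
            raise QualityError(
                f"{_COORDS[j]}: {n_missing}/{n} frames missing "
                f"(> {max_missing_frac:.0%} quality gate)"
            )
        if good.sum() < 4:
            raise InputError(f"{_COORDS[j]}: need >= 4 observed frames for a cubic spline")
        idx = np.arange(n)
        spline = interpolate.CubicSpline(idx[good], col[good])
        first, last = idx[good][0], idx[good][-1]
        fill = spline(idx)
        fill[:first] = col[good][0]
        fill[last + 1 :] = col[good][-1]
        out[~good, j] = fill[~good]
    res = traj.copy()
    for j, c in enumerate(_COORDS):
        res[c] = out[:, j]
    return res


def smooth_positions(traj: pd.DataFrame, cutoff_hz: float = 2.0) -> pd.DataFrame:
    """Zero-phase third-order Butterworth low-pass of each coordinate.

    The filter is applied forward and backward (``filtfilt``) so the output
    has no phase lag; the effective magnitude response is the square of the
    third-order Butterworth response.  ``cutoff_hz`` must lie below the
    Nyquist frequency implied by the sampling interval (5 Hz at 0.1 s).
    """
    tau = _tau_of(traj)
    nyquist = 0.5 / tau
    if not (0 < cutoff_hz < nyquist):
        raise InputError(
            f"cutoff {cutoff_hz} Hz must lie in (0, {nyquist} Hz) for tau={tau} s"
        )
    P = _positions(traj)
    if not np.all(np.isfinite(P)):
        raise InputError("smoothing requires a complete trajectory; impute first")
    b, a = signal.butter(3, cutoff_hz / nyquist)
    res = traj.copy()
    for j, c in enumerate(_COORDS):
        res[c] = signal.filtfilt(b, a, P[:, j])
    return res


# ---------------------------------------------------------------------------
# Steps and turns
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TurnSamples:
    """Relative turn vectors paired with their step lengths.

    ``vectors[i]`` is the direction of displacement i expressed in the
    heading frame of the preceding (last nonzero) displacement: component 0
    forward, 1 lateral, 2 dorsoventral.  ``s[i]`` is the corresponding step
    length in mm.
    """

    s: np.ndarray
    vectors: np.ndarray

    def __post_init__(self):
        if len(self.s) != len(self.vectors):
            raise InputError("mismatched step/vector lengths")

    def __len__(self) -> int:
        return len(self.s)


@dataclass(frozen=True)
class BinnedKentFit:
    """Kent fit to the turn vectors of one 1 mm step-length bin."""

    lo: float
    hi: float
    count: int
    params: KentParams

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.lo + self.hi)


_ZERO_STEP = 1e-12


def steps_and_turns(traj: pd.DataFrame) -> tuple[np.ndarray, TurnSamples]:
    """Step lengths and relative turn vectors of a cleaned trajectory.

    n positions yield n-1 steps and at most n-2 turn samples.  A turn sample
    is emitted for displacement t when it is nonzero and some earlier
    nonzero displacement exists to define the reference heading frame;
    zero-length displacements (rest frames) stay in the step series but
    carry no direction, so the frame of the last moving step is carried
    forward across them.
    """
    P = _positions(traj)
    if P.shape[0] < 3:
        raise InputError("need at least 3 positions")
    if not np.all(np.isfinite(P)):
        raise InputError("trajectory contains missing values; impute first")
    D = np.diff(P, axis=0)
    steps = np.linalg.norm(D, axis=1)
    m = len(steps)
    nz = steps > _ZERO_STEP

    dirs = np.zeros_like(D)
    dirs[nz] = D[nz] / steps[nz, None]

    # lateral axis per displacement (horizontal, = heading x up); near-vertical
    # headings inherit the previous lateral axis for roll continuity
    lat = np.cross(dirs, UP)
    lat_norm = np.linalg.norm(lat, axis=1)
    ok = nz & (lat_norm > 1e-8)
    lat[ok] = lat[ok] / lat_norm[ok, None]
    prev_lat = np.array([0.0, 1.0, 0.0])
    for i in range(m):
        if not nz[i]:
            continue
        if not ok[i]:
            h = dirs[i]
            cand = prev_lat - (prev_lat @ h) * h
            nc = np.linalg.norm(cand)
            if nc < 1e-12:
                cand = np.array([1.0, 0.0, 0.0]) - h[0] * h
                nc = np.linalg.norm(cand)
            lat[i] = cand / nc
        prev_lat = lat[i]

    dv = np.cross(dirs, lat)

    # reference frame index: last nonzero displacement strictly before t
    last_nz = np.where(nz, np.arange(m), -1)
    last_nz = np.maximum.accumulate(last_nz)
    ref = np.full(m, -1, dtype=int)
    ref[1:] = last_nz[:-1]
    emit = nz & (ref >= 0)
    emit[0] = False

    idx = np.nonzero(emit)[0]
    r = ref[idx]
    cur = dirs[idx]
    x1 = np.einsum("ij,ij->i", cur, dirs[r])
    x2 = np.einsum("ij,ij->i", cur, lat[r])
    x3 = np.einsum("ij,ij->i", cur, dv[r])
    vectors = np.column_stack([x1, x2, x3])
    vectors /= np.linalg.norm(vectors, axis=1, keepdims=True)
    return steps, TurnSamples(s=steps[idx], vectors=vectors)


# ---------------------------------------------------------------------------
# Binned Kent fits and power laws
# ---------------------------------------------------------------------------


def binned_kent_fits(
    turns: TurnSamples, bin_width: float = 1.0, min_count: int = 1000
) -> list[BinnedKentFit]:
    """Fit a Kent distribution per step-length bin of width ``bin_width`` mm.

    Bins are half-open ``[i*w, (i+1)*w)``; only bins holding at least
    ``min_count`` turn samples are fitted (sparse bins give unstable
    concentration estimates).  An empty result is a warning, not an error.
    """
    if len(turns) == 0:
        raise InputError("no turn samples")
    bin_idx = np.floor(turns.s / bin_width).astype(int)
    fits: list[BinnedKentFit] = []
    for i in np.unique(bin_idx):
        mask = bin_idx == i
        count = int(mask.sum())
        if count < min_count:
            continue
        params = kent_fit(turns.vectors[mask])
        fits.append(
            BinnedKentFit(lo=i * bin_width, hi=(i + 1) * bin_width, count=count, params=params)
        )
    if not fits:
        warnings.warn(
            f"no step-length bin reached {min_count} samples; no Kent fits produced",
            stacklevel=2,
        )
    return fits


@dataclass(frozen=True)
class PowerLawFit:
    """Fitted power law with percentile-bootstrap confidence intervals."""

    law: PowerLaw
    k_ci: tuple[float, float]
    d_ci: tuple[float, float]


def _fit_power(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    pos = (x > 0) & (y > 0)
    if pos.sum() >= 2:
        slope, icept = np.polyfit(np.log(x[pos]), np.log(y[pos]), 1)
        p0 = (float(np.exp(icept)), float(slope))
    else:
        p0 = (max(float(np.max(y)), 1e-6), 1.0)
    popt, _ = optimize.curve_fit(
        lambda s, k, d: k * np.power(s, d), x, y, p0=p0, maxfev=20000
    )
    return float(popt[0]), float(popt[1])


def fit_power_laws(
    fits: list[BinnedKentFit],
    n_boot: int = 1000,
    rng=None,
    confidence: float = 0.95,
) -> tuple[PowerLawFit, PowerLawFit]:
    """Power laws for Kent concentration and ellipticity versus step length.

    Nonlinear least squares of ``k * s**d`` through the (bin midpoint,
    parameter estimate) points, with percentile bootstrap CIs obtained by
    resampling bins with replacement.
    """
    if len(fits) < 3:
        raise InputError(f"need >= 3 bins to fit power laws, got {len(fits)}")
    rng = _as_rng(rng)
    x = np.array([f.midpoint for f in fits])
    results = []
    for attr in ("kappa", "beta"):
        y = np.array([getattr(f.params, attr) for f in fits])
        try:
            k_hat, d_hat = _fit_power(x, y)
        except Exception as exc:
            raise FitError(f"power-law fit for {attr} failed: {exc}") from exc
        ks, ds = [], []
        for _ in range(n_boot):
            sel = rng.integers(0, len(x), size=len(x))
            if np.unique(x[sel]).size < 2:
                continue
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    kb, db = _fit_power(x[sel], y[sel])
            except Exception:
                continue
            ks.append(kb)
            ds.append(db)
        alpha = 100.0 * (1.0 - confidence) / 2.0
        if ks:
            k_ci = tuple(np.percentile(ks, [alpha, 100 - alpha]))
            d_ci = tuple(np.percentile(ds, [alpha, 100 - alpha]))
        else:  # pragma: no cover - bootstrap can only be empty for n_boot=0
            k_ci = (np.nan, np.nan)
            d_ci = (np.nan, np.nan)
        results.append(PowerLawFit(PowerLaw(k_hat, d_hat), k_ci, d_ci))
    return results[0], results[1]


# ---------------------------------------------------------------------------
# Full per-fish pipeline
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CharacterizeConfig:
    """Tunable settings of the characterisation pipeline.

    ``smoothing_cutoff_hz=None`` disables noise filtering (appropriate for
    noise-free, e.g. simulated, input).  ``near_immobile_median_mm`` flags
    fish whose median step falls below the threshold; flagged fish are
    reported, not dropped.
    """

    smoothing_cutoff_hz: float | None = 2.0
    bin_width_mm: float = 1.0
    min_bin_count: int = 1000
    n_perm: int = 999
    n_boot: int = 1000
    zero_floor_mm: float = 1e-6
    max_missing_frac: float = 0.2
    near_immobile_median_mm: float = 0.05
    min_recommended_frames: int = 5000


def fit_movement_params(
    traj: pd.DataFrame,
    config: CharacterizeConfig | None = None,
    rng=None,
) -> tuple[MovementParams, dict]:
    """Estimate :class:`MovementParams` from a trajectory, with a full report.

    Chains impute -> (optional) smooth -> steps/turns -> gamma + AIC +
    autocorrelation -> binned Kent fits -> power laws.  Returns the fitted
    parameters and a JSON-serialisable report (AIC table, autocorrelation
    test, per-bin Kent table, power-law fits with CIs, quality flags).
    """
    cfg = config or CharacterizeConfig()
    rng = _as_rng(rng)
    if len(traj) < cfg.min_recommended_frames:
        warnings.warn(
            f"only {len(traj)} frames; parameter estimates (especially the "
            f"power laws) are unreliable below ~{cfg.min_recommended_frames}",
            stacklevel=2,
        )
    tau = _tau_of(traj)

    def _stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise type(exc)(f"[{name}] {exc}") from exc

    clean = _stage("impute", impute_positions, traj, cfg.max_missing_frac)
    if cfg.smoothing_cutoff_hz is not None:
        clean = _stage("smooth", smooth_positions, clean, cfg.smoothing_cutoff_hz)
    steps, turns = _stage("steps_and_turns", steps_and_turns, clean)
    g = _stage("fit_gamma", fit_gamma, steps, cfg.zero_floor_mm)
    aic = _stage("aic", aic_model_comparison, steps, cfg.zero_floor_mm)
    ac = _stage("autocorr", autocorr_randomisation_test, steps, cfg.n_perm, rng)
    fits = _stage("binned_kent", binned_kent_fits, turns, cfg.bin_width_mm, cfg.min_bin_count)
    kappa_fit, beta_fit = _stage("power_laws", fit_power_laws, fits, cfg.n_boot, rng)

    params = MovementParams(
        gamma=g,
        rho_s=max(0.0, min(ac.rho_s, 1.0 - 1e-9)),
        kappa_law=kappa_fit.law,
        beta_law=beta_fit.law,
        tau=tau,
    )
    median_step = float(np.median(steps))
    report = {
        "n_frames": int(len(traj)),
        "tau_s": tau,
        "median_step_mm": median_step,
        "near_immobile": bool(median_step < cfg.near_immobile_median_mm),
        "gamma": g.to_dict(),
        "aic_table": aic.to_dict(orient="records"),
        "autocorrelation": {
            "rho_s": ac.rho_s,
            "p_value": ac.p_value,
            "n_permutations": ac.n_permutations,
        },
        "kent_bins": [
            {
                "lo_mm": f.lo,
                "hi_mm": f.hi,
                "count": f.count,
                "kappa": f.params.kappa,
                "beta": f.params.beta,
            }
            for f in fits
        ],
        "kappa_law": {**kappa_fit.law.to_dict(), "k_ci": list(kappa_fit.k_ci), "d_ci": list(kappa_fit.d_ci)},
        "beta_law": {**beta_fit.law.to_dict(), "k_ci": list(beta_fit.k_ci), "d_ci": list(beta_fit.d_ci)},
        "config": asdict(cfg),
    }
    return params, report


# ---------------------------------------------------------------------------
# Population comparison
# ---------------------------------------------------------------------------


def hellinger_distance(p, q) -> float:
    """Hellinger distance between two discrete distributions on a shared binning.

    ``sqrt(1 - sum_i sqrt(p_i * q_i))``, a metric bounded in [0, 1]; 0 for
    identical distributions, 1 for disjoint supports.
    """
    p = np.asarray(p, dtype=float).ravel()
    q = np.asarray(q, dtype=float).ravel()
    if p.shape != q.shape:
        raise InputError("distributions must share one binning")
    if np.any(p < -1e-12) or np.any(q < -1e-12):
        raise InputError("probabilities must be non-negative")
    if abs(p.sum() - 1.0) > 1e-9 or abs(q.sum() - 1.0) > 1e-9:
        raise InputError("probability vectors must sum to 1 (tolerance 1e-9)")
    bc = float(np.sqrt(np.clip(p, 0, None) * np.clip(q, 0, None)).sum())
    return math.sqrt(max(0.0, 1.0 - bc))


def step_histograms(
    step_series: list[np.ndarray], bin_width: float = 1.0, upper: float | None = None
) -> np.ndarray:
    """Per-fish step-length histograms on a shared 1 mm binning.

    The shared range runs to the pooled 99.9th percentile (rounded up to a
    whole bin); longer steps are folded into the final bin so every row sums
    to 1.
    """
    if not step_series:
        raise InputError("no step series supplied")
    pooled = np.concatenate([np.asarray(s, dtype=float).ravel() for s in step_series])
    if upper is None:
        upper = float(np.percentile(pooled, 99.9))
    n_bins = max(1, int(np.ceil(upper / bin_width)))
    edges = np.arange(n_bins + 1) * bin_width
    out = np.empty((len(step_series), n_bins))
    for i, s in enumerate(step_series):
        s = np.clip(np.asarray(s, dtype=float).ravel(), 0.0, edges[-1] - 1e-12)
        counts, _ = np.histogram(s, bins=edges)
        out[i] = counts / counts.sum()
    return out


def turn_histograms(
    turn_list: list[TurnSamples], n_azimuth: int = 36, n_elevation: int = 18
) -> np.ndarray:
    """Per-fish turn-vector histograms on a flattened-sphere grid.

    Each local turn vector (forward, lateral, dorsoventral) is mapped to
    azimuth (horizontal turn angle) and elevation (vertical turn angle) and
    binned on an ``n_azimuth x n_elevation`` grid, matching the flattened
    spherical contour representation of turning distributions.
    """
    if not turn_list:
        raise InputError("no turn samples supplied")
    out = np.empty((len(turn_list), n_azimuth * n_elevation))
    az_edges = np.linspace(-np.pi, np.pi, n_azimuth + 1)
    el_edges = np.linspace(-np.pi / 2, np.pi / 2, n_elevation + 1)
    for i, t in enumerate(turn_list):
        v = t.vectors
        az = np.arctan2(v[:, 1], v[:, 0])
        el = np.arcsin(np.clip(v[:, 2], -1.0, 1.0))
        H, _, _ = np.histogram2d(az, el, bins=[az_edges, el_edges])
        out[i] = H.ravel() / H.sum()
    return out


def _pairwise_hellinger(hists: np.ndarray) -> np.ndarray:
    n = hists.shape[0]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = hellinger_distance(hists[i], hists[j])
    return D


def dissimilarity_matrices(
    step_series: list[np.ndarray],
    turn_list: list[TurnSamples],
    min_samples: int = 100,
    bin_width: float = 1.0,
    n_azimuth: int = 36,
    n_elevation: int = 18,
) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """Pairwise Hellinger dissimilarity between fish, for steps and turns.

    Fish with fewer than ``min_samples`` steps or turns are excluded with a
    warning.  Returns (step matrix, turn matrix, kept indices).
    """
    if len(step_series) != len(turn_list):
        raise InputError("step and turn lists must be parallel")
    if len(step_series) < 3:
        raise InputError("need at least 3 fish")
    kept = [
        i
        for i in range(len(step_series))
        if len(np.ravel(step_series[i])) >= min_samples and len(turn_list[i]) >= min_samples
    ]
    dropped = sorted(set(range(len(step_series))) - set(kept))
    if dropped:
        warnings.warn(f"excluding fish with < {min_samples} samples: {dropped}", stacklevel=2)
    if len(kept) < 3:
        raise InputError("fewer than 3 fish remain after the sample-size filter")
    sh = step_histograms([np.ravel(step_series[i]) for i in kept], bin_width)
    th = turn_histograms([turn_list[i] for i in kept], n_azimuth, n_elevation)
    return _pairwise_hellinger(sh), _pairwise_hellinger(th), kept


def classical_mds(D, dims: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Classical (Torgerson) MDS: principal coordinates of a distance matrix.

    Double-centres ``-D**2 / 2`` and takes the top ``dims`` eigenpairs.
    Returns (coordinates, all eigenvalues, descending).  A warning is issued
    when negative eigenvalues dominate (the matrix is then far from
    Euclidean and the embedding unreliable).
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n) or not np.allclose(D, D.T, atol=1e-8):
        raise InputError("D must be a square symmetric matrix")
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    neg = float(np.abs(evals[evals < 0]).sum())
    pos = float(evals[evals > 0].sum())
    if pos > 0 and neg > pos:
        warnings.warn(
            f"negative eigenvalues dominate (sum |neg| = {neg:.3g} > sum pos = {pos:.3g})",
            stacklevel=2,
        )
    lam = np.clip(evals[:dims], 0.0, None)
    coords = evecs[:, :dims] * np.sqrt(lam)
    return coords, evals


@dataclass(frozen=True)
class MRMResult:
    """Distance-matrix regression: slope, fit and permutation p value."""

    coefficient: float
    r_squared: float
    pseudo_t: float
    p_value: float
    n_permutations: int


def _lower_triangle(D: np.ndarray) -> np.ndarray:
    iu = np.tril_indices(D.shape[0], k=-1)
    return D[iu]


def _ols_t(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Slope, t statistic and R^2 of y ~ 1 + x."""
    m = x.size
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float(xc @ xc)
    if sxx == 0.0:
        raise DegenerateDataError("predictor distances are constant")
    slope = float(xc @ yc) / sxx
    resid = yc - slope * xc
    sse = float(resid @ resid)
    syy = float(yc @ yc)
    r2 = 1.0 - sse / syy if syy > 0 else 1.0
    df = m - 2
    se = math.sqrt(sse / df / sxx) if df > 0 and sse > 0 else 0.0
    t = slope / se if se > 0 else math.inf * np.sign(slope)
    return slope, t, r2


def distance_matrix_regression(
    response, predictor, n_perm: int = 999, rng=None
) -> MRMResult:
    """Regression between two dissimilarity matrices with a permutation test.

    The lower triangles are vectorised and regressed by OLS; significance
    comes from jointly permuting the rows and columns of the *response*
    matrix (which respects the dependence among entries sharing an object):
    ``p = (1 + #{|t*| >= |t_hat|}) / (n_perm + 1)``, two-sided.
    """
    rng = _as_rng(rng)
    R = np.asarray(response, dtype=float)
    X = np.asarray(predictor, dtype=float)
    n = R.shape[0]
    if R.shape != X.shape or R.shape != (n, n):
        raise InputError("response and predictor must be equal-size square matrices")
    if n < 4:
        raise InputError("need at least 4 objects")
    x = _lower_triangle(X)
    y = _lower_triangle(R)
    slope, t_obs, r2 = _ols_t(x, y)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        yp = _lower_triangle(R[np.ix_(perm, perm)])
        _, t_star, _ = _ols_t(x, yp)
        if abs(t_star) >= abs(t_obs) - 1e-12:
            hits += 1
    p = (1 + hits) / (n_perm + 1)
    return MRMResult(coefficient=slope, r_squared=r2, pseudo_t=t_obs, p_value=p, n_permutations=n_perm)


def size_distance_matrix(standard_lengths) -> np.ndarray:
    """Pairwise absolute differences in standard length (mm) between fish."""
    L = np.asarray(standard_lengths, dtype=float).ravel()
    if L.size < 3:
        raise InputError("need at least 3 fish")
    if np.any(~np.isfinite(L)) or np.any(L <= 0):
        raise InputError("standard lengths must be positive")
    return np.abs(L[:, None] - L[None, :])
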