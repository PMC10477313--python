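"""Inverse pipeline: cleaning, steps/turns, binned fits, population comparison."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import special, stats

from sticklesim.characterize import (
    BinnedKentFit,
    CharacterizeConfig,
    TurnSamples,
    binned_kent_fits,
    classical_mds,
    dissimilarity_matrices,
    distance_matrix_regression,
    fit_movement_params,
    fit_power_laws,
    hellinger_distance,
    impute_positions,
    size_distance_matrix,
    smooth_positions,
    steps_and_turns,
    step_histograms,
)
from sticklesim.directional import KentParams, kent_sample
from sticklesim.errors import InputError, QualityError
from sticklesim.fixtures import REGIME_PARAMS
from sticklesim.simulate import DEFAULT_TANK, simulate_path, trajectory_from_positions
from sticklesim.stepproc import sample_correlated_gamma, GammaParams


def make_traj(P):
    return trajectory_from_positions(np.asarray(P, dtype=float))


class TestImpute:
    def test_identity_without_missing(self, rng):
        traj = make_traj(rng.random((50, 3)) * 10)
        out = impute_positions(traj)
        pd.testing.assert_frame_equal(out, traj)

    def test_linear_motion_recovered_exactly(self):
        t = np.arange(100.0)
        P = np.column_stack([2 * t, -t, 0.5 * t])
        traj = make_traj(P)
        traj.loc[[20, 21, 40, 55, 70], ["x_mm", "y_mm", "z_mm"]] = np.nan
        out = impute_positions(traj)
        np.testing.assert_allclose(out[["x_mm", "y_mm", "z_mm"]].to_numpy(), P, atol=1e-9)

    def test_sine_gap_error_bound(self):
        # 0.5 Hz sine sampled at 10 Hz, 10 mm amplitude, 3-frame gaps
        t = np.arange(200) * 0.1
        x = 10 * np.sin(2 * np.pi * 0.5 * t)
        P = np.column_stack([x, np.zeros_like(x), np.zeros_like(x)])
        traj = make_traj(P)
        for start in (30, 80, 130):
            traj.loc[start : start + 2, "x_mm"] = np.nan
        out = impute_positions(traj)
        err = np.max(np.abs(out["x_mm"].to_numpy() - x))
        assert err < 0.1

    def test_leading_trailing_gaps_filled_nearest(self):
        P = np.column_stack([np.arange(20.0), np.zeros(20), np.zeros(20)])
        traj = make_traj(P)
        traj.loc[[0, 1], "x_mm"] = np.nan
        traj.loc[[18, 19], "x_mm"] = np.nan
        out = impute_positions(traj)
        assert out["x_mm"].iloc[0] == out["x_mm"].iloc[2]
        assert out["x_mm"].iloc[19] == out["x_mm"].iloc[17]

    def test_quality_gate(self, rng):
        traj = make_traj(rng.random((100, 3)))
        traj.loc[: 30, "x_mm"] = np.nan
        with pytest.raises(QualityError):
            impute_positions(traj)


class TestSmooth:
    def test_constant_unchanged(self):
        traj = make_traj(np.tile([1.0, 2.0, 3.0], (200, 1)))
        out = smooth_positions(traj, 2.0)
        np.testing.assert_allclose(
            out[["x_mm", "y_mm", "z_mm"]].to_numpy(),
            traj[["x_mm", "y_mm", "z_mm"]].to_numpy(),
            atol=1e-9,
        )

    def test_passband_sine_preserved(self):
        t = np.arange(1000) * 0.1
        x = 10 * np.sin(2 * np.pi * 0.2 * t)
        traj = make_traj(np.column_stack([x, x, x]))
        out = smooth_positions(traj, 2.0)
        y = out["x_mm"].to_numpy()[200:-200]
        assert np.max(np.abs(y)) == pytest.approx(10.0, rel=0.01)

    def test_stopband_sine_attenuated(self):
        t = np.arange(1000) * 0.1
        x = 10 * np.sin(2 * np.pi * 4.5 * t)
        traj = make_traj(np.column_stack([x, x, x]))
        out = smooth_positions(traj, 2.0)
        y = out["x_mm"].to_numpy()[200:-200]
        assert np.max(np.abs(y)) < 1.0  # > 90% attenuation

    def test_zero_phase(self):
        t = np.arange(2000) * 0.1
        x = np.sin(2 * np.pi * 0.3 * t)
        traj = make_traj(np.column_stack([x, x, x]))
        y = smooth_positions(traj, 2.0)["x_mm"].to_numpy()
        lags = np.arange(-5, 6)
        xc = [np.dot(x[5:-5], y[5 + lag : len(y) - 5 + lag]) for lag in lags]
        assert lags[int(np.argmax(xc))] == 0

    def test_cutoff_above_nyquist_rejected(self):
        traj = make_traj(np.zeros((50, 3)))
        with pytest.raises(InputError):
            smooth_positions(traj, 5.0)


class TestStepsAndTurns:
    def test_straight_line_turns_at_pole(self):
        P = np.column_stack([np.arange(10.0) * 2, np.zeros(10), np.zeros(10)])
        steps, turns = steps_and_turns(make_traj(P))
        assert len(steps) == 9 and len(turns) == 8
        np.testing.assert_allclose(turns.vectors, np.tile([1.0, 0.0, 0.0], (8, 1)), atol=1e-12)

    def test_planar_left_turn(self):
        P = np.array([[0.0, 0.0, 5.0], [1.0, 0.0, 5.0], [1.0, 1.0, 5.0]])
        _, turns = steps_and_turns(make_traj(P))
        v = turns.vectors[0]
        assert abs(v[0]) < 1e-12
        assert abs(abs(v[1]) - 1.0) < 1e-12  # lateral component
        assert abs(v[2]) < 1e-12  # no dorsoventral component

    def test_three_four_five_step(self):
        P = np.array([[0.0, 0.0, 0.0], [3.0, 4.0, 0.0], [6.0, 8.0, 0.0]])
        steps, _ = steps_and_turns(make_traj(P))
        assert steps[0] == pytest.approx(5.0)

    def test_zero_displacement_frames_skipped_but_frame_carried(self):
        P = np.array(
            [[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [1.0, 0.0, 0.0], [2.0, 0.0, 0.0]]
        )
        steps, turns = steps_and_turns(make_traj(P))
        assert len(steps) == 3
        # the rest frame emits no turn; the move after it refers to the frame
        # of the last nonzero displacement
        assert len(turns) == 1
        np.testing.assert_allclose(turns.vectors[0], [1.0, 0.0, 0.0], atol=1e-12)
        assert turns.s[0] == pytest.approx(1.0)

    def test_too_short_rejected(self):
        with pytest.raises(InputError):
            steps_and_turns(make_traj(np.zeros((2, 3))))


def synthetic_turns(rng, n=20000, lo=0.5, hi=8.5, kappa_law=(2.0, 1.0), beta_law=(0.5, 1.0)):
    s = rng.uniform(lo, hi, n)
    e = np.eye(3)
    vecs = np.empty((n, 3))
    order = np.argsort(s)
    # draw in blocks of similar s for speed; per-sample parameters
    for i in order:
        kappa = kappa_law[0] * s[i] ** kappa_law[1]
        beta = min(beta_law[0] * s[i] ** beta_law[1], kappa / 2)
        vecs[i] = kent_sample(KentParams(kappa, beta, e[0], e[1], e[2]), 1, rng)[0]
    return TurnSamples(s=s, vectors=vecs)


class TestBinnedKentFits:
    def test_concentration_increases_across_bins(self, rng):
        turns = synthetic_turns(rng, n=12000, lo=0.0, hi=6.0)
        fits = binned_kent_fits(turns, min_count=1000)
        kappas = [f.params.kappa for f in fits]
        assert len(fits) >= 3
        assert all(b > a for a, b in zip(kappas, kappas[1:]))

    def test_sparse_bin_excluded(self, rng):
        s = np.concatenate([np.full(999, 0.5), np.full(1500, 1.5)])
        vecs = kent_sample(
            KentParams(5.0, 1.0, *np.eye(3)), len(s), rng
        )
        fits = binned_kent_fits(TurnSamples(s=s, vectors=vecs), min_count=1000)
        assert [f.lo for f in fits] == [1.0]
        assert fits[0].count == 1500

    def test_half_open_bin_edges(self, rng):
        s = np.full(1200, 1.0)  # exactly 1.0 mm falls in [1, 2)
        vecs = kent_sample(KentParams(5.0, 1.0, *np.eye(3)), 1200, rng)
        fits = binned_kent_fits(TurnSamples(s=s, vectors=vecs), min_count=1000)
        assert len(fits) == 1 and fits[0].lo == 1.0 and fits[0].hi == 2.0

    def test_no_bin_reaching_threshold_warns(self, rng):
        vecs = kent_sample(KentParams(5.0, 1.0, *np.eye(3)), 100, rng)
        with pytest.warns(UserWarning):
            fits = binned_kent_fits(TurnSamples(s=np.full(100, 0.5), vectors=vecs))
        assert fits == []


def exact_fits(midpoints, kappa_law, beta_law):
    e = np.eye(3)
    out = []
    for m in midpoints:
        kappa = kappa_law[0] * m ** kappa_law[1]
        beta = min(beta_law[0] * m ** beta_law[1], kappa / 2)
        out.append(
            BinnedKentFit(m - 0.5, m + 0.5, 2000, KentParams(kappa, beta, e[0], e[1], e[2]))
        )
    return out


class TestFitPowerLaws:
    def test_noiseless_recovery(self, rng):
        fits = exact_fits(np.arange(10) + 0.5, (2.0, 0.7), (0.5, 0.6))
        k_fit, b_fit = fit_power_laws(fits, n_boot=50, rng=rng)
        assert k_fit.law.k == pytest.approx(2.0, abs=1e-6)
        assert k_fit.law.d == pytest.approx(0.7, abs=1e-6)
        assert b_fit.law.k == pytest.approx(0.5, abs=1e-6)
        assert b_fit.law.d == pytest.approx(0.6, abs=1e-6)

    def test_bootstrap_ci_coverage(self, rng):
        """True (k, d) fall inside the percentile 95% CI in ~95% of noisy
        replicates (10% relative noise, 9 bins)."""
        k_true, d_true = 2.0, 0.7
        mids = np.arange(9) + 0.5
        hits = 0
        n_rep = 150
        for _ in range(n_rep):
            y = k_true * mids**d_true * (1 + 0.1 * rng.standard_normal(9))
            fits = [
                BinnedKentFit(
                    m - 0.5,
                    m + 0.5,
                    2000,
                    KentParams(max(yy, 1e-6), 0.0, *np.eye(3)),
                )
                for m, yy in zip(mids, np.abs(y))
            ]
            k_fit, _ = fit_power_laws(fits, n_boot=300, rng=rng)
            if k_fit.k_ci[0] <= k_true <= k_fit.k_ci[1] and k_fit.d_ci[0] <= d_true <= k_fit.d_ci[1]:
                hits += 1
        assert hits / n_rep >= 0.9

    def test_single_bin_rejected(self, rng):
        fits = exact_fits([1.5], (2.0, 0.7), (0.5, 0.6))
        with pytest.raises(InputError):
            fit_power_laws(fits, n_boot=10, rng=rng)


class TestHellinger:
    def test_identical_distributions(self):
        p = np.array([0.2, 0.3, 0.5])
        assert hellinger_distance(p, p) == 0.0

    def test_disjoint_supports(self):
        assert hellinger_distance([1.0, 0.0], [0.0, 1.0]) == pytest.approx(1.0)

    def test_matches_gamma_closed_form(self, rng):
        a1, a2 = 2.0, 4.0
        x = rng.gamma(a1, 1.0, 1_000_000)
        y = rng.gamma(a2, 1.0, 1_000_000)
        edges = np.arange(0, 30.0, 0.1)
        p = np.histogram(np.clip(x, 0, 29.89), bins=edges)[0].astype(float)
        q = np.histogram(np.clip(y, 0, 29.89), bins=edges)[0].astype(float)
        h = hellinger_distance(p / p.sum(), q / q.sum())
        bc = math.exp(
            special.gammaln((a1 + a2) / 2)
            - 0.5 * (special.gammaln(a1) + special.gammaln(a2))
        )  # rates equal: scale terms cancel
        h_exact = math.sqrt(1 - bc)
        assert h == pytest.approx(h_exact, abs=0.01)

    def test_mismatched_binning_rejected(self):
        with pytest.raises(InputError):
            hellinger_distance([0.5, 0.5], [0.3, 0.3, 0.4])

    def test_unnormalised_rejected(self):
        with pytest.raises(InputError):
            hellinger_distance([0.5, 0.4], [0.5, 0.5])

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_triangle_inequality(self, seed):
        r = np.random.default_rng(seed)
        P = r.random((3, 8)) + 1e-12
        P /= P.sum(axis=1, keepdims=True)
        d01 = hellinger_distance(P[0], P[1])
        d12 = hellinger_distance(P[1], P[2])
        d02 = hellinger_distance(P[0], P[2])
        assert d02 <= d01 + d12 + 1e-12


class TestDissimilarityMatrices:
    def _fish(self, rng, mean_scale):
        steps = sample_correlated_gamma(GammaParams(2.0, 2.0 / mean_scale), 0.5, 3000, rng)
        vecs = kent_sample(KentParams(4.0, 1.0, *np.eye(3)), 2999, rng)
        return steps, TurnSamples(s=steps[:-1], vectors=vecs)

    def test_duplicate_fish_zero_distance(self, rng):
        s, t = self._fish(rng, 2.0)
        s2, t2 = self._fish(rng, 6.0)
        D, Dt, kept = dissimilarity_matrices([s, s, s2], [t, t, t2])
        assert D[0, 1] == pytest.approx(0.0, abs=1e-12)
        assert kept == [0, 1, 2]

    def test_symmetry_and_zero_diagonal(self, rng):
        data = [self._fish(rng, m) for m in (1.0, 3.0, 6.0, 9.0)]
        D, Dt, _ = dissimilarity_matrices([d[0] for d in data], [d[1] for d in data])
        for M in (D, Dt):
            np.testing.assert_allclose(M, M.T)
            np.testing.assert_allclose(np.diag(M), 0.0)
            assert (M >= 0).all() and (M <= 1).all()

    def test_groups_separate(self, rng):
        scales = [1.0, 1.1, 0.9, 4.0, 4.2, 3.8, 9.0, 9.5, 8.7]
        data = [self._fish(rng, m) for m in scales]
        D, _, _ = dissimilarity_matrices([d[0] for d in data], [d[1] for d in data])
        groups = np.repeat([0, 1, 2], 3)
        within = [D[i, j] for i in range(9) for j in range(i + 1, 9) if groups[i] == groups[j]]
        between = [D[i, j] for i in range(9) for j in range(i + 1, 9) if groups[i] != groups[j]]
        assert np.mean(within) < np.mean(between)

    def test_small_fish_excluded(self, rng):
        s, t = self._fish(rng, 2.0)
        tiny_s = s[:50]
        tiny_t = TurnSamples(s=t.s[:50], vectors=t.vectors[:50])
        data = [self._fish(rng, m) for m in (1.0, 3.0, 6.0)]
        with pytest.warns(UserWarning):
            _, _, kept = dissimilarity_matrices(
                [d[0] for d in data] + [tiny_s], [d[1] for d in data] + [tiny_t]
            )
        assert kept == [0, 1, 2]


class TestClassicalMDS:
    def test_recovers_planar_configuration(self, rng):
        X = rng.random((10, 2)) * 5
        D = np.linalg.norm(X[:, None, :] - X[None, :, :], axis=2)
        coords, evals = classical_mds(D)
        Dr = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)
        np.testing.assert_allclose(Dr, D, atol=1e-6)

    def test_all_zero_matrix(self):
        coords, _ = classical_mds(np.zeros((5, 5)))
        np.testing.assert_allclose(coords, 0.0, atol=1e-12)

    def test_345_triangle(self):
        D = np.array([[0.0, 3, 4], [3, 0, 5], [4, 5, 0]])
        coords, _ = classical_mds(D)
        Dr = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)
        np.testing.assert_allclose(Dr, D, atol=1e-9)


class TestDistanceMatrixRegression:
    @staticmethod
    def _random_distance_matrix(rng, n):
        X = rng.random((n, 3))
        return np.linalg.norm(X[:, None, :] - X[None, :, :], axis=2)

    def test_perfect_predictor(self, rng):
        D = self._random_distance_matrix(rng, 10)
        res = distance_matrix_regression(D, D, n_perm=999, rng=rng)
        assert res.r_squared == pytest.approx(1.0)
        assert res.coefficient == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1 / 1000)

    def test_power_against_noisy_copy(self, rng):
        D = self._random_distance_matrix(rng, 15)
        noisy = np.abs(D + 0.05 * rng.standard_normal(D.shape))
        noisy = (noisy + noisy.T) / 2
        np.fill_diagonal(noisy, 0.0)
        res = distance_matrix_regression(noisy, D, n_perm=499, rng=rng)
        assert res.p_value <= 0.01

    def test_dimension_mismatch_rejected(self, rng):
        with pytest.raises(InputError):
            distance_matrix_regression(np.zeros((4, 4)), np.zeros((5, 5)), rng=rng)


class TestSizeDistanceMatrix:
    def test_values(self):
        D = size_distance_matrix([40.0, 42.0, 45.0])
        assert D[0, 2] == pytest.approx(5.0)
        np.testing.assert_allclose(D, D.T)
        np.testing.assert_allclose(np.diag(D), 0.0)

    def test_identical_lengths_zero(self):
        np.testing.assert_allclose(size_distance_matrix([40.0] * 4), 0.0)

    def test_non_positive_rejected(self):
        with pytest.raises(InputError):
            size_distance_matrix([40.0, -1.0, 42.0])


class TestFullPipeline:
    def test_near_immobile_flagged(self, rng):
        from sticklesim.fixtures import _OUTLIER_PARAMS

        traj = simulate_path(_OUTLIER_PARAMS, DEFAULT_TANK, 6000, rng)
        cfg = CharacterizeConfig(smoothing_cutoff_hz=None, n_perm=99, n_boot=50)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            with pytest.raises(Exception):
                # near-immobile fish lacks enough long-step bins for power laws
                fit_movement_params(traj, cfg, rng)
        steps = np.linalg.norm(
            np.diff(traj[["x_mm", "y_mm", "z_mm"]].to_numpy(), axis=0), axis=1
        )
        assert np.median(steps) < 0.05

    def test_unnatural_data_not_gamma_by_aic(self, rng):
        from sticklesim.simulate import simulate_unnatural_path
        from sticklesim.stepproc import aic_model_comparison

        traj = simulate_unnatural_path(REGIME_PARAMS["medium"], DEFAULT_TANK, 5000, rng)
        steps = np.linalg.norm(
            np.diff(traj[["x_mm", "y_mm", "z_mm"]].to_numpy(), axis=0), axis=1
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table = aic_model_comparison(steps)
        assert table.iloc[0]["distribution"] != "gamma"

    def test_smoothing_near_passband_is_near_identity(self, rng):
        traj = simulate_path(REGIME_PARAMS["medium"], DEFAULT_TANK, 12_000, rng)
        cfg_off = CharacterizeConfig(smoothing_cutoff_hz=None, n_perm=99, n_boot=50)
        cfg_on = CharacterizeConfig(smoothing_cutoff_hz=4.9, n_perm=99, n_boot=50)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p_off, _ = fit_movement_params(traj, cfg_off, np.random.default_rng(1))
            p_on, _ = fit_movement_params(traj, cfg_on, np.random.default_rng(1))
        assert p_on.gamma.mean == pytest.approx(p_off.gamma.mean, rel=0.01)
        assert p_on.rho_s == pytest.approx(p_off.rho_s, abs=0.01)

    def test_report_structure(self, rng):
        traj = simulate_path(REGIME_PARAMS["medium"], DEFAULT_TANK, 12_000, rng)
        cfg = CharacterizeConfig(smoothing_cutoff_hz=None, n_perm=99, n_boot=50)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            params, report = fit_movement_params(traj, cfg, rng)
        for key in ("gamma", "aic_table", "autocorrelation", "kent_bins", "kappa_law", "beta_law"):
            assert key in report
        assert report["near_immobile"] is False
        assert report["autocorrelation"]["p_value"] <= 0.05
        import json

        json.dumps(report)  # must be serialisable
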