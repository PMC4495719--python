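"""Closure solver: component contracts and end-to-end recovery."""

import numpy as np
import pytest

from mohcaseq.cohcoa import (
    CohcoaConfig,
    _attenuation_from_R,
    fit_background,
    initialize,
    propagate_errors,
    run,
    update_attenuation,
    update_Q,
)
from mohcaseq.errors import ConfigurationError
from mohcaseq.forward_model import simulate_planted_dataset, PlantedContact
from mohcaseq.maps_io import CountMatrix, RnaSequence, upper_mask

from oracles import weighted_rank1_fit


def matrix(F, seq=None, err=None):
    L = F.shape[0]
    seq = seq or RnaSequence(name=f"t{L}", residues="N" * L)
    return CountMatrix(F=F, seq=seq, F_err=err)


class TestConfig:
    def test_default_rho(self):
        assert CohcoaConfig().rho == 2.5

    def test_rho_outside_robust_range(self):
        with pytest.raises(ConfigurationError):
            CohcoaConfig(rho=0.5)

    def test_default_iterations(self):
        assert CohcoaConfig().n_iterations == 40


class TestFitBackground:
    def test_exact_rank1_recovered(self):
        r = np.array([0.1, 0.2, 0.3])
        b = np.array([1.0, 2.0, 3.0])
        X = np.outer(r, b)
        mask = upper_mask(3)
        R, B = fit_background(X, np.ones_like(X), mask)
        np.testing.assert_allclose(np.outer(R, B)[mask], X[mask], atol=1e-10)

    def test_all_zero_input(self):
        mask = upper_mask(3)
        R, B = fit_background(np.zeros((3, 3)), np.ones((3, 3)), mask)
        assert np.all(R == 0) and np.all(B == 0)

    def test_outlier_downweighted_matches_bruteforce(self):
        # an outlier cell with low weight barely perturbs the product,
        # matching a generic bounded optimizer on the same objective
        rng = np.random.default_rng(0)
        n = 5
        r = rng.uniform(0.5, 1.5, n)
        b = rng.uniform(0.5, 1.5, n)
        X = np.outer(r, b)
        X[0, 4] += 50.0
        W = np.ones_like(X)
        W[0, 4] = 1e-4
        mask = upper_mask(n)
        R, B = fit_background(X, W, mask)
        ours = np.outer(R, B)
        oracle = weighted_rank1_fit(X, W, mask)
        clean = mask.copy()
        clean[0, 4] = False
        np.testing.assert_allclose(ours[clean], oracle[clean], rtol=0.05)
        np.testing.assert_allclose(ours[clean], np.outer(r, b)[clean], rtol=0.05)


class TestUpdateQ:
    def test_exact_plaid_gives_zero(self):
        L = 4
        R = np.array([0.1, 0.2, 0.1, 0.05])
        B = np.array([1.0, 2.0, 1.5, 3.0])
        A = _attenuation_from_R(R)
        F = np.where(upper_mask(L), A * np.outer(R, B), 0.0)
        Q = update_Q(matrix(F), A, R, B)
        np.testing.assert_allclose(Q, 0.0, atol=1e-12)

    def test_arithmetic_and_clipping(self):
        L = 3
        F = np.zeros((L, L))
        F[0, 1] = 5.0
        F[0, 2] = 1.0
        A = np.ones((L, L))
        R = np.array([1.0, 0.0, 0.0])
        B = np.array([0.0, 3.0, 3.0])
        Q = update_Q(matrix(F), A, R, B)
        assert Q[0, 1] == pytest.approx(2.0)   # 5/1 - 3
        assert Q[0, 2] == 0.0                  # 1/1 - 3 clipped to zero


class TestUpdateAttenuation:
    def test_q_zero_reduces_to_survival_product(self):
        L = 4
        R = np.full(L, 0.1)
        F = matrix(np.where(upper_mask(L), 1.0, 0.0))
        A, _ = update_attenuation(F, R, np.ones(L), np.zeros((L, L)),
                                  CohcoaConfig())
        assert A[0, 3] == pytest.approx(0.81)  # (1 - 0.1)^2 over m in {2,3}
        assert A[0, 1] == 1.0                  # adjacent: empty product

    def test_no_background_no_signal_gives_unity(self):
        L = 5
        F = matrix(np.where(upper_mask(L), 1.0, 0.0))
        A, A_err = update_attenuation(F, np.zeros(L), np.zeros(L),
                                      np.zeros((L, L)), CohcoaConfig())
        np.testing.assert_allclose(A[upper_mask(L)], 1.0)
        np.testing.assert_allclose(A_err, 0.0)

    def test_signal_strengthens_attenuation(self):
        L = 5
        mask = upper_mask(L)
        F = matrix(np.where(mask, 100.0, 0.0))
        R = np.full(L, 0.05)
        B = np.full(L, 0.5)
        Q = np.zeros((L, L))
        A0, _ = update_attenuation(F, R, B, Q, CohcoaConfig())
        Q[0, 2] = 60.0  # strong correlated damage between 1 and 4
        A1, _ = update_attenuation(F, R, B, Q, CohcoaConfig())
        assert A1[0, 4] < A0[0, 4]


class TestPropagateErrors:
    def test_unit_attenuation_passes_f_errors(self):
        L = 3
        F = matrix(np.where(upper_mask(L), 100.0, 0.0))
        A = np.ones((L, L))
        Q_err = propagate_errors(F, A, np.zeros((L, L)))
        np.testing.assert_allclose(Q_err[upper_mask(L)], 10.0)

    def test_quadrature_combination(self):
        L = 2
        F = np.zeros((L, L))
        F[0, 1] = 100.0
        err = np.zeros((L, L))
        err[0, 1] = 10.0
        A = np.full((L, L), 0.5)
        # A exact: error is F_err / A = 20
        Q_err = propagate_errors(matrix(F, err=err), A, np.zeros((L, L)))
        assert Q_err[0, 1] == pytest.approx(20.0)
        # A uncertain by 0.05: add F * A_err / A^2 = 20 in quadrature
        A_err = np.zeros((L, L))
        A_err[0, 1] = 0.05
        Q_err = propagate_errors(matrix(F, err=err), A, A_err)
        assert Q_err[0, 1] == pytest.approx(np.sqrt(20**2 + 20**2))


class TestInitialize:
    def test_all_zero_counts_fall_back(self):
        L = 20
        F = matrix(np.zeros((L, L)))
        R, A = initialize(F, CohcoaConfig(flank_region=(17, 20)))
        assert np.all(R.values == CohcoaConfig().fallback_stop_rate)
        assert np.all(A[upper_mask(L)] <= 1.0)
        assert A[0, L - 1] < 1.0

    def test_recovers_constant_stop_rate(self):
        data = simulate_planted_dataset(60, [], r=0.05, b=0.02,
                                        read_depth=2e6, seed=3)
        R, _ = initialize(data["counts"], CohcoaConfig(flank_region=(53, 60)))
        interior = R.values[4:50]
        assert np.all(np.abs(interior - 0.05) <= 0.2 * 0.05)

    def test_empty_flank_is_configuration_error(self, toy_counts):
        with pytest.raises(ConfigurationError):
            initialize(toy_counts, CohcoaConfig(flank_region=(4, 2)))

    def test_single_column_flank(self):
        data = simulate_planted_dataset(30, [], read_depth=1e5, seed=1)
        R, A = initialize(data["counts"], CohcoaConfig(flank_region=(30, 30)))
        assert np.all(np.isfinite(R.values))


class TestRun:
    def test_background_only_is_null_within_errors(self):
        data = simulate_planted_dataset(60, [], r=0.01, b=0.01,
                                        read_depth=3e5, seed=4)
        res = run(data["counts"], CohcoaConfig(flank_region=(55, 60)))
        mask = res.Q.mask
        frac = np.mean(res.Q.Q[mask] <= 3 * res.Q.Q_err[mask])
        assert frac >= 0.99

    def test_planted_contact_found_at_peak_snr(self):
        contact = PlantedContact(i=12, j=40, amplitude=0.05,
                                 source_fraction=0.02)
        data = simulate_planted_dataset(60, [contact], r=0.01, b=0.01,
                                        read_depth=5e5, seed=8)
        res = run(data["counts"], CohcoaConfig(flank_region=(55, 60)))
        snr = res.Q.snr()
        i, j = np.unravel_index(np.argmax(snr), snr.shape)
        assert abs((i + 1) - 12) <= 2 and abs((j + 1) - 40) <= 2

    def test_fixed_point_reconstruction(self):
        # noiseless data generated exactly as F = A(R, B, Q) (R B + Q) is
        # reproduced by the solver's decomposition to high relative accuracy
        L = 40
        rng = np.random.default_rng(2)
        R_true = 0.015 + 0.01 * rng.random(L)
        B_true = 0.01 + 0.005 * rng.random(L)
        Q_true = np.zeros((L, L))
        for (i, j) in [(5, 25), (12, 33), (8, 30)]:
            Q_true[i, j] = 8.0 * R_true[i] * B_true[j]
        Q_true[~upper_mask(L)] = 0.0
        dummy = matrix(np.where(upper_mask(L), 1.0, 0.0),
                       err=np.zeros((L, L)))
        A_true, _ = update_attenuation(dummy, R_true, B_true, Q_true,
                                       CohcoaConfig(), epsilon_floor=1e-12)
        scale = 2e6
        F = np.where(upper_mask(L),
                     scale * A_true * (np.outer(R_true, B_true) + Q_true), 0.0)
        # noiseless data: zero counting errors, known normalization
        counts = matrix(F, err=np.zeros((L, L)))
        res = run(counts, CohcoaConfig(flank_region=(35, 40),
                                       convergence_tol=0.0,
                                       transcript_count=scale))
        mask = counts.mask
        recon = res.A * (np.outer(res.R.values, res.B.values) + res.Q.Q)
        rel = np.linalg.norm((recon - F)[mask]) / np.linalg.norm(F[mask])
        assert rel < 1e-3

    def test_trace_recorded_and_converged_flag(self):
        data = simulate_planted_dataset(40, [], read_depth=1e5, seed=6)
        res = run(data["counts"], CohcoaConfig(flank_region=(36, 40)))
        assert len(res.trace) >= 1
        assert res.converged_at is not None
        assert res.trace[-1] < CohcoaConfig().convergence_tol

    def test_extra_iterations_stay_converged(self):
        # once below tolerance, further cycles change Q by less than the
        # tolerance per iteration
        data = simulate_planted_dataset(40, [], read_depth=1e5, seed=6)
        res = run(data["counts"], CohcoaConfig(flank_region=(36, 40),
                                               convergence_tol=0.0))
        assert all(v < 0.01 for v in res.trace[-5:])
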