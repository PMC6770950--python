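"""MCR-ALS engine: LOF, constrained steps (with brute-force oracles), fit."""

import itertools

import numpy as np
import pytest
from scipy import optimize

import rennetmon as rm
from rennetmon.mcr import match_components


def brute_force_nnls(A: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Nonnegative least squares by enumerating every active set.

    For each subset Z of coefficients pinned at zero, solve the
    unconstrained problem on the complement and keep the feasible
    solution with the smallest residual. Exponential, but exact — the
    independent oracle for the per-row constrained concentration step.
    """
    n = A.shape[1]
    best_x, best_r = np.zeros(n), float(np.linalg.norm(b))
    for k in range(1, n + 1):
        for free in itertools.combinations(range(n), k):
            sub = A[:, list(free)]
            coef, *_ = np.linalg.lstsq(sub, b, rcond=None)
            if np.any(coef < -1e-12):
                continue
            x = np.zeros(n)
            x[list(free)] = np.clip(coef, 0.0, None)
            r = float(np.linalg.norm(A @ x - b))
            if r < best_r - 1e-12:
                best_x, best_r = x, r
    return best_x


def qp_unimodal(x: np.ndarray, peak: int) -> np.ndarray:
    """Least-squares unimodal projection by a general-purpose QP solver."""
    n = x.size
    cons = []
    for i in range(n - 1):
        if i < peak:
            cons.append({"type": "ineq", "fun": lambda y, i=i: y[i + 1] - y[i]})
        else:
            cons.append({"type": "ineq", "fun": lambda y, i=i: y[i] - y[i + 1]})
    res = optimize.minimize(
        lambda y: np.sum((y - x) ** 2),
        x0=np.full(n, x.mean()),
        jac=lambda y: 2.0 * (y - x),
        constraints=cons,
        method="SLSQP",
        options={"maxiter": 500, "ftol": 1e-14},
    )
    assert res.success
    return res.x


class TestLOF:
    def test_perfect_fit_zero(self, noiseless_batch):
        D = noiseless_batch.absorbance
        assert rm.lof(D, D) == 0.0

    def test_zero_prediction_is_hundred_percent(self):
        assert rm.lof(np.array([[3.0, 4.0]]), np.zeros((1, 2))) == pytest.approx(100.0)

    def test_partial_fit_literal_value(self):
        got = rm.lof(np.array([[3.0, 4.0]]), np.array([[3.0, 0.0]]))
        assert got == pytest.approx(80.0)  # 100*sqrt(16/25)

    def test_all_zero_data_rejected(self):
        with pytest.raises(ValueError):
            rm.lof(np.zeros((2, 2)), np.zeros((2, 2)))


class TestEnforceUnimodality:
    def test_already_unimodal_unchanged(self):
        x = np.array([0.1, 0.5, 1.0, 0.4, 0.2])
        np.testing.assert_array_equal(rm.enforce_unimodality(x), x)

    def test_literal_pava_example(self):
        out = rm.enforce_unimodality(np.array([1.0, 3.0, 2.0, 4.0, 1.0]), 3)
        np.testing.assert_allclose(out, [1.0, 2.5, 2.5, 4.0, 1.0])

    def test_idempotent(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            x = rng.normal(size=11)
            once = rm.enforce_unimodality(x)
            np.testing.assert_allclose(rm.enforce_unimodality(once), once, atol=1e-12)

    def test_reversal_symmetry(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            x = rng.normal(size=9)
            p = int(np.argmax(x))
            fwd = rm.enforce_unimodality(x, p)
            rev = rm.enforce_unimodality(x[::-1], x.size - 1 - p)
            np.testing.assert_allclose(fwd, rev[::-1], atol=1e-12)

    @pytest.mark.parametrize("peak", range(5))
    def test_matches_quadratic_program_on_5_vectors(self, peak):
        rng = np.random.default_rng(10 + peak)
        for _ in range(10):
            x = rng.normal(size=5)
            ours = rm.enforce_unimodality(x, peak)
            ref = qp_unimodal(x, peak)
            np.testing.assert_allclose(ours, ref, atol=1e-6)
            # feasibility of the chosen peak shape
            assert np.all(np.diff(ours[: peak + 1]) >= -1e-12)
            assert np.all(np.diff(ours[peak:]) <= 1e-12)


class TestSolveC:
    def test_consistent_system_recovered(self, noiseless_truth):
        D = noiseless_truth.C_true @ noiseless_truth.S_true
        C = rm.solve_C(D, noiseless_truth.S_true)
        np.testing.assert_allclose(C, noiseless_truth.C_true, atol=1e-8)

    def test_matches_active_set_enumeration_on_toys(self):
        """Constrained C-step equals exhaustive NNLS on 4x3 problems."""
        rng = np.random.default_rng(0)
        cfg = rm.ConstraintConfig(unimodal_C=False)
        for _ in range(25):
            S_T = rng.normal(size=(3, 4))  # 3 components, 4 wavelengths
            D = rng.normal(size=(5, 4))
            C = rm.solve_C(D, S_T, cfg)
            for i in range(D.shape[0]):
                ref = brute_force_nnls(S_T.T, D[i])
                np.testing.assert_allclose(C[i], ref, atol=1e-8)

    def test_negative_coefficient_clamped_with_larger_residual(self):
        rng = np.random.default_rng(1)
        cfg = rm.ConstraintConfig(unimodal_C=False)
        found = False
        for _ in range(50):
            S_T = rng.normal(size=(2, 3))
            d = rng.normal(size=(1, 3))
            unconstrained, *_ = np.linalg.lstsq(S_T.T, d[0], rcond=None)
            if np.any(unconstrained < -1e-6):
                found = True
                c = rm.solve_C(d, S_T, cfg)[0]
                assert np.all(c >= 0)
                r_con = np.linalg.norm(S_T.T @ c - d[0])
                r_unc = np.linalg.norm(S_T.T @ unconstrained - d[0])
                assert r_con >= r_unc - 1e-12
        assert found

    def test_bimodal_column_projected_unimodal(self):
        rng = np.random.default_rng(4)
        S_T = rng.random((2, 6)) + 0.1
        C0 = np.column_stack(
            [np.array([1.0, 0.1, 1.0, 0.1, 1.0]), np.full(5, 0.5)]
        )
        D = C0 @ S_T  # unconstrained solution has a bimodal first column
        C = rm.solve_C(D, S_T, rm.ConstraintConfig(unimodal_C=True))
        col = C[:, 0]
        rises = np.diff(col) > 1e-12
        # once the column starts falling it never rises again
        first_fall = np.argmax(~rises) if not rises.all() else len(rises)
        assert not rises[first_fall:].any()

    def test_rank_deficient_s_rejected(self):
        S_T = np.array([[1.0, 2.0, 3.0], [2.0, 4.0, 6.0]])
        with pytest.raises(ValueError, match="rank"):
            rm.solve_C(np.ones((2, 3)), S_T)


class TestSolveS:
    def test_consistent_system_recovered_up_to_scale(self, noiseless_truth):
        D = noiseless_truth.C_true @ noiseless_truth.S_true
        S_T, C = rm.solve_S(D, noiseless_truth.C_true)
        np.testing.assert_allclose(C @ S_T, D, atol=1e-8)

    def test_unit_length_normalization(self, noiseless_truth):
        D = noiseless_truth.C_true @ noiseless_truth.S_true
        S_T, _ = rm.solve_S(D, noiseless_truth.C_true)
        np.testing.assert_allclose(np.linalg.norm(S_T, axis=1), 1.0, atol=1e-10)

    def test_normalization_does_not_change_reconstruction(self, noiseless_truth):
        D = noiseless_truth.C_true @ noiseless_truth.S_true
        on = rm.ConstraintConfig(s_normalization="unit_length")
        off = rm.ConstraintConfig(s_normalization="none")
        S1, C1 = rm.solve_S(D, noiseless_truth.C_true, on)
        S2, C2 = rm.solve_S(D, noiseless_truth.C_true, off)
        np.testing.assert_allclose(C1 @ S1, C2 @ S2, atol=1e-10)

    def test_rank_deficient_c_rejected(self):
        C = np.ones((4, 2))
        with pytest.raises(ValueError, match="rank"):
            rm.solve_S(np.ones((4, 3)), C)


class TestFit:
    def test_noiseless_batch_converges_below_floor(
        self, noiseless_batch, raw_fit_config
    ):
        picks = rm.select_pure_spectra(noiseless_batch.absorbance, F=3)
        model = rm.fit(
            noiseless_batch.absorbance,
            picks.initial_S,
            raw_fit_config,
            times=noiseless_batch.times,
        )
        assert model.converged
        assert model.lof_history[-1] < 0.1
        assert model.explained_variance_pct > 99.99

    def test_residual_sd_tracks_injected_noise(
        self, center_kinetics, raw_fit_config, small_grid
    ):
        for seed in range(3):
            truth = rm.make_ground_truth(
                center_kinetics, wavenumbers=small_grid, noise_sd=0.003
            )
            batch = rm.simulate_batch(truth, seed=seed)
            picks = rm.select_pure_spectra(batch.absorbance, F=3)
            model = rm.fit(
                batch.absorbance, picks.initial_S, raw_fit_config, times=batch.times
            )
            assert 0.003 / 1.5 < model.residual_sd < 0.003 * 1.5

    def test_lof_never_rises_with_nonneg_only(self, noiseless_batch):
        cfg = rm.ConstraintConfig(
            unimodal_C=False, nonneg_S=True, max_iterations=30
        )
        picks = rm.select_pure_spectra(noiseless_batch.absorbance, F=3)
        model = rm.fit(noiseless_batch.absorbance, picks.initial_S, cfg)
        diffs = np.diff(model.lof_history)
        assert np.all(diffs <= 1e-9)

    def test_final_lof_below_initial_with_unimodality(self, noiseless_batch):
        cfg = rm.ConstraintConfig(max_iterations=30, nonneg_S=True)
        picks = rm.select_pure_spectra(noiseless_batch.absorbance, F=3)
        model = rm.fit(noiseless_batch.absorbance, picks.initial_S, cfg)
        assert model.lof_history[-1] < model.lof_history[0]

    def test_multiset_shared_spectra_separate_segments(
        self, center_kinetics, small_grid, raw_fit_config, times30
    ):
        """Augmented fit keeps one S_T; in-control and fault segments get
        visibly different transition-phase concentration profiles."""
        fault_kin = rm.apply_fault(
            center_kinetics, rm.FaultSpec(kind="half_rennet", severity=0.5)
        )
        batches = []
        for i, k in enumerate([center_kinetics, center_kinetics, fault_kin]):
            truth = rm.make_ground_truth(
                k, wavenumbers=small_grid, noise_sd=0.003
            )
            batches.append(rm.simulate_batch(truth, seed=40 + i))
        bs = rm.augment(batches)
        picks = rm.select_pure_spectra(batches[0].absorbance, F=3)
        model = rm.fit(
            bs.stacked,
            picks.initial_S,
            raw_fit_config,
            layout=bs.boundaries,
            times=bs.times,
        )
        assert model.S_T.shape == (3, small_grid.size)
        segs = model.segments()
        truth0 = rm.make_concentration_profiles(center_kinetics, times30)
        perm, _ = match_components(model.C[segs[0]], truth0)
        pulse_col = perm.index(1)
        ok = model.C[segs[0], pulse_col]
        bad = model.C[segs[2], pulse_col]
        assert np.abs(ok / ok.max() - bad / bad.max()).max() > 0.05

    def test_scale_ambiguity_invariance(self, noiseless_batch):
        picks = rm.select_pure_spectra(noiseless_batch.absorbance, F=3)
        out = {}
        for norm in ("unit_length", "none"):
            cfg = rm.ConstraintConfig(
                s_normalization=norm, nonneg_S=True, max_iterations=20
            )
            m = rm.fit(noiseless_batch.absorbance, picks.initial_S, cfg)
            out[norm] = m.C @ m.S_T
        np.testing.assert_allclose(
            out["unit_length"], out["none"], atol=1e-6
        )

    def test_dependent_initial_spectra_rejected(self, noiseless_batch):
        bad = np.ones((3, noiseless_batch.n_wavenumbers))
        with pytest.raises(ValueError, match="dependent"):
            rm.fit(noiseless_batch.absorbance, bad)
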