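"""SCF solvers: gradient/Hessian oracles, DIIS, GDM, TRAH, driver behavior.

The finite-difference checks of the analytic orbital gradient and of the
Hessian-vector products are the keystone consistency tests tying the Fock
builders to the total-energy expression.
"""

import math

import numpy as np
import pytest
import scipy.linalg as sla

from neoscf import RunConfig, fixture, scf_drive
from neoscf.basis import HP, SD
from neoscf.config import ConfigError
from neoscf.guess import GuessSpec, make_guess
from neoscf.neo_core import build_focks, total_energy
from neoscf.solvers import (AugHessianProblem, DIISHistory, GDMState,
                            SCFDriver, SolverError, _aug_solve,
                            apply_rotation, diis_error_vector,
                            diis_extrapolate, hessian_vector_product,
                            orbital_gradient, roothaan_step, rotation_layout,
                            trah_step)


def _perturbed_state(mol, name, rep, seed=5, amp=0.08):
    b = mol.bundle(name)
    tab = mol.tables(name)
    lay = mol.layout(name, rep)
    spec = GuessSpec(electronic="sad", nuclear="sad", perturbation=amp, seed=seed)
    return b, tab, make_guess(b.system, tab, lay, spec, basis_dict=b.basis_dict)


# ---------------------------------------------------------------------------
# Gradient / Hessian oracles
# ---------------------------------------------------------------------------

class TestGradientOracle:
    @pytest.mark.parametrize("rep", [SD, HP])
    def test_gradient_matches_finite_differences(self, mol, rep):
        """Central differences along 20 random rotation directions (H3O+)."""
        b, tab, st = _perturbed_state(mol, "h3o+", rep)
        g = orbital_gradient(tab, st)
        lay = rotation_layout(st)
        rng = np.random.default_rng(42)
        h = 1e-5
        for _ in range(20):
            v = rng.standard_normal(lay.dim)
            v /= np.linalg.norm(v)
            Ep = total_energy(tab, apply_rotation(st, h * v, tab.S_e, tab.S_p)).total
            Em = total_energy(tab, apply_rotation(st, -h * v, tab.S_e, tab.S_p)).total
            fd = (Ep - Em) / (2 * h)
            assert float(g @ v) == pytest.approx(fd, rel=1e-6, abs=1e-10)

    def test_converged_gradient_vanishes(self, mol):
        r = mol.run("h3o+", SD)
        g = orbital_gradient(mol.tables("h3o+"), r.state)
        assert math.sqrt(float(g @ g) / g.size) < 1e-7

    def test_decoupled_electronic_gradient_is_rhf_gradient(self, mol):
        """With the ep coupling zeroed, the electronic block reduces to the
        conventional RHF orbital gradient of the same electronic problem."""
        import dataclasses

        b, tab, st = _perturbed_state(mol, "h2", SD)
        tab0 = dataclasses.replace(tab, eri_ep=np.zeros_like(tab.eri_ep))
        g = orbital_gradient(tab0, st)
        lay = rotation_layout(st)
        no = st.n_occ_e
        from neoscf.neo_core import coulomb, exchange
        D = st.electronic_density()
        F = tab.h_e + coulomb(tab.eri_ee, D) - 0.5 * exchange(tab.eri_ee, D)
        Fmo = st.C_e.T @ F @ st.C_e
        np.testing.assert_allclose(g[:lay.sizes[0]],
                                   (4.0 * Fmo[no:, :no]).ravel(), atol=1e-12)


class TestHessianOracle:
    @pytest.mark.parametrize("rep", [SD, HP])
    def test_hessian_action_symmetric(self, mol, rep):
        b, tab, st = _perturbed_state(mol, "h3o+", rep)
        lay = rotation_layout(st)
        rng = np.random.default_rng(3)
        for _ in range(4):
            u = rng.standard_normal(lay.dim)
            v = rng.standard_normal(lay.dim)
            Hu = hessian_vector_product(tab, st, u)
            Hv = hessian_vector_product(tab, st, v)
            assert float(u @ Hv) == pytest.approx(float(v @ Hu), rel=1e-9, abs=1e-9)

    @pytest.mark.parametrize("rep", [SD, HP])
    def test_hessian_action_matches_gradient_differences(self, mol, rep):
        b, tab, st = _perturbed_state(mol, "h3o+", rep)
        lay = rotation_layout(st)
        rng = np.random.default_rng(7)
        h = 1e-4
        for _ in range(6):
            v = rng.standard_normal(lay.dim)
            v /= np.linalg.norm(v)
            gp = orbital_gradient(tab, apply_rotation(st, h * v, tab.S_e, tab.S_p))
            gm = orbital_gradient(tab, apply_rotation(st, -h * v, tab.S_e, tab.S_p))
            fd = (gp - gm) / (2 * h)
            Hv = hessian_vector_product(tab, st, v)
            assert np.linalg.norm(Hv - fd) / np.linalg.norm(fd) < 1e-5

    def test_decoupled_limit_kills_cross_block(self, mol):
        import dataclasses

        b, tab, st = _perturbed_state(mol, "h2", SD)
        tab0 = dataclasses.replace(tab, eri_ep=np.zeros_like(tab.eri_ep))
        lay = rotation_layout(st)
        v = np.zeros(lay.dim)
        v[lay.sizes[0]:] = np.random.default_rng(0).standard_normal(
            lay.dim - lay.sizes[0])
        Hv = hessian_vector_product(tab0, st, v)
        assert np.abs(Hv[:lay.sizes[0]]).max() < 1e-13


# ---------------------------------------------------------------------------
# Rotations
# ---------------------------------------------------------------------------

class TestRotations:
    def test_zero_step_is_identity(self, mol):
        b, tab, st = _perturbed_state(mol, "h2", SD)
        lay = rotation_layout(st)
        st2 = apply_rotation(st, np.zeros(lay.dim), tab.S_e, tab.S_p)
        np.testing.assert_allclose(st2.C_e, st.C_e, atol=1e-14)

    def test_rotation_preserves_orthonormality(self, mol):
        b, tab, st = _perturbed_state(mol, "h3o+", SD)
        lay = rotation_layout(st)
        s = np.random.default_rng(1).standard_normal(lay.dim)
        st2 = apply_rotation(st, s, tab.S_e, tab.S_p)
        assert np.abs(st2.C_e.T @ tab.S_e @ st2.C_e - np.eye(tab.n_e)).max() < 1e-10
        for blk in st2.blocks:
            Sb = tab.S_p[np.ix_(blk.idx, blk.idx)]
            assert np.abs(blk.C.T @ Sb @ blk.C - np.eye(len(blk.idx))).max() < 1e-10

    def test_rotation_inverse_recovers_state(self, mol):
        b, tab, st = _perturbed_state(mol, "h2", HP)
        lay = rotation_layout(st)
        s = 0.3 * np.random.default_rng(2).standard_normal(lay.dim)
        st2 = apply_rotation(apply_rotation(st, s, tab.S_e, tab.S_p),
                             -s, tab.S_e, tab.S_p)
        np.testing.assert_allclose(st2.C_e, st.C_e, atol=1e-10)

    def test_pack_unpack_round_trip(self, mol):
        b, tab, st = _perturbed_state(mol, "h3o+", HP)
        lay = rotation_layout(st)
        s = np.random.default_rng(3).standard_normal(lay.dim)
        x_e, x_blocks = lay.unpack(s)
        np.testing.assert_array_equal(lay.pack(x_e, x_blocks), s)


# ---------------------------------------------------------------------------
# DIIS
# ---------------------------------------------------------------------------

class TestDIIS:
    def test_commuting_pair_gives_zero_error(self):
        F = np.diag([1.0, 2.0, 3.0])
        D = np.diag([1.0, 0.0, 0.0])
        S = np.eye(3)
        assert np.all(diis_error_vector(F, D, S, S) == 0)

    def test_commutator_antisymmetric_before_transform(self):
        rng = np.random.default_rng(0)
        F = rng.normal(size=(4, 4))
        F = F + F.T
        D = rng.normal(size=(4, 4))
        D = D + D.T
        S = np.eye(4)
        comm = F @ D @ S - S @ D @ F
        np.testing.assert_allclose(comm, -comm.T, atol=1e-12)

    def test_converged_error_below_threshold(self, mol):
        r = mol.run("acetylene", SD)
        assert r.error_e[-1] < 1e-8 and r.error_p[-1] < 1e-8

    def test_single_entry_returns_stored_fock(self):
        h = DIISHistory()
        F = np.eye(2)
        h.push(F, [F], np.array([0.1]), np.array([0.1]))
        F_e, F_p = diis_extrapolate(h)
        np.testing.assert_array_equal(F_e, F)
        np.testing.assert_array_equal(h.coefficients, [1.0])

    def test_duplicate_snapshots_pruned(self):
        h = DIISHistory()
        F = np.diag([1.0, 2.0])
        for _ in range(2):
            h.push(F, [F], np.array([0.1, 0.0]), np.array([0.0]))
        F_e, _ = diis_extrapolate(h)
        np.testing.assert_allclose(F_e, F, atol=1e-10)

    def test_linear_problem_solved_exactly(self):
        """Errors linear in F: two snapshots suffice to hit the fixed point."""
        F_star = np.diag([1.0, -2.0])
        h = DIISHistory()
        for F in (F_star + 0.5 * np.eye(2), F_star - 0.25 * np.eye(2)):
            err = (F - F_star).ravel()
            h.push(F, [F], err, np.zeros(1))
        F_e, _ = diis_extrapolate(h)
        np.testing.assert_allclose(F_e, F_star, atol=1e-12)
        assert h.coefficients.sum() == pytest.approx(1.0, abs=1e-12)

    def test_coefficients_sum_to_one_in_scf(self, mol):
        b = mol.bundle("h2")
        tab = mol.tables("h2")
        lay = mol.layout("h2", SD)
        cfg = RunConfig(representation=SD, solver="diis")
        driver = SCFDriver(tab, lay, cfg)
        spec = GuessSpec(electronic="core", nuclear="core")
        st = make_guess(b.system, tab, lay, spec, basis_dict=b.basis_dict)
        hist = DIISHistory()
        for _ in range(5):
            focks = build_focks(tab, st)
            e_e, e_p = driver._errors(st, focks)
            hist.push(focks[0], focks[1], e_e, e_p)
            F_e, F_b = hist.extrapolate()
            assert hist.coefficients.sum() == pytest.approx(1.0, abs=1e-9)
            st = driver._diagonalize(st, F_e, F_b)


# ---------------------------------------------------------------------------
# GDM machinery
# ---------------------------------------------------------------------------

class TestGDM:
    def test_empty_history_is_preconditioned_steepest_descent(self):
        gdm = GDMState()
        g = np.array([1.0, -2.0, 0.5])
        d = np.array([2.0, 4.0, 1.0])
        np.testing.assert_allclose(gdm.direction(g, d), -g / d, atol=1e-14)

    def test_bfgs_exact_on_quadratic(self):
        """L-BFGS with exact line search minimizes 1/2 x^T A x in <= dim+2 steps."""
        rng = np.random.default_rng(0)
        n = 8
        M = rng.normal(size=(n, n))
        A = M @ M.T + n * np.eye(n)
        x = rng.normal(size=n)
        gdm = GDMState()
        diag = np.diag(A).copy()
        for it in range(n + 2):
            g = A @ x
            if np.linalg.norm(g) < 1e-10:
                break
            p = gdm.direction(g, diag)
            t = -float(g @ p) / float(p @ A @ p)
            s = t * p
            x = x + s
            gdm.push_pair(s, A @ s)  # y = g_new - g_old on a quadratic
        assert np.linalg.norm(A @ x) < 1e-10

    def test_curvature_condition_guard(self):
        gdm = GDMState()
        s = np.array([1.0, 0.0])
        y = np.array([-1.0, 0.0])  # negative curvature pair must be skipped
        gdm.push_pair(s, y)
        assert len(gdm.pairs) == 0

    def test_accepted_energies_never_increase(self, mol):
        r = mol.run("h3o+", SD, solver="gdm")
        E = np.array(r.energies)
        assert np.all(np.diff(E) <= 1e-12)


# ---------------------------------------------------------------------------
# TRAH machinery
# ---------------------------------------------------------------------------

def _dense_model(seed, n=10, definite=True):
    rng = np.random.default_rng(seed)
    M = rng.normal(size=(n, n))
    H = M + M.T
    if definite:
        H = H @ H.T / n + 0.5 * np.eye(n)
    g = rng.normal(size=n)
    return H, g


class TestTRAH:
    def test_lowest_eigenpair_matches_dense_solver(self):
        H, g = _dense_model(0, definite=False)
        n = len(g)
        alpha = 0.7
        A = np.zeros((n + 1, n + 1))
        A[0, 1:] = A[1:, 0] = alpha * g
        A[1:, 1:] = H
        w, V = np.linalg.eigh(A)
        problem = AugHessianProblem(g=g, hess_vec=lambda v: H @ v,
                                    diag=np.diag(H).copy(), trust_radius=1.0)
        mu, x = _aug_solve(problem, alpha)
        assert mu == pytest.approx(w[0], abs=1e-9)
        ref = V[1:, 0] / V[0, 0]
        np.testing.assert_allclose(x, ref, atol=1e-8)

    def test_newton_limit_for_definite_hessian(self):
        H, g = _dense_model(1, definite=True)
        g = 1e-5 * g  # small gradient, large trust region -> Newton step
        problem = AugHessianProblem(g=g, hess_vec=lambda v: H @ v,
                                    diag=np.diag(H).copy(), trust_radius=10.0)
        s = trah_step(problem)
        np.testing.assert_allclose(s, -np.linalg.solve(H, g), atol=1e-8)
        assert abs(problem.mu) < 1e-4

    def test_level_shift_equation_residual(self):
        H, g = _dense_model(2, definite=False)
        problem = AugHessianProblem(g=g, hess_vec=lambda v: H @ v,
                                    diag=np.diag(H).copy(), trust_radius=0.5)
        trah_step(problem)
        mu, s = problem.mu, problem.step
        # the applied step solves the level-shifted Newton equation exactly
        np.testing.assert_allclose((H - mu * np.eye(len(g))) @ s, -g, atol=1e-7)

    def test_indefinite_hessian_shifted_downhill(self):
        H, g = _dense_model(3, definite=False)
        problem = AugHessianProblem(g=g, hess_vec=lambda v: H @ v,
                                    diag=np.diag(H).copy(), trust_radius=0.5)
        s = trah_step(problem)
        assert problem.mu < np.linalg.eigvalsh(H).min() + 1e-10
        assert float(g @ s) < 0
        assert np.linalg.norm(s) <= problem.trust_radius * (1 + 1e-6)

    def test_davidson_matches_dense_on_scf_instance(self, mol):
        """<= 60 rotation parameters: dense eigensolver oracle on NEO H2."""
        b, tab, st = _perturbed_state(mol, "h2", SD, amp=0.05)
        lay = rotation_layout(st)
        assert lay.dim <= 60
        g = orbital_gradient(tab, st)
        H = np.column_stack([hessian_vector_product(tab, st, e)
                             for e in np.eye(lay.dim)])
        H = 0.5 * (H + H.T)
        alpha = 1.0
        A = np.zeros((lay.dim + 1, lay.dim + 1))
        A[0, 1:] = A[1:, 0] = alpha * g
        A[1:, 1:] = H
        w = np.linalg.eigvalsh(A)
        from neoscf.solvers import _hessian_diagonal
        focks = build_focks(tab, st)
        problem = AugHessianProblem(
            g=g, hess_vec=lambda v: hessian_vector_product(tab, st, v),
            diag=_hessian_diagonal(st, focks, floor=0.02), trust_radius=1.0)
        mu, x = _aug_solve(problem, alpha)
        assert mu == pytest.approx(w[0], abs=1e-9)

    def test_trah_rejects_hp(self, mol):
        b = mol.bundle("h2")
        cfg = RunConfig(representation=HP, solver="trah")
        with pytest.raises(ConfigError):
            cfg.validate()


# ---------------------------------------------------------------------------
# Driver behavior
# ---------------------------------------------------------------------------

class TestDriver:
    def test_roothaan_fixed_point_at_convergence(self, mol):
        r = mol.run("h2", SD)
        tab = mol.tables("h2")
        st2 = roothaan_step(tab, r.state, layout=mol.layout("h2", SD))
        assert abs(total_energy(tab, st2).total - r.final_energy) < 1e-12

    def test_roothaan_initial_descent(self, mol):
        r = mol.run("h2", SD, solver="roothaan", guess=("core", "core"),
                    max_iter=50)
        E = r.energies
        assert E[1] < E[0] and E[2] < E[1] and E[3] < E[2]

    def test_hp_nuclear_step_exact_with_frozen_electrons(self, single_proton_water):
        """A single proton's HP Fock does not depend on its own density, so one
        diagonalization solves the nuclear subsystem exactly."""
        from neoscf.basis import build_layout
        from neoscf.integrals import build_tables
        from neoscf.neo_core import build_nuclear_fock_hp

        system, esh, psh, bd = single_proton_water
        tab = build_tables(system, esh, psh)
        lay = build_layout(system, esh, psh, HP)
        spec = GuessSpec(electronic="sad", nuclear="core")
        st = make_guess(system, tab, lay, spec, basis_dict=bd)
        D_e = st.electronic_density()
        D_p = st.proton_densities(tab.n_p)
        F = build_nuclear_fock_hp(tab, D_e, D_p, 0)
        eps, C = sla.eigh(F, tab.S_p)
        D_new = np.outer(C[:, 0], C[:, 0])
        F_new = build_nuclear_fock_hp(tab, D_e, [D_new], 0)
        np.testing.assert_allclose(F_new, F, atol=1e-14)  # linear problem
        # the new orbital is already stationary for the rebuilt Fock
        resid = F_new @ C[:, 0] - eps[0] * tab.S_p @ C[:, 0]
        assert np.abs(resid).max() < 1e-10

    @pytest.mark.parametrize("solver", ["diis", "gdm"])
    def test_restart_from_converged_state_is_fixed_point(self, mol, solver):
        r = mol.run("h2", SD)
        tab = mol.tables("h2")
        cfg = RunConfig(representation=SD, solver=solver)
        driver = SCFDriver(tab, mol.layout("h2", SD), cfg)
        rep = driver.run(r.state)
        assert rep.outcome == "converged"
        assert rep.n_iterations <= 2

    def test_solver_agreement_h3o(self, mol):
        """All converging solver/representation pairs land on one energy."""
        finals = []
        for rep, solver in [(SD, "diis"), (SD, "gdm"), (SD, "trah"),
                            (HP, "diis"), (HP, "gdm")]:
            r = mol.run("h3o+", rep, solver=solver)
            assert r.outcome == "converged"
            finals.append(r.final_energy)
        for a in finals:
            for b in finals:
                assert abs(a - b) <= 1e-8

    def test_hp_converges_faster_than_sd_on_acetylene(self, mol):
        n_sd = mol.run("acetylene", SD).n_iterations
        n_hp = mol.run("acetylene", HP).n_iterations
        assert n_hp < n_sd

    def test_hybrid_converges_on_water(self, mol):
        r = mol.run("water", SD, solver="diis_gdm_hybrid", max_iter=200)
        assert r.outcome == "converged"
        assert abs(r.final_energy - mol.run("water", SD).final_energy) < 1e-8

    def test_stepwise_alternation_converges_on_h2(self, mol):
        """Alternating optimization reaches the simultaneous answer, slowly."""
        r = mol.run("h2", SD, solver="stepwise", max_iter=100)
        assert r.outcome == "converged"
        assert abs(r.final_energy - mol.run("h2", SD).final_energy) < 1e-8
        assert r.n_iterations >= mol.run("h2", SD).n_iterations  # no free lunch

    def test_max_iter_exhaustion_reports_failure_with_trace(self, mol):
        r = mol.run("water", SD, solver="roothaan", guess=("core", "core"),
                    max_iter=5)
        assert r.outcome == "failed"
        assert len(r.energies) == 5
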