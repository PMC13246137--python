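"""Simultaneous SCF optimizers over the coupled electronic + nuclear orbitals.

Solvers
-------
``roothaan``
    Plain repeated diagonalization of both subsystem Fock matrices.
``diis``
    Coupled Pulay extrapolation: one shared coefficient vector applied to the
    electronic and nuclear Fock matrices, with the combined error Gram matrix
    <e_k^e|e_l^e> + <e_k^p|e_l^p> over S^{-1/2}-transformed FDS-SDF
    commutators.
``gdm``
    GDM-style preconditioned limited-memory BFGS over the exponential orbital
    rotation parameters of both subsystems at once, with an Armijo
    backtracking line search and a trust-radius fallback.  Curvature pairs
    from earlier iterations are reused unchanged in the current orbital frame
    (a small-step transport approximation).
``trah``
    Trust-radius augmented Hessian: Davidson iteration for the lowest
    eigenpair of the alpha-scaled augmented Hessian, using exact coupled
    orbital Hessian-vector products.  Slater-determinant representation only.
``stepwise``
    Alternating full electronic / nuclear convergence (the non-simultaneous
    baseline).
``diis_gdm_hybrid``
    DIIS until the error norm stalls (relative decrease < 1% over 5
    iterations), then GDM from the current state.

Convergence requires the energy change below ``e_tol`` AND both subsystem
error norms (commutator RMS for Roothaan/DIIS, gradient RMS for GDM/TRAH)
below ``g_tol``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as sla

from .basis import HP, HPSTAR, SD
from .neo_core import (NuclearBlock, SCFState, build_focks, total_energy)


class SolverError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Generic linear algebra helpers
# ---------------------------------------------------------------------------

def _inv_sqrt(S: np.ndarray) -> np.ndarray:
    w, U = np.linalg.eigh(S)
    if w.min() < 1e-12:
        raise SolverError("overlap matrix numerically singular")
    return U @ np.diag(w ** -0.5) @ U.T


def diis_error_vector(F: np.ndarray, D: np.ndarray, S: np.ndarray,
                      X: np.ndarray) -> np.ndarray:
    """Orthonormal-basis DIIS error e = S^-1/2 (FDS - SDF) S^-1/2."""
    comm = F @ D @ S - S @ D @ F
    return X @ comm @ X


def _rms(a: np.ndarray) -> float:
    return 0.0 if a.size == 0 else float(np.sqrt(np.mean(a * a)))


def _eigh_occupy(F, S, n_occ, prev_occ=None, metric=None):
    """Generalized diagonalization + occupation selection.

    With ``prev_occ`` (previous occupied coefficients) the occupied set is
    chosen by maximum overlap with the previous occupied subspace, which
    prevents discontinuous occupation swaps between near-degenerate protonic
    orbitals mid-SCF; otherwise plain aufbau.
    Returns (C, eps) with occupied columns first.
    """
    eps, C = sla.eigh(F, S)
    if prev_occ is None or n_occ == 0 or n_occ == C.shape[1]:
        return C, eps
    O = C.T @ metric @ prev_occ  # (n_orb, n_occ_prev)
    score = np.sum(O * O, axis=1)
    sel = np.sort(np.argsort(-score)[:n_occ])
    rest = np.array([i for i in range(C.shape[1]) if i not in set(sel)])
    order = np.concatenate([sel, rest])
    return C[:, order], eps[order]


# ---------------------------------------------------------------------------
# Orbital rotations
# ---------------------------------------------------------------------------

@dataclass
class RotationLayout:
    """Shapes of the packed orbital-rotation vector (electronic + per block)."""

    n_occ_e: int
    n_virt_e: int
    nuclear: list  # list of (n_occ, n_virt)

    @property
    def sizes(self):
        return [self.n_occ_e * self.n_virt_e] + [o * v for o, v in self.nuclear]

    @property
    def dim(self):
        return sum(self.sizes)

    def pack(self, x_e, x_blocks):
        parts = [np.asarray(x_e).ravel()]
        parts += [np.asarray(x).ravel() for x in x_blocks]
        return np.concatenate(parts) if parts else np.zeros(0)

    def unpack(self, s):
        out_e = s[: self.sizes[0]].reshape(self.n_virt_e, self.n_occ_e)
        off = self.sizes[0]
        blocks = []
        for (o, v), size in zip(self.nuclear, self.sizes[1:]):
            blocks.append(s[off: off + size].reshape(v, o))
            off += size
        return out_e, blocks


def rotation_layout(state: SCFState) -> RotationLayout:
    nuc = [(b.n_occ, b.C.shape[1] - b.n_occ) for b in state.blocks]
    return RotationLayout(n_occ_e=state.n_occ_e,
                          n_virt_e=state.C_e.shape[1] - state.n_occ_e,
                          nuclear=nuc)


def _rotate(C: np.ndarray, x: np.ndarray, n_occ: int, S: np.ndarray) -> np.ndarray:
    """C <- C exp(kappa), kappa the skew matrix with virt-occ block x."""
    n = C.shape[1]
    kappa = np.zeros((n, n))
    kappa[n_occ:, :n_occ] = x
    kappa[:n_occ, n_occ:] = -x.T
    C_new = C @ sla.expm(kappa)
    drift = np.abs(C_new.T @ S @ C_new - np.eye(n)).max()
    if drift > 1e-10:
        w, U = np.linalg.eigh(C_new.T @ S @ C_new)
        C_new = C_new @ U @ np.diag(w ** -0.5) @ U.T
    return C_new


def apply_rotation(state: SCFState, s: np.ndarray, S_e, S_p) -> SCFState:
    """New state with C <- C exp(kappa) applied per subsystem/block."""
    lay = rotation_layout(state)
    x_e, x_blocks = lay.unpack(s)
    C_e = _rotate(state.C_e, x_e, state.n_occ_e, S_e)
    blocks = []
    for b, x in zip(state.blocks, x_blocks):
        Sb = S_p[np.ix_(b.idx, b.idx)]
        blocks.append(NuclearBlock(idx=b.idx, C=_rotate(b.C, x, b.n_occ, Sb),
                                   n_occ=b.n_occ, eps=b.eps))
    return SCFState(C_e=C_e, n_occ_e=state.n_occ_e, blocks=blocks,
                    representation=state.representation, eps_e=state.eps_e)


# ---------------------------------------------------------------------------
# Gradient and Hessian action
# ---------------------------------------------------------------------------

def orbital_gradient(tables, state: SCFState, focks=None) -> np.ndarray:
    """Stacked orbital-rotation gradient dE/dkappa at kappa = 0.

    Electronic block 2*f*F^MO_ai with f = 2; nuclear blocks with f = 1.  For
    HP* the self-term contribution to the occupied-virtual Fock block
    vanishes identically, so the HP Fock gradient is exact for both.
    """
    F_e, F_blocks = focks if focks is not None else build_focks(tables, state)
    lay = rotation_layout(state)
    no = state.n_occ_e
    Fmo = state.C_e.T @ F_e @ state.C_e
    g_e = 4.0 * Fmo[no:, :no]
    g_blocks = []
    for b, F in zip(state.blocks, F_blocks):
        Fb = F[np.ix_(b.idx, b.idx)]
        Fbmo = b.C.T @ Fb @ b.C
        g_blocks.append(2.0 * Fbmo[b.n_occ:, :b.n_occ])
    return lay.pack(g_e, g_blocks)


def _first_order_density(C, x, n_occ, f):
    Co, Cv = C[:, :n_occ], C[:, n_occ:]
    M = Cv @ x @ Co.T
    return f * (M + M.T)


def hessian_vector_product(tables, state: SCFState, v: np.ndarray,
                           focks=None) -> np.ndarray:
    """Exact coupled orbital-Hessian action H v (same packing as the gradient).

    Assembled from the orbital part 2f (F^MO_vv x - x F^MO_oo) plus Fock-like
    contractions of the first-order rotated densities; the electron-proton
    blocks couple the subsystems.
    """
    from .neo_core import coulomb, coulomb_ep, coulomb_pe, exchange

    F_e, F_blocks = focks if focks is not None else build_focks(tables, state)
    lay = rotation_layout(state)
    x_e, x_blocks = lay.unpack(v)
    no = state.n_occ_e
    C_e = state.C_e
    dD_e = _first_order_density(C_e, x_e, no, 2.0)
    dD_blocks = []
    for b, x in zip(state.blocks, x_blocks):
        dD_full = np.zeros((tables.n_p, tables.n_p))
        dD_sub = _first_order_density(b.C, x, b.n_occ, 1.0)
        dD_full[np.ix_(b.idx, b.idx)] = dD_sub
        dD_blocks.append(dD_full)
    dD_p_tot = (np.sum(dD_blocks, axis=0) if dD_blocks
                else np.zeros((tables.n_p, tables.n_p)))

    G_e = coulomb(tables.eri_ee, dD_e) - 0.5 * exchange(tables.eri_ee, dD_e)
    if state.blocks:
        G_e = G_e - coulomb_ep(tables.eri_ep, dD_p_tot)
    Fmo = C_e.T @ F_e @ C_e
    Hv_e = 4.0 * (Fmo[no:, no:] @ x_e - x_e @ Fmo[:no, :no])
    Hv_e += 4.0 * (C_e[:, no:].T @ G_e @ C_e[:, :no])

    Hv_blocks = []
    for bi, (b, x) in enumerate(zip(state.blocks, x_blocks)):
        if state.representation == SD:
            G_p = (coulomb(tables.eri_pp, dD_p_tot)
                   - exchange(tables.eri_pp, dD_p_tot)
                   - coulomb_pe(tables.eri_ep, dD_e))
        else:
            G_p = -coulomb_pe(tables.eri_ep, dD_e)
            for bj, dDj in enumerate(dD_blocks):
                if bj != bi:
                    G_p = G_p + coulomb(tables.eri_pp, dDj)
        F = F_blocks[bi][np.ix_(b.idx, b.idx)]
        Gb = G_p[np.ix_(b.idx, b.idx)]
        Fbmo = b.C.T @ F @ b.C
        nob = b.n_occ
        Hv_b = 2.0 * (Fbmo[nob:, nob:] @ x - x @ Fbmo[:nob, :nob])
        Hv_b += 2.0 * (b.C[:, nob:].T @ Gb @ b.C[:, :nob])
        Hv_blocks.append(Hv_b)
    return lay.pack(Hv_e, Hv_blocks)


def _hessian_diagonal(state: SCFState, focks, floor: float = 0.05) -> np.ndarray:
    """Orbital-energy-difference approximation to diag(H), floored."""
    F_e, F_blocks = focks
    lay = rotation_layout(state)
    no = state.n_occ_e
    eps_e = np.diag(state.C_e.T @ F_e @ state.C_e)
    d_e = 4.0 * np.maximum(eps_e[no:, None] - eps_e[None, :no], floor)
    d_blocks = []
    for b, F in zip(state.blocks, F_blocks):
        Fb = F[np.ix_(b.idx, b.idx)]
        eps_b = np.diag(b.C.T @ Fb @ b.C)
        d_blocks.append(2.0 * np.maximum(eps_b[b.n_occ:, None] - eps_b[None, :b.n_occ],
                                         floor))
    return lay.pack(d_e, d_blocks)


# ---------------------------------------------------------------------------
# DIIS
# ---------------------------------------------------------------------------

@dataclass
class DIISHistory:
    """Stored Fock/error pairs and the combined extrapolation problem."""

    cap: int = 15
    focks_e: list = field(default_factory=list)
    focks_p: list = field(default_factory=list)  # list of lists (per block)
    errors_e: list = field(default_factory=list)
    errors_p: list = field(default_factory=list)
    coefficients: np.ndarray = None

    def push(self, F_e, F_blocks, e_e, e_p):
        self.focks_e.append(F_e)
        self.focks_p.append([F.copy() for F in F_blocks])
        self.errors_e.append(e_e.ravel())
        self.errors_p.append(e_p.ravel())
        while len(self.focks_e) > self.cap:
            self._drop_oldest()

    def _drop_oldest(self):
        for lst in (self.focks_e, self.focks_p, self.errors_e, self.errors_p):
            lst.pop(0)

    def reset(self):
        for lst in (self.focks_e, self.focks_p, self.errors_e, self.errors_p):
            lst.clear()

    def gram(self) -> np.ndarray:
        m = len(self.errors_e)
        B = np.empty((m, m))
        for k in range(m):
            for l in range(k + 1):
                B[k, l] = B[l, k] = (self.errors_e[k] @ self.errors_e[l]
                                     + self.errors_p[k] @ self.errors_p[l])
        return B

    def extrapolate(self):
        """Constrained least squares on the combined Gram matrix.

        One coefficient set applies to both subsystems.  Ill-conditioned Gram
        matrices (cond > 1e12) shed their oldest entries; a fully degenerate
        subspace resets the history and returns the latest Fock matrices.
        """
        while True:
            m = len(self.errors_e)
            if m == 1:
                self.coefficients = np.array([1.0])
                return self.focks_e[0], self.focks_p[0]
            B = self.gram()
            scale = np.abs(B).max()
            if scale > 0 and np.linalg.cond(B / scale) > 1e12 and m > 2:
                self._drop_oldest()
                continue
            A = np.zeros((m + 1, m + 1))
            A[:m, :m] = B
            A[m, :m] = A[:m, m] = -1.0
            rhs = np.zeros(m + 1)
            rhs[m] = -1.0
            try:
                sol = np.linalg.solve(A, rhs)
            except np.linalg.LinAlgError:
                if m > 2:
                    self._drop_oldest()
                    continue
                latest_e, latest_p = self.focks_e[-1], self.focks_p[-1]
                self.reset()
                self.coefficients = np.array([1.0])
                return latest_e, latest_p
            c = sol[:m]
            self.coefficients = c
            F_e = sum(ck * Fk for ck, Fk in zip(c, self.focks_e))
            nblk = len(self.focks_p[0])
            F_blocks = [sum(ck * Fs[b] for ck, Fs in zip(c, self.focks_p))
                        for b in range(nblk)]
            return F_e, F_blocks


def diis_extrapolate(history: DIISHistory):
    if not history.focks_e:
        raise SolverError("DIIS history is empty")
    return history.extrapolate()


# ---------------------------------------------------------------------------
# GDM (quasi-Newton) machinery
# ---------------------------------------------------------------------------

@dataclass
class GDMState:
    """Limited-memory curvature history + line-search bookkeeping."""

    cap: int = 20
    pairs: list = field(default_factory=list)   # (s, y, rho)
    prev_g: np.ndarray = None
    prev_s: np.ndarray = None
    trust_radius: float = 0.5

    def push_pair(self, s, y):
        sy = float(s @ y)
        if sy > 1e-12 * np.linalg.norm(s) * np.linalg.norm(y):
            self.pairs.append((s, y, 1.0 / sy))
            if len(self.pairs) > self.cap:
                self.pairs.pop(0)

    def direction(self, g, diag):
        """Two-loop L-BFGS recursion with diagonal H0 = diag."""
        q = g.copy()
        alphas = []
        for s, y, rho in reversed(self.pairs):
            a = rho * (s @ q)
            alphas.append(a)
            q = q - a * y
        r = q / diag
        for (s, y, rho), a in zip(self.pairs, reversed(alphas)):
            b = rho * (y @ r)
            r = r + (a - b) * s
        return -r


# ---------------------------------------------------------------------------
# TRAH machinery
# ---------------------------------------------------------------------------

@dataclass
class AugHessianProblem:
    """One augmented-Hessian subproblem: gradient, H action, scaling, trust."""

    g: np.ndarray
    hess_vec: callable
    diag: np.ndarray
    trust_radius: float
    alpha: float = 1.0
    mu: float = 0.0
    step: np.ndarray = None


def davidson_lowest(matvec, diag, dim, start, tol=1e-9, max_iter=200):
    """Lowest eigenpair of a symmetric operator by Davidson iteration."""
    V = []
    for v in start:
        w = v.copy()
        for u in V:
            w -= (u @ w) * u
        nrm = np.linalg.norm(w)
        if nrm > 1e-12:
            V.append(w / nrm)
    W = [matvec(v) for v in V]
    theta = None
    for it in range(max_iter):
        Vm = np.array(V)
        Wm = np.array(W)
        T = Vm @ Wm.T
        T = 0.5 * (T + T.T)
        w_eig, y_eig = np.linalg.eigh(T)
        theta = w_eig[0]
        y = y_eig[:, 0]
        x = Vm.T @ y
        r = Wm.T @ y - theta * x
        if np.linalg.norm(r) < tol * max(1.0, abs(theta)):
            return theta, x
        denom = diag - theta
        denom = np.where(np.abs(denom) < 1e-8, np.sign(denom + 1e-30) * 1e-8, denom)
        t = r / denom
        for u in V:
            t -= (u @ t) * u
        nrm = np.linalg.norm(t)
        if nrm < 1e-12:
            t = np.random.default_rng(it).standard_normal(dim)
            for u in V:
                t -= (u @ t) * u
            nrm = np.linalg.norm(t)
        V.append(t / nrm)
        W.append(matvec(V[-1]))
        if len(V) > 80:  # collapse subspace
            V = [x / np.linalg.norm(x)]
            W = [matvec(V[0])]
    raise SolverError(
        f"Davidson failed to converge in {max_iter} microiterations "
        f"(last theta={theta}, residual={np.linalg.norm(r):.3e})")


def _aug_solve(problem: AugHessianProblem, alpha: float):
    """Lowest eigenpair of [[0, a g^T], [a g, H]]; returns (mu, x_tilde)."""
    g, hv = problem.g, problem.hess_vec
    n = g.size

    def matvec(w):
        out = np.empty(n + 1)
        out[0] = alpha * (g @ w[1:])
        out[1:] = alpha * g * w[0] + hv(w[1:])
        return out

    diag = np.concatenate([[0.0], problem.diag])
    gn = np.linalg.norm(g)
    s1 = np.zeros(n + 1)
    s1[0] = 1.0
    starts = [s1]
    if gn > 0:
        s2 = np.zeros(n + 1)
        s2[1:] = -g / gn
        starts.append(s2)
    mu, vec = davidson_lowest(matvec, diag, n + 1, starts)
    if abs(vec[0]) < 1e-12:
        raise SolverError("augmented-Hessian eigenvector has vanishing reference weight")
    x = vec[1:] / vec[0]
    return mu, x


def trah_step(problem: AugHessianProblem):
    """Level-shifted step within the trust radius via bisection on log10(alpha).

    The applied step is s = x_tilde(alpha) / alpha, which satisfies
    (H - mu I) s = -g exactly and whose norm decreases monotonically with
    alpha in both the positive-definite and indefinite regimes.  The
    unscaled (alpha = 1) solution is kept when already interior; otherwise
    alpha grows until ||s|| lands in [0.8 Delta, Delta].
    """
    Delta = problem.trust_radius
    mu, x = _aug_solve(problem, 1.0)
    if np.linalg.norm(x) <= Delta:
        problem.alpha, problem.mu, problem.step = 1.0, mu, x
        return x
    lo, hi = 0.0, 6.0
    best = None
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        alpha = 10.0 ** mid
        mu, x = _aug_solve(problem, alpha)
        s = x / alpha
        nrm = np.linalg.norm(s)
        if nrm <= Delta and (best is None or nrm > np.linalg.norm(best[2])):
            best = (alpha, mu, s)
        if 0.8 * Delta <= nrm <= Delta:
            break
        if nrm > Delta:
            lo = mid
        else:
            hi = mid
    if best is None:  # pathologically flat: fall back to the tiny-step side
        alpha = 10.0 ** hi
        mu, x = _aug_solve(problem, alpha)
        best = (alpha, mu, x / alpha)
    alpha, mu, s = best
    problem.alpha, problem.mu, problem.step = alpha, mu, s
    return s


# ---------------------------------------------------------------------------
# Driver
# ---------------------------------------------------------------------------

@dataclass
class ConvergenceReport:
    """Per-iteration trace + outcome of one SCF optimization."""

    solver: str
    representation: str
    guess: str
    energies: list = field(default_factory=list)
    delta_e: list = field(default_factory=list)
    error_e: list = field(default_factory=list)
    error_p: list = field(default_factory=list)
    outcome: str = "failed"
    final_energy: float = math.nan
    n_iterations: int = 0
    energy_report: dict = None
    state: SCFState = None

    def to_json(self) -> str:
        d = {k: getattr(self, k) for k in (
            "solver", "representation", "guess", "energies", "delta_e",
            "error_e", "error_p", "outcome", "final_energy", "n_iterations")}
        d["delta_e"] = [None if (isinstance(v, float) and math.isnan(v)) else v
                        for v in d["delta_e"]]
        d["energy_report"] = self.energy_report
        return json.dumps(d, indent=1)


class SCFDriver:
    """Holds per-system precomputations and runs one solver to convergence."""

    def __init__(self, tables, layout, config):
        self.tables = tables
        self.layout = layout
        self.config = config
        self.X_e = _inv_sqrt(tables.S_e)
        self.X_blocks = []
        if layout is not None:
            for idx in layout.proton_blocks:
                self.X_blocks.append(_inv_sqrt(tables.S_p[np.ix_(idx, idx)]))

    # -- shared per-iteration quantities ------------------------------------
    def _errors(self, state, focks):
        """(commutator-based err_e, err_p) as RMS values + raw error matrices."""
        F_e, F_blocks = focks
        D_e = state.electronic_density()
        e_e = diis_error_vector(F_e, D_e, self.tables.S_e, self.X_e)
        e_p_parts = []
        for b, F, X in zip(state.blocks, F_blocks, self.X_blocks):
            ix = np.ix_(b.idx, b.idx)
            Db = b.C[:, :b.n_occ] @ b.C[:, :b.n_occ].T
            e_p_parts.append(diis_error_vector(F[ix], Db, self.tables.S_p[ix], X).ravel())
        e_p = np.concatenate(e_p_parts) if e_p_parts else np.zeros(0)
        return e_e, e_p

    def _diagonalize(self, state, F_e, F_blocks):
        """Roothaan update: diagonalize both Fock matrices, track occupations."""
        cfg = self.config
        shift = getattr(cfg, "level_shift", 0.0)
        S_e = self.tables.S_e
        F_use = F_e
        if shift:
            Dv = state.C_e[:, state.n_occ_e:] @ state.C_e[:, state.n_occ_e:].T
            F_use = F_e + shift * S_e @ Dv @ S_e
        eps_e, C_e = sla.eigh(F_use, S_e)
        blocks = []
        for b, F, X in zip(state.blocks, F_blocks, self.X_blocks):
            ix = np.ix_(b.idx, b.idx)
            Sb = self.tables.S_p[ix]
            # max-overlap tracking only for the shared SD block, where several
            # near-degenerate occupied protonic orbitals can swap mid-SCF;
            # singly-occupied HP blocks reoccupy by aufbau
            prev_occ = b.C[:, :b.n_occ] if b.n_occ > 1 else None
            C_b, eps_b = _eigh_occupy(F[ix], Sb, b.n_occ, prev_occ=prev_occ, metric=Sb)
            blocks.append(NuclearBlock(idx=b.idx, C=C_b, n_occ=b.n_occ, eps=eps_b))
        return SCFState(C_e=C_e, n_occ_e=state.n_occ_e, blocks=blocks,
                        representation=state.representation, eps_e=eps_e)

    def energy(self, state):
        return total_energy(self.tables, state).total

    # -- main loop ----------------------------------------------------------
    def run(self, state: SCFState, solver: str = None,
            reference_energy: float = None, max_iter: int = None,
            report: ConvergenceReport = None) -> ConvergenceReport:
        cfg = self.config
        solver = solver or cfg.solver
        max_iter = max_iter if max_iter is not None else cfg.max_iter
        if solver == "trah" and state.representation != SD:
            raise SolverError("TRAH supports only the Slater-determinant representation")
        rep = report or ConvergenceReport(solver=solver,
                                          representation=state.representation,
                                          guess=getattr(cfg, "guess_label", ""))
        if solver == "stepwise":
            return self._run_stepwise(state, rep, reference_energy, max_iter)
        if solver == "diis_gdm_hybrid":
            return self._run_hybrid(state, rep, reference_energy, max_iter)

        history = DIISHistory(cap=cfg.diis_cap) if solver == "diis" else None
        gdm = GDMState() if solver == "gdm" else None
        trust = 0.4
        prev_F = None
        E_prev = None
        for it in range(max_iter):
            focks = build_focks(self.tables, state)
            if getattr(cfg, "damping", 0.0) and prev_F is not None:
                d = cfg.damping
                focks = (
                    (1 - d) * focks[0] + d * prev_F[0],
                    [(1 - d) * Fn + d * Fo for Fn, Fo in zip(focks[1], prev_F[1])],
                )
            prev_F = focks
            E = self.energy(state)
            if solver in ("gdm", "trah"):
                g = orbital_gradient(self.tables, state, focks=focks)
                lay = rotation_layout(state)
                ne = lay.sizes[0]
                err_e, err_p = _rms(g[:ne]), _rms(g[ne:])
            else:
                e_e, e_p = self._errors(state, focks)
                err_e, err_p = _rms(e_e), _rms(e_p)
            dE = math.inf if E_prev is None else E - E_prev
            rep.energies.append(E)
            rep.delta_e.append(dE if E_prev is not None else math.nan)
            rep.error_e.append(err_e)
            rep.error_p.append(err_p)
            if (E_prev is not None and abs(dE) < cfg.e_tol
                    and err_e < cfg.g_tol and err_p < cfg.g_tol):
                self._finish(rep, state, reference_energy, "converged")
                return rep
            E_prev = E

            if solver == "roothaan":
                state = self._diagonalize(state, *focks)
            elif solver == "diis":
                e_e, e_p = self._errors(state, focks)
                history.push(focks[0], focks[1], e_e, e_p)
                F_e, F_blocks = history.extrapolate()
                state = self._diagonalize(state, F_e, F_blocks)
            elif solver == "gdm":
                state, E_new = self._gdm_update(state, focks, E, gdm)
            elif solver == "trah":
                state, trust = self._trah_update(state, focks, E, trust)
            else:
                raise SolverError(f"unknown solver {solver!r}")
        self._finish(rep, state, reference_energy, "failed")
        return rep

    def _finish(self, rep, state, reference_energy, outcome):
        rep.final_energy = rep.energies[-1]
        rep.n_iterations = len(rep.energies)
        rep.state = state
        er = total_energy(self.tables, state)
        rep.energy_report = json.loads(er.to_json())
        if outcome == "converged" and reference_energy is not None \
                and rep.final_energy > reference_energy + 1e-6:
            outcome = "converged_higher_energy"
        rep.outcome = outcome

    # -- GDM ----------------------------------------------------------------
    def _gdm_update(self, state, focks, E, gdm: GDMState):
        g = orbital_gradient(self.tables, state, focks=focks)
        diag = _hessian_diagonal(state, focks)
        p = gdm.direction(g, diag)
        gp = float(g @ p)
        if gp >= 0:  # not a descent direction: reset memory, steepest descent
            gdm.pairs.clear()
            p = -g / diag
            gp = float(g @ p)
        t = 1.0
        rejects = 0
        best = None
        for _ in range(30):
            s = t * p
            if rejects >= 2 and np.linalg.norm(s) > gdm.trust_radius:
                s = s * (gdm.trust_radius / np.linalg.norm(s))
            trial = apply_rotation(state, s, self.tables.S_e, self.tables.S_p)
            E_t = self.energy(trial)
            if E_t <= E + 1e-4 * float(g @ s):
                best = (s, trial, E_t)
                break
            if best is None or E_t < best[2]:
                if E_t < E:
                    best = (s, trial, E_t)
            rejects += 1
            t *= 0.5
        if best is None:  # no decrease found: take a tiny preconditioned step
            s = -1e-3 * g / diag
            trial = apply_rotation(state, s, self.tables.S_e, self.tables.S_p)
            best = (s, trial, self.energy(trial))
        s, trial, E_t = best
        g_new = orbital_gradient(self.tables, trial)
        gdm.push_pair(s, g_new - g)
        return trial, E_t

    # -- TRAH ---------------------------------------------------------------
    def _trah_update(self, state, focks, E, trust):
        g = orbital_gradient(self.tables, state, focks=focks)
        diag = _hessian_diagonal(state, focks, floor=0.02)

        def hv(v):
            return hessian_vector_product(self.tables, state, v, focks=focks)

        for _ in range(12):
            problem = AugHessianProblem(g=g, hess_vec=hv, diag=diag,
                                        trust_radius=trust)
            s = trah_step(problem)
            pred = float(g @ s) + 0.5 * float(s @ hv(s))
            trial = apply_rotation(state, s, self.tables.S_e, self.tables.S_p)
            E_t = self.energy(trial)
            if E_t > E + 1e-12:
                trust *= 0.5
                if trust < 1e-8:
                    break
                continue
            r = (E_t - E) / pred if pred < 0 else 0.0
            if r < 0.25:
                trust *= 0.7
            elif r > 0.75:
                trust = min(1.2 * trust, 1.0)
            return trial, trust
        return trial, trust  # last trial even if uphill-tiny; next loop re-checks

    # -- stepwise -----------------------------------------------------------
    def _run_stepwise(self, state, rep, reference_energy, max_iter):
        """Alternate full electronic and nuclear convergence (DIIS inner loops)."""
        cfg = self.config
        E_prev = None
        total_its = 0
        for cycle in range(max_iter):
            for subsystem in ("e", "p"):
                history = DIISHistory(cap=cfg.diis_cap)
                for _ in range(50):
                    focks = build_focks(self.tables, state)
                    E = self.energy(state)
                    e_e, e_p = self._errors(state, focks)
                    rep.energies.append(E)
                    rep.delta_e.append(E - E_prev if E_prev is not None else math.nan)
                    rep.error_e.append(_rms(e_e))
                    rep.error_p.append(_rms(e_p))
                    total_its += 1
                    err = _rms(e_e) if subsystem == "e" else _rms(e_p)
                    both_done = (E_prev is not None and abs(E - E_prev) < cfg.e_tol
                                 and _rms(e_e) < cfg.g_tol and _rms(e_p) < cfg.g_tol)
                    E_prev = E
                    if both_done:
                        self._finish(rep, state, reference_energy, "converged")
                        return rep
                    if err < cfg.g_tol:
                        break
                    history.push(focks[0], focks[1], e_e, e_p)
                    F_e, F_blocks = history.extrapolate()
                    new = self._diagonalize(state, F_e, F_blocks)
                    if subsystem == "e":
                        state = SCFState(C_e=new.C_e, n_occ_e=state.n_occ_e,
                                         blocks=state.blocks,
                                         representation=state.representation,
                                         eps_e=new.eps_e)
                    else:
                        state = SCFState(C_e=state.C_e, n_occ_e=state.n_occ_e,
                                         blocks=new.blocks,
                                         representation=state.representation,
                                         eps_e=state.eps_e)
                    if total_its >= max_iter * 10:
                        self._finish(rep, state, reference_energy, "failed")
                        return rep
        self._finish(rep, state, reference_energy, "failed")
        return rep

    # -- hybrid -------------------------------------------------------------
    def _run_hybrid(self, state, rep, reference_energy, max_iter):
        """DIIS until the combined error norm stalls, then switch to GDM."""
        cfg = self.config
        history = DIISHistory(cap=cfg.diis_cap)
        E_prev = None
        for it in range(max_iter):
            focks = build_focks(self.tables, state)
            E = self.energy(state)
            e_e, e_p = self._errors(state, focks)
            err_e, err_p = _rms(e_e), _rms(e_p)
            rep.energies.append(E)
            rep.delta_e.append(E - E_prev if E_prev is not None else math.nan)
            rep.error_e.append(err_e)
            rep.error_p.append(err_p)
            if (E_prev is not None and abs(E - E_prev) < cfg.e_tol
                    and err_e < cfg.g_tol and err_p < cfg.g_tol):
                self._finish(rep, state, reference_energy, "converged")
                return rep
            E_prev = E
            errs = [max(a, b) for a, b in zip(rep.error_e, rep.error_p)]
            if len(errs) > 6 and errs[-1] > 0.99 * errs[-6]:
                return self.run(state, solver="gdm",
                                reference_energy=reference_energy,
                                max_iter=max_iter - it, report=rep)
            history.push(focks[0], focks[1], e_e, e_p)
            F_e, F_blocks = history.extrapolate()
            state = self._diagonalize(state, F_e, F_blocks)
        self._finish(rep, state, reference_energy, "failed")
        return rep


def roothaan_step(tables, state: SCFState, layout=None, config=None) -> SCFState:
    """One Roothaan iteration: build Focks, diagonalize, reoccupy."""
    from .config import RunConfig

    driver = SCFDriver(tables, layout, config or RunConfig())
    F_e, F_blocks = build_focks(tables, state)
    return driver._diagonalize(state, F_e, F_blocks)


def scf_drive(system, electronic_shells, protonic_shells, config,
              tables=None, layout=None, guess_state=None,
              reference_energy=None, basis_dict=None) -> ConvergenceReport:
    """High-level entry: guess + simultaneous SCF loop for one configuration."""
    from .basis import build_layout
    from .guess import GuessSpec, make_guess
    from .integrals import build_tables

    config.validate()
    if tables is None:
        tables = build_tables(system, electronic_shells, protonic_shells)
    if layout is None and system.n_protons:
        layout = build_layout(system, electronic_shells, protonic_shells,
                              config.representation,
                              shared_override=config.shared_protonic_layout)
    driver = SCFDriver(tables, layout, config)
    if guess_state is None:
        spec = GuessSpec(electronic=config.guess_electronic,
                         nuclear=config.guess_nuclear,
                         nuclear_block_diagonal=config.nuclear_block_core,
                         perturbation=config.guess_perturbation,
                         seed=config.seed)
        config.guess_label = spec.label
        guess_state = make_guess(system, tables, layout, spec, basis_dict=basis_dict)
    return driver.run(guess_state, reference_energy=reference_energy)
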