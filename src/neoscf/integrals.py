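"""Gaussian integral evaluation via McMurchie-Davidson Hermite expansion.

All one- and two-body integrals over contracted Cartesian Gaussians (l <= 2)
for any pair of particle kinds: overlap, kinetic (with an arbitrary particle
mass), point-charge Coulomb, and the generic two-cloud repulsion tensor in
chemist ordering (mu nu | lambda sigma).  The 1/r12 kernel is kind-agnostic;
interaction signs (electron attraction vs proton repulsion) are applied by the
callers, not here.

Protonic exponents reach ~10^2 bohr^-2, so Coulomb integrals routinely probe
the large-argument regime of the Boys function; the incomplete-gamma route
below is accurate there and a downward recursion supplies the lower orders
stably.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
from scipy.special import gammainc, gammaln

from .basis import cartesian_components, function_offsets

SCHWARZ_THRESHOLD = 1e-14


class IntegralDomainError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Boys function
# ---------------------------------------------------------------------------

def boys_all(nmax: int, x: np.ndarray) -> np.ndarray:
    """F_n(x) for n = 0..nmax, vectorized over x (shape (nmax+1,) + x.shape).

    Top order from the regularized lower incomplete gamma,
    F_n(x) = Gamma(n+1/2) P(n+1/2, x) / (2 x^(n+1/2)), with the x -> 0 limit
    patched by its Taylor series; lower orders by downward recursion
    F_{n-1}(x) = (2x F_n(x) + e^-x) / (2n - 1), which is stable downward.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise IntegralDomainError("Boys function argument must be nonnegative")
    out = np.empty((nmax + 1,) + x.shape)
    a = nmax + 0.5
    tiny = x < 1e-13
    xs = np.where(tiny, 1.0, x)  # avoid 0^negative
    top = 0.5 * np.exp(gammaln(a)) * gammainc(a, xs) * xs ** (-a)
    series = 1.0 / (2 * nmax + 1) - x / (2 * nmax + 3) + x * x / (2 * (2 * nmax + 5))
    out[nmax] = np.where(tiny, series, top)
    if nmax > 0:
        ex = np.exp(-x)
        for n in range(nmax, 0, -1):
            out[n - 1] = (2 * x * out[n] + ex) / (2 * n - 1)
    return out


def boys(n: int, x) -> float:
    """Boys function F_n(x) = integral_0^1 t^(2n) exp(-x t^2) dt."""
    if n < 0 or int(n) != n:
        raise IntegralDomainError("Boys order must be a nonnegative integer")
    scalar = np.isscalar(x)
    val = boys_all(int(n), np.asarray(x, dtype=float))[int(n)]
    return float(val) if scalar else val


# ---------------------------------------------------------------------------
# Hermite expansion coefficients
# ---------------------------------------------------------------------------

def hermite_expansion(imax: int, jmax: int, a: float, b: float, AB: float) -> np.ndarray:
    """1D Hermite coefficients E[i, j, t] for primitives exp(-a(x-A)^2), exp(-b(x-B)^2).

    AB = A - B.  Entries with t > i + j are zero.
    """
    p = a + b
    mu = a * b / p
    E = np.zeros((imax + 1, jmax + 1, imax + jmax + 1))
    E[0, 0, 0] = np.exp(-mu * AB * AB)
    PA = -b / p * AB  # P - A
    PB = a / p * AB   # P - B
    for i in range(imax + 1):
        for j in range(jmax + 1):
            if i == 0 and j == 0:
                continue
            for t in range(i + j + 1):
                if j == 0:
                    v = 0.0
                    if t - 1 >= 0:
                        v += E[i - 1, j, t - 1] / (2 * p)
                    v += PA * E[i - 1, j, t]
                    if t + 1 <= i + j - 1:
                        v += (t + 1) * E[i - 1, j, t + 1]
                else:
                    v = 0.0
                    if t - 1 >= 0:
                        v += E[i, j - 1, t - 1] / (2 * p)
                    v += PB * E[i, j - 1, t]
                    if t + 1 <= i + j - 1:
                        v += (t + 1) * E[i, j - 1, t + 1]
                E[i, j, t] = v
    return E


def hermite_coulomb(Lx: int, Ly: int, Lz: int, p_eff: np.ndarray, PQ: np.ndarray) -> np.ndarray:
    """Hermite Coulomb integrals R_{t,u,v}(p_eff, PQ) on a grid.

    Returns array of shape (Lx+1, Ly+1, Lz+1) + grid, where grid is the shape
    of ``p_eff`` and ``PQ`` has shape grid + (3,).
    """
    p_eff = np.asarray(p_eff, float)
    PQ = np.asarray(PQ, float)
    grid = p_eff.shape
    nmax = Lx + Ly + Lz
    T = p_eff * np.einsum("...i,...i->...", PQ, PQ)
    F = boys_all(nmax, T)
    X, Y, Z = PQ[..., 0], PQ[..., 1], PQ[..., 2]
    cache: dict = {}

    def R(t, u, v, n):
        key = (t, u, v, n)
        if key in cache:
            return cache[key]
        if t == u == v == 0:
            val = (-2.0 * p_eff) ** n * F[n]
        elif t > 0:
            val = X * R(t - 1, u, v, n + 1)
            if t > 1:
                val = val + (t - 1) * R(t - 2, u, v, n + 1)
        elif u > 0:
            val = Y * R(t, u - 1, v, n + 1)
            if u > 1:
                val = val + (u - 1) * R(t, u - 2, v, n + 1)
        else:
            val = Z * R(t, u, v - 1, n + 1)
            if v > 1:
                val = val + (v - 1) * R(t, u, v - 2, n + 1)
        cache[key] = val
        return val

    out = np.empty((Lx + 1, Ly + 1, Lz + 1) + grid)
    for t in range(Lx + 1):
        for u in range(Ly + 1):
            for v in range(Lz + 1):
                out[t, u, v] = R(t, u, v, 0)
    return out


# ---------------------------------------------------------------------------
# One-body integrals
# ---------------------------------------------------------------------------

def overlap_kinetic(shells, mass: float = 1.0):
    """Overlap S and kinetic T = <mu| -1/(2 mass) nabla^2 |nu> over a shell list."""
    offs, n = function_offsets(shells)
    S = np.zeros((n, n))
    T = np.zeros((n, n))
    for si, sa in enumerate(shells):
        comps_a = cartesian_components(sa.l)
        ca = [sa.contraction(*c) for c in comps_a]
        for sj in range(si + 1):
            sb = shells[sj]
            comps_b = cartesian_components(sb.l)
            cb = [sb.contraction(*c) for c in comps_b]
            AB = sa.center - sb.center
            Sblk = np.zeros((len(comps_a), len(comps_b)))
            Tblk = np.zeros_like(Sblk)
            for ia, a in enumerate(sa.exponents):
                for ib, b in enumerate(sb.exponents):
                    p = a + b
                    fac = np.sqrt(np.pi / p)
                    # 1D overlaps up to jmax+2 for the kinetic relation
                    E = [hermite_expansion(sa.l, sb.l + 2, a, b, AB[d]) for d in range(3)]

                    def s1(d, i, j):
                        return 0.0 if j < 0 else E[d][i, j, 0] * fac

                    for A, (lax, lay, laz) in enumerate(comps_a):
                        for B, (lbx, lby, lbz) in enumerate(comps_b):
                            la3 = (lax, lay, laz)
                            lb3 = (lbx, lby, lbz)
                            sv = [s1(d, la3[d], lb3[d]) for d in range(3)]
                            kv = []
                            for d in range(3):
                                j = lb3[d]
                                k = (
                                    -2.0 * b * b * s1(d, la3[d], j + 2)
                                    + b * (2 * j + 1) * sv[d]
                                    - 0.5 * j * (j - 1) * s1(d, la3[d], j - 2)
                                )
                                kv.append(k)
                            c = ca[A][ia] * cb[B][ib]
                            Sblk[A, B] += c * sv[0] * sv[1] * sv[2]
                            Tblk[A, B] += c * (
                                kv[0] * sv[1] * sv[2]
                                + sv[0] * kv[1] * sv[2]
                                + sv[0] * sv[1] * kv[2]
                            )
            ia0, ib0 = offs[si], offs[sj]
            S[ia0:ia0 + len(comps_a), ib0:ib0 + len(comps_b)] = Sblk
            T[ia0:ia0 + len(comps_a), ib0:ib0 + len(comps_b)] = Tblk
            if si != sj:
                S[ib0:ib0 + len(comps_b), ia0:ia0 + len(comps_a)] = Sblk.T
                T[ib0:ib0 + len(comps_b), ia0:ia0 + len(comps_a)] = Tblk.T
    return S, T / mass


def point_charge_matrix(shells, charges, sign: int) -> np.ndarray:
    """V_munu = sign * sum_A Z_A <mu| 1/|r - R_A| |nu>.

    ``charges`` is a list of (Z, position) pairs; sign is -1 for electrons,
    +1 for protons.
    """
    offs, n = function_offsets(shells)
    V = np.zeros((n, n))
    if not charges:
        return V
    Z = np.array([c[0] for c in charges], float)
    Rc = np.array([c[1] for c in charges], float)
    for si, sa in enumerate(shells):
        comps_a = cartesian_components(sa.l)
        ca = [sa.contraction(*c) for c in comps_a]
        for sj in range(si + 1):
            sb = shells[sj]
            comps_b = cartesian_components(sb.l)
            cb = [sb.contraction(*c) for c in comps_b]
            AB = sa.center - sb.center
            L = sa.l + sb.l
            blk = np.zeros((len(comps_a), len(comps_b)))
            for ia, a in enumerate(sa.exponents):
                for ib, b in enumerate(sb.exponents):
                    p = a + b
                    P = (a * sa.center + b * sb.center) / p
                    E = [hermite_expansion(sa.l, sb.l, a, b, AB[d]) for d in range(3)]
                    PQ = P[None, :] - Rc  # (nA, 3)
                    R = hermite_coulomb(L, L, L, np.full(len(Z), p), PQ)
                    RZ = np.tensordot(R, Z, axes=([3], [0]))  # (L+1, L+1, L+1)
                    pref = 2.0 * np.pi / p
                    for A, (lax, lay, laz) in enumerate(comps_a):
                        for B, (lbx, lby, lbz) in enumerate(comps_b):
                            acc = 0.0
                            for t in range(lax + lbx + 1):
                                for u in range(lay + lby + 1):
                                    for v in range(laz + lbz + 1):
                                        acc += (
                                            E[0][lax, lbx, t]
                                            * E[1][lay, lby, u]
                                            * E[2][laz, lbz, v]
                                            * RZ[t, u, v]
                                        )
                            blk[A, B] += pref * ca[A][ia] * cb[B][ib] * acc
            ia0, ib0 = offs[si], offs[sj]
            V[ia0:ia0 + len(comps_a), ib0:ib0 + len(comps_b)] = blk
            if si != sj:
                V[ib0:ib0 + len(comps_b), ia0:ia0 + len(comps_a)] = blk.T
    return sign * V


# ---------------------------------------------------------------------------
# Two-body Coulomb tensor
# ---------------------------------------------------------------------------

class _Pair:
    """Precomputed Hermite data for one shell pair (all primitive combos)."""

    __slots__ = ("i", "j", "rows", "cols", "L", "ps", "Ps", "E3", "E3s",
                 "tuv", "schwarz")

    def __init__(self, shells, offs, i, j):
        sa, sb = shells[i], shells[j]
        self.i, self.j = i, j
        self.rows = np.arange(offs[i], offs[i] + sa.n_functions)
        self.cols = np.arange(offs[j], offs[j] + sb.n_functions)
        L = sa.l + sb.l
        self.L = L
        comps_a = cartesian_components(sa.l)
        comps_b = cartesian_components(sb.l)
        ca = np.array([sa.contraction(*c) for c in comps_a])  # (na, nprim_a)
        cb = np.array([sb.contraction(*c) for c in comps_b])
        AB = sa.center - sb.center
        K = len(sa.exponents) * len(sb.exponents)
        self.ps = np.empty(K)
        self.Ps = np.empty((K, 3))
        nh = (L + 1) ** 3
        tuv = np.array([(t, u, v) for t in range(L + 1) for u in range(L + 1) for v in range(L + 1)])
        self.tuv = tuv
        E3 = np.zeros((K, len(comps_a) * len(comps_b), nh))
        k = 0
        for ia, a in enumerate(sa.exponents):
            for ib, b in enumerate(sb.exponents):
                p = a + b
                self.ps[k] = p
                self.Ps[k] = (a * sa.center + b * sb.center) / p
                E = [hermite_expansion(sa.l, sb.l, a, b, AB[d]) for d in range(3)]
                for A, (lax, lay, laz) in enumerate(comps_a):
                    for B, (lbx, lby, lbz) in enumerate(comps_b):
                        ex = np.zeros(L + 1)
                        ex[: lax + lbx + 1] = E[0][lax, lbx, : lax + lbx + 1]
                        ey = np.zeros(L + 1)
                        ey[: lay + lby + 1] = E[1][lay, lby, : lay + lby + 1]
                        ez = np.zeros(L + 1)
                        ez[: laz + lbz + 1] = E[2][laz, lbz, : laz + lbz + 1]
                        prod = (ex[:, None, None] * ey[None, :, None] * ez[None, None, :]).ravel()
                        E3[k, A * len(comps_b) + B] = ca[A][ia] * cb[B][ib] * prod
                k += 1
        self.E3 = E3
        sign = (-1.0) ** tuv.sum(axis=1)
        self.E3s = E3 * sign[None, None, :]
        self.schwarz = 0.0


def _pair_block(P: _Pair, Q: _Pair) -> np.ndarray:
    """Contracted ERI block ( P.ab | Q.cd ) of shape (nab, ncd)."""
    p = P.ps[:, None]
    q = Q.ps[None, :]
    p_eff = p * q / (p + q)
    pref = 2.0 * np.pi ** 2.5 / (p * q * np.sqrt(p + q))
    PQ = P.Ps[:, None, :] - Q.Ps[None, :, :]
    L1, L2 = P.L, Q.L
    R = hermite_coulomb(L1 + L2, L1 + L2, L1 + L2, p_eff, PQ)
    t1, u1, v1 = P.tuv.T
    t2, u2, v2 = Q.tuv.T
    # (nh1, nh2, K1, K2)
    Rm = R[t1[:, None] + t2[None, :], u1[:, None] + u2[None, :], v1[:, None] + v2[None, :]]
    Rm = Rm * pref[None, None, :, :]
    K1, nab, nh1 = P.E3.shape
    K2, ncd, nh2 = Q.E3s.shape
    A = P.E3.transpose(1, 0, 2).reshape(nab, K1 * nh1)
    B = Q.E3s.transpose(1, 0, 2).reshape(ncd, K2 * nh2)
    M = Rm.transpose(2, 0, 3, 1).reshape(K1 * nh1, K2 * nh2)
    return A @ M @ B.T


def coulomb_tensor(shells_bra, shells_ket=None) -> np.ndarray:
    """Four-index Coulomb tensor (mu nu | lambda sigma), chemist ordering.

    ``shells_bra`` carries the (mu nu) charge cloud, ``shells_ket`` the
    (lambda sigma) cloud (defaults to the bra list).  Pair blocks below the
    Schwarz bound |(mu nu|lam sig)| <= sqrt((mu nu|mu nu)(lam sig|lam sig))
    with threshold 1e-14 are skipped.
    """
    same = shells_ket is None or shells_ket is shells_bra
    offs_b, nb = function_offsets(shells_bra)
    pairs_b = [_Pair(shells_bra, offs_b, i, j)
               for i in range(len(shells_bra)) for j in range(i + 1)]
    if same:
        pairs_k, nk = pairs_b, nb
    else:
        offs_k, nk = function_offsets(shells_ket)
        pairs_k = [_Pair(shells_ket, offs_k, i, j)
                   for i in range(len(shells_ket)) for j in range(i + 1)]
    for plist in ([pairs_b] if same else [pairs_b, pairs_k]):
        for P in plist:
            diag = np.diag(_pair_block(P, P))
            P.schwarz = np.sqrt(np.max(np.abs(diag)))

    out = np.zeros((nb, nb, nk, nk))

    def scatter(P, Q, blk):
        b4 = blk.reshape(len(P.rows), len(P.cols), len(Q.rows), len(Q.cols))
        r, c, R_, C_ = P.rows, P.cols, Q.rows, Q.cols
        out[np.ix_(r, c, R_, C_)] = b4
        out[np.ix_(c, r, R_, C_)] = b4.transpose(1, 0, 2, 3)
        out[np.ix_(r, c, C_, R_)] = b4.transpose(0, 1, 3, 2)
        out[np.ix_(c, r, C_, R_)] = b4.transpose(1, 0, 3, 2)

    for ip, P in enumerate(pairs_b):
        qlist = pairs_k[: ip + 1] if same else pairs_k
        for Q in qlist:
            if P.schwarz * Q.schwarz < SCHWARZ_THRESHOLD:
                continue
            blk = _pair_block(P, Q)
            scatter(P, Q, blk)
            if same and Q is not P:
                b4 = blk.reshape(len(P.rows), len(P.cols), len(Q.rows), len(Q.cols))
                blk_T = b4.transpose(2, 3, 0, 1).reshape(
                    len(Q.rows) * len(Q.cols), len(P.rows) * len(P.cols))
                scatter(Q, P, blk_T)
    return out


# ---------------------------------------------------------------------------
# Assembled tables
# ---------------------------------------------------------------------------

@dataclass
class IntegralTables:
    """All matrices/tensors an SCF needs, in atomic units.

    Nuclear (protonic) quantities use the shared full protonic basis; HP
    restriction to per-proton blocks happens downstream via the layout.
    Sign conventions: V_e is the electron/classical-nucleus attraction
    (negative), V_p the proton/classical-nucleus repulsion (positive);
    the ERI tensors are raw 1/r12 clouds with no interaction sign.
    """

    S_e: np.ndarray
    T_e: np.ndarray
    V_e: np.ndarray
    h_e: np.ndarray
    S_p: np.ndarray
    T_p: np.ndarray
    V_p: np.ndarray
    h_p: np.ndarray
    eri_ee: np.ndarray
    eri_pp: np.ndarray
    eri_ep: np.ndarray
    e_nuclear_repulsion: float

    @property
    def n_e(self):
        return self.S_e.shape[0]

    @property
    def n_p(self):
        return self.S_p.shape[0]


def build_tables(system, electronic_shells, protonic_shells) -> IntegralTables:
    """Evaluate every integral table for one system + basis combination."""
    charges = [(n.charge, n.position) for n in system.nuclei]
    S_e, T_e = overlap_kinetic(electronic_shells, mass=1.0)
    V_e = point_charge_matrix(electronic_shells, charges, sign=-1)
    eri_ee = coulomb_tensor(electronic_shells)
    if protonic_shells:
        masses = {p.mass for p in system.protons}
        if len(masses) != 1:
            raise ValueError("all quantum protons must share one mass")
        m_p = masses.pop()
        S_p, T_p = overlap_kinetic(protonic_shells, mass=m_p)
        V_p = point_charge_matrix(protonic_shells, charges, sign=+1)
        eri_pp = coulomb_tensor(protonic_shells)
        eri_ep = coulomb_tensor(electronic_shells, protonic_shells)
    else:
        n0 = 0
        S_p = T_p = V_p = np.zeros((n0, n0))
        eri_pp = np.zeros((n0,) * 4)
        eri_ep = np.zeros((S_e.shape[0], S_e.shape[0], n0, n0))
    ev = np.linalg.eigvalsh(S_e)
    if ev.min() < 1e-8:
        import warnings

        warnings.warn(
            f"near-linear dependence in electronic basis (min S eigenvalue {ev.min():.2e})"
        )
    return IntegralTables(
        S_e=S_e, T_e=T_e, V_e=V_e, h_e=T_e + V_e,
        S_p=S_p, T_p=T_p, V_p=V_p, h_p=T_p + V_p,
        eri_ee=eri_ee, eri_pp=eri_pp, eri_ep=eri_ep,
        e_nuclear_repulsion=system.classical_repulsion(),
    )


def save_tables(tables: IntegralTables, path: str):
    """Dump tables to a single .npz container with a content checksum."""
    arrays = {f: getattr(tables, f) for f in (
        "S_e", "T_e", "V_e", "h_e", "S_p", "T_p", "V_p", "h_p",
        "eri_ee", "eri_pp", "eri_ep")}
    digest = hashlib.sha256(b"".join(np.ascontiguousarray(a).tobytes()
                                     for a in arrays.values())).hexdigest()
    np.savez(path, e_nuclear_repulsion=tables.e_nuclear_repulsion,
             checksum=np.bytes_(digest.encode()), **arrays)


def load_tables(path: str) -> IntegralTables:
    with np.load(path) as z:
        arrays = {k: z[k] for k in z.files if k not in ("checksum", "e_nuclear_repulsion")}
        digest = hashlib.sha256(b"".join(np.ascontiguousarray(arrays[f]).tobytes()
                                         for f in ("S_e", "T_e", "V_e", "h_e", "S_p",
                                                   "T_p", "V_p", "h_p", "eri_ee",
                                                   "eri_pp", "eri_ep"))).hexdigest()
        stored = bytes(z["checksum"]).decode()
        if digest != stored:
            raise IOError(f"integral table checksum mismatch in {path}")
        return IntegralTables(e_nuclear_repulsion=float(z["e_nuclear_repulsion"]), **arrays)
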