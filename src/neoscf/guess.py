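"""Initial orbital guesses for the electronic and nuclear subsystems.

Electronic variants: ``core`` (diagonalize the one-electron core Hamiltonian)
and ``sad`` (superposition of converged spherically-averaged atomic
densities).  Nuclear variants: ``core`` (block-diagonalized nuclear core
Hamiltonian, one block per proton center, which prevents several protons
collapsing onto the same center) and ``sad`` (each proton's ground state in
the frozen SAD electronic field, solved on its own center's block).

All guesses are deterministic given (system, basis, GuessSpec); an optional
seeded random orthogonal perturbation supports robustness sweeps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as sla

from .basis import HP, HPSTAR, SD, function_offsets, shells_for_system
from .neo_core import (NuclearBlock, SCFState, build_electronic_fock, coulomb,
                       coulomb_pe, density_from_coeffs, exchange)


@dataclass
class GuessSpec:
    electronic: str = "sad"          # core | sad
    nuclear: str = "sad"             # core | sad
    nuclear_block_diagonal: bool = True
    perturbation: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.electronic not in ("core", "sad"):
            raise ValueError(f"unknown electronic guess {self.electronic!r}")
        if self.nuclear not in ("core", "sad"):
            raise ValueError(f"unknown nuclear guess {self.nuclear!r}")
        if self.perturbation < 0:
            raise ValueError("perturbation amplitude must be >= 0")

    @property
    def label(self) -> str:
        return f"{self.electronic},{self.nuclear}"


def localized_first_orbital(c0: np.ndarray, C_full: np.ndarray, S: np.ndarray) -> np.ndarray:
    """Orbital set whose first (occupied) column is ``c0``.

    Used for shared-block HP guesses: the remaining columns of ``C_full`` are
    projected off ``c0`` and Loewdin-orthonormalized, so each distinguishable
    proton starts localized at its own center even when its variational block
    spans every center.
    """
    c0 = c0 / np.sqrt(c0 @ S @ c0)
    ovl = C_full.T @ S @ c0
    drop = int(np.argmax(np.abs(ovl)))
    rest = np.delete(C_full, drop, axis=1)
    rest = rest - np.outer(c0, c0 @ S @ rest)
    rest = symmetric_orthonormalize(rest, S)
    return np.column_stack([c0, rest])


def symmetric_orthonormalize(C: np.ndarray, S: np.ndarray) -> np.ndarray:
    """Loewdin orthonormalization of the columns of C against metric S."""
    M = C.T @ S @ C
    w, U = np.linalg.eigh(M)
    if w.min() < 1e-10:
        raise np.linalg.LinAlgError("guess orbitals are numerically linearly dependent")
    return C @ U @ np.diag(w ** -0.5) @ U.T


def core_guess_electronic(tables) -> tuple:
    """Solve h^e C = S^e C eps; returns (C, eps), occupied by aufbau order."""
    w = np.linalg.eigvalsh(tables.S_e)
    if w.min() < 1e-10:
        raise np.linalg.LinAlgError("electronic overlap matrix is numerically singular")
    eps, C = sla.eigh(tables.h_e, tables.S_e)
    return C, eps


def core_guess_nuclear(tables, layout, representation, block_diagonal: bool = True):
    """Nuclear core guess: list of NuclearBlock matching the representation.

    SD with ``block_diagonal`` zeroes inter-center coupling: each proton
    center's (h, S) sub-block is diagonalized separately, the per-center
    ground states become the occupied orbitals, and the assembled set is
    Loewdin-orthonormalized against the full S^p.  The non-block variant
    (``block_diagonal=False``) diagonalizes the full nuclear core Hamiltonian
    -- the pathological guess in which protons can collapse onto one center.
    """
    n_p = tables.n_p
    if representation == SD:
        n_prot = len(layout.center_blocks)
        if not block_diagonal:
            eps, C = sla.eigh(tables.h_p, tables.S_p)
            return [NuclearBlock(idx=np.arange(n_p), C=C, n_occ=n_prot, eps=eps)]
        occ_cols, virt_cols = [], []
        for idx in layout.center_blocks:
            ix = np.ix_(idx, idx)
            eps_b, C_b = sla.eigh(tables.h_p[ix], tables.S_p[ix])
            full = np.zeros((n_p, C_b.shape[1]))
            full[idx, :] = C_b
            occ_cols.append(full[:, 0])
            virt_cols.extend(full[:, 1:].T)
        C = np.column_stack(occ_cols + virt_cols)
        C = symmetric_orthonormalize(C, tables.S_p)
        return [NuclearBlock(idx=np.arange(n_p), C=C, n_occ=n_prot)]
    blocks = []
    for pi, idx in enumerate(layout.proton_blocks):
        ix = np.ix_(idx, idx)
        eps_b, C_b = sla.eigh(tables.h_p[ix], tables.S_p[ix])
        own = layout.center_blocks[pi]
        if idx.size != own.size:
            # shared-set override: localize the occupied orbital on the
            # proton's own center to avoid center collapse
            jx = np.ix_(own, own)
            _, C_o = sla.eigh(tables.h_p[jx], tables.S_p[jx])
            c0 = np.zeros(n_p)
            c0[own] = C_o[:, 0]
            C_b = localized_first_orbital(c0[idx], C_b, tables.S_p[ix])
            eps_b = None
        blocks.append(NuclearBlock(idx=idx, C=C_b, n_occ=1, eps=eps_b))
    return blocks


# ---------------------------------------------------------------------------
# SAD
# ---------------------------------------------------------------------------

_atomic_cache: dict = {}


def _basis_hash(templates) -> tuple:
    return tuple((l, tuple(np.round(e, 12)), tuple(np.round(c, 12)))
                 for l, e, c in templates)


def _atomic_density(element: str, n_elec: int, templates) -> np.ndarray:
    """Spherically averaged fractional-occupation atomic RHF density.

    Runs a small closed-shell SCF for one atom at the origin in the given
    element basis; electrons in the frontier degenerate set share occupation
    equally, enforcing spherical symmetry.  Cached per (element, basis).
    """
    from .integrals import coulomb_tensor, overlap_kinetic, point_charge_matrix
    from .basis import GaussianShell

    key = (element, n_elec, _basis_hash(templates))
    if key in _atomic_cache:
        return _atomic_cache[key]
    shells = [GaussianShell(center=np.zeros(3), l=l, exponents=e, coeffs=c)
              for l, e, c in templates]
    S, T = overlap_kinetic(shells)
    from .constants import ELEMENT_CHARGES
    V = point_charge_matrix(shells, [(ELEMENT_CHARGES[element], np.zeros(3))], sign=-1)
    h = T + V
    eri = coulomb_tensor(shells)

    def occupations(eps):
        f = np.zeros_like(eps)
        remaining = float(n_elec)
        i = 0
        while remaining > 1e-12 and i < len(eps):
            j = i
            while j + 1 < len(eps) and eps[j + 1] - eps[i] < 1e-6:
                j += 1
            g = j - i + 1
            fill = min(remaining, 2.0 * g)
            f[i:j + 1] = fill / g
            remaining -= fill
            i = j + 1
        return f

    eps, C = sla.eigh(h, S)
    if n_elec == 1:
        # one-electron atom: the core solution is exact, no self-interaction
        D = np.outer(C[:, 0], C[:, 0])
        _atomic_cache[key] = D
        return D
    f = occupations(eps)
    D = (C * f) @ C.T
    converged = False
    for _ in range(500):
        F = h + coulomb(eri, D) - 0.5 * exchange(eri, D)
        eps, C = sla.eigh(F, S)
        f = occupations(eps)
        D_new = (C * f) @ C.T
        D_next = 0.6 * D_new + 0.4 * D
        if np.max(np.abs(D_next - D)) < 1e-10:
            D = D_next
            converged = True
            break
        D = D_next
    if not converged:
        warnings.warn(f"atomic SCF for {element} did not converge; using core density")
        eps, C = sla.eigh(h, S)
        f = occupations(eps)
        D = (C * f) @ C.T
    _atomic_cache[key] = D
    return D


def sad_guess_electronic(system, basis_dict, tables) -> np.ndarray:
    """Block-diagonal superposition of atomic densities, scaled to N_e.

    Classical atoms contribute their neutral-atom density; each quantum-proton
    center contributes a one-electron hydrogen-like density (the electron it
    carries), all assembled block-diagonally and globally rescaled so that
    Tr(D S) = N_e.
    """
    shells = shells_for_system(system, basis_dict)
    offs, n = function_offsets(shells)
    D = np.zeros((n, n))
    shell_ptr = 0
    func_ptr = 0
    for el, pos in system.centers:
        templates = basis_dict[el]
        nfun = sum((l + 1) * (l + 2) // 2 for l, _, _ in templates)
        from .constants import ELEMENT_CHARGES
        n_elec = 1 if (el == "H") else ELEMENT_CHARGES[el]
        D_at = _atomic_density(el, n_elec, templates)
        D[func_ptr:func_ptr + nfun, func_ptr:func_ptr + nfun] = D_at
        func_ptr += nfun
        shell_ptr += len(templates)
    tr = float(np.einsum("mn,mn->", D, tables.S_e))
    if tr > 0:
        D *= system.n_electrons / tr
    return D


def sad_guess_nuclear(system, tables, layout, D_e_sad):
    """Per-proton ground state of h^p - J^pe[D^e_SAD] on its own center block."""
    n_p = tables.n_p
    Vpe = -coulomb_pe(tables.eri_ep, D_e_sad)
    h_eff = tables.h_p + Vpe
    if layout.representation == SD:
        occ_cols, virt_cols = [], []
        for idx in layout.center_blocks:
            ix = np.ix_(idx, idx)
            eps_b, C_b = sla.eigh(h_eff[ix], tables.S_p[ix])
            full = np.zeros((n_p, C_b.shape[1]))
            full[idx, :] = C_b
            occ_cols.append(full[:, 0])
            virt_cols.extend(full[:, 1:].T)
        C = symmetric_orthonormalize(np.column_stack(occ_cols + virt_cols), tables.S_p)
        return [NuclearBlock(idx=np.arange(n_p), C=C, n_occ=len(layout.center_blocks))]
    blocks = []
    for pi, idx in enumerate(layout.proton_blocks):
        own = layout.center_blocks[pi]
        ix = np.ix_(idx, idx)
        eps_b, C_b = sla.eigh(h_eff[ix], tables.S_p[ix])
        if idx.size != own.size:
            # shared-set override: localize the occupied guess orbital on the
            # proton's own center (frozen-field solve on the own-center block)
            jx = np.ix_(own, own)
            _, C_o = sla.eigh(h_eff[jx], tables.S_p[jx])
            c0 = np.zeros(n_p)
            c0[own] = C_o[:, 0]
            C_b = localized_first_orbital(c0[idx], C_b, tables.S_p[ix])
            eps_b = None
        blocks.append(NuclearBlock(idx=idx, C=C_b, n_occ=1, eps=eps_b))
    return blocks


def _perturb(C: np.ndarray, n_occ: int, amp: float, rng) -> np.ndarray:
    """Random occupied-virtual rotation of amplitude ``amp`` (radians-ish)."""
    n = C.shape[1]
    nv = n - n_occ
    if nv == 0 or n_occ == 0 or amp == 0:
        return C
    x = amp * rng.standard_normal((nv, n_occ))
    kappa = np.zeros((n, n))
    kappa[n_occ:, :n_occ] = x
    kappa[:n_occ, n_occ:] = -x.T
    return C @ sla.expm(kappa)


def make_guess(system, tables, layout, spec: GuessSpec, basis_dict=None) -> SCFState:
    """Assemble the full initial SCFState for one run."""
    n_occ_e = system.n_electrons // 2
    if spec.electronic == "core":
        C_e, eps_e = core_guess_electronic(tables)
    else:
        if basis_dict is None:
            raise ValueError("SAD electronic guess needs the electronic basis dict")
        D_sad = sad_guess_electronic(system, basis_dict, tables)
        F0 = build_electronic_fock(tables, D_sad, [])
        eps_e, C_e = sla.eigh(F0, tables.S_e)
    if system.n_protons == 0:
        blocks = []
    elif spec.nuclear == "core":
        blocks = core_guess_nuclear(tables, layout, layout.representation,
                                    block_diagonal=spec.nuclear_block_diagonal)
    else:
        if spec.electronic == "sad":
            D_e_field = D_sad
        else:
            D_e_field = density_from_coeffs(C_e, n_occ_e, 2.0)
        blocks = sad_guess_nuclear(system, tables, layout, D_e_field)
    if spec.perturbation > 0:
        rng = np.random.default_rng(spec.seed)
        C_e = _perturb(C_e, n_occ_e, spec.perturbation, rng)
        for b in blocks:
            b.C = _perturb(b.C, b.n_occ, spec.perturbation, rng)
    rep = layout.representation if layout is not None else SD
    return SCFState(C_e=C_e, n_occ_e=n_occ_e, blocks=blocks,
                    representation=rep)
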