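"""NEO-HF densities, Fock matrices, and the total-energy decomposition.

Representations of the quantum-proton subsystem:

``SD``
    One antisymmetrized (high-spin) nuclear Slater determinant over a shared
    basis block: a single nuclear Fock operator
    F^p = h^p + J^pp[D] - K^pp[D] - J^pe[D^e] whose proton-proton sum runs
    unrestricted, i.e. includes the self-Coulomb and self-exchange terms.
``HP``
    Distinguishable protons (Hartree product): per-proton Fock operators
    F_i = h^p + sum_{j != i} J^pp[D_j] - J^pe[D^e] with no exchange and no
    self-Coulomb.
``HPstar``
    HP plus per-proton self-Coulomb and self-exchange in the Fock operator.
    These cancel exactly in the energy (for a singly-occupied orbital the
    self Coulomb and exchange contractions coincide), so HP and HP* share
    one energy surface while presenting different iteration maps to the SCF.

All densities passed between modules live in the full nuclear basis
dimension; HP block restriction is applied at diagonalization time via the
:class:`~neoscf.basis.BasisLayout`.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .basis import HP, HPSTAR, SD


class RepresentationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Contractions
# ---------------------------------------------------------------------------

def coulomb(eri: np.ndarray, D: np.ndarray) -> np.ndarray:
    """J[D]_munu = (mu nu | lam sig) D_lamsig."""
    return np.einsum("mnls,ls->mn", eri, D, optimize=True)


def exchange(eri: np.ndarray, D: np.ndarray) -> np.ndarray:
    """K[D]_munu = (mu lam | nu sig) D_lamsig."""
    return np.einsum("mlns,ls->mn", eri, D, optimize=True)


def coulomb_ep(eri_ep: np.ndarray, D_p: np.ndarray) -> np.ndarray:
    """Electronic-basis Coulomb matrix of a nuclear density (no sign)."""
    return np.einsum("mnls,ls->mn", eri_ep, D_p, optimize=True)


def coulomb_pe(eri_ep: np.ndarray, D_e: np.ndarray) -> np.ndarray:
    """Nuclear-basis Coulomb matrix of the electronic density (no sign)."""
    return np.einsum("mnls,mn->ls", eri_ep, D_e, optimize=True)


def density_from_coeffs(C: np.ndarray, n_occ: int, occupation: float) -> np.ndarray:
    """D = occupation * C_occ C_occ^T (occupation 2 for RHF electrons, 1 per proton)."""
    if n_occ > C.shape[1]:
        raise ValueError(f"n_occ={n_occ} exceeds orbital count {C.shape[1]}")
    Co = C[:, :n_occ]
    return occupation * (Co @ Co.T)


# ---------------------------------------------------------------------------
# State
# ---------------------------------------------------------------------------

@dataclass
class NuclearBlock:
    """Orbitals of one nuclear diagonalization block.

    SD has a single block with ``n_occ = N_p``; HP/HP* has one block per
    proton with ``n_occ = 1``.  ``idx`` indexes the full nuclear basis.
    """

    idx: np.ndarray
    C: np.ndarray
    n_occ: int
    eps: np.ndarray = None

    def embed_density(self, n_full: int, orbital: int = None) -> np.ndarray:
        """Full-dimension density of all occupied orbitals (or one of them)."""
        D = np.zeros((n_full, n_full))
        cols = [orbital] if orbital is not None else range(self.n_occ)
        sub = sum(np.outer(self.C[:, i], self.C[:, i]) for i in cols)
        D[np.ix_(self.idx, self.idx)] = sub
        return D


@dataclass
class SCFState:
    """Orbital coefficients for both subsystems at one SCF iteration."""

    C_e: np.ndarray
    n_occ_e: int
    blocks: list
    representation: str
    eps_e: np.ndarray = None
    energy: float = math.nan
    iteration: int = 0

    def electronic_density(self) -> np.ndarray:
        return density_from_coeffs(self.C_e, self.n_occ_e, 2.0)

    def proton_densities(self, n_full: int):
        """One full-dimension unit-trace density per quantum proton."""
        if not self.blocks:
            return []
        if self.representation == SD:
            blk = self.blocks[0]
            return [blk.embed_density(n_full, orbital=i) for i in range(blk.n_occ)]
        return [b.embed_density(n_full) for b in self.blocks]


# ---------------------------------------------------------------------------
# Fock builders
# ---------------------------------------------------------------------------

def build_electronic_fock(tables, D_e: np.ndarray, D_p_list) -> np.ndarray:
    """F^e = h^e + J^ee[D^e] - 1/2 K^ee[D^e] - sum_i J^ep[D_i]."""
    if D_e.shape != tables.h_e.shape:
        raise ValueError("electronic density dimension mismatch")
    F = tables.h_e + coulomb(tables.eri_ee, D_e) - 0.5 * exchange(tables.eri_ee, D_e)
    if D_p_list:
        D_tot = np.sum(D_p_list, axis=0)
        F = F - coulomb_ep(tables.eri_ep, D_tot)
    return F


def build_nuclear_fock_sd(tables, D_e: np.ndarray, D_p_total: np.ndarray,
                          representation: str = SD) -> np.ndarray:
    """Shared-determinant nuclear Fock, self terms included by construction."""
    if representation != SD:
        raise RepresentationError("build_nuclear_fock_sd requires the SD layout")
    return (tables.h_p + coulomb(tables.eri_pp, D_p_total)
            - exchange(tables.eri_pp, D_p_total)
            - coulomb_pe(tables.eri_ep, D_e))


def build_nuclear_fock_hp(tables, D_e: np.ndarray, D_p_list, i: int,
                          include_self: bool = False,
                          representation: str = HP) -> np.ndarray:
    """Per-proton Hartree-product Fock (full nuclear dimension).

    ``include_self=True`` gives the HP* operator, adding J[D_i] - K[D_i];
    the addition leaves every converged energy unchanged (exact cancellation)
    but changes the iteration map.
    """
    if representation == SD:
        raise RepresentationError("build_nuclear_fock_hp requires an HP layout")
    F = tables.h_p - coulomb_pe(tables.eri_ep, D_e)
    for j, Dj in enumerate(D_p_list):
        if j != i:
            F = F + coulomb(tables.eri_pp, Dj)
    if include_self:
        Di = D_p_list[i]
        F = F + coulomb(tables.eri_pp, Di) - exchange(tables.eri_pp, Di)
    return F


def build_focks(tables, state: SCFState):
    """All current Fock matrices: (F_e, [F_block in full nuclear dim per block])."""
    D_e = state.electronic_density()
    D_list = state.proton_densities(tables.n_p)
    F_e = build_electronic_fock(tables, D_e, D_list)
    rep = state.representation
    if not state.blocks:
        return F_e, []
    if rep == SD:
        D_tot = np.sum(D_list, axis=0) if D_list else np.zeros_like(tables.h_p)
        return F_e, [build_nuclear_fock_sd(tables, D_e, D_tot)]
    return F_e, [
        build_nuclear_fock_hp(tables, D_e, D_list, i, include_self=(rep == HPSTAR),
                              representation=rep)
        for i in range(len(state.blocks))
    ]


# ---------------------------------------------------------------------------
# Energy
# ---------------------------------------------------------------------------

@dataclass
class EnergyReport:
    """Term-by-term NEO-HF energy (Hartree); components sum to ``total``."""

    kinetic_e: float = 0.0
    kinetic_p: float = 0.0
    classical_e: float = 0.0
    classical_p: float = 0.0
    coulomb_ee: float = 0.0
    exchange_ee: float = 0.0
    coulomb_pp: float = 0.0
    exchange_pp: float = 0.0
    coulomb_ep: float = 0.0
    classical_classical: float = 0.0
    total: float = field(default=0.0)

    def components_sum(self) -> float:
        return (self.kinetic_e + self.kinetic_p + self.classical_e
                + self.classical_p + self.coulomb_ee + self.exchange_ee
                + self.coulomb_pp + self.exchange_pp + self.coulomb_ep
                + self.classical_classical)

    def to_json(self) -> str:
        return json.dumps({k: getattr(self, k) for k in (
            "kinetic_e", "kinetic_p", "classical_e", "classical_p",
            "coulomb_ee", "exchange_ee", "coulomb_pp", "exchange_pp",
            "coulomb_ep", "classical_classical", "total")}, indent=1)


def total_energy(tables, state: SCFState, representation: str = None) -> EnergyReport:
    """Trace-based NEO-HF energy with double-counting corrections.

    HP bookkeeping counts proton-proton Coulomb once over unordered pairs and
    has no exchange term; HP* additionally books the self-Coulomb and
    self-exchange, which cancel; SD books the full determinant expressions.
    """
    rep = representation or state.representation
    r = EnergyReport(classical_classical=tables.e_nuclear_repulsion)
    D_e = state.electronic_density()
    r.kinetic_e = float(np.einsum("mn,mn->", D_e, tables.T_e))
    r.classical_e = float(np.einsum("mn,mn->", D_e, tables.V_e))
    r.coulomb_ee = 0.5 * float(np.einsum("mn,mn->", D_e, coulomb(tables.eri_ee, D_e)))
    r.exchange_ee = -0.25 * float(np.einsum("mn,mn->", D_e, exchange(tables.eri_ee, D_e)))
    D_list = state.proton_densities(tables.n_p)
    if D_list:
        D_tot = np.sum(D_list, axis=0)
        r.kinetic_p = float(np.einsum("mn,mn->", D_tot, tables.T_p))
        r.classical_p = float(np.einsum("mn,mn->", D_tot, tables.V_p))
        r.coulomb_ep = -float(np.einsum("mn,mn->", D_e, coulomb_ep(tables.eri_ep, D_tot)))
        if rep == SD:
            r.coulomb_pp = 0.5 * float(np.einsum("mn,mn->", D_tot, coulomb(tables.eri_pp, D_tot)))
            r.exchange_pp = -0.5 * float(np.einsum("mn,mn->", D_tot, exchange(tables.eri_pp, D_tot)))
        else:
            for i, Di in enumerate(D_list):
                for j in range(i + 1, len(D_list)):
                    r.coulomb_pp += float(np.einsum("mn,mn->", Di, coulomb(tables.eri_pp, D_list[j])))
            if rep == HPSTAR:
                for Di in D_list:
                    self_j = 0.5 * float(np.einsum("mn,mn->", Di, coulomb(tables.eri_pp, Di)))
                    self_k = -0.5 * float(np.einsum("mn,mn->", Di, exchange(tables.eri_pp, Di)))
                    r.coulomb_pp += self_j
                    r.exchange_pp += self_k
    r.total = r.components_sum()
    return r


def proton_exchange_ratio(tables, state: SCFState) -> float:
    """log10(|ee exchange| / |inter-proton pp exchange|) on a converged SD state.

    Inter-proton exchange is the total determinant pp exchange minus every
    per-proton self-exchange.  Returns +inf when the inter-proton part is
    exactly zero (e.g. a single quantum proton).
    """
    if state.representation != SD:
        raise RepresentationError("proton_exchange_ratio is defined for SD states")
    D_e = state.electronic_density()
    e_x_ee = 0.25 * float(np.einsum("mn,mn->", D_e, exchange(tables.eri_ee, D_e)))
    D_list = state.proton_densities(tables.n_p)
    D_tot = np.sum(D_list, axis=0)
    total_x = 0.5 * float(np.einsum("mn,mn->", D_tot, exchange(tables.eri_pp, D_tot)))
    self_x = sum(0.5 * float(np.einsum("mn,mn->", Di, exchange(tables.eri_pp, Di)))
                 for Di in D_list)
    inter = total_x - self_x
    if inter <= 0.0:
        return math.inf
    return math.log10(abs(e_x_ee) / inter)


class EpcFunctionalHook:
    """Placeholder interface for electron-proton correlation functionals.

    NEO-DFT energy terms (electronic XC, epc17-class functionals) are not
    implemented; registering a hook raises until an implementation exists.
    """

    def energy_and_potential(self, rho_e, rho_p):  # pragma: no cover - stub
        raise NotImplementedError("NEO-DFT functionals are not implemented")
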