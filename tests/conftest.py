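"""Shared cached accessors: fixture bundles, integral tables, converged runs.

Integral tables and converged SCF states are expensive, so they are memoized
once per session and shared across test modules.
"""

import numpy as np
import pytest

from neoscf import RunConfig, fixture, scf_drive
from neoscf.basis import build_layout
from neoscf.integrals import build_tables
from neoscf.system import ClassicalNucleus, MolecularSystem, QuantumProton


class MolCache:
    def __init__(self):
        self._bundles = {}
        self._tables = {}
        self._runs = {}

    def bundle(self, name):
        if name not in self._bundles:
            self._bundles[name] = fixture(name)
        return self._bundles[name]

    def tables(self, name):
        if name not in self._tables:
            b = self.bundle(name)
            self._tables[name] = build_tables(b.system, b.electronic_shells,
                                              b.protonic_shells)
        return self._tables[name]

    def layout(self, name, representation, shared=False):
        b = self.bundle(name)
        return build_layout(b.system, b.electronic_shells, b.protonic_shells,
                            representation, shared_override=shared)

    def run(self, name, representation, solver="diis", guess=("sad", "sad"),
            shared=False, max_iter=300, e_tol=1e-8, g_tol=1e-8):
        key = (name, representation, solver, guess, shared, e_tol, g_tol, max_iter)
        if key not in self._runs:
            b = self.bundle(name)
            cfg = RunConfig(representation=representation, solver=solver,
                            guess_electronic=guess[0], guess_nuclear=guess[1],
                            shared_protonic_layout=shared, max_iter=max_iter,
                            e_tol=e_tol, g_tol=g_tol)
            self._runs[key] = scf_drive(b.system, b.electronic_shells,
                                        b.protonic_shells, cfg,
                                        tables=self.tables(name),
                                        basis_dict=b.basis_dict)
        return self._runs[key]


@pytest.fixture(scope="session")
def mol():
    return MolCache()


@pytest.fixture(scope="session")
def single_proton_water():
    """Water with exactly one quantum hydrogen (the other stays classical)."""
    from neoscf.basis import protonic_shells_for_system, shells_for_system
    from neoscf.fixtures import sto3g_basis_dict, _geometry
    from neoscf.constants import angstrom_to_bohr

    classical, proton_pos, charge = _geometry("water")
    nuclei = [ClassicalNucleus(element="O", charge=8,
                               position=angstrom_to_bohr(np.asarray(classical[0][1])))]
    nuclei.append(ClassicalNucleus(element="H", charge=1,
                                   position=angstrom_to_bohr(np.asarray(proton_pos[1]))))
    protons = [QuantumProton(index=0, position=angstrom_to_bohr(np.asarray(proton_pos[0])))]
    system = MolecularSystem(nuclei=nuclei, protons=protons, charge=0)
    bd = sto3g_basis_dict()
    esh = shells_for_system(system, bd)
    psh = protonic_shells_for_system(system)
    return system, esh, psh, bd
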