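"""Deterministic test molecules with built-in electronic and protonic bases.

Geometries are standard experimental-style internal coordinates hard-coded
below (bond lengths in Angstrom, angles in degrees) and converted to bohr at
build time; every hydrogen is a quantum proton.  The electronic basis is a
built-in minimal (STO-3G) set; protons get even-tempered s/p sets from
:func:`neoscf.basis.make_even_tempered_protonic`.

Available fixtures: h2, water, h3o+, acetylene, h5o2+, water_dimer, h9o4+.
The larger Eigen cation uses a reduced 3s1p protonic set to keep its
proton-proton repulsion tensor at desk scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .basis import read_basis, shells_for_system, protonic_shells_for_system
from .constants import angstrom_to_bohr
from .system import ClassicalNucleus, MolecularSystem, QuantumProton

# Standard STO-3G exponents/coefficients (shared 1s and 2sp coefficient sets).
_STO3G = json.loads("""
{
 "H": [{"l": 0, "exponents": [3.42525091, 0.62391373, 0.16885540],
        "coeffs": [0.15432897, 0.53532814, 0.44463454]}],
 "C": [{"l": 0, "exponents": [71.6168370, 13.0450960, 3.5305122],
        "coeffs": [0.15432897, 0.53532814, 0.44463454]},
       {"l": 0, "exponents": [2.9412494, 0.6834831, 0.2222899],
        "coeffs": [-0.09996723, 0.39951283, 0.70011547]},
       {"l": 1, "exponents": [2.9412494, 0.6834831, 0.2222899],
        "coeffs": [0.15591627, 0.60768372, 0.39195739]}],
 "N": [{"l": 0, "exponents": [99.1061690, 18.0523120, 4.8856602],
        "coeffs": [0.15432897, 0.53532814, 0.44463454]},
       {"l": 0, "exponents": [3.7804559, 0.8784966, 0.2857144],
        "coeffs": [-0.09996723, 0.39951283, 0.70011547]},
       {"l": 1, "exponents": [3.7804559, 0.8784966, 0.2857144],
        "coeffs": [0.15591627, 0.60768372, 0.39195739]}],
 "O": [{"l": 0, "exponents": [130.7093200, 23.8088610, 6.4436083],
        "coeffs": [0.15432897, 0.53532814, 0.44463454]},
       {"l": 0, "exponents": [5.0331513, 1.1695961, 0.3803890],
        "coeffs": [-0.09996723, 0.39951283, 0.70011547]},
       {"l": 1, "exponents": [5.0331513, 1.1695961, 0.3803890],
        "coeffs": [0.15591627, 0.60768372, 0.39195739]}]
}
""")


def sto3g_basis_dict() -> dict:
    return read_basis(json.dumps(_STO3G), kind="e")


@dataclass
class FixtureBundle:
    name: str
    system: MolecularSystem
    electronic_shells: list
    protonic_shells: list
    basis_dict: dict
    protonic_params: dict


def _deg(x):
    return np.deg2rad(x)


def _geometry(name: str):
    """(classical atoms [(el, xyz_A)], proton centers [xyz_A], charge)."""
    if name == "h2":
        return [], [np.array([0.0, 0.0, 0.0]), np.array([0.0, 0.0, 0.7414])], 0
    if name == "water":
        r, theta = 0.9572, _deg(104.52)
        O = np.zeros(3)
        H1 = r * np.array([np.sin(theta / 2), 0.0, np.cos(theta / 2)])
        H2 = r * np.array([-np.sin(theta / 2), 0.0, np.cos(theta / 2)])
        return [("O", O)], [H1, H2], 0
    if name == "h3o+":
        # C3v pyramid: O-H 0.98 A, H-O-H 111.3 deg
        r, hoh = 0.98, _deg(111.3)
        s2 = (1.0 - np.cos(hoh)) / 1.5
        theta = np.arcsin(np.sqrt(s2))
        protons = []
        for k in range(3):
            phi = 2 * np.pi * k / 3
            protons.append(r * np.array([np.sin(theta) * np.cos(phi),
                                         np.sin(theta) * np.sin(phi),
                                         np.cos(theta)]))
        return [("O", np.zeros(3))], protons, 1
    if name == "acetylene":
        # linear HCCH: C=C 1.203 A, C-H 1.063 A
        zc, zh = 1.203 / 2, 1.203 / 2 + 1.063
        return ([("C", np.array([0, 0, -zc])), ("C", np.array([0, 0, zc]))],
                [np.array([0, 0, -zh]), np.array([0, 0, zh])], 0)
    if name == "h5o2+":
        # Zundel cation: O-O 2.40 A, shared proton at the midpoint,
        # two outer O-H 0.97 A per oxygen at 115 deg from the O-O axis
        d, r, ang = 2.40, 0.97, _deg(115.0)
        O1, O2 = np.array([0, 0, -d / 2]), np.array([0, 0, d / 2])
        protons = [np.zeros(3)]
        for Oz, sgn, phi0 in ((O1, -1.0, 0.0), (O2, 1.0, np.pi / 2)):
            for phi in (phi0, phi0 + np.pi):
                protons.append(Oz + r * np.array([np.sin(ang) * np.cos(phi),
                                                  np.sin(ang) * np.sin(phi),
                                                  sgn * np.cos(ang)]))
        return [("O", O1), ("O", O2)], protons, 1
    if name == "water_dimer":
        # Cs hydrogen-bonded dimer, O-O 2.976 A, donor H on the O-O axis
        r, theta = 0.9572, _deg(104.52)
        doo = 2.976
        Od = np.zeros(3)
        Oa = np.array([doo, 0.0, 0.0])
        Hd1 = Od + r * np.array([1.0, 0.0, 0.0])                      # donor H
        Hd2 = Od + r * np.array([np.cos(theta), np.sin(theta), 0.0])
        # acceptor water in the xz plane, bisector tilted 125 deg from +x
        alpha = _deg(125.0)
        Ha1 = Oa + r * np.array([np.cos(alpha - theta / 2), 0.0,
                                 np.sin(alpha - theta / 2)])
        Ha2 = Oa + r * np.array([np.cos(alpha + theta / 2), 0.0,
                                 np.sin(alpha + theta / 2)])
        return [("O", Od), ("O", Oa)], [Hd1, Hd2, Ha1, Ha2], 0
    if name == "h9o4+":
        # Eigen cation: central hydronium (O-H 1.02 A, planar trigonal),
        # three acceptor waters at O-O 2.57 A along the O-H directions
        roh, doo, rw, hohw = 1.02, 2.57, 0.96, _deg(104.5)
        Oc = np.zeros(3)
        classical = [("O", Oc)]
        protons = []
        for k in range(3):
            phi = 2 * np.pi * k / 3
            u = np.array([np.cos(phi), np.sin(phi), 0.0])
            protons.append(roh * u)
            Ow = doo * u
            classical.append(("O", Ow))
            for sgn in (1.0, -1.0):
                hdir = (np.cos(hohw / 2) * u
                        + sgn * np.sin(hohw / 2) * np.array([0.0, 0.0, 1.0]))
                protons.append(Ow + rw * hdir)
        return classical, protons, 1
    raise KeyError(
        f"unknown fixture {name!r}; available: h2, water, h3o+, acetylene, "
        f"h5o2+, water_dimer, h9o4+")


FIXTURE_NAMES = ("h2", "water", "h3o+", "acetylene", "h5o2+", "water_dimer", "h9o4+")

#: Fixtures with more than one quantum proton (the convergence-comparison suite).
MULTI_PROTON_FIXTURES = ("h2", "water", "h3o+", "acetylene", "h5o2+", "water_dimer")

_REDUCED_PROTONIC = {"h9o4+": dict(n_s=3, n_p=1, alpha0=4.0, beta=2.5)}
_DEFAULT_PROTONIC = dict(n_s=4, n_p=3, alpha0=4.0, beta=2.5)


def fixture(name: str, protonic: dict = None) -> FixtureBundle:
    """Build a named fixture: system + electronic/protonic shells."""
    classical, proton_pos, charge = _geometry(name)
    nuclei = [ClassicalNucleus(element=el, charge={"O": 8, "C": 6, "N": 7}[el],
                               position=angstrom_to_bohr(np.asarray(p, float)))
              for el, p in classical]
    protons = [QuantumProton(index=i, position=angstrom_to_bohr(np.asarray(p, float)))
               for i, p in enumerate(proton_pos)]
    system = MolecularSystem(nuclei=nuclei, protons=protons, charge=charge)
    basis_dict = sto3g_basis_dict()
    params = dict(protonic or _REDUCED_PROTONIC.get(name, _DEFAULT_PROTONIC))
    return FixtureBundle(
        name=name,
        system=system,
        electronic_shells=shells_for_system(system, basis_dict),
        protonic_shells=protonic_shells_for_system(system, **params),
        basis_dict=basis_dict,
        protonic_params=params,
    )
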