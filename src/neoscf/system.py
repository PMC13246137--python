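"""Molecular system model: classical nuclei plus quantum protons.

A NEO system partitions the nuclei into classical point charges and quantum
protons.  Quantum protons carry no classical point charge anywhere -- their
charge enters the energy only through their one-particle density -- while
classical nuclei interact with everything, including the classical-classical
Coulomb repulsion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import (
    ELEMENT_CHARGES,
    PROTON_MASS_AU,
    angstrom_to_bohr,
    bohr_to_angstrom,
)


class XYZParseError(ValueError):
    """Raised for malformed XYZ input, with the offending line number."""


@dataclass
class ClassicalNucleus:
    """A classical point-charge nucleus at a fixed position (bohr)."""

    element: str
    charge: float
    position: np.ndarray

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if self.charge <= 0:
            raise ValueError(f"nuclear charge must be positive, got {self.charge}")
        if not np.all(np.isfinite(self.position)):
            raise ValueError("nuclear position must be finite")


@dataclass
class QuantumProton:
    """A quantum proton: a fixed basis center and a mass (electron masses)."""

    index: int
    position: np.ndarray
    mass: float = PROTON_MASS_AU

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if self.mass <= 1:
            raise ValueError("quantum nuclear mass must exceed the electron mass")


@dataclass
class MolecularSystem:
    """Classical nuclei, quantum protons, and the electron count.

    ``n_electrons`` is derived from total charge:
    N_e = sum(Z_classical) + N_p - charge, and must be even (restricted
    closed-shell electrons only).
    """

    nuclei: list = field(default_factory=list)
    protons: list = field(default_factory=list)
    charge: int = 0

    def __post_init__(self):
        indices = [p.index for p in self.protons]
        if len(set(indices)) != len(indices):
            raise ValueError("quantum proton indices must be unique")
        if self.n_electrons <= 0:
            raise ValueError("system has no electrons")
        if self.n_electrons % 2 != 0:
            raise ValueError(
                f"restricted closed-shell treatment requires an even electron "
                f"count, got N_e = {self.n_electrons}"
            )

    @property
    def n_electrons(self) -> int:
        return int(round(sum(n.charge for n in self.nuclei))) + len(self.protons) - self.charge

    @property
    def n_protons(self) -> int:
        return len(self.protons)

    @property
    def centers(self):
        """All basis-carrying centers: (element, position) incl. proton centers."""
        out = [(n.element, n.position) for n in self.nuclei]
        out += [("H", p.position) for p in self.protons]
        return out

    def classical_repulsion(self) -> float:
        """Classical nucleus-nucleus Coulomb energy (quantum protons excluded)."""
        e = 0.0
        for a in range(len(self.nuclei)):
            for b in range(a + 1, len(self.nuclei)):
                r = np.linalg.norm(self.nuclei[a].position - self.nuclei[b].position)
                e += self.nuclei[a].charge * self.nuclei[b].charge / r
        return e


def read_xyz(text: str, quantum_tags="all-H", charge: int = 0) -> MolecularSystem:
    """Parse XYZ text (Angstrom) into a :class:`MolecularSystem`.

    Parameters
    ----------
    text:
        Standard XYZ: atom count line, comment line, then ``El x y z`` lines.
        An atom line may carry a trailing ``Q`` token to tag that hydrogen as
        a quantum proton.
    quantum_tags:
        ``"all-H"`` promotes every hydrogen to a quantum proton; a list of
        0-based atom indices promotes exactly those (they must be H); ``None``
        keeps every atom classical except ``Q``-suffixed lines.
    charge:
        Total molecular charge.
    """
    lines = text.splitlines()
    if not lines:
        raise XYZParseError("empty XYZ input")
    try:
        natoms = int(lines[0].split()[0])
    except (IndexError, ValueError) as exc:
        raise XYZParseError(f"line 1: cannot parse atom count: {lines[0]!r}") from exc
    if len(lines) < natoms + 2:
        raise XYZParseError(f"expected {natoms} atom lines, found {len(lines) - 2}")

    atoms = []  # (element, position_bohr, tagged)
    for i in range(natoms):
        lineno = i + 3
        parts = lines[i + 2].split()
        if len(parts) not in (4, 5):
            raise XYZParseError(f"line {lineno}: malformed atom line: {lines[i + 2]!r}")
        el = parts[0].capitalize()
        if el not in ELEMENT_CHARGES:
            raise XYZParseError(f"line {lineno}: unknown element {parts[0]!r}")
        try:
            pos = np.array([float(x) for x in parts[1:4]])
        except ValueError as exc:
            raise XYZParseError(f"line {lineno}: bad coordinate on {lines[i + 2]!r}") from exc
        tagged = len(parts) == 5 and parts[4].upper() == "Q"
        if len(parts) == 5 and not tagged:
            raise XYZParseError(f"line {lineno}: unrecognized trailing token {parts[4]!r}")
        atoms.append((el, angstrom_to_bohr(pos), tagged))

    tag_set = set()
    if quantum_tags == "all-H":
        tag_set = {i for i, (el, _, _) in enumerate(atoms) if el == "H"}
    elif quantum_tags is not None:
        tag_set = set(quantum_tags)
    tag_set |= {i for i, (_, _, t) in enumerate(atoms) if t}

    nuclei, protons = [], []
    for i, (el, pos, _) in enumerate(atoms):
        if i in tag_set:
            if el != "H":
                raise ValueError(f"quantum tag on atom {i} refers to {el}, not H")
            protons.append(QuantumProton(index=len(protons), position=pos))
        else:
            nuclei.append(ClassicalNucleus(element=el, charge=ELEMENT_CHARGES[el], position=pos))
    return MolecularSystem(nuclei=nuclei, protons=protons, charge=charge)


def write_xyz(system: MolecularSystem, comment: str = "") -> str:
    """Serialize a system to XYZ text (Angstrom); quantum protons get a Q tag."""
    rows = []
    for n in system.nuclei:
        x, y, z = bohr_to_angstrom(n.position)
        rows.append(f"{n.element} {x:.12f} {y:.12f} {z:.12f}")
    for p in system.protons:
        x, y, z = bohr_to_angstrom(p.position)
        rows.append(f"H {x:.12f} {y:.12f} {z:.12f} Q")
    return f"{len(rows)}\n{comment}\n" + "\n".join(rows) + "\n"
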