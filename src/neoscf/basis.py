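"""Contracted Cartesian Gaussian shells and the nuclear basis layout.

Conventions
-----------
* Cartesian Gaussians only, l <= 2 (1/3/6 components for s/p/d).
* Each basis function (shell component) is individually normalized to unit
  self-overlap; the per-component double-factorial factors cancel between the
  primitive norms and the self-overlap, so one contraction scale per shell
  suffices.
* Electronic and protonic shells share the same data type, distinguished by
  ``kind`` ("e" or "p").

The :class:`BasisLayout` maps quantum protons onto ranges of nuclear basis
functions: one shared block in the Slater-determinant (SD) representation,
one block per proton in the Hartree-product (HP/HP*) representation.  In HP
the default restricts each proton to shells centered at its own position;
a shared-set override gives every proton the full nuclear set so HP and SD
can be compared in an identical variational space.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import yaml

SD = "SD"
HP = "HP"
HPSTAR = "HPstar"
REPRESENTATIONS = (SD, HP, HPSTAR)


class BasisError(ValueError):
    pass


def n_cartesian(l: int) -> int:
    return (l + 1) * (l + 2) // 2


def cartesian_components(l: int):
    """Component exponent triples in canonical order (xx, xy, xz, yy, yz, zz)."""
    return [
        (lx, ly, l - lx - ly)
        for lx in range(l, -1, -1)
        for ly in range(l - lx, -1, -1)
    ]


def _double_factorial(n: int) -> int:
    return 1 if n <= 0 else math.prod(range(n, 0, -2))


def primitive_norm(alpha: float, lx: int, ly: int, lz: int) -> float:
    """Norm of the primitive x^lx y^ly z^lz exp(-alpha r^2)."""
    l = lx + ly + lz
    df = _double_factorial(2 * lx - 1) * _double_factorial(2 * ly - 1) * _double_factorial(2 * lz - 1)
    return (2 * alpha / np.pi) ** 0.75 * (4 * alpha) ** (l / 2) / math.sqrt(df)


@dataclass
class GaussianShell:
    """One contracted Cartesian Gaussian shell.

    ``coeffs`` are the raw contraction coefficients against normalized
    primitives; ``normalize()`` computes the contraction scale giving each
    component unit self-overlap.
    """

    center: np.ndarray
    l: int
    exponents: np.ndarray
    coeffs: np.ndarray
    kind: str = "e"
    norm_tag: str = "component-normalized"
    _scale: float = field(default=None, repr=False)

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float)
        self.exponents = np.asarray(self.exponents, dtype=float)
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        if self.l not in (0, 1, 2):
            raise BasisError(f"unsupported angular momentum l={self.l} (only l <= 2)")
        if self.exponents.size == 0:
            raise BasisError("shell needs at least one primitive")
        if np.any(self.exponents <= 0):
            raise BasisError("primitive exponents must be positive")
        if self.exponents.shape != self.coeffs.shape:
            raise BasisError("exponents and coefficients must have equal length")
        order = np.argsort(-self.exponents)
        self.exponents = self.exponents[order]
        self.coeffs = self.coeffs[order]
        if self._scale is None:
            self.normalize()

    @property
    def n_functions(self) -> int:
        return n_cartesian(self.l)

    def normalize(self):
        """Set the contraction scale so every component has unit self-overlap."""
        lx, ly, lz = cartesian_components(self.l)[0]
        s = 0.0
        for a, ca in zip(self.exponents, self.coeffs):
            na = primitive_norm(a, lx, ly, lz)
            for b, cb in zip(self.exponents, self.coeffs):
                nb = primitive_norm(b, lx, ly, lz)
                p = a + b
                s1 = (
                    _double_factorial(2 * lx - 1)
                    * _double_factorial(2 * ly - 1)
                    * _double_factorial(2 * lz - 1)
                    / (2 * p) ** (lx + ly + lz)
                    * (np.pi / p) ** 1.5
                )
                s += ca * cb * na * nb * s1
        self._scale = 1.0 / math.sqrt(s)

    def contraction(self, lx: int, ly: int, lz: int) -> np.ndarray:
        """Effective primitive coefficients (contraction x primitive norms x scale)."""
        norms = np.array([primitive_norm(a, lx, ly, lz) for a in self.exponents])
        return self._scale * self.coeffs * norms


def read_basis(source: str, kind: str = "e") -> dict:
    """Parse a JSON/YAML basis definition ``{element: [{l, exponents, coeffs}]}``.

    Returns a dict mapping element symbol to a list of shell *templates*
    (l, exponents, coeffs); call :func:`shells_for_system` to place them.
    """
    try:
        data = json.loads(source)
    except json.JSONDecodeError:
        data = yaml.safe_load(source)
    if not isinstance(data, dict):
        raise BasisError("basis definition must map element -> shell list")
    out = {}
    for el, shells in data.items():
        templates = []
        for sh in shells:
            l = int(sh["l"])
            if l > 2:
                raise BasisError(f"unsupported angular momentum l={l} for {el}")
            templates.append(
                (l, np.asarray(sh["exponents"], float), np.asarray(sh["coeffs"], float))
            )
        out[el.capitalize()] = templates
    # touch kind to validate
    if kind not in ("e", "p"):
        raise BasisError(f"unknown particle kind {kind!r}")
    return out


def shells_for_system(system, basis_dict: dict, kind: str = "e"):
    """Place electronic basis shells on every center (incl. proton centers)."""
    shells = []
    for el, pos in system.centers:
        if el not in basis_dict:
            raise BasisError(f"no basis for element {el}")
        for l, exps, coeffs in basis_dict[el]:
            shells.append(GaussianShell(center=pos, l=l, exponents=exps, coeffs=coeffs, kind=kind))
    return shells


def make_even_tempered_protonic(center, n_s: int = 4, n_p: int = 3,
                                alpha0: float = 4.0, beta: float = 2.5):
    """Even-tempered protonic shells at one center: alpha_k = alpha0 * beta^k.

    Defaults (4s3p, alpha0 = 4 bohr^-2, beta = 2.5) give exponents reaching
    ~60 bohr^-2, compact enough for a proton bound to C/O.
    """
    if alpha0 <= 0 or beta <= 1:
        raise BasisError("need alpha0 > 0 and beta > 1")
    if n_s <= 0 or n_p < 0:
        raise BasisError("need n_s >= 1 and n_p >= 0")
    shells = []
    for l, n in ((0, n_s), (1, n_p)):
        for k in range(n):
            shells.append(
                GaussianShell(center=center, l=l, exponents=[alpha0 * beta**k],
                              coeffs=[1.0], kind="p")
            )
    return shells


def protonic_shells_for_system(system, n_s=4, n_p=3, alpha0=4.0, beta=2.5):
    """Even-tempered protonic shells on every quantum-proton center."""
    shells = []
    for p in system.protons:
        shells += make_even_tempered_protonic(p.position, n_s=n_s, n_p=n_p,
                                              alpha0=alpha0, beta=beta)
    return shells


def function_offsets(shells):
    """Start index of each shell in the flattened function list."""
    offs, n = [], 0
    for sh in shells:
        offs.append(n)
        n += sh.n_functions
    return offs, n


@dataclass
class BasisLayout:
    """Maps protons to nuclear-basis function index ranges.

    ``proton_blocks[i]`` is the index array of functions proton i may occupy:
    the full range under SD, the proton's own-center (or shared, with the
    override) range under HP/HP*.  ``center_blocks`` always records the
    own-center partition; the SD block-diagonal core guess uses it.
    """

    representation: str
    nuclear_shells: list
    n_nuclear: int
    proton_blocks: list
    center_blocks: list

    def validate(self):
        if self.representation in (HP, HPSTAR):
            for blk in self.proton_blocks:
                if blk.size == 0:
                    raise BasisError("a quantum proton has zero basis functions")
        covered = np.unique(np.concatenate(self.center_blocks)) if self.center_blocks else np.array([])
        if covered.size != self.n_nuclear:
            raise BasisError("center blocks must cover all nuclear functions")


def build_layout(system, electronic_shells, protonic_shells, representation,
                 shared_override: bool = False) -> BasisLayout:
    """Assign nuclear basis functions to protons for a given representation."""
    if representation not in REPRESENTATIONS:
        raise BasisError(f"unknown representation {representation!r}")
    offs, n_nuc = function_offsets(protonic_shells)
    center_blocks = []
    for p in system.protons:
        idx = []
        for sh, off in zip(protonic_shells, offs):
            if np.linalg.norm(sh.center - p.position) < 1e-8:
                idx.extend(range(off, off + sh.n_functions))
        center_blocks.append(np.asarray(idx, dtype=int))
        if len(idx) == 0:
            raise BasisError(f"quantum proton {p.index} has zero basis functions")
    if representation == SD:
        blocks = [np.arange(n_nuc)]
    elif shared_override:
        blocks = [np.arange(n_nuc) for _ in system.protons]
    else:
        blocks = list(center_blocks)
        seen = np.concatenate(blocks)
        if len(np.unique(seen)) != len(seen):
            raise BasisError("HP per-proton function ranges must be disjoint")
    layout = BasisLayout(representation=representation,
                         nuclear_shells=list(protonic_shells),
                         n_nuclear=n_nuc,
                         proton_blocks=blocks,
                         center_blocks=center_blocks)
    layout.validate()
    return layout
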