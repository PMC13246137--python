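# neoscf

Multicomponent nuclear–electronic orbital Hartree–Fock (NEO-HF) in Python.

Nuclear quantum effects — zero-point energy, proton delocalization,
anharmonicity — matter wherever hydrogen moves: hydrogen bonding, proton
transfer, proton-coupled electron transfer.  The NEO approach captures them
by treating selected protons quantum mechanically *alongside* the electrons,
beyond the Born–Oppenheimer separation: each quantum proton gets its own
orbital expanded in Gaussian basis functions, with kinetic energy scaled by
1/m_p, coupled to the electrons through the mean-field Coulomb attraction.

`neoscf` is a desk-scale engine for studying how the *representation* of the
quantum protons shapes the self-consistent-field optimization:

* **SD** — nuclear Slater determinant: one antisymmetrized high-spin
  wavefunction for all protons, one shared nuclear Fock operator
  `F^p = h^p + J^pp[D] − K^pp[D] − J^pe[D^e]` including each proton's
  self-Coulomb and self-exchange (which cancel exactly in the energy);
* **HP** — nuclear Hartree product: distinguishable protons, one Fock
  operator per proton, `F_i = h^p + Σ_{j≠i} J^pp[D_j] − J^pe[D^e]`, with no
  exchange and no self-interaction;
* **HP\*** — HP plus the exactly-cancelling self terms, which leaves every
  converged energy unchanged but restores the SD optimization landscape.

Because inter-proton exchange between localized protons is ~8–16 orders of
magnitude below electron–electron exchange, SD and HP converge to the same
NEO-HF energy — but HP does so in far fewer iterations and is dramatically
less sensitive to a poor initial guess.  The package lets you verify all of
this directly.

Three simultaneous SCF solvers optimize electronic and nuclear orbitals in
the same iteration: coupled **DIIS** (one extrapolation coefficient set
shared by both subsystems), a **GDM-style** preconditioned L-BFGS descent in
orbital-rotation space, and a trust-radius augmented Hessian (**TRAH**)
solver using exact coupled Hessian-vector products and a Davidson
eigensolver (SD representation).  Stepwise alternation and a DIIS→GDM hybrid
are included as baselines, as are core/SAD initial guesses for both particle
kinds (with a block-diagonal nuclear core guess that prevents protons
collapsing onto one center).

## Worked example

Converge acetylene with both protons quantum, in the Hartree-product
representation:

```bash
neoscf run --fixture acetylene --repr HP --solver diis
```

```
iter   0  E = -75.413779807870  dE =  nan        err_e = 1.024e-01  err_p = 1.726e-03
iter   1  E = -75.731390816112  dE = -3.176e-01  err_e = 1.800e-02  err_p = 3.216e-03
iter   2  E = -75.769956091660  dE = -3.857e-02  err_e = 1.369e-02  err_p = 1.742e-04
...
iter   9  E = -75.775416676062  dE =  2.842e-14  err_e = 3.932e-09  err_p = 5.530e-12
outcome: converged  E = -75.775416676062  (10 iterations)
```

Each line reports the total NEO-HF energy (Hartree), its change, and the
electronic/nuclear error norms; convergence requires the energy change below
1e-8 Hartree and both norms below 1e-8.  The same molecule in the
Slater-determinant representation (`--repr SD`) converges to
`E = -75.775416676062` as well — identical to within 6e-14 Hartree — but
needs 21 iterations: the difference is caused purely by the nuclear
self-interaction terms in the SD Fock operator, as switching to `--repr
HPstar` (self terms restored, energy provably unchanged) brings the count
back up to the SD value.

The energy is far above a clamped-proton RHF value for the same geometry —
quantizing the protons adds their zero-point-like kinetic energy — and the
absolute numbers reflect the built-in minimal electronic basis; all claims
the package tests are representation/solver comparisons at fixed geometry
and basis.

Robustness sweeps reproduce the guess-sensitivity contrast
(`converged` / `converged_higher_energy` / `failed` per cell):

```bash
neoscf sweep --molecules h2,water,h3o+,acetylene --representations SD,HP \
             --solvers diis --guesses "core,core"
```

With poor core guesses the SD column fails or lands on higher-energy
solutions for several molecules; the HP column converges to the lowest
energy in every case.

Python API:

```python
from neoscf import fixture, scf_drive, RunConfig

b = fixture("h3o+")
cfg = RunConfig(representation="HP", solver="diis")
report = scf_drive(b.system, b.electronic_shells, b.protonic_shells, cfg,
                   basis_dict=b.basis_dict)
print(report.final_energy)   # -75.234539615719
```

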