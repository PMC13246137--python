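# Methods

## Model

`neoscf` solves the multicomponent (nuclear–electronic orbital, NEO)
Hartree–Fock problem: a molecule's electrons and a designated subset of its
nuclei — in practice protons — are both treated quantum mechanically in a
single variational wavefunction, while the remaining nuclei stay classical
point charges at fixed positions.  In atomic units the Hamiltonian contains
the electronic kinetic and electron–electron repulsion terms, the
proton kinetic term scaled by 1/m_p (m_p = 1836.15267343 electron masses),
proton–proton repulsion, electron–proton attraction, the interactions of both
quantum species with the classical nuclei, and the classical–classical
Coulomb sum.  Quantum protons carry no classical point charge anywhere: their
charge enters only through their one-particle density.

Electrons are restricted closed-shell.  Both particle kinds are expanded in
contracted Cartesian Gaussians (l ≤ 2); each proton has a fixed basis center
at its nominal position, so the model describes nuclear delocalization about
those centers, not free translation.

### Nuclear representations

* **SD** — all quantum protons form one high-spin Slater determinant, each
  spatial protonic orbital singly occupied.  One shared nuclear Fock operator
  `F^p = h^p + J^pp[D] − K^pp[D] − J^pe[D^e]`, whose proton–proton sum runs
  unrestricted and therefore contains each orbital's self-Coulomb and
  self-exchange (which cancel exactly in the energy).
* **HP** — protons are distinguishable and the nuclear wavefunction is a
  Hartree product.  Each proton i has its own Fock operator
  `F_i = h^p + Σ_{j≠i} J^pp[D_j] − J^pe[D^e]` with no exchange and no
  self-interaction.  With frozen electrons this operator is linear in nothing
  the proton controls, so one diagonalization solves each proton exactly.
* **HP\*** — HP plus the per-proton self-Coulomb and self-exchange in the
  Fock operator.  For a singly-occupied orbital the two contractions
  coincide, `(J[D_i] − K[D_i]) φ_i = 0`, so the converged energy is
  unchanged to machine precision while the iteration map (the virtual
  spectrum each proton sees) mimics SD.  This isolates the nuclear
  self-interaction terms as the source of the SD convergence difficulty.

The total energy books proton–proton Coulomb once over unordered pairs under
HP (no exchange term exists); SD books the full determinant expressions.
Since inter-proton exchange between well-localized protons is many orders of
magnitude below the electron–electron exchange (the package measures
log10 |E_x^ee / E_x^pp,inter| ≈ 16 on acetylene), SD and HP converge to the
same energy far below the 1e-8 Hartree convergence threshold.

## Integrals

McMurchie–Davidson Hermite expansion for all integral classes (overlap,
mass-scaled kinetic, point-charge Coulomb, and the generic two-cloud
repulsion tensor), chosen as the simplest scheme that uniformly covers the
ee/ep/pp kernels at l ≤ 2.  The Boys function uses the regularized
incomplete-gamma route for the top order plus stable downward recursion;
protonic exponents (up to ~10² bohr⁻²) put Coulomb integrals deep into the
large-argument regime, which the tests probe explicitly up to x ≈ 200.
Tensors are held in memory (desk scale, ≤ ~200 functions); shell-pair blocks
are screened with the Schwarz bound at 1e-14.  No density fitting and no
direct-SCF path.

## Basis sets

The built-in electronic set is minimal (STO-3G parameters for H/C/N/O);
external JSON/YAML basis files are accepted.  The protonic basis is an
even-tempered generator, α_k = α₀·βᵏ per angular momentum, with defaults
α₀ = 4 bohr⁻², β = 2.5, 4s3p.  These defaults bracket the physical width of
a proton bound to C/O (ground-state exponents ~20–30 bohr⁻²).  The large
Eigen-cation fixture uses a reduced 3s1p set to keep its 4-index pp tensor at
desk scale.  In HP each proton's variational block is restricted to shells
on its own center by default; a shared-set override gives every proton the
full nuclear set so that HP and SD energies can be compared in an identical
variational space.

## SCF solvers

All solvers are *simultaneous*: the electronic and nuclear orbitals are
updated in the same iteration.  Convergence requires the energy change below
1e-8 Hartree **and** both subsystem error norms below 1e-8 (commutator-based
DIIS error for Roothaan/DIIS, gradient RMS for GDM/TRAH), mirroring the
convention that both subsystems must be stationary.  No level shifting or
damping by default; both exist behind flags.

* **DIIS** — one coefficient vector from the combined Gram matrix
  ⟨e_k^e|e_l^e⟩ + ⟨e_k^p|e_l^p⟩ extrapolates the electronic and nuclear Fock
  matrices together (subspace cap 15).  Error vectors are the
  S^{-1/2}-transformed FDS−SDF commutators; the orthonormal-basis transform
  is this package's documented convention.  Ill-conditioned Gram matrices
  (condition > 1e12) shed oldest entries; a degenerate subspace resets.
* **GDM-style quasi-Newton** — limited-memory BFGS (20 curvature pairs) over
  the packed occupied–virtual rotation parameters of both subsystems, with a
  diagonal orbital-energy-difference preconditioner (floored at 0.05
  Hartree), Armijo backtracking line search (c₁ = 1e-4) and a trust-radius
  cap ‖s‖ ≤ 0.5 after two rejections.  Curvature pairs are reused unchanged
  in the current orbital frame — a small-step transport approximation; the
  full geodesic-transport machinery of production GDM implementations is not
  reproduced, which is why the docs call this solver "GDM-style".
* **TRAH** — trust-radius augmented Hessian (SD representation only).  The
  exact coupled orbital Hessian acts on trial vectors through Fock-like
  contractions of first-order rotated densities, with the electron–proton
  blocks coupling the subsystems; a Davidson iteration finds the lowest
  eigenpair of the α-scaled augmented matrix.  The applied step is
  s = x̃(α)/α, which satisfies the level-shifted Newton equation
  (H − μI)s = −g exactly and whose norm decreases monotonically with α in
  both the definite and indefinite regimes; α is bisected on log₁₀α ∈ [0, 6]
  until ‖s‖ ∈ [0.8Δ, Δ], with the unscaled step kept when already interior.
  Trust radius: init 0.4; ratio-based update (×0.7 below r = 0.25,
  ×1.2 capped at 1.0 above r = 0.75); steps that raise the energy by more
  than 1e-12 are rejected and retried at Δ/2.  The Davidson preconditioner
  diagonal is refreshed from the current orbital-energy differences every
  outer iteration.  These schedule constants are this package's choices.
* **stepwise** — alternating full electronic / nuclear convergence, the
  non-simultaneous baseline.  It converges on weakly coupled systems (H2)
  and stalls on strongly coupled multi-proton systems, which is precisely
  the behavior that motivates simultaneous optimization.
* **hybrid** — DIIS until the combined error norm stalls (relative decrease
  < 1% over 5 iterations — this package's stall rule, since no standard
  definition exists), then GDM from the current state.

Orbital updates use C ← C·exp(κ) with κ the skew-symmetric matrix assembled
from the packed step; the exponential is evaluated by `scipy.linalg.expm`
with a Löwdin re-orthogonalization guard at 1e-10 drift.

### Occupation selection

Electronic orbitals reoccupy by aufbau.  The shared SD nuclear block uses
maximum-overlap tracking against the previous occupied subspace, preventing
discontinuous swaps between near-degenerate protonic orbitals mid-SCF.
Singly-occupied HP blocks reoccupy by aufbau: each per-proton Fock operator
is self-interaction-free, so its ground eigenvector *is* the correct
conditional orbital — applying overlap tracking there can lock a proton into
an excited eigenvector indefinitely.  This asymmetry is itself a clean
illustration of why the HP representation is the more robust optimization
problem.

## Initial guesses

* **core** (electronic): diagonalize h^e.
* **block-diagonal nuclear core**: diagonalize each proton center's (h^p, S^p)
  sub-block separately, occupy each center's ground state, then Löwdin-
  orthonormalize the assembled set — this prevents several protons collapsing
  onto one center, which the full nuclear core diagonalization (available
  behind a flag as the pathological variant) permits.
* **SAD** (electronic): spherically averaged fractional-occupation atomic RHF
  per element in the same basis, cached per element+basis, assembled
  block-diagonally and rescaled to N_e.  One-electron (hydrogen-like)
  centers use the exact core density.  A non-convergent atomic SCF falls
  back to the core density with a warning.
* **nuclear SAD**: each proton's ground state of h^p − J^pe[D^e_SAD] on its
  own center's block — a one-proton solve in the frozen SAD electronic
  field.  Whether such a guess should include inter-proton Coulomb in the
  frozen field is unsettled; this package omits it.  Under the shared-set
  layout override the occupied guess orbital is still localized on the
  proton's own center before the orbital set is completed, again to avoid
  center collapse.

Optional seeded random occupied–virtual rotations of any guess support
robustness sweeps.

## Fixtures and what the tests show

Fixture geometries are standard experimental-style internal coordinates
hard-coded in source (H2 0.7414 Å; water 0.9572 Å/104.52°; hydronium
0.98 Å/111.3°; acetylene C≡C 1.203 Å, C–H 1.063 Å; a Zundel cation with
O–O 2.40 Å and the shared proton at the midpoint; a Cs water dimer at
O–O 2.976 Å; an Eigen cation at O–O 2.57 Å).  All hydrogens are quantum.
These are deterministic desk-scale stand-ins, not the literature's
MP2-optimized geometries, and the electronic basis is minimal — so absolute
energies here are not comparable to published large-basis values.  Every
acceptance property is a *representation or solver comparison at fixed
geometry and basis*, which is exactly the class of claim that transfers:
representation equivalence, HP/HP* cancellation, solver agreement, and the
HP iteration advantage are all internal identities or robust qualitative
orderings, not basis-converged observables.

Observed on this suite (DIIS, SAD guesses, 1e-8 thresholds): HP converges in
6–14 iterations where SD needs 21–81; with core,core guesses SD fails or
lands on higher-energy solutions for several fixtures while HP converges to
the lowest energy in every case; HP* restores SD-like counts.  TRAH
converges in the fewest outer iterations but each is by far the costliest —
consistent with the expected cost ordering.

## Numerical choices and degenerate inputs

* Linear dependence: overlap eigenvalues below 1e-8 warn; below 1e-12 the
  S^{-1/2} construction raises.
* Boys function accurate to ≤ 1e-12 relative on x ∈ [0, 200]; tiny-argument
  branch switches to the Taylor series at x < 1e-13.
* Shell components are individually normalized to unit self-overlap; the
  double-factorial factors cancel so one contraction scale per shell
  suffices.
* DIIS Gram degeneracy, Davidson subspace collapse (cap 80 vectors,
  200 microiterations), and GDM curvature-condition violations all have
  explicit guards described above.
* Energy-component bookkeeping is validated by a finite-difference oracle:
  the analytic orbital gradient matches central differences of the total
  energy to 1e-6 relative along random coupled directions, and
  Hessian-vector products match finite-differenced gradients to 1e-5 —
  these two tests are what tie the Fock builders to the energy expression.

## Known limitations

* No NEO-DFT: electronic exchange–correlation and electron–proton
  correlation functionals are not implemented (an empty hook interface
  exists).  No open-shell electrons, no ECPs, no point-group symmetry,
  no ghost atoms, no analytic geometry gradients.
* TRAH is SD-only; its HP extension needs distinguishable-particle coupling
  blocks and is out of scope.
* Cartesian (not spherical-harmonic) Gaussians, l ≤ 2.
* In-memory 4-index tensors limit systems to a few hundred basis functions.
* Proton basis centers are fixed; variational optimization of the centers
  is not performed.
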