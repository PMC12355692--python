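# Methods

`hiqem` implements, at desk scale, the three stages of a hierarchical
QM/QM/MM workflow for machine-learning-corrected binding free energies:
projection-based multi-orbital-set embedding with an exact energy
decomposition, transfer-learned ensemble neural-network potentials with an
element-dependent shift fit, and nonequilibrium-switching end-state
corrections assembled through a thermodynamic cycle.  Every stage runs on
synthetic model problems generated by the package itself, so the entire
pipeline is testable without external data or electronic-structure codes.

## Model electronic systems and the mean-field reference

Electronic systems are integral containers: a symmetric one-electron matrix
`h_core` (kinetic energy plus the external potential of the nuclei and any
embedding point charges), a rank-4 two-electron tensor `(pq|rs)` with 8-fold
permutational symmetry, an SPD overlap `S`, a nuclear-repulsion scalar and an
even electron count (closed shell only; open-shell cores are rejected).  The
seeded generator builds chain or ring topologies with distance-decaying
overlaps (SPD enforced by shrinking off-diagonals, with a warning) and a
factorized interaction tensor `g = strength * sum_t L_t (x) L_t` with PSD
`L_t`, which guarantees a positive-semidefinite Coulomb metric and stable
SCF convergence.  Point charges enter the one-electron matrix through a
distance-damped overlap-proportional potential; at large separation the
interaction of a charge `q` with an electron density of total charge `Q`
approaches `qQ/R`, which is the property the tests pin down.

The restricted mean-field reference (`run_scf`) uses DIIS-accelerated
Roothaan iterations, a core-Hamiltonian guess, an energy tolerance of 1e-10
hartree and at most 200 iterations.  Two exchange-correlation models exist:

* `hf` — Hartree-Fock.  The density-functional object returns zero energy
  and potential; exchange enters as the exact contraction of the interaction
  tensor.
* `toy-local` — `E_xc[D] = -c sum_p D_pp^(4/3)` on the basis-density
  diagonal with the matching diagonal derivative potential.  It is grid-free
  yet produces a genuinely nonzero nonadditive XC coupling between orbital
  sets, which is what the embedding machinery needs to be exercised.

## Orbital partitioning and Huzinaga-type embedding

Occupied orbitals are localized by Pipek-Mezey Jacobi sweeps on Mulliken
populations (convergence when the metric gain of a sweep falls below 1e-10;
columns sign-fixed and ordered by leading population for determinism).  Each
localized orbital is routed by the two-step rule: to the environment (LL)
set if its Mulliken population on the environment atoms strictly exceeds
0.4, otherwise to the quantum core where its population is largest, ties
breaking to the lowest core index.

Each core `I` receives an effective one-electron operator

    h^I = h + v_xc^nadd,I + v_C^I + p^I

with `v_C^I` the Coulomb potential of all other sets' densities,
`v_xc^nadd,I` the XC-potential difference between the total and the core
density (zero in hf mode), and `p^I` the level-shifted Huzinaga projector
built from the occupied projectors of all other sets and the embedded Fock
operator, with a default shift of 1.0 hartree.  Core energies are evaluated
either as the single-determinant expectation over the core's occupied
orbitals (no embedded SCF reoptimization) or by dense FCI over the core
occupied orbitals plus the shared virtual space (Slater-Condon rules over
alpha/beta bitmask determinants; capped at 12 spatial orbitals, beyond which
an explicit virtual-truncation option applies).  The LL set contributes a
Kohn-Sham-type energy; the rest term restores the nonadditive XC energy,
subtracts the `v_xc^nadd` expectation values (Kohn-Sham densities only) and
removes the double-counted inter-core Coulomb energy.

Two structural facts make the hf/determinant decomposition exact to machine
precision, and both are enforced by tests rather than assumed: the
nonadditive-XC expectation cancels identically between the core Hamiltonians
and the rest term, and the Huzinaga projector vanishes on the span of the
reference orbitals (every set is orthogonal to every other), which is also
why the decomposed energy is independent of the level shift over
[0.1, 10] hartree at the determinant level.  In hf mode the set-wise XC
energy is exact exchange — including for the LL set, whose textbook
expression omits it — because otherwise the all-LL partition could not
reproduce the Hartree-Fock reference.  With FCI cores the decomposition
deliberately drops below the mean-field reference: that correlation gain is
the point of the embedding.  Nuclear repulsion is booked as an explicit
ledger entry added into the quantum-region total, so that the decomposed
total is directly comparable to the reference energy.

## Three-tier toy potential-energy surfaces

The conformer generator emulates the statistical structure of an
MM / QM-MM / QM-QM-MM hierarchy on a 12-atom molecule (6 atoms tagged as the
QM set Q, the first 3 of those as the quantum core):

* tier 0 — classical force field: harmonic bonds (r0 = 1.5 A,
  k = 250 kJ/mol/A^2), cosine-harmonic angles (109.5 deg, 50 kJ/mol),
  Lennard-Jones (eps = 0.35 kJ/mol, sigma = 2.8 A) and Coulomb interactions
  (alternating +/- 0.15 e) over pairs separated by three or more bonds,
  optional site tethers, and in the "protein" end state a harmonic
  confinement of the QM atoms (4 kJ/mol/A^2).
* tier 1 — Morse-minus-harmonic anharmonicity on the QM-internal bonds
  (depth 320 kJ/mol, a = 1.1/A, scale 0.35) plus polarization-like rescaling
  of the QM charges by 1.2, mimicking an embedded quantum treatment of Q.
* tier 2 — a strictly local bounded correction `A sin(w (r - r0))` on the
  quantum-core internal distances (w = 3/A); the default amplitude
  A = 15 kJ/mol puts the tier-2-minus-tier-1 spread in the ~10 kJ/mol
  regime characteristic of a correlated-core correction on top of a DFT
  region.  A calibration helper rescales A to any requested spread (the
  correction is linear in A and the sampling tier does not depend on it, so
  one probe fixes the scale).

All terms have analytic forces, verified against central finite differences;
every term is evaluated in batch over a leading trajectory axis, which is
what makes many-trajectory switching affordable in numpy.  Tier-2 forces
exist internally but are withheld from generated datasets by default,
forcing the energy-only transfer path downstream; an override exposes them
for the gradients-matter comparison.  Conformers are sampled from the tier-0
Boltzmann ensemble by BAOAB Langevin dynamics (unit masses, reduced time
labelled in ps) or by Metropolis Monte Carlo, with an energy ceiling guard.

Every tier splits exactly into four ledger pieces — MM-only terms,
QM-MM Lennard-Jones, QM-MM pair electrostatics at the unscaled charges, and
a QM part that carries everything the tiers change (including the difference
between polarized and unpolarized electrostatics).  The identity
`tier = E_MM + E_LJ^int + pair + ML-part` holds to machine precision for
energies and forces and is the backbone of the training-target construction
and of the assembled inference surface.

What the generator does not emulate: real solvent degrees of freedom,
conformational multi-modality of a flexible ligand, force-field
parameter heterogeneity, and label noise (tier labels are analytic, so
learning errors are purely representational/statistical).  Passing tests
therefore demonstrate the correctness and statistical behaviour of the
machinery, not chemical accuracy on real systems.

## Ensemble neural-network potential and transfer learning

The potential is a high-dimensional neural-network ansatz: the energy is a
sum of per-atom outputs of small per-element feedforward networks (two tanh
hidden layers, default 25 nodes; experiments here use 16-24) fed with
element-weighted atom-centered symmetry functions (radial Gaussians and
Behler-style angular channels under a smooth cosine cutoff, element weights
making the descriptor dimension independent of the alphabet).  Descriptor
values and their Jacobians are analytic; network forces are exact gradients,
and training on forces uses hand-derived double backpropagation (gradients
of `s . dE/dx` with respect to the weights), verified against finite
differences.  The loss is energy MSE plus `lambda_F` times force MSE
(`lambda_F` default 0.01, chosen so both terms start at the same order of
magnitude on the toy tiers).

An ensemble of 10 members (independent initializations and 90/10 splits)
provides the prediction as the member mean and the uncertainty as
`c = 2` times the population standard deviation across members.  Training
uses full-batch Adam with per-weight first/second moments.  Transfer
learning toward a higher tier freezes the input standardization and the
first hidden layer bit-exactly, re-splits the new data 90/10 per member,
uses all training energies in each of the default 300 epochs, and continues
the per-weight optimizer state: the second moments (the individually adapted
step scales) and step count carry over, while the first-moment momentum —
which belongs to the finished objective — restarts at zero.  This makes a
member already at its optimum an exact fixed point of transfer, at the cost
of cautious early steps after the objective changes (constant-offset
absorption tightens steadily with epochs).  Element-dependent mean shifts
between tiers are removed upstream by a stoichiometric least-squares fit
(minimum-norm for the rank-deficient single-compound case, flagged in the
diagnostics), so the transfer target is a small zero-centered correction.

## Training-set composition and active learning

Equilibrium snapshots alone never visit stretched or compressed QM
geometries, so a potential trained on them has no repulsive or dissociative
walls: its own dynamics can escape the physical region (the saturating tanh
output plateaus beyond the trained range, and a flat unbounded plateau wins
on entropy).  The training set therefore combines three sources, mirroring
how such potentials are built in practice: (i) tier-0 equilibrium snapshots,
sampled 20% hot (360 K against the 300 K evaluation ensemble) to broaden
coverage; (ii) perturbed-geometry augmentation — QM atoms of random
snapshots displaced by Gaussian noise, accepted stratified across mid-tier
energy bands up to the 150 kJ/mol filter window, so the wall is taught at
full height rather than only where random displacements land; and (iii)
active-learning rounds: short Langevin trajectories run on the current
learned surface (one round hot at 1.3 kT), whose visited structures —
including any spurious escape channels — are labelled analytically and added
to the training set, after which training continues from the persisted
optimizer state.  Three such rounds stabilize the learned surface over the
full switching and relaxation timescales used here.

The structure filter keeps conformers within 150 kJ/mol (inclusive) of the
median mid-tier energy (median of an even count: midpoint of the central
pair); the filtered set is what the shift fit and the transfer step see.

## Nonequilibrium switching and the thermodynamic cycle

Work is accumulated along a linear mixture `U_lambda = (1-lambda) U_start +
lambda U_end` driven from 0 to 1: the increment `(lambda_k - lambda_{k-1})
(U_end - U_start)` is taken before one BAOAB Langevin step at the new fixed
lambda, so the zero-step protocol reduces exactly to free-energy
perturbation.  The reference protocol (150 starts, a 10 ps switch, 10 ps
relaxation, 6 repeats) is scaled down in the shipped experiments to 18-24
starts, 180-250 steps, 100-150 relaxation steps and 3 repeats — problem
sizes chosen so the full pipeline runs in minutes on one core while leaving
the statistics meaningful; all counts are parameters of the protocol
object.  After the forward switch the end-state configurations are
importance-resampled with weights proportional to `exp(-W/kT)` (systematic
resampling, effective sample size reported, collapse warned), relaxed on the
end surface and switched back.  Trajectories reaching non-finite energies
are flagged and excluded.

Free energies come from the Bennett acceptance ratio solved to 1e-10 on the
bidirectional works, with the standard two-state asymptotic variance
`Var(beta dF) = [sum_n f(x_n)(1 - f(x_n))]^-1 - 1/n_F - 1/n_R` over the
pooled sign-aligned works (`f` logistic); Jarzynski exponential averaging
and a Crooks Gaussian-intersection estimator serve as cross-checks.  The
Gaussian-intersection estimator is only meaningful for near-Gaussian work
distributions (slow switching); on strongly non-Gaussian instantaneous works
it is biased by construction.

The cycle combines an externally supplied MM-level binding free energy with
per-repeat end-state corrections over the full repeat grid,
`dG(i,j) = dG_MM + dG_P(i) - dG_S(j)`; the reported value is the grid mean,
`sigma_bind` the grid standard deviation (sample convention, n-1), and the
total uncertainty `sqrt(dG_P^2 + dG_S^2 + (2 sigma_bind)^2)` with the
end-state acceptance-ratio errors pooled over repeats.

The switching target is the assembled refined surface
`E_ML + E_MM + E_LJ^int + pair + sum_m n_m (E_atomic,m + shift_m)`: only the
QM part is learned, the classical terms are evaluated by the force field at
inference time.  Besides being the faithful reading of the energy ledger,
this is what keeps the switching dynamics stable — the network only ever
steers the atoms it was trained on.  The end-to-end cross-check compares the
switching estimate per end state with an independent estimate from
instantaneous bidirectional perturbation between equilibrium ensembles of
the two surfaces (tier-0 sampled directly; the refined surface by batched
Langevin with an equilibration prefix).  Standard errors for this comparison
respect the correlation structure of the data: the switching estimate is the
mean of per-repeat acceptance-ratio values with the between-repeat spread as
its error (the backward works within one repeat are strongly correlated
through resampling, so the pooled asymptotic error would be overconfident),
and the perturbation estimate's error comes from a trajectory-blocked
bootstrap (backward samples are correlated along each trajectory).

## Numerical choices and conventions

* Units: hartree/bohr in the electronic-structure modules, kJ/mol, angstrom
  and elementary charges elsewhere; conversions only at module boundaries.
* Coulomb constant 1389.3545755023301 kJ mol^-1 A e^-2 and
  R = 0.00831446261815324 kJ mol^-1 K^-1, both CODATA-derived and pinned to
  all digits used (cross-checked in tests against an independent derivation
  from scipy's constant set).
* Ensemble uncertainty uses the population standard deviation; the cycle
  grid spread uses the sample convention.
* Ties and degeneracies: partition ties break to the lowest core index; the
  environment threshold is a strict `>` ; the median window is inclusive.
* Determinism: every stochastic component takes an explicit seed; equal
  seeds give bit-identical datasets, ensembles and work sets.
* Degenerate inputs: empty LL sets contribute zero energy; cores without
  occupied orbitals, empty datasets, empty work sets, unnormalized orbitals,
  coincident charge pairs and fused atoms raise informative errors.

## Known limitations

* The embedding operates on model integral tensors; there are no real
  Gaussian-basis integrals, no embedded-SCF freeze-and-thaw, no analytic
  nuclear gradients of embedded energies, and no open-shell cores.
* The learned surface is reliable only within its (augmented and
  actively-learned) training coverage; the stabilization strategy documented
  above is empirical, not a guarantee.
* The Crooks estimator's standard error is a rough Gaussian approximation.
* The equilibrium-perturbation cross-check shares the learned surface with
  the switching calculation; it is an independent estimator and sampling
  path, not an independent potential.
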