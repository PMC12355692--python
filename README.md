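# hiqem

Hierarchical quantum embedding with machine-learned end-state corrections,
at desk scale.

## The problem

Alchemical binding free energies are routinely computed with classical force
fields (MM).  Their accuracy can be lifted by correcting the end states —
the protein-ligand complex and the solvated ligand — from the MM surface to
a quantum-mechanically informed surface via nonequilibrium switching.  Going
one level further, small *quantum cores* inside the QM region (e.g. the
aromatic moieties of a ligand) can receive a correlated-wavefunction
treatment through projection-based embedding, and the resulting three-level
QM/QM/MM energies can be fed into the machine-learned potential by transfer
learning.  `hiqem` implements this whole chain on self-generated model
systems, so every stage — the embedding algebra, the learning protocol, the
switching statistics — is exercised and verified end to end without any
external quantum-chemistry or MD engine.

The package is aimed at method developers who want a transparent, fully
testable reference implementation of the three stages and of the statistical
contracts connecting them.

## What is implemented

**Huzinaga-type multi-orbital-set embedding** (`hiqem.embedding_core`).
The occupied orbitals of a converged mean-field reference are localized
(Pipek-Mezey) and partitioned into quantum cores and an environment set by a
Mulliken-population rule (environment if the population on environment atoms
exceeds 0.4, otherwise the core with the largest population).  The total
energy is decomposed as

    E_QM = sum_I E_I^QC + E^LL + E^rest

with each core energy the expectation of an effective Hamiltonian
`h^I = h + v_xc^nadd,I + v_C^I + p^I` (nonadditive XC potential, Coulomb
potential of the other sets, level-shifted Huzinaga projector), the
environment contributing a Kohn-Sham-type energy, and the rest term
restoring nonadditive exchange-correlation and removing double-counted
inter-core Coulomb energy.  At the Hartree-Fock/determinant level the
decomposition is exact to 1e-10 hartree for every partition and independent
of the level shift; FCI cores (dense Slater-Condon CI over the core occupied
orbitals plus the shared virtual space) lower the energy variationally.

**Ensemble neural-network potential with transfer learning**
(`hiqem.mlp_potential`).  Per-element feedforward networks over
element-weighted atom-centered symmetry functions; analytic forces and
double-backpropagation force training; an ensemble (default 10 members)
whose mean is the prediction and `2 x` population std the uncertainty.
Transfer learning toward a higher theory tier freezes input standardization
and the first hidden layer bit-exactly, continues the per-weight optimizer
state, and re-splits the data 90/10 per member over 300 epochs.

**The multilevel energy ledger** (`hiqem.multilevel_energy`).  Exact
bookkeeping between learned and classical terms:

    E_QM/MM     = E_ML + E_MM + E_LJ^int + sum_IA k q_I q_A / r_IA + sum_m n_m E_m^atomic
    E_QM/QM/MM  = E_QM/MM + dE_ML + sum_m n_m shift_m

with element-dependent shifts from a stoichiometric least-squares fit, and
the median-window structure filter (keep within 150 kJ/mol of the median).

**Nonequilibrium switching and the thermodynamic cycle**
(`hiqem.free_energy`).  Bidirectional driven switching between potential
tiers with Langevin dynamics, importance resampling between the forward and
backward legs, free energies from the Bennett acceptance ratio (Jarzynski
and Crooks-intersection cross-checks), cycle assembly over the full repeat
grid and uncertainty propagation
`dG = sqrt(dG_P^2 + dG_S^2 + (2 sigma_bind)^2)`.

**Synthetic data** (`hiqem.synthetic_data`).  Seeded generators for model
electronic systems (integral tensors) and a 12-atom three-tier toy
potential-energy surface (classical force field; Morse + polarization
corrections on the QM atoms; a strictly local correction on the quantum-core
atoms) with analytic forces, conformer samplers, perturbed-geometry
augmentation and tier-gap statistics.

A thin CLI (`hiqem embed`, `hiqem gen-data`, `hiqem train`, `hiqem
transfer`, `hiqem ledger`, `hiqem switch`, `hiqem cycle`) wraps the library.

## Worked example

Decompose a generated 8-basis-function model system into two quantum cores:

```python
from hiqem.synthetic_data import ModelHamiltonianSpec, gen_model_system
from hiqem.systems import XCModel
from hiqem.embedding_core import reference_and_partition, embedding_total

system = gen_model_system(
    ModelHamiltonianSpec(n_atoms=4, n_basis_per_atom=2, n_electrons=6, seed=3)
)
xc = XCModel("hf")
scf, partition = reference_and_partition(system, [[0, 1], [2, 3]], xc)
det = embedding_total(system, partition, xc, solver="determinant-expectation")
fci = embedding_total(system, partition, xc, solver="fci")
print(scf.energy, partition.assignment)
print(det.e_qm - scf.energy)
print(fci.e_qm - scf.energy)
```

prints

```
-10.230399308091414 [0, 1, 1]
-1.78e-15
-0.011362
```

The three occupied orbitals were routed one to core 0 and two to core 1
(no environment orbital exceeded the 0.4 threshold here).  At the
determinant level the sum of core, environment and rest energies (plus
nuclear repulsion) reproduces the undecomposed SCF energy to machine
precision — the decomposition is exact bookkeeping.  Replacing the core
solver by FCI lowers the energy by 11.4 millihartree: that is the
correlation energy the embedding injects into the cores, the quantity the
whole three-level hierarchy exists to capture.

The full pipeline — tiered data, base training, shift fit, energy-only
transfer, bidirectional switching on both end states, cycle assembly — is
driven by `hiqem.workflow.build_end_state_model` and
`hiqem.workflow.run_cycle`; `hiqem.experiments.end_to_end_cycle` runs it
together with an equilibrium-perturbation cross-check.

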