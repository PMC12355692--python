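"""Multi-orbital-set projection-based embedding with exact energy decomposition.

The workflow mirrors hierarchical QM(HL)/QM(LL)/MM embedding on model
Hamiltonians: converge one mean-field reference for the whole system, localize
the occupied orbitals (Pipek-Mezey with Mulliken populations), route each
localized orbital either to a quantum core or to the low-level (LL)
environment set, and decompose the total electronic energy into per-core
energies, an LL Kohn-Sham-type energy and a rest term that restores the
nonadditive exchange-correlation energy and removes the double-counted
inter-core Coulomb interaction.

At the single-determinant level the decomposition is exact: the nonadditive-XC
expectation values cancel between the core Hamiltonians and the rest term, and
the level-shifted Huzinaga projector is identically zero in the occupied(+)
virtual molecular-orbital space (all orbital sets come from one orthonormal
reference), so summing the pieces recovers the undecomposed mean-field energy
to machine precision.  Quantum cores may instead be solved with FCI over the
core occupied orbitals plus the shared virtual space, which lowers the core
energies variationally — that is the point of the embedding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fci import determinant_expectation, fci_ground_state
from .scf import (
    SCFResult,
    coulomb_matrix,
    exact_exchange_energy,
    exchange_matrix,
    run_scf,
)
from .systems import ModelSystem, XCModel

__all__ = [
    "OrbitalSetPartition",
    "EmbeddedHamiltonian",
    "EmbeddingEnergies",
    "MMTerms",
    "mulliken_population",
    "localize_occupied",
    "partition_orbitals",
    "build_core_hamiltonian",
    "core_energy",
    "ll_energy",
    "rest_energy",
    "embedding_total",
]

LL = "LL"


# ---------------------------------------------------------------------------
# Mulliken populations and Pipek-Mezey localization
# ---------------------------------------------------------------------------


def mulliken_population(
    orbital: np.ndarray, atom_group, system: ModelSystem, tol: float = 1e-8
) -> float:
    """Mulliken population of a normalized orbital on a group of atoms.

    pop = sum_{mu in group} c_mu (S c)_mu.  Populations over all atoms sum to
    one; individual group populations may lie outside [0, 1] in a
    nonorthogonal basis.
    """
    c = np.asarray(orbital, dtype=float)
    norm = float(c @ system.overlap @ c)
    if abs(norm - 1.0) > tol:
        raise ValueError(f"orbital not normalized: c^T S c = {norm:.6f}")
    mu = system.basis_on_atoms(atom_group)
    sc = system.overlap @ c
    return float(np.sum(c[mu] * sc[mu]))


def _population_matrices(c_occ: np.ndarray, system: ModelSystem) -> np.ndarray:
    """P[A, s, t]: symmetrized Mulliken pair populations per atom A."""
    sc = system.overlap @ c_occ
    n_at = system.n_atoms
    p = np.zeros((n_at, c_occ.shape[1], c_occ.shape[1]))
    for a in range(n_at):
        mu = system.basis_on_atoms([a])
        if len(mu) == 0:
            continue
        p[a] = 0.5 * (c_occ[mu].T @ sc[mu] + sc[mu].T @ c_occ[mu])
    return p


def localization_metric(c_occ: np.ndarray, system: ModelSystem) -> float:
    """Pipek-Mezey metric: sum over orbitals of squared atomic populations."""
    p = _population_matrices(c_occ, system)
    return float(np.sum(np.einsum("aii->ai", p) ** 2))


def localize_occupied(
    c_occ: np.ndarray,
    system: ModelSystem,
    tol: float = 1e-10,
    max_sweeps: int = 200,
) -> np.ndarray:
    """Pipek-Mezey localization of the occupied block by Jacobi sweeps.

    Rotates occupied orbitals among themselves (the occupied span and every
    quantity invariant under occupied rotations, such as the total mean-field
    energy, are untouched) until the metric gain of a full sweep drops below
    ``tol``.  Columns are sign-fixed (largest-magnitude coefficient positive)
    and ordered by their leading atomic population for determinism.
    """
    c = np.array(c_occ, dtype=float)
    n_occ = c.shape[1]
    metric_in = localization_metric(c, system)
    for _ in range(max_sweeps):
        gain_total = 0.0
        for s in range(n_occ - 1):
            for t in range(s + 1, n_occ):
                p = _population_matrices(c[:, [s, t]], system)
                pst = p[:, 0, 1]
                pss = p[:, 0, 0]
                ptt = p[:, 1, 1]
                a = float(np.sum(pst**2 - 0.25 * (pss - ptt) ** 2))
                b = float(np.sum(pst * (pss - ptt)))
                norm = np.hypot(a, b)
                gain = a + norm
                if gain <= tol:
                    continue
                alpha = 0.25 * np.arctan2(b, -a)
                ca, sa = np.cos(alpha), np.sin(alpha)
                new_s = ca * c[:, s] + sa * c[:, t]
                new_t = -sa * c[:, s] + ca * c[:, t]
                c[:, s], c[:, t] = new_s, new_t
                gain_total += gain
        if gain_total < tol:
            break
    metric_out = localization_metric(c, system)
    if metric_out < metric_in - 1e-8:
        raise RuntimeError(
            f"localization decreased the metric ({metric_in:.6f} -> {metric_out:.6f})"
        )
    # deterministic sign and order
    for i in range(n_occ):
        k = int(np.argmax(np.abs(c[:, i])))
        if c[k, i] < 0:
            c[:, i] *= -1.0
    pops = np.einsum("aii->ia", _population_matrices(c, system))  # (orb, atom)
    order = sorted(
        range(n_occ), key=lambda i: (int(np.argmax(pops[i])), -float(np.max(pops[i])))
    )
    return c[:, order]


# ---------------------------------------------------------------------------
# Orbital-set partitioning
# ---------------------------------------------------------------------------


@dataclass
class OrbitalSetPartition:
    """Localized occupied orbitals with their assignment to cores or LL."""

    c_occ: np.ndarray
    c_virt: np.ndarray
    assignment: list  # per occupied orbital: core index (int) or "LL"
    core_atom_groups: list  # list of atom-index lists, one per quantum core
    epsilon_shift: float = 1.0

    @property
    def n_cores(self) -> int:
        return len(self.core_atom_groups)

    def occupied_of(self, label) -> np.ndarray:
        return np.array([i for i, a in enumerate(self.assignment) if a == label], int)

    def set_density(self, label) -> np.ndarray:
        """Closed-shell density matrix 2 C C^T of one orbital set."""
        idx = self.occupied_of(label)
        c = self.c_occ[:, idx]
        return 2.0 * c @ c.T

    def total_density(self) -> np.ndarray:
        return 2.0 * self.c_occ @ self.c_occ.T

    def validate(self, system: ModelSystem, tol: float = 1e-10) -> None:
        c = np.hstack([self.c_occ, self.c_virt])
        dev = np.max(np.abs(c.T @ system.overlap @ c - np.eye(c.shape[1])))
        if dev > tol:
            raise ValueError(f"orbitals not S-orthonormal (max deviation {dev:.2e})")
        labels = set(range(self.n_cores)) | {LL}
        for a in self.assignment:
            if a not in labels:
                raise ValueError(f"unknown set label {a!r}")
        seen: set[int] = set()
        for group in self.core_atom_groups:
            g = set(int(x) for x in group)
            if not g:
                raise ValueError("empty quantum-core atom group")
            if seen & g:
                raise ValueError("core atom groups must be pairwise disjoint")
            seen |= g


def partition_orbitals(
    c_occ_localized: np.ndarray,
    system: ModelSystem,
    core_atom_groups: list,
    c_virt: np.ndarray | None = None,
    env_threshold: float = 0.4,
    epsilon_shift: float = 1.0,
) -> OrbitalSetPartition:
    """Assign each localized occupied orbital to a quantum core or to LL.

    Two-step rule: an orbital whose Mulliken population on the environment
    atoms strictly exceeds ``env_threshold`` is assigned to LL; otherwise it
    goes to the core on which it has the largest population (exact ties break
    to the lowest core index).
    """
    groups = [sorted(int(a) for a in g) for g in core_atom_groups]
    for g in groups:
        if not g:
            raise ValueError("empty quantum-core atom group")
    core_atoms = set(a for g in groups for a in g)
    env_atoms = [a for a in range(system.n_atoms) if a not in core_atoms]

    assignment = []
    for i in range(c_occ_localized.shape[1]):
        orb = c_occ_localized[:, i]
        pop_env = (
            mulliken_population(orb, env_atoms, system) if env_atoms else 0.0
        )
        if pop_env > env_threshold:
            assignment.append(LL)
            continue
        pops = [mulliken_population(orb, g, system) for g in groups]
        assignment.append(int(np.argmax(pops)))  # argmax ties -> lowest index

    part = OrbitalSetPartition(
        c_occ=c_occ_localized,
        c_virt=c_virt if c_virt is not None else np.zeros((system.n_basis, 0)),
        assignment=assignment,
        core_atom_groups=groups,
        epsilon_shift=epsilon_shift,
    )
    part.validate(system)
    return part


# ---------------------------------------------------------------------------
# Embedded core Hamiltonian and energies
# ---------------------------------------------------------------------------


@dataclass
class EmbeddedHamiltonian:
    """Effective one-electron operator and context for one quantum core."""

    core_index: int
    h_eff: np.ndarray  # h_core + v_xc^nadd + v_C + projector, AO basis
    f_embedded: np.ndarray  # embedded Fock operator of the core, AO basis
    core_occ_indices: np.ndarray
    densities: dict  # {"core": D_I, "ll": D_LL, "tot": D_tot}
    partition: OrbitalSetPartition
    system: ModelSystem
    xc: XCModel


def _set_exc(system: ModelSystem, xc: XCModel, density: np.ndarray) -> float:
    """Set-wise XC energy: exact exchange in hf mode, functional otherwise."""
    if xc.is_hf:
        return exact_exchange_energy(system.g_eri, density)
    return xc.exc(density)


def build_core_hamiltonian(
    system: ModelSystem,
    partition: OrbitalSetPartition,
    core_index: int,
    xc: XCModel | None = None,
) -> EmbeddedHamiltonian:
    """Effective Hamiltonian h^I = h + v_xc^nadd,I + v_C^I + p^I for core I.

    ``v_C^I`` is the Coulomb potential of all other sets' densities,
    ``v_xc^nadd,I`` the difference of XC potentials at the total and the core
    density (zero in hf mode), and ``p^I`` the level-shifted Huzinaga
    projector built from the occupied projectors of all other sets.
    """
    xc = xc or XCModel("hf")
    occ_i = partition.occupied_of(core_index)
    if len(occ_i) == 0:
        raise ValueError(f"quantum core {core_index} holds no occupied orbitals")

    d_core = partition.set_density(core_index)
    d_tot = partition.total_density()
    d_env = d_tot - d_core
    s = system.overlap

    v_coulomb = coulomb_matrix(system.g_eri, d_env)
    v_nadd = xc.vxc(d_tot) - xc.vxc(d_core)
    f_hf = (
        system.h_core
        + coulomb_matrix(system.g_eri, d_core)
        - 0.5 * exchange_matrix(system.g_eri, d_core)
    )
    f_emb = f_hf + v_nadd + v_coulomb

    # occupied projector of all other sets (half density C C^T)
    other = [i for i in range(partition.c_occ.shape[1]) if i not in set(occ_i)]
    dh_env = partition.c_occ[:, other] @ partition.c_occ[:, other].T
    shifted = f_emb - partition.epsilon_shift * s
    projector = -(s @ dh_env @ shifted + shifted @ dh_env @ s)

    h_eff = system.h_core + v_nadd + v_coulomb + projector
    h_eff = 0.5 * (h_eff + h_eff.T)
    return EmbeddedHamiltonian(
        core_index=core_index,
        h_eff=h_eff,
        f_embedded=f_emb,
        core_occ_indices=occ_i,
        densities={"core": d_core, "ll": partition.set_density(LL), "tot": d_tot},
        partition=partition,
        system=system,
        xc=xc,
    )


def core_energy(
    embedded: EmbeddedHamiltonian,
    solver: str = "determinant-expectation",
    n_virtual_max: int | None = None,
    max_orbitals: int = 12,
) -> float:
    """Energy E_I^QC = <Psi_I|H_I|Psi_I> of one embedded quantum core.

    ``determinant-expectation`` evaluates the single-determinant expectation
    over the core's occupied orbitals without reoptimization; ``fci``
    diagonalizes the core Hamiltonian over the core occupied orbitals plus the
    shared virtual space (optionally truncated to the ``n_virtual_max``
    energetically lowest virtuals).
    """
    part = embedded.partition
    system = embedded.system
    c_core = part.c_occ[:, embedded.core_occ_indices]
    if solver == "determinant-expectation":
        active = c_core
    elif solver == "fci":
        c_virt = part.c_virt
        if n_virtual_max is not None:
            c_virt = c_virt[:, :n_virtual_max]
        active = np.hstack([c_core, c_virt])
    else:
        raise ValueError(f"unknown core solver {solver!r}")

    h_mo = active.T @ embedded.h_eff @ active
    g_mo = np.einsum(
        "pqrs,pi,qj,rk,sl->ijkl", system.g_eri, active, active, active, active,
        optimize=True,
    )
    n_elec = 2 * len(embedded.core_occ_indices)
    if solver == "determinant-expectation":
        return determinant_expectation(h_mo, g_mo, np.arange(n_elec // 2))
    energy, _ = fci_ground_state(h_mo, g_mo, n_elec, max_orbitals=max_orbitals)
    return energy


def ll_energy(
    system: ModelSystem, partition: OrbitalSetPartition, xc: XCModel | None = None
) -> float:
    """Kohn-Sham-type energy of the LL orbital set (Eq-3-style ledger term).

    One-electron terms plus the LL-LL Coulomb energy plus the set XC energy
    (exact exchange in hf mode so that the all-LL partition reproduces the HF
    reference; the toy-local functional otherwise).  Zero for an empty LL set;
    the nuclear repulsion is booked separately.
    """
    xc = xc or XCModel("hf")
    if len(partition.occupied_of(LL)) == 0:
        return 0.0
    d_ll = partition.set_density(LL)
    e = float(np.einsum("pq,pq->", d_ll, system.h_core))
    e += 0.5 * float(np.einsum("pq,pq->", d_ll, coulomb_matrix(system.g_eri, d_ll)))
    e += _set_exc(system, xc, d_ll)
    return e


def rest_energy(
    system: ModelSystem,
    partition: OrbitalSetPartition,
    xc: XCModel | None = None,
    return_breakdown: bool = False,
):
    """Rest term: nonadditive XC restoration and inter-core double-counting fix.

    E_rest = E_xc[rho_tot] - sum_sets E_xc[rho_set]
             - sum_cores <Psi_I|v_xc^nadd,I|Psi_I>   (KS densities)
             - sum_{I<J} Coulomb(rho_I, rho_J)
    """
    xc = xc or XCModel("hf")
    d_tot = partition.total_density()
    core_ids = [i for i in range(partition.n_cores) if len(partition.occupied_of(i))]
    d_cores = {i: partition.set_density(i) for i in core_ids}
    d_ll = partition.set_density(LL)

    e_xc_nadd = _set_exc(system, xc, d_tot)
    for d in d_cores.values():
        e_xc_nadd -= _set_exc(system, xc, d)
    if len(partition.occupied_of(LL)):
        e_xc_nadd -= _set_exc(system, xc, d_ll)

    e_vnadd = 0.0
    for i in core_ids:
        v_nadd = xc.vxc(d_tot) - xc.vxc(d_cores[i])
        e_vnadd += float(np.einsum("pq,pq->", d_cores[i], v_nadd))

    e_pair = 0.0
    for a_pos, a in enumerate(core_ids):
        for b in core_ids[a_pos + 1 :]:
            e_pair += float(
                np.einsum("pq,pq->", d_cores[a], coulomb_matrix(system.g_eri, d_cores[b]))
            )

    total = e_xc_nadd - e_vnadd - e_pair
    if return_breakdown:
        return total, {
            "nonadditive_xc": e_xc_nadd,
            "subtracted_vxc_nadd_expectation": -e_vnadd,
            "inter_core_coulomb_correction": -e_pair,
        }
    return total


@dataclass
class MMTerms:
    """Classical terms entering the three-level total energy (kJ/mol-free: hartree)."""

    e_mm: float = 0.0
    e_elec_int: float = 0.0
    e_lj_int: float = 0.0


@dataclass
class EmbeddingEnergies:
    """Itemized multilevel energy ledger of one embedding calculation."""

    e_core: list
    e_ll: float
    e_rest: float
    e_rest_breakdown: dict
    e_nuclear: float
    e_qm: float
    e_total: float
    mm_terms: MMTerms = field(default_factory=MMTerms)

    def to_dict(self) -> dict:
        return {
            "e_core": list(map(float, self.e_core)),
            "e_ll": self.e_ll,
            "e_rest": self.e_rest,
            "e_rest_breakdown": self.e_rest_breakdown,
            "e_nuclear": self.e_nuclear,
            "e_qm": self.e_qm,
            "e_mm": self.mm_terms.e_mm,
            "e_elec_int": self.mm_terms.e_elec_int,
            "e_lj_int": self.mm_terms.e_lj_int,
            "e_total": self.e_total,
        }


def embedding_total(
    system: ModelSystem,
    partition: OrbitalSetPartition,
    xc: XCModel | None = None,
    solver: str = "determinant-expectation",
    mm_terms: MMTerms | None = None,
    n_virtual_max: int | None = None,
) -> EmbeddingEnergies:
    """Assemble the full QM/QM/MM energy ledger for one partition.

    ``e_qm`` is the sum of the core energies, the LL energy, the rest term and
    the nuclear repulsion (booked explicitly so that the hf/determinant ledger
    reproduces the total reference mean-field energy); ``e_total`` adds the
    supplied classical terms.
    """
    xc = xc or XCModel("hf")
    mm = mm_terms or MMTerms()
    core_ids = [i for i in range(partition.n_cores) if len(partition.occupied_of(i))]
    e_core = []
    for i in core_ids:
        emb = build_core_hamiltonian(system, partition, i, xc)
        e_core.append(core_energy(emb, solver=solver, n_virtual_max=n_virtual_max))
    e_ll = ll_energy(system, partition, xc)
    e_rest, breakdown = rest_energy(system, partition, xc, return_breakdown=True)
    e_qm = sum(e_core) + e_ll + e_rest + system.e_nuclear
    e_total = e_qm + mm.e_mm + mm.e_elec_int + mm.e_lj_int
    return EmbeddingEnergies(
        e_core=e_core,
        e_ll=e_ll,
        e_rest=e_rest,
        e_rest_breakdown=breakdown,
        e_nuclear=system.e_nuclear,
        e_qm=e_qm,
        e_total=e_total,
        mm_terms=mm,
    )


def reference_and_partition(
    system: ModelSystem,
    core_atom_groups: list,
    xc: XCModel | None = None,
    env_threshold: float = 0.4,
    epsilon_shift: float = 1.0,
) -> tuple[SCFResult, OrbitalSetPartition]:
    """Convenience pipeline: SCF -> localize -> partition."""
    xc = xc or XCModel("hf")
    scf = run_scf(system, xc)
    c_loc = localize_occupied(scf.c_occ, system)
    part = partition_orbitals(
        c_loc,
        system,
        core_atom_groups,
        c_virt=scf.c_virt,
        env_threshold=env_threshold,
        epsilon_shift=epsilon_shift,
    )
    return scf, part
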