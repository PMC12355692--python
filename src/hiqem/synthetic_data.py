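"""Seeded generators for model Hamiltonians and three-tier toy surfaces.

Two families of artifacts feed the rest of the package:

* :func:`gen_model_system` builds small closed-shell model electronic systems
  (integral tensors with SPD overlap and 8-fold symmetric interactions) for
  the embedding machinery.

* :class:`ToyPES` defines a 12-atom molecule with three nested
  potential-energy tiers emulating the statistical structure of an
  MM / QM-MM / QM-QM-MM hierarchy: tier 0 is a classical force field
  (harmonic bonds and angles, Lennard-Jones, fixed point charges), tier 1
  adds a Morse-type anharmonic correction plus polarization-like charge
  scaling on the tagged QM atoms, and tier 2 adds a strictly local bounded
  correction on the quantum-core atoms.  Tier energy differences concentrate
  into narrow near-Gaussian distributions whose spread is tunable
  (:func:`calibrate_tier2`).  All terms have analytic forces; tier-2 forces
  exist internally but are withheld from generated datasets by default,
  forcing the energy-only transfer-learning path.

Every generator is a pure function of its seed and configuration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .constants import COULOMB_KJ_MOL_ANGSTROM, KB_KJ_MOL_K
from .systems import ModelSystem
from .xyz import REGION_CORE, REGION_MM, REGION_QM, Conformer

__all__ = [
    "ModelHamiltonianSpec",
    "gen_model_system",
    "ToyPESConfig",
    "ToyPES",
    "gen_conformers",
    "augment_conformers",
    "tier_gap_statistics",
    "TierGapStatistics",
    "calibrate_tier2",
]


# ---------------------------------------------------------------------------
# Model Hamiltonians
# ---------------------------------------------------------------------------


@dataclass
class ModelHamiltonianSpec:
    n_atoms: int = 4
    n_basis_per_atom: int = 1
    topology: str = "chain"  # or "ring"
    onsite_range: tuple = (-2.0, -0.5)
    hopping_range: tuple = (-0.45, -0.15)
    interaction_strength: float = 0.3
    overlap_offdiag: float = 0.25
    overlap_decay: float = 0.8
    spacing_bohr: float = 1.5
    n_electrons: int | None = None
    point_charges: list = field(default_factory=list)  # (charge e, xyz bohr)
    seed: int = 0


def _atom_positions(spec: ModelHamiltonianSpec) -> np.ndarray:
    n = spec.n_atoms
    if spec.topology == "chain":
        pos = np.zeros((n, 3))
        pos[:, 0] = np.arange(n) * spec.spacing_bohr
        return pos
    if spec.topology == "ring":
        radius = spec.spacing_bohr / (2.0 * np.sin(np.pi / n))
        ang = 2.0 * np.pi * np.arange(n) / n
        return np.column_stack([radius * np.cos(ang), radius * np.sin(ang), np.zeros(n)])
    raise ValueError(f"unknown topology {spec.topology!r}")


def gen_model_system(spec: ModelHamiltonianSpec) -> ModelSystem:
    """Deterministically generate a valid :class:`ModelSystem` from a spec.

    If the requested overlap off-diagonals make the overlap non-SPD, they are
    shrunk by half and the system regenerated, with a warning.
    """
    rng = np.random.default_rng(spec.seed)
    n_at, nb = spec.n_atoms, spec.n_basis_per_atom
    n = n_at * nb
    pos = _atom_positions(spec)
    atom_of_basis = np.repeat(np.arange(n_at), nb)
    labels = [f"X{i}" for i in range(n_at)]
    dist = np.linalg.norm(pos[atom_of_basis][:, None] - pos[atom_of_basis][None, :], axis=-1)

    # overlap with distance-decaying off-diagonals, SPD enforced by shrinking
    offdiag = spec.overlap_offdiag
    for _ in range(30):
        s = np.eye(n)
        inter = offdiag * np.exp(-spec.overlap_decay * (dist - spec.spacing_bohr))
        same_atom = atom_of_basis[:, None] == atom_of_basis[None, :]
        s = np.where(same_atom, s + 0.15 * offdiag * (1 - np.eye(n)), inter)
        np.fill_diagonal(s, 1.0)
        if np.linalg.eigvalsh(s).min() > 0.05:
            break
        warnings.warn("overlap off-diagonals shrunk by half to restore SPD")
        offdiag *= 0.5

    onsite = rng.uniform(*spec.onsite_range, size=n)
    h = np.diag(onsite)
    adj = np.abs(atom_of_basis[:, None] - atom_of_basis[None, :]) == 1
    if spec.topology == "ring":
        ends = (atom_of_basis[:, None] == 0) & (atom_of_basis[None, :] == n_at - 1)
        adj = adj | ends | ends.T
    hop = rng.uniform(*spec.hopping_range, size=(n, n))
    hop = 0.5 * (hop + hop.T)
    h = h + np.where(adj, hop, 0.0)
    # same-atom inter-basis coupling
    intra = 0.1 * rng.standard_normal((n, n))
    intra = 0.5 * (intra + intra.T)
    h = h + np.where(same_atom & ~np.eye(n, dtype=bool), intra, 0.0)

    # embedding point charges enter the external potential (Mataga-style
    # distance damping on the overlap distribution of each basis pair)
    centers = 0.5 * (pos[atom_of_basis][:, None] + pos[atom_of_basis][None, :])
    for q, rc in spec.point_charges:
        d = np.linalg.norm(centers - np.asarray(rc)[None, None, :], axis=-1)
        h = h - q * s / np.maximum(d, 1e-6)

    # factorized two-electron tensor: g = strength * sum_t L_t (x) L_t with
    # PSD L_t, giving a positive-semidefinite Coulomb metric
    g = np.zeros((n, n, n, n))
    if spec.interaction_strength != 0.0:
        decay = np.exp(-0.5 * dist)
        for _ in range(3):
            a = rng.standard_normal((n, n)) * decay
            lmat = a @ a.T / n
            g += np.einsum("pq,rs->pqrs", lmat, lmat)
        g *= spec.interaction_strength

    n_elec = spec.n_electrons
    if n_elec is None:
        n_elec = 2 * max(1, n // 2)
    system = ModelSystem(
        atom_labels=labels,
        atom_of_basis=atom_of_basis,
        n_electrons=int(n_elec),
        h_core=h,
        g_eri=g,
        overlap=s,
        e_nuclear=float(rng.uniform(0.0, 1.0)),
        point_charges=[(float(q), np.asarray(r, dtype=float)) for q, r in spec.point_charges],
    )
    system.validate()
    return system


# ---------------------------------------------------------------------------
# Three-tier toy potential-energy surface
# ---------------------------------------------------------------------------


@dataclass
class ToyPESConfig:
    """Configuration of the 12-atom three-tier toy molecule.

    Defaults define the study conditions used throughout: 12 atoms, the first
    6 tagged as the QM set Q, the first 3 of those as the quantum core.
    Units: kJ/mol, angstrom, elementary charge, kelvin.
    """

    n_atoms: int = 12
    qm_atoms: tuple = (0, 1, 2, 3, 4, 5)
    core_atoms: tuple = (0, 1, 2)
    elements: tuple = ("C", "N", "C", "O", "C", "C", "H", "O", "H", "N", "H", "H")
    # tier 0: classical terms
    r0: float = 1.5
    k_bond: float = 250.0  # kJ/mol/A^2 (E = 1/2 k dr^2)
    k_angle: float = 50.0  # kJ/mol (E = k (cos t - cos t0)^2)
    theta0_deg: float = 109.5
    lj_epsilon: float = 0.35
    lj_sigma: float = 2.8
    charge_magnitude: float = 0.15  # alternating +/- on atoms
    use_angles: bool = True
    use_lj: bool = True
    use_coulomb: bool = True
    tether_k: float = 0.0  # optional site restraints (harmonic-only configs)
    # environment: "solvent" or "protein" (protein adds a confining field on Q)
    environment: str = "solvent"
    protein_confine_k: float = 4.0
    # tier 1: Morse anharmonicity + polarization-like charge scaling on Q
    tier1_scale: float = 0.35
    morse_depth: float = 320.0
    morse_a: float = 1.1
    qm_charge_scale: float = 1.2
    # tier 2: strictly local bounded correction on core internal distances;
    # the default amplitude puts sigma(tier2 - tier1) in the ~10 kJ/mol regime
    tier2_amplitude: float = 15.0
    tier2_omega: float = 3.0
    # sampling
    temperature: float = 300.0
    energy_ceiling: float = 5.0e4
    seed: int = 0

    @property
    def kT(self) -> float:
        return KB_KJ_MOL_K * self.temperature


def _zigzag_reference(config: ToyPESConfig) -> np.ndarray:
    """Reference chain geometry with the equilibrium bond length and angle."""
    n, r0 = config.n_atoms, config.r0
    phi = (np.pi - np.deg2rad(config.theta0_deg)) / 2.0  # alternating tilt
    pos = np.zeros((n, 3))
    for i in range(1, n):
        sign = 1.0 if i % 2 == 1 else -1.0
        step = np.array([np.cos(phi), sign * np.sin(phi), 0.0])
        pos[i] = pos[i - 1] + r0 * step
    return pos


class ToyPES:
    """Three-tier toy potential-energy surface with analytic forces.

    All terms are evaluated in batch over a leading trajectory axis; the
    single-structure API wraps a batch of one.  Batching is what makes
    many-trajectory switching simulations affordable in pure numpy.
    """

    def __init__(self, config: ToyPESConfig | None = None):
        self.config = config or ToyPESConfig()
        c = self.config
        n = c.n_atoms
        self.bonds = [(i, i + 1) for i in range(n - 1)]
        self.angles = [(i, i + 1, i + 2) for i in range(n - 2)] if c.use_angles else []
        self.nonbonded = [(i, j) for i in range(n) for j in range(i + 3, n)]
        self.charges = c.charge_magnitude * np.array([1.0 if i % 2 == 0 else -1.0 for i in range(n)])
        self.qm = np.array(c.qm_atoms, dtype=int)
        self.core = np.array(c.core_atoms, dtype=int)
        self.reference = _zigzag_reference(c)
        self.qm_bonds = [b for b in self.bonds if b[0] in set(self.qm) and b[1] in set(self.qm)]
        core_set = set(int(i) for i in self.core)
        self.core_pairs = [
            (i, j) for i in sorted(core_set) for j in sorted(core_set) if i < j and j - i <= 2
        ]
        self.region = np.full(n, REGION_MM, dtype=int)
        self.region[self.qm] = REGION_QM
        self.region[self.core] = REGION_CORE
        # precomputed index arrays for batched evaluation, split into the
        # ledger partition: QM-internal terms (the learnable part), MM-only
        # terms, and QM-MM cross terms (LJ^int and pair electrostatics)
        self._b0, self._b1 = (np.array(v, int) for v in zip(*self.bonds))
        self._nb0, self._nb1 = (np.array(v, int) for v in zip(*self.nonbonded))
        if self.angles:
            self._a0, self._a1, self._a2 = (np.array(v, int) for v in zip(*self.angles))
        if self.qm_bonds:
            self._qb0, self._qb1 = (np.array(v, int) for v in zip(*self.qm_bonds))
        self._c0, self._c1 = (np.array(v, int) for v in zip(*self.core_pairs))
        qq = np.outer(self.charges, self.charges)
        self._qq_nb = qq[self._nb0, self._nb1]
        scaled = self.charges.copy()
        scaled[self.qm] *= c.qm_charge_scale
        self._dqq_nb = np.outer(scaled, scaled)[self._nb0, self._nb1] - self._qq_nb
        self._core_r0 = c.r0 * np.where(self._c1 - self._c0 == 1, 1.0, np.sqrt(2.0))
        in_qm = np.zeros(n, dtype=bool)
        in_qm[self.qm] = True
        bond_qm = in_qm[self._b0] & in_qm[self._b1]
        self._bond_class = np.where(bond_qm, 0, 1)  # 0 = QM-internal, 1 = MM/cross
        if self.angles:
            self._angle_qm = in_qm[self._a0] & in_qm[self._a1] & in_qm[self._a2]
        nb_q0, nb_q1 = in_qm[self._nb0], in_qm[self._nb1]
        self._nb_class = np.where(
            nb_q0 & nb_q1, 0, np.where(~nb_q0 & ~nb_q1, 1, 2)
        )  # 0 = QM-QM, 1 = MM-MM, 2 = cross

    # -- batched helpers ----------------------------------------------------

    @staticmethod
    def _accumulate_pairs(x, i0, i1, dedr, forces):
        """Scatter pair force -dE/dr r_hat into the (T, n, 3) force array."""
        rij = x[:, i0] - x[:, i1]
        r = np.linalg.norm(rij, axis=-1)
        f = (-dedr / r)[..., None] * rij
        t_idx = np.arange(x.shape[0])[:, None]
        np.add.at(forces, (t_idx, i0[None, :]), f)
        np.add.at(forces, (t_idx, i1[None, :]), -f)

    def _pair_distances(self, x, i0, i1):
        rij = x[:, i0] - x[:, i1]
        return rij, np.linalg.norm(rij, axis=-1)

    def _bonds_term(self, x, sel, forces):
        c = self.config
        i0, i1 = self._b0[sel], self._b1[sel]
        if len(i0) == 0:
            return np.zeros(x.shape[0])
        _, r = self._pair_distances(x, i0, i1)
        dr = r - c.r0
        self._accumulate_pairs(x, i0, i1, c.k_bond * dr, forces)
        return 0.5 * c.k_bond * np.sum(dr * dr, axis=1)

    def _angles_term(self, x, sel, forces):
        c = self.config
        if not self.angles:
            return np.zeros(x.shape[0])
        a0, a1, a2 = self._a0[sel], self._a1[sel], self._a2[sel]
        if len(a0) == 0:
            return np.zeros(x.shape[0])
        cos0 = np.cos(np.deg2rad(c.theta0_deg))
        u = x[:, a0] - x[:, a1]
        v = x[:, a2] - x[:, a1]
        ru = np.linalg.norm(u, axis=-1)
        rv = np.linalg.norm(v, axis=-1)
        cs = np.sum(u * v, axis=-1) / (ru * rv)
        d = cs - cos0
        dcdu = v / (ru * rv)[..., None] - (cs / ru**2)[..., None] * u
        dcdv = u / (ru * rv)[..., None] - (cs / rv**2)[..., None] * v
        g = (2.0 * c.k_angle * d)[..., None]
        t_idx = np.arange(x.shape[0])[:, None]
        np.add.at(forces, (t_idx, a0[None, :]), -g * dcdu)
        np.add.at(forces, (t_idx, a2[None, :]), -g * dcdv)
        np.add.at(forces, (t_idx, a1[None, :]), g * (dcdu + dcdv))
        return c.k_angle * np.sum(d * d, axis=1)

    def _lj_term(self, x, sel, forces):
        c = self.config
        if not c.use_lj:
            return np.zeros(x.shape[0])
        i0, i1 = self._nb0[sel], self._nb1[sel]
        if len(i0) == 0:
            return np.zeros(x.shape[0])
        _, r = self._pair_distances(x, i0, i1)
        sr6 = (c.lj_sigma / r) ** 6
        dedr = 4.0 * c.lj_epsilon * (-12.0 * sr6 * sr6 + 6.0 * sr6) / r
        self._accumulate_pairs(x, i0, i1, dedr, forces)
        return 4.0 * c.lj_epsilon * np.sum(sr6 * sr6 - sr6, axis=1)

    def _coulomb_term(self, x, qq, sel, forces):
        c = self.config
        if not c.use_coulomb:
            return np.zeros(x.shape[0])
        i0, i1 = self._nb0[sel], self._nb1[sel]
        if len(i0) == 0:
            return np.zeros(x.shape[0])
        _, r = self._pair_distances(x, i0, i1)
        pref = COULOMB_KJ_MOL_ANGSTROM * qq[sel]
        self._accumulate_pairs(x, i0, i1, -pref / r**2, forces)
        return np.sum(pref / r, axis=1)

    def _restraints_term(self, x, forces):
        c = self.config
        energy = np.zeros(x.shape[0])
        if c.tether_k > 0.0:
            disp = x - self.reference
            energy += 0.5 * c.tether_k * np.sum(disp * disp, axis=(1, 2))
            forces -= c.tether_k * disp
        if c.environment == "protein":
            center = self.reference[self.qm].mean(axis=0)
            disp = x[:, self.qm] - center
            energy += 0.5 * c.protein_confine_k * np.sum(disp * disp, axis=(1, 2))
            forces[:, self.qm] -= c.protein_confine_k * disp
        return energy

    def _tier0(self, x):
        energy = np.zeros(x.shape[0])
        forces = np.zeros_like(x)
        all_b = np.ones(len(self._b0), dtype=bool)
        all_a = np.ones(len(self.angles), dtype=bool) if self.angles else None
        all_nb = np.ones(len(self._nb0), dtype=bool)
        energy += self._bonds_term(x, all_b, forces)
        if self.angles:
            energy += self._angles_term(x, all_a, forces)
        energy += self._lj_term(x, all_nb, forces)
        energy += self._coulomb_term(x, self._qq_nb, all_nb, forces)
        energy += self._restraints_term(x, forces)
        return energy, forces

    def _tier1_correction(self, x):
        """Morse-minus-harmonic on QM bonds plus QM charge scaling."""
        c = self.config
        energy = np.zeros(x.shape[0])
        forces = np.zeros_like(x)
        if self.qm_bonds:
            _, r = self._pair_distances(x, self._qb0, self._qb1)
            dr = r - c.r0
            ex = np.exp(-c.morse_a * dr)
            morse = c.morse_depth * (1.0 - ex) ** 2
            dmorse = 2.0 * c.morse_depth * (1.0 - ex) * c.morse_a * ex
            energy += c.tier1_scale * np.sum(morse - 0.5 * c.k_bond * dr * dr, axis=1)
            self._accumulate_pairs(
                x, self._qb0, self._qb1, c.tier1_scale * (dmorse - c.k_bond * dr), forces
            )
        if c.use_coulomb and c.qm_charge_scale != 1.0:
            _, r = self._pair_distances(x, self._nb0, self._nb1)
            pref = COULOMB_KJ_MOL_ANGSTROM * self._dqq_nb
            energy += np.sum(pref / r, axis=1)
            self._accumulate_pairs(x, self._nb0, self._nb1, -pref / r**2, forces)
        return energy, forces

    def _tier2_correction(self, x):
        """Bounded local term on core internal distances (A sin(w (r - r0)))."""
        c = self.config
        energy = np.zeros(x.shape[0])
        forces = np.zeros_like(x)
        _, r = self._pair_distances(x, self._c0, self._c1)
        arg = c.tier2_omega * (r - self._core_r0)
        energy += c.tier2_amplitude * np.sum(np.sin(arg), axis=1)
        self._accumulate_pairs(
            x, self._c0, self._c1, c.tier2_amplitude * c.tier2_omega * np.cos(arg), forces
        )
        return energy, forces

    # -- ledger partition ----------------------------------------------------
    #
    # Every tier surface splits exactly into four classical/learnable pieces:
    #   tier_k = E_MM + E_LJ^int + pair_electrostatics + ML_part(tier_k)
    # E_MM collects all terms not touching the QM set plus cross bonded terms
    # and the external restraints; E_LJ^int the QM-MM Lennard-Jones pairs;
    # the pair term the QM-MM Coulomb sum at the unscaled force-field
    # charges.  The ML part is everything the tiers actually change: the
    # QM-internal interactions plus, at tier >= 1, the difference between
    # polarized and unpolarized electrostatics (the Eq-14-style composite).

    def mm_component_batch(self, x):
        """Classical terms untouched by the tiers (evaluated at inference)."""
        x = np.asarray(x, dtype=float)
        forces = np.zeros_like(x)
        energy = self._bonds_term(x, self._bond_class == 1, forces)
        if self.angles:
            energy += self._angles_term(x, ~self._angle_qm, forces)
        energy += self._lj_term(x, self._nb_class == 1, forces)
        energy += self._coulomb_term(x, self._qq_nb, self._nb_class == 1, forces)
        energy += self._restraints_term(x, forces)
        return energy, forces

    def lj_int_component_batch(self, x):
        """QM-MM Lennard-Jones interaction (classical, tier-independent)."""
        x = np.asarray(x, dtype=float)
        forces = np.zeros_like(x)
        energy = self._lj_term(x, self._nb_class == 2, forces)
        return energy, forces

    def pair_component_batch(self, x):
        """QM-MM Coulomb sum at the unscaled force-field charges."""
        x = np.asarray(x, dtype=float)
        forces = np.zeros_like(x)
        energy = self._coulomb_term(x, self._qq_nb, self._nb_class == 2, forces)
        return energy, forces

    def qm_internal_tier0_batch(self, x):
        """Tier-0 interactions entirely inside the QM set."""
        x = np.asarray(x, dtype=float)
        forces = np.zeros_like(x)
        energy = self._bonds_term(x, self._bond_class == 0, forces)
        if self.angles:
            energy += self._angles_term(x, self._angle_qm, forces)
        energy += self._lj_term(x, self._nb_class == 0, forces)
        energy += self._coulomb_term(x, self._qq_nb, self._nb_class == 0, forces)
        return energy, forces

    def ml_component_batch(self, x, tier: int):
        """The learnable part of the tier surface (QM energy analog).

        QM-internal tier-0 terms plus every tier correction; at tier >= 1 the
        polarization-like charge rescaling contributes the difference between
        embedded and plain QM-MM electrostatics, which belongs to the learned
        part exactly as in the two-tier energy ledger.
        """
        x = np.asarray(x, dtype=float)
        energy, forces = self.qm_internal_tier0_batch(x)
        if tier >= 1:
            e, f = self._tier1_correction(x)
            energy += e
            forces += f
        if tier >= 2:
            e, f = self._tier2_correction(x)
            energy += e
            forces += f
        return energy, forces

    # -- public surface API --------------------------------------------------

    def energy_forces_batch(self, x: np.ndarray, tier: int):
        """Energies (T,) and forces (T, n, 3) of the cumulative tier surface."""
        x = np.asarray(x, dtype=float)
        energy, forces = self._tier0(x)
        if tier >= 1:
            e, f = self._tier1_correction(x)
            energy += e
            forces += f
        if tier >= 2:
            e, f = self._tier2_correction(x)
            energy += e
            forces += f
        return energy, forces

    def energy_forces(self, x: np.ndarray, tier: int):
        """Energy (kJ/mol) and forces (kJ/mol/A) of one structure."""
        e, f = self.energy_forces_batch(np.asarray(x, dtype=float)[None], tier)
        return float(e[0]), f[0]

    def energy(self, x, tier):
        return self.energy_forces(x, tier)[0]

    def surface(self, tier: int) -> "TierSurface":
        return TierSurface(self, tier)


@dataclass
class TierSurface:
    """Adapter exposing one tier as a standalone potential surface."""

    pes: ToyPES
    tier: int

    def energy_forces(self, x):
        return self.pes.energy_forces(x, self.tier)

    def energy_forces_batch(self, x):
        return self.pes.energy_forces_batch(x, self.tier)


# ---------------------------------------------------------------------------
# Conformer sampling
# ---------------------------------------------------------------------------


def _sample_langevin(pes, tier, x0, n_steps, dt, friction, kT, rng, ceiling):
    """BAOAB Langevin integrator at unit mass; yields positions each step."""
    x = x0.copy()
    _, f = pes.energy_forces(x, tier)
    v = rng.standard_normal(x.shape) * np.sqrt(kT)
    c1 = np.exp(-friction * dt)
    c2 = np.sqrt((1.0 - c1 * c1) * kT)
    for _ in range(n_steps):
        v += 0.5 * dt * f
        x += 0.5 * dt * v
        v = c1 * v + c2 * rng.standard_normal(x.shape)
        x += 0.5 * dt * v
        e, f = pes.energy_forces(x, tier)
        v += 0.5 * dt * f
        if not np.isfinite(e) or e > ceiling:
            raise RuntimeError(
                f"toy sampler diverged: energy {e:.3e} above ceiling {ceiling:.3e}"
            )
        yield x


def _sample_metropolis(pes, tier, x0, n_steps, step, kT, rng, ceiling):
    x = x0.copy()
    e, _ = pes.energy_forces(x, tier)
    for _ in range(n_steps):
        prop = x + step * rng.standard_normal(x.shape)
        e_new, _ = pes.energy_forces(prop, tier)
        if e_new > ceiling:
            raise RuntimeError(
                f"toy sampler diverged: energy {e_new:.3e} above ceiling {ceiling:.3e}"
            )
        if np.log(rng.random()) < -(e_new - e) / kT:
            x, e = prop, e_new
        yield x


def gen_conformers(
    config: ToyPESConfig,
    n: int,
    sampler: str = "langevin",
    seed: int | None = None,
    burn_in: int = 1000,
    stride: int = 20,
    dt: float = 0.01,
    friction: float = 2.0,
    step_size: float = 0.03,
    include_tier2_forces: bool = False,
) -> list[Conformer]:
    """Sample labeled conformers from the tier-0 ("MM") Boltzmann ensemble.

    Each conformer carries energies at all three tiers and analytic forces at
    tiers 0 and 1.  Tier-2 forces are withheld by default (the higher-tier
    surface provides energies only); ``include_tier2_forces=True`` overrides
    this for force-training comparison experiments.
    """
    pes = ToyPES(config)
    rng = np.random.default_rng(config.seed if seed is None else seed)
    kT = config.kT
    x0 = pes.reference + 0.02 * rng.standard_normal(pes.reference.shape)
    if sampler == "langevin":
        it = _sample_langevin(
            pes, 0, x0, burn_in + n * stride, dt, friction, kT, rng, config.energy_ceiling
        )
    elif sampler == "metropolis":
        it = _sample_metropolis(
            pes, 0, x0, burn_in + n * stride, step_size, kT, rng, config.energy_ceiling
        )
    else:
        raise ValueError(f"unknown sampler {sampler!r}")

    conformers = []
    for k, x in enumerate(it):
        if k < burn_in or (k - burn_in) % stride:
            continue
        e0, f0 = pes.energy_forces(x, 0)
        e1, f1 = pes.energy_forces(x, 1)
        e2, f2 = pes.energy_forces(x, 2)
        forces = {0: f0, 1: f1}
        if include_tier2_forces:
            forces[2] = f2
        conformers.append(
            Conformer(
                elements=list(config.elements),
                coordinates=x.copy(),
                region=pes.region.copy(),
                energies={0: e0, 1: e1, 2: e2},
                forces=forces,
            )
        )
        if len(conformers) == n:
            break
    return conformers


def augment_conformers(
    config: ToyPESConfig,
    conformers,
    n: int,
    seed: int = 0,
    sigma_range: tuple = (0.05, 0.5),
    energy_cap: float = 150.0,
    include_tier2_forces: bool = False,
) -> list[Conformer]:
    """Active-learning-style augmentation: perturbed QM geometries.

    Equilibrium sampling alone never visits stretched or compressed QM bonds,
    so a potential trained on it has no repulsive/dissociative walls and
    dynamics run *on* the learned surface can escape the physical region.
    This generator emulates the structures an active-learning loop would
    add: QM atoms of randomly chosen base conformers are displaced by
    Gaussian noise of per-structure amplitude drawn from ``sigma_range``
    (angstrom); candidates whose mid-tier energy rises more than
    ``energy_cap`` (kJ/mol) above the base median are rejected so the
    augmented set stays inside the median-window structure filter.
    """
    pes = ToyPES(config)
    rng = np.random.default_rng(seed)
    base_e1 = np.median([c.energies[1] for c in conformers])
    qm = pes.qm
    # stratified acceptance: fill energy bands of 25 kJ/mol uniformly up to
    # the cap, so the repulsive wall is taught at full height rather than
    # only where random perturbations happen to land
    band_width = 25.0
    n_bands = max(1, int(np.ceil(energy_cap / band_width)))
    quota = int(np.ceil(n / n_bands))
    counts = np.zeros(n_bands, dtype=int)
    out: list[Conformer] = []
    attempts = 0
    while len(out) < n and attempts < 200 * n:
        attempts += 1
        c = conformers[rng.integers(0, len(conformers))]
        x = c.coordinates.copy()
        sigma = rng.uniform(*sigma_range)
        x[qm] += sigma * rng.standard_normal((len(qm), 3))
        e1 = pes.energy(x, 1)
        rise = e1 - base_e1
        if not np.isfinite(e1) or rise > energy_cap:
            continue
        band = min(int(max(rise, 0.0) / band_width), n_bands - 1)
        if counts[band] >= quota:
            continue
        counts[band] += 1
        e0, f0 = pes.energy_forces(x, 0)
        e2, f2 = pes.energy_forces(x, 2)
        _, f1 = pes.energy_forces(x, 1)
        forces = {0: f0, 1: f1}
        if include_tier2_forces:
            forces[2] = f2
        out.append(
            Conformer(
                elements=list(config.elements),
                coordinates=x,
                region=pes.region.copy(),
                energies={0: e0, 1: e1, 2: e2},
                forces=forces,
            )
        )
    if len(out) < n:
        warnings.warn(
            f"augmentation produced only {len(out)} of {n} requested structures"
        )
    return out


@dataclass
class TierGapStatistics:
    mean_10: float
    sigma_10: float
    mean_21: float
    sigma_21: float
    histograms: dict

    def as_dict(self) -> dict:
        return {
            "mean_tier1_minus_tier0": self.mean_10,
            "sigma_tier1_minus_tier0": self.sigma_10,
            "mean_tier2_minus_tier1": self.mean_21,
            "sigma_tier2_minus_tier1": self.sigma_21,
        }


def tier_gap_statistics(conformers, bins: int = 40) -> TierGapStatistics:
    """Sample moments and histograms of the inter-tier energy differences."""
    for tier in (0, 1, 2):
        if any(tier not in c.energies for c in conformers):
            raise ValueError(f"missing tier-{tier} energy labels")
    e = np.array([[c.energies[t] for t in (0, 1, 2)] for c in conformers])
    d10 = e[:, 1] - e[:, 0]
    d21 = e[:, 2] - e[:, 1]
    return TierGapStatistics(
        mean_10=float(d10.mean()),
        sigma_10=float(d10.std()),
        mean_21=float(d21.mean()),
        sigma_21=float(d21.std()),
        histograms={
            "tier1_minus_tier0": np.histogram(d10, bins=bins),
            "tier2_minus_tier1": np.histogram(d21, bins=bins),
        },
    )


def calibrate_tier2(
    config: ToyPESConfig, target_sigma: float, n: int = 200, seed: int = 1234
) -> ToyPESConfig:
    """Scale the tier-2 amplitude so sigma(tier2 - tier1) hits ``target_sigma``.

    The tier-2 correction is linear in its amplitude and the sampling ensemble
    (tier 0) does not depend on it, so one measurement fixes the scale.
    """
    probe = replace(config, tier2_amplitude=1.0)
    stats = tier_gap_statistics(gen_conformers(probe, n, seed=seed))
    if stats.sigma_21 <= 0:
        raise RuntimeError("tier-2 correction has zero variance; cannot calibrate")
    return replace(config, tier2_amplitude=target_sigma / stats.sigma_21)
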