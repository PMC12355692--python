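"""End-to-end pipeline: tiered data -> trained potentials -> cycle estimate.

This module wires the pieces together the way the method is meant to be used
on the toy systems: sample conformers from the low-tier ("MM") ensemble of
each end state, apply the median-window structure filter on the mid-tier
energies, strip atomic references and pair electrostatics to form the
learnable targets, train the base ensemble on mid-tier energies and forces,
fit the element-dependent stoichiometric shifts between the tiers, transfer
learn on (energy-only) top-tier targets, reconstruct the refined total-energy
surface, and finally run bidirectional nonequilibrium switching from the
low-tier surface to the refined surface for both end states, assembling the
thermodynamic cycle with full uncertainty propagation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .free_energy import (
    CycleEstimate,
    SwitchingProtocol,
    WorkSet,
    combine_cycle,
    end_state_correction,
    neq_switch,
)
from .mlp_potential import (
    HDNNPEnsemble,
    TrainConfig,
    continue_training,
    train_base,
    transfer_learn,
)
from .multilevel_energy import (
    ChargeAssignment,
    ShiftTable,
    element_counts,
    fit_shifts,
    filter_by_median_window,
    pair_electrostatics,
)
from .synthetic_data import ToyPES, ToyPESConfig, augment_conformers, gen_conformers
from .xyz import Conformer

__all__ = [
    "DEFAULT_ATOMIC_REFERENCE",
    "LedgerSurface",
    "EndStateModel",
    "build_end_state_model",
    "run_cycle",
]

#: Synthetic per-element atomic reference energies (kJ/mol), standing in for
#: the energy of a neutral atom at the quantum level of theory.  Large
#: negative constants, as in real electronic-structure totals: removing them
#: shrinks the absolute values the network must represent.
DEFAULT_ATOMIC_REFERENCE = {"C": -2000.0, "H": -650.0, "N": -2400.0, "O": -3100.0}


def toy_charge_assignment(pes: ToyPES, coordinates) -> ChargeAssignment:
    """QM/MM charge split of a toy conformer using the force-field charges."""
    qm = pes.qm
    mm = np.array([i for i in range(pes.config.n_atoms) if i not in set(pes.qm)])
    x = np.asarray(coordinates)
    return ChargeAssignment(
        q_qm=pes.charges[qm], q_mm=pes.charges[mm], r_qm=x[qm], r_mm=x[mm]
    )


class LedgerSurface:
    """Refined total-energy surface assembled from the ML part and the ledger.

    E(x) = E_ML(x) + E_MM(x) + E_LJ^int(x) + pair_electrostatics(x)
           + sum_m n_m (E_atomic,m + shift_m)

    Only the QM part of the energy is learned; the classical terms are
    evaluated by the force field at inference time, exactly as in the
    two/three-tier energy ledger.  Keeping the MM backbone classical is also
    what keeps switching dynamics on this surface stable: the learned network
    only ever steers the QM atoms it was trained on.
    """

    def __init__(
        self,
        ensemble: HDNNPEnsemble,
        pes: ToyPES,
        atomic_reference: dict,
        shift_table: ShiftTable | None = None,
    ):
        from .fastpath import BatchedEnsemble

        self.ensemble = ensemble
        self.pes = pes
        self.elements = list(pes.config.elements)
        self.region = pes.region
        counts = element_counts(self.elements)
        self.constant = sum(n * atomic_reference[e] for e, n in counts.items())
        if shift_table is not None:
            self.constant += shift_table.shift_sum(counts)
        self._batched = BatchedEnsemble(ensemble, self.elements)

    def energy_forces_batch(self, x):
        """Energies (T,) and forces (T, n, 3) of the assembled surface."""
        x = np.asarray(x, dtype=float)
        e_ml, f_ml = self._batched.energy_forces_batch(x)
        e_mm, f_mm = self.pes.mm_component_batch(x)
        e_lj, f_lj = self.pes.lj_int_component_batch(x)
        e_pr, f_pr = self.pes.pair_component_batch(x)
        return (
            e_ml + e_mm + e_lj + e_pr + self.constant,
            f_ml + f_mm + f_lj + f_pr,
        )

    def energy_forces(self, x):
        e, f = self.energy_forces_batch(np.asarray(x, dtype=float)[None])
        return float(e[0]), f[0]


@dataclass
class EndStateModel:
    """Everything the cycle needs for one end state."""

    config: ToyPESConfig
    pes: ToyPES
    conformers: list  # equilibrium snapshots (switching start ensemble)
    training_kept: list  # filtered training structures (shift fit + transfer)
    kept_mask: np.ndarray
    base: HDNNPEnsemble
    refined: HDNNPEnsemble
    shift_table: ShiftTable
    atomic_reference: dict
    surface: LedgerSurface
    ml_targets_tier1: np.ndarray
    ml_targets_tier2: np.ndarray


def _ml_targets(conformers, pes, atomic_reference, shift_table=None, with_forces=False):
    """Learnable targets: the QM part of the tier energy, references removed.

    Implements the ledger inversion E_ML = E_tier - E_MM - E_LJ^int
    - pair_sum - sum_m n_m (E_atomic,m [+ shift_m]); the same decomposition
    the assembled surface restores at inference time.  Mid-tier (tier-1)
    targets come with the matching analytic force components.
    """
    counts = element_counts(conformers[0].elements)
    const = sum(n * atomic_reference[e] for e, n in counts.items())
    if shift_table is not None:
        const += shift_table.shift_sum(counts)
    tier = 2 if shift_table is not None else 1
    x = np.stack([c.coordinates for c in conformers])
    e_ml, f_ml = pes.ml_component_batch(x, tier)
    targets = e_ml - const
    if with_forces:
        return targets, f_ml
    return targets


def _harvest_on_surface(
    surface, starts, pes: ToyPES, config: ToyPESConfig, rng, n_trajs=16,
    n_blocks=16, block_steps=50, energy_cap=400.0, kt_scale=1.0,
):
    """Active learning: simulate on the learned surface, label what it visits.

    Snapshots are taken along Langevin trajectories run *on* the current ML
    surface — these concentrate exactly in the regions (including any
    spurious escape channels) the next training round must cover.  Labels
    come from the tier surfaces; candidates whose mid-tier energy rises more
    than ``energy_cap`` above the sampled median are dropped.
    """
    from .free_energy import _langevin_steps

    kT = config.kT * kt_scale
    idx = rng.integers(0, len(starts), size=n_trajs)
    x = starts[idx].copy()
    v = rng.standard_normal(x.shape) * np.sqrt(kT)
    base_e1 = np.median(pes.energy_forces_batch(starts, 1)[0])
    harvested = []
    for _ in range(n_blocks):
        x, v = _langevin_steps(surface, x, v, block_steps, 0.01, 2.0, kT, rng)
        e1, f1 = pes.energy_forces_batch(x, 1)
        e0, f0 = pes.energy_forces_batch(x, 0)
        e2, _ = pes.energy_forces_batch(x, 2)
        for k in range(x.shape[0]):
            if not np.isfinite(e1[k]) or e1[k] - base_e1 > energy_cap:
                continue
            harvested.append(
                Conformer(
                    elements=list(config.elements),
                    coordinates=x[k].copy(),
                    region=pes.region.copy(),
                    energies={0: e0[k], 1: e1[k], 2: e2[k]},
                    forces={0: f0[k], 1: f1[k]},
                )
            )
    return harvested


def build_end_state_model(
    config: ToyPESConfig,
    n_conformers: int = 400,
    seed: int = 0,
    train_config: TrainConfig | None = None,
    atomic_reference: dict | None = None,
    filter_window: float = 150.0,
    augment_fraction: float = 0.6,
    active_learning_rounds: int = 2,
    al_epochs: int = 150,
) -> EndStateModel:
    """Sample, augment, train base (with active learning), fit shifts, transfer.

    The base training set combines equilibrium snapshots, perturbed-geometry
    augmentation and, in each active-learning round, structures harvested
    from dynamics on the current learned surface.  The element-shift fit and
    the energy-only transfer toward the top tier use only structures passing
    the median-window filter on the mid-tier energies.
    """
    train_config = train_config or TrainConfig()
    atomic_reference = atomic_reference or DEFAULT_ATOMIC_REFERENCE
    pes = ToyPES(config)
    conformers = gen_conformers(config, n_conformers, seed=seed)
    starts = np.stack([c.coordinates for c in conformers])
    training = list(conformers)
    if augment_fraction > 0:
        training = training + augment_conformers(
            config,
            conformers,
            int(round(augment_fraction * n_conformers)),
            seed=seed + 1000,
            energy_cap=filter_window,
        )

    # base training on mid-tier energies and forces (QM part of the ledger)
    t1, f1 = _ml_targets(training, pes, atomic_reference, with_forces=True)
    base = train_base(
        training,
        config=train_config,
        seed=seed,
        energy_targets=t1,
        force_targets=f1,
    )

    # active learning: patch the surface where its own dynamics goes; one
    # round runs hot to reach escape channels faster
    rng = np.random.default_rng(seed + 500)
    for round_idx in range(active_learning_rounds):
        al_surface = LedgerSurface(base, pes, atomic_reference)
        harvested = _harvest_on_surface(
            al_surface, starts, pes, config, rng,
            kt_scale=1.3 if round_idx % 2 else 1.0,
        )
        if not harvested:
            break
        training = training + harvested
        t1, f1 = _ml_targets(training, pes, atomic_reference, with_forces=True)
        base = continue_training(
            base, training, t1, force_targets=f1, epochs=al_epochs, seed=seed + 2
        )

    # structure filter on the mid-tier energy distribution; the filtered set
    # is what the shift fit and the transfer step see
    e1 = np.array([c.energies[1] for c in training])
    mask = filter_by_median_window(e1, filter_window)
    kept = [c for c, keep in zip(training, mask) if keep]

    # element-dependent shifts between the tiers (same stoichiometry per
    # structure -> rank-deficient design, minimum-norm solution)
    counts = element_counts(kept[0].elements)
    elements = sorted(counts)
    n_mat = np.tile([counts[e] for e in elements], (len(kept), 1))
    delta = np.array([c.energies[2] - c.energies[1] for c in kept])
    shifts = fit_shifts(n_mat, delta, elements)

    # energy-only transfer learning toward the top tier
    t2 = _ml_targets(kept, pes, atomic_reference, shifts)
    refined = transfer_learn(
        base, kept, t2, seed=seed + 1, shift_table=shifts.shifts
    )
    surface = LedgerSurface(refined, pes, atomic_reference, shifts)
    return EndStateModel(
        config=config,
        pes=pes,
        conformers=conformers,
        training_kept=kept,
        kept_mask=mask,
        base=base,
        refined=refined,
        shift_table=shifts,
        atomic_reference=atomic_reference,
        surface=surface,
        ml_targets_tier1=_ml_targets(kept, pes, atomic_reference),
        ml_targets_tier2=t2,
    )


def run_cycle(
    model_complex: EndStateModel,
    model_solvent: EndStateModel,
    dg_mm_bind: float,
    protocol: SwitchingProtocol,
) -> tuple[CycleEstimate, WorkSet, WorkSet]:
    """Switch both end states from the low tier to the refined surface and
    assemble the binding free energy with full uncertainty propagation."""
    estimates = {}
    worksets = {}
    for name, model, seed_off in (
        ("complex", model_complex, 0),
        ("solvent", model_solvent, 1),
    ):
        starts = np.stack([c.coordinates for c in model.conformers])
        proto = replace(protocol, seed=protocol.seed + seed_off)
        ws = neq_switch(
            starts, model.pes.surface(0), model.surface, proto, label=name
        )
        corr, se = end_state_correction(ws, protocol.temperature)
        estimates[name] = (corr, se)
        worksets[name] = ws
    (corr_p, se_p), (corr_s, se_s) = estimates["complex"], estimates["solvent"]
    cycle = combine_cycle(
        dg_mm_bind, corr_p, corr_s, dg_mbar_complex=se_p, dg_mbar_solvent=se_s
    )
    return cycle, worksets["complex"], worksets["solvent"]
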