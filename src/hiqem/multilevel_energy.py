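"""The multilevel energy ledger connecting ML targets to physical totals.

A two-tier (QM/MM-like) total energy is assembled from the learned part, the
classical terms, the explicit QM-MM pair electrostatics and per-element
atomic reference energies; the three-tier total additionally carries
element-dependent mean shifts obtained from a stoichiometric least-squares
fit of the inter-tier energy differences.  Every operation here is exact
bookkeeping — the identities relating the totals, the learned parts and the
shifts hold to machine precision by construction and are enforced in tests.

Units: kJ/mol, angstrom, elementary charge.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .constants import COULOMB_KJ_MOL_ANGSTROM

__all__ = [
    "ChargeAssignment",
    "ShiftTable",
    "EnergyBreakdown",
    "pair_electrostatics",
    "ml_target_from_qmmm",
    "assemble_qmmm",
    "assemble_qmqmmm",
    "fit_shifts",
    "filter_by_median_window",
    "atomic_reference_sum",
    "export_ledger_csv",
]


@dataclass
class ChargeAssignment:
    """Fixed point charges of the QM atoms and of the (represented) MM atoms."""

    q_qm: np.ndarray  # (n_Q,) e
    q_mm: np.ndarray  # (n_E,) e
    r_qm: np.ndarray  # (n_Q, 3) angstrom
    r_mm: np.ndarray  # (n_E, 3) angstrom


def pair_electrostatics(charges: ChargeAssignment) -> float:
    """Coulomb sum over all QM-MM pairs: sum_I sum_A k q_I q_A / |R_I - R_A|.

    The Coulomb constant k = 1389.3545755023301 kJ mol^-1 angstrom e^-2
    (CODATA).  All pairs are included (no cutoff).
    """
    if len(charges.q_qm) == 0 or len(charges.q_mm) == 0:
        return 0.0
    d = np.linalg.norm(charges.r_qm[:, None, :] - charges.r_mm[None, :, :], axis=-1)
    if np.any(d <= 0.0):
        raise ValueError("coincident QM-MM atom pair")
    return float(
        COULOMB_KJ_MOL_ANGSTROM * np.sum(np.outer(charges.q_qm, charges.q_mm) / d)
    )


def pair_electrostatics_forces(charges: ChargeAssignment):
    """Pair Coulomb energy plus forces on the QM and MM atoms.

    Returns ``(energy, f_qm, f_mm)`` with forces in kJ/mol/angstrom; used when
    the assembled ML/MM surface must provide gradients (the pair term is
    evaluated classically at inference time).
    """
    if len(charges.q_qm) == 0 or len(charges.q_mm) == 0:
        z = np.zeros((0, 3))
        return 0.0, z, z
    diff = charges.r_qm[:, None, :] - charges.r_mm[None, :, :]
    d = np.linalg.norm(diff, axis=-1)
    if np.any(d <= 0.0):
        raise ValueError("coincident QM-MM atom pair")
    qq = COULOMB_KJ_MOL_ANGSTROM * np.outer(charges.q_qm, charges.q_mm)
    energy = float(np.sum(qq / d))
    # dE/dR_I = -qq * diff / d^3 summed over A; force = -dE/dR
    grad_pairs = -qq[:, :, None] * diff / d[:, :, None] ** 3
    f_qm = -grad_pairs.sum(axis=1)
    f_mm = grad_pairs.sum(axis=0)
    return energy, f_qm, f_mm


def ml_target_from_qmmm(e_qm: float, e_elec_int: float, pair_sum: float) -> float:
    """Learned part of the two-tier energy: E_ML = E_QM + E_elec^int - pair sum.

    The explicit point-charge pair term is removed because it is evaluated
    classically at inference time; the ML part keeps only the quantum energy
    and the difference between embedded and classical QM-MM electrostatics.
    """
    return e_qm + e_elec_int - pair_sum


def atomic_reference_sum(element_counts: dict, reference: dict) -> float:
    """sum_m n_m E_atomic,m; raises naming any element without an entry."""
    total = 0.0
    for elem, n in element_counts.items():
        if elem not in reference:
            raise KeyError(f"no atomic reference energy for element {elem!r}")
        total += n * reference[elem]
    return float(total)


@dataclass
class ShiftTable:
    """Element-dependent inter-tier mean shifts with fit diagnostics."""

    shifts: dict  # element -> kJ/mol
    residual_rms: float
    rank: int
    n_structures: int
    rank_deficient: bool
    singular_values: np.ndarray = field(default_factory=lambda: np.array([]))

    def shift_sum(self, element_counts: dict) -> float:
        return float(sum(n * self.shifts[e] for e, n in element_counts.items()))


def fit_shifts(stoichiometry: np.ndarray, delta_e: np.ndarray, elements) -> ShiftTable:
    """Least-squares fit of inter-tier energy differences to stoichiometries.

    ``stoichiometry`` is (n_structures, n_elements) with atom counts per
    structure; ``delta_e`` the higher-minus-lower tier energies.  The
    minimum-norm solution is returned (datasets of a single compound have
    identical rows, hence a rank-1 design: the mean shift is then distributed
    over the elements and the table is flagged rank-deficient).
    """
    n_mat = np.atleast_2d(np.asarray(stoichiometry, dtype=float))
    delta_e = np.asarray(delta_e, dtype=float)
    if n_mat.shape[0] == 0 or delta_e.shape[0] == 0:
        raise ValueError("need at least one structure to fit shifts")
    if n_mat.shape[0] != delta_e.shape[0]:
        raise ValueError("stoichiometry rows and energy differences mismatch")
    sol, _, rank, sv = np.linalg.lstsq(n_mat, delta_e, rcond=None)
    residuals = delta_e - n_mat @ sol
    return ShiftTable(
        shifts={e: float(s) for e, s in zip(elements, sol)},
        residual_rms=float(np.sqrt(np.mean(residuals**2))),
        rank=int(rank),
        n_structures=n_mat.shape[0],
        rank_deficient=bool(rank < n_mat.shape[1]),
        singular_values=sv,
    )


@dataclass
class EnergyBreakdown:
    """Per-structure energy ledger; totals are derived, never stored."""

    e_ml_qmmm: float  # learned part of the two-tier energy
    delta_e_ml: float = 0.0  # learned three-tier-minus-two-tier correction
    e_mm: float = 0.0
    e_lj_int: float = 0.0
    pair_electrostatics: float = 0.0
    element_counts: dict = field(default_factory=dict)
    atomic_reference: dict = field(default_factory=dict)
    shift_table: ShiftTable | None = None

    @property
    def atomic_reference_sum(self) -> float:
        return atomic_reference_sum(self.element_counts, self.atomic_reference)

    @property
    def shift_sum(self) -> float:
        if self.shift_table is None:
            return 0.0
        return self.shift_table.shift_sum(self.element_counts)

    @property
    def e_qmmm(self) -> float:
        """Two-tier total."""
        return (
            self.e_ml_qmmm
            + self.e_mm
            + self.e_lj_int
            + self.pair_electrostatics
            + self.atomic_reference_sum
        )

    @property
    def e_qmqmmm(self) -> float:
        """Three-tier total: two-tier pieces plus learned correction and shifts."""
        return self.e_qmmm + self.delta_e_ml + self.shift_sum

    @property
    def delta_qmqmmm_qmmm(self) -> float:
        return self.e_qmqmmm - self.e_qmmm

    def to_dict(self) -> dict:
        return {
            "e_ml_qmmm": self.e_ml_qmmm,
            "delta_e_ml": self.delta_e_ml,
            "e_mm": self.e_mm,
            "e_lj_int": self.e_lj_int,
            "pair_electrostatics": self.pair_electrostatics,
            "atomic_reference_sum": self.atomic_reference_sum,
            "shift_sum": self.shift_sum,
            "e_qmmm": self.e_qmmm,
            "e_qmqmmm": self.e_qmqmmm,
            "delta_qmqmmm_qmmm": self.delta_qmqmmm_qmmm,
        }


def assemble_qmmm(
    e_ml: float,
    e_mm: float,
    e_lj_int: float,
    pair_sum: float,
    element_counts: dict,
    atomic_reference: dict,
) -> float:
    """Two-tier total energy from its ledger pieces."""
    return (
        e_ml
        + e_mm
        + e_lj_int
        + pair_sum
        + atomic_reference_sum(element_counts, atomic_reference)
    )


def assemble_qmqmmm(
    e_ml: float,
    delta_e_ml: float,
    e_mm: float,
    e_lj_int: float,
    pair_sum: float,
    element_counts: dict,
    atomic_reference: dict,
    shift_table: ShiftTable,
) -> float:
    """Three-tier total: adds the learned correction and the element shifts."""
    base = assemble_qmmm(e_ml, e_mm, e_lj_int, pair_sum, element_counts, atomic_reference)
    return base + delta_e_ml + shift_table.shift_sum(element_counts)


def element_counts(elements) -> dict:
    return dict(Counter(elements))


def export_ledger_csv(breakdowns, path, mask=None) -> None:
    """Tabular export of per-structure ledger records (plus a kept flag)."""
    import pandas as pd

    rows = []
    for k, bd in enumerate(breakdowns):
        row = bd.to_dict()
        row["structure"] = k
        if mask is not None:
            row["kept"] = bool(mask[k])
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def filter_by_median_window(energies, window: float = 150.0) -> np.ndarray:
    """Keep structures within ``window`` of the median energy (inclusive).

    The median of an even-count list is the midpoint of the central pair.
    Returns a boolean mask aligned with the input.
    """
    e = np.asarray(energies, dtype=float)
    if e.size == 0:
        raise ValueError("empty energy list")
    med = float(np.median(e))
    return np.abs(e - med) <= window
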