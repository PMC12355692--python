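"""Model electronic systems held as explicit integral tensors.

A :class:`ModelSystem` is the integral-level description of a small closed-shell
electronic system: a one-electron matrix ``h_core`` (kinetic energy plus the
external potential of the nuclei and of any embedding point charges), a rank-4
two-electron tensor ``g_eri`` in chemists' notation ``(pq|rs)``, an overlap
matrix, a nuclear-repulsion scalar and optional embedding point charges.  All
electronic quantities are in hartree; point-charge positions are in bohr.

The container is deliberately basis-set agnostic: any SPD overlap and 8-fold
symmetric interaction tensor define a valid system, which is what lets the
embedding machinery be exercised exhaustively on seeded model Hamiltonians.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import h5py
import numpy as np

__all__ = ["ModelSystem", "XCModel", "save_system", "load_system"]


@dataclass
class ModelSystem:
    """Integral-level description of a toy closed-shell electronic system."""

    atom_labels: list[str]
    atom_of_basis: np.ndarray  # basis index -> atom index
    n_electrons: int
    h_core: np.ndarray
    g_eri: np.ndarray
    overlap: np.ndarray
    e_nuclear: float = 0.0
    point_charges: list[tuple[float, np.ndarray]] = field(default_factory=list)

    @property
    def n_basis(self) -> int:
        return self.h_core.shape[0]

    @property
    def n_atoms(self) -> int:
        return len(self.atom_labels)

    def basis_on_atoms(self, atoms) -> np.ndarray:
        """Indices of basis functions centred on any atom in ``atoms``."""
        atoms = set(int(a) for a in atoms)
        return np.array(
            [mu for mu in range(self.n_basis) if int(self.atom_of_basis[mu]) in atoms],
            dtype=int,
        )

    def validate(self, tol: float = 1e-10) -> None:
        n = self.n_basis
        if self.n_electrons % 2 != 0:
            raise ValueError("only closed-shell systems supported: n_electrons must be even")
        if self.n_electrons < 0 or self.n_electrons > 2 * n:
            raise ValueError("n_electrons outside [0, 2 * n_basis]")
        if self.atom_of_basis.shape != (n,):
            raise ValueError("atom_of_basis must map every basis function")
        if not np.allclose(self.h_core, self.h_core.T, atol=tol):
            raise ValueError("h_core must be symmetric")
        if not np.allclose(self.overlap, self.overlap.T, atol=tol):
            raise ValueError("overlap must be symmetric")
        w = np.linalg.eigvalsh(self.overlap)
        if w.min() <= 0:
            raise ValueError(f"overlap not positive definite (min eigenvalue {w.min():.3e})")
        g = self.g_eri
        if g.shape != (n, n, n, n):
            raise ValueError("g_eri shape mismatch")
        for perm in [(1, 0, 2, 3), (0, 1, 3, 2), (2, 3, 0, 1)]:
            if not np.allclose(g, g.transpose(perm), atol=tol):
                raise ValueError("g_eri lacks 8-fold permutational symmetry")


@dataclass
class XCModel:
    """Exchange-correlation model for the mean-field reference.

    ``hf``
        Hartree-Fock: the density-functional part is identically zero
        (``exc`` and ``vxc`` return 0); exchange is handled as the exact
        contraction of ``g_eri`` wherever a set-wise exchange energy is
        required.

    ``toy-local``
        A grid-free local model ``E_xc[D] = -strength * sum_p D_pp**exponent``
        on the basis-density diagonal, with the matching diagonal derivative
        potential.  It provides a nonzero nonadditive XC coupling between
        orbital sets without quadrature machinery.
    """

    name: str = "hf"
    strength: float = 0.2
    exponent: float = 4.0 / 3.0

    def __post_init__(self):
        if self.name not in ("hf", "toy-local"):
            raise ValueError(f"unknown XC model {self.name!r}")

    @property
    def is_hf(self) -> bool:
        return self.name == "hf"

    def exc(self, density: np.ndarray) -> float:
        """Density-functional XC energy for a (set) density matrix."""
        if self.is_hf:
            return 0.0
        d = np.clip(np.diag(density), 0.0, None)
        return -self.strength * float(np.sum(d**self.exponent))

    def vxc(self, density: np.ndarray) -> np.ndarray:
        """XC potential dE_xc/dD; diagonal for the toy-local model."""
        if self.is_hf:
            return np.zeros_like(density)
        d = np.clip(np.diag(density), 0.0, None)
        return np.diag(-self.strength * self.exponent * d ** (self.exponent - 1.0))


def save_system(system: ModelSystem, path, metadata: dict | None = None) -> None:
    """Write a system to an HDF5 integral container (bit-exact round trip)."""
    with h5py.File(path, "w") as f:
        # track_times=False keeps files bit-identical across identical writes
        def ds(name, data):
            f.create_dataset(name, data=data, track_times=False)

        ds("h_core", system.h_core)
        ds("g_eri", system.g_eri)
        ds("overlap", system.overlap)
        ds("atom_of_basis", system.atom_of_basis)
        ds("atom_labels", np.array(system.atom_labels, dtype=h5py.string_dtype()))
        f.attrs["e_nuclear"] = system.e_nuclear
        f.attrs["n_electrons"] = system.n_electrons
        if system.point_charges:
            ds("point_charge_values", np.array([c for c, _ in system.point_charges]))
            ds("point_charge_positions", np.array([p for _, p in system.point_charges]))
        if metadata is not None:
            f.attrs["metadata_json"] = json.dumps(metadata, sort_keys=True)


def load_system(path) -> ModelSystem:
    with h5py.File(path, "r") as f:
        charges = []
        if "point_charge_values" in f:
            for c, p in zip(f["point_charge_values"][...], f["point_charge_positions"][...]):
                charges.append((float(c), np.asarray(p)))
        return ModelSystem(
            atom_labels=[s.decode() for s in f["atom_labels"][...]],
            atom_of_basis=f["atom_of_basis"][...].astype(int),
            n_electrons=int(f.attrs["n_electrons"]),
            h_core=f["h_core"][...],
            g_eri=f["g_eri"][...],
            overlap=f["overlap"][...],
            e_nuclear=float(f.attrs["e_nuclear"]),
            point_charges=charges,
        )
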