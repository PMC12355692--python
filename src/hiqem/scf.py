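"""Restricted closed-shell mean-field reference (HF or toy-local KS).

DIIS-accelerated Roothaan iterations in a nonorthogonal basis with a
core-Hamiltonian guess.  Densities follow the closed-shell convention
``D = 2 C_occ C_occ^T`` so that ``Tr[D S] = n_electrons``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .systems import ModelSystem, XCModel

__all__ = [
    "SCFResult",
    "SCFConvergenceError",
    "run_scf",
    "coulomb_matrix",
    "exchange_matrix",
    "exact_exchange_energy",
    "mean_field_energy",
]


class SCFConvergenceError(RuntimeError):
    pass


def coulomb_matrix(g_eri: np.ndarray, density: np.ndarray) -> np.ndarray:
    """J(D)_pq = sum_rs (pq|rs) D_rs."""
    return np.einsum("pqrs,rs->pq", g_eri, density, optimize=True)


def exchange_matrix(g_eri: np.ndarray, density: np.ndarray) -> np.ndarray:
    """K(D)_pq = sum_rs (pr|qs) D_rs."""
    return np.einsum("prqs,rs->pq", g_eri, density, optimize=True)


def exact_exchange_energy(g_eri: np.ndarray, density: np.ndarray) -> float:
    """Closed-shell exact exchange -1/4 Tr[D K(D)]."""
    return -0.25 * float(np.einsum("pq,pq->", density, exchange_matrix(g_eri, density)))


def mean_field_energy(system: ModelSystem, xc: XCModel, density: np.ndarray) -> float:
    """Total mean-field energy for a given (full) density matrix."""
    e = float(np.einsum("pq,pq->", density, system.h_core))
    e += 0.5 * float(np.einsum("pq,pq->", density, coulomb_matrix(system.g_eri, density)))
    if xc.is_hf:
        e += exact_exchange_energy(system.g_eri, density)
    else:
        e += xc.exc(density)
    return e + system.e_nuclear


def _fock(system: ModelSystem, xc: XCModel, density: np.ndarray) -> np.ndarray:
    f = system.h_core + coulomb_matrix(system.g_eri, density)
    if xc.is_hf:
        f -= 0.5 * exchange_matrix(system.g_eri, density)
    else:
        f += xc.vxc(density)
    return f


@dataclass
class SCFResult:
    c_occ: np.ndarray
    c_virt: np.ndarray
    mo_energies: np.ndarray
    energy: float
    n_iterations: int
    converged: bool

    @property
    def density(self) -> np.ndarray:
        return 2.0 * self.c_occ @ self.c_occ.T

    @property
    def coefficients(self) -> np.ndarray:
        return np.hstack([self.c_occ, self.c_virt])


def run_scf(
    system: ModelSystem,
    xc: XCModel | None = None,
    tol: float = 1e-10,
    max_iterations: int = 200,
    diis_size: int = 8,
) -> SCFResult:
    """Converge the restricted mean-field problem for a model system.

    Returns orthonormal occupied/virtual coefficients (``C^T S C = 1``) and the
    stationary total energy.  Raises :class:`SCFConvergenceError`, naming the
    last energy change, if the energy is not stationary to ``tol`` within
    ``max_iterations``.
    """
    xc = xc or XCModel("hf")
    system.validate()
    n_occ = system.n_electrons // 2

    s = system.overlap
    w, v = np.linalg.eigh(s)
    x = v @ np.diag(w**-0.5) @ v.T  # symmetric orthogonalizer S^(-1/2)

    def solve(f):
        fo = x @ f @ x
        eps, c_orth = np.linalg.eigh(fo)
        return eps, x @ c_orth

    eps, c = solve(system.h_core)
    density = 2.0 * c[:, :n_occ] @ c[:, :n_occ].T
    energy = mean_field_energy(system, xc, density)

    fock_hist: list[np.ndarray] = []
    err_hist: list[np.ndarray] = []
    delta = np.inf
    for iteration in range(1, max_iterations + 1):
        f = _fock(system, xc, density)
        # DIIS error in the orthonormal basis: [F, D] commutator
        err = x @ (f @ density @ s - s @ density @ f) @ x
        fock_hist.append(f)
        err_hist.append(err)
        if len(fock_hist) > diis_size:
            fock_hist.pop(0)
            err_hist.pop(0)
        if len(fock_hist) > 1:
            m = len(fock_hist)
            b = -np.ones((m + 1, m + 1))
            b[m, m] = 0.0
            for i in range(m):
                for j in range(m):
                    b[i, j] = np.einsum("pq,pq->", err_hist[i], err_hist[j])
            rhs = np.zeros(m + 1)
            rhs[m] = -1.0
            try:
                coef = scipy.linalg.lstsq(b, rhs, lapack_driver="gelsd")[0][:m]
                f = sum(ci * fi for ci, fi in zip(coef, fock_hist))
            except scipy.linalg.LinAlgError:
                pass
        eps, c = solve(f)
        density = 2.0 * c[:, :n_occ] @ c[:, :n_occ].T
        new_energy = mean_field_energy(system, xc, density)
        delta = abs(new_energy - energy)
        energy = new_energy
        if delta < tol and float(np.max(np.abs(err))) < np.sqrt(tol):
            return SCFResult(
                c_occ=c[:, :n_occ].copy(),
                c_virt=c[:, n_occ:].copy(),
                mo_energies=eps,
                energy=energy,
                n_iterations=iteration,
                converged=True,
            )
    raise SCFConvergenceError(
        f"SCF not converged after {max_iterations} iterations; "
        f"last energy change {delta:.3e} hartree"
    )
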