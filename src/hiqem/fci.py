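"""Dense full-configuration-interaction solver for small orbital spaces.

Determinants are enumerated as alpha/beta occupation bitmasks at fixed S_z = 0
and the Hamiltonian is assembled with the Slater-Condon rules.  Integrals are
spatial-orbital matrices: ``h`` one-electron, ``g`` two-electron in chemists'
notation ``(pq|rs)``.  Intended for embedded quantum cores of a handful of
electrons; a hard cap on the determinant count protects against accidental
combinatorial blow-up.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import scipy.linalg

__all__ = ["fci_ground_state", "determinant_expectation", "FCISpaceError"]


class FCISpaceError(ValueError):
    """Raised when the requested CI space exceeds the configured cap."""


def determinant_expectation(h: np.ndarray, g: np.ndarray, occ: np.ndarray) -> float:
    """Closed-shell single-determinant expectation over occupied orbitals ``occ``.

    E = 2 sum_i h_ii + sum_ij [2 (ii|jj) - (ij|ji)] over i, j in occ.
    """
    occ = np.asarray(occ, dtype=int)
    e = 2.0 * float(np.sum(h[occ, occ]))
    for i in occ:
        for j in occ:
            e += 2.0 * g[i, i, j, j] - g[i, j, j, i]
    return e


def _phase_single(mask: int, hole: int, particle: int) -> int:
    lo, hi = (hole, particle) if hole < particle else (particle, hole)
    between = mask & (((1 << hi) - 1) ^ ((1 << (lo + 1)) - 1))
    return -1 if bin(between).count("1") % 2 else 1


def _excitation(det1: int, det2: int):
    """Holes, particles and fermionic phase connecting two bitmask determinants."""
    holes = det1 & ~det2
    parts = det2 & ~det1
    hlist = [i for i in range(holes.bit_length()) if holes >> i & 1]
    plist = [i for i in range(parts.bit_length()) if parts >> i & 1]
    phase = 1
    mask = det1
    for h, p in zip(hlist, plist):
        phase *= _phase_single(mask, h, p)
        mask = (mask & ~(1 << h)) | (1 << p)
    return hlist, plist, phase


def fci_ground_state(
    h: np.ndarray,
    g: np.ndarray,
    n_electrons: int,
    max_orbitals: int = 12,
    max_determinants: int = 20000,
) -> tuple[float, np.ndarray]:
    """Ground-state energy and CI vector for ``n_electrons`` in all orbitals of ``h``.

    Only even electron counts (S_z = 0) are supported.  Raises
    :class:`FCISpaceError` if the orbital space exceeds ``max_orbitals``
    (advising virtual-space truncation) or the determinant space exceeds
    ``max_determinants``.
    """
    m = h.shape[0]
    if n_electrons % 2 != 0:
        raise ValueError("open-shell cores are not supported (odd electron count)")
    n_a = n_electrons // 2
    if n_a > m:
        raise ValueError("more electron pairs than orbitals")
    if m > max_orbitals:
        raise FCISpaceError(
            f"{m} spatial orbitals exceed the FCI cap of {max_orbitals}; "
            "truncate the virtual space (n_virtual_max) or raise the cap"
        )

    strings = [sum(1 << i for i in c) for c in combinations(range(m), n_a)]
    n_str = len(strings)
    dim = n_str * n_str
    if dim > max_determinants:
        raise FCISpaceError(
            f"CI dimension {dim} exceeds max_determinants={max_determinants}"
        )

    # spin-orbital integrals realized on the fly; dets indexed (ia * n_str + ib)
    occ_lists = [[i for i in range(m) if s >> i & 1] for s in strings]

    def one_body(p, q):
        return h[p, q]

    ham = np.zeros((dim, dim))
    # Precompute same-spin single/double couplings between alpha strings.
    for ia, sa in enumerate(strings):
        occ_a = occ_lists[ia]
        for ib, sb in enumerate(strings):
            occ_b = occ_lists[ib]
            row = ia * n_str + ib
            # diagonal
            e = 0.0
            for i in occ_a:
                e += one_body(i, i)
            for i in occ_b:
                e += one_body(i, i)
            for i in occ_a:
                for j in occ_a:
                    e += 0.5 * (g[i, i, j, j] - g[i, j, j, i])
            for i in occ_b:
                for j in occ_b:
                    e += 0.5 * (g[i, i, j, j] - g[i, j, j, i])
            for i in occ_a:
                for j in occ_b:
                    e += g[i, i, j, j]
            ham[row, row] = e

    for ia, sa in enumerate(strings):
        occ_a = occ_lists[ia]
        for ja in range(ia + 1, n_str):
            sa2 = strings[ja]
            diff = bin(sa ^ sa2).count("1")
            if diff > 4:
                continue
            holes, parts, phase = _excitation(sa, sa2)
            if diff == 2:  # alpha single; couples all beta strings diagonally in beta
                hh, pp = holes[0], parts[0]
                common = [i for i in occ_a if i != hh]
                base = one_body(hh, pp) + sum(
                    g[hh, pp, j, j] - g[hh, j, j, pp] for j in common
                )
                for ib in range(n_str):
                    occ_b = occ_lists[ib]
                    val = phase * (base + sum(g[hh, pp, j, j] for j in occ_b))
                    r, c = ia * n_str + ib, ja * n_str + ib
                    ham[r, c] = val
                    ham[c, r] = val
            else:  # alpha double
                h1, h2 = holes
                p1, p2 = parts
                val = phase * (g[h1, p1, h2, p2] - g[h1, p2, h2, p1])
                for ib in range(n_str):
                    r, c = ia * n_str + ib, ja * n_str + ib
                    ham[r, c] = val
                    ham[c, r] = val

    # beta singles/doubles (same structure, strings identical by S_z = 0)
    for ib in range(n_str):
        sb = strings[ib]
        occ_b = occ_lists[ib]
        for jb in range(ib + 1, n_str):
            sb2 = strings[jb]
            diff = bin(sb ^ sb2).count("1")
            if diff > 4:
                continue
            holes, parts, phase = _excitation(sb, sb2)
            if diff == 2:
                hh, pp = holes[0], parts[0]
                common = [i for i in occ_b if i != hh]
                base = one_body(hh, pp) + sum(
                    g[hh, pp, j, j] - g[hh, j, j, pp] for j in common
                )
                for ia in range(n_str):
                    occ_a = occ_lists[ia]
                    val = phase * (base + sum(g[hh, pp, j, j] for j in occ_a))
                    r, c = ia * n_str + ib, ia * n_str + jb
                    ham[r, c] = val
                    ham[c, r] = val
            else:
                h1, h2 = holes
                p1, p2 = parts
                val = phase * (g[h1, p1, h2, p2] - g[h1, p2, h2, p1])
                for ia in range(n_str):
                    r, c = ia * n_str + ib, ia * n_str + jb
                    ham[r, c] = val
                    ham[c, r] = val

    # mixed alpha-beta doubles: alpha single x beta single
    for ia in range(n_str):
        sa = strings[ia]
        for ja in range(n_str):
            if ja == ia:
                continue
            if bin(sa ^ strings[ja]).count("1") != 2:
                continue
            ha, pa, phase_a = _excitation(sa, strings[ja])
            for ib in range(n_str):
                sb = strings[ib]
                for jb in range(n_str):
                    if jb == ib:
                        continue
                    if bin(sb ^ strings[jb]).count("1") != 2:
                        continue
                    hb, pb, phase_b = _excitation(sb, strings[jb])
                    r = ia * n_str + ib
                    c = ja * n_str + jb
                    if c <= r:
                        continue
                    val = phase_a * phase_b * g[ha[0], pa[0], hb[0], pb[0]]
                    ham[r, c] = val
                    ham[c, r] = val

    w, v = scipy.linalg.eigh(ham, subset_by_index=[0, 0])
    return float(w[0]), v[:, 0]
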