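"""Orbital localization, partitioning and the embedding energy decomposition."""

import itertools

import numpy as np
import pytest

from hiqem.embedding_core import (
    build_core_hamiltonian,
    core_energy,
    embedding_total,
    ll_energy,
    localization_metric,
    localize_occupied,
    mulliken_population,
    partition_orbitals,
    reference_and_partition,
    rest_energy,
)
from hiqem.fci import FCISpaceError, fci_ground_state
from hiqem.scf import coulomb_matrix, run_scf
from hiqem.synthetic_data import ModelHamiltonianSpec, gen_model_system
from hiqem.systems import ModelSystem, XCModel


def enumerate_partitions(system, n_cores_max=2):
    """All assignments of atoms into <= n_cores_max cores + environment."""
    atoms = list(range(system.n_atoms))
    seen = set()
    for labels in itertools.product(range(n_cores_max + 1), repeat=len(atoms)):
        groups = [
            [a for a, l in zip(atoms, labels) if l == k]
            for k in range(1, n_cores_max + 1)
        ]
        groups = [g for g in groups if g]
        if not groups:
            continue
        key = tuple(sorted(tuple(g) for g in groups))
        if key in seen:
            continue
        seen.add(key)
        yield groups


# ---------------------------------------------------------------------------
# Mulliken populations and localization
# ---------------------------------------------------------------------------


def test_mulliken_hand_expansion_with_overlap():
    """2-basis orbital c = (1,1)/sqrt(2+2s) at s = 0.5: population by hand.

    pop(atom 1) = c1 (S c)_1 = (1/(2+2s)) (1 + s) = 1/2 exactly.
    """
    s = 0.5
    system = ModelSystem(
        atom_labels=["A", "B"],
        atom_of_basis=np.array([0, 1]),
        n_electrons=2,
        h_core=-np.eye(2),
        g_eri=np.zeros((2, 2, 2, 2)),
        overlap=np.array([[1.0, s], [s, 1.0]]),
    )
    c = np.array([1.0, 1.0]) / np.sqrt(2 + 2 * s)
    assert mulliken_population(c, [0], system) == pytest.approx(0.5, abs=1e-12)
    assert mulliken_population(c, [0, 1], system) == pytest.approx(1.0, abs=1e-12)


def test_mulliken_identity_overlap_and_completeness(small_systems):
    system = small_systems[0]
    res = run_scf(system, XCModel("hf"))
    for i in range(res.c_occ.shape[1]):
        total = mulliken_population(res.c_occ[:, i], range(system.n_atoms), system)
        assert total == pytest.approx(1.0, abs=1e-10)


def test_mulliken_rejects_unnormalized(small_systems):
    system = small_systems[0]
    with pytest.raises(ValueError, match="not normalized"):
        mulliken_population(np.ones(system.n_basis), [0], system)


def test_localization_preserves_span_and_energy(small_systems, hf):
    """Occupied projector and the total mean-field energy are invariant."""
    from hiqem.scf import mean_field_energy

    for system in small_systems[:3]:
        res = run_scf(system, hf)
        c_loc = localize_occupied(res.c_occ, system)
        p0 = res.c_occ @ res.c_occ.T
        p1 = c_loc @ c_loc.T
        assert np.max(np.abs(p0 - p1)) < 1e-10
        d_loc = 2.0 * c_loc @ c_loc.T
        assert mean_field_energy(system, hf, d_loc) == pytest.approx(
            res.energy, abs=1e-10
        )


def test_localization_beats_random_rotations(small_systems, rng):
    """The Jacobi optimum dominates 1000 random occupied rotations."""
    system = small_systems[1]
    res = run_scf(system, XCModel("hf"))
    c_loc = localize_occupied(res.c_occ, system)
    best = localization_metric(c_loc, system)
    n_occ = res.c_occ.shape[1]
    for _ in range(1000):
        q, _ = np.linalg.qr(rng.standard_normal((n_occ, n_occ)))
        assert localization_metric(res.c_occ @ q, system) <= best + 1e-9


def test_localization_fixed_point(small_systems):
    """Re-localizing localized orbitals changes nothing (up to sign/order)."""
    system = small_systems[0]
    res = run_scf(system, XCModel("hf"))
    c1 = localize_occupied(res.c_occ, system)
    c2 = localize_occupied(c1, system)
    assert np.max(np.abs(c1 - c2)) < 1e-8


# ---------------------------------------------------------------------------
# Partitioning rules
# ---------------------------------------------------------------------------


class _FakePopSystem:
    pass


def test_partition_two_step_rule(small_systems):
    """Environment threshold is a strict >; otherwise largest core population."""
    system = small_systems[2]
    scf, part = reference_and_partition(system, [[0], [2]], XCModel("hf"))
    env_atoms = [1, 3]
    for i, label in enumerate(part.assignment):
        orb = part.c_occ[:, i]
        pop_env = mulliken_population(orb, env_atoms, system)
        pops = [mulliken_population(orb, g, system) for g in [[0], [2]]]
        if pop_env > 0.4:
            assert label == "LL"
        else:
            assert label == int(np.argmax(pops))


def test_partition_tie_breaks_to_lowest_core(hf):
    """A symmetric orbital with equal core populations goes to core 0."""
    system = ModelSystem(
        atom_labels=["A", "B"],
        atom_of_basis=np.array([0, 1]),
        n_electrons=2,
        h_core=np.array([[-1.0, -0.3], [-0.3, -1.0]]),
        g_eri=np.zeros((2, 2, 2, 2)),
        overlap=np.eye(2),
    )
    res = run_scf(system, hf)
    part = partition_orbitals(
        res.c_occ, system, [[0], [1]], c_virt=res.c_virt, env_threshold=0.4
    )
    # bonding orbital: exactly 0.5 on each atom -> lowest core index wins
    assert part.assignment == [0]


def test_partition_rejects_empty_core(small_systems):
    system = small_systems[0]
    res = run_scf(system, XCModel("hf"))
    with pytest.raises(ValueError, match="empty"):
        partition_orbitals(res.c_occ, system, [[0], []])


# ---------------------------------------------------------------------------
# Embedded Hamiltonian
# ---------------------------------------------------------------------------


def test_degenerate_partition_heff_equals_hcore(small_systems, hf):
    """One core holding every occupied orbital: v_C = v_nadd = projector = 0."""
    system = small_systems[0]
    scf = run_scf(system, hf)
    part = partition_orbitals(
        scf.c_occ, system, [list(range(system.n_atoms))], c_virt=scf.c_virt,
        env_threshold=1.1,  # nothing exceeds it; all orbitals go to the core
    )
    assert all(a == 0 for a in part.assignment)
    emb = build_core_hamiltonian(system, part, 0, hf)
    assert np.max(np.abs(emb.h_eff - system.h_core)) < 1e-10


def test_hf_nonadditive_xc_potential_is_zero(small_systems, hf):
    system = small_systems[1]
    scf, part = reference_and_partition(system, [[0]], hf)
    emb = build_core_hamiltonian(system, part, 0, hf)
    v_nadd = emb.h_eff - system.h_core  # = v_nadd + v_C + projector
    # reconstruct v_C + projector and subtract: what remains must vanish
    d_tot = part.total_density()
    d_core = part.set_density(0)
    v_c = coulomb_matrix(system.g_eri, d_tot - d_core)
    other = [
        i for i in range(part.c_occ.shape[1]) if i not in set(emb.core_occ_indices)
    ]
    dh = part.c_occ[:, other] @ part.c_occ[:, other].T
    shifted = emb.f_embedded - part.epsilon_shift * system.overlap
    proj = -(system.overlap @ dh @ shifted + shifted @ dh @ system.overlap)
    proj = 0.5 * (proj + proj.T)
    assert np.max(np.abs(v_nadd - v_c - proj)) < 1e-10


def test_coulomb_potential_reproduces_tensor_contraction(small_systems, hf):
    """<v_C applied to core density> equals the explicit g contraction."""
    system = small_systems[2]
    scf, part = reference_and_partition(system, [[0], [2]], hf)
    cores = [i for i in range(2) if len(part.occupied_of(i))]
    for i in cores:
        d_core = part.set_density(i)
        d_env = part.total_density() - d_core
        v_c = coulomb_matrix(system.g_eri, d_env)
        direct = np.einsum("pqrs,pq,rs->", system.g_eri, d_core, d_env)
        assert np.einsum("pq,pq->", d_core, v_c) == pytest.approx(direct, abs=1e-12)


def test_core_with_no_orbitals_rejected(small_systems, hf):
    system = small_systems[0]
    scf = run_scf(system, hf)
    part = partition_orbitals(
        scf.c_occ, system, [[0], [system.n_atoms - 1]], c_virt=scf.c_virt,
        env_threshold=-1.0,  # everything to LL is impossible; force empty core
    )
    # choose a core index that ended up empty, if any; otherwise construct one
    empty = [i for i in range(2) if len(part.occupied_of(i)) == 0]
    if not empty:
        part.assignment = ["LL"] * len(part.assignment)
        empty = [0]
    with pytest.raises(ValueError, match="no occupied"):
        build_core_hamiltonian(system, part, empty[0], hf)


# ---------------------------------------------------------------------------
# Core energies: determinant expectation and FCI
# ---------------------------------------------------------------------------


def test_fci_matches_analytic_two_orbital_ci(hf):
    """2 electrons in 2 orbitals: FCI equals the analytic CI eigenvalue.

    The singlet CI matrix in the determinant basis {|11>, |12>, |21>, |22>}
    is built by hand from the Slater-Condon rules and diagonalized with
    numpy only.
    """
    rng = np.random.default_rng(5)
    h = rng.standard_normal((2, 2))
    h = 0.5 * (h + h.T) - 2.0 * np.eye(2)
    a = rng.standard_normal((2, 2))
    l = a @ a.T / 2
    g = 0.4 * np.einsum("pq,rs->pqrs", l, l)
    # hand-built CI matrix over determinants (1a1b, 1a2b, 2a1b, 2a2b)
    def hd(i, j):  # diagonal: both spatial orbitals i (alpha), j (beta)
        return h[i, i] + h[j, j] + g[i, i, j, j]

    ci = np.zeros((4, 4))
    dets = [(0, 0), (0, 1), (1, 0), (1, 1)]
    for a_i, (ia, ib) in enumerate(dets):
        ci[a_i, a_i] = hd(ia, ib)
        for b_i, (ja, jb) in enumerate(dets):
            if a_i == b_i:
                continue
            na, nb = int(ia != ja), int(ib != jb)
            if na + nb == 1:  # single excitation
                if na:
                    ci[a_i, b_i] = h[ia, ja] + g[ia, ja, ib, ib]
                else:
                    ci[a_i, b_i] = h[ib, jb] + g[ib, jb, ia, ia]
            elif na + nb == 2:
                ci[a_i, b_i] = g[ia, ja, ib, jb]
    expected = np.linalg.eigvalsh(ci)[0]
    e, _ = fci_ground_state(h, g, 2)
    assert e == pytest.approx(expected, abs=1e-10)


def test_fci_noninteracting_limit():
    """g = 0: the FCI energy is twice the sum of the lowest orbital energies."""
    rng = np.random.default_rng(8)
    h = rng.standard_normal((4, 4))
    h = 0.5 * (h + h.T)
    e, _ = fci_ground_state(h, np.zeros((4, 4, 4, 4)), 4)
    eps = np.linalg.eigvalsh(h)
    assert e == pytest.approx(2 * eps[:2].sum(), abs=1e-10)


def test_fci_below_determinant_and_equal_without_virtuals(small_systems, hf):
    """Variational bound; with zero virtuals FCI collapses to the determinant."""
    system = small_systems[1]
    scf, part = reference_and_partition(system, [[0]], hf)
    cores = [i for i in range(1) if len(part.occupied_of(i))]
    for i in cores:
        emb = build_core_hamiltonian(system, part, i, hf)
        e_det = core_energy(emb, "determinant-expectation")
        e_fci = core_energy(emb, "fci")
        assert e_fci <= e_det + 1e-12
        e_fci0 = core_energy(emb, "fci", n_virtual_max=0)
        assert e_fci0 == pytest.approx(e_det, abs=1e-10)


def test_fci_space_cap_raises():
    h = -np.eye(14)
    with pytest.raises(FCISpaceError, match="truncate"):
        fci_ground_state(h, np.zeros((14,) * 4), 4)


# ---------------------------------------------------------------------------
# Energy decomposition
# ---------------------------------------------------------------------------


def test_ll_energy_empty_and_full(small_systems, hf):
    """No LL orbitals -> 0; all-LL at hf reproduces the reference energy."""
    system = small_systems[1]
    scf = run_scf(system, hf)
    c_loc = localize_occupied(scf.c_occ, system)
    all_ll = partition_orbitals(
        c_loc, system, [[0]], c_virt=scf.c_virt, env_threshold=-1.0
    )
    assert all(a == "LL" for a in all_ll.assignment)
    assert ll_energy(system, all_ll, hf) + system.e_nuclear == pytest.approx(
        scf.energy, abs=1e-10
    )
    no_ll = partition_orbitals(
        c_loc, system, [list(range(system.n_atoms))], c_virt=scf.c_virt,
        env_threshold=1.1,
    )
    assert ll_energy(system, no_ll, hf) == 0.0


def test_ll_point_charge_multipole_limit(hf):
    """A distant point charge shifts the LL energy by q Q / R (hartree/bohr)."""
    base = ModelHamiltonianSpec(
        n_atoms=2, n_basis_per_atom=1, n_electrons=2, seed=3,
        interaction_strength=0.0,
    )
    shifts = []
    for r_charge in (60.0, 120.0, 240.0):
        spec_pc = ModelHamiltonianSpec(
            **{**base.__dict__, "point_charges": [(0.5, (r_charge, 0.0, 0.0))]}
        )
        sys0 = gen_model_system(base)
        sys1 = gen_model_system(spec_pc)
        e0 = run_scf(sys0, hf).energy - sys0.e_nuclear
        e1 = run_scf(sys1, hf).energy - sys1.e_nuclear
        # electron charge Q = -n_electrons; expected shift q Q / R
        shifts.append((e1 - e0) * r_charge)
    expected = 0.5 * (-2.0)
    assert shifts[-1] == pytest.approx(expected, rel=0.05)
    # convergence toward the multipole limit as R grows
    assert abs(shifts[2] - expected) <= abs(shifts[0] - expected)


def test_rest_energy_limits(small_systems, hf):
    """Single core at hf -> 0; all-LL -> 0; two cores -> minus the inter-core
    Coulomb energy obtained by explicit tensor contraction."""
    system = small_systems[2]
    scf = run_scf(system, hf)
    c_loc = localize_occupied(scf.c_occ, system)
    one_core = partition_orbitals(
        c_loc, system, [list(range(system.n_atoms))], c_virt=scf.c_virt,
        env_threshold=1.1,
    )
    assert rest_energy(system, one_core, hf) == pytest.approx(0.0, abs=1e-12)
    all_ll = partition_orbitals(
        c_loc, system, [[0]], c_virt=scf.c_virt, env_threshold=-1.0
    )
    assert rest_energy(system, all_ll, hf) == pytest.approx(0.0, abs=1e-12)

    scf2, two_cores = reference_and_partition(system, [[0, 1], [2, 3]], hf)
    used = [i for i in range(2) if len(two_cores.occupied_of(i))]
    if len(used) == 2:
        from hiqem.scf import exact_exchange_energy

        d1 = two_cores.set_density(0)
        d2 = two_cores.set_density(1)
        inter_coulomb = np.einsum("pqrs,pq,rs->", system.g_eri, d1, d2)
        # hf mode carries exact exchange as its set-XC energy (required for
        # the exact decomposition), so the rest term is the nonadditive
        # exchange minus the double-counted inter-core Coulomb energy
        nonadd_x = (
            exact_exchange_energy(system.g_eri, d1 + d2)
            - exact_exchange_energy(system.g_eri, d1)
            - exact_exchange_energy(system.g_eri, d2)
        )
        assert rest_energy(system, two_cores, hf) == pytest.approx(
            nonadd_x - inter_coulomb, abs=1e-10
        )


def test_exact_decomposition_every_partition(small_systems, hf):
    """hf/determinant decomposition reproduces the SCF energy for every
    enumerable <= 2-core partition of every system (the exactness oracle)."""
    for system in small_systems:
        scf = run_scf(system, hf)
        c_loc = localize_occupied(scf.c_occ, system)
        for groups in enumerate_partitions(system):
            part = partition_orbitals(c_loc, system, groups, c_virt=scf.c_virt)
            res = embedding_total(system, part, hf, "determinant-expectation")
            assert res.e_qm == pytest.approx(scf.energy, abs=1e-10)


def test_level_shift_invariance(small_systems, hf):
    """e_qm at determinant level is independent of the Huzinaga shift."""
    system = small_systems[1]
    scf = run_scf(system, hf)
    c_loc = localize_occupied(scf.c_occ, system)
    energies = []
    for shift in (0.1, 1.0, 10.0):
        part = partition_orbitals(
            c_loc, system, [[0], [2]], c_virt=scf.c_virt, epsilon_shift=shift
        )
        energies.append(embedding_total(system, part, hf).e_qm)
    assert max(energies) - min(energies) < 1e-10


def test_orthonormality_preserved_through_pipeline(small_systems, hf):
    for system in small_systems[:2]:
        scf, part = reference_and_partition(system, [[0]], hf)
        c = np.hstack([part.c_occ, part.c_virt])
        dev = np.max(np.abs(c.T @ system.overlap @ c - np.eye(c.shape[1])))
        assert dev < 1e-10


def test_fci_lowers_e_qm_below_reference(small_systems, hf):
    """With FCI cores the decomposed energy drops below the mean-field
    reference: the embedding injects correlation where it is asked to."""
    system = small_systems[1]
    scf, part = reference_and_partition(system, [[0]], hf)
    res = embedding_total(system, part, hf, solver="fci")
    assert res.e_qm <= scf.energy + 1e-12


def test_toy_local_xc_decomposition_consistency(small_systems, toy_local):
    """With the toy-local functional, determinant-level decomposition equals
    the reference KS energy plus the core exact-exchange-minus-functional
    replacement (computed independently)."""
    from hiqem.scf import exact_exchange_energy

    system = small_systems[0]
    scf = run_scf(system, toy_local)
    c_loc = localize_occupied(scf.c_occ, system)
    part = partition_orbitals(c_loc, system, [[0, 1]], c_virt=scf.c_virt)
    res = embedding_total(system, part, toy_local)
    correction = 0.0
    for i in range(part.n_cores):
        if len(part.occupied_of(i)):
            d = part.set_density(i)
            correction += exact_exchange_energy(system.g_eri, d) - toy_local.exc(d)
    assert res.e_qm == pytest.approx(scf.energy + correction, abs=1e-10)
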