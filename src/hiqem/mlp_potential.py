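"""Ensemble high-dimensional neural-network potential with transfer learning.

The potential follows the high-dimensional neural-network ansatz: the energy
of a structure is the sum of per-atom contributions, each produced by a small
feedforward network selected by the atom's element and fed with
element-weighted atom-centered symmetry functions.  An ensemble of
independently initialized and split members provides the prediction (mean)
and its uncertainty (``c`` times the population standard deviation across
members, default ``c = 2``).

Base training fits energies and, by default, forces of one theory tier.
Transfer learning then refines the ensemble toward a higher tier using
(typically energy-only) labels: the input-standardization weights and the
first hidden layer are frozen bit-exactly, every other weight continues from
the persisted per-weight optimizer state, each member re-splits the new data
90/10, and all training energies enter every one of the (default 300) epochs.
Element-dependent mean shifts between tiers are expected to be removed
upstream (stoichiometric shift fit); what remains to be learned is a small,
smooth, zero-centered correction.
"""

from __future__ import annotations

import copy
import json
import pathlib
from dataclasses import dataclass, field

import numpy as np

from .descriptors import DescriptorConfig, compute_features_jacobian
from .network import (
    AdamState,
    adam_step,
    backprop,
    flatten_params,
    forward,
    init_params,
    input_gradient,
    tangent_backprop,
    tangent_forward,
)
from .xyz import Conformer

__all__ = [
    "TrainConfig",
    "FeatureSet",
    "HDNNPEnsemble",
    "RMSEStats",
    "train_base",
    "transfer_learn",
    "continue_training",
    "evaluate_rmse",
    "predict",
    "MLSurface",
    "save_ensemble",
    "load_ensemble",
]


@dataclass
class TrainConfig:
    hidden: tuple = (25, 25)
    n_members: int = 10
    epochs: int = 400
    transfer_epochs: int = 300
    learning_rate: float = 0.01
    lambda_force: float = 0.01  # balances energy and force mean-square terms
    train_fraction: float = 0.9
    uncertainty_c: float = 2.0


class FeatureSet:
    """Precomputed descriptors (and Jacobians) for a homogeneous dataset."""

    def __init__(self, conformers, config: DescriptorConfig, with_jacobian=True):
        if not conformers:
            raise ValueError("empty dataset")
        self.elements = list(conformers[0].elements)
        for c in conformers:
            if list(c.elements) != self.elements:
                raise ValueError("all conformers must share one element sequence")
        self.config = config
        self.region = conformers[0].region.copy()
        gs, js = [], []
        for c in conformers:
            g, j = compute_features_jacobian(c.elements, c.coordinates, config, with_jacobian)
            gs.append(g)
            js.append(j)
        self.G = np.stack(gs)  # (n_conf, n_atoms, d)
        self.J = np.stack(js) if with_jacobian else None
        self.element_atoms = {
            e: np.array([i for i, el in enumerate(self.elements) if el == e])
            for e in sorted(set(self.elements))
        }

    @property
    def n_conformers(self) -> int:
        return self.G.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.G.shape[1]


@dataclass
class Member:
    """One ensemble member: per-element nets plus frozen preprocessing."""

    params: dict  # element -> [(W, b), ...]
    opt: dict  # element -> AdamState
    mu: np.ndarray  # input standardization (frozen after base training)
    sigma: np.ndarray
    e_mean: float  # output standardization (frozen after base training)
    e_scale: float
    split_seed: tuple
    frozen_mask: dict | None = None
    history: list = field(default_factory=list)  # (epoch, train_rmse, test_rmse)
    train_idx: np.ndarray | None = None
    test_idx: np.ndarray | None = None

    def standardize(self, g):
        return (g - self.mu) / self.sigma

    def flat(self) -> np.ndarray:
        return np.concatenate([flatten_params(self.params[e]) for e in sorted(self.params)])


def _member_forward(member: Member, fs: FeatureSet, idx):
    """Energies (and caches) for conformers ``idx``. Returns (E, fwd_by_elem)."""
    n = len(idx)
    e_sum = np.zeros(n)
    fwds = {}
    for elem, atoms in fs.element_atoms.items():
        x = member.standardize(fs.G[idx][:, atoms, :]).reshape(-1, fs.G.shape[2])
        fwd = forward(member.params[elem], x)
        fwds[elem] = fwd
        e_sum += fwd.y.reshape(n, len(atoms)).sum(axis=1)
    return member.e_mean + member.e_scale * e_sum, fwds


def _member_grads_wrt_G(member: Member, fs: FeatureSet, idx, fwds):
    """d(E_pred)/dG for each conformer/atom, shape (n, n_atoms, d)."""
    n = len(idx)
    d = fs.G.shape[2]
    grads = np.zeros((n, fs.n_atoms, d))
    for elem, atoms in fs.element_atoms.items():
        gx = input_gradient(fwds[elem]).reshape(n, len(atoms), d)
        grads[:, atoms, :] = gx / member.sigma
    return grads * member.e_scale


def _member_predict_forces(member, fs, idx, fwds):
    grads = _member_grads_wrt_G(member, fs, idx, fwds)
    return -np.einsum("cid,cidma->cma", grads, fs.J[idx], optimize=True)


def _rmse(a, b):
    return float(np.sqrt(np.mean((np.asarray(a) - np.asarray(b)) ** 2)))


def _train_member(
    member: Member,
    fs: FeatureSet,
    energies: np.ndarray,
    forces,  # (n, n_atoms, 3) or None
    epochs: int,
    lr: float,
    lambda_force: float,
):
    """Full-batch Adam training of one member (in place)."""
    tr, te = member.train_idx, member.test_idx
    n = len(tr)
    e_tr = energies[tr]
    f_tr = forces[tr] if forces is not None else None
    for _ in range(epochs):
        e_pred, fwds = _member_forward(member, fs, tr)
        delta_e = e_pred - e_tr
        grads = {e: None for e in member.params}
        for elem, atoms in fs.element_atoms.items():
            dldy = np.repeat(delta_e * (2.0 * member.e_scale / n), len(atoms))
            g = backprop(fwds[elem], dldy)
            grads[elem] = g
        if f_tr is not None:
            d = fs.G.shape[2]
            gG = _member_grads_wrt_G(member, fs, tr, fwds)
            f_pred = -np.einsum("cid,cidma->cma", gG, fs.J[tr], optimize=True)
            dldf = (2.0 * lambda_force / f_tr.size) * (f_pred - f_tr)
            # tangent in standardized input space per atom
            s = -np.einsum("cidma,cma->cid", fs.J[tr], dldf, optimize=True)
            s *= member.e_scale / member.sigma
            for elem, atoms in fs.element_atoms.items():
                s_e = s[:, atoms, :].reshape(-1, d)
                tangent_forward(fwds[elem], s_e)
                tg = tangent_backprop(fwds[elem], np.ones(s_e.shape[0]))
                grads[elem] = [
                    (gw + tw, gb + tb)
                    for (gw, gb), (tw, tb) in zip(grads[elem], tg)
                ]
        for elem in member.params:
            adam_step(
                member.params[elem],
                grads[elem],
                member.opt[elem],
                lr=lr,
                frozen_mask=member.frozen_mask[elem] if member.frozen_mask else None,
            )
        for elem in member.opt:
            member.opt[elem].epoch += 1
        if len(te):
            e_te, _ = _member_forward(member, fs, te)
            member.history.append(
                (member.opt[next(iter(member.opt))].epoch, _rmse(e_pred, e_tr), _rmse(e_te, energies[te]))
            )
        else:
            member.history.append(
                (member.opt[next(iter(member.opt))].epoch, _rmse(e_pred, e_tr), np.nan)
            )


@dataclass
class HDNNPEnsemble:
    members: list
    descriptor_config: DescriptorConfig
    elements: list
    config: TrainConfig
    shift_table: dict | None = None  # element shift reference carried along

    @property
    def uncertainty_c(self) -> float:
        return self.config.uncertainty_c

    def member_energies(self, fs: FeatureSet, idx=None):
        idx = np.arange(fs.n_conformers) if idx is None else np.asarray(idx)
        return np.stack([_member_forward(m, fs, idx)[0] for m in self.members])

    def predict_dataset(self, fs: FeatureSet, with_forces=False):
        """Ensemble mean energy, per-structure uncertainty and (optionally) forces."""
        idx = np.arange(fs.n_conformers)
        energies = []
        forces = []
        for m in self.members:
            e, fwds = _member_forward(m, fs, idx)
            energies.append(e)
            if with_forces:
                forces.append(_member_predict_forces(m, fs, idx, fwds))
        energies = np.stack(energies)
        mean_e = energies.mean(axis=0)
        unc = self.uncertainty_c * energies.std(axis=0)  # population std
        mean_f = np.stack(forces).mean(axis=0) if with_forces else None
        return mean_e, unc, mean_f

    def copy(self) -> "HDNNPEnsemble":
        return copy.deepcopy(self)


def predict(ensemble: HDNNPEnsemble, conformer: Conformer):
    """(energy mean, forces, uncertainty) for one structure."""
    for e in conformer.elements:
        if e not in ensemble.elements:
            raise ValueError(f"element {e!r} outside the training alphabet")
    fs = FeatureSet([conformer], ensemble.descriptor_config)
    mean_e, unc, mean_f = ensemble.predict_dataset(fs, with_forces=True)
    return float(mean_e[0]), mean_f[0], float(unc[0])


def _init_member(fs: FeatureSet, config: TrainConfig, energies, seed_key, member_idx):
    rng = np.random.default_rng(list(seed_key) + [member_idx])
    n = fs.n_conformers
    perm = rng.permutation(n)
    n_train = max(1, int(round(config.train_fraction * n)))
    tr, te = np.sort(perm[:n_train]), np.sort(perm[n_train:])
    g_train = fs.G[tr].reshape(-1, fs.G.shape[2])
    mu = g_train.mean(axis=0)
    sigma = np.maximum(g_train.std(axis=0), 1e-8)
    e_mean = float(energies[tr].mean())
    e_scale = max(float(energies[tr].std()), 1e-8)
    sizes = [fs.G.shape[2], *config.hidden, 1]
    params = {e: init_params(sizes, rng) for e in fs.element_atoms}
    opt = {e: AdamState.zeros_like(params[e]) for e in fs.element_atoms}
    return Member(
        params=params,
        opt=opt,
        mu=mu,
        sigma=sigma,
        e_mean=e_mean,
        e_scale=e_scale,
        split_seed=tuple(list(seed_key) + [member_idx]),
        train_idx=tr,
        test_idx=te,
    )


def train_base(
    conformers,
    descriptor_config: DescriptorConfig | None = None,
    config: TrainConfig | None = None,
    tier: int = 1,
    seed: int = 0,
    energy_targets=None,
    force_targets=None,
    use_forces: bool = True,
) -> HDNNPEnsemble:
    """Train a fresh ensemble on one tier's energies and (by default) forces.

    ``energy_targets`` / ``force_targets`` override the labels read from the
    conformers (e.g. after atomic-reference removal by the energy ledger).
    """
    descriptor_config = descriptor_config or DescriptorConfig()
    config = config or TrainConfig()
    fs = FeatureSet(conformers, descriptor_config, with_jacobian=True)
    if energy_targets is None:
        energy_targets = np.array([c.energies[tier] for c in conformers])
    else:
        energy_targets = np.asarray(energy_targets, dtype=float)
    if use_forces:
        if force_targets is None:
            if any(tier not in c.forces for c in conformers):
                raise ValueError(
                    f"tier-{tier} force labels missing; pass use_forces=False "
                    "for energy-only training"
                )
            force_targets = np.stack([c.forces[tier] for c in conformers])
        else:
            force_targets = np.asarray(force_targets, dtype=float)
    else:
        force_targets = None

    members = []
    for k in range(config.n_members):
        member = _init_member(fs, config, energy_targets, (seed,), k)
        _train_member(
            member,
            fs,
            energy_targets,
            force_targets,
            config.epochs,
            config.learning_rate,
            config.lambda_force,
        )
        members.append(member)
    return HDNNPEnsemble(
        members=members,
        descriptor_config=descriptor_config,
        elements=sorted(set(fs.elements)),
        config=config,
    )


def continue_training(
    ensemble: HDNNPEnsemble,
    conformers,
    energy_targets,
    force_targets=None,
    epochs: int = 150,
    seed: int = 2,
) -> HDNNPEnsemble:
    """Continue base training on an extended dataset (no freezing).

    Used by active-learning rounds: the dataset grows, every weight stays
    trainable, the per-weight optimizer state carries on, and each member
    draws a fresh split of the extended data.  Standardization weights are
    kept from the original base training.  Returns a new ensemble.
    """
    energy_targets = np.asarray(energy_targets, dtype=float)
    fs = FeatureSet(
        conformers, ensemble.descriptor_config, with_jacobian=force_targets is not None
    )
    if force_targets is not None:
        force_targets = np.stack([np.asarray(f, dtype=float) for f in force_targets])
    refined = ensemble.copy()
    n = fs.n_conformers
    for k, member in enumerate(refined.members):
        rng = np.random.default_rng([seed, k, 13])
        perm = rng.permutation(n)
        n_train = max(1, int(round(ensemble.config.train_fraction * n)))
        member.train_idx = np.sort(perm[:n_train])
        member.test_idx = np.sort(perm[n_train:])
        member.frozen_mask = None
        _train_member(
            member,
            fs,
            energy_targets,
            force_targets,
            epochs,
            ensemble.config.learning_rate,
            ensemble.config.lambda_force,
        )
    return refined


def _freeze_mask(params):
    """Mask pinning the first hidden layer; all other layers trainable."""
    mask = []
    for l, (w, b) in enumerate(params):
        freeze = l == 0
        mask.append(
            (np.full(w.shape, freeze, dtype=bool), np.full(b.shape, freeze, dtype=bool))
        )
    return mask


def transfer_learn(
    ensemble: HDNNPEnsemble,
    conformers,
    energy_targets,
    epochs: int | None = None,
    train_fraction: float = 0.9,
    force_targets=None,
    seed: int = 1,
    shift_table: dict | None = None,
) -> HDNNPEnsemble:
    """Refine an ensemble toward higher-tier energy labels (transfer learning).

    Standardization weights (input and output) and the first hidden layer are
    bit-identical before and after; the per-weight optimizer state continues
    from base training.  Each member draws its own fresh 90/10 split of the
    new data.  Returns a new ensemble; the input ensemble is not modified.
    """
    energy_targets = np.asarray(energy_targets, dtype=float)
    if len(energy_targets) < 10:
        raise ValueError("transfer learning needs at least 10 conformers")
    epochs = ensemble.config.transfer_epochs if epochs is None else epochs
    fs = FeatureSet(
        conformers, ensemble.descriptor_config, with_jacobian=force_targets is not None
    )
    if force_targets is not None:
        force_targets = np.stack(
            [np.asarray(f, dtype=float) for f in force_targets]
        )
    refined = ensemble.copy()
    refined.shift_table = shift_table
    n = fs.n_conformers
    for k, member in enumerate(refined.members):
        rng = np.random.default_rng([seed, k, 7])
        perm = rng.permutation(n)
        n_train = max(1, int(round(train_fraction * n)))
        member.train_idx = np.sort(perm[:n_train])
        member.test_idx = np.sort(perm[n_train:])
        member.frozen_mask = {e: _freeze_mask(member.params[e]) for e in member.params}
        # Continue the per-weight adaptive rates (second moments, step count)
        # from base training; restart the momentum, which belongs to the old
        # objective.  A member already at its optimum therefore stays put.
        for state in member.opt.values():
            state.m = [(np.zeros_like(w), np.zeros_like(b)) for w, b in state.m]
        _train_member(
            member,
            fs,
            energy_targets,
            force_targets,
            epochs,
            ensemble.config.learning_rate,
            ensemble.config.lambda_force,
        )
    return refined


@dataclass
class RMSEStats:
    member_energy_rmse: np.ndarray
    ensemble_energy_rmse: float
    member_force_rmse_qm: np.ndarray | None = None
    member_force_rmse_mm: np.ndarray | None = None
    ensemble_force_rmse_qm: float | None = None
    ensemble_force_rmse_mm: float | None = None
    n_q: int = 0

    @property
    def member_mean(self) -> float:
        return float(self.member_energy_rmse.mean())

    @property
    def member_std(self) -> float:
        return float(self.member_energy_rmse.std())


def evaluate_rmse(
    ensemble: HDNNPEnsemble,
    conformers,
    energy_targets,
    force_targets=None,
    per_qm_atom: bool = False,
) -> RMSEStats:
    """Member-wise (mean +/- std) and ensemble RMSEs on a labeled dataset.

    ``per_qm_atom`` normalizes energy errors by the number of QM-tagged atoms.
    Force RMSEs are reported separately over the force components of QM atoms
    and of the represented-MM atoms.
    """
    if len(conformers) == 0:
        raise ValueError("empty dataset")
    energy_targets = np.asarray(energy_targets, dtype=float)
    fs = FeatureSet(conformers, ensemble.descriptor_config, force_targets is not None)
    n_q = int(np.sum(fs.region >= 1))
    norm = n_q if per_qm_atom else 1
    idx = np.arange(fs.n_conformers)

    member_e, member_fq, member_fm = [], [], []
    forces_all = []
    energies_all = []
    for m in ensemble.members:
        e, fwds = _member_forward(m, fs, idx)
        energies_all.append(e)
        member_e.append(_rmse(e / norm, energy_targets / norm))
        if force_targets is not None:
            f = _member_predict_forces(m, fs, idx, fwds)
            forces_all.append(f)
            ft = np.stack([np.asarray(x) for x in force_targets])
            qm = fs.region >= 1
            member_fq.append(_rmse(f[:, qm, :], ft[:, qm, :]))
            member_fm.append(_rmse(f[:, ~qm, :], ft[:, ~qm, :]))
    mean_e = np.stack(energies_all).mean(axis=0)
    stats = RMSEStats(
        member_energy_rmse=np.array(member_e),
        ensemble_energy_rmse=_rmse(mean_e / norm, energy_targets / norm),
        n_q=n_q,
    )
    if force_targets is not None:
        mean_f = np.stack(forces_all).mean(axis=0)
        ft = np.stack([np.asarray(x) for x in force_targets])
        qm = fs.region >= 1
        stats.member_force_rmse_qm = np.array(member_fq)
        stats.member_force_rmse_mm = np.array(member_fm)
        stats.ensemble_force_rmse_qm = _rmse(mean_f[:, qm, :], ft[:, qm, :])
        stats.ensemble_force_rmse_mm = _rmse(mean_f[:, ~qm, :], ft[:, ~qm, :])
    return stats


class MLSurface:
    """Potential-surface adapter over an ensemble for switching simulations.

    ``offset`` restores the constant ledger terms (atomic references and
    stoichiometric shifts) that were removed from the training targets, so the
    surface lives on the same absolute scale as the physical tiers.
    """

    def __init__(self, ensemble: HDNNPEnsemble, elements, region, offset: float = 0.0):
        self.ensemble = ensemble
        self.elements = list(elements)
        self.region = np.asarray(region)
        self.offset = float(offset)

    def energy_forces(self, x):
        conf = Conformer(
            elements=self.elements, coordinates=np.asarray(x, float), region=self.region
        )
        e, f, _ = predict(self.ensemble, conf)
        return e + self.offset, f


# ---------------------------------------------------------------------------
# Model archive
# ---------------------------------------------------------------------------


def save_ensemble(ensemble: HDNNPEnsemble, directory) -> None:
    """Write per-member weight files plus a JSON manifest."""
    directory = pathlib.Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    dc = ensemble.descriptor_config
    manifest = {
        "elements": ensemble.elements,
        "n_members": len(ensemble.members),
        "uncertainty_c": ensemble.config.uncertainty_c,
        "hidden": list(ensemble.config.hidden),
        "shift_table": ensemble.shift_table,
        "descriptor_config": {
            "cutoff": dc.cutoff,
            "radial_etas": list(dc.radial_etas),
            "radial_centers": list(dc.radial_centers),
            "angular_zetas": list(dc.angular_zetas),
            "angular_lambdas": list(dc.angular_lambdas),
            "angular_eta": dc.angular_eta,
            "element_weights": dc.element_weights,
        },
        "member_seeds": [list(m.split_seed) for m in ensemble.members],
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
    for k, m in enumerate(ensemble.members):
        arrays = {"mu": m.mu, "sigma": m.sigma, "e_out": np.array([m.e_mean, m.e_scale])}
        for elem in m.params:
            for l, (w, b) in enumerate(m.params[elem]):
                arrays[f"{elem}_W{l}"] = w
                arrays[f"{elem}_b{l}"] = b
        np.savez(directory / f"member_{k}.npz", **arrays)


def load_ensemble(directory) -> HDNNPEnsemble:
    directory = pathlib.Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    dcm = manifest["descriptor_config"]
    dc = DescriptorConfig(
        cutoff=dcm["cutoff"],
        radial_etas=tuple(dcm["radial_etas"]),
        radial_centers=tuple(dcm["radial_centers"]),
        angular_zetas=tuple(dcm["angular_zetas"]),
        angular_lambdas=tuple(dcm["angular_lambdas"]),
        angular_eta=dcm["angular_eta"],
        element_weights=dcm["element_weights"],
    )
    config = TrainConfig(
        hidden=tuple(manifest["hidden"]),
        n_members=manifest["n_members"],
        uncertainty_c=manifest["uncertainty_c"],
    )
    members = []
    for k in range(manifest["n_members"]):
        data = np.load(directory / f"member_{k}.npz")
        params = {}
        for elem in manifest["elements"]:
            layers = []
            l = 0
            while f"{elem}_W{l}" in data:
                layers.append((data[f"{elem}_W{l}"], data[f"{elem}_b{l}"]))
                l += 1
            if layers:
                params[elem] = layers
        members.append(
            Member(
                params=params,
                opt={e: AdamState.zeros_like(params[e]) for e in params},
                mu=data["mu"],
                sigma=data["sigma"],
                e_mean=float(data["e_out"][0]),
                e_scale=float(data["e_out"][1]),
                split_seed=tuple(manifest["member_seeds"][k]),
            )
        )
    return HDNNPEnsemble(
        members=members,
        descriptor_config=dc,
        elements=manifest["elements"],
        config=config,
        shift_table=manifest.get("shift_table"),
    )
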