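"""Element-weighted atom-centered symmetry functions with analytic gradients.

Local-environment descriptors in the Behler style, made element-embracing by
multiplying each neighbor contribution with a per-element weight so that the
descriptor dimension is independent of the element alphabet:

* radial:  G = sum_j w_j exp(-eta (r_ij - r_s)^2) fc(r_ij)
* angular: G = 2^(1-zeta) sum_{j<k} w_j w_k (1 + lambda cos theta_jik)^zeta
               exp(-eta_ang (r_ij^2 + r_ik^2 + r_jk^2)) fc(r_ij) fc(r_ik) fc(r_jk)

with the smooth cutoff fc(r) = (cos(pi r / r_c) + 1) / 2 for r < r_c (value
and first derivative vanish at the cutoff).  Descriptors are invariant to
global translation and rotation and to permutation of same-element atoms.
The Jacobian d G_i / d R_m is assembled analytically alongside the values; it
is what turns network input-gradients into atomic forces.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["DescriptorConfig", "compute_features", "compute_features_jacobian"]

MIN_DISTANCE = 0.1  # angstrom; hard floor guarding against fused atoms


@dataclass
class DescriptorConfig:
    cutoff: float = 8.0  # angstrom; wide enough to cover a ~12-atom chain
    radial_etas: tuple = (0.2, 0.6, 1.5, 4.0)
    radial_centers: tuple = (0.0, 1.5, 2.5, 4.0)  # meshgrid with etas
    angular_zetas: tuple = (1.0, 4.0)
    angular_lambdas: tuple = (1.0, -1.0)
    angular_eta: float = 0.12
    element_weights: dict = field(default_factory=lambda: {"H": 1.0, "C": 1.6, "N": 1.9, "O": 2.2})

    def __post_init__(self):
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")

    @property
    def n_features(self) -> int:
        n_rad = len(self.radial_etas) * len(self.radial_centers)
        n_ang = len(self.angular_zetas) * len(self.angular_lambdas)
        return n_rad + n_ang

    def weight(self, element: str) -> float:
        try:
            return self.element_weights[element]
        except KeyError:
            raise KeyError(f"element {element!r} missing from element_weights") from None


def _cutoff(r, rc):
    inside = r < rc
    val = np.where(inside, 0.5 * (np.cos(np.pi * r / rc) + 1.0), 0.0)
    der = np.where(inside, -0.5 * np.pi / rc * np.sin(np.pi * r / rc), 0.0)
    return val, der


def compute_features(elements, coordinates, config: DescriptorConfig) -> np.ndarray:
    """Per-atom descriptor matrix, shape (n_atoms, n_features)."""
    return compute_features_jacobian(elements, coordinates, config, with_jacobian=False)[0]


def compute_features_jacobian(
    elements, coordinates, config: DescriptorConfig, with_jacobian: bool = True
):
    """Descriptors and (optionally) their Jacobian w.r.t. all coordinates.

    Returns ``(G, J)`` with ``G`` of shape (n_atoms, n_features) and ``J`` of
    shape (n_atoms, n_features, n_atoms, 3); ``J`` is None when
    ``with_jacobian`` is False.
    """
    x = np.asarray(coordinates, dtype=float)
    n = x.shape[0]
    if n < 1:
        raise ValueError("at least one atom required")
    w = np.array([config.weight(e) for e in elements])
    rc = config.cutoff

    diff = x[:, None, :] - x[None, :, :]
    dist = np.linalg.norm(diff, axis=-1)
    off = ~np.eye(n, dtype=bool)
    if np.any(dist[off] < MIN_DISTANCE):
        raise ValueError(f"atom pair closer than {MIN_DISTANCE} angstrom")

    etas, centers = np.meshgrid(config.radial_etas, config.radial_centers, indexing="ij")
    etas = etas.ravel()
    centers = centers.ravel()
    n_rad = len(etas)
    n_ang = len(config.angular_zetas) * len(config.angular_lambdas)
    n_feat = n_rad + n_ang

    g = np.zeros((n, n_feat))
    jac = np.zeros((n, n_feat, n, 3)) if with_jacobian else None

    fc, dfc = _cutoff(dist, rc)

    # radial channels
    for i in range(n):
        for j in range(n):
            if j == i or dist[i, j] >= rc:
                continue
            r = dist[i, j]
            gauss = np.exp(-etas * (r - centers) ** 2)
            term = w[j] * gauss * fc[i, j]
            g[i, :n_rad] += term
            if with_jacobian:
                dterm_dr = w[j] * (
                    -2.0 * etas * (r - centers) * gauss * fc[i, j] + gauss * dfc[i, j]
                )
                rhat = diff[i, j] / r
                jac[i, :n_rad, i, :] += dterm_dr[:, None] * rhat[None, :]
                jac[i, :n_rad, j, :] -= dterm_dr[:, None] * rhat[None, :]

    # angular channels
    zl = [(z, l) for z in config.angular_zetas for l in config.angular_lambdas]
    eta_a = config.angular_eta
    for i in range(n):
        neigh = [j for j in range(n) if j != i and dist[i, j] < rc]
        for a_idx in range(len(neigh)):
            for b_idx in range(a_idx + 1, len(neigh)):
                j, k = neigh[a_idx], neigh[b_idx]
                if dist[j, k] >= rc:
                    continue
                u = diff[j, i]  # R_j - R_i
                v = diff[k, i]
                ru, rv, rjk = dist[i, j], dist[i, k], dist[j, k]
                cs = float(u @ v) / (ru * rv)
                expo = np.exp(-eta_a * (ru**2 + rv**2 + rjk**2))
                fcc = fc[i, j] * fc[i, k] * fc[j, k]
                base = w[j] * w[k] * expo * fcc
                for c_idx, (zeta, lam) in enumerate(zl):
                    a = 1.0 + lam * cs
                    if a <= 0.0:
                        continue
                    pref = 2.0 ** (1.0 - zeta)
                    term = pref * a**zeta * base
                    g[i, n_rad + c_idx] += term
                    if not with_jacobian:
                        continue
                    # chain rule through cos(theta) and the three distances
                    dcdu = v / (ru * rv) - cs * u / ru**2
                    dcdv = u / (ru * rv) - cs * v / rv**2
                    dT_dc = pref * zeta * a ** (zeta - 1.0) * lam * base
                    # d/d r_xy of exp * fc products (per distance factor)
                    dlog_ru = -2.0 * eta_a * ru + dfc[i, j] / fc[i, j]
                    dlog_rv = -2.0 * eta_a * rv + dfc[i, k] / fc[i, k]
                    dlog_rjk = -2.0 * eta_a * rjk + dfc[j, k] / fc[j, k]
                    uhat, vhat = u / ru, v / rv
                    jkvec = (x[k] - x[j]) / rjk
                    row = jac[i, n_rad + c_idx]
                    row[j] += dT_dc * dcdu + term * dlog_ru * uhat
                    row[k] += dT_dc * dcdv + term * dlog_rv * vhat
                    row[i] += -dT_dc * (dcdu + dcdv) - term * (
                        dlog_ru * uhat + dlog_rv * vhat
                    )
                    row[j] += -term * dlog_rjk * jkvec
                    row[k] += term * dlog_rjk * jkvec
    return g, jac
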