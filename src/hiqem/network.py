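"""Minimal feedforward machinery for per-element atomic networks.

Hidden layers use tanh; the output layer is linear with a single node.  Three
differentiation paths are provided, all batched over samples:

* ``backprop`` — gradients of a weighted sum of outputs w.r.t. parameters
  (energy-loss training),
* ``input_gradient`` — d(output)/d(input) (atomic forces at inference),
* ``tangent_forward`` / ``tangent_backprop`` — gradients w.r.t. parameters of
  ``R = s . d(output)/d(input)`` for a per-sample tangent ``s``
  (double backprop; this is what force-loss training requires).

The Adam optimizer keeps per-weight first/second moments so its state can be
carried from base training into transfer learning, and honours a frozen-mask
that pins selected parameter blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["init_params", "Forward", "AdamState", "adam_step", "flatten_params"]


def init_params(sizes, rng) -> list:
    """Xavier-initialized [(W, b), ...] for layer sizes [d_in, h1, ..., 1]."""
    params = []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        scale = np.sqrt(2.0 / (fan_in + fan_out))
        params.append(
            (scale * rng.standard_normal((fan_out, fan_in)), np.zeros(fan_out))
        )
    return params


@dataclass
class Forward:
    """Forward pass caches for a batch X (n, d)."""

    params: list
    activations: list  # a_0 = X, a_1..a_H hidden activations
    z_hidden: list  # pre-activations of hidden layers
    y: np.ndarray  # (n,) scalar outputs
    tangents: list = field(default_factory=list)  # c_l caches for double backprop
    t_hidden: list = field(default_factory=list)


def forward(params, x) -> Forward:
    a = [np.asarray(x, dtype=float)]
    z_hidden = []
    cur = a[0]
    for w, b in params[:-1]:
        z = cur @ w.T + b
        z_hidden.append(z)
        cur = np.tanh(z)
        a.append(cur)
    w_out, b_out = params[-1]
    y = cur @ w_out.T + b_out  # (n, 1)
    return Forward(params=params, activations=a, z_hidden=z_hidden, y=y[:, 0])


def backprop(fwd: Forward, dldy: np.ndarray) -> list:
    """Parameter gradients of sum_n dldy_n * y_n."""
    params = fwd.params
    grads = [None] * len(params)
    w_out, _ = params[-1]
    g = dldy[:, None]  # dL/d(pre-output)
    grads[-1] = (g.T @ fwd.activations[-1], g.sum(axis=0))
    da = g @ w_out
    for l in range(len(params) - 2, -1, -1):
        a_l = fwd.activations[l + 1]
        dz = da * (1.0 - a_l * a_l)
        grads[l] = (dz.T @ fwd.activations[l], dz.sum(axis=0))
        if l > 0:
            da = dz @ params[l][0]
    return grads


def input_gradient(fwd: Forward) -> np.ndarray:
    """dy/dx, shape (n, d_in)."""
    params = fwd.params
    g = np.broadcast_to(params[-1][0], (fwd.y.shape[0], params[-1][0].shape[1])).copy()
    for l in range(len(params) - 2, -1, -1):
        a_l = fwd.activations[l + 1]
        g = (g * (1.0 - a_l * a_l)) @ params[l][0]
    return g


def tangent_forward(fwd: Forward, s: np.ndarray) -> np.ndarray:
    """R_n = s_n . (dy/dx)_n via a forward tangent pass; caches for backprop."""
    params = fwd.params
    t = np.asarray(s, dtype=float)
    fwd.tangents = []
    fwd.t_hidden = [t]
    for l, (w, _) in enumerate(params[:-1]):
        c = t @ w.T
        fwd.tangents.append(c)
        a_l = fwd.activations[l + 1]
        t = (1.0 - a_l * a_l) * c
        fwd.t_hidden.append(t)
    w_out, _ = params[-1]
    return t @ w_out.T[:, 0]


def tangent_backprop(fwd: Forward, dldr: np.ndarray) -> list:
    """Parameter gradients of sum_n dldr_n * R_n (after tangent_forward)."""
    params = fwd.params
    grads = [None] * len(params)
    h = len(params) - 1  # number of hidden layers
    w_out, _ = params[-1]
    # output layer: R = t_H @ w_out^T
    grads[-1] = (dldr[:, None].T @ fwd.t_hidden[h], np.zeros(1))
    tt = dldr[:, None] @ w_out  # dR/dt_H
    ta = np.zeros_like(tt)
    for l in range(h - 1, -1, -1):
        a_l = fwd.activations[l + 1]
        c_l = fwd.tangents[l]
        dc = tt * (1.0 - a_l * a_l)
        da_total = ta - 2.0 * a_l * c_l * tt
        dz = da_total * (1.0 - a_l * a_l)
        gw = dz.T @ fwd.activations[l] + dc.T @ fwd.t_hidden[l]
        gb = dz.sum(axis=0)
        grads[l] = (gw, gb)
        if l > 0:
            w_l = params[l][0]
            ta = dz @ w_l
            tt = dc @ w_l
    return grads


def add_grads(total, extra, scale=1.0):
    if total is None:
        return [(scale * gw, scale * gb) for gw, gb in extra]
    return [
        (tw + scale * gw, tb + scale * gb)
        for (tw, tb), (gw, gb) in zip(total, extra)
    ]


# ---------------------------------------------------------------------------
# Adam with persistent per-weight state and frozen masks
# ---------------------------------------------------------------------------


@dataclass
class AdamState:
    m: list  # same structure as params
    v: list
    step: int = 0
    epoch: int = 0

    @classmethod
    def zeros_like(cls, params) -> "AdamState":
        return cls(
            m=[(np.zeros_like(w), np.zeros_like(b)) for w, b in params],
            v=[(np.zeros_like(w), np.zeros_like(b)) for w, b in params],
        )

    def copy(self) -> "AdamState":
        return AdamState(
            m=[(w.copy(), b.copy()) for w, b in self.m],
            v=[(w.copy(), b.copy()) for w, b in self.v],
            step=self.step,
            epoch=self.epoch,
        )


def adam_step(
    params,
    grads,
    state: AdamState,
    lr: float = 0.01,
    beta1: float = 0.9,
    beta2: float = 0.999,
    eps: float = 1e-8,
    frozen_mask=None,
):
    """One in-place Adam update; frozen_mask entries (per layer, (W-bool, b-bool))
    mark parameters that must not move (their moments are not advanced either)."""
    state.step += 1
    t = state.step
    for l, (w, b) in enumerate(params):
        gw, gb = grads[l]
        if frozen_mask is not None:
            fw, fb = frozen_mask[l]
            gw = np.where(fw, 0.0, gw)
            gb = np.where(fb, 0.0, gb)
        mw, mb = state.m[l]
        vw, vb = state.v[l]
        mw[...] = beta1 * mw + (1 - beta1) * gw
        mb[...] = beta1 * mb + (1 - beta1) * gb
        vw[...] = beta2 * vw + (1 - beta2) * gw * gw
        vb[...] = beta2 * vb + (1 - beta2) * gb * gb
        corr1 = 1 - beta1**t
        corr2 = 1 - beta2**t
        dw = lr * (mw / corr1) / (np.sqrt(vw / corr2) + eps)
        db = lr * (mb / corr1) / (np.sqrt(vb / corr2) + eps)
        if frozen_mask is not None:
            dw = np.where(fw, 0.0, dw)
            db = np.where(fb, 0.0, db)
        w -= dw
        b -= db


def flatten_params(params) -> np.ndarray:
    return np.concatenate([np.concatenate([w.ravel(), b.ravel()]) for w, b in params])
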