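"""Minimal fully-connected network with manual backpropagation.

Implements exactly the architecture family used by the embedding and the
feed-forward baseline: linear -> batch-norm -> sigmoid -> dropout hidden
blocks and a linear (or tanh) output layer, trained with Adam.  Written in
numpy so that every gradient is available in closed form and can be checked
against finite differences.
"""

from __future__ import annotations

from typing import Callable, Dict, List, Optional, Tuple

import numpy as np

_BN_EPS = 1e-8


def _sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class MLP:
    """Hidden blocks (linear, optional batch-norm, sigmoid, dropout) plus a
    linear output layer with optional tanh activation.

    Parameters are kept in a flat dict name -> array so optimisers and
    checkpoints can treat them uniformly.
    """

    def __init__(self, input_dim: int, hidden_widths: List[int],
                 output_dim: int, dropout_rate: float = 0.0,
                 batch_norm: bool = True, output_activation: str = "linear",
                 rng: Optional[np.random.Generator] = None):
        if dropout_rate < 0 or dropout_rate >= 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        if output_activation not in ("linear", "tanh"):
            raise ValueError("output_activation must be 'linear' or 'tanh'")
        self.input_dim = int(input_dim)
        self.hidden_widths = [int(w) for w in hidden_widths]
        self.output_dim = int(output_dim)
        self.dropout_rate = float(dropout_rate)
        self.batch_norm = bool(batch_norm)
        self.output_activation = output_activation
        rng = rng if rng is not None else np.random.default_rng()
        self.params: Dict[str, np.ndarray] = {}
        self.running: Dict[str, np.ndarray] = {}
        fan_in = self.input_dim
        for li, width in enumerate(self.hidden_widths):
            self._init_linear(f"h{li}", fan_in, width, rng)
            if self.batch_norm:
                self.params[f"h{li}_gamma"] = np.ones(width)
                self.params[f"h{li}_beta"] = np.zeros(width)
                self.running[f"h{li}_mean"] = np.zeros(width)
                self.running[f"h{li}_var"] = np.ones(width)
            fan_in = width
        self._init_linear("out", fan_in, self.output_dim, rng)

    def _init_linear(self, name: str, fan_in: int, fan_out: int,
                     rng: np.random.Generator) -> None:
        # fan-balanced (Glorot) uniform
        bound = np.sqrt(6.0 / (fan_in + fan_out))
        self.params[f"{name}_W"] = rng.uniform(-bound, bound,
                                               size=(fan_in, fan_out))
        self.params[f"{name}_b"] = np.zeros(fan_out)

    @property
    def n_parameters(self) -> int:
        return sum(p.size for p in self.params.values())

    # ------------------------------------------------------------------
    def forward(self, x: np.ndarray, training: bool = False,
                rng: Optional[np.random.Generator] = None,
                update_stats: bool = False,
                dropout_masks: Optional[List[np.ndarray]] = None,
                ) -> Tuple[np.ndarray, dict]:
        """Forward pass; returns (output, cache-for-backward).

        ``training`` selects batch statistics and active dropout.  Masks may
        be supplied explicitly (gradient checking); otherwise drawn from
        ``rng``.  Running batch-norm statistics are only touched when
        ``update_stats`` is set, keeping the pass side-effect free otherwise.
        """
        x = np.asarray(x, dtype=float)
        if x.ndim == 1:
            x = x[None, :]
        if x.shape[1] != self.input_dim:
            raise ValueError(
                f"input dimension {x.shape[1]} != expected {self.input_dim}"
            )
        cache: dict = {"inputs": [], "bn": [], "sig": [], "masks": [],
                       "x0": x, "training": training}
        h = x
        for li in range(len(self.hidden_widths)):
            cache["inputs"].append(h)
            a = h @ self.params[f"h{li}_W"] + self.params[f"h{li}_b"]
            if self.batch_norm:
                if training:
                    mu = a.mean(axis=0)
                    var = a.var(axis=0)
                    if update_stats:
                        m = 0.9
                        self.running[f"h{li}_mean"] = (
                            m * self.running[f"h{li}_mean"] + (1 - m) * mu)
                        self.running[f"h{li}_var"] = (
                            m * self.running[f"h{li}_var"] + (1 - m) * var)
                else:
                    mu = self.running[f"h{li}_mean"]
                    var = self.running[f"h{li}_var"]
                inv = 1.0 / np.sqrt(var + _BN_EPS)
                ahat = (a - mu) * inv
                a = self.params[f"h{li}_gamma"] * ahat + self.params[f"h{li}_beta"]
                cache["bn"].append((ahat, inv))
            else:
                cache["bn"].append(None)
            s = _sigmoid(a)
            cache["sig"].append(s)
            if training and self.dropout_rate > 0:
                if dropout_masks is not None:
                    mask = dropout_masks[li]
                else:
                    if rng is None:
                        raise ValueError("rng required for dropout in training")
                    mask = (rng.random(s.shape) >= self.dropout_rate)
                mask = mask / (1.0 - self.dropout_rate)
                h = s * mask
                cache["masks"].append(mask)
            else:
                h = s
                cache["masks"].append(None)
        cache["h_last"] = h
        z = h @ self.params["out_W"] + self.params["out_b"]
        if self.output_activation == "tanh":
            z = np.tanh(z)
        cache["z"] = z
        return z, cache

    def backward(self, cache: dict, dz: np.ndarray,
                 ) -> Tuple[Dict[str, np.ndarray], np.ndarray]:
        """Backpropagate dL/dz; returns (parameter grads, dL/dinput)."""
        grads: Dict[str, np.ndarray] = {}
        if self.output_activation == "tanh":
            dz = dz * (1.0 - cache["z"] ** 2)
        grads["out_W"] = cache["h_last"].T @ dz
        grads["out_b"] = dz.sum(axis=0)
        dh = dz @ self.params["out_W"].T
        for li in reversed(range(len(self.hidden_widths))):
            mask = cache["masks"][li]
            if mask is not None:
                dh = dh * mask
            s = cache["sig"][li]
            da = dh * s * (1.0 - s)
            if self.batch_norm:
                ahat, inv = cache["bn"][li]
                grads[f"h{li}_gamma"] = (da * ahat).sum(axis=0)
                grads[f"h{li}_beta"] = da.sum(axis=0)
                dah = da * self.params[f"h{li}_gamma"]
                if cache["training"]:
                    n = ahat.shape[0]
                    da = inv * (dah - dah.mean(axis=0)
                                - ahat * (dah * ahat).mean(axis=0))
                    if n == 1:  # degenerate batch: variance term vanishes
                        da = np.zeros_like(dah)
                else:
                    da = dah * inv
            grads[f"h{li}_W"] = cache["inputs"][li].T @ da
            grads[f"h{li}_b"] = da.sum(axis=0)
            dh = da @ self.params[f"h{li}_W"].T
        return grads, dh

    # ------------------------------------------------------------------
    def get_state(self) -> Dict[str, np.ndarray]:
        state = {f"param::{k}": v.copy() for k, v in self.params.items()}
        state.update({f"running::{k}": v.copy()
                      for k, v in self.running.items()})
        return state

    def set_state(self, state: Dict[str, np.ndarray]) -> None:
        for key, value in state.items():
            kind, name = key.split("::", 1)
            target = self.params if kind == "param" else self.running
            if name not in target:
                raise ValueError(f"unknown state entry {name!r}")
            if target[name].shape != value.shape:
                raise ValueError(
                    f"shape mismatch for {name}: {target[name].shape} "
                    f"vs {value.shape}"
                )
            target[name] = value.copy()


class Adam:
    """Standard Adam with a mutable learning rate (for plateau halving)."""

    def __init__(self, params: Dict[str, np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: Dict[str, np.ndarray],
             grads: Dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def fit_loop(net: MLP, x_train: np.ndarray,
             batch_loss_grad: Callable[[np.ndarray, np.ndarray, dict], Tuple[float, np.ndarray, dict]],
             val_metric: Optional[Callable[[], float]],
             batch_size: int, max_epochs: int, learning_rate: float,
             lr_halving_patience: int, max_halvings: int,
             rng: np.random.Generator,
             min_batch: int = 2) -> Tuple[Dict[str, np.ndarray], "object"]:
    """Generic seeded mini-batch training loop with plateau LR halving.

    ``batch_loss_grad(xb, zb, cache)`` maps a forward-passed batch to
    (loss, dL/dz, info).  ``val_metric`` is evaluated once per epoch; the
    parameter state achieving the best value is returned.  Training stops
    after ``max_halvings`` learning-rate halvings yield no improvement.
    Returns (best_state, history-record list).
    """
    import pandas as pd

    n = x_train.shape[0]
    opt = Adam(net.params, lr=learning_rate)
    best_val = np.inf
    best_state = net.get_state()
    epochs_since_best = 0
    halvings = 0
    any_similar_ever = False
    records = []
    for epoch in range(max_epochs):
        perm = rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, n, batch_size):
            idx = perm[start:start + batch_size]
            if idx.size < min_batch:
                continue
            xb = x_train[idx]
            zb, cache = net.forward(xb, training=True, rng=rng,
                                    update_stats=True)
            loss, dz, info = batch_loss_grad(idx, zb, cache)
            grads, _ = net.backward(cache, dz)
            opt.step(net.params, grads)
            epoch_loss += loss
            n_batches += 1
            if info.get("n_similar", 1) > 0:
                any_similar_ever = True
        val = val_metric() if val_metric is not None else epoch_loss
        improved = val < best_val - 1e-12
        if improved:
            best_val = val
            best_state = net.get_state()
            epochs_since_best = 0
            halvings = 0
        else:
            epochs_since_best += 1
        if epochs_since_best >= lr_halving_patience:
            opt.lr *= 0.5
            halvings += 1
            epochs_since_best = 0
            if halvings > max_halvings:
                records.append({"epoch": epoch, "train_loss": epoch_loss,
                                "val_error": val, "lr": opt.lr,
                                "improved": improved})
                break
        records.append({"epoch": epoch, "train_loss": epoch_loss,
                        "val_error": val, "lr": opt.lr,
                        "improved": improved})
    history = pd.DataFrame.from_records(records)
    history.attrs["best_val"] = best_val
    history.attrs["degenerate_no_similar_pairs"] = not any_similar_ever
    return best_state, history
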