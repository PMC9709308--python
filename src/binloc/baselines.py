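"""Baseline systems: Laplacian-eigenmaps embedding and a feed-forward
direct regressor.

Laplacian eigenmaps (LEM) builds an affinity matrix K over the measurement
vectors (symmetric OR-rule M-nearest-neighbor graph, or a Gaussian kernel
exp(-||x_i-x_j||^2 / eps)), normalises it to the row-stochastic transition
matrix P = D^-1 K, and embeds each point by the entries of eigenvectors
2..d+1 of P (sorted by descending eigenvalue; the constant top eigenvector
is dropped).  New points are extended by a kernel-weighted barycentre of
training coordinates.

The feed-forward baseline shares the siamese branch architecture but adds a
tanh output head and regresses normalised angles u/180 with the MSE loss.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy.linalg import eigh
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import cdist

from . import _network
from .embedding import NetworkSpec, TrainConfig
from .neighborhoods import angular_distance

__all__ = [
    "AffinityGraph",
    "SpectralEmbedding",
    "build_affinity",
    "lem_embed",
    "lem_extend",
    "LaplacianEigenmaps",
    "LaplacianEigenmapsResults",
    "FeedForwardSpec",
    "FeedForwardLocalizer",
    "FeedForwardResults",
]

LABEL_SCALE_DEG = 180.0


@dataclass
class AffinityGraph:
    """Affinity kernel K, degrees and transition matrix P = D^-1 K."""

    kernel: np.ndarray
    mode: str                       # "knn" | "gaussian"
    knn_m: Optional[int] = None
    bandwidth: Optional[float] = None
    points: Optional[np.ndarray] = None  # training vectors, for extension
    degree: np.ndarray = field(init=False)
    transition: np.ndarray = field(init=False)

    def __post_init__(self):
        k = np.asarray(self.kernel, dtype=float)
        if not np.allclose(k, k.T):
            raise ValueError("kernel must be symmetric")
        if np.any(k < 0):
            raise ValueError("kernel must be non-negative")
        self.kernel = k
        self.degree = k.sum(axis=1)
        if np.any(self.degree <= 0):
            raise ValueError("isolated vertex: zero degree in affinity graph")
        self.transition = k / self.degree[:, None]


@dataclass
class SpectralEmbedding:
    """Eigen-pairs of P and the coordinates from eigenvectors 2..d+1."""

    eigenvalues: np.ndarray   # sorted descending, lambda_1 = 1
    eigenvectors: np.ndarray  # columns psi_i, including the constant psi_1
    coords: np.ndarray        # (N, d)


def _m_nearest(dist_row: np.ndarray, self_idx: int, m: int) -> np.ndarray:
    """Indices of the M nearest points, self excluded, ties by lowest index."""
    n = dist_row.size
    order = np.lexsort((np.arange(n), dist_row))
    order = order[order != self_idx]
    return order[:m]


def build_affinity(x: np.ndarray, mode: str = "knn", m: int = 10,
                   bandwidth: Optional[float] = None) -> AffinityGraph:
    """Affinity matrix over measurement vectors.

    knn mode: binary symmetric OR-rule M-NN graph with zero diagonal.
    gaussian mode: K[i,j] = exp(-||x_i-x_j||^2 / bandwidth).
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    d = cdist(x, x)
    if mode == "knn":
        if not 1 <= m < n:
            raise ValueError(f"need N > M >= 1, got N={n}, M={m}")
        kernel = np.zeros((n, n))
        for i in range(n):
            nn = _m_nearest(d[i], i, m)
            kernel[i, nn] = 1.0
        kernel = np.maximum(kernel, kernel.T)  # OR rule
        np.fill_diagonal(kernel, 0.0)
        return AffinityGraph(kernel, "knn", knn_m=m, points=x)
    if mode == "gaussian":
        if bandwidth is None or bandwidth <= 0:
            raise ValueError("gaussian mode needs a positive bandwidth")
        kernel = np.exp(-(d ** 2) / bandwidth)
        return AffinityGraph(kernel, "gaussian", bandwidth=bandwidth,
                             points=x)
    raise ValueError("mode must be 'knn' or 'gaussian'")


def lem_embed(graph: AffinityGraph, d: int = 3) -> SpectralEmbedding:
    """Spectral embedding from the top non-trivial eigenvectors of P.

    Solved through the symmetric matrix D^-1/2 K D^-1/2 (same spectrum as
    P) for numerical stability; eigenvectors are mapped back by D^-1/2.
    """
    k = graph.kernel
    n = k.shape[0]
    if d >= n - 1:
        raise ValueError(f"need d < N - 1 (d={d}, N={n})")
    n_comp, _ = connected_components((k > 0).astype(int), directed=False)
    if n_comp > 1:
        raise ValueError(
            f"affinity graph is disconnected ({n_comp} components)"
        )
    dinv_sqrt = 1.0 / np.sqrt(graph.degree)
    sym = k * dinv_sqrt[:, None] * dinv_sqrt[None, :]
    sym = 0.5 * (sym + sym.T)
    eigvals, eigvecs = eigh(sym)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    psi = dinv_sqrt[:, None] * eigvecs[:, order]
    # fix an overall sign/scale convention: constant psi_1, positive entries
    for j in range(psi.shape[1]):
        pivot = psi[np.argmax(np.abs(psi[:, j])), j]
        if pivot < 0:
            psi[:, j] = -psi[:, j]
    coords = psi[:, 1:d + 1]
    return SpectralEmbedding(eigenvalues=eigvals, eigenvectors=psi,
                             coords=coords)


def lem_extend(x_new: np.ndarray, graph: AffinityGraph,
               embedding: SpectralEmbedding,
               nystrom_correction: bool = False) -> np.ndarray:
    """Out-of-sample extension: kernel-weighted barycentre of train coords.

    knn mode weights the M nearest training points with the localization
    kernel exp(-d^2/eps), eps the median squared neighbor distance;
    gaussian mode uses the graph's own kernel against all training points.
    Weights are normalised to sum to one.  With ``nystrom_correction`` each
    output component j is additionally scaled by 1/lambda_{j+1}.
    """
    if graph.points is None:
        raise ValueError("graph carries no training points for extension")
    x_new = np.asarray(x_new, dtype=float).ravel()
    d = np.linalg.norm(graph.points - x_new, axis=1)
    if graph.mode == "knn":
        order = np.lexsort((np.arange(d.size), d))
        nn = order[: graph.knn_m]
        d_sq = d[nn] ** 2
        eps = np.median(d_sq)
        w_local = (np.ones_like(d_sq) if eps == 0
                   else np.exp(-d_sq / eps))
        weights = np.zeros_like(d)
        weights[nn] = w_local
    else:
        weights = np.exp(-(d ** 2) / graph.bandwidth)
    total = weights.sum()
    if total <= 0 or not np.isfinite(total):
        raise ValueError("query has zero affinity to every training point")
    weights = weights / total
    z = weights @ embedding.coords
    if nystrom_correction:
        lam = embedding.eigenvalues[1:embedding.coords.shape[1] + 1]
        z = z / lam
    return z


class LaplacianEigenmaps:
    """Model object for the unsupervised LEM baseline."""

    def __init__(self, features: np.ndarray, mode: str = "knn", m: int = 10,
                 bandwidth: Optional[float] = None,
                 labels: Optional[np.ndarray] = None):
        self.features = np.asarray(features, dtype=float)
        self.mode = mode
        self.m = m
        self.bandwidth = bandwidth
        self.labels = None if labels is None else np.asarray(labels, float)

    def fit(self, n_components: int = 3) -> "LaplacianEigenmapsResults":
        graph = build_affinity(self.features, self.mode, self.m,
                               self.bandwidth)
        emb = lem_embed(graph, n_components)
        return LaplacianEigenmapsResults(self, graph, emb)


class LaplacianEigenmapsResults:
    """Fitted spectral embedding with out-of-sample transform."""

    def __init__(self, model: LaplacianEigenmaps, graph: AffinityGraph,
                 embedding: SpectralEmbedding):
        self.model = model
        self.graph = graph
        self.embedding = embedding
        self.coords = embedding.coords
        self.eigenvalues = embedding.eigenvalues

    def transform(self, x: np.ndarray,
                  nystrom_correction: bool = False) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        return np.array([lem_extend(row, self.graph, self.embedding,
                                    nystrom_correction) for row in x])

    def localize(self, x: np.ndarray, k: int = 5,
                 weight_mode: str = "exponential") -> np.ndarray:
        from .localizer import LocalizerConfig, knn_regress_batch

        if self.model.labels is None:
            raise ValueError("model was built without labels")
        z = self.transform(x)
        cfg = LocalizerConfig(n_neighbors=k, weight_mode=weight_mode)
        return knn_regress_batch(z, self.coords, self.model.labels, cfg)

    def summary(self) -> str:
        lines = [
            "Laplacian Eigenmaps Results",
            "=" * 32,
            f"n points:        {self.coords.shape[0]}",
            f"mode:            {self.graph.mode}"
            + (f" (M={self.graph.knn_m})" if self.graph.mode == "knn"
               else f" (eps={self.graph.bandwidth})"),
            f"components:      {self.coords.shape[1]}",
            f"top eigenvalues: "
            + ", ".join(f"{v:.4f}" for v in self.eigenvalues[:5]),
        ]
        return "\n".join(lines)


# ----------------------------------------------------------------------
@dataclass(frozen=True)
class FeedForwardSpec:
    """Feed-forward regressor: one siamese branch plus a tanh head.

    The trunk is the full branch (two hidden layers and the 3-unit linear
    layer); an additional tanh unit per latent dimension outputs the
    normalised angle estimate, scaled back by 180 degrees.
    """

    trunk: NetworkSpec
    n_outputs: int = 1
    label_scale: float = LABEL_SCALE_DEG


class _FeedForwardNet:
    """One siamese branch (linear 3-unit output) plus a tanh head.

    Exposes the same forward/backward/state interface as `_network.MLP`
    so the shared training loop can drive it.
    """

    def __init__(self, trunk: NetworkSpec, n_outputs: int,
                 rng: np.random.Generator):
        self.trunk = _network.MLP(
            trunk.input_dim, list(trunk.hidden_widths), trunk.output_dim,
            dropout_rate=trunk.dropout_rate, batch_norm=trunk.batch_norm,
            output_activation="linear", rng=rng)
        self.head = _network.MLP(
            trunk.output_dim, [], n_outputs, dropout_rate=0.0,
            batch_norm=False, output_activation="tanh", rng=rng)
        # shared array objects: Adam's in-place updates reach both nets
        self.params = {f"trunk.{k}": v for k, v in self.trunk.params.items()}
        self.params.update({f"head.{k}": v
                            for k, v in self.head.params.items()})

    @property
    def n_parameters(self) -> int:
        return self.trunk.n_parameters + self.head.n_parameters

    def forward(self, x, training=False, rng=None, update_stats=False):
        z, c1 = self.trunk.forward(x, training=training, rng=rng,
                                   update_stats=update_stats)
        y, c2 = self.head.forward(z, training=training)
        return y, (c1, c2)

    def backward(self, cache, dy):
        c1, c2 = cache
        g_head, dz = self.head.backward(c2, dy)
        g_trunk, dx = self.trunk.backward(c1, dz)
        grads = {f"trunk.{k}": v for k, v in g_trunk.items()}
        grads.update({f"head.{k}": v for k, v in g_head.items()})
        return grads, dx

    def get_state(self):
        state = {f"trunk.{k}": v for k, v in self.trunk.get_state().items()}
        state.update({f"head.{k}": v
                      for k, v in self.head.get_state().items()})
        return state

    def set_state(self, state):
        self.trunk.set_state({k[len("trunk."):]: v for k, v in state.items()
                              if k.startswith("trunk.")})
        self.head.set_state({k[len("head."):]: v for k, v in state.items()
                             if k.startswith("head.")})
        self.params = {f"trunk.{k}": v for k, v in self.trunk.params.items()}
        self.params.update({f"head.{k}": v
                            for k, v in self.head.params.items()})


class FeedForwardLocalizer:
    """Direct regression model from measurement vectors to angles."""

    def __init__(self, features: np.ndarray, labels_deg: np.ndarray,
                 network: Optional[NetworkSpec] = None,
                 val_features: Optional[np.ndarray] = None,
                 val_labels: Optional[np.ndarray] = None):
        self.features = np.asarray(features, dtype=float)
        labels = np.asarray(labels_deg, dtype=float)
        if labels.ndim == 1:
            labels = labels[:, None]
        if np.any(np.abs(labels) > LABEL_SCALE_DEG):
            raise ValueError("labels must lie in [-180, 180] degrees")
        self.labels = labels
        self.network = network or NetworkSpec(input_dim=self.features.shape[1])
        self.spec = FeedForwardSpec(trunk=self.network,
                                    n_outputs=labels.shape[1])
        self.val_features = (None if val_features is None
                             else np.asarray(val_features, dtype=float))
        if val_labels is not None:
            val_labels = np.asarray(val_labels, dtype=float)
            if val_labels.ndim == 1:
                val_labels = val_labels[:, None]
        self.val_labels = val_labels

    def fit(self, config: Optional[TrainConfig] = None,
            **overrides) -> "FeedForwardResults":
        cfg = config or TrainConfig()
        if overrides:
            cfg = replace(cfg, **overrides)
        rng = np.random.default_rng(cfg.seed)
        net = _FeedForwardNet(self.network, self.spec.n_outputs, rng)
        y_norm = self.labels / self.spec.label_scale

        def batch_loss_grad(idx, zb, cache):
            resid = zb - y_norm[idx]
            loss = float((resid ** 2).mean())
            dz = 2.0 * resid / resid.size
            return loss, dz, {"n_similar": 1}

        def val_metric():
            pred, _ = net.forward(self.val_features, training=False)
            err = angular_distance(pred.ravel() * self.spec.label_scale,
                                   self.val_labels.ravel())
            return float(np.median(err))

        best_state, history = _network.fit_loop(
            net, self.features, batch_loss_grad,
            None if self.val_features is None else val_metric,
            batch_size=cfg.batch_size, max_epochs=cfg.max_epochs,
            learning_rate=cfg.learning_rate,
            lr_halving_patience=cfg.lr_halving_patience,
            max_halvings=cfg.max_halvings, rng=rng, min_batch=2)
        net.set_state(best_state)
        return FeedForwardResults(self, net, cfg, history)


class FeedForwardResults:
    """Fitted feed-forward regressor."""

    def __init__(self, model: FeedForwardLocalizer, net: _network.MLP,
                 config: TrainConfig, history: pd.DataFrame):
        self.model = model
        self._net = net
        self.config = config
        self.history = history
        self.best_val_error = float(history.attrs.get("best_val", np.nan))

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Angle estimates in degrees (tanh output scaled by 180)."""
        x = np.asarray(x, dtype=float)
        single = x.ndim == 1
        z, _ = self._net.forward(x, training=False)
        pred = z * self.model.spec.label_scale
        if self.model.spec.n_outputs == 1:
            pred = pred.ravel()
        return pred[0] if single else pred

    def summary(self) -> str:
        trunk = self.model.network
        lines = [
            "Feed-Forward Localizer Results",
            "=" * 32,
            f"n train:           {self.model.features.shape[0]}",
            f"architecture:      {trunk.input_dim} -> "
            + " -> ".join(map(str, trunk.hidden_widths))
            + f" -> {trunk.output_dim} -> tanh({self.model.spec.n_outputs})",
            f"epochs run:        {len(self.history)}",
            f"final train loss:  {self.history['train_loss'].iloc[-1]:.6g}",
            f"best val error:    {self.best_val_error:.4g} deg",
            f"seed:              {self.config.seed}",
        ]
        return "\n".join(lines)
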