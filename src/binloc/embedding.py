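"""Siamese contrastive embedding f_W : R^D -> R^3 and its training loop.

The network (two sigmoid hidden layers of width D with batch-norm and
dropout, linear 3-unit output) is trained on all C(n,2) pairs of each
mini-batch with the adaptive-margin contrastive loss

    L = sum_{i<j}  y_ij ||z_i - z_j||^2
               + (1 - y_ij) max(0, mu_ij - ||z_i - z_j||)^2,

pulling pairs with nearby sources together and pushing others beyond their
margin mu_ij = logistic(d_ij).  Model selection and learning-rate halving
are driven by the median validation localization error of the kernel kNN
regressor applied to the embeddings.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass, replace
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import _network
from .features import FeatureConfig
from .localizer import LocalizerConfig, knn_regress_batch
from .neighborhoods import (ThresholdConfig, PairLabel, angular_distance,
                            batch_pair_arrays)

__all__ = [
    "NetworkSpec",
    "TrainConfig",
    "LossValue",
    "contrastive_loss",
    "ContrastiveEmbedding",
    "ContrastiveEmbeddingResults",
    "save_model",
    "load_model",
]

CHECKPOINT_FORMAT = "binloc-checkpoint-1"


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture of one siamese branch.

    Defaults follow the reference design: two hidden layers as wide as the
    input, sigmoid activations, batch-norm, dropout 0.2, and a linear
    3-dimensional output (d << D).
    """

    input_dim: int
    hidden_widths: Optional[Tuple[int, int]] = None  # default (D, D)
    dropout_rate: float = 0.2
    batch_norm: bool = True
    output_dim: int = 3

    def __post_init__(self):
        if self.hidden_widths is None:
            object.__setattr__(self, "hidden_widths",
                               (self.input_dim, self.input_dim))
        if self.output_dim >= self.input_dim:
            raise ValueError("output_dim must be < input_dim (d << D)")
        if any(w <= 0 for w in self.hidden_widths):
            raise ValueError("hidden widths must be positive")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")

    def to_dict(self) -> dict:
        return {"input_dim": self.input_dim,
                "hidden_widths": list(self.hidden_widths),
                "dropout_rate": self.dropout_rate,
                "batch_norm": self.batch_norm,
                "output_dim": self.output_dim}

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkSpec":
        return cls(input_dim=int(d["input_dim"]),
                   hidden_widths=tuple(d["hidden_widths"]),
                   dropout_rate=float(d["dropout_rate"]),
                   batch_norm=bool(d["batch_norm"]),
                   output_dim=int(d["output_dim"]))


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation settings (Adam, plateau LR halving, best-val selection)."""

    learning_rate: float = 1e-3
    batch_size: int = 128
    max_epochs: int = 500
    lr_halving_patience: int = 20
    max_halvings: int = 3
    seed: int = 0
    loss_reduction: str = "sum"  # or "mean" over pairs

    def __post_init__(self):
        if self.batch_size < 2:
            raise ValueError("batch_size must be >= 2")
        if self.lr_halving_patience < 1:
            raise ValueError("patience must be >= 1")
        if self.loss_reduction not in ("sum", "mean"):
            raise ValueError("loss_reduction must be 'sum' or 'mean'")


@dataclass(frozen=True)
class LossValue:
    """Contrastive loss split into its attractive and repulsive terms."""

    total: float
    similar_term: float
    dissimilar_term: float
    n_pairs: int

    def __post_init__(self):
        if self.total < -1e-12:
            raise ValueError("loss must be non-negative")


def contrastive_loss_grad(z: np.ndarray, iu: np.ndarray, ju: np.ndarray,
                          y: np.ndarray, mu: np.ndarray,
                          reduction: str = "sum",
                          ) -> Tuple[LossValue, np.ndarray, dict]:
    """Loss and its gradient dL/dz over all listed pairs.

    Similar pairs (y=1) contribute the squared distance; dissimilar pairs
    the squared hinge max(0, mu - distance)^2.  At distance exactly zero the
    hinge direction is undefined and the subgradient 0 is used.
    """
    z = np.asarray(z, dtype=float)
    diff = z[iu] - z[ju]
    dist = np.linalg.norm(diff, axis=1)
    y = np.asarray(y)
    sim = y == 1
    hinge = np.maximum(0.0, mu - dist)
    sim_term = float((dist[sim] ** 2).sum())
    dis_term = float((hinge[~sim] ** 2).sum())
    n_pairs = len(iu)
    scale = 1.0 / n_pairs if reduction == "mean" else 1.0

    dz = np.zeros_like(z)
    # attractive: d/dz_i ||z_i - z_j||^2 = 2 (z_i - z_j)
    coeff = np.zeros(n_pairs)
    coeff[sim] = 2.0
    # repulsive (active hinge, nonzero distance):
    act = (~sim) & (hinge > 0) & (dist > 0)
    coeff[act] = -2.0 * hinge[act] / dist[act]
    contrib = coeff[:, None] * diff * scale
    np.add.at(dz, iu, contrib)
    np.add.at(dz, ju, -contrib)
    loss = LossValue(total=(sim_term + dis_term) * scale,
                     similar_term=sim_term * scale,
                     dissimilar_term=dis_term * scale,
                     n_pairs=n_pairs)
    info = {"n_similar": int(sim.sum()), "n_dissimilar": int((~sim).sum())}
    return loss, dz, info


def contrastive_loss(z_pairs: Sequence[Tuple[np.ndarray, np.ndarray]],
                     labels: Sequence[PairLabel],
                     reduction: str = "sum") -> LossValue:
    """Contrastive loss over an explicit list of embedding pairs."""
    if len(z_pairs) != len(labels):
        raise ValueError(
            f"{len(z_pairs)} pairs but {len(labels)} labels"
        )
    z = np.concatenate([[np.asarray(a, float), np.asarray(b, float)]
                        for a, b in z_pairs])
    iu = np.arange(0, 2 * len(z_pairs), 2)
    ju = iu + 1
    y = np.array([lab.indicator for lab in labels])
    mu = np.array([lab.margin for lab in labels])
    loss, _, _ = contrastive_loss_grad(z, iu, ju, y, mu, reduction)
    return loss


class ContrastiveEmbedding:
    """Model object: measurement vectors + latent labels -> trainable f_W.

    Parameters
    ----------
    features : (n, D) array of measurement vectors.
    labels : (n,) angles in degrees (supervised mode) or (n, 3) Cartesian
        source positions (weak mode).
    mode : "supervised" (SCE) or "weak" (WSCE).
    val_features, val_labels : optional held-out set driving model
        selection and learning-rate scheduling.
    """

    def __init__(self, features: np.ndarray, labels: np.ndarray,
                 mode: str = "supervised",
                 network: Optional[NetworkSpec] = None,
                 thresholds: Optional[ThresholdConfig] = None,
                 val_features: Optional[np.ndarray] = None,
                 val_labels: Optional[np.ndarray] = None,
                 feature_config: Optional[FeatureConfig] = None):
        self.features = np.asarray(features, dtype=float)
        if self.features.ndim != 2:
            raise ValueError("features must be a 2-D (n, D) array")
        self.labels = np.asarray(labels, dtype=float)
        if mode not in ("supervised", "weak"):
            raise ValueError("mode must be 'supervised' or 'weak'")
        if mode == "supervised" and self.labels.ndim != 1:
            raise ValueError("supervised mode expects scalar angle labels")
        if mode == "weak" and self.labels.shape[1:] != (3,):
            raise ValueError("weak mode expects (n, 3) Cartesian labels")
        if self.labels.shape[0] != self.features.shape[0]:
            raise ValueError("one label per feature vector required")
        self.mode = mode
        self.network = network or NetworkSpec(input_dim=self.features.shape[1])
        if self.network.input_dim != self.features.shape[1]:
            raise ValueError("network input_dim != feature dimension")
        self.thresholds = thresholds or ThresholdConfig()
        self.val_features = (None if val_features is None
                             else np.asarray(val_features, dtype=float))
        self.val_labels = (None if val_labels is None
                           else np.asarray(val_labels, dtype=float))
        self.feature_config = feature_config

    # ------------------------------------------------------------------
    def _val_error(self, net: _network.MLP) -> float:
        """Median validation localization error (degrees) via kernel kNN."""
        z_train, _ = net.forward(self.features, training=False)
        z_val, _ = net.forward(self.val_features, training=False)
        k = min(5, len(z_train))
        cfg = LocalizerConfig(n_neighbors=k)
        est = knn_regress_batch(z_val, z_train, self.labels, cfg)
        if self.mode == "supervised":
            err = angular_distance(est.ravel(), self.val_labels)
        else:
            # great-circle angle between estimated and true unit directions
            u = est / np.maximum(np.linalg.norm(est, axis=1, keepdims=True),
                                 1e-12)
            v = self.val_labels / np.maximum(
                np.linalg.norm(self.val_labels, axis=1, keepdims=True), 1e-12)
            cosang = np.clip((u * v).sum(axis=1), -1.0, 1.0)
            err = np.rad2deg(np.arccos(cosang))
        return float(np.median(err))

    def fit(self, config: Optional[TrainConfig] = None,
            **overrides) -> "ContrastiveEmbeddingResults":
        cfg = config or TrainConfig()
        if overrides:
            cfg = replace(cfg, **overrides)
        rng = np.random.default_rng(cfg.seed)
        net = _network.MLP(self.network.input_dim,
                           list(self.network.hidden_widths),
                           self.network.output_dim,
                           dropout_rate=self.network.dropout_rate,
                           batch_norm=self.network.batch_norm,
                           rng=rng)

        def batch_loss_grad(idx, zb, cache):
            iu, ju, y, mu, _ = batch_pair_arrays(
                self.labels[idx], self.thresholds, self.mode)
            loss, dz, info = contrastive_loss_grad(
                zb, iu, ju, y, mu, cfg.loss_reduction)
            return loss.total, dz, info

        val_metric = (None if self.val_features is None
                      else (lambda: self._val_error(net)))
        best_state, history = _network.fit_loop(
            net, self.features, batch_loss_grad, val_metric,
            batch_size=cfg.batch_size, max_epochs=cfg.max_epochs,
            learning_rate=cfg.learning_rate,
            lr_halving_patience=cfg.lr_halving_patience,
            max_halvings=cfg.max_halvings, rng=rng)
        net.set_state(best_state)
        return ContrastiveEmbeddingResults(self, net, cfg, history)


class ContrastiveEmbeddingResults:
    """Fitted embedding: weights, history, and localization helpers."""

    def __init__(self, model: ContrastiveEmbedding, net: _network.MLP,
                 config: TrainConfig, history: pd.DataFrame):
        self.model = model
        self._net = net
        self.config = config
        self.history = history
        self.train_embeddings = self.embed(model.features)
        self.best_val_error = float(history.attrs.get("best_val", np.nan))
        self.degenerate_training = bool(
            history.attrs.get("degenerate_no_similar_pairs", False))

    @property
    def n_parameters(self) -> int:
        return self._net.n_parameters

    def embed(self, x: np.ndarray) -> np.ndarray:
        """Map measurement vectors to the 3-D embedding (inference mode)."""
        x = np.asarray(x, dtype=float)
        single = x.ndim == 1
        z, _ = self._net.forward(x, training=False)
        return z[0] if single else z

    def localize(self, x: np.ndarray, k: int = 5,
                 weight_mode: str = "exponential") -> np.ndarray:
        """Embed queries and regress their labels against the training set."""
        z = np.atleast_2d(self.embed(x))
        cfg = LocalizerConfig(n_neighbors=k, weight_mode=weight_mode)
        return knn_regress_batch(z, self.train_embeddings,
                                 self.model.labels, cfg)

    def summary(self) -> str:
        spec = self.model.network
        lines = [
            "Contrastive Embedding Results",
            "=" * 34,
            f"mode:              {self.model.mode}",
            f"n train / val:     {self.model.features.shape[0]} / "
            + ("0" if self.model.val_features is None
               else str(self.model.val_features.shape[0])),
            f"architecture:      {spec.input_dim} -> "
            + " -> ".join(map(str, spec.hidden_widths))
            + f" -> {spec.output_dim}",
            f"dropout / bnorm:   {spec.dropout_rate} / {spec.batch_norm}",
            f"parameters:        {self.n_parameters}",
            f"epochs run:        {len(self.history)}",
            f"final train loss:  {self.history['train_loss'].iloc[-1]:.6g}",
            f"best val error:    {self.best_val_error:.4g} deg",
            f"eps_u (deg):       {self.model.thresholds.angle_threshold_deg}",
            f"seed:              {self.config.seed}",
        ]
        if self.degenerate_training:
            lines.append("WARNING: no batch ever contained a similar pair")
        return "\n".join(lines)

    def save(self, path) -> None:
        save_model(self, path)

    @classmethod
    def load(cls, path) -> "ContrastiveEmbeddingResults":
        return load_model(path)


# ----------------------------------------------------------------------
def save_model(results: ContrastiveEmbeddingResults, path) -> None:
    """Single-file checkpoint: JSON header + exact float64 weights."""
    model = results.model
    header = {
        "format": CHECKPOINT_FORMAT,
        "network": model.network.to_dict(),
        "mode": model.mode,
        "thresholds": {
            "angle_threshold_deg": model.thresholds.angle_threshold_deg,
            "distance_threshold_m": model.thresholds.distance_threshold_m,
            "margin_mode": model.thresholds.margin_mode,
            "constant_margin": model.thresholds.constant_margin,
            "margin_scale": model.thresholds.margin_scale,
            "radius_phi": model.thresholds.radius_phi,
        },
        "feature_config": (model.feature_config.to_dict()
                           if model.feature_config else None),
        "seed": results.config.seed,
    }
    arrays = {f"state/{k}": v for k, v in results._net.get_state().items()}
    arrays["train/features"] = model.features
    arrays["train/labels"] = model.labels
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr("header.json", json.dumps(header, indent=1))
        for name, arr in arrays.items():
            buf = io.BytesIO()
            np.save(buf, arr)
            zf.writestr(name + ".npy", buf.getvalue())


def load_model(path) -> ContrastiveEmbeddingResults:
    """Load a checkpoint written by `save_model`, validating its header."""
    try:
        with zipfile.ZipFile(path) as zf:
            header = json.loads(zf.read("header.json"))
            arrays = {}
            for name in zf.namelist():
                if name.endswith(".npy"):
                    arrays[name[:-4]] = np.load(io.BytesIO(zf.read(name)),
                                                allow_pickle=False)
    except (zipfile.BadZipFile, KeyError, ValueError, OSError) as exc:
        raise ValueError(f"corrupted or unreadable checkpoint {path}: {exc}")
    if header.get("format") != CHECKPOINT_FORMAT:
        raise ValueError(
            f"unsupported checkpoint format {header.get('format')!r}"
        )
    spec = NetworkSpec.from_dict(header["network"])
    thr = ThresholdConfig(
        angle_threshold_deg=header["thresholds"]["angle_threshold_deg"],
        distance_threshold_m=header["thresholds"]["distance_threshold_m"],
        margin_mode=header["thresholds"]["margin_mode"],
        constant_margin=header["thresholds"]["constant_margin"],
        margin_scale=header["thresholds"]["margin_scale"],
        radius_phi=header["thresholds"]["radius_phi"],
    )
    feat_cfg = (FeatureConfig.from_dict(header["feature_config"])
                if header.get("feature_config") else None)
    features = arrays["train/features"]
    if features.shape[1] != spec.input_dim:
        raise ValueError(
            f"checkpoint field input_dim={spec.input_dim} does not match "
            f"stored training features of dimension {features.shape[1]}"
        )
    model = ContrastiveEmbedding(features, arrays["train/labels"],
                                 mode=header["mode"], network=spec,
                                 thresholds=thr, feature_config=feat_cfg)
    rng = np.random.default_rng(0)
    net = _network.MLP(spec.input_dim, list(spec.hidden_widths),
                       spec.output_dim, dropout_rate=spec.dropout_rate,
                       batch_norm=spec.batch_norm, rng=rng)
    state = {k[len("state/"):]: v for k, v in arrays.items()
             if k.startswith("state/")}
    net.set_state(state)
    history = pd.DataFrame({"epoch": [], "train_loss": [], "val_error": [],
                            "lr": [], "improved": []})
    cfg = TrainConfig(seed=int(header.get("seed", 0)))
    return ContrastiveEmbeddingResults(model, net, cfg, history)
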