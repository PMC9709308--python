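"""Kernel-weighted nearest-neighbor regression in embedding space.

A query embedding z is localized from its K nearest training embeddings
z_1..z_K with exponentially decaying weights

    w_i = exp(-||z - z_i||^2 / eps) / sum_j exp(-||z - z_j||^2 / eps),
    eps = median(||z - z_1||^2, ..., ||z - z_K||^2),

and the estimate is the weight-averaged neighbor label (per coordinate for
multidimensional labels).  Errors are reported wrap-aware in degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .neighborhoods import angular_distance

__all__ = [
    "LocalizerConfig",
    "LocalizationReport",
    "median_bandwidth",
    "knn_regress",
    "knn_regress_batch",
    "evaluate",
]


@dataclass(frozen=True)
class LocalizerConfig:
    """Regression neighborhood size and weighting scheme."""

    n_neighbors: int = 5
    weight_mode: str = "exponential"  # exponential | inverse_square | uniform
    circular_mean: bool = False       # wrap-aware averaging for full-range az

    def __post_init__(self):
        if self.n_neighbors < 1:
            raise ValueError("n_neighbors must be >= 1")
        if self.weight_mode not in ("exponential", "inverse_square", "uniform"):
            raise ValueError(f"unknown weight_mode {self.weight_mode!r}")


@dataclass
class LocalizationReport:
    """Per-item absolute errors (degrees) and their summary statistics."""

    errors: np.ndarray
    median: float = field(init=False)
    q1: float = field(init=False)
    q3: float = field(init=False)
    maximum: float = field(init=False)

    def __post_init__(self):
        errors = np.asarray(self.errors, dtype=float)
        if errors.size == 0:
            raise ValueError("no errors to summarize")
        if np.any(errors < 0):
            raise ValueError("errors must be non-negative")
        self.errors = errors
        self.median = float(np.median(errors))
        self.q1 = float(np.percentile(errors, 25))
        self.q3 = float(np.percentile(errors, 75))
        self.maximum = float(errors.max())

    def to_dict(self) -> dict:
        return {"median": self.median, "q1": self.q1, "q3": self.q3,
                "max": self.maximum, "n": int(self.errors.size)}


def median_bandwidth(distances_sq: Sequence[float]) -> float:
    """Median of squared neighbor distances (the kernel bandwidth eps)."""
    distances_sq = np.asarray(distances_sq, dtype=float)
    if distances_sq.size == 0:
        raise ValueError("empty distance list")
    return float(np.median(distances_sq))


def _weights(d_sq: np.ndarray, mode: str) -> np.ndarray:
    if mode == "uniform":
        w = np.ones_like(d_sq)
    elif mode == "exponential":
        eps = median_bandwidth(d_sq)
        if eps == 0.0:
            # all neighbors coincide with the query: uniform fallback
            w = np.ones_like(d_sq)
        else:
            w = np.exp(-d_sq / eps)
    else:  # inverse_square
        if np.any(d_sq == 0.0):
            w = (d_sq == 0.0).astype(float)
        else:
            w = 1.0 / d_sq
    return w / w.sum()


def knn_regress(z: np.ndarray, train_coords: np.ndarray,
                train_labels: np.ndarray,
                cfg: LocalizerConfig = LocalizerConfig()) -> np.ndarray:
    """Estimate the latent label of one query embedding.

    ``train_labels`` may be (N,) scalars in degrees or (N, m) coordinates;
    every coordinate is regressed with the same weights.
    """
    z = np.asarray(z, dtype=float).ravel()
    train_coords = np.asarray(train_coords, dtype=float)
    train_labels = np.asarray(train_labels, dtype=float)
    n = train_coords.shape[0]
    if n < cfg.n_neighbors:
        raise ValueError(
            f"need at least {cfg.n_neighbors} training points, have {n}"
        )
    d_sq = ((train_coords - z) ** 2).sum(axis=1)
    order = np.lexsort((np.arange(n), d_sq))  # ties broken by lowest index
    nn = order[: cfg.n_neighbors]
    w = _weights(d_sq[nn], cfg.weight_mode)
    labels = train_labels[nn]
    if labels.ndim == 1 and cfg.circular_mean:
        ang = np.deg2rad(labels)
        est = np.rad2deg(np.angle(np.sum(w * np.exp(1j * ang))))
        return np.asarray(est)
    return w @ labels


def knn_regress_batch(queries: np.ndarray, train_coords: np.ndarray,
                      train_labels: np.ndarray,
                      cfg: LocalizerConfig = LocalizerConfig()) -> np.ndarray:
    """`knn_regress` applied row-wise to a batch of query embeddings."""
    queries = np.atleast_2d(np.asarray(queries, dtype=float))
    return np.array([knn_regress(q, train_coords, train_labels, cfg)
                     for q in queries])


def evaluate(estimates: np.ndarray, truths: np.ndarray) -> LocalizationReport:
    """Wrap-aware absolute angular errors (degrees) with summary stats."""
    estimates = np.asarray(estimates, dtype=float).ravel()
    truths = np.asarray(truths, dtype=float).ravel()
    if estimates.shape != truths.shape:
        raise ValueError(
            f"length mismatch: {estimates.size} estimates vs "
            f"{truths.size} truths"
        )
    return LocalizationReport(angular_distance(estimates, truths))
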