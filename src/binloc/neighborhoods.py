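"""Pair similarity indicators and adaptive margins from source labels.

Two training examples form a *similar* pair when their sources are close in
the latent space: either in angle (supervised; wrap-aware distance d_u with
threshold eps_u in degrees) or in physical position on a radius-Phi ball
around the receiver (weakly supervised; Euclidean distance d_s with
threshold eps_s in meters, eps_s ~ eps_u * Phi * pi / 180).

Each pair also carries a margin mu = logistic(d) in [0.5, 1): dissimilar
pairs with larger latent distance are pushed further apart by the
contrastive loss.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.special import expit

__all__ = [
    "SourceLabel",
    "PairLabel",
    "ThresholdConfig",
    "angular_distance",
    "supervised_indicator",
    "source_distance",
    "angle_to_arc_threshold",
    "adaptive_margin",
    "pair_labels_for_batch",
    "batch_pair_arrays",
]


@dataclass(frozen=True)
class SourceLabel:
    """Direction and/or position of a source relative to the receiver."""

    azimuth_deg: Optional[float] = None
    elevation_deg: Optional[float] = None
    cartesian: Optional[np.ndarray] = None  # meters, 3-vector
    radius_phi: float = 1.0
    group_key: Optional[str] = None

    def __post_init__(self):
        if self.cartesian is not None:
            cart = np.asarray(self.cartesian, dtype=float)
            if cart.shape != (3,):
                raise ValueError("cartesian must be a 3-vector")
            object.__setattr__(self, "cartesian", cart)

    @classmethod
    def from_angles(cls, azimuth_deg: float, elevation_deg: float,
                    radius_phi: float = 1.0) -> "SourceLabel":
        """Frame: x front, y left, z up; az 0 / el 0 -> (Phi, 0, 0)."""
        az = np.deg2rad(azimuth_deg)
        el = np.deg2rad(elevation_deg)
        cart = radius_phi * np.array(
            [np.cos(el) * np.cos(az), np.cos(el) * np.sin(az), np.sin(el)]
        )
        return cls(azimuth_deg=azimuth_deg, elevation_deg=elevation_deg,
                   cartesian=cart, radius_phi=radius_phi)


@dataclass(frozen=True)
class PairLabel:
    """Similarity indicator, latent distance and margin for one pair."""

    indicator: int                 # y_ij in {0, 1}
    latent_distance: float         # d_ij (degrees or meters)
    margin: float                  # mu_ij in [0.5, 1) (or constant)

    def __post_init__(self):
        if self.indicator not in (0, 1):
            raise ValueError("indicator must be 0 or 1")
        if self.latent_distance < 0:
            raise ValueError("latent distance must be >= 0")


@dataclass(frozen=True)
class ThresholdConfig:
    """Similarity thresholds and margin policy."""

    angle_threshold_deg: float = 5.0       # eps_u
    distance_threshold_m: Optional[float] = None  # eps_s; derived if None
    margin_mode: str = "adaptive"          # or "constant"
    constant_margin: float = 1.0
    margin_scale: float = 1.0              # multiplies d before the logistic
    radius_phi: float = 1.0

    def __post_init__(self):
        if self.angle_threshold_deg <= 0:
            raise ValueError("angle threshold must be positive")
        if self.margin_mode not in ("adaptive", "constant"):
            raise ValueError("margin_mode must be 'adaptive' or 'constant'")

    @property
    def eps_s(self) -> float:
        if self.distance_threshold_m is not None:
            return self.distance_threshold_m
        return angle_to_arc_threshold(self.angle_threshold_deg,
                                      self.radius_phi)


def angular_distance(u_i, u_j):
    """Shortest angular distance in degrees, wrap-aware; in [0, 180]."""
    diff = np.abs(np.asarray(u_i, dtype=float) - np.asarray(u_j, dtype=float))
    return np.minimum(diff, 360.0 - diff)


def supervised_indicator(d_u, eps_u: float):
    """y = 1 iff the angular distance is within the threshold (inclusive)."""
    if eps_u <= 0:
        raise ValueError("eps_u must be positive")
    return (np.asarray(d_u, dtype=float) <= eps_u).astype(int)


def source_distance(s_i, s_j):
    """Euclidean distance between Cartesian source positions (meters)."""
    return float(np.linalg.norm(np.asarray(s_i, float) - np.asarray(s_j, float)))


def angle_to_arc_threshold(eps_u: float, phi: float) -> float:
    """Arc length of an angle eps_u (degrees) on a circle of radius phi."""
    return eps_u * phi * np.pi / 180.0


def adaptive_margin(d_ij):
    """Logistic margin mu = exp(d)/(exp(d)+1) = 1/(1+exp(-d)), in [0.5, 1)."""
    d = np.asarray(d_ij, dtype=float)
    if np.any(d < 0):
        raise ValueError("latent distance must be >= 0")
    return expit(d)


def batch_pair_arrays(labels: np.ndarray, cfg: ThresholdConfig,
                      mode: str = "supervised",
                      ) -> Tuple[np.ndarray, np.ndarray, np.ndarray,
                                 np.ndarray, np.ndarray]:
    """Vectorised pair labelling over all C(n,2) unordered distinct pairs.

    ``labels`` is (n,) of angles in degrees for supervised mode, or (n, 3)
    Cartesian positions for weak mode.  Returns (i, j, y, mu, d) arrays of
    length n(n-1)/2.  Used by the training loop; `pair_labels_for_batch`
    is the object-level wrapper.
    """
    labels = np.asarray(labels, dtype=float)
    n = labels.shape[0]
    if n < 2:
        raise ValueError("need at least 2 items to form pairs")
    iu, ju = np.triu_indices(n, k=1)
    if mode == "supervised":
        if labels.ndim != 1:
            raise ValueError("supervised mode expects scalar angle labels")
        d = angular_distance(labels[iu], labels[ju])
        y = supervised_indicator(d, cfg.angle_threshold_deg)
    elif mode == "weak":
        if labels.ndim != 2 or labels.shape[1] != 3:
            raise ValueError("weak mode expects (n, 3) Cartesian labels")
        d = np.linalg.norm(labels[iu] - labels[ju], axis=1)
        y = (d <= cfg.eps_s).astype(int)
    else:
        raise ValueError("mode must be 'supervised' or 'weak'")
    if cfg.margin_mode == "constant":
        mu = np.full(d.shape, cfg.constant_margin)
    else:
        mu = adaptive_margin(cfg.margin_scale * d)
    return iu, ju, y, mu, d


def pair_labels_for_batch(labels: Sequence[SourceLabel], cfg: ThresholdConfig,
                          mode: str = "supervised",
                          task: str = "azimuth") -> List[PairLabel]:
    """Pair labels over all unordered distinct index pairs of a batch.

    In supervised mode the angle of the chosen ``task`` ("azimuth" or
    "elevation") is compared; in weak mode, Cartesian positions (falling
    back to the grouping key, with the constant margin, when positions are
    absent).
    """
    n = len(labels)
    if n < 2:
        raise ValueError("batch must contain at least 2 items")
    if mode == "supervised":
        attr = "azimuth_deg" if task == "azimuth" else "elevation_deg"
        values = np.array([getattr(lab, attr) for lab in labels], dtype=float)
        iu, ju, y, mu, d = batch_pair_arrays(values, cfg, "supervised")
    elif mode == "weak":
        have_cart = all(lab.cartesian is not None for lab in labels)
        if have_cart:
            values = np.stack([lab.cartesian for lab in labels])
            iu, ju, y, mu, d = batch_pair_arrays(values, cfg, "weak")
        else:
            # grouping-key fallback: same key -> similar, constant margin
            keys = [lab.group_key for lab in labels]
            if any(k is None for k in keys):
                raise ValueError(
                    "weak mode needs Cartesian positions or group keys"
                )
            iu, ju = np.triu_indices(n, k=1)
            y = np.array([int(keys[i] == keys[j]) for i, j in zip(iu, ju)])
            d = np.zeros(len(iu))
            mu = np.full(len(iu), cfg.constant_margin)
    else:
        raise ValueError("mode must be 'supervised' or 'weak'")
    return [PairLabel(int(yi), float(di), float(mi))
            for yi, di, mi in zip(y, d, mu)]
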