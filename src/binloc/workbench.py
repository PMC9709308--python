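"""Experiment orchestration: desk-scale study recipes over the synthetic
generator.

Recipes
-------
dropout_sweep      validation error of SCE and the feed-forward model
                   across dropout rates {0.0, 0.2, 0.5, 0.8}
method_comparison  test-set localization error of SCE, LEM and the
                   feed-forward model, per task
reduced_training   error of each method at training fractions
                   {10, 25, 50, 70}%
wsce_sweep         weakly supervised embedding at similarity thresholds
                   eps_u in {5, 15, 30} degrees, localized jointly

Every cell carries its own deterministically derived seed, and a report is
a pure function of (config, seed); reports serialise to JSON/TSV only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .baselines import FeedForwardLocalizer, LaplacianEigenmaps
from .embedding import ContrastiveEmbedding, NetworkSpec, TrainConfig
from .features import FeatureConfig
from .localizer import evaluate
from .neighborhoods import ThresholdConfig, angle_to_arc_threshold
from .synthetic import (HeadModel, SceneConfig, SyntheticDataset,
                        generate_dataset, reduced_training_subset)

__all__ = [
    "ExperimentConfig",
    "ComparisonReport",
    "run_experiment",
    "export_embedding_cloud",
    "plot_embedding_cloud",
]

RECIPES = ("dropout_sweep", "method_comparison", "reduced_training",
           "wsce_sweep")


@dataclass
class ExperimentConfig:
    """A study recipe plus its sweep values and data source."""

    recipe: str
    dropout_values: Sequence[float] = (0.0, 0.2, 0.5, 0.8)
    eps_u_values: Sequence[float] = (5.0, 15.0, 30.0)
    training_fractions: Sequence[float] = (0.10, 0.25, 0.50, 0.70)
    eps_u: float = 5.0
    dropout: float = 0.2
    max_epochs: int = 100
    batch_size: int = 128
    seed: int = 0
    scene: Optional[SceneConfig] = None
    head: Optional[HeadModel] = None
    feat: Optional[FeatureConfig] = None
    lem_m: int = 10

    def __post_init__(self):
        if self.recipe not in RECIPES:
            raise ValueError(f"unknown recipe {self.recipe!r}; "
                             f"choose from {RECIPES}")
        for name in ("dropout_values", "eps_u_values", "training_fractions"):
            if len(getattr(self, name)) == 0:
                raise ValueError(f"{name} must be non-empty")


@dataclass
class ComparisonReport:
    """Per-method, per-task localization reports with full provenance."""

    recipe: str
    cells: Dict[str, dict] = dc_field(default_factory=dict)
    manifest: Dict[str, object] = dc_field(default_factory=dict)
    failures: List[str] = dc_field(default_factory=list)
    embedding_cloud: Optional[pd.DataFrame] = None

    def to_json(self, path=None) -> str:
        payload = {"recipe": self.recipe, "cells": self.cells,
                   "manifest": self.manifest, "failures": self.failures}
        text = json.dumps(payload, indent=1, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _cell_seed(base: int, label: str) -> int:
    import zlib

    return int(np.random.SeedSequence(
        [zlib.crc32(label.encode()), base]).generate_state(1)[0] % (2 ** 31))


def _train_cfg(cfg: ExperimentConfig, label: str) -> TrainConfig:
    return TrainConfig(batch_size=cfg.batch_size, max_epochs=cfg.max_epochs,
                       seed=_cell_seed(cfg.seed, label))


def _sce_task(ds: SyntheticDataset, cfg: ExperimentConfig, task: str,
              eps_u: float, dropout: float, label: str):
    col = "azimuth_deg" if task == "azimuth" else "elevation_deg"
    spec = NetworkSpec(input_dim=ds.train_features.shape[1],
                       dropout_rate=dropout)
    model = ContrastiveEmbedding(
        ds.train_features, ds.train_labels[col].to_numpy(),
        mode="supervised", network=spec,
        thresholds=ThresholdConfig(angle_threshold_deg=eps_u),
        val_features=ds.val_features,
        val_labels=ds.val_labels[col].to_numpy())
    return model.fit(_train_cfg(cfg, label))


def _ff_task(ds: SyntheticDataset, cfg: ExperimentConfig, task: str,
             dropout: float, label: str):
    col = "azimuth_deg" if task == "azimuth" else "elevation_deg"
    spec = NetworkSpec(input_dim=ds.train_features.shape[1],
                       dropout_rate=dropout)
    model = FeedForwardLocalizer(
        ds.train_features, ds.train_labels[col].to_numpy(), network=spec,
        val_features=ds.val_features,
        val_labels=ds.val_labels[col].to_numpy())
    return model.fit(_train_cfg(cfg, label))


def _wsce(ds: SyntheticDataset, cfg: ExperimentConfig, eps_u: float,
          dropout: float, label: str):
    spec = NetworkSpec(input_dim=ds.train_features.shape[1],
                       dropout_rate=dropout)
    cart_cols = ["x_m", "y_m", "z_m"]
    thr = ThresholdConfig(
        angle_threshold_deg=eps_u,
        distance_threshold_m=angle_to_arc_threshold(
            eps_u, ds.scene.radius_phi))
    model = ContrastiveEmbedding(
        ds.train_features, ds.train_labels[cart_cols].to_numpy(),
        mode="weak", network=spec, thresholds=thr,
        val_features=ds.val_features,
        val_labels=ds.val_labels[cart_cols].to_numpy())
    return model.fit(_train_cfg(cfg, label))


def cartesian_to_angles(v: np.ndarray):
    """Unit-frame conversion back to (azimuth, elevation) in degrees."""
    v = np.atleast_2d(np.asarray(v, float))
    az = np.rad2deg(np.arctan2(v[:, 1], v[:, 0]))
    norm = np.maximum(np.linalg.norm(v, axis=1), 1e-12)
    el = np.rad2deg(np.arcsin(np.clip(v[:, 2] / norm, -1.0, 1.0)))
    return az, el


def _evaluate_tasks(az_est, el_est, labels: pd.DataFrame) -> dict:
    out = {}
    if az_est is not None:
        out["azimuth"] = evaluate(
            az_est, labels["azimuth_deg"].to_numpy()).to_dict()
    if el_est is not None:
        out["elevation"] = evaluate(
            el_est, labels["elevation_deg"].to_numpy()).to_dict()
    return out


def run_experiment(cfg: ExperimentConfig) -> ComparisonReport:
    """Run a full recipe; per-cell failures are recorded, not fatal."""
    ds = generate_dataset(cfg.scene, cfg.head, cfg.feat)
    report = ComparisonReport(recipe=cfg.recipe)
    report.manifest = {
        "seed": cfg.seed, "max_epochs": cfg.max_epochs,
        "batch_size": cfg.batch_size, "provenance": ds.provenance,
    }

    def _run(label, fn):
        try:
            report.cells[label] = fn()
        except Exception as exc:  # pragma: no cover - defensive surface
            report.failures.append(f"{label}: {exc!r}")

    if cfg.recipe == "dropout_sweep":
        for rate in cfg.dropout_values:
            def cell(rate=rate):
                out = {}
                for task in ("azimuth", "elevation"):
                    sce = _sce_task(ds, cfg, task, cfg.eps_u, rate,
                                    f"sce/{task}/do{rate}")
                    ff = _ff_task(ds, cfg, task, rate, f"ff/{task}/do{rate}")
                    out[task] = {"sce_val_median": sce.best_val_error,
                                 "ff_val_median": ff.best_val_error}
                return out
            _run(f"dropout={rate}", cell)

    elif cfg.recipe == "method_comparison":
        def sce_cell():
            out = {}
            for task in ("azimuth", "elevation"):
                res = _sce_task(ds, cfg, task, cfg.eps_u, cfg.dropout,
                                f"sce/{task}")
                est = res.localize(ds.test_features).ravel()
                out.update(_evaluate_tasks(
                    est if task == "azimuth" else None,
                    est if task == "elevation" else None, ds.test_labels))
            return out
        _run("sce", sce_cell)

        def ff_cell():
            out = {}
            for task in ("azimuth", "elevation"):
                res = _ff_task(ds, cfg, task, cfg.dropout, f"ff/{task}")
                est = res.predict(ds.test_features)
                out.update(_evaluate_tasks(
                    est if task == "azimuth" else None,
                    est if task == "elevation" else None, ds.test_labels))
            return out
        _run("feedforward", ff_cell)

        def lem_cell():
            cart = ds.train_labels[["x_m", "y_m", "z_m"]].to_numpy()
            res = LaplacianEigenmaps(ds.train_features, m=cfg.lem_m,
                                     labels=cart).fit(n_components=3)
            est = res.localize(ds.test_features)
            az, el = cartesian_to_angles(est)
            return _evaluate_tasks(az, el, ds.test_labels)
        _run("lem", lem_cell)

    elif cfg.recipe == "reduced_training":
        for frac in cfg.training_fractions:
            def cell(frac=frac):
                sub = reduced_training_subset(ds, frac,
                                              _cell_seed(cfg.seed,
                                                         f"frac{frac}"))
                out = {}
                sce = _sce_task(sub, cfg, "azimuth", cfg.eps_u, cfg.dropout,
                                f"sce/az/frac{frac}")
                out["sce"] = _evaluate_tasks(
                    sce.localize(ds.test_features).ravel(), None,
                    ds.test_labels)
                ff = _ff_task(sub, cfg, "azimuth", cfg.dropout,
                              f"ff/az/frac{frac}")
                out["feedforward"] = _evaluate_tasks(
                    ff.predict(ds.test_features), None, ds.test_labels)
                return out
            _run(f"fraction={frac}", cell)

    elif cfg.recipe == "wsce_sweep":
        for eps_u in cfg.eps_u_values:
            def cell(eps_u=eps_u):
                res = _wsce(ds, cfg, eps_u, cfg.dropout, f"wsce/eps{eps_u}")
                est = res.localize(ds.test_features)
                az, el = cartesian_to_angles(est)
                out = _evaluate_tasks(az, el, ds.test_labels)
                out["eps_s_m"] = angle_to_arc_threshold(
                    eps_u, ds.scene.radius_phi)
                if eps_u == cfg.eps_u_values[0]:
                    report.embedding_cloud = export_embedding_cloud(res, ds)
                return out
            _run(f"eps_u={eps_u}", cell)

    return report


def export_embedding_cloud(results, dataset: SyntheticDataset) -> pd.DataFrame:
    """Embed every split and tabulate (z1, z2, z3, azimuth, elevation, split)."""
    frames = []
    for split in ("train", "val", "test"):
        feats = getattr(dataset, f"{split}_features")
        labels = getattr(dataset, f"{split}_labels")
        z = results.embed(feats)
        frames.append(pd.DataFrame({
            "z1": z[:, 0], "z2": z[:, 1], "z3": z[:, 2],
            "azimuth_deg": labels["azimuth_deg"].to_numpy(),
            "elevation_deg": labels["elevation_deg"].to_numpy(),
            "split": split,
        }))
    return pd.concat(frames, ignore_index=True)


def plot_embedding_cloud(cloud: pd.DataFrame, color_by: str = "azimuth_deg",
                         ax=None):
    """3-D scatter of an exported embedding cloud, colored by a label."""
    import matplotlib.pyplot as plt

    if ax is None:
        fig = plt.figure(figsize=(6, 5))
        ax = fig.add_subplot(projection="3d")
    sc = ax.scatter(cloud["z1"], cloud["z2"], cloud["z3"],
                    c=cloud[color_by], s=8, cmap="viridis")
    ax.figure.colorbar(sc, ax=ax, label=color_by)
    ax.set_xlabel("z1"), ax.set_ylabel("z2"), ax.set_zlabel("z3")
    return ax
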