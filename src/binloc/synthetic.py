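"""Desk-scale synthetic binaural data generator.

Produces labeled measurement vectors on an azimuth/elevation grid without
any external recordings.  The generator is deliberately a *cue-domain*
simulator, not a room-acoustics engine: each source direction has a clean
per-bin (ILD, IPD) template derived from a spherical-head model, and
noisy/reverberant conditions are emulated by per-frame complex
perturbations of the template spectra before the standard time-averaging
feature path.

Template equations (versioned "binloc-synth-1"):
  ITD(az)   = (r/c) (sin az + az)                     (Woodworth form)
  IPD_k     = 2 pi f_k ITD(az)
  ILD_k     = sin(az) * g_khz * f_k[kHz]  -  notch(el, f_k)
  notch     = depth * exp(-(f - center(el))^2 / (2 width^2)),
              center(el) affine in elevation (~4.2-6.8 kHz),

so azimuth is encoded in ILD sign/magnitude and IPD slope, and elevation in
the position of a spectral notch — standing in for the pinna filtering that
makes elevation identifiable in real head-related transfer functions.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .features import (BinauralCues, FeatureConfig, SpectrogramPair,
                       assemble_measurement, per_bin_cues, time_average)
from .neighborhoods import SourceLabel

__all__ = [
    "HeadModel",
    "SceneConfig",
    "SyntheticDataset",
    "head_template",
    "corrupt_and_average",
    "generate_dataset",
    "reduced_training_subset",
    "render_waveform",
]

GENERATOR_VERSION = "binloc-synth-1"


def _seed_seq(tag: str, seed: int) -> np.random.SeedSequence:
    """Deterministic seed stream namespaced by a short tag."""
    import zlib

    return np.random.SeedSequence([zlib.crc32(tag.encode()), int(seed)])

LABEL_COLUMNS = ["azimuth_deg", "elevation_deg", "x_m", "y_m", "z_m"]


@dataclass(frozen=True)
class HeadModel:
    """Spherical-head parameters for the clean cue templates."""

    head_radius_m: float = 0.0875
    speed_of_sound: float = 343.0
    ild_gain_db_per_khz: float = 3.0
    # notch center stays >= 2 sigma inside the 7 kHz ILD band edge at every
    # elevation, so the in-band notch energy is elevation-independent
    notch_center_hz: float = 5200.0        # at elevation 0
    notch_slope_hz_per_deg: float = 22.0   # affine elevation dependence
    notch_width_hz: float = 300.0
    notch_depth_db: float = 12.0

    def __post_init__(self):
        if self.head_radius_m <= 0 or self.speed_of_sound <= 0:
            raise ValueError("head radius and speed of sound must be > 0")

    def itd_seconds(self, azimuth_deg: float) -> float:
        theta = np.deg2rad(azimuth_deg)
        return (self.head_radius_m / self.speed_of_sound) * (
            np.sin(theta) + theta)


@dataclass(frozen=True)
class SceneConfig:
    """Grid of source directions and acoustic-condition knobs.

    Defaults mirror the frontal-hemisphere study layout: azimuth in
    [-90, 90] and elevation in [-45, 45] degrees on a 5-degree grid, a
    70/30 train/validation split, and a test draw under a different
    condition seed (unseen "rooms").
    """

    azimuths_deg: Tuple[float, ...] = tuple(range(-90, 91, 5))
    elevations_deg: Tuple[float, ...] = tuple(range(-45, 46, 5))
    repeats: int = 1
    snr_db: float = 15.0
    reverb_strength: float = 0.3
    n_frames: int = 20
    condition_seed: int = 0
    train_fraction: float = 0.7
    radius_phi: float = 1.0

    def __post_init__(self):
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        if not 0.0 <= self.reverb_strength <= 1.0:
            raise ValueError("reverb_strength must be in [0, 1]")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        az = np.asarray(self.azimuths_deg, float)
        el = np.asarray(self.elevations_deg, float)
        if np.any(np.abs(az) > 90) or np.any(np.abs(el) > 45):
            raise ValueError(
                "grids must stay frontal: |az| <= 90, |el| <= 45 degrees"
            )


@dataclass
class SyntheticDataset:
    """Feature/label splits plus full provenance for regeneration."""

    train_features: np.ndarray
    train_labels: pd.DataFrame
    val_features: np.ndarray
    val_labels: pd.DataFrame
    test_features: np.ndarray
    test_labels: pd.DataFrame
    feature_config: FeatureConfig
    scene: SceneConfig
    head: HeadModel

    @property
    def provenance(self) -> dict:
        return {
            "generator": GENERATOR_VERSION,
            "scene": {
                "azimuths_deg": list(self.scene.azimuths_deg),
                "elevations_deg": list(self.scene.elevations_deg),
                "repeats": self.scene.repeats,
                "snr_db": self.scene.snr_db,
                "reverb_strength": self.scene.reverb_strength,
                "n_frames": self.scene.n_frames,
                "condition_seed": self.scene.condition_seed,
                "train_fraction": self.scene.train_fraction,
                "radius_phi": self.scene.radius_phi,
            },
            "head": {k: getattr(self.head, k)
                     for k in ("head_radius_m", "speed_of_sound",
                               "ild_gain_db_per_khz", "notch_center_hz",
                               "notch_slope_hz_per_deg", "notch_width_hz",
                               "notch_depth_db")},
            "features": self.feature_config.to_dict(),
        }


def head_template(azimuth_deg: float, elevation_deg: float,
                  head: HeadModel, cfg: FeatureConfig,
                  ) -> Tuple[np.ndarray, np.ndarray]:
    """Clean per-bin (ILD dB, IPD radians) template over all one-sided bins."""
    if not -90 <= azimuth_deg <= 90:
        raise ValueError("azimuth must be in [-90, 90] degrees")
    if not -45 <= elevation_deg <= 45:
        raise ValueError("elevation must be in [-45, 45] degrees")
    freqs = cfg.bin_freqs_hz
    itd = head.itd_seconds(azimuth_deg)
    ipd = 2.0 * np.pi * freqs * itd
    ipd = np.angle(np.exp(1j * ipd))  # wrap to (-pi, pi]
    center = head.notch_center_hz + head.notch_slope_hz_per_deg * elevation_deg
    notch = head.notch_depth_db * np.exp(
        -((freqs - center) ** 2) / (2.0 * head.notch_width_hz ** 2))
    ild = (np.sin(np.deg2rad(azimuth_deg))
           * head.ild_gain_db_per_khz * freqs / 1000.0) - notch
    return ild, ipd


def _template_spectra(ild: np.ndarray, ipd: np.ndarray) -> Tuple[np.ndarray,
                                                                 np.ndarray]:
    """Split a cue template into symmetric per-channel complex gains."""
    g1 = 10.0 ** (ild / 40.0) * np.exp(+0.5j * ipd)
    g2 = 10.0 ** (-ild / 40.0) * np.exp(-0.5j * ipd)
    return g1, g2


def corrupt_and_average(template: Tuple[np.ndarray, np.ndarray],
                        snr_db: float, reverb_strength: float,
                        n_frames: int, rng: np.random.Generator,
                        dft_size: Optional[int] = None) -> BinauralCues:
    """Simulate noisy/reverberant frames of a template and average them.

    Each channel's clean gain g is perturbed per frame and bin as
    g * (1 + r h_t) + sigma n_t with h an AR(1) (frame-correlated) complex
    process emulating reverberant channel fluctuation, and n white complex
    sensor noise set by ``snr_db``.  With r = 0 and infinite SNR the
    averaged cues equal the template exactly.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    ild, ipd = template
    n_bins = ild.size
    dft_size = dft_size if dft_size is not None else 2 * (n_bins - 1)
    g1, g2 = _template_spectra(ild, ipd)
    sigma = 0.0 if np.isinf(snr_db) else 10.0 ** (-snr_db / 20.0)
    rho = 0.9  # frame-to-frame correlation of the reverberant fluctuation

    def _channel(g):
        s = np.tile(g, (n_frames, 1)).astype(complex)
        if reverb_strength > 0:
            h = np.empty((n_frames, n_bins), dtype=complex)
            scale = np.sqrt(0.5)
            h[0] = scale * (rng.standard_normal(n_bins)
                            + 1j * rng.standard_normal(n_bins))
            innov = np.sqrt(1.0 - rho ** 2)
            for t in range(1, n_frames):
                h[t] = rho * h[t - 1] + innov * scale * (
                    rng.standard_normal(n_bins)
                    + 1j * rng.standard_normal(n_bins))
            s = s * (1.0 + reverb_strength * h)
        if sigma > 0:
            s = s + sigma * np.sqrt(0.5) * (
                rng.standard_normal((n_frames, n_bins))
                + 1j * rng.standard_normal((n_frames, n_bins)))
        return s

    spec = SpectrogramPair(_channel(g1), _channel(g2), dft_size=dft_size,
                           hop=dft_size)
    return time_average(per_bin_cues(spec))


def _labels_frame(az: np.ndarray, el: np.ndarray,
                  phi: float) -> pd.DataFrame:
    carts = np.array([SourceLabel.from_angles(a, e, phi).cartesian
                      for a, e in zip(az, el)])
    return pd.DataFrame({
        "azimuth_deg": az, "elevation_deg": el,
        "x_m": carts[:, 0], "y_m": carts[:, 1], "z_m": carts[:, 2],
    })


def _draw_split(scene: SceneConfig, head: HeadModel, cfg: FeatureConfig,
                seed_entropy) -> Tuple[np.ndarray, pd.DataFrame]:
    rng = np.random.default_rng(seed_entropy)
    az_grid, el_grid = np.meshgrid(scene.azimuths_deg, scene.elevations_deg,
                                   indexing="ij")
    az = np.repeat(az_grid.ravel(), scene.repeats)
    el = np.repeat(el_grid.ravel(), scene.repeats)
    feats = np.empty((az.size, cfg.dimension))
    for i, (a, e) in enumerate(zip(az, el)):
        cues = corrupt_and_average(
            head_template(a, e, head, cfg), scene.snr_db,
            scene.reverb_strength, scene.n_frames, rng,
            dft_size=cfg.dft_size)
        feats[i] = assemble_measurement(cues, cfg).values
    return feats, _labels_frame(az, el, scene.radius_phi)


def generate_dataset(scene: Optional[SceneConfig] = None,
                     head: Optional[HeadModel] = None,
                     feat: Optional[FeatureConfig] = None) -> SyntheticDataset:
    """Generate deterministic train/val/test splits for a scene.

    Train and validation share one condition draw and are split 70/30 at
    random; the test split is a fresh draw of the full grid under
    ``condition_seed + 1`` — different noise and reverberation
    realisations, emulating evaluation in unseen rooms.
    """
    scene = scene or SceneConfig()
    head = head or HeadModel()
    # desk-scale default analysis: K = 128 gives D = 90 at 16 kHz
    feat = feat or FeatureConfig(dft_size=128)
    feats, labels = _draw_split(scene, head, feat,
                                _seed_seq("train", scene.condition_seed))
    n = feats.shape[0]
    rng = np.random.default_rng(_seed_seq("split", scene.condition_seed))
    perm = rng.permutation(n)
    n_train = int(round(scene.train_fraction * n))
    tr, va = perm[:n_train], perm[n_train:]
    test_scene = replace(scene, condition_seed=scene.condition_seed + 1)
    test_feats, test_labels = _draw_split(
        test_scene, head, feat, _seed_seq("test", test_scene.condition_seed))
    return SyntheticDataset(
        train_features=feats[tr],
        train_labels=labels.iloc[tr].reset_index(drop=True),
        val_features=feats[va],
        val_labels=labels.iloc[va].reset_index(drop=True),
        test_features=test_feats,
        test_labels=test_labels,
        feature_config=feat, scene=scene, head=head)


def reduced_training_subset(dataset: SyntheticDataset, fraction: float,
                            seed: int) -> SyntheticDataset:
    """Uniform random subsample of the training split (labels retained)."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    n = dataset.train_features.shape[0]
    n_keep = int(round(fraction * n))
    if n_keep < 1:
        raise ValueError("fraction leaves an empty training set")
    rng = np.random.default_rng(_seed_seq("subset", seed))
    keep = np.sort(rng.permutation(n)[:n_keep])
    return replace(
        dataset,
        train_features=dataset.train_features[keep],
        train_labels=dataset.train_labels.iloc[keep].reset_index(drop=True),
    )


def render_waveform(azimuth_deg: float, elevation_deg: float,
                    head: Optional[HeadModel] = None,
                    cfg: Optional[FeatureConfig] = None,
                    duration_s: float = 1.0,
                    rng: Optional[np.random.Generator] = None):
    """Render a stereo white-noise waveform whose cues follow the template.

    A broadband noise source is shaped in the frequency domain by the
    per-channel complex gains (level difference plus the interaural delay),
    yielding a WAV-writable stereo pair for the external-audio pipeline.
    """
    from .features import StereoWaveform

    head = head or HeadModel()
    cfg = cfg or FeatureConfig()
    rng = rng if rng is not None else np.random.default_rng()
    fs = cfg.sample_rate_hz
    n = int(round(duration_s * fs))
    src = rng.standard_normal(n)
    spectrum = np.fft.rfft(src)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    itd = head.itd_seconds(azimuth_deg)
    center = (head.notch_center_hz
              + head.notch_slope_hz_per_deg * elevation_deg)
    notch = head.notch_depth_db * np.exp(
        -((freqs - center) ** 2) / (2.0 * head.notch_width_hz ** 2))
    ild = (np.sin(np.deg2rad(azimuth_deg))
           * head.ild_gain_db_per_khz * freqs / 1000.0) - notch
    g1 = 10.0 ** (ild / 40.0) * np.exp(+1j * np.pi * freqs * itd)
    g2 = 10.0 ** (-ild / 40.0) * np.exp(-1j * np.pi * freqs * itd)
    left = np.fft.irfft(spectrum * g1, n=n)
    right = np.fft.irfft(spectrum * g2, n=n)
    peak = max(np.abs(left).max(), np.abs(right).max(), 1e-9)
    return StereoWaveform(0.9 * left / peak, 0.9 * right / peak, fs)
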