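"""Binaural cue extraction: stereo waveform -> ILD/IPD measurement vector.

The measurement vector summarises a two-channel recording by time-averaged
interaural level differences (ILDs, in dB) and interaural phase differences
(IPDs, as mean unit phasors) over selected frequency bands:

    alpha_tk = 20 log10 |S1(t,k)| / |S2(t,k)|          (per-frame ILD)
    phi_tk   = angle( S1(t,k) conj(S2(t,k)) )          (per-frame IPD)
    a_k = mean_t alpha_tk,   p_k = mean_t exp(j phi_tk)
    x   = [a_{k1..k2-1}, Re p_{k3}, Im p_{k3}, ..., Re p_{k4-1}, Im p_{k4-1}]

with band-edge bins k_i = round(f_i * K / f_s) and dimension
D = (k2 - k1) + 2 (k4 - k3).  With the default 16 kHz / K = 1024 analysis
and bands [200, 7000] Hz (ILD) and [200, 2500] Hz (IPD) this gives D = 729.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np

__all__ = [
    "StereoWaveform",
    "SpectrogramPair",
    "FeatureConfig",
    "BinauralCues",
    "MeasurementVector",
    "compute_stft",
    "per_bin_cues",
    "time_average",
    "resolve_bins",
    "assemble_measurement",
    "extract_measurement",
]

#: default floor inside the ILD log; silent bins would otherwise give +-inf
DEFAULT_MAGNITUDE_FLOOR = 1e-12

_WINDOWS = ("cosine", "hann", "rect")


def _round_half_away(x: float) -> int:
    """Round to nearest integer, ties away from zero."""
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


@dataclass(frozen=True)
class StereoWaveform:
    """A two-channel (left/right ear) audio signal."""

    samples_left: np.ndarray
    samples_right: np.ndarray
    sample_rate_hz: int

    def __post_init__(self):
        left = np.asarray(self.samples_left, dtype=float)
        right = np.asarray(self.samples_right, dtype=float)
        if left.ndim != 1 or right.ndim != 1:
            raise ValueError("channels must be 1-D sample sequences")
        if left.shape != right.shape:
            raise ValueError(
                f"channel lengths differ: {left.size} vs {right.size}"
            )
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        object.__setattr__(self, "samples_left", left)
        object.__setattr__(self, "samples_right", right)

    @property
    def n_samples(self) -> int:
        return self.samples_left.size

    def swapped(self) -> "StereoWaveform":
        """Left/right channel swap (useful for symmetry checks)."""
        return StereoWaveform(self.samples_right, self.samples_left,
                              self.sample_rate_hz)

    @classmethod
    def from_wav(cls, path) -> "StereoWaveform":
        """Read a stereo WAV file (PCM or float) via scipy."""
        from scipy.io import wavfile

        rate, data = wavfile.read(path)
        if data.ndim != 2 or data.shape[1] != 2:
            raise ValueError(f"{path}: expected a 2-channel WAV file")
        if np.issubdtype(data.dtype, np.integer):
            data = data.astype(float) / float(np.iinfo(data.dtype).max)
        else:
            data = data.astype(float)
        return cls(data[:, 0], data[:, 1], int(rate))


@dataclass(frozen=True)
class SpectrogramPair:
    """One-sided STFTs of the two channels, frames along axis 0."""

    S1: np.ndarray
    S2: np.ndarray
    dft_size: int
    hop: int
    window_kind: str = "cosine"

    def __post_init__(self):
        if self.S1.shape != self.S2.shape:
            raise ValueError("S1 and S2 must have identical shape")
        bins = self.dft_size // 2 + 1
        if self.S1.shape[1] != bins:
            raise ValueError(
                f"expected {bins} one-sided bins, got {self.S1.shape[1]}"
            )

    @property
    def n_frames(self) -> int:
        return self.S1.shape[0]

    @property
    def n_bins(self) -> int:
        return self.S1.shape[1]


@dataclass(frozen=True)
class FeatureConfig:
    """Analysis bands and DFT bookkeeping for the measurement vector.

    Band-edge bins are resolved as k_i = round(f_i * dft_size / f_s); the
    ILD block uses bins [k1, k2) and the IPD block bins [k3, k4), giving
    dimension D = (k2 - k1) + 2 (k4 - k3).
    """

    sample_rate_hz: int = 16000
    dft_size: int = 1024
    ild_band_hz: Tuple[float, float] = (200.0, 7000.0)
    ipd_band_hz: Tuple[float, float] = (200.0, 2500.0)

    def __post_init__(self):
        resolve_bins(self)  # validates

    @property
    def n_bins(self) -> int:
        return self.dft_size // 2 + 1

    @property
    def bin_indices(self) -> Tuple[int, int, int, int]:
        return resolve_bins(self)[:4]

    @property
    def dimension(self) -> int:
        return resolve_bins(self)[4]

    @property
    def bin_freqs_hz(self) -> np.ndarray:
        return np.arange(self.n_bins) * self.sample_rate_hz / self.dft_size

    def to_dict(self) -> dict:
        k1, k2, k3, k4 = self.bin_indices
        return {
            "sample_rate_hz": self.sample_rate_hz,
            "dft_size": self.dft_size,
            "ild_band_hz": list(self.ild_band_hz),
            "ipd_band_hz": list(self.ipd_band_hz),
            "bins": [k1, k2, k3, k4],
            "dimension": self.dimension,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureConfig":
        return cls(
            sample_rate_hz=int(d["sample_rate_hz"]),
            dft_size=int(d["dft_size"]),
            ild_band_hz=tuple(d["ild_band_hz"]),
            ipd_band_hz=tuple(d["ipd_band_hz"]),
        )


@dataclass
class BinauralCues:
    """Per-frame and/or time-averaged interaural cues over all bins."""

    ild_per_frame: Optional[np.ndarray] = None  # (T, bins), dB
    ipd_per_frame: Optional[np.ndarray] = None  # (T, bins), radians
    ild_avg: Optional[np.ndarray] = None        # (bins,), dB
    ipd_avg: Optional[np.ndarray] = None        # (bins,), complex phasor mean


@dataclass(frozen=True)
class MeasurementVector:
    """The D-dimensional concatenated ILD/IPD feature vector."""

    values: np.ndarray
    config: FeatureConfig = field(compare=False)

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.size != self.config.dimension:
            raise ValueError(
                f"vector length {values.size} != config dimension "
                f"{self.config.dimension}"
            )
        if not np.all(np.isfinite(values)):
            raise ValueError("measurement vector contains non-finite entries")
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return self.values.size


def _window(kind: str, n: int) -> np.ndarray:
    if kind == "cosine":
        # sine (half-cosine) window, the standard audio-STFT reading
        return np.sin(np.pi * (np.arange(n) + 0.5) / n)
    if kind == "hann":
        return np.hanning(n)
    if kind == "rect":
        return np.ones(n)
    raise ValueError(f"unknown window kind {kind!r}; choose from {_WINDOWS}")


def compute_stft(wave: StereoWaveform, dft_size: int = 1024,
                 overlap_fraction: float = 0.75,
                 window_kind: str = "cosine") -> SpectrogramPair:
    """One-sided STFT of both channels with hop = dft_size*(1-overlap).

    Frames are taken without padding, so the frame count is
    T = 1 + floor((N - dft_size) / hop).
    """
    if dft_size < 2:
        raise ValueError("dft_size must be >= 2")
    if not 0.0 <= overlap_fraction < 1.0:
        raise ValueError("overlap_fraction must be in [0, 1)")
    hop = int(round(dft_size * (1.0 - overlap_fraction)))
    if hop < 1:
        raise ValueError("overlap too large: hop would be < 1 sample")
    n = wave.n_samples
    if n < dft_size:
        raise ValueError(
            f"signal of {n} samples shorter than one window ({dft_size})"
        )
    win = _window(window_kind, dft_size)
    specs = []
    for sig in (wave.samples_left, wave.samples_right):
        segs = np.lib.stride_tricks.sliding_window_view(sig, dft_size)[::hop]
        specs.append(np.fft.rfft(segs * win, axis=1))
    return SpectrogramPair(specs[0], specs[1], dft_size, hop, window_kind)


def per_bin_cues(spec: SpectrogramPair,
                 magnitude_floor: float = DEFAULT_MAGNITUDE_FLOOR) -> BinauralCues:
    """Per-frame ILD (dB) and IPD (radians) in every time-frequency bin.

    The IPD is the interaural phase *difference*, the angle of
    S1 * conj(S2) (equivalently of S1/S2), in (-pi, pi].
    """
    if magnitude_floor <= 0:
        raise ValueError("magnitude_floor must be positive")
    m1 = np.maximum(np.abs(spec.S1), magnitude_floor)
    m2 = np.maximum(np.abs(spec.S2), magnitude_floor)
    ild = 20.0 * np.log10(m1 / m2)
    ipd = np.angle(spec.S1 * np.conj(spec.S2))
    return BinauralCues(ild_per_frame=ild, ipd_per_frame=ipd)


def time_average(cues: BinauralCues) -> BinauralCues:
    """Average cues across frames: arithmetic mean ILD, mean unit phasor IPD."""
    if cues.ild_per_frame is None or cues.ipd_per_frame is None:
        raise ValueError("per-frame cues required")
    if cues.ild_per_frame.shape[0] == 0:
        raise ValueError("no frames to average (T = 0)")
    ild_avg = cues.ild_per_frame.mean(axis=0)
    ipd_avg = np.exp(1j * cues.ipd_per_frame).mean(axis=0)
    return BinauralCues(ild_per_frame=cues.ild_per_frame,
                        ipd_per_frame=cues.ipd_per_frame,
                        ild_avg=ild_avg, ipd_avg=ipd_avg)


def resolve_bins(cfg: FeatureConfig) -> Tuple[int, int, int, int, int]:
    """Band edges in Hz -> DFT bin indices and feature dimension.

    Returns (k1, k2, k3, k4, D) with k_i = round(f_i K / f_s) and
    D = (k2 - k1) + 2 (k4 - k3).
    """
    nyquist = cfg.sample_rate_hz / 2.0
    for name, (lo, hi) in (("ild", cfg.ild_band_hz), ("ipd", cfg.ipd_band_hz)):
        if lo < 0 or hi < lo:
            raise ValueError(f"{name} band must satisfy 0 <= low <= high")
        if hi > nyquist:
            raise ValueError(
                f"{name} band edge {hi} Hz exceeds Nyquist {nyquist} Hz"
            )
    scale = cfg.dft_size / cfg.sample_rate_hz
    k1 = _round_half_away(cfg.ild_band_hz[0] * scale)
    k2 = _round_half_away(cfg.ild_band_hz[1] * scale)
    k3 = _round_half_away(cfg.ipd_band_hz[0] * scale)
    k4 = _round_half_away(cfg.ipd_band_hz[1] * scale)
    d = (k2 - k1) + 2 * (k4 - k3)
    return k1, k2, k3, k4, d


def assemble_measurement(cues: BinauralCues,
                         cfg: FeatureConfig) -> MeasurementVector:
    """Concatenate banded averaged cues into the measurement vector x.

    Layout: ILDs a_k for k in [k1, k2), then interleaved (Re, Im) of the
    IPD phasor means p_k for k in [k3, k4).
    """
    if cues.ild_avg is None or cues.ipd_avg is None:
        raise ValueError("time-averaged cues required; call time_average first")
    k1, k2, k3, k4, d = resolve_bins(cfg)
    n_bins = cues.ild_avg.size
    if k2 > n_bins or k4 > n_bins:
        raise ValueError(
            f"band bins (k2={k2}, k4={k4}) out of range for {n_bins} bins"
        )
    ild_block = cues.ild_avg[k1:k2]
    phasors = cues.ipd_avg[k3:k4]
    ipd_block = np.empty(2 * phasors.size)
    ipd_block[0::2] = phasors.real
    ipd_block[1::2] = phasors.imag
    return MeasurementVector(np.concatenate([ild_block, ipd_block]), cfg)


def extract_measurement(wave: StereoWaveform, cfg: FeatureConfig,
                        overlap_fraction: float = 0.75,
                        window_kind: str = "cosine",
                        magnitude_floor: float = DEFAULT_MAGNITUDE_FLOOR,
                        ) -> MeasurementVector:
    """Full pipeline: waveform -> STFT -> cues -> averaged -> vector."""
    if wave.sample_rate_hz != cfg.sample_rate_hz:
        raise ValueError(
            f"waveform rate {wave.sample_rate_hz} != config rate "
            f"{cfg.sample_rate_hz}"
        )
    spec = compute_stft(wave, cfg.dft_size, overlap_fraction, window_kind)
    cues = time_average(per_bin_cues(spec, magnitude_floor))
    return assemble_measurement(cues, cfg)
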