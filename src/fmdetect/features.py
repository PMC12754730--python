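"""STFT spectrograms and the three sensor-fusion feature constructions.

Each cleaned sensor channel is turned into a magnitude short-time Fourier
transform on a fixed window grid (default 8 s windows overlapping by 2 s,
i.e. a 6 s hop, giving 0.125 Hz frequency resolution at 512 Hz), truncated
to the 0-30 Hz band of interest.  Three model-input constructions fuse the
six per-sensor spectrograms into a windowed feature matrix:

* model input 1 ("individual") — one dataset per sensor;
* model input 2 ("concatenated") — the six spectrograms stacked
  feature-wise in the fixed array order PZ_a1 ... PZ_a6;
* model input 3 ("summed") — the element-wise sum of the six magnitudes.

Window labels are binary: a window is "movement" when any annotated UDFM
event overlaps it by a positive duration (a 1 s event inside an 8 s window
would be lost to a majority rule), regardless of movement class.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import fft as sfft
from scipy import signal as sps

from .errors import ConfigurationError
from .synthgen import AnnotationTrack


@dataclass
class SpectralConfig:
    window_s: float = 8.0
    overlap_s: float = 2.0
    fs: float = 512.0
    max_freq_hz: float = 30.0
    taper: str | None = "hann"  # analysis taper inside each frame

    def validate(self) -> None:
        if not 0 < self.overlap_s < self.window_s:
            raise ConfigurationError(
                f"need 0 < overlap_s < window_s; got overlap {self.overlap_s}, window {self.window_s}"
            )
        if self.fs <= 0 or self.max_freq_hz <= 0:
            raise ConfigurationError("fs and max_freq_hz must be positive")

    @property
    def hop_s(self) -> float:
        return self.window_s - self.overlap_s

    @property
    def freq_resolution_hz(self) -> float:
        return 1.0 / self.window_s

    @property
    def nperseg(self) -> int:
        return int(round(self.window_s * self.fs))

    @property
    def nhop(self) -> int:
        return int(round(self.hop_s * self.fs))


@dataclass
class Spectrogram:
    """Magnitude STFT of one channel, bins restricted to <= max_freq_hz."""

    magnitudes: np.ndarray  # (n_freq_bins, n_windows)
    freqs_hz: np.ndarray
    window_starts_s: np.ndarray
    channel_id: str = ""

    @property
    def n_windows(self) -> int:
        return self.magnitudes.shape[1]


@dataclass
class WindowedDataset:
    """Fused feature matrix with binary movement labels per window."""

    X: np.ndarray  # (n_windows, n_features)
    y: np.ndarray  # binary, 1 = movement
    window_starts_s: np.ndarray
    scan_id: str = ""
    fusion: str = "individual"  # individual | concatenated | summed
    sensor_id: str = "all"

    def __post_init__(self) -> None:
        if not (self.X.shape[0] == self.y.shape[0] == self.window_starts_s.shape[0]):
            raise ValueError("X rows, y and window_starts_s must align")

    @property
    def n_windows(self) -> int:
        return self.X.shape[0]


def n_windows_for(n_samples: int, config: SpectralConfig) -> int:
    """floor((n - nperseg) / nhop) + 1 windows starting at 0, hop, 2 hop, ..."""
    return (n_samples - config.nperseg) // config.nhop + 1


def compute_stft(signal: np.ndarray, config: SpectralConfig | None = None,
                 channel_id: str = "") -> Spectrogram:
    """Magnitude STFT over the fixed window grid, no padding at either end."""
    config = config or SpectralConfig()
    config.validate()
    x = np.asarray(signal, dtype=float)
    nperseg, nhop = config.nperseg, config.nhop
    if x.size < nperseg:
        raise ValueError(
            f"signal of {x.size} samples is shorter than one {nperseg}-sample window"
        )
    frames = np.lib.stride_tricks.sliding_window_view(x, nperseg)[::nhop]
    if config.taper is not None:
        frames = frames * sps.get_window(config.taper, nperseg)
    freqs = sfft.rfftfreq(nperseg, d=1.0 / config.fs)
    keep = freqs <= config.max_freq_hz + 1e-9
    magnitudes = np.abs(sfft.rfft(frames, axis=1))[:, keep].T
    starts = np.arange(frames.shape[0]) * nhop / config.fs
    return Spectrogram(magnitudes=magnitudes, freqs_hz=freqs[keep],
                       window_starts_s=starts, channel_id=channel_id)


def label_windows(window_starts_s: np.ndarray, config: SpectralConfig,
                  track: AnnotationTrack) -> np.ndarray:
    """Binary labels: 1 where any UDFM event overlaps [start, start + window_s)."""
    starts = np.asarray(window_starts_s, dtype=float)
    y = np.zeros(starts.shape[0], dtype=int)
    for ev in track.events:
        overlap = (ev.onset_s < starts + config.window_s) & (ev.end_s > starts)
        y[overlap] = 1
    return y


def _check_grid(spectrograms: list[Spectrogram] | tuple[Spectrogram, ...]) -> None:
    if not spectrograms:
        raise ValueError("no spectrograms given")
    ref = spectrograms[0]
    for sp in spectrograms[1:]:
        if sp.n_windows != ref.n_windows or not np.allclose(sp.window_starts_s,
                                                            ref.window_starts_s):
            raise ValueError(
                f"window-grid mismatch between channels {ref.channel_id!r} and {sp.channel_id!r}"
            )


def fuse_individual(spectrograms, y: np.ndarray, scan_id: str = "") -> list[WindowedDataset]:
    """Model input 1: one dataset per sensor, labels replicated."""
    _check_grid(spectrograms)
    y = np.asarray(y)
    return [
        WindowedDataset(X=sp.magnitudes.T.copy(), y=y.copy(),
                        window_starts_s=sp.window_starts_s.copy(),
                        scan_id=scan_id, fusion="individual",
                        sensor_id=sp.channel_id or f"sensor{i}")
        for i, sp in enumerate(spectrograms)
    ]


def fuse_concatenated(spectrograms, y: np.ndarray, scan_id: str = "") -> WindowedDataset:
    """Model input 2: per-sensor frequency bins concatenated in array order."""
    _check_grid(spectrograms)
    X = np.hstack([sp.magnitudes.T for sp in spectrograms])
    return WindowedDataset(X=X, y=np.asarray(y).copy(),
                           window_starts_s=spectrograms[0].window_starts_s.copy(),
                           scan_id=scan_id, fusion="concatenated", sensor_id="all")


def fuse_summed(spectrograms, y: np.ndarray, scan_id: str = "") -> WindowedDataset:
    """Model input 3: element-wise sum of the six magnitude spectrograms."""
    _check_grid(spectrograms)
    ref = spectrograms[0]
    for sp in spectrograms[1:]:
        if sp.magnitudes.shape != ref.magnitudes.shape or not np.allclose(sp.freqs_hz, ref.freqs_hz):
            raise ValueError("frequency-bin grid mismatch between channels")
    total = np.sum([sp.magnitudes for sp in spectrograms], axis=0)
    return WindowedDataset(X=total.T, y=np.asarray(y).copy(),
                           window_starts_s=ref.window_starts_s.copy(),
                           scan_id=scan_id, fusion="summed", sensor_id="all")


def save_dataset(dataset: WindowedDataset, path: str | Path) -> None:
    """Features to ``<path>.csv``; labels and metadata to ``<path>.json``."""
    base = Path(path)
    if base.suffix in (".csv", ".json"):
        base = base.with_suffix("")
    pd.DataFrame(dataset.X).to_csv(base.with_suffix(".csv"), index=False)
    meta = {
        "y": dataset.y.astype(int).tolist(),
        "window_starts_s": dataset.window_starts_s.tolist(),
        "scan_id": dataset.scan_id,
        "fusion": dataset.fusion,
        "sensor_id": dataset.sensor_id,
    }
    base.with_suffix(".json").write_text(json.dumps(meta))


def load_dataset(path: str | Path) -> WindowedDataset:
    base = Path(path)
    if base.suffix in (".csv", ".json"):
        base = base.with_suffix("")
    X = pd.read_csv(base.with_suffix(".csv")).to_numpy()
    meta = json.loads(base.with_suffix(".json").read_text())
    return WindowedDataset(X=X, y=np.asarray(meta["y"], dtype=int),
                           window_starts_s=np.asarray(meta["window_starts_s"], dtype=float),
                           scan_id=meta["scan_id"], fusion=meta["fusion"],
                           sensor_id=meta["sensor_id"])
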