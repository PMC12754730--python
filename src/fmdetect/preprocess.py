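"""Signal-cleaning chain for the vibroacoustic channels.

The stages, applied in this fixed order by :func:`preprocess_pipeline`:

1. synchronise all channels and annotations to the sync button press;
2. remove each sensor channel's DC offset (subtract the mean);
3. RMS-normalise each sensor channel (unit root-mean-square);
4. zero sensor samples where the probe IMU magnitude exceeds a threshold
   (ultrasound-probe motion artefacts; candidate thresholds 4, 5, 6 on the
   raw IMU scale);
5. low-pass filter at 30 Hz with a Kaiser-window FIR (fetal movements live
   below ~30 Hz), applied with group-delay compensation so the output stays
   aligned with the annotation timeline.

The IMU threshold is applied to the *raw* IMU magnitude: the candidate
integer thresholds are absolute values and normalising the IMU would make
them meaningless.  Gated (zeroed) segments are retained in the RMS
computation and in downstream training windows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

from .errors import ConfigurationError
from .synthgen import AnnotationTrack, MovementEvent, Recording

logger = logging.getLogger(__name__)


@dataclass
class NoiseCancelConfig:
    """IMU-gated probe-noise cancellation parameters."""

    imu_threshold: float = 5.0
    guard_s: float = 0.0

    def validate(self) -> None:
        if self.imu_threshold <= 0:
            raise ConfigurationError("imu_threshold must be positive")
        if self.guard_s < 0:
            raise ConfigurationError("guard_s must be non-negative")


@dataclass
class FilterConfig:
    """30 Hz Kaiser-window FIR low-pass.

    The transition band runs from ``cutoff_hz`` to ``cutoff_hz +
    transition_hz`` with at least ``ripple_db`` stopband attenuation; the
    Kaiser beta and tap count come from the standard Kaiser design formula.
    """

    cutoff_hz: float = 30.0
    fs: float = 512.0
    transition_hz: float = 5.0
    ripple_db: float = 45.0

    def validate(self) -> None:
        if not 0 < self.cutoff_hz < self.fs / 2:
            raise ConfigurationError(
                f"cutoff_hz must lie in (0, fs/2); got {self.cutoff_hz} at fs={self.fs}"
            )
        if self.cutoff_hz + self.transition_hz >= self.fs / 2:
            raise ConfigurationError("transition band extends past Nyquist")


def remove_offset(signal: np.ndarray) -> np.ndarray:
    """Subtract the signal mean; output is zero-mean with the same shape."""
    x = np.asarray(signal, dtype=float)
    if x.size == 0:
        raise ValueError("cannot remove offset of an empty signal")
    return x - x.mean()


def rms_normalise(signal: np.ndarray) -> np.ndarray:
    """Divide by the root-mean-square value; output has unit RMS."""
    x = np.asarray(signal, dtype=float)
    if x.size == 0:
        raise ValueError("cannot normalise an empty signal")
    rms = float(np.sqrt(np.mean(x ** 2)))
    if rms == 0.0:
        raise ValueError("zero RMS: degenerate (all-zero) channel")
    return x / rms


def probe_noise_mask(imu: np.ndarray, config: NoiseCancelConfig, fs: float = 512.0) -> np.ndarray:
    """Boolean mask of samples gated out: |imu| > threshold, padded by guard_s."""
    config.validate()
    mask = np.abs(np.asarray(imu, dtype=float)) > config.imu_threshold
    guard = int(round(config.guard_s * fs))
    if guard > 0 and mask.any():
        kernel = np.ones(2 * guard + 1)
        mask = np.convolve(mask.astype(float), kernel, mode="same") > 0
    return mask


def cancel_probe_noise(sensors: np.ndarray, imu: np.ndarray, config: NoiseCancelConfig,
                       fs: float = 512.0) -> np.ndarray:
    """Zero all sensor channels wherever the IMU exceeds its threshold."""
    sensors = np.asarray(sensors, dtype=float)
    imu = np.asarray(imu, dtype=float)
    if sensors.shape[-1] != imu.shape[0]:
        raise ValueError(
            f"sensors ({sensors.shape[-1]} samples) and imu ({imu.shape[0]}) lengths differ"
        )
    mask = probe_noise_mask(imu, config, fs)
    out = sensors.copy()
    out[..., mask] = 0.0
    return out


def synchronise(recording: Recording, track: AnnotationTrack) -> tuple[Recording, AnnotationTrack]:
    """Shift the time origin to the first button press and drop earlier samples.

    Annotation onsets and MPM press times shift identically; events or
    presses that fall before the sync press are dropped with a warning.
    """
    press_idx = np.flatnonzero(recording.button >= 0.5)
    if press_idx.size == 0:
        raise ValueError("no sync press found in the button channel")
    i0 = int(press_idx[0])
    t0 = i0 / recording.fs
    new_rec = Recording(
        sensors=recording.sensors[:, i0:].copy(),
        imu=recording.imu[i0:].copy(),
        button=recording.button[i0:].copy(),
        fs=recording.fs,
        subject_id=recording.subject_id,
        scan_id=recording.scan_id,
        gestation_weeks=recording.gestation_weeks,
        channel_names=recording.channel_names,
    )
    events: list[MovementEvent] = []
    for ev in track.events:
        onset = ev.onset_s - t0
        if onset < 0:
            logger.warning("dropping event at %.3f s: before the sync press at %.3f s",
                           ev.onset_s, t0)
            continue
        events.append(MovementEvent(onset, ev.duration_s, ev.movement_class, ev.perceived))
    presses = [p - t0 for p in track.mpm_press_s if p - t0 >= 0]
    dropped = len(track.mpm_press_s) - len(presses)
    if dropped:
        logger.warning("dropping %d MPM press(es) before the sync press", dropped)
    new_track = AnnotationTrack(events=events, scan_id=track.scan_id,
                                mpm_press_s=presses, sync_press_s=0.0)
    return new_rec, new_track


def design_lowpass(config: FilterConfig) -> np.ndarray:
    """Kaiser-window FIR taps (odd length, linear phase)."""
    config.validate()
    nyq = config.fs / 2.0
    numtaps, beta = sps.kaiserord(config.ripple_db, config.transition_hz / nyq)
    numtaps += 1 - numtaps % 2  # odd length -> integer group delay (L-1)/2
    cutoff = config.cutoff_hz + config.transition_hz / 2.0  # -6 dB at mid-transition
    return sps.firwin(numtaps, cutoff, window=("kaiser", beta), fs=config.fs)


def lowpass(signal: np.ndarray, config: FilterConfig | None = None) -> np.ndarray:
    """Apply the FIR low-pass with group-delay compensation.

    ``mode='same'`` convolution with the odd-length linear-phase kernel
    shifts the output back by (L-1)/2 taps, so filtered samples stay
    aligned with the annotation timeline.
    """
    config = config or FilterConfig()
    x = np.asarray(signal, dtype=float)
    taps = design_lowpass(config)
    if x.size == 0:
        return x.copy()
    return sps.fftconvolve(x, taps, mode="same")


def export_taps(config: FilterConfig, path) -> None:
    """Write the filter coefficients as a one-column CSV for inspection."""
    np.savetxt(path, design_lowpass(config), delimiter=",", header="tap", comments="")


def preprocess_pipeline(recording: Recording, track: AnnotationTrack,
                        noise_cfg: NoiseCancelConfig | None = None,
                        filter_cfg: FilterConfig | None = None,
                        ) -> tuple[Recording, AnnotationTrack]:
    """Full cleaning chain: sync -> de-offset -> RMS -> IMU gating -> low-pass."""
    noise_cfg = noise_cfg or NoiseCancelConfig()
    filter_cfg = filter_cfg or FilterConfig()
    if filter_cfg.fs != recording.fs:
        filter_cfg = replace(filter_cfg, fs=recording.fs)
    rec, track = synchronise(recording, track)
    cleaned = np.empty_like(rec.sensors)
    for ch, name in enumerate(rec.channel_names):
        try:
            cleaned[ch] = rms_normalise(remove_offset(rec.sensors[ch]))
        except ValueError as exc:
            raise ValueError(f"channel {name}: {exc}") from exc
    cleaned = cancel_probe_noise(cleaned, rec.imu, noise_cfg, fs=rec.fs)
    for ch in range(cleaned.shape[0]):
        cleaned[ch] = lowpass(cleaned[ch], filter_cfg)
    out = Recording(sensors=cleaned, imu=rec.imu, button=rec.button, fs=rec.fs,
                    subject_id=rec.subject_id, scan_id=rec.scan_id,
                    gestation_weeks=rec.gestation_weeks, channel_names=rec.channel_names)
    return out, track
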