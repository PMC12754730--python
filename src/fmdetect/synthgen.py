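"""Synthetic annotated vibroacoustic scan sessions.

Clinical sessions pair a six-channel abdominal sensor array (three
piezoelectric, three acoustic contact microphones) with an IMU mounted on
the ultrasound probe and a hand-held push button, all sampled at 512 Hz.
A sonographer calls out fetal movements in real time (UDFM events of four
classes: general, breathing, startle, limb), and the participant presses
the button for movements she perceives (MPM).  This module emulates that
statistical structure so the downstream pipeline can be exercised and
tested end to end:

* ~1 s movement bursts, band-limited below 30 Hz, occupying ~13% of a
  30-minute session at the default event rate;
* per-channel gain, noise and DC-offset heterogeneity;
* probe-motion artefact episodes co-registered with elevated IMU readings;
* a synchronisation button press in the first 30 s of each session;
* partial maternal perception: each UDFM event independently triggers an
  MPM press (0-2 s after onset) with probability ``perception_prob``.

The burst waveform (exponentially damped sinusoid packets, carrier 1-25 Hz)
is a stand-in for the unpublished clinical signal morphology; only its
band-limitation and energy/duration statistics are asserted downstream.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError

SENSOR_CHANNELS: tuple[str, ...] = ("PZ_a1", "PZ_a2", "M_a3", "M_a4", "M_a5", "PZ_a6")
DEFAULT_MODALITIES: tuple[str, ...] = ("piezo", "piezo", "acoustic", "acoustic", "acoustic", "piezo")
EVENT_CLASSES: tuple[str, ...] = ("general", "breathing", "startle", "limb")

# Duration multipliers are mix-weighted to 1.0 so the expected active time
# stays event_rate * event_duration_s.  Startle events are short and large,
# breathing episodes long, small and amplitude-modulated.
_CLASS_DURATION_MULT = {"general": 1.03, "limb": 0.93, "breathing": 1.65, "startle": 0.41}
_CLASS_AMPLITUDE = {"general": 1.0, "limb": 1.2, "breathing": 0.45, "startle": 2.2}

_SYNC_PRESS_WINDOW_S = 30.0  # the sync press always falls in the first 30 s
_PRESS_WIDTH_S = 0.2


@dataclass
class SessionConfig:
    """Parameters of one synthetic scan session.

    ``event_rate`` and ``probe_episode_rate`` default to 240 events and 8
    probe-motion episodes per 30 minutes, scaled by the session duration.
    ``None`` means "use the scaled default".
    """

    duration_s: float = 1800.0
    fs: float = 512.0
    n_sensors: int = 6
    modalities: tuple[str, ...] = DEFAULT_MODALITIES
    event_rate: float | None = None
    event_duration_s: float = 1.0
    event_class_mix: dict[str, float] = field(
        default_factory=lambda: {"general": 0.40, "limb": 0.30, "breathing": 0.15, "startle": 0.15}
    )
    perception_prob: float = 0.61
    perception_latency_s: float = 2.0
    probe_episode_rate: float | None = None
    probe_episode_duration_s: float = 3.0
    probe_noise_sd: float = 1.5
    event_amplitude: float = 1.0
    sensor_gains: tuple[float, ...] = (1.0, 0.9, 0.6, 0.55, 0.5, 0.8)
    sensor_noise_sd: tuple[float, ...] = (0.20, 0.30, 0.25, 0.35, 0.30, 0.22)
    sensor_offsets: tuple[float, ...] = (1.5, -0.8, 0.6, -1.2, 2.0, 0.4)
    subject_id: str = "synthetic"
    scan_id: str = "scan00"
    gestation_weeks: float = 34.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.event_rate is None:
            self.event_rate = 240.0 * (self.duration_s / 1800.0)
        if self.probe_episode_rate is None:
            self.probe_episode_rate = 8.0 * (self.duration_s / 1800.0)

    def validate(self) -> None:
        if self.duration_s <= 0:
            raise ConfigurationError("duration_s must be positive")
        if self.fs <= 0:
            raise ConfigurationError("fs must be positive")
        if not 0.0 <= self.perception_prob <= 1.0:
            raise ConfigurationError("perception_prob must lie in [0, 1]")
        if self.event_rate < 0:
            raise ConfigurationError("event_rate must be non-negative")
        mix_total = sum(self.event_class_mix.values())
        if abs(mix_total - 1.0) > 1e-9:
            raise ConfigurationError(f"event_class_mix must sum to 1, got {mix_total}")
        if set(self.event_class_mix) - set(EVENT_CLASSES):
            raise ConfigurationError(f"unknown event classes in mix: {self.event_class_mix}")
        for name in ("modalities", "sensor_gains", "sensor_noise_sd", "sensor_offsets"):
            if len(getattr(self, name)) != self.n_sensors:
                raise ConfigurationError(f"{name} must have length n_sensors={self.n_sensors}")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fs))

    @property
    def expected_active_fraction(self) -> float:
        """Expected fraction of session time covered by movement events."""
        return self.event_rate * self.event_duration_s / self.duration_s


@dataclass
class MovementEvent:
    onset_s: float
    duration_s: float
    movement_class: str
    perceived: bool

    @property
    def end_s(self) -> float:
        return self.onset_s + self.duration_s


@dataclass
class AnnotationTrack:
    """UDFM events plus MPM press times for one scan.

    ``mpm_press_s`` excludes the synchronisation press, which is stored
    separately in ``sync_press_s``.
    """

    events: list[MovementEvent]
    scan_id: str = ""
    mpm_press_s: list[float] = field(default_factory=list)
    sync_press_s: float = 0.0

    @property
    def n_events(self) -> int:
        return len(self.events)

    def active_fraction(self, duration_s: float) -> float:
        """Fraction of the session overlapped by (non-overlapping) events."""
        return sum(ev.duration_s for ev in self.events) / duration_s

    def validate(self, duration_s: float | None = None) -> None:
        onsets = [ev.onset_s for ev in self.events]
        if any(o < 0 for o in onsets):
            raise ValidationError("event onsets must be non-negative")
        if onsets != sorted(onsets):
            raise ValidationError("events must be sorted by onset")
        for prev, nxt in zip(self.events, self.events[1:]):
            if nxt.onset_s < prev.end_s - 1e-9:
                raise ValidationError(
                    f"events may not overlap: event at {prev.onset_s:.3f}s ends after "
                    f"the next onset {nxt.onset_s:.3f}s"
                )
        for ev in self.events:
            if ev.movement_class not in EVENT_CLASSES:
                raise ValidationError(f"unknown movement class {ev.movement_class!r}")
            if duration_s is not None and ev.end_s > duration_s + 1e-6:
                raise ValidationError("event extends past the session duration")


@dataclass
class Recording:
    """One multichannel session: 6 sensor channels, IMU and button."""

    sensors: np.ndarray  # shape (n_sensors, n_samples)
    imu: np.ndarray
    button: np.ndarray
    fs: float
    subject_id: str = "synthetic"
    scan_id: str = ""
    gestation_weeks: float = 34.0
    channel_names: tuple[str, ...] = SENSOR_CHANNELS

    @property
    def n_samples(self) -> int:
        return self.sensors.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def validate(self) -> None:
        n = self.sensors.shape[1]
        if self.imu.shape[0] != n or self.button.shape[0] != n:
            raise ValidationError("all channels must share the same sample count")
        if self.sensors.shape[0] != len(self.channel_names):
            raise ValidationError(
                f"expected {len(self.channel_names)} sensor channels, got {self.sensors.shape[0]}"
            )
        sync_region = self.button[: int(round(_SYNC_PRESS_WINDOW_S * self.fs))]
        if not np.any(sync_region >= 0.5):
            raise ValidationError("missing sync press in the first 30 s of the button channel")


def _damped_packet(rng: np.random.Generator, duration_s: float, fs: float, movement_class: str,
                   amplitude_scale: float) -> np.ndarray:
    """One band-limited movement burst: damped sinusoid, carrier 1-25 Hz."""
    n = max(int(round(duration_s * fs)), 4)
    t = np.arange(n) / fs
    amp = _CLASS_AMPLITUDE[movement_class] * amplitude_scale * rng.lognormal(0.0, 0.25)
    envelope = np.exp(-3.0 * t / duration_s)
    # soft attack over the first 5% avoids a step edge (broadband splatter)
    attack = np.clip(t / (0.05 * duration_s + 1e-9), 0.0, 1.0)
    # a movement transient excites several modes, not a pure tone: three
    # damped carriers with geometrically decaying amplitudes, all in 1-25 Hz
    tone = np.zeros(n)
    for k in range(3):
        carrier_hz = rng.uniform(1.0, 25.0)
        phase = rng.uniform(0.0, 2.0 * np.pi)
        tone += 0.6 ** k * np.sin(2.0 * np.pi * carrier_hz * t + phase)
    wave = amp * envelope * attack * tone
    if movement_class == "breathing":
        wave *= 0.55 + 0.45 * np.sin(2.0 * np.pi * 1.1 * t)
    return wave


def _place_events(rng: np.random.Generator, config: SessionConfig) -> list[tuple[float, float, str]]:
    """Draw (onset, duration, class) triples, non-overlapping, sorted."""
    n_events = rng.poisson(config.event_rate) if config.event_rate > 0 else 0
    classes = list(config.event_class_mix)
    probs = np.array([config.event_class_mix[c] for c in classes])
    placed: list[tuple[float, float, str]] = []
    attempts = 0
    while len(placed) < n_events and attempts < 60 * max(n_events, 1):
        attempts += 1
        klass = classes[rng.choice(len(classes), p=probs)]
        mean_dur = _CLASS_DURATION_MULT[klass] * config.event_duration_s
        dur = float(np.clip(rng.normal(mean_dur, 0.20 * mean_dur), 0.15, config.duration_s))
        if dur >= config.duration_s:
            continue
        onset = rng.uniform(0.0, config.duration_s - dur)
        if all(onset + dur + 0.05 <= o or onset >= o + d + 0.05 for o, d, _ in placed):
            placed.append((onset, dur, klass))
    placed.sort(key=lambda e: e[0])
    return placed


def generate_recording(config: SessionConfig) -> tuple[Recording, AnnotationTrack]:
    """Generate one synthetic session; bit-identical for a given seed.

    The integer seed expands into independent substreams: one per sensor
    channel (baseline noise), plus streams for event synthesis, IMU/probe
    artefacts, and button/perception, so per-channel noise is reproducible
    independently of what the other streams consume.
    """
    config.validate()
    n = config.n_samples
    fs = config.fs
    children = np.random.SeedSequence(config.seed).spawn(config.n_sensors + 3)
    sensor_rngs = [np.random.default_rng(s) for s in children[: config.n_sensors]]
    rng_events = np.random.default_rng(children[config.n_sensors])
    rng_imu = np.random.default_rng(children[config.n_sensors + 1])
    rng_button = np.random.default_rng(children[config.n_sensors + 2])

    sensors = np.empty((config.n_sensors, n))
    for ch, rng in enumerate(sensor_rngs):
        sensors[ch] = config.sensor_offsets[ch] + rng.normal(0.0, config.sensor_noise_sd[ch], n)

    # movement events
    events: list[MovementEvent] = []
    for onset, dur, klass in _place_events(rng_events, config):
        wave = _damped_packet(rng_events, dur, fs, klass, config.event_amplitude)
        weights = rng_events.uniform(0.3, 1.0, config.n_sensors)  # per-event sensor emphasis
        i0 = int(round(onset * fs))
        i1 = min(i0 + wave.size, n)
        for ch in range(config.n_sensors):
            sensors[ch, i0:i1] += config.sensor_gains[ch] * weights[ch] * wave[: i1 - i0]
        events.append(MovementEvent(onset, dur, klass, perceived=False))

    # IMU: unit-variance quiescent noise; probe episodes raise |imu| to 4-8x
    imu = rng_imu.normal(0.0, 1.0, n)
    n_episodes = rng_imu.poisson(config.probe_episode_rate)
    probe_mask = np.zeros(n, dtype=bool)
    for _ in range(n_episodes):
        dur = float(np.clip(rng_imu.exponential(config.probe_episode_duration_s), 0.5, 10.0))
        start = rng_imu.uniform(0.0, max(config.duration_s - dur, 0.0))
        i0, i1 = int(round(start * fs)), min(int(round((start + dur) * fs)), n)
        probe_mask[i0:i1] = True
    n_mask = int(probe_mask.sum())
    if n_mask:
        imu[probe_mask] = rng_imu.uniform(4.0, 8.0, n_mask) * rng_imu.choice([-1.0, 1.0], n_mask)
        sensors[:, probe_mask] += rng_imu.normal(0.0, config.probe_noise_sd,
                                                 (config.n_sensors, n_mask))

    # button: one sync press in the first 30 s, then MPM presses
    button = np.zeros(n)
    sync_s = float(rng_button.uniform(2.0, min(25.0, 0.9 * config.duration_s)))
    press_w = int(round(_PRESS_WIDTH_S * fs))
    i0 = int(round(sync_s * fs))
    button[i0: i0 + press_w] = 1.0
    mpm_press_s: list[float] = []
    for ev in events:
        if rng_button.uniform() < config.perception_prob:
            ev.perceived = True
            press = ev.onset_s + rng_button.uniform(0.0, config.perception_latency_s)
            if press < config.duration_s:
                j0 = int(round(press * fs))
                button[j0: j0 + press_w] = 1.0
                mpm_press_s.append(float(press))

    recording = Recording(sensors=sensors, imu=imu, button=button, fs=fs,
                          subject_id=config.subject_id, scan_id=config.scan_id,
                          gestation_weeks=config.gestation_weeks)
    track = AnnotationTrack(events=events, scan_id=config.scan_id,
                            mpm_press_s=sorted(mpm_press_s), sync_press_s=sync_s)
    track.validate(config.duration_s)
    return recording, track


# ---------------------------------------------------------------------------
# on-disk schema: one columnar CSV per scan plus a JSON annotation sidecar
# ---------------------------------------------------------------------------

def _paths(path: str | Path) -> tuple[Path, Path]:
    base = Path(path)
    if base.suffix in (".csv", ".json"):
        base = base.with_suffix("")
    return base.with_suffix(".csv"), base.with_suffix(".json")


def write_recording(recording: Recording, track: AnnotationTrack, path: str | Path) -> tuple[Path, Path]:
    """Write ``<path>.csv`` (t + 8 channels, one row per sample) and ``<path>.json``."""
    csv_path, json_path = _paths(path)
    n = recording.n_samples
    columns: dict[str, np.ndarray] = {"t": np.arange(n) / recording.fs}
    for ch, name in enumerate(recording.channel_names):
        columns[name] = recording.sensors[ch]
    columns["IMU"] = recording.imu
    columns["BUTTON"] = recording.button
    pd.DataFrame(columns).to_csv(csv_path, index=False, float_format="%.10g")
    sidecar = {
        "scan_id": track.scan_id,
        "subject_id": recording.subject_id,
        "gestation_weeks": recording.gestation_weeks,
        "fs": recording.fs,
        "sync_press_s": track.sync_press_s,
        "mpm_press_s": list(track.mpm_press_s),
        "events": [
            {"onset_s": ev.onset_s, "duration_s": ev.duration_s,
             "class": ev.movement_class, "perceived": ev.perceived}
            for ev in track.events
        ],
    }
    json_path.write_text(json.dumps(sidecar, indent=1))
    return csv_path, json_path


def read_recording(path: str | Path) -> tuple[Recording, AnnotationTrack]:
    """Read and validate a scan written by :func:`write_recording`.

    Raises :class:`ValidationError` naming the violated invariant for
    malformed files (wrong channel count, missing sync press, unsorted or
    overlapping events).
    """
    csv_path, json_path = _paths(path)
    frame = pd.read_csv(csv_path)
    meta = json.loads(json_path.read_text())
    sensor_cols = [c for c in frame.columns if c not in ("t", "IMU", "BUTTON")]
    if len(sensor_cols) != len(SENSOR_CHANNELS):
        raise ValidationError(
            f"expected {len(SENSOR_CHANNELS)} sensor channels, got {len(sensor_cols)}: {sensor_cols}"
        )
    for col in ("IMU", "BUTTON"):
        if col not in frame.columns:
            raise ValidationError(f"missing required channel column {col!r}")
    recording = Recording(
        sensors=frame[sensor_cols].to_numpy().T,
        imu=frame["IMU"].to_numpy(),
        button=frame["BUTTON"].to_numpy(),
        fs=float(meta["fs"]),
        subject_id=str(meta.get("subject_id", "")),
        scan_id=str(meta.get("scan_id", "")),
        gestation_weeks=float(meta.get("gestation_weeks", float("nan"))),
        channel_names=tuple(sensor_cols),
    )
    recording.validate()
    track = AnnotationTrack(
        events=[
            MovementEvent(float(ev["onset_s"]), float(ev["duration_s"]),
                          str(ev["class"]), bool(ev["perceived"]))
            for ev in meta["events"]
        ],
        scan_id=str(meta.get("scan_id", "")),
        mpm_press_s=[float(p) for p in meta.get("mpm_press_s", [])],
        sync_press_s=float(meta.get("sync_press_s", 0.0)),
    )
    track.validate(recording.duration_s)
    return recording, track


def replace_config(config: SessionConfig, **changes) -> SessionConfig:
    """dataclasses.replace that re-runs the scaled-default resolution."""
    return dataclasses.replace(config, **changes)


def make_threshold_validation_scan(seed: int = 0, artefact_seed: int = 12345,
                                   duration_s: float = 420.0,
                                   ) -> tuple[Recording, AnnotationTrack]:
    """A scan constructed so an IMU gating threshold of 5 is exactly right.

    Two manipulations are injected into the held-out final 30% of an
    otherwise clean session (training data stay identical across candidate
    thresholds, so the comparison isolates the gating decision):

    * decoy IMU excursions of magnitude 4.5 placed over every test-portion
      movement event — a threshold of 4 zeroes these genuine movements and
      loses recall, thresholds 5 and 6 keep them;
    * probe-motion artefacts of IMU magnitude 5.5 whose sensor signature is
      a movement-like damped burst, placed well clear of any real event — a
      threshold of 6 leaves these fake movements in and loses precision,
      thresholds 4 and 5 gate them.
    """
    config = SessionConfig(duration_s=duration_s, probe_episode_rate=0,
                           event_amplitude=4.0, seed=seed, scan_id="threshold-fixture")
    recording, track = generate_recording(config)
    fs, n = recording.fs, recording.n_samples
    rng = np.random.default_rng(artefact_seed)
    test_start = 0.7 * duration_s + 6.0
    for ev in (e for e in track.events if e.onset_s > test_start):
        i0, i1 = int(ev.onset_s * fs), min(int(ev.end_s * fs), n)
        recording.imu[i0:i1] = 4.5 * rng.choice([-1.0, 1.0], i1 - i0)
    placed = 0
    for start in np.arange(test_start + 2.0, duration_s - 8.0, 2.0):
        if placed >= 8:
            break
        if any(ev.onset_s - 9.0 < start < ev.end_s + 9.0 for ev in track.events):
            continue  # keep fake bursts out of genuinely positive windows
        i0, i1 = int(start * fs), int((start + 1.0) * fs)
        recording.imu[i0:i1] = 5.5 * rng.choice([-1.0, 1.0], i1 - i0)
        t = np.arange(i1 - i0) / fs
        burst = np.zeros(i1 - i0)
        for k in range(3):
            burst += 0.6 ** k * np.sin(2.0 * np.pi * rng.uniform(1.0, 25.0) * t
                                       + rng.uniform(0.0, 2.0 * np.pi))
        recording.sensors[:, i0:i1] += 4.0 * np.exp(-3.0 * t) * burst
        placed += 1
    return recording, track


def make_imbalanced_dataset(n_samples: int = 800, n_features: int = 8,
                            n_informative: int = 4, positive_fraction: float = 0.13,
                            separation: float = 0.7, seed: int = 0,
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Feature-level synthetic windows with the study's class imbalance.

    Emulates the statistics of labelled STFT windows directly in feature
    space: 13% positive windows, with a weak mean shift (``separation``
    standard deviations) spread over ``n_informative`` features against
    unit Gaussian noise — separable-with-noise, so an accuracy-driven
    learner is drawn toward the majority class.  Used to study imbalance
    handling (random undersampling) without the cost of full sessions.

    Returns (X, y) with y shuffled but deterministic given ``seed``.
    """
    if not 0.0 < positive_fraction < 1.0:
        raise ConfigurationError("positive_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    n_pos = int(round(positive_fraction * n_samples))
    n_neg = n_samples - n_pos
    X = rng.normal(0.0, 1.0, (n_samples, n_features))
    X[n_neg:, :n_informative] += separation
    y = np.concatenate([np.zeros(n_neg, dtype=int), np.ones(n_pos, dtype=int)])
    order = rng.permutation(n_samples)
    return X[order], y[order]
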