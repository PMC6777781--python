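"""Synthetic click-echo recordings.

Generates mono waveforms emulating rail-mounted-disk measurements: a short
click radiated toward a circular reflector, followed (in reflecting mode) by
a delayed, attenuated copy of the click, all sitting on a decaying room
reverberation tail and a low stationary noise floor.

Levels are expressed as the maximum sound pressure level over running 1-ms
rectangular windows, tied to waveform amplitude by a batch-wide calibration
constant: SPL = 20 log10(window RMS) + calibration_db.  The reflected level
follows an empirical law anchored at a crossover distance where it equals
the direct level and decaying a fixed number of dB per doubling of distance:

    R(d) = direct_level_db - decay * log2(d / crossover_distance_m)

The echo delay is the two-way travel time, delay(d) = (2 d - offset) / c.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.io import wavfile

from .staircase import DiskState

__all__ = [
    "ClickTemplate",
    "PropagationConfig",
    "Recording",
    "make_click",
    "synthesize_recording",
    "synthesize_series",
    "write_recording",
    "read_recording",
    "write_series",
    "read_series",
]

#: Window length used for calibration inside the generator (matches the
#: analyzer's 1-ms rectangular window).
_WINDOW_MS = 1.0


@dataclass(frozen=True)
class ClickTemplate:
    """Parametric echolocation click: a raised-cosine gated sinusoid.

    Defaults approximate a synthetic mouth-click: 3 ms long with dominant
    spectral energy near 3.5 kHz.
    """

    duration_ms: float = 3.0
    center_frequency_hz: float = 3500.0
    sample_rate: int = 48_000
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.duration_ms <= 0:
            raise ValueError("duration_ms must be positive")
        if not 0 < self.center_frequency_hz < self.sample_rate / 2:
            raise ValueError("center_frequency_hz must lie below Nyquist")
        if self.duration_ms * self.center_frequency_hz < 1000.0:
            # fewer than one carrier cycle has no defined spectral peak
            raise ValueError("click must contain at least one carrier cycle")


def make_click(template: ClickTemplate | None = None) -> np.ndarray:
    """Render the click waveform (linear amplitude, unit-scale)."""
    if template is None:
        template = ClickTemplate()
    n = round(template.duration_ms * 1e-3 * template.sample_rate)
    t = np.arange(n) / template.sample_rate
    envelope = 0.5 - 0.5 * np.cos(2 * np.pi * np.arange(n) / n)  # raised cosine
    return template.amplitude * envelope * np.sin(
        2 * np.pi * template.center_frequency_hz * t
    )


@dataclass(frozen=True)
class PropagationConfig:
    """Propagation, level law, and room model for synthetic recordings.

    Parameters
    ----------
    sound_speed : m/s
    direct_level_db : dB
        1-ms windowed maximum SPL of the direct click, identical in every
        recording of a batch (source and receiver never move).
    crossover_distance_m : m
        Distance at which the reflection is as loud as the direct click;
        closer than this the reflection is the louder of the two because the
        source radiates less energy backward toward the receiver than
        forward toward the disk.
    reflected_decay_db_per_doubling : dB
        Drop of the reflected level per doubling of distance.
    reverb_time_s : s
        Room decay time (time for the tail to fall by 60 dB).
    tail_onset_level_db : dB
        1-ms windowed level of the reverberation tail where it starts,
        i.e. right after the direct click excites the room.
    noise_floor_db : dB
        Stationary background level.
    geometry_offset_m : m
        Subtracted inside the delay formula, delay = (2 d - offset) / c, for
        source/receiver geometries that shorten the echo path; 0 keeps the
        pure two-way delay.
    level_jitter_db : dB
        Standard deviation of per-recording scatter added to the reflected
        level, emulating the less systematic behaviour of real rooms at
        long range; defaults off.
    calibration_db : dB
        Batch calibration constant: SPL = 20 log10(window RMS) + this.
    """

    sound_speed: float = 343.0
    direct_level_db: float = 76.0
    crossover_distance_m: float = 1.2
    reflected_decay_db_per_doubling: float = 11.0
    reverb_time_s: float = 0.07
    tail_onset_level_db: float = 50.0
    noise_floor_db: float = 15.0
    geometry_offset_m: float = 0.0
    level_jitter_db: float = 0.0
    calibration_db: float = 100.0
    d_min: float = 0.7
    d_max: float = 3.9

    def __post_init__(self) -> None:
        if self.sound_speed <= 0:
            raise ValueError("sound_speed must be positive")
        if self.crossover_distance_m <= 0:
            raise ValueError("crossover_distance_m must be positive")

    def delay_s(self, distance: float) -> float:
        """Echo delay: two-way travel time less any geometry offset."""
        return (2.0 * distance - self.geometry_offset_m) / self.sound_speed

    def reflected_level_db(self, distance: float) -> float:
        """Level law for the reflection's 1-ms windowed maximum."""
        return self.direct_level_db - self.reflected_decay_db_per_doubling * np.log2(
            distance / self.crossover_distance_m
        )


@dataclass
class Recording:
    """A synthetic (or loaded) mono waveform at a known disk distance/state."""

    samples: np.ndarray
    sample_rate: int
    distance: float
    disk_state: DiskState
    calibration_db: float

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sample_rate

    def manifest(self) -> dict:
        return {
            "distance_m": self.distance,
            "disk_state": DiskState(self.disk_state).value,
            "sample_rate": self.sample_rate,
            "calibration_db": self.calibration_db,
        }


def _windowed_rms_max(x: np.ndarray, sample_rate: int, window_ms: float = _WINDOW_MS) -> float:
    """Maximum RMS over running rectangular windows, 1-sample hop."""
    w = round(window_ms * 1e-3 * sample_rate)
    if w < 1 or w > len(x):
        raise ValueError("window does not fit the waveform")
    csum = np.concatenate(([0.0], np.cumsum(x.astype(float) ** 2)))
    mean_sq = (csum[w:] - csum[:-w]) / w
    return float(np.sqrt(mean_sq.max()))


def synthesize_recording(
    distance: float,
    disk_state: DiskState | str,
    click: np.ndarray | None = None,
    prop_config: PropagationConfig | None = None,
    rng_seed: int | np.random.Generator | None = None,
    *,
    sample_rate: int = 48_000,
    duration_s: float = 0.08,
    include_tail: bool = True,
) -> Recording:
    """Synthesize one recording at a given disk distance and state.

    The direct click starts at time zero, scaled so its 1-ms windowed
    maximum equals ``direct_level_db`` under the batch calibration.  In
    reflecting mode a copy delayed by ``delay_s(distance)`` is added, scaled
    so its isolated windowed maximum equals the level law R(distance).  A
    reverberation tail excited by the direct click (present in both disk
    states) and a stationary noise floor complete the waveform; both are
    drawn from ``rng_seed``, so equal seeds give identical room noise in
    reflecting and non-reflecting recordings.
    """
    if prop_config is None:
        prop_config = PropagationConfig()
    if not prop_config.d_min <= distance <= prop_config.d_max:
        raise ValueError(
            f"distance {distance} outside [{prop_config.d_min}, {prop_config.d_max}] m"
        )
    disk_state = DiskState(disk_state)
    if click is None:
        click = make_click(ClickTemplate(sample_rate=sample_rate))
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )

    n = round(duration_s * sample_rate)
    min_len = 0.030 + prop_config.delay_s(prop_config.d_max)
    if duration_s < min_len:
        raise ValueError(f"duration_s must be at least {min_len:.3f} s")
    cal = prop_config.calibration_db
    unit_max = _windowed_rms_max(click, sample_rate)

    samples = np.zeros(n)
    direct_scale = 10 ** ((prop_config.direct_level_db - cal) / 20) / unit_max
    samples[: len(click)] += direct_scale * click

    # room tail: exponentially decaying white noise, 60 dB down per reverb_time_s
    if include_tail:
        t = np.arange(n) / sample_rate
        decay = np.exp(-t * (3.0 * np.log(10.0)) / prop_config.reverb_time_s)
        tail_scale = 10 ** ((prop_config.tail_onset_level_db - cal) / 20)
        samples += tail_scale * decay * rng.standard_normal(n)
    samples += 10 ** ((prop_config.noise_floor_db - cal) / 20) * rng.standard_normal(n)

    if disk_state is DiskState.REFLECTING:
        level = prop_config.reflected_level_db(distance)
        if prop_config.level_jitter_db > 0:
            level += prop_config.level_jitter_db * rng.standard_normal()
        delay_samples = round(prop_config.delay_s(distance) * sample_rate)
        scale = 10 ** ((level - cal) / 20) / unit_max
        end = min(delay_samples + len(click), n)
        samples[delay_samples:end] += scale * click[: end - delay_samples]

    return Recording(samples, sample_rate, float(distance), disk_state, cal)


def synthesize_series(
    distances=None,
    replicates: int = 1,
    states=(DiskState.REFLECTING, DiskState.NONREFLECTING),
    prop_config: PropagationConfig | None = None,
    click: np.ndarray | None = None,
    seed: int | None = None,
    **kwargs,
) -> list[Recording]:
    """Generate a measurement series over a distance grid.

    Defaults mirror the measurement protocol: distances 0.7 to 3.9 m in
    0.1 m steps, both disk states, ``replicates`` recordings per condition.
    Each (distance, state, replicate) gets its own child seed; the two disk
    states of a replicate share the seed, so their difference isolates the
    reflection component exactly.
    """
    if prop_config is None:
        prop_config = PropagationConfig()
    if distances is None:
        distances = np.round(np.arange(0.7, 3.9 + 1e-9, 0.1), 3)
    root = np.random.SeedSequence(seed)
    recordings = []
    for i, d in enumerate(distances):
        for r in range(replicates):
            child = np.random.SeedSequence(
                entropy=root.entropy if root.entropy is not None else 0,
                spawn_key=(i, r),
            )
            for state in states:
                rng = np.random.default_rng(child)
                recordings.append(
                    synthesize_recording(
                        float(d), state, click, prop_config, rng, **kwargs
                    )
                )
    return recordings


def write_recording(recording: Recording, wav_path) -> None:
    """Write a float32 mono WAV plus a sidecar JSON manifest."""
    wav_path = Path(wav_path)
    wavfile.write(
        wav_path, recording.sample_rate, recording.samples.astype(np.float32)
    )
    with open(wav_path.with_suffix(".json"), "w") as fh:
        json.dump(recording.manifest(), fh, indent=2)


def read_recording(wav_path) -> Recording:
    """Read a WAV + manifest pair written by :func:`write_recording`."""
    wav_path = Path(wav_path)
    sample_rate, samples = wavfile.read(wav_path)
    with open(wav_path.with_suffix(".json")) as fh:
        manifest = json.load(fh)
    if sample_rate != manifest["sample_rate"]:
        raise ValueError("manifest sample_rate disagrees with the WAV header")
    return Recording(
        samples=np.asarray(samples, dtype=float),
        sample_rate=sample_rate,
        distance=manifest["distance_m"],
        disk_state=DiskState(manifest["disk_state"]),
        calibration_db=manifest["calibration_db"],
    )


def write_series(recordings, out_dir) -> list[Path]:
    """Write a series to a directory, one WAV + JSON per recording."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    counters: dict[tuple, int] = {}
    for rec in recordings:
        key = (rec.distance, DiskState(rec.disk_state).value)
        counters[key] = counters.get(key, 0) + 1
        name = f"d{rec.distance:.2f}_{key[1]}_r{counters[key]:02d}.wav"
        path = out_dir / name
        write_recording(rec, path)
        paths.append(path)
    return paths


def read_series(in_dir) -> list[Recording]:
    """Read every WAV + manifest pair from a directory."""
    in_dir = Path(in_dir)
    paths = sorted(in_dir.glob("*.wav"))
    if not paths:
        raise FileNotFoundError(f"no WAV files in {in_dir}")
    return [read_recording(p) for p in paths]
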