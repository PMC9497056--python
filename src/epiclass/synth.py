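"""Synthetic high-density EEG with interictal spike-and-wave activity.

The generator stands in for an undeposited clinical corpus of 105 routine
60 s recordings (15 epileptic and 6 healthy subjects, 5 recordings each,
band-limited to 0-80 Hz).  Background activity is colored noise shaped by
the canonical EEG rhythm bands; epileptic recordings additionally carry
focal spike-and-slow-wave transients at Poisson-distributed times, whose
onset samples and channel spans are retained as ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .errors import ConfigError

#: Canonical EEG rhythm bands (Hz); gamma here means the 30-80 Hz remainder
#: of the recording band.
BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
}
GAMMA_BAND: tuple[float, float] = (30.0, 80.0)

#: Resting background: delta/alpha dominant, moderate theta, weaker beta.
DEFAULT_BAND_WEIGHTS: dict[str, float] = {
    "delta": 1.0,
    "theta": 0.7,
    "alpha": 1.0,
    "beta": 0.5,
}

#: Target background RMS in microvolts (scalp EEG is tens of microvolts).
_BACKGROUND_RMS_UV = 20.0
#: Fraction of each channel drawn from the shared (common-source) signal.
_SHARED_MIX = 0.6


@dataclass(frozen=True)
class SpikeEvent:
    """Ground-truth record of one injected spike-and-wave transient."""

    onset_sample: int
    channel_start: int
    channel_stop: int  # exclusive


@dataclass
class EEGRecording:
    """Multichannel EEG segment: ``data`` is channels x samples, microvolts."""

    data: np.ndarray
    fs: float
    subject_id: str = "S00"
    label: int = 0
    channel_names: list[str] = field(default_factory=list)
    recording_id: str = ""
    events: list[SpikeEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ConfigError("data must be a channels x samples matrix")
        if not np.all(np.isfinite(self.data)):
            raise ConfigError("recording contains non-finite samples")
        if self.label not in (0, 1):
            raise ConfigError(f"label must be 0 or 1, got {self.label!r}")
        if not self.channel_names:
            self.channel_names = [f"E{i + 1:03d}" for i in range(self.n_channels)]
        if len(self.channel_names) != self.n_channels:
            raise ConfigError("channel_names length does not match data rows")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def copy(self) -> "EEGRecording":
        return replace(self, data=self.data.copy(), events=list(self.events),
                       channel_names=list(self.channel_names))


@dataclass
class GeneratorConfig:
    """Corpus-level generation parameters.

    Defaults reproduce the study corpus shape: 15 epileptic + 6 healthy
    subjects, 5 recordings each (105 total), 60 s per recording, 0-80 Hz
    band.  ``spike_amplitude_factor`` is the transient amplitude as a
    multiple of the channel background RMS; ``spike_rate`` is events per
    minute on epileptic recordings.
    """

    n_epileptic_subjects: int = 15
    n_healthy_subjects: int = 6
    recordings_per_subject: int = 5
    duration_s: float = 60.0
    fs: float = 250.0
    n_channels: int = 16
    spike_rate: float = 20.0
    spike_amplitude_factor: float = 8.0
    spike_width_ms: float = 70.0
    background_band_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BAND_WEIGHTS))
    noise_level: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_epileptic_subjects", "n_healthy_subjects",
                     "recordings_per_subject", "n_channels"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        if self.duration_s <= 0:
            raise ConfigError("duration_s must be positive")
        if self.fs <= 160.0:
            raise ConfigError("fs must exceed 160 Hz (Nyquist for the 0-80 Hz band)")
        if self.spike_rate < 0:
            raise ConfigError("spike_rate must be >= 0")
        if self.spike_amplitude_factor <= 0:
            raise ConfigError("spike_amplitude_factor must be > 0")
        if self.spike_width_ms <= 0:
            raise ConfigError("spike_width_ms must be > 0")
        unknown = set(self.background_band_weights) - set(BANDS)
        if unknown:
            raise ConfigError(f"unknown band(s) in weights: {sorted(unknown)}")
        if any(w < 0 for w in self.background_band_weights.values()):
            raise ConfigError("band weights must be non-negative")

    @property
    def n_subjects(self) -> int:
        return self.n_epileptic_subjects + self.n_healthy_subjects

    @property
    def n_recordings(self) -> int:
        return self.n_subjects * self.recordings_per_subject


def _as_rng(rng_state) -> np.random.Generator:
    if isinstance(rng_state, np.random.Generator):
        return rng_state
    return np.random.default_rng(rng_state)


def _bandpass(x: np.ndarray, lo: float, hi: float, fs: float) -> np.ndarray:
    sos = sps.butter(4, [lo, hi], btype="band", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x, axis=-1)


def _lowpass(x: np.ndarray, hi: float, fs: float) -> np.ndarray:
    sos = sps.butter(6, hi, btype="low", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x, axis=-1)


def generate_background(duration_s: float, fs: float, n_channels: int,
                        band_weights: dict[str, float] | None = None,
                        rng_state=0, noise_level: float = 0.2) -> EEGRecording:
    """Band-weighted colored-noise background, channels correlated via a
    shared source.

    Each rhythm band contributes band-passed Gaussian noise normalised to
    unit RMS and scaled by the square root of its weight (weights are
    relative powers); a low-level broadband component fills the band up to
    80 Hz.  Channels mix a shared source with per-channel noise so that
    neighbouring electrodes co-vary, and the result is scaled to a 20 uV
    RMS.  Deterministic given ``rng_state``.
    """
    if duration_s <= 0:
        raise ConfigError("duration_s must be positive")
    if fs <= 160.0:
        raise ConfigError("fs must exceed 160 Hz (Nyquist for the 0-80 Hz band)")
    if n_channels < 1:
        raise ConfigError("n_channels must be >= 1")
    weights = dict(DEFAULT_BAND_WEIGHTS) if band_weights is None else dict(band_weights)
    unknown = set(weights) - set(BANDS)
    if unknown:
        raise ConfigError(f"unknown band(s): {sorted(unknown)}")
    if any(w < 0 for w in weights.values()) or not any(w > 0 for w in weights.values()):
        raise ConfigError("band weights must be non-negative and not all zero")

    rng = _as_rng(rng_state)
    n = int(round(duration_s * fs))
    data = np.zeros((n_channels, n))
    for band, w in weights.items():
        if w == 0:
            continue
        lo, hi = BANDS[band]
        shared = _bandpass(rng.standard_normal(n), lo, hi, fs)
        shared /= max(np.std(shared), 1e-12)
        own = _bandpass(rng.standard_normal((n_channels, n)), lo, hi, fs)
        own /= np.maximum(np.std(own, axis=-1, keepdims=True), 1e-12)
        data += np.sqrt(w) * (_SHARED_MIX * shared + (1.0 - _SHARED_MIX) * own)
    if noise_level > 0:
        broad = _lowpass(rng.standard_normal((n_channels, n)), GAMMA_BAND[1], fs)
        broad /= np.maximum(np.std(broad, axis=-1, keepdims=True), 1e-12)
        data += noise_level * broad
    data *= _BACKGROUND_RMS_UV / np.maximum(np.std(data, axis=-1, keepdims=True), 1e-12)
    return EEGRecording(data=data, fs=fs)


def _spike_wave_template(fs: float, spike_width_ms: float) -> np.ndarray:
    """Biphasic sharp spike followed by a slow half-wave, unit peak."""
    w = max(int(round(spike_width_ms / 1000.0 * fs)), 4)
    w_pos = max(int(round(0.6 * w)), 2)
    w_neg = max(w - w_pos, 2)
    w_slow = 4 * w
    t_pos = np.sin(np.pi * np.arange(w_pos) / w_pos)
    t_neg = -0.8 * np.sin(np.pi * np.arange(w_neg) / w_neg)
    t_slow = 0.45 * np.sin(np.pi * np.arange(w_slow) / w_slow)
    return np.concatenate([t_pos, t_neg, t_slow])


def inject_interictal_activity(recording: EEGRecording, spike_rate: float,
                               spike_amplitude_factor: float,
                               spike_width_ms: float,
                               rng_state=0) -> EEGRecording:
    """Add focal spike-and-slow-wave transients at Poisson times.

    Event count over the record is Poisson with mean
    ``spike_rate * duration / 60``; each event lands on a random contiguous
    channel span (focal character) with amplitude
    ``spike_amplitude_factor`` times that channel's background RMS.  The
    input recording is left unmodified; ground-truth events are stored on
    the returned recording.
    """
    if spike_rate < 0:
        raise ConfigError("spike_rate must be >= 0")
    if spike_amplitude_factor <= 0:
        raise ConfigError("spike_amplitude_factor must be > 0")
    template = _spike_wave_template(recording.fs, spike_width_ms)
    n = recording.n_samples
    if len(template) >= n:
        raise ConfigError("spike-and-wave template longer than the recording")

    out = recording.copy()
    if spike_rate == 0:
        return out
    rng = _as_rng(rng_state)
    n_events = rng.poisson(spike_rate * recording.duration_s / 60.0)
    n_ch = recording.n_channels
    rms = np.sqrt(np.mean(recording.data ** 2, axis=-1))
    events: list[SpikeEvent] = []
    for _ in range(n_events):
        onset = int(rng.integers(0, n - len(template)))
        span = int(rng.integers(max(1, n_ch // 4), max(2, n_ch // 2 + 1)))
        start = int(rng.integers(0, n_ch - span + 1))
        scale = rng.uniform(0.8, 1.2)
        for ch in range(start, start + span):
            amp = spike_amplitude_factor * rms[ch] * scale
            out.data[ch, onset:onset + len(template)] += amp * template
        events.append(SpikeEvent(onset, start, start + span))
    out.events = out.events + sorted(events, key=lambda e: e.onset_sample)
    return out


def generate_dataset(config: GeneratorConfig,
                     event_log_path=None) -> list[EEGRecording]:
    """Generate the full labeled corpus, deterministic given ``config.seed``.

    Epileptic subjects' recordings carry injected interictal activity;
    healthy subjects' do not.  Per-subject band weights are jittered
    (log-normal, sigma 0.15) so subjects differ in background rhythm
    composition.  If ``event_log_path`` is given, a tab-separated sidecar
    with ground-truth spike times is written.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    subject_seeds = ss.spawn(config.n_subjects)
    recordings: list[EEGRecording] = []
    for s in range(config.n_subjects):
        epileptic = s < config.n_epileptic_subjects
        subject_id = f"S{s + 1:02d}"
        srng = np.random.default_rng(subject_seeds[s])
        jitter = {b: w * float(srng.lognormal(0.0, 0.15))
                  for b, w in config.background_band_weights.items()}
        for r in range(config.recordings_per_subject):
            rec = generate_background(config.duration_s, config.fs,
                                      config.n_channels, jitter,
                                      rng_state=srng,
                                      noise_level=config.noise_level)
            if epileptic:
                rec = inject_interictal_activity(
                    rec, config.spike_rate, config.spike_amplitude_factor,
                    config.spike_width_ms, rng_state=srng)
            rec.subject_id = subject_id
            rec.label = int(epileptic)
            rec.recording_id = f"{subject_id}R{r + 1}"
            recordings.append(rec)
    if event_log_path is not None:
        write_event_log(recordings, event_log_path)
    return recordings


def write_event_log(recordings: list[EEGRecording], path) -> None:
    """Tab-separated ground-truth sidecar: recording id, channel span, onset."""
    with open(path, "w") as fh:
        fh.write("recording_id\tchannel_start\tchannel_stop\tonset_sample\n")
        for rec in recordings:
            for ev in rec.events:
                fh.write(f"{rec.recording_id}\t{ev.channel_start}\t"
                         f"{ev.channel_stop}\t{ev.onset_sample}\n")
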