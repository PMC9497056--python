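"""Recording I/O (internal container + EDF) and zero-phase FIR filtering.

The internal container is a single file: a small text header (sampling
rate, channel names, subject, label) terminated by an ``---END---`` line,
followed by raw little-endian float32 samples in channel-major order.
EDF output is written by a minimal built-in 16-bit EDF writer (amplitudes
quantized against the per-channel physical range); EDF input is parsed by
MNE's reader.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import ConfigError, StructuralError
from .synth import EEGRecording

_MAGIC = "EPICLASS-EEG v1"
_HEADER_END = b"---END---\n"

INTERNAL = "internal"
EDF = "edf"


@dataclass
class FilterSpec:
    """Linear-phase FIR design: odd-tap windowed sinc, applied zero-phase."""

    kind: str = "lowpass"  # or "bandpass"
    cutoff_hz: float | tuple[float, float] = 80.0
    numtaps: int = 251
    window: str = "hamming"

    def validate(self, fs: float) -> None:
        if self.kind not in ("lowpass", "bandpass"):
            raise ConfigError(f"unknown filter kind {self.kind!r}")
        cutoffs = np.atleast_1d(np.asarray(self.cutoff_hz, dtype=float))
        expected = 1 if self.kind == "lowpass" else 2
        if cutoffs.size != expected:
            raise ConfigError(f"{self.kind} needs {expected} cutoff(s)")
        if np.any(cutoffs <= 0) or np.any(cutoffs >= fs / 2):
            raise ConfigError(
                f"cutoffs must lie strictly inside (0, {fs / 2}) Hz")
        if self.numtaps % 2 != 1 or self.numtaps < 3:
            raise ConfigError("numtaps must be odd and >= 3 (type-I FIR)")

    def design(self, fs: float) -> np.ndarray:
        self.validate(fs)
        pass_zero = self.kind == "lowpass"
        return sps.firwin(self.numtaps, self.cutoff_hz, window=self.window,
                          pass_zero=pass_zero, fs=fs)


# ---------------------------------------------------------------------------
# internal container
# ---------------------------------------------------------------------------

def _write_internal(rec: EEGRecording, path: str) -> None:
    header = [
        _MAGIC,
        f"fs={rec.fs!r}",
        f"n_channels={rec.n_channels}",
        f"n_samples={rec.n_samples}",
        f"subject_id={rec.subject_id}",
        f"label={rec.label}",
        f"recording_id={rec.recording_id}",
        "channel_names=" + ",".join(rec.channel_names),
    ]
    with open(path, "wb") as fh:
        fh.write(("\n".join(header) + "\n").encode())
        fh.write(_HEADER_END)
        fh.write(rec.data.astype("<f4").tobytes())


def _read_internal(path: str) -> EEGRecording:
    with open(path, "rb") as fh:
        raw = fh.read()
    sep = raw.find(_HEADER_END)
    if sep < 0:
        raise StructuralError(f"{path}: missing header terminator")
    lines = raw[:sep].decode(errors="replace").splitlines()
    if not lines or lines[0] != _MAGIC:
        raise StructuralError(f"{path}: bad magic line {lines[:1]!r}")
    fields = {}
    for i, line in enumerate(lines[1:], start=2):
        if "=" not in line:
            raise StructuralError(f"{path}: malformed header line {i}: {line!r}")
        key, _, val = line.partition("=")
        fields[key] = val
    try:
        fs = float(fields["fs"])
        n_ch = int(fields["n_channels"])
        n_s = int(fields["n_samples"])
        label = int(fields["label"])
    except (KeyError, ValueError) as exc:
        raise StructuralError(f"{path}: bad or missing header field: {exc}") from exc
    payload = raw[sep + len(_HEADER_END):]
    expected = n_ch * n_s * 4
    if len(payload) != expected:
        raise StructuralError(
            f"{path}: payload is {len(payload)} bytes, header implies {expected}")
    data = np.frombuffer(payload, dtype="<f4").reshape(n_ch, n_s).astype(np.float64)
    names = fields.get("channel_names", "")
    return EEGRecording(
        data=data, fs=fs, subject_id=fields.get("subject_id", "S00"),
        label=label, channel_names=names.split(",") if names else [],
        recording_id=fields.get("recording_id", ""))


# ---------------------------------------------------------------------------
# EDF (European Data Format), 16-bit
# ---------------------------------------------------------------------------

def _edf_field(text: str, width: int) -> bytes:
    return text[:width].ljust(width).encode("ascii", "replace")


def _write_edf(rec: EEGRecording, path: str) -> None:
    """Minimal EDF writer: 1 s data records, int16 quantization.

    The trailing partial second, if any, is zero-padded; the true sample
    count survives via the internal container, not EDF.  Subject id and
    label ride in the standard patient/recording identification fields.
    """
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ConfigError("EDF export requires an integer sampling rate")
    fs_i = int(round(fs))
    n_ch = rec.n_channels
    n_records = int(np.ceil(rec.n_samples / fs_i))
    padded = np.zeros((n_ch, n_records * fs_i))
    padded[:, :rec.n_samples] = rec.data

    # symmetric physical range per channel, at least +-1 uV
    phys = np.maximum(np.max(np.abs(padded), axis=1), 1.0)
    dig_max, dig_min = 32767, -32768
    # the EDF linear map: x = cal * (d - dig_min) + phys_min
    cal = 2.0 * phys / (dig_max - dig_min)

    with open(path, "wb") as fh:
        fh.write(_edf_field("0", 8))
        fh.write(_edf_field(f"subject={rec.subject_id}", 80))
        fh.write(_edf_field(f"label={rec.label} id={rec.recording_id}", 80))
        fh.write(_edf_field("01.01.00", 8))
        fh.write(_edf_field("00.00.00", 8))
        fh.write(_edf_field(str(256 * (1 + n_ch)), 8))
        fh.write(_edf_field("", 44))
        fh.write(_edf_field(str(n_records), 8))
        fh.write(_edf_field("1", 8))
        fh.write(_edf_field(str(n_ch), 4))
        for name in rec.channel_names:
            fh.write(_edf_field(name, 16))
        for _ in range(n_ch):
            fh.write(_edf_field("", 80))       # transducer
        for _ in range(n_ch):
            fh.write(_edf_field("uV", 8))      # physical dimension
        for p in phys:
            fh.write(_edf_field(f"{-p:.6g}", 8))
        for p in phys:
            fh.write(_edf_field(f"{p:.6g}", 8))
        for _ in range(n_ch):
            fh.write(_edf_field(str(dig_min), 8))
        for _ in range(n_ch):
            fh.write(_edf_field(str(dig_max), 8))
        for _ in range(n_ch):
            fh.write(_edf_field("LP:80Hz", 80))
        for _ in range(n_ch):
            fh.write(_edf_field(str(fs_i), 8))
        for _ in range(n_ch):
            fh.write(_edf_field("", 32))
        digital = np.clip(
            np.round((padded + phys[:, None]) / cal[:, None]) + dig_min,
            dig_min, dig_max).astype("<i2")
        for r in range(n_records):
            fh.write(digital[:, r * fs_i:(r + 1) * fs_i].tobytes())


def _read_edf(path: str) -> EEGRecording:
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data_uv = raw.get_data() * 1e6  # MNE returns volts
    fs = float(raw.info["sfreq"])
    # recover subject/label from the identification fields we wrote
    with open(path, "rb") as fh:
        head = fh.read(256).decode("ascii", "replace")
    subject_id, label = "S00", 0
    patient, recfield = head[8:88], head[88:168]
    if "subject=" in patient:
        subject_id = patient.split("subject=")[1].split()[0]
    if "label=" in recfield:
        try:
            label = int(recfield.split("label=")[1].split()[0])
        except ValueError:
            label = 0
    rec_id = ""
    if "id=" in recfield:
        tail = recfield.split("id=")[1].split()
        rec_id = tail[0] if tail else ""
    return EEGRecording(data=data_uv, fs=fs, subject_id=subject_id,
                        label=label, channel_names=list(raw.ch_names),
                        recording_id=rec_id)


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def write_recording(recording: EEGRecording, path, format: str = INTERNAL) -> None:
    """Serialize a recording to the internal container or EDF."""
    path = os.fspath(path)
    if format == INTERNAL:
        _write_internal(recording, path)
    elif format == EDF:
        _write_edf(recording, path)
    else:
        raise ConfigError(f"unknown format {format!r}")


def read_recording(path, format: str | None = None) -> EEGRecording:
    """Load a recording; format inferred from the extension if omitted."""
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if format is None:
        format = EDF if path.lower().endswith(".edf") else INTERNAL
    if format == INTERNAL:
        return _read_internal(path)
    if format == EDF:
        return _read_edf(path)
    raise ConfigError(f"unknown format {format!r}")


def apply_fir(recording: EEGRecording, filter_spec: FilterSpec) -> EEGRecording:
    """Zero-phase FIR filtering (forward-backward), length-preserving.

    Forward-backward application squares the magnitude response, which
    doubles the stopband attenuation; the linear-phase delay cancels
    exactly, so passband components keep their timing.
    """
    taps = filter_spec.design(recording.fs)
    out = recording.copy()
    out.data = sps.filtfilt(taps, [1.0], recording.data, axis=-1, padtype="odd")
    return out
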