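"""Five feature families per recording: Welch PSD summaries, Shannon
entropy of the amplitude distribution, and mean/skewness/kurtosis of the
first three IMFs.

Features are computed per channel and, by default, averaged across
channels so the vector length (16) is independent of the montage size;
a concatenation mode keeps per-channel columns for study.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .emd import SiftCriteria, decompose
from .errors import ConfigError, DegenerateInputError, StructuralError
from .synth import BANDS, GAMMA_BAND, EEGRecording

#: Fixed feature column order (aggregated mode).
FEATURE_NAMES: list[str] = (
    ["psd_total_power", "psd_delta", "psd_theta", "psd_alpha", "psd_beta",
     "psd_gamma30_80", "shannon_entropy_bits"]
    + [f"imf{k}_{m}" for k in (1, 2, 3) for m in ("mean", "skewness", "kurtosis")]
)

_META_COLUMNS = ["recording_id", "subject_id", "label"]


@dataclass
class PSDConfig:
    """Welch estimator settings: 2 s Hann windows, 50% overlap by default."""

    window_s: float = 2.0
    overlap: float = 0.5


@dataclass
class PSDEstimate:
    frequencies: np.ndarray
    power: np.ndarray  # density, amplitude^2 / Hz
    window_length: int
    overlap: float

    def band_power(self, lo: float, hi: float) -> float:
        """Integrated density over [lo, hi] (rectangle rule on the grid)."""
        df = float(self.frequencies[1] - self.frequencies[0])
        mask = (self.frequencies >= lo) & (self.frequencies < hi)
        return float(np.sum(self.power[mask]) * df)


@dataclass
class FeatureVector:
    recording_id: str
    subject_id: str
    label: int
    values: dict[str, float] = field(default_factory=dict)


@dataclass
class FeatureTable:
    """Rectangular per-recording feature matrix with labels and subject ids."""

    frame: pd.DataFrame  # columns: recording_id, subject_id, label, features...

    @property
    def feature_names(self) -> list[str]:
        return [c for c in self.frame.columns if c not in _META_COLUMNS]

    @property
    def labels(self) -> np.ndarray:
        return self.frame["label"].to_numpy(dtype=int)

    @property
    def subject_ids(self) -> list[str]:
        return list(self.frame["subject_id"])

    @property
    def X(self) -> np.ndarray:
        return self.frame[self.feature_names].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.frame)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False, float_format="%.17g")

    def csv_bytes(self) -> bytes:
        buf = io.StringIO()
        self.frame.to_csv(buf, index=False, float_format="%.17g")
        return buf.getvalue().encode()

    @classmethod
    def from_csv(cls, path) -> "FeatureTable":
        frame = pd.read_csv(path, float_precision="round_trip")
        missing = [c for c in _META_COLUMNS if c not in frame.columns]
        if missing:
            raise StructuralError(f"feature CSV lacks columns {missing}")
        return cls(frame=frame)


def welch_psd(signal: np.ndarray, fs: float, window_length: int | None = None,
              overlap: float = 0.5) -> PSDEstimate:
    """Averaged modified periodogram (Hann taper, overlapping segments).

    Density scaling: the integral of ``power`` over frequency approximates
    the signal variance (Parseval contract, within the Welch bias).
    """
    x = np.asarray(signal, dtype=np.float64)
    if window_length is None:
        window_length = int(round(2.0 * fs))
    if not 0 <= overlap < 1:
        raise ConfigError("overlap must lie in [0, 1)")
    if window_length > x.size:
        raise ConfigError(
            f"window_length {window_length} exceeds signal length {x.size}")
    freqs, power = sps.welch(x, fs=fs, window="hann", nperseg=window_length,
                             noverlap=int(round(overlap * window_length)),
                             detrend="constant", scaling="density")
    return PSDEstimate(frequencies=freqs, power=power,
                       window_length=window_length, overlap=overlap)


def shannon_entropy(signal: np.ndarray, n_bins: int = 64) -> float:
    """Shannon entropy (bits) of the equal-width amplitude histogram.

    H = -sum p_i log2 p_i with the 0 log 0 = 0 convention; a constant
    signal occupies one bin and returns exactly 0.
    """
    x = np.asarray(signal, dtype=np.float64).ravel()
    if x.size == 0:
        raise DegenerateInputError("empty signal")
    if n_bins < 2:
        raise ConfigError("n_bins must be >= 2")
    lo, hi = float(np.min(x)), float(np.max(x))
    if lo == hi:
        return 0.0
    counts, _ = np.histogram(x, bins=n_bins, range=(lo, hi))
    p = counts[counts > 0] / x.size
    return float(-np.sum(p * np.log2(p)))


def moment_features(signal: np.ndarray) -> tuple[float, float, float]:
    """(mean, skewness, kurtosis) with population (1/N) moment estimators.

    Skewness is the third standardized moment; kurtosis is the non-excess
    fourth standardized moment E[(X-u)^4] / (E[(X-u)^2])^2, equal to 3 for
    a Gaussian and bounded below by 1.
    """
    x = np.asarray(signal, dtype=np.float64).ravel()
    if x.size < 2:
        raise DegenerateInputError("need at least 2 samples")
    mu = float(np.mean(x))
    d = x - mu
    m2 = float(np.mean(d ** 2))
    if m2 == 0.0:
        raise DegenerateInputError("zero variance: skewness/kurtosis undefined")
    skew = float(np.mean(d ** 3)) / m2 ** 1.5
    kurt = float(np.mean(d ** 4)) / m2 ** 2
    return mu, skew, kurt


def _channel_features(x: np.ndarray, fs: float, emd_criteria: SiftCriteria,
                      psd_config: PSDConfig, entropy_bins: int,
                      channel: str) -> np.ndarray:
    est = welch_psd(x, fs, int(round(psd_config.window_s * fs)),
                    psd_config.overlap)
    vals = [est.band_power(0.5, GAMMA_BAND[1])]
    for lo, hi in BANDS.values():
        vals.append(est.band_power(lo, hi))
    vals.append(est.band_power(*GAMMA_BAND))
    vals.append(shannon_entropy(x, entropy_bins))
    imfset = decompose(x, emd_criteria, source_channel=channel)
    if len(imfset.imfs) < emd_criteria.max_imfs:
        raise DegenerateInputError(
            f"channel {channel}: only {len(imfset.imfs)} IMFs extracted")
    for k in range(emd_criteria.max_imfs):
        try:
            vals.extend(moment_features(imfset.imfs[k]))
        except DegenerateInputError as exc:
            raise DegenerateInputError(
                f"channel {channel}, IMF {k + 1}: {exc}") from exc
    return np.asarray(vals)


def extract_features(recording: EEGRecording,
                     emd_criteria: SiftCriteria | None = None,
                     psd_config: PSDConfig | None = None,
                     entropy_bins: int = 64,
                     aggregate: str = "mean") -> FeatureVector:
    """Per-recording feature vector.

    ``aggregate='mean'`` averages each per-channel feature across channels
    (16 values regardless of montage); ``aggregate='concat'`` keeps one
    column per channel and feature.
    """
    emd_criteria = emd_criteria or SiftCriteria()
    psd_config = psd_config or PSDConfig()
    if aggregate not in ("mean", "concat"):
        raise ConfigError(f"unknown aggregation {aggregate!r}")
    per_channel = np.stack([
        _channel_features(recording.data[c], recording.fs, emd_criteria,
                          psd_config, entropy_bins, recording.channel_names[c])
        for c in range(recording.n_channels)
    ])
    names = _names_for(emd_criteria.max_imfs)
    if aggregate == "mean":
        values = dict(zip(names, np.mean(per_channel, axis=0)))
    else:
        values = {
            f"ch{c:03d}_{name}": per_channel[c, j]
            for c in range(recording.n_channels)
            for j, name in enumerate(names)
        }
    return FeatureVector(recording_id=recording.recording_id,
                         subject_id=recording.subject_id,
                         label=recording.label,
                         values={k: float(v) for k, v in values.items()})


def _names_for(max_imfs: int) -> list[str]:
    base = FEATURE_NAMES[:7]
    return base + [f"imf{k}_{m}" for k in range(1, max_imfs + 1)
                   for m in ("mean", "skewness", "kurtosis")]


def build_feature_table(recordings: list[EEGRecording],
                        emd_criteria: SiftCriteria | None = None,
                        psd_config: PSDConfig | None = None,
                        entropy_bins: int = 64,
                        aggregate: str = "mean") -> FeatureTable:
    """One feature row per recording; all rows must share a schema."""
    if not recordings:
        raise StructuralError("empty recording list")
    shapes = {rec.n_channels for rec in recordings}
    if aggregate == "concat" and len(shapes) > 1:
        offenders = [rec.recording_id for rec in recordings
                     if rec.n_channels != recordings[0].n_channels]
        raise StructuralError(f"inconsistent channel counts: {offenders}")
    rows = []
    for rec in recordings:
        fv = extract_features(rec, emd_criteria, psd_config, entropy_bins,
                              aggregate)
        rows.append({"recording_id": fv.recording_id,
                     "subject_id": fv.subject_id,
                     "label": fv.label, **fv.values})
    frame = pd.DataFrame(rows)
    if frame[[c for c in frame.columns if c not in _META_COLUMNS]].isna().any().any():
        raise StructuralError("missing values in assembled feature table")
    return FeatureTable(frame=frame)
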