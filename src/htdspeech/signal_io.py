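"""Audio and manifest I/O plus run configuration.

Waveforms are held as float arrays in [-1, 1] regardless of the on-disk bit
depth; 16-bit PCM RIFF/WAV is the only supported container, matching typical
hand-held recorder output (48 kHz stereo in the target corpus). Datasets are
described by a flat CSV manifest mapping utterance ids to files, word-class
labels, cohort (healthy/aphasic) and optional severity.
"""

from __future__ import annotations

import dataclasses
import io
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml
from scipy.io import wavfile

__all__ = [
    "Waveform",
    "ManifestEntry",
    "DatasetManifest",
    "PreprocessParams",
    "TrainConfig",
    "RunConfig",
    "read_wav",
    "write_wav",
    "load_manifest",
    "save_manifest",
    "load_config",
]

HEALTHY = "healthy"
APHASIC = "aphasic"

_MANIFEST_COLUMNS = ["utterance_id", "path", "label", "cohort", "severity", "speaker_id", "rep"]


@dataclass(frozen=True)
class Waveform:
    """Sampled audio: ``samples`` shaped (n,) mono or (n, 2) stereo, in [-1, 1]."""

    samples: np.ndarray
    rate: int

    def __post_init__(self) -> None:
        s = np.asarray(self.samples, dtype=np.float64)
        object.__setattr__(self, "samples", s)
        if self.rate <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.rate}")
        if s.ndim not in (1, 2) or (s.ndim == 2 and s.shape[1] not in (1, 2)):
            raise ValueError(f"samples must be (n,) or (n, 1|2), got shape {s.shape}")

    @property
    def channels(self) -> int:
        return 1 if self.samples.ndim == 1 else self.samples.shape[1]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate


class FormatError(ValueError):
    """Unsupported audio encoding or malformed manifest."""


def read_wav(path: str | os.PathLike) -> Waveform:
    """Read a PCM16 WAV file into a float Waveform scaled to [-1, 1].

    Raises ``FileNotFoundError`` for a missing file, ``FormatError`` for
    encodings other than 16-bit integer PCM, and ``IOError`` for a
    truncated/unreadable file.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        rate, data = wavfile.read(str(path))
    except FileNotFoundError:
        raise
    except ValueError as exc:
        raise IOError(f"unreadable WAV file {path}: {exc}") from exc
    if data.dtype != np.int16:
        raise FormatError(f"{path}: expected 16-bit PCM, got dtype {data.dtype}")
    if data.ndim == 2 and data.shape[1] > 2:
        raise FormatError(f"{path}: more than 2 channels ({data.shape[1]})")
    return Waveform(samples=data.astype(np.float64) / 32768.0, rate=int(rate))


def write_wav(path: str | os.PathLike, w: Waveform) -> None:
    """Write a Waveform as 16-bit PCM, clipping to [-1, 1) before quantization."""
    q = np.clip(w.samples, -1.0, 32767.0 / 32768.0)
    wavfile.write(str(path), w.rate, np.round(q * 32768.0).astype(np.int16))


@dataclass(frozen=True)
class ManifestEntry:
    utterance_id: str
    path: str  # file path, or "" for in-memory datasets
    label: int
    cohort: str  # healthy | aphasic
    severity: float | None  # in [0, 1], present iff cohort == aphasic
    speaker_id: str
    rep: int


@dataclass
class DatasetManifest:
    """Labeled utterance collection with cohort/severity metadata.

    Invariants enforced at construction: unique utterance ids, contiguous
    class labels 0..C-1 over the whole manifest, severity present exactly for
    the aphasic cohort.
    """

    entries: list[ManifestEntry]

    def __post_init__(self) -> None:
        ids = [e.utterance_id for e in self.entries]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate utterance_id(s): {dup[:5]}")
        labels = sorted({e.label for e in self.entries})
        if self.entries and labels != list(range(len(labels))):
            raise ValueError(f"class labels not contiguous from 0: {labels}")
        for e in self.entries:
            if e.cohort not in (HEALTHY, APHASIC):
                raise ValueError(f"{e.utterance_id}: cohort must be healthy|aphasic, got {e.cohort!r}")
            if e.cohort == APHASIC:
                if e.severity is None or not (0.0 <= e.severity <= 1.0):
                    raise ValueError(f"{e.utterance_id}: aphasic entry needs severity in [0,1]")
            elif e.severity is not None:
                raise ValueError(f"{e.utterance_id}: healthy entry must not carry severity")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def n_classes(self) -> int:
        return len({e.label for e in self.entries})

    def subset(self, cohort: str | None = None, ids: Iterable[str] | None = None) -> "DatasetManifest":
        sel = self.entries
        if cohort is not None:
            sel = [e for e in sel if e.cohort == cohort]
        if ids is not None:
            want = set(ids)
            sel = [e for e in sel if e.utterance_id in want]
        return DatasetManifest(entries=list(sel))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "utterance_id": e.utterance_id,
                "path": e.path,
                "label": e.label,
                "cohort": e.cohort,
                "severity": "" if e.severity is None else e.severity,
                "speaker_id": e.speaker_id,
                "rep": e.rep,
            }
            for e in self.entries
        ]
        return pd.DataFrame(rows, columns=_MANIFEST_COLUMNS)


def save_manifest(manifest: DatasetManifest, path: str | os.PathLike) -> None:
    manifest.to_frame().to_csv(path, index=False)


def _entry_from_row(row: pd.Series) -> ManifestEntry:
    sev = row["severity"]
    if sev is None or (isinstance(sev, float) and np.isnan(sev)) or str(sev).strip() == "":
        severity = None
    else:
        severity = float(sev)
    return ManifestEntry(
        utterance_id=str(row["utterance_id"]),
        path=str(row["path"]) if not pd.isna(row["path"]) else "",
        label=int(row["label"]),
        cohort=str(row["cohort"]),
        severity=severity,
        speaker_id=str(row["speaker_id"]),
        rep=int(row["rep"]),
    )


def load_manifest(path: str | os.PathLike) -> DatasetManifest:
    """Load and validate a manifest CSV (columns: utterance_id, path, label,
    cohort, severity, speaker_id, rep; severity blank for healthy rows)."""
    df = pd.read_csv(path, dtype={"severity": object, "path": object})
    missing = [c for c in _MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"manifest missing column(s): {missing}")
    return DatasetManifest(entries=[_entry_from_row(r) for _, r in df.iterrows()])


# --------------------------------------------------------------------------
# Run configuration


@dataclass
class PreprocessParams:
    """Endpointing and noisy-sample exclusion settings (see preprocess module)."""

    frame_ms: float = 20.0
    silence_threshold_db: float = -40.0  # relative to peak-frame RMS
    target_rate: int | None = None  # None = keep native rate
    snr_floor_db: float = 5.0

    def __post_init__(self) -> None:
        if self.frame_ms <= 0:
            raise ValueError("frame_ms must be positive")


@dataclass
class TrainConfig:
    """Classifier training protocol.

    Defaults follow the fine-tuning recipe used for the TF-image classifiers:
    cyclical learning rate peaking at 3e-3, Adam (beta1=0.9, beta2=0.999),
    decoupled weight decay 0.01, batch size 128, 15 epochs, cross-entropy
    loss. ``backbone`` selects the network; ``tiny-scratch`` is a small
    from-random-init convolutional net on 64x64 inputs suited to desk-scale
    runs without downloaded weights.
    """

    lr_peak: float = 0.003
    lr_policy: str = "cyclical"  # triangular cycle per epoch, lr_peak/10 .. lr_peak
    beta1: float = 0.9
    beta2: float = 0.999
    weight_decay: float = 0.01
    batch_size: int = 128
    epochs: int = 15
    input_size: int = 224  # 224x224x3 for pretrained backbones
    backbone: str = "tiny-scratch"  # tiny-scratch | pretrained-resnet50 | pretrained-small
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("lr_peak", "beta1", "beta2", "batch_size", "input_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.weight_decay < 0 or self.epochs < 0:
            raise ValueError("weight_decay and epochs must be non-negative")


@dataclass
class RunConfig:
    """End-to-end run settings: TFD analysis, imaging, classifier, seed.

    sigma is the kernel sharpness of the hyperbolic smoothing kernel
    R_sigma(t) = k_sigma / cosh^(2 sigma)(t); kernel_time_scale maps the
    dimensionless kernel argument to seconds (larger scale = wider temporal
    smoothing). lag_window is the (odd) number of lags retained; nfft the FFT
    length over lags (defaults to next power of two >= lag_window); hop the
    frame step in samples.
    """

    sigma: float = 1.0
    kernel_time_scale: float = 0.005  # seconds per unit kernel argument
    truncation_eps: float = 1e-4
    lag_window: int = 255
    nfft: int | None = None
    hop: int = 64
    image_size: int = 224
    colormap: str = "viridis"
    floor_db: float = 60.0
    classifier: str = "cnn"  # cnn | lda
    seed: int = 0
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    train: TrainConfig = field(default_factory=TrainConfig)

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be a positive real number")
        if self.lag_window % 2 == 0 or self.lag_window < 3:
            raise ValueError("lag_window must be odd and >= 3")
        if self.hop < 1:
            raise ValueError("hop must be >= 1")

    @property
    def nfft_effective(self) -> int:
        if self.nfft is not None:
            return self.nfft
        n = 1
        while n < self.lag_window:
            n *= 2
        return n


def load_config(path: str | os.PathLike | None) -> RunConfig:
    """Load a YAML run configuration; every field has a default, so a missing
    or ``None`` path yields the stock configuration (the bundled demo)."""
    if path is None or str(path).lower() == "none":
        return RunConfig()
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    pp = PreprocessParams(**raw.pop("preprocess", {}))
    tc = TrainConfig(**raw.pop("train", {}))
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise FormatError(f"unknown config field(s): {sorted(unknown)}")
    return RunConfig(preprocess=pp, train=tc, **raw)


def dump_config(cfg: RunConfig, stream: io.TextIOBase | None = None) -> str:
    d = dataclasses.asdict(cfg)
    text = yaml.safe_dump(d, sort_keys=False)
    if stream is not None:
        stream.write(text)
    return text
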