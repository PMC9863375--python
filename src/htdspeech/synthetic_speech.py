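"""Synthetic isolated-word speech with healthy and severity-graded variants.

The clinical recordings this package was designed around (20 isolated
Mandarin words spoken by healthy volunteers and by people with aphasia) are
not redistributable, so every downstream stage is exercised on a synthetic
corpus with the same shape: C word classes, many speakers, a few
repetitions each, and a severity-graded "impaired" cohort.

Words are acoustic stand-ins, not phonetically faithful Mandarin: each class
is a 1-2 syllable template defined by a formant triple (F1 < F2 < F3), a
linear pitch contour per syllable (emulating lexical tone), and a duration.
Utterances come from classic source-filter synthesis — a glottal impulse
train at the pitch contour driving a cascade of three formant resonators,
under a rise/fall amplitude envelope. Speaker identity is a consistent
multiplicative perturbation of formants and pitch; repetition-level jitter
adds smaller within-speaker variation.

Impairment is modeled along the dimensions impaired speech is commonly
described by — articulation (formant drift), tone (contour flattening),
fluency (tempo warp, syllable deletion), voice quality (jitter/shimmer) and
recording noise — each scaled by a severity in [0, 1], with all effects
vanishing exactly at severity 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import lfilter

from .signal_io import APHASIC, HEALTHY, DatasetManifest, ManifestEntry, Waveform

__all__ = [
    "WordTemplate",
    "Syllable",
    "DegradationParams",
    "make_templates",
    "synthesize_utterance",
    "degrade",
    "generate_dataset",
    "desk_scale_dataset",
]

_FORMANT_SETS = [  # (F1, F2, F3) Hz — seven vowel-like targets, every pair
    (800.0, 1200.0, 2600.0),  # separated by >= 150 Hz in some formant
    (300.0, 2300.0, 3000.0),
    (350.0, 800.0, 2400.0),
    (500.0, 1900.0, 2700.0),
    (620.0, 1000.0, 2150.0),
    (450.0, 1600.0, 2900.0),
    (700.0, 1550.0, 3100.0),
]
_TONE_CONTOURS = [  # (f0 start, f0 end) Hz — the three contour directions
    (220.0, 220.0),  # level
    (160.0, 260.0),  # rising
    (280.0, 160.0),  # falling
]
_BANDWIDTHS = (80.0, 120.0, 180.0)


@dataclass(frozen=True)
class Syllable:
    f0_start: float
    f0_end: float
    formants: tuple[float, float, float]
    duration: float
    attack_frac: float  # rise time as a fraction of duration

    def __post_init__(self) -> None:
        f1, f2, f3 = self.formants
        if not (f1 < f2 < f3):
            raise ValueError(f"formants must be strictly increasing, got {self.formants}")
        if self.duration <= 0:
            raise ValueError("syllable duration must be positive")


@dataclass(frozen=True)
class WordTemplate:
    class_id: int
    syllables: tuple[Syllable, ...]

    @property
    def duration(self) -> float:
        return sum(s.duration for s in self.syllables)


@dataclass(frozen=True)
class DegradationParams:
    """Severity-scaled impairment model; every effect is zero at severity 0
    and its magnitude is non-decreasing in severity."""

    formant_drift_hz: float = 200.0  # max per-formant drift at severity 1
    tone_flatten: float = 1.0  # 1 = contour fully flattened at severity 1
    syllable_deletion_p: float = 0.3  # deletion probability at severity 1
    time_warp_range: float = 0.3  # duration scale in [1 - r s, 1 + r s]
    jitter_shimmer_depth: float = 0.06  # pitch/amplitude modulation at severity 1
    snr_clean_db: float = 40.0  # additive-noise SNR at severity 0+
    snr_slope_db: float = 25.0  # SNR drop per unit severity


def make_templates(n_classes: int, rng_seed: int = 0) -> list[WordTemplate]:
    """Deterministic word-template inventory.

    Classes are laid out on a (formant set x tone contour) grid, so any two
    templates differ in a formant by >= 150 Hz or in tone direction; odd
    classes get a second syllable. Capacity is 42 classes.
    """
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    cap = 2 * len(_FORMANT_SETS) * len(_TONE_CONTOURS)
    if n_classes > cap:
        raise ValueError(f"template grid supports at most {cap} classes")
    rng = np.random.default_rng(rng_seed)
    templates = []
    for c in range(n_classes):
        tone = _TONE_CONTOURS[c % 3]
        formants = _FORMANT_SETS[(c // 3) % 7]
        syls = [
            Syllable(
                f0_start=tone[0],
                f0_end=tone[1],
                formants=formants,
                duration=float(rng.uniform(0.18, 0.28)),
                attack_frac=float(rng.uniform(0.15, 0.3)),
            )
        ]
        if c % 2 == 1:  # two-syllable words
            tone2 = _TONE_CONTOURS[(c + 1) % 3]
            formants2 = _FORMANT_SETS[(c // 3 + 1 + c % 4) % 7]
            syls.append(
                Syllable(
                    f0_start=tone2[0],
                    f0_end=tone2[1],
                    formants=formants2,
                    duration=float(rng.uniform(0.18, 0.28)),
                    attack_frac=float(rng.uniform(0.15, 0.3)),
                )
            )
        templates.append(WordTemplate(class_id=c, syllables=tuple(syls)))
    return templates


def _resonator_cascade(x: np.ndarray, formants, rate: int) -> np.ndarray:
    for f, bw in zip(formants, _BANDWIDTHS):
        f = min(f, 0.45 * rate)  # keep poles inside the analysis band
        r = np.exp(-np.pi * bw / rate)
        theta = 2.0 * np.pi * f / rate
        a = [1.0, -2.0 * r * np.cos(theta), r * r]
        x = lfilter([1.0 - r], a, x)
    return x


def _synth_syllable(
    s: Syllable,
    rate: int,
    formant_scale: np.ndarray,
    pitch_scale: float,
    jitter: float,
    shimmer: float,
    rng: np.random.Generator,
) -> np.ndarray:
    n = max(8, int(round(s.duration * rate)))
    f0 = np.linspace(s.f0_start, s.f0_end, n) * pitch_scale
    if jitter > 0:
        f0 = f0 * (1.0 + jitter * _smooth_noise(n, rate, rng))
    phase = np.cumsum(f0) / rate
    pulses = np.zeros(n)
    pulses[np.flatnonzero(np.diff(np.floor(phase)) > 0)] = 1.0
    formants = np.asarray(s.formants) * formant_scale
    x = _resonator_cascade(pulses, formants, rate)
    env = _rise_fall_envelope(n, s.attack_frac)
    if shimmer > 0:
        env = env * (1.0 + shimmer * _smooth_noise(n, rate, rng))
    x = x * env
    peak = np.abs(x).max()
    return x / peak * 0.5 if peak > 0 else x


def _smooth_noise(n: int, rate: int, rng: np.random.Generator) -> np.ndarray:
    """Zero-mean noise band-limited to ~30 Hz, unit peak scale."""
    raw = rng.standard_normal(n)
    width = max(1, rate // 60)
    kernel = np.hanning(2 * width + 1)
    sm = np.convolve(raw, kernel / kernel.sum(), mode="same")
    peak = np.abs(sm).max()
    return sm / peak if peak > 0 else sm


def _rise_fall_envelope(n: int, attack_frac: float) -> np.ndarray:
    na = max(1, int(n * attack_frac))
    nd = max(1, int(n * 0.3))
    env = np.ones(n)
    env[:na] = 0.5 * (1 - np.cos(np.pi * np.arange(na) / na))
    env[n - nd :] = 0.5 * (1 + np.cos(np.pi * np.arange(nd) / nd))
    return env


def synthesize_utterance(
    t: WordTemplate,
    speaker_jitter: float = 0.03,
    rng: np.random.Generator | None = None,
    rate: int = 8000,
    formant_scale: np.ndarray | None = None,
    pitch_scale: float | None = None,
    jitter: float = 0.0,
    shimmer: float = 0.0,
) -> Waveform:
    """Synthesize one utterance of a word template.

    ``speaker_jitter`` bounds the random multiplicative perturbation of
    formants and pitch (<= 5 %) drawn here when explicit per-speaker scales
    are not supplied; ``formant_scale``/``pitch_scale`` override it for
    consistent speaker identities. ``jitter``/``shimmer`` add pitch and
    amplitude modulation (voice-quality degradation).
    """
    if speaker_jitter > 0.05:
        raise ValueError("speaker_jitter must be <= 0.05")
    rng = rng or np.random.default_rng(0)
    if formant_scale is None:
        formant_scale = 1.0 + speaker_jitter * rng.uniform(-1, 1, size=3)
    if pitch_scale is None:
        pitch_scale = 1.0 + speaker_jitter * rng.uniform(-1, 1)
    gap = np.zeros(int(0.04 * rate))
    parts = []
    for i, s in enumerate(t.syllables):
        if i:
            parts.append(gap)
        parts.append(_synth_syllable(s, rate, np.asarray(formant_scale), pitch_scale, jitter, shimmer, rng))
    return Waveform(np.concatenate(parts), rate)


def degrade(
    w: Waveform,
    t: WordTemplate,
    d: DegradationParams,
    rng: np.random.Generator,
    severity: float,
    formant_scale: np.ndarray | None = None,
    pitch_scale: float | None = None,
) -> Waveform:
    """Produce a severity-degraded version of an utterance of template ``t``.

    Severity 0 returns ``w`` unchanged (bit-exact). Otherwise the utterance
    is re-synthesized from a degraded template — tempo warp, formant drift,
    tone flattening, syllable deletion — with severity-scaled
    jitter/shimmer, then additive white noise at an SNR that falls with
    severity.
    """
    if not 0.0 <= severity <= 1.0:
        raise ValueError("severity must lie in [0, 1]")
    if severity == 0.0:
        return w
    s = severity
    warp = 1.0 + d.time_warp_range * s * rng.uniform(-1, 1)
    syls = []
    for syl in t.syllables:
        drift = d.formant_drift_hz * s * rng.uniform(-1, 1, size=3)
        f1, f2, f3 = np.asarray(syl.formants) + drift
        # preserve ordering with a minimal gap rather than rejecting drifts
        f2 = max(f2, f1 + 50.0)
        f3 = max(f3, f2 + 50.0)
        mid = 0.5 * (syl.f0_start + syl.f0_end)
        flat = d.tone_flatten * s
        syls.append(
            replace(
                syl,
                formants=(float(f1), float(f2), float(f3)),
                f0_start=float(syl.f0_start + flat * (mid - syl.f0_start)),
                f0_end=float(syl.f0_end + flat * (mid - syl.f0_end)),
                duration=float(syl.duration * warp),
            )
        )
    if len(syls) > 1 and rng.uniform() < d.syllable_deletion_p * s:
        del syls[rng.integers(len(syls))]
    t_deg = WordTemplate(class_id=t.class_id, syllables=tuple(syls))
    out = synthesize_utterance(
        t_deg,
        rng=rng,
        rate=w.rate,
        formant_scale=formant_scale if formant_scale is not None else np.ones(3),
        pitch_scale=pitch_scale if pitch_scale is not None else 1.0,
        jitter=d.jitter_shimmer_depth * s,
        shimmer=d.jitter_shimmer_depth * s,
    )
    snr_db = d.snr_clean_db - d.snr_slope_db * s
    sig_pow = np.mean(out.samples**2)
    noise = rng.standard_normal(out.n_samples) * np.sqrt(sig_pow * 10.0 ** (-snr_db / 10.0))
    return Waveform(np.clip(out.samples + noise, -1, 1), w.rate)


@dataclass
class SyntheticDataset:
    """In-memory dataset: manifest plus id -> Waveform store."""

    manifest: DatasetManifest
    waveforms: dict[str, Waveform]
    templates: list[WordTemplate] = field(default_factory=list)


def generate_dataset(
    n_classes: int = 20,
    n_healthy_speakers: int = 34,
    n_patients: int = 12,
    reps_healthy: int = 5,
    reps_aphasic: int = 3,
    severity_levels: tuple[float, ...] = (0.2, 0.4, 0.6, 0.8),
    degradation: DegradationParams | None = None,
    rate: int = 8000,
    seed: int = 0,
) -> SyntheticDataset:
    """Generate a labeled synthetic corpus.

    Defaults mirror the clinical corpus shape: 20 word classes, 34 healthy
    speakers x 5 repetitions and 12 patients x 3 repetitions, patients
    carrying a per-speaker severity drawn uniformly from
    ``severity_levels``. Fully reproducible from ``seed``.
    """
    if min(n_classes, n_healthy_speakers + n_patients, reps_healthy) < 1:
        raise ValueError("counts must be >= 1")
    deg = degradation or DegradationParams()
    rng = np.random.default_rng(seed)
    templates = make_templates(n_classes, rng_seed=seed)
    entries: list[ManifestEntry] = []
    waveforms: dict[str, Waveform] = {}

    def speaker_scales(r):
        return 1.0 + 0.03 * r.uniform(-1, 1, size=3), 1.0 + 0.04 * r.uniform(-1, 1)

    for sp in range(n_healthy_speakers):
        fs, ps = speaker_scales(rng)
        for c, tpl in enumerate(templates):
            for rep in range(reps_healthy):
                uid = f"h{sp:03d}_c{c:02d}_r{rep}"
                w = synthesize_utterance(
                    tpl,
                    rng=rng,
                    rate=rate,
                    formant_scale=fs * (1.0 + 0.01 * rng.uniform(-1, 1, size=3)),
                    pitch_scale=ps * (1.0 + 0.01 * rng.uniform(-1, 1)),
                )
                waveforms[uid] = w
                entries.append(ManifestEntry(uid, "", c, HEALTHY, None, f"H{sp:03d}", rep))
    for pt in range(n_patients):
        fs, ps = speaker_scales(rng)
        severity = float(rng.choice(severity_levels))
        for c, tpl in enumerate(templates):
            for rep in range(reps_aphasic):
                uid = f"a{pt:03d}_c{c:02d}_r{rep}"
                clean = synthesize_utterance(tpl, rng=rng, rate=rate, formant_scale=fs, pitch_scale=ps)
                w = degrade(clean, tpl, deg, rng, severity, formant_scale=fs, pitch_scale=ps)
                waveforms[uid] = w
                entries.append(ManifestEntry(uid, "", c, APHASIC, severity, f"A{pt:03d}", rep))
    return SyntheticDataset(DatasetManifest(entries=entries), waveforms, templates)


def desk_scale_dataset(seed: int = 0, n_classes: int = 20) -> SyntheticDataset:
    """The package's standard test-scale corpus: 20 classes x (10 healthy
    speakers x 3 reps + 5 patients x 2 reps) = 800 utterances at 8 kHz.
    Ten healthy speakers give exactly two speakers per fold under
    speaker-grouped five-fold cross-validation."""
    return generate_dataset(
        n_classes=n_classes,
        n_healthy_speakers=10,
        n_patients=5,
        reps_healthy=3,
        reps_aphasic=2,
        seed=seed,
    )
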