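"""Cross-validated evaluation, performance metrics, exact Wilcoxon test, and
the three train/test scenarios.

Scenarios mirror the clinical study design:

1. train and test within the healthy cohort (5-fold cross-validation,
   speaker-disjoint folds by default);
2. train on all healthy data, test on the impaired cohort (dispersion from
   repeated training seeds, since the test set is disjoint by cohort);
3. train and test within the impaired cohort (5-fold cross-validation) —
   customized models only.

Metrics are accuracy and macro-averaged precision, recall and F1 over the
word classes, reported per fold with mean and standard deviation. Paired
model comparisons use the exact Wilcoxon signed-rank test (the p-value is
computed from the full null distribution of the signed-rank sum, not a
normal approximation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold

from .classifiers import ClassifierModel, extract_lda_features, fit_lda, predict_proba, train_cnn
from .htd_core import compute_htd, render_tf_image
from .preprocess import to_mono, trim_silence, resample
from .signal_io import APHASIC, HEALTHY, DatasetManifest, RunConfig, read_wav
from .synthetic_speech import SyntheticDataset

__all__ = [
    "FoldSplit",
    "MetricsReport",
    "ScenarioSpec",
    "make_folds",
    "score",
    "wilcoxon_exact",
    "prepare_features",
    "run_scenario",
]

METRICS = ("accuracy", "precision", "recall", "f1")


@dataclass(frozen=True)
class FoldSplit:
    folds: list[list[str]]  # utterance_ids per fold
    seed: int
    grouped: bool


@dataclass
class MetricsReport:
    per_fold: list[dict]  # one dict of METRICS per fold
    confusion: np.ndarray  # C x C, rows = truth, summed over folds
    n_classes: int
    # out-of-fold true-class output activation per test utterance (the TCOA
    # severity score under this scenario's models)
    oof_tcoa: dict[str, float] = field(default_factory=dict)

    @property
    def mean(self) -> dict:
        return {m: float(np.mean([f[m] for f in self.per_fold])) for m in METRICS}

    @property
    def sd(self) -> dict:
        return {m: float(np.std([f[m] for f in self.per_fold], ddof=1)) if len(self.per_fold) > 1 else 0.0 for m in METRICS}

    def summary(self) -> dict:
        return {
            "n_folds": len(self.per_fold),
            "mean": self.mean,
            "sd": self.sd,
            "per_fold": self.per_fold,
        }


@dataclass(frozen=True)
class ScenarioSpec:
    """Train/test cohort pairing: 1 healthy->healthy (CV), 2 healthy->aphasic,
    3 aphasic->aphasic (CV, customized models only)."""

    id: int

    def __post_init__(self) -> None:
        if self.id not in (1, 2, 3):
            raise ValueError("scenario id must be 1, 2 or 3")

    @property
    def train_cohort(self) -> str:
        return HEALTHY if self.id in (1, 2) else APHASIC

    @property
    def test_cohort(self) -> str:
        return HEALTHY if self.id == 1 else APHASIC


def make_folds(
    manifest: DatasetManifest, k: int = 5, seed: int = 0, group_by_speaker: bool = True
) -> FoldSplit:
    """Stratified k-fold assignment of utterance ids, optionally
    speaker-disjoint (no speaker contributes to two folds)."""
    ids = np.array([e.utterance_id for e in manifest])
    y = np.array([e.label for e in manifest])
    groups = np.array([e.speaker_id for e in manifest])
    classes, counts = np.unique(y, return_counts=True)
    if group_by_speaker:
        if np.unique(groups).size < k:
            raise ValueError(
                f"grouped {k}-fold split infeasible: only {np.unique(groups).size} speakers"
            )
        splitter = StratifiedGroupKFold(n_splits=k, shuffle=True, random_state=seed)
    else:
        if counts.min() < k:
            lacking = {int(c): int(n) for c, n in zip(classes, counts) if n < k}
            raise ValueError(f"stratified {k}-fold split infeasible; per-class counts {lacking}")
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = [list(ids[test]) for _, test in splitter.split(ids, y, groups)]
    return FoldSplit(folds=folds, seed=seed, grouped=group_by_speaker)


def score(preds, labels, n_classes: int | None = None) -> tuple[dict, np.ndarray]:
    """Accuracy plus macro precision/recall/F1 and the confusion matrix.

    Classes absent from both predictions and labels contribute zero to the
    macro averages (and stay in the denominator).
    """
    preds = np.asarray(preds)
    labels = np.asarray(labels)
    if preds.shape != labels.shape:
        raise ValueError(f"length mismatch: {preds.shape} vs {labels.shape}")
    c = n_classes if n_classes is not None else int(max(preds.max(), labels.max())) + 1
    label_set = np.arange(c)
    cm = confusion_matrix(labels, preds, labels=label_set)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p, r, f1, _ = precision_recall_fscore_support(
            labels, preds, labels=label_set, average="macro", zero_division=0
        )
    metrics = {
        "accuracy": float(np.trace(cm) / cm.sum()),
        "precision": float(p),
        "recall": float(r),
        "f1": float(f1),
    }
    return metrics, cm


def wilcoxon_exact(paired_a, paired_b) -> tuple[float, float]:
    """Exact two-sided Wilcoxon signed-rank test for paired samples.

    Zero differences are discarded before ranking (Wilcoxon's original
    rule); ties among |differences| get mid-ranks. The p-value is the exact
    two-sided tail probability of the positive-rank sum W+ over all 2^n
    equally likely sign assignments, evaluated by dynamic programming over
    the (doubled, hence integral) rank sums. Returns (W+, p).
    """
    a = np.asarray(paired_a, dtype=np.float64)
    b = np.asarray(paired_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    d = a - b
    d = d[d != 0]
    n = d.size
    if n == 0:
        warnings.warn("all paired differences are zero; degenerate test, p = 1")
        return 0.0, 1.0
    if n > 25:
        raise ValueError(f"exact method limited to 25 non-zero differences, got {n}")
    ranks = rankdata(np.abs(d))
    r2 = np.round(2.0 * ranks).astype(np.int64)  # doubled mid-ranks are integers
    w2 = int(r2[d > 0].sum())
    total = int(r2.sum())
    # null distribution of doubled W+: counts over sums 0..total
    counts = np.zeros(total + 1, dtype=np.float64)
    counts[0] = 1.0
    for r in r2:
        counts[r:] += counts[: total + 1 - r]
    denom = 2.0**n
    p_le = counts[: w2 + 1].sum() / denom
    p_ge = counts[w2:].sum() / denom
    p = min(1.0, 2.0 * min(p_le, p_ge))
    return float(w2 / 2.0), float(p)


# --------------------------------------------------------------------------
# End-to-end pipeline


def _load_waveform(entry, store: dict | None):
    if store is not None and entry.utterance_id in store:
        return store[entry.utterance_id]
    if entry.path:
        return read_wav(entry.path)
    raise KeyError(f"no waveform for utterance {entry.utterance_id}")


def prepare_features(
    dataset: SyntheticDataset | DatasetManifest,
    cfg: RunConfig | None = None,
    image_size: int | None = None,
) -> dict[str, dict]:
    """Run preprocess -> HTD -> (pooled features, TF image) for every
    utterance; returns a per-id cache shared by all models and folds."""
    cfg = cfg or RunConfig()
    if isinstance(dataset, SyntheticDataset):
        manifest, store = dataset.manifest, dataset.waveforms
    else:
        manifest, store = dataset, None
    size = image_size or (64 if cfg.train.backbone == "tiny-scratch" else cfg.train.input_size)
    out: dict[str, dict] = {}
    for e in manifest:
        w = to_mono(_load_waveform(e, store))
        if cfg.preprocess.target_rate:
            w = resample(w, cfg.preprocess.target_rate)
        w = trim_silence(w, cfg.preprocess)
        g = compute_htd(w, cfg)
        img = render_tf_image(g, size=size, colormap=cfg.colormap, floor_db=cfg.floor_db)
        out[e.utterance_id] = {"lda": extract_lda_features(g), "img": img.pixels}
    return out


def _fit_kind(kind: str, features: dict, manifest: DatasetManifest, train_ids: list[str], cfg: RunConfig, seed: int) -> ClassifierModel:
    by_id = {e.utterance_id: e for e in manifest}
    y = np.array([by_id[i].label for i in train_ids])
    if kind == "lda":
        X = np.stack([features[i]["lda"] for i in train_ids])
        return fit_lda(X, y, seed=seed)
    if kind == "cnn":
        X = np.stack([features[i]["img"] for i in train_ids])
        tc = cfg.train
        tc = type(tc)(**{**tc.__dict__, "seed": seed})
        return train_cnn(X, y, tc)
    raise ValueError(f"unknown model kind {kind!r}; customized kinds are 'cnn' and 'lda'")


def _predict_kind(model: ClassifierModel, features: dict, ids: list[str]) -> np.ndarray:
    key = "lda" if model.kind == "lda" else "img"
    X = np.stack([features[i][key] for i in ids])
    return predict_proba(model, X)


def run_scenario(
    spec: ScenarioSpec,
    dataset: SyntheticDataset | DatasetManifest,
    model_kinds=("cnn", "lda"),
    cfg: RunConfig | None = None,
    features: dict | None = None,
    k: int = 5,
    n_train_seeds: int = 3,
    return_models: bool = False,
) -> dict[str, MetricsReport]:
    """Run one evaluation scenario end to end and score every model kind.

    ``features`` may carry a precomputed :func:`prepare_features` cache to
    share the TFD work across scenarios. Scenario 2 has a cohort-disjoint
    test set, so its dispersion comes from ``n_train_seeds`` repeated
    trainings (for the deterministic LDA a single fit is reported).
    """
    cfg = cfg or RunConfig()
    manifest = dataset.manifest if isinstance(dataset, SyntheticDataset) else dataset
    for kind in model_kinds:
        if kind not in ("cnn", "lda"):
            raise ValueError(f"scenario evaluation supports customized models only, got {kind!r}")
    train_m = manifest.subset(cohort=spec.train_cohort)
    test_m = manifest.subset(cohort=spec.test_cohort)
    if len(train_m) == 0 or len(test_m) == 0:
        raise ValueError(f"scenario {spec.id}: required cohort is empty")
    if features is None:
        features = prepare_features(dataset, cfg)
    by_id = {e.utterance_id: e for e in manifest}
    n_classes = manifest.n_classes
    reports: dict[str, MetricsReport] = {}
    models: dict[str, ClassifierModel] = {}
    for kind in model_kinds:
        per_fold, cms = [], []
        oof: dict[str, float] = {}
        if spec.id in (1, 3):
            split = make_folds(train_m, k=k, seed=cfg.seed, group_by_speaker=True)
            all_ids = [e.utterance_id for e in train_m]
            for fold_ids in split.folds:
                hold = set(fold_ids)
                tr = [i for i in all_ids if i not in hold]
                model = _fit_kind(kind, features, manifest, tr, cfg, seed=cfg.seed)
                probs = _predict_kind(model, features, fold_ids)
                truth = [by_id[i].label for i in fold_ids]
                m, cm = score(probs.argmax(axis=1), truth, n_classes)
                per_fold.append(m)
                cms.append(cm)
                for j, uid in enumerate(fold_ids):
                    oof[uid] = float(probs[j, truth[j]])
            models[kind] = model
        else:
            tr = [e.utterance_id for e in train_m]
            te = [e.utterance_id for e in test_m]
            truth = [by_id[i].label for i in te]
            n_rep = n_train_seeds if kind == "cnn" else 1
            for rep in range(n_rep):
                model = _fit_kind(kind, features, manifest, tr, cfg, seed=cfg.seed + rep)
                probs = _predict_kind(model, features, te)
                m, cm = score(probs.argmax(axis=1), truth, n_classes)
                per_fold.append(m)
                cms.append(cm)
            for j, uid in enumerate(te):  # TCOA from the last-seed model
                oof[uid] = float(probs[j, truth[j]])
            models[kind] = model
        reports[kind] = MetricsReport(
            per_fold=per_fold, confusion=np.sum(cms, axis=0), n_classes=n_classes, oof_tcoa=oof
        )
    if return_models:
        return reports, models
    return reports
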