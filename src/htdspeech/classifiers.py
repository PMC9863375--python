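"""TF-image recognizers and the TCOA severity score.

Two classifier families operate on the time-frequency representations:

* ``lda`` — shrinkage-regularized linear discriminant analysis on pooled
  log-TFD features. The grid is log-compressed, mean-pooled to a fixed
  32 x 32 tile grid (1024 dims), then projected by a variance-preserving
  linear map (PCA, fitted on training data only) to min(C - 1, 64) dims so
  the within-class covariance stays well below the sample count.
* ``cnn`` — a convolutional network on rendered TF images, trained with
  cross-entropy, Adam (beta1 = 0.9, beta2 = 0.999), decoupled weight decay
  0.01, batch size 128, 15 epochs, and a cyclical learning rate peaking at
  0.003. The ``tiny-scratch`` backbone (3 conv blocks on 64 x 64 inputs)
  trains from random init on a single CPU; pretrained backbones would need
  downloaded weights and are not bundled.

Severity scoring: the normalized true-class output activation (TCOA) is the
model's posterior probability at the utterance's true word class. Healthy
speech scores near 1; impaired speech scores lower in proportion to
severity. A cut-off threshold (default 0.7) turns TCOA into a binary
healthy/aphasic decision, healthy iff TCOA >= threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from ._cnn import TinyConvNet
from .htd_core import TFDGrid
from .signal_io import APHASIC, HEALTHY, TrainConfig

__all__ = [
    "ClassifierModel",
    "SeverityScore",
    "extract_lda_features",
    "fit_lda",
    "train_cnn",
    "predict_proba",
    "tcoa",
    "score_severity",
    "severity_decision",
]

_POOL = 32  # pooled tile grid, 32 x 32 -> 1024 raw dims
_MAX_PROJ = 64


@dataclass
class ClassifierModel:
    kind: str  # "lda" | "cnn"
    n_classes: int
    model: object  # fitted estimator (PCA+LDA tuple or TinyConvNet)
    seed: int = 0


@dataclass(frozen=True)
class SeverityScore:
    tcoa: float
    true_class: int
    decision: str  # healthy | aphasic
    threshold: float


def _pool_block_mean(a: np.ndarray, out_shape: tuple[int, int]) -> np.ndarray:
    """Adaptive mean pooling of a 2-D array to ``out_shape`` tiles."""
    h, w = a.shape
    oh, ow = out_shape
    ei = (np.arange(oh + 1) * h) // oh
    ej = (np.arange(ow + 1) * w) // ow
    rows = np.add.reduceat(a, ei[:-1], axis=0)
    cnt_r = np.maximum(np.diff(ei), 1)[:, None]
    cols = np.add.reduceat(rows / cnt_r, ej[:-1], axis=1)
    cnt_c = np.maximum(np.diff(ej), 1)[None, :]
    return cols / cnt_c


def extract_lda_features(g: TFDGrid) -> np.ndarray:
    """1024-dim pooled log-TFD feature vector for one grid."""
    v = np.clip(g.values, 0.0, None)
    peak = v.max()
    if peak <= 0:
        return np.zeros(_POOL * _POOL)
    logv = 10.0 * np.log10(np.maximum(v / peak, 1e-6))
    return _pool_block_mean(logv, (_POOL, _POOL)).ravel()


def fit_lda(features: np.ndarray, labels: np.ndarray, seed: int = 0) -> ClassifierModel:
    """Shrinkage LDA on projected pooled features.

    Gaussian class-conditional posteriors; the Ledoit-Wolf shrinkage of the
    within-class covariance keeps the fit stable even when raw features
    outnumber samples.
    """
    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("need at least 2 classes")
    if counts.min() < 2:
        raise ValueError("need at least 2 samples per class")
    n_proj = min(classes.size - 1, _MAX_PROJ, X.shape[0] - 1, X.shape[1])
    pca = PCA(n_components=n_proj, random_state=seed).fit(X)
    lda = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
    lda.fit(pca.transform(X), y)
    return ClassifierModel(kind="lda", n_classes=int(classes.size), model=(pca, lda), seed=seed)


def train_cnn(images: np.ndarray, labels: np.ndarray, tc: TrainConfig | None = None) -> ClassifierModel:
    """Train the convolutional TF-image classifier per the training protocol.

    Only the self-contained ``tiny-scratch`` backbone ships with the
    package; the pretrained backbones named in TrainConfig require an
    external weights file and raise if requested.
    """
    tc = tc or TrainConfig()
    if tc.backbone != "tiny-scratch":
        raise NotImplementedError(
            f"backbone {tc.backbone!r} needs externally downloaded weights; only 'tiny-scratch' is bundled"
        )
    labels = np.asarray(labels)
    n_classes = int(labels.max()) + 1
    size = images.shape[1]
    net = TinyConvNet(n_classes=n_classes, input_size=size, seed=tc.seed)
    net.fit(
        images,
        labels,
        epochs=tc.epochs,
        batch_size=tc.batch_size,
        lr_peak=tc.lr_peak,
        beta1=tc.beta1,
        beta2=tc.beta2,
        weight_decay=tc.weight_decay,
    )
    return ClassifierModel(kind="cnn", n_classes=n_classes, model=net, seed=tc.seed)


def predict_proba(m: ClassifierModel, x: np.ndarray) -> np.ndarray:
    """Posterior probability vectors, one simplex row per input."""
    if m.kind == "lda":
        pca, lda = m.model
        x = np.atleast_2d(np.asarray(x, dtype=np.float64))
        if x.shape[1] != pca.n_features_in_:
            raise ValueError(f"feature dim {x.shape[1]} != expected {pca.n_features_in_}")
        return lda.predict_proba(pca.transform(x))
    if m.kind == "cnn":
        x = np.asarray(x)
        if x.ndim == 3:
            x = x[None]
        net: TinyConvNet = m.model
        if x.shape[1] != net.input_size or x.shape[2] != net.input_size:
            raise ValueError(f"image shape {x.shape[1:]} != expected ({net.input_size}, {net.input_size}, 3)")
        return net.predict_proba(x)
    raise ValueError(f"unknown model kind {m.kind!r}")


def tcoa(m: ClassifierModel, x: np.ndarray, true_class: int) -> float:
    """Normalized true-class output activation: posterior at the true class."""
    if not 0 <= true_class < m.n_classes:
        raise ValueError(f"true_class {true_class} outside [0, {m.n_classes})")
    p = predict_proba(m, x)
    return float(p[0, true_class])


def score_severity(m: ClassifierModel, x: np.ndarray, true_class: int, threshold: float = 0.7) -> SeverityScore:
    """TCOA plus the thresholded healthy/aphasic decision, as one record."""
    val = tcoa(m, x, true_class)
    return SeverityScore(
        tcoa=val, true_class=true_class, decision=severity_decision(val, threshold), threshold=threshold
    )


def severity_decision(tcoa_value: float, threshold: float = 0.7) -> str:
    """Binary healthy/aphasic decision from a TCOA score.

    Healthy iff tcoa >= threshold; the tie goes to healthy so the threshold
    itself is the lowest activation still classified as healthy speech.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    if not 0.0 <= tcoa_value <= 1.0:
        raise ValueError("tcoa must lie in [0, 1]")
    return HEALTHY if tcoa_value >= threshold else APHASIC
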