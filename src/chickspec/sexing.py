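"""Sex classifiers and their leave-one-out evaluation.

Two routes to a sex call from a preprocessed cohort:

* **PCA–LDA** — project spectra onto principal components, pick the
  discriminant component (smallest between-class t-test p on the scores),
  and run a two-class Fisher discriminant on it; evaluated with
  leave-one-out cross-validation in which PCA, component selection and LDA
  are all refit on each fold's training data.
* **Ratio plane** — a linear boundary in the 2-D space of two band-intensity
  ratios, fit as a Fisher discriminant; the formalisation of drawing a
  separating line through a ratio–ratio scatter plot.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .band_stats import _ttest_matrix
from .chemometrics import PCAResult, pca
from .spectra import SpectrumSet

__all__ = [
    "ConfusionMatrix",
    "FisherLDA",
    "RatioPlaneModel",
    "select_discriminant_pc",
    "lda_fit",
    "lda_predict",
    "pca_lda_loocv",
    "accuracy",
    "ratio_plane_fit",
    "evaluate_classifier",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts indexed by (true class, predicted class), fixed label order."""

    labels: tuple[str, str]
    counts: np.ndarray  # 2×2, rows = true, cols = predicted

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=int)
        if c.shape != (2, 2):
            raise ValueError("confusion matrix must be 2×2")
        if (c < 0).any():
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", c)

    @classmethod
    def from_predictions(
        cls, true: Sequence[str], predicted: Sequence[str], labels: tuple[str, str] = ("male", "female")
    ) -> "ConfusionMatrix":
        idx = {lab: i for i, lab in enumerate(labels)}
        counts = np.zeros((2, 2), dtype=int)
        for t, p in zip(true, predicted, strict=True):
            counts[idx[t], idx[p]] += 1
        return cls(labels, counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts,
            index=pd.Index(self.labels, name="true"),
            columns=pd.Index(self.labels, name="predicted"),
        )


def accuracy(cm: ConfusionMatrix) -> float:
    """Overall accuracy in percent, rounded to one decimal (e.g. 96.7)."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return round(100.0 * np.trace(cm.counts) / cm.total, 1)


def select_discriminant_pc(
    pca_result: PCAResult,
    labels: Sequence[str],
    rule: Literal["min_p"] = "min_p",
    n_considered: int | None = None,
) -> int:
    """Index of the component whose scores best separate the two classes.

    Automates the visual choice of "the discriminating PC": the component
    with the smallest two-sample t-test p-value between classes wins; ties
    break toward the lower index.
    """
    if rule != "min_p":
        raise ValueError(f"unknown rule {rule!r}")
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError(f"need exactly 2 classes, got {list(classes)}")
    scores = pca_result.scores
    if n_considered is not None:
        scores = scores[:, :n_considered]
    a = scores[labels == classes[0]]
    b = scores[labels == classes[1]]
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need ≥ 2 samples per class")
    _, p = _ttest_matrix(a, b, "student")
    return int(np.argmin(p))  # argmin returns the first (lowest) index on ties


@dataclass(frozen=True)
class FisherLDA:
    """Two-class Fisher discriminant: w ∝ Sw⁻¹(μ₁ − μ₂), midpoint threshold.

    Equal class priors; prediction is by which side of the threshold the
    projection falls on (the class-1 side is the μ₁ side).
    """

    labels: tuple[str, str]
    w: np.ndarray
    threshold: float
    positive_is_first: bool
    class_means: np.ndarray  # 2 × d


def lda_fit(
    scores: np.ndarray,
    labels: Sequence[str],
    class_order: tuple[str, str] | None = None,
    ridge: float = 1e-10,
) -> FisherLDA:
    X = np.atleast_2d(np.asarray(scores, dtype=float))
    if X.shape[0] == 1 and len(labels) > 1:
        X = X.T
    labels = np.asarray(labels)
    if class_order is None:
        cls = tuple(np.unique(labels))
    else:
        cls = class_order
    if len(cls) != 2 or set(np.unique(labels)) - set(cls):
        raise ValueError(f"need exactly 2 classes matching {cls}")
    X1, X2 = X[labels == cls[0]], X[labels == cls[1]]
    if len(X1) < 1 or len(X2) < 1:
        raise ValueError("need at least one sample per class")
    mu1, mu2 = X1.mean(axis=0), X2.mean(axis=0)
    # pooled within-class scatter; a singleton class contributes none
    Sw = np.zeros((X.shape[1], X.shape[1]))
    for Xi, mui in ((X1, mu1), (X2, mu2)):
        if len(Xi) > 1:
            Sw += (Xi - mui).T @ (Xi - mui)
    d = X.shape[1]
    try:
        w = np.linalg.solve(Sw, mu1 - mu2)
        if not np.all(np.isfinite(w)):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        reg = ridge * max(np.trace(Sw) / d, 1.0)
        w = np.linalg.solve(Sw + reg * np.eye(d), mu1 - mu2)
    if not np.any(w):
        raise ValueError("degenerate discriminant: identical class means")
    threshold = 0.5 * float(w @ (mu1 + mu2))
    return FisherLDA(
        labels=cls,
        w=w,
        threshold=threshold,
        positive_is_first=bool(w @ mu1 > threshold),
        class_means=np.vstack([mu1, mu2]),
    )


def lda_predict(model: FisherLDA, scores: np.ndarray) -> np.ndarray:
    X = np.atleast_2d(np.asarray(scores, dtype=float))
    if X.shape[1] != model.w.size:
        X = X.reshape(-1, model.w.size)
    proj = X @ model.w
    first = (proj > model.threshold) == model.positive_is_first
    return np.where(first, model.labels[0], model.labels[1])


def pca_lda_loocv(
    spectra: SpectrumSet,
    n_pcs_considered: int = 8,
    label_key: str = "sex",
    pc_rule: Literal["min_p"] | int = "min_p",
    refit_pca: bool = True,
) -> tuple[ConfusionMatrix, list[str]]:
    """Leave-one-out PCA–LDA classification of a labeled cohort.

    Per fold: fit PCA on the training spectra only, choose the discriminant
    PC on training labels (or use a fixed index), fit the Fisher
    discriminant on the training scores of that PC, project the held-out
    spectrum into the training PCA space and predict.  ``refit_pca=False``
    reproduces the simpler protocol of a single global PCA.

    Returns the accumulated confusion matrix and the per-sample predictions.
    """
    X = spectra.intensity_matrix()
    labels = np.asarray(spectra.labels(label_key))
    n = len(labels)
    if n < 4 or np.unique(labels).size != 2:
        raise ValueError("need ≥ 4 samples and exactly 2 classes")
    global_pca = None
    if not refit_pca:
        global_pca = pca(X, n_components=min(n_pcs_considered, n - 1, X.shape[1]))
    preds: list[str] = []
    for i in range(n):
        keep = np.arange(n) != i
        y_tr = labels[keep]
        if np.unique(y_tr).size < 2:
            preds.append("undefined")
            continue
        if refit_pca:
            p_model = pca(X[keep], n_components=min(n_pcs_considered, n - 2, X.shape[1]))
            tr_scores = p_model.scores
            te_scores = p_model.project(X[i])
        else:
            p_model = global_pca
            tr_scores = p_model.scores[keep]
            te_scores = p_model.scores[i : i + 1]
        if isinstance(pc_rule, int):
            pc = pc_rule
        else:
            pc = select_discriminant_pc(
                PCAResult(tr_scores, p_model.loadings, p_model.explained_variance_ratio, p_model.mean),
                y_tr,
                rule=pc_rule,
            )
        model = lda_fit(tr_scores[:, [pc]], y_tr)
        preds.append(str(lda_predict(model, te_scores[:, [pc]])[0]))
    defined = [i for i, p in enumerate(preds) if p != "undefined"]
    cm = ConfusionMatrix.from_predictions(
        [labels[i] for i in defined],
        [preds[i] for i in defined],
        labels=tuple(np.unique(labels)),
    )
    return cm, preds


@dataclass(frozen=True)
class RatioPlaneModel:
    """Linear decision boundary in a 2-D band-ratio space."""

    feature_names: tuple[str, str]
    lda: FisherLDA

    @property
    def boundary(self) -> tuple[np.ndarray, float]:
        """(weight vector, offset): w·x = offset is the separating line."""
        return self.lda.w, self.lda.threshold


def ratio_plane_fit(
    features: pd.DataFrame,
    pair: tuple[str, str],
    label_key: str = "sex",
) -> RatioPlaneModel:
    """Fisher discriminant in the plane of two ratio features."""
    for name in pair:
        if name not in features.columns:
            raise KeyError(f"feature {name!r} not in table columns {list(features.columns)}")
    X = features[list(pair)].to_numpy(dtype=float)
    labels = features[label_key].to_numpy()
    return RatioPlaneModel(pair, lda_fit(X, labels))


def _ratio_plane_predict(model: RatioPlaneModel, features: pd.DataFrame) -> np.ndarray:
    X = features[list(model.feature_names)].to_numpy(dtype=float)
    return lda_predict(model.lda, X)


def evaluate_classifier(
    features: pd.DataFrame,
    pair: tuple[str, str],
    label_key: str = "sex",
    scheme: Literal["loocv", "resubstitution"] = "loocv",
) -> tuple[ConfusionMatrix, list[str]]:
    """Held-out evaluation of the ratio-plane classifier (LOOCV refits per fold)."""
    labels = features[label_key].to_numpy()
    n = len(features)
    preds: list[str] = []
    if scheme == "resubstitution":
        model = ratio_plane_fit(features, pair, label_key)
        preds = list(_ratio_plane_predict(model, features))
    elif scheme == "loocv":
        for i in range(n):
            train = features.drop(features.index[i])
            if train[label_key].nunique() < 2:
                preds.append("undefined")
                continue
            model = ratio_plane_fit(train, pair, label_key)
            preds.append(str(_ratio_plane_predict(model, features.iloc[[i]])[0]))
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    defined = [i for i, p in enumerate(preds) if p != "undefined"]
    cm = ConfusionMatrix.from_predictions(
        [labels[i] for i in defined],
        [preds[i] for i in defined],
        labels=tuple(np.unique(labels)),
    )
    return cm, preds


def permutation_null_accuracies(
    spectra: SpectrumSet,
    n_permutations: int = 200,
    n_pcs_considered: int = 8,
    label_key: str = "sex",
    seed: int = 0,
    pc_rule: Literal["min_p"] | int = "min_p",
) -> np.ndarray:
    """PCA–LDA LOOCV accuracies under random label permutation.

    The per-fold PCA depends only on the spectra, so the fold projections
    are computed once and reused across permutations; only the component
    selection and the discriminant are refit per permutation.

    With a fixed ``pc_rule`` index the null accuracy centres on chance;
    with adaptive min-p selection it centres slightly *below* chance, the
    conservative anti-learning effect of selecting on training labels that
    carry no signal.
    """
    X = spectra.intensity_matrix()
    labels = np.asarray(spectra.labels(label_key))
    n = len(labels)
    folds = []
    for i in range(n):
        keep = np.arange(n) != i
        p_model = pca(X[keep], n_components=min(n_pcs_considered, n - 2, X.shape[1]))
        folds.append((keep, p_model.scores, p_model.project(X[i])))
    rng = np.random.default_rng(seed)
    accs = np.empty(n_permutations)
    for k in range(n_permutations):
        perm = rng.permutation(labels)
        correct = 0
        for i, (keep, tr_scores, te_scores) in enumerate(folds):
            y_tr = perm[keep]
            if np.unique(y_tr).size < 2:
                continue
            if isinstance(pc_rule, int):
                pc = pc_rule
            else:
                groups = np.unique(y_tr)
                _, p = _ttest_matrix(
                    tr_scores[y_tr == groups[0]], tr_scores[y_tr == groups[1]], "student"
                )
                pc = int(np.argmin(p))
            model = lda_fit(tr_scores[:, [pc]], y_tr)
            if lda_predict(model, te_scores[:, [pc]])[0] == perm[i]:
                correct += 1
        accs[k] = correct / n
    return accs
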