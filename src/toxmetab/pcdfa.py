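"""Principal component discriminant function analysis (PC-DFA).

PCA is computed on the centered (not standardized) feature matrix; the
number of retained components follows the Kaiser-Guttman rule adapted to
a covariance-matrix PCA — keep components whose eigenvalue exceeds the
mean eigenvalue — with a floor of two components. Fisher linear
discriminant analysis is then fit on the retained PC scores, and class
membership is predicted by the nearest class centroid in discriminant
space. Model quality is assessed by Monte-Carlo cross-validation:
repeated stratified splits, the whole model (centering, PCA, component
retention, LDA) refit on each training portion, and accuracy plus Cohen's
kappa averaged over iterations. Kappa is reported with its conventional
Landis-Koch verbal category.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg

__all__ = [
    "PCDFAModel",
    "ConfusionMatrix",
    "CVReport",
    "fit_pcdfa",
    "predict",
    "cohens_kappa",
    "mc_cross_validate",
    "classify_kappa",
]


class PCDFAError(ValueError):
    pass


@dataclass
class PCDFAModel:
    classes: np.ndarray            # sorted class labels
    center: np.ndarray             # per-feature training mean
    eigenvalues: np.ndarray        # full PCA spectrum (non-increasing)
    n_retained: int
    components: np.ndarray         # retained PC directions, (n_retained, n_features)
    discriminant_axes: np.ndarray  # (n_retained, n_ld)
    centroids: np.ndarray          # class centroids in LD space, (n_classes, n_ld)
    pc_scores: np.ndarray          # training samples x retained PCs
    ld_scores: np.ndarray          # training samples x LDs
    loadings: np.ndarray           # alias of components.T, (n_features, n_retained)
    training_accuracy: float = float("nan")


@dataclass
class ConfusionMatrix:
    counts: np.ndarray  # (k, k), rows = true, cols = predicted
    labels: np.ndarray

    @classmethod
    def from_predictions(cls, y_true, y_pred, labels) -> "ConfusionMatrix":
        labels = np.asarray(labels)
        idx = {l: i for i, l in enumerate(labels)}
        counts = np.zeros((len(labels), len(labels)), dtype=int)
        for t, p in zip(y_true, y_pred):
            counts[idx[t], idx[p]] += 1
        return cls(counts=counts, labels=labels)

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        if not np.array_equal(self.labels, other.labels):
            raise PCDFAError("cannot pool confusion matrices with different labels")
        return ConfusionMatrix(self.counts + other.counts, self.labels)

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.counts) / self.counts.sum())


@dataclass
class CVReport:
    n_iterations: int
    test_fraction: float
    accuracy: float                  # mean over iterations
    kappa: float                     # mean over iterations
    kappa_category: str
    per_iteration: pd.DataFrame      # columns accuracy, kappa
    pooled_confusion: ConfusionMatrix

    def to_dict(self) -> dict:
        return {
            "n_iterations": self.n_iterations,
            "test_fraction": self.test_fraction,
            "accuracy": self.accuracy,
            "kappa": self.kappa,
            "kappa_category": self.kappa_category,
            "confusion_labels": [str(l) for l in self.pooled_confusion.labels],
            "confusion_counts": self.pooled_confusion.counts.tolist(),
        }


def _kaiser_retention(eigenvalues: np.ndarray, n_features: int) -> int:
    """Components with eigenvalue above the mean eigenvalue, floor 2.

    For a covariance PCA the classical eigenvalue > 1 cut is meaningless
    (eigenvalues carry the units of squared peak area), so the mean-
    eigenvalue generalization is used: mean over all n_features
    dimensions, zeros beyond the matrix rank included.
    """
    mean_eig = eigenvalues.sum() / n_features
    return max(2, int((eigenvalues > mean_eig).sum()))


def fit_pcdfa(
    matrix: np.ndarray,
    labels: np.ndarray,
    n_retained: int | None = None,
    ridge: float = 1e-6,
) -> PCDFAModel:
    """Fit centering + PCA + Kaiser retention + Fisher LDA.

    ``ridge`` scales the regularization added to the within-class scatter
    (ridge * trace(Sw)/dim on the diagonal), needed when the number of
    retained components approaches the sample count.
    """
    X = np.asarray(matrix, float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) < 2:
        raise PCDFAError("need at least 2 classes")
    for c in classes:
        if (y == c).sum() < 3:
            raise PCDFAError(f"class {c!r} has fewer than 3 samples")
    n, p = X.shape

    center = X.mean(axis=0)
    Xc = X - center
    _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    eigenvalues = s**2 / (n - 1)
    rank = int((s > s[0] * 1e-12).sum()) if s.size and s[0] > 0 else 0
    if rank < 2:
        raise PCDFAError("matrix rank < 2: cannot retain two components")
    if n_retained is None:
        n_retained = _kaiser_retention(eigenvalues, p)
    n_retained = min(n_retained, rank, n - 1, p)
    if n_retained < 2:
        raise PCDFAError("fewer than 2 usable components")

    components = Vt[:n_retained]
    T = Xc @ components.T  # PC scores

    # Fisher LDA on retained scores
    dim = n_retained
    overall = T.mean(axis=0)
    Sw = np.zeros((dim, dim))
    Sb = np.zeros((dim, dim))
    means = {}
    for c in classes:
        Tc = T[y == c]
        mc = Tc.mean(axis=0)
        means[c] = mc
        d = Tc - mc
        Sw += d.T @ d
        db = (mc - overall)[:, None]
        Sb += len(Tc) * (db @ db.T)
    Sw_reg = Sw + ridge * (np.trace(Sw) / dim + 1e-300) * np.eye(dim)
    evals, evecs = linalg.eigh(Sb, Sw_reg)
    order = np.argsort(evals)[::-1]
    n_ld = min(len(classes) - 1, dim)
    axes = evecs[:, order[:n_ld]]
    # sign convention: largest-magnitude coefficient positive
    for j in range(axes.shape[1]):
        k = np.argmax(np.abs(axes[:, j]))
        if axes[k, j] < 0:
            axes[:, j] = -axes[:, j]

    L = T @ axes
    centroids = np.vstack([means[c] @ axes for c in classes])

    model = PCDFAModel(
        classes=classes,
        center=center,
        eigenvalues=eigenvalues,
        n_retained=n_retained,
        components=components,
        discriminant_axes=axes,
        centroids=centroids,
        pc_scores=T,
        ld_scores=L,
        loadings=components.T,
    )
    model.training_accuracy = float(np.mean(predict(model, X) == y))
    return model


def predict(model: PCDFAModel, new_samples: np.ndarray) -> np.ndarray:
    """Nearest-centroid class assignment in discriminant space.

    Ties break deterministically to the lexicographically first label
    (argmin over the sorted class array).
    """
    X = np.asarray(new_samples, float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != model.center.shape[0]:
        raise PCDFAError(
            f"feature mismatch: model has {model.center.shape[0]} features, "
            f"input has {X.shape[1]}"
        )
    L = (X - model.center) @ model.components.T @ model.discriminant_axes
    d2 = ((L[:, None, :] - model.centroids[None, :, :]) ** 2).sum(axis=2)
    return model.classes[np.argmin(d2, axis=1)]


def cohens_kappa(cm: ConfusionMatrix | np.ndarray) -> float:
    """Chance-corrected agreement kappa = (p_o - p_e) / (1 - p_e)."""
    counts = cm.counts if isinstance(cm, ConfusionMatrix) else np.asarray(cm, float)
    total = counts.sum()
    if total <= 0:
        raise PCDFAError("empty confusion matrix")
    p_o = np.trace(counts) / total
    p_e = float((counts.sum(axis=1) * counts.sum(axis=0)).sum()) / total**2
    if p_e >= 1.0 - 1e-15:
        warnings.warn("degenerate confusion matrix (chance agreement 1); kappa set to 0")
        return 0.0
    return float((p_o - p_e) / (1 - p_e))


def _stratified_split(y: np.ndarray, test_fraction: float, rng: np.random.Generator):
    train_idx, test_idx = [], []
    for c in np.unique(y):
        idx = np.flatnonzero(y == c)
        n_test = max(1, int(round(test_fraction * len(idx))))
        if len(idx) - n_test < 3:
            raise PCDFAError(
                f"class {c!r} too small to stratify: {len(idx)} samples, "
                f"{n_test} requested for test"
            )
        perm = rng.permutation(idx)
        test_idx.extend(perm[:n_test])
        train_idx.extend(perm[n_test:])
    return np.array(sorted(train_idx)), np.array(sorted(test_idx))


def mc_cross_validate(
    matrix: np.ndarray,
    labels: np.ndarray,
    n_iter: int = 1000,
    test_fraction: float = 1 / 3,
    seed: int = 0,
    n_retained: int | None = None,
) -> CVReport:
    """Monte-Carlo cross-validation of the full PC-DFA model.

    Each iteration draws a stratified random split and refits everything —
    centering, PCA, component retention, LDA — on the training portion
    only, so no information leaks from the held-out samples. Accuracy and
    kappa are computed per iteration and averaged; a pooled confusion
    matrix over all iterations is also reported.
    """
    X = np.asarray(matrix, float)
    y = np.asarray(labels)
    classes = np.unique(y)
    rng = np.random.default_rng(seed)
    rows = []
    pooled = ConfusionMatrix(np.zeros((len(classes), len(classes)), int), classes)
    for _ in range(n_iter):
        tr, te = _stratified_split(y, test_fraction, rng)
        model = fit_pcdfa(X[tr], y[tr], n_retained=n_retained)
        pred = predict(model, X[te])
        cm = ConfusionMatrix.from_predictions(y[te], pred, classes)
        rows.append((cm.accuracy, cohens_kappa(cm)))
        pooled = pooled + cm
    per_iter = pd.DataFrame(rows, columns=["accuracy", "kappa"])
    kappa = float(per_iter["kappa"].mean())
    return CVReport(
        n_iterations=n_iter,
        test_fraction=test_fraction,
        accuracy=float(per_iter["accuracy"].mean()),
        kappa=kappa,
        kappa_category=classify_kappa(max(-1.0, min(1.0, kappa))),
        per_iteration=per_iter,
        pooled_confusion=pooled,
    )


#: Landis-Koch verbal categories, upper bounds inclusive.
_LANDIS_KOCH = (
    (0.20, "slight"),
    (0.40, "fair"),
    (0.60, "moderate"),
    (0.80, "substantial"),
    (1.00, "almost perfect"),
)


def classify_kappa(kappa: float) -> str:
    """Landis-Koch verbal category for an agreement kappa in [-1, 1]."""
    if not -1 <= kappa <= 1:
        raise PCDFAError(f"kappa out of range [-1, 1]: {kappa}")
    if kappa < 0:
        return "poor"
    for hi, label in _LANDIS_KOCH:
        if kappa <= hi:
            return label
    raise AssertionError("unreachable")
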