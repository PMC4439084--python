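"""PCA feature reduction and leave-one-out nearest-neighbour classification.

Modulated spectra are reduced to scores on the leading principal components
(default 7, which capture the bulk of dataset variance) and each cell is
classified by leave-one-out cross-validation (LOOCV): the principal axes are
refit on all cells except the held-out one, every cell is projected into
that score space, and the held-out cell takes the label of its nearest
training neighbour (Euclidean distance, k = 1, ties broken by smallest cell
id).  Predictions are summarised in an actual-by-predicted confusion matrix;
two-class runs additionally yield sensitivity and specificity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.decomposition import PCA

from .extract import ModulatedSpectrum, SpectraDataset

__all__ = [
    "PCAModel",
    "ConfusionMatrix",
    "PairwiseMetrics",
    "fit_pca",
    "project",
    "loocv_classify",
    "pairwise_metrics",
    "metrics_from_confusion",
    "matrix_summaries",
]


@dataclass
class PCAModel:
    """Mean-centred PCA fit over a set of modulated spectra.

    ``components`` has shape ``(n_components, n_bins)``; rows are mutually
    orthonormal and ordered by non-increasing explained variance.
    """

    axis: np.ndarray
    mean_spectrum: np.ndarray
    components: np.ndarray
    explained_variance_ratios: np.ndarray
    n_components: int

    def __post_init__(self) -> None:
        gram = self.components @ self.components.T
        if not np.allclose(gram, np.eye(self.n_components), atol=1e-8):
            raise ValueError("components must be orthonormal")
        if np.any(np.diff(self.explained_variance_ratios) > 1e-12):
            raise ValueError("explained-variance ratios must be non-increasing")


@dataclass
class ConfusionMatrix:
    """Actual-by-predicted counts; rows are actual classes."""

    class_order: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.class_order)
        if self.counts.shape != (k, k):
            raise ValueError("counts must be square and match class_order")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @classmethod
    def from_predictions(
        cls,
        actual: Sequence[str],
        predicted: Sequence[str],
        class_order: Sequence[str],
    ) -> "ConfusionMatrix":
        order = tuple(class_order)
        index = {c: i for i, c in enumerate(order)}
        counts = np.zeros((len(order), len(order)), dtype=int)
        for a, p in zip(actual, predicted, strict=True):
            counts[index[a], index[p]] += 1
        return cls(class_order=order, counts=counts)


@dataclass(frozen=True)
class PairwiseMetrics:
    """Sensitivity/specificity of a two-class comparison.

    With the designated positive class P: sensitivity = TP/(TP+FN) (recall
    of P), specificity = TN/(TN+FP) (recall of the negative class).
    """

    positive_class: str
    negative_class: str
    sensitivity: float
    specificity: float
    n_positive: int
    n_negative: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.sensitivity <= 1.0 and 0.0 <= self.specificity <= 1.0):
            raise ValueError("metrics must lie in [0, 1]")
        if self.n_positive < 1 or self.n_negative < 1:
            raise ValueError("both classes need at least one member")


def _ordered_unique(labels: Sequence[str]) -> tuple[str, ...]:
    seen: dict[str, None] = {}
    for lab in labels:
        seen.setdefault(lab)
    return tuple(seen)


def fit_pca(dataset: SpectraDataset, n_components: int = 7) -> PCAModel:
    """Fit mean-centred PCA over the cells-by-bins matrix."""
    X = dataset.matrix()
    n, d = X.shape
    limit = min(n - 1, d)
    if not 1 <= n_components <= limit:
        raise ValueError(
            f"n_components={n_components} invalid for {n} spectra over {d} bins "
            f"(must be between 1 and {limit})"
        )
    fit = PCA(n_components=n_components, svd_solver="full").fit(X)
    return PCAModel(
        axis=dataset.axis,
        mean_spectrum=fit.mean_,
        components=fit.components_,
        explained_variance_ratios=fit.explained_variance_ratio_,
        n_components=n_components,
    )


def project(model: PCAModel, spectrum: ModulatedSpectrum | np.ndarray) -> np.ndarray:
    """Scores of one spectrum (or a stacked matrix) in the model's PC space."""
    if isinstance(spectrum, ModulatedSpectrum):
        if spectrum.axis.shape != model.axis.shape or not np.allclose(
            spectrum.axis, model.axis
        ):
            raise ValueError(f"spectrum {spectrum.cell_id!r} is not on the model's axis")
        x = spectrum.values
    else:
        x = np.asarray(spectrum, dtype=float)
    return (x - model.mean_spectrum) @ model.components.T


def loocv_classify(
    dataset: SpectraDataset,
    n_components: int = 7,
    refit_per_fold: bool = True,
) -> tuple[list[str], ConfusionMatrix]:
    """Leave-one-out nearest-neighbour classification in PC-score space.

    For each cell the principal components are refit on the remaining cells
    (``refit_per_fold=False`` reuses one shared fit — faster, approximate),
    all cells are projected, and the held-out cell is assigned the label of
    its Euclidean-nearest training neighbour.  Equidistant neighbours are
    resolved in favour of the smallest cell id.  Every class needs at least
    two members, otherwise its own fold has no same-class neighbour by
    construction.
    """
    labels = np.array(dataset.class_labels())
    ids = np.array(dataset.cell_ids())
    class_order = _ordered_unique(dataset.class_labels())
    if len(class_order) < 2:
        raise ValueError("at least two classes are required")
    for c in class_order:
        if np.sum(labels == c) < 2:
            raise ValueError(f"class {c!r} has a single member; LOOCV needs >= 2 per class")
    X = dataset.matrix()
    n = len(dataset)

    shared = None if refit_per_fold else fit_pca(dataset, n_components)
    predictions: list[str] = []
    for i in range(n):
        train = np.arange(n) != i
        if refit_per_fold:
            model = fit_pca(SpectraDataset([dataset.spectra[j] for j in range(n) if j != i]),
                            n_components)
        else:
            model = shared
        scores_train = project(model, X[train])
        score_i = project(model, X[i])
        dists = np.linalg.norm(scores_train - score_i, axis=1)
        best = np.lexsort((ids[train], dists))[0]
        predictions.append(str(labels[train][best]))
    cm = ConfusionMatrix.from_predictions(labels, predictions, class_order)
    return predictions, cm


def metrics_from_confusion(cm: ConfusionMatrix, positive_class: str) -> PairwiseMetrics:
    """Sensitivity/specificity from a 2x2 confusion matrix."""
    if len(cm.class_order) != 2:
        raise ValueError("metrics_from_confusion requires a 2x2 confusion matrix")
    if positive_class not in cm.class_order:
        raise ValueError(f"{positive_class!r} is not one of {cm.class_order}")
    pos = cm.class_order.index(positive_class)
    neg = 1 - pos
    tp = cm.counts[pos, pos]
    fn = cm.counts[pos, neg]
    tn = cm.counts[neg, neg]
    fp = cm.counts[neg, pos]
    return PairwiseMetrics(
        positive_class=cm.class_order[pos],
        negative_class=cm.class_order[neg],
        sensitivity=tp / (tp + fn),
        specificity=tn / (tn + fp),
        n_positive=int(tp + fn),
        n_negative=int(tn + fp),
    )


def pairwise_metrics(
    dataset: SpectraDataset,
    n_components: int = 7,
    positive_class: str | None = None,
    refit_per_fold: bool = True,
) -> PairwiseMetrics:
    """Two-class LOOCV sensitivity and specificity.

    The dataset must contain exactly two classes.  The positive class
    defaults to the first class encountered in the dataset; this convention
    is a parameter because sensitivity and specificity swap roles when the
    positive class is swapped.
    """
    class_order = _ordered_unique(dataset.class_labels())
    if len(class_order) != 2:
        raise ValueError(f"exactly two classes required, found {len(class_order)}")
    if positive_class is None:
        positive_class = class_order[0]
    _, cm = loocv_classify(dataset, n_components=n_components, refit_per_fold=refit_per_fold)
    return metrics_from_confusion(cm, positive_class)


def matrix_summaries(cm: ConfusionMatrix) -> tuple[int, float, dict[str, float]]:
    """Total cells, overall accuracy (trace/total), per-class recall."""
    total = int(cm.counts.sum())
    if total == 0:
        raise ValueError("confusion matrix is empty")
    accuracy = float(np.trace(cm.counts)) / total
    recalls: dict[str, float] = {}
    for i, c in enumerate(cm.class_order):
        row = cm.counts[i].sum()
        recalls[c] = float(cm.counts[i, i]) / row if row else float("nan")
    return total, accuracy, recalls
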