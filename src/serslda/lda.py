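"""Linear discriminant analysis from scatter matrices.

The discriminant subspace is built directly from the within-class scatter
S_W = sum_i sum_{x in D_i} (x - m_i)(x - m_i)^T and the between-class
scatter S_B = sum_i (m_i - m)(m_i - m)^T, where m_i are the class means
and m the grand mean.  The projection matrix V holds the leading
eigenvectors of S_W^{-1} S_B, solved as a symmetric generalized
eigenproblem with ridge shrinkage on S_W (needed whenever the feature
count exceeds the sample count, the usual situation for full-resolution
spectra).  Scores are Z = (X - m) V; classification is nearest centroid in
the reduced space.

Two scatter conventions are supported.  The default is the unweighted
between-class sum over classes paired with the unweighted mean of class
means as grand mean; `weighted=True` gives the textbook N_i-weighted form
with the pooled sample mean.  Either way sum_i w_i (m_i - m) = 0 exactly,
so rank(S_B) <= c - 1 holds exactly and a c-class problem has exactly
c - 1 discriminant directions with nonzero eigenvalue.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import scipy.linalg

from .exceptions import ConfigurationError, DegenerateInputError
from .preprocess import SpectraMatrix
from .synth import WavenumberAxis

SeedLike = Union[int, np.random.Generator, np.random.SeedSequence]


def _rng(seed: SeedLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class ScatterPair:
    """Within/between-class scatter matrices with the class statistics."""

    S_W: np.ndarray
    S_B: np.ndarray
    class_means: np.ndarray  # c x p, rows ordered like `classes`
    grand_mean: np.ndarray
    class_sizes: np.ndarray
    classes: tuple[str, ...]
    weighted: bool

    @property
    def c(self) -> int:
        return len(self.classes)


@dataclass
class LDAModel:
    V: np.ndarray  # p x k, unit-norm columns
    eigenvalues: np.ndarray  # k leading, descending
    eigenvalues_all: np.ndarray  # full generalized spectrum, descending
    classes: tuple[str, ...]
    centroids: np.ndarray  # c x k, projected class means
    grand_mean: np.ndarray
    shrinkage: float
    scatter: ScatterPair
    axis: Optional[WavenumberAxis] = None

    @property
    def n_components(self) -> int:
        return self.V.shape[1]


@dataclass
class LDScores:
    """n x k matrix of discriminant scores (columns LD1, LD2, ...)."""

    Z: np.ndarray

    @property
    def n(self) -> int:
        return self.Z.shape[0]

    def column(self, k: int) -> np.ndarray:
        return self.Z[:, k]


@dataclass
class ClassMetrics:
    classes: tuple[str, ...]
    confusion: np.ndarray  # rows = truth, cols = prediction
    per_class: dict  # name -> {precision, sensitivity, f_score, support}
    accuracy: float
    undefined: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "per_class": self.per_class,
            "confusion": self.confusion.tolist(),
            "classes": list(self.classes),
            "undefined": list(self.undefined),
        }


def split_train_test(
    M: SpectraMatrix, ratio: float = 0.5, seed: SeedLike = 0
) -> tuple[SpectraMatrix, SpectraMatrix]:
    """Stratified random split; `ratio` is the training fraction.

    The partition is exact (disjoint and exhaustive) and deterministic
    under the seed.  Every class must contribute to both halves.
    """
    if not (0.0 < ratio < 1.0):
        raise ConfigurationError("split ratio must lie strictly between 0 and 1")
    rng = _rng(seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for name in M.classes:
        idx = M.class_indices(name)
        if idx.size < 2:
            raise DegenerateInputError(
                f"class {name!r} has {idx.size} member(s); need >= 2 to split"
            )
        perm = rng.permutation(idx)
        n_train = int(round(ratio * idx.size))
        n_train = min(max(n_train, 1), idx.size - 1)
        train_idx.extend(perm[:n_train].tolist())
        test_idx.extend(perm[n_train:].tolist())
    return M.take_rows(sorted(train_idx)), M.take_rows(sorted(test_idx))


def augment_gaussian(
    train: SpectraMatrix,
    sigma_rel: float = 0.05,
    copies: int = 2,
    seed: SeedLike = 0,
) -> SpectraMatrix:
    """Augment training spectra with Gaussian noise.

    Each of `copies` replicas adds noise with per-feature SD equal to
    `sigma_rel` times that feature's SD over the training set; the output
    stacks the originals first, then the replica blocks.
    """
    if sigma_rel < 0 or copies < 0:
        raise ConfigurationError("sigma_rel and copies must be >= 0")
    if copies == 0:
        return train.take_rows(np.arange(train.n))
    rng = _rng(seed)
    feat_sd = train.X.std(axis=0)
    blocks = [train.X]
    for _ in range(copies):
        blocks.append(train.X + rng.standard_normal(train.X.shape) * sigma_rel * feat_sd)
    X = np.vstack(blocks)
    labels = np.tile(train.labels, copies + 1)
    return SpectraMatrix(X, train.axis, labels, dict(train.meta))


def scatter_matrices(M: SpectraMatrix, weighted: bool = False) -> ScatterPair:
    """Within- and between-class scatter of a labelled matrix.

    Default: S_B is the plain (unweighted) sum over classes and the grand
    mean is the unweighted mean of class means.  `weighted=True` weights
    the between-class terms by class size and centres on the pooled mean.
    """
    classes = M.classes
    if len(classes) < 2:
        raise DegenerateInputError("scatter matrices need >= 2 classes")
    p = M.p
    means = np.empty((len(classes), p))
    sizes = np.empty(len(classes), dtype=int)
    S_W = np.zeros((p, p))
    for i, name in enumerate(classes):
        rows = M.X[M.class_indices(name)]
        sizes[i] = rows.shape[0]
        means[i] = rows.mean(axis=0)
        dev = rows - means[i]
        S_W += dev.T @ dev
    if weighted:
        grand = (sizes[:, None] * means).sum(axis=0) / sizes.sum()
        w = sizes.astype(float)
    else:
        grand = means.mean(axis=0)
        w = np.ones(len(classes))
    dev_b = means - grand
    S_B = (w[:, None] * dev_b).T @ dev_b
    S_W = 0.5 * (S_W + S_W.T)
    S_B = 0.5 * (S_B + S_B.T)
    return ScatterPair(
        S_W=S_W,
        S_B=S_B,
        class_means=means,
        grand_mean=grand,
        class_sizes=sizes,
        classes=classes,
        weighted=weighted,
    )


def _fix_column_signs(V: np.ndarray) -> np.ndarray:
    for j in range(V.shape[1]):
        k = int(np.argmax(np.abs(V[:, j])))
        if V[k, j] < 0:
            V[:, j] = -V[:, j]
    return V


def fit_lda(
    train: SpectraMatrix,
    n_components: int = 2,
    shrinkage: float = 1e-3,
    weighted: bool = False,
) -> LDAModel:
    """Fit the discriminant subspace from the scatter matrices.

    Solves the symmetric generalized eigenproblem
    S_B v = lambda (S_W + gamma * tr(S_W)/p * I) v and keeps the
    `n_components` eigenvectors of largest eigenvalue, unit-normalized,
    with the sign fixed so each column's largest-magnitude entry is
    positive.  `shrinkage` (gamma) must be positive whenever S_W is
    singular, i.e. whenever features outnumber training samples.
    """
    scatter = scatter_matrices(train, weighted=weighted)
    c, p = scatter.c, train.p
    if not (0.0 <= shrinkage < 1.0):
        raise ConfigurationError("shrinkage must lie in [0, 1)")
    if n_components > c - 1:
        raise ConfigurationError(
            f"at most c-1 = {c - 1} components carry between-class signal"
        )
    S_W_reg = scatter.S_W
    if shrinkage > 0.0:
        S_W_reg = scatter.S_W + shrinkage * (np.trace(scatter.S_W) / p) * np.eye(p)
    else:
        try:
            np.linalg.cholesky(scatter.S_W)
        except np.linalg.LinAlgError:
            raise DegenerateInputError(
                "S_W is singular (features >= samples?); set shrinkage > 0"
            ) from None
    evals, evecs = scipy.linalg.eigh(scatter.S_B, S_W_reg)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    V = evecs[:, order[:n_components]]
    V = V / np.linalg.norm(V, axis=0, keepdims=True)
    V = _fix_column_signs(V)
    centroids = (scatter.class_means - scatter.grand_mean) @ V
    return LDAModel(
        V=V,
        eigenvalues=evals[:n_components],
        eigenvalues_all=evals,
        classes=scatter.classes,
        centroids=centroids,
        grand_mean=scatter.grand_mean,
        shrinkage=shrinkage,
        scatter=scatter,
        axis=train.axis,
    )


def project(model: LDAModel, X: np.ndarray) -> LDScores:
    """Discriminant scores Z = (X - grand_mean) V.

    Centering by the training grand mean anchors the origin of the LD
    plane at the overall mean; it shifts all scores equally and leaves
    nearest-centroid classification unchanged.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.V.shape[0]:
        raise ConfigurationError(
            f"feature count {X.shape[1]} does not match model ({model.V.shape[0]})"
        )
    return LDScores(Z=(X - model.grand_mean) @ model.V)


def classify(model: LDAModel, scores: LDScores) -> np.ndarray:
    """Nearest-centroid labels in LD space (Euclidean).

    Class centroids are ordered lexicographically, and `argmin` returns
    the first minimum, so exact ties resolve to the lexicographically
    smallest class name.
    """
    d2 = ((scores.Z[:, None, :] - model.centroids[None, :, :]) ** 2).sum(axis=2)
    return np.array([model.classes[i] for i in np.argmin(d2, axis=1)], dtype=object)


def evaluate(pred: Sequence[str], truth: Sequence[str]) -> ClassMetrics:
    """Per-class precision, sensitivity and F score plus overall accuracy.

    F is the harmonic mean of precision and sensitivity.  A class with no
    true members (sensitivity undefined) or no predictions (precision
    undefined) is reported as NaN and listed in `undefined` rather than
    silently zeroed.
    """
    pred = np.asarray(pred, dtype=object)
    truth = np.asarray(truth, dtype=object)
    if pred.shape != truth.shape:
        raise ConfigurationError("prediction and truth lengths differ")
    classes = tuple(sorted(set(truth.tolist()) | set(pred.tolist())))
    index = {c: i for i, c in enumerate(classes)}
    confusion = np.zeros((len(classes), len(classes)), dtype=int)
    for t, q in zip(truth, pred):
        confusion[index[t], index[q]] += 1
    per_class: dict = {}
    undefined: list[str] = []
    for c in classes:
        i = index[c]
        tp = confusion[i, i]
        fp = confusion[:, i].sum() - tp
        fn = confusion[i, :].sum() - tp
        support = int(confusion[i, :].sum())
        precision = tp / (tp + fp) if tp + fp > 0 else float("nan")
        sensitivity = tp / (tp + fn) if tp + fn > 0 else float("nan")
        if np.isnan(precision) or np.isnan(sensitivity):
            undefined.append(c)
            f = float("nan")
        elif precision + sensitivity == 0:
            f = 0.0
        else:
            f = 2 * precision * sensitivity / (precision + sensitivity)
        per_class[c] = {
            "precision": float(precision),
            "sensitivity": float(sensitivity),
            "f_score": float(f),
            "support": support,
        }
    accuracy = float((pred == truth).mean())
    return ClassMetrics(
        classes=classes,
        confusion=confusion,
        per_class=per_class,
        accuracy=accuracy,
        undefined=tuple(undefined),
    )
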