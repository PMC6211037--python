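"""Fisher linear discriminant analysis of the three-feature duet table.

The discriminant directions maximize the Fisher criterion — the ratio of
between-class to within-class scatter, which in the univariate two-class
case reduces to (mu1 - mu2)^2 / (s1^2 + s2^2) — and are the eigenvectors of
W^-1 B ordered by eigenvalue.  With three lineages and three predictors
there are exactly two directions (LD1, LD2) whose eigenvalue shares give
the proportion of trace.  Classification uses the shared-covariance
Gaussian discriminant with priors proportional to class sizes, evaluated
on the training set (resubstitution), matching the published workflow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .temporal import FeatureRow

__all__ = ["LdaModel", "ConfusionMatrix", "fit_lda", "classify",
           "biplot_data", "rows_to_matrix"]

FEATURE_NAMES = ("dominant_frequency", "sequence_duration", "pant_rate")


@dataclass(frozen=True)
class LdaModel:
    classes: tuple[str, ...]
    class_means: np.ndarray          # (k, p), in transformed space
    pooled_cov: np.ndarray           # (p, p) within-class covariance
    directions: np.ndarray           # (p, d) discriminant vectors (columns)
    eigenvalues: np.ndarray          # (d,)
    proportion_of_trace: np.ndarray  # (d,) eigenvalue shares; NaN if all ~0
    priors: np.ndarray               # (k,)
    standardize: bool
    feature_mean: np.ndarray
    feature_scale: np.ndarray
    feature_names: tuple[str, ...] = FEATURE_NAMES

    def transform_features(self, X: np.ndarray) -> np.ndarray:
        """Apply the fitted standardization (identity when off)."""
        return (np.asarray(X, dtype=float) - self.feature_mean) / self.feature_scale

    def scores(self, X: np.ndarray) -> np.ndarray:
        """Project feature rows onto the discriminant directions."""
        return self.transform_features(X) @ self.directions


@dataclass(frozen=True)
class ConfusionMatrix:
    classes: tuple[str, ...]
    counts: np.ndarray               # true class x predicted class
    misclassified: tuple[str, ...]   # sample ids off the diagonal

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.counts) / self.counts.sum())

    @property
    def n_misclassified(self) -> int:
        return int(self.counts.sum() - np.trace(self.counts))


def rows_to_matrix(rows: list[FeatureRow]) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """(features, class labels, sample ids) from a feature table."""
    X = np.array([[r.dominant_frequency, r.sequence_duration, r.pant_rate]
                  for r in rows])
    y = np.array([r.lineage for r in rows])
    ids = [r.group for r in rows]
    return X, y, ids


def fit_lda(rows_or_X, y=None, standardize: bool = True) -> LdaModel:
    """Fit Fisher LDA with the lineage as class.

    Accepts either a list of :class:`FeatureRow` or an (n, p) matrix plus
    labels.  Features are z-standardized by default.  Directions are unit
    eigenvectors of W^-1 B sorted by decreasing eigenvalue; each is signed
    so the first class's centroid projects non-negatively on LD1 (and the
    largest-magnitude loading is positive on later axes) for reproducible
    plots.
    """
    if y is None:
        X, y, _ = rows_to_matrix(rows_or_X)
    else:
        X = np.asarray(rows_or_X, dtype=float)
        y = np.asarray(y)
    classes = tuple(sorted(set(y.tolist())))
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    n, p = X.shape

    if standardize:
        mean, scale = X.mean(axis=0), X.std(axis=0, ddof=1)
        if np.any(scale == 0):
            dead = [FEATURE_NAMES[i] if i < len(FEATURE_NAMES) else str(i)
                    for i in np.flatnonzero(scale == 0)]
            raise ValueError(f"constant feature(s): {dead}")
    else:
        mean, scale = np.zeros(p), np.ones(p)
    Z = (X - mean) / scale

    grand = Z.mean(axis=0)
    W = np.zeros((p, p))
    B = np.zeros((p, p))
    means = []
    counts = []
    for c in classes:
        sub = Z[y == c]
        if len(sub) < 2:
            raise ValueError(f"class {c!r} needs at least two samples")
        m = sub.mean(axis=0)
        means.append(m)
        counts.append(len(sub))
        centered = sub - m
        W += centered.T @ centered
        B += len(sub) * np.outer(m - grand, m - grand)
    if np.linalg.matrix_rank(W) < p:
        corr = np.corrcoef(Z, rowvar=False)
        hi = np.argwhere(np.triu(np.abs(corr) > 0.999, k=1))
        pairs = [f"{FEATURE_NAMES[i] if i < 3 else i}~{FEATURE_NAMES[j] if j < 3 else j}"
                 for i, j in hi]
        raise ValueError(f"singular within-class scatter; collinear: {pairs}")

    d = min(len(classes) - 1, p)
    eigvals, eigvecs = linalg.eigh(B, W)   # generalized symmetric problem
    order = np.argsort(eigvals)[::-1][:d]
    eigvals = np.clip(eigvals[order], 0.0, None)
    directions = eigvecs[:, order]
    directions /= np.linalg.norm(directions, axis=0)

    means = np.vstack(means)
    # sign convention: first class centroid positive on LD1
    for j in range(directions.shape[1]):
        ref = means[0] @ directions[:, j] if j == 0 else \
            directions[np.argmax(np.abs(directions[:, j])), j]
        if ref < 0:
            directions[:, j] *= -1

    tot = eigvals.sum()
    proportions = eigvals / tot if tot > 1e-12 else np.full(d, np.nan)
    priors = np.array(counts, dtype=float) / n
    pooled_cov = W / (n - len(classes))
    return LdaModel(classes=classes, class_means=means, pooled_cov=pooled_cov,
                    directions=directions, eigenvalues=eigvals,
                    proportion_of_trace=proportions, priors=priors,
                    standardize=standardize, feature_mean=mean,
                    feature_scale=scale)


def _discriminant_scores(model: LdaModel, Z: np.ndarray) -> np.ndarray:
    """Gaussian linear discriminant score for each class (shared covariance)."""
    cov_inv = np.linalg.inv(model.pooled_cov)
    scores = np.empty((len(Z), len(model.classes)))
    for j, m in enumerate(model.class_means):
        scores[:, j] = (Z @ cov_inv @ m - 0.5 * m @ cov_inv @ m
                        + np.log(model.priors[j]))
    return scores


def predict(model: LdaModel, rows_or_X, ids=None) -> np.ndarray:
    """Predicted class labels."""
    if (ids is None and isinstance(rows_or_X, (list, tuple)) and rows_or_X
            and isinstance(rows_or_X[0], FeatureRow)):
        X, _, _ = rows_to_matrix(rows_or_X)
    else:
        X = np.asarray(rows_or_X, dtype=float)
    if X.shape[1] != len(model.feature_mean):
        raise ValueError("feature count does not match the fitted model")
    Z = model.transform_features(X)
    idx = np.argmax(_discriminant_scores(model, Z), axis=1)
    return np.array([model.classes[i] for i in idx])


def classify(model: LdaModel, rows_or_X, y=None, ids=None) -> ConfusionMatrix:
    """Resubstitution confusion matrix and the misclassified sample ids."""
    if y is None:
        X, y, ids = rows_to_matrix(rows_or_X)
    else:
        X = np.asarray(rows_or_X, dtype=float)
        y = np.asarray(y)
        if ids is None:
            ids = [str(i) for i in range(len(X))]
    pred = predict(model, X)
    k = len(model.classes)
    index = {c: i for i, c in enumerate(model.classes)}
    counts = np.zeros((k, k), dtype=int)
    missed = []
    for sample_id, true, hat in zip(ids, y, pred):
        counts[index[true], index[hat]] += 1
        if true != hat:
            missed.append(str(sample_id))
    return ConfusionMatrix(model.classes, counts, tuple(missed))


def biplot_data(model: LdaModel, rows_or_X, y=None) -> dict:
    """Scores, loadings, and per-class 95% confidence ellipses for plotting."""
    if model.directions.shape[1] < 2:
        raise ValueError("biplot needs at least two discriminant directions")
    if y is None:
        X, y, ids = rows_to_matrix(rows_or_X)
    else:
        X = np.asarray(rows_or_X, dtype=float)
        y = np.asarray(y)
        ids = [str(i) for i in range(len(X))]
    scores = model.scores(X)[:, :2]
    loadings = model.directions[:, :2]
    ellipses = {}
    from scipy.stats import chi2
    radius2 = chi2.ppf(0.95, df=2)
    for j, c in enumerate(model.classes):
        pts = scores[y == c]
        center = pts.mean(axis=0)
        cov = np.cov(pts, rowvar=False)
        vals, vecs = np.linalg.eigh(cov)
        angle = float(np.degrees(np.arctan2(vecs[1, -1], vecs[0, -1])))
        ellipses[c] = {"center": center,
                       "width": 2 * np.sqrt(max(vals[-1], 0) * radius2),
                       "height": 2 * np.sqrt(max(vals[0], 0) * radius2),
                       "angle": angle}
    return {"ids": ids, "labels": y, "scores": scores,
            "loadings": loadings, "feature_names": model.feature_names,
            "ellipses": ellipses}
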