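"""Partial least squares discriminant analysis (NIPALS, two classes).

PLS2 with a one-hot class response: the class membership matrix Y (n x 2)
and the feature matrix X are column-centered, then NIPALS extracts
components t = Xw maximizing covariance with Y, deflating X (and Y) after
each component.  "Variance explained" is reported on X — the fraction of
the centered X sum of squares removed by each component's rank-one
reconstruction t p' — which is what metabolomics scores plots annotate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_TOL = 1e-10
_MAX_ITER = 500


@dataclass
class PLSDAModel:
    x_mean: np.ndarray
    y_mean: np.ndarray
    x_weights: np.ndarray      # p x a, unit-norm columns
    x_loadings: np.ndarray     # p x a
    y_loadings: np.ndarray     # 2 x a
    x_scores: np.ndarray       # n x a
    variance_explained: np.ndarray  # a, fractions of total centered-X SS
    classes: tuple = ("KO", "WT")
    n_components: int = 2
    feature_names: list = field(default_factory=list)

    def project(self, X_new: np.ndarray) -> np.ndarray:
        """Scores for new observations (training scores are reproduced)."""
        X_new = np.asarray(X_new, dtype=float)
        if X_new.ndim == 1:
            X_new = X_new[None, :]
        if X_new.shape[1] != self.x_weights.shape[0]:
            raise ValueError(
                f"feature count {X_new.shape[1]} != training {self.x_weights.shape[0]}"
            )
        Xd = X_new - self.x_mean
        T = np.empty((Xd.shape[0], self.n_components))
        for a in range(self.n_components):
            t = Xd @ self.x_weights[:, a]
            T[:, a] = t
            Xd = Xd - np.outer(t, self.x_loadings[:, a])
        return T


def _one_hot(labels, classes) -> np.ndarray:
    Y = np.zeros((len(labels), len(classes)))
    for i, lab in enumerate(labels):
        Y[i, classes.index(lab)] = 1.0
    return Y


def fit_plsda(
    X: np.ndarray,
    labels,
    n_components: int = 2,
    feature_names=None,
) -> PLSDAModel:
    """Fit a two-class PLS-DA model by NIPALS.

    X is samples x features (centered internally); labels a length-n
    sequence with exactly two distinct values, each appearing >= 2 times.
    Weight vectors are unit-norm with a deterministic sign: the
    largest-magnitude weight coordinate is made positive.
    """
    X = np.asarray(X, dtype=float)
    labels = list(labels)
    classes = sorted(set(labels), key=str)
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, got {classes}")
    if min(labels.count(c) for c in classes) < 2:
        raise ValueError("need >=2 samples per class")
    rank = np.linalg.matrix_rank(X - X.mean(axis=0))
    if n_components > rank:
        raise ValueError(
            f"n_components={n_components} exceeds rank(X)={rank}; "
            "reduce components or add samples/features"
        )

    x_mean = X.mean(axis=0)
    Y = _one_hot(labels, classes)
    y_mean = Y.mean(axis=0)
    Xd = X - x_mean
    Yd = Y - y_mean
    ss_total = float((Xd**2).sum())

    n, p = Xd.shape
    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    C = np.zeros((Y.shape[1], n_components))
    T = np.zeros((n, n_components))
    var_exp = np.zeros(n_components)

    for a in range(n_components):
        u = Yd[:, [np.argmax(Yd.var(axis=0))]].ravel()
        t_old = np.zeros(n)
        for _ in range(_MAX_ITER):
            w = Xd.T @ u / (u @ u)
            nw = np.linalg.norm(w)
            if nw == 0:
                raise ValueError("degenerate component: zero weight vector")
            w /= nw
            t = Xd @ w
            c = Yd.T @ t / (t @ t)
            u = Yd @ c / (c @ c)
            if np.linalg.norm(t - t_old) < _TOL * max(1.0, np.linalg.norm(t)):
                break
            t_old = t
        # sign convention: largest-|w| coordinate positive
        j = int(np.argmax(np.abs(w)))
        if w[j] < 0:
            w, t, c = -w, -t, -c
        p_load = Xd.T @ t / (t @ t)
        W[:, a], T[:, a], C[:, a], P[:, a] = w, t, c, p_load
        removed = float((t @ t) * (p_load @ p_load))
        var_exp[a] = removed / ss_total if ss_total > 0 else 0.0
        Xd = Xd - np.outer(t, p_load)
        Yd = Yd - np.outer(t, c)

    return PLSDAModel(
        x_mean=x_mean,
        y_mean=y_mean,
        x_weights=W,
        x_loadings=P,
        y_loadings=C,
        x_scores=T,
        variance_explained=var_exp,
        classes=tuple(classes),
        n_components=n_components,
        feature_names=list(feature_names) if feature_names is not None else [],
    )


def variance_explained(model: PLSDAModel, cumulative_first: int = 2) -> dict:
    """Per-component X-variance fractions plus the cumulative top-k total."""
    k = min(cumulative_first, model.n_components)
    return {
        "per_component": [float(v) for v in model.variance_explained],
        f"cumulative_top{k}": float(model.variance_explained[:k].sum()),
    }


def pca_variance_explained(X: np.ndarray, n_components: int = 2) -> np.ndarray:
    """PCA variance fractions of centered X (comparison view for the 2D plot).

    Provided because scores-plot percentages in metabolomics reports are
    sometimes PCA fractions rather than PLS X-variance; both are exposed.
    """
    Xc = np.asarray(X, dtype=float) - np.asarray(X, dtype=float).mean(axis=0)
    sv = np.linalg.svd(Xc, compute_uv=False)
    frac = sv**2 / (sv**2).sum()
    return frac[:n_components]
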