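"""Independent reference implementations used only as test oracles.

These deliberately avoid the package's own code paths: the PLS1 oracle is a
direct transcription of the textbook one-component algorithm, the
hypergeometric oracle enumerates the tail with exact rational arithmetic,
and the VIP oracle recomputes the score from the raw definition.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np


def pls1_da_predictions(X: np.ndarray, y_labels, scaling: str = "uv"):
    """One-component PLS1 discriminant analysis, coded from the definition.

    Returns training predictions of the centered +/-1 encoding plus the
    training R2Y.  Centering/scaling conventions mirror standard autoscaled
    PLS: column mean/SD (ddof=1), class encoding -1/+1 centered by its mean.
    """
    X = np.asarray(X, dtype=float)
    classes = sorted(set(y_labels))
    y = np.where(np.asarray(y_labels) == classes[1], 1.0, -1.0)
    mu = X.mean(axis=0)
    if scaling == "uv":
        sd = X.std(axis=0, ddof=1)
        sd = np.where(sd > 0, sd, 1.0)
    elif scaling == "center":
        sd = np.ones(X.shape[1])
    else:
        raise ValueError(scaling)
    Z = (X - mu) / sd
    ybar = y.mean()
    u = y - ybar
    w = Z.T @ u
    w = w / np.sqrt((w ** 2).sum())
    t = Z @ w
    q = float((u @ t) / (t @ t))
    yhat = t * q + ybar
    r2y = 1.0 - float(((y - yhat) ** 2).sum()) / float((u ** 2).sum())
    return yhat, r2y


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(overlap >= k) by exact enumeration over all possible overlaps."""
    total = comb(N, n)
    acc = Fraction(0)
    for j in range(k, min(K, n) + 1):
        acc += Fraction(comb(K, j) * comb(N - K, n - j), total)
    return float(acc)


def vip_from_definition(w: np.ndarray, ss_explained: np.ndarray) -> np.ndarray:
    """VIP_j = sqrt(p * sum_a ss_a (w_ja/||w_a||)^2 / sum_a ss_a)."""
    w = np.atleast_2d(np.asarray(w, dtype=float))
    if w.shape[0] < w.shape[1] and w.ndim == 2 and len(ss_explained) == w.shape[0]:
        w = w.T  # accept (a, p) too
    p, n_comp = w.shape
    ss = np.asarray(ss_explained, dtype=float)
    norm_w = np.sqrt((w ** 2).sum(axis=0))
    contrib = ((w / norm_w) ** 2) @ ss
    return np.sqrt(p * contrib / ss.sum())


def pca_from_covariance(X: np.ndarray, n_components: int):
    """PCA via eigendecomposition of the sample covariance matrix."""
    X = np.asarray(X, dtype=float)
    Xc = X - X.mean(axis=0)
    C = Xc.T @ Xc / (X.shape[0] - 1)
    vals, vecs = np.linalg.eigh(C)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    scores = Xc @ vecs[:, :n_components]
    evr = vals[:n_components] / vals.sum()
    return scores, vecs[:, :n_components], evr
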