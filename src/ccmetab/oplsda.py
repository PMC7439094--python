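"""Two-class OPLS-DA engine with cross-validated Q2, permutation pQ2 and VIP.

Orthogonal projections to latent structures discriminant analysis (OPLS-DA)
fits a single predictive latent component to a binary class label after
removing ``k_ortho`` components of X that are orthogonal to the label
(orthogonal signal correction).  The implementation follows the standard
NIPALS formulation:

  for each orthogonal component:
      w   = X'y / ||X'y||
      t   = X w
      p   = X't / t't
      w_o = p - (w'p) w,  normalized;  t_o = X w_o;  p_o = X't_o / t_o't_o
      X  <- X - t_o p_o'
  then one predictive component (w, t, p, q) on the deflated X.

With a single y column the predictive weight has the closed form
``w = X'y/||X'y||``, so no inner NIPALS iteration is required.

Model quality is summarized by R2Y (training fit), R2X per component, and Q2
from stratified K-fold cross-validation in which each held-out fold is first
filtered through the *training* fold's orthogonal components.  Significance
of class separation is assessed by refitting (cross-validation included)
under label permutations; p-values use the add-one counting rule
``p = (1 + #{perm >= obs}) / (1 + n_perm)``.

Variable importance to projection (VIP) is reported separately for the
predictive and the orthogonal parts; for the orthogonal part the
per-component explained X-variance weighting ("VIP_o" convention) is used.
``rmsVIP = sqrt((VIP_pred^2 + VIP_ortho^2)/2)`` is the combined importance
measure used for feature selection in diet models.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .containers import AbundanceMatrix, StudyDesign, ValidationError

SCALINGS = ("uv", "pareto", "center")


class ModelError(ValidationError):
    """Raised for invalid model inputs (single class, excessive k_ortho...)."""


# ---------------------------------------------------------------------------
# Model state
# ---------------------------------------------------------------------------

@dataclass
class OplsModel:
    """Fitted OPLS-DA state (scaled-space weights/loadings/scores)."""

    feature_names: List[str]
    classes: Tuple[str, str]  # (negative, positive) -> encoded (-1, +1)
    center: np.ndarray
    scale: np.ndarray
    scaling: str
    y_mean: float
    # orthogonal part, shape (p, k_ortho) / (n, k_ortho)
    W_ortho: np.ndarray
    P_ortho: np.ndarray
    T_ortho: np.ndarray
    # predictive component
    w_pred: np.ndarray
    p_pred: np.ndarray
    t_pred: np.ndarray
    q_pred: float
    r2x_ortho: np.ndarray
    r2x_pred: float
    r2y: float
    q2: float
    n_folds: int
    k_ortho: int
    seed: int

    def transform(self, X: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        """Return (t_pred, T_ortho) scores for new rows of X (raw scale)."""
        Xs = (np.asarray(X, dtype=float) - self.center) / self.scale
        T_o = np.empty((Xs.shape[0], self.W_ortho.shape[1]))
        for a in range(self.W_ortho.shape[1]):
            t_o = Xs @ self.W_ortho[:, a]
            T_o[:, a] = t_o
            Xs = Xs - np.outer(t_o, self.P_ortho[:, a])
        return Xs @ self.w_pred, T_o

    def predict_score(self, X: np.ndarray) -> np.ndarray:
        """Continuous class score (around -1/+1) for new samples."""
        t, _ = self.transform(X)
        return t * self.q_pred + self.y_mean

    def predict_label(self, X: np.ndarray) -> np.ndarray:
        score = self.predict_score(X)
        return np.where(score >= 0.0, self.classes[1], self.classes[0])


@dataclass
class PermutationResult:
    """Observed vs label-permuted model metrics and their p-values."""

    q2_observed: float
    r2y_observed: float
    q2_permuted: np.ndarray
    r2y_permuted: np.ndarray
    p_q2: float
    p_r2y: float
    n_perm: int
    seed: int


# ---------------------------------------------------------------------------
# Internals
# ---------------------------------------------------------------------------

def _encode_y(y: Sequence) -> Tuple[np.ndarray, Tuple[str, str]]:
    y = np.asarray(y)
    classes = sorted(pd.unique(y).tolist())
    if len(classes) != 2:
        raise ModelError(f"need exactly 2 classes, got {classes}")
    enc = np.where(y == classes[1], 1.0, -1.0)
    return enc, (str(classes[0]), str(classes[1]))


def _scale_matrix(X: np.ndarray, scaling: str):
    center = X.mean(axis=0)
    if scaling == "uv":
        sd = X.std(axis=0, ddof=1)
        scale = np.where(sd > 0, sd, 1.0)
    elif scaling == "pareto":
        sd = X.std(axis=0, ddof=1)
        scale = np.where(sd > 0, np.sqrt(sd), 1.0)
    elif scaling == "center":
        scale = np.ones(X.shape[1])
    else:
        raise ModelError(f"unknown scaling {scaling!r}; expected one of {SCALINGS}")
    return (X - center) / scale, center, scale


def _fit_core(Xs: np.ndarray, yc: np.ndarray, k_ortho: int):
    """NIPALS orthogonal-signal-corrected PLS on pre-scaled data.

    ``yc`` must be centered.  Returns weights/loadings/scores of the
    orthogonal components and the single predictive component.
    """
    Xd = Xs.copy()
    p = Xd.shape[1]
    W_o = np.empty((p, k_ortho))
    P_o = np.empty((p, k_ortho))
    T_o = np.empty((Xd.shape[0], k_ortho))
    for a in range(k_ortho):
        w = Xd.T @ yc
        nw = np.linalg.norm(w)
        if nw == 0:
            raise ModelError("X carries no covariance with y; cannot fit")
        w /= nw
        t = Xd @ w
        p_load = Xd.T @ t / (t @ t)
        w_o = p_load - (w @ p_load) * w
        n_wo = np.linalg.norm(w_o)
        if n_wo < 1e-12:
            raise ModelError(
                f"no orthogonal variation left for component {a + 1}; "
                "reduce k_ortho"
            )
        w_o /= n_wo
        t_o = Xd @ w_o
        p_o = Xd.T @ t_o / (t_o @ t_o)
        Xd -= np.outer(t_o, p_o)
        W_o[:, a], P_o[:, a], T_o[:, a] = w_o, p_o, t_o
    w = Xd.T @ yc
    nw = np.linalg.norm(w)
    if nw == 0:
        raise ModelError("X carries no covariance with y; cannot fit")
    w /= nw
    t = Xd @ w
    p_load = Xd.T @ t / (t @ t)
    q = (yc @ t) / (t @ t)
    return W_o, P_o, T_o, w, p_load, t, q


def _cv_press(Xs: np.ndarray, y_enc: np.ndarray, k_ortho: int, n_folds: int,
              seed: int) -> float:
    """PRESS from stratified K-fold CV on the once-scaled matrix."""
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                          random_state=int(seed) % (2 ** 31))
    press = 0.0
    for train, test in skf.split(Xs, y_enc):
        y_tr = y_enc[train]
        ybar = y_tr.mean()
        try:
            W_o, P_o, _, w, _, t_tr, q = _fit_core(Xs[train], y_tr - ybar, k_ortho)
        except ModelError:
            # degenerate training fold: predict the training mean
            press += float(((y_enc[test] - ybar) ** 2).sum())
            continue
        Xt = Xs[test].copy()
        for a in range(k_ortho):
            t_o = Xt @ W_o[:, a]
            Xt -= np.outer(t_o, P_o[:, a])
        yhat = Xt @ w * q + ybar
        press += float(((y_enc[test] - yhat) ** 2).sum())
    return press


# ---------------------------------------------------------------------------
# Public API
# ---------------------------------------------------------------------------

def fit_oplsda(
    X,
    y: Sequence,
    k_ortho=1,
    scaling: str = "uv",
    n_folds: int = 7,
    seed: int = 0,
    feature_names: Optional[Sequence[str]] = None,
) -> OplsModel:
    """Fit a two-class OPLS-DA model with cross-validated Q2.

    Parameters
    ----------
    X
        Samples x features matrix (array or DataFrame), no missing values.
    y
        Binary class labels, one per sample.  The lexicographically larger
        label is encoded +1.
    k_ortho
        Number of orthogonal (class-uncorrelated) components removed before
        the predictive component; must be < rank(X).  The string ``"auto"``
        selects the dimension by forward search, keeping an extra orthogonal
        component only while it improves cross-validated Q2 by more than
        0.01 — mirroring how cross-validated OPLS software decides the
        orthogonal dimension, and avoiding a forced noise component when the
        data carry no class-orthogonal structure.
    scaling
        ``uv`` (autoscaling, default), ``pareto`` or ``center``.
    n_folds, seed
        Stratified CV folds for Q2; the seed also fixes the partition.
    """
    if k_ortho == "auto":
        return _fit_auto(X, y, scaling=scaling, n_folds=n_folds, seed=seed,
                         feature_names=feature_names)
    if isinstance(X, pd.DataFrame):
        feature_names = list(X.columns)
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    if feature_names is None:
        feature_names = [f"x{j}" for j in range(X.shape[1])]
    if np.isnan(X).any():
        raise ModelError("X contains missing values; impute first")
    y_enc, classes = _encode_y(y)
    n_min = min((y_enc == -1).sum(), (y_enc == 1).sum())
    if len(y_enc) < n_folds or n_min < 1:
        raise ModelError("too few samples for the requested fold count")
    if n_folds < 2:
        raise ModelError("n_folds must be >= 2")

    Xs, center, scale = _scale_matrix(X, scaling)
    if k_ortho > 0:
        rank = np.linalg.matrix_rank(Xs)
        if k_ortho >= rank:
            raise ModelError(f"k_ortho={k_ortho} must be < rank(X)={rank}")

    ybar = y_enc.mean()
    yc = y_enc - ybar
    W_o, P_o, T_o, w, p_load, t, q = _fit_core(Xs, yc, k_ortho)

    ssy = float(yc @ yc)
    resid = yc - t * q
    r2y = 1.0 - float(resid @ resid) / ssy

    ssx = float((Xs ** 2).sum())
    r2x_o = np.array([
        (T_o[:, a] @ T_o[:, a]) * (P_o[:, a] @ P_o[:, a]) / ssx
        for a in range(k_ortho)
    ])
    r2x_pred = (t @ t) * (p_load @ p_load) / ssx

    press = _cv_press(Xs, y_enc, k_ortho, n_folds, seed)
    q2 = 1.0 - press / ssy

    return OplsModel(
        feature_names=list(feature_names), classes=classes,
        center=center, scale=scale, scaling=scaling, y_mean=ybar,
        W_ortho=W_o, P_ortho=P_o, T_ortho=T_o,
        w_pred=w, p_pred=p_load, t_pred=t, q_pred=q,
        r2x_ortho=r2x_o, r2x_pred=float(r2x_pred),
        r2y=float(r2y), q2=float(q2),
        n_folds=n_folds, k_ortho=k_ortho, seed=seed,
    )


#: Minimum cross-validated Q2 gain required to keep an extra orthogonal
#: component during automatic dimension selection.
AUTO_Q2_GAIN = 0.01

#: Upper bound on orthogonal components tried by the automatic search.
AUTO_K_MAX = 5


def _fit_auto(X, y, scaling, n_folds, seed, feature_names):
    model = fit_oplsda(X, y, k_ortho=0, scaling=scaling, n_folds=n_folds,
                       seed=seed, feature_names=feature_names)
    for k in range(1, AUTO_K_MAX + 1):
        try:
            cand = fit_oplsda(X, y, k_ortho=k, scaling=scaling,
                              n_folds=n_folds, seed=seed,
                              feature_names=feature_names)
        except ModelError:
            break
        if cand.q2 > model.q2 + AUTO_Q2_GAIN:
            model = cand
        else:
            break
    return model


def compute_vip(model: OplsModel) -> pd.DataFrame:
    """Predictive and orthogonal VIP scores plus their root mean square.

    With one predictive component, ``VIP_pred_j = sqrt(p) * |w_j|`` (weights
    are unit-norm).  The orthogonal VIP weights each component by its
    explained X-variance.  Both satisfy ``mean(VIP^2) = 1``.  When the model
    has no orthogonal components, ``VIP_ortho`` is 0 and ``rmsVIP`` falls
    back to ``VIP_pred``.
    """
    p = len(model.feature_names)
    vip_pred = np.sqrt(p) * np.abs(model.w_pred)
    if model.k_ortho > 0:
        weights = model.r2x_ortho
        num = (model.W_ortho ** 2) @ weights
        vip_ortho = np.sqrt(p * num / weights.sum())
        rms = np.sqrt((vip_pred ** 2 + vip_ortho ** 2) / 2.0)
    else:
        vip_ortho = np.zeros(p)
        rms = vip_pred.copy()
    out = pd.DataFrame(
        {"VIP_pred": vip_pred, "VIP_ortho": vip_ortho, "rmsVIP": rms},
        index=pd.Index(model.feature_names, name="metabolite"),
    )
    out["selected"] = out["rmsVIP"] >= 1.5
    return out


def permutation_test(
    X,
    y: Sequence,
    k_ortho=1,
    scaling: str = "uv",
    n_folds: int = 7,
    n_perm: int = 1000,
    seed: int = 0,
) -> PermutationResult:
    """Label-permutation significance of Q2 and R2Y.

    Each of the ``n_perm`` permutations triggers a full refit including
    cross-validation.  p-values use the add-one rule, so the smallest
    attainable value is ``1/(n_perm + 1)``.  With ``k_ortho="auto"`` the
    orthogonal dimension is selected once on the observed labels and held
    fixed across permutations, so every refit shares the model complexity.
    """
    if n_perm < 1:
        raise ModelError("n_perm must be >= 1")
    if isinstance(X, pd.DataFrame):
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)

    obs = fit_oplsda(X, y, k_ortho=k_ortho, scaling=scaling,
                     n_folds=n_folds, seed=seed)
    k_ortho = obs.k_ortho
    rng = np.random.default_rng(seed)
    q2_perm = np.empty(n_perm)
    r2y_perm = np.empty(n_perm)
    for b in range(n_perm):
        y_b = y[rng.permutation(len(y))]
        sub_seed = int(rng.integers(2 ** 31))
        m_b = fit_oplsda(X, y_b, k_ortho=k_ortho, scaling=scaling,
                         n_folds=n_folds, seed=sub_seed)
        q2_perm[b] = m_b.q2
        r2y_perm[b] = m_b.r2y
    p_q2 = (1 + int((q2_perm >= obs.q2).sum())) / (1 + n_perm)
    p_r2y = (1 + int((r2y_perm >= obs.r2y).sum())) / (1 + n_perm)
    return PermutationResult(
        q2_observed=obs.q2, r2y_observed=obs.r2y,
        q2_permuted=q2_perm, r2y_permuted=r2y_perm,
        p_q2=p_q2, p_r2y=p_r2y, n_perm=n_perm, seed=seed,
    )


def pca(X, n_components: int = 2, scale: bool = False):
    """Principal components by SVD of the centered (optionally UV-scaled) matrix.

    Returns ``(scores, loadings, explained_variance_ratio)``.
    """
    if isinstance(X, pd.DataFrame):
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    if np.isnan(X).any():
        raise ModelError("X contains missing values")
    Xc = X - X.mean(axis=0)
    if scale:
        sd = Xc.std(axis=0, ddof=1)
        Xc = Xc / np.where(sd > 0, sd, 1.0)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    tol = S.max(initial=0.0) * max(Xc.shape) * np.finfo(float).eps
    rank = int((S > tol).sum())
    if n_components > rank:
        raise ModelError(f"n_components={n_components} exceeds rank {rank}")
    scores = U[:, :n_components] * S[:n_components]
    loadings = Vt[:n_components].T
    total_var = float((S ** 2).sum())
    evr = (S[:n_components] ** 2) / total_var
    return scores, loadings, evr


def strain_signature(
    m: AbundanceMatrix,
    d: StudyDesign,
    strain: str,
    diet_stratum: str,
    k_ortho: int = 1,
    scaling: str = "uv",
    n_folds: int = 7,
    seed: int = 0,
    vip_min: float = 1.5,
):
    """One-strain-vs-rest OPLS-DA within one diet stratum.

    Returns ``(model, vip_table, signature_ids)`` where the signature is the
    set of metabolites with predictive VIP >= ``vip_min`` (plain predictive
    VIP, the convention for strain models).
    """
    d.check_matches(m)
    in_stratum = d.table.index[d.table["diet"] == diet_stratum]
    if len(in_stratum) == 0:
        raise ModelError(f"no samples in diet stratum {diet_stratum!r}")
    sub = d.table.loc[in_stratum]
    if strain not in set(sub["strain"]):
        raise ModelError(f"strain {strain!r} absent from stratum {diet_stratum!r}")
    if sub["strain"].nunique() < 2:
        raise ModelError("stratum contains only the target strain")
    y = np.where(sub["strain"] == strain, strain, "other")
    X = m.values.loc[in_stratum]
    n_folds_eff = min(n_folds, int(min((y == strain).sum(), (y == "other").sum())))
    n_folds_eff = max(n_folds_eff, 2)
    model = fit_oplsda(X, y, k_ortho=k_ortho, scaling=scaling,
                       n_folds=n_folds_eff, seed=seed)
    vip = compute_vip(model)
    signature = vip.index[vip["VIP_pred"] >= vip_min].tolist()
    return model, vip, signature
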