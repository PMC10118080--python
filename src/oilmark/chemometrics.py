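"""Pareto scaling, NIPALS PCA and OPLS-DA with cross-validation,
permutation testing and contribution-based variable ranking.

OPLS-DA is implemented as orthogonal signal correction within NIPALS PLS2 on
a class dummy matrix: each orthogonal component is extracted from a PLS
loading after projecting out the span of ``X'Y`` (so orthogonal scores are
exactly uncorrelated with every class column), the filtered X is then fitted
with standard two-block NIPALS PLS2.  Component notation follows the
"A + O + 0" convention: A predictive + O X-orthogonal + 0 Y-orthogonal
components.

Model statistics:

* ``R2X``  — fraction of (scaled, centred) X sum of squares explained,
  cumulatively and per component (predictive and orthogonal).
* ``R2Y``  — 1 - ||Y - Yhat||^2 / ||Y - Ybar||^2 on the fitted data.
* ``S2Y``  — residual (unmodelled) Y variance, RSS / ((N - 1) * n_classes).
* ``SEE``  — sqrt(RSS / (N - A - 1)) with A the total number of fitted
  components (root-mean-square error of estimates with a df correction).
* ``Q2``   — 1 - PRESS / SS from k-fold cross-validation with deterministic
  venetian-blind fold assignment (sample i -> fold i mod k) and scaling
  re-estimated inside each training fold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

log = logging.getLogger(__name__)

_NIPALS_TOL = 1e-12
_NIPALS_MAX_ITER = 1000


# ------------------------------------------------------------------- scaling

@dataclass
class ScaledMatrix:
    """Mean-centred, Pareto-scaled data: x' = (x - mean) / sqrt(sd)."""

    X: np.ndarray
    centers: np.ndarray
    scales: np.ndarray           # sqrt(sd) of the retained variables
    kept: np.ndarray             # indices of retained (non-constant) variables
    n_dropped: int = 0

    def transform(self, X_new: np.ndarray) -> np.ndarray:
        X_new = np.asarray(X_new, dtype=float)
        return (X_new[:, self.kept] - self.centers) / self.scales


def pareto_scale(X: np.ndarray) -> ScaledMatrix:
    """Centre and Pareto-scale columns; constant columns are dropped with a
    warning (their scale factor would be zero)."""
    X = np.asarray(X, dtype=float)
    sd = X.std(axis=0, ddof=1)
    kept = np.flatnonzero(sd > 0)
    n_dropped = X.shape[1] - len(kept)
    if n_dropped:
        log.warning("pareto_scale: dropped %d zero-variance variable(s)", n_dropped)
    centers = X[:, kept].mean(axis=0)
    scales = np.sqrt(sd[kept])
    return ScaledMatrix(
        X=(X[:, kept] - centers) / scales,
        centers=centers,
        scales=scales,
        kept=kept,
        n_dropped=n_dropped,
    )


# ----------------------------------------------------------------------- PCA

@dataclass
class PcaModel:
    scores: np.ndarray            # (n, A)
    loadings: np.ndarray          # (p, A), orthonormal columns
    r2x_per_component: np.ndarray
    r2x_cum: float


def fit_pca(X: np.ndarray, n_components: int) -> PcaModel:
    """NIPALS principal components of an already-scaled matrix."""
    Xr = np.array(X, dtype=float)
    n, p = Xr.shape
    n_components = min(n_components, n - 1 if n > 1 else 1, p)
    ss_tot = (Xr**2).sum()
    if ss_tot == 0:
        raise ValueError("fit_pca: zero-variance matrix")
    T = np.zeros((n, n_components))
    P = np.zeros((p, n_components))
    r2 = np.zeros(n_components)
    for a in range(n_components):
        t = Xr[:, np.argmax((Xr**2).sum(axis=0))].copy()
        if (t**2).sum() == 0:
            T, P, r2 = T[:, :a], P[:, :a], r2[:a]
            break
        for _ in range(_NIPALS_MAX_ITER):
            pvec = Xr.T @ t / (t @ t)
            pvec /= np.linalg.norm(pvec)
            t_new = Xr @ pvec
            if np.linalg.norm(t_new - t) <= _NIPALS_TOL * np.linalg.norm(t_new):
                t = t_new
                break
            t = t_new
        T[:, a], P[:, a] = t, pvec
        r2[a] = (t @ t) / ss_tot
        Xr -= np.outer(t, pvec)
    return PcaModel(scores=T, loadings=P, r2x_per_component=r2, r2x_cum=float(r2.sum()))


# ------------------------------------------------------------------- OPLS-DA

def class_dummy(classes: np.ndarray, levels: list[str] | None = None) -> tuple[np.ndarray, list[str]]:
    """1/0 class-membership matrix, one column per class level."""
    classes = np.asarray(classes)
    if levels is None:
        levels = sorted(set(classes.tolist()))
    Y = np.column_stack([(classes == lv).astype(float) for lv in levels])
    return Y, list(levels)


def _pls2_nipals(X: np.ndarray, Y: np.ndarray, n_components: int):
    """Two-block PLS2 on centred X, Y.  Returns W, T, P, C, ssy.

    Each weight vector is the dominant right singular vector of ``Y' X``
    (the fixed point the NIPALS inner loop iterates towards), computed
    directly so components are exact and deterministic.
    """
    Xr, Yr = X.copy(), Y.copy()
    n, p = Xr.shape
    k = Yr.shape[1]
    W = np.zeros((p, n_components))
    T = np.zeros((n, n_components))
    P = np.zeros((p, n_components))
    C = np.zeros((k, n_components))
    ssy = np.zeros(n_components)
    for a in range(n_components):
        M = Yr.T @ Xr  # (k, p)
        _, s, Vt = np.linalg.svd(M, full_matrices=False)
        if len(s) == 0 or s[0] <= _NIPALS_TOL * max(np.linalg.norm(Xr), 1e-30):
            raise ValueError("requested components exceed the rank of the data")
        w = Vt[0]
        if w[np.argmax(np.abs(w))] < 0:  # deterministic sign convention
            w = -w
        t = Xr @ w
        tt = t @ t
        if tt <= 0:
            raise ValueError("requested components exceed the rank of the data")
        c = Yr.T @ t / tt
        pvec = Xr.T @ t / tt
        W[:, a], T[:, a], P[:, a], C[:, a] = w, t, pvec, c
        ssy[a] = tt * (c @ c)
        Xr -= np.outer(t, pvec)
        Yr -= np.outer(t, c)
    return W, T, P, C, ssy


def _orth_basis(M: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    """Orthonormal basis of the column space of M (SVD with rank cut)."""
    U, s, _ = np.linalg.svd(M, full_matrices=False)
    rank = int((s > tol * (s[0] if len(s) else 1.0)).sum())
    return U[:, :rank]


@dataclass
class OplsDaModel:
    n_predictive: int
    n_orthogonal: int
    levels: list[str]
    weights: np.ndarray           # predictive W (p, A), unit columns
    scores: np.ndarray            # predictive T (n, A)
    loadings: np.ndarray          # predictive P (p, A)
    y_loadings: np.ndarray        # C (k, A)
    orth_weights: np.ndarray      # (p, O)
    orth_scores: np.ndarray       # (n, O)
    orth_loadings: np.ndarray     # (p, O)
    r2x_per_component: np.ndarray  # predictive components
    r2x_orth_per_component: np.ndarray
    r2x_cum: float
    r2y: float
    s2y: float
    see: float
    vip: np.ndarray
    y_mean: np.ndarray
    scaler: ScaledMatrix | None = None
    q2: float | None = None
    permutation: np.ndarray | None = None   # rows of (R2Y_perm, Q2_perm)
    permutation_p: dict | None = None

    def predict_scaled(self, Xs: np.ndarray) -> np.ndarray:
        """Predict centred Y from already-scaled X (orthogonal filtering then
        the predictive regression)."""
        Xf = np.array(Xs, dtype=float)
        for o in range(self.n_orthogonal):
            t_o = Xf @ self.orth_weights[:, o]
            Xf -= np.outer(t_o, self.orth_loadings[:, o])
        PtW = self.loadings.T @ self.weights
        R = self.weights @ np.linalg.inv(PtW)
        return Xf @ R @ self.y_loadings.T

    def predict(self, X_new: np.ndarray) -> tuple[np.ndarray, list[str]]:
        """Predict class labels for raw (unscaled) data via largest Yhat."""
        if self.scaler is None:
            raise ValueError("model was fitted on pre-scaled data; use predict_scaled")
        Yhat = self.predict_scaled(self.scaler.transform(X_new)) + self.y_mean
        idx = np.argmax(Yhat, axis=1)
        return Yhat, [self.levels[i] for i in idx]


def _fit_opls_core(Xs, Y, n_predictive, n_orthogonal):
    """OPLS fit on scaled X and centred-later Y; returns components + stats."""
    n, p = Xs.shape
    Yc = Y - Y.mean(axis=0)
    ss_x = (Xs**2).sum()
    ss_y = (Yc**2).sum()
    Xr = Xs.copy()

    Wo = np.zeros((p, n_orthogonal))
    To = np.zeros((n, n_orthogonal))
    Po = np.zeros((p, n_orthogonal))
    r2x_orth = np.zeros(n_orthogonal)
    for o in range(n_orthogonal):
        basis = _orth_basis(Xr.T @ Yc)
        _, _, P1, _, _ = _pls2_nipals(Xr, Yc, 1)
        pvec = P1[:, 0]
        w_o = pvec - basis @ (basis.T @ pvec)
        norm = np.linalg.norm(w_o)
        if norm < 1e-9 * max(np.linalg.norm(pvec), 1e-30):
            # all remaining X variation is predictive of Y: stop early
            log.warning(
                "orthogonal variation exhausted after %d component(s)", o
            )
            Wo, To, Po, r2x_orth = Wo[:, :o], To[:, :o], Po[:, :o], r2x_orth[:o]
            n_orthogonal = o
            break
        w_o /= norm
        t_o = Xr @ w_o
        p_o = Xr.T @ t_o / (t_o @ t_o)
        Wo[:, o], To[:, o], Po[:, o] = w_o, t_o, p_o
        r2x_orth[o] = (t_o @ t_o) * (p_o @ p_o) / ss_x
        Xr = Xr - np.outer(t_o, p_o)

    W, T, P, C, ssy = _pls2_nipals(Xr, Yc, n_predictive)
    r2x_pred = np.array(
        [(T[:, a] @ T[:, a]) * (P[:, a] @ P[:, a]) / ss_x for a in range(n_predictive)]
    )
    Yhat = T @ C.T
    rss = ((Yc - Yhat) ** 2).sum()
    r2y = 1.0 - rss / ss_y
    A_total = n_predictive + n_orthogonal
    s2y = rss / ((n - 1) * Yc.shape[1])
    df = max(n - A_total - 1, 1)
    see = np.sqrt(rss / df)

    # VIP over predictive components
    denom = ssy.sum()
    vip = np.sqrt(p * (W**2 @ ssy) / denom) if denom > 0 else np.zeros(p)
    return Wo, To, Po, W, T, P, C, r2x_pred, r2x_orth, r2y, s2y, see, vip


def fit_oplsda(
    X: np.ndarray,
    classes,
    n_predictive: int,
    n_orthogonal: int = 0,
    scale: bool = True,
    cv_folds: int | None = 7,
    levels: list[str] | None = None,
) -> OplsDaModel:
    """Fit an OPLS-DA model on a raw samples x variables abundance matrix.

    With ``scale=True`` (default) the matrix is centred and Pareto-scaled
    internally; pass ``scale=False`` for an already-scaled matrix.  ``Q2`` is
    estimated by venetian-blind cross-validation when ``cv_folds`` is given.
    """
    X = np.asarray(X, dtype=float)
    classes = np.asarray(classes)
    uniq = sorted(set(classes.tolist()))
    if len(uniq) < 2:
        raise ValueError("OPLS-DA requires at least two classes")
    if n_predictive < 1:
        raise ValueError("need at least one predictive component")
    if n_predictive > len(uniq):
        raise ValueError("n_predictive may not exceed the number of classes")
    Y, levels = class_dummy(classes, levels or uniq)

    scaler = pareto_scale(X) if scale else None
    Xs = scaler.X if scale else X

    Wo, To, Po, W, T, P, C, r2x_pred, r2x_orth, r2y, s2y, see, vip = _fit_opls_core(
        Xs, Y, n_predictive, n_orthogonal
    )
    model = OplsDaModel(
        n_predictive=n_predictive,
        n_orthogonal=Wo.shape[1],
        levels=levels,
        weights=W,
        scores=T,
        loadings=P,
        y_loadings=C,
        orth_weights=Wo,
        orth_scores=To,
        orth_loadings=Po,
        r2x_per_component=r2x_pred,
        r2x_orth_per_component=r2x_orth,
        r2x_cum=float(r2x_pred.sum() + r2x_orth.sum()),
        r2y=float(r2y),
        s2y=float(s2y),
        see=float(see),
        vip=vip,
        y_mean=Y.mean(axis=0),
        scaler=scaler,
    )
    if cv_folds:
        model.q2 = cross_validate_q2(
            X, classes, n_predictive, n_orthogonal, scale=scale, n_folds=cv_folds,
            levels=levels,
        )
    return model


def cross_validate_q2(
    X: np.ndarray,
    classes,
    n_predictive: int,
    n_orthogonal: int = 0,
    scale: bool = True,
    n_folds: int = 7,
    levels: list[str] | None = None,
) -> float:
    """Q2 = 1 - PRESS/SS with deterministic venetian-blind folds.

    Sample ``i`` goes to fold ``i mod n_folds``; scaling (centres, Pareto
    factors) is re-estimated inside each training fold so no information
    leaks into the held-out predictions.  ``n_folds = N`` gives leave-one-out.
    """
    X = np.asarray(X, dtype=float)
    classes = np.asarray(classes)
    n = len(classes)
    n_folds = min(n_folds, n)
    Y, levels = class_dummy(classes, levels or sorted(set(classes.tolist())))
    ss = ((Y - Y.mean(axis=0)) ** 2).sum()
    folds = np.arange(n) % n_folds
    press = 0.0
    for f in range(n_folds):
        test = folds == f
        train = ~test
        if len(set(classes[train].tolist())) < 2:
            raise ValueError("a training fold lost all but one class")
        Xtr, Xte = X[train], X[test]
        Ytr, Yte = Y[train], Y[test]
        if scale:
            scaler = pareto_scale(Xtr)
            Xtr_s, Xte_s = scaler.X, scaler.transform(Xte)
        else:
            Xtr_s, Xte_s = Xtr, Xte
        Wo, To, Po, W, T, P, C, *_ = _fit_opls_core(Xtr_s, Ytr, n_predictive, n_orthogonal)
        Xf = Xte_s.copy()
        for o in range(Wo.shape[1]):
            t_o = Xf @ Wo[:, o]
            Xf -= np.outer(t_o, Po[:, o])
        R = W @ np.linalg.inv(P.T @ W)
        Yhat = Xf @ R @ C.T + Ytr.mean(axis=0)
        press += ((Yte - Yhat) ** 2).sum()
    return float(1.0 - press / ss)


def permutation_test(
    X: np.ndarray,
    classes,
    n_predictive: int,
    n_orthogonal: int = 0,
    n_perm: int = 200,
    seed: int = 0,
    scale: bool = True,
    cv_folds: int = 7,
) -> dict:
    """Permute class labels and refit to calibrate R2Y and Q2.

    Returns the observed statistics, the permuted (R2Y, Q2) pairs, and
    p = (1 + #{Q2_perm >= Q2_obs}) / (n_perm + 1) (same for R2Y); p is
    bounded below by 1/(n_perm + 1).
    """
    rng = np.random.default_rng(seed)
    classes = np.asarray(classes)
    obs = fit_oplsda(X, classes, n_predictive, n_orthogonal, scale=scale, cv_folds=cv_folds)
    perm = np.empty((n_perm, 2))
    for i in range(n_perm):
        permuted = rng.permutation(classes)
        try:
            m = fit_oplsda(
                X, permuted, n_predictive, n_orthogonal, scale=scale, cv_folds=cv_folds
            )
            perm[i] = (m.r2y, m.q2)
        except ValueError:
            perm[i] = (np.nan, np.nan)
    ok = ~np.isnan(perm[:, 1])
    n_ok = int(ok.sum())
    p_q2 = (1 + int((perm[ok, 1] >= obs.q2).sum())) / (n_ok + 1)
    p_r2y = (1 + int((perm[ok, 0] >= obs.r2y).sum())) / (n_ok + 1)
    return {
        "r2y_obs": obs.r2y,
        "q2_obs": obs.q2,
        "permuted": perm[ok],
        "p_q2": p_q2,
        "p_r2y": p_r2y,
        "n_perm": n_ok,
    }


def variable_contributions(model: OplsDaModel, class_label: str, classes) -> np.ndarray:
    """Per-variable contribution of ``class_label`` to the predictive scores.

    The class displacement in predictive score space (class mean score minus
    grand mean score, per component) is projected back through the loadings:
    ``contrib_j = sum_a d_a p_aj``.  Variables elevated specifically in the
    class get large positive contributions; flat variables get ~0.  Returned
    on the retained-variable axis of the model's scaler (if any).
    """
    classes = np.asarray(classes)
    if class_label not in set(classes.tolist()):
        raise ValueError(f"class {class_label!r} not present")
    mask = classes == class_label
    d = model.scores[mask].mean(axis=0) - model.scores.mean(axis=0)
    return model.loadings @ d
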