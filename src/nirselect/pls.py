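"""PLS on numeric class codes, cross-validation, Kaiser PCA and the Galtier rule.

Origin classes are coded as a single numeric response y in {1..5} and
regressed on the spectra by PLS1 (NIPALS). This is the regression engine the
Monte-Carlo wavelength selectors drive: they need the raw regression vector
``b`` of thousands of refits, so the implementation is a lean, vectorised
NIPALS loop (validated in the test suite against both a least-squares oracle
at full rank and an independent PLS implementation).

Membership decisions on validation samples follow the Galtier criterion: a
prediction is accepted for a class when its predicted value Y_pre sits near
that class code and its deviation Y_dev is small; large deviations flag a
sample as suspicious, predictions far from every code with small deviation
as uncredited.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np


class RankError(ValueError):
    """Requested latent dimension exceeds the achievable rank."""


@dataclass
class PLSModel:
    """PLS1 latent-variable regression of class codes on spectra."""

    n_components: int
    x_mean: np.ndarray
    y_mean: float
    x_weights: np.ndarray  # W, p x A
    x_loadings: np.ndarray  # P, p x A
    y_loadings: np.ndarray  # q, A
    x_scores: np.ndarray  # T, n x A
    coef: np.ndarray  # b, p: maps centered X to centered y
    class_codes: tuple[int, ...] = ()

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return (X - self.x_mean) @ self.coef + self.y_mean


def pls_fit(X: np.ndarray, y: np.ndarray, n_components: int) -> PLSModel:
    """Fit PLS1 by NIPALS; ``y`` holds numeric class codes (or any response)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    A = int(n_components)
    if not (1 <= A <= min(n - 1, p)):
        raise RankError(f"n_components must be in [1, min(n-1, p)] = [1, {min(n - 1, p)}]")
    codes = tuple(sorted({int(v) for v in y})) if np.allclose(y, np.round(y)) else ()
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xc = X - x_mean
    yc = y - y_mean
    x_scale0 = float(np.linalg.norm(Xc)) or 1.0
    W = np.zeros((p, A))
    P = np.zeros((p, A))
    T = np.zeros((n, A))
    q = np.zeros(A)
    for a in range(A):
        w = Xc.T @ yc
        nw = np.linalg.norm(w)
        if nw <= 1e-12 * x_scale0:
            raise RankError(f"rank deficiency: achievable rank is {a}, requested {A}")
        w /= nw
        t = Xc @ w
        tt = float(t @ t)
        if tt <= (1e-12 * x_scale0) ** 2:
            raise RankError(f"rank deficiency: achievable rank is {a}, requested {A}")
        pvec = Xc.T @ t / tt
        qa = float(yc @ t) / tt
        Xc = Xc - np.outer(t, pvec)
        yc = yc - qa * t
        W[:, a], P[:, a], T[:, a], q[a] = w, pvec, t, qa
    coef = W @ np.linalg.solve(P.T @ W, q)
    return PLSModel(
        n_components=A,
        x_mean=x_mean,
        y_mean=y_mean,
        x_weights=W,
        x_loadings=P,
        y_loadings=q,
        x_scores=T,
        coef=coef,
        class_codes=codes,
    )


@dataclass
class CVMetrics:
    """Cross-validation summary for one PLS model."""

    rmsecv: float
    r2: float
    rmsep: float | None
    folds: int
    seed: int


def stratified_folds(y: np.ndarray, folds: int, seed: int, max_refold: int = 20) -> np.ndarray:
    """Fold assignment spreading every class across folds.

    Each class's samples are shuffled and dealt round-robin, the starting
    fold rotating per class so small classes do not pile onto fold 0. If any
    training complement (all folds but one) would miss a class entirely, a
    warning is issued and the assignment is redrawn with a new seed.
    """
    y = np.asarray(y)
    n = y.size
    if folds > n:
        raise ValueError(f"folds={folds} exceeds n={n}")
    classes = np.unique(y)
    if classes.size > max(folds, n // 2):
        # continuous response: plain shuffled round-robin folds
        rng = np.random.default_rng([seed, folds])
        assign = np.arange(n) % folds
        rng.shuffle(assign)
        return assign
    for attempt in range(max_refold):
        rng = np.random.default_rng([seed + attempt, folds])
        assign = np.empty(n, dtype=int)
        offset = 0
        for c in np.unique(y):
            idx = np.flatnonzero(y == c)
            rng.shuffle(idx)
            assign[idx] = (np.arange(idx.size) + offset) % folds
            offset += idx.size
        ok = all(
            np.array_equal(np.unique(y[assign != f]), np.unique(y)) for f in range(folds)
        )
        if ok:
            return assign
        warnings.warn(f"fold {attempt} left a class untrained; refolding", stacklevel=2)
    raise ValueError("could not build class-covering folds")


def cv_predictions(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int,
    folds: int = 10,
    seed: int = 0,
    X_eval: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Held-out predictions per sample, plus per-fold predictions for X_eval.

    Returns ``(y_hat_cv, eval_preds)`` where ``eval_preds`` is
    ``n_eval x folds`` (each column from one fold's sub-model) or None.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    assign = stratified_folds(y, folds, seed)
    y_hat = np.empty_like(y)
    eval_preds = None if X_eval is None else np.empty((np.atleast_2d(X_eval).shape[0], folds))
    for f in range(folds):
        mask = assign == f
        A_eff = min(n_components, np.sum(~mask) - 1, X.shape[1])
        model = pls_fit(X[~mask], y[~mask], A_eff)
        if np.any(mask):
            y_hat[mask] = model.predict(X[mask])
        if eval_preds is not None:
            eval_preds[:, f] = model.predict(X_eval)
    return y_hat, eval_preds


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int,
    folds: int = 10,
    seed: int = 0,
    X_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
) -> CVMetrics:
    """Stratified k-fold RMSECV; R^2 of the full-data fit; optional RMSEP."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if np.allclose(y, y[0]):
        return CVMetrics(rmsecv=0.0, r2=1.0, rmsep=None, folds=folds, seed=seed)
    y_hat, _ = cv_predictions(X, y, n_components, folds=folds, seed=seed)
    rmsecv = float(np.sqrt(np.mean((y - y_hat) ** 2)))
    A_eff = min(n_components, X.shape[0] - 1, X.shape[1])
    model = pls_fit(X, y, A_eff)
    fit = model.predict(X)
    ss_res = float(np.sum((y - fit) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    rmsep = None
    if X_val is not None and y_val is not None:
        y_val = np.asarray(y_val, dtype=float).ravel()
        rmsep = float(np.sqrt(np.mean((y_val - model.predict(X_val)) ** 2)))
    return CVMetrics(rmsecv=rmsecv, r2=r2, rmsep=rmsep, folds=folds, seed=seed)


def pca_kaiser(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """PCA with the Kaiser rule.

    Expects standardized columns (the eigenvalue >= 1 cut assumes
    correlation-scale eigenvalues). Returns (scores, eigenvalues, k_retained).
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < 3:
        raise ValueError("PCA needs n >= 3")
    Xc = X - X.mean(axis=0)
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    eig = s**2 / (n - 1)
    k = int(np.sum(eig >= 1.0))
    return U * s, eig, k


# -- Galtier membership decision --------------------------------------------

FLAG_OK = "ok"
FLAG_SUSPICIOUS = "suspicious"
FLAG_UNCREDITED = "uncredited"


@dataclass
class GaltierVerdict:
    """Membership decision for one prediction-set sample."""

    sample_id: str
    candidate_class: int
    y_pre: float
    y_dev: float
    flag: str


def galtier_verdict(
    candidate_class: int,
    y_pre: float,
    y_dev: float,
    codes: tuple[int, ...] = (1, 2, 3, 4, 5),
    dev_limit: float = 0.45,
    pre_limit: float = 0.55,
    sample_id: str = "",
) -> GaltierVerdict:
    """Classify one (Y_pre, Y_dev) pair as ok / suspicious / uncredited.

    The 0.45/0.55 limits bracket the 0.5 decision threshold with a 10% error
    margin. Operational rule: a prediction more than ``pre_limit`` below the
    smallest class code with deviation below ``dev_limit`` is *uncredited*
    (it falls outside the class-code range on the side where no class can
    claim it); otherwise a deviation at or above ``dev_limit`` makes the
    sample *suspicious*; anything else is *ok* and the candidate class is
    retained.
    """
    if y_dev < 0:
        raise ValueError("y_dev must be >= 0")
    codes_arr = np.asarray(codes, dtype=float)
    if y_pre < float(codes_arr.min()) - pre_limit and y_dev < dev_limit:
        flag = FLAG_UNCREDITED
    elif y_dev >= dev_limit:
        flag = FLAG_SUSPICIOUS
    else:
        flag = FLAG_OK
    return GaltierVerdict(
        sample_id=sample_id,
        candidate_class=int(candidate_class),
        y_pre=float(y_pre),
        y_dev=float(y_dev),
        flag=flag,
    )


def set_accuracy(verdicts: list[GaltierVerdict], actual: np.ndarray) -> float:
    """Percentage of samples that are ok AND assigned their actual class."""
    actual = np.asarray(actual, dtype=int)
    if len(verdicts) == 0 or actual.size != len(verdicts):
        raise ValueError("need one actual class per verdict, non-empty")
    hits = sum(
        1
        for v, a in zip(verdicts, actual)
        if v.flag == FLAG_OK and v.candidate_class == int(a)
    )
    return round(100.0 * hits / len(verdicts), 2)
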