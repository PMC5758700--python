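"""Stepwise Wilks-lambda screening and Fisher linear discriminant functions.

The characteristic variables that survive consensus voting are screened once
more by classic stepwise discriminant analysis: at every step the candidate
with the largest partial F enters if it clears ``f_enter``, then any retained
variable whose partial F has dropped below ``f_remove`` leaves. Wilks' lambda
det(W)/det(T) is the multivariate separation criterion and never increases
at an entry step.

The Fisher model itself is the set of per-class linear classification
functions  score_c(x) = coef_c . x + const_c  with
coef_c = W^-1 mu_c and const_c = -1/2 mu_c' W^-1 mu_c + ln(prior_c),
W being the pooled within-class covariance. Under equal priors the argmax
class equals the nearest centroid in Mahalanobis distance.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


class FitError(ValueError):
    """Discriminant model cannot be fit (class too small, bad input)."""


@dataclass
class StepwiseTrace:
    """Ordered entry/removal log: (step, action, variable, Wilks lambda, F)."""

    rows: list[dict] = field(default_factory=list)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.rows, columns=["step", "action", "variable", "wilks_lambda", "partial_f"]
        )


def _scatter(X: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Within-class and total scatter matrices."""
    Xc = X - X.mean(axis=0)
    T = Xc.T @ Xc
    W = np.zeros_like(T)
    for c in np.unique(labels):
        G = X[labels == c]
        Gc = G - G.mean(axis=0)
        W += Gc.T @ Gc
    return W, T


def wilks_lambda(X: np.ndarray, labels: np.ndarray) -> float:
    """Wilks' lambda det(W)/det(T) for the given variable block."""
    if X.ndim == 1:
        X = X[:, None]
    W, T = _scatter(X, labels)
    sW, ldW = np.linalg.slogdet(W)
    sT, ldT = np.linalg.slogdet(T)
    if sW <= 0 or sT <= 0:
        return 0.0  # singular scatter: perfect (degenerate) separation
    return float(np.exp(ldW - ldT))


def stepwise_select(
    X: np.ndarray,
    labels: np.ndarray,
    f_enter: float = 3.84,
    f_remove: float = 2.71,
    max_vars: int | None = None,
    wavenumbers: np.ndarray | None = None,
) -> tuple[np.ndarray, StepwiseTrace]:
    """Wilks-lambda stepwise variable screening.

    Returns the retained column indices (or wavenumbers, when given) in
    entry order, plus the trace. Partial F for entering variable j with q
    variables already in:  F = ((n - g - q)/(g - 1)) * (1 - L)/L  with
    L = Lambda(S+j)/Lambda(S).
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    n, p = X.shape
    g = np.unique(labels).size
    if g < 2:
        raise FitError("need >= 2 classes")
    if max_vars is None:
        max_vars = min(p, n - g - 1)
    retained: list[int] = []
    lam_current = 1.0
    trace = StepwiseTrace()
    step = 0
    while True:
        step += 1
        q = len(retained)
        if q >= max_vars or n - g - q <= 0:
            break
        # --- entry ---
        best_j, best_f, best_lam = -1, -np.inf, lam_current
        for j in range(p):
            if j in retained:
                continue
            lam_new = wilks_lambda(X[:, retained + [j]], labels)
            L = lam_new / lam_current if lam_current > 0 else 0.0
            L = min(max(L, 1e-12), 1.0)
            F = ((n - g - q) / (g - 1)) * (1.0 - L) / L
            if F > best_f:
                best_j, best_f, best_lam = j, F, lam_new
        if best_j < 0 or best_f < f_enter:
            if not retained:
                warnings.warn("no variable reaches f_enter; empty retention", stacklevel=2)
            break
        retained.append(best_j)
        lam_current = best_lam
        trace.rows.append(
            {
                "step": step,
                "action": "enter",
                "variable": best_j,
                "wilks_lambda": lam_current,
                "partial_f": best_f,
            }
        )
        # --- removal ---
        changed = True
        while changed and len(retained) > 1:
            changed = False
            q = len(retained)
            worst_j, worst_f, worst_lam = -1, np.inf, lam_current
            for j in retained:
                rest = [r for r in retained if r != j]
                lam_without = wilks_lambda(X[:, rest], labels)
                L = lam_current / lam_without if lam_without > 0 else 1.0
                L = min(max(L, 1e-12), 1.0)
                F = ((n - g - (q - 1)) / (g - 1)) * (1.0 - L) / L
                if F < worst_f:
                    worst_j, worst_f, worst_lam = j, F, lam_without
            if worst_j >= 0 and worst_f < f_remove:
                retained.remove(worst_j)
                lam_current = worst_lam
                trace.rows.append(
                    {
                        "step": step,
                        "action": "remove",
                        "variable": worst_j,
                        "wilks_lambda": lam_current,
                        "partial_f": worst_f,
                    }
                )
                changed = True
    idx = np.asarray(retained, dtype=int)
    if wavenumbers is not None:
        wn = np.asarray(wavenumbers, dtype=float)
        for row in trace.rows:
            row["variable"] = float(wn[int(row["variable"])])
        return wn[idx], trace
    return idx, trace


@dataclass
class FisherModel:
    """Per-class linear classification functions and centroids."""

    classes: tuple[int, ...]
    coefficients: np.ndarray  # g x p, row per class
    constants: np.ndarray  # g
    centroids: np.ndarray  # g x p
    pooled_cov: np.ndarray  # p x p
    wavenumbers: tuple[float, ...] = ()

    def scores(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if x.shape[1] != self.coefficients.shape[1]:
            raise FitError(
                f"expected {self.coefficients.shape[1]} variables, got {x.shape[1]}"
            )
        return x @ self.coefficients.T + self.constants

    def to_json(self, path: str | Path) -> None:
        payload = {
            "classes": list(self.classes),
            "wavenumbers": list(self.wavenumbers),
            "constants": self.constants.tolist(),
            "coefficients": self.coefficients.tolist(),
            "centroids": self.centroids.tolist(),
            "pooled_cov": self.pooled_cov.tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "FisherModel":
        d = json.loads(Path(path).read_text())
        return cls(
            classes=tuple(int(c) for c in d["classes"]),
            coefficients=np.asarray(d["coefficients"], dtype=float),
            constants=np.asarray(d["constants"], dtype=float),
            centroids=np.asarray(d["centroids"], dtype=float),
            pooled_cov=np.asarray(d["pooled_cov"], dtype=float),
            wavenumbers=tuple(float(w) for w in d["wavenumbers"]),
        )


def fisher_fit(
    X: np.ndarray,
    labels: np.ndarray,
    priors: np.ndarray | None = None,
    wavenumbers: np.ndarray | None = None,
    ridge: float | None = None,
) -> FisherModel:
    """Fit per-class Fisher linear classification functions (equal priors)."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    labels = np.asarray(labels).astype(int)
    n, p = X.shape
    classes = tuple(int(c) for c in np.unique(labels))
    g = len(classes)
    for c in classes:
        if np.sum(labels == c) < 2:
            raise FitError(f"class {c} has < 2 samples")
    if priors is None:
        priors = np.full(g, 1.0 / g)
    priors = np.asarray(priors, dtype=float)
    priors = priors / priors.sum()
    centroids = np.vstack([X[labels == c].mean(axis=0) for c in classes])
    W = np.zeros((p, p))
    for c in classes:
        G = X[labels == c]
        Gc = G - G.mean(axis=0)
        W += Gc.T @ Gc
    W /= n - g
    if ridge is None:
        ridge = 1e-8 * np.trace(W) / p or 1e-12
    try:
        Winv = np.linalg.inv(W)
    except np.linalg.LinAlgError:
        warnings.warn(f"singular pooled covariance; ridge {ridge:.3g} added", stacklevel=2)
        Winv = np.linalg.inv(W + ridge * np.eye(p))
    coef = centroids @ Winv
    const = -0.5 * np.sum(coef * centroids, axis=1) + np.log(priors)
    return FisherModel(
        classes=classes,
        coefficients=coef,
        constants=const,
        centroids=centroids,
        pooled_cov=W,
        wavenumbers=tuple(float(w) for w in (wavenumbers if wavenumbers is not None else [])),
    )


def fisher_classify(model: FisherModel, x: np.ndarray) -> np.ndarray:
    """Assign each row of x to the class with the highest linear score.

    Ties break toward the lowest class code.
    """
    sc = model.scores(x)
    # argmax with lowest-code tie-break: scan classes in code order
    order = np.argsort(model.classes)
    n = sc.shape[0]
    best = np.full(n, order[0], dtype=int)
    for i in order[1:]:
        current = sc[np.arange(n), best]
        best[sc[:, i] > current] = int(i)
    return np.asarray([model.classes[int(i)] for i in best], dtype=int)


def resubstitution(X: np.ndarray, labels: np.ndarray, **kw) -> tuple[float, pd.DataFrame]:
    """Accuracy and confusion of the model refit and applied to its own data."""
    model = fisher_fit(X, labels, **kw)
    pred = fisher_classify(model, X)
    return _accuracy_confusion(labels, pred, model.classes)


def loo_cross_validate(X: np.ndarray, labels: np.ndarray, **kw) -> tuple[float, pd.DataFrame]:
    """Leave-one-out validation: each case classified by functions fit on the rest."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    labels = np.asarray(labels).astype(int)
    n = X.shape[0]
    classes = np.unique(labels)
    if n < 2 * classes.size:
        raise FitError("need n >= 2 per class for leave-one-out")
    pred = np.empty(n, dtype=int)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        model = fisher_fit(X[mask], labels[mask], **kw)
        pred[i] = fisher_classify(model, X[i: i + 1])[0]
    return _accuracy_confusion(labels, pred, tuple(int(c) for c in classes))


def _accuracy_confusion(
    actual: np.ndarray, pred: np.ndarray, classes: tuple[int, ...]
) -> tuple[float, pd.DataFrame]:
    acc = round(100.0 * float(np.mean(actual == pred)), 2)
    conf = pd.DataFrame(
        0, index=list(classes), columns=list(classes), dtype=int
    )
    for a, p_ in zip(actual, pred):
        conf.loc[int(a), int(p_)] += 1
    conf.index.name = "actual"
    conf.columns.name = "predicted"
    return acc, conf
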