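"""Replicate stability, iterative outlier screening and Kennard-Stone splitting.

Replicate stability and outlier screening both live in PCA space: Hotelling's
T^2 measures a sample's leverage inside the model plane, the Q statistic its
squared residual off the plane. Outliers are removed one at a time -- worst
T^2 exceeder first, then worst Q exceeder -- with the PCA refit after every
removal, which is the standard conservative reconstruction of iterative
singular-sample diagnosis.

The training/validation partition uses the classic Kennard-Stone maximin
procedure on Euclidean distance, followed by a deterministic repair pass so
both sets contain all five region classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist

from .core_io import SpectraSet


class DegenerateError(ValueError):
    """Score matrix unusable (zero-variance component)."""


class QCError(RuntimeError):
    """Outlier screening removed an implausible fraction of samples."""


class SplitError(ValueError):
    """Kennard-Stone split cannot satisfy class coverage."""


def hotelling_t2(scores: np.ndarray) -> np.ndarray:
    """Hotelling T^2 per sample: sum_j t_ij^2 / var(t_.j)."""
    T = np.asarray(scores, dtype=float)
    if T.ndim == 1:
        T = T[:, None]
    n, k = T.shape
    if n <= k:
        raise DegenerateError(f"need n > k (got n={n}, k={k})")
    var = T.var(axis=0, ddof=1)
    if np.any(var <= 0):
        raise DegenerateError("zero-variance score column")
    return np.sum(T**2 / var, axis=1)


def t2_limit(n: int, k: int, alpha: float) -> float:
    """Hotelling T^2 control limit: k(n-1)/(n-k) * F^-1(alpha; k, n-k)."""
    if not (n > k >= 1):
        raise ValueError(f"need n > k >= 1 (got n={n}, k={k})")
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    return k * (n - 1) / (n - k) * float(stats.f.ppf(alpha, k, n - k))


def q_limit(residual_eigvals: np.ndarray, alpha: float) -> float:
    """Jackson-Mudholkar limit for the Q (squared residual) statistic."""
    lam = np.asarray(residual_eigvals, dtype=float)
    lam = lam[lam > 1e-12]
    if lam.size == 0:
        return 0.0
    th1, th2, th3 = (np.sum(lam**i) for i in (1, 2, 3))
    h0 = 1.0 - 2.0 * th1 * th3 / (3.0 * th2**2)
    if h0 <= 0:
        # heavy-tailed residual spectrum: fall back to the matched
        # chi-square approximation g*chi2(h)
        g, h = th2 / th1, th1**2 / th2
        return float(g * stats.chi2.ppf(alpha, h))
    c = float(stats.norm.ppf(alpha))
    term = (
        c * np.sqrt(2.0 * th2 * h0**2) / th1
        + 1.0
        + th2 * h0 * (h0 - 1.0) / th1**2
    )
    return float(th1 * term ** (1.0 / h0))


def _pca(X: np.ndarray, k: int):
    """Mean-centered PCA; returns (scores, residual Q, residual eigenvalues)."""
    Xc = X - X.mean(axis=0, keepdims=True)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    n = X.shape[0]
    eig = s**2 / (n - 1)
    scores = U[:, :k] * s[:k]
    recon = scores @ Vt[:k]
    Q = np.sum((Xc - recon) ** 2, axis=1)
    return scores, Q, eig[k:]


@dataclass
class OutlierReport:
    """Removal log: who was removed, and the full per-iteration diagnostics."""

    removed_ids: list[str] = field(default_factory=list)
    table: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["iteration", "sample_id", "t2", "q", "t2_limit", "q_limit", "removed"]
        )
    )


def iterative_outlier_removal(
    s: SpectraSet,
    k: int = 5,
    alpha: float = 0.99,
    max_iter: int | None = None,
    max_removed_frac: float = 0.20,
    family_wise: bool = True,
) -> tuple[SpectraSet, OutlierReport]:
    """Iterative PCA T^2/Q screening.

    Loop: fit a k-component PCA on the surviving samples, compute each
    sample's T^2 and Q with their ``alpha`` limits, and remove the single
    worst exceeder (largest T^2 first; if none, largest Q; ties by largest
    T^2 then lowest sample_id). Stops when no sample exceeds either limit or
    ``max_iter`` iterations have run. Sample order never matters.

    Because each iteration screens the *maximum* statistic over the n
    surviving samples, the default applies a Bonferroni family-wise
    correction (per-sample level 1 - (1-alpha)/n) so that a clean dataset
    keeps an overall ~alpha chance of zero removals; ``family_wise=False``
    uses the raw per-sample limits.
    """
    n0 = s.n_samples
    if n0 <= k + 2:
        raise DegenerateError(f"need n > k + 2 (got n={n0}, k={k})")
    if max_iter is None:
        max_iter = n0
    current = s.subset_rows(np.arange(n0))
    report = OutlierReport()
    rows = []
    for it in range(1, max_iter + 1):
        if current.n_samples <= k + 2:
            break
        scores, Q, resid_eig = _pca(current.absorbance, k)
        t2 = hotelling_t2(scores)
        a_eff = 1.0 - (1.0 - alpha) / current.n_samples if family_wise else alpha
        lim_t2 = t2_limit(current.n_samples, k, a_eff)
        lim_q = q_limit(resid_eig, a_eff)
        ids = current.sample_ids
        exceed_t2 = np.flatnonzero(t2 > lim_t2)
        exceed_q = np.flatnonzero(Q > lim_q) if lim_q > 0 else np.array([], dtype=int)
        if exceed_t2.size:
            # largest T^2, ties by lowest sample_id
            order = sorted(exceed_t2, key=lambda i: (-t2[i], ids[i]))
            worst, reason = order[0], "t2"
        elif exceed_q.size:
            order = sorted(exceed_q, key=lambda i: (-Q[i], -t2[i], ids[i]))
            worst, reason = order[0], "q"
        else:
            worst, reason = None, ""
        for i in range(current.n_samples):
            rows.append(
                {
                    "iteration": it,
                    "sample_id": ids[i],
                    "t2": float(t2[i]),
                    "q": float(Q[i]),
                    "t2_limit": float(lim_t2),
                    "q_limit": float(lim_q),
                    "removed": reason if worst is not None and i == worst else "",
                }
            )
        if worst is None:
            break
        report.removed_ids.append(ids[worst])
        keep = np.ones(current.n_samples, dtype=bool)
        keep[worst] = False
        current = current.subset_rows(keep)
        if n0 - current.n_samples > max_removed_frac * n0:
            report.table = pd.DataFrame(rows)
            raise QCError(
                f"removed {n0 - current.n_samples}/{n0} samples (> "
                f"{max_removed_frac:.0%}); removed: {report.removed_ids}"
            )
    report.table = pd.DataFrame(
        rows,
        columns=["iteration", "sample_id", "t2", "q", "t2_limit", "q_limit", "removed"],
    )
    return current, report


def kennard_stone_indices(X: np.ndarray, n_train: int) -> np.ndarray:
    """Classic Kennard-Stone maximin selection of ``n_train`` row indices.

    Seeds with the most distant pair, then repeatedly adds the candidate
    whose minimum distance to the selected set is largest. Deterministic:
    ties break toward the lowest index.
    """
    n = X.shape[0]
    if not (2 <= n_train <= n):
        raise SplitError(f"n_train must be in [2, {n}]")
    D = cdist(X, X)
    # most distant pair, lexicographically smallest on ties
    flat = np.argmax(D)
    best = np.unravel_index(flat, D.shape)
    maxd = D[best]
    pairs = np.argwhere(np.isclose(D, maxd))
    pairs = pairs[pairs[:, 0] < pairs[:, 1]]
    i0, j0 = min(map(tuple, pairs))
    selected = [i0, j0]
    remaining = [i for i in range(n) if i not in (i0, j0)]
    mind = np.minimum(D[i0], D[j0])
    while len(selected) < n_train:
        cand_d = mind[remaining]
        pick = remaining[int(np.argmax(cand_d))]
        selected.append(pick)
        remaining.remove(pick)
        mind = np.minimum(mind, D[pick])
    return np.sort(np.asarray(selected, dtype=int))


def kennard_stone_split(s: SpectraSet, validation_fraction: float = 1 / 3) -> SpectraSet:
    """Kennard-Stone 2:1 partition with class-coverage repair.

    The training set is Kennard-Stone-selected (maximin on Euclidean
    distance); validation size = round(n * validation_fraction). A post-hoc
    repair pass then swaps nearest cross-set pairs until both sets contain
    all five region classes.
    """
    n = s.n_samples
    if n < 6:
        raise SplitError("need n >= 6 to split")
    classes = s.region_classes
    for c in np.unique(classes):
        if np.sum(classes == c) < 2:
            raise SplitError(f"region class {c} has < 2 samples; cannot cover both sets")
    n_val = int(round(n * validation_fraction))
    n_train = n - n_val
    train_idx = set(kennard_stone_indices(s.absorbance, n_train).tolist())
    D = cdist(s.absorbance, s.absorbance)

    def missing(side: set[int]) -> list[int]:
        present = {int(classes[i]) for i in side}
        return [c for c in sorted(set(classes.tolist())) if c not in present]

    all_idx = set(range(n))
    for _ in range(n):
        val_idx = all_idx - train_idx
        fixed = True
        for side, other in ((train_idx, val_idx), (val_idx, train_idx)):
            for c in missing(side):
                donors = [i for i in other if classes[i] == c]
                if not donors:
                    raise SplitError(f"class {c} absent from both sets")
                # donor of class c closest to the deficient side
                donor = min(
                    donors,
                    key=lambda i: (min(D[i, j] for j in side) if side else 0.0, i),
                )
                # send back the donor's nearest counterpart whose class stays covered
                safe = [
                    j
                    for j in side
                    if sum(1 for t in side if classes[t] == classes[j]) >= 2
                ]
                if not safe:
                    raise SplitError(f"cannot repair coverage for class {c}")
                returner = min(safe, key=lambda j: (D[donor, j], j))
                side.add(donor)
                side.remove(returner)
                other.remove(donor)
                other.add(returner)
                fixed = False
        if fixed:
            break
    val_idx = all_idx - train_idx
    if missing(train_idx) or missing(val_idx):
        raise SplitError("class-coverage repair failed")
    assignment = {}
    ids = s.sample_ids
    for i in range(n):
        assignment[ids[i]] = "training" if i in train_idx else "validation"
    return s.with_membership(assignment)
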