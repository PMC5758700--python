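"""Four wavelength-selection algorithms and their consensus vote.

All four methods score every wavenumber of a training :class:`SpectraSet`
and return a :class:`SelectionResult` whose ``selected`` wavenumbers are
bit-for-bit reproducible from (input, seed):

* CARS  -- competitive adaptive reweighted sampling: Monte-Carlo PLS runs
  with an exponentially decreasing retention schedule; variables compete by
  |b| through a forced cut plus weighted resampling.
* MC-UVE -- Monte-Carlo uninformative variable elimination: reliability
  index RI = mean(b)/std(b) over resampled PLS models; forward addition by
  |RI| rank locates the RMSECV minimum.
* SPA   -- subwindow permutation analysis: random (sample, variable)
  submodels; each variable's importance is the one-sided rank-sum P that
  submodels containing it predict better, scored as COSS = -log10(P).
* LPG   -- latent projective graph: variables mapped into the standardized
  PC1-PC2 loading plane; informative variables sit at polyline vertices
  (sharp turning angles) or on the convex hull of the cloud.

The consensus keeps every wavenumber chosen by at least ``min_votes``
methods -- the "common variables" fed to the Fisher stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError
from scipy.stats import mannwhitneyu

from .core_io import SpectraSet
from .pls import RankError, cross_validate, pls_fit


def _safe_rmsecv(X, y, n_components, folds, seed) -> float:
    """RMSECV, with rank-deficient variable subsets scored as +inf."""
    try:
        return cross_validate(X, y, n_components, folds=folds, seed=seed).rmsecv
    except RankError:
        return float("inf")


class SelectionError(ValueError):
    """A selector cannot produce a valid result with these parameters."""


@dataclass
class SelectionResult:
    """One algorithm's chosen wavenumbers plus its diagnostic path."""

    method: str
    selected: np.ndarray  # wavenumbers, ascending
    scores: pd.DataFrame  # per-variable diagnostics, indexed by wavenumber
    rmsecv_path: list[float] = field(default_factory=list)
    chosen_threshold: float | None = None
    seed: int = 0
    extras: dict = field(default_factory=dict)


def _labels(s: SpectraSet, y) -> np.ndarray:
    return s.region_classes.astype(float) if y is None else np.asarray(y, dtype=float).ravel()


def _safe_A(n_components: int, n: int, p: int) -> int:
    return max(1, min(n_components, n - 2, p))


def cars_ratio_schedule(p: int, n_iter: int) -> np.ndarray:
    """Exponentially decreasing retained-variable ratio r_i = a e^{-k i}.

    Pinned so the first iteration keeps all p variables (r_1 = 1) and the
    last keeps two (r_{n_iter} = 2/p).
    """
    if p < 3 or n_iter < 2:
        raise SelectionError("need p >= 3 and n_iter >= 2")
    k = np.log(p / 2.0) / (n_iter - 1)
    a = np.exp(k)
    i = np.arange(1, n_iter + 1)
    return a * np.exp(-k * i)


def cars_select(
    s: SpectraSet,
    y=None,
    n_components: int = 5,
    n_iter: int = 50,
    sample_frac: float = 0.8,
    folds: int = 10,
    n_runs: int = 100,
    seed: int = 0,
) -> SelectionResult:
    """Competitive adaptive reweighted sampling.

    Each run walks the exponential retention schedule: at iteration i a PLS
    model fit on a random ``sample_frac`` subset ranks the active variables
    by |b|; the forced (EDF) cut keeps the top r_i * p, then adaptive
    reweighted sampling draws r_i * p times with probability proportional to
    |b|, keeping the unique survivors. The iteration with minimal 10-fold
    RMSECV defines the run's subset; across runs, ``selected`` is the best
    run's subset (min RMSECV, ties toward fewer variables then lower run
    index) and ``scores`` records each variable's selection frequency.
    """
    X, wn = s.absorbance, s.grid.points
    yv = _labels(s, y)
    n, p = X.shape
    if p < 10:
        raise SelectionError("CARS needs p >= 10")
    ratios = cars_ratio_schedule(p, n_iter)
    n_sub = max(2, int(round(sample_frac * n)))
    # one fold assignment for the whole call: every iteration of every run is
    # scored on identical folds, so RMSECV values are directly comparable
    cv_seed = int(np.random.default_rng([seed, n_runs]).integers(2**31 - 1))
    best_per_run: list[tuple[float, np.ndarray]] = []
    freq = np.zeros(p)
    best_path: list[float] = []
    for run in range(n_runs):
        rng = np.random.default_rng([seed, run])
        active = np.arange(p)
        run_best: tuple[float, np.ndarray] | None = None
        path: list[float] = []
        for i, r in enumerate(ratios):
            keep = int(round(r * p))
            if keep < n_components + 1 or keep < 2:
                break
            sub = rng.choice(n, size=n_sub, replace=False)
            A_eff = _safe_A(n_components, n_sub, active.size)
            try:
                model = pls_fit(X[np.ix_(sub, active)], yv[sub], A_eff)
            except RankError:
                break
            b = np.abs(model.coef)
            # enforced descending-ratio cut by |b|
            order = np.argsort(-b, kind="stable")
            edf = active[order[: min(keep, active.size)]]
            w = b[order[: min(keep, active.size)]]
            if w.sum() <= 0:
                break
            # adaptive reweighted sampling: weighted bootstrap, keep uniques
            draws = rng.choice(edf, size=keep, replace=True, p=w / w.sum())
            active = np.unique(draws)
            if active.size < 2:
                break
            A_cv = _safe_A(n_components, n, active.size)
            rmsecv = _safe_rmsecv(X[:, active], yv, A_cv, folds, cv_seed)
            path.append(rmsecv)
            if run_best is None or rmsecv < run_best[0]:
                run_best = (rmsecv, active.copy())
        if run_best is None or not np.isfinite(run_best[0]):
            continue
        best_per_run.append(run_best)
        freq[run_best[1]] += 1.0
        if not best_path or run_best[0] < min(r[0] for r in best_per_run[:-1]):
            best_path = path
    if not best_per_run:
        raise SelectionError("every CARS run collapsed before producing a subset")
    freq /= len(best_per_run)
    best_idx = min(
        range(len(best_per_run)),
        key=lambda i: (best_per_run[i][0], best_per_run[i][1].size, i),
    )
    chosen = np.sort(best_per_run[best_idx][1])
    scores = pd.DataFrame({"wavenumber": wn, "frequency": freq}).set_index("wavenumber")
    return SelectionResult(
        method="CARS",
        selected=np.sort(wn[chosen]),
        scores=scores,
        rmsecv_path=best_path,
        chosen_threshold=float(best_per_run[best_idx][0]),
        seed=seed,
    )


def mcuve_select(
    s: SpectraSet,
    y=None,
    n_components: int = 5,
    n_mc: int = 500,
    sample_frac: float = 0.8,
    folds: int = 10,
    forward_max: int = 150,
    seed: int = 0,
) -> SelectionResult:
    """Monte-Carlo uninformative variable elimination.

    ``n_mc`` PLS models are fit on random ``sample_frac`` sample subsets and
    the regression vectors collected; RI_j = mean(b_j)/std(b_j). Variables
    are ranked by |RI| and added one at a time; ``selected`` is the prefix at
    the global RMSECV minimum, ``chosen_threshold`` the |RI| of its last
    variable. Zero-spread coefficients get an infinite RI sentinel (ranked
    first, with a warning).
    """
    X, wn = s.absorbance, s.grid.points
    yv = _labels(s, y)
    n, p = X.shape
    rng = np.random.default_rng([seed, 0])
    cv_seed = int(rng.integers(2**31 - 1))
    n_sub = max(2, int(round(sample_frac * n)))
    B = np.empty((n_mc, p))
    for m in range(n_mc):
        sub = rng.choice(n, size=n_sub, replace=False)
        A_eff = _safe_A(n_components, n_sub, p)
        B[m] = pls_fit(X[sub], yv[sub], A_eff).coef
    sd = B.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ri = B.mean(axis=0) / sd
    degenerate = sd <= 0
    if np.any(degenerate):
        warnings.warn(
            f"{int(degenerate.sum())} variable(s) with zero coefficient spread; "
            "RI set to +inf",
            stacklevel=2,
        )
        ri[degenerate] = np.inf * np.sign(B.mean(axis=0)[degenerate])
        ri[degenerate & (B.mean(axis=0) == 0)] = np.inf
    order = np.argsort(-np.abs(ri), kind="stable")
    path: list[float] = []
    limit = min(forward_max, p)
    for m in range(1, limit + 1):
        cols = order[:m]
        A_eff = _safe_A(n_components, n, m)
        path.append(_safe_rmsecv(X[:, cols], yv, A_eff, folds, cv_seed))
    m_star = int(np.argmin(path)) + 1
    chosen = order[:m_star]
    scores = pd.DataFrame({"wavenumber": wn, "ri": ri}).set_index("wavenumber")
    return SelectionResult(
        method="MCUVE",
        selected=np.sort(wn[chosen]),
        scores=scores,
        rmsecv_path=path,
        chosen_threshold=float(np.abs(ri[order[m_star - 1]])),
        seed=seed,
        extras={"coef_draws": B},
    )


def spa_select(
    s: SpectraSet,
    y=None,
    n_components: int = 5,
    n_mc: int = 1000,
    sample_frac: float = 0.8,
    q_vars: int = 10,
    coss_min: float = 2.0,
    seed: int = 0,
) -> SelectionResult:
    """Subwindow permutation analysis.

    Each of ``n_mc`` submodels draws ceil(sample_frac * n) samples and
    ``q_vars`` variables, fits PLS, and records its prediction error on the
    held-out samples. Per variable, a one-sided rank-sum test compares the
    error distributions of submodels that included vs excluded it
    (inclusion improves prediction); COSS_j = -log10(P_j) and variables with
    COSS above ``coss_min`` are selected.
    """
    X, wn = s.absorbance, s.grid.points
    yv = _labels(s, y)
    n, p = X.shape
    if not (1 <= q_vars <= p):
        raise SelectionError("q_vars must be in [1, p]")
    if n_mc < 100:
        raise SelectionError("need n_mc >= 100")
    if n_mc * q_vars < p:
        raise SelectionError(
            f"n_mc * q_vars = {n_mc * q_vars} < p = {p}: some variables can "
            "never be sampled; increase n_mc"
        )
    rng = np.random.default_rng([seed, 0])
    n_in = int(np.ceil(sample_frac * n))
    if n_in >= n:
        n_in = n - 1
    # balanced subwindow allocation: chain random permutations of the
    # variables and cut them into Q-sized windows, so every variable is
    # included floor/ceil(n_mc*q_vars/p) times (the rank-sum comparison is
    # then well defined for all of them)
    n_perm = int(np.ceil(n_mc * q_vars / p))
    sequence = np.concatenate([rng.permutation(p) for _ in range(n_perm)])
    errors = np.empty(n_mc)
    included = np.zeros((n_mc, p), dtype=bool)
    for m in range(n_mc):
        cols = sequence[m * q_vars: (m + 1) * q_vars]
        if np.unique(cols).size < q_vars:  # permutation boundary collision
            cols = rng.choice(p, size=q_vars, replace=False)
        rows = rng.choice(n, size=n_in, replace=False)
        out = np.setdiff1d(np.arange(n), rows, assume_unique=False)
        A_eff = _safe_A(n_components, n_in, q_vars)
        model = pls_fit(X[np.ix_(rows, cols)], yv[rows], A_eff)
        pred = model.predict(X[np.ix_(out, cols)])
        errors[m] = np.sqrt(np.mean((yv[out] - pred) ** 2))
        included[m, cols] = True
    counts = included.sum(axis=0)
    if np.any(counts == 0):
        raise SelectionError(
            f"{int(np.sum(counts == 0))} variable(s) never sampled; increase n_mc"
        )
    coss = np.empty(p)
    for j in range(p):
        inc = errors[included[:, j]]
        exc = errors[~included[:, j]]
        pval = mannwhitneyu(inc, exc, alternative="less").pvalue
        coss[j] = -np.log10(max(pval, 1e-300))
    chosen = np.flatnonzero(coss > coss_min)
    scores = pd.DataFrame(
        {"wavenumber": wn, "coss": coss, "n_included": counts}
    ).set_index("wavenumber")
    return SelectionResult(
        method="SPA",
        selected=np.sort(wn[chosen]),
        scores=scores,
        rmsecv_path=[],
        chosen_threshold=float(coss_min),
        seed=seed,
    )


def lpg_select(
    s: SpectraSet,
    n_pcs: int = 2,
    angle_min: float = 15.0,
) -> SelectionResult:
    """Latent projective graph vertex detection.

    PCA on the standardized spectra places every variable in the PC1-PC2
    loading plane (coordinates weighted by the singular values, i.e.
    correlation loadings). Walking the variables in wavenumber order traces
    a polyline on which collinear (redundant) variables lie along segments;
    a variable is selected as non-collinear when its turning angle exceeds
    ``angle_min`` degrees or it lies on the convex hull of the loading
    cloud. Deterministic -- no randomness.
    """
    X, wn = s.absorbance, s.grid.points
    n, p = X.shape
    if p < 3:
        raise SelectionError("LPG needs p >= 3")
    Xc = X - X.mean(axis=0)
    sd = Xc.std(axis=0, ddof=1)
    sd[sd <= 0] = 1.0
    _, sv, Vt = np.linalg.svd(Xc / sd, full_matrices=False)
    Z = Vt[:n_pcs].T * (sv[:n_pcs] / np.sqrt(n - 1))  # p x n_pcs
    if np.all(np.abs(Z) <= 1e-12):
        warnings.warn("degenerate loadings: all variables identical", stacklevel=2)
        empty = pd.DataFrame(
            {"wavenumber": wn, "turn_angle": np.zeros(p), "on_hull": False}
        ).set_index("wavenumber")
        return SelectionResult("LPG", np.array([]), empty, [], float(angle_min), 0)
    # turning angle along the wavenumber-ordered polyline
    angles = np.zeros(p)
    d1 = Z[1:-1] - Z[:-2]
    d2 = Z[2:] - Z[1:-1]
    n1 = np.linalg.norm(d1, axis=1)
    n2 = np.linalg.norm(d2, axis=1)
    ok = (n1 > 1e-12) & (n2 > 1e-12)
    cosang = np.ones(p - 2)
    cosang[ok] = np.sum(d1[ok] * d2[ok], axis=1) / (n1[ok] * n2[ok])
    angles[1:-1] = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    on_hull = np.zeros(p, dtype=bool)
    try:
        hull = ConvexHull(Z[:, :2])
        on_hull[hull.vertices] = True
    except QhullError:
        warnings.warn("convex hull degenerate; using turning angles only", stacklevel=2)
    chosen = np.flatnonzero((angles > angle_min) | on_hull)
    scores = pd.DataFrame(
        {"wavenumber": wn, "turn_angle": angles, "on_hull": on_hull}
    ).set_index("wavenumber")
    return SelectionResult(
        method="LPG",
        selected=np.sort(wn[chosen]),
        scores=scores,
        rmsecv_path=[],
        chosen_threshold=float(angle_min),
        seed=0,
    )


def consensus_vote(results: list[SelectionResult], min_votes: int = 2) -> np.ndarray:
    """Wavenumbers selected by at least ``min_votes`` of the given methods."""
    if len(results) < 2:
        raise SelectionError("consensus needs >= 2 selection results")
    counts: dict[float, int] = {}
    for r in results:
        for w in np.unique(np.round(np.asarray(r.selected, dtype=float), 6)):
            counts[w] = counts.get(w, 0) + 1
    return np.sort([w for w, c in counts.items() if c >= min_votes])
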