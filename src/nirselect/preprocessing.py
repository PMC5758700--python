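"""Spectral pretreatment chain and SDD band selection.

The default chain follows the instrument-software order used for the study
spectra: Norris smoothing, mean centering, standardization (autoscaling),
then a Savitzky-Golay second derivative. Every step maps a
:class:`~nirselect.core_io.SpectraSet` to a new SpectraSet of the same shape,
so chains are order-sensitive, stateless and exactly reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
from scipy.signal import savgol_filter

from .core_io import SpectraSet, WavenumberGrid


class ParameterError(ValueError):
    """Pretreatment parameter invalid for the data at hand."""


class SelectionError(ValueError):
    """SDD band selection found no admissible window."""


def _fresh(s: SpectraSet, A: np.ndarray) -> SpectraSet:
    return SpectraSet(A, s.grid, [replace(m) for m in s.meta])


def norris_filter(s: SpectraSet, segment: int = 5, gap: int = 5) -> SpectraSet:
    """Norris gap-segment smoothing (segment-mean stage).

    Each spectrum is replaced by a running boxcar mean over ``segment``
    points; edge points use a window shrunk to the available neighbours. The
    ``gap`` parameter is the offset used by the gap-difference stage when a
    Norris derivative is requested (see :func:`norris_gap_derivative`); the
    smoothing itself does not consume it but the chain records it.
    """
    if segment < 1 or segment % 2 == 0:
        raise ParameterError("segment must be an odd integer >= 1")
    if gap < 1:
        raise ParameterError("gap must be >= 1")
    p = s.n_variables
    if segment + gap > p:
        raise ParameterError(f"segment + gap = {segment + gap} exceeds {p} variables")
    if segment == 1:
        return _fresh(s, s.absorbance.copy())
    half = segment // 2
    X = s.absorbance
    # shrinking-window boxcar via cumulative sums, vectorised over samples
    cs = np.cumsum(X, axis=1)
    cs = np.concatenate([np.zeros((X.shape[0], 1)), cs], axis=1)
    idx = np.arange(p)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half, p - 1)
    out = (cs[:, hi + 1] - cs[:, lo]) / (hi - lo + 1)
    return _fresh(s, out)


def norris_gap_derivative(s: SpectraSet, segment: int = 5, gap: int = 5) -> SpectraSet:
    """Norris first derivative: segment smoothing then a gap difference.

    d_i = (x_{i-gap} - x_{i+gap}) / (2 gap) on the smoothed spectrum (grid
    descending, so this is the derivative with respect to wavenumber index);
    edges are padded by replicating the nearest interior value.
    """
    sm = norris_filter(s, segment=segment, gap=gap).absorbance
    p = sm.shape[1]
    d = np.empty_like(sm)
    core = (sm[:, 2 * gap:] - sm[:, : p - 2 * gap]) / (2.0 * gap)
    d[:, gap: p - gap] = core
    d[:, :gap] = core[:, :1]
    d[:, p - gap:] = core[:, -1:]
    return _fresh(s, d)


def second_derivative(s: SpectraSet, window: int = 11, polyorder: int = 2) -> SpectraSet:
    """Savitzky-Golay second derivative with respect to grid index."""
    if polyorder < 2:
        raise ParameterError("polyorder must be >= 2 for a second derivative")
    if window % 2 == 0 or window < polyorder + 1:
        raise ParameterError("window must be odd and >= polyorder + 1")
    if window > s.n_variables:
        raise ParameterError("window exceeds variable count")
    out = savgol_filter(s.absorbance, window_length=window, polyorder=polyorder, deriv=2, axis=1)
    return _fresh(s, out)


def mean_center(s: SpectraSet) -> SpectraSet:
    """Subtract the per-variable mean (column means become 0)."""
    if s.n_samples < 2:
        raise ParameterError("mean centering needs n >= 2")
    return _fresh(s, s.absorbance - s.absorbance.mean(axis=0, keepdims=True))


def standardize(s: SpectraSet) -> SpectraSet:
    """Center and scale each variable to unit (sample) standard deviation.

    Zero-variance columns are left centered only, with a warning.
    """
    if s.n_samples < 2:
        raise ParameterError("standardization needs n >= 2")
    X = s.absorbance - s.absorbance.mean(axis=0, keepdims=True)
    sd = X.std(axis=0, ddof=1)
    zero = sd <= 0
    if np.any(zero):
        warnings.warn(
            f"{int(zero.sum())} zero-variance variable(s) left centered only",
            stacklevel=2,
        )
    sd = np.where(zero, 1.0, sd)
    return _fresh(s, X / sd)


_STEPS: dict[str, Callable[..., SpectraSet]] = {
    "norris_filter": norris_filter,
    "norris_gap_derivative": norris_gap_derivative,
    "mean_center": mean_center,
    "standardize": standardize,
    "second_derivative": second_derivative,
}

#: Step order used for the study spectra.
DEFAULT_CHAIN = ("norris_filter", "mean_center", "standardize", "second_derivative")


@dataclass
class PreprocessChain:
    """Ordered pretreatment steps with their parameters."""

    steps: tuple[str, ...] = DEFAULT_CHAIN
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for step in self.steps:
            if step not in _STEPS:
                raise ParameterError(f"unknown step {step!r}; choose from {sorted(_STEPS)}")

    def apply(self, s: SpectraSet) -> SpectraSet:
        for step in self.steps:
            s = _STEPS[step](s, **self.params.get(step, {}))
        return s

    def describe(self) -> list[dict]:
        return [{"step": st, **self.params.get(st, {})} for st in self.steps]


def sdd_band_select(s: SpectraSet, quantile: float = 0.25, min_run: int = 50) -> WavenumberGrid:
    """Spectrum-standard-deviation (SDD) window selection.

    Computes the per-variable standard deviation across samples and returns
    the longest contiguous wavenumber run whose SD is at or above the given
    quantile of the SD distribution; higher SD means a larger contribution to
    classification. Raises :class:`SelectionError` when no run reaches
    ``min_run`` points.
    """
    if not (0 <= quantile < 1):
        raise SelectionError("quantile must be in [0, 1)")
    sd = s.absorbance.std(axis=0, ddof=1)
    thr = np.quantile(sd, quantile)
    mask = sd >= thr
    best: tuple[int, int] | None = None  # (start, length)
    i = 0
    p = mask.size
    while i < p:
        if mask[i]:
            j = i
            while j + 1 < p and mask[j + 1]:
                j += 1
            length = j - i + 1
            if length >= min_run and (best is None or length > best[1]):
                best = (i, length)
            i = j + 1
        else:
            i += 1
    if best is None:
        raise SelectionError(
            f"no contiguous run of >= {min_run} variables at SD quantile "
            f"{quantile}; lower the quantile or min_run"
        )
    start, length = best
    return WavenumberGrid(s.grid.points[start: start + length])
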