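"""Synthetic NIR spectra with planted, class-discriminating absorption bands.

The generator emulates the study conditions of a diffuse-reflectance FT-NIR
survey of *Wolfiporia cocos* sclerotia: 60 samples per tissue split across
five unbalanced Yunnan region classes (19/12/5/10/14), a descending
wavenumber grid spanning the 10000-4000 cm^-1 scan at ~3.857 cm^-1 spacing,
a smooth per-sample quadratic baseline, broad shared absorption bands, a
small set of narrow class-informative bands, and i.i.d. measurement noise.

Each informative band carries a known center, so every downstream stage
(wavelength selection, consensus voting, Fisher modeling) can be scored
against ground truth. A selected variable "hits" a planted band when it lies
within +/-2 grid steps of the band center.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .core_io import SampleMeta, SpectraSet, WavenumberGrid

#: Bounds of the spectrum-standard-deviation (SDD) window used by the study.
SDD_HIGH = 7501.74
SDD_LOW = 4088.35
#: Instrument scan range (cm^-1).
SCAN_HIGH = 10000.0
SCAN_LOW = 4000.0
#: Exact grid spacing: the SDD window spans 3413.39 cm^-1 over 885 steps
#: (886 points); 3.857 cm^-1 is this value at printed precision.
STUDY_SPACING = (SDD_HIGH - SDD_LOW) / 885

#: Region-class sample counts: central / western / northwestern /
#: southwestern / southeastern Yunnan.
STUDY_CLASS_COUNTS = (19, 12, 5, 10, 14)

#: Ground-truth hit tolerance, in grid steps.
HIT_TOL_STEPS = 2


class ConfigError(ValueError):
    """Invalid synthetic-data configuration."""


def study_grid() -> WavenumberGrid:
    """The emulated instrument grid.

    Anchored so that both SDD window edges (7501.74 and 4088.35 cm^-1) are
    exact grid members -- every characteristic wavenumber reported for this
    instrument lies on this lattice -- and extended to cover the
    10000-4000 cm^-1 scan range.
    """
    k_up = math.floor((SCAN_HIGH - SDD_LOW) / STUDY_SPACING)
    k_dn = math.floor((SDD_LOW - SCAN_LOW) / STUDY_SPACING)
    ks = np.arange(k_up, -k_dn - 1, -1)
    return WavenumberGrid(SDD_LOW + STUDY_SPACING * ks)


@dataclass(frozen=True)
class BandSpec:
    """One Gaussian absorption band.

    ``amplitude_by_class`` gives the band's peak absorbance for region
    classes 1..5; a ``shared`` band is class-invariant background chemistry.
    """

    center: float
    width: float  # Gaussian sigma, cm^-1
    amplitude_by_class: tuple[float, float, float, float, float]
    shared: bool = False

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ConfigError("band width must be > 0")
        amps = np.asarray(self.amplitude_by_class, dtype=float)
        if amps.shape != (5,) or np.any(amps < 0):
            raise ConfigError("amplitude_by_class must be 5 nonnegative values")
        if not self.shared and np.allclose(amps, amps[0]):
            raise ConfigError("non-shared band must differ between some class pair")


@dataclass
class SyntheticConfig:
    """Full recipe for one synthetic tissue dataset."""

    tissue: str
    n_per_class: tuple[int, int, int, int, int]
    grid: WavenumberGrid
    bands: list[BandSpec]
    baseline_offset: float = 0.5
    baseline_slope: float = 0.3
    baseline_curvature: float = -0.2
    baseline_jitter_sd: float = 0.02
    amplitude_jitter: float = 0.10
    #: class-independent structured artifacts: (center, sigma, amplitude sd);
    #: each sample draws a random amplitude per entry, giving the correlated
    #: uninformative background that a derivative filter cannot remove
    nuisance: tuple[tuple[float, float, float], ...] = ()
    noise_sd: float = 0.005
    outlier_count: int = 0
    outlier_scale: float = 10.0
    seed: int = 42

    def __post_init__(self) -> None:
        if len(self.n_per_class) != 5 or any(int(n) < 1 for n in self.n_per_class):
            raise ConfigError("need 5 per-class counts, each >= 1")
        self.n_per_class = tuple(int(n) for n in self.n_per_class)
        if self.outlier_count < 0 or self.noise_sd < 0:
            raise ConfigError("outlier_count and noise_sd must be >= 0")

    @property
    def n_samples(self) -> int:
        return sum(self.n_per_class)


def generate_dataset(cfg: SyntheticConfig) -> tuple[SpectraSet, np.ndarray]:
    """Draw one dataset; returns ``(spectra, truth)``.

    ``truth`` is the sorted array of informative wavenumbers: the centers of
    all non-shared bands snapped to the nearest grid point. Identical seeds
    give bit-identical output.

    absorbance(sample, nu) = baseline(nu)
                             + sum_bands amp[class] * exp(-(nu-center)^2 / (2 width^2))
                             + noise
    """
    rng = np.random.default_rng(cfg.seed)
    nu = cfg.grid.points
    lo, hi = float(nu.min()), float(nu.max())
    for b in cfg.bands:
        if not (lo <= b.center <= hi):
            raise ConfigError(f"band center {b.center} cm^-1 outside grid range")

    labels = np.repeat(np.arange(1, 6), cfg.n_per_class)
    n, p = labels.size, nu.size
    u = (nu - lo) / (hi - lo)  # normalised axis for the baseline polynomial

    # per-sample random quadratic baseline: correlated uninformative background
    c0 = rng.normal(cfg.baseline_offset, cfg.baseline_jitter_sd, n)
    c1 = rng.normal(cfg.baseline_slope, cfg.baseline_jitter_sd, n)
    c2 = rng.normal(cfg.baseline_curvature, cfg.baseline_jitter_sd, n)
    A = c0[:, None] + c1[:, None] * u[None, :] + c2[:, None] * u[None, :] ** 2

    for b in cfg.bands:
        profile = np.exp(-((nu - b.center) ** 2) / (2.0 * b.width**2))
        amps = np.asarray(b.amplitude_by_class)[labels - 1]
        amps = amps * (1.0 + cfg.amplitude_jitter * rng.standard_normal(n))
        A += np.abs(amps)[:, None] * profile[None, :]

    for center, width, amp_sd in cfg.nuisance:
        profile = np.exp(-((nu - center) ** 2) / (2.0 * width**2))
        A += rng.normal(0.0, amp_sd, n)[:, None] * profile[None, :]

    if cfg.outlier_count:
        out_idx = rng.choice(n, size=cfg.outlier_count, replace=False)
        A[out_idx] *= cfg.outlier_scale

    if cfg.noise_sd > 0:
        A += rng.normal(0.0, cfg.noise_sd, size=(n, p))

    meta = [
        SampleMeta(sample_id=f"{cfg.tissue}-{i + 1:02d}", tissue=cfg.tissue, region_class=int(c))
        for i, c in enumerate(labels)
    ]
    truth = np.sort(
        [float(nu[cfg.grid.nearest_index(b.center)]) for b in cfg.bands if not b.shared]
    )
    return SpectraSet(A, cfg.grid, meta), np.asarray(truth)


#: Informative band centers per tissue (disjoint sets; all on the study grid).
BFL_INFORMATIVE = (4092.21, 4308.19, 4439.33, 4597.46, 5079.58, 5866.40)
FLP_INFORMATIVE = (4508.75, 4952.30, 5233.86, 5303.28, 5685.12, 5928.11)

#: Amplitude-by-class profiles of the six informative bands. Each profile is
#: monotone (linear, convex or step-shaped) in the class code, so every band
#: is individually predictive, while the six distinct shapes jointly give the
#: five classes well-separated mean spectra.
INFORMATIVE_PROFILES: tuple[tuple[float, ...], ...] = (
    (0.04, 0.06, 0.08, 0.10, 0.12),
    (0.12, 0.10, 0.08, 0.06, 0.04),
    (0.04, 0.045, 0.06, 0.09, 0.12),
    (0.12, 0.09, 0.06, 0.045, 0.04),
    (0.04, 0.04, 0.12, 0.12, 0.12),
    (0.12, 0.12, 0.12, 0.04, 0.04),
)

#: Width (Gaussian sigma, cm^-1) of the informative bands: ~1.6 grid steps,
#: narrow enough that selection pinpoints the centers, wide enough that the
#: derivative filter does not wash the signal out.
INFORMATIVE_WIDTH = 6.0

#: Structured class-independent artifacts shared by both tissue configs:
#: (center cm^-1, sigma cm^-1, per-sample amplitude sd). Centers sit at
#: least ~80 cm^-1 from every informative center.
STUDY_NUISANCE: tuple[tuple[float, float, float], ...] = (
    (4200.0, 40.0, 0.04),
    (4740.0, 35.0, 0.04),
    (4850.0, 50.0, 0.03),
    (5150.0, 30.0, 0.04),
    (5450.0, 45.0, 0.03),
    (5550.0, 35.0, 0.04),
    (5780.0, 30.0, 0.03),
    (6100.0, 60.0, 0.04),
    (6350.0, 40.0, 0.03),
    (6700.0, 50.0, 0.04),
    (7100.0, 45.0, 0.03),
    (7400.0, 35.0, 0.04),
)

#: Broad, class-invariant background bands (center, sigma, BFL amp, FLP amp).
_SHARED_BANDS = (
    (4250.0, 120.0, 0.30, 0.18),
    (4700.0, 90.0, 0.22, 0.30),
    (5180.0, 140.0, 0.28, 0.16),
    (5600.0, 100.0, 0.18, 0.28),
    (6000.0, 150.0, 0.25, 0.12),
    (6500.0, 120.0, 0.15, 0.26),
    (6900.0, 160.0, 0.20, 0.10),
    (7300.0, 110.0, 0.12, 0.22),
    (8300.0, 200.0, 0.10, 0.16),
    (9200.0, 250.0, 0.08, 0.05),
)


def default_study_config(tissue: str, seed: int = 42) -> SyntheticConfig:
    """The default study conditions for one tissue.

    60 samples in five unbalanced region classes (19/12/5/10/14); 6 narrow
    informative bands (sigma 10 cm^-1) and 10 broad shared bands
    (sigma 90-250 cm^-1); noise sd 0.005 absorbance units. BFL and FLP use
    disjoint informative centers and different shared-band amplitudes, so a
    PCA of the pooled tissues separates them.
    """
    if tissue not in ("BFL", "FLP"):
        raise ConfigError(f"tissue must be BFL or FLP, got {tissue!r}")
    centers = BFL_INFORMATIVE if tissue == "BFL" else FLP_INFORMATIVE
    amp_idx = 0 if tissue == "BFL" else 1
    bands = [
        BandSpec(center=c, width=s, amplitude_by_class=(amps[amp_idx],) * 5, shared=True)
        for (c, s, *amps) in _SHARED_BANDS
    ]
    for center, profile in zip(centers, INFORMATIVE_PROFILES):
        bands.append(
            BandSpec(center=center, width=INFORMATIVE_WIDTH, amplitude_by_class=profile)
        )
    return SyntheticConfig(
        tissue=tissue,
        n_per_class=STUDY_CLASS_COUNTS,
        grid=study_grid(),
        bands=bands,
        nuisance=STUDY_NUISANCE,
        seed=seed,
    )


def hit_rate(
    selected: np.ndarray,
    truth: np.ndarray,
    grid: WavenumberGrid,
    tol_steps: int = HIT_TOL_STEPS,
) -> float:
    """Fraction of planted centers with a selected variable within tolerance."""
    truth = np.atleast_1d(np.asarray(truth, dtype=float))
    selected = np.atleast_1d(np.asarray(selected, dtype=float))
    if truth.size == 0:
        return float("nan")
    if selected.size == 0:
        return 0.0
    tol = tol_steps * grid.spacing + 1e-9
    return float(np.mean([np.min(np.abs(selected - t)) <= tol for t in truth]))
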