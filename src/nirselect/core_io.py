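"""Data model and I/O for NIR absorbance spectra.

The package's universal carrier is the :class:`SpectraSet`: an absorbance
matrix (samples x wavenumbers) on a uniform, descending wavenumber grid,
plus per-sample metadata (tissue, geographic region class, set membership).
Wavenumbers are the public coordinate everywhere -- downstream results are
reported in cm^-1, never as column positions, so that cropping and variable
selection cannot silently shift indices.

Spectra are exchanged as plain CSV: one header row of wavenumbers in
descending order, a leading ``sample_id`` column, one row per sample.
Metadata travels in a second CSV keyed by ``sample_id``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Tolerance (cm^-1) for grid-uniformity checks.
GRID_TOL = 1e-6

TISSUES = ("BFL", "FLP")
REGION_CLASSES = (1, 2, 3, 4, 5)
MEMBERSHIPS = ("unassigned", "training", "validation")


class FormatError(ValueError):
    """Spectra file violates the expected layout (e.g. non-uniform grid)."""


class MetadataError(ValueError):
    """Sample metadata missing, duplicated or inconsistent with spectra."""


class DataError(ValueError):
    """Absorbance values invalid (NaN / non-numeric)."""


class RangeError(ValueError):
    """Requested wavenumber range does not intersect the grid."""


@dataclass(frozen=True)
class WavenumberGrid:
    """Uniform, descending wavenumber axis in cm^-1."""

    points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 1 or pts.size < 1:
            raise FormatError("grid needs at least one wavenumber")
        if pts.size >= 2:
            diffs = -np.diff(pts)
            if np.any(diffs <= 0):
                raise FormatError("wavenumbers must be strictly descending")
            spacing = (pts[0] - pts[-1]) / (pts.size - 1)
            if np.max(np.abs(diffs - spacing)) >= GRID_TOL:
                raise FormatError(
                    "non-uniform wavenumber spacing (max deviation "
                    f"{np.max(np.abs(diffs - spacing)):.3g} cm^-1 >= {GRID_TOL:g})"
                )
        object.__setattr__(self, "points", pts)

    @classmethod
    def from_range(cls, start: float, end: float, spacing: float) -> "WavenumberGrid":
        """Grid from ``start`` (highest) down to ``end`` at ``spacing`` cm^-1."""
        if spacing <= 0 or end >= start:
            raise FormatError("need start > end and spacing > 0")
        count = int(round((start - end) / spacing)) + 1
        return cls(start - spacing * np.arange(count))

    @property
    def start(self) -> float:
        return float(self.points[0])

    @property
    def end(self) -> float:
        return float(self.points[-1])

    @property
    def spacing(self) -> float:
        if self.points.size < 2:
            return 0.0
        return float((self.points[0] - self.points[-1]) / (self.points.size - 1))

    def __len__(self) -> int:
        return int(self.points.size)

    def crop_mask(self, high: float, low: float) -> np.ndarray:
        """Boolean mask of grid points p with low <= p <= high."""
        if low >= high:
            raise RangeError("need low < high")
        eps = 1e-9
        return (self.points >= low - eps) & (self.points <= high + eps)

    def index_of(self, wavenumbers: Iterable[float], tol: float = 1e-6) -> np.ndarray:
        """Column indices of the given wavenumber values (exact to ``tol``)."""
        out = []
        for w in np.atleast_1d(np.asarray(wavenumbers, dtype=float)):
            i = int(np.argmin(np.abs(self.points - w)))
            if abs(self.points[i] - w) > tol:
                raise RangeError(f"wavenumber {w:.4f} cm^-1 not on grid")
            out.append(i)
        return np.asarray(out, dtype=int)

    def nearest_index(self, wavenumber: float) -> int:
        return int(np.argmin(np.abs(self.points - float(wavenumber))))


@dataclass
class SampleMeta:
    """Per-sample metadata: identity, tissue, origin class, set membership."""

    sample_id: str
    tissue: str
    region_class: int
    set_membership: str = "unassigned"

    def __post_init__(self) -> None:
        if self.tissue not in TISSUES:
            raise MetadataError(f"tissue must be one of {TISSUES}, got {self.tissue!r}")
        if int(self.region_class) not in REGION_CLASSES:
            raise MetadataError(f"region_class must be in 1..5, got {self.region_class!r}")
        self.region_class = int(self.region_class)
        if self.set_membership not in MEMBERSHIPS:
            raise MetadataError(f"bad set_membership {self.set_membership!r}")


@dataclass
class SpectraSet:
    """Absorbance matrix + wavenumber grid + sample metadata."""

    absorbance: np.ndarray
    grid: WavenumberGrid
    meta: list[SampleMeta] = field(default_factory=list)

    def __post_init__(self) -> None:
        A = np.asarray(self.absorbance, dtype=float)
        if A.ndim != 2:
            raise DataError("absorbance must be a 2-D matrix")
        if A.shape[1] != len(self.grid):
            raise FormatError(
                f"absorbance has {A.shape[1]} columns but grid has {len(self.grid)} points"
            )
        if A.shape[0] != len(self.meta):
            raise MetadataError(
                f"{A.shape[0]} spectra but {len(self.meta)} metadata rows"
            )
        if not np.all(np.isfinite(A)):
            raise DataError("absorbance contains NaN/inf")
        ids = [m.sample_id for m in self.meta]
        if len(set(ids)) != len(ids):
            raise MetadataError("duplicate sample_id")
        self.absorbance = A

    # -- convenience accessors -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_variables(self) -> int:
        return self.absorbance.shape[1]

    @property
    def sample_ids(self) -> list[str]:
        return [m.sample_id for m in self.meta]

    @property
    def region_classes(self) -> np.ndarray:
        return np.array([m.region_class for m in self.meta], dtype=int)

    @property
    def memberships(self) -> np.ndarray:
        return np.array([m.set_membership for m in self.meta])

    def meta_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "tissue": [m.tissue for m in self.meta],
                "region_class": self.region_classes,
                "set_membership": self.memberships,
            }
        )

    def subset_rows(self, rows: Sequence[int] | np.ndarray) -> "SpectraSet":
        rows = np.asarray(rows)
        if rows.dtype == bool:
            rows = np.flatnonzero(rows)
        return SpectraSet(
            self.absorbance[rows],
            self.grid,
            [replace(self.meta[int(i)]) for i in rows],
        )

    def training_set(self) -> "SpectraSet":
        return self.subset_rows(self.memberships == "training")

    def validation_set(self) -> "SpectraSet":
        return self.subset_rows(self.memberships == "validation")

    def with_membership(self, assignment: dict[str, str]) -> "SpectraSet":
        """Copy with set_membership filled from a sample_id -> membership map."""
        meta = [
            replace(m, set_membership=assignment.get(m.sample_id, m.set_membership))
            for m in self.meta
        ]
        return SpectraSet(self.absorbance.copy(), self.grid, meta)

    def extract(self, wavenumbers: Iterable[float], tol: float = 1e-6) -> tuple[np.ndarray, np.ndarray]:
        """Column submatrix at the given wavenumbers.

        Returns ``(X, wn)``: the selected absorbance columns and their
        wavenumbers. This is the hand-off point from grid-shaped data to the
        scattered variable subsets produced by wavelength selection (which no
        longer satisfy the uniform-grid invariant).
        """
        idx = self.grid.index_of(wavenumbers, tol=tol)
        return self.absorbance[:, idx], self.grid.points[idx]


def band_crop(s: SpectraSet, high: float, low: float) -> SpectraSet:
    """Keep exactly the grid points p with low <= p <= high."""
    mask = s.grid.crop_mask(high, low)
    if not np.any(mask):
        raise RangeError(
            f"[{low:.2f}, {high:.2f}] cm^-1 does not intersect grid "
            f"[{s.grid.end:.2f}, {s.grid.start:.2f}]"
        )
    return SpectraSet(
        s.absorbance[:, mask],
        WavenumberGrid(s.grid.points[mask]),
        [replace(m) for m in s.meta],
    )


# -- CSV round-trip ----------------------------------------------------------

def write_spectra_csv(s: SpectraSet, path: str | Path, meta_path: str | Path) -> None:
    """Write spectra and metadata CSVs (lossless float round-trip)."""
    path, meta_path = Path(path), Path(meta_path)
    header = "sample_id," + ",".join(f"{w:.8f}" for w in s.grid.points)
    lines = [header]
    for sid, row in zip(s.sample_ids, s.absorbance):
        lines.append(sid + "," + ",".join(repr(float(v)) for v in row))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    s.meta_frame().to_csv(meta_path, index=False)


def read_spectra_csv(path: str | Path, meta_path: str | Path) -> SpectraSet:
    """Read spectra + metadata CSVs into a validated :class:`SpectraSet`."""
    df = pd.read_csv(path)
    if df.columns[0] != "sample_id":
        raise FormatError("first spectra column must be 'sample_id'")
    try:
        wavenumbers = np.array([float(c) for c in df.columns[1:]])
    except ValueError as exc:
        raise FormatError(f"non-numeric wavenumber header: {exc}") from None
    grid = WavenumberGrid(wavenumbers)  # validates descending uniform spacing
    A = df.iloc[:, 1:].to_numpy(dtype=float)
    if np.any(~np.isfinite(A)):
        raise DataError("absorbance contains NaN")
    meta_df = pd.read_csv(meta_path).set_index("sample_id", drop=False)
    if meta_df.index.has_duplicates:
        raise MetadataError("duplicate sample_id in metadata")
    meta = []
    for sid in df["sample_id"].astype(str):
        if sid not in meta_df.index:
            raise MetadataError(f"sample_id {sid!r} missing from metadata")
        row = meta_df.loc[sid]
        meta.append(
            SampleMeta(
                sample_id=sid,
                tissue=str(row["tissue"]),
                region_class=int(row["region_class"]),
                set_membership=str(row.get("set_membership", "unassigned")),
            )
        )
    return SpectraSet(A, grid, meta)
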