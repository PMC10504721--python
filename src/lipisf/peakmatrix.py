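"""Peak-matrix container, CSV / imzML import, and deisotoping.

The peak matrix is the standard product of centroid-mode MSI processing:
a [#pixels x #m/z] intensity table with integer pixel coordinates and a
common, strictly increasing m/z axis. No intensity normalization is applied
anywhere in the package.

The deisotoping pre-filter removes m/z features attributable to heavy-isotope
satellites (+k*1.0033548 Da) of a lighter feature, so that only putative
monoisotopic peaks enter the annotation search. It is a deliberately simple
mass-spacing / spatial-correlation / intensity-ratio rule; see
docs/methods.md for what it does not model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .chem import ISOTOPE_SPACING


class PeakMatrixError(ValueError):
    pass


@dataclass
class PeakMatrix:
    """Pixel coordinates + sorted m/z axis + non-negative intensity matrix."""

    pixels: np.ndarray      # (n_pixels, 2) int array of (x, y)
    mz: np.ndarray          # (n_mz,) strictly increasing
    intensity: np.ndarray   # (n_pixels, n_mz) non-negative finite
    polarity: str = "negative"
    ppm_tolerance: float = 5.0
    source: str = ""

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=int).reshape(-1, 2)
        self.mz = np.asarray(self.mz, dtype=float).ravel()
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.shape != (len(self.pixels), len(self.mz)):
            raise PeakMatrixError(
                f"intensity shape {self.intensity.shape} does not match "
                f"{len(self.pixels)} pixels x {len(self.mz)} m/z")
        if not np.all(np.isfinite(self.intensity)) or np.any(self.intensity < 0):
            raise PeakMatrixError("intensities must be finite and non-negative")
        if len(self.mz) and np.any(np.diff(self.mz) <= 0):
            order = np.argsort(self.mz, kind="stable")
            self.mz = self.mz[order]
            self.intensity = self.intensity[:, order]
            if np.any(np.diff(self.mz) <= 0):
                raise PeakMatrixError("duplicate m/z values in axis")
        coords = {tuple(p) for p in self.pixels}
        if len(coords) != len(self.pixels):
            raise PeakMatrixError("duplicate pixel coordinates")

    @property
    def n_pixels(self) -> int:
        return len(self.pixels)

    @property
    def n_mz(self) -> int:
        return len(self.mz)

    def select_peaks(self, indices: Sequence[int]) -> "PeakMatrix":
        idx = np.asarray(indices, dtype=int)
        return PeakMatrix(
            pixels=self.pixels.copy(),
            mz=self.mz[idx],
            intensity=self.intensity[:, idx],
            polarity=self.polarity,
            ppm_tolerance=self.ppm_tolerance,
            source=self.source,
        )


@dataclass
class DeisotopingReport:
    """Partition of the original m/z indices into kept peaks and removed
    isotope satellites, with per-satellite evidence."""

    kept: List[int]
    removed: List[int]
    # per removed index: (parent kept index, isotope order k, ppm error, r)
    evidence: dict = field(default_factory=dict)


def read_peak_matrix_csv(path, polarity: str = "negative") -> PeakMatrix:
    """Read the CSV dialect: header ``x,y,<mz1>,<mz2>,...``, one row per pixel."""
    df = pd.read_csv(path)
    if list(df.columns[:2]) != ["x", "y"]:
        raise PeakMatrixError("peak-matrix CSV must start with columns x,y")
    try:
        mz = np.array([float(c) for c in df.columns[2:]])
    except ValueError as exc:
        raise PeakMatrixError(f"non-numeric m/z column header: {exc}") from exc
    if df.isna().any().any():
        bad = int(df.isna().any(axis=1).idxmax())
        raise PeakMatrixError(f"missing values (ragged row?) near row {bad}")
    return PeakMatrix(
        pixels=df[["x", "y"]].to_numpy(),
        mz=mz,
        intensity=df.iloc[:, 2:].to_numpy(dtype=float),
        polarity=polarity,
        source=str(path),
    )


def write_peak_matrix_csv(pm: PeakMatrix, path) -> None:
    """Write the same dialect the reader accepts; m/z at 6 decimals,
    intensities at full precision so round-trips are bit-exact."""
    cols = ["x", "y"] + [f"{m:.6f}" for m in pm.mz]
    df = pd.DataFrame(
        np.column_stack([pm.pixels, pm.intensity]), columns=cols
    )
    df["x"] = df["x"].astype(int)
    df["y"] = df["y"].astype(int)
    df.to_csv(path, index=False, float_format="%.17g")


def read_peak_matrix_imzml(path, polarity: str = "negative") -> PeakMatrix:
    """Import a centroid ("processed") imzML file.

    Every spectrum must share the same centroid m/z axis (the peak-matrix
    contract); spectra are binned onto the axis of the first spectrum with
    exact matching.
    """
    from pyimzml.ImzMLParser import ImzMLParser

    parser = ImzMLParser(str(path))
    mz0, _ = parser.getspectrum(0)
    mz0 = np.asarray(mz0, dtype=float)
    pixels = []
    rows = []
    for i, (x, y, _z) in enumerate(parser.coordinates):
        mzs, ints = parser.getspectrum(i)
        mzs = np.asarray(mzs, dtype=float)
        if len(mzs) != len(mz0) or not np.allclose(mzs, mz0, rtol=0, atol=1e-9):
            raise PeakMatrixError(
                f"spectrum {i} has a different m/z axis; expected a common "
                "centroid axis (peak-matrix contract)")
        pixels.append((x, y))
        rows.append(np.asarray(ints, dtype=float))
    return PeakMatrix(
        pixels=np.array(pixels),
        mz=mz0,
        intensity=np.vstack(rows),
        polarity=polarity,
        source=str(path),
    )


def read_peak_matrix(path, format: str = "csv", polarity: str = "negative") -> PeakMatrix:
    if format == "csv":
        return read_peak_matrix_csv(path, polarity)
    if format == "imzml":
        return read_peak_matrix_imzml(path, polarity)
    raise PeakMatrixError(f"unknown peak-matrix format {format!r}")


def _pearson_columns(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson r between two intensity columns; 0 if either has no variance."""
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def deisotope(
    pm: PeakMatrix,
    ppm_tol: float = 20.0,
    max_order: int = 2,
    min_corr: float = 0.7,
    max_ratio: float = 1.0,
) -> Tuple[PeakMatrix, DeisotopingReport]:
    """Remove putative heavy-isotope satellite peaks.

    Scanning in ascending m/z, a peak j is flagged as the k-th isotope
    satellite (k <= max_order) of an already-kept peak i when its m/z sits
    within ``ppm_tol`` of mz_i + k*1.0033548, its ion image correlates with
    peak i at Pearson r >= ``min_corr``, and its mean intensity does not
    exceed ``max_ratio`` times that of peak i. Removed peaks never serve as
    parents, so the monoisotopic (lowest-m/z) member of a chain is always
    kept. The operation is idempotent.
    """
    if max_order < 1:
        raise ValueError("max_order must be >= 1")
    kept: List[int] = []
    removed: List[int] = []
    evidence = {}
    mean_int = pm.intensity.mean(axis=0) if pm.n_pixels else np.zeros(pm.n_mz)
    for j in range(pm.n_mz):
        hit = None
        for i in kept:
            for k in range(1, max_order + 1):
                expected = pm.mz[i] + k * ISOTOPE_SPACING
                err_ppm = 1e6 * (pm.mz[j] - expected) / expected
                if abs(err_ppm) <= ppm_tol:
                    r = _pearson_columns(pm.intensity[:, i], pm.intensity[:, j])
                    ratio_ok = mean_int[i] == 0 or mean_int[j] <= max_ratio * mean_int[i]
                    if r >= min_corr and ratio_ok:
                        hit = (i, k, err_ppm, r)
                        break
            if hit:
                break
        if hit:
            removed.append(j)
            evidence[j] = hit
        else:
            kept.append(j)
    return pm.select_peaks(kept), DeisotopingReport(kept, removed, evidence)
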