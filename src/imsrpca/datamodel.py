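"""Data model and I/O for peak-picked imaging mass spectrometry matrices.

An IMS experiment acquires a full mass spectrum at every pixel of a tissue
section.  After peak picking, the data set is a dense matrix ``A`` with one
row per pixel (m rows) and one column per m/z peak (n columns), together
with a pixel-coordinate table and the m/z axis.  This module defines that
container (:class:`IMSMatrix`), readers for imzML and for a simple HDF5
container, refolding of matrix columns into ion images, and trimmed TIC
normalization.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np


class FormatError(ValueError):
    """Raised when a file does not match the expected on-disk layout."""


@dataclasses.dataclass
class IMSMatrix:
    """A pixels x m/z-peaks intensity matrix with spatial and spectral axes.

    Parameters
    ----------
    values
        Real matrix of shape ``(m, n)``; rows are pixels, columns are m/z
        peaks, entries are intensities in arbitrary counts.
    pixel_coords
        Integer array of shape ``(m, 2)`` holding 0-based ``(x, y)`` grid
        indices, one row per pixel.  Pairs must be unique.
    mz_axis
        Strictly increasing real vector of length ``n`` (m/z, Thomson).
    meta
        Free-form key-value annotations.
    """

    values: np.ndarray
    pixel_coords: np.ndarray
    mz_axis: np.ndarray
    meta: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.pixel_coords = np.asarray(self.pixel_coords, dtype=np.int64)
        self.mz_axis = np.asarray(self.mz_axis, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        m, n = self.values.shape
        if self.pixel_coords.shape != (m, 2):
            raise ValueError(
                f"pixel_coords must have shape ({m}, 2), "
                f"got {self.pixel_coords.shape}"
            )
        if self.mz_axis.shape != (n,):
            raise ValueError(
                f"mz_axis must have length {n}, got {self.mz_axis.shape}"
            )
        if n > 1 and not np.all(np.diff(self.mz_axis) > 0):
            raise ValueError("mz_axis must be strictly increasing")
        uniq = {tuple(xy) for xy in self.pixel_coords}
        if len(uniq) != m:
            raise ValueError("pixel_coords pairs must be unique")

    @property
    def m(self) -> int:
        """Number of pixels (rows)."""
        return self.values.shape[0]

    @property
    def n(self) -> int:
        """Number of m/z peaks (columns)."""
        return self.values.shape[1]

    def with_values(self, values: np.ndarray, **meta) -> "IMSMatrix":
        """Return a copy sharing coords/axis but holding new intensities."""
        return IMSMatrix(
            values=np.asarray(values, dtype=np.float64),
            pixel_coords=self.pixel_coords.copy(),
            mz_axis=self.mz_axis.copy(),
            meta={**self.meta, **meta},
        )


@dataclasses.dataclass
class IonImage:
    """A single m/z channel refolded onto the pixel grid.

    ``grid[y, x]`` holds the intensity at pixel ``(x, y)``; cells not
    covered by any measured pixel are masked (``mask=True``) and set to 0.
    """

    grid: np.ndarray
    mask: np.ndarray
    mz_value: float


# ---------------------------------------------------------------------------
# imzML ingestion
# ---------------------------------------------------------------------------

def read_imzml(path, peak_list=None, tol: float = 0.05) -> IMSMatrix:
    """Read an imzML file into an :class:`IMSMatrix`.

    Continuous-mode files share one m/z axis across spectra and map
    directly onto matrix columns.  Processed-mode files store per-spectrum
    centroid lists; a ``peak_list`` (the common m/z axis) is then required
    and intensities are summed within half-open tolerance windows
    ``[mz - tol, mz + tol)`` around each peak.

    Parameters
    ----------
    path
        Path to the ``.imzML`` file (the ``.ibd`` sidecar must sit next
        to it).
    peak_list
        Target m/z axis for processed-mode binning; ignored for
        continuous-mode files.
    tol
        Half-width of each peak bin in Thomson (processed mode only).

    Returns
    -------
    IMSMatrix
        One row per spectrum, in file order; coordinates are converted to
        0-based grid indices.
    """
    from pyimzml.ImzMLParser import ImzMLParser

    path = Path(path)
    parser = ImzMLParser(str(path))
    try:
        mode = "continuous" if "continuous" in parser.metadata.file_description.param_by_name else "processed"
    except AttributeError:  # older pyimzml metadata layout
        mode = "continuous"

    coords = np.array([(c[0], c[1]) for c in parser.coordinates], dtype=np.int64)
    coords -= coords.min(axis=0)  # imzML coordinates are 1-based

    n_spectra = len(parser.coordinates)
    if mode == "continuous":
        mzs, _ = parser.getspectrum(0)
        mz_axis = np.asarray(mzs, dtype=np.float64)
        values = np.zeros((n_spectra, mz_axis.size))
        for i in range(n_spectra):
            _, intens = parser.getspectrum(i)
            values[i] = np.asarray(intens, dtype=np.float64)
    else:
        if peak_list is None:
            raise ValueError(
                "processed-mode imzML requires a peak_list for binning"
            )
        mz_axis = np.asarray(peak_list, dtype=np.float64)
        values = np.zeros((n_spectra, mz_axis.size))
        for i in range(n_spectra):
            mzs, intens = parser.getspectrum(i)
            mzs = np.asarray(mzs, dtype=np.float64)
            intens = np.asarray(intens, dtype=np.float64)
            for j, mz in enumerate(mz_axis):
                sel = (mzs >= mz - tol) & (mzs < mz + tol)
                values[i, j] = intens[sel].sum()

    return IMSMatrix(
        values=values,
        pixel_coords=coords,
        mz_axis=mz_axis,
        meta={"source": str(path), "imzml_mode": mode},
    )


# ---------------------------------------------------------------------------
# dense HDF5 container
# ---------------------------------------------------------------------------

_REQUIRED_KEYS = ("values", "pixel_coords", "mz_axis")


def write_matrix(x: IMSMatrix, path) -> None:
    """Persist an :class:`IMSMatrix` to the HDF5 container format.

    Layout: datasets ``/values``, ``/pixel_coords``, ``/mz_axis`` plus a
    JSON-serialised ``/meta`` attribute.  ``read_matrix(write_matrix(x))``
    is the identity on all fields.
    """
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=x.values)
        f.create_dataset("pixel_coords", data=x.pixel_coords)
        f.create_dataset("mz_axis", data=x.mz_axis)
        f.attrs["meta"] = json.dumps(x.meta, default=str)


def read_matrix(path) -> IMSMatrix:
    """Read an :class:`IMSMatrix` from the HDF5 container format."""
    with h5py.File(path, "r") as f:
        missing = [k for k in _REQUIRED_KEYS if k not in f]
        if missing:
            raise FormatError(f"container missing keys: {missing}")
        meta = json.loads(f.attrs.get("meta", "{}"))
        return IMSMatrix(
            values=f["values"][()],
            pixel_coords=f["pixel_coords"][()],
            mz_axis=f["mz_axis"][()],
            meta=meta,
        )


def write_csv(x: IMSMatrix, path) -> None:
    """Export a small matrix as CSV (x, y, then one column per m/z)."""
    import pandas as pd

    df = pd.DataFrame(x.values, columns=[f"{mz:.6f}" for mz in x.mz_axis])
    df.insert(0, "y", x.pixel_coords[:, 1])
    df.insert(0, "x", x.pixel_coords[:, 0])
    df.to_csv(path, index=False)


def read_csv(path) -> IMSMatrix:
    """Read a matrix exported by :func:`write_csv`."""
    import pandas as pd

    df = pd.read_csv(path)
    if "x" not in df.columns or "y" not in df.columns:
        raise FormatError("CSV matrix must carry 'x' and 'y' columns")
    coords = df[["x", "y"]].to_numpy(dtype=np.int64)
    mz_cols = [c for c in df.columns if c not in ("x", "y")]
    mz_axis = np.array([float(c) for c in mz_cols])
    return IMSMatrix(
        values=df[mz_cols].to_numpy(dtype=np.float64),
        pixel_coords=coords,
        mz_axis=mz_axis,
    )


# ---------------------------------------------------------------------------
# TIC normalization
# ---------------------------------------------------------------------------

def tic_normalize(
    x: IMSMatrix, lower_pct: float = 5.0, upper_pct: float = 95.0
) -> IMSMatrix:
    """Trimmed total-ion-current normalization of each pixel spectrum.

    Each row is divided by the sum of its intensities whose values fall
    within the ``[lower_pct, upper_pct]`` percentile band of that row's
    *nonzero* intensities (linear-interpolation percentiles, band ends
    inclusive).  With the full band ``[0, 100]`` this is classic TIC
    normalization (divide by the row sum).  Rows whose band sum is zero
    are left unchanged and listed in ``meta['tic_skipped_rows']``.

    Notes
    -----
    The percentile-band trimming used for "5-95% TIC" normalization is
    not uniquely standardised across IMS software; this trimmed-sum
    definition is this package's documented dialect and other dialects
    can be substituted upstream.
    """
    if not (0 <= lower_pct < upper_pct <= 100):
        raise ValueError("need 0 <= lower_pct < upper_pct <= 100")
    out = x.values.copy()
    skipped = []
    for i in range(x.m):
        row = x.values[i]
        nz = row[row != 0]
        if nz.size == 0:
            skipped.append(i)
            continue
        lo, hi = np.percentile(nz, [lower_pct, upper_pct])
        band = nz[(nz >= lo) & (nz <= hi)]
        divisor = band.sum()
        if divisor == 0:
            skipped.append(i)
            continue
        out[i] = row / divisor
    return x.with_values(
        out, tic_band=(lower_pct, upper_pct), tic_skipped_rows=skipped
    )


# ---------------------------------------------------------------------------
# refolding columns into ion images
# ---------------------------------------------------------------------------

def refold_image(x: IMSMatrix, column_index: int) -> IonImage:
    """Refold one matrix column into its spatial ion image.

    Produces a ``(max_y - min_y + 1, max_x - min_x + 1)`` grid with
    ``grid[y, x]`` equal to the intensity of the pixel at coordinates
    ``(x, y)``; grid cells not covered by a measured pixel (off-tissue)
    are masked.
    """
    if not (0 <= column_index < x.n):
        raise IndexError(
            f"column_index {column_index} out of range for n={x.n}"
        )
    xs = x.pixel_coords[:, 0]
    ys = x.pixel_coords[:, 1]
    x0, y0 = xs.min(), ys.min()
    grid = np.zeros((ys.max() - y0 + 1, xs.max() - x0 + 1))
    mask = np.ones_like(grid, dtype=bool)
    grid[ys - y0, xs - x0] = x.values[:, column_index]
    mask[ys - y0, xs - x0] = False
    return IonImage(grid=grid, mask=mask, mz_value=float(x.mz_axis[column_index]))


def unfold_image(img: IonImage, coords: np.ndarray) -> np.ndarray:
    """Read the image back into a column vector at the given pixel coords."""
    xs = coords[:, 0] - coords[:, 0].min()
    ys = coords[:, 1] - coords[:, 1].min()
    return img.grid[ys, xs]
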