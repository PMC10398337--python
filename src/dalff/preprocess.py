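"""NIfTI I/O and single-subject preprocessing.

The preprocessing chain applied here is the desk-scale subset that operates on
voxel time series already in a common space: discarding initial volumes,
polynomial detrending, nuisance regression and spatial smoothing.  The fixed
order (discard -> detrend -> nuisance -> smooth) is enforced by
:func:`run_preprocessing`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "BoldImage",
    "load_bold",
    "save_bold",
    "load_covariates",
    "save_covariates",
    "discard_initial_volumes",
    "detrend",
    "regress_nuisance",
    "smooth",
    "run_preprocessing",
    "FWHM_TO_SIGMA",
]

#: Conversion factor between Gaussian FWHM and standard deviation.
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class BoldImage:
    """One subject's 4D voxel time series with geometry, TR and brain mask.

    Parameters
    ----------
    data : ndarray, shape (x, y, z, t)
        Voxel intensities, time last.
    affine : ndarray, shape (4, 4)
        Voxel-to-world transform in mm.
    tr : float
        Repetition time in seconds.
    mask : ndarray of bool, shape (x, y, z)
        Brain mask; analyses are restricted to True voxels.
    """

    data: np.ndarray
    affine: np.ndarray
    tr: float
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        self.mask = np.asarray(self.mask).astype(bool)
        if self.data.ndim != 4:
            raise ValueError(f"data must be 4D (x, y, z, t), got shape {self.data.shape}")
        if self.data.shape[3] < 2:
            raise ValueError("time dimension must have at least 2 volumes")
        if self.tr <= 0:
            raise ValueError(f"tr must be positive, got {self.tr}")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if self.mask.shape != self.data.shape[:3]:
            raise ValueError(
                f"mask shape {self.mask.shape} does not match spatial shape {self.data.shape[:3]}"
            )

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def voxel_size(self) -> np.ndarray:
        """Voxel edge lengths in mm, from the affine."""
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))


def load_bold(path: str | Path, mask: np.ndarray | None = None, tr: float | None = None) -> BoldImage:
    """Read a 4D NIfTI file into a :class:`BoldImage`.

    TR is taken from the header's temporal zoom unless overridden.  If no mask
    is supplied, all voxels are considered in-brain.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=np.float64)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected 4D image, got {data.ndim}D")
    if tr is None:
        zooms = img.header.get_zooms()
        tr = float(zooms[3]) if len(zooms) > 3 else 0.0
        if tr <= 0:
            raise ValueError(f"{path}: TR not present in header; pass tr explicitly")
    if mask is None:
        mask = np.ones(data.shape[:3], dtype=bool)
    return BoldImage(data=data, affine=img.affine, tr=float(tr), mask=mask)


def save_bold(bold: BoldImage, path: str | Path) -> None:
    """Write a :class:`BoldImage` as NIfTI-1 with TR recorded in the header."""
    img = nib.Nifti1Image(bold.data.astype(np.float32), bold.affine)
    zooms = list(img.header.get_zooms())
    zooms[3] = bold.tr
    img.header.set_zooms(zooms)
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))


def load_mask(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a 3D mask NIfTI; returns (bool array, affine)."""
    img = nib.load(str(path))
    return np.asanyarray(img.dataobj) > 0, img.affine


def save_volume(values: np.ndarray, affine: np.ndarray, path: str | Path) -> None:
    """Write a 3D (or labeled int) volume as NIfTI-1."""
    arr = np.asarray(values)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8)
    nib.save(nib.Nifti1Image(arr, affine), str(path))


REQUIRED_COVARIATE_COLUMNS = ("subject_id", "group", "age", "sex", "score")


def load_covariates(path: str | Path) -> pd.DataFrame:
    """Read the subject covariate table (CSV with a header row) and validate it."""
    table = pd.read_csv(path)
    return validate_covariates(table)


def validate_covariates(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COVARIATE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"covariate table missing columns: {missing}")
    if table["subject_id"].duplicated().any():
        dupes = table.loc[table["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValueError(f"duplicate subject ids: {dupes}")
    levels = sorted(table["group"].unique())
    if len(levels) != 2:
        raise ValueError(f"group must have exactly 2 levels, found {levels}")
    return table


def save_covariates(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def discard_initial_volumes(bold: BoldImage, n: int) -> BoldImage:
    """Drop the first ``n`` volumes (magnetization-equilibration discard)."""
    if n < 0:
        raise ValueError("n must be non-negative")
    if n >= bold.n_volumes:
        raise ValueError(f"cannot discard {n} volumes from a series of length {bold.n_volumes}")
    return replace(bold, data=bold.data[..., n:])


def polynomial_design(t: int, order: int) -> np.ndarray:
    """Orthonormal polynomial regressors (Legendre on [-1, 1]) up to ``order``."""
    x = np.linspace(-1.0, 1.0, t)
    cols = [np.polynomial.legendre.Legendre.basis(d)(x) for d in range(order + 1)]
    design = np.column_stack(cols)
    # orthonormalize for conditioning
    q, _ = np.linalg.qr(design)
    return q


def detrend(bold: BoldImage, order: int = 1) -> BoldImage:
    """Remove a least-squares polynomial of the given order from every voxel."""
    if order < 0:
        raise ValueError("order must be >= 0")
    t = bold.n_volumes
    if order >= t:
        raise ValueError(f"polynomial order {order} >= series length {t}")
    data2d = bold.data.reshape(-1, t)
    detrended = detrend_series(data2d.T, order).T
    return replace(bold, data=detrended.reshape(bold.data.shape))


def detrend_series(series: np.ndarray, order: int) -> np.ndarray:
    """Detrend columns of a (t, n) array; returns residuals of a polynomial fit."""
    series = np.asarray(series, dtype=np.float64)
    t = series.shape[0]
    design = polynomial_design(t, order)
    beta = design.T @ series
    return series - design @ beta


def regress_nuisance(bold: BoldImage, confounds: np.ndarray) -> BoldImage:
    """Project out an intercept plus the supplied confound columns per voxel.

    Residuals are orthogonal to every confound column.  A rank-deficient
    design is rejected with the indices of the collinear columns.
    """
    confounds = np.atleast_2d(np.asarray(confounds, dtype=np.float64))
    if confounds.shape[0] != bold.n_volumes:
        if confounds.shape[1] == bold.n_volumes:
            confounds = confounds.T
        else:
            raise ValueError(
                f"confounds have {confounds.shape[0]} rows, expected {bold.n_volumes}"
            )
    if confounds.shape[1] < 1:
        raise ValueError("need at least one confound column")
    t = bold.n_volumes
    design = np.column_stack([np.ones(t), confounds])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        bad = _collinear_columns(design)
        raise ValueError(f"rank-deficient nuisance design; collinear columns (0=intercept): {bad}")
    data2d = bold.data.reshape(-1, t).T  # (t, voxels)
    beta, *_ = np.linalg.lstsq(design, data2d, rcond=None)
    residual = data2d - design @ beta
    return replace(bold, data=residual.T.reshape(bold.data.shape))


def _collinear_columns(design: np.ndarray) -> list[int]:
    """Identify columns that do not increase design rank when added greedily."""
    bad = []
    kept = np.empty((design.shape[0], 0))
    for j in range(design.shape[1]):
        trial = np.column_stack([kept, design[:, j]])
        if np.linalg.matrix_rank(trial) == trial.shape[1]:
            kept = trial
        else:
            bad.append(j)
    return bad


def smooth(bold: BoldImage, fwhm_mm: float | tuple[float, float, float]) -> BoldImage:
    """Gaussian-smooth every volume with a per-axis FWHM given in mm.

    FWHM is converted to voxel-space sigma via the voxel size from the affine.
    Reflective boundary handling preserves flat fields at the edges.
    """
    fwhm = np.broadcast_to(np.asarray(fwhm_mm, dtype=np.float64), (3,)).copy()
    if np.any(fwhm < 0):
        raise ValueError(f"fwhm must be non-negative, got {fwhm_mm}")
    if np.all(fwhm == 0):
        return replace(bold, data=bold.data.copy())
    sigma_vox = fwhm * FWHM_TO_SIGMA / bold.voxel_size
    out = ndimage.gaussian_filter(
        bold.data, sigma=tuple(sigma_vox) + (0.0,), mode="reflect"
    )
    return replace(bold, data=out)


def run_preprocessing(
    bold: BoldImage,
    n_discard: int = 10,
    detrend_order: int = 1,
    confounds: np.ndarray | None = None,
    smooth_fwhm: float = 6.0,
) -> BoldImage:
    """Apply the fixed-order chain: discard -> detrend -> nuisance -> smooth."""
    out = discard_initial_volumes(bold, n_discard)
    out = detrend(out, detrend_order)
    if confounds is not None:
        out = regress_nuisance(out, confounds)
    out = smooth(out, smooth_fwhm)
    return out
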