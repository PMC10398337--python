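"""Static and sliding-window ALFF, and its coefficient-of-variation map.

ALFF is the mean of the one-sided amplitude spectrum over a low-frequency band
(default 0.01-0.08 Hz).  The dynamic variant slides a rectangular window along
the series, computes ALFF per window, and summarizes window-to-window
variability per voxel as CV = sample SD / mean.

Amplitude normalization is fixed so that a pure sinusoid of amplitude A
contributes A at its frequency bin, which makes analytic expectations exact in
tests; any consistent normalization cancels in the CV.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import BoldImage, detrend_series

__all__ = [
    "AlffMap",
    "WindowedAlffStack",
    "DalffMap",
    "band_bins",
    "amplitude_spectrum",
    "compute_alff",
    "n_windows",
    "compute_windowed_alff",
    "compute_dalff_cv",
    "standardize_map",
]

DEFAULT_BAND = (0.01, 0.08)


@dataclass
class AlffMap:
    """3D ALFF map with its frequency band; zero outside the mask."""

    values: np.ndarray
    band: tuple[float, float]
    standardized: bool = False


@dataclass
class WindowedAlffStack:
    """Windows x in-mask-voxels matrix of window-wise ALFF for one subject."""

    matrix: np.ndarray  # (W, V)
    window_length: int  # TR units
    step: int  # TR units
    tr: float
    band: tuple[float, float]
    mask: np.ndarray  # (x, y, z) bool, V = mask.sum()
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    @property
    def n_windows(self) -> int:
        return self.matrix.shape[0]


@dataclass
class DalffMap:
    """Per-voxel CV of windowed ALFF (dimensionless); zero-mean voxels flagged."""

    cv: np.ndarray  # 3D
    window_length: int
    step: int
    zero_mean_mask: np.ndarray | None = None  # in-mask voxels where mean == 0
    standardized: bool = False


def band_bins(t: int, tr: float, band: tuple[float, float]) -> np.ndarray:
    """Indices of DFT bins with band[0] <= f <= band[1] (inclusive both ends).

    Raises if the band is invalid for the sampling setup or contains no bin.
    """
    f_lo, f_hi = band
    nyquist = 1.0 / (2.0 * tr)
    if not (0 < f_lo < f_hi):
        raise ValueError(f"need 0 < f_lo < f_hi, got {band}")
    if f_hi > nyquist + 1e-12:
        raise ValueError(f"band {band} exceeds Nyquist {nyquist:.4g} Hz for tr={tr}")
    freqs = np.fft.rfftfreq(t, d=tr)
    idx = np.where((freqs >= f_lo - 1e-12) & (freqs <= f_hi + 1e-12))[0]
    if idx.size == 0:
        raise ValueError(
            f"no frequency bin inside {band} Hz for series length {t} at tr={tr}"
            f" (bin resolution {1.0 / (t * tr):.4g} Hz)"
        )
    return idx


def amplitude_spectrum(series: np.ndarray) -> np.ndarray:
    """One-sided amplitude spectrum along axis 0.

    Normalized so a pure sinusoid of amplitude A located exactly at a bin
    yields A at that bin (DC and the Nyquist bin, when present, are not
    doubled).
    """
    series = np.asarray(series, dtype=np.float64)
    t = series.shape[0]
    amp = np.abs(np.fft.rfft(series, axis=0)) / t
    scale = np.full(amp.shape[0], 2.0)
    scale[0] = 1.0
    if t % 2 == 0:
        scale[-1] = 1.0
    return amp * scale.reshape((-1,) + (1,) * (series.ndim - 1))


def compute_alff(
    series: np.ndarray,
    tr: float,
    band: tuple[float, float] = DEFAULT_BAND,
) -> np.ndarray | float:
    """Mean in-band amplitude of one or many series (time along axis 0).

    Requires at least 8 time points.  Returns a scalar for 1D input.
    """
    series = np.asarray(series, dtype=np.float64)
    t = series.shape[0]
    if t < 8:
        raise ValueError(f"series too short for spectral estimation (T={t} < 8)")
    idx = band_bins(t, tr, band)
    amp = amplitude_spectrum(series)
    out = amp[idx].mean(axis=0)
    return float(out) if out.ndim == 0 else out


def n_windows(t: int, window_length: int, step: int) -> int:
    """W = floor((T - w)/s) + 1."""
    if window_length > t:
        raise ValueError(f"window length {window_length} exceeds series length {t}")
    if step < 1:
        raise ValueError("step must be >= 1")
    return (t - window_length) // step + 1


def compute_windowed_alff(
    bold: BoldImage,
    window_length: int,
    step: int = 1,
    band: tuple[float, float] = DEFAULT_BAND,
    within_window_detrend: bool = False,
) -> WindowedAlffStack:
    """Sliding-window ALFF: window i covers volumes [i*step, i*step + w).

    Detrending happens once on the full series during preprocessing; windows
    are not re-detrended by default, which keeps the windowed ALFF of a
    stationary signal exactly constant.  ``within_window_detrend=True``
    additionally removes a linear fit from every window segment (note this
    makes the removed component phase-dependent, so even a stationary
    sinusoid then shows small window-to-window variation).
    """
    t = bold.n_volumes
    w = int(window_length)
    s = int(step)
    nwin = n_windows(t, w, s)
    band_bins(w, bold.tr, band)  # validate the band is resolvable at window length
    series = bold.data[bold.mask].T  # (t, V)
    rows = np.empty((nwin, series.shape[1]), dtype=np.float64)
    for i in range(nwin):
        seg = series[i * s : i * s + w]
        if within_window_detrend:
            seg = detrend_series(seg, order=1)
        rows[i] = compute_alff(seg, bold.tr, band)
    return WindowedAlffStack(
        matrix=rows,
        window_length=w,
        step=s,
        tr=bold.tr,
        band=band,
        mask=bold.mask,
        affine=bold.affine,
    )


def compute_dalff_cv(stack: WindowedAlffStack) -> DalffMap:
    """CV across windows per voxel: sample SD (ddof=1) divided by the mean.

    Voxels with zero across-window mean get CV = 0 and are flagged rather
    than raising a division error.
    """
    if stack.n_windows < 2:
        raise ValueError("need at least 2 windows to compute a CV")
    mean = stack.matrix.mean(axis=0)
    sd = stack.matrix.std(axis=0, ddof=1)
    zero = mean == 0
    cv_flat = np.zeros_like(mean)
    np.divide(sd, mean, out=cv_flat, where=~zero)
    cv = np.zeros(stack.mask.shape, dtype=np.float64)
    cv[stack.mask] = cv_flat
    return DalffMap(
        cv=cv,
        window_length=stack.window_length,
        step=stack.step,
        zero_mean_mask=zero,
    )


def standardize_map(values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Z-transform a 3D map within the mask; out-of-mask voxels set to 0."""
    mask = np.asarray(mask, dtype=bool)
    inside = np.asarray(values, dtype=np.float64)[mask]
    if inside.size < 2:
        raise ValueError("need at least 2 in-mask voxels to standardize")
    sd = inside.std(ddof=1)
    if sd == 0:
        raise ValueError("cannot standardize a map with zero within-mask SD")
    out = np.zeros_like(np.asarray(values, dtype=np.float64))
    out[mask] = (inside - inside.mean()) / sd
    return out
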