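"""In-scope BOLD preprocessing: volume dropping, detrend, nuisance
regression, temporal band-pass, Gaussian smoothing.

The canonical order for this pipeline is drop -> detrend -> nuisance ->
band-pass; series feeding degree centrality are NOT spatially smoothed
(the DC z-map is smoothed afterwards instead), while series feeding
seed-based connectivity are smoothed before correlation.

The band-pass is a zero-phase forward-backward Butterworth (order 5),
chosen because zero-phase filtering preserves inter-voxel correlation
structure; smoothing uses reflect-mode boundary handling so constant maps
stay constant on small grids.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from scipy import signal as sps

from .errors import InputError
from .images import BoldSeries, voxel_sizes_mm

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def drop_initial_volumes(series: BoldSeries, n_drop: int) -> BoldSeries:
    """Remove the first ``n_drop`` frames (magnetization-settling volumes)."""
    if n_drop < 0:
        raise InputError(f"n_drop must be >= 0, got {n_drop}")
    if n_drop >= series.n_timepoints:
        raise InputError(
            f"n_drop={n_drop} would leave no data (series has {series.n_timepoints} frames)"
        )
    return series.with_data(series.data[..., n_drop:].copy())


def detrend_linear(series: BoldSeries) -> BoldSeries:
    """Remove a per-voxel least-squares line (intercept + slope).

    Output voxel means are exactly 0 up to round-off.
    """
    t = series.n_timepoints
    if t < 3:
        raise InputError(f"detrending needs >= 3 timepoints, got {t}")
    flat = series.data.reshape(-1, t)
    design = np.c_[np.ones(t), np.arange(t, dtype=float)]
    beta, *_ = np.linalg.lstsq(design, flat.T, rcond=None)
    resid = flat - (design @ beta).T
    return series.with_data(resid.reshape(series.data.shape))


def regress_nuisance(series: BoldSeries, regressors: np.ndarray | None) -> BoldSeries:
    """Residualize every voxel on [intercept | nuisance regressors].

    An empty regressor set therefore mean-centers the series.
    """
    t = series.n_timepoints
    if regressors is None or (hasattr(regressors, "size") and np.size(regressors) == 0):
        design = np.ones((t, 1))
        names = ["intercept"]
    else:
        regressors = np.asarray(regressors, dtype=np.float64)
        if regressors.ndim == 1:
            regressors = regressors[:, None]
        if regressors.shape[0] != t:
            raise InputError(
                f"nuisance rows ({regressors.shape[0]}) must match series length ({t})"
            )
        design = np.c_[np.ones(t), regressors]
        names = ["intercept"] + [f"nuisance_{j}" for j in range(regressors.shape[1])]
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        bad = _collinear_columns(design, names)
        raise InputError(f"nuisance design is rank deficient; collinear columns: {bad}")
    flat = series.data.reshape(-1, t)
    beta, *_ = np.linalg.lstsq(design, flat.T, rcond=None)
    resid = flat - (design @ beta).T
    return series.with_data(resid.reshape(series.data.shape))


def _collinear_columns(design: np.ndarray, names: list[str]) -> list[str]:
    """Name the pivot columns a rank-revealing QR flags as dependent."""
    from scipy.linalg import qr

    _, r, piv = qr(design, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(design.shape) * np.finfo(float).eps
    return [names[piv[i]] for i in range(len(diag)) if diag[i] <= tol] or names


def bandpass(series: BoldSeries, low_hz: float, high_hz: float, order: int = 5) -> BoldSeries:
    """Zero-phase Butterworth band-pass, per voxel, along time.

    ``low_hz = 0`` degrades gracefully to a low-pass.  Output length equals
    input length (forward-backward filtering, odd-reflect padding).
    """
    nyquist = 0.5 / series.tr
    if not (0 <= low_hz < high_hz):
        raise InputError(f"band must satisfy 0 <= low < high, got ({low_hz}, {high_hz})")
    if high_hz > nyquist:
        raise InputError(f"high edge {high_hz} Hz exceeds Nyquist {nyquist} Hz (TR={series.tr}s)")
    fs = 1.0 / series.tr
    if low_hz == 0:
        sos = sps.butter(order, high_hz, btype="lowpass", output="sos", fs=fs)
    else:
        sos = sps.butter(order, [low_hz, high_hz], btype="bandpass", output="sos", fs=fs)
    # sosfiltfilt needs more than padlen frames
    padlen = 3 * (2 * sos.shape[0] + 1 - min((sos[:, 2] == 0).sum(), (sos[:, 5] == 0).sum()))
    if series.n_timepoints <= padlen:
        raise InputError(
            f"series too short for zero-phase filtering: {series.n_timepoints} frames <= padlen {padlen}"
        )
    out = sps.sosfiltfilt(sos, series.data, axis=-1)
    return series.with_data(np.ascontiguousarray(out))


def smooth_gaussian(data: np.ndarray, fwhm_mm: float, affine: np.ndarray) -> np.ndarray:
    """Spatial Gaussian smoothing with a kernel specified by FWHM in mm.

    sigma per axis = fwhm / (2 * sqrt(2 ln 2)) divided by the voxel size on
    that axis; 4D input is smoothed frame-wise (no temporal blurring).
    Reflect-mode boundaries keep constant inputs constant.
    """
    if fwhm_mm < 0:
        raise InputError(f"fwhm_mm must be >= 0, got {fwhm_mm}")
    data = np.asarray(data, dtype=np.float64)
    if fwhm_mm == 0:
        return data.copy()
    sizes = voxel_sizes_mm(affine)
    sigma_vox = (fwhm_mm * FWHM_TO_SIGMA) / sizes
    if data.ndim == 3:
        return ndimage.gaussian_filter(data, sigma=sigma_vox, mode="reflect")
    if data.ndim == 4:
        sigma = tuple(sigma_vox) + (0.0,)
        return ndimage.gaussian_filter(data, sigma=sigma, mode="reflect")
    raise InputError(f"smooth_gaussian expects 3D or 4D data, got ndim={data.ndim}")


def smooth_series(series: BoldSeries, fwhm_mm: float) -> BoldSeries:
    return series.with_data(smooth_gaussian(series.data, fwhm_mm, series.affine))


def preprocess(series: BoldSeries, *, n_drop: int = 10,
               nuisance: np.ndarray | None = None,
               band: tuple[float, float] = (0.01, 0.08),
               fwhm_mm: float = 0.0) -> BoldSeries:
    """Apply the full chain drop -> detrend -> nuisance -> band-pass
    (-> optional spatial smoothing, for connectivity inputs only)."""
    out = drop_initial_volumes(series, n_drop)
    out = detrend_linear(out)
    nuis = None if nuisance is None else np.asarray(nuisance)[n_drop:]
    out = regress_nuisance(out, nuis)
    out = bandpass(out, band[0], band[1])
    if fwhm_mm > 0:
        out = smooth_series(out, fwhm_mm)
    return out
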