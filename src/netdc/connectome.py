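"""Voxel-wise binarized degree centrality and seed-based functional
connectivity.

Degree centrality (DC) of an in-mask voxel is the number of *other*
in-mask voxels whose time-series Pearson correlation with it exceeds the
threshold (default r > 0.25, strict inequality, positive correlations
only).  The DC map is then standardized against the gray-matter
distribution (population-SD convention, divide by n) to a z-score map,
which is what group statistics and MVPA consume.

Seed-based functional connectivity correlates the unweighted mean seed
time series with every gray-matter voxel and applies Fisher's r-to-z
(atanh) transform; |r| = 1 is clipped to 1 - 1e-7 to keep maps finite.

The pairwise correlation is computed blockwise on standardized series, so
memory stays linear in the number of voxels while results match a
brute-force per-pair oracle to round-off.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InputError
from .images import BoldSeries, VolumeMap, check_same_grid

FISHER_CLIP = 1.0 - 1e-7


@dataclass
class SeedSpec:
    """A named seed region: boolean voxel mask + label (e.g. ``HIP.L``)."""

    mask: np.ndarray
    label: str = "seed"
    source: str = "explicit"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise InputError(f"seed '{self.label}' is empty")


def _masked_timeseries(series: BoldSeries, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Extract the (V, T) in-mask series matrix and flat voxel indices.

    Voxel order is the C scan order of the mask — the deterministic
    ordering shared with the MVPA feature matrix.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != series.grid_shape:
        raise InputError(
            f"mask shape {mask.shape} does not match series grid {series.grid_shape}"
        )
    flat_idx = np.flatnonzero(mask.ravel())
    data = series.data.reshape(-1, series.n_timepoints)[flat_idx]
    return data, flat_idx


def _standardize_rows(data: np.ndarray) -> np.ndarray:
    """Center rows and scale to unit norm so dot products are Pearson r."""
    centered = data - data.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered**2).sum(axis=1))
    bad = np.flatnonzero(norms == 0)
    if bad.size:
        raise InputError(
            f"zero-variance in-mask voxel(s); correlation undefined at voxel indices {bad.tolist()}"
        )
    return centered / norms[:, None]


def degree_centrality(series: BoldSeries, mask: np.ndarray, r_threshold: float = 0.25,
                      *, use_absolute: bool = False, weighted: bool = False,
                      block_size: int = 512) -> VolumeMap:
    """Binarized degree-centrality map.

    Parameters
    ----------
    series:
        Preprocessed (unsmoothed) BOLD series.
    mask:
        Gray-matter analysis mask; DC is defined over in-mask voxels only.
    r_threshold:
        Correlation threshold; a connection is counted when
        ``r > r_threshold`` (strict).  Positive-only by default.
    use_absolute:
        Count ``|r| > r_threshold`` instead (non-default convention).
    weighted:
        Sum supra-threshold r values instead of counting them
        (non-default; the default is the binary degree).
    block_size:
        Rows per correlation block; affects memory only — block results
        are bitwise reductions of the same standardized dot products, so
        the map equals the brute-force pairwise oracle.
    """
    if series.n_timepoints < 3:
        raise InputError(f"DC needs >= 3 timepoints, got {series.n_timepoints}")
    data, flat_idx = _masked_timeseries(series, mask)
    z = _standardize_rows(data)
    n_vox = z.shape[0]
    dc = np.zeros(n_vox)
    for start in range(0, n_vox, block_size):
        stop = min(start + block_size, n_vox)
        corr = z[start:stop] @ z.T                       # (b, V) Pearson r
        r_eff = np.abs(corr) if use_absolute else corr
        supra = r_eff > r_threshold
        if weighted:
            vals = np.where(supra, r_eff, 0.0)
            block = vals.sum(axis=1)
            # remove self-connection contribution (r == 1 on the diagonal)
            diag = np.arange(start, stop)
            block -= np.where(supra[np.arange(stop - start), diag],
                              r_eff[np.arange(stop - start), diag], 0.0)
        else:
            block = supra.sum(axis=1).astype(float)
            diag = np.arange(start, stop)
            block -= supra[np.arange(stop - start), diag]
        dc[start:stop] = block

    out = np.full(series.grid_shape, np.nan)
    out.ravel()[flat_idx] = dc
    return VolumeMap(data=out, affine=series.affine.copy(), kind="dc_count")


def degree_centrality_bruteforce(series: BoldSeries, mask: np.ndarray,
                                 r_threshold: float = 0.25) -> VolumeMap:
    """O(V^2) double-loop reference DC (np.corrcoef per pair).

    Independent oracle for :func:`degree_centrality`; intended for tiny
    instances only.
    """
    data, flat_idx = _masked_timeseries(series, mask)
    _standardize_rows(data)  # same zero-variance policy as the fast path
    n_vox = data.shape[0]
    dc = np.zeros(n_vox)
    for i in range(n_vox):
        count = 0
        for j in range(n_vox):
            if j == i:
                continue
            r = np.corrcoef(data[i], data[j])[0, 1]
            if r > r_threshold:
                count += 1
        dc[i] = count
    out = np.full(series.grid_shape, np.nan)
    out.ravel()[flat_idx] = dc
    return VolumeMap(data=out, affine=series.affine.copy(), kind="dc_count")


def zscore_map(vmap: VolumeMap, mask: np.ndarray) -> VolumeMap:
    """Standardize a map against its in-mask distribution.

    z(i) = (v(i) - mean_mask) / sd_mask with the population SD convention
    (divide by n): the map is a normalization, not an inference.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != vmap.grid_shape:
        raise InputError("mask shape does not match map grid")
    vals = vmap.data[mask]
    if vals.size < 2:
        raise InputError("z-scoring needs >= 2 in-mask voxels")
    if np.isnan(vals).any():
        raise InputError("NaN inside mask; cannot z-score")
    sd = vals.std()  # ddof=0: population convention
    if sd == 0:
        raise InputError("degenerate map: zero in-mask standard deviation")
    out = np.full(vmap.grid_shape, np.nan)
    out[mask] = (vals - vals.mean()) / sd
    return VolumeMap(data=out, affine=vmap.affine.copy(), kind="dc_z",
                     mask_ref=vmap.mask_ref)


def seed_mean_timeseries(series: BoldSeries, seed: SeedSpec) -> np.ndarray:
    """Unweighted mean time series across the seed voxels."""
    data, _ = _masked_timeseries(series, seed.mask)
    return data.mean(axis=0)


def seed_fc_map(series: BoldSeries, seed: SeedSpec, mask: np.ndarray) -> VolumeMap:
    """Fisher-z seed-to-voxel connectivity map.

    Seed voxels are included in the output (their r with the seed *mean*
    series is generally < 1 and carries information).
    """
    seed_mask = np.asarray(seed.mask, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    check_same_grid(series, (seed_mask.shape, series.affine), (mask.shape, series.affine))
    if (seed_mask & ~mask).any():
        raise InputError(f"seed '{seed.label}' extends outside the analysis mask")
    ref = seed_mean_timeseries(series, seed)
    if ref.std() == 0:
        raise InputError(f"seed '{seed.label}' mean series has zero variance")
    data, flat_idx = _masked_timeseries(series, mask)
    z = _standardize_rows(data)
    ref_c = ref - ref.mean()
    ref_z = ref_c / np.sqrt((ref_c**2).sum())
    r = z @ ref_z
    r = np.clip(r, -FISHER_CLIP, FISHER_CLIP)
    fz = np.arctanh(r)
    out = np.full(series.grid_shape, np.nan)
    out.ravel()[flat_idx] = fz
    return VolumeMap(data=out, affine=series.affine.copy(), kind="fc_z")
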