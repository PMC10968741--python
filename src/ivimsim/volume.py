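"""Volume-side computations on 4D diffusion-weighted data.

Covers the per-voxel SNR map from repeated b0 volumes (mean/std quotient),
ROI-averaged fitting with per-voxel max normalization, whole-volume
per-voxel fitting, and the range/outlier classification of perfusion-
fraction and pseudo-diffusion maps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .estimators import (
    FitBounds,
    GridSpec,
    SPLIT_THRESHOLD,
    fit_curve_segmented,
    fit_grid_segmented_batch,
    fit_onestep,
)
from .model import AcquisitionScheme

__all__ = [
    "DWIVolume",
    "SNRSummary",
    "ClassificationReport",
    "ParameterMaps",
    "snr_map",
    "roi_average_signal",
    "fit_volume",
    "classify_estimates",
]


@dataclass
class DWIVolume:
    """A 4D diffusion-weighted volume with its acquisition scheme.

    The 4th axis is in the scheme's canonical order (ascending b, repeats
    contiguous).  Spatial meaning is carried solely by the affine; voxel
    coordinates are 0-based array indices.
    """

    data: np.ndarray
    scheme: AcquisitionScheme
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"data must be 4-D, got shape {self.data.shape}")
        if self.data.shape[3] != self.scheme.total_measurements:
            raise ValueError(
                f"4th-axis length {self.data.shape[3]} does not match "
                f"scheme.total_measurements {self.scheme.total_measurements}"
            )
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.data.shape[:3]:
                raise ValueError(
                    f"mask shape {self.mask.shape} does not match spatial shape "
                    f"{self.data.shape[:3]}"
                )

    @property
    def spatial_shape(self) -> tuple:
        return self.data.shape[:3]

    def effective_mask(self) -> np.ndarray:
        if self.mask is not None:
            return self.mask
        return np.ones(self.spatial_shape, dtype=bool)


@dataclass
class SNRSummary:
    """Per-voxel SNR map plus summary statistics over the mask.

    Voxels whose repeated-b0 standard deviation is zero have undefined SNR
    and are NaN in the map and excluded from the summaries.
    """

    map: np.ndarray
    average: float
    median: float
    minimum: float
    maximum: float
    n_voxels: int


def snr_map(volume: DWIVolume, ddof: int = 1) -> SNRSummary:
    """SNR = mean / sample std of the repeated b0 measurements, per voxel.

    Requires at least two b0 volumes.  `ddof=1` (the n-1 denominator) is the
    default sample standard deviation; with only 5 b0 scans the choice is
    material, so it is exposed.
    """
    b = volume.scheme.b_values
    b0_idx = np.flatnonzero(b == 0.0)
    if b0_idx.size < 2:
        raise ValueError(f"need >= 2 b0 volumes to estimate SNR, found {b0_idx.size}")
    b0 = volume.data[..., b0_idx]
    mean = b0.mean(axis=-1)
    std = b0.std(axis=-1, ddof=ddof)
    with np.errstate(divide="ignore", invalid="ignore"):
        snr = np.where(std > 0, mean / np.where(std > 0, std, 1.0), np.nan)
    mask = volume.effective_mask()
    valid = mask & np.isfinite(snr)
    n = int(valid.sum())
    if n == 0:
        warnings.warn("no voxels with nonzero b0 variance inside the mask; SNR undefined")
        nan = float("nan")
        return SNRSummary(map=snr, average=nan, median=nan, minimum=nan, maximum=nan, n_voxels=0)
    vals = snr[valid]
    return SNRSummary(
        map=snr,
        average=float(vals.mean()),
        median=float(np.median(vals)),
        minimum=float(vals.min()),
        maximum=float(vals.max()),
        n_voxels=n,
    )


def roi_average_signal(volume: DWIVolume, labels: np.ndarray, roi_id: int) -> np.ndarray:
    """ROI signal: per-voxel max normalization, then the voxel-wise average.

    Each ROI voxel's measurement vector is divided by that voxel's maximum
    across measurements (making the output invariant to per-voxel positive
    rescaling), then averaged over the ROI.
    """
    labels = np.asarray(labels)
    if labels.shape != volume.spatial_shape:
        raise ValueError(
            f"label map shape {labels.shape} does not match volume spatial shape "
            f"{volume.spatial_shape}"
        )
    sel = (labels == roi_id) & volume.effective_mask()
    if not sel.any():
        raise ValueError(f"ROI {roi_id} is empty within the mask")
    vox = volume.data[sel]  # (n_vox, n_meas)
    peak = vox.max(axis=1, keepdims=True)
    if np.any(peak <= 0):
        raise ValueError(f"ROI {roi_id} contains voxels with non-positive signal")
    return (vox / peak).mean(axis=0)


@dataclass
class ParameterMaps:
    """Per-voxel IVIM parameter maps plus fit-diagnostic maps.

    `maps` holds 3-D float arrays keyed by 's0', 'f', 'd_star', 'd',
    'converged' and 'boundary_<param>'; unmasked voxels carry NaN.
    """

    maps: dict
    affine: np.ndarray
    method: str


def fit_volume(
    volume: DWIVolume,
    method: str = "grid_search",
    grids: GridSpec | None = None,
    bounds: FitBounds | None = None,
    threshold: float = SPLIT_THRESHOLD,
) -> ParameterMaps:
    """Fit every masked voxel independently after per-voxel max normalization.

    Unmasked voxels are set to NaN in every output map.  Voxel-level fit
    failures are flagged (converged map), never fatal.
    """
    mask = volume.effective_mask()
    vox = volume.data[mask]  # (n_vox, n_meas)
    peak = vox.max(axis=1, keepdims=True)
    bad = (peak <= 0).ravel()
    safe_peak = np.where(peak > 0, peak, 1.0)
    norm = vox / safe_peak

    n = norm.shape[0]
    params = {p: np.full(n, np.nan) for p in ("s0", "f", "d_star", "d")}
    flags = {p: np.zeros(n, dtype=bool) for p in ("s0", "f", "d_star", "d")}
    converged = np.zeros(n, dtype=bool)

    if method == "grid_search":
        out = fit_grid_segmented_batch(norm, volume.scheme, grids, threshold)
        for p in params:
            params[p] = out[p].astype(float)
            flags[p] = out[f"boundary_{p}"]
        converged[:] = True
    elif method in ("segmented", "one_step"):
        fit = (
            (lambda row: fit_curve_segmented(row, volume.scheme, bounds, threshold))
            if method == "segmented"
            else (lambda row: fit_onestep(row, volume.scheme, bounds))
        )
        for i in range(n):
            if bad[i]:
                continue
            try:
                r = fit(norm[i])
            except Exception:
                continue
            params["s0"][i] = r.params.s0
            params["f"][i] = r.params.f
            params["d_star"][i] = r.params.d_star
            params["d"][i] = r.params.d
            for p in flags:
                flags[p][i] = r.boundary_flags[p]
            converged[i] = r.converged
    else:
        raise ValueError(f"unknown method {method!r}")

    for arr in params.values():
        arr[bad] = np.nan
    converged[bad] = False

    maps = {}
    for p, arr in params.items():
        full = np.full(volume.spatial_shape, np.nan)
        full[mask] = arr
        maps[p] = full
    conv = np.full(volume.spatial_shape, np.nan)
    conv[mask] = converged.astype(float)
    maps["converged"] = conv
    for p, arr in flags.items():
        full = np.full(volume.spatial_shape, np.nan)
        full[mask] = arr.astype(float)
        maps[f"boundary_{p}"] = full
    return ParameterMaps(maps=maps, affine=volume.affine, method=method)


@dataclass
class ClassificationReport:
    """Composition of perfusion-fraction and pseudo-diffusion estimate maps.

    Interval semantics: the f range is closed ([low, high]); the D* range is
    half-open ([low, high)).  "Near-zero" f outliers are those below the
    lower edge of the f inclusion range.
    """

    n_total: int
    n_f_outliers: int
    pct_f_outliers: float
    pct_f_in_range: float
    pct_dstar_in_range: float
    n_boundary_dstar: int

    def as_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_f_outliers": self.n_f_outliers,
            "pct_f_outliers": self.pct_f_outliers,
            "pct_f_in_range": self.pct_f_in_range,
            "pct_dstar_in_range": self.pct_dstar_in_range,
            "n_boundary_dstar": self.n_boundary_dstar,
        }


def classify_estimates(
    f_map: np.ndarray,
    dstar_map: np.ndarray,
    mask: np.ndarray | None = None,
    f_range: tuple = (0.02, 0.25),
    dstar_range: tuple = (0.006, 0.05),
    dstar_bounds: tuple | None = None,
) -> ClassificationReport:
    """Classify per-voxel estimates by the study's range rules.

    - f in-range uses the closed interval ``[f_range[0], f_range[1]]``;
    - D* in-range uses the half-open interval ``[dstar_range[0], dstar_range[1])``;
    - f outliers are "near zero": ``f < f_range[0]``;
    - `dstar_bounds`, when given, counts D* estimates sitting exactly at the
      configured search bounds.
    """
    f_map = np.asarray(f_map, dtype=float)
    dstar_map = np.asarray(dstar_map, dtype=float)
    if f_map.shape != dstar_map.shape:
        raise ValueError(f"map shapes differ: {f_map.shape} vs {dstar_map.shape}")
    if mask is None:
        mask = np.isfinite(f_map) & np.isfinite(dstar_map)
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != f_map.shape:
            raise ValueError(f"mask shape {mask.shape} does not match maps {f_map.shape}")
        mask = mask & np.isfinite(f_map) & np.isfinite(dstar_map)
    f = f_map[mask]
    ds = dstar_map[mask]
    n = f.size
    if n == 0:
        raise ValueError("no valid voxels to classify")
    f_low, f_high = f_range
    ds_low, ds_high = dstar_range
    n_out = int((f < f_low).sum())
    n_f_in = int(((f >= f_low) & (f <= f_high)).sum())
    n_ds_in = int(((ds >= ds_low) & (ds < ds_high)).sum())
    n_bnd = 0
    if dstar_bounds is not None:
        lo, hi = dstar_bounds
        n_bnd = int((np.isclose(ds, lo) | np.isclose(ds, hi)).sum())
    return ClassificationReport(
        n_total=n,
        n_f_outliers=n_out,
        pct_f_outliers=100.0 * n_out / n,
        pct_f_in_range=100.0 * n_f_in / n,
        pct_dstar_in_range=100.0 * n_ds_in / n,
        n_boundary_dstar=n_bnd,
    )
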