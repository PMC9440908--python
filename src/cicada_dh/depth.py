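"""Dorsal-surface detection from a structural z-stack and ROI depth assignment.

The dorsal horn surface is curved, so cell depth cannot be read off the
optical plane alone.  A high-z-resolution structural volume (acquired under
KCl so every GCaMP cell is bright) is median-filtered, contrast-equalized,
and averaged into 10x10-pixel XY columns; each column's z-profile rises
sigmoidally where the tissue surface comes into focus, and the surface is
taken as the first z where the profile exceeds half of its deep plateau.
ROI depth is then the ROI's absolute plane z minus the local surface z.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, optimize
from skimage import exposure

from .errors import ConfigError, SurfaceError


@dataclass
class SurfaceMap:
    """Per-column surface estimates for the structural volume.

    ``z_um`` holds the estimated surface depth of each 10x10-pixel XY
    column (NaN where the column had no usable contrast); ``quality`` is
    the plateau-to-background contrast of the column profile.
    """

    z_um: np.ndarray  # (ny_cols, nx_cols)
    quality: np.ndarray
    column_xy: int
    z_step_um: float

    @property
    def shape(self) -> tuple[int, int]:
        return self.z_um.shape

    def column_of(self, x_px: float, y_px: float) -> tuple[int, int]:
        """Column indices (row, col) for a pixel position."""
        return int(y_px) // self.column_xy, int(x_px) // self.column_xy


def _column_profiles(volume: np.ndarray, column_xy: int) -> np.ndarray:
    """Average the volume into (nz, ny_cols, nx_cols) column profiles."""
    nz, ny, nx = volume.shape
    ny_c = -(-ny // column_xy)
    nx_c = -(-nx // column_xy)
    out = np.empty((nz, ny_c, nx_c))
    for iy in range(ny_c):
        ys = slice(iy * column_xy, min((iy + 1) * column_xy, ny))
        for ix in range(nx_c):
            xs = slice(ix * column_xy, min((ix + 1) * column_xy, nx))
            out[:, iy, ix] = volume[:, ys, xs].mean(axis=(1, 2))
    return out


def _logistic(z, lo, hi, z0, width):
    return lo + (hi - lo) / (1.0 + np.exp(-(z - z0) / width))


def _surface_z(profile: np.ndarray, method: str) -> tuple[float, float]:
    """Estimate (surface_z_index, quality) from one column z-profile.

    The plateau is the mean of the deepest quartile of slices, the
    background the mean of the shallowest quartile; quality is their
    difference.  ``halfmax`` takes the first z whose intensity exceeds
    half the plateau (sub-step refined by linear interpolation);
    ``logistic`` fits a 4-parameter sigmoid and reports its midpoint.
    """
    nz = profile.size
    q = max(nz // 4, 1)
    plateau = float(profile[-q:].mean())
    background = float(profile[:q].mean())
    quality = plateau - background
    if method == "logistic":
        z = np.arange(nz, dtype=float)
        try:
            popt, _ = optimize.curve_fit(
                _logistic,
                z,
                profile,
                p0=[background, plateau, nz / 2.0, 1.0],
                maxfev=2000,
            )
            return float(np.clip(popt[2], 0, nz - 1)), quality
        except RuntimeError:
            pass  # fall through to half-max
    thresh = 0.5 * plateau
    above = profile >= thresh
    if not above.any():
        return float("nan"), quality
    i = int(np.argmax(above))
    if i == 0:
        return 0.0, quality
    # linear interpolation between the bracketing slices
    lo, hi = profile[i - 1], profile[i]
    frac = (thresh - lo) / (hi - lo) if hi > lo else 0.0
    return float(i - 1 + frac), quality


def detect_surface(
    volume: np.ndarray,
    median_size: int = 3,
    clahe_clip: Optional[float] = 0.01,
    clahe_kernel: int = 32,
    column_xy: int = 10,
    z_step_um: float = 1.0,
    min_quality: float = 0.05,
    method: str = "halfmax",
) -> SurfaceMap:
    """Estimate the dorsal grey-matter surface from a (z, y, x) volume.

    Pipeline: 3-D median filter -> per-slice CLAHE (skipped for slices with
    no dynamic range) -> 10x10x1 column averaging -> per-column half-plateau
    crossing (or logistic fit).  Columns whose plateau-to-background
    contrast falls below ``min_quality`` (on the [0, 1] normalized scale)
    are marked missing with quality 0.

    Raises
    ------
    SurfaceError
        If no column yields a usable estimate (e.g. a uniform dark volume).
    """
    vol = np.asarray(volume, dtype=float)
    if vol.ndim != 3:
        raise ConfigError("volume must be a 3-D (z, y, x) stack")
    if vol.shape[0] < 10:
        raise ConfigError("volume needs at least 10 z-slices spanning the surface")
    if median_size > 1:
        vol = ndimage.median_filter(vol, size=median_size)
    vmin, vmax = vol.min(), vol.max()
    if vmax > vmin:
        vol = (vol - vmin) / (vmax - vmin)
    else:
        vol = np.zeros_like(vol)
    if clahe_clip and vol.max() > vol.min():
        # volumetric CLAHE with a full-depth z kernel: each tile spans the
        # whole z-profile, so slices above the surface stay dark relative
        # to the plateau (slice-wise CLAHE would stretch noise-only slices
        # to mid-gray and erase the rise the surface fit depends on)
        kernel = min(clahe_kernel, min(vol.shape[1], vol.shape[2]))
        vol = exposure.equalize_adapthist(
            vol, kernel_size=(vol.shape[0], kernel, kernel), clip_limit=clahe_clip
        )
    profiles = _column_profiles(vol, column_xy)
    ny_c, nx_c = profiles.shape[1:]
    z_um = np.full((ny_c, nx_c), np.nan)
    quality = np.zeros((ny_c, nx_c))
    for iy in range(ny_c):
        for ix in range(nx_c):
            z_idx, q = _surface_z(profiles[:, iy, ix], method)
            if q < min_quality or not np.isfinite(z_idx):
                quality[iy, ix] = 0.0
                continue
            z_um[iy, ix] = z_idx * z_step_um
            quality[iy, ix] = q
    if not np.isfinite(z_um).any():
        raise SurfaceError("no column produced a usable surface estimate")
    return SurfaceMap(z_um=z_um, quality=quality, column_xy=column_xy, z_step_um=z_step_um)


def surface_table(surface: SurfaceMap) -> pd.DataFrame:
    """Flatten a SurfaceMap to a tidy (col_x, col_y, z_um, quality) table."""
    ny, nx = surface.shape
    iy, ix = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    return pd.DataFrame(
        {
            "col_y": iy.ravel(),
            "col_x": ix.ravel(),
            "z_um": surface.z_um.ravel(),
            "quality": surface.quality.ravel(),
        }
    )


def assign_depth(
    rois: pd.DataFrame,
    surface: SurfaceMap,
    plane_offsets_um: Sequence[float] = (0.0, 14.0, 28.0),
    plane_z0_um: float = 0.0,
) -> pd.DataFrame:
    """Depth below the local surface for each ROI.

    ``depth_um = plane_z0_um + plane_offsets_um[plane_index] - surface_z``
    at the ROI's 10x10 column.  Negative depths (ROI above the detected
    surface) are kept but flagged ``above_surface``; ROIs over columns with
    no surface estimate get NaN and ``missing_surface``.
    """
    offsets = np.asarray(plane_offsets_um, dtype=float)
    depths = np.full(len(rois), np.nan)
    flags = np.array(["ok"] * len(rois), dtype=object)
    ny, nx = surface.shape
    for i, roi in enumerate(rois.itertuples(index=False)):
        plane = int(roi.plane_index)
        if plane < 0 or plane >= offsets.size:
            raise ConfigError(f"plane_index {plane} has no configured z offset")
        cy, cx = surface.column_of(roi.x_px, roi.y_px)
        cy, cx = min(cy, ny - 1), min(cx, nx - 1)
        z_surf = surface.z_um[cy, cx]
        if not np.isfinite(z_surf):
            flags[i] = "missing_surface"
            continue
        d = plane_z0_um + offsets[plane] - z_surf
        depths[i] = d
        if d < 0:
            flags[i] = "above_surface"
    out = rois.copy()
    out["depth_um"] = depths
    out["depth_flag"] = flags
    return out
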