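"""TMA dearraying: locate the core grid, label cores, flag invalid ones.

Tissue is detected by thresholding total optical density; candidate cores
are tissue blobs of roughly core size whose centres are clustered into
rows and columns; a complete regular grid is then fitted by least squares
so blank or missing positions still receive a labelled grid cell. Each
core's tissue fraction is measured inside a disc scaled by the bounds
factor, and the core is valid when that fraction (as a percent) reaches
the density threshold. Manual overrides reproduce the interactive
adjust/invalidate step in a scriptable way.

Grid labels run A1 (top-left) to I18 for the default 9x18 layout: row
letters top-to-bottom, column numbers left-to-right.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from skimage import morphology

from .stain_tools import DEFAULT_BACKGROUND, rgb_to_od
from .synthetic_tma import core_label

__all__ = [
    "CoreRegion",
    "TMAGrid",
    "tissue_mask",
    "dearray",
    "adjust_core",
    "apply_overrides",
    "assign_cells_to_cores",
]


@dataclass(frozen=True)
class CoreRegion:
    label: str
    x_um: float
    y_um: float
    diameter_um: float
    valid: bool
    tissue_fraction: float
    manually_adjusted: bool = False


@dataclass
class TMAGrid:
    rows: int
    cols: int
    cores: list[CoreRegion]

    def __post_init__(self) -> None:
        if len(self.cores) != self.rows * self.cols:
            raise ValueError("grid must contain rows*cols cores")
        labels = [c.label for c in self.cores]
        if len(set(labels)) != len(labels):
            raise ValueError("core labels must be unique")

    def core(self, label: str) -> CoreRegion:
        for c in self.cores:
            if c.label == label:
                return c
        raise KeyError(f"no core labelled {label!r}")

    @property
    def valid_cores(self) -> list[CoreRegion]:
        return [c for c in self.cores if c.valid]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(c) for c in self.cores])

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, rows: int, cols: int) -> "TMAGrid":
        cores = [
            CoreRegion(
                label=r.label, x_um=float(r.x_um), y_um=float(r.y_um),
                diameter_um=float(r.diameter_um), valid=bool(r.valid),
                tissue_fraction=float(r.tissue_fraction),
                manually_adjusted=bool(r.manually_adjusted),
            )
            for r in df.itertuples()
        ]
        return cls(rows=rows, cols=cols, cores=cores)


def tissue_mask(
    image: np.ndarray,
    background_rgb=DEFAULT_BACKGROUND,
    od_floor: float = 0.1,
    pixel_size: float = 0.5,
    min_object_um2: float = 100.0,
) -> np.ndarray:
    """Binary tissue mask: total OD (summed over channels) >= od_floor,
    with objects smaller than ``min_object_um2`` removed."""
    od = rgb_to_od(image, background_rgb)
    mask = od.sum(axis=-1) >= od_floor
    min_px = int(round(min_object_um2 / (pixel_size * pixel_size)))
    if min_px > 1:
        mask = morphology.remove_small_objects(mask, max_size=min_px - 1)
    return mask


def _fit_axis(coords: np.ndarray, n: int, spacing_guess: float) -> tuple[float, float]:
    """Fit coords ~ origin + index*pitch for a 1-D regular grid with n
    positions; returns (origin, pitch)."""
    origin = coords.min()
    pitch = spacing_guess
    for _ in range(3):
        idx = np.clip(np.rint((coords - origin) / pitch), 0, n - 1)
        if n > 1 and np.ptp(idx) > 0:
            A = np.vstack([np.ones_like(idx), idx]).T
            sol, *_ = np.linalg.lstsq(A, coords, rcond=None)
            origin, pitch = float(sol[0]), float(sol[1])
        else:
            origin = float(np.mean(coords))
            break
    return origin, pitch


def dearray(
    image: np.ndarray,
    pixel_size: float = 0.5,
    core_diameter: float = 900.0,
    density_threshold: float = 5.0,
    bounds_scale: float = 105.0,
    rows: int = 9,
    cols: int = 18,
    background_rgb=DEFAULT_BACKGROUND,
    od_floor: float = 0.1,
    work_pixel_size: float = 4.0,
) -> TMAGrid:
    """Locate and label the TMA grid on a whole-slide RGB image.

    ``core_diameter`` (um) is the nominal grid pitch/core size;
    ``density_threshold`` the minimum percent tissue coverage of the
    (scaled) core disc for a valid core; ``bounds_scale`` the percent
    scaling of the measured disc. Tissue detection runs on a view
    downsampled to about ``work_pixel_size`` um/px — ample for 0.9 mm
    cores — so whole slides stay cheap to process.
    """
    factor = max(1, int(round(work_pixel_size / pixel_size)))
    small = image[::factor, ::factor]
    px = pixel_size * factor
    mask = tissue_mask(small, background_rgb, od_floor=od_floor, pixel_size=px)
    labels, n_blob = ndi.label(mask)
    if n_blob:
        areas = np.bincount(labels.ravel())[1:] * px * px
        nominal = np.pi * (core_diameter / 2.0) ** 2
        keep = np.flatnonzero((areas >= 0.01 * nominal) & (areas <= 4.0 * nominal)) + 1
        centroids = np.array(ndi.center_of_mass(mask, labels, keep)) if len(keep) else np.empty((0, 2))
    else:
        centroids = np.empty((0, 2))
    if len(centroids) < 3:
        raise ValueError(
            f"only {len(centroids)} candidate cores found; cannot fit a grid"
        )
    ys = centroids[:, 0] * px
    xs = centroids[:, 1] * px
    x0, dx = _fit_axis(xs, cols, core_diameter)
    y0, dy = _fit_axis(ys, rows, core_diameter)
    radius = 0.5 * core_diameter * bounds_scale / 100.0
    cores: list[CoreRegion] = []
    for r in range(rows):
        for c in range(cols):
            cx = x0 + c * dx
            cy = y0 + r * dy
            frac = _tissue_fraction_at(mask, px, cx, cy, radius)
            cores.append(
                CoreRegion(
                    label=core_label(r, c),
                    x_um=float(cx),
                    y_um=float(cy),
                    diameter_um=core_diameter,
                    valid=frac * 100.0 >= density_threshold,
                    tissue_fraction=frac,
                )
            )
    return TMAGrid(rows=rows, cols=cols, cores=cores)


def _tissue_fraction_at(
    mask: np.ndarray, px: float, x_um: float, y_um: float, radius_um: float
) -> float:
    h, w = mask.shape
    x0 = max(0, int((x_um - radius_um) / px))
    x1 = min(w, int((x_um + radius_um) / px) + 2)
    y0 = max(0, int((y_um - radius_um) / px))
    y1 = min(h, int((y_um + radius_um) / px) + 2)
    if x0 >= x1 or y0 >= y1:
        return 0.0
    yy, xx = np.mgrid[y0:y1, x0:x1]
    disc = ((xx * px - x_um) ** 2 + (yy * px - y_um) ** 2) <= radius_um**2
    n = int(disc.sum())
    return float(mask[y0:y1, x0:x1][disc].sum() / n) if n else 0.0


def adjust_core(
    grid: TMAGrid,
    label: str,
    new_centre: tuple[float, float] | None = None,
    valid: bool | None = None,
    mask: np.ndarray | None = None,
    mask_pixel_size: float | None = None,
    bounds_scale: float = 105.0,
    density_threshold: float = 5.0,
) -> TMAGrid:
    """Manually move or (in)validate one core; idempotent, leaves every
    other core untouched. Moving a core recomputes its tissue fraction
    (and validity, unless ``valid`` is forced) when a tissue mask is
    supplied."""
    target = grid.core(label)  # raises KeyError for unknown labels
    updated = target
    if new_centre is not None:
        updated = replace(updated, x_um=float(new_centre[0]), y_um=float(new_centre[1]))
        if mask is not None and mask_pixel_size is not None:
            frac = _tissue_fraction_at(
                mask, mask_pixel_size, updated.x_um, updated.y_um,
                0.5 * updated.diameter_um * bounds_scale / 100.0,
            )
            updated = replace(
                updated,
                tissue_fraction=frac,
                valid=frac * 100.0 >= density_threshold,
            )
    if valid is not None:
        updated = replace(updated, valid=bool(valid))
    updated = replace(updated, manually_adjusted=True)
    cores = [updated if c.label == label else c for c in grid.cores]
    return TMAGrid(rows=grid.rows, cols=grid.cols, cores=cores)


def apply_overrides(
    grid: TMAGrid,
    overrides: pd.DataFrame,
    mask: np.ndarray | None = None,
    mask_pixel_size: float | None = None,
) -> TMAGrid:
    """Apply a plain-text override table: columns ``label`` plus any of
    ``valid`` (bool), ``x_um``/``y_um`` (new centre)."""
    for row in overrides.itertuples():
        centre = None
        if hasattr(row, "x_um") and hasattr(row, "y_um") and pd.notna(row.x_um):
            centre = (float(row.x_um), float(row.y_um))
        valid = None
        if hasattr(row, "valid") and pd.notna(row.valid):
            valid = bool(row.valid) if not isinstance(row.valid, str) else row.valid.strip().lower() in ("1", "true", "yes")
        grid = adjust_core(
            grid, row.label, new_centre=centre, valid=valid,
            mask=mask, mask_pixel_size=mask_pixel_size,
        )
    return grid


def assign_cells_to_cores(
    grid: TMAGrid, cells: pd.DataFrame, bounds_scale: float = 105.0
) -> pd.DataFrame:
    """Assign each cell to the valid core disc containing its centroid.

    Cells outside every valid disc get an empty ``core_label`` and are
    excluded from certification downstream. Discs are scaled by
    ``bounds_scale`` percent, matching the measurement disc.
    """
    df = cells.copy()
    valid = grid.valid_cores
    if df.empty or not valid:
        df["core_label"] = ""
        return df
    centres = np.array([[c.x_um, c.y_um] for c in valid])
    radii = np.array([0.5 * c.diameter_um * bounds_scale / 100.0 for c in valid])
    labels = np.array([c.label for c in valid], dtype=object)
    xy = df[["x_um", "y_um"]].to_numpy(dtype=float)
    d2 = ((xy[:, None, :] - centres[None, :, :]) ** 2).sum(axis=2)
    nearest = np.argmin(d2, axis=1)
    inside = d2[np.arange(len(xy)), nearest] <= radii[nearest] ** 2
    out = np.where(inside, labels[nearest], "")
    df["core_label"] = out
    return df
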