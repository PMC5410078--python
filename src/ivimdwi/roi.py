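"""Region-of-interest construction and co-localized mean extraction.

ROIs mimic the reading protocol of the modeled study: an oval region drawn
on the b=1000 image and co-localized on every parameter map.  On phantoms
the placement is programmatic — an ellipse centered on the tumor (or
pancreas) label, eroded away from the boundary — standing in for the
readers' manual placement, which is not implementable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .fitting import ParameterMaps, QualityCode

__all__ = [
    "ROIMask",
    "make_oval_roi",
    "roi_from_label",
    "oval_roi_for_label",
    "extract_roi_means",
]


@dataclass
class ROIMask:
    """Binary mask aligned to a parameter-map grid.

    ``area_mm2`` is the in-plane area: voxel count times in-plane voxel
    area, summed over slices (multi-slice ROIs pool their voxels).
    """

    mask: np.ndarray
    area_mm2: float
    provenance: str = ""

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("ROI mask must be 3-D")
        if not self.mask.any():
            raise ValueError("ROI mask is empty")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


def make_oval_roi(
    center: tuple[float, float],
    semi_axes_mm: tuple[float, float],
    slice_index: int,
    grid_shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
) -> ROIMask:
    """Rasterize an axis-aligned oval ROI on one slice.

    A voxel belongs to the ROI iff its center lies inside the ellipse
    (deterministic and orientation-independent at the grid scales used).
    ``center`` is in 0-based grid coordinates (x, y); semi-axes are in mm.

    Raises
    ------
    ValueError
        If the ellipse extends outside the grid, the slice index is out of
        range, or the ellipse is too small to contain any voxel center.
    """
    nx, ny, nz = grid_shape
    dx, dy, _ = spacing
    if not 0 <= slice_index < nz:
        raise ValueError(f"slice {slice_index} outside grid of {nz} slices")
    ax_mm, ay_mm = semi_axes_mm
    cx_mm, cy_mm = center[0] * dx, center[1] * dy
    if (
        cx_mm - ax_mm < -dx / 2 or cx_mm + ax_mm > (nx - 0.5) * dx
        or cy_mm - ay_mm < -dy / 2 or cy_mm + ay_mm > (ny - 0.5) * dy
    ):
        raise ValueError("ellipse extends outside the image grid")
    xs = np.arange(nx)[:, None] * dx
    ys = np.arange(ny)[None, :] * dy
    inside = ((xs - cx_mm) / ax_mm) ** 2 + ((ys - cy_mm) / ay_mm) ** 2 <= 1.0
    if not inside.any():
        raise ValueError("ellipse smaller than a voxel: empty ROI")
    mask = np.zeros(grid_shape, dtype=bool)
    mask[:, :, slice_index] = inside
    area = float(inside.sum()) * dx * dy
    return ROIMask(
        mask=mask,
        area_mm2=area,
        provenance=(
            f"oval ROI, center=({center[0]:g},{center[1]:g}) vox, "
            f"semi-axes=({ax_mm:g},{ay_mm:g}) mm, slice={slice_index}"
        ),
    )


def roi_from_label(
    labels: np.ndarray,
    label_value: int,
    spacing: tuple[float, float, float],
    erode: int = 1,
) -> ROIMask:
    """Programmatic ROI: a labeled region eroded away from its boundary.

    Erosion by one voxel keeps the ROI on the "solid portion" of the
    lesion, away from partial-volume boundary voxels, echoing the manual
    protocol.  Falls back to the un-eroded region if erosion empties it.
    """
    region = labels == label_value
    if not region.any():
        raise ValueError(f"label {label_value} not present")
    mask = region
    if erode > 0:
        eroded = ndimage.binary_erosion(region, iterations=erode)
        if eroded.any():
            mask = eroded
    area = float(mask.sum()) * spacing[0] * spacing[1]
    return ROIMask(
        mask=mask, area_mm2=area,
        provenance=f"label {label_value}, eroded x{erode}",
    )


def oval_roi_for_label(
    labels: np.ndarray,
    label_value: int,
    spacing: tuple[float, float, float],
    margin_mm: float | None = None,
    max_semi_axes_mm: tuple[float, float] | None = None,
) -> ROIMask:
    """Place a single-slice oval ROI inside a labeled region.

    The oval is centered on the region's centroid, on the slice nearest
    the centroid, with semi-axes set to the region's in-plane half-extents
    on that slice shrunk by ``margin_mm`` (default: one in-plane voxel) —
    the programmatic analogue of drawing an oval on the solid portion of a
    lesion, away from its boundary.
    """
    region = labels == label_value
    if not region.any():
        raise ValueError(f"label {label_value} not present")
    dx, dy, _ = spacing
    if margin_mm is None:
        margin_mm = max(dx, dy)
    idx = np.nonzero(region)
    cx, cy, cz = (float(np.mean(ax)) for ax in idx)
    slice_index = int(round(cz))
    plane = region[:, :, slice_index]
    if not plane.any():
        raise ValueError("region empty on its centroid slice")
    px, py = np.nonzero(plane)
    half_x = (px.max() - px.min()) / 2 * dx
    half_y = (py.max() - py.min()) / 2 * dy
    ax_mm = max(half_x - margin_mm, dx)
    ay_mm = max(half_y - margin_mm, dy)
    if max_semi_axes_mm is not None:
        ax_mm = min(ax_mm, max_semi_axes_mm[0])
        ay_mm = min(ay_mm, max_semi_axes_mm[1])
    return make_oval_roi(
        center=(cx, cy),
        semi_axes_mm=(ax_mm, ay_mm),
        slice_index=slice_index,
        grid_shape=labels.shape,
        spacing=spacing,
    )


def extract_roi_means(
    maps: ParameterMaps, roi: ROIMask, min_ok_fraction: float = 0.0
) -> tuple[dict[str, float], float]:
    """Arithmetic mean of every map over the ROI's quality-OK voxels.

    Negative two-point ADCs (flagged but retained) are included — they are
    measurements, not failures.  Returns ``(means, excluded_fraction)``
    where the fraction counts ROI voxels dropped for quality reasons.

    Raises
    ------
    ValueError
        If the ROI lies entirely on failed voxels, or the usable fraction
        falls below ``min_ok_fraction``.
    """
    if roi.mask.shape != maps.quality.shape:
        raise ValueError("ROI grid does not match the parameter maps")
    usable = roi.mask & (
        (maps.quality == QualityCode.OK) | (maps.quality == QualityCode.NEGATIVE_ADC)
    )
    n_total = roi.n_voxels
    n_ok = int(usable.sum())
    if n_ok == 0:
        raise ValueError("ROI contains no successfully fitted voxels")
    excluded = 1.0 - n_ok / n_total
    if n_ok / n_total < min_ok_fraction:
        raise ValueError(
            f"only {n_ok}/{n_total} ROI voxels usable (< {min_ok_fraction:.0%})"
        )
    means = {
        name: float(np.mean(maps.get_map(name)[usable])) for name in maps.map_names()
    }
    return means, excluded
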