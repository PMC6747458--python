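"""Automated per-cell morphometry: soma area, arbor area, tip count.

These are automated proxies for measurements done by hand in the
whole-mount protocol: the soma contour is replaced by the connected
half-maximum region around the detected centroid, and the hand-drawn
polygon through the distal process tips is replaced by the convex hull
of skeleton endpoints (the hull contains the hand polygon in general;
documented as a proxy).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from skimage.morphology import skeletonize

from .detect import DetectionResult
from .types import Field, GliaquantError

__all__ = ["MorphoParams", "MorphometryRecord", "measure_cell", "measure_field"]


class MorphometryError(GliaquantError):
    """Raised when a cell cannot be measured (e.g. centroid on zero
    intensity)."""


@dataclass(frozen=True)
class MorphoParams:
    """Morphometry parameters.

    ``soma_threshold_fraction`` — soma is the connected region at or
    above this fraction of the cell's own peak (half-maximum default,
    robust to global intensity scale).  ``support_threshold_fraction``
    — the fraction of the cell peak defining the above-background
    support used for skeletonization; low enough to keep the dim distal
    processes.  ``window_um`` — side of the analysis crop around the
    centroid (about 3× the expected arbor diameter); competing cells
    inside the window are masked by nearest-centroid assignment.
    """

    soma_threshold_fraction: float = 0.5
    support_threshold_fraction: float = 0.05
    window_um: float = 120.0

    def __post_init__(self) -> None:
        if not (0.0 < self.soma_threshold_fraction <= 1.0):
            raise ValueError("soma_threshold_fraction must lie in (0, 1]")
        if not (0.0 < self.support_threshold_fraction < 1.0):
            raise ValueError("support_threshold_fraction must lie in (0, 1)")
        if not self.window_um > 0:
            raise ValueError("window_um must be positive")


@dataclass
class MorphometryRecord:
    """Per-cell morphometric measures in physical units."""

    cell_id: int
    layer: str
    soma_area: float  # μm²
    arbor_area: float  # μm²
    n_tips: int

    def __post_init__(self) -> None:
        if self.soma_area < 0 or self.arbor_area < 0:
            raise ValueError("areas must be non-negative")
        if self.arbor_area < self.soma_area:
            raise ValueError("arbor_area must be >= soma_area")


_EIGHT = np.ones((3, 3), dtype=bool)


def _crop(field: Field, centroid_um, half_um: float):
    px = field.pixel_size
    cx, cy = centroid_um
    row = int(cy / px)
    col = int(cx / px)
    half = int(np.ceil(half_um / px))
    r0, r1 = max(0, row - half), min(field.shape[0], row + half + 1)
    c0, c1 = max(0, col - half), min(field.shape[1], col + half + 1)
    return field.pixels[r0:r1, c0:c1], (r0, c0)


def _mask_competitors(crop, origin, centroid_um, others_um, px):
    """Zero pixels nearer to a competing centroid than to this cell's.

    Only competitors whose territory can reach the crop matter, so the
    search is restricted to centroids within the crop's circumradius of
    its center."""
    if not others_um:
        return crop
    r0, c0 = origin
    ys = (np.arange(r0, r0 + crop.shape[0]) + 0.5)[:, None] * px
    xs = (np.arange(c0, c0 + crop.shape[1]) + 0.5)[None, :] * px
    others = np.asarray(others_um, dtype=float)
    reach = 0.75 * px * float(np.hypot(*crop.shape))
    near = others[
        np.hypot(others[:, 0] - centroid_um[0], others[:, 1] - centroid_um[1]) < reach
    ]
    if near.size == 0:
        return crop
    own2 = (xs - centroid_um[0]) ** 2 + (ys - centroid_um[1]) ** 2
    other2 = np.full_like(own2, np.inf)
    for ox, oy in near:
        np.minimum(other2, (xs - ox) ** 2 + (ys - oy) ** 2, out=other2)
    out = crop.copy()
    out[other2 < own2] = 0.0
    return out


def _cell_context(field: Field, centroid_um, others_um, params: MorphoParams):
    """Isolate the cell: masked crop, its peak, soma mask, support mask."""
    px = field.pixel_size
    crop, origin = _crop(field, centroid_um, params.window_um / 2.0)
    crop = _mask_competitors(crop, origin, centroid_um, others_um, px)
    r0, c0 = origin
    crow = int(centroid_um[1] / px) - r0
    ccol = int(centroid_um[0] / px) - c0
    crow = min(max(crow, 0), crop.shape[0] - 1)
    ccol = min(max(ccol, 0), crop.shape[1] - 1)
    if crop[crow, ccol] <= 0:
        raise MorphometryError("centroid lies on zero intensity")
    # the cell's own peak: maximum of the connected support containing
    # the centroid, so a brighter neighbour in the window cannot leak in
    support0 = crop >= params.support_threshold_fraction * crop.max()
    labels, _ = ndimage.label(support0, structure=_EIGHT)
    if labels[crow, ccol] == 0:
        raise MorphometryError("centroid not on the above-background support")
    own0 = labels == labels[crow, ccol]
    peak = float(crop[own0].max())

    soma_mask_all = crop >= params.soma_threshold_fraction * peak
    labels_s, _ = ndimage.label(soma_mask_all, structure=_EIGHT)
    lab = labels_s[crow, ccol]
    if lab == 0:
        # centroid pixel below half-max (e.g. interpolated COM between
        # bright pixels): snap to the nearest soma-level pixel of the cell
        cand = soma_mask_all & own0
        if not cand.any():
            raise MorphometryError("no soma-level region for this cell")
        rr, cc = np.nonzero(cand)
        j = np.argmin((rr - crow) ** 2 + (cc - ccol) ** 2)
        lab = labels_s[rr[j], cc[j]]
    soma_mask = labels_s == lab

    support = crop >= params.support_threshold_fraction * peak
    labels_u, _ = ndimage.label(support, structure=_EIGHT)
    own_lab = labels_u[soma_mask]
    support_mask = labels_u == np.bincount(own_lab[own_lab > 0]).argmax()
    return crop, origin, peak, soma_mask, support_mask


def _soma_boundary(soma_mask: np.ndarray) -> np.ndarray:
    inner = ndimage.binary_erosion(soma_mask, structure=_EIGHT)
    boundary = soma_mask & ~inner
    return np.argwhere(boundary if boundary.any() else soma_mask)


def _skeleton_endpoints(support_mask: np.ndarray) -> np.ndarray:
    skel = skeletonize(support_mask)
    if not skel.any():
        return np.zeros((0, 2), dtype=int)
    neighbours = ndimage.convolve(skel.astype(int), np.ones((3, 3)), mode="constant")
    # a skeleton endpoint has exactly one skeleton neighbour (self + 1)
    return np.argwhere(skel & (neighbours == 2))


def measure_cell(
    field: Field,
    centroid_um: tuple[float, float],
    others_um: list[tuple[float, float]] | None = None,
    params: MorphoParams = MorphoParams(),
) -> tuple[float, float, int]:
    """Measure one detected cell: (soma_area μm², arbor_area μm², n_tips).

    Soma area is the pixel count of the connected region containing the
    centroid at ≥ ``soma_threshold_fraction`` of the cell's own peak,
    times pixel area.  Arbor area is the convex hull of the skeleton
    endpoints of the cell's support together with the soma boundary; a
    process-free cell (no endpoints outside the soma) degenerates to the
    soma itself, so arbor_area == soma_area.
    """
    others_um = others_um or []
    px = field.pixel_size
    crop, origin, peak, soma_mask, support_mask = _cell_context(
        field, centroid_um, others_um, params
    )
    soma_area = float(soma_mask.sum()) * px * px

    endpoints = _skeleton_endpoints(support_mask)
    if endpoints.size:
        in_soma = soma_mask[endpoints[:, 0], endpoints[:, 1]]
        outside = endpoints[~in_soma]
    else:
        outside = endpoints
    n_tips = int(len(outside))

    boundary = _soma_boundary(soma_mask)
    hull_pts = np.vstack([boundary, outside]) if n_tips else boundary
    arbor_area = soma_area
    if len(hull_pts) >= 3:
        try:
            hull = ConvexHull(hull_pts[:, ::-1] * px)  # (x, y) μm
            arbor_area = float(hull.volume)
        except QhullError:
            pass
    # discretization can make the boundary-center hull a hair smaller
    # than the pixel-counted soma; the invariant arbor >= soma wins
    arbor_area = max(arbor_area, soma_area)
    return soma_area, arbor_area, n_tips


def measure_field(
    field: Field,
    detection: DetectionResult,
    params: MorphoParams = MorphoParams(),
) -> list[MorphometryRecord]:
    """Morphometry for every detected cell in a field.

    Cells are measured individually; within each analysis window,
    pixels nearer to a competing detected centroid are masked out.
    Cells that cannot be measured (blank centroid) are skipped.
    """
    records: list[MorphometryRecord] = []
    cents = detection.centroids
    for i, c in enumerate(cents):
        others = [o for j, o in enumerate(cents) if j != i]
        try:
            soma, arbor, n_tips = measure_cell(field, c, others, params)
        except MorphometryError:
            continue
        records.append(
            MorphometryRecord(
                cell_id=i,
                layer=field.layer,
                soma_area=soma,
                arbor_area=arbor,
                n_tips=n_tips,
            )
        )
    return records
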