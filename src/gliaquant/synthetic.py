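"""Synthetic fluorescence-field generator with known ground truth.

Emulates Iba-1-like stained retinal whole-mount fields: ramified
microglia tiled in a non-overlapping mosaic, dense round RGC-nucleus
blobs in the ganglion cell layer, and compact bright spots at the
OPL/OS interface (microglial vertical processes).  Rendering is
additive on a noisy background:

* soma — radially symmetric disc with a logistic edge whose half-maximum
  sits exactly at the soma radius, so half-peak pixel counting recovers
  the planted area πr²;
* processes — tapering Gaussian-profile ridges from the soma edge to
  each tip, substantially dimmer than the soma so that a 0.2 relative
  threshold preserves only the most intense part of each cell (the cell
  body), as the counting algorithm assumes.

All randomness flows through an explicitly passed numpy Generator; no
global state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .types import (
    ActivationProfile,
    BASELINE_PROFILE,
    CellTruth,
    Field,
    FieldGeometry,
    PackingError,
    ZStack,
)

__all__ = [
    "CellPopulation",
    "MICROGLIA",
    "RGC_NUCLEUS",
    "VERTICAL_SPOT",
    "render_cell",
    "generate_layer_field",
    "generate_layer_stack",
    "generate_vertical_spots",
]


@dataclass(frozen=True)
class CellPopulation:
    """Rendering/placement parameters for one cell kind.

    All lengths in μm.  ``spacing`` is the mosaic minimum center-to-center
    distance; ``None`` means twice the mean arbor radius (territorial
    tiling).  ``process_base_frac``/``process_tip_frac`` set the ridge
    amplitude at the soma edge and at the distal tip as fractions of the
    cell's peak intensity; they are deliberately below the 0.2 counting
    threshold so somata, not arbors, drive segmentation.
    """

    kind: str = "microglia"
    mean_soma_radius: float = 3.5
    soma_radius_sd: float = 0.5
    mean_arbor_radius: float = 20.0
    arbor_radius_sd: float = 2.5
    n_processes_range: tuple[int, int] = (4, 6)
    peak_range: tuple[float, float] = (0.7, 1.0)
    process_base_frac: float = 0.22
    process_tip_frac: float = 0.08
    spacing: float | None = None

    def effective_spacing(self, profile: ActivationProfile) -> float:
        if self.spacing is not None:
            return self.spacing
        base = 2.0 * self.mean_arbor_radius
        if self.kind == "microglia":
            base *= profile.arbor_factor
        return base


MICROGLIA = CellPopulation()
RGC_NUCLEUS = CellPopulation(
    kind="rgc_nucleus",
    mean_soma_radius=4.0,
    soma_radius_sd=0.4,
    mean_arbor_radius=0.0,
    arbor_radius_sd=0.0,
    n_processes_range=(0, 0),
    spacing=12.0,
)
VERTICAL_SPOT = CellPopulation(
    kind="vertical_spot",
    mean_soma_radius=1.4,
    soma_radius_sd=0.2,
    mean_arbor_radius=0.0,
    arbor_radius_sd=0.0,
    n_processes_range=(0, 0),
    peak_range=(0.6, 1.0),
    spacing=6.0,
)

_POPULATIONS = {
    "microglia": MICROGLIA,
    "rgc_nucleus": RGC_NUCLEUS,
    "vertical_spot": VERTICAL_SPOT,
}


# ---------------------------------------------------------------------------
# rendering

def _cell_image(
    truth: CellTruth,
    shape: tuple[int, int],
    pixel_size: float,
    population: CellPopulation | None = None,
) -> tuple[np.ndarray, tuple[int, int]]:
    """Render one cell on a local crop; returns (crop, (row0, col0))."""
    pop = population or _POPULATIONS.get(truth.kind, MICROGLIA)
    cx, cy = truth.center
    r = truth.soma_radius
    edge_w = max(0.15 * r, 0.6 * pixel_size)  # logistic edge width, μm
    sigma = max(0.7, 0.6 * pixel_size)  # process ridge cross-section, μm

    extent = r + 6.0 * edge_w
    if truth.process_tips:
        extent = max(
            extent,
            max(math.hypot(tx - cx, ty - cy) for tx, ty in truth.process_tips)
            + 4.0 * sigma,
        )
    row0 = max(0, int((cy - extent) / pixel_size) - 1)
    row1 = min(shape[0], int((cy + extent) / pixel_size) + 2)
    col0 = max(0, int((cx - extent) / pixel_size) - 1)
    col1 = min(shape[1], int((cx + extent) / pixel_size) + 2)
    if row0 >= row1 or col0 >= col1:
        return np.zeros((0, 0)), (0, 0)

    ys = (np.arange(row0, row1) + 0.5)[:, None] * pixel_size
    xs = (np.arange(col0, col1) + 0.5)[None, :] * pixel_size
    d = np.hypot(xs - cx, ys - cy)
    img = truth.peak_intensity / (1.0 + np.exp((d - r) / edge_w))

    for tx, ty in truth.process_tips:
        # ridge from just inside the soma edge to the tip
        ux, uy = tx - cx, ty - cy
        norm = math.hypot(ux, uy)
        ax, ay = cx + ux / norm * 0.8 * r, cy + uy / norm * 0.8 * r
        bx, by = tx, ty
        vx, vy = bx - ax, by - ay
        seg2 = vx * vx + vy * vy
        t = np.clip(((xs - ax) * vx + (ys - ay) * vy) / seg2, 0.0, 1.0)
        px, py = ax + t * vx, ay + t * vy
        dist = np.hypot(xs - px, ys - py)
        amp = truth.peak_intensity * (
            pop.process_base_frac
            + (pop.process_tip_frac - pop.process_base_frac) * t
        )
        ridge = amp * np.exp(-0.5 * (dist / sigma) ** 2)
        np.maximum(img, ridge, out=img)

    return img, (row0, col0)


def render_cell(truth: CellTruth, field: Field) -> Field:
    """Additively render one cell onto a field.

    The returned field is a copy with the cell image added, so it is
    everywhere ≥ the input and rendering is exactly additive.

    Raises ``ValueError`` if the cell center lies outside the field
    (process tips may clip at the boundary).
    """
    h, w = field.shape
    cx, cy = truth.center
    if not (0.0 <= cx <= w * field.pixel_size and 0.0 <= cy <= h * field.pixel_size):
        raise ValueError("cell center must lie within the field bounds")
    img, (row0, col0) = _cell_image(truth, field.shape, field.pixel_size)
    out = field.pixels.copy()
    out[row0 : row0 + img.shape[0], col0 : col0 + img.shape[1]] += img
    return field.with_pixels(out)


def _render_into(
    pixels: np.ndarray,
    truth: CellTruth,
    pixel_size: float,
    scale: float = 1.0,
    population: CellPopulation | None = None,
) -> None:
    img, (row0, col0) = _cell_image(truth, pixels.shape, pixel_size, population)
    pixels[row0 : row0 + img.shape[0], col0 : col0 + img.shape[1]] += scale * img


# ---------------------------------------------------------------------------
# placement

def _place_mosaic(
    n_cells: int,
    side: float,
    margin: float,
    spacing: float,
    rng: np.random.Generator,
    max_attempts_per_cell: int = 400,
) -> np.ndarray:
    """Rejection-sample n_cells centers with pairwise distance ≥ spacing.

    Raises :class:`PackingError` after a bounded number of attempts
    rather than silently truncating.
    """
    if n_cells == 0:
        return np.zeros((0, 2))
    lo, hi = margin, side - margin
    if hi <= lo:
        raise PackingError("field too small for the requested margin")
    centers = np.empty((n_cells, 2))
    n_placed = 0
    budget = max_attempts_per_cell * n_cells
    attempts = 0
    while n_placed < n_cells:
        if attempts >= budget:
            raise PackingError(
                f"could not place {n_cells} cells at spacing {spacing:.1f} μm "
                f"in a {side:.0f} μm field after {budget} attempts "
                f"({n_placed} placed)"
            )
        attempts += 1
        cand = rng.uniform(lo, hi, size=2)
        d2 = ((centers[:n_placed] - cand) ** 2).sum(axis=1)
        if n_placed == 0 or d2.min() >= spacing * spacing:
            centers[n_placed] = cand
            n_placed += 1
    return centers


def _draw_truths(
    centers: np.ndarray,
    population: CellPopulation,
    profile: ActivationProfile,
    rng: np.random.Generator,
) -> list[CellTruth]:
    pop = population
    truths: list[CellTruth] = []
    for cx, cy in centers:
        r = float(
            np.clip(
                rng.normal(
                    pop.mean_soma_radius * profile.soma_factor,
                    pop.soma_radius_sd * profile.soma_factor,
                ),
                0.3 * pop.mean_soma_radius * profile.soma_factor,
                2.0 * pop.mean_soma_radius * profile.soma_factor,
            )
        )
        peak = float(rng.uniform(*pop.peak_range))
        lo, hi = pop.n_processes_range
        n_proc = int(rng.integers(lo, hi + 1)) if hi > 0 else 0
        tips: list[tuple[float, float]] = []
        if n_proc > 0:
            arbor = float(
                max(
                    rng.normal(
                        pop.mean_arbor_radius * profile.arbor_factor,
                        pop.arbor_radius_sd * profile.arbor_factor,
                    ),
                    r + 2.0,
                )
            )
            base_angles = (
                2 * np.pi * np.arange(n_proc) / n_proc
                + rng.uniform(0, 2 * np.pi)
                + rng.uniform(-0.3, 0.3, size=n_proc)
            )
            tip_dist = arbor * rng.uniform(0.85, 1.0, size=n_proc)
            tip_dist = np.maximum(tip_dist, r + 1.0)
            for ang, td in zip(base_angles, tip_dist):
                tips.append((cx + td * math.cos(ang), cy + td * math.sin(ang)))
        truths.append(
            CellTruth(
                center=(float(cx), float(cy)),
                soma_radius=r,
                n_processes=n_proc,
                process_tips=tips,
                peak_intensity=peak,
                kind=pop.kind,
            )
        )
    return truths


def _noise_background(
    shape: tuple[int, int],
    background: float,
    noise_level: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Low uniform background with additive Gaussian noise, clipped at 0."""
    pixels = np.full(shape, background, dtype=np.float64)
    if noise_level > 0:
        pixels += rng.normal(0.0, noise_level, size=shape)
    return np.clip(pixels, 0.0, None)


# ---------------------------------------------------------------------------
# public generators

def generate_layer_field(
    n_cells: int,
    profile: ActivationProfile = BASELINE_PROFILE,
    layer: str = "OPL",
    zone: str = "superior",
    geometry: FieldGeometry | None = None,
    noise_level: float = 0.005,
    rng: np.random.Generator | None = None,
    kind: str = "microglia",
    population: CellPopulation | None = None,
    background: float = 0.01,
) -> tuple[Field, list[CellTruth]]:
    """Generate one field with ``n_cells`` planted cells in a mosaic.

    Cells are placed by rejection sampling with pairwise center distance
    ≥ the population's mosaic spacing (default twice the mean arbor
    radius); soma radii and arbor extents are scaled by the activation
    ``profile``.  Returns the field and exactly ``n_cells`` truth
    records.  Raises :class:`PackingError` if the mosaic is infeasible.
    """
    geometry = geometry or FieldGeometry()
    rng = rng if rng is not None else np.random.default_rng()
    pop = population or _POPULATIONS[kind]
    spacing = pop.effective_spacing(profile)
    margin = pop.mean_soma_radius * profile.soma_factor + 1.0
    centers = _place_mosaic(n_cells, geometry.side_um, margin, spacing, rng)
    truths = _draw_truths(centers, pop, profile, rng)
    pixels = _noise_background(geometry.shape, background, noise_level, rng)
    for t in truths:
        _render_into(pixels, t, geometry.pixel_size, population=pop)
    return Field(pixels, geometry.pixel_size, layer, zone), truths


def generate_layer_stack(
    n_cells: int,
    profile: ActivationProfile = BASELINE_PROFILE,
    layer: str = "OPL",
    zone: str = "superior",
    geometry: FieldGeometry | None = None,
    noise_level: float = 0.005,
    rng: np.random.Generator | None = None,
    kind: str = "microglia",
    population: CellPopulation | None = None,
    background: float = 0.01,
    n_sections: int = 5,
    z_spacing: float = 2.0,
) -> tuple[ZStack, list[CellTruth]]:
    """Generate a z-stack of ``n_sections`` optical sections (default 5
    at 2 μm spacing).

    Each cell is centered on one interior section and its intensity is
    spread over adjacent sections with a triangular axial profile
    (weight 1 at the focal section, 0.5 one section away, 0 beyond), so
    a mean projection is meaningful and uniform across cells.
    """
    geometry = geometry or FieldGeometry()
    rng = rng if rng is not None else np.random.default_rng()
    pop = population or _POPULATIONS[kind]
    spacing = pop.effective_spacing(profile)
    margin = pop.mean_soma_radius * profile.soma_factor + 1.0
    centers = _place_mosaic(n_cells, geometry.side_um, margin, spacing, rng)
    truths = _draw_truths(centers, pop, profile, rng)
    focal = (
        rng.integers(1, max(n_sections - 1, 2), size=len(truths))
        if n_sections > 2
        else np.zeros(len(truths), dtype=int)
    )
    sections: list[Field] = []
    for s in range(n_sections):
        pixels = _noise_background(geometry.shape, background, noise_level, rng)
        for t, c in zip(truths, focal):
            w = max(0.0, 1.0 - abs(s - int(c)) / 2.0)
            if w > 0:
                _render_into(pixels, t, geometry.pixel_size, scale=w, population=pop)
        sections.append(Field(pixels, geometry.pixel_size, layer, zone))
    return ZStack(sections, z_spacing), truths


def generate_vertical_spots(
    n_spots: int,
    geometry: FieldGeometry | None = None,
    noise_level: float = 0.005,
    rng: np.random.Generator | None = None,
    spot_factor: float = 1.0,
    background: float = 0.01,
) -> tuple[Field, list[CellTruth]]:
    """Field of the OPL/OS interface plane with ``n_spots`` compact
    bright blobs (microglial vertical processes seen end-on).

    ``spot_factor`` is only a density bookkeeping hook for callers; the
    number rendered is exactly ``n_spots``.  Spot diameter is smaller
    than the default microglial soma diameter.
    """
    geometry = geometry or FieldGeometry()
    rng = rng if rng is not None else np.random.default_rng()
    pop = VERTICAL_SPOT
    centers = _place_mosaic(
        n_spots, geometry.side_um, pop.mean_soma_radius + 1.0, pop.spacing, rng
    )
    truths = _draw_truths(centers, pop, BASELINE_PROFILE, rng)
    pixels = _noise_background(geometry.shape, background, noise_level, rng)
    for t in truths:
        _render_into(pixels, t, geometry.pixel_size, population=pop)
    return Field(pixels, geometry.pixel_size, "OPL-OS", "superior"), truths
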