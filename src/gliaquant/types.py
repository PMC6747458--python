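"""Core domain types for retinal whole-mount quantification.

The unit of every measurement is a :class:`Field` — a single-channel
grayscale micrograph of a fixed physical retinal area with a layer and
quadrant (zone) label.  Plexiform layers are imaged as :class:`ZStack`
objects (ordered optical sections at fixed z spacing) and reduced to a
Field by projection before detection.

Planted cells in synthetic fields carry a :class:`CellTruth` record,
which is the ground-truth oracle for all recovery tests: the soma center
and radius, the distal process tips, and the activation-state rendering
parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np

#: Retinal layers quantified in whole mounts.  "OPL-OS" labels the
#: interface plane between the outer plexiform layer and the photoreceptor
#: outer segments where microglial vertical processes appear as spots.
LAYERS = ("OS", "OPL", "IPL", "NFL-GCL", "OPL-OS")

#: Retinal quadrants relative to the optic disc.
ZONES = ("superior", "inferior", "nasal", "temporal")

CELL_KINDS = ("microglia", "rgc_nucleus", "vertical_spot")

EYE_ROLES = ("OHT", "contralateral", "single")


class GliaquantError(Exception):
    """Base class for package errors."""


class PackingError(GliaquantError):
    """Raised when a mosaic of cells cannot be placed at the requested
    density under the minimum-spacing constraint."""


@dataclass(frozen=True)
class FieldGeometry:
    """Physical geometry of one micrograph field.

    The default physical area is 0.1502 mm² — the area covered by one
    20× field in the whole-mount protocol this package emulates.  The
    field is square; ``pixel_size`` is derived from the area and the
    pixel grid, so changing ``n_pixels`` trades resolution for speed
    without changing the physical field.
    """

    n_pixels: int = 1024
    area_mm2: float = 0.1502

    def __post_init__(self) -> None:
        if self.n_pixels < 8:
            raise ValueError(f"n_pixels must be >= 8, got {self.n_pixels}")
        if not self.area_mm2 > 0:
            raise ValueError("area_mm2 must be positive")

    @property
    def side_um(self) -> float:
        """Side length of the square field in μm."""
        return math.sqrt(self.area_mm2) * 1000.0

    @property
    def pixel_size(self) -> float:
        """Pixel pitch in μm/pixel."""
        return self.side_um / self.n_pixels

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_pixels, self.n_pixels)


@dataclass
class Field:
    """One 2-D grayscale micrograph with physical calibration.

    Coordinates: pixel indices are 0-based row-major; the physical
    position of pixel (row, col) is its center,
    ``x = (col + 0.5) * pixel_size`` and ``y = (row + 0.5) * pixel_size``.
    """

    pixels: np.ndarray
    pixel_size: float
    layer: str = "OPL"
    zone: str = "superior"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError(f"pixels must be 2-D, got ndim={self.pixels.ndim}")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixel intensities must be finite")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive (μm/pixel)")
        if self.layer not in LAYERS:
            raise ValueError(f"layer must be one of {LAYERS}, got {self.layer!r}")
        if self.zone not in ZONES:
            raise ValueError(f"zone must be one of {ZONES}, got {self.zone!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def area_um2(self) -> float:
        """Physical field area in μm² (rows × cols × pixel_size²)."""
        return self.pixels.size * self.pixel_size**2

    def with_pixels(self, pixels: np.ndarray) -> "Field":
        """Copy of this field with new pixel data, calibration preserved."""
        return Field(pixels, self.pixel_size, self.layer, self.zone)


@dataclass
class ZStack:
    """Ordered optical sections at fixed z spacing (default 2 μm).

    All sections share shape and calibration; a stack reduces to a Field
    via :func:`gliaquant.detect.project`.
    """

    sections: list[Field]
    z_spacing: float = 2.0

    def __post_init__(self) -> None:
        if len(self.sections) < 1:
            raise ValueError("a ZStack needs at least one section")
        if not self.z_spacing > 0:
            raise ValueError("z_spacing must be positive (μm)")
        first = self.sections[0]
        for s in self.sections[1:]:
            if s.shape != first.shape or s.pixel_size != first.pixel_size:
                raise ValueError("all sections must share shape and pixel_size")

    def __len__(self) -> int:
        return len(self.sections)

    @property
    def pixel_size(self) -> float:
        return self.sections[0].pixel_size

    @property
    def layer(self) -> str:
        return self.sections[0].layer

    @property
    def zone(self) -> str:
        return self.sections[0].zone


@dataclass
class CellTruth:
    """Ground truth for one planted cell.

    ``center`` and ``process_tips`` are physical (x, y) coordinates in
    μm.  ``peak_intensity`` is the rendering amplitude in relative units
    (0, 1].  Process tips always lie beyond the soma boundary; RGC
    nuclei and vertical spots carry no processes.
    """

    center: tuple[float, float]
    soma_radius: float
    n_processes: int = 0
    process_tips: list[tuple[float, float]] = dc_field(default_factory=list)
    peak_intensity: float = 1.0
    kind: str = "microglia"

    def __post_init__(self) -> None:
        if not self.soma_radius > 0:
            raise ValueError("soma_radius must be positive (μm)")
        if self.n_processes < 0:
            raise ValueError("n_processes must be >= 0")
        if len(self.process_tips) != self.n_processes:
            raise ValueError("process_tips length must equal n_processes")
        if not (0.0 < self.peak_intensity <= 1.0):
            raise ValueError("peak_intensity must lie in (0, 1]")
        if self.kind not in CELL_KINDS:
            raise ValueError(f"kind must be one of {CELL_KINDS}")
        if self.kind in ("rgc_nucleus", "vertical_spot") and self.n_processes != 0:
            raise ValueError(f"{self.kind} must have n_processes = 0")
        cx, cy = self.center
        for tx, ty in self.process_tips:
            if math.hypot(tx - cx, ty - cy) <= self.soma_radius:
                raise ValueError("every process tip must lie beyond the soma radius")

    @property
    def arbor_radius(self) -> float:
        """Distance from center to the farthest process tip (soma radius
        for process-free cells)."""
        cx, cy = self.center
        if not self.process_tips:
            return self.soma_radius
        return max(math.hypot(tx - cx, ty - cy) for tx, ty in self.process_tips)


@dataclass(frozen=True)
class ActivationProfile:
    """Multiplicative morphological-state factors relative to baseline.

    Activated (OHT-like) microglia are denser, have larger somata,
    retracted (smaller) arbors and more vertical processes; RGC survival
    is scaled by ``rgc_factor``.  The baseline profile is all ones.
    Magnitudes are illustrative configuration — the source study reports
    effect directions in figures only, never numeric effect sizes.
    """

    density_factor: float = 1.0
    soma_factor: float = 1.0
    arbor_factor: float = 1.0
    vertical_spot_factor: float = 1.0
    rgc_factor: float = 1.0

    def __post_init__(self) -> None:
        for name in (
            "density_factor",
            "soma_factor",
            "arbor_factor",
            "vertical_spot_factor",
            "rgc_factor",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be a positive multiplier")

    @property
    def is_baseline(self) -> bool:
        return all(
            getattr(self, f) == 1.0
            for f in (
                "density_factor",
                "soma_factor",
                "arbor_factor",
                "vertical_spot_factor",
                "rgc_factor",
            )
        )


BASELINE_PROFILE = ActivationProfile()

#: Illustrative defaults for the morphological contrast between study
#: arms (directions follow the reported activation phenotype; magnitudes
#: are configuration, not measured values).
OHT_PROFILE = ActivationProfile(1.3, 1.5, 0.7, 1.4, 0.75)
CONTRA_PROFILE = ActivationProfile(1.1, 1.2, 0.9, 1.5, 1.0)
SAFFRON_OHT_PROFILE = ActivationProfile(1.15, 1.25, 0.85, 1.35, 0.95)
SAFFRON_CONTRA_PROFILE = ActivationProfile(1.05, 1.1, 0.95, 1.2, 1.0)


@dataclass(frozen=True)
class GroupArm:
    """One eye population of one experimental group.

    Lasered groups contribute two arms sharing a group ``name`` (eye
    roles "OHT" and "contralateral", paired within animal); control
    groups contribute a "single" arm.
    """

    name: str
    eye_role: str
    profile: ActivationProfile
    n_animals: int

    def __post_init__(self) -> None:
        if self.eye_role not in EYE_ROLES:
            raise ValueError(f"eye_role must be one of {EYE_ROLES}")
        if self.n_animals < 2:
            raise ValueError("n_animals must be >= 2")


@dataclass
class StudyDesign:
    """Layout of a full synthetic multi-group study.

    ``fields_per_retina`` fields per layer are distributed round-robin
    over ``zones`` (the whole-mount protocol scans two crossing meridians;
    the zone × field grid is a documented approximation of that layout).
    """

    groups: list[GroupArm]
    layers: Sequence[str] = ("OS", "OPL", "IPL", "NFL-GCL")
    zones: Sequence[str] = ZONES
    fields_per_retina: int = 8
    seed: int = 0
    geometry: FieldGeometry = dc_field(default_factory=FieldGeometry)
    noise_level: float = 0.005
    background: float = 0.01
    use_stacks: bool = True
    n_sections: int = 5
    z_spacing: float = 2.0
    include_vertical_spots: bool = True
    include_rgc: bool = True
    base_counts: dict | None = None
    rgc_base_count: int = 150
    spot_base_count: int = 12

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("design needs at least one group arm")
        for layer in self.layers:
            if layer not in LAYERS:
                raise ValueError(f"unknown layer {layer!r}")
        for zone in self.zones:
            if zone not in ZONES:
                raise ValueError(f"unknown zone {zone!r}")
        if self.fields_per_retina < 1:
            raise ValueError("fields_per_retina must be >= 1")
        # paired eye-roles must come in matched (name, n_animals) pairs
        by_name: dict[str, set[str]] = {}
        for g in self.groups:
            by_name.setdefault(g.name, set()).add(g.eye_role)
        for g in self.groups:
            roles = by_name[g.name]
            if "OHT" in roles or "contralateral" in roles:
                if roles != {"OHT", "contralateral"}:
                    raise ValueError(
                        f"lasered group {g.name!r} must have exactly the paired "
                        f"eye roles OHT and contralateral, got {sorted(roles)}"
                    )
        for name in by_name:
            ns = {g.n_animals for g in self.groups if g.name == name}
            if len(ns) != 1:
                raise ValueError(f"paired arms of group {name!r} disagree on n_animals")
        if self.base_counts is None:
            # illustrative baseline cells per 0.1502 mm² field
            self.base_counts = {"OS": 18, "OPL": 25, "IPL": 25, "NFL-GCL": 15}

    def fields_in_zone(self, zone_index: int) -> int:
        """Number of fields allotted to a zone (round-robin split)."""
        nz = len(self.zones)
        return self.fields_per_retina // nz + (
            1 if zone_index < self.fields_per_retina % nz else 0
        )


def default_design(seed: int = 0, n_animals: int = 6, **kwargs) -> StudyDesign:
    """The desk-scale default study: naïve (NG) and saffron-control (SCG)
    single-eye groups plus lasered (LG) and saffron + lasered (SLG)
    paired-eye groups, n animals per group."""
    groups = [
        GroupArm("NG", "single", BASELINE_PROFILE, n_animals),
        GroupArm("SCG", "single", BASELINE_PROFILE, n_animals),
        GroupArm("LG", "OHT", OHT_PROFILE, n_animals),
        GroupArm("LG", "contralateral", CONTRA_PROFILE, n_animals),
        GroupArm("SLG", "OHT", SAFFRON_OHT_PROFILE, n_animals),
        GroupArm("SLG", "contralateral", SAFFRON_CONTRA_PROFILE, n_animals),
    ]
    return StudyDesign(groups=groups, seed=seed, **kwargs)
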