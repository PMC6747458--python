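"""Reading and writing fields, stacks, ground truth and configs.

Images are written as single-channel 16-bit TIFF (multi-page for
z-stacks).  Intensities are relative units in roughly [0, 1]; on write
they are scaled to the 16-bit range and the scale is recorded in a JSON
sidecar next to the image, together with the physical calibration and
layer/zone labels, so a read round-trips exactly up to quantization.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .types import CellTruth, Field, ZStack

__all__ = [
    "write_field",
    "read_field",
    "write_stack",
    "read_stack",
    "read_image",
    "truth_to_frame",
    "frame_to_truths",
    "load_config",
    "save_config",
    "TRUTH_COLUMNS",
]

TRUTH_COLUMNS = [
    "group",
    "animal",
    "eye",
    "layer",
    "zone",
    "field",
    "kind",
    "x_um",
    "y_um",
    "soma_radius_um",
    "n_processes",
    "tips_json",
    "peak",
]

_MAX16 = 65535


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def _scale_for(pixels: np.ndarray) -> float:
    peak = float(pixels.max())
    return _MAX16 / peak if peak > 0 else 1.0


def write_field(field: Field, path) -> None:
    path = Path(path)
    scale = _scale_for(field.pixels)
    data = np.round(field.pixels * scale).astype(np.uint16)
    tifffile.imwrite(path, data, photometric="minisblack")
    meta = {
        "pixel_size_um": field.pixel_size,
        "layer": field.layer,
        "zone": field.zone,
        "intensity_scale": scale,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def read_field(path) -> Field:
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    data = tifffile.imread(path).astype(np.float64) / meta["intensity_scale"]
    return Field(data, meta["pixel_size_um"], meta["layer"], meta["zone"])


def write_stack(stack: ZStack, path) -> None:
    path = Path(path)
    all_pix = np.stack([s.pixels for s in stack.sections])
    scale = _scale_for(all_pix)
    tifffile.imwrite(
        path,
        np.round(all_pix * scale).astype(np.uint16),
        photometric="minisblack",
    )
    first = stack.sections[0]
    meta = {
        "pixel_size_um": first.pixel_size,
        "layer": first.layer,
        "zone": first.zone,
        "intensity_scale": scale,
        "z_spacing_um": stack.z_spacing,
        "n_sections": len(stack),
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def read_stack(path) -> ZStack:
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    data = tifffile.imread(path).astype(np.float64) / meta["intensity_scale"]
    if data.ndim == 2:
        data = data[None]
    sections = [
        Field(p, meta["pixel_size_um"], meta["layer"], meta["zone"]) for p in data
    ]
    return ZStack(sections, meta["z_spacing_um"])


def read_image(path) -> Field | ZStack:
    """Read a TIFF as Field or ZStack depending on its sidecar."""
    meta = json.loads(_sidecar(Path(path)).read_text())
    return read_stack(path) if "z_spacing_um" in meta else read_field(path)


def truth_to_frame(rows: list[dict]) -> pd.DataFrame:
    """Assemble ground-truth rows (metadata + CellTruth) into the master
    truth table."""
    records = []
    for row in rows:
        t: CellTruth = row["truth"]
        records.append(
            {
                "group": row["group"],
                "animal": row["animal"],
                "eye": row["eye"],
                "layer": row["layer"],
                "zone": row["zone"],
                "field": row["field"],
                "kind": t.kind,
                "x_um": t.center[0],
                "y_um": t.center[1],
                "soma_radius_um": t.soma_radius,
                "n_processes": t.n_processes,
                "tips_json": json.dumps(
                    [[round(a, 4), round(b, 4)] for a, b in t.process_tips]
                ),
                "peak": t.peak_intensity,
            }
        )
    return pd.DataFrame(records, columns=TRUTH_COLUMNS)


def frame_to_truths(frame: pd.DataFrame) -> list[CellTruth]:
    out = []
    for _, r in frame.iterrows():
        tips = [tuple(p) for p in json.loads(r["tips_json"])]
        out.append(
            CellTruth(
                center=(float(r["x_um"]), float(r["y_um"])),
                soma_radius=float(r["soma_radius_um"]),
                n_processes=int(r["n_processes"]),
                process_tips=tips,
                peak_intensity=float(r["peak"]),
                kind=str(r["kind"]),
            )
        )
    return out


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def save_config(config: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
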