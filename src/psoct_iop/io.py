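"""TIFF + JSON sidecar persistence for volumes, surfaces and en face maps.

A dual-channel volume is stored as two multi-page TIFF stacks (one per
polarization channel, page = B-scan, i.e. page ``y`` holds the ``[z, x]``
cross-section) plus a JSON sidecar with the :class:`VolumeGeometry`. Surfaces
and en face maps are single-page float TIFFs with the same sidecar layout.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import tifffile

from .core import PSVolume, VolumeGeometry
from .quantify import EnFaceMap
from .segment import Surface


def _geometry_to_dict(g: VolumeGeometry) -> dict:
    return dataclasses.asdict(g)


def _geometry_from_dict(d: dict) -> VolumeGeometry:
    return VolumeGeometry(**d)


def save_volume(vol: PSVolume, directory: str | Path, stem: str) -> dict[str, Path]:
    """Write ``<stem>_co.tif``, ``<stem>_cross.tif`` and ``<stem>_geometry.json``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "co": directory / f"{stem}_co.tif",
        "cross": directory / f"{stem}_cross.tif",
        "geometry": directory / f"{stem}_geometry.json",
    }
    # pages along y: [y, z, x]
    tifffile.imwrite(paths["co"], np.moveaxis(vol.amp_co, 2, 0).astype(np.float32))
    tifffile.imwrite(paths["cross"], np.moveaxis(vol.amp_cross, 2, 0).astype(np.float32))
    paths["geometry"].write_text(json.dumps(_geometry_to_dict(vol.geometry), indent=2))
    return paths


def load_volume(directory: str | Path, stem: str) -> PSVolume:
    directory = Path(directory)
    geometry = _geometry_from_dict(
        json.loads((directory / f"{stem}_geometry.json").read_text())
    )
    co = np.moveaxis(tifffile.imread(directory / f"{stem}_co.tif"), 0, 2)
    cross = np.moveaxis(tifffile.imread(directory / f"{stem}_cross.tif"), 0, 2)
    return PSVolume(co, cross, geometry)


def save_surface(surface: Surface, path: str | Path) -> None:
    """Single-page float TIFF; geometry goes to ``<path>.json``."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, surface.z_position.astype(np.float32))
    meta = _geometry_to_dict(surface.geometry) | {"registered": surface.registered}
    Path(str(path) + ".json").write_text(json.dumps(meta, indent=2))


def load_surface(path: str | Path) -> Surface:
    path = Path(path)
    meta = json.loads(Path(str(path) + ".json").read_text())
    registered = bool(meta.pop("registered", False))
    return Surface(
        tifffile.imread(path).astype(float), _geometry_from_dict(meta), registered
    )


def save_scalar_volume(
    values: np.ndarray, geometry: VolumeGeometry, directory: str | Path, stem: str
) -> Path:
    """Write a reconstructed scalar volume (reflectivity or retardation) in the
    same page-per-B-scan TIFF + JSON layout as the dual-channel volumes."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    path = directory / f"{stem}.tif"
    tifffile.imwrite(path, np.moveaxis(values, 2, 0).astype(np.float32))
    (directory / f"{stem}_geometry.json").write_text(
        json.dumps(_geometry_to_dict(geometry), indent=2)
    )
    return path


def load_scalar_volume(directory: str | Path, stem: str) -> tuple[np.ndarray, VolumeGeometry]:
    directory = Path(directory)
    geometry = _geometry_from_dict(
        json.loads((directory / f"{stem}_geometry.json").read_text())
    )
    return np.moveaxis(tifffile.imread(directory / f"{stem}.tif"), 0, 2), geometry


def save_shifts(shifts: np.ndarray, path: str | Path) -> None:
    """Per-B-scan axial motion offsets as CSV (bscan_index, shift_px)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = ["bscan_index,shift_px"] + [
        f"{i},{s:.6g}" for i, s in enumerate(np.asarray(shifts, dtype=float))
    ]
    path.write_text("\n".join(lines) + "\n")


def save_map(emap: EnFaceMap, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, emap.values.astype(np.float32))
    meta = _geometry_to_dict(emap.geometry) | {"units": emap.units}
    Path(str(path) + ".json").write_text(json.dumps(meta, indent=2))
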