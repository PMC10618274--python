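"""File formats: DICOM/TIFF/PNG images, geometry sidecars, config files.

Volumes travel as multi-page TIFF (page 1 = breast support surface) plus a
JSON geometry sidecar holding pixel spacing, slice thickness, compressed
breast thickness, and a run-length encoding of the per-slice breast masks.
Cohorts are plain CSV.  Run configuration is TOML (read with stdlib
tomllib; written with a minimal serializer since no TOML writer ships with
the scientific stack).
"""

from __future__ import annotations

import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import imageio.v3 as iio
import numpy as np
import pydicom
import tifffile

from .detection import segment_breast
from .types import DenseLabelMap, GrayImage2D, ProjectionImage, TomoVolume

__all__ = [
    "RunConfig",
    "read_image",
    "write_volume",
    "write_image",
    "write_labels_png",
    "write_sxy_png",
    "mask_to_rle",
    "mask_from_rle",
]

SIDECAR_SCHEMA = 1


def mask_to_rle(mask: np.ndarray) -> dict[str, Any]:
    """Run-length encode a boolean grid (row-major, starting with a 0-run)."""
    flat = np.asarray(mask, dtype=bool).ravel()
    if flat.size == 0:
        raise ValueError("empty mask")
    change = np.flatnonzero(np.diff(flat)) + 1
    bounds = np.concatenate([[0], change, [flat.size]])
    runs = np.diff(bounds).tolist()
    if flat[0]:
        runs = [0] + runs
    return {"shape": list(mask.shape), "runs": runs}


def mask_from_rle(encoded: dict[str, Any]) -> np.ndarray:
    shape = tuple(encoded["shape"])
    runs = encoded["runs"]
    flat = np.zeros(int(np.prod(shape)), dtype=bool)
    pos, value = 0, False
    for run in runs:
        if value:
            flat[pos : pos + run] = True
        pos += run
        value = not value
    if pos != flat.size:
        raise ValueError("run lengths do not cover the mask")
    return flat.reshape(shape)


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_volume(volume: TomoVolume, path: str | Path) -> Path:
    """Write a volume as multi-page TIFF plus a JSON geometry sidecar."""
    path = Path(path)
    stack = np.clip(np.rint(volume.pixel_stack()), 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, stack)
    sidecar = {
        "schema": SIDECAR_SCHEMA,
        "pixel_spacing_mm": volume.pixel_spacing_mm,
        "slice_thickness_mm": volume.slice_thickness_mm,
        "cbt_mm": volume.cbt_mm,
        "n_slices": volume.n_slices,
        "slice_order": "support_surface_first",
        "masks": [mask_to_rle(s.mask) for s in volume.slices],
    }
    _sidecar_path(path).write_text(json.dumps(sidecar))
    return path


def write_image(image: GrayImage2D, path: str | Path) -> Path:
    """Write a single 2D image (TIFF or PNG) plus its sidecar."""
    path = Path(path)
    pixels = np.clip(np.rint(image.pixels), 0, 65535).astype(np.uint16)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, pixels)
    else:
        iio.imwrite(path, pixels)
    sidecar = {
        "schema": SIDECAR_SCHEMA,
        "pixel_spacing_mm": image.pixel_spacing_mm,
        "masks": [mask_to_rle(image.mask)],
    }
    _sidecar_path(path).write_text(json.dumps(sidecar))
    return path


def _load_sidecar(path: Path, sidecar: Optional[str | Path]) -> dict[str, Any]:
    candidate = Path(sidecar) if sidecar else _sidecar_path(path)
    if not candidate.exists():
        raise FileNotFoundError(
            f"no geometry sidecar for {path}; supply pixel spacing via a JSON sidecar at {candidate}"
        )
    return json.loads(candidate.read_text())


def read_image(
    path: str | Path,
    kind: Optional[str] = None,
    sidecar: Optional[str | Path] = None,
    mask: str = "auto",
) -> GrayImage2D | TomoVolume:
    """Read a 2D image or a volume, with geometry.

    DICOM files carry pixel spacing in their headers; TIFF/PNG need the JSON
    sidecar.  Multi-page TIFF yields a :class:`TomoVolume` ordered from the
    breast support surface (page 1).  ``mask='auto'`` segments the breast
    when the sidecar holds no masks.
    """
    path = Path(path)
    kind = kind or path.suffix.lower().lstrip(".")
    if kind in ("dcm", "dicom"):
        ds = pydicom.dcmread(path)
        if "PixelSpacing" not in ds:
            raise ValueError(f"{path}: DICOM lacks PixelSpacing; cannot derive pixel area")
        spacing = float(ds.PixelSpacing[0])
        pixels = ds.pixel_array.astype(float)
        return GrayImage2D(
            pixels=pixels, mask=segment_breast(pixels), pixel_spacing_mm=spacing
        )

    if kind in ("tif", "tiff"):
        data = tifffile.imread(path)
    elif kind == "png":
        data = np.asarray(iio.imread(path))
    else:
        raise ValueError(f"unsupported image kind {kind!r}")
    meta = _load_sidecar(path, sidecar)
    spacing = float(meta["pixel_spacing_mm"])
    encoded_masks = meta.get("masks")

    def mask_for(i: int, pixels: np.ndarray) -> np.ndarray:
        if encoded_masks and mask != "auto":
            return mask_from_rle(encoded_masks[i])
        if encoded_masks:
            return mask_from_rle(encoded_masks[i])
        return segment_breast(pixels)

    if data.ndim == 2:
        return GrayImage2D(
            pixels=data.astype(float), mask=mask_for(0, data), pixel_spacing_mm=spacing
        )
    if data.ndim != 3:
        raise ValueError(f"{path}: expected 2D image or 3D stack, got shape {data.shape}")
    n_expected = meta.get("n_slices")
    if n_expected is not None and n_expected != data.shape[0]:
        raise ValueError(
            f"{path}: truncated stack ({data.shape[0]} pages, sidecar says {n_expected})"
        )
    slices = [
        GrayImage2D(
            pixels=page.astype(float), mask=mask_for(i, page), pixel_spacing_mm=spacing
        )
        for i, page in enumerate(data)
    ]
    return TomoVolume(
        slices=slices,
        slice_thickness_mm=float(meta.get("slice_thickness_mm", 1.0)),
        cbt_mm=meta.get("cbt_mm"),
    )


def write_labels_png(labelmap: DenseLabelMap, path: str | Path) -> Path:
    """Dense labels as an 8-bit PNG (dense = 255, rest = 0)."""
    path = Path(path)
    iio.imwrite(path, (labelmap.labels.astype(np.uint8) * 255))
    return path


def write_sxy_png(projection: ProjectionImage, path: str | Path) -> Path:
    """Standardized synthetic image s(x,y) rescaled 0-100 -> 0-255, 8-bit."""
    path = Path(path)
    scaled = np.clip(np.rint(projection.s * 2.55), 0, 255).astype(np.uint8)
    iio.imwrite(path, scaled)
    return path


# --- configuration -----------------------------------------------------------


def _toml_value(v: Any) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    if isinstance(v, str):
        return json.dumps(v)
    if isinstance(v, (list, tuple)):
        return "[" + ", ".join(_toml_value(x) for x in v) + "]"
    raise TypeError(f"cannot serialize {type(v)} to TOML")


@dataclass
class RunConfig:
    """Resolved configuration of one end-to-end run.

    Sections are plain dicts mirroring the constructor arguments of
    :class:`~tomodensity.phantom.PhantomSpec`,
    :class:`~tomodensity.detection.DetectionParams`, and
    :class:`~tomodensity.phantom.CohortSpec`; a config round-trips losslessly
    through its TOML file.
    """

    phantom: dict[str, Any] = field(default_factory=dict)
    detection: dict[str, Any] = field(default_factory=dict)
    cohort: dict[str, Any] = field(default_factory=dict)
    seed: int = 0
    out_dir: str = "tomodensity_out"
    log_level: str = "INFO"
    schema: int = SIDECAR_SCHEMA

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        return cls(
            phantom=raw.get("phantom", {}),
            detection=raw.get("detection", {}),
            cohort=raw.get("cohort", {}),
            seed=raw.get("run", {}).get("seed", 0),
            out_dir=raw.get("run", {}).get("out_dir", "tomodensity_out"),
            log_level=raw.get("run", {}).get("log_level", "INFO"),
            schema=raw.get("run", {}).get("schema", SIDECAR_SCHEMA),
        )

    def to_toml(self, path: str | Path) -> Path:
        path = Path(path)
        lines = [
            "[run]",
            f"seed = {_toml_value(self.seed)}",
            f"out_dir = {_toml_value(self.out_dir)}",
            f"log_level = {_toml_value(self.log_level)}",
            f"schema = {_toml_value(self.schema)}",
        ]
        for section in ("phantom", "detection", "cohort"):
            table = getattr(self, section)
            if table:
                lines.append(f"\n[{section}]")
                for k, v in table.items():
                    lines.append(f"{k} = {_toml_value(v)}")
        path.write_text("\n".join(lines) + "\n")
        return path
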