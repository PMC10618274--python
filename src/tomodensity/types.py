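"""Core containers shared across the pipeline.

Coordinate conventions: images are row-major 2D arrays with the origin at
the top-left; volume slices are indexed 1..N starting at the breast support
surface.  Pixel values live on the acquisition's stored 10-bit scale
(0..1023) but are held as floats so that filtered/derived images fit the
same container.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd


@dataclass
class GrayImage2D:
    """A single 2D gray-scale image (DBT slice, C-View, or synthetic mammogram).

    Parameters
    ----------
    pixels : 2D float array on the stored intensity scale.
    mask : boolean breast-area grid, same shape as ``pixels``.
    pixel_spacing_mm : in-plane pixel pitch; DBT acquisitions run roughly
        0.085-0.106 mm.
    """

    pixels: np.ndarray
    mask: np.ndarray
    pixel_spacing_mm: float = 0.1

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2D array")
        if self.pixels.shape != self.mask.shape:
            raise ValueError("pixels and mask must share a shape")
        if not (0.05 < self.pixel_spacing_mm < 0.2):
            raise ValueError(
                f"pixel_spacing_mm={self.pixel_spacing_mm} outside the plausible (0.05, 0.2) mm range"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def pixel_area_mm2(self) -> float:
        """A = spacing^2, the in-plane area of one pixel in mm^2."""
        return self.pixel_spacing_mm**2


@dataclass
class TomoVolume:
    """An ordered stack of reconstructed slices with acquisition geometry.

    Slice i = 1 sits at the breast support surface; slice N is nearest the
    compression paddle.  Slice thickness ``t`` is isotropic (1 mm clinically,
    approximately one slice per mm of compressed breast thickness).
    """

    slices: list[GrayImage2D]
    slice_thickness_mm: float = 1.0
    cbt_mm: Optional[float] = None

    def __post_init__(self) -> None:
        if len(self.slices) < 1:
            raise ValueError("a volume needs at least one slice")
        if self.slice_thickness_mm <= 0:
            raise ValueError("slice thickness must be positive")
        shape = self.slices[0].shape
        for s in self.slices:
            if s.shape != shape:
                raise ValueError("all slices must share a shape")
        if self.cbt_mm is None:
            self.cbt_mm = self.n_slices * self.slice_thickness_mm

    @property
    def n_slices(self) -> int:
        return len(self.slices)

    @property
    def shape(self) -> tuple[int, int]:
        return self.slices[0].shape

    @property
    def pixel_spacing_mm(self) -> float:
        return self.slices[0].pixel_spacing_mm

    @property
    def pixel_area_mm2(self) -> float:
        return self.slices[0].pixel_area_mm2

    def pixel_stack(self) -> np.ndarray:
        """(N, rows, cols) float array of all slice pixels."""
        return np.stack([s.pixels for s in self.slices])

    def mask_stack(self) -> np.ndarray:
        return np.stack([s.mask for s in self.slices])


@dataclass
class DenseLabelMap:
    """Binary dense/non-dense labels for one 2D image.

    ``n_pixels`` is the breast-area pixel count n_i and ``d_pixels`` the
    dense-labeled count d_i; the percent density of the image is
    100 * d_i / n_i.  ``meta`` carries detector diagnostics (per-stage
    reference variances, box counts) when the map came from detection.
    """

    labels: np.ndarray
    mask: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.labels.shape != self.mask.shape:
            raise ValueError("labels and mask must share a shape")
        if np.any(self.labels & ~self.mask):
            raise ValueError("dense labels must lie inside the breast mask")
        if self.mask.sum() == 0:
            raise ValueError("empty breast mask")

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())

    @property
    def d_pixels(self) -> int:
        return int(self.labels.sum())

    @property
    def pd_percent(self) -> float:
        return 100.0 * self.d_pixels / self.n_pixels


@dataclass
class LabeledVolume:
    """Per-slice dense label maps plus the geometry needed for volumetrics."""

    maps: list[DenseLabelMap]
    slice_thickness_mm: float
    pixel_area_mm2: float
    cbt_mm: Optional[float] = None

    def __post_init__(self) -> None:
        if len(self.maps) < 1:
            raise ValueError("a labeled volume needs at least one slice")
        shape = self.maps[0].mask.shape
        for m in self.maps:
            if m.mask.shape != shape:
                raise ValueError("all label maps must share a shape")
        if self.cbt_mm is None:
            self.cbt_mm = len(self.maps) * self.slice_thickness_mm

    @property
    def n_slices(self) -> int:
        return len(self.maps)

    @property
    def n_i(self) -> np.ndarray:
        """Breast-area pixel counts per slice."""
        return np.array([m.n_pixels for m in self.maps], dtype=int)

    @property
    def d_i(self) -> np.ndarray:
        """Dense pixel counts per slice."""
        return np.array([m.d_pixels for m in self.maps], dtype=int)

    @property
    def pd_i(self) -> np.ndarray:
        """Per-slice percent density."""
        return np.array([m.pd_percent for m in self.maps], dtype=float)


@dataclass
class ProjectionImage:
    """Dense labels summed along the slice axis.

    ``proj`` counts, per pixel, in how many slices that location was labeled
    dense (0..N).  ``s`` = 100*proj/N is the standardized synthetic image:
    under a parallel-beam approximation each pixel is the percentage of the
    tissue column above it that is dense.
    """

    proj: np.ndarray
    n_slices: int
    union_mask: np.ndarray

    def __post_init__(self) -> None:
        self.proj = np.asarray(self.proj, dtype=int)
        self.union_mask = np.asarray(self.union_mask, dtype=bool)
        if self.proj.shape != self.union_mask.shape:
            raise ValueError("proj and union_mask must share a shape")
        if self.proj.min() < 0 or self.proj.max() > self.n_slices:
            raise ValueError("projection counts must lie in [0, N]")

    @property
    def s(self) -> np.ndarray:
        """Standardized synthetic image, percent scale [0, 100]."""
        return 100.0 * self.proj / self.n_slices

    @property
    def projected_total(self) -> int:
        """PT: total dense pixel count across the volume."""
        return int(self.proj.sum())

    @property
    def normalized_projected_total(self) -> float:
        """NPT = PT / N, the mean dense pixel count per slice."""
        return self.projected_total / self.n_slices


@dataclass
class DensityPanel:
    """The full per-acquisition measurement vector.

    Volumes in mm^3, PD fields in percent; ``m_vol``/``v_vol`` are the raw
    in-mask pixel mean/SD of the volume, ``m_syn`` the raw mean of the 2D
    synthetic (C-View-like) image, and ``p_at_max`` the normalized depth of
    the slice with the largest PD.
    """

    bv_mm3: float
    dv_mm3: float
    pd_vol: float
    pd_m: float
    m_vol: float
    v_vol: float
    m_syn: float
    pd_syn: float
    pd_central: float
    pd_max: float
    p_at_max: float

    _CSV_COLUMNS = (
        "BV_mm3", "Dv_mm3", "PD_vol", "PD_m", "m_vol", "v_vol",
        "m_syn", "PD_syn", "PD_central", "PD_max", "P_at_max",
    )

    def __post_init__(self) -> None:
        for name in ("pd_vol", "pd_m", "pd_syn", "pd_central", "pd_max"):
            v = getattr(self, name)
            if not (0.0 <= v <= 100.0):
                raise ValueError(f"{name}={v} outside [0, 100]")
        if self.dv_mm3 > self.bv_mm3 + 1e-9:
            raise ValueError("dense volume cannot exceed breast volume")
        if not (1.0 <= self.p_at_max <= 100.0):
            raise ValueError("P_at_max must lie in [1, 100]")

    def to_frame(self) -> pd.DataFrame:
        values = [
            self.bv_mm3, self.dv_mm3, self.pd_vol, self.pd_m, self.m_vol,
            self.v_vol, self.m_syn, self.pd_syn, self.pd_central,
            self.pd_max, self.p_at_max,
        ]
        return pd.DataFrame([values], columns=list(self._CSV_COLUMNS))
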