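"""Volumetric density measures derived from per-slice dense labels.

With N slices of thickness t (mm), pixel area A (mm^2), breast pixel counts
n_i and dense counts d_i per slice:

    BV     = t*A*sum(n_i)                    breast volume
    D_v    = t*A*sum(d_i)                    dense tissue volume
    PD_vol = 100 * sum(d_i) / sum(n_i)       volumetric percent density
    PD_m   = (100/N) * sum(d_i / n_i)        slice-mean percent density

When the breast area is the same in every slice, PD_vol and PD_m coincide
exactly.  Summing the binary labels along the slice axis gives the projected
total PT = N*<d_i>; dividing the projection by N and scaling to percent
yields the standardized synthetic image s(x, y), whose in-mask mean equals
PD_vol for a constant mask.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .detection import DetectionParams, detect_density
from .slice_profile import normalize_depth
from .types import (
    DenseLabelMap,
    DensityPanel,
    GrayImage2D,
    LabeledVolume,
    ProjectionImage,
    TomoVolume,
)

__all__ = [
    "breast_volume",
    "dense_volume",
    "pd_vol",
    "pd_mean",
    "project",
    "raw_stats",
    "slice_extremes",
    "label_volume",
    "labeled_from_truth",
    "density_panel",
]


def breast_volume(labeled: LabeledVolume) -> float:
    """BV = t * A * sum(n_i), in mm^3."""
    n_i = labeled.n_i
    if np.any(n_i == 0):
        raise ValueError("every slice must contain breast pixels")
    return labeled.slice_thickness_mm * labeled.pixel_area_mm2 * float(n_i.sum())


def dense_volume(labeled: LabeledVolume) -> float:
    """D_v = t * A * sum(d_i), in mm^3."""
    return labeled.slice_thickness_mm * labeled.pixel_area_mm2 * float(labeled.d_i.sum())


def pd_vol(labeled: LabeledVolume) -> float:
    """Volumetric percent density 100 * sum(d_i) / sum(n_i)."""
    n_total = labeled.n_i.sum()
    if n_total == 0:
        raise ValueError("zero breast volume")
    return 100.0 * float(labeled.d_i.sum()) / float(n_total)


def pd_mean(labeled: LabeledVolume) -> float:
    """Slice-mean percent density (100/N) * sum(d_i / n_i)."""
    n_i = labeled.n_i
    if np.any(n_i == 0):
        raise ValueError("every slice must contain breast pixels")
    return float(np.mean(100.0 * labeled.d_i / n_i))


def project(labeled: LabeledVolume) -> ProjectionImage:
    """Sum dense labels along the slice axis.

    Pixels outside a slice's breast mask count as non-dense in that slice;
    the projection domain is the union of the slice masks.
    """
    shapes = {m.mask.shape for m in labeled.maps}
    if len(shapes) != 1:
        raise ValueError("misaligned slice shapes")
    stack = np.stack([m.labels for m in labeled.maps])
    proj = stack.sum(axis=0)
    union = np.logical_or.reduce([m.mask for m in labeled.maps])
    return ProjectionImage(proj=proj, n_slices=labeled.n_slices, union_mask=union)


def raw_stats(
    data: TomoVolume | GrayImage2D, mask: Optional[np.ndarray] = None
) -> tuple[float, float]:
    """In-mask pixel mean and unbiased SD, all slices pooled for a volume."""
    if isinstance(data, TomoVolume):
        values = np.concatenate(
            [s.pixels[s.mask if mask is None else mask] for s in data.slices]
        )
    else:
        m = data.mask if mask is None else np.asarray(mask, dtype=bool)
        values = data.pixels[m]
    if values.size == 0:
        raise ValueError("empty mask")
    sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
    return float(values.mean()), sd


def slice_extremes(labeled: LabeledVolume) -> tuple[float, float, float]:
    """(PD of the central slice, maximum per-slice PD, its depth P).

    The central slice is index round((N+1)/2), i.e. normalized depth near
    50; the maximum is taken over all slices and reported with the
    normalized depth at which it occurs.
    """
    pd_i = labeled.pd_i
    n = labeled.n_slices
    central_idx = int(round((n + 1) / 2))
    i_max = int(np.argmax(pd_i)) + 1
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # single-slice depth convention
        p_at_max = normalize_depth(i_max, n)
    return float(pd_i[central_idx - 1]), float(pd_i[i_max - 1]), p_at_max


def label_volume(
    volume: TomoVolume, params: Optional[DetectionParams] = None
) -> LabeledVolume:
    """Run the detector on every slice of a volume.

    Each slice gets an independent noise-field realization, seeded
    reproducibly from ``params.seed`` and the slice index.
    """
    params = params or DetectionParams()
    maps = []
    for i, img in enumerate(volume.slices):
        slice_params = DetectionParams(
            box_n=params.box_n,
            alpha_stage1=params.alpha_stage1,
            alpha_stage2=params.alpha_stage2,
            wavelet_name=params.wavelet_name,
            wavelet_level=params.wavelet_level,
            noise_multiplication=params.noise_multiplication,
            seed=params.seed + i,
        )
        maps.append(detect_density(img, slice_params))
    return LabeledVolume(
        maps=maps,
        slice_thickness_mm=volume.slice_thickness_mm,
        pixel_area_mm2=volume.pixel_area_mm2,
        cbt_mm=volume.cbt_mm,
    )


def labeled_from_truth(volume: TomoVolume, truth) -> LabeledVolume:
    """Build a LabeledVolume from generator ground-truth dense masks."""
    maps = [
        DenseLabelMap(labels=d, mask=m)
        for d, m in zip(truth.dense_masks, truth.breast_masks)
    ]
    return LabeledVolume(
        maps=maps,
        slice_thickness_mm=volume.slice_thickness_mm,
        pixel_area_mm2=volume.pixel_area_mm2,
        cbt_mm=volume.cbt_mm,
    )


def density_panel(
    volume: TomoVolume,
    cview: GrayImage2D,
    params: Optional[DetectionParams] = None,
) -> DensityPanel:
    """Assemble the full measurement vector for one acquisition.

    Runs the detector on every DBT slice and on the 2D synthetic view, then
    computes the volumetric measures, the raw pixel statistics, and the
    central/maximum-slice PD.  Deterministic given ``params.seed``.
    """
    params = params or DetectionParams()
    labeled = label_volume(volume, params)
    syn_map = detect_density(cview, params)
    m_vol, v_vol = raw_stats(volume)
    m_syn, _ = raw_stats(cview)
    pd_central, pd_max, p_at_max = slice_extremes(labeled)
    return DensityPanel(
        bv_mm3=breast_volume(labeled),
        dv_mm3=dense_volume(labeled),
        pd_vol=pd_vol(labeled),
        pd_m=pd_mean(labeled),
        m_vol=m_vol,
        v_vol=v_vol,
        m_syn=m_syn,
        pd_syn=syn_map.pd_percent,
        pd_central=pd_central,
        pd_max=pd_max,
        p_at_max=p_at_max,
    )
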