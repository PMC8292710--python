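"""Functional-lung and planning structures derived from ventilation and tumor masks.

Margin chain: GTV -> iGTV (union over breathing phases) -> CTV (isotropic
6-10 mm, default 8 mm) -> PTV (+5 mm). All expansions are Euclidean in
physical millimetres and clipped to the body. Lung dose statistics use
``lungs - iGTV``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from ventavoid.ventilation import VentilationMap

DEFAULT_CTV_MARGIN_MM = 8.0
DEFAULT_PTV_MARGIN_MM = 5.0
DEFAULT_FUNCTIONAL_THRESHOLD_PCT = 15.0


@dataclass(frozen=True)
class StructureSet:
    """Named binary masks on the planning grid plus margin metadata."""

    masks: dict[str, np.ndarray]
    spacing: tuple[float, float, float]
    margins_mm: dict[str, float] = field(default_factory=dict)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.masks[name]

    def __contains__(self, name: str) -> bool:
        return name in self.masks

    @property
    def names(self) -> list[str]:
        return sorted(self.masks)

    def volume_cc(self, name: str) -> float:
        return float(np.sum(self.masks[name])) * float(np.prod(self.spacing)) / 1000.0


def expand_margin(mask: np.ndarray, margin_mm: float,
                  spacing: tuple[float, float, float],
                  body: np.ndarray | None = None) -> np.ndarray:
    """Isotropic physical-distance dilation via the Euclidean distance transform."""
    if margin_mm < 0:
        raise ValueError(f"margin must be >= 0, got {margin_mm}")
    mask = np.asarray(mask, dtype=bool)
    if margin_mm == 0:
        out = mask.copy()
    else:
        dist = ndimage.distance_transform_edt(~mask, sampling=spacing)
        out = dist <= margin_mm
    if body is not None:
        out &= np.asarray(body, dtype=bool)
    return out


def build_igtv(phase_tumor_masks: list[np.ndarray]) -> np.ndarray:
    """Voxelwise union of the tumor mask over all breathing phases."""
    if not phase_tumor_masks:
        raise ValueError("need at least one phase tumor mask")
    union = np.zeros_like(np.asarray(phase_tumor_masks[0], dtype=bool))
    for m in phase_tumor_masks:
        union |= np.asarray(m, dtype=bool)
    if not np.any(union):
        raise ValueError("union of phase tumor masks is empty")
    return union


def functional_lung_mask(vmap: VentilationMap, lung_mask: np.ndarray,
                         threshold_pct: float = DEFAULT_FUNCTIONAL_THRESHOLD_PCT
                         ) -> np.ndarray:
    """Voxels at or above ``threshold_pct`` percent of the global ventilation
    maximum, restricted to the lung mask."""
    if vmap.percent is None:
        raise ValueError("ventilation map has no percent view; run normalize_to_max")
    out = (vmap.percent >= threshold_pct) & np.asarray(lung_mask, dtype=bool) & vmap.valid
    if not np.any(out):
        warnings.warn("functional lung mask is empty", stacklevel=2)
    return out


def build_structure_set(
    anatomy_masks: dict[str, np.ndarray],
    phase_tumor_masks: list[np.ndarray],
    vmap: VentilationMap,
    spacing: tuple[float, float, float],
    ctv_margin_mm: float = DEFAULT_CTV_MARGIN_MM,
    ptv_margin_mm: float = DEFAULT_PTV_MARGIN_MM,
    functional_threshold_pct: float = DEFAULT_FUNCTIONAL_THRESHOLD_PCT,
    tumor_side: str | None = None,
) -> StructureSet:
    """Derive the full planning structure set.

    ``anatomy_masks`` must contain ``body``, ``lung_left``, ``lung_right``,
    ``gtv`` and any OARs (``esophagus``, ``heart``, ``cord``). The functional
    lung is decomposed into optimization substructures: functional minus PTV
    and two rings at 0-10 mm and 10-30 mm from the PTV.
    """
    body = np.asarray(anatomy_masks["body"], dtype=bool)
    gtv = np.asarray(anatomy_masks["gtv"], dtype=bool)
    lung_l = np.asarray(anatomy_masks["lung_left"], dtype=bool)
    lung_r = np.asarray(anatomy_masks["lung_right"], dtype=bool)

    igtv = build_igtv(phase_tumor_masks) | gtv
    ctv = expand_margin(igtv, ctv_margin_mm, spacing, body=body)
    ptv = expand_margin(ctv, ptv_margin_mm, spacing, body=body)

    lungs = lung_l | lung_r
    if tumor_side is None:
        overlap_r = np.sum(expand_margin(gtv, 20.0, spacing) & lung_r)
        overlap_l = np.sum(expand_margin(gtv, 20.0, spacing) & lung_l)
        tumor_side = "right" if overlap_r >= overlap_l else "left"
    ipsi = lung_r if tumor_side == "right" else lung_l
    contra = lung_l if tumor_side == "right" else lung_r

    # lung dose statistics exclude the moving tumor envelope
    lungs_eval = lungs & ~igtv
    functional = functional_lung_mask(vmap, lungs, functional_threshold_pct) & ~igtv

    ring_inner = expand_margin(ptv, 10.0, spacing, body=body) & ~ptv
    ring_outer = expand_margin(ptv, 30.0, spacing, body=body) & ~expand_margin(
        ptv, 10.0, spacing, body=body
    )

    masks = {
        "body": body,
        # hotspot control region for the optimizer: the prescription isodose
        # cannot physically reach far from the target, so the global-max
        # objective only needs rows here
        "hotspot_region": expand_margin(ptv, 40.0, spacing, body=body),
        "gtv": gtv,
        "igtv": igtv,
        "ctv": ctv,
        "ptv": ptv,
        "lungs": lungs_eval,
        "lung_ipsi": ipsi & ~igtv,
        "lung_contra": contra & ~igtv,
        "functional_lung": functional,
        "functional_ipsi": functional & ipsi,
        "functional_contra": functional & contra,
        "functional_minus_ptv": functional & ~ptv,
        "functional_ring_0_10": functional & ring_inner,
        "functional_ring_10_30": functional & ring_outer,
    }
    for name in ("esophagus", "heart", "cord"):
        if name in anatomy_masks:
            masks[name] = np.asarray(anatomy_masks[name], dtype=bool)

    return StructureSet(
        masks=masks, spacing=tuple(spacing),
        margins_mm={"ctv": ctv_margin_mm, "ptv": ptv_margin_mm,
                    "functional_threshold_pct": functional_threshold_pct},
    )
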