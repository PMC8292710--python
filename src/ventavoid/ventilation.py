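"""HU-based fractional ventilation imaging and the regional eligibility screen.

The per-voxel ventilation of a mapped exhale/inhale voxel pair is

    1000 * (HU_in - HU_ex) / (HU_ex * (1000 + HU_in))

evaluated on the peak-exhale grid, with the inhale HU sampled trilinearly at
the displaced coordinate. A value of 0 means no volume change; 1.0 means the
voxel air volume doubled from exhale to inhale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from ventavoid.core import DisplacementField, ImageGrid

LUNG_SIDES = ("left", "right")
LUNG_THIRDS = ("superior", "middle", "inferior")
REGION_LABELS = tuple((s, t) for s in LUNG_SIDES for t in LUNG_THIRDS)


@dataclass(frozen=True)
class VentilationMap:
    """Per-voxel fractional ventilation on the peak-exhale grid."""

    values: np.ndarray
    valid: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    percent: np.ndarray | None = None   # percent-of-global-max view
    global_max: float | None = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        valid = np.asarray(self.valid, dtype=bool)
        if values.shape != valid.shape:
            raise ValueError("values and validity mask shapes differ")
        if not np.all(np.isfinite(values[valid])):
            raise ValueError("non-finite ventilation inside the validity mask")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "valid", valid)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def as_grid(self) -> ImageGrid:
        return ImageGrid(self.values, self.spacing, self.origin)


@dataclass(frozen=True)
class RegionalProfile:
    """Ventilation share and volume of the six lung regions (L/R x thirds)."""

    shares_pct: dict[tuple[str, str], float]
    volumes_mm3: dict[tuple[str, str], float]

    @property
    def total_volume_mm3(self) -> float:
        return float(sum(self.volumes_mm3.values()))

    def expected_share_pct(self, region: tuple[str, str]) -> float:
        """Volume-weighted share this region would carry if ventilation were uniform."""
        return 100.0 * self.volumes_mm3[region] / self.total_volume_mm3


@dataclass(frozen=True)
class EligibilityResult:
    eligible: bool
    deficits_pct: dict[tuple[str, str], float]
    threshold_pct: float

    @property
    def worst_region(self) -> tuple[str, str]:
        return max(self.deficits_pct, key=self.deficits_pct.get)


def segment_lungs(ct: ImageGrid, hu_window: tuple[float, float] = (-1000.0, -250.0),
                  exclusions: list[np.ndarray] | None = None,
                  closing_mm: float = 5.0) -> dict[str, np.ndarray]:
    """Intensity-based lung segmentation split left/right by the x midline.

    Thresholds the HU window, discards air connected to the volume border
    (outside-patient air) and small components, keeps the two largest
    candidates, and closes small holes.
    """
    lo, hi = hu_window
    cand = (ct.data >= lo) & (ct.data <= hi)

    labels, n = ndimage.label(cand)
    if n == 0:
        raise ValueError("no voxels inside the lung HU window; adjust hu_window")
    border = np.zeros(ct.shape, dtype=bool)
    border[[0, -1], :, :] = border[:, [0, -1], :] = border[:, :, [0, -1]] = True
    border_labels = np.unique(labels[border & cand])
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    order = np.argsort(sizes)[::-1] + 1
    keep = [lab for lab in order if lab not in border_labels][:2]
    if len(keep) < 2:
        raise ValueError(
            "fewer than 2 interior components found in the HU window; "
            "adjust hu_window or check the volume"
        )

    structure = None
    if closing_mm > 0:
        rad = [max(1, int(round(closing_mm / s))) for s in ct.spacing]
        zz, yy, xx = np.mgrid[-rad[0]:rad[0] + 1, -rad[1]:rad[1] + 1, -rad[2]:rad[2] + 1]
        structure = (zz / rad[0]) ** 2 + (yy / rad[1]) ** 2 + (xx / rad[2]) ** 2 <= 1.0

    masks = []
    for lab in keep:
        m = labels == lab
        if structure is not None:
            m = ndimage.binary_closing(m, structure=structure)
        masks.append(m)
    for excl in exclusions or []:
        masks = [m & ~excl for m in masks]

    # order by centroid x: smaller x = "left"
    cx = [ndimage.center_of_mass(m)[2] for m in masks]
    left, right = (masks[0], masks[1]) if cx[0] < cx[1] else (masks[1], masks[0])
    return {"left": left, "right": right}


def compute_ventilation(exhale: ImageGrid, inhale: ImageGrid, dvf: DisplacementField,
                        mask: np.ndarray, eps_hu: float = 1.0) -> VentilationMap:
    """Fractional ventilation over ``mask`` using the exhale-to-inhale field.

    Voxels with a near-singular denominator (|HU_ex| < ``eps_hu`` or
    |1000 + HU_in| < ``eps_hu``) are flagged invalid and excluded from all
    downstream statistics.
    """
    if not exhale.same_geometry(dvf):
        raise ValueError("displacement field geometry does not match the exhale grid")
    if not exhale.same_geometry(inhale):
        raise ValueError("inhale grid geometry does not match the exhale grid")
    mask = np.asarray(mask, dtype=bool)

    hu_ex = exhale.data
    hu_in = np.zeros(exhale.shape)
    pts = dvf.displaced_coordinates()[:, mask]
    hu_in[mask] = inhale.sample(pts)

    singular = (np.abs(hu_ex) < eps_hu) | (np.abs(1000.0 + hu_in) < eps_hu)
    valid = mask & ~singular
    values = np.zeros(exhale.shape)
    values[valid] = (
        1000.0 * (hu_in[valid] - hu_ex[valid])
        / (hu_ex[valid] * (1000.0 + hu_in[valid]))
    )
    return VentilationMap(values=values, valid=valid, spacing=exhale.spacing,
                          origin=exhale.origin)


def parenchyma_mask(ct: ImageGrid, lung_mask: np.ndarray,
                    hu_max: float = -250.0, erosion_voxels: int = 2) -> np.ndarray:
    """Aerated parenchyma suitable for ventilation statistics.

    Drops vessel-like (dense) voxels and erodes away partial-volume
    boundaries so displaced-point sampling stays inside parenchyma.
    """
    paren = np.asarray(lung_mask, dtype=bool) & (ct.data <= hu_max)
    return interior_lung_mask(paren, erosion_voxels)


def interior_lung_mask(mask: np.ndarray, voxels: int = 2) -> np.ndarray:
    """Erode a lung mask to drop partial-volume boundary voxels.

    Boundary voxels mix parenchymal and chest-wall/mediastinal HU when the
    inhale volume is sampled at displaced coordinates, which corrupts the
    ventilation ratio there; the pipeline computes ventilation statistics on
    this interior mask.
    """
    if voxels <= 0:
        return np.asarray(mask, dtype=bool)
    return ndimage.binary_erosion(np.asarray(mask, dtype=bool), iterations=voxels)


def ventilation_pair_value(hu_ex: float, hu_in: float) -> float:
    """Scalar form of the ventilation expression for a single mapped pair."""
    return 1000.0 * (hu_in - hu_ex) / (hu_ex * (1000.0 + hu_in))


def normalize_to_max(vmap: VentilationMap) -> VentilationMap:
    """Populate the percent-of-global-max view (negatives clipped to 0 first)."""
    if not np.any(vmap.valid):
        raise ValueError("no valid voxels to normalize")
    clipped = np.where(vmap.valid, np.maximum(vmap.values, 0.0), 0.0)
    gmax = float(np.max(clipped))
    if gmax <= 0.0:
        raise ValueError("global ventilation maximum is not positive; cannot normalize")
    return replace(vmap, percent=100.0 * clipped / gmax, global_max=gmax)


def _third_slabs(mask: np.ndarray) -> list[np.ndarray]:
    """Split a lung mask into three equal cranio-caudal slabs of its bounding box."""
    zs = np.where(np.any(mask, axis=(1, 2)))[0]
    z0, z1 = int(zs[0]), int(zs[-1]) + 1
    if z1 - z0 < 3:
        raise ValueError("lung spans fewer than 3 slices; cannot form thirds")
    edges = np.round(np.linspace(z0, z1, 4)).astype(int)
    slabs = []
    for k in range(3):
        slab = np.zeros_like(mask)
        slab[edges[k]:edges[k + 1]] = mask[edges[k]:edges[k + 1]]
        slabs.append(slab)
    return slabs


def regional_profile(vmap: VentilationMap, lung_masks: dict[str, np.ndarray]
                     ) -> RegionalProfile:
    """Percent ventilation carried by each third of each lung.

    Negative values are clipped to zero before summation; shares are percent
    of the total over all six regions and sum to 100.
    """
    voxel_volume = float(np.prod(vmap.spacing))
    clipped = np.where(vmap.valid, np.maximum(vmap.values, 0.0), 0.0)

    sums: dict[tuple[str, str], float] = {}
    volumes: dict[tuple[str, str], float] = {}
    for side in LUNG_SIDES:
        mask = np.asarray(lung_masks[side], dtype=bool)
        if not np.any(mask):
            raise ValueError(f"{side} lung mask is empty")
        for third, slab in zip(LUNG_THIRDS, _third_slabs(mask)):
            if not np.any(slab):
                raise ValueError(f"{side}/{third} region is empty")
            sums[(side, third)] = float(np.sum(clipped[slab]))
            volumes[(side, third)] = float(np.sum(slab)) * voxel_volume

    total = sum(sums.values())
    if total <= 0:
        raise ValueError("total ventilation is zero; no regional profile")
    shares = {region: 100.0 * s / total for region, s in sums.items()}
    return RegionalProfile(shares_pct=shares, volumes_mm3=volumes)


def screen_eligibility(profile: RegionalProfile, deficit_threshold_pct: float = 15.0
                       ) -> EligibilityResult:
    """Flag the case eligible when any region falls >= threshold percentage
    points below its volume-weighted expected ventilation share."""
    deficits = {
        region: profile.expected_share_pct(region) - share
        for region, share in profile.shares_pct.items()
    }
    eligible = max(deficits.values()) >= deficit_threshold_pct
    return EligibilityResult(eligible=eligible, deficits_pct=deficits,
                             threshold_pct=deficit_threshold_pct)
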