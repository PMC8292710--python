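"""Analytic scanned-proton pencil-beam dose model.

Replaces a clinical TPS/Monte-Carlo engine with a linear, scenario-aware
stand-in: a power-law range curve ``R(E) = 0.022 * E**1.77`` (mm, E in MeV)
with Gaussian range-straggled Bragg peaks, a lateral Gaussian whose in-air
sigma interpolates log-linearly between the machine's printed endpoints and
grows with depth as ``sigma^2 = sigma_air^2 + (k * wepl)^2``.

Beams are axis-aligned in the axial plane (gantry multiples of 90 degrees),
which lets water-equivalent depth be accumulated by a cumulative trapezoid
along the beam axis for the whole CT at once.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage, sparse

from ventavoid.core import ImageGrid

RANGE_ALPHA_MM = 0.022      # 0.0022 cm * MeV^-p expressed in mm
RANGE_EXPONENT = 1.77
STRAGGLING_FRACTION = 0.012  # sigma of range straggling as fraction of range


# --------------------------------------------------------------------------
# machine model
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class MachineModel:
    """Synchrotron spot-scanning machine description."""

    energies_mev: np.ndarray
    sigma_low_mm: float = 5.7
    sigma_high_mm: float = 2.5
    max_mu_per_spot: float = 5.0
    mu_rate_per_s: float = 100.0
    spot_switch_s: float = 0.002
    layer_switch_s: float = 2.0
    sigma_growth_per_mm: float = 0.03   # k in sigma^2 = sigma_air^2 + (k wepl)^2
    gy_per_mu_at_peak: float = 0.01     # reference spot: 1 Gy[RBE] per 100 MU

    def __post_init__(self) -> None:
        e = np.asarray(self.energies_mev, dtype=np.float64)
        if e.ndim != 1 or len(e) < 2 or np.any(np.diff(e) <= 0):
            raise ValueError("energies must be a strictly increasing 1D list")
        object.__setattr__(self, "energies_mev", e)

    @property
    def n_energies(self) -> int:
        return len(self.energies_mev)

    @property
    def e_min(self) -> float:
        return float(self.energies_mev[0])

    @property
    def e_max(self) -> float:
        return float(self.energies_mev[-1])

    def sigma_air_mm(self, energy_mev: np.ndarray | float) -> np.ndarray | float:
        """In-air sigma at isocenter, log-linear between the two endpoints."""
        e = np.asarray(energy_mev, dtype=np.float64)
        b = np.log(self.sigma_high_mm / self.sigma_low_mm) / np.log(self.e_max / self.e_min)
        out = self.sigma_low_mm * (e / self.e_min) ** b
        return float(out) if np.isscalar(energy_mev) else out

    def range_mm(self, energy_mev: np.ndarray | float) -> np.ndarray | float:
        return RANGE_ALPHA_MM * np.asarray(energy_mev, dtype=np.float64) ** RANGE_EXPONENT


def default_machine_model(**overrides) -> MachineModel:
    """97 energies geometrically spaced over 71.3-228.8 MeV."""
    energies = np.geomspace(71.3, 228.8, 97)
    return MachineModel(energies_mev=energies, **overrides)


# --------------------------------------------------------------------------
# stopping power and depth dose
# --------------------------------------------------------------------------


def hu_to_rsp(hu: np.ndarray | float) -> np.ndarray | float:
    """Piecewise-linear HU to relative-stopping-power mapping.

    Water (0 HU) maps to 1.0, air (-1000 HU) to 0.0; values below -1000 are
    clamped with a warning.
    """
    arr = np.asarray(hu, dtype=np.float64)
    if np.any(arr < -1000.0):
        warnings.warn("HU below -1000 clamped to air", stacklevel=2)
        arr = np.maximum(arr, -1000.0)
    rsp = np.where(arr <= 0.0, 1.0 + arr / 1000.0, 1.0 + arr / 1024.0 * 0.5)
    return float(rsp) if np.isscalar(hu) else rsp


class _BraggCache:
    """Per-energy normalized depth-dose tables (peak 1 at exactly R(E))."""

    def __init__(self) -> None:
        self._tables: dict[float, tuple[np.ndarray, np.ndarray]] = {}

    def table(self, energy_mev: float) -> tuple[np.ndarray, np.ndarray]:
        key = round(float(energy_mev), 3)
        if key not in self._tables:
            r = RANGE_ALPHA_MM * key**RANGE_EXPONENT
            sig = max(STRAGGLING_FRACTION * r, 0.3)
            dz = 0.25
            z = np.arange(0.0, r + 10.0 * sig + 20.0, dz)
            depth_left = np.maximum(r - z, 0.05)
            pristine = np.where(z < r, depth_left ** (1.0 / RANGE_EXPONENT - 1.0), 0.0)
            half = int(np.ceil(4.0 * sig / dz))
            kz = np.arange(-half, half + 1) * dz
            kernel = np.exp(-0.5 * (kz / sig) ** 2)
            kernel /= kernel.sum()
            smooth = np.convolve(pristine, kernel, mode="same")
            smooth /= smooth.max()
            # anchor the peak exactly at R(E)
            z_shifted = z + (r - z[int(np.argmax(smooth))])
            self._tables[key] = (z_shifted, smooth)
        return self._tables[key]


_BRAGG = _BraggCache()


def bragg_depth_dose(energy_mev: float, wepl_mm: np.ndarray | float
                     ) -> np.ndarray | float:
    """Normalized (unit-peak) Bragg depth dose at water-equivalent depth."""
    w = np.asarray(wepl_mm, dtype=np.float64)
    if np.any(w < 0):
        raise ValueError("wepl must be >= 0")
    z, d = _BRAGG.table(energy_mev)
    out = np.interp(w, z, d, left=d[0], right=0.0)
    return float(out) if np.isscalar(wepl_mm) else out


def wepl_along_ray(ct: ImageGrid, entry_mm: np.ndarray, direction: np.ndarray,
                   step_mm: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative water-equivalent depth sampled every ``step_mm`` along a ray.

    Returns ``(arc_lengths, cumulative_wepl)``; empty arrays when the ray
    never crosses the grid.
    """
    direction = np.asarray(direction, dtype=np.float64)
    direction = direction / np.linalg.norm(direction)
    entry = np.asarray(entry_mm, dtype=np.float64)
    extent = np.asarray(ct.origin) + np.asarray(ct.spacing) * (np.asarray(ct.shape) - 1)
    n_max = int(np.ceil(np.linalg.norm(extent - np.asarray(ct.origin)) / step_mm)) + 2
    s = np.arange(n_max) * step_mm
    pts = entry[:, None] + direction[:, None] * s[None]
    inside = np.all((pts >= np.asarray(ct.origin)[:, None] - 1e-9)
                    & (pts <= extent[:, None] + 1e-9), axis=0)
    if not np.any(inside):
        return np.empty(0), np.empty(0)
    last = np.where(inside)[0][-1]
    s = s[: last + 1]
    rsp = np.maximum(hu_to_rsp(ct.sample(pts[:, : last + 1], fill=-1000.0)), 0.0)
    w = np.zeros_like(s)
    w[1:] = np.cumsum((rsp[:-1] + rsp[1:]) * 0.5 * step_mm)
    return s, w


# --------------------------------------------------------------------------
# beams, spots, scenarios
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Beam:
    """Axis-aligned treatment field (gantry multiples of 90 degrees).

    Gantry 0 enters anterior (+y travel), 90 from the patient's right
    (+x travel), 180 posterior (-y), 270 from the left (-x).
    """

    gantry_deg: float

    def __post_init__(self) -> None:
        if self.gantry_deg % 90 != 0:
            raise ValueError("only axis-aligned gantry angles (multiples of 90) are supported")

    @property
    def axis(self) -> int:
        """Grid axis the beam travels along (1 = y, 2 = x)."""
        return 1 if self.gantry_deg % 180 == 0 else 2

    @property
    def forward(self) -> bool:
        """True when the beam travels in the +axis direction."""
        return self.gantry_deg % 360 in (0, 90)

    @property
    def lateral_axes(self) -> tuple[int, int]:
        return (0, 2) if self.axis == 1 else (0, 1)


@dataclass(frozen=True)
class Scenario:
    """Setup shift (mm, grid axes z/y/x) and proton range scale factor."""

    shift_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    range_scale: float = 1.0

    @property
    def is_nominal(self) -> bool:
        return self.range_scale == 1.0 and all(s == 0.0 for s in self.shift_mm)


@dataclass
class SpotPlan:
    """Beams, energy layers and weighted spots of a scanned-proton plan."""

    beams: list[Beam]
    spot_beam: np.ndarray       # (n,) beam index
    spot_energy: np.ndarray     # (n,) MeV
    spot_lat: np.ndarray        # (n, 2) physical mm along the beam's lateral axes
    weights: np.ndarray         # (n,) MU
    prescription_gy: float
    n_fractions: int = 1
    repaints: np.ndarray | None = None   # (n,) paint multiplicity after repainting

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if np.any(self.weights < 0):
            raise ValueError("spot weights must be >= 0")

    @property
    def n_spots(self) -> int:
        return len(self.weights)

    def layers(self) -> list[tuple[int, float, np.ndarray]]:
        """Energy layers as (beam index, energy, spot indices), beam-major,
        high energy delivered first within each beam."""
        out = []
        for b in range(len(self.beams)):
            sel = np.where(self.spot_beam == b)[0]
            for e in sorted(set(self.spot_energy[sel]), reverse=True):
                out.append((b, float(e), sel[self.spot_energy[sel] == e]))
        return out

    def with_weights(self, weights: np.ndarray) -> "SpotPlan":
        plan = SpotPlan(
            beams=self.beams, spot_beam=self.spot_beam, spot_energy=self.spot_energy,
            spot_lat=self.spot_lat, weights=np.asarray(weights, dtype=np.float64),
            prescription_gy=self.prescription_gy, n_fractions=self.n_fractions,
            repaints=self.repaints,
        )
        return plan


# --------------------------------------------------------------------------
# dose computation
# --------------------------------------------------------------------------


def beam_wepl_volume(ct: ImageGrid, beam: Beam, range_scale: float = 1.0
                     ) -> np.ndarray:
    """Water-equivalent depth of every voxel along the beam axis.

    Range uncertainty is applied by dividing the accumulated WEPL by
    ``range_scale`` (scale > 1 means protons penetrate deeper).
    """
    rsp = np.maximum(hu_to_rsp(ct.data), 0.0)
    axis = beam.axis
    step = ct.spacing[axis]
    if not beam.forward:
        rsp = np.flip(rsp, axis=axis)
    pad = np.concatenate([np.zeros_like(np.take(rsp, [0], axis=axis)), rsp], axis=axis)
    mid = (np.take(pad, range(0, ct.shape[axis]), axis=axis)
           + np.take(pad, range(1, ct.shape[axis] + 1), axis=axis)) * 0.5
    w = np.cumsum(mid, axis=axis) * step
    if not beam.forward:
        w = np.flip(w, axis=axis)
    return w / range_scale


def spot_dose(ct: ImageGrid, beam: Beam, energy_mev: float,
              lat_mm: tuple[float, float], machine: MachineModel,
              range_scale: float = 1.0, wepl: np.ndarray | None = None,
              cutoff: float = 1e-4,
              bbox: tuple[slice, slice, slice] | None = None
              ) -> tuple[np.ndarray, np.ndarray]:
    """Sparse dose column of one spot: (voxel linear indices, Gy[RBE] per MU).

    ``dose = gy_per_mu_at_peak * bragg(E, wepl) * exp(-r^2 / 2 sigma^2)
    * (sigma_peak / sigma)^2`` — the last factor conserves the lateral
    integral as the Gaussian widens with depth.
    """
    if wepl is None:
        wepl = beam_wepl_volume(ct, beam, range_scale)
    r_mm = float(machine.range_mm(energy_mev))
    sigma_air = float(machine.sigma_air_mm(energy_mev))
    k = machine.sigma_growth_per_mm
    sigma_peak2 = sigma_air**2 + (k * r_mm) ** 2

    la, lb = beam.lateral_axes
    coords = [np.asarray(ct.origin[a]) + ct.spacing[a] * np.arange(ct.shape[a])
              for a in range(3)]
    sigma_max = np.sqrt(sigma_peak2)
    in_a = np.abs(coords[la] - lat_mm[0]) <= 3.5 * sigma_max
    in_b = np.abs(coords[lb] - lat_mm[1]) <= 3.5 * sigma_max
    if bbox is not None:
        keep_a = np.zeros_like(in_a)
        keep_a[bbox[la]] = True
        keep_b = np.zeros_like(in_b)
        keep_b[bbox[lb]] = True
        in_a &= keep_a
        in_b &= keep_b
    sel_a = np.where(in_a)[0]
    sel_b = np.where(in_b)[0]
    if sel_a.size == 0 or sel_b.size == 0:
        if bbox is None:
            warnings.warn("spot axis misses the grid; zero contribution", stacklevel=2)
        return np.empty(0, dtype=np.int64), np.empty(0)

    slicer = [slice(None)] * 3
    slicer[la] = slice(sel_a[0], sel_a[-1] + 1)
    slicer[lb] = slice(sel_b[0], sel_b[-1] + 1)
    if bbox is not None:
        slicer[beam.axis] = bbox[beam.axis]
    w_box = wepl[tuple(slicer)]

    depth_ok = w_box <= r_mm + 20.0
    bragg = bragg_depth_dose(energy_mev, np.where(depth_ok, w_box, 0.0)) * depth_ok

    da = (coords[la][sel_a] - lat_mm[0]).reshape([sel_a.size if i == la else 1 for i in range(3)])
    db = (coords[lb][sel_b] - lat_mm[1]).reshape([sel_b.size if i == lb else 1 for i in range(3)])
    r2 = da**2 + db**2
    sigma2 = sigma_air**2 + (k * w_box) ** 2
    dose = (machine.gy_per_mu_at_peak * bragg
            * np.exp(-0.5 * r2 / sigma2) * (sigma_peak2 / sigma2))

    keep = dose > cutoff * machine.gy_per_mu_at_peak
    if not np.any(keep):
        return np.empty(0, dtype=np.int64), np.empty(0)
    box_idx = np.nonzero(keep)
    offsets = [0, 0, 0]
    offsets[la], offsets[lb] = sel_a[0], sel_b[0]
    if bbox is not None and bbox[beam.axis].start:
        offsets[beam.axis] = bbox[beam.axis].start
    lin = np.ravel_multi_index(
        tuple(box_idx[d] + offsets[d] for d in range(3)), ct.shape
    )
    return lin, dose[keep]


def compute_dose_volume(ct: ImageGrid, plan: SpotPlan, machine: MachineModel,
                        weights: np.ndarray | None = None,
                        scenario: Scenario | None = None,
                        spot_subset: np.ndarray | None = None) -> ImageGrid:
    """Dense accumulated dose (Gy[RBE]) for the plan under a scenario.

    Memory-friendly alternative to a full-grid influence matrix: spot
    columns are accumulated directly. ``spot_subset`` restricts to selected
    spot indices (used by the interplay simulation's per-phase deposits).
    """
    scenario = scenario or Scenario()
    weights = plan.weights if weights is None else np.asarray(weights, dtype=np.float64)

    shift_vox = np.round(np.asarray(scenario.shift_mm) / np.asarray(ct.spacing)).astype(int)
    ct_beam = ct if not np.any(shift_vox != 0) else ct.with_data(
        ndimage.shift(ct.data, shift_vox, order=0, cval=-1000.0)
    )
    wepls = {b: beam_wepl_volume(ct_beam, beam, scenario.range_scale)
             for b, beam in enumerate(plan.beams)}

    dose = np.zeros(int(np.prod(ct.shape)))
    indices = range(plan.n_spots) if spot_subset is None else np.asarray(spot_subset)
    for s in indices:
        if weights[s] == 0.0:
            continue
        beam_idx = int(plan.spot_beam[s])
        lin, d = spot_dose(ct_beam, plan.beams[beam_idx], float(plan.spot_energy[s]),
                           tuple(plan.spot_lat[s]), machine,
                           range_scale=scenario.range_scale, wepl=wepls[beam_idx])
        np.add.at(dose, lin, weights[s] * d)
    dose = dose.reshape(ct.shape)
    if np.any(shift_vox != 0):
        dose = ndimage.shift(dose, -shift_vox, order=0, cval=0.0)
    return ct.with_data(dose)


@dataclass(frozen=True)
class InfluenceMatrix:
    """Sparse spot-to-voxel dose operator for one scenario.

    ``matrix`` is (n_rows, n_spots) in Gy[RBE] per MU; ``voxel_indices``
    maps rows to linear grid indices (None = all voxels in C order).
    """

    matrix: sparse.csc_matrix
    shape3d: tuple[int, int, int]
    voxel_indices: np.ndarray | None
    scenario: Scenario

    def compose(self, weights: np.ndarray) -> np.ndarray:
        """Dose vector (rows) for the given spot weights."""
        return np.asarray(self.matrix @ np.asarray(weights, dtype=np.float64)).ravel()

    def compose_volume(self, weights: np.ndarray) -> np.ndarray:
        """Full 3D dose grid (only for full-grid influence)."""
        if self.voxel_indices is not None:
            raise ValueError("influence is restricted to a voxel subset")
        return self.compose(weights).reshape(self.shape3d)


def build_influence(ct: ImageGrid, plan: SpotPlan, machine: MachineModel,
                    scenario: Scenario | None = None,
                    voxel_subset: np.ndarray | None = None) -> InfluenceMatrix:
    """Influence matrix of all plan spots under a setup/range scenario.

    Setup shift: the CT content is translated so the beam sees the displaced
    patient, and the resulting dose indices are translated back to the
    patient frame. Shifts are applied in whole voxels (nearest rounding).
    ``voxel_subset`` (boolean mask) restricts rows to masked voxels.
    """
    scenario = scenario or Scenario()
    if plan.n_spots == 0:
        raise ValueError("plan has no spots")

    shift_vox = np.round(np.asarray(scenario.shift_mm) / np.asarray(ct.spacing)).astype(int)
    if np.any(shift_vox != 0):
        data = ndimage.shift(ct.data, shift_vox, order=0, cval=-1000.0)
        ct_beam = ct.with_data(data)
    else:
        ct_beam = ct

    wepls = {b: beam_wepl_volume(ct_beam, beam, scenario.range_scale)
             for b, beam in enumerate(plan.beams)}

    row_map = None
    bbox = None
    if voxel_subset is not None:
        subset_mask = np.asarray(voxel_subset, dtype=bool)
        flat = subset_mask.ravel()
        row_map = np.full(flat.size, -1, dtype=np.int64)
        subset_idx = np.where(flat)[0]
        row_map[subset_idx] = np.arange(subset_idx.size)
        n_rows = subset_idx.size
        # restrict dose evaluation to the subset bounding box (beam frame)
        where = np.where(subset_mask)
        bbox = tuple(
            slice(max(int(where[a].min()) + shift_vox[a] - 1, 0),
                  min(int(where[a].max()) + shift_vox[a] + 2, ct.shape[a]))
            for a in range(3)
        )
    else:
        subset_idx = None
        n_rows = int(np.prod(ct.shape))

    cols, rows, vals = [], [], []
    for s in range(plan.n_spots):
        beam = plan.beams[int(plan.spot_beam[s])]
        lin, dose = spot_dose(
            ct_beam, beam, float(plan.spot_energy[s]),
            tuple(plan.spot_lat[s]), machine,
            range_scale=scenario.range_scale, wepl=wepls[int(plan.spot_beam[s])],
            bbox=bbox,
        )
        if np.any(shift_vox != 0) and lin.size:
            # translate dose back to the patient frame
            zyx = np.stack(np.unravel_index(lin, ct.shape))
            zyx -= shift_vox[:, None]
            ok = np.all((zyx >= 0) & (zyx < np.asarray(ct.shape)[:, None]), axis=0)
            lin = np.ravel_multi_index(tuple(zyx[:, ok]), ct.shape)
            dose = dose[ok]
        if row_map is not None and lin.size:
            r = row_map[lin]
            ok = r >= 0
            lin, dose = r[ok], dose[ok]
        rows.append(lin)
        vals.append(dose)
        cols.append(np.full(lin.size, s, dtype=np.int64))

    matrix = sparse.csc_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n_rows, plan.n_spots),
    )
    return InfluenceMatrix(matrix=matrix, shape3d=ct.shape,
                           voxel_indices=subset_idx, scenario=scenario)
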