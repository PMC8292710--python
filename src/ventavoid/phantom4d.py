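"""Synthetic deformable 4DCT lung phantom with analytic ground truth.

The phantom couples three analytic ingredients so that every downstream
stage can be validated against closed-form answers:

1. an *air-fraction field* ``f_air`` on the exhale reference anatomy,
2. a *rank-1 displacement field* ``u(x) = s(x) * v`` with a constant unit
   direction ``v``, for which ``det(I + c * grad u) = 1 + c * (J1 - 1)``
   holds exactly (``J1`` being the Jacobian determinant at full amplitude),
3. a *tissue-conserving HU model*: ``HU = -1000 * f_air`` (tissue HU is
   configurable), so that each rendered phase satisfies
   ``f_air_phase = 1 - (1 - f_air) / J_c`` voxel by voxel.

Fractional ventilation then has the closed form ``(J - 1) / f_air`` on the
exhale grid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from ventavoid.core import DisplacementField, ImageGrid
from ventavoid.ventilation import VentilationMap

AIR_HU = -1000.0

_LUNG_SIDES = ("left", "right")  # "right" = +x half of the grid
_LUNG_THIRDS = ("superior", "middle", "inferior")


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry and material parameters of the reference anatomy."""

    shape: tuple[int, int, int] = (96, 96, 96)
    spacing: tuple[float, float, float] = (2.5, 2.5, 2.5)
    f_air_bounds: tuple[float, float] = (0.35, 0.75)
    tumor_radius_mm: float = 12.0
    tumor_center_rel: tuple[float, float, float] = (0.52, 0.50, 0.71)
    tumor_hu: float = 20.0
    tissue_hu: float = 0.0
    defect_side: str = "right"
    defect_third: str = "middle"
    noise_hu: float = 0.0
    vessel_fraction: float = 0.08
    vessel_hu: float = 50.0

    def __post_init__(self) -> None:
        if any(n < 32 for n in self.shape):
            raise ValueError(f"grid dims must be >= 32^3, got {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        lo, hi = self.f_air_bounds
        if not (0.0 <= lo <= hi < 1.0):
            raise ValueError(f"f_air bounds must satisfy 0 <= lo <= hi < 1, got {self.f_air_bounds}")
        if self.defect_side not in _LUNG_SIDES:
            raise ValueError(f"defect_side must be one of {_LUNG_SIDES}")
        if self.defect_third not in _LUNG_THIRDS:
            raise ValueError(f"defect_third must be one of {_LUNG_THIRDS}")

    @property
    def extent_mm(self) -> np.ndarray:
        return np.asarray(self.shape) * np.asarray(self.spacing)


@dataclass(frozen=True)
class BreathingConfig:
    """Periodic breathing waveform configuration.

    ``c(t) = ((1 - cos(2 pi t / T)) / 2) ** shape_power`` dwells longer near
    exhale for ``shape_power > 1``; a ``max_inhale`` start offsets time by
    half a period.
    """

    period_s: float = 5.0
    start_phase: str = "max_exhale"
    tumor_amplitude_mm: float = 6.0
    n_phases: int = 10
    shape_power: float = 2.0

    def __post_init__(self) -> None:
        if self.period_s <= 0:
            raise ValueError("period must be positive")
        if self.tumor_amplitude_mm < 0:
            raise ValueError("amplitude must be >= 0")
        if self.n_phases < 2:
            raise ValueError("need at least 2 phases")
        if self.start_phase not in ("max_exhale", "max_inhale"):
            raise ValueError("start_phase must be 'max_exhale' or 'max_inhale'")

    def cycle_fraction(self, t: np.ndarray | float) -> np.ndarray | float:
        """Inhale fraction ``c`` in [0, 1] at absolute time ``t`` (seconds)."""
        t = np.asarray(t, dtype=np.float64)
        if self.start_phase == "max_inhale":
            t = t + self.period_s / 2.0
        base = (1.0 - np.cos(2.0 * np.pi * t / self.period_s)) / 2.0
        return base**self.shape_power

    def phase_fractions(self) -> np.ndarray:
        """The ``c`` value of each of the ``n_phases`` uniform time bins."""
        t = np.arange(self.n_phases) * self.period_s / self.n_phases
        return np.asarray(self.cycle_fraction(t))


# --------------------------------------------------------------------------
# analytic geometry primitives
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class _Ellipsoid:
    center: tuple[float, float, float]
    semi: tuple[float, float, float]

    def contains(self, pts: np.ndarray) -> np.ndarray:
        c = np.asarray(self.center).reshape((3,) + (1,) * (pts.ndim - 1))
        s = np.asarray(self.semi).reshape((3,) + (1,) * (pts.ndim - 1))
        return np.sum(((pts - c) / s) ** 2, axis=0) <= 1.0


@dataclass(frozen=True)
class _ZTube:
    center_yx: tuple[float, float]
    radius: float
    z_range: tuple[float, float]

    def contains(self, pts: np.ndarray) -> np.ndarray:
        z, y, x = pts[0], pts[1], pts[2]
        r2 = (y - self.center_yx[0]) ** 2 + (x - self.center_yx[1]) ** 2
        return (r2 <= self.radius**2) & (z >= self.z_range[0]) & (z <= self.z_range[1])


@dataclass(frozen=True)
class _BodyCylinder:
    center_yx: tuple[float, float]
    semi_yx: tuple[float, float]
    z_range: tuple[float, float]

    def contains(self, pts: np.ndarray) -> np.ndarray:
        z, y, x = pts[0], pts[1], pts[2]
        rho2 = ((y - self.center_yx[0]) / self.semi_yx[0]) ** 2 + (
            (x - self.center_yx[1]) / self.semi_yx[1]
        ) ** 2
        return (rho2 <= 1.0) & (z >= self.z_range[0]) & (z <= self.z_range[1])

    def rho(self, pts: np.ndarray) -> np.ndarray:
        """Elliptic radial coordinate in the axial plane (1.0 at the skin)."""
        y, x = pts[1], pts[2]
        return np.sqrt(
            ((y - self.center_yx[0]) / self.semi_yx[0]) ** 2
            + ((x - self.center_yx[1]) / self.semi_yx[1]) ** 2
        )


@dataclass(frozen=True)
class _Geometry:
    body: _BodyCylinder
    lungs: dict[str, _Ellipsoid]
    airway: _ZTube
    tumor: _Ellipsoid
    esophagus: _ZTube
    heart: _Ellipsoid
    cord: _ZTube

    def lung_membership(self, pts: np.ndarray, side: str) -> np.ndarray:
        inside = self.lungs[side].contains(pts)
        # carve overlapping structures out of the parenchyma
        inside &= ~self.heart.contains(pts)
        inside &= ~self.tumor.contains(pts)
        inside &= ~self.airway.contains(pts)
        return inside


def _make_geometry(config: PhantomConfig) -> _Geometry:
    Lz, Ly, Lx = config.extent_mm
    cy, cx = Ly / 2.0, Lx / 2.0
    body = _BodyCylinder(
        center_yx=(cy, cx),
        semi_yx=(0.36 * Ly, 0.42 * Lx),
        z_range=(0.06 * Lz, 0.94 * Lz),
    )
    lung_cz = 0.48 * Lz
    lung_semi = (0.30 * Lz, 0.23 * Ly, 0.14 * Lx)
    lungs = {
        "left": _Ellipsoid((lung_cz, cy, cx - 0.21 * Lx), lung_semi),
        "right": _Ellipsoid((lung_cz, cy, cx + 0.21 * Lx), lung_semi),
    }
    tumor_center = tuple(np.asarray(config.tumor_center_rel) * config.extent_mm)
    r = config.tumor_radius_mm
    tumor = _Ellipsoid(tumor_center, (r, r, r))
    geometry = _Geometry(
        body=body,
        lungs=lungs,
        airway=_ZTube((cy - 0.04 * Ly, cx), 0.025 * Lx, (0.10 * Lz, 0.44 * Lz)),
        tumor=tumor,
        esophagus=_ZTube((cy + 0.075 * Ly, cx + 0.025 * Lx), 5.0, (0.08 * Lz, 0.90 * Lz)),
        heart=_Ellipsoid(
            (0.62 * Lz, cy + 0.03 * Ly, cx - 0.05 * Lx),
            (0.125 * Lz, 0.11 * Ly, 0.11 * Lx),
        ),
        cord=_ZTube((cy + 0.28 * Ly, cx), 5.0, (0.06 * Lz, 0.94 * Lz)),
    )
    # validate the tumor fits inside a lung
    for side, lung in lungs.items():
        c = np.asarray(lung.center)
        t = np.asarray(tumor_center)
        if np.sum(((t - c) / np.asarray(lung_semi)) ** 2) <= 1.0:
            margin = np.min(np.asarray(lung_semi)) * (
                1.0 - np.sqrt(np.sum(((t - c) / np.asarray(lung_semi)) ** 2))
            )
            if r > margin + np.min(np.asarray(lung_semi)) * 0.35:
                raise ValueError(
                    f"tumor radius {r} mm exceeds the {side} lung extent "
                    f"(available margin about {margin:.1f} mm around the tumor center)"
                )
            return geometry
    raise ValueError(
        f"tumor center {tumor_center} lies outside both lungs "
        f"(lung semi-axes {lung_semi} mm)"
    )


# --------------------------------------------------------------------------
# analytic random fields
# --------------------------------------------------------------------------


class _CosineField:
    """Band-limited random field ``sum_m a_m cos(k_m . x + phi_m)``.

    Normalized so that values lie in [-1, 1]; value and gradient are analytic
    and evaluable at arbitrary physical points.
    """

    def __init__(self, rng: np.random.Generator, n_modes: int = 8,
                 wavelength_mm: tuple[float, float] = (80.0, 160.0),
                 lateral_only: bool = False) -> None:
        lam = rng.uniform(*wavelength_mm, size=n_modes)
        direction = rng.normal(size=(n_modes, 3))
        if lateral_only:
            direction[:, 0] = 0.0
        direction /= np.linalg.norm(direction, axis=1, keepdims=True)
        self.k = (2.0 * np.pi / lam)[:, None] * direction  # (M, 3)
        self.phi = rng.uniform(0.0, 2.0 * np.pi, size=n_modes)
        amp = rng.uniform(0.5, 1.0, size=n_modes)
        self.a = amp / np.sum(amp)

    def value(self, pts: np.ndarray) -> np.ndarray:
        phase = np.tensordot(self.k, pts, axes=(1, 0)) + self.phi.reshape(
            (-1,) + (1,) * (pts.ndim - 1)
        )
        return np.sum(self.a.reshape((-1,) + (1,) * (pts.ndim - 1)) * np.cos(phase), axis=0)

    def gradient(self, pts: np.ndarray) -> np.ndarray:
        phase = np.tensordot(self.k, pts, axes=(1, 0)) + self.phi.reshape(
            (-1,) + (1,) * (pts.ndim - 1)
        )
        s = -np.sin(phase) * self.a.reshape((-1,) + (1,) * (pts.ndim - 1))
        return np.tensordot(self.k.T, s, axes=(1, 0))  # (3, ...)


def _smooth_rise(t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """C1 ramp 0 -> 1 on [0, 1] (``sin^2``); returns value and derivative."""
    tc = np.clip(t, 0.0, 1.0)
    val = np.sin(0.5 * np.pi * tc) ** 2
    dval = 0.5 * np.pi * np.sin(np.pi * tc)
    dval = np.where((t <= 0.0) | (t >= 1.0), 0.0, dval)
    return val, dval


def _window(x: np.ndarray, a: float, b: float, ra: float, rb: float
            ) -> tuple[np.ndarray, np.ndarray]:
    """C1 window: rises over [a, a+ra], plateaus, falls over [b-rb, b]."""
    up, dup = _smooth_rise((x - a) / ra)
    down, ddown = _smooth_rise((b - x) / rb)
    return up * down, dup / ra * down - up * ddown / rb


# --------------------------------------------------------------------------
# anatomy
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class PhantomAnatomy:
    """Reference (peak-exhale) anatomy with analytic field accessors."""

    config: PhantomConfig
    grid: ImageGrid                     # exhale HU volume
    body_mask: np.ndarray
    lung_masks: dict[str, np.ndarray]   # keys "left", "right"
    airway_mask: np.ndarray
    tumor_mask: np.ndarray
    oar_masks: dict[str, np.ndarray]    # esophagus, heart, cord
    f_air: np.ndarray                   # exhale air fraction on the grid
    defect: dict
    geometry: _Geometry = field(repr=False)
    f_air_fn: Callable[[np.ndarray], np.ndarray] = field(repr=False)
    hu_fn: Callable[[np.ndarray], np.ndarray] = field(repr=False)

    @property
    def spacing(self) -> tuple[float, float, float]:
        return self.grid.spacing

    @property
    def origin(self) -> tuple[float, float, float]:
        return self.grid.origin

    @property
    def lung_mask(self) -> np.ndarray:
        return self.lung_masks["left"] | self.lung_masks["right"]

    def lung_third_bounds(self, side: str, third: str) -> tuple[float, float]:
        """Cranio-caudal physical bounds (mm) of one lung third."""
        lung = self.geometry.lungs[side]
        z0 = lung.center[0] - lung.semi[0]
        z1 = lung.center[0] + lung.semi[0]
        k = _LUNG_THIRDS.index(third)
        h = (z1 - z0) / 3.0
        return z0 + k * h, z0 + (k + 1) * h


def build_reference_anatomy(config: PhantomConfig | None = None, seed: int = 0
                            ) -> PhantomAnatomy:
    """Construct the deterministic exhale reference anatomy for ``seed``."""
    config = config or PhantomConfig()
    geometry = _make_geometry(config)
    rng = np.random.default_rng(seed)
    # two texture bands: broad functional heterogeneity plus a finer
    # parenchymal component that gives the registration local contrast
    texture_lo = _CosineField(rng, n_modes=8, wavelength_mm=(110.0, 200.0))
    texture_hi = _CosineField(rng, n_modes=6, wavelength_mm=(45.0, 85.0))
    # vessel-like tissue strands: air-free, so their HU is advected unchanged
    # between phases — the intensity-preserved anchors SSD registration needs
    vessel_field = _CosineField(rng, n_modes=16, wavelength_mm=(12.0, 30.0))

    lo, hi = config.f_air_bounds

    if config.vessel_fraction > 0:
        probe = ImageGrid(np.zeros(config.shape), config.spacing)
        ppts = probe.voxel_coordinates()
        in_lungs = (geometry.lung_membership(ppts, "left")
                    | geometry.lung_membership(ppts, "right"))
        vessel_threshold = float(
            np.quantile(vessel_field.value(ppts)[in_lungs], 1.0 - config.vessel_fraction)
        )
    else:
        vessel_threshold = np.inf

    def vessel_indicator(pts: np.ndarray) -> np.ndarray:
        return vessel_field.value(pts) > vessel_threshold

    def f_air_fn(pts: np.ndarray) -> np.ndarray:
        in_lung = geometry.lung_membership(pts, "left") | geometry.lung_membership(pts, "right")
        g = 0.7 * texture_lo.value(pts) + 0.3 * texture_hi.value(pts)
        base = lo + (hi - lo) * 0.5 * (1.0 + g)
        return np.where(in_lung & ~vessel_indicator(pts), base, 0.0)

    def hu_fn(pts: np.ndarray) -> np.ndarray:
        hu = np.full(pts.shape[1:], AIR_HU)
        in_body = geometry.body.contains(pts)
        hu[in_body] = config.tissue_hu
        in_lung = (geometry.lung_membership(pts, "left")
                   | geometry.lung_membership(pts, "right"))
        hu[in_lung & vessel_indicator(pts) & in_body] = config.vessel_hu
        f = f_air_fn(pts)
        lung = f > 0.0
        hu[lung] = AIR_HU * f[lung] + config.tissue_hu * (1.0 - f[lung])
        hu[geometry.heart.contains(pts) & in_body] = 45.0
        hu[geometry.esophagus.contains(pts) & in_body] = 30.0
        hu[geometry.cord.contains(pts) & in_body] = 35.0
        hu[geometry.tumor.contains(pts) & in_body] = config.tumor_hu
        hu[geometry.airway.contains(pts) & in_body] = AIR_HU
        return hu

    ref = ImageGrid(np.zeros(config.shape), config.spacing)
    pts = ref.voxel_coordinates()

    body = geometry.body.contains(pts)
    lung_masks = {s: geometry.lung_membership(pts, s) for s in _LUNG_SIDES}
    f_air = f_air_fn(pts)
    grid = ref.with_data(hu_fn(pts))

    return PhantomAnatomy(
        config=config,
        grid=grid,
        body_mask=body,
        lung_masks=lung_masks,
        airway_mask=geometry.airway.contains(pts) & body,
        tumor_mask=geometry.tumor.contains(pts) & body,
        oar_masks={
            "esophagus": geometry.esophagus.contains(pts) & body,
            "heart": geometry.heart.contains(pts) & body,
            "cord": geometry.cord.contains(pts) & body,
        },
        f_air=f_air,
        defect={"side": config.defect_side, "third": config.defect_third},
        geometry=geometry,
        f_air_fn=f_air_fn,
        hu_fn=hu_fn,
    )


# --------------------------------------------------------------------------
# displacement synthesis
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class PhantomDVF(DisplacementField):
    """Displacement field with analytic accessors.

    Restricted to the rank-1 form ``u(x) = s(x) * v`` (constant direction
    ``v``), for which the scaled-field Jacobian obeys
    ``det(I + c grad u) = 1 + c * (J1 - 1)`` exactly.
    """

    u_fn: Callable[[np.ndarray], np.ndarray] | None = field(default=None, repr=False)
    jm1_fn: Callable[[np.ndarray], np.ndarray] | None = field(default=None, repr=False)
    scale: float = 1.0

    def evaluate(self, pts: np.ndarray) -> np.ndarray:
        """Displacement vectors (mm) at arbitrary physical points ``(3, ...)``."""
        return self.scale * self.u_fn(pts)

    def jacobian(self, pts: np.ndarray) -> np.ndarray:
        """Exact Jacobian determinant at arbitrary physical points."""
        return 1.0 + self.scale * self.jm1_fn(pts)

    def scaled(self, factor: float) -> "PhantomDVF":
        return replace(self, vectors=self.vectors * float(factor),
                       scale=self.scale * float(factor))

    def jacobian_determinant(self) -> np.ndarray:
        grid = ImageGrid(np.zeros(self.shape), self.spacing, self.origin)
        return self.jacobian(grid.voxel_coordinates())


def synthesize_dvf(anatomy: PhantomAnatomy, amplitude_mm: float = 6.0,
                   defect_factor: float = 0.05, seed: int = 0,
                   transverse: tuple[float, float] = (0.15, 0.10),
                   heterogeneity: float = 0.15) -> PhantomDVF:
    """Smooth analytic exhale-to-inhale field, cranio-caudal dominant.

    The scalar profile integrates a non-negative axial expansion density
    that rises from the apex and peaks at the diaphragm, so the Jacobian
    exceeds 1 throughout the lungs; inside the configured defect region the
    expansion density is multiplied by ``defect_factor`` exactly. The field
    tapers to zero at the body surface. Raises if the requested amplitude
    drives the Jacobian determinant non-positive.
    """
    if amplitude_mm < 0:
        raise ValueError("amplitude must be >= 0")
    if not (0.0 <= defect_factor <= 1.0):
        raise ValueError("defect_factor must be in [0, 1]")

    config = anatomy.config
    geometry = anatomy.geometry
    Lz, _, _ = config.extent_mm
    rng = np.random.default_rng(seed + 104729)
    modulation = _CosineField(rng, n_modes=6, wavelength_mm=(100.0, 200.0),
                              lateral_only=True)

    lung = geometry.lungs["left"]
    z_apex = lung.center[0] - lung.semi[0] - 0.05 * Lz
    z_diaphragm = lung.center[0] + lung.semi[0] + 0.04 * Lz
    z_bottom = geometry.body.z_range[1]
    plateau = 8.0  # mm of full displacement just below the diaphragm
    taper_rho = 0.30  # fraction of the elliptic radius used for the skin taper

    dz0, dz1 = anatomy.lung_third_bounds(config.defect_side, config.defect_third)
    defect_lung = geometry.lungs[config.defect_side]
    dtaper = 15.0

    def g_profile(z: np.ndarray):
        """Axial profile G (rise to the diaphragm, fall to the body base)."""
        return _window(z, z_apex, z_bottom,
                       z_diaphragm - z_apex, z_bottom - z_diaphragm - plateau)

    def dz_window(z: np.ndarray):
        return _window(z, dz0 - dtaper, dz1 + dtaper, dtaper, dtaper)

    def wx_window(x: np.ndarray):
        x0 = defect_lung.center[2] - defect_lung.semi[2]
        x1 = defect_lung.center[2] + defect_lung.semi[2]
        return _window(x, x0 - dtaper, x1 + dtaper, dtaper, dtaper)

    # H(z) = integral of G'(z) Dz(z): the part of the axial expansion that the
    # defect removes. Tabulated once on a fine axis, linearly interpolated.
    z_fine = np.linspace(0.0, Lz, 4096)
    _, dg_fine = g_profile(z_fine)
    dz_fine, _ = dz_window(z_fine)
    h_fine = np.concatenate(
        [[0.0], np.cumsum((dg_fine * dz_fine)[:-1] + (dg_fine * dz_fine)[1:])]
    ) * 0.5 * (z_fine[1] - z_fine[0])

    fall_len = z_bottom - z_diaphragm - plateau

    def scalar_parts(pts: np.ndarray):
        """Value and gradient of the un-normalized scalar profile."""
        z = pts[0]
        g, dg = g_profile(z)
        dz_val, _ = dz_window(z)
        wx, dwx = wx_window(pts[2])
        # fade the defect correction out with G's own falling edge so the
        # field still vanishes at the inferior body surface
        down, ddown = _smooth_rise((z_bottom - z) / fall_len)
        h = np.interp(z, z_fine, h_fine) * down
        dh_extra = -np.interp(z, z_fine, h_fine) * ddown / fall_len

        rho = geometry.body.rho(pts)
        er, der = _smooth_rise((1.0 - rho) / taper_rho)
        der_drho = -der / taper_rho
        safe_rho = np.maximum(rho, 1e-9)
        cy, cx = geometry.body.center_yx
        ay, ax = geometry.body.semi_yx
        drho_dy = (pts[1] - cy) / (ay**2 * safe_rho)
        drho_dx = (pts[2] - cx) / (ax**2 * safe_rho)

        mod = 1.0 + heterogeneity * modulation.value(pts)
        dmod = heterogeneity * modulation.gradient(pts)
        m_val = er * mod
        dm = np.empty_like(pts)
        dm[0] = 0.0
        dm[1] = der_drho * drho_dy * mod + er * dmod[1]
        dm[2] = der_drho * drho_dx * mod + er * dmod[2]

        loss = 1.0 - defect_factor
        axial = g - loss * wx * h
        daxial_dz = dg - loss * wx * (down * dg * dz_val + dh_extra)
        val = m_val * axial
        grad = np.empty_like(pts)
        grad[0] = m_val * daxial_dz
        grad[1] = dm[1] * axial
        grad[2] = dm[2] * axial - m_val * loss * dwx * h
        return val, grad

    # normalize so the maximum displacement magnitude on the grid equals the
    # requested amplitude
    pts = anatomy.grid.voxel_coordinates()
    raw_val, _ = scalar_parts(pts)
    peak = float(np.max(np.abs(raw_val)))
    if peak <= 0:
        raise ValueError("degenerate scalar profile (all zero)")

    v = np.array([1.0, transverse[0], transverse[1]])
    v /= np.linalg.norm(v)
    scale = amplitude_mm / peak

    def u_fn(p: np.ndarray) -> np.ndarray:
        val, _ = scalar_parts(p)
        return scale * val[None] * v.reshape((3,) + (1,) * val.ndim)

    def jm1_fn(p: np.ndarray) -> np.ndarray:
        _, grad = scalar_parts(p)
        return scale * np.tensordot(v, grad, axes=(0, 0))

    vectors = u_fn(pts)
    jm1 = jm1_fn(pts)
    min_j = float(1.0 + np.min(jm1))
    if min_j <= 0.0:
        raise ValueError(
            f"amplitude {amplitude_mm} mm produces a folding deformation "
            f"(min Jacobian determinant {min_j:.4f} <= 0)"
        )
    return PhantomDVF(
        vectors=vectors, spacing=anatomy.spacing, origin=anatomy.origin,
        u_fn=u_fn, jm1_fn=jm1_fn,
    )


def synthesize_affine_core_dvf(anatomy: PhantomAnatomy, stretch: float = 1.25
                               ) -> PhantomDVF:
    """Validation field that is exactly affine over the lung region.

    ``u_z = (stretch - 1) * (z - z_bot)`` inside a core slab spanning the
    lungs (anchored at its inferior end ``z_bot``), so ``J == stretch``
    exactly in the core; the superior cap translates rigidly (``J == 1``).
    With a constant air fraction the rendered phase HU is constant over the
    deformed lung, trilinear resampling is exact, and the ventilation
    closure can be checked to machine precision. Unlike the physiologic
    field this one is not forced to zero at the superior body surface — it
    exists only for closure validation.
    """
    if stretch <= 0:
        raise ValueError("stretch must be positive")
    geometry = anatomy.geometry
    lungs = geometry.lungs
    z_top = min(l.center[0] - l.semi[0] for l in lungs.values()) - 4.0
    z_bot = max(l.center[0] + l.semi[0] for l in lungs.values()) + 4.0

    def profile(z: np.ndarray):
        val = np.clip(z, z_top, z_bot) - z_bot
        dval = ((z >= z_top) & (z <= z_bot)).astype(np.float64)
        return val, dval

    s1 = stretch - 1.0

    def u_fn(p: np.ndarray) -> np.ndarray:
        val, _ = profile(p[0])
        u = np.zeros_like(p)
        u[0] = s1 * val
        return u

    def jm1_fn(p: np.ndarray) -> np.ndarray:
        _, dval = profile(p[0])
        return s1 * dval

    pts = anatomy.grid.voxel_coordinates()
    vectors = u_fn(pts)
    min_j = float(1.0 + np.min(jm1_fn(pts)))
    if min_j <= 0.0:
        raise ValueError(f"stretch {stretch} folds the taper (min J {min_j:.4f})")
    return PhantomDVF(vectors=vectors, spacing=anatomy.spacing,
                      origin=anatomy.origin, u_fn=u_fn, jm1_fn=jm1_fn)


# --------------------------------------------------------------------------
# phase rendering
# --------------------------------------------------------------------------


def _invert_map(dvf: PhantomDVF, pts: np.ndarray, c: float,
                tol: float = 1e-10, max_iter: int = 60) -> np.ndarray:
    """Solve ``x + c u(x) = y`` by fixed-point iteration (contraction)."""
    if c == 0.0:
        return pts.copy()
    x = pts.copy()
    flat_pts = pts.reshape(3, -1)
    flat_x = x.reshape(3, -1)
    active = np.arange(flat_x.shape[1])
    for _ in range(max_iter):
        u = dvf.evaluate(flat_x[:, active]) if isinstance(dvf, PhantomDVF) else None
        new = flat_pts[:, active] - c * u
        delta = np.max(np.abs(new - flat_x[:, active]), axis=0)
        flat_x[:, active] = new
        still = delta > tol
        active = active[still]
        if active.size == 0:
            break
    return flat_x.reshape(pts.shape)


def render_phase(anatomy: PhantomAnatomy, dvf: PhantomDVF, c: float,
                 tumor_shift_mm: Sequence[float] = (0.0, 0.0, 0.0),
                 noise_rng: np.random.Generator | None = None) -> ImageGrid:
    """Render the HU volume of breathing phase ``c`` on the fixed grid.

    Parenchymal voxels follow tissue conservation: the exhale pre-image
    ``x`` of each grid point carries air fraction
    ``1 - (1 - f_air(x)) / J_c(x)``. Non-lung tissue is advected unchanged;
    the tumor is painted rigidly at ``tumor_shift_mm``.
    """
    if not (0.0 <= c <= 1.0):
        raise ValueError(f"phase fraction must be in [0, 1], got {c}")
    grid = anatomy.grid
    pts = grid.voxel_coordinates()
    x = _invert_map(dvf, pts, c)

    f_ex = anatomy.f_air_fn(x)
    jc = 1.0 + c * dvf.jm1_fn(x)
    hu = anatomy.hu_fn(x)

    lung = f_ex > 0.0
    f_phase = np.where(lung, 1.0 - (1.0 - f_ex) / np.where(lung, jc, 1.0), 0.0)
    bad = lung & (f_phase < 0.0)
    if np.any(bad):
        worst = float(np.min(f_phase[bad]))
        raise ValueError(
            "tissue volume exceeds the deformed voxel volume "
            f"(min phase air fraction {worst:.4f} < 0); reduce compression"
        )
    hu = np.where(lung, AIR_HU * f_phase + anatomy.config.tissue_hu * (1.0 - f_phase), hu)

    # rigid tumor translation painted on top of the parenchymal field
    shift = np.asarray(tumor_shift_mm, dtype=np.float64)
    tumor = anatomy.geometry.tumor
    moved = _Ellipsoid(tuple(np.asarray(tumor.center) + shift), tumor.semi)
    hu = np.where(moved.contains(pts), anatomy.config.tumor_hu, hu)

    if noise_rng is not None and anatomy.config.noise_hu > 0:
        hu = hu + noise_rng.normal(0.0, anatomy.config.noise_hu, size=hu.shape)
    return grid.with_data(hu)


def tumor_mask_at(anatomy: PhantomAnatomy, shift_mm: Sequence[float]) -> np.ndarray:
    tumor = anatomy.geometry.tumor
    moved = _Ellipsoid(tuple(np.asarray(tumor.center) + np.asarray(shift_mm)), tumor.semi)
    return moved.contains(anatomy.grid.voxel_coordinates()) & anatomy.body_mask


def ground_truth_ventilation(dvf: PhantomDVF, anatomy: PhantomAnatomy) -> VentilationMap:
    """Closed-form exhale-grid ventilation ``(J - 1) / f_air``."""
    jac = dvf.jacobian_determinant() if isinstance(dvf, PhantomDVF) else dvf.jacobian_determinant()
    mask = anatomy.lung_mask
    valid = mask & (anatomy.f_air > 0.0)
    values = np.zeros(anatomy.grid.shape)
    values[valid] = (jac[valid] - 1.0) / anatomy.f_air[valid]
    return VentilationMap(values=values, valid=valid, spacing=anatomy.spacing,
                          origin=anatomy.origin)


# --------------------------------------------------------------------------
# 4DCT assembly
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class FourDCT:
    """Phase-resolved volumes plus the ground truth that generated them."""

    anatomy: PhantomAnatomy
    dvf: PhantomDVF
    breathing: BreathingConfig
    phase_fractions: np.ndarray
    phases: list[ImageGrid]
    phase_dvfs: list[PhantomDVF]
    tumor_masks: list[np.ndarray]
    ventilation_truth: VentilationMap
    motion_axis: tuple[float, float, float] = (1.0, 0.0, 0.0)

    @property
    def n_phases(self) -> int:
        return len(self.phases)

    @property
    def exhale_index(self) -> int:
        return int(np.argmin(self.phase_fractions))

    @property
    def inhale_index(self) -> int:
        return int(np.argmax(self.phase_fractions))


def make_4dct(anatomy: PhantomAnatomy, dvf: PhantomDVF,
              breathing: BreathingConfig | None = None,
              seed: int | None = None) -> FourDCT:
    """Render all breathing phases with per-phase DVFs and tumor masks."""
    breathing = breathing or BreathingConfig()
    fractions = breathing.phase_fractions()
    axis = np.array([1.0, 0.0, 0.0])  # cranio-caudal tumor excursion
    noise_rng = (
        np.random.default_rng(seed) if seed is not None and anatomy.config.noise_hu > 0
        else None
    )

    phases, phase_dvfs, tumor_masks = [], [], []
    for c in fractions:
        shift = c * breathing.tumor_amplitude_mm * axis
        phases.append(render_phase(anatomy, dvf, float(c), tumor_shift_mm=shift,
                                   noise_rng=noise_rng))
        phase_dvfs.append(dvf.scaled(float(c)))
        tumor_masks.append(tumor_mask_at(anatomy, shift))

    return FourDCT(
        anatomy=anatomy, dvf=dvf, breathing=breathing,
        phase_fractions=fractions, phases=phases, phase_dvfs=phase_dvfs,
        tumor_masks=tumor_masks,
        ventilation_truth=ground_truth_ventilation(dvf, anatomy),
        motion_axis=tuple(axis),
    )


def total_tissue_volume(anatomy: PhantomAnatomy, dvf: PhantomDVF, c: float) -> float:
    """Lung tissue volume (mm^3) of phase ``c``: ``sum (1 - f_phase) J_c v``.

    Equals the exhale tissue volume identically under tissue conservation.
    """
    mask = anatomy.lung_mask & (anatomy.f_air > 0)
    pts = anatomy.grid.voxel_coordinates()[:, mask]
    jc = 1.0 + c * dvf.jm1_fn(pts)
    f_phase = 1.0 - (1.0 - anatomy.f_air[mask]) / jc
    return float(np.sum((1.0 - f_phase) * jc) * anatomy.grid.voxel_volume_mm3)
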