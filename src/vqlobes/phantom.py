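"""Digital thorax phantoms with five lung lobes and known lobar activity.

The phantom is an analytic description — ellipsoidal thorax, two ellipsoidal
lungs, planar fissure surfaces — rasterised on demand at any voxel grid by a
voxel-centre inside/outside test, so no label resampling is ever needed.
Each phantom carries a CT-like Hounsfield-unit volume, per-lobe ventilation
and perfusion activity, and the exact ground-truth lobar fractions that both
quantification methods are judged against.

Geometry of the fissures
------------------------
Fissures are planes expressed in the lung's own bounding frame: a fractional
apex-to-base height ``h`` in (0, 1) and a sagittal tilt angle.  The oblique
fissures run superior-posterior to inferior-anterior (positive tilt raises
the plane posteriorly), which gives the lower lobes their posterior-basal
character; the right horizontal fissure is near-axial and, together with the
oblique plane, carves out the anterior wedge of the middle lobe.  This is the
simplest geometry in which the lobar extents differ from equal axial thirds —
the effect the planar template method is blind to.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace, asdict
from typing import Sequence

import numpy as np

from .distribution import (LOBE_CODES, LOBE_NAMES, LEFT_LOBES, RIGHT_LOBES,
                           LobarDistribution)
from .grid import DEFAULT_SPECT_GRID, VoxelGrid

__all__ = [
    "FissureSet", "Hotspot", "PhantomSpec", "LobeLabelMap", "Phantom",
    "build_phantom", "apply_lobectomy", "apply_emphysema", "insert_hotspot",
    "true_lobar_fractions", "sample_spec",
]


@dataclass(frozen=True)
class FissureSet:
    """Planar fissure parameters: fractional apex-base heights and sagittal tilts.

    Heights are fractions of the lung's superior-inferior extent measured
    from the lung base; tilts are in degrees, positive raising the plane on
    the posterior side.  Defaults are calibrated so the right-lobe volume
    shares sit near typical 3D-SPECT lobar means (≈39/18/43 % of the right
    lung) and the left split near 56/44.
    """

    right_oblique_height: float = 0.46
    right_oblique_tilt_deg: float = 28.0
    right_horizontal_height: float = 0.58
    right_horizontal_tilt_deg: float = 0.0
    left_oblique_height: float = 0.46
    left_oblique_tilt_deg: float = 28.0

    def __post_init__(self) -> None:
        for name in ("right_oblique_height", "right_horizontal_height",
                     "left_oblique_height"):
            h = getattr(self, name)
            if not 0.0 < h < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {h}")


@dataclass(frozen=True)
class Hotspot:
    """Spherical focal activity multiplier (ventilation hotspots in severe
    airway obstruction)."""

    center_mm: tuple[float, float, float]
    radius_mm: float
    multiplier: float = 5.0

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError("hotspot radius must be > 0")
        if self.multiplier < 0:
            raise ValueError("hotspot multiplier must be >= 0")


def _uniform_activity() -> dict[str, float]:
    return {name: 1.0 for name in LOBE_NAMES}


@dataclass(frozen=True)
class PhantomSpec:
    """Analytic phantom description.

    Lengths are millimetres in the patient frame (x left+, y anterior+,
    z superior+); activities are arbitrary units per voxel.
    """

    thorax_half_axes_mm: tuple[float, float, float] = (155.0, 105.0, 185.0)
    thorax_center_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    right_lung_center_mm: tuple[float, float, float] = (-60.0, -4.0, 5.0)
    right_lung_half_axes_mm: tuple[float, float, float] = (48.0, 72.0, 118.0)
    left_lung_center_mm: tuple[float, float, float] = (60.0, -4.0, 5.0)
    left_lung_half_axes_mm: tuple[float, float, float] = (44.0, 68.0, 116.0)
    fissures: FissureSet = field(default_factory=FissureSet)
    activity_v: dict[str, float] = field(default_factory=_uniform_activity)
    activity_q: dict[str, float] = field(default_factory=_uniform_activity)
    hu_air: float = -1000.0
    hu_parenchyma: float = -800.0
    hu_soft_tissue: float = 40.0
    hu_emphysema: float = -950.0
    emphysema_lobes: tuple[str, ...] = ()
    emphysema_activity_factor: float = 1.0
    hotspots: tuple[Hotspot, ...] = ()
    lobectomy: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for tag, act in (("activity_v", self.activity_v),
                         ("activity_q", self.activity_q)):
            for name, a in act.items():
                if name not in LOBE_NAMES:
                    raise ValueError(f"{tag}: unknown lobe {name!r}")
                if a < 0:
                    raise ValueError(f"{tag}[{name}] must be >= 0, got {a}")
        if not 0.0 <= self.emphysema_activity_factor <= 1.0:
            raise ValueError("emphysema_activity_factor must be in [0, 1]")
        if self.lobectomy is not None and self.lobectomy not in LOBE_NAMES:
            raise ValueError(f"unknown lobectomy lobe {self.lobectomy!r}")
        for lobe in self.emphysema_lobes:
            if lobe not in LOBE_NAMES:
                raise ValueError(f"unknown emphysema lobe {lobe!r}")

    def to_jsonable(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class LobeLabelMap:
    """Integer lobe label volume on a grid; codes per ``LOBE_CODES`` (0 = background)."""

    grid: VoxelGrid
    labels: np.ndarray

    def __post_init__(self) -> None:
        if tuple(self.labels.shape) != self.grid.shape:
            raise ValueError("label array shape does not match grid")
        if self.labels.dtype != np.uint8:
            object.__setattr__(self, "labels",
                               self.labels.astype(np.uint8, copy=False))

    def lobe_mask(self, name: str) -> np.ndarray:
        return self.labels == LOBE_CODES[name]

    def lung_mask(self, side: str) -> np.ndarray:
        lobes = RIGHT_LOBES if side == "right" else LEFT_LOBES
        codes = [LOBE_CODES[name] for name in lobes]
        return np.isin(self.labels, codes)

    def present_lobes(self) -> tuple[str, ...]:
        present = np.unique(self.labels)
        return tuple(n for n in LOBE_NAMES if LOBE_CODES[n] in present)

    def voxel_counts(self) -> dict[str, int]:
        counts = np.bincount(self.labels.ravel(), minlength=6)
        return {name: int(counts[LOBE_CODES[name]]) for name in LOBE_NAMES}


@dataclass(frozen=True)
class Phantom:
    """Rasterised phantom: labels, HU, and per-tracer activity on one grid."""

    spec: PhantomSpec
    grid: VoxelGrid
    labels: LobeLabelMap
    hu: np.ndarray
    activity_v: np.ndarray
    activity_q: np.ndarray

    def activity(self, tracer: str) -> np.ndarray:
        if tracer == "V":
            return self.activity_v
        if tracer == "Q":
            return self.activity_q
        raise ValueError(f"tracer must be 'V' or 'Q', got {tracer!r}")

    @property
    def truth_v(self) -> LobarDistribution:
        return true_lobar_fractions(self, "V")

    @property
    def truth_q(self) -> LobarDistribution:
        return true_lobar_fractions(self, "Q")

    def body_mask(self) -> np.ndarray:
        """Thorax mask (everything denser than air), for planar body outlines."""
        return self.hu > self.spec.hu_air + 1.0


# ---------------------------------------------------------------------------
# rasterisation


def _ellipsoid_mask(grid: VoxelGrid, center: Sequence[float],
                    half_axes: Sequence[float]) -> np.ndarray:
    x, y, z = grid.coordinate_mesh()
    cx, cy, cz = center
    ax, ay, az = half_axes
    return ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2 <= 1.0


def _plane_height(y: np.ndarray, center_y: float, z_base: float,
                  lung_height: float, frac_height: float,
                  tilt_deg: float) -> np.ndarray:
    """z-coordinate of a fissure plane as a function of y.

    Positive tilt raises the plane posteriorly (y < center_y)."""
    return (z_base + frac_height * lung_height
            - np.tan(np.radians(tilt_deg)) * (y - center_y))


def assign_lobes(grid: VoxelGrid, right_mask: np.ndarray, left_mask: np.ndarray,
                 spec: PhantomSpec, fissures: FissureSet | None = None) -> np.ndarray:
    """Partition the lung masks into the five lobe codes using planar fissures.

    ``fissures`` overrides the spec's fissure set (used by the observer
    perturbation model, which moves internal fissures while keeping the outer
    lung boundaries fixed).
    """
    f = fissures if fissures is not None else spec.fissures
    _, y, z = grid.coordinate_mesh()
    labels = np.zeros(grid.shape, dtype=np.uint8)

    # right lung: oblique plane splits off RLL, horizontal plane then splits
    # the remainder into RML (below, anterior wedge) and RUL (above)
    rcy = spec.right_lung_center_mm[1]
    rcz = spec.right_lung_center_mm[2]
    raz = spec.right_lung_half_axes_mm[2]
    r_base, r_height = rcz - raz, 2.0 * raz
    z_ro = _plane_height(y, rcy, r_base, r_height,
                         f.right_oblique_height, f.right_oblique_tilt_deg)
    z_rh = _plane_height(y, rcy, r_base, r_height,
                         f.right_horizontal_height, f.right_horizontal_tilt_deg)
    rll = right_mask & (z < z_ro)
    rml = right_mask & ~rll & (z < z_rh)
    rul = right_mask & ~rll & ~rml
    labels[rul] = LOBE_CODES["RUL"]
    labels[rml] = LOBE_CODES["RML"]
    labels[rll] = LOBE_CODES["RLL"]

    # left lung: single oblique plane, LLL below
    lcy = spec.left_lung_center_mm[1]
    lcz = spec.left_lung_center_mm[2]
    laz = spec.left_lung_half_axes_mm[2]
    l_base, l_height = lcz - laz, 2.0 * laz
    z_lo = _plane_height(y, lcy, l_base, l_height,
                         f.left_oblique_height, f.left_oblique_tilt_deg)
    lll = left_mask & (z < z_lo)
    lul = left_mask & ~lll
    labels[lul] = LOBE_CODES["LUL"]
    labels[lll] = LOBE_CODES["LLL"]
    return labels


def rasterize_lungs(spec: PhantomSpec, grid: VoxelGrid
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Thorax, right-lung and left-lung boolean masks at voxel centres."""
    thorax = _ellipsoid_mask(grid, spec.thorax_center_mm, spec.thorax_half_axes_mm)
    right = _ellipsoid_mask(grid, spec.right_lung_center_mm,
                            spec.right_lung_half_axes_mm)
    left = _ellipsoid_mask(grid, spec.left_lung_center_mm,
                           spec.left_lung_half_axes_mm)
    return thorax, right, left


def build_phantom(spec: PhantomSpec, grid: VoxelGrid = DEFAULT_SPECT_GRID) -> Phantom:
    """Rasterise a phantom analytically at the requested grid.

    Deterministic given ``(spec, grid)``.  Raises ``ValueError`` for
    degenerate geometry: a lung poking outside the thorax, or a lobe that is
    empty at the requested resolution (unless lobectomised).
    """
    thorax, right, left = rasterize_lungs(spec, grid)
    for side, mask in (("right", right), ("left", left)):
        if mask.any() and not np.all(thorax[mask]):
            raise ValueError(f"{side} lung extends outside the thorax; "
                             "check lung centre/half-axes vs thorax half-axes")

    labels_arr = assign_lobes(grid, right, left, spec)

    expected = [n for n in LOBE_NAMES if n != spec.lobectomy]
    counts = np.bincount(labels_arr.ravel(), minlength=6)
    for name in expected:
        if counts[LOBE_CODES[name]] == 0:
            raise ValueError(f"lobe {name} is empty at grid spacing "
                             f"{grid.spacing_mm}; geometry is degenerate")

    hu = np.full(grid.shape, spec.hu_air, dtype=np.float32)
    hu[thorax] = spec.hu_soft_tissue
    lung = labels_arr > 0
    hu[lung] = spec.hu_parenchyma

    activity = {}
    for tracer, per_lobe in (("V", spec.activity_v), ("Q", spec.activity_q)):
        vol = np.zeros(grid.shape, dtype=np.float32)
        for name in LOBE_NAMES:
            vol[labels_arr == LOBE_CODES[name]] = per_lobe.get(name, 0.0)
        activity[tracer] = vol

    phantom = Phantom(spec=spec, grid=grid,
                      labels=LobeLabelMap(grid=grid, labels=labels_arr),
                      hu=hu, activity_v=activity["V"], activity_q=activity["Q"])

    if spec.emphysema_lobes:
        phantom = apply_emphysema(phantom, spec.emphysema_lobes,
                                  spec.emphysema_activity_factor,
                                  spec.hu_emphysema, _update_spec=False)
    for hs in spec.hotspots:
        phantom = insert_hotspot(phantom, hs.center_mm, hs.radius_mm,
                                 hs.multiplier, _update_spec=False)
    if spec.lobectomy is not None:
        phantom = apply_lobectomy(phantom, spec.lobectomy, _update_spec=False)
    return phantom


# ---------------------------------------------------------------------------
# structural modifications


def apply_lobectomy(phantom: Phantom, lobe: str, fill: str = "soft_tissue",
                    _update_spec: bool = True) -> Phantom:
    """Remove a lobe: labels to background, HU to soft tissue (or air),
    activity to zero."""
    if lobe not in LOBE_NAMES:
        raise ValueError(f"unknown lobe {lobe!r}")
    mask = phantom.labels.lobe_mask(lobe)
    if not mask.any():
        raise ValueError(f"lobe {lobe} is already absent; cannot lobectomise")
    labels = phantom.labels.labels.copy()
    labels[mask] = 0
    hu = phantom.hu.copy()
    hu[mask] = (phantom.spec.hu_air if fill == "air"
                else phantom.spec.hu_soft_tissue)
    av = phantom.activity_v.copy()
    aq = phantom.activity_q.copy()
    av[mask] = 0.0
    aq[mask] = 0.0
    spec = (replace(phantom.spec, lobectomy=lobe) if _update_spec
            else phantom.spec)
    return Phantom(spec=spec, grid=phantom.grid,
                   labels=LobeLabelMap(grid=phantom.grid, labels=labels),
                   hu=hu, activity_v=av, activity_q=aq)


def apply_emphysema(phantom: Phantom, lobes: Sequence[str],
                    activity_factor: float, hu_value: float | None = None,
                    _update_spec: bool = True) -> Phantom:
    """Scale activity by ``activity_factor`` and lower HU in the given lobes."""
    if not 0.0 <= activity_factor <= 1.0:
        raise ValueError("activity_factor must be in [0, 1]")
    lobes = tuple(lobes)
    if not lobes:
        warnings.warn("apply_emphysema called with an empty lobe set; no-op",
                      stacklevel=2)
        return phantom
    if hu_value is None:
        hu_value = phantom.spec.hu_emphysema
    mask = np.zeros(phantom.grid.shape, dtype=bool)
    for lobe in lobes:
        mask |= phantom.labels.lobe_mask(lobe)
    hu = phantom.hu.copy()
    hu[mask] = hu_value
    av = phantom.activity_v.copy()
    aq = phantom.activity_q.copy()
    av[mask] *= activity_factor
    aq[mask] *= activity_factor
    spec = phantom.spec
    if _update_spec:
        spec = replace(spec, emphysema_lobes=lobes,
                       emphysema_activity_factor=activity_factor)
    return Phantom(spec=spec, grid=phantom.grid, labels=phantom.labels,
                   hu=hu, activity_v=av, activity_q=aq)


def insert_hotspot(phantom: Phantom, center_mm: Sequence[float],
                   radius_mm: float, multiplier: float,
                   _update_spec: bool = True) -> Phantom:
    """Multiply activity inside a sphere.  Hotspot counts are *not* subtracted
    later: they bias all quantification methods identically, which is the
    clinically realistic behaviour."""
    if radius_mm <= 0:
        raise ValueError("hotspot radius must be > 0")
    if multiplier < 0:
        raise ValueError("hotspot multiplier must be >= 0")
    x, y, z = phantom.grid.coordinate_mesh()
    cx, cy, cz = center_mm
    sphere = ((x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2) <= radius_mm ** 2
    in_lung = sphere & (phantom.labels.labels > 0)
    if not in_lung.any():
        warnings.warn("hotspot sphere does not intersect any lung; no-op",
                      stacklevel=2)
        return phantom
    av = phantom.activity_v.copy()
    aq = phantom.activity_q.copy()
    av[sphere] *= multiplier
    aq[sphere] *= multiplier
    spec = phantom.spec
    if _update_spec:
        hs = Hotspot(center_mm=tuple(center_mm), radius_mm=float(radius_mm),
                     multiplier=float(multiplier))
        spec = replace(spec, hotspots=spec.hotspots + (hs,))
    return Phantom(spec=spec, grid=phantom.grid, labels=phantom.labels,
                   hu=phantom.hu, activity_v=av, activity_q=aq)


def true_lobar_fractions(phantom: Phantom, tracer: str = "V") -> LobarDistribution:
    """Ground-truth relative distribution: per-lobe activity sums over total."""
    act = phantom.activity(tracer)
    sums = np.bincount(phantom.labels.labels.ravel(),
                       weights=act.ravel().astype(np.float64), minlength=6)
    counts = {name: float(sums[LOBE_CODES[name]]) for name in LOBE_NAMES}
    absent = tuple(n for n in LOBE_NAMES
                   if n not in phantom.labels.present_lobes())
    return LobarDistribution.from_counts(counts, tracer=tracer, method="truth",
                                         absent=absent)


# ---------------------------------------------------------------------------
# random phantom population


def sample_spec(rng: np.random.Generator | int | None = None,
                activity_cv: float = 0.15) -> PhantomSpec:
    """Draw one phantom spec from the default population ranges.

    The population emulates inter-patient anatomical variability: lung sizes
    jittered by ±8%, fissure heights by ±0.04, tilts by ±5°, and per-lobe
    specific activity log-normally with coefficient of variation
    ``activity_cv``.  The ranges are narrow enough that the anatomical
    ordering invariants (lobe laterality, RML anterior to RLL, RUL superior)
    hold for every draw.
    """
    rng = np.random.default_rng(rng)

    def u(lo: float, hi: float) -> float:
        return float(rng.uniform(lo, hi))

    def scale3(base: tuple[float, float, float], frac: float
               ) -> tuple[float, float, float]:
        return tuple(float(b * rng.uniform(1 - frac, 1 + frac)) for b in base)

    base = PhantomSpec()
    fiss = FissureSet(
        right_oblique_height=base.fissures.right_oblique_height + u(-0.04, 0.04),
        right_oblique_tilt_deg=base.fissures.right_oblique_tilt_deg + u(-5, 5),
        right_horizontal_height=base.fissures.right_horizontal_height + u(-0.04, 0.04),
        right_horizontal_tilt_deg=u(-2, 2),
        left_oblique_height=base.fissures.left_oblique_height + u(-0.04, 0.04),
        left_oblique_tilt_deg=base.fissures.left_oblique_tilt_deg + u(-5, 5),
    )
    sigma = np.sqrt(np.log(1 + activity_cv ** 2))
    act_v = {n: float(np.exp(rng.normal(-sigma ** 2 / 2, sigma)))
             for n in LOBE_NAMES}
    act_q = {n: float(np.exp(rng.normal(-sigma ** 2 / 2, sigma)))
             for n in LOBE_NAMES}
    return replace(
        base,
        right_lung_half_axes_mm=scale3(base.right_lung_half_axes_mm, 0.08),
        left_lung_half_axes_mm=scale3(base.left_lung_half_axes_mm, 0.08),
        fissures=fiss,
        activity_v=act_v,
        activity_q=act_q,
        seed=int(rng.integers(0, 2 ** 31 - 1)),
    )
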