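"""Attenuated forward projection of SPECT volumes into planar views.

Planar anterior and posterior scintigraphy images are synthesised by
ray-summing the reconstructed emission volume along the anterior–posterior
axis, weighting each voxel by the exponential attenuation of the µ integral
between it and the detector.  This reprojection approach produces high-count
planar images directly comparable to a conventional planar acquisition,
without re-acquiring the patient.

Conventions
-----------
* Parallel-beam geometry (parallel-hole collimator), views at 0° (anterior,
  detector on the +y side) and 180° (posterior) only.
* The emitting voxel contributes half of its own µ·Δy to the path integral
  (midpoint emitter, second-order accurate); voxels strictly between the
  emitter and the detector-side boundary contribute fully.
* No additional PSF at projection time — the SPECT volume is already blurred.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .distribution import LOBE_CODES, LEFT_LOBES, RIGHT_LOBES
from .imaging import MuMap, SpectVolume
from .phantom import LobeLabelMap

__all__ = ["PlanarImage", "attenuation_factors", "path_attenuation",
           "project_planar", "project_mask"]

VIEWS = ("anterior", "posterior")


@dataclass(frozen=True)
class PlanarImage:
    """2D planar count image indexed (x, z), with its view tag."""

    view: str
    pixels: np.ndarray
    pixel_spacing_mm: tuple[float, float]
    attenuated: bool = True

    def __post_init__(self) -> None:
        if self.view not in VIEWS:
            raise ValueError(f"view must be one of {VIEWS}, got {self.view!r}")
        if np.any(self.pixels < 0):
            raise ValueError("planar pixels must be >= 0")


def attenuation_factors(mu_map: MuMap, view: str) -> np.ndarray:
    """Per-voxel attenuation factors exp(−∫µ dy) toward the given detector.

    The integral runs from each voxel centre to the detector-side boundary:
    the full µ·Δy of every voxel strictly between, plus half the emitting
    voxel's own µ·Δy.
    """
    if view not in VIEWS:
        raise ValueError(f"view must be one of {VIEWS}, got {view!r}")
    mu = mu_map.mu
    dy = mu_map.grid.spacing_mm[1]
    if view == "anterior":
        # material at larger y (toward +y detector): suffix sum, exclusive
        inclusive = np.cumsum(mu[:, ::-1, :], axis=1)[:, ::-1, :]
    else:
        inclusive = np.cumsum(mu, axis=1)
    path = (inclusive - 0.5 * mu) * dy
    return np.exp(-path)


def path_attenuation(mu_map: MuMap, voxel_index: tuple[int, int, int],
                     view: str) -> float:
    """Attenuation factor in [0, 1] for a single voxel (convenience scalar)."""
    ix, iy, iz = voxel_index
    for axis, i in enumerate((ix, iy, iz)):
        if not 0 <= i < mu_map.grid.shape[axis]:
            raise IndexError(f"voxel index {voxel_index} outside grid "
                             f"{mu_map.grid.shape}")
    mu = mu_map.mu
    dy = mu_map.grid.spacing_mm[1]
    if view == "anterior":
        between = mu[ix, iy + 1:, iz].sum()
    elif view == "posterior":
        between = mu[ix, :iy, iz].sum()
    else:
        raise ValueError(f"view must be one of {VIEWS}, got {view!r}")
    return float(np.exp(-(between + 0.5 * mu[ix, iy, iz]) * dy))


def project_planar(spect: SpectVolume, mu_map: MuMap | None,
                   view: str) -> PlanarImage:
    """Forward-project a SPECT volume into one planar view.

    With a µ-map, each voxel's counts are weighted by its attenuation factor
    before the ray sum; with ``mu_map=None`` the projection is a plain ray
    sum and conserves total counts exactly.
    """
    if view not in VIEWS:
        raise ValueError(f"view must be one of {VIEWS}, got {view!r}")
    if mu_map is not None and not spect.grid.same_geometry(mu_map.grid):
        raise ValueError("SPECT and µ-map grids differ; resample the µ-map "
                         "onto the SPECT grid first (see resample_block)")
    counts = spect.counts
    if mu_map is not None:
        counts = counts * attenuation_factors(mu_map, view)
    pixels = counts.sum(axis=1)  # -> (x, z)
    sx, _, sz = spect.grid.spacing_mm
    return PlanarImage(view=view, pixels=pixels, pixel_spacing_mm=(sx, sz),
                       attenuated=mu_map is not None)


def project_mask(label_map: LobeLabelMap, view: str = "anterior",
                 lung: str = "both") -> np.ndarray:
    """2D binary silhouette of a lung: pixel true iff any voxel of the
    selected lung's labels lies along its anterior–posterior ray.

    The silhouette is identical for both views (the ray set is the same);
    ``view`` is accepted for interface symmetry.
    """
    if lung == "right":
        names = RIGHT_LOBES
    elif lung == "left":
        names = LEFT_LOBES
    elif lung == "both":
        names = RIGHT_LOBES + LEFT_LOBES
    else:
        raise ValueError(f"lung must be left/right/both, got {lung!r}")
    codes = [LOBE_CODES[n] for n in names]
    return np.isin(label_map.labels, codes).any(axis=1)


def project_body_mask(body: np.ndarray) -> np.ndarray:
    """2D silhouette of the body (thorax) mask, for background-ROI placement."""
    return np.asarray(body, dtype=bool).any(axis=1)
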