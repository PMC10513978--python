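"""Reconstructed-SPECT surrogate and CT-to-attenuation conversion.

The acquisition/reconstruction chain (projections, collimator response,
scatter windows, OSEM) is not simulated; the quantification methods consume
*reconstructed* images, so their product is modelled directly as an isotropic
Gaussian blur (the clinical 5 mm FWHM post-filter) followed by Poisson
counting noise.  HU volumes are converted to 140 keV linear attenuation
coefficients with the standard bilinear mapping anchored at air and water.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grid import VoxelGrid

__all__ = ["MU_WATER_140KEV_PER_MM", "FWHM_TO_SIGMA", "MuMap", "SpectVolume",
           "hu_to_mu", "simulate_spect", "resample_block"]

#: Linear attenuation coefficient of water at 140 keV (99mTc), mm^-1.
MU_WATER_140KEV_PER_MM = 0.0151

#: FWHM = sigma * 2*sqrt(2 ln 2).
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class MuMap:
    """Linear attenuation coefficients (mm^-1) at 140 keV on a voxel grid."""

    grid: VoxelGrid
    mu: np.ndarray
    mu_water: float = MU_WATER_140KEV_PER_MM
    bone_slope_factor: float = 0.5

    def __post_init__(self) -> None:
        if tuple(self.mu.shape) != self.grid.shape:
            raise ValueError("mu array shape does not match grid")
        if np.any(self.mu < 0):
            raise ValueError("attenuation coefficients must be >= 0")


@dataclass(frozen=True)
class SpectVolume:
    """Reconstructed-SPECT-like count volume with its simulation metadata."""

    grid: VoxelGrid
    counts: np.ndarray
    tracer: str = "V"
    psf_fwhm_mm: float = 5.0
    total_counts: float = 5e6
    noise: bool = True
    seed: int | None = None

    def __post_init__(self) -> None:
        if tuple(self.counts.shape) != self.grid.shape:
            raise ValueError("count array shape does not match grid")
        if np.any(self.counts < 0):
            raise ValueError("counts must be >= 0 everywhere")


def hu_to_mu(hu: np.ndarray, grid: VoxelGrid,
             mu_water: float = MU_WATER_140KEV_PER_MM,
             bone_slope_factor: float = 0.5) -> MuMap:
    """Bilinear HU → µ conversion at 140 keV.

    For HU ≤ 0 (air–water segment): µ = µ_w·(1 + HU/1000), floored at 0.
    For HU > 0 (water–bone segment): µ = µ_w·(1 + σ_b·HU/1000), with the
    reduced slope σ_b because bone attenuates photons less per HU than the
    water-equivalent extrapolation would predict at emission energies.
    Monotone nondecreasing in HU and continuous at HU = 0.
    """
    hu = np.asarray(hu, dtype=np.float64)
    if not np.all(np.isfinite(hu)):
        raise ValueError("HU volume contains non-finite values")
    if mu_water <= 0:
        raise ValueError("mu_water must be > 0")
    mu = np.where(hu <= 0,
                  mu_water * (1.0 + hu / 1000.0),
                  mu_water * (1.0 + bone_slope_factor * hu / 1000.0))
    np.clip(mu, 0.0, None, out=mu)
    return MuMap(grid=grid, mu=mu, mu_water=mu_water,
                 bone_slope_factor=bone_slope_factor)


def simulate_spect(activity: np.ndarray, grid: VoxelGrid,
                   psf_fwhm_mm: float = 5.0, total_counts: float = 5e6,
                   noise: bool = True, seed: int | None = None,
                   tracer: str = "V") -> SpectVolume:
    """Turn an activity volume into a reconstructed-SPECT-like count volume.

    The activity is scaled to ``total_counts``, blurred with an isotropic
    Gaussian of the given FWHM (kernel truncated at 4σ; the image is
    renormalised afterwards so edge truncation never breaks count
    conservation), and, with ``noise`` on, each voxel is replaced by a Poisson
    draw with that mean.  Deterministic given ``seed``.
    """
    activity = np.asarray(activity, dtype=np.float64)
    if np.any(activity < 0):
        raise ValueError("activity must be >= 0")
    total = activity.sum()
    if total <= 0:
        raise ValueError("activity sums to zero; nothing to image")
    if total_counts <= 0:
        raise ValueError("total_counts must be > 0")
    if psf_fwhm_mm < 0:
        raise ValueError("psf_fwhm_mm must be >= 0")

    img = activity * (total_counts / total)
    if psf_fwhm_mm > 0:
        sigma_vox = [psf_fwhm_mm * FWHM_TO_SIGMA / s for s in grid.spacing_mm]
        img = ndimage.gaussian_filter(img, sigma=sigma_vox, mode="constant",
                                      cval=0.0, truncate=4.0)
        img *= total_counts / img.sum()
    if noise:
        rng = np.random.default_rng(seed)
        img = rng.poisson(img).astype(np.float64)
    return SpectVolume(grid=grid, counts=img, tracer=tracer,
                       psf_fwhm_mm=psf_fwhm_mm, total_counts=total_counts,
                       noise=noise, seed=seed)


def resample_block(volume: np.ndarray, factor: int | tuple[int, int, int],
                   mode: str = "mean") -> np.ndarray:
    """Downsample by integer block aggregation.

    ``mean`` averages each block (sum-conserving once multiplied by block
    volume); ``majority`` takes the modal label per block with ties broken by
    the smallest label code, and is only meaningful for label volumes.
    """
    volume = np.asarray(volume)
    if np.isscalar(factor):
        factor = (int(factor),) * 3
    factor = tuple(int(f) for f in factor)
    if any(f < 1 for f in factor):
        raise ValueError("block factors must be integers >= 1")
    if any(n % f != 0 for n, f in zip(volume.shape, factor)):
        raise ValueError(f"shape {volume.shape} not divisible by factor "
                         f"{factor}; pad before resampling")
    fx, fy, fz = factor
    nx, ny, nz = (n // f for n, f in zip(volume.shape, factor))
    blocks = volume.reshape(nx, fx, ny, fy, nz, fz)
    if mode == "mean":
        return blocks.mean(axis=(1, 3, 5))
    if mode == "majority":
        if not np.issubdtype(volume.dtype, np.integer):
            raise ValueError("majority mode requires an integer label volume")
        flat = blocks.transpose(0, 2, 4, 1, 3, 5).reshape(nx, ny, nz, -1)
        n_codes = int(flat.max()) + 1
        counts = np.stack([(flat == c).sum(axis=-1) for c in range(n_codes)],
                          axis=-1)
        # argmax returns the first maximum -> smallest label wins ties
        return counts.argmax(axis=-1).astype(volume.dtype)
    raise ValueError(f"unknown mode {mode!r}")
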