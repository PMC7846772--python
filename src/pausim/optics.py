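"""Light transport in the diffusion approximation and laser-safety limits.

Optical coefficients are in 1/cm and the diffusion coefficient in cm; fiber
and pixel coordinates arrive in metres and are converted internally.  The
fluence model is the infinite-medium point-source Green's function

    Phi(r) = exp(-mu_eff * r) / (4 pi D r),   D = 1 / (3 mu_s')

which captures the far-field, mu_eff-dominated amplitude-vs-distance shape
used by both the forward simulator and the inverse fit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import ImageGrid, ProbeGeometry

M_TO_CM = 100.0

__all__ = [
    "FluenceParams",
    "FluenceMap",
    "MpeResult",
    "effective_attenuation",
    "diffusion_coefficient",
    "fluence_point_source",
    "fiber_pixel_distances",
    "total_fluence_map",
    "mpe_skin",
]


@dataclass(frozen=True)
class FluenceParams:
    """Diffusion-model parameters at one wavelength."""

    mu_eff: float  # 1/cm
    D: float  # cm
    wavelength: float  # nm

    def __post_init__(self) -> None:
        if self.mu_eff < 0:
            raise ValueError("mu_eff must be non-negative")
        if self.D <= 0:
            raise ValueError("diffusion coefficient must be positive")

    @classmethod
    def from_optical(cls, mu_a: float, mu_s_prime: float, wavelength: float) -> "FluenceParams":
        return cls(
            mu_eff=effective_attenuation(mu_a, mu_s_prime),
            D=diffusion_coefficient(mu_s_prime),
            wavelength=wavelength,
        )


def effective_attenuation(mu_a: float, mu_s_prime: float) -> float:
    """mu_eff = sqrt(3 mu_a mu_s') (1/cm), consistent with D = 1/(3 mu_s')."""
    if mu_a < 0 or mu_s_prime < 0:
        raise ValueError("optical coefficients must be non-negative")
    return float(np.sqrt(3.0 * mu_a * mu_s_prime))


def diffusion_coefficient(mu_s_prime: float) -> float:
    if mu_s_prime <= 0:
        raise ValueError("mu_s_prime must be positive")
    return 1.0 / (3.0 * mu_s_prime)


def fluence_point_source(r, params: FluenceParams):
    """Relative fluence at distance ``r`` (cm) from a unit point source."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("r must be positive (Green's function is singular at 0)")
    return np.exp(-params.mu_eff * r) / (4.0 * np.pi * params.D * r)


def fiber_pixel_distances(geometry: ProbeGeometry, grid: ImageGrid, fibers=None) -> np.ndarray:
    """3-D distances (cm) from each fiber to each in-plane pixel.

    Returns shape (n_fibers, nz, nx).  The elevation offset of the fiber rows
    keeps every distance strictly positive.
    """
    if fibers is None:
        fibers = np.arange(geometry.n_fibers)
    fp = geometry.fiber_positions[np.asarray(fibers, dtype=int)]
    X, Z = grid.mesh()
    dx = X[None, :, :] - fp[:, 0, None, None]
    dy = -fp[:, 1, None, None]
    dz = Z[None, :, :] - fp[:, 2, None, None]
    return np.sqrt(dx * dx + dy * dy + dz * dz) * M_TO_CM


@dataclass(frozen=True)
class FluenceMap:
    """Per-fiber and summed fluence on an image grid (unit source power)."""

    per_fiber: np.ndarray  # (n_fired, nz, nx)
    fired_fibers: tuple
    grid: ImageGrid
    wavelength: float
    params: FluenceParams

    @property
    def total(self) -> np.ndarray:
        return self.per_fiber.sum(axis=0)


def total_fluence_map(
    geometry: ProbeGeometry,
    params: FluenceParams,
    grid: ImageGrid,
    fired_fibers: Sequence[int] | None = None,
) -> FluenceMap:
    """Evaluate the diffusion fluence of each fired fiber on the grid."""
    if fired_fibers is None:
        fired_fibers = tuple(range(geometry.n_fibers))
    fired_fibers = tuple(int(f) for f in fired_fibers)
    if len(fired_fibers) == 0:
        raise ValueError("fired_fibers must not be empty")
    r = fiber_pixel_distances(geometry, grid, fired_fibers)
    per_fiber = fluence_point_source(r, params)
    return FluenceMap(
        per_fiber=per_fiber,
        fired_fibers=fired_fibers,
        grid=grid,
        wavelength=params.wavelength,
        params=params,
    )


@dataclass(frozen=True)
class MpeResult:
    """Skin maximum-permissible-exposure limit for one wavelength/duration."""

    wavelength: float  # nm
    exposure_time: float | None  # s; None marks the per-pulse (1-100 ns) case
    c_a: float
    limit_fluence: float | None = None  # J/cm^2 (per pulse, or total for t <= 10 s)
    limit_irradiance: float | None = None  # W/cm^2 (time-averaged)


def correction_factor_ca(wavelength: float) -> float:
    """Spectral correction factor: 1 up to 700 nm, then 10^(0.002 (lambda-700))
    capped at 5 (the cap takes over at ~1050 nm, keeping C_A nondecreasing)."""
    if wavelength <= 700.0:
        return 1.0
    return float(min(10.0 ** (0.002 * (wavelength - 700.0)), 5.0))


def mpe_skin(wavelength: float, exposure_time: float | str = "pulse") -> MpeResult:
    """Skin MPE for 400-1400 nm.

    ``exposure_time`` is either the string ``"pulse"`` (single 1-100 ns pulse,
    limit 20 C_A mJ/cm^2), a duration in seconds up to 10 s (limit
    1.1 C_A t^0.25 J/cm^2, reported also as average irradiance), or a longer
    duration (limit 0.2 C_A W/cm^2).
    """
    if not 400.0 <= wavelength <= 1400.0:
        raise ValueError("wavelength must lie within 400-1400 nm")
    c_a = correction_factor_ca(wavelength)
    if isinstance(exposure_time, str):
        if exposure_time != "pulse":
            raise ValueError("exposure_time must be a duration in s or 'pulse'")
        return MpeResult(wavelength, None, c_a, limit_fluence=20e-3 * c_a)
    t = float(exposure_time)
    if t <= 0:
        raise ValueError("exposure_time must be positive")
    if t > 10.0:
        return MpeResult(wavelength, t, c_a, limit_irradiance=0.2 * c_a)
    if t > 1e-7:
        fluence = 1.1 * c_a * t**0.25
        return MpeResult(wavelength, t, c_a, limit_fluence=fluence, limit_irradiance=fluence / t)
    raise ValueError("sub-100-ns exposures are covered by the per-pulse limit")
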