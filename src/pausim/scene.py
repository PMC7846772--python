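"""Synthetic phantom generation: chromophore spectra, optical property maps,
speckle scatterer fields and ground-truth motion."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.ndimage import map_coordinates

from .core import ImageGrid

log = logging.getLogger(__name__)

__all__ = [
    "Spectrum",
    "Phantom",
    "MotionField",
    "chromophore_spectrum",
    "make_phantom",
    "sample_motion",
    "intralipid_mu_s_prime",
]

# Resonance parameters of the nanorod-like chromophore: unimodal peak at
# 776 nm whose full width at 80% of maximum is 68 nm.  For a Lorentzian
# 1/(1 + u^2) the 0.8-level crossings are at u = +/- 0.5, so the width at 80%
# equals the scale parameter itself.
GNR_PEAK_NM = 776.0
GNR_WIDTH80_NM = 68.0

# Broad, blue-heavy background absorber table (Prussian-blue-like shape,
# normalized absorbance): decays smoothly across the NIR window.
_BACKGROUND_TABLE_NM = np.array([650.0, 700.0, 750.0, 800.0, 850.0, 900.0, 950.0])
_BACKGROUND_TABLE_VAL = np.array([0.95, 1.00, 0.84, 0.62, 0.43, 0.29, 0.20])


@dataclass(frozen=True)
class Spectrum:
    """Sampled absorption spectrum (or normalized absorbance)."""

    wavelengths: np.ndarray  # nm, strictly increasing
    values: np.ndarray  # >= 0
    name: str = ""

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if wl.ndim != 1 or wl.size == 0 or wl.shape != v.shape:
            raise ValueError("wavelengths and values must be matching 1-D arrays")
        if wl.size > 1 and not np.all(np.diff(wl) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if np.any(v < 0):
            raise ValueError("spectrum values must be non-negative")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "values", v)

    def __call__(self, wavelength) -> np.ndarray | float:
        """Linear interpolation onto arbitrary wavelengths (clamped ends)."""
        return np.interp(wavelength, self.wavelengths, self.values)

    def resample(self, wavelengths: Sequence[float]) -> "Spectrum":
        wl = np.asarray(wavelengths, dtype=float)
        return Spectrum(wl, self(wl), name=self.name)

    def area_normalized(self) -> "Spectrum":
        """Scale so the trapezoid integral over wavelength equals 1 (for a
        single-sample spectrum, so the value itself is 1)."""
        if self.wavelengths.size == 1:
            area = float(self.values[0])
        else:
            area = np.trapezoid(self.values, self.wavelengths)
        if area <= 0:
            raise ValueError("cannot area-normalize an all-zero spectrum")
        return Spectrum(self.wavelengths, self.values / area, name=self.name)


def chromophore_spectrum(kind: str, wavelengths: Sequence[float]) -> Spectrum:
    """Built-in chromophore spectra on the given wavelength grid (nm).

    ``gnr``   Lorentzian resonance, peak 776 nm, width-at-80%-max 68 nm.
    ``ink``   gently, monotonically decreasing with wavelength.
    ``background``  broad blue-heavy absorber (table lookup).
    ``flat``  constant.
    """
    wl = np.asarray(wavelengths, dtype=float)
    if np.any(wl < 650.0) or np.any(wl > 950.0):
        raise ValueError("wavelengths must lie within 650-950 nm")
    if kind == "gnr":
        u = (wl - GNR_PEAK_NM) / GNR_WIDTH80_NM
        values = 1.0 / (1.0 + u * u)
    elif kind == "ink":
        values = np.exp(-(wl - 650.0) / 400.0)
    elif kind == "background":
        values = np.interp(wl, _BACKGROUND_TABLE_NM, _BACKGROUND_TABLE_VAL)
    elif kind == "flat":
        values = np.ones_like(wl)
    else:
        raise ValueError(f"unknown chromophore kind {kind!r}")
    return Spectrum(wl, values, name=kind)


def intralipid_mu_s_prime(wavelength, mu_s_prime_700: float = 10.0, power: float = 1.6):
    """Reduced scattering coefficient (1/cm) with an Intralipid-like power-law
    decrease in wavelength, anchored at 700 nm."""
    return mu_s_prime_700 * (np.asarray(wavelength, dtype=float) / 700.0) ** (-power)


@dataclass(frozen=True)
class MotionField:
    """In-plane displacement field on an :class:`ImageGrid` (metres)."""

    d_axial: np.ndarray  # (nz, nx), m
    d_lateral: np.ndarray  # (nz, nx), m
    grid: ImageGrid

    def __post_init__(self) -> None:
        da = np.asarray(self.d_axial, dtype=float)
        dl = np.asarray(self.d_lateral, dtype=float)
        if da.shape != self.grid.shape or dl.shape != self.grid.shape:
            raise ValueError("displacement arrays must match the grid shape")
        if not (np.all(np.isfinite(da)) and np.all(np.isfinite(dl))):
            raise ValueError("displacements must be finite")
        object.__setattr__(self, "d_axial", da)
        object.__setattr__(self, "d_lateral", dl)

    @classmethod
    def zero(cls, grid: ImageGrid) -> "MotionField":
        return cls(np.zeros(grid.shape), np.zeros(grid.shape), grid)

    @property
    def magnitude(self) -> np.ndarray:
        return np.hypot(self.d_axial, self.d_lateral)

    def in_pixels(self):
        """Return (axial, lateral) displacement in pixel units."""
        return self.d_axial / self.grid.dz, self.d_lateral / self.grid.dx


def sample_motion(motion_model: dict | None, frame_index: int, grid: ImageGrid) -> MotionField:
    """Ground-truth displacement of frame ``frame_index`` relative to frame 0.

    Models: ``{"model": "none"}``; rigid per-frame translation
    ``{"model": "rigid", "per_frame_axial": m, "per_frame_lateral": m}``;
    smooth oscillation ``{"model": "sinusoidal", "amplitude_axial": m,
    "amplitude_lateral": m, "period_frames": T, "spatial_period": m}`` whose
    peak magnitude over frames equals the configured amplitude.
    """
    if motion_model is None:
        motion_model = {"model": "none"}
    kind = motion_model.get("model", "none")
    if frame_index == 0 or kind == "none":
        return MotionField.zero(grid)
    if kind == "rigid":
        dz = float(motion_model.get("per_frame_axial", 0.0)) * frame_index
        dx = float(motion_model.get("per_frame_lateral", 0.0)) * frame_index
        return MotionField(np.full(grid.shape, dz), np.full(grid.shape, dx), grid)
    if kind == "sinusoidal":
        T = float(motion_model.get("period_frames", 8))
        phase = np.sin(2.0 * np.pi * frame_index / T)
        sp = motion_model.get("spatial_period", None)
        X, Z = grid.mesh()
        if sp is None:
            profile = np.ones(grid.shape)
        else:
            # Smooth in-plane modulation, unit peak so max |d| = amplitude.
            profile = np.cos(np.pi * X / float(sp)) * np.cos(np.pi * (Z - Z.min()) / float(sp))
        da = float(motion_model.get("amplitude_axial", 0.0)) * phase * profile
        dl = float(motion_model.get("amplitude_lateral", 0.0)) * phase * profile
        return MotionField(da, dl, grid)
    raise ValueError(f"unknown motion model {kind!r}")


@dataclass
class Phantom:
    """Gridded synthetic scene: chromophore concentration maps with spectra,
    background optics, speckle scatterers and a motion model.

    The absorption map composes linearly,
    ``mu_a(p, lambda) = mu_a_bg(lambda) + sum_k c_k(p) * eps_k(lambda)``,
    with concentrations in arbitrary units times spectra in 1/cm.
    """

    grid: ImageGrid
    chromophores: dict  # name -> (concentration map (nz, nx), Spectrum)
    background_mu_a: Spectrum  # 1/cm vs nm (spatially uniform)
    mu_s_prime_700: float = 10.0  # 1/cm at 700 nm
    scattering_power: float = 1.6
    scatterer_positions: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))
    scatterer_reflectivity: np.ndarray = field(default_factory=lambda: np.zeros(0))
    grueneisen: float = 0.2
    motion_model: dict | None = None

    def mu_s_prime(self, wavelength) -> float:
        return float(intralipid_mu_s_prime(wavelength, self.mu_s_prime_700, self.scattering_power))

    def background_mu_eff(self, wavelength) -> float:
        """Background effective attenuation sqrt(3 mu_a mu_s') in 1/cm."""
        mu_a = float(self.background_mu_a(wavelength))
        return float(np.sqrt(3.0 * mu_a * self.mu_s_prime(wavelength)))

    def mu_a_map(self, wavelength: float, frame_index: int = 0) -> np.ndarray:
        """Per-pixel absorption (1/cm) at ``wavelength``, displaced to the
        scene state at ``frame_index`` per the motion model."""
        out = np.full(self.grid.shape, float(self.background_mu_a(wavelength)))
        for cmap, spec in self.chromophores.values():
            out = out + cmap * float(spec(wavelength))
        if frame_index:
            out = _pushforward(out, sample_motion(self.motion_model, frame_index, self.grid), self.grid)
        return out

    def scatterers_at_frame(self, frame_index: int = 0):
        """Scatterer positions displaced by the motion model at this frame."""
        pos = self.scatterer_positions
        if frame_index == 0 or self.motion_model is None or not len(pos):
            return pos, self.scatterer_reflectivity
        f = sample_motion(self.motion_model, frame_index, self.grid)
        zi = np.clip((pos[:, 2] - self.grid.z0) / self.grid.dz, 0, self.grid.nz - 1)
        xi = np.clip((pos[:, 0] - self.grid.x0) / self.grid.dx, 0, self.grid.nx - 1)
        da = map_coordinates(f.d_axial, [zi, xi], order=1, mode="nearest")
        dl = map_coordinates(f.d_lateral, [zi, xi], order=1, mode="nearest")
        moved = pos.copy()
        moved[:, 0] += dl
        moved[:, 2] += da
        return moved, self.scatterer_reflectivity

    def concentration_mask(self, name: str, frame_index: int = 0, level: float = 0.5) -> np.ndarray:
        """Boolean support of one chromophore (above ``level`` x its max)."""
        cmap, _ = self.chromophores[name]
        if frame_index:
            cmap = _pushforward(cmap, sample_motion(self.motion_model, frame_index, self.grid), self.grid)
        peak = cmap.max()
        return cmap > level * peak if peak > 0 else np.zeros(self.grid.shape, bool)


def _pushforward(image: np.ndarray, f: MotionField, grid: ImageGrid) -> np.ndarray:
    """Move image content by +d: out(x) = image(x - d(x)) (small-motion form)."""
    zi, xi = np.meshgrid(np.arange(grid.nz), np.arange(grid.nx), indexing="ij")
    da, dl = f.in_pixels()
    return map_coordinates(image, [zi - da, xi - dl], order=1, mode="nearest")


def make_phantom(config: dict, seed: int, grid: ImageGrid | None = None) -> Phantom:
    """Build a reproducible phantom from a structured config.

    ``config`` keys (lengths in mm):
      background: mu_a_scale (1/cm), mu_s_prime_700, scattering_power
      inclusions: list of {shape: disk, center_mm: [x, z], radius_mm,
                           chromophore: kind or {csv spectrum already loaded},
                           mu_a: peak absorption in 1/cm at the spectrum max}
      scatterer_density_per_mm2, scatterer_region_mm (optional [x0,x1,z0,z1])
      grueneisen, motion (model dict with *_mm entries)

    Scatterers are seeded independently of the optics so changing optical
    content leaves the speckle realization unchanged.
    """
    if grid is None:
        g = config.get("grid", {})
        grid = ImageGrid.centered(
            width=float(g.get("width_mm", 12.8)) * 1e-3,
            depth=float(g.get("depth_mm", 10.0)) * 1e-3,
            pitch=float(g.get("pitch_mm", 0.1)) * 1e-3,
            z0=float(g.get("z0_mm", 2.0)) * 1e-3,
        )
    bg = config.get("background", {})
    wl_grid = np.arange(650.0, 951.0, 5.0)
    mu_a_bg = chromophore_spectrum("background", wl_grid)
    mu_a_bg = Spectrum(wl_grid, mu_a_bg.values * float(bg.get("mu_a_scale", 0.05)), name="background")

    X, Z = grid.mesh()
    chromophores: dict = {}
    occupied = np.zeros(grid.shape, bool)
    for k, inc in enumerate(config.get("inclusions", [])):
        kind = inc.get("chromophore", "flat")
        spec = chromophore_spectrum(kind, wl_grid) if isinstance(kind, str) else kind
        peak = spec.values.max()
        scale = float(inc.get("mu_a", 1.0)) / peak
        cx, cz = (float(v) * 1e-3 for v in inc.get("center_mm", [0.0, 5.0]))
        r = float(inc.get("radius_mm", 0.5)) * 1e-3
        mask = (X - cx) ** 2 + (Z - cz) ** 2 <= r**2
        if np.any(mask & occupied):
            log.warning("inclusion %d overlaps an earlier one; last writer wins", k)
            for cmap, _ in chromophores.values():
                cmap[mask] = 0.0
        occupied |= mask
        name = inc.get("name", f"{spec.name}_{k}")
        cmap = np.zeros(grid.shape)
        cmap[mask] = scale
        chromophores[name] = (cmap, spec)

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5CA7]))
    density = float(config.get("scatterer_density_per_mm2", 300.0))
    region = config.get("scatterer_region_mm", None)
    if region is None:
        x0, x1 = grid.x[0], grid.x[-1]
        z0, z1 = grid.z[0], grid.z[-1]
    else:
        x0, x1, z0, z1 = (float(v) * 1e-3 for v in region)
    area_mm2 = (x1 - x0) * (z1 - z0) * 1e6
    n_scat = rng.poisson(density * area_mm2)
    pos = np.column_stack(
        [rng.uniform(x0, x1, n_scat), np.zeros(n_scat), rng.uniform(z0, z1, n_scat)]
    )
    refl = rng.normal(0.0, 1.0, n_scat)

    motion = config.get("motion", None)
    if motion is not None:
        motion = dict(motion)
        for key in list(motion):
            if key.endswith("_mm"):
                motion[key[:-3]] = float(motion[key]) * 1e-3
                del motion[key]

    return Phantom(
        grid=grid,
        chromophores=chromophores,
        background_mu_a=mu_a_bg,
        mu_s_prime_700=float(bg.get("mu_s_prime_700", 10.0)),
        scattering_power=float(bg.get("scattering_power", 1.6)),
        scatterer_positions=pos,
        scatterer_reflectivity=refl,
        grueneisen=float(config.get("grueneisen", 0.2)),
        motion_model=motion,
    )
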