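"""Dataset container (HDF5), reference-spectrum CSV readers and seeded
random substreams shared by the pipeline and the CLI."""

from __future__ import annotations

import zlib
from pathlib import Path

import h5py
import numpy as np
import yaml

from .acoustics import RFFrame
from .beamform import SpectroStack
from .core import ImageGrid
from .scene import MotionField, Spectrum

__all__ = ["Dataset", "read_spectrum_csv", "write_spectrum_csv", "rng_for", "seed_for"]

FORMAT_VERSION = "1"


def seed_for(seed: int, name: str) -> list:
    """Stable named substream key derived from the top-level seed."""
    return [int(seed), zlib.crc32(name.encode())]


def rng_for(seed: int, name: str) -> np.random.Generator:
    """Named random substream: changing one stream's draws leaves the others
    unchanged."""
    return np.random.default_rng(seed_for(seed, name))


def read_spectrum_csv(path) -> Spectrum:
    """Read a two-column CSV (header ``wavelength_nm,value``) into a Spectrum.

    Wavelengths must be strictly increasing; malformed rows are rejected with
    their line number.
    """
    path = Path(path)
    wavelengths, values = [], []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            parts = [p.strip() for p in line.split(",")]
            if lineno == 1 and not _is_number(parts[0]):
                if [p.lower() for p in parts[:2]] != ["wavelength_nm", "value"]:
                    raise ValueError(f"{path}:{lineno}: expected header 'wavelength_nm,value'")
                continue
            if len(parts) < 2 or not (_is_number(parts[0]) and _is_number(parts[1])):
                raise ValueError(f"{path}:{lineno}: malformed row {raw.rstrip()!r}")
            wl = float(parts[0])
            if wavelengths and wl <= wavelengths[-1]:
                raise ValueError(f"{path}:{lineno}: wavelengths not strictly increasing")
            wavelengths.append(wl)
            values.append(float(parts[1]))
    if not wavelengths:
        raise ValueError(f"{path}: no data rows")
    return Spectrum(np.asarray(wavelengths), np.asarray(values), name=path.stem)


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def write_spectrum_csv(spectrum: Spectrum, path) -> None:
    with open(path, "w") as fh:
        fh.write("wavelength_nm,value\n")
        for wl, v in zip(spectrum.wavelengths, spectrum.values):
            fh.write(f"{wl:.6g},{v:.10g}\n")


def _wkey(wavelength: float) -> str:
    return f"{float(wavelength):.1f}"


class Dataset:
    """Hierarchical result container with groups /config, /phantom, /rf,
    /images, /motion, /images_mc and /spectral.

    Derived groups record the identifiers of their inputs; deterministic
    stages re-run with identical inputs and seed reproduce identical content.
    """

    def __init__(self, path, mode: str = "a"):
        self._f = h5py.File(path, mode)

    # -- lifecycle ---------------------------------------------------------
    def close(self) -> None:
        self._f.close()

    def __enter__(self) -> "Dataset":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    @property
    def h5(self) -> h5py.File:
        return self._f

    # -- provenance --------------------------------------------------------
    def set_provenance(self, seed: int, config: dict) -> None:
        g = self._f.require_group("config")
        g.attrs["seed"] = int(seed)
        g.attrs["version"] = FORMAT_VERSION
        g.attrs["config_yaml"] = yaml.safe_dump(config)

    def get_config(self) -> tuple:
        g = self._f["config"]
        return int(g.attrs["seed"]), yaml.safe_load(g.attrs["config_yaml"])

    # -- grid --------------------------------------------------------------
    def _write_grid(self, group: h5py.Group, grid: ImageGrid) -> None:
        for k in ("x0", "z0", "dx", "dz"):
            group.attrs[f"grid_{k}"] = getattr(grid, k)
        group.attrs["grid_nx"] = grid.nx
        group.attrs["grid_nz"] = grid.nz

    def _read_grid(self, group: h5py.Group) -> ImageGrid:
        a = group.attrs
        return ImageGrid(x0=float(a["grid_x0"]), z0=float(a["grid_z0"]),
                         nx=int(a["grid_nx"]), nz=int(a["grid_nz"]),
                         dx=float(a["grid_dx"]), dz=float(a["grid_dz"]))

    # -- RF ----------------------------------------------------------------
    def write_rf(self, frame: int, firing: str, rf: RFFrame) -> None:
        g = self._f.require_group(f"rf/{frame:03d}")
        d = g.create_dataset(str(firing), data=rf.samples)
        d.attrs["sampling_rate"] = rf.sampling_rate
        d.attrs["t0"] = rf.t0
        d.attrs["kind"] = rf.kind
        d.attrs["laser_energy"] = rf.laser_energy
        if rf.wavelength is not None:
            d.attrs["wavelength_nm"] = rf.wavelength
        if rf.fiber_index is not None:
            d.attrs["fiber_index"] = rf.fiber_index

    def read_rf(self, frame: int, firing: str) -> RFFrame:
        d = self._f[f"rf/{frame:03d}/{firing}"]
        a = d.attrs
        return RFFrame(
            samples=d[()], sampling_rate=float(a["sampling_rate"]), t0=float(a["t0"]),
            kind=str(a["kind"]), laser_energy=float(a["laser_energy"]),
            wavelength=float(a["wavelength_nm"]) if "wavelength_nm" in a else None,
            fiber_index=int(a["fiber_index"]) if "fiber_index" in a else None,
        )

    def rf_frames(self) -> list:
        return sorted(int(k) for k in self._f["rf"])

    def rf_firings(self, frame: int) -> list:
        return sorted(self._f[f"rf/{frame:03d}"].keys())

    # -- beamformed stacks -------------------------------------------------
    def write_stack(self, stack: SpectroStack, group: str = "images") -> None:
        g = self._f.require_group(group)
        self._write_grid(g, stack.grid)
        g.attrs["wavelengths"] = list(stack.wavelengths)
        g.attrs["laser_off_wavelengths"] = list(stack.laser_off_wavelengths)
        g.attrs["motion_corrected"] = stack.motion_corrected
        g.attrs["fluence_compensated"] = stack.fluence_compensated
        for w in stack.wavelengths:
            gw = g.require_group(_wkey(w))
            gw.create_dataset("subimages", data=stack.subimages[w])
            gw.create_dataset("compound", data=stack.compound[w])
            gw.attrs["laser_energy"] = stack.laser_energy.get(w, 1.0)
            if w in stack.bmode:
                gw.create_dataset("bmode", data=stack.bmode[w])

    def read_stack(self, group: str = "images") -> SpectroStack:
        g = self._f[group]
        grid = self._read_grid(g)
        stack = SpectroStack(
            grid=grid,
            wavelengths=tuple(float(w) for w in g.attrs["wavelengths"]),
            laser_off_wavelengths=tuple(float(w) for w in g.attrs["laser_off_wavelengths"]),
            motion_corrected=bool(g.attrs["motion_corrected"]),
            fluence_compensated=bool(g.attrs["fluence_compensated"]),
        )
        for w in stack.wavelengths:
            gw = g[_wkey(w)]
            stack.subimages[w] = gw["subimages"][()]
            stack.compound[w] = gw["compound"][()]
            stack.laser_energy[w] = float(gw.attrs["laser_energy"])
            if "bmode" in gw:
                stack.bmode[w] = gw["bmode"][()]
        return stack

    # -- motion ------------------------------------------------------------
    def write_motion(self, fields: dict, grid: ImageGrid) -> None:
        g = self._f.require_group("motion")
        self._write_grid(g, grid)
        for w, f in fields.items():
            gw = g.require_group(_wkey(w))
            gw.create_dataset("d_axial", data=f.d_axial)
            gw.create_dataset("d_lateral", data=f.d_lateral)

    def read_motion(self) -> dict:
        g = self._f["motion"]
        grid = self._read_grid(g)
        return {
            float(k): MotionField(g[k]["d_axial"][()], g[k]["d_lateral"][()], grid)
            for k in g if isinstance(g[k], h5py.Group)
        }

    # -- phantom ground truth ----------------------------------------------
    def write_phantom(self, phantom, wavelengths) -> None:
        g = self._f.require_group("phantom")
        self._write_grid(g, phantom.grid)
        g.attrs["grueneisen"] = phantom.grueneisen
        g.create_dataset("scatterer_positions", data=phantom.scatterer_positions)
        g.create_dataset("scatterer_reflectivity", data=phantom.scatterer_reflectivity)
        for w in wavelengths:
            g.create_dataset(f"mu_a/{_wkey(w)}", data=phantom.mu_a_map(w))
        for name, (cmap, spec) in phantom.chromophores.items():
            g.create_dataset(f"concentration/{name}", data=cmap)

    def read_phantom_maps(self) -> dict:
        g = self._f["phantom"]
        return {float(k): g[f"mu_a/{k}"][()] for k in g["mu_a"]}

    # -- spectral outputs --------------------------------------------------
    def write_spectral(self, fits: dict, sigma_lambda: np.ndarray, components: dict,
                       noise_floor: np.ndarray | None = None,
                       fluence_maps: dict | None = None) -> None:
        g = self._f.require_group("spectral")
        wl = sorted(fits)
        table = np.array([[w, fits[w].mu_eff_hat, fits[w].d_hat, fits[w].residual] for w in wl])
        g.create_dataset("mu_eff_per_wavelength", data=table)
        g["mu_eff_per_wavelength"].attrs["columns"] = "wavelength_nm,mu_eff_1_cm,D_cm,residual"
        for w, phi in (fluence_maps or {}).items():
            g.create_dataset(f"fluence/{_wkey(w)}", data=phi)
        g.create_dataset("sigma_lambda", data=sigma_lambda)
        if noise_floor is not None:
            g.create_dataset("noise_floor", data=noise_floor)
        for name, comp in components.items():
            gc = g.require_group(f"component/{name}")
            gc.create_dataset("image", data=comp.image)
            gc.create_dataset("ncc_map", data=comp.ncc_map)
            gc.create_dataset("display_mask", data=comp.display_mask)

    def read_spectral(self) -> dict:
        g = self._f["spectral"]
        out = {
            "mu_eff_per_wavelength": g["mu_eff_per_wavelength"][()],
            "sigma_lambda": g["sigma_lambda"][()],
            "components": {},
        }
        if "noise_floor" in g:
            out["noise_floor"] = g["noise_floor"][()]
        if "component" in g:
            for name in g["component"]:
                gc = g[f"component/{name}"]
                out["components"][name] = {
                    "image": gc["image"][()],
                    "ncc_map": gc["ncc_map"][()],
                    "display_mask": gc["display_mask"][()],
                }
        return out


def save_png(image: np.ndarray, path, dynamic_range_db: float = 40.0) -> None:
    """Log-compressed display export over the given dynamic range."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    env = np.abs(image)
    peak = env.max() if env.max() > 0 else 1.0
    db = 20.0 * np.log10(np.maximum(env / peak, 10 ** (-dynamic_range_db / 20.0 - 1)))
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.imshow(db, cmap="gray", vmin=-dynamic_range_db, vmax=0.0, aspect="auto")
    ax.set_axis_off()
    fig.savefig(path, bbox_inches="tight", dpi=150)
    plt.close(fig)
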