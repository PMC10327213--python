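"""Density-grid I/O, model-to-density synthesis, and residue footprints.

Grids are orthorhombic P1 boxes: a 3-D scalar array with per-axis voxel
spacing and a Cartesian origin; voxel (i,j,k) is centered at
``origin + (i,j,k) * spacing``.  Model density is synthesized in real space
as per-atom isotropic Gaussians whose variance combines the atomic B-factor
with a resolution-dependent blur, and whose amplitude is the element's
electron count (X-ray) or a tabulated electron-scattering amplitude (EM).
This real-space Gaussian model is linear in occupancy and additive over
atoms, which is exactly what the occupancy QP requires.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gemmi
import numpy as np

from multiconf.structure import Conformer

# X-ray amplitudes: electron count per element.
XRAY_AMPLITUDE = {"H": 1.0, "C": 6.0, "N": 7.0, "O": 8.0, "S": 16.0,
                  "P": 15.0, "Se": 34.0}
# Electron scattering amplitudes: sums of the 5-Gaussian fit coefficients
# (Angstrom), giving relative forward-scattering weights per element.
EM_AMPLITUDE = {"H": 0.529, "C": 2.509, "N": 2.213, "O": 1.983, "S": 5.448,
                "P": 5.488, "Se": 8.09}

# Resolution-dependent blur: sigma_res = BLUR_CONSTANT * d (Angstrom).
BLUR_CONSTANT = 0.225


class UnsupportedCellError(ValueError):
    pass


class OutOfMapError(ValueError):
    pass


@dataclass
class ScatteringMode:
    """X-ray vs cryo-EM scoring mode.

    X-ray maps carry a flat bulk-solvent background which is subtracted
    from the target density (0.3 by default); EM maps do not.
    """

    mode: str = "xray"
    solvent_level: float | None = None

    def __post_init__(self):
        if self.mode not in ("xray", "em"):
            raise ValueError(f"unknown scattering mode {self.mode!r}")
        if self.solvent_level is None:
            self.solvent_level = 0.3 if self.mode == "xray" else 0.0
        if self.mode == "em" and self.solvent_level != 0.0:
            raise ValueError("EM mode uses solvent_level 0")

    @property
    def amplitudes(self) -> dict[str, float]:
        return XRAY_AMPLITUDE if self.mode == "xray" else EM_AMPLITUDE


@dataclass
class DensityGrid:
    values: np.ndarray            # (nx, ny, nz), x-fast Cartesian order
    spacing: np.ndarray           # (3,) A per voxel
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float32)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        if np.any(self.spacing <= 0):
            raise ValueError("grid spacing must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def cell(self) -> np.ndarray:
        return self.spacing * np.array(self.shape)

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    def index_to_xyz(self, idx: np.ndarray) -> np.ndarray:
        return self.origin + np.asarray(idx, dtype=float) * self.spacing

    def xyz_to_index(self, xyz: np.ndarray) -> np.ndarray:
        return (np.asarray(xyz, dtype=float) - self.origin) / self.spacing

    def copy(self) -> "DensityGrid":
        return DensityGrid(self.values.copy(), self.spacing.copy(),
                           self.origin.copy())


@dataclass
class Footprint:
    """Deterministic voxel mask over which a residue's candidates are scored."""

    indices: np.ndarray           # (n, 3) int voxel indices
    xyz: np.ndarray               # (n, 3) Cartesian voxel centers

    @property
    def n(self) -> int:
        return len(self.indices)


def read_map(path) -> DensityGrid:
    """Read a CCP4/MRC map, axis order normalized to x-fast."""
    m = gemmi.read_ccp4_map(str(path))
    m.setup(float("nan"))
    cell = m.grid.unit_cell
    if not (abs(cell.alpha - 90) < 1e-3 and abs(cell.beta - 90) < 1e-3
            and abs(cell.gamma - 90) < 1e-3):
        raise UnsupportedCellError("only orthorhombic P1 cells are supported")
    values = np.array(m.grid, copy=True)
    shape = np.array(values.shape, dtype=float)
    spacing = np.array([cell.a, cell.b, cell.c]) / shape
    origin = np.array([m.header_float(w) for w in (50, 51, 52)])
    if np.allclose(origin, 0.0):
        nstart = np.array([m.header_i32(w) for w in (5, 6, 7)], dtype=float)
        origin = nstart * spacing
    return DensityGrid(values, spacing, origin)


def write_map(grid: DensityGrid, path) -> None:
    m = gemmi.Ccp4Map()
    nx, ny, nz = grid.shape
    cell = gemmi.UnitCell(*(grid.cell), 90, 90, 90)
    m.grid = gemmi.FloatGrid(np.ascontiguousarray(grid.values, dtype=np.float32),
                             cell, gemmi.SpaceGroup("P1"))
    m.update_ccp4_header()
    for w, v in zip((50, 51, 52), grid.origin):
        m.set_header_float(w, float(v))
    m.write_ccp4_map(str(path))


def sigma2_from_b(b: float, resolution: float,
                  blur_constant: float = BLUR_CONSTANT) -> float:
    """Gaussian variance (A^2) for an atom: B/(8 pi^2) plus resolution blur."""
    return b / (8.0 * np.pi ** 2) + (blur_constant * resolution) ** 2


def density_from_conformer(conformer: Conformer, footprint: Footprint,
                           mode: ScatteringMode, resolution: float,
                           blur_constant: float = BLUR_CONSTANT) -> np.ndarray:
    """Synthesize the conformer's density over a footprint.

    Each atom contributes ``occ * A * (2 pi s2)^-1.5 * exp(-r^2 / (2 s2))``
    with ``s2 = B/(8 pi^2) + (blur_constant * d)^2``; the profile integrates
    to ``occ * A`` so total density is conserved across B-factors.
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    out = np.zeros(footprint.n)
    amps = mode.amplitudes
    for atom in conformer.atoms:
        if atom.b <= 0:
            raise ValueError(f"atom {atom.name} has non-positive B")
        s2 = sigma2_from_b(atom.b, resolution, blur_constant)
        amp = amps.get(atom.element, float(max(1.0, len(atom.element) * 6.0)))
        r2 = np.sum((footprint.xyz - atom.pos) ** 2, axis=1)
        out += (atom.occupancy * amp * (2 * np.pi * s2) ** -1.5
                * np.exp(-r2 / (2 * s2)))
    return out


def density_on_grid(conformers: list[Conformer], grid: DensityGrid,
                    mode: ScatteringMode, resolution: float,
                    cutoff_sigmas: float = 4.0,
                    blur_constant: float = BLUR_CONSTANT) -> None:
    """Accumulate conformer densities into grid.values in place."""
    shape = np.array(grid.shape)
    amps = mode.amplitudes
    for conf in conformers:
        for atom in conf.atoms:
            s2 = sigma2_from_b(atom.b, resolution, blur_constant)
            rcut = cutoff_sigmas * np.sqrt(s2)
            lo = np.floor(grid.xyz_to_index(atom.pos - rcut)).astype(int)
            hi = np.ceil(grid.xyz_to_index(atom.pos + rcut)).astype(int) + 1
            lo = np.clip(lo, 0, shape)
            hi = np.clip(hi, 0, shape)
            if np.any(lo >= hi):
                continue
            axes = [np.arange(lo[k], hi[k]) for k in range(3)]
            xs = grid.origin[0] + axes[0] * grid.spacing[0] - atom.pos[0]
            ys = grid.origin[1] + axes[1] * grid.spacing[1] - atom.pos[1]
            zs = grid.origin[2] + axes[2] * grid.spacing[2] - atom.pos[2]
            r2 = (xs[:, None, None] ** 2 + ys[None, :, None] ** 2
                  + zs[None, None, :] ** 2)
            amp = amps.get(atom.element, 6.0)
            contrib = (atom.occupancy * amp * (2 * np.pi * s2) ** -1.5
                       * np.exp(-r2 / (2 * s2)))
            grid.values[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] += contrib


def extract_footprint(conformers: list[Conformer], grid: DensityGrid,
                      rmask: float) -> Footprint:
    """Union of voxels within rmask of any atom of any conformer.

    Ordering is deterministic: ascending flattened (x-major) voxel index.
    """
    if not conformers:
        raise ValueError("no conformers for footprint")
    shape = np.array(grid.shape)
    flat: set[int] = set()
    for conf in conformers:
        for atom in conf.atoms:
            lo = np.floor(grid.xyz_to_index(atom.pos - rmask)).astype(int)
            hi = np.ceil(grid.xyz_to_index(atom.pos + rmask)).astype(int) + 1
            lo_c = np.clip(lo, 0, shape - 1)
            hi_c = np.clip(hi, 1, shape)
            if np.any(lo_c >= hi_c):
                continue
            axes = [np.arange(lo_c[k], hi_c[k]) for k in range(3)]
            ii, jj, kk = np.meshgrid(*axes, indexing="ij")
            idx = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)
            xyz = grid.index_to_xyz(idx)
            d2 = np.sum((xyz - atom.pos) ** 2, axis=1)
            within = idx[d2 <= rmask ** 2]
            if len(within) == 0:
                # guarantee at least the nearest voxel per atom
                near = np.round(grid.xyz_to_index(atom.pos)).astype(int)
                if np.all(near >= 0) and np.all(near < shape):
                    within = near[None, :]
            for f in np.ravel_multi_index(within.T, grid.shape):
                flat.add(int(f))
    if not flat:
        raise OutOfMapError("residue footprint does not intersect the map")
    order = np.array(sorted(flat))
    indices = np.stack(np.unravel_index(order, grid.shape), axis=1)
    return Footprint(indices, grid.index_to_xyz(indices))


def default_rmask(resolution: float) -> float:
    """Resolution-scaled footprint radius (A)."""
    return 0.5 + resolution / 3.0


def target_vector(grid: DensityGrid, fp: Footprint,
                  mode: ScatteringMode) -> np.ndarray:
    """Observed density over a footprint, solvent-subtracted and floored at 0."""
    vals = grid.values[fp.indices[:, 0], fp.indices[:, 1], fp.indices[:, 2]]
    return np.maximum(vals.astype(float) - mode.solvent_level, 0.0)


def normalize_grid(grid: DensityGrid) -> DensityGrid:
    """Rescale so the mean of positive density is 1 (for arbitrary map scales)."""
    pos = grid.values[grid.values > 0]
    scale = float(pos.mean()) if pos.size else 1.0
    out = grid.copy()
    if scale > 0:
        out.values = out.values / scale
    return out
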