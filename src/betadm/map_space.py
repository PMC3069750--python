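"""Reciprocal <-> real space transforms for P1 density maps.

Synthesis convention: the density is the real part of the hemisphere sum,
rho(x) = sum_h Re[F(h) exp(2 pi i h.x)], i.e. half of the full Friedel-
completed Fourier sum.  A single reflection (1,0,0) with F = 1 therefore
synthesizes exactly cos(2 pi x).  Inversion is normalized so that
synthesize followed by invert is the identity on band-limited maps.
F(000) is treated as zero everywhere, so maps are mean-zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthetic_crystal import UnitCell

__all__ = [
    "DensityMap",
    "default_grid_shape",
    "synthesize_map",
    "map_to_structure_factors",
    "map_correlation",
    "write_ccp4",
]


@dataclass
class DensityMap:
    """Real-valued density samples on a regular grid over a P1 cell."""

    values: np.ndarray  # (nx, ny, nz) float
    cell: UnitCell
    label: str = "experimental"  # experimental | modified | combined | model

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def size(self) -> int:
        return self.values.size

    def copy(self, label: str | None = None) -> "DensityMap":
        return DensityMap(self.values.copy(), self.cell, label or self.label)


def default_grid_shape(
    cell: UnitCell, d_min: float, factor: float = 3.0
) -> tuple[int, int, int]:
    """Smallest grid with spacing <= d_min / factor along every axis."""
    return tuple(int(np.ceil(factor * ax / d_min)) for ax in cell.lengths)


def _check_grid(cell: UnitCell, shape: tuple[int, int, int], d_min: float) -> None:
    spacing = cell.lengths / np.asarray(shape)
    if np.any(spacing > d_min / 3.0 + 1e-12):
        raise ValueError(
            f"grid {shape} too coarse for d_min={d_min:.3g}: "
            f"spacing must be <= d_min/3 on every axis"
        )


def _check_nyquist(hkl: np.ndarray, shape: tuple[int, int, int]) -> None:
    if np.any(2 * np.abs(hkl) >= np.asarray(shape)):
        raise ValueError("Miller index beyond the grid Nyquist limit")


def synthesize_map(
    hkl: np.ndarray,
    coeffs: np.ndarray,
    cell: UnitCell,
    shape: tuple[int, int, int],
    label: str = "combined",
) -> DensityMap:
    """Inverse Fourier synthesis of hemisphere coefficients onto a grid."""
    hkl = np.asarray(hkl, dtype=int)
    coeffs = np.asarray(coeffs, dtype=complex)
    d = UnitCell.d_spacing(cell, hkl)
    _check_grid(cell, shape, float(d.min()))
    _check_nyquist(hkl, shape)
    grid = np.zeros(shape, dtype=complex)
    idx = tuple((hkl % shape).T)
    idx_m = tuple(((-hkl) % shape).T)
    np.add.at(grid, idx, coeffs / 2.0)
    np.add.at(grid, idx_m, np.conj(coeffs) / 2.0)
    rho = np.fft.ifftn(grid).real * grid.size
    return DensityMap(values=rho, cell=cell, label=label)


def map_to_structure_factors(map_: DensityMap, hkl: np.ndarray) -> np.ndarray:
    """Forward Fourier analysis restricted to the requested Miller set."""
    hkl = np.asarray(hkl, dtype=int)
    if not np.isfinite(map_.values).all():
        raise ValueError("map contains non-finite values")
    _check_nyquist(hkl, map_.shape)
    f_full = np.fft.fftn(map_.values)
    idx = tuple((hkl % map_.shape).T)
    return 2.0 * f_full[idx] / map_.size


def map_correlation(a: DensityMap, b: DensityMap) -> float:
    """Pearson correlation of two maps over all grid points."""
    if a.shape != b.shape:
        raise ValueError(f"grid mismatch: {a.shape} vs {b.shape}")
    x = a.values.ravel()
    y = b.values.ravel()
    x = x - x.mean()
    y = y - y.mean()
    denom = np.sqrt((x @ x) * (y @ y))
    if denom == 0:
        raise ValueError("cannot correlate a constant map")
    return float(x @ y / denom)


def write_ccp4(map_: DensityMap, path) -> None:
    """Write a CCP4/MRC map (X fastest) for visual inspection."""
    import gemmi

    grid = gemmi.FloatGrid(np.ascontiguousarray(map_.values, dtype=np.float32))
    cell = map_.cell
    grid.unit_cell = gemmi.UnitCell(cell.a, cell.b, cell.c, 90, 90, 90)
    grid.spacegroup = gemmi.SpaceGroup("P1")
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = grid
    ccp4.update_ccp4_header()
    ccp4.write_ccp4_map(str(path))
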