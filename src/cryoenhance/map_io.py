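"""Reading, writing, resampling and normalizing cryo-EM density maps.

Maps live on orthogonal voxel grids.  After reading, a map is always in
canonical axis order: ``data[ix, iy, iz]`` with the physical position of a
voxel center given by ``origin + index * voxel_size`` (0-based indices).
MRC/CCP4 parsing and serialization are delegated to gemmi; this module owns
the canonicalization, resampling and normalization semantics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
from scipy.ndimage import map_coordinates

__all__ = [
    "DensityMap",
    "NormalizationRecord",
    "read_density_map",
    "write_density_map",
    "resample_to_grid",
    "normalize_percentile",
]

_ANGLE_TOL = 1e-3


@dataclass
class DensityMap:
    """A 3-D density grid with physical metadata.

    Attributes
    ----------
    data : ndarray, shape (nx, ny, nz)
        Density values; axis i of the array runs along crystallographic
        axis i (canonical order).
    voxel_size : tuple of float
        Edge length of a voxel along each axis, in Å.
    origin : tuple of float
        Physical position (Å) of the center of voxel (0, 0, 0).
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError("density data must be a non-empty 3-D array")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.voxel_size) != 3 or any(
            not np.isfinite(v) or v <= 0 for v in self.voxel_size
        ):
            raise ValueError("voxel_size components must be positive and finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def copy(self) -> "DensityMap":
        return DensityMap(self.data.copy(), self.voxel_size, self.origin)


@dataclass
class NormalizationRecord:
    """Provenance of a percentile normalization: value / scale, then clipping."""

    percentile: float
    scale: float
    clip_low: bool

    def __post_init__(self):
        if not 0 < self.percentile <= 100:
            raise ValueError("percentile must lie in (0, 100]")
        if not self.scale > 0:
            raise ValueError("normalization scale must be positive")

    def invert(self, values: np.ndarray) -> np.ndarray:
        """Undo the division for voxels that were not clipped."""
        return np.asarray(values) * self.scale


def _check_orthogonal(cell: gemmi.UnitCell, path) -> None:
    angles = (cell.alpha, cell.beta, cell.gamma)
    if any(abs(a - 90.0) > _ANGLE_TOL for a in angles):
        raise ValueError(
            f"non-orthogonal axes in {path}: cell angles {angles} (only "
            "orthogonal maps are supported)"
        )


def read_density_map(path) -> DensityMap:
    """Read an MRC/CCP4 map (optionally .gz) into canonical axis order.

    The voxel size is reconstructed from the header cell and sampling counts;
    the origin comes from the MRC2014 ORIGIN words when set, otherwise from
    the start indices (NXSTART...) times the voxel size.  Axis permutations
    declared via MAPC/MAPR/MAPS are undone so that array axis i always runs
    along crystallographic axis i.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        ccp4 = gemmi.read_ccp4_map(str(path))
    except Exception as exc:  # gemmi raises RuntimeError on malformed files
        raise ValueError(f"cannot parse {path} as an MRC/CCP4 map: {exc}") from exc
    _check_orthogonal(ccp4.grid.unit_cell, path)

    raw = np.array(ccp4.grid, copy=True)
    # axis_positions()[a] = array axis of crystallographic axis a
    pos = ccp4.axis_positions()
    data = np.transpose(raw, axes=pos)

    cell = ccp4.grid.unit_cell
    mx = ccp4.header_i32(8), ccp4.header_i32(9), ccp4.header_i32(10)
    if any(m <= 0 for m in mx):
        raise ValueError(f"{path}: non-positive sampling counts in header")
    voxel = (cell.a / mx[0], cell.b / mx[1], cell.c / mx[2])

    origin_words = tuple(ccp4.header_float(w) for w in (50, 51, 52))
    if any(abs(o) > 0 for o in origin_words):
        origin = origin_words
    else:
        # NXSTART/NYSTART/NZSTART are per file axis; map them to crystallographic axes
        nstart_file = [ccp4.header_i32(w) for w in (5, 6, 7)]
        nstart = tuple(nstart_file[pos[a]] for a in range(3))
        origin = tuple(nstart[a] * voxel[a] for a in range(3))
    return DensityMap(data, voxel, origin)


def write_density_map(dmap: DensityMap, path) -> None:
    """Write a canonical map as MRC2014 mode 2 (float32)."""
    nx, ny, nz = dmap.shape
    vx, vy, vz = dmap.voxel_size
    grid = gemmi.FloatGrid(nx, ny, nz)
    grid.set_unit_cell(gemmi.UnitCell(nx * vx, ny * vy, nz * vz, 90.0, 90.0, 90.0))
    np.asarray(grid)[...] = dmap.data.astype(np.float32)
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = grid
    ccp4.update_ccp4_header()
    for word, value in zip((50, 51, 52), dmap.origin):
        ccp4.set_header_float(word, float(value))
    ccp4.write_ccp4_map(str(path))


def resample_to_grid(dmap: DensityMap, target_voxel: float,
                     order: int = 1) -> DensityMap:
    """Resample onto an axis-aligned grid of uniform spacing `target_voxel`.

    The output covers the same physical extent (shape = ceil(extent/voxel)),
    keeps the input origin, interpolates trilinearly by default (``order=3``
    selects cubic), and fills points outside the source extent with zero.
    """
    if not target_voxel > 0:
        raise ValueError("target_voxel must be positive")
    if all(abs(v - target_voxel) < 1e-12 for v in dmap.voxel_size):
        return dmap.copy()
    extent = [n * v for n, v in zip(dmap.shape, dmap.voxel_size)]
    new_shape = tuple(int(np.ceil(e / target_voxel - 1e-9)) for e in extent)
    # fractional source indices of the new voxel centers
    idx = [
        np.arange(n) * target_voxel / dmap.voxel_size[a]
        for a, n in enumerate(new_shape)
    ]
    coords = np.meshgrid(*idx, indexing="ij")
    out = map_coordinates(
        dmap.data.astype(np.float64), np.stack(coords), order=order,
        mode="constant", cval=0.0,
    )
    return DensityMap(out.astype(dmap.data.dtype, copy=False),
                      (target_voxel,) * 3, dmap.origin)


def normalize_percentile(
    dmap: DensityMap, percentile: float = 99.999, clip_low: bool = True
) -> tuple[DensityMap, NormalizationRecord]:
    """Divide by the given percentile of the density and clip into [0, 1].

    The divisor is the linear-interpolation percentile of all voxel values.
    Values above 1 after division (the tail beyond the percentile) are always
    clipped to 1; negatives are clipped to 0 when `clip_low` is set.
    """
    if not 0 < percentile <= 100:
        raise ValueError("percentile must lie in (0, 100]")
    scale = float(np.percentile(dmap.data, percentile))
    if not scale > 0:
        raise ValueError(
            f"cannot normalize map: the {percentile} percentile density "
            f"({scale}) is not positive (degenerate all-zero/negative map)"
        )
    data = dmap.data / scale
    upper = np.minimum(data, 1.0)
    out = np.maximum(upper, 0.0) if clip_low else upper
    record = NormalizationRecord(percentile=percentile, scale=scale, clip_low=clip_low)
    return DensityMap(out, dmap.voxel_size, dmap.origin), record
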