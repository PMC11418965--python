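"""Clean target maps from atomic models via a per-atom Gaussian kernel.

Each atom contributes ``C * A * exp(-k * ||x_atom - y||^2)`` to the density
at grid point ``y``, where ``A`` is the atomic number, ``k = pi/(0.9*R0)^2``
for a nominal map resolution ``R0`` (Å) and ``C = (k/pi)^{3/2}`` so that one
unit of atomic number integrates to one unit of density.  These simulated
maps serve as training targets and as model-calculated maps for map-model
comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import gemmi
import numpy as np

from .map_io import DensityMap

__all__ = [
    "AtomicStructure",
    "GaussianKernelSpec",
    "GridSpec",
    "read_structure",
    "gaussian_constants",
    "simulate_map",
    "auto_grid_for_structure",
]


@dataclass
class AtomicStructure:
    """A flat list of atoms: element symbols, atomic numbers, positions, occupancies."""

    elements: list[str]
    atomic_numbers: np.ndarray  # (n,) int
    positions: np.ndarray  # (n, 3) float, Å
    occupancies: np.ndarray  # (n,) float in (0, 1]
    id: str = ""

    def __post_init__(self):
        self.atomic_numbers = np.asarray(self.atomic_numbers, dtype=int)
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        self.occupancies = np.asarray(self.occupancies, dtype=float)
        n = len(self.atomic_numbers)
        if n < 1:
            raise ValueError("a structure needs at least one atom")
        if len(self.positions) != n or len(self.occupancies) != n or len(self.elements) != n:
            raise ValueError("inconsistent atom array lengths")
        if (self.atomic_numbers < 1).any():
            raise ValueError("atomic numbers must be >= 1")
        if not np.isfinite(self.positions).all():
            raise ValueError("atom coordinates must be finite")

    def __len__(self) -> int:
        return len(self.atomic_numbers)

    def without_hydrogens(self) -> "AtomicStructure":
        keep = self.atomic_numbers > 1
        if not keep.any():
            raise ValueError("structure contains only hydrogens")
        return AtomicStructure(
            [e for e, k in zip(self.elements, keep) if k],
            self.atomic_numbers[keep], self.positions[keep],
            self.occupancies[keep], self.id,
        )


@dataclass
class GaussianKernelSpec:
    """Kernel constants for one resolution: density = C * A * exp(-k d^2)."""

    R0: float
    k: float
    C: float
    cutoff_radius: float

    def __post_init__(self):
        if not self.k > 0:
            raise ValueError("k must be positive")
        if not np.isclose(self.C, (self.k / np.pi) ** 1.5, rtol=1e-12):
            raise ValueError("C must equal (k/pi)^{3/2}")


@dataclass
class GridSpec:
    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float]
    origin: tuple[float, float, float]


def gaussian_constants(R0: float, k_convention: str = "pi-over-square") -> GaussianKernelSpec:
    """Kernel constants for a nominal resolution R0 (Å).

    ``k_convention`` selects the parenthesization of the width formula:
    "pi-over-square" (default) gives k = pi/(0.9*R0)^2; "squared-ratio"
    gives k = (pi/(0.9*R0))^2.  The cutoff radius is where the kernel falls
    to 1e-6 of its peak, so even summed tails from many atoms stay well
    below 1e-4 of the map peak.
    """
    if not R0 > 0:
        raise ValueError("R0 must be positive")
    if k_convention == "pi-over-square":
        k = np.pi / (0.9 * R0) ** 2
    elif k_convention == "squared-ratio":
        k = (np.pi / (0.9 * R0)) ** 2
    else:
        raise ValueError(f"unknown k_convention {k_convention!r}")
    C = (k / np.pi) ** 1.5
    cutoff = float(np.sqrt(np.log(1e6) / k))
    return GaussianKernelSpec(R0=float(R0), k=float(k), C=float(C), cutoff_radius=cutoff)


_ELEMENT_FALLBACK = {"D": 1}


def read_structure(path, include_hydrogens: bool = True,
                   include_hetero: bool = True) -> AtomicStructure:
    """Read atoms from a PDB or mmCIF file.

    Altloc conformers are resolved to the highest-occupancy one (ties go to
    the first in file order).  Waters are excluded when ``include_hetero``
    is false, as are all other non-polymer heteroatoms.  Hydrogen inclusion
    is always explicit via ``include_hydrogens``.
    """
    path = Path(path)
    try:
        structure = gemmi.read_structure(str(path))
    except Exception as exc:
        raise ValueError(f"cannot parse structure file {path}: {exc}") from exc
    structure.setup_entities()
    elements: list[str] = []
    numbers: list[int] = []
    positions: list[tuple[float, float, float]] = []
    occupancies: list[float] = []
    if len(structure) == 0:
        raise ValueError(f"{path}: no models in structure")
    model = structure[0]
    for chain in model:
        for residue in chain:
            if residue.is_water():
                continue
            if not include_hetero and residue.het_flag == "H" and not residue.is_amino_acid():
                continue
            best: dict[str, gemmi.Atom] = {}
            for atom in residue:
                key = atom.name
                prev = best.get(key)
                if prev is None or atom.occ > prev.occ:
                    best[key] = atom
            for atom in best.values():
                el = atom.element
                z = el.atomic_number
                if z == 0:
                    z = _ELEMENT_FALLBACK.get(atom.name.strip(), 0)
                if z == 0:
                    raise ValueError(
                        f"{path}: atom {chain.name}/{residue.name}/{atom.name} "
                        "has an unresolvable element symbol"
                    )
                if z == 1 and not include_hydrogens:
                    continue
                elements.append(el.name)
                numbers.append(z)
                positions.append((atom.pos.x, atom.pos.y, atom.pos.z))
                occupancies.append(atom.occ if atom.occ > 0 else 1.0)
    if not numbers:
        raise ValueError(f"{path}: no atoms selected")
    return AtomicStructure(elements, np.array(numbers), np.array(positions),
                           np.array(occupancies), id=path.stem)


def auto_grid_for_structure(structure: AtomicStructure, voxel_size: float = 1.0,
                            padding: float = 5.0) -> GridSpec:
    """Smallest grid at the given spacing containing all atoms plus padding."""
    if padding < 0:
        raise ValueError("padding must be nonnegative")
    lo = structure.positions.min(axis=0) - padding
    hi = structure.positions.max(axis=0) + padding
    shape = tuple(int(np.floor((h - l) / voxel_size + 1e-9)) + 1 for l, h in zip(lo, hi))
    return GridSpec(shape=shape, voxel_size=(voxel_size,) * 3, origin=tuple(lo))


def simulate_map(structure: AtomicStructure, kernel: GaussianKernelSpec,
                 grid: GridSpec, occupancy_weighted: bool = True) -> DensityMap:
    """Sum the per-atom Gaussians onto a voxel grid.

    Each atom touches only the voxels within ``kernel.cutoff_radius`` of its
    center (set ``cutoff_radius=inf`` or 0-disabled via a large value for the
    exact sum); voxels with no atom in range are exactly zero.
    """
    shape = tuple(grid.shape)
    voxel = np.asarray(grid.voxel_size, dtype=float)
    origin = np.asarray(grid.origin, dtype=float)
    data = np.zeros(shape, dtype=np.float64)
    cutoff = kernel.cutoff_radius if kernel.cutoff_radius > 0 else np.inf

    any_inside = False
    axes_cache = [np.arange(n) * voxel[a] + origin[a] for a, n in enumerate(shape)]
    for z, pos, occ in zip(structure.atomic_numbers, structure.positions,
                           structure.occupancies):
        weight = kernel.C * z * (occ if occupancy_weighted else 1.0)
        if np.isinf(cutoff):
            lo_idx = [0, 0, 0]
            hi_idx = list(shape)
        else:
            lo_idx = [max(0, int(np.ceil((pos[a] - cutoff - origin[a]) / voxel[a])))
                      for a in range(3)]
            hi_idx = [min(shape[a],
                          int(np.floor((pos[a] + cutoff - origin[a]) / voxel[a])) + 1)
                      for a in range(3)]
        if any(lo >= hi for lo, hi in zip(lo_idx, hi_idx)):
            continue
        any_inside = True
        dx = [axes_cache[a][lo_idx[a]:hi_idx[a]] - pos[a] for a in range(3)]
        d2 = (dx[0][:, None, None] ** 2 + dx[1][None, :, None] ** 2
              + dx[2][None, None, :] ** 2)
        contrib = weight * np.exp(-kernel.k * d2)
        if not np.isinf(cutoff):
            contrib[d2 > cutoff**2] = 0.0
        data[lo_idx[0]:hi_idx[0], lo_idx[1]:hi_idx[1], lo_idx[2]:hi_idx[2]] += contrib
    if not any_inside:
        import warnings

        warnings.warn("structure lies entirely outside the grid extent; "
                      "returning an all-zero map", stacklevel=2)
    return DensityMap(data, tuple(voxel), tuple(origin))
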