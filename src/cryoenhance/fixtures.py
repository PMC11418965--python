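"""Synthetic structure/map triples for desk-scale testing and demos.

Generates poly-alanine-like backbones (helix, strand or coil), simulates
their clean Gaussian target maps, and degrades the clean maps with a
low-pass blur, a background offset and additive white noise to stand in for
deposited experimental maps.  The degradation is an explicit stand-in for
the contrast loss and noise of real reconstructions, not an image-formation
model; its job is to give the network a learnable inverse at toy scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .map_io import DensityMap, write_density_map
from .simulate import (
    AtomicStructure,
    auto_grid_for_structure,
    gaussian_constants,
    simulate_map,
)

__all__ = ["DegradationSpec", "make_toy_structure", "degrade_map",
           "write_structure_pdb", "make_dataset"]


@dataclass
class DegradationSpec:
    """How a clean map is corrupted: blur (Å), noise and offset as peak fractions."""

    blur_sigma: float = 1.5
    noise_sigma: float = 0.15
    background_offset: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if min(self.blur_sigma, self.noise_sigma, self.background_offset) < 0:
            raise ValueError("degradation parameters must be nonnegative")


_BACKBONE = (("N", 7, 1.46), ("CA", 6, 0.0), ("C", 6, 1.52), ("O", 8, 2.4))


def _ca_trace(n_residues: int, motif: str, rng: np.random.Generator) -> np.ndarray:
    if motif == "helix":
        # ideal alpha-like helix: rise 1.5 Å and 100 degrees per residue;
        # radius chosen so consecutive CA-CA distance is 3.8 Å
        rise, twist = 1.5, np.deg2rad(100.0)
        radius = np.sqrt(3.8**2 - rise**2) / (2 * np.sin(twist / 2))
        t = np.arange(n_residues)
        return np.stack([radius * np.cos(twist * t),
                         radius * np.sin(twist * t),
                         rise * t], axis=1)
    if motif == "strand":
        rise = 3.3
        zig = np.sqrt(3.8**2 - rise**2) / 2
        t = np.arange(n_residues)
        return np.stack([rise * t, zig * (-1.0) ** t, np.zeros(n_residues)], axis=1)
    if motif == "coil":
        # correlated random walk with fixed 3.8 Å steps
        steps = rng.standard_normal((n_residues - 1, 3)) if n_residues > 1 else \
            np.zeros((0, 3))
        direction = np.array([1.0, 0.0, 0.0])
        pts = [np.zeros(3)]
        for s in steps:
            direction = direction + 0.7 * s
            direction /= np.linalg.norm(direction)
            pts.append(pts[-1] + 3.8 * direction)
        return np.asarray(pts)
    raise ValueError(f"unknown motif {motif!r} (expected helix/strand/coil)")


def make_toy_structure(n_residues: int, motif: str = "helix",
                       rng: np.random.Generator | None = None) -> AtomicStructure:
    """A poly-alanine-like backbone (N, CA, C, O per residue) along a motif."""
    if n_residues < 1:
        raise ValueError("n_residues must be >= 1")
    rng = rng or np.random.default_rng(0)
    ca = _ca_trace(n_residues, motif, rng)
    elements, numbers, positions = [], [], []
    for i in range(n_residues):
        # local frame along the chain for plausible substituent directions
        nxt = ca[min(i + 1, n_residues - 1)] - ca[i]
        prv = ca[i] - ca[max(i - 1, 0)]
        fwd = nxt if np.linalg.norm(nxt) > 0 else prv
        if np.linalg.norm(fwd) == 0:
            fwd = np.array([1.0, 0.0, 0.0])
        fwd = fwd / np.linalg.norm(fwd)
        ortho = np.cross(fwd, [0.0, 0.0, 1.0])
        if np.linalg.norm(ortho) < 1e-6:
            ortho = np.cross(fwd, [0.0, 1.0, 0.0])
        ortho /= np.linalg.norm(ortho)
        offsets = {
            "N": -1.46 * fwd + 0.3 * ortho,
            "CA": np.zeros(3),
            "C": 1.52 * fwd + 0.3 * ortho,
            "O": 1.52 * fwd + 1.53 * ortho,
        }
        for name, z, _ in _BACKBONE:
            elements.append("N" if z == 7 else ("O" if z == 8 else "C"))
            numbers.append(z)
            positions.append(ca[i] + offsets[name])
    return AtomicStructure(elements, np.array(numbers), np.array(positions),
                           np.ones(len(numbers)), id=f"{motif}{n_residues}")


def write_structure_pdb(structure: AtomicStructure, path) -> None:
    """Write a toy backbone as a poly-ALA PDB file."""
    st = gemmi.Structure()
    st.name = structure.id or "toy"
    model = gemmi.Model("1")
    chain = gemmi.Chain("A")
    names = ["N", "CA", "C", "O"]
    for i in range(0, len(structure), 4):
        res = gemmi.Residue()
        res.name = "ALA"
        res.seqid = gemmi.SeqId(i // 4 + 1, " ")
        for j, name in enumerate(names):
            atom = gemmi.Atom()
            atom.name = name
            atom.element = gemmi.Element(structure.elements[i + j])
            atom.occ = float(structure.occupancies[i + j])
            atom.pos = gemmi.Position(*structure.positions[i + j])
            res.add_atom(atom)
        chain.add_residue(res)
    model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


def degrade_map(clean: DensityMap, spec: DegradationSpec) -> DensityMap:
    """Blur + background offset + white noise, deterministic under spec.seed."""
    peak = float(clean.data.max())
    if spec.blur_sigma > 0:
        sigma_vox = [spec.blur_sigma / v for v in clean.voxel_size]
        data = gaussian_filter(clean.data.astype(np.float64), sigma_vox,
                               mode="constant", truncate=4.0)
    else:
        data = clean.data.astype(np.float64).copy()
    data += spec.background_offset * peak
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        data += rng.normal(0.0, spec.noise_sigma * peak, size=clean.shape)
    return DensityMap(data, clean.voxel_size, clean.origin)


def make_dataset(out_dir, n_structures: int = 20,
                 residues_range: tuple[int, int] = (8, 24),
                 R0_range: tuple[float, float] = (3.0, 6.0),
                 blur_range: tuple[float, float] = (1.0, 2.0),
                 noise_range: tuple[float, float] = (0.10, 0.20),
                 offset_range: tuple[float, float] = (0.0, 0.03),
                 voxel: float = 1.0, padding: float = 6.0,
                 seed: int = 0) -> pd.DataFrame:
    """Write (structure.pdb, clean.mrc, degraded.mrc) triples plus a manifest.

    Everything is reproducible from `seed`; the manifest records the sampled
    resolution and degradation parameters per entry.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    motifs = ("helix", "strand", "coil")
    rows = []
    for idx in range(n_structures):
        motif = motifs[int(rng.integers(0, len(motifs)))]
        n_res = int(rng.integers(residues_range[0], residues_range[1] + 1))
        structure = make_toy_structure(n_res, motif, rng)
        r0 = float(rng.uniform(*R0_range))
        spec = DegradationSpec(
            blur_sigma=float(rng.uniform(*blur_range)),
            noise_sigma=float(rng.uniform(*noise_range)),
            background_offset=float(rng.uniform(*offset_range)),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        grid = auto_grid_for_structure(structure, voxel_size=voxel, padding=padding)
        clean = simulate_map(structure, gaussian_constants(r0), grid)
        degraded = degrade_map(clean, spec)
        name = f"entry{idx:03d}"
        paths = {
            "structure": out_dir / f"{name}.pdb",
            "clean_map": out_dir / f"{name}_clean.mrc",
            "degraded_map": out_dir / f"{name}_degraded.mrc",
        }
        write_structure_pdb(structure, paths["structure"])
        write_density_map(clean, paths["clean_map"])
        write_density_map(degraded, paths["degraded_map"])
        rows.append({
            "id": name, "motif": motif, "n_residues": n_res, "R0": r0,
            "blur_sigma": spec.blur_sigma, "noise_sigma": spec.noise_sigma,
            "background_offset": spec.background_offset, "noise_seed": spec.seed,
            **{k: str(v) for k, v in paths.items()},
        })
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
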