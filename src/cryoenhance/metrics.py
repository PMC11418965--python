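"""Map-model validation: Fourier shell correlation and box correlation.

These are textbook, self-contained implementations — unmasked FSC over
shells of one reciprocal-voxel width, threshold-crossing resolution by
linear interpolation, and whole-box Pearson correlation.  They are *not*
drop-in equivalents of phenix.mtriage / phenix.map_model_cc, which apply
their own masking and map-calculation conventions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .map_io import DensityMap
from .simulate import AtomicStructure, GridSpec, gaussian_constants, simulate_map

__all__ = ["FSCCurve", "fsc_curve", "fsc_resolution", "map_model_fsc", "cc_box"]


@dataclass
class FSCCurve:
    """Per-shell Fourier correlations at ascending shell-center frequencies (1/Å)."""

    shell_frequencies: np.ndarray
    correlations: np.ndarray
    shell_width: float

    def __post_init__(self):
        self.shell_frequencies = np.asarray(self.shell_frequencies, dtype=float)
        self.correlations = np.asarray(self.correlations, dtype=float)
        if self.shell_frequencies.shape != self.correlations.shape:
            raise ValueError("frequencies and correlations must align")
        if np.any(np.diff(self.shell_frequencies) <= 0):
            raise ValueError("shell frequencies must be strictly ascending")


def _as_map(m) -> DensityMap:
    return m if isinstance(m, DensityMap) else DensityMap(np.asarray(m))


def fsc_curve(map_a: DensityMap, map_b: DensityMap) -> FSCCurve:
    """Unmasked FSC between two maps on identical grids.

    Shells are one reciprocal voxel wide (1 / (N_max * voxel)); the shell of
    a Fourier coefficient is the nearest-integer radius of its frequency
    magnitude in those units.  Shells beyond Nyquist are discarded.
    """
    map_a, map_b = _as_map(map_a), _as_map(map_b)
    if map_a.shape != map_b.shape:
        raise ValueError("maps must share a shape")
    if not np.allclose(map_a.voxel_size, map_b.voxel_size):
        raise ValueError("maps must share a voxel size")
    voxel = float(map_a.voxel_size[0])
    fa = np.fft.fftn(map_a.data)
    fb = np.fft.fftn(map_b.data)
    freqs = np.meshgrid(
        *[np.fft.fftfreq(n, d=v) for n, v in zip(map_a.shape, map_a.voxel_size)],
        indexing="ij",
    )
    fmag = np.sqrt(sum(f**2 for f in freqs))
    shell_width = 1.0 / (max(map_a.shape) * voxel)
    shell_idx = np.rint(fmag / shell_width).astype(int)
    nyquist = 1.0 / (2.0 * voxel)
    n_shells = int(np.floor(nyquist / shell_width + 1e-9)) + 1

    idx = shell_idx.ravel()
    cross = (fa * np.conj(fb)).real.ravel()
    pa = (np.abs(fa) ** 2).ravel()
    pb = (np.abs(fb) ** 2).ravel()
    valid = idx < n_shells
    num = np.bincount(idx[valid], weights=cross[valid], minlength=n_shells)
    da = np.bincount(idx[valid], weights=pa[valid], minlength=n_shells)
    db = np.bincount(idx[valid], weights=pb[valid], minlength=n_shells)
    populated = (da > 0) & (db > 0)
    # skip the DC shell: it is a single coefficient, not a correlation shell
    populated[0] = False
    shells = np.arange(n_shells)[populated]
    corr = num[populated] / np.sqrt(da[populated] * db[populated])
    return FSCCurve(shells * shell_width, np.clip(corr, -1.0, 1.0), shell_width)


def fsc_resolution(curve: FSCCurve, threshold: float) -> tuple[float, str]:
    """Resolution (Å) where the curve first falls below `threshold`.

    Interpolates the crossing frequency linearly between the bracketing
    shells and returns its reciprocal.  The second element flags the
    degenerate cases: "crossed" for a genuine crossing, "nyquist" when the
    curve never falls below the threshold, "below-at-start" when it starts
    under it.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    f = curve.shell_frequencies
    c = curve.correlations
    if len(f) == 0:
        raise ValueError("empty FSC curve")
    if c[0] < threshold:
        return float(1.0 / f[0]), "below-at-start"
    below = np.nonzero(c < threshold)[0]
    if len(below) == 0:
        return float(1.0 / f[-1]), "nyquist"
    j = int(below[0])
    f_star = f[j - 1] + (f[j] - f[j - 1]) * (c[j - 1] - threshold) / (c[j - 1] - c[j])
    return float(1.0 / f_star), "crossed"


def map_model_fsc(dmap: DensityMap, structure: AtomicStructure, R0: float,
                  threshold: float = 0.5,
                  k_convention: str = "pi-over-square") -> tuple[float, str]:
    """Map-model FSC resolution against a Gaussian model-calculated map.

    The model map is simulated on the experimental grid with the kernel for
    resolution R0, then compared by unmasked FSC.  This is a simplified,
    self-contained analogue of a phenix map-model FSC, not its equivalent.
    """
    grid = GridSpec(shape=dmap.shape, voxel_size=dmap.voxel_size, origin=dmap.origin)
    model_map = simulate_map(structure, gaussian_constants(R0, k_convention), grid)
    return fsc_resolution(fsc_curve(dmap, model_map), threshold)


def cc_box(map_a: DensityMap | np.ndarray, map_b: DensityMap | np.ndarray) -> float:
    """Pearson correlation between two maps over every voxel of the box."""
    a = (map_a.data if isinstance(map_a, DensityMap) else np.asarray(map_a)).ravel()
    b = (map_b.data if isinstance(map_b, DensityMap) else np.asarray(map_b)).ravel()
    if a.shape != b.shape:
        raise ValueError("maps must share a shape")
    da = a - a.mean()
    db = b - b.mean()
    na = np.sqrt((da**2).sum())
    nb = np.sqrt((db**2).sum())
    if na == 0 or nb == 0:
        raise ValueError("cc_box undefined for a zero-variance map")
    return float(np.clip((da * db).sum() / (na * nb), -1.0, 1.0))
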