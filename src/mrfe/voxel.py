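"""Signed five-channel voxelization of protein–ligand complexes.

Each atom paints a density onto the grid through a piecewise profile:
1 inside its ionic radius, a Gaussian fall-off between the ionic and
van-der-Waals radii, and 0 beyond the van-der-Waals radius.  Densities of
atoms sharing a channel are summed (ligand −, receptor +) and the sum is
clamped to [−1, 1] per voxel at the end.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from .structures import MolecularComplex, assign_channel

__all__ = [
    "GridSpec",
    "VoxelMap",
    "atomic_density",
    "voxelize",
    "voxel_similarity",
    "default_grid",
    "save_voxelmap",
    "load_voxelmap",
]

N_CHANNELS = 5
CHANNEL_NAMES = ("polar_hydrogen", "hydrophobic", "nitrogen", "oxygen_fluorine", "d_elements")


@dataclass(frozen=True)
class GridSpec:
    """Axis-aligned voxel grid: ``origin`` is the corner of voxel (0,0,0);
    the centre of voxel (i,j,k) sits at origin + (i+½, j+½, k+½)·spacing."""

    origin: tuple[float, float, float]
    spacing: float
    shape: tuple[int, int, int]

    def __post_init__(self):
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if any(int(s) < 1 for s in self.shape):
            raise ValueError("shape components must be >= 1")
        object.__setattr__(self, "origin", tuple(float(x) for x in self.origin))
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))

    def axis_centers(self, axis: int) -> np.ndarray:
        return self.origin[axis] + (np.arange(self.shape[axis]) + 0.5) * self.spacing

    def translated(self, shift) -> "GridSpec":
        o = np.asarray(self.origin) + np.asarray(shift, dtype=float)
        return GridSpec(tuple(o), self.spacing, self.shape)


@dataclass
class VoxelMap:
    """5 × D × H × W signed density grid; every value lies in [−1, 1]."""

    grid: GridSpec
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        expected = (N_CHANNELS,) + self.grid.shape
        if self.values.shape != expected:
            raise ValueError(f"values shape {self.values.shape} != {expected}")
        if np.abs(self.values).max(initial=0.0) > 1.0 + 1e-12:
            raise ValueError("voxel values must lie in [-1, 1]")


def atomic_density(r, r_ion: float, r_vdw: float):
    """Density of one atom at distance ``r`` (Å) from its centre.

    Piecewise: 1 for r < r_ion; exp(−2·((r−r_ion)/(r_vdw−r_ion))²) for
    r_ion ≤ r ≤ r_vdw; 0 for r > r_vdw.  The profile is deliberately
    discontinuous at r_vdw (left limit exp(−2), then 0); r = r_vdw takes
    the exponential branch's boundary value.  Accepts scalars or arrays.
    """
    if r_vdw <= r_ion:
        raise ValueError("require r_vdw > r_ion")
    r = np.asarray(r, dtype=float)
    if (r < 0).any():
        raise ValueError("distances must be non-negative")
    x = (r - r_ion) / (r_vdw - r_ion)
    mid = np.exp(-2.0 * x**2)
    out = np.where(r < r_ion, 1.0, np.where(r <= r_vdw, mid, 0.0))
    return float(out) if out.ndim == 0 else out


def default_grid(
    complex_: MolecularComplex,
    shape: int | tuple[int, int, int] = 24,
    spacing: float = 1.0,
) -> GridSpec:
    """Cubic grid (default 24³ at 1 Å) centred on the ligand centroid."""
    if isinstance(shape, int):
        shape = (shape, shape, shape)
    center = complex_.ligand_centroid()
    origin = tuple(center[i] - shape[i] * spacing / 2.0 for i in range(3))
    return GridSpec(origin, spacing, shape)


def voxelize(complex_: MolecularComplex, grid: GridSpec) -> VoxelMap:
    """Paint a complex onto ``grid``.

    Signed densities accumulate per channel; the accumulated sum is clamped
    once at the end so |value| ≤ 1 (mixed ligand/receptor contributions in
    one channel may cancel before clamping).  Atoms outside the grid, or
    with no channel assignment, contribute nothing.
    """
    if len(complex_.atoms) == 0:
        raise ValueError("empty complex")
    acc = np.zeros((N_CHANNELS,) + grid.shape, dtype=float)
    axes = [grid.axis_centers(i) for i in range(3)]
    for atom in complex_.atoms:
        if not np.isfinite(atom.coords).all():
            raise ValueError("non-finite atom coordinate")
        ca = assign_channel(atom)
        if ca is None:
            continue
        # Bounding box of voxels within r_vdw of the atom centre.
        lo, hi = [], []
        skip = False
        for ax in range(3):
            centers = axes[ax]
            i0 = int(np.searchsorted(centers, atom.coords[ax] - atom.r_vdw))
            i1 = int(np.searchsorted(centers, atom.coords[ax] + atom.r_vdw, side="right"))
            if i0 >= len(centers) or i1 <= 0:
                skip = True
                break
            lo.append(max(i0 - 1, 0))
            hi.append(min(i1 + 1, len(centers)))
        if skip:
            continue
        dx = axes[0][lo[0]:hi[0]] - atom.coords[0]
        dy = axes[1][lo[1]:hi[1]] - atom.coords[1]
        dz = axes[2][lo[2]:hi[2]] - atom.coords[2]
        r = np.sqrt(dx[:, None, None] ** 2 + dy[None, :, None] ** 2 + dz[None, None, :] ** 2)
        acc[ca.channel, lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] += ca.sign * atomic_density(
            r, atom.r_ion, atom.r_vdw
        )
    np.clip(acc, -1.0, 1.0, out=acc)
    return VoxelMap(grid, acc)


def voxel_similarity(a: VoxelMap, b: VoxelMap, metric: str = "cosine") -> float:
    """Geometric similarity of two maps on the same grid (higher = closer).

    ``cosine``: cosine of the flattened 5-channel arrays, in [−1, 1]
    (defined as 0 if either map is identically zero).
    ``negative-rms``: −RMS difference, in (−∞, 0].
    """
    if a.grid != b.grid or a.values.shape != b.values.shape:
        raise ValueError("voxel maps live on different grids")
    va, vb = a.values.ravel(), b.values.ravel()
    if metric == "cosine":
        na, nb = np.linalg.norm(va), np.linalg.norm(vb)
        if na == 0.0 or nb == 0.0:
            return 0.0
        return float(np.dot(va, vb) / (na * nb))
    if metric == "negative-rms":
        return float(-np.sqrt(np.mean((va - vb) ** 2)))
    raise ValueError(f"unknown metric {metric!r}")


def save_voxelmap(vmap: VoxelMap, path: str | Path) -> None:
    """Write a map as flat binary (.npy) plus a JSON sidecar with the grid."""
    path = Path(path)
    np.save(path.with_suffix(".npy"), vmap.values)
    sidecar = {
        "origin": list(vmap.grid.origin),
        "spacing": vmap.grid.spacing,
        "shape": list(vmap.grid.shape),
        "channels": list(CHANNEL_NAMES),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_voxelmap(path: str | Path) -> VoxelMap:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    grid = GridSpec(tuple(meta["origin"]), meta["spacing"], tuple(meta["shape"]))
    return VoxelMap(grid, np.load(path.with_suffix(".npy")))
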