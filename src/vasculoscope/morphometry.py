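"""Voxel-grid morphometry of vascular networks.

Three maps summarize vascular morphology on regular grids:

* **D_v** — Euclidean distance (µm) from each voxel to the nearest vessel
  voxel, on a fine grid (default 8 µm isotropic);
* **L_v** — vascular length density (mm/mm³): per-voxel centerline length
  shares box-averaged over a kernel window (default 20³ voxels of 8 µm,
  i.e. a 160 µm³ window);
* **S_v** — vascular surface area density (mm²/mm³): the same for lateral
  cylinder area πD·L shares.

Each segment's arc length is attributed to the voxels its centerline
traverses by supersampling the centerline at spacing/4, so total assigned
length (and surface) is conserved for networks inside the grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .network import VascularNetwork

__all__ = [
    "VoxelGrid",
    "MorphometryMaps",
    "rasterize_network",
    "distance_map",
    "density_maps",
    "morphology_summary",
]


@dataclass
class VoxelGrid:
    """A scalar field on a regular axis-aligned grid.

    ``origin`` is the world coordinate (µm) of the *center* of voxel
    (0, 0, 0); axis order of ``values`` is (x, y, z).
    """

    origin: np.ndarray  # (3,) µm
    spacing: np.ndarray  # (3,) µm
    values: np.ndarray  # (nx, ny, nz)

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        if np.any(self.spacing <= 0):
            raise ValueError("spacing must be > 0")
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError("values must be a 3D array")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def voxel_centers_axis(self, axis: int) -> np.ndarray:
        return self.origin[axis] + self.spacing[axis] * np.arange(self.shape[axis])

    def world_to_voxel(self, points: np.ndarray) -> np.ndarray:
        """Nearest-voxel indices for world points (no bounds check)."""
        return np.rint((np.asarray(points, float) - self.origin) / self.spacing).astype(int)

    def save_nifti(self, path) -> None:
        import nibabel as nib

        affine = np.diag([*self.spacing, 1.0])
        affine[:3, 3] = self.origin
        nib.save(nib.Nifti1Image(np.asarray(self.values, dtype=np.float32), affine), str(path))

    def save_tiff(self, path) -> None:
        import tifffile

        # multipage TIFF with z as page axis
        tifffile.imwrite(str(path), np.moveaxis(self.values, 2, 0).astype(np.float32))


@dataclass
class MorphometryMaps:
    """The D_v / L_v / S_v map bundle plus the scalar volume density."""

    dv: VoxelGrid  # µm, fine grid
    lv: VoxelGrid  # mm/mm³, coarse window average on the fine grid
    sv: VoxelGrid  # mm²/mm³
    volume_density: float | None = None  # vascular volume / tumor volume


def _grid_for(net: VascularNetwork, spacing: float, pad: float = 0.0) -> tuple[np.ndarray, tuple]:
    lo = net.positions.min(axis=0) - pad
    hi = net.positions.max(axis=0) + pad
    shape = tuple(np.maximum(np.ceil((hi - lo) / spacing).astype(int) + 1, 1))
    return lo, shape


def rasterize_network(net: VascularNetwork, spacing: float = 8.0, pad: float | None = None) -> VoxelGrid:
    """Binary vessel mask: a voxel is set iff its center lies within D/2 of
    a segment centerline (segments as straight chords between endpoints).
    """
    if spacing <= 0:
        raise ValueError("spacing must be > 0")
    if net.n_segments == 0:
        warnings.warn("network has no segments; returning empty grid", stacklevel=2)
        origin, shape = _grid_for(net, spacing)
        return VoxelGrid(origin, np.full(3, spacing), np.zeros(shape, dtype=bool))
    if pad is None:
        pad = float(np.max(net.diameters)) / 2.0
    origin, shape = _grid_for(net, spacing, pad)
    mask = np.zeros(shape, dtype=bool)
    sp3 = np.full(3, float(spacing))
    e = net.endpoint_indices
    for s in range(net.n_segments):
        a = net.positions[e[s, 0]]
        b = net.positions[e[s, 1]]
        r = net.diameters[s] / 2.0
        lo_v = np.maximum(np.floor((np.minimum(a, b) - r - origin) / sp3).astype(int), 0)
        hi_v = np.minimum(np.ceil((np.maximum(a, b) + r - origin) / sp3).astype(int) + 1, shape)
        if np.any(lo_v >= hi_v):
            continue
        xs = [origin[k] + sp3[k] * np.arange(lo_v[k], hi_v[k]) for k in range(3)]
        gx, gy, gz = np.meshgrid(*xs, indexing="ij")
        pts = np.stack([gx, gy, gz], axis=-1)
        ab = b - a
        denom = float(ab @ ab)
        if denom == 0:
            d2 = np.sum((pts - a) ** 2, axis=-1)
        else:
            t = np.clip(((pts - a) @ ab) / denom, 0.0, 1.0)
            proj = a + t[..., None] * ab
            d2 = np.sum((pts - proj) ** 2, axis=-1)
        sub = d2 <= r * r
        mask[lo_v[0]:hi_v[0], lo_v[1]:hi_v[1], lo_v[2]:hi_v[2]] |= sub
    return VoxelGrid(origin, sp3, mask)


def distance_map(vessel_mask: VoxelGrid) -> VoxelGrid:
    """Euclidean distance (µm) from every voxel center to the nearest
    vessel voxel center; exactly zero on vessel voxels.
    """
    mask = np.asarray(vessel_mask.values, dtype=bool)
    if not mask.any():
        raise ValueError("distance map needs at least one vessel voxel")
    dist = ndimage.distance_transform_edt(~mask, sampling=vessel_mask.spacing)
    return VoxelGrid(vessel_mask.origin.copy(), vessel_mask.spacing.copy(), dist)


def centerline_shares(net: VascularNetwork, grid: VoxelGrid, supersample: int = 4):
    """Accumulate per-voxel centerline length and lateral-surface shares.

    Each segment is sampled at ``supersample`` points per voxel spacing
    along its chord; every sample carries an equal share of the segment's
    *recorded* arc length (curved centerlines keep their full length) and
    of its lateral surface πD·L.
    """
    length_vox = np.zeros(grid.shape)
    surf_vox = np.zeros(grid.shape)
    e = net.endpoint_indices
    h = float(np.min(grid.spacing)) / supersample
    for s in range(net.n_segments):
        a = net.positions[e[s, 0]]
        b = net.positions[e[s, 1]]
        chord = float(np.linalg.norm(b - a))
        n_samp = max(int(np.ceil(chord / h)), 1)
        t = (np.arange(n_samp) + 0.5) / n_samp
        pts = a + t[:, None] * (b - a)
        idx = grid.world_to_voxel(pts)
        ok = np.all((idx >= 0) & (idx < np.array(grid.shape)), axis=1)
        idx = idx[ok]
        if len(idx) == 0:
            continue
        l_share = net.lengths[s] / len(idx)
        s_share = np.pi * net.diameters[s] * net.lengths[s] / len(idx)
        np.add.at(length_vox, (idx[:, 0], idx[:, 1], idx[:, 2]), l_share)
        np.add.at(surf_vox, (idx[:, 0], idx[:, 1], idx[:, 2]), s_share)
    return length_vox, surf_vox


def density_maps(
    net: VascularNetwork,
    spacing: float = 8.0,
    kernel: int = 20,
    grid: VoxelGrid | None = None,
) -> tuple[VoxelGrid, VoxelGrid]:
    """Vascular length density L_v (mm/mm³) and surface density S_v
    (mm²/mm³), box-averaged over ``kernel``³ voxels (default 20³ × 8 µm =
    a 160 µm window).  Border windows are normalized by their in-bounds
    volume.
    """
    if grid is None:
        if net.n_segments == 0:
            warnings.warn("network has no segments; empty density maps", stacklevel=2)
            origin, shape = _grid_for(net, spacing)
            z = np.zeros(shape)
            g = VoxelGrid(origin, np.full(3, spacing), z)
            return g, VoxelGrid(origin, np.full(3, spacing), z.copy())
        origin, shape = _grid_for(net, spacing, pad=0.0)
        grid = VoxelGrid(origin, np.full(3, spacing), np.zeros(shape))
    length_vox, surf_vox = centerline_shares(net, grid)
    size = (kernel, kernel, kernel)
    sum_l = ndimage.uniform_filter(length_vox, size=size, mode="constant") * kernel**3
    sum_s = ndimage.uniform_filter(surf_vox, size=size, mode="constant") * kernel**3
    ones = np.ones(grid.shape)
    n_in = ndimage.uniform_filter(ones, size=size, mode="constant") * kernel**3
    voxel_vol = float(np.prod(grid.spacing))  # µm³
    window_vol = n_in * voxel_vol
    # µm/µm³ → mm/mm³ is ×1e6 ; µm²/µm³ → mm²/mm³ is ×1e3
    lv = VoxelGrid(grid.origin.copy(), grid.spacing.copy(), sum_l / window_vol * 1e6)
    sv = VoxelGrid(grid.origin.copy(), grid.spacing.copy(), sum_s / window_vol * 1e3)
    return lv, sv


def morphology_summary(net: VascularNetwork, maps: MorphometryMaps | None = None) -> pd.DataFrame:
    """Scalar morphology table: medians/means of D, L and, when maps are
    given, of D_v, L_v, S_v, plus volume density Σ(πD²/4·L)/Vol.
    """
    rows = {}

    def stats(name, values):
        v = np.asarray(values, dtype=float).ravel()
        rows[name] = {
            "median": float(np.median(v)),
            "mean": float(np.mean(v)),
            "std": float(np.std(v, ddof=1)) if v.size > 1 else 0.0,
            "n": int(v.size),
        }

    stats("diameter_um", net.diameters)
    stats("length_um", net.lengths)
    if maps is not None:
        stats("dv_um", maps.dv.values)
        stats("lv_mm_mm3", maps.lv.values)
        stats("sv_mm2_mm3", maps.sv.values)
    vascular_volume_um3 = float(np.sum(np.pi * net.diameters**2 / 4.0 * net.lengths))
    if net.tumor_volume_mm3 is not None:
        rows["volume_density"] = {
            "median": vascular_volume_um3 / (net.tumor_volume_mm3 * 1e9),
            "mean": vascular_volume_um3 / (net.tumor_volume_mm3 * 1e9),
            "std": 0.0,
            "n": 1,
        }
    else:
        warnings.warn("tumor volume unknown; volume density omitted", stacklevel=2)
    return pd.DataFrame(rows).T


def compute_morphometry(
    net: VascularNetwork, spacing: float = 8.0, kernel: int = 20
) -> MorphometryMaps:
    """Convenience bundle: rasterize, distance map, density maps, volume density."""
    mask = rasterize_network(net, spacing)
    dv = distance_map(mask)
    lv, sv = density_maps(net, spacing, kernel)
    vol_density = None
    if net.tumor_volume_mm3 is not None:
        vasc_vol = float(np.sum(np.pi * net.diameters**2 / 4.0 * net.lengths))  # µm³
        vol_density = vasc_vol / (net.tumor_volume_mm3 * 1e9)
    return MorphometryMaps(dv=dv, lv=lv, sv=sv, volume_density=vol_density)
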