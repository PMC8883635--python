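"""Voxel-phantom cavity volumetry with fiducial capping.

The orbital cavity is an open space: before its volume can be measured by
voxel counting, the anterior aperture must be sealed with a virtual surface
triangulated from rim fiducial points, and the posterior opening clipped at
a plane.  This module reproduces that measurement chain on synthetic
phantoms with known analytic volume:

- :func:`generate_phantom` voxelizes an ellipsoid (or an open
  half-ellipsoid) cavity with a one-voxel bone shell and rim fiducials
  along the open aperture;
- :func:`cap_aperture` triangulates the fiducial cloud (Delaunay-based
  convex surface, thickened one-sidedly outward by ~2 voxels) and relabels
  voxels inside it as barrier, closing the cavity;
- :func:`crop_posterior` zeroes everything beyond a clipping plane
  (half-open rule: a voxel is kept iff its center lies strictly before the
  plane);
- :func:`measure_volume` counts labeled voxels times the voxel volume.

Grids use isotropic spacing; world coordinates place voxel centers at
half-integer multiples of the spacing so no center falls exactly on the
default aperture plane.  Labels: 0 background/air, 1 bone/barrier,
2 cavity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import Delaunay, QhullError

__all__ = [
    "AIR",
    "BONE",
    "CAVITY",
    "VoxelGrid",
    "FiducialSet",
    "PhantomSpec",
    "generate_phantom",
    "cap_aperture",
    "crop_posterior",
    "measure_volume",
    "is_closed",
    "save_grid",
    "load_grid",
    "write_fiducials_csv",
    "read_fiducials_csv",
]

AIR, BONE, CAVITY = 0, 1, 2


@dataclass
class VoxelGrid:
    """Labeled 3-D grid with isotropic spacing.

    ``origin`` is the world coordinate (mm) of the center of voxel
    (0, 0, 0); the center of voxel ``(i, j, k)`` is
    ``origin + spacing * (i, j, k)``.
    """

    labels: np.ndarray
    spacing: float
    origin: Tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3-D array")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        bad = set(np.unique(self.labels)) - {AIR, BONE, CAVITY}
        if bad:
            raise ValueError(f"undeclared label values: {sorted(bad)}")

    def axis_coords(self, axis: int) -> np.ndarray:
        """World coordinates of voxel centers along one axis."""
        return self.origin[axis] + self.spacing * np.arange(self.labels.shape[axis])

    def copy(self) -> "VoxelGrid":
        return VoxelGrid(self.labels.copy(), self.spacing, tuple(self.origin))


@dataclass
class FiducialSet:
    """Ordered rim landmark points in world coordinates (mm)."""

    points: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must be an (n, 3) array")
        if self.points.shape[0] < 4:
            raise ValueError("need >= 4 fiducial points for a 3-D cap")


@dataclass
class PhantomSpec:
    """Analytic phantom: a (half-)ellipsoid cavity of known volume.

    ``shape="ellipsoid"`` is closed; ``shape="half_ellipsoid"`` keeps the
    half with third-axis coordinate <= 0 and leaves the equatorial face at
    z = 0 open (the aperture), to be sealed by :func:`cap_aperture`.
    """

    shape: str = "half_ellipsoid"
    semi_axes: Tuple[float, float, float] = (20.0, 17.5, 22.5)
    n_rim_fiducials: int = 24

    def __post_init__(self) -> None:
        if self.shape not in ("ellipsoid", "half_ellipsoid"):
            raise ValueError("shape must be 'ellipsoid' or 'half_ellipsoid'")
        if any(s <= 0 for s in self.semi_axes):
            raise ValueError("semi-axes must be positive")
        if self.n_rim_fiducials < 4:
            raise ValueError("need >= 4 rim fiducials")

    @property
    def analytic_volume(self) -> float:
        a, b, c = self.semi_axes
        v = 4.0 / 3.0 * math.pi * a * b * c
        return v if self.shape == "ellipsoid" else v / 2.0


def generate_phantom(
    spec: PhantomSpec,
    spacing: float = 0.3,
    seed: Optional[int] = None,
    margin_voxels: int = 3,
) -> Tuple[VoxelGrid, FiducialSet]:
    """Voxelize the phantom cavity with a one-voxel bone shell and rim
    fiducials.

    A voxel is cavity iff its *center* lies inside the analytic shape; the
    shell is the one-voxel dilation of the cavity, opened across the
    aperture face for the half-ellipsoid.  Fiducials sit on the bone crest
    of the aperture rim (one voxel outside the cavity rim ellipse), evenly
    spaced in angle with a small seeded angular jitter emulating manual
    placement; ``seed=None`` places them exactly evenly.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    a, b, c = spec.semi_axes
    half_extent = np.array([a, b, c]) + (margin_voxels + 1) * spacing
    n = 2 * np.ceil(half_extent / spacing).astype(int)  # even counts
    origin = tuple(-(n - 1) / 2.0 * spacing)
    xs = origin[0] + spacing * np.arange(n[0])
    ys = origin[1] + spacing * np.arange(n[1])
    zs = origin[2] + spacing * np.arange(n[2])
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    inside = (X / a) ** 2 + (Y / b) ** 2 + (Z / c) ** 2 <= 1.0
    if spec.shape == "half_ellipsoid":
        inside &= Z <= 0.0
    if not inside.any():
        raise ValueError("shape contains no voxel centers at this spacing")
    shell = ndimage.binary_dilation(inside) & ~inside
    if spec.shape == "half_ellipsoid":
        # open the aperture: remove shell voxels sitting above the equator
        # strictly inside the rim ellipse (the crest ring itself survives)
        above = Z > 0.0
        inside_rim = (X / a) ** 2 + (Y / b) ** 2 < 1.0
        shell &= ~(above & inside_rim)
    labels = np.zeros(tuple(n), dtype=np.uint8)
    labels[shell] = BONE
    labels[inside] = CAVITY
    grid = VoxelGrid(labels, spacing, origin)

    theta = np.linspace(0.0, 2.0 * math.pi, spec.n_rim_fiducials, endpoint=False)
    if seed is not None:
        rng = np.random.default_rng(seed)
        step = 2.0 * math.pi / spec.n_rim_fiducials
        theta = theta + rng.uniform(-0.1 * step, 0.1 * step, size=theta.size)
    # crest radius: one voxel outside the cavity rim ellipse
    rim = np.column_stack(
        [(a + spacing) * np.cos(theta), (b + spacing) * np.sin(theta),
         np.zeros_like(theta)]
    )
    return grid, FiducialSet(rim)


def _aperture_normal(points: np.ndarray) -> np.ndarray:
    """Unit normal of the best-fit rim plane (smallest principal axis)."""
    centered = points - points.mean(axis=0)
    _, svals, vt = np.linalg.svd(centered, full_matrices=False)
    if svals[1] < 1e-9 * max(svals[0], 1e-30):
        raise ValueError("rim fiducials are collinear; cap is degenerate")
    return vt[-1]


def cap_aperture(
    grid: VoxelGrid, rim: FiducialSet, thickness_voxels: float = 2.0
) -> VoxelGrid:
    """Seal the aperture with a triangulated cap built from rim fiducials.

    The rim cloud is thickened into a slab by duplicating the points
    ``thickness_voxels * spacing`` along the outward rim-plane normal
    (outward = away from the cavity centroid), and the convex triangulated
    surface of the combined cloud is voxelized: every voxel whose center
    lies inside or on it becomes barrier.  One-sided outward thickening
    leaves cavity voxel centers untouched, so the measured volume changes
    only where the cap itself overlaps cavity voxels.

    Returns a new grid; raises for fewer than 4 usable points or a
    degenerate (collinear) rim.
    """
    points = rim.points
    normal = _aperture_normal(points)
    out = grid.copy()
    # orient the normal away from the cavity centroid
    cav_idx = np.argwhere(grid.labels == CAVITY)
    if cav_idx.size:
        centroid = np.asarray(grid.origin) + grid.spacing * cav_idx.mean(axis=0)
        if np.dot(normal, points.mean(axis=0) - centroid) < 0:
            normal = -normal
    slab = np.vstack([points, points + normal * thickness_voxels * grid.spacing])
    try:
        hull = Delaunay(slab, qhull_options="QJ")
    except QhullError as exc:  # pragma: no cover - degenerate rims raise above
        raise ValueError(f"degenerate rim configuration: {exc}") from exc

    lo = slab.min(axis=0) - grid.spacing
    hi = slab.max(axis=0) + grid.spacing
    idx_lo = np.maximum(
        np.floor((lo - np.asarray(grid.origin)) / grid.spacing).astype(int), 0
    )
    idx_hi = np.minimum(
        np.ceil((hi - np.asarray(grid.origin)) / grid.spacing).astype(int) + 1,
        np.asarray(grid.labels.shape),
    )
    slices = tuple(slice(l, h) for l, h in zip(idx_lo, idx_hi))
    coords = np.meshgrid(
        *[grid.axis_coords(ax)[slices[ax]] for ax in range(3)], indexing="ij"
    )
    pts = np.column_stack([c.ravel() for c in coords])
    inside = hull.find_simplex(pts) >= 0
    sub = out.labels[slices]
    sub_flat = sub.reshape(-1)
    sub_flat[inside] = BONE
    out.labels[slices] = sub_flat.reshape(sub.shape)
    return out


def crop_posterior(grid: VoxelGrid, plane_coord: float, axis: int = 2) -> VoxelGrid:
    """Zero all voxels at or beyond a clipping plane along one axis.

    Half-open rule: a voxel is retained iff its center coordinate is
    strictly less than ``plane_coord``.  The plane must lie within the
    grid's world extent.
    """
    coords = grid.axis_coords(axis)
    lo = coords[0] - grid.spacing / 2.0
    hi = coords[-1] + grid.spacing / 2.0
    if not lo <= plane_coord <= hi:
        raise ValueError(
            f"plane {plane_coord} outside grid extent [{lo}, {hi}] on axis {axis}"
        )
    out = grid.copy()
    mask = coords >= plane_coord
    sl = [slice(None)] * 3
    sl[axis] = mask
    out.labels[tuple(sl)] = AIR
    return out


def measure_volume(grid: VoxelGrid, label: int = CAVITY) -> float:
    """Volume (mm^3) of one label: voxel count times spacing cubed."""
    return float(np.count_nonzero(grid.labels == label)) * grid.spacing**3


def is_closed(grid: VoxelGrid) -> bool:
    """True iff no outside-connected flood fill can reach a cavity voxel.

    The fill starts from every non-barrier voxel on the grid boundary and
    propagates through 6-connected non-barrier voxels; the cavity is closed
    iff the fill never touches a cavity-labeled voxel.
    """
    passable = grid.labels != BONE
    structure = ndimage.generate_binary_structure(3, 1)
    comp, _ = ndimage.label(passable, structure=structure)
    border_labels = set()
    for ax in range(3):
        sl = [slice(None)] * 3
        for end in (0, -1):
            sl[ax] = end
            border_labels |= set(np.unique(comp[tuple(sl)]))
    border_labels.discard(0)
    if not border_labels:
        return True
    outside = np.isin(comp, sorted(border_labels))
    return not bool(np.any(outside & (grid.labels == CAVITY)))


# ---------------------------------------------------------------------------
# I/O: NIfTI grids (spacing kept bit-exactly in the affine), CSV fiducials


def save_grid(grid: VoxelGrid, path) -> None:
    import nibabel as nib

    affine = np.diag([grid.spacing] * 3 + [1.0])
    affine[:3, 3] = grid.origin
    # NIfTI-2 stores the affine in float64, so spacing survives bit-exactly
    nib.save(nib.Nifti2Image(grid.labels.astype(np.uint8), affine), str(path))


def load_grid(path) -> VoxelGrid:
    import nibabel as nib

    img = nib.load(str(path))
    affine = img.affine
    diag = np.diag(affine)[:3]
    if not np.allclose(diag, diag[0]) or np.any(
        affine[:3, :3] != np.diag(diag)
    ):
        raise ValueError("grid must have an axis-aligned isotropic affine")
    return VoxelGrid(
        np.asarray(img.dataobj).astype(np.uint8),
        float(diag[0]),
        tuple(float(v) for v in affine[:3, 3]),
    )


def write_fiducials_csv(fiducials: FiducialSet, path) -> None:
    pd.DataFrame(fiducials.points, columns=["x_mm", "y_mm", "z_mm"]).to_csv(
        path, index=False
    )


def read_fiducials_csv(path) -> FiducialSet:
    frame = pd.read_csv(path)
    missing = {"x_mm", "y_mm", "z_mm"} - set(frame.columns)
    if missing:
        raise ValueError(f"fiducial table missing columns: {sorted(missing)}")
    return FiducialSet(frame[["x_mm", "y_mm", "z_mm"]].to_numpy())
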