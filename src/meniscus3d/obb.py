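"""Root-aligned oriented-bounding-box morphometry.

Meniscal width, length, and height are read off a rectangular box whose
z-axis is the canonical superior direction, whose x-axis is the
projection of the anterior-to-posterior root line onto the x-y plane,
and whose extents are tightened to the min/max vertex projections, so
the box just encloses the whole meniscus body. Width is the y-extent,
length the x-extent, height the z-extent.

The covariance-based seeding of the box that an interactive tool would
start from is omitted: once the z-axis is fixed and the x-axis is pinned
to the root line, the tightened box is fully determined, so the seed has
no effect on the result.
"""
from __future__ import annotations

import dataclasses

import numpy as np

from .mesh_model import MeniscusMesh, MeshError

__all__ = [
    "MeniscusDimensions",
    "OrientedBox",
    "RootAlignmentError",
    "compute_obb",
    "measure_dimensions",
    "measure_dimensions_2d",
]

#: roots closer than this (mm) cannot define the length axis
MIN_ROOT_DISTANCE_MM = 1.0


class RootAlignmentError(MeshError):
    """Root landmarks too close together to orient the box."""


@dataclasses.dataclass(frozen=True)
class MeniscusDimensions:
    """Width/length/height in mm; height is None for 2D measurements."""

    width: float
    length: float
    height: float | None = None

    def __post_init__(self):
        for name in ("width", "length", "height"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise ValueError(f"{name} must be positive, got {v}")


@dataclasses.dataclass(frozen=True)
class OrientedBox:
    """Box center, orthonormal axes (rows: x, y, z roles), extents (mm)."""

    center: np.ndarray
    axes: np.ndarray  # (3, 3), rows x/y/z
    extents: np.ndarray  # (3,) mm, same order


def _root_axes(mesh: MeniscusMesh) -> np.ndarray:
    root_vec = mesh.root_posterior - mesh.root_anterior
    if np.linalg.norm(root_vec) < MIN_ROOT_DISTANCE_MM:
        raise RootAlignmentError(
            f"root landmarks {np.linalg.norm(root_vec):.3f} mm apart "
            f"(need >= {MIN_ROOT_DISTANCE_MM} mm)"
        )
    xy = np.array([root_vec[0], root_vec[1], 0.0])
    if np.linalg.norm(xy) < 1e-9:
        raise RootAlignmentError("root line is vertical; cannot rotate about z")
    x = xy / np.linalg.norm(xy)
    z = np.array([0.0, 0.0, 1.0])
    y = np.cross(z, x)
    return np.vstack([x, y, z])


def compute_obb(mesh: MeniscusMesh) -> OrientedBox:
    """Root-aligned oriented bounding box of the mesh.

    z is the canonical superior axis (taken from the frame, not
    estimated); the box is rotated about z so its x-axis is parallel to
    the x-y projection of the anterior-to-posterior root line; extents
    are the min/max vertex projections on the three axes.
    """
    axes = _root_axes(mesh)
    proj = mesh.vertices @ axes.T  # (n, 3) coordinates in box frame
    lo = proj.min(axis=0)
    hi = proj.max(axis=0)
    center = axes.T @ ((lo + hi) / 2.0)
    return OrientedBox(center=center, axes=axes, extents=hi - lo)


def measure_dimensions(mesh: MeniscusMesh) -> MeniscusDimensions:
    """Width (y-extent), length (x-extent), height (z-extent) in mm."""
    box = compute_obb(mesh)
    return MeniscusDimensions(
        width=float(box.extents[1]),
        length=float(box.extents[0]),
        height=float(box.extents[2]),
    )


def measure_dimensions_2d(
    mesh: MeniscusMesh,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> MeniscusDimensions:
    """Width/length of the axial footprint (the in-silico 2D-MRI box).

    The mesh is projected onto the x-y plane and boxed with the same
    root-aligned axes; optional Gaussian noise of ``noise_sd`` mm
    emulates manual 2D reading error (off by default; deterministic when
    noise_sd = 0).
    """
    axes = _root_axes(mesh)
    proj = mesh.vertices @ axes[:2].T  # footprint coordinates
    extents = proj.max(axis=0) - proj.min(axis=0)
    length, width = float(extents[0]), float(extents[1])
    if noise_sd > 0:
        rng = np.random.default_rng(mesh.seed(0x2D) if seed is None else seed)
        width += float(rng.normal(0.0, noise_sd))
        length += float(rng.normal(0.0, noise_sd))
        width = max(width, 1e-6)
        length = max(length, 1e-6)
    return MeniscusDimensions(width=width, length=length, height=None)
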