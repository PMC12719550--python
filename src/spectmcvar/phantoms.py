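"""Synthetic digital phantoms: a hot-sphere water cylinder and a NEMA-IQ-like
body, with attenuation maps, ROI masks and ground-truth activity tables.

Phantom bodies use voxel-center inclusion (conserves totals on any grid);
ROI masks for the cylinder experiment use the stricter rule that a voxel
belongs to a sphere ROI only if all eight of its corners lie inside the
sphere. This module is fully deterministic: no randomness anywhere.
"""
from __future__ import annotations

import numpy as np

from .grids import ActivityImage, Grid3D, MuMap, ROISet
from .physics import MU_WATER_208

MU_AIR = 0.0


def make_interior_mask(center, diameter, grid: Grid3D) -> np.ndarray:
    """Voxels contained entirely within a sphere (all 8 corners inside).

    An empty mask is a valid result when the sphere is small relative to
    the voxel diagonal.
    """
    if diameter <= 0:
        raise ValueError("diameter must be positive")
    r2 = (diameter / 2.0) ** 2
    cx, cy, cz = center
    x, y, z = grid.center_mesh()
    dx, dy, dz = grid.spacing
    mask = np.ones(grid.shape, dtype=bool)
    for sx in (-0.5, 0.5):
        for sy in (-0.5, 0.5):
            for sz in (-0.5, 0.5):
                d2 = ((x + sx * dx - cx) ** 2 + (y + sy * dy - cy) ** 2
                      + (z + sz * dz - cz) ** 2)
                mask &= d2 < r2
    return mask


def make_center_mask(center, diameter, grid: Grid3D) -> np.ndarray:
    """Voxels whose center lies inside a sphere (drawn-ROI convention)."""
    if diameter <= 0:
        raise ValueError("diameter must be positive")
    cx, cy, cz = center
    x, y, z = grid.center_mesh()
    return (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2 < (diameter / 2.0) ** 2


def _check_sphere_layout(centers, diameters, container_radius, container_name):
    for i, (c, d) in enumerate(zip(centers, diameters)):
        if np.hypot(c[0], c[1]) + d / 2.0 > container_radius:
            raise ValueError(
                f"sphere {i} (d={d} mm at {c}) crosses the {container_name} wall")
        for j in range(i):
            dist = float(np.linalg.norm(np.subtract(c, centers[j])))
            if dist < d / 2.0 + diameters[j] / 2.0:
                raise ValueError(
                    f"spheres {i} and {j} overlap (centers {dist:.1f} mm apart)")


# Sphere placements for the cylinder phantom (mm). The source description
# fixes diameters and contrast but not positions; this layout keeps every
# sphere clear of the wall and of its neighbors and is recorded in output
# metadata of the experiment drivers.
CYLINDER_SPHERE_CENTERS = ((-50.0, 0.0, 0.0), (45.0, 35.0, 0.0), (30.0, -50.0, 0.0))


def build_cylinder_sphere_phantom(
    grid: Grid3D,
    cylinder_diameter: float = 200.0,
    sphere_diameters=(72.0, 40.0, 20.0),
    contrast: float = 10.0,
    cylinder_height: float = 160.0,
    sphere_centers=CYLINDER_SPHERE_CENTERS,
    background_margin: float = 25.0,
    sphere_guard: float = 15.0,
):
    """Water cylinder with hot spheres at ``contrast``:1 over the background.

    Returns (ActivityImage, MuMap, ROISet). The ROI set holds one strict
    interior mask per sphere plus a warm-background ROI. The background
    guard band along the wall defaults to ~2 PSF FWHM (25 mm): the
    calibration-factor method assumes the background ROI is free of
    resolution effects, and edge ringing from the cylinder wall extends
    roughly two FWHM inward.
    """
    if contrast <= 0:
        raise ValueError("contrast must be positive")
    _check_sphere_layout(sphere_centers, sphere_diameters,
                         cylinder_diameter / 2.0, "cylinder")
    x, y, z = grid.center_mesh()
    r_cyl = cylinder_diameter / 2.0
    in_cyl = (x ** 2 + y ** 2 < r_cyl ** 2) & (np.abs(z) < cylinder_height / 2.0)

    act = np.where(in_cyl, 1.0, 0.0)
    for c, d in zip(sphere_centers, sphere_diameters):
        sph = make_center_mask(c, d, grid)
        act[sph & in_cyl] = contrast
    mu = np.where(in_cyl, MU_WATER_208, MU_AIR)
    labels = in_cyl.astype(np.uint8)

    rois = ROISet(grid)
    vv = grid.voxel_volume
    for c, d in zip(sphere_centers, sphere_diameters):
        m = make_interior_mask(c, d, grid)
        rois.add(f"sphere_{int(round(d))}mm", m, "sphere",
                 float(contrast * m.sum() * vv))

    bkg = in_cyl & (x ** 2 + y ** 2 < (r_cyl - background_margin) ** 2) \
        & (np.abs(z) < cylinder_height / 2.0 - background_margin)
    for c, d in zip(sphere_centers, sphere_diameters):
        bkg &= ~make_center_mask(c, d + 2 * sphere_guard, grid)
    rois.add("background", bkg, "background", float(bkg.sum() * vv))

    return (ActivityImage(grid, act), MuMap(grid, mu, labels), rois)


def build_nema_like_phantom(
    grid: Grid3D,
    sphere_diameters=(37.0, 28.0, 22.0, 17.0, 13.0, 10.0),
    contrast: float = 9.0,
    body_semi_axes=(130.0, 95.0),
    body_height: float = 180.0,
    ring_radius: float = 57.2,
    cold_cylinder_diameter: float = 50.0,
    background_sphere_diameter: float = 50.0,
    background_centers=((-55.0, 0.0, -60.0), (55.0, 0.0, -60.0)),
):
    """NEMA-IQ-like phantom: six hot spheres on a ring around a central cold
    cylinder, inside a warm elliptical-cylinder body.

    Eight ROIs: the six spheres (drawn, voxel-center masks), a warm
    background made of two 50 mm spheres, and the cold cylinder. The exact
    sphere placement (ring radius, z-plane, cold insert size) follows a
    standard IEC-body-like layout; it is a geometric fixture, not a claim.
    """
    if contrast <= 0:
        raise ValueError("contrast must be positive")
    ax, ay = body_semi_axes
    centers = []
    for i, d in enumerate(sphere_diameters):
        ang = np.deg2rad(90.0 + 60.0 * i)
        centers.append((ring_radius * np.cos(ang), ring_radius * np.sin(ang), 0.0))
        if ring_radius - d / 2.0 < cold_cylinder_diameter / 2.0:
            raise ValueError(f"sphere d={d} overlaps the cold cylinder")
    _check_sphere_layout(centers, sphere_diameters, min(ax, ay), "body")

    x, y, z = grid.center_mesh()
    in_body = ((x / ax) ** 2 + (y / ay) ** 2 < 1.0) & (np.abs(z) < body_height / 2.0)
    cold = (x ** 2 + y ** 2 < (cold_cylinder_diameter / 2.0) ** 2) \
        & (np.abs(z) < body_height / 2.0)

    act = np.where(in_body, 1.0, 0.0)
    for c, d in zip(centers, sphere_diameters):
        act[make_center_mask(c, d, grid) & in_body] = contrast
    act[cold] = 0.0
    mu = np.where(in_body, MU_WATER_208, MU_AIR)

    rois = ROISet(grid)
    vv = grid.voxel_volume
    for c, d in zip(centers, sphere_diameters):
        m = make_center_mask(c, d, grid)
        rois.add(f"sphere_{int(round(d))}mm", m, "sphere",
                 float(contrast * m.sum() * vv))
    bkg = np.zeros(grid.shape, dtype=bool)
    for c in background_centers:
        bkg |= make_center_mask(c, background_sphere_diameter, grid)
    bkg &= in_body & ~cold
    for c, d in zip(centers, sphere_diameters):
        bkg &= ~make_center_mask(c, d + 10.0, grid)
    rois.add("background", bkg, "background", float(bkg.sum() * vv))
    rois.add("cold_cylinder", cold & in_body, "cold", 0.0)

    return (ActivityImage(grid, act), MuMap(grid, mu, in_body.astype(np.uint8)), rois)


def default_grid(desk_scale: bool = True) -> Grid3D:
    """Desk-scale 64x64x48 grid at 4.8 mm; full scale doubles the matrix."""
    if desk_scale:
        return Grid3D((64, 64, 48), (4.8, 4.8, 4.8))
    return Grid3D((128, 128, 96), (4.8, 4.8, 4.8))
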