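"""Digital 3-D phantoms of a gravid uterus with dark intraplacental bands.

A phantom is a voxel label grid containing a placenta (an ellipsoid attached
to the top of an ellipsoidal uterine cavity), ellipsoidal low-signal lesions
(DIB) inside the placenta, and a myometrial shell whose minimum thickness is
controlled analytically.  Every downstream measurement (slice-summation
volumetry, thinnest-site grading) can therefore be checked against exact
ground truth.

Conventions
-----------
* Axis order is (x, y, z) with x the sagittal normal, y the coronal normal
  and z the axial normal; right-handed, 0-based voxel indices.
* A voxel belongs to a structure iff its **center** lies inside the analytic
  shape; the center of voxel ``i`` along an axis with spacing ``s`` is at
  physical coordinate ``(i + 0.5) * s``, so the grid starts at coordinate 0.
* Slice stacks are anchored at physical coordinate 0 of the grid, with no
  half-slice offset.
* Masks only: no MR signal, noise or bias fields are simulated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import nibabel as nib
import numpy as np
import yaml
from scipy import ndimage

from .volumetry import SliceStack

# voxel labels
BACKGROUND, PLACENTA, DIB, MYOMETRIUM = 0, 1, 2, 3

#: axis index normal to each imaging plane
PLANE_AXIS = {"sagittal": 0, "coronal": 1, "axial": 2}

#: grid step (mm) of the fine-grid reference used for overlapping lesions
FINE_ORACLE_SPACING = 0.25


@dataclass(frozen=True)
class AcquisitionGeometry:
    """Slice geometry of one acquired plane.

    Only geometry is modelled (thickness, gap, pixel size); pulse-sequence
    contrast is out of scope.
    """

    plane: str
    slice_thickness: float
    slice_gap: float
    in_plane_spacing: tuple

    def __post_init__(self):
        if self.plane not in PLANE_AXIS:
            raise ValueError(f"unknown plane {self.plane!r}")
        if self.slice_thickness <= 0:
            raise ValueError("slice thickness must be > 0")
        if self.slice_gap < 0:
            raise ValueError("slice gap must be >= 0")
        if len(self.in_plane_spacing) != 2 or any(s <= 0 for s in self.in_plane_spacing):
            raise ValueError("in-plane spacings must be two positive lengths")
        object.__setattr__(self, "in_plane_spacing", tuple(float(s) for s in self.in_plane_spacing))

    @property
    def voxel_edges(self) -> tuple:
        """All three voxel edge lengths (two in-plane, one through-plane)."""
        return (*self.in_plane_spacing, float(self.slice_thickness))


@dataclass
class Ellipsoid:
    """Axis-aligned ellipsoid, physical coordinates in mm."""

    center: tuple
    semiaxes: tuple

    def __post_init__(self):
        self.center = tuple(float(c) for c in self.center)
        self.semiaxes = tuple(float(a) for a in self.semiaxes)
        if len(self.center) != 3 or len(self.semiaxes) != 3:
            raise ValueError("center and semiaxes must be 3-vectors")
        if any(a <= 0 for a in self.semiaxes):
            raise ValueError("all semi-axes must be > 0")

    @property
    def volume(self) -> float:
        a, b, c = self.semiaxes
        return 4.0 / 3.0 * np.pi * a * b * c

    def contains(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(pts)
        q = ((pts - np.asarray(self.center)) / np.asarray(self.semiaxes)) ** 2
        return q.sum(axis=1) <= 1.0


@dataclass
class PhantomConfig:
    """Parameters of the digital phantom.

    The default grid is a 96 mm cube at 1 mm isotropic spacing holding a
    scaled-down uterus: ellipsoidal cavity, myometrial shell of base
    thickness ``myometrium_thickness`` thinning to ``min_myometrial_thickness``
    at the placental bed (top pole), and a placenta tangent to the cavity
    wall there.  Lesions are axis-aligned ellipsoids placed inside the
    placenta, either explicitly (``dib_ellipsoids``) or at random
    (``n_dib`` with semi-axes drawn from ``dib_semiaxis_range``).
    """

    shape: tuple = (96, 96, 96)
    spacing: tuple = (1.0, 1.0, 1.0)
    cavity_semiaxes: tuple = (40.0, 36.0, 34.0)
    cavity_center: Optional[tuple] = None        # defaults to grid center
    myometrium_thickness: float = 6.0
    min_myometrial_thickness: float = 3.0
    interrupted: bool = False
    hole_radius: float = 8.0
    placenta_semiaxes: tuple = (30.0, 26.0, 20.0)
    n_dib: int = 3
    dib_semiaxis_range: tuple = (4.0, 9.0)
    dib_ellipsoids: Optional[Sequence[Ellipsoid]] = None

    def __post_init__(self):
        if any(n < 4 for n in self.shape):
            raise ValueError("grid too small")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        if not (0 < self.min_myometrial_thickness <= self.myometrium_thickness):
            raise ValueError("0 < min thickness <= base thickness required")
        if self.n_dib < 0:
            raise ValueError("n_dib must be >= 0")


@dataclass
class Phantom3D:
    """Voxel phantom with ground truth for volumetry and grading."""

    voxel_grid: np.ndarray          # uint8 labels
    spacing: tuple                  # mm per axis
    dib_params: list                # list[Ellipsoid]
    true_dib_volume: float          # mm^3, analytic union volume
    true_min_thickness: float       # mm, myometrial shell minimum
    interrupted: bool
    config: Optional[PhantomConfig] = None

    @property
    def extent(self) -> tuple:
        """Physical grid extent per axis, mm."""
        return tuple(n * s for n, s in zip(self.voxel_grid.shape, self.spacing))

    def voxel_volume_of(self, label: int) -> float:
        """Voxel-count volume of one label, mm^3."""
        return float(np.count_nonzero(self.voxel_grid == label) * np.prod(self.spacing))


# ---------------------------------------------------------------------------
# construction helpers


def _voxel_centers(shape, spacing):
    return [(np.arange(n) + 0.5) * s for n, s in zip(shape, spacing)]


def _ellipsoid_mask(shape, spacing, ell: Ellipsoid) -> np.ndarray:
    cx, cy, cz = ell.center
    ax, ay, az = ell.semiaxes
    gx, gy, gz = _voxel_centers(shape, spacing)
    qx = ((gx - cx) / ax) ** 2
    qy = ((gy - cy) / ay) ** 2
    qz = ((gz - cz) / az) ** 2
    return qx[:, None, None] + qy[None, :, None] + qz[None, None, :] <= 1.0


def _fibonacci_directions(n: int = 256) -> np.ndarray:
    """Deterministic quasi-uniform unit vectors for surface containment checks."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5 ** 0.5) * i
    return np.column_stack([np.sin(phi) * np.cos(theta),
                            np.sin(phi) * np.sin(theta),
                            np.cos(phi)])

_DIRECTIONS = _fibonacci_directions()


def _inside(inner: Ellipsoid, outer: Ellipsoid) -> bool:
    """Surface-sampled check that ``inner`` lies within ``outer``."""
    pts = np.asarray(inner.center) + _DIRECTIONS * np.asarray(inner.semiaxes)
    return bool(np.all(outer.contains(pts)))


def _surely_disjoint(e1: Ellipsoid, e2: Ellipsoid) -> bool:
    d = np.linalg.norm(np.asarray(e1.center) - np.asarray(e2.center))
    return d > max(e1.semiaxes) + max(e2.semiaxes)


def union_volume(ellipsoids: Sequence[Ellipsoid],
                 fine_spacing: float = FINE_ORACLE_SPACING) -> float:
    """Volume of a union of ellipsoids, mm^3.

    Pairwise-separated lesions sum analytically (4/3 pi abc each).  When any
    pair may overlap the union is evaluated on a fine reference grid
    (voxel-center rule at ``fine_spacing``) restricted to the union bounding
    box; overlapping lesions are merged, as a reader outlines visible
    regions, not constituent shapes.
    """
    ells = list(ellipsoids)
    if not ells:
        return 0.0
    if all(_surely_disjoint(a, b) for i, a in enumerate(ells) for b in ells[i + 1:]):
        return float(sum(e.volume for e in ells))
    lo = np.min([np.asarray(e.center) - np.asarray(e.semiaxes) for e in ells], axis=0)
    hi = np.max([np.asarray(e.center) + np.asarray(e.semiaxes) for e in ells], axis=0)
    lo -= fine_spacing
    hi += fine_spacing
    axes = [np.arange(l + fine_spacing / 2, h, fine_spacing) for l, h in zip(lo, hi)]
    inside = None
    for e in ells:
        qx = ((axes[0] - e.center[0]) / e.semiaxes[0]) ** 2
        qy = ((axes[1] - e.center[1]) / e.semiaxes[1]) ** 2
        qz = ((axes[2] - e.center[2]) / e.semiaxes[2]) ** 2
        m = qx[:, None, None] + qy[None, :, None] + qz[None, None, :] <= 1.0
        inside = m if inside is None else (inside | m)
    return float(np.count_nonzero(inside) * fine_spacing ** 3)


def build_phantom(config: PhantomConfig, seed: int = 0) -> Phantom3D:
    """Build a deterministic phantom from ``config`` and ``seed``.

    Raises ``ValueError`` if a requested lesion cannot fit inside the
    placental region.
    """
    rng = np.random.default_rng(seed)
    shape, spacing = tuple(config.shape), tuple(config.spacing)
    center = config.cavity_center
    if center is None:
        center = tuple(n * s / 2 for n, s in zip(shape, spacing))

    # myometrial shell: outer ellipsoid = cavity + base thickness, displaced
    # down the z axis so the gap narrows to min thickness at the top pole
    offset = config.myometrium_thickness - config.min_myometrial_thickness
    cavity = Ellipsoid(center, config.cavity_semiaxes)
    outer = Ellipsoid((center[0], center[1], center[2] - offset),
                      tuple(a + config.myometrium_thickness for a in config.cavity_semiaxes))

    # placenta tangent to the cavity wall at the top pole (placental bed)
    pz = center[2] + config.cavity_semiaxes[2] - config.placenta_semiaxes[2]
    placenta = Ellipsoid((center[0], center[1], pz), config.placenta_semiaxes)
    if not _inside(placenta, cavity):
        raise ValueError("placenta does not fit inside the uterine cavity")

    # lesions
    if config.dib_ellipsoids is not None:
        lesions = [e if isinstance(e, Ellipsoid) else Ellipsoid(*e)
                   for e in config.dib_ellipsoids]
        for e in lesions:
            if not _inside(e, placenta):
                raise ValueError(
                    f"DIB lesion with semi-axes {e.semiaxes} at {e.center} does not "
                    "fit inside the placental region")
    else:
        lesions = []
        lo, hi = config.dib_semiaxis_range
        for _ in range(config.n_dib):
            placed = False
            for _attempt in range(200):
                semi = tuple(rng.uniform(lo, hi, 3))
                u = rng.uniform(-1, 1, 3)
                cand = Ellipsoid(tuple(np.asarray(placenta.center)
                                       + u * (np.asarray(placenta.semiaxes)
                                              - np.asarray(semi))), semi)
                if min(np.asarray(placenta.semiaxes) - np.asarray(semi)) <= 0:
                    break
                if _inside(cand, placenta):
                    lesions.append(cand)
                    placed = True
                    break
            if not placed:
                raise ValueError(
                    f"could not place a DIB lesion with semi-axes in {config.dib_semiaxis_range}"
                    " inside the placental region")

    grid = np.zeros(shape, dtype=np.uint8)
    shell = _ellipsoid_mask(shape, spacing, outer) & ~_ellipsoid_mask(shape, spacing, cavity)
    grid[shell] = MYOMETRIUM
    plac_mask = _ellipsoid_mask(shape, spacing, placenta)
    grid[plac_mask] = PLACENTA
    for e in lesions:
        grid[_ellipsoid_mask(shape, spacing, e) & plac_mask] = DIB

    if config.interrupted:
        # spherical-cap hole through the shell at the top pole
        pole = (center[0], center[1], center[2] + config.cavity_semiaxes[2])
        hole = Ellipsoid(pole, (config.hole_radius,) * 3)
        grid[_ellipsoid_mask(shape, spacing, hole) & (grid == MYOMETRIUM)] = BACKGROUND

    return Phantom3D(
        voxel_grid=grid,
        spacing=spacing,
        dib_params=lesions,
        true_dib_volume=union_volume(lesions),
        true_min_thickness=float(config.min_myometrial_thickness),
        interrupted=bool(config.interrupted),
        config=config,
    )


def shell_is_closed(phantom: Phantom3D) -> bool:
    """True iff the myometrial shell separates the cavity from the exterior.

    Checked by connected-component labelling of the non-shell voxels: a
    closed shell leaves the cavity interior in a different component from
    the grid corner.
    """
    free = phantom.voxel_grid != MYOMETRIUM
    lab, _ = ndimage.label(free)
    center_idx = tuple(n // 2 for n in phantom.voxel_grid.shape)
    return lab[center_idx] != lab[0, 0, 0]


# ---------------------------------------------------------------------------
# slicing


def slice_phantom(phantom: Phantom3D, geometry: AcquisitionGeometry) -> SliceStack:
    """Resample the phantom's DIB mask into one plane's slice stack.

    Slice ``i`` covers the physical interval
    ``[i*(thickness+gap), i*(thickness+gap) + thickness)`` along the plane
    normal; gap regions belong to no slice.  Each slice's ROI is the voxel
    layer containing the slice midplane (central-section convention: the
    displayed image is taken to represent the center of the excited slab),
    so a lesion confined to a gap appears in no slice.
    """
    axis = PLANE_AXIS[geometry.plane]
    t, g = geometry.slice_thickness, geometry.slice_gap
    s_axis = phantom.spacing[axis]
    if s_axis >= t:
        raise ValueError("phantom spacing must be finer than the slice thickness")
    extent = phantom.extent[axis]
    in_plane_axes = [a for a in range(3) if a != axis]
    in_plane_spacing = tuple(phantom.spacing[a] for a in in_plane_axes)

    masks = []
    i = 0
    while i * (t + g) + t / 2 < extent:
        mid = i * (t + g) + t / 2
        layer = min(int(mid // s_axis), phantom.voxel_grid.shape[axis] - 1)
        masks.append(np.take(phantom.voxel_grid, layer, axis=axis) == DIB)
        i += 1
    return SliceStack.from_masks(geometry.plane, t, g, masks, in_plane_spacing)


# ---------------------------------------------------------------------------
# I/O: NIfTI masks + JSON sidecar, YAML geometry


def save_phantom(phantom: Phantom3D, path) -> None:
    """Write labels as NIfTI (uint8, spacing in the affine) plus a JSON sidecar."""
    path = Path(path)
    affine = np.diag([*phantom.spacing, 1.0])
    nib.save(nib.Nifti1Image(phantom.voxel_grid.astype(np.uint8), affine), str(path))
    sidecar = {
        "spacing_mm": list(phantom.spacing),
        "dib_ellipsoids": [{"center_mm": list(e.center), "semiaxes_mm": list(e.semiaxes)}
                           for e in phantom.dib_params],
        "true_dib_volume_mm3": phantom.true_dib_volume,
        "true_min_thickness_mm": phantom.true_min_thickness,
        "interrupted": phantom.interrupted,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_phantom(path) -> Phantom3D:
    path = Path(path)
    img = nib.load(str(path))
    meta = json.loads(path.with_suffix(".json").read_text())
    return Phantom3D(
        voxel_grid=np.asarray(img.dataobj, dtype=np.uint8),
        spacing=tuple(meta["spacing_mm"]),
        dib_params=[Ellipsoid(tuple(d["center_mm"]), tuple(d["semiaxes_mm"]))
                    for d in meta["dib_ellipsoids"]],
        true_dib_volume=float(meta["true_dib_volume_mm3"]),
        true_min_thickness=float(meta["true_min_thickness_mm"]),
        interrupted=bool(meta["interrupted"]),
    )


def save_slice_stack(stack: SliceStack, path) -> None:
    """Write a slice stack's ROI masks as a 3-D NIfTI plus JSON sidecar."""
    if stack.masks is None:
        raise ValueError("stack has no masks to save")
    path = Path(path)
    vol = np.stack(stack.masks, axis=-1).astype(np.uint8)
    affine = np.diag([*stack.in_plane_spacing_mm, stack.period_mm, 1.0])
    nib.save(nib.Nifti1Image(vol, affine), str(path))
    path.with_suffix(".json").write_text(json.dumps({
        "plane": stack.plane,
        "thickness_mm": stack.thickness_mm,
        "gap_mm": stack.gap_mm,
        "in_plane_spacing_mm": list(stack.in_plane_spacing_mm),
    }, indent=2))


def load_slice_stack(path) -> SliceStack:
    path = Path(path)
    img = nib.load(str(path))
    meta = json.loads(path.with_suffix(".json").read_text())
    vol = np.asarray(img.dataobj) > 0
    masks = [vol[..., k] for k in range(vol.shape[-1])]
    return SliceStack.from_masks(meta["plane"], meta["thickness_mm"], meta["gap_mm"],
                                 masks, tuple(meta["in_plane_spacing_mm"]))


def load_geometries(path) -> dict:
    """Read a YAML mapping plane -> {slice_thickness, slice_gap, in_plane_spacing}."""
    raw = yaml.safe_load(Path(path).read_text())
    return {plane: AcquisitionGeometry(plane=plane,
                                       slice_thickness=float(v["slice_thickness"]),
                                       slice_gap=float(v["slice_gap"]),
                                       in_plane_spacing=tuple(v["in_plane_spacing"]))
            for plane, v in raw.items()}


def save_geometries(geometries: dict, path) -> None:
    out = {p: {"slice_thickness": g.slice_thickness,
               "slice_gap": g.slice_gap,
               "in_plane_spacing": list(g.in_plane_spacing)}
           for p, g in geometries.items()}
    Path(path).write_text(yaml.safe_dump(out, sort_keys=True))


def default_geometries(slice_thickness: float = 5.0, slice_gap: float = 1.0,
                       in_plane: float = 400.0 / 256.0) -> dict:
    """Three-plane geometry matching a typical steady-state acquisition:
    5 mm slices, 1 mm gap, 400 mm field of view on a 256 matrix."""
    return {p: AcquisitionGeometry(p, slice_thickness, slice_gap, (in_plane, in_plane))
            for p in PLANE_AXIS}
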