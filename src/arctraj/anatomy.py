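"""Cranial structure-set model: masks, primitives, PRV expansion, segmentation.

Patient coordinate convention used throughout the package:

* axis 0 — lateral ``x`` in mm, right hemisphere negative, left positive;
* axis 1 — anterior-posterior ``ap`` in mm, increasing anterior -> posterior
  (the frontal pole of a typical head sits near -80 mm, the occipital pole
  near +100 mm);
* axis 2 — superior-inferior ``si`` in mm.

Files exported from RAS-convention tools have the AP axis flipped relative to
this convention; readers are expected to flip the sign on ingestion (the
loader logs a reminder).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

logger = logging.getLogger("arctraj")

AXIS_CONVENTION = "x-ap-si"

#: AP boundaries (mm) separating frontal/medial/posterior cranial segments.
FRONTAL_MEDIAL_AP_MM = 20.0
MEDIAL_POSTERIOR_AP_MM = 60.0

ROLES = frozenset({"target", "oar", "avoidance", "brain", "prv", "ring"})


class ArctrajError(Exception):
    """Base class for package errors."""


class ValidationError(ArctrajError):
    """Invalid argument or violated invariant."""


class FormatError(ArctrajError):
    """Malformed or inconsistent input file."""


class GridMismatchError(FormatError):
    """Structures do not share a common voxel grid."""


class OutOfDomainError(ValidationError):
    """A query point lies outside the supported domain."""


# ---------------------------------------------------------------------------
# Grid and geometric primitives
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Grid:
    """A regular voxel grid in patient coordinates.

    ``origin`` is the patient-coordinate position (mm) of the *center* of
    voxel (0, 0, 0); voxel centers are ``origin + index * spacing``.
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]
    axis_convention: str = AXIS_CONVENTION

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(n <= 0 for n in self.shape):
            raise ValidationError(f"grid shape must be 3 positive ints, got {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValidationError(f"grid spacing must be > 0 on all axes, got {self.spacing}")

    def axes_mm(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Voxel-center coordinates along each axis."""
        return tuple(
            self.origin[a] + self.spacing[a] * np.arange(self.shape[a])
            for a in range(3)
        )

    def index_of(self, point_mm) -> tuple[int, int, int]:
        """Nearest voxel index of a patient-coordinate point."""
        idx = np.rint((np.asarray(point_mm, float) - self.origin) / self.spacing).astype(int)
        if np.any(idx < 0) or np.any(idx >= self.shape):
            raise OutOfDomainError(f"point {point_mm} lies outside the grid")
        return tuple(int(i) for i in idx)

    def voxel_volume_cc(self) -> float:
        return float(np.prod(self.spacing)) / 1000.0

    def points_mm(self, mask: np.ndarray) -> np.ndarray:
        """(N, 3) patient coordinates of the voxel centers where ``mask`` is set."""
        idx = np.argwhere(mask)
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)


@dataclass(frozen=True)
class Sphere:
    center: tuple[float, float, float]
    diameter: float

    def __post_init__(self):
        if self.diameter <= 0:
            raise ValidationError("sphere diameter must be > 0")

    def contains(self, x, ap, si) -> np.ndarray:
        r = self.diameter / 2.0
        return ((x - self.center[0]) ** 2 + (ap - self.center[1]) ** 2
                + (si - self.center[2]) ** 2) <= r * r

    def analytic_volume_cc(self) -> float:
        return np.pi * self.diameter ** 3 / 6.0 / 1000.0


@dataclass(frozen=True)
class Ellipsoid:
    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]

    def __post_init__(self):
        if any(a <= 0 for a in self.semi_axes):
            raise ValidationError("ellipsoid semi-axes must be > 0")

    def contains(self, x, ap, si) -> np.ndarray:
        a, b, c = self.semi_axes
        return (((x - self.center[0]) / a) ** 2 + ((ap - self.center[1]) / b) ** 2
                + ((si - self.center[2]) / c) ** 2) <= 1.0

    def analytic_volume_cc(self) -> float:
        return 4.0 / 3.0 * np.pi * float(np.prod(self.semi_axes)) / 1000.0


@dataclass(frozen=True)
class Capsule:
    """Cylinder with hemispherical caps, from ``p1`` to ``p2`` with ``radius``."""

    p1: tuple[float, float, float]
    p2: tuple[float, float, float]
    radius: float

    def __post_init__(self):
        if self.radius <= 0:
            raise ValidationError("capsule radius must be > 0")

    def contains(self, x, ap, si) -> np.ndarray:
        p1 = np.asarray(self.p1, float)
        d = np.asarray(self.p2, float) - p1
        dd = float(d @ d)
        px, pap, psi = x - p1[0], ap - p1[1], si - p1[2]
        if dd == 0.0:
            t = 0.0
        else:
            t = np.clip((px * d[0] + pap * d[1] + psi * d[2]) / dd, 0.0, 1.0)
        return ((px - t * d[0]) ** 2 + (pap - t * d[1]) ** 2
                + (psi - t * d[2]) ** 2) <= self.radius ** 2

    def analytic_volume_cc(self) -> float:
        h = float(np.linalg.norm(np.asarray(self.p2) - np.asarray(self.p1)))
        r = self.radius
        return (np.pi * r * r * h + 4.0 / 3.0 * np.pi * r ** 3) / 1000.0


Primitive = Sphere | Ellipsoid | Capsule


# ---------------------------------------------------------------------------
# Structures and structure sets
# ---------------------------------------------------------------------------

@dataclass
class Structure:
    """A named anatomical structure: binary voxel mask and/or symbolic primitive.

    Primitives are voxelized lazily with a voxel-center-inclusion rule: a
    voxel belongs to the structure iff its center lies inside the primitive.
    """

    name: str
    role: str
    grid: Grid
    mask: np.ndarray | None = None
    primitive: Primitive | None = None
    _cached_mask: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValidationError(f"unknown role {self.role!r} for structure {self.name!r}")
        if self.mask is None and self.primitive is None:
            raise ValidationError(f"structure {self.name!r} has neither mask nor primitive")
        if self.mask is not None:
            self.mask = np.asarray(self.mask)
            if self.mask.shape != self.grid.shape:
                raise GridMismatchError(
                    f"mask shape {self.mask.shape} != grid shape {self.grid.shape} "
                    f"for structure {self.name!r}")
            if self.mask.dtype != bool:
                uniq = np.unique(self.mask)
                if not np.all(np.isin(uniq, (0, 1))):
                    raise ValidationError(f"mask of {self.name!r} is not binary")
                self.mask = self.mask.astype(bool)

    def voxelize(self) -> np.ndarray:
        """Binary mask on the parent grid (voxel-center rule for primitives)."""
        if self.mask is not None:
            return self.mask
        if self._cached_mask is None:
            xs, aps, sis = self.grid.axes_mm()
            self._cached_mask = self.primitive.contains(
                xs[:, None, None], aps[None, :, None], sis[None, None, :])
        return self._cached_mask

    def volume_cc(self) -> float:
        return int(self.voxelize().sum()) * self.grid.voxel_volume_cc()

    def centroid_mm(self) -> np.ndarray:
        if self.primitive is not None and not isinstance(self.primitive, Capsule):
            return np.asarray(self.primitive.center, float)
        m = self.voxelize()
        if not m.any():
            raise ValidationError(f"structure {self.name!r} is empty")
        return self.grid.points_mm(m).mean(axis=0)


@dataclass
class StructureSet:
    """Named structures sharing one voxel grid."""

    grid: Grid
    structures: dict[str, Structure] = field(default_factory=dict)

    def add(self, s: Structure) -> None:
        if s.grid != self.grid:
            raise GridMismatchError(
                f"structure {s.name!r} grid differs from the set's grid")
        self.structures[s.name] = s

    def __getitem__(self, name: str) -> Structure:
        try:
            return self.structures[name]
        except KeyError:
            raise KeyError(f"no structure named {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name in self.structures

    def names(self, role: str | None = None) -> list[str]:
        return [n for n, s in self.structures.items()
                if role is None or s.role == role]

    def brain(self) -> Structure:
        brains = self.names("brain")
        if len(brains) != 1:
            raise ValidationError(
                f"expected exactly one structure with role 'brain', found {len(brains)}")
        return self.structures[brains[0]]


# ---------------------------------------------------------------------------
# Six-class cranial segmentation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SegmentClass:
    """One of six cranial segments: laterality x (frontal, medial, posterior).

    Class ids: 1=right-frontal, 2=left-frontal, 3=right-medial, 4=left-medial,
    5=right-posterior, 6=left-posterior. AP bounds are half-open [lo, hi) in
    mm, with hi of the posterior segment inclusive at the brain extent.
    """

    id: int
    laterality: str
    region: str
    ap_bounds: tuple[float, float]


_CLASS_ID = {
    ("right", "frontal"): 1, ("left", "frontal"): 2,
    ("right", "medial"): 3, ("left", "medial"): 4,
    ("right", "posterior"): 5, ("left", "posterior"): 6,
}


def class_name(class_id: int) -> str:
    """Human-readable name, e.g. 1 -> 'right_frontal'."""
    for (lat, reg), cid in _CLASS_ID.items():
        if cid == class_id:
            return f"{lat}_{reg}"
    raise ValidationError(f"class id must be 1..6, got {class_id}")


def classify_segment(point_mm, brain: Structure) -> SegmentClass:
    """Assign a brain-interior point to one of the six cranial segments.

    Laterality: right if lateral x < 0, left if x >= 0. Region by AP
    coordinate: frontal [brain min, 20), medial [20, 60), posterior
    [60, brain max].
    """
    point_mm = np.asarray(point_mm, float)
    idx = brain.grid.index_of(point_mm)
    if not brain.voxelize()[idx]:
        raise OutOfDomainError(f"point {tuple(point_mm)} is outside the brain contour")

    ap_pts = brain.grid.points_mm(brain.voxelize())[:, 1]
    ap_min, ap_max = float(ap_pts.min()), float(ap_pts.max())

    x, ap = point_mm[0], point_mm[1]
    laterality = "right" if x < 0 else "left"
    if ap < FRONTAL_MEDIAL_AP_MM:
        region, bounds = "frontal", (ap_min, FRONTAL_MEDIAL_AP_MM)
    elif ap < MEDIAL_POSTERIOR_AP_MM:
        region, bounds = "medial", (FRONTAL_MEDIAL_AP_MM, MEDIAL_POSTERIOR_AP_MM)
    else:
        region, bounds = "posterior", (MEDIAL_POSTERIOR_AP_MM, ap_max)
    return SegmentClass(id=_CLASS_ID[(laterality, region)],
                        laterality=laterality, region=region, ap_bounds=bounds)


# ---------------------------------------------------------------------------
# Morphology and distances
# ---------------------------------------------------------------------------

def merge_oars(sset: StructureSet, names: list[str],
               merged_name: str = "avoidance") -> Structure:
    """Voxelwise union of the named OARs into a single avoidance structure."""
    if not names:
        raise ValidationError("no OAR names given to merge")
    union = np.zeros(sset.grid.shape, dtype=bool)
    for name in names:
        s = sset[name]
        if s.role != "oar":
            raise ValidationError(f"structure {name!r} has role {s.role!r}, expected 'oar'")
        union |= s.voxelize()
    return Structure(name=merged_name, role="avoidance", grid=sset.grid, mask=union)


def expand_prv(oar: Structure, margin_mm: float,
               name: str | None = None) -> Structure:
    """Isotropic Euclidean dilation of an OAR by ``margin_mm`` into a PRV.

    Spheres and capsules dilate exactly (their Euclidean dilation is again a
    sphere / capsule with the radius grown by the margin); other
    representations use a distance-transform threshold, marking every voxel
    whose center is within ``margin_mm`` of an OAR voxel center. Either way
    the PRV is a superset of the OAR and monotone in the margin.
    """
    if margin_mm < 0:
        raise ValidationError(f"PRV margin must be >= 0, got {margin_mm}")
    prv_name = name or f"{oar.name}_prv"
    if isinstance(oar.primitive, Sphere) and margin_mm > 0:
        grown = Sphere(center=oar.primitive.center,
                       diameter=oar.primitive.diameter + 2 * margin_mm)
        return Structure(name=prv_name, role="prv", grid=oar.grid, primitive=grown)
    if isinstance(oar.primitive, Capsule) and margin_mm > 0:
        grown = Capsule(p1=oar.primitive.p1, p2=oar.primitive.p2,
                        radius=oar.primitive.radius + margin_mm)
        return Structure(name=prv_name, role="prv", grid=oar.grid, primitive=grown)
    mask = oar.voxelize()
    if margin_mm == 0:
        out = mask.copy()
    else:
        dist = ndimage.distance_transform_edt(~mask, sampling=oar.grid.spacing)
        out = dist <= margin_mm
    return Structure(name=prv_name, role="prv", grid=oar.grid, mask=out)


def min_distance(a: Structure, b: Structure) -> float:
    """Minimum Euclidean distance (mm) between two voxelized structures.

    Measured between voxel centers in full 3D (not per-slice); 0 when the
    structures intersect. Symmetric in its arguments.
    """
    if a.grid != b.grid:
        raise GridMismatchError("structures are not on a common grid")
    am, bm = a.voxelize(), b.voxelize()
    if not am.any() or not bm.any():
        raise ValidationError("min_distance requires two non-empty structures")
    if (am & bm).any():
        return 0.0
    dist_to_b = ndimage.distance_transform_edt(~bm, sampling=a.grid.spacing)
    return float(dist_to_b[am].min())


# ---------------------------------------------------------------------------
# I/O: JSON geometry dialect and NIfTI manifests
# ---------------------------------------------------------------------------

def _primitive_from_json(rec: dict) -> Primitive:
    shape = rec.get("shape")
    if shape == "sphere":
        return Sphere(center=tuple(rec["center_mm"]), diameter=float(rec["diameter_mm"]))
    if shape == "ellipsoid":
        return Ellipsoid(center=tuple(rec["center_mm"]),
                         semi_axes=tuple(rec["semi_axes_mm"]))
    if shape == "capsule":
        return Capsule(p1=tuple(rec["p1_mm"]), p2=tuple(rec["p2_mm"]),
                       radius=float(rec["radius_mm"]))
    raise FormatError(f"unknown primitive shape {shape!r}")


def _primitive_to_json(p: Primitive) -> dict:
    if isinstance(p, Sphere):
        return {"shape": "sphere", "center_mm": list(p.center), "diameter_mm": p.diameter}
    if isinstance(p, Ellipsoid):
        return {"shape": "ellipsoid", "center_mm": list(p.center),
                "semi_axes_mm": list(p.semi_axes)}
    return {"shape": "capsule", "p1_mm": list(p.p1), "p2_mm": list(p.p2),
            "radius_mm": p.radius}


def load_structures(path: str | Path) -> StructureSet:
    """Load a StructureSet from a JSON geometry file or a NIfTI mask manifest.

    A geometry file has keys ``grid`` ({"shape", "spacing_mm", "origin_mm"})
    and ``structures`` (list of primitive records). A manifest has key
    ``structures`` whose records carry ``file`` entries pointing at one
    ``.nii``/``.nii.gz`` binary mask each; all masks must share one grid.
    """
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path} is not valid JSON: {exc}") from exc
    records = doc.get("structures")
    if not records:
        raise FormatError(f"{path}: no structures")

    if "grid" in doc:  # geometry dialect
        g = doc["grid"]
        grid = Grid(shape=tuple(g["shape"]), spacing=tuple(g["spacing_mm"]),
                    origin=tuple(g["origin_mm"]))
        sset = StructureSet(grid=grid)
        for rec in records:
            sset.add(Structure(name=rec["name"], role=rec["role"], grid=grid,
                               primitive=_primitive_from_json(rec)))
        return sset

    # NIfTI manifest
    import nibabel as nib

    logger.info("loading NIfTI masks; AP axis is assumed anterior->posterior "
                "increasing (flip the sign of RAS-convention files on export)")
    sset = None
    for rec in records:
        img = nib.load(path.parent / rec["file"])
        data = np.asanyarray(img.dataobj)
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        origin = tuple(float(v) for v in img.affine[:3, 3])
        grid = Grid(shape=data.shape, spacing=spacing, origin=origin)
        if sset is None:
            sset = StructureSet(grid=grid)
        elif grid != sset.grid:
            raise GridMismatchError(
                f"{rec['file']}: grid {grid} differs from {sset.grid}")
        sset.add(Structure(name=rec["name"], role=rec["role"], grid=grid,
                           mask=data > 0))
    return sset


def save_structures(sset: StructureSet, out_dir: str | Path,
                    fmt: str = "nifti") -> Path:
    """Write a StructureSet as NIfTI masks + manifest, or one geometry JSON.

    Returns the manifest / geometry-file path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if fmt == "json":
        recs = []
        for s in sset.structures.values():
            if s.primitive is None:
                raise ValidationError(
                    f"structure {s.name!r} has no primitive; use fmt='nifti'")
            recs.append({"name": s.name, "role": s.role, **_primitive_to_json(s.primitive)})
        doc = {"grid": {"shape": list(sset.grid.shape),
                        "spacing_mm": list(sset.grid.spacing),
                        "origin_mm": list(sset.grid.origin)},
               "structures": recs}
        out = out_dir / "geometry.json"
        out.write_text(json.dumps(doc, indent=2))
        return out

    import nibabel as nib

    affine = np.diag(list(sset.grid.spacing) + [1.0])
    affine[:3, 3] = sset.grid.origin
    recs = []
    for s in sset.structures.values():
        fname = f"{s.name}.nii.gz"
        nib.save(nib.Nifti1Image(s.voxelize().astype(np.uint8), affine),
                 out_dir / fname)
        recs.append({"file": fname, "name": s.name, "role": s.role})
    manifest = out_dir / "manifest.json"
    manifest.write_text(json.dumps({"structures": recs}, indent=2))
    return manifest
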