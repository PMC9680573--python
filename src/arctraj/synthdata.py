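"""Parameterized cranial phantom, 18-case synthetic suite, analytic dose grids.

The phantom stands in for a population-averaged brain atlas: an ellipsoidal
brain contour populated with eight organ-at-risk primitives (brainstem,
optic chiasm, paired optic nerves, eyes and lenses) positioned at
anatomically plausible locations, mirror-symmetric across the midline. Its
default AP extent (-80 mm anterior pole to +100 mm occipital pole) matches
the segmentation bounds used for the six cranial classes, so targets placed
in each class fall in anatomically sensible positions relative to the OARs.

All downstream computation (overlap maps, templates, arc optimization,
objectives, metrics, statistics) runs on this phantom without any external
data. Dose grids are analytic fields (uniform / linear falloff /
inverse-cube), never optimizer outputs: treatment-planning-system dose
calculation is deliberately outside this package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .anatomy import (Capsule, Ellipsoid, Grid, Primitive, Sphere, Structure,
                      StructureSet, ValidationError, classify_segment,
                      class_name, FRONTAL_MEDIAL_AP_MM, MEDIAL_POSTERIOR_AP_MM)
from .metrics import DoseGrid

logger = logging.getLogger("arctraj")

#: Target sphere diameters (mm) of the synthetic single-metastasis suite.
CASE_DIAMETERS_MM = (5.0, 10.0, 20.0)

DOSE_MODELS = ("uniform", "linear-falloff", "inverse-cube")


def _default_oars() -> dict[str, Primitive]:
    # Coordinates in (x lateral, ap anterior->posterior, si) mm; brain is
    # centered at ap=+10 so its AP extent is [-80, +100]. Left/right pairs
    # mirror across x=0.
    return {
        "brainstem": Capsule(p1=(0.0, 18.0, -12.0), p2=(0.0, 28.0, -60.0), radius=9.0),
        "chiasm": Ellipsoid(center=(0.0, 5.0, -10.0), semi_axes=(7.0, 4.0, 2.5)),
        "optic_nerve_r": Capsule(p1=(-28.0, -70.0, -16.0), p2=(-5.0, 0.0, -11.0), radius=2.0),
        "optic_nerve_l": Capsule(p1=(28.0, -70.0, -16.0), p2=(5.0, 0.0, -11.0), radius=2.0),
        "eye_r": Sphere(center=(-30.0, -78.0, -18.0), diameter=24.0),
        "eye_l": Sphere(center=(30.0, -78.0, -18.0), diameter=24.0),
        "lens_r": Sphere(center=(-30.0, -89.0, -18.0), diameter=8.0),
        "lens_l": Sphere(center=(30.0, -89.0, -18.0), diameter=8.0),
    }


@dataclass
class PhantomConfig:
    """Geometry of the cranial phantom.

    ``brain_semi_axes_mm`` are the lateral/AP/SI semi-axes of the brain
    ellipsoid; with the default center (0, +10, 0) the AP extent runs from
    -80 mm to +100 mm. ``oars`` must contain exactly 8 primitives with
    left/right pairs mirrored across x = 0.
    """

    brain_semi_axes_mm: tuple[float, float, float] = (70.0, 90.0, 65.0)
    brain_center_mm: tuple[float, float, float] = (0.0, 10.0, 0.0)
    spacing_mm: float = 2.0
    pad_mm: float = 6.0
    seed: int = 0
    oars: dict[str, Primitive] = field(default_factory=_default_oars)


def _primitive_bbox(p: Primitive) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(p, Sphere):
        c = np.asarray(p.center)
        r = p.diameter / 2.0
        return c - r, c + r
    if isinstance(p, Ellipsoid):
        c, s = np.asarray(p.center), np.asarray(p.semi_axes)
        return c - s, c + s
    lo = np.minimum(p.p1, p.p2) - p.radius
    hi = np.maximum(p.p1, p.p2) + p.radius
    return lo, hi


def build_phantom(cfg: PhantomConfig | None = None) -> StructureSet:
    """Voxel grid + brain ellipsoid + 8 OAR primitives, deterministic per config."""
    cfg = cfg or PhantomConfig()
    if len(cfg.oars) != 8:
        raise ValidationError(f"phantom requires exactly 8 OARs, got {len(cfg.oars)}")

    c = np.asarray(cfg.brain_center_mm)
    semi = np.asarray(cfg.brain_semi_axes_mm)
    lo, hi = c - semi, c + semi
    for name, prim in cfg.oars.items():
        plo, phi = _primitive_bbox(prim)
        lo, hi = np.minimum(lo, plo), np.maximum(hi, phi)
        # OARs must sit inside or immediately adjacent to the cranium
        center = (plo + phi) / 2.0
        if np.any(np.abs(center - c) > 1.5 * semi):
            raise ValidationError(f"OAR {name!r} lies far outside the brain ellipsoid")

    lo -= cfg.pad_mm
    hi += cfg.pad_mm
    origin = np.floor(lo / cfg.spacing_mm) * cfg.spacing_mm
    shape = tuple(int(n) for n in
                  np.ceil((hi - origin) / cfg.spacing_mm).astype(int) + 1)
    grid = Grid(shape=shape, spacing=(cfg.spacing_mm,) * 3,
                origin=tuple(float(v) for v in origin))

    sset = StructureSet(grid=grid)
    sset.add(Structure(name="brain", role="brain", grid=grid,
                       primitive=Ellipsoid(center=tuple(c), semi_axes=tuple(semi))))
    for name, prim in cfg.oars.items():
        sset.add(Structure(name=name, role="oar", grid=grid, primitive=prim))
    return sset


# ---------------------------------------------------------------------------
# 18-case synthetic suite
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticCase:
    case_id: str
    class_id: int
    diameter_mm: float
    center_mm: tuple[float, float, float]


@dataclass
class CaseSuite:
    """Six cranial classes x three target diameters = 18 single-target cases."""

    cases: list[SyntheticCase]

    def __len__(self) -> int:
        return len(self.cases)

    def __iter__(self):
        return iter(self.cases)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"case_id": k.case_id, "class": k.class_id,
              "diameter_mm": k.diameter_mm, "center_x": k.center_mm[0],
              "center_ap": k.center_mm[1], "center_si": k.center_mm[2]}
             for k in self.cases])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "CaseSuite":
        df = pd.read_csv(path)
        return cls([SyntheticCase(case_id=str(r.case_id), class_id=int(r["class"]),
                                  diameter_mm=float(r.diameter_mm),
                                  center_mm=(float(r.center_x), float(r.center_ap),
                                             float(r.center_si)))
                    for _, r in df.iterrows()])


def make_case_suite(phantom: StructureSet, seed: int = 0) -> CaseSuite:
    """Place one spherical target per (class, diameter) inside the phantom brain.

    Placement is seeded rejection-free sampling over brain voxels that can
    host the full sphere (interior distance-to-surface >= radius), restricted
    to the class region and weighted toward the region centroid so targets
    land in representative, fully contained positions.
    """
    brain = phantom.brain()
    grid = phantom.grid
    mask = brain.voxelize()
    depth_mm = ndimage.distance_transform_edt(mask, sampling=grid.spacing)
    pts = grid.points_mm(mask)
    depth = depth_mm[mask]

    x, ap = pts[:, 0], pts[:, 1]
    region_of = np.where(ap < FRONTAL_MEDIAL_AP_MM, 0,
                         np.where(ap < MEDIAL_POSTERIOR_AP_MM, 1, 2))
    side_of = (x >= 0).astype(int)  # 0=right, 1=left

    rng = np.random.default_rng(seed)
    cases: list[SyntheticCase] = []
    for class_id in range(1, 7):
        side = (class_id - 1) % 2       # 1,3,5 right; 2,4,6 left
        region = (class_id - 1) // 2    # frontal, medial, posterior
        in_class = (side_of == side) & (region_of == region)
        if not in_class.any():
            raise ValidationError(
                f"class {class_id} ({class_name(class_id)}) region is empty")
        centroid = pts[in_class].mean(axis=0)
        for diameter in CASE_DIAMETERS_MM:
            radius = diameter / 2.0
            ok = in_class & (depth >= radius)
            # the sphere must also stay within the class region laterally/AP
            if not ok.any():
                raise ValidationError(
                    f"class {class_id} ({class_name(class_id)}) cannot host a "
                    f"{diameter:g} mm diameter target")
            cand = pts[ok]
            d = np.linalg.norm(cand - centroid, axis=1)
            w = np.exp(-d / 25.0)
            center = cand[rng.choice(len(cand), p=w / w.sum())]
            assigned = classify_segment(center, brain)
            if assigned.id != class_id:  # pragma: no cover - construction invariant
                raise ValidationError(
                    f"placed center classifies to {assigned.id}, expected {class_id}")
            cases.append(SyntheticCase(
                case_id=f"c{class_id}_d{diameter:g}mm", class_id=class_id,
                diameter_mm=diameter,
                center_mm=tuple(float(v) for v in center)))
    return CaseSuite(cases)


def case_target(phantom: StructureSet, case: SyntheticCase,
                name: str = "PTV") -> Structure:
    """Spherical PTV structure for a synthetic case, on the phantom grid."""
    return Structure(name=name, role="target", grid=phantom.grid,
                     primitive=Sphere(center=case.center_mm,
                                      diameter=case.diameter_mm))


def case_structure_set(phantom: StructureSet, case: SyntheticCase) -> StructureSet:
    """Phantom structures plus the case's PTV, as one StructureSet."""
    sset = StructureSet(grid=phantom.grid,
                        structures=dict(phantom.structures))
    sset.add(case_target(phantom, case))
    return sset


# ---------------------------------------------------------------------------
# Analytic dose fixtures
# ---------------------------------------------------------------------------

def synth_dose(model: str, rx_cgy: float, r0_mm: float, grid: Grid,
               center_mm=(0.0, 0.0, 0.0), falloff_per_mm: float = 0.10) -> DoseGrid:
    """Spherically symmetric analytic dose field.

    Inside radius ``r0_mm`` the dose is ``rx_cgy``; outside it follows the
    model: ``uniform`` keeps rx everywhere, ``linear-falloff`` is
    rx * max(0, 1 - falloff_per_mm * (r - r0)), ``inverse-cube`` is
    rx * (r0 / r)**3. All models are monotone non-increasing in radius.
    """
    if model not in DOSE_MODELS:
        raise ValidationError(f"unknown dose model {model!r}; choose from {DOSE_MODELS}")
    if rx_cgy <= 0 or r0_mm <= 0:
        raise ValidationError("rx and r0 must be > 0")
    xs, aps, sis = grid.axes_mm()
    r = np.sqrt((xs[:, None, None] - center_mm[0]) ** 2
                + (aps[None, :, None] - center_mm[1]) ** 2
                + (sis[None, None, :] - center_mm[2]) ** 2)
    if model == "uniform":
        dose = np.full(grid.shape, float(rx_cgy))
    elif model == "linear-falloff":
        dose = rx_cgy * np.maximum(0.0, 1.0 - falloff_per_mm * (r - r0_mm))
        dose[r <= r0_mm] = rx_cgy
    else:  # inverse-cube
        with np.errstate(divide="ignore"):
            dose = rx_cgy * (r0_mm / np.maximum(r, 1e-9)) ** 3
        dose[r <= r0_mm] = rx_cgy
    return DoseGrid(grid=grid, dose=dose)
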