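"""Class-solution template maps: systematic target grids + per-class maxima.

A template overlap map for each of the six cranial segments is built by
tiling the brain contour with equally sized, equally spaced spherical
targets (2 cm diameter, 2 cm apart by default), computing each target's
BEV overlap map against the merged avoidance structure, grouping targets
into segments by centroid, and taking the bin-wise *maximum* over each
group. The maximum makes every template a conservative overestimate of the
overlap any individual target in that segment could see, so a trajectory
that avoids the template's hot regions avoids every member's hot regions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .anatomy import (Structure, StructureSet, ValidationError,
                      classify_segment, class_name, merge_oars)
from .bev import OverlapMap, compute_overlap_maps

logger = logging.getLogger("arctraj")

DEFAULT_TARGET_DIAMETER_MM = 20.0
DEFAULT_TARGET_SPACING_MM = 20.0


@dataclass
class TargetGrid:
    """Axis-aligned lattice of fully contained sphere centers."""

    centers_mm: np.ndarray   # (N, 3)
    diameter_mm: float
    spacing_mm: float
    containing: str          # name of the containing structure

    def __len__(self) -> int:
        return len(self.centers_mm)


@dataclass
class ClassTemplate:
    """Bin-wise maximum overlap map over one cranial segment's targets."""

    class_id: int
    template: OverlapMap
    contributing: int

    @property
    def name(self) -> str:
        return f"class{self.class_id}_{class_name(self.class_id)}"


def grid_targets(brain: Structure, diameter_mm: float = DEFAULT_TARGET_DIAMETER_MM,
                 spacing_mm: float = DEFAULT_TARGET_SPACING_MM) -> TargetGrid:
    """Lattice of sphere centers whose spheres fit entirely inside the contour.

    The lattice is anchored at the brain centroid and steps +/- spacing per
    axis; a center is kept iff the full sphere (every point within
    diameter/2 of it) lies inside the contour, assessed via the interior
    Euclidean distance transform. Ordering is deterministic: ascending SI,
    then AP, then lateral.
    """
    if diameter_mm <= 0 or spacing_mm <= 0:
        raise ValidationError("diameter and spacing must be > 0")
    grid = brain.grid
    mask = brain.voxelize()
    if not mask.any():
        logger.warning("empty brain contour: target grid is empty")
        return TargetGrid(np.empty((0, 3)), diameter_mm, spacing_mm, brain.name)
    radius = diameter_mm / 2.0
    depth = ndimage.distance_transform_edt(mask, sampling=grid.spacing)

    anchor = brain.centroid_mm()
    lo = np.asarray(grid.origin)
    hi = lo + (np.asarray(grid.shape) - 1) * np.asarray(grid.spacing)
    axes = []
    for a in range(3):
        n_neg = int(np.floor((anchor[a] - lo[a]) / spacing_mm))
        n_pos = int(np.floor((hi[a] - anchor[a]) / spacing_mm))
        axes.append(anchor[a] + spacing_mm * np.arange(-n_neg, n_pos + 1))

    centers = []
    for si in axes[2]:
        for ap in axes[1]:
            for x in axes[0]:
                idx = np.rint((np.array([x, ap, si]) - lo) / grid.spacing).astype(int)
                if np.any(idx < 0) or np.any(idx >= grid.shape):
                    continue
                idx = tuple(idx)
                if mask[idx] and depth[idx] >= radius:
                    centers.append([x, ap, si])
    if not centers:
        logger.warning("no %g mm sphere fits inside %r at %g mm spacing",
                       diameter_mm, brain.name, spacing_mm)
        return TargetGrid(np.empty((0, 3)), diameter_mm, spacing_mm, brain.name)
    return TargetGrid(np.asarray(centers, float), diameter_mm, spacing_mm, brain.name)


def aggregate_max(maps: list[OverlapMap]) -> OverlapMap:
    """Bin-wise maximum of overlap maps (associative, commutative, idempotent).

    All maps must share shape and collision mask; the mask is propagated
    unchanged.
    """
    if not maps:
        raise ValidationError("aggregate_max requires at least one map")
    first = maps[0]
    for m in maps[1:]:
        if m.shape != first.shape:
            raise ValidationError(f"map shape {m.shape} != {first.shape}")
        if not np.array_equal(m.collision, first.collision):
            raise ValidationError("collision masks differ between maps")
    values = np.maximum.reduce([m.values for m in maps])
    return OverlapMap(couch_deg=first.couch_deg.copy(),
                      gantry_deg=first.gantry_deg.copy(),
                      values=values, collision=first.collision.copy(),
                      meta={"aggregate": "max", "n_maps": len(maps)})


def build_class_templates(phantom: StructureSet,
                          diameter_mm: float = DEFAULT_TARGET_DIAMETER_MM,
                          spacing_mm: float = DEFAULT_TARGET_SPACING_MM,
                          resolution_deg: float = 5.0,
                          pixel_mm: float = 1.0) -> dict[int, ClassTemplate]:
    """Template overlap maps for all six cranial segments.

    Tiles the brain with the systematic target grid, computes every
    target's overlap map against the merged avoidance structure, assigns
    each target to a segment by its centroid, and aggregates bin-wise
    maxima per segment. Deterministic for a fixed phantom and grid config.
    """
    brain = phantom.brain()
    tgrid = grid_targets(brain, diameter_mm, spacing_mm)
    if len(tgrid) == 0:
        raise ValidationError("target grid is empty; cannot build templates")
    avoidance = merge_oars(phantom, phantom.names("oar"))

    from .anatomy import Sphere
    targets = [Structure(name=f"tpl_{i}", role="target", grid=phantom.grid,
                         primitive=Sphere(center=tuple(c), diameter=diameter_mm))
               for i, c in enumerate(tgrid.centers_mm)]
    logger.info("computing %d template target maps at %g deg resolution",
                len(targets), resolution_deg)
    maps = compute_overlap_maps(targets, avoidance, resolution_deg, pixel_mm)

    by_class: dict[int, list[OverlapMap]] = {cid: [] for cid in range(1, 7)}
    for center, omap in zip(tgrid.centers_mm, maps):
        cid = classify_segment(center, brain).id
        by_class[cid].append(omap)

    templates = {}
    for cid, members in by_class.items():
        if not members:
            raise ValidationError(
                f"class {cid} ({class_name(cid)}) received no targets; "
                "refine the grid spacing")
        templates[cid] = ClassTemplate(class_id=cid,
                                       template=aggregate_max(members),
                                       contributing=len(members))
    return templates
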