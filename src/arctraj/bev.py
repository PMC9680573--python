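"""4-pi beam's-eye-view overlap maps over couch x gantry angle space.

For every (couch, gantry) combination the target and the merged avoidance
structure are projected onto the plane orthogonal to the beam axis
(parallel-ray approximation) and rasterized; the map value is the fraction
of the target shadow covered by the avoidance shadow, in [0, 1]. Depth is
ignored deliberately: an OAR distal to the target still receives exit dose,
so overlap counts regardless of which structure is proximal to the source.

Angle conventions (IEC-61217-like, head-first supine):

* gantry 0 deg sends the beam anterior -> posterior, i.e. along +AP;
* gantry rotates about the SI axis at couch 0;
* couch rotation turns the patient about the room-vertical (patient AP)
  axis, tilting the gantry plane; couch angles span [-90, +90) deg.

Under parallel projection the shadow depends only on the beam axis *line*,
so O(couch, g) = O(couch, g + 180) exactly (antipodal symmetry); the
implementation canonicalizes the axis so this holds bit-for-bit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .anatomy import ArctrajError, Structure, ValidationError

logger = logging.getLogger("arctraj")

DEFAULT_RESOLUTION_DEG = 1.0
DEFAULT_PIXEL_MM = 1.0

COUCH_MIN_DEG = -90.0
COUCH_MAX_DEG = 90.0  # exclusive


class ComputationError(ArctrajError):
    """An overlap computation could not produce a defined value."""


def beam_axis(couch_deg: float, gantry_deg: float) -> np.ndarray:
    """Unit beam direction (source -> isocenter) in (x, ap, si) coordinates.

    (couch 0, gantry 0) -> (0, +1, 0): the beam travels anterior to
    posterior. Angles are normalized mod 360.
    """
    c = np.deg2rad(couch_deg)
    g = np.deg2rad(gantry_deg)
    return np.array([np.sin(g) * np.cos(c), np.cos(g), np.sin(g) * np.sin(c)])


def _projection_basis(axis: np.ndarray) -> np.ndarray:
    """(2, 3) orthonormal basis of the plane orthogonal to the beam axis.

    The axis is canonicalized to its first component of magnitude > tol
    being positive, so antipodal directions share one basis and produce
    identical shadows.
    """
    d = axis / np.linalg.norm(axis)
    for comp in d:
        if abs(comp) > 1e-12:
            if comp < 0:
                d = -d
            break
    ref = np.array([0.0, 0.0, 1.0])
    if abs(d @ ref) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    u = np.cross(d, ref)
    u /= np.linalg.norm(u)
    v = np.cross(d, u)
    return np.vstack([u, v])


@dataclass
class OverlapMap:
    """Fractional BEV overlap on a couch x gantry grid, with collision mask."""

    couch_deg: np.ndarray   # (C,) ascending, [-90, 90)
    gantry_deg: np.ndarray  # (G,) ascending, [0, 360)
    values: np.ndarray      # (C, G) fractions in [0, 1]
    collision: np.ndarray | None = None  # (C, G) bool, True = infeasible
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.couch_deg = np.asarray(self.couch_deg, float)
        self.gantry_deg = np.asarray(self.gantry_deg, float)
        self.values = np.asarray(self.values, float)
        if self.values.shape != (len(self.couch_deg), len(self.gantry_deg)):
            raise ValidationError(
                f"values shape {self.values.shape} does not match angle axes")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("overlap values must be finite (collisions are "
                                  "flagged in the mask, not stored as NaN)")
        if self.values.min() < 0 or self.values.max() > 1:
            raise ValidationError("overlap values must lie in [0, 1]")
        if self.collision is None:
            self.collision = np.zeros(self.values.shape, dtype=bool)
        else:
            self.collision = np.asarray(self.collision, bool)
            if self.collision.shape != self.values.shape:
                raise ValidationError("collision mask shape mismatch")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def resolution_deg(self) -> float:
        return float(self.gantry_deg[1] - self.gantry_deg[0]) if len(self.gantry_deg) > 1 \
            else 360.0

    # -- serialization ------------------------------------------------------

    def save_csv(self, path: str | Path, collision_path: str | Path | None = None) -> None:
        """Write the map (and optionally its collision mask) as CSV.

        Layout: first column holds couch angles, the header row holds gantry
        angles, cells hold fractions at 6 decimals.
        """
        df = pd.DataFrame(np.round(self.values, 6), index=self.couch_deg,
                          columns=self.gantry_deg)
        df.index.name = "couch_deg"
        df.to_csv(path, float_format="%.6f")
        if collision_path is not None:
            cdf = pd.DataFrame(self.collision.astype(int), index=self.couch_deg,
                               columns=self.gantry_deg)
            cdf.index.name = "couch_deg"
            cdf.to_csv(collision_path)

    @classmethod
    def load_csv(cls, path: str | Path,
                 collision_path: str | Path | None = None) -> "OverlapMap":
        df = pd.read_csv(path, index_col=0)
        collision = None
        if collision_path is not None:
            collision = pd.read_csv(collision_path, index_col=0).to_numpy().astype(bool)
        return cls(couch_deg=df.index.to_numpy(float),
                   gantry_deg=np.array([float(c) for c in df.columns]),
                   values=df.to_numpy(float), collision=collision)

    def save_png(self, path: str | Path) -> None:
        """Optional heat-map rendering (collision bins hatched dark)."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(8, 4))
        shown = np.ma.masked_where(self.collision, self.values)
        im = ax.pcolormesh(self.gantry_deg, self.couch_deg, shown,
                           cmap="viridis", vmin=0, vmax=1)
        ax.set_xlabel("gantry angle (deg)")
        ax.set_ylabel("couch angle (deg)")
        fig.colorbar(im, ax=ax, label="fractional BEV overlap")
        fig.savefig(path, dpi=120)
        plt.close(fig)


def default_angle_grid(resolution_deg: float = DEFAULT_RESOLUTION_DEG
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Couch [-90, 90) and gantry [0, 360) axes at the given resolution."""
    if resolution_deg <= 0 or 360.0 % resolution_deg != 0:
        raise ValidationError(f"resolution must divide 360, got {resolution_deg}")
    couch = np.arange(COUCH_MIN_DEG, COUCH_MAX_DEG, resolution_deg)
    gantry = np.arange(0.0, 360.0, resolution_deg)
    return couch, gantry


def _shadow_pixels(points_mm: np.ndarray, basis: np.ndarray,
                   pixel_mm: float) -> np.ndarray:
    """Unique rasterized pixel ids of projected voxel centers."""
    uv = points_mm @ basis.T
    ij = np.floor(uv / pixel_mm).astype(np.int64)
    return np.unique(ij[:, 0] * (1 << 32) + ij[:, 1])


def compute_overlap_maps(targets: list[Structure], avoidance: Structure,
                         resolution_deg: float = DEFAULT_RESOLUTION_DEG,
                         pixel_mm: float = DEFAULT_PIXEL_MM) -> list[OverlapMap]:
    """Overlap maps of several targets against one avoidance structure.

    The avoidance shadow is projected once per angle bin and shared across
    targets, which makes template construction (hundreds of targets, one
    merged avoidance structure) tractable. Antipodal gantry bins are filled
    by symmetry.
    """
    couch, gantry = default_angle_grid(resolution_deg)
    C, G = len(couch), len(gantry)

    tpoints = []
    for t in targets:
        pts = t.grid.points_mm(t.voxelize())
        if len(pts) == 0:
            raise ComputationError(f"target {t.name!r} has an empty shadow "
                                   "(no voxels on this grid)")
        tpoints.append(pts)
    apoints = avoidance.voxelize()
    apoints = avoidance.grid.points_mm(apoints)

    values = [np.zeros((C, G)) for _ in targets]
    # antipodal fill: O(c, g) == O(c, g + 180) exactly under parallel rays
    use_symmetry = G % 2 == 0
    gcount = G // 2 if use_symmetry else G
    for ci in range(C):
        for gi in range(gcount):
            basis = _projection_basis(beam_axis(couch[ci], gantry[gi]))
            if len(apoints) == 0:
                frac_by_target = [0.0] * len(targets)
            else:
                ash = _shadow_pixels(apoints, basis, pixel_mm)
                frac_by_target = []
                for pts in tpoints:
                    tsh = _shadow_pixels(pts, basis, pixel_mm)
                    inter = np.intersect1d(tsh, ash, assume_unique=True)
                    frac_by_target.append(len(inter) / len(tsh))
            for vi, frac in enumerate(frac_by_target):
                values[vi][ci, gi] = frac
                if use_symmetry:
                    values[vi][ci, gi + gcount] = frac

    return [OverlapMap(couch_deg=couch, gantry_deg=gantry, values=v,
                       meta={"target": t.name, "resolution_deg": resolution_deg,
                             "pixel_mm": pixel_mm, "projection": "parallel"})
            for t, v in zip(targets, values)]


def compute_overlap_map(target: Structure, avoidance: Structure,
                        resolution_deg: float = DEFAULT_RESOLUTION_DEG,
                        pixel_mm: float = DEFAULT_PIXEL_MM) -> OverlapMap:
    """Fractional target-shadow overlap with the avoidance structure per angle."""
    return compute_overlap_maps([target], avoidance, resolution_deg, pixel_mm)[0]


def per_oar_maps(target: Structure, oars: list[Structure],
                 resolution_deg: float = DEFAULT_RESOLUTION_DEG,
                 pixel_mm: float = DEFAULT_PIXEL_MM) -> list[OverlapMap]:
    """One overlap map per individual OAR (instead of the merged structure).

    The merged-structure map dominates each per-OAR map pointwise, because
    the union shadow contains every member shadow.
    """
    return [compute_overlap_map(target, oar, resolution_deg, pixel_mm)
            for oar in oars]


def count_per_oar_maps(n_targets: int, n_oars: int) -> int:
    """Number of maps the per-OAR scheduler would compute (targets x OARs)."""
    if n_targets < 0 or n_oars < 0:
        raise ValidationError("counts must be non-negative")
    return n_targets * n_oars


def apply_collision_mask(omap: OverlapMap, spec) -> OverlapMap:
    """Flag mechanically infeasible couch/gantry bins.

    ``spec`` is either a boolean array of the map's shape or a list of
    rectangles ``{"couch": [lo, hi), "gantry": [lo, hi)}`` in degrees
    (gantry intervals may wrap past 360). Flagged bins keep their overlap
    values; the flag marks them infeasible for the arc solver.
    """
    mask = omap.collision.copy()
    if isinstance(spec, np.ndarray) or (
            isinstance(spec, list) and spec and isinstance(spec[0], (list, np.ndarray))):
        arr = np.asarray(spec, bool)
        if arr.shape != omap.shape:
            raise ValidationError(
                f"collision grid shape {arr.shape} != map shape {omap.shape}")
        mask |= arr
    else:
        for rect in spec:
            clo, chi = rect["couch"]
            glo, ghi = rect["gantry"]
            csel = (omap.couch_deg >= clo) & (omap.couch_deg < chi)
            g = omap.gantry_deg % 360.0
            glo, ghi = glo % 360.0, ghi if ghi == 360.0 else ghi % 360.0
            if glo < ghi:
                gsel = (g >= glo) & (g < ghi)
            else:  # wrapped interval
                gsel = (g >= glo) | (g < ghi)
            mask |= csel[:, None] & gsel[None, :]
    return replace(omap, values=omap.values.copy(), collision=mask,
                   meta=dict(omap.meta))


def raycast_overlap_oracle(target: Structure, avoidance: Structure,
                           couch_deg: float, gantry_deg: float,
                           pixel_mm: float = DEFAULT_PIXEL_MM) -> float:
    """Slow independent overlap estimate by per-voxel line-of-sight binning.

    Casts the beam direction through every voxel center and bins the rays on
    a fixed transverse lattice; overlap is the fraction of target-occupied
    ray bins also occupied by avoidance voxels. Used as a cross-check for
    :func:`compute_overlap_map`, not by it.
    """
    axis = beam_axis(couch_deg, gantry_deg)
    axis = axis / np.linalg.norm(axis)
    for comp in axis:
        if abs(comp) > 1e-12:
            if comp < 0:
                axis = -axis
            break
    ref = np.array([0.0, 0.0, 1.0])
    if abs(axis @ ref) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    u = np.cross(axis, ref)
    u /= np.linalg.norm(u)
    v = np.cross(axis, u)

    def bins(struct: Structure) -> set[tuple[int, int]]:
        pts = struct.grid.points_mm(struct.voxelize())
        out = set()
        for p in pts:
            out.add((int(np.floor((p @ u) / pixel_mm)),
                     int(np.floor((p @ v) / pixel_mm))))
        return out

    tbins = bins(target)
    if not tbins:
        raise ComputationError("target has an empty shadow")
    abins = bins(avoidance)
    return len(tbins & abins) / len(tbins)
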