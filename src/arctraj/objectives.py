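"""Distance-based VMAT optimization-objective generation.

Objectives are emitted as data for a downstream VMAT optimizer; no
optimizer is called here. The central rule converts the minimum PTV-OAR
distance d (mm) into an upper dose objective at 0% volume:

    objective(d) = Rx * (1 - 0.10 * d)   for d < 10 mm
    objective(d) = 150 cGy               for d >= 10 mm

i.e. the prescription minus 10% of the prescription per millimetre of
separation, modelling achievable dose falloff near the target; OARs beyond
10 mm get a low flat floor instead of a distance-derived value. An OAR
closer than 10 mm is "proximity constrained". The rule is applied verbatim
even in the narrow band where it undercuts the 150 cGy floor (d between
8.5 and 10 mm); such records are flagged in the log rather than blended.

The full objective set for a case additionally contains: a PTV lower
objective (>= 99% volume at Rx) and upper objective (0% volume at 115% of
Rx, the hotspot cap), and a tuning-ring upper objective at one third of Rx
(800 cGy at Rx = 2400) on a shell of inner diameter 1 cm / outer diameter
3 cm around the target. Serial OARs with tight tolerances (brainstem,
chiasm, optic nerves) are evaluated through their 2 mm planning-risk-volume
expansions.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .anatomy import (Sphere, Structure, StructureSet, ValidationError,
                      expand_prv, min_distance)

logger = logging.getLogger("arctraj")

GRADIENT_PER_MM = 0.10          # fraction of Rx lost per mm of separation
PROXIMITY_THRESHOLD_MM = 10.0   # OARs closer than this are proximity constrained
FAR_OAR_FLOOR_CGY = 150.0
PTV_COVERAGE_PCT = 99.0
HOTSPOT_FACTOR = 1.15
RING_INNER_DIAMETER_MM = 10.0
RING_OUTER_DIAMETER_MM = 30.0
PRV_MARGIN_MM = 2.0
PRV_OARS = ("brainstem", "chiasm", "optic_nerve_r", "optic_nerve_l")


def upper_dose_objective(d_min_mm: float, rx_cgy: float) -> float:
    """Upper dose objective (cGy) for an OAR at minimum distance d from the PTV.

    Rounded to the nearest cGy. The worked reference point: d = 1.7 mm at
    Rx = 2400 cGy gives 83% of Rx = 1992 cGy.
    """
    if d_min_mm < 0:
        raise ValidationError(f"distance must be >= 0, got {d_min_mm}")
    if rx_cgy <= 0:
        raise ValidationError(f"prescription must be > 0, got {rx_cgy}")
    if d_min_mm < PROXIMITY_THRESHOLD_MM:
        value = rx_cgy * (1.0 - GRADIENT_PER_MM * d_min_mm)
        if value < FAR_OAR_FLOOR_CGY:
            logger.warning(
                "distance rule yields %.0f cGy at d=%.2f mm, below the far-OAR "
                "floor of %.0f cGy; applying the rule verbatim",
                value, d_min_mm, FAR_OAR_FLOOR_CGY)
        return float(round(value))
    return FAR_OAR_FLOOR_CGY


@dataclass(frozen=True)
class ObjectiveRecord:
    structure: str
    bound: str           # "upper" | "lower"
    volume_pct: float    # percent of the structure's volume
    dose_cgy: float
    rule: str            # provenance tag: "distance", "floor", "ptv", "ring"


@dataclass(frozen=True)
class ProximityEntry:
    oar: str
    min_distance_mm: float
    proximity_constrained: bool


@dataclass
class ObjectiveSet:
    """Per-structure dose objectives plus the PTV-OAR proximity table."""

    prescription_cgy: float
    records: list[ObjectiveRecord] = field(default_factory=list)
    proximity: list[ProximityEntry] = field(default_factory=list)

    def record_for(self, structure: str, bound: str = "upper") -> ObjectiveRecord:
        for r in self.records:
            if r.structure == structure and r.bound == bound:
                return r
        raise KeyError(f"no {bound} objective for {structure!r}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(r) for r in self.records])

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {"prescription_cgy": self.prescription_cgy,
               "records": [asdict(r) for r in self.records],
               "proximity": [asdict(p) for p in self.proximity]}
        text = json.dumps(doc, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def build_ring(target: Structure, name: str = "ring") -> Structure:
    """Tuning-ring shell around the target: inner d 1 cm, outer d 3 cm.

    For a spherical target the shell is centered on the sphere center with
    the target volume subtracted. For non-spherical targets it falls back to
    a Euclidean-distance shell measured from the target surface, between the
    same inner and outer radii.
    """
    grid = target.grid
    xs, aps, sis = grid.axes_mm()
    if isinstance(target.primitive, Sphere):
        c = target.primitive.center
        r2 = ((xs[:, None, None] - c[0]) ** 2 + (aps[None, :, None] - c[1]) ** 2
              + (sis[None, None, :] - c[2]) ** 2)
        shell = (r2 <= (RING_OUTER_DIAMETER_MM / 2) ** 2) \
            & (r2 > (RING_INNER_DIAMETER_MM / 2) ** 2)
    else:
        logger.info("non-spherical target %r: tuning ring built as a "
                    "distance shell from the target surface", target.name)
        from scipy import ndimage
        dist = ndimage.distance_transform_edt(~target.voxelize(),
                                              sampling=grid.spacing)
        shell = (dist > RING_INNER_DIAMETER_MM / 2) \
            & (dist <= RING_OUTER_DIAMETER_MM / 2)
    shell &= ~target.voxelize()
    return Structure(name=name, role="ring", grid=grid, mask=shell)


def ring_objective_cgy(rx_cgy: float) -> float:
    """Tuning-ring upper objective: one third of the prescription, to the cGy."""
    if rx_cgy <= 0:
        raise ValidationError("prescription must be > 0")
    return float(round(rx_cgy / 3.0))


def build_objective_set(sset: StructureSet, rx_cgy: float,
                        target_name: str = "PTV") -> ObjectiveSet:
    """Full objective set for one case from geometry alone.

    Serial OARs (brainstem, chiasm, optic nerves) are measured through their
    2 mm PRV expansions (expanded here if not already present in the set);
    eyes and lenses are measured directly. Every OAR gets exactly one upper
    objective at 0% volume from the distance rule or the far-OAR floor.
    """
    if target_name not in sset:
        raise ValidationError(f"no target structure {target_name!r} in the set")
    target = sset[target_name]

    oset = ObjectiveSet(prescription_cgy=rx_cgy)
    for name in sset.names("oar"):
        if name in PRV_OARS:
            prv_name = f"{name}_prv"
            subject = sset[prv_name] if prv_name in sset \
                else expand_prv(sset[name], PRV_MARGIN_MM)
        else:
            subject = sset[name]
        d = min_distance(target, subject)
        dose = upper_dose_objective(d, rx_cgy)
        rule = "distance" if d < PROXIMITY_THRESHOLD_MM else "floor"
        oset.records.append(ObjectiveRecord(
            structure=subject.name, bound="upper", volume_pct=0.0,
            dose_cgy=dose, rule=rule))
        oset.proximity.append(ProximityEntry(
            oar=name, min_distance_mm=d,
            proximity_constrained=d < PROXIMITY_THRESHOLD_MM))

    oset.records.append(ObjectiveRecord(
        structure=target_name, bound="lower", volume_pct=PTV_COVERAGE_PCT,
        dose_cgy=float(rx_cgy), rule="ptv"))
    oset.records.append(ObjectiveRecord(
        structure=target_name, bound="upper", volume_pct=0.0,
        dose_cgy=float(round(rx_cgy * HOTSPOT_FACTOR)), rule="ptv"))
    oset.records.append(ObjectiveRecord(
        structure="ring", bound="upper", volume_pct=0.0,
        dose_cgy=ring_objective_cgy(rx_cgy), rule="ring"))
    return oset
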