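"""Plan-quality metrics on 3D dose grids: Paddick CI and GI, V12Gy, Dmax.

Volumes are voxel-counting volumes (voxel centers, no sub-voxel
interpolation): ``V(level)`` is the number of voxels with dose >= level
times the voxel volume. The Paddick conformity index for a target T and
reference isodose level D_ref is

    CI = (V_T,ref / V_T) * (V_T,ref / V_ref)

with V_T,ref the target volume receiving >= D_ref, V_T the target volume and
V_ref the total volume receiving >= D_ref; CI = 1 is perfect conformity. The
gradient index is GI = V(D_ref / 2) / V(D_ref), smaller meaning steeper dose
falloff. V12Gy is the normal-brain volume (target excluded) receiving at
least 12 Gy, a radionecrosis-risk surrogate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .anatomy import (Grid, GridMismatchError, Structure, StructureSet,
                      ValidationError)

logger = logging.getLogger("arctraj")

TECHNIQUES = ("VMATi", "OFIXEDc", "OFIXEDi")

V12GY_LEVEL_CGY = 1200.0


@dataclass
class DoseGrid:
    """A 3D dose distribution in cGy on a regular grid."""

    grid: Grid
    dose: np.ndarray  # cGy

    def __post_init__(self) -> None:
        self.dose = np.asarray(self.dose, dtype=float)
        if self.dose.shape != self.grid.shape:
            raise GridMismatchError(
                f"dose shape {self.dose.shape} != grid shape {self.grid.shape}")
        if not np.all(np.isfinite(self.dose)) or np.any(self.dose < 0):
            raise ValidationError("dose values must be finite and >= 0")

    def volume_at_least(self, level_cgy: float) -> float:
        """Volume (cc) of the isodose region dose >= level."""
        return int((self.dose >= level_cgy).sum()) * self.grid.voxel_volume_cc()


def _check_grid(dose: DoseGrid, s: Structure) -> None:
    if s.grid != dose.grid:
        raise GridMismatchError(
            f"structure {s.name!r} is not co-registered with the dose grid")


def ci_paddick(dose: DoseGrid, target: Structure, ref_dose_cgy: float) -> float:
    """Paddick conformity index at the reference isodose (default: Rx)."""
    if ref_dose_cgy <= 0:
        raise ValidationError("reference dose must be > 0")
    _check_grid(dose, target)
    tmask = target.voxelize()
    if not tmask.any():
        raise ValidationError("target structure is empty")
    hot = dose.dose >= ref_dose_cgy
    v_ref = int(hot.sum())
    if v_ref == 0:
        logger.warning("reference isodose volume is empty; CI defined as 0")
        return 0.0
    v_t = int(tmask.sum())
    v_t_ref = int((hot & tmask).sum())
    return (v_t_ref / v_t) * (v_t_ref / v_ref)


def gi_paddick(dose: DoseGrid, ref_dose_cgy: float) -> float:
    """Paddick gradient index: V(ref/2) / V(ref)."""
    if ref_dose_cgy <= 0:
        raise ValidationError("reference dose must be > 0")
    v_ref = int((dose.dose >= ref_dose_cgy).sum())
    if v_ref == 0:
        raise ValidationError("prescription isodose volume is empty; GI undefined")
    v_half = int((dose.dose >= ref_dose_cgy / 2.0).sum())
    return v_half / v_ref


def v12gy(dose: DoseGrid, brain: Structure, target: Structure) -> float:
    """Normal-brain volume (cc) receiving >= 12 Gy, target excluded."""
    _check_grid(dose, brain)
    _check_grid(dose, target)
    normal = brain.voxelize() & ~target.voxelize()
    n = int((normal & (dose.dose >= V12GY_LEVEL_CGY)).sum())
    return n * dose.grid.voxel_volume_cc()


def dmax(dose: DoseGrid, s: Structure) -> float:
    """Maximum voxel dose (cGy) inside a structure (point max, no volume qualifier)."""
    _check_grid(dose, s)
    m = s.voxelize()
    if not m.any():
        raise ValidationError(f"structure {s.name!r} is empty; Dmax undefined")
    return float(dose.dose[m].max())


@dataclass
class MetricReport:
    """Plan-quality record for one case under one planning technique."""

    case_id: str
    technique: str
    ci: float
    gi: float
    v12gy_cc: float
    dmax_cgy: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.technique not in TECHNIQUES:
            raise ValidationError(
                f"technique must be one of {TECHNIQUES}, got {self.technique!r}")


def evaluate_plan(dose: DoseGrid, sset: StructureSet, target_name: str,
                  case_id: str, technique: str,
                  rx_cgy: float = 2400.0) -> MetricReport:
    """Compute CI, GI, V12Gy and per-OAR Dmax for one plan."""
    target = sset[target_name]
    report = MetricReport(
        case_id=case_id, technique=technique,
        ci=ci_paddick(dose, target, rx_cgy),
        gi=gi_paddick(dose, rx_cgy),
        v12gy_cc=v12gy(dose, sset.brain(), target),
    )
    for name in sset.names("oar"):
        report.dmax_cgy[name] = dmax(dose, sset[name])
    return report


def reports_to_frame(reports: list[MetricReport]) -> pd.DataFrame:
    """MetricReport list -> tidy table (one row per case x technique)."""
    rows = []
    for r in reports:
        row = {"case_id": r.case_id, "technique": r.technique,
               "CI": r.ci, "GI": r.gi, "V12Gy_cc": r.v12gy_cc}
        for name, v in r.dmax_cgy.items():
            row[f"Dmax_{name}_cGy"] = v
        rows.append(row)
    return pd.DataFrame(rows)
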