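"""End-to-end workflow orchestration with reproducible seeds and manifests.

Stages: cranial phantom -> merged avoidance structure -> systematic target
grid -> per-target overlap maps -> six class templates -> OFIXED class
trajectories (OFIXEDc inputs) -> 18-case synthetic suite -> patient-specific
overlap maps and OFIXED trajectories (OFIXEDi) -> objective sets. Every
output is written under one directory with a MANIFEST.json listing file
checksums, the seed, and a config hash, so a rerun with the same config is
byte-identical and verifiable.

The standard four-arc cranial template (full coplanar arc, partial vertex
arc, and two partial arcs at couch +/-45 deg) serves as the VMATi baseline
geometry. Its exact partial-arc spans are an institutional convention, so
they ship as editable defaults (see ``STANDARD_ARC_TEMPLATE``) and can be
overridden with a geometry file rather than being treated as ground truth.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .anatomy import ValidationError, class_name, merge_oars
from .bev import apply_collision_mask, compute_overlap_map
from .objectives import ObjectiveSet, build_objective_set
from .ofixed import Arc, ArcConstraints, ArcSolution, solve
from .synthdata import (CaseSuite, PhantomConfig, build_phantom,
                        case_structure_set, case_target, make_case_suite)
from .templates import build_class_templates

logger = logging.getLogger("arctraj")

TECHNIQUES = ("VMATi", "OFIXEDc", "OFIXEDi")

#: Editable defaults for the standard four-arc cranial template: a full
#: coplanar arc, a partial vertex arc at couch 90, and two partial arcs
#: with the couch offset 45 deg to each side.
STANDARD_ARC_TEMPLATE = [
    {"couch_deg": 0.0, "gantry_start_deg": 0.0, "span_deg": 360.0},
    {"couch_deg": -90.0, "gantry_start_deg": 30.0, "span_deg": 120.0},
    {"couch_deg": -45.0, "gantry_start_deg": 0.0, "span_deg": 180.0},
    {"couch_deg": 45.0, "gantry_start_deg": 180.0, "span_deg": 180.0},
]


@dataclass
class RunConfig:
    """Configuration for a full template + case workflow run."""

    out_dir: str = "arctraj_run"
    resolution_deg: float = 5.0
    pixel_mm: float = 1.0
    target_diameter_mm: float = 20.0
    target_spacing_mm: float = 20.0
    max_arcs: int = 4
    min_span_deg: float = 30.0
    rx_cgy: float = 2400.0
    seed: int = 0
    phantom_spacing_mm: float = 2.0
    collision_rects: list = field(default_factory=list)
    standard_template_path: str | None = None

    def __post_init__(self) -> None:
        if self.resolution_deg not in (1.0, 2.0, 5.0, 10.0, 1, 2, 5, 10):
            raise ValidationError(
                f"supported angular resolutions are 1, 2, 5, 10 deg, "
                f"got {self.resolution_deg}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**doc)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    def constraints(self) -> ArcConstraints:
        return ArcConstraints(max_arcs=self.max_arcs, min_span_deg=self.min_span_deg)

    def phantom_config(self) -> PhantomConfig:
        return PhantomConfig(spacing_mm=self.phantom_spacing_mm, seed=self.seed)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


def standard_arc_template(cfg: RunConfig) -> ArcSolution:
    """The VMATi baseline geometry (fixed; identical for every case)."""
    arcs = STANDARD_ARC_TEMPLATE
    if cfg.standard_template_path:
        arcs = yaml.safe_load(Path(cfg.standard_template_path).read_text())
    return ArcSolution(arcs=[Arc(**a) for a in arcs], total_cost=None,
                       resolution_deg=float(cfg.resolution_deg))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_template_workflow(cfg: RunConfig) -> dict:
    """Build six class templates and their OFIXED trajectories; write manifest.

    Outputs under ``cfg.out_dir``: one template CSV and collision CSV per
    class, one trajectory JSON per class, the case-suite CSV, and
    MANIFEST.json with per-file checksums.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    logger.info("stage=phantom seed=%d config=%s", cfg.seed, cfg.config_hash())
    phantom = build_phantom(cfg.phantom_config())

    logger.info("stage=templates resolution=%g deg", cfg.resolution_deg)
    templates = build_class_templates(
        phantom, diameter_mm=cfg.target_diameter_mm,
        spacing_mm=cfg.target_spacing_mm,
        resolution_deg=float(cfg.resolution_deg), pixel_mm=cfg.pixel_mm)

    files: dict[str, str] = {}
    constraints = cfg.constraints()
    for cid, tpl in sorted(templates.items()):
        omap = tpl.template
        if cfg.collision_rects:
            omap = apply_collision_mask(omap, cfg.collision_rects)
        stem = f"class{cid}_{class_name(cid)}"
        map_path = out / f"{stem}.csv"
        col_path = out / f"{stem}_collision.csv"
        omap.save_csv(map_path, col_path)
        traj = solve(omap, constraints)
        traj_path = out / f"{stem}_trajectory.json"
        traj.to_json(traj_path)
        for p in (map_path, col_path, traj_path):
            files[p.name] = _sha256(p)

    manifest = {"stage": "templates", "seed": cfg.seed,
                "config_hash": cfg.config_hash(),
                "n_templates": len(templates),
                "contributing": {cid: templates[cid].contributing
                                 for cid in sorted(templates)},
                "files": files}
    logger.info("stage=templates done elapsed=%.1fs", time.time() - t0)
    (out / "MANIFEST.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def run_case_workflow(cfg: RunConfig, case_id: str, technique: str,
                      phantom=None, suite: CaseSuite | None = None,
                      templates_dir: str | Path | None = None
                      ) -> tuple[ArcSolution, ObjectiveSet]:
    """Trajectory + objective set for one synthetic case and technique.

    VMATi returns the fixed standard arc template; OFIXEDc returns the
    class-solution trajectory of the case's cranial class (requires a prior
    template run); OFIXEDi solves on the case's own overlap map. The
    objective set depends only on geometry, so it is identical across the
    three techniques for a given case.
    """
    if technique not in TECHNIQUES:
        raise ValidationError(f"unknown technique {technique!r}; "
                              f"choose from {TECHNIQUES}")
    phantom = phantom if phantom is not None else build_phantom(cfg.phantom_config())
    suite = suite or make_case_suite(phantom, seed=cfg.seed)
    matches = [c for c in suite if c.case_id == case_id]
    if not matches:
        raise ValidationError(f"no case {case_id!r} in the suite")
    case = matches[0]

    if technique == "VMATi":
        traj = standard_arc_template(cfg)
    elif technique == "OFIXEDc":
        tdir = Path(templates_dir or cfg.out_dir)
        stem = f"class{case.class_id}_{class_name(case.class_id)}"
        path = tdir / f"{stem}_trajectory.json"
        if not path.exists():
            raise ValidationError(
                f"class template trajectory {path} not found; run the "
                "template workflow first")
        traj = ArcSolution.from_json(path)
    else:  # OFIXEDi
        avoidance = merge_oars(phantom, phantom.names("oar"))
        omap = compute_overlap_map(case_target(phantom, case), avoidance,
                                   resolution_deg=float(cfg.resolution_deg),
                                   pixel_mm=cfg.pixel_mm)
        if cfg.collision_rects:
            omap = apply_collision_mask(omap, cfg.collision_rects)
        traj = solve(omap, cfg.constraints())

    sset = case_structure_set(phantom, case)
    objectives = build_objective_set(sset, cfg.rx_cgy)
    return traj, objectives


def run(cfg: RunConfig) -> dict:
    """Full reproducible workflow: templates + 18-case OFIXEDi trajectories.

    Deterministic for a fixed config and seed: rerunning yields
    byte-identical files and checksums.
    """
    out = Path(cfg.out_dir)
    manifest = run_template_workflow(cfg)
    files = manifest["files"]

    phantom = build_phantom(cfg.phantom_config())
    suite = make_case_suite(phantom, seed=cfg.seed)
    suite_path = out / "cases.csv"
    suite.to_csv(suite_path)
    files[suite_path.name] = _sha256(suite_path)

    avoidance = merge_oars(phantom, phantom.names("oar"))
    constraints = cfg.constraints()
    for case in suite:
        logger.info("stage=case case=%s", case.case_id)
        omap = compute_overlap_map(case_target(phantom, case), avoidance,
                                   resolution_deg=float(cfg.resolution_deg),
                                   pixel_mm=cfg.pixel_mm)
        if cfg.collision_rects:
            omap = apply_collision_mask(omap, cfg.collision_rects)
        traj = solve(omap, constraints)
        tpath = out / f"ofixedi_{case.case_id}_trajectory.json"
        traj.to_json(tpath)
        files[tpath.name] = _sha256(tpath)

        sset = case_structure_set(phantom, case)
        oset = build_objective_set(sset, cfg.rx_cgy)
        opath = out / f"objectives_{case.case_id}.json"
        oset.to_json(opath)
        files[opath.name] = _sha256(opath)

    manifest["stage"] = "full"
    manifest["n_cases"] = len(suite)
    (out / "MANIFEST.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
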