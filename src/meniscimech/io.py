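"""Configuration schema, loaders and output writers.

A single structured config file (YAML or JSON) drives a full reproduction
run: geometry, materials, solver and experiment blocks, validated against a
pydantic schema that rejects unknown keys.  Outputs are CSV tables and JSON
reports written at a fixed precision (6 significant digits) with a hash
manifest for reproducible diffs.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Tuple

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from . import geometry as _geometry
from .experiments import ExperimentPlan
from .materials import (
    AttachmentMaterial,
    CartilageMaterial,
    LigamentMaterial,
    MeniscusMaterial,
    _LIGAMENT_TABLE,
)
from .solver import JointMaterials, SolverConfig

__all__ = [
    "ConfigError",
    "RunConfig",
    "load_config",
    "save_config",
    "default_config",
    "config_hash",
    "build_geometry",
    "build_materials",
    "build_solver_config",
    "build_plan",
    "write_outputs",
    "SCHEMA_VERSION",
]

SCHEMA_VERSION = 1


class ConfigError(ValueError):
    """Invalid run configuration."""


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class LigamentBlock(_Strict):
    C1: float = Field(gt=0)
    D1: float = Field(gt=0)
    C3: float = Field(ge=0)
    C4: float = Field(gt=0)
    C5: float = Field(gt=0)
    lambda_star: float = Field(gt=1)


class MeniscusBlock(_Strict):
    E_theta: float = Field(default=120.0, gt=0)
    E_z: float = Field(default=20.0, gt=0)
    E_r: float = Field(default=20.0, gt=0)
    nu_rz: float = 0.2
    nu_rtheta: float = 0.3
    nu_ztheta: float = 0.3
    G_rz: float = Field(default=8.33, gt=0)
    G_rtheta: float = Field(default=57.7, gt=0)
    G_ztheta: float = Field(default=57.7, gt=0)
    theta_ratio_convention: str = "major"


class CartilageBlock(_Strict):
    E: float = Field(default=10.0, gt=0)
    nu: float = Field(default=0.45, ge=0.0, lt=0.5)


class AttachmentBlock(_Strict):
    lateral_anterior: float = Field(default=161.0, gt=0)
    lateral_posterior: float = Field(default=96.3, gt=0)
    medial_anterior: float = Field(default=179.0, gt=0)
    medial_posterior: float = Field(default=85.3, gt=0)
    area: float = Field(default=30.0, gt=0)
    length: float = Field(default=12.0, gt=0)


class MaterialsBlock(_Strict):
    ligaments: Dict[str, LigamentBlock] = Field(
        default_factory=lambda: {
            name: LigamentBlock(
                C1=p[0], D1=p[1], C3=p[2], C4=p[3], C5=p[4], lambda_star=p[5]
            )
            for name, p in _LIGAMENT_TABLE.items()
        }
    )
    meniscus: MeniscusBlock = Field(default_factory=MeniscusBlock)
    cartilage: CartilageBlock = Field(default_factory=CartilageBlock)
    attachments: AttachmentBlock = Field(default_factory=AttachmentBlock)


class LigamentLineBlock(_Strict):
    femur_x: float
    femur_y: float
    tibia_x: float
    tibia_y: float
    area: float = Field(gt=0)


def _default_lig_lines() -> Dict[str, "LigamentLineBlock"]:
    return {
        name: LigamentLineBlock(
            femur_x=v[0], femur_y=v[1], tibia_x=v[2], tibia_y=v[3], area=v[4]
        )
        for name, v in _geometry.DEFAULT_GEOMETRY_CONFIG["ligaments"].items()
    }


class GeometryBlock(_Strict):
    h_lateral: float = Field(default=4.6, gt=0)
    h_medial: float = Field(default=4.2, gt=0)
    beta_target_lateral: float = Field(default=32.7, gt=0, lt=90)
    beta_target_medial: float = Field(default=23.9, gt=0, lt=90)
    inner_height: float = Field(default=0.0, ge=0)
    n_sections: int = Field(default=7, ge=3)
    condyle_radius: float = Field(default=20.0, gt=0)
    plateau_curvature_medial: float = -0.049
    plateau_curvature_lateral: float = 0.04
    plateau_apex_offset_medial: float = 0.0
    plateau_apex_offset_lateral: float = -3.0
    compartment_halfwidth: float = Field(default=16.0, gt=0)
    cartilage_thickness: float = Field(default=4.25, gt=0)
    intercompartment_distance: float = Field(default=44.0, gt=0)
    depth_medial: float = Field(default=12.0, gt=0)
    depth_lateral: float = Field(default=26.0, gt=0)
    cc_depth_medial: float = Field(default=40.0, gt=0)
    cc_depth_lateral: float = Field(default=40.0, gt=0)
    cc_inner_extent: float = Field(default=6.0, gt=0)
    wedge_clearance: float = Field(default=0.02, ge=0)
    symmetric: bool = False
    ligaments: Dict[str, LigamentLineBlock] = Field(
        default_factory=_default_lig_lines
    )


class SolverBlock(_Strict):
    station_spacing: float = Field(default=0.4, gt=0)
    stabilization_factor: float = Field(default=0.1, ge=0)
    smoothing_scale: float = Field(default=0.1, gt=0)
    tol_rel: float = Field(default=1e-8, gt=0)
    tol_abs: float = Field(default=1e-9, gt=0)
    max_iterations: int = Field(default=80, ge=1)
    prestretch: float = Field(default=1.05, gt=0)
    hoop_ring_radius: float = Field(default=32.0, gt=0)
    hoop_arc_length: float = Field(default=30.0, gt=0)
    horn_radial_fraction: float = Field(default=0.5, gt=0, le=1)


class ExperimentBlock(_Strict):
    variants: List[str] = Field(
        default_factory=lambda: list(_geometry.VARIANT_DELTAS)
    )
    modes: List[str] = Field(default_factory=lambda: ["free", "cml"])
    loads: List[float] = Field(default_factory=lambda: [1000.0])
    n_increments: int = Field(default=10, ge=1)
    seed: int = 0


class RunConfig(_Strict):
    """Validated top-level configuration of a reproduction run."""

    schema_version: int = SCHEMA_VERSION
    geometry: GeometryBlock = Field(default_factory=GeometryBlock)
    materials: MaterialsBlock = Field(default_factory=MaterialsBlock)
    solver: SolverBlock = Field(default_factory=SolverBlock)
    experiment: ExperimentBlock = Field(default_factory=ExperimentBlock)


def default_config() -> RunConfig:
    return RunConfig()


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML/JSON run configuration."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    text = path.read_text()
    data = (
        json.loads(text) if path.suffix.lower() == ".json"
        else yaml.safe_load(text)
    )
    if data is None:
        data = {}
    try:
        cfg = RunConfig.model_validate(data)
    except ValidationError as err:
        first = err.errors()[0]
        loc = ".".join(str(p) for p in first["loc"])
        raise ConfigError(
            f"invalid config {path}: {loc}: {first['msg']}"
        ) from err
    if cfg.schema_version != SCHEMA_VERSION:
        raise ConfigError(
            f"unsupported schema_version {cfg.schema_version} "
            f"(expected {SCHEMA_VERSION})"
        )
    return cfg


def save_config(cfg: RunConfig, path: str | Path) -> None:
    path = Path(path)
    data = cfg.model_dump()
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2, sort_keys=True))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=True))


def config_hash(cfg: RunConfig) -> str:
    """Deterministic hash of the full validated configuration."""
    payload = json.dumps(cfg.model_dump(), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# domain object construction
# ---------------------------------------------------------------------------

def build_geometry(cfg: RunConfig) -> _geometry.JointGeometry:
    g = cfg.geometry
    raw = g.model_dump()
    raw["ligaments"] = {
        name: (l.femur_x, l.femur_y, l.tibia_x, l.tibia_y, l.area)
        for name, l in g.ligaments.items()
    }
    try:
        return _geometry.make_intact_joint(raw)
    except _geometry.GeometryError as err:
        raise ConfigError(str(err)) from err


def build_materials(cfg: RunConfig) -> JointMaterials:
    m = cfg.materials
    ligaments = {
        name: LigamentMaterial(name=name, **blk.model_dump())
        for name, blk in m.ligaments.items()
    }
    horns = m.attachments.model_dump()
    area = horns.pop("area")
    length = horns.pop("length")
    return JointMaterials(
        ligaments=ligaments,
        meniscus=MeniscusMaterial(**m.meniscus.model_dump()),
        cartilage=CartilageMaterial(**m.cartilage.model_dump()),
        attachments=AttachmentMaterial(
            E_per_horn=horns, area=area, length=length
        ),
    )


def build_solver_config(cfg: RunConfig) -> SolverConfig:
    return SolverConfig(**cfg.solver.model_dump())


def build_plan(cfg: RunConfig) -> ExperimentPlan:
    e = cfg.experiment
    return ExperimentPlan(
        variants=tuple(e.variants),
        modes=tuple(e.modes),
        loads=tuple(e.loads),
        n_increments=e.n_increments,
        seed=e.seed,
    )


# ---------------------------------------------------------------------------
# output writers
# ---------------------------------------------------------------------------

def _format_table(table: pd.DataFrame) -> pd.DataFrame:
    """Render numerics at 6 significant digits for reproducible diffs."""
    out = table.copy()
    for col in out.columns:
        if pd.api.types.is_float_dtype(out[col]):
            out[col] = out[col].map(
                lambda v: f"{v:.6g}" if pd.notna(v) else ""
            )
    return out


def write_outputs(
    table: pd.DataFrame,
    out_dir: str | Path,
    trend: Optional[Mapping[str, object]] = None,
    sweeps: Optional[Mapping[str, pd.DataFrame]] = None,
    provenance: Optional[Mapping[str, object]] = None,
) -> Dict[str, str]:
    """Write the outcome table (and reports) to a directory.

    Returns a manifest mapping file names to content hashes; the manifest
    itself is stored as ``manifest.json``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: Dict[str, str] = {}

    def _put(name: str, text: str) -> None:
        p = out_dir / name
        p.write_text(text)
        written[name] = hashlib.sha256(text.encode()).hexdigest()[:16]

    _put("outcome_table.csv", _format_table(table).to_csv(index=False))
    if trend is not None:
        _put("trend_report.json", json.dumps(trend, indent=2, sort_keys=True))
    for name, df in (sweeps or {}).items():
        _put(f"sweep_{name}.csv", _format_table(df).to_csv(index=False))
    if provenance is not None:
        _put(
            "provenance.json",
            json.dumps(dict(provenance), indent=2, sort_keys=True),
        )
    _put("manifest.json", json.dumps(written, indent=2, sort_keys=True))
    return written
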