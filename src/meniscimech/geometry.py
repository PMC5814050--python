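"""Parametric two-compartment coronal knee cross-section geometry.

This is the synthetic stand-in for patient imaging: each compartment is a
circular femoral condyle over a tibial plateau profile, with a wedge-shaped
meniscus at the periphery.  The medial compartment is conforming (concave
plateau), the lateral compartment convex-on-convex.  The wedge peripheral
height ``h`` and radial width define the slope angle ``beta`` of the
femoral-facing face; heights can be perturbed per side to build the nine
model variants of the height-change study.

Coordinate convention: x is medio-lateral (positive toward medial), y is the
proximal axial direction, origin at the joint centre between the compartments
at the level of the condyle centres.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, replace, asdict
from typing import Dict, List, Mapping, Tuple

import numpy as np

__all__ = [
    "GeometryError",
    "MeniscusGeometry",
    "CompartmentGeometry",
    "LigamentElement",
    "JointGeometry",
    "make_intact_joint",
    "apply_height_change",
    "slope_angle",
    "variant_suite",
    "mirror_joint",
    "VARIANT_DELTAS",
    "DEFAULT_GEOMETRY_CONFIG",
]


class GeometryError(ValueError):
    """Inconsistent or degenerate geometry configuration."""


@dataclass(frozen=True)
class MeniscusGeometry:
    """Wedge meniscus cross-section sampled at ``n_sections`` stations.

    ``h`` is the peripheral height [mm], ``inner_height`` the height at the
    inner rim, ``radial_width`` the wedge base width [mm].  A per-section
    profile (multipliers on h - inner_height) supports non-uniform crescents;
    the default is a uniform wedge.
    """

    h: float
    radial_width: float
    side: str
    inner_height: float = 0.0
    n_sections: int = 7
    section_height_factors: Tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.side not in ("medial", "lateral"):
            raise GeometryError(f"unknown meniscus side {self.side!r}")
        if self.radial_width <= 0:
            raise GeometryError("meniscus radial_width must be positive")
        if not (self.h > self.inner_height >= 0):
            raise GeometryError(
                f"need h > inner_height >= 0, got h={self.h}, "
                f"inner_height={self.inner_height}"
            )
        if self.n_sections < 3:
            raise GeometryError("n_sections must be at least 3")
        if self.section_height_factors:
            if len(self.section_height_factors) != self.n_sections:
                raise GeometryError(
                    "section_height_factors length must equal n_sections"
                )
            if min(self.section_height_factors) <= 0:
                raise GeometryError("section height factors must be positive")

    @property
    def factors(self) -> np.ndarray:
        if self.section_height_factors:
            return np.asarray(self.section_height_factors, dtype=float)
        return np.ones(self.n_sections)

    @property
    def section_heights(self) -> np.ndarray:
        """Peripheral height per cross-section station [mm]."""
        return self.inner_height + (self.h - self.inner_height) * self.factors

    @property
    def mean_slope_tan(self) -> float:
        return float(np.tan(np.radians(slope_angle(self)).mean()))

    @property
    def cross_section_area(self) -> float:
        """Trapezoidal wedge cross-section area [mm^2]."""
        return 0.5 * (self.h + self.inner_height) * self.radial_width


def slope_angle(men: MeniscusGeometry) -> np.ndarray:
    """Per-section slope angles beta [degrees] of the femoral-facing face.

    beta = atan((height - inner_height) / radial_width); constant for a
    uniform wedge.
    """
    rise = men.section_heights - men.inner_height
    return np.degrees(np.arctan2(rise, men.radial_width))


@dataclass(frozen=True)
class CompartmentGeometry:
    """One tibiofemoral compartment of the coronal cross-section.

    ``plateau_curvature`` [1/mm] is signed: negative = concave (conforming,
    medial-like), zero-to-positive = flat-to-convex (lateral-like).
    ``plateau_apex_offset`` [mm] shifts the plateau profile's apex along the
    local outward axis (negative = toward the joint centre); the lateral
    plateau peaks near the intercondylar eminence, so its apex sits inward.
    ``wedge_inner_offset`` [mm] locates the meniscus inner rim outward of the
    condyle centre; it is calibrated so the wedge face hugs the condyle where
    the surface slopes match.
    """

    condyle_radius: float
    plateau_curvature: float
    plateau_apex_offset: float
    compartment_halfwidth: float
    cartilage_thickness: float
    meniscus: MeniscusGeometry
    wedge_inner_offset: float
    depth: float = 30.0           # meniscus-zone out-of-plane depth [mm]
    cc_depth: float = 32.0        # cartilage-cartilage zone depth [mm]
    cc_inner_extent: float = 6.0  # cartilage-cartilage zone inner reach [mm]
    wedge_clearance: float = 0.02  # reference condyle-wedge standoff [mm]

    def __post_init__(self) -> None:
        if self.condyle_radius <= 0:
            raise GeometryError("condyle_radius must be positive")
        if self.cartilage_thickness <= 0:
            raise GeometryError("cartilage_thickness must be positive")
        if self.compartment_halfwidth <= 0 or self.depth <= 0:
            raise GeometryError("compartment dimensions must be positive")
        outer = self.wedge_inner_offset + self.meniscus.radial_width
        if outer >= 0.98 * self.condyle_radius:
            raise GeometryError(
                "meniscus wedge extends beyond the condyle profile "
                f"(outer offset {outer:.2f} mm vs radius "
                f"{self.condyle_radius:.2f} mm)"
            )


@dataclass(frozen=True)
class LigamentElement:
    """A 1-D ligament line: femur and tibia anchors, area, material name."""

    material: str
    femur_xy: Tuple[float, float]
    tibia_xy: Tuple[float, float]
    area: float

    def __post_init__(self) -> None:
        if self.area <= 0:
            raise GeometryError(f"{self.material}: ligament area must be positive")
        if self.reference_length <= 0:
            raise GeometryError(f"{self.material}: zero-length ligament line")

    @property
    def reference_length(self) -> float:
        dx = self.femur_xy[0] - self.tibia_xy[0]
        dy = self.femur_xy[1] - self.tibia_xy[1]
        return math.hypot(dx, dy)


@dataclass(frozen=True)
class JointGeometry:
    """Two-compartment coronal joint with ligament layout.

    ``femur_lift`` [mm] raises the femur reference position (used for
    raised-meniscus variants to avoid reference interpenetration; ligament
    natural lengths are re-derived at the lifted reference).
    """

    medial: CompartmentGeometry
    lateral: CompartmentGeometry
    intercompartment_distance: float
    ligaments: Tuple[LigamentElement, ...]
    femur_lift: float = 0.0
    height_change_log: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.medial.meniscus.side != "medial":
            raise GeometryError("medial compartment must hold the medial meniscus")
        if self.lateral.meniscus.side != "lateral":
            raise GeometryError("lateral compartment must hold the lateral meniscus")
        if self.intercompartment_distance <= 0:
            raise GeometryError("intercompartment_distance must be positive")
        half = 0.5 * self.intercompartment_distance
        for comp in (self.medial, self.lateral):
            if comp.cc_inner_extent >= half:
                raise GeometryError("compartments overlap at the joint centre")

    def compartment(self, side: str) -> CompartmentGeometry:
        if side == "medial":
            return self.medial
        if side == "lateral":
            return self.lateral
        raise GeometryError(f"unknown side {side!r}")

    def condyle_centre_x(self, side: str) -> float:
        half = 0.5 * self.intercompartment_distance
        return half if side == "medial" else -half

    def content_hash(self) -> str:
        """Deterministic hash of the full geometric description."""
        payload = json.dumps(asdict(self), sort_keys=True, default=float)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------

#: Intact defaults.  The wedge widths are not free: they are calibrated from
#: the intact peripheral heights and the target average slope angles
#: (beta_L = 32.7 deg, beta_M = 23.9 deg), anchoring the synthetic joint to
#: the study's printed geometric observables.
DEFAULT_GEOMETRY_CONFIG: Dict[str, object] = {
    "h_lateral": 4.6,
    "h_medial": 4.2,
    "beta_target_lateral": 32.7,
    "beta_target_medial": 23.9,
    "inner_height": 0.0,
    "n_sections": 7,
    "condyle_radius": 20.0,
    "plateau_curvature_medial": -0.049,  # concave, closely conforming
    "plateau_curvature_lateral": 0.04,   # convex-on-convex
    "plateau_apex_offset_medial": 0.0,
    "plateau_apex_offset_lateral": -3.0,  # apex toward the eminence
    "compartment_halfwidth": 16.0,
    # effective compliant-layer thickness of each articular surface (cartilage
    # plus the adjacent soft-tissue compliance lumped into the foundation)
    "cartilage_thickness": 4.25,
    "intercompartment_distance": 44.0,
    # out-of-plane depths: the menisci cover only part of each compartment's
    # anterior-posterior extent, the lateral one a larger fraction than the
    # medial one, so the wedge zones are shallower than the central
    # cartilage-cartilage zones
    "depth_medial": 12.0,
    "depth_lateral": 26.0,
    "cc_depth_medial": 40.0,
    "cc_depth_lateral": 40.0,
    "cc_inner_extent": 6.0,
    "wedge_clearance": 0.02,
    "symmetric": False,
    "ligaments": {
        # material: (femur_x, femur_y, tibia_x, tibia_y, area_mm2)
        "MCL": (40.0, 45.0, 40.0, -55.0, 25.0),
        "LCL": (-40.0, 40.0, -40.0, -25.0, 15.0),
        "ACL": (0.0, 20.0, 0.0, -15.0, 32.0),
        "PCL": (0.0, 22.0, 0.0, -18.0, 40.0),
    },
}


def _build_compartment(side: str, cfg: Mapping[str, object]) -> CompartmentGeometry:
    h = float(cfg[f"h_{side}"])
    beta = float(cfg[f"beta_target_{side}"])
    if not (0.0 < beta < 90.0):
        raise GeometryError("beta target must lie in (0, 90) degrees")
    inner = float(cfg["inner_height"])
    width = (h - inner) / math.tan(math.radians(beta))
    men = MeniscusGeometry(
        h=h,
        radial_width=width,
        side=side,
        inner_height=inner,
        n_sections=int(cfg["n_sections"]),
    )
    R = float(cfg["condyle_radius"])
    # place the wedge mid-face where the condyle surface slope equals tan(beta)
    dx_mid = R * math.sin(math.radians(beta))
    return CompartmentGeometry(
        condyle_radius=R,
        plateau_curvature=float(cfg[f"plateau_curvature_{side}"]),
        plateau_apex_offset=float(cfg[f"plateau_apex_offset_{side}"]),
        compartment_halfwidth=float(cfg["compartment_halfwidth"]),
        cartilage_thickness=float(cfg["cartilage_thickness"]),
        meniscus=men,
        wedge_inner_offset=dx_mid - 0.5 * width,
        depth=float(cfg[f"depth_{side}"]),
        cc_depth=float(cfg[f"cc_depth_{side}"]),
        cc_inner_extent=float(cfg["cc_inner_extent"]),
        wedge_clearance=float(cfg["wedge_clearance"]),
    )


def make_intact_joint(config: Mapping[str, object] | None = None) -> JointGeometry:
    """Build the intact joint from a geometry config (defaults filled in).

    With ``symmetric=True`` the lateral compartment mirrors the medial one
    exactly (used by symmetry tests); otherwise the medial compartment is
    conforming and the lateral convex-on-convex, with the calibrated intact
    heights h_L = 4.6 mm and h_M = 4.2 mm.
    """
    cfg = dict(DEFAULT_GEOMETRY_CONFIG)
    if config:
        unknown = set(config) - set(cfg)
        if unknown:
            raise GeometryError(f"unknown geometry config keys: {sorted(unknown)}")
        cfg.update(config)
    for key in ("h_lateral", "h_medial", "condyle_radius", "depth_medial",
                "depth_lateral", "cartilage_thickness",
                "intercompartment_distance"):
        if float(cfg[key]) <= 0:
            raise GeometryError(f"geometry config {key} must be positive")
    if cfg["symmetric"]:
        for key in ("h", "beta_target", "plateau_curvature",
                    "plateau_apex_offset", "depth", "cc_depth"):
            cfg[f"{key}_lateral"] = cfg[f"{key}_medial"]
    medial = _build_compartment("medial", cfg)
    lateral = _build_compartment("lateral", cfg)
    ligs = []
    for name, (fx, fy, tx, ty, area) in dict(cfg["ligaments"]).items():
        ligs.append(LigamentElement(name, (fx, fy), (tx, ty), area))
    if cfg["symmetric"]:
        # mirror-identical collateral layout; drop the (already central) cruciates
        ligs = [
            LigamentElement("MCL", (40.0, 45.0), (40.0, -55.0), 25.0),
            LigamentElement("MCL", (-40.0, 45.0), (-40.0, -55.0), 25.0),
            LigamentElement("ACL", (0.0, 20.0), (0.0, -15.0), 32.0),
        ]
    return JointGeometry(
        medial=medial,
        lateral=lateral,
        intercompartment_distance=float(cfg["intercompartment_distance"]),
        ligaments=tuple(ligs),
    )


def apply_height_change(
    geom: JointGeometry, side: str, delta_h: float
) -> JointGeometry:
    """Return a new joint with the peripheral height h := h + delta_h on one side.

    Everything else (wedge width and placement, the other compartment, the
    ligament layout) is unchanged, so the slope angle changes with the height.
    For raised heights the femur reference position is lifted by delta_h to
    avoid reference interpenetration.  The relative-change log records
    delta_h / h_original.
    """
    comp = geom.compartment(side)
    men = comp.meniscus
    new_h = men.h + delta_h
    if new_h <= men.inner_height:
        raise GeometryError(
            f"height change {delta_h:+.2f} mm makes the {side} wedge degenerate"
        )
    if delta_h == 0.0:
        return geom
    new_men = replace(men, h=new_h)
    new_comp = replace(comp, meniscus=new_men)
    rel = 100.0 * delta_h / men.h
    log = geom.height_change_log + (
        f"{side}:{delta_h:+.3f}mm ({rel:+.1f}% of {men.h:.3f}mm)",
    )
    lift = max(geom.femur_lift, delta_h if delta_h > 0 else 0.0)
    kwargs = {side: new_comp}
    return replace(
        geom, femur_lift=lift, height_change_log=log, **kwargs
    )


#: The nine model variants: name -> (side, delta_h [mm]).  The intact lateral
#: height is perturbed by +-1.0 / +-2.0 mm and the medial by +-0.9 / +-1.8 mm.
VARIANT_DELTAS: Dict[str, Tuple[str, float]] = {
    "Intact": ("medial", 0.0),
    "MMH+": ("medial", +0.9),
    "MMH++": ("medial", +1.8),
    "MMH-": ("medial", -0.9),
    "MMH--": ("medial", -1.8),
    "LMH+": ("lateral", +1.0),
    "LMH++": ("lateral", +2.0),
    "LMH-": ("lateral", -1.0),
    "LMH--": ("lateral", -2.0),
}


def variant_suite(geom: JointGeometry) -> List[Tuple[str, JointGeometry]]:
    """The nine named height variants built from an intact joint."""
    out = []
    for name, (side, dh) in VARIANT_DELTAS.items():
        out.append((name, apply_height_change(geom, side, dh)))
    return out


def mirror_joint(geom: JointGeometry) -> JointGeometry:
    """Reflect the joint about the joint centre (x -> -x).

    Compartment contents swap sides; ligament anchors mirror in x.  Used by
    the mirror-antisymmetry invariants (u and F_M-L flip sign).
    """
    new_med = replace(
        geom.lateral, meniscus=replace(geom.lateral.meniscus, side="medial")
    )
    new_lat = replace(
        geom.medial, meniscus=replace(geom.medial.meniscus, side="lateral")
    )
    ligs = tuple(
        replace(
            l,
            femur_xy=(-l.femur_xy[0], l.femur_xy[1]),
            tibia_xy=(-l.tibia_xy[0], l.tibia_xy[1]),
        )
        for l in geom.ligaments
    )
    return replace(geom, medial=new_med, lateral=new_lat, ligaments=ligs)
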