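"""Outcome metrics of a solved joint: extrusion, congruence, kinematics.

The measured quantities mirror the outcome set of the height-change study:

* external shift ``w`` per meniscus - radial outward displacement relative to
  the tibia, loaded minus unloaded state;
* average slope angles ``beta_bar`` per compartment and their difference;
* extrusion forces ``F_M``/``F_L`` - radially outward components of the
  contact resultants acting on each meniscus;
* medio-lateral femur translation ``u`` and the CM-L constraint force;
* the congruence measure ``CM = F / p0`` per compartment (resultant contact
  force over peak contact pressure; equals the contact area for a uniform
  pressure field, smaller for concentrated contact) plus total contact areas.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List

import numpy as np
import pandas as pd

from .geometry import JointGeometry, slope_angle
from .solver import JointSolution, SolverError

__all__ = [
    "CongruenceMetrics",
    "external_shift",
    "average_angle",
    "extrusion_force",
    "congruence",
    "metrics_row",
    "METRICS_COLUMNS",
]

#: Fixed column order of a metrics table: the kinematic/constraint block
#: first, then extrusion and congruence outcomes, then interface details.
METRICS_COLUMNS: List[str] = [
    "model",
    "mode",
    "load",
    "beta_L",
    "beta_M",
    "beta_diff",
    "F_ML",
    "u",
    "w_M",
    "w_L",
    "F_M",
    "F_L",
    "CM_medial",
    "CM_lateral",
    "area_medial",
    "area_lateral",
    "cc_force_medial",
    "cc_force_lateral",
    "cc_area_medial",
    "cc_area_lateral",
    "mt_force_medial",
    "mt_force_lateral",
    "mt_area_medial",
    "mt_area_lateral",
    "converged",
]


def _require_converged(solution: JointSolution) -> None:
    if not solution.converged:
        raise SolverError("metrics require a converged solution")


def external_shift(solution: JointSolution, side: str) -> float:
    """Radial outward shift w [mm] of one meniscus, relative to the tibia.

    Loaded-minus-unloaded displacement of the wedge (the unloaded state is
    the prestretched zero-load equilibrium), positive outward - the extrusion
    direction.
    """
    _require_converged(solution)
    return float(
        solution.kinematics_absolute.w_shift[side]
        - solution.baseline.w_shift[side]
    )


def average_angle(geom: JointGeometry, side: str) -> float:
    """Arithmetic mean of the per-section slope angles beta [degrees]."""
    return float(slope_angle(geom.compartment(side).meniscus).mean())


def extrusion_force(solution: JointSolution, side: str) -> float:
    """Radially outward contact force [N] on one meniscus.

    Sum over sections of the medio-lateral components of the contact
    resultants transmitted by the femoral condyle to the wedge face; for a
    single face under normal force N inclined at beta this reduces to
    N sin(beta).
    """
    _require_converged(solution)
    return solution.contact.extrusion_force(side)


@dataclass(frozen=True)
class CongruenceMetrics:
    """Per-compartment congruence outcome: CM = F / p0."""

    CM: float           # congruence measure [mm^2]
    F: float            # resultant contact force magnitude [N]
    p0: float           # peak contact pressure [MPa]
    total_area: float   # contact area with positive pressure [mm^2]


def congruence(solution: JointSolution, side: str) -> CongruenceMetrics:
    """Congruence measure of one compartment: resultant force / peak pressure.

    Computed over the tibial-side interfaces (cartilage-cartilage and
    meniscus-tibial cartilage).  A compartment without contact (p0 = 0) gets
    CM = 0 with a warning.
    """
    _require_converged(solution)
    F = float(np.linalg.norm(solution.contact.compartment_resultant(side)))
    p0 = solution.contact.compartment_peak_pressure(side)
    area = solution.contact.compartment_area(side)
    if p0 <= 0.0:
        warnings.warn(
            f"no contact in the {side} compartment: CM set to 0", stacklevel=2
        )
        return CongruenceMetrics(CM=0.0, F=F, p0=0.0, total_area=area)
    return CongruenceMetrics(CM=F / p0, F=F, p0=p0, total_area=area)


def metrics_row(
    solution: JointSolution, geom: JointGeometry, model_name: str
) -> Dict[str, object]:
    """One full outcome record of a (variant, mode, load) solve."""
    _require_converged(solution)
    beta_l = average_angle(geom, "lateral")
    beta_m = average_angle(geom, "medial")
    row: Dict[str, object] = {
        "model": model_name,
        "mode": solution.mode,
        "load": solution.load.compressive_force,
        "beta_L": beta_l,
        "beta_M": beta_m,
        "beta_diff": beta_l - beta_m,
        "F_ML": solution.constraint_force,
        "u": solution.kinematics_absolute.u,
        "w_M": external_shift(solution, "medial"),
        "w_L": external_shift(solution, "lateral"),
        "F_M": extrusion_force(solution, "medial"),
        "F_L": extrusion_force(solution, "lateral"),
        "converged": solution.converged,
    }
    for side in ("medial", "lateral"):
        cm = congruence(solution, side)
        row[f"CM_{side}"] = cm.CM
        row[f"area_{side}"] = cm.total_area
        cc = solution.contact.patch(side, "cartilage-cartilage")
        mt = solution.contact.patch(side, "meniscus-tibia")
        row[f"cc_force_{side}"] = cc.total_force
        row[f"cc_area_{side}"] = cc.contact_area
        row[f"mt_force_{side}"] = mt.total_force
        row[f"mt_area_{side}"] = mt.contact_area
    return row


def metrics_table(rows: List[Dict[str, object]]) -> pd.DataFrame:
    """Assemble rows into a DataFrame with the documented column order."""
    return pd.DataFrame(rows, columns=METRICS_COLUMNS)
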