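"""The virtual height-change experiment: nine variants x two modes.

Replays the full study design on the calibrated synthetic joint: the intact
model plus eight meniscus-height variants, each solved under a 1000 N
compressive load with free and with constrained (CM-L) medio-lateral
relative bone motion, collecting the full outcome table and checking the
qualitative findings (trend report).  The pipeline is fully deterministic -
there is no randomness anywhere in the solve path.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .geometry import (
    JointGeometry,
    VARIANT_DELTAS,
    apply_height_change,
    make_intact_joint,
)
from .metrics import METRICS_COLUMNS, metrics_row, metrics_table
from .solver import (
    ConvergenceError,
    JointMaterials,
    LoadCase,
    SolverConfig,
    default_materials,
    solve_equilibrium,
)

__all__ = [
    "ExperimentPlan",
    "REFERENCE_OUTCOMES",
    "run_suite",
    "trend_report",
    "load_sweep",
    "MEDIAL_FAMILY",
    "LATERAL_FAMILY",
]

logger = logging.getLogger(__name__)

#: Variant families ordered by decreasing height change.
MEDIAL_FAMILY = ["MMH--", "MMH-", "Intact", "MMH+", "MMH++"]
LATERAL_FAMILY = ["LMH--", "LMH-", "Intact", "LMH+", "LMH++"]

#: Reference outcome values for the nine variants under the study conditions
#: (average slope angles [deg], their difference [deg], constraint force [N],
#: free-mode medio-lateral translation [mm]).  The intact angles anchor the
#: geometry calibration; the angle columns satisfy the definitional identity
#: beta_L - beta_M = beta_diff at the printed precision.
REFERENCE_OUTCOMES: Dict[str, Dict[str, float]] = {
    "MMH--": {"beta_L": 32.7, "beta_M": 14.5, "beta_diff": 18.2,
              "F_ML": 158.3, "u": 0.899},
    "MMH-": {"beta_L": 32.7, "beta_M": 19.3, "beta_diff": 13.4,
             "F_ML": 124.7, "u": 0.650},
    "Intact": {"beta_L": 32.7, "beta_M": 23.9, "beta_diff": 8.8,
               "F_ML": 79.6, "u": 0.392},
    "MMH+": {"beta_L": 32.7, "beta_M": 28.2, "beta_diff": 4.5,
             "F_ML": 33.4, "u": 0.159},
    "MMH++": {"beta_L": 32.7, "beta_M": 32.1, "beta_diff": 0.6,
              "F_ML": -7.8, "u": -0.060},
    "LMH--": {"beta_L": 21.8, "beta_M": 23.9, "beta_diff": -2.1,
              "F_ML": 1.2, "u": -0.008},
    "LMH-": {"beta_L": 27.9, "beta_M": 23.9, "beta_diff": 4.0,
             "F_ML": 33.7, "u": 0.155},
    "LMH+": {"beta_L": 37.4, "beta_M": 23.9, "beta_diff": 13.5,
             "F_ML": 130.2, "u": 0.752},
    "LMH++": {"beta_L": 40.8, "beta_M": 23.9, "beta_diff": 16.9,
              "F_ML": 132.6, "u": 1.484},
}


@dataclass(frozen=True)
class ExperimentPlan:
    """The suite layout: which variants, modes and loads to run.

    ``seed`` is reserved for interface stability - the pipeline itself is
    deterministic and does not consume it.
    """

    variants: Tuple[str, ...] = tuple(VARIANT_DELTAS)
    modes: Tuple[str, ...] = ("free", "cml")
    loads: Tuple[float, ...] = (1000.0,)
    n_increments: int = 10
    seed: int = 0
    output_dir: Optional[str] = None

    def __post_init__(self) -> None:
        unknown = set(self.variants) - set(VARIANT_DELTAS)
        if unknown:
            raise ValueError(f"unknown variants: {sorted(unknown)}")
        if len(set(self.variants)) != len(self.variants):
            raise ValueError("variant names must be unique")
        bad = set(self.modes) - {"free", "cml"}
        if bad:
            raise ValueError(f"unknown modes: {sorted(bad)}")


def build_variant(
    intact: JointGeometry, name: str
) -> JointGeometry:
    side, dh = VARIANT_DELTAS[name]
    return apply_height_change(intact, side, dh)


def run_suite(
    plan: Optional[ExperimentPlan] = None,
    geom_config: Optional[Mapping[str, object]] = None,
    materials: Optional[JointMaterials] = None,
    solver_config: Optional[SolverConfig] = None,
) -> pd.DataFrame:
    """Solve every (variant, mode, load) combination of the plan.

    Solver failures are isolated per combination: the affected row carries
    ``converged = False`` and NaN outcomes, and the rest of the table is
    still produced.
    """
    plan = plan or ExperimentPlan()
    materials = materials or default_materials()
    intact = make_intact_joint(geom_config)
    rows: List[Dict[str, object]] = []
    for name in plan.variants:
        geom = build_variant(intact, name)
        for mode in plan.modes:
            for load_value in plan.loads:
                load = LoadCase(
                    compressive_force=load_value,
                    n_increments=plan.n_increments,
                    constrain_mediolateral=(mode == "cml"),
                )
                try:
                    sol = solve_equilibrium(
                        geom, materials, load, solver_config
                    )
                    rows.append(metrics_row(sol, geom, name))
                except ConvergenceError as err:
                    logger.warning(
                        "%s/%s at %g N failed: %s", name, mode, load_value, err
                    )
                    row = {c: np.nan for c in METRICS_COLUMNS}
                    row.update(
                        model=name, mode=mode, load=load_value, converged=False
                    )
                    rows.append(row)
    return metrics_table(rows)


def _terminal(table: pd.DataFrame, mode: str) -> pd.DataFrame:
    t = table[table["mode"] == mode]
    return t[t["load"] == t["load"].max()].set_index("model")


def _strictly_decreasing(values: Sequence[float]) -> bool:
    arr = np.asarray(values, dtype=float)
    return bool(np.all(np.diff(arr) < 0))


def trend_report(table: pd.DataFrame) -> Dict[str, object]:
    """Evaluate the study's qualitative findings on a full suite table.

    Checks (all on the terminal load):

    * ``u_ordering`` - free-mode u strictly ordered
      MMH-- > MMH- > Intact > MMH+ > MMH++ and
      LMH++ > LMH+ > Intact > LMH- > LMH--;
    * ``fml_rank_correlation`` - CM-L constraint force F_M-L co-monotone
      (Spearman rho = 1) with the angle difference beta_L - beta_M;
    * ``w_monotone_in_height`` - CM-L external shift of the modified meniscus
      strictly increasing in its height change;
    * ``reduced_height_unloads_meniscus`` - a lower meniscus carries less
      meniscus-cartilage contact force and area in its compartment;
    * ``raised_height_reduces_cc_area`` - a higher meniscus lowers the
      cartilage-cartilage contact area in its compartment;
    * ``extrusion_max_at_raised_height`` - the largest extrusion force of
      each family occurs at the most raised variant (CM-L mode).
    """
    required = set(VARIANT_DELTAS)
    for mode in ("free", "cml"):
        have = set(table.loc[table["mode"] == mode, "model"])
        if not required <= have:
            raise ValueError(
                f"incomplete table: mode {mode!r} misses "
                f"{sorted(required - have)}"
            )
    free = _terminal(table, "free")
    cml = _terminal(table, "cml")
    checks: Dict[str, object] = {}

    checks["u_ordering_medial"] = _strictly_decreasing(
        [free.loc[m, "u"] for m in MEDIAL_FAMILY]
    )
    checks["u_ordering_lateral"] = _strictly_decreasing(
        [free.loc[m, "u"] for m in LATERAL_FAMILY[::-1]]
    )
    rho = spearmanr(cml["F_ML"], cml["beta_diff"]).statistic
    checks["fml_rank_correlation"] = float(rho)
    checks["fml_co_monotone"] = bool(rho >= 1.0 - 1e-12)

    checks["w_monotone_medial"] = _strictly_decreasing(
        [cml.loc[m, "w_M"] for m in MEDIAL_FAMILY[::-1]]
    )
    checks["w_monotone_lateral"] = _strictly_decreasing(
        [cml.loc[m, "w_L"] for m in LATERAL_FAMILY[::-1]]
    )

    checks["reduced_height_unloads_meniscus"] = bool(
        all(
            free.loc[m, f"mt_force_{s}"] < free.loc["Intact", f"mt_force_{s}"]
            and free.loc[m, f"mt_area_{s}"] < free.loc["Intact", f"mt_area_{s}"]
            for s, fam in (("medial", ("MMH-", "MMH--")),
                           ("lateral", ("LMH-", "LMH--")))
            for m in fam
        )
    )
    checks["raised_height_reduces_cc_area"] = bool(
        all(
            free.loc[m, f"cc_area_{s}"] < free.loc["Intact", f"cc_area_{s}"]
            for s, fam in (("medial", ("MMH+", "MMH++")),
                           ("lateral", ("LMH+", "LMH++")))
            for m in fam
        )
    )
    checks["extrusion_max_at_raised_height"] = bool(
        cml.loc[MEDIAL_FAMILY, "F_M"].idxmax() == "MMH++"
        and cml.loc[LATERAL_FAMILY, "F_L"].idxmax() == "LMH++"
    )
    checks["all_pass"] = bool(
        all(
            v for k, v in checks.items()
            if isinstance(v, (bool, np.bool_))
        )
    )
    return checks


def load_sweep(
    variant: str,
    mode: str = "free",
    loads: Sequence[float] = (0.0, 250.0, 500.0, 750.0, 1000.0),
    geom_config: Optional[Mapping[str, object]] = None,
    materials: Optional[JointMaterials] = None,
    solver_config: Optional[SolverConfig] = None,
) -> pd.DataFrame:
    """Extrusion-force curves F_M(load), F_L(load) for one variant.

    Each load level is solved independently; the curves are non-decreasing in
    the compressive force.
    """
    if list(loads) != sorted(loads):
        raise ValueError("loads must be increasing")
    materials = materials or default_materials()
    geom = build_variant(make_intact_joint(geom_config), variant)
    records = []
    for load_value in loads:
        sol = solve_equilibrium(
            geom,
            materials,
            LoadCase(
                compressive_force=load_value,
                constrain_mediolateral=(mode == "cml"),
            ),
            solver_config,
        )
        records.append(
            {
                "load": load_value,
                "F_M": sol.contact.extrusion_force("medial"),
                "F_L": sol.contact.extrusion_force("lateral"),
                "u": sol.kinematics_absolute.u,
            }
        )
    return pd.DataFrame.from_records(records)
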