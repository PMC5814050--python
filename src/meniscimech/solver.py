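"""Static coronal-plane contact equilibrium of the reduced knee joint.

The femur is a rigid body with three planar degrees of freedom (medio-lateral
translation ``u``, axial translation ``u_y``, varus/valgus rotation
``phi_z``); each meniscus has one radial outward shift ``w``.  The tibia is
fixed.  Contact is a frictionless unilateral elastic (Winkler) foundation:
station pressures are proportional to the local surface interpenetration,
with the foundation constant derived from the cartilage (and meniscus)
confined moduli and layer thicknesses.  Ligaments are tension-only 1-D
nonlinear springs using the fiber-reinforced constitutive law; each meniscus
is restrained radially by a hoop-tension ring stiffness plus its horn
attachments.

Equilibrium is found by damped Newton iteration on the analytic gradient of
the total potential energy, with load ramping.  Because the residual is
exactly that gradient, the independent brute-force oracle (derivative-free
minimisation of the same potential) must agree with the Newton solution.

For a station on a face inclined at angle beta, the vertical-gap foundation
transmits a lateral force equal to the vertical force times tan(beta) -
exactly the frictionless wedge decomposition.  This is what drives meniscal
extrusion (outward force on the wedge) and the medio-lateral imbalance
between the two compartments (net lateral force on the femur).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .geometry import JointGeometry, MeniscusGeometry
from .materials import (
    AttachmentMaterial,
    CartilageMaterial,
    LigamentMaterial,
    MeniscusMaterial,
    default_attachments,
    default_cartilage,
    default_ligaments,
    default_meniscus,
    ligament_spring_energy,
    meniscus_confined_axial_modulus,
    uniaxial_cauchy_stress,
)

__all__ = [
    "SolverError",
    "ConvergenceError",
    "LoadCase",
    "SolverConfig",
    "JointMaterials",
    "KinematicState",
    "ContactPatch",
    "ContactState",
    "JointSolution",
    "OracleResult",
    "station_contact_pressure",
    "foundation_modulus",
    "meniscus_restraint_stiffness",
    "meniscus_restraint_force",
    "assemble_residual",
    "total_potential",
    "solve_equilibrium",
    "brute_force_oracle",
    "minimise_derivative_free",
    "default_materials",
]

DOF_NAMES = ("u", "u_y", "phi_z", "w_medial", "w_lateral")
_MOMENT_SCALE = 30.0  # [mm] lever converting the moment residual to force units


class SolverError(RuntimeError):
    """Solver-level failure (degenerate contact, bad configuration)."""


class ConvergenceError(SolverError):
    """Newton iteration failed to reach the residual tolerance."""

    def __init__(self, message: str, residual_norm: float):
        super().__init__(message)
        self.residual_norm = residual_norm


# ---------------------------------------------------------------------------
# configuration containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LoadCase:
    """Axial compressive load on the femur, ramped in increments.

    ``constrain_mediolateral`` activates the CM-L mode: the relative
    medio-lateral bone translation is held at zero and its reaction is
    reported as the constraint force F_M-L.  ``mediolateral_force`` [N] is an
    optional external medio-lateral force at the femur reference point
    (positive toward medial), used by the constraint-consistency checks.
    """

    compressive_force: float = 1000.0
    n_increments: int = 10
    constrain_mediolateral: bool = False
    mediolateral_force: float = 0.0

    def __post_init__(self) -> None:
        if self.compressive_force < 0:
            raise SolverError("compressive force must be non-negative")
        if self.n_increments < 1:
            raise SolverError("n_increments must be at least 1")


@dataclass(frozen=True)
class SolverConfig:
    """Numerical parameters of the equilibrium solve.

    ``stabilization_factor`` scales the C1 smoothing band of the unilateral
    contact law (band = factor * smoothing_scale, default 0.1 * 0.1 mm =
    0.01 mm), a small regularisation aiding convergence.  ``prestretch`` is
    the initial ligament stretch lambda_0 imposed before loading.
    """

    station_spacing: float = 0.4       # [mm]
    stabilization_factor: float = 0.1
    smoothing_scale: float = 0.1       # [mm]
    tol_rel: float = 1e-8              # residual tolerance x applied load
    tol_abs: float = 1e-9              # [N] floor for zero-load solves
    max_iterations: int = 80
    prestretch: float = 1.05
    hoop_ring_radius: float = 32.0     # [mm] effective meniscus ring radius
    hoop_arc_length: float = 30.0      # [mm] engaged circumference
    horn_radial_fraction: float = 0.5  # radial projection of horn stiffness

    @property
    def smoothing_band(self) -> float:
        return self.stabilization_factor * self.smoothing_scale


@dataclass(frozen=True)
class JointMaterials:
    """Bundle of all material parameter sets used by a solve."""

    ligaments: Mapping[str, LigamentMaterial]
    meniscus: MeniscusMaterial
    cartilage: CartilageMaterial
    attachments: AttachmentMaterial


def default_materials() -> JointMaterials:
    return JointMaterials(
        ligaments=default_ligaments(),
        meniscus=default_meniscus(),
        cartilage=default_cartilage(),
        attachments=default_attachments(),
    )


def mirror_materials(mats: JointMaterials) -> JointMaterials:
    """Materials of the mirror-image joint (horn moduli swap sides)."""
    return JointMaterials(
        ligaments=mats.ligaments,
        meniscus=mats.meniscus,
        cartilage=mats.cartilage,
        attachments=mats.attachments.mirrored(),
    )


def symmetric_materials(mats: JointMaterials) -> JointMaterials:
    """Materials with side-averaged horn moduli (mirror-symmetric joint)."""
    return JointMaterials(
        ligaments=mats.ligaments,
        meniscus=mats.meniscus,
        cartilage=mats.cartilage,
        attachments=mats.attachments.symmetrised(),
    )


# ---------------------------------------------------------------------------
# elementary contact / restraint laws
# ---------------------------------------------------------------------------

def station_contact_pressure(
    gap: float, foundation_modulus: float, smoothing_band: float = 0.0
) -> float:
    """Unilateral foundation pressure [MPa]: k * max(0, -gap).

    Zero for open gaps, linear in the interpenetration, continuous at zero
    gap.  With a positive ``smoothing_band`` the kink is replaced by a C1
    quadratic transition of that width (the solver's stabilisation); the
    unsmoothed law is the default.
    """
    if foundation_modulus <= 0:
        raise SolverError("foundation modulus must be positive")
    pen = np.asarray(-gap, dtype=float)
    return float(foundation_modulus * _smooth_ramp(pen, smoothing_band))


def foundation_modulus(E: float, nu: float, thickness: float) -> float:
    """Winkler constant [MPa/mm] of a confined elastic layer.

    E(1-nu)/((1+nu)(1-2nu)) / thickness, the closed-form foundation constant
    of a thin bonded layer.
    """
    if thickness <= 0:
        raise SolverError("layer thickness must be positive")
    return E * (1 - nu) / ((1 + nu) * (1 - 2 * nu)) / thickness


def meniscus_restraint_stiffness(
    men: MeniscusGeometry,
    mat: MeniscusMaterial,
    attach: AttachmentMaterial,
    ring_radius: float = 32.0,
    arc_length: float = 30.0,
    horn_radial_fraction: float = 0.5,
) -> float:
    """Radial restraint stiffness [N/mm]: hoop ring plus horn attachments.

    Thin-ring hoop line stiffness E_theta * A_c / R^2 integrated over the
    engaged arc, plus the two horn axial stiffnesses E*A/L projected
    radially.
    """
    k_hoop = mat.E_theta * men.cross_section_area / ring_radius ** 2 * arc_length
    k_horn = attach.horn_stiffness(men.side) * horn_radial_fraction
    return k_hoop + k_horn


def meniscus_restraint_force(
    w_shift: float,
    men: MeniscusGeometry,
    mat: MeniscusMaterial,
    attach: AttachmentMaterial,
    **stiffness_kwargs,
) -> float:
    """Linear radial restoring force [N] opposing an outward shift."""
    if w_shift < -0.5 * men.radial_width:
        raise SolverError("shift exceeds half the wedge width inward")
    return meniscus_restraint_stiffness(men, mat, attach, **stiffness_kwargs) * w_shift


# smoothed unilateral ramp: rho(x) = 0 (x<=0), x^2/2e (0<x<e), x - e/2 (x>=e)
def _smooth_ramp(x: np.ndarray, eps: float) -> np.ndarray:
    if eps <= 0.0:
        return np.maximum(0.0, x)
    return np.where(
        x <= 0.0, 0.0, np.where(x < eps, x * x / (2 * eps), x - 0.5 * eps)
    )


def _smooth_ramp_integral(x: np.ndarray, eps: float) -> np.ndarray:
    """int_0^x rho(t) dt, the station foundation energy kernel."""
    if eps <= 0.0:
        xp = np.maximum(0.0, x)
        return 0.5 * xp * xp
    return np.where(
        x <= 0.0,
        0.0,
        np.where(
            x < eps,
            x ** 3 / (6 * eps),
            eps * eps / 6.0 + 0.5 * x * x - 0.5 * eps * x,
        ),
    )


# ---------------------------------------------------------------------------
# station discretisation
# ---------------------------------------------------------------------------

@dataclass
class _Stations:
    """Precomputed contact stations of one compartment."""

    side: str
    sign: float               # outward direction in global x (+1 medial)
    x_c: float                # condyle/plateau centre [mm]
    radius: float
    x_cc: np.ndarray          # global x of cartilage-cartilage stations
    s_cc: np.ndarray          # their (fixed) support heights
    a_cc: np.ndarray          # vertical-projected station areas [mm^2]
    k_cc: float
    x_w: np.ndarray           # global x of meniscus wedge stations
    a_w: np.ndarray
    k_wf: float
    y_base: float             # wedge base height [mm]
    wedge_inner: float        # inner-rim offset from centre [mm]
    wedge_width: float
    tan_beta: float
    inner_height: float

    def wedge_support(self, w: float) -> Tuple[np.ndarray, np.ndarray]:
        """Wedge top surface heights and slope mask for outward shift w.

        The inclined face is extended linearly below the inner rim and capped
        flat at the peripheral height, so the support is continuous in w
        (stations never drop out discontinuously).  The returned mask flags
        stations on the inclined part (which transmit the wedge slope).
        """
        xi = self.sign * (self.x_w - self.x_c) - self.wedge_inner - w
        on_slope = xi <= self.wedge_width
        s = self.y_base + self.inner_height + np.minimum(
            xi, self.wedge_width
        ) * self.tan_beta
        return s, on_slope


def _build_stations(
    geom: JointGeometry, mats: JointMaterials, config: SolverConfig
) -> List[_Stations]:
    out = []
    m_men = meniscus_confined_axial_modulus(mats.meniscus)
    m_cart = mats.cartilage.confined_modulus
    for side in ("medial", "lateral"):
        comp = geom.compartment(side)
        sign = 1.0 if side == "medial" else -1.0
        x_c = geom.condyle_centre_x(side)
        R = comp.condyle_radius
        ds = config.station_spacing
        men = comp.meniscus
        # cartilage-cartilage zone: inner reach up to just short of the wedge
        lo, hi = -comp.cc_inner_extent, comp.wedge_inner_offset - 0.5 * ds
        if hi <= lo:
            raise SolverError(f"{side}: no cartilage-cartilage zone")
        n_cc = max(3, int(round((hi - lo) / ds)))
        xi_cc = lo + (np.arange(n_cc) + 0.5) * (hi - lo) / n_cc
        kappa = comp.plateau_curvature
        s_cc = -R - 0.5 * kappa * (xi_cc - comp.plateau_apex_offset) ** 2
        t_cart = comp.cartilage_thickness
        k_cc = m_cart / (2.0 * t_cart)
        # meniscus wedge zone
        W = men.radial_width
        n_w = max(3, int(round(W / ds)))
        xi_w = comp.wedge_inner_offset + (np.arange(n_w) + 0.5) * W / n_w
        y_base = (
            -math.sqrt(R * R - comp.wedge_inner_offset ** 2)
            - comp.wedge_clearance
        )
        t_men = max(0.5 * (men.h + men.inner_height), 1.0)
        k_wf = 1.0 / (2.0 * t_cart / m_cart + t_men / m_men)
        out.append(
            _Stations(
                side=side,
                sign=sign,
                x_c=x_c,
                radius=R,
                x_cc=x_c + sign * xi_cc,
                s_cc=s_cc,
                a_cc=np.full(n_cc, (hi - lo) / n_cc * comp.cc_depth),
                k_cc=k_cc,
                x_w=x_c + sign * xi_w,
                a_w=np.full(n_w, W / n_w * comp.depth),
                k_wf=k_wf,
                y_base=y_base,
                wedge_inner=comp.wedge_inner_offset,
                wedge_width=W,
                tan_beta=(men.h - men.inner_height) / W,
                inner_height=men.inner_height,
            )
        )
    return out


@dataclass
class _Ligament1D:
    name: str
    material: LigamentMaterial
    p0: np.ndarray            # femur anchor in the (lifted) reference [mm]
    p_t: np.ndarray           # tibia anchor [mm]
    area: float
    natural_length: float     # slack length: reference length / lambda_0


def _build_ligaments(
    geom: JointGeometry, mats: JointMaterials, config: SolverConfig
) -> List[_Ligament1D]:
    out = []
    for el in geom.ligaments:
        mat = mats.ligaments[el.material]
        p0 = np.array([el.femur_xy[0], el.femur_xy[1] + geom.femur_lift])
        p_t = np.array([el.tibia_xy[0], el.tibia_xy[1]])
        ref_len = float(np.linalg.norm(p0 - p_t))
        # natural length chosen so the stretch at this variant's reference
        # configuration equals lambda_0; ligament resultants of lifted
        # variants then match the intact model by construction
        out.append(
            _Ligament1D(
                el.material, mat, p0, p_t, el.area, ref_len / config.prestretch
            )
        )
    return out


# ---------------------------------------------------------------------------
# the assembled reduced model
# ---------------------------------------------------------------------------

class _Model:
    """Evaluates total potential energy, its analytic gradient and the
    station-resolved contact state for a given DOF vector."""

    def __init__(
        self, geom: JointGeometry, mats: JointMaterials, config: SolverConfig
    ):
        self.geom = geom
        self.mats = mats
        self.config = config
        self.stations = _build_stations(geom, mats, config)
        self.ligs = _build_ligaments(geom, mats, config)
        self.k_restraint = {
            st.side: meniscus_restraint_stiffness(
                geom.compartment(st.side).meniscus,
                mats.meniscus,
                mats.attachments,
                ring_radius=config.hoop_ring_radius,
                arc_length=config.hoop_arc_length,
                horn_radial_fraction=config.horn_radial_fraction,
            )
            for st in self.stations
        }
        self.eps = config.smoothing_band
        self.lift = geom.femur_lift

    def _zone_gaps(self, st: _Stations, zone: str, cc_pos: np.ndarray,
                   w: float):
        """Station gaps, condyle slopes and wedge-slope factors of one zone."""
        if zone == "cc":
            x, a, k = st.x_cc, st.a_cc, st.k_cc
            supp = st.s_cc
            slope_w = np.zeros_like(x)
        else:
            x, a, k = st.x_w, st.a_w, st.k_wf
            supp, on_slope = st.wedge_support(w)
            slope_w = np.where(on_slope, st.tan_beta, 0.0)
        dx = x - cc_pos[0]
        under = st.radius ** 2 - dx * dx
        active = under > 0.04 * st.radius ** 2
        root = np.sqrt(np.where(active, under, 1.0))
        gap = np.where(active, cc_pos[1] - root - supp, 1e9)
        tau = np.where(active, dx / root, 0.0)  # condyle surface slope
        return x, a, k, gap, tau, slope_w

    # q = [u, u_y, phi_z, w_medial, w_lateral]
    def energy_gradient(
        self, q: np.ndarray, P: float, F_ml: float = 0.0
    ) -> Tuple[float, np.ndarray]:
        u, uy, phi, w_m, w_l = q
        c, s = math.cos(phi), math.sin(phi)
        rot = np.array([[c, -s], [s, c]])
        drot = np.array([[-s, -c], [c, -s]])
        energy = P * uy - F_ml * u
        grad = np.array([-F_ml, P, 0.0, 0.0, 0.0])
        w_by_side = {"medial": w_m, "lateral": w_l}
        w_idx = {"medial": 3, "lateral": 4}
        for st in self.stations:
            c0 = np.array([st.x_c, self.lift])
            cc_pos = rot @ c0 + np.array([u, uy])
            dc = drot @ c0
            for zone in ("cc", "wedge"):
                x, a, k, gap, tau, slope_w = self._zone_gaps(
                    st, zone, cc_pos, w_by_side[st.side]
                )
                pen = -gap
                p = k * _smooth_ramp(pen, self.eps)
                energy += float(
                    np.sum(k * a * _smooth_ramp_integral(pen, self.eps))
                )
                pa = p * a
                # dgap/du = -tau ; dgap/du_y = 1 ; dgap/dphi = -tau dcx + dcy
                grad[0] += float(np.sum(pa * tau))
                grad[1] -= float(np.sum(pa))
                grad[2] -= float(np.sum(pa * (-tau * dc[0] + dc[1])))
                if zone == "wedge":
                    # dgap/dw = +tan(beta) on the inclined part of the wedge
                    grad[w_idx[st.side]] -= float(np.sum(pa * slope_w))
        for side, iw in w_idx.items():
            k_r = self.k_restraint[side]
            w = w_by_side[side]
            energy += 0.5 * k_r * w * w
            grad[iw] += k_r * w
        for lig in self.ligs:
            pf = rot @ lig.p0 + np.array([u, uy])
            d = pf - lig.p_t
            length = float(np.linalg.norm(d))
            lam = length / lig.natural_length
            energy += ligament_spring_energy(
                lam, lig.material, lig.area, lig.natural_length
            )
            tension = lig.area * max(
                0.0, uniaxial_cauchy_stress(lam, lig.material)
            )
            if tension > 0.0:
                uhat = d / length
                dpdphi = drot @ lig.p0
                grad[0] += tension * uhat[0]
                grad[1] += tension * uhat[1]
                grad[2] += tension * float(uhat @ dpdphi)
        return energy, grad

    def contact_state(self, q: np.ndarray) -> "ContactState":
        u, uy, phi, w_m, w_l = q
        c, s = math.cos(phi), math.sin(phi)
        rot = np.array([[c, -s], [s, c]])
        w_by_side = {"medial": w_m, "lateral": w_l}
        patches: Dict[Tuple[str, str], ContactPatch] = {}
        for st in self.stations:
            cc_pos = rot @ np.array([st.x_c, self.lift]) + np.array([u, uy])
            for zone, iface in (
                ("cc", "cartilage-cartilage"), ("wedge", "femur-meniscus")
            ):
                x, a, k, gap, tau, slope_w = self._zone_gaps(
                    st, zone, cc_pos, w_by_side[st.side]
                )
                p = k * _smooth_ramp(-gap, self.eps)
                pa = p * a
                if zone == "cc":
                    # force on the tibial cartilage; lateral component from
                    # the condyle surface slope (energy-consistent)
                    force = np.vstack([pa * tau, -pa])
                    face = a * np.sqrt(1.0 + tau ** 2)
                else:
                    # force on the meniscus wedge face (slope tan(beta) on
                    # the inclined part, flat at the peripheral cap)
                    slope = st.sign * slope_w
                    force = np.vstack([pa * slope, -pa])
                    face = a * np.sqrt(1.0 + slope_w ** 2)
                    patches[(st.side, "meniscus-tibia")] = ContactPatch(
                        side=st.side,
                        interface="meniscus-tibia",
                        x=x.copy(),
                        pressure=p.copy(),
                        face_area=a.copy(),
                        force=np.vstack([np.zeros_like(pa), -pa]),
                    )
                patches[(st.side, iface)] = ContactPatch(
                    side=st.side,
                    interface=iface,
                    x=x.copy(),
                    pressure=p,
                    face_area=np.broadcast_to(face, p.shape).copy(),
                    force=force,
                )
        return ContactState(patches=patches)


# ---------------------------------------------------------------------------
# solution containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KinematicState:
    """Femur and meniscus kinematics.

    ``u`` [mm] medio-lateral femur translation (positive = medial), ``u_y``
    [mm] axial translation, ``phi_z`` [rad] varus/valgus rotation,
    ``w_shift`` radial outward shift per meniscus [mm].  External/internal
    rotation is out of the coronal plane and fixed at zero.
    """

    u: float
    u_y: float
    phi_z: float
    w_shift: Mapping[str, float]

    def as_vector(self) -> np.ndarray:
        return np.array(
            [self.u, self.u_y, self.phi_z,
             self.w_shift["medial"], self.w_shift["lateral"]]
        )

    @staticmethod
    def from_vector(q: Sequence[float]) -> "KinematicState":
        q = np.asarray(q, dtype=float)
        return KinematicState(
            u=float(q[0]), u_y=float(q[1]), phi_z=float(q[2]),
            w_shift={"medial": float(q[3]), "lateral": float(q[4])},
        )


@dataclass(frozen=True)
class ContactPatch:
    """Station-resolved contact data of one interface of one compartment."""

    side: str
    interface: str
    x: np.ndarray           # station positions [mm]
    pressure: np.ndarray    # station pressures [MPa] (>= 0)
    face_area: np.ndarray   # station face areas [mm^2]
    force: np.ndarray       # 2 x n station force vectors [N] on the support

    @property
    def resultant(self) -> np.ndarray:
        return self.force.sum(axis=1)

    @property
    def total_force(self) -> float:
        return float(np.linalg.norm(self.resultant))

    @property
    def contact_area(self) -> float:
        return float(self.face_area[self.pressure > 0].sum())

    @property
    def peak_pressure(self) -> float:
        return float(self.pressure.max(initial=0.0))


_TIBIAL_INTERFACES = ("cartilage-cartilage", "meniscus-tibia")


@dataclass(frozen=True)
class ContactState:
    """All contact patches of a solution, keyed by (side, interface)."""

    patches: Mapping[Tuple[str, str], ContactPatch]

    def patch(self, side: str, interface: str) -> ContactPatch:
        return self.patches[(side, interface)]

    def compartment_resultant(self, side: str) -> np.ndarray:
        """Resultant contact force vector [N] on the tibial surfaces."""
        return sum(
            self.patches[(side, i)].resultant for i in _TIBIAL_INTERFACES
        )

    def compartment_peak_pressure(self, side: str) -> float:
        return max(
            self.patches[(side, i)].peak_pressure for i in _TIBIAL_INTERFACES
        )

    def compartment_area(self, side: str) -> float:
        return sum(
            self.patches[(side, i)].contact_area for i in _TIBIAL_INTERFACES
        )

    def extrusion_force(self, side: str) -> float:
        """Radially outward force [N] on one meniscus."""
        patch = self.patches[(side, "femur-meniscus")]
        sign = 1.0 if side == "medial" else -1.0
        return float(sign * patch.resultant[0])

    def axial_resultant(self) -> float:
        """Total upward contact force [N] carried by both compartments."""
        return float(
            -sum(self.compartment_resultant(s)[1] for s in ("medial", "lateral"))
        )


@dataclass(frozen=True)
class JointSolution:
    """Converged equilibrium state of one load case.

    Kinematic outcomes are reported relative to the zero-external-load
    (post-prestretch) equilibrium, matching the loaded-minus-unloaded
    definition of the external shift; contact forces are absolute.
    """

    kinematics: KinematicState            # relative to the unloaded state
    kinematics_absolute: KinematicState
    baseline: KinematicState
    contact: ContactState
    constraint_force: float               # F_M-L [N]; 0 in free mode
    residual_norm: float
    converged: bool
    mode: str                             # 'free' | 'cml'
    load: LoadCase
    increments: Tuple[Dict[str, float], ...] = ()


# ---------------------------------------------------------------------------
# residual and energy entry points
# ---------------------------------------------------------------------------

def total_potential(
    state: KinematicState,
    geom: JointGeometry,
    materials: JointMaterials,
    load: LoadCase,
    solver_config: Optional[SolverConfig] = None,
    load_fraction: float = 1.0,
) -> float:
    """Total potential energy [N mm] of the reduced joint at a given state."""
    config = solver_config or SolverConfig()
    model = _Model(geom, materials, config)
    e, _ = model.energy_gradient(
        state.as_vector(),
        load_fraction * load.compressive_force,
        load_fraction * load.mediolateral_force,
    )
    return e


def assemble_residual(
    state: KinematicState,
    geom: JointGeometry,
    materials: JointMaterials,
    load: LoadCase,
    solver_config: Optional[SolverConfig] = None,
) -> np.ndarray:
    """Generalized force/moment imbalance at a kinematic state.

    Components (order ``DOF_NAMES``): medio-lateral force balance [N], axial
    force balance [N], varus/valgus moment balance [N mm], and radial balance
    of each meniscus [N]; all vanish at a free equilibrium.  The residual is
    the gradient of the total potential, so in CM-L mode the medio-lateral
    component evaluated at u = 0 equals minus the constraint reaction F_M-L.
    """
    config = solver_config or SolverConfig()
    model = _Model(geom, materials, config)
    _, grad = model.energy_gradient(
        state.as_vector(), load.compressive_force, load.mediolateral_force
    )
    return grad


# ---------------------------------------------------------------------------
# Newton solve
# ---------------------------------------------------------------------------

def _scaled_norm(grad: np.ndarray, free: np.ndarray) -> float:
    scale = np.array([1.0, 1.0, 1.0 / _MOMENT_SCALE, 1.0, 1.0])
    return float(np.abs(grad[free] * scale[free]).max())


def _newton(
    model: _Model,
    q0: np.ndarray,
    P: float,
    F_ml: float,
    free: np.ndarray,
    tol: float,
    max_iter: int,
) -> Tuple[np.ndarray, float, int]:
    q = q0.copy()
    fd_step = np.array([1e-7, 1e-7, 1e-8, 1e-7, 1e-7])
    energy, grad = model.energy_gradient(q, P, F_ml)
    for it in range(max_iter):
        rnorm = _scaled_norm(grad, free)
        if rnorm <= tol:
            return q, rnorm, it
        # finite-difference Jacobian of the gradient (Hessian), free DOFs only
        n = free.sum()
        J = np.zeros((n, n))
        idx = np.flatnonzero(free)
        for col, j in enumerate(idx):
            qp = q.copy()
            qp[j] += fd_step[j]
            _, gp = model.energy_gradient(qp, P, F_ml)
            qm = q.copy()
            qm[j] -= fd_step[j]
            _, gm = model.energy_gradient(qm, P, F_ml)
            J[:, col] = (gp[idx] - gm[idx]) / (2.0 * fd_step[j])
        g_free = grad[idx]
        mu = 0.0
        for attempt in range(8):
            try:
                dq_free = np.linalg.solve(J + mu * np.eye(n), -g_free)
            except np.linalg.LinAlgError:
                mu = max(10.0 * mu, 1e-6 * np.abs(J).max())
                continue
            if np.dot(dq_free, g_free) < 0.0:
                break
            mu = max(10.0 * mu, 1e-6 * max(np.abs(J).max(), 1.0))
        else:
            dq_free = -g_free  # damped gradient fallback
        # trust-region style step cap: keeps near-singular tangents (grazing
        # contact, slack ligaments) from throwing the iterate far away
        step_cap = np.where(idx == 2, 0.02, 0.5)
        over = np.abs(dq_free) / step_cap
        if over.max() > 1.0:
            dq_free = dq_free / over.max()
        # backtracking line search on the energy
        t = 1.0
        accepted = False
        g_dot_d = float(np.dot(g_free, dq_free))
        while t > 1e-10:
            q_try = q.copy()
            q_try[idx] += t * dq_free
            e_try, g_try = model.energy_gradient(q_try, P, F_ml)
            if e_try <= energy + 1e-4 * t * g_dot_d or _scaled_norm(
                g_try, free
            ) < rnorm:
                q, energy, grad = q_try, e_try, g_try
                accepted = True
                break
            t *= 0.5
        if not accepted:
            raise ConvergenceError(
                f"line search stalled at residual {rnorm:.3e} N", rnorm
            )
    rnorm = _scaled_norm(grad, free)
    if rnorm <= tol:
        return q, rnorm, max_iter
    raise ConvergenceError(
        f"no convergence in {max_iter} iterations "
        f"(residual {rnorm:.3e} N, tolerance {tol:.3e} N)",
        rnorm,
    )


def solve_equilibrium(
    geom: JointGeometry,
    materials: Optional[JointMaterials] = None,
    load: Optional[LoadCase] = None,
    solver_config: Optional[SolverConfig] = None,
    initial_state: Optional[KinematicState] = None,
) -> JointSolution:
    """Solve static equilibrium under the given load case.

    The prestretched zero-load equilibrium is solved first (the unloaded
    baseline); the compressive load is then ramped in ``n_increments`` steps.
    Deterministic: no randomness anywhere in the path.
    """
    materials = materials or default_materials()
    load = load or LoadCase()
    config = solver_config or SolverConfig()
    model = _Model(geom, materials, config)
    free = np.ones(5, dtype=bool)
    if load.constrain_mediolateral:
        free[0] = False

    q = (initial_state.as_vector() if initial_state is not None
         else np.zeros(5))
    P_target = load.compressive_force
    tol0 = config.tol_rel * max(P_target, 1.0) + config.tol_abs

    # unloaded (post-prestretch) baseline
    q, _, _ = _newton(model, q, 0.0, 0.0, free, tol0, config.max_iterations)
    baseline = KinematicState.from_vector(q)

    increments: List[Dict[str, float]] = []
    rnorm = 0.0
    fractions = (
        np.arange(1, load.n_increments + 1) / load.n_increments
        if P_target > 0 or load.mediolateral_force != 0.0
        else np.array([1.0])
    )
    for frac in fractions:
        P = frac * P_target
        F_ml = frac * load.mediolateral_force
        q, rnorm, n_it = _newton(
            model, q, P, F_ml, free, tol0, config.max_iterations
        )
        cs = model.contact_state(q)
        increments.append(
            {
                "load": P,
                "iterations": n_it,
                "residual": rnorm,
                "extrusion_medial": cs.extrusion_force("medial"),
                "extrusion_lateral": cs.extrusion_force("lateral"),
                "axial_contact": cs.axial_resultant(),
            }
        )

    contact = model.contact_state(q)
    if P_target > 0 and contact.axial_resultant() < 1e-9 * P_target:
        raise SolverError(
            "degenerate contact: full separation under a nonzero load"
        )
    constraint_force = 0.0
    if load.constrain_mediolateral:
        _, grad = model.energy_gradient(q, P_target, load.mediolateral_force)
        constraint_force = float(-grad[0])
    absolute = KinematicState.from_vector(q)
    relative = KinematicState.from_vector(q - baseline.as_vector())
    return JointSolution(
        kinematics=relative,
        kinematics_absolute=absolute,
        baseline=baseline,
        contact=contact,
        constraint_force=constraint_force,
        residual_norm=rnorm,
        converged=True,
        mode="cml" if load.constrain_mediolateral else "free",
        load=load,
        increments=tuple(increments),
    )


# ---------------------------------------------------------------------------
# brute-force verification oracle
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OracleResult:
    """Derivative-free energy-minimum estimate and its resolution."""

    state: KinematicState
    energy: float
    resolution: float


def minimise_derivative_free(
    fun: Callable[[np.ndarray], float],
    x0: np.ndarray,
    spans: np.ndarray,
    resolution: float = 1e-4,
    n_points: int = 13,
    max_sweeps: int = 80,
) -> Tuple[np.ndarray, float]:
    """Cyclic coordinate grid search with bracket shrinking.

    Scans each coordinate on a regular grid over its current bracket, moves
    to the grid minimum and shrinks the bracket around it; terminates when
    every bracket spacing falls below ``resolution``.  Derivative-free by
    construction, hence independent of the Newton path.
    """
    x = np.asarray(x0, dtype=float).copy()
    spans = np.asarray(spans, dtype=float).copy()
    f_best = fun(x)
    for _ in range(max_sweeps):
        moved = False
        for j in range(len(x)):
            if spans[j] <= 0.0:
                continue
            grid = x[j] + np.linspace(-spans[j], spans[j], n_points)
            vals = []
            for gj in grid:
                xt = x.copy()
                xt[j] = gj
                vals.append(fun(xt))
            k = int(np.argmin(vals))
            if vals[k] < f_best:
                f_best = vals[k]
                if grid[k] != x[j]:
                    moved = True
                x[j] = grid[k]
            spacing = 2.0 * spans[j] / (n_points - 1)
            spans[j] = max(spacing, 0.25 * resolution)
        if spans.max() <= resolution and not moved:
            break
    return x, f_best


def brute_force_oracle(
    geom: JointGeometry,
    materials: Optional[JointMaterials] = None,
    load: Optional[LoadCase] = None,
    grid_spec: Optional[Mapping[str, object]] = None,
    solver_config: Optional[SolverConfig] = None,
) -> OracleResult:
    """Locate the equilibrium by derivative-free minimisation of the
    total potential (baseline-inclusive, i.e. absolute kinematics).

    ``grid_spec`` keys: ``spans`` (per-DOF initial half-widths, order
    ``DOF_NAMES``), ``resolution`` [mm], ``n_points``.  Independent check of
    the Newton solution; agreement is expected within the grid resolution.
    """
    materials = materials or default_materials()
    load = load or LoadCase()
    config = solver_config or SolverConfig()
    spec = dict(grid_spec or {})
    spans = np.asarray(
        spec.get("spans", [1.5, 1.5, 0.05, 1.0, 1.0]), dtype=float
    )
    resolution = float(spec.get("resolution", 1e-4))
    n_points = int(spec.get("n_points", 13))
    model = _Model(geom, materials, config)
    P = load.compressive_force
    F_ml = load.mediolateral_force
    if load.constrain_mediolateral:
        spans = spans.copy()
        spans[0] = 0.0

    def fun(q: np.ndarray) -> float:
        e, _ = model.energy_gradient(q, P, F_ml)
        return e

    q, energy = minimise_derivative_free(
        fun, np.zeros(5), spans, resolution=max(resolution, 1e-3),
        n_points=n_points,
    )
    # simplex polish (still derivative-free) down to the target resolution
    from scipy.optimize import minimize

    free_idx = np.flatnonzero(spans > 0)

    def fun_free(qf: np.ndarray) -> float:
        qq = q.copy()
        qq[free_idx] = qf
        return fun(qq)

    res = minimize(
        fun_free, q[free_idx], method="Nelder-Mead",
        options={"xatol": 0.2 * resolution, "fatol": 1e-12,
                 "maxiter": 20000, "maxfev": 20000},
    )
    if res.fun <= energy:
        q = q.copy()
        q[free_idx] = res.x
        energy = float(res.fun)
    return OracleResult(
        state=KinematicState.from_vector(q), energy=energy,
        resolution=resolution,
    )
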