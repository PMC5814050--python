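"""Constitutive models for the knee soft tissues.

Ligaments follow a nearly incompressible, transversely isotropic hyperelastic
law: a Neo-Hookean matrix with a quadratic volumetric penalty plus a single
collagen-fiber family with an exponential toe region that becomes linear once
the fibers straighten at the stretch ``lambda_star``,

    Phi = C1 (I1_bar - 3) + (1/D1) (J - 1)^2 + F2(lambda),

    lambda dF2/dlambda = 0                          for lambda <= 1
                       = C3 (exp(C4 (lambda-1))-1)  for 1 < lambda < lambda*
                       = C5 lambda + C6             for lambda >= lambda*,

where ``I1_bar`` is the first invariant of the modified (isochoric) left
Cauchy-Green tensor, ``J = det F`` and ``lambda`` is the fiber stretch.  The
offset ``C6`` is not a free parameter: it is fixed by continuity of the two
fiber branches at ``lambda_star``.

Menisci are linear, elastic and transversely isotropic about the
circumferential (hoop) axis; articular cartilage is linear isotropic; the
meniscal horn attachments are linear axial springs with per-horn moduli.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, Mapping

import numpy as np
from scipy.special import expi

__all__ = [
    "LigamentMaterial",
    "DeformationState",
    "MeniscusMaterial",
    "CartilageMaterial",
    "AttachmentMaterial",
    "MaterialError",
    "InvalidDeformationError",
    "continuity_constant",
    "fiber_force_term",
    "fiber_energy",
    "strain_energy",
    "cauchy_stress",
    "prestretch_gradient",
    "uniaxial_stretch_gradient",
    "uniaxial_cauchy_stress",
    "ligament_spring_force",
    "ligament_spring_energy",
    "meniscus_compliance",
    "default_ligaments",
    "default_meniscus",
    "default_cartilage",
    "default_attachments",
]

#: exp() argument beyond which the fiber law is declared out of range.
_EXP_ARG_CAP = 700.0


class MaterialError(ValueError):
    """Invalid or out-of-range material parameters."""


class InvalidDeformationError(ValueError):
    """Deformation gradient with non-positive determinant."""


def _checked_exp(arg: float) -> float:
    if arg > _EXP_ARG_CAP:
        raise MaterialError(
            f"fiber law exponent argument {arg:.3g} exceeds overflow guard "
            f"({_EXP_ARG_CAP:g}); check C4/lambda parameters"
        )
    return math.exp(arg)


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LigamentMaterial:
    """Parameters of the fiber-reinforced hyperelastic ligament law.

    C1 [MPa] matrix shear-like coefficient, D1 [MPa^-1] volumetric compliance,
    C3 [MPa]/C4 [-] toe-region scale and exponent, C5 [MPa] linear-region
    modulus, lambda_star [-] fiber straightening stretch.  C6 [MPa] is derived.
    """

    name: str
    C1: float
    D1: float
    C3: float
    C4: float
    C5: float
    lambda_star: float

    def __post_init__(self) -> None:
        if self.C1 <= 0 or self.D1 <= 0:
            raise MaterialError(f"{self.name}: C1 and D1 must be positive")
        if self.C3 < 0 or self.C4 <= 0 or self.C5 <= 0:
            raise MaterialError(f"{self.name}: fiber coefficients out of range")
        if self.lambda_star <= 1.0:
            raise MaterialError(f"{self.name}: lambda_star must exceed 1")

    @property
    def C6(self) -> float:
        return continuity_constant(self)


@dataclass(frozen=True)
class DeformationState:
    """A deformation gradient together with the reference fiber direction."""

    F: np.ndarray
    fiber_direction: np.ndarray = field(
        default_factory=lambda: np.array([1.0, 0.0, 0.0])
    )

    def __post_init__(self) -> None:
        F = np.asarray(self.F, dtype=float)
        a = np.asarray(self.fiber_direction, dtype=float)
        object.__setattr__(self, "F", F)
        object.__setattr__(self, "fiber_direction", a / np.linalg.norm(a))
        if F.shape != (3, 3):
            raise InvalidDeformationError("F must be a 3x3 matrix")
        if np.linalg.det(F) <= 0:
            raise InvalidDeformationError("det(F) must be positive")

    @property
    def J(self) -> float:
        return float(np.linalg.det(self.F))

    @property
    def I1_bar(self) -> float:
        J = self.J
        return float(J ** (-2.0 / 3.0) * np.trace(self.F @ self.F.T))

    @property
    def fiber_stretch(self) -> float:
        return float(np.linalg.norm(self.F @ self.fiber_direction))


@dataclass(frozen=True)
class MeniscusMaterial:
    """Transversely isotropic meniscus elasticity (hoop axis = theta).

    ``theta_ratio_convention`` controls how the printed theta-coupling Poisson
    ratios are read: ``"major"`` (default) treats them as fiber-major ratios
    nu_theta_r / nu_theta_z; ``"as_printed"`` treats them as nu_r_theta /
    nu_z_theta against the small in-plane moduli (not positive definite for
    the shipped parameter set, so it raises on assembly).
    """

    E_theta: float = 120.0
    E_z: float = 20.0
    E_r: float = 20.0
    nu_rz: float = 0.2
    nu_rtheta: float = 0.3
    nu_ztheta: float = 0.3
    G_rz: float = 8.33
    G_rtheta: float = 57.7
    G_ztheta: float = 57.7
    theta_ratio_convention: str = "major"

    def __post_init__(self) -> None:
        for name in ("E_theta", "E_z", "E_r", "G_rz", "G_rtheta", "G_ztheta"):
            if getattr(self, name) <= 0:
                raise MaterialError(f"meniscus {name} must be positive")
        if self.theta_ratio_convention not in ("major", "as_printed"):
            raise MaterialError(
                "theta_ratio_convention must be 'major' or 'as_printed'"
            )


@dataclass(frozen=True)
class CartilageMaterial:
    """Linear isotropic articular cartilage."""

    E: float = 10.0
    nu: float = 0.45

    def __post_init__(self) -> None:
        if self.E <= 0:
            raise MaterialError("cartilage E must be positive")
        if not (0.0 <= self.nu < 0.5):
            raise MaterialError("cartilage nu must lie in [0, 0.5)")

    @property
    def confined_modulus(self) -> float:
        """Confined (oedometric) modulus E(1-nu)/((1+nu)(1-2nu)) [MPa]."""
        return self.E * (1 - self.nu) / ((1 + self.nu) * (1 - 2 * self.nu))


#: Per-horn attachment moduli [MPa].
_HORN_MODULI = {
    "lateral_anterior": 161.0,
    "lateral_posterior": 96.3,
    "medial_anterior": 179.0,
    "medial_posterior": 85.3,
}


@dataclass(frozen=True)
class AttachmentMaterial:
    """Meniscal horn attachments: axial springs E*A/L per horn."""

    E_per_horn: Mapping[str, float] = field(
        default_factory=lambda: dict(_HORN_MODULI)
    )
    area: float = 30.0    # horn cross-section [mm^2]
    length: float = 12.0  # attachment length [mm]

    def __post_init__(self) -> None:
        if set(self.E_per_horn) != set(_HORN_MODULI):
            raise MaterialError(
                f"E_per_horn must have keys {sorted(_HORN_MODULI)}"
            )
        if any(v <= 0 for v in self.E_per_horn.values()):
            raise MaterialError("all horn moduli must be positive")
        if self.area <= 0 or self.length <= 0:
            raise MaterialError("horn area and length must be positive")

    def horn_stiffness(self, side: str) -> float:
        """Sum of E*A/L over the two horns of one side [N/mm]."""
        keys = [k for k in self.E_per_horn if k.startswith(side)]
        if not keys:
            raise MaterialError(f"unknown side {side!r}")
        return sum(self.E_per_horn[k] * self.area / self.length for k in keys)

    def mirrored(self) -> "AttachmentMaterial":
        """Swap the medial and lateral horn moduli (mirror-image joint)."""
        swap = {"medial": "lateral", "lateral": "medial"}
        moduli = {}
        for key, val in self.E_per_horn.items():
            side, horn = key.split("_", 1)
            moduli[f"{swap[side]}_{horn}"] = val
        return AttachmentMaterial(moduli, self.area, self.length)

    def symmetrised(self) -> "AttachmentMaterial":
        """Average the horn moduli across sides (mirror-symmetric joint)."""
        moduli = {}
        for key in self.E_per_horn:
            side, horn = key.split("_", 1)
            other = {"medial": "lateral", "lateral": "medial"}[side]
            moduli[key] = 0.5 * (
                self.E_per_horn[key] + self.E_per_horn[f"{other}_{horn}"]
            )
        return AttachmentMaterial(moduli, self.area, self.length)


# ---------------------------------------------------------------------------
# fiber law
# ---------------------------------------------------------------------------

def continuity_constant(mat: LigamentMaterial) -> float:
    """Fiber linear-branch offset C6 [MPa] from branch continuity.

    Equating the toe and linear branches of ``lambda dF2/dlambda`` at
    ``lambda_star`` gives C6 = C3 (exp(C4 (l*-1)) - 1) - C5 l*.
    """
    e = _checked_exp(mat.C4 * (mat.lambda_star - 1.0))
    c6 = mat.C3 * (e - 1.0) - mat.C5 * mat.lambda_star
    if not math.isfinite(c6):
        raise MaterialError(f"{mat.name}: non-finite continuity constant")
    return c6


def fiber_force_term(lam: float, mat: LigamentMaterial) -> float:
    """The fiber stress measure ``lambda dF2/dlambda`` [MPa].

    Zero for slack fibers (lambda <= 1), exponential toe up to lambda_star,
    then linear; continuous everywhere by construction of C6.
    """
    if lam <= 0:
        raise MaterialError("fiber stretch must be positive")
    if lam <= 1.0:
        return 0.0
    if lam < mat.lambda_star:
        return mat.C3 * (_checked_exp(mat.C4 * (lam - 1.0)) - 1.0)
    return mat.C5 * lam + mat.C6


def fiber_energy(lam: float, mat: LigamentMaterial) -> float:
    """Fiber strain energy F2(lambda) [MPa], with F2(1) = 0.

    Integrating ``dF2/dlambda = C3 (exp(C4 (l-1)) - 1)/l`` on the toe branch
    involves the exponential integral Ei; the linear branch integrates in
    elementary terms.  Value continuity is enforced at lambda_star.
    """
    if lam <= 0:
        raise MaterialError("fiber stretch must be positive")
    if lam <= 1.0:
        return 0.0
    _checked_exp(mat.C4 * max(lam, mat.lambda_star))  # overflow guard

    def toe(l: float) -> float:
        # int_1^l C3 (exp(C4 (s-1)) - 1)/s ds
        return mat.C3 * (
            math.exp(-mat.C4) * (expi(mat.C4 * l) - expi(mat.C4))
            - math.log(l)
        )

    if lam < mat.lambda_star:
        return toe(lam)
    ls = mat.lambda_star
    c6 = mat.C6
    lin = mat.C5 * (lam - ls) + c6 * math.log(lam / ls)
    return toe(ls) + lin


# ---------------------------------------------------------------------------
# 3-D energy and stress
# ---------------------------------------------------------------------------

def strain_energy(state: DeformationState, mat: LigamentMaterial) -> float:
    """Strain-energy density Phi [MPa] of the ligament law."""
    J = state.J
    iso = mat.C1 * (state.I1_bar - 3.0)
    vol = (J - 1.0) ** 2 / mat.D1
    return iso + vol + fiber_energy(state.fiber_stretch, mat)


def cauchy_stress(state: DeformationState, mat: LigamentMaterial) -> np.ndarray:
    """Cauchy stress sigma = J^-1 (dPhi/dF) F^T [MPa], 3x3 symmetric.

    Closed form: isochoric Neo-Hookean deviator, volumetric pressure, and a
    rank-one fiber term along the spatial fiber direction carrying
    ``lambda dF2/dlambda``.
    """
    F = state.F
    J = state.J
    B = F @ F.T
    B_bar = J ** (-2.0 / 3.0) * B
    I1_bar = np.trace(B_bar)
    sigma = (2.0 * mat.C1 / J) * (B_bar - (I1_bar / 3.0) * np.eye(3))
    sigma += (2.0 / mat.D1) * (J - 1.0) * np.eye(3)
    lam = state.fiber_stretch
    if lam > 1.0:
        m = (F @ state.fiber_direction) / lam
        sigma += (fiber_force_term(lam, mat) / J) * np.outer(m, m)
    return 0.5 * (sigma + sigma.T)


def prestretch_gradient(lambda0: float) -> np.ndarray:
    """Isochoric uniaxial prestretch gradient diag(l0, l0^-1/2, l0^-1/2)."""
    if lambda0 <= 0:
        raise MaterialError("prestretch must be positive")
    t = lambda0 ** -0.5
    return np.diag([lambda0, t, t])


uniaxial_stretch_gradient = prestretch_gradient


def uniaxial_cauchy_stress(lam: float, mat: LigamentMaterial) -> float:
    """Axial Cauchy stress [MPa] of the incompressible uniaxial response.

    Matrix term 2 C1 (lambda^2 - 1/lambda) plus the fiber term, with the fiber
    aligned with the loading axis.
    """
    if lam <= 0:
        raise MaterialError("stretch must be positive")
    return 2.0 * mat.C1 * (lam ** 2 - 1.0 / lam) + fiber_force_term(lam, mat)


def ligament_spring_force(
    lam: float, mat: LigamentMaterial, area: float, prestretch: float = 1.0
) -> float:
    """Axial force [N] of the 1-D ligament spring at total stretch l0*lam.

    The 3-D ligament is reduced to a nonlinear spring: force = cross-section
    area times the axial Cauchy stress of the incompressible uniaxial response
    (declared approximation of the 3-D mixed formulation).  The fiber
    contributes nothing when the total stretch is at or below 1.
    """
    if area <= 0:
        raise MaterialError("ligament area must be positive")
    return area * uniaxial_cauchy_stress(prestretch * lam, mat)


def _uniaxial_tension_energy_density(lam: float, mat: LigamentMaterial) -> float:
    """int_1^lambda max(0, sigma_uniaxial(s)) ds  [MPa]; 0 for lambda <= 1.

    The uniaxial stress is negative exactly for stretches below 1, so the
    tension-only clamp reduces to truncating the integral at 1.  Closed form
    on each fiber branch.
    """
    if lam <= 1.0:
        return 0.0
    matrix = 2.0 * mat.C1 * (lam ** 3 / 3.0 - math.log(lam) - 1.0 / 3.0)

    def toe_int(l: float) -> float:
        # int_1^l C3 (exp(C4 (s-1)) - 1) ds
        return mat.C3 * (
            (_checked_exp(mat.C4 * (l - 1.0)) - 1.0) / mat.C4 - (l - 1.0)
        )

    ls = mat.lambda_star
    if lam < ls:
        fib = toe_int(lam)
    else:
        fib = toe_int(ls) + 0.5 * mat.C5 * (lam ** 2 - ls ** 2) + mat.C6 * (
            lam - ls
        )
    return matrix + fib


def ligament_spring_energy(
    lam: float, mat: LigamentMaterial, area: float, natural_length: float
) -> float:
    """Potential energy [N*mm] of the tension-only 1-D ligament spring."""
    return area * natural_length * _uniaxial_tension_energy_density(lam, mat)


# ---------------------------------------------------------------------------
# meniscus compliance
# ---------------------------------------------------------------------------

def meniscus_compliance(mat: MeniscusMaterial) -> np.ndarray:
    """Assemble the 6x6 orthotropic compliance in (r, theta, z) axes [MPa^-1].

    Voigt order (rr, tt, zz, tz, rz, rt).  The normal block is symmetrised via
    the reciprocal relations nu_ij/E_i = nu_ji/E_j; assembly must be symmetric
    positive definite.
    """
    S = np.zeros((6, 6))
    S[0, 0] = 1.0 / mat.E_r
    S[1, 1] = 1.0 / mat.E_theta
    S[2, 2] = 1.0 / mat.E_z
    S[0, 2] = S[2, 0] = -mat.nu_rz / mat.E_r
    if mat.theta_ratio_convention == "major":
        # printed theta ratios read as fiber-major nu_theta_j / E_theta
        S[0, 1] = S[1, 0] = -mat.nu_rtheta / mat.E_theta
        S[1, 2] = S[2, 1] = -mat.nu_ztheta / mat.E_theta
    else:
        S[0, 1] = S[1, 0] = -mat.nu_rtheta / mat.E_r
        S[1, 2] = S[2, 1] = -mat.nu_ztheta / mat.E_z
    S[3, 3] = 1.0 / mat.G_ztheta
    S[4, 4] = 1.0 / mat.G_rz
    S[5, 5] = 1.0 / mat.G_rtheta
    eigvals = np.linalg.eigvalsh(S)
    if eigvals.min() <= 0:
        raise MaterialError(
            "assembled meniscus compliance is not positive definite "
            f"(min eigenvalue {eigvals.min():.3g} MPa^-1)"
        )
    return S


def meniscus_confined_axial_modulus(mat: MeniscusMaterial) -> float:
    """Constrained axial modulus C_zz [MPa] from the inverted compliance."""
    C = np.linalg.inv(meniscus_compliance(mat))
    return float(C[2, 2])


# ---------------------------------------------------------------------------
# shipped defaults
# ---------------------------------------------------------------------------

_LIGAMENT_TABLE = {
    # name: (C1, D1, C3, C4, C5, lambda_star)
    "ACL": (1.95, 0.01366, 0.0139, 116.22, 535.039, 1.046),
    "LCL": (1.44, 0.00252, 0.57, 48.0, 467.1, 1.062),
    "MCL": (1.44, 0.00252, 0.57, 48.0, 467.1, 1.062),
    "PCL": (3.25, 0.0082, 0.1196, 87.178, 431.063, 1.035),
}


def default_ligaments() -> Dict[str, LigamentMaterial]:
    """The four shipped ligament parameter sets."""
    return {
        name: LigamentMaterial(name, *params)
        for name, params in _LIGAMENT_TABLE.items()
    }


def default_meniscus(**overrides) -> MeniscusMaterial:
    return replace(MeniscusMaterial(), **overrides) if overrides else MeniscusMaterial()


def default_cartilage(**overrides) -> CartilageMaterial:
    return replace(CartilageMaterial(), **overrides) if overrides else CartilageMaterial()


def default_attachments(**overrides) -> AttachmentMaterial:
    return replace(AttachmentMaterial(), **overrides) if overrides else AttachmentMaterial()
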