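"""Layer material constants and per-station cross-section compliance.

The closure of the one-dimensional wave model is the linear elastic response
of each transverse section: how the syrinx and SAS areas and the cord axial
force react to the two fluid pressures and the cord axial strain.

* The cord is a thick-walled (Lame) annulus between the syrinx and its outer
  surface, in generalized plane strain so that the classical Poisson coupling
  between radial pressure and axial stress is retained.
* The dura is a thin hoop shell of thickness ``h_dura`` at the SAS radius,
  supported in parallel by the confined epidural fat annulus whose outer edge
  is fixed at the canal wall (the vertebral constraint).
* The fluids are water-like; their bulk modulus only adds a (negligible)
  volumetric compliance term, which is retained so the incompressible
  treatment in the solver can be justified quantitatively.

Per station the module assembles a symmetric positive-definite stiffness in
the conserved variables (syrinx area, SAS area, cord volumetric strain), the
form consumed directly by the wave solver.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import GeometryError, PhysicsError, SingularModulusError, ThinWallWarning
from .geometry import GeometryProfile

__all__ = [
    "LayerElastic",
    "FluidProps",
    "MaterialSet",
    "DEFAULT_MATERIALS",
    "derived_moduli",
    "lame_constants",
    "cord_annulus_compliance",
    "dura_compliance",
    "moens_korteweg_speed",
    "assemble_compliance_matrix",
    "ComplianceField",
]

#: cord annulus thickness ratio beyond which the thin-wall divergence warning fires
THIN_WALL_RATIO = 0.95


@dataclass(frozen=True)
class LayerElastic:
    """Isotropic linear-elastic solid layer."""

    E: float  # Young's modulus, Pa
    nu: float  # Poisson ratio
    rho: float  # density, kg/m^3

    def __post_init__(self):
        if self.E <= 0:
            raise PhysicsError(f"Young's modulus must be positive, got {self.E}")
        if not (0 <= self.nu < 0.5):
            if self.nu == 0.5:
                raise SingularModulusError("nu = 0.5 makes the elastic moduli singular")
            raise PhysicsError(f"Poisson ratio must lie in [0, 0.5), got {self.nu}")
        if self.rho <= 0:
            raise PhysicsError("density must be positive")


@dataclass(frozen=True)
class FluidProps:
    """Inviscid fluid (CSF and syrinx content)."""

    K: float  # bulk modulus, Pa
    rho: float  # kg/m^3
    G: float = 0.0  # shear modulus, identically zero for a true fluid

    def __post_init__(self):
        if self.K <= 0 or self.rho <= 0:
            raise PhysicsError("fluid K and rho must be positive")
        if self.G != 0.0:
            raise PhysicsError("fluid shear modulus must be exactly 0")


@dataclass(frozen=True)
class MaterialSet:
    cord: LayerElastic = field(default_factory=lambda: LayerElastic(62.5e3, 0.49, 1000.0))
    dura: LayerElastic = field(default_factory=lambda: LayerElastic(1.25e6, 0.40, 1000.0))
    fat: LayerElastic = field(default_factory=lambda: LayerElastic(1.0e3, 0.25, 900.0))
    fluid: FluidProps = field(default_factory=lambda: FluidProps(2.2e9, 1000.0))
    h_dura: float = 1.0e-3  # dural shell thickness, m

    def __post_init__(self):
        if self.h_dura <= 0:
            raise PhysicsError("dura thickness must be positive")

    def with_overrides(self, **kw) -> "MaterialSet":
        return replace(self, **kw)


DEFAULT_MATERIALS = MaterialSet()


def shear_modulus(E: float, nu: float) -> float:
    if nu == 0.5:
        raise SingularModulusError("nu = 0.5 makes the elastic moduli singular")
    return E / (2.0 * (1.0 + nu))


def plane_strain_modulus(E: float, nu: float) -> float:
    return E / (1.0 - nu**2)


def lame_constants(E: float, nu: float) -> tuple[float, float]:
    if nu == 0.5:
        raise SingularModulusError("nu = 0.5 makes the elastic moduli singular")
    lam = E * nu / ((1.0 + nu) * (1.0 - 2.0 * nu))
    mu = shear_modulus(E, nu)
    return lam, mu


def derived_moduli(ms: MaterialSet) -> dict[str, dict[str, float]]:
    """Shear and plane-strain moduli for every solid layer."""
    out = {}
    for name in ("cord", "dura", "fat"):
        layer: LayerElastic = getattr(ms, name)
        out[name] = {
            "G": shear_modulus(layer.E, layer.nu),
            "E_plane_strain": plane_strain_modulus(layer.E, layer.nu),
        }
    return out


def moens_korteweg_speed(E: float, h: float, R: float, rho: float) -> float:
    """Classical thin-tube pulse-wave speed sqrt(E h / (2 rho R))."""
    for name, v in (("E", E), ("h", h), ("R", R), ("rho", rho)):
        if v <= 0:
            raise PhysicsError(f"moens_korteweg_speed: {name} must be positive, got {v}")
    return float(np.sqrt(E * h / (2.0 * rho * R)))


# ---------------------------------------------------------------------------
# cross-section blocks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CordSectionBlock:
    """Mixed linear map of the cord annulus (generalized plane strain).

    (a_syrinx, a_outer, N) = T @ (p_syrinx, p_outer, e) where ``a_outer`` is
    the area swept by the cord outer surface, ``N`` the axial force and ``e``
    the axial strain.  ``S`` is the 2x2 radial compliance block in the
    pressures, ``g`` the Poisson coupling column, ``m`` the axial stiffness.
    Reciprocity makes dN/dp = -g automatically.
    """

    S: np.ndarray  # 2x2, m^2/Pa per unit length
    g: np.ndarray  # 2, m^2 (area change per unit axial strain)
    m: float  # Pa*m^2 (axial force per unit strain)


def cord_annulus_compliance(r_syrinx: float | None, r_cord: float,
                            E: float, nu: float) -> CordSectionBlock:
    """Lame thick-wall solution for the cord annulus (solid disc if no syrinx).

    Returns the mixed compliance block relating (p_syrinx, p at the outer
    surface, axial strain) to (syrinx area change, outer-surface area sweep,
    axial force).  Inner entries vanish exactly when there is no syrinx.
    """
    a = 0.0 if r_syrinx is None else float(r_syrinx)
    b = float(r_cord)
    if b <= 0:
        raise GeometryError("cord radius must be positive")
    if a >= b:
        raise GeometryError(f"syrinx radius {a} m >= cord radius {b} m")
    if a > THIN_WALL_RATIO * b:
        warnings.warn(
            f"cord wall very thin (r_syrinx/r_cord = {a / b:.3f} > {THIN_WALL_RATIO}); "
            "radial compliance diverges as the wall vanishes",
            ThinWallWarning, stacklevel=2,
        )
    lam, mu = lame_constants(E, nu)
    beta = 2.0 * (lam + mu)
    d = b**2 - a**2
    # displacement u(r) = C1 r + C2 / r ; sensitivities to (p1, p2, e)
    dC1 = np.array([a**2 / d, -(b**2) / d, -lam]) / beta
    dC2 = np.array([a**2 * b**2 / (2 * mu * d), -(a**2) * b**2 / (2 * mu * d), 0.0])
    da1 = 2 * np.pi * (dC1 * a**2 + dC2)
    daout = 2 * np.pi * (dC1 * b**2 + dC2)
    S = np.array([[da1[0], da1[1]], [daout[0], daout[1]]])
    g = np.array([da1[2], daout[2]])
    m = float(np.pi * d * (lam + 2 * mu - 2 * lam**2 / beta))  # == E * pi * d
    return CordSectionBlock(S=S, g=g, m=m)


@dataclass(frozen=True)
class DuraFoundation:
    """Radial stiffness of the dural shell with its epidural-fat backing."""

    c_dura: float  # SAS area compliance per unit length, m^2/Pa
    k_shell: float  # shell radial stiffness, Pa/m
    k_fat: float  # confined-fat foundation stiffness, Pa/m

    @property
    def k_radial(self) -> float:
        return self.k_shell + self.k_fat


def dura_compliance(r_sas: float, r_eds: float, ms: MaterialSet) -> DuraFoundation:
    """Hoop compliance of the dural tube on its epidural-fat foundation.

    The thin shell of thickness ``h_dura`` at radius ``r_sas`` and the
    plane-strain fat annulus (outer edge fixed at ``r_eds``) resist the same
    radial displacement, so their stiffnesses add.  The shell-only limit is
    c = 2 pi R^3 (1 - nu^2) / (E h).
    """
    R, Re = float(r_sas), float(r_eds)
    if R <= 0 or Re < R:
        raise GeometryError(f"need 0 < r_sas <= r_eds, got {R}, {Re}")
    k_shell = plane_strain_modulus(ms.dura.E, ms.dura.nu) * ms.h_dura / R**2
    if Re > R:
        lf, mf = lame_constants(ms.fat.E, ms.fat.nu)
        k_fat = (2 * (lf + mf) / Re**2 + 2 * mf / R**2) / (1.0 / R - R / Re**2)
    else:
        k_fat = np.inf  # zero fat gap against the rigid wall
    c = 0.0 if np.isinf(k_fat) else 2 * np.pi * R / (k_shell + k_fat)
    return DuraFoundation(c_dura=c, k_shell=k_shell, k_fat=k_fat)


# ---------------------------------------------------------------------------
# per-station assembly
# ---------------------------------------------------------------------------

def station_stiffness(r_syrinx: float | None, r_cord: float, r_sas: float,
                      r_eds: float, ms: MaterialSet,
                      include_fluid_compressibility: bool = True):
    """Symmetric stiffness K with p = K z, z = (a_syrinx, a_sas, a_cord).

    ``a_cord = -A_cord * e`` is the cord volumetric strain per unit length, so
    all three compartments obey the same conservation form and K stays
    symmetric (an energy functional exists).  Without a syrinx the first
    row/column is zero and only the trailing 2x2 block is active.

    Returns (K 3x3, S 2x2 compliance in the pressures, c_dura, k_radial).
    """
    cord = cord_annulus_compliance(r_syrinx, r_cord, ms.cord.E, ms.cord.nu)
    dura = dura_compliance(r_sas, r_eds, ms)
    a = 0.0 if r_syrinx is None else float(r_syrinx)
    A1 = np.pi * a**2
    Ac = np.pi * (r_cord**2 - a**2)
    A2 = np.pi * (r_sas**2 - r_cord**2)
    if A2 <= 0:
        raise GeometryError("SAS annulus area must be positive")

    # mixed map (a1, a2, N) <- (p1, p2, e):  a2 = c_dura p2 - a_outer
    S = np.array([
        [cord.S[0, 0], cord.S[0, 1]],
        [-cord.S[1, 0], dura.c_dura - cord.S[1, 1]],
    ])
    g = np.array([cord.g[0], -cord.g[1]])
    if include_fluid_compressibility:
        S[0, 0] += A1 / ms.fluid.K
        S[1, 1] += A2 / ms.fluid.K

    has_syx = a > 0
    if has_syx:
        Si = np.linalg.inv(S)
        Kpp = Si
        Kpe = -Si @ g
        ce = cord.m + g @ Si @ g
        M = np.zeros((3, 3))
        M[:2, :2] = Kpp
        M[:2, 2] = Kpe
        M[2, :2] = Kpe
        M[2, 2] = ce
        J = np.diag([1.0, 1.0, -1.0 / Ac])
        K3 = J @ M @ J
        Sout = S
    else:
        s22 = S[1, 1]
        g2 = g[1]
        kpp = 1.0 / s22
        kpe = -g2 / s22
        ce = cord.m + g2**2 / s22
        K3 = np.zeros((3, 3))
        K3[1, 1] = kpp
        K3[1, 2] = K3[2, 1] = -kpe / Ac
        K3[2, 2] = ce / Ac**2
        Sout = np.array([[0.0, 0.0], [0.0, s22]])
    return K3, Sout, dura.c_dura, dura.k_radial


@dataclass
class ComplianceField:
    """Per-station cross-section stiffness/compliance along a profile.

    ``stiffness[j]`` maps (a_syrinx, a_sas, a_cord) to (p_syrinx, p_sas,
    p_cord) where p_cord = -N/A_cord is the cord axial-stress-like conjugate;
    ``S[j]`` is the radial compliance in the pressures (area change per unit
    pressure); ``c_dura``/``k_radial`` describe the dural foundation.
    """

    stiffness: np.ndarray  # (n, 3, 3)
    S: np.ndarray  # (n, 2, 2)
    c_dura: np.ndarray  # (n,)
    k_radial: np.ndarray  # (n,)
    has_syrinx: np.ndarray  # (n,) bool

    @property
    def n_stations(self) -> int:
        return self.stiffness.shape[0]

    def active_compliance(self, j: int) -> np.ndarray:
        """The positive-definite compliance block actually present at j."""
        return self.S[j] if self.has_syrinx[j] else self.S[j][1:, 1:]


def assemble_compliance_matrix(profile: GeometryProfile, ms: MaterialSet,
                               include_fluid_compressibility: bool = True) -> ComplianceField:
    """Station-by-station assembly over a resampled profile."""
    n = profile.n_stations
    K = np.zeros((n, 3, 3))
    S = np.zeros((n, 2, 2))
    c_dura = np.zeros(n)
    k_rad = np.zeros(n)
    for j in range(n):
        try:
            rx = profile.r_syrinx[j] if profile.has_syrinx[j] else None
            K[j], S[j], c_dura[j], k_rad[j] = station_stiffness(
                rx, profile.r_cord[j], profile.r_sas[j], profile.r_eds[j], ms,
                include_fluid_compressibility,
            )
        except (GeometryError, PhysicsError) as exc:
            raise type(exc)(f"station {j} (s = {profile.s[j]:.4f} m): {exc}") from exc
    return ComplianceField(stiffness=K, S=S, c_dura=c_dura, k_radial=k_rad,
                           has_syrinx=profile.has_syrinx.copy())
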