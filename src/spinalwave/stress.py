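"""Curved-beam stress surrogate for the spinal cord.

Mechanism: when the craniocervical junction blocks CSF exchange, the cardiac
volume shift drags the cord axially.  Sliding a cord by ``u`` along a channel
of curvature ``kappa(s)`` forces a first-order rotation of its cross-sections,
``psi = kappa * u`` — the material tangent at a station must realign with the
channel tangent one sliding length away.  The forced rotation is then
partitioned into a bending part (curvature change ``dkappa = dpsi_b/ds``,
generating perimeter axial fibre stress) and a shear part
(``gamma = psi - psi_b``, generating transverse shear), by a quasi-static
energy minimum of a Timoshenko cord restrained by the canal:

    min over psi_b of  1/2 * int [ E I (psi_b')^2          (bending)
                                 + G A (psi - psi_b)^2      (internal shear)
                                 + k_rot psi_b^2 ] ds       (canal restraint)

with free rotation (natural) boundary conditions.  The restraint stiffness is
the series combination of the canal's radial stiffness acting over the snug
perimeter lever (``k_radial * r_cord^3``) and the cord's own shear rigidity
``G A`` — neither path can transmit more rotation restraint than it
possesses.  A truly inviscid annulus cannot restrain section rotation in
closed form; this term is the 1-D surrogate for the three-dimensional snug
contact load transfer, and its rigid-canal limit is an even bending/shear
split rather than pure conformation.  Quasi-static evaluation per saved time
step is valid because the cord displacement evolves at cardiac frequency,
far below the mode transit rates of the canal.

Stress composition at the perimeter fibre (worst case, magnitudes):
radial = |p_sas|, axial = |p_sas| + E r |dkappa|, shear = G |gamma|.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import solveh_banded

from .errors import AlignmentError, ConfigurationError
from .geometry import GeometryProfile
from .materials import MaterialSet, shear_modulus

__all__ = [
    "transport_rotation",
    "solve_constrained_beam",
    "compose_stress",
    "closed_form_check",
    "BeamPartition",
    "StressFields",
]


def _check_grid(profile: GeometryProfile, fld: np.ndarray, name: str) -> None:
    if fld.shape[-1] != profile.n_stations:
        raise AlignmentError(
            f"{name} has {fld.shape[-1]} stations, profile has {profile.n_stations}")


def transport_rotation(profile: GeometryProfile, u_cord: np.ndarray) -> np.ndarray:
    """Forced section rotation psi(s, t) = kappa(s) * u_cord(s, t), radians."""
    u_cord = np.asarray(u_cord, dtype=float)
    _check_grid(profile, u_cord, "u_cord")
    return profile.kappa * u_cord


@dataclass
class BeamPartition:
    """Bending/shear split of the forced rotation at each saved time."""

    psi: np.ndarray  # forced rotation (nt, n)
    psi_b: np.ndarray  # bending rotation
    dkappa: np.ndarray  # curvature change, 1/m
    gamma: np.ndarray  # shear strain
    k_rot: np.ndarray  # restraint stiffness used, N


def cord_section_properties(profile: GeometryProfile, ms: MaterialSet):
    """Area, second moment (annulus-corrected where a syrinx exists) and
    shear rigidity of the cord along the profile."""
    rc = profile.r_cord
    rs = np.where(profile.has_syrinx, profile.r_syrinx, 0.0)
    A = np.pi * (rc**2 - rs**2)
    I = np.pi * (rc**4 - rs**4) / 4.0
    G = shear_modulus(ms.cord.E, ms.cord.nu)
    return A, I, G


def solve_constrained_beam(profile: GeometryProfile, ms: MaterialSet,
                           u_cord: np.ndarray,
                           k_radial: np.ndarray) -> BeamPartition:
    """Quasi-static Timoshenko partition of the forced rotation.

    ``u_cord`` is (nt, n) on the profile stations; ``k_radial`` (Pa/m) is the
    local radial stiffness of the dura/fat path (from the compliance
    assembly).  Solved independently at each saved time step by one banded
    SPD factorization shared across steps.
    """
    u_cord = np.atleast_2d(np.asarray(u_cord, dtype=float))
    _check_grid(profile, u_cord, "u_cord")
    k_radial = np.asarray(k_radial, dtype=float)
    _check_grid(profile, k_radial, "k_radial")
    if np.any(profile.A_sas <= 0):
        raise ConfigurationError("zero SAS gap: the foundation is singular")

    n = profile.n_stations
    ds = profile.ds
    A, I, G = cord_section_properties(profile, ms)
    GA = G * A
    k_contact = k_radial * profile.r_cord**3
    k_rot = k_contact * GA / (k_contact + GA)

    psi = transport_rotation(profile, u_cord)

    # operator  -d/ds(EI d/ds) + (GA + k_rot)  with natural (free-rotation)
    # boundary conditions, assembled in symmetric banded form
    EI = ms.cord.E * I
    EI_half = 0.5 * (EI[1:] + EI[:-1]) / ds**2
    diag = np.zeros(n)
    diag[:-1] += EI_half
    diag[1:] += EI_half
    diag += GA + k_rot
    ab = np.zeros((2, n))
    ab[0, 1:] = -EI_half  # superdiagonal
    ab[1, :] = diag
    rhs = (GA * psi).T  # (n, nt)
    psi_b = solveh_banded(ab, rhs, lower=False).T

    dkappa = np.gradient(psi_b, ds, axis=-1)
    gamma = psi - psi_b
    return BeamPartition(psi=psi, psi_b=psi_b, dkappa=dkappa, gamma=gamma,
                         k_rot=k_rot)


@dataclass
class StressFields:
    """Perimeter stress component magnitudes (nt, n), Pa."""

    radial: np.ndarray
    axial: np.ndarray
    shear: np.ndarray


def compose_stress(p_sas: np.ndarray, dkappa: np.ndarray, gamma: np.ndarray,
                   profile: GeometryProfile, ms: MaterialSet) -> StressFields:
    """Combine SAS pressure and beam fields into perimeter stress magnitudes.

    The normal stresses in the cord are compressive; magnitudes are reported.
    The axial component adds the bending fibre stress to the pressure in the
    worst-case (magnitude-additive) sense.
    """
    p_sas = np.atleast_2d(np.asarray(p_sas, dtype=float))
    for name, f in (("p_sas", p_sas), ("dkappa", dkappa), ("gamma", gamma)):
        _check_grid(profile, np.atleast_2d(f), name)
    if p_sas.shape != np.atleast_2d(dkappa).shape:
        raise AlignmentError("p_sas and dkappa must share the (nt, n) grid")
    G = shear_modulus(ms.cord.E, ms.cord.nu)
    radial = np.abs(p_sas)
    axial = np.abs(p_sas) + ms.cord.E * profile.r_cord * np.abs(dkappa)
    shear = G * np.abs(gamma)
    return StressFields(radial=radial, axial=axial, shear=shear)


def closed_form_check(profile: GeometryProfile, ms: MaterialSet,
                      u_cord: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Independent order-of-magnitude oracle for the beam partition.

    sigma_axial ~ E r |u| |dkappa/ds| (fully conforming bending) and
    tau ~ G |kappa u| (fully non-rotating shear) bracket the partitioned
    solution from above component-wise.
    """
    u_cord = np.atleast_2d(np.asarray(u_cord, dtype=float))
    _check_grid(profile, u_cord, "u_cord")
    dkds = np.gradient(profile.kappa, profile.ds)
    G = shear_modulus(ms.cord.E, ms.cord.nu)
    sigma = ms.cord.E * profile.r_cord * np.abs(u_cord) * np.abs(dkds)
    tau = G * np.abs(profile.kappa * u_cord)
    return sigma, tau
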