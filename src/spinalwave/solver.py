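"""Linearized 1-D coaxial fluid-structure wave solver.

Three coupled compartments share the canal cross-section: the syrinx fluid,
the SAS fluid, and the elastic cord treated as a third "compartment" whose
conserved variable is its volumetric strain per unit length
``a_cord = -A_cord du/ds``.  With that choice every compartment obeys the
same conservation/momentum pair

    da_i/dt + d(A_i v_i)/ds = 0,      rho_i dv_i/dt = -dp_i/ds,

closed by the symmetric per-station stiffness p = K(s) a from
:mod:`spinalwave.materials` (for the cord, p_cord = -N/A_cord, so its
momentum row is the axial elastic force balance including the Poisson
coupling to both fluid pressures).  Curvature never enters the propagation
equations: arc length is the coordinate, and pulse transmission in this model
is insensitive to the sagittal shape of the canal.

Spatial discretization is a staggered conservative grid (areas/pressures at
stations, velocities at half-stations) whose semi-discrete energy is exactly
conserved for closed boundaries; time marching is implicit midpoint
(unconditionally stable and energy-conservative for this linear system), with
an explicit leapfrog available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .errors import (
    PhysicsError,
    ResolutionError,
    SolverBlowupError,
    StabilityError,
    UsageError,
)
from .geometry import GeometryProfile
from .materials import ComplianceField, MaterialSet

__all__ = [
    "Excitation",
    "Scenario",
    "ScenarioConfig",
    "LinearSystem",
    "WaveField",
    "ModeResult",
    "assemble_system",
    "simulate",
    "compute_mode_speeds",
    "mode_speeds_from_matrices",
    "wavefront_speeds",
    "pressure_summary",
    "PressureSummary",
]

MMHG = 133.322  # Pa per mmHg


# ---------------------------------------------------------------------------
# excitation and scenarios
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Excitation:
    """Volumetric inflow applied at the cranial face.

    The cardiac input is ``Q0 sin(2 pi t / period)`` (period 0.4 s = 150 bpm,
    the upper limit of the CKCS heart rate); the transient probe is a half-sine
    pulse of duration ``pulse_duration``.
    """

    kind: str  # "cardiac_sinusoid" | "transient_pulse"
    Q0: float = 0.35e-6  # m^3/s
    period: float = 0.4  # s
    pulse_duration: float = 0.01  # s
    n_cycles: int = 4

    def __post_init__(self):
        if self.kind not in ("cardiac_sinusoid", "transient_pulse"):
            raise UsageError(f"unknown excitation kind {self.kind!r}")
        if self.Q0 < 0:
            raise UsageError("Q0 must be nonnegative")
        if self.kind == "cardiac_sinusoid" and self.period <= 0:
            raise UsageError("cardiac excitation needs period > 0")
        if self.kind == "transient_pulse" and self.pulse_duration <= 0:
            raise UsageError("transient excitation needs pulse_duration > 0")

    @classmethod
    def cardiac(cls, Q0=0.35e-6, period=0.4, n_cycles=4) -> "Excitation":
        return cls("cardiac_sinusoid", Q0=Q0, period=period, n_cycles=n_cycles)

    @classmethod
    def pulse(cls, Q0=0.35e-6, duration=0.01) -> "Excitation":
        return cls("transient_pulse", Q0=Q0, pulse_duration=duration)

    def flow(self, t: np.ndarray | float) -> np.ndarray | float:
        if self.kind == "cardiac_sinusoid":
            return self.Q0 * np.sin(2 * np.pi * np.asarray(t) / self.period)
        t = np.asarray(t)
        return np.where(
            (t >= 0) & (t <= self.pulse_duration),
            self.Q0 * np.sin(np.pi * t / self.pulse_duration), 0.0)

    @property
    def duration(self) -> float:
        return self.n_cycles * self.period if self.kind == "cardiac_sinusoid" \
            else self.pulse_duration


class Scenario(str, Enum):
    NORMAL = "normal"
    CHIARI_NO_SYRINX = "chiari_no_syrinx"
    CHIARI_WITH_SYRINX = "chiari_with_syrinx"
    PULSE_PRELIMINARY = "pulse_preliminary"


@dataclass(frozen=True)
class ScenarioConfig:
    """Craniocervical boundary-condition variant.

    Caudal ends of cord and SAS are always fixed/closed.  ``open_inflow``
    prescribes the volumetric input as SAS inflow with the cord face fixed
    (normal craniocervical junction); ``blocked`` moves the whole cranial face
    (cord plus the trapped CSF column, a piston) with the velocity that
    accommodates the same volumetric input.
    """

    scenario: Scenario
    cranial_cord_bc: str  # "fixed" | "free"
    cranial_csf_bc: str  # "open_inflow" | "blocked"
    syrinx_included: bool

    @classmethod
    def from_scenario(cls, scenario: Scenario | str) -> "ScenarioConfig":
        scenario = Scenario(scenario)
        table = {
            Scenario.NORMAL: ("fixed", "open_inflow", False),
            Scenario.CHIARI_NO_SYRINX: ("free", "blocked", False),
            Scenario.CHIARI_WITH_SYRINX: ("free", "blocked", True),
            Scenario.PULSE_PRELIMINARY: ("fixed", "open_inflow", True),
        }
        cord, csf, syx = table[scenario]
        return cls(scenario, cord, csf, syx)


# ---------------------------------------------------------------------------
# semidiscrete system
# ---------------------------------------------------------------------------

@dataclass
class LinearSystem:
    """Semidiscrete dz/dt = L z + f Q(t) on the staggered grid."""

    L: sp.csr_matrix
    f: np.ndarray
    profile: GeometryProfile
    compliance: ComplianceField
    scenario: ScenarioConfig
    rho_fluid: float
    rho_cord: float
    n: int  # stations
    idx: dict  # state slices
    A: np.ndarray  # (n, 3) station areas (syrinx, sas, cord)
    A_half: np.ndarray  # (n-1, 3)
    v1_active: np.ndarray  # (n-1,) bool

    @property
    def size(self) -> int:
        return self.L.shape[0]

    def state_parts(self, z: np.ndarray):
        i = self.idx
        return {k: z[..., v] for k, v in i.items()}

    # --- diagnostics used by the invariant suite -------------------------
    def stored_volume(self, z: np.ndarray) -> np.ndarray:
        """Net volume stored in all compartments (syrinx, SAS, cord column)."""
        w = np.ones(self.n)
        w[0] = w[-1] = 0.5
        ds = self.profile.ds
        a = z[..., self.idx["a1"]] + z[..., self.idx["a2"]] + z[..., self.idx["a3"]]
        return (a * w).sum(axis=-1) * ds

    def energy(self, z: np.ndarray) -> np.ndarray:
        """Total (elastic + kinetic) energy of a state."""
        ds = self.profile.ds
        w = np.ones(self.n)
        w[0] = w[-1] = 0.5
        a = np.stack([z[..., self.idx["a1"]], z[..., self.idx["a2"]],
                      z[..., self.idx["a3"]]], axis=-1)
        K = self.compliance.stiffness
        elastic = 0.5 * np.einsum("...ji,jik,...jk,j->...", a, K, a, w) * ds
        rho = np.array([self.rho_fluid, self.rho_fluid, self.rho_cord])
        v = np.stack([z[..., self.idx["v1"]], z[..., self.idx["v2"]],
                      z[..., self.idx["vc"]]], axis=-1)
        kinetic = 0.5 * np.einsum("...ji,ji,...ji->...", v, self.A_half * rho, v) * ds
        return elastic + kinetic


def assemble_system(profile: GeometryProfile, compliance: ComplianceField,
                    scenario: ScenarioConfig | Scenario | str,
                    ms: MaterialSet | None = None) -> LinearSystem:
    """Build the semidiscrete operator and forcing for one scenario.

    State layout: areas a1 (syrinx), a2 (SAS), a3 (cord strain variable) at
    the ``n`` stations; velocities v1, v2, vc and cord displacement u at the
    ``n-1`` half-stations.  Inactive syrinx degrees of freedom are frozen.
    """
    if not isinstance(scenario, ScenarioConfig):
        scenario = ScenarioConfig.from_scenario(scenario)
    ms = ms or MaterialSet()
    n = profile.n_stations
    h = n - 1
    ds = profile.ds
    rho_f = ms.fluid.rho
    rho_c = ms.cord.rho

    if scenario.syrinx_included != bool(profile.has_syrinx.any()):
        # the pipeline normally reconciles this; keep the solver strict
        if scenario.syrinx_included:
            raise UsageError("scenario includes a syrinx but the profile has none")

    A = np.column_stack([profile.A_syrinx, profile.A_sas, profile.A_cord])
    A_half = 0.5 * (A[1:] + A[:-1])
    syx_st = profile.has_syrinx & (A[:, 0] > 0)
    v1_active = syx_st[1:] & syx_st[:-1]
    A_half[~v1_active, 0] = 0.0

    ofs = 0
    idx = {}
    for name, size in (("a1", n), ("a2", n), ("a3", n),
                       ("v1", h), ("v2", h), ("vc", h), ("u", h)):
        idx[name] = slice(ofs, ofs + size)
        ofs += size
    size = ofs

    K = compliance.stiffness  # (n, 3, 3) rows/cols (a1, a2, a3)
    rows, cols, vals = [], [], []

    def add(r, c, v):
        if v != 0.0:
            rows.append(r)
            cols.append(c)
            vals.append(v)

    a_of = [idx["a1"].start, idx["a2"].start, idx["a3"].start]
    v_of = [idx["v1"].start, idx["v2"].start, idx["vc"].start]
    rho_of = [rho_f, rho_f, rho_c]

    # momentum: dv_i,h/dt = -(p_i,j+1 - p_i,j) / (rho_i ds)
    for hh in range(h):
        j, j1 = hh, hh + 1
        for i in range(3):
            if i == 0 and not v1_active[hh]:
                continue
            r = v_of[i] + hh
            for l in range(3):
                add(r, a_of[l] + j1, -K[j1][i, l] / (rho_of[i] * ds))
                add(r, a_of[l] + j, +K[j][i, l] / (rho_of[i] * ds))

    # mass: da_i,j/dt = -(F_h - F_{h-1}) / (w_j ds), F = A_half v
    for j in range(n):
        w = 0.5 if j in (0, n - 1) else 1.0
        for i in range(3):
            if i == 0 and not syx_st[j]:
                continue
            r = a_of[i] + j
            if j < n - 1 and (i != 0 or v1_active[j]):
                add(r, v_of[i] + j, -A_half[j, i] / (w * ds))
            if j > 0 and (i != 0 or v1_active[j - 1]):
                add(r, v_of[i] + j - 1, +A_half[j - 1, i] / (w * ds))

    # displacement integrator du_h/dt = vc_h
    for hh in range(h):
        add(idx["u"].start + hh, v_of[2] + hh, 1.0)

    L = sp.coo_matrix((vals, (rows, cols)), shape=(size, size)).tocsr()

    # forcing: boundary face fluxes at the cranial end (unit inflow Q = 1)
    f = np.zeros(size)
    half_cell = 0.5 * ds
    if scenario.cranial_csf_bc == "open_inflow":
        f[idx["a2"].start] = 1.0 / half_cell
    else:  # blocked: piston of cord + trapped fluid columns
        areas = [A[0, i] for i in range(3)]
        if not syx_st[0]:
            areas[0] = 0.0
        A_tot = sum(areas)
        for i in range(3):
            if areas[i] > 0:
                f[a_of[i]] = (areas[i] / A_tot) / half_cell

    return LinearSystem(L=L, f=f, profile=profile, compliance=compliance,
                        scenario=scenario, rho_fluid=rho_f, rho_cord=rho_c,
                        n=n, idx=idx, A=A, A_half=A_half, v1_active=v1_active)


# ---------------------------------------------------------------------------
# time marching
# ---------------------------------------------------------------------------

@dataclass
class WaveField:
    """Saved space-time fields of one run (stations unless noted)."""

    t: np.ndarray  # (nt,)
    s: np.ndarray  # (n,)
    s_half: np.ndarray  # (n-1,)
    p_syrinx: np.ndarray  # (nt, n) Pa
    p_sas: np.ndarray  # (nt, n) Pa
    a: np.ndarray  # (nt, n, 3) area perturbations
    v_syrinx: np.ndarray  # (nt, n-1) m/s (half-stations)
    v_sas: np.ndarray  # (nt, n-1)
    v_cord: np.ndarray  # (nt, n-1)
    u_cord: np.ndarray  # (nt, n-1) m
    Q: np.ndarray  # (nt,) applied inflow
    excitation: Excitation
    scenario: ScenarioConfig
    profile: GeometryProfile
    dt: float
    system: LinearSystem = field(repr=False)
    states: np.ndarray = field(repr=False)  # (nt, size) raw saved states

    def station_field(self, half_field: np.ndarray) -> np.ndarray:
        """Average a half-station field onto stations (one-sided at ends)."""
        out = np.empty(half_field.shape[:-1] + (self.s.size,))
        out[..., 1:-1] = 0.5 * (half_field[..., 1:] + half_field[..., :-1])
        out[..., 0] = half_field[..., 0]
        out[..., -1] = half_field[..., -1]
        return out

    @property
    def u_cord_stations(self) -> np.ndarray:
        return self.station_field(self.u_cord)

    @property
    def v_cord_stations(self) -> np.ndarray:
        return self.station_field(self.v_cord)

    def final_cycle_mask(self) -> np.ndarray:
        if self.excitation.kind != "cardiac_sinusoid":
            raise UsageError("final cycle is only defined for cardiac runs")
        t0 = (self.excitation.n_cycles - 1) * self.excitation.period
        return self.t >= t0 - 1e-12


def simulate(system: LinearSystem, excitation: Excitation,
             duration: float | None = None, dt: float = 1e-4,
             save_stride: int = 10, integrator: str = "midpoint") -> WaveField:
    """March the semidiscrete system from rest and return saved fields.

    ``midpoint`` (default) is the unconditionally stable, energy-conserving
    implicit midpoint rule; ``leapfrog`` is an explicit kick-drift scheme that
    must respect the CFL bound of the fastest mode.
    """
    if duration is None:
        duration = excitation.duration
    n_steps = int(round(duration / dt))
    if n_steps < 1:
        raise UsageError("duration shorter than one time step")
    L, f = system.L, system.f
    size = system.size

    if integrator == "leapfrog":
        c_max = _max_mode_speed(system)
        dt_cfl = system.profile.ds / c_max
        if dt > dt_cfl:
            raise StabilityError(
                f"explicit dt = {dt} exceeds CFL bound {dt_cfl:.3e} s "
                f"(fastest mode {c_max:.2f} m/s at ds = {system.profile.ds} m)",
                suggested_dt=0.5 * dt_cfl)
        # symplectic kick-drift: positions (areas, u) advance first with the
        # current velocities, velocities then use the updated pressures
        vel_mask = np.zeros(size, dtype=bool)
        for key in ("v1", "v2", "vc"):
            vel_mask[system.idx[key]] = True
        pos_ix = np.flatnonzero(~vel_mask)
        vel_ix = np.flatnonzero(vel_mask)
        Lp = L[pos_ix].tocsr()
        Lv = L[vel_ix].tocsr()
        f_pos = f[pos_ix]

        def step(z, t):
            z = z.copy()
            z[pos_ix] += dt * (Lp @ z + f_pos * float(excitation.flow(t + 0.5 * dt)))
            z[vel_ix] += dt * (Lv @ z)
            return z
    elif integrator == "midpoint":
        eye = sp.identity(size, format="csc")
        lu = splu((eye - 0.5 * dt * L).tocsc())
        B = (eye + 0.5 * dt * L).tocsr()

        def step(z, t):
            rhs = B @ z + dt * f * float(excitation.flow(t + 0.5 * dt))
            return lu.solve(rhs)
    else:
        raise UsageError(f"unknown integrator {integrator!r}")

    z = np.zeros(size)
    saved = [z.copy()]
    t_saved = [0.0]
    t = 0.0
    for k in range(n_steps):
        z = step(z, t)
        t = (k + 1) * dt
        if (k + 1) % save_stride == 0 or k == n_steps - 1:
            if not np.isfinite(z[:: max(1, size // 64)]).all():
                raise SolverBlowupError(
                    f"non-finite state at t = {t:.5f} s "
                    f"(first bad index {int(np.flatnonzero(~np.isfinite(z))[0])})")
            saved.append(z.copy())
            t_saved.append(t)

    states = np.array(saved)
    t_arr = np.array(t_saved)
    i = system.idx
    a = np.stack([states[:, i["a1"]], states[:, i["a2"]], states[:, i["a3"]]], axis=-1)
    K = system.compliance.stiffness
    p = np.einsum("jkl,tjl->tjk", K, a)
    prof = system.profile
    return WaveField(
        t=t_arr, s=prof.s, s_half=0.5 * (prof.s[1:] + prof.s[:-1]),
        p_syrinx=p[:, :, 0], p_sas=p[:, :, 1], a=a,
        v_syrinx=states[:, i["v1"]], v_sas=states[:, i["v2"]],
        v_cord=states[:, i["vc"]], u_cord=states[:, i["u"]],
        Q=np.asarray(excitation.flow(t_arr), dtype=float),
        excitation=excitation, scenario=system.scenario, profile=prof,
        dt=dt, system=system, states=states,
    )


def _max_mode_speed(system: LinearSystem) -> float:
    c = 0.0
    comp = system.compliance
    for j in range(system.n):
        res = _station_modes(system.profile, comp, j,
                             system.rho_fluid, system.rho_cord)
        c = max(c, res[0].max())
    return c


# ---------------------------------------------------------------------------
# eigenmodes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModeResult:
    """Propagating plane-wave modes of one uniform cross-section.

    ``speeds`` ascend; ``shapes[k]`` holds the relative signed axial-velocity
    amplitudes (syrinx fluid, cord, SAS fluid) normalized to unit maximum.
    """

    speeds: np.ndarray
    shapes: list[np.ndarray]
    station: int | None = None


def mode_speeds_from_matrices(K: np.ndarray, A: np.ndarray,
                              rho: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Plane-wave eigenproblem c^2 z = diag(A/rho) K z.

    K is the symmetric stiffness in the conserved variables, A the compartment
    areas, rho the densities.  Returns ascending speeds and the corresponding
    velocity-space eigenvectors v_i ~ z_i / A_i (columns).
    """
    K = np.asarray(K, dtype=float)
    A = np.asarray(A, dtype=float)
    rho = np.asarray(rho, dtype=float)
    Dh = np.diag(np.sqrt(A / rho))
    B = Dh @ K @ Dh
    w, V = np.linalg.eigh(0.5 * (B + B.T))
    if np.any(w <= 0):
        raise PhysicsError(f"cross-section stiffness not positive definite (c^2 = {w})")
    order = np.argsort(w)
    speeds = np.sqrt(w[order])
    vel = (Dh @ V[:, order]) / A[:, None]
    return speeds, vel


def _station_modes(profile, comp, j, rho_f, rho_c):
    A3 = np.array([profile.A_syrinx[j], profile.A_sas[j], profile.A_cord[j]])
    rho3 = np.array([rho_f, rho_f, rho_c])
    K = comp.stiffness[j]
    if comp.has_syrinx[j] and A3[0] > 0:
        return mode_speeds_from_matrices(K, A3, rho3)
    return mode_speeds_from_matrices(K[1:, 1:], A3[1:], rho3[1:])


def compute_mode_speeds(profile: GeometryProfile, compliance: ComplianceField,
                        station: int, ms: MaterialSet | None = None) -> ModeResult:
    """Eigenmode speeds and layer-motion shapes at one station.

    Three propagating modes exist where a syrinx is present, two otherwise.
    Shapes are reported in (syrinx fluid, cord, SAS fluid) order.
    """
    ms = ms or MaterialSet()
    speeds, vel = _station_modes(profile, compliance, station,
                                 ms.fluid.rho, ms.cord.rho)
    shapes = []
    with_syx = vel.shape[0] == 3
    for k in range(speeds.size):
        v = vel[:, k]
        if with_syx:
            out = np.array([v[0], v[2], v[1]])  # (syrinx, cord, sas)
        else:
            out = np.array([0.0, v[1], v[0]])
        shapes.append(out / np.max(np.abs(out)))
    return ModeResult(speeds=speeds, shapes=shapes, station=station)


# ---------------------------------------------------------------------------
# wavefront tracking (independent time-of-flight oracle)
# ---------------------------------------------------------------------------

def wavefront_speeds(fieldv: WaveField, threshold: float = 0.3,
                     s_min: float | None = None,
                     min_points: int = 6) -> dict:
    """Estimate per-mode propagation speeds from packet arrival times.

    At every station the local velocity vector (syrinx, SAS, cord) is
    projected on that station's eigenmode shapes (the layer-motion sign
    signatures); a branch's arrival at a station is the time of its modal
    amplitude maximum (stations below ``threshold`` of the branch maximum, or
    whose packet has not peaked inside the window, are excluded), and a
    robust Theil-Sen fit of distance versus arrival time gives the branch
    speed.  This is a time-of-flight measurement, independent of the eigen
    *values*.
    """
    prof = fieldv.profile
    sys_ = fieldv.system
    comp = sys_.compliance
    s_half = fieldv.s_half
    if s_min is None:
        s_min = prof.extension_length + 5 * prof.ds

    # per half-station mode projections
    n_half = s_half.size
    has3 = sys_.v1_active
    n_modes = 3 if has3.any() else 2
    eta = np.full((n_modes, fieldv.t.size, n_half), np.nan)
    for hh in range(n_half):
        j = hh  # use the cranial-side station's shapes
        try:
            speeds, vel = _station_modes(prof, comp, j, sys_.rho_fluid, sys_.rho_cord)
        except PhysicsError:
            continue
        v_loc = [fieldv.v_syrinx[:, hh], fieldv.v_sas[:, hh], fieldv.v_cord[:, hh]]
        if vel.shape[0] == 3:
            if not has3[hh]:
                continue
            V = np.stack(v_loc, axis=-1)
            coef = np.linalg.lstsq(vel, V.T, rcond=None)[0]
            eta[:, :, hh] = coef
        else:
            V = np.stack([v_loc[1], v_loc[2]], axis=-1)
            coef = np.linalg.lstsq(vel, V.T, rcond=None)[0]
            if n_modes == 3:
                # geometry has a syrinx elsewhere; align slow/fast by speed rank
                eta[0, :, hh] = np.nan
                eta[1:, :, hh] = coef
            else:
                eta[:, :, hh] = coef

    out = {"speeds": [], "n_points": [], "residual": []}
    sel = s_half >= s_min
    nt = fieldv.t.size
    for m in range(n_modes):
        amp = np.nan_to_num(np.abs(eta[m][:, sel]))
        if not amp.any():
            raise ResolutionError(f"mode {m}: no usable stations")
        ref = amp.max()
        t_arr, s_arr = [], []
        for k, hh in enumerate(np.flatnonzero(sel)):
            col = amp[:, k]
            # only stations the mode's packet has genuinely reached and passed:
            # track the packet peak (group arrival), excluding window-truncated
            # peaks; cross-mode leakage is rejected by the amplitude gate plus
            # the robust fit below
            if col.max() < threshold * ref:
                continue
            t_pk = int(col.argmax())
            if t_pk >= nt - 2 or t_pk <= 1:
                continue
            t_arr.append(fieldv.t[t_pk])
            s_arr.append(s_half[hh])
        t_arr, s_arr = np.array(t_arr), np.array(s_arr)
        spread = np.unique(t_arr).size
        if t_arr.size < min_points or spread < 3:
            raise ResolutionError(
                f"mode {m}: wavefront not resolved ({t_arr.size} arrivals, "
                f"{spread} distinct times); lengthen the run or shorten the pulse")
        # median-of-pairwise-slopes fit: immune to the minority of stations
        # contaminated by other branches
        from scipy.stats import theilslopes
        slope, intercept, _, _ = theilslopes(s_arr, t_arr)
        if slope <= 0:
            raise ResolutionError(f"mode {m}: non-causal arrival fit")
        resid = np.sqrt(np.median((s_arr - (slope * t_arr + intercept)) ** 2))
        out["speeds"].append(float(slope))
        out["n_points"].append(int(t_arr.size))
        out["residual"].append(float(resid))
    out["speeds"] = np.array(out["speeds"])
    return out


# ---------------------------------------------------------------------------
# cardiac-cycle summary
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PressureSummary:
    """Final-cycle scalars of a cardiac run (pressures in Pa)."""

    p_amp_zero_to_peak: float  # max |p_sas| at mid-length
    p_amp_harmonic: float  # half peak-to-peak at mid-length
    dp_craniocaudal_max: float  # max |p_sas(cranial) - p_sas(caudal)|
    v_sas_peak_cranial: float
    v_cord_peak_cranial: float
    v_syrinx_peak_cranial: float
    u_cord_peak_to_peak: float  # max over stations, m
    u_cord_caudal_max: float  # largest caudally directed displacement, m

    @property
    def dp_craniocaudal_mmhg(self) -> float:
        return self.dp_craniocaudal_max / MMHG

    @property
    def p_amp_mmhg(self) -> float:
        return self.p_amp_zero_to_peak / MMHG


def pressure_summary(fieldv: WaveField) -> PressureSummary:
    """Zero-to-peak SAS pressure, end-to-end gradient and peak kinematics
    over the final cardiac cycle."""
    if fieldv.excitation.kind != "cardiac_sinusoid":
        raise UsageError("pressure_summary requires a cardiac run")
    mask = fieldv.final_cycle_mask()
    prof = fieldv.profile
    ext = prof.extension_length
    mid = prof.station_nearest(ext + 0.5 * (prof.s[-1] - ext))
    p_mid = fieldv.p_sas[mask][:, mid]
    p2 = fieldv.p_sas[mask]
    dp = np.abs(p2[:, 0] - p2[:, -1]).max()
    c2_half = int(np.argmin(np.abs(fieldv.s_half - ext)))
    u = fieldv.u_cord[mask]
    return PressureSummary(
        p_amp_zero_to_peak=float(np.abs(p_mid).max()),
        p_amp_harmonic=float(0.5 * (p_mid.max() - p_mid.min())),
        dp_craniocaudal_max=float(dp),
        v_sas_peak_cranial=float(np.abs(fieldv.v_sas[mask][:, c2_half]).max()),
        v_cord_peak_cranial=float(np.abs(fieldv.v_cord[mask][:, c2_half]).max()),
        v_syrinx_peak_cranial=float(np.abs(fieldv.v_syrinx[mask][:, c2_half]).max())
        if fieldv.system.v1_active.any() else 0.0,
        u_cord_peak_to_peak=float((u.max(axis=0) - u.min(axis=0)).max()),
        u_cord_caudal_max=float(max(u.max(), 0.0)),
    )
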