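"""Curved multi-layer spinal-canal geometry.

The canal is described by a sagittal centreline (x cranial->caudal, y
ventral->dorsal) with four nested, circular, concentric layers around it:
an optional syrinx cavity inside the spinal cord, the cord itself, the
subarachnoid space (SAS) and the epidural space (EDS).  Tabulated transverse
sections (millimetres, as printed in anatomical tables) are interpolated with
C2-continuous cubic splines onto a uniform arc-length grid in SI units,
together with per-station cross-sectional areas and the signed sagittal
curvature.  A straight cranial extension can be prepended so the physiological
inlet is loaded away from the region of interest.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .errors import GeometryError, InsufficientDataError, OrderingError

__all__ = [
    "CenterlineSample",
    "GeometryProfile",
    "load_centerline_table",
    "load_centerline_workbook",
    "write_centerline_table",
    "resample_profile",
    "compute_curvature",
    "extend_cranially",
]

MM = 1e-3
#: canonical column order of the geometry table dialect
TABLE_COLUMNS = ("x_mm", "y_mm", "r_syrinx_mm", "r_cord_mm", "r_sas_mm", "r_eds_mm")
#: maximum believable radius for a canine spinal canal, mm
_MAX_RADIUS_MM = 20.0
#: sentinel strings treated as "absent" in delimited tables
_ABSENT = {"", "-", "–", "—", "na", "nan", "none"}


@dataclass(frozen=True)
class CenterlineSample:
    """One tabulated transverse section (all values in millimetres).

    ``None`` marks an absent radius (no syrinx at that level, or a terminal
    station where the table prints no value); absence is never encoded as 0.
    """

    x_mm: float
    y_mm: float
    r_syrinx_mm: float | None
    r_cord_mm: float | None
    r_sas_mm: float
    r_eds_mm: float | None

    def radii(self) -> tuple[float | None, float | None, float, float | None]:
        return (self.r_syrinx_mm, self.r_cord_mm, self.r_sas_mm, self.r_eds_mm)


@dataclass
class GeometryProfile:
    """Canal geometry resampled on a uniform arc-length grid (SI units).

    Stations are indexed cranial (``s=0``) to caudal (``s=arc_length``); the
    original cranial end sits at ``s = extension_length`` after a cranial
    extension has been applied.
    """

    s: np.ndarray  # arc-length grid, m, shape (n,)
    xy: np.ndarray  # centroid path, m, shape (n, 2)
    r_syrinx: np.ndarray  # m; 0 where no syrinx (see has_syrinx)
    r_cord: np.ndarray
    r_sas: np.ndarray
    r_eds: np.ndarray
    kappa: np.ndarray  # signed sagittal curvature, 1/m
    has_syrinx: np.ndarray  # bool per station
    ds: float  # uniform spacing, m
    extension_length: float = 0.0  # m

    # areas are derived, cached for convenience
    A_syrinx: np.ndarray = field(init=False)
    A_cord: np.ndarray = field(init=False)
    A_sas: np.ndarray = field(init=False)
    A_eds: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.A_syrinx = np.pi * self.r_syrinx**2
        self.A_cord = np.pi * self.r_cord**2 - self.A_syrinx
        self.A_sas = np.pi * (self.r_sas**2 - self.r_cord**2)
        self.A_eds = np.pi * (self.r_eds**2 - self.r_sas**2)

    @property
    def n_stations(self) -> int:
        return self.s.size

    @property
    def arc_length(self) -> float:
        return float(self.s[-1] - self.s[0])

    @property
    def s_from_c2(self) -> np.ndarray:
        """Arc length measured from the original cranial end (C2)."""
        return self.s - self.extension_length

    def station_nearest(self, s_target: float) -> int:
        return int(np.argmin(np.abs(self.s - s_target)))

    def to_samples(self) -> list[CenterlineSample]:
        """Export the grid stations back to a millimetre table (round-trip aid)."""
        out = []
        for j in range(self.n_stations):
            out.append(
                CenterlineSample(
                    x_mm=float(self.xy[j, 0] / MM),
                    y_mm=float(self.xy[j, 1] / MM),
                    r_syrinx_mm=float(self.r_syrinx[j] / MM) if self.has_syrinx[j] else None,
                    r_cord_mm=float(self.r_cord[j] / MM),
                    r_sas_mm=float(self.r_sas[j] / MM),
                    r_eds_mm=float(self.r_eds[j] / MM),
                )
            )
        return out


# ---------------------------------------------------------------------------
# table I/O
# ---------------------------------------------------------------------------

def _parse_cell(v) -> float | None:
    if v is None:
        return None
    if isinstance(v, float) and np.isnan(v):
        return None
    if isinstance(v, str):
        if v.strip().lower() in _ABSENT:
            return None
        return float(v.replace("−", "-"))
    return float(v)


def validate_samples(samples: list[CenterlineSample]) -> None:
    """Check ordering and radius nesting; raise with the offending station."""
    if len(samples) < 1:
        raise InsufficientDataError("empty centerline table")
    x = np.array([s.x_mm for s in samples], dtype=float)
    if np.any(np.diff(x) <= 0):
        bad = int(np.argmax(np.diff(x) <= 0)) + 1
        raise OrderingError(
            f"x coordinates must be strictly increasing cranial->caudal; "
            f"violated at row {bad} (x = {x[bad]} mm)"
        )
    for s in samples:
        rs, rc, rsas, reds = s.radii()
        chain = [(r, name) for r, name in
                 [(rs, "syrinx"), (rc, "cord"), (rsas, "sas"), (reds, "eds")]
                 if r is not None]
        for r, name in chain:
            if not np.isfinite(r) or r <= 0 or r >= _MAX_RADIUS_MM:
                raise GeometryError(
                    f"station x = {s.x_mm} mm: {name} radius {r} mm is not in (0, {_MAX_RADIUS_MM})"
                )
        for (r1, n1), (r2, n2) in zip(chain, chain[1:]):
            strict = not (n1 == "sas" and n2 == "eds")  # r_sas <= r_eds allowed to touch
            if (r1 >= r2) if strict else (r1 > r2):
                raise GeometryError(
                    f"station x = {s.x_mm} mm: radius nesting violated ({n1} = {r1} mm "
                    f"{'>=' if strict else '>'} {n2} = {r2} mm)"
                )


def load_centerline_table(source) -> list[CenterlineSample]:
    """Read a delimited (comma or tab) geometry table into samples.

    ``source`` may be a path or any file-like handle.  Blank cells and dash
    sentinels denote absent radii.
    """
    df = pd.read_csv(source, sep=None, engine="python", dtype=str,
                     skipinitialspace=True)
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise GeometryError(f"geometry table lacks columns: {missing}")
    samples = []
    for _, row in df.iterrows():
        vals = {c: _parse_cell(row[c]) for c in TABLE_COLUMNS}
        if vals["x_mm"] is None or vals["y_mm"] is None:
            raise GeometryError("x_mm and y_mm must be present in every row")
        if vals["r_sas_mm"] is None:
            raise GeometryError(f"station x = {vals['x_mm']} mm: r_sas_mm is required")
        samples.append(CenterlineSample(
            x_mm=vals["x_mm"], y_mm=vals["y_mm"],
            r_syrinx_mm=vals["r_syrinx_mm"], r_cord_mm=vals["r_cord_mm"],
            r_sas_mm=vals["r_sas_mm"], r_eds_mm=vals["r_eds_mm"],
        ))
    validate_samples(samples)
    return samples


def load_centerline_workbook(path, sheet=0) -> list[CenterlineSample]:
    """Read a one-sheet spreadsheet with the same columns as the text dialect."""
    df = pd.read_excel(path, sheet_name=sheet)
    buf = _io.StringIO()
    df.to_csv(buf, index=False)
    buf.seek(0)
    return load_centerline_table(buf)


def write_centerline_table(samples: list[CenterlineSample], path_or_handle) -> None:
    """Write samples in the canonical delimited dialect (empty cell = absent)."""
    rows = []
    for s in samples:
        rows.append({
            "x_mm": repr(s.x_mm), "y_mm": repr(s.y_mm),
            "r_syrinx_mm": "" if s.r_syrinx_mm is None else repr(s.r_syrinx_mm),
            "r_cord_mm": "" if s.r_cord_mm is None else repr(s.r_cord_mm),
            "r_sas_mm": repr(s.r_sas_mm),
            "r_eds_mm": "" if s.r_eds_mm is None else repr(s.r_eds_mm),
        })
    pd.DataFrame(rows, columns=list(TABLE_COLUMNS)).to_csv(path_or_handle, index=False)


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------

def _fill_terminal_radius(x, values, ref, name):
    """Fill absent terminal entries of a radius column by holding the ratio to
    a fully populated reference column (the relative-thickness rule)."""
    vals = np.array([np.nan if v is None else v for v in values], dtype=float)
    present = np.flatnonzero(np.isfinite(vals))
    if present.size == 0:
        raise GeometryError(f"no station provides a {name} radius")
    for j in range(len(vals)):
        if not np.isfinite(vals[j]):
            k = present[np.argmin(np.abs(present - j))]
            vals[j] = ref[j] * vals[k] / ref[k]
    return vals


def resample_profile(samples: list[CenterlineSample], ds: float) -> GeometryProfile:
    """Interpolate tabulated sections onto a uniform arc-length grid.

    ``ds`` is the grid spacing in metres and must not exceed half the smallest
    station spacing.  Radii are interpolated with C2 cubics in x, arc length is
    accumulated along the interpolated centreline, and nesting is re-checked at
    every grid station.  The syrinx is flagged only between the first and last
    station that list a syrinx radius, with a one-step ramp to zero at an
    interior terminus.
    """
    validate_samples(samples)
    if len(samples) < 2:
        raise InsufficientDataError("resampling needs at least 2 stations")
    x = np.array([s.x_mm for s in samples]) * MM
    y = np.array([s.y_mm for s in samples]) * MM
    if ds <= 0:
        raise GeometryError("ds must be positive")
    if ds > 0.5 * np.min(np.diff(x)):
        raise GeometryError(
            f"ds = {ds} m exceeds half the smallest station spacing "
            f"({0.5 * np.min(np.diff(x))} m)"
        )

    r_sas = np.array([s.r_sas_mm for s in samples], dtype=float) * MM
    r_cord = _fill_terminal_radius(
        x, [None if s.r_cord_mm is None else s.r_cord_mm * MM for s in samples],
        r_sas, "cord")
    r_eds = _fill_terminal_radius(
        x, [None if s.r_eds_mm is None else s.r_eds_mm * MM for s in samples],
        r_sas, "eds")

    syx_idx = [j for j, s in enumerate(samples) if s.r_syrinx_mm is not None]
    if syx_idx and syx_idx != list(range(syx_idx[0], syx_idx[-1] + 1)):
        raise GeometryError("syrinx radii must occupy a contiguous block of stations")

    # C2 cubic splines in x (the table parameter); straight tables stay straight
    spl_y = CubicSpline(x, y)
    spl_rc = CubicSpline(x, r_cord)
    spl_rs = CubicSpline(x, r_sas)
    spl_re = CubicSpline(x, r_eds)
    if syx_idx:
        xs = x[syx_idx]
        rsx = np.array([samples[j].r_syrinx_mm for j in syx_idx]) * MM
        spl_rx = CubicSpline(xs, rsx) if len(syx_idx) > 1 else (lambda q: np.full_like(q, rsx[0]))
        syx_span = (xs[0], xs[-1])
    else:
        spl_rx, syx_span = None, None

    # cumulative arc length on a fine parameter grid
    n_fine = max(20 * len(samples), 2000)
    xf = np.linspace(x[0], x[-1], n_fine)
    slope = spl_y(xf, 1)
    seg = np.sqrt(1.0 + slope**2)
    sf = np.concatenate([[0.0], np.cumsum(0.5 * (seg[1:] + seg[:-1]) * np.diff(xf))])
    L = float(sf[-1])

    n = int(round(L / ds))
    if n < 2:
        raise InsufficientDataError("grid too coarse for the table extent")
    s_grid = np.arange(n + 1) * ds
    x_grid = np.interp(np.minimum(s_grid, L), sf, xf)

    y_grid = spl_y(x_grid)
    rc = spl_rc(x_grid)
    rs = spl_rs(x_grid)
    re = spl_re(x_grid)
    if spl_rx is not None:
        inside = (x_grid >= syx_span[0] - 1e-12) & (x_grid <= syx_span[1] + 1e-12)
        rx = np.where(inside, np.asarray(spl_rx(x_grid)), 0.0)
        # one-step ramp to zero at an interior terminus (avoids a hard
        # impedance discontinuity that would reflect waves spuriously)
        if syx_span[0] > x[0] + 1e-12:
            rx = rx * np.clip((x_grid - syx_span[0]) / ds, 0.0, 1.0)
        if syx_span[1] < x[-1] - 1e-12:
            rx = rx * np.clip((syx_span[1] - x_grid) / ds, 0.0, 1.0)
        has_syx = inside & (rx > 0)
        rx = np.where(has_syx, rx, 0.0)
    else:
        rx = np.zeros_like(x_grid)
        has_syx = np.zeros_like(x_grid, dtype=bool)

    for j in range(n + 1):
        pairs = [("cord", rc[j], "sas", rs[j]), ("sas", rs[j], "eds", re[j] + 1e-12)]
        if has_syx[j]:
            pairs.insert(0, ("syrinx", rx[j], "cord", rc[j]))
        for n1, r1, n2, r2 in pairs:
            if not (0 <= r1 < r2):
                raise GeometryError(
                    f"interpolated nesting violated at s = {s_grid[j]:.4f} m "
                    f"({n1} = {r1 * 1e3:.3f} mm vs {n2} = {r2 * 1e3:.3f} mm)"
                )

    prof = GeometryProfile(
        s=s_grid,
        xy=np.column_stack([x_grid, y_grid]),
        r_syrinx=rx, r_cord=rc, r_sas=rs, r_eds=re,
        kappa=np.zeros_like(s_grid),
        has_syrinx=has_syx,
        ds=ds,
    )
    prof.kappa = compute_curvature(prof)
    return prof


def compute_curvature(profile: GeometryProfile) -> np.ndarray:
    """Signed sagittal plane-curve curvature by centred finite differences.

    kappa = (x' y'' - y' x'') / (x'^2 + y'^2)^(3/2) on the arc-length grid,
    one-sided at the ends; positive kappa bends toward +y (dorsally) in the
    right-handed sagittal frame.
    """
    if profile.n_stations < 3:
        raise InsufficientDataError("curvature needs at least 3 stations")
    xy = profile.xy
    d1 = np.gradient(xy, profile.ds, axis=0)
    d2 = np.gradient(d1, profile.ds, axis=0)
    num = d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0]
    den = (d1[:, 0] ** 2 + d1[:, 1] ** 2) ** 1.5
    with np.errstate(divide="ignore", invalid="ignore"):
        kappa = np.where(den > 0, num / den, 0.0)
    return kappa


def extend_cranially(profile: GeometryProfile, length: float) -> GeometryProfile:
    """Prepend a straight extrusion of the cranial-most cross-section.

    Radii (hence areas) are held constant and curvature is zero in the
    extension.  The arc-length origin moves so that the original cranial end
    sits at ``s = extension_length``.
    """
    if length < 0:
        raise GeometryError("extension length must be nonnegative")
    k = int(round(length / profile.ds))
    if k == 0:
        return profile
    ext = k * profile.ds
    tan = profile.xy[1] - profile.xy[0]
    tan = tan / np.linalg.norm(tan)
    steps = np.arange(k, 0, -1)[:, None]
    xy_ext = profile.xy[0][None, :] - steps * profile.ds * tan

    def _pre(a, val=None):
        v = a[0] if val is None else val
        return np.concatenate([np.full(k, v, dtype=a.dtype), a])

    n_new = profile.n_stations + k
    return replace(
        profile,
        s=np.arange(n_new) * profile.ds,
        xy=np.vstack([xy_ext, profile.xy]),
        r_syrinx=_pre(profile.r_syrinx),
        r_cord=_pre(profile.r_cord),
        r_sas=_pre(profile.r_sas),
        r_eds=_pre(profile.r_eds),
        kappa=_pre(profile.kappa, 0.0),
        has_syrinx=_pre(profile.has_syrinx),
        extension_length=profile.extension_length + ext,
    )
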