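"""Fixture and synthetic canal geometries.

The canonical geometry is the 13-station centreline-and-radii table of a
Cavalier King Charles Spaniel spinal canal with a fully developed syrinx
(C2-S1), embedded verbatim in millimetres.  The helpers derive controlled
variants from any sample list: a curvature-free control, scaled sagittal
curvature, syrinx removal/rescaling/re-windowing, and smooth seeded random
perturbations, so that every stage of the pipeline is testable without any
external data.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, replace

import numpy as np

from .errors import GeometryError, PerturbationError
from .geometry import CenterlineSample, load_centerline_table, validate_samples

__all__ = [
    "FIXTURE_TABLE",
    "builtin_fixture",
    "straightened",
    "scale_curvature",
    "set_syrinx",
    "PerturbationSpec",
    "perturb",
]

#: 13 transverse sections: centroid (x cranial->caudal, y ventral->dorsal) and
#: nested radii in mm; empty cells are absent (no syrinx caudally; the cord
#: table ends before the caudal-most section).
FIXTURE_TABLE = """\
x_mm,y_mm,r_syrinx_mm,r_cord_mm,r_sas_mm,r_eds_mm
0,0,2.2,4.5,6.4,7.2
20,3.4,3.7,4.6,5.6,6.3
45,-7.9,4.5,5.1,6.3,7.1
75,-22.8,2.5,4.3,5.6,6.2
95,-24.2,2.6,3.8,5.1,6.0
125,-20.0,3.0,3.6,4.5,5.4
170,-9.3,3.1,3.5,4.6,5.5
205,-5.7,2.7,3.3,4.3,5.1
245,-12.0,3.0,3.7,4.9,5.5
275,-22.3,2.4,3.9,5.3,6.2
285,-25.7,1.8,4.1,5.2,6.2
325,-35.2,,2.5,4.0,5.0
335,-34.5,,,3.8,4.3
"""


def builtin_fixture() -> list[CenterlineSample]:
    """The embedded 13-station canal table, as printed (mm)."""
    return load_centerline_table(io.StringIO(FIXTURE_TABLE))


def straightened(samples: list[CenterlineSample]) -> list[CenterlineSample]:
    """Curvature-null control: y set to 0 everywhere, radii untouched."""
    return [replace(s, y_mm=0.0) for s in samples]


def scale_curvature(samples: list[CenterlineSample], f: float) -> list[CenterlineSample]:
    """Scale the sagittal excursion (y -> f*y); f=0 equals ``straightened``."""
    if f < 0:
        raise GeometryError("curvature scale factor must be nonnegative")
    return [replace(s, y_mm=f * s.y_mm) for s in samples]


def set_syrinx(samples, mode: str, *, factor: float | None = None,
               extent_mm: tuple[float, float] | None = None) -> list[CenterlineSample]:
    """Remove, rescale, or re-window the syrinx.

    mode "remove": drop all syrinx radii; "scale": multiply them by ``factor``
    (result must stay inside the cord); "extent": keep syrinx radii only for
    stations with x in ``extent_mm``.
    """
    if mode == "remove":
        return [replace(s, r_syrinx_mm=None) for s in samples]
    if mode == "scale":
        if factor is None or factor < 0:
            raise GeometryError("scale mode needs a nonnegative factor")
        out = []
        for s in samples:
            if s.r_syrinx_mm is None or factor == 0.0:
                out.append(replace(s, r_syrinx_mm=None) if factor == 0.0 else s)
                continue
            r = s.r_syrinx_mm * factor
            if s.r_cord_mm is not None and r >= s.r_cord_mm:
                raise GeometryError(
                    f"station x = {s.x_mm} mm: scaled syrinx radius {r} mm "
                    f">= cord radius {s.r_cord_mm} mm"
                )
            out.append(replace(s, r_syrinx_mm=r))
        return out
    if mode == "extent":
        if extent_mm is None:
            raise GeometryError("extent mode needs extent_mm = (x1, x2)")
        x1, x2 = extent_mm
        return [
            replace(s, r_syrinx_mm=s.r_syrinx_mm if x1 <= s.x_mm <= x2 else None)
            for s in samples
        ]
    raise GeometryError(f"unknown syrinx mode {mode!r}")


@dataclass(frozen=True)
class PerturbationSpec:
    """Smooth correlated random perturbation of a sample table.

    amplitude_mm: standard deviation of the added field; correlation_length_mm:
    squared-exponential correlation scale along x; target: which columns to
    perturb.  The generator is PCG64 seeded with ``seed``, so identical specs
    give identical tables on every platform.
    """

    amplitude_mm: float
    correlation_length_mm: float
    seed: int
    target: str = "both"  # centerline | radii | both

    def __post_init__(self):
        if self.amplitude_mm < 0:
            raise PerturbationError("amplitude must be nonnegative")
        if self.correlation_length_mm <= 0:
            raise PerturbationError("correlation length must be positive")
        if self.target not in ("centerline", "radii", "both"):
            raise PerturbationError(f"unknown target {self.target!r}")


def _gp_draws(rng, x, ell, n_draws):
    d = x[:, None] - x[None, :]
    cov = np.exp(-0.5 * (d / ell) ** 2) + 1e-10 * np.eye(x.size)
    chol = np.linalg.cholesky(cov)
    return chol @ rng.standard_normal((x.size, n_draws))


def perturb(samples: list[CenterlineSample], spec: PerturbationSpec) -> list[CenterlineSample]:
    """Add smooth seeded noise; re-validate, attenuating up to 5 times."""
    if spec.amplitude_mm == 0.0:
        return list(samples)
    x = np.array([s.x_mm for s in samples])
    rng = np.random.default_rng(spec.seed)
    draws = _gp_draws(rng, x, spec.correlation_length_mm, 5)  # y, rsyx, rc, rsas, reds
    amp = spec.amplitude_mm
    for _attempt in range(5):
        out = []
        for j, s in enumerate(samples):
            y = s.y_mm + amp * draws[j, 0] if spec.target in ("centerline", "both") else s.y_mm
            if spec.target in ("radii", "both"):
                def bump(r, k):
                    return None if r is None else r + amp * draws[j, k]
                rsx, rc = bump(s.r_syrinx_mm, 1), bump(s.r_cord_mm, 2)
                rsas, reds = s.r_sas_mm + amp * draws[j, 3], bump(s.r_eds_mm, 4)
            else:
                rsx, rc, rsas, reds = s.r_syrinx_mm, s.r_cord_mm, s.r_sas_mm, s.r_eds_mm
            out.append(CenterlineSample(s.x_mm, y, rsx, rc, rsas, reds))
        try:
            validate_samples(out)
            return out
        except GeometryError:
            amp *= 0.5
    raise PerturbationError(
        f"could not produce a valid geometry after 5 attenuated attempts "
        f"(seed {spec.seed}, amplitude {spec.amplitude_mm} mm)"
    )
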