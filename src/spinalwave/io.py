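"""Run configuration, report serialization and manifests.

Configuration is a small YAML file whose keys mirror the material table
symbols and the excitation parameters; anything omitted falls back to the
study defaults (cord E = 62.5 kPa, nu = 0.49; dura E = 1.25 MPa, nu = 0.4;
fat E = 1 kPa; fluid K = 2.2 GPa; h_dura = 1 mm; T = 0.4 s; Q0 = 0.35 cm^3/s;
pulse 0.01 s; extension 15 mm; 1 mm stress bins).  Reports are written as one
machine-readable summary record plus delimited stress tables, with a manifest
(checksums, config echo, version, seed) sufficient to re-execute the run.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import pandas as pd
import yaml
from pydantic import BaseModel, Field, ValidationError, field_validator

from . import __version__
from .errors import ConfigError
from .materials import FluidProps, LayerElastic, MaterialSet
from .pipeline import Numerics, SimulationReport, StressProfile
from .solver import Excitation

__all__ = ["RunConfig", "load_config", "write_report", "read_summary"]


class LayerCfg(BaseModel):
    E: float = Field(gt=0)
    nu: float = Field(ge=0, lt=0.5)
    rho: float = Field(gt=0)

    @field_validator("nu")
    @classmethod
    def _not_incompressible(cls, v):
        if v >= 0.5:
            raise ValueError("nu = 0.5 makes the elastic moduli singular")
        return v


class FluidCfg(BaseModel):
    K: float = Field(gt=0)
    rho: float = Field(gt=0)


class MaterialsCfg(BaseModel):
    cord: LayerCfg = LayerCfg(E=62.5e3, nu=0.49, rho=1000.0)
    dura: LayerCfg = LayerCfg(E=1.25e6, nu=0.40, rho=1000.0)
    fat: LayerCfg = LayerCfg(E=1.0e3, nu=0.25, rho=900.0)
    fluid: FluidCfg = FluidCfg(K=2.2e9, rho=1000.0)
    h_dura_mm: float = Field(default=1.0, gt=0)

    def to_material_set(self) -> MaterialSet:
        return MaterialSet(
            cord=LayerElastic(self.cord.E, self.cord.nu, self.cord.rho),
            dura=LayerElastic(self.dura.E, self.dura.nu, self.dura.rho),
            fat=LayerElastic(self.fat.E, self.fat.nu, self.fat.rho),
            fluid=FluidProps(self.fluid.K, self.fluid.rho),
            h_dura=self.h_dura_mm * 1e-3,
        )


class ExcitationCfg(BaseModel):
    kind: str = "cardiac_sinusoid"
    Q0_cm3_s: float = Field(default=0.35, gt=0)
    period_s: float = Field(default=0.4, gt=0)
    pulse_duration_s: float = Field(default=0.01, gt=0)
    n_cycles: int = Field(default=4, ge=1)

    def to_excitation(self) -> Excitation:
        return Excitation(self.kind, Q0=self.Q0_cm3_s * 1e-6,
                          period=self.period_s,
                          pulse_duration=self.pulse_duration_s,
                          n_cycles=self.n_cycles)


class NumericsCfg(BaseModel):
    ds_mm: float = Field(default=1.0, gt=0)
    dt_cardiac_s: float = Field(default=1e-4, gt=0)
    dt_pulse_s: float = Field(default=2e-5, gt=0)
    n_cycles: int = Field(default=4, ge=1)
    extension_mm: float = Field(default=15.0, ge=0)
    integrator: str = "midpoint"

    def to_numerics(self) -> Numerics:
        return Numerics(ds=self.ds_mm * 1e-3, dt_cardiac=self.dt_cardiac_s,
                        dt_pulse=self.dt_pulse_s, n_cycles=self.n_cycles,
                        integrator=self.integrator,
                        extension=self.extension_mm * 1e-3)


class RunConfig(BaseModel):
    """Fully resolvable run description with study defaults."""

    geometry: str | None = None  # path to a geometry table; None = fixture
    scenario: str = "normal"
    materials: MaterialsCfg = MaterialsCfg()
    excitation: ExcitationCfg = ExcitationCfg()
    numerics: NumericsCfg = NumericsCfg()
    output: str | None = None
    log_level: str = "INFO"
    seed: int | None = None


_KNOWN_TOP = set(RunConfig.model_fields)


def load_config(path: str | Path | None) -> RunConfig:
    """Read a YAML config; missing keys filled from defaults, unknown keys
    warn, type-invalid values raise one error listing every offender."""
    data = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"config root must be a mapping, got {type(data).__name__}")
    unknown = set(data) - _KNOWN_TOP
    if unknown:
        warnings.warn(f"ignoring unknown config keys: {sorted(unknown)}",
                      stacklevel=2)
        data = {k: v for k, v in data.items() if k in _KNOWN_TOP}
    try:
        return RunConfig(**data)
    except ValidationError as exc:
        lines = [f"{'.'.join(str(p) for p in e['loc'])}: {e['msg']}"
                 for e in exc.errors()]
        raise ConfigError("invalid configuration:\n  " + "\n  ".join(lines)) from exc


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_report(report: SimulationReport, outdir: str | Path,
                 config: RunConfig | None = None, seed: int | None = None) -> dict:
    """Write summary record, stress-profile table and manifest; returns the
    manifest dict."""
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
        probe = outdir / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise ConfigError(f"output directory {outdir} is not writable: {exc}") from exc

    summary = {
        **report.scalars(),
        "peak_table": [
            {"component": c, "position_mm": p, "value_Pa": v}
            for c, p, v in report.peak_table
        ],
        "numerics": {
            "ds_m": report.numerics.ds,
            "dt_cardiac_s": report.numerics.dt_cardiac,
            "dt_pulse_s": report.numerics.dt_pulse,
            "n_cycles": report.numerics.n_cycles,
            "integrator": report.numerics.integrator,
            "extension_m": report.numerics.extension,
        },
        "version": __version__,
        "seed": seed,
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2))
    report.stress.to_frame().to_csv(outdir / "stress_profile.csv", index=False)
    if config is not None:
        (outdir / "config_echo.yaml").write_text(
            yaml.safe_dump(json.loads(config.model_dump_json())))
    manifest = {
        "files": {
            f.name: {"sha256": _sha256(f), "bytes": f.stat().st_size}
            for f in sorted(outdir.iterdir()) if f.name != "manifest.json"
        },
        "version": __version__,
        "seed": seed,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def read_summary(outdir: str | Path) -> dict:
    return json.loads((Path(outdir) / "summary.json").read_text())


def read_stress_profile(outdir: str | Path) -> StressProfile:
    df = pd.read_csv(Path(outdir) / "stress_profile.csv")
    return StressProfile(bin_mm=df["bin_mm"].to_numpy(),
                         radial_pa=df["radial_Pa"].to_numpy(),
                         axial_pa=df["axial_Pa"].to_numpy(),
                         shear_pa=df["shear_Pa"].to_numpy())
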