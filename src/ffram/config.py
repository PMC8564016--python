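"""Run configuration: every physiological constant and numerical knob,
serializable to YAML and hashed into output provenance."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass

import yaml

from .flow import DEFAULT_EXPONENT, HyperemiaParams, PatientContext
from .pressure import FluidProperties


@dataclass
class RunConfig:
    """Pinned defaults for an end-to-end FFR computation.

    Units are clinical at this boundary: mm for grid and windows, mmHg
    for pressures.
    """

    grid_step_mm: float = 0.25
    smooth_window_mm: float = 1.0
    ds_min: float = 0.25
    throat_tol: float = 1.05
    q0: float = 0.8                      # mL/min/g resting perfusion
    scaling_exponent: float = DEFAULT_EXPONENT
    k_max: float = 4.0
    ds_lo: float = 0.3
    ds_hi: float = 0.9
    k_floor: float = 1.0
    mu: float = 3.5e-3                   # Pa·s
    rho: float = 1060.0                  # kg/m³
    use_hct_viscosity: bool = False
    pa_offset_mmhg: float = 6.8
    ischemia_threshold: float = 0.80
    ffr_floor: float = 0.01
    include_bernoulli_net: bool = False
    seed: int = 0
    verbose: int = 0

    def hyperemia(self) -> HyperemiaParams:
        return HyperemiaParams(k_max=self.k_max, ds_lo=self.ds_lo,
                               ds_hi=self.ds_hi, k_floor=self.k_floor)

    def fluid(self, ctx: PatientContext | None = None) -> FluidProperties:
        mu = ctx.viscosity if ctx is not None else self.mu
        return FluidProperties(mu=mu, rho=self.rho)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def digest(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def load_patient(path) -> PatientContext:
    """Read a patient-context JSON ({"lvm_g", "sbp_mmHg", "dbp_mmHg", "hct"?})."""
    with open(path, "r", encoding="utf-8") as fh:
        doc = json.load(fh)
    for key in ("lvm_g", "sbp_mmHg", "dbp_mmHg"):
        if key not in doc:
            raise ValueError(f"patient file missing key {key!r}")
    return PatientContext(lvm=doc["lvm_g"], sbp=doc["sbp_mmHg"],
                          dbp=doc["dbp_mmHg"], hct=doc.get("hct"))


def apply_config(ctx: PatientContext, cfg: RunConfig) -> PatientContext:
    """Re-bind a patient context to the run configuration's constants."""
    return PatientContext(
        lvm=ctx.lvm, sbp=ctx.sbp, dbp=ctx.dbp, hct=ctx.hct,
        q0=cfg.q0, mu=cfg.mu, rho=cfg.rho,
        use_hct_viscosity=cfg.use_hct_viscosity,
        hyperemia=cfg.hyperemia(),
    )
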