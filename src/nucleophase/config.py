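"""Validated run configuration with YAML round-tripping.

A ``RunConfig`` fully determines one simulation: domain geometry, free
energy, kinetics, gene clusters, initial condition (including the seeded
random perturbation used in symmetry-breaking studies) and integration /
output controls.  Serialisation is lossless and every run output embeds
the resolved config together with a content hash.
"""

from __future__ import annotations

from typing import Literal, Optional

import numpy as np
import yaml
from pydantic import BaseModel, Field, model_validator

from .dynamics import EvolveControls, KineticParams, config_hash
from .equilibrium import calibrate_defaults
from .free_energy import FreeEnergyParams
from .geometry import GeneCluster

__all__ = ["RunConfig", "DomainSpec", "ClusterSpec", "InitialSpec",
           "IntegrationSpec", "OutputSpec"]

_defaults = calibrate_defaults()


class DomainSpec(BaseModel):
    radius: float = 30.0
    dx: float = 0.2


class FreeEnergySpec(BaseModel):
    rho_P: float = _defaults.rho_P
    alpha: float = _defaults.alpha
    beta: float = _defaults.beta
    chi: float = _defaults.chi
    c_rep: float = _defaults.c_rep
    rho_R: float = _defaults.rho_R
    kappa: float = _defaults.kappa

    def to_params(self) -> FreeEnergyParams:
        return FreeEnergyParams(**self.model_dump())


class KineticSpec(BaseModel):
    M_p: float = 1.0
    M_r: float = 1.0
    k_d: float = 0.5

    def to_params(self) -> KineticParams:
        return KineticParams(**self.model_dump())


class ClusterSpec(BaseModel):
    x: float
    y: float
    sigma: float = Field(gt=0)
    k_T: float = Field(ge=0)

    def to_cluster(self) -> GeneCluster:
        return GeneCluster(center=(self.x, self.y), sigma=self.sigma,
                           k_T=self.k_T)


class InitialSpec(BaseModel):
    kind: Literal["seed_droplet", "uniform"] = "seed_droplet"
    center: tuple[float, float] = (0.0, 0.0)
    R0: float = 4.0
    phi_in: float = 0.63
    phi_out: float = 0.13
    phi_P0: float = 0.13          # uniform initial concentration
    perturbation_amplitude: float = 0.0
    perturbation_seed: int = 0


class IntegrationSpec(BaseModel):
    dt0: float = 0.05
    dt_max: float = 0.5
    dt_min: float = 1e-4
    growth: float = 1.1
    max_steps: int = 15000
    t_end: Optional[float] = None
    steady_tol: float = 1e-6
    steady_window: int = 50
    sweep_tol: float = 1e-6
    max_sweeps: int = 5

    def to_controls(self, snapshot_every: int) -> EvolveControls:
        return EvolveControls(dt0=self.dt0, dt_max=self.dt_max,
                              dt_min=self.dt_min, growth=self.growth,
                              max_steps=self.max_steps, t_end=self.t_end,
                              steady_tol=self.steady_tol,
                              steady_window=self.steady_window,
                              snapshot_every=snapshot_every,
                              max_sweeps=self.max_sweeps,
                              sweep_tol=self.sweep_tol)


class OutputSpec(BaseModel):
    snapshot_every: int = 200
    trajectory_path: Optional[str] = None
    scalars_csv: Optional[str] = None
    reports_csv: Optional[str] = None


class RunConfig(BaseModel):
    scenario: str = "custom"
    domain: DomainSpec = DomainSpec()
    free_energy: FreeEnergySpec = FreeEnergySpec()
    kinetics: KineticSpec = KineticSpec()
    clusters: list[ClusterSpec] = []
    initial: InitialSpec = InitialSpec()
    integration: IntegrationSpec = IntegrationSpec()
    output: OutputSpec = OutputSpec()

    @model_validator(mode="after")
    def _check(self):
        for i, cl in enumerate(self.clusters):
            if np.hypot(cl.x, cl.y) > self.domain.radius:
                raise ValueError(f"clusters[{i}] lies outside the domain")
        if self.initial.kind == "seed_droplet":
            cx, cy = self.initial.center
            if np.hypot(cx, cy) + self.initial.R0 > self.domain.radius:
                raise ValueError("initial seed extends outside the domain")
        return self

    @property
    def content_hash(self) -> str:
        return config_hash(self.model_dump(mode="json"))

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.model_dump(mode="json"),
                              sort_keys=False)
        if path is not None:
            with open(path, "w") as f:
                f.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "RunConfig":
        if hasattr(source, "read"):
            data = yaml.safe_load(source.read())
        else:
            try:
                import os
                is_file = os.path.exists(source)
            except (TypeError, ValueError):
                is_file = False
            if is_file:
                with open(source) as f:
                    data = yaml.safe_load(f)
            else:
                data = yaml.safe_load(source)
        return cls.model_validate(data)

    def with_overrides(self, **dotted) -> "RunConfig":
        """Copy with dotted-path overrides, e.g.
        with_overrides(**{"kinetics.k_d": 1.0})."""
        data = self.model_dump(mode="json")
        for key, value in dotted.items():
            node = data
            parts = key.split(".")
            for part in parts[:-1]:
                node = node[int(part)] if isinstance(node, list) \
                    else node[part]
            leaf = parts[-1]
            if isinstance(node, list):
                node[int(leaf)] = value
            else:
                node[leaf] = value
        return RunConfig.model_validate(data)
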