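"""Validated run configuration: one schema for every pipeline stage.

A run is described by a YAML file and/or command-line overrides; unknown
keys are rejected before any computation starts so typos fail fast.
"""

from __future__ import annotations

from pydantic import BaseModel, ConfigDict, Field

import yaml

__all__ = ["RunConfig", "CASConfig", "NoiseConfig", "CriteriaConfig",
           "OptimizerConfig", "load_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class CASConfig(_Strict):
    n_electrons: int = 2
    n_orbitals: int = 2
    indices: list[int] | None = None   # explicit MO indices (else frontier)


class NoiseConfig(_Strict):
    depolarizing_1q: float = 0.0
    depolarizing_2q: float = 0.0
    readout_flip: float = 0.0

    def to_spec(self):
        from .noise import NoiseSpec
        return NoiseSpec(self.depolarizing_1q, self.depolarizing_2q,
                         self.readout_flip)


class CriteriaConfig(_Strict):
    energy_tol: float = 1e-8
    gradient_tol: float = 1e-5
    max_macro: int = 50

    def to_criteria(self):
        from .casscf import ConvergenceCriteria
        return ConvergenceCriteria(self.energy_tol, self.gradient_tol,
                                   self.max_macro)


class OptimizerConfig(_Strict):
    method: str = "slsqp"
    maxiter: int = 200
    spsa_iterations: int = 100

    def to_spec(self):
        from .vqe import OptimizerSpec
        return OptimizerSpec(method=self.method, maxiter=self.maxiter,
                             spsa_iterations=self.spsa_iterations)


class RunConfig(_Strict):
    """Complete configuration tree for a quantumcas run."""

    molecule: str = "co_1.54"          # bundled name or XYZ file path
    charge: int = 0
    spin_multiplicity: int = 1
    basis: str = "cc-pvdz"
    cas: CASConfig = Field(default_factory=CASConfig)
    driver: str = "fci"                # fci | uccsd-vqe | hea-vqe
    mapping: str = "jw"                # jw | parity_reduced
    canonical: bool = True
    shots: int | None = None
    seed: int = 0
    hea_layers: int = 1
    repeats: int = 20
    noise: NoiseConfig = Field(default_factory=NoiseConfig)
    optimizer: OptimizerConfig | None = None
    criteria: CriteriaConfig = Field(default_factory=CriteriaConfig)
    output_prefix: str | None = None


def load_config(path: str | None, overrides: dict | None = None) -> RunConfig:
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    for key, value in (overrides or {}).items():
        if value is not None:
            data[key] = value
    return RunConfig.model_validate(data)
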