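"""Noisy quantum-CASSCF benchmark harness.

Repeats the full hybrid loop (HEA ansatz, SPSA optimizer, parity mapping
with two-qubit reduction, sampled expectation values under depolarizing +
readout noise) many times with different seeds, and aggregates per-iteration
statistics: mean energy, sample standard deviation and normal-approximation
95% confidence half-widths, plus the summary quantities used to compare
canonical against noncanonical orbital processing (minimum average energy,
averaged dispersion over all data points).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .active_space import frontier_active_space
from .casscf import ConvergenceCriteria, Driver, run_casscf
from .geometry import Geometry, bundled_geometry
from .integrals import compute_ao_integrals
from .mapping import Encoding
from .noise import DEFAULT_NOISE, NoiseSpec
from .scf import run_hf
from .vqe import OptimizerSpec

__all__ = ["BenchConfig", "ExperimentStats", "run_repeated",
           "compare_canonical"]


@dataclass(frozen=True)
class BenchConfig:
    """One noisy quantum-CASSCF experiment configuration."""

    geometry: str = "co_1.54"          # bundled geometry name or XYZ path
    basis: str = "cc-pvdz"
    n_active_electrons: int = 2
    n_active_orbitals: int = 2
    canonical: bool = True
    noise: NoiseSpec = DEFAULT_NOISE
    shots: int = 1000
    max_iterations: int = 9
    hea_layers: int = 1
    spsa_iterations: int = 100

    def with_canonical(self, canonical: bool) -> "BenchConfig":
        return replace(self, canonical=canonical)


@dataclass
class ExperimentStats:
    """Per-iteration statistics over repeated noisy runs."""

    mean_energy: np.ndarray
    std_energy: np.ndarray            # sample std (ddof=1) per iteration
    ci95: np.ndarray                  # 1.96 * std / sqrt(n_repeats)
    n_repeats: int
    energies: np.ndarray              # (n_repeats, n_iterations)
    min_average_energy: float
    avg_std_all_points: float
    avg_ci95_all_points: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "iteration": np.arange(len(self.mean_energy)),
            "mean_energy": self.mean_energy,
            "std_energy": self.std_energy,
            "ci95": self.ci95,
        })


def _prepare(config: BenchConfig):
    try:
        geom = bundled_geometry(config.geometry)
    except Exception:
        from .geometry import load_xyz
        geom = load_xyz(config.geometry)
    ints = compute_ao_integrals(geom, config.basis)
    scf = run_hf(ints, geom)
    act = frontier_active_space(scf, config.n_active_electrons,
                                config.n_active_orbitals)
    return ints, scf, act


def _single_run(ints, scf, act, config: BenchConfig, seed: int) -> np.ndarray:
    """One noisy quantum CASSCF; returns energies padded to max_iterations."""
    opt = OptimizerSpec(method="spsa",
                        spsa_iterations=config.spsa_iterations)
    options = {
        "encoding": Encoding.PARITY_REDUCED,
        "noise": config.noise,
        "shots": config.shots,
        "seed": seed,
        "canonical": config.canonical,
        "optimizer": opt,
        "hea_layers": config.hea_layers,
        # one first-order diagonal-Hessian orbital update per iteration:
        # the update quality then depends on the active-orbital basis,
        # which is what the canonical-vs-noncanonical comparison probes
        "orbital_scheme": "diagonal",
        "inner_steps": 1,
        # a fresh VQE per macro-iteration keeps the canonical/noncanonical
        # comparison clean: warm-started parameters would be invalidated by
        # the natural-orbital rotation in the canonical arm only
        "vqe_warm_start": False,
    }
    crit = ConvergenceCriteria(energy_tol=1e-5, gradient_tol=1e-2,
                               max_macro=config.max_iterations)
    _, trace = run_casscf(ints, scf.mo_coefficients, act,
                          Driver.HEA_VQE, crit, options)
    energies = list(trace.energies)
    while len(energies) < config.max_iterations:
        energies.append(energies[-1])   # converged runs carry the last energy
    return np.array(energies[:config.max_iterations])


def run_repeated(config: BenchConfig, n_repeats: int,
                 base_seed: int) -> ExperimentStats:
    """Run the experiment n_repeats times with seeds base_seed + i."""
    if n_repeats < 2:
        raise ValueError("statistics need n_repeats >= 2")
    ints, scf, act = _prepare(config)
    rows = [_single_run(ints, scf, act, config, base_seed + i)
            for i in range(n_repeats)]
    E = np.vstack(rows)
    mean = E.mean(axis=0)
    std = E.std(axis=0, ddof=1)
    ci = 1.96 * std / np.sqrt(n_repeats)
    return ExperimentStats(
        mean_energy=mean, std_energy=std, ci95=ci, n_repeats=n_repeats,
        energies=E,
        min_average_energy=float(mean.min()),
        avg_std_all_points=float(std.mean()),
        avg_ci95_all_points=float(ci.mean()),
    )


def compare_canonical(config_canonical: BenchConfig,
                      config_noncanonical: BenchConfig,
                      n_repeats: int, seed: int) -> dict:
    """Paired canonical-vs-noncanonical summary report."""
    if config_canonical.with_canonical(False) != \
            config_noncanonical.with_canonical(False):
        raise ValueError("configs must differ only in the canonical flag")
    if not config_canonical.canonical or config_noncanonical.canonical:
        raise ValueError("pass (canonical=True, canonical=False) configs")
    stats_c = run_repeated(config_canonical, n_repeats, seed)
    stats_n = run_repeated(config_noncanonical, n_repeats, seed)
    report = {
        "canonical": _summary(stats_c),
        "noncanonical": _summary(stats_n),
    }
    report["canonical_min_leq_noncanonical"] = (
        stats_c.min_average_energy <= stats_n.min_average_energy)
    return report


def _summary(stats: ExperimentStats) -> dict:
    return {
        "min_average_energy": stats.min_average_energy,
        "avg_std_all_points": stats.avg_std_all_points,
        "avg_ci95_all_points": stats.avg_ci95_all_points,
        "final_iteration_std": float(stats.std_energy[-1]),
        "first_iteration_std": float(stats.std_energy[0]),
        "per_iteration_mean": stats.mean_energy.tolist(),
        "per_iteration_std": stats.std_energy.tolist(),
    }
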