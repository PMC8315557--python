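"""Built-in benchmark scenarios and ensemble helpers.

The elementary A+B association benchmarks (irreversible and reversible, low
and high density) share one parameterization: degree of diffusion control
λπρ²/D_tot = 50 with λ = 3183.1 s⁻¹, ρ = 0.005 μm, D = 0.0025 μm²/s per
molecule, on an L = 1 μm periodic square with voxel size h = 5ρ for the
mesoscopic runs.  The polarity scenarios reproduce the 2D Cdc42 circuit
parameter table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import particles, rdme
from .model import (
    BimolecularReaction,
    Compartment,
    GeometryConstants,
    ModelSpec,
    RateClass,
    SpeciesSpec,
    UnimolecularReaction,
    build_polarity_model,
    kmicro_from_lambda_2d,
)

__all__ = [
    "BENCHMARK_LAMBDA",
    "BENCHMARK_RHO",
    "BENCHMARK_D",
    "association_model",
    "make_fixture",
    "child_seeds",
    "EnsembleResult",
    "ensemble_totals",
    "run_benchmark",
]

BENCHMARK_LAMBDA = 3183.1  # s⁻¹
BENCHMARK_RHO = 0.005  # μm
BENCHMARK_D = 0.0025  # μm²/s per molecule (D_tot = 2D)


def association_model(
    n_a: int = 5,
    n_b: int | None = None,
    k_micro_d: float | None = None,
    lambda_rate: float = BENCHMARK_LAMBDA,
    rho: float = BENCHMARK_RHO,
    D: float = BENCHMARK_D,
) -> ModelSpec:
    """A + B -> C (optionally reversible) with all species diffusing at D."""
    if n_b is None:
        n_b = n_a
    k_micro = kmicro_from_lambda_2d(lambda_rate, rho)
    uni = ()
    if k_micro_d is not None:
        uni = (
            UnimolecularReaction(
                "unbind", "C", ("A", "B"), k_micro_d,
                RateClass.MEM_FIRST_ORDER, reverse_of="bind",
            ),
        )
    return ModelSpec(
        species=(
            SpeciesSpec("A", Compartment.MEMBRANE, D, {"a": 1}),
            SpeciesSpec("B", Compartment.MEMBRANE, D, {"b": 1}),
            SpeciesSpec("C", Compartment.MEMBRANE, D, {"a": 1, "b": 1}),
        ),
        unimolecular=uni,
        bimolecular=(
            BimolecularReaction(
                "bind", "A", "B", ("C",), k_micro, rho, RateClass.MEM_BIMOLECULAR
            ),
        ),
        initial_counts={"A": n_a, "B": n_b, "C": 0},
    )


def make_fixture(name: str, **kwargs):
    """Named scenario -> (ModelSpec, default settings dict).

    Known names: ``fig2_low_irrev``, ``fig2_low_rev``, ``fig2_high_irrev``,
    ``fig2_high_rev``, ``s1_sweep`` (pass L), ``polarity_base``,
    ``polarity_updated``, ``polarity_sweep`` (pass overrides).
    """
    h = 5 * BENCHMARK_RHO
    bench = {
        "L": 1.0,
        "h": h,
        "dt": particles.benchmark_dt(BENCHMARK_RHO, 2 * BENCHMARK_D),
    }
    if name == "fig2_low_irrev":
        return association_model(5), dict(bench)
    if name == "fig2_low_rev":
        return association_model(5, k_micro_d=kwargs.pop("k_micro_d", 1.0)), dict(bench)
    if name == "fig2_high_irrev":
        return association_model(5000), dict(bench)
    if name == "fig2_high_rev":
        return (
            association_model(5000, k_micro_d=kwargs.pop("k_micro_d", 10.0)),
            dict(bench),
        )
    if name == "s1_sweep":
        L = kwargs.pop("L")
        return (
            association_model(2000, k_micro_d=kwargs.pop("k_micro_d", None)),
            {**bench, "L": L},
        )
    if name in ("polarity_base", "polarity_updated", "polarity_sweep"):
        gef_total = kwargs.pop("gef_total", 500)
        k_4a = kwargs.pop("k_4a", 2.0)
        include_r7 = name != "polarity_base"
        model = build_polarity_model(
            gef_total, k_4a, include_reaction_7=include_r7, **kwargs
        )
        geom = model.geometry or GeometryConstants()
        return model, {
            "L": geom.L,
            "h": 5 * 0.02,
            "dt": particles.polarity_dt(0.02, 10.0),
        }
    raise KeyError(f"unknown fixture {name!r}")


def child_seeds(base: int, n: int) -> list[int]:
    """Independent 31-bit child seeds derived from one base seed."""
    ss = np.random.SeedSequence(base)
    return [int(s & 0x7FFFFFFF) for s in ss.generate_state(n, dtype=np.uint64)]


@dataclass(frozen=True)
class EnsembleResult:
    times: np.ndarray
    mean: np.ndarray  # (T, S)
    sd: np.ndarray  # (T, S)
    n: int
    species_names: tuple[str, ...]

    def series(self, species: str):
        j = self.species_names.index(species)
        return self.mean[:, j], self.sd[:, j]

    @property
    def sem(self) -> np.ndarray:
        return self.sd / math.sqrt(self.n)


def ensemble_totals(
    model: ModelSpec,
    config,
    n_replicates: int,
    seed: int,
    engine: str = "rdme",
) -> EnsembleResult:
    """Mean ± SD of per-species totals over independent replicates.

    ``engine`` selects the mesoscopic ("rdme") or microscopic ("particle")
    simulator; ``config`` is the matching GridConfig / PbConfig and is
    re-seeded per replicate from ``seed``.
    """
    import dataclasses as _dc

    runner = rdme.run if engine == "rdme" else particles.run
    acc = None
    acc2 = None
    times = None
    for s in child_seeds(seed, n_replicates):
        cfg = _dc.replace(config, seed=s)
        if engine == "rdme":
            cfg = _dc.replace(cfg, record_voxels=False)
        else:
            cfg = _dc.replace(cfg, record_positions=False)
        traj = runner(model, cfg)
        x = traj.totals.astype(float)
        if acc is None:
            acc = np.zeros_like(x)
            acc2 = np.zeros_like(x)
            times = traj.times
            names = traj.species_names
        acc += x
        acc2 += x * x
    mean = acc / n_replicates
    var = np.maximum(acc2 / n_replicates - mean**2, 0.0)
    return EnsembleResult(
        times=times,
        mean=mean,
        sd=np.sqrt(var),
        n=n_replicates,
        species_names=names,
    )


def run_benchmark(
    name: str,
    engine: str,
    replicates: int,
    seed: int,
    t_end: float,
    record_interval: float,
    rate_mode: str = "k_c",
    **fixture_args,
) -> EnsembleResult:
    """Ensemble mean/SD time series for a named scenario.

    ``engine`` is "rdme" (with ``rate_mode``) or "particle" (with the
    scenario's benchmark time step).
    """
    model, defaults = make_fixture(name, **fixture_args)
    if engine == "rdme":
        cfg = rdme.GridConfig(
            L=defaults["L"], h=defaults["h"], rate_mode=rate_mode,
            t_end=t_end, record_interval=record_interval, seed=0,
            record_voxels=False,
        )
    elif engine == "particle":
        cfg = particles.PbConfig(
            L=defaults["L"], dt=defaults["dt"], t_end=t_end,
            record_interval=record_interval, seed=0, record_positions=False,
        )
    else:
        raise ValueError(f"unknown engine {engine!r}")
    return ensemble_totals(model, cfg, replicates, seed, engine=engine)
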