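"""2D Brownian-dynamics engine with λ-ρ bimolecular reactions.

This is the microscopic ground truth against which the mesoscopic rate
modes are benchmarked.  Molecules are point particles on a periodic L×L
square; membrane and cytosol are coincident domains distinguished only by
diffusion coefficients.  Time advances in fixed steps Δt:

* displacement per coordinate: ``Z·√(2 D Δt)`` (Euler-Maruyama);
* first-order reactions fire with ``P = 1 - exp(-k Δt)`` per molecule;
* a reactant pair within distance ρ fires with ``P = 1 - exp(-λ Δt)``,
  ``λ = k_micro/(πρ²)``;
* dissociation places one product at the complex position, the other at
  ρ+ε in a uniformly random direction.

The module-level step functions (:func:`brownian_step`,
:func:`attempt_unimolecular`, :func:`attempt_bimolecular`,
:func:`dissociate_place`) are plain-numpy reference implementations of the
per-step rules; :func:`run` executes the same scheme in a compiled kernel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
import numpy as np

from . import _particle_kernel as _k
from .model import BimolecularReaction, ModelSpec, lambda_from_kmicro_2d
from .trajectory import Trajectory

__all__ = [
    "PbConfig",
    "ParticleState",
    "benchmark_dt",
    "polarity_dt",
    "brownian_step",
    "attempt_unimolecular",
    "attempt_bimolecular",
    "dissociate_place",
    "neighbor_pairs",
    "run",
    "pair_first_passage_times",
]


def _pkg_version() -> str:
    from . import __version__

    return __version__


def benchmark_dt(rho: float, d_tot: float) -> float:
    """Δt = (0.1ρ)²/(4·D_tot): RMS displacement below 0.1ρ per step."""
    return (0.1 * rho) ** 2 / (4.0 * d_tot)


def polarity_dt(rho: float, d_cyto: float) -> float:
    """Δt = ρ²/(4·D_cyto): RMS displacement of cytosolic species ≈ ρ."""
    return rho**2 / (4.0 * d_cyto)


@dataclass(frozen=True)
class PbConfig:
    """Time step, domain and recording settings for a particle run.

    ``epsilon`` is the extra dissociation offset beyond ρ; the default
    1e-3·ρ merely guarantees the fresh pair is not reaction-eligible on the
    next step.
    """

    L: float
    dt: float
    t_end: float
    record_interval: float
    seed: int = 0
    epsilon: float | None = None  # μm; default 1e-3 · ρ per reaction
    record_positions: bool = True

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.L <= 0:
            raise ValueError("dt and L must be positive")
        if self.t_end <= 0 or self.record_interval <= 0:
            raise ValueError("t_end and record_interval must be positive")
        if self.epsilon is not None and not self.epsilon > 0:
            raise ValueError("epsilon must be positive")


@dataclass
class ParticleState:
    """Continuous-space state: positions wrapped to [0, L)."""

    positions: np.ndarray  # (N, 2)
    species: np.ndarray  # (N,) int indices into species_names
    species_names: tuple[str, ...]
    L: float
    time: float = 0.0

    def counts(self) -> dict[str, int]:
        out = {}
        for i, name in enumerate(self.species_names):
            out[name] = int(np.sum(self.species == i))
        return out


# -- reference step operations ----------------------------------------------


def brownian_step(
    positions: np.ndarray,
    D,
    dt: float,
    L: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One Euler-Maruyama step with periodic wrap.

    ``D`` is a scalar or per-molecule array of diffusion coefficients.
    """
    positions = np.asarray(positions, dtype=float)
    sigma = np.sqrt(2.0 * np.asarray(D, dtype=float) * dt)
    if sigma.ndim == 1:
        sigma = sigma[:, None]
    return np.mod(positions + rng.standard_normal(positions.shape) * sigma, L)


def min_image(delta: np.ndarray, L: float) -> np.ndarray:
    return delta - np.round(delta / L) * L


def neighbor_pairs(
    positions: np.ndarray, cutoff: float, L: float, method: str = "cell"
) -> np.ndarray:
    """Index pairs (i < j) within ``cutoff`` under the minimum-image metric.

    ``method="cell"`` uses a linked cell list; ``method="brute"`` an
    all-pairs scan (the oracle the cell list is tested against).
    """
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    if n < 2:
        return np.empty((0, 2), dtype=int)
    if method == "brute":
        d = min_image(positions[:, None, :] - positions[None, :, :], L)
        within = (d**2).sum(-1) <= cutoff**2
        iu = np.triu_indices(n, k=1)
        mask = within[iu]
        return np.column_stack([iu[0][mask], iu[1][mask]])
    if method != "cell":
        raise ValueError(f"unknown method {method!r}")
    ncell = max(1, int(L / cutoff))
    if ncell < 3:
        return neighbor_pairs(positions, cutoff, L, method="brute")
    cell_xy = np.minimum((positions / (L / ncell)).astype(int), ncell - 1)
    cells: dict[tuple[int, int], list[int]] = {}
    for i, (cx, cy) in enumerate(map(tuple, cell_xy)):
        cells.setdefault((cx, cy), []).append(i)
    out = []
    cutoff2 = cutoff**2
    for (cx, cy), members in cells.items():
        for ox in (-1, 0, 1):
            for oy in (-1, 0, 1):
                other = cells.get(((cx + ox) % ncell, (cy + oy) % ncell))
                if other is None:
                    continue
                for i in members:
                    for j in other:
                        if j <= i:
                            continue
                        d = min_image(positions[i] - positions[j], L)
                        if d @ d <= cutoff2:
                            out.append((i, j))
    if not out:
        return np.empty((0, 2), dtype=int)
    return np.unique(np.array(sorted(out), dtype=int), axis=0)


def attempt_unimolecular(
    state: ParticleState,
    model: ModelSpec,
    dt: float,
    rng: np.random.Generator,
    epsilon: float | None = None,
) -> ParticleState:
    """Apply one step of first-order reactions to every molecule."""
    pairs = model.reversible_pairs()
    bi_by_name = {b.name: b for b in model.bimolecular}
    name_to_idx = {n: i for i, n in enumerate(state.species_names)}
    positions = list(map(np.array, state.positions))
    species = list(state.species)
    remove: set[int] = set()
    for i in range(len(species)):
        sname = state.species_names[species[i]]
        for r in model.unimolecular:
            if r.reactant != sname:
                continue
            if rng.random() >= 1.0 - math.exp(-r.rate_constant * dt):
                continue
            if len(r.products) == 0:
                remove.add(i)
            elif len(r.products) == 1:
                species[i] = name_to_idx[r.products[0]]
            else:
                rho = bi_by_name[pairs[r.name]].rho if r.name in pairs else 0.0
                eps = epsilon if epsilon is not None else 1e-3 * rho
                p0, p1 = dissociate_place(positions[i], rho, eps, rng, state.L)
                positions[i] = p0
                species[i] = name_to_idx[r.products[0]]
                positions.append(p1)
                species.append(name_to_idx[r.products[1]])
            break
    keep = [i for i in range(len(species)) if i not in remove]
    return ParticleState(
        positions=np.array([positions[i] for i in keep]).reshape(len(keep), 2),
        species=np.array([species[i] for i in keep], dtype=int),
        species_names=state.species_names,
        L=state.L,
        time=state.time,
    )


def attempt_bimolecular(
    state: ParticleState,
    model: ModelSpec,
    dt: float,
    rng: np.random.Generator,
) -> ParticleState:
    """Apply one step of λ-ρ bimolecular reactions.

    Candidate pairs within ρ are processed in random order; each molecule
    reacts at most once per step.
    """
    if not model.bimolecular:
        return state
    name_to_idx = {n: i for i, n in enumerate(state.species_names)}
    rxn_of: dict[tuple[int, int], BimolecularReaction] = {}
    for b in model.bimolecular:
        ia, ib = name_to_idx[b.reactant_a], name_to_idx[b.reactant_b]
        rxn_of[(ia, ib)] = b
        rxn_of[(ib, ia)] = b
    cutoff = max(b.rho for b in model.bimolecular)
    cand = neighbor_pairs(state.positions, cutoff, state.L)
    order = rng.permutation(len(cand))
    species = state.species.copy()
    positions = state.positions.copy()
    used = np.zeros(len(species), dtype=bool)
    dead = np.zeros(len(species), dtype=bool)
    for k in order:
        i, j = cand[k]
        if used[i] or used[j] or dead[i] or dead[j]:
            continue
        b = rxn_of.get((species[i], species[j]))
        if b is None:
            continue
        d = min_image(positions[i] - positions[j], state.L)
        if d @ d > b.rho**2:
            continue
        if rng.random() >= 1.0 - math.exp(-b.lambda_rate() * dt):
            continue
        used[i] = used[j] = True
        a_mol, b_mol = (
            (i, j) if species[i] == name_to_idx[b.reactant_a] else (j, i)
        )
        if len(b.products) == 1:
            keep = a_mol if b.product_at == 0 else b_mol
            drop = b_mol if keep == a_mol else a_mol
            species[keep] = name_to_idx[b.products[0]]
            dead[drop] = True
        else:
            for p, src in zip(b.products, b.product_sources):
                mol = a_mol if src[0] == 0 else b_mol
                species[mol] = name_to_idx[p]
    keep = ~dead
    return ParticleState(
        positions=positions[keep],
        species=species[keep],
        species_names=state.species_names,
        L=state.L,
        time=state.time,
    )


def dissociate_place(
    position: np.ndarray,
    rho: float,
    epsilon: float,
    rng: np.random.Generator,
    L: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Product positions after dissociation of a complex.

    The first product sits at the complex position; the second at distance
    ρ+ε in a uniformly random direction (wrapped periodically), so the fresh
    pair is never reaction-eligible on the next step.
    """
    position = np.asarray(position, dtype=float)
    theta = rng.uniform(0.0, 2.0 * math.pi)
    offset = (rho + epsilon) * np.array([math.cos(theta), math.sin(theta)])
    return position.copy(), np.mod(position + offset, L)


# -- compiled full runs ------------------------------------------------------


def _compile(model: ModelSpec, config: PbConfig):
    S = len(model.species)
    idx = {s.name: i for i, s in enumerate(model.species)}
    sigma = np.array(
        [math.sqrt(2.0 * s.diffusion_coefficient * config.dt) for s in model.species]
    )
    pairs = model.reversible_pairs()
    bi_by_name = {b.name: b for b in model.bimolecular}

    # first-order reactions grouped by reactant species
    per_species: list[list[int]] = [[] for _ in range(S)]
    for r_id, u in enumerate(model.unimolecular):
        per_species[idx[u.reactant]].append(r_id)
    u_off = np.zeros(S + 1, dtype=np.int64)
    u_idx_flat: list[int] = []
    for s in range(S):
        u_off[s + 1] = u_off[s] + len(per_species[s])
        u_idx_flat.extend(per_species[s])
    nu = len(model.unimolecular)
    u_p = np.zeros(nu)
    u_nprod = np.zeros(nu, dtype=np.int64)
    u_prod = np.zeros((nu, 2), dtype=np.int64)
    u_sep = np.zeros(nu)
    for r_id, u in enumerate(model.unimolecular):
        u_p[r_id] = 1.0 - math.exp(-u.rate_constant * config.dt)
        u_nprod[r_id] = len(u.products)
        for p, name in enumerate(u.products):
            u_prod[r_id, p] = idx[name]
        if len(u.products) == 2 and u.name in pairs:
            rho = bi_by_name[pairs[u.name]].rho
            eps = config.epsilon if config.epsilon is not None else 1e-3 * rho
            u_sep[r_id] = rho + eps

    nb = len(model.bimolecular)
    pairmap = np.full((S, S), -1, dtype=np.int64)
    b_p = np.zeros(nb)
    b_rho2 = np.zeros(nb)
    b_nprod = np.zeros(nb, dtype=np.int64)
    b_prod = np.zeros((nb, 2), dtype=np.int64)
    b_at = np.zeros((nb, 4), dtype=np.int64)
    for r_id, b in enumerate(model.bimolecular):
        ia, ib = idx[b.reactant_a], idx[b.reactant_b]
        pairmap[ia, ib] = r_id
        pairmap[ib, ia] = r_id
        lam = lambda_from_kmicro_2d(b.k_micro, b.rho)
        b_p[r_id] = 1.0 - math.exp(-lam * config.dt)
        b_rho2[r_id] = b.rho**2
        b_nprod[r_id] = len(b.products)
        for p, name in enumerate(b.products):
            b_prod[r_id, p] = idx[name]
        b_at[r_id, 0] = ia
        b_at[r_id, 1] = b.product_at
        for p, src in enumerate(b.product_sources[:2]):
            b_at[r_id, 2 + p] = src[0]
    cutoff = max((b.rho for b in model.bimolecular), default=config.L)
    ncell = max(1, int(config.L / cutoff))
    return (
        sigma, u_off, np.array(u_idx_flat, dtype=np.int64), u_p, u_nprod,
        u_prod, u_sep, pairmap, b_p, b_rho2, b_nprod, b_prod, b_at, ncell,
    )


def run(
    model: ModelSpec,
    config: PbConfig,
    initial_state: ParticleState | None = None,
) -> Trajectory:
    """One particle-based realization; snapshots every record_interval."""
    S = len(model.species)
    (
        sigma, u_off, u_idx, u_p, u_nprod, u_prod, u_sep,
        pairmap, b_p, b_rho2, b_nprod, b_prod, b_at, ncell,
    ) = _compile(model, config)

    _k._seed(config.seed)
    if initial_state is not None:
        n0 = len(initial_state.species)
        cap = n0 + 8
        pos = np.zeros((cap, 2))
        spec = np.zeros(cap, dtype=np.int64)
        alive = np.zeros(cap, dtype=np.bool_)
        pos[:n0] = initial_state.positions
        spec[:n0] = initial_state.species
        alive[:n0] = True
    else:
        n0 = sum(model.initial_counts.values())
        cap = n0 + 8
        pos = np.zeros((cap, 2))
        spec = np.zeros(cap, dtype=np.int64)
        alive = np.zeros(cap, dtype=np.bool_)
        _k._place_uniform(pos, n0, config.L)
        i = 0
        for name, cnt in model.initial_counts.items():
            s = model.species_index(name)
            spec[i : i + cnt] = s
            alive[i : i + cnt] = True
            i += cnt

    nsteps = int(round(config.t_end / config.dt))
    rec_every = max(1, int(round(config.record_interval / config.dt)))
    n_rec = nsteps // rec_every + 1
    totals_out = np.zeros((n_rec, S), dtype=np.int64)
    if config.record_positions:
        pos_out = np.zeros((n_rec, cap, 2), dtype=np.float32)
        spec_out = np.zeros((n_rec, cap), dtype=np.int16)
    else:
        pos_out = np.zeros((0, cap, 2), dtype=np.float32)
        spec_out = np.zeros((0, cap), dtype=np.int16)

    _, flag = _k._run_particles(
        pos, spec, alive, n0, sigma,
        u_off, u_idx, u_p, u_nprod, u_prod, u_sep,
        pairmap, b_p, b_rho2, b_nprod, b_prod, b_at,
        config.L, nsteps, rec_every,
        totals_out, pos_out, spec_out, config.record_positions, ncell,
    )
    if flag == -1:
        raise RuntimeError("pair candidate buffer overflow; density too high")
    times = np.arange(n_rec) * rec_every * config.dt
    positions = None
    position_species = None
    if config.record_positions:
        positions = []
        position_species = []
        for t_i in range(n_rec):
            mask = spec_out[t_i] >= 0
            positions.append(pos_out[t_i][mask].astype(float))
            position_species.append(spec_out[t_i][mask].astype(int))
    return Trajectory(
        times=times,
        species_names=tuple(s.name for s in model.species),
        L=config.L,
        totals=totals_out,
        kind="particle",
        positions=positions,
        position_species=position_species,
        metadata={
            "package_version": _pkg_version(),
            "engine": "particle-lambda-rho",
            "dt": config.dt,
            "seed": config.seed,
        },
    )


def pair_first_passage_times(
    L: float,
    d_tot: float,
    rho: float,
    lambda_rate: float,
    dt: float,
    n_trials: int,
    seed: int,
    t_max: float,
) -> np.ndarray:
    """Monte-Carlo first-reaction times of one A-B pair (relative coordinate).

    Independent oracle for the microscopic mean association time: the pair's
    separation diffuses with D_tot on the torus and reacts with probability
    1-exp(-λΔt) per step while within ρ.
    """
    _k._seed(seed)
    return _k._pair_first_passage(
        n_trials, L, d_tot, rho**2,
        1.0 - math.exp(-lambda_rate * dt), dt, int(round(t_max / dt)),
    )
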