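"""Spatial Gillespie (RDME) engine on a 2D periodic square grid.

Realizations are generated with the Next Subvolume Method: every voxel keeps
its next-event time in an indexed binary heap, the event channel within a
voxel is drawn proportionally to the channel propensities, and only the
affected voxels are updated after each event.  Diffusion is a jump reaction
with total per-molecule propensity 4D/h²; within a voxel reactions use the
well-stirred propensities with the mesoscopic rate of the configured mode
(naive ``k_micro``, scale-dependent ``k_h``, or occupancy-dependent ``k_c``).

Membrane and cytosol are coincident grids: compartments differ only through
the species diffusion coefficients.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from . import _rdme_kernel as _k
from .meso_rates import MesoRateTable, MicroParams, RateMode
from .model import ModelSpec
from .trajectory import Trajectory

def _pkg_version() -> str:
    from . import __version__

    return __version__


__all__ = [
    "GridConfig",
    "diffusion_propensity",
    "unimolecular_propensity",
    "reaction_propensity",
    "run",
    "mean_association_time",
]


@dataclass(frozen=True)
class GridConfig:
    """Grid and run settings for one RDME realization."""

    L: float  # μm, domain side
    h: float  # μm, voxel size; L/h must be an integer
    rate_mode: RateMode | str = RateMode.K_C
    t_end: float = 1.0  # s
    record_interval: float = 0.1  # s
    seed: int = 0
    record_voxels: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "rate_mode", RateMode(self.rate_mode))
        if not (self.L > 0 and self.h > 0):
            raise ValueError("L and h must be positive")
        ratio = self.L / self.h
        if abs(ratio - round(ratio)) > 1e-9 * ratio:
            raise ValueError(
                f"h must tile the domain exactly: L/h = {ratio} is not an integer"
            )
        if self.t_end <= 0 or self.record_interval <= 0:
            raise ValueError("t_end and record_interval must be positive")

    @property
    def n_side(self) -> int:
        return round(self.L / self.h)


# -- propensity primitives (reference implementations of the kernel rules) --


def diffusion_propensity(n: int, D: float, h: float) -> float:
    """Total jump propensity of n molecules: 4nD/h² (nD/h² per neighbour)."""
    if n < 0:
        raise ValueError("count must be >= 0")
    return 4.0 * n * D / (h * h)


def unimolecular_propensity(rate: float, n: int) -> float:
    return rate * n


def reaction_propensity(
    table: MesoRateTable, n_a: int, n_b: int, h: float
) -> float:
    """Bimolecular voxel propensity k_meso·n_A·n_B/h².

    In k_c mode the mesoscopic rate is evaluated at the occupancy of the more
    abundant reactant, max(n_A, n_B); in the other modes the table is flat.
    """
    if n_a < 0 or n_b < 0:
        raise ValueError("counts must be >= 0")
    if n_a == 0 or n_b == 0:
        return 0.0
    return table.association_at(max(n_a, n_b)) * n_a * n_b / (h * h)


# -- model compilation -------------------------------------------------------


class _Compiled(NamedTuple):
    hjump: np.ndarray
    inv_h2: float
    neigh: np.ndarray
    u_reac: np.ndarray
    u_nprod: np.ndarray
    u_prod: np.ndarray
    u_table: np.ndarray
    u_link: np.ndarray
    b_ra: np.ndarray
    b_rb: np.ndarray
    b_nprod: np.ndarray
    b_prod: np.ndarray
    b_table: np.ndarray
    sp_ch_off: np.ndarray
    sp_ch: np.ndarray
    rate_tables: dict


def _neighbour_table(n: int) -> np.ndarray:
    V = n * n
    neigh = np.empty((V, 4), dtype=np.int64)
    for iy in range(n):
        for ix in range(n):
            v = iy * n + ix
            neigh[v, 0] = iy * n + (ix + 1) % n
            neigh[v, 1] = iy * n + (ix - 1) % n
            neigh[v, 2] = ((iy + 1) % n) * n + ix
            neigh[v, 3] = ((iy - 1) % n) * n + ix
    return neigh


def compile_model(model: ModelSpec, config: GridConfig) -> _Compiled:
    """Lower a ModelSpec to the dense arrays the NSM kernel consumes.

    Raises :class:`mesopolar.meso_rates.GridTooFineError` in k_h mode when h
    is below the admissible bound of any bimolecular reaction.
    """
    mode = RateMode(config.rate_mode)
    h = config.h
    S = len(model.species)
    idx = {s.name: i for i, s in enumerate(model.species)}
    D = np.array([s.diffusion_coefficient for s in model.species])
    hjump = 4.0 * D / (h * h)

    pairs = model.reversible_pairs()  # uni name -> bi name
    bi_index = {b.name: j for j, b in enumerate(model.bimolecular)}

    # per-bimolecular mesoscopic tables
    tables: dict[str, MesoRateTable] = {}
    for b in model.bimolecular:
        k_micro_d = None
        for u in model.unimolecular:
            if pairs.get(u.name) == b.name:
                k_micro_d = u.rate_constant
        micro = MicroParams(
            k_micro=b.k_micro, rho=b.rho, d_tot=model.d_tot(b), k_micro_d=k_micro_d
        )
        tables[b.name] = MesoRateTable.build(mode, h, micro)

    width = max((t.n_cap for t in tables.values()), default=1) + 1

    nb = len(model.bimolecular)
    b_ra = np.zeros(nb, dtype=np.int64)
    b_rb = np.zeros(nb, dtype=np.int64)
    b_nprod = np.zeros(nb, dtype=np.int64)
    b_prod = np.zeros((nb, 2), dtype=np.int64)
    b_table = np.zeros((nb, width))
    for j, b in enumerate(model.bimolecular):
        b_ra[j] = idx[b.reactant_a]
        b_rb[j] = idx[b.reactant_b]
        b_nprod[j] = len(b.products)
        for p, name in enumerate(b.products):
            b_prod[j, p] = idx[name]
        t = tables[b.name].association
        b_table[j, : len(t)] = t
        b_table[j, len(t):] = t[-1]

    nu = len(model.unimolecular)
    u_reac = np.zeros(nu, dtype=np.int64)
    u_nprod = np.zeros(nu, dtype=np.int64)
    u_prod = np.zeros((nu, 2), dtype=np.int64)
    u_table = np.zeros((nu, width))
    u_link = np.full(nu, -1, dtype=np.int64)
    for r, u in enumerate(model.unimolecular):
        u_reac[r] = idx[u.reactant]
        u_nprod[r] = len(u.products)
        for p, name in enumerate(u.products):
            u_prod[r, p] = idx[name]
        if u.name in pairs:
            j = bi_index[pairs[u.name]]
            table = tables[model.bimolecular[j].name]
            if table.dissociation is None:
                # linked bi was built without k_micro_d (shouldn't happen)
                u_table[r, :] = u.rate_constant
            else:
                d = table.dissociation
                u_table[r, : len(d)] = d
                u_table[r, len(d):] = d[-1]
                u_table[r, 0] = d[-1]
                if mode is RateMode.K_C:
                    u_link[r] = j
        else:
            u_table[r, :] = u.rate_constant

    # species -> dependent channels (diffusion | uni | bi channel ids)
    ch_lists: list[list[int]] = [[] for _ in range(S)]
    for s in range(S):
        ch_lists[s].append(s)
    for r, u in enumerate(model.unimolecular):
        ch_lists[idx[u.reactant]].append(S + r)
        if u_link[r] >= 0:
            j = u_link[r]
            for s in (b_ra[j], b_rb[j]):
                if S + r not in ch_lists[s]:
                    ch_lists[s].append(S + r)
    for j, b in enumerate(model.bimolecular):
        for name in {b.reactant_a, b.reactant_b}:
            ch_lists[idx[name]].append(S + nu + j)
    sp_ch_off = np.zeros(S + 1, dtype=np.int64)
    flat: list[int] = []
    for s in range(S):
        sp_ch_off[s + 1] = sp_ch_off[s] + len(ch_lists[s])
        flat.extend(ch_lists[s])
    sp_ch = np.array(flat, dtype=np.int64)

    return _Compiled(
        hjump=hjump,
        inv_h2=1.0 / (h * h),
        neigh=_neighbour_table(config.n_side),
        u_reac=u_reac,
        u_nprod=u_nprod,
        u_prod=u_prod,
        u_table=u_table,
        u_link=u_link,
        b_ra=b_ra,
        b_rb=b_rb,
        b_nprod=b_nprod,
        b_prod=b_prod,
        b_table=b_table,
        sp_ch_off=sp_ch_off,
        sp_ch=sp_ch,
        rate_tables=tables,
    )


def _table_digest(compiled: _Compiled) -> str:
    hasher = hashlib.sha256()
    hasher.update(compiled.b_table.tobytes())
    hasher.update(compiled.u_table.tobytes())
    return hasher.hexdigest()[:16]


# -- running -----------------------------------------------------------------


def run(
    model: ModelSpec,
    config: GridConfig,
    initial_counts: np.ndarray | None = None,
) -> Trajectory:
    """Simulate one statistically exact RDME realization.

    Initial molecules are placed in uniformly random voxels from
    ``model.initial_counts`` unless an explicit ``initial_counts`` array of
    shape (S, n, n) is given (e.g. to continue from a previous state).
    Snapshots are taken every ``record_interval`` starting at t = 0.
    """
    compiled = compile_model(model, config)
    S = len(model.species)
    n = config.n_side
    V = n * n
    C = S + len(model.unimolecular) + len(model.bimolecular)

    counts = np.zeros((S, V), dtype=np.int64)
    _k._seed(config.seed)
    if initial_counts is not None:
        arr = np.asarray(initial_counts)
        if arr.shape not in ((S, n, n), (S, V)):
            raise ValueError(f"initial_counts must have shape {(S, n, n)}")
        counts[:, :] = arr.reshape(S, V)
    else:
        totals = np.zeros(S, dtype=np.int64)
        for name, cnt in model.initial_counts.items():
            totals[model.species_index(name)] = cnt
        _k._place_uniform(counts, totals)

    prop = np.zeros((V, C))
    asum = np.zeros(V)
    htau = np.zeros(V)
    hid = np.zeros(V, dtype=np.int64)
    hpos = np.zeros(V, dtype=np.int64)
    _k._init_state(
        counts, prop, asum, htau, hid, hpos,
        compiled.hjump, compiled.inv_h2,
        compiled.u_reac, compiled.u_table, compiled.u_link,
        compiled.b_ra, compiled.b_rb, compiled.b_table,
        S, len(model.unimolecular), 0.0,
    )
    n_rec = int(math.floor(config.t_end / config.record_interval + 1e-9)) + 1
    rec_times = np.arange(n_rec) * config.record_interval
    totals_out = np.zeros((n_rec, S), dtype=np.int64)
    snaps_out = (
        np.zeros((n_rec, S, V), dtype=np.int32)
        if config.record_voxels
        else np.zeros((0, S, V), dtype=np.int32)
    )
    t_final, flag, n_events, n_recorded = _k._run_core(
        counts, prop, asum, htau, hid, hpos,
        compiled.hjump, compiled.inv_h2, compiled.neigh,
        compiled.u_reac, compiled.u_nprod, compiled.u_prod,
        compiled.u_table, compiled.u_link,
        compiled.b_ra, compiled.b_rb, compiled.b_nprod, compiled.b_prod,
        compiled.b_table,
        compiled.sp_ch_off, compiled.sp_ch,
        0.0, config.t_end, rec_times, totals_out, snaps_out,
        config.record_voxels, False,
    )
    if flag == -2.0:
        raise RuntimeError(
            "non-finite propensity encountered (event-rate overflow); "
            "check rate constants and grid spacing"
        )
    snapshot_times = rec_times[:n_recorded]
    return Trajectory(
        times=snapshot_times,
        species_names=tuple(s.name for s in model.species),
        L=config.L,
        totals=totals_out[:n_recorded],
        kind="rdme",
        h=config.h,
        counts=(
            snaps_out[:n_recorded].reshape(n_recorded, S, n, n)
            if config.record_voxels
            else None
        ),
        metadata={
            "package_version": _pkg_version(),
            "engine": "rdme-nsm",
            "rate_mode": RateMode(config.rate_mode).value,
            "seed": config.seed,
            "t_end": config.t_end,
            "n_events": int(n_events),
            "kc_table_digest": _table_digest(compiled),
        },
    )


def mean_association_time(
    model: ModelSpec,
    config: GridConfig,
    n_trials: int,
    t_max: float | None = None,
) -> np.ndarray:
    """First-bimolecular-reaction times over repeated fresh realizations.

    Each trial places the initial molecules in uniformly random voxels and
    runs to the first bimolecular event (NaN where none occurred before
    ``t_max``).  The two-molecule case is the sampler behind the
    mean-association-time benchmark against the microscopic closed form.
    """
    compiled = compile_model(model, config)
    S = len(model.species)
    totals = np.zeros(S, dtype=np.int64)
    for name, cnt in model.initial_counts.items():
        totals[model.species_index(name)] = cnt
    _k._seed(config.seed)
    return _k._first_passage_batch(
        n_trials, totals, config.n_side**2,
        compiled.hjump, compiled.inv_h2, compiled.neigh,
        compiled.u_reac, compiled.u_nprod, compiled.u_prod,
        compiled.u_table, compiled.u_link,
        compiled.b_ra, compiled.b_rb, compiled.b_nprod, compiled.b_prod,
        compiled.b_table,
        compiled.sp_ch_off, compiled.sp_ch,
        t_max if t_max is not None else 1e9,
    )
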