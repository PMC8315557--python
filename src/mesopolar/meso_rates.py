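"""Mesoscopic bimolecular rate constants for 2D RDME simulations.

The RDME treats voxels as well-stirred, so the propensity of A+B within a
voxel is ``k_meso · n_A · n_B / h²``.  A naive choice ``k_meso = k_micro``
ignores that for diffusion-limited reactions the encounter time depends on
the grid.  Two corrected rates are provided:

``k_h`` (scale-dependent)
    chosen so the mean association time of a single A-B pair on the grid
    matches the microscopic (Smoluchowski) two-molecule result; a scalar per
    reaction, valid only above a lower bound on the voxel size ``h``.

``k_c`` (concentration-dependent)
    chosen so the reaction time of a molecule matches that of a pair confined
    to the local mean free area ``A_c = h²/max(n_A, n_B)``; a function of the
    voxel occupancy, accurate at high local densities and defined for any
    ``h > ρ``.

Dissociation counterparts ``k_h^d``/``k_c^d`` preserve the microscopic
equilibrium: ``k_meso^d = k_micro^d · k_meso / k_micro``.

All formulas use natural logarithms; the constant 0.1951 comes from the
first-passage asymptotics of the discrete square torus.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np

__all__ = [
    "MicroParams",
    "RateMode",
    "MesoRateTable",
    "F_nu",
    "tau_micro",
    "tau_micro_small_nu",
    "tau_meso",
    "k_h",
    "h_min",
    "k_h_d",
    "k_c",
    "k_c_d",
    "k_c_table",
    "GridTooFineError",
]

#: torus first-passage constant in the mesoscopic mean association time
TORUS_CONST = 0.1951


class GridTooFineError(ValueError):
    """h is below the admissible lower bound for the scale-dependent rate."""


class RateMode(str, Enum):
    NAIVE = "naive"
    K_H = "k_h"
    K_C = "k_c"


@dataclass(frozen=True)
class MicroParams:
    """Microscopic parameters of one bimolecular reaction.

    ``d_tot`` is the *sum* of the two reactants' diffusion coefficients.
    ``k_micro_d`` is the microscopic dissociation rate of the reverse
    reaction, if any.
    """

    k_micro: float  # μm²/s
    rho: float  # μm
    d_tot: float  # μm²/s
    k_micro_d: float | None = None  # s⁻¹

    def __post_init__(self) -> None:
        if self.k_micro < 0:
            raise ValueError("k_micro must be >= 0")
        if not self.rho > 0:
            raise ValueError("rho must be > 0")
        if not self.d_tot > 0:
            raise ValueError("d_tot must be > 0")
        if self.k_micro_d is not None and self.k_micro_d < 0:
            raise ValueError("k_micro_d must be >= 0")

    @property
    def alpha(self) -> float:
        """α = k_micro / (2πD), the degree of diffusion control."""
        return self.k_micro / (2.0 * math.pi * self.d_tot)


def F_nu(nu: float) -> float:
    """Geometric factor of the two-molecule association time on a disc.

    ``F(ν) = ln(1/ν)/(1-ν²)² - (3-ν²)/(4(1-ν²))`` for ν = ρ/R in (0, 1):
    one molecule diffuses on a reflective disc of radius R, the partner sits
    at the centre with reactive radius ρ.
    """
    nu = float(nu)
    if not 0.0 < nu < 1.0:
        raise ValueError(f"nu must be in (0, 1), got {nu}")
    one_minus = 1.0 - nu * nu
    return math.log(1.0 / nu) / one_minus**2 - (3.0 - nu * nu) / (4.0 * one_minus)


def tau_micro(R: float, micro: MicroParams) -> float:
    """Microscopic mean association time of a pair on a disc of radius R.

    ``τ_micro = (πR²/k_micro)(1 + α F(ρ/R))`` — reaction time plus
    diffusion-controlled search time.
    """
    if not R > micro.rho:
        raise ValueError(f"R must exceed rho ({micro.rho}), got {R}")
    if micro.k_micro == 0:
        return math.inf
    area = math.pi * R * R
    return (area / micro.k_micro) * (1.0 + micro.alpha * F_nu(micro.rho / R))


def tau_micro_small_nu(R: float, micro: MicroParams) -> float:
    """τ_micro with the small-ν asymptote F(ν) ≈ ln(1/ν) - 3/4.

    This is the form under which the scale-dependent rate is derived; with it
    ``tau_meso(L, h, D, k_h(h)) == tau_micro_small_nu(L/√π)`` is an algebraic
    identity.
    """
    if not R > micro.rho:
        raise ValueError(f"R must exceed rho ({micro.rho}), got {R}")
    if micro.k_micro == 0:
        return math.inf
    area = math.pi * R * R
    f = math.log(R / micro.rho) - 0.75
    return (area / micro.k_micro) * (1.0 + micro.alpha * f)


def tau_meso(L: float, h: float, d_tot: float, k_meso: float) -> float:
    """Mesoscopic mean association time of a pair on an L×L periodic grid.

    ``τ_meso = L²/(2πD)·ln(L/h) + 0.1951·L²/(4D) + L²/k_meso``: the first two
    terms are the mean time for the pair to land in one voxel, the last the
    well-stirred reaction time within it.
    """
    if not h > 0 or h > L:
        raise ValueError(f"need 0 < h <= L, got h={h}, L={L}")
    if not k_meso > 0:
        raise ValueError("k_meso must be > 0")
    L2 = L * L
    return (
        L2 / (2.0 * math.pi * d_tot) * math.log(L / h)
        + TORUS_CONST * L2 / (4.0 * d_tot)
        + L2 / k_meso
    )


def _G(h: float, rho: float) -> float:
    return (1.0 / (2.0 * math.pi)) * math.log(h / (math.sqrt(math.pi) * rho)) - 0.25 * (
        3.0 / (2.0 * math.pi) + TORUS_CONST
    )


def h_min(micro: MicroParams) -> float:
    """Lower bound on the voxel size below which k_h does not exist.

    ``h_min = √π · exp[(3 + 2·0.1951·π)/4 - 2πD/k_micro] · ρ``.  For strongly
    diffusion-limited reactions this saturates at ≈ 5ρ.
    """
    if micro.k_micro == 0:
        return 0.0
    exponent = (3.0 + 2.0 * TORUS_CONST * math.pi) / 4.0 - (
        2.0 * math.pi * micro.d_tot / micro.k_micro
    )
    return math.sqrt(math.pi) * math.exp(exponent) * micro.rho


def k_h(h: float, micro: MicroParams) -> float:
    """Scale-dependent mesoscopic rate constant (μm²/s).

    ``k_h = k_micro·[1 + (k_micro/D)·G(h)]⁻¹`` with
    ``G = ln(h/(√π ρ))/2π - (3/2π + 0.1951)/4``; diverges as h approaches the
    lower bound from above and is undefined below it.
    """
    if micro.k_micro == 0:
        return 0.0
    denom = 1.0 + (micro.k_micro / micro.d_tot) * _G(h, micro.rho)
    if denom <= 0.0:
        bound = h_min(micro)
        raise GridTooFineError(
            f"grid too fine for k_h: h = {h:.6g} μm is at or below the lower "
            f"bound h_min = {bound:.6g} μm = {bound / micro.rho:.3g}ρ; use a "
            f"coarser grid or the concentration-dependent rate"
        )
    return micro.k_micro / denom


def k_h_d(k_micro_d: float, k_h_val: float, k_micro: float) -> float:
    """Mesoscopic dissociation rate preserving the microscopic equilibrium.

    ``k_h^d = k_micro^d · k_h / k_micro``; the ratio tends to 1 as
    k_micro → 0, so a vanishing association rate leaves dissociation at its
    microscopic value.
    """
    if k_micro == 0:
        return k_micro_d
    return k_micro_d * k_h_val / k_micro


def k_c(n: int, h: float, micro: MicroParams) -> float:
    """Concentration-dependent mesoscopic rate at voxel occupancy n (μm²/s).

    The pair is confined to the mean free area ``A_c = h²/n`` of the more
    abundant reactant (``n = max(n_A, n_B)``), i.e. a disc of radius
    ``R_c = h/√(πn)``; then ``k_c = k_micro·[1 + α F(ρ/R_c)]⁻¹``.  In crowded
    voxels where R_c ≤ ρ the microscopic rate is used directly.
    """
    if n < 1:
        raise ValueError(f"occupancy must be >= 1, got {n}")
    if not h > micro.rho:
        raise ValueError(
            f"invalid grid: k_c requires h > rho, got h={h}, rho={micro.rho}"
        )
    if micro.k_micro == 0:
        return 0.0
    r_c = h / math.sqrt(math.pi * n)
    if r_c <= micro.rho:
        return micro.k_micro
    return micro.k_micro / (1.0 + micro.alpha * F_nu(micro.rho / r_c))


def k_c_d(k_micro_d: float, k_c_val: float, k_micro: float) -> float:
    """Dissociation counterpart of k_c (same equilibrium condition as k_h^d)."""
    if k_micro == 0:
        return k_micro_d
    return k_micro_d * k_c_val / k_micro


def occupancy_cap(h: float, rho: float) -> int:
    """Smallest occupancy at which the crowding cap R_c ≤ ρ applies."""
    return max(1, math.ceil(h * h / (math.pi * rho * rho)))


def k_c_table(h: float, micro: MicroParams) -> np.ndarray:
    """Precomputed ``k_c(n)`` for n = 1 … n_cap (index 0 unused, set to 0).

    ``table[min(n, n_cap)]`` gives the rate for any occupancy; beyond the cap
    the value is exactly ``k_micro``.
    """
    n_cap = occupancy_cap(h, micro.rho)
    table = np.zeros(n_cap + 1)
    for n in range(1, n_cap + 1):
        table[n] = k_c(n, h, micro)
    return table


@dataclass(frozen=True)
class MesoRateTable:
    """Per-reaction mesoscopic rates ready for the RDME engine.

    In ``k_h``/``naive`` mode ``association[n]`` is constant in n; in ``k_c``
    mode it is the occupancy lookup table (indexed by ``min(n, n_cap)`` with
    ``n = max(n_A, n_B)``).  ``dissociation`` matches the association entries
    through the equilibrium condition, or is ``None`` for irreversible
    reactions.
    """

    mode: RateMode
    h: float
    micro: MicroParams
    association: np.ndarray  # shape (n_cap+1,), index 0 unused
    dissociation: np.ndarray | None = None

    @classmethod
    def build(
        cls, mode: RateMode | str, h: float, micro: MicroParams
    ) -> "MesoRateTable":
        mode = RateMode(mode)
        if mode is RateMode.K_C:
            assoc = k_c_table(h, micro)
        else:
            if mode is RateMode.K_H:
                scalar = k_h(h, micro)
            else:
                scalar = micro.k_micro
            assoc = np.full(2, scalar)
            assoc[0] = 0.0
        dissoc = None
        if micro.k_micro_d is not None:
            if micro.k_micro > 0:
                dissoc = micro.k_micro_d * assoc / micro.k_micro
                dissoc[0] = 0.0
            else:
                dissoc = np.full_like(assoc, micro.k_micro_d)
        return cls(mode=mode, h=h, micro=micro, association=assoc, dissociation=dissoc)

    @property
    def n_cap(self) -> int:
        return len(self.association) - 1

    def association_at(self, n: int) -> float:
        return float(self.association[min(max(n, 0), self.n_cap)])

    def dissociation_at(self, n: int) -> float:
        if self.dissociation is None:
            raise ValueError("reaction has no dissociation counterpart")
        return float(self.dissociation[min(max(n, 1), self.n_cap)])

    def to_text(self) -> str:
        """Columnar dump (occupancy, k_assoc, k_dissoc) for inspection."""
        lines = [f"# mode={self.mode.value} h={self.h} k_micro={self.micro.k_micro}"]
        lines.append("n\tk_assoc\tk_dissoc")
        for n in range(1, self.n_cap + 1):
            d = "" if self.dissociation is None else f"{self.dissociation[n]:.8g}"
            lines.append(f"{n}\t{self.association[n]:.8g}\t{d}")
        return "\n".join(lines)
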