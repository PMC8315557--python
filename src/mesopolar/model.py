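"""Reaction-network definitions and unit/dimension conversions.

Units are fixed package-wide: lengths in μm, times in s, amounts in molecules.
First-order rate constants are s⁻¹; 2D bimolecular microscopic rate constants
(``k_micro``) are μm²/s; 3D ones are μm³/s (cytosol binds membrane) or μm/s
(cytosol-to-surface attachment).

A membrane-bound reaction system is described by a :class:`ModelSpec`: species
with compartments and diffusion coefficients, unimolecular and bimolecular
reactions carrying *microscopic* rate parameters, geometry constants, and
initial molecule counts.  The same spec drives both the mesoscopic (RDME)
engine and the particle-based engine.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Mapping

__all__ = [
    "Compartment",
    "RateClass",
    "SpeciesSpec",
    "UnimolecularReaction",
    "BimolecularReaction",
    "GeometryConstants",
    "ModelSpec",
    "lambda_from_kmicro_2d",
    "kmicro_from_lambda_2d",
    "lambda_from_kmicro_3d_halfsphere",
    "scale_macroscopic_to_2d",
    "convert_2d_to_3d",
    "build_polarity_model",
    "add_tagged_species",
    "TAG_SUFFIX",
]

TAG_SUFFIX = "*"  # naming convention for tagged shadow species


class Compartment(str, Enum):
    MEMBRANE = "membrane"
    CYTOSOL = "cytosol"


class RateClass(str, Enum):
    """Reaction class controlling macroscopic↔2D↔3D rate scaling.

    The class is an explicit tag (not inferred from product compartments):
    e.g. a membrane-only catalytic reaction has a membrane product yet scales
    like any other membrane bimolecular reaction.
    """

    CYTO_TO_MEM_FIRST_ORDER = "cyto_to_mem_first_order"
    MEM_TO_CYTO_FIRST_ORDER = "mem_to_cyto_first_order"
    MEM_FIRST_ORDER = "mem_first_order"
    MEM_BIMOLECULAR = "mem_bimolecular"
    CYTO_MEM_BIMOLECULAR = "cyto_mem_bimolecular"


class ModelError(ValueError):
    """Invalid model definition or parameter."""


@dataclass(frozen=True)
class SpeciesSpec:
    """One molecular species.

    ``composition`` counts conserved molecular units carried by the species
    (e.g. ``{"cdc42": 1, "gef": 1}`` for the Cdc42T-GEF complex); conservation
    vectors and the tagged-species machinery are derived from it.
    """

    name: str
    compartment: Compartment
    diffusion_coefficient: float
    composition: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.name:
            raise ModelError("species name must be non-empty")
        if not self.diffusion_coefficient > 0:
            raise ModelError(
                f"species {self.name!r}: diffusion coefficient must be > 0, "
                f"got {self.diffusion_coefficient}"
            )


@dataclass(frozen=True)
class UnimolecularReaction:
    """First-order reaction ``reactant -> products`` (0-2 products).

    ``product_sources`` records, per product, which reactant the product
    descends from; for a unimolecular reaction this is always ``(0,)`` and is
    kept only for symmetry with :class:`BimolecularReaction` (it drives tag
    propagation).  ``reverse_of`` optionally names the bimolecular reaction
    this dissociation reverses; if left ``None`` the link is inferred
    structurally by :meth:`ModelSpec.reversible_pairs`.
    """

    name: str
    reactant: str
    products: tuple[str, ...]
    rate_constant: float
    rate_class: RateClass
    reverse_of: str | None = None

    def __post_init__(self) -> None:
        if self.rate_constant < 0:
            raise ModelError(f"reaction {self.name!r}: rate constant must be >= 0")
        if len(self.products) > 2:
            raise ModelError(f"reaction {self.name!r}: at most 2 products supported")


@dataclass(frozen=True)
class BimolecularReaction:
    """Second-order reaction ``A + B -> products`` between distinct species.

    ``k_micro`` is the microscopic (contact-level) rate constant; the λ-ρ
    probability rate follows from :func:`lambda_from_kmicro_2d` (or the
    half-sphere 3D variant for cytosol-binds-membrane reactions).

    ``product_sources`` gives, per product, the indices of the reactants it
    descends from: ``((0, 1),)`` for an association complex, and e.g.
    ``((0,), (1,))`` for a catalytic conversion where each product inherits
    the position (particle engine) and the tag (tagged-species machinery) of
    its source.  ``product_at`` selects which reactant's position a single
    association product takes.
    """

    name: str
    reactant_a: str
    reactant_b: str
    products: tuple[str, ...]
    k_micro: float
    rho: float
    rate_class: RateClass
    product_sources: tuple[tuple[int, ...], ...] | None = None
    product_at: int = 0

    def __post_init__(self) -> None:
        if self.reactant_a == self.reactant_b:
            raise ModelError(
                f"reaction {self.name!r}: A+A reactions are not supported"
            )
        if self.k_micro < 0:
            raise ModelError(f"reaction {self.name!r}: k_micro must be >= 0")
        if not self.rho > 0:
            raise ModelError(f"reaction {self.name!r}: reactive radius must be > 0")
        if not 1 <= len(self.products) <= 2:
            raise ModelError(f"reaction {self.name!r}: 1 or 2 products required")
        if self.product_sources is None:
            sources = (
                ((0, 1),) if len(self.products) == 1 else ((0,), (1,))
            )
            object.__setattr__(self, "product_sources", sources)
        if len(self.product_sources) != len(self.products):
            raise ModelError(
                f"reaction {self.name!r}: product_sources must match products"
            )
        if self.product_at not in (0, 1):
            raise ModelError(f"reaction {self.name!r}: product_at must be 0 or 1")

    @property
    def reactants(self) -> tuple[str, str]:
        return (self.reactant_a, self.reactant_b)

    def lambda_rate(self) -> float:
        """λ (s⁻¹) of the λ-ρ model for this reaction in 2D."""
        return lambda_from_kmicro_2d(self.k_micro, self.rho)


@dataclass(frozen=True)
class GeometryConstants:
    """Cell geometry.

    The 2D simulation domain is the square of side ``L`` with L² equal to the
    membrane surface area.  ``membrane_volume`` and ``eta`` are derived, so the
    invariants V_m = A_m·Δz and η = V_m/V_c hold by construction.
    """

    membrane_area: float = 64.0  # μm²
    membrane_thickness: float = 0.0083  # μm
    cytosol_volume: float = 48.144  # μm³

    def __post_init__(self) -> None:
        if min(self.membrane_area, self.membrane_thickness, self.cytosol_volume) <= 0:
            raise ModelError("geometry constants must be positive")

    @property
    def L(self) -> float:
        """Side of the square domain, μm (L² = A_m)."""
        return math.sqrt(self.membrane_area)

    @property
    def membrane_volume(self) -> float:
        """V_m = A_m · Δz, μm³."""
        return self.membrane_area * self.membrane_thickness

    @property
    def eta(self) -> float:
        """η = V_m / V_c (dimensionless)."""
        return self.membrane_volume / self.cytosol_volume


@dataclass(frozen=True)
class ModelSpec:
    species: tuple[SpeciesSpec, ...]
    unimolecular: tuple[UnimolecularReaction, ...] = ()
    bimolecular: tuple[BimolecularReaction, ...] = ()
    geometry: GeometryConstants | None = None
    initial_counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [s.name for s in self.species]
        if len(set(names)) != len(names):
            raise ModelError("species names must be unique")
        declared = set(names)
        rxn_names = [r.name for r in self.unimolecular + self.bimolecular]
        if len(set(rxn_names)) != len(rxn_names):
            raise ModelError("reaction names must be unique")
        for r in self.unimolecular:
            for s in (r.reactant, *r.products):
                if s not in declared:
                    raise ModelError(f"reaction {r.name!r} references unknown species {s!r}")
        for r in self.bimolecular:
            for s in (*r.reactants, *r.products):
                if s not in declared:
                    raise ModelError(f"reaction {r.name!r} references unknown species {s!r}")
        for s, n in self.initial_counts.items():
            if s not in declared:
                raise ModelError(f"initial count for unknown species {s!r}")
            if n < 0 or n != int(n):
                raise ModelError(f"initial count for {s!r} must be a non-negative integer")

    # -- lookups ---------------------------------------------------------

    def species_index(self, name: str) -> int:
        for i, s in enumerate(self.species):
            if s.name == name:
                return i
        raise KeyError(name)

    def species_by_name(self, name: str) -> SpeciesSpec:
        return self.species[self.species_index(name)]

    def d_tot(self, rxn: BimolecularReaction) -> float:
        """Sum of the two reactants' diffusion coefficients, μm²/s."""
        return (
            self.species_by_name(rxn.reactant_a).diffusion_coefficient
            + self.species_by_name(rxn.reactant_b).diffusion_coefficient
        )

    def reversible_pairs(self) -> dict[str, str]:
        """Map dissociation (unimolecular) name -> forward bimolecular name.

        Explicit ``reverse_of`` tags win; otherwise the reverse relation is
        inferred structurally: u reverses b iff b's single product is u's
        reactant and u's products are exactly b's reactants.
        """
        pairs: dict[str, str] = {}
        bi_by_name = {b.name: b for b in self.bimolecular}
        for u in self.unimolecular:
            if u.reverse_of is not None:
                if u.reverse_of not in bi_by_name:
                    raise ModelError(
                        f"{u.name!r}: reverse_of target {u.reverse_of!r} not found"
                    )
                pairs[u.name] = u.reverse_of
                continue
            if len(u.products) != 2:
                continue
            for b in self.bimolecular:
                if (
                    len(b.products) == 1
                    and b.products[0] == u.reactant
                    and set(u.products) == set(b.reactants)
                ):
                    pairs[u.name] = b.name
                    break
        return pairs

    # -- stoichiometry and conservation ---------------------------------

    def stoichiometry_matrix(self):
        """Net stoichiometry, shape (n_species, n_reactions); uni first."""
        import numpy as np

        ns = len(self.species)
        rxns = list(self.unimolecular) + list(self.bimolecular)
        mat = np.zeros((ns, len(rxns)), dtype=int)
        for j, r in enumerate(rxns):
            if isinstance(r, UnimolecularReaction):
                mat[self.species_index(r.reactant), j] -= 1
            else:
                mat[self.species_index(r.reactant_a), j] -= 1
                mat[self.species_index(r.reactant_b), j] -= 1
            for p in r.products:
                mat[self.species_index(p), j] += 1
        return mat

    def conservation_vectors(self):
        """Per conserved molecular unit, the count vector over species.

        Each returned vector v satisfies vᵀ·S = 0 for the stoichiometry
        matrix S whenever every reaction conserves the unit (true for the
        polarity network: total Cdc42 and total GEF are invariant).
        """
        import numpy as np

        units = sorted({u for s in self.species for u in s.composition})
        return {
            u: np.array([s.composition.get(u, 0) for s in self.species], dtype=int)
            for u in units
        }

    def total_initial(self, unit: str) -> int:
        vec = self.conservation_vectors()[unit]
        return int(
            sum(
                vec[self.species_index(name)] * n
                for name, n in self.initial_counts.items()
            )
        )


# ---------------------------------------------------------------------------
# microscopic-parameter conversions
# ---------------------------------------------------------------------------


def lambda_from_kmicro_2d(k_micro: float, rho: float) -> float:
    """λ = k_micro/(πρ²) — λ-ρ probability rate from the 2D microscopic rate.

    In 2D the concentration of one partner inside the reactive disc is
    1/(πρ²), so the λ-ρ and contact-rate descriptions are identified through
    λ = k_micro·[B]_ρ.
    """
    if not rho > 0:
        raise ModelError(f"reactive radius must be > 0, got {rho}")
    if k_micro < 0:
        raise ModelError("k_micro must be >= 0")
    return k_micro / (math.pi * rho**2)


def kmicro_from_lambda_2d(lambda_rate: float, rho: float) -> float:
    """Inverse of :func:`lambda_from_kmicro_2d`: k_micro = λ·πρ²."""
    if not rho > 0:
        raise ModelError(f"reactive radius must be > 0, got {rho}")
    if lambda_rate < 0:
        raise ModelError("lambda must be >= 0")
    return lambda_rate * math.pi * rho**2


def lambda_from_kmicro_3d_halfsphere(k_micro: float, rho: float) -> float:
    """λ = 3·k_micro/(2πρ³) for a cytosolic molecule binding a membrane one.

    The partner concentration is that of one molecule in the half-sphere of
    radius ρ above the membrane, [B]_ρ = 3/(2πρ³); used for the 3D parameter
    sets of the cytosol-recruitment reactions.
    """
    if not rho > 0:
        raise ModelError(f"reactive radius must be > 0, got {rho}")
    if k_micro < 0:
        raise ModelError("k_micro must be >= 0")
    return 3.0 * k_micro / (2.0 * math.pi * rho**3)


_SCALE_2D = {
    RateClass.CYTO_TO_MEM_FIRST_ORDER: lambda g: g.eta,
    RateClass.MEM_BIMOLECULAR: lambda g: 1.0 / g.membrane_thickness,
    RateClass.CYTO_MEM_BIMOLECULAR: lambda g: g.membrane_area / g.cytosol_volume,
    RateClass.MEM_FIRST_ORDER: lambda g: 1.0,
    RateClass.MEM_TO_CYTO_FIRST_ORDER: lambda g: 1.0,
}

# reaction classes whose rates pick up a factor V_c/A_m when the flat 2D
# cytosol is promoted back to a true 3D compartment
_CYTOSOL_BINDING = {
    RateClass.CYTO_TO_MEM_FIRST_ORDER,
    RateClass.CYTO_MEM_BIMOLECULAR,
}


def scale_macroscopic_to_2d(
    rate_set: Mapping[str, tuple[float, RateClass]],
    geometry: GeometryConstants,
) -> dict[str, float]:
    """Scale macroscopic (volumetric) rate constants to the flat 2D model.

    The 2D representation collapses the cytosol onto the membrane plane;
    concentrations rescale by V_c/A_m (cytosolic) or Δz (membrane species
    treated as a slab of thickness Δz), which per reaction class multiplies
    the rate constant by η, 1/Δz, A_m/V_c or leaves it unchanged (the
    membrane-to-cytosol detachment factor 1/η cancels against the η carried
    by the source rate equations).
    """
    out: dict[str, float] = {}
    for name, entry in rate_set.items():
        try:
            value, rate_class = entry
            rate_class = RateClass(rate_class)
        except (TypeError, ValueError) as exc:
            raise ModelError(
                f"rate {name!r} must be tagged as (value, RateClass)"
            ) from exc
        out[name] = value * _SCALE_2D[rate_class](geometry)
    return out


def convert_2d_to_3d(
    model_2d: ModelSpec | Mapping[str, tuple[float, RateClass]],
    geometry: GeometryConstants | None = None,
) -> dict[str, float]:
    """Convert 2D rate constants to the 3D (spherical-cell) parameter set.

    Reactions confined to the membrane keep their 2D values; reactions in
    which a cytosolic species binds the membrane (or a membrane molecule) are
    multiplied by V_c/A_m, promoting their units by one power of length.
    Accepts either a :class:`ModelSpec` (geometry taken from it unless
    overridden) or a tagged rate mapping plus explicit geometry.
    """
    if isinstance(model_2d, ModelSpec):
        geometry = geometry or model_2d.geometry
        if geometry is None:
            raise ModelError("convert_2d_to_3d requires geometry constants")
        tagged: dict[str, tuple[float, RateClass]] = {}
        for r in model_2d.unimolecular:
            tagged[r.name] = (r.rate_constant, r.rate_class)
        for r in model_2d.bimolecular:
            tagged[r.name] = (r.k_micro, r.rate_class)
    else:
        if geometry is None:
            raise ModelError("convert_2d_to_3d requires geometry constants")
        tagged = {k: (v, RateClass(c)) for k, (v, c) in model_2d.items()}
    factor = geometry.cytosol_volume / geometry.membrane_area
    return {
        name: value * (factor if RateClass(cls) in _CYTOSOL_BINDING else 1.0)
        for name, (value, cls) in tagged.items()
    }


# ---------------------------------------------------------------------------
# polarity-model factory
# ---------------------------------------------------------------------------

#: Table of default 2D microscopic parameters for the yeast Cdc42 polarity
#: circuit (μm, s, molecules).  k_4a has no single default (it is swept over
#: 0-2 μm²/s in the source model) and must be supplied by the caller.
POLARITY_DEFAULTS: dict[str, float] = {
    "k_1a": 0.1,
    "k_1b": 10.0,
    "k_2a": 0.032,
    "k_2b": 0.63,
    "k_3": 0.07,
    "k_4b": 10.0,
    "k_5a": 4.0,
    "k_5b": 6.5,
    "k_6": 0.2,
    "k_7": 0.5,
    "D_cyto": 10.0,
    "D_memb": 0.0045,
    "rho": 0.02,
    "cdc42_total": 5000,
}


def build_polarity_model(
    gef_total: int,
    k_4a: float,
    *,
    include_reaction_7: bool = False,
    tagged: str | None = None,
    tag_region: None = None,
    **overrides: float,
) -> ModelSpec:
    """Build the stochastic Cdc42 polarization network.

    The circuit couples membrane/cytosol shuttling of the GEF (Cdc24) and of
    inactive Cdc42 (Cdc42D) with GEF-catalyzed activation of Cdc42 and
    positive feedback through the membrane complex Cdc42T-GEF.  With
    ``include_reaction_7`` the complex additionally recruits and activates
    cytosolic Cdc42D directly (the "updated model").

    Parameters default to the 2D column of the reference parameter table;
    any rate, diffusion coefficient, ``rho`` or ``cdc42_total`` can be
    overridden by keyword.  ``tagged`` ("cdc42" or "gef") appends the shadow
    species used by the dwell-time washout protocol.
    """
    params = dict(POLARITY_DEFAULTS)
    unknown = set(overrides) - set(params)
    if unknown:
        raise ModelError(f"unknown polarity parameters: {sorted(unknown)}")
    params.update(overrides)
    if k_4a < 0:
        raise ModelError("k_4a must be >= 0")
    if params["k_2a"] == 0:
        warnings.warn(
            "k_2a = 0: a minimal GEF_m-mediated activation rate is required "
            "to start Cdc42 activation; the network cannot leave the "
            "all-inactive state",
            stacklevel=2,
        )
    Dc, Dm, rho = params["D_cyto"], params["D_memb"], params["rho"]

    species = (
        SpeciesSpec("GEF_c", Compartment.CYTOSOL, Dc, {"gef": 1}),
        SpeciesSpec("GEF_m", Compartment.MEMBRANE, Dm, {"gef": 1}),
        SpeciesSpec("Cdc42D_c", Compartment.CYTOSOL, Dc, {"cdc42": 1}),
        SpeciesSpec("Cdc42D_m", Compartment.MEMBRANE, Dm, {"cdc42": 1}),
        SpeciesSpec("Cdc42T", Compartment.MEMBRANE, Dm, {"cdc42": 1}),
        SpeciesSpec("Cdc42T_GEF", Compartment.MEMBRANE, Dm, {"cdc42": 1, "gef": 1}),
    )
    uni = [
        UnimolecularReaction(
            "R1a", "GEF_c", ("GEF_m",), params["k_1a"],
            RateClass.CYTO_TO_MEM_FIRST_ORDER,
        ),
        UnimolecularReaction(
            "R1b", "GEF_m", ("GEF_c",), params["k_1b"],
            RateClass.MEM_TO_CYTO_FIRST_ORDER,
        ),
        UnimolecularReaction(
            "R2b", "Cdc42T", ("Cdc42D_m",), params["k_2b"], RateClass.MEM_FIRST_ORDER
        ),
        UnimolecularReaction(
            "R4b", "Cdc42T_GEF", ("GEF_m", "Cdc42T"), params["k_4b"],
            RateClass.MEM_FIRST_ORDER, reverse_of="R4a",
        ),
        UnimolecularReaction(
            "R5a", "Cdc42D_c", ("Cdc42D_m",), params["k_5a"],
            RateClass.CYTO_TO_MEM_FIRST_ORDER,
        ),
        UnimolecularReaction(
            "R5b", "Cdc42D_m", ("Cdc42D_c",), params["k_5b"],
            RateClass.MEM_TO_CYTO_FIRST_ORDER,
        ),
    ]
    bi = [
        BimolecularReaction(
            "R2a", "GEF_m", "Cdc42D_m", ("GEF_m", "Cdc42T"), params["k_2a"], rho,
            RateClass.MEM_BIMOLECULAR, product_sources=((0,), (1,)),
        ),
        BimolecularReaction(
            "R3", "Cdc42T_GEF", "Cdc42D_m", ("Cdc42T_GEF", "Cdc42T"), params["k_3"],
            rho, RateClass.MEM_BIMOLECULAR, product_sources=((0,), (1,)),
        ),
        BimolecularReaction(
            "R4a", "GEF_m", "Cdc42T", ("Cdc42T_GEF",), k_4a, rho,
            RateClass.MEM_BIMOLECULAR, product_at=1,
        ),
        BimolecularReaction(
            "R6", "GEF_c", "Cdc42T", ("Cdc42T_GEF",), params["k_6"], rho,
            RateClass.CYTO_MEM_BIMOLECULAR, product_at=1,
        ),
    ]
    if include_reaction_7:
        bi.append(
            BimolecularReaction(
                "R7", "Cdc42T_GEF", "Cdc42D_c", ("Cdc42T_GEF", "Cdc42T"),
                params["k_7"], rho, RateClass.CYTO_MEM_BIMOLECULAR,
                product_sources=((0,), (1,)),
            )
        )
    model = ModelSpec(
        species=species,
        unimolecular=tuple(uni),
        bimolecular=tuple(bi),
        geometry=GeometryConstants(),
        initial_counts={
            "Cdc42D_c": int(params["cdc42_total"]),
            "GEF_c": int(gef_total),
        },
    )
    if tagged is not None:
        model = add_tagged_species(model, tagged)
    return model


# ---------------------------------------------------------------------------
# tagged (washout) species
# ---------------------------------------------------------------------------


def tagged_name(name: str) -> str:
    return name + TAG_SUFFIX


def is_tagged(name: str) -> bool:
    return name.endswith(TAG_SUFFIX)


def add_tagged_species(model: ModelSpec, unit: str = "cdc42") -> ModelSpec:
    """Append tagged shadow species for the dwell-time washout protocol.

    Every *membrane* species whose composition carries ``unit`` gets a tagged
    twin with identical diffusion and kinetics.  Reactions are expanded
    mechanically over all tagged/untagged combinations of the shadowed
    reactants; a product is tagged iff it is itself shadowable and descends
    (via ``product_sources``) from a tagged reactant.  Because cytosolic
    species are never shadowed, membrane detachment of a tagged species
    yields the untagged cytosolic form — the washout rule.
    """
    units = {u for s in model.species for u in s.composition}
    if unit not in units:
        raise ModelError(f"no species carries the unit {unit!r}")
    shadow = {
        s.name
        for s in model.species
        if s.compartment is Compartment.MEMBRANE and s.composition.get(unit, 0) > 0
    }
    if not shadow:
        raise ModelError(f"no membrane species carries the unit {unit!r}")

    species = list(model.species) + [
        replace(s, name=tagged_name(s.name))
        for s in model.species
        if s.name in shadow
    ]

    def out_name(product: str, sources: tuple[int, ...], tagged_flags) -> str:
        if product in shadow and any(tagged_flags[i] for i in sources):
            return tagged_name(product)
        return product

    uni = list(model.unimolecular)
    for r in model.unimolecular:
        if r.reactant not in shadow:
            continue
        flags = (True,)
        uni.append(
            replace(
                r,
                name=tagged_name(r.name),
                reactant=tagged_name(r.reactant),
                products=tuple(
                    out_name(p, (0,), flags) for p in r.products
                ),
                reverse_of=(
                    tagged_name(r.reverse_of) if r.reverse_of is not None else None
                ),
            )
        )

    bi = list(model.bimolecular)
    for r in model.bimolecular:
        shadowable = [i for i, s in enumerate(r.reactants) if s in shadow]
        for combo in itertools.product([False, True], repeat=len(shadowable)):
            if not any(combo):
                continue
            flags = [False, False]
            for i, f in zip(shadowable, combo):
                flags[i] = f
            reactants = [
                tagged_name(s) if flags[i] else s
                for i, s in enumerate(r.reactants)
            ]
            suffix = "".join(TAG_SUFFIX if f else "" for f in flags) or TAG_SUFFIX
            bi.append(
                replace(
                    r,
                    name=r.name + "~" + "".join("t" if f else "u" for f in flags),
                    reactant_a=reactants[0],
                    reactant_b=reactants[1],
                    products=tuple(
                        out_name(p, src, flags)
                        for p, src in zip(r.products, r.product_sources)
                    ),
                )
            )

    # relink tagged dissociations to the matching tagged association variant
    # (structural inference in ModelSpec.reversible_pairs handles them, but an
    # explicit reverse_of pointing at a missing name must be patched)
    bi_names = {b.name for b in bi}
    uni = [
        replace(r, reverse_of=None)
        if r.reverse_of is not None and r.reverse_of not in bi_names
        else r
        for r in uni
    ]
    return replace(
        model,
        species=tuple(species),
        unimolecular=tuple(uni),
        bimolecular=tuple(bi),
    )
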