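"""Reaction-network definitions, unit conversions and the polarity factory."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mesopolar.model import (
    BimolecularReaction,
    Compartment,
    GeometryConstants,
    ModelError,
    ModelSpec,
    RateClass,
    SpeciesSpec,
    UnimolecularReaction,
    add_tagged_species,
    build_polarity_model,
    convert_2d_to_3d,
    kmicro_from_lambda_2d,
    lambda_from_kmicro_2d,
    lambda_from_kmicro_3d_halfsphere,
    scale_macroscopic_to_2d,
)

PRINTED_REL = 1e-3  # parameter-table entries are truncated to 3-4 sig figs


class TestMicroscopicConversions:
    def test_benchmark_lambda(self):
        # k_micro = 0.25 um^2/s at rho = 5 nm gives the benchmark rate
        assert lambda_from_kmicro_2d(0.25, 0.005) == pytest.approx(3183.1, rel=1e-4)

    def test_zero_rate(self):
        assert lambda_from_kmicro_2d(0.0, 0.01) == 0.0
        assert lambda_from_kmicro_3d_halfsphere(0.0, 0.01) == 0.0

    def test_inverse_worked_example(self):
        assert kmicro_from_lambda_2d(55.7, 0.02) == pytest.approx(0.07, rel=1e-2)

    @given(st.floats(1e-6, 1e3), st.floats(1e-4, 1.0))
    @settings(max_examples=50, deadline=None)
    def test_round_trip(self, k, rho):
        lam = lambda_from_kmicro_2d(k, rho)
        assert kmicro_from_lambda_2d(lam, rho) == pytest.approx(k, rel=1e-12)

    def test_halfsphere_normalization(self):
        rho = 0.02
        assert lambda_from_kmicro_3d_halfsphere(
            2 * math.pi * rho**3 / 3, rho
        ) == pytest.approx(1.0)

    def test_halfsphere_direct(self):
        assert lambda_from_kmicro_3d_halfsphere(0.15, 0.02) == pytest.approx(
            3 * 0.15 / (2 * math.pi * 0.02**3)
        )

    def test_invalid_rho(self):
        with pytest.raises(ModelError):
            lambda_from_kmicro_2d(1.0, 0.0)
        with pytest.raises(ModelError):
            lambda_from_kmicro_3d_halfsphere(1.0, -1.0)


class TestGeometry:
    def test_printed_values(self, geometry):
        assert geometry.membrane_volume == pytest.approx(0.53, rel=PRINTED_REL * 3)
        assert geometry.eta == pytest.approx(0.011, rel=4e-3)
        assert geometry.L == pytest.approx(8.0)

    def test_derived_invariants(self, geometry):
        assert geometry.membrane_volume == pytest.approx(
            geometry.membrane_area * geometry.membrane_thickness
        )
        assert geometry.eta == pytest.approx(
            geometry.membrane_volume / geometry.cytosol_volume
        )


class TestRateScaling:
    def test_macroscopic_to_2d_classes(self, geometry):
        rates = {
            "attach": (0.1, RateClass.CYTO_TO_MEM_FIRST_ORDER),
            "detach": (10.0, RateClass.MEM_TO_CYTO_FIRST_ORDER),
            "mem_cat": (1.0, RateClass.MEM_BIMOLECULAR),
            "recruit": (2.0, RateClass.CYTO_MEM_BIMOLECULAR),
            "flip": (0.63, RateClass.MEM_FIRST_ORDER),
        }
        out = scale_macroscopic_to_2d(rates, geometry)
        assert out["attach"] == pytest.approx(0.1 * geometry.eta)
        assert out["detach"] == 10.0  # the 1/eta factor cancels
        assert out["mem_cat"] == pytest.approx(1.0 / geometry.membrane_thickness)
        assert out["recruit"] == pytest.approx(
            2.0 * geometry.membrane_area / geometry.cytosol_volume
        )
        assert out["flip"] == 0.63

    def test_identity_geometry(self):
        geom = GeometryConstants(
            membrane_area=4.0, membrane_thickness=1.0, cytosol_volume=4.0
        )
        rates = {
            name: (3.3, cls) for name, cls in zip("abcde", RateClass)
        }
        out = scale_macroscopic_to_2d(rates, geom)
        assert all(v == pytest.approx(3.3) for v in out.values())

    def test_untagged_rate_rejected(self, geometry):
        with pytest.raises(ModelError, match="tagged"):
            scale_macroscopic_to_2d({"x": 1.0}, geometry)

    def test_2d_to_3d_requires_geometry(self):
        with pytest.raises(ModelError, match="geometry"):
            convert_2d_to_3d({"x": (1.0, RateClass.MEM_FIRST_ORDER)})


class TestTable2dTo3d:
    """The 3D parameter column follows from the 2D one by a V_c/A_m factor
    on every reaction where a cytosolic species binds the membrane."""

    def test_printed_3d_column(self, geometry):
        model = build_polarity_model(500, 2.0, include_reaction_7=True)
        out = convert_2d_to_3d(model)
        assert out["R1a"] == pytest.approx(0.07522, rel=PRINTED_REL)
        assert out["R5a"] == pytest.approx(3.009, rel=PRINTED_REL)
        assert out["R6"] == pytest.approx(0.15, rel=4e-3)
        assert out["R7"] == pytest.approx(0.376, rel=PRINTED_REL)

    def test_membrane_reactions_unchanged(self):
        model = build_polarity_model(500, 2.0, include_reaction_7=True)
        out = convert_2d_to_3d(model)
        for name, value in (
            ("R1b", 10.0), ("R2a", 0.032), ("R2b", 0.63), ("R3", 0.07),
            ("R4a", 2.0), ("R4b", 10.0), ("R5b", 6.5),
        ):
            assert out[name] == value


class TestPolarityFactory:
    def test_defaults_and_totals(self, polarity_model):
        m = polarity_model
        assert m.total_initial("cdc42") == 5000
        assert m.total_initial("gef") == 500
        assert {s.name for s in m.species} == {
            "GEF_c", "GEF_m", "Cdc42D_c", "Cdc42D_m", "Cdc42T", "Cdc42T_GEF"
        }

    def test_reaction_7_toggle(self):
        base = build_polarity_model(500, 2.0)
        updated = build_polarity_model(500, 2.0, include_reaction_7=True)
        assert not any(b.name == "R7" for b in base.bimolecular)
        assert any(b.name == "R7" for b in updated.bimolecular)

    def test_k2a_zero_warns(self):
        with pytest.warns(UserWarning, match="k_2a"):
            build_polarity_model(500, 2.0, k_2a=0.0)

    def test_unknown_override_rejected(self):
        with pytest.raises(ModelError, match="unknown"):
            build_polarity_model(500, 2.0, k_9=1.0)

    def test_reversible_link(self, polarity_model):
        assert polarity_model.reversible_pairs()["R4b"] == "R4a"

    def test_stoichiometry_annihilates_conservation_vectors(self):
        model = build_polarity_model(300, 1.0, include_reaction_7=True)
        S = model.stoichiometry_matrix()
        for unit, vec in model.conservation_vectors().items():
            assert not np.any(vec @ S), f"{unit} not conserved"


class TestTaggedSpecies:
    def test_shadow_species_doubling(self, polarity_model):
        tagged = add_tagged_species(polarity_model, "cdc42")
        names = {s.name for s in tagged.species}
        # every membrane Cdc42-carrying species gets a twin
        assert {"Cdc42D_m*", "Cdc42T*", "Cdc42T_GEF*"} <= names
        assert "Cdc42D_c*" not in names and "GEF_m*" not in names

    def test_tagged_conservation(self, polarity_model):
        tagged = add_tagged_species(polarity_model, "cdc42")
        S = tagged.stoichiometry_matrix()
        for unit, vec in tagged.conservation_vectors().items():
            assert not np.any(vec @ S)

    def test_detachment_untagging(self, polarity_model):
        tagged = add_tagged_species(polarity_model, "cdc42")
        detach = next(u for u in tagged.unimolecular if u.name == "R5b*")
        assert detach.reactant == "Cdc42D_m*"
        assert detach.products == ("Cdc42D_c",)  # cytosolic form is untagged

    def test_complex_dissociation_keeps_tag_on_cdc42(self, polarity_model):
        tagged = add_tagged_species(polarity_model, "cdc42")
        dis = next(u for u in tagged.unimolecular if u.name == "R4b*")
        assert dis.reactant == "Cdc42T_GEF*"
        assert set(dis.products) == {"GEF_m", "Cdc42T*"}

    def test_gef_tagging(self, polarity_model):
        tagged = add_tagged_species(polarity_model, "gef")
        names = {s.name for s in tagged.species}
        assert {"GEF_m*", "Cdc42T_GEF*"} <= names
        dis = next(u for u in tagged.unimolecular if u.name == "R4b*")
        assert set(dis.products) == {"GEF_m*", "Cdc42T"}

    def test_tagged_dissociation_links_to_tagged_association(self, polarity_model):
        tagged = add_tagged_species(polarity_model, "cdc42")
        pairs = tagged.reversible_pairs()
        fwd = next(b for b in tagged.bimolecular if b.name == pairs["R4b*"])
        assert fwd.products == ("Cdc42T_GEF*",)


class TestValidation:
    def test_unknown_species_in_reaction(self):
        with pytest.raises(ModelError, match="unknown species"):
            ModelSpec(
                species=(SpeciesSpec("A", Compartment.MEMBRANE, 1.0),),
                unimolecular=(
                    UnimolecularReaction(
                        "r", "A", ("B",), 1.0, RateClass.MEM_FIRST_ORDER
                    ),
                ),
            )

    def test_duplicate_species_names(self):
        with pytest.raises(ModelError, match="unique"):
            ModelSpec(
                species=(
                    SpeciesSpec("A", Compartment.MEMBRANE, 1.0),
                    SpeciesSpec("A", Compartment.CYTOSOL, 2.0),
                )
            )

    def test_self_reaction_rejected(self):
        with pytest.raises(ModelError, match="A\\+A"):
            BimolecularReaction(
                "r", "A", "A", ("B",), 1.0, 0.01, RateClass.MEM_BIMOLECULAR
            )

    def test_negative_rate_rejected(self):
        with pytest.raises(ModelError):
            UnimolecularReaction(
                "r", "A", ("B",), -1.0, RateClass.MEM_FIRST_ORDER
            )

    def test_nonpositive_diffusion_rejected(self):
        with pytest.raises(ModelError):
            SpeciesSpec("A", Compartment.MEMBRANE, 0.0)
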