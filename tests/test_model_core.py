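import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from glusim.model_core import (
    ConfigurationError,
    ModelDefinition,
    ModificationCycle,
    RateLaw,
    Reaction,
    ResolutionError,
    Species,
    build_network,
    inhibition_factor,
    mm_rate,
    modification_fluxes,
)

positive = st.floats(min_value=1e-6, max_value=1e6, allow_nan=False)
conc = st.floats(min_value=0.0, max_value=1e6, allow_nan=False)


class TestInhibitionFactor:
    def test_no_inhibitor(self):
        assert inhibition_factor(0.0, 2.0) == 1.0

    def test_half_inhibition_at_ki(self):
        assert inhibition_factor(3.0, 3.0) == pytest.approx(0.5)

    def test_nine_ki(self):
        # 1 / (1 + 9)
        assert inhibition_factor(9 * 0.4, 0.4) == pytest.approx(0.1)

    def test_bad_ki(self):
        with pytest.raises(ConfigurationError):
            inhibition_factor(1.0, 0.0)

    def test_negative_conc(self):
        with pytest.raises(ValueError):
            inhibition_factor(-1.0, 1.0)

    @given(x=conc, ki=positive)
    def test_range(self, x, ki):
        f = inhibition_factor(x, ki)
        assert 0.0 < f <= 1.0

    @given(x=st.floats(min_value=1e-3, max_value=1e3), ki=positive)
    def test_strictly_decreasing(self, x, ki):
        assert inhibition_factor(x * 1.5, ki) < inhibition_factor(x, ki)


def _single_substrate_law(kcat=10.0, km=0.5, inhibitors=()):
    law = RateLaw(
        form="irreversible_mm", kcat=kcat, Km={"S": km}, inhibitors=list(inhibitors)
    )
    law.substrates = ["S"]
    return law


class TestMMRate:
    def test_zero_substrate(self):
        assert mm_rate(_single_substrate_law(), 0.5, {"S": 0.0}) == 0.0

    def test_half_saturation(self):
        # kcat * E / 2 at S = Km
        law = _single_substrate_law(kcat=10.0, km=0.5)
        assert mm_rate(law, 0.5, {"S": 0.5}) == pytest.approx(2.5)

    def test_half_saturation_with_inhibitor(self):
        law = _single_substrate_law(
            kcat=10.0, km=0.5, inhibitors=[("I", 2.0, "noncompetitive")]
        )
        assert mm_rate(law, 0.5, {"S": 0.5, "I": 2.0}) == pytest.approx(1.25)

    def test_missing_substrate_is_config_error(self):
        with pytest.raises(ConfigurationError):
            mm_rate(_single_substrate_law(), 0.5, {})

    def test_negative_input_is_domain_error(self):
        with pytest.raises(ValueError):
            mm_rate(_single_substrate_law(), -0.1, {"S": 1.0})
        with pytest.raises(ValueError):
            mm_rate(_single_substrate_law(), 0.1, {"S": -1.0})

    def test_multisubstrate_product_convention(self):
        law = RateLaw(form="irreversible_mm", kcat=4.0, Km={"A": 1.0, "B": 2.0})
        law.substrates = ["A", "B"]
        # product of independent saturation terms
        expected = 4.0 * 0.3 * (1 / 2) * (2 / 4)
        assert mm_rate(law, 0.3, {"A": 1.0, "B": 2.0}) == pytest.approx(expected)

    def test_reversible_vanishes_at_equilibrium(self):
        law = RateLaw(
            form="reversible_mm", kcat=5.0, Keq=2.0, Km={"S": 1.0, "P": 1.0}
        )
        law.substrates, law.products = ["S"], ["P"]
        assert mm_rate(law, 1.0, {"S": 1.0, "P": 2.0}) == pytest.approx(0.0, abs=1e-12)
        assert mm_rate(law, 1.0, {"S": 1.0, "P": 1.0}) > 0
        assert mm_rate(law, 1.0, {"S": 1.0, "P": 3.0}) < 0

    def test_reversible_requires_keq(self):
        with pytest.raises(ConfigurationError):
            RateLaw(form="reversible_mm", kcat=1.0, Km={"S": 1.0})

    @given(
        s=st.floats(min_value=1e-3, max_value=1e3),
        e=st.floats(min_value=1e-3, max_value=1e3),
    )
    @settings(max_examples=50)
    def test_monotone_in_substrate_and_enzyme(self, s, e):
        law = _single_substrate_law()
        v = mm_rate(law, e, {"S": s})
        assert mm_rate(law, e, {"S": s * 1.01}) >= v
        assert mm_rate(law, e * 1.01, {"S": s}) >= v

    def test_mass_action_uncatalysed(self):
        law = RateLaw(form="mass_action", kcat=0.5)
        law.substrates = ["S"]
        assert mm_rate(law, 1.0, {"S": 3.0}) == pytest.approx(1.5)


def _cycle(k_kin=2.0, k_phos=2.0, ki=1.0, km=1000.0):
    return ModificationCycle(
        target="ICD",
        modified_form="ICD-P",
        converter="ICDK",
        k_kin=k_kin,
        k_phos=k_phos,
        kinase_inhibitor="3PG",
        Ki_inh=ki,
        Km_kin=km,
        Km_phos=km,
    )


def _cycle_steady_state_unphos_fraction(cycle, pg_conc, total=1.0):
    """Integrate the isolated cycle to steady state; return [ICD]/total."""

    def rhs(t, y):
        concs = {
            "ICD": y[0],
            "ICD-P": y[1],
            "ICDK": 1.0,
            "3PG": pg_conc,
        }
        kin, phos = modification_fluxes(cycle, concs)
        return [phos - kin, kin - phos]

    sol = solve_ivp(rhs, (0, 50000), [total / 2, total / 2], rtol=1e-10, atol=1e-12)
    return sol.y[0, -1] / (sol.y[0, -1] + sol.y[1, -1])


class TestModificationCycle:
    def test_conserves_total(self):
        cycle = _cycle()
        concs = {"ICD": 0.3, "ICD-P": 0.7, "ICDK": 0.1, "3PG": 0.5}
        kin, phos = modification_fluxes(cycle, concs)
        # net d[ICD]/dt + d[ICD-P]/dt = (phos-kin) + (kin-phos) = 0 exactly
        assert (phos - kin) + (kin - phos) == 0.0

    def test_full_kinase_inhibition_limit(self):
        cycle = _cycle()
        concs = {"ICD": 0.5, "ICD-P": 0.5, "ICDK": 1.0, "3PG": 1e9}
        kin, _phos = modification_fluxes(cycle, concs)
        assert kin == pytest.approx(0.0, abs=1e-9)
        frac = _cycle_steady_state_unphos_fraction(_cycle(), pg_conc=1e9)
        assert frac == pytest.approx(1.0, abs=1e-6)

    def test_symmetric_steady_state(self):
        frac = _cycle_steady_state_unphos_fraction(_cycle(k_kin=2e9, k_phos=2e9, km=1e9), pg_conc=0.0)
        assert frac == pytest.approx(0.5, abs=1e-6)

    def test_two_thirds_at_ki(self):
        # k_kin = k_phos and [3PG] = Ki halves the kinase leg:
        # steady state [ICD]/total = k_phos / (k_phos + k_kin/2) = 2/3
        # the closed form holds in the first-order limit, so use Km >> pool
        frac = _cycle_steady_state_unphos_fraction(_cycle(k_kin=2e9, k_phos=2e9, km=1e9), pg_conc=1.0)
        assert frac == pytest.approx(2.0 / 3.0, abs=1e-6)

    def test_missing_species_is_config_error(self):
        with pytest.raises(ConfigurationError):
            modification_fluxes(_cycle(), {"ICD": 1.0, "ICD-P": 1.0})


class TestBuildNetwork:
    def test_chain_matrix(self):
        defn = ModelDefinition(
            species=[Species(id=s) for s in "ABC"],
            reactions=[
                Reaction(
                    id="r1",
                    stoichiometry={"A": -1, "B": 1},
                    rate_law=RateLaw(form="mass_action"),
                ),
                Reaction(
                    id="r2",
                    stoichiometry={"B": -1, "C": 1},
                    rate_law=RateLaw(form="mass_action"),
                ),
            ],
        )
        net = build_network(defn)
        np.testing.assert_array_equal(
            net.S, np.array([[-1, 0], [1, -1], [0, 1]], dtype=float)
        )

    def test_dangling_species_named(self):
        defn = ModelDefinition(
            species=[Species(id="A")],
            reactions=[
                Reaction(
                    id="r1",
                    stoichiometry={"A": -1, "XYZ": 1},
                    rate_law=RateLaw(form="mass_action"),
                )
            ],
        )
        with pytest.raises(ResolutionError, match="XYZ"):
            build_network(defn)

    def test_duplicate_reaction_id(self):
        rxn = dict(
            stoichiometry={"A": -1, "B": 1}, rate_law=RateLaw(form="mass_action")
        )
        defn = ModelDefinition(
            species=[Species(id="A"), Species(id="B")],
            reactions=[Reaction(id="r", **rxn), Reaction(id="r", **rxn)],
        )
        with pytest.raises(ConfigurationError, match="duplicate reaction"):
            build_network(defn)

    def test_duplicate_species_id(self):
        defn = ModelDefinition(species=[Species(id="A"), Species(id="A")])
        with pytest.raises(ConfigurationError, match="duplicate species"):
            build_network(defn)

    def test_deterministic(self):
        def make():
            defn = ModelDefinition(
                species=[Species(id=s) for s in "ABC"],
                reactions=[
                    Reaction(
                        id="r1",
                        stoichiometry={"A": -1, "B": 2, "C": -0.5},
                        rate_law=RateLaw(form="mass_action"),
                    )
                ],
            )
            return build_network(defn)

        np.testing.assert_array_equal(make().S, make().S)

    def test_reference_model_structure(self, reference):
        network, _profile, _biomass = reference
        assert network.cycles and network.cycles[0].target == "ICD"
        assert network.cycles[0].kinase_inhibitor == "3PG"
        # the knockout leaves the KGDH step present but silenced
        unit = network.get_gene_unit("sucAB")
        assert unit.removed

    def test_column_matches_stoichiometry(self, reference):
        network, _, _ = reference
        for j, rxn in enumerate(network.reactions):
            col = network.S[:, j]
            for sid, c in rxn.stoichiometry.items():
                assert col[network.species_index[sid]] == c
            assert np.count_nonzero(col) == len(rxn.stoichiometry)


class TestSpeciesValidation:
    def test_bad_role(self):
        with pytest.raises(ConfigurationError):
            Species(id="A", role="enzyme")

    def test_negative_concentration(self):
        with pytest.raises(ConfigurationError):
            Species(id="A", concentration=-1.0)

    def test_nonpositive_kinetics(self):
        with pytest.raises(ConfigurationError):
            RateLaw(kcat=0.0)
        with pytest.raises(ConfigurationError):
            RateLaw(Km={"S": -1.0})
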