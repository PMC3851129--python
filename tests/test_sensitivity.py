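import numpy as np
import pytest

from glusim.gene_expression import GeneUnit, MachineryProfile
from glusim.model_core import (
    ConfigurationError,
    ModelDefinition,
    RateLaw,
    Reaction,
    Species,
    build_network,
)
from glusim.sensitivity import (
    PerturbationGrid,
    SensitivityResult,
    default_grid,
    dose_response,
    rank_all,
    sweep_gene,
)
from glusim.simulation_engine import GrowthProfile, SimulationConfig, simulate, yield_metric


class TestPerturbationGrid:
    def test_default_contains_one_and_bounds(self):
        grid = default_grid()
        assert grid.factors.size == 61
        assert grid.factors[0] == pytest.approx(0.001)
        assert grid.factors[-1] == pytest.approx(1000.0)
        assert 1.0 in grid.factors

    def test_rejects_nonpositive(self):
        with pytest.raises(ConfigurationError):
            PerturbationGrid(np.array([0.0, 1.0]))

    def test_rejects_missing_one(self):
        with pytest.raises(ConfigurationError):
            PerturbationGrid(np.array([2.0, 3.0]))

    def test_rejects_unsorted(self):
        with pytest.raises(ConfigurationError):
            PerturbationGrid(np.array([1.0, 0.5, 2.0]))


# ---------------------------------------------------------------------------
# toy model: uptake -> X, then a productive linear branch (X -> GLUxt) in
# competition with a second-order waste branch (2X -> W).  The gene unit g1
# scales the uptake enzyme E1; higher dosage raises the X level and hence
# the share lost to waste, so the quasi-steady-state yield
#     Y(u) = k2 X / u   with   k2 X + 2 k4 X^2 = u,  u = k1 E1 G
# is strictly decreasing in the copy factor (closed form via the quadratic).

K1, K2, K4, GCLAMP, E1 = 0.5, 8.0, 6.0, 10.0, 0.02
FAST_MACHINERY = MachineryProfile(
    table=[(0.0, 1.0, 1.0), (1.0, 1.0, 1.0)], K_rnap=1e-9, K_ribo=1e-9
)


def toy_network():
    mdeg, pdeg = 40.0, 20.0
    m_ss = 1.0
    unit = GeneUnit(
        id="g1",
        member_proteins=["E1"],
        promoter_conc=1.0,
        k_tx=m_ss * mdeg,
        mRNA_deg=mdeg,
        k_tl=E1 * pdeg / m_ss,
        protein_deg=pdeg,
        mrna0=0.0,
    )
    defn = ModelDefinition(
        species=[
            Species(id="GLCxt", role="boundary", concentration=GCLAMP,
                    compartment="extracellular"),
            Species(id="X", concentration=0.0),
            Species(id="GLUxt", concentration=0.0, compartment="extracellular"),
            Species(id="W", concentration=0.0),
            Species(id="GLC_used", concentration=0.0, compartment="extracellular"),
            Species(id="E1", role="protein", concentration=0.0),
            Species(id="E0", role="protein", concentration=1.0),  # idle enzyme
        ],
        reactions=[
            Reaction(
                id="uptake",
                stoichiometry={"GLCxt": -1, "X": 1, "GLC_used": 1},
                catalyst="E1",
                rate_law=RateLaw(form="mass_action", kcat=K1),
            ),
            Reaction(
                id="product",
                stoichiometry={"X": -1, "GLUxt": 1},
                rate_law=RateLaw(form="mass_action", kcat=K2),
            ),
            Reaction(
                id="waste",
                stoichiometry={"X": -2, "W": 1},
                rate_law=RateLaw(form="mass_action", kcat=K4),
            ),
        ],
        gene_units=[unit],
        machinery=FAST_MACHINERY,
    )
    return build_network(defn)


def closed_form_yield(factor: float) -> float:
    u = K1 * E1 * factor * GCLAMP
    # steady state of 2 k4 x^2 + k2 x - u = 0 (waste consumes 2 X per event)
    x = (-K2 + np.sqrt(K2 * K2 + 8 * K4 * u)) / (4 * K4)
    return K2 * x / u


TOY_CONFIG = SimulationConfig(
    t_end=2000.0,
    output_interval=50.0,
    rel_tol=1e-10,
    abs_tol=1e-12,
    consumption_species="GLC_used",
)


@pytest.fixture(scope="module")
def toy():
    return toy_network()


class TestSweepGene:
    def test_formula_arithmetic(self):
        # Y0 = 0.10, best Y = 0.134 at factor 1000
        res = SensitivityResult(
            gene_unit="u",
            curve=[(1.0, 0.10), (1000.0, 0.134)],
            Y0=0.10,
            max_sensitivity=(0.134 - 0.10) / 0.10,
            scale_factor=1000.0,
        )
        assert res.max_sensitivity == pytest.approx(0.34)

    def test_curve_matches_closed_form(self, toy):
        grid = PerturbationGrid(np.array([0.01, 0.1, 1.0, 10.0, 100.0]))
        res = sweep_gene(toy, None, TOY_CONFIG, "g1", grid)
        for factor, y in res.curve:
            # expression and pool transients are ~0.2 min of the 2000 min
            # horizon, so the quasi-steady-state form holds to ~1e-4
            assert y == pytest.approx(closed_form_yield(factor), rel=2e-4)

    def test_argmax_matches_brute_force(self, toy):
        grid = default_grid(points=13)
        res = sweep_gene(toy, None, TOY_CONFIG, "g1", grid)
        dense = np.power(10.0, np.linspace(-3, 3, 10_000))
        y0 = closed_form_yield(1.0)
        sens = (np.vectorize(closed_form_yield)(dense) - y0) / y0
        best = dense[int(np.argmax(sens))]
        # within one grid step on the log axis
        step = np.diff(np.log10(grid.factors)).max()
        assert abs(np.log10(res.scale_factor) - np.log10(best)) <= step + 1e-9
        assert res.max_sensitivity == pytest.approx(sens.max(), rel=1e-3)

    def test_flat_curve_snaps_to_zero(self, toy):
        # E0 catalyses nothing: dosage of a unit driving it cannot matter
        import copy

        net = copy.deepcopy(toy)
        unit = GeneUnit(
            id="g0", member_proteins=["E0"], k_tx=1.0, mRNA_deg=1.0,
            k_tl=1.0, protein_deg=1.0,
        )
        net.gene_units.append(unit)
        net2 = build_network(net.to_definition())
        grid = PerturbationGrid(np.array([0.1, 1.0, 10.0]))
        res = sweep_gene(net2, None, TOY_CONFIG, "g0", grid)
        assert res.max_sensitivity == 0.0
        assert res.scale_factor == 1.0

    def test_unknown_unit(self, toy):
        from glusim.model_core import ResolutionError

        with pytest.raises(ResolutionError):
            sweep_gene(toy, None, TOY_CONFIG, "nope", default_grid(points=3))

    def test_internal_consistency(self, toy):
        grid = default_grid(points=7)
        res = sweep_gene(toy, None, TOY_CONFIG, "g1", grid)
        assert res.yield_at(res.scale_factor) == pytest.approx(
            res.Y0 * (1 + res.max_sensitivity), rel=1e-12
        )

    def test_grid_refinement_monotone(self, toy):
        coarse = PerturbationGrid(np.power(10.0, np.linspace(-3, 3, 5)))
        fine = PerturbationGrid(np.power(10.0, np.linspace(-3, 3, 13)))
        res_c = sweep_gene(toy, None, TOY_CONFIG, "g1", coarse)
        res_f = sweep_gene(toy, None, TOY_CONFIG, "g1", fine)
        # the fine grid contains the coarse one: max over superset >= subset
        assert res_f.max_sensitivity >= res_c.max_sensitivity - 1e-12


class TestRankAll:
    def test_affected_unit_ranks_first(self, toy):
        import copy

        net = copy.deepcopy(toy)
        net.gene_units.append(
            GeneUnit(id="g0", member_proteins=["E0"], k_tx=1.0, mRNA_deg=1.0,
                     k_tl=1.0, protein_deg=1.0)
        )
        net2 = build_network(net.to_definition())
        grid = PerturbationGrid(np.array([0.1, 1.0, 10.0]))
        table, results = rank_all(net2, None, TOY_CONFIG, grid)
        assert list(table["unit"]) == ["g1", "g0"]
        assert table.loc[0, "max_sensitivity"] > 0
        assert list(table["rank"]) == [1, 2]

    def test_requires_units(self, toy):
        import copy

        net = copy.deepcopy(toy)
        net.gene_units.clear()
        net2 = build_network(net.to_definition())
        with pytest.raises(ConfigurationError):
            rank_all(net2, None, TOY_CONFIG, default_grid(points=3))


class TestDoseResponse:
    def test_factor_one_all_ratios_one(self, toy):
        grid = PerturbationGrid(np.array([0.5, 1.0, 2.0]))
        df = dose_response(toy, None, TOY_CONFIG, "g1", grid, observables=["X", "W"])
        row = df[df["factor"] == 1.0].iloc[0]
        assert row["X"] == 1.0 and row["W"] == 1.0

    def test_x_monotone_in_uptake_dosage(self, toy):
        grid = PerturbationGrid(np.array([1.0, 3.0, 10.0, 30.0]))
        df = dose_response(toy, None, TOY_CONFIG, "g1", grid, observables=["X"])
        assert df["X"].is_monotonic_increasing

    def test_requires_observables(self, toy):
        with pytest.raises(ConfigurationError):
            dose_response(toy, None, TOY_CONFIG, "g1", default_grid(points=3), [])
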