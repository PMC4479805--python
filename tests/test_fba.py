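"""The LP engine and the simulation modes."""

import numpy as np
import pytest

from acarflux.fba import (
    FBAError,
    UndefinedFluxRatioError,
    pathway_flux_ratio,
    robustness_scan,
    simulate_growth,
    simulate_production,
    solve_fba,
)
from acarflux.medium import MediumSpec
from acarflux.model import MetabolicModel, Metabolite, Reaction
from acarflux.synthetic import make_branched_tradeoff, make_linear_chain

from _oracles import to_cobra, vertex_enumeration_optimum


class TestSolveFBA:
    @pytest.mark.parametrize(
        "n, yld, cap", [(1, 0.5, 10.0), (3, 1.0, 7.0), (2, 0.5, 10.0), (4, 0.8, 3.0)]
    )
    def test_chain_analytic_optimum(self, n, yld, cap):
        model = make_linear_chain(n, yld, cap)
        sol = solve_fba(model)
        assert sol.ok
        assert sol.objective_value == pytest.approx(cap * yld ** n, abs=1e-9)

    def test_steady_state_and_bounds_hold(self, mini, synthesis):
        from acarflux.medium import apply_medium
        from acarflux.model import build_stoichiometric_matrix

        sol = solve_fba(mini, synthesis, parsimonious=True)
        constrained = apply_medium(mini, synthesis)
        S, met_index, rxn_index = build_stoichiometric_matrix(constrained)
        v = np.array([sol.fluxes[r] for r in constrained.reaction_ids])
        assert np.max(np.abs(S @ v)) < 1e-6
        for rxn in constrained.reactions:
            assert rxn.lower_bound - 1e-6 <= sol.fluxes[rxn.id] <= rxn.upper_bound + 1e-6

    def test_matches_vertex_enumeration_on_toys(self):
        cases = [
            (make_linear_chain(2, 0.5, 10.0), "EX_bio"),
            (make_linear_chain(3, 0.7, 4.0), "EX_bio"),
            (make_branched_tradeoff(10.0, 0.5, 0.3), "BIOMASS"),
            (make_branched_tradeoff(5.0, 0.25, 1.0), "EX_prod"),
        ]
        for model, objective in cases:
            lp = solve_fba(model, objective=objective).objective_value
            oracle = vertex_enumeration_optimum(model, objective)
            assert lp == pytest.approx(oracle, abs=1e-9)

    def test_matches_cobra_on_mini(self, mini, synthesis):
        ours = solve_fba(mini, synthesis).objective_value
        theirs = to_cobra(mini, synthesis).optimize().objective_value
        assert ours == pytest.approx(theirs, abs=1e-6)

    def test_blocked_objective_reports_zero_not_failure(self, chain):
        blocked = chain.copy()
        blocked.reaction("R1").upper_bound = 0.0
        sol = solve_fba(blocked)
        assert sol.ok
        assert sol.objective_value == pytest.approx(0.0, abs=1e-12)

    def test_infeasible_status_propagated(self, chain):
        sol = solve_fba(chain, fixed_rates={"EX_bio": 100.0})
        assert sol.status == "infeasible"
        assert sol.objective_value is None

    def test_uptake_relaxation_monotone(self, mini, synthesis):
        base = solve_fba(mini, synthesis).objective_value
        for cap in (1.5, 2.0, 5.0):
            relaxed = solve_fba(mini, synthesis.with_uptake(EX_malt=cap))
            assert relaxed.objective_value >= base - 1e-9
            base = relaxed.objective_value

    def test_permutation_invariance(self, mini, synthesis):
        baseline = solve_fba(mini, synthesis).objective_value
        shuffled = mini.copy()
        rng = np.random.default_rng(7)
        order_r = rng.permutation(len(shuffled.reactions))
        order_m = rng.permutation(len(shuffled.metabolites))
        shuffled.reactions = [shuffled.reactions[i] for i in order_r]
        shuffled.metabolites = [shuffled.metabolites[i] for i in order_m]
        assert solve_fba(shuffled, synthesis).objective_value == pytest.approx(
            baseline, abs=1e-9
        )

    def test_deterministic_across_repeats(self, mini, synthesis):
        values = {solve_fba(mini, synthesis).objective_value for _ in range(5)}
        assert len(values) == 1

    def test_parsimonious_keeps_optimum_and_shrinks_flux(self, mini, synthesis):
        plain = solve_fba(mini, synthesis)
        pfba = solve_fba(mini, synthesis, parsimonious=True)
        assert pfba.objective_value == pytest.approx(plain.objective_value, abs=1e-8)
        assert sum(map(abs, pfba.fluxes.values())) <= \
            sum(map(abs, plain.fluxes.values())) + 1e-6


class TestGrowthAndProduction:
    def test_fixed_rates_are_equalities(self):
        model = make_branched_tradeoff(10.0, 0.5, 0.3)
        sol = simulate_growth(model, fixed_rates={"EX_sub": -4.0})
        assert sol.fluxes["EX_sub"] == pytest.approx(-4.0)
        assert sol.objective_value == pytest.approx(2.0)  # 4 * 0.5

    def test_production_closed_form_on_branched(self):
        cap, yb, yp = 10.0, 0.5, 0.3
        model = make_branched_tradeoff(cap, yb, yp)
        mu_max = cap * yb
        for mu in (0.0, mu_max / 2, mu_max):
            sol = simulate_production(model, None, mu, "EX_prod")
            expected = yp * (cap - mu / yb)
            assert sol.objective_value == pytest.approx(expected, abs=1e-8)

    def test_infeasible_growth_raises(self):
        model = make_branched_tradeoff(10.0, 0.5, 0.3)
        with pytest.raises(FBAError):
            simulate_production(model, None, 10.0, "EX_prod")

    def test_contradictory_constraints_infeasible(self, chain):
        # chain(2, 0.5, cap 10) converts at most 10 -> 2.5; demanding an
        # output of 5 from an input of 10 cannot balance
        sol = simulate_growth(
            chain, fixed_rates={"EX_sub": -10.0, "EX_bio": 5.0}
        )
        assert sol.status == "infeasible"


class TestRobustness:
    def test_decoupled_reaction_gives_flat_curve(self):
        # scanning the redundant transporter pair member: T1+T2 split is
        # degenerate, so fixing T1 anywhere below the cap leaves the
        # optimum unchanged
        model = make_branched_tradeoff(10.0, 0.5, 0.3)
        curve = robustness_scan(
            model, None, "T1", [0.0, 2.0, 4.0, 6.0], objective="BIOMASS"
        )
        assert all(v == pytest.approx(5.0, abs=1e-9) for v in curve.values)

    def test_empty_grid_rejected(self, mini, synthesis):
        with pytest.raises(ValueError):
            robustness_scan(mini, synthesis, "EX_o2", [], objective="EX_acb")

    def test_non_increasing_grid_rejected(self, mini, synthesis):
        with pytest.raises(ValueError):
            robustness_scan(mini, synthesis, "EX_o2", [0.0, 0.0], objective="EX_acb")

    def test_infeasible_points_recorded(self, chain):
        curve = robustness_scan(
            chain, None, "EX_bio", [0.0, 2.0, 100.0], objective="EX_bio"
        )
        assert curve.statuses[-1] == "infeasible"
        assert curve.values[-1] is None
        assert curve.values[0] == pytest.approx(0.0)


class TestPathwayRatio:
    def test_equal_fluxes_give_one(self, mini, synthesis):
        sol = solve_fba(mini, synthesis, parsimonious=True)
        assert pathway_flux_ratio(sol, ["GLYC"], ["GLYC"]) == 1.0

    def test_zero_numerator_gives_zero(self, mini, synthesis):
        sol = solve_fba(mini, synthesis, parsimonious=True)
        assert pathway_flux_ratio(sol, ["TREY"], ["GLYC"]) == pytest.approx(0.0)

    def test_zero_denominator_signalled(self, mini, synthesis):
        sol = solve_fba(mini, synthesis, parsimonious=True)
        with pytest.raises(UndefinedFluxRatioError):
            pathway_flux_ratio(sol, ["GLYC"], ["TREY"])

    def test_ppp_to_glycolysis_ratio_rises_with_enforced_product(
        self, mini, synthesis
    ):
        """The PPP/glycolysis split shifts toward the PPP when product
        formation is enforced (the oxygen-level/flux-partition effect)."""
        low = solve_fba(mini, synthesis, parsimonious=True,
                        fixed_rates={"EX_acb": 0.05})
        high = solve_fba(mini, synthesis, parsimonious=True,
                         fixed_rates={"EX_acb": 0.4})
        r_low = pathway_flux_ratio(low, ["PPPOX"], ["GLYC"])
        r_high = pathway_flux_ratio(high, ["PPPOX"], ["GLYC"])
        assert r_high > r_low
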