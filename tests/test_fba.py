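"""LP solutions, duals and their semantics."""

import itertools

import numpy as np
import pytest

from phenoflux import fba
from phenoflux.model import Metabolite, Model, Reaction
from phenoflux.synth import ToyModelSpec, gen_toy_model, synthetic_base_model


def _relaxed_solve(model, met_id, eps):
    """Re-solve with an epsilon supply of one metabolite (a free source
    reaction fixed at eps) — the finite-difference oracle for duals."""
    m = model.copy()
    m.add_reaction(
        Reaction(
            id="__supply__",
            stoichiometry={met_id: 1},
            lower_bound=eps,
            upper_bound=eps,
        )
    )
    return fba.solve_fba(m)


class TestSolveFBA:
    def test_single_bottleneck_chain(self, chain_model):
        sol = fba.solve_fba(chain_model)
        assert sol.status == "optimal"
        assert sol.objective_value == pytest.approx(10.0, abs=1e-9)

    def test_parallel_routes_vs_vertex_enumeration(self, parallel_model):
        """Optimum 7 = brute-force over the route-cap vertices."""
        best = max(
            r1 + r2
            for r1, r2 in itertools.product([0.0, 3.0], [0.0, 4.0])
        )
        sol = fba.solve_fba(parallel_model)
        assert sol.objective_value == pytest.approx(best, abs=1e-9)
        assert best == 7.0

    def test_no_source_zero_objective(self, chain_model):
        preset = fba.ConditionPreset("closed", {"EX_A": (0.0, 0.0)})
        sol = fba.solve_fba(chain_model, preset=preset)
        assert sol.objective_value == pytest.approx(0.0, abs=1e-12)

    def test_infeasible_reported_not_raised(self):
        m = Model()
        m.add_metabolite(Metabolite("A[c]"))
        m.add_reaction(
            Reaction(id="forced", stoichiometry={"A[c]": 1},
                     lower_bound=1.0, upper_bound=2.0)
        )
        m.add_reaction(
            Reaction(id="biomass", stoichiometry={"A[c]": -1},
                     lower_bound=0.0, upper_bound=0.5)
        )
        m.objective = "biomass"
        assert fba.solve_fba(m).status == "infeasible"

    def test_unbounded_reported_not_raised(self):
        m = Model()
        m.add_metabolite(Metabolite("A[c]"))
        m.add_reaction(
            Reaction(id="src", stoichiometry={"A[c]": 1},
                     lower_bound=0.0, upper_bound=float("inf"))
        )
        m.add_reaction(
            Reaction(id="biomass", stoichiometry={"A[c]": -1},
                     lower_bound=0.0, upper_bound=float("inf"))
        )
        m.objective = "biomass"
        assert fba.solve_fba(m).status == "unbounded"

    def test_steady_state_and_bounds_respected(self):
        model, _ = gen_toy_model(ToyModelSpec(seed=5, n_chains=4))
        sol = fba.solve_fba(model)
        rxn_ids = list(model.reactions)
        for mid, met in model.metabolites.items():
            net = sum(
                r.stoichiometry.get(mid, 0) * sol.fluxes[r.id]
                for r in model.reactions.values()
            )
            assert abs(net) < 1e-9
        for rid in rxn_ids:
            r = model.reactions[rid]
            assert r.lower_bound - 1e-9 <= sol.fluxes[rid] <= r.upper_bound + 1e-9

    def test_strong_duality(self):
        for seed in range(5):
            model, _ = gen_toy_model(ToyModelSpec(seed=seed))
            sol = fba.solve_fba(model)
            assert sol.duality_gap < 1e-6

    def test_cobrapy_agrees_on_toy_optimum(self, tmp_path):
        """Independent solver route: cobrapy on the same SBML model."""
        import cobra.io

        from phenoflux.model import write_sbml

        model, ans = gen_toy_model(ToyModelSpec(seed=11))
        path = tmp_path / "toy.xml"
        write_sbml(model, path)
        cm = cobra.io.read_sbml_model(str(path))
        cm.objective = "biomass"
        assert cm.optimize().objective_value == pytest.approx(
            ans["optimum"], abs=1e-6
        )
        assert fba.solve_fba(model).objective_value == pytest.approx(
            ans["optimum"], abs=1e-6
        )


class TestShadowPrices:
    @pytest.mark.parametrize("seed", range(6))
    def test_finite_difference_semantics(self, seed):
        """Supplying eps of metabolite m shifts the optimum by sp_m * eps
        on non-degenerate toys (eps = 1e-3)."""
        model, ans = gen_toy_model(ToyModelSpec(seed=seed))
        sol = fba.solve_fba(model)
        assert not sol.degenerate_flag
        eps = 1e-3
        rng = np.random.default_rng(seed)
        mets = rng.choice(sorted(sol.shadow_prices), size=4, replace=False)
        for mid in mets:
            relaxed = _relaxed_solve(model, mid, eps)
            fd = (relaxed.objective_value - sol.objective_value) / eps
            assert fd == pytest.approx(sol.shadow_prices[mid], abs=1e-6)

    def test_analytic_duals_on_planted_chains(self):
        for seed in range(8):
            model, ans = gen_toy_model(ToyModelSpec(seed=seed, n_chains=3))
            sol = fba.solve_fba(model)
            for mid, expected in ans["shadow_prices"].items():
                assert sol.shadow_prices[mid] == pytest.approx(
                    expected, abs=1e-6
                ), (seed, mid)

    def test_scale_covariance(self):
        model, _ = gen_toy_model(ToyModelSpec(seed=3))
        sol1 = fba.solve_fba(model)
        scaled = model.copy()
        for r in scaled.reactions.values():
            r.lower_bound *= 3.0
            r.upper_bound *= 3.0
        sol3 = fba.solve_fba(scaled)
        assert sol3.objective_value == pytest.approx(
            3 * sol1.objective_value, rel=1e-9
        )
        for mid, sp in sol1.shadow_prices.items():
            assert sol3.shadow_prices[mid] == pytest.approx(sp, abs=1e-8)

    def test_monotone_relaxation(self):
        """Widening any bound (or adding a reaction) never lowers the
        optimum."""
        model, _ = gen_toy_model(ToyModelSpec(seed=9))
        base_opt = fba.solve_fba(model).objective_value
        for rid in list(model.reactions)[:6]:
            widened = model.copy()
            widened.reactions[rid].upper_bound += 5.0
            assert fba.solve_fba(widened).objective_value >= base_opt - 1e-9
        richer = model.copy()
        richer.add_reaction(
            Reaction(id="extra_src", stoichiometry={"prec[c]": 1},
                     upper_bound=1.0)
        )
        assert fba.solve_fba(richer).objective_value >= base_opt - 1e-9

    def test_new_pathway_shifts_only_adjacent_duals(self):
        """A bypass route around a capped conversion step changes the dual
        of the metabolite it touches (and nothing else), matching
        finite-difference re-solves."""
        m = Model()
        for mid in ("S[c]", "A[c]"):
            m.add_metabolite(Metabolite(mid))
        m.add_reaction(
            Reaction(id="EX_S", stoichiometry={"S[c]": -1}, reversible=True,
                     lower_bound=-10.0, upper_bound=0.0, category="exchange")
        )
        m.add_reaction(
            Reaction(id="conv", stoichiometry={"S[c]": -1, "A[c]": 1},
                     upper_bound=6.0)  # binding in the base model
        )
        m.add_reaction(Reaction(id="biomass", stoichiometry={"A[c]": -1}))
        m.objective = "biomass"
        sol_a = fba.solve_fba(m)
        assert sol_a.objective_value == pytest.approx(6.0)
        richer = m.copy()
        richer.add_reaction(
            Reaction(id="bypass", stoichiometry={"S[c]": -1, "A[c]": 1})
        )
        sol_b = fba.solve_fba(richer)
        assert sol_b.objective_value == pytest.approx(10.0)
        cmp = fba.compare_shadow_prices(sol_a, sol_b, tau=1e-6)
        differing = set(cmp.table.loc[cmp.table.differs, "metabolite"])
        assert differing == {"S[c]"}  # binding moved to the S uptake
        eps = 1e-3
        for sol, model in ((sol_a, m), (sol_b, richer)):
            for mid in ("S[c]", "A[c]"):
                fd = (
                    _relaxed_solve(model, mid, eps).objective_value
                    - sol.objective_value
                ) / eps
                assert fd == pytest.approx(sol.shadow_prices[mid], abs=1e-6)


class TestClassification:
    @pytest.mark.parametrize(
        "sp,expected",
        [(0.0, "neutral"), (0.168, "excess"), (-0.65, "limiting"),
         (1e-12, "neutral")],
    )
    def test_sign_classes(self, sp, expected):
        assert fba.classify_metabolite(sp, tol=1e-9) == expected

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            fba.classify_metabolite(float("nan"))


class TestComparison:
    def test_identical_solutions(self, chain_model):
        sol = fba.solve_fba(chain_model)
        cmp = fba.compare_shadow_prices(sol, sol)
        assert cmp.n_differing == 0

    def test_absent_metabolites_not_counted(self, chain_model):
        sol = fba.solve_fba(chain_model)
        other = fba.FluxSolution(
            "optimal", sol.objective_value, {}, {"Z[c]": 5.0}
        )
        cmp = fba.compare_shadow_prices(sol, other, tau=1e-3)
        assert cmp.n_differing == 0  # nothing shared
        assert set(cmp.table.metabolite) == {"A[c]", "Z[c]"}

    def test_non_optimal_rejected(self, chain_model):
        sol = fba.solve_fba(chain_model)
        bad = fba.FluxSolution("infeasible", float("nan"), {}, {})
        with pytest.raises(ValueError, match="optimal"):
            fba.compare_shadow_prices(sol, bad)

    def test_radar_report_round_trip(self, tmp_path, chain_model):
        import pandas as pd

        sol = fba.solve_fba(chain_model)
        cmp = fba.compare_shadow_prices(sol, sol)
        table = fba.radar_report(cmp)
        assert len(table) == len(sol.shadow_prices)
        path = tmp_path / "radar.tsv"
        table.to_csv(path, sep="\t", index=False)
        back = pd.read_csv(path, sep="\t")
        pd.testing.assert_frame_equal(back, table)

    def test_empty_comparison(self):
        a = fba.FluxSolution("optimal", 0.0, {}, {})
        cmp = fba.compare_shadow_prices(a, a)
        assert len(fba.radar_report(cmp)) == 0


class TestPresets:
    def test_light_dark_switch_carbon_source(self, base_model):
        light = fba.light_preset(base_model)
        dark = fba.dark_preset(base_model)
        sol_light = fba.solve_fba(base_model, preset=light)
        sol_dark = fba.solve_fba(base_model, preset=dark)
        assert sol_light.optimal and sol_dark.optimal
        # light: photons drive growth, acetate uptake closed
        assert sol_light.fluxes["EX_ac_e"] >= -1e-9
        assert sol_light.fluxes["EX_photon_e"] < 0
        # dark: photons closed, acetate taken up
        assert sol_dark.fluxes["EX_photon_e"] >= -1e-9
        assert sol_dark.fluxes["EX_ac_e"] < 0
        assert sol_light.objective_value != pytest.approx(
            sol_dark.objective_value
        )

    def test_preset_invariants(self, base_model):
        light = fba.light_preset(base_model)
        dark = fba.dark_preset(base_model)
        assert light.exchange_overrides["EX_ac_e"][0] == 0.0
        assert dark.exchange_overrides["EX_photon_e"][0] == 0.0
        assert dark.exchange_overrides["EX_ac_e"][0] < 0

    def test_unknown_exchange_rejected(self, chain_model):
        preset = fba.ConditionPreset("x", {"EX_missing": (0, 0)})
        with pytest.raises(KeyError, match="EX_missing"):
            fba.solve_fba(chain_model, preset=preset)
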