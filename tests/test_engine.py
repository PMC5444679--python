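"""LP engine: assembly, optimality, parsimony, FVA and invariants."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import kmflux as kf
from kmflux.core import Metabolite, Reaction, StoichiometricModel, stoichiometric_matrix
from kmflux.engine import (
    ConfigurationError,
    ExchangePolicy,
    Objective,
    assemble_lp,
    flux_variability,
    metabolite_balance,
    parsimonious_refine,
    solve_fba,
)


def chain_model(n_inner=2, bound=50.0):
    """A -> B -> ... linear chain with uptake on the first, export on the last."""
    spec = kf.GeneratorSpec(
        n_metabolites=n_inner + 1, n_reactions=n_inner, seed=0, bound_magnitude=bound
    )
    return kf.random_small_model(spec)


class TestSolveFBA:
    def test_linear_chain_conserves_uptake(self):
        model = chain_model()
        lp = assemble_lp(
            model, kf.uptake_export_policy(model, 10), kf.export_objective(model)
        )
        sol = solve_fba(lp)
        assert sol.optimal
        assert sol.objective_value == pytest.approx(10, abs=1e-9)
        assert all(v == pytest.approx(10, abs=1e-9) for v in sol.v.values())

    def test_lp_has_56_internal_variables_for_builtin(self, ref_model):
        cfg = kf.scenario_registry("fig1")
        _, lp = kf.configure_scenario(ref_model, cfg)
        assert lp.n_reactions == 56

    def test_all_exchanges_closed_forces_null_flux(self, ref_model):
        lp = assemble_lp(
            ref_model, ExchangePolicy(), Objective(reaction_weights={"vgrowth": 1})
        )
        sol = solve_fba(lp)
        assert sol.optimal and sol.objective_value == pytest.approx(0, abs=1e-9)
        refined = parsimonious_refine(lp, sol.objective_value)
        assert max(abs(v) for v in refined.v.values()) <= 1e-9

    def test_zero_carbon_uptake_means_zero_growth(self, ref_model):
        cfg = dataclasses.replace(kf.scenario_registry("fig1"), uptake=0.0)
        rep = kf.run_scenario(ref_model, cfg, fva=False)
        assert rep.optimal and rep.growth == pytest.approx(0, abs=1e-9)

    def test_infeasible_reported_as_status(self):
        # forced export with no producing pathway
        model = chain_model()
        policy = ExchangePolicy(
            modes={"m0": "closed", "m2": "fixed"}, bounds={"m2": 5.0}
        )
        sol = solve_fba(assemble_lp(model, policy, kf.export_objective(model)))
        assert sol.status == "infeasible"

    def test_unknown_ids_rejected(self, ref_model):
        cfg = kf.scenario_registry("fig1")
        with pytest.raises(ConfigurationError):
            assemble_lp(
                ref_model, cfg.exchange_policy(),
                Objective(reaction_weights={"nosuch": 1.0}),
            )
        with pytest.raises(ConfigurationError):
            assemble_lp(
                ref_model, cfg.exchange_policy(), cfg.objective,
                edits={"nosuch": (0.0, 0.0)},
            )


class TestCrossCheck:
    def test_lp_optimum_matches_cobrapy_on_nadph_maximisation(self, ref_model):
        """Independent LP route: the same scenario rebuilt in cobrapy (GLPK)
        reproduces the NADPH-maximisation optimum."""
        import cobra

        scenario_model, lp = kf.configure_scenario(
            ref_model, kf.scenario_registry("fig3")
        )
        cm = cobra.Model("fig3")
        mets = {m.id: cobra.Metabolite(m.id) for m in scenario_model.metabolites}
        reactions = []
        for j, rxn in enumerate(scenario_model.reactions):
            cr = cobra.Reaction(rxn.id)
            cr.bounds = (lp.lb[j], lp.ub[j])
            reactions.append((cr, {mets[m]: c for m, c in rxn.stoich.items()}))
        for k, met in enumerate(lp.exchange_order):
            cr = cobra.Reaction(f"EX_{met}")
            j = lp.n_reactions + k
            cr.bounds = (lp.lb[j], lp.ub[j])
            reactions.append((cr, {mets[met]: -1.0}))
        for cr, stoich in reactions:
            cm.add_reactions([cr])
            cr.add_metabolites(stoich)
        cm.objective = "EX_nadph"
        cobra_opt = cm.optimize().objective_value
        ours = solve_fba(lp).objective_value
        assert ours == pytest.approx(cobra_opt, abs=1e-6)


class TestParsimony:
    def test_free_two_reaction_loop_is_zeroed(self):
        model = StoichiometricModel(
            metabolites=(
                Metabolite("a", default_exchangeable=True),
                Metabolite("b"),
                Metabolite("c", default_exchangeable=True),
            ),
            reactions=(
                Reaction(id="in2out", stoich={"a": -1, "c": 1}, upper_bound=100),
                Reaction(id="loop_fwd", stoich={"a": -1, "b": 1}, upper_bound=100),
                Reaction(id="loop_back", stoich={"b": -1, "a": 1}, upper_bound=100),
            ),
            exchangeable=frozenset({"a", "c"}),
        )
        policy = ExchangePolicy(modes={"a": "uptake", "c": "export"}, bounds={"a": -10})
        lp = assemble_lp(model, policy, Objective(exchange_weights={"c": 1.0}))
        sol = solve_fba(lp)
        refined = parsimonious_refine(lp, sol.objective_value)
        assert refined.objective_value == pytest.approx(sol.objective_value, abs=2e-9)
        assert refined.v["loop_fwd"] == pytest.approx(0, abs=1e-8)
        assert refined.v["loop_back"] == pytest.approx(0, abs=1e-8)

    def test_fbp_stays_silent_on_xylose_growth(self, figure_reports):
        assert figure_reports["fig2"].flux("fbp") == pytest.approx(0, abs=1e-8)


class TestFVA:
    def test_fixed_chain_is_fully_determined(self):
        model = chain_model()
        lp = assemble_lp(
            model, kf.uptake_export_policy(model, 10), kf.export_objective(model)
        )
        sol = solve_fba(lp)
        fva = flux_variability(lp, sol.objective_value)
        for rid in model.reaction_ids:
            lo, hi = fva[rid]
            assert lo == pytest.approx(hi, abs=1e-8)
            assert lo == pytest.approx(10, abs=1e-8)

    def test_refined_solution_lies_inside_fva_ranges(self, fig2_with_fva):
        rep = fig2_with_fva
        assert not rep.fva.failures
        for rid, flux in rep.solution.v.items():
            lo, hi = rep.fva[rid]
            assert lo - 1e-6 <= flux <= hi + 1e-6, rid

    def test_unconstrained_loop_flagged_by_wide_range(self):
        """With FBP and PFK both active and ATP accumulating, FVA exposes
        the substrate cycle as an undetermined flux direction."""
        model = kf.build_reference_model()
        cfg = kf.scenario_registry("fig2")
        _, lp = kf.configure_scenario(model, cfg)
        sol = solve_fba(lp)
        fva = flux_variability(lp, sol.objective_value, variables=["fbp", "pfk"])
        assert fva.width("fbp") > 1.0
        assert fva.width("pfk") > 1.0


class TestInvariants:
    def test_mass_balance_residual_below_tolerance(self, figure_reports):
        for fig, rep in figure_reports.items():
            assert rep.optimal, fig
            assert rep.solution.residual <= 1e-9, fig

    def test_balance_equals_exchange_and_zero_when_closed(self, figure_reports):
        rep = figure_reports["fig2"]
        model = rep.model
        S, _, _ = stoichiometric_matrix(model)
        v = np.array([rep.solution.v[r.id] for r in model.reactions])
        net = S @ v
        midx = model.metabolite_index()
        for met in ("atp", "co2", "o2"):
            assert rep.balances[met] == pytest.approx(net[midx[met]], abs=1e-8)
        # NADPH exchange is closed in fig2: balance must be exactly zero
        assert metabolite_balance(model, rep.solution, "nadph") == 0.0
        assert abs(net[midx["nadph"]]) <= 1e-9
        with pytest.raises(KeyError):
            metabolite_balance(model, rep.solution, "unobtainium")

    @settings(max_examples=15, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 2_000))
    def test_deactivating_a_reaction_never_raises_optimum(self, seed):
        spec = kf.GeneratorSpec(seed=seed)
        model = kf.random_small_model(spec)
        policy = kf.uptake_export_policy(model, spec.bound_magnitude / 2)
        objective = kf.export_objective(model)
        base = solve_fba(assemble_lp(model, policy, objective))
        rng = np.random.Generator(np.random.Philox(key=seed))
        victim = model.reaction_ids[int(rng.integers(len(model.reactions)))]
        knocked = solve_fba(
            assemble_lp(model, policy, objective, edits={victim: (0.0, 0.0)})
        )
        if knocked.optimal:
            assert knocked.objective_value <= base.objective_value + 1e-7

    def test_opening_an_exchange_never_lowers_growth(self, ref_model):
        cfg = kf.scenario_registry("fig2")
        base = kf.run_scenario(ref_model, cfg, fva=False)
        wider = dataclasses.replace(cfg, accumulate=cfg.accumulate + ("nadph",))
        opened = kf.run_scenario(ref_model, wider, fva=False)
        assert opened.growth >= base.growth - 1e-7

    @pytest.mark.parametrize("k", [0.5, 2.0])
    def test_optimum_scales_with_carbon_uptake(self, ref_model, figure_reports, k):
        cfg = dataclasses.replace(
            kf.scenario_registry("fig2"), uptake=10.0 * k
        )
        scaled = kf.run_scenario(ref_model, cfg, fva=False)
        assert scaled.growth == pytest.approx(
            k * figure_reports["fig2"].growth, rel=1e-6
        )
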