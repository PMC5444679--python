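"""Scenario registry, model edits and the figure-level flux routing facts."""

import dataclasses
import math

import pytest

import kmflux as kf
from kmflux.engine import ConfigurationError

TOL = 1e-6


class TestRegistry:
    def test_fig9_swaps_g6p_dehydrogenase_to_nad(self):
        cfg = kf.scenario_registry("fig9")
        assert (("zwf", ("nadp", "nadph"), ("nad", "nadh")),) == cfg.cofactor_swaps

    def test_fig11_is_anaerobic_with_oxygen_closed(self):
        cfg = kf.scenario_registry("fig11")
        assert not cfg.aerobic
        assert cfg.exchange_policy().mode("o2") == "closed"

    def test_fig7_closes_atp_but_opens_glycerol(self):
        policy = kf.scenario_registry("fig7").exchange_policy()
        assert policy.mode("atp") == "closed"
        assert policy.mode("glyc") == "export"

    def test_unknown_figure_rejected(self):
        with pytest.raises(ConfigurationError):
            kf.scenario_registry("fig99")

    def test_carbon_source_has_fixed_uptake_of_10(self):
        for fig in kf.FIGURE_IDS:
            cfg = kf.scenario_registry(fig)
            carbon = "glc" if cfg.carbon_source == "glucose" else "xyl"
            policy = cfg.exchange_policy()
            assert policy.mode(carbon) == "fixed"
            assert policy.bounds[carbon] == -10.0


class TestReactionActivity:
    def test_deactivating_pfk_by_metacyc_id_silences_it(self, ref_model):
        cfg = kf.set_reaction_activity(
            kf.scenario_registry("fig5"), "6PFRUCTPHOS-RXN", False, model=ref_model
        )
        rep = kf.run_scenario(ref_model, cfg, fva=False)
        assert rep.flux("pfk") == pytest.approx(0, abs=TOL)

    def test_deactivating_growth_zeroes_the_objective(self, ref_model):
        cfg = kf.set_reaction_activity(
            kf.scenario_registry("fig2"), "vgrowth", False, model=ref_model
        )
        rep = kf.run_scenario(ref_model, cfg, fva=False)
        assert rep.optimal and rep.growth == pytest.approx(0, abs=TOL)

    def test_reactivation_restores_config(self, ref_model):
        base = kf.scenario_registry("fig2")
        off = kf.set_reaction_activity(base, "fbp", False, model=ref_model)
        on = kf.set_reaction_activity(off, "fbp", True, model=ref_model)
        assert on.inactive_reactions == base.inactive_reactions

    def test_unknown_reaction_rejected(self, ref_model):
        with pytest.raises(ConfigurationError):
            kf.set_reaction_activity(
                kf.scenario_registry("fig2"), "NOSUCH-RXN", False, model=ref_model
            )


class TestCofactorSwap:
    def test_swap_moves_coefficients_unchanged(self, ref_model):
        swapped = kf.swap_cofactor(
            ref_model, "GLU6PDEHYDROG-RXN", ("nadp", "nadph"), ("nad", "nadh")
        )
        rxn = swapped.reaction("zwf")
        assert rxn.stoich["nad"] == -1 and rxn.stoich["nadh"] == 1
        assert "nadp" not in rxn.stoich and "nadph" not in rxn.stoich

    def test_swap_is_an_involution(self, ref_model):
        once = kf.swap_cofactor(ref_model, "zwf", ("nadp", "nadph"), ("nad", "nadh"))
        back = kf.swap_cofactor(once, "zwf", ("nad", "nadh"), ("nadp", "nadph"))
        assert back == ref_model

    def test_swap_without_the_old_pair_is_an_error(self, ref_model):
        with pytest.raises(ConfigurationError, match="nadp"):
            kf.swap_cofactor(ref_model, "pgi", ("nadp", "nadph"), ("nad", "nadh"))


class TestFluxRouting:
    """The per-figure narratives, asserted on the refined solutions."""

    def test_pgi_switches_direction_between_glucose_and_xylose(self, figure_reports):
        assert figure_reports["fig1"].flux("pgi") > TOL
        assert figure_reports["fig2"].flux("pgi") < -TOL

    def test_fig3_complete_cycling_yields_nadph_balance_90(self, figure_reports):
        rep = figure_reports["fig3"]
        assert rep.balances["nadph"] == pytest.approx(90, abs=1e-5)
        assert rep.flux("fbp") > TOL  # gluconeogenic PPP cycling runs through FBP

    def test_fig4_incomplete_cycling_yields_nadph_balance_30(self, figure_reports):
        rep = figure_reports["fig4"]
        assert rep.balances["nadph"] == pytest.approx(30, abs=1e-5)
        assert rep.solution.e["gap"] == pytest.approx(10, abs=1e-5)

    def test_fig5_overproduces_only_nadph_among_precursors(self, figure_reports):
        rep = figure_reports["fig5"]
        assert rep.balances["nadph"] > 1.0
        assert rep.flux("fbp") == pytest.approx(0, abs=TOL)
        for met in kf.BIOMASS_PRECURSORS:
            assert rep.solution.e[met] == pytest.approx(0, abs=TOL), met

    def test_fig6_accumulates_hexose_phosphate_and_grows_slower(self, figure_reports):
        rep = figure_reports["fig6"]
        hexose_export = rep.solution.e["g6p"] + rep.solution.e["f6p"]
        assert hexose_export > 1.0
        assert rep.growth < figure_reports["fig5"].growth - TOL

    def test_fig7_closed_atp_recruits_glycerol_and_pdb(self, figure_reports):
        rep = figure_reports["fig7"]
        assert rep.balances["glyc"] > TOL
        for step in ("pdc", "aldh", "acs"):  # the pyruvate dehydrogenase bypass
            assert rep.flux(step) > TOL, step
        assert rep.growth < figure_reports["fig2"].growth - TOL
        assert abs(rep.balances["o2"]) < abs(figure_reports["fig2"].balances["o2"])

    def test_fig8_substrate_cycle_replaces_glycerol(self, figure_reports):
        rep = figure_reports["fig8"]
        assert rep.balances["glyc"] == pytest.approx(0, abs=TOL)
        assert rep.flux("fbp") > 1.0 and rep.flux("pfk") > 1.0
        cycle_sets = [c.reactions for c, _ in rep.active_cycles]
        assert frozenset({"fbp", "pfk"}) in cycle_sets
        assert rep.growth > figure_reports["fig7"].growth + TOL

    def test_fig9_cyclic_ppp_beats_fig10(self, figure_reports):
        assert figure_reports["fig9"].growth > figure_reports["fig10"].growth + TOL
        assert figure_reports["fig9"].flux("fbp") > TOL

    def test_fig11_anaerobic_ferments_without_fbp_or_oxppp(self, figure_reports):
        rep = figure_reports["fig11"]
        assert rep.balances["etoh"] > 1.0
        assert rep.balances["atp"] == pytest.approx(0, abs=TOL)
        assert rep.flux("fbp") == pytest.approx(0, abs=TOL)
        assert rep.flux("zwf") == pytest.approx(0, abs=TOL)
        assert rep.flux("mae") > TOL

    def test_fig11_needs_malic_enzyme(self, ref_model):
        ko = kf.set_reaction_activity(
            kf.scenario_registry("fig11"), "MALIC-NADP-RXN", False, model=ref_model
        )
        rep = kf.run_scenario(ref_model, ko, fva=False)
        assert (not rep.optimal) or rep.growth == pytest.approx(0, abs=TOL)

    def test_limiting_malic_enzyme_exports_xylitol(self, ref_model):
        cfg = kf.limited_malic_config(ref_model, fraction=0.5)
        rep = kf.run_scenario(ref_model, cfg, fva=False)
        assert rep.optimal
        assert rep.balances["xlt"] > 0.5


class TestComparisons:
    def test_fig1_vs_fig2_flags_pgi_flip(self, figure_reports):
        cmp = kf.compare_conditions([figure_reports["fig1"], figure_reports["fig2"]])
        assert "pgi" in cmp.direction_flips[("fig1", "fig2")]
        assert cmp.table.loc["balance:atp", "fig2"] > cmp.table.loc["balance:atp", "fig1"]

    def test_identical_reports_have_unit_ratios_and_no_flips(self, figure_reports):
        rep = figure_reports["fig2"]
        cmp = kf.compare_conditions([rep, rep])
        key = ("fig2", "fig2")
        assert cmp.direction_flips[key] == ()
        ratios = cmp.ratios[key].dropna()
        assert ratios.sub(1.0).abs().le(1e-9).all()

    def test_comparison_requires_two_reports(self, figure_reports):
        with pytest.raises(ValueError):
            kf.compare_conditions([figure_reports["fig1"]])


class TestExpression:
    @pytest.mark.parametrize(
        "gene, expected",
        [("FBP1", 27.34), ("PFK1", 0.21), ("PFK2", 0.21)],
    )
    def test_fold_changes_match_printed_table(self, gene, expected):
        rec = next(r for r in kf.TABLE1 if r.gene == gene)
        assert round(kf.expression_fold_change(rec), 2) == expected

    def test_equal_fpkm_gives_unit_fold_change(self):
        assert kf.expression_fold_change(kf.ExpressionRecord("X", 5.0, 5.0)) == 1.0

    def test_zero_denominator_is_undefined_not_infinite(self):
        rec = kf.ExpressionRecord("X", 0.0, 7.0)
        assert kf.expression_fold_change(rec) is None
        table = kf.fold_change_table([rec])
        assert not table.loc["X", "defined"]
        assert not math.isinf(table.loc["X", "fold_change"] or 0.0)

    def test_negative_fpkm_rejected(self):
        with pytest.raises(ValueError):
            kf.ExpressionRecord("X", -1.0, 2.0)
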