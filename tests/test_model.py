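"""Structure of the built-in 56-reaction model and its domain types."""

import dataclasses

import numpy as np
import pytest

import kmflux as kf
from kmflux.core import ModelValidationError


class TestReferenceModel:
    def test_has_56_reactions_with_display_indices_1_to_56(self, ref_model):
        assert len(ref_model.reactions) == 56
        indices = sorted(r.display_index for r in ref_model.reactions)
        assert indices == list(range(1, 57))

    def test_fructose_bisphosphatase_stoichiometry(self, ref_model):
        rxn = ref_model.by_metacyc("F16BDEPHOS-RXN")
        assert rxn.display_index == 19
        assert rxn.stoich == {"fdp": -1, "h2o": -1, "f6p": 1, "pi": 1}
        assert not rxn.reversible and rxn.lower_bound == 0.0

    def test_fbp_pfk_pair_nets_atp_hydrolysis(self, ref_model):
        """The FBP + PFK column sum cancels all sugar phosphates, leaving
        ATP + H2O -> ADP + Pi."""
        S, _, _ = kf.stoichiometric_matrix(ref_model)
        ridx = ref_model.reaction_index()
        combined = S[:, ridx["fbp"]] + S[:, ridx["pfk"]]
        net = {
            m.id: c for m, c in zip(ref_model.metabolites, combined) if c != 0
        }
        assert net == {"atp": -1, "h2o": -1, "adp": 1, "pi": 1}

    def test_irreversible_reactions_have_zero_lower_bound(self, ref_model):
        for rxn in ref_model.reactions:
            if not rxn.reversible:
                assert rxn.lower_bound == 0.0, rxn.id

    def test_cofactors_flagged_and_used_widely(self, ref_model):
        cofactors = {m.id for m in ref_model.metabolites if m.is_cofactor}
        assert cofactors == {"atp", "adp", "nad", "nadh", "nadp", "nadph", "pi", "coa"}
        for cof in cofactors:
            users = [r for r in ref_model.reactions if cof in r.stoich]
            assert len(users) >= 2, cof

    def test_validator_passes_builtin_model(self, ref_model):
        assert kf.validate_model(ref_model) == []

    def test_electron_transport_po_ratio(self, ref_model):
        etc = ref_model.reaction("vetc")
        assert etc.stoich["atp"] == pytest.approx(2.5)
        assert etc.stoich["o2"] == pytest.approx(-0.5)
        assert ref_model.constants["po_ratio"] == 2.5


class TestStoichiometricMatrix:
    def test_shapes_and_zero_for_absent_metabolite(self, ref_model):
        S, E, order = kf.stoichiometric_matrix(ref_model)
        assert S.shape == (len(ref_model.metabolites), 56)
        midx = ref_model.metabolite_index()
        # glucose takes no part in the TCA aconitase step
        assert S[midx["glc"], ref_model.reaction_index()["aco1"]] == 0.0

    def test_exchange_selector_is_identity_like(self, ref_model):
        _, E, order = kf.stoichiometric_matrix(ref_model)
        assert E.shape[1] == len(order) == len(ref_model.exchangeable)
        for k in range(E.shape[1]):
            col = E[:, k]
            assert np.count_nonzero(col) == 1
            assert col.sum() == 1.0


class TestValidator:
    def test_dead_end_metabolite_is_reported(self, ref_model):
        extra = kf.Metabolite("orphanac", "dead-end product")
        rxn = ref_model.reaction("pdc")
        patched = rxn.with_stoich({**rxn.stoich, "orphanac": 1.0})
        model = dataclasses.replace(
            ref_model,
            metabolites=ref_model.metabolites + (extra,),
        ).replace_reaction(patched)
        kinds = {(f.kind, f.subject) for f in kf.validate_model(model)}
        assert ("dead-end", "orphanac") in kinds

    def test_deleting_growth_orphans_biomass(self, ref_model):
        model = ref_model.drop_reaction("vgrowth")
        findings = kf.validate_model(model)
        assert any(
            f.kind == "orphan-metabolite" and f.subject == "biomass"
            for f in findings
        )


class TestBiomassSpec:
    def test_invalid_drains_are_rejected_by_name(self):
        with pytest.raises(ModelValidationError, match="pyr"):
            kf.BiomassSpec(precursors={"pyr": -1.0}, atp=10, nadph=1)
        with pytest.raises(ModelValidationError, match="ATP"):
            kf.BiomassSpec(precursors={"pyr": 1.0}, atp=0, nadph=1)
        with pytest.raises(ModelValidationError, match="unknown metabolite"):
            kf.build_reference_model(
                kf.BiomassSpec(precursors={"nosuch": 1.0}, atp=10, nadph=1)
            )

    def test_growth_reaction_embeds_spec(self, ref_model):
        growth = ref_model.reaction("vgrowth")
        spec = kf.STANDIN_BIOMASS
        assert growth.stoich["g6p"] == -spec.precursors["g6p"]
        assert growth.stoich["atp"] == -spec.atp
        assert growth.stoich["adp"] == spec.atp
        assert growth.stoich["nadph"] == -spec.nadph
        assert growth.stoich["nadh"] == spec.nadh  # produced
        assert growth.stoich["coa"] == spec.precursors["accoa"]
        assert growth.stoich["biomass"] == 1.0

    def test_irreversible_with_negative_lower_bound_rejected(self):
        with pytest.raises(ModelValidationError, match="lower bound"):
            kf.Reaction(id="bad", stoich={"a": -1}, reversible=False, lower_bound=-1)
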