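"""The packaged 56-reaction *Kluyveromyces marxianus* central-metabolism model.

Single compartment, one pool per cofactor.  Glycolysis/gluconeogenesis,
pentose phosphate pathway, xylose assimilation (NADPH-dependent xylose
reductase, xylitol dehydrogenase, xylulokinase), TCA cycle, glyoxylate
shunt, a one-round generic beta-oxidation block, fermentative reactions
(pyruvate decarboxylase, alcohol/acetaldehyde dehydrogenase, glycerol
branch, ethyl acetate synthesis), anaplerosis (pyruvate carboxylase, PEP
carboxylase/carboxykinase, PEP synthase, malic enzyme), a lumped electron
transport chain at P/O 2.5 and a biomass drain.

Conventions
-----------
* Protons are not tracked; water is tracked but its exchange is always open,
  so it is effectively unbalanced.  Orthophosphate is tracked with an
  always-open exchange.
* AMP-forming ligases (acetate-CoA ligase, acyl-CoA synthetase, PEP
  synthase) are written as hydrolysing two ATP -> ADP equivalents, avoiding
  an AMP pool.
* Succinate dehydrogenase is lumped with ubiquinol oxidation at P/O 1.5;
  NADH oxidation (vETC) runs at P/O 2.5.
* The generic fatty acyl-CoA of the beta-oxidation block is the shortest
  even-chain species (C4), so one round terminates in two acetyl-CoA and the
  block introduces no artificial carbon loop.  The generic fatty acid is
  exchangeable but its exchange is closed by default.
* The pyruvate dehydrogenase complex is split into its three component
  reactions with explicit lipoamide intermediates, matching the reaction
  list (display indices 42-44).
"""

from __future__ import annotations

from .core import BiomassSpec, Metabolite, ModelValidationError, Reaction, StoichiometricModel

__all__ = [
    "STANDIN_BIOMASS",
    "BIOMASS_PRECURSORS",
    "COFACTOR_PARTNERS",
    "build_reference_model",
]

# Metabolite id, name, is_cofactor, default_exchangeable
_METABOLITES: list[tuple[str, str, bool, bool]] = [
    ("glc", "D-glucose", False, True),
    ("xyl", "D-xylose", False, True),
    ("xlt", "xylitol", False, True),
    ("xlu", "D-xylulose", False, False),
    ("g6p", "glucose 6-phosphate", False, False),
    ("f6p", "fructose 6-phosphate", False, False),
    ("fdp", "fructose 1,6-bisphosphate", False, False),
    ("dhap", "dihydroxyacetone phosphate", False, False),
    ("gap", "glyceraldehyde 3-phosphate", False, False),
    ("dpg", "1,3-bisphosphoglycerate", False, False),
    ("pg3", "3-phosphoglycerate", False, False),
    ("pg2", "2-phosphoglycerate", False, False),
    ("pep", "phosphoenolpyruvate", False, False),
    ("pyr", "pyruvate", False, False),
    ("pgl", "6-phosphogluconolactone", False, False),
    ("pg6", "6-phosphogluconate", False, False),
    ("ru5p", "ribulose 5-phosphate", False, False),
    ("r5p", "ribose 5-phosphate", False, False),
    ("x5p", "xylulose 5-phosphate", False, False),
    ("s7p", "sedoheptulose 7-phosphate", False, False),
    ("e4p", "erythrose 4-phosphate", False, False),
    ("glyc3p", "glycerol 3-phosphate", False, False),
    ("glyc", "glycerol", False, True),
    ("acald", "acetaldehyde", False, False),
    ("etoh", "ethanol", False, True),
    ("ac", "acetate", False, True),
    ("etac", "ethyl acetate", False, True),
    ("accoa", "acetyl-CoA", False, False),
    ("cit", "citrate", False, False),
    ("acon", "cis-aconitate", False, False),
    ("icit", "isocitrate", False, False),
    ("akg", "2-oxoglutarate", False, False),
    ("succoa", "succinyl-CoA", False, False),
    ("succ", "succinate", False, False),
    ("fum", "fumarate", False, False),
    ("mal", "malate", False, False),
    ("oaa", "oxaloacetate", False, False),
    ("glx", "glyoxylate", False, False),
    ("fa", "generic fatty acid (C4)", False, True),
    ("acylcoa", "generic fatty acyl-CoA", False, False),
    ("enoylcoa", "generic 2-enoyl-CoA", False, False),
    ("hacylcoa", "generic 3-hydroxyacyl-CoA", False, False),
    ("ketoacylcoa", "generic 3-ketoacyl-CoA", False, False),
    ("lpam", "enzyme-bound lipoamide", False, False),
    ("dhlam", "enzyme-bound dihydrolipoamide", False, False),
    ("aclam", "enzyme-bound S-acetyldihydrolipoamide", False, False),
    ("biomass", "biomass", False, True),
    ("atp", "ATP", True, False),
    ("adp", "ADP", True, False),
    ("nad", "NAD+", True, False),
    ("nadh", "NADH", True, False),
    ("nadp", "NADP+", True, False),
    ("nadph", "NADPH", True, False),
    ("pi", "orthophosphate", True, True),
    ("coa", "coenzyme A", True, False),
    ("co2", "carbon dioxide", False, True),
    ("o2", "oxygen", False, True),
    ("h2o", "water", False, True),
]

# Conjugate partner opened for free exchange when a metabolite is allowed
# to accumulate (keeps conserved moieties exchangeable as a pair).
COFACTOR_PARTNERS: dict[str, str] = {
    "atp": "adp",
    "adp": "atp",
    "nadh": "nad",
    "nad": "nadh",
    "nadph": "nadp",
    "nadp": "nadph",
    "accoa": "coa",
}

# Carbon-skeleton precursors drained by the growth reaction (used by the
# scenario suite to open "all biomass precursors may accumulate" policies).
BIOMASS_PRECURSORS: tuple[str, ...] = (
    "g6p", "f6p", "r5p", "e4p", "gap", "pg3", "pep", "pyr", "accoa", "oaa", "akg",
)

#: Documented stand-in biomass coefficients (mmol per unit growth flux; one
#: growth-flux unit corresponds to ~10 g dry biomass so growth fluxes land
#: near 0.1 at the reference sugar uptake of 10).  Values follow textbook
#: yeast precursor demands.
STANDIN_BIOMASS = BiomassSpec(
    precursors={
        "g6p": 21.0,
        "f6p": 3.0,
        "r5p": 9.0,
        "e4p": 3.0,
        "gap": 2.0,
        "pg3": 15.0,
        "pep": 7.0,
        "pyr": 28.0,
        "accoa": 24.0,
        "oaa": 18.0,
        "akg": 11.0,
    },
    atp=350.0,
    nadph=110.0,
    nadh=60.0,
    provenance="standin",
)

_PO_NADH = 2.5   # P/O for NADH via the lumped ETC
_PO_FADH = 1.5   # P/O for succinate-derived electrons (folded into SDH)

# index, id, metacyc id, stoichiometry, reversible
_REACTIONS: list[tuple[int, str, str, dict[str, float], bool]] = [
    (1, "gpd", "1.1.1.8-RXN",
     {"dhap": -1, "nadh": -1, "glyc3p": 1, "nad": 1}, False),
    (2, "tkt1", "1TRANSKETO-RXN",
     {"r5p": -1, "x5p": -1, "s7p": 1, "gap": 1}, True),
    (3, "ogdh", "2OXOGLUTARATEDEH-RXN",
     {"akg": -1, "coa": -1, "nad": -1, "succoa": 1, "co2": 1, "nadh": 1}, False),
    (4, "eno", "2PGADEHYDRAT-RXN",
     {"pg2": -1, "pep": 1, "h2o": 1}, True),
    (5, "tkt2", "2TRANSKETO-RXN",
     {"e4p": -1, "x5p": -1, "f6p": 1, "gap": 1}, True),
    (6, "gpm", "3PGAREARR-RXN",
     {"pg3": -1, "pg2": 1}, True),
    (7, "pfk", "6PFRUCTPHOS-RXN",
     {"f6p": -1, "atp": -1, "fdp": 1, "adp": 1}, False),
    (8, "gnd", "6PGLUCONDEHYDROG-RXN",
     {"pg6": -1, "nadp": -1, "ru5p": 1, "co2": 1, "nadph": 1}, False),
    (9, "sol", "6PGLUCONOLACT-RXN",
     {"pgl": -1, "h2o": -1, "pg6": 1}, False),
    (10, "acs", "ACETATE--COA-LIGASE-RXN",
     {"ac": -1, "coa": -1, "atp": -2, "accoa": 1, "adp": 2, "pi": 2}, False),
    (11, "aco1", "ACONITATEDEHYDR-RXN",
     {"cit": -1, "acon": 1, "h2o": 1}, True),
    (12, "aco2", "ACONITATEHYDR-RXN",
     {"acon": -1, "h2o": -1, "icit": 1}, True),
    (13, "facs", "ACYLCOASYN-RXN",
     {"fa": -1, "coa": -1, "atp": -2, "acylcoa": 1, "adp": 2, "pi": 2}, False),
    (14, "adh", "ALCOHOL-DEHYDROG-RXN",
     {"acald": -1, "nadh": -1, "etoh": 1, "nad": 1}, True),
    (15, "cs", "CITSYN-RXN",
     {"accoa": -1, "oaa": -1, "h2o": -1, "cit": 1, "coa": 1}, False),
    (16, "xdh", "D-XYLULOSE-REDUCTASE-RXN",
     {"xlt": -1, "nad": -1, "xlu": 1, "nadh": 1}, True),
    (17, "ech", "ENOYL-COA-HYDRAT-RXN",
     {"enoylcoa": -1, "h2o": -1, "hacylcoa": 1}, False),
    (18, "fda", "F16ALDOLASE-RXN",
     {"fdp": -1, "dhap": 1, "gap": 1}, True),
    (19, "fbp", "F16BDEPHOS-RXN",
     {"fdp": -1, "h2o": -1, "f6p": 1, "pi": 1}, False),
    (20, "fumh", "FUMHYDR-RXN",
     {"fum": -1, "h2o": -1, "mal": 1}, True),
    (21, "gapdh", "GAPOXNPHOSPHN-RXN",
     {"gap": -1, "nad": -1, "pi": -1, "dpg": 1, "nadh": 1}, True),
    (22, "zwf", "GLU6PDEHYDROG-RXN",
     {"g6p": -1, "nadp": -1, "pgl": 1, "nadph": 1}, False),
    (23, "glk", "GLUCOKIN-RXN",
     {"glc": -1, "atp": -1, "g6p": 1, "adp": 1}, False),
    (24, "gpp", "GLYCEROL-1-PHOSPHATASE-RXN",
     {"glyc3p": -1, "h2o": -1, "glyc": 1, "pi": 1}, False),
    (25, "icl", "ISOCIT-CLEAV-RXN",
     {"icit": -1, "succ": 1, "glx": 1}, False),
    (26, "idp", "ISOCITDEH-RXN",
     {"icit": -1, "nadp": -1, "akg": 1, "co2": 1, "nadph": 1}, False),
    (27, "idh", "ISOCITRATE-DEHYDROGENASE-NAD+-RXN",
     {"icit": -1, "nad": -1, "akg": 1, "co2": 1, "nadh": 1}, False),
    (28, "kat", "KETOACYLCOATHIOL-RXN",
     {"ketoacylcoa": -1, "coa": -1, "accoa": 2}, False),
    (29, "mdh", "MALATE-DEH-RXN",
     {"mal": -1, "nad": -1, "oaa": 1, "nadh": 1}, True),
    (30, "mae", "MALIC-NADP-RXN",
     {"mal": -1, "nadp": -1, "pyr": 1, "co2": 1, "nadph": 1}, False),
    (31, "mls", "MALSYN-RXN",
     {"glx": -1, "accoa": -1, "h2o": -1, "mal": 1, "coa": 1}, False),
    (32, "hadh", "OHACYL-COA-DEHYDROG-RXN",
     {"hacylcoa": -1, "nad": -1, "ketoacylcoa": 1, "nadh": 1}, False),
    (33, "ppc", "PEPCARBOX-RXN",
     {"pep": -1, "co2": -1, "h2o": -1, "oaa": 1, "pi": 1}, False),
    (34, "pck", "PEPCARBOXYKIN-RXN",
     {"oaa": -1, "atp": -1, "pep": 1, "co2": 1, "adp": 1}, False),
    (35, "pyk", "PEPDEPHOS-RXN",
     {"pep": -1, "adp": -1, "pyr": 1, "atp": 1}, False),
    (36, "pps", "PEPSYNTH-RXN",
     {"pyr": -1, "atp": -2, "h2o": -1, "pep": 1, "adp": 2, "pi": 1}, False),
    (37, "pgi", "PGLUCISOM-RXN",
     {"g6p": -1, "f6p": 1}, True),
    (38, "pgk", "PHOSGLYPHOS-RXN",
     {"dpg": -1, "adp": -1, "pg3": 1, "atp": 1}, True),
    (39, "pyc", "PYRUVATE-CARBOXYLASE-RXN",
     {"pyr": -1, "co2": -1, "atp": -1, "h2o": -1, "oaa": 1, "adp": 1, "pi": 1}, False),
    (40, "rpi", "RIB5PISOM-RXN",
     {"ru5p": -1, "r5p": 1}, True),
    (41, "rpe", "RIBULP3EPIM-RXN",
     {"ru5p": -1, "x5p": 1}, True),
    (42, "lpd", "RXN0-1132",
     {"dhlam": -1, "nad": -1, "lpam": 1, "nadh": 1}, False),
    (43, "pdb2", "RXN0-1133",
     {"aclam": -1, "coa": -1, "accoa": 1, "dhlam": 1}, False),
    (44, "pdb1", "RXN0-1134",
     {"pyr": -1, "lpam": -1, "aclam": 1, "co2": 1}, False),
    (45, "aox", "RXN-11026",
     {"acylcoa": -1, "o2": -0.5, "enoylcoa": 1, "h2o": 1}, False),
    (46, "pdc", "RXN-6161",
     {"pyr": -1, "acald": 1, "co2": 1}, False),
    (47, "aldh", "RXN66-3",
     {"acald": -1, "nad": -1, "h2o": -1, "ac": 1, "nadh": 1}, False),
    (48, "xr", "RXN-8773",
     {"xyl": -1, "nadph": -1, "xlt": 1, "nadp": 1}, False),
    (49, "scs", "SUCCCOASYN-RXN",
     {"succoa": -1, "adp": -1, "pi": -1, "succ": 1, "atp": 1, "coa": 1}, True),
    (50, "sdh", "SUCCINATE-DEHYDROGENASE-UBIQUINONE-RXN",
     {"succ": -1, "o2": -0.5, "adp": -_PO_FADH, "pi": -_PO_FADH,
      "fum": 1, "atp": _PO_FADH, "h2o": 1}, False),
    (51, "tal", "TRANSALDOL-RXN",
     {"s7p": -1, "gap": -1, "e4p": 1, "f6p": 1}, True),
    (52, "tpi", "TRIOSEPISOMERIZATION-RXN",
     {"dhap": -1, "gap": 1}, True),
    (53, "vetc", "vETC",
     {"nadh": -1, "o2": -0.5, "adp": -_PO_NADH, "pi": -_PO_NADH,
      "nad": 1, "atp": _PO_NADH, "h2o": 1}, False),
    (54, "veta", "vEthylAcetate",
     {"accoa": -1, "etoh": -1, "etac": 1, "coa": 1}, False),
    (55, "vgrowth", "vGrowth", {}, False),  # filled from the BiomassSpec
    (56, "xk", "XYLULOKIN-RXN",
     {"xlu": -1, "atp": -1, "x5p": 1, "adp": 1}, False),
]


def build_reference_model(biomass: BiomassSpec | None = None) -> StoichiometricModel:
    """Assemble the 56-reaction model around a biomass specification.

    Parameters
    ----------
    biomass:
        Drain coefficients for the growth reaction.  Defaults to the
        documented stand-in set (``STANDIN_BIOMASS``).

    Raises
    ------
    ModelValidationError
        If the biomass spec is invalid (checked on construction of the
        spec) or drains reference metabolites absent from the model.
    """
    if biomass is None:
        biomass = STANDIN_BIOMASS
    metabolites = [Metabolite(*row) for row in _METABOLITES]
    met_ids = {m.id for m in metabolites}
    for met in biomass.precursors:
        if met not in met_ids:
            raise ModelValidationError(
                f"biomass spec drains unknown metabolite {met!r}"
            )
    reactions = []
    for index, rid, metacyc, stoich, reversible in _REACTIONS:
        if rid == "vgrowth":
            stoich = biomass.growth_stoich()
        reactions.append(
            Reaction(
                id=rid,
                stoich=stoich,
                metacyc_id=metacyc,
                display_index=index,
                reversible=reversible,
                lower_bound=-float("inf") if reversible else 0.0,
                upper_bound=float("inf"),
            )
        )
    exchangeable = {m.id for m in metabolites if m.default_exchangeable}
    return StoichiometricModel(
        metabolites=tuple(metabolites),
        reactions=tuple(reactions),
        exchangeable=frozenset(exchangeable),
        constants={"po_ratio": _PO_NADH, "default_uptake": 10.0},
    )
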