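"""Medium-scale constraint-based model of central carbon metabolism, biomass
production and the pathways to DHA.

A reduced (~90 reaction) three-compartment reconstruction with the full
kinetic subnetwork embedded under identical reaction ids, extended by the
pentose phosphate pathway, gluconeogenesis (FBPase, PEP carboxykinase), the
glyoxylate shunt (required for net carbon assimilation from ethanol and
acetate), the lipogenic citrate-malate cycle (ATP-citrate lyase + cytosolic
malate dehydrogenase + cytosolic NADP-malic enzyme, the canonical acetyl-CoA
and NADPH supply of oleaginous heterotrophs), lumped oxidative phosphorylation
(P/O 2.5 for NADH, 1.5 for FADH2), lumped macromolecule synthesis, a biomass
equation assembled from a macromolecular composition, and a DHA synthesis /
export route used to probe overproduction.

Flux unit: mmol.gDW-1.h-1 (biomass flux in h-1).  The linear programs are
solved with HiGHS via :func:`scipy.optimize.linprog`; reported flux vectors
can be canonicalized parsimoniously (minimum total |v| at fixed objective).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

from .netcore import (
    Compartment,
    MetabolicNetwork,
    Metabolite,
    Reaction,
    carbon_count,
    parse_equation,
)

__all__ = [
    "BiomassComposition",
    "StoichModel",
    "FBASolution",
    "DHAScanResult",
    "composition_from_fractions",
    "build_stoich_model",
    "solve_fba",
    "max_growth",
    "min_carbon_per_biomass",
    "dha_potential_scan",
    "KINETIC_TO_STOICH",
    "MONOMER_MASS",
    "DHA_MOLAR_MASS",
]

_BIG = 1000.0

#: kinetic reaction ids that map to a differently named stoichiometric
#: reaction (everything else maps to itself)
KINETIC_TO_STOICH = {"accoa_sink": "fas"}

#: molar masses (g/mol) of the lumped biomass building blocks
MONOMER_MASS = {
    "prot_c": 110.0,    # average amino-acid residue
    "carb_c": 162.14,   # anhydroglucose unit
    "tag_c": 807.3,     # generic triacylglycerol (C51)
    "dha_c": 328.5,     # docosahexaenoic acid
    "rna_c": 321.0,     # average ribonucleotide monophosphate residue
    "dna_c": 309.0,     # average deoxyribonucleotide residue
}
DHA_MOLAR_MASS = MONOMER_MASS["dha_c"]

#: growth-associated maintenance, mmol ATP per gDW (kept modest because the
#: lumped synthesis reactions already carry their own ATP costs)
GAM_ATP = 1.0


@dataclass
class BiomassComposition:
    """Precursor demands (mmol/gDW) plus the macromolecule mass fractions."""

    components: dict[str, float]
    macromolecule_fractions: dict[str, float]

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.components.values()):
            raise ValueError("biomass coefficients must be >= 0")
        core = sum(self.macromolecule_fractions.get(k, 0.0)
                   for k in ("protein", "carbohydrate", "lipid", "rna", "dna"))
        if not 0.95 <= core <= 1.0 + 1e-9:
            raise ValueError(
                f"macromolecule fractions sum to {core:.3f}, outside [0.95, 1.0]"
            )

    def mass_per_gdw(self) -> float:
        """Sum of coefficient x monomer molar mass, in mg/gDW (~1000 - ash)."""
        return sum(coeff * MONOMER_MASS[met]
                   for met, coeff in self.components.items())


def composition_from_fractions(fractions: dict[str, float]) -> BiomassComposition:
    """Monomer coefficients (mmol/gDW) = mass fraction / monomer molar mass.

    The DHA share of the lipid fraction is drawn from the DHA pool; the
    remainder is generic triacylglycerol.
    """
    non_dha_lipid = fractions["lipid"] - fractions["dha"]
    if non_dha_lipid < 0:
        raise ValueError("DHA fraction cannot exceed the lipid fraction")
    grams = {
        "prot_c": fractions["protein"],
        "carb_c": fractions["carbohydrate"],
        "tag_c": non_dha_lipid,
        "dha_c": fractions["dha"],
        "rna_c": fractions["rna"],
        "dna_c": fractions["dna"],
    }
    components = {met: 1000.0 * g / MONOMER_MASS[met] for met, g in grams.items()}
    return BiomassComposition(components, dict(fractions))


# ---------------------------------------------------------------------------
# network construction
# ---------------------------------------------------------------------------

# id, name, compartment, n_carbon
_METS = [
    # extracellular
    ("glc_e", "glucose", "e", 6), ("glyc_e", "glycerol", "e", 3),
    ("etoh_e", "ethanol", "e", 2), ("ac_e", "acetate", "e", 2),
    ("o2_e", "oxygen", "e", 0), ("co2_e", "carbon dioxide", "e", 1),
    ("h2o_e", "water", "e", 0), ("h_e", "proton", "e", 0),
    ("nh3_e", "ammonia", "e", 0), ("pi_e", "phosphate", "e", 0),
    ("dha_e", "docosahexaenoate", "e", 22),
    # cytosol: carbon backbone
    ("glc_c", "glucose", "c", 6), ("glyc_c", "glycerol", "c", 3),
    ("etoh_c", "ethanol", "c", 2), ("ac_c", "acetate", "c", 2),
    ("g6p_c", "glucose 6-phosphate", "c", 6), ("f6p_c", "fructose 6-phosphate", "c", 6),
    ("fdp_c", "fructose 1,6-bisphosphate", "c", 6),
    ("dhap_c", "dihydroxyacetone phosphate", "c", 3),
    ("gap_c", "glyceraldehyde 3-phosphate", "c", 3),
    ("bpg13_c", "1,3-bisphosphoglycerate", "c", 3),
    ("pg3_c", "3-phosphoglycerate", "c", 3), ("pg2_c", "2-phosphoglycerate", "c", 3),
    ("pep_c", "phosphoenolpyruvate", "c", 3), ("pyr_c", "pyruvate", "c", 3),
    ("glyc3p_c", "glycerol 3-phosphate", "c", 3),
    ("acald_c", "acetaldehyde", "c", 2), ("cit_c", "citrate", "c", 6),
    ("accoa_c", "acetyl-CoA (acetyl)", "c", 2), ("oaa_c", "oxaloacetate", "c", 4),
    ("mal_c", "malate", "c", 4), ("akg_c", "2-oxoglutarate", "c", 5),
    ("pgl6_c", "6-phosphogluconolactone", "c", 6),
    ("pg6_c", "6-phosphogluconate", "c", 6),
    ("ru5p_c", "ribulose 5-phosphate", "c", 5), ("r5p_c", "ribose 5-phosphate", "c", 5),
    ("x5p_c", "xylulose 5-phosphate", "c", 5),
    ("s7p_c", "sedoheptulose 7-phosphate", "c", 7),
    ("e4p_c", "erythrose 4-phosphate", "c", 4),
    ("acp_c", "acetyl phosphate", "c", 2),
    # cytosol: cofactors & inorganics
    ("atp_c", "ATP", "c", 0), ("adp_c", "ADP", "c", 0),
    ("nad_c", "NAD+", "c", 0), ("nadh_c", "NADH", "c", 0),
    ("nadp_c", "NADP+", "c", 0), ("nadph_c", "NADPH", "c", 0),
    ("pi_c", "phosphate", "c", 0), ("h_c", "proton", "c", 0),
    ("h2o_c", "water", "c", 0), ("o2_c", "oxygen", "c", 0),
    ("co2_c", "carbon dioxide", "c", 1), ("nh3_c", "ammonia", "c", 0),
    # cytosol: lumped biomass building blocks
    ("fa_c", "fatty acyl (C16)", "c", 16),
    ("tag_c", "triacylglycerol", "c", 51),
    ("dha_c", "docosahexaenoate", "c", 22),
    ("prot_c", "protein residue equivalent", "c", 5),
    ("carb_c", "carbohydrate unit", "c", 6),
    ("rna_c", "RNA residue equivalent", "c", 10),
    ("dna_c", "DNA residue equivalent", "c", 10),
    # mitochondria
    ("pyr_m", "pyruvate", "m", 3), ("ac_m", "acetate", "m", 2),
    ("accoa_m", "acetyl-CoA (acetyl)", "m", 2), ("oaa_m", "oxaloacetate", "m", 4),
    ("cit_m", "citrate", "m", 6), ("icit_m", "isocitrate", "m", 6),
    ("akg_m", "2-oxoglutarate", "m", 5), ("succoa_m", "succinyl-CoA (succinyl)", "m", 4),
    ("succ_m", "succinate", "m", 4), ("fum_m", "fumarate", "m", 4),
    ("mal_m", "malate", "m", 4), ("glx_m", "glyoxylate", "m", 2),
    ("atp_m", "ATP", "m", 0), ("adp_m", "ADP", "m", 0),
    ("nad_m", "NAD+", "m", 0), ("nadh_m", "NADH", "m", 0),
    ("nadp_m", "NADP+", "m", 0), ("nadph_m", "NADPH", "m", 0),
    ("fad_m", "FAD", "m", 0), ("fadh2_m", "FADH2", "m", 0),
    ("pi_m", "phosphate", "m", 0), ("h_m", "proton", "m", 0),
    ("h2o_m", "water", "m", 0), ("o2_m", "oxygen", "m", 0),
    ("co2_m", "carbon dioxide", "m", 1),
]

# id, name, equation, transport?  ("->" irreversible, "<=>" reversible)
_RXNS = [
    # exchanges (negative flux = uptake); carbon uptakes closed by default
    ("EX_glc", "glucose exchange", "glc_e <=> ", True),
    ("EX_glyc", "glycerol exchange", "glyc_e <=> ", True),
    ("EX_etoh", "ethanol exchange", "etoh_e <=> ", True),
    ("EX_ac", "acetate exchange", "ac_e <=> ", True),
    ("EX_o2", "oxygen exchange", "o2_e <=> ", True),
    ("EX_co2", "CO2 exchange", "co2_e <=> ", True),
    ("EX_h2o", "water exchange", "h2o_e <=> ", True),
    ("EX_h", "proton exchange", "h_e <=> ", True),
    ("EX_nh3", "ammonia exchange", "nh3_e <=> ", True),
    ("EX_pi", "phosphate exchange", "pi_e <=> ", True),
    ("EX_dha", "DHA overproduction sink", "dha_e -> ", True),
    # plasma-membrane transports
    ("glc_up", "glucose uptake", "glc_e -> glc_c", True),
    ("glyc_up", "glycerol uptake", "glyc_e -> glyc_c", True),
    ("etoh_up", "ethanol uptake", "etoh_e -> etoh_c", True),
    ("ac_up", "acetate uptake", "ac_e -> ac_c", True),
    ("o2t", "oxygen diffusion", "o2_e <=> o2_c", True),
    ("co2t", "CO2 diffusion", "co2_c <=> co2_e", True),
    ("h2ot", "water diffusion", "h2o_e <=> h2o_c", True),
    ("ht", "proton exchange membrane", "h_e <=> h_c", True),
    ("nh3t", "ammonia uptake", "nh3_e <=> nh3_c", True),
    ("pit", "phosphate uptake", "pi_e <=> pi_c", True),
    ("dhat", "DHA export", "dha_c -> dha_e", True),
    # mitochondrial transports / shuttles
    ("pyr_t", "pyruvate carrier", "pyr_c -> pyr_m", True),
    ("cit_t", "citrate export", "cit_m -> cit_c", True),
    ("oaa_t", "oxaloacetate shuttle", "oaa_c -> oaa_m", True),
    ("mal_t", "malate carrier", "mal_c <=> mal_m", True),
    ("akg_t", "2-oxoglutarate carrier", "akg_c <=> akg_m", True),
    ("ac_t", "acetate carrier", "ac_c <=> ac_m", True),
    ("co2_mt", "CO2 diffusion (mito)", "co2_m <=> co2_c", True),
    ("o2_mt", "oxygen diffusion (mito)", "o2_c -> o2_m", True),
    ("h2o_mt", "water diffusion (mito)", "h2o_c <=> h2o_m", True),
    ("h_mt", "proton shuttle (mito)", "h_c <=> h_m", True),
    ("atp_t", "adenine nucleotide translocase",
     "atp_m + adp_c -> atp_c + adp_m", True),
    ("pi_mt", "phosphate carrier (mito)", "pi_c <=> pi_m", True),
    ("nadh_sh", "NADH shuttle (lumped malate-aspartate)",
     "nadh_c + nad_m -> nad_c + nadh_m", True),
    # glycolysis / gluconeogenesis
    ("hk", "hexokinase", "glc_c + atp_c -> g6p_c + adp_c + h_c", False),
    ("pgi", "phosphoglucose isomerase", "g6p_c <=> f6p_c", False),
    ("pfk", "phosphofructokinase", "f6p_c + atp_c -> fdp_c + adp_c + h_c", False),
    ("fbp", "fructose 1,6-bisphosphatase", "fdp_c + h2o_c -> f6p_c + pi_c", False),
    ("ald", "fructose-bisphosphate aldolase", "fdp_c <=> dhap_c + gap_c", False),
    ("tpi", "triosephosphate isomerase", "dhap_c <=> gap_c", False),
    ("gra3pdh", "GAP dehydrogenase",
     "gap_c + nad_c + pi_c <=> bpg13_c + nadh_c + h_c", False),
    ("pgk", "phosphoglycerate kinase", "bpg13_c + adp_c <=> pg3_c + atp_c", False),
    ("pgm", "phosphoglycerate mutase", "pg3_c <=> pg2_c", False),
    ("eno", "enolase", "pg2_c <=> pep_c + h2o_c", False),
    ("pyk", "pyruvate kinase", "pep_c + adp_c + h_c -> pyr_c + atp_c", False),
    ("ppck", "PEP carboxykinase", "oaa_c + atp_c -> pep_c + co2_c + adp_c", False),
    # pentose phosphate pathway
    ("g6pdh", "G6P dehydrogenase", "g6p_c + nadp_c -> pgl6_c + nadph_c + h_c", False),
    ("pgl", "6-phosphogluconolactonase", "pgl6_c + h2o_c -> pg6_c + h_c", False),
    ("gnd", "6-phosphogluconate dehydrogenase",
     "pg6_c + nadp_c -> ru5p_c + co2_c + nadph_c", False),
    ("rpi", "ribose-5-phosphate isomerase", "ru5p_c <=> r5p_c", False),
    ("rpe", "ribulose-phosphate epimerase", "ru5p_c <=> x5p_c", False),
    ("tkt1", "transketolase 1", "x5p_c + r5p_c <=> s7p_c + gap_c", False),
    ("tal", "transaldolase", "s7p_c + gap_c <=> e4p_c + f6p_c", False),
    ("tkt2", "transketolase 2", "x5p_c + e4p_c <=> f6p_c + gap_c", False),
    # glycerol route
    ("pk", "phosphoketolase", "x5p_c + pi_c -> acp_c + gap_c + h2o_c", False),
    ("ack", "acetate kinase", "acp_c + adp_c -> ac_c + atp_c", False),
    ("glk", "glycerol kinase", "glyc_c + atp_c -> glyc3p_c + adp_c + h_c", False),
    ("g3pdh", "glycerol-3-phosphate dehydrogenase",
     "glyc3p_c + nad_c <=> dhap_c + nadh_c + h_c", False),
    # ethanol / acetate routes
    ("adh", "alcohol dehydrogenase", "etoh_c + nad_c <=> acald_c + nadh_c + h_c", False),
    ("aldh", "acetaldehyde dehydrogenase",
     "acald_c + nad_c + h2o_c -> ac_c + nadh_c + 2 h_c", False),
    ("acs", "acetyl-CoA synthetase (cytosolic, lumped 1 ATP)",
     "ac_c + atp_c -> accoa_c + adp_c + pi_c", False),
    ("acalig", "acetate-CoA ligase (mitochondrial, lumped 1 ATP)",
     "ac_m + atp_m -> accoa_m + adp_m + pi_m", False),
    # lipogenic citrate-malate cycle (cytosol)
    ("acl", "ATP-citrate lyase",
     "cit_c + atp_c -> accoa_c + oaa_c + adp_c + pi_c", False),
    ("mdh_c", "malate dehydrogenase (cytosolic)",
     "oaa_c + nadh_c + h_c <=> mal_c + nad_c", False),
    ("mez_c", "NADP-malic enzyme (cytosolic)",
     "mal_c + nadp_c -> pyr_c + co2_c + nadph_c", False),
    # TCA cycle, anaplerosis, glyoxylate shunt (mitochondria)
    ("pdh", "pyruvate dehydrogenase",
     "pyr_m + nad_m -> accoa_m + co2_m + nadh_m", False),
    ("pyc", "pyruvate carboxylase",
     "pyr_m + co2_m + atp_m -> oaa_m + adp_m + pi_m", False),
    ("cs", "citrate synthase", "accoa_m + oaa_m + h2o_m -> cit_m + h_m", False),
    ("aco", "aconitase", "cit_m <=> icit_m", False),
    ("ide", "isocitrate dehydrogenase (NAD)",
     "icit_m + nad_m -> akg_m + co2_m + nadh_m", False),
    ("idp", "isocitrate dehydrogenase (NADP)",
     "icit_m + nadp_m -> akg_m + co2_m + nadph_m", False),
    ("ogdh", "2-oxoglutarate dehydrogenase",
     "akg_m + nad_m -> succoa_m + co2_m + nadh_m", False),
    ("ss", "succinyl-CoA synthetase",
     "succoa_m + adp_m + pi_m <=> succ_m + atp_m", False),
    ("sde", "succinate dehydrogenase", "succ_m + fad_m <=> fum_m + fadh2_m", False),
    ("fuh", "fumarase", "fum_m + h2o_m <=> mal_m", False),
    ("mde", "malate dehydrogenase", "mal_m + nad_m <=> oaa_m + nadh_m + h_m", False),
    ("me", "malic enzyme (NAD)", "mal_m + nad_m -> pyr_m + co2_m + nadh_m", False),
    ("mez", "malic enzyme (NADP)", "mal_m + nadp_m -> pyr_m + co2_m + nadph_m", False),
    ("ps", "pyruvate synthase (reductive acetyl-CoA carboxylation, lumped)",
     "accoa_m + co2_m + nadh_m + h_m -> pyr_m + nad_m + h2o_m", False),
    ("icl", "isocitrate lyase", "icit_m -> succ_m + glx_m", False),
    ("mas", "malate synthase", "glx_m + accoa_m + h2o_m -> mal_m + h_m", False),
    # oxidative phosphorylation & maintenance
    ("nadh_ox", "NADH oxidation (P/O 3)",
     "nadh_m + 0.5 o2_m + 3 adp_m + 3 pi_m + h_m -> nad_m + 3 atp_m + h2o_m",
     False),
    ("fadh_ox", "FADH2 oxidation (P/O 2)",
     "fadh2_m + 0.5 o2_m + 2 adp_m + 2 pi_m -> fad_m + 2 atp_m + h2o_m",
     False),
    ("atp_maint", "ATP hydrolysis (maintenance/surplus)",
     "atp_c + h2o_c -> adp_c + pi_c + h_c", False),
    ("nnt", "transhydrogenase (mito)",
     "nadh_m + nadp_m -> nad_m + nadph_m", False),
    ("nadph_sh", "NADPH shuttle (lumped isocitrate/2-oxoglutarate)",
     "nadph_m + nadp_c -> nadp_m + nadph_c", True),
    # fatty acid, DHA, lumped macromolecule synthesis
    ("fas", "fatty acid synthesis (C16 acyl)",
     "8 accoa_c + 14 nadph_c + 7 atp_c -> fa_c + 14 nadp_c + 7 adp_c + 7 pi_c",
     False),
    ("dha_syn", "DHA synthesis (PKS route, lumped)",
     "11 accoa_c + 10 nadph_c + 9 atp_c -> dha_c + 10 nadp_c + 9 adp_c + 9 pi_c",
     False),
    ("tag_syn", "triacylglycerol assembly",
     "3 fa_c + glyc3p_c + atp_c -> tag_c + adp_c + 2 pi_c", False),
    ("prot_syn", "protein synthesis (lumped)",
     "0.6 pyr_c + 0.35 oaa_c + 0.35 akg_c + 0.05 e4p_c + 1.35 nh3_c "
     "+ atp_c + nadph_c + h2o_c -> prot_c + 0.15 co2_c + adp_c "
     "+ pi_c + nadp_c", False),
    ("carb_syn", "storage carbohydrate synthesis (lumped)",
     "g6p_c + atp_c -> carb_c + adp_c + 2 pi_c", False),
    ("rna_syn", "RNA synthesis (lumped)",
     "r5p_c + oaa_c + co2_c + 3.75 nh3_c + 6 atp_c + nadph_c -> rna_c "
     "+ 6 adp_c + 6 pi_c + nadp_c", False),
    ("dna_syn", "DNA synthesis (lumped)",
     "r5p_c + oaa_c + co2_c + 3.75 nh3_c + 7 atp_c + 2 nadph_c -> dna_c "
     "+ 7 adp_c + 7 pi_c + 2 nadp_c", False),
]

#: substrate name -> (exchange id, uptake transport id)
SUBSTRATE_EXCHANGES = {
    "glucose": ("EX_glc", "glc_up"),
    "glycerol": ("EX_glyc", "glyc_up"),
    "ethanol": ("EX_etoh", "etoh_up"),
    "acetate": ("EX_ac", "ac_up"),
}


@dataclass
class FBASolution:
    fluxes: dict[str, float]
    objective_value: float
    status: str  # optimal | infeasible | unbounded


@dataclass
class DHAScanResult:
    fraction: float
    mu: float
    dha_flux: float            # mmol DHA /gDW/h exported
    pct_carbon_to_dha: float   # % of substrate carbon
    pct_dha_of_tfa: float      # % DHA of total fatty acids (by mass)
    feasible: bool


class StoichModel:
    """Stoichiometric network + biomass/DHA reaction handles + LP matrices."""

    biomass_id = "biomass"
    dha_synthesis_id = "dha_syn"
    dha_sink_id = "EX_dha"

    def __init__(self, network: MetabolicNetwork,
                 composition: BiomassComposition) -> None:
        self.network = network
        self.composition = composition
        self.reaction_ids = list(network.reactions)
        self._index = {r: j for j, r in enumerate(self.reaction_ids)}
        met_ids = list(network.metabolites)
        met_index = {m: i for i, m in enumerate(met_ids)}
        s = np.zeros((len(met_ids), len(self.reaction_ids)))
        for j, rid in enumerate(self.reaction_ids):
            for met, coeff in network.reactions[rid].stoichiometry.items():
                s[met_index[met], j] = coeff
        self.S = s
        self.met_ids = met_ids

    @property
    def biomass_reaction(self) -> Reaction:
        return self.network.reactions[self.biomass_id]

    @property
    def dha_reaction(self) -> Reaction:
        return self.network.reactions[self.dha_sink_id]

    def bounds_vector(self) -> list[tuple[float, float]]:
        return [
            (r.lower_bound, r.upper_bound)
            for r in (self.network.reactions[rid] for rid in self.reaction_ids)
        ]

    def copy(self) -> "StoichModel":
        return StoichModel(self.network.copy(), self.composition)


def build_stoich_model(composition: BiomassComposition | None = None) -> StoichModel:
    """Assemble the reconstruction and its biomass equation.

    All substrate exchanges are closed by default (lower bound 0); CO2 and DHA
    exchanges are efflux-only so the model cannot fix external carbon.
    """
    if composition is None:
        from .synthdata import gen_biomass_composition

        composition = gen_biomass_composition()
    unknown = set(composition.components) - set(MONOMER_MASS)
    if unknown:
        raise KeyError(f"unknown biomass precursors: {sorted(unknown)}")

    comps = [
        Compartment("e", "extracellular", 1.0),
        Compartment("c", "cytosol", 1.0),
        Compartment("m", "mitochondria", 0.01),
    ]
    mets = [Metabolite(i, n, c, None, nc) for i, n, c, nc in _METS]
    rxns = []
    for rid, name, eq, transport in _RXNS:
        stoich, rev = parse_equation(eq)
        lb, ub = (-_BIG, _BIG) if rev else (0.0, _BIG)
        rxns.append(Reaction(rid, name, stoich, reversible=rev,
                             lower_bound=lb, upper_bound=ub,
                             is_transport=transport))
    # biomass equation from the composition
    bm_stoich = {met: -coeff for met, coeff in composition.components.items()}
    bm_stoich.update({"atp_c": bm_stoich.get("atp_c", 0.0) - GAM_ATP,
                      "h2o_c": -GAM_ATP, "adp_c": GAM_ATP, "pi_c": GAM_ATP,
                      "h_c": GAM_ATP})
    rxns.append(Reaction("biomass", "biomass assembly", bm_stoich,
                         reversible=False, lower_bound=0.0, upper_bound=_BIG))

    net = MetabolicNetwork(comps, mets, rxns, id="cohnii_stoich")
    # default exchange policy
    for rid in ("EX_glc", "EX_glyc", "EX_etoh", "EX_ac"):
        net.reactions[rid].lower_bound = 0.0
    net.reactions["EX_co2"].lower_bound = 0.0   # efflux only
    net.reactions["EX_dha"].lower_bound = 0.0
    for rid in ("EX_o2", "EX_h2o", "EX_h", "EX_nh3", "EX_pi"):
        net.reactions[rid].lower_bound = -_BIG
    return StoichModel(net, composition)


# ---------------------------------------------------------------------------
# FBA core
# ---------------------------------------------------------------------------

_LP_OPTIONS = {"presolve": True}


def _linprog(c, A_eq, b_eq, bounds):
    res = linprog(c, A_eq=A_eq, b_eq=b_eq, bounds=bounds, method="highs",
                  options=_LP_OPTIONS)
    return res


def solve_fba(
    model: StoichModel,
    objective_reaction: str = "biomass",
    fixed_bounds: dict[str, tuple[float, float]] | None = None,
    maximize: bool = True,
    parsimonious: bool = False,
) -> FBASolution:
    """Maximize (or minimize) one reaction flux subject to S v = 0 and bounds.

    With ``parsimonious`` the returned flux vector additionally minimizes
    sum |v| at the fixed optimal objective (degenerate optima are otherwise
    solver-dependent); the objective value is identical either way.
    """
    if objective_reaction not in model._index:
        raise KeyError(f"unknown reaction {objective_reaction!r}")
    bounds = model.bounds_vector()
    if fixed_bounds:
        for rid, (lo, hi) in fixed_bounds.items():
            bounds[model._index[rid]] = (lo, hi)
    bounds = [(max(lo, -_BIG * 10), min(hi, _BIG * 10)) for lo, hi in bounds]
    n = len(model.reaction_ids)
    c = np.zeros(n)
    c[model._index[objective_reaction]] = -1.0 if maximize else 1.0
    b_eq = np.zeros(model.S.shape[0])
    res = _linprog(c, model.S, b_eq, bounds)
    if res.status == 2:
        return FBASolution({}, float("nan"), "infeasible")
    if res.status == 3:
        return FBASolution({}, float("inf") if maximize else float("-inf"),
                           "unbounded")
    if res.status != 0:
        return FBASolution({}, float("nan"), "infeasible")
    v = res.x
    obj = float(v[model._index[objective_reaction]])
    if parsimonious:
        # min sum(v+ + v-) with the objective pinned; variables split by sign
        A = np.hstack([model.S, -model.S])
        bounds2 = [(0.0, max(0.0, hi)) for lo, hi in bounds] + \
                  [(0.0, max(0.0, -lo)) for lo, hi in bounds]
        j = model._index[objective_reaction]
        pin = np.zeros(2 * n)
        pin[j], pin[n + j] = 1.0, -1.0
        A_eq = np.vstack([A, pin])
        b_eq2 = np.concatenate([b_eq, [obj]])
        res2 = _linprog(np.ones(2 * n), A_eq, b_eq2, bounds2)
        if res2.status == 0:
            v = res2.x[:n] - res2.x[n:]
    fluxes = dict(zip(model.reaction_ids, v.tolist()))
    return FBASolution(fluxes, obj, "optimal")


def max_growth(model: StoichModel, substrate: str, uptake: float,
               parsimonious: bool = False) -> tuple[float, FBASolution]:
    """Biomass-maximizing solution with only the named substrate's carbon
    uptake open (at the given rate) plus the inorganic exchanges."""
    if substrate not in SUBSTRATE_EXCHANGES:
        raise KeyError(f"unknown substrate {substrate!r}")
    fixed: dict[str, tuple[float, float]] = {}
    for sub, (ex_id, _) in SUBSTRATE_EXCHANGES.items():
        fixed[ex_id] = (-uptake, 0.0) if sub == substrate else (0.0, 0.0)
    sol = solve_fba(model, "biomass", fixed, parsimonious=parsimonious)
    if sol.status != "optimal":
        return 0.0, sol
    return max(sol.objective_value, 0.0), sol


def min_carbon_per_biomass(model: StoichModel, substrate: str,
                           uptake: float = 1.0) -> float:
    """Minimal substrate carbon required per gram of biomass, mmolC1/gDW.

    Computed as n_C * uptake / mu_max at the FBA optimum; the LP is
    homogeneous in the uptake bound, so the ratio is scale-invariant (this is
    asserted against a doubled uptake).
    """
    n_c = carbon_count(substrate)
    mu1, _ = max_growth(model, substrate, uptake)
    if mu1 <= 0:
        raise ValueError(f"no growth on {substrate}")
    mu2, _ = max_growth(model, substrate, 2.0 * uptake)
    r1, r2 = n_c * uptake / mu1, n_c * 2.0 * uptake / mu2
    if abs(r1 - r2) > 1e-6 * r1:
        raise AssertionError(
            f"carbon-per-biomass ratio is not scale-invariant: {r1} vs {r2}"
        )
    return r1


def _tfa_mass_per_gdw(composition: BiomassComposition) -> float:
    """Total fatty acid mass in 1 gDW of biomass (g): the acyl share of the
    generic TAG (3 x C16 acyl, 256.4 g/mol each) plus the DHA share."""
    frac = composition.macromolecule_fractions
    tag_g = frac["lipid"] - frac["dha"]
    acyl_share = 3 * 256.43 / MONOMER_MASS["tag_c"]
    return tag_g * acyl_share + frac["dha"]


def dha_potential_scan(model: StoichModel, substrate: str, uptake: float,
                       biomass_fractions: list[float]) -> list[DHAScanResult]:
    """DHA overproduction at fixed sub-maximal biomass production.

    For each fraction f of mu_max the biomass flux is pinned at f*mu_max and
    the DHA export is maximized.  ``pct_carbon_to_dha`` counts the exported
    (overproduced) DHA against the substrate carbon uptake;
    ``pct_dha_of_tfa`` additionally counts the DHA inside biomass against all
    fatty acids made per unit time.
    """
    if any(not 0 < f <= 1 for f in biomass_fractions):
        raise ValueError("biomass fractions must be in (0, 1]")
    n_c = carbon_count(substrate)
    mu_max, _ = max_growth(model, substrate, uptake)
    if mu_max <= 0:
        raise ValueError(f"no growth on {substrate}")
    fixed: dict[str, tuple[float, float]] = {}
    for sub, (ex_id, _) in SUBSTRATE_EXCHANGES.items():
        fixed[ex_id] = (-uptake, 0.0) if sub == substrate else (0.0, 0.0)
    tfa_biomass = _tfa_mass_per_gdw(model.composition)
    dha_frac = model.composition.macromolecule_fractions["dha"]
    out = []
    for f in biomass_fractions:
        mu = f * mu_max
        fb = dict(fixed)
        fb["biomass"] = (mu, mu)
        sol = solve_fba(model, model.dha_sink_id, fb)
        if sol.status != "optimal":
            out.append(DHAScanResult(f, mu, float("nan"), float("nan"),
                                     float("nan"), False))
            continue
        v_dha = sol.objective_value
        pct_c = 100.0 * 22.0 * v_dha / (n_c * uptake)
        over_g = v_dha * DHA_MOLAR_MASS / 1000.0      # g DHA /gDW/h
        bio_dha_g = mu * dha_frac
        tfa_g = mu * tfa_biomass + over_g
        pct_tfa = 100.0 * (over_g + bio_dha_g) / tfa_g if tfa_g > 0 else 0.0
        out.append(DHAScanResult(f, mu, v_dha, pct_c, pct_tfa, True))
    return out


# ---------------------------------------------------------------------------
# solution I/O
# ---------------------------------------------------------------------------

def write_solution(solution: FBASolution, flux_path, summary_path=None) -> None:
    with open(flux_path, "w") as fh:
        fh.write("reaction\tflux\n")
        for rid, v in solution.fluxes.items():
            fh.write(f"{rid}\t{v:.10g}\n")
    if summary_path is not None:
        with open(summary_path, "w") as fh:
            json.dump({"objective": solution.objective_value,
                       "status": solution.status}, fh, indent=1)
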